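"""Attribute utilities and the discrete-choice adoption probability.

Each production system's total utility is the sum of the utilities of its
attributes: grain and biomass terms are linear in yield (marginal utility per
kg, from stated-preference choice experiments), while the perennial system
additionally carries fixed soil-fertility and labor-savings attributes.  The
probability that a farmer prefers the perennial system is the binary logit

    Pa = exp(U_p) / (exp(U_p) + exp(U_a)) = logistic(U_p - U_a),

which represents population heterogeneity in costs and benefits around the
mean utilities.  The ratio ``U_p / U_a`` ("relative performance") drives the
skill-transfer and disappointment dynamics elsewhere; both the difference and
the ratio are carried here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError
from .production import YieldBundle

__all__ = [
    "UtilityCoefficients",
    "SystemUtilities",
    "system_utility",
    "adoption_probability",
    "evaluate_systems",
    "update_histories",
]

HISTORY_LENGTH = 3


@dataclass(frozen=True)
class UtilityCoefficients:
    """Marginal utilities per kg plus the perennial-only attribute utilities.

    ``u_soil`` and ``u_labor`` may be negative (a net disamenity), which the
    utility-shock scenario requires; the per-kg marginal utilities must be
    non-negative (more grain or biomass is never worse).
    """

    mu_maize: float
    mu_pigeonpea: float
    mu_biomass: float
    u_soil: float = 0.0
    u_labor: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_maize", "mu_pigeonpea", "mu_biomass"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")


def system_utility(coeffs: UtilityCoefficients, bundle: YieldBundle, system: str) -> float:
    """Total utility of one system for one season's production.

    Strictly additive and linear in yields.  For a grazed perennial system the
    pigeonpea grain and biomass yields are already zero in the bundle and the
    soil-fertility attribute is suppressed (no standing biomass decomposes
    into the soil); labor savings remain.
    """
    if system == "annual":
        return (
            coeffs.mu_maize * bundle.maize_annual
            + coeffs.mu_pigeonpea * bundle.pigeonpea_annual
            + coeffs.mu_biomass * bundle.biomass_annual
        )
    if system == "perennial":
        total = (
            coeffs.mu_maize * bundle.maize_perennial
            + coeffs.mu_pigeonpea * bundle.pigeonpea_perennial
            + coeffs.mu_biomass * bundle.biomass_perennial
            + coeffs.u_labor
        )
        if not bundle.grazed:
            total += coeffs.u_soil
        return total
    raise ConfigurationError(f"system must be 'annual' or 'perennial', got {system!r}")


def adoption_probability(U_p: float, U_a: float) -> float:
    """Binary logit choice probability of the perennial system.

    Numerically stable formulation of ``exp(U_p) / (exp(U_p) + exp(U_a))``;
    valid for utility differences up to about +-700.
    """
    if not (math.isfinite(U_p) and math.isfinite(U_a)):
        raise ConfigurationError(f"utilities must be finite, got U_p={U_p}, U_a={U_a}")
    diff = U_p - U_a
    if diff >= 0:
        return 1.0 / (1.0 + math.exp(-diff))
    e = math.exp(diff)
    return e / (1.0 + e)


@dataclass(frozen=True)
class SystemUtilities:
    """One season's utilities, choice probability, and rolling histories.

    Histories hold at most the last three entries; averages over fewer entries
    are used in the first two years.
    """

    U_a: float
    U_p: float
    Pa: float
    Pa_history: tuple[float, ...] = field(default=())
    rel_history: tuple[float, ...] = field(default=())

    @property
    def rel_diff(self) -> float:
        return self.U_p - self.U_a

    @property
    def rel_ratio(self) -> float:
        """Relative performance U_p/U_a; mapped to 1 + (U_p - U_a) if U_a <= 0."""
        if self.U_a > 0:
            return self.U_p / self.U_a
        return 1.0 + self.rel_diff

    @property
    def Pa_avg3(self) -> float:
        """Three-year average adoption probability (fewer entries early on)."""
        if not self.Pa_history:
            return self.Pa
        return sum(self.Pa_history) / len(self.Pa_history)

    @property
    def performance_ratio(self) -> float:
        """This year's relative performance over last year's; 1.0 in year one."""
        if len(self.rel_history) < 2:
            return 1.0
        prev = self.rel_history[-2]
        if prev <= 0:
            return 1.0
        return self.rel_history[-1] / prev


def evaluate_systems(
    coeffs: UtilityCoefficients,
    bundle: YieldBundle,
    previous: SystemUtilities | None = None,
    utility_shift: float = 0.0,
) -> SystemUtilities:
    """Evaluate both systems for one season and roll the histories forward.

    ``utility_shift`` is added to the perennial utility (the permanent-shock
    scenario rescales the perennial system's attribute utilities by a constant).
    """
    U_a = system_utility(coeffs, bundle, "annual")
    U_p = system_utility(coeffs, bundle, "perennial") + utility_shift
    Pa = adoption_probability(U_p, U_a)
    current = SystemUtilities(U_a=U_a, U_p=U_p, Pa=Pa)
    return update_histories(previous, Pa, current.rel_ratio, base=current)


def update_histories(
    utilities: SystemUtilities | None,
    new_Pa: float,
    new_rel: float,
    base: SystemUtilities | None = None,
) -> SystemUtilities:
    """Append to the rolling three-entry windows, returning a new record."""
    prev_pa = utilities.Pa_history if utilities is not None else ()
    prev_rel = utilities.rel_history if utilities is not None else ()
    if base is None:
        base = utilities if utilities is not None else SystemUtilities(0.0, 0.0, new_Pa)
    return SystemUtilities(
        U_a=base.U_a,
        U_p=base.U_p,
        Pa=new_Pa,
        Pa_history=(prev_pa + (new_Pa,))[-HISTORY_LENGTH:],
        rel_history=(prev_rel + (new_rel,))[-HISTORY_LENGTH:],
    )
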