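"""Synthetic inputs standing in for the study's external data sources.

Two external inputs drive the model and are not derivable from first
principles: a crop-model-driven distribution of season quality (historic
1980--2006 rainfall run through a process-based crop simulator) and the
marginal-utility coefficients estimated from farmer choice experiments.
Neither raw source is available, so this module generates calibrated
synthetic equivalents:

* ``make_season_series`` draws i.i.d. season-quality indices from the
  rescaled beta distribution (support [0.2, 1.6], mean 1 under defaults);
* ``calibrate_coefficients`` produces a marginal-utility set whose
  perennial-minus-annual utility difference at the average-yield anchor
  equals a target (1.2 for the baseline) exactly.

The calibration splits the annual system's total utility (the ``base_utility``
scale) across maize grain, pigeonpea grain and woody biomass by configurable
shares, then assigns the perennial-only surplus (whatever the ratoon effect on
yields does not already provide) to the soil-fertility and labor-savings
attributes by a configurable split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError, ConfigurationError
from .preferences import UtilityCoefficients, evaluate_systems
from .production import (
    Envelopes,
    RatoonAnchors,
    SeasonModel,
    YieldEnvelope,
    apply_grazing,
    perennial_yields,
    sample_annual_yields,
)

__all__ = [
    "SeasonSeries",
    "CoefficientFixture",
    "make_season_series",
    "calibrate_coefficients",
    "fixture_config",
    "FIXTURE_NAMES",
]

#: Default allocation of annual-system utility across (maize, pigeonpea grain,
#: woody biomass).  Maize is valued more per kg than pigeonpea grain (ratio
#: ~1.55 with the default averages), while the pigeonpea-linked attributes
#: jointly dominate the season response, so that wetter-than-average seasons
#: suppress the perennial system's relative advantage.
DEFAULT_ATTRIBUTE_SHARES = (0.45, 0.03, 0.52)

#: Total annual-system utility at the calibration anchor.  Sets how strongly
#: a season swing moves the relative-performance ratio U_p/U_a, and therefore
#: how often the disappointment mechanism fires in stochastic runs.
DEFAULT_BASE_UTILITY = 3.0

DEFAULT_EXTRAS_SPLIT = (0.6, 0.4)


@dataclass(frozen=True)
class SeasonSeries:
    """An ordered draw of season quality indices with its generator settings."""

    values: tuple[float, ...]
    model: SeasonModel
    seed: int

    def __post_init__(self) -> None:
        for v in self.values:
            if not self.model.support_low <= v <= self.model.support_high:
                raise ConfigurationError(f"season index {v} outside support")


def make_season_series(
    n_years: int,
    season_model: SeasonModel | None = None,
    seed: int = 0,
) -> SeasonSeries:
    """Draw ``n_years`` i.i.d. season indices; deterministic per seed."""
    if n_years < 1:
        raise ConfigurationError(f"n_years must be >= 1, got {n_years}")
    model = season_model or SeasonModel()
    rng = np.random.default_rng(seed)
    values = tuple(float(v) for v in model.sample(rng, size=n_years))
    return SeasonSeries(values=values, model=model, seed=seed)


@dataclass(frozen=True)
class CoefficientFixture:
    """A calibrated coefficient set and the difference it achieves."""

    coefficients: UtilityCoefficients
    target_rel_diff: float
    achieved_rel_diff: float

    def __post_init__(self) -> None:
        if abs(self.achieved_rel_diff - self.target_rel_diff) >= 1e-9:
            raise CalibrationError(
                f"calibration off target: achieved {self.achieved_rel_diff}, "
                f"target {self.target_rel_diff}"
            )


def _calibration_bundle(average_yields, biomass_ratio, anchors, grazing=False):
    envelopes = Envelopes(
        maize=YieldEnvelope("maize", average_yields[0], width=0.0),
        pigeonpea=YieldEnvelope("pigeonpea", average_yields[1], width=0.0),
        biomass_ratio=biomass_ratio,
    )
    bundle = sample_annual_yields(None, 1.0, envelopes)
    bundle = perennial_yields(bundle, 1.0, anchors, cycle_average=True)
    return apply_grazing(bundle, grazing)


def calibrate_coefficients(
    target_rel_diff: float = 1.2,
    average_yields: tuple[float, float] = (2800.0, 289.0),
    extras_split: tuple[float, float] = DEFAULT_EXTRAS_SPLIT,
    base_utility: float = DEFAULT_BASE_UTILITY,
    attribute_shares: tuple[float, float, float] = DEFAULT_ATTRIBUTE_SHARES,
    biomass_ratio: float = 3.0,
    anchors: RatoonAnchors | None = None,
) -> CoefficientFixture:
    """Build a coefficient set achieving an exact utility difference at the anchor.

    The anchor point is a normal season (index 1) at the given average yields
    with the three-year cycle-average ratoon effect.  The marginal utilities
    are fixed by the attribute shares of ``base_utility``; whatever part of
    ``target_rel_diff`` the yield terms do not provide is assigned to the
    soil-fertility and labor-savings attributes via ``extras_split``.  The
    extras may come out negative (a net disamenity) for low or negative
    targets, as the utility-shock scenario requires.
    """
    maize_avg, pp_avg = average_yields
    if maize_avg <= 0 or pp_avg <= 0:
        raise CalibrationError(f"average yields must be positive, got {average_yields}")
    if min(extras_split) < 0 or abs(sum(extras_split) - 1.0) > 1e-12:
        raise CalibrationError(f"extras_split must be non-negative and sum to 1, got {extras_split}")
    if min(attribute_shares) < 0 or abs(sum(attribute_shares) - 1.0) > 1e-12:
        raise CalibrationError(
            f"attribute_shares must be non-negative and sum to 1, got {attribute_shares}"
        )
    if base_utility <= 0:
        raise CalibrationError(f"base_utility must be positive, got {base_utility}")
    if biomass_ratio <= 0:
        raise CalibrationError(f"biomass_ratio must be positive, got {biomass_ratio}")
    anchors = anchors or RatoonAnchors()

    w_maize, w_pp, w_bio = attribute_shares
    mu_maize = w_maize * base_utility / maize_avg
    mu_pigeonpea = w_pp * base_utility / pp_avg
    mu_biomass = w_bio * base_utility / (pp_avg * biomass_ratio)

    bundle = _calibration_bundle(average_yields, biomass_ratio, anchors)
    probe = UtilityCoefficients(mu_maize, mu_pigeonpea, mu_biomass)
    yield_diff = evaluate_systems(probe, bundle).rel_diff
    extras = target_rel_diff - yield_diff
    coeffs = UtilityCoefficients(
        mu_maize=mu_maize,
        mu_pigeonpea=mu_pigeonpea,
        mu_biomass=mu_biomass,
        u_soil=extras * extras_split[0],
        u_labor=extras * extras_split[1],
    )
    achieved = evaluate_systems(coeffs, bundle).rel_diff
    return CoefficientFixture(
        coefficients=coeffs,
        target_rel_diff=target_rel_diff,
        achieved_rel_diff=achieved,
    )


FIXTURE_NAMES = (
    "baseline",
    "stochastic",
    "grazing",
    "shock",
    "conformity",
    "conformity_low_risk_aversion",
    "maize_sweep",
    "season_sweep",
    "tipping_scan",
)

#: Default sweep grids used by the named sweep/scan fixtures.
SWEEP_GRIDS = {
    "maize_sweep": ("maize_average", (1400.0, 2100.0, 2800.0, 3500.0, 4200.0)),
    "season_sweep": ("fixed_season_index", (0.4, 0.6, 0.8, 1.0, 1.2, 1.4, 1.6)),
    "tipping_scan": (1.0, 2.0),
}


def fixture_config(name: str):
    """Return the fully specified named scenario configuration.

    Sweep/scan names return the base configuration the sweep runs from; the
    grids live in :data:`SWEEP_GRIDS`.
    """
    from .scenarios import ScenarioConfig  # deferred: scenarios imports this module

    if name not in FIXTURE_NAMES:
        raise ConfigurationError(
            f"unknown scenario {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    if name == "baseline":
        return ScenarioConfig()
    if name == "stochastic":
        return ScenarioConfig(stochastic=True)
    if name == "grazing":
        return ScenarioConfig(grazing=True)
    if name == "shock":
        return ScenarioConfig(shock=(10, -1.0))
    if name == "conformity":
        return ScenarioConfig(stochastic=True, conformity_multiplier=2.0)
    if name == "conformity_low_risk_aversion":
        return ScenarioConfig(
            stochastic=True, conformity_multiplier=2.0, risk_aversion_off=True
        )
    if name == "maize_sweep" or name == "season_sweep":
        return ScenarioConfig()
    # tipping_scan
    return ScenarioConfig(stochastic=True, n_iterations=200)
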