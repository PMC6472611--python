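"""Full simulation runs, Monte-Carlo ensembles, sweeps and the tipping-point scan.

A :class:`ScenarioConfig` fully describes one experiment: the production
environment (crop averages, season distribution, ratoon anchors), the
preference calibration, the behavioral parameters, and the scenario switches
(stochasticity, grazing, utility shock, conformity multiplier, reduced risk
aversion).  :func:`run_simulation` produces a :class:`Trajectory` (per-year
records); :func:`run_ensemble` repeats the run with independent streams and
summarises the adopter share as per-year mean/min/max.

All simulations default to 1000 households deciding annually over 25 years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .diffusion import BehavioralParams, BeliefState, FlowRecord, PopulationState, step
from .errors import ConfigurationError
from .preferences import SystemUtilities, evaluate_systems
from .production import (
    SUPPORT,
    Envelopes,
    RatoonAnchors,
    SeasonModel,
    YieldEnvelope,
    apply_grazing,
    perennial_yields,
    sample_annual_yields,
    sample_season_index,
)
from .synthetic import (
    DEFAULT_ATTRIBUTE_SHARES,
    DEFAULT_BASE_UTILITY,
    DEFAULT_EXTRAS_SPLIT,
    calibrate_coefficients,
)

__all__ = [
    "ProductionParams",
    "PreferenceParams",
    "ScenarioConfig",
    "Trajectory",
    "EnsembleSummary",
    "run_simulation",
    "run_ensemble",
    "apply_shock",
    "sweep",
    "tipping_point_scan",
]


@dataclass(frozen=True)
class ProductionParams:
    """Production-side knobs: season distribution, envelopes, ratoon anchors."""

    season_alpha: float = 4.0
    season_beta: float = 3.0
    envelope_width: float = 0.15
    biomass_ratio: float = 3.0
    maize_anchors: tuple[float, float, float] = (0.80, 0.95, 1.10)
    pigeonpea_anchors: tuple[float, float, float] = (1.30, 1.10, 0.90)

    def season_model(self) -> SeasonModel:
        return SeasonModel(alpha=self.season_alpha, beta=self.season_beta)

    def anchors(self) -> RatoonAnchors:
        return RatoonAnchors(maize=self.maize_anchors, pigeonpea=self.pigeonpea_anchors)


@dataclass(frozen=True)
class PreferenceParams:
    """Preference calibration: the baseline utility gap and its decomposition.

    Calibration is anchored at fixed reference yields (the study-area
    averages) so that scenario sweeps over the production environment change
    the environment, not the farmers' preferences.
    """

    target_rel_diff: float = 1.2
    base_utility: float = DEFAULT_BASE_UTILITY
    attribute_shares: tuple[float, float, float] = DEFAULT_ATTRIBUTE_SHARES
    extras_split: tuple[float, float] = DEFAULT_EXTRAS_SPLIT
    calibration_yields: tuple[float, float] = (2800.0, 289.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """One experiment, fully specified."""

    horizon: int = 25
    population: float = 1000.0
    stochastic: bool = False
    fixed_season_index: float = 1.0
    maize_average: float = 2800.0
    pigeonpea_average: float = 289.0
    grazing: bool = False
    pigeonpea_utility_multiplier: float = 1.0
    shock: tuple[int, float] | None = None
    conformity_multiplier: float = 1.0
    risk_aversion_off: bool = False
    n_iterations: int = 1000
    master_seed: int = 0
    production: ProductionParams = field(default_factory=ProductionParams)
    preferences: PreferenceParams = field(default_factory=PreferenceParams)
    behavior: BehavioralParams = field(default_factory=BehavioralParams)

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ConfigurationError(f"horizon must be >= 1, got {self.horizon}")
        if self.population < 1:
            raise ConfigurationError(f"population must be >= 1, got {self.population}")
        if self.n_iterations < 1:
            raise ConfigurationError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if not SUPPORT[0] <= self.fixed_season_index <= SUPPORT[1]:
            raise ConfigurationError(
                f"fixed_season_index must lie in {SUPPORT}, got {self.fixed_season_index}"
            )
        for name in ("maize_average", "pigeonpea_average"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("pigeonpea_utility_multiplier", "conformity_multiplier"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.shock is not None:
            year, _ = self.shock
            if not 1 <= year <= self.horizon:
                raise ConfigurationError(
                    f"shock year must lie within the horizon 1..{self.horizon}, got {year}"
                )

    # -- derived model components -------------------------------------------------

    def envelopes(self) -> Envelopes:
        width = 0.0 if not self.stochastic else self.production.envelope_width
        return Envelopes(
            maize=YieldEnvelope("maize", self.maize_average, width=width),
            pigeonpea=YieldEnvelope("pigeonpea", self.pigeonpea_average, width=width),
            biomass_ratio=self.production.biomass_ratio,
        )

    def coefficients(self):
        fixture = calibrate_coefficients(
            target_rel_diff=self.preferences.target_rel_diff,
            average_yields=self.preferences.calibration_yields,
            extras_split=self.preferences.extras_split,
            base_utility=self.preferences.base_utility,
            attribute_shares=self.preferences.attribute_shares,
            biomass_ratio=self.production.biomass_ratio,
            anchors=self.production.anchors(),
        )
        coeffs = fixture.coefficients
        if self.pigeonpea_utility_multiplier != 1.0:
            coeffs = dataclasses.replace(
                coeffs, mu_pigeonpea=coeffs.mu_pigeonpea * self.pigeonpea_utility_multiplier
            )
        return coeffs

    def effective_behavior(self) -> BehavioralParams:
        params = self.behavior
        if self.conformity_multiplier != 1.0:
            params = params.with_conformity_multiplier(self.conformity_multiplier)
        if self.risk_aversion_off:
            params = dataclasses.replace(params, willingness_low=params.willingness_high)
        return params


@dataclass(frozen=True)
class Trajectory:
    """Per-year records of one simulation run."""

    frame: pd.DataFrame
    config: ScenarioConfig

    @property
    def adopter_share(self) -> np.ndarray:
        return self.frame["adopter_share"].to_numpy()

    @property
    def final_share(self) -> float:
        return float(self.frame["adopter_share"].iloc[-1])

    def years_to_share(self, share: float) -> int | None:
        """First year the adopter share reaches ``share``, or None if never."""
        hit = self.frame.loc[self.frame["adopter_share"] >= share, "year"]
        return int(hit.iloc[0]) if len(hit) else None

    def plot(self, ax=None):
        """Convenience adoption-curve plot (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.frame["year"], self.frame["adopter_share"])
        ax.set_xlabel("year")
        ax.set_ylabel("adopter share")
        ax.set_ylim(0, 1)
        return ax


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-year mean/min/max adopter share across ensemble iterations."""

    frame: pd.DataFrame
    n_iterations: int
    master_seed: int

    @property
    def mean_final_share(self) -> float:
        return float(self.frame["mean"].iloc[-1])


def apply_shock(
    config: ScenarioConfig, utilities: SystemUtilities, year: int
) -> SystemUtilities:
    """Impose the permanent utility shift from the shock year onward.

    The perennial system's attribute utilities are rescaled so that the
    constant-yield utility difference equals the shock value; implemented as
    a constant shift of U_p by (shock value - baseline target).
    """
    if config.shock is None or year < config.shock[0]:
        return utilities
    shift = config.shock[1] - config.preferences.target_rel_diff
    U_p = utilities.U_p + shift
    from .preferences import adoption_probability

    Pa = adoption_probability(U_p, utilities.U_a)
    shocked = SystemUtilities(U_a=utilities.U_a, U_p=U_p, Pa=Pa)
    return shocked


def _utility_shift(config: ScenarioConfig, year: int) -> float:
    if config.shock is None or year < config.shock[0]:
        return 0.0
    return config.shock[1] - config.preferences.target_rel_diff


def run_simulation(
    config: ScenarioConfig, rng: np.random.Generator | None = None
) -> Trajectory:
    """Run one scenario over the full horizon.

    Deterministic given the config and master seed.  Non-stochastic runs use
    the fixed season index and envelope-midpoint (average) yields.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.master_seed))
    season_model = config.production.season_model()
    anchors = config.production.anchors()
    envelopes = config.envelopes()
    coeffs = config.coefficients()
    params = config.effective_behavior()

    state = PopulationState(X=config.population, N=config.population, A=0.0, D=0.0)
    belief = BeliefState()
    utilities: SystemUtilities | None = None

    records: list[dict[str, Any]] = []
    for year in range(1, config.horizon + 1):
        if config.stochastic:
            season = sample_season_index(rng, season_model)
            bundle = sample_annual_yields(rng, season, envelopes)
        else:
            season = config.fixed_season_index
            bundle = sample_annual_yields(None, season, envelopes)
        bundle = perennial_yields(bundle, season, anchors, cycle_average=True)
        bundle = apply_grazing(bundle, config.grazing)

        utilities = evaluate_systems(
            coeffs, bundle, previous=utilities, utility_shift=_utility_shift(config, year)
        )
        state, belief, flows = step(state, belief, utilities, params)

        records.append(
            {
                "year": year,
                "season_index": season,
                "maize_annual": bundle.maize_annual,
                "pigeonpea_annual": bundle.pigeonpea_annual,
                "biomass_annual": bundle.biomass_annual,
                "maize_perennial": bundle.maize_perennial,
                "pigeonpea_perennial": bundle.pigeonpea_perennial,
                "biomass_perennial": bundle.biomass_perennial,
                "U_a": utilities.U_a,
                "U_p": utilities.U_p,
                "rel_diff": utilities.rel_diff,
                "Pa": utilities.Pa,
                "Pa_avg3": utilities.Pa_avg3,
                "N": state.N,
                "A": state.A,
                "D": state.D,
                "adopter_share": state.adopter_share,
                "T": belief.T,
                "L": belief.L,
                "C": belief.C,
                "promoted": flows.promoted,
                "adopted": flows.adopted,
                "disadopted": flows.disadopted,
                "readopted": flows.readopted,
                "seed_cap": flows.seed_cap,
            }
        )
    return Trajectory(frame=pd.DataFrame.from_records(records), config=config)


def _iteration_rng(master_seed: int, iteration: int) -> np.random.Generator:
    # Seeding is order-independent: each iteration owns an independent stream.
    return np.random.default_rng(np.random.SeedSequence((master_seed, iteration)))


def run_ensemble(config: ScenarioConfig, n_iterations: int | None = None) -> EnsembleSummary:
    """Monte-Carlo ensemble: independent runs summarised per year.

    Reports the mean, min and max adopter share for each year across
    iterations; bit-identical for identical (config, master seed).
    """
    n = n_iterations if n_iterations is not None else config.n_iterations
    if n < 1:
        raise ConfigurationError(f"n_iterations must be >= 1, got {n}")
    shares = np.empty((n, config.horizon))
    for i in range(n):
        traj = run_simulation(config, rng=_iteration_rng(config.master_seed, i))
        shares[i] = traj.adopter_share
    frame = pd.DataFrame(
        {
            "year": np.arange(1, config.horizon + 1),
            "mean": shares.mean(axis=0),
            "min": shares.min(axis=0),
            "max": shares.max(axis=0),
        }
    )
    return EnsembleSummary(frame=frame, n_iterations=n, master_seed=config.master_seed)


def _replace_path(config: ScenarioConfig, factor: str, value: Any) -> ScenarioConfig:
    """Return a config with the (possibly nested) ``factor`` path replaced."""
    parts = factor.split(".")
    if len(parts) == 1:
        if parts[0] not in {f.name for f in dataclasses.fields(ScenarioConfig)}:
            raise ConfigurationError(f"unknown factor path {factor!r}")
        return dataclasses.replace(config, **{parts[0]: value})
    if len(parts) == 2:
        section_name, key = parts
        if section_name not in ("production", "preferences", "behavior"):
            raise ConfigurationError(f"unknown factor path {factor!r}")
        section = getattr(config, section_name)
        if key not in {f.name for f in dataclasses.fields(section)}:
            raise ConfigurationError(f"unknown factor path {factor!r}")
        return dataclasses.replace(
            config, **{section_name: dataclasses.replace(section, **{key: value})}
        )
    raise ConfigurationError(f"unknown factor path {factor!r}")


def sweep(config: ScenarioConfig, factor: str, grid) -> pd.DataFrame:
    """One run (or ensemble, for stochastic configs) per grid point.

    Summarises each point as the first year reaching 50% adoption, the final
    adopter share, and the mean share over the horizon.
    """
    rows = []
    for value in grid:
        point = _replace_path(config, factor, value)
        if point.stochastic and point.n_iterations > 1:
            summary = run_ensemble(point)
            curve = summary.frame["mean"].to_numpy()
        else:
            curve = run_simulation(point).adopter_share
        reached = np.nonzero(curve >= 0.5)[0]
        rows.append(
            {
                "factor": factor,
                "value": value,
                "years_to_50pct": int(reached[0]) + 1 if len(reached) else np.nan,
                "final_share": curve[-1],
                "mean_share": curve.mean(),
            }
        )
    return pd.DataFrame(rows)


def tipping_point_scan(
    config: ScenarioConfig,
    multipliers=(1.0, 2.0),
    n_iterations: int | None = None,
) -> pd.DataFrame:
    """Full-factorial scan over the three social factors.

    Each cell multiplies the conformity pressure (divides I), the disadopter
    communication rate, and the disadopter persuasiveness by its grid value
    and runs an ensemble.  A cell is flagged ``suppressed`` when its mean
    final adopter share falls below half of the all-defaults cell's.
    """
    multipliers = tuple(multipliers)
    if 1.0 not in multipliers or 2.0 not in multipliers:
        raise ConfigurationError("multiplier grid must include 1.0 and 2.0")
    base = config.behavior
    rows = []
    for m_conf in multipliers:
        for m_contacts in multipliers:
            for m_pers in multipliers:
                behavior = dataclasses.replace(
                    base,
                    conformity_I=base.conformity_I / m_conf,
                    disadopter_contacts=base.disadopter_contacts * m_contacts,
                    disadopter_persuasiveness_scale=(
                        base.disadopter_persuasiveness_scale * m_pers
                    ),
                )
                point = dataclasses.replace(config, behavior=behavior)
                summary = run_ensemble(point, n_iterations=n_iterations)
                rows.append(
                    {
                        "conformity_multiplier": m_conf,
                        "contacts_multiplier": m_contacts,
                        "persuasiveness_multiplier": m_pers,
                        "mean_final_share": summary.mean_final_share,
                    }
                )
    table = pd.DataFrame(rows)
    baseline_mask = (
        (table["conformity_multiplier"] == 1.0)
        & (table["contacts_multiplier"] == 1.0)
        & (table["persuasiveness_multiplier"] == 1.0)
    )
    baseline_share = float(table.loc[baseline_mask, "mean_final_share"].iloc[0])
    table["suppressed"] = table["mean_final_share"] < 0.5 * baseline_share
    return table
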