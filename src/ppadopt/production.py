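"""Season quality and crop production for annual and ratooned maize--pigeonpea systems.

The production model has three layers:

1. A *season quality index* ``s`` on ``[0.2, 1.6]``: each season's sole-maize
   yield expressed as a proportion of the long-run average, used as a proxy for
   rainfall-driven growing conditions.  Stochastic runs draw ``s`` from a beta
   distribution rescaled onto that support (defaults give mean exactly 1).
2. *Annual-system yields*: for each crop a linear yield envelope in ``s`` whose
   mean line passes through the configured average at ``s = 1``; stochastic
   yields are uniform between the envelope bounds, deterministic yields sit on
   the mean line.
3. *Perennial-system yields*: the annual yields multiplied by a crop- and
   season-specific ratoon effect.  Ratooning favours pigeonpea in dry seasons
   (deeper roots of the established shrub) and maize in wet seasons; the effect
   is interpolated through anchors at a very dry (0.2), normal (1.0) and very
   wet (1.6) season.  The perennial system runs on a three-year cycle
   (establish, ratoon, ratoon); establishment years produce annual yields.

Woody stem biomass is modelled as proportional to pigeonpea grain.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

SUPPORT = (0.2, 1.6)

__all__ = [
    "SUPPORT",
    "SeasonModel",
    "YieldEnvelope",
    "RatoonAnchors",
    "YieldBundle",
    "sample_season_index",
    "yield_bounds",
    "sample_annual_yields",
    "ratoon_multiplier",
    "cycle_average_multiplier",
    "perennial_yields",
    "apply_grazing",
]


@dataclass(frozen=True)
class SeasonModel:
    """Beta-distributed season quality index rescaled onto a bounded support.

    Defaults (``alpha=4, beta=3`` on ``[0.2, 1.6]``) put the mean at exactly
    ``0.2 + 1.4 * 4/7 = 1.0``, i.e. an average season.
    """

    alpha: float = 4.0
    beta: float = 3.0
    support_low: float = SUPPORT[0]
    support_high: float = SUPPORT[1]

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ConfigurationError(
                f"season beta shapes must be positive, got alpha={self.alpha}, beta={self.beta}"
            )
        if not self.support_low < self.support_high:
            raise ConfigurationError(
                f"season support must satisfy low < high, got [{self.support_low}, {self.support_high}]"
            )

    @property
    def mean(self) -> float:
        """Closed-form mean of the rescaled beta draw."""
        width = self.support_high - self.support_low
        return self.support_low + width * self.alpha / (self.alpha + self.beta)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        draw = rng.beta(self.alpha, self.beta, size=size)
        return self.support_low + (self.support_high - self.support_low) * draw


def sample_season_index(rng: np.random.Generator, season_model: SeasonModel) -> float:
    """Draw one season quality index from the rescaled beta distribution."""
    return float(season_model.sample(rng))


@dataclass(frozen=True)
class YieldEnvelope:
    """Linear-in-season yield band for one crop.

    The mean line is ``season_index * average`` (so it passes through the crop
    average at a normal season) and the band spans ``+-width`` of the mean
    line.  ``width=0`` collapses the band onto the mean line.
    """

    crop: str
    average: float
    width: float = 0.15
    support_low: float = SUPPORT[0]
    support_high: float = SUPPORT[1]

    def __post_init__(self) -> None:
        if self.average < 0:
            raise ConfigurationError(f"{self.crop} average yield must be >= 0, got {self.average}")
        if not 0 <= self.width < 1:
            raise ConfigurationError(f"{self.crop} envelope width must be in [0, 1), got {self.width}")

    def _check(self, season_index: float) -> None:
        if not self.support_low <= season_index <= self.support_high:
            raise ConfigurationError(
                f"season index {season_index} outside support [{self.support_low}, {self.support_high}]"
            )

    def mean_at(self, season_index: float) -> float:
        self._check(season_index)
        return season_index * self.average

    def lower_at(self, season_index: float) -> float:
        return self.mean_at(season_index) * (1.0 - self.width)

    def upper_at(self, season_index: float) -> float:
        return self.mean_at(season_index) * (1.0 + self.width)


def yield_bounds(season_index: float, envelope: YieldEnvelope) -> tuple[float, float]:
    """Lower/upper yield limits (kg/ha) for a crop at a given season quality."""
    return envelope.lower_at(season_index), envelope.upper_at(season_index)


@dataclass(frozen=True)
class RatoonAnchors:
    """Ratoon-effect multipliers at the dry (0.2), normal (1.0) and wet (1.6) anchors.

    Sign pattern from ratooned-intercrop trials: in a dry year the ratooned
    system yields more pigeonpea and less maize than the annual system; in a
    wet year the reverse.
    """

    maize: tuple[float, float, float] = (0.80, 0.95, 1.10)
    pigeonpea: tuple[float, float, float] = (1.30, 1.10, 0.90)

    def __post_init__(self) -> None:
        for crop, (dry, normal, wet) in (("maize", self.maize), ("pigeonpea", self.pigeonpea)):
            if min(dry, normal, wet) <= 0:
                raise ConfigurationError(f"{crop} ratoon multipliers must be positive")
        m_dry, _, m_wet = self.maize
        p_dry, _, p_wet = self.pigeonpea
        if not (m_dry <= 1.0 <= m_wet):
            raise ConfigurationError("maize ratoon anchors must satisfy dry <= 1 <= wet")
        if not (p_dry >= 1.0 >= p_wet):
            raise ConfigurationError("pigeonpea ratoon anchors must satisfy dry >= 1 >= wet")

    def for_crop(self, crop: str) -> tuple[float, float, float]:
        try:
            return {"maize": self.maize, "pigeonpea": self.pigeonpea, "biomass": self.pigeonpea}[crop]
        except KeyError:
            raise ConfigurationError(f"unknown crop {crop!r}") from None


def ratoon_multiplier(crop: str, season_index: float, anchors: RatoonAnchors) -> float:
    """Piecewise-linear ratoon effect through the (0.2, 1.0, 1.6) anchors.

    Clamped to the anchor values outside the support so extrapolation can never
    produce a negative multiplier.
    """
    dry, normal, wet = anchors.for_crop(crop)
    s = float(np.clip(season_index, SUPPORT[0], SUPPORT[1]))
    if s <= 1.0:
        return dry + (s - SUPPORT[0]) / (1.0 - SUPPORT[0]) * (normal - dry)
    return normal + (s - 1.0) / (SUPPORT[1] - 1.0) * (wet - normal)


def cycle_average_multiplier(crop: str, season_index: float, anchors: RatoonAnchors) -> float:
    """Ratoon effect averaged over the three-year perennial cycle.

    Year 1 (establishment) is identical to the annual system; years 2 and 3
    carry the full ratoon effect.  Population-level simulations use this
    average instead of tracking each household's cycle phase.
    """
    return (1.0 + 2.0 * ratoon_multiplier(crop, season_index, anchors)) / 3.0


@dataclass(frozen=True)
class YieldBundle:
    """Per-season yields (kg/ha) for both systems, plus season metadata."""

    maize_annual: float
    pigeonpea_annual: float
    biomass_annual: float
    maize_perennial: float
    pigeonpea_perennial: float
    biomass_perennial: float
    season: float
    perennial_cycle_year: int = 1
    grazed: bool = False

    def __post_init__(self) -> None:
        for name in (
            "maize_annual", "pigeonpea_annual", "biomass_annual",
            "maize_perennial", "pigeonpea_perennial", "biomass_perennial",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class Envelopes:
    """The three crop envelopes used by the annual system."""

    maize: YieldEnvelope = field(default_factory=lambda: YieldEnvelope("maize", 2800.0))
    pigeonpea: YieldEnvelope = field(default_factory=lambda: YieldEnvelope("pigeonpea", 289.0))
    biomass_ratio: float = 3.0  # woody biomass per kg pigeonpea grain

    @property
    def biomass(self) -> YieldEnvelope:
        return YieldEnvelope(
            "biomass", self.pigeonpea.average * self.biomass_ratio, self.pigeonpea.width
        )


def sample_annual_yields(
    rng: np.random.Generator | None,
    season_index: float,
    envelopes: Envelopes,
) -> YieldBundle:
    """Annual-system yields at a given season quality.

    Stochastic mode (``rng`` given) draws maize and pigeonpea independently
    and uniformly between their envelope bounds; biomass follows pigeonpea
    grain at the configured ratio.  Deterministic mode (``rng=None``) returns
    the envelope midpoints exactly.
    """
    lo_m, hi_m = yield_bounds(season_index, envelopes.maize)
    lo_p, hi_p = yield_bounds(season_index, envelopes.pigeonpea)
    if rng is None:
        maize = (lo_m + hi_m) / 2.0
        pigeonpea = (lo_p + hi_p) / 2.0
    else:
        maize = float(rng.uniform(lo_m, hi_m))
        pigeonpea = float(rng.uniform(lo_p, hi_p))
    biomass = pigeonpea * envelopes.biomass_ratio
    return YieldBundle(
        maize_annual=maize,
        pigeonpea_annual=pigeonpea,
        biomass_annual=biomass,
        maize_perennial=maize,
        pigeonpea_perennial=pigeonpea,
        biomass_perennial=biomass,
        season=season_index,
    )


def perennial_yields(
    annual_bundle: YieldBundle,
    season_index: float,
    anchors: RatoonAnchors,
    perennial_cycle_year: int = 2,
    cycle_average: bool = False,
) -> YieldBundle:
    """Apply the ratoon effect to annual yields.

    Cycle year 1 is establishment: perennial yields equal annual yields.
    Cycle years 2-3 multiply each crop by its ratoon effect; woody biomass
    scales with the pigeonpea multiplier.  ``cycle_average=True`` uses the
    three-year mean effect instead (aggregate simulations).
    """
    if perennial_cycle_year not in (1, 2, 3):
        raise ConfigurationError(
            f"perennial_cycle_year must be 1, 2 or 3, got {perennial_cycle_year}"
        )
    if cycle_average:
        m_mult = cycle_average_multiplier("maize", season_index, anchors)
        p_mult = cycle_average_multiplier("pigeonpea", season_index, anchors)
    elif perennial_cycle_year == 1:
        m_mult = p_mult = 1.0
    else:
        m_mult = ratoon_multiplier("maize", season_index, anchors)
        p_mult = ratoon_multiplier("pigeonpea", season_index, anchors)
    return replace(
        annual_bundle,
        maize_perennial=annual_bundle.maize_annual * m_mult,
        pigeonpea_perennial=annual_bundle.pigeonpea_annual * p_mult,
        biomass_perennial=annual_bundle.biomass_annual * p_mult,
        season=season_index,
        perennial_cycle_year=perennial_cycle_year,
    )


def apply_grazing(bundle: YieldBundle, grazing: bool) -> YieldBundle:
    """Dry-season livestock grazing of the standing perennial crop.

    Grazing eliminates the perennial pigeonpea harvest and the woody biomass;
    the ``grazed`` marker additionally suppresses the soil-fertility utility
    attribute downstream.  Maize is harvested before the dry season and is
    unaffected.
    """
    if not grazing:
        return bundle
    return replace(bundle, pigeonpea_perennial=0.0, biomass_perennial=0.0, grazed=True)
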