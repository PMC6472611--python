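"""Annual stock-and-flow update for the three behavioral stocks.

The population is well mixed and split into non-adopters ``N``, adopters ``A``
and disadopters ``D`` (``N + A + D = X`` always).  Two belief stocks shape the
flows: the proportion ``T`` trusting the technology, the proportion ``L``
lacking trust (distrust), and a cumulative count ``C`` of farmers who have
gained the skills and self-efficacy to ratoon.

Flows per year, in evaluation order:

* exogenous promotion  -- an outside program supplies 10 confident, trusting
  farmers per year while adoption is at or below 10%;
* skills/confidence    -- adopters mentor trainees at 0.1..2.0 trainees per
  adopter per year depending on the perennial:annual utility ratio; a
  willingness (risk-aversion) ramp from 40% at parity to 80% at double
  utility converts trainees into confident farmers;
* trust                -- adopters persuade (10 contacts/yr at the three-year
  average adoption probability), non-adopters chat (10 contacts/yr at 1%),
  disadopters discourage (20 contacts/yr at one minus that average); distrust
  fades slowly as peer pressure wears off;
* adoption             -- R = N * (C/X) * T * Pa, capped by the seed supply
  S = 10 + 2 * A_prev and by N;
* disadoption          -- direct (performance disappointment) plus indirect
  (distrust scaled by the conformity divisor I);
* readoption           -- disadopters who regained trust return, resisted by
  conformity pressure toward the disadopting crowd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from .errors import ConfigurationError, InvariantViolationError
from .preferences import SystemUtilities

__all__ = [
    "PopulationState",
    "BeliefState",
    "BehavioralParams",
    "FlowRecord",
    "seed_limit",
    "adoption_flow",
    "disappointment_rate",
    "disadoption_flow",
    "readoption_flow",
    "trust_update",
    "confidence_update",
    "promotion",
    "step",
]

_CONSERVATION_RTOL = 1e-9


def _lininterp(x: float, x0: float, y0: float, x1: float, y1: float) -> float:
    """Linear interpolation clamped to the endpoint values outside [x0, x1]."""
    if x <= x0:
        return y0
    if x >= x1:
        return y1
    return y0 + (x - x0) / (x1 - x0) * (y1 - y0)


@dataclass(frozen=True)
class PopulationState:
    """Continuous-valued behavioral stocks with exact conservation."""

    X: float = 1000.0
    N: float = 1000.0
    A: float = 0.0
    D: float = 0.0

    def __post_init__(self) -> None:
        if min(self.N, self.A, self.D) < 0:
            raise InvariantViolationError(
                f"stocks must be non-negative: N={self.N}, A={self.A}, D={self.D}"
            )
        if abs(self.N + self.A + self.D - self.X) > _CONSERVATION_RTOL * self.X:
            raise InvariantViolationError(
                f"conservation violated: N+A+D={self.N + self.A + self.D} != X={self.X}"
            )

    @property
    def adopter_share(self) -> float:
        return self.A / self.X


@dataclass(frozen=True)
class BeliefState:
    """Trust/distrust proportions and the cumulative skilled-and-confident count."""

    T: float = 0.0
    L: float = 0.0
    C: float = 0.0

    def __post_init__(self) -> None:
        eps = 1e-12
        if not (-eps <= self.T <= 1 + eps and -eps <= self.L <= 1 + eps):
            raise InvariantViolationError(f"T and L must lie in [0, 1]: T={self.T}, L={self.L}")
        if self.T + self.L > 1 + 1e-9:
            raise InvariantViolationError(f"T + L must not exceed 1: T={self.T}, L={self.L}")
        if self.C < 0:
            raise InvariantViolationError(f"C must be >= 0: C={self.C}")


@dataclass(frozen=True)
class BehavioralParams:
    """All behavioral rates and thresholds, with the study's default values.

    ``conformity_I`` is the divisor converting the distrusting proportion into
    an indirect disadoption rate (lower I = stronger pressure to conform).
    ``distrust_fade`` is the yearly proportion of distrust that wears off, and
    ``readoption_conformity`` scales how strongly the conformity pressure of a
    large disadopter crowd resists readoption; both are transfer-law details
    of the trust stocks, exposed as parameters.
    """

    adopter_contacts: float = 10.0
    disadopter_contacts: float = 20.0
    nonadopter_contacts: float = 10.0
    nonadopter_persuasiveness: float = 0.01
    disadopter_persuasiveness_scale: float = 1.0
    conformity_I: float = 20.0
    disappointment_threshold: float = 0.9
    disappointment_max: float = 0.10
    willingness_low: float = 0.40
    willingness_high: float = 0.80
    trainee_rate_low: float = 0.1
    trainee_rate_high: float = 2.0
    promotion_rate: float = 10.0
    promotion_threshold: float = 0.10
    seed_base: float = 10.0
    seed_per_adopter: float = 2.0
    distrust_fade: float = 0.2
    readoption_conformity: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "adopter_contacts", "disadopter_contacts", "nonadopter_contacts",
            "disadopter_persuasiveness_scale", "conformity_I", "disappointment_max",
            "trainee_rate_low", "trainee_rate_high", "promotion_rate",
            "seed_base", "seed_per_adopter", "readoption_conformity",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in (
            "nonadopter_persuasiveness", "disappointment_threshold",
            "willingness_low", "willingness_high", "promotion_threshold", "distrust_fade",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {getattr(self, name)}")
        if self.willingness_low > self.willingness_high:
            raise ConfigurationError("willingness_low must not exceed willingness_high")

    @property
    def social_pressure_index(self) -> float:
        """Product of the three social factors relative to their defaults.

        Equals 1 at the defaults and 8 when conformity pressure, disadopter
        contacts and disadopter persuasiveness are all doubled.
        """
        return (
            (20.0 / self.conformity_I)
            * (self.disadopter_contacts / 20.0)
            * self.disadopter_persuasiveness_scale
        )

    def with_conformity_multiplier(self, m: float) -> "BehavioralParams":
        """Scale the three social factors jointly (the conformity scenario)."""
        if m <= 0:
            raise ConfigurationError(f"conformity multiplier must be > 0, got {m}")
        return replace(
            self,
            conformity_I=self.conformity_I / m,
            disadopter_contacts=self.disadopter_contacts * m,
            disadopter_persuasiveness_scale=self.disadopter_persuasiveness_scale * m,
        )


@dataclass(frozen=True)
class FlowRecord:
    """The flows realised in one annual step (farmers/yr unless noted)."""

    promoted: float = 0.0
    adopted: float = 0.0
    disadopted: float = 0.0
    readopted: float = 0.0
    trainees: float = 0.0
    willingness: float = 0.0
    trust_gain: float = 0.0  # proportion of the population gaining trust
    trust_loss: float = 0.0
    seed_cap: float = 0.0


def seed_limit(A_prev: float, params: BehavioralParams) -> float:
    """Maximum new adopters supported by last year's seed production."""
    if A_prev < 0:
        raise ConfigurationError(f"A_prev must be >= 0, got {A_prev}")
    return params.seed_base + params.seed_per_adopter * A_prev


def adoption_flow(N: float, C: float, T: float, X: float, Pa: float, S: float) -> float:
    """Adoption rate R = N * (C/X) * T * Pa, capped by seed supply and by N."""
    unconstrained = N * (C / X) * T * Pa
    return max(0.0, min(unconstrained, S, N))


def disappointment_rate(perf_ratio: float, params: BehavioralParams | None = None) -> float:
    """Direct disadoption from disappointing year-on-year relative performance.

    Zero while this year's performance (relative to the annual system) is at
    least 90% of last year's, rising linearly to 10% as the ratio falls to 0.
    """
    p = params or BehavioralParams()
    if perf_ratio < 0:
        raise ConfigurationError(f"performance ratio must be >= 0, got {perf_ratio}")
    thr = p.disappointment_threshold
    if perf_ratio >= thr:
        return 0.0
    return p.disappointment_max * (thr - perf_ratio) / thr


def disadoption_flow(
    A: float,
    utilities: SystemUtilities,
    L: float,
    params: BehavioralParams,
) -> float:
    """Total disadoption: direct (performance) plus indirect (distrust/conformity).

    Three exclusive cases on the relative utility:
      (i)  U_p < U_a: one minus the three-year average adoption probability,
           plus the indirect term;
      (ii) U_p >= U_a but relative performance dropped below the threshold:
           the disappointment ramp, plus the indirect term;
      (iii) otherwise: the indirect term alone.
    The indirect term is A * L / I in every case; the result is capped at A.
    """
    indirect = A * L / params.conformity_I
    if utilities.rel_diff < 0:
        direct = A * (1.0 - utilities.Pa_avg3)
    else:
        direct = A * disappointment_rate(utilities.performance_ratio, params)
    return min(A, direct + indirect)


def readoption_flow(
    D: float,
    trust_gain_prop: float,
    params: BehavioralParams | None = None,
    disadopter_share: float = 0.0,
) -> float:
    """Disadopters who regained trust return to adoption.

    The base flow is the proportion of the population that gained trust this
    year times the number of disadopters.  Conformity pressure toward the
    majority resists readoption when the disadopting crowd is large: the flow
    is scaled by ``1 - readoption_conformity * social_pressure_index *
    disadopter_share``, floored at zero.
    """
    if not 0 <= trust_gain_prop <= 1:
        raise ConfigurationError(f"trust_gain_prop must be in [0, 1], got {trust_gain_prop}")
    base = D * trust_gain_prop
    if params is not None:
        resistance = 1.0 - params.readoption_conformity * params.social_pressure_index * disadopter_share
        base *= max(0.0, resistance)
    return min(D, base)


def trust_update(
    belief: BeliefState,
    pop: PopulationState,
    Pa_avg3: float,
    params: BehavioralParams,
) -> tuple[float, float, float]:
    """One year of word-of-mouth trust dynamics.

    Gain pressure comes from adopters (contacts times the three-year average
    adoption probability as persuasiveness) and non-adopter chatter; it
    recruits from the neutral remainder ``1 - T - L``.  Loss pressure comes
    from disadopters (contacts times one minus the average, doubled in the
    conformity scenario) and transfers trust to distrust.  Distrust fades
    toward neutral at ``distrust_fade`` per year as peer pressure wears off.
    Pressures saturate as ``1 - exp(-x)`` so the per-capita persuaded fraction
    stays in [0, 1].

    Returns ``(new_T, new_L, trust_gain_prop)`` where the last element is the
    proportion of the population that gained trust this year (feeds
    readoption).
    """
    gain_pressure = (
        pop.A * params.adopter_contacts * Pa_avg3
        + pop.N * params.nonadopter_contacts * params.nonadopter_persuasiveness
    ) / pop.X
    persuasiveness = min(1.0, params.disadopter_persuasiveness_scale * (1.0 - Pa_avg3))
    loss_pressure = pop.D * params.disadopter_contacts * persuasiveness / pop.X

    g = 1.0 - math.exp(-gain_pressure)
    l = 1.0 - math.exp(-loss_pressure)

    neutral = max(0.0, 1.0 - belief.T - belief.L)
    trust_gain = g * neutral
    trust_loss = l * belief.T
    fade = params.distrust_fade * belief.L

    new_T = min(1.0, belief.T + trust_gain - trust_loss)
    new_L = min(1.0, belief.L + trust_loss - fade)
    return max(0.0, new_T), max(0.0, new_L), trust_gain


def confidence_update(
    C: float,
    A: float,
    X: float,
    rel_measure: float,
    params: BehavioralParams,
) -> tuple[float, float, float]:
    """Skill transfer and the risk-aversion willingness ramp.

    Trainees per adopter ramp linearly from ``trainee_rate_low`` (0.1, i.e.
    ten adopters train one farmer) at utility parity to ``trainee_rate_high``
    (2.0) at double-or-more utility.  Willingness to try ramps from 40% to
    80% over the same range.  Skills and confidence are permanent: C never
    decreases and is capped at X.

    Returns ``(new_C, trainees, willingness)``.
    """
    trainees = A * _lininterp(rel_measure, 1.0, params.trainee_rate_low, 2.0, params.trainee_rate_high)
    willingness = _lininterp(rel_measure, 1.0, params.willingness_low, 2.0, params.willingness_high)
    new_C = min(X, C + trainees * willingness)
    return new_C, trainees, willingness


def promotion(adoption_share: float, params: BehavioralParams) -> float:
    """Exogenous promotion while adoption is at or below the threshold share."""
    if not 0 <= adoption_share <= 1:
        raise ConfigurationError(f"adoption_share must be in [0, 1], got {adoption_share}")
    return params.promotion_rate if adoption_share <= params.promotion_threshold else 0.0


def step(
    state: PopulationState,
    belief: BeliefState,
    utilities: SystemUtilities,
    params: BehavioralParams,
) -> tuple[PopulationState, BeliefState, FlowRecord]:
    """Advance the stocks one year.

    Evaluation order: promotion -> confidence -> trust -> adoption ->
    disadoption -> readoption.  All flows are clamped to the available stock
    so the stocks stay non-negative and conservation is exact; promoted
    farmers bypass the seed constraint (they are externally supplied) but
    their adoption is still gated by the choice probability.
    """
    X = state.X
    N, A, D = state.N, state.A, state.D
    T, L, C = belief.T, belief.L, belief.C
    A_prev = A

    promoted = promotion(state.adopter_share, params)
    promoted_adopting = 0.0
    if promoted > 0:
        C = min(X, C + promoted)
        T = min(1.0 - L, T + promoted / X)
        promoted_adopting = min(N, promoted * utilities.Pa)
        N -= promoted_adopting
        A += promoted_adopting

    C, trainees, willingness = confidence_update(C, A, X, utilities.rel_ratio, params)

    T, L, trust_gain = trust_update(
        BeliefState(T=T, L=L, C=C), PopulationState(X=X, N=N, A=A, D=D),
        utilities.Pa_avg3, params,
    )

    S = seed_limit(A_prev, params)
    adopted = adoption_flow(N, C, T, X, utilities.Pa, S)
    N -= adopted
    A += adopted

    disadopted = disadoption_flow(A, utilities, L, params)
    A -= disadopted
    D += disadopted

    readopted = readoption_flow(D, trust_gain, params, disadopter_share=D / X)
    D -= readopted
    A += readopted

    new_state = PopulationState(X=X, N=N, A=A, D=D)
    new_belief = BeliefState(T=T, L=L, C=C)
    flows = FlowRecord(
        promoted=promoted,
        adopted=adopted + promoted_adopting,
        disadopted=disadopted,
        readopted=readopted,
        trainees=trainees,
        willingness=willingness,
        trust_gain=trust_gain,
        trust_loss=L - belief.L,
        seed_cap=S,
    )
    return new_state, new_belief, flows
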