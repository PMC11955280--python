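"""Multi-state live-encounter / dead-recovery process model.

The ecological process is a discrete-time Markov chain on states that encode
location (subarea 1, subarea 2, outside — or simply inside/outside for a
one-area population) crossed with alive / died-this-interval / dead-before
status.  Mortality is assumed to happen before movement within an interval,
so a carcass can only be recovered in the area the animal occupied at the
start of the interval.  Observation is a categorical emission: an alive
animal is detected with probability ``p`` in its current area, a
died-this-interval animal is recovered with probability ``r``, and the
absorbed "dead before" state is silent.

Annual survival ``S`` acts on the logit scale through sex/age/area intercepts
plus a normal year random effect; the per-interval survival used in the
transition matrix is ``S**(1/K)`` with ``K`` intervals per lynx year (6 for a
2-month grid, 12 for a monthly grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

N_SEXES = 2
N_AGES = 3
SEX_LABELS = ("F", "M")
AGE_LABELS = ("juvenile", "subadult", "adult")

TWO_SUBAREA = "two_subarea"
ONE_AREA = "one_area"


class StateSpace:
    """State and observation-code bookkeeping for one of the two layouts.

    two_subarea (7 states): alive sub1, died sub1, alive sub2, died sub2,
    alive outside, died outside, dead before.
    one_area (5 states): alive inside, alive outside, died inside,
    died outside, dead before.

    Observation codes: 0 = not detected, then alternating
    detected-alive / recovered-dead per area.
    """

    def __init__(self, layout: str):
        if layout not in (TWO_SUBAREA, ONE_AREA):
            raise ValueError(f"unknown layout {layout!r}")
        self.layout = layout
        if layout == TWO_SUBAREA:
            self.n_areas = 3
            self.area_labels = ("sub1", "sub2", "outside")
            self.n_states = 7
            self.dead_before = 6
        else:
            self.n_areas = 2
            self.area_labels = ("inside", "outside")
            self.n_states = 5
            self.dead_before = 4
        self.n_inside = self.n_areas - 1
        self.n_codes = 1 + 2 * self.n_areas

    def alive_state(self, area: int) -> int:
        if self.layout == TWO_SUBAREA:
            return 2 * area
        return area

    def died_state(self, area: int) -> int:
        if self.layout == TWO_SUBAREA:
            return 2 * area + 1
        return self.n_inside + 1 + area

    def code_detected(self, area: int) -> int:
        return 1 + 2 * area

    def code_recovered(self, area: int) -> int:
        return 2 + 2 * area

    def code_name(self, code: int) -> str:
        if code == 0:
            return "not_detected"
        area = (code - 1) // 2
        kind = "detected_alive" if code % 2 == 1 else "recovered_dead"
        return f"{kind}_{self.area_labels[area]}"

    def code_from_name(self, name: str) -> int:
        for c in range(self.n_codes):
            if self.code_name(c) == name:
                return c
        raise ValueError(f"unknown observation code {name!r}")

    def state_of_code(self, code: int) -> int:
        """Latent state implied by a non-zero observation code."""
        if code == 0:
            raise ValueError("'not detected' does not identify a state")
        area = (code - 1) // 2
        return self.alive_state(area) if code % 2 == 1 else self.died_state(area)

    @property
    def alive_states(self) -> list[int]:
        return [self.alive_state(a) for a in range(self.n_areas)]

    @property
    def died_states(self) -> list[int]:
        return [self.died_state(a) for a in range(self.n_areas)]

    def n_movement(self) -> int:
        """Free movement probabilities per sex/age cell."""
        return 4 if self.layout == TWO_SUBAREA else 1


@dataclass
class PriorSpec:
    """Hyperparameters of the weakly-informative priors.

    intercept_sd: SD of the normal prior on logit-scale intercepts.
    coef_sd: SD of the normal prior on covariate coefficients and
        additive area offsets.
    sigma_scale / sigma_df: scale and df of the half-t prior on the
        random-effect standard deviations.
    """

    intercept_sd: float = 1.5
    coef_sd: float = 0.5
    sigma_scale: float = 1.0
    sigma_df: float = 2.0


@dataclass
class ModelSpec:
    """Structural description of one model fit.

    layout: "two_subarea" (7 states) or "one_area" (5 states).
    intervals_per_year: 6 (2-month occasions) or 12 (monthly).
    n_years: number of lynx years spanned by the occasion grid.
    year_effects: normal random lynx-year effect on survival (per subarea
        in the two-subarea layout, per age class in the one-area layout).
    individual_effects: normal random individual effect on detection.
    effort_effects: systematic (systmon) and opportunistic (oppmon)
        monitoring-effort covariates on detection.
    telemetry: distinct detection intercept for occasions with an active
        collar, tied across sex and age.
    fix_telemetry_detection: one-area layout only — detection of collared
        animals fixed to 1.
    sub2_full_predictor: include the oppmon and individual-effect terms in
        subarea 2's detection predictor (on by default).
    estimate_movement: movement/emigration probabilities estimated rather
        than fixed to zero.
    """

    layout: str = TWO_SUBAREA
    intervals_per_year: int = 6
    n_years: int = 10
    year_effects: bool = True
    individual_effects: bool = True
    effort_effects: bool = True
    telemetry: bool = True
    fix_telemetry_detection: bool | None = None
    sub2_full_predictor: bool = True
    estimate_movement: bool = True
    priors: PriorSpec = field(default_factory=PriorSpec)

    def __post_init__(self):
        if self.intervals_per_year not in (6, 12):
            raise ValueError("intervals_per_year must be 6 or 12")
        if self.fix_telemetry_detection is None:
            self.fix_telemetry_detection = self.layout == ONE_AREA
        self.space = StateSpace(self.layout)

    def to_dict(self) -> dict:
        return {
            "layout": self.layout,
            "intervals_per_year": self.intervals_per_year,
            "n_years": self.n_years,
            "year_effects": self.year_effects,
            "individual_effects": self.individual_effects,
            "effort_effects": self.effort_effects,
            "telemetry": self.telemetry,
            "fix_telemetry_detection": self.fix_telemetry_detection,
            "sub2_full_predictor": self.sub2_full_predictor,
            "estimate_movement": self.estimate_movement,
            "priors": vars(self.priors).copy(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        pr = d.pop("priors", None)
        spec = cls(**d)
        if pr:
            spec.priors = PriorSpec(**pr)
        return spec


@dataclass
class ParameterSet:
    """All model parameters on their natural/link scales.

    Shapes (A_in = number of inside subareas, A = A_in + 1 incl. outside):
      b0:        (A_in, 2, 3)   survival intercepts, logit of annual S
      b_out:     float          outside-survival intercept (overall mean)
      sigma_S:   (A_in,) or (3,) year-effect SD (per age in one-area layout)
      gamma:     (groups, n_years) standard-normal year deviates
      a0:        (A, 2, 3, 2)   detection intercepts [area, sex, age, telemetry]
      a1, a2:    float          systmon / oppmon coefficients
      sigma_p:   float          individual-effect SD on detection
      epsilon:   (n_individuals,) standard-normal individual deviates
      d0:        (2, 3)         recovery intercepts [sex, age]
      d_area:    (A,)           additive recovery offsets, d_area[0] == 0
      m:         (2, 3, 4) [m12, m13, m21, m23]  or  (2, 3, 1) [emigration]
      psi:       (2,)           sex mixture (F, M)
    """

    b0: np.ndarray
    b_out: float
    sigma_S: np.ndarray
    gamma: np.ndarray
    a0: np.ndarray
    a1: float
    a2: float
    sigma_p: float
    epsilon: np.ndarray
    d0: np.ndarray
    d_area: np.ndarray
    m: np.ndarray
    psi: np.ndarray

    def a0_constrained(self) -> np.ndarray:
        """Detection intercepts with the telemetry slice tied across sex/age."""
        a0 = np.array(self.a0, dtype=float, copy=True)
        for area in range(a0.shape[0]):
            a0[area, :, :, 1] = a0[area, 0, 0, 1]
        return a0

    @classmethod
    def zeros(cls, spec: ModelSpec, n_individuals: int = 0) -> "ParameterSet":
        A_in = spec.space.n_inside
        A = spec.space.n_areas
        n_groups = N_AGES if spec.layout == ONE_AREA else A_in
        return cls(
            b0=np.zeros((A_in, N_SEXES, N_AGES)),
            b_out=0.0,
            sigma_S=np.zeros(n_groups),
            gamma=np.zeros((n_groups, spec.n_years)),
            a0=np.zeros((A, N_SEXES, N_AGES, 2)),
            a1=0.0,
            a2=0.0,
            sigma_p=0.0,
            epsilon=np.zeros(n_individuals),
            d0=np.zeros((N_SEXES, N_AGES)),
            d_area=np.zeros(A),
            m=np.zeros((N_SEXES, N_AGES, spec.space.n_movement())),
            psi=np.array([0.5, 0.5]),
        )


def interval_survival(S_annual, intervals_per_year: int):
    """Per-interval survival s = S**(1/K) for K intervals per lynx year."""
    S = np.asarray(S_annual, dtype=float)
    if np.any(S < 0) or np.any(S > 1):
        raise ValueError("annual survival must lie in [0, 1]")
    if intervals_per_year not in (6, 12):
        raise ValueError("intervals_per_year must be 6 or 12")
    out = S ** (1.0 / intervals_per_year)
    return float(out) if np.isscalar(S_annual) else out


def annualize(s_interval, intervals_per_year: int):
    """Inverse of :func:`interval_survival`: S = s**K."""
    s = np.asarray(s_interval, dtype=float)
    out = s ** intervals_per_year
    return float(out) if np.isscalar(s_interval) else out


def survival_logit(params: ParameterSet, spec: ModelSpec, area: int,
                   sex: int, age: int, year: int) -> float:
    """Linear predictor for annual survival on the logit scale.

    Outside the study population only an overall mean is used.  In the
    one-area layout the year random effect is age-specific; in the
    two-subarea layout it is subarea-specific.
    """
    if area == spec.space.n_areas - 1:
        return float(params.b_out)
    if spec.layout == ONE_AREA:
        lg = params.b0[0, sex, age]
        if spec.year_effects:
            lg = lg + params.sigma_S[age] * params.gamma[age, year]
    else:
        lg = params.b0[area, sex, age]
        if spec.year_effects:
            lg = lg + params.sigma_S[area] * params.gamma[area, year]
    return float(lg)


def detection_logit(params: ParameterSet, spec: ModelSpec, area: int,
                    sex: int, age: int, telemetry: bool,
                    systmon: float = 0.0, oppmon: float = 1.0,
                    individual: int | None = None) -> float:
    """Linear predictor for per-occasion detection on the logit scale.

    oppmon enters centred at its baseline level 1, so intercepts refer to
    passive opportunistic monitoring.  Returns +inf when the layout fixes
    telemetry detection to certainty.
    """
    tel = int(bool(telemetry))
    if tel and spec.layout == ONE_AREA and spec.fix_telemetry_detection:
        return np.inf
    a0 = params.a0_constrained()
    lg = a0[area, sex, age, tel]
    outside = area == spec.space.n_areas - 1
    if not outside:
        if spec.effort_effects:
            lg = lg + params.a1 * systmon
            if area == 0 or spec.sub2_full_predictor or spec.layout == ONE_AREA:
                lg = lg + params.a2 * (oppmon - 1.0)
        if spec.individual_effects and individual is not None:
            if area == 0 or spec.sub2_full_predictor or spec.layout == ONE_AREA:
                lg = lg + params.sigma_p * params.epsilon[individual]
    return float(lg)


def recovery_logit(params: ParameterSet, spec: ModelSpec, area: int,
                   sex: int, age: int) -> float:
    """Linear predictor for dead-recovery probability on the logit scale."""
    return float(params.d0[sex, age] + params.d_area[area])


def build_transition_matrix(s: Sequence[float], m: Sequence[float],
                            space: StateSpace) -> np.ndarray:
    """Row-stochastic transition matrix for one interval.

    s: per-area interval survival evaluated for the origin state's
       subarea/sex/age/year (length n_areas).
    m: movement probabilities for the relevant sex/age cell —
       (m12, m13, m21, m23) in the 7-state layout, (m_out,) in the
       5-state layout.  Mortality happens before movement, so the
       died-this-interval destination is always the origin area.
    """
    s = np.asarray(s, dtype=float)
    m = np.asarray(m, dtype=float)
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("interval survival must lie in [0, 1]")
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("movement probabilities must lie in [0, 1]")
    S = space.n_states
    T = np.zeros((S, S))
    if space.layout == TWO_SUBAREA:
        m12, m13, m21, m23 = m
        if m12 + m13 > 1 + 1e-12 or m21 + m23 > 1 + 1e-12:
            raise ValueError("movement probabilities from one subarea exceed 1")
        s1, s2, s3 = s
        T[0] = [s1 * (1 - m12 - m13), 1 - s1, s1 * m12, 0.0, s1 * m13, 0.0, 0.0]
        T[2] = [s2 * m21, 0.0, s2 * (1 - m21 - m23), 1 - s2, s2 * m23, 0.0, 0.0]
        T[4] = [0.0, 0.0, 0.0, 0.0, s3, 1 - s3, 0.0]
        for a in range(3):
            T[space.died_state(a), space.dead_before] = 1.0
    else:
        (mo,) = m
        s_in, s_out = s
        T[0] = [s_in * (1 - mo), s_in * mo, 1 - s_in, 0.0, 0.0]
        T[1] = [0.0, s_out, 0.0, 1 - s_out, 0.0]
        for a in range(2):
            T[space.died_state(a), space.dead_before] = 1.0
    T[space.dead_before, space.dead_before] = 1.0
    return T


def build_observation_matrix(p: Sequence[float], r: Sequence[float],
                             space: StateSpace) -> np.ndarray:
    """Row-stochastic emission matrix O (states x observation codes)."""
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(r < 0) or np.any(r > 1):
        raise ValueError("detection and recovery probabilities must lie in [0, 1]")
    O = np.zeros((space.n_states, space.n_codes))
    for a in range(space.n_areas):
        ia = space.alive_state(a)
        O[ia, space.code_detected(a)] = p[a]
        O[ia, 0] = 1 - p[a]
        da = space.died_state(a)
        O[da, space.code_recovered(a)] = r[a]
        O[da, 0] = 1 - r[a]
    O[space.dead_before, 0] = 1.0
    return O


def half_t_logpdf(x, scale: float = 1.0, df: float = 2.0):
    """Log density of the folded (half) t distribution on [0, inf)."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x < 0, -np.inf,
        np.log(2.0) + stats.t.logpdf(x / scale, df) - np.log(scale),
    )
    return float(out) if out.ndim == 0 else out


def _movement_log_prior(m_cell: np.ndarray, space: StateSpace) -> float:
    # Uniform over each constrained pair-simplex {m_a + m_b <= 1}, which has
    # area 1/2, hence density 2 on the support.
    if np.any(m_cell < 0) or np.any(m_cell > 1):
        return -np.inf
    if space.layout == TWO_SUBAREA:
        if m_cell[0] + m_cell[1] > 1 or m_cell[2] + m_cell[3] > 1:
            return -np.inf
        return 2 * np.log(2.0)
    return 0.0  # uniform(0, 1) on the emigration probability


def log_prior(params: ParameterSet, spec: ModelSpec) -> float:
    """Joint log prior density over the active parameter blocks.

    Normal(0, intercept_sd) on intercepts, normal(0, coef_sd) on covariate
    coefficients and area offsets, half-t on the random-effect SDs,
    standard normal on the year and individual deviates, uniform on each
    movement simplex, and a flat Dirichlet on the sex mixture.
    """
    pr = spec.priors
    space = spec.space
    lp = 0.0

    intercepts = [np.ravel(params.b0), [params.b_out], np.ravel(params.d0)]
    intercepts.append(np.ravel(params.a0[:, :, :, 0]))
    if spec.telemetry and not (spec.layout == ONE_AREA
                               and spec.fix_telemetry_detection):
        intercepts.append(params.a0[:, 0, 0, 1])
    vals = np.concatenate([np.asarray(v, dtype=float).ravel() for v in intercepts])
    if not np.all(np.isfinite(vals)):
        return -np.inf
    lp += stats.norm.logpdf(vals, 0.0, pr.intercept_sd).sum()

    coefs = []
    if spec.effort_effects:
        coefs += [params.a1, params.a2]
    if spec.layout == TWO_SUBAREA:
        coefs += list(params.d_area[1:])
    if coefs:
        coefs = np.asarray(coefs, dtype=float)
        if not np.all(np.isfinite(coefs)):
            return -np.inf
        lp += stats.norm.logpdf(coefs, 0.0, pr.coef_sd).sum()

    if spec.year_effects:
        sv = half_t_logpdf(params.sigma_S, pr.sigma_scale, pr.sigma_df)
        if np.any(np.isneginf(sv)):
            return -np.inf
        lp += np.sum(sv)
        lp += stats.norm.logpdf(params.gamma).sum()
    if spec.individual_effects:
        sv = half_t_logpdf(params.sigma_p, pr.sigma_scale, pr.sigma_df)
        if np.isneginf(sv):
            return -np.inf
        lp += sv
        lp += stats.norm.logpdf(params.epsilon).sum()

    if spec.estimate_movement:
        for sex in range(N_SEXES):
            for age in range(N_AGES):
                v = _movement_log_prior(params.m[sex, age], space)
                if np.isneginf(v):
                    return -np.inf
                lp += v

    psi = np.asarray(params.psi, dtype=float)
    if np.any(psi < 0) or abs(psi.sum() - 1.0) > 1e-9:
        return -np.inf
    # flat Dirichlet(1, 1): density Gamma(2)/Gamma(1)^2 = 1 on the simplex
    return float(lp)


def natural_survival(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Annual survival probabilities at gamma = 0, shape (A_in, 2, 3)."""
    return expit(params.b0)
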