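"""Marginalized (forward-algorithm) likelihood of encounter histories.

The latent state sequence is never sampled: conditioning on the observed
state at first capture, the likelihood of the subsequent observations is
computed by alternating transition and emission steps with per-occasion
normalization accumulated in log space.  Unknown sex is marginalized as a
two-component mixture over the sex ratio psi.

Two implementations are provided: a transparent per-history reference
(`forward_loglik` over explicit matrix sequences) and a dataset-level
vectorized version used for fitting; the test-suite checks that they agree
with each other and with exhaustive path enumeration.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .age_at_death import age_at_death_loglik
from .data_model import AgeAtDeathRecord, MultiStateDataset
from .multistate import (ModelSpec, ONE_AREA, ParameterSet, StateSpace,
                         build_observation_matrix, build_transition_matrix,
                         log_prior)

_TINY = 1e-300

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:      # pragma: no cover - numba is an optional speed-up
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=False)
def _forward_rows(init, E, tindex, Ttab_flat, first, last):
    """Scaled forward recursion for a batch of rows (compiled hot loop).

    init: (R, S) one-hot first-capture state; E: (R, S, T) emission
    probability of the observed code; tindex: (R, T) flat index into
    Ttab_flat for the transition leaving occasion t; first/last: the
    per-row likelihood window.  Returns per-row log-likelihoods.
    """
    R, S, T = E.shape
    out = np.zeros(R)
    for rr in range(R):
        f = first[rr]
        l = last[rr]
        alpha = init[rr].copy()
        ll = 0.0
        for t in range(f + 1, l):
            Tt = Ttab_flat[tindex[rr, t - 1]]
            new = np.zeros(S)
            for j in range(S):
                aj = alpha[j]
                if aj > 0.0:
                    for k in range(S):
                        new[k] += aj * Tt[j, k]
            c = 0.0
            for k in range(S):
                new[k] *= E[rr, k, t]
                c += new[k]
            if c <= 0.0:
                ll = -np.inf
                break
            ll += np.log(c)
            for k in range(S):
                alpha[k] = new[k] / c
        out[rr] = ll
    return out


def forward_loglik(codes: Sequence[int], first: int,
                   T_seq: Sequence[np.ndarray], O_seq: Sequence[np.ndarray],
                   space: StateSpace, last: Optional[int] = None) -> float:
    """Log P(y_{first+1..last-1} | z_first) by the scaled forward recursion.

    T_seq[t] is the transition matrix from occasion t to t+1; O_seq[t] the
    emission matrix at occasion t.  The initial state is fixed to the state
    implied by the observation at first capture.  Occasions at or beyond
    ``last`` (censoring) contribute nothing.  Impossible histories return
    -inf.
    """
    codes = np.asarray(codes)
    if last is None:
        last = len(codes)
    if codes[first] == 0:
        raise ValueError("history must start with an observation at first capture")
    alpha = np.zeros(space.n_states)
    alpha[space.state_of_code(int(codes[first]))] = 1.0
    ll = 0.0
    for t in range(first + 1, last):
        alpha = alpha @ T_seq[t - 1]
        alpha = alpha * O_seq[t][:, int(codes[t])]
        c = alpha.sum()
        if c <= 0.0:
            return -np.inf
        ll += np.log(c)
        alpha = alpha / c
    return float(ll)


def smoothed_state_probs(codes: Sequence[int], first: int,
                         T_seq: Sequence[np.ndarray],
                         O_seq: Sequence[np.ndarray], space: StateSpace,
                         last: Optional[int] = None) -> np.ndarray:
    """Posterior state probabilities per occasion (forward-backward)."""
    codes = np.asarray(codes)
    if last is None:
        last = len(codes)
    S = space.n_states
    n = last - first
    fwd = np.zeros((n, S))
    fwd[0, space.state_of_code(int(codes[first]))] = 1.0
    for k in range(1, n):
        t = first + k
        a = (fwd[k - 1] @ T_seq[t - 1]) * O_seq[t][:, int(codes[t])]
        s = a.sum()
        if s <= 0:
            raise ValueError("impossible history in smoothing")
        fwd[k] = a / s
    bwd = np.ones((n, S))
    for k in range(n - 2, -1, -1):
        t = first + k
        b = T_seq[t] @ (O_seq[t + 1][:, int(codes[t + 1])] * bwd[k + 1])
        bwd[k] = b / max(b.sum(), _TINY)
    post = fwd * bwd
    post /= post.sum(axis=1, keepdims=True)
    return post


def sex_marginal_loglik(codes: Sequence[int], first: int, sex: int,
                        make_seqs: Callable[[int], tuple], psi: Sequence[float],
                        space: StateSpace, last: Optional[int] = None) -> float:
    """Marginal log-likelihood over latent sex for one history.

    ``make_seqs(sex)`` returns the (T_seq, O_seq) matrix sequences for that
    sex.  Known sex evaluates that component only; unknown sex mixes the
    two components with weights psi.
    """
    if sex in (0, 1):
        T_seq, O_seq = make_seqs(sex)
        return forward_loglik(codes, first, T_seq, O_seq, space, last)
    parts = []
    for s in range(2):
        T_seq, O_seq = make_seqs(s)
        parts.append(forward_loglik(codes, first, T_seq, O_seq, space, last))
    lw = np.log(np.maximum(np.asarray(psi, dtype=float), _TINY))
    return float(logsumexp(lw + np.asarray(parts)))


# ---------------------------------------------------------------------------
# parameter -> probability machinery
# ---------------------------------------------------------------------------

def interval_survival_table(params: ParameterSet, spec: ModelSpec
                            ) -> np.ndarray:
    """Interval survival per (sex, age, year, area), shape (2, 3, Y, A)."""
    Y = spec.n_years
    A = spec.space.n_areas
    out = np.empty((2, 3, Y, A))
    K = spec.intervals_per_year
    for sex in range(2):
        for age in range(3):
            for area in range(A - 1):
                if spec.layout == ONE_AREA:
                    lg = params.b0[0, sex, age]
                    if spec.year_effects:
                        lg = lg + params.sigma_S[age] * params.gamma[age]
                else:
                    lg = params.b0[area, sex, age]
                    if spec.year_effects:
                        lg = lg + params.sigma_S[area] * params.gamma[area]
                out[sex, age, :, area] = expit(np.broadcast_to(lg, (Y,)))
    out[:, :, :, A - 1] = expit(params.b_out)
    return out ** (1.0 / K)


def transition_table(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    """Transition matrices per (sex, age, year), shape (2, 3, Y, S, S)."""
    s_int = interval_survival_table(params, spec)
    space = spec.space
    Y = spec.n_years
    out = np.empty((2, 3, Y, space.n_states, space.n_states))
    for sex in range(2):
        for age in range(3):
            m_cell = params.m[sex, age]
            for y in range(Y):
                out[sex, age, y] = build_transition_matrix(
                    s_int[sex, age, y], m_cell, space)
    return out


def detection_prob_rows(params: ParameterSet, spec: ModelSpec,
                        ds: MultiStateDataset, sex_r: np.ndarray,
                        ind_r: np.ndarray, age_rt: np.ndarray,
                        tel_rt: np.ndarray) -> np.ndarray:
    """Detection probability per (row, area, occasion), vectorized."""
    space = spec.space
    R, T = age_rt.shape
    a0 = params.a0_constrained()
    tel_idx = tel_rt.astype(int) if spec.telemetry \
        else np.zeros_like(age_rt, dtype=int)
    p = np.empty((R, space.n_areas, T))
    for area in range(space.n_areas):
        lg = a0[area][sex_r[:, None], age_rt, tel_idx]
        inside = area < space.n_inside
        full_pred = (area == 0 or spec.layout == ONE_AREA
                     or spec.sub2_full_predictor)
        if inside and spec.effort_effects:
            lg = lg + params.a1 * ds.effort.systmon[area][None, :]
            if full_pred:
                lg = lg + params.a2 * (ds.effort.oppmon[area][None, :] - 1.0)
        if inside and spec.individual_effects and full_pred:
            lg = lg + params.sigma_p * params.epsilon[ind_r][:, None]
        p[:, area, :] = expit(lg)
    if spec.telemetry and spec.layout == ONE_AREA and spec.fix_telemetry_detection:
        p = np.where(tel_rt[:, None, :], 1.0, p)
    return p


def recovery_prob_rows(params: ParameterSet, spec: ModelSpec,
                       sex_r: np.ndarray, age_rt: np.ndarray) -> np.ndarray:
    """Recovery probability per (row, area, occasion)."""
    space = spec.space
    lg = params.d0[sex_r[:, None], age_rt]           # (R, T)
    return expit(lg[:, None, :] + params.d_area[None, :, None]
                 * np.ones((1, space.n_areas, 1)))


def history_matrices(params: ParameterSet, spec: ModelSpec,
                     ds: MultiStateDataset, i: int, sex: int
                     ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Explicit per-occasion (T_seq, O_seq) for one individual and sex.

    Reference path used by tests and utilities; the fitting code uses the
    vectorized equivalent below.
    """
    space = spec.space
    Ttab = transition_table(params, spec)
    sex_r = np.array([sex])
    ind_r = np.array([i])
    age_rt = ds.age[i][None, :]
    tel_rt = ds.telemetry[i][None, :]
    p = detection_prob_rows(params, spec, ds, sex_r, ind_r, age_rt, tel_rt)[0]
    r = recovery_prob_rows(params, spec, sex_r, age_rt)[0]
    T_seq = [Ttab[sex, ds.age[i, t], ds.year_index[t]]
             for t in range(ds.grid.n_occasions)]
    O_seq = [build_observation_matrix(p[:, t], r[:, t], space)
             for t in range(ds.grid.n_occasions)]
    return T_seq, O_seq


# ---------------------------------------------------------------------------
# vectorized dataset likelihood
# ---------------------------------------------------------------------------

def _expand_rows(ds: MultiStateDataset) -> tuple[np.ndarray, np.ndarray]:
    """Rows = individuals x candidate sex (unknown-sex individuals twice)."""
    ind_r, sex_r = [], []
    for i in range(ds.n_individuals):
        if ds.sex[i] in (0, 1):
            ind_r.append(i)
            sex_r.append(int(ds.sex[i]))
        else:
            ind_r += [i, i]
            sex_r += [0, 1]
    return np.asarray(ind_r), np.asarray(sex_r)


def per_individual_loglik(ds: MultiStateDataset, params: ParameterSet,
                          spec: ModelSpec) -> np.ndarray:
    """Sex-marginalized log-likelihood per individual (vectorized forward)."""
    space = ds.space
    S = space.n_states
    T = ds.grid.n_occasions
    ind_r, sex_r = _expand_rows(ds)
    R = len(ind_r)
    age_rt = ds.age[ind_r]
    tel_rt = ds.telemetry[ind_r]
    codes_r = ds.codes[ind_r]
    first_r = ds.first[ind_r]
    last_r = ds.last[ind_r]

    p = detection_prob_rows(params, spec, ds, sex_r, ind_r, age_rt, tel_rt)
    r = recovery_prob_rows(params, spec, sex_r, age_rt)
    Ttab = transition_table(params, spec)

    # emission probability of the observed code given each state: (R, S, T)
    E = np.zeros((R, S, T))
    E[:, space.dead_before, :] = 1.0
    for a in range(space.n_areas):
        E[:, space.alive_state(a), :] = 1.0 - p[:, a, :]
        E[:, space.died_state(a), :] = 1.0 - r[:, a, :]
    for a in range(space.n_areas):
        det = codes_r == space.code_detected(a)
        rec = codes_r == space.code_recovered(a)
        for mask, st, prob in ((det, space.alive_state(a), p[:, a, :]),
                               (rec, space.died_state(a), r[:, a, :])):
            if mask.any():
                keep = np.zeros((R, S, T))
                keep[:, st, :] = prob
                E = np.where(mask[:, None, :], keep, E)

    init = np.zeros((R, S))
    for row in range(R):
        init[row, space.state_of_code(int(codes_r[row, first_r[row]]))] = 1.0

    if _HAVE_NUMBA:
        Y = spec.n_years
        tindex = ((sex_r[:, None] * 3 + age_rt) * Y
                  + ds.year_index[None, :]).astype(np.int64)
        Ttab_flat = np.ascontiguousarray(Ttab.reshape(6 * Y, S, S))
        ll = _forward_rows(init, np.ascontiguousarray(E), tindex, Ttab_flat,
                           first_r.astype(np.int64), last_r.astype(np.int64))
    else:
        alpha = np.zeros((R, S))
        ll = np.zeros(R)
        dead_row = np.zeros(R, dtype=bool)  # rows that hit probability zero
        for t in range(T):
            starting = first_r == t
            if starting.any():
                alpha[starting] = init[starting]
            act = (first_r < t) & (t < last_r)
            if not act.any():
                continue
            Tt = Ttab[sex_r, age_rt[:, t - 1], ds.year_index[t - 1]]
            anew = np.einsum("rj,rjk->rk", alpha, Tt) * E[:, :, t]
            c = anew.sum(axis=1)
            bad = act & (c <= 0.0)
            dead_row |= bad
            safe = np.maximum(c, _TINY)
            ll = np.where(act, ll + np.log(safe), ll)
            alpha = np.where(act[:, None], anew / safe[:, None], alpha)
        ll[dead_row] = -np.inf

    out = np.empty(ds.n_individuals)
    lw = np.log(np.maximum(np.asarray(params.psi, dtype=float), _TINY))
    known = ds.sex >= 0
    row_of_ind = np.zeros(ds.n_individuals, dtype=int)
    row_of_ind[1:] = np.cumsum(2 - known.astype(int))[:-1]
    out[known] = ll[row_of_ind[known]]
    unk_rows = row_of_ind[~known]
    out[~known] = np.logaddexp(lw[0] + ll[unk_rows], lw[1] + ll[unk_rows + 1])
    return out


def dataset_loglik(ds: MultiStateDataset, params: ParameterSet,
                   spec: ModelSpec) -> float:
    """Total encounter-history log-likelihood (sum over individuals).

    Includes the categorical sex term log psi_sex for known-sex
    individuals, which is what lets the data inform the sex ratio.
    """
    ll = float(per_individual_loglik(ds, params, spec).sum())
    lw = np.log(np.maximum(np.asarray(params.psi, dtype=float), _TINY))
    n_f = int((ds.sex == 0).sum())
    n_m = int((ds.sex == 1).sum())
    return ll + n_f * lw[0] + n_m * lw[1]


def age_model_schedules(params: ParameterSet, spec: ModelSpec,
                        area_weights: Optional[np.ndarray] = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sex-by-age survival and recovery schedules shared with the age model.

    Annual survival comes from the inside-subarea intercepts (equal weights
    by default); recovery from the multi-state recovery parameters averaged
    over inside subareas, or with caller-supplied weights over all areas.
    """
    n_in = spec.space.n_inside
    if area_weights is None:
        w = np.zeros(spec.space.n_areas)
        w[:n_in] = 1.0 / n_in
    else:
        w = np.asarray(area_weights, dtype=float)
        w = w / w.sum()
    s_by_sex = np.einsum("a,ast->st", w[:n_in] / w[:n_in].sum(),
                         expit(params.b0))
    r_areas = expit(params.d0[None, :, :] + params.d_area[:, None, None])
    r_by_sex = np.einsum("a,ast->st", w, r_areas)
    return s_by_sex, r_by_sex


def total_loglik(ds: Optional[MultiStateDataset], params: ParameterSet,
                 spec: ModelSpec,
                 age_records: Optional[Sequence[AgeAtDeathRecord]] = None,
                 include_prior: bool = True,
                 area_weights: Optional[np.ndarray] = None) -> float:
    """Posterior kernel: encounter + age-at-death log-likelihood + log prior."""
    lp = log_prior(params, spec) if include_prior else 0.0
    if not np.isfinite(lp):
        return -np.inf
    ll = lp
    if ds is not None and ds.n_individuals > 0:
        ll += dataset_loglik(ds, params, spec)
    if age_records:
        s_by_sex, r_by_sex = age_model_schedules(params, spec, area_weights)
        ll += age_at_death_loglik(age_records, s_by_sex, r_by_sex, params.psi)
        # categorical sex term for known-sex carcasses
        lw = np.log(np.maximum(np.asarray(params.psi, dtype=float), _TINY))
        for rec in age_records:
            if rec.sex in (0, 1):
                ll += lw[rec.sex]
    return float(ll)
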