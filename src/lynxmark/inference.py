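"""Model fitting: MCMC over the marginalized posterior, and a fast
maximum-likelihood mode.

Sampling uses an affine-invariant ensemble sampler (emcee) on an
unconstrained reparameterization: logit-scale intercepts are sampled
directly, standard deviations through log, movement probability pairs
through a multinomial-logit map onto their simplex, and the sex ratio
through a logit.  The appropriate log-Jacobian terms are added so the
priors declared on the natural scale are respected.  Walkers are treated as
chains for split-r-hat and effective-sample-size diagnostics (arviz).

Latent discrete structure (state sequences, unknown sex) never appears in
the sampler: it is marginalized in the likelihood, which makes the
posterior kernel a smooth deterministic function of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit

from .data_model import AGE_NAMES, MultiStateDataset
from .likelihood import total_loglik
from .multistate import (ModelSpec, ONE_AREA, ParameterSet, SEX_LABELS,
                         TWO_SUBAREA)


@dataclass
class FitConfig:
    mode: str = "mcmc"            # "mcmc" | "mle"
    chains: int = 4               # minimum walker-group count for diagnostics
    warmup: int = 1000
    draws: int = 1000
    seed: int = 0
    n_walkers: Optional[int] = None
    rhat_limit: float = 1.05
    min_ess: float = 400.0
    max_iter: int = 500
    init_jitter: float = 0.05

    def __post_init__(self):
        if self.mode not in ("mcmc", "mle"):
            raise ValueError("mode must be 'mcmc' or 'mle'")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for r-hat")
        if self.draws <= 0:
            raise ValueError("draws must be positive")


class ParamTransform:
    """Bijection between a flat unconstrained vector and a ParameterSet.

    Only the blocks activated by the ModelSpec appear in the vector, so a
    model without random effects has no sigma/deviate coordinates at all.
    """

    def __init__(self, spec: ModelSpec, n_individuals: int = 0):
        self.spec = spec
        self.n_individuals = n_individuals
        space = spec.space
        self.blocks: list[tuple[str, int]] = []
        labels: list[str] = []
        areas_in = space.area_labels[:space.n_inside]

        def add(name, size, labs):
            self.blocks.append((name, size))
            labels.extend(labs)

        add("b0", space.n_inside * 6,
            [f"b0[{a},{s},{g}]" for a in areas_in
             for s in SEX_LABELS for g in AGE_NAMES])
        add("b_out", 1, ["b_out"])
        add("a0", space.n_areas * 6,
            [f"a0[{a},{s},{g}]" for a in space.area_labels
             for s in SEX_LABELS for g in AGE_NAMES])
        if spec.telemetry and not (spec.layout == ONE_AREA
                                   and spec.fix_telemetry_detection):
            add("a0_tel", space.n_areas,
                [f"a0_tel[{a}]" for a in space.area_labels])
        if spec.effort_effects:
            add("a1", 1, ["a1"])
            add("a2", 1, ["a2"])
        add("d0", 6, [f"d0[{s},{g}]" for s in SEX_LABELS for g in AGE_NAMES])
        if spec.layout == TWO_SUBAREA:
            add("d_area", 2, ["d_area[sub2]", "d_area[outside]"])
        if spec.estimate_movement:
            nm = space.n_movement()
            mlabs = (("m12", "m13", "m21", "m23") if nm == 4 else ("m_out",))
            add("m", 6 * nm,
                [f"{ml}[{s},{g}]" for s in SEX_LABELS for g in AGE_NAMES
                 for ml in mlabs])
        add("psi", 1, ["psi_F"])
        if spec.year_effects:
            ng = 3 if spec.layout == ONE_AREA else space.n_inside
            self._n_groups = ng
            add("sigma_S", ng, [f"sigma_S[{g}]" for g in range(ng)])
            add("gamma", ng * spec.n_years,
                [f"gamma[{g},{y}]" for g in range(ng)
                 for y in range(spec.n_years)])
        if spec.individual_effects:
            add("sigma_p", 1, ["sigma_p"])
            add("epsilon", n_individuals,
                [f"epsilon[{i}]" for i in range(n_individuals)])
        self.labels = labels
        self.slices: dict[str, slice] = {}
        pos = 0
        for name, size in self.blocks:
            self.slices[name] = slice(pos, pos + size)
            pos += size
        self.n_dim = pos

    # -- unconstrained -> ParameterSet ------------------------------------

    def unpack(self, theta: np.ndarray) -> tuple[ParameterSet, float]:
        """Return (ParameterSet, log|Jacobian|) for one unconstrained vector."""
        spec = self.spec
        space = spec.space
        p = ParameterSet.zeros(spec, self.n_individuals)
        sl = self.slices
        ljac = 0.0
        p.b0 = theta[sl["b0"]].reshape(space.n_inside, 2, 3).copy()
        p.b_out = float(theta[sl["b_out"]][0])
        a0 = np.zeros((space.n_areas, 2, 3, 2))
        a0[:, :, :, 0] = theta[sl["a0"]].reshape(space.n_areas, 2, 3)
        if "a0_tel" in sl:
            for a in range(space.n_areas):
                a0[a, :, :, 1] = theta[sl["a0_tel"]][a]
        p.a0 = a0
        if "a1" in sl:
            p.a1 = float(theta[sl["a1"]][0])
            p.a2 = float(theta[sl["a2"]][0])
        p.d0 = theta[sl["d0"]].reshape(2, 3).copy()
        if "d_area" in sl:
            p.d_area = np.concatenate([[0.0], theta[sl["d_area"]]])
        if "m" in sl:
            nm = space.n_movement()
            x = theta[sl["m"]].reshape(2, 3, nm)
            m = np.empty_like(x)
            tiny = 1e-12
            if nm == 4:
                for pair in (slice(0, 2), slice(2, 4)):
                    e = np.exp(np.clip(x[:, :, pair], -300, 300))
                    denom = 1.0 + e.sum(axis=2, keepdims=True)
                    m[:, :, pair] = e / denom
                    rest = 1.0 / denom[:, :, 0]
                    ljac += float(
                        np.log(np.maximum(m[:, :, pair], tiny)).sum()
                        + np.log(np.maximum(rest, tiny)).sum())
            else:
                m[:, :, 0] = expit(x[:, :, 0])
                ljac += float(
                    np.log(np.maximum(m[:, :, 0], tiny)).sum()
                    + np.log(np.maximum(1.0 - m[:, :, 0], tiny)).sum())
            p.m = m
        psi_f = float(np.clip(expit(theta[sl["psi"]][0]), 1e-12, 1 - 1e-12))
        p.psi = np.array([psi_f, 1.0 - psi_f])
        ljac += float(np.log(psi_f) + np.log1p(-psi_f))
        if "sigma_S" in sl:
            x = theta[sl["sigma_S"]]
            p.sigma_S = np.exp(x)
            ljac += float(x.sum())
            p.gamma = theta[sl["gamma"]].reshape(self._n_groups,
                                                 spec.n_years).copy()
        if "sigma_p" in sl:
            x = float(theta[sl["sigma_p"]][0])
            p.sigma_p = np.exp(x)
            ljac += x
            p.epsilon = theta[sl["epsilon"]].copy()
        return p, ljac

    def pack(self, p: ParameterSet) -> np.ndarray:
        """Inverse of unpack (Jacobian not needed)."""
        spec = self.spec
        space = spec.space
        theta = np.zeros(self.n_dim)
        sl = self.slices
        theta[sl["b0"]] = np.ravel(p.b0)
        theta[sl["b_out"]] = p.b_out
        theta[sl["a0"]] = np.ravel(p.a0[:, :, :, 0])
        if "a0_tel" in sl:
            theta[sl["a0_tel"]] = p.a0[:, 0, 0, 1]
        if "a1" in sl:
            theta[sl["a1"]] = p.a1
            theta[sl["a2"]] = p.a2
        theta[sl["d0"]] = np.ravel(p.d0)
        if "d_area" in sl:
            theta[sl["d_area"]] = p.d_area[1:]
        if "m" in sl:
            nm = space.n_movement()
            m = np.clip(p.m, 1e-9, 1 - 1e-9)
            x = np.empty_like(m)
            if nm == 4:
                for pair in (slice(0, 2), slice(2, 4)):
                    rest = np.clip(1.0 - m[:, :, pair].sum(axis=2), 1e-9, None)
                    x[:, :, pair] = np.log(m[:, :, pair]) \
                        - np.log(rest)[:, :, None]
            else:
                x[:, :, 0] = logit(m[:, :, 0])
            theta[sl["m"]] = np.ravel(x)
        theta[sl["psi"]] = logit(np.clip(p.psi[0], 1e-9, 1 - 1e-9))
        if "sigma_S" in sl:
            theta[sl["sigma_S"]] = np.log(np.maximum(p.sigma_S, 1e-12))
            theta[sl["gamma"]] = np.ravel(p.gamma)
        if "sigma_p" in sl:
            theta[sl["sigma_p"]] = np.log(max(p.sigma_p, 1e-12))
            theta[sl["epsilon"]] = p.epsilon
        return theta

    def constrain_vector(self, theta: np.ndarray) -> np.ndarray:
        """Natural-scale values aligned with ``labels`` (for summaries)."""
        p, _ = self.unpack(theta)
        out = np.array(theta, dtype=float, copy=True)
        sl = self.slices
        if "m" in sl:
            out[sl["m"]] = np.ravel(p.m)
        out[sl["psi"]] = p.psi[0]
        if "sigma_S" in sl:
            out[sl["sigma_S"]] = p.sigma_S
        if "sigma_p" in sl:
            out[sl["sigma_p"]] = p.sigma_p
        return out

    def default_start(self) -> np.ndarray:
        """A mild, data-free starting point in the interior."""
        p = ParameterSet.zeros(self.spec, self.n_individuals)
        p.b0[:] = logit(0.7)
        p.b_out = float(logit(0.7))
        p.a0[:, :, :, 0] = logit(0.15)
        p.a0[:, :, :, 1] = logit(0.8)
        p.d0[:] = logit(0.1)
        p.m[:] = 0.02
        p.sigma_S = np.full_like(p.sigma_S, 0.3)
        p.sigma_p = 0.5
        return self.pack(p)


@dataclass
class FitResult:
    mode: str
    spec: ModelSpec
    transform: ParamTransform
    params: ParameterSet               # point estimate
    summary: pd.DataFrame              # natural-scale per-parameter summary
    loglik: float
    draws: Optional[np.ndarray] = None            # (chains, draws, ndim)
    constrained_draws: Optional[np.ndarray] = None
    converged: bool = True
    flags: list = field(default_factory=list)

    def survival_table(self) -> pd.DataFrame:
        """Annual survival by inside subarea, sex, and age class."""
        space = self.spec.space
        rows = []
        for a in range(space.n_inside):
            for s in range(2):
                for g in range(3):
                    label = f"b0[{space.area_labels[a]},{SEX_LABELS[s]},{AGE_NAMES[g]}]"
                    if self.constrained_draws is not None:
                        k = self.transform.labels.index(label)
                        d = expit(self.constrained_draws[:, :, k].ravel())
                        rows.append((space.area_labels[a], SEX_LABELS[s],
                                     AGE_NAMES[g], d.mean(),
                                     np.quantile(d, 0.025),
                                     np.quantile(d, 0.975)))
                    else:
                        rows.append((space.area_labels[a], SEX_LABELS[s],
                                     AGE_NAMES[g],
                                     float(expit(self.params.b0[a, s, g])),
                                     np.nan, np.nan))
        return pd.DataFrame(rows, columns=["subarea", "sex", "age_class",
                                           "S_mean", "S_q2.5", "S_q97.5"])


def _data_flags(ds: Optional[MultiStateDataset], age_records) -> list[str]:
    flags = []
    if ds is not None and ds.n_individuals:
        n_rec = int((ds.codes % 2 == 0)[ds.codes != 0].sum())
        if n_rec == 0 and not age_records:
            flags.append("recovery parameters unidentifiable: "
                         "no dead recoveries and no age-at-death records")
    return flags


def fit(ds: Optional[MultiStateDataset], spec: ModelSpec,
        config: FitConfig, age_records: Sequence = None) -> FitResult:
    """Fit the integrated model in MCMC or maximum-likelihood mode.

    MLE mode maximizes the data log-likelihood (plus the random-effect
    prior terms when random effects are active, i.e. a MAP over those
    blocks); MCMC samples the full posterior kernel.  Both are
    deterministic given ``config.seed``.
    """
    n_ind = ds.n_individuals if ds is not None else 0
    tr = ParamTransform(spec, n_ind)
    flags = _data_flags(ds, age_records)
    if config.mode == "mle":
        return _fit_mle(ds, spec, config, tr, age_records, flags)
    return _fit_mcmc(ds, spec, config, tr, age_records, flags)


def _mle_objective(tr: ParamTransform, ds, spec, age_records):
    penalized = spec.year_effects or spec.individual_effects

    def nll(theta):
        p, _ = tr.unpack(theta)
        ll = total_loglik(ds, p, spec, age_records,
                          include_prior=penalized)
        if not np.isfinite(ll):
            return 1e12
        return -ll

    return nll


def _fit_mle(ds, spec, config, tr, age_records, flags) -> FitResult:
    nll = _mle_objective(tr, ds, spec, age_records)
    x0 = tr.default_start()
    bounds = [(-15.0, 15.0)] * tr.n_dim
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": config.max_iter,
                                     "maxfun": 10 ** 6,
                                     "ftol": 1e-8, "gtol": 1e-4})
    if not res.success and "ABNORMAL" in str(res.message):
        flags = flags + [f"optimizer: {res.message}"]
    params, _ = tr.unpack(res.x)
    natural = tr.constrain_vector(res.x)
    summary = pd.DataFrame({"mean": natural}, index=tr.labels)
    ll = -float(res.fun)
    return FitResult("mle", spec, tr, params, summary, ll, flags=flags)


def _fit_mcmc(ds, spec, config, tr, age_records, flags) -> FitResult:
    def log_post(theta):
        p, ljac = tr.unpack(theta)
        ll = total_loglik(ds, p, spec, age_records, include_prior=True)
        if not np.isfinite(ll):
            return -np.inf
        return ll + ljac

    ndim = tr.n_dim
    nwalkers = config.n_walkers or 2 * ndim + 2
    nwalkers = max(nwalkers, 2 * ndim + 2, 2 * config.chains)
    if nwalkers % 2:
        nwalkers += 1
    rng = np.random.default_rng(config.seed)

    if ds is not None and ds.n_individuals > 0:
        mle_cfg = FitConfig(mode="mle", seed=config.seed,
                            max_iter=min(config.max_iter, 300))
        center = _fit_mle(ds, spec, mle_cfg, tr, age_records, []).params
        x_center = tr.pack(center)
    else:
        x_center = tr.default_start()
    p0 = x_center[None, :] + config.init_jitter * \
        rng.standard_normal((nwalkers, ndim))
    # make sure every walker starts at finite posterior density
    for w in range(nwalkers):
        tries = 0
        while not np.isfinite(log_post(p0[w])) and tries < 50:
            p0[w] = x_center + config.init_jitter * rng.standard_normal(ndim)
            tries += 1

    moves = [(emcee.moves.DEMove(), 0.8),
             (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nwalkers, ndim, log_post, moves=moves)
    sampler._random = np.random.RandomState(config.seed)
    # warmup and draws count ensemble steps; retained samples = walkers * draws
    sampler.run_mcmc(p0, config.warmup + config.draws, progress=False)
    chain = sampler.get_chain(discard=config.warmup)  # (kept, walkers, ndim)
    draws = np.transpose(chain, (1, 0, 2))            # (walkers, kept, ndim)

    constrained = np.empty_like(draws)
    for c in range(draws.shape[0]):
        for d in range(draws.shape[1]):
            constrained[c, d] = tr.constrain_vector(draws[c, d])

    diag = diagnostics(constrained, tr.labels)
    flat = constrained.reshape(-1, ndim)
    mean_theta = draws.reshape(-1, ndim).mean(axis=0)
    params, _ = tr.unpack(mean_theta)
    summary = pd.DataFrame(
        {"mean": flat.mean(axis=0),
         "q2.5": np.quantile(flat, 0.025, axis=0),
         "q97.5": np.quantile(flat, 0.975, axis=0),
         "r_hat": diag["r_hat"].to_numpy(),
         "ess": diag["ess"].to_numpy()},
        index=tr.labels)
    bad_rhat = summary["r_hat"].max() > config.rhat_limit
    low_ess = summary["ess"].min() < config.min_ess
    converged = not bad_rhat
    if bad_rhat:
        flags = flags + [
            f"non-convergence: max r-hat {summary['r_hat'].max():.3f} "
            f"exceeds {config.rhat_limit}"]
    if low_ess:
        flags = flags + [
            f"low effective sample size: min ESS {summary['ess'].min():.0f}"]
    ll = float(np.max(sampler.get_log_prob(discard=config.warmup)))
    return FitResult("mcmc", spec, tr, params, summary, ll, draws=draws,
                     constrained_draws=constrained, converged=converged,
                     flags=flags)


def diagnostics(draws: np.ndarray, labels: Sequence[str] = None
                ) -> pd.DataFrame:
    """Split-chain r-hat and effective sample size per parameter.

    draws: (chains, draws, n_params); at least two chains are required.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim == 2:
        draws = draws[:, :, None]
    if draws.shape[0] < 2:
        raise ValueError("r-hat requires at least 2 chains")
    n_par = draws.shape[2]
    labels = list(labels) if labels is not None else \
        [f"p{k}" for k in range(n_par)]
    data = az.convert_to_dataset(
        {lab: draws[:, :, k] for k, lab in enumerate(labels)})
    rh = az.rhat(data)
    es = az.ess(data)
    out = pd.DataFrame(
        {"r_hat": [float(rh[lab]) for lab in labels],
         "ess": [float(es[lab]) for lab in labels]},
        index=labels)
    return out


def posterior_predictive_check(result: FitResult, ds: MultiStateDataset,
                               n_rep: int = 200, seed: int = 0
                               ) -> pd.DataFrame:
    """Simulate replicate observation sets from the fitted model.

    For each replicate a parameter draw is taken (posterior draws in MCMC
    mode, the point estimate in MLE mode), each individual's latent
    trajectory is re-simulated from its first-capture state, and the
    detection / recovery totals are compared with the observed data.
    """
    from .likelihood import (detection_prob_rows, recovery_prob_rows,
                             transition_table)
    rng = np.random.default_rng(seed)
    spec = result.spec
    space = ds.space
    T = ds.grid.n_occasions
    n = ds.n_individuals
    obs_det = int(((ds.codes != 0) & (ds.codes % 2 == 1)).sum())
    obs_rec = int(((ds.codes != 0) & (ds.codes % 2 == 0)).sum())
    stats = np.empty((n_rep, 2))
    sex_fill = np.where(ds.sex >= 0, ds.sex, 0).astype(int)
    for rep in range(n_rep):
        if result.draws is not None:
            c = rng.integers(result.draws.shape[0])
            d = rng.integers(result.draws.shape[1])
            params, _ = result.transform.unpack(result.draws[c, d])
        else:
            params = result.params
        # unknown sex: draw from the fitted mixture
        sex = sex_fill.copy()
        unk = ds.sex < 0
        sex[unk] = (rng.random(unk.sum()) < params.psi[1]).astype(int)
        Ttab = transition_table(params, spec)
        p = detection_prob_rows(params, spec, ds, sex, np.arange(n),
                                ds.age, ds.telemetry)
        r = recovery_prob_rows(params, spec, sex, ds.age)
        z = np.full((n, T), -1, dtype=np.int8)
        for i in range(n):
            z[i, ds.first[i]] = space.state_of_code(
                int(ds.codes[i, ds.first[i]]))
        for t in range(T - 1):
            act = (ds.first <= t) & (t + 1 < ds.last) & (z[:, t] >= 0)
            if not act.any():
                continue
            rows_T = Ttab[sex[act], ds.age[act, t], ds.year_index[t]]
            P = rows_T[np.arange(act.sum()), z[act, t]]
            z[act, t + 1] = (rng.random(act.sum())[:, None]
                             > np.cumsum(P, axis=1)).sum(axis=1)
        n_det = n  # first captures count as detections
        n_rec = 0
        u_det = rng.random((n, T))
        u_rec = rng.random((n, T))
        for a in range(space.n_areas):
            alive = z == space.alive_state(a)
            died = z == space.died_state(a)
            after_first = np.arange(T)[None, :] > ds.first[:, None]
            n_det += int((alive & after_first
                          & (u_det < p[:, a, :])).sum())
            n_rec += int((died & after_first
                          & (u_rec < r[:, a, :])).sum())
        stats[rep] = (n_det, n_rec)
    rows = []
    for j, (name, obs) in enumerate((("n_detections", obs_det),
                                     ("n_recoveries", obs_rec))):
        rows.append((name, obs, stats[:, j].mean(),
                     np.quantile(stats[:, j], 0.025),
                     np.quantile(stats[:, j], 0.975), n_rep))
    return pd.DataFrame(rows, columns=["statistic", "observed", "rep_mean",
                                       "rep_q2.5", "rep_q97.5", "n_rep"])
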