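"""Dead-recovery model for age-at-death data and its recovery-corrected form.

Carcasses with a known birth year give an independent sample of whole-year
ages at death (categories 1..18; no lynx in the study area is documented
older than 18).  With age-specific annual survival s_j the probability of
dying in year j, conditional on dying within 18 years, is

    theta_j = prod(s_{1..j-1}) (1 - s_j) / (1 - prod(s_{1..18})).

This classic form assumes every carcass is equally likely to be found
regardless of age.  The integrated model removes that assumption using the
multi-state model's age-specific recovery probabilities r_j:

    theta_j = prod(s_{1..j-1}) (1 - s_j) r_j / P,

where P is the probability of dying AND being found within 18 years.  The
18-year schedule collapses to three classes: year 1 = juvenile survival,
year 2 = subadult, years 3..18 = adult.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .data_model import AgeAtDeathRecord

T_MAX = 18


def expand_schedule(s: Sequence[float], t_max: int = T_MAX) -> np.ndarray:
    """Expand (juvenile, subadult, adult) survival to a per-year schedule."""
    s = np.asarray(s, dtype=float)
    if s.shape == (t_max,):
        return s
    if s.shape != (3,):
        raise ValueError("schedule must have length 3 or t_max")
    return np.concatenate([s[:2], np.full(t_max - 2, s[2])])


def _check_probs(x, name):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def uncorrected_theta(s: Sequence[float], t_max: int = T_MAX) -> np.ndarray:
    """Age-at-death distribution assuming age-independent carcass recovery."""
    s18 = _check_probs(expand_schedule(s, t_max), "survival")
    cum = np.concatenate([[1.0], np.cumprod(s18[:-1])])
    denom = 1.0 - np.prod(s18)
    if denom <= 0:
        raise ValueError("survival of 1 in every year: the age-at-death "
                         "distribution is undefined")
    return cum * (1.0 - s18) / denom


def recovery_probability_P(s: Sequence[float], r: Sequence[float],
                           t_max: int = T_MAX) -> float:
    """Probability of dying and being found within t_max years.

    Closed form with a geometric series over the adult years; the identity
    (1 - s3) * (s3**(t_max-2) - 1) / (s3 - 1) == 1 - s3**(t_max-2)
    is used, which is exact in the s3 -> 1 limit as well.
    """
    s = _check_probs(np.asarray(s, dtype=float), "survival")
    r = _check_probs(np.asarray(r, dtype=float), "recovery")
    if s.shape != (3,) or r.shape != (3,):
        raise ValueError("class schedules must have length 3")
    s1, s2, s3 = s
    r1, r2, r3 = r
    return float((1 - s1) * r1
                 + s1 * (1 - s2) * r2
                 + s1 * s2 * (1 - s3 ** (t_max - 2)) * r3)


def corrected_theta(s: Sequence[float], r: Sequence[float],
                    t_max: int = T_MAX) -> np.ndarray:
    """Recovery-corrected age-at-death distribution (sums to 1 via P)."""
    s18 = _check_probs(expand_schedule(s, t_max), "survival")
    r18 = _check_probs(expand_schedule(r, t_max), "recovery")
    s3 = np.asarray(s, dtype=float)
    r3 = np.asarray(r, dtype=float)
    if s3.shape == (t_max,):
        s3 = np.array([s18[0], s18[1], s18[2]])
        r3 = np.array([r18[0], r18[1], r18[2]])
    P = recovery_probability_P(s3, r3, t_max)
    if P <= 0:
        raise ValueError("probability of dying and being found is zero")
    cum = np.concatenate([[1.0], np.cumprod(s18[:-1])])
    return cum * (1.0 - s18) * r18 / P


def age_at_death_loglik(records: Sequence[AgeAtDeathRecord],
                        s_by_sex: np.ndarray, r_by_sex: np.ndarray,
                        psi: Sequence[float], corrected: bool = True,
                        t_max: int = T_MAX) -> float:
    """Log-likelihood of age-at-death records under the categorical model.

    s_by_sex, r_by_sex: (2, 3) class schedules per sex.  Unknown-sex records
    are marginalized over the sex mixture psi.
    """
    s_by_sex = np.asarray(s_by_sex, dtype=float)
    r_by_sex = np.asarray(r_by_sex, dtype=float)
    psi = np.asarray(psi, dtype=float)
    thetas = []
    for sex in range(2):
        if corrected:
            thetas.append(corrected_theta(s_by_sex[sex], r_by_sex[sex], t_max))
        else:
            thetas.append(uncorrected_theta(s_by_sex[sex], t_max))
    log_theta = np.log(np.maximum(np.stack(thetas), 1e-300))
    ll = 0.0
    for rec in records:
        if not 1 <= rec.age <= t_max:
            raise ValueError(f"age at death {rec.age} outside 1..{t_max}")
        j = rec.age - 1
        if rec.sex in (0, 1):
            ll += log_theta[rec.sex, j]
        else:
            ll += logsumexp(np.log(np.maximum(psi, 1e-300)) + log_theta[:, j])
    return float(ll)
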