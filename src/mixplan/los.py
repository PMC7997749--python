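"""Length-of-stay probability machinery and the expected-census operator.

The LOS of an admitted patient is a discrete random variable on
{1, ..., tau} (stays truncated at the cycle length tau).  Two equivalent
descriptions are used:

* the pmf ``P[t]`` = probability the stay lasts exactly ``t`` days
  (``t = 1..tau``), and
* the survival curve ``S[s]`` = probability the stay exceeds ``s`` days
  (``s = 0..tau-1``), with ``S[0] = 1``.

They are related by ``S[s] = 1 - sum_{t<=s} P[t]`` and
``P[t] = S[t-1] - S[t]`` (``S[tau] = 0``).  The expected number of type-i
patients in hospital on day t ("census") is the convolution of the
admission cohorts with the survival curve:

    M[i, t] = sum_{u<=t} S_i[t-u] * x[i, u]

so a patient admitted on day u counts toward the census of day u (S[0]=1)
and contributes to later days with probability S[elapsed days].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instance import LOSSurvival

__all__ = [
    "LOSPmf",
    "survival_from_pmf",
    "pmf_from_survival",
    "expected_los",
    "census_matrix",
]

_EPS = 1e-9


@dataclass(frozen=True)
class LOSPmf:
    """Probability mass function of LOS; ``values[k]`` = P(LOS = k+1 days).

    Mass may sum to less than 1: stays longer than the horizon are
    truncated, their probability residing implicitly in "still in hospital
    at the end of the cycle".
    """

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    @property
    def horizon(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def survival_from_pmf(pmf: LOSPmf) -> LOSSurvival:
    """Convert an LOS pmf to its survival curve.

    Returns ``S`` with ``S[s] = 1 - sum_{t<=s} P[t]`` for s = 0..tau-1.
    Raises ``ValueError`` on negative masses or total mass > 1.
    """
    p = pmf.as_array()
    if np.any(p < -_EPS):
        raise ValueError("pmf has negative mass")
    if p.sum() > 1 + 1e-6:
        raise ValueError(f"pmf mass sums to {p.sum()} > 1")
    s = 1.0 - np.concatenate([[0.0], np.cumsum(p)[:-1]])
    return LOSSurvival(tuple(np.clip(s, 0.0, 1.0)))


def pmf_from_survival(surv: LOSSurvival) -> LOSPmf:
    """Invert :func:`survival_from_pmf`: ``P[t] = S[t-1] - S[t]``, S[tau]=0."""
    bad = surv.violations()
    if bad:
        raise ValueError("; ".join(bad))
    s = np.concatenate([surv.as_array(), [0.0]])
    p = -np.diff(s)
    return LOSPmf(tuple(p))


def expected_los(surv: LOSSurvival) -> float:
    """Mean LOS (days, truncated at the horizon): sum of the survival curve."""
    return float(surv.as_array().sum())


def census_matrix(x: np.ndarray, survivals) -> np.ndarray:
    """Expected in-hospital headcount per type per day.

    Parameters
    ----------
    x : array (n_types, tau)
        Admissions per type per day (day index 0 = cycle day 1).
    survivals : sequence of LOSSurvival or array (n_types, >=tau)
        Per-type survival curves.

    Returns
    -------
    array (n_types, tau) of expected census values
    ``M[i, t] = sum_{u<=t} S_i[t-u] x[i, u]`` — the cohort convolution,
    linear in ``x`` and truncated at the horizon.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n_types, tau = x.shape
    if isinstance(survivals, np.ndarray):
        S = np.atleast_2d(survivals)
    else:
        S = np.zeros((len(survivals), tau))
        for i, sv in enumerate(survivals):
            v = sv.as_array()[:tau]
            S[i, : len(v)] = v
    if S.shape[0] != n_types:
        raise ValueError(f"{n_types} admission rows but {S.shape[0]} survival curves")
    if S.shape[1] < tau:
        raise ValueError("survival curves shorter than the planning horizon")
    M = np.empty((n_types, tau))
    for i in range(n_types):
        M[i] = np.convolve(x[i], S[i, :tau])[:tau]
    return M
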