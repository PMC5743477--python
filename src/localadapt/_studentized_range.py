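"""Fast vectorized tail probabilities of the studentized range distribution.

The Tukey all-pairwise step needs the survival function of
``Q = range(Z_1..Z_k) / S`` with ``S^2 ~ chi2_df / df`` independent of the
``k`` iid standard normals.  ``scipy.stats.studentized_range`` computes the
same quantity but at several milliseconds per evaluation, which is
prohibitive inside simulation studies that classify tens of thousands of
garden × species cells.  This module evaluates the classical double-integral
representation with fixed Gauss–Legendre rules, fully vectorized over a
batch of ``q`` values:

    P(range <= w)  =  k * Int phi(z) [Phi(z) - Phi(z - w)]^(k-1) dz
    P(Q <= q)      =  E_S[ P(range <= q S) ]

For ``k = 2`` the exact identity ``Q = sqrt(2) |t_df|`` is used instead, so
two-group Tukey p-values agree with the pooled two-sided t-test to machine
precision.  Accuracy against scipy's implementation is ~1e-7 (verified in
the test suite).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.special import ndtr

__all__ = ["sr_sf"]

# z-rule: the integrand lives where the max of k normals does, |z| <~ 8.5
_NZ = 80
_zn, _zw = np.polynomial.legendre.leggauss(_NZ)
_Z = 9.0 * _zn
_WZ = 9.0 * _zw
_PHI_Z = stats.norm.pdf(_Z)
_CDF_Z = ndtr(_Z)

_NS = 50  # s-rule nodes

# beyond this df the scale factor S is numerically 1
_DF_NORMAL_LIMIT = 1e5


def _range_cdf(w: np.ndarray, k: int) -> np.ndarray:
    """CDF of the range of k iid standard normals, vectorized over w >= 0."""
    diff = _CDF_Z[None, :] - ndtr(_Z[None, :] - w[:, None])
    vals = (_WZ * _PHI_Z)[None, :] * diff ** (k - 1)
    return np.clip(k * vals.sum(axis=1), 0.0, 1.0)


@lru_cache(maxsize=256)
def _s_rule(df: float) -> tuple[np.ndarray, np.ndarray]:
    """Gauss–Legendre nodes/weights for S = sqrt(chi2_df / df)."""
    lo = stats.chi.ppf(1e-13, df) / np.sqrt(df)
    hi = stats.chi.isf(1e-13, df) / np.sqrt(df)
    xn, xw = np.polynomial.legendre.leggauss(_NS)
    s = 0.5 * (hi - lo) * xn + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * xw
    dens = stats.chi.pdf(s * np.sqrt(df), df) * np.sqrt(df)
    w = w * dens
    return s, w / w.sum()  # renormalize: truncation mass ~1e-13


def sr_sf(q, k: int, df: float):
    """P(Q_{k, df} >= q), vectorized over ``q``.

    Parameters
    ----------
    q
        Observed studentized-range statistic(s); nonpositive values give 1.
    k
        Number of groups (>= 2).
    df
        Residual degrees of freedom (> 0); ``np.inf`` uses the normal limit.
    """
    scalar = np.ndim(q) == 0
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if k < 2:
        raise ValueError("studentized range needs k >= 2 groups")
    if df <= 0:
        raise ValueError("df must be positive")
    out = np.ones_like(q)
    pos = q > 0
    qp = q[pos]
    if qp.size:
        if k == 2:
            # |X1 - X2| / S = sqrt(2) |t_df|, exactly
            out[pos] = 2.0 * stats.t.sf(qp / np.sqrt(2.0), df)
        elif not np.isfinite(df) or df > _DF_NORMAL_LIMIT:
            out[pos] = 1.0 - _range_cdf(qp, k)
        else:
            s, w = _s_rule(float(df))
            wmat = qp[:, None] * s[None, :]
            cdf = _range_cdf(wmat.ravel(), k).reshape(wmat.shape)
            out[pos] = np.clip(1.0 - cdf @ w, 0.0, 1.0)
    return float(out[0]) if scalar else out
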