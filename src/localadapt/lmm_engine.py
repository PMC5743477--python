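"""Gaussian linear mixed models with a single random-intercept grouping.

Both sympatric/allopatric tiers fit the same model class:

    y = X beta + Z u + eps,   u ~ N(0, sigma2_group I_q),
                              eps ~ N(0, sigma2_resid I_n)

with ``X`` built from garden identity and the sympatry indicator and ``Z``
the indicator matrix of the random grouping (ecotype, or the composite
species:ecotype key in the cross-species tier).  Because there is only one
variance ratio ``lambda = sigma2_group / sigma2_resid``, the (restricted)
likelihood is profiled analytically down to a 1-D function of ``lambda``:
for each candidate, ``beta`` is the GLS solution and ``sigma2_resid`` the
scaled GLS residual quadratic form, computed in closed form per group via
the rank-one Woodbury identity — no n × n matrices are ever formed.  The
profiled criterion is maximized by a coarse log-scale grid followed by
bounded Brent refinement, with the boundary ``sigma2_group = 0`` always
considered, so variances are nonnegative by construction.

REML is the default (the standard choice for variance components); ML is
available, e.g. for resampling procedures where comparability of fits
across subsamples matters more than unbiased variance estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = ["LmmSpec", "MixedModelFit", "fit_lmm", "loglik_at", "build_fixed_design", "predict_fixed"]

_LOG2PI = float(np.log(2.0 * np.pi))

# log(lambda) search window; the left edge stands in for the boundary fit
_T_LO, _T_HI = -25.0, 25.0


class RankDeficientError(ValueError):
    """Fixed-effect design matrix is not full rank."""


@dataclass(frozen=True)
class LmmSpec:
    """Model specification: response, fixed factors, random grouping, method.

    ``fixed_factors`` columns that are non-numeric are dummy-coded with the
    first-observed level as reference; numeric columns (e.g. the 0/1
    sympatry indicator) enter as-is.  ``random_group`` names the grouping
    column; nesting (ecotype within species) is expressed by passing a
    composite key column such as ``"species:ecotype"``.
    """

    response: str
    fixed_factors: tuple[str, ...]
    random_group: str
    method: str = "REML"

    def __post_init__(self) -> None:
        if self.method not in ("REML", "ML"):
            raise ValueError(f"method must be 'REML' or 'ML', got {self.method!r}")


@dataclass(frozen=True)
class MixedModelFit:
    """Maximum-(restricted-)likelihood fit of the random-intercept LMM."""

    beta: np.ndarray
    beta_names: tuple[str, ...]
    beta_cov: np.ndarray
    sigma2_resid: float
    sigma2_group: float
    loglik: float
    n_obs: int
    n_groups: int
    df_resid: int  # n_obs - n_fixed
    method: str
    design_info: Mapping = field(repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.beta_cov))

    def coef(self, name: str) -> float:
        return float(self.beta[self.beta_names.index(name)])

    def to_dict(self) -> dict:
        return {
            "beta": dict(zip(self.beta_names, map(float, self.beta))),
            "sigma2_resid": self.sigma2_resid,
            "sigma2_group": self.sigma2_group,
            "loglik": self.loglik,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "method": self.method,
            "design_info": {
                k: (dict(v) if isinstance(v, Mapping) else v)
                for k, v in self.design_info.items()
            },
        }


def build_fixed_design(
    df: pd.DataFrame,
    fixed_factors: Sequence[str],
    design_info: Mapping | None = None,
) -> tuple[np.ndarray, tuple[str, ...], dict]:
    """Fixed-effect model matrix with an intercept and dummy coding.

    When ``design_info`` (from a previous call) is given, the same levels
    and reference categories are reused so new rows — e.g. prediction grids
    — are encoded consistently with the fitted model.
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["Intercept"]
    info: dict = {"factors": list(fixed_factors), "levels": {}, "reference": {}}
    prior = design_info or {}
    for f in fixed_factors:
        s = df[f]
        if pd.api.types.is_numeric_dtype(s):
            cols.append(s.to_numpy(float))
            names.append(f)
            info["levels"][f] = None
        else:
            if prior:
                levels = list(prior["levels"][f])
            else:
                levels = list(dict.fromkeys(s))
            unknown = set(s) - set(levels)
            if unknown:
                raise ValueError(f"column {f!r} has unseen level(s) {sorted(unknown)}")
            info["levels"][f] = levels
            info["reference"][f] = levels[0]
            for lv in levels[1:]:
                cols.append((s == lv).to_numpy(float))
                names.append(f"{f}[{lv}]")
    return np.column_stack(cols), tuple(names), info


def _prepare(df: pd.DataFrame, spec: LmmSpec):
    data = df[df[spec.response].notna()]
    if data.empty:
        raise ValueError("no non-missing observations for response")
    y = data[spec.response].to_numpy(float)
    X, names, info = build_fixed_design(data, spec.fixed_factors)
    codes, levels = pd.factorize(data[spec.random_group], sort=False)
    if len(levels) < 2:
        raise ValueError(
            f"random grouping {spec.random_group!r} has {len(levels)} level(s); need >= 2"
        )
    # full-rank check on the fixed design
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[min(j, r.shape[0] - 1), j]) < 1e-8]
        raise RankDeficientError(f"fixed design is rank deficient; suspect column(s): {bad}")
    info["random_group"] = spec.random_group
    info["group_levels"] = list(map(str, levels))
    return y, X, names, info, codes


class _Profiler:
    """Profiled (restricted) log-likelihood over the variance ratio."""

    def __init__(self, y: np.ndarray, X: np.ndarray, codes: np.ndarray, method: str):
        self.n, self.p = X.shape
        self.q = int(codes.max()) + 1
        self.method = method
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group sums of X columns and of y
        self.SX = np.zeros((self.q, self.p))
        np.add.at(self.SX, codes, X)
        self.Sy = np.bincount(codes, weights=y, minlength=self.q)
        self.nj = np.bincount(codes, minlength=self.q).astype(float)

    def _gls(self, lam: float):
        c = lam / (1.0 + lam * self.nj)  # Woodbury rank-one correction per group
        A = self.XtX - self.SX.T @ (c[:, None] * self.SX)
        b = self.Xty - self.SX.T @ (c * self.Sy)
        beta = np.linalg.solve(A, b)
        quad = (self.yty - float(c @ self.Sy**2)) - float(beta @ b)
        logdetV = float(np.log1p(lam * self.nj).sum())
        return beta, A, max(quad, 1e-300), logdetV

    def profile_loglik(self, lam: float) -> float:
        """Maximized loglik over (beta, sigma2) at fixed variance ratio."""
        _, A, quad, logdetV = self._gls(lam)
        n, p = self.n, self.p
        if self.method == "ML":
            s2 = quad / n
            return -0.5 * (n * (_LOG2PI + np.log(s2)) + logdetV + n)
        s2 = quad / (n - p)
        sign, logdetA = np.linalg.slogdet(A)
        return -0.5 * ((n - p) * (_LOG2PI + np.log(s2)) + logdetV + logdetA + (n - p))

    def loglik(self, sigma2_resid: float, sigma2_group: float, beta=None) -> float:
        """(Restricted) log-likelihood at arbitrary admissible parameters."""
        if sigma2_resid <= 0 or sigma2_group < 0:
            raise ValueError("need sigma2_resid > 0 and sigma2_group >= 0")
        lam = sigma2_group / sigma2_resid
        beta_gls, A, quad_gls, logdetV = self._gls(lam)
        n, p = self.n, self.p
        if self.method == "ML":
            if beta is None:
                beta = beta_gls
            beta = np.asarray(beta, float)
            d = beta - beta_gls
            quad = quad_gls + float(d @ A @ d)
            return -0.5 * (
                n * (_LOG2PI + np.log(sigma2_resid)) + logdetV + quad / sigma2_resid
            )
        sign, logdetA = np.linalg.slogdet(A)
        return -0.5 * (
            (n - p) * (_LOG2PI + np.log(sigma2_resid))
            + logdetV
            + logdetA
            + quad_gls / sigma2_resid
        )

    def solve(self):
        """Maximize the profiled criterion over log(lambda)."""
        grid = np.linspace(_T_LO, _T_HI, 41)
        vals = np.array([self.profile_loglik(np.exp(t)) for t in grid])
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -self.profile_loglik(np.exp(t)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        t_hat, ll_hat = float(res.x), -float(res.fun)
        lam = float(np.exp(t_hat))
        ll0 = self.profile_loglik(0.0)
        if ll0 >= ll_hat:  # boundary solution: no between-group variance
            lam, ll_hat = 0.0, ll0
        return lam, ll_hat


def fit_lmm(df: pd.DataFrame, spec: LmmSpec) -> MixedModelFit:
    """Fit the random-intercept LMM by profiled ML or REML.

    Rows with a missing response are dropped (complete case).  The reported
    log-likelihood is the maximized (restricted) criterion; ``sigma2_group``
    may be exactly 0 when the data show no between-group variability.

    Raises
    ------
    RankDeficientError
        Collinear fixed-effect columns (named in the message).
    ValueError
        Fewer than two random-effect levels.
    """
    y, X, names, info, codes = _prepare(df, spec)
    prof = _Profiler(y, X, codes, spec.method)
    lam, ll = prof.solve()
    beta, A, quad, _ = prof._gls(lam)
    dof = prof.n - prof.p if spec.method == "REML" else prof.n
    s2 = quad / dof
    beta_cov = s2 * np.linalg.inv(A)
    beta_cov = 0.5 * (beta_cov + beta_cov.T)
    return MixedModelFit(
        beta=beta,
        beta_names=names,
        beta_cov=beta_cov,
        sigma2_resid=float(s2),
        sigma2_group=float(lam * s2),
        loglik=float(ll),
        n_obs=prof.n,
        n_groups=prof.q,
        df_resid=prof.n - prof.p,
        method=spec.method,
        design_info=info,
    )


def loglik_at(
    df: pd.DataFrame,
    spec: LmmSpec,
    sigma2_resid: float,
    sigma2_group: float,
    beta: np.ndarray | None = None,
) -> float:
    """(Restricted) log-likelihood at user-supplied parameters.

    For ``method='ML'`` an explicit ``beta`` may be supplied (defaults to
    the GLS solution at the given variances); for REML the criterion does
    not involve ``beta`` and the argument is ignored.  Exposed so the
    optimizer in :func:`fit_lmm` can be audited against grid search.
    """
    y, X, names, info, codes = _prepare(df, spec)
    prof = _Profiler(y, X, codes, spec.method)
    return prof.loglik(sigma2_resid, sigma2_group, beta=beta)


def predict_fixed(fit: MixedModelFit, df: pd.DataFrame, beta: np.ndarray | None = None) -> np.ndarray:
    """Fixed-effects predictions for new rows (random effects at 0).

    ``beta`` overrides the fitted coefficients, e.g. to evaluate posterior
    draws on a prediction grid.
    """
    X, names, _ = build_fixed_design(df, fit.design_info["factors"], fit.design_info)
    if names != fit.beta_names:
        raise ValueError("prediction design does not match fitted design")
    b = fit.beta if beta is None else np.asarray(beta, float)
    if b.ndim == 2:  # one column of predictions per draw
        return X @ b.T
    return X @ b
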