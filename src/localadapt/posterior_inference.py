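"""Simulation-based Bayesian summaries of fixed effects from a fitted LMM.

Instead of likelihood-ratio p-values, inference on the sympatry effect uses
the posterior of the fixed effects under a noninformative prior, simulated
directly from the fitted model (the "sim" convention of applied Bayesian
mixed modeling): for each draw

    sigma2 ~ sigma2_hat * df / chi2_df          (scaled inverse chi-square)
    beta | sigma2 ~ N(beta_hat, (sigma2 / sigma2_hat) * Cov_hat)

with the variance components held at their point estimates — random-effect
uncertainty is deliberately not propagated, a documented limitation of the
convention.  From the draws one obtains equal-tailed credible intervals and
posterior probabilities such as P(sympatry effect > 0); a probability above
0.95 is read as evidence of local adaptation, below 0.05 as evidence of
maladaptation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .lmm_engine import MixedModelFit

__all__ = [
    "PosteriorDraws",
    "simulate_posterior",
    "credible_interval",
    "posterior_probability",
]


@dataclass(frozen=True)
class PosteriorDraws:
    """Joint posterior draws of the fixed effects and residual SD."""

    coef: np.ndarray  # (n_draws, n_fixed)
    names: tuple[str, ...]
    sigma: np.ndarray  # (n_draws,) residual SD draws
    seed: int

    @property
    def n_draws(self) -> int:
        return self.coef.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.coef[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.coef, columns=list(self.names))
        df["sigma"] = self.sigma
        return df


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Cholesky-like factor of a PSD matrix (eigendecomposition fallback)."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(cov)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("beta_cov is not positive semidefinite") from None
        return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_posterior(fit: MixedModelFit, n_draws: int = 10_000, seed: int = 0) -> PosteriorDraws:
    """Draw from the noninformative-prior posterior of the fixed effects.

    Reproducible bit-for-bit from ``seed``.  Requires positive residual
    degrees of freedom; raises ``ValueError`` on a non-PSD coefficient
    covariance.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if fit.df_resid < 1:
        raise ValueError("posterior simulation needs positive residual df")
    rng = np.random.default_rng(seed)
    df = fit.df_resid
    sigma2 = fit.sigma2_resid * df / rng.chisquare(df, size=n_draws)
    L = _psd_factor(fit.beta_cov)
    z = rng.standard_normal((n_draws, len(fit.beta)))
    scale = np.sqrt(sigma2 / fit.sigma2_resid)
    coef = fit.beta[None, :] + scale[:, None] * (z @ L.T)
    return PosteriorDraws(coef=coef, names=fit.beta_names, sigma=np.sqrt(sigma2), seed=seed)


EffectLike = int | str | Sequence[float] | Callable[[np.ndarray], np.ndarray]


def _effect_values(draws: PosteriorDraws, effect: EffectLike) -> np.ndarray:
    """Per-draw values of a coefficient, linear combination, or callable.

    ``effect`` may be a coefficient name or index, a weight vector defining
    a linear combination of the coefficients, or a callable mapping the
    (n_draws, p) coefficient matrix to per-draw values (for nonlinear
    transforms such as percent effect sizes).
    """
    if callable(effect):
        vals = np.asarray(effect(draws.coef), float)
    elif isinstance(effect, str):
        vals = draws.column(effect)
    elif isinstance(effect, (int, np.integer)):
        vals = draws.coef[:, int(effect)]
    else:
        w = np.asarray(effect, float)
        if w.shape != (draws.coef.shape[1],):
            raise ValueError(f"weight vector must have length {draws.coef.shape[1]}")
        vals = draws.coef @ w
    if vals.shape != (draws.n_draws,):
        raise ValueError("effect must produce one value per draw")
    return vals


def credible_interval(
    draws: PosteriorDraws, effect: EffectLike, level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed credible interval for an effect at the given level.

    Uses linear interpolation between order statistics (the type-7 quantile
    rule, numpy's default), so intervals are reproducible across platforms.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    vals = _effect_values(draws, effect)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(vals, [tail, 1.0 - tail])
    return float(lo), float(hi)


def posterior_probability(
    draws: PosteriorDraws, effect: EffectLike, direction: str = ">0"
) -> float:
    """Posterior probability that the effect is positive (or negative).

    Exact zeros count half toward each direction, so
    ``P(>0) + P(<0) = 1`` identically.
    """
    vals = _effect_values(draws, effect)
    gt = np.mean(vals > 0) + 0.5 * np.mean(vals == 0)
    if direction == ">0":
        return float(gt)
    if direction == "<0":
        return float(1.0 - gt)
    raise ValueError("direction must be '>0' or '<0'")
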