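"""Tiers 2 and 3: sympatric vs. allopatric mixed-model contrasts.

Tier 2 fits, separately for each species, a linear mixed model of raw
biomass on garden identity and the sympatry indicator (fixed effects) with
ecotype identity as a random intercept — the random term corrects for the
*variance* of intrinsic ecotype quality without absorbing its mean, which
is the relevant correction when the question is which seed material to use
rather than which evolutionary process acted.  The effect size is reported
as the percentage biomass difference of sympatric relative to allopatric
plants, where the allopatric baseline is the model-fitted mean over all
allopatric garden × ecotype combinations.

Tier 3 pools all species: biomasses are first standardized within species
(mean 0, SD 1), then a single model with garden + sympatry fixed effects
and a random intercept per ecotype-within-species composite group is fit;
its sympatry coefficient is the cross-species effect in SD units.

Both tiers draw their uncertainty statements from posterior simulation
(:mod:`.posterior_inference`): a posterior probability of a positive
sympatry effect above 0.95 is evidence of local adaptation, below 0.05
evidence of maladaptation, anything else inconclusive.

The module also provides the resampling check that equalizes statistical
power between tiers: the cross-species model is refit many times on
subsamples of the size of a single-species dataset, and the fraction of
refits whose sympatry effect is positive is reported.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design_and_io import TransplantDataset
from .lmm_engine import LmmSpec, MixedModelFit, fit_lmm, predict_fixed
from .posterior_inference import (
    PosteriorDraws,
    credible_interval,
    posterior_probability,
    simulate_posterior,
)

__all__ = [
    "AdaptationVerdict",
    "SympatryResult",
    "ResampleReport",
    "add_sympatry",
    "standardize_within_species",
    "analyze_species",
    "analyze_all_species",
    "conditional_r2",
    "resample_power_check",
    "largest_species_n",
    "results_frame",
]

SYMPATRY_COL = "sympatric"
COMPOSITE_COL = "species_ecotype"

#: Posterior-probability thresholds for the evidence verdict.
ADAPTATION_THRESHOLD = 0.95
MALADAPTATION_THRESHOLD = 0.05


class AdaptationVerdict(enum.Enum):
    LOCAL_ADAPTATION = "LOCAL_ADAPTATION"
    MALADAPTATION = "MALADAPTATION"
    INCONCLUSIVE = "INCONCLUSIVE"


def _verdict(posterior_prob: float) -> AdaptationVerdict:
    if posterior_prob > ADAPTATION_THRESHOLD:
        return AdaptationVerdict.LOCAL_ADAPTATION
    if posterior_prob < MALADAPTATION_THRESHOLD:
        return AdaptationVerdict.MALADAPTATION
    return AdaptationVerdict.INCONCLUSIVE


@dataclass(frozen=True)
class SympatryResult:
    """Sympatric/allopatric contrast for one species or the pooled analysis.

    ``effect_size_percent`` is the percentage biomass difference sympatric
    vs. allopatric (single-species scope, raw grams);
    ``effect_size_standardized`` is the sympatry coefficient in
    within-species SD units (cross-species scope).  The credible interval
    is equal-tailed at 95% on whichever effect scale the scope reports.
    """

    scope: str  # species id or "ALL"
    effect_size_percent: float | None
    effect_size_standardized: float | None
    credible_interval: tuple[float, float]
    posterior_probability: float
    conditional_r2: float
    verdict: AdaptationVerdict
    n_obs: int
    n_draws: int
    seed: int
    fit: MixedModelFit = field(repr=False, compare=False)
    draws: PosteriorDraws = field(repr=False, compare=False)


@dataclass(frozen=True)
class ResampleReport:
    """Outcome of the power-equalizing resampling of the cross-species model."""

    n_permutations: int
    target_n: int
    n_positive: int
    proportion_positive: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "target_n": self.target_n,
            "n_positive": self.n_positive,
            "proportion_positive": self.proportion_positive,
            "seed": self.seed,
        }


def add_sympatry(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with the 0/1 sympatry indicator column added."""
    out = df.copy()
    out[SYMPATRY_COL] = (out["ecotype"] == out["garden"]).astype(int)
    return out


def standardize_within_species(ds: TransplantDataset) -> pd.DataFrame:
    """Standardize biomass to mean 0, SD 1 within each species.

    Returns the records as a DataFrame with an added ``biomass_std`` column
    (sample SD, n−1 denominator); missing biomass stays missing.  Raises
    ``ValueError`` for a species with fewer than two measured plants or
    zero within-species SD.
    """
    df = ds.df
    out = df.copy()
    out["biomass_std"] = np.nan
    for sp, grp in df.groupby("species", sort=False):
        vals = grp["biomass"].dropna()
        if len(vals) < 2:
            raise ValueError(f"species {sp!r} has {len(vals)} measured plant(s); need >= 2")
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"species {sp!r} has zero biomass SD; cannot standardize")
        out.loc[grp.index, "biomass_std"] = (grp["biomass"] - float(vals.mean())) / sd
    return out


def _allopatric_grid(regions: tuple[str, ...]) -> pd.DataFrame:
    rows = [
        {"garden": g, "ecotype": e, SYMPATRY_COL: 0}
        for g in regions
        for e in regions
        if e != g
    ]
    return pd.DataFrame(rows)


def _percent_effect(fit: MixedModelFit, grid: pd.DataFrame):
    """Percent sympatry effect as a function of a coefficient vector/matrix.

    Baseline = model-fitted mean biomass over all allopatric garden ×
    ecotype combinations; effect = 100 * beta_sympatry / baseline.  Keeping
    the baseline a function of the coefficients makes the percent effect a
    pure model functional, propagated draw-by-draw through the posterior.
    """
    j = fit.beta_names.index(SYMPATRY_COL)

    def percent(coef: np.ndarray) -> np.ndarray:
        coef = np.asarray(coef, float)
        pred = predict_fixed(fit, grid, beta=coef)  # (n_cells,) or (n_cells, n_draws)
        baseline = pred.mean(axis=0)
        symp = coef[..., j]
        return 100.0 * symp / baseline

    return percent


def conditional_r2(fit: MixedModelFit, fixed_predictions: np.ndarray) -> float:
    """Approximate conditional R² of a random-intercept mixed model.

    Variance explained by fixed plus random effects as a share of the
    total:

        (var_f + sigma2_group) / (var_f + sigma2_group + sigma2_resid)

    where ``var_f`` is the sample variance of the fixed-effect predicted
    values over the fitted rows.  Returns 0 by convention when all three
    variance terms are zero.
    """
    var_f = float(np.var(np.asarray(fixed_predictions, float), ddof=1)) if len(
        fixed_predictions
    ) > 1 else 0.0
    num = var_f + fit.sigma2_group
    den = num + fit.sigma2_resid
    return 0.0 if den == 0.0 else num / den


def analyze_species(
    ds: TransplantDataset,
    species: str,
    n_draws: int = 10_000,
    seed: int = 0,
    method: str = "REML",
) -> SympatryResult:
    """Tier-2 sympatric/allopatric analysis of one species.

    Fits the raw-biomass mixed model (garden + sympatry fixed, ecotype
    random), then reports the percent effect size with its 95% credible
    interval, the posterior probability of a sympatric advantage, the
    conditional R², and the evidence verdict.
    """
    regions = tuple(sorted(ds.species_regions[species]))
    if len(regions) < 2:
        raise ValueError(f"species {species!r} has < 2 regions; no contrast possible")
    df = add_sympatry(ds.df)
    sub = df[df["species"] == species]
    spec = LmmSpec("biomass", ("garden", SYMPATRY_COL), "ecotype", method)
    fit = fit_lmm(sub, spec)
    draws = simulate_posterior(fit, n_draws=n_draws, seed=seed)

    grid = _allopatric_grid(regions)
    percent = _percent_effect(fit, grid)
    est = float(percent(fit.beta))
    ci = credible_interval(draws, percent, level=0.95)
    pp = posterior_probability(draws, SYMPATRY_COL, ">0")
    fitted_rows = sub[sub["biomass"].notna()]
    cr2 = conditional_r2(fit, predict_fixed(fit, fitted_rows))
    return SympatryResult(
        scope=species,
        effect_size_percent=est,
        effect_size_standardized=None,
        credible_interval=ci,
        posterior_probability=pp,
        conditional_r2=cr2,
        verdict=_verdict(pp),
        n_obs=fit.n_obs,
        n_draws=n_draws,
        seed=seed,
        fit=fit,
        draws=draws,
    )


def analyze_all_species(
    ds: TransplantDataset,
    n_draws: int = 10_000,
    seed: int = 0,
    method: str = "REML",
) -> SympatryResult:
    """Tier-3 cross-species sympatric/allopatric analysis.

    Standardizes biomass within species, then fits one mixed model with
    garden + sympatry fixed effects and a random intercept for each
    ecotype-within-species group.  The sympatry coefficient is the general
    local-adaptation effect in within-species SD units.
    """
    if len(ds.species) < 2:
        raise ValueError("cross-species analysis needs >= 2 species")
    df = add_sympatry(standardize_within_species(ds))
    df[COMPOSITE_COL] = df["species"] + ":" + df["ecotype"]
    spec = LmmSpec("biomass_std", ("garden", SYMPATRY_COL), COMPOSITE_COL, method)
    fit = fit_lmm(df, spec)
    draws = simulate_posterior(fit, n_draws=n_draws, seed=seed)
    est = fit.coef(SYMPATRY_COL)
    ci = credible_interval(draws, SYMPATRY_COL, level=0.95)
    pp = posterior_probability(draws, SYMPATRY_COL, ">0")
    fitted_rows = df[df["biomass_std"].notna()]
    cr2 = conditional_r2(fit, predict_fixed(fit, fitted_rows))
    return SympatryResult(
        scope="ALL",
        effect_size_percent=None,
        effect_size_standardized=est,
        credible_interval=ci,
        posterior_probability=pp,
        conditional_r2=cr2,
        verdict=_verdict(pp),
        n_obs=fit.n_obs,
        n_draws=n_draws,
        seed=seed,
        fit=fit,
        draws=draws,
    )


def largest_species_n(ds: TransplantDataset) -> int:
    """Measured-plant count of the largest single-species dataset."""
    df = ds.df
    return int(df[df["biomass"].notna()].groupby("species").size().max())


def resample_power_check(
    ds: TransplantDataset,
    target_n: int | None = None,
    n_permutations: int = 10_000,
    seed: int = 0,
    max_redraws: int = 100,
) -> ResampleReport:
    """Equalize power: refit the cross-species model on subsamples.

    Each permutation draws ``target_n`` measured rows without replacement
    from the standardized cross-species dataset — stratified by species in
    proportion to the original counts, so no species vanishes — refits the
    model by ML (comparable likelihoods across subsamples), and records
    whether the sympatry coefficient is positive.  ``target_n`` defaults to
    the size of the largest single-species dataset, i.e. the sample size a
    tier-2 model has to work with.

    A subsample leaving fewer than two random-effect groups is redrawn, at
    most ``max_redraws`` times per permutation before an error suggests a
    larger ``target_n``.
    """
    if target_n is None:
        target_n = largest_species_n(ds)
    df = add_sympatry(standardize_within_species(ds))
    df[COMPOSITE_COL] = df["species"] + ":" + df["ecotype"]
    df = df[df["biomass_std"].notna()].reset_index(drop=True)
    if target_n > len(df):
        raise ValueError(f"target_n={target_n} exceeds {len(df)} measured rows")

    # proportional stratified allocation, largest-remainder rounding
    counts = df.groupby("species", sort=False).size()
    exact = counts / counts.sum() * target_n
    alloc = np.floor(exact).astype(int)
    remainder = exact - alloc
    short = target_n - int(alloc.sum())
    for sp in remainder.sort_values(ascending=False).index[:short]:
        alloc[sp] += 1
    indices = {sp: df.index[df["species"] == sp].to_numpy() for sp in counts.index}

    spec = LmmSpec("biomass_std", ("garden", SYMPATRY_COL), COMPOSITE_COL, "ML")
    rng = np.random.default_rng(seed)
    n_positive = 0
    for _ in range(n_permutations):
        for attempt in range(max_redraws + 1):
            take = np.concatenate(
                [rng.choice(indices[sp], size=alloc[sp], replace=False) for sp in counts.index]
            )
            sub = df.loc[take]
            if sub[COMPOSITE_COL].nunique() >= 2:
                break
        else:
            raise ValueError(
                f"could not draw a subsample with >= 2 random-effect groups in "
                f"{max_redraws} redraws; increase target_n"
            )
        fit = fit_lmm(sub, spec)
        if fit.coef(SYMPATRY_COL) > 0:
            n_positive += 1
    return ResampleReport(
        n_permutations=n_permutations,
        target_n=int(target_n),
        n_positive=n_positive,
        proportion_positive=n_positive / n_permutations,
        seed=seed,
    )


def results_frame(results: list[SympatryResult]) -> pd.DataFrame:
    """Tidy effect-size table (one row per analysis scope) for CSV export."""
    rows = []
    for r in results:
        rows.append(
            {
                "scope": r.scope,
                "effect_size_percent": r.effect_size_percent,
                "effect_size_standardized": r.effect_size_standardized,
                "ci_lower": r.credible_interval[0],
                "ci_upper": r.credible_interval[1],
                "posterior_probability": r.posterior_probability,
                "conditional_r2": r.conditional_r2,
                "verdict": r.verdict.value,
                "n_obs": r.n_obs,
                "n_draws": r.n_draws,
                "seed": r.seed,
            }
        )
    return pd.DataFrame(rows)
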