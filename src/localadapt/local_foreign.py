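"""Tier 1: strict local-vs-foreign classification per garden × species cell.

Within one garden and one species, a one-way linear model compares the mean
biomass of the ecotypes planted there, followed by Tukey all-pairwise
comparisons (studentized-range adjustment, Tukey–Kramer form under unequal
group sizes).  A cell supports the "local is best" paradigm only when the
local ecotype's mean is *significantly higher than every* nonlocal ecotype;
it supports "nonlocal is best" (maladaptation) when *at least one* nonlocal
ecotype significantly outperforms the local one.  Everything else is "no
difference".  The asymmetry of the rule — all pairs must be won to accept,
a single loss suffices to reject — makes this by far the most conservative
of the three tiers.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._studentized_range import sr_sf
from .design_and_io import DesignError, TransplantDataset

__all__ = [
    "Verdict",
    "CellFit",
    "PairwiseComparison",
    "PairwiseComparisonTable",
    "CellVerdict",
    "fit_cell",
    "tukey_pairwise",
    "classify_cell",
    "run_local_foreign",
    "verdicts_frame",
]

DEFAULT_ALPHA = 0.05


class Verdict(enum.Enum):
    LOCAL_IS_BEST = "LOCAL_IS_BEST"
    NONLOCAL_IS_BEST = "NONLOCAL_IS_BEST"
    NO_DIFFERENCE = "NO_DIFFERENCE"


@dataclass(frozen=True)
class CellFit:
    """One-way fit of biomass on ecotype within a single garden × species cell."""

    species: str
    garden: str
    ecotype_means: Mapping[str, float]
    ecotype_n: Mapping[str, int]
    residual_variance: float  # pooled within-group variance, grams^2
    residual_df: int  # n - k
    r_squared: float  # between-group SS / total SS (0 when total SS is 0)


@dataclass(frozen=True)
class PairwiseComparison:
    ecotype_a: str
    ecotype_b: str
    mean_difference: float  # mean_a - mean_b, grams
    p_adjusted: float


@dataclass(frozen=True)
class PairwiseComparisonTable:
    """All k(k-1)/2 Tukey-adjusted ecotype contrasts within one cell."""

    species: str
    garden: str
    comparisons: tuple[PairwiseComparison, ...]
    alpha: float

    def lookup(self, a: str, b: str) -> PairwiseComparison:
        """Comparison for the unordered pair {a, b}, oriented as a - b."""
        for c in self.comparisons:
            if (c.ecotype_a, c.ecotype_b) == (a, b):
                return c
            if (c.ecotype_a, c.ecotype_b) == (b, a):
                return PairwiseComparison(a, b, -c.mean_difference, c.p_adjusted)
        raise KeyError(f"no comparison for pair ({a}, {b})")

    @property
    def ecotypes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.comparisons:
            seen.setdefault(c.ecotype_a)
            seen.setdefault(c.ecotype_b)
        return tuple(seen)


@dataclass(frozen=True)
class CellVerdict:
    species: str
    garden: str
    verdict: Verdict
    local_ecotype: str
    n_significant_pairs: int
    supporting: tuple[PairwiseComparison, ...] = ()


def fit_cell(ds: TransplantDataset, species: str, garden: str) -> CellFit:
    """One-way model of biomass on ecotype for one garden × species cell.

    Group means are the per-ecotype arithmetic means, the residual variance
    is the pooled within-group variance, and R² is the between-group share
    of the total sum of squares (0 by convention when all observations are
    identical).  Missing biomass rows are excluded (complete case).

    Raises
    ------
    DesignError
        Fewer than two ecotypes in the cell, or an ecotype with fewer than
        two measured plants (no within-group variance estimate).
    """
    df = ds.df
    sub = df[(df["species"] == species) & (df["garden"] == garden) & df["biomass"].notna()]
    if sub.empty:
        raise DesignError(f"no measured plants for species {species!r} in garden {garden!r}")
    groups = {e: g["biomass"].to_numpy() for e, g in sub.groupby("ecotype", sort=False)}
    if len(groups) < 2:
        raise DesignError(
            f"cell ({species!r}, {garden!r}) has {len(groups)} ecotype(s); need >= 2"
        )
    for e, v in groups.items():
        if len(v) < 2:
            raise DesignError(
                f"ecotype {e!r} in cell ({species!r}, {garden!r}) has {len(v)} "
                "measured plant(s); need >= 2"
            )
    means = {e: float(v.mean()) for e, v in groups.items()}
    ns = {e: int(len(v)) for e, v in groups.items()}
    n = sum(ns.values())
    k = len(groups)
    ss_within = sum(float(((v - means[e]) ** 2).sum()) for e, v in groups.items())
    grand = float(sub["biomass"].mean())
    ss_between = sum(ns[e] * (means[e] - grand) ** 2 for e in groups)
    ss_total = ss_within + ss_between
    return CellFit(
        species=species,
        garden=garden,
        ecotype_means=means,
        ecotype_n=ns,
        residual_variance=ss_within / (n - k),
        residual_df=n - k,
        r_squared=0.0 if ss_total == 0 else ss_between / ss_total,
    )


def tukey_pairwise(fit: CellFit, alpha: float = DEFAULT_ALPHA) -> PairwiseComparisonTable:
    """Tukey all-pairwise ecotype comparisons for one fitted cell.

    For the pair (a, b) the statistic is the Tukey–Kramer studentized range

        q_obs = |mean_a - mean_b| / sqrt(s^2 / 2 * (1/n_a + 1/n_b))

    referred to the studentized-range distribution with ``k`` groups and the
    cell's residual degrees of freedom.  With equal group sizes this is the
    classical Tukey HSD; the Kramer form handles groups thinned by
    mortality.  A degenerate cell with zero residual variance reports
    ``p = 0`` for unequal means and ``p = 1`` for exactly equal ones.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if fit.residual_df < 1:
        raise ValueError("tukey_pairwise needs residual_df >= 1")
    ecotypes = list(fit.ecotype_means)
    k = len(ecotypes)
    pairs = list(itertools.combinations(ecotypes, 2))
    diffs = np.array([fit.ecotype_means[a] - fit.ecotype_means[b] for a, b in pairs])
    if fit.residual_variance > 0:
        se = np.array(
            [
                np.sqrt(
                    fit.residual_variance / 2.0 * (1.0 / fit.ecotype_n[a] + 1.0 / fit.ecotype_n[b])
                )
                for a, b in pairs
            ]
        )
        q_obs = np.abs(diffs) / se
        p_adj = np.atleast_1d(sr_sf(q_obs, k, fit.residual_df))
    else:
        p_adj = np.where(diffs == 0.0, 1.0, 0.0)
    comparisons = tuple(
        PairwiseComparison(a, b, float(d), float(p))
        for (a, b), d, p in zip(pairs, diffs, p_adj)
    )
    return PairwiseComparisonTable(fit.species, fit.garden, comparisons, alpha)


def classify_cell(pairs: PairwiseComparisonTable, local_ecotype: str) -> CellVerdict:
    """Apply the strict local/foreign rule to one cell's pairwise table.

    * ``LOCAL_IS_BEST`` — the local ecotype's mean is greater than that of
      every nonlocal ecotype and every one of those comparisons is
      significant at the table's alpha.
    * ``NONLOCAL_IS_BEST`` — at least one nonlocal ecotype has a greater
      mean than the local one with a significant comparison.
    * ``NO_DIFFERENCE`` — anything else.

    The first two outcomes are mutually exclusive by construction.
    """
    ecotypes = pairs.ecotypes
    if local_ecotype not in ecotypes:
        raise KeyError(f"local ecotype {local_ecotype!r} not in comparison table {ecotypes}")
    nonlocal_es = [e for e in ecotypes if e != local_ecotype]
    vs_local = [pairs.lookup(local_ecotype, e) for e in nonlocal_es]
    n_sig = sum(c.p_adjusted < pairs.alpha for c in pairs.comparisons)

    local_wins = [c for c in vs_local if c.mean_difference > 0 and c.p_adjusted < pairs.alpha]
    local_losses = [c for c in vs_local if c.mean_difference < 0 and c.p_adjusted < pairs.alpha]
    if local_losses:
        verdict, support = Verdict.NONLOCAL_IS_BEST, tuple(local_losses)
    elif len(local_wins) == len(nonlocal_es):
        verdict, support = Verdict.LOCAL_IS_BEST, tuple(local_wins)
    else:
        verdict, support = Verdict.NO_DIFFERENCE, ()
    return CellVerdict(
        species=pairs.species,
        garden=pairs.garden,
        verdict=verdict,
        local_ecotype=local_ecotype,
        n_significant_pairs=int(n_sig),
        supporting=support,
    )


@dataclass(frozen=True)
class CellOutcome:
    """Result (or skip reason) of the tier-1 analysis for one cell."""

    species: str
    garden: str
    verdict: Verdict | None
    r_squared: float | None = None
    n_significant_pairs: int | None = None
    skipped_reason: str | None = None
    table: PairwiseComparisonTable | None = field(default=None, repr=False)


def run_local_foreign(
    ds: TransplantDataset, alpha: float = DEFAULT_ALPHA
) -> dict[tuple[str, str], CellOutcome]:
    """Tier-1 analysis of every species × garden cell in the dataset.

    The local ecotype of a cell is the one whose origin region equals the
    garden region.  Cells that fail the fit preconditions (too few ecotypes
    or replicates, or no local ecotype planted) are reported as skipped with
    the reason rather than aborting the run.
    """
    out: dict[tuple[str, str], CellOutcome] = {}
    df = ds.df
    for (sp, g), _ in df.groupby(["species", "garden"], sort=False):
        try:
            fit = fit_cell(ds, sp, g)
            table = tukey_pairwise(fit, alpha=alpha)
            if g not in fit.ecotype_means:
                raise DesignError(f"local ecotype {g!r} absent from cell ({sp!r}, {g!r})")
            cv = classify_cell(table, local_ecotype=g)
        except (DesignError, KeyError) as exc:
            out[(sp, g)] = CellOutcome(sp, g, verdict=None, skipped_reason=str(exc))
            continue
        out[(sp, g)] = CellOutcome(
            sp,
            g,
            verdict=cv.verdict,
            r_squared=fit.r_squared,
            n_significant_pairs=cv.n_significant_pairs,
            table=table,
        )
    return out


def verdicts_frame(results: Mapping[tuple[str, str], CellOutcome]) -> pd.DataFrame:
    """Tidy verdict table (one row per cell) for CSV export."""
    rows = []
    for (sp, g), oc in results.items():
        rows.append(
            {
                "species": sp,
                "garden": g,
                "verdict": oc.verdict.value if oc.verdict else "SKIPPED",
                "n_significant_pairs": oc.n_significant_pairs,
                "r_squared": oc.r_squared,
                "skipped_reason": oc.skipped_reason,
            }
        )
    return pd.DataFrame(rows)
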