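"""Data model and CSV input/output for reciprocal-transplant biomass records.

A reciprocal transplant experiment grows plant ecotypes (seed origins, named
after their source region) in gardens placed in those same regions.  Each row
of the tidy input table is one measured plant: which species, which garden
region it grew in, which region its seeds came from, a replicate label, and
its aboveground dry biomass in grams (the fitness proxy).  A plant is
*sympatric* (local) when its ecotype region equals its garden region and
*allopatric* (foreign) otherwise.

The module provides the validated in-memory container
(:class:`TransplantDataset`, a thin wrapper around a pandas DataFrame),
CSV read/write, the reduction of an arbitrary origin set to a *full
reciprocal design* (only ecotypes whose home region hosts a garden), and
design summaries (cell and plant counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ParseError",
    "DesignError",
    "TransplantRecord",
    "TransplantDataset",
    "DesignSummary",
    "read_dataset",
    "write_dataset",
    "simplify_to_full_reciprocal",
    "summarize_design",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = ("species", "garden", "ecotype", "replicate", "biomass")

#: String written for a missing biomass value (dead or unmeasured plant).
MISSING_TOKEN = "NA"


class SchemaError(ValueError):
    """Input table lacks a required column or has an unusable layout."""


class ParseError(ValueError):
    """A cell could not be parsed (reported with its row number)."""


class DesignError(ValueError):
    """The experimental design cannot support the requested analysis."""


@dataclass(frozen=True)
class TransplantRecord:
    """One measured plant.

    ``biomass`` is dry aboveground biomass in grams; ``None`` marks a plant
    with no usable measurement (e.g. it died before harvest).  When present
    the value is strictly positive and finite.
    """

    species: str
    garden: str
    ecotype: str
    replicate: int
    biomass: float | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be a positive integer, got {self.replicate}")
        if self.biomass is not None:
            if not np.isfinite(self.biomass) or self.biomass <= 0:
                raise ValueError(
                    f"biomass must be positive and finite or None, got {self.biomass}"
                )

    @property
    def sympatric(self) -> bool:
        """True when the plant grows in its region of origin."""
        return self.ecotype == self.garden


class TransplantDataset:
    """Validated collection of transplant records.

    Parameters
    ----------
    df
        DataFrame with columns ``species, garden, ecotype, replicate,
        biomass``.  ``biomass`` may contain NaN for dead/unmeasured plants;
        all present values must be positive and finite.
    regions
        Optional ordered region vocabulary.  When omitted it is inferred as
        the union of garden and ecotype values in order of first appearance.
    """

    def __init__(self, df: pd.DataFrame, regions: Sequence[str] | None = None) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in ("species", "garden", "ecotype"):
            df[col] = df[col].astype(str)
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            bad = df.index[df["replicate"] < 1][0]
            raise ValueError(f"replicate must be >= 1 (row {bad})")
        df["biomass"] = df["biomass"].astype(float)
        present = df["biomass"].notna()
        vals = df.loc[present, "biomass"]
        if ((vals <= 0) | ~np.isfinite(vals)).any():
            bad = vals.index[(vals <= 0) | ~np.isfinite(vals)][0]
            raise ValueError(f"biomass must be positive and finite (row {bad})")
        df = df.reset_index(drop=True)

        if regions is None:
            seen: dict[str, None] = {}
            for v in pd.concat([df["garden"], df["ecotype"]]):
                seen.setdefault(v, None)
            regions = tuple(seen)
        else:
            regions = tuple(dict.fromkeys(str(r) for r in regions))
            observed = set(df["garden"]) | set(df["ecotype"])
            unknown = observed - set(regions)
            if unknown:
                raise ValueError(f"garden/ecotype value(s) outside region vocabulary: {sorted(unknown)}")

        self._df = df
        self._regions: tuple[str, ...] = tuple(regions)

    # -- accessors -----------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """The underlying records as a DataFrame (copy)."""
        return self._df.copy()

    @property
    def regions(self) -> tuple[str, ...]:
        return self._regions

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self._df["species"]))

    @property
    def species_regions(self) -> dict[str, frozenset[str]]:
        """Map species -> regions with an available ecotype of that species."""
        out: dict[str, frozenset[str]] = {}
        for sp, grp in self._df.groupby("species", sort=False):
            out[sp] = frozenset(grp["ecotype"])
        return out

    @property
    def records(self) -> list[TransplantRecord]:
        recs = []
        for row in self._df.itertuples(index=False):
            b = None if pd.isna(row.biomass) else float(row.biomass)
            recs.append(
                TransplantRecord(row.species, row.garden, row.ecotype, int(row.replicate), b)
            )
        return recs

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransplantDataset):
            return NotImplemented
        return self._regions == other._regions and self._df.equals(other._df)

    def __repr__(self) -> str:
        return (
            f"TransplantDataset({len(self)} records, "
            f"{len(self.species)} species, {len(self._regions)} regions)"
        )


def read_dataset(path, column_map: Mapping[str, str] | None = None) -> TransplantDataset:
    """Read a tidy transplant CSV into a validated :class:`TransplantDataset`.

    Parameters
    ----------
    path
        CSV file with a header row.  Expected columns ``species, garden,
        ecotype, replicate, biomass``; ``column_map`` translates canonical
        names to the file's actual column names, e.g. ``{"biomass": "agb_g"}``.
    column_map
        Optional mapping canonical name -> file column name.

    Notes
    -----
    Missing biomass is written/read as ``NA`` or an empty cell.  Rows whose
    biomass is missing or nonpositive are retained with biomass flagged
    missing (a dead plant carries design information even without a
    measurement); non-numeric biomass text raises :class:`ParseError` with
    the offending row number.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    rename = {}
    for canon in REQUIRED_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise SchemaError(f"cannot map required column '{canon}' (looked for '{src}')")
        rename[src] = canon
    raw = raw.rename(columns=rename)

    biomass_txt = raw["biomass"].str.strip()
    is_missing = (biomass_txt == "") | (biomass_txt.str.upper() == MISSING_TOKEN)
    parsed = pd.to_numeric(biomass_txt.where(~is_missing), errors="coerce")
    bad = ~is_missing & parsed.isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ParseError(
            f"non-numeric biomass {biomass_txt.iloc[row]!r} at data row {row + 1}"
        )
    # nonpositive measurements carry no usable biomass: flag as missing
    parsed = parsed.where(parsed > 0)

    try:
        replicate = pd.to_numeric(raw["replicate"], errors="raise").astype(int)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"non-integer replicate value: {exc}") from exc

    df = pd.DataFrame(
        {
            "species": raw["species"],
            "garden": raw["garden"],
            "ecotype": raw["ecotype"],
            "replicate": replicate,
            "biomass": parsed.astype(float),
        }
    )
    return TransplantDataset(df)


def write_dataset(ds: TransplantDataset, path) -> None:
    """Write a dataset as tidy CSV (inverse of :func:`read_dataset`).

    Finite biomass values round-trip bit-exactly (written with ``repr``
    precision); missing biomass is written as ``NA``.
    """
    df = ds.df
    df["biomass"] = df["biomass"].map(lambda v: MISSING_TOKEN if pd.isna(v) else repr(float(v)))
    df.to_csv(path, index=False)


def simplify_to_full_reciprocal(
    ds: TransplantDataset, garden_regions: Iterable[str]
) -> TransplantDataset:
    """Reduce a dataset to a full reciprocal design over ``garden_regions``.

    Keeps, for each species, only records whose ecotype *and* garden lie in
    the intersection of ``garden_regions`` with the regions where that
    species has ecotypes.  After the reduction every retained species ×
    garden cell contains its local ecotype, which the local/foreign
    classification requires.  The operation is idempotent.

    Raises
    ------
    DesignError
        If a species retains fewer than two regions (no sympatric vs.
        allopatric contrast is possible for it).
    """
    garden_regions = tuple(dict.fromkeys(str(r) for r in garden_regions))
    unknown = set(garden_regions) - set(ds.regions)
    if unknown:
        raise DesignError(f"garden region(s) not in dataset vocabulary: {sorted(unknown)}")

    df = ds.df
    keep = np.zeros(len(df), dtype=bool)
    for sp, available in ds.species_regions.items():
        allowed = set(garden_regions) & set(available)
        if len(allowed) < 2:
            raise DesignError(
                f"species {sp!r} retains {len(allowed)} region(s) within "
                f"{garden_regions}; at least 2 are needed for a reciprocal contrast"
            )
        m = (df["species"] == sp) & df["ecotype"].isin(allowed) & df["garden"].isin(allowed)
        keep |= m.to_numpy()
    return TransplantDataset(df.loc[keep], regions=garden_regions)


@dataclass(frozen=True)
class DesignSummary:
    """Counts describing a (simplified) reciprocal-transplant design."""

    n_species: int
    n_gardens: int
    n_cells: int
    n_plants: int
    per_cell_counts: Mapping[tuple[str, str], Mapping[str, int]] = field(repr=False)


def summarize_design(ds: TransplantDataset) -> DesignSummary:
    """Summarize the design: species/garden/cell counts and measured plants.

    ``n_cells`` counts species × garden combinations present in the data;
    ``n_plants`` counts records with a non-missing biomass.  The per-cell
    table gives, for each cell, the number of measured plants per ecotype.
    """
    df = ds.df
    measured = df[df["biomass"].notna()]
    per_cell: dict[tuple[str, str], dict[str, int]] = {}
    for (sp, g), grp in measured.groupby(["species", "garden"], sort=False):
        per_cell[(sp, g)] = grp.groupby("ecotype", sort=False).size().to_dict()
    cells = df.groupby(["species", "garden"], sort=False).ngroups
    return DesignSummary(
        n_species=df["species"].nunique(),
        n_gardens=df["garden"].nunique(),
        n_cells=cells,
        n_plants=len(measured),
        per_cell_counts=per_cell,
    )
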