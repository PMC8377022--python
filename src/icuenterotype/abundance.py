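"""Abundance tables: reading, validation, normalisation, rank aggregation,
rarefaction and alpha diversity.

The in-memory substrate of the whole pipeline is :class:`AbundanceTable`, a
thin wrapper over a samples x taxa :class:`pandas.DataFrame` whose columns are
parallel to a list of :class:`~icuenterotype.taxonomy.TaxonLineage`.  Counts
and relative abundances are distinguished by an explicit ``mode`` flag so that
each stage can state its precondition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import RANKS, TaxonLineage

_ROW_SUM_TOL = 1e-9


@dataclass
class AbundanceTable:
    data: pd.DataFrame  # samples x taxa, columns are lineage strings
    lineages: tuple[TaxonLineage, ...]
    mode: str = "counts"  # {"counts", "relative"}

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxa: {dups}")
        if len(self.lineages) != self.data.shape[1]:
            raise ValueError("lineages not parallel to columns")
        values = self.data.to_numpy()
        if np.any(values < 0):
            raise ValueError("negative abundance values")
        if self.mode == "relative":
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-6
            if bad.any():
                raise ValueError(
                    f"relative rows not summing to 1: {self.data.index[bad].tolist()}"
                )

    # -- basic views ---------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.mode == other.mode
            and self.lineages == other.lineages
            and list(self.data.index) == list(other.data.index)
            and np.allclose(self.data.to_numpy(float), other.data.to_numpy(float))
        )


# -- construction ------------------------------------------------------------

def table_from_frame(frame: pd.DataFrame, mode: str | None = None) -> AbundanceTable:
    """Build a validated table from a samples x taxa frame whose column names
    are ';'-separated lineage strings.  ``mode`` is auto-detected from the
    values when not given (integral values => counts)."""
    lineages = tuple(TaxonLineage.from_string(str(c)) for c in frame.columns)
    values = frame.to_numpy(dtype=float)
    if mode is None:
        mode = "counts" if np.allclose(values, np.round(values)) else "relative"
    frame = frame.astype(float)
    frame.index = frame.index.astype(str)
    frame.columns = [str(l) for l in lineages]
    return AbundanceTable(frame, lineages, mode)


def read_abundance_table(
    path: str | Path,
    format: str = "tsv",
    samples_as_rows: bool = False,
    mode: str | None = None,
) -> AbundanceTable:
    """Read an abundance table from TSV (default) or BIOM 2.x HDF5.

    TSV layout: first column holds the lineage string (';' rank separator),
    remaining columns are samples — unless ``samples_as_rows``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if frame.empty or frame.shape[1] == 0:
            raise ValueError(f"malformed abundance table (no data columns): {path}")
        if not samples_as_rows:
            frame = frame.T
        return table_from_frame(frame, mode=mode)
    if format == "biom":
        from . import biom_io

        return biom_io.read_biom(path, mode=mode)
    raise ValueError(f"unknown format {format!r}")


def write_abundance_table(table: AbundanceTable, path: str | Path,
                          samples_as_rows: bool = False) -> None:
    frame = table.data if samples_as_rows else table.data.T
    frame.rename_axis("taxon" if not samples_as_rows else "sample_id").to_csv(
        path, sep="\t")


# -- transformations ---------------------------------------------------------

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Convert counts to relative abundances (idempotent on relative input)."""
    values = table.values()
    sums = values.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise ValueError(
            f"all-zero sample(s): {table.data.index[zero].tolist()}")
    frame = table.data.div(sums, axis=0)
    return AbundanceTable(frame, table.lineages, "relative")


def aggregate_to_rank(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Merge columns at ``rank``; unclassified taxa collapse onto their nearest
    classified ancestor with an asterisk.  Per-sample totals are conserved."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    groups: dict[str, list[str]] = {}
    group_lineage: dict[str, TaxonLineage] = {}
    for col, lin in zip(table.data.columns, table.lineages):
        label = lin.label_at(rank)
        groups.setdefault(label, []).append(col)
        trunc = lin.truncate(rank)
        prev = group_lineage.get(label)
        if prev is None or trunc.depth < prev.depth:
            group_lineage[label] = trunc
    agg = pd.DataFrame(
        {label: table.data[cols].sum(axis=1) for label, cols in groups.items()},
        index=table.data.index,
    )
    lineages = tuple(group_lineage[label] for label in agg.columns)
    agg.columns = [str(l) for l in lineages]
    return AbundanceTable(agg, lineages, table.mode)


def rarefy(table: AbundanceTable, depth: int, seed: int) -> AbundanceTable:
    """Subsample each sample's counts without replacement to exactly ``depth``
    reads (multivariate hypergeometric).  Samples shallower than ``depth`` are
    dropped with a warning."""
    if table.mode != "counts":
        raise ValueError("rarefaction requires a counts table")
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    counts = np.round(table.values()).astype(np.int64)
    totals = counts.sum(axis=1)
    keep, rows = [], []
    for i, sample in enumerate(table.data.index):
        if totals[i] < depth:
            warnings.warn(
                f"sample {sample!r} has {totals[i]} < {depth} reads; dropped "
                "from rarefied table", stacklevel=2)
            continue
        if totals[i] == depth:
            rows.append(counts[i])
        else:
            rows.append(rng.multivariate_hypergeometric(counts[i], depth))
        keep.append(sample)
    frame = pd.DataFrame(np.asarray(rows, dtype=float), index=keep,
                         columns=table.data.columns)
    return AbundanceTable(frame, table.lineages, "counts")


@dataclass(frozen=True)
class AlphaDiversity:
    sample_id: str
    observed_units: int
    shannon: float  # natural log


def shannon_index(p: np.ndarray) -> float:
    """Shannon entropy, natural log, of a (possibly unnormalised) nonnegative
    vector; zero entries contribute nothing."""
    p = np.asarray(p, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot compute Shannon index of an empty sample")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: AbundanceTable, depth: int, seed: int) -> list[AlphaDiversity]:
    """Observed taxa and Shannon index on the rarefied table."""
    rare = rarefy(table, depth, seed)
    out = []
    for sample, row in zip(rare.data.index, rare.values()):
        out.append(AlphaDiversity(
            sample_id=sample,
            observed_units=int((row > 0).sum()),
            shannon=shannon_index(row),
        ))
    return out


# -- clinical metadata -------------------------------------------------------

CLINICAL_COLUMNS = (
    "sample_id", "patient_id", "day", "status", "apache_ii", "sofa",
    "lactate", "carbapenem_use", "infection_site", "survival_28d",
)

STATUS_VALUES = {"sepsis", "septic_shock"}


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate per-sample clinical metadata (CSV or TSV), indexed by
    sample_id.  Extra numeric columns are carried through."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    meta = pd.read_csv(path, sep=sep)
    return validate_metadata(meta)


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("sample_id", "patient_id", "status") if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    bad_status = set(meta["status"].dropna()) - STATUS_VALUES
    if bad_status:
        raise ValueError(f"unknown status values: {sorted(bad_status)}")
    for col in ("apache_ii", "sofa", "lactate"):
        if col in meta.columns and (meta[col].dropna() < 0).any():
            raise ValueError(f"negative values in {col}")
    return meta.set_index(meta["sample_id"].astype(str), drop=False)


def first_samples(meta: pd.DataFrame) -> pd.DataFrame:
    """One record per patient: each patient's earliest-day sample (ties broken
    by sample id), mirroring a one-sample-per-subject association analysis."""
    meta = meta.reset_index(drop=True)
    meta = meta.sort_values(["patient_id", "day", "sample_id"])
    first = meta.groupby("patient_id", sort=False).head(1)
    first.index = first["sample_id"].astype(str)
    return first
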