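"""Enterotype-outcome association statistics.

Fisher's exact tests on 2x2 tables (severity- and lactate-stratified),
Mann-Whitney comparisons, a Pearson correlation matrix of z-scored clinical
parameters, and Mantel tests relating the microbiota distance matrix to
per-patient scalar clinical parameters (turned into distance matrices via
absolute differences of z-scores).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

from .enterotype import E1, E2

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable2x2:
    """Rows = outcome groups, columns = (ICU_E1, ICU_E2)."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group_1", "group_2")
    col_labels: tuple[str, str] = (E1, E2)

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def cells(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_dict(self) -> dict:
        return {"rows": self.row_labels, "cols": self.col_labels,
                "cells": self.cells.tolist()}


def fisher_exact(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test (point-probability convention: sums all
    hypergeometric tables no more probable than the observed one).  Returns
    (p, sample odds ratio; inf when b*c == 0 and a*d > 0)."""
    cells = table.cells
    odds, p = stats.fisher_exact(cells, alternative="two-sided")
    return float(p), float(odds)


@dataclass
class StratumResult:
    stratum: str
    table: ContingencyTable2x2 | None
    p: float | None
    odds_ratio: float | None

    def to_dict(self) -> dict:
        return {"stratum": self.stratum, "p": self.p, "odds_ratio": self.odds_ratio,
                "table": self.table.to_dict() if self.table else None}


def _status_by_enterotype(meta: pd.DataFrame, enterotypes: pd.Series,
                          stratum: str) -> StratumResult:
    status = meta["status"]
    ent = enterotypes.reindex(meta.index)
    counts = []
    for st in ("septic_shock", "sepsis"):
        sel = status == st
        counts.append([int(((ent == E1) & sel).sum()),
                       int(((ent == E2) & sel).sum())])
    (a, b), (c, d) = counts
    if a + b == 0 or c + d == 0:
        logger.warning("stratum %s has an empty outcome group; p undefined",
                       stratum)
        try:
            tab = ContingencyTable2x2(a, b, c, d, ("septic_shock", "sepsis"))
        except ValueError:
            tab = None
        return StratumResult(stratum, tab, None, None)
    tab = ContingencyTable2x2(a, b, c, d, ("septic_shock", "sepsis"))
    p, odds = fisher_exact(tab)
    return StratumResult(stratum, tab, p, odds)


def stratified_enterotype_test(meta: pd.DataFrame, enterotypes: pd.Series,
                               cutoff: float = 18.0) -> list[StratumResult]:
    """Fisher's exact test of septic shock vs enterotype, separately within
    the high-severity (APACHE II > cutoff) and low-severity strata."""
    meta = meta.dropna(subset=["apache_ii", "status"])
    high = meta[meta["apache_ii"] > cutoff]
    low = meta[meta["apache_ii"] <= cutoff]
    return [
        _status_by_enterotype(high, enterotypes, f"apache_ii > {cutoff:g}"),
        _status_by_enterotype(low, enterotypes, f"apache_ii <= {cutoff:g}"),
    ]


def lactate_group_test(meta: pd.DataFrame, enterotypes: pd.Series,
                       cutoff: float = 2.5) -> StratumResult:
    """Fisher's exact test of lactate group (>= cutoff mM vs below) against
    enterotype, on one record per patient."""
    n_missing = int(meta["lactate"].isna().sum())
    if n_missing:
        logger.warning("excluding %d records with missing lactate", n_missing)
    meta = meta.dropna(subset=["lactate"])
    ent = enterotypes.reindex(meta.index)
    hi = meta["lactate"] >= cutoff
    a = int(((ent == E1) & hi).sum())
    b = int(((ent == E2) & hi).sum())
    c = int(((ent == E1) & ~hi).sum())
    d = int(((ent == E2) & ~hi).sum())
    tab = ContingencyTable2x2(a, b, c, d, (f"lactate >= {cutoff:g}",
                                           f"lactate < {cutoff:g}"))
    if a + b == 0 or c + d == 0:
        logger.warning("empty lactate group; p undefined")
        return StratumResult("lactate", tab, None, None)
    p, odds = fisher_exact(tab)
    return StratumResult("lactate", tab, p, odds)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact enumeration for small untied samples,
    tie-corrected normal approximation otherwise.  Returns (U of x, p)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def clinical_corr_matrix(meta: pd.DataFrame,
                         parameters: list[str]) -> pd.DataFrame:
    """Pearson correlation matrix of z-scored clinical parameters, pairwise
    deletion; zero-variance columns yield NaN and are flagged."""
    data = meta[parameters].apply(pd.to_numeric, errors="coerce")
    sd = data.std(ddof=0)
    flat = sd[sd == 0].index.tolist()
    if flat:
        logger.warning("zero-variance parameters, correlation undefined: %s",
                       flat)
    z = (data - data.mean()) / sd.replace(0, np.nan)
    corr = z.corr(method="pearson", min_periods=3)
    return corr


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    n: int

    def to_dict(self) -> dict:
        return {"r": self.r, "p": self.p, "n_perm": self.n_perm, "n": self.n}


def scalar_distance_matrix(values: pd.Series) -> DistanceMatrix:
    """Distance matrix of a scalar clinical parameter: absolute differences
    of z-scores."""
    v = pd.to_numeric(values, errors="coerce")
    if v.isna().any():
        raise ValueError("missing values in clinical parameter")
    sd = v.std(ddof=0)
    if sd == 0:
        raise ValueError("zero-variance clinical parameter")
    z = ((v - v.mean()) / sd).to_numpy()
    return DistanceMatrix(np.abs(z[:, None] - z[None, :]),
                          ids=[str(i) for i in values.index])


def mantel_test(d_micro: DistanceMatrix, parameter: pd.Series,
                n_perm: int = 9999, seed: int = 0) -> MantelResult:
    """One-sided (upper-tail) Mantel test of the microbiota distance matrix
    against the clinical-parameter distance matrix, p = (#{r_perm >= r} + 1)
    / (n_perm + 1)."""
    d_param = scalar_distance_matrix(parameter)
    ids = [i for i in d_micro.ids if i in set(d_param.ids)]
    if len(ids) != len(d_micro.ids) or len(ids) != len(d_param.ids):
        raise ValueError("sample ids of the two matrices do not match")
    r, p, n = _skbio_mantel(d_micro.filter(ids), d_param.filter(ids),
                            method="pearson", permutations=n_perm,
                            alternative="greater", seed=seed)
    if math.isnan(r):
        raise ValueError("Mantel statistic undefined (zero variance)")
    return MantelResult(r=float(r), p=float(p), n_perm=n_perm, n=n)


def association_battery(meta: pd.DataFrame, enterotypes: pd.Series,
                        d_micro: DistanceMatrix | None = None,
                        apache_cutoff: float = 18.0,
                        lactate_cutoff: float = 2.5,
                        parameters: tuple[str, ...] = ("apache_ii", "sofa",
                                                       "lactate"),
                        n_perm: int = 9999, seed: int = 0) -> dict:
    """The full association report: stratified shock tests on all samples,
    per-patient lactate grouping, Mann-Whitney parameter comparisons between
    enterotypes, the clinical correlation matrix, and per-enterotype Mantel
    tests of the microbiota distances against each parameter."""
    from .abundance import first_samples

    per_patient = first_samples(meta)
    ent = enterotypes.reindex(meta.index)
    ent_pp = enterotypes.reindex(per_patient.index)

    report: dict = {
        "stratified_shock": [r.to_dict() for r in stratified_enterotype_test(
            meta, enterotypes, apache_cutoff)],
        "lactate_group": lactate_group_test(
            per_patient, ent_pp, lactate_cutoff).to_dict(),
        "mann_whitney": {},
        "correlation_matrix": clinical_corr_matrix(
            per_patient, list(parameters)).to_dict(),
        "mantel": {},
    }
    for param in parameters:
        vals = pd.to_numeric(per_patient[param], errors="coerce")
        g1 = vals[(ent_pp == E1) & vals.notna()]
        g2 = vals[(ent_pp == E2) & vals.notna()]
        if len(g1) and len(g2):
            u, p = mann_whitney(g1, g2)
            report["mann_whitney"][param] = {"U": u, "p": p}
    if d_micro is not None:
        for ent_name in (E1, E2):
            ids = [s for s in per_patient.index
                   if ent_pp.get(s) == ent_name and s in set(d_micro.ids)]
            for param in parameters:
                vals = pd.to_numeric(per_patient.loc[ids, param],
                                     errors="coerce").dropna()
                if len(vals) < 4 or vals.std(ddof=0) == 0:
                    continue
                sub = d_micro.filter(list(vals.index))
                res = mantel_test(sub, vals, n_perm=n_perm, seed=seed)
                report["mantel"][f"{ent_name}:{param}"] = res.to_dict()
    return report
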