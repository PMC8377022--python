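"""Taxonomic biomarker selection for the two enterotypes.

Two stages, mirroring the common biomarker-discovery practice for microbiome
class comparisons:

1. an LDA effect-size procedure: a Kruskal-Wallis screen at ``alpha`` on
   per-sample abundances scaled to 1e6 within each rank, then a bootstrapped
   one-axis linear discriminant whose per-feature effect size is averaged over
   subsample rounds and reported as log10; features are retained above a
   log10-LDA gate (default 2.0);
2. greedy mRMR (MID variant) on the retained features of each enterotype,
   picking a fixed number (default 5) of mutually non-redundant markers using
   mutual information over 3-level discretised abundances.

Features are built jointly across ranks phylum -> genus, so a genus and its
phylum may both compete; redundancy between them is penalised by mRMR.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import mutual_info_score

from .abundance import AbundanceTable, aggregate_to_rank
from .enterotype import E1, E2
from .taxonomy import RANKS, TaxonLineage

logger = logging.getLogger(__name__)

FEATURE_RANKS = tuple(RANKS[1:])  # phylum ... genus
SCALE = 1e6


def multirank_features(table: AbundanceTable,
                       ranks=FEATURE_RANKS) -> tuple[pd.DataFrame, dict[str, TaxonLineage]]:
    """Per-sample feature matrix across ranks, each rank scaled to sum 1e6.

    Feature names are the truncated lineage strings, unique across ranks.
    """
    if table.mode != "relative":
        raise ValueError("feature construction requires relative abundances")
    blocks, lineages = [], {}
    for rank in ranks:
        agg = aggregate_to_rank(table, rank)
        block = agg.data * SCALE
        blocks.append(block)
        lineages.update(dict(zip(block.columns, agg.lineages)))
    return pd.concat(blocks, axis=1), lineages


@dataclass(frozen=True)
class LdaScoredTaxon:
    name: str
    taxon: TaxonLineage
    enriched_in: str  # ICU_E1 or ICU_E2
    kw_p: float
    lda_log10: float


def kruskal_wallis(values: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in np.unique(labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("Kruskal-Wallis needs >= 2 non-empty groups")
    if np.all(values == values[0]):
        return 0.0, 1.0
    stat, p = stats.kruskal(*groups)
    return float(stat), float(p)


def lda_effect_size(features: pd.DataFrame, labels: np.ndarray,
                    lineages: dict[str, TaxonLineage] | None = None,
                    alpha: float = 0.05, gate: float = 2.0,
                    n_boot: int = 30, subsample: float = 2 / 3,
                    seed: int = 0, max_retries: int = 100) -> list[LdaScoredTaxon]:
    """Score features by a bootstrapped linear-discriminant effect size and
    keep those with log10 score above ``gate``.

    The effect size of a feature is the mean, over ``n_boot`` class-stratified
    subsamples of fraction ``subsample``, of half the sum of (a) the absolute
    class-mean difference of the feature projected on the unit discriminant
    axis and (b) the absolute raw class-mean difference.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {list(classes)}")
    rng = np.random.default_rng(seed)

    # Kruskal-Wallis screen
    survivors = []
    kw_ps = {}
    for name in features.columns:
        _, p = kruskal_wallis(features[name].to_numpy(), labels)
        if p < alpha:
            survivors.append(name)
            kw_ps[name] = p
    if not survivors:
        return []

    x_all = features[survivors].to_numpy(float)
    y_all = (labels == classes[1]).astype(int)
    idx_by_class = [np.flatnonzero(y_all == c) for c in (0, 1)]
    effects = np.zeros((n_boot, len(survivors)))
    for b in range(n_boot):
        for _ in range(max_retries):
            take = np.concatenate([
                idx[rng.random(len(idx)) < subsample] for idx in idx_by_class])
            yb = y_all[take]
            if (yb == 0).sum() >= 2 and (yb == 1).sum() >= 2:
                break
        else:
            raise RuntimeError("could not draw a subsample with both classes")
        xb = x_all[take]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collinear features are expected
            lda = LinearDiscriminantAnalysis(solver="svd", n_components=1)
            lda.fit(xb, yb)
        w = lda.scalings_[:, 0]
        norm = np.linalg.norm(w)
        w = w / norm if norm > 0 else w
        mu_diff = xb[yb == 1].mean(axis=0) - xb[yb == 0].mean(axis=0)
        effects[b] = 0.5 * (np.abs(w * mu_diff) + np.abs(mu_diff))

    mean_effect = effects.mean(axis=0)
    out = []
    for j, name in enumerate(survivors):
        score = float(np.log10(max(mean_effect[j], 1.0)))
        if score <= gate:
            continue
        col = features[name].to_numpy(float)
        means = [col[labels == c].mean() for c in classes]
        enriched = str(classes[int(np.argmax(means))])
        lineage = (lineages or {}).get(name, TaxonLineage.from_string(name))
        out.append(LdaScoredTaxon(name=name, taxon=lineage, enriched_in=enriched,
                                  kw_p=kw_ps[name], lda_log10=score))
    out.sort(key=lambda t: (-t.lda_log10, t.name))
    return out


# -- mRMR --------------------------------------------------------------------

def discretize(values: np.ndarray) -> np.ndarray:
    """3-level discretisation at mean +/- 0.5 sd (the classical mRMR binning)."""
    values = np.asarray(values, float)
    mu, sd = values.mean(), values.std()
    out = np.ones(len(values), dtype=int)
    out[values < mu - 0.5 * sd] = 0
    out[values > mu + 0.5 * sd] = 2
    return out


def mrmr_select(candidates: pd.DataFrame, labels: np.ndarray,
                n_select: int = 5) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance (MID: relevance minus mean
    redundancy) over discretised features.  Deterministic: ties go to higher
    relevance, then lexicographically smaller feature name."""
    labels = np.asarray(labels)
    names = list(candidates.columns)
    if len(names) < n_select:
        logger.warning("only %d candidates for n_select=%d; returning all",
                       len(names), n_select)
    disc = {n: discretize(candidates[n].to_numpy()) for n in names}
    relevance = {n: mutual_info_score(labels, disc[n]) for n in names}

    selected: list[str] = []
    remaining = set(names)
    while remaining and len(selected) < n_select:
        def criterion(n: str) -> float:
            if not selected:
                return relevance[n]
            red = np.mean([mutual_info_score(disc[n], disc[s]) for s in selected])
            return relevance[n] - red

        best = min(remaining,
                   key=lambda n: (-criterion(n), -relevance[n], n))
        selected.append(best)
        remaining.discard(best)
    return selected


@dataclass
class BiomarkerSet:
    """The 2 x 5 non-redundant markers; e1_markers are the MHI numerator
    taxa S_i, e2_markers the denominator taxa S_j."""

    e1_markers: list[str]
    e2_markers: list[str]
    provenance: list[LdaScoredTaxon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.e1_markers) & set(self.e2_markers):
            raise ValueError("e1 and e2 marker sets overlap")

    @property
    def scores(self) -> dict[str, float]:
        return {t.name: t.lda_log10 for t in self.provenance
                if t.name in set(self.e1_markers) | set(self.e2_markers)}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"e1": self.e1_markers, "e2": self.e2_markers,
             "scores": self.scores}, indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "BiomarkerSet":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        obj = json.loads(text)
        prov = [LdaScoredTaxon(name=n, taxon=TaxonLineage.from_string(n),
                               enriched_in=E1 if n in obj["e1"] else E2,
                               kw_p=float("nan"),
                               lda_log10=obj.get("scores", {}).get(n, float("nan")))
                for n in obj["e1"] + obj["e2"]]
        return cls(list(obj["e1"]), list(obj["e2"]), prov)

    def to_table(self, path: str | Path | None = None) -> pd.DataFrame:
        rows = [{"taxon": n, "direction": d, "lda_log10": self.scores.get(n)}
                for d, markers in ((E1, self.e1_markers), (E2, self.e2_markers))
                for n in markers]
        frame = pd.DataFrame(rows)
        if path is not None:
            frame.to_csv(path, sep="\t", index=False)
        return frame


def build_biomarker_set(table: AbundanceTable, labels: np.ndarray,
                        alpha: float = 0.05, gate: float = 2.0,
                        n_boot: int = 30, subsample: float = 2 / 3,
                        n_select: int = 5, seed: int = 0) -> BiomarkerSet:
    """LDA effect-size scoring followed by per-enterotype mRMR selection."""
    labels = np.asarray(labels)
    features, lineages = multirank_features(table)
    scored = lda_effect_size(features, labels, lineages, alpha=alpha, gate=gate,
                             n_boot=n_boot, subsample=subsample, seed=seed)
    per_class: dict[str, list[str]] = {}
    for t in scored:
        per_class.setdefault(t.enriched_in, []).append(t.name)
    missing = [c for c in (E1, E2) if not per_class.get(c)]
    if missing:
        raise ValueError(
            f"no LDA-retained candidates enriched in {missing}; inspect the "
            "abundance table and partition before selecting biomarkers")
    selections = {
        cls_name: mrmr_select(features[cands], labels, n_select=n_select)
        for cls_name, cands in per_class.items()}
    return BiomarkerSet(e1_markers=selections[E1], e2_markers=selections[E2],
                        provenance=scored)
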