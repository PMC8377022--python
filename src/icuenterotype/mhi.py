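"""The microbial-based human index (MHI) and its threshold classifier.

For a sample with relative abundances ABU_r, the score is

    MHI = ( sum_i ABU_r(S_i) + eps ) / ( sum_j ABU_r(S_j) + eps )

with S_i the five enterotype-1 markers, S_j the five enterotype-2 markers and
eps = 1e-6 a stabiliser: a sample missing every denominator taxon still gets
a finite, large score (semantically E1) and a sample missing all ten markers
scores exactly 1 (uninformative).  The decision threshold is trained by a
fixed 1001-point sweep from the minimum to the maximum training score,
selecting the point that maximises Youden's J = sensitivity + specificity - 1
(E1 positive; smallest threshold on ties).  Scores strictly above the
threshold call ICU_E1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .abundance import AbundanceTable
from .biomarkers import SCALE, BiomarkerSet, multirank_features
from .enterotype import E1, E2

EPSILON = 1e-6
SWEEP_STEPS = 1000


def marker_abundances(table: AbundanceTable, names: list[str]) -> pd.DataFrame:
    """Relative abundances of (possibly multi-rank) marker features, resolved
    against the table; unresolvable markers contribute zero columns."""
    features, _ = multirank_features(table)
    features = features / SCALE
    out = pd.DataFrame(0.0, index=features.index, columns=names)
    for name in names:
        if name in features.columns:
            out[name] = features[name]
    return out


def mhi_scores(table: AbundanceTable, biomarkers: BiomarkerSet,
               epsilon: float = EPSILON) -> pd.Series:
    """Per-sample MHI score (index: sample_id)."""
    num = marker_abundances(table, biomarkers.e1_markers).sum(axis=1)
    den = marker_abundances(table, biomarkers.e2_markers).sum(axis=1)
    scores = (num + epsilon) / (den + epsilon)
    scores.name = "mhi_score"
    return scores


def matched_fraction(table: AbundanceTable, biomarkers: BiomarkerSet) -> float:
    """Fraction of the ten markers resolvable in the table's taxa."""
    features, _ = multirank_features(table)
    names = biomarkers.e1_markers + biomarkers.e2_markers
    return sum(n in features.columns for n in names) / len(names)


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "bi":
        return labels.astype(int)
    return (labels == E1).astype(int)


def train_threshold(scores: np.ndarray, labels) -> "MhiClassifier":
    """Sweep 1001 equally spaced thresholds over [min, max] of the training
    scores and keep the Youden-optimal one (ties -> smallest threshold)."""
    scores = np.asarray(scores, float)
    y = _as_binary(labels)
    if y.min() == y.max():
        raise ValueError("threshold training needs both enterotypes present")
    lo, hi = scores.min(), scores.max()
    if hi <= lo:
        raise ValueError("degenerate scores: zero range, cannot sweep")
    grid = lo + (hi - lo) * np.arange(SWEEP_STEPS + 1) / SWEEP_STEPS
    calls = scores[None, :] > grid[:, None]
    sens = (calls & (y == 1)).sum(axis=1) / (y == 1).sum()
    spec = (~calls & (y == 0)).sum(axis=1) / (y == 0).sum()
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first occurrence = smallest threshold
    return MhiClassifier(threshold=float(grid[best]),
                         train_sensitivity=float(sens[best]),
                         train_specificity=float(spec[best]))


@dataclass
class MhiClassifier:
    """Trained decision threshold, optionally carrying its biomarker set."""

    threshold: float
    train_sensitivity: float | None = None
    train_specificity: float | None = None
    biomarkers: BiomarkerSet | None = None

    @classmethod
    def fit(cls, table: AbundanceTable, labels, biomarkers: BiomarkerSet,
            epsilon: float = EPSILON) -> "MhiClassifier":
        scores = mhi_scores(table, biomarkers, epsilon)
        clf = train_threshold(scores.to_numpy(), labels)
        clf.biomarkers = biomarkers
        return clf

    def classify(self, scores) -> np.ndarray:
        """Strictly-above-threshold scores call ICU_E1, the rest ICU_E2."""
        scores = np.asarray(scores, float)
        return np.where(scores > self.threshold, E1, E2)

    def classify_table(self, table: AbundanceTable) -> pd.DataFrame:
        if self.biomarkers is None:
            raise ValueError("classifier carries no biomarker set")
        scores = mhi_scores(table, self.biomarkers)
        return pd.DataFrame({"mhi_score": scores,
                             "call": self.classify(scores.to_numpy())})

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold": self.threshold,
            "train_sensitivity": self.train_sensitivity,
            "train_specificity": self.train_specificity,
            "biomarkers": (json.loads(self.biomarkers.to_json())
                           if self.biomarkers else None),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MhiClassifier":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        obj = json.loads(text)
        biom = (BiomarkerSet.from_json(json.dumps(obj["biomarkers"]))
                if obj.get("biomarkers") else None)
        return cls(threshold=obj["threshold"],
                   train_sensitivity=obj.get("train_sensitivity"),
                   train_specificity=obj.get("train_specificity"),
                   biomarkers=biom)


# -- evaluation --------------------------------------------------------------

def auc_score(scores, labels) -> float:
    """AUC by the Mann-Whitney rank construction with half credit for ties."""
    scores = np.asarray(scores, float)
    y = _as_binary(labels)
    n1, n0 = int(y.sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_auc(scores, labels, n_boot: int = 9999, seed: int = 0,
            ci: float = 0.95) -> tuple[float, float, float]:
    """Point AUC plus a percentile CI from class-stratified bootstrap
    resampling of the samples."""
    scores = np.asarray(scores, float)
    y = _as_binary(labels)
    point = auc_score(scores, y)
    rng = np.random.default_rng(seed)
    idx1, idx0 = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(idx1, len(idx1), replace=True),
                               rng.choice(idx0, len(idx0), replace=True)])
        aucs[b] = auc_score(scores[take], y[take])
    tail = (1 - ci) / 2
    lo, hi = np.percentile(aucs, [100 * tail, 100 * (1 - tail)])
    return point, float(lo), float(hi)


def f1_score_e1(calls, labels) -> float:
    """F1 with ICU_E1 as the positive class."""
    pred, true = _as_binary(calls), _as_binary(labels)
    tp = int((pred & true).sum())
    fp = int((pred & ~true.astype(bool)).sum())
    fn = int((~pred.astype(bool) & true).sum())
    if tp == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


@dataclass
class EvalReport:
    set_name: str
    n: int
    auc: float
    auc_ci: tuple[float, float]
    f1: float
    sensitivity: float
    specificity: float
    n_boot: int
    calls: pd.Series | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {"set": self.set_name, "n": self.n, "auc": self.auc,
                "auc_ci_low": self.auc_ci[0], "auc_ci_high": self.auc_ci[1],
                "f1": self.f1, "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def evaluate(scores: pd.Series, labels, classifier: MhiClassifier,
             set_name: str, n_boot: int = 9999, seed: int = 0) -> EvalReport:
    y = _as_binary(labels)
    calls = classifier.classify(scores.to_numpy())
    pred = (calls == E1).astype(int)
    auc, lo, hi = roc_auc(scores.to_numpy(), y, n_boot=n_boot, seed=seed)
    sens = float(pred[y == 1].mean()) if (y == 1).any() else float("nan")
    spec = float(1 - pred[y == 0].mean()) if (y == 0).any() else float("nan")
    return EvalReport(set_name=set_name, n=len(y), auc=auc, auc_ci=(lo, hi),
                      f1=f1_score_e1(pred, y), sensitivity=sens,
                      specificity=spec, n_boot=n_boot,
                      calls=pd.Series(calls, index=scores.index, name="call"))


@dataclass
class MhiEvaluation:
    """Results object for a train/test evaluation of the MHI classifier."""

    classifier: MhiClassifier
    reports: list[EvalReport]
    train_ids: list[str]
    test_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.reports])

    def summary(self) -> str:
        lines = [f"MHI classifier: threshold = {self.classifier.threshold:.4f} "
                 f"(train sens = {self.classifier.train_sensitivity:.3f}, "
                 f"spec = {self.classifier.train_specificity:.3f})",
                 self.to_frame().to_string(index=False, float_format="%.4f")]
        return "\n".join(lines)


def stratified_split(labels, train_fraction: float = 0.8, seed: int = 0,
                     max_retries: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Random split stratified by class; retries (new child seed) in the
    degenerate case of a single-class side."""
    y = _as_binary(labels)
    n = len(y)
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed, attempt])
        train_mask = np.zeros(n, dtype=bool)
        for c in (0, 1):
            idx = np.flatnonzero(y == c)
            idx = rng.permutation(idx)
            n_train = int(round(train_fraction * len(idx)))
            train_mask[idx[:n_train]] = True
        tr, te = np.flatnonzero(train_mask), np.flatnonzero(~train_mask)
        if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
            return tr, te
    raise ValueError("could not produce a two-class train/test split")


def evaluate_split(table: AbundanceTable, labels, biomarkers: BiomarkerSet,
                   train_fraction: float = 0.8, seed: int = 0,
                   n_boot: int = 9999) -> MhiEvaluation:
    """Train the threshold on a stratified 80/20 split and report train and
    test performance in a Table-1-style layout."""
    labels = np.asarray(labels)
    scores = mhi_scores(table, biomarkers)
    tr, te = stratified_split(labels, train_fraction, seed)
    clf = train_threshold(scores.to_numpy()[tr], labels[tr])
    clf.biomarkers = biomarkers
    reports = [
        evaluate(scores.iloc[tr], labels[tr], clf, "training", n_boot, seed),
        evaluate(scores.iloc[te], labels[te], clf, "testing_I", n_boot, seed),
    ]
    ids = np.asarray(table.sample_ids)
    return MhiEvaluation(classifier=clf, reports=reports,
                         train_ids=list(ids[tr]), test_ids=list(ids[te]))


def external_cohort_eval(classifier: MhiClassifier, table: AbundanceTable,
                         labels, set_name: str = "testing_II",
                         n_boot: int = 9999, seed: int = 0,
                         min_matched: float = 0.5) -> EvalReport:
    """Apply a frozen classifier (threshold + biomarkers) to an external
    cohort; hard error when more than half the markers cannot be resolved."""
    if classifier.biomarkers is None:
        raise ValueError("classifier carries no biomarker set")
    frac = matched_fraction(table, classifier.biomarkers)
    if frac < min_matched:
        raise ValueError(
            f"only {frac:.0%} of biomarkers resolvable in the external table; "
            "classifier is not transferable")
    scores = mhi_scores(table, classifier.biomarkers)
    return evaluate(scores, labels, classifier, set_name, n_boot, seed)
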