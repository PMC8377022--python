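"""End-to-end orchestration: enterotypes -> biomarkers -> MHI -> associations.

Every stage derives its own child seed from the single global seed, so
toggling one stage never shifts another stage's random stream.  All artifacts
are written under the output directory together with a manifest of content
hashes, the seed and package versions.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import child_seed
from .abundance import (AbundanceTable, aggregate_to_rank, alpha_diversity,
                        read_abundance_table, read_metadata, to_relative,
                        write_abundance_table)
from .associations import association_battery
from .biomarkers import BiomarkerSet, build_biomarker_set
from .enterotype import jsd_matrix, pcoa, select_k
from .mhi import MhiClassifier, evaluate_split, external_cohort_eval, mhi_scores

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    k_min: int = 2
    k_max: int = 10
    lda_gate: float = 2.0
    lda_alpha: float = 0.05
    mrmr_n: int = 5
    train_fraction: float = 0.8
    n_boot: int = 9999
    n_perm: int = 9999
    apache_cutoff: float = 18.0
    lactate_cutoff: float = 2.5
    rarefaction_depth: int = 4000
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        overrides = json.loads(Path(path).read_text())
        return cls(**overrides)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, config: PipelineConfig,
                    inputs: dict[str, str]) -> None:
    files = sorted(p for p in outdir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "icuenterotype",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "inputs": inputs,
        "outputs": {p.name: _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_full_pipeline(table: AbundanceTable, meta: pd.DataFrame,
                      config: PipelineConfig | None = None,
                      outdir: str | Path | None = None,
                      biomarkers: BiomarkerSet | None = None) -> dict:
    """Run every stage on an abundance table + metadata; returns the bundle
    of in-memory results and, when ``outdir`` is given, writes the artifacts
    with a manifest."""
    config = config or PipelineConfig()
    bundle: dict = {"config": config}

    stage = "alpha_diversity"
    if table.mode == "counts":
        try:
            bundle["alpha_diversity"] = alpha_diversity(
                table, config.rarefaction_depth, child_seed(config.seed, stage))
        except Exception as exc:  # noqa: BLE001 - reported, not fatal
            logger.warning("stage %s skipped: %s", stage, exc)
        rel = to_relative(table)
    else:
        rel = table
    genus = aggregate_to_rank(rel, "genus")

    logger.info("stage enterotype: JSD + PAM, k in [%d, %d]",
                config.k_min, config.k_max)
    dm = jsd_matrix(genus)
    partition, diagnostics = select_k(
        dm, range(config.k_min, config.k_max + 1), table=genus)
    bundle.update(distance_matrix=dm, partition=partition,
                  k_diagnostics=diagnostics, embedding=pcoa(dm, 2))
    labels = np.asarray(partition.named_labels())

    if partition.k != 2:
        raise RuntimeError(
            f"stage enterotype: CH selected k={partition.k}, not 2; the "
            "downstream two-class stages are undefined for this partition")

    logger.info("stage biomarkers")
    if biomarkers is None:
        biomarkers = build_biomarker_set(
            genus, labels, alpha=config.lda_alpha, gate=config.lda_gate,
            n_select=config.mrmr_n, seed=child_seed(config.seed, "biomarkers"))
    bundle["biomarkers"] = biomarkers

    logger.info("stage mhi")
    evaluation = evaluate_split(
        genus, labels, biomarkers, train_fraction=config.train_fraction,
        seed=child_seed(config.seed, "mhi"), n_boot=config.n_boot)
    bundle["mhi"] = evaluation

    logger.info("stage associations")
    ent = pd.Series(labels, index=genus.sample_ids)
    bundle["associations"] = association_battery(
        meta, ent, d_micro=dm, apache_cutoff=config.apache_cutoff,
        lactate_cutoff=config.lactate_cutoff, n_perm=config.n_perm,
        seed=child_seed(config.seed, "associations"))

    if outdir is not None:
        write_bundle(bundle, Path(outdir), table, meta)
    return bundle


def write_bundle(bundle: dict, outdir: Path, table: AbundanceTable,
                 meta: pd.DataFrame) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    config: PipelineConfig = bundle["config"]
    part = bundle["partition"]
    part.to_frame().to_csv(outdir / "enterotypes.tsv", sep="\t", index=False)
    bundle["k_diagnostics"].to_csv(outdir / "k_diagnostics.tsv", sep="\t",
                                   index=False)
    dm = bundle["distance_matrix"]
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        outdir / "jsd_matrix.tsv", sep="\t")
    emb = bundle["embedding"]
    emb.to_frame().to_csv(outdir / "pcoa.tsv", sep="\t")
    (outdir / "pcoa_eigenvalues.json").write_text(json.dumps(
        {"eigenvalues": emb.eigenvalues.tolist(),
         "explained_fraction": emb.explained_fraction.tolist()}))
    bundle["biomarkers"].to_json(outdir / "biomarkers.json")
    bundle["biomarkers"].to_table(outdir / "biomarkers.tsv")
    evaluation = bundle["mhi"]
    evaluation.classifier.to_json(outdir / "mhi_classifier.json")
    evaluation.to_frame().to_csv(outdir / "mhi_evaluation.tsv", sep="\t",
                                 index=False)
    (outdir / "associations.json").write_text(
        json.dumps(bundle["associations"], indent=2, default=str))
    if "alpha_diversity" in bundle:
        pd.DataFrame([vars(a) for a in bundle["alpha_diversity"]]).to_csv(
            outdir / "alpha_diversity.tsv", sep="\t", index=False)
    inputs = {
        "abundance_sha256": hashlib.sha256(
            table.data.to_csv().encode()).hexdigest(),
        "metadata_sha256": hashlib.sha256(
            meta.to_csv().encode()).hexdigest(),
    }
    _write_manifest(outdir, config, inputs)


def run_from_paths(abundance_path: str | Path, metadata_path: str | Path,
                   config: PipelineConfig | None = None,
                   outdir: str | Path | None = None,
                   samples_as_rows: bool = False) -> dict:
    table = read_abundance_table(abundance_path, samples_as_rows=samples_as_rows)
    meta = read_metadata(metadata_path)
    return run_full_pipeline(table, meta, config=config, outdir=outdir)


def evaluate_external(classifier_path: str | Path, abundance_path: str | Path,
                      labels_path: str | Path, n_boot: int = 9999,
                      seed: int = 0):
    """Apply a frozen classifier JSON to an external cohort table with known
    enterotype labels (testing-set-II mode)."""
    clf = MhiClassifier.from_json(classifier_path)
    table = read_abundance_table(abundance_path)
    rel = to_relative(table) if table.mode == "counts" else table
    genus = aggregate_to_rank(rel, "genus")
    labels = pd.read_csv(labels_path, sep="\t").set_index("sample_id")
    labels = labels["enterotype"].reindex(genus.sample_ids).to_numpy()
    return external_cohort_eval(clf, genus, labels, n_boot=n_boot, seed=seed)
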