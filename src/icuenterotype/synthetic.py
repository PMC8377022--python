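"""Synthetic ICU cohorts with known ground truth.

The generator emulates the statistical structure of a two-enterotype ICU
cohort: two mixture components driven by near log-normal *Bacteroides* /
*Enterococcus* gradients plus a dominant unclassified Enterobacteriaceae
genus in enterotype 1, a Dirichlet background over ~30 commensal and
pathogenic genera, multinomial sequencing depth, and enterotype-conditional
clinical covariates (APACHE II, SOFA, septic-shock risk concentrated in the
high-severity stratum, and per-enterotype log-normal serum lactate).

Default moments follow the printed cohort summaries: enterotype prevalence
89:42, Enterobacteriaceae* mean relative abundance 0.251 (E1) vs 0.082 (E2),
APACHE II 20.37 +/- 8.14, SOFA 10.67 +/- 4.02, lactate 2.66 +/- 3.30 mM (E1)
vs 1.42 +/- 0.52 mM (E2).  Ground truth is returned separately and never
leaks into the emitted tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .enterotype import E1, E2
from .taxonomy import TaxonLineage

BACTEROIDES = "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Bacteroidaceae;Bacteroides"
ENTEROCOCCUS = "Bacteria;Firmicutes;Bacilli;Lactobacillales;Enterococcaceae;Enterococcus"
ENTEROBACTERIACEAE_STAR = (
    "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;")

DRIVERS = (BACTEROIDES, ENTEROCOCCUS, ENTEROBACTERIACEAE_STAR)

_BACKGROUND = (
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Tannerellaceae;Parabacteroides",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Prevotellaceae;Prevotella",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Rikenellaceae;Alistipes",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Marinifilaceae;Odoribacter",
    "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus",
    "Bacteria;Firmicutes;Bacilli;Lactobacillales;Enterococcaceae;Vagococcus",
    "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus",
    "Bacteria;Firmicutes;Bacilli;Bacillales;Staphylococcaceae;Staphylococcus",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Clostridiaceae;Clostridium",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Faecalibacterium",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Ruminococcus",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Oscillibacter",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Roseburia",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Blautia",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Dorea",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Lachnospiraceae;Coprococcus",
    "Bacteria;Firmicutes;Negativicutes;Veillonellales;Veillonellaceae;Veillonella",
    "Bacteria;Firmicutes;Negativicutes;Veillonellales;Veillonellaceae;Dialister",
    "Bacteria;Firmicutes;Negativicutes;Selenomonadales;Selenomonadaceae;Megamonas",
    "Bacteria;Actinobacteria;Actinomycetia;Bifidobacteriales;Bifidobacteriaceae;Bifidobacterium",
    "Bacteria;Actinobacteria;Coriobacteriia;Coriobacteriales;Coriobacteriaceae;Collinsella",
    "Bacteria;Actinobacteria;Actinomycetia;Corynebacteriales;Corynebacteriaceae;Corynebacterium",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;Escherichia",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;Klebsiella",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Moraxellales;Moraxellaceae;Acinetobacter",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae;Pseudomonas",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Pasteurellales;Pasteurellaceae;Haemophilus",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Sutterellaceae;Sutterella",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Sutterellaceae;Parasutterella",
    "Bacteria;Fusobacteria;Fusobacteriia;Fusobacteriales;Fusobacteriaceae;Fusobacterium",
    "Bacteria;Verrucomicrobia;Verrucomicrobiae;Verrucomicrobiales;Akkermansiaceae;Akkermansia",
)

INFECTION_SITES = ("pulmonary", "abdominal", "urinary", "bloodstream", "other")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a log-normal with the given mean and sd."""
    sigma2 = np.log(1 + (sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2), float(np.sqrt(sigma2))


@dataclass
class CohortConfig:
    n_samples: int = 131
    n_patients: int = 64
    e1_prevalence: float = 89 / 131
    # per-driver (mean under E1, mean under E2, log-sd of the log-normal draw)
    driver_params: dict = field(default_factory=lambda: {
        BACTEROIDES: (0.25, 0.02, 0.45),
        ENTEROCOCCUS: (0.01, 0.18, 0.45),
        ENTEROBACTERIACEAE_STAR: (0.251, 0.082, 0.35),
    })
    background_taxa: tuple = _BACKGROUND
    dirichlet_concentration: float = 40.0
    depth_range: tuple[int, int] = (6000, 16000)
    apache_mean_sd: tuple[float, float] = (20.37, 8.14)
    sofa_mean_sd: tuple[float, float] = (10.67, 4.02)
    # serum lactate (mM): per-enterotype target mean and sd
    lactate_mean_sd: dict = field(default_factory=lambda: {
        E1: (2.66, 3.30), E2: (1.42, 0.52)})
    lactate_floor: float = 0.1
    # septic-shock probability by (enterotype, severity stratum)
    shock_risk: dict = field(default_factory=lambda: {
        (E1, "high"): 0.45, (E1, "low"): 0.10,
        (E2, "high"): 0.05, (E2, "low"): 0.10})
    apache_cutoff: float = 18.0
    max_samples_per_patient: int = 5
    n_days: int = 9

    def __post_init__(self) -> None:
        # accept "ICU_E1:high"-style keys (JSON configs cannot carry tuples)
        self.shock_risk = {
            (tuple(k.split(":")) if isinstance(k, str) else k): v
            for k, v in self.shock_risk.items()}
        if not 0 < self.e1_prevalence < 1:
            raise ValueError("e1_prevalence must lie in (0, 1)")
        for which, idx in ((E1, 0), (E2, 1)):
            total = sum(p[idx] for p in self.driver_params.values())
            if total >= 1:
                raise ValueError(
                    f"expected driver mass under {which} is {total:.2f} >= 1")
        if self.dirichlet_concentration <= 0 or self.lactate_floor <= 0:
            raise ValueError("scale parameters must be positive")

    def taxa(self) -> list[str]:
        return list(self.driver_params) + list(self.background_taxa)


def _background_base(n: int) -> np.ndarray:
    """Decreasing power-law base proportions for the background community."""
    w = 1.0 / np.arange(1, n + 1) ** 0.8
    return w / w.sum()


def generate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    ) -> tuple[AbundanceTable, pd.DataFrame, pd.DataFrame]:
    """Draw a cohort: genus count table, clinical metadata, ground truth.

    Enterotype is drawn per patient; each patient contributes 1..5 samples on
    distinct days.  Fully deterministic given ``seed``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)

    # patients and their sampling schedule
    counts = np.ones(config.n_patients, dtype=int)
    extra = config.n_samples - config.n_patients
    if extra < 0:
        raise ValueError("n_samples must be >= n_patients")
    while extra > 0:
        cand = np.flatnonzero(counts < min(config.max_samples_per_patient,
                                           config.n_days))
        counts[rng.choice(cand)] += 1
        extra -= 1

    patient_ent = np.where(rng.random(config.n_patients) < config.e1_prevalence,
                           E1, E2)
    patient_carb = rng.random(config.n_patients) < 0.5
    patient_site = rng.choice(INFECTION_SITES, config.n_patients,
                              p=(0.45, 0.2, 0.12, 0.13, 0.10))
    patient_surv = rng.random(config.n_patients) < 0.7

    taxa = config.taxa()
    base = _background_base(len(config.background_taxa))
    apache_mu, apache_sd = config.apache_mean_sd
    sofa_mu, sofa_sd = config.sofa_mean_sd
    lact_params = {ent: _lognormal_params(*ms)
                   for ent, ms in config.lactate_mean_sd.items()}

    meta_rows, truth_rows, count_rows, sample_ids = [], [], [], []
    for p in range(config.n_patients):
        patient_id = f"P{p+1:03d}"
        days = np.sort(rng.choice(np.arange(1, config.n_days + 1), counts[p],
                                  replace=False))
        for day in days:
            sample_id = f"{patient_id}D{day}"
            ent = patient_ent[p]
            col = 0 if ent == E1 else 1

            # composition: log-normal drivers, Dirichlet background
            driver = np.array([
                rng.lognormal(np.log(m[col]) - m[2] ** 2 / 2, m[2])
                for m in config.driver_params.values()])
            if driver.sum() >= 0.95:
                driver *= 0.9 / driver.sum()
            bg = rng.dirichlet(base * config.dirichlet_concentration)
            rel = np.concatenate([driver, (1 - driver.sum()) * bg])
            depth = int(rng.integers(*config.depth_range))
            count_rows.append(rng.multinomial(depth, rel / rel.sum()))

            apache = max(0.0, rng.normal(apache_mu, apache_sd))
            sofa = max(0.0, rng.normal(sofa_mu, sofa_sd))
            lactate = max(config.lactate_floor,
                          rng.lognormal(*lact_params[ent]))
            stratum = "high" if apache > config.apache_cutoff else "low"
            shock = rng.random() < config.shock_risk[(ent, stratum)]

            sample_ids.append(sample_id)
            meta_rows.append({
                "sample_id": sample_id, "patient_id": patient_id,
                "day": int(day),
                "status": "septic_shock" if shock else "sepsis",
                "apache_ii": round(apache, 1), "sofa": round(sofa, 1),
                "lactate": round(lactate, 2),
                "carbapenem_use": bool(patient_carb[p]),
                "infection_site": patient_site[p],
                "survival_28d": bool(patient_surv[p]),
            })
            truth_rows.append({
                "sample_id": sample_id, "patient_id": patient_id,
                "enterotype": ent,
                **{f"driver_{i}": driver[i] for i in range(len(driver))},
            })

    frame = pd.DataFrame(np.asarray(count_rows, dtype=float),
                         index=sample_ids, columns=taxa)
    lineages = tuple(TaxonLineage.from_string(t) for t in taxa)
    table = AbundanceTable(frame, lineages, "counts")
    meta = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    truth = pd.DataFrame(truth_rows).set_index("sample_id", drop=False)
    return table, meta, truth


def null_config(config: CohortConfig | None = None) -> CohortConfig:
    """A single-enterotype variant: every driver's E1 and E2 parameters are
    replaced by their geometric-mean compromise, shock risk loses its
    enterotype dependence, and lactate follows one pooled distribution."""
    config = config or CohortConfig()
    mixed = {name: (float(np.sqrt(m1 * m2)), float(np.sqrt(m1 * m2)), sd)
             for name, (m1, m2, sd) in config.driver_params.items()}
    pooled_lactate = {E1: (2.33, 2.88), E2: (2.33, 2.88)}
    flat_risk = {k: 0.19 for k in config.shock_risk}
    return replace(config, driver_params=mixed, lactate_mean_sd=pooled_lactate,
                   shock_risk=flat_risk)


def equalized_config(config: CohortConfig | None = None) -> CohortConfig:
    """Keep the two-enterotype labels but equalise the E1/E2 generative
    parameters, so microbiota recovery must collapse to chance."""
    return null_config(config)


def generate_null_cohort(config: CohortConfig | None = None, seed: int = 0):
    """Cohort with a single microbiota component and clinical covariates
    independent of the microbiota (negative control)."""
    return generate_cohort(null_config(config), seed=seed)


def driver_recovered(markers: list[str], driver: str) -> bool:
    """Whether a selected marker pins down the planted driver: some marker is
    the driver feature itself or a (below-kingdom) ancestor on its lineage
    path.  In the synthetic community a driver's ancestors are abundance-wise
    near-duplicates of the driver, so selecting e.g. the family where the
    driver genus lives recovers the same signal."""
    for name in markers:
        if len(name.rstrip(";").split(";")) < 2:
            continue  # kingdom-level features do not identify anything
        if driver == name:
            return True
        if driver.startswith(name) and driver[len(name)] == ";":
            return True
    return False


def worked_example_fixture() -> tuple[AbundanceTable, list[str]]:
    """Tiny 8-sample x 6-genus relative table with hand-checkable JSD, PAM
    and MHI values; first four samples are archetypal E1, last four E2."""
    taxa = [
        BACTEROIDES,
        ENTEROBACTERIACEAE_STAR,
        ENTEROCOCCUS,
        "Bacteria;Firmicutes;Bacilli;Lactobacillales;Lactobacillaceae;Lactobacillus",
        "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae;Faecalibacterium",
        "Bacteria;Proteobacteria;Gammaproteobacteria;Enterobacterales;Enterobacteriaceae;Escherichia",
    ]
    rows = {
        "S1": [0.50, 0.30, 0.02, 0.03, 0.10, 0.05],
        "S2": [0.40, 0.35, 0.05, 0.05, 0.10, 0.05],
        "S3": [0.55, 0.20, 0.05, 0.05, 0.10, 0.05],
        "S4": [0.45, 0.25, 0.10, 0.05, 0.10, 0.05],
        "S5": [0.05, 0.05, 0.50, 0.20, 0.15, 0.05],
        "S6": [0.02, 0.08, 0.60, 0.10, 0.15, 0.05],
        "S7": [0.10, 0.05, 0.45, 0.20, 0.15, 0.05],
        "S8": [0.05, 0.10, 0.55, 0.10, 0.15, 0.05],
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=taxa)
    lineages = tuple(TaxonLineage.from_string(t) for t in taxa)
    table = AbundanceTable(frame, lineages, "relative")
    labels = [E1] * 4 + [E2] * 4
    return table, labels
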