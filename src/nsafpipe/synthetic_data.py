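"""Seeded synthetic study generator with known ground truth.

The generator emulates the statistical structure of post-search spectral
counting reports so every downstream stage (ladder, NSAF statistics, set
comparison) can be exercised against a known answer:

* protein lengths are log-normal;
* per-run spectral counts are negative-binomial (overdispersed Poisson)
  with mean proportional to class abundance x length, multiplied by a
  per-replicate stability factor -- tight for *stable* proteins, loose for
  *unstable* ones, which is what the CV/FC reproducibility filter keys on;
* abundance classes LOW/MEDIUM/HIGH differ by a fixed fold step, so the
  quartile categorization has a recoverable target;
* truly present proteins carry >= 2 distinct high-scoring peptides per run,
  spurious ones carry few low-scoring peptides, exercising the two-peptide
  score filter;
* contaminants receive identification frequencies drawn on both sides of
  the 0.67 exclusion boundary.

Everything is driven by one integer seed; identical (design, params) yield
identical studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .abundance import Category
from .errors import ValidationError
from .report_io import (
    AnnotationTable,
    ContaminantList,
    PeptideEvidence,
    ProteinRow,
    RunKey,
    RunReport,
    StudyDesign,
    StudyTable,
    build_study,
    write_annotation_table,
    write_contaminant_table,
    write_design,
    write_peptide_report,
    write_protein_report,
)

logger = logging.getLogger(__name__)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: Fold step between successive abundance classes (LOW -> MEDIUM -> HIGH).
CLASS_FOLD_STEP = 4.0

#: Relative abundance of a spurious protein compared with a LOW one.
SPURIOUS_RELATIVE_ABUNDANCE = 0.03


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the generator.

    ``counts_per_residue`` sets the expected spectral count per amino acid
    for a LOW-class protein (MEDIUM and HIGH are 4x and 16x that);
    ``spectral_dispersion`` is the negative-binomial size parameter (larger
    means closer to Poisson); ``cv_target_stable``/``cv_target_unstable``
    are the log-normal sigmas of the per-replicate stability factor.
    """

    n_proteins: int = 500
    fraction_contaminant: float = 0.10
    fraction_placenta: float = 0.85
    fraction_spurious: float = 0.10
    abundance_class_weights: tuple[float, float, float] = (0.25, 0.50, 0.25)
    length_log_mean: float = 5.99  # median length ~400 aa
    length_log_sd: float = 0.45
    counts_per_residue: float = 0.25
    spectral_dispersion: float = 300.0
    score_confident_mean: float = 99.6
    score_unconfident_mean: float = 85.0
    stable_fraction: float = 0.70
    cv_target_stable: float = 0.08
    cv_target_unstable: float = 0.80
    fraction_dataset_specific: float = 0.30
    dataset_detect_prob: float = 0.5
    dataset_effect_sd: float = 0.5
    contaminant_freq_range: tuple[float, float] | None = None
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        for name in ("fraction_contaminant", "fraction_placenta",
                     "fraction_spurious", "stable_fraction",
                     "fraction_dataset_specific", "dataset_detect_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        w = self.abundance_class_weights
        if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
            raise ValidationError("abundance_class_weights must be 3 non-negative weights summing to 1")
        if self.counts_per_residue <= 0 or self.spectral_dispersion <= 0:
            raise ValidationError("counts_per_residue and spectral_dispersion must be > 0")
        if self.cv_target_stable <= 0 or self.cv_target_unstable <= 0:
            raise ValidationError("cv targets must be > 0")
        for name in ("score_confident_mean", "score_unconfident_mean"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name} must lie in [0, 100], got {v}")

    @classmethod
    def well_separated(cls, **overrides) -> "SimulationParams":
        """Parameters with cleanly separated stable/unstable and class
        structure, used when testing ground-truth recovery: deeper sampling
        (more counts per protein) and a tighter stable replicate factor make
        the CV/FC criterion nearly noiseless for stable proteins."""
        base = cls(counts_per_residue=1.2, cv_target_stable=0.03,
                   spectral_dispersion=500.0)
        return replace(base, **overrides)


@dataclass(frozen=True)
class ProteinTruth:
    accession: str
    true_class: Category
    is_contaminant: bool
    contaminant_frequency: float
    placenta_transcript: bool
    is_stable: bool
    is_present: bool


@dataclass(frozen=True)
class GroundTruth:
    """Per-accession generation record for every synthetic protein."""

    records: Mapping[str, ProteinTruth]

    def accessions_where(self, **flags) -> frozenset[str]:
        """Accessions whose truth record matches all given field values,
        e.g. ``accessions_where(is_stable=True, is_contaminant=False)``."""
        out = []
        for acc, rec in self.records.items():
            if all(getattr(rec, k) == v for k, v in flags.items()):
                out.append(acc)
        return frozenset(out)


def _make_peptide_pool(rng: np.random.Generator, n: int) -> list[str]:
    pool = []
    for _ in range(n):
        length = int(rng.integers(7, 31))  # detectable tryptic range
        pool.append("".join(rng.choice(_AA, size=length)))
    return pool


def simulate_study(design: StudyDesign, params: SimulationParams,
                   ) -> tuple[StudyTable, GroundTruth]:
    """Generate a complete synthetic study plus its ground truth.

    Deterministic for fixed (design, params).
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins

    accessions = [f"SYN{i:05d}" for i in range(n)]
    lengths = np.maximum(
        50, np.round(rng.lognormal(params.length_log_mean, params.length_log_sd, n))
    ).astype(int)
    class_idx = rng.choice(3, size=n, p=np.asarray(params.abundance_class_weights))
    class_order = (Category.LOW, Category.MEDIUM, Category.HIGH)
    classes = [class_order[i] for i in class_idx]
    is_contaminant = rng.random(n) < params.fraction_contaminant
    placenta = rng.random(n) < params.fraction_placenta
    is_spurious = (~is_contaminant) & (rng.random(n) < params.fraction_spurious)
    is_present = ~is_spurious
    is_stable = rng.random(n) < params.stable_fraction

    # contaminant identification frequencies: two clusters straddling the
    # 0.67 exclusion boundary unless an explicit range is requested
    freqs = np.zeros(n)
    for i in np.flatnonzero(is_contaminant):
        if params.contaminant_freq_range is not None:
            lo, hi = params.contaminant_freq_range
            freqs[i] = lo + (hi - lo) * rng.random()
        elif rng.random() < 0.75:  # above the boundary -> excluded
            freqs[i] = 0.67 + 0.33 * rng.beta(2.0, 2.0)
        else:  # below the boundary -> retained
            freqs[i] = 0.67 * rng.beta(6.0, 2.0)

    # expected spectral count per run before replicate noise
    fold = CLASS_FOLD_STEP ** class_idx.astype(float)
    base_mean = params.counts_per_residue * lengths * fold
    base_mean[is_spurious] = (params.counts_per_residue * lengths[is_spurious]
                              * SPURIOUS_RELATIVE_ABUNDANCE)

    # dataset-level structure: a fraction of proteins is detectable only in
    # a random subset of datasets, and every protein carries a per-dataset
    # abundance effect shared by all of that dataset's runs (extraction /
    # tissue effects).  Within-dataset spread stays governed by the
    # per-replicate stability factor, so this shapes between-dataset overlap
    # and clustering without touching the CV/FC criterion.
    dataset_ids = sorted(design.datasets)
    is_specific = rng.random(n) < params.fraction_dataset_specific
    detectable: dict[int, np.ndarray] = {}
    effect: dict[int, np.ndarray] = {}
    for d in dataset_ids:
        mask = np.ones(n, dtype=bool)
        keep = rng.random(n) < params.dataset_detect_prob
        mask[is_specific] = keep[is_specific]
        detectable[d] = mask
        s = params.dataset_effect_sd
        effect[d] = rng.lognormal(-s * s / 2.0, s, n) if s > 0 else np.ones(n)

    pools = [_make_peptide_pool(rng, 12) for _ in range(n)]

    runs = []
    for key in sorted(design.expected_keys()):
        sigma = np.where(is_stable, params.cv_target_stable, params.cv_target_unstable)
        factor = rng.lognormal(-sigma ** 2 / 2.0, sigma)
        mu = base_mean * effect[key.dataset] * detectable[key.dataset] * factor
        r = params.spectral_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
        detected = np.flatnonzero(counts > 0)

        proteins = [ProteinRow(accessions[i], int(lengths[i]), int(counts[i]))
                    for i in detected]
        peptides: list[PeptideEvidence] = []
        for i in detected:
            if is_present[i]:
                k = 2 + int(rng.poisson(1.5))
                scores = rng.normal(params.score_confident_mean, 0.35, size=k)
            else:
                k = 1 + int(rng.poisson(0.5))
                scores = rng.normal(params.score_unconfident_mean, 5.0, size=k)
            k = min(k, len(pools[i]))
            for seq, s in zip(pools[i][:k], scores):
                peptides.append(PeptideEvidence(
                    seq, frozenset({accessions[i]}),
                    float(np.clip(round(s, 2), 0.0, 100.0))))
        runs.append(RunReport(key, tuple(peptides), tuple(proteins),
                              int(counts.sum())))

    contaminants = ContaminantList(
        {accessions[i]: float(round(freqs[i], 4)) for i in np.flatnonzero(is_contaminant)})
    annotation = AnnotationTable({accessions[i]: bool(placenta[i]) for i in range(n)})
    study = build_study(design, runs, contaminants, annotation)

    truth = GroundTruth({
        accessions[i]: ProteinTruth(
            accession=accessions[i],
            true_class=classes[i],
            is_contaminant=bool(is_contaminant[i]),
            contaminant_frequency=float(round(freqs[i], 4)),
            placenta_transcript=bool(placenta[i]),
            is_stable=bool(is_stable[i]),
            is_present=bool(is_present[i]),
        )
        for i in range(n)
    })
    logger.info("simulated study: %d proteins, %d runs, %d contaminants",
                n, len(runs), int(is_contaminant.sum()))
    return study, truth


# ---------------------------------------------------------------------------
# fixture emission
# ---------------------------------------------------------------------------

def write_fixture(study: StudyTable, truth: GroundTruth,
                  directory: str | Path) -> list[Path]:
    """Write a study in the exact on-disk dialect read by ``read_study``,
    plus a ``ground_truth.tsv``.  Returns the files written."""
    directory = Path(directory)
    run_dir = directory / "runs"
    run_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    write_design(study.design, directory / "design.yaml")
    written.append(directory / "design.yaml")
    write_contaminant_table(study.contaminants, directory / "contaminants.tsv")
    written.append(directory / "contaminants.tsv")
    write_annotation_table(study.annotation, directory / "annotation.tsv")
    written.append(directory / "annotation.tsv")

    runs_rows = []
    for key in sorted(study.runs):
        run = study.runs[key]
        ppath = run_dir / f"{key}.peptides.tsv"
        qpath = run_dir / f"{key}.proteins.tsv"
        write_peptide_report(run.peptides, ppath)
        write_protein_report(run.proteins, qpath)
        written += [ppath, qpath]
        runs_rows.append({"run": str(key), "n_spectra": run.n_spectra})
    pd.DataFrame(runs_rows, columns=["run", "n_spectra"]).to_csv(
        directory / "runs.tsv", sep="\t", index=False)
    written.append(directory / "runs.tsv")

    gt_rows = [{
        "accession": rec.accession, "true_class": rec.true_class.value,
        "is_contaminant": int(rec.is_contaminant),
        "contaminant_frequency": repr(rec.contaminant_frequency),
        "placenta_transcript": int(rec.placenta_transcript),
        "is_stable": int(rec.is_stable), "is_present": int(rec.is_present),
    } for rec in (truth.records[a] for a in sorted(truth.records))]
    pd.DataFrame(gt_rows).to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    written.append(directory / "ground_truth.tsv")
    return written


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = {}
    for row in df.itertuples(index=False):
        records[row.accession] = ProteinTruth(
            accession=row.accession,
            true_class=Category(row.true_class),
            is_contaminant=row.is_contaminant == "1",
            contaminant_frequency=float(row.contaminant_frequency),
            placenta_transcript=row.placenta_transcript == "1",
            is_stable=row.is_stable == "1",
            is_present=row.is_present == "1",
        )
    return GroundTruth(records)
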