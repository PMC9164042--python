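"""Reading, validation and assembly of post-search identification reports.

A *study* is a collection of LC-MS/MS runs organized as
dataset -> sample -> replicate.  Each run contributes a peptide-level and a
protein-level report table (tab-separated, UTF-8, header row, ";" joining
multi-accession cells -- the dialect of delimiter-separated PeptideShaker
exports).  On top of the runs sit two study-wide tables: a CRAPome-style
contaminant frequency list and an annotation table flagging accessions with
known placental transcripts.

The module also performs run-level QC (spectrum-count exclusion) and
assembles everything into a :class:`StudyTable` validated against the
declared :class:`StudyDesign`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ReportFormatError, StudyDesignError, ValidationError

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Accessions removed unconditionally regardless of contaminant frequency:
#: immunoglobulin kappa constant and serum albumin.
DEFAULT_EXTRA_EXCLUSIONS = frozenset({"P01834", "P02768"})

_RUN_KEY_RE = re.compile(r"^(\d+)_(\d+)_(\d+)$")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class RunKey:
    """Identity of one LC-MS/MS run: ``dataset_sample_replicate``."""

    dataset: int
    sample: int
    replicate: int

    def __post_init__(self) -> None:
        for name in ("dataset", "sample", "replicate"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValidationError(f"RunKey.{name} must be a positive integer, got {v!r}")

    def __str__(self) -> str:
        return f"{self.dataset}_{self.sample}_{self.replicate}"

    @classmethod
    def parse(cls, text: str) -> "RunKey":
        m = _RUN_KEY_RE.match(text.strip())
        if not m:
            raise ValidationError(f"run key {text!r} does not match 'dataset_sample_replicate'")
        return cls(*(int(g) for g in m.groups()))


@dataclass(frozen=True)
class PeptideEvidence:
    """One peptide-spectrum identification with its confidence score (0-100)."""

    sequence: str
    protein_accessions: frozenset[str]
    score: float

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("peptide sequence must be non-empty")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"peptide {self.sequence!r} contains non-amino-acid letters {sorted(bad)}"
            )
        if not self.protein_accessions:
            raise ValidationError(f"peptide {self.sequence!r} maps to no protein accession")
        if not (0.0 <= self.score <= 100.0):
            raise ValidationError(
                f"peptide {self.sequence!r} score {self.score} outside [0, 100]"
            )


@dataclass(frozen=True)
class ProteinRow:
    """One protein-level report row: accession, length (aa), spectral count."""

    accession: str
    length: int
    spectral_count: int

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("protein accession must be non-empty")
        if self.length < 1:
            raise ValidationError(f"{self.accession}: length must be >= 1, got {self.length}")
        if self.spectral_count < 0:
            raise ValidationError(
                f"{self.accession}: spectral_count must be >= 0, got {self.spectral_count}"
            )


@dataclass(frozen=True)
class RunReport:
    """Parsed evidence of one run: peptides, proteins, and the run-level
    spectrum count used for QC exclusion."""

    key: RunKey
    peptides: tuple[PeptideEvidence, ...]
    proteins: tuple[ProteinRow, ...]
    n_spectra: int

    def __post_init__(self) -> None:
        if self.n_spectra < 0:
            raise ValidationError(f"{self.key}: n_spectra must be >= 0")
        accs = [p.accession for p in self.proteins]
        seen = set()
        for a in accs:
            if a in seen:
                raise ValidationError(f"{self.key}: duplicate protein accession {a!r}")
            seen.add(a)
        referenced = set().union(*(p.protein_accessions for p in self.peptides)) if self.peptides else set()
        orphan = referenced - seen
        if orphan:
            raise ValidationError(
                f"{self.key}: peptides reference accessions absent from the protein report: "
                f"{sorted(orphan)[:5]}"
            )

    @property
    def accessions(self) -> frozenset[str]:
        """Accessions detected (reported) in this run."""
        return frozenset(p.accession for p in self.proteins)

    def peptides_of(self, accession: str) -> tuple[PeptideEvidence, ...]:
        return tuple(p for p in self.peptides if accession in p.protein_accessions)


@dataclass(frozen=True)
class DatasetDesign:
    state: str  # "elective" | "missed"
    protocol: str
    n_samples: int
    n_replicates: int

    def __post_init__(self) -> None:
        if self.state not in ("elective", "missed"):
            raise ValidationError(f"dataset state must be 'elective' or 'missed', got {self.state!r}")
        if self.n_samples < 1 or self.n_replicates < 1:
            raise ValidationError("n_samples and n_replicates must be >= 1")


@dataclass(frozen=True)
class StudyDesign:
    """The dataset -> sample -> replicate layout of a study."""

    datasets: Mapping[int, DatasetDesign]

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValidationError("study design must declare at least one dataset")
        for d in self.datasets:
            if d < 1:
                raise ValidationError(f"dataset ids must be >= 1, got {d}")

    def expected_keys(self) -> frozenset[RunKey]:
        return frozenset(
            RunKey(d, s, r)
            for d, dd in self.datasets.items()
            for s in range(1, dd.n_samples + 1)
            for r in range(1, dd.n_replicates + 1)
        )

    @classmethod
    def chorionic_villus_study(cls) -> "StudyDesign":
        """The six-dataset chorionic-villus design: three extraction
        protocols (2% SDS, 4% SDS, urea-thiourea), each applied to elective
        and to missed abortion tissue; 17 runs in total."""
        return cls({
            1: DatasetDesign("elective", "Protocol 1.1", 3, 2),
            2: DatasetDesign("elective", "Protocol 1.2", 1, 3),
            3: DatasetDesign("elective", "Protocol 2", 1, 3),
            4: DatasetDesign("missed", "Protocol 1.1", 1, 2),
            5: DatasetDesign("missed", "Protocol 1.2", 1, 3),
            6: DatasetDesign("missed", "Protocol 2", 1, 3),
        })


@dataclass(frozen=True)
class ContaminantList:
    """CRAPome-style contaminant frequencies plus unconditional exclusions."""

    frequencies: Mapping[str, float]
    extra_exclusions: frozenset[str] = DEFAULT_EXTRA_EXCLUSIONS

    def __post_init__(self) -> None:
        for acc, f in self.frequencies.items():
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"contaminant frequency of {acc} is {f}, outside [0, 1]")

    def is_excluded(self, accession: str, cutoff: float) -> bool:
        if accession in self.extra_exclusions:
            return True
        return self.frequencies.get(accession, 0.0) >= cutoff


@dataclass
class AnnotationTable:
    """accession -> has a known placental transcript.

    The mapping is total: accessions absent from the table are treated as
    *not* placenta-annotated (the conservative direction for the placenta
    filter) and counted so the omission is visible in logs.
    """

    placenta: Mapping[str, bool]
    _misses: set = field(default_factory=set, repr=False, compare=False)

    def placenta_transcript(self, accession: str) -> bool:
        try:
            return self.placenta[accession]
        except KeyError:
            self._misses.add(accession)
            return False

    @property
    def missing_accessions(self) -> frozenset[str]:
        return frozenset(self._misses)


@dataclass(frozen=True)
class StudyTable:
    """All runs of a study plus the study-wide tables, validated against the
    design."""

    design: StudyDesign
    runs: Mapping[RunKey, RunReport]
    contaminants: ContaminantList
    annotation: AnnotationTable

    def dataset_runs(self, dataset: int) -> list[RunReport]:
        return [self.runs[k] for k in sorted(self.runs) if k.dataset == dataset]

    def sample_runs(self, dataset: int, sample: int) -> list[RunReport]:
        return [r for r in self.dataset_runs(dataset) if r.key.sample == sample]

    def dataset_ids(self) -> list[int]:
        return sorted(self.design.datasets)

    def all_accessions(self) -> frozenset[str]:
        return frozenset().union(*(r.accessions for r in self.runs.values()))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise ReportFormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ReportFormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_peptide_report(path: str | Path) -> list[PeptideEvidence]:
    """Read a peptide-level TSV (columns: sequence, accessions, score).

    Multi-accession cells are split on ";" with surrounding whitespace
    stripped.
    """
    df = _read_tsv(path, ["sequence", "accessions", "score"])
    out: list[PeptideEvidence] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            score = float(row.score)
        except ValueError:
            raise ValidationError(f"{path}: line {i}: score {row.score!r} is not numeric")
        accs = frozenset(a.strip() for a in str(row.accessions).split(";") if a.strip())
        try:
            out.append(PeptideEvidence(str(row.sequence).strip(), accs, score))
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    return out


def read_protein_report(path: str | Path) -> list[ProteinRow]:
    """Read a protein-level TSV (columns: accession, length, spectral_count)."""
    df = _read_tsv(path, ["accession", "length", "spectral_count"])
    out: list[ProteinRow] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        acc = str(row.accession).strip()
        if acc in seen:
            raise ValidationError(f"{path}: line {i}: duplicate accession {acc!r}")
        seen.add(acc)
        try:
            length = int(row.length)
            spc = int(row.spectral_count)
        except ValueError:
            raise ValidationError(
                f"{path}: line {i}: length/spectral_count must be integers "
                f"(got {row.length!r}, {row.spectral_count!r})"
            )
        try:
            out.append(ProteinRow(acc, length, spc))
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    return out


def read_contaminant_table(path: str | Path,
                           extra_exclusions: Iterable[str] = DEFAULT_EXTRA_EXCLUSIONS,
                           ) -> ContaminantList:
    """Read a contaminant TSV (columns: accession, frequency)."""
    df = _read_tsv(path, ["accession", "frequency"])
    freqs: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            f = float(row.frequency)
        except ValueError:
            raise ValidationError(f"{path}: line {i}: frequency {row.frequency!r} is not numeric")
        freqs[str(row.accession).strip()] = f
    return ContaminantList(freqs, frozenset(extra_exclusions))


def read_annotation_table(path: str | Path) -> AnnotationTable:
    """Read an annotation TSV (columns: accession, placenta_transcript as 0/1)."""
    df = _read_tsv(path, ["accession", "placenta_transcript"])
    mapping: dict[str, bool] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        raw = str(row.placenta_transcript).strip()
        if raw not in ("0", "1"):
            raise ValidationError(f"{path}: line {i}: placenta_transcript must be 0 or 1, got {raw!r}")
        mapping[str(row.accession).strip()] = raw == "1"
    return AnnotationTable(mapping)


def read_design(path: str | Path) -> StudyDesign:
    """Read a study design from YAML (datasets: id -> state/protocol/samples/replicates)."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "datasets" not in raw:
        raise ReportFormatError(f"{path}: design file must contain a 'datasets' mapping")
    datasets: dict[int, DatasetDesign] = {}
    for d, spec in raw["datasets"].items():
        try:
            datasets[int(d)] = DatasetDesign(
                state=spec["state"],
                protocol=spec["protocol"],
                n_samples=int(spec["samples"]),
                n_replicates=int(spec["replicates"]),
            )
        except KeyError as exc:
            raise ReportFormatError(f"{path}: dataset {d}: missing field {exc}") from exc
    return StudyDesign(datasets)


def read_run_report(run_dir: str | Path, key: RunKey, n_spectra: int) -> RunReport:
    run_dir = Path(run_dir)
    peptides = read_peptide_report(run_dir / f"{key}.peptides.tsv")
    proteins = read_protein_report(run_dir / f"{key}.proteins.tsv")
    return RunReport(key, tuple(peptides), tuple(proteins), n_spectra)


def read_study(directory: str | Path) -> StudyTable:
    """Read a complete study directory (design.yaml, contaminants.tsv,
    annotation.tsv, runs.tsv, runs/<key>.{peptides,proteins}.tsv)."""
    directory = Path(directory)
    design = read_design(directory / "design.yaml")
    contaminants = read_contaminant_table(directory / "contaminants.tsv")
    annotation = read_annotation_table(directory / "annotation.tsv")
    runs_df = _read_tsv(directory / "runs.tsv", ["run", "n_spectra"])
    runs = []
    for row in runs_df.itertuples(index=False):
        key = RunKey.parse(str(row.run))
        runs.append(read_run_report(directory / "runs", key, int(row.n_spectra)))
    return build_study(design, runs, contaminants, annotation)


# ---------------------------------------------------------------------------
# writers (round-trip counterparts; also used by the synthetic generator)
# ---------------------------------------------------------------------------

def write_peptide_report(peptides: Iterable[PeptideEvidence], path: str | Path) -> None:
    rows = [
        {"sequence": p.sequence, "accessions": ";".join(sorted(p.protein_accessions)),
         "score": repr(p.score)}
        for p in peptides
    ]
    pd.DataFrame(rows, columns=["sequence", "accessions", "score"]).to_csv(
        path, sep="\t", index=False)


def write_protein_report(proteins: Iterable[ProteinRow], path: str | Path) -> None:
    rows = [{"accession": p.accession, "length": p.length, "spectral_count": p.spectral_count}
            for p in proteins]
    pd.DataFrame(rows, columns=["accession", "length", "spectral_count"]).to_csv(
        path, sep="\t", index=False)


def write_contaminant_table(contaminants: ContaminantList, path: str | Path) -> None:
    rows = [{"accession": a, "frequency": repr(f)}
            for a, f in sorted(contaminants.frequencies.items())]
    pd.DataFrame(rows, columns=["accession", "frequency"]).to_csv(path, sep="\t", index=False)


def write_annotation_table(annotation: AnnotationTable, path: str | Path) -> None:
    rows = [{"accession": a, "placenta_transcript": int(v)}
            for a, v in sorted(annotation.placenta.items())]
    pd.DataFrame(rows, columns=["accession", "placenta_transcript"]).to_csv(
        path, sep="\t", index=False)


def write_design(design: StudyDesign, path: str | Path) -> None:
    raw = {"datasets": {
        d: {"state": dd.state, "protocol": dd.protocol,
            "samples": dd.n_samples, "replicates": dd.n_replicates}
        for d, dd in sorted(design.datasets.items())
    }}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


def write_study_long(study: StudyTable, tsv_path: str | Path, manifest_path: str | Path) -> None:
    """Serialize a study as one long TSV (protein x run) plus a JSON manifest."""
    rows = []
    for key in sorted(study.runs):
        for p in study.runs[key].proteins:
            rows.append({"run": str(key), "accession": p.accession,
                         "length": p.length, "spectral_count": p.spectral_count})
    pd.DataFrame(rows, columns=["run", "accession", "length", "spectral_count"]).to_csv(
        tsv_path, sep="\t", index=False)
    manifest = {
        "datasets": {
            str(d): {"state": dd.state, "protocol": dd.protocol,
                     "samples": dd.n_samples, "replicates": dd.n_replicates}
            for d, dd in sorted(study.design.datasets.items())
        },
        "runs": {str(k): {"n_spectra": study.runs[k].n_spectra,
                          "n_proteins": len(study.runs[k].proteins),
                          "n_peptides": len(study.runs[k].peptides)}
                 for k in sorted(study.runs)},
    }
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# QC and assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExcludedRun:
    key: RunKey
    n_spectra: int


def qc_runs(runs: Sequence[RunReport], min_spectra: int,
            ) -> tuple[list[RunReport], list[ExcludedRun]]:
    """Partition runs into (kept, excluded) by the run-level spectrum count.

    A run is excluded when ``n_spectra < min_spectra``.  The threshold is a
    study-specific configuration value: it reflects the spread of spectrum
    counts actually acquired, so no universal default exists.
    """
    if min_spectra < 0:
        raise ValidationError(f"min_spectra must be >= 0, got {min_spectra}")
    kept, excluded = [], []
    for r in runs:
        if r.n_spectra >= min_spectra:
            kept.append(r)
        else:
            excluded.append(ExcludedRun(r.key, r.n_spectra))
    if excluded:
        logger.info("QC excluded %d/%d runs (min_spectra=%d): %s",
                    len(excluded), len(runs), min_spectra,
                    ", ".join(f"{e.key}({e.n_spectra})" for e in excluded))
    return kept, excluded


def build_study(design: StudyDesign, runs: Sequence[RunReport],
                contaminants: ContaminantList, annotation: AnnotationTable,
                ) -> StudyTable:
    """Assemble a validated StudyTable.

    Succeeds iff the run keys are exactly the design's expected key set
    (no duplicates, none missing, none out of range).
    """
    expected = design.expected_keys()
    mapping: dict[RunKey, RunReport] = {}
    for r in runs:
        if r.key in mapping:
            raise StudyDesignError(f"duplicate run key {r.key}")
        if r.key not in expected:
            raise StudyDesignError(f"run key {r.key} does not fit the declared design")
        mapping[r.key] = r
    missing = expected - set(mapping)
    if missing:
        raise StudyDesignError(
            f"design expects {len(expected)} runs but {len(missing)} are missing: "
            f"{', '.join(str(k) for k in sorted(missing)[:5])}"
        )
    for d in sorted(design.datasets):
        n = sum(1 for k in mapping if k.dataset == d)
        logger.info("dataset %d: %d runs", d, n)
    return StudyTable(design, mapping, contaminants, annotation)


def subset_design(design: StudyDesign, keys: Iterable[RunKey]) -> StudyDesign:
    """The effective design spanned by ``keys`` (used after QC exclusion).

    Samples that lose all replicates are dropped; sample/replicate indices
    are renumbered contiguously so the result is a valid design.  Raises if
    the surviving replicate counts are unbalanced across a dataset's samples
    (the design model assumes one replicate count per dataset).
    """
    keys = sorted(set(keys))
    out: dict[int, DatasetDesign] = {}
    for d, dd in design.datasets.items():
        per_sample = {}
        for k in keys:
            if k.dataset == d:
                per_sample.setdefault(k.sample, 0)
                per_sample[k.sample] += 1
        if not per_sample:
            continue
        counts = set(per_sample.values())
        if len(counts) != 1:
            raise StudyDesignError(
                f"dataset {d}: unbalanced replicate counts after exclusion {per_sample}; "
                "declare an explicit design instead"
            )
        out[d] = DatasetDesign(dd.state, dd.protocol, len(per_sample), counts.pop())
    if not out:
        raise StudyDesignError("no runs survive QC exclusion")
    return StudyDesign(out)


def renumber_runs(design: StudyDesign, runs: Sequence[RunReport]) -> list[RunReport]:
    """Renumber surviving runs contiguously to match ``subset_design``."""
    by_dataset: dict[int, dict[int, list[RunReport]]] = {}
    for r in sorted(runs, key=lambda r: r.key):
        by_dataset.setdefault(r.key.dataset, {}).setdefault(r.key.sample, []).append(r)
    out = []
    for d, samples in by_dataset.items():
        for si, (_, reps) in enumerate(sorted(samples.items()), start=1):
            for ri, r in enumerate(reps, start=1):
                out.append(RunReport(RunKey(d, si, ri), r.peptides, r.proteins, r.n_spectra))
    return out
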