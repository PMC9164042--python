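"""Hand-built miniature studies for unit tests."""

from nsafpipe import (
    AnnotationTable,
    ContaminantList,
    PeptideEvidence,
    ProteinRow,
    RunKey,
    RunReport,
    StudyDesign,
    build_study,
)
from nsafpipe.report_io import DatasetDesign


def make_run(key, proteins, peptides=(), n_spectra=10000):
    """proteins: (accession, length, spectral_count); peptides:
    (sequence, accessions, score)."""
    return RunReport(
        RunKey.parse(key) if isinstance(key, str) else key,
        tuple(PeptideEvidence(s, frozenset(a), sc) for s, a, sc in peptides),
        tuple(ProteinRow(a, ln, c) for a, ln, c in proteins),
        n_spectra,
    )


def single_dataset_design(n_samples=1, n_replicates=3, state="elective"):
    return StudyDesign({1: DatasetDesign(state, "Protocol X", n_samples, n_replicates)})


def toy_study(design, runs, contaminant_freqs=None, placenta=None,
              extra_exclusions=frozenset()):
    accessions = {p.accession for r in runs for p in r.proteins}
    annotation = AnnotationTable(
        {a: True for a in accessions} if placenta is None else placenta)
    contaminants = ContaminantList(contaminant_freqs or {}, frozenset(extra_exclusions))
    return build_study(design, runs, contaminants, annotation)
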