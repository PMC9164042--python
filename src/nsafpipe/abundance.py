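"""NSAF quantification and abundance categorization.

The normalized spectral abundance factor of protein *i* in a run is

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)

where SpC is the spectral count and L the protein length in amino acids, the
sum running over the run's quantified proteins.  NSAF values therefore sum
to one per run and act as relative abundance proxies.

Replicate reproducibility of a protein is summarized by the coefficient of
variation (sample SD / mean of NSAF across runs) and the fold change
(max / min NSAF).  For occurrence categories, per-protein mean NSAF values
within a dataset are mean-centered (so they sum to zero), sorted ascending,
and split into quartiles: the first quartile is LOW, the fourth HIGH, the
middle two MEDIUM.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .report_io import ProteinRow, StudyTable

logger = logging.getLogger(__name__)


class Category(str, enum.Enum):
    LOW = "LOW"
    MEDIUM = "MEDIUM"
    HIGH = "HIGH"


def nsaf(proteins: Sequence[ProteinRow]) -> dict[str, float]:
    """Per-run NSAF values.

    Proteins with a zero spectral count receive NSAF 0 and are considered
    unquantified in the run (they do not enter the normalizing sum).
    """
    if not proteins:
        raise ValidationError("cannot compute NSAF of an empty protein report")
    saf = {p.accession: p.spectral_count / p.length for p in proteins}
    total = sum(saf.values())
    if total <= 0:
        raise ValidationError("all spectral counts are zero; NSAF undefined")
    zeroes = [a for a, v in saf.items() if v == 0]
    if zeroes:
        logger.debug("%d protein(s) unquantified (zero counts) in run", len(zeroes))
    return {a: v / total for a, v in saf.items()}


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation: sample standard deviation over mean."""
    if len(values) < 2:
        raise ValidationError("CV requires at least 2 values")
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise ValidationError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


def fc(values: Sequence[float]) -> float:
    """Fold change: highest over lowest value."""
    if len(values) < 2:
        raise ValidationError("FC requires at least 2 values")
    arr = np.asarray(values, dtype=float)
    if (arr <= 0).any():
        raise ValidationError("FC requires strictly positive values")
    return float(arr.max() / arr.min())


def center(values: Sequence[float]) -> np.ndarray:
    """Subtract the mean so the values sum to zero; order preserved."""
    if len(values) == 0:
        raise ValidationError("cannot center an empty sequence")
    arr = np.asarray(values, dtype=float)
    return arr - arr.mean()


@dataclass(frozen=True)
class CategoryThresholds:
    """Boundary centered-NSAF values of the quartile split."""

    low_cut: float   # upper boundary of the first quartile (max LOW value)
    high_cut: float  # lower boundary of the fourth quartile (min HIGH value)

    def __post_init__(self) -> None:
        if self.low_cut > self.high_cut:
            raise ValidationError(
                f"low_cut {self.low_cut} exceeds high_cut {self.high_cut}")


def categorize(centered: Mapping[str, float],
               ) -> tuple[dict[str, Category], CategoryThresholds]:
    """Quartile-based occurrence categories from centered mean NSAF values.

    Proteins are sorted ascending (ties broken by accession); the lowest
    floor(n/4) are LOW, the highest floor(n/4) are HIGH, the remainder
    MEDIUM.  Rank cutoffs make the category counts deterministic.
    """
    n = len(centered)
    if n < 4:
        raise ValidationError(f"quartile categorization requires >= 4 proteins, got {n}")
    order = sorted(centered.items(), key=lambda kv: (kv[1], kv[0]))
    q = n // 4
    cats: dict[str, Category] = {}
    for i, (acc, _) in enumerate(order):
        if i < q:
            cats[acc] = Category.LOW
        elif i >= n - q:
            cats[acc] = Category.HIGH
        else:
            cats[acc] = Category.MEDIUM
    thresholds = CategoryThresholds(low_cut=order[q - 1][1], high_cut=order[n - q][1])
    return cats, thresholds


def threshold_summary(thresholds: Sequence[CategoryThresholds],
                      ) -> dict[str, tuple[float, float]]:
    """Mean and sample SD of the LOW/HIGH boundaries across datasets,
    rounded to 3 decimals."""
    if len(thresholds) < 2:
        raise ValidationError("threshold summary requires >= 2 datasets")
    lows = np.array([t.low_cut for t in thresholds])
    highs = np.array([t.high_cut for t in thresholds])
    return {
        "low_cut": (round(float(lows.mean()), 3), round(float(lows.std(ddof=1)), 3)),
        "high_cut": (round(float(highs.mean()), 3), round(float(highs.std(ddof=1)), 3)),
    }


# ---------------------------------------------------------------------------
# dataset-level tables
# ---------------------------------------------------------------------------

def run_nsaf_tables(study: StudyTable, dataset: int) -> dict[str, dict[str, float]]:
    """NSAF per run of a dataset, keyed by the run's string key."""
    return {str(r.key): nsaf(r.proteins) for r in study.dataset_runs(dataset)}


def abundance_records(study: StudyTable, dataset: int,
                      proteins: Iterable[str]) -> pd.DataFrame:
    """Per-protein NSAF reproducibility statistics over a dataset's runs.

    Only positive (quantified) NSAF observations enter CV/FC.  Proteins with
    fewer than 2 observations get NaN statistics and are flagged.
    """
    per_run = run_nsaf_tables(study, dataset)
    rows = []
    for acc in sorted(proteins):
        vals = [v[acc] for v in per_run.values() if v.get(acc, 0.0) > 0.0]
        rec = {"accession": acc, "n_runs": len(vals),
               "mean_nsaf": float(np.mean(vals)) if vals else np.nan,
               "cv": np.nan, "fc": np.nan}
        if len(vals) >= 2:
            rec["cv"] = cv(vals)
            rec["fc"] = fc(vals)
        rows.append(rec)
    return pd.DataFrame(rows, columns=["accession", "n_runs", "mean_nsaf", "cv", "fc"])


def categorize_dataset(table: pd.DataFrame,
                       ) -> tuple[pd.DataFrame, CategoryThresholds]:
    """Add centered mean NSAF and occurrence categories to an abundance table."""
    table = table.dropna(subset=["mean_nsaf"]).copy()
    centered_vals = center(table["mean_nsaf"].to_numpy())
    table["centered_nsaf"] = centered_vals
    cats, thresholds = categorize(dict(zip(table["accession"], centered_vals)))
    table["category"] = [cats[a].value for a in table["accession"]]
    return table, thresholds


def low_abundance_crosscheck(categories_by_dataset: Mapping[int, Mapping[str, Category]],
                             external_low: Iterable[str]) -> dict[str, str]:
    """Intersect LOW-category proteins with an externally supplied
    low-expression list (e.g. a tissue atlas extract).

    Returns accession -> comma-joined dataset provenance, e.g. ``"1, 6"``.
    """
    external = set(external_low)
    found: dict[str, list[int]] = {}
    for dataset, cats in categories_by_dataset.items():
        for acc, cat in cats.items():
            if cat is Category.LOW and acc in external:
                found.setdefault(acc, []).append(dataset)
    return {acc: ", ".join(str(d) for d in sorted(ds)) for acc, ds in sorted(found.items())}
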