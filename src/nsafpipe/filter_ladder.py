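"""The six-stage identification/quantification filter ladder.

Each dataset's protein complement is reduced in a fixed order:

    P_total      union of all accessions reported in any run
    P_placenta   restricted to placenta-annotated accessions, with CRAPome
                 contaminants (frequency >= cutoff) and the unconditional
                 exclusions removed
    I_successful confident identification: >= 2 distinct peptides, each
                 scoring >= 99, in at least one run
    I_proteins   >= 2 distinct peptides (any score) in the required fraction
                 of a sample's replicates, in at least one sample
    I_reliably   the I_proteins per-sample criterion met in the required
                 fraction of the dataset's samples
    Q_reliably   reproducibly quantified: CV of NSAF <= 0.16 OR fold change
                 of NSAF <= 1.25 across the dataset's runs

Stages are intersected with their predecessor, so the sets form a chain
P_total ⊇ P_placenta ⊇ ... ⊇ Q_reliably.

"2/3 or more" occupancy generalizes to >= ceil(2k/3) of k items; note that
for k = 2 this coincides with "all", so the two rule flavours differ only
for k >= 3.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import abundance
from .errors import ValidationError
from .report_io import AnnotationTable, ContaminantList, RunReport, StudyTable

logger = logging.getLogger(__name__)

STAGES = ("P_total", "P_placenta", "I_successful", "I_proteins", "I_reliably", "Q_reliably")


class OccupancyRule(str, enum.Enum):
    """How many of a group's members (replicates or samples) must qualify."""

    ALL = "all"
    TWO_THIRDS = "two_thirds"


def required_count(k: int, rule: OccupancyRule) -> int:
    if k < 1:
        raise ValidationError("group size must be >= 1")
    if rule is OccupancyRule.ALL:
        return k
    return math.ceil(2 * k / 3)


@dataclass(frozen=True)
class LadderRules:
    """Tunable thresholds of the ladder.

    ``replicate_rule``/``sample_rule`` map dataset id -> occupancy rule and
    fall back to the given default for datasets not listed.
    """

    min_peptides: int = 2
    min_score: float = 99.0
    contaminant_freq_cutoff: float = 0.67
    cv_max: float = 0.16
    fc_max: float = 1.25
    replicate_rule: Mapping[int, OccupancyRule] = field(default_factory=dict)
    sample_rule: Mapping[int, OccupancyRule] = field(default_factory=dict)
    default_replicate_rule: OccupancyRule = OccupancyRule.TWO_THIRDS
    default_sample_rule: OccupancyRule = OccupancyRule.ALL

    def __post_init__(self) -> None:
        if self.min_peptides < 1:
            raise ValidationError("min_peptides must be >= 1")
        if not (0.0 <= self.contaminant_freq_cutoff <= 1.0):
            raise ValidationError("contaminant_freq_cutoff must lie in [0, 1]")
        if self.cv_max <= 0:
            raise ValidationError("cv_max must be > 0")
        if self.fc_max < 1:
            raise ValidationError("fc_max must be >= 1")

    def replicate_rule_for(self, dataset: int) -> OccupancyRule:
        return self.replicate_rule.get(dataset, self.default_replicate_rule)

    def sample_rule_for(self, dataset: int) -> OccupancyRule:
        return self.sample_rule.get(dataset, self.default_sample_rule)

    @classmethod
    def chorionic_villus_rules(cls) -> "LadderRules":
        """The rules used for the six-dataset chorionic-villus study:
        replicate occupancy ALL for the 2-replicate datasets (1, 4) and
        2/3 for the 3-replicate ones (2, 3, 5, 6); sample occupancy 2/3 for
        the multi-sample dataset 1 and ALL elsewhere."""
        return cls(
            replicate_rule={1: OccupancyRule.ALL, 4: OccupancyRule.ALL,
                            2: OccupancyRule.TWO_THIRDS, 3: OccupancyRule.TWO_THIRDS,
                            5: OccupancyRule.TWO_THIRDS, 6: OccupancyRule.TWO_THIRDS},
            sample_rule={1: OccupancyRule.TWO_THIRDS},
        )


@dataclass(frozen=True)
class FilterLadderResult:
    """Per-dataset protein sets at each ladder stage."""

    stages: Mapping[int, Mapping[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for d, by_stage in self.stages.items():
            for a, b in zip(STAGES, STAGES[1:]):
                if not by_stage[b] <= by_stage[a]:
                    raise ValidationError(f"dataset {d}: stage {b} is not a subset of {a}")

    def counts(self) -> dict[int, dict[str, int]]:
        return {d: {s: len(v[s]) for s in STAGES} for d, v in sorted(self.stages.items())}

    def stage_set(self, dataset: int, stage: str) -> frozenset[str]:
        return self.stages[dataset][stage]


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def p_total(runs: Sequence[RunReport]) -> frozenset[str]:
    """Union of all accessions reported in any run of the dataset."""
    if not runs:
        raise ValidationError("p_total requires at least one run")
    return frozenset().union(*(r.accessions for r in runs))


def p_placenta(total: frozenset[str], contaminants: ContaminantList,
               annotation: AnnotationTable, cutoff: float = 0.67) -> frozenset[str]:
    """Placenta-annotated accessions minus contaminants.

    Removes accessions with contaminant identification frequency >= cutoff,
    removes the unconditional exclusions, and keeps only accessions with a
    known placental transcript.  The three restrictions commute.
    """
    return frozenset(
        a for a in total
        if not contaminants.is_excluded(a, cutoff) and annotation.placenta_transcript(a)
    )


def _distinct_peptides(run: RunReport, accession: str, min_score: float) -> int:
    return len({p.sequence for p in run.peptides
                if accession in p.protein_accessions and p.score >= min_score})


def i_successful(runs: Sequence[RunReport], survivors: frozenset[str],
                 rules: LadderRules) -> frozenset[str]:
    """Confident identification: >= min_peptides distinct peptide sequences,
    each scoring >= min_score, within a single run."""
    out = set()
    for acc in survivors:
        for run in runs:
            if _distinct_peptides(run, acc, rules.min_score) >= rules.min_peptides:
                out.add(acc)
                break
    return frozenset(out)


def _sample_qualifies(sample_runs: Sequence[RunReport], accession: str,
                      rules: LadderRules, rule: OccupancyRule) -> bool:
    k = len(sample_runs)
    need = required_count(k, rule)
    hits = sum(1 for run in sample_runs
               if _distinct_peptides(run, accession, 0.0) >= rules.min_peptides)
    return hits >= need


def _runs_by_sample(runs: Sequence[RunReport]) -> dict[int, list[RunReport]]:
    by_sample: dict[int, list[RunReport]] = {}
    for r in runs:
        by_sample.setdefault(r.key.sample, []).append(r)
    return by_sample


def i_proteins(runs: Sequence[RunReport], survivors: frozenset[str],
               rules: LadderRules, dataset: int) -> frozenset[str]:
    """Replicate-level reproducible identification: >= min_peptides distinct
    peptides (any score) in the required fraction of a sample's replicates,
    in at least one sample."""
    by_sample = _runs_by_sample(runs)
    rule = rules.replicate_rule_for(dataset)
    return frozenset(
        acc for acc in survivors
        if any(_sample_qualifies(sr, acc, rules, rule) for sr in by_sample.values())
    )


def i_reliably(runs: Sequence[RunReport], survivors: frozenset[str],
               rules: LadderRules, dataset: int) -> frozenset[str]:
    """Sample-level reproducible identification: the i_proteins per-sample
    criterion met in the required fraction of the dataset's samples.
    Degenerates to I_proteins for single-sample datasets."""
    by_sample = _runs_by_sample(runs)
    rep_rule = rules.replicate_rule_for(dataset)
    need = required_count(len(by_sample), rules.sample_rule_for(dataset))
    out = set()
    for acc in survivors:
        hits = sum(1 for sr in by_sample.values()
                   if _sample_qualifies(sr, acc, rules, rep_rule))
        if hits >= need:
            out.add(acc)
    return frozenset(out)


def q_reliably(nsaf_by_run: Mapping[str, Mapping[str, float]],
               survivors: frozenset[str], rules: LadderRules) -> frozenset[str]:
    """Reproducible quantification: CV <= cv_max OR FC <= fc_max over the
    protein's positive NSAF values across the dataset's runs.

    The criterion is the printed disjunction: a protein passes on either
    ground.  Proteins with fewer than 2 quantified observations are dropped
    (CV/FC undefined) and logged.
    """
    out = set()
    underquantified = []
    for acc in survivors:
        vals = [table[acc] for table in nsaf_by_run.values() if table.get(acc, 0.0) > 0.0]
        if len(vals) < 2:
            underquantified.append(acc)
            continue
        if abundance.cv(vals) <= rules.cv_max or abundance.fc(vals) <= rules.fc_max:
            out.add(acc)
    if underquantified:
        logger.info("%d protein(s) dropped from Q_reliably with < 2 NSAF observations",
                    len(underquantified))
    return frozenset(out)


# ---------------------------------------------------------------------------
# the full ladder and the summary statistic
# ---------------------------------------------------------------------------

def run_ladder(study: StudyTable, rules: LadderRules) -> FilterLadderResult:
    """Apply all six stages, per dataset, in order."""
    stages: dict[int, dict[str, frozenset[str]]] = {}
    for d in study.dataset_ids():
        runs = study.dataset_runs(d)
        total = p_total(runs)
        placenta = p_placenta(total, study.contaminants, study.annotation,
                              rules.contaminant_freq_cutoff)
        succ = i_successful(runs, placenta, rules)
        prot = i_proteins(runs, succ, rules, d)
        reli = i_reliably(runs, prot, rules, d)
        nsaf_by_run = abundance.run_nsaf_tables(study, d)
        quant = q_reliably(nsaf_by_run, reli, rules)
        stages[d] = {"P_total": total, "P_placenta": placenta, "I_successful": succ,
                     "I_proteins": prot, "I_reliably": reli, "Q_reliably": quant}
        logger.info("dataset %d attrition: %s", d,
                    " -> ".join(f"{s}={len(stages[d][s])}" for s in STAGES))
    return FilterLadderResult(stages)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_counts(values: Sequence[int]) -> tuple[int, int]:
    """Mean and sample standard deviation (n-1 denominator) of a count
    column, each rounded half-away-from-zero to an integer."""
    if len(values) < 2:
        raise ValidationError("summarize_counts requires >= 2 values")
    arr = np.asarray(values, dtype=float)
    return _round_half_away(float(arr.mean())), _round_half_away(float(arr.std(ddof=1)))
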