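"""End-to-end orchestration: read/QC -> filter ladder -> NSAF abundance ->
set comparison, driven by one configuration file.

All outputs are deterministic functions of the inputs, the configuration
and the seed; rerunning on identical inputs yields byte-identical files
(the provenance block records a configuration hash, never a timestamp).
Outputs are assembled in a temporary directory and committed only on
success, so a failing stage leaves no partial results behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .abundance import (
    Category,
    CategoryThresholds,
    abundance_records,
    categorize_dataset,
    low_abundance_crosscheck,
    threshold_summary,
)
from .errors import ConfigError, ValidationError
from .filter_ladder import (
    STAGES,
    FilterLadderResult,
    LadderRules,
    OccupancyRule,
    run_ladder,
    summarize_counts,
)
from .report_io import (
    RunKey,
    StudyTable,
    build_study,
    qc_runs,
    read_annotation_table,
    read_contaminant_table,
    read_design,
    read_run_report,
    renumber_runs,
    subset_design,
    write_study_long,
    _read_tsv,
)
from .set_comparison import (
    EntanglementResult,
    RankSumResult,
    cluster,
    design_leaf_order,
    entanglement,
    exclusive_intersections,
    protocol_variability_comparison,
    stage_run_lists,
    variability_matrix,
)

logger = logging.getLogger(__name__)


def rules_from_dict(raw: Mapping | None) -> LadderRules:
    """Build LadderRules from a configuration mapping (missing keys keep
    their defaults; occupancy rules given as 'all' / 'two_thirds')."""
    if not raw:
        return LadderRules.chorionic_villus_rules()
    kwargs = {}
    for key in ("min_peptides", "min_score", "contaminant_freq_cutoff", "cv_max", "fc_max"):
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("replicate_rule", "sample_rule"):
        if key in raw:
            kwargs[key] = {int(d): OccupancyRule(v) for d, v in raw[key].items()}
    for key in ("default_replicate_rule", "default_sample_rule"):
        if key in raw:
            kwargs[key] = OccupancyRule(raw[key])
    return LadderRules(**kwargs)


@dataclass(frozen=True)
class ComparisonSettings:
    stage: str = "Q_reliably"
    group_a: tuple[int, ...] = ()
    group_b: tuple[int, ...] = ()
    linkage: str = "complete"
    entanglement_exponent: float = 1.5
    untangle: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    study_dir: Path
    output_dir: Path
    min_spectra: int = 0
    rules: LadderRules = field(default_factory=LadderRules.chorionic_villus_rules)
    comparison: ComparisonSettings = field(default_factory=ComparisonSettings)
    external_low_list: Path | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            comp = raw.get("comparison", {}) or {}
            return cls(
                study_dir=Path(raw["study_dir"]),
                output_dir=Path(raw["output_dir"]),
                min_spectra=int(raw.get("min_spectra", 0)),
                rules=rules_from_dict(raw.get("rules")),
                comparison=ComparisonSettings(
                    stage=comp.get("stage", "Q_reliably"),
                    group_a=tuple(comp.get("group_a", ())),
                    group_b=tuple(comp.get("group_b", ())),
                    linkage=comp.get("linkage", "complete"),
                    entanglement_exponent=float(comp.get("entanglement_exponent", 1.5)),
                    untangle=bool(comp.get("untangle", False)),
                ),
                external_low_list=(Path(raw["external_low_list"])
                                   if raw.get("external_low_list") else None),
                seed=int(raw.get("seed", 0)),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: missing required key {exc}") from exc

    def validate(self) -> None:
        """Fail-fast path and settings validation (before any computation)."""
        for name, p in (("study_dir", self.study_dir),
                        ("external_low_list", self.external_low_list)):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name} does not exist: {p}")
        for fname in ("design.yaml", "contaminants.tsv", "annotation.tsv", "runs.tsv"):
            if not (self.study_dir / fname).exists():
                raise ConfigError(f"study_dir is missing {fname}: {self.study_dir / fname}")
        if self.comparison.stage not in STAGES:
            raise ConfigError(f"unknown comparison stage {self.comparison.stage!r}")
        if self.min_spectra < 0:
            raise ConfigError("min_spectra must be >= 0")

    def digest(self) -> str:
        # output_dir is deliberately not hashed: it has no effect on results
        blob = json.dumps({
            "study_dir": str(self.study_dir),
            "min_spectra": self.min_spectra, "seed": self.seed,
            "rules": {"min_peptides": self.rules.min_peptides,
                      "min_score": self.rules.min_score,
                      "contaminant_freq_cutoff": self.rules.contaminant_freq_cutoff,
                      "cv_max": self.rules.cv_max, "fc_max": self.rules.fc_max,
                      "replicate_rule": {d: r.value for d, r in sorted(self.rules.replicate_rule.items())},
                      "sample_rule": {d: r.value for d, r in sorted(self.rules.sample_rule.items())},
                      "default_replicate_rule": self.rules.default_replicate_rule.value,
                      "default_sample_rule": self.rules.default_sample_rule.value},
            "comparison": {"stage": self.comparison.stage,
                           "group_a": list(self.comparison.group_a),
                           "group_b": list(self.comparison.group_b),
                           "linkage": self.comparison.linkage,
                           "L": self.comparison.entanglement_exponent,
                           "untangle": self.comparison.untangle},
            "external_low_list": str(self.external_low_list) if self.external_low_list else None,
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    counts: pd.DataFrame
    footers: list[str]
    thresholds: dict[int, CategoryThresholds]
    thresholds_summary: dict[str, tuple[float, float]] | None
    intersections: dict[str, pd.DataFrame]
    entanglements: dict[str, EntanglementResult]
    rank_sum: RankSumResult | None
    crosscheck: dict[str, str]
    excluded_runs: list[str]
    provenance: dict


def load_study(config: PipelineConfig) -> tuple[StudyTable, list[str]]:
    """Read a study directory, applying run-level QC exclusion.

    When runs are excluded, the effective design spanned by the surviving
    runs replaces the declared one (replicate indices renumbered).
    """
    design = read_design(config.study_dir / "design.yaml")
    contaminants = read_contaminant_table(config.study_dir / "contaminants.tsv")
    annotation = read_annotation_table(config.study_dir / "annotation.tsv")
    runs_df = _read_tsv(config.study_dir / "runs.tsv", ["run", "n_spectra"])
    runs = [read_run_report(config.study_dir / "runs", RunKey.parse(str(r.run)),
                            int(r.n_spectra))
            for r in runs_df.itertuples(index=False)]
    kept, excluded = qc_runs(runs, config.min_spectra)
    if excluded:
        design = subset_design(design, [r.key for r in kept])
        kept = renumber_runs(design, kept)
    study = build_study(design, kept, contaminants, annotation)
    return study, [str(e.key) for e in excluded]


def render_table2(ladder: FilterLadderResult,
                  groupings: Sequence[tuple[str, Sequence[int], str]] = (),
                  ) -> tuple[pd.DataFrame, list[str]]:
    """Counts table (one dataset per row, six stage columns in ladder order)
    plus mean ± SD footer lines for the requested (label, datasets, stage)
    groupings."""
    counts = ladder.counts()
    df = pd.DataFrame(
        [{"dataset": d, **{s: counts[d][s] for s in STAGES}} for d in sorted(counts)],
        columns=["dataset", *STAGES])
    footers = []
    for label, datasets, stage in groupings:
        vals = [counts[d][stage] for d in datasets]
        mean, sd = summarize_counts(vals)
        footers.append(f"{label} {stage}: {mean} ± {sd} (n = {len(vals)})")
    return df, footers


def default_groupings(study: StudyTable) -> list[tuple[str, list[int], str]]:
    by_state: dict[str, list[int]] = {}
    for d, dd in sorted(study.design.datasets.items()):
        by_state.setdefault(dd.state, []).append(d)
    groupings = [(state, ds, "I_successful")
                 for state, ds in by_state.items() if len(ds) >= 2]
    if len(study.design.datasets) >= 2:
        groupings.append(("all", sorted(study.design.datasets), "Q_reliably"))
    return groupings


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full pipeline and write all outputs to
    ``config.output_dir``."""
    config.validate()
    study, excluded = load_study(config)
    ladder = run_ladder(study, config.rules)

    # abundance per dataset, on the Q_reliably survivors
    thresholds: dict[int, CategoryThresholds] = {}
    abundance_tables: dict[int, pd.DataFrame] = {}
    categories: dict[int, dict[str, Category]] = {}
    for d in study.dataset_ids():
        q = ladder.stage_set(d, "Q_reliably")
        table = abundance_records(study, d, q)
        if len(table.dropna(subset=["mean_nsaf"])) >= 4:
            table, thr = categorize_dataset(table)
            thresholds[d] = thr
            categories[d] = {a: Category(c) for a, c in zip(table["accession"], table["category"])}
        else:
            logger.warning("dataset %d: %d quantified proteins, too few for quartiles",
                           d, len(table))
        abundance_tables[d] = table
    thr_summary = (threshold_summary(list(thresholds.values()))
                   if len(thresholds) >= 2 else None)

    # cross-dataset set comparison
    intersections = {
        stage: exclusive_intersections(
            {d: ladder.stage_set(d, stage) for d in study.dataset_ids()})
        for stage in ("I_reliably", "Q_reliably")
    }
    matrices, dendrograms, entanglements = {}, {}, {}
    for stage in ("I_successful", "Q_reliably"):
        lists = stage_run_lists(study, ladder, stage)
        if len(lists) >= 2 and all(lists.values()):
            mat = variability_matrix(lists)
            tree = cluster(mat, config.comparison.linkage)
            matrices[stage] = mat
            dendrograms[stage] = tree
            entanglements[stage] = entanglement(
                design_leaf_order(study), tree,
                L=config.comparison.entanglement_exponent,
                untangle=config.comparison.untangle)

    rank_sum = None
    if config.comparison.group_a and config.comparison.group_b:
        rank_sum = protocol_variability_comparison(
            study, ladder, config.comparison.stage,
            config.comparison.group_a, config.comparison.group_b)

    crosscheck: dict[str, str] = {}
    if config.external_low_list is not None:
        ext = _read_tsv(config.external_low_list, ["accession"])
        crosscheck = low_abundance_crosscheck(
            categories, [str(a).strip() for a in ext["accession"]])

    groupings = default_groupings(study)
    counts_df, footers = render_table2(ladder, groupings)

    report = PipelineReport(
        counts=counts_df, footers=footers, thresholds=thresholds,
        thresholds_summary=thr_summary, intersections=intersections,
        entanglements=entanglements, rank_sum=rank_sum, crosscheck=crosscheck,
        excluded_runs=excluded,
        provenance={"package_version": __version__, "config_hash": config.digest(),
                    "seed": config.seed},
    )
    _write_outputs(config, study, ladder, abundance_tables, matrices,
                   dendrograms, report)
    return report


def _write_outputs(config: PipelineConfig, study: StudyTable,
                   ladder: FilterLadderResult,
                   abundance_tables: Mapping[int, pd.DataFrame],
                   matrices, dendrograms, report: PipelineReport) -> None:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        write_study_long(study, tmp / "study_long.tsv", tmp / "study_manifest.json")
        report.counts.to_csv(tmp / "ladder_counts.tsv", sep="\t", index=False)

        stage_rows = []
        for d in study.dataset_ids():
            order = {s: i for i, s in enumerate(STAGES)}
            for acc in sorted(ladder.stage_set(d, "P_total")):
                last = max((s for s in STAGES if acc in ladder.stage_set(d, s)),
                           key=order.get)
                stage_rows.append({"dataset": d, "accession": acc, "last_stage_passed": last})
        pd.DataFrame(stage_rows, columns=["dataset", "accession", "last_stage_passed"]).to_csv(
            tmp / "stage_membership.tsv", sep="\t", index=False)

        (tmp / "abundance").mkdir()
        for d, table in abundance_tables.items():
            table.to_csv(tmp / "abundance" / f"dataset_{d}.tsv", sep="\t", index=False)

        for stage, df in report.intersections.items():
            out = df.copy()
            out["combination"] = ["+".join(map(str, c)) for c in out["combination"]]
            out["members"] = [";".join(m) for m in out["members"]]
            out.to_csv(tmp / f"intersections_{stage}.tsv", sep="\t", index=False)
        for stage, mat in matrices.items():
            mat.to_frame().to_csv(tmp / f"variability_{stage}.tsv", sep="\t")
        for stage, tree in dendrograms.items():
            (tmp / f"dendrogram_{stage}.nwk").write_text(tree.to_newick() + "\n")

        summary = {
            "ladder_counts": {str(d): c for d, c in ladder.counts().items()},
            "summary_lines": report.footers,
            "thresholds": {str(d): {"low_cut": t.low_cut, "high_cut": t.high_cut}
                           for d, t in report.thresholds.items()},
            "thresholds_summary": report.thresholds_summary,
            "entanglement": {s: {"value": e.value, "exponent": e.exponent}
                             for s, e in report.entanglements.items()},
            "rank_sum": (None if report.rank_sum is None else
                         {"W": report.rank_sum.statistic, "p": report.rank_sum.p_value,
                          "n1": report.rank_sum.n1, "n2": report.rank_sum.n2,
                          "method": report.rank_sum.method,
                          "significant_at_0.05": report.rank_sum.p_value <= 0.05}),
            "low_abundance_crosscheck": report.crosscheck,
            "excluded_runs": report.excluded_runs,
            "provenance": report.provenance,
        }
        with open(tmp / "report.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)

        config.output_dir.mkdir(parents=True, exist_ok=True)
        for item in tmp.iterdir():
            target = config.output_dir / item.name
            if item.is_dir():
                if target.exists():
                    shutil.rmtree(target)
                shutil.copytree(item, target)
            else:
                shutil.copy2(item, target)
    logger.info("pipeline outputs written to %s", config.output_dir)
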