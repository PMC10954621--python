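"""End-to-end study replica: configuration, orchestration and file output.

``run_full_study`` chains every stage — cohort generation (or CSV input),
exclusions, 70/30 split, optional SMOTE, per-site score development, weighted
overall-score combination and the cross-site validation grid — and writes all
artifacts (demographics tables, SMD comparison, parsimony curves, scorecards,
weights, validation report and a run manifest) to an output directory. A
fixed configuration reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .cohort import Cohort, generate_cohort
from .imbalance import ResamplingPlan
from .model import TriageScoreModel
from .multisite import overall_score, site_weights
from .ops import apply_exclusions, demographics_table, pairwise_smd
from .profiles import SiteProfile, default_profiles
from .scoring import CLINICAL_SCORE_VARS, CutoffScheme, ScoreTable, apply_score
from .validation import cross_validation_matrix

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure; carries a machine-readable error record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.record = {"stage": stage, "error": message}


@dataclass
class PipelineConfig:
    """Configuration of a full study run.

    ``profiles`` is ``"builtin"`` or a list of YAML profile paths;
    ``cohort_size`` is drawn per site. ``cutoffs`` is ``"clinical"``,
    ``"auto-quantile"`` or a YAML cutoff-scheme path. ``n_variables`` forces
    the scorecard size (None lets the parsimony curve decide at
    ``parsimony_tol``).
    """

    profiles: str | list[str] = "builtin"
    cohort_size: int = 30_000
    seed: int = 0
    exclusions: bool = True
    dev_fraction: float = 0.7
    smote: bool = True
    smote_k: int = 5
    smote_multiplier: float = 2.0
    smote_majority_target: str = "match-enlarged"
    cutoffs: str = "clinical"
    # "clinical" fixes the published 8-variable list (clinical-review
    # substitution after ranking) so per-site tables stay structurally
    # compatible for combination; "ranked" takes each site's top-n_variables.
    variable_policy: str = "clinical"
    n_variables: int | None = 8
    parsimony_tol: float = 0.005
    rf_trees: int = 500
    bootstrap_reps: int = 1000
    bootstrap_level: float = 0.95
    threshold: str | float = "youden"
    output_dir: str = "edscore_run"
    write_cohorts: bool = False

    def validate(self) -> None:
        if not 0.0 < self.dev_fraction < 1.0:
            raise PipelineError("config", f"dev_fraction {self.dev_fraction} outside (0, 1)")
        if self.cohort_size < 1:
            raise PipelineError("config", "cohort_size must be positive")
        if int(self.seed) != self.seed:
            raise PipelineError("config", "seed must be an integer")
        if self.bootstrap_reps < 1:
            raise PipelineError("config", "bootstrap_reps must be positive")
        if not 0.0 < self.bootstrap_level < 1.0:
            raise PipelineError("config", "bootstrap_level outside (0, 1)")
        if self.variable_policy not in ("clinical", "ranked"):
            raise PipelineError("config", f"unknown variable_policy {self.variable_policy!r}")
        if self.cutoffs not in ("clinical", "auto-quantile") and not Path(self.cutoffs).exists():
            raise PipelineError("config", f"cutoff scheme file not found: {self.cutoffs}")
        if isinstance(self.profiles, list):
            for p in self.profiles:
                if not Path(p).exists():
                    raise PipelineError("config", f"profile file not found: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_dict(self) -> dict:
        return asdict(self)


def _load_profiles(config: PipelineConfig) -> list[SiteProfile]:
    if config.profiles == "builtin":
        return default_profiles()
    return [SiteProfile.from_yaml(p) for p in config.profiles]


def run_full_study(config: PipelineConfig) -> Path:
    """Run every stage and write artifacts; returns the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "error.json").unlink(missing_ok=True)

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as err:
            record = PipelineError(name, str(err))
            with open(out / "error.json", "w") as fh:
                json.dump(record.record, fh, indent=2)
            raise record from err

    profiles = stage("profiles", _load_profiles, config)

    cohorts: dict[str, Cohort] = {}
    for i, profile in enumerate(profiles):
        cohort = stage(
            f"generate[{profile.site_id}]",
            generate_cohort,
            profile,
            config.cohort_size,
            config.seed + i,
        )
        if config.exclusions:
            cohort, tally = stage(f"exclusions[{profile.site_id}]", apply_exclusions, cohort)
            logger.info("site %s exclusions: %s", profile.site_id, tally)
        cohorts[profile.site_id] = cohort
        if config.write_cohorts:
            cohort.to_csv(out / f"cohort_{profile.site_id}.csv")

    for site, cohort in cohorts.items():
        report = stage(f"demographics[{site}]", demographics_table, cohort)
        report.to_csv(out / f"demographics_{site}.csv")
        (out / f"demographics_{site}.md").write_text(report.to_markdown())

    sites = list(cohorts)
    smd_rows = []
    for i, a in enumerate(sites):
        for b in sites[i + 1 :]:
            tab = stage(f"smd[{a},{b}]", pairwise_smd, cohorts[a], cohorts[b])
            tab.insert(0, "pair", f"{a}-{b}")
            smd_rows.append(tab)
    pd.concat(smd_rows, ignore_index=True).to_csv(out / "smd_pairwise.csv", index=False)

    cutoffs: str | CutoffScheme = config.cutoffs
    if cutoffs not in ("clinical", "auto-quantile"):
        cutoffs = CutoffScheme.from_yaml(cutoffs)
    plan = (
        ResamplingPlan(
            k_neighbors=config.smote_k,
            minority_multiplier=config.smote_multiplier,
            majority_target=config.smote_majority_target,
            seed=config.seed,
        )
        if config.smote
        else False
    )

    tables: dict[str, ScoreTable] = {}
    weight_inputs = []
    test_cohorts: dict[str, Cohort] = {}
    for site, cohort in cohorts.items():
        results = stage(
            f"develop[{site}]",
            lambda c=cohort, s=site: TriageScoreModel.from_cohort(c).fit(
                seed=config.seed,
                dev_fraction=config.dev_fraction,
                smote=plan,
                cutoffs=cutoffs,
                variables=(
                    list(CLINICAL_SCORE_VARS)
                    if config.variable_policy == "clinical"
                    else None
                ),
                n_variables=config.n_variables,
                parsimony_tol=config.parsimony_tol,
                rf_trees=config.rf_trees,
                bootstrap_reps=config.bootstrap_reps,
            ),
        )
        tables[site] = results.score_table
        test_cohorts[site] = results.test
        weight_inputs.append((site, results.auroc, len(cohort)))
        results.score_table.to_json(out / f"scorecard_{site}.json")
        (out / f"scorecard_{site}.md").write_text(results.score_table.to_markdown())
        if results.parsimony is not None:
            results.parsimony.to_frame().to_csv(out / f"parsimony_{site}.csv", index=False)
        (out / f"summary_{site}.txt").write_text(results.summary() + "\n")

    weights = stage("weights", site_weights, weight_inputs)
    with open(out / "weights.json", "w") as fh:
        json.dump(
            [{"site_id": w.site_id, "auc": w.auc, "n": w.n, "weight": w.weight} for w in weights],
            fh,
            indent=2,
        )
    overall = stage("combine", overall_score, list(tables.values()), weights)
    overall.to_json(out / "scorecard_overall.json")
    (out / "scorecard_overall.md").write_text(overall.to_markdown())

    all_tables = dict(tables)
    all_tables["overall"] = overall
    report = stage(
        "validate",
        cross_validation_matrix,
        all_tables,
        test_cohorts,
        seed=config.seed,
        reps=config.bootstrap_reps,
        level=config.bootstrap_level,
        threshold=config.threshold,
        include_threshold_metrics=True,
    )
    report.to_csv(out / "validation_report.csv")
    (out / "validation_report.md").write_text(report.to_markdown())

    manifest = {"package_version": __version__, "config": config.to_dict()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def read_patient_csv(path, column_map: dict | str | None = None) -> pd.DataFrame:
    """Read a patient-level CSV, optionally renaming foreign column names.

    ``column_map`` maps source column names (e.g. OMOP-style measurement
    exports such as ``systolic_blood_pressure``) onto triage record fields;
    it may be a dict or the path of a YAML file holding one. This thin
    renaming layer stands in for a full common-data-model ETL, which is out
    of scope.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as err:
        raise PipelineError("read", f"empty input file: {path}") from err
    if column_map:
        if not isinstance(column_map, dict):
            with open(column_map) as fh:
                column_map = yaml.safe_load(fh)
        unknown = [c for c in column_map if c not in df.columns]
        if unknown:
            raise PipelineError("read", f"mapped columns absent from input: {unknown}")
        df = df.rename(columns=column_map)
    return df


def score_patients(
    input_csv, scorecard_json, output_csv, column_map: dict | str | None = None
) -> pd.DataFrame:
    """Score a patient CSV with a scorecard JSON; append ``total_score``.

    Raises on empty input (no output written); unmapped category values are
    reported per row in the error message. ``column_map`` is forwarded to
    :func:`read_patient_csv`.
    """
    try:
        df = read_patient_csv(input_csv, column_map)
    except PipelineError as err:
        raise PipelineError("score", err.record["error"]) from err
    if df.empty:
        raise PipelineError("score", f"no records in input file: {input_csv}")
    table = ScoreTable.from_json(scorecard_json)
    try:
        totals = apply_score(df, table)
    except Exception:
        # per-row error report
        errors = []
        totals = []
        for i, row in df.iterrows():
            try:
                totals.append(apply_score(row.to_dict(), table))
            except Exception as err:
                errors.append(f"row {i}: {err}")
        if errors:
            raise PipelineError("score", "; ".join(errors)) from None
    out = df.copy()
    out["total_score"] = totals
    out.to_csv(output_csv, index=False)
    return out
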