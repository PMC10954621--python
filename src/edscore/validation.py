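"""Internal and cross-hospital score evaluation.

AUROC is the Mann–Whitney concordance probability
P(score_pos > score_neg) + 0.5 * P(tie) — integer point scores tie often, so
half-credit tie handling matters. Confidence intervals are percentile
bootstrap over record indices (default 1000 replicates). Threshold metrics
(accuracy, sensitivity, specificity, PPV, NPV) are reported at an explicit
threshold or at the Youden-optimal one (maximising sensitivity +
specificity - 1 on the evaluated data).

``cross_validation_matrix`` fills the (score source × test site) grid:
diagonal cells are internal validation, off-diagonal cells external
transport of one hospital's score to another hospital's patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort
from .schema import OUTCOME
from .scoring import ScoreTable, apply_score

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


def _check_classes(outcomes: np.ndarray) -> tuple[int, int]:
    n_pos = int(outcomes.sum())
    n_neg = int(len(outcomes) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both outcome classes must be present")
    return n_pos, n_neg


def auroc(scores, outcomes) -> float:
    """Mann–Whitney AUROC with half-credit for ties.

    Rank-based computation; equals exhaustive enumeration of
    positive–negative pairs.
    """
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes).astype(bool)
    n_pos, n_neg = _check_classes(outcomes)
    ranks = stats.rankdata(scores)  # average ranks handle ties
    u = ranks[outcomes].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_ci(
    scores,
    outcomes,
    reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for AUROC (resampling record indices).

    Single-class resamples are skipped with a logged count; more than 50%
    degenerate resamples raises (cohort too small or too imbalanced).
    """
    if reps < 1:
        raise ValidationError("reps must be at least 1")
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes).astype(bool)
    _check_classes(outcomes)
    rng = np.random.default_rng(seed)
    n = len(scores)
    values, skipped = [], 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        y = outcomes[idx]
        if y.all() or not y.any():
            skipped += 1
            continue
        values.append(auroc(scores[idx], y))
    if skipped:
        logger.info("bootstrap: skipped %d single-class resamples", skipped)
    if skipped > reps / 2:
        raise ValidationError(
            f"{skipped}/{reps} bootstrap resamples were single-class; "
            "cohort too small or too imbalanced"
        )
    alpha = (1.0 - level) / 2.0
    low, high = np.percentile(values, [100 * alpha, 100 * (1 - alpha)])
    return float(low), float(high)


def threshold_metrics(scores, outcomes, threshold="youden") -> dict:
    """Confusion-matrix metrics with score >= threshold called positive.

    ``threshold="youden"`` picks the cut maximising sensitivity +
    specificity - 1 on the same data (the chosen threshold is reported;
    ties resolved toward the lowest threshold).
    """
    scores = np.asarray(scores, float)
    outcomes = np.asarray(outcomes).astype(bool)
    _check_classes(outcomes)

    if isinstance(threshold, str):
        if threshold != "youden":
            raise ValidationError(f"unknown threshold policy {threshold!r}")
        best_t, best_j = None, -np.inf
        for t in np.unique(scores):
            pred = scores >= t
            sens = (pred & outcomes).sum() / outcomes.sum()
            spec = (~pred & ~outcomes).sum() / (~outcomes).sum()
            j = sens + spec - 1.0
            if j > best_j:
                best_t, best_j = float(t), j
        threshold = best_t

    pred = scores >= float(threshold)
    tp = int((pred & outcomes).sum())
    fp = int((pred & ~outcomes).sum())
    fn = int((~pred & outcomes).sum())
    tn = int((~pred & ~outcomes).sum())
    return {
        "threshold": float(threshold),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "accuracy": (tp + tn) / len(scores),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "ppv": tp / (tp + fp) if tp + fp else float("nan"),
        "npv": tn / (tn + fn) if tn + fn else float("nan"),
    }


@dataclass
class ValidationReport:
    """(score source × test site) grid of AUROC with bootstrap CI.

    ``cells`` maps (source, site) to a dict with auroc/ci_low/ci_high and
    optional threshold metrics; failed cells carry an ``error`` entry
    instead.
    """

    cells: dict[tuple[str, str], dict] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (source, site), cell in self.cells.items():
            for metric, value in cell.items():
                rows.append(
                    dict(score_source=source, test_site=site, metric=metric, value=value)
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def auroc_matrix(self) -> pd.DataFrame:
        sources = list(dict.fromkeys(s for s, _ in self.cells))
        sites = list(dict.fromkeys(t for _, t in self.cells))
        return pd.DataFrame(
            [[self.cells[(s, t)].get("auroc", np.nan) for t in sites] for s in sources],
            index=pd.Index(sources, name="score_source"),
            columns=pd.Index(sites, name="test_site"),
        )

    def to_markdown(self) -> str:
        sites = list(dict.fromkeys(t for _, t in self.cells))
        lines = [
            "# Cross-hospital validation — AUROC (95% CI)",
            "",
            "| Development | " + " | ".join(f"Validation {t}" for t in sites) + " |",
            "|" + "---|" * (len(sites) + 1),
        ]
        for source in dict.fromkeys(s for s, _ in self.cells):
            row = [source]
            for site in sites:
                cell = self.cells.get((source, site), {})
                if "auroc" in cell:
                    row.append(
                        f"{cell['auroc']:.3f} ({cell['ci_low']:.3f}-{cell['ci_high']:.3f})"
                    )
                else:
                    row.append("failed")
            lines.append("| " + " | ".join(row) + " |")
        return "\n".join(lines) + "\n"


def cross_validation_matrix(
    tables: dict[str, ScoreTable],
    test_cohorts: dict[str, Cohort],
    seed: int = 0,
    reps: int = 1000,
    level: float = 0.95,
    threshold="youden",
    include_threshold_metrics: bool = False,
) -> ValidationReport:
    """Evaluate every scorecard on every test cohort.

    Per-cell errors are recorded (cell marked failed) rather than raised, so
    a single degenerate cohort does not void the rest of the grid. Bootstrap
    seeds are derived per cell from ``seed`` so results do not depend on grid
    order.
    """
    report = ValidationReport()
    for i, (source, table) in enumerate(tables.items()):
        for j, (site, cohort) in enumerate(test_cohorts.items()):
            cell_seed = seed + 1000 * i + j
            try:
                scores = apply_score(cohort.data, table)
                y = cohort.data[OUTCOME].astype(bool).to_numpy()
                value = auroc(scores, y)
                low, high = bootstrap_ci(scores, y, reps=reps, level=level, seed=cell_seed)
                cell = {"auroc": value, "ci_low": low, "ci_high": high}
                if include_threshold_metrics:
                    cell.update(
                        {k: v for k, v in threshold_metrics(scores, y, threshold).items()}
                    )
                report.cells[(source, site)] = cell
            except (ValidationError, ValueError) as err:
                logger.warning("cell (%s, %s) failed: %s", source, site, err)
                report.cells[(source, site)] = {"error": str(err)}
    return report
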