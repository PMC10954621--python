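"""Model/Results interface over the score-generation pipeline.

:class:`TriageScoreModel` is constructed from patient-level data and
``fit()`` runs the whole score-development procedure — development/test
split, optional SMOTE rebalancing, random-forest variable ranking,
categorisation, logistic point fitting and held-out evaluation — returning a
:class:`TriageScoreResults` carrying the scorecard, the ranking, the
parsimony curve, the internal-validation AUROC with bootstrap CI, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .imbalance import ResamplingPlan, smote_rebalance
from .ops import prevalence, split_cohort
from .schema import OUTCOME, RECORD_COLUMNS
from .scoring import (
    CutoffScheme,
    ParsimonyCurve,
    RankedVariables,
    ScoreTable,
    apply_score,
    categorize,
    clinical_cutoff_scheme,
    fit_points,
    parsimony_curve,
    rank_variables,
)
from .validation import auroc, bootstrap_ci, threshold_metrics


class TriageScoreModel:
    """Interpretable point-score model for a binary triage outcome.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per ED visit with the triage record schema (see
        :mod:`edscore.schema`) including the binary outcome column.
    site_id : str
        Label for the hospital the data came from.
    """

    def __init__(self, data: pd.DataFrame, site_id: str = "site"):
        missing = [c for c in RECORD_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing record columns: {missing}")
        self.cohort = Cohort(site_id=site_id, data=data.reset_index(drop=True))
        self.site_id = site_id

    @classmethod
    def from_cohort(cls, cohort: Cohort) -> "TriageScoreModel":
        return cls(cohort.data, site_id=cohort.site_id)

    def fit(
        self,
        seed: int = 0,
        dev_fraction: float = 0.7,
        smote: bool | ResamplingPlan = True,
        cutoffs: str | CutoffScheme = "clinical",
        variables: list[str] | None = None,
        n_variables: int | None = None,
        parsimony_tol: float = 0.005,
        parsimony_k_max: int | None = None,
        candidates: list[str] | None = None,
        rf_trees: int = 500,
        bootstrap_reps: int = 1000,
        compute_parsimony: bool = True,
    ) -> "TriageScoreResults":
        """Develop a scorecard and evaluate it on the held-out test split.

        ``variables`` forces an explicit variable list (clinical override);
        otherwise the top ``n_variables`` ranked variables are used, with
        ``n_variables=None`` delegating the choice to the parsimony curve at
        tolerance ``parsimony_tol``. ``cutoffs`` is ``"clinical"`` (the
        domain-knowledge scheme), ``"auto-quantile"`` or an explicit
        :class:`CutoffScheme`.
        """
        dev, test = split_cohort(self.cohort, dev_fraction, seed=seed)
        fit_dev = dev
        plan = None
        if smote:
            plan = smote if isinstance(smote, ResamplingPlan) else ResamplingPlan(seed=seed)
            fit_dev = smote_rebalance(dev, plan)

        ranking = rank_variables(fit_dev, seed=seed, candidates=candidates, n_estimators=rf_trees)

        curve = None
        if compute_parsimony or (variables is None and n_variables is None):
            k_max = parsimony_k_max or len(ranking.items)
            scheme_for_curve = (
                clinical_cutoff_scheme(ranking.names) if cutoffs == "clinical" else cutoffs
            )
            curve = parsimony_curve(ranking, fit_dev, test, k_max, scheme_for_curve)
        if variables is None:
            k = n_variables if n_variables is not None else curve.select(tol=parsimony_tol)
            variables = ranking.top(k)

        if cutoffs == "clinical":
            scheme: CutoffScheme | str = clinical_cutoff_scheme(variables)
        else:
            scheme = cutoffs
        design, resolved = categorize(fit_dev, variables, scheme)
        table = fit_points(design, fit_dev.data[OUTCOME], resolved, site_id=self.site_id)

        test_scores = apply_score(test.data, table)
        y_test = test.data[OUTCOME].astype(bool).to_numpy()
        value = auroc(test_scores, y_test)
        ci = bootstrap_ci(test_scores, y_test, reps=bootstrap_reps, seed=seed)
        metrics = threshold_metrics(test_scores, y_test, "youden")

        return TriageScoreResults(
            model=self,
            score_table=table,
            ranking=ranking,
            parsimony=curve,
            cutoff_scheme=resolved,
            dev=dev,
            test=test,
            resampling_plan=plan,
            auroc_=float(value),
            auroc_ci=ci,
            threshold_metrics_=metrics,
            seed=seed,
        )


@dataclass
class TriageScoreResults:
    """Fitted scorecard with its development artifacts and diagnostics."""

    model: TriageScoreModel
    score_table: ScoreTable
    ranking: RankedVariables
    parsimony: ParsimonyCurve | None
    cutoff_scheme: CutoffScheme
    dev: Cohort
    test: Cohort
    resampling_plan: ResamplingPlan | None
    auroc_: float
    auroc_ci: tuple[float, float]
    threshold_metrics_: dict = field(default_factory=dict)
    seed: int = 0

    @property
    def auroc(self) -> float:
        """Internal-validation AUROC on the held-out test split."""
        return self.auroc_

    def predict(self, data: pd.DataFrame | dict):
        """Total integer score per record."""
        return apply_score(data, self.score_table)

    def validate(self, cohort: Cohort, reps: int = 1000, seed: int | None = None) -> dict:
        """External validation of this scorecard on another cohort."""
        scores = apply_score(cohort.data, self.score_table)
        y = cohort.data[OUTCOME].astype(bool).to_numpy()
        low, high = bootstrap_ci(scores, y, reps=reps, seed=self.seed if seed is None else seed)
        return {"auroc": auroc(scores, y), "ci_low": low, "ci_high": high}

    def summary(self) -> str:
        """Human-readable account of the fitted score."""
        m = self.model
        lines = [
            "Interpretable triage score — 2-day mortality",
            "=" * 52,
            f"Site:                  {m.site_id}",
            f"Records:               {len(m.cohort)} "
            f"(dev {len(self.dev)}, test {len(self.test)})",
            f"Outcome prevalence:    {prevalence(m.cohort):.2f}%",
            f"Rebalancing:           "
            + (
                f"SMOTE k={self.resampling_plan.k_neighbors} "
                f"x{self.resampling_plan.minority_multiplier:g}"
                if self.resampling_plan
                else "none"
            ),
            f"Variables:             {', '.join(self.score_table.variables)}",
            f"Maximum total score:   {self.score_table.max_total}",
            f"Test AUROC (95% CI):   {self.auroc_:.3f} "
            f"({self.auroc_ci[0]:.3f}-{self.auroc_ci[1]:.3f})",
        ]
        if self.threshold_metrics_:
            tm = self.threshold_metrics_
            lines.append(
                f"Youden threshold {tm['threshold']:g}: "
                f"sens {tm['sensitivity']:.3f}, spec {tm['specificity']:.3f}, "
                f"PPV {tm['ppv']:.3f}, NPV {tm['npv']:.3f}, acc {tm['accuracy']:.3f}"
            )
        lines.append("-" * 52)
        lines.append(f"{'Variable':<16}{'Category':<14}{'Points':>6}")
        for var, spec in self.score_table.variables.items():
            from .scoring import interval_labels

            order = (
                interval_labels(spec["cuts"])
                if spec["type"] == "continuous"
                else list(spec["points"])
            )
            for label in order:
                lines.append(f"{var:<16}{label:<14}{spec['points'][label]:>6}")
        return "\n".join(lines)

    def plot_parsimony(self, ax=None):
        if self.parsimony is None:
            raise ValueError("parsimony curve was not computed for this fit")
        return self.parsimony.plot(ax=ax)
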