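"""Combining per-hospital scorecards into one overall score.

Each site i contributes a weight

    w_i = sqrt(AUC_i) * N_i^3 / sum_j sqrt(AUC_j) * N_j^3

where AUC_i is the site's validation AUROC and N_i its cohort size, so large
well-discriminating sites dominate. Overall points per category are the
weighted average of the per-site points, rounded half away from zero.

``PUBLISHED_WEIGHTS`` stores the weights printed with the published overall
scorecard, (0.472, 0.410, 0.116) for hospitals A/B/C, verbatim: the exact
(AUC, N) pairs behind them are not identifiable, and recomputing from the
printed internal-validation AUROCs gives (0.475, 0.410, 0.115).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import ScoreTable, ScoreError, _round_half_away

PUBLISHED_WEIGHTS: dict[str, float] = {"A": 0.472, "B": 0.410, "C": 0.116}


@dataclass
class SiteWeight:
    site_id: str
    auc: float
    n: int
    weight: float


def site_weights(sites: list[tuple]) -> list[SiteWeight]:
    """Weights from (auc, n) pairs, or (site_id, auc, n) triples.

    Requires at least two sites, AUROC in (0, 1] and positive n.
    """
    if len(sites) < 2:
        raise ScoreError("need at least 2 sites")
    parsed = []
    for i, site in enumerate(sites):
        if len(site) == 3:
            sid, auc, n = site
        else:
            auc, n = site
            sid = str(i)
        if not 0.0 < auc <= 1.0:
            raise ScoreError(f"site {sid}: AUROC {auc} outside (0, 1]")
        if n < 1:
            raise ScoreError(f"site {sid}: cohort size must be positive, got {n}")
        parsed.append((str(sid), float(auc), int(n)))
    raw = np.array([np.sqrt(auc) * float(n) ** 3 for _, auc, n in parsed])
    weights = raw / raw.sum()
    return [
        SiteWeight(site_id=sid, auc=auc, n=n, weight=float(w))
        for (sid, auc, n), w in zip(parsed, weights)
    ]


def overall_score(
    tables: list[ScoreTable], weights: list[SiteWeight] | list[float]
) -> ScoreTable:
    """Weighted combination of structurally identical per-site scorecards.

    Per category the overall points are round_half_away(sum_i w_i * p_i).
    Raises on any structural mismatch, naming the differing categories.
    """
    if len(tables) != len(weights):
        raise ScoreError("one weight per table required")
    w = [sw.weight if isinstance(sw, SiteWeight) else float(sw) for sw in weights]

    ref_table = tables[0]
    for other in tables[1:]:
        if set(other.variables) != set(ref_table.variables):
            raise ScoreError(
                "tables differ in variables: "
                f"{sorted(set(other.variables) ^ set(ref_table.variables))}"
            )
        for var in ref_table.variables:
            a = set(ref_table.variables[var]["points"])
            b = set(other.variables[var]["points"])
            if a != b:
                raise ScoreError(f"variable {var!r}: categories differ: {sorted(a ^ b)}")

    variables: dict[str, dict] = {}
    for var, spec in ref_table.variables.items():
        pts = {}
        for label in spec["points"]:
            combined = sum(wi * t.variables[var]["points"][label] for wi, t in zip(w, tables))
            pts[label] = int(_round_half_away(combined))
        new_spec: dict = {"type": spec["type"], "points": pts, "reference": spec.get("reference")}
        if spec["type"] == "continuous":
            new_spec["cuts"] = list(spec["cuts"])
        variables[var] = new_spec

    return ScoreTable(
        site_id="overall",
        variables=variables,
        metadata={
            "weights": {
                (sw.site_id if isinstance(sw, SiteWeight) else str(i)): float(wi)
                for i, (sw, wi) in enumerate(zip(weights, w))
            }
        },
    )
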