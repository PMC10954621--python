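"""Class rebalancing of the development cohort.

Two-day mortality is a heavily imbalanced outcome (~0.5% positive). The
rebalancing scheme used for score development doubles the minority class with
SMOTE-style synthetic interpolants and down-samples the majority class,
without replacement, to the enlarged minority count, yielding an exactly
balanced development set:

* every original minority record is kept;
* each synthetic record is a convex combination ``x + u * (x_nn - x)``,
  ``u ~ Uniform(0, 1)``, of a minority record and one of its ``k`` nearest
  minority neighbours (Euclidean distance on z-scored continuous features);
* categorical fields of a synthetic record are copied from its seed point
  (a mixed-type "SMOTE-NC-lite");
* the whole procedure is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .cohort import Cohort
from .schema import CONTINUOUS_VARS, OUTCOME


class ResamplingError(ValueError):
    pass


@dataclass
class ResamplingPlan:
    """Parameters of the rebalancing step.

    ``minority_multiplier`` is the target minority size as a multiple of the
    original count (2 doubles it). ``majority_target`` selects how many
    majority records are kept: ``"match-enlarged"`` keeps as many as the
    enlarged minority (the default, giving a 1:1 ratio) while
    ``"match-original"`` keeps only the original minority count.
    """

    k_neighbors: int = 5
    minority_multiplier: float = 2.0
    majority_target: str = "match-enlarged"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ResamplingError("k_neighbors must be at least 1")
        if self.minority_multiplier <= 1:
            raise ResamplingError("minority_multiplier must exceed 1")
        if self.majority_target not in ("match-enlarged", "match-original"):
            raise ResamplingError(f"unknown majority_target {self.majority_target!r}")


def smote_rebalance(dev: Cohort, plan: ResamplingPlan | None = None) -> Cohort:
    """Return a balanced development cohort per the resampling plan."""
    plan = plan or ResamplingPlan()
    df = dev.data.reset_index(drop=True)
    dead = df[OUTCOME].astype(bool)
    minority, majority = df[dead], df[~dead]
    if len(minority) == 0 or len(majority) == 0:
        raise ResamplingError("both outcome classes must be present")
    if len(minority) <= plan.k_neighbors:
        raise ResamplingError(
            f"minority class ({len(minority)}) must exceed k_neighbors ({plan.k_neighbors})"
        )

    rng = np.random.default_rng(plan.seed)
    n_min = len(minority)
    n_synth = int(round(n_min * (plan.minority_multiplier - 1.0)))

    # kNN in z-scored continuous feature space of the minority class
    x = minority[CONTINUOUS_VARS].to_numpy(float)
    mu, sigma = x.mean(axis=0), x.std(axis=0)
    sigma[sigma == 0] = 1.0
    z = (x - mu) / sigma
    nn = NearestNeighbors(n_neighbors=plan.k_neighbors + 1).fit(z)
    neighbor_idx = nn.kneighbors(z, return_distance=False)[:, 1:]  # drop self

    seed_idx = rng.integers(0, n_min, size=n_synth)
    pick = rng.integers(0, plan.k_neighbors, size=n_synth)
    u = rng.random(n_synth)

    synth = minority.iloc[seed_idx].reset_index(drop=True)
    x_seed = x[seed_idx]
    x_nn = x[neighbor_idx[seed_idx, pick]]
    synth[CONTINUOUS_VARS] = x_seed + u[:, None] * (x_nn - x_seed)

    target = n_min + n_synth if plan.majority_target == "match-enlarged" else n_min
    if target > len(majority):
        raise ResamplingError(
            f"majority class ({len(majority)}) smaller than target sample ({target})"
        )
    keep = rng.choice(len(majority), size=target, replace=False)
    majority_sample = majority.iloc[np.sort(keep)]

    balanced = pd.concat([minority, synth, majority_sample], ignore_index=True)
    return Cohort(
        site_id=dev.site_id,
        data=balanced,
        provenance=dev.provenance
        + f" | smote k={plan.k_neighbors} x{plan.minority_multiplier} seed={plan.seed}",
    )
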