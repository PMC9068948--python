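"""Global sensitivity analysis and iterative panel reduction.

A trained network's inputs are ranked by how much neutralizing each one
inflates the classification loss: the variable's column is replaced by its
mean (or permuted), the loss is recomputed, and the ratio to the baseline
loss is the variable's usefulness. Ratios near 1 mark variables the network
ignores. Pruning repeatedly drops the least-useful miRNA, re-runs the
architecture search on the reduced panel (the hidden-width range shrinks
with the panel), and accepts the drop only while the test-split selection
metric does not fall by more than a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import mlp
from .io import SampleMeta, ValidationError, log
from .mlp import MLPModel
from .preprocess import NormalizedMatrix
from .search import (
    POSITIVE_GROUPS,
    Leaderboard,
    SearchConfig,
    SplitAssignment,
    labels_from_meta,
    search_models,
)


@dataclass
class SensitivityReport:
    """Per-variable loss-inflation ratios (>= 0); larger = more useful."""

    ratios: pd.Series
    baseline_loss: float
    method: str

    def least_useful(self) -> str:
        """Variable with the smallest ratio; ties break lexicographically."""
        s = self.ratios.sort_index()
        return str(s.index[int(np.argmin(s.to_numpy()))])


def sensitivity_analysis(
    model: MLPModel,
    X: pd.DataFrame,
    y,
    method: str = "mean_substitution",
    n_permutations: int = 10,
    seed: int = 0,
    l2: float = 1e-4,
) -> SensitivityReport:
    """Loss ratio per input variable, with the column neutralized.

    ``mean_substitution`` replaces the column by its mean; ``permutation``
    averages the ratio over ``n_permutations`` seeded shuffles.
    """
    if method not in ("mean_substitution", "permutation"):
        raise ValidationError(f"unknown sensitivity method {method!r}")
    if model.feature_names is not None and list(X.columns) != list(model.feature_names):
        raise ValidationError("data columns do not match the model's variables")
    y = np.asarray(y, dtype=float).ravel()
    base = mlp.loss(model, X.to_numpy(), y, l2=l2)
    if base <= 0:
        raise ValidationError("baseline loss must be > 0")
    rng = np.random.default_rng(seed)
    ratios = {}
    values = X.to_numpy()
    for j, var in enumerate(X.columns):
        if method == "mean_substitution":
            Xn = values.copy()
            Xn[:, j] = values[:, j].mean()
            ratios[str(var)] = mlp.loss(model, Xn, y, l2=l2) / base
        else:
            acc = 0.0
            for _ in range(n_permutations):
                Xn = values.copy()
                Xn[:, j] = rng.permutation(values[:, j])
                acc += mlp.loss(model, Xn, y, l2=l2) / base
            ratios[str(var)] = acc / n_permutations
    return SensitivityReport(
        ratios=pd.Series(ratios), baseline_loss=base, method=method
    )


@dataclass
class PruneStep:
    removed: str
    ratio: float
    metric_before: float
    metric_after: float
    accepted: bool


@dataclass
class PruneResult:
    features: list[str]
    leaderboard: Leaderboard
    model: MLPModel
    trace: list[PruneStep] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.trace])


def iterative_prune(
    data: NormalizedMatrix,
    meta: list[SampleMeta],
    splits: SplitAssignment,
    config: SearchConfig,
    min_features: int = 2,
    tolerance: float = 0.01,
    method: str = "mean_substitution",
    positive_groups=POSITIVE_GROUPS,
) -> PruneResult:
    """Drop least-useful variables while the test metric survives.

    Each step: sensitivity analysis of the currently selected model on the
    test split; remove the lowest-ratio variable; re-search the architecture
    on the reduced panel; accept if the new test metric is within
    ``tolerance`` of the current one. Stops at the first rejected drop or at
    ``min_features``. Fully deterministic for a fixed config seed.
    """
    features = [str(c) for c in data.data.columns]
    if len(features) < min_features:
        raise ValidationError("fewer variables than min_features")
    if config.hidden_range is not None:
        log.warning("pruning re-derives hidden_range per panel; override ignored")
        config = dc_replace(config, hidden_range=None)

    y = labels_from_meta(meta, positive_groups)
    sample_split = splits.sample_split(meta)
    test_ids = [s for s in data.data.index if sample_split.get(s) == "test"]

    def run_search(feats: list[str]) -> Leaderboard:
        sub = NormalizedMatrix(
            matrix=data.matrix.select_probes(feats),
            normalizer_pair=data.normalizer_pair,
            epsilon=data.epsilon,
        )
        return search_models(sub, meta, splits, config, positive_groups)

    board = run_search(features)
    current = board.selected.test_metrics[config.selection_metric]
    trace: list[PruneStep] = []

    while len(features) > min_features:
        X_test = data.data.loc[test_ids, features]
        report = sensitivity_analysis(
            board.selected.model, X_test, y.loc[test_ids].to_numpy(),
            method=method, seed=config.seed, l2=config.l2,
        )
        victim = report.least_useful()
        trial_features = [f for f in features if f != victim]
        trial_board = run_search(trial_features)
        trial_metric = trial_board.selected.test_metrics[config.selection_metric]
        accepted = trial_metric >= current - tolerance
        trace.append(PruneStep(
            removed=victim,
            ratio=float(report.ratios[victim]),
            metric_before=current,
            metric_after=trial_metric,
            accepted=accepted,
        ))
        if not accepted:
            break
        features = trial_features
        board = trial_board
        current = trial_metric
        log.info(
            "prune: dropped %s (ratio %.3f), test %s now %.3f, %d variables left",
            victim, trace[-1].ratio, config.selection_metric, current, len(features),
        )

    return PruneResult(
        features=features,
        leaderboard=board,
        model=board.selected.model,
        trace=trace,
    )
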