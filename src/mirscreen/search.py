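"""Split assignment and the semi-automated architecture search.

Splitting is at the subject level (all replicates and timepoints of a
subject share a split, so no technical-replicate leakage), stratified by
class, with largest-remainder rounding of split sizes.

The search samples candidate (hidden width, link function, init seed)
configurations uniformly at random — hidden widths confined to
[ceil(p/3), floor(1.5 p)] for p input variables — trains each candidate on
the training split with BFGS, scores it on the test split, and keeps the
best. Candidates are drawn from a single seeded stream, so a longer search
extends (never replaces) a shorter one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import mlp
from .evaluation import confusion_at_cutoff, roc_auc
from .io import SampleMeta, ValidationError, log, metadata_frame
from .mlp import HIDDEN_LINKS, MLPModel, MLPSpec
from .preprocess import NormalizedMatrix

#: group labels counted as the positive (diseased) class
POSITIVE_GROUPS = frozenset({"tumor", "cancer"})

_SPLIT_NAMES = {2: ("train", "test"), 3: ("train", "test", "validation")}


def _apportion(quotas: np.ndarray) -> np.ndarray:
    """Round float quotas (summing to an integer) to integers by largest
    remainder, ties to the earlier split."""
    base = np.floor(quotas).astype(int)
    base = np.maximum(base, 0)
    short = int(round(quotas.sum())) - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for k in order[:short]:
        base[k] += 1
    return base


def largest_remainder(n: int, proportions) -> list[int]:
    """Integer split sizes summing to ``n``, proportional with largest-remainder
    rounding (ties to the earlier split)."""
    props = np.asarray(proportions, dtype=float)
    return _apportion(n * props / props.sum()).tolist()


@dataclass
class SplitAssignment:
    """subject_id -> split name; every subject appears exactly once."""

    assignment: dict[str, str]
    proportions: tuple[float, ...]
    seed: int

    def subjects(self, split: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == split]

    def sample_split(self, meta: list[SampleMeta]) -> dict[str, str]:
        """Resolve the subject-level assignment to sample level."""
        out = {}
        for m in meta:
            if m.subject_id in self.assignment:
                out[m.sample_id] = self.assignment[m.subject_id]
        return out


def assign_splits(
    meta: list[SampleMeta],
    proportions,
    seed: int = 0,
) -> SplitAssignment:
    """Class-stratified subject-level randomization into 2 or 3 splits."""
    props = tuple(float(p) for p in proportions)
    if len(props) not in (2, 3):
        raise ValidationError("proportions must have length 2 or 3")
    if any(p < 0 for p in props) or sum(props) <= 0:
        raise ValidationError("proportions must be non-negative with positive sum")
    names = _SPLIT_NAMES[len(props)]

    subject_group: dict[str, str] = {}
    for m in meta:
        prev = subject_group.get(m.subject_id)
        if prev is not None and prev != m.group:
            raise ValidationError(
                f"subject {m.subject_id!r} carries conflicting group labels"
            )
        subject_group[m.subject_id] = m.group

    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    classes = sorted(set(subject_group.values()))
    # carry rounding residuals across classes so overall split sizes match
    # the largest-remainder apportionment of the whole cohort
    residual = np.zeros(len(props))
    for cls in classes:
        members = [s for s, g in subject_group.items() if g == cls]
        rng.shuffle(members)
        quotas = len(members) * np.asarray(props) / sum(props) + residual
        sizes = _apportion(quotas)
        residual = quotas - sizes
        sizes = sizes.tolist()
        if any(sz == 0 for sz in sizes):
            raise ValidationError(
                f"class {cls!r} would be absent from a split at these "
                f"proportions; use a larger cohort"
            )
        start = 0
        for name, sz in zip(names, sizes):
            for s in members[start:start + sz]:
                assignment[s] = name
            start += sz
    log.info(
        "splits (%s): %s",
        "/".join(names),
        {name: sum(1 for v in assignment.values() if v == name) for name in names},
    )
    return SplitAssignment(assignment=assignment, proportions=props, seed=seed)


# ---------------------------------------------------------------------------
# Architecture search
# ---------------------------------------------------------------------------


def hidden_range(n_inputs: int) -> tuple[int, int]:
    """Admissible hidden-layer widths for p inputs: [ceil(p/3), floor(1.5 p)]."""
    lo = max(1, math.ceil(n_inputs / 3))
    hi = max(lo, math.floor(1.5 * n_inputs))
    return lo, hi


@dataclass
class SearchConfig:
    """Candidate-sampling and training policy for the model search."""

    n_candidates: int = 500
    hidden_range: tuple[int, int] | None = None  # None = derive from p
    admissible_links: tuple[str, ...] = HIDDEN_LINKS
    selection_metric: str = "balanced_accuracy"
    seed: int = 0
    restarts_per_candidate: int = 1
    max_iter: int = 80
    tol: float = 1e-6
    l2: float = 1e-4
    weight_init_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_candidates < 1:
            raise ValidationError("n_candidates must be >= 1")
        if not self.admissible_links or any(
            l not in HIDDEN_LINKS for l in self.admissible_links
        ):
            raise ValidationError(f"admissible_links must be a subset of {HIDDEN_LINKS}")
        if self.hidden_range is not None and self.hidden_range[0] > self.hidden_range[1]:
            raise ValidationError("hidden_range is empty")


def sample_candidates(config: SearchConfig, n_inputs: int, n: int | None = None):
    """The seeded candidate stream: (n_hidden, link, init seed) per candidate."""
    lo, hi = config.hidden_range or hidden_range(n_inputs)
    rng = np.random.default_rng(config.seed)
    links = list(config.admissible_links)
    specs = []
    for _ in range(n if n is not None else config.n_candidates):
        n_hidden = int(rng.integers(lo, hi + 1))
        link = links[int(rng.integers(len(links)))]
        init_seed = int(rng.integers(2**31))
        specs.append(MLPSpec(
            n_inputs=n_inputs,
            n_hidden=n_hidden,
            hidden_link=link,
            weight_init_sd=config.weight_init_sd,
            seed=init_seed,
        ))
    return specs


def score_metrics(scores: np.ndarray, y: np.ndarray) -> dict:
    cm = confusion_at_cutoff(scores, y)
    out = {
        "balanced_accuracy": 0.5 * (cm.sensitivity + cm.specificity),
        "accuracy": cm.accuracy,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
    }
    out["auc"] = roc_auc(scores, y).auc if 0 < y.sum() < len(y) else float("nan")
    return out


@dataclass
class CandidateResult:
    index: int
    spec: MLPSpec
    model: MLPModel
    train_metrics: dict
    test_metrics: dict


@dataclass
class Leaderboard:
    """Candidates ordered by test-split metric (desc); ties -> fewer hidden
    neurons, then lower candidate index."""

    entries: list[CandidateResult]
    metric: str

    @property
    def selected(self) -> CandidateResult:
        return self.entries[0]


def labels_from_meta(
    meta: list[SampleMeta],
    positive_groups=POSITIVE_GROUPS,
) -> pd.Series:
    mdf = metadata_frame(meta)
    return (mdf["group"].isin(positive_groups)).astype(int)


def _split_arrays(data: pd.DataFrame, y: pd.Series, sample_split: dict, name: str):
    ids = [s for s in data.index if sample_split.get(s) == name]
    return np.asarray(data.loc[ids]), y.loc[ids].to_numpy(), ids


def search_models(
    data: NormalizedMatrix,
    meta: list[SampleMeta],
    splits: SplitAssignment,
    config: SearchConfig,
    positive_groups=POSITIVE_GROUPS,
) -> Leaderboard:
    """Train ``n_candidates`` sampled architectures; rank by test performance.

    Input standardisation constants are fitted on the training split and
    stored in each model. The validation split (if any) is never touched.
    """
    df = data.data
    y = labels_from_meta(meta, positive_groups).reindex(df.index)
    if y.isna().any():
        raise ValidationError("metadata does not cover every sample in the matrix")
    sample_split = splits.sample_split(meta)
    X_tr, y_tr, _ = _split_arrays(df, y, sample_split, "train")
    X_te, y_te, _ = _split_arrays(df, y, sample_split, "test")
    for name, yy in (("train", y_tr), ("test", y_te)):
        if len(yy) == 0 or yy.min() == yy.max():
            raise ValidationError(f"{name} split lacks one of the classes")

    x_mean = X_tr.mean(axis=0)
    x_sd = np.maximum(X_tr.std(axis=0, ddof=0), 1e-8)
    feature_names = [str(c) for c in df.columns]

    entries: list[CandidateResult] = []
    for idx, spec in enumerate(sample_candidates(config, df.shape[1])):
        best_model, best_loss = None, np.inf
        for r in range(config.restarts_per_candidate):
            restart_spec = spec if r == 0 else replace(spec, seed=spec.seed + 9973 * r)
            model = mlp.init_mlp(restart_spec)
            model.x_mean, model.x_sd = x_mean, x_sd
            model.feature_names = feature_names
            model = mlp.train(
                model, X_tr, y_tr,
                max_iter=config.max_iter, tol=config.tol, l2=config.l2,
            )
            if model.training["loss"] < best_loss:
                best_loss = model.training["loss"]
                best_model = model
        entries.append(CandidateResult(
            index=idx,
            spec=best_model.spec,
            model=best_model,
            train_metrics=score_metrics(mlp.forward(best_model, X_tr), y_tr),
            test_metrics=score_metrics(mlp.forward(best_model, X_te), y_te),
        ))

    metric = config.selection_metric
    entries.sort(key=lambda e: (-e.test_metrics[metric], e.spec.n_hidden, e.index))
    log.info(
        "search: %d candidates, best test %s = %.3f (%s, h=%d)",
        len(entries), metric, entries[0].test_metrics[metric],
        entries[0].spec.hidden_link, entries[0].spec.n_hidden,
    )
    return Leaderboard(entries=entries, metric=metric)
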