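"""End-to-end seeded workflows.

* Mouse workflow: simulate the fluorescence xenograft study, background-
  correct, pick the two most stable reference miRNAs, normalize, collapse
  technical triplicates, train/test split of the three-cell-line cohort,
  architecture search, sensitivity pruning, then independent validation on
  a simulated dose-range cohort (day-28 sera).
* Human workflow: simulate the sequencing case/benign/healthy cohort,
  log2 signature matrix, 3:1:1 subject split, architecture search
  (optionally with pruning), per-split evaluation at the 50% cutoff, and
  prevalence modeling of screening performance from the validation split.

All stage seeds derive deterministically from one global seed; two runs
with equal config and seed produce identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import mlp
from .evaluation import auc_ci, confusion_at_cutoff
from .io import (
    ValidationError,
    log,
    save_json,
    save_model,
    write_expression,
    write_metadata,
)
from .prevalence import fold_risk, npv, ppv, prevalence_curve
from .preprocess import (
    background_correct,
    collapse_replicates,
    log2_signature,
    normalize,
    rank_normalizer_stability,
)
from .pruning import iterative_prune
from .search import (
    SearchConfig,
    assign_splits,
    labels_from_meta,
    score_metrics,
    search_models,
)
from .synthetic import (
    HumanCohortConfig,
    SyntheticConfig,
    mouse_training_design,
    ovcar8_validation_design,
    simulate_fireplex_cohort,
    simulate_human_cohort,
)


@dataclass
class RunConfig:
    """Pipeline-level knobs; stage seeds derive from the global seed."""

    workflow: str = "human"  # "human" or "mouse"
    seed: int = 0
    outdir: str | None = None
    n_candidates: int = 200
    prune: bool = True
    min_features: int = 7  # mirrors the 14 -> 7 panel reduction
    prune_tolerance: float = 0.01
    replicate_policy: str = "mean"
    selection_metric: str = "balanced_accuracy"
    screening_prevalence: float = 0.01

    def __post_init__(self) -> None:
        if self.workflow not in ("human", "mouse"):
            raise ValidationError(f"unknown workflow {self.workflow!r}")


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31, n)]


def _split_eval(model, features, data_df, meta, sample_split, positive_groups):
    """Confusion + AUC (DeLong CI) per split for a trained model."""
    y = labels_from_meta(meta, positive_groups)
    out = {}
    for name in sorted(set(sample_split.values())):
        ids = [s for s in data_df.index if sample_split.get(s) == name]
        if not ids:
            continue
        X = data_df.loc[ids, features].to_numpy()
        yy = y.loc[ids].to_numpy()
        scores = mlp.forward(model, X)
        metrics = score_metrics(scores, yy)
        cm = confusion_at_cutoff(scores, yy)
        entry = {**metrics, "confusion": cm.as_dict(), "n": len(ids)}
        if 0 < yy.sum() < len(yy):
            lo, hi = auc_ci(scores, yy, method="delong")
            entry["auc_ci"] = [lo, hi]
        out[name] = entry
    return out


def run_human_workflow(
    config: RunConfig,
    cohort: HumanCohortConfig | None = None,
) -> dict:
    """Simulate -> signature matrix -> 3:1:1 split -> search (-> prune) ->
    evaluate -> prevalence modeling. Returns the run report."""
    s_cohort, s_split, s_search, s_boot, *_ = _stage_seeds(config.seed)
    if cohort is None:
        cohort = HumanCohortConfig(seed=s_cohort)
    tpm, meta = simulate_human_cohort(cohort)
    nm = log2_signature(tpm, cohort.panel)
    splits = assign_splits(meta, (3, 1, 1), seed=s_split)
    sample_split = splits.sample_split(meta)

    search_cfg = SearchConfig(
        n_candidates=config.n_candidates,
        seed=s_search,
        selection_metric=config.selection_metric,
    )
    if config.prune:
        pruned = iterative_prune(
            nm, meta, splits, search_cfg,
            min_features=config.min_features,
            tolerance=config.prune_tolerance,
        )
        model, features = pruned.model, pruned.features
        trace = [vars(s) for s in pruned.trace]
        board = pruned.leaderboard
    else:
        board = search_models(nm, meta, splits, search_cfg)
        model, features, trace = board.selected.model, list(nm.data.columns), []

    per_split = _split_eval(
        model, features, nm.data, meta, sample_split, {"cancer"}
    )
    val_cm_dict = per_split["validation"]["confusion"]
    sens = val_cm_dict["sensitivity"]
    spec = val_cm_dict["specificity"]
    cm = confusion_at_cutoff(
        # reconstruct for the curve from the stored counts
        np.concatenate([
            np.ones(val_cm_dict["tp"]), np.zeros(val_cm_dict["fn"]),
            np.ones(val_cm_dict["fp"]), np.zeros(val_cm_dict["tn"]),
        ]),
        np.concatenate([
            np.ones(val_cm_dict["tp"] + val_cm_dict["fn"]),
            np.zeros(val_cm_dict["fp"] + val_cm_dict["tn"]),
        ]),
    )
    curve = prevalence_curve(cm, n_boot=2000, seed=s_boot)
    pi = config.screening_prevalence
    screening = {"prevalence": pi}
    for name, fn in (("ppv", ppv), ("npv", npv), ("fold_risk", fold_risk)):
        try:
            screening[name] = fn(sens, spec, pi)
        except ValueError:
            # degenerate confusion table (e.g. sens or spec of exactly 0)
            screening[name] = None

    report = {
        "workflow": "human",
        "seed": config.seed,
        "cohort": {
            "n_cancer": cohort.n_cancer,
            "n_benign": cohort.n_benign,
            "n_healthy": cohort.n_healthy,
        },
        "split_sizes": {
            name: sum(1 for v in sample_split.values() if v == name)
            for name in ("train", "test", "validation")
        },
        "selected_model": {
            "n_hidden": model.spec.n_hidden,
            "hidden_link": model.spec.hidden_link,
            "n_inputs": model.spec.n_inputs,
        },
        "features": features,
        "metrics": per_split,
        "pruning_trace": trace,
        "screening": screening,
    }
    _persist(config, report, model=model, board=board, curve=curve,
             matrix=tpm, meta=meta)
    return _pyify(report)


def run_mouse_workflow(
    config: RunConfig,
    training: SyntheticConfig | None = None,
    validation: SyntheticConfig | None = None,
) -> dict:
    """Simulate -> preprocess -> 75/25 split -> search -> prune -> validate
    on an independently simulated dose-range cohort."""
    s_train, s_val, s_split, s_search, *_ = _stage_seeds(config.seed)
    if training is None:
        training = mouse_training_design(seed=s_train)
    if validation is None:
        validation = ovcar8_validation_design(seed=s_val)

    matrix, meta, panel = simulate_fireplex_cohort(training)
    corrected = background_correct(matrix, panel)
    ranking = rank_normalizer_stability(corrected, panel)
    pair = ranking.top_pair
    nm = normalize(corrected, panel, pair)
    collapsed, meta_c = collapse_replicates(
        nm.matrix, [m for m in meta if m.sample_id in set(nm.data.index)],
        policy=config.replicate_policy,
    )
    # model on day-28 sera: the saturated steady-state contrast
    day28 = [m.sample_id for m in meta_c if m.timepoint_day == max(training.timepoints)]
    model_matrix = collapsed.select_samples(day28)
    model_meta = [m for m in meta_c if m.sample_id in set(day28)]
    nm_model = type(nm)(matrix=model_matrix, normalizer_pair=pair, epsilon=nm.epsilon)

    splits = assign_splits(model_meta, (3, 1), seed=s_split)
    sample_split = splits.sample_split(model_meta)
    search_cfg = SearchConfig(
        n_candidates=config.n_candidates,
        seed=s_search,
        selection_metric=config.selection_metric,
    )
    if config.prune:
        pruned = iterative_prune(
            nm_model, model_meta, splits, search_cfg,
            min_features=config.min_features,
            tolerance=config.prune_tolerance,
        )
        model, features = pruned.model, pruned.features
        trace = [vars(s) for s in pruned.trace]
        board = pruned.leaderboard
    else:
        board = search_models(nm_model, model_meta, splits, search_cfg)
        model, features, trace = (
            board.selected.model, list(nm_model.data.columns), [],
        )

    per_split = _split_eval(
        model, features, nm_model.data, model_meta, sample_split, {"tumor"}
    )

    # independent validation cohort, preprocessed with the SAME reference pair
    vmatrix, vmeta, vpanel = simulate_fireplex_cohort(validation)
    vcorr = background_correct(vmatrix, vpanel)
    vnm = normalize(vcorr, vpanel, pair)
    vcollapsed, vmeta_c = collapse_replicates(
        vnm.matrix, [m for m in vmeta if m.sample_id in set(vnm.data.index)],
        policy=config.replicate_policy,
    )
    vday28 = [m.sample_id for m in vmeta_c
              if m.timepoint_day == max(validation.timepoints)]
    vX = vcollapsed.data.loc[vday28, features].to_numpy()
    vy = labels_from_meta(
        [m for m in vmeta_c if m.sample_id in set(vday28)], {"tumor"}
    ).loc[vday28].to_numpy()
    vscores = mlp.forward(model, vX)
    vcm = confusion_at_cutoff(vscores, vy)
    validation_metrics = {
        **score_metrics(vscores, vy),
        "confusion": vcm.as_dict(),
        "auc_ci": list(auc_ci(vscores, vy, method="delong")),
        "n": len(vday28),
    }

    report = {
        "workflow": "mouse",
        "seed": config.seed,
        "normalizer_pair": list(pair),
        "normalizer_ranking": [[p, s] for p, s in ranking.ranking],
        "split_sizes": {
            name: sum(1 for v in sample_split.values() if v == name)
            for name in ("train", "test")
        },
        "selected_model": {
            "n_hidden": model.spec.n_hidden,
            "hidden_link": model.spec.hidden_link,
            "n_inputs": model.spec.n_inputs,
        },
        "features": features,
        "metrics": per_split,
        "pruning_trace": trace,
        "validation": validation_metrics,
    }
    _persist(config, report, model=model, board=board, matrix=matrix, meta=meta)
    return _pyify(report)


def run_pipeline(config: RunConfig, **kwargs) -> dict:
    """Dispatch to the configured workflow; persists artifacts when outdir set."""
    if config.workflow == "human":
        return run_human_workflow(config, **kwargs)
    return run_mouse_workflow(config, **kwargs)


def _pyify(obj):
    """Recursively convert numpy scalars/arrays for JSON round-tripping."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _persist(config: RunConfig, report: dict, model=None, board=None,
             curve=None, matrix=None, meta=None) -> None:
    if config.outdir is None:
        return
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_json(_pyify(report), outdir / "report.json")
    if model is not None:
        save_model(model, outdir / "model.json")
    if matrix is not None:
        write_expression(matrix, outdir / "expression.csv")
    if meta is not None:
        write_metadata(meta, outdir / "metadata.csv")
    if board is not None:
        save_json(_pyify([
            {
                "index": e.index,
                "n_hidden": e.spec.n_hidden,
                "hidden_link": e.spec.hidden_link,
                "test_metrics": e.test_metrics,
                "train_metrics": e.train_metrics,
            }
            for e in board.entries[:25]
        ]), outdir / "leaderboard.json")
    if curve is not None:
        import pandas as pd

        df = pd.DataFrame({
            "prevalence": curve.prevalence,
            "ppv": curve.ppv,
            "npv": curve.npv,
            "fold_risk": curve.fold_risk,
        })
        for key, (lo, hi) in curve.ci.items():
            df[f"{key}_lo"] = lo
            df[f"{key}_hi"] = hi
        df.to_csv(outdir / "prevalence_curve.csv", index=False)
    log.info("artifacts written to %s", outdir)
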