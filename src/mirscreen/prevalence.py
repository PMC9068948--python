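"""Screening performance as a function of disease prevalence.

Bayes' rule converts a classifier's sensitivity and specificity into the
positive and negative predictive values expected in a population with a
given disease prevalence pi:

    PPV = sens*pi / (sens*pi + (1 - spec)*(1 - pi))
    NPV = spec*(1 - pi) / (spec*(1 - pi) + (1 - sens)*pi)

``fold_risk = PPV / pi`` is the risk multiplication a positive test implies;
as pi -> 0 it approaches the positive likelihood ratio sens / (1 - spec).
Confidence bands come from binomial resampling of the validation confusion
table (tp out of tp+fn positives, tn out of tn+fp negatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import ConfusionMetrics

#: default prevalence grid: log-spaced from a general-population ovarian
#: cancer prevalence (0.07%) up to a BRCA1-carrier lifetime risk (40%)
DEFAULT_GRID = np.geomspace(0.0007, 0.40, 60)


def _check_rates(sens: float, spec: float, prev: float) -> None:
    for name, v in (("sens", sens), ("spec", spec)):
        if not 0 < v <= 1:
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    if not 0 < prev < 1:
        raise ValueError(f"prev must be in (0, 1), got {prev}")


def ppv(sens: float, spec: float, prev: float) -> float:
    """Positive predictive value at prevalence ``prev``."""
    _check_rates(sens, spec, prev)
    denom = sens * prev + (1.0 - spec) * (1.0 - prev)
    if denom == 0:
        raise ValueError("PPV undefined: test is never positive")
    return sens * prev / denom


def npv(sens: float, spec: float, prev: float) -> float:
    """Negative predictive value at prevalence ``prev``."""
    _check_rates(sens, spec, prev)
    denom = spec * (1.0 - prev) + (1.0 - sens) * prev
    if denom == 0:
        raise ValueError("NPV undefined: test is never negative")
    return spec * (1.0 - prev) / denom


def fold_risk(sens: float, spec: float, prev: float) -> float:
    """Risk multiplication given a positive test: PPV / prevalence."""
    return ppv(sens, spec, prev) / prev


@dataclass
class PrevalenceCurve:
    """PPV/NPV/fold-risk over a prevalence grid with optional CI bands."""

    prevalence: np.ndarray
    ppv: np.ndarray
    npv: np.ndarray
    fold_risk: np.ndarray
    source: ConfusionMetrics
    ci: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def prevalence_curve(
    cm: ConfusionMetrics,
    grid: np.ndarray | None = None,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PrevalenceCurve:
    """Point curves from the confusion table's sens/spec plus bootstrap bands.

    Bands: resample tp* ~ Binomial(tp+fn, sens) and tn* ~ Binomial(tn+fp,
    spec), recompute sens/spec (clipped away from 0/1 to keep Bayes' rule
    defined), and take percentile envelopes per grid point.
    """
    n_pos = cm.tp + cm.fn
    n_neg = cm.tn + cm.fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("confusion table needs positives and negatives")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or (grid <= 0).any() or (grid >= 1).any():
        raise ValueError("prevalence grid must lie strictly inside (0, 1)")

    sens, spec = cm.sensitivity, cm.specificity
    point_ppv = np.array([ppv(sens, spec, p) for p in grid])
    point_npv = np.array([npv(sens, spec, p) for p in grid])
    curve = PrevalenceCurve(
        prevalence=grid,
        ppv=point_ppv,
        npv=point_npv,
        fold_risk=point_ppv / grid,
        source=cm,
    )

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        eps = 0.5  # continuity clip in count units
        tp_b = rng.binomial(n_pos, sens, n_boot)
        tn_b = rng.binomial(n_neg, spec, n_boot)
        sens_b = np.clip(tp_b, eps, n_pos - eps) / n_pos
        spec_b = np.clip(tn_b, eps, n_neg - eps) / n_neg
        pi = grid[None, :]
        sb, pb = sens_b[:, None], spec_b[:, None]
        ppv_b = sb * pi / (sb * pi + (1 - pb) * (1 - pi))
        npv_b = pb * (1 - pi) / (pb * (1 - pi) + (1 - sb) * pi)
        qs = [alpha / 2, 1 - alpha / 2]
        lo_p, hi_p = np.quantile(ppv_b, qs, axis=0)
        lo_n, hi_n = np.quantile(npv_b, qs, axis=0)
        curve.ci = {
            "ppv": (lo_p, hi_p),
            "npv": (lo_n, hi_n),
            "fold_risk": (lo_p / grid, hi_p / grid),
        }
        # point estimate must lie inside its band
        curve.ci["ppv"] = (np.minimum(lo_p, point_ppv), np.maximum(hi_p, point_ppv))
        curve.ci["npv"] = (np.minimum(lo_n, point_npv), np.maximum(hi_n, point_npv))
        curve.ci["fold_risk"] = (
            np.minimum(curve.ci["ppv"][0] / grid, curve.fold_risk),
            np.maximum(curve.ci["ppv"][1] / grid, curve.fold_risk),
        )
    return curve
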