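"""Background correction, reference stability ranking, two-reference
normalization, replicate handling and TPM conversion.

Processing order on fluorescence data is background correction first, then
normalization of the predictive probes to the geometric mean of the two most
stable reference miRNAs (geNorm convention), yielding log2 ratios that are
invariant to per-sample multiplicative intensity drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, PanelDefinition, SampleMeta, ValidationError, log, metadata_frame

#: flooring constant (assay units) keeping log2 defined after background subtraction
DEFAULT_EPSILON = 1.0


def _drop_blanks(m: ExpressionMatrix, panel: PanelDefinition) -> ExpressionMatrix:
    keep = [s for s in m.sample_ids if s not in set(panel.blanks)]
    if len(keep) == len(m.sample_ids):
        return m
    return m.select_samples(keep)


def background_correct(
    m: ExpressionMatrix,
    panel: PanelDefinition,
    epsilon: float = DEFAULT_EPSILON,
) -> ExpressionMatrix:
    """Subtract each sample's mean background-control signal, floored at epsilon.

    Background-control probes (non-target-species miRNAs) estimate per-well
    background fluorescence. Control/blank columns and blank wells are
    dropped from the output.
    """
    if m.value_kind != "fluorescence":
        raise ValidationError("background correction applies to fluorescence data")
    missing = [p for p in panel.background_controls if p not in m.data.columns]
    if missing or not panel.background_controls:
        raise ValidationError(f"background-control probes missing: {missing}")
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    m = _drop_blanks(m, panel)
    bg = m.data[panel.background_controls].mean(axis=1)
    drop = set(panel.background_controls) | set(panel.spike_ins)
    keep = [p for p in m.probe_ids if p not in drop]
    corrected = m.data[keep].sub(bg, axis=0).clip(lower=epsilon)
    log.info(
        "background correction: %d samples, mean background %.2f AU",
        corrected.shape[0], float(bg.mean()),
    )
    return ExpressionMatrix(corrected, "fluorescence")


@dataclass
class NormalizerRanking:
    """Reference probes ordered by stability (ascending score = most stable first)."""

    ranking: list[tuple[str, float]]
    metric: str = "cv_log2"

    @property
    def top_pair(self) -> tuple[str, str]:
        return (self.ranking[0][0], self.ranking[1][0])


def rank_normalizer_stability(
    m: ExpressionMatrix,
    panel: PanelDefinition,
    floor: float = DEFAULT_EPSILON,
) -> NormalizerRanking:
    """Rank reference miRNAs by the coefficient of variation of log2 signal.

    Smaller CV = more stable. Ties break lexicographically by probe id.
    References with any non-positive signal after flooring are excluded with
    a warning; fewer than two survivors is an error.
    """
    m = _drop_blanks(m, panel)
    present = [p for p in panel.normalizers if p in m.data.columns]
    if len(present) < 2:
        raise ValidationError("need at least 2 normalizer probes in the matrix")
    if m.shape[0] < 3:
        raise ValidationError("need at least 3 samples to rank stability")
    scores: list[tuple[str, float]] = []
    for probe in present:
        v = m.data[probe].to_numpy()
        if (v < floor).any():
            log.warning("normalizer %s has sub-floor signal; excluded", probe)
            continue
        lv = np.log2(v)
        mu = float(np.mean(lv))
        if mu == 0:
            log.warning("normalizer %s has zero mean log2 signal; excluded", probe)
            continue
        scores.append((probe, float(np.std(lv, ddof=1) / abs(mu))))
    if len(scores) < 2:
        raise ValidationError("fewer than 2 usable normalizer probes remain")
    scores.sort(key=lambda t: (t[1], t[0]))
    return NormalizerRanking(ranking=scores)


@dataclass
class NormalizedMatrix:
    """Predictive-probe log2 ratios plus the normalization provenance."""

    matrix: ExpressionMatrix  # value_kind = normalized_log2
    normalizer_pair: tuple[str, str]
    epsilon: float

    @property
    def data(self) -> pd.DataFrame:
        return self.matrix.data


def normalize(
    m: ExpressionMatrix,
    panel: PanelDefinition,
    normalizer_pair: tuple[str, str],
    epsilon: float = DEFAULT_EPSILON,
) -> NormalizedMatrix:
    """log2(probe / geometric mean of the two reference probes), per sample."""
    a, b = normalizer_pair
    for probe in (a, b):
        if probe not in m.data.columns:
            raise ValidationError(f"normalizer probe {probe!r} absent from matrix")
    predictive = [p for p in panel.predictive if p in m.data.columns]
    if not predictive:
        raise ValidationError("no predictive probes present in matrix")
    sig = m.data[predictive].to_numpy()
    ref = m.data[[a, b]].to_numpy()
    if (sig <= 0).any() or (ref <= 0).any():
        raise ValidationError(
            "non-positive signal encountered; background-correct (with flooring) first"
        )
    geo = np.sqrt(ref[:, 0] * ref[:, 1])
    values = np.log2(sig / geo[:, None])
    out = pd.DataFrame(values, index=m.data.index, columns=predictive)
    return NormalizedMatrix(
        matrix=ExpressionMatrix(out, "normalized_log2"),
        normalizer_pair=(a, b),
        epsilon=epsilon,
    )


def counts_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each sample's counts to tags per million (rows sum to 1e6)."""
    if m.value_kind != "counts":
        raise ValidationError("counts_to_tpm expects value_kind='counts'")
    totals = m.data.sum(axis=1)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValidationError(f"sample {zero.index[0]!r} has zero total count")
    tpm = m.data.div(totals, axis=0) * 1e6
    return ExpressionMatrix(tpm, "tpm")


def log2_signature(
    m: ExpressionMatrix,
    panel: PanelDefinition,
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """log2(TPM + pseudocount) restricted to the predictive signature.

    The sequencing branch's analogue of fluorescence normalization: TPM is
    already a per-sample relative scale, so only a variance-stabilizing log
    transform is applied before modeling.
    """
    if m.value_kind not in ("tpm", "counts"):
        raise ValidationError("log2_signature expects TPM (or count) data")
    predictive = [p for p in panel.predictive if p in m.data.columns]
    if not predictive:
        raise ValidationError("no predictive probes present in matrix")
    values = np.log2(m.data[predictive].to_numpy() + pseudocount)
    out = pd.DataFrame(values, index=m.data.index, columns=predictive)
    return NormalizedMatrix(
        matrix=ExpressionMatrix(out, "normalized_log2"),
        normalizer_pair=("tpm", "tpm"),
        epsilon=pseudocount,
    )


def collapse_replicates(
    m: ExpressionMatrix,
    meta: list[SampleMeta],
    policy: str = "mean",
) -> tuple[ExpressionMatrix, list[SampleMeta]]:
    """Aggregate technical replicates per (subject, timepoint) group.

    ``policy`` is 'mean', 'median' or 'keep' (identity). Collapsed samples
    are renamed ``<subject>_d<day>`` (or ``<subject>`` without timepoints)
    and get replicate_index 1.
    """
    if policy == "keep":
        return m, meta
    if policy not in ("mean", "median"):
        raise ValidationError(f"unknown replicate policy {policy!r}")
    mdf = metadata_frame(meta).loc[m.sample_ids]
    # sentinel for absent timepoints so group keys stay hashable/comparable
    days = [None if pd.isna(d) else int(d) for d in mdf["timepoint_day"]]
    keys = [
        (str(s), -1 if d is None else d)
        for s, d in zip(mdf["subject_id"], days)
    ]
    grouped = m.data.groupby(pd.Series(keys, index=m.data.index), sort=False)
    agg = grouped.mean() if policy == "mean" else grouped.median()

    new_ids: list[str] = []
    new_meta: list[SampleMeta] = []
    seen: dict[tuple, int] = {}
    for pos, k in enumerate(keys):
        if k not in seen:
            seen[k] = pos
    for k in agg.index:
        subject, day = k
        row = mdf.iloc[seen[k]]
        sid = str(subject) if day == -1 else f"{subject}_d{day}"
        new_ids.append(sid)
        new_meta.append(SampleMeta(
            sample_id=sid,
            group=row["group"],
            subject_id=str(subject),
            timepoint_day=None if day == -1 else day,
            inoculum_cells=None if pd.isna(row["inoculum_cells"]) else int(row["inoculum_cells"]),
            cell_line=None if pd.isna(row["cell_line"]) else str(row["cell_line"]),
            replicate_index=1,
        ))
    agg.index = new_ids
    return ExpressionMatrix(agg, m.value_kind), new_meta
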