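"""Synthetic cohort generators.

Two assay styles are emulated so every downstream stage is testable without
any external download:

* ``simulate_fireplex_cohort`` — particle-fluorescence measurements of a
  mouse xenograft study: control vs tumor-bearing animals bled at baseline,
  day 5 and day 28, technical triplicates, stable reference miRNAs,
  background-control probes, spike-ins and blank wells. Tumor animals'
  signature miRNAs rise along a saturating time course (no effect at
  baseline, a configurable fraction at day 5, full effect at day 28) whose
  day-28 level is independent of the tumor-cell inoculum — the steady-state
  behaviour the downstream clustering analysis expects.
* ``simulate_human_cohort`` — small-RNA sequencing of a case/benign/healthy
  cohort (defaults 75/100/100): negative-binomial counts over the signature
  plus a background transcriptome, converted to tags per million. Signature
  effects include both up- and down-regulated members.

Noise model: log-normal biological variation and log-normal technical
replicate noise for fluorescence; negative-binomial counts for sequencing.
All randomness flows from the config seed; equal configs give identical
matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    PanelDefinition,
    SampleMeta,
    ValidationError,
    log,
)
from .preprocess import counts_to_tpm

# ---------------------------------------------------------------------------
# Fireplex-style mouse cohorts
# ---------------------------------------------------------------------------


def _default_mouse_effects(panel: PanelDefinition) -> dict[str, tuple[str, float]]:
    sizes = [1.0, 1.5, 2.0, 1.2, 1.8, 0.8, 1.4]
    return {
        p: ("up", sizes[i % len(sizes)])
        for i, p in enumerate(panel.predictive)
    }


def _default_normalizer_cv(panel: PanelDefinition) -> dict[str, float]:
    # the two canonical references are the most stable on this assay
    cvs = {}
    others = [p for p in panel.normalizers if p not in ("miR-222", "miR-181a")]
    if "miR-222" in panel.normalizers:
        cvs["miR-222"] = 0.015
    if "miR-181a" in panel.normalizers:
        cvs["miR-181a"] = 0.018
    for i, p in enumerate(others):
        cvs[p] = 0.03 + 0.008 * i
    return cvs


def _default_baselines(panel: PanelDefinition) -> dict[str, float]:
    base = {}
    for i, p in enumerate(panel.predictive):
        base[p] = 9.0 + 0.5 * (i % 6)
    for p in panel.normalizers:
        base[p] = 11.0
    return base


@dataclass
class SyntheticConfig:
    """Design and noise parameters of the fluorescence mouse study."""

    n_control: int = 10
    n_tumor_per_group: int = 10
    groups: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("COV362", 500_000), ("Kuramochi", 500_000), ("OVSAHO", 500_000)
        ]
    )
    timepoints: tuple[int, ...] = (0, 5, 28)
    n_replicates: int = 3
    panel: PanelDefinition = field(default_factory=PanelDefinition)
    effect: dict[str, tuple[str, float]] | None = None  # probe -> (direction, log2 size)
    day5_fraction: float = 0.4
    trend_onset_day: int = 0
    baseline_log2_mean: dict[str, float] | None = None
    biological_sd_log2: float = 0.5
    technical_cv: float = 0.08
    normalizer_cv: dict[str, float] | None = None  # approx CV of log2 signal
    background_mean: float = 50.0
    background_sd: float = 10.0
    spike_in_log2: float = 13.0
    n_blanks: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect is None:
            self.effect = _default_mouse_effects(self.panel)
        if self.normalizer_cv is None:
            self.normalizer_cv = _default_normalizer_cv(self.panel)
        if self.baseline_log2_mean is None:
            self.baseline_log2_mean = _default_baselines(self.panel)
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for name, value in (
            ("biological_sd_log2", self.biological_sd_log2),
            ("technical_cv", self.technical_cv),
            ("background_sd", self.background_sd),
        ):
            if value < 0:
                raise ValidationError(f"{name} must be >= 0")
        if any(cv < 0 for cv in self.normalizer_cv.values()):
            raise ValidationError("normalizer CVs must be >= 0")
        for probe, (direction, size) in self.effect.items():
            if direction not in ("up", "down"):
                raise ValidationError(f"effect direction {direction!r} for {probe!r}")
            if probe in self.panel.normalizers:
                raise ValidationError(
                    f"effect assigned to normalizer probe {probe!r}"
                )
            if size < 0:
                raise ValidationError("effect sizes are magnitudes; use direction for sign")


def mouse_training_design(seed: int = 0, **overrides) -> SyntheticConfig:
    """The 40-animal design: 10 controls + 10 each of three cell lines at 5e5 cells."""
    return SyntheticConfig(seed=seed, **overrides)


def ovcar8_validation_design(seed: int = 0, **overrides) -> SyntheticConfig:
    """The 30-animal dose-range design: 15 controls + 5 each at 5e4/5e5/5e6 cells."""
    return SyntheticConfig(
        n_control=15,
        n_tumor_per_group=5,
        groups=[("OVCAR8", 50_000), ("OVCAR8", 500_000), ("OVCAR8", 5_000_000)],
        seed=seed,
        **overrides,
    )


def _trend_fraction(day: int, cfg: SyntheticConfig) -> float:
    """Saturating time course: 0 at baseline, day5_fraction at day 5, 1 at day 28."""
    last = max(cfg.timepoints)
    if day <= cfg.trend_onset_day:
        return 0.0
    if day >= last:
        return 1.0
    if day == 5:
        return cfg.day5_fraction
    return (day - cfg.trend_onset_day) / (last - cfg.trend_onset_day)


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Unit-mean multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    s = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * s * s, s, shape))


def simulate_fireplex_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, list[SampleMeta], PanelDefinition]:
    """Generate one fluorescence matrix + metadata + panel (with blank wells).

    One matrix row per (animal, timepoint, replicate) specimen well plus
    ``n_blanks`` no-specimen wells (listed in the returned panel's
    ``blanks``). Noise draws do not depend on effect sizes, so increasing an
    effect at fixed seed shifts group means monotonically.
    """
    cfg = config
    panel = cfg.panel
    if cfg.n_control < 1 or cfg.n_tumor_per_group < 1 or not cfg.groups:
        raise ValidationError("empty control or tumor groups")
    rng = np.random.default_rng(cfg.seed)

    subjects: list[tuple[str, str, str | None, int | None]] = []
    for i in range(cfg.n_control):
        subjects.append((f"CTRL-{i + 1:02d}", "control", None, 0))
    for g, (line, inoc) in enumerate(cfg.groups):
        for i in range(cfg.n_tumor_per_group):
            subjects.append((f"{line}-{g + 1}{i + 1:02d}", "tumor", line, int(inoc)))

    pred = list(panel.predictive)
    norm = list(panel.normalizers)
    probes = pred + norm + list(panel.background_controls) + list(panel.spike_ins)
    n_sub, T, R = len(subjects), len(cfg.timepoints), cfg.n_replicates
    n_wells = n_sub * T * R

    # biological draws shared by a well's technical replicates
    bio_pred = rng.normal(0.0, cfg.biological_sd_log2, (n_sub, T, len(pred)))
    sd_norm = np.array([cfg.normalizer_cv[p] * cfg.baseline_log2_mean[p] for p in norm])
    bio_norm = rng.normal(0.0, 1.0, (n_sub, T, len(norm))) * sd_norm

    tech = _lognormal_noise(rng, cfg.technical_cv, (n_sub, T, R, len(probes)))
    background = np.clip(
        rng.normal(cfg.background_mean, cfg.background_sd, (n_sub, T, R, len(probes))),
        0.0, None,
    )

    base_pred = np.array([cfg.baseline_log2_mean[p] for p in pred])
    base_norm = np.array([cfg.baseline_log2_mean[p] for p in norm])
    signed = np.zeros(len(pred))
    for j, p in enumerate(pred):
        if p in cfg.effect:
            direction, size = cfg.effect[p]
            signed[j] = size if direction == "up" else -size

    rows, meta = [], []
    for si, (subject, group, line, inoc) in enumerate(subjects):
        for ti, day in enumerate(cfg.timepoints):
            frac = _trend_fraction(day, cfg) if group == "tumor" else 0.0
            level_pred = base_pred + frac * signed + bio_pred[si, ti]
            level_norm = base_norm + bio_norm[si, ti]
            signal = np.concatenate([
                np.exp2(level_pred),
                np.exp2(level_norm),
                np.zeros(len(panel.background_controls)),
                np.full(len(panel.spike_ins), 2.0 ** cfg.spike_in_log2),
            ])
            for r in range(cfg.n_replicates):
                well = signal * tech[si, ti, r] + background[si, ti, r]
                sid = f"{subject}_d{day}_r{r + 1}"
                rows.append((sid, well))
                meta.append(SampleMeta(
                    sample_id=sid, group=group, subject_id=subject,
                    timepoint_day=int(day), inoculum_cells=inoc,
                    cell_line=line, replicate_index=r + 1,
                ))

    blank_ids = []
    for b in range(cfg.n_blanks):
        well = np.clip(
            rng.normal(cfg.background_mean, cfg.background_sd, len(probes)), 0.0, None
        )
        sid = f"blank-{b + 1}"
        blank_ids.append(sid)
        rows.append((sid, well))
        meta.append(SampleMeta(sample_id=sid, group="control", subject_id=sid))

    data = pd.DataFrame(
        np.vstack([v for _, v in rows]),
        index=[s for s, _ in rows],
        columns=probes,
    )
    out_panel = PanelDefinition(
        predictive=list(panel.predictive),
        normalizers=list(panel.normalizers),
        background_controls=list(panel.background_controls),
        spike_ins=list(panel.spike_ins),
        blanks=blank_ids,
    )
    log.info(
        "fireplex cohort: %d subjects, %d wells (%d blanks), %d probes",
        n_sub, n_wells + cfg.n_blanks, cfg.n_blanks, len(probes),
    )
    return ExpressionMatrix(data, "fluorescence"), meta, out_panel


# ---------------------------------------------------------------------------
# Human sequencing cohorts
# ---------------------------------------------------------------------------


def _default_human_effects(panel: PanelDefinition) -> dict[str, tuple[str, float, str]]:
    """Signature effects for the case/benign/healthy cohort, both directions."""
    directions = ["up", "up", "down", "up", "down", "up", "down",
                  "up", "down", "up", "up", "down", "up", "down"]
    sizes = [1.6, 1.2, 1.8, 1.4, 1.2, 2.0, 1.5, 1.3, 1.7, 1.2, 1.9, 1.4, 1.6, 1.3]
    return {
        p: (directions[i % len(directions)], sizes[i % len(sizes)], "cancer")
        for i, p in enumerate(panel.predictive)
    }


def recovery_effects(
    panel: PanelDefinition | None = None,
    n_informative: int = 7,
    lfc: float = 2.0,
) -> dict[str, tuple[str, float, str]]:
    """Effects on the first ``n_informative`` signature probes only (alternating
    directions, equal |log2FC|); the rest of the signature is pure noise."""
    panel = panel or PanelDefinition()
    return {
        p: ("up" if i % 2 == 0 else "down", lfc, "cancer")
        for i, p in enumerate(panel.predictive[:n_informative])
    }


@dataclass
class HumanCohortConfig:
    """Design and noise parameters of the sequencing case-control cohort."""

    n_cancer: int = 75
    n_benign: int = 100
    n_healthy: int = 100
    panel: PanelDefinition = field(default_factory=PanelDefinition)
    n_extra_probes: int = 150
    # probe -> (direction, |log2FC|, applies_to in {"cancer", "cancer+benign"})
    effect: dict[str, tuple[str, float, str]] | None = None
    library_depth_mean: int = 1_000_000
    depth_cv: float = 0.2
    dispersion: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect is None:
            self.effect = _default_human_effects(self.panel)
        if min(self.n_cancer, self.n_benign, self.n_healthy) < 0:
            raise ValidationError("cohort sizes must be >= 0")
        if self.library_depth_mean <= 0:
            raise ValidationError("library_depth_mean must be > 0")
        if self.dispersion < 0 or self.depth_cv < 0:
            raise ValidationError("dispersion and depth_cv must be >= 0")
        for probe, (direction, size, applies) in self.effect.items():
            if direction not in ("up", "down"):
                raise ValidationError(f"effect direction {direction!r} for {probe!r}")
            if applies not in ("cancer", "cancer+benign"):
                raise ValidationError(f"effect applies_to {applies!r} for {probe!r}")
            if size < 0:
                raise ValidationError("effect sizes are magnitudes; use direction for sign")


def simulate_human_cohort(
    config: HumanCohortConfig,
) -> tuple[ExpressionMatrix, list[SampleMeta]]:
    """Generate a TPM matrix + metadata for the case/benign/healthy cohort.

    Counts are negative binomial around group-specific expected proportions
    of a log-normally varying library depth; TPM conversion then puts every
    sample on the common 1e6 scale. Noise draws do not depend on effect
    sizes (monotonicity at fixed seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    panel = cfg.panel

    sig = list(panel.predictive)
    extras = [f"probe-{i + 1:03d}" for i in range(cfg.n_extra_probes)]
    probes = sig + extras

    # deterministic baseline abundances (log2 relative units)
    base_log2 = np.array(
        [6.0 + (i % 5) for i in range(len(sig))]
        + [2.0 + (i % 11) for i in range(len(extras))]
    )
    base_frac = np.exp2(base_log2)
    base_frac = base_frac / base_frac.sum()

    signed = np.zeros(len(probes))
    applies_benign = np.zeros(len(probes), dtype=bool)
    for j, p in enumerate(probes):
        if p in cfg.effect:
            direction, size, applies = cfg.effect[p]
            signed[j] = size if direction == "up" else -size
            applies_benign[j] = applies == "cancer+benign"

    groups = (
        [("healthy", "H")] * cfg.n_healthy
        + [("benign", "B")] * cfg.n_benign
        + [("cancer", "C")] * cfg.n_cancer
    )
    counters = {"H": 0, "B": 0, "C": 0}

    depth = np.maximum(
        1.0,
        cfg.library_depth_mean
        * _lognormal_noise(rng, cfg.depth_cv, len(groups)),
    )

    rows, meta = [], []
    inv_disp = None if cfg.dispersion == 0 else 1.0 / cfg.dispersion
    for si, (group, prefix) in enumerate(groups):
        counters[prefix] += 1
        sid = f"{prefix}{counters[prefix]:03d}"
        if group == "cancer":
            shift = signed
        elif group == "benign":
            shift = np.where(applies_benign, signed, 0.0)
        else:
            shift = 0.0
        frac = base_frac * np.exp2(shift)
        frac = frac / frac.sum()
        mu = frac * depth[si]
        if inv_disp is None:
            counts = rng.poisson(mu)
        else:
            p_nb = inv_disp / (inv_disp + mu)
            counts = rng.negative_binomial(inv_disp, p_nb)
        rows.append((sid, counts))
        meta.append(SampleMeta(sample_id=sid, group=group, subject_id=sid))

    data = pd.DataFrame(
        np.vstack([v for _, v in rows]).astype(float),
        index=[s for s, _ in rows],
        columns=probes,
    )
    counts_matrix = ExpressionMatrix(data, "counts")
    tpm = counts_to_tpm(counts_matrix)
    log.info("human cohort: %d samples, %d probes", *tpm.shape)
    return tpm, meta
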