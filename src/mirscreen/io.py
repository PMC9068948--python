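"""Readers and writers for the pipeline's artifacts.

Conventions: tables are UTF-8 CSV/TSV with a mandatory header row; samples
are rows, probes are columns. Trained models are self-describing JSON
(weights, link-function names, probe order, input-standardisation
constants) so a model file is portable and its predictions reproducible
bit-exactly after a round trip. Run configuration is YAML.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("mirscreen")

VALUE_KINDS = ("fluorescence", "counts", "tpm", "normalized_log2")
#: value kinds that must be non-negative (log-ratio matrices may go negative)
NONNEGATIVE_KINDS = ("fluorescence", "counts", "tpm")
GROUPS = ("control", "tumor", "healthy", "benign", "cancer")

MODEL_FORMAT = "mirscreen-mlp"
MODEL_VERSION = 1


class ValidationError(ValueError):
    """Raised when an input table, panel or model file violates its contract."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Samples x probes numeric table (fluorescence AU, counts, TPM or log2 ratios).

    ``data`` is a float DataFrame with sample ids as index and probe ids as
    columns; both id lists must be duplicate-free and all values finite.
    """

    data: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"unknown value_kind {self.value_kind!r}; expected one of {VALUE_KINDS}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric expression values: {exc}") from exc
        values = self.data.to_numpy()
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at sample {self.data.index[i]!r}, "
                f"probe {self.data.columns[j]!r}"
            )
        if self.value_kind in NONNEGATIVE_KINDS and (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative {self.value_kind} value at sample "
                f"{self.data.index[i]!r}, probe {self.data.columns[j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def probe_ids(self) -> list[str]:
        return [str(p) for p in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def select_probes(self, probes: list[str]) -> "ExpressionMatrix":
        missing = [p for p in probes if p not in self.data.columns]
        if missing:
            raise ValidationError(f"probes absent from matrix: {missing}")
        return ExpressionMatrix(self.data[list(probes)].copy(), self.value_kind)

    def select_samples(self, samples: list[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(samples)].copy(), self.value_kind)


def _detect_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_expression(path: str | Path, value_kind: str) -> ExpressionMatrix:
    """Read a delimited samples-x-probes table (delimiter auto-detected).

    Non-numeric cells and duplicate ids raise :class:`ValidationError`
    naming the offending cell / id.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_detect_sep(path), index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"{path.name}: duplicate sample id {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValidationError(f"{path.name}: duplicate probe id {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        cell = raw.iloc[i, j]
        raise ValidationError(
            f"{path.name}: non-numeric cell {cell!r} at sample "
            f"{raw.index[i]!r}, probe {raw.columns[j]!r}"
        )
    return ExpressionMatrix(numeric, value_kind)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    out = m.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMeta:
    """Per-sample annotations: group label, subject, timepoint, dose, replicate."""

    sample_id: str
    group: str
    subject_id: str | None = None
    timepoint_day: int | None = None
    inoculum_cells: int | None = None
    cell_line: str | None = None
    replicate_index: int = 1
    plate_well: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown group {self.group!r} for sample {self.sample_id!r}; "
                f"admissible labels: {', '.join(GROUPS)}"
            )
        if self.subject_id is None:
            self.subject_id = self.sample_id
        if self.replicate_index < 1:
            raise ValidationError(
                f"replicate_index must be >= 1 (sample {self.sample_id!r})"
            )


_META_OPTIONAL_INT = ("timepoint_day", "inoculum_cells", "replicate_index")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    """Read a metadata table; ``sample_id`` and ``group`` columns are required."""
    path = Path(path)
    df = pd.read_csv(path, sep=_detect_sep(path))
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: required column {col!r} missing")
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {"sample_id": str(row["sample_id"]), "group": str(row["group"])}
        for col in ("subject_id", "cell_line", "plate_well"):
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = str(row[col])
        for col in _META_OPTIONAL_INT:
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = int(row[col])
        records.append(SampleMeta(**kwargs))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(s for s in ids if ids.count(s) > 1)
        raise ValidationError(f"{path.name}: duplicate sample_id {dup!r}")
    return records


def write_metadata(meta: list[SampleMeta], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame([dataclasses.asdict(m) for m in meta]).to_csv(path, sep=sep, index=False)


def metadata_frame(meta: list[SampleMeta]) -> pd.DataFrame:
    """Metadata as a DataFrame indexed by sample_id."""
    df = pd.DataFrame([dataclasses.asdict(m) for m in meta])
    return df.set_index("sample_id")


def check_matrix_metadata(m: ExpressionMatrix, meta: list[SampleMeta]) -> None:
    """Every matrix sample must have exactly one metadata row."""
    ids = {r.sample_id for r in meta}
    missing = [s for s in m.sample_ids if s not in ids]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:5]}")


# ---------------------------------------------------------------------------
# Panel definition
# ---------------------------------------------------------------------------

#: The 14-member predictive serum miRNA signature.
DEFAULT_PREDICTIVE = [
    "miR-23b-3p", "miR-29a-3p", "miR-32-5p", "miR-92a-3p", "miR-150-5p",
    "miR-200a-3p", "miR-200c-3p", "miR-203a", "miR-320c", "miR-320d",
    "miR-335-5p", "miR-450b-5p", "miR-1246", "miR-1307-5p",
]

#: Nine endogenous reference ("normalizer") miRNAs with stable serum levels;
#: miR-222 and miR-181a are the assay's two most stable references.
DEFAULT_NORMALIZERS = [
    "miR-222", "miR-181a", "miR-26a-5p", "miR-24-3p", "miR-93-5p",
    "miR-103a-3p", "miR-191-5p", "miR-423-5p", "miR-484",
]

#: Probes for miRNAs from other species, measuring background fluorescence.
DEFAULT_BACKGROUND = ["cel-miR-39-3p", "cel-miR-54-3p", "ath-miR-159a"]

DEFAULT_SPIKE_INS = ["spike-in-1", "spike-in-2"]


@dataclass
class PanelDefinition:
    """Probe roles on the assay: predictive signature, references, controls."""

    predictive: list[str] = field(default_factory=lambda: list(DEFAULT_PREDICTIVE))
    normalizers: list[str] = field(default_factory=lambda: list(DEFAULT_NORMALIZERS))
    background_controls: list[str] = field(default_factory=lambda: list(DEFAULT_BACKGROUND))
    spike_ins: list[str] = field(default_factory=lambda: list(DEFAULT_SPIKE_INS))
    blanks: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        roles = {
            "predictive": self.predictive,
            "normalizers": self.normalizers,
            "background_controls": self.background_controls,
            "spike_ins": self.spike_ins,
        }
        for name, probes in roles.items():
            if len(set(probes)) != len(probes):
                raise ValidationError(f"duplicate probe within {name}")
        names = list(roles)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = set(roles[a]) & set(roles[b])
                if overlap:
                    raise ValidationError(
                        f"probe roles {a} and {b} overlap: {sorted(overlap)}"
                    )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelDefinition":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Model files
# ---------------------------------------------------------------------------

def save_model(model, path: str | Path) -> None:
    """Serialize an :class:`~mirscreen.mlp.MLPModel` to self-describing JSON."""
    from .mlp import MLPModel  # local import avoids a cycle

    assert isinstance(model, MLPModel)
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "spec": dataclasses.asdict(model.spec),
        "W1": model.W1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": float(model.b2),
        "x_mean": None if model.x_mean is None else model.x_mean.tolist(),
        "x_sd": None if model.x_sd is None else model.x_sd.tolist(),
        "feature_names": model.feature_names,
        "training": model.training,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path):
    from .mlp import MLPModel, MLPSpec

    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"model file {path} is truncated or corrupt: {exc}") from exc
    if payload.get("format") != MODEL_FORMAT or payload.get("version") != MODEL_VERSION:
        raise ValidationError(
            f"model file {path} has format/version "
            f"{payload.get('format')!r}/{payload.get('version')!r}; "
            f"expected {MODEL_FORMAT!r}/{MODEL_VERSION}"
        )
    spec = MLPSpec(**payload["spec"])
    return MLPModel(
        spec=spec,
        W1=np.asarray(payload["W1"], dtype=float),
        b1=np.asarray(payload["b1"], dtype=float),
        w2=np.asarray(payload["w2"], dtype=float),
        b2=float(payload["b2"]),
        x_mean=None if payload["x_mean"] is None else np.asarray(payload["x_mean"], float),
        x_sd=None if payload["x_sd"] is None else np.asarray(payload["x_sd"], float),
        feature_names=payload["feature_names"],
        training=payload.get("training", {}),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

def load_run_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"run config {path} must be a YAML mapping")
    return cfg


def save_json(obj, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
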