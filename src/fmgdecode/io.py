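"""Trial CSV format, dataset manifest, and run configuration.

On-disk interchange formats:

* trial CSV — header ``s1..s{N},label,angle``, one row per sample, full
  float precision; ``label`` is the integer finger class 0..4 in the fixed
  order thumb=0, index=1, middle=2, ring=3, pinky=4.
* manifest — tab-separated table with columns ``subject_id, trial_id, path,
  sample_rate``, one row per trial CSV.
* run config — YAML with nested sections (sim / augment / model / shallow /
  evaluate) mirroring the module config types; unknown keys are rejected and
  every defaulted field is logged at load time.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .models import DualModelConfig
from .shallow import ShallowConfig
from .simulate import SimConfig, TrialRecording

__all__ = [
    "ParseError",
    "read_trial_csv",
    "write_trial_csv",
    "write_manifest",
    "read_manifest",
    "load_trials",
    "RunConfig",
    "load_config",
    "parse_weight_ratio",
]

logger = logging.getLogger(__name__)

N_CLASSES = 5


class ParseError(ValueError):
    """Malformed trial CSV, manifest, or config file."""


def write_trial_csv(recording: TrialRecording, path) -> None:
    """Write one trial to CSV (columns s1..sN, label, angle; lossless floats)."""
    path = Path(path)
    n = recording.n_channels
    df = pd.DataFrame(
        recording.pressures, columns=[f"s{i}" for i in range(1, n + 1)]
    )
    df["label"] = recording.labels
    df["angle"] = recording.angles
    # default str() formatting emits the shortest round-trip repr
    df.to_csv(path, index=False)


def read_trial_csv(path, subject_id: int = 0, trial_id: int = 0,
                   sample_rate: float = 40.0) -> TrialRecording:
    """Read a trial CSV, validating the schema and the label range."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = list(df.columns)
    n_sensors = sum(1 for c in cols if c.startswith("s") and c[1:].isdigit())
    expected = [f"s{i}" for i in range(1, n_sensors + 1)] + ["label", "angle"]
    if cols != expected:
        raise ParseError(
            f"{path}: header {cols} does not match the schema s1..sN,label,angle"
        )
    for col in cols:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[~df[col].apply(lambda v: isinstance(v, (int, float)))].index
            row = int(bad[0]) if len(bad) else -1
            raise ParseError(f"{path}: non-numeric value in column {col!r} row {row}")
    labels = df["label"].to_numpy()
    if not np.allclose(labels, np.rint(labels)):
        raise ParseError(f"{path}: label column must be integer-valued")
    labels = labels.astype(int)
    if labels.size and (labels.min() < 0 or labels.max() >= N_CLASSES):
        bad = int(np.flatnonzero((labels < 0) | (labels >= N_CLASSES))[0])
        raise ParseError(
            f"{path}: label outside 0..{N_CLASSES - 1} at row {bad}"
        )
    return TrialRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        pressures=df[expected[:n_sensors]].to_numpy(dtype=float),
        labels=labels,
        angles=df["angle"].to_numpy(dtype=float),
        sample_rate=sample_rate,
    )


def write_manifest(recordings: list[TrialRecording], paths: list, out_path) -> None:
    """Write the dataset manifest (TSV: subject_id, trial_id, path, sample_rate)."""
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in recordings],
            "trial_id": [r.trial_id for r in recordings],
            "path": [str(p) for p in paths],
            "sample_rate": [r.sample_rate for r in recordings],
        }
    )
    df.to_csv(out_path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["subject_id", "trial_id", "path", "sample_rate"]
    if list(df.columns) != required:
        raise ParseError(f"{path}: manifest columns must be {required}")
    return df


def load_trials(manifest_path) -> list[TrialRecording]:
    """Load every trial referenced by a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    trials = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        trials.append(
            read_trial_csv(
                p,
                subject_id=int(row.subject_id),
                trial_id=int(row.trial_id),
                sample_rate=float(row.sample_rate),
            )
        )
    return trials


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def parse_weight_ratio(text: str) -> tuple[float, float]:
    """Parse a 'w_r:w_c' weight-ratio string, e.g. '4:1' -> (4.0, 1.0)."""
    try:
        w_r, w_c = (float(part) for part in text.split(":"))
    except ValueError as exc:
        raise ParseError(f"weight ratio {text!r} is not of the form 'w_r:w_c'") from exc
    if w_r < 0 or w_c < 0 or (w_r == 0 and w_c == 0):
        raise ParseError("weight-ratio components must be non-negative, not both zero")
    return w_r, w_c


@dataclasses.dataclass(frozen=True)
class EvaluateConfig:
    concat_mode: str = "paper"
    window_len: int = 42
    arrangement: str = "paper_fixture"


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration mirroring the pipeline stages."""

    sim: SimConfig = SimConfig()
    model: DualModelConfig = DualModelConfig()
    shallow: ShallowConfig = ShallowConfig()
    evaluate: EvaluateConfig = EvaluateConfig()
    seed: int = 0
    out_dir: str = "fmgdecode_out"
    verbosity: str = "INFO"


_SECTIONS = {
    "sim": SimConfig,
    "model": DualModelConfig,
    "shallow": ShallowConfig,
    "evaluate": EvaluateConfig,
}


def _build_section(cls, data: dict, section: str):
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - field_names
    if unknown:
        raise ParseError(
            f"unknown key(s) in section {section!r}: {sorted(unknown)}"
        )
    for f in dataclasses.fields(cls):
        if f.name not in data:
            logger.debug("config %s.%s defaulted", section, f.name)
    coerced = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; absent keys take the reference
    defaults (window 42, weight ratio 4:1, batch 32, 10 epochs, SVC C=5
    gamma=0.1, SVR C=10 gamma=0.1, forests with 100/60 trees).

    A ``model.weight_ratio: "4:1"`` shorthand sets (w_r, w_c).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config root must be a mapping")
    top_known = set(_SECTIONS) | {"seed", "out_dir", "verbosity"}
    unknown = set(raw) - top_known
    if unknown:
        raise ParseError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    sections = {}
    for name, cls in _SECTIONS.items():
        data = dict(raw.get(name) or {})
        if name == "model" and "weight_ratio" in data:
            w_r, w_c = parse_weight_ratio(str(data.pop("weight_ratio")))
            data.setdefault("w_r", w_r)
            data.setdefault("w_c", w_c)
        sections[name] = _build_section(cls, data, name)
    for key in ("seed", "out_dir", "verbosity"):
        if key in raw:
            sections[key] = raw[key]
    config = RunConfig(**sections)
    logger.info("loaded run config from %s (seed=%s)", path, config.seed)
    return config
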