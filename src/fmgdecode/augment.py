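"""Channel-permutation movement-image augmentation.

Multichannel wristband signals are widened column-wise so that channel pairs
become spatially adjacent, then cut into square sliding windows ("movement
images") that a 2-D convolutional network can consume:

1. arrange the N channel series as an L x N array;
2. permute/repeat columns into an L x M array via an *arrangement* — an
   ordered channel-index sequence designed to put channels next to each other;
3. slide a length-M window along time with unit step, producing Ls - M square
   images, each labelled with the window's modal finger class and the final
   time step's MCP angle;
4. standardize sensors and angles to zero mean, unit variance (statistics
   fitted on training trials only).

Two arrangements are provided. ``paper_fixture`` reproduces a fixed published
42-element sequence for N=10 (and the [1, 2, 3, 1] worked example for N=3)
verbatim. Note that the 42-element sequence does NOT make every channel pair
adjacent — the pairs (2,7), (3,8), (4,9) and (5,10) never touch — and is kept
as-is deliberately. ``pair_complete`` builds a genuinely pair-complete
sequence as an Eulerian path on the complete channel-pair graph with minimal
edge duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .simulate import TrialRecording

__all__ = [
    "Arrangement",
    "MovementImage",
    "ImageDataset",
    "StandardizationParams",
    "UnsupportedFixtureError",
    "InsufficientLengthError",
    "build_arrangement",
    "expand_signals",
    "slice_windows",
    "assign_targets",
    "fit_standardizer",
    "apply_standardizer",
    "standardize_trial",
    "make_image_dataset",
    "save_image_dataset",
    "load_image_dataset",
    "PAPER_ARRANGEMENT_10",
    "PAPER_ARRANGEMENT_3",
]

logger = logging.getLogger(__name__)

#: Published fixed arrangement for the 10-channel wristband (1-based), M=42.
PAPER_ARRANGEMENT_10: tuple[int, ...] = (
    1, 2, 3, 4, 5, 6, 7, 8, 9, 10,
    1, 3, 5, 7, 9,
    1, 4, 6, 8, 10,
    2, 4, 7, 10,
    3, 6, 9,
    2, 5, 8,
    1, 5, 9,
    3, 7,
    1, 6, 10,
    4, 8,
    2, 6,
)

#: Published worked example for 3 channels: make columns 3 and 1 adjacent.
PAPER_ARRANGEMENT_3: tuple[int, ...] = (1, 2, 3, 1)


class UnsupportedFixtureError(ValueError):
    """paper_fixture arrangements exist only for channel counts 3 and 10."""


class InsufficientLengthError(ValueError):
    """Signal shorter than (or equal to) the window length."""


@dataclass(frozen=True)
class Arrangement:
    """Ordered channel-index sequence (1-based) defining movement-image
    columns; expanding an L x N signal with it yields L x M."""

    channels: tuple[int, ...]
    n_channels: int

    def __post_init__(self) -> None:
        present = set(self.channels)
        if present != set(range(1, self.n_channels + 1)):
            missing = set(range(1, self.n_channels + 1)) - present
            extra = present - set(range(1, self.n_channels + 1))
            raise ValueError(
                f"arrangement must use every channel 1..{self.n_channels} "
                f"exactly (missing {sorted(missing)}, out-of-range {sorted(extra)})"
            )

    @property
    def length(self) -> int:
        """M, the number of movement-image columns."""
        return len(self.channels)

    def adjacent_pairs(self) -> set[frozenset[int]]:
        """Unordered channel pairs occupying adjacent columns."""
        return {
            frozenset((a, b))
            for a, b in zip(self.channels, self.channels[1:])
            if a != b
        }

    def missing_pairs(self) -> set[frozenset[int]]:
        """Unordered channel pairs that never occur adjacently."""
        all_pairs = {
            frozenset((i, j))
            for i in range(1, self.n_channels + 1)
            for j in range(i + 1, self.n_channels + 1)
        }
        return all_pairs - self.adjacent_pairs()


def _eulerian_sequence(n: int) -> tuple[int, ...]:
    """Deterministic Eulerian walk through the complete graph on 1..n.

    Every unordered pair is an edge; for even n > 2 all vertices have odd
    degree, so (n-2)/2 duplicate edges pair up vertices 2..n-1, leaving an
    Eulerian path from 1 to n. Hierholzer's algorithm with smallest-neighbor
    selection makes the walk deterministic.
    """
    if n == 2:
        return (1, 2)
    adj: dict[int, dict[int, int]] = {v: {} for v in range(1, n + 1)}

    def add_edge(a: int, b: int) -> None:
        adj[a][b] = adj[a].get(b, 0) + 1
        adj[b][a] = adj[b].get(a, 0) + 1

    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            add_edge(i, j)
    if n % 2 == 0:
        # leave exactly vertices 1 and n odd
        for v in range(2, n - 1, 2):
            add_edge(v, v + 1)

    stack = [1]
    path: list[int] = []
    while stack:
        v = stack[-1]
        nbrs = adj[v]
        if nbrs:
            u = min(k for k, c in nbrs.items() if c > 0)
            nbrs[u] -= 1
            adj[u][v] -= 1
            if nbrs[u] == 0:
                del nbrs[u]
            if adj[u][v] == 0:
                del adj[u][v]
            stack.append(u)
        else:
            path.append(stack.pop())
    return tuple(reversed(path))


def build_arrangement(n_channels: int, mode: str = "pair_complete") -> Arrangement:
    """Build a channel arrangement.

    mode="paper_fixture" returns the published verbatim sequence (only defined
    for 3 and 10 channels). mode="pair_complete" returns a deterministic
    Eulerian-path sequence in which every unordered channel pair is adjacent
    at least once, with minimal edge duplication.
    """
    if n_channels < 2:
        raise ValueError("need at least two channels")
    if mode == "paper_fixture":
        if n_channels == 3:
            return Arrangement(PAPER_ARRANGEMENT_3, 3)
        if n_channels == 10:
            return Arrangement(PAPER_ARRANGEMENT_10, 10)
        raise UnsupportedFixtureError(
            f"no published fixture for {n_channels} channels (only 3 and 10)"
        )
    if mode == "pair_complete":
        return Arrangement(_eulerian_sequence(n_channels), n_channels)
    raise ValueError(f"unknown arrangement mode {mode!r}")


def expand_signals(pressures: np.ndarray, arrangement: Arrangement) -> np.ndarray:
    """Column-expand an L x N signal array to L x M by the arrangement.

    Output column j is a copy of input column arrangement.channels[j]
    (1-based); time rows are untouched, so the original array is recoverable
    from the first occurrence of each channel.
    """
    pressures = np.asarray(pressures)
    if pressures.ndim != 2 or pressures.shape[1] != arrangement.n_channels:
        raise ValueError(
            f"expected [L x {arrangement.n_channels}] input, got {pressures.shape}"
        )
    idx = np.asarray(arrangement.channels) - 1
    return pressures[:, idx]


def slice_windows(
    expanded: np.ndarray, window_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a length-Ls expanded signal into Ls - window_len unit-step windows.

    Start offsets run 1..Ls-w (0-based), so the final window ends at the very
    last sample; this reproduces the published Ls - w sample count (958 images
    per 1000-sample trial at w=42). Returns (windows [n x w x M], starts [n]).
    """
    expanded = np.asarray(expanded)
    ls = expanded.shape[0]
    if window_len < 1:
        raise ValueError("window_len must be positive")
    if ls <= window_len:
        raise InsufficientLengthError(
            f"need more than window_len={window_len} samples, got {ls}"
        )
    starts = np.arange(1, ls - window_len + 1)
    windows = np.lib.stride_tricks.sliding_window_view(
        expanded, window_len, axis=0
    )  # [Ls-w+1, M, w]
    windows = np.moveaxis(windows, -1, 1)[1:]
    return np.ascontiguousarray(windows), starts


def assign_targets(
    window_labels: np.ndarray, window_angles: np.ndarray
) -> tuple[int, float]:
    """Targets for one window: modal finger class and final-step angle.

    A frequency tie between classes is broken in favour of the tied class
    whose last occurrence in the window is latest, consistent with the
    last-time-step convention used for the angle target.
    """
    window_labels = np.asarray(window_labels)
    window_angles = np.asarray(window_angles)
    if window_labels.size == 0:
        raise ValueError("empty window")
    if window_labels.shape != window_angles.shape:
        raise ValueError("labels and angles must have equal length")
    counts = np.bincount(window_labels)
    tied = np.flatnonzero(counts == counts.max())
    if tied.size == 1:
        label = int(tied[0])
    else:
        last_pos = {int(c): int(np.flatnonzero(window_labels == c)[-1]) for c in tied}
        label = max(last_pos, key=lambda c: last_pos[c])
    return label, float(window_angles[-1])


@dataclass(frozen=True)
class StandardizationParams:
    """Zero-mean/unit-variance statistics for sensors and angle, fitted on
    training trials only and applied unchanged to test trials."""

    channel_mean: np.ndarray
    channel_sd: np.ndarray
    angle_mean: float
    angle_sd: float
    ddof: int = 0


def fit_standardizer(trials: list[TrialRecording], ddof: int = 0) -> StandardizationParams:
    """Fit per-channel and angle standardization statistics on a training
    split. ``ddof=0`` is the population standard-deviation convention
    (default); zero-variance channels fall back to sd=1 with a logged warning.
    """
    if not trials:
        raise ValueError("training split is empty")
    pressures = np.concatenate([t.pressures for t in trials], axis=0)
    angles = np.concatenate([t.angles for t in trials])
    ch_mean = pressures.mean(axis=0)
    ch_sd = pressures.std(axis=0, ddof=ddof)
    degenerate = ch_sd <= 0
    if degenerate.any():
        logger.warning(
            "zero-variance channel(s) %s: standard deviation replaced by 1",
            np.flatnonzero(degenerate).tolist(),
        )
        ch_sd = np.where(degenerate, 1.0, ch_sd)
    a_sd = angles.std(ddof=ddof)
    if a_sd <= 0:
        logger.warning("zero-variance angle target: standard deviation replaced by 1")
        a_sd = 1.0
    return StandardizationParams(ch_mean, ch_sd, float(angles.mean()), float(a_sd), ddof)


def apply_standardizer(
    pressures: np.ndarray, params: StandardizationParams
) -> np.ndarray:
    """Standardize a [T x N] pressure array with fitted statistics."""
    return (np.asarray(pressures) - params.channel_mean) / params.channel_sd


def standardize_trial(
    trial: TrialRecording, params: StandardizationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Return (standardized pressures, standardized angles) for one trial."""
    z = apply_standardizer(trial.pressures, params)
    a = (trial.angles - params.angle_mean) / params.angle_sd
    return z, a


@dataclass(frozen=True)
class MovementImage:
    """One standardized window with its targets and provenance."""

    values: np.ndarray
    label: int
    angle_target: float
    subject_id: int
    trial_id: int
    start_index: int


@dataclass
class ImageDataset:
    """Stack of movement images with targets and per-image provenance.

    ``trial_start``/``trial_end`` record the trial ids of each window's first
    and last rows; in per-trial mode they always coincide, in concatenated
    mode a window may span a trial boundary.
    """

    images: np.ndarray  # [n x w x M] float32, standardized
    labels: np.ndarray  # [n] int
    angles: np.ndarray  # [n] float32, standardized
    subject_ids: np.ndarray  # [n]
    trial_start: np.ndarray  # [n]
    trial_end: np.ndarray  # [n]
    start_indices: np.ndarray  # [n] offset within the (possibly concatenated) split
    window_len: int = 0
    arrangement: tuple[int, ...] = ()

    def __len__(self) -> int:
        return self.images.shape[0]

    def __getitem__(self, i: int) -> MovementImage:
        return MovementImage(
            self.images[i],
            int(self.labels[i]),
            float(self.angles[i]),
            int(self.subject_ids[i]),
            int(self.trial_start[i]),
            int(self.start_indices[i]),
        )


def make_image_dataset(
    trials: list[TrialRecording],
    arrangement: Arrangement,
    window_len: int,
    standardizer: StandardizationParams,
    concat_mode: str = "paper",
) -> ImageDataset:
    """Build the movement-image dataset for a split.

    concat_mode="paper": trials are concatenated along time (trial-id order)
    before windowing, reproducing the published 9*1000 - 42 training count;
    windows may span trial boundaries. concat_mode="per_trial": each trial is
    windowed separately and windows never cross boundaries.
    """
    if not trials:
        raise ValueError("no trials")
    n_ch = {t.n_channels for t in trials}
    if len(n_ch) != 1:
        raise ValueError(f"mixed channel counts {sorted(n_ch)}")
    if n_ch.pop() != arrangement.n_channels:
        raise ValueError("trial channel count does not match the arrangement")
    if concat_mode not in ("paper", "per_trial"):
        raise ValueError(f"unknown concat_mode {concat_mode!r}")

    trials = sorted(trials, key=lambda t: (t.subject_id, t.trial_id))
    groups: list[list[TrialRecording]]
    if concat_mode == "paper":
        groups = [trials]
    else:
        groups = [[t] for t in trials]

    img_parts, lab_parts, ang_parts = [], [], []
    subj_parts, tstart_parts, tend_parts, start_parts = [], [], [], []
    for group in groups:
        z = np.concatenate(
            [expand_signals(standardize_trial(t, standardizer)[0], arrangement)
             for t in group],
            axis=0,
        )
        raw_labels = np.concatenate([t.labels for t in group])
        std_angles = np.concatenate(
            [standardize_trial(t, standardizer)[1] for t in group]
        )
        subj = np.concatenate([np.full(t.n_samples, t.subject_id) for t in group])
        tid = np.concatenate([np.full(t.n_samples, t.trial_id) for t in group])
        windows, starts = slice_windows(z, window_len)
        labels = np.empty(len(starts), dtype=int)
        angles = np.empty(len(starts), dtype=np.float32)
        for k, s in enumerate(starts):
            lab, ang = assign_targets(
                raw_labels[s : s + window_len], std_angles[s : s + window_len]
            )
            labels[k], angles[k] = lab, ang
        img_parts.append(windows.astype(np.float32))
        lab_parts.append(labels)
        ang_parts.append(angles)
        subj_parts.append(subj[starts])
        tstart_parts.append(tid[starts])
        tend_parts.append(tid[starts + window_len - 1])
        start_parts.append(starts)

    return ImageDataset(
        images=np.concatenate(img_parts, axis=0),
        labels=np.concatenate(lab_parts),
        angles=np.concatenate(ang_parts),
        subject_ids=np.concatenate(subj_parts),
        trial_start=np.concatenate(tstart_parts),
        trial_end=np.concatenate(tend_parts),
        start_indices=np.concatenate(start_parts),
        window_len=window_len,
        arrangement=arrangement.channels,
    )


def save_image_dataset(dataset: ImageDataset, path) -> None:
    """Write an ImageDataset to a .npz container.

    Layout: arrays ``images`` [n x w x M] float32, ``labels`` [n] int64,
    ``angles`` [n] float32, ``subject_ids``/``trial_start``/``trial_end``/
    ``start_indices`` [n] int64, ``window_len`` scalar, ``arrangement`` [M].
    """
    np.savez_compressed(
        path,
        images=dataset.images,
        labels=dataset.labels.astype(np.int64),
        angles=dataset.angles,
        subject_ids=dataset.subject_ids.astype(np.int64),
        trial_start=dataset.trial_start.astype(np.int64),
        trial_end=dataset.trial_end.astype(np.int64),
        start_indices=dataset.start_indices.astype(np.int64),
        window_len=np.int64(dataset.window_len),
        arrangement=np.asarray(dataset.arrangement, dtype=np.int64),
    )


def load_image_dataset(path) -> ImageDataset:
    """Read an ImageDataset written by :func:`save_image_dataset`."""
    with np.load(path) as z:
        return ImageDataset(
            images=z["images"],
            labels=z["labels"],
            angles=z["angles"],
            subject_ids=z["subject_ids"],
            trial_start=z["trial_start"],
            trial_end=z["trial_end"],
            start_indices=z["start_indices"],
            window_len=int(z["window_len"]),
            arrangement=tuple(int(c) for c in z["arrangement"]),
        )
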