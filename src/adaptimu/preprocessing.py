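"""Signal conditioning and labeling: raw IMU stream -> normalized 200 ms windows.

Fixed pipeline order: bias/scale calibration -> 20 Hz zero-phase Butterworth
low-pass (acc + gyro channels) -> complementary-filter gravity removal ->
resampling to the common 200 Hz grid -> 200 ms / 50 %-overlap windowing ->
z-normalization with training-split statistics.  Class imbalance in the
training split is addressed with SMOTE on flattened window vectors plus
inverse-frequency class weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.neighbors import NearestNeighbors

from .synthetic import GRAVITY, LabeledImuStream

WINDOW_S = 0.2
OVERLAP = 0.5


@dataclass
class CalibrationParams:
    """Per-channel bias and positive scale factors: out = (in - bias) * scale."""

    bias: dict[str, float]
    scale: dict[str, float]

    def __post_init__(self) -> None:
        for ch, s in self.scale.items():
            if s <= 0:
                raise ValueError(f"scale for {ch!r} must be positive")

    @classmethod
    def identity(cls, channels) -> "CalibrationParams":
        return cls({c: 0.0 for c in channels}, {c: 1.0 for c in channels})

    def inverse(self) -> "CalibrationParams":
        inv_scale = {c: 1.0 / s for c, s in self.scale.items()}
        inv_bias = {c: -self.bias[c] * self.scale[c] for c in self.bias}
        return CalibrationParams(inv_bias, inv_scale)


@dataclass
class NormStats:
    """Per-channel mean/sd, tagged with the split they were computed on."""

    mean: np.ndarray
    sd: np.ndarray
    split: str = "train"

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd <= 0):
            raise ValueError("degenerate channel: sd must be positive")


@dataclass
class MotionWindow:
    """One 200 ms window (window_samples x channels) with its risk label."""

    x: np.ndarray
    start_s: float
    label: int = 0          # 1 = risk, 0 = no_risk
    scenario: str | None = None
    subject_id: int = 0
    valid: np.ndarray | None = None  # per-sample/channel validity mask

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.x.shape, dtype=bool)


def correct_bias_scale(stream: LabeledImuStream,
                       calib: CalibrationParams) -> LabeledImuStream:
    missing = [c for c in stream.channels
               if c not in calib.bias or c not in calib.scale]
    if missing:
        raise ValueError(f"calibration missing channels: {missing}")
    out = stream.copy()
    for j, ch in enumerate(stream.channels):
        out.values[:, j] = (out.values[:, j] - calib.bias[ch]) * calib.scale[ch]
    return out


def lowpass_filter(series: np.ndarray, sample_rate: float = 200.0,
                   order: int = 4, cutoff_hz: float = 20.0) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass of one series."""
    if sample_rate <= 2 * cutoff_hz:
        raise ValueError("sample_rate must exceed twice the cutoff")
    series = np.asarray(series, dtype=float)
    b, a = sps.butter(order, cutoff_hz, fs=sample_rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if series.shape[0] <= padlen:
        raise ValueError(
            f"series of length {series.shape[0]} shorter than the "
            f"filter warm-up length {padlen + 1}")
    return sps.filtfilt(b, a, series, axis=0)


def lowpass_stream(stream: LabeledImuStream, order: int = 4,
                   cutoff_hz: float = 20.0) -> LabeledImuStream:
    """Apply the low-pass to acceleration and gyroscope channels only.

    Missing samples are bridged by linear interpolation for the filter pass
    and re-flagged missing afterwards.
    """
    out = stream.copy()
    for j, ch in enumerate(stream.channels):
        if "acc" not in ch and "gyro" not in ch:
            continue
        col = out.values[:, j]
        valid = out.mask[:, j]
        filled = _fill_missing(col, valid)
        filt = lowpass_filter(filled, stream.sample_rate, order, cutoff_hz)
        filt[~valid] = np.nan
        out.values[:, j] = filt
    return out


def _fill_missing(col: np.ndarray, valid: np.ndarray) -> np.ndarray:
    if valid.all():
        return col
    if not valid.any():
        return np.zeros_like(col)
    idx = np.arange(col.size)
    return np.interp(idx, idx[valid], col[valid])


def remove_gravity(acc: np.ndarray, gyro: np.ndarray, dt: float,
                   blend: float = 0.02) -> np.ndarray:
    """Subtract gravity from accelerometer data via a complementary filter.

    The unit gravity direction in the sensor frame is propagated with the
    gyroscope rates (rotating-frame transport, g <- g - omega x g dt) and
    nudged toward the normalized accelerometer vector with weight ``blend``
    per step (default 0.02 accel / 0.98 gyro).  ``blend = 1`` is the
    accelerometer-only limit.  Zero-norm accelerometer samples fall back to
    the gyro-only update.
    """
    acc = np.asarray(acc, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    if acc.shape != gyro.shape or acc.ndim != 2 or acc.shape[1] != 3:
        raise ValueError("acc and gyro must be aligned (n, 3) arrays")
    if not (0.0 < blend <= 1.0):
        raise ValueError("blend must be in (0, 1]")

    n = acc.shape[0]
    linear = np.empty_like(acc)
    a0 = acc[0]
    norm0 = np.linalg.norm(a0)
    g_hat = a0 / norm0 if norm0 > 1e-9 else np.array([0.0, 0.0, 1.0])
    for i in range(n):
        if i > 0:
            # transport the gravity direction through the body rotation
            g_hat = g_hat - np.cross(gyro[i], g_hat) * dt
            nrm = np.linalg.norm(g_hat)
            if nrm > 1e-12:
                g_hat = g_hat / nrm
            a_norm = np.linalg.norm(acc[i])
            if a_norm > 1e-9:
                g_hat = (1.0 - blend) * g_hat + blend * (acc[i] / a_norm)
                g_hat = g_hat / np.linalg.norm(g_hat)
        linear[i] = acc[i] - GRAVITY * g_hat
    return linear


def remove_gravity_stream(stream: LabeledImuStream,
                          blend: float = 0.02) -> LabeledImuStream:
    """Replace acc channels with gravity-free linear acceleration, per side."""
    out = stream.copy()
    sides = sorted({c.split("_", 1)[0] for c in stream.channels
                    if c.startswith(("left_", "right_"))}) or [""]
    dt = 1.0 / stream.sample_rate
    for side in sides:
        prefix = f"{side}_" if side else ""
        try:
            aidx = [stream.channel_index(prefix + f"acc_{a}") for a in "xyz"]
            gidx = [stream.channel_index(prefix + f"gyro_{a}") for a in "xyz"]
        except KeyError:
            continue
        acc = np.column_stack([_fill_missing(out.values[:, j], out.mask[:, j])
                               for j in aidx])
        gyro = np.column_stack([_fill_missing(out.values[:, j], out.mask[:, j])
                                for j in gidx])
        linear = remove_gravity(acc, gyro, dt, blend)
        for k, j in enumerate(aidx):
            col = linear[:, k]
            col[~out.mask[:, j]] = np.nan
            out.values[:, j] = col
    return out


def resample_align(timestamps: np.ndarray, values: np.ndarray,
                   target_hz: float = 200.0,
                   max_gap_s: float = 0.1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly interpolate channels onto a shared uniform grid.

    Returns ``(grid_times, grid_values, valid)`` where ``valid`` flags grid
    samples not inside an input gap longer than ``max_gap_s`` (long gaps are
    marked as dropout rather than interpolated across).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != timestamps.shape[0]:
        values = values.T
    if np.any(np.diff(timestamps) <= 0):
        raise ValueError("input timestamps must be strictly increasing")
    dt = 1.0 / target_hz
    n_out = int(np.floor((timestamps[-1] - timestamps[0]) / dt)) + 1
    grid = timestamps[0] + np.arange(n_out) * dt
    out = np.column_stack([np.interp(grid, timestamps, values[:, j])
                           for j in range(values.shape[1])])
    valid = np.ones(n_out, dtype=bool)
    gaps = np.diff(timestamps)
    for i in np.nonzero(gaps > max_gap_s)[0]:
        valid &= ~((grid > timestamps[i]) & (grid < timestamps[i + 1]))
    return grid, out, valid


def segment_windows(stream: LabeledImuStream, window_s: float = WINDOW_S,
                    overlap: float = OVERLAP) -> list[MotionWindow]:
    """Cut the stream into fixed windows; the trailing partial is discarded."""
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    wlen = int(round(window_s * stream.sample_rate))
    stride = int(round(wlen * (1.0 - overlap)))
    if stride < 1:
        raise ValueError("stride below one sample")
    windows = []
    for i0 in range(0, stream.n_samples - wlen + 1, stride):
        start_s = i0 / stream.sample_rate
        windows.append(MotionWindow(
            x=stream.values[i0:i0 + wlen].copy(),
            start_s=start_s,
            scenario=stream.scenario_at(start_s),
            subject_id=stream.subject_id,
            valid=stream.mask[i0:i0 + wlen].copy(),
        ))
    return windows


def label_risk_windows(windows: list[MotionWindow], events,
                       window_s: float = WINDOW_S) -> list[MotionWindow]:
    """Label as risk every window overlapping a pre-injury segment by >= 50 %.

    The pre-injury segment is the ``window_s`` span immediately before each
    event, [time_s - window_s, time_s).  With 50 % overlap two consecutive
    windows meet the >= half-window overlap rule; windows starting before
    the segment are excluded even at exactly half overlap, since their
    content is dominated by pre-drift motion.
    """
    for w in windows:
        w.label = 0
    for ev in events:
        t = ev.time_s if hasattr(ev, "time_s") else float(ev)
        if t < window_s:
            warnings.warn(f"event at {t:.3f}s has incomplete pre-injury "
                          "history; labeling available windows only")
        seg0, seg1 = t - window_s, t
        for w in windows:
            lo = max(w.start_s, seg0)
            hi = min(w.start_s + window_s, seg1)
            if (hi - lo >= 0.5 * window_s - 1e-9
                    and w.start_s >= seg0 - 1e-9):
                w.label = 1
    return windows


def compute_norm_stats(windows: list[MotionWindow],
                       split: str = "train") -> NormStats:
    stacked = np.concatenate([w.x for w in windows], axis=0)
    valid = np.concatenate([w.valid for w in windows], axis=0)
    mean = np.empty(stacked.shape[1])
    sd = np.empty(stacked.shape[1])
    for j in range(stacked.shape[1]):
        col = stacked[valid[:, j], j]
        mean[j] = col.mean() if col.size else 0.0
        sd[j] = col.std() if col.size else 1.0
    return NormStats(mean=mean, sd=sd, split=split)


def z_normalize(windows: list[MotionWindow], stats: NormStats,
                impute_missing: bool = True) -> list[MotionWindow]:
    """Standardize windows by training-split stats; missing samples -> 0."""
    if stats.split != "train":
        raise ValueError("normalization statistics must come from the "
                         "training split (leakage guard)")
    out = []
    for w in windows:
        x = (w.x - stats.mean) / stats.sd
        if impute_missing:
            x[~w.valid] = 0.0
        out.append(MotionWindow(x=x, start_s=w.start_s, label=w.label,
                                scenario=w.scenario, subject_id=w.subject_id,
                                valid=w.valid.copy()))
    return out


def smote_oversample(X: np.ndarray, y: np.ndarray, ratio: float = 1.0,
                     k: int = 5, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE on flattened vectors: synthetic minority points on segments
    between nearest-neighbor minority pairs, up to minority/majority = ratio."""
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_oversample expects a binary label vector")
    minority = classes[np.argmin(counts)]
    Xmin = X[y == minority]
    n_maj = counts.max()
    n_target = int(round(ratio * n_maj))
    n_new = n_target - Xmin.shape[0]
    if n_new <= 0:
        return X, y
    k_eff = min(k, Xmin.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xmin)
    _, nbr = nn.kneighbors(Xmin)
    base = rng.integers(0, Xmin.shape[0], size=n_new)
    pick = rng.integers(1, k_eff + 1, size=n_new)  # skip self at column 0
    gamma = rng.uniform(0.0, 1.0, size=n_new)
    synth = Xmin[base] + gamma[:, None] * (Xmin[nbr[base, pick]] - Xmin[base])
    return (np.vstack([X, synth]),
            np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)]))


def rebalance_training(
    windows_x: np.ndarray, labels: np.ndarray, ratio: float = 1.0,
    k: int = 5, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SMOTE + inverse-frequency class weights for the training split.

    ``windows_x`` is (n, samples, channels); SMOTE interpolates the flattened
    vectors.  Returns (windows, labels, class_weights) with weights indexed
    by class label and normalized to mean 1 over samples.
    """
    windows_x = np.asarray(windows_x, dtype=float)
    labels = np.asarray(labels)
    n, t, c = windows_x.shape
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if counts.min() >= counts.max() * ratio - 0.5:
        w = np.ones(2)
        return windows_x, labels, w
    if counts.min() < 2:
        warnings.warn("single minority sample: SMOTE skipped, "
                      "falling back to class weights only")
        Xr, yr = windows_x.reshape(n, -1), labels
    else:
        Xr, yr = smote_oversample(windows_x.reshape(n, -1), labels,
                                  ratio=ratio, k=k, seed=seed)
    _, post = np.unique(yr, return_counts=True)
    w = post.sum() / (2.0 * post)   # inverse post-SMOTE frequency
    w = w / np.mean(w[yr])          # mean weight 1 over samples
    return Xr.reshape(-1, t, c), yr, w


def split_subjects(subject_ids, fractions=(0.70, 0.115, 0.185),
                   seed: int = 0) -> dict[str, np.ndarray]:
    """Subject-level train/val/test split by the configured fractions."""
    ids = np.unique(np.asarray(subject_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ids)
    n = len(ids)
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = max(1, int(round(fractions[1] * n))) if n - n_train >= 2 else 0
    return {
        "train": np.sort(perm[:n_train]),
        "val": np.sort(perm[n_train:n_train + n_val]),
        "test": np.sort(perm[n_train + n_val:]),
    }


def preprocess_stream(stream: LabeledImuStream,
                      calib: CalibrationParams | None = None,
                      blend: float = 0.02) -> list[MotionWindow]:
    """Run the fixed conditioning chain and return labeled raw windows
    (normalization is applied separately with training-split stats)."""
    s = stream if calib is None else correct_bias_scale(stream, calib)
    s = lowpass_stream(s)
    s = remove_gravity_stream(s, blend=blend)
    windows = segment_windows(s)
    return label_risk_windows(windows, s.events)
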