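"""Seeded generator of labeled bilateral ankle-IMU sessions.

Emulates the structure of an athletic ankle-motion recording: a 200 Hz
multichannel inertial stream partitioned into motion-scenario segments
(steady running, directional changes, jump landings, external collisions,
fatigue-induced degradation, sensor dropout), sprinkled with injury events
of four categories (inversion/eversion sprains, rotational injuries,
impact traumas) preceded by a short kinematic drift, plus intervals of
partial sensor dropout.

The generator makes no claim of biomechanical fidelity: it produces
signals whose second-order statistics differ detectably between scenarios
(gait periodicity under steady running, broadband transients at jump
landings, growing variance under fatigue) so that downstream models have
real structure to learn, while every draw is reproducible from one seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

SCENARIOS = (
    "steady_running",
    "directional_change",
    "jump_landing",
    "external_collision",
    "fatigue_degradation",
    "sensor_dropout",
)

INJURY_TYPES = ("inversion", "eversion", "rotational", "impact")

#: Injury-category proportions (inversion, eversion, rotational, impact).
DEFAULT_TYPE_PROPORTIONS = (0.625, 0.168, 0.126, 0.080)

#: Channel basis for a single ankle-mounted 6-axis IMU.
BASE_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z")
MAG_CHANNELS = ("mag_x", "mag_y", "mag_z")

GRAVITY = 9.81  # m/s^2
STRIDE_HZ = 1.4  # stride frequency of the synthetic runner


@dataclass
class ScenarioSegment:
    scenario: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not self.end_s > self.start_s:
            raise ValueError("segment must have end_s > start_s")


@dataclass
class InjuryEvent:
    time_s: float
    itype: str
    side: str = "left"

    def __post_init__(self) -> None:
        if self.itype not in INJURY_TYPES:
            raise ValueError(f"unknown injury type {self.itype!r}")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


@dataclass
class LabeledImuStream:
    """Timestamped multichannel inertial series with annotations.

    ``values`` is a samples x channels float matrix; samples inside dropout
    intervals are NaN and flagged False in ``mask``.  All other samples are
    finite.
    """

    sample_rate: float
    channels: list[str]
    values: np.ndarray
    segments: list[ScenarioSegment] = field(default_factory=list)
    events: list[InjuryEvent] = field(default_factory=list)
    dropout: list[tuple[str, float, float]] = field(default_factory=list)
    mask: np.ndarray | None = None
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.channels):
            raise ValueError("values must be samples x channels")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None

    def copy(self) -> "LabeledImuStream":
        return LabeledImuStream(
            sample_rate=self.sample_rate,
            channels=list(self.channels),
            values=self.values.copy(),
            segments=copy.deepcopy(self.segments),
            events=copy.deepcopy(self.events),
            dropout=list(self.dropout),
            mask=self.mask.copy(),
            subject_id=self.subject_id,
        )

    def scenario_at(self, t: float) -> str | None:
        for seg in self.segments:
            if seg.start_s <= t < seg.end_s:
                return seg.scenario
        return None


def default_scenario_mix() -> dict[str, float]:
    return {
        "steady_running": 0.40,
        "directional_change": 0.15,
        "jump_landing": 0.15,
        "external_collision": 0.08,
        "fatigue_degradation": 0.14,
        "sensor_dropout": 0.08,
    }


def _base_gait(t: np.ndarray, phase: float, rng: np.random.Generator,
               amp: float = 1.0, noise: float = 1.0) -> np.ndarray:
    """Harmonic gait model: 2-3 harmonics of the stride frequency."""
    w = 2 * np.pi * STRIDE_HZ
    cols = [
        amp * (1.5 * np.sin(w * t + phase) + 0.5 * np.sin(2 * w * t + phase)),
        amp * (1.0 * np.cos(w * t + phase) + 0.3 * np.sin(3 * w * t)),
        GRAVITY + amp * 2.5 * np.sin(2 * w * t + phase),
        amp * (0.8 * np.sin(w * t + phase + 0.5)),
        amp * (1.2 * np.sin(w * t + phase + 1.0) + 0.4 * np.cos(2 * w * t)),
        amp * (0.6 * np.sin(w * t + phase + 2.0)),
    ]
    x = np.stack(cols, axis=1)
    sig = np.array([0.30, 0.30, 0.40, 0.10, 0.10, 0.10]) * noise
    x += rng.standard_normal(x.shape) * sig
    return x


def _segment_signal(scenario: str, t: np.ndarray, phase: float,
                    rng: np.random.Generator, fs: float) -> np.ndarray:
    n = t.size
    rel = t - t[0]
    if scenario == "steady_running":
        return _base_gait(t, phase, rng)
    if scenario == "directional_change":
        x = _base_gait(t, phase, rng)
        # yaw bursts roughly once a second
        n_bursts = max(1, int(rel[-1]))
        for _ in range(n_bursts):
            t0 = rng.uniform(0, max(rel[-1] - 0.3, 0.01))
            env = np.exp(-np.clip(rel - t0, 0, None) / 0.08) * (rel >= t0)
            x[:, 5] += rng.choice([-1, 1]) * 4.0 * env
            x[:, 0] += 2.0 * env
        return x
    if scenario == "jump_landing":
        # quiet flight phases punctuated by broadband landing impacts
        x = _base_gait(t, phase, rng, amp=0.3, noise=0.4)
        # landing impacts: broadband acceleration transients every ~1.2 s
        t0 = rng.uniform(0.2, 0.6)
        while t0 < rel[-1]:
            env = np.exp(-np.clip(rel - t0, 0, None) / 0.03) * (rel >= t0)
            x[:, 0] += 10.0 * env * rng.standard_normal(n) * 0.8
            x[:, 1] += 10.0 * env * rng.standard_normal(n) * 0.8
            x[:, 2] += 18.0 * env
            x[:, 3:6] += 2.5 * env[:, None] * rng.standard_normal((n, 3))
            t0 += rng.uniform(0.9, 1.5)
        return x
    if scenario == "external_collision":
        x = _base_gait(t, phase, rng)
        for _ in range(rng.integers(1, 3)):
            t0 = rng.uniform(0, max(rel[-1] - 0.1, 0.01))
            env = np.exp(-np.clip(rel - t0, 0, None) / 0.02) * (rel >= t0)
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            x[:, 0:3] += 20.0 * env[:, None] * direction
            x[:, 3:6] += 5.0 * env[:, None] * rng.standard_normal(3)
        return x
    if scenario == "fatigue_degradation":
        # variance grows linearly across the segment; stride weakens
        g = np.linspace(1.0, 3.0, n)
        x = _base_gait(t, phase, rng, amp=1.0, noise=1.0)
        x += (g[:, None] - 1.0) * rng.standard_normal((n, 6)) * \
            np.array([0.3, 0.3, 0.4, 0.12, 0.12, 0.12])
        return x
    if scenario == "sensor_dropout":
        return _base_gait(t, phase, rng)
    raise ValueError(f"unknown scenario {scenario!r}")


def draw_injury_types(n: int, rng: np.random.Generator,
                      proportions=DEFAULT_TYPE_PROPORTIONS) -> list[str]:
    p = np.asarray(proportions, dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(INJURY_TYPES), size=n, p=p)
    return [INJURY_TYPES[i] for i in idx]


def generate_session(
    duration_s: float,
    scenario_mix: dict[str, float] | None = None,
    injury_rate: float = 2.0,
    seed: int = 0,
    sample_rate: float = 200.0,
    type_proportions=DEFAULT_TYPE_PROPORTIONS,
    bilateral: bool = False,
    include_mag: bool = False,
    drift_window_s: float = 0.5,
    subject_id: int = 0,
) -> LabeledImuStream:
    """Generate one labeled session.

    Parameters
    ----------
    duration_s : session length in seconds (rows = duration * sample_rate).
    scenario_mix : scenario -> probability map (must sum to 1).
    injury_rate : expected injury events per minute (Poisson).
    seed : RNG seed; identical (config, seed) gives bit-identical streams.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    mix = dict(scenario_mix) if scenario_mix is not None else default_scenario_mix()
    for k in mix:
        if k not in SCENARIOS:
            raise ValueError(f"unknown scenario {k!r} in mix")
    probs = np.array([mix.get(s, 0.0) for s in SCENARIOS], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("scenario_mix probabilities must sum to 1")
    if injury_rate < 0:
        raise ValueError("injury_rate must be non-negative")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate

    sides = ("left", "right") if bilateral else ("left",)
    channels: list[str] = []
    for side in sides:
        prefix = f"{side}_" if bilateral else ""
        channels += [prefix + c for c in BASE_CHANNELS]
        if include_mag:
            channels += [prefix + c for c in MAG_CHANNELS]

    # scenario timeline
    segments: list[ScenarioSegment] = []
    pos = 0.0
    while pos < duration_s - 1e-9:
        seg_len = min(float(rng.uniform(4.0, 8.0)), duration_s - pos)
        scen = SCENARIOS[rng.choice(len(SCENARIOS), p=probs)]
        segments.append(ScenarioSegment(scen, pos, pos + seg_len))
        pos += seg_len

    values = np.zeros((n, len(channels)))
    dropout_plan: list[tuple[str, float, float]] = []
    for si, side in enumerate(sides):
        phase = float(rng.uniform(0, 2 * np.pi))
        base = si * (9 if include_mag else 6)
        for seg in segments:
            i0 = int(round(seg.start_s * sample_rate))
            i1 = int(round(seg.end_s * sample_rate))
            if i1 <= i0:
                continue
            x = _segment_signal(seg.scenario, t[i0:i1], phase, rng, sample_rate)
            values[i0:i1, base:base + 6] = x
            if seg.scenario == "sensor_dropout":
                ch = channels[base + int(rng.integers(0, 6))]
                d0 = float(rng.uniform(seg.start_s, max(seg.end_s - 0.6, seg.start_s)))
                d1 = min(d0 + float(rng.uniform(0.2, 0.6)), seg.end_s)
                dropout_plan.append((ch, d0, d1))
        if include_mag:
            # slowly-varying geomagnetic field seen through body rotation
            m = np.stack([
                25 + 5 * np.sin(2 * np.pi * 0.2 * t + phase),
                5 * np.cos(2 * np.pi * 0.2 * t),
                -40 + 3 * np.sin(2 * np.pi * 0.1 * t),
            ], axis=1) + rng.standard_normal((n, 3)) * 0.5
            values[:, base + 6:base + 9] = m

    stream = LabeledImuStream(
        sample_rate=sample_rate,
        channels=channels,
        values=values,
        segments=segments,
        subject_id=subject_id,
    )

    # injury events
    n_events = int(rng.poisson(injury_rate * duration_s / 60.0))
    if n_events > 0 and duration_s > 2 * drift_window_s + 1.0:
        times = np.sort(rng.uniform(drift_window_s + 0.5,
                                    duration_s - 0.5, size=n_events))
        itypes = draw_injury_types(n_events, rng, type_proportions)
        for et, ity in zip(times, itypes):
            side = sides[int(rng.integers(0, len(sides)))]
            stream = inject_injury_event(
                stream, InjuryEvent(float(et), ity, side), drift_window_s)

    for ch, d0, d1 in dropout_plan:
        stream = inject_sensor_dropout(stream, ch, d0, d1)
    return stream


#: Peak perturbation amplitudes at the event instant, per injury type.
DRIFT_AMPLITUDES = {
    "inversion": 5.0,   # rad/s on the roll-axis gyro
    "eversion": 5.0,
    "rotational": 5.0,  # rad/s on the yaw-axis gyro
    "impact": 14.0,     # m/s^2 spread over the acceleration axes
}


def inject_injury_event(stream: LabeledImuStream, event: InjuryEvent,
                        drift_window_s: float = 0.5) -> LabeledImuStream:
    """Superimpose a ramped pre-injury perturbation ending at the event.

    A linear ramp rises from zero at ``time_s - drift_window_s`` to the
    type-specific peak at ``time_s``: inversion/eversion load the roll-axis
    gyro (opposite signs), rotational injuries the yaw-axis gyro, and
    impacts the acceleration magnitude.
    """
    if not (0.0 <= event.time_s <= stream.duration_s):
        raise ValueError("event time outside stream duration")
    if event.time_s - drift_window_s < 0:
        raise ValueError("drift window extends before stream start")
    if drift_window_s < 0:
        raise ValueError("drift_window_s must be non-negative")

    out = stream.copy()
    fs = stream.sample_rate
    i1 = min(int(round(event.time_s * fs)), stream.n_samples - 1)
    i0 = int(round((event.time_s - drift_window_s) * fs))
    ramp = np.linspace(0.0, 1.0, i1 - i0 + 1) if i1 > i0 else np.ones(1)

    bilateral = any(c.startswith(("left_", "right_")) for c in stream.channels)
    prefix = f"{event.side}_" if bilateral else ""
    amp = DRIFT_AMPLITUDES[event.itype]
    if event.itype in ("inversion", "eversion"):
        sign = 1.0 if event.itype == "inversion" else -1.0
        j = out.channel_index(prefix + "gyro_x")
        out.values[i0:i1 + 1, j] += sign * amp * ramp
    elif event.itype == "rotational":
        j = out.channel_index(prefix + "gyro_z")
        out.values[i0:i1 + 1, j] += amp * ramp
    else:  # impact: spread across acceleration axes
        for axis, w in (("acc_x", 0.4), ("acc_y", 0.4), ("acc_z", 0.8)):
            j = out.channel_index(prefix + axis)
            out.values[i0:i1 + 1, j] += w * amp * ramp
    out.events.append(event)
    out.events.sort(key=lambda e: e.time_s)
    return out


def inject_sensor_dropout(stream: LabeledImuStream, channel: str,
                          start_s: float, end_s: float) -> LabeledImuStream:
    """Flag samples of one channel missing over [start_s, end_s)."""
    j = stream.channel_index(channel)
    if start_s > end_s:
        raise ValueError("start_s must not exceed end_s")
    if start_s < 0 or end_s > stream.duration_s + 1e-9:
        raise ValueError("dropout interval outside session")
    out = stream.copy()
    fs = stream.sample_rate
    i0 = int(round(start_s * fs))
    i1 = int(round(end_s * fs))
    if i1 > i0:
        out.values[i0:i1, j] = np.nan
        out.mask[i0:i1, j] = False
        out.dropout.append((channel, float(start_s), float(end_s)))
    return out
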