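"""Cycle segmentation and kinematic feature extraction from hand-aperture traces.

The movement signal is a one-dimensional, normalized hand aperture (distance
between third-digit tip and wrist, divided by hand length) sampled at a fixed
rate while the patient performs repetitive hand opening-closing.  From that
signal this module segments individual open-close cycles and computes a
23-parameter feature set spanning five families: amplitude, speed/vigor,
temporal rhythm, variability, and decrement.

The catalog of features is configuration, not code: each entry carries a name,
family, and an orientation flag (``higher_better`` / ``lower_better``) that
downstream scoring uses to orient percent changes so that positive always
means clinical improvement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ApertureTrace",
    "CycleSegmentation",
    "CatalogEntry",
    "FeatureCatalog",
    "FeatureVector",
    "SmoothingConfig",
    "InsufficientCyclesError",
    "default_catalog",
    "segment_cycles",
    "compute_features",
    "batch_extract",
]

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"


class InsufficientCyclesError(ValueError):
    """Raised when a trace does not contain at least two complete cycles."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ApertureTrace:
    """Uniformly sampled normalized hand-aperture signal.

    Parameters
    ----------
    samples : array-like
        Dimensionless aperture values (distance(third-digit tip, wrist) /
        hand length).
    sampling_rate : float
        Samples per second; smartphone video yields 60.
    patient_id, hand, condition : str
        Identifiers carried through to feature provenance.  ``hand`` is
        ``"left"`` or ``"right"``; ``condition`` labels the stimulation state
        (e.g. ``"OFF"`` or a program name).
    """

    samples: np.ndarray
    sampling_rate: float = 60.0
    patient_id: str = ""
    hand: str = "right"
    condition: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"trace {self.key} contains non-finite samples")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.hand, self.condition)

    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass
class SmoothingConfig:
    """Low-pass / peak-detection configuration for cycle segmentation.

    The cutoff sits above the task band (~0.5-4 Hz open-close rate) and below
    sensor/pose-estimation noise.  Peak prominence is expressed as a fraction
    of the robust (5th-95th percentile) signal range so that segmentation is
    amplitude-scale invariant.
    """

    cutoff_hz: float = 8.0
    filter_order: int = 4
    min_prominence_frac: float = 0.2
    min_peak_separation_s: float = 0.2


@dataclass
class CycleRecord:
    amplitude: float
    opening_duration: float
    closing_duration: float
    opening_peak_speed: float
    closing_peak_speed: float
    cycle_duration: float


@dataclass
class CycleSegmentation:
    """Alternating peak/valley indices plus per-cycle kinematic records."""

    peak_indices: np.ndarray
    valley_indices: np.ndarray
    cycles: list[CycleRecord]
    smoothed: np.ndarray
    velocity: np.ndarray
    sampling_rate: float

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def cycle_array(self, attr: str) -> np.ndarray:
        return np.array([getattr(c, attr) for c in self.cycles], dtype=float)

    @property
    def segmented_span(self) -> float:
        """Seconds from the first to the last cycle boundary (valley)."""
        return (self.valley_indices[-1] - self.valley_indices[0]) / self.sampling_rate


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    family: str
    orientation: str
    definition_id: str

    def __post_init__(self) -> None:
        if self.family not in {"amplitude", "speed", "rhythm", "variability", "decrement"}:
            raise ValueError(f"unknown family {self.family!r}")
        if self.orientation not in {HIGHER_BETTER, LOWER_BETTER}:
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class FeatureCatalog:
    """Ordered collection of feature definitions with orientation metadata."""

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("catalog feature names must be unique")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def orientation_sign(self, name: str) -> int:
        entry = self[name]
        return 1 if entry.orientation == HIGHER_BETTER else -1

    def __getitem__(self, name: str) -> CatalogEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self, path: str) -> None:
        payload = [e.__dict__ for e in self.entries]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "FeatureCatalog":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls([CatalogEntry(**e) for e in payload])


@dataclass
class FeatureVector:
    """Feature name -> value map with trace provenance.

    Values are finite floats or NaN; NaN marks a feature that is undefined for
    the trace (e.g. decay slopes with fewer than three cycles) and is treated
    as explicitly missing downstream, never as zero.
    """

    values: dict[str, float]
    patient_id: str = ""
    hand: str = ""
    condition: str = ""

    def __getitem__(self, name: str) -> float:
        return self.values[name]


# ---------------------------------------------------------------------------
# Default catalog: 23 features across five families
# ---------------------------------------------------------------------------

_DEFAULT_ENTRIES: list[tuple[str, str, str]] = [
    # amplitude
    ("mean_amplitude", "amplitude", HIGHER_BETTER),
    ("max_amplitude", "amplitude", HIGHER_BETTER),
    ("cv_amplitude", "variability", LOWER_BETTER),
    ("amplitude_decay", "decrement", HIGHER_BETTER),
    # speed / vigor
    ("mean_speed", "speed", HIGHER_BETTER),
    ("mean_rms_velocity", "speed", HIGHER_BETTER),
    ("mean_opening_speed", "speed", HIGHER_BETTER),
    ("mean_closing_speed", "speed", HIGHER_BETTER),
    ("max_speed", "speed", HIGHER_BETTER),
    ("opening_speed_decay", "decrement", HIGHER_BETTER),
    ("closing_speed_decay", "decrement", HIGHER_BETTER),
    ("velocity_decay", "decrement", HIGHER_BETTER),
    # rhythm
    ("frequency", "rhythm", HIGHER_BETTER),
    ("mean_cycle_duration", "rhythm", LOWER_BETTER),
    ("mean_opening_duration", "rhythm", LOWER_BETTER),
    ("mean_closing_duration", "rhythm", LOWER_BETTER),
    ("opening_closing_ratio", "rhythm", LOWER_BETTER),
    ("frequency_decay", "decrement", HIGHER_BETTER),
    # variability
    ("cv_cycle_duration", "variability", LOWER_BETTER),
    ("cv_peak_speed", "variability", LOWER_BETTER),
    ("jerkiness", "variability", LOWER_BETTER),
    ("n_hesitations", "variability", LOWER_BETTER),
    ("amplitude_range_consistency", "variability", LOWER_BETTER),
]


def default_catalog() -> FeatureCatalog:
    """The default 23-feature catalog.

    Decay features are signed ordinary-least-squares slopes over cycle index
    (percent of the per-trace mean per cycle); in disease they are negative,
    and a slope moving toward zero means less within-sequence decrement, so
    they are oriented higher-is-better.  All coefficient-of-variation,
    duration, and hesitation features are lower-is-better; amplitude, speed
    and frequency features are higher-is-better.
    """
    entries = [CatalogEntry(n, f, o, definition_id=n) for n, f, o in _DEFAULT_ENTRIES]
    catalog = FeatureCatalog(entries)
    assert len(catalog) == 23
    return catalog


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _smooth(samples: np.ndarray, fs: float, config: SmoothingConfig) -> np.ndarray:
    nyq = fs / 2.0
    cutoff = config.cutoff_hz
    if cutoff >= nyq:  # nothing to remove below Nyquist
        return samples.astype(float)
    b, a = sps.butter(config.filter_order, cutoff / nyq, btype="low")
    padlen = min(3 * max(len(a), len(b)), len(samples) - 1)
    return sps.filtfilt(b, a, samples, padlen=padlen)


def _alternate(peaks: np.ndarray, valleys: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Enforce a strictly alternating valley/peak sequence.

    Between consecutive events of the same type, keep the more extreme one
    (ties broken toward the earlier sample).
    """
    events = sorted(
        [(int(i), "p") for i in peaks] + [(int(i), "v") for i in valleys]
    )
    kept: list[tuple[int, str]] = []
    for idx, kind in events:
        if kept and kept[-1][1] == kind:
            prev_idx = kept[-1][0]
            if kind == "p":
                better = idx if s[idx] > s[prev_idx] else prev_idx
            else:
                better = idx if s[idx] < s[prev_idx] else prev_idx
            kept[-1] = (better, kind)
        else:
            kept.append((idx, kind))
    new_peaks = np.array([i for i, k in kept if k == "p"], dtype=int)
    new_valleys = np.array([i for i, k in kept if k == "v"], dtype=int)
    return new_peaks, new_valleys


def segment_cycles(
    trace: ApertureTrace, config: SmoothingConfig | None = None
) -> CycleSegmentation:
    """Detect open-close cycles as valley->peak->valley triplets.

    A cycle starts at a valley (hand closed), opens to a peak and closes to
    the next valley.  Amplitude is peak value minus the preceding valley
    value; peak opening/closing speeds are extrema of the first derivative of
    the smoothed signal within each phase.

    Raises
    ------
    InsufficientCyclesError
        If fewer than two complete cycles are found.
    """
    config = config or SmoothingConfig()
    fs = trace.sampling_rate
    s = _smooth(trace.samples, fs, config)
    lo, hi = np.percentile(s, [5, 95])
    rng = hi - lo
    if rng <= 1e-9 * max(float(np.max(np.abs(s))), 1e-300):
        raise InsufficientCyclesError(
            f"insufficient cycles in trace {trace.key}: signal has no oscillation"
        )
    prominence = config.min_prominence_frac * rng
    distance = max(1, int(round(config.min_peak_separation_s * fs)))
    peaks, _ = sps.find_peaks(s, prominence=prominence, distance=distance)
    valleys, _ = sps.find_peaks(-s, prominence=prominence, distance=distance)
    # find_peaks cannot mark the trace boundaries; admit an endpoint as a
    # valley when it sits at the detected valley level, so cycles that start
    # or end exactly at the recording edge are not lost
    if len(valleys):
        valley_level = float(np.median(s[valleys]))
        for edge in (0, len(s) - 1):
            if edge not in valleys and s[edge] <= valley_level + 0.5 * prominence:
                valleys = np.sort(np.append(valleys, edge))
    peaks, valleys = _alternate(peaks, valleys, s)

    # assemble complete valley -> peak -> valley cycles
    v = np.gradient(s) * fs
    cycles: list[CycleRecord] = []
    used_valleys: list[int] = []
    used_peaks: list[int] = []
    for i in range(len(valleys) - 1):
        v0, v1 = valleys[i], valleys[i + 1]
        between = peaks[(peaks > v0) & (peaks < v1)]
        if len(between) != 1:
            continue
        p = int(between[0])
        opening = v[v0 : p + 1]
        closing = v[p : v1 + 1]
        cycles.append(
            CycleRecord(
                amplitude=float(s[p] - s[v0]),
                opening_duration=(p - v0) / fs,
                closing_duration=(v1 - p) / fs,
                opening_peak_speed=float(np.max(opening)) if len(opening) else np.nan,
                closing_peak_speed=float(np.max(-closing)) if len(closing) else np.nan,
                cycle_duration=(v1 - v0) / fs,
            )
        )
        used_peaks.append(p)
        if not used_valleys or used_valleys[-1] != int(v0):
            used_valleys.append(int(v0))
        used_valleys.append(int(v1))
    if len(cycles) < 2:
        raise InsufficientCyclesError(
            f"insufficient cycles in trace {trace.key}: "
            f"found {len(cycles)} complete cycle(s), need at least 2"
        )
    if len(cycles) < 4:
        warnings.warn(
            f"trace {trace.key}: only {len(cycles)} cycles; "
            "decay and variability estimates will be unstable",
            stacklevel=2,
        )
    return CycleSegmentation(
        peak_indices=np.array(used_peaks, dtype=int),
        valley_indices=np.array(sorted(set(used_valleys)), dtype=int),
        cycles=cycles,
        smoothed=s,
        velocity=v,
        sampling_rate=fs,
    )


# ---------------------------------------------------------------------------
# Feature computation
# ---------------------------------------------------------------------------


def _cv(x: np.ndarray) -> float:
    m = np.mean(x)
    if m == 0:
        return np.nan
    return float(np.std(x, ddof=1) / abs(m))


def _decay_slope_pct(values: np.ndarray) -> float:
    """OLS slope of values over cycle index, as percent of the mean per cycle.

    Requires >= 3 cycles; NaN (missing) otherwise or when the mean is zero.
    """
    n = len(values)
    if n < 3:
        return np.nan
    mean = np.mean(values)
    if mean == 0:
        return np.nan
    k = np.arange(n, dtype=float)
    slope = float(np.polyfit(k, values, 1)[0])
    return 100.0 * slope / abs(mean)


def _count_hesitations(seg: CycleSegmentation, threshold_frac: float = 0.1) -> float:
    """Mean number of sub-threshold velocity dips per cycle.

    Within each opening/closing phase, interior runs where |velocity| drops
    below ``threshold_frac`` of that phase's peak speed count as hesitations;
    the natural near-zero velocity at the phase boundaries is excluded by a
    10%-of-phase margin on each side.
    """
    v = seg.velocity
    valleys = seg.valley_indices
    peaks = seg.peak_indices
    total = 0
    phases: list[tuple[int, int, float]] = []
    for i, p in enumerate(peaks):
        prev_v = valleys[valleys < p]
        next_v = valleys[valleys > p]
        if len(prev_v) == 0 or len(next_v) == 0:
            continue
        phases.append((int(prev_v[-1]), int(p), seg.cycles[i].opening_peak_speed))
        phases.append((int(p), int(next_v[0]), seg.cycles[i].closing_peak_speed))
    for a, b, peak_speed in phases:
        if not np.isfinite(peak_speed) or peak_speed <= 0:
            continue
        margin = max(1, int(0.1 * (b - a)))
        interior = np.abs(v[a + margin : b - margin])
        if len(interior) == 0:
            continue
        below = interior < threshold_frac * peak_speed
        # count connected runs of below-threshold samples
        total += int(np.sum(below[1:] & ~below[:-1]) + (1 if below[0] else 0))
    return total / seg.n_cycles


def compute_features(
    trace: ApertureTrace,
    catalog: FeatureCatalog | None = None,
    config: SmoothingConfig | None = None,
) -> FeatureVector:
    """Compute the 23-parameter kinematic feature set for one trace.

    All speeds are in units of normalized aperture per second (1/s);
    durations in seconds; frequency in Hz; decay slopes in percent of the
    per-trace mean per cycle; CV and consistency features dimensionless.
    """
    catalog = catalog or default_catalog()
    seg = segment_cycles(trace, config)
    s, v, fs = seg.smoothed, seg.velocity, seg.sampling_rate
    accel = np.gradient(v) * fs

    amplitudes = seg.cycle_array("amplitude")
    opening_speeds = seg.cycle_array("opening_peak_speed")
    closing_speeds = seg.cycle_array("closing_peak_speed")
    cycle_durations = seg.cycle_array("cycle_duration")
    opening_durations = seg.cycle_array("opening_duration")
    closing_durations = seg.cycle_array("closing_duration")
    peak_speeds = np.maximum(opening_speeds, closing_speeds)
    rates = 1.0 / cycle_durations

    # per-cycle RMS velocity for the velocity-decay slope
    rms_per_cycle = []
    valleys = seg.valley_indices
    for i in range(len(valleys) - 1):
        chunk = v[valleys[i] : valleys[i + 1] + 1]
        rms_per_cycle.append(float(np.sqrt(np.mean(chunk**2))))
    rms_per_cycle = np.array(rms_per_cycle)

    mean_speed = float(np.mean(np.abs(v)))
    span = seg.segmented_span

    values: dict[str, float] = {
        "mean_amplitude": float(np.mean(amplitudes)),
        "max_amplitude": float(np.max(amplitudes)),
        "cv_amplitude": _cv(amplitudes),
        "amplitude_decay": _decay_slope_pct(amplitudes),
        "mean_speed": mean_speed,
        "mean_rms_velocity": float(np.sqrt(np.mean(v**2))),
        "mean_opening_speed": float(np.mean(opening_speeds)),
        "mean_closing_speed": float(np.mean(closing_speeds)),
        "max_speed": float(np.max(np.abs(v))),
        "opening_speed_decay": _decay_slope_pct(opening_speeds),
        "closing_speed_decay": _decay_slope_pct(closing_speeds),
        "velocity_decay": _decay_slope_pct(rms_per_cycle),
        "frequency": seg.n_cycles / span if span > 0 else np.nan,
        "mean_cycle_duration": float(np.mean(cycle_durations)),
        "mean_opening_duration": float(np.mean(opening_durations)),
        "mean_closing_duration": float(np.mean(closing_durations)),
        "opening_closing_ratio": float(
            np.mean(opening_durations) / np.mean(closing_durations)
        ),
        "frequency_decay": _decay_slope_pct(rates),
        "cv_cycle_duration": _cv(cycle_durations) if seg.n_cycles >= 3 else np.nan,
        "cv_peak_speed": _cv(peak_speeds) if seg.n_cycles >= 3 else np.nan,
        "jerkiness": float(np.mean(np.abs(accel)) / mean_speed) if mean_speed > 0 else np.nan,
        "n_hesitations": _count_hesitations(seg),
        "amplitude_range_consistency": (
            float(
                (np.percentile(amplitudes, 75) - np.percentile(amplitudes, 25))
                / np.median(amplitudes)
            )
            if seg.n_cycles >= 3
            else np.nan
        ),
    }
    ordered = {name: float(values[name]) for name in catalog.names}
    return FeatureVector(
        values=ordered,
        patient_id=trace.patient_id,
        hand=trace.hand,
        condition=trace.condition,
    )


def batch_extract(
    traces: Iterable[ApertureTrace],
    catalog: FeatureCatalog | None = None,
    config: SmoothingConfig | None = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Extract features for a collection of traces.

    Returns a table with key columns (patient_id, hand, condition) followed by
    the 23 feature columns, plus a per-trace error report for traces that
    failed extraction (they are reported, never silently dropped).

    Raises
    ------
    ValueError
        If two traces share the same (patient_id, hand, condition) key.
    """
    catalog = catalog or default_catalog()
    rows: list[dict] = []
    errors: list[dict] = []
    seen: set[tuple[str, str, str]] = set()
    for trace in traces:
        if trace.key in seen:
            raise ValueError(f"duplicate trace key {trace.key}")
        seen.add(trace.key)
        try:
            fv = compute_features(trace, catalog, config)
        except (InsufficientCyclesError, ValueError) as exc:
            errors.append({"key": trace.key, "error": str(exc)})
            continue
        row = {"patient_id": fv.patient_id, "hand": fv.hand, "condition": fv.condition}
        row.update(fv.values)
        rows.append(row)
    columns = ["patient_id", "hand", "condition", *catalog.names]
    table = pd.DataFrame(rows, columns=columns)
    return table, errors
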