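"""From raw marker trajectories to the 60 normalized kinematic series.

Pipeline order is reflect -> crop -> derive -> normalize:

1. **Side unification.**  Right-limb recordings are mirrored through the
   sagittal (yz) plane (x -> -x) so both limbs share one coordinate
   convention.  Reflection precedes derivation so velocity/acceleration
   signs stay consistent.
2. **Cropping.**  Only the lift-lower phase is analyzed.  The threshold is
   10% of the fingertip marker's vertical range; samples whose FN z value
   exceeds the starting z plus that threshold delimit the kept window.
3. **Derivation.**  Per marker M: trajectory Mx/My/Mz, displacement from
   the first cropped sample Mdx/Mdy/Mdz and its module MD, velocity
   Mvx/Mvy/Mvz (central differences, one-sided ends) and speed MV,
   acceleration Max/May/Maz (central second differences, one-sided ends)
   and its module MA — 15 series per marker, 60 per recording.  Modules
   are per-sample Euclidean norms of the 3-vector.
4. **Normalization.**  Each series is min-max scaled to [0, 1]
   independently; constant series map to zeros and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, NoMovementError, ValidationError
from .io import AXES, MARKERS, Recording

#: per-marker series-name suffixes in catalog order
_SUFFIXES = ("x", "y", "z", "dx", "dy", "dz", "D",
             "vx", "vy", "vz", "V", "ax", "ay", "az", "A")

#: the 60 series names, grouped by marker
SERIES_NAMES: tuple[str, ...] = tuple(f"{m}{s}" for m in MARKERS for s in _SUFFIXES)


@dataclass
class CropResult:
    """Lift-phase window of a recording (inclusive indices into the original)."""

    start_index: int
    end_index: int
    threshold_value: float
    cropped: Recording


@dataclass
class DerivedSeriesSet:
    """The 60 named scalar kinematic series of one recording."""

    recording_id: str
    class_label: str
    sampling_rate_hz: float
    series: dict[str, np.ndarray]
    normalized: bool = False
    constant_series: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        missing = [n for n in SERIES_NAMES if n not in self.series]
        extra = [n for n in self.series if n not in SERIES_NAMES]
        if missing or extra:
            raise ValidationError(f"derived series set must contain exactly the 60 "
                                  f"named series (missing={missing[:3]}, extra={extra[:3]})")
        lengths = {len(v) for v in self.series.values()}
        if len(lengths) != 1:
            raise ValidationError(f"derived series lengths differ: {sorted(lengths)}")


def reflect_to_common_side(recording: Recording) -> Recording:
    """Mirror right-limb recordings through the sagittal (yz) plane.

    Left recordings are returned as an unchanged (but side-unified) copy;
    right recordings have every marker's x coordinate negated.  Applying
    the raw coordinate map twice restores the input.
    """
    out = recording.copy()
    if recording.side == "right":
        for arr in out.markers.values():
            arr[:, 0] *= -1.0
    out.side_unified = True
    return out


def crop_to_lift(recording: Recording, threshold_frac: float = 0.10) -> CropResult:
    """Crop to the lift-lower phase using the fingertip vertical excursion.

    The threshold is ``threshold_frac`` of the FN marker's total z range;
    the kept window spans the first through last sample whose FN z exceeds
    the starting value plus the threshold.
    """
    if not 0 < threshold_frac < 1:
        raise ValidationError("threshold_frac must lie in (0, 1)")
    fnz = recording.axis("FN", "z")
    rng = float(fnz.max() - fnz.min())
    if rng <= 0:
        raise DegenerateInputError(
            f"recording {recording.recording_id}: FN z-series is constant; crop threshold undefined")
    theta = threshold_frac * rng
    above = fnz > fnz[0] + theta
    if not above.any():
        raise NoMovementError(
            f"recording {recording.recording_id}: no sample exceeds the lift threshold")
    idx = np.flatnonzero(above)
    start, end = int(idx[0]), int(idx[-1])
    if end - start + 1 < 2:
        raise NoMovementError(
            f"recording {recording.recording_id}: lift window shorter than 2 samples")
    cropped = recording.copy()
    for m in MARKERS:
        cropped.markers[m] = cropped.markers[m][start:end + 1]
    return CropResult(start_index=start, end_index=end,
                      threshold_value=theta, cropped=cropped)


def _velocity(x: np.ndarray, rate: float) -> np.ndarray:
    # central differences in the interior, one-sided first differences at the ends
    return np.gradient(x) * rate


def _acceleration(x: np.ndarray, rate: float) -> np.ndarray:
    a = np.empty_like(x)
    a[1:-1] = x[2:] - 2 * x[1:-1] + x[:-2]
    a[0] = x[2] - 2 * x[1] + x[0]
    a[-1] = x[-1] - 2 * x[-2] + x[-3]
    return a * rate ** 2


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving-average smoother with edge truncation (optional step)."""
    if window < 2:
        return np.asarray(x, dtype=float).copy()
    kernel = np.ones(window) / window
    padded = np.pad(np.asarray(x, dtype=float), window // 2, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[window // 2: window // 2 + len(x)]
    return out


def derive_series(cropped: Recording, smoothing_window: int | None = None) -> DerivedSeriesSet:
    """Compute the 60 kinematic series from a cropped recording."""
    n = cropped.n_frames
    if n < 3:
        raise ValidationError("derive_series needs at least 3 samples for second differences")
    rate = cropped.sampling_rate_hz
    series: dict[str, np.ndarray] = {}
    for m in MARKERS:
        coords = {}
        for a in AXES:
            x = cropped.axis(m, a).astype(float)
            if smoothing_window:
                x = moving_average(x, smoothing_window)
            coords[a] = x
            series[f"{m}{a}"] = x
        disp = {a: coords[a] - coords[a][0] for a in AXES}
        vel = {a: _velocity(coords[a], rate) for a in AXES}
        acc = {a: _acceleration(coords[a], rate) for a in AXES}
        for a in AXES:
            series[f"{m}d{a}"] = disp[a]
            series[f"{m}v{a}"] = vel[a]
            series[f"{m}a{a}"] = acc[a]
        series[f"{m}D"] = np.sqrt(sum(disp[a] ** 2 for a in AXES))
        series[f"{m}V"] = np.sqrt(sum(vel[a] ** 2 for a in AXES))
        series[f"{m}A"] = np.sqrt(sum(acc[a] ** 2 for a in AXES))
    return DerivedSeriesSet(
        recording_id=cropped.recording_id,
        class_label=cropped.class_label,
        sampling_rate_hz=rate,
        series=series,
    )


def normalize_minmax(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """Min-max scale one series to [0, 1].

    Returns ``(scaled, is_constant)``; a constant series maps to all zeros
    with the flag set (decided convention).
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot normalize an empty series")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x), True
    return (x - lo) / (hi - lo), False


def normalize_series_set(dss: DerivedSeriesSet) -> DerivedSeriesSet:
    """Min-max normalize each of the 60 series independently."""
    out: dict[str, np.ndarray] = {}
    constants = []
    for name, x in dss.series.items():
        scaled, const = normalize_minmax(x)
        out[name] = scaled
        if const:
            constants.append(name)
    return DerivedSeriesSet(
        recording_id=dss.recording_id,
        class_label=dss.class_label,
        sampling_rate_hz=dss.sampling_rate_hz,
        series=out,
        normalized=True,
        constant_series=tuple(constants),
    )


def preprocess_recording(recording: Recording, threshold_frac: float = 0.10,
                         smoothing_window: int | None = None
                         ) -> tuple[DerivedSeriesSet, CropResult]:
    """Full preprocessing chain: reflect -> crop -> derive -> normalize."""
    unified = reflect_to_common_side(recording)
    crop = crop_to_lift(unified, threshold_frac)
    dss = derive_series(crop.cropped, smoothing_window=smoothing_window)
    return normalize_series_set(dss), crop
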