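"""Synthetic reach-lift-return cohorts with minimal-jerk kinematics.

The generator emulates the structure of a seated object-lifting task
recorded with an optical motion-capture system: four markers along the
upper-limb chain (fingernail FN, lateral epicondyle LEP, mid-humerus MPH,
acromion ACR) sampled at 100 Hz, each tracing a lift phase followed by a
return, with still rest frames before and after.  Point-to-point segments
follow the minimal-jerk law

    x(t) = x0 + (xf - x0) * (10 tau^3 - 15 tau^4 + 6 tau^5),  tau = t / T,

the standard model of smooth reaching: velocity is bell-shaped and zero at
both endpoints.  Amplitudes grade from distal to proximal (FN largest, ACR
smallest) and the vertical (z) axis dominates, mirroring an "as high as
possible" lift.

Class structure follows the three-class design of a post-stroke cohort:
G0 = non-affected post-stroke limb, G1 = affected limb, G2 = healthy
control limbs (both sides).  Inter-class differences are injected through
:class:`ClassEffect` entries — amplitude scaling, extra superimposed
submovements, or position noise that roughens the derivative signals —
chosen because they perturb exactly the displacement/velocity/acceleration
statistics the downstream relevance tests examine.

Coordinate convention: x = transverse (left/right), y = sagittal
(forward/backward), z = vertical (up/down); positions in meters, time in
seconds.  Right-limb recordings are generated with negated x so that the
preprocessing reflection step has real work to do.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import ACTIVITIES, AXES, CLASSES, MARKERS, Recording

EFFECT_KINDS = ("amplitude_scale", "submovement_count", "jerk_noise_sd")

#: peak per-axis excursion of the distal (FN) marker, meters
_AXIS_AMPLITUDE = {"x": 0.06, "y": 0.18, "z": 0.45}

#: approximate rest pose of a left upper limb, meters
_BASE_POSITION = {
    "ACR": (0.20, 0.00, 0.45),
    "MPH": (0.22, 0.05, 0.30),
    "LEP": (0.24, 0.12, 0.18),
    "FN": (0.30, 0.30, 0.05),
}

_SUBMOVEMENT_WIDTH_S = 0.15
_SUBMOVEMENT_REL_AMPLITUDE = 0.3

#: temporal correlation of measurement noise (Gaussian kernel sd, seconds).
#: Optical capture residuals are smooth — the system tracks and low-passes
#: marker centroids — so baseline noise is band-limited.  Unfiltered white
#: noise would be amplified by rate^2 under double differentiation and
#: drown every acceleration signal, which filtered capture output does not.
_NOISE_SMOOTH_S = 0.08


def _smooth_noise(rng: np.random.Generator, sd: float, n: int, rate: float) -> np.ndarray:
    """Band-limited Gaussian noise with marginal standard deviation ``sd``."""
    sig = max(_NOISE_SMOOTH_S * rate, 1e-9)
    half = int(np.ceil(4 * sig))
    t = np.arange(-half, half + 1)
    kernel = np.exp(-t ** 2 / (2 * sig ** 2))
    kernel /= kernel.sum()
    white = rng.normal(0.0, 1.0, n + kernel.size - 1)
    sm = np.convolve(white, kernel, mode="valid")
    return sm * (sd / np.sqrt(np.sum(kernel ** 2)))


@dataclass(frozen=True)
class ClassEffect:
    """A controlled kinematic difference applied to one class.

    ``amplitude_scale`` multiplies the movement amplitude of the targeted
    marker/axis by ``magnitude``; ``submovement_count`` superimposes
    ``round(magnitude)`` small minimal-jerk pulses during the movement;
    ``jerk_noise_sd`` adds white position noise of that standard deviation
    (meters) over the movement window, which dominates the differentiated
    (velocity/acceleration) signals.
    """

    target_class: str
    marker: str
    axis: str
    effect_kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.target_class not in CLASSES:
            raise ValidationError(f"unknown target_class {self.target_class!r}")
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}")
        if self.axis not in AXES:
            raise ValidationError(f"unknown axis {self.axis!r}")
        if self.effect_kind not in EFFECT_KINDS:
            raise ValidationError(f"unknown effect_kind {self.effect_kind!r}")
        if not self.magnitude >= 0:
            raise ValidationError("effect magnitude must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort- and trajectory-level parameters of the generator.

    Defaults reproduce the study conditions the pipeline assumes:
    35 post-stroke and 19 control participants, 3 recordings per limb,
    100 Hz sampling, and a distal-to-proximal amplitude gradation.
    """

    n_stroke_participants: int = 35
    n_control_participants: int = 19
    recordings_per_limb: int = 3
    sampling_rate_hz: float = 100.0
    movement_duration_s: float = 2.0
    marker_amplitude_scale: dict[str, float] = field(
        default_factory=lambda: {"FN": 1.0, "LEP": 0.7, "MPH": 0.4, "ACR": 0.15})
    rest_padding_s: float = 0.5
    noise_sd: float = 2e-4  # ~0.2 mm, typical optical mocap positional accuracy
    activity: str = "large_cylinder"
    class_effects: tuple[ClassEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stroke_participants < 0 or self.n_control_participants < 0:
            raise ValidationError("participant counts must be >= 0")
        if self.recordings_per_limb < 1:
            raise ValidationError("recordings_per_limb must be >= 1")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        if not self.movement_duration_s > 0:
            raise ValidationError("movement_duration_s must be positive")
        if not self.rest_padding_s >= 0:
            raise ValidationError("rest_padding_s must be >= 0")
        if not self.noise_sd >= 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.activity not in ACTIVITIES:
            raise ValidationError(f"unknown activity {self.activity!r}")
        for m in MARKERS:
            if not self.marker_amplitude_scale.get(m, 0) > 0:
                raise ValidationError(f"marker_amplitude_scale[{m}] must be positive")
        object.__setattr__(self, "class_effects", tuple(self.class_effects))
        for eff in self.class_effects:
            if eff.effect_kind == "amplitude_scale" and eff.magnitude <= 0:
                raise ValidationError("amplitude_scale effect must keep amplitudes positive")


def derive_seed(base_seed: int, *tokens: str) -> int:
    """Stable fan-out of a global seed to per-recording seeds (< 2**31).

    Hashing recording identity rather than enumeration order means that
    subsetting a cohort never shifts the noise of the remaining recordings.
    """
    h = zlib.crc32("|".join(str(t) for t in tokens).encode())
    return (int(base_seed) * 2654435761 + h) % (2 ** 31)


def minimal_jerk_profile(x0: float, xf: float, duration_s: float,
                         sampling_rate_hz: float) -> np.ndarray:
    """Minimal-jerk point-to-point position profile, endpoints included.

    Returns ``round(duration_s * rate) + 1`` samples running monotonically
    from ``x0`` to ``xf`` with zero endpoint velocity.
    """
    if not duration_s > 0:
        raise ValidationError("duration_s must be positive")
    if not sampling_rate_hz > 0:
        raise ValidationError("sampling_rate_hz must be positive")
    n = int(round(duration_s * sampling_rate_hz)) + 1
    tau = np.linspace(0.0, 1.0, n)
    s = 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5
    return x0 + (xf - x0) * s


def _lift_lower(amplitude: float, duration_s: float, rate: float) -> np.ndarray:
    """Minimal-jerk rise then return, sharing the apex sample."""
    half = duration_s / 2.0
    up = minimal_jerk_profile(0.0, amplitude, half, rate)
    down = minimal_jerk_profile(amplitude, 0.0, half, rate)
    return np.concatenate([up, down[1:]])


def _submovement_pulse(amplitude: float, width_s: float, rate: float) -> np.ndarray:
    half = width_s / 2.0
    up = minimal_jerk_profile(0.0, amplitude, half, rate)
    down = minimal_jerk_profile(amplitude, 0.0, half, rate)
    return np.concatenate([up, down[1:]])


def simulate_recording(config: SimulationConfig, class_label: str, participant_id: str,
                       side: str, seed: int, recording_id: str | None = None) -> Recording:
    """Generate one reach-lift-return recording.

    Deterministic in ``(config, class_label, participant_id, side, seed)``.
    """
    if class_label not in CLASSES:
        raise ValidationError(f"unknown class label {class_label!r}")
    if side not in ("left", "right"):
        raise ValidationError(f"unknown side {side!r}")
    rate = config.sampling_rate_hz
    rng = np.random.default_rng([int(seed) % (2 ** 31),
                                 zlib.crc32(participant_id.encode()),
                                 zlib.crc32(side.encode()),
                                 CLASSES.index(class_label)])

    n_pad = int(round(config.rest_padding_s * rate))
    move = _lift_lower(1.0, config.movement_duration_s, rate)  # unit template
    n_move = move.size
    n_total = n_move + 2 * n_pad
    move_slice = slice(n_pad, n_pad + n_move)

    effects = [e for e in config.class_effects if e.target_class == class_label]

    markers: dict[str, np.ndarray] = {}
    for marker in MARKERS:
        arr = np.empty((n_total, 3))
        # one amplitude-jitter factor per recording and axis; identically
        # distributed in every class, so the null cohort is exchangeable
        jitter = rng.uniform(0.85, 1.15, size=3)
        for ai, axis_name in enumerate(AXES):
            amp = (_AXIS_AMPLITUDE[axis_name]
                   * config.marker_amplitude_scale[marker] * jitter[ai])
            for eff in effects:
                if (eff.marker, eff.axis, eff.effect_kind) == (marker, axis_name, "amplitude_scale"):
                    amp *= eff.magnitude
            base = _BASE_POSITION[marker][ai]
            sig = np.full(n_total, base)
            sig[move_slice] += amp * move

            for eff in effects:
                if eff.marker != marker or eff.axis != axis_name:
                    continue
                if eff.effect_kind == "submovement_count":
                    k = int(round(eff.magnitude))
                    for _ in range(k):
                        pulse = _submovement_pulse(
                            _SUBMOVEMENT_REL_AMPLITUDE * max(abs(amp), 1e-6),
                            _SUBMOVEMENT_WIDTH_S, rate)
                        start_max = max(n_move - pulse.size, 1)
                        start = n_pad + int(rng.integers(0, start_max))
                        stop = min(start + pulse.size, n_total)
                        sig[start:stop] += pulse[:stop - start]
                elif eff.effect_kind == "jerk_noise_sd" and eff.magnitude > 0:
                    sig[move_slice] += rng.normal(0.0, eff.magnitude, n_move)

            if config.noise_sd > 0:
                sig += _smooth_noise(rng, config.noise_sd, n_total, rate)
            arr[:, ai] = sig
        markers[marker] = arr

    if side == "right":
        for arr in markers.values():
            arr[:, 0] *= -1.0

    return Recording(
        recording_id=recording_id or f"{participant_id}_{side}_{class_label}",
        participant_id=participant_id,
        class_label=class_label,
        side=side,
        activity=config.activity,
        sampling_rate_hz=rate,
        markers=markers,
    )


def simulate_cohort(config: SimulationConfig):
    """Generate a full cohort plus its manifest.

    Post-stroke participants contribute ``recordings_per_limb`` recordings
    per limb — the non-affected limb labeled G0, the affected limb G1 (the
    affected side alternates across participants).  Control participants
    contribute ``recordings_per_limb`` recordings per limb, all labeled G2.
    Returns ``(recordings, manifest)`` with the manifest as a DataFrame.
    """
    import pandas as pd

    recordings = []
    rows = []

    def add(class_label: str, participant_id: str, side: str, rep: int) -> None:
        rec_id = f"{participant_id}_{side}_r{rep + 1}"
        seed = derive_seed(config.seed, rec_id, class_label)
        rec = simulate_recording(config, class_label, participant_id, side, seed,
                                 recording_id=rec_id)
        recordings.append(rec)
        rows.append({
            "recording_id": rec_id, "path": f"{rec_id}.trc",
            "class_label": class_label, "participant_id": participant_id,
            "side": side, "activity": config.activity,
        })

    for i in range(config.n_stroke_participants):
        pid = f"S{i + 1:03d}"
        affected = "left" if i % 2 == 0 else "right"
        unaffected = "right" if affected == "left" else "left"
        for rep in range(config.recordings_per_limb):
            add("G0", pid, unaffected, rep)
        for rep in range(config.recordings_per_limb):
            add("G1", pid, affected, rep)
    for i in range(config.n_control_participants):
        pid = f"C{i + 1:03d}"
        for side in ("left", "right"):
            for rep in range(config.recordings_per_limb):
                add("G2", pid, side, rep)

    from .io import MANIFEST_COLUMNS, validate_manifest
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    if len(manifest):
        validate_manifest(manifest)
    return recordings, manifest
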