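"""Marker-trajectory recordings and cohort manifests: containers and file I/O.

A :class:`Recording` holds one limb's four-marker (FN, LEP, MPH, ACR)
3D position time series plus the metadata the downstream statistics need
(participant, class label, side, activity, sampling rate).  Recordings are
exchanged on disk either as TRC (the plain-text motion-capture interchange
dialect: tab-separated, ``PathFileType`` / ``DataRate`` header rows, one
X/Y/Z column triple per marker) or as a wide CSV with a two-line metadata
header.  A cohort manifest is a plain CSV table listing every recording
with its file path and labels.

Frames are 0-based internally; TRC's 1-based ``Frame#`` is converted at the
boundary.  Floats are written with 9 significant digits, so a write/read
round trip preserves coordinates to ~1e-9 relative accuracy.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MARKERS = ("FN", "LEP", "MPH", "ACR")
AXES = ("x", "y", "z")
CLASSES = ("G0", "G1", "G2")
SIDES = ("left", "right")
ACTIVITIES = ("large_cylinder", "small_cylinder", "drinking")

MANIFEST_COLUMNS = ("recording_id", "path", "class_label", "participant_id", "side", "activity")

_FLOAT_FMT = "%.9g"


@dataclass
class Recording:
    """One limb's marker trajectories for a single recorded activity.

    ``markers`` maps each marker name to an ``(n, 3)`` float array of x, y, z
    positions in meters, sampled at ``sampling_rate_hz``.  ``side_unified``
    marks a recording whose right-limb coordinates have already been
    reflected through the sagittal (yz) plane.
    """

    recording_id: str
    participant_id: str
    class_label: str
    side: str
    activity: str
    sampling_rate_hz: float
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    side_unified: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.class_label not in CLASSES:
            raise ValidationError(f"unknown class label {self.class_label!r}; expected one of {CLASSES}")
        if self.side not in SIDES:
            raise ValidationError(f"unknown side {self.side!r}; expected one of {SIDES}")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        missing = [m for m in MARKERS if m not in self.markers]
        if missing:
            raise ValidationError(f"recording {self.recording_id}: missing markers {missing}")
        lengths = set()
        for name in MARKERS:
            arr = np.asarray(self.markers[name], dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"marker {name}: expected an (n, 3) array, got shape {arr.shape}")
            self.markers[name] = arr
            lengths.add(arr.shape[0])
        if len(lengths) != 1:
            raise ValidationError(f"recording {self.recording_id}: marker series lengths differ: {sorted(lengths)}")
        if lengths.pop() < 2:
            raise ValidationError(f"recording {self.recording_id}: needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.markers[MARKERS[0]].shape[0]

    def copy(self) -> "Recording":
        return replace(self, markers={m: a.copy() for m, a in self.markers.items()})

    def axis(self, marker: str, axis: str) -> np.ndarray:
        """Return one coordinate series, e.g. ``axis('FN', 'z')``."""
        return self.markers[marker][:, AXES.index(axis)]


def allclose_recordings(a: Recording, b: Recording, rtol: float = 1e-8, atol: float = 1e-9) -> bool:
    if a.n_frames != b.n_frames or a.sampling_rate_hz != b.sampling_rate_hz:
        return False
    return all(np.allclose(a.markers[m], b.markers[m], rtol=rtol, atol=atol) for m in MARKERS)


# ---------------------------------------------------------------------------
# TRC

def write_recording(recording: Recording, path: str | Path, format: str = "trc") -> Path:
    """Write a recording to ``path`` in TRC or wide-CSV format."""
    path = Path(path)
    if format == "trc":
        text = _to_trc(recording, path.name)
    elif format == "csv":
        text = _to_csv(recording)
    else:
        raise ValidationError(f"unknown format {format!r}; expected 'trc' or 'csv'")
    try:
        path.write_text(text)
    except OSError as exc:
        raise IOError(f"cannot write recording to {path}: {exc}") from exc
    return path


def read_recording(path: str | Path, format: str = "trc", *, meta: dict | None = None) -> Recording:
    """Read a recording from TRC or wide CSV.

    TRC carries no cohort metadata; supply labels via ``meta`` (normally
    taken from the manifest row).  CSV files embed their own metadata header,
    which ``meta`` entries override.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise IOError(f"cannot read recording from {path}: {exc}") from exc
    if format == "trc":
        rate, markers = _parse_trc(text, str(path))
        fields = {
            "recording_id": path.stem,
            "participant_id": "",
            "class_label": "G2",
            "side": "left",
            "activity": ACTIVITIES[0],
        }
    elif format == "csv":
        rate, markers, fields = _parse_csv(text, str(path))
    else:
        raise ValidationError(f"unknown format {format!r}; expected 'trc' or 'csv'")
    if meta:
        fields.update({k: v for k, v in meta.items() if k in
                       {"recording_id", "participant_id", "class_label", "side", "activity"}})
    return Recording(sampling_rate_hz=rate, markers=markers, **fields)


def _to_trc(rec: Recording, filename: str) -> str:
    n = rec.n_frames
    rate = rec.sampling_rate_hz
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{filename}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{_FLOAT_FMT % rate}\t{_FLOAT_FMT % rate}\t{n}\t{len(MARKERS)}\tm\t{_FLOAT_FMT % rate}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(MARKERS) + "\t\t",
        "\t\t" + "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(len(MARKERS))),
        "",
    ]
    data = np.column_stack([rec.markers[m] for m in MARKERS])
    times = np.arange(n) / rate
    rows = []
    for i in range(n):
        vals = "\t".join(_FLOAT_FMT % v for v in data[i])
        rows.append(f"{i + 1}\t{_FLOAT_FMT % times[i]}\t{vals}")
    return "\n".join(lines + rows) + "\n"


def _parse_trc(text: str, source: str) -> tuple[float, dict[str, np.ndarray]]:
    lines = text.splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise FormatError(f"{source}: not a TRC file (missing PathFileType header)")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        rate = float(header["DataRate"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{source}: missing or invalid DataRate in TRC header") from exc
    marker_row = [t for t in lines[3].split("\t")[2:] if t]
    missing = [m for m in MARKERS if m not in marker_row]
    if missing:
        raise FormatError(f"{source}: TRC is missing marker(s) {missing}")
    order = marker_row
    data_rows = []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        try:
            data_rows.append([float(v) for v in parts[2:2 + 3 * len(order)]])
        except ValueError as exc:
            raise FormatError(f"{source}: unparseable TRC data row: {ln[:60]!r}") from exc
    arr = np.asarray(data_rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 * len(order):
        raise FormatError(f"{source}: ragged TRC data rows")
    markers = {m: arr[:, 3 * i:3 * i + 3] for i, m in enumerate(order) if m in MARKERS}
    return rate, markers


# ---------------------------------------------------------------------------
# wide CSV (metadata header + Frame,Time,FN_x..ACR_z)

_CSV_COORD_COLS = [f"{m}_{a}" for m in MARKERS for a in AXES]


def _to_csv(rec: Recording) -> str:
    buf = _io.StringIO()
    buf.write("recording_id,participant_id,class_label,side,activity,sampling_rate_hz\n")
    buf.write(f"{rec.recording_id},{rec.participant_id},{rec.class_label},"
              f"{rec.side},{rec.activity},{_FLOAT_FMT % rec.sampling_rate_hz}\n")
    n = rec.n_frames
    df = pd.DataFrame(
        np.column_stack([rec.markers[m] for m in MARKERS]),
        columns=_CSV_COORD_COLS,
    )
    df.insert(0, "time", np.arange(n) / rec.sampling_rate_hz)
    df.insert(0, "frame", np.arange(n))
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    return buf.getvalue()


def _parse_csv(text: str, source: str) -> tuple[float, dict[str, np.ndarray], dict]:
    lines = text.splitlines()
    if len(lines) < 4:
        raise FormatError(f"{source}: truncated recording CSV")
    meta_keys = lines[0].split(",")
    meta_vals = lines[1].split(",")
    meta = dict(zip(meta_keys, meta_vals))
    try:
        rate = float(meta["sampling_rate_hz"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{source}: missing sampling_rate_hz metadata row") from exc
    df = pd.read_csv(_io.StringIO("\n".join(lines[2:])))
    missing_markers = sorted({c.split("_")[0] for c in _CSV_COORD_COLS if c not in df.columns})
    if missing_markers:
        raise FormatError(f"{source}: CSV is missing marker column(s) for {missing_markers}")
    if df[_CSV_COORD_COLS].isna().any().any():
        raise FormatError(f"{source}: ragged/missing values in coordinate columns")
    markers = {m: df[[f"{m}_{a}" for a in AXES]].to_numpy(dtype=float) for m in MARKERS}
    fields = {
        "recording_id": meta.get("recording_id", Path(source).stem),
        "participant_id": meta.get("participant_id", ""),
        "class_label": meta.get("class_label", "G2"),
        "side": meta.get("side", "left"),
        "activity": meta.get("activity", ACTIVITIES[0]),
    }
    return rate, markers, fields


# ---------------------------------------------------------------------------
# cohort manifest

def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValidationError(f"manifest missing column(s) {missing}")
    if manifest["recording_id"].duplicated().any():
        dups = manifest.loc[manifest["recording_id"].duplicated(), "recording_id"].tolist()
        raise ValidationError(f"duplicate recording_id(s) in manifest: {dups[:5]}")
    bad = sorted(set(manifest["class_label"]) - set(CLASSES))
    if bad:
        raise ValidationError(f"unknown class label(s) in manifest: {bad}")
    return manifest


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    validate_manifest(manifest)
    path = Path(path)
    manifest.loc[:, list(MANIFEST_COLUMNS)].to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), dtype=str).fillna("")
    return validate_manifest(df)


def class_counts(manifest: pd.DataFrame) -> dict[str, int]:
    """Number of recordings per class, e.g. ``{'G0': 105, 'G1': 105, 'G2': 114}``."""
    counts = manifest["class_label"].value_counts().to_dict()
    return {c: int(counts.get(c, 0)) for c in CLASSES}


def write_cohort(recordings: list[Recording], directory: str | Path, format: str = "trc") -> pd.DataFrame:
    """Write every recording plus a ``manifest.csv`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        fname = f"{rec.recording_id}.{format}"
        write_recording(rec, directory / fname, format=format)
        rows.append({
            "recording_id": rec.recording_id, "path": fname,
            "class_label": rec.class_label, "participant_id": rec.participant_id,
            "side": rec.side, "activity": rec.activity,
        })
    manifest = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    write_manifest(manifest, directory / "manifest.csv")
    return manifest


def load_cohort(manifest_path: str | Path) -> tuple[list[Recording], pd.DataFrame]:
    """Load all recordings listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    recordings = []
    for row in manifest.itertuples(index=False):
        fmt = Path(row.path).suffix.lstrip(".").lower() or "trc"
        rec = read_recording(base / row.path, format=fmt, meta={
            "recording_id": row.recording_id, "participant_id": row.participant_id,
            "class_label": row.class_label, "side": row.side, "activity": row.activity,
        })
        recordings.append(rec)
    return recordings, manifest
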