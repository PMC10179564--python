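"""Scalar feature extraction: map each kinematic series to named statistics.

Every feature is a pure, deterministic function of a single series,
returning a real value (or exactly 0/1 for binary features); undefined
cases (e.g. autocorrelation of a constant series) yield NaN, which is kept
and flagged rather than dropped.  The core catalog fixes ~40 features per
series by explicit formula; :func:`reference_catalog` extends it with
deterministic parameter grids to any requested dimensionality, matching
the large systematic catalogs used for FRESH-style relevance testing.

Conventions pinned here (and in the tests):

* population (biased) moments inside skewness, kurtosis (excess), and
  autocorrelation;
* ``autocorrelation(lag)`` is the standard ACF estimator
  ``sum((x_i - mean)(x_{i+lag} - mean)) / (n * var_pop)``;
* relative locations of extrema lie in [0, 1] with first occurrence at
  ``argmax/n`` and last at ``1 - argmax(reversed)/n``.

Column identifiers are flat strings ``"<series>__<feature>"`` so the
matrix round-trips through CSV without a hierarchical header.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .preprocess import SERIES_NAMES, DerivedSeriesSet

COLUMN_SEP = "__"

REAL = "real"
BINARY = "binary"


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    func: Callable[[np.ndarray], float]
    value_kind: str = REAL


def _moments(x: np.ndarray):
    mu = x.mean()
    d = x - mu
    return mu, d


def _f_mean(x): return float(x.mean())
def _f_median(x): return float(np.median(x))
def _f_std(x): return float(x.std())
def _f_var(x): return float(x.var())
def _f_max(x): return float(x.max())
def _f_min(x): return float(x.min())
def _f_abs_energy(x): return float(np.dot(x, x))
def _f_rms(x): return float(np.sqrt(np.mean(x * x)))


def _f_mean_abs_change(x):
    if x.size < 2:
        return float("nan")
    return float(np.mean(np.abs(np.diff(x))))


def _f_mean_change(x):
    if x.size < 2:
        return float("nan")
    return float((x[-1] - x[0]) / (x.size - 1))


def _f_skewness(x):
    mu, d = _moments(x)
    m2 = np.mean(d ** 2)
    if m2 == 0:
        return float("nan")
    return float(np.mean(d ** 3) / m2 ** 1.5)


def _f_kurtosis(x):
    mu, d = _moments(x)
    m2 = np.mean(d ** 2)
    if m2 == 0:
        return float("nan")
    return float(np.mean(d ** 4) / m2 ** 2 - 3.0)


def _f_autocorrelation(lag):
    def f(x, lag=lag):
        n = x.size
        if n <= lag:
            return float("nan")
        mu, d = _moments(x)
        var = np.mean(d ** 2)
        if var == 0:
            return float("nan")
        return float(np.sum(d[:n - lag] * d[lag:]) / (n * var))
    return f


def _f_number_of_peaks(support):
    def f(x, support=support):
        n = x.size
        if n < 2 * support + 1:
            return 0.0
        count = 0
        for i in range(support, n - support):
            xi = x[i]
            if all(xi > x[i - k] and xi > x[i + k] for k in range(1, support + 1)):
                count += 1
        return float(count)
    return f


def _f_count_above_mean(x): return float(np.sum(x > x.mean()))
def _f_count_below_mean(x): return float(np.sum(x < x.mean()))


def _f_longest_strike_above_mean(x):
    above = x > x.mean()
    best = run = 0
    for flag in above:
        run = run + 1 if flag else 0
        best = max(best, run)
    return float(best)


def _f_first_loc_max(x): return float(np.argmax(x) / x.size)
def _f_last_loc_max(x): return float(1.0 - np.argmax(x[::-1]) / x.size)
def _f_first_loc_min(x): return float(np.argmin(x) / x.size)
def _f_last_loc_min(x): return float(1.0 - np.argmin(x[::-1]) / x.size)


def _f_quantile(q):
    def f(x, q=q):
        return float(np.quantile(x, q))
    return f


def _f_fft_magnitude(k):
    def f(x, k=k):
        coeffs = np.fft.rfft(x)
        if k >= coeffs.size:
            return float("nan")
        return float(np.abs(coeffs[k]))
    return f


def _f_c3(lag):
    def f(x, lag=lag):
        n = x.size
        if n <= 2 * lag:
            return float("nan")
        return float(np.mean(x[2 * lag:] * x[lag:n - lag] * x[:n - 2 * lag]))
    return f


def _f_cid_ce(x):
    return float(np.sqrt(np.sum(np.diff(x) ** 2)))


def _f_has_duplicate(x):
    return float(np.unique(x).size < x.size)


def _f_has_duplicate_max(x):
    return float(np.sum(x == x.max()) >= 2)


def _f_has_duplicate_min(x):
    return float(np.sum(x == x.min()) >= 2)


def _f_large_std(r):
    def f(x, r=r):
        return float(x.std() > r * (x.max() - x.min()))
    return f


def _f_symmetry_looking(r):
    def f(x, r=r):
        return float(abs(x.mean() - np.median(x)) < r * (x.max() - x.min()))
    return f


def core_catalog() -> list[FeatureDefinition]:
    """The fixed core feature set: 36 real + 6 binary features."""
    defs: list[FeatureDefinition] = [
        FeatureDefinition("mean", _f_mean),
        FeatureDefinition("median", _f_median),
        FeatureDefinition("standard_deviation", _f_std),
        FeatureDefinition("variance", _f_var),
        FeatureDefinition("maximum", _f_max),
        FeatureDefinition("minimum", _f_min),
        FeatureDefinition("abs_energy", _f_abs_energy),
        FeatureDefinition("root_mean_square", _f_rms),
        FeatureDefinition("mean_abs_change", _f_mean_abs_change),
        FeatureDefinition("mean_change", _f_mean_change),
        FeatureDefinition("skewness", _f_skewness),
        FeatureDefinition("kurtosis", _f_kurtosis),
    ]
    for lag in (1, 2, 5, 10):
        defs.append(FeatureDefinition(f"autocorrelation_lag{lag}", _f_autocorrelation(lag)))
    for support in (1, 3):
        defs.append(FeatureDefinition(f"number_of_peaks_n{support}", _f_number_of_peaks(support)))
    defs += [
        FeatureDefinition("count_above_mean", _f_count_above_mean),
        FeatureDefinition("count_below_mean", _f_count_below_mean),
        FeatureDefinition("longest_strike_above_mean", _f_longest_strike_above_mean),
        FeatureDefinition("first_location_of_maximum", _f_first_loc_max),
        FeatureDefinition("last_location_of_maximum", _f_last_loc_max),
        FeatureDefinition("first_location_of_minimum", _f_first_loc_min),
        FeatureDefinition("last_location_of_minimum", _f_last_loc_min),
    ]
    for q in (0.1, 0.25, 0.75, 0.9):
        defs.append(FeatureDefinition(f"quantile_q{q}", _f_quantile(q)))
    for k in range(1, 6):
        defs.append(FeatureDefinition(f"fft_coefficient_magnitude_k{k}", _f_fft_magnitude(k)))
    defs += [
        FeatureDefinition("c3_lag1", _f_c3(1)),
        FeatureDefinition("cid_ce", _f_cid_ce),
        FeatureDefinition("has_duplicate", _f_has_duplicate, BINARY),
        FeatureDefinition("has_duplicate_max", _f_has_duplicate_max, BINARY),
        FeatureDefinition("has_duplicate_min", _f_has_duplicate_min, BINARY),
        FeatureDefinition("large_standard_deviation_r0.25", _f_large_std(0.25), BINARY),
        FeatureDefinition("large_standard_deviation_r0.35", _f_large_std(0.35), BINARY),
        FeatureDefinition("symmetry_looking_r0.25", _f_symmetry_looking(0.25), BINARY),
    ]
    names = [d.name for d in defs]
    assert len(names) == len(set(names))
    return defs


def _extension_definitions():
    """Deterministic stream of extra parameterized features (no duplicates
    with the core catalog), used to reach a target catalog size."""
    for lag in range(11, 211):
        yield FeatureDefinition(f"autocorrelation_lag{lag}", _f_autocorrelation(lag))
    for k in range(6, 106):
        yield FeatureDefinition(f"fft_coefficient_magnitude_k{k}", _f_fft_magnitude(k))
    for qi in range(1, 100):
        q = qi / 100
        if q in (0.1, 0.25, 0.75, 0.9):
            continue
        yield FeatureDefinition(f"quantile_q{q}", _f_quantile(q))
    for lag in range(2, 102):
        yield FeatureDefinition(f"c3_lag{lag}", _f_c3(lag))
    for support in range(2, 102):
        if support == 3:
            continue
        yield FeatureDefinition(f"number_of_peaks_n{support}", _f_number_of_peaks(support))
    for ri in range(1, 100):
        r = ri / 100
        if r in (0.25, 0.35):
            continue
        yield FeatureDefinition(f"large_standard_deviation_r{r}", _f_large_std(r), BINARY)
    for ri in range(1, 100):
        r = ri / 100
        if r == 0.25:
            continue
        yield FeatureDefinition(f"symmetry_looking_r{r}", _f_symmetry_looking(r), BINARY)


def reference_catalog(size: int = 794) -> list[FeatureDefinition]:
    """Core catalog extended with parameter grids up to ``size`` features.

    ``size`` defaults to the dimensionality of the large systematic
    reference catalog (794 features per series, hence 47,640 per
    recording), which the package treats as a configuration constant.
    """
    core = core_catalog()
    if size < len(core):
        raise ValidationError(f"catalog size must be >= the {len(core)} core features")
    defs = list(core)
    for d in _extension_definitions():
        if len(defs) >= size:
            break
        defs.append(d)
    if len(defs) < size:
        raise ValidationError(f"cannot build a catalog of size {size}; "
                              f"only {len(defs)} definitions available")
    return defs


def get_catalog(selector: str | int = "core") -> list[FeatureDefinition]:
    """Resolve a catalog selector: ``"core"``, ``"reference"``, or an int size."""
    if selector == "core":
        return core_catalog()
    if selector == "reference":
        return reference_catalog()
    if isinstance(selector, int):
        return reference_catalog(selector)
    raise ValidationError(f"unknown catalog selector {selector!r}")


def compute_feature(definition: FeatureDefinition, series: np.ndarray) -> float:
    """Evaluate one feature on one series (NaN = explicitly undefined)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot compute a feature of an empty series")
    if not np.isfinite(x).all():
        raise ValidationError("series contains non-finite values")
    value = definition.func(x)
    if definition.value_kind == BINARY and not np.isnan(value):
        assert value in (0.0, 1.0)
    return value


def column_id(series_name: str, feature_name: str) -> str:
    return f"{series_name}{COLUMN_SEP}{feature_name}"


def split_column_id(cid: str) -> tuple[str, str]:
    series_name, _, feature_name = cid.partition(COLUMN_SEP)
    if not feature_name:
        raise SchemaError(f"malformed feature column id {cid!r}")
    return series_name, feature_name


def extract_features(series_set: DerivedSeriesSet,
                     catalog: list[FeatureDefinition]) -> pd.Series:
    """One recording's feature vector: length ``60 * len(catalog)``."""
    values = {}
    for sname in SERIES_NAMES:
        if sname not in series_set.series:
            raise SchemaError(f"series {sname!r} missing from the derived set")
        x = np.asarray(series_set.series[sname], dtype=float)
        for d in catalog:
            values[column_id(sname, d.name)] = compute_feature(d, x)
    return pd.Series(values, name=series_set.recording_id)


@dataclass
class FeatureMatrix:
    """Recordings x (series, feature) matrix with per-column typing.

    ``values`` is indexed by recording_id in manifest order; ``value_kinds``
    maps each column to ``"real"`` or ``"binary"``.  Constant and all-NaN
    columns are flagged, never silently dropped.
    """

    values: pd.DataFrame
    value_kinds: dict[str, str]
    class_labels: pd.Series
    flagged_constant: tuple[str, ...] = field(default_factory=tuple)
    flagged_all_nan: tuple[str, ...] = field(default_factory=tuple)

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def build_feature_matrix(series_sets: list[DerivedSeriesSet],
                         catalog: list[FeatureDefinition],
                         manifest: pd.DataFrame) -> FeatureMatrix:
    """Extract features for a preprocessed cohort, rows in manifest order."""
    by_id = {s.recording_id: s for s in series_sets}
    manifest_ids = list(manifest["recording_id"])
    missing = [rid for rid in manifest_ids if rid not in by_id]
    extra = [s.recording_id for s in series_sets if s.recording_id not in set(manifest_ids)]
    if missing or extra:
        raise ValidationError(
            f"manifest/recording mismatch (missing={missing[:3]}, unlisted={extra[:3]})")
    rows = [extract_features(by_id[rid], catalog) for rid in manifest_ids]
    values = pd.DataFrame(rows)
    values.index = pd.Index(manifest_ids, name="recording_id")
    kinds = {column_id(s, d.name): d.value_kind for s in SERIES_NAMES for d in catalog}
    labels = pd.Series(list(manifest["class_label"]), index=values.index, name="class_label")

    arr = values.to_numpy()
    all_nan = np.isnan(arr).all(axis=0)
    with np.errstate(invalid="ignore"):
        constant = np.array([np.nanmin(col) == np.nanmax(col) if not np.isnan(col).all() else False
                             for col in arr.T])
    cols = np.asarray(values.columns)
    return FeatureMatrix(
        values=values,
        value_kinds=kinds,
        class_labels=labels,
        flagged_constant=tuple(cols[constant]),
        flagged_all_nan=tuple(cols[all_nan]),
    )


def write_feature_matrix(matrix: FeatureMatrix, csv_path, meta_path=None) -> None:
    """Serialize as wide CSV plus a sidecar JSON of column metadata."""
    import json
    from pathlib import Path

    csv_path = Path(csv_path)
    out = matrix.values.copy()
    out.insert(0, "class_label", matrix.class_labels)
    out.to_csv(csv_path, float_format="%.12g")
    meta = {
        "columns": [
            {"column_id": c, "series_name": split_column_id(c)[0],
             "feature_name": split_column_id(c)[1], "value_kind": matrix.value_kinds[c]}
            for c in matrix.values.columns
        ],
        "flagged_constant": list(matrix.flagged_constant),
        "flagged_all_nan": list(matrix.flagged_all_nan),
    }
    meta_path = Path(meta_path) if meta_path else csv_path.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1))
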