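"""Aggregate significant features by marker, axis, and signal domain.

Every feature column descends from one of the 60 kinematic series, and
every series name maps deterministically to a taxon (marker, domain,
axis): ``MPHax`` -> (MPH, acceleration, x); module series such as ``FNV``
are counted under their kinematic domain with axis = "module" — exactly
how the wide report grid organizes its Module column (A/V/D sub-rows per
marker).  Counts are aggregated into a (marker x domain x axis) tensor
with marginals by marker, axis, and domain, and exported both tidy (long)
and in the wide grid layout used for cross-study comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError
from .features import FeatureMatrix, split_column_id
from .io import MARKERS
from .preprocess import SERIES_NAMES
from .selection import CommonFeatureSet

DOMAINS = ("trajectory", "displacement", "velocity", "acceleration")
AXIS_CATEGORIES = ("x", "y", "z", "module")


@dataclass(frozen=True)
class SeriesTaxon:
    marker: str
    domain: str
    axis: str


_NAME_RE = re.compile(r"^(ACR|MPH|LEP|FN)(x|y|z|dx|dy|dz|D|vx|vy|vz|V|ax|ay|az|A)$")

_SUFFIX_TAXON = {
    "x": ("trajectory", "x"), "y": ("trajectory", "y"), "z": ("trajectory", "z"),
    "dx": ("displacement", "x"), "dy": ("displacement", "y"), "dz": ("displacement", "z"),
    "D": ("displacement", "module"),
    "vx": ("velocity", "x"), "vy": ("velocity", "y"), "vz": ("velocity", "z"),
    "V": ("velocity", "module"),
    "ax": ("acceleration", "x"), "ay": ("acceleration", "y"), "az": ("acceleration", "z"),
    "A": ("acceleration", "module"),
}


def classify_series_name(series_name: str) -> SeriesTaxon:
    """Map a series name to its (marker, domain, axis) taxon."""
    m = _NAME_RE.match(series_name)
    if not m:
        raise SchemaError(f"unknown series name {series_name!r}")
    marker, suffix = m.group(1), m.group(2)
    domain, axis = _SUFFIX_TAXON[suffix]
    return SeriesTaxon(marker=marker, domain=domain, axis=axis)


def _empty_cells() -> pd.Series:
    idx = pd.MultiIndex.from_tuples(
        [(t.marker, t.domain, t.axis) for t in map(classify_series_name, SERIES_NAMES)],
        names=["marker", "domain", "axis"])
    return pd.Series(0, index=idx, dtype=int)


@dataclass
class AggregationReport:
    """Count tensor over (marker, domain, axis) with its marginals."""

    cells: pd.Series  # full 60-cell MultiIndex, zeros included

    @classmethod
    def from_series_counts(cls, counts: Mapping[str, int]) -> "AggregationReport":
        """Build from per-series counts, e.g. ``{"MPHax": 34, ...}``."""
        cells = _empty_cells()
        for name, count in counts.items():
            t = classify_series_name(name)
            cells.loc[(t.marker, t.domain, t.axis)] += int(count)
        return cls(cells=cells)

    @classmethod
    def from_column_ids(cls, column_ids: Iterable[str]) -> "AggregationReport":
        """Build from feature column ids (``"<series>__<feature>"``)."""
        counts: dict[str, int] = {}
        for cid in column_ids:
            sname, _ = split_column_id(cid)
            classify_series_name(sname)  # raises SchemaError on unknown names
            counts[sname] = counts.get(sname, 0) + 1
        return cls.from_series_counts(counts)

    @property
    def grand_total(self) -> int:
        return int(self.cells.sum())

    @property
    def marker_totals(self) -> dict[str, int]:
        s = self.cells.groupby(level="marker").sum()
        return {m: int(s.get(m, 0)) for m in MARKERS}

    @property
    def axis_totals(self) -> dict[str, int]:
        s = self.cells.groupby(level="axis").sum()
        return {a: int(s.get(a, 0)) for a in AXIS_CATEGORIES}

    @property
    def domain_totals(self) -> dict[str, int]:
        s = self.cells.groupby(level="domain").sum()
        return {d: int(s.get(d, 0)) for d in DOMAINS}

    def to_long(self) -> pd.DataFrame:
        df = self.cells.reset_index()
        df.columns = ["marker", "domain", "axis", "count"]
        return df

    def to_wide(self) -> pd.DataFrame:
        """Wide grid: one marker x sub-row block, Module column split A/V/D,
        plus trajectory/acceleration/velocity/displacement x (x, y, z)."""
        module_rows = {"acceleration": "A", "velocity": "V", "displacement": "D"}
        rows = []
        for marker in MARKERS:
            for i, (mod_domain, mod_code) in enumerate(module_rows.items()):
                axis = ("x", "y", "z")[i]
                rows.append({
                    "marker": marker,
                    "module": int(self.cells.loc[(marker, mod_domain, "module")]),
                    "module_kind": mod_code,
                    "trajectory": int(self.cells.loc[(marker, "trajectory", axis)]),
                    "acceleration": int(self.cells.loc[(marker, "acceleration", axis)]),
                    "velocity": int(self.cells.loc[(marker, "velocity", axis)]),
                    "displacement": int(self.cells.loc[(marker, "displacement", axis)]),
                    "axis": axis.upper(),
                })
        return pd.DataFrame(rows)

    def top_cell(self) -> tuple[str, str, str]:
        """(marker, domain, axis) of the largest cell (first on ties)."""
        return tuple(self.cells.idxmax())


def aggregate_counts(common: CommonFeatureSet | Iterable[str]) -> AggregationReport:
    """Aggregate a common-feature set (or iterable of column ids)."""
    ids = common.common if isinstance(common, CommonFeatureSet) else common
    return AggregationReport.from_column_ids(ids)


def feature_class_summary(matrix: FeatureMatrix, column_id: str) -> pd.DataFrame:
    """Five-number summary (min, q1, median, q3, max) per class for one column."""
    if column_id not in matrix.values.columns:
        raise SchemaError(f"feature column {column_id!r} not in the matrix")
    v = matrix.values[column_id]
    rows = []
    for cls, grp in v.groupby(matrix.class_labels):
        vals = grp.dropna().to_numpy()
        if vals.size == 0:
            rows.append({"class_label": cls, "n": 0, "min": np.nan, "q1": np.nan,
                         "median": np.nan, "q3": np.nan, "max": np.nan})
            continue
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        rows.append({"class_label": cls, "n": int(vals.size),
                     "min": float(vals.min()), "q1": float(q1), "median": float(med),
                     "q3": float(q3), "max": float(vals.max())})
    return pd.DataFrame(rows)


def export_report(report: AggregationReport, common: CommonFeatureSet | None,
                  matrix: FeatureMatrix | None, out_dir,
                  summary_features: Iterable[str] | None = None) -> dict[str, Path]:
    """Write the aggregation grids (wide + long + marginals) and optional
    per-feature class summaries; returns the written paths."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        wide = out_dir / "report_wide.csv"
        report.to_wide().to_csv(wide, index=False)
        paths["wide"] = wide
        long = out_dir / "report_long.csv"
        report.to_long().to_csv(long, index=False)
        paths["long"] = long
        marg = out_dir / "report_marginals.csv"
        rows = ([{"margin": "marker", "level": k, "count": v} for k, v in report.marker_totals.items()]
                + [{"margin": "axis", "level": k, "count": v} for k, v in report.axis_totals.items()]
                + [{"margin": "domain", "level": k, "count": v} for k, v in report.domain_totals.items()]
                + [{"margin": "total", "level": "all", "count": report.grand_total}])
        pd.DataFrame(rows).to_csv(marg, index=False)
        paths["marginals"] = marg
        if common is not None:
            for cls, tbl in common.per_problem.items():
                p = out_dir / f"relevance_{cls}.csv"
                tbl.table.to_csv(p, index=False)
                paths[f"relevance_{cls}"] = p
            p = out_dir / "common_features.csv"
            pd.DataFrame({"column_id": sorted(common.common)}).to_csv(p, index=False)
            paths["common"] = p
        if matrix is not None and summary_features:
            frames = []
            for cid in summary_features:
                df = feature_class_summary(matrix, cid)
                df.insert(0, "column_id", cid)
                frames.append(df)
            p = out_dir / "feature_class_summaries.csv"
            pd.concat(frames, ignore_index=True).to_csv(p, index=False)
            paths["summaries"] = p
        return paths
    except OSError as exc:
        raise IOError(f"cannot write report files under {out_dir}: {exc}") from exc
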