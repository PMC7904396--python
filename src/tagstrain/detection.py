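"""Infarct detection from segmental circumferential-strain series.

Two-stage rule, applied per left ventricle (16 AHA segments across the
basal, midventricular and apical slices):

1. *Benchmark flagging.*  The median end-systolic circumferential strain
   of a segment, ES_calculated = Med(CS at ES), is compared with a
   literature benchmark of healthy end-systolic CS per slice and sector.
   A segment whose shortening magnitude falls below the benchmark mean
   magnitude (|ES_calculated| < |ES_literature|, both negative by
   convention) is flagged "potentially infarcted".

2. *Infarction Condition.*  For every segment the H-spread — the
   interquartile range of the per-frame segment-median CS values from
   end-diastole to end-systole — is computed.  A flagged segment is
   declared infarcted when its H-spread is reduced by at least alpha %
   relative to the mean H-spread of the unflagged ("remaining") segments
   of the same slice; if a slice has no unflagged segment, the unflagged
   segments of the whole LV serve as the reference.  Slice-specific
   defaults are alpha = 30 (basal), 30 (mid), 20 (apical).

Akinetic (fibrotic) myocardium neither shortens nor lengthens, so its
per-frame median CS barely moves and its H-spread collapses — the
reduction percentage is the detection score.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strain import SEGMENT_NAMES, SLICE_SEGMENT_IDS, AHASegmentation, StrainField

__all__ = [
    "SegmentSeries",
    "BenchmarkTable",
    "SegmentResult",
    "DetectionReport",
    "DEFAULT_ALPHAS",
    "hspread",
    "flag_potential",
    "healthy_reference",
    "classify",
    "build_segment_series",
]

#: calibrated H-spread reduction thresholds (percent) per slice level
DEFAULT_ALPHAS = {"basal": 30.0, "midventricular": 30.0, "apical": 20.0}

_SLICE_OF_SEGMENT = {
    sid: lvl for lvl, ids in SLICE_SEGMENT_IDS.items() for sid in ids
}


@dataclass
class SegmentSeries:
    """Per-frame median circumferential strain of one AHA segment.

    ``s_f[i]`` is Med(CS) over the segment's valid pixels at frame ``i``
    (ED..ES); the end-systolic value is the last element.
    """

    segment_id: int
    slice_level: str
    s_f: np.ndarray
    n_pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s_f = np.asarray(self.s_f, dtype=float)
        if self.s_f.ndim != 1 or len(self.s_f) < 2:
            raise ValueError("s_f must hold at least 2 frames (ED..ES)")

    @property
    def es_calculated(self) -> float:
        """Median end-systolic CS (last frame)."""
        return float(self.s_f[-1])


class BenchmarkTable:
    """Healthy end-systolic CS benchmarks (mean, SD) per slice and sector.

    Ships with literature values for the six wall sectors of each slice
    level.  The apical slice of the 16-segment model has only 4 segments;
    its 'septal' entry is the mean of the antero-/inferoseptal columns and
    'lateral' the mean of the antero-/inferolateral columns (lossless here
    because the paired columns are equal).
    """

    _APICAL_MERGE = {
        "septal": ("anteroseptal", "inferoseptal"),
        "lateral": ("anterolateral", "inferolateral"),
    }

    def __init__(self, table: pd.DataFrame):
        required = {"slice_level", "sector", "mean", "sd"}
        if not required.issubset(table.columns):
            raise ValueError(f"benchmark table needs columns {sorted(required)}")
        if (table["mean"] >= 0).any():
            raise ValueError("benchmark means must be negative (shortening)")
        if (table["sd"] <= 0).any():
            raise ValueError("benchmark SDs must be positive")
        self._table = table.set_index(["slice_level", "sector"]).sort_index()

    @classmethod
    def default(cls) -> "BenchmarkTable":
        path = importlib.resources.files("tagstrain.data") / "benchmark_cs.csv"
        with importlib.resources.as_file(path) as p:
            return cls(pd.read_csv(p))

    @classmethod
    def from_csv(cls, path) -> "BenchmarkTable":
        return cls(pd.read_csv(path))

    def lookup(self, slice_level: str, sector: str) -> tuple[float, float]:
        """(mean, sd) of healthy end-systolic CS for a slice/sector."""
        merge = self._APICAL_MERGE.get(sector) if slice_level == "apical" else None
        if merge is not None:
            vals = [self._table.loc[(slice_level, s)] for s in merge]
            return (
                float(np.mean([v["mean"] for v in vals])),
                float(np.mean([v["sd"] for v in vals])),
            )
        try:
            row = self._table.loc[(slice_level, sector)]
        except KeyError as exc:
            raise KeyError(f"no benchmark for {slice_level}/{sector}") from exc
        return float(row["mean"]), float(row["sd"])

    def lookup_segment(self, segment_id: int) -> tuple[float, float]:
        return self.lookup(_SLICE_OF_SEGMENT[segment_id], SEGMENT_NAMES[segment_id])


@dataclass
class SegmentResult:
    """Classification outcome for one AHA segment."""

    segment_id: int
    slice_level: str
    es_calculated: float
    potentially_infarcted: bool
    h_spread: float
    h_reference: float = float("nan")
    reference_source: str = ""
    reduction_pct: float = 0.0
    infarcted: bool = False
    alpha: float = float("nan")


@dataclass
class DetectionReport:
    """Per-LV detection outcome: one SegmentResult per AHA segment."""

    segments: dict[int, SegmentResult]
    alphas: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def infarcted_ids(self) -> list[int]:
        return sorted(s.segment_id for s in self.segments.values() if s.infarcted)

    @property
    def flagged_ids(self) -> list[int]:
        return sorted(
            s.segment_id for s in self.segments.values() if s.potentially_infarcted
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.segments.values()]).set_index(
            "segment_id"
        )


# -- core statistics ----------------------------------------------------------


def hspread(values: np.ndarray | SegmentSeries) -> float:
    """Interquartile range (H-spread) of per-frame segment-median strains.

    Quartiles use linear interpolation of the order statistics; for a
    constant series the spread is exactly 0.  E.g. hspread((1, 2, 3, 4))
    = 3.25 - 1.75 = 1.5.
    """
    if isinstance(values, SegmentSeries):
        values = values.s_f
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("H-spread needs at least 2 valid frame medians")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    return float(q3 - q1)


def flag_potential(
    series: SegmentSeries, benchmarks: BenchmarkTable, margin_sd: float = 0.0
) -> bool:
    """Benchmark flagging: shortening magnitude below the healthy benchmark.

    Flags the segment when |ES_calculated| < |mean| - margin_sd * SD with a
    strict inequality (both values negative by convention; ``margin_sd``
    defaults to 0 so only the benchmark mean enters the rule).
    """
    es = series.es_calculated
    if not np.isfinite(es):
        raise ValueError(f"segment {series.segment_id}: ES_calculated not finite")
    mean, sd = benchmarks.lookup_segment(series.segment_id)
    return bool(abs(es) < abs(mean) - margin_sd * sd)


def healthy_reference(
    all_series: dict[int, SegmentSeries], flags: dict[int, bool]
) -> tuple[dict[int, tuple[float, str]], list[str]]:
    """Mean healthy H-spread reference for every flagged segment.

    For a flagged segment the reference is the arithmetic mean H-spread of
    the *unflagged* segments of the same slice (source ``H_healthy_<slice>``);
    if the slice has no unflagged segment, the mean over all unflagged
    segments of the whole LV is used (source ``H_healthy_all``).  Returns
    ``(refs, warnings)`` where ``refs[segment_id] = (H_ref, source)``.

    If every segment of the LV is flagged there is no healthy reference at
    all; each flagged segment then gets ``H_ref = nan`` with source
    ``none`` and a structured warning (the caller classifies all of them
    infarcted).
    """
    h = {sid: hspread(s) for sid, s in all_series.items()}
    notes: list[str] = []
    slice_tag = {"basal": "H_healthy_basal", "midventricular": "H_healthy_mid",
                 "apical": "H_healthy_apical"}
    healthy_by_slice: dict[str, list[float]] = {}
    for sid, s in all_series.items():
        if not flags.get(sid, False):
            healthy_by_slice.setdefault(s.slice_level, []).append(h[sid])
    all_healthy = [v for vs in healthy_by_slice.values() for v in vs]
    refs: dict[int, tuple[float, str]] = {}
    for sid, s in all_series.items():
        if not flags.get(sid, False):
            continue
        same = healthy_by_slice.get(s.slice_level, [])
        if same:
            refs[sid] = (float(np.mean(same)), slice_tag[s.slice_level])
        elif all_healthy:
            refs[sid] = (float(np.mean(all_healthy)), "H_healthy_all")
            notes.append(
                f"slice {s.slice_level}: all segments flagged; "
                "using healthy segments of the whole LV as H-spread reference"
            )
        else:
            refs[sid] = (float("nan"), "none")
            notes.append(
                "all 16 segments flagged: no healthy H-spread reference exists; "
                "flagged segments classified infarcted"
            )
    return refs, sorted(set(notes), key=notes.index)


def classify(
    all_series: dict[int, SegmentSeries],
    benchmarks: BenchmarkTable | None = None,
    alphas: dict[str, float] | None = None,
    margin_sd: float = 0.0,
) -> DetectionReport:
    """Full two-stage classification of one LV's 16 segments.

    A flagged segment is infarcted iff its H-spread reduction
    ``100 * (H_ref - H_seg) / H_ref`` reaches its slice's alpha threshold;
    unflagged segments are healthy with reduction 0.
    """
    benchmarks = benchmarks or BenchmarkTable.default()
    alphas = dict(DEFAULT_ALPHAS, **(alphas or {}))
    for lvl, a in alphas.items():
        if not 0.0 < a <= 100.0:
            raise ValueError(f"alpha for {lvl} must lie in (0, 100]")
    flags = {sid: flag_potential(s, benchmarks, margin_sd) for sid, s in all_series.items()}
    refs, notes = healthy_reference(all_series, flags)
    segments: dict[int, SegmentResult] = {}
    for sid, s in all_series.items():
        h_seg = hspread(s)
        res = SegmentResult(
            segment_id=sid,
            slice_level=s.slice_level,
            es_calculated=s.es_calculated,
            potentially_infarcted=flags[sid],
            h_spread=h_seg,
            alpha=alphas[s.slice_level],
        )
        if flags[sid]:
            h_ref, source = refs[sid]
            res.h_reference = h_ref
            res.reference_source = source
            if source == "none":
                res.reduction_pct = float("nan")
                res.infarcted = True
            elif h_ref == 0.0:
                res.reduction_pct = float("nan")
                res.infarcted = False
                notes.append(
                    f"segment {sid}: reference H-spread is 0, reduction undefined; "
                    "classified not infarcted"
                )
            else:
                res.reduction_pct = 100.0 * (h_ref - h_seg) / h_ref
                res.infarcted = res.reduction_pct >= alphas[s.slice_level]
        segments[sid] = res
    for note in notes:
        warnings.warn(note, stacklevel=2)
    return DetectionReport(segments=segments, alphas=alphas, warnings=list(notes))


# -- bridging from strain fields ----------------------------------------------


def build_segment_series(
    strain_field: StrainField, segmentation: AHASegmentation
) -> dict[int, SegmentSeries]:
    """Per-segment, per-frame median CS from a pointwise strain field."""
    seeds = np.rint(strain_field.points).astype(int)
    seg_of_point = segmentation.labels[seeds[:, 1], seeds[:, 0]]
    out: dict[int, SegmentSeries] = {}
    for sid in segmentation.segment_ids:
        sel = seg_of_point == sid
        if not sel.any():
            continue
        cs = strain_field.cs[sel]  # (n_sel, T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            s_f = np.nanmedian(cs, axis=0)
        n_pix = np.isfinite(cs).sum(axis=0)
        out[sid] = SegmentSeries(
            segment_id=sid,
            slice_level=segmentation.slice_level,
            s_f=s_f,
            n_pixels=n_pix,
        )
    return out
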