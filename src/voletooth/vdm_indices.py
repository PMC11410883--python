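"""Automatic Van der Meulen linear indices and La/Li asymmetry.

Measurements are taken on the full closed outline in canonical pose
(anterior left, buccal down, y-up mm):

* ``L`` — total anteroposterior extent (x-extent of the outline);
* ``W`` — maximal width (y-extent) of the part posterior to the 'a' line;
* ``a`` — anteroposterior extent of the anteroconid complex: x-distance
  from the 'a' line (through the deepest points of BRA3 and LRA4) to the
  anterior-most point;
* ``b`` — maximal width across the T4-T5 region (between the 'a' line and
  the re-entrants bounding the anterior cap);
* ``c`` — maximal width of the anterior cap;
* ``e`` — distance between the lowest point of T6 and the highest point of
  T7 (absent when T6 cannot be identified, e.g. *Alexandromys*-like teeth);
* ``La`` / ``Li`` — asymmetry: distances from the anterior apex to the
  buccal and lingual ends of the 'a' line (chord by default, arc length
  optionally).

Derived ratios A/L = 100·a/L, B/W = 100·b/W, C/W = 100·c/W are recomputed
whenever a segment changes.  A segment whose defining features were not
detected is reported absent with a reason — never silently guessed.  Each
segment can be overridden manually; overriding the 'a' line re-anchors the
dependent a, La and Li.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .outline_geometry import FeatureAnnotation, OutlineTrace

__all__ = ["SegmentMeasurement", "IndexMeasurements", "measure_indices",
           "override_segment", "compare_auto_manual"]

SEGMENTS = ("L", "W", "a", "b", "c", "e", "La", "Li")


@dataclass
class SegmentMeasurement:
    value: float | None = None
    p1: tuple[float, float] | None = None
    p2: tuple[float, float] | None = None
    provenance: str = "automatic"  # automatic | manual | derived-from-manual
    reason_absent: str | None = None

    @property
    def present(self) -> bool:
        return self.value is not None


@dataclass
class IndexMeasurements:
    segments: dict[str, SegmentMeasurement] = field(default_factory=dict)
    #: anchor points (mm): apex, a_buccal, a_lingual
    anchors: dict[str, tuple[float, float]] = field(default_factory=dict)

    def value(self, name: str) -> float | None:
        seg = self.segments.get(name)
        return seg.value if seg else None

    @property
    def ratios(self) -> dict[str, float | None]:
        def ratio(num, den):
            a, b = self.value(num), self.value(den)
            return 100.0 * a / b if a is not None and b not in (None, 0.0) else None

        return {"A_L": ratio("a", "L"), "B_W": ratio("b", "W"), "C_W": ratio("c", "W")}

    def to_dict(self) -> dict:
        return {
            "segments": {
                k: {
                    "value_mm": s.value,
                    "p1": s.p1,
                    "p2": s.p2,
                    "provenance": s.provenance,
                    "reason_absent": s.reason_absent,
                }
                for k, s in self.segments.items()
            },
            "ratios": self.ratios,
            "anchors": self.anchors,
        }


def _extent_segment(pts: np.ndarray, axis: int) -> SegmentMeasurement:
    lo, hi = pts[:, axis].min(), pts[:, axis].max()
    other = pts[:, 1 - axis].mean()
    if axis == 0:
        p1, p2 = (lo, other), (hi, other)
    else:
        p1, p2 = (other, lo), (other, hi)
    return SegmentMeasurement(value=float(hi - lo), p1=p1, p2=p2)


def measure_indices(
    trace: OutlineTrace,
    ann: FeatureAnnotation,
    scale: float | None = None,
    asymmetry_mode: str = "chord",
) -> IndexMeasurements:
    """Measure all indices from a full closed trace and its annotation.

    Missing annotation features make only the affected indices absent (with
    a reason); everything else is still measured.
    """
    if asymmetry_mode not in ("chord", "arc"):
        raise ValidationError(f"unknown asymmetry_mode {asymmetry_mode!r}")
    if scale is not None and scale != trace.scale:
        trace = OutlineTrace(points=trace.points, scale=scale)
    pts = trace.to_mm()
    m = IndexMeasurements()
    seg = m.segments

    seg["L"] = _extent_segment(pts, axis=0)
    apex = pts[ann.apex]
    m.anchors["apex"] = (float(apex[0]), float(apex[1]))

    have_a = ann.a_endpoint_buccal is not None and ann.a_endpoint_lingual is not None
    if not have_a:
        reason = "segment 'a' endpoints (BRA3/LRA4) not detected"
        for name in ("a", "W", "b", "La", "Li"):
            seg[name] = SegmentMeasurement(value=None, reason_absent=reason)
    else:
        ab = pts[ann.a_endpoint_buccal]
        al = pts[ann.a_endpoint_lingual]
        m.anchors["a_buccal"] = (float(ab[0]), float(ab[1]))
        m.anchors["a_lingual"] = (float(al[0]), float(al[1]))
        _measure_from_anchors(m, pts, ann, asymmetry_mode)

    # cap region: bounded by the most anterior re-entrant on each side
    if len(ann.buccal_reentrants) >= 4 and len(ann.lingual_reentrants) >= 5:
        x_cap = 0.5 * (
            pts[ann.buccal_reentrants[-1], 0] + pts[ann.lingual_reentrants[-1], 0]
        )
        cap = pts[pts[:, 0] <= x_cap]
        seg["c"] = _extent_segment(cap, axis=1) if len(cap) else SegmentMeasurement(
            value=None, reason_absent="empty cap region"
        )
        if have_a:
            x_a = 0.5 * (m.anchors["a_buccal"][0] + m.anchors["a_lingual"][0])
            mid = pts[(pts[:, 0] >= x_cap) & (pts[:, 0] <= x_a)]
            seg["b"] = _extent_segment(mid, axis=1) if len(mid) else SegmentMeasurement(
                value=None, reason_absent="empty T4-T5 region"
            )
    else:
        reason = "anterior-cap re-entrants not detected"
        seg["c"] = SegmentMeasurement(value=None, reason_absent=reason)
        if have_a:
            seg["b"] = SegmentMeasurement(value=None, reason_absent=reason)

    # e: requires T6 (between BRA4 and BRA5) and T7 (between LRA5 and LRA6)
    if len(ann.buccal_reentrants) >= 5 and len(ann.lingual_reentrants) >= 6:
        t6 = _salient_between(pts, ann.buccal_reentrants[3], ann.buccal_reentrants[4], lowest=True)
        t7 = _salient_between(pts, ann.lingual_reentrants[4], ann.lingual_reentrants[5], lowest=False)
        if t6 is not None and t7 is not None:
            p1 = tuple(map(float, pts[t6]))
            p2 = tuple(map(float, pts[t7]))
            seg["e"] = SegmentMeasurement(
                value=float(np.linalg.norm(pts[t6] - pts[t7])), p1=p1, p2=p2
            )
        else:
            seg["e"] = SegmentMeasurement(value=None, reason_absent="T6/T7 arc empty")
    else:
        seg["e"] = SegmentMeasurement(value=None, reason_absent="T6 not detected")

    return m


def _salient_between(pts: np.ndarray, i: int, j: int, lowest: bool) -> int | None:
    lo, hi = sorted((i, j))
    idx = np.arange(lo + 1, hi)
    if len(idx) == 0:
        return None
    ys = pts[idx, 1]
    return int(idx[np.argmin(ys) if lowest else np.argmax(ys)])


def _measure_from_anchors(
    m: IndexMeasurements,
    pts: np.ndarray | None,
    ann: FeatureAnnotation | None,
    asymmetry_mode: str,
) -> None:
    """(Re)compute a, W, La, Li from the stored anchors.

    Needs the trace points for W and arc-mode asymmetry; with pts=None
    (after a manual 'a' override) W is left as-is and chord mode is used.
    """
    seg = m.segments
    apex = np.array(m.anchors["apex"])
    ab = np.array(m.anchors["a_buccal"])
    al = np.array(m.anchors["a_lingual"])
    x_a = 0.5 * (ab[0] + al[0])
    x_min = pts[:, 0].min() if pts is not None else apex[0]
    seg["a"] = SegmentMeasurement(
        value=float(x_a - x_min),
        p1=(float(x_min), float(0.5 * (ab[1] + al[1]))),
        p2=(float(x_a), float(0.5 * (ab[1] + al[1]))),
    )
    if pts is not None:
        post = pts[pts[:, 0] >= x_a]
        seg["W"] = _extent_segment(post, axis=1) if len(post) else SegmentMeasurement(
            value=None, reason_absent="empty posterior region"
        )
    la = float(np.linalg.norm(apex - ab))
    li = float(np.linalg.norm(apex - al))
    if asymmetry_mode == "arc" and pts is not None and ann is not None:
        la = _arc_length(pts, ann.apex, ann.a_endpoint_buccal)
        li = _arc_length(pts, ann.apex, ann.a_endpoint_lingual)
    seg["La"] = SegmentMeasurement(value=la, p1=tuple(apex), p2=tuple(ab))
    seg["Li"] = SegmentMeasurement(value=li, p1=tuple(apex), p2=tuple(al))


def _arc_length(pts: np.ndarray, i: int, j: int) -> float:
    n = len(pts)
    fwd = np.arange(i, j + 1) if i <= j else np.concatenate([np.arange(i, n), np.arange(0, j + 1)])
    bwd = np.arange(j, i + 1) if j <= i else np.concatenate([np.arange(j, n), np.arange(0, i + 1)])
    arcs = []
    for sel in (fwd, bwd):
        p = pts[sel]
        arcs.append(float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum()))
    return min(arcs)


def override_segment(
    m: IndexMeasurements,
    segment: str,
    p1: tuple[float, float],
    p2: tuple[float, float],
) -> IndexMeasurements:
    """Replace one segment with a manual measurement; recompute dependents.

    The new value is the Euclidean distance |p1 - p2|.  Overriding ``a``
    reinterprets (p1, p2) as the new buccal and lingual 'a'-line endpoints
    and recomputes a, La and Li from them (flagged ``derived-from-manual``).
    All ratios always reflect current segment values.
    """
    if segment not in SEGMENTS:
        raise ValidationError(f"unknown segment {segment!r}; expected one of {SEGMENTS}")
    out = copy.deepcopy(m)
    p1 = (float(p1[0]), float(p1[1]))
    p2 = (float(p2[0]), float(p2[1]))
    if segment == "a":
        out.anchors["a_buccal"] = p1
        out.anchors["a_lingual"] = p2
        _measure_from_anchors(out, None, None, "chord")
        out.segments["a"].provenance = "manual"
        for name in ("La", "Li"):
            out.segments[name].provenance = "derived-from-manual"
    else:
        out.segments[segment] = SegmentMeasurement(
            value=float(np.hypot(p1[0] - p2[0], p1[1] - p2[1])),
            p1=p1,
            p2=p2,
            provenance="manual",
        )
    return out


def compare_auto_manual(
    auto: IndexMeasurements | list[IndexMeasurements],
    manual: IndexMeasurements | list[IndexMeasurements],
) -> pd.DataFrame:
    """Per-index absolute discrepancy |auto - manual| in mm.

    Accepts single measurements or batches (same length/order).  Indices
    absent on either side are excluded from the means; the table reports,
    per index, the number compared, the mean and the maximum discrepancy.
    """
    autos = auto if isinstance(auto, list) else [auto]
    manuals = manual if isinstance(manual, list) else [manual]
    if len(autos) != len(manuals):
        raise ValidationError("auto and manual batches must have equal length")
    rows = []
    for name in SEGMENTS:
        diffs = []
        absent = 0
        for a_m, m_m in zip(autos, manuals):
            va, vm = a_m.value(name), m_m.value(name)
            if va is None or vm is None:
                absent += 1
                continue
            diffs.append(abs(va - vm))
        rows.append(
            {
                "index": name,
                "n_compared": len(diffs),
                "n_absent": absent,
                "mean_abs_diff_mm": float(np.mean(diffs)) if diffs else np.nan,
                "max_abs_diff_mm": float(np.max(diffs)) if diffs else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("index")
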