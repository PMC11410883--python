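"""Parametric generator of vole-like first-lower-molar (m1) outlines.

The generator emulates the occlusal outline of an arvicoline m1 in its
canonical pose (anterior apex at the left, posterior lobe at the right,
buccal side down, lingual side up, y-up mm coordinates): an elongate closed
outline with alternating buccal/lingual enamel triangles (T1..T7), re-entrant
angles (BRA1.. from the posterior end on the buccal side, LRA1.. on the
lingual side), an anterior cap (AC) and a posterior lobe (PL).  Every named
feature point lies exactly on the generated polyline, so the generator serves
as ground truth for the image-processing, feature-detection and measurement
stages.

Outlines are built from two per-side knot tables interpolated with monotone
(PCHIP) cubics, so each labelled knot is an exact local extremum of its
chain.  Specimens are produced by displacing the template along its outward
normals with smooth (arc-length-correlated) Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import LinearRing

from .errors import ValidationError

__all__ = [
    "TemplateParams",
    "MolarTemplate",
    "MolarSpecimen",
    "PRESETS",
    "make_template",
    "generate_specimen",
    "render",
    "truth_semiperimeter",
    "truth_landmarks",
    "truth_indices",
]


@dataclass(frozen=True)
class TemplateParams:
    """Dimensional parameters of a synthetic m1 template.

    Parameters are in mm (length) or dimensionless scale factors applied to
    the base outline (a generic *Microtus*-like topology of total length
    2.80 mm and width ~1.1 mm).
    """

    length_mm: float = 2.80
    #: scales the half-width of every triangle apex
    width_factor: float = 1.00
    #: 1.0 = re-entrant tips almost reach the midline; smaller = shallower folds
    reentrant_depth: float = 1.00
    #: scales the anterior-cap height/width
    cap_factor: float = 1.00
    #: whether the buccal triangle T6 is present (absent in Alexandromys-like teeth)
    t6_present: bool = True
    #: buccal/lingual width asymmetry: buccal y scaled by (1+asym), lingual by (1-asym)
    asymmetry: float = 0.0
    #: stretches the anteroconid complex (anterior to the 'a' line) along x while
    #: keeping total length fixed, i.e. controls the a/L proportion
    acc_stretch: float = 1.0

    def validate(self) -> None:
        if self.length_mm <= 0:
            raise ValidationError(f"length_mm must be positive, got {self.length_mm}")
        if self.width_factor <= 0 or self.cap_factor <= 0:
            raise ValidationError("width_factor and cap_factor must be positive")
        if not (0.0 < self.reentrant_depth <= 1.2):
            raise ValidationError(
                f"reentrant_depth must lie in (0, 1.2], got {self.reentrant_depth}"
            )
        if abs(self.asymmetry) > 0.5:
            raise ValidationError("asymmetry must lie in [-0.5, 0.5]")
        if not (0.5 <= self.acc_stretch <= 1.5):
            raise ValidationError("acc_stretch must lie in [0.5, 1.5]")


#: Named parameter sets.  The names evoke arvicoline genera only to indicate a
#: plausible morphotype (size, fold depth, cap shape, T6 presence); they are
#: not calibrated to any real species.
PRESETS: dict[str, TemplateParams] = {
    "microtus-like": TemplateParams(2.90, 0.80, 0.81, 0.97, True, 0.08, 1.30),
    "terricola-like": TemplateParams(2.25, 1.30, 0.70, 1.30, True, 0.15, 0.81),
    "iberomys-like": TemplateParams(3.42, 1.30, 0.70, 0.70, True, 0.15, 1.20),
    "chionomys-like": TemplateParams(3.60, 1.30, 0.82, 1.30, True, -0.12, 1.30),
    "allophaiomys-like": TemplateParams(2.20, 0.80, 0.72, 0.82, True, -0.05, 0.85),
    "oeconomus-like": TemplateParams(3.00, 1.30, 0.85, 1.17, False, -0.15, 1.02),
}

_BASE_LENGTH = 2.80

# Knot tables for the base outline, anterior (apex) to posterior, as
# (x, y, label).  Labels: triangle apices T1..T7, re-entrant tips BRA*/LRA*
# (numbered from the posterior end), AC flanks, PL bulge.  None = shaping knot.
# Buccal chain: y <= 0 (canonical pose, y-up).
_BUCCAL_KNOTS = [
    (0.00, 0.000, "apex"),
    (0.16, -0.460, "_ACb"),  # cap's buccal flank (unnumbered salient)
    (0.33, -0.060, "BRA5"),
    (0.52, -0.550, "T6"),
    (0.72, -0.050, "BRA4"),
    (0.93, -0.560, "T4"),
    (1.14, -0.040, "BRA3"),
    (1.36, -0.530, None),  # minor salient between BRA3 and BRA2
    (1.58, -0.050, "BRA2"),
    (1.81, -0.570, "T2"),
    (2.05, -0.050, "BRA1"),
    (2.33, -0.540, "_PLb"),  # posterior lobe, buccal bulge
    (2.62, -0.380, None),
    (2.80, 0.000, "posterior"),
]
# Lingual chain: y >= 0; one more triangle (T1) than the buccal side.
_LINGUAL_KNOTS = [
    (0.00, 0.000, "apex"),
    (0.14, 0.420, "_ACl"),
    (0.29, 0.060, "LRA6"),
    (0.45, 0.540, "T7"),
    (0.63, 0.050, "LRA5"),
    (0.84, 0.550, "T5"),
    (1.05, 0.040, "LRA4"),
    (1.27, 0.520, None),
    (1.49, 0.050, "LRA3"),
    (1.72, 0.560, "T3"),
    (1.95, 0.040, "LRA2"),
    (2.17, 0.570, "T1"),
    (2.42, 0.050, "LRA1"),
    (2.60, 0.460, "PL"),
    (2.80, 0.000, "posterior"),
]

# knots rescaled by cap_factor (the anterior cap region)
_CAP_LABELS = {"_ACb", "_ACl"}
# re-entrant tip labels, whose |y| is controlled by reentrant_depth
_REENTRANT_PREFIXES = ("BRA", "LRA")


@dataclass(frozen=True)
class MolarTemplate:
    """A deterministic, labelled m1 outline (closed polyline, mm, y-up)."""

    name: str
    params: TemplateParams
    points: np.ndarray  # (N, 2), closed (last point adjacent to first, not repeated)
    labels: dict[str, int] = field(default_factory=dict)

    @property
    def length_mm(self) -> float:
        return float(np.ptp(self.points[:, 0]))

    @property
    def buccal_reentrants(self) -> list[str]:
        return sorted(
            (k for k in self.labels if k.startswith("BRA")), key=lambda s: int(s[3:])
        )

    @property
    def lingual_reentrants(self) -> list[str]:
        return sorted(
            (k for k in self.labels if k.startswith("LRA")), key=lambda s: int(s[3:])
        )


@dataclass(frozen=True)
class MolarSpecimen:
    """A noisy realisation of a template, with transported feature labels."""

    template: MolarTemplate
    points: np.ndarray
    labels: dict[str, int]
    noise_sigma_mm: float
    seed: int


_BASE_ALINE_X = 1.10  # base-table x of the 'a' line (midway BRA3/LRA4)


def _scaled_knots(knots, params: TemplateParams, buccal: bool):
    """Apply template parameters to a base knot table."""
    t6_present = params.t6_present
    sx = params.length_mm / _BASE_LENGTH
    wf = params.width_factor * (
        1.0 + params.asymmetry if buccal else 1.0 - params.asymmetry
    )
    s = params.acc_stretch
    out = []
    for x, y, lab in knots:
        if buccal and not t6_present and lab in ("T6", "BRA4"):
            continue  # BRA5/T6/BRA4 fold collapses into a single re-entrant
        # redistribute anterior vs posterior extent at constant total length
        if x <= _BASE_ALINE_X + 1e-9:
            x = x * s
        else:
            xa = _BASE_ALINE_X
            x = xa * s + (x - xa) * (_BASE_LENGTH - xa * s) / (_BASE_LENGTH - xa)
        yy = y * wf
        if lab in _CAP_LABELS:
            yy = y * wf * params.cap_factor
        if lab and lab.startswith(_REENTRANT_PREFIXES):
            # shallower folds move the tip away from the midline, toward the
            # flanking triangle apices (|y| of a typical apex ~ 0.55)
            yy = np.sign(y) * (abs(y) + (1.0 - params.reentrant_depth) * 0.45) * wf
        out.append((x * sx, yy, lab))
    if not t6_present:
        # renumber: the single cap-adjacent buccal re-entrant becomes BRA4
        out = [
            (x, y, "BRA4" if lab == "BRA5" else lab) for x, y, lab in out
        ]
    return out


def _flatten_extrema(knots, dx: float = 0.03, eps: float = 0.005):
    """Insert auxiliary knots flanking each interior extremum knot.

    Gives every fold/triangle tip a finite curvature radius (~dx^2 / 2 eps,
    i.e. tens of microns, as in real enamel) instead of the near-cusp a bare
    PCHIP extremum produces; without this, tips narrower than a pixel are
    clipped at rasterization.
    """
    out = [knots[0]]
    for prev, cur, nxt in zip(knots[:-2], knots[1:-1], knots[2:]):
        x, y, lab = cur
        lo = min(x - prev[0], nxt[0] - x)
        d = min(dx, 0.4 * lo)
        if y > prev[1] and y > nxt[1]:
            s = -1.0
        elif y < prev[1] and y < nxt[1]:
            s = 1.0
        else:
            out.append(cur)
            continue
        out.append((x - d, y + s * eps, None))
        out.append(cur)
        out.append((x + d, y + s * eps, None))
    out.append(knots[-1])
    return out


def _sample_chain(knots, step_mm: float):
    """PCHIP-interpolate a chain and sample it densely.

    Knot x positions are inserted into the sample grid exactly, so every
    labelled knot is a vertex of the returned polyline.  Returns
    (points (K,2), {label: index}).
    """
    knots = _flatten_extrema(knots)
    xs = np.array([k[0] for k in knots])
    ys = np.array([k[1] for k in knots])
    if np.any(np.diff(xs) <= 0):
        raise ValidationError("chain knots must have strictly increasing x")
    interp = PchipInterpolator(xs, ys)
    grid = [np.array([xs[0]])]
    for a, b in zip(xs[:-1], xs[1:]):
        n = max(int(np.ceil((b - a) / step_mm)), 4)
        grid.append(np.linspace(a, b, n + 1)[1:])
    gx = np.concatenate(grid)
    pts = np.column_stack([gx, interp(gx)])
    idx = {}
    for x, _, lab in knots:
        if lab:
            idx[lab] = int(np.argmin(np.abs(gx - x)))
    return pts, idx


def make_template(species_preset: str | TemplateParams, step_mm: float = 0.004) -> MolarTemplate:
    """Build a labelled template outline from a preset name or parameter set.

    The outline is a closed simple polyline traversed counter-clockwise
    (y-up): posterior end -> lingual chain -> anterior apex -> buccal chain.
    """
    if isinstance(species_preset, str):
        try:
            params = PRESETS[species_preset]
        except KeyError:
            raise ValidationError(
                f"unknown preset {species_preset!r}; available: {sorted(PRESETS)}"
            ) from None
        name = species_preset
    else:
        params = species_preset
        name = "custom"
    params.validate()

    buccal = _scaled_knots(_BUCCAL_KNOTS, params, True)
    lingual = _scaled_knots(_LINGUAL_KNOTS, params, False)
    b_pts, b_idx = _sample_chain(buccal, step_mm)
    l_pts, l_idx = _sample_chain(lingual, step_mm)

    n_l = len(l_pts)
    # posterior -> apex along the lingual side, then apex -> posterior buccally
    outline = np.vstack([l_pts[::-1][:-1], b_pts[:-1]])
    labels: dict[str, int] = {}
    for lab, i in l_idx.items():
        labels[lab] = (n_l - 1) - i
    for lab, i in b_idx.items():
        if lab == "posterior":
            labels[lab] = 0
        else:
            labels[lab] = (n_l - 1) + i
    labels["AC"] = labels["apex"]  # the cap's apex is the anterior apex
    labels["a_buccal"] = labels["BRA3"]
    labels["a_lingual"] = labels["LRA4"]

    tpl = MolarTemplate(name=name, params=params, points=outline, labels=labels)
    _check_simple(outline)
    return tpl


def _check_simple(points: np.ndarray) -> None:
    ring = LinearRing(points)
    if not ring.is_simple or not ring.is_valid:
        raise ValidationError("generated outline self-intersects")


def _outward_normals(points: np.ndarray) -> np.ndarray:
    """Unit outward normals of a closed CCW (y-up) polyline."""
    t = np.roll(points, -1, axis=0) - np.roll(points, 1, axis=0)
    n = np.column_stack([t[:, 1], -t[:, 0]])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return n / norm


def generate_specimen(
    template: MolarTemplate,
    noise_sigma_mm: float,
    seed: int,
    correlation_mm: float = 0.30,
    max_retries: int = 8,
) -> MolarSpecimen:
    """Displace a template along its outward normals with smooth noise.

    The displacement field is white Gaussian noise smoothed circularly along
    the outline with a Gaussian kernel of width ``correlation_mm`` (arc
    length), then rescaled to standard deviation ``noise_sigma_mm``.  Feature
    labels keep their vertex indices.  A draw whose outline self-intersects
    is rejected and redrawn (deterministically, from the same seeded
    generator) up to ``max_retries`` times before raising.
    """
    if noise_sigma_mm < 0:
        raise ValidationError("noise_sigma_mm must be >= 0")
    pts = template.points.copy()
    if noise_sigma_mm > 0:
        rng = np.random.default_rng(seed)
        seg = np.linalg.norm(np.diff(pts, axis=0, append=pts[:1]), axis=1)
        sig = correlation_mm / float(seg.mean())
        # smooth the normal field too: at cusps (apex, fold tips) raw normals
        # flip direction abruptly, and coherent wall motion is needed to keep
        # the perturbed outline simple
        normals = gaussian_filter1d(_outward_normals(pts), sigma=sig, mode="wrap", axis=0)
        nn = np.linalg.norm(normals, axis=1, keepdims=True)
        nn[nn < 1e-9] = 1.0
        normals /= nn
        for attempt in range(max_retries + 1):
            raw = rng.standard_normal(len(pts))
            smooth = gaussian_filter1d(raw, sigma=sig, mode="wrap")
            sd = smooth.std()
            if sd > 0:
                smooth *= noise_sigma_mm / sd
            cand = pts + smooth[:, None] * normals
            try:
                _check_simple(cand)
            except ValidationError:
                if attempt == max_retries:
                    raise ValidationError(
                        "perturbed outline self-intersects; reduce noise_sigma_mm "
                        "or increase correlation_mm"
                    ) from None
                continue
            pts = cand
            break
    return MolarSpecimen(
        template=template,
        points=pts,
        labels=dict(template.labels),
        noise_sigma_mm=noise_sigma_mm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground-truth extraction (oracles for the image pipeline)
# ---------------------------------------------------------------------------

def _outline_points(obj) -> tuple[np.ndarray, dict]:
    if isinstance(obj, MolarTemplate):
        return obj.points, obj.labels
    return obj.points, obj.labels


def truth_semiperimeter(spec: MolarSpecimen | MolarTemplate) -> np.ndarray:
    """The anterior semiperimeter polyline, buccal 'a' endpoint first.

    Runs from the deepest point of BRA3, through the anterior apex, to the
    deepest point of LRA4 (the arc that excludes the posterior lobe).
    """
    pts, labels = _outline_points(spec)
    i_l, i_a, i_b = labels["a_lingual"], labels["apex"], labels["a_buccal"]
    assert i_l < i_a < i_b, "outline ordering violated"
    return pts[i_l : i_b + 1][::-1].copy()


def _resample_polyline(poly: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, poly[:, 0]), np.interp(t, s, poly[:, 1])])


def truth_landmarks(spec: MolarSpecimen | MolarTemplate, n: int = 200) -> np.ndarray:
    """Equal-arc-length resampling of the ground-truth semiperimeter (mm)."""
    return _resample_polyline(truth_semiperimeter(spec), n)


def truth_indices(spec: MolarSpecimen | MolarTemplate) -> dict[str, float | None]:
    """Linear indices computed directly from the labelled ground truth.

    Uses the same geometric definitions as the measurement module but reads
    feature points from the generator labels instead of detecting them.
    """
    pts, labels = _outline_points(spec)
    apex = pts[labels["apex"]]
    ab, al = pts[labels["a_buccal"]], pts[labels["a_lingual"]]
    x_a = 0.5 * (ab[0] + al[0])
    out: dict[str, float | None] = {}
    out["L"] = float(np.ptp(pts[:, 0]))
    post = pts[pts[:, 0] >= x_a]
    out["W"] = float(np.ptp(post[:, 1]))
    out["a"] = float(x_a - pts[:, 0].min())
    if "T6" in labels and "T7" in labels:
        out["e"] = float(np.linalg.norm(pts[labels["T6"]] - pts[labels["T7"]]))
    else:
        out["e"] = None
    # cap region bounded by the most anterior re-entrant pair
    bnames = sorted((k for k in labels if k.startswith("BRA")), key=lambda s: int(s[3:]))
    lnames = sorted((k for k in labels if k.startswith("LRA")), key=lambda s: int(s[3:]))
    x_cap = 0.5 * (pts[labels[bnames[-1]], 0] + pts[labels[lnames[-1]], 0])
    mid = pts[(pts[:, 0] >= x_cap) & (pts[:, 0] <= x_a)]
    out["b"] = float(np.ptp(mid[:, 1])) if len(mid) else None
    cap = pts[pts[:, 0] <= x_cap]
    out["c"] = float(np.ptp(cap[:, 1])) if len(cap) else None
    out["La"] = float(np.linalg.norm(apex - ab))
    out["Li"] = float(np.linalg.norm(apex - al))
    return out


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def render(
    polyline_mm: np.ndarray,
    scale_mm_per_px: float,
    style: str = "filled",
    labels: dict[str, int] | None = None,
    margin_px: int = 10,
    stroke_px: int = 3,
) -> tuple[np.ndarray, dict]:
    """Rasterize a closed outline as a photo- or drawing-dialect image.

    ``filled`` emulates a segmented photograph: a solid dark tooth on white.
    ``stroke+cement`` emulates a literature line drawing: a ~``stroke_px``
    wide dark outline plus filled cement blobs nestled in the deep re-entrant
    folds (touching the stroke, as drawn cement does).

    Returns ``(image, truth)`` where image is uint8 grayscale (white
    background, dark foreground) and truth is a JSON-serializable dict with
    the polyline and labels in both mm and pixel coordinates.
    """
    from scipy.ndimage import binary_dilation
    from skimage.draw import disk as draw_disk
    from skimage.draw import line as draw_line
    from skimage.draw import polygon as draw_polygon
    from skimage.morphology import disk as disk_se

    if scale_mm_per_px <= 0:
        raise ValidationError("scale_mm_per_px must be positive")
    if style not in ("filled", "stroke+cement"):
        raise ValidationError(f"unknown render style {style!r}")

    pts = np.asarray(polyline_mm, dtype=float)
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    w = int(np.ceil((xmax - xmin) / scale_mm_per_px)) + 2 * margin_px + 1
    h = int(np.ceil((ymax - ymin) / scale_mm_per_px)) + 2 * margin_px + 1
    # mm (y-up) -> px (y-down)
    col = (pts[:, 0] - xmin) / scale_mm_per_px + margin_px
    row = (ymax - pts[:, 1]) / scale_mm_per_px + margin_px
    mask = np.zeros((h, w), dtype=bool)

    if style == "filled":
        rr, cc = draw_polygon(row, col, shape=mask.shape)
        mask[rr, cc] = True
    else:
        ri, ci = np.round(row).astype(int), np.round(col).astype(int)
        for k in range(len(ri)):
            k2 = (k + 1) % len(ri)
            rr, cc = draw_line(ri[k], ci[k], ri[k2], ci[k2])
            mask[rr, cc] = True
        mask = binary_dilation(mask, structure=disk_se(max(stroke_px // 2, 1)))
        if labels:
            from scipy.spatial import cKDTree

            normals = _outward_normals(pts)
            poly_px = np.column_stack([col, row])
            tree = cKDTree(poly_px)
            deep = [
                k
                for k in labels
                if k.startswith(("BRA", "LRA")) and k[3:].isdigit() and int(k[3:]) <= 4
            ]
            for k in deep:
                i = labels[k]
                # outward normal in the px (y-down) frame
                nvec = np.array([normals[i, 0], -normals[i, 1]])
                # slide into the fold pocket to the spot with the largest wall
                # clearance; keep a 2 px gap to the stroke so the blob is its
                # own connected component (removed later as "not part of the
                # skeleton cycle")
                best_r, best_c = 0.0, None
                for d in range(5, 26):
                    centre = np.array([col[i], row[i]]) + nvec * d
                    clearance, _ = tree.query(centre)
                    r_fit = min(clearance - stroke_px / 2.0 - 2.0, 6.0)
                    if r_fit > best_r:
                        best_r, best_c = r_fit, centre
                if best_c is None or best_r < 3.5:
                    continue  # pocket too tight for a credible cement blob
                cc_, rc = best_c
                if not (best_r < rc < h - best_r and best_r < cc_ < w - best_r):
                    continue
                rr, cc = draw_disk((rc, cc_), best_r, shape=mask.shape)
                mask[rr, cc] = True

    image = np.full((h, w), 255, dtype=np.uint8)
    image[mask] = 0

    truth = {
        "style": style,
        "scale_mm_per_px": scale_mm_per_px,
        "points_mm": pts.tolist(),
        "points_px": np.column_stack([col, row]).tolist(),
        "labels": dict(labels) if labels else {},
        "foreground_px": int(mask.sum()),
        "origin_mm": [float(xmin), float(ymin)],
    }
    return image, truth


def save_truth(truth: dict, path) -> None:
    """Write a render's ground-truth sidecar as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)


def template_to_dict(tpl: MolarTemplate) -> dict:
    return {
        "name": tpl.name,
        "params": dataclasses.asdict(tpl.params),
        "labels": dict(tpl.labels),
        "points": tpl.points.tolist(),
    }


def synthetic_database(
    presets=None,
    n_per_species: int = 30,
    noise_sigma_mm: float = 0.02,
    seed: int = 0,
    n_landmarks: int = 200,
):
    """A labelled reference database of noisy synthetic specimens.

    Landmarks come from the ground-truth semiperimeters (no rasterization),
    one species per preset; specimen seeds are drawn deterministically from
    ``seed``.
    """
    from .outline_geometry import LandmarkSet
    from .reference_db import ReferenceDatabase, SpecimenRecord

    names = list(presets) if presets is not None else list(PRESETS)
    rng = np.random.default_rng(seed)
    records = []
    for name in names:
        tpl = make_template(name)
        for k in range(n_per_species):
            s = int(rng.integers(0, 2**31 - 1))
            spec = generate_specimen(tpl, noise_sigma_mm, s)
            lm = LandmarkSet(
                coords=truth_landmarks(spec, n_landmarks),
                specimen_id=f"{name}-{k:03d}",
                species=name,
                source_kind="photo",
            )
            records.append(
                SpecimenRecord(specimen_id=lm.specimen_id, species=name, landmarks=lm)
            )
    return ReferenceDatabase(records)
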