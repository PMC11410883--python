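"""Shared fixtures: synthetic molars rendered to disk and loaded back."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from PIL import Image
from scipy.spatial.distance import cdist

import voletooth as vt


def sym_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    d = cdist(a, b)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def resample_polyline(poly: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, poly[:, 0]), np.interp(t, s, poly[:, 1])])


def truth_semi_px(truth: dict) -> np.ndarray:
    """Ground-truth semiperimeter in raster pixel coordinates, buccal first."""
    tp = np.array(truth["points_px"])
    lab = truth["labels"]
    return tp[lab["a_lingual"] : lab["a_buccal"] + 1][::-1]


def render_and_load(tmp_path, points_mm, scale, style, labels=None, name="spec"):
    """Render an outline, write the PNG, and load it back as an oriented image."""
    raster, truth = vt.render(points_mm, scale, style, labels=labels)
    path = tmp_path / f"{name}.png"
    Image.fromarray(raster).save(path)
    kind = "photo" if style == "filled" else "drawing"
    img = vt.load_specimen_image(path, scale, kind)
    return dataclasses.replace(img, oriented=True), truth


@pytest.fixture(scope="session")
def microtus_template():
    return vt.make_template("microtus-like")


@pytest.fixture(scope="session")
def small_db():
    """6 presets x 6 specimens, sigma = 0.02 mm."""
    return vt.synthetic_database(n_per_species=6, noise_sigma_mm=0.02, seed=11)


@pytest.fixture(scope="session")
def microtus_processed(microtus_template, tmp_path_factory):
    """Rendered (photo) + loaded + extracted microtus template."""
    tmp = tmp_path_factory.mktemp("microtus")
    img, truth = render_and_load(
        tmp, microtus_template.points, 0.01, "filled", microtus_template.labels
    )
    trace = vt.extract_outline(img)
    ann = vt.detect_feature_points(trace)
    return {"img": img, "truth": truth, "trace": trace, "ann": ann}
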