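"""The four affinity-estimation methods against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import voletooth as vt
from voletooth.classifiers import fit_ecoc_svm, fit_fisher_ldc, predict_ldc, predict_svm
from voletooth.errors import DegenerateShapeError, ValidationError
from voletooth.outline_geometry import LandmarkSet
from voletooth.reference_db import SpecimenRecord, build_database


def brute_force_mhd(a, b):
    """O(n*m) double-loop oracle."""
    def directed(p, q):
        return np.mean([min(np.hypot(*(pp - qq)) for qq in q) for pp in p])

    return max(directed(a, b), directed(b, a))


# ---------------------------------------------------------------------------
# MHD
# ---------------------------------------------------------------------------

def test_mhd_identical_sets_is_zero():
    a = np.array([[0.0, 0.0], [1.0, 0.0]])
    assert vt.mhd(a, a) == 0.0


def test_mhd_single_pair_is_euclidean():
    assert vt.mhd(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])) == pytest.approx(5.0)


def test_mhd_empty_set_rejected():
    with pytest.raises(ValidationError):
        vt.mhd(np.empty((0, 2)), np.array([[1.0, 1.0]]))


@pytest.mark.parametrize("seed", range(12))
def test_mhd_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(rng.integers(1, 61), 2))
    b = rng.normal(size=(rng.integers(1, 61), 2))
    assert vt.mhd(a, b) == pytest.approx(brute_force_mhd(a, b), abs=1e-12)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    st.lists(st.tuples(st.integers(-5, 5), st.integers(-5, 5)), min_size=1, max_size=15),
    st.lists(st.tuples(st.integers(-5, 5), st.integers(-5, 5)), min_size=1, max_size=15),
)
def test_mhd_symmetry_nonnegativity_identity(pa, pb):
    a, b = np.array(pa, dtype=float), np.array(pb, dtype=float)
    d = vt.mhd(a, b)
    assert d >= 0.0
    assert d == pytest.approx(vt.mhd(b, a), abs=1e-15)
    if set(map(tuple, pa)) == set(map(tuple, pb)):
        assert d == 0.0
    elif d == 0.0:
        assert set(map(tuple, pa)) == set(map(tuple, pb))


# ---------------------------------------------------------------------------
# helpers to build small landmark databases
# ---------------------------------------------------------------------------

def _lm(coords, sid="q", species="", kind="photo"):
    return LandmarkSet(coords=coords, specimen_id=sid, species=species, source_kind=kind)


def _db_from_arrays(named_arrays):
    recs = []
    for sid, species, coords in named_arrays:
        recs.append(
            SpecimenRecord(
                specimen_id=sid, species=species, landmarks=_lm(coords, sid, species)
            )
        )
    return build_database(recs)


def _gaussian_class_db(n_classes, n_per_class, sep, sigma, seed, n_points=200):
    rng = np.random.default_rng(seed)
    means = [rng.normal(scale=1.0, size=(n_points, 2)) for _ in range(n_classes)]
    entries = []
    for c in range(n_classes):
        for i in range(n_per_class):
            coords = means[c] * sep + rng.normal(0, sigma, size=(n_points, 2))
            entries.append((f"c{c}-{i:02d}", f"species-{c}", coords))
    return _db_from_arrays(entries)


# ---------------------------------------------------------------------------
# classify_mhd
# ---------------------------------------------------------------------------

def test_classify_mhd_recovers_db_member(small_db):
    rec = small_db.records[7]
    sp, d = vt.classify_mhd(rec.landmarks, small_db)
    assert sp == rec.species
    assert d == pytest.approx(0.0, abs=1e-12)


def test_classify_mhd_two_well_separated_species():
    a = vt.truth_landmarks(vt.make_template("microtus-like"))
    b = vt.truth_landmarks(vt.make_template("iberomys-like"))
    db = _db_from_arrays([("a0", "A", a), ("b0", "B", b)])
    rng = np.random.default_rng(3)
    for _ in range(20):
        q = _lm(a + rng.normal(0, 0.05, a.shape))
        assert vt.classify_mhd(q, db)[0] == "A"


def test_classify_mhd_centroid_mode_equals_specimen_mode_for_singletons(small_db):
    singles = _db_from_arrays(
        [(r.specimen_id, r.species, r.landmarks.coords)
         for r in small_db.records if r.specimen_id.endswith("-000")]
    )
    q = small_db.records[10].landmarks
    assert vt.classify_mhd(q, singles, "specimens") == vt.classify_mhd(q, singles, "centroids")


def test_classify_tie_break_is_first_in_db_order():
    c = np.random.default_rng(0).normal(size=(200, 2))
    db = _db_from_arrays([("x2", "B", c.copy()), ("x1", "A", c.copy())])
    sp, _ = vt.classify_mhd(_lm(c), db)
    assert sp == "A"  # records sorted by (species, id): A first
    sp, _, nid = vt.classify_procrustes(_lm(c), db)
    assert (sp, nid) == ("A", "x1")


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def _similarity(coords, theta, s, t, reflect=False):
    r = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    if reflect:
        r = r @ np.diag([1.0, -1.0])
    return coords @ r.T * s + np.asarray(t)


@pytest.mark.parametrize("seed", range(10))
def test_procrustes_similarity_invariance(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(50, 2))
    b = _similarity(
        a,
        theta=rng.uniform(0, 2 * np.pi),
        s=rng.uniform(0.2, 5.0),
        t=rng.normal(size=2) * 10,
        reflect=bool(seed % 2),
    )
    d, _ = vt.procrustes_dist(a, b)
    assert d <= 1e-9


def test_procrustes_rotated_scaled_translated_copy():
    a = vt.truth_landmarks(vt.make_template("microtus-like"))
    b = _similarity(a, np.deg2rad(37), 2.5, (5.0, 5.0))
    assert vt.procrustes_dist(a, b)[0] <= 1e-9


def test_procrustes_mirror_image_allowed():
    a = vt.truth_landmarks(vt.make_template("microtus-like"))
    assert vt.procrustes_dist(a, a * [1.0, -1.0])[0] <= 1e-9


def test_procrustes_degenerate_rejected():
    a = np.zeros((10, 2))
    with pytest.raises(DegenerateShapeError):
        vt.procrustes_dist(a, np.random.default_rng(0).normal(size=(10, 2)))


def grid_search_procrustes(a, b, n_theta=4096):
    """Independent oracle: standardize, then scan rotation x reflection with
    a 1-D scale optimization per angle."""
    def standardize(x):
        x = x - x.mean(axis=0)
        return x / np.linalg.norm(x)

    a_, b_ = standardize(a), standardize(b)

    def cost(theta, reflect):
        r = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        if reflect:
            r = r @ np.diag([1.0, -1.0])
        bb = b_ @ r.T

        def of_scale(s):
            return float(((a_ - s * bb) ** 2).sum())

        res = minimize_scalar(of_scale, bounds=(1e-6, 10.0), method="bounded")
        return res.fun

    best = np.inf
    for reflect in (False, True):
        thetas = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        costs = [cost(t, reflect) for t in thetas]
        k = int(np.argmin(costs))
        res = minimize_scalar(
            lambda t: cost(t, reflect),
            bounds=(thetas[k] - 0.01, thetas[k] + 0.01),
            method="bounded",
        )
        best = min(best, res.fun)
    return best


def test_procrustes_triangle_matches_grid_search_oracle():
    a = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    b = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 1.0]])
    d, _ = vt.procrustes_dist(a, b)
    assert d == pytest.approx(grid_search_procrustes(a, b, n_theta=512), abs=1e-6)


# ---------------------------------------------------------------------------
# Fisher LDC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n_classes", [2, 5, 10])
def test_ldc_canonical_dimension_contract(n_classes):
    """q = min(N-1, p') with ample samples and features."""
    db = _gaussian_class_db(n_classes, n_per_class=12, sep=5.0, sigma=0.5, seed=n_classes)
    model = fit_fisher_ldc(db)
    assert model.q == n_classes - 1
    assert model.pca_components >= model.q
    # discriminant power decreasing
    assert np.all(np.diff(model.eigenvalues) <= 1e-9)


def test_ldc_well_separated_gaussians_loo_100pct():
    """Two classes, means 10 sigma apart: Bayes error ~ 0, LOO = 100%."""
    sigma = 0.1
    db = _gaussian_class_db(2, n_per_class=40, sep=sigma * 10, sigma=sigma, seed=42)
    table = vt.leave_one_out(db, methods=("ldc",), seed=0)
    assert table.totals()["ldc"] == 100.0


def test_ldc_query_at_class_mean_assigned_to_it(small_db):
    model = fit_fisher_ldc(small_db)
    sp = small_db.species[2]
    q = _lm(small_db.centroids[sp])
    pred, dist = predict_ldc(model, q)
    assert pred == sp


# ---------------------------------------------------------------------------
# ECOC-SVM
# ---------------------------------------------------------------------------

def test_svm_learner_count_is_n_choose_2():
    db = _gaussian_class_db(5, n_per_class=4, sep=3.0, sigma=0.3, seed=5)
    model = fit_ecoc_svm(db)
    assert model.n_learners == 10
    assert model.coding.shape == (5, 10)
    # each learner involves exactly one +1 and one -1 class
    assert np.all(np.abs(model.coding).sum(axis=0) == 2)


def test_svm_training_accuracy_on_separable_species():
    a = vt.truth_landmarks(vt.make_template("microtus-like"))
    b = vt.truth_landmarks(vt.make_template("iberomys-like"))
    rng = np.random.default_rng(1)
    entries = []
    for i in range(10):
        entries.append((f"a{i}", "A", a + rng.normal(0, 0.01, a.shape)))
        entries.append((f"b{i}", "B", b + rng.normal(0, 0.01, b.shape)))
    db = _db_from_arrays(entries)
    model = fit_ecoc_svm(db)
    correct = sum(
        predict_svm(model, r.landmarks)[0] == r.species for r in db.records
    )
    assert correct == len(db.records)


def test_svm_single_specimen_class_flagged():
    rng = np.random.default_rng(2)
    entries = [("a0", "A", rng.normal(size=(200, 2)))]
    entries += [(f"b{i}", "B", rng.normal(size=(200, 2))) for i in range(3)]
    model = fit_ecoc_svm(_db_from_arrays(entries))
    assert model.singletons == ["A"]


def test_svm_deterministic_given_seed(small_db):
    q = small_db.records[0].landmarks
    p1 = predict_svm(fit_ecoc_svm(small_db, seed=3), q)
    p2 = predict_svm(fit_ecoc_svm(small_db, seed=3), q)
    assert p1 == p2


# ---------------------------------------------------------------------------
# classify_all
# ---------------------------------------------------------------------------

def test_classify_all_returns_all_methods(small_db):
    res = vt.classify_all(small_db.records[0].landmarks, small_db)
    assert sorted(res.predictions) == ["ldc", "mhd_c", "mhd_v", "procrustes", "svm"]
    assert res.failures == {}
    assert res.nearest_specimen_id is not None
    d = res.to_dict()
    assert {"specimen_id", "predictions", "nearest_specimen_id", "failures"} <= set(d)


def test_classify_all_records_partial_failures():
    rng = np.random.default_rng(0)
    db = _db_from_arrays([("a0", "A", rng.normal(size=(200, 2)))])
    res = vt.classify_all(_lm(rng.normal(size=(200, 2))), db)
    assert "mhd_v" in res.predictions  # distance methods still work
    assert "ldc" in res.failures and "svm" in res.failures


def test_classify_all_empty_db_rejected():
    from voletooth.reference_db import ReferenceDatabase

    with pytest.raises(ValidationError):
        vt.classify_all(_lm(np.zeros((200, 2))), ReferenceDatabase([]))
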