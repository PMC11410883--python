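"""The four affinity-estimation methods for 200-landmark molar shapes.

* ``mhd`` / ``classify_mhd`` — modified Hausdorff distance (mean of directed
  nearest-neighbour distances, maximized over the two directions), against
  every database specimen (HDV) or against per-species centroid shapes (HDC).
* ``procrustes_dist`` / ``classify_procrustes`` — Procrustes dissimilarity
  (residual sum of squares after optimal translation, scaling, rotation and
  reflection), nearest neighbour over the database.
* ``fit_fisher_ldc`` / ``predict_ldc`` — Fisher canonical discriminant:
  canonical variates of the between- vs within-class scatter (after a PCA
  pre-reduction, see below), assignment by Mahalanobis distance in canonical
  space.
* ``fit_ecoc_svm`` / ``predict_svm`` — error-correcting output codes over
  all one-vs-one linear support-vector machines, decoded by minimal
  aggregate hinge loss; uniform class priors, default 0/1 cost.

Feature conventions: every specimen is centred on its own centroid before
any comparison (absolute position in the image is arbitrary) but NOT
rescaled — the images are calibrated, so absolute size is diagnostic among
arvicolines.  LDC/SVM operate on the flattened 400-vector of centred
coordinates.

Because p = 400 exceeds the per-class sample counts of any realistic
reference database, the pooled within-class scatter is singular in the raw
feature space; the LDC therefore first reduces to
p' = min(n - N, 400) principal components retaining >= 99% of the variance,
and the canonical space has q = min(N - 1, p') dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .errors import DegenerateShapeError, ValidationError
from .outline_geometry import LandmarkSet
from .reference_db import ReferenceDatabase

logger = logging.getLogger(__name__)

__all__ = [
    "mhd",
    "classify_mhd",
    "procrustes_dist",
    "classify_procrustes",
    "LdcModel",
    "fit_fisher_ldc",
    "predict_ldc",
    "SvmModel",
    "fit_ecoc_svm",
    "predict_svm",
    "ClassificationResult",
    "classify_all",
]


# ---------------------------------------------------------------------------
# modified Hausdorff distance
# ---------------------------------------------------------------------------

def mhd(a: np.ndarray, b: np.ndarray) -> float:
    """Modified Hausdorff distance between two 2-D point sets (vectorised).

    d(A,B) = mean over a in A of the distance to the nearest b in B;
    MHD(A,B) = max(d(A,B), d(B,A)).  Symmetric, non-negative, zero iff the
    sets are equal; not a metric (no triangle inequality).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValidationError("mhd: point sets must be non-empty")
    d = cdist(a, b)
    return float(max(d.min(axis=1).mean(), d.min(axis=0).mean()))


def _centred(coords: np.ndarray) -> np.ndarray:
    return coords - coords.mean(axis=0)


def classify_mhd(
    query: LandmarkSet, db: ReferenceDatabase, mode: str = "specimens"
) -> tuple[str, float]:
    """Nearest species by modified Hausdorff distance.

    ``specimens`` mode (HDV) compares against every database specimen;
    ``centroids`` mode (HDC) against the per-species mean shapes.  Both the
    query and each reference are centred on their own centroid first.  Ties
    break to the first occurrence in database order.
    """
    if len(db.records) == 0:
        raise ValidationError("empty reference database")
    if mode not in ("specimens", "centroids"):
        raise ValidationError(f"unknown MHD mode {mode!r}")
    q = _centred(query.coords)
    if mode == "specimens":
        dists = [mhd(q, _centred(r.landmarks.coords)) for r in db.records]
        k = int(np.argmin(dists))
        return db.records[k].species, float(dists[k])
    species = list(db.centroids)
    dists = [mhd(q, _centred(db.centroids[s])) for s in species]
    k = int(np.argmin(dists))
    return species[k], float(dists[k])


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

def procrustes_dist(a: LandmarkSet | np.ndarray, b: LandmarkSet | np.ndarray):
    """Procrustes dissimilarity between two corresponding configurations.

    Both configurations are centred at the origin and scaled to unit
    centroid size; the similarity transform (rotation, reflection allowed,
    scaling) minimizing the sum of squared pointwise differences is applied
    to the second.  Returns ``(dissimilarity, transformed_b)`` where the
    transformed copy of ``b`` can be overlaid on the standardized ``a``.
    """
    ca = a.coords if isinstance(a, LandmarkSet) else np.asarray(a, dtype=float)
    cb = b.coords if isinstance(b, LandmarkSet) else np.asarray(b, dtype=float)
    if ca.shape != cb.shape:
        raise ValidationError("procrustes: configurations must have equal shape")
    if np.linalg.norm(_centred(ca)) < 1e-12 or np.linalg.norm(_centred(cb)) < 1e-12:
        raise DegenerateShapeError("procrustes: degenerate (all points coincident)")
    _, mtx2, disparity = _scipy_procrustes(ca, cb)
    return float(disparity), mtx2


def classify_procrustes(
    query: LandmarkSet, db: ReferenceDatabase
) -> tuple[str, float, str]:
    """Nearest database specimen by Procrustes dissimilarity.

    Returns ``(species, dissimilarity, nearest_specimen_id)``; ties break to
    the first occurrence in database order.
    """
    if len(db.records) == 0:
        raise ValidationError("empty reference database")
    dists = [procrustes_dist(query, r.landmarks)[0] for r in db.records]
    k = int(np.argmin(dists))
    return db.records[k].species, float(dists[k]), db.records[k].specimen_id


# ---------------------------------------------------------------------------
# Fisher canonical discriminant (LDC)
# ---------------------------------------------------------------------------

@dataclass
class LdcModel:
    classes: list[str]
    pca: PCA
    pca_components: int  # p': PCA dimensions actually used
    basis: np.ndarray  # (p', q) canonical directions, within-scatter normalized
    class_means: np.ndarray  # (N, q) class projections in canonical space
    within_cov_inv: np.ndarray  # (q, q) inverse pooled within-class covariance
    eigenvalues: np.ndarray  # (q,) discriminant power, decreasing

    @property
    def q(self) -> int:
        return self.basis.shape[1]


def _feature_matrix(db: ReferenceDatabase) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([_centred(r.landmarks.coords).ravel() for r in db.records])
    y = np.array([r.species for r in db.records])
    return x, y


def _query_vector(query: LandmarkSet) -> np.ndarray:
    return _centred(query.coords).ravel()


def fit_fisher_ldc(db: ReferenceDatabase, var_retained: float = 0.99) -> LdcModel:
    """Fit the Fisher canonical discriminant on a reference database.

    PCA pre-reduction to p' = min(n - N, 400) components (further truncated
    at >= ``var_retained`` cumulative variance), then the generalized
    eigenproblem of between-class vs pooled within-class scatter.  The
    q = min(N - 1, p') leading canonical variates are kept; a query is
    assigned to the class with the smallest Mahalanobis distance in
    canonical space.
    """
    x, y = _feature_matrix(db)
    classes = sorted(set(y))
    n, p = x.shape
    n_classes = len(classes)
    if n_classes < 2:
        raise ValidationError("LDC needs at least two species")
    cap = min(n - n_classes, p)
    if cap < 1:
        raise ValidationError("LDC needs more specimens than species")
    pca = PCA(n_components=cap, svd_solver="full")
    xp = pca.fit_transform(x)
    evr = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(evr, var_retained) + 1)
    keep = min(max(keep, n_classes - 1), cap)  # never below q target
    xp = xp[:, :keep]
    pca_components = keep

    grand = xp.mean(axis=0)
    s_w = np.zeros((keep, keep))
    s_b = np.zeros((keep, keep))
    for c in classes:
        xc = xp[y == c]
        mu = xc.mean(axis=0)
        dev = xc - mu
        s_w += dev.T @ dev
        dm = (mu - grand)[:, None]
        s_b += len(xc) * (dm @ dm.T)
    # guard a singular pooled scatter (e.g. duplicated specimens)
    if np.linalg.matrix_rank(s_w) < keep:
        ridge = 1e-8 * np.trace(s_w) if np.trace(s_w) > 0 else 1e-8
        s_w = s_w + ridge * np.eye(keep)
        logger.info("LDC: singular within-class scatter; ridge %.3g added", ridge)

    evals, evecs = eigh(s_b, s_w)  # ascending; vectors are S_w-normalized
    q = min(n_classes - 1, pca_components)
    order = np.argsort(evals)[::-1][:q]
    basis = evecs[:, order]
    evals = evals[order]

    z = xp @ basis
    class_means = np.stack([z[y == c].mean(axis=0) for c in classes])
    dev = np.concatenate([z[y == c] - z[y == c].mean(axis=0) for c in classes])
    cov = dev.T @ dev / max(n - n_classes, 1)
    if np.linalg.matrix_rank(cov) < q:
        cov = cov + 1e-8 * max(np.trace(cov), 1.0) * np.eye(q)
    return LdcModel(
        classes=classes,
        pca=pca,
        pca_components=pca_components,
        basis=basis,
        class_means=class_means,
        within_cov_inv=np.linalg.inv(cov),
        eigenvalues=evals,
    )


def predict_ldc(model: LdcModel, query: LandmarkSet) -> tuple[str, float]:
    """Assign a query to the class with minimal canonical-space Mahalanobis
    distance; returns ``(species, distance)``."""
    v = _query_vector(query)
    xp = model.pca.transform(v[None, :])[0][: model.pca_components]
    z = xp @ model.basis
    diff = model.class_means - z
    d2 = np.einsum("ij,jk,ik->i", diff, model.within_cov_inv, diff)
    k = int(np.argmin(d2))
    return model.classes[k], float(np.sqrt(max(d2[k], 0.0)))


# ---------------------------------------------------------------------------
# ECOC-SVM
# ---------------------------------------------------------------------------

@dataclass
class SvmModel:
    classes: list[str]
    coding: np.ndarray  # (N, L) one-vs-one coding matrix with entries +1/-1/0
    learners: list[SVC]
    mean: np.ndarray  # feature standardization
    std: np.ndarray
    singletons: list[str] = field(default_factory=list)  # classes with one specimen

    @property
    def n_learners(self) -> int:
        return len(self.learners)


def fit_ecoc_svm(db: ReferenceDatabase, c: float = 1.0, seed: int = 0) -> SvmModel:
    """Train one-vs-one linear SVMs under a one-vs-one ECOC coding.

    Features are the flattened centred coordinates, standardized per
    feature over the training set.  N classes yield N(N-1)/2 binary
    learners.  Classes with a single specimen are trained but flagged.
    """
    x, y = _feature_matrix(db)
    classes = sorted(set(y))
    n_classes = len(classes)
    if n_classes < 2:
        raise ValidationError("SVM needs at least two species")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std < 1e-12] = 1.0
    xs = (x - mean) / std

    singletons = [cl for cl in classes if np.sum(y == cl) == 1]
    if singletons:
        logger.warning("SVM: single-specimen classes flagged: %s", singletons)

    pairs = [(i, j) for i in range(n_classes) for j in range(i + 1, n_classes)]
    coding = np.zeros((n_classes, len(pairs)))
    learners: list[SVC] = []
    for idx, (i, j) in enumerate(pairs):
        coding[i, idx] = 1.0
        coding[j, idx] = -1.0
        sel = (y == classes[i]) | (y == classes[j])
        target = np.where(y[sel] == classes[i], 1, -1)
        clf = SVC(kernel="linear", C=c, random_state=seed)
        clf.fit(xs[sel], target)
        learners.append(clf)
    return SvmModel(
        classes=classes,
        coding=coding,
        learners=learners,
        mean=mean,
        std=std,
        singletons=singletons,
    )


def predict_svm(model: SvmModel, query: LandmarkSet) -> tuple[str, float]:
    """ECOC decoding: the class minimizing the aggregate binary hinge loss
    over all learners; returns ``(species, negative_loss_margin)``."""
    v = (_query_vector(query) - model.mean) / model.std
    f = np.array([clf.decision_function(v[None, :])[0] for clf in model.learners])
    m = model.coding
    losses = (np.abs(m) * np.maximum(0.0, 1.0 - m * f[None, :]) / 2.0).sum(axis=1)
    losses /= np.abs(m).sum(axis=1)
    k = int(np.argmin(losses))
    return model.classes[k], float(-losses[k])


# ---------------------------------------------------------------------------
# combined call
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    """Per-method species assignments for one query specimen."""

    specimen_id: str
    predictions: dict  # method -> {"species": str, "score": float}
    nearest_specimen_id: str | None = None
    failures: dict = field(default_factory=dict)  # method -> reason

    METHODS = ("mhd_v", "mhd_c", "procrustes", "ldc", "svm")

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "predictions": self.predictions,
            "nearest_specimen_id": self.nearest_specimen_id,
            "failures": self.failures,
        }


def classify_all(
    query: LandmarkSet,
    db: ReferenceDatabase,
    ldc_model: LdcModel | None = None,
    svm_model: SvmModel | None = None,
    seed: int = 0,
) -> ClassificationResult:
    """Run all five methods; failed methods are recorded, not raised,
    as long as at least one method succeeds."""
    if len(db.records) == 0:
        raise ValidationError("empty reference database")
    preds: dict = {}
    failures: dict = {}
    nearest = None

    def attempt(name, fn):
        nonlocal nearest
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - failures are reported per method
            failures[name] = str(exc)
            return
        preds[name] = out

    attempt("mhd_v", lambda: dict(zip(("species", "score"), classify_mhd(query, db, "specimens"))))
    attempt("mhd_c", lambda: dict(zip(("species", "score"), classify_mhd(query, db, "centroids"))))

    def _proc():
        sp, d, nid = classify_procrustes(query, db)
        return {"species": sp, "score": d, "nearest": nid}

    attempt("procrustes", _proc)
    if "procrustes" in preds:
        nearest = preds["procrustes"].pop("nearest")

    def _ldc():
        model = ldc_model if ldc_model is not None else fit_fisher_ldc(db)
        return dict(zip(("species", "score"), predict_ldc(model, query)))

    attempt("ldc", _ldc)

    def _svm():
        model = svm_model if svm_model is not None else fit_ecoc_svm(db, seed=seed)
        return dict(zip(("species", "score"), predict_svm(model, query)))

    attempt("svm", _svm)

    if not preds:
        raise ValidationError(f"all classification methods failed: {failures}")
    return ClassificationResult(
        specimen_id=query.specimen_id,
        predictions=preds,
        nearest_specimen_id=nearest,
        failures=failures,
    )
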