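"""Leave-one-out accuracy tables and the species-exemplar similarity cluster.

``leave_one_out`` classifies every database specimen against the database
minus itself, refitting the trained models (LDC, SVM) per fold, and
aggregates accuracies by species x method and by source kind (photographs
vs drawings).  The pairwise distance matrices used by the nearest-neighbour
methods (MHD, Procrustes) are precomputed once; excluding the held-out
specimen then reduces to masking its column, which keeps the fold loop fast
without ever letting a specimen match itself.

``exemplar_cluster`` picks, per species, one specimen that every method
classifies correctly (the one nearest its species centroid by Procrustes),
computes the pairwise Procrustes dissimilarities among these exemplars and
links them by UPGMA.  The tree summarizes geometric similarity between the
species as represented in the database — it has no phylogenetic meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .classifiers import (
    fit_ecoc_svm,
    fit_fisher_ldc,
    mhd,
    predict_ldc,
    predict_svm,
    procrustes_dist,
)
from .errors import ValidationError
from .reference_db import ReferenceDatabase

__all__ = ["AccuracyTable", "leave_one_out", "exemplar_cluster"]

ALL_METHODS = ("mhd_v", "mhd_c", "procrustes", "ldc", "svm")


@dataclass
class AccuracyTable:
    """Leave-one-out results: per-specimen predictions and aggregates."""

    predictions: pd.DataFrame  # specimen_id, species, source_kind, <method> columns
    methods: list[str]
    seed: int

    def by_species(self) -> pd.DataFrame:
        """Correct counts, totals and percentages per species x method."""
        rows = []
        for sp, grp in self.predictions.groupby("species"):
            row: dict = {"species": sp, "total": len(grp)}
            for m in self.methods:
                correct = int((grp[m] == grp["species"]).sum())
                row[f"{m}_correct"] = correct
                row[f"{m}_pct"] = 100.0 * correct / len(grp)
            rows.append(row)
        return pd.DataFrame(rows).set_index("species")

    def by_source(self) -> pd.DataFrame:
        """Correct counts per species x source kind x method."""
        rows = []
        for (sp, src), grp in self.predictions.groupby(["species", "source_kind"]):
            row = {"species": sp, "source_kind": src, "total": len(grp)}
            for m in self.methods:
                row[f"{m}_correct"] = int((grp[m] == grp["species"]).sum())
            rows.append(row)
        return pd.DataFrame(rows)

    def totals(self) -> dict[str, float]:
        """Overall percentage per method (pooled over species)."""
        out = {}
        for m in self.methods:
            out[m] = float(
                100.0 * (self.predictions[m] == self.predictions["species"]).mean()
            )
        return out

    def all_correct_ids(self) -> list[str]:
        ok = np.ones(len(self.predictions), dtype=bool)
        for m in self.methods:
            ok &= (self.predictions[m] == self.predictions["species"]).to_numpy()
        return self.predictions.loc[ok, "specimen_id"].tolist()


def _pairwise_matrices(db: ReferenceDatabase, need_mhd: bool, need_proc: bool):
    n = len(db.records)
    centred = [r.landmarks.centred() for r in db.records]
    d_mhd = np.zeros((n, n)) if need_mhd else None
    d_proc = np.zeros((n, n)) if need_proc else None
    for i in range(n):
        for j in range(i + 1, n):
            if need_mhd:
                d_mhd[i, j] = d_mhd[j, i] = mhd(centred[i], centred[j])
            if need_proc:
                d = procrustes_dist(db.records[i].landmarks, db.records[j].landmarks)[0]
                d_proc[i, j] = d_proc[j, i] = d
    return d_mhd, d_proc


def leave_one_out(
    db: ReferenceDatabase,
    methods: tuple[str, ...] = ALL_METHODS,
    seed: int = 0,
) -> AccuracyTable:
    """Leave-one-out cross-validation over the whole database.

    Species with a single specimen cannot be scored against their own
    species and are excluded from the table (logged via the returned
    frame's attrs).  Deterministic given (db, seed).
    """
    bad = [m for m in methods if m not in ALL_METHODS]
    if bad:
        raise ValidationError(f"unknown methods: {bad}")
    species_counts = {sp: sum(r.species == sp for r in db.records) for sp in db.species}
    skipped = [sp for sp, c in species_counts.items() if c < 2]
    records = [r for r in db.records if species_counts[r.species] >= 2]
    if not records:
        raise ValidationError("no species with >= 2 specimens")
    eval_db = ReferenceDatabase(records)
    n = len(records)
    labels = np.array([r.species for r in records])

    d_mhd, d_proc = _pairwise_matrices(
        eval_db, need_mhd="mhd_v" in methods, need_proc="procrustes" in methods
    )

    rows = []
    for i, rec in enumerate(records):
        fold_db = eval_db.without(rec.specimen_id)
        row = {
            "specimen_id": rec.specimen_id,
            "species": rec.species,
            "source_kind": rec.landmarks.source_kind,
        }
        others = np.array([j for j in range(n) if j != i])
        if "mhd_v" in methods:
            k = others[np.argmin(d_mhd[i, others])]
            row["mhd_v"] = labels[k]
        if "mhd_c" in methods:
            q = rec.landmarks.centred()
            cents = fold_db.centroids
            sps = list(cents)
            dists = [mhd(q, cents[s] - cents[s].mean(axis=0)) for s in sps]
            row["mhd_c"] = sps[int(np.argmin(dists))]
        if "procrustes" in methods:
            k = others[np.argmin(d_proc[i, others])]
            row["procrustes"] = labels[k]
            row["nearest_specimen_id"] = records[k].specimen_id
        if "ldc" in methods:
            model = fit_fisher_ldc(fold_db)
            row["ldc"] = predict_ldc(model, rec.landmarks)[0]
        if "svm" in methods:
            model = fit_ecoc_svm(fold_db, seed=seed)
            row["svm"] = predict_svm(model, rec.landmarks)[0]
        rows.append(row)

    preds = pd.DataFrame(rows)
    preds.attrs["skipped_species"] = skipped
    preds.attrs["seed"] = seed
    return AccuracyTable(predictions=preds, methods=list(methods), seed=seed)


# ---------------------------------------------------------------------------
# exemplar cluster
# ---------------------------------------------------------------------------

def _linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    # ultrametric convention: a join at cophenetic distance d sits at height
    # d/2, so two leaves merge with branch lengths of half their distance
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(z):
        a, b = int(a), int(b)
        la = h / 2.0 - heights[a]
        lb = h / 2.0 - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.9g},{nodes[b]}:{lb:.9g})"
        heights[n + k] = h / 2.0
    return nodes[n + len(z) - 1] + ";"


def exemplar_cluster(
    db: ReferenceDatabase,
    loo: AccuracyTable | None = None,
    methods: tuple[str, ...] = ALL_METHODS,
    linkage_method: str = "average",
    seed: int = 0,
) -> dict:
    """UPGMA cluster of one all-methods-correct exemplar per species.

    Returns a dict with the newick string, the exemplar ids, the pairwise
    Procrustes dissimilarity matrix and a disclaimer.  Species without any
    all-correct specimen are dropped with a warning entry.
    """
    if loo is None:
        loo = leave_one_out(db, methods=methods, seed=seed)
    ok_ids = set(loo.all_correct_ids())
    exemplars = []
    dropped = []
    for sp in db.species:
        candidates = [
            r for r in db.records if r.species == sp and r.specimen_id in ok_ids
        ]
        if not candidates:
            dropped.append(sp)
            continue
        cent = db.centroids[sp]
        dists = [procrustes_dist(r.landmarks.coords, cent)[0] for r in candidates]
        exemplars.append(candidates[int(np.argmin(dists))])
    if len(exemplars) < 2:
        raise ValidationError("fewer than 2 species have an all-correct exemplar")

    m = len(exemplars)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = procrustes_dist(
                exemplars[i].landmarks, exemplars[j].landmarks
            )[0]
    z = linkage(squareform(d), method=linkage_method)
    species = [r.species for r in exemplars]
    return {
        "newick": _linkage_to_newick(z, species),
        "exemplars": {r.species: r.specimen_id for r in exemplars},
        "species": species,
        "distance_matrix": d.tolist(),
        "dropped_species": dropped,
        "linkage": linkage_method,
        "disclaimer": (
            "geometric similarity of database shapes only; "
            "no biological or phylogenetic significance"
        ),
    }
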