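"""Persistent reference database of labelled 200-landmark specimens.

The on-disk layout is a directory with

* ``landmarks.csv`` — one row per landmark with header
  ``specimen_id,species,source_kind,point_index,x_mm,y_mm`` (200 rows per
  specimen);
* ``centroids.csv`` — same columns (minus source_kind) for the per-species
  mean shapes;
* ``meta.json`` — record/species counts and format version.

Open, diff-able text formats replace the original binary containers.
Centroids are the pointwise arithmetic mean over each species' raw
(calibrated, oriented) landmark coordinates — no superimposition is applied
before averaging.  Records are kept sorted by (species, specimen_id) so
database order, and therefore every tie-break, is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .outline_geometry import LandmarkSet

__all__ = [
    "SpecimenRecord",
    "ReferenceDatabase",
    "build_database",
    "species_centroids",
    "db_save",
    "db_load",
]

N_LANDMARKS = 200
#: database storage is lossless (round-trips float64 exactly); 9-significant-
#: digit formatting is reserved for human-facing reports
FLOAT_FMT = "%.17g"
_CENTROID_TOL = 1e-9


@dataclass(frozen=True)
class SpecimenRecord:
    specimen_id: str
    species: str
    landmarks: LandmarkSet
    provenance: str = ""

    def validate(self) -> None:
        if not self.species:
            raise ValidationError(f"record {self.specimen_id!r}: species is empty")
        if len(self.landmarks) != N_LANDMARKS:
            raise ValidationError(
                f"record {self.specimen_id!r}: {len(self.landmarks)} landmarks "
                f"(expected {N_LANDMARKS})"
            )


@dataclass
class ReferenceDatabase:
    records: list[SpecimenRecord] = field(default_factory=list)

    def __post_init__(self):
        self.records = sorted(self.records, key=lambda r: (r.species, r.specimen_id))
        self._centroids: dict[str, np.ndarray] | None = None

    @property
    def species(self) -> list[str]:
        return sorted({r.species for r in self.records})

    @property
    def centroids(self) -> dict[str, np.ndarray]:
        if self._centroids is None:
            self._centroids = species_centroids(self)
        return self._centroids

    def validate(self) -> None:
        errors = []
        seen: set[str] = set()
        for r in self.records:
            try:
                r.validate()
            except ValidationError as exc:
                errors.append(str(exc))
            if r.specimen_id in seen:
                errors.append(f"duplicate specimen_id {r.specimen_id!r}")
            seen.add(r.specimen_id)
        if errors:
            raise ValidationError("; ".join(errors))

    def without(self, specimen_id: str) -> "ReferenceDatabase":
        """A copy excluding one specimen (for leave-one-out folds)."""
        return ReferenceDatabase(
            [r for r in self.records if r.specimen_id != specimen_id]
        )


def build_database(records: list[SpecimenRecord]) -> ReferenceDatabase:
    db = ReferenceDatabase(records)
    db.validate()
    return db


def species_centroids(db: ReferenceDatabase) -> dict[str, np.ndarray]:
    """Pointwise mean shape per species over aligned landmark indices."""
    if not db.records:
        raise ValidationError("empty database has no centroids")
    out: dict[str, np.ndarray] = {}
    for sp in db.species:
        stack = np.stack(
            [r.landmarks.coords for r in db.records if r.species == sp]
        )
        out[sp] = stack.mean(axis=0)
    return out


def _records_frame(db: ReferenceDatabase) -> pd.DataFrame:
    rows = []
    for r in db.records:
        c = r.landmarks.coords
        rows.append(
            pd.DataFrame(
                {
                    "specimen_id": r.specimen_id,
                    "species": r.species,
                    "source_kind": r.landmarks.source_kind,
                    "point_index": np.arange(len(c)),
                    "x_mm": c[:, 0],
                    "y_mm": c[:, 1],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def db_save(db: ReferenceDatabase, path: str | Path) -> Path:
    """Write the database to a directory (created if needed)."""
    db.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _records_frame(db).to_csv(path / "landmarks.csv", index=False, float_format=FLOAT_FMT)
    cent_rows = []
    for sp, c in db.centroids.items():
        cent_rows.append(
            pd.DataFrame(
                {
                    "species": sp,
                    "point_index": np.arange(len(c)),
                    "x_mm": c[:, 0],
                    "y_mm": c[:, 1],
                }
            )
        )
    pd.concat(cent_rows, ignore_index=True).to_csv(
        path / "centroids.csv", index=False, float_format=FLOAT_FMT
    )
    meta = {
        "format": "voletooth-refdb-1",
        "n_records": len(db.records),
        "n_landmarks": N_LANDMARKS,
        "species": {sp: sum(r.species == sp for r in db.records) for sp in db.species},
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def db_load(path: str | Path) -> ReferenceDatabase:
    """Load a database directory; validates records and cross-checks the
    stored centroids against freshly recomputed ones (tolerance 1e-9 mm)."""
    path = Path(path)
    f = path / "landmarks.csv"
    if not f.exists():
        raise ValidationError(f"no landmarks.csv under {path}")
    df = pd.read_csv(f, float_precision="round_trip")
    required = {"specimen_id", "species", "source_kind", "point_index", "x_mm", "y_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"landmarks.csv lacks columns: {sorted(missing)}")
    records = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("point_index")
        coords = grp[["x_mm", "y_mm"]].to_numpy(dtype=float)
        lm = LandmarkSet(
            coords=coords,
            specimen_id=str(sid),
            species=str(grp["species"].iloc[0]),
            source_kind=str(grp["source_kind"].iloc[0]),
        )
        records.append(
            SpecimenRecord(specimen_id=str(sid), species=str(grp["species"].iloc[0]), landmarks=lm)
        )
    db = build_database(records)
    cf = path / "centroids.csv"
    if cf.exists():
        cdf = pd.read_csv(cf, float_precision="round_trip")
        for sp, grp in cdf.groupby("species", sort=False):
            stored = grp.sort_values("point_index")[["x_mm", "y_mm"]].to_numpy(dtype=float)
            fresh = db.centroids.get(str(sp))
            if fresh is None or not np.allclose(stored, fresh, atol=_CENTROID_TOL * 10):
                raise ValidationError(
                    f"stored centroid for {sp!r} disagrees with recomputed centroid"
                )
    return db


def landmarks_to_csv(lm: LandmarkSet, path: str | Path) -> None:
    """Write a single specimen's landmarks in the database CSV schema."""
    c = lm.coords
    pd.DataFrame(
        {
            "specimen_id": lm.specimen_id,
            "species": lm.species,
            "source_kind": lm.source_kind,
            "point_index": np.arange(len(c)),
            "x_mm": c[:, 0],
            "y_mm": c[:, 1],
        }
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def landmarks_from_csv(path: str | Path) -> list[LandmarkSet]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("point_index")
        out.append(
            LandmarkSet(
                coords=grp[["x_mm", "y_mm"]].to_numpy(dtype=float),
                specimen_id=str(sid),
                species=str(grp["species"].iloc[0]) if not grp["species"].isna().all() else "",
                source_kind=str(grp["source_kind"].iloc[0]),
            )
        )
    return out
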