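"""Cohort container and tabular I/O.

A cohort is a feature matrix ``X`` (n observations x d features) together with
per-observation metadata: each row is one lymph node observed in one CT phase
(staging, planning or restaging), carries the node and patient identifiers and
the node's class label (reactive / pathologic / ecs).  All observations of a
node share its label and patient — the repeated-measure structure the
evaluation machinery must respect.

Files are comma-separated UTF-8 with a header; metadata columns come first,
then features in manifest order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .manifest import FeatureManifest

PHASES = ("staging", "planning", "restaging")
LABELS = ("reactive", "pathologic", "ecs")

#: default metadata column names in tabular files
META_COLUMNS = ("observation_id", "node_id", "patient_id", "phase", "label")


class CohortError(ValueError):
    """Raised when a cohort violates a structural invariant."""


@dataclass(frozen=True)
class ObservationMeta:
    observation_id: str
    node_id: str
    patient_id: str
    phase: str
    label: str

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise CohortError(f"phase {self.phase!r} not in {PHASES}")
        if self.label not in LABELS:
            raise CohortError(f"label {self.label!r} not in {LABELS}")


@dataclass
class Cohort:
    """Validated feature matrix + metadata.

    Invariants: X is n x d with d == len(manifest) and n == len(meta); X is
    finite; observation ids are unique; every node carries exactly one label
    and one patient across its observations.
    """

    X: np.ndarray
    manifest: FeatureManifest
    meta: list[ObservationMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise CohortError("X must be 2-dimensional")
        n, d = self.X.shape
        if d != len(self.manifest):
            raise CohortError(
                f"X has {d} columns but manifest has {len(self.manifest)} names"
            )
        if n != len(self.meta):
            raise CohortError(f"X has {n} rows but meta has {len(self.meta)} entries")
        if n and not np.isfinite(self.X).all():
            bad = np.argwhere(~np.isfinite(self.X))[0]
            raise CohortError(
                f"non-finite feature value at row {bad[0]}, "
                f"column {self.manifest.names[bad[1]]!r}"
            )
        obs_ids = [m.observation_id for m in self.meta]
        if len(set(obs_ids)) != len(obs_ids):
            raise CohortError("duplicate observation_id")
        node_label: dict[str, tuple[str, str]] = {}
        for m in self.meta:
            prev = node_label.setdefault(m.node_id, (m.label, m.patient_id))
            if prev != (m.label, m.patient_id):
                raise CohortError(
                    f"node {m.node_id!r} carries conflicting label/patient: "
                    f"{prev} vs {(m.label, m.patient_id)}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.label for m in self.meta], dtype=object)

    @property
    def node_ids(self) -> np.ndarray:
        return np.array([m.node_id for m in self.meta], dtype=object)

    def node_label_map(self) -> dict[str, str]:
        return {m.node_id: m.label for m in self.meta}

    def feature_index(self, names: Sequence[str]) -> np.ndarray:
        lookup = {n: i for i, n in enumerate(self.manifest.names)}
        try:
            return np.array([lookup[n] for n in names], dtype=int)
        except KeyError as e:
            raise KeyError(f"feature {e.args[0]!r} not in manifest") from None

    def select_features(self, names: Sequence[str]) -> "Cohort":
        idx = self.feature_index(names)
        return Cohort(self.X[:, idx], self.manifest.subset(list(names)), list(self.meta))

    def select_rows(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Cohort(self.X[idx], self.manifest, [self.meta[i] for i in idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "observation_id": [m.observation_id for m in self.meta],
                "node_id": [m.node_id for m in self.meta],
                "patient_id": [m.patient_id for m in self.meta],
                "phase": [m.phase for m in self.meta],
                "label": [m.label for m in self.meta],
            }
        )
        feat = pd.DataFrame(self.X, columns=list(self.manifest.names))
        return pd.concat([df, feat.set_index(df.index)], axis=1)


def infer_manifest(names: Sequence[str]) -> FeatureManifest:
    """Build a manifest from column names, tagging by the family prefix.

    Unrecognized prefixes are tagged ``firstorder`` — the family tag only
    matters for family-level reporting, never for the selection mathematics.
    """
    family = {}
    for n in names:
        prefix = n.split("_", 1)[0]
        family[n] = prefix if prefix in {
            "firstorder", "shape3d", "shape2d", "glcm", "glrlm", "glszm",
            "gldm", "ngtdm",
        } else "firstorder"
    return FeatureManifest(tuple(names), family)


def read_cohort(path: str | Path, schema: dict[str, str] | None = None) -> Cohort:
    """Read a cohort from a CSV file.

    Parameters
    ----------
    path:
        CSV file with a header row.
    schema:
        Maps the canonical metadata field names (``observation_id``,
        ``node_id``, ``patient_id``, ``phase``, ``label``) to the file's
        column names.  Defaults to the identity mapping.  Every column not
        named in the schema is treated as a feature, in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = schema or {c: c for c in META_COLUMNS}
    missing = [c for c in META_COLUMNS if c not in schema]
    if missing:
        raise CohortError(f"schema missing metadata fields: {missing}")
    df = pd.read_csv(path, dtype={schema[c]: str for c in META_COLUMNS},
                     float_precision="round_trip")
    absent = [schema[c] for c in META_COLUMNS if schema[c] not in df.columns]
    if absent:
        raise CohortError(f"file {path} missing metadata columns: {absent}")
    meta_cols = [schema[c] for c in META_COLUMNS]
    feature_cols = [c for c in df.columns if c not in meta_cols]
    X = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, c in enumerate(feature_cols):
        col = pd.to_numeric(df[c], errors="coerce")
        bad = col.isna() & df[c].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise CohortError(
                f"non-numeric feature value at row {row}, column {c!r}: "
                f"{df[c].iloc[row]!r}"
            )
        if col.isna().any():
            row = int(col.isna().idxmax())
            raise CohortError(f"missing feature value at row {row}, column {c!r}")
        X[:, j] = col.to_numpy()
    meta = [
        ObservationMeta(
            observation_id=str(r[schema["observation_id"]]),
            node_id=str(r[schema["node_id"]]),
            patient_id=str(r[schema["patient_id"]]),
            phase=str(r[schema["phase"]]),
            label=str(r[schema["label"]]),
        )
        for _, r in df[meta_cols].iterrows()
    ]
    return Cohort(X, infer_manifest(feature_cols), meta)


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to CSV: metadata columns first, then manifest order.

    Floats are written with ``repr`` round-trip precision so that
    ``read_cohort(write_cohort(c)) == c`` exactly.
    """
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def cohorts_equal(a: Cohort, b: Cohort) -> bool:
    return (
        a.manifest.names == b.manifest.names
        and a.meta == b.meta
        and a.X.shape == b.X.shape
        and np.array_equal(a.X, b.X)
    )
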