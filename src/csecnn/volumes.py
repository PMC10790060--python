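"""Reference normalization of CSE matrices and seed-ROI volume painting.

Each subject's raw entropy matrix is z-scored entrywise against the mean
and standard deviation of a reference group — the non-suicidal subjects —
so that 0 means "at the reference mean".  Row ``i`` of the normalized
matrix is then painted into atlas space: every voxel of region k receives
the entry (i, k), producing one 3-D "CSE volume" per seed region.  These
volumes are the classifier inputs.

To avoid information leaking from test subjects into the features, the
default cross-validation mode fits the reference statistics on
training-fold reference subjects only; a "global" mode using the whole
reference group is available for comparison.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .entropy import RawCSEMatrix
from .simulate import AtlasVolume

__all__ = [
    "ReferenceStats",
    "NormalizedCSEMatrix",
    "CSEVolume",
    "fit_reference_stats",
    "normalize_matrix",
    "paint_cse_volume",
    "build_subject_volumes",
    "readback_row",
    "ReferenceNormalizer",
]


@dataclass
class ReferenceStats:
    """Entrywise mean and sample SD of the reference group's CSE matrices."""

    mean_matrix: np.ndarray
    sd_matrix: np.ndarray
    n_reference: int
    reference_ids: list[str]

    def __post_init__(self) -> None:
        self.mean_matrix = np.asarray(self.mean_matrix, dtype=float)
        self.sd_matrix = np.asarray(self.sd_matrix, dtype=float)
        if self.mean_matrix.shape != self.sd_matrix.shape:
            raise ValueError("mean and sd matrices must share a shape")
        if np.any(self.sd_matrix < 0):
            raise ValueError("sd entries must be nonnegative")

    def content_hash(self) -> str:
        """Stable digest for leakage audits."""
        h = hashlib.sha256()
        h.update(self.mean_matrix.tobytes())
        h.update(self.sd_matrix.tobytes())
        h.update(",".join(sorted(self.reference_ids)).encode())
        return h.hexdigest()


@dataclass
class NormalizedCSEMatrix:
    subject_id: str
    values: np.ndarray
    reference: str = ""
    roi_labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.roi_labels:
            self.roi_labels = list(range(1, self.values.shape[0] + 1))


@dataclass
class CSEVolume:
    """3-D grid holding one seed region's normalized entropy profile."""

    values: np.ndarray
    seed_roi: int
    atlas_id: str = "atlas"
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("CSE volume must be 3-D")


def fit_reference_stats(
    matrices: Iterable[RawCSEMatrix],
    reference_ids: Sequence[str],
) -> ReferenceStats:
    """Entrywise mean and sample SD (n-1) over the reference subjects only."""
    reference_ids = list(reference_ids)
    if not reference_ids:
        raise ValueError("reference_ids must be nonempty")
    by_id = {m.subject_id: m for m in matrices}
    missing = [sid for sid in reference_ids if sid not in by_id]
    if missing:
        raise ValueError(f"reference subjects without matrices: {missing}")
    stack = np.stack([by_id[sid].values for sid in reference_ids])
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 reference subjects for a sample SD")
    return ReferenceStats(
        mean_matrix=stack.mean(axis=0),
        sd_matrix=stack.std(axis=0, ddof=1),
        n_reference=stack.shape[0],
        reference_ids=reference_ids,
    )


def normalize_matrix(raw: RawCSEMatrix, stats: ReferenceStats) -> NormalizedCSEMatrix:
    """Entrywise z-score against the reference; zero-SD entries map to 0."""
    if raw.values.shape != stats.mean_matrix.shape:
        raise ValueError(
            f"matrix shape {raw.values.shape} does not match "
            f"reference {stats.mean_matrix.shape}"
        )
    centered = raw.values - stats.mean_matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(stats.sd_matrix > 0, centered / stats.sd_matrix, 0.0)
    return NormalizedCSEMatrix(
        subject_id=raw.subject_id,
        values=z,
        reference=f"ref-n{stats.n_reference}",
        roi_labels=list(raw.roi_labels),
    )


def paint_cse_volume(
    matrix: NormalizedCSEMatrix, seed_roi: int, atlas: AtlasVolume
) -> CSEVolume:
    """Paint row ``seed_roi`` of the matrix into atlas space.

    Every voxel labelled k receives entry (seed_roi, k); background voxels
    carry 0, which after normalization is the reference mean and therefore
    uninformative.
    """
    labels = atlas.labels
    if seed_roi not in labels:
        raise ValueError(f"seed ROI {seed_roi} not among atlas labels")
    if len(labels) != matrix.values.shape[0]:
        raise ValueError(
            f"atlas has {len(labels)} labels but matrix has "
            f"{matrix.values.shape[0]} rows"
        )
    row = matrix.values[matrix.roi_labels.index(seed_roi)]
    lookup = np.zeros(max(labels) + 1)
    for col, label in enumerate(matrix.roi_labels):
        lookup[label] = row[col]
    values = lookup[atlas.data]
    return CSEVolume(
        values=values, seed_roi=seed_roi, atlas_id=atlas.atlas_id,
        affine=atlas.affine.copy(),
    )


def build_subject_volumes(
    matrix: NormalizedCSEMatrix, atlas: AtlasVolume
) -> list[CSEVolume]:
    """One painted volume per seed region, in ascending label order."""
    return [paint_cse_volume(matrix, seed, atlas) for seed in atlas.labels]


def readback_row(volume: CSEVolume, atlas: AtlasVolume) -> np.ndarray:
    """Recover the painted matrix row by averaging within each region."""
    return np.array(
        [volume.values[atlas.data == label].mean() for label in atlas.labels]
    )


class ReferenceNormalizer:
    """Transformer z-scoring CSE matrices against a reference group.

    ``fit`` consumes the reference subjects' raw matrices (optionally
    selected by ``reference_ids`` from a larger collection); ``transform``
    normalizes any collection of matrices against the fitted statistics.
    Fitted state lives in ``stats_``.
    """

    def __init__(self, reference_ids: Sequence[str] | None = None):
        self.reference_ids = reference_ids

    def fit(self, X: Iterable[RawCSEMatrix], y=None) -> "ReferenceNormalizer":
        X = list(X)
        ids = list(self.reference_ids) if self.reference_ids is not None else [
            m.subject_id for m in X
        ]
        self.stats_ = fit_reference_stats(X, ids)
        return self

    def transform(self, X):
        if not hasattr(self, "stats_"):
            raise RuntimeError("ReferenceNormalizer is not fitted")
        if isinstance(X, RawCSEMatrix):
            return normalize_matrix(X, self.stats_)
        return [normalize_matrix(m, self.stats_) for m in X]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {"reference_ids": self.reference_ids}

    def set_params(self, **kwargs) -> "ReferenceNormalizer":
        for key, value in kwargs.items():
            if key != "reference_ids":
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self
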