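"""Per-vertex feature matrices: assembly, cohort min-max scaling, noise augmentation.

The feature vector of a vertex concatenates, in this fixed order, whichever
of the following the :class:`FeatureSpec` enables: the (x, y, z) coordinates
(3), cortical thickness (1), curvature (1), and the 642-long conductance
connectivity row — up to d = 647 with everything enabled.

Normalization is min-max per column over every vertex of every subject in
the fitted set.  Fitting over the entire cohort (the default) reproduces the
original protocol, which normalizes across the whole dataset and therefore
leaks test statistics into training; pass the training subjects only for
leakage-free operation.  A fitted scaler can be serialized and re-applied to
unseen subjects, whose out-of-range values are clipped to [0, 1].
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .synthetic_cohort import Subject

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "MissingFeatureError",
    "assemble_features",
    "CohortMinMaxScaler",
    "cohort_minmax",
    "augment_noise",
]


class MissingFeatureError(ValueError):
    """A requested feature is not available on the subject."""


@dataclass(frozen=True)
class FeatureSpec:
    """Which vertex attributes enter the feature vector."""

    coords: bool = True
    thickness: bool = False
    curvature: bool = False
    conductance: bool = False

    def __post_init__(self) -> None:
        if not (self.coords or self.thickness or self.curvature or self.conductance):
            raise ValueError("at least one feature flag must be set")

    @property
    def dimension(self) -> int:
        return 3 * self.coords + self.thickness + self.curvature + 642 * self.conductance

    @property
    def name(self) -> str:
        parts = [n for n, f in [("coords", self.coords), ("thickness", self.thickness),
                                ("curvature", self.curvature),
                                ("conductance", self.conductance)] if f]
        return "+".join(parts)

    @classmethod
    def from_names(cls, names: str) -> "FeatureSpec":
        wanted = {n.strip() for n in names.split(",") if n.strip()}
        known = {"coords", "thickness", "curvature", "conductance"}
        unknown = wanted - known
        if unknown:
            raise ValueError(f"unknown feature names: {sorted(unknown)}")
        return cls(**{k: k in wanted for k in known})


@dataclass
class FeatureMatrix:
    """V × d feature values plus normalization state."""

    values: np.ndarray
    spec: FeatureSpec
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.spec.dimension:
            raise ValueError(
                f"feature matrix shape {self.values.shape} does not match "
                f"spec dimension {self.spec.dimension}"
            )


def assemble_features(subject: Subject, spec: FeatureSpec) -> FeatureMatrix:
    """Concatenate the enabled per-vertex attributes (coords, thickness,
    curvature, conductance — in that order)."""
    blocks: list[np.ndarray] = []
    if spec.coords:
        blocks.append(subject.mesh.vertices)
    if spec.thickness:
        blocks.append(subject.thickness[:, None])
    if spec.curvature:
        blocks.append(subject.curvature[:, None])
    if spec.conductance:
        if subject.connectivity is None:
            raise MissingFeatureError(
                f"subject {subject.id}/{subject.hemisphere} has no connectivity map"
            )
        blocks.append(subject.connectivity.matrix)
    return FeatureMatrix(values=np.concatenate(blocks, axis=1), spec=spec)


class CohortMinMaxScaler:
    """Column-wise min-max scaler fitted over all vertices of a cohort.

    Constant columns map to 0; transformed values of unseen subjects are
    clipped to [0, 1].
    """

    def __init__(self, col_min: np.ndarray, col_max: np.ndarray, spec: FeatureSpec):
        self.col_min = np.asarray(col_min, dtype=np.float64)
        self.col_max = np.asarray(col_max, dtype=np.float64)
        self.spec = spec

    @classmethod
    def fit(cls, matrices: list[FeatureMatrix]) -> "CohortMinMaxScaler":
        if not matrices:
            raise ValueError("cannot fit a scaler on an empty cohort")
        spec = matrices[0].spec
        if any(m.spec != spec for m in matrices):
            raise ValueError("all feature matrices must share one FeatureSpec")
        col_min = matrices[0].values.min(axis=0)
        col_max = matrices[0].values.max(axis=0)
        for m in matrices[1:]:
            col_min = np.minimum(col_min, m.values.min(axis=0))
            col_max = np.maximum(col_max, m.values.max(axis=0))
        return cls(col_min, col_max, spec)

    def transform(self, matrix: FeatureMatrix, clip: bool = True) -> FeatureMatrix:
        span = self.col_max - self.col_min
        safe = np.where(span > 0, span, 1.0)
        out = (matrix.values - self.col_min) / safe
        out[:, span == 0] = 0.0
        if clip:
            out = np.clip(out, 0.0, 1.0)
        return FeatureMatrix(values=out, spec=matrix.spec, normalized=True)

    def inverse_transform(self, matrix: FeatureMatrix) -> FeatureMatrix:
        span = self.col_max - self.col_min
        out = matrix.values * span + self.col_min
        return FeatureMatrix(values=out, spec=matrix.spec, normalized=False)

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        doc = json.dumps({
            "spec": {k: getattr(self.spec, k)
                     for k in ("coords", "thickness", "curvature", "conductance")},
            "col_min": self.col_min.tolist(),
            "col_max": self.col_max.tolist(),
        })
        if path is not None:
            with open(path, "w") as fh:
                fh.write(doc)
        return doc

    @classmethod
    def from_json(cls, doc_or_path: str | os.PathLike) -> "CohortMinMaxScaler":
        text = str(doc_or_path)
        if os.path.exists(text):
            with open(text) as fh:
                text = fh.read()
        doc = json.loads(text)
        return cls(doc["col_min"], doc["col_max"], FeatureSpec(**doc["spec"]))


def cohort_minmax(
    matrices: list[FeatureMatrix],
) -> tuple[list[FeatureMatrix], CohortMinMaxScaler]:
    """Fit a min-max scaler on the given matrices and return them normalized."""
    scaler = CohortMinMaxScaler.fit(matrices)
    return [scaler.transform(m) for m in matrices], scaler


def augment_noise(features: FeatureMatrix, sigma: float,
                  seed: int | np.random.Generator) -> FeatureMatrix:
    """Add i.i.d. zero-mean Gaussian noise of sd ``sigma`` (training augmentation)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return FeatureMatrix(values=features.values.copy(), spec=features.spec,
                             normalized=features.normalized)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noisy = features.values + rng.normal(0.0, sigma, size=features.values.shape)
    return FeatureMatrix(values=noisy, spec=features.spec, normalized=features.normalized)
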