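"""Synthetic labeled feature matrices with planted statistical structure.

The generator emulates the distributional shape of CNN-derived deep feature
vectors: a few strongly class-informative Gaussian features, near-duplicate
redundant copies of them, and many class-independent noise features. It
exists so that every downstream stage (filter scoring, the genetic
algorithm, the KNN classifier) can be exercised and validated against a
known ground truth without any external image data.

Class means for the informative block are placed on the vertices of a
regular simplex, tiled across the informative columns and scaled so that
the Euclidean distance between any two class centroids (over the whole
informative block) equals ``class_separation`` within-class standard
deviations. Every informative column therefore carries the same
between-class variance, and pairwise separation holds for any number of
classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import InvalidSpecError, MissingSplitError

ROLE_INFORMATIVE = "informative"
ROLE_REDUNDANT = "redundant"
ROLE_NOISE = "noise"

SPLIT_NAMES = ("train", "val", "test")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-structure dataset.

    Parameters
    ----------
    n_samples:
        Total number of rows.
    n_classes:
        Number of classes (>= 2). Balanced by default; see ``class_weights``.
    n_informative:
        Number of columns whose class-conditional means differ.
    n_redundant:
        Number of near-duplicate copies of informative columns. Copy ``j``
        duplicates informative column ``j mod n_informative`` plus
        ``N(0, redundancy_noise_sd^2)`` jitter.
    n_noise:
        Number of class-independent standard-normal columns.
    class_separation:
        Euclidean distance between class centroids over the informative
        block, in units of the within-class standard deviation (which is 1).
    redundancy_noise_sd:
        Standard deviation of the jitter added to redundant copies.
    seed:
        Seed of the generator; identical spec + seed => identical dataset.
    class_weights:
        Optional per-class sampling weights; defaults to balanced classes.
    """

    n_samples: int = 300
    n_classes: int = 3
    n_informative: int = 8
    n_redundant: int = 8
    n_noise: int = 48
    class_separation: float = 5.0
    redundancy_noise_sd: float = 0.1
    seed: int = 0
    class_weights: Optional[tuple] = None

    def __post_init__(self):
        if self.n_classes < 2:
            raise InvalidSpecError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.n_samples < 2 * self.n_classes:
            raise InvalidSpecError(
                "n_samples must allow >= 2 samples per class "
                f"(got n_samples={self.n_samples}, n_classes={self.n_classes})"
            )
        if self.n_informative < 0 or self.n_redundant < 0 or self.n_noise < 0:
            raise InvalidSpecError("feature counts must be nonnegative")
        if self.n_informative == 0 and self.class_separation > 0:
            raise InvalidSpecError(
                "class_separation > 0 requires at least one informative feature"
            )
        if self.n_redundant > 0 and self.n_informative == 0:
            raise InvalidSpecError("redundant columns need informative sources")
        if self.class_separation < 0 or self.redundancy_noise_sd < 0:
            raise InvalidSpecError("scale parameters must be nonnegative")
        if self.class_weights is not None:
            w = np.asarray(self.class_weights, dtype=float)
            if w.shape != (self.n_classes,) or np.any(w <= 0):
                raise InvalidSpecError(
                    "class_weights must be n_classes positive numbers"
                )

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


@dataclass
class FeatureDataset:
    """A labeled feature matrix: ``matrix`` is (n_samples, n_features),
    ``labels`` holds one integer class id per row.

    ``feature_roles`` and ``redundant_source`` are populated only for
    synthetic data; ``split_assignment`` (per-row 'train'/'val'/'test')
    only after :func:`split_dataset`.
    """

    matrix: np.ndarray
    labels: np.ndarray
    feature_roles: Optional[np.ndarray] = None
    redundant_source: Optional[np.ndarray] = None  # -1 for non-redundant columns
    split_assignment: Optional[np.ndarray] = None
    feature_names: Optional[list] = field(default=None, repr=False)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise InvalidSpecError("matrix must be 2-D (samples x features)")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise InvalidSpecError(
                f"matrix has {self.matrix.shape[0]} rows but "
                f"{self.labels.shape[0]} labels"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise InvalidSpecError("matrix contains non-finite values")
        if np.unique(self.labels).size < 2:
            raise InvalidSpecError("labels must contain at least 2 classes")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def rows(self, split: Optional[str]) -> np.ndarray:
        """Boolean row mask for one split ('train'/'val'/'test'), or all rows
        when ``split`` is None. A dataset without split assignment treats
        every row as train."""
        if split is None:
            return np.ones(self.n_samples, dtype=bool)
        if split not in SPLIT_NAMES:
            raise InvalidSpecError(f"unknown split {split!r}")
        if self.split_assignment is None:
            if split == "train":
                return np.ones(self.n_samples, dtype=bool)
            raise MissingSplitError(
                f"dataset has no split assignment; cannot take split {split!r}"
            )
        return np.asarray(self.split_assignment) == split

    def subset(self, mask: np.ndarray) -> "FeatureDataset":
        """Row-subset copy (keeps feature metadata)."""
        return FeatureDataset(
            matrix=self.matrix[mask],
            labels=self.labels[mask],
            feature_roles=self.feature_roles,
            redundant_source=self.redundant_source,
            split_assignment=None
            if self.split_assignment is None
            else np.asarray(self.split_assignment)[mask],
            feature_names=self.feature_names,
        )


def _simplex_vertices(k: int) -> np.ndarray:
    """k vertices of a regular simplex in R^(k-1), centered at the origin,
    with unit pairwise distance. Deterministic."""
    if k == 1:
        return np.zeros((1, 1))
    # vertices e_i / sqrt(2) in R^k have unit pairwise distance; center and
    # express in an orthonormal basis of the (k-1)-dim affine hull
    pts = np.eye(k) / np.sqrt(2.0)
    pts -= pts.mean(axis=0)
    # SVD gives deterministic coordinates up to column signs; fix signs
    u, s, _ = np.linalg.svd(pts, full_matrices=False)
    coords = u[:, : k - 1] * s[: k - 1]
    signs = np.sign(coords[0])
    signs[signs == 0] = 1.0
    return coords * signs


def _class_means(spec: SyntheticSpec) -> np.ndarray:
    """(n_classes, n_informative) matrix of class means on the informative
    block, with centroid pairwise distances == class_separation (exact when
    n_informative is a multiple of n_classes-1, mean-exact otherwise)."""
    if spec.n_informative == 0:
        return np.zeros((spec.n_classes, 0))
    m = max(spec.n_classes - 1, 1)
    verts = _simplex_vertices(spec.n_classes)  # (k, m), unit pairwise distance
    cols = np.arange(spec.n_informative) % m
    tiled = verts[:, cols]  # (k, n_informative)
    # scale so the mean pairwise squared distance equals class_separation^2
    k = spec.n_classes
    d2 = [
        np.sum((tiled[a] - tiled[b]) ** 2)
        for a in range(k)
        for b in range(a + 1, k)
    ]
    mean_d2 = float(np.mean(d2))
    if mean_d2 <= 0:
        return np.zeros_like(tiled)
    return tiled * (spec.class_separation / np.sqrt(mean_d2))


def _class_sizes(spec: SyntheticSpec) -> np.ndarray:
    """Per-class row counts by largest remainder; balanced unless weights."""
    if spec.class_weights is None:
        w = np.full(spec.n_classes, 1.0 / spec.n_classes)
    else:
        w = np.asarray(spec.class_weights, dtype=float)
        w = w / w.sum()
    return _largest_remainder(w * spec.n_samples, spec.n_samples)


def _largest_remainder(target: np.ndarray, total: int) -> np.ndarray:
    base = np.floor(target).astype(int)
    rem = total - base.sum()
    if rem > 0:
        frac = target - base
        # stable: larger fractional part first, ties by lower index
        order = np.lexsort((np.arange(len(target)), -frac))
        base[order[:rem]] += 1
    return base


def generate_dataset(spec: SyntheticSpec) -> FeatureDataset:
    """Draw a dataset with planted informative / redundant / noise columns.

    Column order is informative, then redundant, then noise; roles and the
    source index of each redundant copy are recorded on the result.
    Deterministic for a fixed spec (the seed lives in the spec).
    """
    rng = np.random.default_rng(spec.seed)
    sizes = _class_sizes(spec)
    labels = np.repeat(np.arange(spec.n_classes), sizes)

    means = _class_means(spec)  # (k, n_informative)
    informative = means[labels] + rng.standard_normal(
        (spec.n_samples, spec.n_informative)
    )

    sources = np.arange(spec.n_redundant) % max(spec.n_informative, 1)
    redundant = informative[:, sources] + rng.standard_normal(
        (spec.n_samples, spec.n_redundant)
    ) * spec.redundancy_noise_sd if spec.n_redundant else np.empty(
        (spec.n_samples, 0)
    )

    noise = rng.standard_normal((spec.n_samples, spec.n_noise))

    matrix = np.concatenate([informative, redundant, noise], axis=1)
    roles = np.array(
        [ROLE_INFORMATIVE] * spec.n_informative
        + [ROLE_REDUNDANT] * spec.n_redundant
        + [ROLE_NOISE] * spec.n_noise
    )
    redundant_source = np.full(spec.n_features, -1, dtype=int)
    redundant_source[
        spec.n_informative : spec.n_informative + spec.n_redundant
    ] = sources

    return FeatureDataset(
        matrix=matrix,
        labels=labels,
        feature_roles=roles,
        redundant_source=redundant_source,
    )


def split_dataset(
    ds: FeatureDataset,
    fractions: Sequence[float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> FeatureDataset:
    """Assign each row to train/val/test, stratified by class.

    ``fractions`` are the (train, val, test) proportions and must sum to 1.
    Within every class the counts follow the fractions to within one row
    (largest-remainder apportionment of a seeded shuffle), so the overall
    split is exactly stratified for balanced classes. Returns a new dataset;
    the input is not modified.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (3,) or np.any(fractions < 0):
        raise InvalidSpecError("fractions must be three nonnegative numbers")
    if abs(fractions.sum() - 1.0) > 1e-8:
        raise InvalidSpecError(
            f"fractions must sum to 1, got sum {fractions.sum()!r}"
        )
    for f in fractions:
        if 0 < f * ds.n_samples < 1:
            raise InvalidSpecError(
                f"fraction {f} of {ds.n_samples} samples is below one row"
            )

    rng = np.random.default_rng(seed)
    assignment = np.empty(ds.n_samples, dtype=object)
    for cls in ds.classes:
        idx = np.flatnonzero(ds.labels == cls)
        idx = rng.permutation(idx)
        counts = _largest_remainder(fractions * idx.size, idx.size)
        start = 0
        for name, cnt in zip(SPLIT_NAMES, counts):
            assignment[idx[start : start + cnt]] = name
            start += cnt

    out = replace_split(ds, assignment.astype(str))
    return out


def replace_split(ds: FeatureDataset, assignment: np.ndarray) -> FeatureDataset:
    return FeatureDataset(
        matrix=ds.matrix.copy(),
        labels=ds.labels.copy(),
        feature_roles=ds.feature_roles,
        redundant_source=ds.redundant_source,
        split_assignment=np.asarray(assignment),
        feature_names=ds.feature_names,
    )
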