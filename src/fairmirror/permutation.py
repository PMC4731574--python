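"""Group-level permutation inference for classification accuracies.

The exchangeability unit of a between-subject (leave-one-subject-out)
design is the subject, so the null is generated by per-subject class
relabelings: a scheme flips (or not) the two class labels of each
subject, and the flip travels with the subject into every training and
test role. The identity scheme is excluded from the sampled null set, and
the p value is (1 + #{null >= observed}) / (1 + m), which cannot reach 0
and attains its floor 1/(m+1) — .001 for m = 1000 — when the observed
accuracy beats every relabeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from fairmirror.io import VolumeGeometry
from fairmirror.mvpa import (
    CVFolds,
    ExampleSet,
    SearchlightSpec,
    _loso_accuracy,
    _resolve_mask_columns,
)
from fairmirror.univariate import StatMap


@dataclass(frozen=True)
class RelabelingScheme:
    """Per-subject label-flip indicators, applied in train and test alike."""

    id: int
    flips: dict[str, bool]

    def flip_vector(self, subjects: np.ndarray) -> np.ndarray:
        return np.array([self.flips[s] for s in subjects], dtype=bool)


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic with its permutation null distribution."""

    observed: float
    null_values: np.ndarray
    p_value: float
    m: int
    seed: int

    def __post_init__(self) -> None:
        null_values = np.asarray(self.null_values, dtype=float)
        if null_values.size != self.m:
            raise ValueError("null_values length must equal m")
        if self.p_value < 1.0 / (self.m + 1) - 1e-12:
            raise ValueError("p_value below the attainable floor 1/(m+1)")
        object.__setattr__(self, "null_values", null_values)


def generate_relabelings(subject_ids, m: int, seed: int = 0) -> list[RelabelingScheme]:
    """Sample m distinct per-subject flip vectors, identity excluded.

    Schemes are drawn uniformly without replacement from the 2^n - 1
    non-identity flip vectors. When fewer than m exist, all of them are
    returned and a warning records the reduction. Deterministic given
    ``seed``.
    """
    ids = sorted(set(subject_ids))
    n = len(ids)
    if m < 1:
        raise ValueError("m must be >= 1")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    total = (1 << n) - 1  # non-identity flip vectors
    rng = np.random.default_rng(seed)
    if total <= m:
        warnings.warn(
            f"only {total} distinct relabelings exist for {n} subjects; "
            f"requested m={m} reduced to {total}",
            stacklevel=2,
        )
        codes = np.arange(1, total + 1)
    elif n <= 24:
        codes = rng.choice(total, size=m, replace=False) + 1
    else:  # rejection sampling for huge spaces
        chosen: set[int] = set()
        while len(chosen) < m:
            draw = int(rng.integers(1, total + 1))
            chosen.add(draw)
        codes = np.fromiter(chosen, dtype=np.int64)
    schemes = []
    for sid, code in enumerate(codes):
        flips = {ids[j]: bool((int(code) >> j) & 1) for j in range(n)}
        schemes.append(RelabelingScheme(id=sid, flips=flips))
    return schemes


def permutation_p(observed: float, null_values) -> float:
    """p = (1 + #{null >= observed}) / (1 + m); ties count against observed."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("null_values is empty")
    b = int(np.sum(null_values >= observed))
    return (1 + b) / (1 + null_values.size)


def _permuted_labels(y: np.ndarray, subjects: np.ndarray, scheme: RelabelingScheme) -> np.ndarray:
    flip = scheme.flip_vector(subjects)
    return np.where(flip, 1.0 - y, y)


def roi_permutation_test(
    examples: ExampleSet,
    folds: CVFolds,
    mask: np.ndarray | None = None,
    m: int = 1000,
    seed: int = 0,
    cost_c: float = 1.0,
    schemes: list[RelabelingScheme] | None = None,
) -> PermutationResult:
    """Permutation test of LOSO accuracy in one ROI.

    Each null value reruns the full LOSO loop with one relabeling scheme
    applied to every subject's examples (train and test alike).
    """
    X, y, subjects = examples.matrices()
    cols = _resolve_mask_columns(examples, mask)
    if cols is not None:
        if cols.size == 0:
            raise ValueError("ROI mask selects no voxels of the example set")
        X = X[:, cols]
    if schemes is None:
        schemes = generate_relabelings(examples.subject_ids, m, seed)
    observed = _loso_accuracy(X, y, subjects, folds, cost_c)
    null = np.empty(len(schemes))
    for i, scheme in enumerate(schemes):
        null[i] = _loso_accuracy(X, _permuted_labels(y, subjects, scheme), subjects, folds, cost_c)
    return PermutationResult(
        observed=observed,
        null_values=null,
        p_value=permutation_p(observed, null),
        m=len(schemes),
        seed=seed,
    )


def searchlight_permutation_map(
    examples: ExampleSet,
    spec: SearchlightSpec,
    folds: CVFolds,
    brain_mask: np.ndarray,
    m: int = 1000,
    seed: int = 0,
    geometry: VolumeGeometry | None = None,
) -> tuple[StatMap, StatMap]:
    """Per-voxel permutation p map for searchlight accuracies.

    One scheme list is sampled per map and reused at every centre voxel,
    preserving the spatial structure of the null; thresholding and
    clustering of the resulting p map are delegated to
    :func:`fairmirror.univariate.extract_clusters`.

    Returns
    -------
    (p_map, accuracy_map)
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    dims = brain_mask.shape
    if examples.dims is not None and tuple(examples.dims) != dims:
        raise ValueError("brain mask dims do not match example set dims")
    schemes = generate_relabelings(examples.subject_ids, m, seed)
    X, y, subjects = examples.matrices()
    permuted_ys = [_permuted_labels(y, subjects, s) for s in schemes]

    col_of_voxel = np.full(int(np.prod(dims)), -1, dtype=int)
    col_of_voxel[examples.voxel_indices] = np.arange(examples.voxel_indices.size)
    acc = np.full(dims, np.nan)
    pmap = np.full(dims, np.nan)
    dims_arr = np.asarray(dims)
    for center in np.argwhere(brain_mask):
        neigh = center + spec.offsets
        ok = np.all((neigh >= 0) & (neigh < dims_arr), axis=1)
        lin = np.ravel_multi_index(tuple(neigh[ok].T), dims)
        cols = col_of_voxel[lin]
        cols = cols[cols >= 0]
        if cols.size == 0:
            continue
        Xc = X[:, cols]
        observed = _loso_accuracy(Xc, y, subjects, folds, spec.cost_c)
        null = np.empty(len(schemes))
        for i, yp in enumerate(permuted_ys):
            null[i] = _loso_accuracy(Xc, yp, subjects, folds, spec.cost_c)
        acc[tuple(center)] = observed
        pmap[tuple(center)] = permutation_p(observed, null)
    return (
        StatMap(values=pmap, kind="p", geometry=geometry),
        StatMap(values=acc, kind="accuracy", geometry=geometry),
    )


def bonferroni_adjust(p_values, k: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * k) for k tests."""
    p = np.asarray(p_values, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if p.size > k:
        raise ValueError(f"k={k} is smaller than the number of tests ({p.size})")
    return np.minimum(1.0, p * k)
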