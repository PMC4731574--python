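"""Between-subject multivoxel pattern analysis.

Pattern preparation (across-voxel centering, balanced averaging,
action-minus-control subtraction images) and linear-SVM classification
with leave-one-subject-out (LOSO) folds, as ROI accuracies or a
searchlight accuracy map.

Why between-subject: confederate identity, colour and role are perfectly
confounded *within* any one subject (each subject sees one identity per
role), but counterbalanced *across* subjects. Training on n-1 subjects
and testing on the held-out subject therefore removes identity/colour as
usable cues: only a role-linked pattern shared across subjects can
support above-chance accuracy. Within-subject partitioning on the same
data is provided solely as a leakage demonstration.

Classifier: hard/soft-margin linear SVM with hinge loss and fixed cost
(default c = 1), solved by libsvm (through scikit-learn's bundled
low-level binding, which avoids estimator-construction overhead in the
permutation loops; equivalence with ``sklearn.svm.SVC(kernel='linear')``
is asserted by the test suite). Example order is canonicalized (sorted
by subject id, then label) before fitting, and a decision value of
exactly zero is assigned to the lexicographically first class, so
classification is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fairmirror.io import VolumeGeometry
from fairmirror.simulate import SubjectBetas
from fairmirror.univariate import StatMap

try:  # scikit-learn's bundled libsvm binding (fast path)
    from sklearn.svm import _libsvm as _libsvm_backend

    _libsvm_backend.set_verbosity_wrap(0)
except Exception:  # pragma: no cover - exercised only if the binding moves
    _libsvm_backend = None


def _fit_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, cost_c: float) -> np.ndarray:
    """Fit a linear SVM and predict class codes for Xte.

    ``ytr`` holds class codes 0/1 where code 0 is the lexicographically
    first class; ties at decision value 0 go to code 0.
    """
    classes = np.unique(ytr)
    if classes.size < 2:
        raise ValueError("training set must contain both classes")
    if _libsvm_backend is not None:
        out = _libsvm_backend.fit(
            np.ascontiguousarray(Xtr, dtype=np.float64),
            np.ascontiguousarray(ytr, dtype=np.float64),
            svm_type=0,
            kernel="linear",
            C=float(cost_c),
        )
        SV, sv_coef, intercept = out[1], out[3], out[4]
        # the wrapper returns (w, b) oriented so that w.x + b > 0 means
        # code 0 (the lexicographically first class); equivalently the
        # sklearn decision function is -(w.x + b). Ties (exactly 0) go to
        # code 0 by the >= below.
        f = Xte @ (sv_coef @ SV).ravel() + float(intercept[0])
        return np.where(f >= 0, 0.0, 1.0)
    from sklearn.svm import SVC  # pragma: no cover - fallback path

    clf = SVC(kernel="linear", C=float(cost_c))
    clf.fit(Xtr, ytr)
    d = clf.decision_function(Xte)
    return np.where(d > 0, clf.classes_[1], clf.classes_[0])


@dataclass(frozen=True)
class PatternExample:
    """One labelled pattern vector (one subject, one class).

    ``chunk`` optionally records a within-subject partition unit (e.g.
    the run an example came from) for the within-subject leakage check.
    """

    subject_id: str
    label: str
    vector: np.ndarray
    chunk: int | None = None

    def __post_init__(self) -> None:
        vector = np.asarray(self.vector, dtype=float).ravel()
        if not np.all(np.isfinite(vector)):
            raise ValueError("pattern vector contains non-finite values")
        object.__setattr__(self, "vector", vector)


@dataclass(frozen=True)
class ExampleSet:
    """Labelled pattern vectors over a fixed, ordered voxel index set."""

    examples: tuple
    voxel_indices: np.ndarray  # linear indices into the volume, ordered
    class_labels: tuple[str, str]
    dims: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        examples = tuple(self.examples)
        idx = np.asarray(self.voxel_indices, dtype=int)
        labels = tuple(sorted(self.class_labels))
        for ex in examples:
            if ex.vector.size != idx.size:
                raise ValueError("example vector length must equal the voxel index set size")
            if ex.label not in labels:
                raise ValueError(f"example label {ex.label!r} not in {labels}")
        counts: dict[tuple[str, str], int] = {}
        for ex in examples:
            counts[(ex.subject_id, ex.label)] = counts.get((ex.subject_id, ex.label), 0) + 1
        subjects = {s for s, _ in counts}
        for s in subjects:
            if counts.get((s, labels[0]), 0) != counts.get((s, labels[1]), 0):
                raise ValueError(
                    "every subject must contribute equally many examples per class"
                )
        object.__setattr__(self, "examples", examples)
        object.__setattr__(self, "voxel_indices", idx)
        object.__setattr__(self, "class_labels", labels)

    @property
    def subject_ids(self) -> list[str]:
        return sorted({ex.subject_id for ex in self.examples})

    def canonical_order(self) -> list[int]:
        """Example order sorted by (subject, label, chunk)."""
        keyed = [
            (ex.subject_id, ex.label, -1 if ex.chunk is None else ex.chunk, i)
            for i, ex in enumerate(self.examples)
        ]
        return [i for *_, i in sorted(keyed)]

    def matrices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, y_codes, subject_codes) in canonical order.

        y codes: 0 for the lexicographically first class, 1 for the other.
        """
        order = self.canonical_order()
        X = np.stack([self.examples[i].vector for i in order])
        y = np.array(
            [self.class_labels.index(self.examples[i].label) for i in order], dtype=float
        )
        subjects = np.array([self.examples[i].subject_id for i in order])
        return X, y, subjects


@dataclass(frozen=True)
class SearchlightSpec:
    """Shape and classifier cost of the moving searchlight."""

    radius_voxels: int = 3
    cost_c: float = 1.0
    offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.radius_voxels < 0:
            raise ValueError("radius must be >= 0")
        offsets = (
            searchlight_offsets(self.radius_voxels)
            if self.offsets is None
            else np.asarray(self.offsets, dtype=int)
        )
        present = {tuple(o) for o in offsets}
        if (0, 0, 0) not in present:
            raise ValueError("offsets must include the origin")
        if any(tuple(-np.asarray(o)) not in present for o in offsets):
            raise ValueError("offsets must be symmetric under negation")
        object.__setattr__(self, "offsets", offsets)


@dataclass(frozen=True)
class CVFolds:
    """Cross-validation folds over subjects; test sets partition them."""

    folds: tuple

    def __post_init__(self) -> None:
        folds = tuple((tuple(tr), tuple(te)) for tr, te in self.folds)
        seen: list[str] = []
        for train, test in folds:
            if set(train) & set(test):
                raise ValueError("train and test subjects overlap within a fold")
            seen.extend(test)
        if len(seen) != len(set(seen)):
            raise ValueError("test sets must partition the subjects (no repeats)")
        object.__setattr__(self, "folds", folds)

    def __len__(self) -> int:
        return len(self.folds)


def loso_folds(subject_ids) -> CVFolds:
    """Leave-one-subject-out folds: one fold per subject."""
    ids = sorted(set(subject_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 subjects for cross-validation")
    return CVFolds(
        folds=tuple((tuple(s for s in ids if s != held), (held,)) for held in ids)
    )


def center_pattern(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Subtract the across-voxel in-mask mean; out-of-mask voxels untouched."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    out = np.asarray(volume, dtype=float).copy()
    out[mask] -= out[mask].mean()
    return out


def balance_and_average(
    betas: SubjectBetas, grouping: tuple[str, ...], seed: int = 0,
    center_mask: np.ndarray | None = None,
) -> tuple[dict, dict]:
    """Average analyzable block betas per factor group, balanced by subsetting.

    Odd-ball/button-press/error blocks are dropped; each group defined by
    the ``grouping`` factors is randomly subsampled (seeded) to the
    smallest group size before voxelwise averaging, so no class is
    represented by more blocks than another. If ``center_mask`` is given,
    each block pattern is centered (across-voxel mean zero within the
    mask) before averaging.

    Returns
    -------
    (averages, retained)
        ``averages`` maps group key (tuple of factor values) to the mean
        volume; ``retained`` maps group key to the retained block indices.
    """
    blocks, volumes = betas.analyzable()
    groups: dict[tuple, list[int]] = {}
    for j, b in enumerate(blocks):
        key = tuple(getattr(b, f) for f in grouping)
        groups.setdefault(key, []).append(j)
    if not groups:
        raise ValueError("no analyzable blocks to average")
    k = min(len(v) for v in groups.values())
    if k == 0:
        raise ValueError("a group is empty after dropping flagged blocks")
    rng = np.random.default_rng(seed)
    averages: dict[tuple, np.ndarray] = {}
    retained: dict[tuple, list[int]] = {}
    schedule_idx = betas.schedule.analyzable_indices()
    for key in sorted(groups):
        members = groups[key]
        if len(members) > k:
            keep = sorted(rng.choice(len(members), size=k, replace=False))
            members = [members[i] for i in keep]
        vols = volumes[members]
        if center_mask is not None:
            vols = np.stack([center_pattern(v, center_mask) for v in vols])
        averages[key] = vols.mean(axis=0)
        retained[key] = [int(schedule_idx[m]) for m in members]
    return averages, retained


def role_difference_images(averages: dict, modality: str = "visual") -> dict:
    """Per-role action-minus-control subtraction images.

    ``averages`` must be keyed by (modality, stim_type, role). The
    subtraction removes role-unspecific stimulus structure, leaving the
    component of the action response that differs with confederate role.
    """
    out = {}
    for role in ("fair", "unfair"):
        for stim in ("action", "control"):
            if (modality, stim, role) not in averages:
                raise KeyError(f"missing condition {(modality, stim, role)}")
        out[role] = (
            averages[(modality, "action", role)] - averages[(modality, "control", role)]
        )
    return out


def searchlight_offsets(radius_voxels: int) -> np.ndarray:
    """Integer offsets of the Euclidean lattice ball of the given radius.

    All (i, j, k) with i^2 + j^2 + k^2 <= radius^2, in lexicographic
    order; always symmetric and containing the origin. Radius 3 gives
    123 offsets.
    """
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius_voxels)
    grid = np.arange(-r, r + 1)
    ii, jj, kk = np.meshgrid(grid, grid, grid, indexing="ij")
    keep = ii**2 + jj**2 + kk**2 <= r**2
    return np.column_stack([ii[keep], jj[keep], kk[keep]])


def build_example_set(
    per_subject: dict, mask: np.ndarray, dims: tuple[int, int, int] | None = None
) -> ExampleSet:
    """Assemble an ExampleSet from per-subject {label: volume} mappings.

    ``per_subject`` maps subject id to either ``{label: 3D volume}`` or
    ``{label: [3D volume, ...]}`` (multiple chunks per class). ``mask``
    is the boolean analysis mask defining the ordered voxel index set.
    """
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask.ravel())
    labels = sorted({lab for vols in per_subject.values() for lab in vols})
    if len(labels) != 2:
        raise ValueError(f"expected exactly two class labels, got {labels}")
    examples = []
    for subject in sorted(per_subject):
        for label in labels:
            vols = per_subject[subject][label]
            if isinstance(vols, np.ndarray) and vols.ndim == 3:
                vols = [vols]
            for chunk, vol in enumerate(vols):
                examples.append(
                    PatternExample(
                        subject_id=subject,
                        label=label,
                        vector=np.asarray(vol, dtype=float).ravel()[idx],
                        chunk=chunk if len(vols) > 1 else None,
                    )
                )
    return ExampleSet(
        examples=tuple(examples),
        voxel_indices=idx,
        class_labels=(labels[0], labels[1]),
        dims=dims if dims is not None else tuple(mask.shape),
    )


def classify_fold(train: ExampleSet, test: ExampleSet, cost_c: float = 1.0) -> list[str]:
    """Train on one example set, return predicted labels for another.

    Both sets must share the same ordered voxel index set and class
    labels. Deterministic: examples are canonicalized before fitting and
    decision ties go to the lexicographically first class.
    """
    if train.voxel_indices.size != test.voxel_indices.size or not np.array_equal(
        train.voxel_indices, test.voxel_indices
    ):
        raise ValueError("train and test voxel index sets differ")
    if train.class_labels != test.class_labels:
        raise ValueError("train and test class labels differ")
    Xtr, ytr, _ = train.matrices()
    order = test.canonical_order()
    Xte = np.stack([test.examples[i].vector for i in order])
    pred_codes = _fit_predict(Xtr, ytr, Xte, cost_c)
    labels_in_input_order = [""] * len(test.examples)
    for row, i in enumerate(order):
        labels_in_input_order[i] = train.class_labels[int(pred_codes[row])]
    return labels_in_input_order


def _loso_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    folds: CVFolds,
    cost_c: float,
) -> float:
    """Mean over folds of the held-out proportion correct."""
    accs = np.empty(len(folds))
    for i, (train_ids, test_ids) in enumerate(folds.folds):
        tr = np.isin(subjects, train_ids)
        te = np.isin(subjects, test_ids)
        pred = _fit_predict(X[tr], y[tr], X[te], cost_c)
        accs[i] = float(np.mean(pred == y[te]))
    return float(accs.mean())


def roi_accuracy(
    examples: ExampleSet,
    folds: CVFolds,
    mask: np.ndarray | None = None,
    cost_c: float = 1.0,
) -> float:
    """LOSO classification accuracy over the voxels of one ROI.

    ``mask`` may be a boolean volume (matching the set's dims), a boolean
    vector over the example columns, or an integer array of columns; None
    uses every voxel in the set.
    """
    X, y, subjects = examples.matrices()
    cols = _resolve_mask_columns(examples, mask)
    if cols is not None:
        if cols.size == 0:
            raise ValueError("ROI mask selects no voxels of the example set")
        X = X[:, cols]
    return _loso_accuracy(X, y, subjects, folds, cost_c)


def _resolve_mask_columns(examples: ExampleSet, mask) -> np.ndarray | None:
    if mask is None:
        return None
    mask = np.asarray(mask)
    if mask.ndim == 3:
        lin = np.flatnonzero(mask.astype(bool).ravel())
        return np.flatnonzero(np.isin(examples.voxel_indices, lin))
    if mask.dtype == bool:
        if mask.size != examples.voxel_indices.size:
            raise ValueError("boolean mask length must equal the voxel index set size")
        return np.flatnonzero(mask)
    return mask.astype(int)


def within_subject_accuracy(examples: ExampleSet, cost_c: float = 1.0) -> float:
    """Leave-one-chunk-out accuracy *within* each subject, averaged.

    Diagnostic only: with identity/colour confounds planted, this exceeds
    chance even when no between-subject role signal exists — the leakage
    that LOSO partitioning is designed to rule out.
    """
    X, y, subjects = examples.matrices()
    order = examples.canonical_order()
    chunks = np.array(
        [-1 if examples.examples[i].chunk is None else examples.examples[i].chunk for i in order]
    )
    if np.all(chunks < 0):
        raise ValueError("within-subject folding needs chunked examples (chunk set)")
    accs = []
    for subject in np.unique(subjects):
        rows = subjects == subject
        for chunk in np.unique(chunks[rows]):
            tr = rows & (chunks != chunk)
            te = rows & (chunks == chunk)
            if np.unique(y[tr]).size < 2:
                continue
            pred = _fit_predict(X[tr], y[tr], X[te], cost_c)
            accs.append(float(np.mean(pred == y[te])))
    if not accs:
        raise ValueError("no valid within-subject folds")
    return float(np.mean(accs))


def searchlight_accuracy_map(
    examples: ExampleSet,
    spec: SearchlightSpec,
    folds: CVFolds,
    brain_mask: np.ndarray,
    geometry: VolumeGeometry | None = None,
) -> StatMap:
    """LOSO accuracy at every in-mask searchlight centre.

    The searchlight at a centre uses the lattice-ball offsets clipped to
    the analysis mask; the accuracy is assigned to the centre voxel.
    Voxels outside the mask are NaN.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    dims = brain_mask.shape
    if examples.dims is not None and tuple(examples.dims) != dims:
        raise ValueError("brain mask dims do not match example set dims")
    X, y, subjects = examples.matrices()
    col_of_voxel = np.full(int(np.prod(dims)), -1, dtype=int)
    col_of_voxel[examples.voxel_indices] = np.arange(examples.voxel_indices.size)

    out = np.full(dims, np.nan)
    centers = np.argwhere(brain_mask)
    offsets = spec.offsets
    dims_arr = np.asarray(dims)
    for center in centers:
        neigh = center + offsets
        ok = np.all((neigh >= 0) & (neigh < dims_arr), axis=1)
        lin = np.ravel_multi_index(tuple(neigh[ok].T), dims)
        cols = col_of_voxel[lin]
        cols = cols[cols >= 0]
        if cols.size == 0:
            continue
        out[tuple(center)] = _loso_accuracy(X[:, cols], y, subjects, folds, spec.cost_c)
    return StatMap(values=out, kind="accuracy", geometry=geometry)
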