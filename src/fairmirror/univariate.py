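"""Second-level mass-univariate inference.

Subject-level contrasts feed voxelwise one-sample t-tests; thresholding
uses one-tailed p values with Benjamini-Hochberg voxelwise FDR (the
standard neuroimaging convention) or uncorrected cutoffs, followed by
connected-component cluster extraction and reporting in mm coordinates.
The t-to-z conversion maps a t statistic to the standard-normal deviate
with the same upper-tail probability, computed in log space so extreme
tails stay accurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, special, stats

from fairmirror.io import VolumeGeometry

STAT_KINDS = ("t", "z", "p", "accuracy", "beta")


def _identity_geometry(dims: tuple[int, int, int]) -> VolumeGeometry:
    return VolumeGeometry(dims, np.eye(4))


@dataclass(frozen=True)
class StatMap:
    """A 3D statistic volume with its inferential context."""

    values: np.ndarray
    kind: str
    df: int | None = None
    geometry: VolumeGeometry | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError("StatMap values must be 3D")
        if self.kind not in STAT_KINDS:
            raise ValueError(f"unknown statistic kind {self.kind!r}")
        if self.kind == "t" and self.df is None:
            raise ValueError("t maps require degrees of freedom")
        if self.kind == "p":
            finite = values[np.isfinite(values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("p maps must lie in [0, 1]")
        geometry = self.geometry or _identity_geometry(values.shape)
        if geometry.dims != values.shape:
            raise ValueError("geometry dims do not match values shape")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "geometry", geometry)


@dataclass(frozen=True)
class Contrast:
    """Named weighted combination of condition beta images."""

    name: str
    weights: dict

    def __post_init__(self) -> None:
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError("contrast must have at least one nonzero weight")


def subject_contrast(betas: dict, contrast: Contrast) -> np.ndarray:
    """Voxelwise weighted sum of a subject's condition beta volumes."""
    out = None
    for key, w in contrast.weights.items():
        if w == 0:
            continue
        if key not in betas:
            raise KeyError(f"condition {key!r} missing for contrast {contrast.name!r}")
        vol = np.asarray(betas[key], dtype=float)
        out = w * vol if out is None else out + w * vol
    return out


def one_sample_t(maps: list[np.ndarray], geometry: VolumeGeometry | None = None) -> StatMap:
    """Voxelwise one-sample t-test of n subject maps against zero.

    t = mean / (sd / sqrt(n)) with df = n - 1; voxels with zero sample
    variance (including all-zero voxels) are flagged non-finite (NaN).
    """
    if len(maps) < 2:
        raise ValueError("one_sample_t needs at least 2 maps")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    if geometry is not None and stack.shape[1:] != geometry.dims:
        raise ValueError("maps do not match geometry dims")
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    return StatMap(values=t, kind="t", df=n - 1, geometry=geometry)


def p_from_t(t, df: int, tails: str = "one"):
    """Upper-tail (or two-tailed) probability of a t statistic."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    t = np.asarray(t, dtype=float)
    p = stats.t.sf(t, df) if tails == "one" else 2 * stats.t.sf(np.abs(t), df)
    return float(p) if p.ndim == 0 else p


def t_threshold(p: float, df: int, tails: str = "one") -> float:
    """Inverse of :func:`p_from_t`: the t cutoff at a given p level."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.t.isf(p if tails == "one" else p / 2, df))


def t_to_z(t, df: int):
    """Map t to the standard-normal deviate with equal tail probability.

    Computed through the log upper-tail probability
    (``z = -ndtri_exp(log sf)``) so the conversion stays numerically
    stable far into the tail (p well below 1e-10).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, dtype=float)
    z = np.where(
        np.isfinite(t),
        -special.ndtri_exp(stats.t.logsf(t, df)),
        np.nan,
    )
    return float(z) if z.ndim == 0 else z


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, float | None]:
    """Benjamini-Hochberg step-up over a flat list of p values.

    Returns
    -------
    (mask, threshold)
        ``mask[i]`` is True where ``p_values[i]`` is declared a
        discovery; ``threshold`` is the data-dependent cutoff p(k) (the
        largest sorted p with p(k) <= k q / m), or None when nothing
        survives.
    """
    p = np.asarray(p_values, dtype=float)
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if p.size == 0:
        return np.zeros(0, dtype=bool), None
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p values must be finite and in [0, 1]")
    m = p.size
    order = np.sort(p)
    crit = np.arange(1, m + 1) * q / m
    passing = np.nonzero(order <= crit)[0]
    if passing.size == 0:
        return np.zeros(m, dtype=bool), None
    threshold = order[passing[-1]]
    return p <= threshold, float(threshold)


@dataclass(frozen=True)
class Cluster:
    """A connected suprathreshold component."""

    size_voxels: int
    member_voxels: list = field(repr=False)
    peak_voxel: tuple[int, int, int]
    peak_value: float
    center_of_mass_mm: tuple[float, float, float]


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    return ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])


def _filter_clusters_mask(mask: np.ndarray, min_size: int, connectivity: int) -> np.ndarray:
    """Remove connected components smaller than min_size from a boolean mask."""
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = sizes[1:] >= min_size
    return keep[labels]


def extract_clusters(
    stat_map: StatMap,
    threshold: float,
    min_size: int = 10,
    connectivity: int = 18,
) -> list[Cluster]:
    """Connected components of voxels with value > threshold.

    Components below ``min_size`` voxels are discarded; the remainder are
    sorted by size (descending; ties by peak value). Peaks are the
    maximum-value member voxel (first in array order on exact ties);
    centres of mass are unweighted mean member coordinates mapped to mm
    through the affine.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    values = stat_map.values
    supra = np.where(np.isfinite(values), values > threshold, False)
    labels, n = ndimage.label(supra, structure=_structure(connectivity))
    clusters: list[Cluster] = []
    affine = stat_map.geometry.affine
    for lab in range(1, n + 1):
        members = np.argwhere(labels == lab)
        if len(members) < min_size:
            continue
        vals = values[tuple(members.T)]
        peak_i = int(np.argmax(vals))
        com_vox = members.mean(axis=0)
        com_mm = (affine @ np.append(com_vox, 1.0))[:3]
        clusters.append(
            Cluster(
                size_voxels=len(members),
                member_voxels=[tuple(int(v) for v in m) for m in members],
                peak_voxel=tuple(int(v) for v in members[peak_i]),
                peak_value=float(vals[peak_i]),
                center_of_mass_mm=tuple(float(v) for v in com_mm),
            )
        )
    clusters.sort(key=lambda c: (-c.size_voxels, -c.peak_value, c.peak_voxel))
    return clusters


def clusters_from_mask(
    mask: np.ndarray,
    value_map: StatMap,
    min_size: int = 1,
    connectivity: int = 18,
) -> list[Cluster]:
    """Connected components of an externally thresholded boolean mask.

    Used where the significance rule is not a simple "value > cutoff"
    (e.g. permutation p < alpha): peaks and centres of mass are taken
    from ``value_map`` within each component.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    values = value_map.values
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    clusters: list[Cluster] = []
    affine = value_map.geometry.affine
    for lab in range(1, n + 1):
        members = np.argwhere(labels == lab)
        if len(members) < min_size:
            continue
        vals = values[tuple(members.T)]
        vals = np.where(np.isfinite(vals), vals, -np.inf)
        peak_i = int(np.argmax(vals))
        com_mm = (affine @ np.append(members.mean(axis=0), 1.0))[:3]
        clusters.append(
            Cluster(
                size_voxels=len(members),
                member_voxels=[tuple(int(v) for v in m) for m in members],
                peak_voxel=tuple(int(v) for v in members[peak_i]),
                peak_value=float(values[tuple(members[peak_i])]),
                center_of_mass_mm=tuple(float(v) for v in com_mm),
            )
        )
    clusters.sort(key=lambda c: (-c.size_voxels, -c.peak_value, c.peak_voxel))
    return clusters


def shared_voxel_mask(
    perception_p: StatMap,
    execution_t: StatMap,
    q: float = 0.05,
    exec_p_unc: float = 0.001,
    min_size: int = 10,
    connectivity: int = 18,
    cluster_filter: str = "conjunction",
) -> np.ndarray:
    """Voxels active both when perceiving and when executing actions.

    The execution localizer mask is the set of clusters (>= min_size)
    whose one-tailed p is below ``exec_p_unc``. Within it, perception
    voxels surviving voxelwise FDR at ``q`` define the shared voxels;
    the min-size cluster filter is then applied either to the conjunction
    (``cluster_filter="conjunction"``, default) or to the perception map
    before intersecting (``"perception"``) — the ordering is exposed
    because either reading of the procedure is defensible.
    """
    if perception_p.kind != "p":
        raise ValueError("perception_p must be a p map")
    if execution_t.kind != "t":
        raise ValueError("execution_t must be a t map")
    perception_p.geometry.require_match(execution_t.geometry)
    if cluster_filter not in ("conjunction", "perception"):
        raise ValueError(f"unknown cluster_filter {cluster_filter!r}")

    exec_p = p_from_t(execution_t.values, execution_t.df, tails="one")
    exec_supra = np.where(np.isfinite(exec_p), exec_p < exec_p_unc, False)
    exec_mask = _filter_clusters_mask(exec_supra, min_size, connectivity)

    pvals = perception_p.values
    finite = np.isfinite(pvals)
    sig = np.zeros(pvals.shape, dtype=bool)
    if finite.any():
        mask_flat, _ = fdr_bh(pvals[finite], q)
        sig[finite] = mask_flat
    if cluster_filter == "perception":
        sig = _filter_clusters_mask(sig, min_size, connectivity)
        return sig & exec_mask
    conj = sig & exec_mask
    return _filter_clusters_mask(conj, min_size, connectivity)
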