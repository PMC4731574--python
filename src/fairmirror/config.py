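"""Simulation and pipeline configuration objects.

The defaults of :class:`SimConfig` encode the study design the simulator
emulates: 15 analyzed subjects, three perception runs of 32 blocks, blocks
of three same-type stimuli, a 2 (modality) x 2 (action/control) x 2
(fair/unfair confederate) factorial, two odd-ball attention blocks per
subject, and a sparse-sampling acquisition (1.23 s scan burst followed by
4 s of silence, consecutive blocks separated by 3 scan cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from fairmirror.io import VolumeGeometry

MODALITIES = ("visual", "auditory")
STIM_TYPES = ("action", "control")
ROLES = ("fair", "unfair")
IDENTITIES = ("A", "B")
COLORS = ("blue", "orange")

#: The factor cells that must be balanced within each run.
FACTOR_CELLS = tuple(
    (m, s, r) for m in MODALITIES for s in STIM_TYPES for r in ROLES
)


@dataclass(frozen=True)
class SimConfig:
    """Design parameters of the simulated scanning session.

    Attributes
    ----------
    n_subjects, n_runs, blocks_per_run, stimuli_per_block, n_oddballs :
        Factorial design counts. ``blocks_per_run`` must be divisible by
        the 8 modality x type x role cells.
    volume_dims, voxel_size_mm :
        Desk-scale volume geometry; an affine centred on the volume keeps
        mm coordinate reporting meaningful.
    tr_acquire_s, tr_silence_s :
        Sparse-sampling cycle: scan burst then silence (stimuli play in the
        silent gap). One stimulus occupies one cycle.
    inter_block_trs :
        Silent cycles separating consecutive blocks.
    oddball_mode :
        ``"replace"`` flags existing blocks as odd-balls (total block count
        unchanged); ``"add"`` inserts extra odd-ball blocks so the pure
        factor cells stay perfectly balanced.
    error_rate :
        Bernoulli rate of stray button presses / execution errors per
        non-odd-ball block; flagged blocks are excluded from analysis.
    oddball_detection_rate :
        Probability an odd-ball block draws its (task-required) button press.
    """

    n_subjects: int = 15
    n_runs: int = 3
    blocks_per_run: int = 32
    stimuli_per_block: int = 3
    n_oddballs: int = 2
    volume_dims: tuple[int, int, int] = (24, 24, 18)
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    tr_acquire_s: float = 1.23
    tr_silence_s: float = 4.0
    inter_block_trs: int = 3
    oddball_mode: Literal["replace", "add"] = "replace"
    error_rate: float = 0.02
    oddball_detection_rate: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_runs", "blocks_per_run", "stimuli_per_block"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_oddballs < 0:
            raise ValueError("n_oddballs must be non-negative")
        if any(d < 1 for d in self.volume_dims):
            raise ValueError("volume_dims must be positive")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel_size_mm must be positive")
        if self.tr_acquire_s <= 0 or self.tr_silence_s < 0:
            raise ValueError("acquisition timing must be positive")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.oddball_mode not in ("replace", "add"):
            raise ValueError(f"unknown oddball_mode {self.oddball_mode!r}")

    @property
    def cycle_s(self) -> float:
        """Duration of one scan cycle (TR): acquisition burst + silence."""
        return self.tr_acquire_s + self.tr_silence_s

    @property
    def block_duration_s(self) -> float:
        return self.stimuli_per_block * self.cycle_s

    @property
    def block_period_trs(self) -> int:
        """Cycles from one block onset to the next (block + gap)."""
        return self.stimuli_per_block + self.inter_block_trs

    def run_duration_s(self, n_blocks: int | None = None) -> float:
        n = self.blocks_per_run if n_blocks is None else n_blocks
        return n * self.block_period_trs * self.cycle_s

    @property
    def geometry(self) -> VolumeGeometry:
        """Affine with voxel scaling and the volume centre at 0 mm."""
        dx, dy, dz = self.voxel_size_mm
        nx, ny, nz = self.volume_dims
        affine = np.diag([dx, dy, dz, 1.0])
        affine[:3, 3] = [-dx * (nx - 1) / 2, -dy * (ny - 1) / 2, -dz * (nz - 1) / 2]
        return VolumeGeometry(self.volume_dims, affine)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SignalSpec:
    """Planted signal structure for the simulator.

    The multivoxel role signal encodes the statistical structure that
    between-subject role decoding assumes: the same signed voxel pattern,
    added with opposite sign for fair vs unfair action blocks, in every
    subject. The identity-linked confound patterns are confounded with
    role *within* a subject (each subject sees one identity per role) but
    balanced across subjects, so they carry no between-subject role
    information; they are orthogonalized against the role pattern so the
    two amplitudes have independent meaning.

    Amplitudes are in beta units (same scale as ``noise_sd``); patterns are
    unit-RMS inside their region before scaling.
    """

    shared_region: np.ndarray
    role_pattern_region: np.ndarray
    shared_amplitude: float = 1.0
    role_pattern_amplitude: float = 0.5
    confound_pattern_amplitude: float = 0.5
    noise_sd: float = 1.0
    smooth_fwhm_mm: float = 4.0
    subject_offset_sd: float = 0.5

    def __post_init__(self) -> None:
        shared = np.asarray(self.shared_region, dtype=bool)
        role = np.asarray(self.role_pattern_region, dtype=bool)
        if shared.shape != role.shape:
            raise ValueError("shared_region and role_pattern_region shapes differ")
        for name in (
            "shared_amplitude",
            "role_pattern_amplitude",
            "confound_pattern_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.noise_sd < 0 or self.smooth_fwhm_mm < 0 or self.subject_offset_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        object.__setattr__(self, "shared_region", shared)
        object.__setattr__(self, "role_pattern_region", role)

    def with_(self, **kwargs) -> "SignalSpec":
        return replace(self, **kwargs)


def _box_mask(dims: tuple[int, int, int], lo: tuple[int, int, int], size: int) -> np.ndarray:
    mask = np.zeros(dims, dtype=bool)
    sl = tuple(slice(l, min(l + size, d)) for l, d in zip(lo, dims))
    mask[sl] = True
    return mask


def default_signal_spec(config: SimConfig, **overrides) -> SignalSpec:
    """Default planted-signal layout scaled to the configured volume.

    The univariate action>control region is a cube in the upper-posterior
    quadrant (a stand-in for parietal/premotor shared circuits); the
    multivoxel role region is a separate 5-voxel cube so searchlight
    recovery can be scored against a known locus.
    """
    nx, ny, nz = config.volume_dims
    shared = _box_mask(config.volume_dims, (nx // 4, ny // 2, nz // 2), max(3, nx // 4))
    role_side = 5 if min(config.volume_dims) >= 8 else 3
    role = _box_mask(
        config.volume_dims,
        (max(0, 3 * nx // 5), max(0, ny // 5), max(0, nz // 4)),
        role_side,
    )
    return SignalSpec(shared_region=shared, role_pattern_region=role, **overrides)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings (simulation + analysis thresholds).

    Threshold defaults follow the study conventions: q=.05 voxelwise FDR,
    execution localizer at p<.001 uncorrected with 10-voxel clusters,
    exploratory contrasts at p<.005 uncorrected, searchlight radius 3
    voxels, linear SVM cost 1, 1000 permutations.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    q_fdr: float = 0.05
    p_exec: float = 0.001
    p_unc: float = 0.005
    p_searchlight: float = 0.01
    min_cluster: int = 10
    min_cluster_searchlight: int = 50
    searchlight_radius: int = 3
    cost_c: float = 1.0
    m_permutations: int = 1000
    connectivity: int = 18
    n_rois: int = 6
    run_searchlight: bool = True
    smooth_fwhm_univariate_mm: float = 6.0
    signal_overrides: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q_fdr", "p_exec", "p_unc", "p_searchlight"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.m_permutations < 1:
            raise ValueError("m_permutations must be >= 1")
        if self.min_cluster < 1 or self.min_cluster_searchlight < 1:
            raise ValueError("cluster minima must be >= 1")
        if self.searchlight_radius < 0:
            raise ValueError("searchlight_radius must be >= 0")
        if self.cost_c <= 0:
            raise ValueError("cost_c must be > 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")

    def signal_spec(self) -> SignalSpec:
        return default_signal_spec(self.sim, **self.signal_overrides)
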