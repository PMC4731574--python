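"""Multi-subject synthetic block-design fMRI generator.

The generator reproduces the structure of the observation experiment it
emulates: a 2 (visual/auditory) x 2 (action/control) x 2 (fair/unfair
confederate) factorial presented in blocks of three same-type stimuli
under sparse sampling, with two odd-ball attention blocks per subject,
and — crucially — confederate identity, colour, and role confounded
*within* each subject but counterbalanced *across* subjects.

Planted signals:

* a univariate action>control offset inside ``shared_region`` (the
  stand-in for shared action-execution circuits),
* a signed multivoxel role pattern, identical for all subjects, added
  with opposite sign to fair vs unfair action blocks inside
  ``role_pattern_region``,
* identity-linked confound patterns (orthogonal to the role pattern)
  which within any single subject are perfectly confounded with role —
  the structure that makes leave-one-subject-out partitioning necessary.

All randomness flows through explicit integer seeds; two calls with the
same arguments are bit-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fairmirror.config import (
    COLORS,
    FACTOR_CELLS,
    IDENTITIES,
    MODALITIES,
    ROLES,
    STIM_TYPES,
    SimConfig,
    SignalSpec,
)
from fairmirror.io import SCHEDULE_COLUMNS, VolumeGeometry


@dataclass(frozen=True)
class ConfederateAssignment:
    """Per-subject mapping of confederate identity to role and colour.

    Both mappings are bijections: one confederate is fair and the other
    unfair, one wears blue and the other orange.
    """

    subject_id: str
    identity_to_role: dict[str, str]
    identity_to_color: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.identity_to_role) != set(IDENTITIES) or set(
            self.identity_to_role.values()
        ) != set(ROLES):
            raise ValueError("identity_to_role must be a bijection {A,B}->{fair,unfair}")
        if set(self.identity_to_color) != set(IDENTITIES) or set(
            self.identity_to_color.values()
        ) != set(COLORS):
            raise ValueError("identity_to_color must be a bijection {A,B}->{blue,orange}")

    @property
    def role_to_identity(self) -> dict[str, str]:
        return {r: i for i, r in self.identity_to_role.items()}


@dataclass(frozen=True)
class Block:
    """One stimulus block of the schedule."""

    run: int
    onset_s: float
    modality: str
    stim_type: str
    role: str
    identity: str
    color: str
    is_oddball: bool = False
    has_button_press: bool = False
    has_error: bool = False

    @property
    def is_analyzable(self) -> bool:
        """Odd-ball, button-press and error blocks never enter analysis."""
        return not (self.is_oddball or self.has_button_press or self.has_error)

    @property
    def cell(self) -> tuple[str, str, str]:
        return (self.modality, self.stim_type, self.role)


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered per-subject list of blocks with the subject's assignment."""

    subject_id: str
    blocks: tuple[Block, ...]
    assignment: ConfederateAssignment

    def __post_init__(self) -> None:
        for b in self.blocks:
            if self.assignment.identity_to_role[b.identity] != b.role:
                raise ValueError(
                    f"block role {b.role!r} inconsistent with assignment for "
                    f"identity {b.identity!r}"
                )
            if self.assignment.identity_to_color[b.identity] != b.color:
                raise ValueError(
                    f"block color {b.color!r} inconsistent with assignment for "
                    f"identity {b.identity!r}"
                )

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def runs(self) -> tuple[int, ...]:
        return tuple(sorted({b.run for b in self.blocks}))

    def analyzable_indices(self) -> np.ndarray:
        return np.array([i for i, b in enumerate(self.blocks) if b.is_analyzable], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": self.subject_id,
                "run": b.run,
                "onset_s": b.onset_s,
                "modality": b.modality,
                "stim_type": b.stim_type,
                "role": b.role,
                "identity": b.identity,
                "color": b.color,
                "is_oddball": b.is_oddball,
                "has_button_press": b.has_button_press,
                "has_error": b.has_error,
            }
            for b in self.blocks
        ]
        return pd.DataFrame(rows, columns=SCHEDULE_COLUMNS)


def _assignment_from_combo(subject_id: str, role_of_a: str, color_of_a: str) -> ConfederateAssignment:
    other_role = ROLES[1] if role_of_a == ROLES[0] else ROLES[0]
    other_color = COLORS[1] if color_of_a == COLORS[0] else COLORS[0]
    return ConfederateAssignment(
        subject_id=subject_id,
        identity_to_role={"A": role_of_a, "B": other_role},
        identity_to_color={"A": color_of_a, "B": other_color},
    )


def make_counterbalance(n_subjects: int, seed: int = 0) -> list[ConfederateAssignment]:
    """Assign confederate role/colour per subject, balanced across subjects.

    Each confederate plays each role and wears each colour equally often:
    the four identity x role x colour combinations are cycled, so for
    ``n_subjects`` divisible by 4 every cell count is exact and otherwise
    cell counts differ by at most 1. Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    combos = list(itertools.product(ROLES, COLORS))  # (role_of_A, color_of_A)
    picks: list[tuple[str, str]] = []
    picks.extend(combos * (n_subjects // 4))
    remainder = n_subjects % 4
    if remainder:
        extra = rng.choice(4, size=remainder, replace=False)
        picks.extend(combos[i] for i in sorted(extra))
    order = rng.permutation(n_subjects)
    return [
        _assignment_from_combo(f"sub-{i + 1:02d}", *picks[order[i]])
        for i in range(n_subjects)
    ]


def _run_onset(config: SimConfig, position: int) -> float:
    return position * config.block_period_trs * config.cycle_s


def make_block_schedule(
    config: SimConfig, assignment: ConfederateAssignment, seed: int = 0
) -> BlockSchedule:
    """Build one subject's randomized block schedule.

    Every run holds ``blocks_per_run`` blocks split equally over the 8
    modality x type x role cells, in a seeded random order. Odd-ball
    (mixed attention-check) blocks are then placed according to
    ``config.oddball_mode``:

    ``"replace"``
        ``n_oddballs`` existing blocks are flagged in place (total count
        unchanged; the flagged cells lose one analyzable block each).
    ``"add"``
        ``n_oddballs`` extra flagged blocks are inserted at random
        positions, so the pure cells stay perfectly balanced.

    Stray button presses / errors are Bernoulli(``error_rate``) per
    non-odd-ball block; odd-ball blocks draw their required button press
    with ``oddball_detection_rate``.
    """
    if config.blocks_per_run % len(FACTOR_CELLS) != 0:
        raise ValueError(
            f"blocks_per_run={config.blocks_per_run} not divisible by "
            f"{len(FACTOR_CELLS)} factor cells"
        )
    rng = np.random.default_rng(seed)
    per_cell = config.blocks_per_run // len(FACTOR_CELLS)
    role_to_identity = assignment.role_to_identity

    # cell labels per run, shuffled
    run_cells: list[list[tuple[str, str, str]]] = []
    for _ in range(config.n_runs):
        cells = [c for c in FACTOR_CELLS for _ in range(per_cell)]
        rng.shuffle(cells)
        run_cells.append(cells)

    # odd-ball placement: (run, position) slots
    oddball_slots: set[tuple[int, int]] = set()
    if config.n_oddballs:
        flat = [(r, p) for r in range(config.n_runs) for p in range(config.blocks_per_run)]
        chosen = rng.choice(len(flat), size=config.n_oddballs, replace=False)
        oddball_slots = {flat[i] for i in sorted(chosen)}

    blocks: list[Block] = []
    for run in range(config.n_runs):
        cells = list(run_cells[run])
        oddball_positions = {p for (r, p) in oddball_slots if r == run}
        if config.oddball_mode == "add":
            # insert extra mixed blocks, pushing later blocks back
            for p in sorted(oddball_positions):
                mixed = (
                    rng.choice(MODALITIES),
                    rng.choice(STIM_TYPES),
                    rng.choice(ROLES),
                )
                cells.insert(min(p, len(cells)), ("ODD",) + tuple(mixed))
        position = 0
        for cell in cells:
            if cell[0] == "ODD":
                modality, stim_type, role = cell[1], cell[2], cell[3]
                is_oddball = True
            else:
                modality, stim_type, role = cell
                is_oddball = (
                    config.oddball_mode == "replace" and position in oddball_positions
                )
            identity = role_to_identity[role]
            color = assignment.identity_to_color[identity]
            if is_oddball:
                pressed = bool(rng.random() < config.oddball_detection_rate)
                error = False
            else:
                pressed = bool(rng.random() < config.error_rate)
                error = bool(rng.random() < config.error_rate)
            blocks.append(
                Block(
                    run=run,
                    onset_s=_run_onset(config, position),
                    modality=str(modality),
                    stim_type=str(stim_type),
                    role=str(role),
                    identity=identity,
                    color=color,
                    is_oddball=is_oddball,
                    has_button_press=pressed,
                    has_error=error,
                )
            )
            position += 1
    return BlockSchedule(subject_id=assignment.subject_id, blocks=tuple(blocks), assignment=assignment)


@dataclass(frozen=True)
class SignalTemplates:
    """Noise-free per-condition mean volumes plus the planted patterns.

    ``volumes`` is keyed by (modality, stim_type, role, identity); the
    role and confound patterns are exposed for parameter-recovery tests.
    """

    volumes: dict[tuple[str, str, str, str], np.ndarray]
    role_pattern: np.ndarray
    confound_patterns: dict[str, np.ndarray]
    geometry: VolumeGeometry

    def for_block(self, block: Block) -> np.ndarray:
        return self.volumes[(block.modality, block.stim_type, block.role, block.identity)]


def _unit_rms(pattern: np.ndarray, region: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(pattern[region] ** 2))
    if rms > 0:
        pattern = pattern / rms
    return pattern


def make_signal_templates(
    config: SimConfig, spec: SignalSpec, seed: int = 0
) -> SignalTemplates:
    """Construct noise-free condition templates with the planted structure.

    * action conditions carry ``shared_amplitude`` inside ``shared_region``;
    * fair/unfair action conditions differ only by ±(amplitude x pattern)
      inside ``role_pattern_region`` — the same signed pattern for every
      subject;
    * each identity contributes a confound pattern to its action blocks,
      orthogonalized against the role pattern (zero dot product) so the
      two amplitudes are independently meaningful.
    """
    dims = config.volume_dims
    if spec.shared_region.shape != dims or spec.role_pattern_region.shape != dims:
        raise ValueError(
            f"signal regions shaped {spec.shared_region.shape} do not match "
            f"volume dims {dims}"
        )
    rng = np.random.default_rng(seed)
    region = spec.role_pattern_region

    role_pattern = np.zeros(dims)
    role_pattern[region] = rng.standard_normal(int(region.sum()))
    role_pattern = _unit_rms(role_pattern, region)

    confound: dict[str, np.ndarray] = {}
    denom = float(np.sum(role_pattern**2))
    for identity in IDENTITIES:
        pat = np.zeros(dims)
        pat[region] = rng.standard_normal(int(region.sum()))
        if denom > 0:
            pat -= (np.sum(pat * role_pattern) / denom) * role_pattern
        confound[identity] = _unit_rms(pat, region)

    volumes: dict[tuple[str, str, str, str], np.ndarray] = {}
    role_sign = {"fair": 1.0, "unfair": -1.0}
    for modality in MODALITIES:
        for stim_type in STIM_TYPES:
            for role in ROLES:
                for identity in IDENTITIES:
                    vol = np.zeros(dims)
                    if stim_type == "action":
                        vol[spec.shared_region] += spec.shared_amplitude
                        vol += (
                            role_sign[role]
                            * spec.role_pattern_amplitude
                            * role_pattern
                        )
                        vol += spec.confound_pattern_amplitude * confound[identity]
                    volumes[(modality, stim_type, role, identity)] = vol
    return SignalTemplates(
        volumes=volumes,
        role_pattern=role_pattern,
        confound_patterns=confound,
        geometry=config.geometry,
    )


@dataclass
class SubjectBetas:
    """Per-subject collection of 3D parameter-estimate volumes, one per block."""

    subject_id: str
    schedule: BlockSchedule
    volumes: np.ndarray  # (n_blocks, nx, ny, nz)
    geometry: VolumeGeometry

    def __post_init__(self) -> None:
        if self.volumes.shape[0] != len(self.schedule):
            raise ValueError("one volume per scheduled block required")
        if tuple(self.volumes.shape[1:]) != self.geometry.dims:
            raise ValueError("beta volume shape does not match geometry")

    def analyzable(self) -> tuple[list[Block], np.ndarray]:
        idx = self.schedule.analyzable_indices()
        return [self.schedule.blocks[i] for i in idx], self.volumes[idx]


def simulate_subject_betas(
    schedule: BlockSchedule,
    templates: SignalTemplates,
    spec: SignalSpec,
    seed: int = 0,
) -> SubjectBetas:
    """Emulate first-level per-block parameter-estimate images.

    Each block's volume is its condition template plus a subject-constant
    random offset field (sd ``subject_offset_sd``), a spatially smoothed
    Gaussian noise component (FWHM ``smooth_fwhm_mm``), and white Gaussian
    noise (sd ``noise_sd``). Bit-reproducible given ``seed``.
    """
    from fairmirror.glm import gaussian_smooth

    dims = templates.geometry.dims
    rng = np.random.default_rng(seed)
    offset = rng.standard_normal(dims) * spec.subject_offset_sd
    voxel_size = np.diag(templates.geometry.affine)[:3]
    n_blocks = len(schedule)
    volumes = np.empty((n_blocks,) + dims)
    for i, block in enumerate(schedule.blocks):
        vol = templates.for_block(block) + offset
        white = rng.standard_normal(dims) * spec.noise_sd
        smooth_src = rng.standard_normal(dims) * spec.noise_sd
        if spec.smooth_fwhm_mm > 0 and spec.noise_sd > 0:
            vol = vol + gaussian_smooth(smooth_src, spec.smooth_fwhm_mm, tuple(np.abs(voxel_size)))
        vol = vol + white
        volumes[i] = vol
    return SubjectBetas(
        subject_id=schedule.subject_id,
        schedule=schedule,
        volumes=volumes,
        geometry=templates.geometry,
    )


def simulate_execution_maps(
    n_subjects: int, config: SimConfig, spec: SignalSpec, seed: int = 0
) -> list[np.ndarray]:
    """Synthetic action-execution localizer contrasts (one map per subject).

    The observation experiment's execution run is not simulated at the
    time-series level; this helper emits per-subject contrast maps with
    the shared-region effect plus white noise so the shared-voxel
    conjunction analysis can be exercised end to end.
    """
    rng = np.random.default_rng(seed)
    dims = config.volume_dims
    maps = []
    for _ in range(n_subjects):
        vol = np.zeros(dims)
        vol[spec.shared_region] += spec.shared_amplitude
        vol += rng.standard_normal(dims) * spec.noise_sd
        maps.append(vol)
    return maps


def simulate_timeseries(
    schedule: BlockSchedule,
    truth: dict[str, np.ndarray | float],
    config: SimConfig,
    noise_sd: float = 0.0,
    seed: int = 0,
    design=None,
    mode: str = "per_condition",
    cutoff_s: float | None = None,
):
    """Forward-generate a sparse-sampling 4D series from known coefficients.

    The signal at each acquisition is the design-matrix row times the true
    coefficient volumes (columns absent from ``truth`` contribute zero),
    plus white noise. Acquisition times follow the sparse cycle: a
    ``tr_acquire_s`` burst then ``tr_silence_s`` of silence.

    Returns
    -------
    (series, times, design)
        ``series`` has shape ``(*volume_dims, n_acquisitions)``; ``times``
        are the acquisition midpoints in seconds (concatenated runs);
        ``design`` is the :class:`~fairmirror.glm.DesignMatrix` used.
    """
    from fairmirror.glm import build_design_matrix

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if design is None:
        design = build_design_matrix(schedule, config, mode=mode, cutoff_s=cutoff_s)
    rng = np.random.default_rng(seed)
    dims = config.volume_dims
    n_vox = int(np.prod(dims))
    n_t = design.matrix.shape[0]
    coef = np.zeros((design.matrix.shape[1], n_vox))
    for name, value in truth.items():
        if name not in design.names:
            raise KeyError(f"truth column {name!r} not in design ({design.names[:5]}...)")
        j = design.names.index(name)
        value = np.asarray(value, dtype=float)
        coef[j] = value.ravel() if value.ndim else np.full(n_vox, float(value))
    signal = design.matrix @ coef  # (n_t, n_vox)
    if noise_sd > 0:
        signal = signal + rng.standard_normal((n_t, n_vox)) * noise_sd
    series = signal.T.reshape(dims + (n_t,))
    return series, design.acquisition_times_s.copy(), design
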