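"""Synthetic registered volumes, arena trajectories and wingbeat traces.

Every generator here emulates the statistical structure of one of the
study's input streams with exact, machine-checkable ground truth:

* replicate confocal stacks of a branched, arbor-like neurite signal on a
  common registered grid, with rigid replicate-to-replicate jitter standing
  in for residual registration error;
* mask pairs and box-arbor stack pairs with an exactly designed directional
  overlap fraction, the ground truth for overlap-recovery tests;
* group trajectories in the four-quadrant valence arena and the Flybowl,
  driven by a biased random walk whose illuminated-pair membership follows
  an explicit two-state Markov chain (so stationary occupancy has a closed
  form);
* tethered-flight wingbeat sessions with the assay's 6-block randomised
  trial structure and designed step responses.

Determinism contract: every generator is a pure function of its design
object, whose ``seed`` deterministically spawns independent per-object
substreams.  Generated objects carry their generating parameters, so
recovery tests never re-derive ground truth from file names.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .flight import WingbeatTrace
from .quadrant import ArenaGeometry, Epoch, TrialTrack, validate_schedule
from .volumes import DEFAULT_SPACE, DEFAULT_SPACING, BinaryMask, LabelVolume

DEFAULT_GRID = (64, 64, 32)


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# arbor stacks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArborParams:
    """Parameters of the synthetic branched-arbor volume generator.

    The default grid is 64 x 64 x 32 voxels at the template stacks' 20x voxel
    size of 0.56 x 0.56 x 1.0 um, i.e. a spatially scaled-down registered
    stack.  ``jitter_sd`` is the per-axis SD (um) of the rigid displacement
    applied independently to each replicate; the default of one in-plane
    voxel stands in for residual registration error.
    """

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    n_branches: int = 6
    branch_length: float = 12.0  # um
    # >= 2 voxels thick along every axis, so a sigma = 1 voxel blur cannot
    # erode the tube below the threshold (the pipeline stays non-degrading
    # on noise-free input)
    tube_radius: float = 2.0  # um
    intensity_fg: float = 200.0
    intensity_bg: float = 20.0
    noise_sd: float = 10.0
    jitter_sd: float = 0.56  # um, one in-plane voxel
    seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive per axis")
        if self.branch_length <= 0 or self.tube_radius <= 0:
            raise ValueError("branch_length and tube_radius must be positive")
        if self.intensity_fg <= self.intensity_bg:
            raise ValueError("intensity_fg must exceed intensity_bg")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise_sd and jitter_sd must be non-negative")


@dataclass
class ReplicateStacks:
    """Replicate volumes plus the ground truth that generated them."""

    volumes: list[LabelVolume]
    truth: BinaryMask  # unjittered arbor voxel set
    offsets_um: np.ndarray  # (n_replicates, 3) rigid jitter per replicate
    params: ArborParams


def _arbor_skeleton(params: ArborParams, rng: np.random.Generator) -> np.ndarray:
    """Sample points (um) of a random branched walk, confined to the grid
    with a margin of one tube radius so the painted tube always fits."""
    extent = np.array(params.grid_shape) * np.array(params.voxel_spacing)
    margin = params.tube_radius + max(params.voxel_spacing)
    for axis, e in enumerate(extent):
        if e <= 2 * margin:
            raise ValueError(
                f"grid too small to contain the arbor along axis {axis} "
                f"({'xyz'[axis]}): extent {e:.2f} um <= 2 x margin {margin:.2f} um"
            )
    lo, hi = margin, extent - margin
    step = min(params.voxel_spacing) / 2.0
    nodes = [extent / 2.0]
    points = [extent / 2.0]
    for _ in range(params.n_branches):
        start = nodes[rng.integers(len(nodes))]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = start.copy()
        travelled = 0.0
        while travelled < params.branch_length:
            direction += 0.3 * rng.normal(size=3)  # gentle meander
            direction /= np.linalg.norm(direction)
            pos = pos + direction * step
            # reflect at the margin box so the tube stays inside the grid
            for ax in range(3):
                if pos[ax] < lo:
                    pos[ax] = 2 * lo - pos[ax]
                    direction[ax] *= -1
                elif pos[ax] > hi[ax]:
                    pos[ax] = 2 * hi[ax] - pos[ax]
                    direction[ax] *= -1
            points.append(pos.copy())
            travelled += step
        nodes.append(pos.copy())
    return np.asarray(points)


def _paint_tube(points_um: np.ndarray, params: ArborParams) -> np.ndarray:
    """Voxelise a skeleton: voxels whose centre lies within one tube radius
    of any sample point."""
    shape = params.grid_shape
    spacing = np.array(params.voxel_spacing)
    mask = np.zeros(shape, dtype=bool)
    r_vox = np.ceil(params.tube_radius / spacing).astype(int)
    offs = np.stack(
        np.meshgrid(
            *[np.arange(-r, r + 1) for r in r_vox], indexing="ij"
        ),
        axis=-1,
    ).reshape(-1, 3)
    offs_um = offs * spacing
    within = np.linalg.norm(offs_um, axis=1) <= params.tube_radius
    offs = offs[within]
    centers = np.round(points_um / spacing - 0.5).astype(int)
    centers = np.unique(centers, axis=0)
    vox = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    ok = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    vox = vox[ok]
    mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return mask


def generate_replicate_stacks(params: ArborParams, n_replicates: int = 3) -> ReplicateStacks:
    """Replicate registered stacks of one arbor with independent rigid jitter.

    Each replicate contains the same ground-truth arbor displaced by a
    Gaussian rigid translation (``jitter_sd`` per axis, um) plus additive
    Gaussian intensity noise.  With ``noise_sd = jitter_sd = 0`` the
    replicates are identical.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng_skel, rng_jitter, rng_noise = _rng_streams(params.seed, 3)
    skeleton = _arbor_skeleton(params, rng_skel)
    truth_data = _paint_tube(skeleton, params)
    truth = BinaryMask(
        truth_data,
        spacing=params.voxel_spacing,
        cell_type="synthetic_arbor",
        compartment="whole",
    )
    offsets = rng_jitter.normal(0.0, params.jitter_sd, size=(n_replicates, 3))
    if params.jitter_sd == 0:
        offsets[:] = 0.0
    volumes = []
    for r in range(n_replicates):
        arbor = (
            truth_data
            if not offsets[r].any()
            else _paint_tube(skeleton + offsets[r], params)
        )
        data = np.full(params.grid_shape, params.intensity_bg, dtype=np.float32)
        data[arbor] = params.intensity_fg
        if params.noise_sd > 0:
            data = data + rng_noise.normal(0.0, params.noise_sd, params.grid_shape).astype(
                np.float32
            )
        volumes.append(LabelVolume(data, spacing=params.voxel_spacing))
    return ReplicateStacks(volumes=volumes, truth=truth, offsets_um=offsets, params=params)


# ---------------------------------------------------------------------------
# mask pairs with exact designed overlap
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapDesign:
    """Design for a mask pair with exact directional overlap.

    ``target_fraction_a_in_b`` is the designed |A intersect B| / |A|; the
    intersection size is ``round(target * size_a)`` exactly by construction.
    """

    target_fraction_a_in_b: float
    size_a: int
    size_b: int
    seed: int = 0
    grid_shape: tuple[int, int, int] = DEFAULT_GRID

    def __post_init__(self):
        if not 0.0 <= self.target_fraction_a_in_b <= 1.0:
            raise ValueError("target_fraction_a_in_b must be in [0, 1]")
        if self.size_a < 1 or self.size_b < 1:
            raise ValueError("mask sizes must be >= 1")
        k = round(self.target_fraction_a_in_b * self.size_a)
        if k > self.size_b:
            raise ValueError(
                f"infeasible design: intersection {k} exceeds size_b {self.size_b}"
            )
        if self.size_a + self.size_b - k > int(np.prod(self.grid_shape)):
            raise ValueError("infeasible design: masks do not fit on the grid")

    @property
    def intersection(self) -> int:
        return round(self.target_fraction_a_in_b * self.size_a)


def generate_mask_pair(design: OverlapDesign) -> tuple[BinaryMask, BinaryMask]:
    """Random mask pair with |A| = size_a, |B| = size_b and the exact
    designed intersection voxel count."""
    rng = np.random.default_rng(design.seed)
    n_vox = int(np.prod(design.grid_shape))
    k = design.intersection
    picks = rng.choice(n_vox, size=design.size_a + design.size_b - k, replace=False)
    idx_a = picks[: design.size_a]
    idx_b = np.concatenate([picks[:k], picks[design.size_a :]])
    a = np.zeros(n_vox, dtype=bool)
    b = np.zeros(n_vox, dtype=bool)
    a[idx_a] = True
    b[idx_b] = True
    mk = lambda flat, name: BinaryMask(
        flat.reshape(design.grid_shape), cell_type=name, compartment="whole"
    )
    return mk(a, "A"), mk(b, "B")


@dataclass(frozen=True)
class OverlapStackDesign:
    """Replicate-stack pair whose pipeline masks should recover a designed
    directional overlap.

    Two equal boxes of ``box_shape`` voxels are painted as foreground, the
    second shifted along x by ``(1 - target_p1) * length`` voxels, so the
    ground-truth P1 (overlap of A in B) equals ``target_p1`` exactly when
    that shift is integral.  Replicates differ by intensity noise only —
    jitter would displace the designed intersection.
    """

    target_p1: float
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    box_shape: tuple[int, int, int] = (30, 18, 14)
    intensity_fg: float = 200.0
    intensity_bg: float = 20.0
    noise_sd: float = 15.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.target_p1 <= 1.0:
            raise ValueError("target_p1 must be in [0, 1]")
        shift = round((1.0 - self.target_p1) * self.box_shape[0])
        if self.box_shape[0] + shift + 4 > self.grid_shape[0]:
            raise ValueError("grid too small along x for the designed overlap")
        if any(b + 4 > g for b, g in zip(self.box_shape[1:], self.grid_shape[1:])):
            raise ValueError("grid too small for the box cross-section")


def generate_overlap_stacks(design: OverlapStackDesign):
    """Replicate stacks for two 'cell types' with designed directional overlap.

    Returns ``(stacks_a, stacks_b, truth_a, truth_b, true_p1)`` where the
    stacks are lists of noisy LabelVolumes and ``true_p1`` is the exact
    ground-truth |A intersect B| / |A| in percent.
    """
    rng = np.random.default_rng(design.seed)
    shape = design.grid_shape
    bx, by, bz = design.box_shape
    shift = round((1.0 - design.target_p1) * bx)
    x0 = (shape[0] - (bx + shift)) // 2
    y0 = (shape[1] - by) // 2
    z0 = (shape[2] - bz) // 2
    a = np.zeros(shape, dtype=bool)
    b = np.zeros(shape, dtype=bool)
    a[x0 : x0 + bx, y0 : y0 + by, z0 : z0 + bz] = True
    b[x0 + shift : x0 + shift + bx, y0 : y0 + by, z0 : z0 + bz] = True
    true_p1 = 100.0 * np.logical_and(a, b).sum() / a.sum()

    def stacks(mask: np.ndarray) -> list[LabelVolume]:
        out = []
        for _ in range(design.n_replicates):
            data = np.full(shape, design.intensity_bg, dtype=np.float32)
            data[mask] = design.intensity_fg
            if design.noise_sd > 0:
                data = data + rng.normal(0, design.noise_sd, shape).astype(np.float32)
            out.append(LabelVolume(data, spacing=design.voxel_spacing))
        return out

    truth_a = BinaryMask(a, spacing=design.voxel_spacing, cell_type="A", compartment="whole")
    truth_b = BinaryMask(b, spacing=design.voxel_spacing, cell_type="B", compartment="whole")
    return stacks(a), stacks(b), truth_a, truth_b, float(true_p1)


# ---------------------------------------------------------------------------
# arena trajectories
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadrantMotion:
    """Two-state biased walk for the four-quadrant arena.

    Each frame a fly either keeps to its current half-disk (the illuminated
    pair of quadrants or the dark pair) or switches: from dark to lit with
    probability ``p_enter`` and from lit to dark with probability ``p_leave``
    during ON epochs, and symmetrically with ``p_switch_off`` when no light
    is on.  Membership is therefore an explicit two-state Markov chain with
    stationary lit-occupancy p_enter / (p_enter + p_leave); within the
    current half-disk the fly takes a uniformly resampled step of SD
    ``step_mm``, rejected at the boundary, so positions never leave the
    arena.
    """

    p_enter: float = 0.05
    p_leave: float = 0.05
    p_switch_off: float = 0.05
    step_mm: float = 2.0

    def __post_init__(self):
        for name in ("p_enter", "p_leave", "p_switch_off"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")

    @property
    def stationary_lit(self) -> float:
        """Closed-form stationary probability of being in the lit pair."""
        if self.p_enter + self.p_leave == 0:
            return 0.5
        return self.p_enter / (self.p_enter + self.p_leave)


@dataclass(frozen=True)
class FlybowlMotion:
    """Random walk for the Flybowl: speed scales with LED intensity."""

    speed_mm_s: float = 4.0
    #: fractional speed increase per uW/mm^2 of LED intensity
    stim_gain: float = 0.0


@dataclass(frozen=True)
class ArenaDesign:
    """Design of one simulated arena trial."""

    arena_kind: str = "four_quadrant"
    diameter_mm: float = 100.0
    n_flies: int = 20
    frame_rate: float = 30.0
    schedule: tuple[Epoch, ...] | None = None
    motion: QuadrantMotion | FlybowlMotion | None = None
    duration_s: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.arena_kind not in ("four_quadrant", "flybowl"):
            raise ValueError(f"unknown arena_kind {self.arena_kind!r}")
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")

    def resolved_schedule(self) -> list[Epoch]:
        if self.schedule is not None:
            sched = list(self.schedule)
        elif self.arena_kind == "four_quadrant":
            sched = default_quadrant_schedule()
        else:
            sched = default_flybowl_schedule()
        validate_schedule(sched)
        dur = self.resolved_duration()
        if any(e.end_s > dur + 1e-9 for e in sched):
            raise ValueError("schedule extends past the trial duration")
        return sched

    def resolved_duration(self) -> float:
        if self.duration_s is not None:
            return self.duration_s
        sched = self.schedule if self.schedule is not None else (
            default_quadrant_schedule()
            if self.arena_kind == "four_quadrant"
            else default_flybowl_schedule()
        )
        return max(e.end_s for e in sched)


def default_quadrant_schedule() -> list[Epoch]:
    """The two-minute valence trial: 30 s dark, 30 s one lit pair, 30 s dark,
    30 s the other lit pair."""
    return [
        Epoch(0.0, 30.0, None),
        Epoch(30.0, 60.0, (2, 3)),
        Epoch(60.0, 90.0, None),
        Epoch(90.0, 120.0, (1, 4)),
    ]


#: Flybowl LED intensities, uW/mm^2 (weak, medium, strong)
FLYBOWL_INTENSITIES = (3.59, 11.88, 25.2)


def default_flybowl_schedule() -> list[Epoch]:
    """30 s acclimatisation, then three 5 s whole-field epochs of increasing
    intensity separated by 30 s."""
    out, t = [], 30.0
    for inten in FLYBOWL_INTENSITIES:
        out.append(Epoch(t, t + 5.0, "whole_field", intensity=inten))
        t += 35.0
    return out


def _uniform_in_half(rng, radius: float, lit: bool) -> np.ndarray:
    """Uniform point in the lit (x < 0, i.e. Q2+Q3) or dark (x > 0) half-disk
    for the canonical lit pair {2, 3}; callers flip x when the lit pair is
    {1, 4}."""
    while True:
        p = rng.uniform(-radius, radius, size=2)
        if p[0] ** 2 + p[1] ** 2 <= radius**2 and (p[0] < 0) == lit:
            return p


def generate_quadrant_trial(design: ArenaDesign) -> TrialTrack:
    """Simulate a four-quadrant valence trial.

    During ON epochs each fly's membership of the illuminated half-disk
    follows the design's two-state chain; during OFF epochs the two
    half-disks are symmetric.  Positions are confined to the arena.
    """
    if design.arena_kind != "four_quadrant":
        raise ValueError("generate_quadrant_trial needs arena_kind='four_quadrant'")
    motion = design.motion if design.motion is not None else QuadrantMotion()
    if not isinstance(motion, QuadrantMotion):
        raise TypeError("four_quadrant trials need a QuadrantMotion model")
    schedule = design.resolved_schedule()
    arena = ArenaGeometry(diameter_mm=design.diameter_mm)
    radius = arena.radius_mm
    rng = np.random.default_rng(design.seed)
    n_frames = int(round(design.resolved_duration() * design.frame_rate))
    times = np.arange(n_frames) / design.frame_rate
    # epoch lookup per frame: lit pair tuple or None
    lit_pair: list = [None] * n_frames
    for e in schedule:
        if e.is_on and e.quadrants != "whole_field":
            pair = tuple(sorted(e.quadrants))
            for idx in np.nonzero((times >= e.start_s) & (times < e.end_s))[0]:
                lit_pair[idx] = pair
    pos = np.empty((design.n_flies, 2))
    in_left = rng.random(design.n_flies) < 0.5  # left half-disk = Q2+Q3
    for i in range(design.n_flies):
        pos[i] = _uniform_in_half(rng, radius, lit=in_left[i])
    records = []
    for f in range(n_frames):
        pair = lit_pair[f]
        for i in range(design.n_flies):
            if pair is None:
                switch = rng.random() < motion.p_switch_off
            else:
                lit_is_left = pair == (2, 3)
                in_lit = in_left[i] == lit_is_left
                switch = rng.random() < (motion.p_leave if in_lit else motion.p_enter)
            if switch:
                in_left[i] = not in_left[i]
                pos[i] = _uniform_in_half(rng, radius, lit=in_left[i])
            else:
                for _ in range(64):  # rejection walk step within the half-disk
                    cand = pos[i] + rng.normal(0.0, motion.step_mm, size=2)
                    inside = cand[0] ** 2 + cand[1] ** 2 <= radius**2
                    if inside and (cand[0] < 0) == in_left[i]:
                        pos[i] = cand
                        break
            records.append((times[f], i, pos[i, 0], pos[i, 1]))
    frames = pd.DataFrame(records, columns=["time_s", "fly_id", "x_mm", "y_mm"])
    return TrialTrack(
        frames=frames, arena=arena, schedule=schedule, frame_rate=design.frame_rate
    )


def generate_flybowl_trial(design: ArenaDesign) -> TrialTrack:
    """Simulate a Flybowl whole-field trial: a reflecting random walk whose
    step size scales with LED intensity through ``stim_gain``."""
    if design.arena_kind != "flybowl":
        raise ValueError("generate_flybowl_trial needs arena_kind='flybowl'")
    motion = design.motion if design.motion is not None else FlybowlMotion()
    if not isinstance(motion, FlybowlMotion):
        raise TypeError("flybowl trials need a FlybowlMotion model")
    schedule = design.resolved_schedule()
    arena = ArenaGeometry(diameter_mm=design.diameter_mm)
    radius = arena.radius_mm
    rng = np.random.default_rng(design.seed)
    n_frames = int(round(design.resolved_duration() * design.frame_rate))
    times = np.arange(n_frames) / design.frame_rate
    intensity = np.zeros(n_frames)
    for e in schedule:
        if e.quadrants == "whole_field":
            sel = (times >= e.start_s) & (times < e.end_s)
            intensity[sel] = e.intensity or 0.0
    base_step = motion.speed_mm_s / design.frame_rate
    theta0 = rng.uniform(0, 2 * np.pi, design.n_flies)
    r0 = radius * np.sqrt(rng.uniform(0, 1, design.n_flies)) * 0.9
    pos = np.stack([r0 * np.cos(theta0), r0 * np.sin(theta0)], axis=1)
    heading = rng.uniform(0, 2 * np.pi, design.n_flies)
    records = []
    for f in range(n_frames):
        step = base_step * (1.0 + motion.stim_gain * intensity[f])
        heading += rng.normal(0.0, 0.4, design.n_flies)
        delta = step * np.stack([np.cos(heading), np.sin(heading)], axis=1)
        cand = pos + delta
        outside = np.einsum("ij,ij->i", cand, cand) > radius**2
        heading[outside] += np.pi  # turn back at the wall
        cand[outside] = pos[outside]
        pos = cand
        for i in range(design.n_flies):
            records.append((times[f], i, pos[i, 0], pos[i, 1]))
    frames = pd.DataFrame(records, columns=["time_s", "fly_id", "x_mm", "y_mm"])
    return TrialTrack(
        frames=frames, arena=arena, schedule=schedule, frame_rate=design.frame_rate
    )


# ---------------------------------------------------------------------------
# tethered flight sessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlightDesign:
    """Design of one tethered-flight session group.

    Matches the assay's trial structure: ``n_blocks`` blocks per fly, each a
    random interleaving of (visual condition x LED on/off) combinations;
    10 s trials sampled at 1 kHz with a 500 ms LED train starting at 5 s.
    ``effect_sizes`` maps a flight parameter (yaw, thrust, freq) to the step
    change evoked during stimulation in effector-expressing flies; the step
    holds for the stimulation window and decays exponentially afterwards
    with time constant ``decay_s``.
    """

    n_flies: int = 6
    n_blocks: int = 6
    trial_length_s: float = 10.0
    stim_onset_s: float = 5.0
    stim_duration_s: float = 0.5
    sample_rate: float = 1000.0
    visual_conditions: tuple[str, ...] = ("dark", "stationary_stripe", "closed_loop_stripe")
    effect_sizes: dict = field(default_factory=dict)
    decay_s: float = 1.0
    noise_sd: float = 0.08
    base_freq_hz: float = 200.0
    base_amp: float = 1.0
    has_effector: bool = True
    group_label: str = "experimental"
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not (0 <= self.stim_onset_s
                and self.stim_onset_s + self.stim_duration_s <= self.trial_length_s):
            raise ValueError("stimulation window must lie inside the trial")


def generate_flight_session(design: FlightDesign) -> list[WingbeatTrace]:
    """Simulate wingbeat traces for a group of tethered flies.

    Yaw effects are embedded antisymmetrically (+e/2 on the left wing, -e/2
    on the right), thrust effects symmetrically, and frequency effects on the
    frequency channel, so the designed step is exactly what the corresponding
    analysis parameter recovers.  Effects appear only in LED trials of
    effector-expressing flies.
    """
    n_samples = int(round(design.trial_length_s * design.sample_rate))
    t = np.arange(n_samples) / design.sample_rate
    onset, offset = design.stim_onset_s, design.stim_onset_s + design.stim_duration_s
    envelope = np.zeros(n_samples)
    during = (t >= onset) & (t < offset)
    after = t >= offset
    envelope[during] = 1.0
    envelope[after] = np.exp(-(t[after] - offset) / design.decay_s)
    combos = [(v, s) for v in design.visual_conditions for s in (False, True)]
    traces = []
    fly_rngs = _rng_streams(design.seed, design.n_flies)
    for fi in range(design.n_flies):
        rng = fly_rngs[fi]
        fly_id = f"{design.group_label}_{fi}"
        # per-fly baseline offsets: fly-to-fly variability removed by the
        # baseline subtraction in the analysis
        freq0 = design.base_freq_hz + rng.normal(0, 2.0)
        ampL0 = design.base_amp + rng.normal(0, 0.05)
        ampR0 = design.base_amp + rng.normal(0, 0.05)
        for block in range(design.n_blocks):
            order = rng.permutation(len(combos))
            for slot, ci in enumerate(order):
                visual, stim = combos[ci]
                freq = freq0 + rng.normal(0, design.noise_sd * 10, n_samples)
                ampL = ampL0 + rng.normal(0, design.noise_sd, n_samples)
                ampR = ampR0 + rng.normal(0, design.noise_sd, n_samples)
                if stim and design.has_effector:
                    e_yaw = design.effect_sizes.get("yaw", 0.0)
                    e_thrust = design.effect_sizes.get("thrust", 0.0)
                    e_freq = design.effect_sizes.get("freq", 0.0)
                    ampL = ampL + envelope * (e_yaw / 2.0 + e_thrust / 2.0)
                    ampR = ampR + envelope * (-e_yaw / 2.0 + e_thrust / 2.0)
                    freq = freq + envelope * e_freq
                led = np.zeros(n_samples, dtype=bool)
                if stim:
                    led[during] = True
                traces.append(
                    WingbeatTrace(
                        time_s=t,
                        freq_hz=freq,
                        amp_left=ampL,
                        amp_right=ampR,
                        led_on=led,
                        visual_condition=visual,
                        trial_id=f"{fly_id}_b{block}_t{slot}",
                        block_id=block,
                        fly_id=fly_id,
                        has_effector=design.has_effector,
                        stim_onset_s=design.stim_onset_s,
                    )
                )
    return traces
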