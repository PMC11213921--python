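"""Synthetic behavioral and imaging data with known ground truth.

Two generators mirror the study's two experimental arms:

* ``generate_calcium_movies`` plants non-overlapping Gaussian-disc cell bodies
  in a frame and gives each a parameterized temporal response motif (phasic,
  strong phasic, sustained, delayed, or inhibitory), then adds a linear
  bleaching trend, Gaussian shot-like noise and rigid per-frame jitter.  The
  returned ground truth (cell centers, label image, motif ids, applied
  shifts) lets segmentation and response quantification be scored exactly.

* ``generate_choice_trajectories`` simulates agents choosing among four
  patches with the cue-integration choice probabilities, dwelling near the
  chosen patch under Ornstein-Uhlenbeck attraction and re-drawing targets at
  a fixed per-frame rate, so the stationary quarter occupancy matches the
  model evaluated at the known true reliabilities.

All randomness flows from the single seed in the spec object; generators
never consume global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .behavior import Trajectory
from .choice_model import CueModel, patch_probabilities

__all__ = [
    "MotifTemplates",
    "default_motif_templates",
    "SceneSpec",
    "AgentSpec",
    "CalciumMovie",
    "generate_calcium_movies",
    "generate_choice_trajectories",
    "default_patch_centers",
    "place_cells",
    "generate_profile_rows",
    "generate_triplet_population",
]


# ---------------------------------------------------------------------------
# temporal response motifs

class MotifTemplates:
    """Library of bounded temporal response motifs.

    Maps integer motif ids to callables f(t_seconds) -> response multiplier,
    where t is time since stimulus onset (f(t) = 0 for t < 0).
    """

    def __init__(self, templates: dict[int, callable]):
        self._templates = dict(templates)

    @property
    def ids(self):
        return sorted(self._templates)

    def __contains__(self, motif_id) -> bool:
        return motif_id in self._templates

    def render(self, motif_id: int, n_frames: int, onset_frame: int,
               frame_rate: float) -> np.ndarray:
        """Sample a motif time course on the frame grid of a movie."""
        if motif_id not in self._templates:
            raise KeyError(f"motif id {motif_id!r} missing from template library")
        t = (np.arange(n_frames) - onset_frame) / frame_rate
        out = np.zeros(n_frames)
        post = t >= 0
        out[post] = self._templates[motif_id](t[post])
        return out


def default_motif_templates(include_silent: bool = False) -> MotifTemplates:
    """Six motifs in the canonical order used throughout: 1-2 inhibitory,
    3 delayed, 4 phasic, 5 strong phasic, 6 sustained.

    Time constants are in seconds and sized for 1 Hz acquisition, where a
    2 s odor pulse evokes responses spanning tens of frames.  With
    ``include_silent`` the library also carries motif id 0, a flat zero time
    course, for planting non-responding cells.
    """
    silent = {0: lambda t: np.zeros_like(t)} if include_silent else {}
    return MotifTemplates(silent | {
        # sustained inhibition
        1: lambda t: -0.7 * (1.0 - np.exp(-t / 2.0)),
        # transient inhibition, recovering
        2: lambda t: -0.9 * (t / 3.0) * np.exp(1.0 - t / 3.0),
        # delayed excitation peaking late
        3: lambda t: (t / 8.0) ** 3 * np.exp(3.0 * (1.0 - t / 8.0)),
        # phasic excitation
        4: lambda t: (t / 2.5) * np.exp(1.0 - t / 2.5),
        # strong phasic excitation: larger, sharper and earlier-peaked
        5: lambda t: 2.0 * (t / 1.0) * np.exp(1.0 - t / 1.0),
        # sustained excitation (fast rise, plateau)
        6: lambda t: 1.0 - np.exp(-t / 1.5),
    })


# ---------------------------------------------------------------------------
# calcium movies

@dataclass(frozen=True)
class CalciumMovie:
    """One stimulus presentation: raw fluorescence stack plus metadata.

    ``stack`` is (n_frames, height, width); intensities are raw F.
    """

    stack: np.ndarray
    stimulus: str
    onset_frame: int
    frame_rate: float

    def __post_init__(self):
        if self.stack.ndim != 3:
            raise ValueError("stack must be (n_frames, height, width)")
        if not np.all(np.isfinite(self.stack)):
            raise ValueError("non-finite intensities")
        if self.onset_frame < 6:
            raise ValueError("onset_frame must be >= 6 (5 baseline frames needed)")

    @property
    def n_frames(self) -> int:
        return self.stack.shape[0]

    @property
    def frame_shape(self):
        return self.stack.shape[1:]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a planted-cell imaging scene."""

    frame_shape: tuple = (100, 100)
    n_cells: int = 20
    cell_radius_px: float = 4.0
    n_frames: int = 40
    onset_frame: int = 10
    frame_rate: float = 1.0
    motif_assignment: np.ndarray | None = None  # (n_cells, n_stimuli) ids
    stimuli: tuple = ("Lct", "Laa", "LaaLct")
    amplitude: float = 0.6
    baseline: float = 100.0
    noise_sd: float = 2.0
    bleach_slope: float = -0.05
    jitter_px: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_frames < 1 or self.frame_rate <= 0:
            raise ValueError("counts and rates must be positive")
        if self.onset_frame < 6:
            raise ValueError("onset_frame must be >= 6")
        if self.onset_frame >= self.n_frames:
            raise ValueError("onset_frame beyond movie end")


def place_cells(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample non-overlapping cell centers (distance > 2 radius),
    kept one diameter clear of the frame edge (plus jitter margin)."""
    h, w = spec.frame_shape
    margin = 2 * spec.cell_radius_px + spec.jitter_px
    centers = []
    for _ in range(20000):
        cand = np.array([rng.uniform(margin, h - margin),
                         rng.uniform(margin, w - margin)])
        if all(np.hypot(*(cand - c)) > 2 * spec.cell_radius_px for c in centers):
            centers.append(cand)
            if len(centers) == spec.n_cells:
                return np.array(centers)
    raise ValueError("could not place non-overlapping cells; frame too crowded")


def _disc(frame_shape, center, sigma) -> np.ndarray:
    h, w = frame_shape
    r = np.arange(h)[:, None]
    c = np.arange(w)[None, :]
    return np.exp(-((r - center[0]) ** 2 + (c - center[1]) ** 2) / (2 * sigma ** 2))


def generate_calcium_movies(
    scene: SceneSpec, motif_library: MotifTemplates | None = None
):
    """Generate one raw movie per stimulus plus ground truth.

    Each cell's pixel time course is
    ``baseline * (1 + amplitude * disc * motif(t - onset)) + bleach_slope*t``
    plus Gaussian noise, with an isotropic Gaussian disc profile
    (sigma = radius/2).  A rigid integer shift (|shift| <= jitter_px, drawn
    per frame) displaces the whole scene.  Returns ``(movies, truth)`` where
    truth holds cell centers, a label image (1-based cell ids, 0 background),
    per-cell per-stimulus motif ids and the applied per-frame shifts.
    """
    if motif_library is None:
        motif_library = default_motif_templates()
    rng = np.random.default_rng(scene.seed)
    centers = place_cells(spec=scene, rng=rng)

    n_stim = len(scene.stimuli)
    if scene.motif_assignment is None:
        assignment = rng.choice(motif_library.ids, size=(scene.n_cells, n_stim))
    else:
        assignment = np.asarray(scene.motif_assignment)
        if assignment.shape != (scene.n_cells, n_stim):
            raise ValueError("motif_assignment must be (n_cells, n_stimuli)")
        for mid in np.unique(assignment):
            if mid not in motif_library:
                raise KeyError(f"motif id {mid!r} missing from template library")

    sigma = scene.cell_radius_px / 2.0
    h, w = scene.frame_shape
    t_frames = np.arange(scene.n_frames)

    # ground-truth label image (unshifted scene): the 1.5-sigma core of each
    # disc, where the cell contributes >= ~32% of its peak amplitude; beyond
    # that the Gaussian skirt fades into background and pixel ownership is
    # not meaningful
    labels = np.zeros((h, w), dtype=np.int32)
    for i, ctr in enumerate(centers, start=1):
        rr = np.arange(h)[:, None] - ctr[0]
        cc = np.arange(w)[None, :] - ctr[1]
        labels[(rr ** 2 + cc ** 2) <= (1.5 * sigma) ** 2] = i

    movies = []
    all_shifts = {}
    for s_idx, stim in enumerate(scene.stimuli):
        if scene.jitter_px > 0:
            shifts = rng.integers(-scene.jitter_px, scene.jitter_px + 1,
                                  size=(scene.n_frames, 2))
        else:
            shifts = np.zeros((scene.n_frames, 2), dtype=int)
        signal = np.zeros((scene.n_frames, h, w))
        courses = np.array([
            motif_library.render(assignment[c, s_idx], scene.n_frames,
                                 scene.onset_frame, scene.frame_rate)
            for c in range(scene.n_cells)
        ])
        for f in range(scene.n_frames):
            frame = np.zeros((h, w))
            for c, ctr in enumerate(centers):
                if courses[c, f] == 0.0:
                    continue
                frame += courses[c, f] * _disc((h, w), ctr + shifts[f], sigma)
            signal[f] = frame
        stack = scene.baseline * (1.0 + scene.amplitude * signal)
        stack += scene.bleach_slope * t_frames[:, None, None]
        if scene.noise_sd > 0:
            stack = stack + rng.normal(0.0, scene.noise_sd, size=stack.shape)
        movies.append(CalciumMovie(stack, stim, scene.onset_frame, scene.frame_rate))
        all_shifts[stim] = shifts

    truth = {
        "centers": centers,
        "labels": labels,
        "motif_ids": assignment,
        "stimuli": tuple(scene.stimuli),
        "shifts": all_shifts,
    }
    return movies, truth


# ---------------------------------------------------------------------------
# choice trajectories

def default_patch_centers(arena_diameter: float = 90.0) -> np.ndarray:
    """Four patch centers at 90 degree spacing, 7 cm in from the arena wall,
    in canonical patch order (top, right, bottom, left quadrants)."""
    r = arena_diameter / 2.0 - 7.0
    return np.array([(0.0, -r), (r, 0.0), (0.0, r), (-r, 0.0)])


@dataclass(frozen=True)
class AgentSpec:
    """Parameters of the patch-choice trajectory generator."""

    n_agents: int = 50
    n_frames: int = 10_000
    fps: float = 25.0
    arena_diameter: float = 90.0
    patch_centers: np.ndarray = field(
        default_factory=lambda: default_patch_centers(90.0))
    true_C: np.ndarray = field(default_factory=lambda: np.ones(4))
    W: np.ndarray = field(default_factory=lambda: np.eye(4))
    switching_rate: float = 0.005
    pull: float = 0.3          # OU per-frame attraction toward the target
    wander_sd: float = 1.8     # per-frame positional noise, arena units
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "patch_centers", np.asarray(self.patch_centers, float))
        object.__setattr__(self, "true_C", np.asarray(self.true_C, float))
        object.__setattr__(self, "W", np.asarray(self.W, float))
        if np.any(self.true_C <= 0):
            raise ValueError("true_C must be positive")
        if not np.all(np.isin(self.W, (0.0, 1.0))):
            raise ValueError("W entries must be 0/1")
        if np.any(np.hypot(*self.patch_centers.T) > self.arena_diameter / 2):
            raise ValueError("patch centers outside arena")
        if not 0.0 <= self.switching_rate <= 1.0:
            raise ValueError("switching_rate must be a probability")


def generate_choice_trajectories(spec: AgentSpec):
    """Biased random walks whose stationary quarter occupancy follows the
    cue-integration choice probabilities at the spec's true reliabilities.

    Each agent holds a target patch drawn with probability P_x (re-drawn each
    frame with probability ``switching_rate``) and relaxes toward the target
    center under discrete Ornstein-Uhlenbeck dynamics.  An all-zero W makes
    targets uniform (not an error).  Returns ``(trajectories, truth)``.
    """
    model = CueModel(spec.true_C, {"sim": spec.W})
    P = patch_probabilities(model, "sim")

    rng = np.random.default_rng(spec.seed)
    A, T = spec.n_agents, spec.n_frames
    drawn = rng.choice(len(P), p=P, size=(A, T))
    redraw = rng.random((A, T)) < spec.switching_rate
    redraw[:, 0] = True
    last = np.maximum.accumulate(np.where(redraw, np.arange(T), 0), axis=1)
    targets = drawn[np.arange(A)[:, None], last]          # (A, T) patch index
    mu = spec.patch_centers[targets]                      # (A, T, 2)

    theta = spec.pull
    u = theta * mu + rng.normal(0.0, spec.wander_sd, size=(A, T, 2))
    u[:, 0, :] = mu[:, 0, :]                              # start at first target
    pos = lfilter([1.0], [1.0, -(1.0 - theta)], u, axis=1)

    trajs = [Trajectory(f"agent{(i + 1):03d}", pos[i], spec.fps) for i in range(A)]
    truth = {"true_C": spec.true_C.copy(), "P": P, "targets": targets}
    return trajs, truth


def quarter_occupancy_from_trajectories(trajs, patch_quadrants: dict[str, int],
                                        arena_center=(0.0, 0.0)) -> np.ndarray:
    """Per-animal quarter-occupancy fractions by direct frame counting.

    Fast, smoothing-free counterpart of the density-map route; each frame is
    assigned to the diagonal-cut quadrant containing it.  Returns
    (n_animals, 4) in canonical patch order.
    """
    from .choice_model import PATCHES

    cx, cy = arena_center
    quad_for_patch = [patch_quadrants[p] for p in PATCHES]
    rows = []
    for t in trajs:
        dx = t.positions[:, 0] - cx
        dy = t.positions[:, 1] - cy
        quad = np.full(len(t), 3)
        quad[dy <= -np.abs(dx)] = 0
        quad[dx > np.abs(dy)] = 1
        quad[dy > np.abs(dx)] = 2
        counts = np.bincount(quad, minlength=4).astype(float)
        frac = counts / counts.sum()
        rows.append([frac[q] for q in quad_for_patch])
    return np.asarray(rows)


# ---------------------------------------------------------------------------
# motif-level population synthesis (for triplet / transition analyses)

def generate_profile_rows(motif_ids, n_frames: int = 40, onset_frame: int = 10,
                          frame_rate: float = 1.0, noise_sd: float = 0.05,
                          seed: int = 0,
                          motif_library: MotifTemplates | None = None):
    """Temporal response profiles drawn from motif templates plus noise.

    Returns an (n_rows, n_frames) array on the response-multiplier scale;
    rows are NOT z-scored (that is the profile-matrix builder's job).
    """
    if motif_library is None:
        motif_library = default_motif_templates()
    rng = np.random.default_rng(seed)
    motif_ids = np.asarray(motif_ids)
    rows = np.array([
        motif_library.render(int(m), n_frames, onset_frame, frame_rate)
        for m in motif_ids
    ])
    return rows + rng.normal(0.0, noise_sd, size=rows.shape)


def generate_triplet_population(
    triplet_probs: dict[tuple, float], n_animals: int, units_per_animal: int,
    seed: int = 0, phenotype: str = "greg",
):
    """Sample per-animal motif triplets from a triplet distribution.

    ``triplet_probs`` maps (m_Lct, m_Laa, m_LaaLct) motif-id triplets to
    probabilities (normalized internally).  Returns a list of
    ``(animal_id, phenotype, triplets)`` with triplets shaped
    (units_per_animal, 3).
    """
    rng = np.random.default_rng(seed)
    keys = list(triplet_probs)
    p = np.array([triplet_probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    out = []
    for a in range(n_animals):
        idx = rng.choice(len(keys), p=p, size=units_per_animal)
        trips = np.array([keys[i] for i in idx])
        out.append((f"{phenotype}{a:02d}", phenotype, trips))
    return out
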