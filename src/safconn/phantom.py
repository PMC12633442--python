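"""Synthetic U-fiber phantom populations with known ground truth.

The phantom emulates the geometry the pipeline consumes, not diffusion
physics: 14 cortical patch ROIs are placed on a hemispheric shell inside a
common 1-mm grid (standing in for a normalized group space), and each
connection is a bundle of quadratic-Bezier arcs bowing outward from the
shell — the classic U-fiber shape between nearby cortical patches.  The
generator controls, per connection: the probability a subject expresses the
bundle, the bundle's geometric mode (plausible U-arc or spurious looping
trajectories), within-bundle streamline jitter, between-subject bundle
displacement, and smaller test-retest (session) displacement.  Every draw
derives from one root seed through a counter-based spawn-key scheme, so any
single bundle can be regenerated in isolation, bit-identically.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

from .atlas import ConnectionKey, build_atlas, build_connection_keys
from .concordance import SubjectObservation
from .streamlines import Bundle, GridSpec, streamline_length

__all__ = [
    "PhantomLayout",
    "ConnectionProfile",
    "PhantomConfig",
    "PhantomTruthRecord",
    "PhantomPopulation",
    "PhantomError",
    "make_layout",
    "generate_u_bundle",
    "generate_spurious_bundle",
    "generate_population",
    "simulate_observations",
    "roi_label_volume",
]

# spawn-key purposes for the counter-based seeding scheme
_PRESENCE, _SUBJECT_SHIFT, _SESSION_SHIFT, _GEOMETRY = 0, 1, 2, 3

_N_POINTS = 24  # points per generated streamline


class PhantomError(ValueError):
    """Infeasible phantom configuration or generation failure."""


@dataclass(frozen=True)
class PhantomLayout:
    """ROI geometry of the phantom: 14 spherical cortical patches on a shell."""

    grid: GridSpec
    roi_centers: Mapping[str, tuple[float, float, float]]
    roi_radius_mm: float = 6.0

    def center(self, area_id: str) -> np.ndarray:
        return np.asarray(self.roi_centers[area_id], dtype=np.float64)


@dataclass(frozen=True)
class ConnectionProfile:
    """Generative parameters for one connection."""

    presence_probability: float = 0.9
    plausible_mode: str = "u_arc"  # {"u_arc", "spurious"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.presence_probability <= 1.0:
            raise PhantomError("presence_probability must lie in [0, 1]")
        if self.plausible_mode not in ("u_arc", "spurious"):
            raise PhantomError(f"unknown plausible_mode {self.plausible_mode!r}")


@dataclass(frozen=True)
class PhantomConfig:
    """Population-level generative parameters.

    ``session_jitter_sd_mm`` < ``subject_jitter_sd_mm`` in the default
    profile, mirroring test-retest displacements being smaller than
    anatomical differences between individuals.
    """

    n_subjects: int = 20
    sessions: int = 1
    seed: int = 0
    n_streamlines: int = 800
    arc_depth_mm: float = 10.0
    streamline_jitter_sd_mm: float = 1.5
    subject_jitter_sd_mm: float = 3.0
    session_jitter_sd_mm: float = 1.0
    profiles: Mapping[ConnectionKey, ConnectionProfile] = field(default_factory=dict)
    default_profile: ConnectionProfile = ConnectionProfile()

    def __post_init__(self) -> None:
        if self.sessions not in (1, 2):
            raise PhantomError("sessions must be 1 or 2")
        if self.n_subjects < 1 or self.n_streamlines < 1:
            raise PhantomError("n_subjects and n_streamlines must be positive")
        for sd in (
            self.streamline_jitter_sd_mm,
            self.subject_jitter_sd_mm,
            self.session_jitter_sd_mm,
        ):
            if sd < 0:
                raise PhantomError("jitter standard deviations must be non-negative")

    def profile(self, key: ConnectionKey) -> ConnectionProfile:
        return self.profiles.get(key, self.default_profile)


@dataclass(frozen=True)
class PhantomTruthRecord:
    """Ground truth for one generated subject x session x connection cell."""

    subject_id: str
    session: str
    connection: ConnectionKey
    generated_present: bool
    plausible_mode: str
    subject_shift: tuple[float, float, float]
    session_shift: tuple[float, float, float]
    spawn_key: tuple[int, ...]


@dataclass
class PhantomPopulation:
    """In-memory phantom population: bundles plus the truth table."""

    layout: PhantomLayout
    config: PhantomConfig
    bundles: dict[tuple[str, str, ConnectionKey], Bundle]
    truth: list[PhantomTruthRecord]

    def bundle(self, subject_id: str, session: str, key: ConnectionKey) -> Bundle:
        return self.bundles[(subject_id, session, key)]


def _rng(seed: int, spawn_key: tuple[int, ...]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, n: int) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t**2 * p2


def _arc_depth(chord: float, nominal: float) -> float:
    """Arc depth, deepened for short chords so every centroid arc is >= ~40 mm."""
    depth = nominal
    for _ in range(40):
        # quadratic Bezier with apex displaced `depth` from the chord midpoint
        length = _bezier_arc_length(chord, depth)
        if length >= 40.0:
            return depth
        depth += 1.0
    raise PhantomError(f"cannot reach 40 mm arc for chord {chord:.1f} mm")


def _bezier_arc_length(chord: float, depth: float) -> float:
    p0 = np.array([-chord / 2, 0.0, 0.0])
    p2 = np.array([chord / 2, 0.0, 0.0])
    p1 = np.array([0.0, 2 * depth, 0.0])
    pts = _bezier(p0, p1, p2, 200)
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def make_layout(
    seed: int = 0,
    grid: GridSpec | None = None,
    roi_radius_mm: float = 6.0,
    shell_radius_mm: float = 50.0,
    cap_angle_deg: float = 72.0,
) -> PhantomLayout:
    """Place the 14 ROIs on a hemispheric shell, deterministically for *seed*.

    Uses a Fibonacci spiral on the spherical cap with a seeded azimuthal
    rotation, then checks feasibility: all ROI spheres inside the grid and
    every centroid arc length within [38, 125] mm (after adaptive arc
    deepening for the closest pairs).  Raises :class:`PhantomError` when the
    radius/grid combination cannot satisfy those bounds.
    """
    grid = grid or GridSpec(voxel_size=1.0, origin=(0.0, 0.0, 0.0), shape=(120, 120, 120))
    areas = [a.area_id for a in build_atlas()]
    rng = _rng(seed, (99,))
    phi0 = float(rng.uniform(0, 2 * np.pi))
    extent = np.asarray(grid.shape) * grid.voxel_size
    sphere_center = np.array([extent[0] / 2, extent[1] / 2, 28.0])
    cos_cap = np.cos(np.deg2rad(cap_angle_deg))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    centers = {}
    n = len(areas)
    for k, area in enumerate(areas):
        cos_t = 1.0 - (1.0 - cos_cap) * (k + 0.5) / n
        sin_t = np.sqrt(max(0.0, 1.0 - cos_t**2))
        phi = phi0 + golden * k
        direction = np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
        centers[area] = tuple(sphere_center + shell_radius_mm * direction)

    layout = PhantomLayout(grid=grid, roi_centers=centers, roi_radius_mm=roi_radius_mm)
    _validate_layout(layout)
    return layout


def _validate_layout(layout: PhantomLayout) -> None:
    grid = layout.grid
    lo = np.asarray(grid.origin)
    hi = lo + np.asarray(grid.shape) * grid.voxel_size
    for area, c in layout.roi_centers.items():
        c = np.asarray(c)
        if np.any(c - layout.roi_radius_mm < lo) or np.any(c + layout.roi_radius_mm > hi):
            raise PhantomError(f"ROI sphere for area {area} extends outside the grid")
    keys = build_connection_keys(build_atlas())
    for key in keys:
        chord = float(
            np.linalg.norm(layout.center(key.area_a) - layout.center(key.area_b))
        )
        if chord < 2 * layout.roi_radius_mm:
            raise PhantomError(f"ROI spheres overlap for connection {key}")
        length = _bezier_arc_length(chord, _arc_depth(chord, 10.0))
        if not 38.0 <= length <= 125.0:
            raise PhantomError(
                f"centroid arc for {key} is {length:.1f} mm, outside [38, 125]"
            )


def _sample_in_sphere(rng: np.random.Generator, center: np.ndarray, radius: float) -> np.ndarray:
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    r = radius * rng.uniform() ** (1 / 3)
    return center + r * v


def generate_u_bundle(
    layout: PhantomLayout,
    key: ConnectionKey,
    config: PhantomConfig,
    spawn_key: tuple[int, ...],
    shift: np.ndarray | None = None,
    n_streamlines: int | None = None,
) -> Bundle:
    """Generate one plausible U-arc bundle for *key*.

    Streamlines are quadratic Bezier arcs from points inside the two ROI
    spheres, apex displaced outward (away from the shell centre) by the arc
    depth, with Gaussian control-point jitter.  Deterministic for a given
    (config.seed, spawn_key); *shift* applies a whole-bundle displacement
    (subject + session jitter).  Every streamline is guaranteed <= 125 mm
    (jitter redraw, then error).
    """
    rng = _rng(config.seed, spawn_key)
    n = n_streamlines if n_streamlines is not None else config.n_streamlines
    a = layout.center(key.area_a)
    b = layout.center(key.area_b)
    mid = 0.5 * (a + b)
    extent = np.asarray(layout.grid.shape) * layout.grid.voxel_size
    sphere_center = np.array([extent[0] / 2, extent[1] / 2, 28.0])
    outward = mid - sphere_center
    norm = np.linalg.norm(outward)
    outward = outward / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
    chord = float(np.linalg.norm(b - a))
    depth = _arc_depth(chord, config.arc_depth_mm)
    control = mid + 2.0 * depth * outward
    shift = np.zeros(3) if shift is None else np.asarray(shift, dtype=np.float64)

    streamlines = []
    for _ in range(n):
        for _attempt in range(20):
            p0 = _sample_in_sphere(rng, a, layout.roi_radius_mm)
            p2 = _sample_in_sphere(rng, b, layout.roi_radius_mm)
            p1 = control + rng.normal(scale=2.0 * config.streamline_jitter_sd_mm, size=3)
            pts = _bezier(p0, p1, p2, _N_POINTS) + shift
            if streamline_length(pts) <= 125.0:
                streamlines.append(pts)
                break
        else:
            raise PhantomError(f"arc for {key} infeasible under the 125 mm length cap")
    return Bundle(streamlines=streamlines, connection=key)


def generate_spurious_bundle(
    layout: PhantomLayout,
    key: ConnectionKey,
    config: PhantomConfig,
    spawn_key: tuple[int, ...],
    shift: np.ndarray | None = None,
    n_streamlines: int | None = None,
) -> Bundle:
    """Generate an anatomically implausible bundle: looping, wandering streamlines.

    Each streamline runs 1.5 turns around a jittered loop centre between the
    two ROIs, so its end-to-end distance is far below a quarter of its arc
    length — the signature the plausibility heuristic flags.
    """
    rng = _rng(config.seed, spawn_key)
    n = n_streamlines if n_streamlines is not None else config.n_streamlines
    a = layout.center(key.area_a)
    b = layout.center(key.area_b)
    mid = 0.5 * (a + b)
    shift = np.zeros(3) if shift is None else np.asarray(shift, dtype=np.float64)

    streamlines = []
    for _ in range(n):
        center = mid + rng.normal(scale=3.0, size=3)
        radius = rng.uniform(6.0, 10.0)
        # random loop plane
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v = np.cross(u, rng.normal(size=3))
        v /= np.linalg.norm(v)
        theta = np.linspace(0.0, 3.0 * np.pi, _N_POINTS)[:, None]  # 1.5 turns
        pts = center + radius * (np.cos(theta) * u + np.sin(theta) * v)
        pts += rng.normal(scale=config.streamline_jitter_sd_mm * 0.3, size=pts.shape)
        pts += shift
        if streamline_length(pts) > 125.0:  # radius bound keeps loops ~90 mm
            pts = center + 0.7 * radius * (np.cos(theta) * u + np.sin(theta) * v) + shift
        streamlines.append(pts)
    return Bundle(streamlines=streamlines, connection=key)


def _iter_cells(
    config: PhantomConfig, keys: list[ConnectionKey]
) -> Iterator[tuple[int, str, int, str, int, ConnectionKey]]:
    for s in range(config.n_subjects):
        subject_id = f"sub-{s:03d}"
        for e in range(config.sessions):
            session = "test" if e == 0 else "retest"
            for c, key in enumerate(keys):
                yield s, subject_id, e, session, c, key


def generate_population(
    layout: PhantomLayout,
    config: PhantomConfig,
    keys: list[ConnectionKey] | None = None,
    out_dir: str | Path | None = None,
) -> PhantomPopulation:
    """Generate a multi-subject (optionally two-session) phantom population.

    Presence is a subject-level Bernoulli draw per connection (both sessions
    of a subject agree on presence); the bundle is displaced by a per-subject
    Gaussian shift shared across sessions plus a smaller per-session shift.
    With ``out_dir`` set, TCK files (``<subject>_<session>_<a>-<b>.tck``), a
    truth CSV and a config echo are also written.
    """
    keys = keys if keys is not None else build_connection_keys(build_atlas())
    bundles: dict[tuple[str, str, ConnectionKey], Bundle] = {}
    truth: list[PhantomTruthRecord] = []

    for s, subject_id, e, session, c, key in _iter_cells(config, keys):
        profile = config.profile(key)
        present = bool(
            _rng(config.seed, (_PRESENCE, s, c)).uniform() < profile.presence_probability
        )
        subject_shift = _rng(config.seed, (_SUBJECT_SHIFT, s, c)).normal(
            scale=config.subject_jitter_sd_mm, size=3
        )
        session_shift = (
            _rng(config.seed, (_SESSION_SHIFT, s, e, c)).normal(
                scale=config.session_jitter_sd_mm, size=3
            )
            if config.sessions > 1
            else np.zeros(3)
        )
        spawn = (_GEOMETRY, s, e, c)
        if present:
            gen = (
                generate_u_bundle
                if profile.plausible_mode == "u_arc"
                else generate_spurious_bundle
            )
            bundle = gen(layout, key, config, spawn, shift=subject_shift + session_shift)
        else:
            bundle = Bundle(streamlines=[], connection=key)
        bundle.subject_id = subject_id
        bundle.session = session
        bundles[(subject_id, session, key)] = bundle
        truth.append(
            PhantomTruthRecord(
                subject_id=subject_id,
                session=session,
                connection=key,
                generated_present=present,
                plausible_mode=profile.plausible_mode,
                subject_shift=tuple(subject_shift),
                session_shift=tuple(session_shift),
                spawn_key=spawn,
            )
        )

    population = PhantomPopulation(layout=layout, config=config, bundles=bundles, truth=truth)
    if out_dir is not None:
        _write_population(population, Path(out_dir))
    return population


def _write_population(population: PhantomPopulation, out_dir: Path) -> None:
    from .streamlines import write_tck  # local import to avoid cycle at module load

    out_dir.mkdir(parents=True, exist_ok=True)
    tck_dir = out_dir / "tck"
    tck_dir.mkdir(exist_ok=True)
    for (subject, session, key), bundle in population.bundles.items():
        name = f"{subject}_{session}_{key.area_a}-{key.area_b}".replace("/", "x")
        write_tck(bundle, tck_dir / f"{name}.tck")
    with open(out_dir / "truth.csv", "w", encoding="utf-8") as f:
        f.write(
            "subject_id,session,area_a,area_b,generated_present,plausible_mode,"
            "subject_shift_x,subject_shift_y,subject_shift_z,"
            "session_shift_x,session_shift_y,session_shift_z,spawn_key\n"
        )
        for r in population.truth:
            f.write(
                f"{r.subject_id},{r.session},{r.connection.area_a},{r.connection.area_b},"
                f"{int(r.generated_present)},{r.plausible_mode},"
                + ",".join(f"{v:.6f}" for v in (*r.subject_shift, *r.session_shift))
                + ","
                + ":".join(map(str, r.spawn_key))
                + "\n"
            )
    cfg = asdict(population.config)
    cfg["profiles"] = {
        str(k): asdict(v) for k, v in population.config.profiles.items()
    }
    cfg["default_profile"] = asdict(population.config.default_profile)
    (out_dir / "config.json").write_text(json.dumps(cfg, indent=2))


def simulate_observations(
    config: PhantomConfig, keys: list[ConnectionKey] | None = None
) -> dict[ConnectionKey, list[SubjectObservation]]:
    """Observation-level fast path of the generator.

    Draws the same per-subject presence Bernoulli stream as
    :func:`generate_population` and converts it directly into
    :class:`SubjectObservation` records (streamline count = configured budget
    when present, 0 when absent; plausibility from the connection's mode),
    skipping streamline geometry.  Used for large replicate studies of the
    classification stage.
    """
    keys = keys if keys is not None else build_connection_keys(build_atlas())
    out: dict[ConnectionKey, list[SubjectObservation]] = {k: [] for k in keys}
    for s in range(config.n_subjects):
        subject_id = f"sub-{s:03d}"
        for c, key in enumerate(keys):
            profile = config.profile(key)
            present = bool(
                _rng(config.seed, (_PRESENCE, s, c)).uniform()
                < profile.presence_probability
            )
            out[key].append(
                SubjectObservation(
                    subject_id=subject_id,
                    connection=key,
                    n_streamlines_clean=config.n_streamlines if present else 0,
                    plausible=profile.plausible_mode == "u_arc",
                    present=present,
                )
            )
    return out


def roi_label_volume(layout: PhantomLayout) -> np.ndarray:
    """Integer label volume of the ROI spheres (1-based, canonical area order)."""
    grid = layout.grid
    shape = grid.shape
    coords = np.stack(
        np.meshgrid(
            *[np.arange(s) * grid.voxel_size + o + grid.voxel_size / 2
              for s, o in zip(shape, grid.origin)],
            indexing="ij",
        ),
        axis=-1,
    )
    labels = np.zeros(shape, dtype=np.int16)
    for i, area in enumerate([a.area_id for a in build_atlas()], start=1):
        d = np.linalg.norm(coords - layout.center(area), axis=-1)
        labels[d <= layout.roi_radius_mm] = i
    return labels
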