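"""Ground-truth-known synthetic 3D time-lapse embryos.

The generator emulates the statistical structure of a ventrolateral germband
acquisition: a packed columnar monolayer of hexagonal-prism cells (~20 µm
deep, ~50 µm² cross-section) each containing one ellipsoidal nucleus
(~280 µm³, midplane ~10 µm below the apical surface), imaged as a
two-channel (membrane + nuclear marker, optional myosin) z-stack with
1 µm z-steps, 0.16 µm pixels and 15 s frames.

Cells are the power diagram of a triangular seed lattice; each z-layer gets
a small static seed jitter so prisms have realistic per-layer area
variation.  Prescribed dynamics — apical–basal nuclear drift, in-plane
nuclear deformation, per-depth area oscillations, T1 neighbour exchanges
and apical extrusion — are injected through seed motion and recorded
exactly in the returned ground truth, so every downstream measurement can
be checked against what was put in.

T1 events are scripted through the exact four-point Voronoi relation: for a
quartet with the contracting pair a distance ``d`` apart and the flanking
pair at ``±h`` from the shared axis, the shared-edge length is
``L = (h² − d²/4)/h``; inverting ``h(L)`` yields a seed schedule whose
rasterised interface follows a prescribed linear length schedule, through
the vertex (T2) and into growth of the orthogonal (T3) interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .volumes import ImageVolumeSeries, LabelVolumeSeries

# Geometry defaults: a 280 µm³ ellipsoid (c_z = 5 µm) occupying 84% of the
# cell cross-section at its midplane fixes the in-plane semi-axes and the
# hexagonal lattice pitch.
DEFAULT_SEMI_Z = 5.0
DEFAULT_SEMI_XY = math.sqrt(280.0 * 3.0 / (4.0 * math.pi * DEFAULT_SEMI_Z))  # 3.6564 µm
DEFAULT_OCCUPANCY = 0.84
DEFAULT_CELL_AREA = math.pi * DEFAULT_SEMI_XY**2 / DEFAULT_OCCUPANCY  # ~50 µm²
DEFAULT_PITCH = math.sqrt(2.0 * DEFAULT_CELL_AREA / math.sqrt(3.0))  # ~7.598 µm


@dataclass
class EmbryoSpec:
    """Acquisition and tissue geometry of a synthetic embryo.

    All sizes in µm, frame interval in seconds.  ``grid_shape`` counts cells
    along (rows, cols) of the hexagonal lattice; a ring of unlabelled
    boundary cells surrounds the interior so every interior cell has a full
    neighbourhood.
    """

    grid_shape: tuple[int, int] = (3, 3)
    cell_depth: float = 20.0
    cell_pitch: float = DEFAULT_PITCH
    voxel_size: tuple[float, float, float] = (1.0, 0.16, 0.16)
    frame_interval: float = 15.0
    n_frames: int = 1
    noise_sigma: float = 0.0
    seed: int = 0
    apical_offset: float = 2.0  # µm of empty medium above the apical surface
    jitter: float = 0.1  # per-z seed jitter σ, µm
    tilt: tuple[float, float] = (0.0, 0.0)  # (y, x) µm of lateral shear per µm depth
    n_z: int | None = None

    def __post_init__(self) -> None:
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be at least 1x1")
        for name in ("cell_depth", "cell_pitch", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sigma < 0 or self.jitter < 0:
            raise ValueError("noise_sigma and jitter must be non-negative")
        if self.n_z is None:
            dz = self.voxel_size[0]
            self.n_z = int(round(self.apical_offset / dz)) + int(math.ceil(self.cell_depth / dz))

    @property
    def apical_z(self) -> int:
        """Index of the first z-layer containing cells (the apical surface)."""
        return int(round(self.apical_offset / self.voxel_size[0]))

    def depth_of_z(self, z) -> np.ndarray | float:
        """Depth below the apical surface (µm) of z-layer index ``z``."""
        return (np.asarray(z) - self.apical_z) * self.voxel_size[0]


@dataclass
class NucleusSpec:
    """One ellipsoidal nucleus per cell.

    ``center_depth`` is µm below the apical surface; ``semi_axes`` is
    (c_z, b_y, a_x) in µm; ``drift_z`` a prescribed apical–basal midplane
    velocity in µm/min (sign pattern set by ``DynamicsSpec.drift_stagger``);
    ``deform_rate`` a relative in-plane axis-ratio change per minute
    (area-preserving).
    """

    center_depth: float = 10.0
    semi_axes: tuple[float, float, float] = (DEFAULT_SEMI_Z, DEFAULT_SEMI_XY, DEFAULT_SEMI_XY)
    drift_z: float = 0.0
    deform_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be strictly positive")


@dataclass
class T1EventSpec:
    """A scripted neighbour exchange.

    ``quartet`` is (a, b, c, d): cells a and b share the contracting (T1)
    interface; c and d are their common neighbours that gain the new (T3)
    interface.  ``rate`` is the signed interface length change in µm/min
    (negative = contraction); the signed length runs linearly from the
    initial length through 0 (the T2 vertex) into minus the T3 length.
    ``ab_separation_rate`` optionally moves a and b apart so their cell
    centroids separate at roughly the stated µm/min.
    """

    quartet: tuple[int, int, int, int]
    onset_min: float = 0.0
    rate: float = -0.3
    ab_separation_rate: float = 0.0


@dataclass
class DynamicsSpec:
    """Prescribed tissue dynamics."""

    osc_frequency: float = 0.008  # Hz
    osc_rel_amplitude: float = 0.05  # relative area amplitude before profile scaling
    osc_amplitude_profile: object = None  # None | {offset_um: factor} | callable
    signal_noise: float = 0.5  # additive σ on ground-truth area signals, µm²
    t1_events: list[T1EventSpec] = field(default_factory=list)
    extrusions: list[tuple[int, float]] = field(default_factory=list)  # (track, onset_min)
    extrusion_loss_depth: float = 5.0  # µm of apical column lost by extruding cells
    drift_stagger: bool = False  # alternate drift sign on a checkerboard

    def validate(self, spec: EmbryoSpec) -> None:
        nyquist = 1.0 / (2.0 * spec.frame_interval)
        if not (0 <= self.osc_frequency < nyquist):
            raise ValueError(
                f"osc_frequency {self.osc_frequency} Hz is not below the Nyquist "
                f"frequency {nyquist:.4g} Hz for a {spec.frame_interval} s frame interval"
            )
        if not 0 <= self.osc_rel_amplitude < 1:
            raise ValueError("osc_rel_amplitude must be in [0, 1)")

    def profile_factor(self, offset_um: float) -> float:
        p = self.osc_amplitude_profile
        if p is None:
            return 1.0
        if callable(p):
            return float(p(offset_um))
        keys = np.array(sorted(p))
        k = keys[np.argmin(np.abs(keys - offset_um))]
        return float(p[k])


@dataclass
class MyosinSpec:
    """Optional third channel: junctional + medial myosin."""

    base: float = 0.5  # non-vertical junctional intensity
    vertical_factor: float = 2.0  # brightness factor on DV-aligned interfaces
    vertical_band_deg: float = 15.0
    medial: float = 0.5  # medial blob intensity in the apical layers
    medial_radius: float = 1.5  # µm
    background: float = 0.02


class TissueLattice:
    """Triangular seed lattice whose power diagram is the cell tiling.

    Interior cells carry track ids 1..gy*gx (row-major); the surrounding
    ring of boundary cells maps to label 0 (background / out of field).
    """

    def __init__(self, grid_shape=(3, 3), pitch: float = DEFAULT_PITCH):
        gy, gx = grid_shape
        self.pitch = float(pitch)
        self.row_step = self.pitch * math.sqrt(3.0) / 2.0
        rows, cols = gy + 2, gx + 2
        seeds, labels = [], []
        for j in range(rows):
            for i in range(cols):
                x = (i + 0.5 * (j % 2) + 0.5) * self.pitch
                y = (j + 0.5) * self.row_step
                seeds.append((y, x))
                if 1 <= j <= gy and 1 <= i <= gx:
                    labels.append((j - 1) * gx + (i - 1) + 1)
                else:
                    labels.append(0)
        self.seeds = np.asarray(seeds, dtype=float)  # (N, 2) as (y, x) µm
        self.seed_labels = np.asarray(labels, dtype=np.int32)
        self.grid_shape = (gy, gx)
        self.fov = ((rows) * self.row_step, (cols + 0.5) * self.pitch)  # (Ly, Lx) µm
        self.n_cells = gy * gx
        self._index_of = {int(l): k for k, l in enumerate(self.seed_labels) if l > 0}

    @property
    def hexagon_edge(self) -> float:
        return self.pitch / math.sqrt(3.0)

    @property
    def cell_area(self) -> float:
        return math.sqrt(3.0) / 2.0 * self.pitch**2

    def seed_of(self, track: int) -> np.ndarray:
        return self.seeds[self._index_of[track]]

    def adjacency(self) -> set[tuple[int, int]]:
        """Interior neighbour pairs (a < b) of the unperturbed lattice."""
        pairs = set()
        idx = [self._index_of[t] for t in range(1, self.n_cells + 1)]
        for ka in idx:
            for kb in idx:
                if kb <= ka:
                    continue
                if np.linalg.norm(self.seeds[ka] - self.seeds[kb]) < 1.1 * self.pitch:
                    pairs.add((int(self.seed_labels[ka]), int(self.seed_labels[kb])))
        return pairs

    def common_neighbors(self, a: int, b: int) -> list[int]:
        adj = self.adjacency()

        def nb(t):
            return {y for x, y in adj if x == t} | {x for x, y in adj if y == t}

        return sorted(nb(a) & nb(b))

    def validate_quartet(self, quartet) -> None:
        a, b, c, d = quartet
        for t in quartet:
            if t not in self._index_of:
                raise ValueError(f"cell {t} is not an interior lattice cell")
        sa, sb = self.seed_of(a), self.seed_of(b)
        if abs(sa[0] - sb[0]) > 1e-9 or abs(abs(sa[1] - sb[1]) - self.pitch) > 1e-6:
            raise ValueError(f"cells {a},{b} are not a horizontally adjacent pair")
        common = self.common_neighbors(a, b)
        if c not in common or d not in common or c == d:
            raise ValueError(f"cells {c},{d} are not common neighbours of {a},{b}")


def _h_from_signed_length(L: float, d: float, h0: float) -> float:
    """Invert the four-point Voronoi edge-length relation.

    For flanking seeds at ±h and a contracting pair a distance d apart, the
    shared edge has length (h² − d²/4)/h for h > d/2 (T1 side) and the
    orthogonal edge has length (d²/4 − h²)·2/d for h < d/2 (T3 side, signed
    negative here).
    """
    if L >= 0:
        return 0.5 * (L + math.sqrt(L * L + d * d))
    arg = d * d / 4.0 + L * d / 2.0
    if arg <= 0:
        raise ValueError(f"signed length {L} exceeds the geometric T3 limit for pitch {d}")
    return math.sqrt(arg)


def render_t1_event(
    quartet,
    onset_min: float,
    rate: float,
    *,
    n_frames: int,
    frame_interval: float,
    initial_length: float | None = None,
    lattice: TissueLattice | None = None,
    max_t3_fraction: float = 0.4,
) -> pd.DataFrame:
    """Signed interface-length schedule for a scripted T1 event.

    The signed length decreases linearly at ``rate`` (µm/min) from the
    initial T1 length, crosses 0 at the T2 vertex and continues negative as
    the orthogonal T3 interface grows, clamped at ``-max_t3_fraction·pitch``
    where the four-point geometry degenerates.
    """
    if lattice is not None:
        lattice.validate_quartet(quartet)
        pitch = lattice.pitch
        l0 = lattice.hexagon_edge if initial_length is None else initial_length
    else:
        pitch = DEFAULT_PITCH
        l0 = pitch / math.sqrt(3.0) if initial_length is None else initial_length
    t_min = np.arange(n_frames) * frame_interval / 60.0
    signed = l0 + rate * np.clip(t_min - onset_min, 0.0, None)
    lo = -max_t3_fraction * pitch
    signed = np.clip(signed, lo, max(l0, signed.max(initial=l0)))
    t2 = onset_min + l0 / abs(rate) if rate < 0 else math.inf
    out = pd.DataFrame(
        {"frame": np.arange(n_frames), "time_min": t_min, "signed_length_um": signed}
    )
    out.attrs["t2_min"] = t2
    out.attrs["quartet"] = tuple(quartet)
    out.attrs["rate"] = rate
    return out


@dataclass
class GroundTruth:
    """Everything the generator prescribed, for checking measurements."""

    cell_labels: LabelVolumeSeries
    nucleus_labels: LabelVolumeSeries
    midplanes: pd.DataFrame  # track, frame, time_min, midplane_depth_um
    area_signals: pd.DataFrame  # track, frame, time_min, z, depth_um, offset_um, area_um2
    t1_truth: pd.DataFrame  # per scripted event: frame-by-frame signed lengths
    adjacency: set
    lattice: TissueLattice
    spec: EmbryoSpec
    nuclei: dict  # track -> NucleusSpec
    dynamics: DynamicsSpec
    apical_z: int
    extrusions: pd.DataFrame  # track, onset_min


class _Engine:
    """Shared seed-motion machinery for volumetric and planar rendering."""

    def __init__(self, spec: EmbryoSpec, dynamics: DynamicsSpec, nuclei, rng):
        self.spec = spec
        self.dynamics = dynamics
        self.lattice = TissueLattice(spec.grid_shape, spec.cell_pitch)
        dynamics.validate(spec)
        # nuclei: one spec for all cells, or {track: NucleusSpec}
        if isinstance(nuclei, NucleusSpec) or nuclei is None:
            base = nuclei or NucleusSpec()
            self.nuclei = {t: base for t in range(1, self.lattice.n_cells + 1)}
        else:
            self.nuclei = dict(nuclei)
        self._check_fit()
        for ev in dynamics.t1_events:
            self.lattice.validate_quartet(ev.quartet)
        # static per-z jitter, identical at every frame
        self.jitter = rng.normal(
            0.0, spec.jitter, size=(spec.n_z, len(self.lattice.seeds), 2)
        )
        self.phases = rng.uniform(0, 2 * math.pi, size=self.lattice.n_cells + 1)
        self.schedules = [
            render_t1_event(
                ev.quartet,
                ev.onset_min,
                ev.rate,
                n_frames=spec.n_frames,
                frame_interval=spec.frame_interval,
                lattice=self.lattice,
            )
            for ev in dynamics.t1_events
        ]
        gy, gx = spec.grid_shape
        self.drift_sign = np.ones(self.lattice.n_cells + 1)
        if dynamics.drift_stagger:
            for t in range(1, self.lattice.n_cells + 1):
                r, c = divmod(t - 1, gx)
                self.drift_sign[t] = 1.0 if (r + c) % 2 == 0 else -1.0

    def _check_fit(self) -> None:
        apothem = self.lattice.pitch / 2.0
        for t, nuc in self.nuclei.items():
            if max(nuc.semi_axes[1:]) >= apothem - self.spec.jitter:
                raise ValueError(
                    f"nucleus of cell {t} (in-plane semi-axis "
                    f"{max(nuc.semi_axes[1:]):.2f} µm) does not fit inside its host "
                    f"cell (apothem {apothem:.2f} µm minus jitter {self.spec.jitter} µm)"
                )

    # --- per-nucleus kinematics ---------------------------------------
    def center_depth(self, track: int, t_min: float) -> float:
        nuc = self.nuclei[track]
        return nuc.center_depth + self.drift_sign[track] * nuc.drift_z * t_min

    def semi_axes(self, track: int, t_min: float) -> tuple[float, float, float]:
        c, b, a = self.nuclei[track].semi_axes
        r = 1.0 + self.nuclei[track].deform_rate * t_min
        s = math.sqrt(max(r, 1e-6))
        return c, b / s, a * s

    # --- seed state ----------------------------------------------------
    def seed_state(self, frame: int, z: int | None):
        """Seed (y, x) positions, power weights and active mask at (t, z)."""
        spec, dyn, lat = self.spec, self.dynamics, self.lattice
        t_min = frame * spec.frame_interval / 60.0
        pos = lat.seeds.copy()
        if z is not None:
            pos = pos + self.jitter[z]
            depth = float(spec.depth_of_z(z))
            if depth > 0 and (spec.tilt[0] or spec.tilt[1]):
                pos = pos + depth * np.asarray(spec.tilt)
        for ev, sched in zip(dyn.t1_events, self.schedules):
            a, b, c, d = ev.quartet
            ia, ib = lat._index_of[a], lat._index_of[b]
            ic, id_ = lat._index_of[c], lat._index_of[d]
            if ev.ab_separation_rate and t_min > ev.onset_min:
                # a cell centroid follows its seed at half speed (all
                # bisectors move half the seed displacement), so script
                # twice the prescribed centroid-separation rate
                dx = 2.0 * ev.ab_separation_rate * (t_min - ev.onset_min)
                sgn = 1.0 if lat.seeds[ib, 1] > lat.seeds[ia, 1] else -1.0
                pos[ia, 1] -= sgn * dx
                pos[ib, 1] += sgn * dx
            Ls = float(sched["signed_length_um"].iloc[frame])
            d_ab = abs(pos[ib, 1] - pos[ia, 1])
            h = _h_from_signed_length(Ls, d_ab, lat.row_step)
            ymid = 0.5 * (lat.seeds[ic, 0] + lat.seeds[id_, 0])
            up, dn = (ic, id_) if lat.seeds[ic, 0] < lat.seeds[id_, 0] else (id_, ic)
            pos[up, 0] = ymid - h + (self.jitter[z][up, 0] if z is not None else 0.0)
            pos[dn, 0] = ymid + h + (self.jitter[z][dn, 0] if z is not None else 0.0)
        # oscillation -> power weights (first-order area response)
        w = np.zeros(len(pos))
        if dyn.osc_rel_amplitude > 0 and z is not None:
            depth = float(self.spec.depth_of_z(z))
            for t in range(1, lat.n_cells + 1):
                off = self.center_depth(t, t_min) - depth
                m = (
                    dyn.osc_rel_amplitude
                    * dyn.profile_factor(off)
                    * math.sin(2 * math.pi * dyn.osc_frequency * frame * spec.frame_interval + self.phases[t])
                )
                w[lat._index_of[t]] = m * lat.cell_area / math.sqrt(3.0)
        active = np.ones(len(pos), dtype=bool)
        if z is not None:
            depth = float(self.spec.depth_of_z(z))
            for track, onset in dyn.extrusions:
                if t_min >= onset and depth < dyn.extrusion_loss_depth:
                    active[lat._index_of[track]] = False
        return pos, w, active

    def plane_labels(self, frame: int, z: int | None, shape_px, pixel: float) -> np.ndarray:
        pos, w, active = self.seed_state(frame, z)
        pos, w = pos[active], w[active]
        labs = self.lattice.seed_labels[active]
        ny, nx = shape_px
        yy = ((np.arange(ny) + 0.5) * pixel).astype(np.float32)
        xx = ((np.arange(nx) + 0.5) * pixel).astype(np.float32)
        d2 = (
            (yy[:, None, None] - pos[:, 0].astype(np.float32)) ** 2
            + (xx[None, :, None] - pos[:, 1].astype(np.float32)) ** 2
            - w.astype(np.float32)
        )
        return labs[np.argmin(d2, axis=-1)]


def _pair_boundary(lab: np.ndarray, a: int, b: int) -> np.ndarray:
    """Both-sided boundary pixels between labels a and b (4-connectivity)."""
    m = np.zeros(lab.shape, dtype=bool)
    for s1, s2, m1, m2 in (
        (lab[:-1, :], lab[1:, :], m[:-1, :], m[1:, :]),
        (lab[:, :-1], lab[:, 1:], m[:, :-1], m[:, 1:]),
    ):
        hit = ((s1 == a) & (s2 == b)) | ((s1 == b) & (s2 == a))
        m1 |= hit
        m2 |= hit
    return m


def _boundary_mask(lab: np.ndarray) -> np.ndarray:
    """Two-pixel-wide ridge on every label discontinuity (4-connectivity)."""
    b = np.zeros(lab.shape, dtype=bool)
    dy = lab[:-1, :] != lab[1:, :]
    b[:-1, :] |= dy
    b[1:, :] |= dy
    dx = lab[:, :-1] != lab[:, 1:]
    b[:, :-1] |= dx
    b[:, 1:] |= dx
    return b


def _cell_layers(spec: EmbryoSpec) -> list[int]:
    return [z for z in range(spec.n_z) if 0 <= float(spec.depth_of_z(z)) < spec.cell_depth]


def _base_areas(eng: _Engine) -> dict[int, np.ndarray]:
    """Per-z per-track areas (µm²) of the t = 0 geometry without oscillation."""
    spec, lat = eng.spec, eng.lattice
    dz, dy, dx = spec.voxel_size
    ny = int(round(lat.fov[0] / dy))
    nx = int(round(lat.fov[1] / dx))
    saved = eng.dynamics.osc_rel_amplitude
    eng.dynamics.osc_rel_amplitude = 0.0
    out = {}
    for z in _cell_layers(spec):
        lab0 = eng.plane_labels(0, z, (ny, nx), dx)
        counts = np.bincount(lab0.ravel(), minlength=lat.n_cells + 1)
        out[z] = counts * dy * dx
    eng.dynamics.osc_rel_amplitude = saved
    return out


def _area_signal_table(eng: _Engine, base_areas: dict, rng) -> pd.DataFrame:
    """Prescribed (pre-render) per-cell per-layer area signals."""
    spec, dyn, lat = eng.spec, eng.dynamics, eng.lattice
    nt = spec.n_frames
    t_min = np.arange(nt) * spec.frame_interval / 60.0
    t_s = np.arange(nt) * spec.frame_interval
    parts = []
    for track in range(1, lat.n_cells + 1):
        drift = np.array([eng.center_depth(track, tm) for tm in t_min])
        for z, areas in base_areas.items():
            a0 = float(areas[track])
            if a0 <= 0:
                continue
            depth = float(spec.depth_of_z(z))
            off = drift - depth
            fac = np.array([dyn.profile_factor(o) for o in off])
            mod = (
                dyn.osc_rel_amplitude
                * fac
                * np.sin(2 * math.pi * dyn.osc_frequency * t_s + eng.phases[track])
            )
            parts.append(
                pd.DataFrame(
                    {
                        "track": track,
                        "frame": np.arange(nt),
                        "time_min": t_min,
                        "z": z,
                        "depth_um": depth,
                        "offset_um": off,
                        "area_um2": a0 * (1.0 + mod),
                    }
                )
            )
    if not parts:
        return pd.DataFrame(
            columns=["track", "frame", "time_min", "z", "depth_um", "offset_um", "area_um2"]
        )
    df = pd.concat(parts, ignore_index=True)
    if dyn.signal_noise > 0:
        df["area_um2"] += rng.normal(0, dyn.signal_noise, len(df))
    return df


def generate_area_signals(
    spec: EmbryoSpec,
    nuclei: NucleusSpec | dict | None = None,
    dynamics: DynamicsSpec | None = None,
) -> pd.DataFrame:
    """Ground-truth area-signal table without rendering the movie.

    Renders only the t = 0 geometry to obtain each cell's base area per
    layer, then applies the prescribed oscillation/drift modulation
    analytically — the same table :func:`generate_embryo` returns in
    ``GroundTruth.area_signals``, at a fraction of the cost.
    """
    dynamics = dynamics or DynamicsSpec()
    rng = np.random.default_rng(spec.seed)
    eng = _Engine(spec, dynamics, nuclei, rng)
    return _area_signal_table(eng, _base_areas(eng), rng)


def generate_embryo(
    spec: EmbryoSpec,
    nuclei: NucleusSpec | dict | None = None,
    dynamics: DynamicsSpec | None = None,
    myosin: MyosinSpec | None = None,
) -> tuple[ImageVolumeSeries, GroundTruth]:
    """Render a synthetic embryo movie together with its exact ground truth.

    Returns the image series (membrane, nuclei[, myosin] channels) and a
    :class:`GroundTruth` holding label volumes, nuclear midplane
    trajectories, prescribed per-cell per-depth area signals and the T1
    schedules.  Identical ``spec.seed`` and specs give bit-identical output.
    """
    dynamics = dynamics or DynamicsSpec()
    rng = np.random.default_rng(spec.seed)
    eng = _Engine(spec, dynamics, nuclei, rng)
    lat = eng.lattice
    dz, dy, dx = spec.voxel_size
    if abs(dy - dx) > 1e-12:
        raise ValueError("in-plane pixels must be square (dy == dx)")
    ny = int(round(lat.fov[0] / dy))
    nx = int(round(lat.fov[1] / dx))
    nz, nt = spec.n_z, spec.n_frames
    apz = spec.apical_z
    n_ch = 3 if myosin is not None else 2
    names = ["membrane", "nuclei"] + (["myosin"] if myosin is not None else [])

    img = np.zeros((nt, nz, n_ch, ny, nx), dtype=np.float32)
    cells = np.zeros((nt, nz, ny, nx), dtype=np.int32)
    nucs = np.zeros((nt, nz, ny, nx), dtype=np.int32)
    pix_area = dy * dx

    cell_zs = _cell_layers(spec)
    yy = (np.arange(ny) + 0.5) * dy
    xx = (np.arange(nx) + 0.5) * dx
    base_areas = _base_areas(eng)

    # analytic interface angles (from seed geometry) for myosin painting
    pair_angles: dict[tuple[int, int], float] = {}
    if myosin is not None:
        for ka in range(len(lat.seeds)):
            for kb in range(ka + 1, len(lat.seeds)):
                la, lb = int(lat.seed_labels[ka]), int(lat.seed_labels[kb])
                if la == 0 or lb == 0:
                    continue
                dvec = lat.seeds[kb] - lat.seeds[ka]
                if float(np.hypot(*dvec)) > 1.1 * lat.pitch:
                    continue
                theta = math.degrees(math.atan2(dvec[0], -dvec[1]))
                pair_angles[(la, lb)] = (theta + 90.0) % 180.0 - 90.0

    for t in range(nt):
        t_min = t * spec.frame_interval / 60.0
        for z in range(nz):
            if z not in cell_zs:
                continue
            lab = eng.plane_labels(t, z, (ny, nx), dx)
            cells[t, z] = lab
            ridge = _boundary_mask(lab)
            img[t, z, 0][ridge] = 1.0
            if z == apz:  # apical cap layer: bright cell tops
                img[t, z, 0][lab > 0] += 0.3
            if myosin is not None:
                # Gaussian ridge of distance to each interface so the
                # integrated junctional signal per unit edge length is
                # orientation-independent (a rasterised diagonal boundary
                # has ~2x the pixel count of a vertical one)
                my = img[t, z, 2]
                sigma_px = 1.0
                for (a, b), theta in pair_angles.items():
                    mask = _pair_boundary(lab, a, b)
                    if not mask.any():
                        continue
                    fac = (
                        myosin.vertical_factor
                        if abs(theta) <= myosin.vertical_band_deg
                        else 1.0
                    )
                    dist = ndi.distance_transform_edt(~mask)
                    np.maximum(
                        my,
                        myosin.base * fac * np.exp(-(dist**2) / (2 * sigma_px**2)),
                        out=my,
                    )
                my += myosin.background
        # nuclei
        for track in range(1, lat.n_cells + 1):
            c, b, a = eng.semi_axes(track, t_min)
            zc_depth = eng.center_depth(track, t_min)
            sy, sx = lat.seed_of(track)
            z_lo = max(0, int(math.floor((zc_depth - c) / dz)) + apz - 1)
            z_hi = min(nz - 1, int(math.ceil((zc_depth + c) / dz)) + apz + 1)
            y_sel = np.abs(yy - sy) <= b * 1.4
            x_sel = np.abs(xx - sx) <= a * 1.4
            ys, xs = np.where(y_sel)[0], np.where(x_sel)[0]
            if len(ys) == 0 or len(xs) == 0:
                continue
            ry = ((yy[ys] - sy) / b) ** 2
            rx = ((xx[xs] - sx) / a) ** 2
            for z in range(z_lo, z_hi + 1):
                if z not in cell_zs:
                    continue
                rz = ((float(spec.depth_of_z(z)) - zc_depth) / c) ** 2
                r2 = rz + ry[:, None] + rx[None, :]
                if r2.min() > 1.96:  # nothing near the surface at this layer
                    continue
                r = np.sqrt(r2)
                inten = 1.0 / (1.0 + np.exp((r - 1.0) / 0.03))
                img[t, z, 1][np.ix_(ys, xs)] += inten.astype(np.float32)
                inside = (r2 <= 1.0) & (cells[t, z][np.ix_(ys, xs)] == track)
                sub = nucs[t, z][np.ix_(ys, xs)]
                sub[inside] = track
                nucs[t, z][np.ix_(ys, xs)] = sub
        if myosin is not None:
            for track in range(1, lat.n_cells + 1):
                sy, sx = lat.seed_of(track)
                ys = np.abs(yy - sy) <= myosin.medial_radius
                xs = np.abs(xx - sx) <= myosin.medial_radius
                blob = (
                    (yy[ys][:, None] - sy) ** 2 + (xx[xs][None, :] - sx) ** 2
                ) <= myosin.medial_radius**2
                for z in cell_zs[:4]:
                    sub = img[t, z, 2][np.ix_(np.where(ys)[0], np.where(xs)[0])]
                    sub[blob] += myosin.medial
                    img[t, z, 2][np.ix_(np.where(ys)[0], np.where(xs)[0])] = sub

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape).astype(np.float32)
        np.clip(img, 0.0, None, out=img)

    # ground-truth tables
    rows = []
    for t in range(nt):
        t_min = t * spec.frame_interval / 60.0
        for track in range(1, lat.n_cells + 1):
            rows.append((track, t, t_min, eng.center_depth(track, t_min)))
    midplanes = pd.DataFrame(rows, columns=["track", "frame", "time_min", "midplane_depth_um"])

    area_signals = _area_signal_table(eng, base_areas, rng)

    t1_frames = []
    for ev, sched in zip(dynamics.t1_events, eng.schedules):
        df = sched.copy()
        df["a"], df["b"], df["c"], df["d"] = ev.quartet
        df["onset_min"] = ev.onset_min
        df["rate"] = ev.rate
        df["t2_min"] = sched.attrs["t2_min"]
        t1_frames.append(df)
    t1_truth = (
        pd.concat(t1_frames, ignore_index=True)
        if t1_frames
        else pd.DataFrame(
            columns=[
                "frame", "time_min", "signed_length_um",
                "a", "b", "c", "d", "onset_min", "rate", "t2_min",
            ]
        )
    )

    volume = ImageVolumeSeries(img, spec.voxel_size, spec.frame_interval, names)
    truth = GroundTruth(
        cell_labels=LabelVolumeSeries(cells, spec.voxel_size, spec.frame_interval),
        nucleus_labels=LabelVolumeSeries(nucs, spec.voxel_size, spec.frame_interval),
        midplanes=midplanes,
        area_signals=area_signals,
        t1_truth=t1_truth,
        adjacency=lat.adjacency(),
        lattice=lat,
        spec=spec,
        nuclei=eng.nuclei,
        dynamics=dynamics,
        apical_z=apz,
        extrusions=pd.DataFrame(dynamics.extrusions, columns=["track", "onset_min"]),
    )
    return volume, truth


@dataclass
class PlaneMovie:
    """A single-layer label movie with its scripted truth (cheap T1 fixture)."""

    labels: np.ndarray  # (t, y, x) int32
    pixel: float
    frame_interval: float
    t1_truth: pd.DataFrame
    adjacency: set
    lattice: TissueLattice
    depth_um: float


def generate_plane_movie(
    spec: EmbryoSpec, dynamics: DynamicsSpec | None = None, depth_um: float = 7.0
) -> PlaneMovie:
    """Render only the label plane at ``depth_um`` below the apical surface.

    This is exactly the layer the volumetric generator would produce at that
    depth, without paying for the full stack — the natural fixture for
    interface-dynamics analyses that operate on one sub-apical layer.
    """
    dynamics = dynamics or DynamicsSpec()
    rng = np.random.default_rng(spec.seed)
    eng = _Engine(spec, dynamics, None, rng)
    lat = eng.lattice
    dz, dy, dx = spec.voxel_size
    z = spec.apical_z + int(round(depth_um / dz))
    ny = int(round(lat.fov[0] / dy))
    nx = int(round(lat.fov[1] / dx))
    labs = np.zeros((spec.n_frames, ny, nx), dtype=np.int32)
    for t in range(spec.n_frames):
        labs[t] = eng.plane_labels(t, z, (ny, nx), dx)
    t1_frames = []
    for ev, sched in zip(dynamics.t1_events, eng.schedules):
        df = sched.copy()
        df["a"], df["b"], df["c"], df["d"] = ev.quartet
        df["t2_min"] = sched.attrs["t2_min"]
        df["rate"] = ev.rate
        t1_frames.append(df)
    t1_truth = pd.concat(t1_frames, ignore_index=True) if t1_frames else pd.DataFrame()
    return PlaneMovie(
        labels=labs,
        pixel=dx,
        frame_interval=spec.frame_interval,
        t1_truth=t1_truth,
        adjacency=lat.adjacency(),
        lattice=lat,
        depth_um=depth_um,
    )
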