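# Methods

This note documents the models, conventions and numerical choices behind
`nucleoscope`, and what the synthetic-data validation does and does not
establish about real microscopy data.

## Coordinate and unit conventions

All volumes are `(t, z, y, x)` with 0-based indices; `z` increases
basally, so `z = 0` is the apical-most layer.  Physical quantities derive
from `voxel_size = (dz, dy, dx)` in µm (default 1.0, 0.16, 0.16 — a
spinning-disk stack with 1 µm z-steps and 0.16 µm pixels) and
`frame_interval` in seconds (default 15 s).  Interface angles are measured
from the image y-axis, the dorsoventral (DV) direction: θ = 0° is a
vertical, DV-aligned interface (the canonically contracting class during
convergent extension), θ = ±90° is horizontal/AP-aligned.  Depth offsets
from the nuclear midplane are positive apically and negative basally.

## The synthetic embryo

The generator emulates the statistical structure the analysis assumes, not
tissue mechanics.  Cells are the power diagram (weighted Voronoi) of a
triangular seed lattice, giving hexagonal prisms; each z-layer receives a
small static seed jitter (σ = 0.1 µm) so prisms have realistic per-layer
area variation, and an optional shear (`tilt`) slants the columns.  A ring
of unlabelled boundary cells surrounds the interior so every interior cell
has a complete neighbourhood; the ring maps to background (label 0).

Default geometry is fixed by three observed set-points: nuclear volume
280 µm³ with polar semi-axis c_z = 5 µm (hence in-plane semi-axes
3.656 µm), midplane nuclear occupancy 84% of the cell cross-section (hence
cell area ≈ 50 µm² and lattice pitch 7.598 µm), and nuclear centres 10 µm
below the apical surface in a 20 µm-deep monolayer.  Two µm of empty
medium sit above the apical surface; the first cell layer renders
brightened apical caps so apical-surface detection is exercised.

Channels: the membrane channel is a two-pixel ridge on every label
discontinuity; the nuclear channel is an ellipsoid with a steep sigmoid
falloff (width 0.03 of the normalised radius) so that half-maximum sits at
the true surface; optional myosin paints each interface as a Gaussian
ridge of distance-to-interface (σ = 1 px) — making the integrated signal
per unit edge length orientation-independent, which a per-pixel painting
of rasterised diagonals is not — with DV-aligned interfaces brighter by a
configurable factor (default 2×), plus a medial blob and a flat
background.  Noise is additive Gaussian, clipped at zero.  The
membrane-marker intensity statistics are a free choice of the generator
(no measured values exist for them); they are documented here and in the
config defaults.

Prescribed dynamics, all recorded exactly in the returned ground truth:

- **Drift** — nuclear centres move apical–basally at `drift_z` µm/min,
  uniformly or with a checkerboard sign pattern (`drift_stagger`) that
  emulates dispersion of initially coplanar nuclei.
- **Deformation** — in-plane axis ratio changes at `deform_rate` per
  minute, area-preserving.
- **Area oscillations** — per-cell sinusoids at `osc_frequency`
  (default 0.008 Hz, validated against the Nyquist limit) with relative
  amplitude 5% and random phases; a depth profile scales the amplitude as
  a function of offset from the nuclear midplane.  The prescribed signals
  are stored in `GroundTruth.area_signals` (and produced cheaply by
  `generate_area_signals`); the rendered labels receive a first-order
  power-weight modulation (w = m·A/√3 for relative area change m) so the
  images oscillate too, but spectral analyses are validated on the
  prescribed signals, where the injected amplitude is exact.
- **T1 events** — for a quartet with the contracting pair d apart and the
  flanking pair at ±h, the shared Voronoi edge has length
  L = (h² − d²/4)/h (h > d/2) and the orthogonal edge
  (d² − 4h²)/(2d) (h < d/2).  Inverting h(L) yields a seed schedule whose
  rasterised interface follows a prescribed *linear* signed-length
  schedule through the vertex.  Scripted A–B separations move seeds at
  twice the prescribed centroid rate (a Voronoi cell centroid follows its
  seed at half speed); the calibration is first-order and holds while
  displacements stay small relative to the pitch.
- **Extrusions** — a scripted cell loses its apical column (default the
  top 5 µm) from its onset time; neighbours tile over the vacated area.

Determinism: all randomness (jitter, phases, signal noise, image noise)
derives from one `numpy` generator seeded by `EmbryoSpec.seed`; identical
specs give bit-identical volumes.

What the generator does **not** emulate: force balance or vertex-model
energetics, optical PSF/anisotropic blur, bleaching, z-drift of the whole
embryo, segmentation-adversarial texture, or curvature of the embryo
surface.  Passing recovery tests on this data therefore validates the
*measurement pipeline* — that each operation returns what was put in, at
the stated tolerances — not robustness to every imaging pathology.

## Segmentation

Seeds (when not supplied) are distance-transform peaks of the
Otsu-thresholded, Gaussian-smoothed membrane layer, at least 3 µm apart.
Watershed runs on the smoothed membrane; regions touching the image border
are relabelled background (disable with `background="none"` for
membrane-free Voronoi partitions).  Propagation proceeds from the
reference layer outward, apically then basally, each layer seeded by the
5×5-eroded regions of its segmented neighbour; layers with < 5% of the
reference layer's mean membrane signal are copied verbatim (interior gaps)
or left empty (beyond the cell span) and flagged.  Time tracking is greedy
maximal-overlap matching with a minimum overlap fraction of 0.5 of the
previous region, ties broken by centroid distance; unmatched regions open
new tracks and disappearances are recorded for extrusion counting.

Nuclei are segmented per cell inside the cell's 3D column: Otsu threshold
within the bounding box (overridable), largest connected component as the
rough outline, then accretion of connected voxels within ±25% of the rough
segmentation's median intensity.  Labels are inherited from the host cell.
On noise-free synthetic data this recovers cell IoU ≈ 0.99 and nucleus
IoU ≈ 0.95, nuclear volume within 5% and the midplane within half a
z-step; IoU degrades monotonically with added noise.

A note on z-extent: the nucleus length definition (distance between first
and last occupied layers) loses up to 2·dz on an ellipsoid whose tips fall
exactly on sampling planes — a 10 µm nucleus can read 8 µm from
voxel-centre ground-truth labels at dz = 1 µm.  Sphericity recovery tests
therefore voxelise at finer dz or use off-grid centres; on segmented data
the soft intensity edge restores the boundary layers.

## Analysis conventions and numerical choices

- **Midplane** — plane of maximum area (apical-most among ties), then on
  each side the occupied plane with area closest to 50% of the maximum
  (ties toward the maximum); midpoint of the two, so half-integer values
  occur.  A missing side uses the occupied extremum and flags truncation.
  The rule is property-tested against an exhaustive plane search.
- **Apical surface** — first layer whose cell coverage reaches 50% of the
  best-covered layer's.  Coverage is taken relative to the maximum, not
  the full field, because the tissue footprint occupies only part of the
  image; a manual override is accepted.
- **Velocity** — forward difference of midplane depth over a 1 min window
  (2 min recommended for slower-developing injected preparations); per
  track, the peak is max |v| and the mean is mean |v|.  Midplane
  quantisation (0.5 µm) averages out over windows and tracks; mean-drift
  recovery on synthetic data is within ~1%.
- **MSD** — the time-averaged squared increment of pairwise midplane
  distances, exactly equal to the double-loop definition (tested).  Pairs
  default to nuclei of edge-adjacent cells.  A curvature hint
  (active/diffusive/constrained) is attached but never asserted.
- **Packing / ACA** — packing profiles drop absent nuclei; the cluster is
  a central cell plus its first-ring neighbours.  The ACA denominator
  averages over the whole cluster including the central cell
  (neighbours-only available via flag); half-integer midplanes evaluate on
  the nearer layer, ties apical; clusters whose central cell touches the
  field boundary are excluded.
- **Interfaces** — vertices are clustered 2×2-blocks containing ≥3
  distinct labels; interface length is the Euclidean distance between the
  two farthest endpoint vertices of a pair, and a pair whose endpoints
  have merged carries length 0.  T2 is the first frame the new (T3)
  interface exists, with a 0.5 µm / 2-frame collapse criterion as the
  trigger; vertices with more than four cells are flagged as rosettes and
  excluded from rate statistics.
- **Rates** — T1 rates are (value at 10 min after T2 − value at 10 min
  before) / 20 min, endpoint values averaged over a 1 min window against
  pixel jitter; vertical-interface rates are endpoint differences over
  0–20 min on signed lengths (the tissue-extension onset frame is
  config-supplied, since onset is defined observationally).  Because
  vertex positions quantise to the 0.16 µm grid, a −0.02 µm/min rate (an
  eighth of a pixel per minute) is recovered by pooling interfaces,
  movies and analysis depths and widening the endpoint window to 4 min;
  single-interface readings at that rate are quantisation-limited.
  Contractile interfaces for directionality use rate ≤ −0.5 µm/min and
  15° bins, with the vertical band 0–15°.
- **Oscillations** — linear least-squares detrending by default
  (moving-average subtraction available), no taper (Hann optional),
  signals shorter than 3 min excluded, all signals truncated to the
  shortest common length so spectra share one frequency grid.  Amplitude
  spectra are scaled so a pure on-grid tone of amplitude A reads A;
  Parseval's identity is tested.  Spectra are averaged across cells per
  1 µm depth-offset bin (signal-first averaging via flag).  Dampening is
  100·(amp(−4 µm) − amp(0 µm))/amp(−4 µm), positive when the midplane is
  dampened; injected profiles of 0/24/51% recover within ~2.5 points at
  the default signal noise, the residual coming from the additive noise
  floor inflating the denominator.
- **Myosin** — interface ROIs are 4-iteration dilations of the 1-px
  pair skeleton (≈9 px wide); per-interface value is the max over depths
  of the ROI mean, normalised so interface values average 1 per frame.
  Adjacent ROIs overlap only near vertices and overlap pixels contribute
  to both interfaces; an optional junction-trim radius removes skeleton
  pixels near vertices, which isolates mid-interface signal and is what
  recovers the painted 2× vertical contrast on the hexagonal fixture
  (whose "horizontal" class sits at ±60°, the lattice's only non-vertical
  orientation).  Medial intensity uses a max projection of the four
  apical-most layers, excludes a 4-px dilated junctional band, subtracts
  the histogram-mode background of the extra-embryonic field and divides
  by cell area.
- **Extrusions** — a tracked cell that loses all apical-layer presence for
  ≥2 consecutive frames through the end of the movie, without touching the
  image border in its last present frame, counted per ROI as a percent of
  cells present at the counting frame.  This is a stated automated
  operationalisation of what is conventionally counted manually.
- **Perimeter** — Crofton-formula estimate by default (<1% bias on
  rasterised circles); the corner-weighted contour length (~4% high on
  circles) is available.  Raw pixel-edge counting is not offered as a
  default because it biases circle shape factors upward by ~11%.
- **Shape-metric invariance** — shape factor and aspect ratio are tested
  invariant (≤2%) under translation and under rotations applied by
  rasterising the rotated shape analytically; re-interpolating a raster
  genuinely roughens and lengthens the contour and is not a test of the
  metric.

## Problem sizes used in validation

The test and acceptance suites run on small embryos chosen to exercise
every code path at interactive scale: 3×3 to 3×6 cell grids (9–25 µm
fields at 0.16 µm pixels, 22 z-layers), single frames for static
recovery, 21 frames (5 min) for drift, 81–105 frames (20–26 min) for
oscillation and T1 analyses.  Slow-rate recovery pools 27 interface
readings (3 movies × 3 scripted events × 3 analysis depths).  The full
suite completes in a few minutes on one CPU; the same code runs unchanged
on larger fields.

## Known limitations

- The generator's Voronoi kinematics are first-order calibrated; scripted
  seed displacements beyond ~1–2 µm leave the linear regime and realized
  centroid rates drift upward.
- Sub-pixel interface rates are only recoverable in ensemble; the package
  does not attempt sub-pixel vertex localisation.
- Absolute nuclear depth requires the apical surface in the volume; when
  it is absent, only relative (pairwise) dispersion measures are
  meaningful.
- The myosin polarity summary assumes the segmentation and myosin channel
  are co-registered; no registration is performed.
- Whole-embryo z-drift correction is out of scope; movies are assumed
  pre-screened for minimal z-shift.
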