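"""Cell and nucleus segmentation for columnar epithelia.

Cells are segmented in a single reference z-layer with a seeded watershed
on the membrane channel, propagated layer by layer to the rest of the
stack (each layer seeded by the eroded regions of its already-segmented
neighbour) and tracked in time by maximal pixel overlap.  Nuclei are then
segmented per cell inside the cell's 3D column — a rough intensity
threshold followed by accretion of connected voxels whose intensity is
close to the median of the rough segmentation — and inherit the host
cell's track label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed


def derive_seeds(
    membrane: np.ndarray,
    pixel: float,
    *,
    smooth_um: float = 0.5,
    min_seed_distance_um: float = 3.0,
) -> np.ndarray:
    """Seed points (N, 2) from local interior maxima of the distance map.

    The membrane channel is Gaussian-smoothed, thresholded (Otsu) into
    ridge vs interior, and seeds are placed at distance-transform peaks of
    the interior, at least ``min_seed_distance_um`` apart.
    """
    sm = gaussian(membrane.astype(float), sigma=smooth_um / pixel, preserve_range=True)
    thr = threshold_otsu(sm)
    interior = sm < thr
    dist = ndi.distance_transform_edt(interior)
    md = max(1, int(round(min_seed_distance_um / pixel)))
    return peak_local_max(dist, min_distance=md, exclude_border=False)


def segment_cells_seeded(
    frame: np.ndarray,
    reference_z: int,
    seeds: np.ndarray | None = None,
    *,
    membrane_channel: int = 0,
    pixel: float = 0.16,
    smooth_um: float = 0.5,
    min_seed_distance_um: float = 3.0,
    background: str = "border",
) -> np.ndarray:
    """Seeded watershed of one z-layer of one frame.

    Parameters
    ----------
    frame : ndarray, shape (z, c, y, x)
        One time point of the image series.
    seeds : ndarray (N, 2), optional
        One (row, col) seed per expected cell; derived automatically from
        the membrane channel when absent.
    background : {"border", "none"}
        With ``"border"`` every watershed region touching the image border
        is relabelled 0 (out-of-field tissue); ``"none"`` keeps all regions
        (e.g. for membrane-free Voronoi-style partitions).

    Returns
    -------
    labels : ndarray (y, x), int32
        One region per seed; 0 is background.
    """
    mem = np.asarray(frame)[reference_z, membrane_channel].astype(float)
    if mem.size == 0 or not np.any(mem > 0):
        raise ValueError("empty frame: membrane channel has no signal")
    sm = gaussian(mem, sigma=smooth_um / pixel, preserve_range=True)
    if seeds is None:
        seeds = derive_seeds(mem, pixel, smooth_um=smooth_um, min_seed_distance_um=min_seed_distance_um)
    seeds = np.asarray(seeds, dtype=int)
    if len(seeds) < 2:
        raise ValueError(f"need at least 2 seeds, got {len(seeds)}")
    markers = np.zeros(mem.shape, dtype=np.int32)
    for k, (r, c) in enumerate(seeds, start=1):
        markers[r, c] = k
    labels = watershed(sm, markers).astype(np.int32)
    if background == "border":
        edge = np.unique(
            np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
        )
        labels[np.isin(labels, edge)] = 0
    return labels


def area_outlier_report(labels: np.ndarray, pixel: float, *, small_fraction: float = 0.6) -> pd.DataFrame:
    """Flag regions whose area departs from the population (e.g. split cells)."""
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    areas = counts * pixel * pixel
    med = np.median(areas) if len(areas) else np.nan
    return pd.DataFrame(
        {
            "label": ids,
            "area_um2": areas,
            "flag_small": areas < small_fraction * med,
        }
    )


def _eroded_markers(labels: np.ndarray, size: int = 5) -> np.ndarray:
    """Per-label erosion: keep pixels whose whole neighbourhood is one label."""
    mn = ndi.minimum_filter(labels, size=size)
    mx = ndi.maximum_filter(labels, size=size)
    uniform = mn == mx
    bg_id = labels.max() + 1
    markers = np.where(uniform, labels, 0).astype(np.int32)
    markers[uniform & (labels == 0)] = bg_id
    return markers


def propagate_z(
    reference_labels: np.ndarray,
    frame: np.ndarray,
    reference_z: int,
    *,
    membrane_channel: int = 0,
    pixel: float = 0.16,
    smooth_um: float = 0.5,
    signal_fraction: float = 0.05,
) -> tuple[np.ndarray, list[int]]:
    """Propagate a reference-layer segmentation to every z-layer.

    Works outward from ``reference_z`` apically then basally; each layer is
    watershed-segmented using the eroded regions of its already-segmented
    neighbour as seeds, so track labels are preserved.  Layers with
    essentially no membrane signal are copied verbatim (interior gaps) or
    left empty (beyond the cell span); either way they are flagged.

    Returns
    -------
    labels3d : ndarray (z, y, x), int32
    flagged : list of int
        z-layers that had no usable membrane signal.
    """
    frame = np.asarray(frame)
    nz = frame.shape[0]
    mem = frame[:, membrane_channel].astype(float)
    out = np.zeros((nz,) + reference_labels.shape, dtype=np.int32)
    out[reference_z] = reference_labels
    ref_mean = mem[reference_z].mean()
    has_signal = mem.reshape(nz, -1).mean(axis=1) >= signal_fraction * ref_mean
    # contiguous signal span around the reference layer
    lo = reference_z
    while lo > 0 and has_signal[lo - 1]:
        lo -= 1
    hi = reference_z
    while hi < nz - 1 and has_signal[hi + 1]:
        hi += 1
    flagged: list[int] = []
    bg_id = int(reference_labels.max()) + 1

    def segment_layer(z: int, prev: np.ndarray) -> np.ndarray:
        if not has_signal[z]:
            flagged.append(z)
            if lo <= z <= hi:
                return prev.copy()
            return np.zeros_like(prev)
        if z < lo or z > hi:
            flagged.append(z)
            return np.zeros_like(prev)
        sm = gaussian(mem[z], sigma=smooth_um / pixel, preserve_range=True)
        markers = _eroded_markers(prev)
        lab = watershed(sm, markers).astype(np.int32)
        lab[lab == bg_id] = 0
        return lab

    for z in range(reference_z - 1, -1, -1):
        out[z] = segment_layer(z, out[z + 1])
    for z in range(reference_z + 1, nz):
        out[z] = segment_layer(z, out[z - 1])
    return out, sorted(set(flagged))


@dataclass
class TrackEvents:
    """Track bookkeeping from time tracking (feeds extrusion counting)."""

    starts: dict  # track -> first frame
    ends: dict  # track -> last frame


def track_time(
    frames: np.ndarray, *, min_overlap: float = 0.5
) -> tuple[np.ndarray, TrackEvents]:
    """Greedy maximal-overlap label tracking across frames.

    ``frames`` is (t, y, x) with frame-local labels; the result carries
    globally stable track ids.  A region is matched to the previous-frame
    region with the largest pixel overlap, provided the overlap covers at
    least ``min_overlap`` of the previous region; ties break by centroid
    distance.  Unmatched regions open new tracks.
    """
    frames = np.asarray(frames)
    nt = frames.shape[0]
    out = np.zeros_like(frames, dtype=np.int32)
    if nt == 0:
        return out, TrackEvents({}, {})
    out[0] = frames[0]
    next_track = int(frames[0].max()) + 1
    starts = {int(t): 0 for t in np.unique(frames[0]) if t > 0}
    ends = dict.fromkeys(starts, 0)
    for t in range(1, nt):
        prev, cur = out[t - 1], frames[t]
        prev_ids = [i for i in np.unique(prev) if i > 0]
        cur_ids = [i for i in np.unique(cur) if i > 0]
        prev_area = {i: int((prev == i).sum()) for i in prev_ids}
        # overlap counts via joint histogram
        joint = prev.astype(np.int64) * (cur.max() + 1) + cur
        vals, counts = np.unique(joint[(prev > 0) & (cur > 0)], return_counts=True)
        pairs = []
        for v, c in zip(vals, counts):
            p, q = divmod(int(v), int(cur.max() + 1))
            pairs.append((c, p, q))
        pcent = {i: ndi.center_of_mass(prev == i) for i in prev_ids}
        ccent = {i: ndi.center_of_mass(cur == i) for i in cur_ids}
        pairs.sort(
            key=lambda pc: (
                -pc[0],
                float(np.hypot(*(np.subtract(pcent[pc[1]], ccent[pc[2]])))),
            )
        )
        assigned_prev, mapping = set(), {}
        for c, p, q in pairs:
            if q in mapping or p in assigned_prev:
                continue
            if c < min_overlap * prev_area[p]:
                continue
            mapping[q] = p
            assigned_prev.add(p)
        frame_out = np.zeros_like(cur)
        for q in cur_ids:
            if q in mapping:
                tid = mapping[q]
            else:
                tid = next_track
                next_track += 1
                starts[tid] = t
            frame_out[cur == q] = tid
            ends[tid] = t
        out[t] = frame_out
    return out, TrackEvents(starts, ends)


def apply_track_map(volume_labels: np.ndarray, ref_frames: np.ndarray, tracked_ref: np.ndarray) -> np.ndarray:
    """Relabel a (t, z, y, x) volume so labels match the tracked reference layer."""
    out = np.zeros_like(volume_labels)
    for t in range(volume_labels.shape[0]):
        mapping = {}
        ref, trk = ref_frames[t], tracked_ref[t]
        for i in np.unique(ref):
            if i > 0:
                j = trk[ref == i]
                mapping[int(i)] = int(np.bincount(j[j > 0]).argmax()) if np.any(j > 0) else 0
        lut = np.zeros(int(volume_labels[t].max()) + 1, dtype=np.int32)
        for k, v in mapping.items():
            if k < len(lut):
                lut[k] = v
        out[t] = lut[volume_labels[t]]
    return out


def segment_nucleus(
    cell_mask: np.ndarray,
    nuclear: np.ndarray,
    *,
    threshold: float | None = None,
    median_tol: float = 0.25,
) -> np.ndarray | None:
    """Segment one nucleus inside a cell's 3D column.

    A rough outline is the largest connected component above ``threshold``
    (Otsu within the cell's bounding box by default); voxels connected to
    it with intensity within ``±median_tol`` of the rough-segmentation
    median are then accreted.  Returns a boolean (z, y, x) mask, or None
    when no voxel clears the threshold (nucleus absent — not an error).
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    vals = nuclear[cell_mask]
    if vals.size == 0 or float(vals.max()) <= 1e-9:
        return None
    if threshold is None:
        sl = ndi.find_objects(cell_mask.astype(np.int8))[0]
        box = nuclear[sl]
        if float(box.max()) - float(box.min()) < 1e-9:
            return None
        threshold = threshold_otsu(box)
    rough = (nuclear >= threshold) & cell_mask
    if not rough.any():
        return None
    lab, n = ndi.label(rough)
    if n > 1:
        sizes = ndi.sum_labels(rough, lab, index=np.arange(1, n + 1))
        rough = lab == (1 + int(np.argmax(sizes)))
    med = float(np.median(nuclear[rough]))
    band = cell_mask & (nuclear >= (1.0 - median_tol) * med) & (nuclear <= (1.0 + median_tol) * med)
    refined = ndi.binary_propagation(rough, mask=band | rough)
    return refined


def segment_nuclei(
    cell_labels: np.ndarray,
    nuclear: np.ndarray,
    *,
    threshold: float | None = None,
    median_tol: float = 0.25,
    dilate_mask_px: int = 1,
) -> np.ndarray:
    """Per-cell 3D nucleus segmentation with label inheritance.

    ``cell_labels`` and ``nuclear`` are single-frame (z, y, x) arrays.  Each
    nucleus carries the track label of its host cell.
    """
    out = np.zeros_like(cell_labels, dtype=np.int32)
    for track in np.unique(cell_labels):
        if track <= 0:
            continue
        mask = cell_labels == track
        if dilate_mask_px:
            mask = ndi.binary_dilation(mask, iterations=dilate_mask_px)
        sl = ndi.find_objects(mask.astype(np.int8))
        if not sl:
            continue
        sl = sl[0]
        nuc = segment_nucleus(mask[sl], nuclear[sl], threshold=threshold, median_tol=median_tol)
        if nuc is not None:
            sub = out[sl]
            sub[nuc] = track
            out[sl] = sub
    return out


def nucleus_length(mask: np.ndarray, dz: float) -> float:
    """z-extent (µm) between the first and last occupied z-layers."""
    zs = np.where(np.asarray(mask).reshape(mask.shape[0], -1).any(axis=1))[0]
    if len(zs) == 0:
        return float("nan")
    return float((zs[-1] - zs[0]) * dz)


def areas_by_z(labels: np.ndarray, pixel_area: float) -> pd.DataFrame:
    """Per-(label, z) areas of a (z, y, x) label volume, in µm²."""
    rows = []
    for z in range(labels.shape[0]):
        ids, counts = np.unique(labels[z][labels[z] > 0], return_counts=True)
        rows.extend((int(i), z, float(c * pixel_area)) for i, c in zip(ids, counts))
    return pd.DataFrame(rows, columns=["track", "z", "area_um2"])


def nucleus_table(nucleus_labels: np.ndarray, voxel_size, frame: int = 0) -> pd.DataFrame:
    """Volume, z-length and per-z area summary of one frame of nuclei."""
    dz, dy, dx = voxel_size
    vox = dz * dy * dx
    rows = []
    for track in np.unique(nucleus_labels):
        if track <= 0:
            continue
        mask = nucleus_labels == track
        rows.append(
            {
                "track": int(track),
                "frame": frame,
                "volume_um3": float(mask.sum() * vox),
                "length_um": nucleus_length(mask, dz),
            }
        )
    return pd.DataFrame(rows)
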