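"""Myosin intensity quantification and extrusion-like event counting.

Interfacial intensity: the skeletonised interface between each cell pair
is dilated into a ~8-pixel-wide ROI, the myosin channel averaged inside
it per depth, the maximum over depths taken as the interface value, and
values normalised so the per-frame mean of interface values is 1.  The
planar-polarity summary compares the vertical (0–15°) and horizontal
(75–90°) angle bins.

Medial intensity: background-subtracted mean of the central (junction-
excluded) region of each cell over a maximum projection of the four
apical-most z-layers, divided by cell area.

Extrusion-like events: tracked cells that lose all presence in a
representative apical layer for at least two consecutive frames without
exiting through the image border, counted per fixed ROI as a percentage
of cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .interfaces import build_interfaces, label_adjacency


def _pair_skeleton(labels: np.ndarray, a: int, b: int) -> np.ndarray:
    """1-px skeleton of the a|b interface: pixels of a 4-adjacent to b."""
    ma, mb = labels == a, labels == b
    grow_b = ndi.binary_dilation(mb)
    return ma & grow_b


def interfacial_intensity(
    cell_labels: np.ndarray,
    myosin: np.ndarray,
    pixel: float,
    *,
    dilation_iter: int = 4,
    angle_z: int | None = None,
    min_skeleton_px: int | None = None,
    trim_junction_px: int = 0,
) -> pd.DataFrame:
    """Normalised per-interface myosin intensity with angle bins.

    ``cell_labels`` and ``myosin`` are single-frame (z, y, x) arrays with
    co-registered segmentation and myosin channel.  Per pair: the skeleton
    is dilated ``dilation_iter`` times (≈ 2·iter+1 px wide), the mean ROI
    intensity taken per depth, and the maximum over depths kept.  Values
    are normalised by the mean interface value of the frame, so the
    normalised values average to exactly 1.  Interfaces shorter than the
    dilation width are flagged and excluded.

    ``trim_junction_px`` removes skeleton pixels within that radius of
    tissue vertices before dilation, isolating mid-interface signal from
    the bright pools of adjoining interfaces; 0 keeps the full skeleton
    (adjacent ROIs then overlap only at vertices, with overlap pixels
    contributing to both interfaces).
    """
    nz = cell_labels.shape[0]
    angle_z = nz // 2 if angle_z is None else angle_z
    if min_skeleton_px is None:
        min_skeleton_px = 2 * dilation_iter + 1
    angles = {}
    table = build_interfaces(cell_labels[angle_z], pixel)
    for _, r in table.iterrows():
        angles[(int(r["a"]), int(r["b"]))] = float(r["angle_deg"])
    pairs = sorted(label_adjacency(cell_labels[angle_z]))
    junction_masks = {}
    if trim_junction_px > 0:
        from .interfaces import extract_vertices

        for z in range(nz):
            mask = np.zeros(cell_labels[z].shape, dtype=bool)
            for (vy, vx), _members in extract_vertices(cell_labels[z]):
                mask[int(round(vy)), int(round(vx))] = True
            junction_masks[z] = ndi.binary_dilation(mask, iterations=trim_junction_px)
    rows = []
    for a, b in pairs:
        per_depth = []
        short = False
        for z in range(nz):
            skel = _pair_skeleton(cell_labels[z], a, b) | _pair_skeleton(cell_labels[z], b, a)
            if trim_junction_px > 0 and skel.any():
                skel = skel & ~junction_masks[z]
            if skel.sum() == 0:
                continue
            if skel.sum() < min_skeleton_px:
                short = True
            roi = ndi.binary_dilation(skel, iterations=dilation_iter)
            per_depth.append(float(myosin[z][roi].mean()))
        if not per_depth:
            continue
        rows.append(
            {
                "a": a,
                "b": b,
                "intensity_max": max(per_depth),
                "angle_deg": angles.get((a, b), float("nan")),
                "flag_short": short,
            }
        )
    df = pd.DataFrame(rows)
    if not len(df):
        return df
    kept = ~df["flag_short"]
    df = df[kept].reset_index(drop=True)
    mean_val = df["intensity_max"].mean()
    df["intensity_norm"] = df["intensity_max"] / mean_val if mean_val > 0 else 0.0
    return df


def polarity_ratio(intensities: pd.DataFrame, *, vertical_max_deg: float = 15.0,
                   horizontal_min_deg: float = 75.0) -> float:
    """Median vertical-bin over median horizontal-bin normalised intensity."""
    ang = intensities["angle_deg"].abs()
    v = intensities.loc[ang <= vertical_max_deg, "intensity_norm"]
    h = intensities.loc[ang >= horizontal_min_deg, "intensity_norm"]
    if len(v) == 0 or len(h) == 0 or h.median() == 0:
        return float("nan")
    return float(v.median() / h.median())


def estimate_background(plane: np.ndarray, field_mask: np.ndarray | None = None,
                        *, bins: int = 64) -> float:
    """Histogram mode of the extra-embryonic / field pixels."""
    vals = plane[field_mask] if field_mask is not None else plane.ravel()
    if vals.size == 0:
        return 0.0
    hist, edges = np.histogram(vals, bins=bins)
    k = int(np.argmax(hist))
    return float(0.5 * (edges[k] + edges[k + 1]))


def medial_intensity(
    cell_labels: np.ndarray,
    myosin: np.ndarray,
    pixel: float,
    *,
    apical_z: int = 0,
    n_layers: int = 4,
    exclusion_dilate_px: int = 4,
    background: float | None = None,
) -> pd.DataFrame:
    """Per-µm² medial myosin intensity of each cell.

    Uses a max projection of the ``n_layers`` apical-most cell layers
    (2 µm at 0.5 µm steps, 4 µm at 1 µm steps).  The central region is the
    cell footprint minus a ``exclusion_dilate_px``-dilated band around the
    segmented cell contacts; cells whose central region vanishes are
    reported as missing (NaN).
    """
    proj = myosin[apical_z : apical_z + n_layers].max(axis=0)
    lab = cell_labels[apical_z]
    if background is None:
        background = estimate_background(proj, lab == 0)
    boundary = np.zeros(lab.shape, dtype=bool)
    for s1, s2 in ((lab[:-1, :], lab[1:, :]), (lab[:, :-1], lab[:, 1:])):
        d = s1 != s2
        b1 = np.zeros_like(boundary)
        b1[: s1.shape[0], : s1.shape[1]] |= d
        boundary |= b1
    excl = ndi.binary_dilation(boundary, iterations=exclusion_dilate_px)
    rows = []
    for track in np.unique(lab):
        if track <= 0:
            continue
        cell = lab == track
        central = cell & ~excl
        area = float(cell.sum()) * pixel * pixel
        if central.sum() == 0:
            val = float("nan")
        else:
            val = (float(proj[central].mean()) - background) / area
        rows.append({"track": int(track), "area_um2": area, "medial_per_um2": val})
    return pd.DataFrame(rows)


def count_extrusions(
    apical_labels: np.ndarray,
    rois: list[tuple[int, int, int, int]],
    *,
    min_absent_frames: int = 2,
    count_frame: int = 0,
) -> pd.DataFrame:
    """Extrusion-like events per ROI on a tracked apical-layer label movie.

    ``apical_labels`` is (t, y, x) at the representative apical layer;
    ``rois`` are (y0, x0, height, width) pixel boxes.  An event is a track
    that loses all apical-layer presence for at least
    ``min_absent_frames`` consecutive frames (through the end of the
    movie) while not touching the image border in its last present frame.
    Percent = events / cells in the ROI at ``count_frame`` × 100.
    """
    nt, ny, nx = apical_labels.shape
    # classify every track once
    events = set()
    tracks = [int(v) for v in np.unique(apical_labels) if v > 0]
    for track in tracks:
        present = [(apical_labels[t] == track).any() for t in range(nt)]
        if not any(present):
            continue
        last = max(i for i, p in enumerate(present) if p)
        absent_after = nt - 1 - last
        if absent_after < min_absent_frames:
            continue
        mask = apical_labels[last] == track
        touches = mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
        if touches:
            continue
        events.add(track)
    rows = []
    for y0, x0, h, w in rois:
        if y0 < 0 or x0 < 0 or y0 + h > ny or x0 + w > nx:
            raise ValueError(f"ROI ({y0},{x0},{h},{w}) lies outside the {ny}x{nx} field")
        box = apical_labels[count_frame, y0 : y0 + h, x0 : x0 + w]
        cells_in = {int(v) for v in np.unique(box) if v > 0}
        ev = cells_in & events
        n_cells = len(cells_in)
        rows.append(
            {
                "y0": y0,
                "x0": x0,
                "n_cells": n_cells,
                "n_events": len(ev),
                "percent": 100.0 * len(ev) / n_cells if n_cells else float("nan"),
            }
        )
    return pd.DataFrame(rows)
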