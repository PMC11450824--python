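"""Nuclear dispersion kinematics.

A nucleus's apical–basal position is summarised by its *midplane*: find
the z-plane of maximum cross-sectional area, then the planes on either
side whose area is closest to 50% of that maximum; the midplane is the
midpoint of those two half-maximum planes (robust to top-/bottom-heavy
volume shifts, unlike the widest plane).  From midplane trajectories the
module computes absolute depths, packing profiles, apical–basal
velocities and the MSD of pairwise midplane distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Midplane:
    z: float  # may be half-integer (z-index units)
    truncated: bool  # a half-maximum plane was missing on one side


def find_midplane(areas, z0: int = 0) -> Midplane:
    """Midplane of a nucleus from its per-z area profile.

    ``areas`` is a 1D profile over consecutive z-layers starting at index
    ``z0``; zeros mean the nucleus is absent from that layer.  Among planes
    of equal maximum area the apical-most (smallest z) is taken; "closest
    to 50%" ties resolve toward the plane nearer the maximum.  If a side
    has no occupied plane beyond the maximum, the occupied extremum on that
    side is used and the result is flagged truncated.
    """
    a = np.asarray(areas, dtype=float)
    occ = np.where(a > 0)[0]
    if len(occ) == 0:
        raise ValueError("nucleus occupies no z-plane")
    zmax = int(occ[np.argmax(a[occ])])  # argmax returns first max -> apical-most
    half = a[zmax] / 2.0
    truncated = False

    def side(indices, toward_max_sign):
        nonlocal truncated
        idx = [z for z in indices if a[z] > 0]
        if not idx:
            truncated = True
            return zmax
        devs = np.abs(a[idx] - half)
        best = np.min(devs)
        cands = [z for z, d in zip(idx, devs) if d == best]
        # tie toward the plane nearer the maximum
        return min(cands, key=lambda z: (abs(z - zmax), z))

    z_apical = side(range(0, zmax), +1)
    z_basal = side(range(zmax + 1, len(a)), -1)
    return Midplane(z=z0 + (z_apical + z_basal) / 2.0, truncated=truncated)


def absolute_depth(midplane_z: float, apical_z: float, dz: float) -> float:
    """Distance (µm) from the apical surface to the nuclear midplane."""
    return (midplane_z - apical_z) * dz


def detect_apical_surface(cell_labels: np.ndarray, *, coverage_fraction: float = 0.5) -> int:
    """First z-layer where apical cell caps are visible.

    Operationalised as the first z whose labelled-cell coverage reaches
    ``coverage_fraction`` of the best-covered layer (the tissue footprint
    occupies only part of the field, so coverage is taken relative to the
    maximum rather than the full image).
    """
    lab = np.asarray(cell_labels)
    cover = (lab > 0).reshape(lab.shape[0], -1).mean(axis=1)
    if cover.max() <= 0:
        raise ValueError("no cell labels in volume; apical surface unavailable")
    hits = np.where(cover >= coverage_fraction * cover.max())[0]
    return int(hits[0])


def packing_profile(area_profiles: np.ndarray) -> np.ndarray:
    """packing(z) = ΣA_i(z) / Σ max_z A_i for a cluster of nuclei.

    ``area_profiles`` is (n_nuclei, n_z); all-zero rows (absent nuclei) are
    dropped.  The profile is 1 at z iff every nucleus attains its maximum
    area there.
    """
    a = np.atleast_2d(np.asarray(area_profiles, dtype=float))
    a = a[a.max(axis=1) > 0]
    if a.shape[0] == 0:
        raise ValueError("empty cluster: no nucleus has any area")
    return a.sum(axis=0) / a.max(axis=1).sum()


def max_packing(area_profiles: np.ndarray) -> float:
    """Maximum over z of the packing profile (the paper-style summary)."""
    return float(packing_profile(area_profiles).max())


def nucleus_velocity(
    depth_um: np.ndarray, frame_interval: float, *, window_min: float = 1.0
) -> pd.DataFrame:
    """Apical–basal midplane velocity over a sliding time window.

    ``depth_um`` is the midplane depth trajectory of one nucleus; velocity
    at frame k is (z[k+w] − z[k]) / window with w = window frames.  1 min
    windows suit wild-type acquisitions; injected embryos develop more
    slowly and are conventionally analysed with 2 min windows.
    """
    z = np.asarray(depth_um, dtype=float)
    w = int(round(window_min * 60.0 / frame_interval))
    if w < 1 or len(z) <= w:
        return pd.DataFrame(columns=["frame", "velocity_um_min"])
    v = (z[w:] - z[:-w]) / window_min
    return pd.DataFrame({"frame": np.arange(len(v)), "velocity_um_min": v})


def velocity_summary(depth_um, frame_interval, *, window_min: float = 1.0) -> dict:
    """Peak (max |v|) and mean (mean |v|) velocity of one nucleus track."""
    v = nucleus_velocity(depth_um, frame_interval, window_min=window_min)["velocity_um_min"]
    if len(v) == 0:
        return {"peak_um_min": float("nan"), "mean_um_min": float("nan")}
    return {"peak_um_min": float(np.abs(v).max()), "mean_um_min": float(np.abs(v).mean())}


def msd(distance: np.ndarray, taus=None) -> pd.DataFrame:
    """Mean squared displacement of a pairwise-distance trajectory.

    MSD(τ) = 1/(t−τ) · Σ_{k=1}^{t−τ} [d(k+τ) − d(k)]², for τ in frames.
    Upward curvature indicates active transport, linearity diffusion,
    downward curvature constraint; a curvature hint is attached in
    ``DataFrame.attrs["classification"]`` but never asserted.
    """
    d = np.asarray(distance, dtype=float)
    t = len(d)
    if taus is None:
        taus = range(1, t)
    taus = [int(tau) for tau in taus if 0 < tau < t]
    vals = [float(np.mean((d[tau:] - d[:-tau]) ** 2)) for tau in taus]
    out = pd.DataFrame({"tau": taus, "msd": vals})
    if len(out) >= 4:
        mid = len(out) // 2
        early = np.polyfit(out.tau[:mid], out.msd[:mid], 1)[0]
        late = np.polyfit(out.tau[mid:], out.msd[mid:], 1)[0]
        if late > 1.25 * early:
            out.attrs["classification"] = "active (upward curvature)"
        elif late < 0.8 * early:
            out.attrs["classification"] = "constrained (downward curvature)"
        else:
            out.attrs["classification"] = "diffusive (linear)"
    return out


def pair_distances(midplanes: pd.DataFrame, pairs) -> pd.DataFrame:
    """|midplane_i − midplane_j| time series for the given track pairs.

    ``midplanes`` needs columns track, frame, midplane_depth_um; ``pairs``
    is an iterable of (a, b) — conventionally nuclei of edge-adjacent
    cells.
    """
    piv = midplanes.pivot_table(index="frame", columns="track", values="midplane_depth_um")
    rows = []
    for a, b in pairs:
        if a not in piv.columns or b not in piv.columns:
            continue
        d = (piv[a] - piv[b]).abs()
        for f, v in d.items():
            if not np.isnan(v):
                rows.append((a, b, int(f), float(v)))
    return pd.DataFrame(rows, columns=["a", "b", "frame", "distance_um"])


def relative_depth_histogram(pair_dist: pd.DataFrame, bin_um: float = 1.0) -> pd.DataFrame:
    """Probability-normalised histogram of relative midplane distances."""
    d = pair_dist["distance_um"].to_numpy()
    if len(d) == 0:
        return pd.DataFrame(columns=["bin_left_um", "probability"])
    edges = np.arange(0, d.max() + bin_um, bin_um)
    hist, edges = np.histogram(d, bins=edges)
    return pd.DataFrame({"bin_left_um": edges[:-1], "probability": hist / hist.sum()})
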