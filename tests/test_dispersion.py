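"""Midplane rule, packing, velocities and MSD — each checked against an
independent brute-force oracle or closed form."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucleoscope import dispersion as disp


# --- independent oracles -------------------------------------------------

def midplane_oracle(areas):
    """Exhaustive re-derivation of the midplane rule over all planes."""
    areas = list(areas)
    occ = [z for z, a in enumerate(areas) if a > 0]
    zmax = min((z for z in occ if areas[z] == max(areas[o] for o in occ)))
    half = areas[zmax] / 2.0

    def pick(cands):
        if not cands:
            return zmax
        best = min(abs(areas[z] - half) for z in cands)
        tied = [z for z in cands if abs(areas[z] - half) == best]
        return min(tied, key=lambda z: (abs(z - zmax), z))

    lo = pick([z for z in occ if z < zmax])
    hi = pick([z for z in occ if z > zmax])
    return (lo + hi) / 2.0


def msd_oracle(d):
    """Literal double-loop MSD."""
    d = list(d)
    t = len(d)
    out = {}
    for tau in range(1, t):
        acc = 0.0
        for k in range(t - tau):
            acc += (d[k + tau] - d[k]) ** 2
        out[tau] = acc / (t - tau)
    return out


# --- midplane ------------------------------------------------------------

def test_midplane_symmetric_profile_is_central():
    areas = [0, 2, 6, 10, 6, 2, 0]
    mp = disp.find_midplane(areas)
    assert mp.z == 3.0 and not mp.truncated


def test_midplane_top_heavy_profile_matches_exhaustive_search():
    areas = [10, 10, 8, 4, 2]
    mp = disp.find_midplane(areas)
    assert mp.z == midplane_oracle(areas)
    assert mp.truncated  # no plane apical of the maximum


def test_midplane_single_plane():
    mp = disp.find_midplane([0, 0, 5, 0])
    assert mp.z == 2.0 and mp.truncated


@given(
    areas=st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=15).filter(
        lambda a: any(v > 0 for v in a)
    )
)
@settings(deadline=None, max_examples=200)
def test_midplane_rule_equals_exhaustive_search(areas):
    assert disp.find_midplane(areas).z == midplane_oracle(areas)


def test_midplane_empty_profile_raises():
    with pytest.raises(ValueError):
        disp.find_midplane([0, 0, 0])


# --- absolute depth ------------------------------------------------------

def test_absolute_depth_arithmetic():
    assert disp.absolute_depth(12.0, 2.0, 1.0) == 10.0
    assert disp.absolute_depth(5.0, 5.0, 1.0) == 0.0


def test_apical_surface_detection():
    labels = np.zeros((10, 20, 20), dtype=np.int32)
    labels[3:, 2:18, 2:18] = 1
    assert disp.detect_apical_surface(labels) == 3


# --- packing -------------------------------------------------------------

def test_packing_one_when_maxima_coplanar():
    prof = np.array([[0, 5, 10, 5, 0], [0, 3, 6, 3, 0], [1, 2, 4, 2, 1]], dtype=float)
    p = disp.packing_profile(prof)
    assert p[2] == pytest.approx(1.0)
    assert disp.max_packing(prof) == pytest.approx(1.0)
    assert np.all(p <= 1.0) and np.all(p[prof.sum(axis=0) > 0] > 0)


def test_packing_single_nucleus_is_one():
    assert disp.max_packing(np.array([[0, 2, 8, 2]])) == 1.0


def test_packing_offset_ellipsoids_matches_voxel_oracle():
    # two identical voxelised ellipsoids offset in z so they share no
    # plane: max packing 0.5 + residual overlap, via brute-force voxel sums
    zz, yy, xx = np.mgrid[0:30, 0:30, 0:30].astype(float)

    def ellipsoid(zc):
        return (((zz - zc) / 4.0) ** 2 + ((yy - 15) / 8) ** 2 + ((xx - 15) / 8) ** 2) <= 1

    m1, m2 = ellipsoid(7.0), ellipsoid(20.0)
    prof = np.stack([m1.sum(axis=(1, 2)), m2.sum(axis=(1, 2))]).astype(float)
    # oracle: literal sums over voxels
    best = 0.0
    denom = sum(max(m.sum(axis=(1, 2))) for m in (m1, m2))
    for z in range(30):
        best = max(best, (m1[z].sum() + m2[z].sum()) / denom)
    assert disp.max_packing(prof) == pytest.approx(best, rel=1e-12)
    assert best == pytest.approx(0.5, abs=0.01)  # no z-overlap here


def test_packing_empty_cluster_raises():
    with pytest.raises(ValueError):
        disp.packing_profile(np.zeros((2, 5)))


# --- velocity ------------------------------------------------------------

def test_static_nucleus_has_zero_velocity():
    s = disp.velocity_summary(np.full(20, 10.0), 15.0)
    assert s["peak_um_min"] == 0.0 and s["mean_um_min"] == 0.0


def test_triangle_wave_peak_velocity():
    # z(t) triangle wave, slope ±2 µm/min, 2-min legs, 15 s sampling
    t_min = np.arange(0, 12, 0.25)
    z = 10 + 2 * np.abs(((t_min / 2.0) % 2) - 1) * 2.0  # legs of slope ±2
    s = disp.velocity_summary(z, 15.0, window_min=1.0)
    assert s["peak_um_min"] == pytest.approx(2.0, abs=0.1)


def test_velocity_missing_for_short_trajectory():
    s = disp.velocity_summary(np.array([10.0, 10.5]), 15.0, window_min=1.0)
    assert np.isnan(s["peak_um_min"])


# --- MSD -----------------------------------------------------------------

def test_msd_constant_distance_is_zero():
    out = disp.msd(np.full(30, 3.0))
    assert np.allclose(out["msd"], 0.0)


def test_msd_linear_distance_closed_form():
    v = 0.3
    d = v * np.arange(40)
    out = disp.msd(d)
    assert np.allclose(out["msd"], (v * out["tau"]) ** 2)


def test_msd_equals_brute_force_double_loop():
    rng = np.random.default_rng(5)
    for n in (3, 17, 50):
        d = rng.normal(size=n).cumsum()
        out = disp.msd(d).set_index("tau")["msd"]
        oracle = msd_oracle(d)
        for tau, val in oracle.items():
            assert out[tau] == pytest.approx(val, rel=1e-12)


def test_msd_random_walk_is_linear_in_tau():
    # 1D random walk, step σ² = 0.25: MSD(τ) = 0.25·τ within 3 SE over
    # 200 independent pairs
    rng = np.random.default_rng(42)
    sigma2 = 0.25
    taus = [1, 2, 4, 8]
    acc = {tau: [] for tau in taus}
    for _ in range(200):
        d = rng.normal(0, np.sqrt(sigma2), size=60).cumsum()
        out = disp.msd(d, taus=taus).set_index("tau")["msd"]
        for tau in taus:
            acc[tau].append(out[tau])
    for tau in taus:
        mean = np.mean(acc[tau])
        se = np.std(acc[tau], ddof=1) / np.sqrt(len(acc[tau]))
        assert abs(mean - sigma2 * tau) <= 3 * se


def test_msd_excludes_tau_beyond_series():
    out = disp.msd(np.arange(5.0), taus=[1, 2, 7])
    assert set(out["tau"]) == {1, 2}


def test_pair_distances_symmetric_and_nonnegative():
    import pandas as pd

    mid = pd.DataFrame(
        {
            "track": [1, 2, 1, 2],
            "frame": [0, 0, 1, 1],
            "midplane_depth_um": [10.0, 12.5, 11.0, 10.0],
        }
    )
    d12 = disp.pair_distances(mid, [(1, 2)])["distance_um"].to_numpy()
    d21 = disp.pair_distances(mid, [(2, 1)])["distance_um"].to_numpy()
    assert np.allclose(d12, [2.5, 1.0])
    assert np.allclose(d12, d21)
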