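"""Interface-length dynamics, T1 neighbour exchanges and directionality.

Interfaces are straight-line segments between tissue vertices (points
where three or more regions meet); their length is the Euclidean distance
between the two endpoint vertices.  Angles are measured from the DV axis
(image y): θ = 0° is a vertical, DV-aligned interface, θ = ±90° a
horizontal, AP-aligned one.  A T1 event is the collapse of a vertical
interface between cells A and B to a four-cell vertex (T2) followed by
growth of an orthogonal interface between the flanking cells C and D;
signed lengths are positive for the T1 interface and negative for the
extending T3 interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi


def fold_angle(theta_deg: float) -> float:
    """Fold an orientation into (−90°, 90°], measured from the y (DV) axis."""
    t = (theta_deg + 90.0) % 180.0 - 90.0
    return 90.0 if t == -90.0 else t


def extract_vertices(labels: np.ndarray) -> list[tuple[tuple[float, float], frozenset]]:
    """Tissue vertices of a 2D label plane.

    Every 2×2 pixel block containing ≥3 distinct labels (background
    counts) marks a junction corner; adjacent candidate corners are
    clustered and each cluster reported as (centroid (y, x) in pixel
    units, set of labels meeting there).
    """
    lab = np.asarray(labels)
    q = np.stack(
        [lab[:-1, :-1], lab[1:, :-1], lab[:-1, 1:], lab[1:, 1:]], axis=-1
    )
    s = np.sort(q, axis=-1)
    ndistinct = 1 + (np.diff(s, axis=-1) != 0).sum(axis=-1)
    cand = ndistinct >= 3
    cc, n = ndi.label(cand, structure=np.ones((3, 3), dtype=int))
    verts = []
    for i in range(1, n + 1):
        ys, xs = np.where(cc == i)
        members = set()
        for y, x in zip(ys, xs):
            members.update(int(v) for v in q[y, x])
        # corner of block (y, x) sits between pixel centres
        verts.append(((float(ys.mean()) + 0.5, float(xs.mean()) + 0.5), frozenset(members)))
    return verts


def label_adjacency(labels: np.ndarray) -> set[tuple[int, int]]:
    lab = np.asarray(labels)
    pairs = set()
    for s1, s2 in ((lab[:-1, :], lab[1:, :]), (lab[:, :-1], lab[:, 1:])):
        diff = s1 != s2
        a, b = s1[diff], s2[diff]
        sel = (a > 0) & (b > 0)
        for x, y in zip(a[sel].ravel(), b[sel].ravel()):
            pairs.add((int(min(x, y)), int(max(x, y))))
    return pairs


def build_interfaces(labels: np.ndarray, pixel: float, *, t: int | None = None) -> pd.DataFrame:
    """Interface table of one label plane.

    One record per adjacent cell pair (both labels > 0) with endpoint
    vertices, Euclidean length (µm) and angle from the DV axis.  A pair
    whose two endpoint vertices have merged (interface at or past the
    vertex) gets length 0 and NaN angle.
    """
    verts = extract_vertices(labels)
    rows = []
    for a, b in sorted(label_adjacency(labels)):
        vs = [pos for pos, mem in verts if a in mem and b in mem]
        if len(vs) >= 2:
            pts = np.asarray(vs)
            d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            i, j = np.unravel_index(np.argmax(d2), d2.shape)
            (y1, x1), (y2, x2) = pts[i], pts[j]
            length = float(np.hypot(y2 - y1, x2 - x1)) * pixel
            ang = fold_angle(float(np.degrees(np.arctan2(x2 - x1, y2 - y1))))
        elif len(vs) == 1:
            (y1, x1) = (y2, x2) = vs[0]
            length, ang = 0.0, float("nan")
        else:
            continue
        rows.append(
            {
                "a": a,
                "b": b,
                "length_um": length,
                "angle_deg": ang,
                "y1": y1 * pixel,
                "x1": x1 * pixel,
                "y2": y2 * pixel,
                "x2": x2 * pixel,
                "n_vertices": len(vs),
            }
        )
    df = pd.DataFrame(rows)
    if t is not None and len(df):
        df.insert(0, "t", t)
    return df


def interface_series(label_frames: np.ndarray, pixel: float) -> pd.DataFrame:
    """Interface tables of a (t, y, x) label movie, concatenated."""
    parts = [build_interfaces(label_frames[t], pixel, t=t) for t in range(label_frames.shape[0])]
    parts = [p for p in parts if len(p)]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()


@dataclass
class T1Event:
    a: int
    b: int
    c: int
    d: int
    t2_frame: int
    t2_min: float
    rosette: bool = False


def detect_t1(
    series: pd.DataFrame,
    frame_interval: float,
    *,
    collapse_um: float = 0.5,
    min_collapsed_frames: int = 2,
) -> list[T1Event]:
    """Detect neighbour exchanges in a tracked interface series.

    An event fires when a tracked interface stays below ``collapse_um``
    (or loses adjacency) for at least ``min_collapsed_frames`` consecutive
    frames, and a new interface appears between a pair of cells that were
    common neighbours of the collapsing pair.  Vertices where more than
    four cells meet are flagged as rosettes and excluded from T1 rate
    statistics by callers.
    """
    if not len(series):
        return []
    frames = sorted(series["t"].unique())
    by_frame = {f: g for f, g in series.groupby("t")}
    adj = {f: set(zip(g["a"], g["b"])) for f, g in by_frame.items()}
    neigh = {}
    for f, pairs in adj.items():
        m: dict[int, set] = {}
        for x, y in pairs:
            m.setdefault(x, set()).add(y)
            m.setdefault(y, set()).add(x)
        neigh[f] = m
    events = []
    all_pairs = set(zip(series["a"], series["b"]))
    for a, b in sorted(all_pairs):
        lengths = {}
        for f in frames:
            g = by_frame[f]
            row = g[(g["a"] == a) & (g["b"] == b)]
            if len(row):
                lengths[f] = float(row["length_um"].iloc[0])
        present = [f for f in frames if f in lengths]
        if not present or lengths[present[0]] < collapse_um:
            continue  # never open, or born collapsed
        run = 0
        t2 = None
        for f in frames:
            collapsed = (f not in lengths) or (lengths[f] < collapse_um)
            if collapsed and f >= present[0]:
                run += 1
                if run >= min_collapsed_frames:
                    t2 = f - run + 1
                    break
            else:
                run = 0
        if t2 is None:
            continue
        before = max(present[0], t2 - 1)
        common = neigh[before].get(a, set()) & neigh[before].get(b, set())
        common = {c for c in common if c > 0}
        cand = []
        for f in frames:
            if f <= before:
                continue
            for c, d in adj[f]:
                if c in common and d in common and (c, d) not in adj[before]:
                    cand.append((c, d, f))
            if cand:
                break
        if not cand:
            continue
        c, d, f_new = cand[0]
        rosette = len(common) > 2
        # T2 (four-cell vertex) is when the new interface first exists; at
        # slow rates this is later than the collapse-threshold crossing
        t2 = max(t2, int(f_new))
        events.append(
            T1Event(a=a, b=b, c=c, d=d, t2_frame=int(t2),
                    t2_min=t2 * frame_interval / 60.0, rosette=rosette)
        )
    return events


def signed_length_series(series: pd.DataFrame, event: T1Event) -> pd.DataFrame:
    """Signed interface length through a T1: +AB before T2, −CD after."""
    frames = sorted(series["t"].unique())
    rows = []
    for f in frames:
        g = series[series["t"] == f]
        if f < event.t2_frame:
            row = g[(g["a"] == min(event.a, event.b)) & (g["b"] == max(event.a, event.b))]
            val = float(row["length_um"].iloc[0]) if len(row) else 0.0
        else:
            row = g[(g["a"] == min(event.c, event.d)) & (g["b"] == max(event.c, event.d))]
            val = -float(row["length_um"].iloc[0]) if len(row) else 0.0
        rows.append((f, val))
    return pd.DataFrame(rows, columns=["t", "signed_length_um"])


def t1_rate_metrics(
    signed: pd.DataFrame,
    t2_frame: int,
    frame_interval: float,
    *,
    centroid_distance: pd.DataFrame | None = None,
    window_min: float = 10.0,
    endpoint_window_min: float = 1.0,
) -> dict:
    """Interface and extension rates of one T1 event.

    Each rate is (value at ``window_min`` minutes after T2 − value at
    ``window_min`` minutes before T2) / (2·window_min), applied to the
    signed interface length and to the A–B centroid distance when given;
    for a linear schedule this recovers the schedule slope.  Endpoint
    values are means over a ``endpoint_window_min`` window centred on
    T2 ± ``window_min`` to suppress rasterisation jitter.  NaN when an
    endpoint lies outside the series.
    """
    w = window_min * 60.0 / frame_interval
    ew = max(1.0, endpoint_window_min * 60.0 / frame_interval)

    def rate(df: pd.DataFrame, col: str) -> float:
        t = df["t"].to_numpy()
        v = df[col].to_numpy(dtype=float)
        pre = v[np.abs(t - (t2_frame - w)) <= ew / 2.0]
        post = v[np.abs(t - (t2_frame + w)) <= ew / 2.0]
        if len(pre) == 0 or len(post) == 0 or t.min() > t2_frame - w or t.max() < t2_frame + w:
            return float("nan")
        return (post.mean() - pre.mean()) / (2.0 * window_min)

    out = {"interface_rate_um_min": rate(signed, "signed_length_um")}
    if centroid_distance is not None:
        out["extension_rate_um_min"] = rate(centroid_distance, "distance_um")
    return out


def vertical_interface_rate(
    signed: pd.DataFrame,
    t0_min: float,
    t1_min: float,
    frame_interval: float,
    *,
    endpoint_window_min: float = 0.0,
) -> float:
    """(L(t1) − L(t0)) / (t1 − t0) on signed lengths (µm/min).

    Negative values indicate contraction of a vertical interface.  With
    ``endpoint_window_min`` > 0 each endpoint value is the mean over a
    centred window of that many minutes, which suppresses the ±pixel
    rasterisation jitter of vertex positions.
    """
    t_min = signed["t"].to_numpy() * frame_interval / 60.0
    v = signed["signed_length_um"].to_numpy(dtype=float)

    def at(tm: float) -> float:
        if endpoint_window_min > 0:
            sel = np.abs(t_min - tm) <= endpoint_window_min / 2.0
        else:
            sel = np.isclose(t_min, tm, atol=frame_interval / 120.0)
        if not sel.any():
            return float("nan")
        return float(v[sel].mean())

    l0, l1 = at(t0_min), at(t1_min)
    return (l1 - l0) / (t1_min - t0_min)


def interface_rates(series: pd.DataFrame, frame_interval: float) -> pd.DataFrame:
    """Per-interface length-change rate (µm/min) by linear regression."""
    rows = []
    for (a, b), g in series.groupby(["a", "b"]):
        if len(g) < 3:
            continue
        t_min = g["t"].to_numpy() * frame_interval / 60.0
        slope = np.polyfit(t_min, g["length_um"].to_numpy(dtype=float), 1)[0]
        ang = g["angle_deg"].dropna()
        rows.append(
            {
                "a": a,
                "b": b,
                "rate_um_min": float(slope),
                "angle_deg": float(ang.median()) if len(ang) else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def directionality_histogram(
    rates: pd.DataFrame, *, rate_threshold: float = -0.5, bin_deg: float = 15.0
) -> pd.DataFrame:
    """Angle histogram of contractile interfaces (rate ≤ threshold).

    Bins span [−90°, 90°]; an empty selection returns an all-zero
    histogram (with a warning attribute) rather than failing.
    """
    sel = rates[rates["rate_um_min"] <= rate_threshold].dropna(subset=["angle_deg"])
    edges = np.arange(-90.0, 90.0 + bin_deg, bin_deg)
    hist, edges = np.histogram(sel["angle_deg"], bins=edges)
    out = pd.DataFrame(
        {"bin_left_deg": edges[:-1], "bin_right_deg": edges[1:], "count": hist}
    )
    if hist.sum() == 0:
        out.attrs["warning"] = "no interfaces met the contraction threshold"
    return out


def centroid_distance_series(
    label_frames: np.ndarray, a: int, b: int, pixel: float
) -> pd.DataFrame:
    """Centroid separation (µm) of two tracked cells over a label movie."""
    rows = []
    for t in range(label_frames.shape[0]):
        lab = label_frames[t]
        if not ((lab == a).any() and (lab == b).any()):
            continue
        ca = ndi.center_of_mass(lab == a)
        cb = ndi.center_of_mass(lab == b)
        rows.append((t, float(np.hypot(ca[0] - cb[0], ca[1] - cb[1])) * pixel))
    return pd.DataFrame(rows, columns=["t", "distance_um"])
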