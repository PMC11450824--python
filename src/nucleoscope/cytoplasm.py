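"""Average cytoplasmic area (ACA) — an inverse measure of nuclear packing.

For a central cell and its immediate neighbours, evaluate at z* (the
central nucleus's midplane layer) the mean cytoplasmic area of the
neighbours — cell area minus nucleus area, with nucleus area 0 where a
neighbour's nucleus does not intersect z* — divided by the mean cell area
in the cluster.  The ratio approaches 1 when neighbouring nuclei have
dispersed away from z* and falls as nuclei pack into that plane.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dispersion import find_midplane


def aca_ratio(
    cell_areas: dict[int, float],
    nucleus_areas: dict[int, float],
    central: int,
    *,
    include_central_in_mean: bool = True,
) -> float:
    """ACA ratio of one cluster at the central nucleus's midplane layer.

    ``cell_areas`` maps every cluster member (central + neighbours) to its
    cell area at z*; ``nucleus_areas`` maps members to nucleus area at z*
    (members whose nucleus misses z* may be omitted or 0).  The denominator
    averages over the whole cluster by default (``include_central_in_mean``)
    or over neighbours only.
    """
    neighbors = [t for t in cell_areas if t != central]
    if not neighbors:
        return float("nan")
    cyto = [cell_areas[t] - nucleus_areas.get(t, 0.0) for t in neighbors]
    denom_members = list(cell_areas) if include_central_in_mean else neighbors
    denom = np.mean([cell_areas[t] for t in denom_members])
    if denom <= 0:
        return float("nan")
    return float(np.mean(cyto) / denom)


def _round_half_apical(z: float) -> int:
    """Nearest z-layer; half-integer midplanes tie toward the apical layer."""
    return int(np.floor(z + 0.5 - 1e-9))


def aca_table(
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    pixel_area: float,
    *,
    adjacency: set | None = None,
    frame: int = 0,
    exclude_border_clusters: bool = True,
    include_central_in_mean: bool = True,
) -> pd.DataFrame:
    """ACA ratio per central cell on one (z, y, x) frame of labels.

    The cluster is the central cell plus its edge-adjacent neighbours at
    z*; clusters containing a cell that touches the field boundary are
    excluded by default (incomplete neighbourhoods bias the mean).
    """
    from .morphometry import adjacency_pairs

    nz = cell_labels.shape[0]
    tracks = [int(t) for t in np.unique(cell_labels) if t > 0]
    # per-track nucleus area profiles for midplane determination
    rows = []
    for central in tracks:
        prof = np.array(
            [(nucleus_labels[z] == central).sum() * pixel_area for z in range(nz)]
        )
        if prof.max() <= 0:
            continue
        zstar = _round_half_apical(find_midplane(prof).z)
        plane_c, plane_n = cell_labels[zstar], nucleus_labels[zstar]
        pairs = adjacency if adjacency is not None else adjacency_pairs(plane_c)
        neigh = {b for a, b in pairs if a == central} | {a for a, b in pairs if b == central}
        neigh.discard(0)
        if not neigh:
            continue
        if exclude_border_clusters:
            border = set(
                int(v)
                for v in np.unique(
                    np.concatenate(
                        [plane_c[0], plane_c[-1], plane_c[:, 0], plane_c[:, -1]]
                    )
                )
            )
            for s1, s2 in ((plane_c[:-1], plane_c[1:]), (plane_c[:, :-1], plane_c[:, 1:])):
                diff = s1 != s2
                a_, b_ = s1[diff], s2[diff]
                border |= {int(v) for v in np.concatenate([a_[b_ == 0], b_[a_ == 0]])}
            border.discard(0)
            # the central cell needs a complete neighbourhood; neighbours
            # themselves may sit at the field boundary
            if central in border:
                continue
        members = [central] + sorted(neigh)
        cell_areas = {t: float((plane_c == t).sum() * pixel_area) for t in members}
        nuc_areas = {t: float((plane_n == t).sum() * pixel_area) for t in members}
        if any(a <= 0 for a in cell_areas.values()):
            continue
        rows.append(
            {
                "central": central,
                "frame": frame,
                "zstar": zstar,
                "aca_ratio": aca_ratio(
                    cell_areas,
                    nuc_areas,
                    central,
                    include_central_in_mean=include_central_in_mean,
                ),
                "n_neighbors": len(neigh),
            }
        )
    return pd.DataFrame(rows)
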