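"""End-to-end orchestration: simulate → segment → metrics → report.

The pipeline runs each analysis stage on a synthetic embryo (or a
supplied volume), collects every stage's table into a
:class:`RunReport`, and records provenance (config hash, per-table
checksums) so identical configurations yield byte-identical reports.
Time windows and the tissue-extension onset frame live in the
configuration, since onset is defined observationally, not
algorithmically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cytoplasm, dispersion, interfaces, intensity, morphometry, oscillations, segmentation
from .synthetic import DynamicsSpec, EmbryoSpec, MyosinSpec, NucleusSpec, generate_embryo


@dataclass
class RunConfig:
    """Thresholds, channel assignments and analysis windows of one run."""

    membrane_channel: int = 0
    nuclei_channel: int = 1
    myosin_channel: int | None = None
    reference_depth_um: float = 7.0  # sub-apical layer for planar analyses
    gbe_onset_min: float = 0.0
    window_pre: tuple[float, float] = (-5.0, 0.0)
    window_early: tuple[float, float] = (0.0, 10.0)
    window_mid: tuple[float, float] = (15.0, 20.0)
    contraction_threshold: float = -0.5  # µm/min
    vertical_band_deg: float = 15.0
    f0_hz: float = 0.008
    dampening_depth_um: float = -4.0
    velocity_window_min: float = 1.0
    use_ground_truth_labels: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    tables: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    def checksum(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.tables):
            h.update(name.encode())
            h.update(self.tables[name].to_csv(index=False).encode())
        return h.hexdigest()


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved in .report."""

    def __init__(self, stage: str, report: RunReport, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.report = report


def _midplane_table(nucleus_labels: np.ndarray, pixel_area: float, apical_z: int, dz: float,
                    frame_interval: float) -> pd.DataFrame:
    rows = []
    for t in range(nucleus_labels.shape[0]):
        vol = nucleus_labels[t]
        for track in np.unique(vol):
            if track <= 0:
                continue
            prof = (vol == track).reshape(vol.shape[0], -1).sum(axis=1) * pixel_area
            if prof.max() <= 0:
                continue
            mp = dispersion.find_midplane(prof)
            rows.append(
                {
                    "track": int(track),
                    "frame": t,
                    "time_min": t * frame_interval / 60.0,
                    "midplane_z": mp.z,
                    "midplane_depth_um": dispersion.absolute_depth(mp.z, apical_z, dz),
                    "truncated": mp.truncated,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    spec: EmbryoSpec | None = None,
    *,
    nuclei: NucleusSpec | dict | None = None,
    dynamics: DynamicsSpec | None = None,
    myosin: MyosinSpec | None = None,
    volume=None,
    truth=None,
) -> RunReport:
    """Run every stage and return a :class:`RunReport`.

    Either pass an :class:`EmbryoSpec` (with optional nucleus/dynamics/
    myosin specs) to simulate, or a pre-loaded ``volume`` (and optionally
    ground-truth ``truth`` labels, which bypass segmentation when
    ``config.use_ground_truth_labels`` is set).  Deterministic given the
    seeds in the specs and config.
    """
    report = RunReport(tables={}, provenance={"config": asdict(config), "config_digest": config.digest()})
    stage = "simulate"
    try:
        if spec is not None:
            volume, truth = generate_embryo(spec, nuclei, dynamics, myosin)
        if volume is None:
            raise ValueError("need either an EmbryoSpec or a volume")
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, report, e) from e

    dz, dy, dx = volume.voxel_size
    pixel, pix_area = dx, dy * dx
    fi = volume.frame_interval

    stage = "segment"
    try:
        if config.use_ground_truth_labels and truth is not None:
            cell_labels = truth.cell_labels.labels
            nuc_labels = truth.nucleus_labels.labels
        else:
            mem = volume.channel(config.membrane_channel)
            nuc_ch = volume.channel(config.nuclei_channel)
            apz_guess = None
            per_frame_cells, per_frame_nucs, ref_frames = [], [], []
            nz = volume.n_z
            ref_z = nz // 2
            for t in range(volume.n_frames):
                frame = volume.data[t]
                ref = segmentation.segment_cells_seeded(frame, ref_z, membrane_channel=config.membrane_channel, pixel=pixel)
                lab3d, _ = segmentation.propagate_z(ref, frame, ref_z, membrane_channel=config.membrane_channel, pixel=pixel)
                per_frame_cells.append(lab3d)
                ref_frames.append(ref)
            ref_stack = np.stack(ref_frames)
            tracked_ref, _events = segmentation.track_time(ref_stack)
            cell_labels = segmentation.apply_track_map(np.stack(per_frame_cells), ref_stack, tracked_ref)
            nuc_labels = np.stack(
                [
                    segmentation.segment_nuclei(cell_labels[t], nuc_ch[t])
                    for t in range(volume.n_frames)
                ]
            )
        apical_z = dispersion.detect_apical_surface(cell_labels[0])
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, report, e) from e

    stage = "tables"
    try:
        cell_area_tabs = []
        for t in range(cell_labels.shape[0]):
            tab = segmentation.areas_by_z(cell_labels[t], pix_area)
            tab.insert(0, "frame", t)
            cell_area_tabs.append(tab)
        report.tables["cell_areas"] = pd.concat(cell_area_tabs, ignore_index=True)
        nuc_tabs = [
            segmentation.nucleus_table(nuc_labels[t], volume.voxel_size, frame=t)
            for t in range(nuc_labels.shape[0])
        ]
        report.tables["nuclei"] = pd.concat([x for x in nuc_tabs if len(x)], ignore_index=True)
        midplanes = _midplane_table(nuc_labels, pix_area, apical_z, dz, fi)
        report.tables["midplanes"] = midplanes
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, report, e) from e

    ref_plane_z = apical_z + int(round(config.reference_depth_um / dz))

    stage = "morphometry"
    try:
        shape_rows = []
        for t in range(cell_labels.shape[0]):
            for _, r in midplanes[midplanes.frame == t].iterrows():
                zstar = cytoplasm._round_half_apical(r["midplane_z"])
                track = int(r["track"])
                cmask = cell_labels[t, zstar] == track
                nmask = nuc_labels[t, zstar] == track
                if not cmask.any():
                    continue
                ctab = morphometry.region_table(np.where(cmask, track, 0), pixel)
                ratio, flagged = morphometry.nucleus_cell_area_ratio(
                    float(cmask.sum() * pix_area), float(nmask.sum() * pix_area)
                )
                row = ctab.iloc[0].to_dict()
                row.update(
                    frame=t,
                    nucleus_area_um2=float(nmask.sum() * pix_area),
                    nucleus_cell_ratio=ratio,
                    ratio_flag=flagged,
                )
                if nmask.any():
                    prof_mask = nuc_labels[t] == track
                    row["nucleus_length_um"] = segmentation.nucleus_length(prof_mask, dz)
                    row["sphericity"] = morphometry.sphericity(
                        row["nucleus_length_um"], row["nucleus_area_um2"]
                    )
                shape_rows.append(row)
        report.tables["shape_metrics"] = pd.DataFrame(shape_rows)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, report, e) from e

    stage = "dispersion"
    try:
        vel_rows = []
        for track, g in midplanes.groupby("track"):
            g = g.sort_values("frame")
            summ = dispersion.velocity_summary(
                g["midplane_depth_um"].to_numpy(), fi, window_min=config.velocity_window_min
            )
            vel_rows.append({"track": int(track), **summ})
        report.tables["velocities"] = pd.DataFrame(vel_rows)

        adj = morphometry.adjacency_pairs(cell_labels[0, ref_plane_z])
        pairs = sorted(adj)
        pd_series = dispersion.pair_distances(midplanes, pairs)
        report.tables["pair_distances"] = pd_series
        msd_rows = []
        for (a, b), g in pd_series.groupby(["a", "b"]):
            m = dispersion.msd(g.sort_values("frame")["distance_um"].to_numpy())
            m["a"], m["b"] = a, b
            msd_rows.append(m)
        report.tables["msd"] = (
            pd.concat(msd_rows, ignore_index=True) if msd_rows else pd.DataFrame()
        )

        packing_rows = []
        nz = nuc_labels.shape[1]
        for t in range(nuc_labels.shape[0]):
            profs = {}
            for track in np.unique(nuc_labels[t]):
                if track <= 0:
                    continue
                profs[int(track)] = (
                    (nuc_labels[t] == track).reshape(nz, -1).sum(axis=1) * pix_area
                )
            for central in profs:
                neigh = {b for a, b in adj if a == central} | {a for a, b in adj if b == central}
                cluster = [central] + [n for n in sorted(neigh) if n in profs]
                arr = np.stack([profs[c] for c in cluster])
                packing_rows.append(
                    {
                        "central": central,
                        "frame": t,
                        "max_packing": dispersion.max_packing(arr),
                        "n_nuclei": len(cluster),
                    }
                )
        report.tables["packing"] = pd.DataFrame(packing_rows)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, report, e) from e

    stage = "aca"
    try:
        aca_tabs = [
            cytoplasm.aca_table(cell_labels[t], nuc_labels[t], pix_area, frame=t)
            for t in range(cell_labels.shape[0])
        ]
        report.tables["aca"] = pd.concat([x for x in aca_tabs if len(x)], ignore_index=True)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, report, e) from e

    stage = "interfaces"
    try:
        plane_movie = cell_labels[:, ref_plane_z]
        series = interfaces.interface_series(plane_movie, pixel)
        report.tables["interfaces"] = series
        rates = interfaces.interface_rates(series, fi) if len(series) else pd.DataFrame()
        report.tables["interface_rates"] = rates
        if len(rates):
            report.tables["directionality"] = interfaces.directionality_histogram(
                rates, rate_threshold=config.contraction_threshold
            )
        events = interfaces.detect_t1(series, fi) if len(series) else []
        report.tables["t1_events"] = pd.DataFrame(
            [
                {"a": e.a, "b": e.b, "c": e.c, "d": e.d, "t2_frame": e.t2_frame,
                 "t2_min": e.t2_min, "rosette": e.rosette}
                for e in events
            ]
        )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, report, e) from e

    stage = "oscillations"
    try:
        if truth is not None and len(getattr(truth, "area_signals", [])):
            signals = truth.area_signals
        else:
            # measured per-z cell areas aligned to each cell's midplane
            ca = report.tables["cell_areas"].merge(
                midplanes[["track", "frame", "midplane_z"]], on=["track", "frame"], how="inner"
            )
            ca["offset_um"] = (ca["midplane_z"] - ca["z"]) * dz
            signals = ca.rename(columns={})
        omap = oscillations.fft_amplitude_map(signals, fi)
        if len(omap):
            report.tables["oscillation_map"] = omap.reset_index()
            report.provenance["dampening_percent"] = oscillations.dampening_percent(
                omap, config.f0_hz, 0.0, config.dampening_depth_um
            )
        else:
            report.tables["oscillation_map"] = pd.DataFrame()
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, report, e) from e

    stage = "intensity"
    try:
        if config.myosin_channel is not None and volume.data.shape[2] > config.myosin_channel:
            myo = volume.channel(config.myosin_channel)
            tab = intensity.interfacial_intensity(
                cell_labels[0], myo[0], pixel, angle_z=ref_plane_z
            )
            report.tables["interfacial_myosin"] = tab
            report.tables["medial_myosin"] = intensity.medial_intensity(
                cell_labels[0], myo[0], pixel, apical_z=apical_z
            )
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, report, e) from e

    report.provenance["apical_z"] = int(apical_z)
    report.provenance["reference_plane_z"] = int(ref_plane_z)
    report.provenance["checksum"] = report.checksum()
    return report


def write_tables(report: RunReport, out_dir) -> None:
    """Write every report table as CSV plus a provenance JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    with open(out / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, default=str)
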