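"""Batch orchestration of the foam analysis chain over a time series.

A single YAML config per experiment describes the frame range, the output
root and one parameter block per stage.  Every stage writes one artifact
per frame (or per frame pair for tracking/plasticity stages), named
deterministically, plus a JSON manifest recording parameters and per-frame
status.  Frames whose outputs already exist are skipped unless forced, and
a missing input frame is recorded as a per-frame failure without aborting
the batch.  All randomness flows from the seed in the config, so a full
run is bit-reproducible.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contacts as contacts_mod
from . import events as events_mod
from . import fields as fields_mod
from . import io as _io
from . import mechanics as mechanics_mod
from . import process as process_mod
from . import structure as structure_mod
from . import synth as synth_mod
from . import tracking as tracking_mod

log = logging.getLogger("foam3d")

STAGES = (
    "synth",
    "process",
    "structure",
    "contacts",
    "mechanics",
    "track",
    "plasticity",
    "fields",
    "report",
)


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    for key in ("output_root", "frames"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    first, last = cfg["frames"]
    if last < first:
        raise ValueError("frame range must be increasing")
    unknown = set(cfg) - set(STAGES) - {"output_root", "frames", "voxel_size"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return cfg


def _frames(cfg) -> list[int]:
    first, last = cfg["frames"]
    return list(range(first, last + 1))


def _root(cfg) -> Path:
    return Path(cfg["output_root"])


def _outputs_exist(paths) -> bool:
    return all(Path(p).exists() for p in paths)


def _neighbors_to_str(topology: pd.DataFrame) -> pd.DataFrame:
    out = topology.copy()
    out["neighbors"] = [";".join(str(n) for n in t) for t in out["neighbors"]]
    return out


def _str_to_neighbors(topology: pd.DataFrame) -> pd.DataFrame:
    out = topology.copy()
    out["neighbors"] = [
        tuple(int(v) for v in str(s).split(";") if v not in ("", "nan"))
        for s in out["neighbors"].fillna("")
    ]
    return out


def run_stage(stage: str, cfg: dict, force: bool = False) -> dict:
    """Run one pipeline stage; returns (and writes) its manifest."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    entries = _STAGE_FUNCS[stage](cfg, force)
    manifest = {
        "stage": stage,
        "params": cfg.get(stage, {}),
        "frames": cfg["frames"],
        "entries": entries,
    }
    _io.write_json(_root(cfg) / "manifests" / f"{stage}.json", manifest)
    n_fail = sum(1 for e in entries if str(e["status"]).startswith("failed"))
    log.info("stage %s: %d entries, %d failed", stage, len(entries), n_fail)
    return manifest


def run_all(cfg: dict, force: bool = False) -> list[dict]:
    return [run_stage(stage, cfg, force=force) for stage in STAGES]


# --------------------------------------------------------------------------
# stage implementations


def _stage_synth(cfg, force):
    p = dict(cfg["synth"])
    frames = _frames(cfg)
    root = _root(cfg)
    law = p["radius_law"]
    spec = synth_mod.FoamSpec(
        box_shape=tuple(p["box"]),
        n_bubbles=int(p["n_bubbles"]),
        radius_law=(law[0], *[float(v) for v in law[1:]]),
        film_thickness=float(p.get("film_thickness", 1.0)),
        seed=int(p.get("seed", 0)),
        drift=tuple(p.get("drift", (0.0, 0.0, 0.0))),
        arrangement=p.get("arrangement", "random"),
    )
    outputs = {
        i: [
            root / "gray" / f"gray_{i:04d}.tif",
            root / "truth" / f"labels_{i:04d}.tif",
        ]
        for i in frames
    }
    truth_csv = root / "truth" / "truth.csv"
    if not force and _outputs_exist(
        [q for paths in outputs.values() for q in paths] + [truth_csv]
    ):
        return [
            {"frame": i, "outputs": [str(q) for q in outputs[i]], "status": "skipped"}
            for i in frames
        ]
    labels0, _, truth = synth_mod.make_packing(spec)
    seq = synth_mod.deform_sequence(
        labels0, np.eye(3), spec.drift, n_frames=len(frames)
    )
    entries = []
    for k, i in enumerate(frames):
        lab = seq.frames[k]
        phase = (lab == 0).astype(np.uint8)
        gray = synth_mod.render_tomogram(
            phase,
            gas_level=float(p.get("gas_level", 50.0)),
            liquid_level=float(p.get("liquid_level", 200.0)),
            blur_sigma=float(p.get("blur_sigma", 0.7)),
            noise_sigma=float(p.get("noise_sigma", 0.0)),
            seed=(spec.seed + 7919 * k) % 2**31,
        )
        _io.write_volume(outputs[i][0], gray)
        _io.write_volume(outputs[i][1], lab.astype(np.uint16))
        entries.append(
            {"frame": i, "outputs": [str(q) for q in outputs[i]], "status": "written"}
        )
    table = pd.DataFrame(
        {
            "label": truth.labels,
            "z": truth.centroids[:, 0],
            "y": truth.centroids[:, 1],
            "x": truth.centroids[:, 2],
            "radius": truth.radii,
            "V": truth.volumes,
            "R_V": truth.equivalent_radii,
        }
    )
    _io.write_table(truth_csv, table)
    _io.write_table(
        root / "truth" / "adjacency.csv",
        pd.DataFrame(sorted(truth.adjacency), columns=["label_p", "label_q"]),
    )
    return entries


def _stage_process(cfg, force):
    p = dict(cfg.get("process", {}))
    root = _root(cfg)
    entries = []
    for i in _frames(cfg):
        src = root / "gray" / f"gray_{i:04d}.tif"
        outs = [root / "phase" / f"phase_{i:04d}.tif", root / "labels" / f"labels_{i:04d}.tif"]
        if not force and _outputs_exist(outs):
            entries.append({"frame": i, "outputs": [str(q) for q in outs], "status": "skipped"})
            continue
        if not src.exists():
            entries.append({"frame": i, "outputs": [], "status": f"failed: missing input {src}"})
            continue
        vol = _io.read_volume(src)
        phase, labels = process_mod.process_chain(
            vol,
            background_scale=float(p.get("background_scale", 0.0)),
            method=p.get("method", "otsu"),
            threshold=p.get("threshold"),
            liquid_high=bool(p.get("liquid_high", True)),
            min_size_liquid=int(p.get("min_size_liquid", 0)),
            min_size_gas=int(p.get("min_size_gas", 0)),
            h=float(p.get("h", 2.0)),
            min_volume=int(p.get("min_volume", 0)),
        )
        _io.write_volume(outs[0], phase)
        _io.write_volume(outs[1], labels.astype(np.uint16))
        entries.append({"frame": i, "outputs": [str(q) for q in outs], "status": "written"})
    return entries


def _stage_structure(cfg, force):
    p = dict(cfg.get("structure", {}))
    root = _root(cfg)
    entries = []
    lf_rows = []
    lf_csv = root / "structure" / "liquid_fraction.csv"
    for i in _frames(cfg):
        phase_p = root / "phase" / f"phase_{i:04d}.tif"
        labels_p = root / "labels" / f"labels_{i:04d}.tif"
        out = root / "structure" / f"regions_{i:04d}.csv"
        if not force and _outputs_exist([out, lf_csv]):
            entries.append({"frame": i, "outputs": [str(out)], "status": "skipped"})
            continue
        if not (phase_p.exists() and labels_p.exists()):
            entries.append({"frame": i, "outputs": [], "status": "failed: missing input"})
            continue
        phase = _io.read_volume(phase_p)
        labels = _io.read_volume(labels_p).astype(np.int32)
        regions = structure_mod.region_properties(labels)
        _io.write_table(out, regions)
        lf_rows.append({"frame": i, "phi_liquid": structure_mod.liquid_fraction(phase)})
        entries.append({"frame": i, "outputs": [str(out)], "status": "written"})
    if lf_rows:
        _io.write_table(lf_csv, pd.DataFrame(lf_rows))
    if lf_rows:
        entries.append({"frame": None, "outputs": [str(lf_csv)], "status": "written"})
    return entries


def _stage_contacts(cfg, force):
    p = dict(cfg.get("contacts", {}))
    root = _root(cfg)
    entries = []
    for i in _frames(cfg):
        labels_p = root / "labels" / f"labels_{i:04d}.tif"
        outs = [
            root / "contacts" / f"topology_{i:04d}.csv",
            root / "contacts" / f"pairs_{i:04d}.csv",
            root / "contacts" / f"films_{i:04d}.csv",
            root / "contacts" / f"contact_labels_{i:04d}.tif",
        ]
        if not force and _outputs_exist(outs):
            entries.append({"frame": i, "outputs": [str(q) for q in outs], "status": "skipped"})
            continue
        if not labels_p.exists():
            entries.append({"frame": i, "outputs": [], "status": "failed: missing input"})
            continue
        labels = _io.read_volume(labels_p).astype(np.int32)
        net = contacts_mod.get_contacts(labels, dilation=int(p.get("dilation", 1)))
        films = contacts_mod.contact_properties(net)
        _io.write_table(outs[0], _neighbors_to_str(net.topology))
        _io.write_table(outs[1], net.pairs)
        _io.write_table(outs[2], films)
        _io.write_volume(outs[3], net.contact_labels.astype(np.uint16))
        entries.append({"frame": i, "outputs": [str(q) for q in outs], "status": "written"})
    return entries


def _stage_mechanics(cfg, force):
    p = dict(cfg.get("mechanics", {}))
    gamma = float(p.get("gamma", 1.0))
    voxel_size = float(cfg.get("voxel_size", 1.0))
    root = _root(cfg)
    _io.write_json(
        root / "mechanics" / "meta.json",
        {"gamma": gamma, "voxel_size": voxel_size},
    )
    entries = []
    for i in _frames(cfg):
        labels_p = root / "labels" / f"labels_{i:04d}.tif"
        regions_p = root / "structure" / f"regions_{i:04d}.csv"
        topo_p = root / "contacts" / f"topology_{i:04d}.csv"
        outs = [
            root / "mechanics" / f"texture_{i:04d}.csv",
            root / "mechanics" / f"stress_{i:04d}.csv",
        ]
        if not force and _outputs_exist(outs):
            entries.append({"frame": i, "outputs": [str(q) for q in outs], "status": "skipped"})
            continue
        if not (labels_p.exists() and regions_p.exists() and topo_p.exists()):
            entries.append({"frame": i, "outputs": [], "status": "failed: missing input"})
            continue
        labels = _io.read_volume(labels_p).astype(np.int32)
        regions = _io.read_table(regions_p)
        topology = _str_to_neighbors(_io.read_table(topo_p))
        _io.write_table(outs[0], mechanics_mod.texture_table(regions, topology))
        _io.write_table(
            outs[1],
            mechanics_mod.stress_table(labels, gamma=gamma, voxel_size=voxel_size),
        )
        entries.append({"frame": i, "outputs": [str(q) for q in outs], "status": "written"})
    return entries


def _stage_track(cfg, force):
    p = dict(cfg.get("track", {}))
    root = _root(cfg)
    frames = _frames(cfg)
    entries = []
    tables = []
    traj_csv = root / "track" / "trajectories.csv"
    for i in frames[:-1]:
        r0 = root / "structure" / f"regions_{i:04d}.csv"
        r1 = root / "structure" / f"regions_{i + 1:04d}.csv"
        out = root / "track" / f"track_{i:04d}.csv"
        if not force and out.exists():
            tables.append(_io.read_table(out))
            entries.append({"frame": i, "outputs": [str(out)], "status": "skipped"})
            continue
        if not (r0.exists() and r1.exists()):
            entries.append({"frame": i, "outputs": [], "status": "failed: missing input"})
            tables.append(None)
            continue
        tracks = tracking_mod.track_labels(
            _io.read_table(r0),
            _io.read_table(r1),
            search_radius=p.get("search_radius"),
            vol_tol=float(p.get("vol_tol", 0.3)),
        )
        _io.write_table(out, tracks)
        tables.append(tracks)
        entries.append({"frame": i, "outputs": [str(out)], "status": "written"})
    if tables and all(t is not None for t in tables):
        traj = tracking_mod.combine_tracking(tables, frames=frames)
        _io.write_table(traj_csv, traj)
        entries.append({"frame": None, "outputs": [str(traj_csv)], "status": "written"})
    return entries


def _stage_plasticity(cfg, force):
    root = _root(cfg)
    frames = _frames(cfg)
    entries = []
    for i in frames[:-1]:
        pairs0_p = root / "contacts" / f"pairs_{i:04d}.csv"
        pairs1_p = root / "contacts" / f"pairs_{i + 1:04d}.csv"
        topo0_p = root / "contacts" / f"topology_{i:04d}.csv"
        topo1_p = root / "contacts" / f"topology_{i + 1:04d}.csv"
        track_p = root / "track" / f"track_{i:04d}.csv"
        regions1_p = root / "structure" / f"regions_{i + 1:04d}.csv"
        outs = [
            root / "plasticity" / f"translated_{i:04d}.csv",
            root / "plasticity" / f"lostnew_{i:04d}.csv",
            root / "plasticity" / f"t1_{i:04d}.csv",
        ]
        if not force and _outputs_exist(outs):
            entries.append({"frame": i, "outputs": [str(q) for q in outs], "status": "skipped"})
            continue
        needed = [pairs0_p, pairs1_p, topo0_p, topo1_p, track_p, regions1_p]
        if not all(q.exists() for q in needed):
            entries.append({"frame": i, "outputs": [], "status": "failed: missing input"})
            continue
        tracks = _io.read_table(track_p)
        pairs0 = _io.read_table(pairs0_p)
        pairs1 = _io.read_table(pairs1_p)
        translated = events_mod.translate_pairs(pairs0, tracks)
        L, N = events_mod.lost_new(translated, pairs1)
        mapping = tracking_mod.match_dict(tracks)
        topo0 = contacts_mod.topology_dict(_str_to_neighbors(_io.read_table(topo0_p)))
        topo1 = contacts_mod.topology_dict(_str_to_neighbors(_io.read_table(topo1_p)))
        topo0_t1 = {
            mapping[lab]: {mapping[n] for n in nbrs if n in mapping}
            for lab, nbrs in topo0.items()
            if lab in mapping
        }
        t1s, other = events_mod.detect_t1(L, N, topo0_t1, topo1)
        ln_rows = [{"kind": "lost", "label_p": a, "label_q": b} for a, b in sorted(L)]
        ln_rows += [{"kind": "new", "label_p": a, "label_q": b} for a, b in sorted(N)]
        _io.write_table(outs[0], translated)
        _io.write_table(outs[1], pd.DataFrame(ln_rows, columns=["kind", "label_p", "label_q"]))
        _io.write_table(
            outs[2], events_mod.t1_table(t1s, _io.read_table(regions1_p), frame=i)
        )
        entries.append({"frame": i, "outputs": [str(q) for q in outs], "status": "written"})
    return entries


def _stage_fields(cfg, force):
    p = dict(cfg.get("fields", {}))
    cell = tuple(p.get("grid_cell", (32, 32, 32)))
    root = _root(cfg)
    entries = []
    for i in _frames(cfg):
        phase_p = root / "phase" / f"phase_{i:04d}.tif"
        regions_p = root / "structure" / f"regions_{i:04d}.csv"
        outs = [
            root / "fields" / f"liquid_fraction_grid_{i:04d}.csv",
            root / "fields" / f"regions_cyl_{i:04d}.csv",
        ]
        if not force and _outputs_exist(outs):
            entries.append({"frame": i, "outputs": [str(q) for q in outs], "status": "skipped"})
            continue
        if not (phase_p.exists() and regions_p.exists()):
            entries.append({"frame": i, "outputs": [], "status": "failed: missing input"})
            continue
        phase = _io.read_volume(phase_p)
        grid = structure_mod.GridSpec(cell_shape=cell, extent=phase.shape)
        gf = structure_mod.liquid_fraction(phase, grid=grid)
        rows = []
        for idx in np.ndindex(*gf.values.shape):
            rows.append(
                {
                    "cz": idx[0], "cy": idx[1], "cx": idx[2],
                    "phi_liquid": gf.values[idx],
                    "count": int(gf.counts[idx]),
                    "full_cell": bool(gf.full[idx]),
                }
            )
        _io.write_table(outs[0], pd.DataFrame(rows))
        regions = _io.read_table(regions_p)
        pts = regions[["z", "y", "x"]].to_numpy(float)
        origin = (0.0, phase.shape[1] / 2.0, phase.shape[2] / 2.0)
        conv = fields_mod.to_cylindrical(pts, origin=origin)
        cyl = regions[["label"]].copy()
        cyl[["r", "theta", "z_cyl"]] = conv["points"]
        _io.write_table(outs[1], cyl)
        entries.append({"frame": i, "outputs": [str(q) for q in outs], "status": "written"})
    return entries


def _stage_report(cfg, force):
    import imageio.v3 as iio

    root = _root(cfg)
    entries = []
    summary = {"frames": {}}
    for i in _frames(cfg):
        gray_p = root / "gray" / f"gray_{i:04d}.tif"
        labels_p = root / "labels" / f"labels_{i:04d}.tif"
        out = root / "report" / f"slices_{i:04d}.png"
        if not force and out.exists():
            entries.append({"frame": i, "outputs": [str(out)], "status": "skipped"})
            continue
        if not (gray_p.exists() and labels_p.exists()):
            entries.append({"frame": i, "outputs": [], "status": "failed: missing input"})
            continue
        gray = _io.read_volume(gray_p)
        labels = _io.read_volume(labels_p)
        z = gray.shape[0] // 2
        g = gray[z].astype(float)
        g8 = np.zeros_like(g, dtype=np.uint8) if np.ptp(g) == 0 else (
            (g - g.min()) / np.ptp(g) * 255
        ).astype(np.uint8)
        lab = labels[z].astype(np.int64)
        rng_colors = np.random.default_rng(0).integers(
            60, 255, size=(int(labels.max()) + 1, 3), dtype=np.uint8
        )
        rng_colors[0] = 0
        panel = np.concatenate(
            [np.stack([g8] * 3, axis=-1), rng_colors[lab]], axis=1
        )
        out.parent.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out, panel)
        summary["frames"][str(i)] = {
            "n_bubbles": int(len(np.unique(labels)) - 1),
        }
        entries.append({"frame": i, "outputs": [str(out)], "status": "written"})
    _io.write_json(root / "report" / "summary.json", summary)
    return entries


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "process": _stage_process,
    "structure": _stage_structure,
    "contacts": _stage_contacts,
    "mechanics": _stage_mechanics,
    "track": _stage_track,
    "plasticity": _stage_plasticity,
    "fields": _stage_fields,
    "report": _stage_report,
}
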