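"""Config-driven orchestration of the analysis stages, with run manifests.

A run is described by a single JSON config: an ordered stage list, per-stage
parameter blocks, input paths, an output directory and a seed.  The manifest
(JSON, written into the output directory before the first stage and
finalized after the last) records every resolved parameter, input checksum,
the package version, seeds and timestamps, so a run can be reproduced
exactly from its manifest.

Exit codes: 0 success, 2 validation error, 3 runtime error, 4 I/O error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, contacts, coupling, geomdyn, mutscan, structio, synthdata

log = logging.getLogger("fwdyn")

STAGES = ("simulate", "scan", "dynamics", "contacts", "coupling")

EXIT_OK, EXIT_VALIDATION, EXIT_RUNTIME, EXIT_IO = 0, 2, 3, 4


class ConfigError(ValueError):
    """Raised when a run configuration does not validate."""


@dataclass
class RunConfig:
    stages: list[str]
    output_dir: Path
    seed: int = 0
    inputs: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    _KNOWN_KEYS = {"stages", "output_dir", "seed", "inputs", "params"}

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        errors = []
        unknown = set(raw) - cls._KNOWN_KEYS
        for k in sorted(unknown):
            errors.append(f"unknown config key: {k!r}")
        stages = raw.get("stages", [])
        for s in stages:
            if s not in STAGES:
                errors.append(f"unknown stage: {s!r} (choose from {STAGES})")
        if not stages:
            errors.append("config must list at least one stage")
        if "output_dir" not in raw:
            errors.append("config must set output_dir")
        for key, path in raw.get("inputs", {}).items():
            if not Path(path).exists():
                errors.append(f"input {key!r}: file not found: {path}")
        for stage in raw.get("params", {}):
            if stage not in STAGES:
                errors.append(f"params given for unknown stage: {stage!r}")
        if errors:
            raise ConfigError("; ".join(errors))
        return cls(
            stages=list(stages),
            output_dir=Path(raw["output_dir"]),
            seed=int(raw.get("seed", 0)),
            inputs={k: Path(v) for k, v in raw.get("inputs", {}).items()},
            params=dict(raw.get("params", {})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _default_criteria(params: dict) -> contacts.GeomCriteria:
    allowed = set(contacts.GeomCriteria().__dict__)
    return contacts.GeomCriteria(**{k: v for k, v in params.items() if k in allowed})


# --- stage implementations ----------------------------------------------


def _stage_simulate(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params.get("simulate", {})
    spec = synthdata.ToyComplexSpec(
        n_res=int(p.get("n_res", 12)),
        n_antigen=int(p.get("n_antigen", 10)),
        drift=float(p.get("drift", 0.0)),
        F=int(p.get("frames", 100)),
        jitter=float(p.get("jitter", 0.1)),
        placed_motifs=p.get("placed_motifs", []),
        seed=cfg.seed,
    )
    ref, traj, sels, gt = synthdata.gen_toy_complex(spec)
    structio.write_structure(ref, outdir / "toy_reference.pdb")
    structio.write_structure(traj, outdir / "toy_trajectory.pdb")
    rows = []
    for name, sel in sels.items():
        for chain, start, end in _selection_ranges(traj.topology, sel):
            rows.append(dict(name=name, chain_id=chain, start=start, end=end, atoms="all"))
    structio.write_table(pd.DataFrame(rows), outdir / "selections.tsv")

    cspec = synthdata.CouplingSpec(
        n_fragments=int(p.get("n_fragments", 10)),
        M=int(p.get("n_states", 4)),
        F=int(p.get("coupling_frames", 2000)),
        replicas=int(p.get("replicas", 3)),
        coupled_pairs=[tuple(x) for x in p.get("coupled_pairs", [])],
        seed=cfg.seed,
    )
    ens, cgt = synthdata.gen_state_sequences(cspec)
    rows = []
    for cond, reps in ens.items():
        for r, seqs in enumerate(reps):
            for s in seqs:
                for f, state in enumerate(s.states):
                    rows.append(dict(condition=cond, replica=r, fragment=s.fragment_index,
                                     frame=f, state=int(state)))
    structio.write_table(pd.DataFrame(rows), outdir / "state_sequences.tsv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump({"toy_complex": gt, "coupling": cgt}, fh, indent=1)
    return {"toy_complex": str(outdir / "toy_trajectory.pdb"),
            "state_sequences": str(outdir / "state_sequences.tsv")}


def _selection_ranges(topology, sel):
    """Collapse a selection into per-chain contiguous residue ranges."""
    per_chain: dict[str, set[int]] = {}
    for i in sel.indices:
        a = topology[i]
        per_chain.setdefault(a.chain_id, set()).add(a.residue_index)
    out = []
    for chain, resids in sorted(per_chain.items()):
        ordered = sorted(resids)
        start = prev = ordered[0]
        for r in ordered[1:]:
            if r != prev + 1:
                out.append((chain, start, prev))
                start = r
            prev = r
        out.append((chain, start, prev))
    return out


def _stage_scan(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params.get("scan", {})
    region_map = (
        structio.load_region_map(cfg.inputs["region_map"])
        if "region_map" in cfg.inputs
        else None
    )
    if "fasta" in cfg.inputs:
        sequences = structio.read_fasta(cfg.inputs["fasta"])
    else:
        raise ConfigError("scan stage requires inputs.fasta")
    bias = {k: float(v) for k, v in p.get("wt_bias_by_region", {"FW1": 6, "FW2": 6, "FW3": 6, "FW4": 6}).items()}
    profiles = []
    for name, seqstr in sequences.items():
        chain_id = p.get("chain_id", "H")
        seq = structio.ChainSequence(chain_id, list(enumerate(seqstr, start=1)))
        scorer, _ = synthdata.gen_mutation_scores(seq, region_map, bias, seed=cfg.seed)
        grid = mutscan.scan_positions(seq, scorer)
        result = mutscan.wt_rank_profile(grid, region_map)
        out = result.table.copy()
        out.insert(0, "antibody", name)
        profiles.append(out)
        structio.write_table(
            pd.DataFrame(grid.scores, columns=list(mutscan.AA_ORDER)),
            outdir / f"grid_{name}.tsv",
        )
    combined = pd.concat(profiles, ignore_index=True)
    structio.write_table(combined, outdir / "wt_rank_profiles.tsv")
    return {"wt_rank_profiles": str(outdir / "wt_rank_profiles.tsv")}


def _resolve_traj(cfg: RunConfig, outdir: Path):
    path = cfg.inputs.get("trajectory", outdir / "toy_trajectory.pdb")
    obj = structio.read_structure(path, model_index="all")
    if isinstance(obj, structio.Structure):
        obj = structio.Trajectory(obj.atoms, obj.coords[None])
    sel_path = cfg.inputs.get("selections", outdir / "selections.tsv")
    sels = geomdyn.load_selections(sel_path, obj.topology)
    return obj, sels


def _stage_dynamics(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params.get("dynamics", {})
    traj, sels = _resolve_traj(cfg, outdir)
    outputs = {}
    series = []
    if "CDR" in sels and "AG" in sels:
        series.append(geomdyn.com_distance_series(traj, sels["CDR"], sels["AG"]))
    if {"CDRL", "VL", "VH"} <= set(sels):
        series.append(geomdyn.vh_vl_angle_series(traj, sels["CDRL"], sels["VL"], sels["VH"]))
    if {"VH", "VL"} <= set(sels):
        series.append(geomdyn.vh_vl_distance_series(traj, sels["VH"], sels["VL"]))
    ref_path = cfg.inputs.get("reference")
    if ref_path:
        ref = structio.read_structure(ref_path, model_index=1)
        all_sel = geomdyn.ComSelection("all", np.arange(traj.n_atoms))
        series.append(geomdyn.rmsd_series(traj, ref, all_sel))
        ncon = geomdyn.native_contacts(ref, cutoff=float(p.get("contact_cutoff", 4.5)),
                                       exclusion=int(p.get("contact_exclusion", 3)))
        retention = geomdyn.contact_retention(traj, ncon,
                                              tolerance_factor=float(p.get("tolerance_factor", 1.2)))
        structio.write_table(retention, outdir / "contact_retention.tsv")
        outputs["contact_retention"] = str(outdir / "contact_retention.tsv")
    for s in series:
        fname = outdir / f"{s.name.replace(':', '_')}.tsv"
        structio.write_table(
            pd.DataFrame({"frame_time_ps": s.frame_times, "value": s.values, "unit": s.unit}),
            fname,
        )
        outputs[s.name] = str(fname)
        if s.name.startswith("com_distance") and len(s) > 20:
            call = geomdyn.detect_unbinding(
                s,
                baseline_window=int(p.get("baseline_window", max(2, len(s) // 20))),
                factor=float(p.get("unbinding_factor", 1.5)),
                persistence=float(p.get("persistence", 0.1)),
            )
            with open(outdir / "unbinding.json", "w") as fh:
                json.dump(
                    dict(flag=call.flag, onset_frame=call.onset_frame,
                         baseline=call.baseline, threshold=call.threshold),
                    fh, indent=1,
                )
            outputs["unbinding"] = str(outdir / "unbinding.json")
    return outputs


def _auto_rings(traj) -> list[contacts.RingDefinition]:
    ring_names = ("CG0", "CG1", "CG2", "CG3", "CG4", "CG5")
    found: dict[tuple[str, int], set[str]] = {}
    for a in traj.topology:
        if a.atom_name in ring_names:
            found.setdefault((a.chain_id, a.residue_index), set()).add(a.atom_name)
    return [
        contacts.RingDefinition(resid, chain, tuple(sorted(names)))
        for (chain, resid), names in sorted(found.items())
        if len(names) >= 5
    ]


def _stage_contacts(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params.get("contacts", {})
    traj, _ = _resolve_traj(cfg, outdir)
    criteria = _default_criteria(p)
    rings = _auto_rings(traj)
    events: list[contacts.InteractionEvent] = []
    if rings and len(rings) >= 2:
        events += contacts.detect_pipi(traj, rings, criteria)
    if rings:
        events += contacts.detect_xh_ring(traj, rings, criteria, X="C")
        events += contacts.detect_xh_ring(traj, rings, criteria, X="N")
    try:
        events += contacts.detect_hbonds(traj, criteria)
    except ValueError:
        log.warning("no donor hydrogens resolvable; skipping H-bond detection")
    ev_df = pd.DataFrame([e.__dict__ for e in events])
    structio.write_table(ev_df, outdir / "interaction_events.tsv")
    net = contacts.build_network(events, F=traj.n_frames,
                                 min_frequency=float(p.get("min_frequency", 0.1)))
    structio.write_table(net.edges, outdir / "interaction_network.tsv")
    return {"events": str(outdir / "interaction_events.tsv"),
            "network": str(outdir / "interaction_network.tsv")}


def _load_state_sequences(path: Path):
    df = structio.read_table(path)
    ens: dict[str, list[list[coupling.StateSequence]]] = {}
    for cond, cgrp in df.groupby("condition"):
        reps = []
        for _, rgrp in cgrp.groupby("replica"):
            seqs = []
            for frag, fgrp in rgrp.groupby("fragment"):
                fgrp = fgrp.sort_values("frame")
                seqs.append(
                    coupling.StateSequence(
                        fragment_index=int(frag),
                        states=fgrp["state"].to_numpy(dtype=int),
                        n_states=int(df["state"].max()),
                    )
                )
            reps.append(seqs)
        ens[str(cond)] = reps
    return ens


def _stage_coupling(cfg: RunConfig, outdir: Path) -> dict:
    p = cfg.params.get("coupling", {})
    path = cfg.inputs.get("state_sequences", outdir / "state_sequences.tsv")
    ens = _load_state_sequences(Path(path))
    if not {"bound", "unbound"} <= set(ens):
        raise ConfigError("state sequences must cover both 'bound' and 'unbound' conditions")
    window = float(p.get("window", 0.5))
    correction = p.get("correction", "analytic")
    mats = {
        cond: [coupling.mi_matrix(rep, frame_window=window, correction=correction,
                                  seed=cfg.seed) for rep in reps]
        for cond, reps in ens.items()
    }
    dc = coupling.diff_coupling(
        mats["bound"], mats["unbound"],
        pseudocount=float(p.get("pseudocount", 1e-6)),
        test=p.get("test", "permutation"),
        seed=cfg.seed,
    )
    structio.write_table(dc.table, outdir / "diff_coupling.tsv")
    hubs = coupling.call_hubs(dc, lfc_threshold=float(p.get("lfc", 2.0)),
                              alpha=float(p.get("alpha", 0.01)))
    structio.write_table(hubs.pairs, outdir / "hub_table.tsv")
    n_frag = max(m.fragments[-1] for m in mats["bound"])
    freq = coupling.position_hub_frequency(hubs, L=n_frag + 3)
    structio.write_table(
        pd.DataFrame({"residue": np.arange(1, len(freq) + 1), "hub_count": freq}),
        outdir / "hub_frequency.tsv",
    )
    return {"diff_coupling": str(outdir / "diff_coupling.tsv"),
            "hub_table": str(outdir / "hub_table.tsv"),
            "hub_frequency": str(outdir / "hub_frequency.tsv")}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "dynamics": _stage_dynamics,
    "contacts": _stage_contacts,
    "coupling": _stage_coupling,
}


def run_pipeline(config: RunConfig) -> int:
    """Execute the configured stages in order; returns a process exit code.

    The manifest is written before the first stage and finalized after the
    last; a failing stage aborts with a partial manifest and a nonzero
    status.
    """
    try:
        outdir = config.output_dir
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        log.error("cannot create output directory: %s", exc)
        return EXIT_IO
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stages": config.stages,
        "params": config.params,
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in config.inputs.items()},
        "defaults": {
            "geom_criteria": contacts.GeomCriteria().to_dict(),
            "coupling": dict(window=0.5, correction="analytic", pseudocount=1e-6,
                             test="permutation", lfc=2.0, alpha=0.01),
            "dynamics": dict(contact_cutoff=4.5, contact_exclusion=3,
                             tolerance_factor=1.2, unbinding_factor=1.5, persistence=0.1),
        },
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "status": "running",
        "stage_outputs": {},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    for stage in config.stages:
        t0 = time.time()
        log.info("stage %s: starting", stage)
        try:
            outputs = _STAGE_FUNCS[stage](config, outdir)
        except ConfigError as exc:
            log.error("stage %s: validation error: %s", stage, exc)
            manifest["status"] = f"failed:{stage}"
            with open(manifest_path, "w") as fh:
                json.dump(manifest, fh, indent=1)
            return EXIT_VALIDATION
        except OSError as exc:
            log.error("stage %s: I/O error: %s", stage, exc)
            manifest["status"] = f"failed:{stage}"
            with open(manifest_path, "w") as fh:
                json.dump(manifest, fh, indent=1)
            return EXIT_IO
        except Exception as exc:
            log.error("stage %s: %s", stage, exc)
            manifest["status"] = f"failed:{stage}"
            with open(manifest_path, "w") as fh:
                json.dump(manifest, fh, indent=1)
            return EXIT_RUNTIME
        manifest["stage_outputs"][stage] = outputs
        log.info("stage %s: done in %.2f s", stage, time.time() - t0)
    manifest["status"] = "ok"
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return EXIT_OK
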