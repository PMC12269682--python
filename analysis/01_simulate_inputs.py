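#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes, under results/inputs/: a bound antibody–antigen toy complex (stable)
and a destabilised variant whose antigen drifts away (emulating an unbinding
event), bound/unbound fragment-state ensembles with one injected
bound-favoured backbone coupling, a mock repertoire, and a region map.
"""

import json
from pathlib import Path

import pandas as pd

from fwdyn import structio, synthdata

OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 2026

# the stable complex keeps its stacking/H-bond motifs; the destabilised
# variant loses both (the ring pair pulled apart, the H-bond stretched)
# and its antigen drifts away
VARIANTS = {
    "wt_bound": dict(drift=0.0, motifs=[
        {"kind": "ring_pair", "distance": 4.0, "angle": 10.0},
        {"kind": "hbond", "distance": 2.0, "angle": 170.0}]),
    "mutant_unbinding": dict(drift=0.2, motifs=[
        {"kind": "ring_pair", "distance": 7.0, "angle": 10.0},
        {"kind": "hbond", "distance": 3.4, "angle": 170.0}]),
}

for name, v in VARIANTS.items():
    spec = synthdata.ToyComplexSpec(F=200, drift=v["drift"], jitter=0.1,
                                    placed_motifs=v["motifs"], seed=SEED)
    ref, traj, sels, gt = synthdata.gen_toy_complex(spec)
    structio.write_structure(ref, OUT / f"{name}_reference.pdb")
    structio.write_structure(traj, OUT / f"{name}_trajectory.pdb")
    with open(OUT / f"{name}_ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1)
    print(f"{name}: {traj.n_frames} frames, drift {v['drift']} Å/frame, "
          f"frame-0 CDR–antigen distance {gt['com_distance_frame0']:.2f} Å")

# bound/unbound fragment-state ensembles with one injected coupling
s_b = synthdata.strength_for_nmi(0.4, 4)
s_u = synthdata.strength_for_nmi(0.05, 4)
cspec = synthdata.CouplingSpec(
    n_fragments=10, M=4, F=2000, replicas=3,
    coupled_pairs=[(2, 7, "bound", s_b), (2, 7, "unbound", s_u)], seed=SEED,
)
ens, cgt = synthdata.gen_state_sequences(cspec)
rows = []
for cond, reps in ens.items():
    for r, seqs in enumerate(reps):
        for s in seqs:
            for f, state in enumerate(s.states):
                rows.append(dict(condition=cond, replica=r,
                                 fragment=s.fragment_index, frame=f, state=int(state)))
structio.write_table(pd.DataFrame(rows), OUT / "state_sequences.tsv")
with open(OUT / "coupling_ground_truth.json", "w") as fh:
    json.dump(cgt, fh, indent=1)
print(f"state sequences: fragments 2–7 coupled, analytic log2FC "
      f"= log2(0.4/0.05) = 3.0, {cspec.replicas} replicas x {cspec.F} frames")

# repertoire for the occurrence filter
profile, fasta = synthdata.gen_repertoire(
    120, 2000,
    {40: {"R": 0.04, "A": 0.9}, 43: {"D": 0.06, "K": 0.9},
     85: {"N": 0.05, "S": 0.9}, 87: {"T": 0.08, "R": 0.9},
     50: {"S": 0.002, "R": 0.99}, 59: {"N": 0.03, "R": 0.9}},
    seed=SEED,
)
structio.write_table(profile.df, OUT / "repertoire_profile.tsv")
structio.write_fasta(fasta, OUT / "repertoire.fasta")
print(f"repertoire: {len(fasta)} sequences over 120 positions")

# heavy-chain region map
bounds = [("FW1", 1, 25), ("CDR1", 26, 33), ("FW2", 34, 50), ("CDR2", 51, 58),
          ("FW3", 59, 96), ("CDR3", 97, 110), ("FW4", 111, 120)]
pd.DataFrame(
    [dict(chain_id="H", region=r, start=s, end=e) for r, s, e in bounds]
).to_csv(OUT / "region_map.tsv", sep="\t", index=False)
print("wrote region map (IMGT-style FW/CDR bounds)")
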