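"""Seeded synthetic-data generators with machine-readable ground truth.

Every generator derives one pseudo-random stream per call from the user
seed plus a stable per-component offset (``np.random.default_rng([seed,
...]))``), so outputs are bit-reproducible and adding new outputs never
reshuffles existing ones.

The generators emulate the statistical/geometric structure each pipeline
stage assumes:

* :func:`gen_state_sequences` — two-condition (bound/unbound) fragment-state
  ensembles with injected pairwise coupling through a noisy copy channel
  whose mutual information is known in closed form;
* :func:`gen_toy_complex` — a rigid two-domain antibody-like complex plus an
  antigen blob with optional center-of-mass drift (unbinding) and placed
  ring/H-bond motifs at controlled geometry;
* :func:`gen_mutation_scores` — a deterministic mock per-position scorer
  with a controllable wild-type logit bias per region;
* :func:`gen_repertoire` — repertoire sequences with prescribed per-position
  residue frequencies and their empirical occurrence profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .coupling import StateSequence
from .geomdyn import ComSelection
from .mutscan import AA_ORDER, RepertoireProfile
from .structio import AtomRecord, ChainSequence, RegionMap, Structure, Trajectory

__all__ = [
    "CouplingSpec",
    "ToyComplexSpec",
    "channel_mi",
    "channel_nmi",
    "strength_for_nmi",
    "gen_state_sequences",
    "gen_toy_complex",
    "analytic_unbinding_onset",
    "MockScorer",
    "gen_mutation_scores",
    "gen_repertoire",
]


# --- coupled state sequences ---------------------------------------------


@dataclass
class CouplingSpec:
    """Two-condition fragment-dynamics ensemble specification.

    ``coupled_pairs`` entries are (i, j, condition, strength) with condition
    in {"bound", "unbound", "both"}; fragment j copies fragment i's state
    with probability ``strength``, else redraws uniformly over M states.
    """

    n_fragments: int
    M: int = 4
    F: int = 2000
    replicas: int = 3
    coupled_pairs: list[tuple[int, int, str, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        for i, j, cond, s in self.coupled_pairs:
            if i == j:
                raise ValueError("coupled pair must join two distinct fragments")
            if not 0 <= s <= 1:
                raise ValueError(f"coupling strength {s} outside [0, 1]")
            if cond not in ("bound", "unbound", "both"):
                raise ValueError(f"unknown condition {cond!r}")


def channel_mi(s: float, M: int) -> float:
    """Analytic MI (bits) of the noisy copy channel used for injection.

    X uniform over M states; Y = X with probability s, else uniform.  So
    P(Y = X) = s + (1−s)/M and each other state has probability (1−s)/M.
    """
    a = s + (1 - s) / M
    b = (1 - s) / M
    h_cond = 0.0
    if a > 0:
        h_cond -= a * math.log2(a)
    if b > 0:
        h_cond -= (M - 1) * b * math.log2(b)
    return math.log2(M) - h_cond


def channel_nmi(s: float, M: int) -> float:
    """Analytic joint-entropy-normalized channel MI (the F→∞ coupling value)."""
    i = channel_mi(s, M)
    h_joint = 2 * math.log2(M) - i  # H(X,Y) = H(X) + H(Y) − I
    return i / h_joint if h_joint > 0 else 0.0


def strength_for_nmi(target: float, M: int) -> float:
    """Invert :func:`channel_nmi`: the strength giving a target coupling."""
    from scipy.optimize import brentq

    if not 0 < target < 1:
        raise ValueError("target must lie in (0, 1)")
    return float(brentq(lambda s: channel_nmi(s, M) - target, 1e-9, 1 - 1e-9))


def gen_state_sequences(spec: CouplingSpec):
    """Generate bound/unbound replica ensembles of fragment-state series.

    Returns ``(ensembles, ground_truth)`` where ``ensembles`` maps condition
    → list of replicas, each a list of :class:`StateSequence` (one per
    fragment, states in 1..M); ``ground_truth`` records, per injected pair
    and condition, the strength and the analytic channel MI/nMI.
    """
    conditions = ("bound", "unbound")
    ensembles: dict[str, list[list[StateSequence]]] = {c: [] for c in conditions}
    for ci, cond in enumerate(conditions):
        active = [
            (i, j, s)
            for (i, j, c, s) in spec.coupled_pairs
            if c == cond or c == "both"
        ]
        for rep in range(spec.replicas):
            rng = np.random.default_rng([spec.seed, 101 + ci, rep])
            states = rng.integers(1, spec.M + 1, size=(spec.n_fragments, spec.F))
            for i, j, s in active:
                copy = rng.random(spec.F) < s
                fresh = rng.integers(1, spec.M + 1, size=spec.F)
                states[j - 1] = np.where(copy, states[i - 1], fresh)
            ensembles[cond].append(
                [
                    StateSequence(fragment_index=k + 1, states=states[k], n_states=spec.M)
                    for k in range(spec.n_fragments)
                ]
            )
    ground_truth = {
        "pairs": [
            dict(
                frag_i=i, frag_j=j, condition=c, strength=s,
                analytic_mi_bits=channel_mi(s, spec.M),
                analytic_nmi=channel_nmi(s, spec.M),
            )
            for (i, j, c, s) in spec.coupled_pairs
        ],
        "M": spec.M,
        "F": spec.F,
        "replicas": spec.replicas,
        "seed": spec.seed,
    }
    return ensembles, ground_truth


# --- toy complexes -------------------------------------------------------


@dataclass
class ToyComplexSpec:
    """Rigid toy antibody–antigen complex specification.

    Two antibody-like domains (chains H and L, ``n_res`` residues each, one
    Cα and one sidechain bead per residue) and an antigen blob (chain A).
    ``drift`` (Å/frame, along +x) moves the antigen away from the antibody
    (0 = stays bound).  ``placed_motifs`` are dicts: ``{"kind": "ring_pair",
    "distance": Å, "angle": °}`` or ``{"kind": "hbond", "distance": Å,
    "angle": °}``, realised at exact geometry in frame 0.  ``jitter``
    (Å, σ) perturbs frames after the first.
    """

    n_res: int = 12
    n_antigen: int = 10
    drift: float = 0.0
    placed_motifs: list[dict] = field(default_factory=list)
    F: int = 100
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        if self.F < 1:
            raise ValueError("F must be >= 1")


_RING_TEMPLATE = 1.39 * np.array(
    [[math.cos(k * math.pi / 3), math.sin(k * math.pi / 3), 0.0] for k in range(6)]
)


def _domain(rng, n_res, chain, center, first_res=1):
    """A compact rigid bead cluster: one CA + one CB per residue."""
    atoms, coords = [], []
    for r in range(n_res):
        ca = center + rng.normal(scale=2.5, size=3)
        cb = ca + rng.normal(scale=0.8, size=3)
        resid = first_res + r
        atoms.append(AtomRecord(0, "CA", "C", resid, "ALA", chain, 12.011))
        coords.append(ca)
        atoms.append(AtomRecord(0, "CB", "C", resid, "ALA", chain, 12.011))
        coords.append(cb)
    return atoms, coords


def gen_toy_complex(spec: ToyComplexSpec):
    """Build the toy complex: reference, trajectory, selections, ground truth.

    Selections: VH and VL (all beads of chains H and L), CDR (the
    antigen-proximal third of both chains), AG (antigen blob).  Ground
    truth lists the exact frame-0 COM distances, the drift, the analytic
    motif geometries, and per-frame noiseless CDR–antigen COM distances.
    """
    rng = np.random.default_rng([spec.seed, 11])
    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    ah, ch = _domain(rng, spec.n_res, "H", np.array([0.0, 8.0, 0.0]))
    al, cl = _domain(rng, spec.n_res, "L", np.array([0.0, -8.0, 0.0]))
    atoms += ah + al
    coords += ch + cl
    # antigen blob sits along +x from the antibody
    ag_center = np.array([22.0, 0.0, 0.0])
    aa, ca = _domain(rng, spec.n_antigen, "A", ag_center)
    atoms += aa
    coords += ca

    motif_truth = []
    for k, motif in enumerate(spec.placed_motifs):
        if motif["kind"] == "ring_pair":
            d = float(motif["distance"])
            tilt = math.radians(float(motif.get("angle", 0.0)))
            base = np.array([0.0, 30.0 + 12.0 * k, 0.0])
            ring1 = _RING_TEMPLATE + base
            rot = np.array(
                [[1, 0, 0],
                 [0, math.cos(tilt), -math.sin(tilt)],
                 [0, math.sin(tilt), math.cos(tilt)]]
            )
            ring2 = _RING_TEMPLATE @ rot.T + base + np.array([0.0, 0.0, d])
            resid1, resid2 = 2 * k + 1, 2 * k + 2
            for ring, resid in ((ring1, resid1), (ring2, resid2)):
                for i, p in enumerate(ring):
                    atoms.append(
                        AtomRecord(0, f"CG{i}", "C", resid, "PHE", "M", 12.011)
                    )
                    coords.append(p)
            motif_truth.append(
                dict(kind="ring_pair", residues=(resid1, resid2),
                     distance=d, angle=float(motif.get("angle", 0.0)))
            )
        elif motif["kind"] == "hbond":
            d = float(motif["distance"])
            theta = math.radians(float(motif.get("angle", 180.0)))
            base = np.array([0.0, -30.0 - 12.0 * k, 0.0])
            donor = base
            hyd = base + np.array([1.0, 0.0, 0.0])
            # acceptor at H…A = d with D–H…A angle theta
            acc = hyd + d * np.array([-math.cos(theta), math.sin(theta), 0.0])
            resid_d, resid_a = 100 + 2 * k, 101 + 2 * k
            atoms.append(AtomRecord(0, "N", "N", resid_d, "GLY", "M", 14.007))
            coords.append(donor)
            atoms.append(AtomRecord(0, "H", "H", resid_d, "GLY", "M", 1.008))
            coords.append(hyd)
            atoms.append(AtomRecord(0, "O", "O", resid_a, "GLY", "M", 15.999))
            coords.append(acc)
            motif_truth.append(
                dict(kind="hbond", residues=(resid_d, resid_a),
                     distance=d, angle=float(motif.get("angle", 180.0)))
            )
        else:
            raise ValueError(f"unknown motif kind {motif['kind']!r}")

    for i, a in enumerate(atoms):
        atoms[i] = AtomRecord(i, a.atom_name, a.element, a.residue_index,
                              a.residue_name, a.chain_id, a.mass)
    base_coords = np.array(coords)
    ref = Structure(atoms, base_coords.copy())

    ag_mask = np.array([a.chain_id == "A" for a in atoms])
    jitter_rng = np.random.default_rng([spec.seed, 12])
    frames = np.repeat(base_coords[None], spec.F, axis=0)
    for f in range(spec.F):
        frames[f, ag_mask, 0] += spec.drift * f
        if f > 0 and spec.jitter > 0:
            frames[f] += jitter_rng.normal(scale=spec.jitter, size=base_coords.shape)
    traj = Trajectory(atoms, frames)

    def chain_indices(cid):
        return np.array([i for i, a in enumerate(atoms) if a.chain_id == cid])

    h_idx, l_idx, a_idx = chain_indices("H"), chain_indices("L"), chain_indices("A")
    # antigen-proximal third of each antibody chain plays the CDR
    def proximal(idx):
        order = np.argsort(-base_coords[idx, 0])
        return idx[order[: max(2, len(idx) // 3)]]

    cdr_idx = np.concatenate([proximal(h_idx), proximal(l_idx)])
    cdrl_idx = proximal(l_idx)
    selections = {
        "VH": ComSelection("VH", h_idx),
        "VL": ComSelection("VL", l_idx),
        "AG": ComSelection("AG", a_idx),
        "CDR": ComSelection("CDR", cdr_idx),
        "CDRL": ComSelection("CDRL", cdrl_idx),
    }

    masses = np.array([a.mass for a in atoms])

    def com(idx, xyz):
        w = masses[idx]
        return (xyz[idx] * w[:, None]).sum(axis=0) / w.sum()

    com_cdr0 = com(cdr_idx, base_coords)
    com_ag0 = com(a_idx, base_coords)
    d0 = float(np.linalg.norm(com_cdr0 - com_ag0))
    noiseless = []
    for f in range(spec.F):
        shifted = com_ag0 + np.array([spec.drift * f, 0.0, 0.0])
        noiseless.append(float(np.linalg.norm(com_cdr0 - shifted)))
    ground_truth = {
        "com_distance_frame0": d0,
        "com_distance_noiseless": noiseless,
        "drift_per_frame": spec.drift,
        "vh_vl_distance_frame0": float(
            np.linalg.norm(com(h_idx, base_coords) - com(l_idx, base_coords))
        ),
        "motifs": motif_truth,
        "seed": spec.seed,
    }
    return ref, traj, selections, ground_truth


def analytic_unbinding_onset(
    ground_truth: dict, baseline_window: int, factor: float = 1.5
) -> int | None:
    """First frame where the noiseless drift series crosses the threshold.

    Mirrors the detector's rule on the generator's own noiseless series:
    baseline = mean of the first ``baseline_window`` noiseless distances,
    onset = first frame exceeding factor × baseline.
    """
    series = np.asarray(ground_truth["com_distance_noiseless"])
    baseline = series[:baseline_window].mean()
    above = np.nonzero(series > factor * baseline)[0]
    return int(above[0]) if above.size else None


# --- mock mutational scorers ---------------------------------------------


class MockScorer:
    """Deterministic logit scorer with a per-region wild-type bias.

    Logits at each masked position are standard-normal draws (seeded by
    position, independent of the rest of the sequence) with the wild-type
    amino acid's logit raised by the bias of the region containing that
    position (0 for unannotated positions).
    """

    emits = "logits"

    def __init__(self, seq: ChainSequence, region_map: RegionMap | None,
                 wt_bias_by_region: dict[str, float], seed: int = 0):
        for region, bias in wt_bias_by_region.items():
            if bias < 0:
                raise ValueError(f"bias for {region} must be >= 0")
        self.seq = seq
        self.region_map = region_map
        self.bias = dict(wt_bias_by_region)
        self.seed = seed
        self.n_calls = 0

    def __call__(self, sequence: str, position: int) -> np.ndarray:
        self.n_calls += 1
        rng = np.random.default_rng([self.seed, 31, position])
        logits = rng.normal(size=20)
        residue_index, wt = self.seq.residues[position]
        if wt != "X":
            region = (
                self.region_map.region_of(self.seq.chain_id, residue_index)
                if self.region_map
                else None
            )
            logits[AA_ORDER.index(wt)] += self.bias.get(region, 0.0)
        return logits


def gen_mutation_scores(
    seq: ChainSequence,
    region_map: RegionMap | None,
    wt_bias_by_region: dict[str, float],
    seed: int = 0,
) -> tuple[MockScorer, dict]:
    """Mock scorer plus ground truth (bias map and expected limit behaviour).

    At bias → ∞ the wild type ranks 1 at every biased position; at bias 0
    the wild-type rank is uniform over 1..20.
    """
    scorer = MockScorer(seq, region_map, wt_bias_by_region, seed=seed)
    ground_truth = {
        "wt_bias_by_region": dict(wt_bias_by_region),
        "seed": seed,
        "expected_rank_at_infinite_bias": 1,
        "expected_rank_distribution_at_zero_bias": "uniform over 1..20",
    }
    return scorer, ground_truth


# --- repertoires ---------------------------------------------------------


def gen_repertoire(
    L: int,
    n_sequences: int,
    residue_freqs: dict[int, dict[str, float]],
    seed: int = 0,
) -> tuple[RepertoireProfile, dict[str, str]]:
    """Sample a repertoire and its empirical occurrence profile.

    ``residue_freqs`` maps 1-based positions to amino-acid probability
    mappings (must sum to ≤ 1; the remainder goes to a per-position
    consensus residue drawn once from the seed).  Unlisted positions are
    fixed at their consensus.  The returned profile holds the *empirical*
    fractions of the emitted sequences, so recomputing the profile from the
    FASTA reproduces it exactly.
    """
    import pandas as pd

    rng = np.random.default_rng([seed, 41])
    consensus = [AA_ORDER[i] for i in rng.integers(0, 20, size=L)]
    seqs = []
    for _ in range(n_sequences):
        chars = list(consensus)
        for pos, freqs in residue_freqs.items():
            total = sum(freqs.values())
            if total > 1 + 1e-9:
                raise ValueError(f"position {pos}: frequencies sum to {total} > 1")
            u = rng.random()
            acc = 0.0
            chosen = None
            for aa, p in freqs.items():
                acc += p
                if u < acc:
                    chosen = aa
                    break
            chars[pos - 1] = chosen if chosen is not None else consensus[pos - 1]
        seqs.append("".join(chars))
    fasta = {f"seq{i+1}": s for i, s in enumerate(seqs)}

    rows = []
    for pos in range(1, L + 1):
        column = [s[pos - 1] for s in seqs]
        for aa in sorted(set(column)):
            rows.append(
                dict(position=pos, aa=aa, fraction=column.count(aa) / n_sequences)
            )
    return RepertoireProfile(pd.DataFrame(rows)), fasta
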