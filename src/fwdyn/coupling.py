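"""Structural-alphabet coupling analysis of bound vs unbound ensembles.

Each trajectory frame is coarse-grained into local backbone states:
consecutive four-residue Cα fragments are assigned to the closest prototype
of a structural alphabet (canonically the 25-state M32K25 alphabet; any
M-state alphabet in the same schema is accepted).  Fragment-state time
series then yield pairwise coupling strengths as corrected, normalized
mutual information (MI):

    nMI(X, Y) = clamp₀¹ [ (I(X;Y) − b) / (H(X,Y) − b) ]

where I is the plug-in MI in bits from the frame-wise contingency table,
H(X,Y) the joint entropy, and b a finite-sampling bias — analytically
(Rx−1)(Ry−1)/(2 F ln 2) bits (Rx, Ry = occupied state counts), or the mean
MI over seeded permutations of one sequence.  Subtracting b from numerator
and denominator keeps identical non-constant sequences at exactly 1 and
drives independent sequences to ~0.

Comparing mean coupling between antigen-bound and unbound replica
ensembles gives a per-pair log2 fold change and a p-value (replica-label
permutation or Welch's t-test), BH-adjusted across pairs.  "Hubs" are
pairs with |log2FC| above a threshold at FDR below alpha; per-residue hub
frequencies localize binding-coupled backbone motion on the sequence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geomdyn import kabsch_rotate
from .structio import Trajectory

__all__ = [
    "AlphabetPrototypes",
    "StateSequence",
    "MIMatrix",
    "DiffCoupling",
    "HubTable",
    "load_alphabet",
    "default_alphabet",
    "encode_alphabet",
    "mutual_information",
    "joint_entropy",
    "corrected_normalized_mi",
    "mi_matrix",
    "diff_coupling",
    "call_hubs",
    "position_hub_frequency",
]


@dataclass
class AlphabetPrototypes:
    """A structural alphabet: M labelled prototypes of 4 Cα positions (Å)."""

    labels: list[int]
    coords: np.ndarray  # (M, 4, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise ValueError("prototype coordinates must have shape (M, 4, 3)")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("label count must match prototype count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("prototype labels must be unique")

    @property
    def M(self) -> int:
        return len(self.labels)


@dataclass
class StateSequence:
    """Per-frame structural-alphabet state of one backbone fragment.

    ``fragment_index`` is 1-based: fragment i covers residues i..i+3.
    """

    fragment_index: int
    states: np.ndarray  # (F,) integer state labels
    n_states: int

    def __post_init__(self):
        self.states = np.asarray(self.states)
        if self.states.ndim != 1:
            raise ValueError("states must be one-dimensional")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class MIMatrix:
    """Pairwise corrected normalized MI over a fragment set (one replica)."""

    fragments: list[int]
    values: np.ndarray  # (n, n), symmetric, NaN diagonal

    def pair(self, i: int, j: int) -> float:
        a = self.fragments.index(i)
        b = self.fragments.index(j)
        return float(self.values[a, b])


@dataclass
class DiffCoupling:
    """Per-pair bound-vs-unbound contrast.

    ``table`` columns: frag_i, frag_j, mean_bound, mean_unbound, log2fc,
    pvalue, padj.
    """

    table: pd.DataFrame
    test: str
    pseudocount: float


@dataclass
class HubTable:
    """Significant fragment pairs plus the thresholds that selected them."""

    pairs: pd.DataFrame  # frag_i, frag_j, log2fc, padj, direction
    lfc_threshold: float
    alpha: float


# --- alphabet ------------------------------------------------------------


def load_alphabet(path: str | Path) -> AlphabetPrototypes:
    """Load an alphabet file: TSV with columns state, point, x, y, z.

    ``point`` runs 1–4 within each state.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"state", "point", "x", "y", "z"}
    if required - set(df.columns):
        raise ValueError(f"alphabet file needs columns {sorted(required)}")
    labels, coords = [], []
    for state, grp in df.groupby("state", sort=True):
        grp = grp.sort_values("point")
        if len(grp) != 4:
            raise ValueError(f"state {state}: expected 4 points, got {len(grp)}")
        labels.append(int(state))
        coords.append(grp[["x", "y", "z"]].to_numpy(dtype=float))
    return AlphabetPrototypes(labels=labels, coords=np.stack(coords))


def default_alphabet() -> AlphabetPrototypes:
    """The bundled 25-state alphabet.

    This file is a synthetic stand-in with the canonical schema and
    cardinality (25 states × 4 Cα points); substitute a real M32K25 file via
    :func:`load_alphabet` for production encodings.
    """
    with resources.as_file(
        resources.files("fwdyn.data") / "alphabet_synthetic_m25.tsv"
    ) as p:
        return load_alphabet(p)


def _fragment_rmsd_to_prototypes(frag: np.ndarray, protos: np.ndarray) -> np.ndarray:
    """Minimal RMSD of batched 4-point fragments to each centred prototype.

    frag: (F, 4, 3); protos: (M, 4, 3) already centred.  Returns (F, M).
    """
    F = frag.shape[0]
    M = protos.shape[0]
    frag_c = frag - frag.mean(axis=1, keepdims=True)
    out = np.empty((F, M))
    for m in range(M):
        rotated = kabsch_rotate(frag_c, protos[m])
        diff = rotated - protos[m]
        out[:, m] = np.sqrt(np.einsum("fni,fni->f", diff, diff) / 4.0)
    return out


def encode_alphabet(
    traj: Trajectory, chain: str, prototypes: AlphabetPrototypes
) -> list[StateSequence]:
    """Encode a chain's backbone into per-fragment state sequences.

    For every frame and every fragment of four consecutive residues, the
    state is the prototype with minimal Cα RMSD after optimal superposition
    (ties break to the lowest label).  Fragments spanning residues without a
    Cα atom are excluded.
    """
    ca = [
        (a.residue_index, i)
        for i, a in enumerate(traj.topology)
        if a.chain_id == chain and a.atom_name == "CA"
    ]
    if len(ca) < 4:
        raise ValueError(f"chain {chain!r} has fewer than 4 Cα atoms")
    ca_by_res = dict(ca)
    residues = sorted(ca_by_res)
    protos_c = prototypes.coords - prototypes.coords.mean(axis=1, keepdims=True)
    labels = np.array(prototypes.labels)
    order = np.argsort(labels, kind="stable")  # tie-break to lowest label
    protos_sorted = protos_c[order]
    labels_sorted = labels[order]

    sequences = []
    for k, first in enumerate(residues[:-3]):
        window = [first + d for d in range(4)]
        if any(r not in ca_by_res for r in window):
            continue  # missing Cα: fragment invalid
        idx = [ca_by_res[r] for r in window]
        frag = traj.frames[:, idx, :]
        rmsd = _fragment_rmsd_to_prototypes(frag, protos_sorted)
        best = labels_sorted[np.argmin(rmsd, axis=1)]
        sequences.append(
            StateSequence(fragment_index=first, states=best, n_states=prototypes.M)
        )
    return sequences


# --- mutual information --------------------------------------------------


def _contingency(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xv, xi = np.unique(x, return_inverse=True)
    yv, yi = np.unique(y, return_inverse=True)
    joint = np.zeros((len(xv), len(yv)))
    np.add.at(joint, (xi, yi), 1.0)
    return joint / len(x)


def mutual_information(x: StateSequence, y: StateSequence) -> float:
    """Plug-in mutual information in bits from the frame-wise joint table."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise ValueError("need at least 2 frames")
    p = _contingency(x.states, y.states)
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def joint_entropy(x: StateSequence, y: StateSequence) -> float:
    """Joint Shannon entropy H(X, Y) in bits."""
    p = _contingency(x.states, y.states)
    nz = p > 0
    return float(-np.sum(p[nz] * np.log2(p[nz])))


def corrected_normalized_mi(
    x: StateSequence,
    y: StateSequence,
    correction: str = "analytic",
    n_perm: int = 200,
    seed: int | None = None,
) -> float:
    """Finite-sampling-corrected, normalized MI in [0, 1].

    The bias ``b`` is subtracted from both the MI and the joint-entropy
    normalizer: nMI = (I − b)/(H(X,Y) − b), clamped to [0, 1].  ``analytic``
    uses the first-order plug-in bias (Rx−1)(Ry−1)/(2 F ln 2) bits;
    ``permutation`` uses the mean MI over ``n_perm`` seeded shuffles of
    ``y``.  Two constant sequences (H = 0) give 0 by definition.
    """
    I = mutual_information(x, y)
    H = joint_entropy(x, y)
    if H == 0.0:
        return 0.0
    F = len(x)
    if correction == "analytic":
        rx = len(np.unique(x.states))
        ry = len(np.unique(y.states))
        b = (rx - 1) * (ry - 1) / (2.0 * F * math.log(2.0))
    elif correction == "permutation":
        rng = np.random.default_rng(seed)
        acc = 0.0
        ys = y.states.copy()
        for _ in range(n_perm):
            rng.shuffle(ys)
            acc += mutual_information(x, StateSequence(y.fragment_index, ys, y.n_states))
        b = acc / n_perm
    else:
        raise ValueError("correction must be 'analytic' or 'permutation'")
    denom = H - b
    if denom <= 0:
        return 0.0
    val = min(1.0, max(0.0, (I - b) / denom))
    # I and H are accumulated by different sums; snap roundoff at the top end
    # so identical sequences (I = H exactly) report exactly 1
    if 1.0 - val < 1e-12:
        val = 1.0
    return float(val)


def mi_matrix(
    encodings: list[StateSequence],
    frame_window: float = 0.5,
    correction: str = "analytic",
    seed: int | None = None,
) -> MIMatrix:
    """All-pairs corrected normalized MI over the tail of each sequence.

    ``frame_window`` is the tail fraction of frames used (0.5 = the last
    half, mirroring equilibrated-tail analysis); self-pairings are excluded
    (NaN diagonal).
    """
    if len(encodings) < 2:
        raise ValueError("need at least 2 fragments")
    F = len(encodings[0])
    if any(len(e) != F for e in encodings):
        raise ValueError("all state sequences must have equal length")
    n_tail = int(round(frame_window * F))
    if n_tail < 2:
        raise ValueError("frame window shorter than 2 frames")
    tails = [
        StateSequence(e.fragment_index, e.states[F - n_tail :], e.n_states)
        for e in encodings
    ]
    n = len(tails)
    vals = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            v = corrected_normalized_mi(tails[i], tails[j], correction=correction, seed=seed)
            vals[i, j] = vals[j, i] = v
    return MIMatrix(fragments=[e.fragment_index for e in encodings], values=vals)


# --- differential coupling ----------------------------------------------

_EXHAUSTIVE_LIMIT = math.comb(10, 5)


def permutation_pvalue(a: np.ndarray, b: np.ndarray, n_perm: int = 10_000,
                       seed: int | None = None) -> float:
    """Two-sided replica-label permutation p for a difference of means.

    Exhaustive over all C(n, n_a) label assignments when that count is at
    most C(10, 5) = 252; otherwise ``n_perm`` seeded random assignments.
    The observed assignment is included in the null set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    obs = abs(a.mean() - b.mean())
    n_arr = math.comb(n, na)
    count = total = 0
    if n_arr <= _EXHAUSTIVE_LIMIT:
        for combo in itertools.combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            stat = abs(pooled[mask].mean() - pooled[~mask].mean())
            count += stat >= obs - 1e-12
            total += 1
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            stat = abs(pooled[perm[:na]].mean() - pooled[perm[na:]].mean())
            count += stat >= obs - 1e-12
            total += 1
    return count / total


def _t_pvalue(a: np.ndarray, b: np.ndarray, equal_var: bool) -> float:
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def diff_coupling(
    bound: list[MIMatrix],
    unbound: list[MIMatrix],
    pseudocount: float = 1e-6,
    test: str = "permutation",
    seed: int | None = None,
    n_perm: int = 10_000,
) -> DiffCoupling:
    """Contrast per-pair coupling between bound and unbound replica sets.

    log2FC = log2((mean_bound + ε)/(mean_unbound + ε)) with pseudocount ε.
    P-values come from a replica-label permutation test (default), Welch's
    t-test, or a pooled-variance Student t-test.  With 3 vs 3 replicas the
    permutation null has only 20 assignments (minimum two-sided p = 0.1),
    so a t-test is required to call significance below that resolution;
    with equal group sizes the pooled test keeps its nominal size under
    variance heterogeneity while retaining df = 4, which matters at such
    small replica counts.  BH adjustment is applied across all pairs.
    """
    if not bound or not unbound:
        raise ValueError("need at least one replica per condition")
    frag_sets = {tuple(m.fragments) for m in bound + unbound}
    if len(frag_sets) != 1:
        raise ValueError("all MI matrices must cover the same fragment set")
    if test not in ("permutation", "welch", "student"):
        raise ValueError("test must be 'permutation', 'welch' or 'student'")
    fragments = bound[0].fragments
    n = len(fragments)
    b_stack = np.stack([m.values for m in bound])  # (Rb, n, n)
    u_stack = np.stack([m.values for m in unbound])
    can_test = len(bound) >= 2 and len(unbound) >= 2
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            bv = b_stack[:, i, j]
            uv = u_stack[:, i, j]
            mb, mu = float(bv.mean()), float(uv.mean())
            lfc = math.log2((mb + pseudocount) / (mu + pseudocount))
            if not can_test:
                p = float("nan")
            elif test == "permutation":
                p = permutation_pvalue(bv, uv, n_perm=n_perm, seed=seed)
            else:
                p = _t_pvalue(bv, uv, equal_var=(test == "student"))
            rows.append(
                dict(frag_i=fragments[i], frag_j=fragments[j],
                     mean_bound=mb, mean_unbound=mu, log2fc=lfc, pvalue=p)
            )
    table = pd.DataFrame(rows)
    padj = np.full(len(table), np.nan)
    mask = table["pvalue"].notna().to_numpy()
    if mask.any():
        padj[mask] = multipletests(table.loc[mask, "pvalue"], method="fdr_bh")[1]
    table["padj"] = padj
    return DiffCoupling(table=table, test=test, pseudocount=pseudocount)


def call_hubs(dc: DiffCoupling, lfc_threshold: float = 2.0, alpha: float = 0.01) -> HubTable:
    """Select hub pairs: |log2FC| > threshold and BH-adjusted p < alpha.

    Direction is bound-favoured for positive log2FC, unbound-favoured for
    negative.
    """
    t = dc.table
    sel = (t["log2fc"].abs() > lfc_threshold) & (t["padj"] < alpha)
    pairs = t[sel].copy()
    pairs["direction"] = np.where(pairs["log2fc"] > 0, "bound", "unbound")
    cols = ["frag_i", "frag_j", "mean_bound", "mean_unbound", "log2fc", "pvalue", "padj", "direction"]
    return HubTable(pairs=pairs[cols].reset_index(drop=True),
                    lfc_threshold=lfc_threshold, alpha=alpha)


def position_hub_frequency(hubs: HubTable, L: int, mode: str = "pairs") -> np.ndarray:
    """Per-residue hub counts along a length-L chain.

    Fragment i covers residues i..i+3.  ``mode='pairs'`` (default) adds one
    count per hub pair to every residue covered by either member fragment;
    ``mode='fragments'`` counts each unique hub-participating fragment once.
    """
    counts = np.zeros(L, dtype=int)

    def cover(frag: int):
        for r in range(frag, min(frag + 4, L + 1)):
            counts[r - 1] += 1

    if mode == "pairs":
        for rec in hubs.pairs.itertuples(index=False):
            cover(int(rec.frag_i))
            cover(int(rec.frag_j))
    elif mode == "fragments":
        frags = set(hubs.pairs["frag_i"].astype(int)) | set(hubs.pairs["frag_j"].astype(int))
        for f in sorted(frags):
            cover(f)
    else:
        raise ValueError("mode must be 'pairs' or 'fragments'")
    return counts
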