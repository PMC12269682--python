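"""Geometric classification of non-covalent interactions in trajectories.

Three interaction families are detected frame by frame with purely geometric
two-test criteria (a distance test and an angle test; boundary equality
satisfies a criterion):

* hydrogen bonds — Baker–Hubbard style: H…acceptor distance and
  donor–H…acceptor angle;
* π–π stacking — distance between aromatic ring centers of mass and the
  angle between the ring normals (folded to [0°, 90°], since a plane normal
  is sign-ambiguous);
* XH–ring (X = C or N) — distance between X and the ring COM and the
  X–H–COM angle.

Detected events aggregate into residue-interaction networks whose edges are
(unordered residue pair, interaction type) with a frame frequency — the
fraction of frames in which at least one event of that type links the pair.
Differencing two networks highlights residues whose local interaction
pattern a mutation perturbs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structio import Trajectory

__all__ = [
    "RingDefinition",
    "GeomCriteria",
    "InteractionEvent",
    "InteractionNetwork",
    "ring_geometry",
    "detect_hbonds",
    "detect_pipi",
    "detect_xh_ring",
    "count_interactions",
    "build_network",
    "diff_network",
]

EVENT_TYPES = ("hbond", "pipi", "ch_ring", "nh_ring")


@dataclass
class RingDefinition:
    """An aromatic ring: residue, chain and the names of its ring atoms."""

    residue_index: int
    chain_id: str
    ring_atoms: tuple[str, ...]

    def __post_init__(self):
        if len(self.ring_atoms) < 5:
            raise ValueError("a ring needs at least 5 atoms")

    def resolve(self, topology) -> np.ndarray:
        idx = [
            i
            for i, a in enumerate(topology)
            if a.chain_id == self.chain_id
            and a.residue_index == self.residue_index
            and a.atom_name in self.ring_atoms
        ]
        if len(idx) < 5:
            raise ValueError(
                f"ring {self.chain_id}/{self.residue_index}: only {len(idx)} of "
                f"{len(self.ring_atoms)} ring atoms found in topology"
            )
        return np.array(idx, dtype=int)


@dataclass
class GeomCriteria:
    """Numeric cutoffs for the interaction detectors (Å, degrees).

    Defaults follow standard literature conventions; every value is
    configurable and recorded in run manifests.
    """

    hbond_max_distance: float = 2.5
    hbond_min_angle: float = 120.0
    pipi_max_distance: float = 5.5
    pipi_max_angle: float = 30.0
    xh_max_distance: float = 4.5
    xh_min_angle: float = 120.0

    def __post_init__(self):
        for name in ("hbond_max_distance", "pipi_max_distance", "xh_max_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("hbond_min_angle", "pipi_max_angle", "xh_min_angle"):
            v = getattr(self, name)
            if not 0 <= v <= 180:
                raise ValueError(f"{name} must lie in [0°, 180°]")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class InteractionEvent:
    """One detected interaction in one frame."""

    frame: int
    type: str  # hbond | pipi | ch_ring | nh_ring
    chain_a: str
    residue_a: int
    chain_b: str
    residue_b: int
    partners: str  # human-readable atom/ring identifiers
    distance: float  # Å
    angle: float  # degrees

    def residue_pair(self) -> tuple[tuple[str, int], tuple[str, int]]:
        a = (self.chain_a, self.residue_a)
        b = (self.chain_b, self.residue_b)
        return (a, b) if a <= b else (b, a)


@dataclass
class InteractionNetwork:
    """Residue-interaction graph: edges are (pair, type) with frame frequency."""

    edges: pd.DataFrame  # chain_a, res_a, chain_b, res_b, type, frequency
    n_frames: int

    def to_networkx(self):
        import networkx as nx

        g = nx.MultiGraph()
        for r in self.edges.itertuples(index=False):
            g.add_edge(
                (r.chain_a, int(r.res_a)),
                (r.chain_b, int(r.res_b)),
                key=r.type,
                frequency=float(r.frequency),
            )
        return g


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle between batched vectors, degrees, numerically stable."""
    cross = np.linalg.norm(np.cross(v1, v2), axis=-1)
    dot = np.einsum("...i,...i->...", v1, v2)
    return np.degrees(np.arctan2(cross, dot))


# boundary equality satisfies a criterion; a small absolute guard keeps the
# comparison robust to coordinate roundoff when a geometry sits exactly on it
_EPS = 1e-9


def _le(values, bound):
    return values <= bound + _EPS


def _ge(values, bound):
    return values >= bound - _EPS


def ring_geometry(traj: Trajectory, ring: RingDefinition):
    """Per-frame ring COM (mass-weighted) and unit normal.

    The normal is the smallest principal axis of the centred ring atoms
    (best-fit plane).  Frames where the ring atoms are degenerate
    (collinear) yield NaN normals and are skipped by the detectors with a
    warning.
    """
    idx = ring.resolve(traj.topology)
    masses = traj.masses()[idx]
    coords = traj.frames[:, idx, :]  # (F, n, 3)
    com = np.einsum("fni,n->fi", coords, masses) / masses.sum()
    centered = coords - com[:, None, :]
    # smallest right singular vector of each frame's centred coordinates
    _, s, vt = np.linalg.svd(centered)
    normals = vt[:, 2, :]
    degenerate = s[:, 1] < 1e-9  # collinear: plane undefined
    if degenerate.any():
        warnings.warn(
            f"ring {ring.chain_id}/{ring.residue_index}: "
            f"{int(degenerate.sum())} degenerate frames skipped"
        )
        normals = normals.copy()
        normals[degenerate] = np.nan
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        normals = normals / norms
    return com, normals


def _infer_dh_pairs(traj: Trajectory, donors: str = "NO") -> list[tuple[int, int]]:
    """Pair each hydrogen with its covalently bonded heavy atom (frame 0)."""
    h_idx = [i for i, a in enumerate(traj.topology) if a.element.upper() == "H"]
    heavy = [i for i, a in enumerate(traj.topology) if a.element.upper() in donors]
    pairs = []
    if not h_idx or not heavy:
        return pairs
    coords = traj.frames[0]
    heavy_arr = np.array(heavy)
    for h in h_idx:
        d = np.linalg.norm(coords[heavy_arr] - coords[h], axis=1)
        j = int(np.argmin(d))
        if d[j] <= 1.3:  # covalent X–H bond length
            pairs.append((int(heavy_arr[j]), h))
    return pairs


def detect_hbonds(
    traj: Trajectory,
    criteria: GeomCriteria | None = None,
    triples: list[tuple[int, int, int]] | None = None,
) -> list[InteractionEvent]:
    """Detect hydrogen bonds: H…A ≤ max distance and ∠D–H…A ≥ min angle.

    ``triples`` supplies explicit (donor, hydrogen, acceptor) atom indices;
    otherwise donors are N/O atoms with a covalently bonded hydrogen and
    acceptors are all other N/O atoms.  Intra-residue pairs are ignored.
    """
    criteria = criteria or GeomCriteria()
    top = traj.topology
    if triples is None:
        dh = _infer_dh_pairs(traj)
        if not dh:
            raise ValueError(
                "topology has no resolvable donor hydrogens; pass explicit "
                "(donor, hydrogen, acceptor) triples"
            )
        acceptors = [i for i, a in enumerate(top) if a.element.upper() in "NO"]
        triples = [
            (d, h, acc)
            for d, h in dh
            for acc in acceptors
            if acc != d
            and not (
                top[acc].chain_id == top[d].chain_id
                and top[acc].residue_index == top[d].residue_index
            )
        ]
    events = []
    for d, h, a in triples:
        if top[d].chain_id == top[a].chain_id and top[d].residue_index == top[a].residue_index:
            continue
        ha = np.linalg.norm(traj.frames[:, a, :] - traj.frames[:, h, :], axis=1)
        ang = _angle_deg(
            traj.frames[:, d, :] - traj.frames[:, h, :],
            traj.frames[:, a, :] - traj.frames[:, h, :],
        )
        hits = np.nonzero(_le(ha, criteria.hbond_max_distance) & _ge(ang, criteria.hbond_min_angle))[0]
        for f in hits:
            events.append(
                InteractionEvent(
                    frame=int(f), type="hbond",
                    chain_a=top[d].chain_id, residue_a=top[d].residue_index,
                    chain_b=top[a].chain_id, residue_b=top[a].residue_index,
                    partners=f"{top[d].atom_name}-{top[h].atom_name}...{top[a].atom_name}",
                    distance=float(ha[f]), angle=float(ang[f]),
                )
            )
    return events


def detect_pipi(
    traj: Trajectory,
    rings: list[RingDefinition],
    criteria: GeomCriteria | None = None,
) -> list[InteractionEvent]:
    """Detect π–π stacking between ring pairs.

    Criterion: ring COM–COM distance ≤ max distance and the inter-normal
    angle, folded to [0°, 90°] as min(θ, 180°−θ), ≤ max angle.
    """
    criteria = criteria or GeomCriteria()
    if len(rings) < 2:
        raise ValueError("need at least two rings")
    geom = [ring_geometry(traj, r) for r in rings]
    events = []
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            ri, rj = rings[i], rings[j]
            if ri.chain_id == rj.chain_id and ri.residue_index == rj.residue_index:
                continue
            com_i, n_i = geom[i]
            com_j, n_j = geom[j]
            d = np.linalg.norm(com_i - com_j, axis=1)
            theta = _angle_deg(n_i, n_j)
            folded = np.minimum(theta, 180.0 - theta)
            ok = _le(d, criteria.pipi_max_distance) & _le(folded, criteria.pipi_max_angle)
            ok &= np.isfinite(folded)
            for f in np.nonzero(ok)[0]:
                events.append(
                    InteractionEvent(
                        frame=int(f), type="pipi",
                        chain_a=ri.chain_id, residue_a=ri.residue_index,
                        chain_b=rj.chain_id, residue_b=rj.residue_index,
                        partners=f"ring{ri.residue_index}...ring{rj.residue_index}",
                        distance=float(d[f]), angle=float(folded[f]),
                    )
                )
    return events


def detect_xh_ring(
    traj: Trajectory,
    rings: list[RingDefinition],
    criteria: GeomCriteria | None = None,
    X: str = "C",
    xh_pairs: list[tuple[int, int]] | None = None,
) -> list[InteractionEvent]:
    """Detect CH–π / NH–π interactions between X–H groups and ring faces.

    Criterion: X–COMring distance ≤ max distance and ∠X–H–COMring ≥ min
    angle.  ``X`` selects the heavy-atom element (C or N); X–H bonded pairs
    are inferred from frame 0 unless supplied.
    """
    criteria = criteria or GeomCriteria()
    if X not in ("C", "N"):
        raise ValueError("X must be 'C' or 'N'")
    etype = "ch_ring" if X == "C" else "nh_ring"
    top = traj.topology
    if xh_pairs is None:
        xh_pairs = _infer_dh_pairs(traj, donors=X)
        if not xh_pairs:
            return []
    events = []
    for ring in rings:
        com, _ = ring_geometry(traj, ring)
        for x, h in xh_pairs:
            if top[x].chain_id == ring.chain_id and top[x].residue_index == ring.residue_index:
                continue
            d = np.linalg.norm(traj.frames[:, x, :] - com, axis=1)
            ang = _angle_deg(
                traj.frames[:, x, :] - traj.frames[:, h, :],
                com - traj.frames[:, h, :],
            )
            ok = _le(d, criteria.xh_max_distance) & _ge(ang, criteria.xh_min_angle)
            for f in np.nonzero(ok)[0]:
                events.append(
                    InteractionEvent(
                        frame=int(f), type=etype,
                        chain_a=top[x].chain_id, residue_a=top[x].residue_index,
                        chain_b=ring.chain_id, residue_b=ring.residue_index,
                        partners=f"{top[x].atom_name}-{top[h].atom_name}...ring{ring.residue_index}",
                        distance=float(d[f]), angle=float(ang[f]),
                    )
                )
    return events


def count_interactions(
    events: list[InteractionEvent],
    focus_residue: tuple[str, int] | int,
    n_frames: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame, per-type counts of events involving a focus residue.

    ``focus_residue`` is (chain_id, residue_index), or a bare residue index
    matched in any chain.  Returns (per-frame count table, summary table
    with median and inter-quartile range per type).
    """

    def involves(e: InteractionEvent) -> bool:
        if isinstance(focus_residue, int):
            return focus_residue in (e.residue_a, e.residue_b)
        return focus_residue in ((e.chain_a, e.residue_a), (e.chain_b, e.residue_b))

    counts = pd.DataFrame(0, index=pd.RangeIndex(n_frames, name="frame"), columns=list(EVENT_TYPES))
    for e in events:
        if involves(e):
            counts.loc[e.frame, e.type] += 1
    summary = pd.DataFrame(
        {
            "type": list(EVENT_TYPES),
            "median": [float(counts[t].median()) for t in EVENT_TYPES],
            "iqr": [
                float(counts[t].quantile(0.75) - counts[t].quantile(0.25))
                for t in EVENT_TYPES
            ],
            "total": [int(counts[t].sum()) for t in EVENT_TYPES],
        }
    )
    return counts.reset_index(), summary


def build_network(
    events: list[InteractionEvent], F: int, min_frequency: float = 0.1
) -> InteractionNetwork:
    """Aggregate events into a residue-interaction network.

    An edge's frequency is the number of frames with at least one event of
    that type between the residue pair, divided by ``F`` (multiple events in
    a frame count once).  Edges below ``min_frequency`` are dropped.
    """
    if F < 1:
        raise ValueError("F must be >= 1")
    frames_per_edge: dict[tuple, set[int]] = {}
    for e in events:
        (a, b) = e.residue_pair()
        if a == b:
            continue
        frames_per_edge.setdefault((a, b, e.type), set()).add(e.frame)
    rows = []
    for (a, b, etype), frames in sorted(frames_per_edge.items()):
        freq = len(frames) / F
        if freq >= min_frequency:
            rows.append(
                dict(chain_a=a[0], res_a=a[1], chain_b=b[0], res_b=b[1],
                     type=etype, frequency=freq)
            )
    cols = ["chain_a", "res_a", "chain_b", "res_b", "type", "frequency"]
    return InteractionNetwork(edges=pd.DataFrame(rows, columns=cols), n_frames=F)


def diff_network(
    net_ref: InteractionNetwork,
    net_alt: InteractionNetwork,
    perturb_threshold: float = 0.25,
) -> tuple[pd.DataFrame, set[tuple[str, int]]]:
    """Edge-level difference of two interaction networks.

    Returns the union-join table (pair, type, freq_ref, freq_alt, dfreq =
    freq_alt − freq_ref) and the set of perturbed residues: endpoints of
    edges with |Δfreq| ≥ ``perturb_threshold``.  An edge absent from one
    network has frequency 0 there.
    """
    key_cols = ["chain_a", "res_a", "chain_b", "res_b", "type"]

    def keyed(net: InteractionNetwork) -> dict[tuple, float]:
        return {
            tuple(getattr(r, c) for c in key_cols): float(r.frequency)
            for r in net.edges.itertuples(index=False)
        }

    ref = keyed(net_ref)
    alt = keyed(net_alt)
    rows = []
    perturbed: set[tuple[str, int]] = set()
    for key in sorted(set(ref) | set(alt)):
        f_ref = ref.get(key, 0.0)
        f_alt = alt.get(key, 0.0)
        dfreq = f_alt - f_ref
        rows.append(
            dict(zip(key_cols, key)) | dict(freq_ref=f_ref, freq_alt=f_alt, dfreq=dfreq)
        )
        if abs(dfreq) >= perturb_threshold:
            perturbed.add((key[0], int(key[1])))
            perturbed.add((key[2], int(key[3])))
    table = pd.DataFrame(rows, columns=key_cols + ["freq_ref", "freq_alt", "dfreq"])
    return table, perturbed
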