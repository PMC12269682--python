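"""Frame-wise geometric descriptors of antibody–antigen trajectories.

Implements the ensemble observables used to triage mutant behaviour:
center-of-mass (COM) distance between the CDR loops and the antigen
juxtamembrane region as a binding proxy, the VH–VL packing angle and
distance, RMSD to a reference after optimal superposition, native-contact
retention, and a persistence-based detector for unbinding events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import Structure, Trajectory

__all__ = [
    "ComSelection",
    "load_selections",
    "SeriesResult",
    "ContactSet",
    "UnbindingCall",
    "center_of_mass",
    "com_distance_series",
    "vh_vl_angle_series",
    "vh_vl_distance_series",
    "rmsd_series",
    "native_contacts",
    "contact_retention",
    "detect_unbinding",
]


@dataclass
class ComSelection:
    """A named atom selection for COM computation (mass-weighted by default)."""

    name: str
    indices: np.ndarray
    mass_weighted: bool = True

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise ValueError(f"selection {self.name!r} is empty")

    def validate(self, n_atoms: int) -> None:
        if self.indices.min() < 0 or self.indices.max() >= n_atoms:
            raise IndexError(
                f"selection {self.name!r} has indices outside the {n_atoms}-atom topology"
            )


@dataclass
class SeriesResult:
    """A per-frame scalar series (Å or degrees); NaN marks undefined frames."""

    values: np.ndarray
    frame_times: np.ndarray
    unit: str = "angstrom"
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.values.shape != self.frame_times.shape:
            raise ValueError("values and frame_times must have equal length")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ContactSet:
    """Reference heavy-atom contact pairs with their reference distances."""

    pairs: np.ndarray  # (n, 2) atom indices
    reference_distances: np.ndarray  # (n,) Å
    cutoff: float
    exclusion: int

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.reference_distances = np.asarray(self.reference_distances, dtype=float)
        if np.any(self.reference_distances > self.cutoff + 1e-9):
            raise ValueError("reference distances must not exceed the cutoff")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class UnbindingCall:
    flag: bool
    onset_frame: int | None
    baseline: float
    threshold: float


def load_selections(path, topology) -> dict[str, ComSelection]:
    """Load named atom selections from a TSV.

    Columns: name, chain_id, start, end, atoms (comma-separated atom names
    or ``all``).  Rows sharing a name are unioned.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"name", "chain_id", "start", "end", "atoms"}
    if required - set(df.columns):
        raise ValueError(f"selections file needs columns {sorted(required)}")
    groups: dict[str, list[int]] = {}
    for r in df.itertuples(index=False):
        names = None if str(r.atoms).lower() == "all" else {
            s.strip() for s in str(r.atoms).split(",")
        }
        idx = [
            i
            for i, a in enumerate(topology)
            if a.chain_id == str(r.chain_id)
            and int(r.start) <= a.residue_index <= int(r.end)
            and (names is None or a.atom_name in names)
        ]
        groups.setdefault(str(r.name), []).extend(idx)
    return {
        name: ComSelection(name, np.array(sorted(set(idx))))
        for name, idx in groups.items()
    }


def _com_per_frame(frames: np.ndarray, sel: ComSelection, masses: np.ndarray) -> np.ndarray:
    sub = frames[:, sel.indices, :]
    if sel.mass_weighted:
        w = masses[sel.indices]
    else:
        w = np.ones(len(sel.indices))
    return np.einsum("fai,a->fi", sub, w) / w.sum()


def center_of_mass(traj: Trajectory, sel: ComSelection) -> np.ndarray:
    """Per-frame COM of a selection: Σ mᵢrᵢ / Σ mᵢ.  Shape (F, 3), Å."""
    sel.validate(traj.n_atoms)
    return _com_per_frame(traj.frames, sel, traj.masses())


def com_distance_series(traj: Trajectory, selA: ComSelection, selB: ComSelection) -> SeriesResult:
    """Euclidean distance between the COMs of two selections, per frame."""
    a = center_of_mass(traj, selA)
    b = center_of_mass(traj, selB)
    d = np.linalg.norm(a - b, axis=1)
    return SeriesResult(d, traj.frame_times, unit="angstrom",
                        name=f"com_distance:{selA.name}-{selB.name}")


def vh_vl_angle_series(
    traj: Trajectory,
    sel_cdrL: ComSelection,
    sel_VL: ComSelection,
    sel_VH: ComSelection,
    vertex: str = "VL",
) -> SeriesResult:
    """Planar VH–VL packing angle from three COMs, in degrees.

    The angle is measured at the ``vertex`` COM (default the VL domain, which
    the light-chain CDR and the VH domain flank) between the two vectors to
    the remaining COMs.  Frames where two COMs coincide (vector norm
    < 1e-9 Å) are undefined and reported as NaN.
    """
    coms = {
        "CDRL": center_of_mass(traj, sel_cdrL),
        "VL": center_of_mass(traj, sel_VL),
        "VH": center_of_mass(traj, sel_VH),
    }
    if vertex not in coms:
        raise ValueError(f"vertex must be one of {list(coms)}, got {vertex!r}")
    others = [k for k in coms if k != vertex]
    v1 = coms[others[0]] - coms[vertex]
    v2 = coms[others[1]] - coms[vertex]
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    ok = (n1 >= 1e-9) & (n2 >= 1e-9)
    ang = np.full(traj.n_frames, np.nan)
    cross = np.linalg.norm(np.cross(v1[ok], v2[ok]), axis=1)
    dot = np.einsum("ij,ij->i", v1[ok], v2[ok])
    ang[ok] = np.degrees(np.arctan2(cross, dot))
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} frames with coincident COMs flagged NaN")
    return SeriesResult(ang, traj.frame_times, unit="degree", name="vh_vl_angle")


def vh_vl_distance_series(traj: Trajectory, sel_VH: ComSelection, sel_VL: ComSelection) -> SeriesResult:
    """Straight-line distance between VH and VL domain COMs, per frame."""
    out = com_distance_series(traj, sel_VH, sel_VL)
    out.name = "vh_vl_distance"
    return out


def kabsch_rotate(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (reflections disallowed) of centred point sets.

    ``mobile`` may be batched (..., N, 3); ``target`` is (N, 3).  Both are
    assumed already centred.  Returns the rotated mobile coordinates.
    """
    mob = np.asarray(mobile, dtype=float)
    tgt = np.asarray(target, dtype=float)
    batched = mob.ndim == 3
    if not batched:
        mob = mob[None]
    H = np.einsum("fni,nj->fij", mob, tgt)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fij,fjk->fik", U, Vt))
    D = np.repeat(np.eye(3)[None], len(mob), axis=0)
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("fij,fjk,fkl->fil", U, D, Vt)
    rotated = np.einsum("fni,fij->fnj", mob, R)
    return rotated if batched else rotated[0]


def rmsd_series(traj: Trajectory, reference: Structure, sel: ComSelection) -> SeriesResult:
    """Per-frame RMSD (Å) to a reference after optimal rigid superposition.

    Mass-unweighted Kabsch alignment on the selected atoms; the selection
    must address the same atoms in trajectory and reference.
    """
    sel.validate(traj.n_atoms)
    if reference.n_atoms != traj.n_atoms:
        raise ValueError(
            f"reference has {reference.n_atoms} atoms but trajectory has {traj.n_atoms}"
        )
    ref = reference.coords[sel.indices]
    ref_c = ref - ref.mean(axis=0)
    mob = traj.frames[:, sel.indices, :]
    mob_c = mob - mob.mean(axis=1, keepdims=True)
    rotated = kabsch_rotate(mob_c, ref_c)
    diff = rotated - ref_c
    rmsd = np.sqrt(np.einsum("fni,fni->f", diff, diff) / ref.shape[0])
    return SeriesResult(rmsd, traj.frame_times, unit="angstrom", name="rmsd")


def native_contacts(
    reference: Structure, cutoff: float = 4.5, exclusion: int = 3
) -> ContactSet:
    """Heavy-atom contact pairs of a reference structure.

    A pair qualifies if its distance is ≤ ``cutoff`` Å and the two atoms are
    in different chains or at least ``exclusion`` residues apart in sequence
    (intra-residue pairs never qualify).
    """
    heavy = np.array([i for i, a in enumerate(reference.atoms) if a.element.upper() != "H"])
    if heavy.size == 0:
        raise ValueError("reference contains no heavy atoms")
    coords = reference.coords[heavy]
    tree = cKDTree(coords)
    pairs_local = np.array(sorted(tree.query_pairs(cutoff)), dtype=int).reshape(-1, 2)
    keep, dists = [], []
    for i_loc, j_loc in pairs_local:
        ai = reference.atoms[heavy[i_loc]]
        aj = reference.atoms[heavy[j_loc]]
        if ai.chain_id == aj.chain_id and abs(ai.residue_index - aj.residue_index) < exclusion:
            continue
        d = float(np.linalg.norm(coords[i_loc] - coords[j_loc]))
        keep.append((heavy[i_loc], heavy[j_loc]))
        dists.append(d)
    return ContactSet(
        pairs=np.array(keep, dtype=int).reshape(-1, 2),
        reference_distances=np.array(dists),
        cutoff=cutoff,
        exclusion=exclusion,
    )


def contact_retention(
    traj: Trajectory, contacts: ContactSet, tolerance_factor: float = 1.2
):
    """Fraction of native contacts each residue retains, per frame.

    A contact is retained in a frame if its distance is ≤ cutoff ×
    ``tolerance_factor``.  Returns a DataFrame with columns chain_id,
    residue_index, frame, retained_fraction; residues with no native
    contacts do not appear (their fraction is undefined).
    """
    import pandas as pd

    if len(contacts) == 0:
        return pd.DataFrame(columns=["chain_id", "residue_index", "frame", "retained_fraction"])
    pi = contacts.pairs[:, 0]
    pj = contacts.pairs[:, 1]
    d = np.linalg.norm(traj.frames[:, pi, :] - traj.frames[:, pj, :], axis=2)  # (F, n)
    retained = d <= contacts.cutoff * tolerance_factor

    # map contacts onto the residues of both endpoint atoms
    res_keys: dict[tuple[str, int], list[int]] = {}
    for c, (i, j) in enumerate(contacts.pairs):
        for atom_idx in (i, j):
            a = traj.topology[atom_idx]
            res_keys.setdefault((a.chain_id, a.residue_index), []).append(c)
    rows = []
    for (chain, resid), contact_ids in sorted(res_keys.items()):
        frac = retained[:, contact_ids].mean(axis=1)
        for f in range(traj.n_frames):
            rows.append(dict(chain_id=chain, residue_index=resid, frame=f,
                             retained_fraction=float(frac[f])))
    return pd.DataFrame(rows)


def detect_unbinding(
    series: SeriesResult,
    baseline_window: int,
    factor: float = 1.5,
    persistence: float = 0.1,
) -> UnbindingCall:
    """Detect a sustained, unrecovered excursion of a distance series.

    The baseline is the mean over the first ``baseline_window`` frames.  The
    call is positive iff, after the last frame that dips below the baseline,
    the series exceeds ``factor`` × baseline for at least ``persistence`` of
    the total frames; the onset is the first such frame of that terminal
    excursion.  A transient spike that returns to baseline is not an
    unbinding event.
    """
    v = series.values
    if not np.all(np.isfinite(v)):
        raise ValueError("series contains non-finite values")
    if len(v) <= baseline_window:
        raise ValueError("series must be longer than the baseline window")
    baseline = float(v[:baseline_window].mean())
    threshold = factor * baseline
    below = np.nonzero(v < baseline)[0]
    tail_start = int(below[-1]) + 1 if below.size else 0
    exceed = np.nonzero(v[tail_start:] > threshold)[0]
    flag = exceed.size >= persistence * len(v)
    onset = int(tail_start + exceed[0]) if flag else None
    return UnbindingCall(flag=bool(flag), onset_frame=onset,
                         baseline=baseline, threshold=threshold)
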