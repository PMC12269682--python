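"""Structures, trajectories, sequences, region annotations and tabular I/O.

Coordinates are in Å throughout.  Residue indexing is 1-based per chain with
inclusive ranges, matching PDB conventions.  Multi-frame ensembles are
interchanged as multi-model PDB (one MODEL per frame); there is no dependency
on MD-engine trajectory formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.info as bstinfo
import biotite.structure.io.pdb as bstpdb
from biotite.sequence import ProteinSequence

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "RegionMap",
    "RegionEntry",
    "ChainSequence",
    "ParseError",
    "REGION_LABELS",
    "read_structure",
    "write_structure",
    "extract_sequence",
    "load_region_map",
    "read_fasta",
    "write_fasta",
    "write_table",
    "read_table",
]

REGION_LABELS = ("FW1", "CDR1", "FW2", "CDR2", "FW3", "CDR3", "FW4")


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a topology.

    ``residue_index`` is 1-based within its chain; ``mass`` is in daltons.
    """

    atom_id: int
    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    mass: float

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"atom {self.atom_name}: mass must be > 0, got {self.mass}")


@dataclass
class Structure:
    """A single-conformation structure: an ordered topology plus coordinates (Å)."""

    atoms: list[AtomRecord]
    coords: np.ndarray  # (A, 3)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


@dataclass
class Trajectory:
    """A multi-frame coordinate set over a fixed topology.

    ``frames`` has shape (F, A, 3) in Å; ``frame_times`` is in picoseconds and
    must be nondecreasing.
    """

    topology: list[AtomRecord]
    frames: np.ndarray  # (F, A, 3)
    frame_times: np.ndarray | None = None  # (F,) ps

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frames shape {self.frames.shape} incompatible with "
                f"{len(self.topology)}-atom topology"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates")
        if self.frame_times is None:
            self.frame_times = np.arange(self.frames.shape[0], dtype=float)
        else:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if self.frame_times.shape != (self.frames.shape[0],):
                raise ValueError("frame_times length must equal number of frames")
            if np.any(np.diff(self.frame_times) < 0):
                raise ValueError("frame_times must be nondecreasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])

    def frame(self, i: int) -> Structure:
        return Structure(self.topology, self.frames[i].copy())


@dataclass(frozen=True)
class RegionEntry:
    chain_id: str
    region: str
    start: int
    end: int  # inclusive


@dataclass
class RegionMap:
    """FW/CDR region annotation: per-chain, non-overlapping inclusive ranges."""

    entries: list[RegionEntry]
    scheme_name: str = "IMGT"

    def __post_init__(self):
        by_chain: dict[str, list[RegionEntry]] = {}
        for e in self.entries:
            if e.region not in REGION_LABELS:
                raise ValueError(
                    f"unknown region label {e.region!r}; expected one of {REGION_LABELS}"
                )
            if e.end < e.start:
                raise ValueError(f"region {e.region}: end {e.end} < start {e.start}")
            by_chain.setdefault(e.chain_id, []).append(e)
        for chain, ents in by_chain.items():
            ents.sort(key=lambda e: e.start)
            for a, b in zip(ents, ents[1:]):
                if b.start <= a.end:
                    raise ValueError(
                        f"chain {chain}: regions {a.region} ({a.start}-{a.end}) and "
                        f"{b.region} ({b.start}-{b.end}) overlap"
                    )

    def region_of(self, chain_id: str, residue_index: int) -> str | None:
        for e in self.entries:
            if e.chain_id == chain_id and e.start <= residue_index <= e.end:
                return e.region
        return None

    def residues_in(self, chain_id: str, region: str) -> list[int]:
        out: list[int] = []
        for e in self.entries:
            if e.chain_id == chain_id and e.region == region:
                out.extend(range(e.start, e.end + 1))
        return out


@dataclass
class ChainSequence:
    """Amino-acid sequence of one chain as (residue_index, one-letter) pairs."""

    chain_id: str
    residues: list[tuple[int, str]]

    def __post_init__(self):
        idx = [i for i, _ in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("residue indices must be strictly increasing")
        valid = set("ACDEFGHIKLMNPQRSTVWYX")
        for i, aa in self.residues:
            if aa not in valid:
                raise ValueError(f"invalid amino acid {aa!r} at residue {i}")

    @property
    def sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    @property
    def indices(self) -> list[int]:
        return [i for i, _ in self.residues]

    def __len__(self) -> int:
        return len(self.residues)


# --- PDB reading/writing -------------------------------------------------

_COORD_SLICES = (slice(30, 38), slice(38, 46), slice(46, 54))


def _check_pdb_lines(path: Path) -> None:
    """Pre-validate ATOM/HETATM records so parse errors can name the line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}: line {lineno}: truncated ATOM/HETATM record")
                for sl in _COORD_SLICES:
                    try:
                        float(line[sl])
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: unparseable coordinate field "
                            f"{line[sl]!r}"
                        ) from None


def _element_mass(element: str, atom_name: str) -> float:
    elem = element.strip()
    if not elem:
        # fall back to the first alphabetic character of the atom name
        elem = next((c for c in atom_name if c.isalpha()), "C")
    m = bstinfo.mass(elem.capitalize(), is_residue=False)
    if m is None or m <= 0:
        raise ParseError(f"unknown element {element!r} for atom {atom_name}")
    return float(m)


def _records_from_atom_array(arr: bst.AtomArray) -> list[AtomRecord]:
    records = []
    for k in range(arr.array_length()):
        records.append(
            AtomRecord(
                atom_id=k,
                atom_name=str(arr.atom_name[k]),
                element=str(arr.element[k]),
                residue_index=int(arr.res_id[k]),
                residue_name=str(arr.res_name[k]),
                chain_id=str(arr.chain_id[k]),
                mass=_element_mass(str(arr.element[k]), str(arr.atom_name[k])),
            )
        )
    return records


def read_structure(path: str | Path, model_index: int | str = "all"):
    """Read a PDB file into a :class:`Structure` or :class:`Trajectory`.

    Parameters
    ----------
    path:
        PDB file.  MODEL records map to frames in file order.
    model_index:
        ``"all"`` returns a :class:`Trajectory` when the file holds more than
        one model (a single-model file yields a :class:`Structure`); an
        integer (1-based, as in the PDB MODEL record) selects one model.
    """
    path = Path(path)
    _check_pdb_lines(path)
    try:
        pdb_file = bstpdb.PDBFile.read(str(path))
        n_models = pdb_file.get_model_count()
    except Exception as exc:  # pragma: no cover - biotite-internal failures
        raise ParseError(f"{path}: {exc}") from exc
    if n_models == 0:
        raise ParseError(f"{path}: no models found")

    if model_index == "all" and n_models > 1:
        stack = pdb_file.get_structure(model=None)
        if stack.array_length() == 0:
            raise ParseError(f"{path}: empty model")
        topology = _records_from_atom_array(stack[0])
        return Trajectory(topology, np.asarray(stack.coord, dtype=float))

    model = 1 if model_index == "all" else int(model_index)
    try:
        arr = pdb_file.get_structure(model=model)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read model {model}: {exc}") from exc
    if arr.array_length() == 0:
        raise ParseError(f"{path}: empty model {model}")
    return Structure(_records_from_atom_array(arr), np.asarray(arr.coord, dtype=float))


def _atom_array_from(topology: Sequence[AtomRecord], coords: np.ndarray) -> bst.AtomArray:
    n = len(topology)
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = np.array([a.chain_id for a in topology], dtype="U4")
    arr.res_id = np.array([a.residue_index for a in topology], dtype=int)
    arr.res_name = np.array([a.residue_name for a in topology], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in topology], dtype="U6")
    arr.element = np.array([a.element for a in topology], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def write_structure(obj: Structure | Trajectory, path: str | Path) -> None:
    """Write a Structure (single model) or Trajectory (multi-model) as PDB."""
    path = Path(path)
    pdb_file = bstpdb.PDBFile()
    if isinstance(obj, Structure):
        pdb_file.set_structure(_atom_array_from(obj.atoms, obj.coords))
    else:
        stack = bst.stack(
            [_atom_array_from(obj.topology, obj.frames[i]) for i in range(obj.n_frames)]
        )
        pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def extract_sequence(s: Structure, chain_id: str) -> ChainSequence:
    """One-letter sequence of a chain; non-standard residues map to X."""
    chains = s.chain_ids()
    if chain_id not in chains:
        raise KeyError(f"chain {chain_id!r} not found; available chains: {chains}")
    seen: dict[int, str] = {}
    for a in s.atoms:
        if a.chain_id != chain_id or a.residue_index in seen:
            continue
        try:
            one = ProteinSequence.convert_letter_3to1(a.residue_name.upper())
        except Exception:
            one = "X"
        if one not in "ACDEFGHIKLMNPQRSTVWY":
            one = "X"
        seen[a.residue_index] = one
    residues = sorted(seen.items())
    return ChainSequence(chain_id=chain_id, residues=residues)


def load_region_map(path: str | Path, scheme_name: str = "IMGT") -> RegionMap:
    """Load a region annotation table (TSV with chain_id, region, start, end)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chain_id", "region", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    entries = [
        RegionEntry(str(r.chain_id), str(r.region), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]
    return RegionMap(entries, scheme_name=scheme_name)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} mapping (order preserved)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_table(records: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a result table deterministically (TSV or JSON; NaN → "NA").

    Floats are emitted at 6 significant digits.
    """
    df = pd.DataFrame(records)
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    elif format == "json":
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_float_dtype(out[col]):
                out[col] = out[col].map(
                    lambda v: None if pd.isna(v) else float(f"{v:.6g}")
                )
        out = out.where(pd.notna(out), None)
        with open(path, "w") as fh:
            json.dump(out.to_dict(orient="records"), fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'json'")


def read_table(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown format {format!r}")
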