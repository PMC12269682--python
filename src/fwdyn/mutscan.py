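"""Saturated per-position mutational scanning and candidate filtering.

The scanning harness masks one position at a time and asks a pluggable
scorer for the 20 amino-acid propensities at that position, mirroring the
masked-prediction protocol of protein language models.  Scorers declare
whether they emit logits (converted here via a plain softmax, temperature 1)
or probabilities.  Downstream statistics summarise how strongly the
wild-type residue is preferred — rank 1 means the wild type is scored best —
and contrast framework (FW) against CDR positions.

ΔΔG handling ingests externally produced stability-scan tables (kcal/mol):
negative ΔΔG is stabilizing, positive destabilizing; zero is classified
destabilizing by convention.  Double-mutant candidates must be predicted
stabilizing as a pair and each mutant residue must occur above a threshold
fraction in a natural antibody repertoire; agreement in sign between the
double and the summed single scans is recorded but not required, because a
pair of individually destabilizing substitutions can be jointly stabilizing.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import pandas as pd
from scipy.special import softmax
from scipy.stats import spearmanr

from .structio import ChainSequence, RegionMap

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

__all__ = [
    "AA_ORDER",
    "Scorer",
    "MutationGrid",
    "ScanResult",
    "DdGTable",
    "RepertoireProfile",
    "CandidateSet",
    "scan_positions",
    "wt_rank_profile",
    "region_summary",
    "germline_identity_correlation",
    "classify_stability",
    "repertoire_occurrence",
    "filter_double_mutants",
]


@runtime_checkable
class Scorer(Protocol):
    """Per-position scoring contract.

    ``emits`` is ``"logits"`` or ``"probabilities"``.  The call receives the
    full one-letter sequence and the 0-based index of the masked position and
    returns 20 raw scores ordered as :data:`AA_ORDER`.
    """

    emits: str

    def __call__(self, sequence: str, position: int) -> np.ndarray: ...


@dataclass
class MutationGrid:
    """L×20 per-position probability matrix over :data:`AA_ORDER`."""

    sequence: ChainSequence
    scores: np.ndarray  # (L, 20), rows sum to 1
    amino_acid_order: str = AA_ORDER

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        L = len(self.sequence)
        if self.scores.shape != (L, 20):
            raise ValueError(f"scores shape {self.scores.shape} != ({L}, 20)")
        if np.any(self.scores < -1e-12) or np.any(self.scores > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.scores.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"row {bad} sums to {sums[bad]:.8f}, not 1")


@dataclass
class ScanResult:
    """Per-position wild-type statistics.

    ``table`` columns: residue_index, wt_aa, wt_probability, wt_rank, region.
    ``wt_rank`` follows the strictly-greater convention (1 = best, ties share
    the best rank); positions with unknown wild type (X) carry NaN rank and
    probability and ``missing=True``.
    """

    table: pd.DataFrame


class DdGTable:
    """Single/double mutant ΔΔG records (kcal/mol).

    Columns: pos1, wt1, mut1, pos2, wt2, mut2 (NA for singles), ddg, scan_kind.
    """

    COLUMNS = ["pos1", "wt1", "mut1", "pos2", "wt2", "mut2", "ddg", "scan_kind"]

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"DdGTable missing columns {sorted(missing)}")
        df = df[self.COLUMNS].copy()
        if not np.all(np.isfinite(df["ddg"].to_numpy(dtype=float))):
            raise ValueError("ddg must be finite")
        doubles = df[df["scan_kind"] == "double"]
        if len(doubles) and (doubles["pos1"] == doubles["pos2"]).any():
            raise ValueError("double records must carry two distinct positions")
        self.df = df

    @classmethod
    def from_records(cls, records) -> "DdGTable":
        return cls(pd.DataFrame(records, columns=cls.COLUMNS))

    @classmethod
    def from_tsv(cls, path) -> "DdGTable":
        return cls(pd.read_csv(path, sep="\t", na_values=["NA"]))

    def singles(self) -> pd.DataFrame:
        return self.df[self.df["scan_kind"] == "single"]

    def doubles(self) -> pd.DataFrame:
        return self.df[self.df["scan_kind"] == "double"]

    def __len__(self) -> int:
        return len(self.df)


class RepertoireProfile:
    """Per-(position, amino acid) occurrence fractions across a repertoire."""

    def __init__(self, df: pd.DataFrame):
        required = {"position", "aa", "fraction"}
        if required - set(df.columns):
            raise ValueError(f"profile needs columns {sorted(required)}")
        frac = df["fraction"].to_numpy(dtype=float)
        if np.any(frac < 0) or np.any(frac > 1):
            raise ValueError("fractions must lie in [0, 1]")
        sums = df.groupby("position")["fraction"].sum()
        if np.any(sums.to_numpy() > 1 + 1e-9):
            raise ValueError("per-position fractions must sum to ≤ 1")
        self.df = df.copy()
        self._lookup = {
            (int(p), str(a)): float(f)
            for p, a, f in zip(df["position"], df["aa"], df["fraction"])
        }
        self._positions = set(int(p) for p in df["position"])

    @classmethod
    def from_tsv(cls, path) -> "RepertoireProfile":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def positions(self) -> set[int]:
        return self._positions

    def fraction(self, position: int, aa: str) -> float:
        if position not in self._positions:
            raise KeyError(f"position {position} not present in repertoire profile")
        return self._lookup.get((int(position), aa), 0.0)


@dataclass
class CandidateSet:
    """Filtered double-mutant candidates with per-filter flags.

    ``table`` columns: pos1, wt1, mut1, pos2, wt2, mut2, ddg_double,
    ddg_single_1, ddg_single_2, occ_1, occ_2, pass_ddg, consistent,
    pass_occurrence, incomplete, passes.
    """

    table: pd.DataFrame
    occ_threshold: float

    def passing(self) -> pd.DataFrame:
        return self.table[self.table["passes"]]


# --- scanning ------------------------------------------------------------


def scan_positions(seq: ChainSequence, scorer: Scorer) -> MutationGrid:
    """Mask each position in turn, score it, and assemble the L×20 grid.

    The scorer is invoked exactly once per position.  Logit scorers are
    converted to probabilities with a temperature-1 softmax; probability
    scorers must be non-negative and are renormalised to machine precision.
    """
    emits = getattr(scorer, "emits", "logits")
    if emits not in ("logits", "probabilities"):
        raise ValueError(f"scorer.emits must be 'logits' or 'probabilities', got {emits!r}")
    sequence = seq.sequence
    rows = np.empty((len(sequence), 20))
    for i in range(len(sequence)):
        raw = np.asarray(scorer(sequence, i), dtype=float).ravel()
        if raw.shape != (20,):
            raise ValueError(
                f"scorer returned {raw.shape[0] if raw.ndim == 1 else raw.shape} "
                f"scores at position {i}; expected 20"
            )
        if not np.all(np.isfinite(raw)):
            raise ValueError(f"scorer returned non-finite score at position {i}")
        if emits == "logits":
            rows[i] = softmax(raw)
        else:
            if np.any(raw < 0):
                raise ValueError(f"negative probability at position {i}")
            total = raw.sum()
            if total <= 0:
                raise ValueError(f"all-zero probabilities at position {i}")
            rows[i] = raw / total
    return MutationGrid(sequence=seq, scores=rows)


def wt_rank_profile(grid: MutationGrid, region_map: RegionMap | None = None) -> ScanResult:
    """Wild-type probability and rank (1 = best) per position.

    Rank is 1 plus the number of amino acids scored strictly higher than the
    wild type, so tied scores share the best rank.
    """
    seq = grid.sequence
    records = []
    for row, (residue_index, wt) in zip(grid.scores, seq.residues):
        region = (
            region_map.region_of(seq.chain_id, residue_index) if region_map else None
        )
        if wt == "X":
            records.append(
                dict(residue_index=residue_index, wt_aa=wt, wt_probability=np.nan,
                     wt_rank=np.nan, region=region, missing=True)
            )
            continue
        p_wt = row[_AA_INDEX[wt]]
        rank = 1 + int(np.sum(row > p_wt))
        records.append(
            dict(residue_index=residue_index, wt_aa=wt, wt_probability=float(p_wt),
                 wt_rank=rank, region=region, missing=False)
        )
    return ScanResult(pd.DataFrame.from_records(records))


def region_summary(results: list[ScanResult], region_map: RegionMap) -> pd.DataFrame:
    """Median and inter-quartile range of rank/probability per aligned position.

    All profiles must share one region scheme; positions are aligned by
    residue index across antibodies.  Empty regions are omitted with a
    warning.
    """
    frames = [r.table for r in results]
    combined = pd.concat(frames, keys=range(len(frames)), names=["antibody"])
    combined = combined[~combined["missing"]]
    rows = []
    for (pos, region), grp in combined.groupby(["residue_index", "region"], dropna=False):
        ranks = grp["wt_rank"].to_numpy(dtype=float)
        probs = grp["wt_probability"].to_numpy(dtype=float)
        q25r, medr, q75r = np.percentile(ranks, [25, 50, 75])
        q25p, medp, q75p = np.percentile(probs, [25, 50, 75])
        rows.append(
            dict(residue_index=int(pos), region=region, n=len(grp),
                 median_rank=medr, iqr_rank=q75r - q25r,
                 median_probability=medp, iqr_probability=q75p - q25p)
        )
    out = pd.DataFrame(rows).sort_values("residue_index").reset_index(drop=True)
    observed = set(out["region"].dropna())
    for entry in region_map.entries:
        if entry.region not in observed:
            warnings.warn(f"region {entry.region} ({entry.chain_id}) has no positions; omitted")
    return out


def germline_identity_correlation(
    wt_probs: np.ndarray, identities: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation between WT confidence and germline identity.

    Exact permutation p-value for n ≤ 9 (tie-free inputs); the large-sample
    t approximation otherwise.  Returns (rho, p).  A constant input vector
    makes the correlation undefined: (nan, nan) is returned.
    """
    x = np.asarray(wt_probs, dtype=float)
    y = np.asarray(identities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = spearmanr(x, y)
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if n <= 9 and not has_ties:
        # exact null distribution of rho by full enumeration of rankings
        rx = np.argsort(np.argsort(x)).astype(float)
        ry = np.argsort(np.argsort(y)).astype(float)
        perms = np.array(list(itertools.permutations(range(n))), dtype=float)
        d2 = ((perms - ry) ** 2).sum(axis=1)
        rhos = 1 - 6 * d2 / (n * (n**2 - 1))
        obs = 1 - 6 * ((rx - ry) ** 2).sum() / (n * (n**2 - 1))
        p = float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))
        rho = obs
    return float(rho), float(p)


# --- ΔΔG classification and filtering ------------------------------------


def classify_stability(table: DdGTable) -> tuple[pd.DataFrame, float]:
    """Label each record stabilizing (ΔΔG < 0) or destabilizing (ΔΔG ≥ 0).

    Zero ΔΔG is destabilizing by convention (only strictly negative values
    count as stabilizing).  Returns the labelled table and the overall
    destabilizing fraction.
    """
    df = table.df.copy()
    ddg = df["ddg"].to_numpy(dtype=float)
    df["label"] = np.where(ddg < 0, "stabilizing", "destabilizing")
    frac = float(np.mean(ddg >= 0)) if len(df) else float("nan")
    return df, frac


def repertoire_occurrence(profile: RepertoireProfile, position: int, aa: str) -> float:
    """Occurrence fraction of ``aa`` at ``position``; 0 if never observed."""
    return profile.fraction(position, aa)


def filter_double_mutants(
    singles: DdGTable,
    doubles: DdGTable,
    profile: RepertoireProfile,
    occ_threshold: float = 0.01,
) -> CandidateSet:
    """Filter double mutants for stabilizing, repertoire-supported candidates.

    A candidate passes iff (a) the double-scan ΔΔG is negative and (c) each
    mutant residue occurs in more than ``occ_threshold`` of the repertoire.
    Sign agreement between the double ΔΔG and the sum of the single ΔΔGs
    (b) is recorded per candidate but not required — individually
    destabilizing substitutions can be jointly stabilizing.  Doubles without
    both matching single records are flagged incomplete and excluded.
    """
    single_lookup: dict[tuple[int, str, str], float] = {}
    for r in singles.singles().itertuples(index=False):
        single_lookup[(int(r.pos1), str(r.wt1), str(r.mut1))] = float(r.ddg)

    rows = []
    for r in doubles.doubles().itertuples(index=False):
        key1 = (int(r.pos1), str(r.wt1), str(r.mut1))
        key2 = (int(r.pos2), str(r.wt2), str(r.mut2))
        s1 = single_lookup.get(key1)
        s2 = single_lookup.get(key2)
        incomplete = s1 is None or s2 is None
        ddg_d = float(r.ddg)
        try:
            occ1 = profile.fraction(int(r.pos1), str(r.mut1))
        except KeyError:
            occ1 = 0.0
        try:
            occ2 = profile.fraction(int(r.pos2), str(r.mut2))
        except KeyError:
            occ2 = 0.0
        pass_ddg = ddg_d < 0
        if incomplete:
            consistent = False
        else:
            consistent = math.copysign(1, ddg_d) == math.copysign(1, s1 + s2) or (
                ddg_d == 0 and s1 + s2 == 0
            )
        pass_occ = occ1 > occ_threshold and occ2 > occ_threshold
        rows.append(
            dict(pos1=int(r.pos1), wt1=r.wt1, mut1=r.mut1,
                 pos2=int(r.pos2), wt2=r.wt2, mut2=r.mut2,
                 ddg_double=ddg_d,
                 ddg_single_1=np.nan if s1 is None else s1,
                 ddg_single_2=np.nan if s2 is None else s2,
                 occ_1=occ1, occ_2=occ2,
                 pass_ddg=pass_ddg, consistent=bool(consistent),
                 pass_occurrence=pass_occ, incomplete=incomplete,
                 passes=bool(pass_ddg and pass_occ and not incomplete))
        )
    cols = ["pos1", "wt1", "mut1", "pos2", "wt2", "mut2", "ddg_double",
            "ddg_single_1", "ddg_single_2", "occ_1", "occ_2", "pass_ddg",
            "consistent", "pass_occurrence", "incomplete", "passes"]
    table = pd.DataFrame(rows, columns=cols)
    return CandidateSet(table=table, occ_threshold=occ_threshold)
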