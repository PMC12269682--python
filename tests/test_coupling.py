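"""Alphabet encoding, mutual information, differential coupling, hub calls."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

from fwdyn import coupling, synthdata
from fwdyn.coupling import AlphabetPrototypes, MIMatrix, StateSequence
from fwdyn.structio import AtomRecord, Trajectory


def _seq(states, M=None):
    states = np.asarray(states)
    return StateSequence(1, states, M or int(states.max()))


def _toy_alphabet(M=5, seed=0):
    rng = np.random.default_rng(seed)
    coords = []
    for _ in range(M):
        pts = np.cumsum(rng.normal(scale=2.0, size=(4, 3)), axis=0)
        coords.append(pts - pts.mean(axis=0))
    return AlphabetPrototypes(labels=list(range(1, M + 1)), coords=np.stack(coords))


def _ca_traj(frames_of_fragments, chain="H"):
    """Build a trajectory whose chain Cα positions are given per frame."""
    frames = np.asarray(frames_of_fragments, dtype=float)
    n_res = frames.shape[1]
    atoms = [AtomRecord(i, "CA", "C", i + 1, "ALA", chain, 12.0) for i in range(n_res)]
    return Trajectory(atoms, frames)


class TestAlphabet:
    def test_bundled_synthetic_alphabet_loads(self):
        ab = coupling.default_alphabet()
        assert ab.M == 25
        assert ab.coords.shape == (25, 4, 3)

    def test_duplicate_labels_rejected(self):
        ab = _toy_alphabet(3)
        with pytest.raises(ValueError, match="unique"):
            AlphabetPrototypes(labels=[1, 1, 2], coords=ab.coords)

    def test_alphabet_file_roundtrip(self, tmp_path):
        ab = _toy_alphabet(4)
        rows = []
        for label, pts in zip(ab.labels, ab.coords):
            for k, p in enumerate(pts, start=1):
                rows.append(f"{label}\t{k}\t{p[0]}\t{p[1]}\t{p[2]}")
        path = tmp_path / "ab.tsv"
        path.write_text("state\tpoint\tx\ty\tz\n" + "\n".join(rows) + "\n")
        back = coupling.load_alphabet(path)
        np.testing.assert_allclose(back.coords, ab.coords, atol=1e-12)


class TestEncodeAlphabet:
    def test_exact_prototype_match(self, rng):
        ab = _toy_alphabet(5)
        # one frame, 4 residues shaped exactly like prototype 3 (rotated+shifted)
        from scipy.spatial.transform import Rotation

        R = Rotation.random(rng=5).as_matrix()
        frag = ab.coords[2] @ R.T + np.array([4.0, 5.0, 6.0])
        traj = _ca_traj(frag[None])
        seqs = coupling.encode_alphabet(traj, "H", ab)
        assert len(seqs) == 1
        assert seqs[0].states[0] == 3

    def test_tie_breaks_to_lowest_label(self):
        ab = _toy_alphabet(2)
        # make both prototypes identical: any fragment is equidistant
        ab = AlphabetPrototypes(labels=[3, 9], coords=np.stack([ab.coords[0]] * 2))
        traj = _ca_traj(np.random.default_rng(0).normal(size=(2, 4, 3)))
        seqs = coupling.encode_alphabet(traj, "H", ab)
        assert (seqs[0].states == 3).all()

    def test_matches_brute_force_scan(self, rng):
        ab = _toy_alphabet(5, seed=7)
        frames = rng.normal(scale=3.0, size=(6, 8, 3))
        traj = _ca_traj(frames)
        seqs = coupling.encode_alphabet(traj, "H", ab)
        assert len(seqs) == 5  # 8 residues -> fragments 1..5
        from fwdyn.geomdyn import kabsch_rotate

        for s in seqs:
            i0 = s.fragment_index - 1
            for f in range(6):
                frag = frames[f, i0 : i0 + 4]
                frag_c = frag - frag.mean(axis=0)
                best, best_r = None, np.inf
                for label, proto in zip(ab.labels, ab.coords):
                    pc = proto - proto.mean(axis=0)
                    rot = kabsch_rotate(frag_c, pc)
                    r = np.sqrt(((rot - pc) ** 2).sum() / 4)
                    if r < best_r - 1e-12:
                        best, best_r = label, r
                assert s.states[f] == best

    def test_missing_ca_invalidates_fragment(self):
        frames = np.random.default_rng(0).normal(size=(2, 6, 3))
        atoms = [AtomRecord(i, "CA", "C", i + 1, "ALA", "H", 12.0) for i in range(6)]
        atoms[3] = AtomRecord(3, "CB", "C", 4, "ALA", "H", 12.0)  # residue 4 lost its CA
        traj = Trajectory(atoms, frames)
        seqs = coupling.encode_alphabet(traj, "H", _toy_alphabet(3))
        # only fragments avoiding residue 4 remain; residues are 1,2,3,5,6
        assert all(4 not in range(s.fragment_index, s.fragment_index + 4) for s in seqs)


class TestMutualInformation:
    def test_identical_balanced_binary_is_one_bit(self):
        x = _seq([1, 1, 2, 2])
        assert coupling.mutual_information(x, x) == pytest.approx(1.0)

    def test_independent_by_construction_is_zero(self):
        x = _seq([1, 1, 2, 2])
        y = _seq([1, 2, 1, 2])
        assert coupling.mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_contingency_definition(self, rng):
        for _ in range(50):
            F = int(rng.integers(10, 200))
            x = _seq(rng.integers(1, 4, F), M=3)
            y = _seq(rng.integers(1, 4, F), M=3)
            mine = coupling.mutual_information(x, y)
            oracle = mutual_info_score(x.states, y.states) / math.log(2)
            assert mine == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            coupling.mutual_information(_seq([1, 2]), _seq([1, 2, 1]))

    def test_symmetric_nonnegative_bounded(self, rng):
        for _ in range(100):
            F = int(rng.integers(5, 60))
            x = _seq(rng.integers(1, 5, F), M=4)
            y = _seq(rng.integers(1, 5, F), M=4)
            ixy = coupling.mutual_information(x, y)
            assert ixy == pytest.approx(coupling.mutual_information(y, x), abs=1e-12)
            assert ixy >= -1e-12
            hx = coupling.joint_entropy(x, x)
            hy = coupling.joint_entropy(y, y)
            assert ixy <= min(hx, hy) + 1e-9


class TestCorrectedNormalizedMI:
    def test_identical_nonconstant_is_exactly_one(self, rng):
        x = _seq(rng.integers(1, 4, 100), M=3)
        assert coupling.corrected_normalized_mi(x, x) == 1.0

    def test_constant_sequences_give_zero(self):
        x = _seq(np.ones(50, dtype=int), M=2)
        assert coupling.corrected_normalized_mi(x, x) == 0.0

    def test_independent_sequences_near_zero(self):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = _seq(r.integers(1, 5, 2000), M=4)
            y = _seq(r.integers(1, 5, 2000), M=4)
            vals.append(coupling.corrected_normalized_mi(x, y))
        assert np.mean(vals) <= 0.01

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(100):
            F = int(rng.integers(4, 100))
            x = _seq(rng.integers(1, 6, F), M=5)
            y = _seq(rng.integers(1, 6, F), M=5)
            v = coupling.corrected_normalized_mi(x, y)
            assert 0.0 <= v <= 1.0

    def test_permutation_correction_mode(self, rng):
        x = _seq(rng.integers(1, 4, 400), M=3)
        y = _seq(rng.integers(1, 4, 400), M=3)
        v = coupling.corrected_normalized_mi(x, y, correction="permutation",
                                             n_perm=50, seed=11)
        assert 0.0 <= v <= 0.05


class TestMIMatrix:
    def test_pair_count(self, rng):
        seqs = [StateSequence(i + 1, rng.integers(1, 4, 50), 3) for i in range(3)]
        m = coupling.mi_matrix(seqs, frame_window=1.0)
        off_diag = ~np.isnan(m.values)
        assert off_diag.sum() == 6  # 3 unordered pairs, symmetric
        np.testing.assert_allclose(m.values, m.values.T, equal_nan=True)

    def test_duplicated_fragment_pairs_at_one(self, rng):
        states = rng.integers(1, 4, 200)
        seqs = [StateSequence(1, states, 3), StateSequence(2, states.copy(), 3)]
        m = coupling.mi_matrix(seqs, frame_window=1.0)
        assert m.pair(1, 2) == 1.0
        assert np.isnan(m.values[0, 0])

    def test_tail_window_used(self, rng):
        # head and tail differ: tail constant, head random
        states = np.concatenate([rng.integers(1, 4, 100), np.ones(100, dtype=int)])
        seqs = [StateSequence(1, states, 3), StateSequence(2, states.copy(), 3)]
        m = coupling.mi_matrix(seqs, frame_window=0.5)
        # tail is constant: H = 0 -> defined as 0
        assert m.pair(1, 2) == 0.0

    def test_short_window_rejected(self, rng):
        seqs = [StateSequence(i + 1, rng.integers(1, 3, 10), 2) for i in range(2)]
        with pytest.raises(ValueError, match="window"):
            coupling.mi_matrix(seqs, frame_window=0.05)


def _mi_matrices(values_by_replica):
    out = []
    for v in values_by_replica:
        m = np.full((2, 2), np.nan)
        m[0, 1] = m[1, 0] = v
        out.append(MIMatrix(fragments=[1, 2], values=m))
    return out


class TestDiffCoupling:
    def test_identical_means_zero_lfc(self):
        dc = coupling.diff_coupling(_mi_matrices([0.3, 0.3]), _mi_matrices([0.3, 0.3]))
        assert dc.table["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_four_fold_change_is_two(self):
        dc = coupling.diff_coupling(
            _mi_matrices([0.4, 0.4, 0.4]), _mi_matrices([0.1, 0.1, 0.1])
        )
        assert dc.table["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-4)

    def test_antisymmetric_under_condition_swap(self, rng):
        a = _mi_matrices(rng.random(3))
        b = _mi_matrices(rng.random(3))
        ab = coupling.diff_coupling(a, b).table["log2fc"].iloc[0]
        ba = coupling.diff_coupling(b, a).table["log2fc"].iloc[0]
        assert ab == pytest.approx(-ba, abs=1e-12)

    def test_single_replica_gives_nan_p(self):
        dc = coupling.diff_coupling(_mi_matrices([0.4]), _mi_matrices([0.1]))
        assert np.isnan(dc.table["pvalue"].iloc[0])
        assert dc.table["log2fc"].iloc[0] == pytest.approx(2.0, abs=1e-4)

    def test_fragment_set_mismatch_rejected(self):
        a = _mi_matrices([0.4, 0.4])
        bad = MIMatrix(fragments=[1, 3], values=a[0].values.copy())
        with pytest.raises(ValueError, match="fragment set"):
            coupling.diff_coupling(a, [bad, bad])

    def test_permutation_p_matches_exhaustive_enumeration(self, rng):
        for _ in range(25):
            a = rng.normal(size=3)
            b = rng.normal(loc=rng.uniform(0, 2), size=3)
            p = coupling.permutation_pvalue(a, b)
            pooled = np.concatenate([a, b])
            obs = abs(a.mean() - b.mean())
            count = sum(
                abs(pooled[list(c)].mean()
                    - pooled[[i for i in range(6) if i not in c]].mean())
                >= obs - 1e-12
                for c in itertools.combinations(range(6), 3)
            )
            assert p == pytest.approx(count / 20)

    def test_padj_never_below_p(self, rng):
        a = [_mi_matrices(rng.random(3))[0] for _ in range(3)]
        b = [_mi_matrices(rng.random(3))[0] for _ in range(3)]
        dc = coupling.diff_coupling(a, b, test="welch")
        assert (dc.table["padj"] >= dc.table["pvalue"] - 1e-12).all()


class TestCallHubs:
    def _dc(self, rows):
        df = pd.DataFrame(rows, columns=["frag_i", "frag_j", "mean_bound",
                                         "mean_unbound", "log2fc", "pvalue", "padj"])
        return coupling.DiffCoupling(table=df, test="welch", pseudocount=1e-6)

    def test_threshold_rules(self):
        dc = self._dc([
            (1, 5, 0.4, 0.05, 2.5, 0.001, 0.005),   # hub, bound
            (2, 6, 0.4, 0.05, 2.5, 0.01, 0.02),     # fails alpha
            (3, 7, 0.01, 0.1, -3.1, 0.0005, 0.001), # hub, unbound
            (4, 8, 0.2, 0.1, 1.0, 0.0001, 0.001),   # fails lfc
        ])
        hubs = coupling.call_hubs(dc)
        assert len(hubs.pairs) == 2
        directions = dict(zip(hubs.pairs["frag_i"], hubs.pairs["direction"]))
        assert directions == {1: "bound", 3: "unbound"}

    def test_boundary_is_exclusive(self):
        dc = self._dc([(1, 5, 0.4, 0.1, 2.0, 0.001, 0.005)])
        assert len(coupling.call_hubs(dc, lfc_threshold=2.0).pairs) == 0


class TestHubFrequency:
    def _hubs(self, pairs):
        df = pd.DataFrame(
            [dict(frag_i=i, frag_j=j, mean_bound=0.4, mean_unbound=0.05,
                  log2fc=3.0, pvalue=0.001, padj=0.005, direction="bound")
             for i, j in pairs]
        )
        return coupling.HubTable(pairs=df, lfc_threshold=2, alpha=0.01)

    def test_single_pair_coverage(self):
        counts = coupling.position_hub_frequency(self._hubs([(5, 20)]), L=30)
        expected = np.zeros(30, dtype=int)
        expected[4:8] = 1
        expected[19:23] = 1
        np.testing.assert_array_equal(counts, expected)

    def test_no_hubs_all_zero(self):
        counts = coupling.position_hub_frequency(self._hubs([]), L=10)
        assert (counts == 0).all()

    def test_matches_brute_force_tally(self, rng):
        pairs = [(int(i), int(j)) for i, j in
                 zip(rng.integers(1, 17, 12), rng.integers(1, 17, 12)) if i != j]
        counts = coupling.position_hub_frequency(self._hubs(pairs), L=20)
        expected = np.zeros(20, dtype=int)
        for i, j in pairs:
            for frag in (i, j):
                for r in range(frag, min(frag + 4, 21)):
                    expected[r - 1] += 1
        np.testing.assert_array_equal(counts, expected)

    def test_fragment_mode_counts_unique_fragments(self):
        counts = coupling.position_hub_frequency(
            self._hubs([(5, 20), (5, 9)]), L=30, mode="fragments"
        )
        assert counts[4] == 1  # fragment 5 counted once despite two pairs
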