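"""Mutational scan harness, rank statistics, ΔΔG classification, filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import softmax
from scipy.stats import spearmanr

from fwdyn import mutscan, structio, synthdata
from fwdyn.mutscan import AA_ORDER, DdGTable, RepertoireProfile


class _FixedScorer:
    def __init__(self, vec, emits="logits"):
        self.vec = np.asarray(vec, dtype=float)
        self.emits = emits
        self.n_calls = 0

    def __call__(self, sequence, position):
        self.n_calls += 1
        return self.vec


def _seq(s, chain="H"):
    return structio.ChainSequence(chain, list(enumerate(s, start=1)))


class TestScanPositions:
    def test_logit_scorer_row_is_softmax(self):
        vec = np.zeros(20)
        vec[0] = 1.0
        grid = mutscan.scan_positions(_seq("AAA"), _FixedScorer(vec))
        expected = softmax(vec)  # max entry e/(e+19)
        np.testing.assert_allclose(grid.scores[0], expected, atol=1e-12)
        assert grid.scores[0, 0] == pytest.approx(math.e / (math.e + 19))

    def test_uniform_probability_scorer(self):
        grid = mutscan.scan_positions(
            _seq("ACD"), _FixedScorer(np.full(20, 0.05), emits="probabilities")
        )
        np.testing.assert_allclose(grid.scores, 1 / 20)

    def test_scorer_invoked_once_per_position_and_rows_normalized(self, rng):
        scorer = _FixedScorer(rng.normal(size=20))
        grid = mutscan.scan_positions(_seq("ACDEF"), scorer)
        assert scorer.n_calls == 5
        np.testing.assert_allclose(grid.scores.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_length_vector_rejected(self):
        with pytest.raises(ValueError, match="expected 20"):
            mutscan.scan_positions(_seq("AC"), _FixedScorer(np.zeros(19)))

    def test_nonfinite_score_rejected(self):
        vec = np.zeros(20)
        vec[3] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            mutscan.scan_positions(_seq("AC"), _FixedScorer(vec))


class TestWtRank:
    def test_unique_maximum_gets_rank_one(self):
        row = np.full(20, 0.03)
        row[AA_ORDER.index("M")] = 1 - 0.03 * 19
        grid = mutscan.MutationGrid(_seq("M"), row[None])
        res = mutscan.wt_rank_profile(grid)
        assert res.table["wt_rank"].iloc[0] == 1

    def test_uniform_row_ties_share_best_rank(self):
        grid = mutscan.MutationGrid(_seq("W"), np.full((1, 20), 1 / 20))
        assert mutscan.wt_rank_profile(grid).table["wt_rank"].iloc[0] == 1

    def test_unknown_wildtype_flagged_missing(self):
        grid = mutscan.MutationGrid(_seq("X"), np.full((1, 20), 1 / 20))
        row = mutscan.wt_rank_profile(grid).table.iloc[0]
        assert row["missing"] and np.isnan(row["wt_rank"])

    def test_rank_matches_sort_oracle_on_random_rows(self, rng):
        n = 1000
        raw = rng.random((n, 20))
        probs = raw / raw.sum(axis=1, keepdims=True)
        wt_letters = [AA_ORDER[i] for i in rng.integers(0, 20, n)]
        for k in range(n):
            grid = mutscan.MutationGrid(_seq(wt_letters[k]), probs[k][None])
            got = mutscan.wt_rank_profile(grid).table["wt_rank"].iloc[0]
            # oracle: position of the WT score in the descending sort
            order = np.argsort(-probs[k], kind="stable")
            expected = 1 + int(np.sum(probs[k] > probs[k, AA_ORDER.index(wt_letters[k])]))
            assert got == expected
            assert got <= 1 + int(np.nonzero(order == AA_ORDER.index(wt_letters[k]))[0][0]) + 1


class TestRegionSummary:
    def _profiles(self, ranks_by_position, region_map):
        out = []
        for ranks in ranks_by_position:
            rows = []
            for pos, r in enumerate(ranks, start=1):
                rows.append(
                    dict(residue_index=pos, wt_aa="A", wt_probability=1.0 / r,
                         wt_rank=r, region=region_map.region_of("H", pos), missing=False)
                )
            out.append(mutscan.ScanResult(pd.DataFrame(rows)))
        return out

    def test_constant_rank_one_gives_median_one_iqr_zero(self, vh_region_map):
        profiles = self._profiles([[1] * 120] * 5, vh_region_map)
        summary = mutscan.region_summary(profiles, vh_region_map)
        fw = summary[summary["region"] == "FW1"]
        assert (fw["median_rank"] == 1).all()
        assert (fw["iqr_rank"] == 0).all()

    def test_median_of_three(self, vh_region_map):
        profiles = self._profiles([[1] * 120, [2] * 120, [3] * 120], vh_region_map)
        summary = mutscan.region_summary(profiles, vh_region_map)
        assert (summary["median_rank"] == 2).all()

    def test_matches_brute_force_column_medians(self, vh_region_map, rng):
        ranks = rng.integers(1, 21, size=(10, 120))
        profiles = self._profiles(ranks.tolist(), vh_region_map)
        summary = mutscan.region_summary(profiles, vh_region_map)
        for pos in (1, 40, 120):
            expected = np.median(ranks[:, pos - 1])
            got = summary.loc[summary["residue_index"] == pos, "median_rank"].iloc[0]
            assert got == expected


class TestGermlineCorrelation:
    def test_monotone_pairs(self):
        x = np.arange(10, dtype=float)
        rho, p = mutscan.germline_identity_correlation(x, x**2 + 1)
        assert rho == pytest.approx(1.0)
        assert p < 0.05

    def test_reversed_pairs(self):
        x = np.arange(8, dtype=float)
        rho, _ = mutscan.germline_identity_correlation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_formula(self, rng):
        x = np.sort(rng.normal(size=20)) + rng.normal(scale=0.3, size=20)
        y = np.arange(20, dtype=float)
        rho, _ = mutscan.germline_identity_correlation(x, y)
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        expected = 1 - 6 * np.sum((rx - ry) ** 2) / (20 * (20**2 - 1))
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_exact_small_sample_p_matches_scipy_shape(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        rho, p = mutscan.germline_identity_correlation(x, y)
        assert 0 < p <= 1
        assert rho == pytest.approx(spearmanr(x, y).statistic)

    def test_constant_vector_flagged(self):
        rho, p = mutscan.germline_identity_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)


def _ddg_records(ddgs, kind="single"):
    recs = []
    for k, d in enumerate(ddgs):
        recs.append(dict(pos1=k + 1, wt1="A", mut1="V", pos2=None, wt2=None,
                         mut2=None, ddg=d, scan_kind=kind))
    return DdGTable(pd.DataFrame(recs))


class TestClassifyStability:
    def test_negative_is_stabilizing(self):
        df, _ = mutscan.classify_stability(_ddg_records([-1.2]))
        assert df["label"].iloc[0] == "stabilizing"

    def test_zero_is_destabilizing_by_convention(self):
        df, _ = mutscan.classify_stability(_ddg_records([0.0]))
        assert df["label"].iloc[0] == "destabilizing"

    def test_destabilizing_fraction_counts(self, rng):
        ddgs = np.concatenate([np.abs(rng.normal(size=94)) + 0.01,
                               -np.abs(rng.normal(size=6)) - 0.01])
        df, frac = mutscan.classify_stability(_ddg_records(ddgs.tolist()))
        assert frac == pytest.approx(0.94)
        # the two labels partition every record
        assert (df["label"].isin(["stabilizing", "destabilizing"])).all()
        stab_frac = (df["label"] == "stabilizing").mean()
        assert stab_frac + frac == pytest.approx(1.0)


class TestRepertoire:
    def test_counting_oracle(self):
        profile, fasta = synthdata.gen_repertoire(
            100, 200, {85: {"N": 0.05}}, seed=9
        )
        observed = sum(1 for s in fasta.values() if s[84] == "N")
        assert mutscan.repertoire_occurrence(profile, 85, "N") == pytest.approx(
            observed / 200
        )

    def test_unobserved_amino_acid_is_zero(self):
        profile, _ = synthdata.gen_repertoire(10, 50, {}, seed=1)
        # consensus-only repertoire: any non-consensus letter has fraction 0
        present = {aa for (_, aa) in zip(profile.df["position"], profile.df["aa"])}
        absent = next(a for a in AA_ORDER if a not in present)
        assert mutscan.repertoire_occurrence(profile, 1, absent) == 0.0

    def test_out_of_range_position_rejected(self):
        profile, _ = synthdata.gen_repertoire(10, 20, {}, seed=2)
        with pytest.raises(KeyError):
            mutscan.repertoire_occurrence(profile, 999, "A")

    def test_per_position_fractions_sum_to_at_most_one(self):
        profile, _ = synthdata.gen_repertoire(30, 100, {5: {"A": 0.4, "C": 0.4}}, seed=3)
        sums = profile.df.groupby("position")["fraction"].sum()
        assert (sums <= 1 + 1e-9).all()


def _profile_with(entries):
    rows = [dict(position=p, aa=a, fraction=f) for p, a, f in entries]
    return RepertoireProfile(pd.DataFrame(rows))


def _pair_tables(ddg_double, s1, s2):
    singles = DdGTable(pd.DataFrame([
        dict(pos1=40, wt1="A", mut1="R", pos2=None, wt2=None, mut2=None,
             ddg=s1, scan_kind="single"),
        dict(pos1=43, wt1="K", mut1="D", pos2=None, wt2=None, mut2=None,
             ddg=s2, scan_kind="single"),
    ]))
    doubles = DdGTable(pd.DataFrame([
        dict(pos1=40, wt1="A", mut1="R", pos2=43, wt2="K", mut2="D",
             ddg=ddg_double, scan_kind="double"),
    ]))
    return singles, doubles


class TestFilterDoubles:
    def test_all_filters_met(self):
        singles, doubles = _pair_tables(-0.8, -0.3, -0.2)
        profile = _profile_with([(40, "R", 0.04), (43, "D", 0.06)])
        cs = mutscan.filter_double_mutants(singles, doubles, profile)
        row = cs.table.iloc[0]
        assert row["passes"] and row["consistent"]

    def test_positive_double_fails_regardless(self):
        singles, doubles = _pair_tables(+0.5, -0.3, -0.2)
        profile = _profile_with([(40, "R", 0.5), (43, "D", 0.5)])
        cs = mutscan.filter_double_mutants(singles, doubles, profile)
        assert not cs.table["passes"].iloc[0]

    def test_inconsistent_but_stabilizing_pair_still_passes(self):
        # a jointly stabilizing pair of individually destabilizing mutations
        singles, doubles = _pair_tables(-0.6, +0.4, +0.3)
        profile = _profile_with([(40, "R", 0.02), (43, "D", 0.02)])
        cs = mutscan.filter_double_mutants(singles, doubles, profile)
        row = cs.table.iloc[0]
        assert row["passes"] and not row["consistent"]

    def test_missing_single_excluded_as_incomplete(self):
        singles, doubles = _pair_tables(-0.6, -0.1, -0.1)
        singles = DdGTable(singles.df.iloc[:1])
        profile = _profile_with([(40, "R", 0.2), (43, "D", 0.2)])
        cs = mutscan.filter_double_mutants(singles, doubles, profile)
        row = cs.table.iloc[0]
        assert row["incomplete"] and not row["passes"]

    def test_occurrence_threshold_is_strict(self):
        singles, doubles = _pair_tables(-0.6, -0.1, -0.1)
        profile = _profile_with([(40, "R", 0.01), (43, "D", 0.5)])
        cs = mutscan.filter_double_mutants(singles, doubles, profile, occ_threshold=0.01)
        assert not cs.table["passes"].iloc[0]  # 0.01 is not > 0.01

    def test_candidate_set_monotone_in_threshold(self, rng):
        n = 40
        recs_s, recs_d, prof = [], [], []
        for k in range(n):
            p1, p2 = 2 * k + 1, 2 * k + 2
            s1, s2 = rng.normal(), rng.normal()
            recs_s.append(dict(pos1=p1, wt1="A", mut1="V", pos2=None, wt2=None,
                               mut2=None, ddg=s1, scan_kind="single"))
            recs_s.append(dict(pos1=p2, wt1="A", mut1="L", pos2=None, wt2=None,
                               mut2=None, ddg=s2, scan_kind="single"))
            recs_d.append(dict(pos1=p1, wt1="A", mut1="V", pos2=p2, wt2="A",
                               mut2="L", ddg=rng.normal(), scan_kind="double"))
            prof.append((p1, "V", rng.random() * 0.2))
            prof.append((p2, "L", rng.random() * 0.2))
        singles = DdGTable(pd.DataFrame(recs_s))
        doubles = DdGTable(pd.DataFrame(recs_d))
        profile = _profile_with(prof)
        prev = None
        for thr in np.linspace(0, 0.2, 20):
            passing = set(
                mutscan.filter_double_mutants(singles, doubles, profile, thr)
                .passing()["pos1"]
            )
            if prev is not None:
                assert passing <= prev
            prev = passing
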