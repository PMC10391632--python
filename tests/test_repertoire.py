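"""Lineages, SHM profiling, R/S, Morisita overlap, permutation test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from scipy import stats

from bmasc.config import LineageParams, SimulationConfig
from bmasc.errors import InputError
from bmasc.repertoire import (classify_rs, classify_substitution,
                              cluster_lineages, join_vdj_expression,
                              lineage_cluster_table, morisita,
                              morisita_matrix, mutation_permutation_test,
                              mutation_profile, permutation_pvalue, rs_ratio,
                              track_clones)
from bmasc.synthetic import simulate_expression, simulate_repertoire

from conftest import random_repertoire


def _records(cdr3s, v="IGHV1-1*01", j="IGHJ1*01"):
    return pd.DataFrame({
        "sequence_id": [f"r{i}" for i in range(len(cdr3s))],
        "cell_id": [f"c{i}" for i in range(len(cdr3s))],
        "subject_id": "S1",
        "v_call": v, "j_call": j, "cdr3": cdr3s,
    })


def brute_force_single_linkage(records: pd.DataFrame,
                               threshold: float) -> dict[str, int]:
    """All-pairs oracle: link records with same subject/V/J/length and
    CDR3 identity >= threshold, then take connected components."""
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(records["sequence_id"])
    for (_, a), (_, b) in itertools.combinations(records.iterrows(), 2):
        if (a["subject_id"] != b["subject_id"]
                or a["v_call"].split("*")[0] != b["v_call"].split("*")[0]
                or a["j_call"].split("*")[0] != b["j_call"].split("*")[0]
                or len(a["cdr3"]) != len(b["cdr3"])):
            continue
        diffs = sum(x != y for x, y in zip(a["cdr3"], b["cdr3"]))
        if 1 - diffs / len(a["cdr3"]) >= threshold - 1e-12:
            g.add_edge(a["sequence_id"], b["sequence_id"])
    out = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            out[node] = i
    return out


def _same_partition(a: pd.Series, b: dict) -> bool:
    pairs_a = {tuple(sorted(p)) for p in
               itertools.combinations(a.index, 2) if a[p[0]] == a[p[1]]}
    pairs_b = {tuple(sorted(p)) for p in
               itertools.combinations(b, 2) if b[p[0]] == b[p[1]]}
    return pairs_a == pairs_b


class TestClusterLineages:
    def test_identical_cdr3_one_lineage(self):
        lin = cluster_lineages(_records(["ACGTACGT", "ACGTACGT"]))
        assert lin.nunique() == 1

    def test_homology_threshold_arithmetic(self):
        base = "A" * 20
        two_diff = "C" * 2 + "A" * 18   # 90% identity
        four_diff = "C" * 4 + "A" * 16  # 80% identity
        lin = cluster_lineages(_records([base, two_diff]))
        assert lin.nunique() == 1
        lin = cluster_lineages(_records([base, four_diff]))
        assert lin.nunique() == 2

    def test_single_linkage_chains(self):
        # A~B 90%, B~C 90%, A~C 80%: one lineage of three
        a = "A" * 20
        b = "C" * 2 + "A" * 18
        c = "C" * 4 + "A" * 16
        lin = cluster_lineages(_records([a, b, c]))
        assert lin.nunique() == 1

    def test_different_vj_split(self):
        recs = _records(["ACGTACGT", "ACGTACGT"])
        recs.loc[1, "v_call"] = "IGHV2-1*01"
        assert cluster_lineages(recs).nunique() == 2

    def test_input_order_invariance(self):
        rng = np.random.default_rng(0)
        recs = random_repertoire(rng, 40)
        lin = cluster_lineages(recs)
        shuffled = recs.sample(frac=1, random_state=1).reset_index(drop=True)
        lin2 = cluster_lineages(shuffled)
        assert lin.sort_index().equals(lin2.sort_index())

    def test_missing_cdr3_excluded(self):
        recs = _records(["ACGTACGT", None])
        lin = cluster_lineages(recs)
        assert list(lin.index) == ["r0"]

    @pytest.mark.parametrize("block", range(4))
    def test_matches_brute_force_oracle(self, block):
        for trial in range(50):
            rng = np.random.default_rng(1000 * block + trial)
            recs = random_repertoire(rng, int(rng.integers(5, 51)))
            lin = cluster_lineages(recs)
            oracle = brute_force_single_linkage(recs, 0.85)
            assert _same_partition(lin, oracle)


class TestTrackClones:
    def test_identical_same_clone(self):
        assert track_clones(_records(["ACGT" * 5] * 2)).nunique() == 1

    def test_98_percent_boundary(self):
        base = "A" * 50
        one = "C" + "A" * 49    # 98%
        two = "CC" + "A" * 48   # 96%
        assert track_clones(_records([base, one])).nunique() == 1
        assert track_clones(_records([base, two])).nunique() == 2

    def test_clones_refine_lineages(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            recs = random_repertoire(rng, 30)
            lin = cluster_lineages(recs)
            clones = track_clones(recs)
            # every clone sits inside exactly one lineage
            df = pd.DataFrame({"lin": lin, "clone": clones})
            assert (df.groupby("clone")["lin"].nunique() == 1).all()


def _aligned_record(germ, obs, regions=None, frame=0):
    rec = {"sequence_id": "r0", "v_sequence_alignment": obs,
           "v_germline_alignment": germ, "v_frame_offset": frame}
    n = len(germ)
    if regions is None:
        # tile the alignment with five regions
        bounds = [0, n // 5, 2 * n // 5, 3 * n // 5, 4 * n // 5, n]
        names = ["fwr1", "cdr1", "fwr2", "cdr2", "fwr3"]
        for name, s, e in zip(names, bounds[:-1], bounds[1:]):
            rec[f"{name}_start"] = s + 1
            rec[f"{name}_end"] = e
    else:
        rec.update(regions)
    return pd.Series(rec)


class TestMutationProfile:
    def test_identity_gives_zero(self):
        germ = "ACGT" * 25
        prof = mutation_profile(_aligned_record(germ, germ))
        assert (prof["frequency"] == 0).all()

    def test_global_frequency(self):
        germ = "A" * 250
        obs = "C" * 5 + "A" * 245
        prof = mutation_profile(_aligned_record(germ, obs), classify=False)
        assert prof.loc["V", "frequency"] == pytest.approx(0.02)
        assert prof.loc["V", "n_nongap_bases"] == 250

    def test_gap_columns_excluded_from_both_sides(self):
        # 100 columns, 10 gap columns (5 in each sequence), 2 mismatches
        germ = "A" * 10 + "-" * 5 + "A" * 85
        obs = ("A" * 10 + "C" * 5 + "A" * 25 + "." * 5 + "A" * 9 + "G"
               + "A" * 44 + "G")
        rec = _aligned_record(germ, obs)
        prof = mutation_profile(rec, classify=False)
        assert prof.loc["V", "n_nongap_bases"] == 90
        assert prof.loc["V", "n_mutations"] == 2

    def test_region_sums(self, small_repertoire):
        recs, _ = small_repertoire
        prof = mutation_profile(recs.iloc[3])
        assert prof.loc["CDR", "n_mutations"] == \
            prof.loc[["CDR1", "CDR2"], "n_mutations"].sum()
        assert prof.loc["V", "n_mutations"] == \
            prof.loc[["FR", "CDR"], "n_mutations"].sum()
        assert prof.loc["V", "n_mutations"] == (
            prof.loc["V", ["n_replacement", "n_silent",
                           "n_unclassifiable"]].sum())

    def test_truth_agreement(self, small_repertoire):
        recs, truth = small_repertoire
        t = truth.mutation_truth.set_index(["sequence_id", "region"])
        for _, rec in recs.head(20).iterrows():
            prof = mutation_profile(rec)
            for region in ("FR1", "CDR", "V"):
                row = t.loc[(rec["sequence_id"], region)]
                assert prof.loc[region, "n_mutations"] == row["n_mutations"]
                assert prof.loc[region, "n_replacement"] == \
                    row["n_replacement"]
                assert prof.loc[region, "n_silent"] == row["n_silent"]

    def test_bad_region_interval(self):
        rec = _aligned_record("ACGTACGTAC", "ACGTACGTAC")
        rec["fwr3_end"] = 99
        with pytest.raises(InputError, match="FR3"):
            mutation_profile(rec)

    def test_shm_rate_recovery_per_region(self):
        cfg = SimulationConfig(n_cells=400, n_genes=400, n_clusters=4,
                               n_lineages=40, v_mutation_rate=0.05, seed=13)
        _, truth = simulate_expression(cfg)
        recs, _ = simulate_repertoire(cfg, truth.cluster_labels)
        totals = {}
        for _, rec in recs.iterrows():
            prof = mutation_profile(rec, classify=False)
            for region in ("FR1", "CDR", "FR", "V"):
                m, b = totals.get(region, (0, 0))
                totals[region] = (m + prof.loc[region, "n_mutations"],
                                  b + prof.loc[region, "n_nongap_bases"])
        for region, (m, b) in totals.items():
            assert b >= 10_000
            se = np.sqrt(0.05 * 0.95 / b)
            assert abs(m / b - 0.05) < 3 * se, region


class TestClassifyRS:
    def test_silent_and_replacement_examples(self):
        germ = "GGAGGA"
        silent = "GGGGGA"       # GGA->GGG, Gly->Gly
        replacement = "AGAGGA"  # GGA->AGA, Gly->Arg
        rec = _aligned_record(germ, silent)
        assert classify_rs(rec)["status"].tolist() == ["silent"]
        rec = _aligned_record(germ, replacement)
        assert classify_rs(rec)["status"].tolist() == ["replacement"]

    def test_two_mismatches_one_at_a_time(self):
        # AAA -> AGG: A2G (Lys->Arg) replacement, A3G (Lys->Lys) silent
        rec = _aligned_record("AAA", "AGG")
        out = classify_rs(rec).set_index("alignment_position")["status"]
        assert out[1] == "replacement" and out[2] == "silent"

    def test_gapped_codon_unclassifiable(self):
        rec = _aligned_record("AAATTT", "AG-TTT")
        out = classify_rs(rec)
        assert out["status"].tolist() == ["unclassifiable"]

    def test_missing_frame_rejected(self):
        rec = _aligned_record("AAA", "AGA")
        rec = rec.drop("v_frame_offset")
        with pytest.raises(InputError):
            classify_rs(rec)

    @pytest.mark.parametrize("block", range(2))
    def test_exhaustive_substitution_oracle(self, block):
        """All 9 substitutions of 250 random codon contexts per block,
        against a translate-and-compare oracle."""
        rng = np.random.default_rng(block)
        for _ in range(250):
            codon = "".join(rng.choice(list("ACGT"), 3))
            for pos in range(3):
                for new in "ACGT":
                    if new == codon[pos]:
                        continue
                    mutated = codon[:pos] + new + codon[pos + 1:]
                    expected = ("silent"
                                if Seq(codon).translate()
                                == Seq(mutated).translate()
                                else "replacement")
                    assert classify_substitution(codon, pos, new) == expected
                    rec = _aligned_record(codon * 2, mutated + codon)
                    got = classify_rs(rec)
                    assert got["status"].tolist() == [expected]


class TestRSRatio:
    def _profile(self, r, s):
        return pd.DataFrame({"n_replacement": [r], "n_silent": [s]},
                            index=["CDR"])

    def test_plain_ratio(self):
        res = rs_ratio(self._profile(6, 2), "CDR")
        assert res.ratio == pytest.approx(3.0) and res.selected

    def test_silent_floor(self):
        res = rs_ratio(self._profile(3, 0), "CDR")
        assert res.s_denominator == 1 and res.ratio == pytest.approx(3.0)
        assert res.selected

    def test_no_mutations_not_applicable(self):
        res = rs_ratio(self._profile(0, 0), "CDR")
        assert np.isnan(res.ratio) and not res.selected

    def test_selection_flag_switches_at_2_9(self):
        assert not rs_ratio(self._profile(29, 10), "CDR").selected  # = 2.9
        assert rs_ratio(self._profile(30, 10), "CDR").selected      # > 2.9


class TestConnectivity:
    def test_abundance_split(self):
        assignments = pd.DataFrame({"cell_id": ["c1", "c2", "c3"],
                                    "lineage_id": ["L1"] * 3})
        labels = pd.Series({"c1": "A", "c2": "A", "c3": "B"})
        table = lineage_cluster_table(assignments, labels)
        assert table.loc["L1"].tolist() == [2, 1]

    def test_all_singletons_removed(self, caplog):
        assignments = pd.DataFrame({"cell_id": ["c1", "c2"],
                                    "lineage_id": ["L1", "L2"]})
        labels = pd.Series({"c1": "A", "c2": "B"})
        with caplog.at_level("WARNING"):
            table = lineage_cluster_table(assignments, labels,
                                          remove_singletons=True)
        assert table.empty

    def test_column_sums_conserved(self, small_repertoire):
        recs, _ = small_repertoire
        lin = cluster_lineages(recs)
        assignments = recs[["sequence_id", "cell_id"]].copy()
        assignments["lineage_id"] = assignments["sequence_id"].map(lin)
        labels = pd.Series("K", index=recs["cell_id"])
        table = lineage_cluster_table(assignments, labels)
        assert table["K"].sum() == len(recs)

    def test_morisita_identity_and_disjoint(self):
        x = np.array([3.0, 2.0, 1.0])
        assert morisita(x, x) == pytest.approx(1.0)
        assert morisita(np.array([2.0, 0.0]),
                        np.array([0.0, 5.0])) == pytest.approx(0.0)

    def test_morisita_worked_example(self):
        assert morisita(np.array([2.0, 0.0]),
                        np.array([1.0, 1.0])) == pytest.approx(2 / 3)

    def test_morisita_matrix_properties(self):
        rng = np.random.default_rng(8)
        abund = pd.DataFrame(rng.integers(0, 5, (30, 4)),
                             columns=list("ABCD"))
        abund["D"] = 0  # empty cluster
        mat = morisita_matrix(abund)
        sub = mat.loc[["A", "B", "C"], ["A", "B", "C"]].to_numpy()
        assert np.allclose(sub, sub.T)
        assert np.allclose(np.diag(sub), 1.0)
        assert ((sub >= 0) & (sub <= 1 + 1e-12)).all()
        assert mat["D"].isna().all()
        # invariance to lineage relabeling (row permutation)
        mat2 = morisita_matrix(abund.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(mat, mat2)


class TestPermutationTest:
    def test_printed_formula(self):
        # 7 of 100 permutations below the observed p -> 0.07 exactly
        permuted = np.concatenate([np.full(7, 0.01), np.full(93, 0.9)])
        assert permutation_pvalue(0.5, permuted) == 0.07

    def test_strict_inequality_degenerate(self):
        freqs = pd.Series(np.ones(20))
        labels = pd.Series(np.repeat(["a", "b"], 10))
        res = mutation_permutation_test(freqs, labels, n_perm=50, seed=0)
        assert res.pairs["tukey_p"].iloc[0] == pytest.approx(1.0)
        assert res.pairs["perm_p"].iloc[0] == 0.0

    def test_observed_matches_scipy(self):
        rng = np.random.default_rng(3)
        labels = pd.Series(np.repeat(["a", "b", "c"], 15))
        freqs = pd.Series(rng.normal(0, 1, 45)
                          + np.repeat([0.0, 0.4, 0.9], 15))
        res = mutation_permutation_test(freqs, labels, n_perm=10, seed=0)
        groups = [freqs[labels == g].to_numpy() for g in ("a", "b", "c")]
        assert res.anova_p == pytest.approx(stats.f_oneway(*groups).pvalue)
        th = stats.tukey_hsd(*groups)
        expected = [th.pvalue[0, 1], th.pvalue[0, 2], th.pvalue[1, 2]]
        assert res.pairs["tukey_p"].to_numpy() == pytest.approx(expected)

    def test_unbalanced_groups_match_scipy(self):
        rng = np.random.default_rng(4)
        labels = pd.Series(["a"] * 8 + ["b"] * 15 + ["c"] * 5)
        freqs = pd.Series(rng.normal(0, 1, 28))
        res = mutation_permutation_test(freqs, labels, n_perm=5, seed=0)
        groups = [freqs[labels == g].to_numpy() for g in ("a", "b", "c")]
        th = stats.tukey_hsd(*groups)
        expected = [th.pvalue[0, 1], th.pvalue[0, 2], th.pvalue[1, 2]]
        assert res.pairs["tukey_p"].to_numpy() == pytest.approx(expected)

    def test_small_cluster_excluded(self, caplog):
        freqs = pd.Series(np.arange(21, dtype=float))
        labels = pd.Series(["a"] * 10 + ["b"] * 10 + ["tiny"])
        with caplog.at_level("WARNING"):
            res = mutation_permutation_test(freqs, labels, n_perm=10, seed=0)
        assert res.excluded_clusters == ["tiny"]
        assert len(res.pairs) == 1

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        freqs = pd.Series(rng.normal(size=30))
        labels = pd.Series(np.repeat(["a", "b", "c"], 10))
        r1 = mutation_permutation_test(freqs, labels, n_perm=50, seed=9)
        r2 = mutation_permutation_test(freqs, labels, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(r1.pairs, r2.pairs)


class TestJoinVDJExpression:
    def _records(self, cells, dups):
        return pd.DataFrame({"cell_id": cells, "sequence_id":
                             [f"s{i}" for i in range(len(cells))],
                             "duplicate_count": dups})

    def test_full_match(self):
        matched, rate, dom = join_vdj_expression(
            ["c1", "c2"], self._records(["c1", "c2"], [10, 150]))
        assert rate == 1.0
        assert dom.tolist() == [False, True]  # >100 transcripts dominates

    def test_disjoint(self):
        matched, rate, _ = join_vdj_expression(
            ["c1"], self._records(["x1"], [10]))
        assert rate == 0.0 and matched.empty

    def test_duplicate_barcode_keeps_heaviest(self):
        matched, _, _ = join_vdj_expression(
            ["c1"], self._records(["c1", "c1"], [5, 50]))
        assert len(matched) == 1
        assert matched["duplicate_count"].iloc[0] == 50
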