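"""Signal2Noise, enrichment score, permutation nulls, P/NES/FDR q."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trmsig as t
from trmsig.gsea import (
    GeneSet,
    RankedList,
    _es_from_positions,
    distinct_phenotype_splits,
    enrichment_score,
    rank_genes,
)

from .conftest import make_design, make_log2_matrix


def brute_force_es(genes, scores, members, weight=1.0):
    """Independent running-sum oracle: literal loop over the ranked list."""
    members = set(members)
    n = len(genes)
    nh = sum(g in members for g in genes)
    nr = sum(abs(s) ** weight for g, s in zip(genes, scores) if g in members)
    p_hit = p_miss = 0.0
    best = 0.0
    for g, s in zip(genes, scores):
        if g in members:
            p_hit += abs(s) ** weight / nr
        else:
            p_miss += 1.0 / (n - nh)
        dev = p_hit - p_miss
        if abs(dev) > abs(best):
            best = dev
    return best


def ranked_fixture(n=10, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.sort(rng.normal(size=n))[::-1]
    genes = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
    return RankedList(genes=genes, scores=scores)


class TestSignalToNoise:
    def _matrix(self, a_rows, b_rows):
        data = np.hstack([a_rows, b_rows])
        samples = [f"A_rep{i}" for i in range(1, a_rows.shape[1] + 1)] + [
            f"B_rep{i}" for i in range(1, b_rows.shape[1] + 1)
        ]
        matrix = make_log2_matrix(data, samples=samples)
        design = make_design(
            ["TGFb"] * a_rows.shape[1] + ["Untreated"] * b_rows.shape[1],
            sample_ids=samples,
        )
        return matrix, design

    def test_equal_means_score_zero(self):
        a = np.array([[1.0, 2.0, 3.0]])
        matrix, design = self._matrix(a, a)
        r = t.signal_to_noise(matrix, design, ("TGFb",), ("Untreated",))
        assert r.iloc[0] == pytest.approx(0.0)

    def test_closed_form_unit_variance(self):
        # mu_A=2, mu_B=0, sigma=1 each -> r = 2 / (1 + 1) = 1
        a = np.array([[1.0, 2.0, 3.0]])
        b = np.array([[-1.0, 0.0, 1.0]])
        matrix, design = self._matrix(a, b)
        r = t.signal_to_noise(matrix, design, ("TGFb",), ("Untreated",))
        assert r.iloc[0] == pytest.approx(1.0)

    def test_zero_variance_uses_floors(self):
        # mu_A=1, mu_B=0, both sd 0 -> denominator max(.2*1,.2) + max(0,.2) = 0.4
        a = np.ones((1, 3))
        b = np.zeros((1, 3))
        matrix, design = self._matrix(a, b)
        r = t.signal_to_noise(matrix, design, ("TGFb",), ("Untreated",))
        assert r.iloc[0] == pytest.approx(2.5)

    def test_single_sample_group_rejected(self):
        a = np.array([[1.0, 2.0, 3.0]])
        b = np.array([[1.0]])
        matrix, design = self._matrix(a, b)
        with pytest.raises(t.ConfigurationError):
            t.signal_to_noise(matrix, design, ("TGFb",), ("Untreated",))


class TestRanking:
    def test_descending_with_lexicographic_ties(self):
        metric = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0})
        ranked = rank_genes(metric)
        assert list(ranked.genes) == ["c", "a", "b"]

    def test_duplicate_genes_rejected(self):
        with pytest.raises(t.ConfigurationError):
            RankedList(
                genes=np.array(["a", "a"], dtype=object), scores=np.array([1.0, 0.5])
            )


class TestEnrichmentScore:
    def test_single_member_at_top_scores_one(self):
        ranked = ranked_fixture()
        es = enrichment_score(ranked, GeneSet("s", (str(ranked.genes[0]),))).es
        assert es == pytest.approx(1.0)

    def test_single_member_at_bottom(self):
        # all 9 misses accrue before the hit: P_miss = 9/(N - N_h) = 9/9
        ranked = ranked_fixture()
        profile = enrichment_score(ranked, GeneSet("s", (str(ranked.genes[-1]),)))
        assert profile.es == pytest.approx(
            brute_force_es(ranked.genes, ranked.scores, {str(ranked.genes[-1])})
        )
        assert profile.es == pytest.approx(-1.0)

    def test_top_block_matches_oracle(self):
        genes = np.array([f"g{i}" for i in range(10)], dtype=object)
        scores = np.arange(10, 0, -1, dtype=float)
        ranked = RankedList(genes=genes, scores=scores)
        members = ("g0", "g1", "g2")
        es = enrichment_score(ranked, GeneSet("s", members)).es
        assert es == pytest.approx(brute_force_es(genes, scores, members), abs=1e-12)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=3, max_value=20),
        set_size=st.integers(min_value=1, max_value=6),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_exhaustive_oracle_on_random_grid(self, n, set_size, seed):
        rng = np.random.default_rng(seed)
        set_size = min(set_size, n - 1)
        ranked = ranked_fixture(n=n, seed=seed)
        members = tuple(str(g) for g in rng.choice(ranked.genes, set_size, replace=False))
        profile = enrichment_score(ranked, GeneSet("s", members))
        expected = brute_force_es(ranked.genes, ranked.scores, members)
        assert profile.es == pytest.approx(expected, abs=1e-12)
        assert abs(profile.es) <= 1.0
        # fast hit-boundary evaluation agrees exactly with the full profile
        pos = np.sort([list(ranked.genes).index(g) for g in members])
        fast = _es_from_positions(pos, np.abs(ranked.scores[pos]), n)
        assert fast == pytest.approx(profile.es, abs=1e-15)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        set_size=st.integers(min_value=1, max_value=6),
    )
    def test_reversing_list_and_negating_metric_negates_es(self, seed, set_size):
        rng = np.random.default_rng(seed)
        n = 15
        scores = rng.normal(size=n)
        scores = np.sort(np.round(scores, 6))[::-1]
        genes = np.array([f"g{i:02d}" for i in range(n)], dtype=object)
        ranked = RankedList(genes=genes, scores=scores)
        flipped = RankedList(genes=genes[::-1].copy(), scores=-scores[::-1].copy())
        members = tuple(str(g) for g in rng.choice(genes, set_size, replace=False))
        profile = enrichment_score(ranked, GeneSet("s", members))
        es_flipped = enrichment_score(flipped, GeneSet("s", members)).es
        assert abs(es_flipped) == pytest.approx(abs(profile.es), abs=1e-9)
        # when the positive and negative extrema tie exactly, the
        # first-occurrence tie-break fixes the sign; skip the sign check then
        if abs(profile.running.max() + profile.running.min()) > 1e-9:
            assert es_flipped == pytest.approx(-profile.es, abs=1e-9)

    def test_leading_edge_contains_top_members(self):
        ranked = ranked_fixture(n=20, seed=3)
        members = tuple(str(g) for g in ranked.genes[:4])
        profile = enrichment_score(ranked, GeneSet("s", members))
        assert set(profile.leading_edge) == set(members)

    def test_set_equal_to_universe_rejected(self):
        ranked = ranked_fixture(n=5)
        with pytest.raises(t.ConfigurationError):
            enrichment_score(ranked, GeneSet("s", tuple(str(g) for g in ranked.genes)))

    def test_all_zero_metrics_give_zero_es_with_warning(self):
        genes = np.array(["a", "b", "c", "d"], dtype=object)
        ranked = RankedList(genes=genes, scores=np.array([1.0, 0.0, 0.0, -1.0]))
        with pytest.warns(UserWarning, match="ES set to 0"):
            profile = enrichment_score(ranked, GeneSet("s", ("b", "c")))
        assert profile.es == 0.0 and profile.degenerate

    def test_agrees_with_gseapy_prerank(self):
        """Independent cross-check against an external GSEA implementation."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(4)
        genes = [f"g{i:03d}" for i in range(200)]
        scores = np.sort(rng.normal(0, 1, 200))[::-1]
        ranked = RankedList(genes=np.array(genes, dtype=object), scores=scores)
        sets = {f"s{j}": [str(g) for g in rng.choice(genes, 20, replace=False)] for j in range(4)}
        pre = gseapy.prerank(
            rnk=pd.DataFrame({"gene": genes, "score": scores}),
            gene_sets=sets, permutation_num=5, min_size=5, max_size=500,
            weight=1.0, outdir=None, seed=1, no_plot=True, threads=1,
        )
        for name, members in sets.items():
            mine = enrichment_score(ranked, GeneSet(name, tuple(members))).es
            theirs = float(pre.res2d.loc[pre.res2d.Term == name, "ES"].iloc[0])
            assert mine == pytest.approx(theirs, abs=1e-6)


class TestPermutationNull:
    def test_three_vs_three_has_ten_distinct_splits(self):
        assert distinct_phenotype_splits(3, 3) == 10

    def test_phenotype_null_exhausts_small_designs(self, default_study):
        cfg = t.SimulationConfig(seed=1, n_genes=400)
        matrix, design, truth = t.generate_expression_matrix(cfg)
        logged = t.log2_transform(matrix)
        sets = [GeneSet("s", tuple(truth.genes[:20]))]
        nulls = t.permutation_null(
            logged, design, sets, ("TGFb",), ("Untreated",),
            mode="phenotype", n_perm=100_000, seed=1,
        )
        assert len(nulls["s"]) == 10  # C(6,3)/2 distinct splits, enumerated

    def test_seed_reproducibility(self):
        cfg = t.SimulationConfig(seed=2, n_genes=300)
        matrix, design, truth = t.generate_expression_matrix(cfg)
        logged = t.log2_transform(matrix)
        sets = [GeneSet("s", tuple(truth.genes[:25]))]
        kwargs = dict(mode="gene_set", n_perm=50, seed=77)
        a = t.permutation_null(logged, design, sets, ("TGFb",), ("Untreated",), **kwargs)
        b = t.permutation_null(logged, design, sets, ("TGFb",), ("Untreated",), **kwargs)
        np.testing.assert_array_equal(a["s"], b["s"])

    def test_gene_set_null_centred_near_zero(self):
        cfg = t.SimulationConfig(seed=3, n_genes=1000, frac_tgfb_responsive=0.0)
        matrix, design, truth = t.generate_expression_matrix(cfg)
        logged = t.log2_transform(matrix)
        sets = [GeneSet("s", tuple(truth.genes[:30]))]
        nulls = t.permutation_null(
            logged, design, sets, ("TGFb",), ("Untreated",),
            mode="gene_set", n_perm=500, seed=5,
        )["s"]
        se = nulls.std(ddof=1) / np.sqrt(len(nulls))
        assert abs(nulls.mean()) < 3 * se + 0.02

    def test_unknown_mode_rejected(self, default_study, default_processed):
        with pytest.raises(t.ConfigurationError):
            t.permutation_null(
                default_processed["logged"], default_study["design"],
                default_study["sets"], ("TGFb",), ("Untreated",),
                mode="banana", n_perm=5, seed=1,
            )


class TestPAndFdr:
    def test_observed_beyond_all_nulls_hits_floor(self):
        nulls = {"s": np.concatenate([np.linspace(0.01, 0.5, 99), [-0.3]])}
        res = t.nominal_p_and_fdr({"s": 0.9}, nulls)
        assert res.table.loc["s", "pvalue"] == pytest.approx(1 / 100)

    def test_null_centre_gives_p_near_one(self):
        rng = np.random.default_rng(0)
        nulls = {"s": rng.normal(0, 0.2, 1000)}
        res = t.nominal_p_and_fdr({"s": 0.0}, nulls)
        assert res.table.loc["s", "pvalue"] > 0.95
        assert res.table.loc["s", "fdr_q"] > 0.5

    def test_empty_same_sign_null_is_flagged(self):
        nulls = {"s": np.array([0.1, 0.2, 0.3])}
        res = t.nominal_p_and_fdr({"s": -0.5}, nulls)
        assert "s" in res.flagged
        assert np.isnan(res.table.loc["s", "pvalue"])

    def test_stronger_nes_never_has_larger_q(self):
        rng = np.random.default_rng(1)
        observed = {f"s{i}": v for i, v in enumerate([0.9, 0.7, 0.5, 0.3])}
        nulls = {k: rng.normal(0, 0.3, 500) for k in observed}
        res = t.nominal_p_and_fdr(observed, nulls)
        tab = res.table.sort_values("nes", ascending=False)
        assert (np.diff(tab["fdr_q"].to_numpy()) >= -1e-12).all()


class TestRunGsea:
    def test_planted_sets_significant_controls_not(self, default_study, default_processed):
        """Fig 5 / S4 analog on the default synthetic study."""
        res = t.run_gsea(
            default_processed["logged"], default_study["design"],
            default_study["sets"],
            ("TGFb", "IL2_TGFb"), ("Untreated", "IL2"),
            mode="gene_set", n_perm=1000, seed=42,
        )
        planted = res.table.index.str.startswith("planted")
        assert res.table.loc[planted, "significant"].all()
        assert not res.table.loc[~planted, "significant"].any()
        up = res.table.index.str.startswith("planted_up")
        assert (res.table.loc[up, "es"] > 0).all()
        assert (res.table.loc[res.table.index.str.startswith("planted_down"), "es"] < 0).all()

    def test_undersized_set_excluded_with_reason(self, default_study, default_processed):
        small = GeneSet("tiny", tuple(default_study["truth"].genes[:10]))
        res = t.run_gsea(
            default_processed["logged"], default_study["design"],
            default_study["sets"] + [small],
            ("TGFb", "IL2_TGFb"), ("Untreated", "IL2"),
            mode="gene_set", n_perm=50, seed=1,
        )
        assert "tiny" in res.excluded
        assert "minimum gene set size" in res.excluded["tiny"]
        assert "tiny" not in res.table.index

    def test_nominal_p_calibrated_on_null_data(self):
        """gene_set-mode type-I error sits in a 3-SE band around 0.05."""
        cfg = t.SimulationConfig(seed=6, n_genes=800, frac_tgfb_responsive=0.0,
                                 frac_il2_responsive=0.0)
        matrix, design, truth = t.generate_expression_matrix(cfg)
        logged = t.log2_transform(matrix)
        rng = np.random.default_rng(13)
        sets = [
            GeneSet(f"r{i}", tuple(str(g) for g in rng.choice(truth.genes, 30, replace=False)))
            for i in range(100)
        ]
        res = t.run_gsea(
            logged, design, sets, ("TGFb",), ("Untreated",),
            mode="gene_set", n_perm=400, seed=99,
        )
        frac = float((res.table["pvalue"] < 0.05).mean())
        band = 3 * np.sqrt(0.05 * 0.95 / 100)
        assert abs(frac - 0.05) <= band
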