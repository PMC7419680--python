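"""ssGSEA and permutation GSEA against independent oracles."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from tnbcstrat.enrichment import (
    EnrichmentParams,
    _es_weighted_ks,
    _ordered_positions,
    _ranking_metric,
    combine_axis_scores,
    gsea,
    ssgsea_score,
)
from tnbcstrat.genesets import GeneSet, GeneSetCollection

from conftest import make_matrix


def ssgsea_oracle(values, genes, set_genes, alpha):
    """Hand-written running-sum evaluation (plain python, no vectorization)."""
    ordered = sorted(range(len(values)), key=lambda i: (-values[i], genes[i]))
    n = len(values)
    in_set = [genes[i] in set_genes for i in ordered]
    denom = sum((n - pos) ** alpha for pos, flag in enumerate(in_set) if flag)
    n_out = n - sum(in_set)
    score, p_in, p_out = 0.0, 0.0, 0.0
    for pos, flag in enumerate(in_set):
        if flag:
            p_in += (n - pos) ** alpha / denom
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


class TestSsgsea:
    def test_matches_hand_summation_oracle(self):
        genes = ["G1", "G2", "G3", "G4"]
        m = make_matrix([[4.0], [3.0], [2.0], [1.0]], genes=genes)
        s = GeneSet("top2", frozenset({"G1", "G2"}))
        got = ssgsea_score(m, s, EnrichmentParams(alpha=0.25)).iloc[0]
        expected = 4 ** 0.25 / (4 ** 0.25 + 3 ** 0.25) + 1.5
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(
            ssgsea_oracle([4, 3, 2, 1], genes, s.genes, 0.25), abs=1e-10
        )

    @pytest.mark.parametrize("n_genes,set_size,seed", [(6, 2, 0), (8, 3, 1), (10, 4, 2)])
    def test_oracle_equivalence_on_random_instances(self, n_genes, set_size, seed):
        rng = np.random.default_rng(seed)
        genes = [f"G{i}" for i in range(n_genes)]
        values = rng.normal(size=(n_genes, 3))
        m = make_matrix(values, genes=genes)
        set_genes = frozenset(rng.choice(genes, size=set_size, replace=False))
        scores = ssgsea_score(m, GeneSet("s", set_genes), EnrichmentParams(alpha=0.25))
        for j, sample in enumerate(m.sample_ids):
            expected = ssgsea_oracle(values[:, j], genes, set_genes, 0.25)
            assert scores[sample] == pytest.approx(expected, abs=1e-10)

    def test_identical_ranking_gives_identical_scores(self):
        m = make_matrix([[5, 50], [4, 40], [3, 30], [2, 20]], genes=list("ABCD"))
        s = GeneSet("s", frozenset({"A", "C"}))
        scores = ssgsea_score(m, s)
        assert scores.iloc[0] == pytest.approx(scores.iloc[1])

    @pytest.mark.parametrize("transform", [np.exp, lambda x: 3 * x + 7, np.tanh])
    def test_invariant_under_monotone_transforms(self, transform):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(30)]
        values = rng.normal(size=(30, 4))
        s = GeneSet("s", frozenset(genes[:7]))
        base = ssgsea_score(make_matrix(values, genes=genes), s)
        warped = ssgsea_score(make_matrix(transform(values), genes=genes), s)
        pd.testing.assert_series_equal(base, warped)

    def test_top_ranked_set_outscores_bottom_ranked_set(self):
        genes = [f"G{i}" for i in range(6)]
        m = make_matrix(np.arange(6, 0, -1).reshape(-1, 1), genes=genes)
        top = ssgsea_score(m, GeneSet("top", frozenset(genes[:2]))).iloc[0]
        bottom = ssgsea_score(m, GeneSet("bot", frozenset(genes[-2:]))).iloc[0]
        assert top > bottom

    def test_no_overlap_is_an_error(self):
        m = make_matrix([[1], [2]], genes=["A", "B"])
        with pytest.raises(ValueError, match="no genes"):
            ssgsea_score(m, GeneSet("s", frozenset({"Z"})))


class TestCombineAxisScores:
    def test_single_set_reduces_to_standardized_score(self):
        row = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["s1"])
        combined = combine_axis_scores(row)
        z = (row.iloc[0] - row.iloc[0].mean()) / row.iloc[0].std(ddof=0)
        pd.testing.assert_series_equal(combined, z, check_names=False)

    def test_identical_sets_equal_their_standardized_vector(self):
        row = pd.Series([5.0, 1.0, 3.0, 9.0])
        table = pd.DataFrame([row, row], index=["a", "b"])
        combined = combine_axis_scores(table)
        z = (row - row.mean()) / row.std(ddof=0)
        np.testing.assert_allclose(combined.to_numpy(), z.to_numpy())

    def test_zero_variance_set_excluded(self):
        table = pd.DataFrame(
            [[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]], index=["ok", "flat"]
        )
        combined = combine_axis_scores(table)
        z = (table.loc["ok"] - 2.0) / table.loc["ok"].std(ddof=0)
        np.testing.assert_allclose(combined.to_numpy(), z.to_numpy())

    def test_averaging_noisy_replicates_improves_signal_recovery(self):
        rng = np.random.default_rng(21)
        signal = rng.normal(size=300)
        sets = pd.DataFrame(
            [signal + rng.normal(0, 1.0, 300) for _ in range(3)],
            index=["a", "b", "c"],
        )
        combined = combine_axis_scores(sets)
        r_combined = np.corrcoef(combined, signal)[0, 1]
        singles = [np.corrcoef(sets.loc[k], signal)[0, 1] for k in sets.index]
        assert r_combined > max(singles)


class TestGsea:
    def _planted_instance(self, seed=5, shift=3.0):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:02d}" for i in range(40)]
        X = rng.normal(0, 1, (40, 8))
        X[:5, 4:] += shift
        m = make_matrix(X, genes=genes)
        coll = GeneSetCollection([
            GeneSet("planted", frozenset(genes[:5])),
            GeneSet("random", frozenset(genes[20:28])),
        ])
        return m, coll, ["A"] * 4 + ["B"] * 4, X, genes

    def _exhaustive_oracle(self, X, genes, set_genes):
        gene_arr = np.array(genes, dtype=object)
        member = np.array([g in set_genes for g in genes])

        def es(mask):
            metric = _ranking_metric(X[:, mask], X[:, ~mask], "signal_to_noise")
            order = _ordered_positions(metric, gene_arr)
            return _es_weighted_ks(metric[order], member[order], 1.0)

        obs_mask = np.array([False] * 4 + [True] * 4)
        null = []
        for c in combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(c)] = True
            null.append(es(mask))
        null = np.asarray(null)
        obs = es(obs_mask)
        return obs, (np.abs(null) >= abs(obs)).mean()

    def test_planted_shift_yields_positive_nes_and_minimal_exhaustive_p(self):
        m, coll, labels, X, genes = self._planted_instance()
        res = gsea(m, labels, coll, EnrichmentParams(n_perm=1000, seed=0))
        row = res.set_index("set").loc["planted"]
        assert row["es"] > 0 and row["nes"] > 0
        obs, p_oracle = self._exhaustive_oracle(X, genes, coll["planted"].genes)
        assert row["es"] == pytest.approx(obs, abs=1e-12)
        assert row["p"] == pytest.approx(p_oracle, abs=1e-12)
        # a strong planted 4v4 shift achieves the smallest exhaustive p
        assert row["p"] == pytest.approx(2 / 70)

    def test_nominal_p_matches_exhaustive_enumeration_for_random_sets(self):
        m, coll, labels, X, genes = self._planted_instance(seed=17, shift=0.0)
        res = gsea(m, labels, coll, EnrichmentParams(n_perm=1000, seed=0)).set_index("set")
        for name in ("planted", "random"):
            _, p_oracle = self._exhaustive_oracle(X, genes, coll[name].genes)
            assert res.loc[name, "p"] == pytest.approx(p_oracle, abs=1e-12)

    def test_single_group_labels_rejected(self):
        m, coll, _, _, _ = self._planted_instance()
        with pytest.raises(ValueError, match="two groups"):
            gsea(m, ["A"] * 8, coll)

    def test_swapping_reference_flips_every_es_sign(self):
        m, coll, labels, _, _ = self._planted_instance(seed=3, shift=1.0)
        fwd = gsea(m, labels, coll, EnrichmentParams(n_perm=1000, seed=0)).set_index("set")
        # renaming groups so sort order flips which one is the reference
        swapped = ["Z" if lab == "A" else "B" for lab in labels]
        rev = gsea(m, swapped, coll, EnrichmentParams(n_perm=1000, seed=0)).set_index("set")
        for name in fwd.index:
            assert rev.loc[name, "es"] == pytest.approx(-fwd.loc[name, "es"], abs=1e-12)

    def test_null_type_one_error_calibrated(self):
        # random set independent of labels: exhaustive nominal p <= 0.05
        # should occur at close to the nominal rate
        rng = np.random.default_rng(42)
        genes = [f"G{i:02d}" for i in range(25)]
        coll = GeneSetCollection([GeneSet("s", frozenset(genes[:6]))])
        labels = ["A"] * 4 + ["B"] * 4
        params = EnrichmentParams(n_perm=1000, seed=0)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            m = make_matrix(rng.normal(size=(25, 8)), genes=genes)
            hits += gsea(m, labels, coll, params)["p"].iloc[0] <= 0.05
        assert 0.03 <= hits / n_sim <= 0.07
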