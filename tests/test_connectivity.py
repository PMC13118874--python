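"""KS enrichment statistic and connectivity scoring.

The KS statistic is checked against an exhaustive running-sum oracle that
evaluates the empirical-CDF deviation at every list position by brute force.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from woundsig.containers import ReferenceSignatureSet, WoundSignature
from woundsig import connectivity as conn


def ks_oracle(tag_positions, n_total):
    """Brute force: walk every position, track the running-sum extrema."""
    tags = set(tag_positions)
    t = len(tags)
    best_a = -np.inf
    best_b = -np.inf
    hits = 0
    for pos in range(1, n_total + 1):
        if pos in tags:
            hits += 1
            best_a = max(best_a, hits / t - pos / n_total)
            best_b = max(best_b, pos / n_total - (hits - 1) / t)
    return best_a if best_a > best_b else -best_b


def make_reference(z: np.ndarray, genes, pert_of=None) -> ReferenceSignatureSet:
    sig_ids = [f"SIG-{k:03d}" for k in range(z.shape[1])]
    pert_of = pert_of or {s: f"CMPD-{k:03d}" for k, s in enumerate(sig_ids)}
    sig_meta = pd.DataFrame({"pert_id": [pert_of[s] for s in sig_ids]}, index=sig_ids)
    pert_meta = pd.DataFrame(index=sorted(set(sig_meta["pert_id"])))
    return ReferenceSignatureSet(
        z=pd.DataFrame(z, index=genes, columns=sig_ids),
        sig_meta=sig_meta,
        pert_meta=pert_meta,
    )


class TestKsEnrichment:
    @pytest.mark.parametrize(
        "positions,n,expected",
        [
            ([1], 10, 0.9),
            ([1, 2, 3], 10, 0.7),
            ([8, 9, 10], 10, -0.8),
        ],
    )
    def test_known_values(self, positions, n, expected):
        assert conn.ks_enrichment(positions, n) == pytest.approx(expected)

    def test_exhaustive_oracle_small_lists(self):
        """Exact agreement with brute force for every tag subset, n <= 8."""
        for n in range(2, 9):
            for r in range(1, n):
                for tags in itertools.combinations(range(1, n + 1), r):
                    assert conn.ks_enrichment(tags, n) == pytest.approx(
                        ks_oracle(tags, n), abs=1e-14
                    ), (tags, n)

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            conn.ks_enrichment([], 10)
        with pytest.raises(ValueError, match="whole"):
            conn.ks_enrichment([1, 2, 3], 3)
        with pytest.raises(ValueError, match="distinct"):
            conn.ks_enrichment([2, 2], 10)

    @given(
        st.integers(min_value=2, max_value=200).flatmap(
            lambda n: st.tuples(
                st.just(n),
                st.sets(st.integers(min_value=1, max_value=n), min_size=1, max_size=n - 1),
            )
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds_property(self, case):
        n, tags = case
        es = conn.ks_enrichment(sorted(tags), n)
        # a-branch maxima are bounded by 1 - 1/n; the b-branch attains exactly
        # 1 when the whole tag set sits at the bottom of the list
        assert -1.0 <= es < 1.0
        assert es == pytest.approx(ks_oracle(sorted(tags), n), abs=1e-14)


class TestCombinedScore:
    def test_zero_when_signs_agree(self):
        assert conn.combine_scores(0.5, 0.2) == 0.0
        assert conn.combine_scores(-0.5, -0.2) == 0.0

    def test_average_when_signs_differ(self):
        assert conn.combine_scores(0.6, -0.4) == pytest.approx(0.5)
        assert conn.combine_scores(-0.6, 0.4) == pytest.approx(-0.5)

    @given(
        st.floats(min_value=-0.99, max_value=1.0),
        st.floats(min_value=-0.99, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_magnitude_bound(self, es_up, es_down):
        score = conn.combine_scores(es_up, es_down)
        assert abs(score) <= max(abs(es_up), abs(es_down)) + 1e-12


class TestScoreSignature:
    def test_self_connectivity_positive_and_maximal(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i:03d}" for i in range(50)]
        z = rng.normal(size=50)
        order = np.argsort(-z)
        query = WoundSignature(
            timepoint="T1",
            up_genes=[genes[i] for i in order[:5]],
            down_genes=[genes[i] for i in order[-5:]],
        )
        col = pd.Series(z, index=genes)
        score = conn.score_signature(query, col)["score"]
        assert score > 0
        for seed in range(10):
            rnd = np.random.default_rng(seed).permutation(50)
            random_query = WoundSignature(
                timepoint="T1",
                up_genes=[genes[i] for i in rnd[:5]],
                down_genes=[genes[i] for i in rnd[5:10]],
            )
            assert conn.score_signature(random_query, col)["score"] <= score

    def test_antisymmetry_under_negation(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i:03d}" for i in range(40)]
        z = rng.normal(size=40)  # continuous draws: tie-free
        query = WoundSignature(
            timepoint="T1", up_genes=genes[:4], down_genes=genes[10:14]
        )
        s_pos = conn.score_signature(query, pd.Series(z, index=genes))
        s_neg = conn.score_signature(query, pd.Series(-z, index=genes))
        assert s_pos["score"] == pytest.approx(-s_neg["score"], abs=1e-12)

    def test_toy_column_matches_oracle(self):
        genes = [f"G{i:02d}" for i in range(20)]
        z = np.array(
            [2.5, 2.1, 1.8, 1.2, 0.9, 0.7, 0.5, 0.3, 0.2, 0.1,
             -0.1, -0.2, -0.4, -0.6, -0.8, -1.1, -1.4, -1.9, -2.2, -2.6]
        )
        query = WoundSignature(
            timepoint="T1",
            up_genes=["G00", "G03", "G10"],
            down_genes=["G17", "G18", "G19"],
        )
        res = conn.score_signature(query, pd.Series(z, index=genes))
        # ranks: z already sorted descending, so positions are index + 1
        es_up = ks_oracle([1, 4, 11], 20)
        es_down = ks_oracle([18, 19, 20], 20)
        assert res["es_up"] == pytest.approx(es_up)
        assert res["es_down"] == pytest.approx(es_down)
        expected = 0.0 if es_up * es_down > 0 else (es_up - es_down) / 2
        assert res["score"] == pytest.approx(expected)

    def test_absent_query_genes_only_removed(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i:03d}" for i in range(30)]
        z = pd.Series(rng.normal(size=30), index=genes)
        query = WoundSignature(timepoint="T1", up_genes=genes[:3], down_genes=genes[5:8])
        padded = WoundSignature(
            timepoint="T1",
            up_genes=genes[:3] + ["NOT_IN_REF_A"],
            down_genes=genes[5:8] + ["NOT_IN_REF_B"],
        )
        assert conn.score_signature(query, z)["score"] == pytest.approx(
            conn.score_signature(padded, z)["score"]
        )

    def test_case_insensitive_matching(self):
        genes = ["Abca1", "Tp53", "Egfr", "Vegfa", "Il6", "Ccl2"]
        z = pd.Series([3.0, 2.0, 1.0, -1.0, -2.0, -3.0], index=genes)
        query = WoundSignature(
            timepoint="T1", up_genes=["ABCA1"], down_genes=["CCL2"]
        )
        res = conn.score_signature(query, z)
        assert res["n_matched_up"] == 1 and res["n_matched_down"] == 1
        assert res["score"] > 0

    def test_unmatched_query_flagged(self):
        genes = [f"G{i}" for i in range(10)]
        z = pd.Series(np.arange(10.0), index=genes)
        query = WoundSignature(timepoint="T1", up_genes=["X1"], down_genes=["G1"])
        res = conn.score_signature(query, z)
        assert res["unmatched"]
        assert np.isnan(res["score"])


class TestScoreAll:
    def test_planted_reverser_attains_minimum(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i:03d}" for i in range(100)]
        z = rng.normal(size=(100, 20))
        query = WoundSignature(
            timepoint="T1", up_genes=genes[:10], down_genes=genes[10:20]
        )
        z[:10, 7] = -50 - np.arange(10)  # perfect reverser in column 7
        z[10:20, 7] = 50 + np.arange(10)
        ref = make_reference(z, genes)
        scores = conn.score_all(query, ref)
        assert scores["score"].idxmin() == "SIG-007"

    def test_column_permutation_permutes_rows(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i:03d}" for i in range(60)]
        z = rng.normal(size=(60, 8))
        query = WoundSignature(timepoint="T1", up_genes=genes[:5], down_genes=genes[5:10])
        ref = make_reference(z, genes)
        scores = conn.score_all(query, ref)
        perm = [3, 1, 7, 0, 2, 6, 4, 5]
        ref_perm = make_reference(
            z[:, perm], genes, pert_of={f"SIG-{k:03d}": f"CMPD-{perm[k]:03d}" for k in range(8)}
        )
        # permuted reference: signature k holds what used to be column perm[k]
        scores_perm = conn.score_all(query, ref_perm)
        for k, orig in enumerate(perm):
            assert scores_perm["score"].iloc[k] == pytest.approx(
                scores["score"].iloc[orig]
            )


class TestPermutationNull:
    def test_minimum_possible_score_gets_smallest_p(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i:03d}" for i in range(50)]
        col = pd.Series(rng.normal(size=50), index=genes)
        p = conn.permutation_null((5, 5), col, observed_score=-1.0, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)

    def test_requires_enough_permutations(self):
        col = pd.Series(np.arange(10.0), index=[f"G{i}" for i in range(10)])
        with pytest.raises(ValueError):
            conn.permutation_null((2, 2), col, 0.0, n_perm=10)

    def test_planted_reverser_is_significant(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i:03d}" for i in range(200)]
        query = WoundSignature(
            timepoint="T1", up_genes=genes[:20], down_genes=genes[20:40]
        )
        z = rng.normal(size=200)
        z[:20] -= 3.0
        z[20:40] += 3.0
        col = pd.Series(z, index=genes)
        observed = conn.score_signature(query, col)["score"]
        assert observed < 0
        p = conn.permutation_null((20, 20), col, observed, n_perm=200, seed=1)
        assert p <= 0.01
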