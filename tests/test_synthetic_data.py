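"""Generators: determinism, planted-class bookkeeping, recovery properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from woundsig import differential_expression as de
from woundsig import normalization
from woundsig import synthetic_data as syn
from woundsig.containers import TIMEPOINTS
from woundsig.connectivity import score_all


class TestSimulateCounts:
    def test_determinism(self, small_design):
        a, truth_a = syn.simulate_counts(small_design)
        b, truth_b = syn.simulate_counts(small_design)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_series_equal(a.gene_lengths, b.gene_lengths)
        assert truth_a.gene_class == truth_b.gene_class

    def test_subgroup_sizes_and_labels(self, small_experiment):
        experiment, _ = small_experiment
        assert experiment.counts.shape[1] == sum(syn.STUDY_SUBGROUP_SIZES.values())
        for label, n in syn.STUDY_SUBGROUP_SIZES.items():
            assert len(experiment.subgroup(label)) == n

    def test_gene_classes_disjoint_per_timepoint(self, small_experiment):
        _, truth = small_experiment
        for tp in TIMEPOINTS:
            classes = truth.gene_class[tp]
            # mapping form guarantees one class per gene; check counts add up
            by_class = pd.Series(list(classes.values())).value_counts()
            assert by_class.get("progression", 0) == 60
            assert by_class.get("anesthesia", 0) == 60
            assert by_class.get("wound_up", 0) + by_class.get("wound_down", 0) == 120
            assert not (
                {g for g, c in classes.items() if c == "wound_up"}
                & {g for g, c in classes.items() if c == "wound_down"}
            )

    def test_gene_lengths_in_range(self, small_experiment):
        experiment, _ = small_experiment
        assert experiment.gene_lengths.between(500, 10000).all()

    def test_planted_fold_change_on_mean_scale(self, small_design):
        """Wound-up genes should show ~ +2 log2FC in AW vs baseline."""
        experiment, truth = syn.simulate_counts(small_design)
        expr = normalization.normalize(experiment)
        deg = de.test_contrast(expr, de.ContrastSpec("T2", "AW"))
        up = sorted(truth.genes_of("T2", "wound_up"))
        med = deg.table.loc[up, "log2fc"].median()
        assert 1.5 < med < 2.5

    def test_zero_size_subgroup_error_names_subgroup(self):
        sizes = dict(syn.STUDY_SUBGROUP_SIZES)
        sizes["T2_A"] = 0
        with pytest.raises(ValueError, match="T2_A"):
            syn.SimDesign(n_genes=500, subgroup_sizes=sizes)

    def test_too_many_planted_genes_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            syn.SimDesign(n_genes=100, n_progression=50, n_anesthesia=50, n_wound=50)

    def test_global_null_false_positive_rate(self):
        """With no planted effects the DEG caller operates at <= alpha."""
        rates = []
        for seed in range(3):
            design = syn.SimDesign(
                n_genes=800,
                n_progression=0,
                n_anesthesia=0,
                n_wound=0,
                effect_log2fc=0.0,
                seed=100 + seed,
            )
            experiment, _ = syn.simulate_counts(design)
            expr = normalization.normalize(experiment)
            deg = de.test_contrast(expr, de.ContrastSpec("T2", "AW"))
            rates.append(deg.table["is_deg"].mean())
        assert np.mean(rates) <= 0.07


class TestSimulateReference:
    @staticmethod
    def query(seed=0):
        genes = [f"G{i:05d}" for i in range(300)]
        return syn.random_wound_signature(genes, 40, 40, seed)

    def test_determinism(self):
        q = self.query()
        a, ta = syn.simulate_reference(500, 20, 5, 3, q, seed=7)
        b, tb = syn.simulate_reference(500, 20, 5, 3, q, seed=7)
        pd.testing.assert_frame_equal(a.z, b.z)
        assert ta.reverser_compounds == tb.reverser_compounds

    def test_no_reversers_means_no_planted_shift(self):
        q = self.query()
        ref, truth = syn.simulate_reference(500, 30, 4, 0, q, seed=1)
        assert not truth.reverser_compounds
        # signature-gene rows are iid N(0,1): column-mean distribution ~ N(0, 1/sqrt(80))
        sub = ref.z.loc[list(q.genes)]
        z_of_means = sub.mean(axis=0) * np.sqrt(len(q.genes))
        _, p = stats.kstest(z_of_means, "norm")
        assert p > 1e-4

    def test_extreme_loading_reversers_rank_most_negative(self):
        q = self.query()
        ref, truth = syn.simulate_reference(
            500, 30, 4, 3, q, seed=2, loading=1000.0, noise_sd=1e-6
        )
        scores = score_all(q, ref)
        n_reverser_sigs = 3 * 4
        worst = scores.sort_values("score").head(n_reverser_sigs)
        assert set(worst["pert_id"]) == truth.reverser_compounds
        assert (worst["score"] < -0.9).all()

    def test_empty_signature_error(self):
        from woundsig.containers import WoundSignature

        with pytest.raises(ValueError, match="empty"):
            syn.simulate_reference(
                100, 5, 2, 1, WoundSignature("T1", [], []), seed=0
            )

    def test_annotations_cover_all_compounds(self):
        q = self.query()
        ref, _ = syn.simulate_reference(400, 12, 3, 2, q, seed=3)
        assert set(ref.sig_meta["pert_id"]) <= set(ref.pert_meta.index)
        assert ref.z.shape == (400, 36)
        assert {"moa", "phase"} <= set(ref.pert_meta.columns)


class TestSimulateGmt:
    def test_planted_set_overlap_and_determinism(self):
        universe = [f"G{i:05d}" for i in range(1000)]
        signature = universe[:100]
        sets_a, truth = syn.simulate_gmt(universe, 20, (30, 80), signature, seed=5)
        sets_b, _ = syn.simulate_gmt(universe, 20, (30, 80), signature, seed=5)
        assert sets_a == sets_b
        assert truth.enriched_terms == {"PLANTED_WOUND_SET"}
        planted = set(sets_a["PLANTED_WOUND_SET"])
        assert len(planted & set(signature)) >= 0.5 * len(planted)

    def test_planted_set_passes_ora_filters(self):
        """Planted set sharing 30/50 genes with a 100-gene query passes count>3, p<0.01."""
        from woundsig.enrichment import ora_hypergeometric

        universe = [f"G{i:05d}" for i in range(1000)]
        signature = universe[:100]
        planted = universe[:30] + universe[900:920]  # 30 of 50 from signature
        overlap, p = ora_hypergeometric(set(signature), set(planted), 1000)
        assert overlap > 3 and p < 0.01

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="empty"):
            syn.simulate_gmt([], 5, (2, 3), ["x"], seed=0)

    def test_oversized_sets_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            syn.simulate_gmt([f"G{i}" for i in range(10)], 5, (5, 50), ["G1"], seed=0)


class TestSimulateTumorWeights:
    def test_default_design_labels(self):
        w = syn.simulate_tumor_weights(seed=3)
        assert set(w["timepoint"]) == {"T1", "T2", "T3"}
        assert set(w["intervention"]) == {"N", "A", "AW"}
        assert (w["weight"] >= 0).all()

    def test_determinism(self):
        pd.testing.assert_frame_equal(
            syn.simulate_tumor_weights(seed=9), syn.simulate_tumor_weights(seed=9)
        )

    def test_sd_zero_degenerate_groups(self):
        w = syn.simulate_tumor_weights(
            group_sds={k: 0.0 for k in ("T1_N", "T1_A", "T1_AW")}, seed=0
        )
        t1 = w[w["timepoint"] == "T1"]
        assert (t1.groupby("intervention")["weight"].std() == 0).all()

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            syn.simulate_tumor_weights(group_ns={"T1_N": 1}, seed=0)

    def test_power_for_default_t1_effect(self):
        """means 1.0 vs 1.6 g, sd 0.3, n=10: significant in >= 80% of seeds."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            w = syn.simulate_tumor_weights(seed=seed)
            out = de.compare_tumor_burden(w)
            row = out[
                (out["timepoint"] == "T1")
                & (out["group_a"] == "AW")
                & (out["group_b"] == "N")
            ].iloc[0]
            hits += row["p"] < 0.05
        assert hits / n_seeds >= 0.8
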