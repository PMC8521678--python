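"""Composition, differential expression, diffusion maps, and
ligand-receptor scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from conftest import make_adata
from lrtme import sc


class TestComposition:
    def test_proportions_from_counts(self):
        adata = make_adata(
            np.zeros((10, 2)),
            clusters=["Treg"] * 3 + ["B"] * 7,
        )
        comp = sc.composition(adata)
        treg = comp[comp["cell_type"] == "Treg"]
        assert treg["proportion"].iloc[0] == pytest.approx(0.3)

    def test_proportions_sum_to_one_per_sample(self, small_adata):
        comp = sc.composition(small_adata)
        sums = comp.groupby("sample_id")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0)

    def test_unmapped_cluster_is_error(self):
        adata = make_adata(np.zeros((4, 2)), clusters=["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="b"):
            sc.composition(adata, type_map={"a": "T"})

    def test_type_map_merges_clusters(self):
        adata = make_adata(
            np.zeros((4, 2)), clusters=["a", "b", "c", "c"]
        )
        comp = sc.composition(
            adata, type_map={"a": "T", "b": "T", "c": "B"}
        )
        t = comp[comp["cell_type"] == "T"]["proportion"].iloc[0]
        assert t == pytest.approx(0.5)

    def test_planted_treg_depletion_detected(self):
        """LR-vs-other Treg composition difference is detected with the
        right direction in >=95% of 60 simulated cohorts."""
        from lrtme import synthetic
        from lrtme.spatial import compare_between_groups

        hits = 0
        n_rep = 60
        for seed in range(n_rep):
            adata = synthetic.generate_expression(
                synthetic.default_expression_spec(seed=seed)
            )
            comp = sc.composition(adata)
            treg = comp[comp["cell_type"] == "Treg"].set_index("sample_id")
            groups = treg["subtype"].to_dict()
            res = compare_between_groups(treg["proportion"], groups)
            direction = res.group_means["LR"] < res.group_means["otherCHL"]
            hits += (res.p_value < 0.05) and direction
        assert hits / n_rep >= 0.95


class TestTypeRatio:
    def test_simple_ratio(self):
        adata = make_adata(
            np.zeros((50, 2)), clusters=["NaiveB"] * 40 + ["GCB"] * 10
        )
        ratio = sc.type_ratio(sc.composition(adata), "NaiveB", "GCB")
        assert ratio["ratio"].iloc[0] == pytest.approx(4.0)

    def test_zero_denominator_is_flagged_undefined(self):
        adata = make_adata(
            np.zeros((5, 2)),
            clusters=["NaiveB"] * 5,
            samples=["s0"] * 5,
        )
        comp = sc.composition(adata, type_map={"NaiveB": "NaiveB", "GCB": "GCB"})
        ratio = sc.type_ratio(comp, "NaiveB", "GCB")
        assert not ratio["defined"].iloc[0]
        assert np.isnan(ratio["ratio"].iloc[0])

    def test_equals_proportion_ratio(self, small_adata):
        comp = sc.composition(small_adata)
        ratio = sc.type_ratio(comp, "NaiveB", "GCB")
        wide = comp.pivot_table(
            index="sample_id", columns="cell_type", values="proportion"
        )
        expected = (wide["NaiveB"] / wide["GCB"]).to_numpy()
        got = ratio.set_index("sample_id")["ratio"].to_numpy()
        defined = ratio["defined"].to_numpy()
        np.testing.assert_allclose(got[defined], expected[defined])


class TestDifferentialExpression:
    def test_identical_groups_zero_lfc(self):
        X = np.tile(np.array([[1.0, 2.0, 3.0]]), (6, 1))
        adata = make_adata(X)
        res = sc.differential_expression(
            adata, np.arange(6) < 3, np.arange(6) >= 3
        )
        np.testing.assert_allclose(res["log2_fold_change"], 0.0)
        assert not res["significant"].any()

    def test_exact_wilcoxon_two_vs_two(self):
        """A={3,3} vs B={1,1}: log2FC=2 and exact two-sided rank-sum
        p = 1/3 (2 extreme arrangements out of C(4,2)=6)."""
        X = np.array([[3.0], [3.0], [1.0], [1.0]])
        adata = make_adata(X)
        res = sc.differential_expression(
            adata, np.array([1, 1, 0, 0], bool), np.array([0, 0, 1, 1], bool)
        )
        assert res["log2_fold_change"].iloc[0] == pytest.approx(2.0)
        assert res["p_value"].iloc[0] == pytest.approx(1 / 3)

    def test_symmetry_under_group_swap(self, small_adata):
        tfh = (small_adata.obs["cluster"] == "TFH").to_numpy()
        lr = (small_adata.obs["subtype"] == "LR").to_numpy()
        ab = sc.differential_expression(small_adata, tfh & lr, tfh & ~lr)
        ba = sc.differential_expression(small_adata, tfh & ~lr, tfh & lr)
        np.testing.assert_allclose(
            ab["log2_fold_change"], -ba["log2_fold_change"], atol=1e-12
        )
        np.testing.assert_allclose(ab["p_value"], ba["p_value"], atol=1e-12)

    def test_volcano_rule(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5, 1, size=(40, 3))
        X[:20, 0] += 3.0  # large shift -> significant
        X[:20, 1] += 0.5  # small shift -> fails |lfc| >= 1
        adata = make_adata(X)
        res = sc.differential_expression(
            adata, np.arange(40) < 20, np.arange(40) >= 20
        ).set_index("gene")
        assert bool(res.loc["g0", "significant"])
        assert not bool(res.loc["g1", "significant"])

    def test_too_few_cells_rejected(self):
        adata = make_adata(np.zeros((3, 1)))
        with pytest.raises(ValueError):
            sc.differential_expression(
                adata, np.array([1, 0, 0], bool), np.array([0, 1, 1], bool)
            )


class TestBenjaminiHochberg:
    def test_hand_worked_stepup(self):
        # p = (0.01, 0.02, 0.03, 0.04), m=4:
        # q4 = 0.04; q3 = min(0.04, 0.03*4/3)=0.04; q2 = min(.04, .02*2)=0.04;
        # q1 = min(0.04, 0.01*4) = 0.04
        np.testing.assert_allclose(
            sc.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), 0.04
        )

    @staticmethod
    def bh_oracle(p):
        """Step-up definition: q_(i) = min over j>=i of p_(j) * m / j."""
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p, kind="stable")
        q_sorted = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        return q

    def test_matches_stepup_oracle_on_fuzzed_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(1, 40)
            p = rng.uniform(0, 1, n)
            if rng.random() < 0.3:  # inject ties
                p = np.round(p, 1)
            np.testing.assert_allclose(
                sc.bh_adjust(p), self.bh_oracle(p), atol=1e-12
            )


class TestDiffusionMap:
    def test_transition_rows_sum_to_one(self, rng):
        X = rng.normal(size=(30, 5))
        P = sc.transition_matrix(X, bandwidth=2.0)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_matches_dense_eigendecomposition_oracle(self, rng):
        """Embedding equals the explicit eigendecomposition of the
        transition operator, component-wise up to sign, at 1e-8."""
        X = rng.normal(size=(40, 6))
        adata = make_adata(X)
        emb = sc.diffusion_map(adata, n_components=3, bandwidth=2.5)
        P = sc.transition_matrix(X, bandwidth=2.5)
        vals, vecs = linalg.eig(P)
        order = np.argsort(vals.real)[::-1]
        vals, vecs = vals.real[order], vecs.real[:, order]
        np.testing.assert_allclose(emb.eigenvalues, vals[1:4], atol=1e-8)
        for k in range(3):
            oracle = vecs[:, k + 1] * vals[k + 1]
            got = emb.coordinates[:, k]
            # unit-normalize both; sign is a free choice
            oracle = oracle / np.linalg.norm(oracle)
            gotn = got / np.linalg.norm(got)
            err = min(
                np.abs(gotn - oracle).max(), np.abs(gotn + oracle).max()
            )
            assert err < 1e-8

    def test_two_separated_clusters_split_by_component_one(self, rng):
        X = np.vstack(
            [rng.normal(0, 0.3, size=(15, 4)), rng.normal(8, 0.3, size=(15, 4))]
        )
        adata = make_adata(X)
        emb = sc.diffusion_map(adata, n_components=2)
        signs = np.sign(emb.coordinates[:, 0])
        assert len(set(signs[:15])) == 1
        assert len(set(signs[15:])) == 1
        assert signs[0] != signs[20]

    def test_permutation_equivariance_up_to_sign(self, rng):
        X = rng.normal(size=(25, 4))
        perm = rng.permutation(25)
        emb = sc.diffusion_map(make_adata(X), n_components=2, bandwidth=2.0)
        emb_p = sc.diffusion_map(
            make_adata(X[perm]), n_components=2, bandwidth=2.0
        )
        for k in range(2):
            a = emb.coordinates[perm, k]
            b = emb_p.coordinates[:, k]
            assert min(
                np.abs(a - b).max(), np.abs(a + b).max()
            ) < 1e-8

    def test_duplicate_cells_only_is_degenerate(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="degenerate|identical"):
            sc.diffusion_map(make_adata(X), n_components=2)

    def test_eigenvalues_nonincreasing(self, rng):
        X = rng.normal(size=(30, 5))
        emb = sc.diffusion_map(make_adata(X), n_components=4, bandwidth=2.0)
        assert (np.diff(emb.eigenvalues) <= 1e-12).all()


class TestGeneDimensionCorrelation:
    def test_gene_equal_to_score_has_r_one(self, rng):
        X = rng.normal(size=(20, 3))
        adata = make_adata(X)
        emb = sc.diffusion_map(adata, n_components=2, bandwidth=2.0)
        adata.X[:, 0] = emb.dimension_score(2)
        res = sc.gene_dimension_correlation(adata, emb, dimension=2)
        assert res.set_index("gene").loc["g0", "r"] == pytest.approx(1.0)

    def test_hand_computed_correlation(self):
        # r((0,0,1,1),(1,2,3,4)) = 2/sqrt(5)
        x = np.array([0.0, 0.0, 1.0, 1.0])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([x, np.ones(4)])
        adata = make_adata(X, genes=["gx", "gconst"])
        emb = sc.DiffusionEmbedding(
            coordinates=np.column_stack([y, y]),
            eigenvalues=np.array([1.0, 0.5]),
            kernel_bandwidth=1.0,
        )
        res = sc.gene_dimension_correlation(adata, emb, dimension=2)
        res = res.set_index("gene")
        assert res.loc["gx", "r"] == pytest.approx(2 / np.sqrt(5))
        # constant gene: undefined, reported missing, not zero
        assert not res.loc["gconst", "defined"]
        assert np.isnan(res.loc["gconst", "r"])

    def test_sorted_descending_with_lexicographic_ties(self):
        X = np.column_stack([
            [1.0, 2, 3, 4], [1.0, 2, 3, 4], [4.0, 3, 2, 1],
        ])
        adata = make_adata(X, genes=["b", "a", "c"])
        emb = sc.DiffusionEmbedding(
            coordinates=np.array([[1.0], [2.0], [3.0], [4.0]]),
            eigenvalues=np.array([1.0]),
            kernel_bandwidth=1.0,
        )
        res = sc.gene_dimension_correlation(adata, emb, dimension=1)
        assert res["gene"].tolist() == ["a", "b", "c"]


class TestInteractionScores:
    def build(self):
        # senders: cluster T; receivers: cluster B; two conditions
        X = np.array(
            [
                # CXCL13, CXCR5
                [2.0, 0.0],   # LR sender
                [2.0, 0.0],   # LR sender
                [0.0, 1.5],   # LR receiver
                [0.5, 0.0],   # other sender
                [0.5, 0.0],   # other sender
                [0.0, 1.0],   # other receiver
            ]
        )
        return make_adata(
            X,
            clusters=["T", "T", "B", "T", "T", "B"],
            subtypes=["LR", "LR", "LR", "otherCHL", "otherCHL", "otherCHL"],
            genes=["CXCL13", "CXCR5"],
        )

    def test_worked_arithmetic(self):
        res = sc.interaction_scores(
            self.build(), [("CXCL13", "CXCR5")], ["T"], ["B"]
        )
        assert res["score_a"].iloc[0] == pytest.approx(3.0)
        assert res["score_b"].iloc[0] == pytest.approx(0.5)
        assert res["delta"].iloc[0] == pytest.approx(2.5)

    def test_absent_ligand_scores_zero(self):
        adata = self.build()
        adata.X[:, 0] = 0.0
        res = sc.interaction_scores(
            adata, [("CXCL13", "CXCR5")], ["T"], ["B"]
        )
        assert res["score_a"].iloc[0] == 0.0

    def test_missing_gene_pair_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="NOPE"):
            res = sc.interaction_scores(
                self.build(), [("NOPE", "CXCR5"), ("CXCL13", "CXCR5")],
                ["T"], ["B"],
            )
        assert len(res) == 1

    def test_delta_linear_in_ligand_mean(self):
        adata = self.build()
        base = sc.interaction_scores(
            adata, [("CXCL13", "CXCR5")], ["T"], ["B"]
        )["score_a"].iloc[0]
        adata.X[:2, 0] *= 3.0  # triple LR sender ligand mean
        tripled = sc.interaction_scores(
            adata, [("CXCL13", "CXCR5")], ["T"], ["B"]
        )["score_a"].iloc[0]
        assert tripled == pytest.approx(3 * base)

    def test_permutation_p_small_for_planted_signal(self, small_adata):
        res = sc.interaction_scores(
            small_adata,
            [("CXCL13", "CXCR5")],
            sender_clusters=["TFH", "CD4_helper"],
            receiver_clusters=["NaiveB", "GCB", "MemB"],
            n_permutations=99,
            seed=0,
        )
        assert res["permutation_p"].iloc[0] <= 0.05
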