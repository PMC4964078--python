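"""Recurrence score, subtype-correlation score, mean-Z index, Spearman."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nodesig as ns
from nodesig.errors import MissingFeatureError, UndefinedStatisticError
from nodesig.signature_registry import SignatureGene, GeneSignature

from conftest import make_matrix
from helpers import spearman_formula


def zscore_matrix_for(symbols, values):
    """Build a zscore-scale matrix with the given per-gene rows."""
    return make_matrix(values, gene_ids=list(symbols), scale="zscore")


@pytest.fixture(scope="module")
def oncotype_sig():
    return ns.load_builtin("oncotype")


class TestOncotypeRS:
    def _matrix(self, sig, fill=0.0, n=3):
        vals = np.full((len(sig.genes), n), fill)
        return zscore_matrix_for(sig.symbols, vals)

    def test_all_zero_gives_zero(self, oncotype_sig):
        sv = ns.oncotype_rs(self._matrix(oncotype_sig))
        np.testing.assert_allclose(sv.scores, 0.0)
        assert sv.orientation == "higher_is_worse"

    def test_proliferation_unit_column_gives_coefficient(self, oncotype_sig):
        m = self._matrix(oncotype_sig, 0.0, n=2)
        vals = m.values.copy()
        prolif = [g.symbol for g in oncotype_sig.genes if g.group == "proliferation"]
        vals.loc[prolif, vals.columns[0]] = 1.0
        sv = ns.oncotype_rs(ns.ExpressionMatrix(vals, scale="zscore"))
        # hand evaluation: group mean = 1, proliferation coefficient 1.04
        assert sv.scores.iloc[0] == pytest.approx(1.04)
        assert sv.scores.iloc[1] == pytest.approx(0.0)

    def test_homogeneity(self, oncotype_sig, rng):
        vals = rng.normal(size=(len(oncotype_sig.genes), 4))
        m1 = zscore_matrix_for(oncotype_sig.symbols, vals)
        m2 = zscore_matrix_for(oncotype_sig.symbols, 2 * vals)
        np.testing.assert_allclose(
            2 * ns.oncotype_rs(m1).scores, ns.oncotype_rs(m2).scores
        )

    def test_missing_gene_named_in_error(self, oncotype_sig):
        m = self._matrix(oncotype_sig)
        vals = m.values.drop(index="GRB7")
        with pytest.raises(MissingFeatureError, match="GRB7"):
            ns.oncotype_rs(ns.ExpressionMatrix(vals, scale="zscore"))

    def test_full_linear_form_hand_computed(self, oncotype_sig, rng):
        vals = rng.normal(size=(16, 3))
        m = zscore_matrix_for(oncotype_sig.symbols, vals)
        sv = ns.oncotype_rs(m)
        # independent evaluation of sum_groups coef * weighted mean
        expected = np.zeros(3)
        for group, coef in oncotype_sig.group_coefficients.items():
            members = [g for g in oncotype_sig.genes if g.group == group]
            gscore = sum(m.values.loc[g.symbol].to_numpy() * g.weight for g in members)
            expected += coef * gscore
        np.testing.assert_allclose(sv.scores.to_numpy(), expected)


class TestSpearman:
    def test_perfect_and_reversed(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert ns.spearman_rho(x, x) == pytest.approx(1.0)
        assert ns.spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_matches_rank_formula_and_scipy(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        expected = spearman_formula(x, y)  # 1 - 6*sum(d^2)/(n(n^2-1))
        assert ns.spearman_rho(x, y) == pytest.approx(expected)
        assert ns.spearman_rho(x, y) == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_ties_use_midranks(self, rng):
        x = rng.integers(0, 4, 20).astype(float)
        y = rng.normal(size=20)
        assert ns.spearman_rho(x, y) == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_constant_vector_raises(self):
        with pytest.raises(UndefinedStatisticError):
            ns.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def pam():
    return ns.load_builtin("pam50")


class TestProsignaROR:

    def test_sample_equal_to_centroid_has_rho_one(self, pam, rng):
        genes = pam.genes
        luma = pam.matrix["LumA"].to_numpy()
        other = rng.normal(size=len(genes))
        m = zscore_matrix_for(genes, np.column_stack([luma, other]))
        sv = ns.prosigna_ror(m, pam)
        # hand-computed expected ROR for the LumA-identical sample
        expected = sum(
            coef * ns.spearman_rho(luma, pam.matrix[st].to_numpy())
            for st, coef in pam.ror_coefficients.items()
        )
        assert sv.scores.iloc[0] == pytest.approx(expected)
        assert ns.spearman_rho(luma, luma) == pytest.approx(1.0)

    def test_identical_samples_identical_scores(self, pam, rng):
        v = rng.normal(size=len(pam.genes))
        m = zscore_matrix_for(pam.genes, np.column_stack([v, v]))
        sv = ns.prosigna_ror(m, pam)
        assert sv.scores.iloc[0] == pytest.approx(sv.scores.iloc[1])

    def test_monotone_transform_invariance(self, pam, rng):
        v = rng.normal(size=len(pam.genes))
        m1 = zscore_matrix_for(pam.genes, v[:, None])
        m2 = zscore_matrix_for(pam.genes, (np.exp(v) * 3 + 1)[:, None])
        np.testing.assert_allclose(
            ns.prosigna_ror(m1, pam).scores, ns.prosigna_ror(m2, pam).scores
        )

    def test_gene_subset_restriction(self, pam, rng):
        available = [g for g in pam.genes if g not in set(pam.default_exclusion)]
        v = rng.normal(size=len(pam.genes))
        m = zscore_matrix_for(pam.genes, v[:, None])
        full = ns.prosigna_ror(m, pam)
        restricted = ns.prosigna_ror(m, pam, gene_subset=available)
        assert full.scores.iloc[0] != pytest.approx(restricted.scores.iloc[0])

    def test_too_few_genes_raises(self, pam, rng):
        m = zscore_matrix_for(pam.genes[:5], rng.normal(size=(5, 2)))
        with pytest.raises(MissingFeatureError):
            ns.prosigna_ror(m, pam)


class TestDirectionalMeanIndex:
    @pytest.fixture
    def sig(self):
        genes = [SignatureGene(s, "good") for s in ("G1", "G2", "G3")] + [
            SignatureGene(s, "poor") for s in ("P1", "P2")
        ]
        return GeneSignature("toy", genes)

    def test_zero_matrix_gives_zero(self, sig):
        m = zscore_matrix_for(["G1", "G2", "G3", "P1", "P2"], np.zeros((5, 2)))
        np.testing.assert_allclose(ns.directional_mean_index(m, sig).scores, 0.0)

    def test_good_up_poor_down_gives_two(self, sig):
        vals = np.array([[1.0]] * 3 + [[-1.0]] * 2)
        m = zscore_matrix_for(["G1", "G2", "G3", "P1", "P2"], vals)
        sv = ns.directional_mean_index(m, sig)
        assert sv.scores.iloc[0] == pytest.approx(2.0)
        assert sv.orientation == "higher_is_better"

    def test_matches_independent_means(self, sig, rng):
        vals = rng.normal(size=(5, 4))
        m = zscore_matrix_for(["G1", "G2", "G3", "P1", "P2"], vals)
        sv = ns.directional_mean_index(m, sig)
        expected = vals[:3].mean(axis=0) - vals[3:].mean(axis=0)
        np.testing.assert_allclose(sv.scores.to_numpy(), expected)

    def test_missing_direction_class_raises(self, sig, rng):
        m = zscore_matrix_for(["G1", "G2", "G3"], rng.normal(size=(3, 2)))
        with pytest.raises(MissingFeatureError):
            ns.directional_mean_index(m, sig)
        # but tolerated when explicitly allowed
        sv = ns.directional_mean_index(m, sig, allow_one_sided=True)
        np.testing.assert_allclose(
            sv.scores.to_numpy(), m.values.to_numpy().mean(axis=0)
        )


class TestScoreProperties:
    def test_permutation_equivariance(self, rng):
        sig = ns.load_builtin("oncotype")
        vals = rng.normal(size=(16, 6))
        m = zscore_matrix_for(sig.symbols, vals)
        sv = ns.oncotype_rs(m)
        perm = rng.permutation(6)
        m2 = ns.ExpressionMatrix(m.values.iloc[:, perm], scale="zscore")
        sv2 = ns.oncotype_rs(m2)
        np.testing.assert_allclose(sv.scores.loc[sv2.scores.index], sv2.scores)

    def test_mean_z_index_tracks_survival_direction(self):
        # poor-direction genes elevated in short-survival samples -> index
        # correlates positively with survival time
        rng = np.random.default_rng(3)
        n = 60
        surv = rng.exponential(50, n)
        short = surv < np.median(surv)
        poor_expr = np.where(short, 1.0, -1.0) + rng.normal(0, 0.3, n)
        good_expr = np.where(short, -1.0, 1.0) + rng.normal(0, 0.3, n)
        m = zscore_matrix_for(["G", "P"], np.vstack([good_expr, poor_expr]))
        sig = GeneSignature(
            "toy", [SignatureGene("G", "good"), SignatureGene("P", "poor")]
        )
        sv = ns.directional_mean_index(m, sig)
        assert np.corrcoef(sv.scores, surv)[0, 1] > 0.3
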