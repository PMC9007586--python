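import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prodemand import (
    CANONICAL_RESIDUES,
    CompositionVector,
    GeneSet,
    ValidationError,
    composition,
    fold_enrichment,
    group_compare,
    percent_increase,
    percentile_analysis,
    set_composition,
)
from prodemand.set_stats import midrank_percentiles
from tests.conftest import make_proteome


def uniformish(pro=0.05):
    """A valid 20-residue fraction vector with a chosen Pro fraction."""
    rest = (1.0 - pro) / 19
    return CompositionVector(
        fractions={a: (pro if a == "P" else rest) for a in CANONICAL_RESIDUES}
    )


class TestSetComposition:
    def test_singleton_set_equals_protein_under_both_aggregations(self, toy_proteome):
        gs = GeneSet("GO:1", "x", frozenset({"g3"}))
        direct = composition("PAPA").fractions
        for agg in ("mean_of_proteins", "pooled_residues"):
            result = set_composition(gs, toy_proteome, aggregation=agg)
            assert result.composition.fractions == pytest.approx(direct)

    def test_mean_vs_pooled_distinguished(self, toy_proteome):
        # "PP" (Pro 1.0) and "AAAA" (Pro 0.0): mean 0.5, pooled 2/6
        gs = GeneSet("GO:1", "x", frozenset({"g1", "g2"}))
        mean = set_composition(gs, toy_proteome, aggregation="mean_of_proteins")
        pooled = set_composition(gs, toy_proteome, aggregation="pooled_residues")
        assert mean.composition.fractions["P"] == pytest.approx(0.5)
        assert pooled.composition.fractions["P"] == pytest.approx(2 / 6)

    def test_unresolved_members_reported_not_dropped(self, toy_proteome):
        gs = GeneSet("GO:1", "x", frozenset({"g1", "ghost"}))
        result = set_composition(gs, toy_proteome)
        assert result.n_resolved == 1
        assert result.unresolved_gene_ids == ["ghost"]

    def test_zero_resolvable_members_rejected(self, toy_proteome):
        gs = GeneSet("GO:1", "x", frozenset({"ghost"}))
        with pytest.raises(ValidationError):
            set_composition(gs, toy_proteome)

    def test_mean_invariant_to_member_order(self, toy_proteome):
        a = set_composition(GeneSet("GO:1", "x", frozenset(["g1", "g2", "g3"])), toy_proteome)
        b = set_composition(GeneSet("GO:2", "y", frozenset(["g3", "g1", "g2"])), toy_proteome)
        assert a.composition.fractions == b.composition.fractions


class TestEnrichment:
    def test_identity_entity_gives_all_ones(self):
        bg = uniformish(0.05)
        matrix = fold_enrichment({"self": bg}, bg)
        assert np.allclose(matrix.values.to_numpy(), 1.0)
        assert not matrix.below_background_mask().any().any()

    def test_printed_marker_fold_change(self):
        # Pro-rich transcription factor vs proteome background: .105/.061
        entity = uniformish(0.105)
        background = uniformish(0.061)
        fold = fold_enrichment({"marker": entity}, background)
        assert round(fold.values.loc["marker", "P"], 2) == 1.72

    def test_percent_increase_from_printed_set_values(self):
        fold = percent_increase({"osteoblast": uniformish(0.0711)}, uniformish(0.0612))
        assert round(fold.values.loc["osteoblast", "P"], 1) == 16.2

    def test_zero_background_fraction_names_residue(self):
        bg = composition("ACDEFGHIKLMNQRSTVWY")  # no Pro
        with pytest.raises(ValidationError, match="P"):
            fold_enrichment({"x": uniformish(0.1)}, bg)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, derandomize=True)
    def test_percent_equals_100_times_fold_minus_one(self, seed):
        rng = np.random.default_rng(seed)
        vecs = rng.dirichlet(np.ones(20), size=3)
        bg_vec = rng.dirichlet(np.full(20, 5.0))
        entities = {
            f"e{i}": CompositionVector(
                fractions=dict(zip(CANONICAL_RESIDUES, vecs[i] / vecs[i].sum()))
            )
            for i in range(3)
        }
        bg = CompositionVector(fractions=dict(zip(CANONICAL_RESIDUES, bg_vec / bg_vec.sum())))
        fold = fold_enrichment(entities, bg).values
        pct = percent_increase(entities, bg).values
        assert np.abs(pct - 100.0 * (fold - 1.0)).to_numpy().max() < 1e-9

    def test_fold_matches_elementwise_division_oracle(self):
        rng = np.random.default_rng(7)
        v = rng.dirichlet(np.ones(20))
        b = rng.dirichlet(np.full(20, 3.0))
        entity = CompositionVector(fractions=dict(zip(CANONICAL_RESIDUES, v / v.sum())))
        bg = CompositionVector(fractions=dict(zip(CANONICAL_RESIDUES, b / b.sum())))
        fold = fold_enrichment({"e": entity}, bg).values.loc["e"]
        for i, a in enumerate(CANONICAL_RESIDUES):
            assert fold[a] == pytest.approx(entity.fractions[a] / bg.fractions[a], abs=1e-12)


class TestPercentiles:
    def test_midrank_formula_hand_case(self):
        # background 0.01..1.00; the 91st smallest value has 90 below + itself
        background = np.round(np.arange(0.01, 1.005, 0.01), 2)
        assert midrank_percentiles(background, np.array([0.91]))[0] == pytest.approx(90.5)

    def test_midrank_with_ties_counts_half(self):
        bg = np.array([1.0, 2.0, 2.0, 3.0])
        assert midrank_percentiles(bg, np.array([2.0]))[0] == pytest.approx(
            100 * (1 + 0.5 * 2) / 4
        )

    def _distinct_proteome(self, n=100):
        # n proteins with strictly increasing Pro fractions i/(n+something)
        spec = []
        for i in range(1, n + 1):
            seq = "P" * i + "A" * (n + 1 - i)
            spec.append((f"P{i:03d}", f"g{i:03d}", f"t{i:03d}", seq))
        return make_proteome(spec)

    def test_whole_background_above_its_own_quantile(self):
        proteome = self._distinct_proteome(100)
        gs = GeneSet("GO:ALL", "all", frozenset(f"g{i:03d}" for i in range(1, 101)))
        summary = percentile_analysis(gs, proteome, residue="P", threshold_q=0.75)
        # distinct values: fraction strictly above the q-quantile = floor(N(1-q))/N
        assert summary.fraction_above == pytest.approx(0.25)
        assert summary.n_background == 100

    @pytest.mark.parametrize("q", [0.1, 0.25, 0.5, 0.9])
    def test_self_consistency_floor_rule(self, q):
        proteome = self._distinct_proteome(60)
        gs = GeneSet("GO:ALL", "all", frozenset(f"g{i:03d}" for i in range(1, 61)))
        summary = percentile_analysis(gs, proteome, residue="P", threshold_q=q)
        expected = math.floor(60 * (1 - q) + 1e-9) / 60  # guard float representation
        assert summary.fraction_above == pytest.approx(expected)

    def test_members_above_background_max(self):
        spec = [(f"P{i}", f"g{i}", f"t{i}", "A" * 20) for i in range(1, 9)]
        spec += [("PX", "gx", "tx", "P" * 10 + "A" * 10), ("PY", "gy", "ty", "P" * 15 + "A" * 5)]
        proteome = make_proteome(spec)
        gs = GeneSet("GO:HI", "hi", frozenset({"gx", "gy"}))
        summary = percentile_analysis(gs, proteome, residue="P", threshold_q=0.75)
        assert summary.fraction_above == 1.0

    def test_small_background_rejected(self):
        proteome = self._distinct_proteome(3)
        gs = GeneSet("GO:1", "x", frozenset({"g001"}))
        with pytest.raises(ValidationError):
            percentile_analysis(gs, proteome)


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_pooled_case(self):
        res = group_compare([0.05, 0.06, 0.07], [0.08, 0.09, 0.10])
        assert res.t_stat == pytest.approx(-3.674, abs=5e-4)
        assert res.df == 4

    def test_antisymmetry(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1.3, 9)
        fwd = group_compare(a, b)
        rev = group_compare(b, a)
        assert fwd.t_stat == pytest.approx(-rev.t_stat)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_welch_variant_df_below_pooled(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 5, 10)
        welch = group_compare(a, b, variant="welch")
        pooled = group_compare(a, b, variant="pooled")
        assert pooled.df == 18
        assert welch.df < pooled.df

    def test_quartiles_and_medians_reported(self):
        res = group_compare([1, 2, 3, 4, 5], [10, 20, 30, 40])
        assert res.medians == (3.0, 25.0)
        assert res.quartiles[0] == (2.0, 4.0)

    def test_constant_equal_groups_rejected(self):
        with pytest.raises(ValidationError):
            group_compare([1.0, 1.0], [1.0, 1.0])

    def test_constant_unequal_groups_warn_p_zero(self):
        with pytest.warns(UserWarning):
            res = group_compare([1.0, 1.0], [2.0, 2.0])
        assert res.p_value == 0.0

    def test_matches_textbook_pooled_formula(self):
        rng = np.random.default_rng(123)
        a, b = rng.normal(0, 1, 8), rng.normal(0.3, 1, 14)
        res = group_compare(a, b)
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert res.t_stat == pytest.approx(t, abs=1e-12)
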