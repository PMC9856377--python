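"""Upstream-regulator statistics tests (Fisher overlap + activation z-score)."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epibarrier import (
    RegulatorNetwork,
    UndefinedResultError,
    ValidationError,
    activation_zscore,
    overlap_pvalue,
    rank_regulators,
    select_de_genes,
)
from epibarrier.enrichment_stats import overlap_pvalue_exact
from epibarrier.synthetic_data import make_random_network, simulate_de_table


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "padj"])


class TestSelectDeGenes:
    def test_zero_thresholds_select_everything(self):
        table = de_table([("a", 0.5, 0.5, 0.6), ("b", -2.0, 0.01, 0.02)])
        sel = select_de_genes(table, lfc_threshold=0.0, p_threshold=1.0)
        assert sel == {"a": 1, "b": -1}

    def test_downregulated_transporter_selected_with_sign(self):
        # NKCC1-style row: strong down-regulation at small p
        table = de_table([("SLC12A2", -1.8, 0.0005, 0.004), ("OCLN", 1.2, 0.4, 0.6)])
        sel = select_de_genes(table, lfc_threshold=1.0, p_threshold=0.05)
        assert sel == {"SLC12A2": -1}

    def test_raw_vs_adjusted_p_switch(self):
        table = de_table([("a", 2.0, 0.01, 0.2)])
        assert select_de_genes(table, 1.0, 0.05, use_adjusted=True) == {}
        assert select_de_genes(table, 1.0, 0.05, use_adjusted=False) == {"a": 1}

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            select_de_genes(de_table([]))

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValidationError):
            select_de_genes(de_table([("a", 1.0, 0.1, 0.1), ("a", 2.0, 0.1, 0.1)]))


class TestOverlapPvalue:
    def test_zero_overlap_gives_one(self):
        assert overlap_pvalue({"a", "b"}, {"c", "d"}, 20) == pytest.approx(1.0)

    def test_worked_hypergeometric_case(self):
        # universe 20, 5 targets, 4 DE, overlap 3 -> 155/4845
        de = {"t1", "t2", "t3", "x1"}
        targets = {"t1", "t2", "t3", "t4", "t5"}
        p = overlap_pvalue(de, targets, 20)
        assert p == pytest.approx(155 / 4845, rel=1e-12)

    def test_brute_force_draw_enumeration_matches_worked_case(self):
        # enumerate all C(20,4) DE draws; count overlap >= 3 with 5 targets
        universe = range(20)
        targets = set(range(5))
        hits = sum(1 for draw in combinations(universe, 4)
                   if len(targets & set(draw)) >= 3)
        total = sum(1 for _ in combinations(universe, 4))
        assert hits / total == pytest.approx(155 / 4845, rel=1e-12)

    def test_degenerate_full_overlap(self):
        genes = {"a", "b", "c"}
        assert overlap_pvalue(genes, genes, 3) == pytest.approx(1.0)

    def test_exact_fraction_oracle_small_universes(self):
        # implementation equals exact integer enumeration on a small sweep
        for universe in (5, 10, 17):
            for n_targets in range(universe + 1):
                for n_de in range(universe + 1):
                    for k in range(min(n_targets, n_de) + 1):
                        exact = overlap_pvalue_exact(universe, n_targets, n_de, k)
                        de = set(range(n_de))
                        tg = set(range(k)) | set(range(n_de, n_de + n_targets - k))
                        if len(de | tg) > universe:
                            continue
                        p = overlap_pvalue(de, tg, universe)
                        assert p == pytest.approx(float(exact), rel=1e-9)

    def test_undersized_universe_rejected(self):
        with pytest.raises(ValidationError):
            overlap_pvalue({"a", "b"}, {"c"}, 2)


class TestActivationZscore:
    def test_all_agree(self):
        de = {g: 1 for g in "abcd"}
        targets = {g: 1 for g in "abcd"}
        assert activation_zscore(de, targets) == pytest.approx(2.0)

    def test_nine_one_split(self):
        genes = [f"g{i}" for i in range(10)]
        de = {g: 1 for g in genes}
        targets = {g: 1 for g in genes[:9]}
        targets[genes[9]] = -1
        assert activation_zscore(de, targets) == pytest.approx(8 / np.sqrt(10), rel=1e-9)
        assert activation_zscore(de, targets) == pytest.approx(2.530, abs=5e-4)

    def test_balanced_split_is_zero(self):
        de = {"a": 1, "b": 1}
        targets = {"a": 1, "b": -1}
        assert activation_zscore(de, targets) == pytest.approx(0.0)

    def test_no_overlap_is_undefined_not_zero(self):
        with pytest.raises(UndefinedResultError):
            activation_zscore({"a": 1}, {"b": 1})

    @settings(max_examples=100, derandomize=True)
    @given(signs=st.lists(st.tuples(st.sampled_from([-1, 1]), st.sampled_from([-1, 1])),
                          min_size=1, max_size=30))
    def test_bound_and_sign_antisymmetry(self, signs):
        genes = [f"g{i}" for i in range(len(signs))]
        de = {g: s[0] for g, s in zip(genes, signs)}
        targets = {g: s[1] for g, s in zip(genes, signs)}
        z = activation_zscore(de, targets)
        assert abs(z) <= np.sqrt(len(signs)) + 1e-12
        flipped = {g: -s for g, s in de.items()}
        assert activation_zscore(flipped, targets) == pytest.approx(-z, abs=1e-12)


class TestRankRegulators:
    def test_simulated_activated_regulator_ranks_first(self):
        network = make_random_network(n_regulators=5, n_genes=200, seed=3)
        reg = network.regulators[2]
        table = simulate_de_table(network, [(reg, 1)], n_genes=200, noise_sd=0.0,
                                  seed=3)
        ranked = rank_regulators(table, network)
        assert ranked[0].regulator == reg
        assert ranked[0].z_score == pytest.approx(np.sqrt(ranked[0].n_overlap))

    def test_empty_selection_propagates_error(self):
        network = make_random_network(seed=0)
        table = simulate_de_table(network, [], noise_sd=0.0, seed=0)
        with pytest.raises(ValidationError):
            rank_regulators(table, network)

    def test_tied_regulators_sorted_lexicographically(self):
        table = de_table([("a", 2.0, 1e-4, 1e-3), ("b", 2.0, 1e-4, 1e-3),
                          ("c", 0.0, 0.9, 0.9)])
        network = RegulatorNetwork({"ZZ": {"a": 1, "b": 1}, "AA": {"a": 1, "b": 1}})
        ranked = rank_regulators(table, network)
        assert [r.regulator for r in ranked] == ["AA", "ZZ"]

    def test_unknown_regulator_lookup_error(self):
        network = make_random_network(seed=0)
        with pytest.raises(ValidationError):
            simulate_de_table(network, [("NOPE", 1)])

    def test_no_active_regulators_zero_noise_gives_flat_table(self):
        network = make_random_network(seed=1)
        table = simulate_de_table(network, [], noise_sd=0.0, seed=1)
        assert (table["log2fc"] == 0.0).all()

    def test_targets_get_signed_effect_exactly(self):
        network = make_random_network(n_regulators=2, seed=5)
        reg = network.regulators[0]
        table = simulate_de_table(network, [(reg, 1)], effect_log2fc=2.0,
                                  noise_sd=0.0, seed=5)
        targets = network.targets(reg)
        sub = table.set_index("gene").loc[list(targets)]
        expected = [2.0 * s for s in targets.values()]
        assert list(sub["log2fc"]) == pytest.approx(expected)
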