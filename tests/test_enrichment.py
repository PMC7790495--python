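"""Marginal fitness, pairwise epistasis, and composition summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from epifit import (
    CountTable,
    background_profile,
    diversity_trajectory,
    filter_for_epistasis,
    focal_mutations,
    make_benchmark,
    marginal_fitness,
    pair_fitness,
    pairwise_epistasis,
    position_composition,
)


def brute_force_W(table, members, t_from, t_to, pseudocount):
    """Independent per-allele aggregation oracle: explicit python loops,
    no masks, no vectorisation."""
    panel = table.panel
    mut = {t: 0 for t in (t_from, t_to)}
    wt = {t: 0 for t in (t_from, t_to)}
    for allele in table.df.index:
        is_mut = all(allele[panel.index_of(p)] == r for p, r in members)
        is_wt = all(
            allele[panel.index_of(p)] == panel.locus(p).wt_residue for p, _ in members
        )
        for t in (t_from, t_to):
            n = int(table.df.loc[allele, t])
            if is_mut:
                mut[t] += n
            elif is_wt:
                wt[t] += n
    m0, w0 = mut[t_from] + pseudocount, wt[t_from] + pseudocount
    m1, w1 = mut[t_to] + pseudocount, wt[t_to] + pseudocount
    if min(m0, w0, m1, w1) <= 0:
        return float("nan")
    return math.log((m1 / w1) / (m0 / w0))


class TestFilter:
    def test_wt_retained_and_degenerate_loci_enforced(self, panel):
        wt = panel.wt_allele_id
        d_at_319 = wt[: panel.index_of(319)] + "D" + wt[panel.index_of(319) + 1 :]
        unexpected = "Z" + wt[1:]
        table = CountTable.from_counts(
            {"t0": {wt: 5, d_at_319: 3, unexpected: 2}, "c1": {wt: 5}}, panel
        )
        kept = filter_for_epistasis(table)
        assert list(kept.df.index) == [wt]

    def test_eleven_focal_mutations_fiftyfive_pairs(self, panel):
        singles = focal_mutations(panel)
        assert len(singles) == 11
        assert len(singles) * (len(singles) - 1) // 2 == 55
        assert not any(p in (319, 320) for p, _ in singles)

    def test_empty_filter_result_is_an_error(self, panel):
        bad = "Z" + panel.wt_allele_id[1:]
        table = CountTable.from_counts({"t0": {bad: 5}}, panel)
        with pytest.raises(ValueError, match="no alleles"):
            filter_for_epistasis(table)


class TestMarginalFitness:
    def test_doubling_mutant_gives_ln2(self, toy_panel):
        table = CountTable.from_counts(
            {"t0": {"VCE": 100, "ACE": 100}, "c1": {"VCE": 200, "ACE": 100}},
            toy_panel,
        )
        w = marginal_fitness(table, 1, "V", pseudocount=0.0)
        assert w.W == pytest.approx(math.log(2))
        assert (w.mut_t0, w.wt_t0, w.mut_t1, w.wt_t1) == (100, 100, 200, 100)

    def test_ratio_invariance_when_both_double(self, toy_panel):
        table = CountTable.from_counts(
            {"t0": {"VCE": 50, "ACE": 80}, "c1": {"VCE": 100, "ACE": 160}},
            toy_panel,
        )
        assert marginal_fitness(table, 1, "V", pseudocount=0.0).W == pytest.approx(0.0)

    def test_matches_brute_force_oracle(self, toy_table):
        for pos, res in [(1, "V"), (2, "D"), (3, "F")]:
            for pc in (0.0, 0.5):
                got = marginal_fitness(toy_table, pos, res, pseudocount=pc).W
                want = brute_force_W(toy_table, [(pos, res)], "t0", "c1", pc)
                assert got == pytest.approx(want)

    def test_sequencing_depth_invariance(self, toy_table):
        """Scaling all counts at one timepoint leaves every W unchanged."""
        scaled = CountTable(df=toy_table.df.assign(c1=toy_table.df["c1"] * 10),
                            panel=toy_table.panel)
        for pos, res in [(1, "V"), (3, "F")]:
            assert marginal_fitness(scaled, pos, res, pseudocount=0.0).W == pytest.approx(
                marginal_fitness(toy_table, pos, res, pseudocount=0.0).W
            )
        # epistasis inherits the invariance
        eps0 = pairwise_epistasis(toy_table, pseudocount=0.0)
        eps1 = pairwise_epistasis(scaled, pseudocount=0.0)
        assert np.allclose(eps0["epsilon"], eps1["epsilon"])


class TestPairFitness:
    def test_absent_double_mutant_undefined_at_zero_pseudocount(self, toy_panel):
        table = CountTable.from_counts(
            {"t0": {"ACE": 10, "VCE": 10, "ADE": 10}, "c1": {"ACE": 10, "VCE": 10, "ADE": 10}},
            toy_panel,
        )
        w = pair_fitness(table, 1, "V", 2, "D", pseudocount=0.0)
        assert not w.defined and math.isnan(w.W)
        assert pair_fitness(table, 1, "V", 2, "D", pseudocount=0.5).defined

    def test_multiplicative_table_gives_exact_additivity(self, toy_panel):
        # counts factorise over loci => W_ij == W_i + W_j exactly
        A = {"A": 20, "V": 10}
        B = {"C": 8, "D": 4}
        A1 = {"A": 10, "V": 30}
        B1 = {"C": 5, "D": 15}
        t0 = {a + b + "E": A[a] * B[b] for a in "AV" for b in "CD"}
        t1 = {a + b + "E": A1[a] * B1[b] for a in "AV" for b in "CD"}
        table = CountTable.from_counts({"t0": t0, "c1": t1}, toy_panel)
        wi = marginal_fitness(table, 1, "V", pseudocount=0.0).W
        wj = marginal_fitness(table, 2, "D", pseudocount=0.0).W
        wij = pair_fitness(table, 1, "V", 2, "D", pseudocount=0.0).W
        assert wij == pytest.approx(wi + wj)

    def test_mixed_alleles_belong_to_neither_group(self, toy_table):
        w = pair_fitness(toy_table, 1, "V", 2, "D", pseudocount=0.0)
        want = brute_force_W(toy_table, [(1, "V"), (2, "D")], "t0", "c1", 0.0)
        assert w.W == pytest.approx(want)
        carriers = [a for a in toy_table.df.index if a[0] == "V" and a[1] == "D"]
        wts = [a for a in toy_table.df.index if a[0] == "A" and a[1] == "C"]
        assert w.mut_t0 == int(toy_table.df.loc[carriers, "t0"].sum())
        assert w.wt_t0 == int(toy_table.df.loc[wts, "t0"].sum())


class TestPairwiseEpistasis:
    def test_epsilon_is_exact_arithmetic(self, toy_table):
        eps = pairwise_epistasis(toy_table, pseudocount=0.0)
        assert np.allclose(eps["epsilon"], eps["W_ij"] - eps["W_i"] - eps["W_j"])
        assert len(eps) == 3  # three pairs on a 3-locus panel

    def test_later_interval_warns(self, panel):
        exp = make_benchmark("study-like", seed=0)
        table = filter_for_epistasis(exp.table)
        with pytest.warns(UserWarning, match="first cycle"):
            pairwise_epistasis(table, t_from="c1", t_to="c3")

    def test_unbiased_under_multiplicative_truth(self):
        """Mean estimated epsilon over seeds is within 2 SE of 0 per pair."""
        vals = []
        for seed in range(8):
            exp = make_benchmark("null", seed=seed)
            eps = pairwise_epistasis(filter_for_epistasis(exp.table))
            vals.append(eps["epsilon"].to_numpy())
        arr = np.vstack(vals)
        mean = arr.mean(axis=0)
        se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        assert (np.abs(mean) < 3 * se + 1e-12).mean() > 0.9

    def test_injected_sign_recovered(self):
        """An injected negative interaction shows up with the right sign."""
        hits = 0
        for seed in range(10):
            exp = make_benchmark("sign-epistasis", seed=seed)
            eps = pairwise_epistasis(filter_for_epistasis(exp.table))
            row = eps[(eps.locus_i == 315) & (eps.locus_j == 321)].iloc[0]
            hits += row.epsilon < 0
        assert hits >= 9


class TestComposition:
    def test_single_allele_is_indicator(self, toy_panel):
        table = CountTable.from_counts({"t0": {"VDE": 7}}, toy_panel)
        comp = position_composition(table, "t0")
        assert comp.loc[1, "V"] == 1.0 and comp.loc[2, "D"] == 1.0 and comp.loc[3, "E"] == 1.0

    def test_rows_sum_to_one(self, toy_table):
        comp = position_composition(toy_table, "t0")
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_preselection_library_matches_design(self):
        exp = make_benchmark("null", seed=3)
        comp = position_composition(exp.table, "t0")
        # binary loci drawn 50/50; 319 from GRM: G 1/2, E 1/4, D 1/4
        n = exp.table.totals["t0"]
        se = np.sqrt(0.25 / n)
        assert abs(comp.loc[103, "K"] - 0.5) < 4 * se
        assert abs(comp.loc[319, "G"] - 0.5) < 4 * se
        assert abs(comp.loc[319, "E"] - 0.25) < 4 * se
        assert abs(comp.loc[320, "N"] - 0.25) < 4 * se

    def test_background_profiles_similar_across_focal_mutations(self):
        """Balanced library: carrier backgrounds are ~50/50 at other loci
        and near-identical across focal mutations (total variation)."""
        exp = make_benchmark("null", seed=4)
        table = filter_for_epistasis(exp.table)
        profiles = {}
        for pos, res in focal_mutations(table.panel)[:4]:
            carrier, ref = background_profile(table, pos, res)
            assert not carrier.empty and not ref.empty
            profiles[(pos, res)] = carrier
        keys = list(profiles)
        for a in keys:
            for b in keys:
                shared = profiles[a].index.intersection(profiles[b].index)
                pa, pb = profiles[a].loc[shared].align(
                    profiles[b].loc[shared], axis=1, fill_value=0.0
                )
                tv = 0.5 * (pa - pb).abs().to_numpy().sum() / len(shared)
                assert tv < 0.05

    def test_single_allele_profile(self, toy_panel):
        table = CountTable.from_counts({"t0": {"VDE": 7}}, toy_panel)
        carrier, ref = background_profile(table, 1, "V")
        assert carrier.loc[2, "D"] == 1.0 and carrier.loc[3, "E"] == 1.0
        assert ref.empty  # no WT-at-locus alleles present


class TestDiversity:
    def test_identical_composition_equal_entropy(self, toy_panel):
        table = CountTable.from_counts(
            {"t0": {"ACE": 10, "VCE": 30}, "c1": {"ACE": 20, "VCE": 60}}, toy_panel
        )
        div = diversity_trajectory(table)
        assert div.entropy.iloc[0] == pytest.approx(div.entropy.iloc[1])

    def test_fixed_allele_zero_entropy(self, toy_panel):
        table = CountTable.from_counts({"t0": {"ACE": 5}, "c1": {"ACE": 50}}, toy_panel)
        div = diversity_trajectory(table)
        assert (div.entropy == 0).all() and (div.richness == 1).all()

    def test_selection_reduces_entropy(self):
        exp = make_benchmark("study-like", seed=2)
        div = diversity_trajectory(exp.table)
        assert div.entropy.iloc[-1] < div.entropy.iloc[0]
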