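import numpy as np
import pandas as pd
import pytest

import commphen as cp
from commphen.phenotypes import BinaryPhenotypeMatrix


def make_bpm(rows, species, panels=None):
    values = pd.DataFrame(rows).T if isinstance(rows, dict) else rows
    return BinaryPhenotypeMatrix(values, pd.Series(species), panels=panels)


@pytest.fixture
def toy():
    """Three species; one with three genomes of mixed phenotypes."""
    values = pd.DataFrame(
        {
            "phenA": [1, 1, 0, 1, 0],
            "phenB": [0, 0, 0, 1, 1],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    species = {"g1": "Sp one", "g2": "Sp one", "g3": "Sp one",
               "g4": "Sp two", "g5": "Sp three"}
    taxonomy = pd.DataFrame(
        {
            "species": ["Sp one", "Sp two", "Sp three", None],
            "genus": ["G"] * 4,
            "family": ["F"] * 4,
        },
        index=["t1", "t2", "t3", "t_unassigned"],
    )
    return make_bpm(values, species), taxonomy


class TestMapTaxa:
    def test_multi_genome_mean(self, toy):
        bpm, tax = toy
        cpm, unmapped = cp.map_taxa(tax, bpm)
        assert cpm.loc["t1", "phenA"] == pytest.approx(2 / 3)
        assert cpm.loc["t2", "phenA"] == 1.0
        assert unmapped == ["t_unassigned"]

    def test_any_genome_mode(self, toy):
        bpm, tax = toy
        cpm, _ = cp.map_taxa(tax, bpm, genome_agg="any")
        assert cpm.loc["t1", "phenA"] == 1.0
        assert cpm.loc["t1", "phenB"] == 0.0

    def test_species_name_normalization(self, toy):
        bpm, tax = toy
        tax2 = tax.copy()
        tax2.loc["t1", "species"] = "  SP  ONE "
        cpm, _ = cp.map_taxa(tax2, bpm)
        assert cpm.loc["t1", "phenA"] == pytest.approx(2 / 3)

    def test_random_panel_matches_brute_force(self, rng):
        n_gen, n_phen = 30, 6
        species = rng.choice([f"sp{j}" for j in range(8)], size=n_gen)
        values = pd.DataFrame(
            rng.integers(0, 2, size=(n_gen, n_phen)),
            index=[f"g{i}" for i in range(n_gen)],
            columns=[f"ph{j}" for j in range(n_phen)],
        )
        bpm = make_bpm(values, dict(zip(values.index, species)))
        tax = pd.DataFrame(
            {"species": [f"sp{j}" for j in range(8)],
             "genus": "g", "family": "f"},
            index=[f"t{j}" for j in range(8)],
        )
        cpm, _ = cp.map_taxa(tax, bpm)
        for j in range(8):
            mask = species == f"sp{j}"
            expected = values.to_numpy()[mask].mean(axis=0)
            np.testing.assert_allclose(cpm.loc[f"t{j}"].to_numpy(), expected)

    def test_empty_bpm_errors(self, toy):
        _, tax = toy
        empty = make_bpm(pd.DataFrame(columns=["p"], dtype=int), {})
        with pytest.raises(ValueError, match="empty"):
            cp.CommunityPhenotypeProfiler(empty, tax).fit()

    def test_non_binary_entries_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            make_bpm(pd.DataFrame({"p": [0.5]}, index=["g"]), {"g": "s"})


class TestCPI:
    def test_full_abundance_full_phenotype(self):
        cpm = pd.DataFrame({"p": [1.0]}, index=["t1"])
        table = pd.DataFrame({"s": [1.0]}, index=["t1"])
        out = cp.cpi(table, cpm)
        assert out["cpi"].iloc[0] == pytest.approx(100.0)

    def test_dot_product(self):
        cpm = pd.DataFrame({"p": [1.0, 0.0]}, index=["t1", "t2"])
        table = pd.DataFrame({"s": [0.25, 0.75]}, index=["t1", "t2"])
        assert cp.cpi(table, cpm)["cpi"].iloc[0] == pytest.approx(25.0)

    def test_random_community_matches_brute_force(self, rng):
        n = 50
        taxa = [f"t{i}" for i in range(n)]
        cpm = pd.DataFrame(rng.random((n, 4)), index=taxa,
                           columns=list("wxyz"))
        ab = rng.dirichlet(np.ones(n))
        table = pd.DataFrame({"s": ab}, index=taxa)
        out = cp.cpi(table, cpm).set_index("phenotype")["cpi"]
        for phen in "wxyz":
            expected = 100.0 * sum(
                ab[i] * cpm.loc[taxa[i], phen] for i in range(n)
            )
            assert out[phen] == pytest.approx(expected, abs=1e-9)

    def test_unmapped_dilution_vs_renormalization(self):
        cpm = pd.DataFrame({"p": [1.0]}, index=["t1"])
        table = pd.DataFrame({"s": [0.5, 0.5]}, index=["t1", "t_unmapped"])
        diluted = cp.cpi(table, cpm)
        renorm = cp.cpi(table, cpm, renormalize=True)
        assert diluted["cpi"].iloc[0] == pytest.approx(50.0)
        assert renorm["cpi"].iloc[0] == pytest.approx(100.0)
        assert diluted["mapped_fraction"].iloc[0] == pytest.approx(0.5)

    def test_no_mapped_taxa_flagged_not_zero(self):
        cpm = pd.DataFrame({"p": [1.0]}, index=["other"])
        table = pd.DataFrame({"s": [1.0]}, index=["t1"])
        out = cp.cpi(table, cpm)
        assert np.isnan(out["cpi"].iloc[0])
        assert out["mapped_fraction"].iloc[0] == 0.0

    def test_linearity_in_abundance(self, rng):
        n = 20
        taxa = [f"t{i}" for i in range(n)]
        cpm = pd.DataFrame({"p": rng.random(n)}, index=taxa)
        a = rng.dirichlet(np.ones(n))
        b = rng.dirichlet(np.ones(n))
        alpha = 0.3
        mix = alpha * a + (1 - alpha) * b
        tbl = pd.DataFrame({"a": a, "b": b, "m": mix}, index=taxa)
        out = cp.cpi(tbl, cpm).pivot(index="sample", columns="phenotype",
                                     values="cpi")["p"]
        assert out["m"] == pytest.approx(
            alpha * out["a"] + (1 - alpha) * out["b"], abs=1e-9
        )

    def test_monotone_under_abundance_transfer(self):
        cpm = pd.DataFrame({"p": [0.0, 1.0]}, index=["lo", "hi"])
        before = pd.DataFrame({"s": [0.6, 0.4]}, index=["lo", "hi"])
        after = pd.DataFrame({"s": [0.4, 0.6]}, index=["lo", "hi"])
        c0 = cp.cpi(before, cpm)["cpi"].iloc[0]
        c1 = cp.cpi(after, cpm)["cpi"].iloc[0]
        assert c1 >= c0

    def test_all_ones_bpm_gives_mapped_fraction(self, dataset, relabund):
        ones = BinaryPhenotypeMatrix(
            pd.DataFrame(
                np.ones_like(dataset.bpm.values.to_numpy()),
                index=dataset.bpm.values.index,
                columns=dataset.bpm.values.columns,
            ),
            dataset.bpm.species,
        )
        prof = cp.CommunityPhenotypeProfiler(ones, dataset.taxonomy).fit()
        long = prof.profile(relabund)
        np.testing.assert_allclose(long["cpi"], 100 * long["mapped_fraction"],
                                   atol=1e-9)
        prof_r = cp.CommunityPhenotypeProfiler(
            ones, dataset.taxonomy, renormalize=True
        ).fit()
        np.testing.assert_allclose(prof_r.profile(relabund)["cpi"], 100.0,
                                   atol=1e-9)


class TestPathwaySets:
    @pytest.fixture
    def butyrate(self):
        _, psets = cp.load_panels()
        return psets["butyrate"]

    @pytest.fixture
    def route_bpm(self):
        # g_sugar encodes only a carbohydrate route; g_aa only lysine;
        # g_all all four routes
        cols = [
            "butyrate_via_pyruvate",
            "butyrate_via_succinate",
            "butyrate_via_lysine",
            "butyrate_via_glutamate",
        ]
        values = pd.DataFrame(
            [[1, 0, 0, 0], [0, 0, 1, 0], [1, 1, 1, 1]],
            index=["g_sugar", "g_aa", "g_all"],
            columns=cols,
        )
        species = {"g_sugar": "S sugar", "g_aa": "S aa", "g_all": "S all"}
        tax = pd.DataFrame(
            {"species": ["S sugar", "S aa", "S all"],
             "genus": "G", "family": "F"},
            index=["t_sugar", "t_aa", "t_all"],
        )
        return make_bpm(values, species), tax

    def test_sugar_route_irrelevant_in_control_medium(self, route_bpm,
                                                      butyrate):
        bpm, tax = route_bpm
        prof = cp.CommunityPhenotypeProfiler(bpm, tax).fit()
        table = pd.DataFrame({"s": [1.0, 0.0, 0.0]},
                             index=["t_sugar", "t_aa", "t_all"])
        ctrl = prof.pathway_set_profile(table, butyrate, "control")
        herb = prof.pathway_set_profile(table, butyrate, "herb")
        assert ctrl["cpi"].iloc[0] == pytest.approx(0.0)
        assert herb["cpi"].iloc[0] == pytest.approx(100.0)

    def test_all_route_genome_counts_in_both_contexts(self, route_bpm,
                                                      butyrate):
        bpm, tax = route_bpm
        prof = cp.CommunityPhenotypeProfiler(bpm, tax).fit()
        table = pd.DataFrame({"s": [0.0, 0.0, 1.0]},
                             index=["t_sugar", "t_aa", "t_all"])
        for ctx in ("control", "herb"):
            out = prof.pathway_set_profile(table, butyrate, ctx)
            assert out["cpi"].iloc[0] == pytest.approx(100.0)

    def test_genome_level_or_before_averaging(self, butyrate):
        # two genomes of one species, each encoding a different active
        # route: every genome is a producer, so the species value is 1.0
        # (the OR of averaged fractions would be wrong here)
        cols = butyrate.members
        values = pd.DataFrame([[0, 0, 1, 0], [0, 0, 0, 1]],
                              index=["gA", "gB"], columns=cols)
        bpm = make_bpm(values, {"gA": "Sp", "gB": "Sp"})
        tax = pd.DataFrame({"species": ["Sp"], "genus": "G", "family": "F"},
                           index=["t"])
        prof = cp.CommunityPhenotypeProfiler(bpm, tax).fit()
        table = pd.DataFrame({"s": [1.0]}, index=["t"])
        out = prof.pathway_set_profile(table, butyrate, "control")
        assert out["cpi"].iloc[0] == pytest.approx(100.0)

    def test_restricted_context_never_exceeds_full(self, dataset, relabund,
                                                   profiler, butyrate):
        ctrl = profiler.pathway_set_profile(relabund, butyrate, "control")
        herb = profiler.pathway_set_profile(relabund, butyrate, "herb")
        assert (ctrl["cpi"].to_numpy() <= herb["cpi"].to_numpy() + 1e-12).all()

    def test_unknown_context_errors(self, butyrate):
        with pytest.raises(ValueError, match="context"):
            butyrate.active("broth")


class TestSugarCapability:
    @pytest.mark.parametrize(
        "cat,tra,expected", [(1, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 0)]
    )
    def test_truth_table(self, cat, tra, expected):
        assert cp.sugar_capability(cat, tra) == expected

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            cp.sugar_capability(2, 1)

    def test_matrix_combination(self):
        cat = pd.DataFrame({"Glc": [1, 1], "Xyl": [0, 1]}, index=["g1", "g2"])
        tra = pd.DataFrame({"Glc": [1, 0], "Xyl": [1, 1]}, index=["g1", "g2"])
        out = cp.combine_sugar_bpm(cat, tra)
        assert out.loc["g1", "Glc"] == 1
        assert out.loc["g2", "Glc"] == 0
        assert out.loc["g1", "Xyl"] == 0


class TestCpiDelta:
    def _long(self, phen_vals, samples):
        rows = []
        for s in samples:
            for p, v in phen_vals.items():
                rows.append({"sample": s, "phenotype": p, "cpi": v})
        return pd.DataFrame(rows)

    def test_equal_means_unchanged(self):
        herb = self._long({"GH13": 10.0}, ["h1", "h2"])
        ctrl = self._long({"GH13": 10.0}, ["c1", "c2"])
        out, net = cp.cpi_delta(herb, ctrl)
        assert out.loc["GH13", "delta"] == 0.0
        assert out.loc["GH13", "direction"] == "unchanged"

    def test_increase_classified(self):
        herb = self._long({"GH13": 30.0}, ["h1"])
        ctrl = self._long({"GH13": 10.0}, ["c1"])
        out, _ = cp.cpi_delta(herb, ctrl)
        assert out.loc["GH13", "delta"] == pytest.approx(20.0)
        assert out.loc["GH13", "direction"] == "increased"

    def test_net_effect_averages_signed_changes(self):
        herb = self._long({"GH13": 20.0, "GH16": 6.0}, ["h1"])
        ctrl = self._long({"GH13": 10.0, "GH16": 10.0}, ["c1"])
        _, net = cp.cpi_delta(herb, ctrl)
        assert net == pytest.approx((10.0 - 4.0) / 2)

    def test_one_sided_phenotype_skipped_with_warning(self):
        herb = self._long({"GH13": 5.0, "GH99": 1.0}, ["h1"])
        ctrl = self._long({"GH13": 5.0}, ["c1"])
        with pytest.warns(UserWarning, match="GH99"):
            out, _ = cp.cpi_delta(herb, ctrl)
        assert "GH99" not in out.index
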