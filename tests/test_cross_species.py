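import math

import numpy as np
import pandas as pd
import pytest

from fogpipe.cross_species import (
    classify_patterns,
    hypergeometric_enrichment,
    per_replicate_log2fc,
    project_degs,
    type_correlation,
    venn_partition,
)
from fogpipe.errors import ValidationError
from fogpipe.io_formats import GeneSetCollection, OrthologMap, SpeciesSheet


def species_sheet(c3, c4):
    return SpeciesSheet(
        pd.DataFrame(
            [(sp, "C3") for sp in c3] + [(sp, "C4") for sp in c4],
            columns=["species_id", "photosynthesis_type"],
        )
    )


FIVE_SPECIES = species_sheet(["a", "b"], ["x", "y", "z"])


def ortholog_map(groups, species):
    rows = [(g, sp, f"{sp}_{g}") for g in groups for sp in species]
    return OrthologMap(pd.DataFrame(rows, columns=["group_id", "species_id", "gene_id"]))


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

class TestProjectDegs:
    def test_empty_deg_sets(self):
        omap = ortholog_map(["og1", "og2"], ["a", "b"])
        membership, mappable = project_degs({"a": set(), "b": set()}, omap)
        assert not membership.any().any()
        assert mappable.all().all()

    def test_partial_mapping(self):
        rows = [("og1", "a", "a_og1")]  # unmapped in species b
        omap = OrthologMap(pd.DataFrame(rows, columns=["group_id", "species_id", "gene_id"]))
        membership, mappable = project_degs({"a": {"a_og1"}, "b": set()}, omap)
        assert membership.loc["og1", "a"]
        assert not mappable.loc["og1", "b"]

    def test_matches_brute_force(self, rng):
        """Exhaustive per-(group, species) lookup oracle on a random instance."""
        groups = [f"og{i}" for i in range(30)]
        species = ["a", "b", "x"]
        rows = [
            (g, sp, f"{sp}_{g}")
            for g in groups
            for sp in species
            if rng.random() < 0.8
        ]
        omap = OrthologMap(pd.DataFrame(rows, columns=["group_id", "species_id", "gene_id"]))
        deg_sets = {
            sp: {f"{sp}_{g}" for g in groups if rng.random() < 0.4} for sp in species
        }
        membership, mappable = project_degs(deg_sets, omap)
        lookup = {(g, sp): gene for g, sp, gene in rows}
        for g in omap.group_ids():
            for sp in species:
                gene = lookup.get((g, sp))
                assert mappable.loc[g, sp] == (gene is not None)
                expected = gene is not None and gene in deg_sets[sp]
                assert membership.loc[g, sp] == expected


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------

class TestVennPartition:
    def test_disjoint_sets_no_common(self):
        omap = ortholog_map(["og1", "og2"], ["a", "x"])
        membership, _ = project_degs({"a": {"a_og1"}, "x": {"x_og2"}}, omap)
        venn = venn_partition(membership, species_sheet(["a"], ["x"]))
        assert venn.common_all == set()

    def test_counts_match_enumeration(self, rng):
        """Counts equal brute-force subset enumeration (random <=6 species)."""
        for trial in range(5):
            n_species = int(rng.integers(2, 7))
            species = [f"s{i}" for i in range(n_species)]
            c3 = species[: max(1, n_species // 2)]
            c4 = species[max(1, n_species // 2):]
            sheet = species_sheet(c3, c4)
            groups = [f"og{i}" for i in range(40)]
            membership = pd.DataFrame(
                rng.random((40, n_species)) < 0.5, index=groups, columns=species
            )
            venn = venn_partition(membership, sheet)
            brute: dict[frozenset, int] = {}
            for g in groups:
                subset = frozenset(sp for sp in species if membership.loc[g, sp])
                if subset:
                    brute[subset] = brute.get(subset, 0) + 1
            assert venn.subset_counts == brute
            assert venn.total() == sum(
                1 for g in groups if membership.loc[g].any()
            )

    def test_c4_specific_requires_all_c4_no_c3(self):
        groups = ["og1", "og2", "og3"]
        membership = pd.DataFrame(
            [
                [False, False, True, True, True],  # all C4, no C3 -> specific
                [True, False, True, True, True],   # one C3 -> not
                [False, False, True, True, False], # missing one C4 -> not
            ],
            index=groups,
            columns=["a", "b", "x", "y", "z"],
        )
        venn = venn_partition(membership, FIVE_SPECIES)
        assert venn.c4_specific == {"og1"}

    def test_common_subset_of_projections(self, small_experiment):
        from fogpipe.diffexpr import call_degs, run_de

        experiment = small_experiment
        deg_sets = {
            sp: call_degs(run_de(m, experiment.sample_sheet))
            for sp, m in experiment.counts.items()
        }
        membership, _ = project_degs(deg_sets, experiment.ortholog_map)
        venn = venn_partition(membership, experiment.species_sheet)
        for sp in experiment.counts:
            projected = set(membership.index[membership[sp]])
            assert venn.common_all <= projected


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

class TestEnrichment:
    def test_query_equals_universe(self):
        universe = {f"g{i}" for i in range(10)}
        collection = GeneSetCollection({"all5": set(list(universe)[:5])})
        result = hypergeometric_enrichment(universe, universe, collection)
        row = result.iloc[0]
        assert row["k"] == row["K"] == 5
        assert row["p_value"] == pytest.approx(1.0)

    def test_known_combinatorial_value(self):
        # N=10, K=5, n=4, k=4: p = C(5,4)C(5,0)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        members = {f"g{i}" for i in range(5)}
        query = {f"g{i}" for i in range(4)}
        result = hypergeometric_enrichment(query, universe, GeneSetCollection({"s": members}))
        assert result.iloc[0]["p_value"] == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_overlap_never_enriched(self):
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}
        members = {f"g{i}" for i in range(10, 16)}
        result = hypergeometric_enrichment(query, universe, GeneSetCollection({"s": members}))
        assert result.iloc[0]["p_value"] >= 0.5
        assert not result.iloc[0]["enriched"]

    def test_matches_direct_sum(self, rng):
        """scipy tail vs exact comb-sum oracle, <=1e-12."""
        for _ in range(20):
            big_n = int(rng.integers(5, 40))
            big_k = int(rng.integers(1, big_n + 1))
            n = int(rng.integers(1, big_n + 1))
            universe = {f"g{i}" for i in range(big_n)}
            members = set(list(universe)[:big_k])
            query = set(rng.choice(sorted(universe), size=n, replace=False))
            k = len(query & members)
            result = hypergeometric_enrichment(query, universe, GeneSetCollection({"s": members}))
            total = math.comb(big_n, n)
            exact = (
                sum(
                    math.comb(big_k, i) * math.comb(big_n - big_k, n - i)
                    for i in range(k, min(big_k, n) + 1)
                )
                / total
            )
            assert result.iloc[0]["p_value"] == pytest.approx(exact, abs=1e-12)

    def test_empty_universe(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment(set(), set(), GeneSetCollection({"s": {"g"}}))

    def test_query_outside_universe(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment({"q"}, {"g"}, GeneSetCollection({"s": {"g"}}))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def de_frame(stats_by_gene):
    """stats: gene_id -> (log2fc, p_adj, is_deg, null_flag)"""
    rows = [
        {"gene_id": g, "log2fc": lfc, "p_adj": p, "is_deg": deg, "null_flag": null}
        for g, (lfc, p, deg, null) in stats_by_gene.items()
    ]
    return pd.DataFrame(rows)


def build_case(per_species_lfc, deg=True, null_species=None):
    """One ortholog group 'og1' across the five test species."""
    de_results = {}
    for sp, lfc in per_species_lfc.items():
        de_results[sp] = de_frame(
            {
                f"{sp}_og1": (
                    lfc,
                    0.001,
                    deg,
                    null_species is not None and sp == null_species,
                )
            }
        )
    omap = ortholog_map(["og1"], list(per_species_lfc))
    return de_results, omap


class TestClassifyPatterns:
    def classify_one(self, per_species_lfc, **kwargs):
        de_results, omap = build_case(per_species_lfc, **kwargs)
        out = classify_patterns(de_results, omap, FIVE_SPECIES)
        return out.iloc[0]["class"]

    def test_flip_over(self):
        lfc = {"a": 2.0, "b": 1.5, "x": -2.0, "y": -1.8, "z": -2.2}
        assert self.classify_one(lfc) == "flip_over"

    def test_conserved_signature(self):
        lfc = {"a": 2.0, "b": 1.5, "x": 2.0, "y": 1.8, "z": 2.2}
        assert self.classify_one(lfc) == "conserved_signature"

    def test_inconsistent_within_type(self):
        lfc = {"a": 2.0, "b": -1.5, "x": -2.0, "y": -1.8, "z": -2.2}
        assert self.classify_one(lfc) == "inconsistent"

    def test_dropped_null(self):
        lfc = {"a": 2.0, "b": 1.5, "x": -2.0, "y": -1.8, "z": -2.2}
        assert self.classify_one(lfc, null_species="x") == "dropped_null"

    def test_not_common_beats_null(self):
        lfc = {"a": 2.0, "b": 1.5, "x": -2.0, "y": -1.8, "z": -2.2}
        assert self.classify_one(lfc, deg=False, null_species="x") == "not_common"

    def test_unmappable_is_not_common(self):
        lfc = {"a": 2.0, "b": 1.5, "x": -2.0, "y": -1.8, "z": -2.2}
        de_results, _ = build_case(lfc)
        rows = [("og1", sp, f"{sp}_og1") for sp in ["a", "b", "x", "y"]]  # z missing
        omap = OrthologMap(pd.DataFrame(rows, columns=["group_id", "species_id", "gene_id"]))
        out = classify_patterns(de_results, omap, FIVE_SPECIES)
        assert out.iloc[0]["class"] == "not_common"
        assert out.iloc[0]["sign_vector"].endswith(".")

    def test_pathway_filter_drops_sign_classes_only(self):
        lfc = {"a": 2.0, "b": 1.5, "x": 2.0, "y": 1.8, "z": 2.2}
        de_results, omap = build_case(lfc)
        out = classify_patterns(de_results, omap, FIVE_SPECIES, pathway_filter={"og_other"})
        assert out.empty  # og1 was heading for a sign class and is filtered out

    def test_missing_species_error(self):
        lfc = {"a": 2.0, "b": 1.5, "x": 2.0, "y": 1.8}
        de_results, omap = build_case(lfc)
        with pytest.raises(ValidationError, match="z"):
            classify_patterns(de_results, omap, FIVE_SPECIES)


class TestEndToEndRecovery:
    def test_default_design_recovery(self, default_experiment):
        from fogpipe.diffexpr import run_de

        experiment = default_experiment
        de_results = {
            sp: run_de(m, experiment.sample_sheet) for sp, m in experiment.counts.items()
        }
        classes = classify_patterns(
            de_results, experiment.ortholog_map, experiment.species_sheet
        )
        truth = experiment.truth
        called = classes.set_index("group_id")["class"]
        fogs = set(truth.groups_of("flip_over"))
        called_fog = set(called[called == "flip_over"].index)
        assert len(fogs & called_fog) / len(fogs) >= 0.8  # single seed; 10-seed bound in acceptance
        conserved = set(truth.groups_of("conserved_signature"))
        assert not (conserved & called_fog)
        nulls = set(truth.groups_of("null"))
        signature_calls = called_fog | set(called[called == "conserved_signature"].index)
        assert len(nulls & signature_calls) / len(nulls) <= 0.01


# ---------------------------------------------------------------------------
# type correlation
# ---------------------------------------------------------------------------

class TestTypeCorrelation:
    def test_perfect_separation(self):
        values = {"a": [2.0, 2.0], "b": [2.0], "x": [-2.0], "y": [-2.0], "z": [-2.0]}
        assert type_correlation(values, FIVE_SPECIES) == pytest.approx(-1.0)

    def test_constant_values_undefined(self):
        values = {"a": [1.0], "b": [1.0], "x": [1.0]}
        r = type_correlation(values, FIVE_SPECIES)
        assert math.isnan(r)
        assert r != 0.0  # undefined is reported distinctly from zero

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            type_correlation({"a": [1.0], "x": [2.0]}, FIVE_SPECIES)

    def test_matches_closed_form(self):
        values = {"a": [1.8], "b": [2.1], "x": [-1.9], "y": [-2.2], "z": [-2.0]}
        v = np.array([1.8, 2.1, -1.9, -2.2, -2.0])
        t = np.array([0.0, 0.0, 1.0, 1.0, 1.0])
        expected = ((v - v.mean()) * (t - t.mean())).sum() / (
            np.sqrt(((v - v.mean()) ** 2).sum()) * np.sqrt(((t - t.mean()) ** 2).sum())
        )
        assert type_correlation(values, FIVE_SPECIES) == pytest.approx(expected, abs=1e-12)

    def test_fog_correlation_beats_conserved(self, small_experiment):
        """Planted FOGs correlate with type more strongly than conserved genes."""
        experiment = small_experiment
        truth = experiment.truth

        def group_r(group):
            values = {}
            for sp, matrix in experiment.counts.items():
                values[sp] = per_replicate_log2fc(
                    matrix, experiment.sample_sheet, f"{sp}_{group}"
                )
            return abs(type_correlation(values, experiment.species_sheet))

        fog_rs = [group_r(g) for g in truth.groups_of("flip_over")]
        cons_rs = [group_r(g) for g in truth.groups_of("conserved_signature")]
        assert np.median(fog_rs) > np.median(cons_rs)
        assert np.median(fog_rs) > 0.9


class TestPerReplicateLog2fc:
    def test_formula(self):
        from fogpipe.io_formats import CountMatrix, SampleSheet

        counts = CountMatrix(
            "sp",
            ["g1", "g2"],
            ["bs1", "bs2", "m1", "m2"],
            np.array([[7, 15, 3, 1], [10, 10, 10, 10]]),
        )
        sheet = SampleSheet(
            pd.DataFrame(
                {
                    "sample_id": ["bs1", "bs2", "m1", "m2"],
                    "species_id": ["sp"] * 4,
                    "cell_type": ["BS", "BS", "M", "M"],
                    "replicate": [1, 2, 1, 2],
                }
            )
        )
        sf = np.ones(4)
        values = per_replicate_log2fc(counts, sheet, "g1", sf)
        assert values == pytest.approx([np.log2(8 / 4), np.log2(16 / 2)])
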