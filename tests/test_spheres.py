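"""Sphere p-value pooling, greedy expansion, merging, host linkage,
model assembly and the supplement-biome selection rule."""

import itertools
import math

import numpy as np
import pytest

from enrichsphere.core_io import BiomeCounts, GeneAnnotationMap, aggregate_by_biome
from enrichsphere.enrichment import hypergeom_tail
from enrichsphere.ontology import OntologyGraph
from enrichsphere.spheres import (
    FunctionSphere,
    SphereModel,
    build_sphere_model,
    expand_sphere,
    link_hosts,
    merge_spheres,
    select_supplement_biome,
    sphere_pvalue,
)


def _chain_counts():
    """Five-term chain with the middle three inflated in biome A."""
    chain = OntologyGraph.from_terms(
        {f"T:{i}": (f"t{i}", "biological_process") for i in range(1, 6)},
        [(f"T:{i + 1}", f"T:{i}") for i in range(1, 5)],
    )
    counts = BiomeCounts(
        ["T:1", "T:2", "T:3", "T:4", "T:5", "BG"],
        ["A", "B"],
        np.array([[5, 15], [50, 10], [50, 10], [50, 10], [5, 15], [400, 900]]),
    )
    return chain, counts


class TestSpherePvalue:
    def test_single_member_is_univariate(self, toy_counts):
        assert sphere_pvalue(["F1"], toy_counts, "A") == hypergeom_tail(
            50, 50, 80, 200
        )

    def test_pooling_identity_two_members(self):
        counts = BiomeCounts(
            ["m1", "m2", "BG"],
            ["A", "B"],
            np.array([[4, 1], [4, 1], [8, 22]]),
        )
        assert sphere_pvalue(["m1", "m2"], counts, "A") == hypergeom_tail(
            8, 10, 16, 40
        )

    def test_monte_carlo_multivariate_urn_agrees(self):
        """The closed-form tail matches sampling from the actual multivariate
        hypergeometric urn (member colors + pooled 'other') within 3 SE."""
        rng = np.random.default_rng(2024)
        K = rng.integers(10, 60, size=5)
        other = 1500 - K.sum()
        n = 400
        counts = BiomeCounts(
            [f"m{i}" for i in range(5)] + ["other"],
            ["A", "B"],
            np.column_stack([np.append(K // 2, other // 2), np.append(K - K // 2, other - other // 2)]),
        )
        members = [f"m{i}" for i in range(5)]
        t_obs = int(sum(counts.counts[i, 0] for i in range(5)))
        # the biome column is one draw of size n from the pooled urn only if
        # margins match; build the urn directly from totals instead
        colors = np.append(K, other)
        draws = rng.multivariate_hypergeometric(colors, n, size=100_000)
        t_draws = draws[:, :5].sum(axis=1)
        t_stat = int(np.quantile(t_draws, 0.9))
        p_mc = float((t_draws >= t_stat).mean())
        p_exact = hypergeom_tail(t_stat, int(K.sum()), n, 1500)
        se = math.sqrt(p_exact * (1 - p_exact) / 100_000)
        assert abs(p_mc - p_exact) <= 3 * se

    def test_empty_member_set_rejected(self, toy_counts):
        with pytest.raises(ValueError):
            sphere_pvalue([], toy_counts, "A")

    def test_unknown_member_rejected(self, toy_counts):
        with pytest.raises(KeyError):
            sphere_pvalue(["ghost"], toy_counts, "A")


class TestExpandSphere:
    def test_immediate_stop_when_neighbors_dilute(self):
        graph = OntologyGraph.from_terms(
            {"T:S": ("s", "ns"), "T:N": ("n", "ns")}, [("T:N", "T:S")]
        )
        counts = BiomeCounts(
            ["T:S", "T:N", "BG"], ["A", "B"], np.array([[8, 2], [0, 40], [42, 108]])
        )
        sphere = expand_sphere("T:S", graph, counts, "A")
        assert sphere.member_terms == ["T:S"]
        assert sphere.p_value == pytest.approx(sphere_pvalue(["T:S"], counts, "A"))

    def test_recovers_planted_chain_and_matches_exhaustive_search(self):
        chain, counts = _chain_counts()
        sphere = expand_sphere("T:3", chain, counts, "A")
        assert set(sphere.member_terms) >= {"T:2", "T:3", "T:4"}
        # oracle: exhaustive scan of all connected (= contiguous) subsets
        terms = ["T:1", "T:2", "T:3", "T:4", "T:5"]
        best_p = min(
            sphere_pvalue(list(sub), counts, "A")
            for r in range(1, 6)
            for sub in itertools.combinations(terms, r)
            if "T:3" in sub
            and max(terms.index(t) for t in sub) - min(terms.index(t) for t in sub)
            == len(sub) - 1
        )
        assert sphere.p_value == pytest.approx(best_p, rel=1e-9)

    def test_tie_broken_lexicographically(self):
        graph = OntologyGraph.from_terms(
            {"T:R": ("r", "ns"), "T:X": ("x", "ns"), "T:Y": ("y", "ns")},
            [("T:X", "T:R"), ("T:Y", "T:R")],
        )
        counts = BiomeCounts(
            ["T:R", "T:X", "T:Y", "BG"],
            ["A", "B"],
            np.array([[40, 10], [30, 5], [30, 5], [300, 800]]),
        )
        sphere = expand_sphere("T:R", graph, counts, "A")
        assert sphere.member_terms == ["T:R", "T:X", "T:Y"]

    def test_unenriched_seed_rejected(self):
        chain, counts = _chain_counts()
        with pytest.raises(ValueError, match="not enriched"):
            expand_sphere("T:1", chain, counts, "A")

    def test_seed_absent_from_graph_rejected(self):
        chain, counts = _chain_counts()
        with pytest.raises(KeyError):
            expand_sphere("BG", chain, counts, "A")

    def test_exclusion_fences_off_claimed_terms(self):
        chain, counts = _chain_counts()
        sphere = expand_sphere("T:3", chain, counts, "A", exclude={"T:2", "T:4"})
        assert sphere.member_terms == ["T:3"]

    def test_trace_is_monotone_and_gated(self):
        chain, counts = _chain_counts()
        sphere, trace = expand_sphere("T:3", chain, counts, "A", return_trace=True)
        ps = [p for _, _, p in trace]
        assert all(a >= b for a, b in zip(ps, ps[1:]))  # improvement at each step
        assert all(p < 0.01 for p in ps)
        assert [t for _, t, _ in trace] == sphere.member_terms


class TestMergeSpheres:
    def _sphere(self, members, counts, biome="X"):
        return FunctionSphere(
            biome=biome,
            member_terms=members,
            p_value=sphere_pvalue(members, counts, biome),
            namespace="ns",
        )

    # B strongly enriched in X; A and C slightly depleted: each pair passes
    # the gate but the three-way union does not
    _COUNTS = BiomeCounts(
        ["A", "B", "C", "BG"],
        ["X", "Y"],
        np.array([[4, 76], [25, 75], [4, 76], [67, 673]]),
    )

    def test_disjoint_unchanged(self):
        counts = self._COUNTS
        out = merge_spheres(
            [self._sphere(["A"], counts), self._sphere(["B"], counts)], counts
        )
        assert sorted(tuple(s.member_terms) for s in out) == [("A",), ("B",)]

    def test_identical_duplicates_collapse(self):
        counts = self._COUNTS
        dup = [self._sphere(["A", "B"], counts), self._sphere(["A", "B"], counts)]
        out = merge_spheres(dup, counts)
        assert len(out) == 1

    def test_failing_union_keeps_originals(self):
        counts = self._COUNTS
        s1 = self._sphere(["A", "B"], counts)
        s2 = self._sphere(["B", "C"], counts)
        assert s1.p_value < 0.01 and s2.p_value < 0.01  # both pass alone
        assert sphere_pvalue(["A", "B", "C"], counts, "X") >= 0.01  # union fails
        out = merge_spheres([s1, s2], counts)
        assert sorted(tuple(s.member_terms) for s in out) == [
            ("A", "B"),
            ("B", "C"),
        ]

    def test_passing_union_merges(self):
        counts = BiomeCounts(
            ["A", "B", "C", "BG"],
            ["X", "Y"],
            np.array([[25, 75], [25, 75], [25, 75], [25, 775]]),
        )
        s1 = self._sphere(["A", "B"], counts)
        s2 = self._sphere(["B", "C"], counts)
        (merged,) = merge_spheres([s1, s2], counts)
        assert set(merged.member_terms) == {"A", "B", "C"}
        assert merged.p_value == pytest.approx(
            sphere_pvalue(["A", "B", "C"], counts, "X")
        )


class TestLinkHosts:
    _SPECIES = BiomeCounts(
        ["sp_hot", "sp_flat", "sp_nogene"],
        ["A", "B"],
        np.array([[40, 0], [20, 20], [40, 0]]),
    )

    def _sphere(self):
        return FunctionSphere(
            biome="A", member_terms=["T:1"], p_value=1e-6, namespace="ns"
        )

    def test_enriched_linked_species_returned(self):
        gm = GeneAnnotationMap(
            records=[("g1", "T:1", "sp_hot"), ("g2", "T:1", "sp_flat")]
        )
        hosts = link_hosts(self._sphere(), gm, self._SPECIES)
        assert [sp for sp, _ in hosts] == ["sp_hot"]

    def test_flat_species_excluded(self):
        gm = GeneAnnotationMap(records=[("g2", "T:1", "sp_flat")])
        assert link_hosts(self._sphere(), gm, self._SPECIES) == []

    def test_enriched_species_without_gene_excluded(self):
        gm = GeneAnnotationMap(records=[("g9", "T:OTHER", "sp_nogene")])
        assert link_hosts(self._sphere(), gm, self._SPECIES) == []

    def test_empty_gene_map_gives_empty_hosts(self):
        assert link_hosts(self._sphere(), GeneAnnotationMap(), self._SPECIES) == []


class TestBuildSphereModel:
    def test_null_data_yields_no_spheres(self, chain_graph):
        # counts exactly proportional to biome totals: no enrichment anywhere
        counts = BiomeCounts(
            ["T:A", "T:B", "T:C"],
            ["X", "Y"],
            np.array([[10, 30], [20, 60], [40, 120]]),
        )
        model = build_sphere_model(chain_graph, counts, None, None)
        assert model.spheres == []

    def test_recovers_planted_spheres(self, planted_dataset):
        from enrichsphere.synthetic import score_recovery

        d = planted_dataset
        model = build_sphere_model(
            d["graph"],
            aggregate_by_biome(d["term_table"]),
            aggregate_by_biome(d["species_table"]),
            d["gene_map"],
        )
        report = score_recovery(model, d["truth"])
        assert report.mean_term_recall >= 0.9
        assert report.mean_term_precision >= 0.9
        assert report.host_recall >= 0.9

    def test_spheres_connected_and_gated(self, planted_dataset):
        d = planted_dataset
        model = build_sphere_model(
            d["graph"], aggregate_by_biome(d["term_table"]), None, None
        )
        graph = d["graph"]
        for s in model.spheres:
            assert s.p_value < 0.01
            assert len({graph.namespace(t) for t in s.member_terms}) == 1
            # connectivity under the neighbor relation, by traversal
            seen = {s.member_terms[0]}
            frontier = [s.member_terms[0]]
            member_set = set(s.member_terms)
            while frontier:
                t = frontier.pop()
                for u in graph.neighbors(t) & member_set - seen:
                    seen.add(u)
                    frontier.append(u)
            assert seen == member_set

    def test_deterministic(self, planted_dataset):
        d = planted_dataset
        args = (d["graph"], aggregate_by_biome(d["term_table"]), None, None)
        assert build_sphere_model(*args).to_dict() == build_sphere_model(*args).to_dict()

    def test_json_roundtrip(self, planted_dataset, tmp_path):
        from enrichsphere.core_io import write_results

        d = planted_dataset
        model = build_sphere_model(
            d["graph"],
            aggregate_by_biome(d["term_table"]),
            aggregate_by_biome(d["species_table"]),
            d["gene_map"],
        )
        path = tmp_path / "model.json"
        write_results(model, path)
        assert SphereModel.from_json(path).to_dict() == model.to_dict()


class TestSelectSupplementBiome:
    def test_soil_homolog_example(self):
        from enrichsphere.reference import (
            PFAM_BIOME_HOMOLOGS,
            PFAM_REFERENCE_HOMOLOGS,
        )

        sel = select_supplement_biome(
            PFAM_BIOME_HOMOLOGS["PF12597"], PFAM_REFERENCE_HOMOLOGS["PF12597"]
        )
        assert sel.biome == "Soil"
        assert sel.supplemented_total == 365
        assert not sel.tie

    def test_tie_gives_no_selection(self):
        sel = select_supplement_biome({"A": 7, "B": 7, "C": 3}, 10)
        assert sel.tie and sel.biome is None and sel.supplemented_total is None

    def test_single_nonzero_biome_wins(self):
        sel = select_supplement_biome({"A": 0, "B": 12}, 5)
        assert sel.biome == "B" and sel.supplemented_total == 17

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no homologs"):
            select_supplement_biome({"A": 0, "B": 0}, 5)
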