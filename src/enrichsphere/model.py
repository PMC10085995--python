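"""statsmodels-style facade: a model object built from data, fit() -> results.

:class:`EnrichmentSphereModel` bundles the four inputs of the mining method
(GO-term abundances, species abundances, the ontology, the gene->term->host
map); ``fit`` prepares counts, aggregates by biome, runs the enrichment
scans, sphere expansion/merging and host linkage, and returns an
:class:`EnrichmentSphereResults` carrying the fitted sphere collection, the
underlying per-test tables, a ``summary()`` table, and hooks for downstream
classification and serialization.
"""

from __future__ import annotations

import os

from enrichsphere.classifier import (
    ClassifierReport,
    build_feature_matrix,
    train_evaluate,
)
from enrichsphere.core_io import (
    AbundanceTable,
    GeneAnnotationMap,
    aggregate_by_biome,
    prepare_counts,
    read_abundance_table,
    read_gene_map,
    write_results,
)
from enrichsphere.ontology import OntologyGraph, parse_obo, validate_ontology
from enrichsphere.spheres import SphereModel, build_sphere_model


class EnrichmentSphereModel:
    """The enrichment-sphere mining model for one multi-biome dataset.

    Parameters
    ----------
    term_table : AbundanceTable of kind ``go_term`` (proportions or counts).
    ontology : the is_a DAG the terms live in.
    species_table : optional AbundanceTable of kind ``species``.
    gene_map : optional gene -> term -> host species map for host linkage.
    """

    def __init__(
        self,
        term_table: AbundanceTable,
        ontology: OntologyGraph,
        species_table: AbundanceTable | None = None,
        gene_map: GeneAnnotationMap | None = None,
    ):
        self.term_table = term_table
        self.ontology = ontology
        self.species_table = species_table
        self.gene_map = gene_map
        if gene_map is not None:
            gene_map.validate_against(ontology)

    @classmethod
    def from_files(
        cls,
        term_path: str | os.PathLike,
        meta_path: str | os.PathLike,
        obo_path: str | os.PathLike,
        species_path: str | os.PathLike | None = None,
        gene_map_path: str | os.PathLike | None = None,
    ) -> "EnrichmentSphereModel":
        """Build from the TSV/OBO files the CLI exchanges."""
        term_table = read_abundance_table(term_path, "go_term", meta_path)
        species_table = (
            read_abundance_table(species_path, "species", meta_path)
            if species_path
            else None
        )
        gene_map = read_gene_map(gene_map_path) if gene_map_path else None
        return cls(
            term_table=term_table,
            ontology=parse_obo(obo_path),
            species_table=species_table,
            gene_map=gene_map,
        )

    def diagnostics(self) -> dict:
        """Ontology diagnostics including terms missing from the graph."""
        return validate_ontology(self.ontology, self.term_table.feature_ids)

    def fit(
        self,
        alpha: float = 0.01,
        bh: bool = False,
        require_improvement: bool = True,
        seed: int | None = None,
    ) -> "EnrichmentSphereResults":
        """Run the full pipeline and return the fitted results."""
        term_counts = aggregate_by_biome(prepare_counts(self.term_table))
        species_counts = (
            aggregate_by_biome(prepare_counts(self.species_table))
            if self.species_table is not None
            else None
        )
        sphere_model = build_sphere_model(
            self.ontology,
            term_counts,
            species_counts,
            self.gene_map,
            alpha=alpha,
            bh=bh,
            require_improvement=require_improvement,
            seed=seed,
        )
        return EnrichmentSphereResults(self, sphere_model)


class EnrichmentSphereResults:
    """Fitted sphere collection plus per-test tables and downstream hooks."""

    def __init__(self, model: EnrichmentSphereModel, sphere_model: SphereModel):
        self.model = model
        self.sphere_model = sphere_model

    @property
    def spheres(self):
        return self.sphere_model.spheres

    @property
    def term_results(self):
        return self.sphere_model.term_results

    @property
    def species_results(self):
        return self.sphere_model.species_results

    @property
    def parameters(self) -> dict:
        return self.sphere_model.parameters

    def summary(self) -> str:
        """Human-readable table of the fitted spheres."""
        lines = [
            "Enrichment sphere model",
            "=======================",
            f"alpha = {self.parameters['alpha']}, "
            f"spheres = {len(self.spheres)}, "
            f"enriched terms = {len(self.sphere_model.enriched_terms)}, "
            f"enriched hosts = {len(self.sphere_model.enriched_hosts)}",
            "",
            f"{'biome':<12} {'namespace':<22} {'size':>4} {'p_value':>10}  members (seed first)",
            "-" * 96,
        ]
        for s in self.spheres:
            members = ",".join(s.member_terms)
            if len(members) > 40:
                members = members[:37] + "..."
            lines.append(
                f"{s.biome:<12} {s.namespace:<22} {len(s.member_terms):>4} "
                f"{s.p_value:>10.3g}  {members}"
            )
            for sp, p in s.host_species[:3]:
                lines.append(f"{'':<12} host: {sp} (p = {p:.3g})")
        return "\n".join(lines)

    def to_json(self, path: str | os.PathLike) -> None:
        write_results(self.sphere_model, path)

    def feature_matrix(self, variant: str = "both"):
        """Samples x enriched-feature matrix for the biome classifier."""
        tables = [self.model.term_table.to_proportions()]
        if self.model.species_table is not None:
            tables.append(self.model.species_table.to_proportions())
        return build_feature_matrix(tables, self.sphere_model, variant=variant)

    def classify(
        self,
        variant: str = "both",
        trees: int = 100,
        folds: int = 10,
        seed: int = 0,
    ) -> ClassifierReport:
        """Cross-validated biome identification from the enriched features."""
        return train_evaluate(
            self.feature_matrix(variant), trees=trees, folds=folds, seed=seed
        )

    def score(self, truth) -> "object":
        """Recovery report against a synthetic planted truth."""
        from enrichsphere.synthetic import score_recovery

        return score_recovery(self.sphere_model, truth)
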