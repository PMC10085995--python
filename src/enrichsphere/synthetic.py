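"""Ground-truth generator: random ontologies, planted spheres, and
Dirichlet-multinomial abundance simulation.

The generator emulates the structure the mining pipeline assumes: biome-
labeled samples whose GO-term and species counts follow a Dirichlet-
multinomial, with DAG-connected sets of terms (and linked host species)
inflated in one biome by a configurable effect multiplier.  The Dirichlet-
multinomial is the standard overdispersed count model for compositional
sequencing data; its single ``concentration`` knob interpolates between
heavy sample-to-sample variation (small values) and the plain multinomial
limit (``concentration=None``).  Because expected proportions are
renormalized after the effect multiplication, the realized between-biome
fold of a planted feature is somewhat below the nominal effect.

Everything is a pure function of its seed, so fixtures are reproducible
bit-for-bit and recovery scoring against the planted truth is exact.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from enrichsphere.core_io import (
    AbundanceTable,
    GeneAnnotationMap,
    SampleMeta,
    write_abundance_table,
    write_gene_map,
    write_metadata,
)
from enrichsphere.ontology import OntologyGraph
from enrichsphere.spheres import SphereModel

DEFAULT_BIOMES = ["Engineered", "Freshwater", "Gut", "Soil"]
_GO_NAMESPACES = ["biological_process", "cellular_component", "molecular_function"]


@dataclass
class PlantedTruth:
    """The ground truth behind a simulated dataset."""

    ontology: OntologyGraph
    biomes: list[str]
    planted_spheres: list[tuple[str, list[str], float]]  # (biome, members, effect)
    planted_species: list[tuple[str, str, float]]  # (biome, species_id, effect)
    gene_map: GeneAnnotationMap
    term_baseline: dict[str, float]
    species_baseline: dict[str, float]
    seed: int

    def planted_terms(self, biome: str | None = None) -> set[str]:
        out: set[str] = set()
        for b, members, _ in self.planted_spheres:
            if biome is None or b == biome:
                out.update(members)
        return out

    def planted_hosts(self, biome: str | None = None) -> set[str]:
        return {
            sp for b, sp, _ in self.planted_species if biome is None or b == biome
        }

    def to_dict(self) -> dict:
        return {
            "biomes": list(self.biomes),
            "planted_spheres": [
                {"biome": b, "member_terms": list(m), "effect": float(e)}
                for b, m, e in self.planted_spheres
            ],
            "planted_species": [
                {"biome": b, "species_id": sp, "effect": float(e)}
                for b, sp, e in self.planted_species
            ],
            "seed": self.seed,
        }


@dataclass
class RecoveryReport:
    """Recovered-vs-planted scoring of a fitted sphere model."""

    per_sphere: list[dict] = field(default_factory=list)
    mean_term_recall: float = 0.0
    mean_term_precision: float = 0.0
    mean_term_f1: float = 0.0
    biome_assignment_rate: float = 0.0
    host_recall: float = 0.0
    host_precision: float = 0.0

    def to_dict(self) -> dict:
        return {
            "per_sphere": self.per_sphere,
            "mean_term_recall": self.mean_term_recall,
            "mean_term_precision": self.mean_term_precision,
            "mean_term_f1": self.mean_term_f1,
            "biome_assignment_rate": self.biome_assignment_rate,
            "host_recall": self.host_recall,
            "host_precision": self.host_precision,
        }


def _term_id(i: int) -> str:
    return f"T:{i:06d}"


def make_ontology(
    n_terms: int,
    n_namespaces: int = 3,
    mean_parents: float = 1.5,
    seed: int = 0,
) -> OntologyGraph:
    """Grow a random is_a DAG, acyclic by construction.

    Each namespace gets one root; every subsequent term draws
    ``1 + Poisson(mean_parents - 1)`` parents (capped at the number of
    existing terms in its namespace) uniformly from that namespace.
    Namespaces reuse the three GO names, then fall back to ``namespace_k``.
    """
    if n_namespaces < 1 or n_terms < n_namespaces:
        raise ValueError(
            f"need n_terms >= n_namespaces >= 1, got {n_terms}, {n_namespaces}"
        )
    if mean_parents < 1.0:
        raise ValueError(f"mean_parents must be >= 1, got {mean_parents}")
    rng = np.random.default_rng(seed)
    ns_names = [
        _GO_NAMESPACES[i] if i < len(_GO_NAMESPACES) else f"namespace_{i + 1}"
        for i in range(n_namespaces)
    ]
    terms: dict[str, tuple[str, str]] = {}
    edges: list[tuple[str, str]] = []
    per_ns: list[list[str]] = [[] for _ in range(n_namespaces)]
    for i in range(n_terms):
        tid = _term_id(i + 1)
        ns_idx = i % n_namespaces
        terms[tid] = (f"synthetic term {tid}", ns_names[ns_idx])
        existing = per_ns[ns_idx]
        if existing:
            n_parents = 1 + int(rng.poisson(mean_parents - 1.0))
            n_parents = min(n_parents, len(existing))
            parents = rng.choice(len(existing), size=n_parents, replace=False)
            for p in sorted(parents):
                edges.append((tid, existing[p]))
        per_ns[ns_idx].append(tid)
    return OntologyGraph.from_terms(terms, edges)


def _grow_connected(
    graph: OntologyGraph, seed_term: str, size: int, forbidden: set[str], rng
) -> list[str] | None:
    """Grow a connected member set by random frontier additions."""
    members = [seed_term]
    member_set = {seed_term}
    while len(members) < size:
        frontier = set()
        for m in members:
            frontier |= graph.neighbors(m)
        frontier -= member_set
        frontier -= forbidden
        if not frontier:
            return None
        pick = sorted(frontier)[rng.integers(len(frontier))]
        members.append(pick)
        member_set.add(pick)
    return members


def plant_truth(
    graph: OntologyGraph,
    biomes: list[str] | None = None,
    n_spheres: int = 5,
    sphere_size_range: tuple[int, int] = (3, 6),
    effect: float = 5.0,
    n_species: int = 300,
    seed: int = 0,
) -> PlantedTruth:
    """Plant disjoint connected term sets (and linked species) across biomes.

    Spheres are assigned to biomes round-robin; each grows from a uniformly
    chosen seed term by random frontier additions to a size uniform in
    ``sphere_size_range``.  Two planted host species per sphere share the
    sphere's biome and effect and get gene-map entries to its member terms.
    Baseline proportions for terms and species are flat Dirichlet draws.
    """
    if biomes is None:
        biomes = list(DEFAULT_BIOMES)
    lo, hi = sphere_size_range
    if not 1 <= lo <= hi:
        raise ValueError(f"bad sphere_size_range {sphere_size_range}")
    if effect <= 1.0:
        raise ValueError(f"effect must be > 1, got {effect}")
    rng = np.random.default_rng(seed)
    all_terms = graph.terms
    planted: set[str] = set()
    spheres: list[tuple[str, list[str], float]] = []
    for si in range(n_spheres):
        biome = biomes[si % len(biomes)]
        size = int(rng.integers(lo, hi + 1))
        members = None
        for _ in range(200):
            cand = all_terms[rng.integers(len(all_terms))]
            if cand in planted:
                continue
            members = _grow_connected(graph, cand, size, planted, rng)
            if members is not None:
                break
        if members is None:
            raise RuntimeError(
                f"could not fit {n_spheres} disjoint planted spheres of size "
                f"{sphere_size_range} into this ontology"
            )
        planted.update(members)
        spheres.append((biome, members, float(effect)))

    species_ids = [f"SP:{i:04d}" for i in range(1, n_species + 1)]
    planted_species: list[tuple[str, str, float]] = []
    records: list[tuple[str, str, str]] = []
    free = list(species_ids)
    gene_counter = 1
    for biome, members, eff in spheres:
        for _ in range(2):
            if not free:
                raise RuntimeError("not enough species to plant 2 per sphere")
            sp = free.pop(int(rng.integers(len(free))))
            planted_species.append((biome, sp, eff))
            for t in members:
                records.append((f"G:{gene_counter:06d}", t, sp))
                gene_counter += 1

    term_base = rng.dirichlet(np.ones(len(all_terms)))
    species_base = rng.dirichlet(np.ones(n_species))
    return PlantedTruth(
        ontology=graph,
        biomes=list(biomes),
        planted_spheres=spheres,
        planted_species=planted_species,
        gene_map=GeneAnnotationMap(records=records),
        term_baseline=dict(zip(all_terms, term_base.tolist())),
        species_baseline=dict(zip(species_ids, species_base.tolist())),
        seed=int(seed),
    )


def _biome_expected(
    baseline: dict[str, float], inflated: dict[str, float]
) -> np.ndarray:
    props = np.array(
        [baseline[f] * inflated.get(f, 1.0) for f in baseline], dtype=float
    )
    return props / props.sum()


def simulate_dataset(
    truth: PlantedTruth,
    samples_per_biome: int = 30,
    depth: int = 50_000,
    concentration: float | None = 100_000.0,
    seed: int = 0,
) -> tuple[AbundanceTable, AbundanceTable, list[SampleMeta], GeneAnnotationMap]:
    """Draw Dirichlet-multinomial count tables for terms and species.

    Per sample of biome b: expected proportions are the baseline with that
    biome's planted features multiplied by their effect and renormalized;
    sample proportions are Dirichlet(concentration x expected) draws
    (``concentration=None`` skips the Dirichlet stage, giving exact
    multinomial sampling at the expected proportions); counts are
    Multinomial(depth, sample proportions).  Column sums equal `depth`
    exactly and every sample's read_depth is `depth`.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    if concentration is not None and concentration <= 0:
        raise ValueError(f"concentration must be > 0, got {concentration}")
    if samples_per_biome < 1:
        raise ValueError("samples_per_biome must be >= 1")
    rng = np.random.default_rng(seed)

    term_ids = list(truth.term_baseline)
    species_ids = list(truth.species_baseline)
    term_expected: dict[str, np.ndarray] = {}
    species_expected: dict[str, np.ndarray] = {}
    for b in truth.biomes:
        t_mult = {t: e for bb, ms, e in truth.planted_spheres if bb == b for t in ms}
        s_mult = {sp: e for bb, sp, e in truth.planted_species if bb == b}
        term_expected[b] = _biome_expected(truth.term_baseline, t_mult)
        species_expected[b] = _biome_expected(truth.species_baseline, s_mult)

    samples: list[SampleMeta] = []
    term_cols: list[np.ndarray] = []
    species_cols: list[np.ndarray] = []
    for b in truth.biomes:
        for i in range(samples_per_biome):
            samples.append(SampleMeta(f"{b}_s{i + 1:03d}", b, int(depth)))
            for expected, cols in (
                (term_expected[b], term_cols),
                (species_expected[b], species_cols),
            ):
                if concentration is None:
                    p = expected
                else:
                    p = rng.dirichlet(concentration * expected)
                cols.append(rng.multinomial(depth, p))

    term_table = AbundanceTable(
        feature_ids=term_ids,
        samples=samples,
        values=np.column_stack(term_cols),
        kind="go_term",
        stage="count",
    )
    species_table = AbundanceTable(
        feature_ids=species_ids,
        samples=samples,
        values=np.column_stack(species_cols),
        kind="species",
        stage="count",
    )
    return term_table, species_table, samples, truth.gene_map


def score_recovery(recovered: SphereModel, truth: PlantedTruth) -> RecoveryReport:
    """Score a fitted model against the planted truth.

    Each planted sphere is matched to the same-biome recovered sphere with
    maximal member overlap; term precision/recall/F1 are computed on matched
    pairs, an unmatched planted sphere scores 0/0/0.  Host metrics compare
    the matched sphere's linked species with the sphere's planted species.
    """
    report = RecoveryReport()
    if not truth.planted_spheres:
        return report
    per_sphere = []
    host_tp = host_fp = host_fn = 0
    matched_count = 0
    for biome, members, _ in truth.planted_spheres:
        planted_set = set(members)
        candidates = recovered.spheres_in(biome)
        best = None
        best_overlap = 0
        for s in candidates:
            overlap = len(planted_set & set(s.member_terms))
            if overlap > best_overlap:
                best, best_overlap = s, overlap
        planted_hosts = {
            sp
            for b, sp, _ in truth.planted_species
            if b == biome and sp in truth.gene_map.species_for_terms(planted_set)
        }
        if best is None:
            per_sphere.append(
                {
                    "biome": biome,
                    "planted": sorted(planted_set),
                    "recovered": [],
                    "precision": 0.0,
                    "recall": 0.0,
                    "f1": 0.0,
                }
            )
            host_fn += len(planted_hosts)
            continue
        matched_count += 1
        rec_set = set(best.member_terms)
        tp = len(planted_set & rec_set)
        precision = tp / len(rec_set) if rec_set else 0.0
        recall = tp / len(planted_set)
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        per_sphere.append(
            {
                "biome": biome,
                "planted": sorted(planted_set),
                "recovered": list(best.member_terms),
                "precision": precision,
                "recall": recall,
                "f1": f1,
            }
        )
        rec_hosts = {sp for sp, _ in best.host_species}
        host_tp += len(rec_hosts & planted_hosts)
        host_fp += len(rec_hosts - planted_hosts)
        host_fn += len(planted_hosts - rec_hosts)

    report.per_sphere = per_sphere
    report.mean_term_precision = float(
        np.mean([d["precision"] for d in per_sphere])
    )
    report.mean_term_recall = float(np.mean([d["recall"] for d in per_sphere]))
    report.mean_term_f1 = float(np.mean([d["f1"] for d in per_sphere]))
    report.biome_assignment_rate = matched_count / len(truth.planted_spheres)
    report.host_recall = host_tp / (host_tp + host_fn) if host_tp + host_fn else 0.0
    report.host_precision = host_tp / (host_tp + host_fp) if host_tp + host_fp else 0.0
    return report


def write_dataset(
    out_dir: str | os.PathLike,
    truth: PlantedTruth,
    term_table: AbundanceTable,
    species_table: AbundanceTable,
) -> dict[str, str]:
    """Write OBO + the four TSVs + a truth JSON; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "ontology": os.path.join(out_dir, "ontology.obo"),
        "terms": os.path.join(out_dir, "go_abundance.tsv"),
        "species": os.path.join(out_dir, "species_abundance.tsv"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
        "gene_map": os.path.join(out_dir, "gene_map.tsv"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    truth.ontology.write_obo(paths["ontology"])
    write_abundance_table(term_table, paths["terms"])
    write_abundance_table(species_table, paths["species"])
    write_metadata(term_table.samples, paths["metadata"])
    write_gene_map(truth.gene_map, paths["gene_map"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
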