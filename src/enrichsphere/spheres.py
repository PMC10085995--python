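"""Function spheres: greedy expansion of enriched GO terms over the ontology.

A *function sphere* is a connected set of GO terms within one namespace that
is jointly over-represented in one biome.  Joint enrichment of a member set S
is judged under the central multivariate hypergeometric urn whose colors are
the member terms plus one pooled "other" color; the test statistic is the
pooled member count T = sum of in-biome counts over S.  By the pooling
identity, T is itself univariate hypergeometric with pooled success count,
so the sphere p-value has the exact closed form

    p(S) = P(X >= sum_m k_m),  X ~ Hypergeometric(N, sum_m K_m, n_biome).

Expansion starts from an enriched seed term and greedily adds, one at a
time, the frontier neighbor (distance-1 in the is_a DAG, either direction)
that minimizes the sphere p-value.  A candidate is accepted only while the
sphere p-value stays below alpha *and* strictly improves; with deeply
sequenced data the pooled tail of a strong seed can stay below alpha through
many diluting additions, so the improvement requirement is what keeps
spheres tight around the genuinely co-enriched terms (it can be switched off
with ``require_improvement=False``, which leaves the threshold as the only
stop rule).

Also here: host-species linkage, sphere merging, full model assembly, and
the enriched-biome selection rule for homolog supplementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from enrichsphere.core_io import BiomeCounts, GeneAnnotationMap
from enrichsphere.enrichment import (
    EnrichmentResult,
    adjust_bh,
    hypergeom_tail,
    scan_enrichment,
)
from enrichsphere.ontology import OntologyGraph


@dataclass
class FunctionSphere:
    """A biome, its connected enriched term set, and linked host species.

    ``member_terms`` is in order of addition, seed first.  ``host_species``
    holds (species_id, p_value) pairs sorted by p then id.
    """

    biome: str
    member_terms: list[str]
    p_value: float
    namespace: str
    host_species: list[tuple[str, float]] = field(default_factory=list)

    @property
    def seed(self) -> str:
        return self.member_terms[0]

    def to_dict(self) -> dict:
        return {
            "biome": self.biome,
            "member_terms": list(self.member_terms),
            "p_value": float(self.p_value),
            "namespace": self.namespace,
            "host_species": [[sp, float(p)] for sp, p in self.host_species],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FunctionSphere":
        return cls(
            biome=d["biome"],
            member_terms=list(d["member_terms"]),
            p_value=float(d["p_value"]),
            namespace=d["namespace"],
            host_species=[(sp, float(p)) for sp, p in d["host_species"]],
        )


@dataclass
class SphereModel:
    """The full collection of spheres and enrichment calls across biomes."""

    spheres: list[FunctionSphere]
    term_results: list[EnrichmentResult]
    species_results: list[EnrichmentResult]
    parameters: dict

    def spheres_in(self, biome: str) -> list[FunctionSphere]:
        return [s for s in self.spheres if s.biome == biome]

    @property
    def enriched_terms(self) -> list[str]:
        """Union of sphere member terms, sorted."""
        out: set[str] = set()
        for s in self.spheres:
            out.update(s.member_terms)
        return sorted(out)

    @property
    def enriched_hosts(self) -> list[str]:
        """Union of linked host species, sorted."""
        out: set[str] = set()
        for s in self.spheres:
            out.update(sp for sp, _ in s.host_species)
        return sorted(out)

    def to_dict(self) -> dict:
        def result_dict(r: EnrichmentResult) -> dict:
            return {
                "feature_id": r.feature_id,
                "biome": r.biome,
                "k": int(r.k),
                "K": int(r.K),
                "n": int(r.n),
                "N": int(r.N),
                "p_value": float(r.p_value),
                "q_value": None if r.q_value is None else float(r.q_value),
                "enriched": bool(r.enriched),
                "fold": float(r.fold),
                "skipped": bool(r.skipped),
            }

        return {
            "spheres": [s.to_dict() for s in self.spheres],
            "term_results": [result_dict(r) for r in self.term_results],
            "species_results": [result_dict(r) for r in self.species_results],
            "parameters": dict(self.parameters),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SphereModel":
        def result(rd: dict) -> EnrichmentResult:
            return EnrichmentResult(
                feature_id=rd["feature_id"],
                biome=rd["biome"],
                k=rd["k"],
                K=rd["K"],
                n=rd["n"],
                N=rd["N"],
                p_value=rd["p_value"],
                q_value=rd["q_value"],
                enriched=rd["enriched"],
                fold=rd["fold"],
                skipped=rd["skipped"],
            )

        return cls(
            spheres=[FunctionSphere.from_dict(s) for s in d["spheres"]],
            term_results=[result(r) for r in d["term_results"]],
            species_results=[result(r) for r in d["species_results"]],
            parameters=dict(d["parameters"]),
        )

    @classmethod
    def from_json(cls, path) -> "SphereModel":
        import json

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def sphere_pvalue(
    members: Iterable[str], counts: BiomeCounts, biome: str, log: bool = False
) -> float:
    """Joint upper-tail probability of the pooled member count in `biome`.

    Exactly equals ``hypergeom_tail(sum k_m, sum K_m, n, N)`` by the pooling
    identity of the central multivariate hypergeometric distribution.
    ``log=True`` returns the natural log of the tail, which expansion uses
    internally so that p-values too small for a float still compare cleanly.
    """
    members = list(members)
    if not members:
        raise ValueError("member set is empty")
    j = counts.biome_index(biome)
    k_sum = 0
    K_sum = 0
    for m in members:
        i = counts.feature_index(m)
        k_sum += int(counts.counts[i, j])
        K_sum += int(counts.totals_per_feature[i])
    n = int(counts.totals_per_biome[j])
    return hypergeom_tail(k_sum, K_sum, n, counts.grand_total, log=log)


def expand_sphere(
    seed: str,
    graph: OntologyGraph,
    counts: BiomeCounts,
    biome: str,
    alpha: float = 0.01,
    require_improvement: bool = True,
    exclude: set[str] | None = None,
    return_trace: bool = False,
):
    """Greedily grow a function sphere around an enriched seed term.

    At each step the candidate set is the namespace-restricted frontier of
    the whole current sphere (neighbors of any member, minus members,
    restricted to terms present in `counts` and not in `exclude`).  The
    candidate minimizing the sphere p-value is added -- ties broken by
    lexicographically smallest term id -- while the p-value stays below
    `alpha` and (by default) strictly decreases; the failing candidate is
    never included.  Fully deterministic.

    `exclude` lets the caller fence off terms already claimed by another
    sphere; without it, a marginal seed sitting next to a strongly enriched
    sphere would always absorb that sphere's members (any addition of a
    strong term improves the pooled p) and spuriously annex it.

    Returns the sphere, or ``(sphere, trace)`` with ``return_trace=True``
    where trace rows are (step, term_added, sphere_p_after).
    """
    import math

    if seed not in graph:
        raise KeyError(f"seed term {seed!r} absent from the ontology")
    log_alpha = math.log(alpha)
    logp_seed = sphere_pvalue([seed], counts, biome, log=True)
    if logp_seed >= log_alpha:
        raise ValueError(
            f"seed {seed!r} is not enriched in {biome!r} "
            f"(p = {math.exp(logp_seed):.4g} >= alpha = {alpha})"
        )
    namespace = graph.namespace(seed)
    available = set(counts.feature_ids)
    if exclude:
        available -= set(exclude) - {seed}
    members = [seed]
    member_set = {seed}
    logp_current = logp_seed
    trace = [(0, seed, float(min(1.0, math.exp(logp_seed))))]
    step = 1
    while True:
        frontier: set[str] = set()
        for m in members:
            frontier |= graph.neighbors(m)
        frontier -= member_set
        frontier = {
            c for c in frontier if c in available and graph.namespace(c) == namespace
        }
        if not frontier:
            break
        best = None
        best_logp = None
        for c in sorted(frontier):
            logp = sphere_pvalue(member_set | {c}, counts, biome, log=True)
            if best_logp is None or logp < best_logp:
                best, best_logp = c, logp
        assert best is not None
        if best_logp >= log_alpha:
            break
        if require_improvement and best_logp >= logp_current:
            break
        members.append(best)
        member_set.add(best)
        logp_current = best_logp
        trace.append((step, best, float(min(1.0, math.exp(best_logp)))))
        step += 1
    sphere = FunctionSphere(
        biome=biome,
        member_terms=members,
        p_value=float(min(1.0, math.exp(logp_current))),
        namespace=namespace,
    )
    if return_trace:
        return sphere, trace
    return sphere


def merge_spheres(
    spheres: list[FunctionSphere], counts: BiomeCounts, alpha: float = 0.01
) -> list[FunctionSphere]:
    """Union overlapping spheres of one biome/namespace when the union passes.

    Spheres sharing at least one member term are merged and the union's
    p-value recomputed; a union failing the alpha gate leaves the pre-merge
    spheres in place.  Iterates to a fixed point, deterministically.
    """
    if not spheres:
        return []
    biomes = {s.biome for s in spheres}
    namespaces = {s.namespace for s in spheres}
    if len(biomes) > 1 or len(namespaces) > 1:
        raise ValueError("merge_spheres expects spheres from one biome and namespace")
    work = sorted(spheres, key=lambda s: (s.p_value, s.member_terms[0]))
    blocked: set[tuple[frozenset, frozenset]] = set()
    changed = True
    while changed:
        changed = False
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                a, b = work[i], work[j]
                sa, sb = frozenset(a.member_terms), frozenset(b.member_terms)
                if not sa & sb:
                    continue
                if (sa, sb) in blocked or (sb, sa) in blocked:
                    continue
                union = list(a.member_terms) + [
                    t for t in b.member_terms if t not in sa
                ]
                p = sphere_pvalue(union, counts, a.biome)
                if p < alpha:
                    merged = FunctionSphere(
                        biome=a.biome,
                        member_terms=union,
                        p_value=p,
                        namespace=a.namespace,
                    )
                    work = [s for idx, s in enumerate(work) if idx not in (i, j)]
                    work.append(merged)
                    work.sort(key=lambda s: (s.p_value, s.member_terms[0]))
                    changed = True
                    break
                blocked.add((sa, sb))
            if changed:
                break
    return work


def link_hosts(
    sphere: FunctionSphere,
    gene_map: GeneAnnotationMap,
    species_counts: BiomeCounts,
    alpha: float = 0.01,
) -> list[tuple[str, float]]:
    """Attach host species enriched in the sphere's biome.

    Candidates are species owning at least one gene annotated to a member
    term; each is tested univariately on its species counts in the sphere's
    biome and kept when p < alpha.  Sorted by p then species id; also stored
    on the sphere.
    """
    candidates = sorted(gene_map.species_for_terms(sphere.member_terms))
    hosts: list[tuple[str, float]] = []
    for sp in candidates:
        k, K, n, N = species_counts.urn(sp, sphere.biome)
        if K == 0:
            continue
        p = hypergeom_tail(k, K, n, N)
        if p < alpha:
            hosts.append((sp, p))
    hosts.sort(key=lambda t: (t[1], t[0]))
    sphere.host_species = hosts
    return hosts


def build_sphere_model(
    graph: OntologyGraph,
    term_counts: BiomeCounts,
    species_counts: BiomeCounts | None,
    gene_map: GeneAnnotationMap | None,
    alpha: float = 0.01,
    bh: bool = False,
    require_improvement: bool = True,
    seed: int | None = None,
) -> SphereModel:
    """Run the full sphere-mining pipeline and assemble the model.

    Stages: univariate scans of terms and species, greedy expansion from
    every enriched term not yet absorbed into an earlier sphere (seeds in
    ascending univariate p, ties by term id), per-biome/namespace merging,
    and host linkage.  Output is deterministic for fixed inputs.
    """
    term_results = scan_enrichment(term_counts, alpha)
    if bh:
        adjust_bh(term_results, alpha)
    species_results: list[EnrichmentResult] = []
    if species_counts is not None:
        species_results = scan_enrichment(species_counts, alpha)
        if bh:
            adjust_bh(species_results, alpha)

    seeds = sorted(
        (
            r
            for r in term_results
            if r.enriched and not r.skipped and r.feature_id in graph
        ),
        key=lambda r: (r.p_value, r.feature_id, r.biome),
    )
    absorbed: dict[str, set[str]] = {}
    raw: dict[tuple[str, str], list[FunctionSphere]] = {}
    for r in seeds:
        if r.feature_id in absorbed.get(r.biome, set()):
            continue
        sphere = expand_sphere(
            r.feature_id,
            graph,
            term_counts,
            r.biome,
            alpha=alpha,
            require_improvement=require_improvement,
            exclude=absorbed.get(r.biome),
        )
        absorbed.setdefault(r.biome, set()).update(sphere.member_terms)
        raw.setdefault((r.biome, sphere.namespace), []).append(sphere)

    spheres: list[FunctionSphere] = []
    for key in sorted(raw):
        spheres.extend(merge_spheres(raw[key], term_counts, alpha))
    if gene_map is not None and species_counts is not None:
        for s in spheres:
            link_hosts(s, gene_map, species_counts, alpha)
    spheres.sort(key=lambda s: (s.biome, s.namespace, s.p_value, s.member_terms[0]))

    return SphereModel(
        spheres=spheres,
        term_results=term_results,
        species_results=species_results,
        parameters={
            "alpha": alpha,
            "bh": bh,
            "require_improvement": require_improvement,
            "seed": seed,
        },
    )


@dataclass(frozen=True)
class SupplementSelection:
    """Outcome of the enriched-biome selection rule for homolog mining."""

    biome: str | None
    supplemented_total: int | None
    tie: bool


def select_supplement_biome(
    homolog_counts: Mapping[str, int], reference_count: int
) -> SupplementSelection:
    """Pick the biome to mine for extra homologs of a protein family.

    The biome with the strictly maximal homolog count is selected and the
    supplemented alignment size is ``reference_count + selected count``.  A
    tie for the maximum returns ``tie=True`` and no selection.
    """
    if len(homolog_counts) < 2:
        raise ValueError("need homolog counts for at least 2 biomes")
    if reference_count < 0:
        raise ValueError("reference_count must be >= 0")
    if any(c < 0 for c in homolog_counts.values()):
        raise ValueError("homolog counts must be non-negative")
    if all(c == 0 for c in homolog_counts.values()):
        raise ValueError("no homologs in any biome")
    best = max(homolog_counts.values())
    winners = sorted(b for b, c in homolog_counts.items() if c == best)
    if len(winners) > 1:
        return SupplementSelection(biome=None, supplemented_total=None, tie=True)
    return SupplementSelection(
        biome=winners[0],
        supplemented_total=int(reference_count) + int(best),
        tie=False,
    )
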