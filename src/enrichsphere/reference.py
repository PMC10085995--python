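"""Published reference figures used as worked-example inputs.

These constants come from a four-biome (Engineered, Gut, Freshwater, Soil)
survey of 1,705 MGnify metagenomes: per-biome homolog counts for protein
families whose structures were modeled with biome-supplemented alignments,
the Pfam reference alignment sizes they started from, and the tallies of GO
annotations involved.  They are *inputs* to the worked examples (e.g. the
supplement-biome selection rule), not outputs of this package.
"""

# Homolog counts per biome for the copper-resistance family PF12597.
PFAM_BIOME_HOMOLOGS: dict[str, dict[str, int]] = {
    "PF12597": {"Soil": 183, "Freshwater": 125, "Gut": 39, "Engineered": 68},
}

# Homologous sequences in the Pfam reference alignment before supplementation.
PFAM_REFERENCE_HOMOLOGS: dict[str, int] = {
    "PF12597": 182,
    "PF05425": 425,
    "PF14109": 285,
    "PF14044": 411,
}

# GO annotations retrieved for the four-biome dataset, per namespace.
GO_ANNOTATIONS_PER_NAMESPACE: dict[str, int] = {
    "biological_process": 421,
    "cellular_component": 284,
    "molecular_function": 140,
}

# Enriched GO annotations and enriched gene-host species found per biome.
ENRICHED_GO_PER_BIOME: dict[str, int] = {
    "Soil": 32,
    "Freshwater": 11,
    "Gut": 9,
    "Engineered": 10,
}
ENRICHED_HOSTS_PER_BIOME: dict[str, int] = {
    "Soil": 66,
    "Freshwater": 28,
    "Gut": 22,
    "Engineered": 12,
}
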