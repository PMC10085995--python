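"""Data model and TSV/JSON plumbing for abundance profiles.

The central objects are :class:`AbundanceTable` (feature x sample matrix,
either relative proportions as emitted by a profiler or prepared integer
counts) and :class:`BiomeCounts`, the feature x biome aggregated integer
matrix that plays the role of the urn in every hypergeometric test: for a
feature ``f`` and biome ``b`` the urn quantities are

    k = counts[f, b]        (feature count inside the biome)
    K = row total of f      (feature count over all biomes)
    n = column total of b   (biome total)
    N = grand total

TSV dialect: tab-separated, UTF-8, lines starting with ``#`` are comments,
no quoting.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_PROPORTION_TOL = 1e-6
SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: id, habitat biome label and total read depth."""

    sample_id: str
    biome: str
    read_depth: int

    def __post_init__(self) -> None:
        if self.read_depth < 0:
            raise ValueError(
                f"read_depth for sample {self.sample_id!r} must be >= 0, "
                f"got {self.read_depth}"
            )


@dataclass
class AbundanceTable:
    """Feature x sample abundance matrix with its sample metadata.

    Parameters
    ----------
    feature_ids : ordered feature identifiers (GO term ids, species ids ...).
    samples : per-sample metadata, in column order.
    values : (n_features, n_samples) array; non-negative proportions when
        ``stage == "proportion"``, non-negative integers when
        ``stage == "count"``.
    kind : what the features are: ``"go_term"``, ``"species"`` or ``"domain"``.
    stage : ``"proportion"`` or ``"count"``.
    """

    feature_ids: list[str]
    samples: list[SampleMeta]
    values: np.ndarray
    kind: str
    stage: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.samples)} samples"
            )
        if self.kind not in ("go_term", "species", "domain"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.stage not in ("proportion", "count"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = sorted(
                {f for f in self.feature_ids if self.feature_ids.count(f) > 1}
            )
            raise ValueError(f"duplicate feature ids: {dupes}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids in metadata")
        if np.any(self.values < 0):
            f, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative abundance at feature {self.feature_ids[f]!r}, "
                f"sample {sample_ids[s]!r}"
            )
        if self.stage == "proportion":
            sums = self.values.sum(axis=0)
            bad = np.argwhere(sums > 1.0 + _PROPORTION_TOL)
            if bad.size:
                s = int(bad[0][0])
                raise ValueError(
                    f"sample {sample_ids[s]!r} proportions sum to {sums[s]:.8f} > 1"
                )
        else:
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("stage='count' table contains non-integer values")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def biomes(self) -> list[str]:
        """Distinct biome labels, lexicographically ordered."""
        return sorted({s.biome for s in self.samples})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def to_proportions(self) -> "AbundanceTable":
        """Convert a count-stage table back to per-sample proportions."""
        if self.stage == "proportion":
            return self
        depths = self.values.sum(axis=0)
        depths[depths == 0] = 1.0
        return AbundanceTable(
            feature_ids=list(self.feature_ids),
            samples=list(self.samples),
            values=self.values / depths,
            kind=self.kind,
            stage="proportion",
        )


@dataclass
class BiomeCounts:
    """Feature x biome integer count matrix: the urn for enrichment tests."""

    feature_ids: list[str]
    biomes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.feature_ids), len(self.biomes)):
            raise ValueError("counts shape does not match feature/biome lists")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        self._findex = {f: i for i, f in enumerate(self.feature_ids)}
        self._bindex = {b: j for j, b in enumerate(self.biomes)}
        # counts are treated as immutable once built; cache the urn margins
        self._n_b = self.counts.sum(axis=0)
        self._K_f = self.counts.sum(axis=1)
        self._N = int(self.counts.sum())

    @property
    def totals_per_biome(self) -> np.ndarray:
        """n_b: column sums."""
        return self._n_b

    @property
    def totals_per_feature(self) -> np.ndarray:
        """K_f: row sums."""
        return self._K_f

    @property
    def grand_total(self) -> int:
        """N."""
        return self._N

    def feature_index(self, feature_id: str) -> int:
        try:
            return self._findex[feature_id]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in counts") from None

    def biome_index(self, biome: str) -> int:
        try:
            return self._bindex[biome]
        except KeyError:
            raise KeyError(f"biome {biome!r} not in counts") from None

    def urn(self, feature_id: str, biome: str) -> tuple[int, int, int, int]:
        """Return (k, K, n, N) for one feature/biome cell."""
        i = self.feature_index(feature_id)
        j = self.biome_index(biome)
        return (
            int(self.counts[i, j]),
            int(self.totals_per_feature[i]),
            int(self.totals_per_biome[j]),
            self.grand_total,
        )


@dataclass
class GeneAnnotationMap:
    """Gene -> GO term -> host species triples linking functions to hosts."""

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = [tuple(r) for r in self.records]
        if len(set(self.records)) != len(self.records):
            raise ValueError("duplicate (gene_id, term_id, species_id) triples")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> set[str]:
        return {sp for _, _, sp in self.records}

    @property
    def terms(self) -> set[str]:
        return {t for _, t, _ in self.records}

    def species_for_terms(self, terms: Iterable[str]) -> set[str]:
        """Species owning at least one gene annotated to any of `terms`."""
        terms = set(terms)
        return {sp for _, t, sp in self.records if t in terms}

    def validate_against(self, ontology) -> None:
        missing = sorted(self.terms - set(ontology.terms))
        if missing:
            raise ValueError(f"gene map references unknown ontology terms: {missing}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_metadata(path: str | os.PathLike) -> list[SampleMeta]:
    """Read a sample metadata TSV with columns sample_id, biome, read_depth."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str, "biome": str})
    required = {"sample_id", "biome", "read_depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata file {path} is missing columns: {sorted(missing)}")
    return [
        SampleMeta(str(r.sample_id), str(r.biome), int(r.read_depth))
        for r in df.itertuples(index=False)
    ]


def read_abundance_table(
    path: str | os.PathLike, kind: str, meta_path: str | os.PathLike
) -> AbundanceTable:
    """Read a feature x sample TSV plus its metadata TSV.

    The data file carries sample ids in the header row and feature ids in the
    first column.  The stage is inferred: all-integer matrices are counts,
    anything else is proportions.  Every sample column must have metadata;
    sample order follows the data file.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    feature_ids = [str(f) for f in df.index]
    if len(set(feature_ids)) != len(feature_ids):
        dupes = sorted({f for f in feature_ids if feature_ids.count(f) > 1})
        raise ValueError(f"duplicate feature ids in {path}: {dupes}")
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        f, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative value in {path} at feature {feature_ids[f]!r}, "
            f"sample {df.columns[s]!r}"
        )
    meta = {m.sample_id: m for m in read_metadata(meta_path)}
    samples = []
    for sid in df.columns:
        if str(sid) not in meta:
            raise ValueError(f"no metadata for sample {str(sid)!r}")
        samples.append(meta[str(sid)])
    stage = "count" if np.allclose(values, np.round(values)) else "proportion"
    return AbundanceTable(
        feature_ids=feature_ids,
        samples=samples,
        values=values,
        kind=kind,
        stage=stage,
    )


def read_gene_map(path: str | os.PathLike) -> GeneAnnotationMap:
    """Read a gene map TSV with columns gene_id, term_id, species_id."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene_id", "term_id", "species_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene map {path} is missing columns: {sorted(missing)}")
    records = [
        (str(r.gene_id), str(r.term_id), str(r.species_id))
        for r in df.itertuples(index=False)
    ]
    return GeneAnnotationMap(records=records)


# ---------------------------------------------------------------------------
# Count preparation and biome aggregation
# ---------------------------------------------------------------------------


def prepare_counts(table: AbundanceTable) -> AbundanceTable:
    """Turn per-sample proportions into integer read counts.

    Each cell becomes round(proportion * read_depth), with half-away-from-zero
    rounding so the tie rule is unambiguous across platforms.  Tables already
    at the count stage pass through unchanged.
    """
    if table.stage == "count":
        return table
    depths = np.array([s.read_depth for s in table.samples], dtype=float)
    zero = [s.sample_id for s, d in zip(table.samples, depths) if d == 0]
    if zero:
        raise ValueError(f"read_depth is 0 for samples {zero}; cannot prepare counts")
    # values >= 0, so floor(x + 0.5) is round-half-away-from-zero
    counts = np.floor(table.values * depths[np.newaxis, :] + 0.5)
    return AbundanceTable(
        feature_ids=list(table.feature_ids),
        samples=list(table.samples),
        values=counts,
        kind=table.kind,
        stage="count",
    )


def aggregate_by_biome(table: AbundanceTable) -> BiomeCounts:
    """Sum prepared counts over the samples of each biome.

    Biome columns are ordered lexicographically so the result is invariant to
    sample order.
    """
    if table.stage != "count":
        raise ValueError(
            "aggregate_by_biome needs a count-stage table; run prepare_counts first"
        )
    biomes = table.biomes
    if not biomes:
        raise ValueError("no biome labels present")
    counts = np.zeros((len(table.feature_ids), len(biomes)), dtype=np.int64)
    bindex = {b: j for j, b in enumerate(biomes)}
    for col, s in enumerate(table.samples):
        counts[:, bindex[s.biome]] += table.values[:, col].astype(np.int64)
    return BiomeCounts(
        feature_ids=list(table.feature_ids), biomes=biomes, counts=counts
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _sanitize(obj):
    """Make an object JSON-safe: NaN -> null, numpy scalars -> python."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return _sanitize(obj.tolist())
    return obj


_RESULT_COLUMNS = (
    "feature_id",
    "biome",
    "k",
    "K",
    "n",
    "N",
    "p_value",
    "q_value",
    "fold",
    "enriched",
    "skipped",
)


def write_results(obj, path: str | os.PathLike) -> None:
    """Serialize pipeline outputs.

    Lists of enrichment results go to TSV; model/report objects exposing
    ``to_dict`` go to JSON with a ``schema_version`` field.  Floats are written
    with ``repr`` so a round-trip read reproduces the object exactly;
    undefined metrics (NaN) are serialized as null.
    """
    if isinstance(obj, (list, tuple)):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join(_RESULT_COLUMNS) + "\n")
            for r in obj:
                q = "" if r.q_value is None else repr(float(r.q_value))
                fh.write(
                    "\t".join(
                        [
                            r.feature_id,
                            r.biome,
                            str(r.k),
                            str(r.K),
                            str(r.n),
                            str(r.N),
                            repr(float(r.p_value)),
                            q,
                            repr(float(r.fold)),
                            str(int(r.enriched)),
                            str(int(r.skipped)),
                        ]
                    )
                    + "\n"
                )
        return
    if hasattr(obj, "to_dict"):
        payload = _sanitize(obj.to_dict())
        payload["schema_version"] = SCHEMA_VERSION
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    raise TypeError(f"do not know how to serialize {type(obj).__name__}")


def read_results_tsv(path: str | os.PathLike) -> list:
    """Read back an enrichment results TSV written by :func:`write_results`."""
    from enrichsphere.enrichment import EnrichmentResult

    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _RESULT_COLUMNS:
            raise ValueError(f"unexpected results header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                EnrichmentResult(
                    feature_id=f[0],
                    biome=f[1],
                    k=int(f[2]),
                    K=int(f[3]),
                    n=int(f[4]),
                    N=int(f[5]),
                    p_value=float(f[6]),
                    q_value=None if f[7] == "" else float(f[7]),
                    fold=float(f[8]),
                    enriched=bool(int(f[9])),
                    skipped=bool(int(f[10])),
                )
            )
    return out


def write_abundance_table(table: AbundanceTable, path: str | os.PathLike) -> None:
    """Write the feature x sample matrix as TSV (header = sample ids)."""
    df = table.to_dataframe()
    if table.stage == "count":
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="feature_id")


def write_metadata(samples: Sequence[SampleMeta], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tbiome\tread_depth\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.biome}\t{s.read_depth}\n")


def write_gene_map(gene_map: GeneAnnotationMap, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tterm_id\tspecies_id\n")
        for g, t, sp in gene_map.records:
            fh.write(f"{g}\t{t}\t{sp}\n")
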