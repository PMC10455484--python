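"""Cross-referencing P450s into secondary-metabolite biosynthetic gene
clusters (BGCs).

The module consumes simplified tabular cluster summaries (one row per member
gene: species, cluster index, cluster type, gene id, 1-based inclusive
coordinates, strand) such as can be exported from anti-SMASH spreadsheets, and
cross-references member genes against the assigned P450 name map.  Hybrid
cluster types are comma-joined tokens ("NRPS, T1PKS"); per-type tallies count
each token, totals count the cluster once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .config import round_half_away
from .fixtures import load_fixture


@dataclass(frozen=True)
class GeneSpan:
    gene_id: str
    start: int   # 1-based inclusive
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} must be < end "
                f"{self.end}")


@dataclass
class BgcCluster:
    species_id: str
    cluster_index: int
    cluster_type: str
    member_genes: list[GeneSpan] = field(default_factory=list)

    @property
    def type_tokens(self) -> list[str]:
        return [t.strip() for t in self.cluster_type.split(",") if t.strip()]


@dataclass(frozen=True)
class BgcXrefEntry:
    species_id: str
    cluster_index: int
    cluster_type: str
    p450_name: str
    gene_id: str


def parse_cluster_table(path) -> list[BgcCluster]:
    """Parse a cluster TSV into one BgcCluster per (species, cluster_index).

    Required columns: species_id, cluster_index, cluster_type, gene_id,
    start, end, strand.  Rows of one cluster must agree on cluster_type;
    conflicting duplicates raise.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"species_id", "cluster_index", "cluster_type",
                "gene_id", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cluster table missing columns: {sorted(missing)}")
    clusters: dict[tuple[str, int], BgcCluster] = {}
    for row in df.itertuples():
        key = (row.species_id, int(row.cluster_index))
        span = GeneSpan(str(row.gene_id), int(row.start), int(row.end),
                        str(row.strand))
        if key not in clusters:
            clusters[key] = BgcCluster(
                species_id=row.species_id,
                cluster_index=int(row.cluster_index),
                cluster_type=str(row.cluster_type),
                member_genes=[span],
            )
        else:
            existing = clusters[key]
            if existing.cluster_type != str(row.cluster_type):
                raise ValueError(
                    f"cluster {key}: duplicate cluster_index with "
                    f"conflicting types {existing.cluster_type!r} vs "
                    f"{row.cluster_type!r}")
            existing.member_genes.append(span)
    return [clusters[k] for k in sorted(clusters)]


def xref_p450s(clusters: Sequence[BgcCluster],
               p450_gene_map: Mapping[str, str]) -> list[BgcXrefEntry]:
    """One entry per cluster member gene that maps to an assigned P450 name.

    Unmatched genes are ignored.  Entries are ordered by (species,
    cluster_index, gene_id).
    """
    entries = [
        BgcXrefEntry(
            species_id=c.species_id,
            cluster_index=c.cluster_index,
            cluster_type=c.cluster_type,
            p450_name=p450_gene_map[g.gene_id],
            gene_id=g.gene_id,
        )
        for c in clusters
        for g in c.member_genes
        if g.gene_id in p450_gene_map
    ]
    entries.sort(key=lambda e: (e.species_id, e.cluster_index, e.gene_id))
    return entries


@dataclass
class BgcSummary:
    per_species: dict[str, int]
    per_type: dict[str, int]
    total: int
    mean_per_species: int
    p450_entry_count: int
    p450_in_type: dict[str, int]


def bgc_summary(clusters: Sequence[BgcCluster],
                xrefs: Sequence[BgcXrefEntry] = ()) -> BgcSummary:
    """Tally clusters per species and per type, plus P450 membership counts.

    Hybrid types contribute one count to each of their tokens in the per-type
    tallies but count once in the total and the per-species counts.
    """
    per_species = Counter(c.species_id for c in clusters)
    per_type: Counter = Counter()
    for c in clusters:
        per_type.update(c.type_tokens)
    p450_in_type: Counter = Counter()
    for e in xrefs:
        p450_in_type.update(
            t.strip() for t in e.cluster_type.split(",") if t.strip())
    total = len(clusters)
    mean = round_half_away(total / len(per_species)) if per_species else 0
    return BgcSummary(
        per_species=dict(per_species),
        per_type=dict(per_type),
        total=total,
        mean_per_species=mean,
        p450_entry_count=len(list(xrefs)),
        p450_in_type=dict(p450_in_type),
    )


def clusters_from_fixture() -> tuple[list[BgcCluster], list[BgcXrefEntry]]:
    """Reconstruct cluster objects from the packaged 12-species table.

    The published table records only per-species cluster counts plus the
    clusters that carry P450s, so clusters without a recorded type are typed
    ``unknown`` and member genes are synthesized placeholders; the P450
    member genes are planted so that cross-reference recovery can be run on
    the fixture.
    """
    counts = load_fixture("table7")
    p450s = load_fixture("table7_p450s")
    clusters: list[BgcCluster] = []
    gene_map: dict[str, str] = {}
    typed = {
        (r.species_id, int(r.cluster_index)): str(r.cluster_type)
        for r in p450s.itertuples()
    }
    for row in counts.itertuples():
        for idx in range(1, int(row.n_clusters) + 1):
            ctype = typed.get((row.species_id, idx), "unknown")
            start = 1 + (idx - 1) * 10_000
            genes = [GeneSpan(f"{row.species_id}_c{idx:02d}_g1",
                              start, start + 1_500)]
            clusters.append(BgcCluster(row.species_id, idx, ctype, genes))
    by_key = {(c.species_id, c.cluster_index): c for c in clusters}
    for n, r in enumerate(p450s.itertuples(), start=1):
        cluster = by_key[(r.species_id, int(r.cluster_index))]
        gene_id = f"{r.species_id}_c{int(r.cluster_index):02d}_p450_{n}"
        pos = 2_000 + 2_000 * n
        base = 1 + (cluster.cluster_index - 1) * 10_000
        cluster.member_genes.append(
            GeneSpan(gene_id, base + pos, base + pos + 1_500))
        gene_map[gene_id] = str(r.p450_name)
    return clusters, xref_p450s(clusters, gene_map)


def xref_report(xrefs: Sequence[BgcXrefEntry]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "species_id": e.species_id,
            "cluster_index": e.cluster_index,
            "cluster_type": e.cluster_type,
            "p450_name": e.p450_name,
            "gene_id": e.gene_id,
        }
        for e in xrefs
    ], columns=["species_id", "cluster_index", "cluster_type",
                "p450_name", "gene_id"])
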