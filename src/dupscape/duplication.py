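"""Duplication-mode classification of family genes.

Each family gene whose protein belongs to a paralog cluster of size >= 2 is
labelled by how its nearest paralogous copy sits in the genome:

* TANDEM — an immediate neighbour in the chromosome-wide gene order (all
  annotated genes, not just family members) is a same-cluster paralog;
* PROXIMAL — not flanked by a paralog, but the closest same-cluster paralog
  on the same chromosome lies within 100 kb (intergenic gap, inclusive);
* DISPERSED — the closest paralog is farther than 100 kb or on another
  chromosome (the typical footprint of transposon-mediated duplication).

Genes in size-1 clusters are SINGLETON.  Strand is ignored: tandem arrays
are usually co-oriented but the definition does not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

from .io import GeneRecord, sort_genes
from .paralogs import ParalogClusterSet
from .util import percent


class Mode(str, Enum):
    SINGLETON = "SINGLETON"
    TANDEM = "TANDEM"
    PROXIMAL = "PROXIMAL"
    DISPERSED = "DISPERSED"


MODES: tuple[Mode, ...] = tuple(Mode)


@dataclass(frozen=True)
class DuplicationCall:
    gene_id: str
    mode: Mode
    nearest_paralog_id: str | None = None
    nearest_paralog_distance: int | None = None  # bp intergenic gap


def intergenic_distance(gene_a: GeneRecord, gene_b: GeneRecord) -> int:
    """Gap in bp between the nearer boundaries of two same-chromosome genes.

    Overlapping or book-ended genes have distance 0.  With 1-based inclusive
    coordinates the gap between [.., e] and [s, ..] is s - e - 1.
    """
    if gene_a.chromosome_id != gene_b.chromosome_id:
        raise ValueError(
            f"{gene_a.gene_id} and {gene_b.gene_id} are on different chromosomes"
        )
    if gene_a.start > gene_b.start:
        gene_a, gene_b = gene_b, gene_a
    return max(0, gene_b.start - gene_a.end - 1)


def build_gene_order(
    records: Iterable[GeneRecord],
) -> dict[str, list[GeneRecord]]:
    """Coordinate-sorted gene lists per chromosome (ties: end, then id)."""
    order: dict[str, list[GeneRecord]] = {}
    for rec in sort_genes(records):
        order.setdefault(rec.chromosome_id, []).append(rec)
    return order


def classify_duplication(
    gene: GeneRecord,
    gene_order: Mapping[str, list[GeneRecord]],
    cluster_set: ParalogClusterSet,
    proximal_limit: int = 100_000,
    gene_to_member: Mapping[str, str] | None = None,
) -> DuplicationCall:
    """Classify one family gene's duplication mode.

    *gene_order* must contain ALL annotated genes per chromosome (flanking is
    judged against the full order).  The gene's cluster is looked up through
    *gene_to_member* (identity mapping by default).  Nearest-paralog fields
    are populated whenever a same-chromosome paralog exists.
    """
    member = (gene_to_member or {}).get(gene.gene_id, gene.gene_id)
    cluster = cluster_set.cluster_of(member)
    member_to_gene = (
        {m: g for g, m in gene_to_member.items()} if gene_to_member else None
    )
    paralog_gene_ids = {
        (member_to_gene[m] if member_to_gene else m) for m in cluster
    } - {gene.gene_id}

    chrom_genes = gene_order.get(gene.chromosome_id, [])
    try:
        pos = next(
            i for i, g in enumerate(chrom_genes) if g.gene_id == gene.gene_id
        )
    except StopIteration:
        raise KeyError(f"gene {gene.gene_id!r} absent from gene order") from None

    if not paralog_gene_ids:
        return DuplicationCall(gene.gene_id, Mode.SINGLETON)

    # nearest same-chromosome paralog by intergenic gap (ties: smaller id)
    same_chrom = [g for g in chrom_genes if g.gene_id in paralog_gene_ids]
    nearest_id = None
    nearest_dist = None
    for g in same_chrom:
        d = intergenic_distance(gene, g)
        if nearest_dist is None or (d, g.gene_id) < (nearest_dist, nearest_id):
            nearest_id, nearest_dist = g.gene_id, d

    flanks = []
    if pos > 0:
        flanks.append(chrom_genes[pos - 1])
    if pos + 1 < len(chrom_genes):
        flanks.append(chrom_genes[pos + 1])
    if any(f.gene_id in paralog_gene_ids for f in flanks):
        return DuplicationCall(gene.gene_id, Mode.TANDEM, nearest_id, nearest_dist)
    if nearest_dist is not None and nearest_dist <= proximal_limit:
        return DuplicationCall(gene.gene_id, Mode.PROXIMAL, nearest_id, nearest_dist)
    return DuplicationCall(gene.gene_id, Mode.DISPERSED, nearest_id, nearest_dist)


def classify_all(
    records: Iterable[GeneRecord],
    cluster_set: ParalogClusterSet,
    proximal_limit: int = 100_000,
    gene_to_member: Mapping[str, str] | None = None,
) -> list[DuplicationCall]:
    """Duplication calls for every family gene in *records*."""
    records = list(records)
    order = build_gene_order(records)
    return [
        classify_duplication(g, order, cluster_set, proximal_limit, gene_to_member)
        for g in sort_genes(records)
        if g.is_family
    ]


def summarize_duplication(
    calls: Iterable[DuplicationCall],
    gene_records: Iterable[GeneRecord],
) -> dict:
    """Per-chromosome mode counts plus genome-wide fractions.

    Returns a dict with ``counts`` (DataFrame chromosomes x modes with
    totals), ``fractions_pct`` (mode -> percent of family genes, 2 decimals,
    half away from zero) and ``tandem_proximal_share_pct`` (per-chromosome
    percentage of family genes that are tandem or proximal).
    """
    calls = list(calls)
    gene_chrom = {g.gene_id: g.chromosome_id for g in gene_records}
    rows = []
    for c in calls:
        chrom = gene_chrom.get(c.gene_id)
        if chrom is None:
            raise KeyError(f"call for unknown gene {c.gene_id!r}")
        rows.append({"chromosome_id": chrom, "mode": c.mode.value})
    total = len(calls)
    chroms = sorted({r["chromosome_id"] for r in rows})
    counts = pd.DataFrame(0, index=chroms, columns=[m.value for m in MODES], dtype=int)
    for r in rows:
        counts.loc[r["chromosome_id"], r["mode"]] += 1
    counts["Total"] = counts.sum(axis=1)
    counts.loc["Total"] = counts.sum(axis=0)

    fractions = {
        m.value: (percent(counts.loc["Total", m.value], total) if total else 0.0)
        for m in MODES
    }
    share = {}
    for chrom in chroms:
        chrom_total = counts.loc[chrom, "Total"]
        tp = counts.loc[chrom, Mode.TANDEM.value] + counts.loc[chrom, Mode.PROXIMAL.value]
        share[chrom] = percent(tp, chrom_total) if chrom_total else 0.0
    return {
        "counts": counts,
        "fractions_pct": fractions,
        "tandem_proximal_share_pct": share,
    }


def write_calls(calls: Iterable[DuplicationCall], path: str) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "mode": c.mode.value,
                "nearest_paralog_id": c.nearest_paralog_id or "",
                "distance_bp": "" if c.nearest_paralog_distance is None
                else c.nearest_paralog_distance,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
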