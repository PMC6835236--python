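"""Synthetic genomes and codon alignments with known duplication history.

The genome simulator plants a focal gene family on a small multi-chromosome
annotation through three duplication mechanisms — tandem arrays (adjacent
copies a few kb apart), proximal duplicates (within 100 kb but separated by
intervening background genes) and dispersed copies (far from every paralog,
mimicking transposon-mediated duplication) — with tunable per-copy sequence
divergence and a configurable fraction of fresh, zero-divergence copies.
Every emitted gene carries ground truth (cluster, duplication mode,
architecture category), so the whole pipeline can be validated without any
real assembly.

The alignment simulator evolves codon sequences along a random bifurcating
tree with per-site selection pressure (synonymous rate 1, nonsynonymous
rate omega), recording the true substitution history, and is the test bed
for the counting-based selection caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .architecture import Category
from .duplication import Mode
from .io import DomainHit, GeneRecord, write_fasta
from .selection import (
    STOP_CODONS,
    CodonAlignment,
    PhyloTree,
    SENSE_CODONS,
    TreeNode,
    translate_codon,
)

_NT = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_AA_CODONS: dict[str, list[str]] = {}
for codon in SENSE_CODONS:
    _AA_CODONS.setdefault(translate_codon(codon), []).append(codon)
_AA_LIST = sorted(_AA_CODONS)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate a compact family-expansion landscape: three 12-Mb
    chromosomes, 300 background genes, 12 tandem arrays of 3-15 copies, 20
    proximally duplicated genes (10 pairs), 15 dispersed copies seeded from
    tandem arrays, and 5% expected nucleotide divergence per copy relative
    to its event founder.  Introns evolve 3x faster than exons and may pick
    up short indels; with probability *near_identical_fraction* a new copy
    is emitted with zero coding divergence (only its intron drifts),
    mimicking very recent duplication events.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chromosome_lengths: Sequence[int] | None = None  # default 12 Mb each
    n_background_genes: int = 300
    n_tandem_arrays: int = 12
    array_size_min: int = 3
    array_size_max: int = 15
    n_proximal: int = 20  # proximal genes (must be even: placed as pairs)
    n_dispersed: int = 15  # dispersed copies, each seeded from an array
    n_singletons: int = 0
    divergence: float = 0.05  # expected substitutions/site per copy
    near_identical_fraction: float = 0.1
    intron_rate_multiplier: float = 3.0
    intron_indel_probability: float = 0.3
    protein_length: int = 200
    tandem_gap: tuple[int, int] = (1_000, 10_000)
    proximal_gap: tuple[int, int] = (30_000, 90_000)
    feature_noise: float = 0.0  # probability of dropping a signal-peptide row

    def resolved_chromosome_lengths(self) -> dict[str, int]:
        lengths = self.chromosome_lengths or [12_000_000] * self.n_chromosomes
        if len(lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths does not match n_chromosomes")
        return {f"chr{i + 1}": int(l) for i, l in enumerate(lengths)}

    def validate(self) -> None:
        if self.n_proximal % 2:
            raise ValueError("n_proximal must be even (placed as pairs)")
        if not 0 <= self.near_identical_fraction <= 1:
            raise ValueError("near_identical_fraction must be in [0, 1]")
        if self.divergence < 0:
            raise ValueError("divergence must be non-negative")
        if self.array_size_min < 2 or self.array_size_max < self.array_size_min:
            raise ValueError("bad array size range")
        if self.n_dispersed > self.n_tandem_arrays * 3:
            raise ValueError("too many dispersed copies for the available arrays")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every simulated genome."""

    table: pd.DataFrame  # gene_id, cluster_id, mode, category, parent_id, zero_divergence

    def cluster_of(self) -> dict[str, str]:
        return dict(zip(self.table.gene_id, self.table.cluster_id))

    def mode_of(self) -> dict[str, Mode]:
        return {g: Mode(m) for g, m in zip(self.table.gene_id, self.table["mode"])}

    def category_of(self) -> dict[str, Category]:
        return {
            g: Category(c) for g, c in zip(self.table.gene_id, self.table.category)
        }

    def write_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# templates and mutation
# ---------------------------------------------------------------------------


@dataclass
class _Template:
    category: Category
    protein: str
    cds: str  # coding sequence including the stop codon
    intron: str
    exon1_len: int  # nt of the CDS in exon 1
    feature_rows: list[dict]
    domain_rows: list[dict]  # domain_name, ali_start, ali_end


def _random_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(rng.choice(list(_AA_LIST), size=length - 1))
    return "M" + body


def _encode(rng: np.random.Generator, protein: str) -> str:
    codons = [rng.choice(_AA_CODONS[aa]) for aa in protein]
    return "".join(codons) + "TAA"


def _random_intron(rng: np.random.Generator) -> str:
    length = int(rng.integers(200, 800))
    body = "".join(rng.choice(list(_NT), size=length - 4))
    return "GT" + body + "AG"


def make_template(
    rng: np.random.Generator, category: Category, protein_length: int = 200
) -> _Template:
    """A family-protein template with feature layout matching *category*."""
    length = protein_length
    protein = _random_protein(rng, length)
    features: list[dict] = []
    domains: list[dict] = []

    def feat(ftype, start, end, score=1.0):
        features.append(
            {"feature_type": ftype, "start": start, "end": end, "score": score}
        )

    def dom(name, start, end):
        domains.append({"domain_name": name, "ali_start": start, "ali_end": end})

    if length < 80:
        raise ValueError("template proteins must be at least 80 aa")
    if category is not Category.OTHER_UNCERTAIN:
        feat("signal_peptide", 1, 19)
    # domain layouts scale with protein length
    if category is Category.SGH_C1Q:
        dom("C1q", 30, length - 10)
    elif category is Category.C1Q_LIKE_TYPE_II:
        coil_end = 30 + max(20, length // 5)
        feat("coiled_coil", 30, coil_end, 0.9)
        dom("C1q", coil_end + 20, length - 10)
    elif category is Category.SMULTI_C1Q:
        first_end = 30 + (length - 60) // 2
        dom("C1q", 30, first_end)
        dom("C1q", first_end + 10, length - 5)
    elif category is Category.SSUEL_C1Q:
        suel_end = 25 + (length - 70) // 2
        dom("SUEL", 25, suel_end)
        dom("C1q", suel_end + 20, length - 5)
    elif category is Category.C1Q_LIKE_TYPE_I:
        col_end = 25 + (length - 70) // 2
        dom("Collagen", 25, col_end)
        dom("C1q", col_end + 20, length - 5)
    else:  # OTHER_UNCERTAIN: a C1q hit but no signal peptide
        dom("C1q", 30, length - 10)

    cds = _encode(rng, protein)
    intron = _random_intron(rng)
    exon1_len = (len(cds) // 2) // 3 * 3  # split on a codon boundary
    return _Template(
        category=category,
        protein=protein,
        cds=cds,
        intron=intron,
        exon1_len=exon1_len,
        feature_rows=features,
        domain_rows=domains,
    )


def _mutate_base(rng: np.random.Generator, base: str) -> str:
    """Transition:transversion 2:1."""
    if rng.random() < 0.5:
        return _TRANSITION[base]
    choices = [n for n in _NT if n != base and n != _TRANSITION[base]]
    return choices[int(rng.integers(0, 2))]

def mutate_cds(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Point mutations at *rate* per site over the coding part; the stop
    codon is untouched and mutations creating internal stops are reverted."""
    if rate <= 0:
        return cds
    coding = list(cds[:-3])
    for i in range(len(coding)):
        if rng.random() < rate:
            old = coding[i]
            coding[i] = _mutate_base(rng, old)
            codon_start = (i // 3) * 3
            codon = "".join(coding[codon_start : codon_start + 3])
            if codon in STOP_CODONS:
                coding[i] = old
    return "".join(coding) + cds[-3:]


def mutate_intron(
    rng: np.random.Generator, intron: str, rate: float, indel_probability: float
) -> str:
    """Faster intron drift: substitutions plus occasional short indels
    (microsatellite-like), splice dinucleotides preserved."""
    body = list(intron[2:-2])
    for i in range(len(body)):
        if rng.random() < rate:
            body[i] = _mutate_base(rng, body[i])
    if body and rng.random() < indel_probability:
        size = int(rng.integers(1, 11))
        pos = int(rng.integers(0, len(body)))
        if rng.random() < 0.5:
            insert = "".join(rng.choice(list(_NT), size=size))
            body[pos:pos] = list(insert)
        else:
            del body[pos : pos + size]
    return "GT" + "".join(body) + "AG"


def _translate_cds(cds: str) -> str:
    codons = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
    return "".join(translate_codon(c) for c in codons)


# ---------------------------------------------------------------------------
# genome assembly from event blocks
# ---------------------------------------------------------------------------


@dataclass
class _FamilyGene:
    gene_id: str
    cluster_id: str
    mode: Mode
    category: Category
    cds: str
    intron: str
    exon1_len: int
    template: _Template
    parent_id: str
    zero_divergence: bool
    strand: str

    @property
    def protein(self) -> str:
        return _translate_cds(self.cds)

    @property
    def genomic_length(self) -> int:
        return len(self.cds) + len(self.intron)


@dataclass
class SimulatedGenome:
    """In-memory result of :func:`simulate_genome`; writable to disk in the
    same formats the pipeline consumes."""

    config: SimulationConfig
    chromosome_lengths: dict[str, int]
    genes: list[GeneRecord]
    proteins: dict[str, str]
    cds: dict[str, str]
    features: pd.DataFrame  # protein_id, feature_type, start, end, score
    domain_hits: list[DomainHit]
    truth: SyntheticTruth
    _gene_meta: dict[str, _FamilyGene] = field(default_factory=dict, repr=False)

    @property
    def family_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes if g.is_family]

    def gff3_text(self) -> str:
        lines = ["##gff-version 3"]
        for chrom, length in sorted(self.chromosome_lengths.items()):
            lines.append(f"##sequence-region {chrom} 1 {length}")
        for g in self.genes:
            attrs = f"ID={g.gene_id}"
            lines.append(
                "\t".join(
                    [
                        g.chromosome_id,
                        "dupscape_sim",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
            )
            rna_id = f"{g.gene_id}.t1"
            lines.append(
                "\t".join(
                    [
                        g.chromosome_id,
                        "dupscape_sim",
                        "mRNA",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={rna_id};Parent={g.gene_id}",
                    ]
                )
            )
            meta = self._gene_meta.get(g.gene_id)
            if meta is None:
                exons = [(g.start, g.end)]
            else:
                e1 = meta.exon1_len
                exons = [
                    (g.start, g.start + e1 - 1),
                    (g.start + e1 + len(meta.intron), g.end),
                ]
            for k, (s, e) in enumerate(exons, start=1):
                lines.append(
                    "\t".join(
                        [
                            g.chromosome_id,
                            "dupscape_sim",
                            "exon",
                            str(s),
                            str(e),
                            ".",
                            g.strand,
                            ".",
                            f"ID={rna_id}.exon{k};Parent={rna_id}",
                        ]
                    )
                )
        return "\n".join(lines) + "\n"

    def write(self, outdir: str) -> dict[str, str]:
        """Write genome.gff3, proteins.faa, cds.fna, features.tsv,
        domains.tsv, family_ids.txt and truth.tsv; returns the path map."""
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {
            "gff3": os.path.join(outdir, "genome.gff3"),
            "proteins": os.path.join(outdir, "proteins.faa"),
            "cds": os.path.join(outdir, "cds.fna"),
            "features": os.path.join(outdir, "features.tsv"),
            "domains": os.path.join(outdir, "domains.tsv"),
            "family_ids": os.path.join(outdir, "family_ids.txt"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        with open(paths["gff3"], "w") as fh:
            fh.write(self.gff3_text())
        write_fasta(self.proteins, paths["proteins"])
        write_fasta(self.cds, paths["cds"])
        self.features.to_csv(paths["features"], sep="\t", index=False)
        with open(paths["domains"], "w") as fh:
            for h in self.domain_hits:
                fh.write(
                    f"{h.protein_id}\t{h.domain_name}\t{h.ali_start}\t"
                    f"{h.ali_end}\t{h.e_value}\t{h.model_coverage}\n"
                )
        with open(paths["family_ids"], "w") as fh:
            fh.write("\n".join(self.family_ids) + "\n")
        self.truth.write_tsv(paths["truth"])
        return paths


_ARRAY_CATEGORIES = [
    Category.C1Q_LIKE_TYPE_II,
    Category.SGH_C1Q,
    Category.C1Q_LIKE_TYPE_II,
    Category.SMULTI_C1Q,
    Category.SSUEL_C1Q,
]


def simulate_genome(config: SimulationConfig | None = None) -> SimulatedGenome:
    """Generate a synthetic annotated genome with planted duplication truth.

    Deterministic under ``config.seed``.  Raises if the requested genes do
    not fit on the configured chromosomes or if background genes cannot
    separate all event blocks (at least one is required between blocks so
    that tandem flanking never leaks across events).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_lengths = config.resolved_chromosome_lengths()
    chroms = list(chrom_lengths)

    fam_counter = iter(range(1, 100_000))
    events: list[dict] = []  # each: {"kind", "genes": [_FamilyGene, ...]}
    cluster_counter = iter(range(1, 10_000))

    def new_copy(
        template: _Template,
        founder: _FamilyGene | None,
        cluster_id: str,
        mode: Mode,
        strand: str,
    ) -> _FamilyGene:
        gid = f"fam{next(fam_counter):04d}"
        if founder is None:
            cds, intron, zero = template.cds, template.intron, False
        else:
            zero = rng.random() < config.near_identical_fraction
            rate = 0.0 if zero else config.divergence
            cds = mutate_cds(rng, founder.cds, rate)
            intron = mutate_intron(
                rng,
                founder.intron,
                config.divergence * config.intron_rate_multiplier,
                config.intron_indel_probability,
            )
        return _FamilyGene(
            gene_id=gid,
            cluster_id=cluster_id,
            mode=mode,
            category=template.category,
            cds=cds,
            intron=intron,
            exon1_len=template.exon1_len,
            template=template,
            parent_id=founder.gene_id if founder else "",
            zero_divergence=zero,
            strand=strand,
        )

    # tandem arrays
    arrays: list[dict] = []
    for a in range(config.n_tandem_arrays):
        category = _ARRAY_CATEGORIES[a % len(_ARRAY_CATEGORIES)]
        template = make_template(rng, category, config.protein_length)
        cluster_id = f"cluster{next(cluster_counter):03d}"
        strand = "+" if rng.random() < 0.8 else "-"
        size = int(rng.integers(config.array_size_min, config.array_size_max + 1))
        founder = new_copy(template, None, cluster_id, Mode.TANDEM, strand)
        members = [founder] + [
            new_copy(template, founder, cluster_id, Mode.TANDEM, strand)
            for _ in range(size - 1)
        ]
        event = {"kind": "array", "genes": members}
        arrays.append(event)
        events.append(event)

    # proximal pairs
    for _ in range(config.n_proximal // 2):
        category = (
            Category.C1Q_LIKE_TYPE_II if rng.random() < 0.6 else Category.SGH_C1Q
        )
        template = make_template(rng, category, config.protein_length)
        cluster_id = f"cluster{next(cluster_counter):03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        founder = new_copy(template, None, cluster_id, Mode.PROXIMAL, strand)
        copy = new_copy(template, founder, cluster_id, Mode.PROXIMAL, strand)
        events.append({"kind": "proximal", "genes": [founder, copy]})

    # dispersed copies, each seeded from a distinct-ish tandem array
    for k in range(config.n_dispersed):
        src = arrays[k % len(arrays)]
        founder = src["genes"][0]
        copy = new_copy(
            founder.template,
            founder,
            founder.cluster_id,
            Mode.DISPERSED,
            "+" if rng.random() < 0.5 else "-",
        )
        events.append({"kind": "dispersed", "genes": [copy]})

    # singletons: unrelated templates, no paralog above threshold
    for _ in range(config.n_singletons):
        template = make_template(rng, Category.SGH_C1Q, config.protein_length)
        cluster_id = f"cluster{next(cluster_counter):03d}"
        gene = new_copy(template, None, cluster_id, Mode.SINGLETON, "+")
        events.append({"kind": "singleton", "genes": [gene]})

    # shuffle events, deal them across chromosomes
    order = rng.permutation(len(events))
    per_chrom: dict[str, list[dict]] = {c: [] for c in chroms}
    for pos, idx in enumerate(order):
        per_chrom[chroms[pos % len(chroms)]].append(events[idx])

    # background-gene budget: intervening genes inside proximal blocks are
    # drawn on the fly; spacers between blocks share the remaining budget
    n_spacers = sum(len(blocks) for blocks in per_chrom.values())
    intervening_total = 0
    for ev in events:
        if ev["kind"] == "proximal":
            ev["n_intervening"] = int(rng.integers(1, 4))
            intervening_total += ev["n_intervening"]
    remaining_bg = config.n_background_genes - intervening_total
    if remaining_bg < n_spacers:
        raise ValueError(
            "n_background_genes too small to separate all event blocks"
        )
    spacer_fill = [remaining_bg // n_spacers] * n_spacers
    for i in range(remaining_bg - sum(spacer_fill)):
        spacer_fill[i] += 1
    spacer_iter = iter(spacer_fill)

    bg_counter = iter(range(1, 100_000))
    gene_records: list[GeneRecord] = []
    meta: dict[str, _FamilyGene] = {}

    def bg_len() -> int:
        return int(rng.integers(2_000, 6_000))

    def place_bg(chrom: str, start: int, length: int | None = None) -> GeneRecord:
        gid = f"bg{next(bg_counter):04d}"
        end = start + (length or bg_len()) - 1
        rec = GeneRecord(gid, chrom, start, end, "+" if rng.random() < 0.5 else "-")
        gene_records.append(rec)
        return rec

    def place_family(gene: _FamilyGene, chrom: str, start: int) -> GeneRecord:
        end = start + gene.genomic_length - 1
        rec = GeneRecord(gene.gene_id, chrom, start, end, gene.strand, is_family=True)
        gene_records.append(rec)
        meta[gene.gene_id] = gene
        return rec

    for chrom in chroms:
        cursor = 50_001
        for block in per_chrom[chrom]:
            # leading spacer: half gap, background genes, half gap
            n_fill = next(spacer_iter)
            cursor += 55_000
            for _ in range(n_fill):
                rec = place_bg(chrom, cursor)
                cursor = rec.end + 1 + 10_000
            cursor += 55_000

            genes = block["genes"]
            if block["kind"] == "array":
                for i, g in enumerate(genes):
                    rec = place_family(g, chrom, cursor)
                    gap = int(rng.integers(*config.tandem_gap))
                    cursor = rec.end + 1 + gap
            elif block["kind"] == "proximal":
                founder, copy = genes
                rec_a = place_family(founder, chrom, cursor)
                total_gap = int(rng.integers(*config.proximal_gap))
                k = block["n_intervening"]
                # short intervening background genes, evenly spread in the gap
                step = total_gap // (k + 1)
                for i in range(1, k + 1):
                    place_bg(chrom, rec_a.end + 1 + i * step, length=2_000)
                rec_b = place_family(copy, chrom, rec_a.end + 1 + total_gap)
                cursor = rec_b.end + 1
            else:  # dispersed or singleton
                rec = place_family(genes[0], chrom, cursor)
                cursor = rec.end + 1
        if cursor > chrom_lengths[chrom] - 50_000:
            raise ValueError(
                f"requested genes exceed placeable space on {chrom} "
                f"(needed {cursor} bp of {chrom_lengths[chrom]})"
            )

    # emit per-protein artifacts
    proteins: dict[str, str] = {}
    cds_out: dict[str, str] = {}
    feature_rows: list[dict] = []
    domain_hits: list[DomainHit] = []
    truth_rows: list[dict] = []
    for rec in sorted(gene_records, key=lambda r: (r.chromosome_id, r.start)):
        g = meta.get(rec.gene_id)
        if g is None:
            continue
        proteins[g.gene_id] = g.protein
        cds_out[g.gene_id] = g.cds
        dropped_signal = rng.random() < config.feature_noise
        for row in g.template.feature_rows:
            if dropped_signal and row["feature_type"] == "signal_peptide":
                continue
            feature_rows.append({"protein_id": g.gene_id, **row})
        for row in g.template.domain_rows:
            domain_hits.append(
                DomainHit(
                    protein_id=g.gene_id,
                    domain_name=row["domain_name"],
                    ali_start=row["ali_start"],
                    ali_end=row["ali_end"],
                    e_value=1e-10,
                    model_coverage=1.0,
                )
            )
        truth_rows.append(
            {
                "gene_id": g.gene_id,
                "cluster_id": g.cluster_id,
                "mode": g.mode.value,
                "category": g.category.value,
                "parent_id": g.parent_id,
                "zero_divergence": g.zero_divergence,
            }
        )

    features = pd.DataFrame(
        feature_rows, columns=["protein_id", "feature_type", "start", "end", "score"]
    )
    truth = SyntheticTruth(
        pd.DataFrame(
            truth_rows,
            columns=[
                "gene_id",
                "cluster_id",
                "mode",
                "category",
                "parent_id",
                "zero_divergence",
            ],
        )
    )
    from .io import sort_genes

    return SimulatedGenome(
        config=config,
        chromosome_lengths=chrom_lengths,
        genes=sort_genes(gene_records),
        proteins=proteins,
        cds=cds_out,
        features=features,
        domain_hits=domain_hits,
        truth=truth,
        _gene_meta=meta,
    )


# ---------------------------------------------------------------------------
# codon-alignment simulation with per-site selection pressure
# ---------------------------------------------------------------------------


@dataclass
class SelectionTruth:
    omega: dict[int, float]  # 1-based site -> omega
    true_syn: dict[int, int]  # substitution events in the true history
    true_nonsyn: dict[int, int]

    def omega_class(self, site: int) -> str:
        w = self.omega[site]
        return "POSITIVE" if w > 1 else "NEGATIVE" if w < 1 else "NEUTRAL"


def _random_topology(rng: np.random.Generator, n_seqs: int) -> PhyloTree:
    nodes: list[TreeNode] = [TreeNode(f"seq{i + 1:02d}") for i in range(n_seqs)]
    counter = 1
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode(f"anc{counter}", [(a, 0.0), (b, 0.0)])
        counter += 1
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    return PhyloTree(nodes[0])


def _scale_to_depth(tree: PhyloTree, rng: np.random.Generator, depth: float) -> None:
    """Exponential branch lengths rescaled so the mean root-to-tip path
    equals *depth* (expected neutral substitutions per site)."""
    for node in tree.postorder():
        node.children = [
            (child, float(rng.exponential(1.0)) + 1e-3)
            for child, _ in node.children
        ]
    paths: list[float] = []

    def walk(node: TreeNode, acc: float):
        if node.is_leaf:
            paths.append(acc)
        for child, length in node.children:
            walk(child, acc + length)

    walk(tree.root, 0.0)
    mean_path = sum(paths) / len(paths)
    factor = depth / mean_path if mean_path > 0 else 0.0
    for node in tree.postorder():
        node.children = [(c, l * factor) for c, l in node.children]


def simulate_selection_alignment(
    n_seqs: int = 20,
    n_sites: int = 200,
    tree_depth: float = 1.0,
    omega_map: Mapping[int, float] | None = None,
    seed: int = 0,
) -> tuple[CodonAlignment, PhyloTree, SelectionTruth]:
    """Evolve codons along a random bifurcating tree under per-site omega.

    Per site, each viable single-nucleotide change has base rate 1/9
    (so the total neutral rate is ~1 per unit branch length), multiplied by
    the site's omega when nonsynonymous; stop codons are unreachable.
    *omega_map* maps 1-based sites to omega (default 1 everywhere).  The
    true substitution history is recorded per site.  Deterministic under
    *seed*; ``tree_depth`` is the mean root-to-tip length in expected
    neutral substitutions per site.
    """
    if n_seqs < 3:
        raise ValueError("need at least 3 sequences")
    rng = np.random.default_rng(seed)
    omega = {s: 1.0 for s in range(1, n_sites + 1)}
    for s, w in (omega_map or {}).items():
        if not 1 <= s <= n_sites:
            raise ValueError(f"omega_map site {s} outside 1..{n_sites}")
        if w < 0:
            raise ValueError("omega must be non-negative")
        omega[s] = float(w)

    tree = _random_topology(rng, n_seqs)
    _scale_to_depth(tree, rng, tree_depth)

    root_codons = [str(rng.choice(SENSE_CODONS)) for _ in range(n_sites)]
    truth = SelectionTruth(
        omega=omega,
        true_syn={s: 0 for s in range(1, n_sites + 1)},
        true_nonsyn={s: 0 for s in range(1, n_sites + 1)},
    )

    def evolve_codon(codon: str, t: float, w: float, site: int) -> str:
        remaining = t
        while True:
            neighbors = []
            rates = []
            aa = translate_codon(codon)
            for pos in range(3):
                for nt in _NT:
                    if nt == codon[pos]:
                        continue
                    mutant = codon[:pos] + nt + codon[pos + 1 :]
                    if mutant in STOP_CODONS:
                        continue
                    syn = translate_codon(mutant) == aa
                    neighbors.append((mutant, syn))
                    rates.append((1.0 if syn else w) / 9.0)
            total = sum(rates)
            if total <= 0:
                return codon
            wait = rng.exponential(1.0 / total)
            if wait > remaining:
                return codon
            remaining -= wait
            probs = np.array(rates) / total
            choice = int(rng.choice(len(neighbors), p=probs))
            codon, syn = neighbors[choice]
            if syn:
                truth.true_syn[site] += 1
            else:
                truth.true_nonsyn[site] += 1

    sequences: dict[str, list[str]] = {}

    def descend(node: TreeNode, codons: list[str]):
        if node.is_leaf:
            sequences[node.name] = codons
        for child, length in node.children:
            child_codons = [
                evolve_codon(c, length, omega[s + 1], s + 1)
                for s, c in enumerate(codons)
            ]
            descend(child, child_codons)

    descend(tree.root, root_codons)
    ids = sorted(sequences)
    aln = CodonAlignment(ids=ids, rows={i: "".join(sequences[i]) for i in ids})
    return aln, tree, truth
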