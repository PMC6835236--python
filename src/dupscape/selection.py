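"""Counting-based per-site selection analysis of paralog codon alignments.

The caller is a SLAC-style counting method: a neighbor-joining guide tree is
built from the codon alignment, ancestral codons are reconstructed by Fitch
parsimony, synonymous and nonsynonymous substitutions are counted per branch
and site by averaging over the minimal mutational paths between parent and
child codons (paths through stop codons excluded), and the observed
synonymous count at each site is compared with the expectation from the
potential-synonymous-site content of the codons observed there, using a
two-sided binomial test.  Sites with a significant nonsynonymous excess are
called POSITIVE (diversifying selection), significant synonymous excess
NEGATIVE (purifying), otherwise NEUTRAL.

Likelihood-based site methods are not re-implemented; their per-site hit
lists can be merged with the internal caller through
:func:`consensus_support` (a site found by >= 2 methods is STRONG, by
exactly one MODERATE).
"""

from __future__ import annotations

import itertools
import math
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from scipy.special import betainc

_TABLE = unambiguous_dna_by_id[1]  # the standard genetic code
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_NT = "ACGT"
GAP_CODON = "---"


def translate_codon(codon: str) -> str:
    """One-letter amino acid, or '*' for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


class TreeNode:
    """A rooted tree node; children stored as (child, branch_length) pairs."""

    __slots__ = ("name", "children")

    def __init__(self, name: str, children: list[tuple["TreeNode", float]] | None = None):
        self.name = name
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """A rooted representation of an (conceptually unrooted) tree with
    non-negative branch lengths; leaf names label alignment rows."""

    root: TreeNode

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode):
            for child, _ in node.children:
                walk(child)
            out.append(node)

        walk(self.root)
        return out

    def leaves(self) -> list[str]:
        return [n.name for n in self.postorder() if n.is_leaf]

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for node in self.postorder():
            for child, length in node.children:
                out.append((node.name, child.name, length))
        return out

    def total_length(self) -> float:
        return sum(length for _, _, length in self.edges())

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{fmt(child)}:{length:.6f}" for child, length in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"


def nj_tree(distance_matrix: pd.DataFrame) -> PhyloTree:
    """Neighbor-joining tree from a symmetric distance matrix.

    Agglomeration order is fully deterministic: when several pairs tie on
    the Q criterion the pair with the smallest (row, column) index in the
    current node ordering is joined.  Negative limb lengths are clamped to
    zero.  For fewer than three taxa a trivial tree is returned with a
    warning.
    """
    ids = list(distance_matrix.index)
    d = {
        (a, b): float(distance_matrix.loc[a, b]) for a in ids for b in ids if a != b
    }
    n = len(ids)
    counter = itertools.count(1)

    nodes: dict[str, TreeNode] = {i: TreeNode(i) for i in ids}
    if n == 0:
        raise ValueError("empty distance matrix")
    if n == 1:
        warnings.warn("single taxon: trivial tree", stacklevel=2)
        return PhyloTree(nodes[ids[0]])
    if n == 2:
        warnings.warn("two taxa: trivial cherry", stacklevel=2)
        half = d[(ids[0], ids[1])] / 2
        root = TreeNode(f"node{next(counter)}")
        root.children = [(nodes[ids[0]], half), (nodes[ids[1]], half)]
        return PhyloTree(root)

    active = list(ids)
    while len(active) > 3:
        m = len(active)
        totals = {i: sum(d[(i, j)] for j in active if j != i) for i in active}
        best = None
        best_pair = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d[(i, j)] - totals[i] - totals[j]
                if best is None or q < best - 1e-12:
                    best, best_pair = q, (i, j)
        i, j = best_pair
        dij = d[(i, j)]
        limb_i = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        limb_j = dij - limb_i
        new_name = f"node{next(counter)}"
        new_node = TreeNode(
            new_name,
            [(nodes[i], max(0.0, limb_i)), (nodes[j], max(0.0, limb_j))],
        )
        nodes[new_name] = new_node
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[(i, k)] + d[(j, k)] - dij)
            d[(new_name, k)] = d[(k, new_name)] = max(0.0, dk)
        active = [k for k in active if k not in (i, j)] + [new_name]

    i, j, k = active
    li = 0.5 * (d[(i, j)] + d[(i, k)] - d[(j, k)])
    lj = 0.5 * (d[(i, j)] + d[(j, k)] - d[(i, k)])
    lk = 0.5 * (d[(i, k)] + d[(j, k)] - d[(i, j)])
    root = TreeNode(
        f"node{next(counter)}",
        [
            (nodes[i], max(0.0, li)),
            (nodes[j], max(0.0, lj)),
            (nodes[k], max(0.0, lk)),
        ],
    )
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Aligned coding sequences; rows are nucleotide strings whose length is
    a multiple of three, gaps appear as whole gap triplets."""

    ids: list[str]
    rows: dict[str, str]
    trimmed: bool = False
    #: original codon-column index (1-based) of each retained column
    provenance: list[int] | None = None

    def __post_init__(self):
        lengths = {len(self.rows[i]) for i in self.ids}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        (length,) = lengths
        if length % 3:
            raise ValueError("alignment length not divisible by 3")

    @property
    def n_sites(self) -> int:
        return len(self.rows[self.ids[0]]) // 3

    def codon(self, seq_id: str, site: int) -> str:
        """Codon at 0-based *site* for one row."""
        return self.rows[seq_id][3 * site : 3 * site + 3]

    def column(self, site: int) -> list[str]:
        return [self.codon(i, site) for i in self.ids]


def backtranslate_alignment(
    protein_msa: Mapping[str, str], cds_set: Mapping[str, str] | "object"
) -> CodonAlignment:
    """Thread each CDS onto its aligned protein, codon by codon.

    Every aligned residue becomes its codon, every gap a gap triplet.  The
    CDS (with any trailing stop codon ignored) must translate exactly to the
    ungapped protein; the first discordant codon is reported on mismatch.
    """
    cds_map = getattr(cds_set, "sequences", cds_set)
    rows: dict[str, str] = {}
    ids = list(protein_msa)
    for sid in ids:
        aligned = protein_msa[sid].upper()
        protein = aligned.replace("-", "")
        cds = cds_map[sid].upper()
        if len(cds) % 3:
            raise ValueError(f"{sid}: CDS length {len(cds)} not divisible by 3")
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        if len(codons) != len(protein):
            raise ValueError(
                f"{sid}: CDS encodes {len(codons)} aa but protein has "
                f"{len(protein)}"
            )
        for pos, (codon, aa) in enumerate(zip(codons, protein), start=1):
            if translate_codon(codon) != aa:
                raise ValueError(
                    f"{sid}: codon {codon} at position {pos} translates to "
                    f"{translate_codon(codon)}, protein has {aa}"
                )
        it = iter(codons)
        rows[sid] = "".join(
            next(it) if aa != "-" else GAP_CODON for aa in aligned
        )
    return CodonAlignment(ids=ids, rows=rows)


def trim_alignment(
    codon_aln: CodonAlignment, region: tuple[int, int] | None = None
) -> CodonAlignment:
    """Keep only gap-free codon columns, optionally inside *region*.

    *region* is a (start, end) pair of 1-based codon-column indices (e.g.,
    the span of the globular domain in alignment coordinates).  The
    provenance map records each retained column's original index so site
    positions remain reportable.
    """
    n = codon_aln.n_sites
    lo, hi = region if region is not None else (1, n)
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"region {region} outside alignment of {n} columns")
    keep = [
        site
        for site in range(n)
        if lo <= site + 1 <= hi
        and all(c != GAP_CODON for c in codon_aln.column(site))
    ]
    if not keep:
        raise ValueError("no analyzable sites after trimming")
    rows = {
        sid: "".join(codon_aln.codon(sid, s) for s in keep) for sid in codon_aln.ids
    }
    base = codon_aln.provenance or list(range(1, n + 1))
    return CodonAlignment(
        ids=list(codon_aln.ids),
        rows=rows,
        trimmed=True,
        provenance=[base[s] for s in keep],
    )


def jc_distance_matrix(codon_aln: CodonAlignment) -> pd.DataFrame:
    """Nucleotide p-distance with Jukes-Cantor correction over the codon
    alignment (gap positions in either row skipped; saturated pairs capped)."""
    ids = codon_aln.ids
    n = len(ids)
    mat = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = codon_aln.rows[ids[a]], codon_aln.rows[ids[b]]
            pairs = [
                (x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"
            ]
            if not pairs:
                dist = 0.0
            else:
                p = sum(x != y for x, y in pairs) / len(pairs)
                p = min(p, 0.749)
                dist = -0.75 * math.log(1 - 4 * p / 3)
            mat[a, b] = mat[b, a] = dist
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# ancestral reconstruction (Fitch parsimony over codon states)
# ---------------------------------------------------------------------------


def _nt_diff(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def ancestral_codons(
    tree: PhyloTree, codon_aln: CodonAlignment
) -> dict[str, list[str]]:
    """Fitch parsimony codon states at every node, per alignment column.

    Ties in the final assignment are broken by preferring the state with the
    fewest nucleotide differences from the candidate states below/above it,
    then by lexicographic codon order, so reconstruction is deterministic.
    Returns node name -> list of codons (leaves included, echoing their
    observed states).
    """
    leaf_set = set(tree.leaves())
    if leaf_set != set(codon_aln.ids):
        raise ValueError("tree leaves do not match alignment ids")

    states: dict[str, list[str]] = {
        node.name: [] for node in tree.postorder()
    }
    post = tree.postorder()
    for site in range(codon_aln.n_sites):
        fitch_set: dict[str, frozenset[str]] = {}
        for node in post:
            if node.is_leaf:
                fitch_set[node.name] = frozenset([codon_aln.codon(node.name, site)])
            else:
                child_sets = [fitch_set[c.name] for c, _ in node.children]
                inter = frozenset.intersection(*child_sets)
                fitch_set[node.name] = inter if inter else frozenset.union(*child_sets)

        assigned: dict[str, str] = {}

        def assign(node: TreeNode, parent_state: str | None):
            cands = sorted(fitch_set[node.name])
            if node.is_leaf:
                assigned[node.name] = cands[0]
            elif parent_state is not None and parent_state in fitch_set[node.name]:
                assigned[node.name] = parent_state
            elif parent_state is not None:
                assigned[node.name] = min(
                    cands, key=lambda s: (_nt_diff(s, parent_state), s)
                )
            else:  # root: closest to the child candidate sets
                def root_cost(s: str) -> int:
                    return sum(
                        min(_nt_diff(s, t) for t in fitch_set[c.name])
                        for c, _ in node.children
                    )

                assigned[node.name] = min(cands, key=lambda s: (root_cost(s), s))
            for child, _ in node.children:
                assign(child, assigned[node.name])

        assign(tree.root, None)
        for name, state in assigned.items():
            states[name].append(state)
    return states


def parsimony_score(tree: PhyloTree, codon_aln: CodonAlignment, site: int) -> int:
    """Fitch union count (minimum number of codon changes) for one column."""
    post = tree.postorder()
    fitch_set: dict[str, frozenset[str]] = {}
    score = 0
    for node in post:
        if node.is_leaf:
            fitch_set[node.name] = frozenset([codon_aln.codon(node.name, site)])
        else:
            sets = [fitch_set[c.name] for c, _ in node.children]
            current = sets[0]
            for s in sets[1:]:
                inter = current & s
                if inter:
                    current = inter
                else:
                    current = current | s
                    score += 1
            fitch_set[node.name] = current
    return score


# ---------------------------------------------------------------------------
# substitution counting and the per-site binomial test
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def synonymous_site_fraction(codon: str, position: int) -> float:
    """Fraction of viable single-nucleotide changes at one codon position
    that are synonymous (stop-codon mutants excluded from the denominator)."""
    if codon in STOP_CODONS:
        raise ValueError("stop codon has no synonymous-site content")
    aa = translate_codon(codon)
    syn = valid = 0
    for nt in _NT:
        if nt == codon[position]:
            continue
        mutant = codon[:position] + nt + codon[position + 1 :]
        if mutant in STOP_CODONS:
            continue
        valid += 1
        if translate_codon(mutant) == aa:
            syn += 1
    return syn / valid if valid else 0.0


@lru_cache(maxsize=None)
def potential_synonymous_sites(codon: str) -> float:
    """Synonymous-site content of a codon, in [0, 3]."""
    return sum(synonymous_site_fraction(codon, pos) for pos in range(3))


@lru_cache(maxsize=None)
def _path_counts(parent: str, child: str) -> tuple[float, float, bool]:
    """Average (synonymous, nonsynonymous) step counts over all minimal
    mutational paths from *parent* to *child* that avoid stop codons.

    Returns (syn, nonsyn, all_paths_blocked).  When every minimal path
    passes through a stop codon the pair contributes nonsynonymous-only
    minimal counts (0, d) and the flag is set.
    """
    diff = [i for i in range(3) if parent[i] != child[i]]
    if not diff:
        return 0.0, 0.0, False
    totals = []
    for order in itertools.permutations(diff):
        current = parent
        syn = nonsyn = 0
        ok = True
        for step, pos in enumerate(order):
            nxt = current[:pos] + child[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and step < len(order) - 1:
                ok = False
                break
            if nxt in STOP_CODONS:  # child itself is a stop: invalid path
                ok = False
                break
            if translate_codon(nxt) == translate_codon(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if ok:
            totals.append((syn, nonsyn))
    if not totals:
        return 0.0, float(len(diff)), True
    mean_syn = sum(t[0] for t in totals) / len(totals)
    mean_nonsyn = sum(t[1] for t in totals) / len(totals)
    return mean_syn, mean_nonsyn, False


def _binom_cdf(k: float, n: float, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p), continuously extended to fractional
    k and n through the regularized incomplete beta function."""
    if k >= n:
        return 1.0
    if k < 0:
        return 0.0
    if p <= 0:
        return 1.0
    if p >= 1:
        return 0.0
    return float(betainc(n - k, k + 1, 1 - p))


def _binom_sf(k: float, n: float, p: float) -> float:
    """P(X >= k), continuously extended."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if p <= 0:
        return 0.0
    if p >= 1:
        return 1.0
    return float(betainc(k, n - k + 1, p))


class SelectionClass(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    NEUTRAL = "NEUTRAL"


class Support(str, Enum):
    STRONG = "STRONG"
    MODERATE = "MODERATE"
    NONE = "NONE"


@dataclass
class SiteSelectionCall:
    site_index: int  # 1-based codon position in the trimmed alignment
    observed_syn: float
    observed_nonsyn: float
    expected_syn_fraction: float
    p_value: float
    selection_class: SelectionClass
    support: Support = Support.NONE


def site_selection(
    tree: PhyloTree,
    codon_aln: CodonAlignment,
    alpha: float = 0.05,
    ancestors: dict[str, list[str]] | None = None,
    bh_correction: bool = False,
) -> list[SiteSelectionCall]:
    """Per-site synonymous/nonsynonymous counting test.

    For every branch and site, substitutions between the (reconstructed)
    parent codon and child codon are counted by minimal-path averaging.  The
    expected synonymous fraction at a site is the mean potential-synonymous
    site content of the codons observed there (leaf rows), divided by 3.
    A two-sided binomial test compares the observed synonymous count with
    that expectation; significance at *alpha* plus a nonsynonymous excess
    gives POSITIVE, a synonymous excess NEGATIVE.  Sites without
    substitutions are NEUTRAL with p = 1.  With ``bh_correction`` the
    Benjamini-Hochberg adjusted p-values are used for classification.
    """
    if ancestors is None:
        ancestors = ancestral_codons(tree, codon_aln)
    edges = tree.edges()
    n_sites = codon_aln.n_sites
    calls: list[SiteSelectionCall] = []
    blocked_pairs = 0
    raw = []
    for site in range(n_sites):
        syn = nonsyn = 0.0
        for parent, child, _ in edges:
            s, n, blocked = _path_counts(
                ancestors[parent][site], ancestors[child][site]
            )
            if blocked:
                blocked_pairs += 1
            syn += s
            nonsyn += n
        column = [c for c in codon_aln.column(site) if c != GAP_CODON]
        expected = (
            sum(potential_synonymous_sites(c) for c in column) / (3 * len(column))
            if column
            else 0.0
        )
        total = syn + nonsyn
        if total <= 0:
            p = 1.0
        else:
            p = min(
                1.0,
                2
                * min(
                    _binom_cdf(syn, total, expected),
                    _binom_sf(syn, total, expected),
                ),
            )
        raw.append((site, syn, nonsyn, expected, p))
    if blocked_pairs:
        warnings.warn(
            f"{blocked_pairs} branch/site codon pairs had all minimal paths "
            "through stop codons; counted as nonsynonymous-only",
            stacklevel=2,
        )

    pvals = [r[4] for r in raw]
    if bh_correction and pvals:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            running = min(running, pvals[idx] * m / (rank_pos + 1))
            adj[idx] = running
        effective = list(adj)
    else:
        effective = pvals

    for (site, syn, nonsyn, expected, p), eff in zip(raw, effective):
        total = syn + nonsyn
        cls = SelectionClass.NEUTRAL
        if total > 0 and eff < alpha:
            observed_fraction = syn / total
            if observed_fraction < expected:
                cls = SelectionClass.POSITIVE
            elif observed_fraction > expected:
                cls = SelectionClass.NEGATIVE
        calls.append(
            SiteSelectionCall(
                site_index=site + 1,
                observed_syn=syn,
                observed_nonsyn=nonsyn,
                expected_syn_fraction=expected,
                p_value=p,
                selection_class=cls,
            )
        )
    return calls


def consensus_support(
    site_calls_by_method: Mapping[str, Iterable[int]], n_sites: int
) -> dict[int, Support]:
    """Merge positively-selected site lists from several methods.

    A site reported by at least two methods is STRONG, by exactly one
    MODERATE, otherwise NONE.  Site indices are 1-based positions in the
    trimmed alignment; anything outside [1, n_sites] is an error.
    """
    tallies: dict[int, int] = {}
    for method, sites in site_calls_by_method.items():
        for site in set(sites):
            if not 1 <= site <= n_sites:
                raise ValueError(
                    f"method {method!r}: site {site} outside alignment "
                    f"of {n_sites} sites"
                )
            tallies[site] = tallies.get(site, 0) + 1
    out = {}
    for site in range(1, n_sites + 1):
        n = tallies.get(site, 0)
        out[site] = (
            Support.STRONG if n >= 2 else Support.MODERATE if n == 1 else Support.NONE
        )
    return out


def apply_consensus(
    calls: Sequence[SiteSelectionCall],
    external_site_lists: Mapping[str, Iterable[int]] | None = None,
    internal_method_name: str = "counting",
) -> list[SiteSelectionCall]:
    """Attach consensus support levels to the internal caller's results."""
    methods: dict[str, set[int]] = {
        internal_method_name: {
            c.site_index
            for c in calls
            if c.selection_class is SelectionClass.POSITIVE
        }
    }
    for name, sites in (external_site_lists or {}).items():
        methods[name] = set(sites)
    support = consensus_support(methods, n_sites=len(calls))
    return [
        SiteSelectionCall(
            c.site_index,
            c.observed_syn,
            c.observed_nonsyn,
            c.expected_syn_fraction,
            c.p_value,
            c.selection_class,
            support[c.site_index],
        )
        for c in calls
    ]


def read_method_site_lists(path: str) -> dict[str, set[int]]:
    """External per-method positive-site lists: two-column TSV
    (method, site_index)."""
    df = pd.read_csv(path, sep="\t", names=["method", "site_index"], header=None,
                     comment="#")
    out: dict[str, set[int]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.method), set()).add(int(row.site_index))
    return out


def write_site_calls(calls: Iterable[SiteSelectionCall], path: str) -> None:
    pd.DataFrame(
        [
            {
                "site_index": c.site_index,
                "observed_syn": round(c.observed_syn, 6),
                "observed_nonsyn": round(c.observed_nonsyn, 6),
                "expected_syn_fraction": round(c.expected_syn_fraction, 6),
                "p_value": c.p_value,
                "selection_class": c.selection_class.value,
                "support": c.support.value,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# protein MSA helper for the pipeline's selection stage
# ---------------------------------------------------------------------------


def align_proteins(seqs: Mapping[str, str]) -> dict[str, str]:
    """Multiple-align proteins with mafft; equal-length inputs (already
    columnwise comparable, as for substitution-only paralog sets) pass
    through unchanged."""
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) == 1:
        return dict(seqs)
    if shutil.which("mafft") is None:
        raise RuntimeError(
            "mafft not found on PATH and sequences are not equal-length"
        )
    with tempfile.NamedTemporaryFile("w", suffix=".fasta", delete=False) as fh:
        for sid, seq in seqs.items():
            fh.write(f">{sid}\n{seq}\n")
        path = fh.name
    result = subprocess.run(
        ["mafft", "--quiet", "--auto", path],
        capture_output=True,
        text=True,
        check=True,
    )
    aligned: dict[str, str] = {}
    current = None
    for line in result.stdout.splitlines():
        if line.startswith(">"):
            current = line[1:].split()[0]
            aligned[current] = ""
        elif current is not None:
            aligned[current] += line.strip().upper()
    return {sid: aligned[sid] for sid in seqs}
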