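"""Pairwise protein identity and identity-threshold paralog clustering.

Family members are treated as putative paralogs when their proteins share
more than a threshold fraction of identical residues (default > 50%), the
convention of representative-clustering tools such as CD-HIT: identity is
counted over a global alignment and divided by the length of the *shorter*
sequence.  The default partition semantics are single-linkage connected
components of the identity graph, which are order-independent and admit an
exact brute-force oracle; a CD-HIT-style greedy representative mode is
provided for parity with that tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap global alignment parameters (gap of length L costs
    open + (L-1)*extend)."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scoring.matrix_name)
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring | None = None,
    denominator: str = "shorter",
) -> float:
    """Identity fraction of the optimal global alignment of two proteins.

    identity = identical aligned positions / denominator, where the
    denominator is the shorter sequence length (default, the
    representative-clustering convention) or the alignment length
    (``denominator="alignment"``).  When several alignments are co-optimal
    the first alignment in the aligner's deterministic enumeration is used.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_a == seq_b:
        return 1.0
    aligner = _make_aligner(scoring or AlignmentScoring())
    aln = next(iter(aligner.align(seq_a, seq_b)))
    counts = aln.counts()
    if denominator == "shorter":
        denom = min(len(seq_a), len(seq_b))
    elif denominator == "alignment":
        denom = aln.length
    else:
        raise ValueError("denominator must be 'shorter' or 'alignment'")
    return counts.identities / denom


def identity_matrix(
    seqs: dict[str, str],
    scoring: AlignmentScoring | None = None,
    denominator: str = "shorter",
) -> pd.DataFrame:
    """Symmetric all-vs-all identity matrix (diagonal 1.0), ids sorted."""
    ids = sorted(seqs)
    n = len(ids)
    mat = np.eye(n)
    scoring = scoring or AlignmentScoring()
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(
                seqs[ids[i]], seqs[ids[j]], scoring, denominator
            )
            mat[i, j] = mat[j, i] = ident
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class ParalogClusterSet:
    """A partition of protein ids into paralog clusters at a threshold.

    Clusters are sorted by descending size, ties by lexicographically
    smallest member; singletons are included as size-1 clusters.
    """

    threshold: float
    clusters: list[frozenset[str]]

    def __post_init__(self):
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")
        seen: set[str] = set()
        for c in self.clusters:
            if not c:
                raise ValueError("empty cluster")
            if seen & c:
                raise ValueError("clusters are not disjoint")
            seen |= c
        self._member_to_index = {m: i for i, c in enumerate(self.clusters) for m in c}

    def cluster_of(self, member_id: str) -> frozenset[str]:
        return self.clusters[self._member_to_index[member_id]]

    def cluster_index(self, member_id: str) -> int:
        return self._member_to_index[member_id]

    @property
    def members(self) -> set[str]:
        return set(self._member_to_index)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_id": m, "cluster_id": f"cluster{i:03d}", "cluster_size": len(c)}
            for i, c in enumerate(self.clusters)
            for m in sorted(c)
        ]
        return pd.DataFrame(rows, columns=["protein_id", "cluster_id", "cluster_size"])

    def write_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _sorted_components(components: list[set[str]]) -> list[frozenset[str]]:
    return [
        frozenset(c)
        for c in sorted(components, key=lambda c: (-len(c), min(c)))
    ]


def cluster_paralogs(
    seqs: dict[str, str],
    threshold: float = 0.5,
    method: str = "single",
    matrix: pd.DataFrame | None = None,
    scoring: AlignmentScoring | None = None,
) -> ParalogClusterSet:
    """Partition proteins into paralog clusters at an identity threshold.

    An edge joins two proteins when pairwise identity is strictly greater
    than *threshold*.  ``method="single"`` (default) returns the connected
    components of that graph; ``method="greedy"`` emulates representative
    clustering (sequences visited by decreasing length, joined to the first
    representative exceeding the threshold).  A precomputed identity
    *matrix* may be supplied to avoid re-alignment.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if not seqs:
        raise ValueError("at least one sequence required")
    if matrix is None:
        matrix = identity_matrix(seqs, scoring)

    ids = sorted(seqs)
    if method == "single":
        parent = {i: i for i in ids}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i_pos, a in enumerate(ids):
            for b in ids[i_pos + 1 :]:
                if matrix.loc[a, b] > threshold:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[ra] = rb
        groups: dict[str, set[str]] = {}
        for x in ids:
            groups.setdefault(find(x), set()).add(x)
        components = list(groups.values())
    elif method == "greedy":
        order = sorted(ids, key=lambda i: (-len(seqs[i]), i))
        reps: list[str] = []
        assignment: dict[str, set[str]] = {}
        for sid in order:
            for rep in reps:
                if matrix.loc[sid, rep] > threshold:
                    assignment[rep].add(sid)
                    break
            else:
                reps.append(sid)
                assignment[sid] = {sid}
        components = list(assignment.values())
    else:
        raise ValueError("method must be 'single' or 'greedy'")
    return ParalogClusterSet(threshold, _sorted_components(components))


def closest_paralog_identity(
    protein_id: str, matrix: pd.DataFrame
) -> tuple[str | None, float]:
    """Closest paralog of a protein: the maximal off-diagonal identity.

    Ties break toward the lexicographically smallest id.  For a 1x1 matrix
    there is no paralog: returns ``(None, 0.0)``.
    """
    if protein_id not in matrix.index:
        raise KeyError(f"protein {protein_id!r} not in identity matrix")
    others = [i for i in matrix.index if i != protein_id]
    if not others:
        return None, 0.0
    row = matrix.loc[protein_id, others]
    best = row.max()
    best_id = min(i for i in others if row[i] == best)
    return best_id, float(best)


def large_clusters(
    cluster_set: ParalogClusterSet, min_size: int = 10
) -> list[frozenset[str]]:
    """Clusters with at least *min_size* members (order preserved)."""
    return [c for c in cluster_set.clusters if len(c) >= min_size]
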