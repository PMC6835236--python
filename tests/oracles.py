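"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, BFS) and
shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def all_alignment_scores(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0
) -> list[tuple[float, int]]:
    """(score, identities) for EVERY global alignment of two short sequences.

    Affine gap cost: a run of length L costs open + (L-1)*extend.  Exponential
    enumeration — only for tiny inputs.
    """
    results: list[tuple[float, int]] = []

    def walk(i, j, score, identities, last):
        if i == len(a) and j == len(b):
            results.append((score, identities))
            return
        if i < len(a) and j < len(b):
            s = _BLOSUM62[a[i]][b[j]]
            walk(i + 1, j + 1, score + s, identities + (a[i] == b[j]), "m")
        if i < len(a):
            cost = gap_extend if last == "a" else gap_open
            walk(i + 1, j, score - cost, identities, "a")
        if j < len(b):
            cost = gap_extend if last == "b" else gap_open
            walk(i, j + 1, score - cost, identities, "b")

    walk(0, 0, 0.0, 0, None)
    return results


def optimal_identity_fractions(a: str, b: str) -> tuple[float, set[float]]:
    """Optimal score and the set of identity fractions (over the shorter
    sequence) achievable by score-optimal alignments."""
    scored = all_alignment_scores(a, b)
    best = max(s for s, _ in scored)
    denom = min(len(a), len(b))
    idents = {i / denom for s, i in scored if abs(s - best) < 1e-9}
    return best, idents


def single_linkage_components(matrix, threshold: float) -> set[frozenset[str]]:
    """Connected components of the identity graph by plain BFS."""
    ids = list(matrix.index)
    unvisited = set(ids)
    components = set()
    while unvisited:
        seed = unvisited.pop()
        comp = {seed}
        queue = [seed]
        while queue:
            node = queue.pop()
            for other in list(unvisited):
                if matrix.loc[node, other] > threshold:
                    unvisited.discard(other)
                    comp.add(other)
                    queue.append(other)
        components.add(frozenset(comp))
    return components


def min_codon_changes(tree_edges, leaf_states: dict[str, str]) -> int:
    """Brute-force minimum number of codon changes over all labelings of the
    internal nodes with the observed codon states."""
    internal = sorted(
        {n for e in tree_edges for n in e[:2]} - set(leaf_states)
    )
    states = sorted(set(leaf_states.values()))
    best = None
    for combo in itertools.product(states, repeat=len(internal)):
        labels = dict(zip(internal, combo))
        labels.update(leaf_states)
        changes = sum(labels[p] != labels[c] for p, c, *_ in tree_edges)
        if best is None or changes < best:
            best = changes
    return best


def syn_fraction_by_enumeration(codon: str, stops: frozenset[str], code) -> float:
    """Synonymous-site content of a codon by enumerating all 9 mutants."""
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1 :]
            if mutant in stops:
                continue
            valid += 1
            if code[mutant] == code[codon]:
                syn += 1
        total += syn / valid if valid else 0.0
    return total
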