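"""Domain-architecture classification of family proteins.

Secreted C1q-domain-containing (C1qDC) proteins fall into recurrent
architectures: *sghC1q* (a signal peptide immediately followed by the
globular C1q domain), *C1q-like type I* (collagen tail before the C1q
domain), *C1q-like type II* (coiled-coil tail before the C1q domain),
*smultiC1q* (multiple C1q domains) and *sSUEL/C1q* (an N-terminal
sea-urchin-egg-lectin rhamnose-binding domain).  Everything else — proteins
without a predicted signal peptide, with transmembrane segments, or with an
unexpected layout — lands in *other/uncertain*.

The classifier consumes pre-computed feature predictions (signal peptide,
transmembrane segments, coiled-coil segments, profile-HMM domain hits); it
never re-runs the predictors themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import DomainHit, GeneRecord


class Category(str, Enum):
    SGH_C1Q = "SGH_C1Q"
    C1Q_LIKE_TYPE_I = "C1Q_LIKE_TYPE_I"
    C1Q_LIKE_TYPE_II = "C1Q_LIKE_TYPE_II"
    SMULTI_C1Q = "SMULTI_C1Q"
    SSUEL_C1Q = "SSUEL_C1Q"
    OTHER_UNCERTAIN = "OTHER_UNCERTAIN"


#: canonical row order for summary matrices
CATEGORIES: tuple[Category, ...] = tuple(Category)


@dataclass
class ProteinFeatures:
    """Per-protein feature annotations consumed by the classifier.

    Intervals are 1-based inclusive aa positions.  ``coiled_coil_segments``
    carry the predictor's probability; only segments above the probability
    threshold count as coiled-coil evidence.
    """

    protein_id: str
    length: int
    has_signal_peptide: bool = False
    cleavage_pos: int | None = None  # last aa of the signal peptide
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    coiled_coil_segments: list[tuple[int, int, float]] = field(default_factory=list)
    domain_hits: list[DomainHit] = field(default_factory=list)

    def __post_init__(self):
        if self.cleavage_pos is not None and not self.has_signal_peptide:
            raise ValueError(
                f"{self.protein_id}: cleavage position without signal peptide"
            )
        for s, e in self.tm_segments:
            if not (1 <= s <= e <= self.length):
                raise ValueError(f"{self.protein_id}: TM segment outside protein")
        for s, e, p in self.coiled_coil_segments:
            if not (1 <= s <= e <= self.length) or not (0.0 <= p <= 1.0):
                raise ValueError(f"{self.protein_id}: bad coiled-coil segment")


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    category: Category
    n_c1q_domains: int


class NotFamilyMemberError(ValueError):
    """Protein has no retained C1q domain hit."""


def classify_architecture(
    features: ProteinFeatures,
    linker_tolerance: int = 30,
    coil_probability_threshold: float = 0.5,
    c1q_domain_name: str = "C1q",
    suel_domain_name: str = "SUEL",
    collagen_domain_name: str = "Collagen",
) -> ArchitectureCall:
    """Assign a single architecture category from feature annotations.

    Decision cascade (first rule that fires wins):

    1. no retained C1q hit -> error (not a family member);
    2. no signal peptide, or any transmembrane segment -> OTHER_UNCERTAIN
       (not a plain secreted protein);
    3. >= 2 C1q domains -> SMULTI_C1Q;
    4. a SUEL domain preceding the C1q domain -> SSUEL_C1Q;
    5. a collagen domain preceding the C1q domain -> C1Q_LIKE_TYPE_I;
    6. a coiled-coil segment (probability above threshold) strictly between
       the signal-peptide cleavage site and the C1q start -> C1Q_LIKE_TYPE_II;
    7. C1q domain starting within *linker_tolerance* aa of the cleavage site
       ("immediately followed") -> SGH_C1Q;
    8. anything else -> OTHER_UNCERTAIN.
    """

    def named(name: str) -> list[DomainHit]:
        return [
            h for h in features.domain_hits if h.domain_name.lower() == name.lower()
        ]

    c1q_hits = sorted(named(c1q_domain_name), key=lambda h: h.ali_start)
    if not c1q_hits:
        raise NotFamilyMemberError(
            f"{features.protein_id}: no C1q domain hit; not a family member"
        )
    n_c1q = len(c1q_hits)
    first_c1q = c1q_hits[0].ali_start

    def call(cat: Category) -> ArchitectureCall:
        return ArchitectureCall(features.protein_id, cat, n_c1q)

    if not features.has_signal_peptide or features.tm_segments:
        return call(Category.OTHER_UNCERTAIN)
    if n_c1q >= 2:
        return call(Category.SMULTI_C1Q)

    suel_before = [h for h in named(suel_domain_name) if h.ali_start < first_c1q]
    collagen_before = [
        h for h in named(collagen_domain_name) if h.ali_start < first_c1q
    ]
    if suel_before and collagen_before:
        warnings.warn(
            f"{features.protein_id}: both SUEL and collagen hits precede the "
            "C1q domain; classifying as sSUEL/C1q",
            stacklevel=2,
        )
    if suel_before:
        return call(Category.SSUEL_C1Q)
    if collagen_before:
        return call(Category.C1Q_LIKE_TYPE_I)

    cleavage = features.cleavage_pos if features.cleavage_pos is not None else 0
    for s, e, p in features.coiled_coil_segments:
        if p > coil_probability_threshold and s > cleavage and e < first_c1q:
            return call(Category.C1Q_LIKE_TYPE_II)

    if 0 < first_c1q - cleavage <= linker_tolerance:
        return call(Category.SGH_C1Q)
    return call(Category.OTHER_UNCERTAIN)


def build_protein_features(
    feature_rows: pd.DataFrame | Iterable[Mapping],
    domain_hits: Iterable[DomainHit],
    protein_lengths: Mapping[str, int],
) -> dict[str, ProteinFeatures]:
    """Assemble :class:`ProteinFeatures` from a feature TSV plus domain hits.

    ``feature_rows`` columns: protein_id, feature_type (signal_peptide /
    transmembrane / coiled_coil), start, end, score.  For signal peptides the
    end column is the cleavage position.  Every protein in
    ``protein_lengths`` gets an entry, even with no feature rows.
    """
    if isinstance(feature_rows, pd.DataFrame):
        rows = feature_rows.to_dict("records")
    else:
        rows = list(feature_rows)
    feats = {
        pid: ProteinFeatures(protein_id=pid, length=length)
        for pid, length in protein_lengths.items()
    }
    for row in rows:
        pid = str(row["protein_id"])
        if pid not in feats:
            raise KeyError(f"feature row for unknown protein {pid!r}")
        f = feats[pid]
        ftype = str(row["feature_type"])
        start, end = int(row["start"]), int(row["end"])
        if ftype == "signal_peptide":
            f.has_signal_peptide = True
            f.cleavage_pos = end
        elif ftype == "transmembrane":
            f.tm_segments.append((start, end))
        elif ftype == "coiled_coil":
            f.coiled_coil_segments.append((start, end, float(row["score"])))
        else:
            raise ValueError(f"unknown feature_type {ftype!r}")
    for hit in domain_hits:
        if hit.protein_id in feats:
            feats[hit.protein_id].domain_hits.append(hit)
    return feats


def read_feature_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"protein_id": str, "feature_type": str},
    )
    expected = {"protein_id", "feature_type", "start", "end", "score"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} missing columns: {sorted(missing)}")
    return df


def summarize_architectures(
    calls: Iterable[ArchitectureCall],
    gene_records: Iterable[GeneRecord],
    protein_to_gene: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-chromosome-by-category count matrix with Total row and column.

    Rows are the six categories (all present even when empty), columns the
    chromosomes carrying classified genes, sorted.  Protein ids are mapped
    to genes via *protein_to_gene* (identity by default); an unmapped
    protein is an error.
    """
    gene_chrom = {g.gene_id: g.chromosome_id for g in gene_records}
    counts: dict[tuple[str, str], int] = {}
    unmapped = []
    for c in calls:
        gid = (protein_to_gene or {}).get(c.protein_id, c.protein_id)
        chrom = gene_chrom.get(gid)
        if chrom is None:
            unmapped.append(c.protein_id)
            continue
        key = (c.category.value, chrom)
        counts[key] = counts.get(key, 0) + 1
    if unmapped:
        raise KeyError(
            "proteins not mappable to genes: " + ", ".join(sorted(unmapped))
        )
    chroms = sorted({chrom for _, chrom in counts})
    mat = pd.DataFrame(
        0, index=[c.value for c in CATEGORIES], columns=chroms, dtype=int
    )
    for (cat, chrom), n in counts.items():
        mat.loc[cat, chrom] = n
    mat["Total"] = mat.sum(axis=1)
    mat.loc["Total"] = mat.sum(axis=0)
    return mat


def write_calls(calls: Iterable[ArchitectureCall], path: str) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "category": c.category.value,
                "n_c1q_domains": c.n_c1q_domains,
            }
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
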