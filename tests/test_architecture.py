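import pytest

from dupscape import architecture as arch
from dupscape.architecture import Category, ProteinFeatures, classify_architecture
from dupscape.io import DomainHit, GeneRecord


def hit(name, start, end, pid="p1"):
    return DomainHit(pid, name, start, end, 1e-6, 1.0)


def features(**kw):
    base = dict(protein_id="p1", length=300)
    base.update(kw)
    return ProteinFeatures(**base)


CASES = [
    # signal peptide, C1q right after cleavage -> secreted globular-head only
    (
        features(
            has_signal_peptide=True,
            cleavage_pos=20,
            domain_hits=[hit("C1q", 35, 180)],
        ),
        Category.SGH_C1Q,
    ),
    # coiled-coil tail between cleavage site and the C1q domain -> type II
    (
        features(
            has_signal_peptide=True,
            cleavage_pos=20,
            coiled_coil_segments=[(40, 90, 0.9)],
            domain_hits=[hit("C1q", 110, 240)],
        ),
        Category.C1Q_LIKE_TYPE_II,
    ),
    # collagen tail before the C1q domain -> type I
    (
        features(
            has_signal_peptide=True,
            cleavage_pos=20,
            domain_hits=[hit("Collagen", 30, 90), hit("C1q", 110, 240)],
        ),
        Category.C1Q_LIKE_TYPE_I,
    ),
    # three C1q domains -> smultiC1q
    (
        features(
            has_signal_peptide=True,
            cleavage_pos=20,
            domain_hits=[hit("C1q", 30, 100), hit("C1q", 110, 180), hit("C1q", 190, 260)],
        ),
        Category.SMULTI_C1Q,
    ),
    # SUEL lectin domain before the C1q domain -> sSUEL/C1q
    (
        features(
            has_signal_peptide=True,
            cleavage_pos=20,
            domain_hits=[hit("SUEL", 25, 120), hit("C1q", 140, 270)],
        ),
        Category.SSUEL_C1Q,
    ),
    # no signal peptide -> other/uncertain
    (
        features(domain_hits=[hit("C1q", 35, 180)]),
        Category.OTHER_UNCERTAIN,
    ),
    # transmembrane segment -> not a plain secreted protein
    (
        features(
            has_signal_peptide=True,
            cleavage_pos=20,
            tm_segments=[(150, 172)],
            domain_hits=[hit("C1q", 35, 140)],
        ),
        Category.OTHER_UNCERTAIN,
    ),
    # long unexplained linker before the C1q domain -> other/uncertain
    (
        features(
            has_signal_peptide=True,
            cleavage_pos=20,
            domain_hits=[hit("C1q", 120, 280)],
        ),
        Category.OTHER_UNCERTAIN,
    ),
]


@pytest.mark.parametrize("feats,expected", CASES)
def test_classification_cascade(feats, expected):
    call = classify_architecture(feats)
    assert call.category is expected
    assert call.n_c1q_domains == sum(
        1 for h in feats.domain_hits if h.domain_name == "C1q"
    )


def test_smulti_requires_at_least_two_domains():
    call = classify_architecture(CASES[3][0])
    assert call.n_c1q_domains == 3


def test_no_c1q_hit_is_an_error():
    with pytest.raises(arch.NotFamilyMemberError):
        classify_architecture(features(has_signal_peptide=True, cleavage_pos=20))


def test_contradictory_hits_warn_but_classify():
    f = features(
        has_signal_peptide=True,
        cleavage_pos=20,
        domain_hits=[hit("SUEL", 25, 80), hit("Collagen", 85, 120), hit("C1q", 140, 270)],
    )
    with pytest.warns(UserWarning, match="both"):
        call = classify_architecture(f)
    assert call.category is Category.SSUEL_C1Q


def test_coiled_coil_below_probability_threshold_ignored():
    f = features(
        has_signal_peptide=True,
        cleavage_pos=20,
        coiled_coil_segments=[(40, 90, 0.4)],
        domain_hits=[hit("C1q", 110, 240)],
    )
    assert classify_architecture(f).category is Category.OTHER_UNCERTAIN


def test_linker_tolerance_configurable():
    f = features(
        has_signal_peptide=True, cleavage_pos=20, domain_hits=[hit("C1q", 120, 280)]
    )
    assert classify_architecture(f, linker_tolerance=100).category is Category.SGH_C1Q


class TestSummary:
    GENES = [
        GeneRecord("g1", "chr1", 100, 200, "+", True),
        GeneRecord("g2", "chr1", 300, 400, "+", True),
        GeneRecord("g3", "chr2", 100, 200, "+", True),
    ]

    def test_counts_and_grand_total(self):
        calls = [
            arch.ArchitectureCall("g1", Category.SGH_C1Q, 1),
            arch.ArchitectureCall("g2", Category.SGH_C1Q, 1),
            arch.ArchitectureCall("g3", Category.C1Q_LIKE_TYPE_II, 1),
        ]
        mat = arch.summarize_architectures(calls, self.GENES)
        assert mat.loc["SGH_C1Q", "chr1"] == 2
        assert mat.loc["C1Q_LIKE_TYPE_II", "chr2"] == 1
        assert mat.loc["Total", "Total"] == 3

    def test_empty_input_gives_all_zero_matrix(self):
        mat = arch.summarize_architectures([], self.GENES)
        assert (mat.to_numpy() == 0).all()

    def test_totals_balance(self):
        calls = [
            arch.ArchitectureCall("g1", Category.SGH_C1Q, 1),
            arch.ArchitectureCall("g3", Category.SMULTI_C1Q, 2),
        ]
        mat = arch.summarize_architectures(calls, self.GENES)
        body = mat.drop(index="Total", columns="Total")
        assert body.sum(axis=1).sum() == mat.loc["Total", "Total"]
        assert (body.sum(axis=0) == mat.loc["Total"].drop("Total")).all()

    def test_unmapped_protein_raises(self):
        calls = [arch.ArchitectureCall("ghost", Category.SGH_C1Q, 1)]
        with pytest.raises(KeyError, match="ghost"):
            arch.summarize_architectures(calls, self.GENES)

    def test_input_order_never_changes_calls(self):
        cats = [classify_architecture(f).category for f, _ in CASES[:5]]
        rev = [classify_architecture(f).category for f, _ in reversed(CASES[:5])]
        assert cats == list(reversed(rev))


def test_simulated_genome_matrix_matches_planted_truth(small_sim):
    """The architecture matrix on a simulated genome equals the generator's
    per-category, per-chromosome truth counts exactly."""
    lengths = {pid: len(s) for pid, s in small_sim.proteins.items()}
    feats = arch.build_protein_features(
        small_sim.features, small_sim.domain_hits, lengths
    )
    calls = [arch.classify_architecture(feats[p]) for p in sorted(feats)]
    mat = arch.summarize_architectures(calls, small_sim.genes)

    truth_cat = small_sim.truth.category_of()
    chrom_of = {g.gene_id: g.chromosome_id for g in small_sim.genes}
    import collections

    expected = collections.Counter(
        (truth_cat[g].value, chrom_of[g]) for g in truth_cat
    )
    for (cat, chrom), n in expected.items():
        assert mat.loc[cat, chrom] == n
    assert mat.loc["Total", "Total"] == len(truth_cat)
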