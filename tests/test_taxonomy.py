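import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutmetab.taxonomy import (
    RANKS,
    AbundanceTable,
    RefRecord,
    ReferenceDB,
    aggregate_at_rank,
    assign_multitaxonomy,
    copy_number_normalize,
    mta_threshold,
    percent_identity,
)
from oracles import optimal_identities


def _lineage(**over):
    base = {"phylum": "P", "class": "C", "order": "O", "family": "F", "genus": "G", "species": "S"}
    base.update(over)
    return base


# --- percent identity -------------------------------------------------------

def test_identity_of_identical_sequences_is_one():
    assert percent_identity("ACGT", "ACGT") == 1.0


def test_identity_single_mismatch():
    assert percent_identity("ACGTACGT", "ACGAACGT") == pytest.approx(0.875)


@pytest.mark.parametrize("a, b", [("ACGT", "TGCA"), ("ACG", "GCA"), ("AATT", "TTAA"), ("ACGT", "A")])
def test_identity_matches_exhaustive_alignment_oracle(a, b):
    """On tiny strings the reported identity is that of some maximum-score
    alignment found by brute-force enumeration."""
    assert percent_identity(a, b) in optimal_identities(a, b)


def test_identity_is_symmetric():
    a, b = "ACGTACGTAAGG", "ACGTTCGTAAG"
    assert percent_identity(a, b) == pytest.approx(percent_identity(b, a))


def test_identity_rejects_empty_and_bad_alphabet():
    with pytest.raises(ValueError):
        percent_identity("", "ACGT")
    with pytest.raises(ValueError):
        percent_identity("ACGU", "ACGT")


# --- threshold --------------------------------------------------------------

@pytest.mark.parametrize("m, expected", [(1.0, 1.0), (0.90, 0.875), (0.80, 0.75), (0.0, -0.25)])
def test_mta_threshold_formula(m, expected):
    assert mta_threshold(m) == pytest.approx(expected)


@given(st.floats(0, 1), st.floats(0, 1))
@settings(max_examples=200, deadline=None)
def test_threshold_monotone_and_gap_shrinks(m1, m2):
    if m1 >= m2:
        assert mta_threshold(m1) >= mta_threshold(m2)
    # the retention window (M - threshold) closes as M -> 1
    assert m1 - mta_threshold(m1) == pytest.approx((1 - m1) / 4)


def test_threshold_rejects_out_of_range():
    with pytest.raises(ValueError):
        mta_threshold(1.5)


# --- multitaxonomy assignment ----------------------------------------------

def _db_with_identities():
    """Three references engineered so identities to the ASV are 0.99 (best),
    0.9875 (exactly at the M-(1-M)/4 threshold) and 0.90 (excluded)."""
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    asv = "".join(bases[rng.integers(0, 4, 400)])

    def mutate(seq, k):
        arr = np.array(list(seq))
        for pos in rng.choice(400, k, replace=False):
            arr[pos] = [b for b in "ACGT" if b != arr[pos]][rng.integers(0, 3)]
        return "".join(arr)

    recs = [
        RefRecord("r1", mutate(asv, 4), _lineage(genus="G1", species="S1")),
        RefRecord("r2", mutate(asv, 5), _lineage(genus="G2", species="S2")),
        RefRecord("r3", mutate(asv, 40), _lineage(genus="G3", species="S3")),
    ]
    return asv, ReferenceDB(recs)


def test_assignment_retains_close_hits_and_merges_labels():
    """References above M-(1-M)/4 are retained and labels are "/"-joined,
    deduplicated, alphabetically sorted."""
    asv, db = _db_with_identities()
    a = assign_multitaxonomy("asv", asv, db)
    assert a.retained_refs == ["r1", "r2"]
    assert a.label_per_rank["genus"] == "G1/G2"
    assert a.label_per_rank["phylum"] == "P"  # shared phylum collapses
    assert a.threshold <= a.max_identity
    assert "r1" in a.retained_refs  # argmax always kept


def test_single_reference_assignment_is_its_lineage():
    rec = RefRecord("r1", "ACGTACGTACGTACGT", _lineage())
    a = assign_multitaxonomy("asv", "ACGTACGTACGTACGT", ReferenceDB([rec]))
    assert a.max_identity == 1.0
    for rank in RANKS:
        assert a.label_per_rank[rank] == rec.lineage[rank]


def test_assignment_brute_force_equivalence_small_dbs():
    """Retained sets equal a brute-force filter over all identities."""
    rng = np.random.default_rng(11)
    bases = np.array(list("ACGT"))
    for trial in range(20):
        ancestor = bases[rng.integers(0, 4, 80)]
        n_ref = int(rng.integers(2, 13))
        recs = []
        for i in range(n_ref):
            arr = ancestor.copy()
            for pos in np.nonzero(rng.random(80) < 0.1)[0]:
                arr[pos] = [b for b in "ACGT" if b != arr[pos]][rng.integers(0, 3)]
            recs.append(RefRecord(f"r{i}", "".join(arr), _lineage(genus=f"G{i}", species=f"S{i}")))
        arr = ancestor.copy()
        for pos in rng.choice(80, 3, replace=False):
            arr[pos] = [b for b in "ACGT" if b != arr[pos]][rng.integers(0, 3)]
        asv = "".join(arr)
        db = ReferenceDB(recs)
        a = assign_multitaxonomy("asv", asv, db)
        idents = {r.id: percent_identity(asv, r.sequence) for r in recs}
        m = max(idents.values())
        brute = {rid for rid, v in idents.items() if v >= m - (1 - m) / 4}
        assert set(a.retained_refs) == brute


# --- aggregation and copy-number renormalization ---------------------------

def _toy_assignments():
    from gutmetab.taxonomy import TaxonomicAssignment

    def mk(asv, genus, phylum):
        return TaxonomicAssignment(asv, 1.0, 1.0, ["r"], _lineage(genus=genus, phylum=phylum))

    return [mk("a1", "G1", "P1"), mk("a2", "G1", "P1"), mk("a3", "G2", "P2")]


def test_aggregate_merges_identical_labels_and_conserves_totals():
    counts = pd.DataFrame([[5, 1], [7, 2], [3, 4]], index=["a1", "a2", "a3"], columns=["s1", "s2"])
    agg = aggregate_at_rank(_toy_assignments(), counts, "genus")
    assert agg.loc["G1"].tolist() == [12, 3]
    assert (agg.sum() == counts.sum()).all()


def test_aggregate_hierarchy_consistency():
    """Genus-level aggregation re-aggregated by phylum equals direct phylum
    aggregation when lineages are consistent."""
    counts = pd.DataFrame([[5, 1], [7, 2], [3, 4]], index=["a1", "a2", "a3"], columns=["s1", "s2"])
    assigns = _toy_assignments()
    direct = aggregate_at_rank(assigns, counts, "phylum")
    genus = aggregate_at_rank(assigns, counts, "genus")
    genus_to_phylum = {a.label_per_rank["genus"]: a.label_per_rank["phylum"] for a in assigns}
    indirect = genus.groupby([genus_to_phylum[g] for g in genus.index]).sum()
    pd.testing.assert_frame_equal(direct.sort_index(), indirect.sort_index(), check_names=False)


def test_aggregate_unassigned_asv_is_named():
    counts = pd.DataFrame([[1]], index=["mystery"], columns=["s1"])
    with pytest.raises(ValueError, match="mystery"):
        aggregate_at_rank(_toy_assignments(), counts, "genus")


def test_copy_number_normalize_hand_case():
    """Copies {A:1, B:5}, counts (10, 10) -> abundances 10/12 and 2/12."""
    counts = pd.DataFrame({"s1": [10.0, 10.0]}, index=["A", "B"])
    cn = {("genus", "A"): 1.0, ("genus", "B"): 5.0}
    table = copy_number_normalize(counts, cn, "genus")
    assert table.matrix.loc["A", "s1"] == pytest.approx(10 / 12)
    assert table.matrix.loc["B", "s1"] == pytest.approx(2 / 12)
    assert table.normalized


def test_uniform_copy_numbers_reduce_to_relative_abundance():
    rng = np.random.default_rng(3)
    counts = pd.DataFrame(rng.integers(1, 100, (4, 3)).astype(float),
                          index=list("ABCD"), columns=["s1", "s2", "s3"])
    cn = {("genus", t): 4.0 for t in "ABCD"}
    table = copy_number_normalize(counts, cn, "genus")
    expected = counts / counts.sum()
    pd.testing.assert_frame_equal(table.matrix, expected)
    assert np.allclose(table.matrix.sum(), 1.0, atol=1e-9)


def test_multitaxonomy_label_uses_mean_copies():
    counts = pd.DataFrame({"s1": [6.0, 6.0]}, index=["A/B", "C"])
    cn = {("genus", "A"): 2.0, ("genus", "B"): 4.0, ("genus", "C"): 3.0}
    table = copy_number_normalize(counts, cn, "genus")
    # A/B divided by mean(2, 4) = 3 -> equal to C's 6/3
    assert table.matrix.loc["A/B", "s1"] == pytest.approx(0.5)


def test_missing_copy_number_without_any_fallback_raises():
    counts = pd.DataFrame({"s1": [1.0]}, index=["A"])
    with pytest.raises(KeyError, match="A"):
        copy_number_normalize(counts, {}, "genus")


def test_abundance_table_rejects_unclosed_normalized_matrix():
    bad = pd.DataFrame({"s1": [0.4, 0.4]}, index=["A", "B"])
    with pytest.raises(ValueError):
        AbundanceTable("genus", bad, normalized=True)
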