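"""Read classification, deduplication, QC histograms and aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from binless.classify import (CONTACT_CATEGORIES, ClassificationParams,
                              CutSiteMap, aggregate_counts, classify_all,
                              classify_read, dangling_position_histogram,
                              deduplicate_reads, filter_short_range,
                              sonication_length_histogram)
from oracles import classify_oracle


def make_read(p1, s1, p2, s2, chrom="chr", length=30):
    return {"chrom1": chrom, "start1": p1, "length1": length, "strand1": s1,
            "up_site1": -1, "down_site1": -1,
            "chrom2": chrom, "start2": p2, "length2": length, "strand2": s2,
            "up_site2": -1, "down_site2": -1}


TWO_SITES = CutSiteMap("chr", np.array([1000, 1400]))


@pytest.mark.parametrize("read,expected", [
    # 5' start exactly on a cut site, converging: un-religated fragment
    (make_read(1000, "+", 1150, "-"), "dangling_L"),
    (make_read(1250, "+", 1400, "-"), "dangling_R"),
    # converging inside one fragment, touching no site: genomic DNA
    (make_read(1100, "+", 1250, "-"), "random"),
    # converging across exactly one site: re-ligated cut
    (make_read(950, "+", 1100, "-"), "rejoined"),
    # converging spanning both sites: far contact
    (make_read(950, "+", 1450, "-"), "contact_far"),
    # diverging toward neighboring sites: self-circle (replaces close)
    (make_read(1100, "-", 1300, "+"), "self_circle"),
    # both ends upstream of their sites, pointing downstream
    (make_read(950, "+", 1350, "+"), "contact_up"),
    (make_read(1050, "-", 1450, "-"), "contact_down"),
])
def test_hand_classified_reads(read, expected):
    assert classify_read(read, TWO_SITES).category == expected


def test_close_contact_needs_non_neighboring_sites():
    sites = CutSiteMap("chr", np.array([1000, 1400, 3000]))
    res = classify_read(make_read(1050, "-", 2900, "+"), sites)
    assert res.category == "contact_close"
    assert (res.site_i, res.site_j) == (0, 2)


def test_wrong_chromosome_raises():
    with pytest.raises(ValueError):
        classify_read(make_read(1000, "+", 1100, "-", chrom="chrX"), TWO_SITES)


def test_exhaustive_enumeration_matches_decision_tree_oracle():
    """Every position/strand combination on a two-site toy map classifies
    exactly as the independent scalar decision tree does."""
    sites = TWO_SITES
    params = ClassificationParams(tol_dangling=0, max_cutsite_distance=150)
    positions = np.arange(800, 1601, 13)
    rows, expected = [], []
    for p1 in positions:
        for p2 in positions:
            for s1 in "+-":
                for s2 in "+-":
                    rows.append(make_read(int(p1), s1, int(p2), s2))
                    expected.append(classify_oracle(
                        int(p1), s1, int(p2), s2, [1000, 1400],
                        tol_dangling=0, max_cutsite_distance=150))
    df = pd.DataFrame(rows)
    classified, tally = classify_all(df, sites, params)
    agree = (classified["category"].to_numpy() == np.array(expected))
    assert agree.all(), (
        f"{(~agree).sum()} of {len(agree)} disagree with the oracle")
    assert tally.sum() == len(df)


def test_tally_conserves_reads(micro_truth, micro_classified):
    classified, tally = micro_classified
    assert tally.sum() == len(classified)
    assert (classified.groupby("category").size().sum() == len(classified))


def test_classification_is_deterministic(micro_truth, micro_reads):
    a, _ = classify_all(micro_reads, micro_truth.cutsites)
    b, _ = classify_all(micro_reads, micro_truth.cutsites)
    pd.testing.assert_frame_equal(a, b)


def test_trans_reads_become_other(micro_truth, micro_reads):
    reads = micro_reads.head(10).copy()
    reads.loc[reads.index[:3], "chrom2"] = "chrOther"
    classified, tally = classify_all(reads, micro_truth.cutsites)
    assert (classified["category"].head(3) == "other").all()
    assert tally.sum() == len(reads)


# --- deduplication -------------------------------------------------------

def test_deduplicate_no_duplicates_is_identity(micro_reads):
    reads = micro_reads.drop(columns="true_category").drop_duplicates(
        subset=["chrom1", "start1", "length1", "strand1",
                "chrom2", "start2", "length2", "strand2"]).reset_index(drop=True)
    out, n = deduplicate_reads(reads)
    assert n == 0
    pd.testing.assert_frame_equal(out, reads)


def test_repeated_read_collapses():
    df = pd.DataFrame([make_read(1000, "+", 1100, "-")] * 5)
    out, n = deduplicate_reads(df)
    assert len(out) == 1 and n == 4


@given(st.lists(st.integers(min_value=1, max_value=6), min_size=1, max_size=8))
@settings(deadline=None, max_examples=30)
def test_planted_multiplicities(multiplicities):
    """n_removed equals the sum of (multiplicity − 1), per a hash oracle."""
    rows = []
    for k, mult in enumerate(multiplicities):
        read = make_read(1000 + 10 * k, "+", 2000 + 10 * k, "-")
        rows.extend([read] * mult)
    df = pd.DataFrame(rows)
    out, n = deduplicate_reads(df)
    keys = df.apply(lambda r: tuple(r[c] for c in
                                    ("start1", "length1", "strand1",
                                     "start2", "length2", "strand2")), axis=1)
    assert n == sum(c - 1 for c in keys.value_counts())
    assert len(out) == len(set(keys))


def test_deduplication_idempotent(micro_reads):
    once, _ = deduplicate_reads(micro_reads.drop(columns="true_category"))
    twice, n = deduplicate_reads(once)
    assert n == 0
    pd.testing.assert_frame_equal(once, twice)


# --- short-range filter --------------------------------------------------

def test_filter_short_range_brute_force(micro_classified):
    classified, _ = micro_classified
    out = filter_short_range(classified, min_distance=1000)
    is_contact = classified["category"].isin(CONTACT_CATEGORIES)
    expected = int((~is_contact).sum()
                   + (is_contact & (classified["distance"] >= 1000)).sum())
    assert len(out) == expected
    assert filter_short_range(classified, min_distance=0).shape == classified.shape
    none_left = filter_short_range(classified, min_distance=10 ** 9)
    assert not none_left["category"].isin(CONTACT_CATEGORIES).any()


# --- QC histograms -------------------------------------------------------

def test_sonication_histogram_counts(micro_classified):
    classified, _ = micro_classified
    hist = sonication_length_histogram(classified, bin_width=10)
    contributing = classified["category"].isin(
        ("dangling_L", "dangling_R", "rejoined", "random")).sum()
    assert hist.sum() == contributing


def test_sonication_histogram_mode_of_lognormal_lengths():
    rng = np.random.default_rng(42)
    lengths = rng.lognormal(np.log(200), 0.25, 5000).astype(int)
    df = pd.DataFrame({"category": "random",
                       "start1": 1000,
                       "start2": 1000 + lengths - 1})
    hist = sonication_length_histogram(df, bin_width=20)
    # log-normal mode = exp(mu - sigma^2) = 188; one 20 bp bin of slack
    assert abs(hist.idxmax() - 180) <= 20


def test_sonication_histogram_empty_and_single():
    empty = pd.DataFrame({"category": [], "start1": [], "start2": []})
    assert len(sonication_length_histogram(empty)) == 0
    single = pd.DataFrame({"category": ["random"], "start1": [100],
                           "start2": [299]})
    hist = sonication_length_histogram(single, bin_width=10)
    assert hist.sum() == 1 and hist.index[0] == 200


def test_dangling_offsets_spike_at_zero(micro_truth, micro_classified):
    classified, _ = micro_classified
    hist = dangling_position_histogram(classified, micro_truth.cutsites)
    assert hist.idxmax() == 0
    n_dangling = classified["category"].isin(("dangling_L", "dangling_R")).sum()
    assert hist.sum() == n_dangling


def test_dangling_offsets_planted_shift():
    sites = CutSiteMap("chr", np.array([1000, 2000]))
    reads = pd.DataFrame([make_read(1004, "+", 1200, "-")])
    classified, _ = classify_all(reads, sites,
                                 ClassificationParams(tol_dangling=5))
    assert classified["category"].iloc[0] == "dangling_L"
    hist = dangling_position_histogram(classified, sites)
    assert hist.index[0] == 4 and hist.iloc[0] == 1


# --- aggregation ---------------------------------------------------------

def test_aggregate_single_contact():
    sites = CutSiteMap("chr", np.arange(1, 9) * 1000)
    reads = pd.DataFrame([make_read(3900, "+", 6900, "+")])
    classified, _ = classify_all(reads, sites)
    agg = aggregate_counts(classified, sites)
    assert len(agg.contacts) == 1
    rec = agg.contacts.iloc[0]
    assert (rec["site_i"], rec["site_j"], rec["category"], rec["count"]) \
        == (3, 6, "up", 1)


def test_aggregate_conserves_reads_and_matches_groupby(micro_truth,
                                                       micro_classified):
    classified, _ = micro_classified
    agg = aggregate_counts(classified, micro_truth.cutsites)
    total = (agg.cutsite_counts.to_numpy().sum()
             + agg.contacts["count"].sum() + agg.other_tally.sum())
    assert total == len(classified)
    # group-by oracle on the contact reads
    con = classified[classified["category"].isin(CONTACT_CATEGORIES)]
    oracle = con.groupby(
        ["site_i", "site_j", con["category"].str.replace("contact_", "")]
    ).size()
    ours = agg.contacts.set_index(["site_i", "site_j", "category"])["count"]
    assert oracle.sort_index().to_numpy().tolist() \
        == ours.sort_index().to_numpy().tolist()


def test_aggregate_empty():
    sites = CutSiteMap("chr", np.array([1000, 2000]))
    empty, _ = classify_all(pd.DataFrame(columns=list(make_read(1, "+", 2, "-"))),
                            sites)
    agg = aggregate_counts(empty, sites)
    assert agg.cutsite_counts.to_numpy().sum() == 0
    assert len(agg.contacts) == 0
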