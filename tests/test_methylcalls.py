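"""Fractional methylation, coverage filtering, bulk stats and call-table IO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seedmethylome.errors import ParseError, UndefinedValueError
from seedmethylome.genome import Feature, FeatureClass
from seedmethylome.methylcalls import (
    CytosineCall,
    bulk_methylation,
    filter_coverage,
    fractional_methylation,
    gene_report,
    methylation_distribution,
    read_calls,
    write_calls,
)

from conftest import random_calls


def calls_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )


@pytest.mark.parametrize(
    "n_meth,n_unmeth,expected",
    [(8, 2, 0.8), (0, 5, 0.0), (10, 0, 1.0)],
)
def test_fractional_methylation(n_meth, n_unmeth, expected):
    call = CytosineCall("chr1", 0, "+", "CG", n_meth, n_unmeth)
    assert fractional_methylation(call) == pytest.approx(expected)


def test_fractional_methylation_zero_coverage():
    with pytest.raises(UndefinedValueError):
        fractional_methylation(CytosineCall("chr1", 0, "+", "CG", 0, 0))


def test_filter_coverage_boundary_and_oracle(rng):
    calls = random_calls(rng, n=100)
    out = filter_coverage(calls, 10)
    expected = calls[(calls.n_meth + calls.n_unmeth) >= 10].reset_index(drop=True)
    pd.testing.assert_frame_equal(out, expected)
    boundary = calls_frame([("c", 0, "+", "CG", 5, 5), ("c", 1, "+", "CG", 4, 5)])
    kept = filter_coverage(boundary, 10)
    assert list(kept["pos"]) == [0]  # coverage 10 retained ("at least 10"), 9 discarded


def test_bulk_methylation_is_read_weighted():
    calls = calls_frame([("c", 0, "+", "CG", 1, 1), ("c", 1, "+", "CG", 0, 9)])
    assert bulk_methylation(calls, "CG") == pytest.approx(1 / 11)
    # site-mean alternative distinguishes itself on the same input
    assert bulk_methylation(calls, "CG", method="site") == pytest.approx(0.25)
    full = calls_frame([("c", 0, "+", "CHH", 3, 0), ("c", 1, "+", "CHH", 7, 0)])
    assert bulk_methylation(full, "CHH") == 1.0
    with pytest.raises(UndefinedValueError):
        bulk_methylation(calls, "CHG")


def test_bulk_methylation_permutation_and_chunking_invariance(rng):
    calls = random_calls(rng, n=200)
    calls = calls[(calls.n_meth + calls.n_unmeth) > 0]
    ref = bulk_methylation(calls, None)
    shuffled = calls.sample(frac=1, random_state=0)
    assert bulk_methylation(shuffled, None) == pytest.approx(ref)
    # chunked pooling: combining the pooled counts of chunks equals the whole
    parts = [calls.iloc[i::7] for i in range(7)]
    m = sum(p["n_meth"].sum() for p in parts)
    c = sum((p["n_meth"] + p["n_unmeth"]).sum() for p in parts)
    assert m / c == pytest.approx(ref)


def test_bulk_binary_limit(rng):
    """For coverage-1 sites, the bulk frequency is the fraction of methylated sites."""
    n = 500
    meth = rng.random(n) < 0.3
    calls = calls_frame(
        [("c", i, "+", "CG", int(m), int(not m)) for i, m in enumerate(meth)]
    )
    assert bulk_methylation(calls, "CG") == pytest.approx(meth.mean())


def test_distribution_examples_and_boundaries():
    sites = calls_frame(
        [("c", 0, "+", "CG", 1, 9), ("c", 1, "+", "CG", 5, 5), ("c", 2, "+", "CG", 9, 1)]
    )
    dist = methylation_distribution(sites, "CG", min_reads=10)
    assert dist.bin_fractions == pytest.approx([1 / 3, 0, 1 / 3, 0, 1 / 3])
    full = calls_frame([("c", 0, "+", "CG", 10, 0), ("c", 1, "+", "CG", 12, 0)])
    assert methylation_distribution(full, "CG").bin_fractions == pytest.approx([0, 0, 0, 0, 1])
    # boundary percentages land deterministically in the right-hand bin
    edges = calls_frame(
        [("c", 0, "+", "CG", 2, 8), ("c", 1, "+", "CG", 4, 6),
         ("c", 2, "+", "CG", 6, 4), ("c", 3, "+", "CG", 8, 2)]
    )
    assert methylation_distribution(edges, "CG").bin_fractions == pytest.approx(
        [0, 0.25, 0.25, 0.25, 0.25]
    )


def test_distribution_matches_brute_force(rng):
    calls = random_calls(rng, n=300)
    dist = methylation_distribution(calls, "CHH", min_reads=10)
    sub = calls[(calls.context == "CHH") & ((calls.n_meth + calls.n_unmeth) >= 10)]
    sub = sub[sub.n_meth > 0]
    pct = 100 * sub.n_meth / (sub.n_meth + sub.n_unmeth)
    expected = np.zeros(5)
    for value in pct:
        expected[min(int(value // 20), 4)] += 1
    assert dist.bin_fractions == pytest.approx(expected / expected.sum())
    assert dist.bin_fractions.sum() == pytest.approx(1.0)


def test_distribution_no_methylated_sites_warns():
    calls = calls_frame([("c", 0, "+", "CG", 0, 12)])
    with pytest.warns(UserWarning):
        dist = methylation_distribution(calls, "CG")
    assert dist.bin_fractions == pytest.approx([0, 0, 0, 0, 0])


@settings(derandomize=True, max_examples=30)
@given(
    st.lists(
        st.tuples(st.integers(0, 30), st.integers(0, 30)).filter(lambda t: sum(t) > 0),
        min_size=1,
        max_size=40,
    )
)
def test_bulk_bounds_property(counts):
    calls = calls_frame(
        [("c", i, "+", "CG", m, u) for i, (m, u) in enumerate(counts)]
    )
    value = bulk_methylation(calls, "CG")
    assert 0.0 <= value <= 1.0
    assert value == pytest.approx(
        sum(m for m, _ in counts) / sum(m + u for m, u in counts)
    )


def test_gene_report_orientation_and_means():
    feature = Feature("g1", FeatureClass.PROTEIN_CODING_GENE, "c", 200, 700, "-")
    calls = calls_frame(
        [
            ("c", 699, "-", "CG", 10, 0),   # first base of the - strand gene -> offset 0
            ("c", 650, "+", "CHG", 0, 10),  # offset 49, same window
            ("c", 720, "+", "CHH", 5, 5),   # offset -21 (upstream on - strand)
            ("c", 100, "+", "CG", 10, 0),   # offset 599, inside downstream flank
        ]
    )
    report = gene_report(calls, feature, flank=200, window=50)
    got = report.sites.sort_values("offset")
    assert list(got["offset"]) == [-21, 0, 49, 599]
    window = report.window_means
    cg_mean = window[(window.offset_start == 0) & (window.context == "CG")]["mean"].iloc[0]
    assert cg_mean == pytest.approx(1.0)


def test_gene_report_empty_track():
    feature = Feature("g1", FeatureClass.PROTEIN_CODING_GENE, "c", 200, 700)
    report = gene_report(calls_frame([("c", 5000, "+", "CG", 10, 0)]), feature)
    assert len(report.sites) == 0 and len(report.window_means) == 0


def test_gene_report_planted_tissue_difference(small_dataset):
    """Embryo means exceed endosperm means in all contexts for a TE feature."""
    te = next(
        f for f in small_dataset.features
        if f.feature_class is FeatureClass.TRANSPOSABLE_ELEMENT
    )
    reports = {
        t: gene_report(small_dataset.calls[t], te, flank=0) for t in ("embryo", "endosperm")
    }
    for context in ("CHG", "CHH"):
        means = {
            t: reports[t].sites.loc[reports[t].sites.context == context, "fraction"].mean()
            for t in reports
        }
        assert means["embryo"] > means["endosperm"]


def test_call_table_round_trip(tmp_path, rng):
    calls = random_calls(rng, n=100)
    path = tmp_path / "calls.tsv"
    write_calls(calls, path)
    loaded = read_calls(path)
    pd.testing.assert_frame_equal(loaded, calls.astype({"pos": "int64"}))


def test_call_table_one_based_dialect(tmp_path, rng):
    calls = random_calls(rng, n=20)
    path = tmp_path / "calls1.tsv"
    write_calls(calls, path, one_based=True)
    pd.testing.assert_frame_equal(read_calls(path, one_based=True), calls)
    zero = read_calls(path)  # read as 0-based: positions shifted by +1
    assert (zero["pos"].to_numpy() == calls["pos"].to_numpy() + 1).all()


def test_call_table_rejects_bad_rows(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "chrom\tpos\tstrand\tcontext\tn_meth\tn_unmeth\n"
        "c\t1\t+\tCG\t-3\t4\n"
    )
    with pytest.raises(ParseError, match="line 2"):
        read_calls(path)
    path.write_text(
        "chrom\tpos\tstrand\tcontext\tn_meth\tn_unmeth\n"
        "c\t1\t+\tCXX\t3\t4\n"
    )
    with pytest.raises(ParseError, match="context"):
        read_calls(path)
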