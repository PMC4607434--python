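"""Stratified profiles, co-profile correlation and CHH island detection."""

import numpy as np
import pandas as pd
import pytest

from seedmethylome.errors import UndefinedValueError
from seedmethylome.genome import Feature, FeatureClass
from seedmethylome.integrate import (
    coprofile_correlation,
    detect_chh_islands,
    stratified_metagene,
    stratified_srna,
)
from seedmethylome.metagene import MetageneProfile, metagene_profile
from seedmethylome.srna_expression import SRNAProfile, srna_profile

GENE = FeatureClass.PROTEIN_CODING_GENE


def calls_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )


def make_profile(values, bin_width=50, upstream=2000, inward=4000, n=20):
    values = np.asarray(values, dtype=float)
    offsets = np.arange(-upstream, inward, bin_width)
    assert len(values) == len(offsets)
    bin_n = np.full(len(values), n)
    bin_n[np.isnan(values)] = 0
    return MetageneProfile(
        anchor="five_prime", context="CHH", feature_class=GENE,
        bin_width=bin_width, upstream=upstream, inward=inward,
        offsets=offsets, bin_mean=values, bin_n=bin_n,
        bin_sum=np.where(np.isnan(values), 0.0, values) * bin_n,
    )


def make_srna(values, bin_width=100, upstream=2000, inward=4000):
    values = np.asarray(values, dtype=float)
    offsets = np.arange(-upstream, inward, bin_width)
    return SRNAProfile(
        length=24, anchor="five_prime", feature_class=GENE,
        bin_width=bin_width, upstream=upstream, inward=inward,
        total_srna=10_000, offsets=offsets, bin_value=values,
        bin_count=(values * 100).astype(int),
    )


def test_degenerate_single_class_equals_unstratified():
    feats = [Feature("a", GENE, "c", 3000, 6000, "+"),
             Feature("b", GENE, "c", 10000, 13000, "-")]
    calls = calls_frame(
        [("c", p, "+", "CG", 6, 4) for p in range(2000, 14000, 131)]
    )
    expr = pd.DataFrame({"feature_id": ["a", "b"], "expr_class": [3, 3]})
    strat = stratified_metagene(calls, feats, expr, "CG", "five_prime")
    whole = metagene_profile(calls, feats, "five_prime", "CG")
    np.testing.assert_array_equal(strat.profiles[3].bin_n, whole.bin_n)
    np.testing.assert_allclose(strat.profiles[3].bin_sum, whole.bin_sum)
    assert strat.n_features == {1: 0, 2: 0, 3: 2, 4: 0, 5: 0}


def test_stratification_conserves_mass():
    feats = [Feature(f"g{i}", GENE, "c", 3000 + 7000 * i, 6000 + 7000 * i, "+")
             for i in range(4)]
    calls = calls_frame(
        [("c", p, "+", "CHH", 2, 8) for p in range(1000, 28000, 97)]
    )
    expr = pd.DataFrame(
        {"feature_id": [f.id for f in feats], "expr_class": [1, 2, 3, 5]}
    )
    strat = stratified_metagene(calls, feats, expr, "CHH", "five_prime")
    whole = metagene_profile(calls, feats, "five_prime", "CHH")
    total = sum(p.bin_n for p in strat.profiles.values())
    np.testing.assert_array_equal(total, whole.bin_n)


def test_missing_expression_goes_to_class1_with_warning():
    feats = [Feature("a", GENE, "c", 3000, 6000, "+")]
    calls = calls_frame([("c", 3100, "+", "CG", 10, 0)])
    expr = pd.DataFrame({"feature_id": [], "expr_class": []})
    with pytest.warns(UserWarning, match="class 1"):
        strat = stratified_metagene(calls, feats, expr, "CG", "five_prime")
    assert strat.n_features[1] == 1


def test_sparse_classes_flagged_not_dropped():
    feats = [Feature("a", GENE, "c", 3000, 6000, "+")]
    calls = calls_frame([("c", 3100, "+", "CG", 10, 0)])
    expr = pd.DataFrame({"feature_id": ["a"], "expr_class": [5]})
    strat = stratified_metagene(calls, feats, expr, "CG", "five_prime")
    assert strat.sparse_classes == (5,)
    assert strat.profiles[5].bin_n.sum() > 0


def test_stratified_srna_degenerate_and_conservation(rng):
    feats = [Feature("a", GENE, "c", 5000, 8000, "+"),
             Feature("b", GENE, "c", 15000, 18000, "-")]
    rows = []
    for _ in range(400):
        start = int(rng.integers(0, 20000))
        rows.append(("c", start, start + 24, str(rng.choice(["+", "-"])), 24))
    reads = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "length"])
    expr = pd.DataFrame({"feature_id": ["a", "b"], "expr_class": [2, 2]})
    strat = stratified_srna(reads, feats, expr, 24, "five_prime")
    whole = srna_profile(reads, feats, 24, "five_prime", total_srna=len(reads))
    np.testing.assert_array_equal(strat.profiles[2].bin_count, whole.bin_count)
    expr2 = pd.DataFrame({"feature_id": ["a", "b"], "expr_class": [1, 4]})
    strat2 = stratified_srna(reads, feats, expr2, 24, "five_prime")
    total = sum(p.bin_count for p in strat2.profiles.values())
    np.testing.assert_array_equal(total, whole.bin_count)


def test_correlation_identical_vectors():
    values = np.concatenate([np.linspace(0.01, 0.2, 40), np.full(80, 0.05)])
    meth = make_profile(values, n=50)
    # srna vector equals the pair-rebinned methylation over the upstream region
    srna = make_srna((values[0::2] + values[1::2]) / 2)
    result = coprofile_correlation(meth, srna, region=(-2000, 0), n_perm=500, seed=1)
    assert result.rho == pytest.approx(1.0)
    assert result.p_value < 0.05


def test_correlation_constant_vector_undefined():
    meth = make_profile(np.full(120, 0.05), n=50)
    srna = make_srna(np.linspace(0, 1, 60))
    result = coprofile_correlation(meth, srna, n_perm=100, seed=0)
    assert np.isnan(result.rho) and np.isnan(result.p_value)


def test_correlation_too_few_bins_is_undefined():
    values = np.full(120, np.nan)
    values[:3] = 0.1
    meth = make_profile(values, n=10)
    srna = make_srna(np.linspace(0, 1, 60))
    with pytest.raises(UndefinedValueError):
        coprofile_correlation(meth, srna, region=(-2000, 0), n_perm=100, seed=0)


def test_correlation_symmetry_and_rank_invariance():
    rng = np.random.default_rng(3)
    values = rng.random(120) * 0.2
    meth = make_profile(values, n=30)
    srna_vals = rng.random(60)
    srna = make_srna(srna_vals)
    r1 = coprofile_correlation(meth, srna, n_perm=2000, seed=9)
    # monotone rescaling of the sRNA track leaves the rank correlation unchanged
    srna_scaled = make_srna(np.exp(3 * srna_vals))
    r2 = coprofile_correlation(meth, srna_scaled, n_perm=2000, seed=9)
    assert r1.rho == pytest.approx(r2.rho)
    assert r1.p_value == pytest.approx(r2.p_value)


def test_islands_flat_profile_none():
    assert detect_chh_islands(make_profile(np.full(120, 0.02), n=40)) == []


def test_islands_two_planted_peaks():
    values = np.full(120, 0.02)
    offsets = np.arange(-2000, 4000, 50)
    for a, b in ((-1500, -1300), (-400, -200)):
        values[(offsets >= a) & (offsets < b)] = 0.25
    islands = detect_chh_islands(make_profile(values, n=40))
    assert [(isl.start_offset, isl.end_offset) for isl in islands] == [
        (-1500, -1300), (-400, -200)
    ]
    assert all(isl.mean_level > 2 * isl.background for isl in islands)


def test_single_bin_spike_rejected_by_width_rule():
    values = np.full(120, 0.02)
    values[10] = 0.5
    assert detect_chh_islands(make_profile(values, n=40), min_width=2) == []
    assert len(detect_chh_islands(make_profile(values, n=40), min_width=1)) == 1


def test_islands_all_undefined_empty():
    assert detect_chh_islands(make_profile(np.full(120, np.nan))) == []


def test_planted_inverse_expression_link(small_dataset):
    """Class-5 genes show lower TSS methylation than class-1 in every context."""
    from seedmethylome.recovery import tss_contrast
    from seedmethylome.srna_expression import expression_table

    genes = [f for f in small_dataset.features if f.feature_class is GENE]
    expr = expression_table(
        small_dataset.expression,
        total_mapped=small_dataset.config.library_size,
    )
    for context in ("CG", "CHG", "CHH"):
        strat = stratified_metagene(
            small_dataset.calls["embryo"], genes, expr, context, "five_prime"
        )
        contrast = tss_contrast(strat)
        assert contrast[5] < contrast[1]


def test_planted_islands_detected(small_dataset):
    genes = [f for f in small_dataset.features if f.feature_class is GENE]
    profile = metagene_profile(
        small_dataset.calls["embryo"], genes, "five_prime", "CHH"
    )
    islands = detect_chh_islands(profile)
    assert [(isl.start_offset, isl.end_offset) for isl in islands] == [
        (-1500, -1300), (-400, -200)
    ]
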