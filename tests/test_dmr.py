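"""Windowed differential methylation: pooling, calling, summarising."""

import numpy as np
import pandas as pd
import pytest

from seedmethylome.dmr import (
    HYPER_EMBRYO,
    HYPER_ENDOSPERM,
    call_dmrs,
    merge_adjacent,
    summarize_dmrs,
    window_fractions,
)
from seedmethylome.errors import AlignmentError

from conftest import random_calls


def calls_frame(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]
    )


def test_window_pooling_example():
    calls = calls_frame([("c", 10, "+", "CG", 3, 1), ("c", 40, "+", "CG", 1, 3)])
    win = window_fractions(calls, "CG", "+", contig_lengths={"c": 100})
    assert len(win) == 2
    first = win.iloc[0]
    assert first["fraction"] == pytest.approx(0.5)           # pooled 4/8
    assert first["fraction_site_mean"] == pytest.approx(0.5)  # (0.75 + 0.25)/2
    assert first["n_sites"] == 2
    assert np.isnan(win.iloc[1]["fraction"])  # empty window -> undefined


def test_window_fractions_match_brute_force(rng):
    calls = random_calls(rng, n=400, span=2000)
    win = window_fractions(calls, "CHG", "-", window_size=50, step=50,
                           contig_lengths={"chr1": 2000})
    sub = calls[(calls.context == "CHG") & (calls.strand == "-")]
    for row in win.itertuples():
        inside = sub[(sub.pos >= row.start) & (sub.pos < row.end)]
        m, u = inside.n_meth.sum(), inside.n_unmeth.sum()
        if m + u:
            assert row.fraction == pytest.approx(m / (m + u))
        else:
            assert np.isnan(row.fraction)


def test_sliding_step_tiles_every_offset():
    calls = calls_frame([("c", 60, "+", "CG", 4, 0)])
    win = window_fractions(calls, "CG", "+", window_size=50, step=25,
                           contig_lengths={"c": 150})
    assert list(win["start"]) == [0, 25, 50, 75, 100, 125]
    covered = win[win["n_sites"] > 0]["start"].tolist()
    assert covered == [25, 50]  # windows [25,75) and [50,100) contain pos 60


def windows_from_fractions(fracs, n_sites=5, coverage=50, context="CG", strand="+"):
    rows = []
    for i, value in enumerate(fracs):
        m = int(round(value * coverage))
        rows.append(
            {
                "chrom": "c", "start": 50 * i, "end": 50 * (i + 1),
                "strand": strand, "context": context, "n_sites": n_sites,
                "n_meth": m, "n_unmeth": coverage - m,
                "fraction": value, "fraction_site_mean": value,
            }
        )
    return pd.DataFrame(rows)


def test_call_dmrs_examples():
    embryo = windows_from_fractions([0.9, 0.5])
    endosperm = windows_from_fractions([0.2, 0.5])
    dmrs = call_dmrs(embryo, endosperm, min_delta=0.2, test=None)
    assert len(dmrs) == 1  # zero-delta window is never a DMR
    assert dmrs.iloc[0]["delta"] == pytest.approx(0.7)
    assert dmrs.iloc[0]["direction"] == HYPER_EMBRYO


def test_call_dmrs_tiling_mismatch():
    embryo = windows_from_fractions([0.9, 0.5])
    endosperm = windows_from_fractions([0.2])
    with pytest.raises(AlignmentError):
        call_dmrs(embryo, endosperm)


def test_call_dmrs_respects_coverage_and_sites():
    embryo = windows_from_fractions([0.9], coverage=8)    # pooled coverage < 10
    endosperm = windows_from_fractions([0.1], coverage=8)
    assert len(call_dmrs(embryo, endosperm, test=None)) == 0
    embryo = windows_from_fractions([0.9], n_sites=2)     # too few covered sites
    endosperm = windows_from_fractions([0.1], n_sites=2)
    assert len(call_dmrs(embryo, endosperm, test=None)) == 0


def test_swap_symmetry(rng):
    """Swapping sample labels negates deltas and flips every direction."""
    calls_a = random_calls(rng, n=600, span=3000, max_reads=40)
    calls_b = random_calls(rng, n=600, span=3000, max_reads=40)
    lengths = {"chr1": 3000}
    win_a = window_fractions(calls_a, "CG", "+", contig_lengths=lengths)
    win_b = window_fractions(calls_b, "CG", "+", contig_lengths=lengths)
    ab = call_dmrs(win_a, win_b, min_delta=0.05, min_coverage=1, min_sites=1, test=None)
    ba = call_dmrs(win_b, win_a, min_delta=0.05, min_coverage=1, min_sites=1, test=None)
    assert len(ab) == len(ba) and len(ab) > 0
    merged = ab.merge(ba, on=["chrom", "start", "strand", "context"], suffixes=("_ab", "_ba"))
    assert np.allclose(merged["delta_ab"], -merged["delta_ba"])
    flip = {HYPER_EMBRYO: HYPER_ENDOSPERM, HYPER_ENDOSPERM: HYPER_EMBRYO}
    assert (merged["direction_ab"].map(flip) == merged["direction_ba"]).all()
    # summaries: pct_hyper(A,B) + pct_hyper(B,A) = 100 when no delta is 0
    pct_ab = summarize_dmrs(ab)["pct_hyper_embryo"].iloc[0]
    pct_ba = summarize_dmrs(ba)["pct_hyper_embryo"].iloc[0]
    assert pct_ab + pct_ba == pytest.approx(100.0, abs=0.02)


def test_identical_inputs_give_no_dmrs(rng):
    calls = random_calls(rng, n=300, span=2000, max_reads=40)
    win = window_fractions(calls, "CHH", "+", contig_lengths={"chr1": 2000})
    assert len(call_dmrs(win, win.copy(), min_delta=1e-9, min_coverage=1,
                         min_sites=1, test=None)) == 0


def test_summarize_printed_count_arithmetic():
    """Percent-hyper accounting reproduces the published worked examples."""
    cases = [
        ("CG", "+", 421_137, 285_017, 67.68),
        ("CG", "-", 415_490, 281_796, 67.82),
        ("CHH", "+", 577_714, 364_486, 63.1),
    ]
    frames = []
    for context, strand, n_dmr, n_hyper, _ in cases:
        directions = np.where(np.arange(n_dmr) < n_hyper, HYPER_EMBRYO, HYPER_ENDOSPERM)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": "c", "start": np.arange(n_dmr) * 50,
                    "end": np.arange(n_dmr) * 50 + 50,
                    "strand": strand, "context": context,
                    "fraction_embryo": 0.5, "fraction_endosperm": 0.5,
                    "delta": np.where(directions == HYPER_EMBRYO, 0.3, -0.3),
                    "direction": directions,
                }
            )
        )
    summary = summarize_dmrs(pd.concat(frames, ignore_index=True))
    by_key = summary.set_index(["context", "strand"])
    assert by_key.loc[("CG", "+"), "pct_hyper_embryo"] == pytest.approx(67.68, abs=0.005)
    assert by_key.loc[("CG", "-"), "pct_hyper_embryo"] == pytest.approx(67.82, abs=0.005)
    assert round(by_key.loc[("CHH", "+"), "pct_hyper_embryo"], 1) == pytest.approx(63.1)
    assert by_key.loc[("CG", "+"), "total_bp"] == 421_137 * 50


def test_summarize_empty_and_zero():
    empty = summarize_dmrs(pd.DataFrame(columns=[
        "chrom", "start", "end", "strand", "context",
        "fraction_embryo", "fraction_endosperm", "delta", "direction"]))
    assert len(empty) == 0


def test_merge_adjacent():
    dmrs = pd.DataFrame(
        {
            "chrom": ["c"] * 3, "start": [0, 50, 150], "end": [50, 100, 200],
            "strand": "+", "context": "CG",
            "fraction_embryo": 0.9, "fraction_endosperm": 0.2,
            "delta": [0.7, 0.7, 0.7], "direction": HYPER_EMBRYO,
        }
    )
    merged = merge_adjacent(dmrs)
    assert list(zip(merged["start"], merged["end"])) == [(0, 100), (150, 200)]


def test_planted_dmr_recovery_small(small_sim, small_dataset):
    """Planted 50-bp CG windows (delta 0.5) are recovered at the default thresholds."""
    from seedmethylome.recovery import dmr_recovery

    lengths = {"chr1": small_sim.config.genome_size}
    frames = []
    for strand in "+-":
        win = {
            t: window_fractions(small_dataset.calls[t], "CG", strand, contig_lengths=lengths)
            for t in ("embryo", "endosperm")
        }
        frames.append(call_dmrs(win["embryo"], win["endosperm"]))
    result = dmr_recovery(pd.concat(frames, ignore_index=True), small_dataset.truth)
    assert result.recall >= 0.95
    assert result.precision >= 0.9
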