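"""Two-sample windowed differential methylation.

Fractional methylation is pooled per context and per strand within fixed
windows (50 bp, non-overlapping by default; a smaller step gives a sliding
tiling), endosperm is subtracted from embryo window-by-window, and windows
whose absolute difference exceeds a threshold in both-sample-covered
windows are reported as DMRs.  Strands are processed independently.

No published threshold exists for this kind of subtraction-based caller,
so the cutoff (``min_delta``), the per-window pooled-coverage requirement
and an optional Fisher exact test with BH-FDR are all explicit, documented
parameters rather than baked-in constants.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError

WINDOW_COLUMNS = [
    "chrom", "start", "end", "strand", "context",
    "n_sites", "n_meth", "n_unmeth", "fraction", "fraction_site_mean",
]

HYPER_EMBRYO = "hyper_in_embryo"
HYPER_ENDOSPERM = "hyper_in_endosperm"


def window_fractions(
    calls: pd.DataFrame,
    context: str,
    strand: str,
    window_size: int = 50,
    step: int = 50,
    contig_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Pooled window methylation for one context and strand.

    Tiles each contig from 0 in steps of ``step``; each window pools the
    methylated/unmethylated counts of in-window cytosines and reports
    fraction = pooled #C/(#C+#T) (NaN when the window has no coverage).
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    sub = calls.loc[(calls["context"] == context) & (calls["strand"] == strand)]
    if contig_lengths is None:
        contig_lengths = {
            chrom: int(grp["pos"].max()) + 1 for chrom, grp in sub.groupby("chrom", observed=True)
        }
    frames = []
    for chrom in sorted(contig_lengths):
        length = contig_lengths[chrom]
        grp = sub.loc[sub["chrom"] == chrom].sort_values("pos")
        pos = grp["pos"].to_numpy(np.int64)
        cm = np.concatenate([[0], np.cumsum(grp["n_meth"].to_numpy(np.int64))])
        cu = np.concatenate([[0], np.cumsum(grp["n_unmeth"].to_numpy(np.int64))])
        starts = np.arange(0, length, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window_size, side="left")
        site_cov = (grp["n_meth"] + grp["n_unmeth"]).to_numpy(np.int64)
        covered = np.concatenate([[0], np.cumsum((site_cov > 0).astype(np.int64))])
        with np.errstate(invalid="ignore", divide="ignore"):
            site_frac = np.where(site_cov > 0, grp["n_meth"].to_numpy() / np.maximum(site_cov, 1), 0.0)
        cf = np.concatenate([[0.0], np.cumsum(site_frac)])
        n_meth = cm[hi] - cm[lo]
        n_unmeth = cu[hi] - cu[lo]
        n_sites = covered[hi] - covered[lo]
        cov = n_meth + n_unmeth
        with np.errstate(invalid="ignore", divide="ignore"):
            fraction = np.where(cov > 0, n_meth / np.maximum(cov, 1), np.nan)
            site_mean = np.where(n_sites > 0, (cf[hi] - cf[lo]) / np.maximum(n_sites, 1), np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + window_size,
                    "strand": strand,
                    "context": context,
                    "n_sites": n_sites.astype(np.int64),
                    "n_meth": n_meth,
                    "n_unmeth": n_unmeth,
                    "fraction": fraction,
                    "fraction_site_mean": site_mean,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=WINDOW_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _check_tiling(a: pd.DataFrame, b: pd.DataFrame) -> None:
    keys = ["chrom", "start", "end", "strand", "context"]
    if len(a) != len(b) or not all(
        a[k].reset_index(drop=True).equals(b[k].reset_index(drop=True)) for k in keys
    ):
        raise AlignmentError("window streams do not share the same tiling/context/strand")


def call_dmrs(
    windows_embryo: pd.DataFrame,
    windows_endosperm: pd.DataFrame,
    min_delta: float = 0.2,
    min_coverage: int = 10,
    min_sites: int = 3,
    delta_mode: str = "site",
    test: str | None = "fisher",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Windows where |embryo − endosperm| fractional methylation >= ``min_delta``.

    Both samples must share the tiling; a window is evaluated only when
    each sample has pooled coverage >= ``min_coverage`` and at least
    ``min_sites`` covered cytosines in it (one noisy cytosine should not
    make a region).  ``delta`` is embryo − endosperm; direction is
    ``hyper_in_embryo`` iff delta > 0.

    ``delta_mode="site"`` (default) differences the equal-site-weight
    window fractions: at ~10x depth the read-pooled fraction picks up
    coverage-composition noise whenever a window mixes heavily- and
    un-methylated cytosines, which inflates the null |delta| tail by two
    orders of magnitude; weighting sites equally cancels that term.
    ``delta_mode="pooled"`` differences the literal pooled #C/(#C+#T)
    fractions instead.  With ``test="fisher"`` (default) a two-proportion
    Fisher exact test on the pooled counts, with Benjamini–Hochberg FDR
    control at ``alpha`` over the delta-passing candidate windows, is
    additionally required: an effect-size cutoff alone admits ~1e-3 of
    null windows at 10x depth, so candidate windows must also show more
    evidence than read sampling explains.  ``test=None`` gives the bare
    subtraction caller.
    """
    a = windows_embryo.reset_index(drop=True)
    b = windows_endosperm.reset_index(drop=True)
    _check_tiling(a, b)
    cov_a = (a["n_meth"] + a["n_unmeth"]).to_numpy()
    cov_b = (b["n_meth"] + b["n_unmeth"]).to_numpy()
    covered = (
        (cov_a >= min_coverage) & (cov_b >= min_coverage)
        & (a["n_sites"].to_numpy() >= min_sites) & (b["n_sites"].to_numpy() >= min_sites)
    )
    if delta_mode == "site":
        frac_a = a["fraction_site_mean"].to_numpy()
        frac_b = b["fraction_site_mean"].to_numpy()
    elif delta_mode == "pooled":
        frac_a = a["fraction"].to_numpy()
        frac_b = b["fraction"].to_numpy()
    else:
        raise ValueError(f"unknown delta_mode {delta_mode!r}")
    delta = frac_a - frac_b
    keep = covered & (np.abs(delta) >= min_delta) & (delta != 0)
    out = pd.DataFrame(
        {
            "chrom": a["chrom"],
            "start": a["start"],
            "end": a["end"],
            "strand": a["strand"],
            "context": a["context"],
            "fraction_embryo": frac_a,
            "fraction_endosperm": frac_b,
            "delta": delta,
        }
    ).loc[keep]
    if test == "fisher" and len(out):
        idx = out.index
        pvals = np.array(
            [
                stats.fisher_exact(
                    [
                        [a.at[i, "n_meth"], a.at[i, "n_unmeth"]],
                        [b.at[i, "n_meth"], b.at[i, "n_unmeth"]],
                    ]
                )[1]
                for i in idx
            ]
        )
        qvals = stats.false_discovery_control(pvals)
        out = out.loc[idx[qvals <= alpha]]
    elif test not in (None, "fisher"):
        raise ValueError(f"unknown test {test!r}")
    out = out.assign(direction=np.where(out["delta"] > 0, HYPER_EMBRYO, HYPER_ENDOSPERM))
    return out.reset_index(drop=True)


def merge_adjacent(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Merge bookended same-direction DMR windows (optional post-processing)."""
    if not len(dmrs):
        return dmrs.copy()
    d = dmrs.sort_values(["context", "strand", "chrom", "start"]).reset_index(drop=True)
    new_block = (
        (d["chrom"] != d["chrom"].shift())
        | (d["strand"] != d["strand"].shift())
        | (d["context"] != d["context"].shift())
        | (d["direction"] != d["direction"].shift())
        | (d["start"] != d["end"].shift())
    )
    block = new_block.cumsum()
    merged = (
        d.groupby(block)
        .agg(
            chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"),
            strand=("strand", "first"), context=("context", "first"),
            delta=("delta", "mean"), direction=("direction", "first"),
        )
        .reset_index(drop=True)
    )
    return merged


def summarize_dmrs(dmrs: pd.DataFrame, window_size: int = 50) -> pd.DataFrame:
    """Per (context, strand) DMR counts, bp totals and percent hyper-in-embryo.

    ``pct_hyper_embryo`` = 100 × n_hyper_embryo / n_dmr rounded to 2 decimals
    (NaN when no DMRs).
    """
    cols = ["context", "strand", "n_dmr", "total_bp", "n_hyper_embryo", "pct_hyper_embryo"]
    if not len(dmrs):
        return pd.DataFrame(columns=cols)
    grouped = (
        dmrs.assign(hyper=dmrs["direction"] == HYPER_EMBRYO)
        .groupby(["context", "strand"], observed=True)
        .agg(n_dmr=("direction", "size"), n_hyper_embryo=("hyper", "sum"))
        .reset_index()
    )
    grouped["total_bp"] = grouped["n_dmr"] * window_size
    grouped["pct_hyper_embryo"] = (100.0 * grouped["n_hyper_embryo"] / grouped["n_dmr"]).round(2)
    return grouped[cols]


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """Write DMRs as BED6+3: name=context, score=0, extra delta + fractions."""
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["context"],
            "score": 0,
            "strand": dmrs["strand"],
            "delta": dmrs["delta"].round(6),
            "fraction_embryo": dmrs["fraction_embryo"].round(6),
            "fraction_endosperm": dmrs["fraction_endosperm"].round(6),
        }
    )
    out.to_csv(str(path), sep="\t", index=False, header=False)
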