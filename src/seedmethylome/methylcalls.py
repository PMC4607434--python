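"""Per-cytosine methylation calls and bulk statistics.

The canonical in-memory container for a call table is a pandas DataFrame
with columns ``chrom, pos, strand, context, n_meth, n_unmeth`` — one row
per covered cytosine, where ``n_meth`` is the number of bisulfite reads
reporting C (methylated, "#C") and ``n_unmeth`` the number reporting T
(unmethylated, "#T").  Fractional methylation of a site or a pooled region
is #C/(#C+#T).

The bulk methylation frequency of a context is read-weighted by default:
sum(#C)/sum(#C+#T) over all sites, i.e. the literal per-site formula applied
to pooled counts.  The unweighted mean of per-site fractions is available
as ``method="site"``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, UndefinedValueError
from .genome import CONTEXTS, Feature

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]


@dataclass(frozen=True)
class CytosineCall:
    """A single cytosine's strand, context and methylated/unmethylated counts."""

    contig: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self):
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be nonnegative")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


def fractional_methylation(call) -> float:
    """#C/(#C+#T) for one call (CytosineCall or any object with the counts)."""
    cov = call.n_meth + call.n_unmeth
    if cov <= 0:
        raise UndefinedValueError("fractional methylation undefined at zero coverage")
    return call.n_meth / cov


def site_fractions(calls: pd.DataFrame) -> pd.Series:
    """Vectorised per-site fractional methylation (NaN at zero coverage)."""
    cov = calls["n_meth"] + calls["n_unmeth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        return calls["n_meth"] / cov.replace(0, np.nan)


def filter_coverage(calls: pd.DataFrame, min_reads: int = 10) -> pd.DataFrame:
    """Retain calls covered by at least ``min_reads`` reads.

    The default keeps sites covered by at least 10 deduplicated reads; the
    boundary is inclusive.  Retained/discarded counts are logged.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    keep = (calls["n_meth"] + calls["n_unmeth"]) >= min_reads
    out = calls.loc[keep].reset_index(drop=True)
    logger.info(
        "coverage filter (>=%d reads): retained %d, discarded %d",
        min_reads, int(keep.sum()), int((~keep).sum()),
    )
    return out


def bulk_methylation(
    calls: pd.DataFrame, context: str | None = None, method: str = "read"
) -> float:
    """Bulk methylation frequency over calls of one context (or all).

    method="read": sum(#C)/sum(#C+#T) (default, read-weighted).
    method="site": unweighted mean of per-site fractions.
    """
    sub = calls if context is None else calls.loc[calls["context"] == context]
    cov = int(sub["n_meth"].sum() + sub["n_unmeth"].sum())
    if len(sub) == 0 or cov == 0:
        raise UndefinedValueError(
            f"bulk methylation undefined: no covered calls for context {context!r}"
        )
    if method == "read":
        return float(sub["n_meth"].sum() / cov)
    if method == "site":
        fracs = site_fractions(sub).dropna()
        return float(fracs.mean())
    raise ValueError(f"unknown method {method!r}")


def bulk_methylation_se(calls: pd.DataFrame, context: str | None = None) -> float:
    """Cluster-robust standard error of the read-weighted bulk frequency.

    Sites are the independent units: SE = sqrt(sum_i (m_i - c_i * p)^2) / sum_i c_i
    with m_i methylated reads, c_i coverage of site i and p the bulk estimate.
    This accounts for both read-sampling noise and between-site rate dispersion.
    """
    sub = calls if context is None else calls.loc[calls["context"] == context]
    cov = (sub["n_meth"] + sub["n_unmeth"]).to_numpy(float)
    m = sub["n_meth"].to_numpy(float)
    total = cov.sum()
    if total == 0:
        raise UndefinedValueError("bulk SE undefined: no coverage")
    p = m.sum() / total
    return float(np.sqrt(np.sum((m - cov * p) ** 2)) / total)


@dataclass
class MethylationDistribution:
    """Fraction of methylated cytosines per 20%-wide methylation bin.

    Bins are [0,20), [20,40), [40,60), [60,80), [80,100]; the denominator
    is the number of methylated sites (n_meth > 0).
    """

    context: str
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([0, 20, 40, 60, 80, 100]))
    bin_fractions: np.ndarray = field(default_factory=lambda: np.zeros(5))
    n_sites: int = 0


def methylation_distribution(
    calls: pd.DataFrame, context: str, min_reads: int = 10
) -> MethylationDistribution:
    """20%-bin distribution of per-site percent methylation over methylated sites."""
    sub = filter_coverage(calls.loc[calls["context"] == context], min_reads)
    sub = sub.loc[sub["n_meth"] > 0]
    if len(sub) == 0:
        warnings.warn(f"no methylated {context} sites: returning all-zero distribution")
        return MethylationDistribution(context=context)
    pct = site_fractions(sub).to_numpy() * 100.0
    # boundary values 20/40/60/80 land in the right-hand bin; 100 in the last
    idx = np.digitize(pct, [20, 40, 60, 80], right=False)
    counts = np.bincount(idx, minlength=5).astype(float)
    return MethylationDistribution(
        context=context, bin_fractions=counts / counts.sum(), n_sites=len(sub)
    )


@dataclass
class GeneReport:
    """Per-cytosine and per-window methylation across a feature ± flank.

    Offsets are strand-oriented: 0 is the feature's first (5') base and
    negative offsets are upstream of it.
    """

    feature: Feature
    flank: int
    sites: pd.DataFrame       # offset, strand, context, n_meth, n_unmeth, fraction
    window_means: pd.DataFrame  # offset_start, context, mean, n_sites


def gene_report(
    calls: pd.DataFrame, feature: Feature, flank: int = 2000,
    window: int = 50, min_reads: int = 10,
) -> GeneReport:
    """Per-context methylation track over ``feature`` ± ``flank`` bp."""
    if not (calls["chrom"] == feature.contig).any() and len(calls):
        if feature.contig not in set(calls["chrom"].unique()):
            raise KeyError(f"contig {feature.contig!r} absent from call table")
    lo, hi = feature.start - flank, feature.end + flank
    sub = calls.loc[
        (calls["chrom"] == feature.contig) & (calls["pos"] >= lo) & (calls["pos"] < hi)
    ]
    sub = filter_coverage(sub, min_reads) if len(sub) else sub
    if feature.strand == "+":
        offset = sub["pos"] - feature.start
    else:
        offset = (feature.end - 1) - sub["pos"]
    sites = sub.assign(offset=offset, fraction=site_fractions(sub))
    sites = sites[["offset", "strand", "context", "n_meth", "n_unmeth", "fraction"]]
    sites = sites.sort_values("offset").reset_index(drop=True)
    if len(sites):
        bin_start = (sites["offset"] + flank) // window * window - flank
        grouped = (
            sites.assign(offset_start=bin_start)
            .groupby(["offset_start", "context"], observed=True)["fraction"]
            .agg(mean="mean", n_sites="count")
            .reset_index()
        )
    else:
        grouped = pd.DataFrame(columns=["offset_start", "context", "mean", "n_sites"])
    return GeneReport(feature=feature, flank=flank, sites=sites, window_means=grouped)


def read_calls(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    """Read a tab-delimited call table (chrom, pos, strand, context, n_meth, n_unmeth).

    With ``one_based=True`` positions are shifted by −1 on read (1-based dialect).
    """
    try:
        table = pd.read_csv(
            str(path), sep="\t", comment="#", header=0,
            dtype={"chrom": str, "strand": str, "context": str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise ParseError(f"cannot parse call table {path}: {exc}") from exc
    missing = [c for c in CALL_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"call table {path} missing columns {missing}")
    table = table[CALL_COLUMNS].copy()
    for col in ("pos", "n_meth", "n_unmeth"):
        try:
            table[col] = pd.to_numeric(table[col], errors="raise").astype(np.int64)
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(table[col], errors="coerce").isna()
            lineno = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"non-integer value in column {col!r}", lineno) from exc
    for col in ("n_meth", "n_unmeth"):
        bad = table[col] < 0
        if bad.any():
            raise ParseError(f"negative count in column {col!r}", int(bad.idxmax()) + 2)
    bad_ctx = ~table["context"].isin(CONTEXTS)
    if bad_ctx.any():
        raise ParseError(
            f"unknown context {table.loc[bad_ctx.idxmax(), 'context']!r}",
            int(bad_ctx.idxmax()) + 2,
        )
    if one_based:
        table["pos"] -= 1
    return table


def write_calls(calls: pd.DataFrame, path: str | Path, one_based: bool = False) -> None:
    """Write a call table; lossless round trip with :func:`read_calls`."""
    out = calls[CALL_COLUMNS].copy()
    if one_based:
        out["pos"] += 1
    out.to_csv(str(path), sep="\t", index=False)


def write_bedgraph(
    calls: pd.DataFrame, path: str | Path, context: str, min_reads: int = 1
) -> None:
    """Export per-site fractions of one context as 4-column bedGraph."""
    sub = filter_coverage(calls.loc[calls["context"] == context], min_reads)
    frac = site_fractions(sub)
    table = pd.DataFrame(
        {
            "chrom": sub["chrom"],
            "start": sub["pos"],
            "end": sub["pos"] + 1,
            "value": frac.round(6),
        }
    )
    table.to_csv(str(path), sep="\t", index=False, header=False)
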