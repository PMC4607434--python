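"""Small-RNA length stratification, positional accumulation and RPKM classes.

sRNA alignments (BED6-like, 0-based half-open, length = end − start) are
separated by length (21–24 nt), assigned strand-oriented offsets around
feature anchors exactly as methylation sites are, accumulated into 100-nt
bins from −2 kb to +4 kb, and normalised as a percentage of the total
number of mapped sRNA reads (all lengths, by default).

Expression is quantified as RPKM = 1e9 × reads / (length × library size)
and classified into five levels: 1 (silent, RPKM = 0), 2 ((0, 1]),
3 ((1, 10]), 4 ((10, 100]) and 5 (> 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import Feature, FeatureClass
from .metagene import _SENTINEL, Anchor, _offsets_for_feature

SRNA_COLUMNS = ["chrom", "start", "end", "strand", "length"]
CANONICAL_LENGTHS = (21, 22, 23, 24)

#: default class boundaries: upper edges of classes 2..4 (class 1 is RPKM == 0)
DEFAULT_CLASS_BOUNDS = (1.0, 10.0, 100.0)


def read_srna_bed(path: str | Path) -> pd.DataFrame:
    """Read sRNA alignments from BED6; length inferred from the interval."""
    table = pd.read_csv(
        str(path), sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "strand": str},
    )
    out = table[["chrom", "start", "end", "strand"]].copy()
    out["length"] = out["end"] - out["start"]
    n_odd = int((~out["length"].isin(CANONICAL_LENGTHS)).sum())
    if n_odd:
        warnings.warn(f"{n_odd} sRNA reads outside 21-24 nt retained but flagged")
    out["canonical"] = out["length"].isin(CANONICAL_LENGTHS)
    return out


def write_srna_bed(reads: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "chrom": reads["chrom"],
            "start": reads["start"],
            "end": reads["end"],
            "name": "sRNA_" + reads["length"].astype(str) + "nt",
            "score": 0,
            "strand": reads["strand"],
        }
    )
    out.to_csv(str(path), sep="\t", index=False, header=False)


def rpkm(read_count, feature_length, total_mapped) -> float | np.ndarray:
    """Reads per kilobase of transcript per million mapped reads."""
    read_count = np.asarray(read_count, dtype=float)
    if np.any(np.asarray(feature_length) <= 0):
        raise ValueError("feature_length must be positive")
    if np.any(np.asarray(total_mapped) <= 0):
        raise ValueError("total_mapped must be positive")
    out = 1e9 * read_count / (np.asarray(feature_length, float) * np.asarray(total_mapped, float))
    return float(out) if out.ndim == 0 else out


def classify_expression(value, bounds: Sequence[float] = DEFAULT_CLASS_BOUNDS):
    """Expression class 1..5 from RPKM (monotone in RPKM; boundaries inclusive above).

    Class 1: RPKM == 0; class 2: (0, bounds[0]]; class 3: (bounds[0], bounds[1]];
    class 4: (bounds[1], bounds[2]]; class 5: > bounds[2].
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("RPKM must be nonnegative")
    cls = 2 + np.searchsorted(np.asarray(bounds, float), arr, side="left")
    cls = np.where(arr == 0, 1, cls)
    return int(cls) if cls.ndim == 0 else cls.astype(int)


def expression_table(
    counts: pd.DataFrame,
    total_mapped: int | None = None,
    bounds: Sequence[float] = DEFAULT_CLASS_BOUNDS,
) -> pd.DataFrame:
    """Attach RPKM and expression class to a (feature_id, read_count, feature_length) table."""
    out = counts[["feature_id", "read_count", "feature_length"]].copy()
    if total_mapped is None:
        total_mapped = int(out["read_count"].sum())
    out["rpkm"] = rpkm(out["read_count"].to_numpy(), out["feature_length"].to_numpy(), total_mapped)
    out["expr_class"] = classify_expression(out["rpkm"].to_numpy(), bounds)
    return out


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t", dtype={"feature_id": str})


def write_expression(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(str(path), sep="\t", index=False, float_format="%.6g")


@dataclass
class SRNAProfile:
    """Percentage of total sRNA reads per offset bin around feature anchors."""

    length: int
    anchor: Anchor
    feature_class: FeatureClass | None
    bin_width: int
    upstream: int
    inward: int
    total_srna: int
    offsets: np.ndarray
    bin_value: np.ndarray   # percent of total_srna
    bin_count: np.ndarray   # raw (read, feature) pair counts

    @property
    def n_bins(self) -> int:
        return len(self.offsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_start": self.offsets,
                "offset_end": self.offsets + self.bin_width,
                "percent": self.bin_value,
                "n_reads": self.bin_count,
            }
        )


def srna_profile(
    reads: pd.DataFrame,
    features: Sequence[Feature],
    length: int,
    anchor: Anchor,
    bin_width: int = 100,
    upstream: int = 2000,
    inward: int = 4000,
    total_srna: int | None = None,
    read_anchor: str = "five_prime",
) -> SRNAProfile:
    """Positional accumulation of one sRNA length class around feature anchors.

    Each read is located at its strand-oriented 5' end (``read_anchor=
    "midpoint"`` uses the midpoint), assigned an offset per feature, and
    counted into 100-nt bins; bin_value = 100 × reads-in-bin / total_srna,
    where ``total_srna`` defaults to the total mapped reads of all lengths.
    """
    if total_srna is None:
        total_srna = len(reads)
    if total_srna <= 0:
        raise ValueError("total_srna must be positive")
    sub = reads.loc[reads["length"] == length]
    if read_anchor == "five_prime":
        anchor_pos = np.where(sub["strand"] == "+", sub["start"], sub["end"] - 1)
    elif read_anchor == "midpoint":
        anchor_pos = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
    else:
        raise ValueError(f"unknown read_anchor {read_anchor!r}")
    locs = pd.DataFrame({"chrom": sub["chrom"].to_numpy(), "pos": np.asarray(anchor_pos, np.int64)})
    by_chrom = {}
    for chrom, grp in locs.groupby("chrom", observed=True):
        by_chrom[chrom] = np.sort(grp["pos"].to_numpy(np.int64))
    n_bins = (upstream + inward) // bin_width
    offsets = np.arange(-upstream, inward, bin_width, dtype=np.int64)
    bin_count = np.zeros(n_bins, dtype=np.int64)
    classes = {f.feature_class for f in features}
    fclass = classes.pop() if len(classes) == 1 else None
    for feat in features:
        if feat.contig not in by_chrom:
            continue
        pos = by_chrom[feat.contig]
        lo = np.searchsorted(pos, feat.start - (upstream + inward))
        hi = np.searchsorted(pos, feat.end + upstream + inward)
        if lo == hi:
            continue
        off = _offsets_for_feature(feat, pos[lo:hi], anchor, upstream, inward)
        ok = off != _SENTINEL
        if ok.any():
            bins = (off[ok] + upstream) // bin_width
            np.add.at(bin_count, bins, 1)
    return SRNAProfile(
        length=length, anchor=anchor, feature_class=fclass,
        bin_width=bin_width, upstream=upstream, inward=inward,
        total_srna=int(total_srna), offsets=offsets,
        bin_value=100.0 * bin_count / total_srna, bin_count=bin_count,
    )


def write_srna_profile(profile: SRNAProfile, path) -> None:
    profile.to_frame().to_csv(str(path), sep="\t", index=False, float_format="%.6g")
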