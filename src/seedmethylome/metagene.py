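"""Feature-anchored metagene methylation profiles.

Sites are assigned strand-oriented offsets relative to a feature's 5' or
3' end: offset 0 is the anchor base, negative offsets lie outside the
feature (upstream for a 5' anchor, downstream for a 3' anchor) and
positive offsets run into the feature.  Offsets are binned (50 nt by
default) from −2 kb outside to +4 kb into the feature; inward offsets are
clipped at each feature's own length, so short features simply stop
contributing.  A site inside two overlapping features contributes once
per feature (pair-based counting).

The per-bin average is the unweighted mean of per-site fractional
methylation over all in-bin (site, feature) pairs; ``weight="read"``
pools raw counts instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError
from .genome import Feature, FeatureClass
from .methylcalls import filter_coverage, site_fractions

Anchor = Literal["five_prime", "three_prime"]

DEFAULT_UPSTREAM = 2000
DEFAULT_INWARD = 4000


def anchored_offsets(
    feature: Feature,
    pos: int,
    anchor: Anchor,
    upstream: int = DEFAULT_UPSTREAM,
    inward: int = DEFAULT_INWARD,
) -> int | None:
    """Strand-oriented signed offset of a site from a feature anchor.

    Returns ``None`` when the offset falls outside [−upstream, inward) or,
    for inward (positive) offsets, beyond the feature's length.
    """
    off = _offsets_for_feature(feature, np.asarray([pos]), anchor, upstream, inward)[0]
    return None if off == _SENTINEL else int(off)


_SENTINEL = np.iinfo(np.int64).min


def _offsets_for_feature(
    feature: Feature,
    positions: np.ndarray,
    anchor: Anchor,
    upstream: int,
    inward: int,
) -> np.ndarray:
    """Vectorised offsets; out-of-range entries are set to ``_SENTINEL``."""
    if anchor == "five_prime":
        if feature.strand == "+":
            off = positions - feature.start
        else:
            off = (feature.end - 1) - positions
    elif anchor == "three_prime":
        if feature.strand == "+":
            off = (feature.end - 1) - positions
        else:
            off = positions - feature.start
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    off = off.astype(np.int64)
    bad = (off < -upstream) | (off >= inward) | (off >= feature.length)
    off[bad] = _SENTINEL
    return off


@dataclass
class MetageneProfile:
    """Binned average methylation anchored at feature ends.

    ``offsets`` holds the bin start offsets; ``bin_mean`` is NaN where no
    (site, feature) pair contributed.  ``bin_sum`` retains the raw per-bin
    numerator so that profiles can be re-binned or pooled exactly.
    """

    anchor: Anchor
    context: str | None
    feature_class: FeatureClass | None
    bin_width: int
    upstream: int
    inward: int
    offsets: np.ndarray
    bin_mean: np.ndarray
    bin_n: np.ndarray
    bin_sum: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.offsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset_start": self.offsets,
                "offset_end": self.offsets + self.bin_width,
                "mean": self.bin_mean,
                "n": self.bin_n,
            }
        )


def _calls_by_chrom(calls: pd.DataFrame) -> dict[str, tuple[np.ndarray, ...]]:
    out = {}
    frac = site_fractions(calls).to_numpy(float)
    cov = (calls["n_meth"] + calls["n_unmeth"]).to_numpy(float)
    m = calls["n_meth"].to_numpy(float)
    for chrom, idx in calls.groupby("chrom", observed=True).indices.items():
        pos = calls["pos"].to_numpy(np.int64)[idx]
        order = np.argsort(pos, kind="mergesort")
        out[chrom] = (pos[order], frac[idx][order], m[idx][order], cov[idx][order])
    return out


def metagene_profile(
    calls: pd.DataFrame,
    features: Sequence[Feature],
    anchor: Anchor,
    context: str | None,
    bin_width: int = 50,
    upstream: int = DEFAULT_UPSTREAM,
    inward: int = DEFAULT_INWARD,
    min_reads: int = 10,
    weight: str = "site",
    drop_unstranded: bool = False,
) -> MetageneProfile:
    """Average methylation per offset bin over a set of same-class features.

    ``weight="site"`` (default) averages per-site fractions; ``"read"``
    pools raw counts per bin.  Features with undefined strand are profiled
    as + strand unless ``drop_unstranded``.
    """
    if upstream % bin_width or inward % bin_width:
        raise ValueError("upstream and inward spans must be multiples of bin_width")
    sub = calls if context is None else calls.loc[calls["context"] == context]
    sub = filter_coverage(sub, min_reads) if min_reads > 1 else sub
    n_bins = (upstream + inward) // bin_width
    offsets = np.arange(-upstream, inward, bin_width, dtype=np.int64)
    bin_sum = np.zeros(n_bins)
    bin_n = np.zeros(n_bins, dtype=np.int64)
    bin_m = np.zeros(n_bins)
    bin_cov = np.zeros(n_bins)
    by_chrom = _calls_by_chrom(sub)
    classes = {f.feature_class for f in features}
    fclass = classes.pop() if len(classes) == 1 else None
    for feat in features:
        if feat.contig not in by_chrom:
            continue
        pos, frac, m, cov = by_chrom[feat.contig]
        lo = np.searchsorted(pos, feat.start - (upstream + inward))
        hi = np.searchsorted(pos, feat.end + upstream + inward)
        if lo == hi:
            continue
        p = pos[lo:hi]
        off = _offsets_for_feature(feat, p, anchor, upstream, inward)
        ok = off != _SENTINEL
        if not ok.any():
            continue
        bins = (off[ok] + upstream) // bin_width
        np.add.at(bin_sum, bins, frac[lo:hi][ok])
        np.add.at(bin_n, bins, 1)
        np.add.at(bin_m, bins, m[lo:hi][ok])
        np.add.at(bin_cov, bins, cov[lo:hi][ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        if weight == "site":
            bin_mean = np.where(bin_n > 0, bin_sum / np.maximum(bin_n, 1), np.nan)
        elif weight == "read":
            bin_mean = np.where(bin_cov > 0, bin_m / np.maximum(bin_cov, 1), np.nan)
        else:
            raise ValueError(f"unknown weight {weight!r}")
    return MetageneProfile(
        anchor=anchor, context=context, feature_class=fclass,
        bin_width=bin_width, upstream=upstream, inward=inward,
        offsets=offsets, bin_mean=bin_mean, bin_n=bin_n, bin_sum=bin_sum,
    )


def compare_profiles(profile_a: MetageneProfile, profile_b: MetageneProfile) -> np.ndarray:
    """Bin-wise difference a − b where both are defined (NaN elsewhere)."""
    if (
        profile_a.bin_width != profile_b.bin_width
        or profile_a.anchor != profile_b.anchor
        or len(profile_a.offsets) != len(profile_b.offsets)
        or not np.array_equal(profile_a.offsets, profile_b.offsets)
    ):
        raise AlignmentError("profiles do not share anchor/binning")
    diff = profile_a.bin_mean - profile_b.bin_mean
    both = (profile_a.bin_n > 0) & (profile_b.bin_n > 0)
    return np.where(both, diff, np.nan)


def write_profile(profile: MetageneProfile, path) -> None:
    profile.to_frame().to_csv(str(path), sep="\t", index=False, float_format="%.6g")
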