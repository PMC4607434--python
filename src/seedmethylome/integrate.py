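"""Cross-layer analyses: expression-stratified profiles, methylation–sRNA
co-profiles and upstream CHH-island detection.

Stratified profiles partition a feature set by its five expression classes
and compute one metagene (or sRNA) profile per class, so that e.g. the
inverse relation between TSS-proximal methylation and transcript abundance
becomes visible as ordered traces.  The methylation–sRNA association is
quantified by a rank (Spearman) correlation between the two binned tracks
over a chosen offset region, with a seeded bin-label permutation null.
CHH islands — localized runs of dense CHH methylation upstream of genes —
are called as contiguous bins exceeding a multiple of the upstream-region
median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, UndefinedValueError
from .genome import Feature
from .metagene import Anchor, MetageneProfile, metagene_profile
from .srna_expression import SRNAProfile, srna_profile

EXPRESSION_CLASSES = (1, 2, 3, 4, 5)


@dataclass
class StratifiedProfiles:
    """One profile per expression class plus per-class feature counts.

    Classes with fewer than ``sparse_threshold`` features are listed in
    ``sparse_classes`` (reported, never dropped).
    """

    profiles: dict[int, MetageneProfile | SRNAProfile]
    n_features: dict[int, int]
    sparse_classes: tuple[int, ...]


def _partition_features(
    features: Sequence[Feature], expression: pd.DataFrame | Mapping[str, int]
) -> dict[int, list[Feature]]:
    if isinstance(expression, pd.DataFrame):
        class_of = dict(zip(expression["feature_id"], expression["expr_class"]))
    else:
        class_of = dict(expression)
    parts: dict[int, list[Feature]] = {c: [] for c in EXPRESSION_CLASSES}
    missing = 0
    for feat in features:
        cls = class_of.get(feat.id)
        if cls is None:
            missing += 1
            cls = 1
        parts[int(cls)].append(feat)
    if missing:
        warnings.warn(f"{missing} features without expression record assigned to class 1")
    return parts


def stratified_metagene(
    calls: pd.DataFrame,
    features: Sequence[Feature],
    expression: pd.DataFrame | Mapping[str, int],
    context: str,
    anchor: Anchor,
    sparse_threshold: int = 30,
    **profile_kwargs,
) -> StratifiedProfiles:
    """Per-expression-class metagene methylation profiles."""
    parts = _partition_features(features, expression)
    profiles = {}
    for cls, feats in parts.items():
        profiles[cls] = metagene_profile(calls, feats, anchor, context, **profile_kwargs)
    n = {cls: len(feats) for cls, feats in parts.items()}
    sparse = tuple(c for c in EXPRESSION_CLASSES if 0 < n[c] < sparse_threshold)
    return StratifiedProfiles(profiles=profiles, n_features=n, sparse_classes=sparse)


def stratified_srna(
    reads: pd.DataFrame,
    features: Sequence[Feature],
    expression: pd.DataFrame | Mapping[str, int],
    length: int,
    anchor: Anchor,
    total_srna: int | None = None,
    sparse_threshold: int = 30,
    **profile_kwargs,
) -> StratifiedProfiles:
    """Per-expression-class sRNA accumulation profiles (shared normaliser)."""
    if total_srna is None:
        total_srna = len(reads)
    parts = _partition_features(features, expression)
    profiles = {
        cls: srna_profile(reads, feats, length, anchor, total_srna=total_srna, **profile_kwargs)
        for cls, feats in parts.items()
    }
    n = {cls: len(feats) for cls, feats in parts.items()}
    sparse = tuple(c for c in EXPRESSION_CLASSES if 0 < n[c] < sparse_threshold)
    return StratifiedProfiles(profiles=profiles, n_features=n, sparse_classes=sparse)


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n_bins: int
    n_perm: int
    seed: int
    region: tuple[int, int]


def _rebin_methylation(profile: MetageneProfile, bin_width: int) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate a metagene profile onto a coarser grid (site-weighted means)."""
    if bin_width % profile.bin_width:
        raise AlignmentError("target bin width must be a multiple of the profile's")
    factor = bin_width // profile.bin_width
    n = profile.n_bins // factor
    sums = profile.bin_sum[: n * factor].reshape(n, factor).sum(axis=1)
    counts = profile.bin_n[: n * factor].reshape(n, factor).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    offsets = profile.offsets[::factor][:n]
    return offsets, means


def coprofile_correlation(
    methyl_profile: MetageneProfile,
    srna_prof: SRNAProfile,
    region: tuple[int, int] = (-2000, 0),
    n_perm: int = 10000,
    seed: int = 0,
    alternative: str = "greater",
) -> CorrelationResult:
    """Rank correlation between methylation and sRNA tracks over a region.

    The methylation profile is re-binned onto the sRNA profile's (coarser)
    grid; Spearman's rho is computed over bins inside ``region`` where both
    tracks are defined, with a seeded bin-label permutation p-value.
    """
    offsets, meth = _rebin_methylation(methyl_profile, srna_prof.bin_width)
    if len(offsets) != len(srna_prof.offsets) or not np.array_equal(offsets, srna_prof.offsets):
        raise AlignmentError("profiles do not cover the same offset grid")
    lo, hi = region
    sel = (offsets >= lo) & (offsets < hi)
    x = meth[sel]
    y = srna_prof.bin_value[sel]
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise UndefinedValueError(f"only {len(x)} common bins in region {region}; need >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(np.nan, np.nan, len(x), n_perm, seed, region)
    rho = float(stats.spearmanr(x, y).statistic)
    # permutation null: permute one rank vector, rho = Pearson of ranks
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, len(x))), axis=1)
    perm_rho = (ry[order] @ rx) / len(x)
    if alternative == "greater":
        exceed = np.sum(perm_rho >= rho)
    elif alternative == "two-sided":
        exceed = np.sum(np.abs(perm_rho) >= abs(rho))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = float((1 + exceed) / (n_perm + 1))
    return CorrelationResult(rho, p, len(x), n_perm, seed, region)


@dataclass
class CHHIslandCall:
    """A contiguous run of upstream bins with dense CHH methylation."""

    start_offset: int
    end_offset: int
    mean_level: float
    background: float
    n_bins: int


def detect_chh_islands(
    chh_profile: MetageneProfile,
    enrichment: float = 2.0,
    min_width: int = 2,
    region: tuple[int, int] = (-2000, 0),
) -> list[CHHIslandCall]:
    """Call CHH islands in the upstream portion of a metagene profile.

    An island is a run of >= ``min_width`` contiguous defined bins whose
    mean exceeds ``enrichment`` × the median of all defined upstream bins.
    Calls are ordered by offset.
    """
    lo, hi = region
    sel = (chh_profile.offsets >= lo) & (chh_profile.offsets < hi)
    offsets = chh_profile.offsets[sel]
    means = chh_profile.bin_mean[sel]
    defined = chh_profile.bin_n[sel] > 0
    if not defined.any():
        return []
    background = float(np.median(means[defined]))
    above = defined & (means > enrichment * background)
    islands: list[CHHIslandCall] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if j - i + 1 >= min_width:
                run = means[i : j + 1]
                islands.append(
                    CHHIslandCall(
                        start_offset=int(offsets[i]),
                        end_offset=int(offsets[j] + chh_profile.bin_width),
                        mean_level=float(np.mean(run)),
                        background=background,
                        n_bins=j - i + 1,
                    )
                )
            i = j + 1
        else:
            i += 1
    return islands


def write_islands(islands: Sequence[CHHIslandCall], path) -> None:
    table = pd.DataFrame(
        [
            {
                "start_offset": isl.start_offset,
                "end_offset": isl.end_offset,
                "mean_level": round(isl.mean_level, 6),
                "background": round(isl.background, 6),
                "n_bins": isl.n_bins,
            }
            for isl in islands
        ],
        columns=["start_offset", "end_offset", "mean_level", "background", "n_bins"],
    )
    table.to_csv(str(path), sep="\t", index=False)
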