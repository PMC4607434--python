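"""Recovered-vs-planted evaluation of a synthetic pipeline run.

These helpers compare what the pipeline measures on a simulated dataset
against the generator's truth tables: bulk methylation per compartment,
planted DMR recall/precision, the +1-base CHH preference ratio, CHH-island
offsets and the expression-stratified TSS contrast.  They are used by the
end-to-end demo and by the acceptance machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylcalls import bulk_methylation, bulk_methylation_se, filter_coverage, site_fractions
from .simulate import MethylomeTruth


@dataclass
class BulkRecovery:
    estimate: float
    planted: float
    se: float

    @property
    def within_3se(self) -> bool:
        return abs(self.estimate - self.planted) <= 3 * self.se


def bulk_recovery(
    calls: pd.DataFrame,
    truth: MethylomeTruth,
    compartment: str,
    context: str,
    planted: float,
    exclude_planted_effects: bool = True,
) -> BulkRecovery:
    """Compare the read-weighted bulk estimate in one compartment to its target.

    Sites carrying planted local modifications (islands, TSS factors, DMR
    windows) are excluded by default so the comparison targets the
    compartment base level.  The SE is cluster-robust over sites, covering
    both read noise and the bimodal site-state sampling.
    """
    sites = truth.sites
    mask = (sites["compartment"] == compartment) & (sites["context"] == context)
    if exclude_planted_effects:
        mask &= ~(sites["is_island"] | sites["is_tss"] | sites["is_dmr"])
    key = sites.loc[mask, ["chrom", "pos", "strand"]]
    merged = calls.merge(key, on=["chrom", "pos", "strand"], how="inner")
    est = bulk_methylation(merged, context)
    se = bulk_methylation_se(merged, context)
    return BulkRecovery(estimate=est, planted=planted, se=se)


@dataclass
class DMRRecovery:
    recall: float
    precision: float
    n_truth: int
    n_called: int
    n_matched: int


def dmr_recovery(called: pd.DataFrame, truth: MethylomeTruth, context: str = "CG") -> DMRRecovery:
    """Recall/precision of called DMRs against planted windows.

    Truth units are (window, strand) pairs — a planted window affects the
    context's cytosines on both strands.  A called DMR matches a truth pair
    when chromosome, window start, strand, context and direction all agree.
    Precision is evaluated over called DMRs of the planted context.
    """
    planted = truth.dmr_windows
    truth_pairs = set()
    for row in planted.itertuples(index=False):
        for strand in ("+", "-"):
            truth_pairs.add((row.chrom, int(row.start), strand, row.context, row.direction))
    sub = called.loc[called["context"] == context]
    called_keys = [
        (row.chrom, int(row.start), row.strand, row.context, row.direction)
        for row in sub.itertuples(index=False)
    ]
    matched = sum(1 for key in called_keys if key in truth_pairs)
    recalled = len({key for key in called_keys if key in truth_pairs})
    n_truth = len(truth_pairs)
    recall = recalled / n_truth if n_truth else float("nan")
    precision = matched / len(called_keys) if called_keys else float("nan")
    return DMRRecovery(
        recall=recall, precision=precision,
        n_truth=n_truth, n_called=len(called_keys), n_matched=matched,
    )


@dataclass
class PreferenceRatio:
    ratio: float
    planted: float
    se: float

    @property
    def within_3se(self) -> bool:
        return abs(self.ratio - self.planted) <= 3 * self.se


def chh_preference_ratio(
    calls: pd.DataFrame,
    genome,
    position: int = 1,
    base_num: str = "A",
    base_den: str = "C",
    planted: float = 2.0,
    min_reads: int = 10,
) -> PreferenceRatio:
    """Ratio of mean CHH site methylation between two bases at a flank position.

    With the default arguments this is the CA_H / CC_H contrast: the planted
    preference multiplies the CHH rate by 2 for A versus C at +1 (and +2).
    The SE follows from the delta method on the two group means.
    """
    from .seqcontext import _sevenmer_matrix

    sub = filter_coverage(calls.loc[calls["context"] == "CHH"], min_reads).reset_index(drop=True)
    mat, valid = _sevenmer_matrix(genome, sub)
    sub = sub.loc[valid].reset_index(drop=True)
    col = mat[valid][:, position + 2]
    frac = site_fractions(sub).to_numpy(float)

    def _group(base):
        values = frac[col == ord(base)]
        return values.mean(), values.std(ddof=1) / np.sqrt(len(values))

    m_num, se_num = _group(base_num)
    m_den, se_den = _group(base_den)
    ratio = m_num / m_den
    se = ratio * np.sqrt((se_num / m_num) ** 2 + (se_den / m_den) ** 2)
    return PreferenceRatio(ratio=float(ratio), planted=planted, se=float(se))


def tss_contrast(stratified, region: tuple[int, int] = (-150, 150)) -> dict[int, float]:
    """Site-weighted mean methylation near the anchor per expression class."""
    out = {}
    for cls, profile in stratified.profiles.items():
        sel = (profile.offsets >= region[0]) & (profile.offsets < region[1])
        n = profile.bin_n[sel].sum()
        out[cls] = float(profile.bin_sum[sel].sum() / n) if n else float("nan")
    return out


def island_offsets_match(
    islands, expected: tuple, tolerance: int = 50
) -> bool:
    """True when called islands coincide with the planted offset intervals."""
    if len(islands) != len(expected):
        return False
    for isl, (a, b) in zip(islands, sorted(expected)):
        if abs(isl.start_offset - a) > tolerance or abs(isl.end_offset - b) > tolerance:
            return False
    return True
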