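"""Local-sequence (7-mer) methylation preference analysis.

Each covered cytosine is described by the strand-oriented 7-mer spanning
two bases upstream through four bases downstream of it (the cytosine sits
at index 2).  Grouping per-site methylation fractions by 7-mer, and
marginally by the base at each of the six flanking positions, quantifies
how the local sequence biases methylation — in maize seeds this effect is
essentially confined to the CHH context (e.g. CA_H sites are methylated
about twice as often as CC_H sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NotACytosineError, OutOfBoundsError
from .genome import _COMPLEMENT, _IS_ACGT, ReferenceGenome, _C, _G
from .methylcalls import filter_coverage, site_fractions

#: flanking positions of the 7-mer relative to the cytosine (index 2)
MARGINAL_POSITIONS = (-2, -1, 1, 2, 3, 4)
_KMER_OFFSETS = np.arange(-2, 5)  # window [-2, +4] around the C


def extract_sevenmer(
    genome: ReferenceGenome, contig: str, pos: int, strand: str
) -> str | None:
    """Strand-oriented 5'->3' 7-mer around the cytosine at (contig, pos, strand).

    Returns ``None`` when the window exits the contig or contains non-ACGT.
    """
    codes = genome.codes(contig)
    if not 0 <= pos < len(codes):
        raise OutOfBoundsError(f"position {pos} outside contig {contig!r}")
    if strand == "+":
        if codes[pos] != _C:
            raise NotACytosineError(f"{contig}:{pos}(+) is not a cytosine")
        if pos - 2 < 0 or pos + 4 >= len(codes):
            return None
        window = codes[pos - 2 : pos + 5]
    elif strand == "-":
        if codes[pos] != _G:
            raise NotACytosineError(f"{contig}:{pos}(-) is not a reverse-strand cytosine")
        if pos - 4 < 0 or pos + 2 >= len(codes):
            return None
        window = _COMPLEMENT[codes[pos - 4 : pos + 3]][::-1]
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if not _IS_ACGT[window].all():
        return None
    return window.tobytes().decode("ascii")


def _sevenmer_matrix(genome: ReferenceGenome, calls: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """7-mer byte matrix (n, 7) for each call; valid mask for in-bounds/ACGT."""
    n = len(calls)
    mat = np.zeros((n, 7), dtype=np.uint8)
    valid = np.zeros(n, dtype=bool)
    pos_all = calls["pos"].to_numpy(np.int64)
    plus = (calls["strand"] == "+").to_numpy()
    for chrom, idx in calls.groupby("chrom", observed=True).indices.items():
        codes = genome.codes(chrom)
        length = len(codes)
        p = pos_all[idx]
        is_plus = plus[idx]
        ok_p = is_plus & (p - 2 >= 0) & (p + 4 < length)
        ok_m = ~is_plus & (p - 4 >= 0) & (p + 2 < length)
        if ok_p.any():
            rows = idx[ok_p]
            gather = p[ok_p][:, None] + _KMER_OFFSETS[None, :]
            mat[rows] = codes[gather]
            valid[rows] = True
        if ok_m.any():
            rows = idx[ok_m]
            gather = p[ok_m][:, None] - _KMER_OFFSETS[None, :]
            mat[rows] = _COMPLEMENT[codes[gather]]
            valid[rows] = True
    valid &= _IS_ACGT[mat].all(axis=1)
    return mat, valid


@dataclass
class SevenMerPreferences:
    """Per-7-mer and per-position methylation preferences for one context.

    ``kmer_table`` columns: context, kmer, n_sites, mean_methylation
    (7-mers with fewer than ``min_sites`` sites are omitted from the table
    but still contribute to the marginals).  ``marginals`` is indexed by
    flanking position (−2, −1, +1, +2, +3, +4) with one column per base,
    each cell the mean site fraction over sites carrying that base there.
    """

    context: str
    kmer_table: pd.DataFrame
    marginals: pd.DataFrame
    n_sites: int


def sevenmer_preferences(
    calls: pd.DataFrame,
    genome: ReferenceGenome,
    context: str,
    min_reads: int = 10,
    min_sites: int = 10,
    method: str = "site",
) -> SevenMerPreferences:
    """Group covered cytosines of ``context`` by their 7-mer.

    ``method="site"`` (default) averages per-site fractions per 7-mer;
    ``"read"`` pools raw counts.  7-mers containing N or clipped by contig
    edges are excluded; both strands contribute after strand orientation.
    """
    sub = filter_coverage(calls.loc[calls["context"] == context], min_reads).reset_index(drop=True)
    mat, valid = _sevenmer_matrix(genome, sub)
    sub = sub.loc[valid].reset_index(drop=True)
    mat = mat[valid]
    frac = site_fractions(sub).to_numpy(float)
    kmers = (
        np.ascontiguousarray(mat).view(dtype="S7").ravel().astype("U7")
        if len(mat)
        else np.empty(0, dtype="U7")
    )
    table = pd.DataFrame({"kmer": kmers, "fraction": frac,
                          "n_meth": sub["n_meth"], "n_unmeth": sub["n_unmeth"]})
    if method == "site":
        grouped = table.groupby("kmer")["fraction"].agg(n_sites="count", mean_methylation="mean")
    elif method == "read":
        pooled = table.groupby("kmer").agg(
            n_sites=("fraction", "count"), m=("n_meth", "sum"), u=("n_unmeth", "sum")
        )
        pooled["mean_methylation"] = pooled["m"] / (pooled["m"] + pooled["u"])
        grouped = pooled[["n_sites", "mean_methylation"]]
    else:
        raise ValueError(f"unknown method {method!r}")
    kmer_table = (
        grouped.loc[grouped["n_sites"] >= min_sites]
        .reset_index()
        .assign(context=context)[["context", "kmer", "n_sites", "mean_methylation"]]
        .sort_values("kmer")
        .reset_index(drop=True)
    )
    # marginal mean methylation per flanking position x base, over all sites
    marg = pd.DataFrame(index=list(MARGINAL_POSITIONS), columns=list("ACGT"), dtype=float)
    marg.index.name = "position"
    for j, rel in enumerate(MARGINAL_POSITIONS):
        col = mat[:, rel + 2]
        for base in "ACGT":
            sel = col == ord(base)
            marg.loc[rel, base] = float(np.mean(frac[sel])) if sel.any() else np.nan
    return SevenMerPreferences(
        context=context, kmer_table=kmer_table, marginals=marg, n_sites=len(sub)
    )


def write_kmer_table(prefs: SevenMerPreferences, path) -> None:
    prefs.kmer_table.to_csv(str(path), sep="\t", index=False, float_format="%.6g")


def write_marginals(prefs: SevenMerPreferences, path) -> None:
    prefs.marginals.to_csv(str(path), sep="\t", float_format="%.6g")
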