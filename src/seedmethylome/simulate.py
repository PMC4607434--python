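"""Seeded generator of a miniature two-tissue seed methylome dataset.

The generator emulates the structure of an embryo/endosperm bisulfite
experiment at count level (the pipeline consumes call tables, so read-level
simulation would add nothing testable):

* a random ~46%-GC genome with four non-overlapping feature classes
  (protein-coding genes, pseudogenes, TEs, repeats), each with >= 2-kb
  flanks;
* per-cytosine true methylation rates built from compartment base levels
  (CG and CHG sites are bimodal — a site is either heavily methylated or
  essentially unmethylated, as in real plant methylomes — while CHH is
  uniformly low), modulated by: a multiplicative endosperm hypomethylation
  factor for CHG/CHH (and ~1.0 for CG), two planted upstream CHH islands
  per gene, a +1/+2 downstream-base preference multiplier for CHH
  (A twice the rate of C), a per-gene TSS-openness factor that later
  drives the expression link, and planted 50-bp CG DMR windows;
* binomial read counts at Poisson coverage per tissue;
* five-level expression with the TSS-methylation/expression inverse link
  obtained by ranking genes on their true TSS-region methylation;
* length-stratified sRNA reads mixing a uniform background with
  island-targeted gene-flank components (24-nt strongest in embryo) and
  expression-linked body components.

Per-site truth rates, planted DMR labels, island intervals and class
assignments are first-class outputs so every pipeline stage has an oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SizingError
from .genome import Feature, FeatureClass, ReferenceGenome, cytosine_table, write_features_gff3
from .methylcalls import CALL_COLUMNS, write_calls
from .srna_expression import write_expression, write_srna_bed

TISSUES = ("embryo", "endosperm")

_GENE = FeatureClass.PROTEIN_CODING_GENE.value
_PSEUDO = FeatureClass.PSEUDOGENE.value
_TE = FeatureClass.TRANSPOSABLE_ELEMENT.value
_REPEAT = FeatureClass.REPEAT.value
_INTERGENIC = "intergenic"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic dataset; defaults define the study conditions."""

    seed: int = 0
    genome_size: int = 1_000_000
    gc_content: float = 0.46
    contig_name: str = "chr1"

    n_features: dict = field(
        default_factory=lambda: {_GENE: 60, _PSEUDO: 20, _TE: 40, _REPEAT: 40}
    )
    feature_length: dict = field(
        default_factory=lambda: {
            _GENE: (2000, 4000),
            _PSEUDO: (1500, 3000),
            _TE: (1000, 3000),
            _REPEAT: (500, 2000),
        }
    )
    min_flank: int = 2000
    max_extra_gap: int = 400

    coverage_mean: float = 10.0
    #: compartment base methylation levels per context
    rates: dict = field(
        default_factory=lambda: {
            _GENE: {"CG": 0.60, "CHG": 0.20, "CHH": 0.05},
            _PSEUDO: {"CG": 0.75, "CHG": 0.45, "CHH": 0.075},
            _TE: {"CG": 0.90, "CHG": 0.70, "CHH": 0.10},
            _REPEAT: {"CG": 0.90, "CHG": 0.70, "CHH": 0.10},
            _INTERGENIC: {"CG": 0.80, "CHG": 0.50, "CHH": 0.02},
        }
    )
    #: bimodal site states for CG/CHG: heavily methylated vs essentially unmethylated
    high_rate: float = 0.95
    low_rate: float = 0.02
    #: multiplicative endosperm hypomethylation per context
    endosperm_factor: dict = field(
        default_factory=lambda: {"CG": 1.0, "CHG": 0.85, "CHH": 0.70}
    )
    #: two upstream CHH islands per protein-coding gene (strand-oriented offsets)
    island_offsets: tuple = ((-1500, -1300), (-400, -200))
    island_rate: float = 0.25
    #: CHH rate multiplier by downstream base at +1 and +2 (normalised to mean 1)
    seqpref: dict = field(default_factory=lambda: {"A": 2.0, "C": 1.0, "T": 1.0})
    #: per-gene TSS-openness factor applied to all contexts within +/- tss_window
    tss_window: int = 300
    tss_factor_range: tuple = (0.2, 1.5)
    #: planted CG DMR windows
    dmr_n_windows: int = 100
    dmr_window_size: int = 50
    dmr_rate_high: float = 0.95
    dmr_rate_low: float = 0.45
    dmr_context: str = "CG"
    dmr_min_sites: int = 3

    expression_proportions: tuple = (0.25, 0.25, 0.20, 0.20, 0.10)
    rpkm_class_ranges: tuple = ((0.0, 0.0), (0.05, 1.0), (1.0, 10.0), (10.0, 100.0), (100.0, 1000.0))
    library_size: int = 10_000_000

    srna_total: int = 80_000
    srna_length_props: dict = field(
        default_factory=lambda: {21: 0.18, 22: 0.18, 23: 0.14, 24: 0.50}
    )
    #: per-tissue multiplier on per-length read totals (21-23 nt higher in endosperm)
    srna_length_tissue_factor: dict = field(
        default_factory=lambda: {
            "embryo": {21: 0.8, 22: 0.8, 23: 0.8, 24: 1.2},
            "endosperm": {21: 1.2, 22: 1.2, 23: 1.2, 24: 0.85},
        }
    )
    srna_flank_frac_24: dict = field(
        default_factory=lambda: {"embryo": 0.40, "endosperm": 0.15}
    )
    srna_flank_frac_other: float = 0.12
    srna_gene_end_frac: float = 0.10
    srna_gene_body_frac: float = 0.08
    srna_tepg_frac: float = 0.10


@dataclass
class MethylomeTruth:
    """Ground-truth per-site rates and planted-effect labels."""

    sites: pd.DataFrame          # chrom,pos,strand,context,compartment,rate_embryo,
                                 # rate_endosperm,is_island,is_tss,is_dmr
    dmr_windows: pd.DataFrame    # chrom,start,end,direction
    tss_factors: pd.DataFrame    # feature_id,factor
    island_offsets: tuple
    island_rate: float


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: ReferenceGenome
    features: list
    truth: MethylomeTruth
    calls: dict                  # tissue -> call DataFrame
    expression: pd.DataFrame
    srna: dict                   # tissue -> sRNA read DataFrame


class SeedMethylomeSimulator:
    """Deterministic generator; all randomness flows from ``config.seed``."""

    def __init__(self, config: SimulationConfig | None = None):
        self.config = config or SimulationConfig()
        self._genome: ReferenceGenome | None = None
        self._features: list[Feature] | None = None
        self._truth: MethylomeTruth | None = None

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.config.seed) % (2**31), stream])

    # ---------------------------------------------------------------- genome

    def simulate_genome(self) -> tuple[ReferenceGenome, list[Feature]]:
        cfg = self.config
        rng = self._rng(1)
        probs = [(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
                 cfg.gc_content / 2, (1 - cfg.gc_content) / 2]
        bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=cfg.genome_size, p=probs)
        seq = bases.tobytes().decode("ascii")

        specs: list[tuple[str, int]] = []
        for fclass, n in cfg.n_features.items():
            lo, hi = cfg.feature_length[fclass]
            lengths = rng.integers(lo, hi + 1, size=n)
            specs.extend((fclass, int(length)) for length in lengths)
        rng.shuffle(specs)

        features: list[Feature] = []
        counters: dict[str, int] = {}
        pos = cfg.min_flank
        for fclass, length in specs:
            pos += int(rng.integers(0, cfg.max_extra_gap + 1))
            start, end = pos, pos + length
            if end + cfg.min_flank > cfg.genome_size:
                raise SizingError(
                    f"genome of {cfg.genome_size} bp too small for requested features "
                    f"with {cfg.min_flank}-bp flanks (failed at {start})"
                )
            counters[fclass] = counters.get(fclass, 0) + 1
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                Feature(
                    id=f"{fclass}_{counters[fclass]:04d}",
                    feature_class=FeatureClass(fclass),
                    contig=cfg.contig_name,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
            pos = end + cfg.min_flank
        genome = ReferenceGenome({cfg.contig_name: seq})
        self._genome, self._features = genome, features
        self._truth = None
        return genome, features

    # ----------------------------------------------------------------- truth

    def _island_intervals(self, feat: Feature) -> list[tuple[int, int]]:
        out = []
        for a, b in self.config.island_offsets:
            if feat.strand == "+":
                out.append((feat.start + a, feat.start + b))
            else:
                out.append((feat.end - b, feat.end - a))
        return out

    def _tss_interval(self, feat: Feature) -> tuple[int, int]:
        tw = self.config.tss_window
        if feat.strand == "+":
            return (feat.start - tw, feat.start + tw)
        return (feat.end - tw, feat.end + tw)

    def _build_truth(self, genome: ReferenceGenome, features: Sequence[Feature]) -> MethylomeTruth:
        cfg = self.config
        rng = self._rng(2)
        table = cytosine_table(genome)
        pos = table["pos"].to_numpy(np.int64)
        strand_plus = (table["strand"] == "+").to_numpy()
        ctx = table["context"].to_numpy()
        L = cfg.genome_size

        comp = np.full(L, _INTERGENIC, dtype=object)
        for feat in features:
            comp[feat.start : feat.end] = feat.feature_class.value
        site_comp = comp[pos]

        # per-gene TSS-openness factor (shared across contexts and tissues);
        # for bimodal CG/CHG sites it scales the probability of the
        # methylated state (sites stay bimodal, as at real plant TSSs),
        # for CHH it scales the rate directly
        genes = [f for f in features if f.feature_class is FeatureClass.PROTEIN_CODING_GENE]
        tss_factor_arr = np.ones(L, dtype=float)
        factors = rng.uniform(*cfg.tss_factor_range, size=len(genes))
        tss_mask = np.zeros(L, dtype=bool)
        for feat, factor in zip(genes, factors):
            a, b = self._tss_interval(feat)
            tss_factor_arr[max(a, 0) : max(b, 0)] = factor
            tss_mask[max(a, 0) : max(b, 0)] = True
        is_tss = tss_mask[pos]
        site_tssf = tss_factor_arr[pos]

        # base rates: bimodal for CG/CHG, uniform low level for CHH
        rate = np.empty(len(table), dtype=float)
        span = cfg.high_rate - cfg.low_rate
        uniform = rng.random(len(table))
        chh = ctx == "CHH"
        p_high = np.zeros(len(table))
        for compartment, levels in cfg.rates.items():
            in_comp = site_comp == compartment
            for context in ("CG", "CHG"):
                sel = in_comp & (ctx == context)
                if span > 0:
                    p_high[sel] = np.clip((levels[context] - cfg.low_rate) / span, 0.0, 1.0)
            sel = in_comp & chh
            rate[sel] = levels["CHH"]
        p_high = np.clip(p_high * site_tssf, 0.0, 1.0)
        bimodal = ~chh
        rate[bimodal] = np.where(uniform[bimodal] < p_high[bimodal], cfg.high_rate, cfg.low_rate)

        # planted upstream CHH islands (protein-coding genes only)
        island_mask = np.zeros(L, dtype=bool)
        for feat in genes:
            for a, b in self._island_intervals(feat):
                island_mask[max(a, 0) : max(b, 0)] = True
        is_island = island_mask[pos] & chh
        rate[is_island] = cfg.island_rate

        # CHH local-sequence preference by the +1/+2 downstream bases
        rate *= self._seqpref_multiplier(genome, pos, strand_plus, ctx)
        rate[chh] *= site_tssf[chh]

        rate_embryo = rate.copy()
        factor_by_ctx = np.array(
            [cfg.endosperm_factor[c] for c in ("CG", "CHG", "CHH")]
        )
        ctx_code = np.select([ctx == "CG", ctx == "CHG"], [0, 1], default=2)
        rate_endosperm = rate * factor_by_ctx[ctx_code]

        # planted DMR windows in the configured context
        dmr_windows = self._plant_dmr_windows(rng, pos, strand_plus, ctx, island_mask | tss_mask)
        dmr_dir = np.zeros(L, dtype=np.int8)
        for row in dmr_windows.itertuples(index=False):
            dmr_dir[row.start : row.end] = 1 if row.direction == "hyper_in_embryo" else 2
        site_dir = dmr_dir[pos] * (ctx == cfg.dmr_context)
        rate_embryo[site_dir == 1] = cfg.dmr_rate_high
        rate_endosperm[site_dir == 1] = cfg.dmr_rate_low
        rate_embryo[site_dir == 2] = cfg.dmr_rate_low
        rate_endosperm[site_dir == 2] = cfg.dmr_rate_high
        is_dmr = site_dir > 0

        n_clipped = int(np.sum(rate_embryo > 1) + np.sum(rate_endosperm > 1))
        if n_clipped:
            warnings.warn(f"{n_clipped} site rates clipped to [0, 1]")
        np.clip(rate_embryo, 0.0, 1.0, out=rate_embryo)
        np.clip(rate_endosperm, 0.0, 1.0, out=rate_endosperm)

        sites = table.assign(
            compartment=site_comp,
            rate_embryo=rate_embryo,
            rate_endosperm=rate_endosperm,
            is_island=is_island,
            is_tss=is_tss,
            is_dmr=is_dmr,
        )
        tss_factors = pd.DataFrame({"feature_id": [f.id for f in genes], "factor": factors})
        return MethylomeTruth(
            sites=sites,
            dmr_windows=dmr_windows,
            tss_factors=tss_factors,
            island_offsets=cfg.island_offsets,
            island_rate=cfg.island_rate,
        )

    def _seqpref_multiplier(
        self, genome: ReferenceGenome, pos: np.ndarray,
        strand_plus: np.ndarray, ctx: np.ndarray,
    ) -> np.ndarray:
        """Normalised +1/+2 base multiplier for CHH sites (mean 1 by design)."""
        cfg = self.config
        codes = genome.codes(cfg.contig_name)
        mult = np.ones(len(pos), dtype=float)
        chh = ctx == "CHH"
        if not chh.any():
            return mult
        p_at = (1 - cfg.gc_content) / 2
        p_c = cfg.gc_content / 2
        denom = 2 * p_at + p_c
        expected = (
            cfg.seqpref["A"] * p_at + cfg.seqpref["T"] * p_at + cfg.seqpref["C"] * p_c
        ) / denom
        lut = np.ones(256, dtype=float)
        for base, value in cfg.seqpref.items():
            lut[ord(base)] = value / expected
        comp_lut = np.zeros(256, dtype=np.uint8)
        for x, y in zip(b"ACGT", b"TGCA"):
            comp_lut[x] = y
        p = pos[chh]
        plus = strand_plus[chh]
        b1 = np.where(plus, codes[np.minimum(p + 1, len(codes) - 1)], comp_lut[codes[np.maximum(p - 1, 0)]])
        b2 = np.where(plus, codes[np.minimum(p + 2, len(codes) - 1)], comp_lut[codes[np.maximum(p - 2, 0)]])
        mult[chh] = lut[b1] * lut[b2]
        return mult

    def _plant_dmr_windows(
        self, rng: np.random.Generator, pos: np.ndarray,
        strand_plus: np.ndarray, ctx: np.ndarray, excluded: np.ndarray,
    ) -> pd.DataFrame:
        cfg = self.config
        w = cfg.dmr_window_size
        starts = np.arange(0, cfg.genome_size - w + 1, w, dtype=np.int64)
        in_ctx = ctx == cfg.dmr_context
        pos_p = np.sort(pos[in_ctx & strand_plus])
        pos_m = np.sort(pos[in_ctx & ~strand_plus])
        n_p = np.searchsorted(pos_p, starts + w) - np.searchsorted(pos_p, starts)
        n_m = np.searchsorted(pos_m, starts + w) - np.searchsorted(pos_m, starts)
        excl_cum = np.concatenate([[0], np.cumsum(excluded.astype(np.int64))])
        touched = (excl_cum[starts + w] - excl_cum[starts]) > 0
        eligible = (n_p >= cfg.dmr_min_sites) & (n_m >= cfg.dmr_min_sites) & ~touched
        candidates = starts[eligible]
        if len(candidates) < cfg.dmr_n_windows:
            raise SizingError(
                f"only {len(candidates)} eligible windows for {cfg.dmr_n_windows} planted DMRs"
            )
        chosen = np.sort(rng.choice(candidates, size=cfg.dmr_n_windows, replace=False))
        direction = np.where(
            rng.random(cfg.dmr_n_windows) < 0.5, "hyper_in_embryo", "hyper_in_endosperm"
        )
        return pd.DataFrame(
            {
                "chrom": cfg.contig_name,
                "start": chosen,
                "end": chosen + w,
                "context": cfg.dmr_context,
                "direction": direction,
            }
        )

    # ------------------------------------------------------------- methylome

    def _ensure(self) -> tuple[ReferenceGenome, list[Feature], MethylomeTruth]:
        if self._genome is None or self._features is None:
            self.simulate_genome()
        if self._truth is None:
            self._truth = self._build_truth(self._genome, self._features)
        return self._genome, self._features, self._truth

    @property
    def truth(self) -> MethylomeTruth:
        return self._ensure()[2]

    def simulate_methylome(self, tissue: str) -> pd.DataFrame:
        """Binomial call table for one tissue at Poisson coverage."""
        if tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {tissue!r}")
        _, _, truth = self._ensure()
        cfg = self.config
        rng = self._rng(10 + TISSUES.index(tissue))
        rates = truth.sites[f"rate_{tissue}"].to_numpy()
        coverage = rng.poisson(cfg.coverage_mean, size=len(rates))
        n_meth = rng.binomial(coverage, rates)
        calls = pd.DataFrame(
            {
                "chrom": truth.sites["chrom"],
                "pos": truth.sites["pos"],
                "strand": truth.sites["strand"],
                "context": truth.sites["context"],
                "n_meth": n_meth,
                "n_unmeth": coverage - n_meth,
            }
        )
        return calls.loc[coverage > 0, CALL_COLUMNS].reset_index(drop=True)

    # ------------------------------------------------------------ expression

    def simulate_expression(self) -> pd.DataFrame:
        """Five-level expression; genes ranked so TSS methylation is inverse to class."""
        genome, features, truth = self._ensure()
        cfg = self.config
        rng = self._rng(20)
        props = np.asarray(cfg.expression_proportions, dtype=float)
        props = props / props.sum()

        rows = []
        genes = [f for f in features if f.feature_class is FeatureClass.PROTEIN_CODING_GENE]
        others = [
            f for f in features
            if f.feature_class in (FeatureClass.PSEUDOGENE, FeatureClass.TRANSPOSABLE_ELEMENT)
        ]
        # true TSS-region methylation per gene, from the planted site rates
        sites = truth.sites
        tss_meth = []
        for feat in genes:
            a, b = self._tss_interval(feat)
            sel = (sites["pos"] >= a) & (sites["pos"] < b)
            tss_meth.append(float(sites.loc[sel, "rate_embryo"].mean()))
        order = np.argsort(tss_meth, kind="mergesort")  # ascending methylation
        counts = self._class_counts(len(genes), props)
        gene_class = np.empty(len(genes), dtype=int)
        taken = 0
        for cls, n_cls in zip((5, 4, 3, 2, 1), counts[::-1]):
            gene_class[order[taken : taken + n_cls]] = cls
            taken += n_cls
        for feat, cls in zip(genes, gene_class):
            rows.append((feat, int(cls)))
        for feat in others:
            rows.append((feat, int(rng.choice([1, 2, 3, 4, 5], p=props))))

        records = []
        for feat, cls in rows:
            lo, hi = cfg.rpkm_class_ranges[cls - 1]
            if hi <= 0:
                value = 0.0
            else:
                value = float(np.exp(rng.uniform(np.log(max(lo, 1e-3)), np.log(hi))))
            read_count = int(np.rint(value * feat.length * cfg.library_size / 1e9))
            records.append(
                {
                    "feature_id": feat.id,
                    "feature_class": feat.feature_class.value,
                    "read_count": read_count,
                    "feature_length": feat.length,
                    "true_rpkm": value,
                    "true_class": cls,
                }
            )
        return pd.DataFrame(records)

    @staticmethod
    def _class_counts(n: int, props: np.ndarray) -> np.ndarray:
        counts = np.floor(props * n).astype(int)
        remainder = props * n - counts
        for idx in np.argsort(-remainder)[: n - counts.sum()]:
            counts[idx] += 1
        return counts

    # ------------------------------------------------------------------ sRNA

    def simulate_srna(self, tissue: str, expression: pd.DataFrame | None = None) -> pd.DataFrame:
        """Length-stratified sRNA reads: background + flank + expression-linked parts."""
        if tissue not in TISSUES:
            raise ValueError(f"tissue must be one of {TISSUES}, got {tissue!r}")
        genome, features, _ = self._ensure()
        cfg = self.config
        rng = self._rng(30 + TISSUES.index(tissue))
        L = cfg.genome_size
        genes = [f for f in features if f.feature_class is FeatureClass.PROTEIN_CODING_GENE]
        tepg = [
            f for f in features
            if f.feature_class in (FeatureClass.TRANSPOSABLE_ELEMENT, FeatureClass.PSEUDOGENE)
        ]
        class_of = (
            dict(zip(expression["feature_id"], expression["true_class"]))
            if expression is not None else {}
        )
        gene_w = np.array([class_of.get(f.id, 3) for f in genes], dtype=float)
        tepg_w = np.array([6 - class_of.get(f.id, 3) for f in tepg], dtype=float)
        gene_w /= gene_w.sum() if gene_w.sum() else 1
        tepg_w /= tepg_w.sum() if tepg_w.sum() else 1

        all_rows = []
        for length, prop in sorted(cfg.srna_length_props.items()):
            factor = cfg.srna_length_tissue_factor[tissue][length]
            n_reads = int(round(cfg.srna_total * prop * factor))
            flank_frac = (
                cfg.srna_flank_frac_24[tissue] if length == 24 else cfg.srna_flank_frac_other
            )
            n_flank = int(round(n_reads * flank_frac))
            n_end = int(round(n_reads * cfg.srna_gene_end_frac))
            n_body = int(round(n_reads * cfg.srna_gene_body_frac))
            n_tepg = int(round(n_reads * cfg.srna_tepg_frac))
            n_bg = n_reads - n_flank - n_end - n_body - n_tepg

            anchors = [rng.integers(0, L, size=n_bg)]
            anchors.append(self._flank_positions(rng, genes, n_flank))
            anchors.append(self._gene_end_positions(rng, genes, n_end))
            anchors.append(self._body_positions(rng, genes, gene_w, n_body))
            anchors.append(self._tepg_positions(rng, tepg, tepg_w, n_tepg))
            anchor_pos = np.concatenate(anchors)
            strands = np.where(rng.random(len(anchor_pos)) < 0.5, "+", "-")
            start = np.where(strands == "+", anchor_pos, anchor_pos - (length - 1))
            start = np.clip(start, 0, L - length)
            all_rows.append(
                pd.DataFrame(
                    {
                        "chrom": cfg.contig_name,
                        "start": start.astype(np.int64),
                        "end": (start + length).astype(np.int64),
                        "strand": strands,
                        "length": length,
                    }
                )
            )
        reads = pd.concat(all_rows, ignore_index=True)
        return reads.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)

    def _flank_positions(self, rng, genes, n) -> np.ndarray:
        """Island-targeted upstream positions plus a small downstream component."""
        if not genes or n == 0:
            return np.empty(0, dtype=np.int64)
        comp = rng.choice(3, size=n, p=[0.25, 0.65, 0.10])  # island1, island2, downstream
        gidx = rng.integers(0, len(genes), size=n)
        out = np.empty(n, dtype=np.int64)
        for i in range(n):
            feat = genes[gidx[i]]
            if comp[i] < 2:
                a, b = self._island_intervals(feat)[comp[i]]
            else:  # just past the 3' end
                if feat.strand == "+":
                    a, b = feat.end + 200, feat.end + 400
                else:
                    a, b = feat.start - 400, feat.start - 200
            out[i] = rng.integers(max(a, 0), max(b, 1))
        return out

    def _gene_end_positions(self, rng, genes, n) -> np.ndarray:
        if not genes or n == 0:
            return np.empty(0, dtype=np.int64)
        gidx = rng.integers(0, len(genes), size=n)
        use_tss = rng.random(n) < 0.5
        out = np.empty(n, dtype=np.int64)
        for i in range(n):
            feat = genes[gidx[i]]
            center = feat.tss if use_tss[i] else feat.tts
            out[i] = rng.integers(max(center - 300, 0), center + 300)
        return out

    def _body_positions(self, rng, feats, weights, n) -> np.ndarray:
        if not feats or n == 0:
            return np.empty(0, dtype=np.int64)
        fidx = rng.choice(len(feats), size=n, p=weights)
        out = np.empty(n, dtype=np.int64)
        for i in range(n):
            feat = feats[fidx[i]]
            out[i] = rng.integers(feat.start, feat.end)
        return out

    def _tepg_positions(self, rng, feats, weights, n) -> np.ndarray:
        """TE/pseudogene component: half in-body, half upstream (-500..0)."""
        if not feats or n == 0:
            return np.empty(0, dtype=np.int64)
        fidx = rng.choice(len(feats), size=n, p=weights)
        upstream = rng.random(n) < 0.5
        out = np.empty(n, dtype=np.int64)
        for i in range(n):
            feat = feats[fidx[i]]
            if upstream[i]:
                if feat.strand == "+":
                    a, b = feat.start - 500, feat.start
                else:
                    a, b = feat.end, feat.end + 500
            else:
                a, b = feat.start, feat.end
            out[i] = rng.integers(max(a, 0), max(b, 1))
        return out

    # --------------------------------------------------------------- dataset

    def simulate_dataset(self) -> SyntheticDataset:
        genome, features, truth = self._ensure()
        calls = {tissue: self.simulate_methylome(tissue) for tissue in TISSUES}
        expression = self.simulate_expression()
        srna = {tissue: self.simulate_srna(tissue, expression) for tissue in TISSUES}
        return SyntheticDataset(
            config=self.config, genome=genome, features=features,
            truth=truth, calls=calls, expression=expression, srna=srna,
        )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the same formats the pipeline reads, plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    dataset.genome.to_fasta(paths["genome"])
    paths["features"] = outdir / "features.gff3"
    write_features_gff3(dataset.features, paths["features"])
    for tissue, calls in dataset.calls.items():
        paths[f"calls_{tissue}"] = outdir / f"calls_{tissue}.tsv"
        write_calls(calls, paths[f"calls_{tissue}"])
    for tissue, reads in dataset.srna.items():
        paths[f"srna_{tissue}"] = outdir / f"srna_{tissue}.bed"
        write_srna_bed(reads, paths[f"srna_{tissue}"])
    paths["expression"] = outdir / "expression.tsv"
    write_expression(dataset.expression, paths["expression"])
    dataset.truth.sites.to_csv(truth_dir / "sites.tsv", sep="\t", index=False, float_format="%.6g")
    dataset.truth.dmr_windows.to_csv(truth_dir / "dmr_windows.tsv", sep="\t", index=False)
    dataset.truth.tss_factors.to_csv(
        truth_dir / "tss_factors.tsv", sep="\t", index=False, float_format="%.6g"
    )
    return paths
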