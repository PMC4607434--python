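"""Pipeline orchestration: configuration, manifests and the end-to-end demo.

The demo generates a synthetic two-tissue dataset, runs every analysis
stage on the files it wrote (bulk statistics, methylation distributions,
DMR calling and summary, metagene profiles for all four feature classes,
7-mer preferences, sRNA accumulation, expression classification,
stratified profiles, CHH islands and the methylation–sRNA correlation),
and writes a recovered-versus-planted report.  Outputs carry a manifest
(parameters, seed, input checksums) and are byte-identical across repeat
runs with the same seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import dmr as dmr_mod
from . import integrate, metagene, methylcalls, recovery, seqcontext, srna_expression
from .genome import FeatureClass, ReferenceGenome, read_features
from .simulate import (
    SeedMethylomeSimulator,
    SimulationConfig,
    TISSUES,
    write_dataset,
)

#: keys accepted in a pipeline configuration file
KNOWN_CONFIG_KEYS = {
    "genome", "features", "calls_embryo", "calls_endosperm",
    "srna_embryo", "srna_endosperm", "expression", "outdir",
    "seed", "genome_size", "min_reads", "window_size", "step",
    "min_delta", "min_coverage", "bin_width", "srna_bin_width",
    "class_bounds", "enrichment", "min_width", "n_perm",
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a YAML pipeline configuration; unknown keys rejected."""
    import yaml

    with open(path) as handle:
        config = yaml.safe_load(handle) or {}
    if not isinstance(config, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(config) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return config


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(
    outdir: Path, stage: str, params: Mapping[str, Any], inputs: Mapping[str, str | Path]
) -> Path:
    """Record provenance (parameters, input checksums, version) for a stage run."""
    manifest = {
        "stage": stage,
        "version": __version__,
        "params": {k: params[k] for k in sorted(params)},
        "inputs": {
            name: {"file": Path(p).name, "sha256": _sha256(Path(p))}
            for name, p in sorted(inputs.items())
        },
    }
    path = Path(outdir) / f"manifest_{stage}.json"
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return path


def _round_json(obj):
    if isinstance(obj, dict):
        return {k: _round_json(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_json(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        value = float(obj)
        return None if np.isnan(value) else round(value, 6)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def run_demo(
    seed: int,
    outdir: str | Path,
    genome_size: int | None = None,
    n_perm: int = 10000,
) -> dict[str, Any]:
    """Generate a dataset, run every stage and write a recovery report.

    Returns the report dictionary (also written as ``report.json``).
    """
    outdir = Path(outdir)
    data_dir = outdir / "data"
    results = outdir / "results"
    results.mkdir(parents=True, exist_ok=True)

    sim_kwargs = {"seed": int(seed)}
    if genome_size is not None:
        sim_kwargs["genome_size"] = int(genome_size)
        scale = genome_size / SimulationConfig().genome_size
        if scale < 1:
            base = SimulationConfig()
            sim_kwargs["n_features"] = {
                k: max(2, int(round(v * scale))) for k, v in base.n_features.items()
            }
            sim_kwargs["dmr_n_windows"] = max(5, int(round(base.dmr_n_windows * scale)))
            sim_kwargs["srna_total"] = max(2000, int(round(base.srna_total * scale)))
    config = SimulationConfig(**sim_kwargs)
    simulator = SeedMethylomeSimulator(config)
    dataset = simulator.simulate_dataset()
    paths = write_dataset(dataset, data_dir)

    # ------------------------------------------------------------ re-read inputs
    genome = ReferenceGenome.from_fasta(paths["genome"])
    features = read_features(paths["features"])
    calls = {t: methylcalls.read_calls(paths[f"calls_{t}"]) for t in TISSUES}
    srna = {t: srna_expression.read_srna_bed(paths[f"srna_{t}"]) for t in TISSUES}
    expr_input = srna_expression.read_expression(paths["expression"])
    by_class = {
        fc: [f for f in features if f.feature_class is fc] for fc in FeatureClass
    }
    genes = by_class[FeatureClass.PROTEIN_CODING_GENE]

    # ---------------------------------------------------------------- bulk stats
    bulk_rows = []
    for tissue in TISSUES:
        filtered = methylcalls.filter_coverage(calls[tissue], 10)
        for context in ("CG", "CHG", "CHH"):
            bulk_rows.append(
                {
                    "tissue": tissue,
                    "context": context,
                    "bulk_read_weighted": methylcalls.bulk_methylation(filtered, context),
                    "bulk_site_mean": methylcalls.bulk_methylation(filtered, context, "site"),
                }
            )
    bulk = pd.DataFrame(bulk_rows)
    bulk.to_csv(results / "bulk.tsv", sep="\t", index=False, float_format="%.6g")

    dist_rows = []
    for tissue in TISSUES:
        for context in ("CG", "CHG", "CHH"):
            dist = methylcalls.methylation_distribution(calls[tissue], context)
            for edge, frac in zip(dist.bin_edges[:-1], dist.bin_fractions):
                dist_rows.append(
                    {"tissue": tissue, "context": context, "bin_start_pct": int(edge),
                     "fraction": frac}
                )
    pd.DataFrame(dist_rows).to_csv(
        results / "distributions.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # ----------------------------------------------------------------- DMR stage
    lengths = genome.lengths
    dmr_frames = []
    for context in ("CG", "CHG", "CHH"):
        for strand in ("+", "-"):
            win = {
                t: dmr_mod.window_fractions(calls[t], context, strand, contig_lengths=lengths)
                for t in TISSUES
            }
            dmr_frames.append(dmr_mod.call_dmrs(win["embryo"], win["endosperm"]))
    dmrs = pd.concat(dmr_frames, ignore_index=True)
    dmr_mod.write_dmrs_bed(dmrs, results / "dmrs.bed")
    summary = dmr_mod.summarize_dmrs(dmrs)
    summary.to_csv(results / "dmr_summary.tsv", sep="\t", index=False)

    # ----------------------------------------------------------------- metagene
    meta_rows = []
    meta_profiles = {}
    for fc in FeatureClass:
        feats = by_class[fc]
        if not feats:
            continue
        for context in ("CG", "CHG", "CHH"):
            for anchor in ("five_prime", "three_prime"):
                prof = {
                    t: metagene.metagene_profile(calls[t], feats, anchor, context)
                    for t in TISSUES
                }
                meta_profiles[(fc, context, anchor)] = prof
                diff = metagene.compare_profiles(prof["embryo"], prof["endosperm"])
                for i, off in enumerate(prof["embryo"].offsets):
                    meta_rows.append(
                        {
                            "feature_class": fc.value, "context": context, "anchor": anchor,
                            "offset_start": int(off),
                            "mean_embryo": prof["embryo"].bin_mean[i],
                            "n_embryo": int(prof["embryo"].bin_n[i]),
                            "mean_endosperm": prof["endosperm"].bin_mean[i],
                            "n_endosperm": int(prof["endosperm"].bin_n[i]),
                            "difference": diff[i],
                        }
                    )
    pd.DataFrame(meta_rows).to_csv(
        results / "metagene.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # -------------------------------------------------------- 7-mer preferences
    for context in ("CG", "CHG", "CHH"):
        prefs = seqcontext.sevenmer_preferences(calls["embryo"], genome, context)
        seqcontext.write_kmer_table(prefs, results / f"sevenmer_{context}.tsv")
        seqcontext.write_marginals(prefs, results / f"sevenmer_marginals_{context}.tsv")
    pref = recovery.chh_preference_ratio(calls["embryo"], genome)

    # ------------------------------------------------------------ sRNA profiles
    srna_rows = []
    srna_profiles = {}
    for tissue in TISSUES:
        total = len(srna[tissue])
        for fc in (FeatureClass.PROTEIN_CODING_GENE, FeatureClass.TRANSPOSABLE_ELEMENT):
            for length in (21, 22, 23, 24):
                prof = srna_expression.srna_profile(
                    srna[tissue], by_class[fc], length, "five_prime", total_srna=total
                )
                srna_profiles[(tissue, fc, length)] = prof
                for i, off in enumerate(prof.offsets):
                    srna_rows.append(
                        {
                            "tissue": tissue, "feature_class": fc.value, "length": length,
                            "offset_start": int(off), "percent": prof.bin_value[i],
                            "n_reads": int(prof.bin_count[i]),
                        }
                    )
    pd.DataFrame(srna_rows).to_csv(
        results / "srna_profiles.tsv", sep="\t", index=False, float_format="%.6g"
    )

    # ------------------------------------------------------- expression classes
    expr = srna_expression.expression_table(expr_input, total_mapped=config.library_size)
    srna_expression.write_expression(expr, results / "expression_classes.tsv")

    # ------------------------------------------------------------- integration
    strat = {
        context: integrate.stratified_metagene(
            calls["embryo"], genes, expr, context, "five_prime"
        )
        for context in ("CG", "CHG", "CHH")
    }
    strat_rows = []
    for context, stratified in strat.items():
        for cls, prof in stratified.profiles.items():
            for i, off in enumerate(prof.offsets):
                strat_rows.append(
                    {
                        "context": context, "expr_class": cls, "offset_start": int(off),
                        "mean": prof.bin_mean[i], "n": int(prof.bin_n[i]),
                    }
                )
    pd.DataFrame(strat_rows).to_csv(
        results / "stratified_metagene.tsv", sep="\t", index=False, float_format="%.6g"
    )

    chh_prof = meta_profiles[(FeatureClass.PROTEIN_CODING_GENE, "CHH", "five_prime")]["embryo"]
    islands = integrate.detect_chh_islands(chh_prof)
    integrate.write_islands(islands, results / "chh_islands.tsv")

    srna24 = srna_profiles[("embryo", FeatureClass.PROTEIN_CODING_GENE, 24)]
    corr = integrate.coprofile_correlation(chh_prof, srna24, n_perm=n_perm, seed=int(seed))
    pd.DataFrame(
        [
            {
                "region_start": corr.region[0], "region_end": corr.region[1],
                "rho": round(corr.rho, 6), "n_bins": corr.n_bins,
                "p_perm": round(corr.p_value, 6), "n_perm": corr.n_perm, "seed": corr.seed,
            }
        ]
    ).to_csv(results / "coprofile_correlation.tsv", sep="\t", index=False)

    # ------------------------------------------------------------- truth report
    truth = simulator.truth
    bulk_by = {(r["tissue"], r["context"]): r["bulk_read_weighted"] for r in bulk_rows}
    te_recovery = {
        context: recovery.bulk_recovery(
            methylcalls.filter_coverage(calls["embryo"], 1), truth,
            "transposable_element", context,
            config.rates["transposable_element"][context],
        )
        for context in ("CG", "CHG", "CHH")
    }
    dmr_rec = recovery.dmr_recovery(dmrs, truth)
    tss = {
        context: recovery.tss_contrast(strat[context]) for context in ("CG", "CHG", "CHH")
    }
    report = {
        "seed": int(seed),
        "genome_size": config.genome_size,
        "bulk": {f"{t}_{c}": bulk_by[(t, c)] for t in TISSUES for c in ("CG", "CHG", "CHH")},
        "checks": {
            "context_ordering_both_tissues": all(
                bulk_by[(t, "CG")] > bulk_by[(t, "CHG")] > bulk_by[(t, "CHH")]
                for t in TISSUES
            ),
            "endosperm_hypomethylated_chg_chh": all(
                bulk_by[("endosperm", c)] < bulk_by[("embryo", c)] for c in ("CHG", "CHH")
            ),
            "cg_difference_small": abs(
                bulk_by[("embryo", "CG")] - bulk_by[("endosperm", "CG")]
            ) < 0.02,
            "te_bulk_within_3se": {
                c: te_recovery[c].within_3se for c in ("CG", "CHG", "CHH")
            },
            "dmr_recall": dmr_rec.recall,
            "dmr_precision": dmr_rec.precision,
            "chh_preference_ratio": pref.ratio,
            "chh_preference_within_3se": pref.within_3se,
            "n_chh_islands": len(islands),
            "island_offsets_match": recovery.island_offsets_match(
                islands, truth.island_offsets
            ),
            "tss_class5_below_class1": {
                c: tss[c][5] < tss[c][1] for c in ("CG", "CHG", "CHH")
            },
            "upstream_chh_srna_rho": corr.rho,
            "upstream_chh_srna_p": corr.p_value,
        },
    }
    report = _round_json(report)
    with open(results / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
        handle.write("\n")
    write_manifest(
        results, "demo",
        {"seed": int(seed), "genome_size": config.genome_size, "n_perm": n_perm},
        {name: path for name, path in paths.items()},
    )
    return report
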