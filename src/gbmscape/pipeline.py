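"""End-to-end orchestration: simulate -> call DMRs -> metagene -> overlap ->
enrichment, with a machine-readable run manifest.

A run is driven by a single YAML config (validated against a fixed key
schema); every stage parameter — including defaulted ones such as the
100-bp tile size or the 0.01 FDR — is recorded in the manifest, and a
rerun with the same config reproduces identical outputs byte for byte.

The run's enrichment statistic asks, on the run's own data: are the genes
overlapped by hypo-CG-DMRs enriched among the highly expressed (top two
quintiles)?  With the default simulation, where knockdown CG loss grows
with expression, this should be strongly significant.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import dmr as dmr_mod
from .dmr import DmrParams, call_dmrs
from .enrichment import gene_set_enrichment, overlap_fraction
from .errors import GbmscapeError, ValidationError
from .io import read_bed, read_cytosine_report, read_expression_table, read_chrom_sizes
from .metagene import (
    MethylationSource,
    QUINTILE_LABELS,
    differential_profile,
    expression_quintile_grouping,
    metagene,
)
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

_TOP_LEVEL_KEYS = {"seed", "simulation", "dmr", "metagene", "n_kd_replicates", "tracks"}
_DMR_KEYS = set(DmrParams.__dataclass_fields__) | {"context"}
_METAGENE_KEYS = {"n_bins_body", "n_bins_flank", "min_fpkm", "relative_mode"}


def load_config(path) -> dict:
    """Load and validate a pipeline YAML config; unknown keys error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def validate_config(raw: dict) -> dict:
    if not isinstance(raw, dict):
        raise ValidationError("pipeline config must be a mapping")
    bad = set(raw) - _TOP_LEVEL_KEYS
    if bad:
        raise ValidationError(f"unknown config keys: {sorted(bad)}")
    bad = set(raw.get("dmr", {})) - _DMR_KEYS
    if bad:
        raise ValidationError(f"unknown dmr config keys: {sorted(bad)}")
    bad = set(raw.get("metagene", {})) - _METAGENE_KEYS
    if bad:
        raise ValidationError(f"unknown metagene config keys: {sorted(bad)}")
    cfg = {
        "seed": int(raw.get("seed", 0)),
        "simulation": dict(raw.get("simulation", {})),
        "dmr": dict(raw.get("dmr", {})),
        "metagene": dict(raw.get("metagene", {})),
        "n_kd_replicates": int(raw.get("n_kd_replicates", 2)),
        "tracks": bool(raw.get("tracks", False)),
    }
    cfg["simulation"].setdefault("seed", cfg["seed"])
    SimulationConfig.from_dict(cfg["simulation"])  # validate early
    return cfg


def run_pipeline(config: dict | str | Path, out_dir) -> dict:
    """Run every stage in dependency order; returns the manifest dict.

    ``config`` is either a validated config mapping or a YAML path.
    Outputs land under ``out_dir``: data/ (synthetic inputs), dmrs.bed,
    metagene_*.tsv, summary-ready stats, and manifest.json.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_config = SimulationConfig.from_dict(config["simulation"])
    manifest: dict = {
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config["seed"],
        "stages": {},
        "outputs": {},
        "counts": {},
    }

    # -- stage 1: simulate ------------------------------------------------
    data_dir = out / "data"
    sim_manifest = simulate_dataset(sim_config, data_dir,
                                    n_kd_replicates=config["n_kd_replicates"],
                                    tracks=config["tracks"])
    manifest["stages"]["simulate"] = {"config": sim_config.to_dict(),
                                      "files": sim_manifest["files"]}

    genes = read_bed(data_dir / "genes.bed", kind="gene")
    tes = read_bed(data_dir / "tes.bed", kind="TE")
    h33 = read_bed(data_dir / "h33.bed", kind="h33_region")
    expr = read_expression_table(data_dir / "expr.tsv")
    chrom_sizes = read_chrom_sizes(data_dir / "chrom.sizes")
    wt = read_cytosine_report(data_dir / "wt.cx.tsv")
    kds = [
        read_cytosine_report(data_dir / f"kd_rep{i + 1}.cx.tsv")
        for i in range(config["n_kd_replicates"])
    ]

    # -- stage 2: DMR calling --------------------------------------------
    dmr_cfg = dict(config["dmr"])
    context = dmr_cfg.pop("context", "CG")
    params = DmrParams(**dmr_cfg)
    dmrs, details = call_dmrs(wt, kds, chrom_sizes, context, params,
                              return_details=True)
    dmr_mod.write_dmrs(dmrs, out / "dmrs.bed")
    manifest["stages"]["dmr"] = {"params": asdict(params), "context": context}
    manifest["counts"]["tiles_tested_per_rep"] = [r.n_tested for r in details]
    manifest["counts"]["tiles_selected"] = int(
        len(dmr_mod.select_hypo_tiles(details, params))
    )
    manifest["counts"]["n_dmrs"] = len(dmrs)
    manifest["outputs"]["dmrs"] = "dmrs.bed"

    # -- stage 3: metagene profiles --------------------------------------
    mg_cfg = config["metagene"]
    nb = int(mg_cfg.get("n_bins_body", 40))
    nf = int(mg_cfg.get("n_bins_flank", 20))
    min_fpkm = mg_cfg.get("min_fpkm", 0.5)
    grouping = expression_quintile_grouping(expr, genes, min_fpkm=min_fpkm)
    wt_prof = metagene(MethylationSource(wt, context), genes, grouping,
                       nb, nf, chrom_sizes, group_order=list(QUINTILE_LABELS))
    kd_pooled = kds[0]
    if len(kds) > 1:
        import pandas as pd
        kd_pooled = pd.concat(kds, ignore_index=True)
    kd_prof = metagene(MethylationSource(kd_pooled, context), genes, grouping,
                       nb, nf, chrom_sizes, group_order=list(QUINTILE_LABELS))
    mode = mg_cfg.get("relative_mode", "difference")
    diff = differential_profile(kd_prof, wt_prof, mode=mode)
    wt_prof.write_tsv(out / "metagene_wt.tsv")
    kd_prof.write_tsv(out / "metagene_kd.tsv")
    diff.write_tsv(out / "metagene_kd_vs_wt.tsv")
    manifest["stages"]["metagene"] = {
        "n_bins_body": nb, "n_bins_flank": nf,
        "min_fpkm": min_fpkm, "relative_mode": mode,
    }
    manifest["counts"]["genes_profiled"] = int(wt_prof.n_genes.sum())
    manifest["outputs"]["metagene"] = [
        "metagene_wt.tsv", "metagene_kd.tsv", "metagene_kd_vs_wt.tsv"
    ]

    # -- stage 4: overlap + enrichment stats ------------------------------
    stats: dict = {"n_dmrs": len(dmrs)}
    dmr_ivs = [d.interval for d in dmrs]
    if dmrs:
        stats["frac_dmrs_in_gene_bodies"] = overlap_fraction(dmr_ivs, genes)
        stats["frac_dmrs_in_h33_regions"] = overlap_fraction(dmr_ivs, h33)
        stats["frac_tes_overlapped"] = overlap_fraction(dmr_ivs, tes, by="target")
        hit_genes = {
            g.id for g in genes
            if overlap_fraction([g], dmr_ivs) > 0
        }
        population = [g.id for g in genes]
        quint_all = {g.id: q for g, q in
                     ((g, grouping.get(g.id)) for g in genes) if q is not None}
        successes = [gid for gid, q in quint_all.items() if q in ("Q4", "Q5")]
        if hit_genes and successes:
            enr = gene_set_enrichment(hit_genes, successes, population)
            stats["enrichment"] = {
                "N": enr.population_size, "K": enr.population_successes,
                "n": enr.sample_size, "k": enr.sample_successes,
                "p_upper": enr.p_upper,
            }
            stats["enrichment_p"] = enr.p_upper
        else:
            stats["enrichment_p"] = None
    else:
        stats["frac_dmrs_in_gene_bodies"] = None
        stats["frac_dmrs_in_h33_regions"] = None
        stats["frac_tes_overlapped"] = None
        stats["enrichment_p"] = None
    manifest["stages"]["stats"] = stats

    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest["outputs"]["stats"] = "stats.json"

    # checksums of every produced file
    checksums = {}
    for rel in ["dmrs.bed", "metagene_wt.tsv", "metagene_kd.tsv",
                "metagene_kd_vs_wt.tsv", "stats.json"]:
        checksums[rel] = hashlib.sha256((out / rel).read_bytes()).hexdigest()
    manifest["checksums"] = checksums

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def summarize(run_dir) -> str:
    """Build the run's TSV summary (returned as a string and written to
    summary.tsv): DMR count, annotation-overlap fractions, enrichment p.

    Undefined fractions (zero DMRs) are reported as NA, not 0.
    """
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    stats_path = run / "stats.json"
    if not manifest_path.exists() or not stats_path.exists():
        raise GbmscapeError(f"{run_dir} does not contain a completed run "
                            "(manifest.json / stats.json missing)")
    with open(stats_path) as fh:
        stats = json.load(fh)

    def fmt(x):
        if x is None:
            return "NA"
        if isinstance(x, float):
            return f"{x:.6g}"
        return str(x)

    rows = [
        ("n_dmrs", fmt(stats.get("n_dmrs"))),
        ("frac_dmrs_in_gene_bodies", fmt(stats.get("frac_dmrs_in_gene_bodies"))),
        ("frac_dmrs_in_h33_regions", fmt(stats.get("frac_dmrs_in_h33_regions"))),
        ("frac_tes_overlapped", fmt(stats.get("frac_tes_overlapped"))),
        ("enrichment_p", fmt(stats.get("enrichment_p"))),
    ]
    text = "".join(f"{k}\t{v}\n" for k, v in rows)
    with open(run / "summary.tsv", "w") as fh:
        fh.write(text)
    return text
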