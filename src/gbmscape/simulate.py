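"""Synthetic epigenome generator.

Emulates, at desk scale, the statistical structure of a plant
leaf methylome and its histone-variant knockdown: 3'-biased gene-body CG
methylation whose amplitude depends non-monotonically on expression
quintile (highest over expressed but not the most highly expressed genes),
TE methylation in all three contexts that the knockdown leaves untouched,
expression-correlated genic CG loss in the knockdown, and
knockdown-specific H1/H2A.Z gain over gene bodies.

No nucleotide sequence is generated: cytosine positions, strands and
contexts are sampled directly, which is all the downstream modules consume.

Randomness protocol: every operation derives its generator from
``numpy.random.SeedSequence(seed, spawn_key=(domain, index))`` with fixed
integer domains (0 = annotation, 1 = cytosine positions, 2 = methylome
sample, 3 = track), so replicates are independent but reproducible, and a
fixed config yields byte-identical files across runs and platforms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .io import (
    CYTOSINE_COLUMNS,
    GenomicInterval,
    SignalTrack,
    write_bed,
    write_bedgraph,
    write_chrom_sizes,
    write_cytosine_report,
    write_expression_table,
)
from .metagene import QUINTILE_LABELS, assign_quintiles

FACTORS = ("H1", "H2A.Z", "H3K4me3", "H3K36me3")
CONDITIONS = ("WT", "kd")

_DOMAIN_ANNOTATION = 0
_DOMAIN_POSITIONS = 1
_DOMAIN_METHYLOME = 2
_DOMAIN_TRACK = 3


@dataclass
class SimulationConfig:
    """Shape and effect-size parameters of the synthetic epigenome.

    Defaults describe the study conditions every test runs under: a
    2 x 500-kb genome carrying 200 genes, WGBS-like coverage of 30 calls
    per cytosine, peak genic CG methylation 0.9 reached at the TES of the
    middle expression quintiles, and knockdown CG loss that grows with
    expression while TE methylation is untouched.
    """

    seed: int = 0
    # genome / annotation shape
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1_000, 4_000)
    n_tes: int = 100
    te_length_range: tuple[int, int] = (500, 3_000)
    # cytosine landscape
    cytosine_density: dict = field(
        default_factory=lambda: {"CG": 0.04, "CHG": 0.03, "CHH": 0.08}
    )
    coverage_mean: float = 30.0
    # WT gene-body CG methylation: wt_gbm_max * weight(quintile) * relpos^ramp
    wt_gbm_max: float = 0.9
    gbm_quintile_weights: tuple[float, ...] = (0.2, 0.5, 1.0, 1.0, 0.7)
    ramp_exponent: float = 1.0
    # knockdown: genic CG probability multiplied by (1 - loss_fraction(quintile))
    kd_loss_fraction: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)
    # TE methylation per context (identical in WT and kd)
    te_meth: dict = field(
        default_factory=lambda: {"CG": 0.85, "CHG": 0.35, "CHH": 0.10}
    )
    background_meth: float = 0.02
    # expression
    fpkm_zero_fraction: float = 0.10
    fpkm_log_mean: float = 1.0
    fpkm_log_sigma: float = 1.2
    # chromatin tracks (intensities are expected read starts per base)
    track_bin_size: int = 10
    track_baseline: float = 0.5
    h1_intergenic: float = 4.0
    h1_body_depletion: float = 0.7     # per quintile step below intergenic
    h1_gain: tuple[float, ...] = (0.2, 0.5, 1.0, 1.5, 2.0)
    h2az_peak: float = 6.0
    h2az_gain: tuple[float, ...] = (0.2, 0.5, 1.0, 1.5, 2.0)

    def __post_init__(self):
        for name, v in (("wt_gbm_max", self.wt_gbm_max),
                        ("background_meth", self.background_meth)):
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be a probability, got {v}")
        for ctx, v in self.te_meth.items():
            if not 0 <= v <= 1:
                raise ValidationError(f"te_meth[{ctx}] must be a probability, got {v}")
        for name, vec in (("gbm_quintile_weights", self.gbm_quintile_weights),
                          ("kd_loss_fraction", self.kd_loss_fraction),
                          ("h1_gain", self.h1_gain), ("h2az_gain", self.h2az_gain)):
            if len(vec) != 5:
                raise ValidationError(f"{name} needs 5 entries (one per quintile)")
            if any(x < 0 for x in vec):
                raise ValidationError(f"{name} entries must be non-negative")
        w = self.gbm_quintile_weights
        if int(np.argmax(w)) == 4:
            raise ValidationError(
                "gbm_quintile_weights must peak strictly before Q5 "
                "(gene-body methylation is highest over expressed, not the "
                "most highly expressed, genes)"
            )
        if any(f > 1 for f in self.kd_loss_fraction):
            raise ValidationError("kd_loss_fraction entries must be <= 1")
        if self.coverage_mean < 0:
            raise ValidationError("coverage_mean must be >= 0")
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValidationError("genome shape must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("gene_length_range", "te_length_range", "gbm_quintile_weights",
                    "kd_loss_fraction", "h1_gain", "h2az_gain"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ValidationError(f"unknown simulation config keys: {sorted(bad)}")
        d = dict(d)
        for key in ("gene_length_range", "te_length_range", "gbm_quintile_weights",
                    "kd_loss_fraction", "h1_gain", "h2az_gain"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class Annotation:
    """Simulated annotation bundle shared by methylome and track samplers."""

    genes: list[GenomicInterval]
    tes: list[GenomicInterval]
    h33_regions: list[GenomicInterval]
    expression: dict[str, float]
    chrom_sizes: dict[str, int]
    quintile: dict[str, str]  # gene id -> Q1..Q5, computed over all genes

    def quintile_index(self, gene_id: str) -> int:
        return QUINTILE_LABELS.index(self.quintile[gene_id])


def _rng(config: SimulationConfig, domain: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config.seed, spawn_key=(domain, index))
    )


def _place_features(rng, chrom_sizes, lengths, max_retries: int = 100):
    """Place non-overlapping features of the given lengths uniformly.

    Features are assigned to chromosomes proportionally to length, their
    order shuffled, and the free space split into random gaps, which is
    uniform over packings and always succeeds when the features fit.
    """
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    for _ in range(max_retries):
        assign = rng.choice(len(chroms), size=len(lengths), p=sizes / sizes.sum())
        ok = all(
            lengths[assign == ci].sum() <= chrom_sizes[chroms[ci]]
            for ci in range(len(chroms))
        )
        if ok:
            break
    else:
        raise ValidationError(
            "could not pack features into the genome; reduce counts or lengths"
        )
    placements = [None] * len(lengths)
    for ci, chrom in enumerate(chroms):
        idx = np.flatnonzero(assign == ci)
        if idx.size == 0:
            continue
        perm = rng.permutation(idx)
        free = chrom_sizes[chrom] - int(lengths[perm].sum())
        # split free space into len(perm)+1 gaps, uniformly
        cuts = np.sort(rng.integers(0, free + 1, size=len(perm)))
        gaps = np.diff(np.concatenate(([0], cuts, [free])))
        pos = 0
        for j, fi in enumerate(perm):
            pos += int(gaps[j])
            placements[fi] = (chrom, pos, pos + int(lengths[fi]))
            pos += int(lengths[fi])
    return placements


def simulate_annotation(config: SimulationConfig) -> Annotation:
    """Draw genes, TEs, H3.3-enriched regions and an FPKM table.

    H3.3 regions are the 3' two-thirds of genes in the top three expression
    quintiles, mirroring the variant's TES-proximal, transcription-linked
    enrichment.
    """
    rng = _rng(config, _DOMAIN_ANNOTATION)
    n_feat = config.n_genes + config.n_tes
    lengths = np.concatenate([
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1,
                     size=config.n_genes),
        rng.integers(config.te_length_range[0], config.te_length_range[1] + 1,
                     size=config.n_tes),
    ]) if n_feat else np.empty(0, dtype=int)
    placements = _place_features(rng, config.chrom_sizes, lengths) if n_feat else []
    strands = rng.choice(["+", "-"], size=n_feat)
    genes, tes = [], []
    for i in range(config.n_genes):
        chrom, start, end = placements[i]
        genes.append(GenomicInterval(chrom, start, end, strands[i],
                                     f"g{i + 1:04d}", "gene"))
    for i in range(config.n_tes):
        chrom, start, end = placements[config.n_genes + i]
        tes.append(GenomicInterval(chrom, start, end, strands[config.n_genes + i],
                                   f"te{i + 1:04d}", "TE"))
    genes.sort(key=lambda g: (g.chrom, g.start))
    tes.sort(key=lambda t: (t.chrom, t.start))

    zero = rng.random(config.n_genes) < config.fpkm_zero_fraction
    fpkm = np.where(
        zero, 0.0,
        np.round(rng.lognormal(config.fpkm_log_mean, config.fpkm_log_sigma,
                               size=config.n_genes), 4),
    )
    expression = {g.id: float(v) for g, v in zip(genes, fpkm)}
    quintile = assign_quintiles(expression, [g.id for g in genes]) if genes else {}

    h33 = []
    for g in genes:
        if quintile[g.id] in ("Q3", "Q4", "Q5"):
            third = g.length // 3
            if g.strand == "+":
                iv = GenomicInterval(g.chrom, g.start + third, g.end, g.strand,
                                     f"h33_{g.id}", "h33_region")
            else:
                iv = GenomicInterval(g.chrom, g.start, g.end - third, g.strand,
                                     f"h33_{g.id}", "h33_region")
            h33.append(iv)
    return Annotation(genes=genes, tes=tes, h33_regions=h33, expression=expression,
                      chrom_sizes=dict(config.chrom_sizes), quintile=quintile)


def simulate_cytosine_positions(annotation: Annotation, config: SimulationConfig) -> pd.DataFrame:
    """Sample the genome's cytosine positions, strands and contexts.

    Positions are fixed by the (virtual) genome and therefore shared by
    every condition and replicate.  Returns a frame with columns
    (chrom, pos, strand, context), 1-based positions, sorted by position
    within chromosome.
    """
    rng = _rng(config, _DOMAIN_POSITIONS)
    frames = []
    for chrom, size in annotation.chrom_sizes.items():
        for context, density in config.cytosine_density.items():
            n = rng.binomial(size, min(density, 1.0))
            pos0 = np.sort(rng.choice(size, size=n, replace=False))
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": pos0 + 1,
                "strand": rng.choice(["+", "-"], size=n),
                "context": context,
            }))
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return out


def _true_probabilities(positions: pd.DataFrame, annotation: Annotation,
                        config: SimulationConfig, condition: str) -> np.ndarray:
    """Per-cytosine true methylation probability for one condition."""
    if condition not in CONDITIONS:
        raise ValidationError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    prob = np.full(len(positions), config.background_meth)
    pos0 = positions["pos"].to_numpy() - 1
    chrom_arr = positions["chrom"].to_numpy()
    ctx_arr = positions["context"].to_numpy()
    # TE methylation, all contexts, identical between conditions
    for te in annotation.tes:
        mask = (chrom_arr == te.chrom) & (pos0 >= te.start) & (pos0 < te.end)
        for context, level in config.te_meth.items():
            prob[mask & (ctx_arr == context)] = level
    # genic CG ramp toward the TES
    weights = np.asarray(config.gbm_quintile_weights)
    loss = np.asarray(config.kd_loss_fraction)
    is_cg = ctx_arr == "CG"
    for g in annotation.genes:
        mask = is_cg & (chrom_arr == g.chrom) & (pos0 >= g.start) & (pos0 < g.end)
        if not mask.any():
            continue
        centers = pos0[mask] + 0.5
        relpos = (centers - g.start) / g.length if g.strand == "+" else (g.end - centers) / g.length
        qi = annotation.quintile_index(g.id)
        p = config.wt_gbm_max * weights[qi] * relpos ** config.ramp_exponent
        if condition == "kd":
            p = p * (1.0 - loss[qi])
        prob[mask] = p
    return np.clip(prob, 0.0, 1.0)


def simulate_methylome(annotation: Annotation, config: SimulationConfig,
                       condition: str = "WT", replicate: int = 0,
                       positions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Draw a cytosine call table for one condition/replicate.

    Per cytosine the call total is Poisson(coverage_mean) and the
    methylated count Binomial(total, true probability).  Positions come
    from :func:`simulate_cytosine_positions` (shared across samples).
    """
    if positions is None:
        positions = simulate_cytosine_positions(annotation, config)
    prob = _true_probabilities(positions, annotation, config, condition)
    stream = CONDITIONS.index(condition) * 16 + replicate
    rng = _rng(config, _DOMAIN_METHYLOME, stream)
    total = rng.poisson(config.coverage_mean, size=len(positions))
    n_meth = rng.binomial(total, prob)
    out = positions.copy()
    out["n_meth"] = n_meth
    out["n_unmeth"] = total - n_meth
    return out[list(CYTOSINE_COLUMNS)]


def expected_gene_body_loss(annotation: Annotation, config: SimulationConfig) -> dict[str, float]:
    """Analytic mean WT-minus-kd CG methylation probability per gene body.

    This is the planted effect size the DMR caller is meant to recover;
    it depends only on the config, not on sampled counts.
    """
    weights = np.asarray(config.gbm_quintile_weights)
    loss = np.asarray(config.kd_loss_fraction)
    mean_ramp = 1.0 / (config.ramp_exponent + 1.0)  # integral of x^e over [0,1]
    out = {}
    for g in annotation.genes:
        qi = annotation.quintile_index(g.id)
        out[g.id] = float(config.wt_gbm_max * weights[qi] * mean_ramp * loss[qi])
    return out


def _track_intensity(annotation: Annotation, config: SimulationConfig,
                     factor: str, condition: str) -> dict[str, np.ndarray]:
    """Expected read starts per base for one factor/condition."""
    if factor not in FACTORS:
        raise ValidationError(f"unknown factor {factor!r}; expected one of {FACTORS}")
    if condition not in CONDITIONS:
        raise ValidationError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    lam = {c: np.full(s, config.track_baseline) for c, s in annotation.chrom_sizes.items()}
    h1_gain = np.asarray(config.h1_gain)
    h2az_gain = np.asarray(config.h2az_gain)
    if factor == "H1":
        for c in lam:
            lam[c][:] = config.h1_intergenic
    for g in annotation.genes:
        vec = lam[g.chrom]
        qi = annotation.quintile_index(g.id)
        L = g.length
        rel = np.arange(L) / L
        if g.strand == "-":
            rel = rel[::-1]
        body = slice(g.start, g.end)
        if factor == "H1":
            # linker histone: depleted over transcribed bodies, invading in kd
            vec[body] = max(config.h1_intergenic - config.h1_body_depletion * qi,
                            config.track_baseline)
            if condition == "kd":
                vec[body] += h1_gain[qi]
        elif factor == "H2A.Z":
            vec[body] += config.h2az_peak * (rel < 0.15)
            if condition == "kd":
                vec[body] = vec[body] + h2az_gain[qi] * rel
        elif factor == "H3K4me3":
            vec[body] += 8.0 * (0.2 + 0.2 * qi) * (rel < 0.10)
        elif factor == "H3K36me3":
            vec[body] += 3.0 * (0.25 + 0.25 * qi)
    return lam


def simulate_track(annotation: Annotation, config: SimulationConfig,
                   factor: str, condition: str = "WT") -> SignalTrack:
    """Draw a read-count coverage track for one chromatin factor.

    Counts are Poisson with the factor-specific intensity, drawn per
    fixed-size bin (default 10 bp; a sum of per-base Poisson draws is the
    same Poisson), and the track's ``total_reads`` is the summed count,
    ready for counts-per-million normalization.
    """
    lam = _track_intensity(annotation, config, factor, condition)
    stream = FACTORS.index(factor) * 8 + CONDITIONS.index(condition)
    rng = _rng(config, _DOMAIN_TRACK, stream)
    data = {}
    total = 0
    bs = config.track_bin_size
    for chrom, vec in lam.items():
        n_bins = int(np.ceil(vec.size / bs))
        pad = n_bins * bs - vec.size
        binned = np.concatenate([vec, np.zeros(pad)]).reshape(n_bins, bs).sum(axis=1)
        counts = rng.poisson(binned)
        total += int(counts.sum())
        perbase = np.repeat(counts.astype(float), bs)[:vec.size]
        data[chrom] = perbase
    return SignalTrack(data=data, total_reads=max(total, 1))


def simulate_dataset(config: SimulationConfig, out_dir,
                     n_kd_replicates: int = 2, tracks: bool = True) -> dict:
    """Write a complete synthetic dataset and return its manifest.

    Emits genes.bed, tes.bed, h33.bed, expr.tsv, chrom.sizes, wt.cx.tsv,
    kd_rep*.cx.tsv, tracks/<factor>_<condition>.bedgraph and manifest.json
    (seeds, config hash, per-track read totals, file checksums).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    positions = simulate_cytosine_positions(annotation, config)

    write_bed(annotation.genes, out / "genes.bed")
    write_bed(annotation.tes, out / "tes.bed")
    write_bed(annotation.h33_regions, out / "h33.bed")
    write_expression_table(annotation.expression, out / "expr.tsv")
    write_chrom_sizes(annotation.chrom_sizes, out / "chrom.sizes")

    files = ["genes.bed", "tes.bed", "h33.bed", "expr.tsv", "chrom.sizes"]
    wt = simulate_methylome(annotation, config, "WT", 0, positions)
    write_cytosine_report(wt, out / "wt.cx.tsv")
    files.append("wt.cx.tsv")
    for rep in range(n_kd_replicates):
        kd = simulate_methylome(annotation, config, "kd", rep, positions)
        name = f"kd_rep{rep + 1}.cx.tsv"
        write_cytosine_report(kd, out / name)
        files.append(name)

    track_totals = {}
    if tracks:
        (out / "tracks").mkdir(exist_ok=True)
        for factor in FACTORS:
            for condition in CONDITIONS:
                track = simulate_track(annotation, config, factor, condition)
                safe = factor.replace(".", "")
                name = f"tracks/{safe}_{condition}.bedgraph"
                write_bedgraph(track, out / name)
                track_totals[name] = track.total_reads
                files.append(name)

    def _sha(path):
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_kd_replicates": n_kd_replicates,
        "track_total_reads": track_totals,
        "files": {f: _sha(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
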