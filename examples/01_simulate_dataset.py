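"""Generate a synthetic epigenome dataset on disk.

Writes annotation (genes, TEs, H3.3-enriched regions), an FPKM table, WT
and two knockdown cytosine-call reports, and chromatin coverage tracks,
all from one seed.  The printed counts describe the simulated genome.
"""

from pathlib import Path

from gbmscape import SimulationConfig, simulate_dataset

out = Path("scratch/example_dataset")
config = SimulationConfig(seed=11, n_chroms=1, chrom_length=200_000,
                          n_genes=50, n_tes=25)
manifest = simulate_dataset(config, out, n_kd_replicates=2, tracks=True)

print(f"dataset written to {out} (config hash {manifest['config_hash']})")
print(f"files: {len(manifest['files'])}")
for name, reads in sorted(manifest["track_total_reads"].items()):
    print(f"  {name}: {reads:,} simulated reads")
print("Each cytosine report row is (chrom, pos, strand, #C, #T, context);")
print("the knockdown replicates share true methylation probabilities but")
print("are independent sequencing draws.")
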