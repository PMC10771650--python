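#!/usr/bin/env python
"""Generate the synthetic study: genome, annotation, retina-style TPM
matrix, cohort VCF with planted variants, evidence tables, capture
designs, gene panel and case metadata — all with machine-readable truth.

Writes results/simulated/ (seed 7; rerunning reproduces identical bytes).
"""
from pathlib import Path

from fiveutr.synthetic_data import SimulationConfig, generate_all

OUT = Path("results/simulated")

if __name__ == "__main__":
    world = generate_all(SimulationConfig(seed=7), OUT)
    print(f"wrote {OUT}/: {len(world.genes)} genes on "
          f"{len(world.chrom_seqs)} chromosomes, {len(world.plants)} planted "
          f"variants, {len(world.cases)} cases")
    print("spliced 5'UTR canonical transcripts:",
          sum(g.spliced_canonical for g in world.genes))
    print("genes with planted enriched non-canonical isoform:",
          sum(g.expected_enriched for g in world.genes))
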