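"""Generate a synthetic multi-cell-type world and inspect its structure.

The world is one random chromosome shared by several cell types: a fixed
motif is planted at every candidate site, each cell binds each site with
probability p_bind, decoy motif occurrences are never bound, and each cell's
signal track has a Gaussian bump at its own bound sites.
"""

import tempfile
from pathlib import Path

from tftf import WorldConfig, ansr_difficulty, generate

config = WorldConfig(
    genome_length=200_000,
    n_cell_types=4,
    n_sites=30,
    n_decoys=15,
    p_bind=0.6,
    seed=7,
)
world = generate(config)

print(f"genome: {len(world.genome['chr1']):,} bp, motif: {config.motif}")
for cell in world.cells:
    n = len(world.peaks_by_cell[cell])
    print(f"  {cell}: {n} bound sites of {config.n_sites}")
print(f"decoy motif occurrences (never bound): {config.n_decoys}")
print(f"cross-cell-inconsistent sites: {ansr_difficulty(world)}")
print("  (sites bound in some but not all cells - the pool ANSR negatives",
      "come from when one cell is held out)")

with tempfile.TemporaryDirectory() as tmp:
    world.write(tmp)
    files = sorted(p.name for p in Path(tmp).iterdir())
    print(f"world serializes to: {', '.join(files)}")
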