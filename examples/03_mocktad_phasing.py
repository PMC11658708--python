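"""Mocktad reconstruction: recovering octad information from a tetrad.

When post-meiotic mother/daughter separation is impractical, whole
spore colonies of an MMR-deficient cross are sequenced instead: markers
with ~50:50 mixed reads are heteroduplex. Splitting each mixed call
into a strand pair rebuilds a pseudo-octad ("mocktad"), and a
resequenced single colony restores the mother/daughter strand polarity.
This script verifies the reconstruction against the true octad.
"""

import numpy as np

import meiomap as mm
from meiomap.genotyping import (
    assemble_octad,
    build_mocktad,
    calls_to_matrices,
    phase_with_colony,
)

genome = mm.yeast_genome()
marker_map = mm.generate_marker_map(genome, mean_spacing=169.0,
                                    indel_fraction=0.0, seed=1)
params = mm.SimParams(seed=7, mmr="deficient", multi_dsb_rate=0.0,
                      min_event_sep=7000.0)
matrices, _ = mm.simulate_meiosis(marker_map, genome, params)

# route 1: true octad (8 single-strand samples)
oc = mm.emit_site_counts(matrices, depth_mean=150, error_rate=0.0, seed=11)
calls = calls_to_matrices(oc, marker_map, [f"s{i}" for i in range(8)])
octads = {c: assemble_octad(cl, pos, c) for c, (pos, cl) in calls.items()}
ev_octad = mm.analyze_matrices(octads, mode="octad")

# route 2: whole-colony tetrad + one resequenced colony per spore
tc = mm.emit_site_counts(matrices, depth_mean=150, error_rate=0.0, seed=12,
                         mode="tetrad",
                         colony_strands={k: 2 * k for k in range(4)})
samples = [f"c{i}" for i in range(4)] + [f"colony{i}" for i in range(4)]
calls_t = calls_to_matrices(tc, marker_map, samples)
mocktads = {}
n_het = 0
for c, (pos, cl) in calls_t.items():
    sm = build_mocktad(cl[:4], pos, c)
    n_het += int(sm.het_mask.sum())
    for spore in range(4):
        keep = np.isin(pos, sm.positions)
        sm, _ = phase_with_colony(sm, spore, cl[4 + spore][keep], strand="mother")
    mocktads[c] = sm
ev_mocktad = mm.analyze_matrices(mocktads, mode="mocktad")

sig = lambda evs: sorted(
    (e.chrom, e.co_count, e.nco_count, e.category.multi_dsb,
     e.category.nco_class, e.category.co_class)
    for e in evs if not e.type_u
)
a, b = sig(ev_octad), sig(ev_mocktad)
match = sum(1 for x in a if x in set(b))
print(f"heteroduplex markers split into strand pairs: {n_het}")
print(f"octad events: {len(a)}, phased-mocktad events: {len(b)}, "
      f"identical calls: {match}/{len(a)}")
# with full colony phasing the two routes agree event for event
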