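# meiomap

Genome-wide mapping of meiotic recombination events from tetrad and
octad sequencing of hybrid yeast crosses.

## The problem

In *Saccharomyces cerevisiae*, meiotic double-strand breaks (DSBs) made
by Spo11 are repaired as crossovers (COs) or noncrossovers (NCOs,
gene conversions). Sequencing all products of a single meiosis from an
S288c × SK1 hybrid — the four spores of a tetrad, or the eight DNA
strands of an octad obtained by separating each spore's first
mother/daughter division — reveals every event as a local departure
from Mendelian 4:4 marker segregation. In mismatch-repair-deficient
(*msh2*Δ) backgrounds, heteroduplex DNA (hDNA) survives and segregates
post-meiotically, producing the 5:3, 6:2, 4:4\* etc. patterns that
encode the strand-transfer mechanism of each event.

`meiomap` implements the post-alignment portion of this analysis as a
reusable library:

* **genotyping** — threshold-based binary genotype calls from pileup
  allele counts (depth ≥ 5; SNP variant ≥ 0.70 / reference ≥ 0.90;
  heteroduplex if reference+variant ≥ 0.90 of reads and balanced within
  70%; asymmetric indel rules, never heteroduplex), assembly into
  8 × markers strand matrices, and reconstruction of pseudo-octads
  ("mocktads") from *msh2*Δ tetrads with optional colony-resequencing
  phasing;
* **events** — segmentation of each chromosome into maximal runs of
  identical strand vectors, grouping of non-Mendelian runs and
  haplotype switch points into recombination events (separated by at
  least 1.5 kb of 4:4), CO counting from flanking haplotypes;
* **classify** — the observational event taxonomy: conservative
  multi-DSB classes (dCO, double NCOs on sisters or perfectly
  overlapping homologues, CO+NCO on a third chromatid), 8:0/7:1
  trans-DSB evidence, CO/NCO strand-transfer subcategories, DSB-hotspot
  overlap, and mitotic-artefact QC;
* **meiostats** — event mid-lengths and quartiles, the
  length-proportional random-allocation null for non-exchange
  chromosomes (CO assurance), inter-CO distance gamma modelling
  (CO interference: shape γα = 1 is exponential/random, γα > 1 means
  more even spacing), matched exponential references, the CO:NCO
  homeostasis trend, telomere/centromere distance curves, and the
  Fisher / Wilcoxon / Welch-t / KS tests with Benjamini–Hochberg
  correction;
* **simdata** — a synthetic-meiosis generator producing marker maps,
  strand matrices and pileup counts with known ground truth, used for
  every validation in the test suite.

## Worked example

```bash
python examples/01_simulate_and_call_events.py
```

```
marker map: 71146 markers on 16 chromosomes
pileup counts: 569168 sample-marker rows
planted: 83 COs, 27 NCOs (106 initiation clusters)
called:  81 COs, 29 NCOs in 103 events (+0 unclassifiable chromosome-end events)
multi-DSB events: 7 {'dCO': 2, 'dNCO_sister': 0, 'dNCO_overlap': 0, 'CO_plus_NCO': 5}
non-exchange chromosomes (zero COs): none
```

One simulated meiosis (90 expected COs under interference, *msh2*Δ-like
hDNA retention, 45× simulated coverage) is genotyped and analysed end
to end; called totals track the planted truth, with small differences
where independently planted events fall within 1.5 kb and merge, as
the method dictates. `examples/02_interference_gamma.py` contrasts
random and interfering CO landscapes through the gamma/KS analysis
(fitted shapes ≈ 1.1 vs ≈ 4.2), and `examples/03_mocktad_phasing.py`
shows that a colony-phased mocktad reproduces the direct octad analysis
event for event.

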