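# hrdcc

High-resolution differential cell counting (HRDCC) for bovine blood and
milk flow cytometry: synthetic cohort simulation with ground truth,
automated hierarchical gating, and the agreement and discrimination
statistics that validate and exploit the counts.

## What problem this addresses

The somatic cell count of a milk sample treats "cells" as one number, but
milk and blood contain a rich mixture of leukocyte types whose composition
shifts within days of an immune challenge. An HRDCC quantifies that
composition at high resolution — ten terminal immune subpopulations in
blood (neutrophils, eosinophils, classical/intermediate/nonclassical
monocytes, NK cells, γδ T cells, CD4+ and CD8+ T cells, B cells), the
macrophage analogs plus mammary epithelial cells in milk, viability, and
an immature-neutrophil (CD11b-dim) overlay — via a hierarchical gating
scheme: debris exclusion → singlets (FSC-A vs FSC-H) → live/dead
(viability dye) → CD45 vs SSC-A compartments → per-compartment marker
gates (autofluorescence for eosinophils; CD14 × CD16 monocyte quadrants;
CD335, gdTCR, CD4 × CD8, CD21 for the lymphocyte subsets; pan-cytokeratin
for MEC).

This package is for computational cytometrists and veterinary
immunologists who need that pipeline as *tested, automated code*: a
generator of realistic event-level data with known truth, a data-driven
gate-placement engine (kernel-density "valley" thresholds with quantile
fallbacks, robust singlet band, deterministic three-way SSC split), and
the downstream statistics — Pearson/OLS concordance, Bland–Altman limits
of agreement, the Friedman rank test for within-animal time courses, PCA,
Ward clustering, and sparse PLS-DA (3 components, at most 5 features
each) with leave-one-out one-vs-rest AUROC.

## Worked example

```python
from hrdcc import make_panel, default_templates, simulate_sample, build_tree, gate_sample
from hrdcc.simulate import BLOOD_PROPORTIONS

panel = make_panel("blood-5c")                      # myeloid blood panel
sample = simulate_sample(panel, default_templates(panel), BLOOD_PROPORTIONS,
                         n_events=50_000, doublet_rate=0.03, dead_rate=0.05,
                         debris_rate=0.05, seed=7)
tree = build_tree("blood", "myeloid", placement="auto")
result = gate_sample(sample.events, tree)           # compensate + gate

print(f"viability: {100*result.counts['live']/result.counts['singlets']:.1f}% of single cells")
for pop in ("neutrophils", "eosinophils", "cM", "intM", "ncM"):
    print(f"{pop:>12}: {result.percent_of(pop, 'live'):5.2f}% of live"
          f"  (true {100*sample.true_proportions[pop]:5.2f}%)")
```

prints

```
viability: 95.0% of single cells
 neutrophils: 27.80% of live  (true 28.00%)
 eosinophils:  3.86% of live  (true  4.00%)
          cM:  5.82% of live  (true  6.00%)
        intM:  1.41% of live  (true  1.50%)
         ncM:  1.46% of live  (true  1.50%)
```

Every auto-placed threshold used is recorded in `result.provenance`. The
simulated sample carries 5% dead cells and 3% doublets, so viability reads
95% and each recovered percentage sits within a fraction of a percentage
point of the generating truth — the gates were placed from the data alone.

The same flow runs from the shell: `hrdcc simulate` writes a cohort as FCS
3.1 files with a checksum manifest, `hrdcc hrdcc` gates it into a record
table, `hrdcc analyze` produces PCA/sPLS-DA/AUROC reports, and
`hrdcc concordance` compares two gating runs.

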