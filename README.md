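# coreclades

Ecophylogenetic core-microbiome discovery and exposure-sensitivity
profiling for multi-study 16S ASV data.

Cross-study comparisons of amplicon surveys stumble on the fact that the
same organism often receives different ASV identifiers in different
studies, and that most individual ASVs are rare.  `coreclades` works at the
level of **monophyletic clades** instead: every internal node of an ASV
phylogeny is treated as a taxonomic unit whose abundance in a sample is the
sum of its member tips' counts.  A clade is *core* when it is present in
significantly more samples than expected under a tip-label permutation
null:

- clade abundance: `A(c, s) = Σ_{t ∈ L(c)} X[s, t]` for tip set `L(c)`;
- observed prevalence: fraction of (control) samples with `A(c, s) > 0`;
- null: prevalence recomputed under uniform permutations of the tip↔label
  assignment (default 999), giving a per-clade null mean and SD;
- test: one-sided z-test, Benjamini–Hochberg FDR across clades,
  `q < 0.05` ⇒ core.

Each core clade's response to environmental exposures is then modelled with
per-study negative-binomial regressions (log link, control arm as base
level); exposure levels with BH-corrected `q < 0.1` mark the clade as
*sensitive* to that exposure.

The package is aimed at microbiome researchers integrating several amplicon
studies of the same host system.  It ships a synthetic-data module that
plants core clades and exposure effects with known truth, so the entire
pipeline is testable without downloading any sequencing data.

## Worked example

```python
from coreclades import SimulationConfig, ExposureSpec, run_pipeline
import numpy as np

config = SimulationConfig(
    n_tips=1500,
    n_studies=3,
    samples_per_study=(40, 32, 28),
    n_core_clades=5,
    exposures=[ExposureSpec("study1", "antibiotic", np.log(4), n_affected=2)],
    seed=42,
)
result = run_pipeline(config, outdir="demo", n_perm=999, seed=42)
for key, value in result.report.summary.items():
    print(f"{key}: {value}")
```

prints

```
planted_core_sensitivity: 1.0
planted_core_fdp: 0.0
exposure_effect_sensitivity: 1.0
exposure_null_arm_call_rate: nan
n_core_clades: 20
n_clades_total: 1484
median_core_prevalence: 1.0
n_top_quartile: 13
n_sensitive_clades: 16
n_robust_clades: 4
```

Of 1484 clades in the (pruned, midpoint-rooted) 1500-tip phylogeny, 20 are
called core at FDR 0.05 — all 5 planted core clades are among them
(`planted_core_sensitivity: 1.0`) and every other call contains planted-core
members (`planted_core_fdp: 0.0`; ancestors of a planted clade genuinely
exceed the null).  Both clades with the planted 4-fold antibiotic effect are
flagged sensitive (`exposure_effect_sensitivity: 1.0`); the null-arm rate is
`nan` because this design has no effect-free exposure arm.  16 core clades
respond to at least one exposure (largely compositional spillover from the
strong planted shift at fixed rarefaction depth), leaving 4 robust.
`demo/` contains the full outputs: `core_clades.tsv`, `clade_abundance.tsv`,
`sensitivity.tsv`, summary tables, and a regenerable `report.json` with all
seeds.

The same stages are available from the shell:

```sh
coreclades simulate --out data --seed 4
coreclades rarefy --counts data/counts.tsv --depth 1000 --seed 1 --out rare.tsv
coreclades core --tree data/tree.nwk --counts rare.tsv \
    --metadata data/metadata.tsv --n-perm 999 --seed 2 --out core_out
coreclades exposure --clade-matrix core_out/clade_abundance.tsv \
    --metadata data/metadata.tsv --core core_out/core_clades.tsv --out exp_out
```

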