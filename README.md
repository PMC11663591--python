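# xomap

Simulation, calling and fine-scale analysis of **meiotic crossovers** in F2
plant populations.

Crossovers — reciprocal exchanges between homologous chromosomes during
meiosis — are mapped in plants at three scales: genome-wide from
low-coverage sequencing of F2 individuals (genotype switches along
chromosomes), at interval scale from the segregation of linked fluorescent
seed reporters, and at hotspot scale by sequencing individual recombinants
across a short interval. `xomap` implements all three analyses as a tested,
reusable library plus CLI, together with a meiosis and observation
simulator that provides full ground truth, so every stage can be validated
by parameter recovery without any external data.

## What's inside

* **`xomap.simulate`** — forward simulator of F2 populations. Class I
  (interfering) crossovers follow a stationary gamma-renewal chiasma process
  with shape ν and chromatid thinning; Class II events are a Poisson overlay
  carrying a fraction *p₂* of the map length, so the expected crossovers per
  gamete always equal the chromosome's genetic length. A sparse-sequencing
  observation model (Poisson depth, per-read allele error) emulates
  genotyping-by-sequencing data. Also simulates fluorescent-seed class
  counts and hotspot-mixture recombinant panels.
* **`xomap.calling`** — crossover calling from genotype matrices
  (`{A, H, B, -}` per marker per individual): library/marker filters,
  noise-robust window smoothing, minimum-segment merging, exact boundary
  refinement, and midpoint-assigned crossover calls (direct A↔B switches
  count twice — both gametes must have recombined).
* **`xomap.landscape`** — fixed windows (default 300 kb, per F2) and pooled
  telomere→centromere scaled profiles; region and per-chromosome
  comparisons by Mann–Whitney U.
* **`xomap.interference`** — cis double-crossover (cis-DCO) distances from
  parental–heterozygous–parental genotype runs, compared between genotypes
  per chromosome.
* **`xomap.seeds`** — genetic distance from seed fluorescence classes:
  `cM = 100·(1 − √(1 − 2(NG + NR)/NT))` for standard intervals and the
  linear `100·(NG + NR)/NT` for extremely short ones; Welch *t* /
  ANOVA + Tukey HSD group comparisons.
* **`xomap.hotspots`** — breakpoint localization on a thinned SNP scaffold,
  hotspot usage with chi-square homogeneity testing, per-SNP-section rates
  scaled to the interval's cM, and mutant/wild-type section ratios with
  Kruskal–Wallis + Dunn comparisons.
* **`xomap.stats`** — the above tests behind one uniform result type, with
  exact small-sample Mann–Whitney p-values.

## Worked example

```python
import numpy as np
from xomap.genome import arabidopsis_like_genome
from xomap.pipeline import make_marker_scaffold
from xomap.simulate import (MeiosisParams, ObservationParams,
                            simulate_f2_population, observe_genotypes)
from xomap.calling import CallerParams, call_population, count_per_individual
from xomap.seeds import SeedCounts, ftl_cm

rng = np.random.default_rng(11)
genome = arabidopsis_like_genome()                 # 5 chromosomes, 4.04 M/gamete
markers = make_marker_scaffold(genome, 50_000)     # markers every 50 kb
geno, truth = simulate_f2_population(genome, MeiosisParams(), 50, markers, rng)
obs, _ = observe_genotypes(geno, ObservationParams(), rng)   # depth 1.5x
segments, calls = call_population(obs, CallerParams())
_, mean = count_per_individual(calls, 50)
print(f"true crossovers per F2:   {len(truth)/50:.2f}")
print(f"called crossovers per F2: {mean:.2f}")

est = ftl_cm(SeedCounts(n_green_only=90, n_red_only=90, n_both=640, n_none=180))
print(f"FTL interval distance:    {est.value:.1f} cM from {est.n_total} seeds")
```

prints

```
true crossovers per F2:   8.22
called crossovers per F2: 7.62
FTL interval distance:    20.0 cM from 1000 seeds
```

The simulated population averages 8.22 crossovers per individual (two
gametes × 4.04 Morgans); at 1.5× coverage the caller recovers 93% of them —
events within ~250 kb of chromosome ends or closer together than the
smoothing window are genuinely unresolvable at this noise level. The seed
example inverts the two-reporter segregation model exactly: 180 of 1,000
seeds showing a single color corresponds to 20 cM.

The same stages are available from the shell:

```bash
xomap simulate-f2 --n 50 --seed 11 --out geno.tsv --truth-out truth.tsv
xomap observe --matrix geno.tsv --seed 12 --out observed.tsv
xomap call --matrix observed.tsv --out calls.tsv
xomap landscape --calls calls.tsv --n-individuals 50 \
      --out-fixed windows.tsv --out-scaled telcen.tsv
```

or end-to-end via `xomap run --config pipeline.yaml`.

## Documentation

`docs/methods.md` describes the meiosis model and its assumptions, the
caller's smoothing rule, every estimator and test convention, the default
parameters and why, and the known limitations of the synthetic data.
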