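# Methods

This note records the models, conventions and design choices behind
`xomap`, and what the synthetic data do and do not establish about real
data.

## Meiosis model

Each chromosome carries a genetic length *L* (Morgans per gamete) and a
piecewise-constant relative crossover intensity over base pairs. Crossovers
are simulated per gamete in genetic coordinates and then mapped to bp by
inverting the normalized cumulative intensity, so any landscape shape
(arm/pericentromere contrast, a crossover-free centromere) can be imposed
exactly.

Two pathways are mixed:

* **Class I (interfering).** Chiasmata form along the bivalent as a
  *stationary* gamma renewal process with shape ν ≥ 1 and intensity
  2 chiasmata per Morgan of the Class I map share (1 − p₂)·*L*. The first
  arrival is drawn from the equilibrium forward-recurrence distribution
  (sampled as *U*·*X* with *X* length-biased, i.e. Gamma(ν + 1)), which
  keeps the process translation-invariant — without it, event density would
  dip near the left telomere. Each chiasma involves the sampled chromatid
  with probability 1/2 (chromatid thinning). Thinning at the chiasma level,
  rather than running a renewal process directly on the gamete, preserves
  both the expected event rate and the empirically weaker interference seen
  between crossovers on a single chromatid.
* **Class II (non-interfering).** A homogeneous Poisson overlay with mean
  p₂·*L* per gamete, positions uniform in genetic coordinates.

The overlay *partitions* the map length: expected total crossovers per
gamete equal *L* for every (ν, p₂), so interference settings can be compared
at a fixed map. With ν = 1 and p₂ = 0 the model reduces exactly to a Poisson
process of rate 1 per Morgan, which is the closed-form oracle used in the
tests.

An optional obligate-crossover mode rejection-samples bivalents with zero
chiasmata. It is off by default; switching it on inflates the realized map
length of short chromosomes (the rejection conditions on ≥ 1 chiasma), which
is why it is not part of the default study conditions.

An F2 individual is the union of two independent meioses; selfing enters
only through that union (no shared parental meiosis between individuals).
Genotypes at marker positions are the allele dose: 0 = parent-1 homozygote
(A), 1 = heterozygote (H), 2 = parent-2 homozygote (B).

### Default parameters

| parameter | default | rationale |
|---|---|---|
| genome | 5 chromosomes, TAIR10-like lengths (119.1 Mb total) | Arabidopsis-scale geometry |
| total map length | 4.04 M per gamete, split ∝ physical length | ≈ 8.1 crossovers per F2, the scale of Col×Ler F2 populations |
| intensity | arm 1.0, pericentromere 0.4, centromere 0 | pericentromeric suppression; centromeres are crossover-free |
| ν (interference shape) | 5 | plants show strong interference; the exact value is a free simulation parameter, not an estimate of any real population |
| p₂ (Class II share) | 0.12 | roughly 1 in 9 crossovers from the non-interfering pathway |
| observation depth | Poisson, mean 1.5 per marker | low-coverage genotyping-by-sequencing regime |
| allele error | 0.005 per read | typical post-filter sequencing error |

## Observation model

Per marker and individual, depth *d* ~ Poisson(mean_depth). Each read
reports one allele — the true allele for homozygotes, either with
probability 1/2 for heterozygotes — miscalled with probability *e*. The call
is missing at *d* = 0, H when both alleles are seen, else the observed
homozygote. The key consequence, which drives the caller design: at mean
depth 1.5 a heterozygous site is called *homozygous* about 64% of the time
(a single read can never reveal heterozygosity), while a homozygous site is
miscalled with probability ≲ 0.6%.

## Crossover caller

Crossovers are genotype switches assigned to the midpoint between flanking
informative markers (floor of the mean; 1-based inclusive coordinates).
Direct A↔B switches emit multiplicity 2: in an F2 both gametes must have
exchanged in the interval. Whether published per-individual counts treat
such switches as one or two events is generally not stated; this package's
convention is two, applied consistently to both the caller and the
simulator truth.

Segmentation is deterministic, in three stages per individual/chromosome:

1. **Asymmetric window smoothing.** Each informative marker is relabeled
   from the counts (n_A, n_H, n_B) in a centered window of *w* informative
   calls: label A if n_H + n_B ≤ m, label B if n_H + n_A ≤ m
   (m ≈ 0.13·w), else H — unless the window contains *no* H call, in which
   case it is a direct A↔B switch zone and the A/B majority decides (ties
   keep the previous label; the first marker keeps its own call). The
   asymmetry matches the observation model: true homozygous stretches are
   nearly pure, while heterozygous stretches are a noisy A/H/B mixture that
   a symmetric plurality vote would shatter — under the default noisy
   regime a symmetric vote inflates crossover counts by more than 50%,
   whereas this rule's false-segment rate is a few percent. With w = 1 the
   stage is the identity.
2. **Minimum-segment merging.** Maximal runs become segments; segments with
   fewer than `min_segment_markers` informative markers merge into the
   flanking segment with more informative markers (ties merge left),
   leftmost first, until stable.
3. **Boundary refinement.** Each boundary is re-placed at the split of the
   *raw* informative calls that maximizes agreement with the two segment
   genotypes (choosing the split nearest the coarse boundary on ties). On
   noise-free data this restores the exact transition position, making the
   caller with w = 1 provably identical to a brute-force transition scan.

Missing calls are dropped, never imputed. Filters follow strict printed
conventions: markers kept at quality > 100 and coverage > 2.5; libraries
kept at ≥ 95,000 reads.

**Resolution limits.** At finite marker spacing some simulated truth is
unobservable in principle: events outside the marker span, an even number
of same-gamete events inside one inter-marker interval, and opposite-phase
cross-gamete pairs (H→H). `simulate.marker_resolvable_truth` computes the
resolvable subset; the caller is validated to match it *exactly* on
noise-free data. Under the default noisy regime the caller recovers the
mean count to within ~5%: losses come from crossovers within
`min_segment_markers` markers of chromosome ends and from genuine segments
shorter than the smoothing window.

**Idempotence** of the smoothing holds for segments longer than the window
(the regime of real data, where segments span megabases); very short
segments near the window size are not fixed points of stage 1 and are
instead handled by stage 3.

## Landscapes

Fixed windows (default 300 kb) assign each call by its midpoint — not by
fractional interval overlap — keeping counts integral and conserved; the
terminal partial window keeps its true width. Window labels
(arm/pericentromere/centromere) follow the label covering the majority of
the window's span.

The scaled profile places each call at x = (distance from its arm's
telomere)/(arm length), arms running telomere → centromere edge, pooled
over all arms, binned uniformly on [0, 1] (default 50 bins). Since "per
300 kb" has no unique meaning for bins of varying physical width, per-bin
frequencies are normalized per F2 and per 300 kb of the *mean* physical bin
width (recorded in the output). Calls inside a centromere are assigned
x = 1 and flagged with a warning.

## cis-DCO interference readout

Every consecutive segment triple A-H-A or B-H-B yields one record; the
distance is between the two flanking calls' midpoints, in bp (the readout
axis is physical). A-H-B triples are excluded — they may be trans
configurations (events on different gametes). Overlapping triples
(A-H-A-H-A) each contribute a record. Triples touching chromosome ends are
included. Per-chromosome group comparisons use Mann–Whitney U without
multiple-testing correction, matching per-chromosome reporting conventions.
Under ν = 1 the extracted distance distribution matches a brute-force
gamete-level Poisson oracle (two-sample Kolmogorov–Smirnov check in the
tests); the median distance grows monotonically with ν.

## Seed-based estimators

With recombination fraction *r* per gamete, gametes of a two-reporter
hemizygote are RG, ++ (each (1 − r)/2) and R+, +G (each r/2); a selfed seed
is green iff it carries ≥ 1 G and red iff ≥ 1 R. Hence single-color classes
each have probability (1 − (1 − r)²)/4 and the estimator

  cM = 100·(1 − √(1 − 2(NG + NR)/NT))

inverts the model exactly at the expectation (verified symbolically in the
tests). A linearized variant of this formula (dividing by 2 instead of
taking the square root) appears in some legacy spreadsheets; it returns
50 cM at zero recombinants and is therefore only available behind an
explicit acknowledgment flag. For extremely short intervals (< 50 kb) the
linear form RF = 100·(NG + NR)/NT is used; it differs from the square-root
form by r/2 relative (0.05% at r = 0.001). NT is the sum of the four
classes. The experimental unit is the plant: one estimate per plant,
Welch *t* for two groups, one-way ANOVA + Tukey HSD for more.

## Hotspot fine-mapping

SNPs are thinned greedily left-to-right to ≥ 100 bp spacing (the spacing is
standard; the thinning order is this package's choice). A recombinant
vector must show exactly one parental transition on the retained scaffold;
others are excluded and reported. Breakpoints are the interval between the
last left-parent and first right-parent retained SNP. Usage assigns
breakpoints to hotspots by midpoint, with a background category by default
(toggleable). Section rates spread multi-section breakpoints fractionally
and uniformly; `cm_scaled` renormalizes so sections sum exactly to the
interval's measured cM. Mutant/wild-type ratios exclude (and report)
sections with zero wild-type rate; ratios are compared across hotspots by
Kruskal–Wallis with Dunn's post hoc, unadjusted by default (Bonferroni and
Holm available).

## Statistical conventions

* Mann–Whitney U: two-sided; exact permutation distribution when
  min(n) ≤ 8 with no ties (p = doubled smaller tail, capped at 1), else
  normal approximation with tie and continuity corrections. The continuity
  correction changes third-decimal p-values; with it, the approximation
  tracks enumeration to within ~0.011 at n = 8, 8.
* Welch *t* with Satterthwaite df; zero variance in both groups with equal
  means returns p = 1 by convention.
* Pearson chi-square without continuity correction; a warning is raised
  when any expected count is below 5.
* Kruskal–Wallis with tie correction; Dunn z-tests use the tie-corrected
  rank variance.
* No multiple-testing correction across chromosomes or windows by default.
* Degenerate inputs (all observations identical) return statistic 0, p = 1
  rather than NaN.

Standard tests delegate to SciPy internally; the test suite validates each
against an independent enumeration or closed-form oracle.

## Determinism and numerics

A single seeded `numpy.random.Generator` threads through all sampling; the
pipeline records the seed and a parameter hash in its manifest, and reruns
with the same config are byte-identical. Midpoints use floor division.
Window/bin edges are half-open on the right except the final bin/window,
which absorbs the boundary.

## What the synthetic data do not show

The simulator emulates the statistical structure of F2 mapping data —
interfering/non-interfering pathway mixture, landscape shape, sparse noisy
genotyping, seed segregation, hotspot mixtures — with full ground truth.
It does not model segregation distortion, translocations or aneuploidy,
sex-specific maps (a single sex-averaged map is used), read-level artifacts
(alignment bias, duplicated regions), SNP density variation along real
chromosomes, or biological interference mechanisms beyond the gamma-renewal
phenomenology. Passing recovery tests therefore demonstrates correctness of
the *analysis* under these assumptions, not robustness to every property of
real sequencing data. Problem sizes in the tests (populations of 100–1,300
individuals, 6,000–10,000 landscape events, 300 recombinants) were chosen
as the smallest at which the targeted effects are statistically unambiguous.
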