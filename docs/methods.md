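# Methods

`flcdmap` re-creates, as a tested pipeline, the computational chain used to
map a female-limited colour dimorphism (FLCD) locus by introgression
pool-sequencing and to characterise ancient balancing selection at the
mapped enhancer.  This note records the models, the parameter choices, and
the limits of what the bundled simulator can demonstrate.

## The mapping model

Two inbred parental lines differ by a dominant, X-linked dark allele.  The
dark allele is moved into the light background by repeated backcrossing of
carrier females to light-line males, selecting dark (carrier) offspring
each generation.  After *n* backcrosses a pooled sample of carrier females
is sequenced; a homozygous introgression line is derived later by sibling
intercross with selection of dark homozygotes.

For each diagnostic SNP — a diallelic site with total read count ≥ 10 in
every line whose one allele is fixed in the dark parental line and absent
in the light line — the **dark-ancestry proportion** of a pool is the
fraction of its reads carrying the dark-line allele.  Proportions are
averaged in non-overlapping 100-kb windows tiled from coordinate 1.
Windows with fewer than 1 parental fixed difference per 1,000 sites are
excluded as potentially identical-by-descent between the parental strains
(`ibd_filter`; "fewer than" is read strictly, so a window at exactly the
threshold is retained).  At the causal locus the heterozygous backcross
pool is expected at 50% dark ancestry, the homozygous line at 100%, and
their average — the combined window score — at 75%.  Candidate windows are
maximal runs with |score − 0.75| ≤ 0.05 (the band is configurable and
reported in output headers), ranked by |score − 0.75|.

Expected ancestry at a linked neutral site is available in closed form
(`expected_carrier_ancestry`): with Haldane recombination fraction
r(d) = (1 − e^(−2m))/2 over map distance m, a carrier gamete after n
selected backcross meioses is dark with probability (1 − r)^n — 1 at the
causal site, (1/2)^n when unlinked.  The pooled heterozygous females add
one intact light X each, halving the pool-scale expectation.  The
simulator is tested against this closed form.

## Divergence and HKA scans

Per-SNP divergence between the two parental lines is
Dxy = p₁q₂ + p₂q₁, where p is each line's frequency of the allele matching
the reference genome and q = 1 − p, computed at diallelic SNPs with
coverage ≥ 2.  This standard two-population per-site form is consistent
with the p/q definitions given for the statistic.  Smoothing averages each
SNP ± 250 SNPs (501-SNP windows) with truncation at chromosome ends (never
padding; a flag marks truncated windows) and re-indexing after all filters.
Peak intervals are runs of SNPs whose smoothed Dxy exceeds 5× the
chromosome median — the multiplier is a package convention, not a
literature value.

The HKA-like scan classifies SNPs as *polymorphic* (Dxy > 0 between the
lines) or *divergent* (Dxy = 1 between both lines and the outgroup) and
compares the observed class counts in each SNP ± 50 SNPs (101-SNP windows,
indexed over classified SNPs) with expectations from the chromosome-wide
class proportions, using a χ² test at 1 df.  Chromosome-wide proportions
include the focal window (the bias is negligible at genome scale).  No
Yates correction and no multiple-testing correction are applied to the
reported p-values; a Bonferroni column is emitted as a convenience only.
The locus-level test is a plain 2×2 contingency χ² (locus × class, 1 df,
no continuity correction) on raw counts — loci of roughly equal length are
assumed, so counts are not length-normalised.

## Haplotype statistics

Distances are uncorrected p-distances with pairwise deletion of gaps and
ambiguity codes (MEGA-style defaults); a long outgroup indel is therefore
missing data, not a stack of differences.  Haplotypes are clustered with
Saitou–Nei neighbour joining (scikit-bio's implementation; negative branch
lengths clamped to zero), and the two haplogroups are the two sides of the
longest internal branch, with deterministic lexicographic tie-breaking.
Per-site differentiation uses the Hudson estimator FST = 1 − Hw/Hb with
unbiased within-group heterozygosity (1 − Σp²)·n/(n − 1) — the
DnaSP-family form, which permits slightly negative values in finite
samples.  Segregating sites, between-group fixed differences, and mean
between-group Dxy are counted directly from the alignment.  The
incomplete-lineage-sorting (ILS) scan flags windows where
Dxy(A, B) > min(Dxy(A, outgroup), Dxy(B, outgroup)) and merges overlapping
flagged windows.

## Clock dating

Divergence times use a strict linear clock on Jukes–Cantor corrected
distances: age(A, B) = 11 My × d(A, B)/d(calibration split), calibrated by
the ~11-My age of the melanogaster-subgroup ancestor.  Uncertainty is a
site bootstrap (columns resampled with replacement, seeded; 1,000
resamples by default, 2.5–97.5 percentile interval).  This replaces a
Bayesian HKY+I MCMC: a deliberate simplification.  Bootstrap intervals are
sampling-variance analogues of, not identical to, posterior credible
intervals, and the linear clock ignores rate variation, so dating output
is expected to agree with model-based estimates on scale rather than to
the decimal.

## The simulator

The generator's defaults are the study conditions; they are set once and
are not fitting knobs.

**Parental genomes.**  Sites are SNPs independently at density 0.02 per
base (the density of sites variable among two inbred conspecific lines and
a ~3–5%-diverged outgroup); 10% of SNPs are parental fixed differences,
65% outgroup-divergent, the rest shared-derived.  These proportions give a
parental fixed-difference density of 2 × 10⁻³ per site (comfortably above
the 10⁻³ IBD threshold, as expected for two independent inbred strains)
and a background smoothed Dxy near 0.10.  A *balanced core* plants extra
fixed differences around the causal position at peak density 0.10 decaying
exponentially over 2 kb — a deeply diverged balanced polymorphism fixed
for opposite alleles in the two lines, with divergence decaying into the
flanks.  A fixed-difference SNP always sits exactly at the causal position
(the causal variant itself).

**Cross design.**  7 backcrosses for the heterozygous pool and 12 for the
homozygous line, pools of 30 females, and a homozygous line founded from
four dark-homozygous pairs (12 X copies) — the stated breeding scheme.
Crossovers are Poisson with uniform placement and no interference, at
0.02 crossovers/Mb per female meiosis (2 cM/Mb, a standard *Drosophila*
scale; the true map is not stated, so this is a configuration choice).
Males are achiasmatic and transmit an intact X, so recombination is
female-only; selection is implemented as rejection sampling of gametes
carrying the dark allele at the causal position, which is exactly
conditioning under complete dominance.  Pooled copies of the homozygous
line are drawn with replacement from the founder gametes, so founder
chunkiness — frozen drift — is part of the simulated truth.

**Pooled sequencing.**  Depth is Poisson per site (defaults ×30/×17 for
the parental lines, ×44/×80 for the introgression pools, ×21 for the
outgroup, following the sequenced genomes); the dark-allele read count is
binomial with symmetric error between the two site alleles (default
10⁻³).  Conservation (dark + other reads = depth) is asserted.

**Balanced haplotype locus.**  Mutations are placed site-by-site
(infinite sites, at most one per column) on a fixed 4-branch genealogy:
per-tip branches carry within-group diversity (0.005), group stems and a
deep shared branch carry the between-group excess (0.07 in the core), and
the outgroup attaches *inside* the ingroup genealogy — on the branch it
shares with haplogroup A — so that in the core it is closer to A (0.05)
than the haplogroups are to each other.  Outside the 500-bp core all
group-defining branch lengths decay as exp(−distance/500 bp), leaving the
haplogroups exchangeable in the far flanks while the outgroup stays at its
background species divergence.  A 44-bp gap can be planted in the outgroup
to exercise missing-data handling.  This is deliberately not a coalescent:
no recombination within the locus, no frequency spectrum beyond singletons
and fixed classes — sufficient to produce every signature the pipeline
tests (haplogroup clustering, high FST, fixed differences, the ILS
interval), but not a model of real genealogical variance.

**Randomness.**  Every stage draws from `numpy.random.Generator` streams
derived from one run seed; identical config + seed reproduce outputs
byte-for-byte (checksummed in the run manifest).

## Problem sizes and tolerances

Simulated chromosomes default to 10 Mb (100 ancestry windows, ~200k SNPs)
— a scaled-down chromosome that preserves all densities and rates while
keeping a full replicate experiment below a second of compute; replicate
studies use 200 crosses and recovery checks 50 full experiments.
Stochastic recovery tests compare means over seeds with Monte-Carlo
standard-error bands (typically 2–4 SE); configuration-recovery checks on
the balanced locus use 10–15% relative tolerances driven by the Poisson
noise of a 500-bp core.

## Known limitations

* Single-window localization is noise-limited: with a 2 cM/Mb map, 100-kb
  windows, and the stated pool structure (30 carrier lineages; 12 founder
  copies for the homozygous line), the expected score margin between the
  causal window and its neighbours (~0.005–0.015) is comparable to the
  founder/lineage sampling noise (~0.015–0.035).  The causal window
  therefore tops the candidate ranking in only ~70% of replicates, while
  the merged candidate interval contains it essentially always.  This is a
  property of the design, not of the estimator.
* The site classification applies the literal Dxy rules to noisy pooled
  frequencies, so a single error read converts a divergent site into a
  polymorphic one; with symmetric error this inflates the polymorphic
  class uniformly and leaves the windowed test calibrated, but class
  *totals* are error-sensitive.
* The infinite-sites haplotype generator has no intra-locus recombination,
  so the ILS interval decays exactly as configured; real data would show
  recombination-broken boundaries.
* The clock is strict and Jukes–Cantor only; saturation (p ≥ 0.75) raises
  rather than being modelled.
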