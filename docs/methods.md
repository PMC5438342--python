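# Methods

`regulonexo` reconstructs a transcription factor's regulon genome-wide by
combining three measurements a bacterial regulatory-genomics study produces:
strand-specific ChIP-exo binding profiles under a stress condition (in
biological duplicate, with a mock-IP control), a binding-motif analysis of the
called peaks, and RNA-seq of wild-type versus TF-knockout cultures. The
pipeline's output is a causally classified regulon: every bound transcription
unit (TU) labelled *activated*, *repressed*, or *not determined*, plus the
downstream comparative summaries (cross-TF regulon overlap, functional and
localization tabulation, ortholog conservation, relative growth rates).

## Peak calling from ChIP-exo borders

Lambda-exonuclease digestion trims immunoprecipitated fragments up to the
protein-DNA crosslink, so read 5′ ends accumulate in sharp, strand-asymmetric
borders: forward-strand 5′ ends at the left edge of the protected footprint,
reverse-strand 5′ ends at the right edge. The caller exploits exactly this
geometry:

1. **Depth normalization.** Each strand track is scaled to reads per million
   (RPM), so duplicate libraries of different depth are comparable.
2. **Candidate borders.** A position is a candidate border when it is a local
   maximum and its RPM value is at least `peak_k` (default 3) times the local
   background, the mean over a centered `peak_bg_window` (default 2 kb) floored
   at the genome-wide uniform density `1e6 / genome length`. The floor keeps
   the threshold meaningful in regions where the local window is nearly empty.
3. **Border pairing.** Each forward border is paired with the nearest
   downstream reverse border within `peak_max_span` (default 100 bp); the peak
   interval is `[fwd, rev+1)`. Unpaired borders are discarded.
4. **Reproducibility.** Peaks from the two biological duplicates are merged
   when their intervals overlap by ≥ 1 bp; the merged peak takes the union
   interval and the mean of the two replicate signal-to-noise values.
5. **Filtering.** Peaks with S/N < `peak_sn_min` (default 1.0) are dropped, as
   is any peak overlapping a peak called on the mock-IP track with the same
   parameters. S/N is the mean combined-strand border density inside the peak
   divided by the genome-wide mean density.

Everything after the simulation is deterministic: no randomness enters the
caller, and peak counts are monotone in both thresholds.

## Motif discovery

The finder runs expectation-maximization over a ZOOPS model (zero or one
occurrence per sequence, either strand), with a fixed per-sequence occurrence
prior of 0.9, a strand-symmetrized 0-order background estimated from the input
composition, and a Dirichlet pseudocount of 0.25 per base per column in the
M-step. Peak sequences are the peak interval ± a 10 bp flank.

Numerical choices worth knowing:

- The tracked and reported objective is the MAP objective (data log-likelihood
  plus the Dirichlet log-prior term). Plain data likelihood need not be
  monotone under a pseudocounted M-step; the MAP objective provably is, and
  the implementation asserts that invariant.
- Restarts (default 20) are seeded deterministically from the lexicographically
  sorted pool of all subsequence windows, so the result does not depend on the
  order sequences are supplied in. Ties between restarts break toward the
  lower restart index.
- After the seeded restarts, EM is re-run from ±1 and ±2 column-shifted
  variants of the best matrix (vacated columns filled with background). EM on
  short windows can converge to a register one column off the optimum; the
  shift moves, a standard device in motif finders, repair that
  deterministically.
- A motif learned from double-stranded input is identified only up to reverse
  complement; any comparison to a reference consensus must consider both
  orientations.

The IUPAC rendering uses thresholds of this package's convention: one base at
column probability ≥ 0.6; the two-base code when the top two sum to ≥ 0.8; the
three-base code at ≥ 0.95; otherwise N.

## Differential expression

Bacterial data has no isoforms, so the stage is gene-level and exactly
computable:

- **log2 fold change** (knockout/wild-type orientation): means of library-size-
  normalized counts with a pseudocount of 1. Size factors are each library
  total divided by the geometric mean of library totals. Deleting an activator
  sends its targets to log2FC ≤ −1; deleting a repressor to ≥ +1.
- **Exact test:** counts are pooled within condition; given the total
  `t = a + b`, the two-sided p-value is the minimum-likelihood tail of
  `Binomial(t, π₀)` with `π₀` the knockout share of total library mass.
- **FDR:** Benjamini–Hochberg step-up.
- **Call:** significant ⇔ |log2FC| ≥ 1 and q ≤ 0.01.

The conditional binomial test assumes Poisson-level noise around the pooled
proportion. With biological overdispersion (negative-binomial dispersion α)
its z-scores are inflated by roughly √(1+αμ), so at high coverage the p-values
are anti-conservative — which is precisely why the significance call combines
the FDR threshold with the fold-change threshold rather than relying on the
p-value alone. The null-calibration test therefore runs in the low-coverage
regime (mean count 10 at α = 0.1, where αμ ≈ 1 and BH discreteness keeps the
q ≤ 0.01 rate under 2%); at study-scale coverage the fold-change filter, not
the p-value, is what excludes unperturbed genes.

Total-count size factors (and the test's library-mass proportion) are unbiased
only when the two conditions carry equal expected RNA mass. The synthetic
generator plants a mass-balanced effect composition for exactly this reason
(below); on real data with a strongly asymmetric response, a robust
normalization (e.g. median-of-ratios) should replace the size factors — the
normalization is deliberately confined to one function.

## Regulon integration

A peak is assigned to every TU whose strand-aware TSS-relative window contains
the peak center; the default window is −500 to +200 bp (negative = upstream),
wide enough to cover the three observed location classes (upstream of the
promoter, promoter, 5′-proximal). The upstream/promoter boundary sits at
−100 bp; changing it relabels locations but cannot change regulon membership
(tested). The causal mode of a bound TU comes from its member genes' knockout
response: all significant genes at log2FC ≤ −1 → activated; all at ≥ +1 →
repressed; none significant → not determined; mixed signs are flagged
*conflict* rather than coerced — a conflict would indicate a caller or
annotation problem and must stay visible. A gene counts once even when its TU
carries several peaks; a multi-peak TU reports the peak closest to its TSS.

## The synthetic generator

No sequencing accessions accompany the study this pipeline operationalizes, so
a generator with planted ground truth stands in for raw data. It emulates, at
desk scale, the features the pipeline actually consumes; its `paper_scale`
preset encodes the study conditions, and its defaults are fixed, not tuning
knobs.

- **Genome and annotation:** 500 kb with 600 genes in 350 TUs (a desk-scale
  stand-in for a 4.6 Mb chromosome that preserves per-TU structure), gene
  lengths uniform 250–700 bp, TSS 30 bp upstream of each TU's first gene.
  The 24 regulon TUs are laid out with enlarged promoter-side clearance
  (≥ 1 kb) so each planted site falls in the TSS window of exactly one TU —
  verified, not assumed, at generation time.
- **Binding sites:** 25 ChIP-detectable sites over the 24 TUs (one TU carries
  two), each a 21 bp footprint with a motif instance sampled from the planted
  PWM (consensus KWWGTTACAT) embedded at its center on a random strand. Eight
  sites are flagged as previously reported; one of those carries no ChIP
  signal, so a perfect caller detects 7 of 8 (88%).
- **ChIP-exo tracks:** for each library, reads split evenly between strands
  and are drawn multinomially; each site contributes 5′ borders at its
  footprint edges with a ±2 bp truncated-geometric jitter (decay 0.5), the
  rest is uniform background. Per-site read mass is set so the realized
  peak S/N ≈ 5 (corrected for the jitter mass falling outside the footprint),
  and the default depth of 10 M reads per library makes the background Poisson
  rate high enough that a spurious thresholded border is a ≪ 1-per-genome
  event — so exact recovery of the planted sites is the expected outcome, by
  design. The mock track carries background plus 2 planted artifact sites
  shared with both ChIP replicates (mock artifact abundance is a parameter;
  the source study does not report one).
- **RNA-seq:** negative-binomial counts (default dispersion 0.01) for two
  wild-type and two knockout libraries with distinct library-size factors;
  per-gene base levels are lognormal around a mean of 800 (yielding a few
  hundred counts per gene). Direct targets change by |log2| effects drawn from
  U(2, 3.5) in the mode's direction; 385 indirect responders (no binding site)
  plus the deleted TF gene itself (knockout mean 0) complete a genome-wide DE
  set of exactly 412 genes. Indirect effect signs are assigned greedily
  against the running expected-mass imbalance so both conditions carry equal
  total RNA mass (see the normalization note above).
- **Side tables:** an 8-TF stress-regulon membership universe of 243 genes
  (206 regulated by one TF, 33 by two, 4 by three; 34 of the 37 focal-regulon
  genes touched by no other stress TF, 18 by no known TF at all once 30
  non-stress TF columns are included); an ortholog presence/absence matrix
  over 257 genomes in groups of 13/3/2/7/134/40/58 across proteobacterial
  taxa, with the TF itself nearly universal (present in 252/257) and regulon
  genes heterogeneously and less conserved; logistic OD600 growth curves in
  which the repressed-gene overexpression strain grows 40% slower than
  wild-type under osmotic stress.

**What passing tests do and do not show.** The generator plants sharp,
well-separated, singly-assigned sites, balanced RNA mass, and effects well
above threshold. Recovery of every planted count therefore demonstrates that
the pipeline's logic is correct and internally consistent — not that these
exact counts would re-emerge from noisy biological libraries with closely
spaced sites, weak effects, batch structure, or compositionally skewed
responses. The stated limitations of the binomial test and of total-count
normalization are where real data would bite first.

## Growth rates

The maximum specific growth rate is the largest least-squares slope of
ln(OD600) versus time over a sliding window of 4 consecutive points (the
source figure names the statistic but not an estimator; the log-linear sliding
window is this package's choice and is exact on pure exponentials). Relative
rates divide a mutant's rate by the wild-type rate under the same condition.

## Percentages

All printed percentages are integers rounded half-up (7/8 → 88, 34/37 → 92,
25/37 → 68, 206/243 → 85). Note 33/243 = 13.58% renders as 14 under this
convention.

## Problem sizes

Tests and the acceptance script run entirely on generated data: the 500 kb /
600-gene study-scale preset (six 10 M-read border tracks, four count
libraries), a 30 kb small preset for unit tests, 2 000-gene null simulations
over 20 seeds for FDR calibration, and 20 independent study-scale replicates
for the motif-recovery check.
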