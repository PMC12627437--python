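# Methods

## Model and assumptions

The detector works on diploid ALT-dosage genotypes (0/1/2, −1 missing)
and assumes that freely recombining sequence shows a *shared baseline*
of heterozygosity across individuals: at any window, everyone's mean
dosage fluctuates around a common level set by the local allele-frequency
spectrum.  A non-recombining block violates this — its two haplotype
arrangements accumulate fixed differences, so individuals separate into
three dosage classes (≈0, ≈1, ≈2 at the differentiated sites).  The
method is therefore sensitive to any large linked block, of which
inversions are the archetype; it cannot by itself prove that a detected
block is an inversion rather than another recombination-suppressing
structure, and it does not resolve breakpoints to base-pair precision
(differentiation decays gradually at region edges, and windows are
SNP-count based so their bp extent varies with SNP density).

## Scan procedure and parameters

| parameter | default | meaning |
|---|---|---|
| `window_snps` | 10,000 | window size in SNPs; calibrate to SNP density (small windows resolve micro-blocks, large ones are cheap and smooth) |
| `step_snps` | 2,500 | window advance in SNPs |
| `range_threshold` δ | 1.0 | min across-sample spread (max−min) of window means for a divergent window; 1.0 = one full genotype class |
| `min_run` | 3 | divergent windows required per candidate |
| `merge_gap` | 1 | quiet windows tolerated inside a run |
| `peak_tol` ε | 0.05 | windows with H ≥ (1−ε)·max H count as maximum homozygosity peaks |
| `t_low`, `t_high` | 0.5, 1.5 | karyotype call boundaries (midpoints between ideal scores 0, 1, 2) |
| `min_window_callrate` | 0.5 | min non-missing fraction for a window mean to be defined |

For dense panels (≈50k SNPs per chromosome in the bundled benchmarks) a
1,000-SNP window with 250-SNP steps resolves megabase-scale regions
well; the 10,000/2,500 default targets macro-inversions on much larger
WGS panels.

Candidate detection formalizes "divergent genotype blocks" as an
across-sample range criterion, a single interpretable knob.  `min_run`
= 3 with `merge_gap` = 1 means a single noisy window can neither create
nor split a region.

**Influence-area delimitation.**  Provisional homokaryotypes are the
samples whose mean dosage over the whole candidate span falls at or
below `t_low` or at or above `t_high`; heterokaryotypes sit near 1
inside the region and would dilute the homozygosity signal, so the peak
profile H\_w = mean over provisional homokaryotypes of |M − 1| is
computed from homokaryotypes only.  "Maximum peaks" are implemented as
the windows whose H reaches the tolerance band (1−ε)·max H within the
candidate span plus one buffer window per side; a flat plateau therefore
counts as one long peak spanning it entirely, and the influence area
runs from the start of the first band window to the end of the last.  A
strict local-maximum filter was deliberately not applied: on a plateau
the identity of the first strict maximum is set by sampling noise, which
would make the reported bounds unstable by a window step or more, while
band membership is stable.  Interior peak structure (regions can show
several internal peaks) is reported via `n_peaks` but does not affect
the bounds.  A candidate with no provisional homokaryotype is returned
flagged `undelimited` with the candidate bp span as fallback.

**Karyotype calls** are deterministic threshold calls on the area mean
dosage; a score of exactly 1.0 is heterokaryotype, and the margin to the
nearest boundary is reported so borderline calls are visible.  An
optional clustering of scores was considered and rejected as a default
because threshold calls are deterministic and auditable.

**Basal differentiation** is each individual's mean window dosage over
all windows outside every influence area — a per-individual genome-wide
background level that can expose population-specific shifts unrelated to
the linked regions.

## Corroboration statistics

* **F\_ST**: two-population Weir–Cockerham (1984) variance components
  (a, b, c) per site, vectorized; windowed value is the weighted
  Σa / Σ(a+b+c).  Negative per-site components are kept as computed.
* **LD r²**: squared Pearson correlation of dosage vectors (composite
  LD), not EM haplotype r² — the data are unphased, the estimator is
  deterministic, and block structure is what the corroboration needs.
  This can differ from phased-haplotype r² in magnitude.  Variants are
  randomly thinned (seeded) *before* pair evaluation, and pair
  separation is capped in bp.
* **π**: per-site pairwise diversity 2j(m−j)/(m(m−1)) summed per sliding
  window and divided by window length in bp.
* **Tajima's D**: non-overlapping windows, standard constants, with the
  chromosome count fixed at twice the sample count; π̂ is the summed
  per-site diversity (unnormalized).  Windows without segregating sites
  are undefined.
* **Wilcoxon contrast**: two-sided unpaired rank-sum of windowed D
  inside vs outside influence areas; exact enumeration when the smaller
  side has ≤ 10 windows and no ties, otherwise the normal approximation
  with tie and continuity corrections (the convention of the common R
  implementation).
* **MDS**: classical principal coordinates on IBS distances
  d = Σ|g\_j − g\_k| / (2·n\_shared).  Axis signs are arbitrary; the
  convention fixes the largest-magnitude loading positive.  Restricted
  to a region's SNPs, a polymorphic inversion produces three axis-1
  clusters with heterokaryotypes intermediate.
* **Rosner / generalized ESD**: k suspected outliers from the 1.5×IQR
  rule, Student-t critical values, declared outliers up to the largest
  significant rank.  Note the declared count grows (weakly) with alpha,
  since larger alpha lowers the critical values.  Applying this
  one-dimensional test to spatially autocorrelated windowed F\_ST
  reproduces common practice; no autocorrelation correction is applied.

## Synthetic data

The generator draws SNP positions uniformly without replacement,
per-site ALT frequencies uniform on [maf\_min, 0.5] folded to either
allele (so the expected ALT dosage is 1 and individual window means are
centred, as real panels are after MAF filtering), and independent
Hardy–Weinberg genotypes outside inversions.  Inside an inversion, each
individual's arrangement count κ ∈ {0,1,2} is Hardy–Weinberg in the
arrangement frequency q (or explicit); a fraction `divergence` of region
SNPs are fixed differences where genotype = κ, with the reference
arrangement carrying the REF allele; the rest stay baseline.  Defaults
(24 samples, 50,000 SNPs per 5 Mb chromosome, q = 0.5, divergence 0.9,
MAF floor 0.1, no missingness) emulate a filtered worldwide WGS panel.

What the generator deliberately omits: linkage outside inversions (the
null is fully independent sites), realistic site-frequency spectra
(the folded-uniform law plus the MAF floor yields positive baseline
Tajima's D everywhere — only the inside/outside *contrast* is
meaningful), recombination gradients at region edges, sequencing error,
and population structure.  Passing benchmarks therefore demonstrate
correct behaviour under the method's own model; on real data, edge
recombination in heterokaryotypes blurs boundaries beyond what the
benchmarks show.

## Numerical choices

* Window grid: full-length windows at every step offset, plus one
  clipped terminal window only when SNPs would otherwise be uncovered.
* Window means via cumulative sums (O(1) per window); undefined entries
  are NaN and propagate by being excluded from spreads/means.
* Coordinates are 1-based inclusive everywhere in memory and TSVs; BED
  export is 0-based half-open.
* Ties in karyotype thresholds resolve to the heterokaryote class
  (closed interval [t\_low, t\_high]).
* MAF and all frequency computations use non-missing alleles only.
* Site filters apply in the order depth → missingness → MAF (the
  per-genotype depth filter blanks genotypes, which the missingness
  filter then sees), with per-filter removal counts reported.
* CLI exit codes: 0 ok, 2 usage error (the click convention), 1 data
  error.

## Benchmark problem sizes

The bundled benchmarks (`karyoscan.benchmarks`, also driven by
`scripts/acceptance.py`) use 24 samples × three 5 Mb chromosomes of
50,000 SNPs: 20 replicates for parameter recovery, 100 for the null
false-positive rate, and one replicate for the cross-method consistency
suite.  These sizes give stable rates at interactive runtimes on a
single CPU.  In the consistency suite the MDS cluster/karyotype
agreement is scored under the better of the two axis orientations, the
axis sign being arbitrary.

## Known limitations

* Regions other than inversions (e.g. large introgressed or
  translocated blocks) produce the same signature; attribution requires
  orthogonal evidence.
* Boundary precision is limited to roughly one window step and degrades
  with low SNP density.
* A region monomorphic for one arrangement (no divergent block among the
  sampled individuals) is undetectable by construction.
* The r² estimator is composite (dosage) LD; haplotype-frequency r²
  is out of scope.
* F\_ST supports exactly two groups.
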