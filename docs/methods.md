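# Methods

## Pattern model

A glucuronide's MS/MS signature is carried by the conjugate moiety, not the
metabolite: collision-induced dissociation cleaves the glycosidic bond,
producing a fragment at the aglycone's mass (a neutral loss of the
dehydrated moiety, C6H8O6 = 176.0321 Da, or of intact glucuronic acid,
C6H10O7 = 194.0425 Da) and, in negative ESI, glucuronate product ions at
*m/z* 113.0244 (C5H5O3⁻) and 85.0295 (CO loss from 113).  All diagnostic
masses are computed at import time from elemental monoisotopic masses
(`gluconet.chem`), never hard-coded, and are unit-tested against independent
atomic-mass sums.

A `PatternQuery` is the declarative form of this fingerprint: neutral-loss
clauses OR-combined, product-ion clauses AND-combined, each clause with an
inclusive m/z tolerance (default 0.003 Da) and an inclusive
relative-intensity floor in percent of the base peak.  Four presets ship:
`neg_standards` / `neg_biological` (both losses + both products; the
biological variant adds 5% / 3% floors to tolerate matrix MS/MS noise) and
`pos_standards` / `pos_biological` (losses only — the product ions are a
negative-mode signature).  Two less common glucuronate ions (75.0088,
71.0139) are available as constants but excluded from the default queries.

Assumptions and conventions:

* Neutral losses are computed as `precursor_mz − fragment_mz` on singly
  charged precursors; multiply charged spectra are skipped with a warning by
  the collection filter rather than silently mis-scored.
* Intensity floors apply to the fragment peak relative to the base peak
  (percent-of-base convention); filtering is therefore invariant to uniform
  raw-intensity scaling and to peak order.
* Galacturonic-acid conjugates (C6 epimers) satisfy the fingerprint but show
  a discriminating fragment at *m/z* 115.0038 (C4H3O4⁻).  "High intensity"
  for this discriminator is not standardized; the default `IsomerRule`
  requires ≥ 10% of the base peak (configurable).  Suspects are *flagged*,
  not removed — the decoy evaluator (`estimate_fdr`) optionally counts them
  as negatives (`veto=True`), mirroring a visual-inspection QC step.

## Modified cosine and networking

Peak weights are √intensity, L2-normalized per spectrum (the convention of
the GNPS ecosystem).  Candidate fragment pairs match either directly
(|Δm/z| ≤ tolerance) or shifted by the precursor difference; pairs are
selected greedily by descending weight product, each peak used once, ties
broken by smaller pairing error then lower m/z.  The greedy score is
deterministic, symmetric, bounded in [0, 1], equals 1 for identical spectra,
and is tested to (a) equal the optimal assignment score on exhaustively
solvable small spectra and (b) agree with the matchms `ModifiedCosine`
reference to 1e-9 on random pairs.

Networks are built by scoring all node pairs, keeping edges with cosine and
matched-fragment counts above threshold that rank within the top-K edges of
*both* endpoints, then shrinking any connected component above the cap by
removing its lowest-cosine edge (ties: lexicographic node pair) until the
cap holds.  Two presets: `standards` (frag tol 0.005 Da, prec tol 0.002,
cosine 0.25, 3 matched, top 5, cap 25) and `biological` (0.01 Da, cosine
0.4, 3 matched, top 10, cap 100, ≥ 2 supporting files for clustering).

Because top-K pruning favors dense within-class edges (metabolite families
share many fragments), conjugate:aglycone links are preferentially removed.
`readd_delta_edges` restores any scored pair — the pre-pruning pool already
thresholded at the build cosine/fragment minima — whose |Δprecursor| lies
within 0.003 Da of a conjugation shift (176.032, 194.042, or the
glucuronide-vs-sulfate spacing 96.075).  Δ targets are matched on absolute
differences since either node may be the conjugate; re-added edges are
tagged `origin="readded"` and exempt from the top-K/component limits.

Library matching returns each node's single best match at cosine ≥ 0.7 with
≥ 4 shared peaks within a precursor tolerance; a candidate whose retention
time disagrees beyond `rt_tol` is tiered `suspected_isomer` (same mass and
fragmentation, different chromatographic identity).  Suspect propagation is
depth-1 only: an unannotated pattern-positive node linked at a glucuronide
Δ to a library-annotated aglycone *A* becomes "suspect *A* glucuronide";
a node linked at the 96.075 Δ to an annotated "*X* glucuronide" becomes
"suspect *X* sulfate".  Multiple candidate labels are all reported, ranked
by edge cosine; direct library matches are never overwritten.

## Feature-table statistics

* **Richness**: per-sample count of features with area strictly above a
  matrix-specific noise threshold.  Shipped thresholds (area units):
  colon 250,000; germ-free/colonized urine 250,000; serum 50,000;
  antibiotic-study urine 300,000.
* **Poisson count test**: two-group log-linear comparison; the MLE rate
  ratio is mean_b/mean_a and the Wald SE of its log is √(1/Σa + 1/Σb) —
  verified against an IRLS Poisson GLM to 1e-6.  A zero group total gets a
  0.5 continuity correction on both sums (logged).
* **Differential abundance**: areas are log2-transformed (zeros replaced by
  half the smallest nonzero area in the table, configurable), Welch
  two-sample *t* per feature, Benjamini–Hochberg across features;
  significant iff q < 0.1 and |log2FC| > 1.  log2FC is computed on raw
  group means.  Features with zero variance in both groups get p = 1
  (logged).  Dunnett-style many-to-one comparisons are out of scope; Welch
  + BH per comparison is the supported design.
* **Ordination**: Bray–Curtis d = Σ|x−y| / Σ(x+y) (all-zero pairs defined
  as distance 0), classical PCoA by double centering + eigendecomposition;
  negative eigenvalues (expected for non-Euclidean dissimilarities) are
  reported, not dropped, and axis variance fractions are relative to the
  positive-eigenvalue sum.  PERMANOVA is intentionally not implemented —
  distance matrices are exportable for external testing.
* **Cross-matrix overlap**: features match across matrices when |Δm/z| ≤
  0.01 Da, |ΔRT| ≤ 12 s and (when representative spectra exist) modified
  cosine ≥ 0.7; matches merge into connected components counted Venn-style.
  The tolerances are package defaults, chosen at typical UHPLC–Orbitrap
  reproducibility.

## Synthetic data: what it emulates, and what it does not

The generator (`gluconet.synth`) draws aglycone spectra with uniform-random
fragments below the precursor and builds conjugates by shifting the
precursor by the *exact* moiety mass (C6H8O6 176.0321; SO3 79.9568) while
retaining the aglycone fragments.  Key modeling choices:

* Retained fragments are intensity-jittered (×0.5–1.5) and dropped with
  probability 0.2 (≥ 3 always kept): conjugation alters fragmentation
  efficiency, so a conjugate resembles but does not duplicate its aglycone.
  This is what makes network pruning non-trivial — with verbatim copies the
  conjugate:aglycone edge would always dominate and edge re-addition would
  never fire.
* Diagnostic intensities (product ions, 115.0038 discriminator) are drawn
  at 20–80% of base, above the 3–5% query floors and the 10% veto, so on
  clean data filter sensitivity is exactly 1.
* Galacturonide decoys always carry the neutral loss and the 115.0038
  discriminator but yield the 113/85 product pair only with probability 0.7,
  emulating variable fragmentation; this separates the NL-only and
  NL+product queries' FDR, the property the decoy evaluation exists to show.
* Noise peaks are uniform in m/z with intensity capped below 3% of base, so
  default noise can never satisfy a floored clause or the veto.
* Family-structured datasets (default 4 families × 15 aglycones for the
  network benchmarks; 10 × 25 for the 500-spectrum end-to-end run) share a
  6-fragment core per family, emulating metabolite classes that form dense
  network components.
* Feature tables plant colonization shifts at 4-fold (log2FC = 2) with
  log-normal noise (σ = 0.5 log2 units, ≈ 41% CV): 90% of colon features
  shifted down, 60% of serum and 20% of urine shifted up, with 20 shared
  conjugates across all three matrices carrying identical m/z, RT and
  representative spectra.

What passing tests on these data do **not** show: real fragmentation
chemistry (no isotope patterns, no chimeric spectra, no mass-dependent
intensity structure), real decoy diversity (only galacturonides, not the
broader glycoside space), chromatographic drift, or MS1 alignment errors.
Results on synthetic data demonstrate correctness of the algorithms under
the stated model, not instrument-level performance.

## Numerical and design details

* Peaks within 1e-6 Da are merged (intensity sum, intensity-weighted
  centroid) at construction, so greedy matching sees unique m/z values.
* All tolerance comparisons are inclusive (≤); widening a tolerance or
  lowering a floor can only add matches (tested monotonicity).
* Retention times are stored in seconds; mzML readers convert
  minute-denominated scan times.
* MGF dialects: `PEPMASS` may carry an intensity second token; `CHARGE`
  accepts `1-` and `-1`; polarity comes from the charge sign with a
  per-file override.  mzML support is a compact internal reader/writer for
  the PSI 1.1 schema (centroided MS2, 32/64-bit plain or zlib arrays).
* Determinism: every stochastic routine takes a `numpy.random.Generator`
  seeded from a single config seed; a fixed seed reproduces MGF/TSV outputs
  byte for byte.
* Problem sizes in the shipped benchmarks (decoy library 200/100/200,
  network datasets of 120 and 500 spectra, 50 replicates of 200-feature
  tables) were chosen as the smallest sizes at which the measured
  proportions are stable to a few percent across seeds.

## Known limitations

Charge > 1 spectra are skipped, not deconvoluted.  Classical-style
clustering collapses isomers into consensus nodes; positional isomerism is
therefore not resolved (suspect labels deliberately omit attachment
positions).  The Poisson richness test ignores overdispersion; for strongly
overdispersed designs a negative-binomial model would be preferable.  The
suspect propagation is depth-1 by design and will not chain through
unannotated intermediates.
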