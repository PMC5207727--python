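# Methods

`cfwgs` re-implements, at desk scale, the standard shallow whole-genome
analyses applied to circulating cell-free DNA (cfDNA): insert-size spectra,
coverage uniformity, 10 kb window profiles for sample similarity, GC-corrected
copy-number profiling with circular binary segmentation, and nucleosome
footprints read off fragment boundaries.  Because no patient-scale data ship
with the package, every analysis is validated by *parameter recovery*: a
synthetic fragment generator plants known structure, and the analyses must
recover it.  This note records the generative model, the defaults and why they
hold, and what passing tests do and do not establish.

## Generative model for cfDNA fragments

cfDNA is modelled as the product of inter-nucleosomal nuclease digestion
during apoptosis.  The simulator (`cfwgs.sim`) draws each fragment as follows:

1. **Site selection.**  A nucleosome dyad is chosen with probability
   proportional to `occupancy x copy-number weight x GC factor`.  The
   copy-number weight of a position with tumor copy number `c` at tumor
   fraction `tf` is `tf*c/2 + (1-tf)`, i.e. a mixture of tumor-derived and
   normal-diploid fragments.  The GC factor is
   `exp(-gc_bias_strength * (GC - 0.35)^2)` over the protected interval:
   smooth, monotone decreasing above 35% GC, and deliberately of a form a
   LOESS fit can recover and remove.
2. **Positioned vs diffuse fragments.**  With probability `phased_fraction`
   (default **0.16**) the fragment is centred on the chosen dyad; otherwise it
   is centred at a diffuse genomic position drawn with the same copy-number/GC
   weighting.  The diffuse component models the cell-population average:
   most cells do not share the reference nucleosome phasing, which is what
   limits the coverage dip over the nucleosome-depleted region (NDR) to ~20%
   rather than ~100%.  The default is the closed-form calibration to that
   20% target: the NDR coverage level is `(1-phi)/((1-phi)+phi*rho)`, where
   `rho ~= 1.33` is the measured phased/diffuse regional density ratio on the
   default TSS scene, giving `phi = 0.25/(rho+0.25) ~= 0.16`.
3. **Protected span.**  The pre-trim span is `protection_len + round(trim_quantum)`
   = 167 + 11 = **178 bp**, i.e. cuts initiate one trimming quantum into the
   linker beyond the 167 bp chromatosome.  With probability
   `dinucleosome_fraction` and an adjacent dyad within 260 bp, a dinucleosomal
   span of 2 x 167 = 334 bp centred on the pair midpoint is emitted instead
   (2% in plasma mode, 20% in body-fluid effusion mode — the effusion value is
   a placeholder; the real fraction is reported only as "noticeable").
4. **End trimming.**  Each end is independently trimmed by `round(k * 10.6)` bp
   with `k ~ Geometric(p=0.45)` (support 0, 1, 2, ...), floored so at least
   `min_frag_len` = 80 bp remain.  The sum of two such trims has its mode at
   *one* quantum, so the emitted length spectrum peaks at 178 - 11 = 167 bp
   with a ladder of sub-peaks spaced ~10.6 bp below it — the observed
   mononucleosomal mode and sub-peak ladder.  The 178/167 geometry also makes
   the 5'/3' boundary-frequency peaks of one nucleosome sit ~177 bp apart
   (the reported ~180 bp), which a directly-emitted 167 bp span cannot do.
   The quantised-end-trimming model is one of two readings of the 10.6 bp
   ladder (the alternative is helical-pitch periodicity of the cut sites
   themselves); the package adopts trimming and plants it accordingly.
5. **Masking.**  Fragments overlapping an N gap or one of the sample
   patient's private germline deletions are redrawn.  Output is fully
   deterministic given `SamplingConfig.seed`.

Sheared gDNA controls (whole blood, tumor tissue) instead draw insert sizes
from Normal(350, 35) truncated to [50, 700] and positions uniformly under the
same copy-number/GC weighting — mechanical shearing carries no nucleosome
signal.

## Planted nucleosome architecture

* **TSS** (priority zone ±1000 bp): an NDR over gene-oriented (-170, 0), four
  upstream dyads at -250, -430, -610, -790 and five downstream at +90 ... +810
  (180 bp repeat), occupancy 1.  These counts and the repeat are what the
  footprint caller must recover.
* **ESS/EES** (zone ±500 bp): two sub-nucleosomal particles (120 bp span,
  occupancy 0.5) at ±120 bp of the exon boundary plus two minor full
  nucleosomes (occupancy 0.4) at ±350 bp.  The particle edges produce four
  sharp boundary peaks at ~±60 and ~±180 bp — within ±200 bp and closer
  together than a mononucleosome, as observed at exon starts — and the minor
  dyads produce the two weaker peaks further out.  The 120 bp span is chosen
  so trimmed particle fragments land on the main 10.6 bp ladder and do not
  add foreign peaks to the size spectrum.
* **Background**: dyads every ~200 bp with ±60 bp jitter elsewhere,
  excluded from anchor zones and N gaps.

Anchors are edge coordinates, gene-oriented (minus-strand exon `[s,e)` has
its start site at `e`); all intervals are 0-based half-open; relative
coordinates are `p - a` on plus and `a - p` on minus strand.

## Analysis defaults

* **Size-spectrum peak detector**: centred moving average (3 bp), prominence
  ≥ 0.1% of total count, separation ≥ 5 bp; the primary mode is the raw
  histogram argmax.  The source figures mark maxima without stating a
  detector; these are package defaults, documented rather than inferred.
* **Windows**: consecutive non-overlapping 10 kb; trailing partial windows
  are kept for coverage fractions but excluded from clustering/PCA/CNV
  vectors; fragments map to the window containing their midpoint; windows
  with raw count strictly above the 99.9th percentile are masked.
* **GC normalization**: LOESS (span 0.3, 2 robustness iterations) of count on
  window GC over unmasked autosomal windows with GC in [0.25, 0.70];
  normalized count = raw x median(fit)/fit(GC); degenerate GC spread
  (< 0.02) skips normalization.
* **Clustering / PCA**: Euclidean distance on covered-fraction vectors with
  Ward linkage on raw observations (equivalent to R's Ward.D2); PCA is
  centred but unscaled, since the features are already commensurate
  fractions in [0, 1].
* **log2 ratios**: each profile's GC-normalized counts are scaled by their
  autosomal **median** (not the mean): a focal amplification inflates the
  mean and would bias every absolute copy call downward, while the median
  pins the 2-copy baseline at log2 = 0.  Windows with zero or masked control
  are dropped.
* **CBS**: exhaustive O(m²) arc scan of the pooled-sd standardized
  arc-vs-complement mean difference; permutation test with alpha = 0.01 and
  n_perm = 1000, with sequential early stopping once the exceedance count
  already implies p > alpha (identical accept/reject decisions, large
  speedup on null segments); segments narrower than 3 windows merge into the
  neighbour with the closer mean; "undo splits" pruning is omitted.
  Copy calls: raw CN = `2 * 2^mean_log2`; with a known tumor fraction,
  `CN_tumor = (CN_raw - 2(1-tf))/tf`, clamped at 0 and rounded.
* **Footprints**: boundaries tallied per 5 bp window over ±1000 bp (TSS) or
  ±500 bp (ESS/EES), divided by the number of deduplicated, autosomal
  anchors.  Peaks are unsmoothed local maxima filtered by prominence
  (≥ 15% of the track's dynamic range *and* ≥ 4 sd of the median per-window
  Poisson count — the absolute floor is what keeps featureless gDNA tracks
  call-free) and separation (120 bp at TSS scale, 80 bp at exon scale, where
  the planted peaks are 120 bp apart and trim echoes fall within 80 bp).
  Each 5' peak pairs with the nearest 3' peak downstream; pairs spaced
  120-220 bp count as nucleosomes, classed upstream/downstream by midpoint
  sign.

## Packaged study conditions

Scenes are deliberately desk-scale so the full pipeline runs in seconds:

* size spectrum: 1 Mb genome, 10 genes, 1e5 fragments;
* TSS footprints: 2 Mb genome, 200 genes at 10 kb pitch, 2e5 fragments;
* exon footprints: 1 Mb genome, 100 four-exon genes (300 interior exon
  starts), 2e5 fragments;
* cohort: 4 x 1.2 Mb autosomes + 0.6 Mb chrX (one 20 kb N gap), 3 patients x
  {blood, tumor tf=1, plasma cfDNA tf=0.5}, 1e5 fragments per sample.  Each
  patient carries 50 private homozygous germline deletions of 300-3000 bp
  shared by all their samples, and an aneuploid somatic profile (per autosome,
  2 of 3 random segments at copy number in {1, 3, 4, 6});
* focal amplification: 5 Mb genome with the packaged 500 kb, 20-copy
  amplicon against a flat sheared control;
* GC properties: a 30 Mb flat diploid chromosome (3000 windows).  The
  window count matters: under the null, Spearman's rho between counts and GC
  has sd ≈ 1/sqrt(n_windows), so the |rho| < 0.05 neutrality/de-biasing
  checks are only meaningful well above ~2000 windows.

A small helper (`add_promoter_gc`) plants a CpG-island-like GC elevation
(+0.12, sd 300 bp) at each TSS; it is used by the scene that demonstrates the
negative correlation between metagene coverage and GC in GC-biased sheared
gDNA, since that relationship is undefined on a GC-flat landscape.

## What the synthetic cohort does and does not emulate

Emulated: mononucleosomal size structure with the 10.6 bp ladder and
dinucleosomal shoulder; phased TSS/exon-boundary protection with an upstream
NDR; normal-distributed sheared controls; smooth monotone GC bias; planted
segmental CNV diluted by tumor fraction; patient-private germline deletions
that drive patient-wise clustering.

Not emulated: sequencing error and base qualities, mappability structure,
duplicate reads, chromatin heterogeneity between tissues, somatic SNV/indels,
isoform-level TSS multiplicity, centromeric/telomeric artifacts, and real
inter-patient variability in fragment-size distributions.  Passing recovery
tests therefore demonstrates the *analyses* are correct and well-calibrated
on data satisfying their own assumptions — not that those assumptions hold in
any particular clinical sample.

## Numerical and degenerate-input choices

Histogram peak tracks are padded below zero so boundary maxima count; a
histogram with under three distinct lengths yields a flagged single/empty
peak set.  Interval work is integer; depth uses difference arrays;
zero-count or all-N windows are masked, never pseudocounted.  The CBS arc
statistic is exactly symmetric under circular complementation, so scanning
linear arcs covers wrapped ones.  Constant segments (sd 0) never split.
Fragment end trimming floors at `min_frag_len` by reducing the 3' then 5'
trim.  Mirrored minus-strand fragments can sit one base off their plus-strand
images because the even 178 bp span cannot centre symmetrically on a dyad;
strand-symmetry comparisons therefore rebin 5 bp windows to 10 bp.

## Known limitations

The 5'→3' boundary peak spacing recovered from the planted architecture is
~175 bp at 5 bp window resolution (the planted repeat is 180 bp); the
detector reports window centres, so sub-window accuracy is not available.
CBS p-values use within-segment permutation only; no undo-splits pruning
means over-segmentation is possible at very high signal-to-noise (the narrow
-segment merge absorbs most of it).  The LOESS fit is univariate in GC;
mappability or replication-timing covariates are out of scope.  Copy-number
deconvolution by tumor fraction assumes the fraction is known rather than
estimating it.
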