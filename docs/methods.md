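# Methods

## The measurement model

An 8-plex isobaric-tag experiment labels up to eight samples with tags that
co-elute and co-fragment; each fragmentation spectrum therefore yields one
reporter-ion intensity per label, and relative quantification is *within
spectrum*: whatever governs how well a peptide ionizes is common to all eight
channels and cancels in any cross-channel ratio. The pipeline leans on this
in two places: protein signals are summed over the same PSMs in every
channel, so stage-to-stage protein ratios are free of per-peptide efficiency;
and the synthetic generator draws one ionization factor per peptide shared
across channels, which makes the cancellation a testable property rather
than an assumption (`test_ionization_factors_cancel_noise_free`).

Because each channel is labeled with (nominally) the same total protein
amount, per-channel signals are *composition* measurements: a protein's
reporter intensity tracks its share of that stage's total protein, not its
absolute titer. All downstream quantities (clearance ratios, detectability,
composition) are defined on that scale.

## Channel-sum normalization

Labeling efficiency and loading are never perfectly equal, so each sample
channel is rescaled to make all channel sums equal to the mean input sum.
The operation is linear per column, hence idempotent and exactly
ratio-preserving within a column. The target (mean of column sums) is a
symmetric choice; max- or reference-anchored targets would differ only by a
global scalar.

Blank channels are deliberately excluded from the equal-sum constraint: a
sample-free channel's sum is pure background, orders of magnitude below a
sample channel's, and forcing it equal would inflate the noise floor by the
same orders. Blanks are instead scaled by the mean of the sample factors so
that background and signal stay on one common scale. Consequence: the
normalization (and the detection threshold) presumes roughly equal loading
across sample channels; for data with grossly unequal loading the blank
scaling is only as good as the mean factor.

## Protein roll-up and the unique-peptide gate

Per-protein signal sums normalized intensities over PSMs whose peptide maps
to exactly one protein group. Shared peptides are kept as identification
evidence (they raise the spectral count) but contribute no signal, since
their intensity cannot be attributed. A protein is *quantifiable* with at
least `min_unique_peptides = 3` distinct unique peptide sequences — the
conventional robustness gate; it is a parameter, not a constant, and the
quantifiable count is non-increasing in it. All-zero-intensity PSMs are kept
as identifications and excluded from every ratio.

Protein ratio vectors divide each sample label's signal by the mean over
sample labels (blanks are not samples and would dilute the mean); each
vector has mean 1 by construction. Zeros propagate as true zeros — no
imputation anywhere, because imputed values would leak into the
detectability calls.

## Noise model and limit of detection

Background reporter intensity (chemical noise, co-isolation residue) is
modeled log-normally from the pooled positive blank-channel intensities:
`μ_log, σ_log` are the mean and (n−1) standard deviation of the log blanks,
and the limit of detection is `exp(μ_log + k·σ_log)`, `k = 3` by default —
the standard mean + 3σ convention applied where the noise is approximately
Gaussian (the log domain). One global model is fitted: blanks carry no
protein-specific information.

A protein's stage signal for the detection call is its replicate-mean signal
divided by its quantified PSM count, i.e. a per-spectrum-scale quantity
directly comparable to the per-spectrum blank distribution. Without this
division a protein with many spectra would look "detectable" merely because
it was sampled often. Designs without blank labels (the eight-sample layout)
must supply an explicit floor (`set_noise_floor`), which is flagged
`user-supplied` in all reports.

Measured operating characteristics under the default generator (1000
proteins × 10 seeds): pure-background proteins are called detectable in
far less than 2% of protein×stage cells, and proteins whose expected
per-spectrum signal exceeds 10× the threshold are detected in >99% of cells
(`test_detection_operating_characteristics`, recomputed by
`scripts/acceptance.py`).

## Flux classification

For an ordered stage pair, each quantifiable protein's mean ratio is the
destination-stage replicate-mean signal over the source-stage replicate-mean
signal — means are taken *before* the division, which is robust to a single
replicate dropout (the mean-of-ratios alternative is undefined whenever any
single source replicate is zero). Fate: retained if the ratio is ≥ 1
(a tie reads as "preferentially retained"; the comparator is configurable),
decreased if < 1, infinite ratios (0 → signal) count as retained, 0/0 is
undefined and reported below detection. Merging with the detection calls
yields the three per-step lists: above detection at the destination, and its
retained/decreased partition. Both previous-stage and arbitrary anchored
transitions (e.g. everything relative to HCCF) are supported — the two
framings answer different questions and neither is privileged by the API.

## The synthetic generator

The generator produces PSM tables whose statistical structure matches what
the analysis assumes, with full ground truth:

* **Abundances.** HCP abundances at HCCF are log-normal (`abundance_sdlog`
  default 1.5 ≈ four orders of magnitude across ±3σ), normalized to the HCP
  share of a fixed per-channel total. Truth lives in composition space:
  every stage's channel total is the same constant, emulating equal protein
  loading per label, and the mAb takes up whatever the HCPs do not. The
  drawn clearance factor is then *exactly* the quantity a channel-sum
  normalized ratio estimates, and `abundance(s+1) = abundance(s) × factor`
  holds identically.
* **Clearance.** Per transition, a protein is retained with probability
  `frac_retained` (default 0.1); retained factors are `exp(+|N(log 1.4, 0.3)|)`,
  decreased factors `exp(−|N(log 0.3, 0.5)|)` by default — a typical
  polishing-step depletion of ~3×, overridable per transition. The folded
  draws guarantee class and factor never disagree.
* **mAb dominance.** The product chains' PSM count is inflated to a target
  share of all PSMs (default 83.4%), reproducing the stochastic
  undersampling of HCP identifications a capture-stage-heavy multiplex
  shows; their abundance share defaults to the same fraction (spectral
  sampling roughly proportional to amount). One consequence worth knowing:
  because a PSM's intensity scales with the whole chain's abundance, the
  *intensity-share* composition reads higher for the mAb than its molar
  share — as in real reporter data, where product peptides are individually
  intense.
* **Chain stoichiometry.** LC:HC is 2:1 at HCCF (free light chain present)
  and 1:1 from the Protein A eluate onward; the balanced HC:LC series
  recovers 2.0 at HCCF within 3 SE over seeds
  (`test_hc_lc_stoichiometry_recovery`).
* **Intensities.** `I = abundance × ion_factor × noise + background`, with
  mean-one log-normal noise (`replicate_cv`, default 0.1), per-peptide
  log-normal ion factors (sdlog 1.0), and additive log-normal background
  `LN(blank_mu=0, blank_sigma=0.8)` in *every* channel; blank labels receive
  only background. ~5% of HCP peptides are shared with a second protein.
  No isotope-impurity cross-channel bleed is simulated.

What the generator does **not** emulate: chromatographic physics (the
Protein A flow-through keeps a nominal mAb share rather than being
product-free), retention-time or fragmentation structure, ratio compression
from co-isolation, decoys/FDR, or abundance-dependent PSM sampling for HCPs
(peptide and spectra counts are drawn independently of abundance). Passing
tests therefore validate the *analysis contracts* — normalization,
cancellation, thresholding, classification — not instrument realism.

## Problem sizes and numerical choices

Validation studies use 200 HCPs × 10 seeds for clearance recovery
(measured median |log2 est − log2 true| ≈ 0.07, bound 0.15), 1000 proteins
× 10 seeds for detection characteristics, and 100 HCPs × 10 seeds for
stoichiometry — sizes at which standard errors are comfortably below the
acceptance bands while a full run stays in the tens of seconds. Determinism:
one `numpy` `default_rng` per generation, fixed draw order; identical seeds
give byte-identical PSM tables and report bundles. Row z-scores use the
sample (n−1) standard deviation; constant rows map to zeros with a warning.
Heatmap values are log2 protein ratios before z-scoring (a symmetric
transform for a symmetric color scale); rows containing zero or undefined
ratios are dropped from the heatmap rather than pseudocounted. Histogram
bins are half-open `[i·w, (i+1)·w)` anchored at 0 with `w = 0.2`; infinite
ratios are tallied separately.

## Known limitations

* Detectability calls inherit the equal-loading assumption of channel-sum
  normalization; strongly unequal designs should supply an explicit floor.
* The noise model is global and log-normal; heavy-tailed or
  protein-correlated background would need a per-protein extension.
* No absolute (ppm-by-mass) calibration: all quantities are relative shares;
  anchoring to an ELISA-style total would be a separate calibration layer.
* Ratio compression from co-isolation is neither simulated nor corrected;
  real clearance factors will be attenuated relative to truth.
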