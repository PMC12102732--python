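# Methods

## The data-reduction model

The package operates downstream of peak detection and database search: its
inputs are per-replicate peptide-identification tables, one CSV per
replicate injection, sorted into subfolders named for the DT-vs-FWHM
trendline used during processing (`11_13` for the 11–13 line; single-pass
data, processed with an auto-calculated trendline, is always `1_1`).

A **trendline** is the straight line through (DT bin 0, FWHM_start) and
(DT bin 200, FWHM_end). Only the two anchors are part of the notation; the
interpolation between them is taken to be linear because the auto-calculated
trendline is itself a linear regression of observed DT-vs-FWHM points, so a
line is the faithful model family. Evaluation outside [0, 200] clamps to the
nearest anchor: drift-time bins are bounded by the 200-push gated
acquisition window, so no extrapolation beyond it is meaningful. The
auto-calculated trendline is an ordinary-least-squares fit evaluated at
bins 0 and 200; anchors that come out non-positive are clamped to a floor
of 1.0 bin, the smallest physically sensible smoothing width.

The per-trendline pipeline runs in a fixed stage order:

1. **replicate merge** on the identity key (protein, sequence,
   modification) — charge states collapse into one key, while a
   modification distinguishes otherwise-identical sequences;
2. **replicate-count and RT-RSD filters**;
3. **metric averaging and filtering**;
4. **rank by PLGS score, deduplicate** to one record per key.

Stage order matters: replicate agreement and retention-time stability are
evidence about the *identification*, so they are judged before metric
averaging can blur them.

### Numerical conventions

* RT-RSD is the sample (n−1) standard deviation over the mean, in percent.
  A key seen in one replicate has RSD 0 by convention, so the replicate-count
  threshold, not RSD, governs singletons.
* If a replicate contains the same key more than once, its highest-scoring
  instance represents that replicate; coordinates are taken from the overall
  top-scoring representative.
* All metric averages are arithmetic means over the representing instances.
  The ppm mass error is averaged as a mean of absolute values, since the
  filter is two-sided and systematic sign information is calibration, not
  identification quality.
* Every threshold comparison is inclusive (≥ / ≤).
* Ranking ties break on higher summed product intensity, then smaller
  absolute ppm error, then the lexicographic identity key, making the
  pipeline deterministic and invariant to input row and file order.
* Best-trendline ties break toward the smaller FWHM_start: the
  least-smoothing line carries the least risk of merging distinct
  ion-mobility features.

### Threshold defaults

The shipped defaults (`FilterThresholds()`) are working values typical of
HDX peptide-map curation practice, not calibrated constants: 2 replicates,
RT-RSD ≤ 5%, ≥ 0.2 products per amino acid, intensity ≥ 5000, length 5–40,
≥ 3 matched and ≥ 2 consecutive products, summed product intensity ≥ 1000,
PLGS score ≥ 6.5, |ppm error| ≤ 10. They are meant to be tuned per
instrument and target through the YAML profile; every algebraic guarantee
the tests assert (monotonicity, union law, idempotence) holds for any
threshold set.

### Pooling

Multi-sequence merging pools the single-pass (`1_1`) list with the best
multipass trendline's list; multi-trendline merging pools every folder.
In both cases each folder is replicate-merged and replicate/RSD-filtered
separately — those two filters are per-experiment properties — and only
then pooled, metric-filtered and deduplicated. Because the metric filters
act record-wise, the pooled unique-key set equals the union of the
per-folder filtered key sets (the "union law" checked against a brute-force
set-union oracle in the tests), and pooling can only add peptides relative
to the best single route.

## Coverage and redundancy

Coverage is 100 × (residues with depth ≥ 1) / protein length, with depth
counting unique peptides whose [start, end] span (1-based, inclusive)
contains the residue. Redundancy is the summed depth divided by the number
of *covered* residues — the mean number of peptides informing each covered
position — and 0 when nothing is covered. The alternative full-length
denominator is available as a switch (`redundancy_denominator="total"`),
since both conventions appear in practice; the covered-residue form is the
default because it matches "peptides covering each amide position" averaged
over positions that have coverage. No HDX-specific exclusion of the first
one or two residues is applied: these are peptide-level mapping metrics,
not uptake metrics.

## The simulator

The simulator replaces the proprietary, platform-bound peak-detection and
search engine so the pipeline can be exercised against known ground truth.
What it emulates, and how:

* **Digestion** — nonspecific acid proteases cut promiscuously, so planted
  peptides are `round(density × length)` random overlapping fragments with
  lengths uniform in 5–25 residues (default density 0.5). Cleavage-rule
  tables are deliberately not modeled; the pipeline is agnostic to where
  peptides come from.
* **Wrap-around** — an ion with per-pass drift time *t* observed after *n*
  passes appears at `(t·n) mod 200`. The default profile uses 6 passes.
* **Detection** — each true peptide draws its multipass FWHM from a
  two-component Gaussian mixture (means 8 and 20 bins, SD 1, equal
  weights), *independent of drift time* — this independence is precisely
  the broken DT-FWHM correlation that wrap-around causes. A trendline
  detects the peptide per replicate with probability
  `p_max · exp(−(FWHM_trendline(dt) − FWHM_true)²/(2σ²))`, `p_max` = 0.95,
  σ = 3 bins. The Gaussian kernel is this package's own model of the
  under-/over-smoothing loss mechanism; only the qualitative shape (IDs
  collapse when the trendline is far from the true width) is anchored in
  observation, so the kernel parameters are config-exposed.
* **Single pass** — FWHM follows the linear law 4 + 0.01·DT with SD 0.3,
  and detection uses the auto-fitted trendline at a lower ceiling
  (`sp_p_max` = 0.7), emulating the co-elution losses that motivate
  multipass separation. The default trendlines (7–9 and 19–21) are matched
  to the two mixture components.
* **Noise** — per-emission jitter: RT SD 0.02 min, score SD 0.3, ppm error
  N(0, 2), 10% lognormal intensity scatter. Base metrics are drawn so true
  peptides pass the default thresholds in expectation (scores 7–9.5,
  intensities 10⁴–10^5.5, ≥ 3 matched products, …).
* **False positives** — one decoy per filter rule, each violating its rule
  by a wide *deterministic* margin (e.g. score at 30% of the threshold;
  RT offsets of ±1.5 min giving ~15% RSD; presence in a single replicate)
  while passing every other rule comfortably. This makes per-rule filter
  efficacy auditable: a decoy must vanish when its rule is active and
  survive when that rule alone is disabled.
* **Randomness** — one user seed is fanned out deterministically to a
  substream per (trendline tag, replicate) via seed sequences keyed on a
  stable CRC of the tag, so output is byte-identical across runs and
  independent of iteration order.

What the simulator does **not** model: raw ion-mobility spectra, isotopic
envelopes and deconvolution errors, fragment spectra, chimeric
co-elution, charge states, deuterated data, and realistic score
distributions for near-threshold identifications. Passing tests therefore
demonstrate that the *data-reduction logic* is correct (merging, filtering,
ranking, pooling, accounting), not that the thresholds are well-calibrated
for any particular instrument's error structure.

## Problem sizes

Tests and the acceptance script use a 300-residue protein, ~150 true
peptides, 11 decoys, 3 replicates and 2–6 trendlines — sizes chosen so the
full suite runs in seconds while keeping per-replicate detection counts
(~70–120 rows) in the regime where replicate statistics behave like real
triplicate injections. The trendline-response sweep uses a 400-residue
protein and a single-component width population so the expected count
profile is unimodal by construction (a bimodal population would correctly
produce a bimodal response).

## Known limitations

* The export CSV dialect is self-defined (documented column names with a
  configurable column map); it is not guaranteed byte-compatible with any
  vendor import format.
* Periodic-DT "unwrapping" (re-linearizing DT-vs-FWHM from ion periodic
  drift times) is out of scope; the iterative multi-trendline strategy is
  the supported mitigation.
* FDR estimation by decoy databases is not implemented; quality control is
  threshold filtering plus downstream manual curation, with the simulator's
  planted decoys serving validation, not production FDR control.
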