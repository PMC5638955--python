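# Methods

`ptascreen` implements two computational pipelines used when engineering
synthetic incompatibility: screening candidate genes for lethal
overexpression by colony growth-rate estimation from petri-dish scanner
time-lapses, and assessing how many polymorphism-free promoter sites are
available for programmable transcriptional activators (PTAs) in outbred
populations. This note records the models, the parameter choices that
matter, what the synthetic benchmarks do and do not show, and the design
decisions that were genuinely open.

## Stage 1 — colony growth rates from plate scans

### Image model and pipeline

Frames are RGB scans taken on a fixed cadence (default 2 h) with the first
frame acquired before any colony appears. The pipeline:

1. **Value channel.** Each frame is reduced to the HSV value channel,
   `V = max(R, G, B)` scaled to [0, 1] — the channel with the highest
   colony/background contrast on dark-background scans. A config flag
   inverts the signal for scans where colonies are darker than background.
2. **Background subtraction.** The colony-free first frame is subtracted
   from every frame and the result clipped to [0, 1]; frame 0 becomes
   all-zero by construction.
3. **Smoothing.** Every frame is convolved twice with a truncated,
   renormalized Gaussian (sd 1 px, 7 × 7 support). Because the truncation
   window is square, separable 1-D filtering is exact.
4. **Thresholding.** A single scalar threshold is applied to all frames of
   a series (pixel on ⇔ value > threshold). The default resolves the
   threshold automatically as Otsu's threshold on the final smoothed frame,
   which has the best-separated bimodal histogram; a near-constant final
   frame triggers a warning and a configured fallback.
5. **Seeding.** Colony centres are regional maxima of the through-time
   z-projection (per-pixel *sum* of the binary masks — a maximum projection
   of binary masks carries no peak structure), smoothed once with the
   preprocessing kernel to stabilize maxima on the integer-valued sum.
   Peaks closer than `min_seed_separation_px` are suppressed and seeds must
   lie on the final-frame foreground.
6. **Splitting and tracking.** Every frame is partitioned by a watershed on
   the negated Euclidean distance transform, flooded from the global seeds,
   so merged colonies are divided along the ridge between their distance
   peaks. Rerunning the watershed per frame with global seeds keeps track
   identity stable by construction. A colony's area at a frame is its
   label's pixel count; frames before appearance give area 0.
7. **Exclusions.** A colony is flagged `edge` when its final-frame region
   reaches within `edge_margin_px` (default 5) of the image border,
   `merged_with_edge` when it shares a final-frame connected component with
   an edge colony, and `ambiguous_merge` when its component holds more than
   `max_seeds_per_component` (default 5) seeds. Any flag excludes the
   colony from rate estimation. The ambiguity cap is a quantitative
   stand-in for an inherently qualitative judgement ("too many peaks in one
   blob"); it is configurable and recorded in the output.

**`min_seed_separation_px`.** This parameter means "roughly a small colony
diameter at first detection". The package default is 10 px; analyses should
set it from the data. With the synthetic generator's 150 px² initial
colonies (≈14 px diameter), 10 px allows two regional peaks on one
just-appeared colony's plateau, so the recovery studies derive the value
from the known initial area (15 px). For real scans, estimate the diameter
of the smallest colony at first appearance.

### Growth-rate estimator

Rates are maximum moving-window slopes: within every window of
`window_h = 12` h starting at an observed timestamp, ln(area) is regressed
on time by ordinary least squares using only frames with positive area, and
the largest slope over all windows (≥ `min_points = 3` positive frames) is
the colony's rate, in e-folds per hour (natural log; other bases only
rescale). Zero areas are dropped rather than pseudo-counted, which avoids
offset-induced bias and lets windows straddling the colony's appearance fit
the purely exponential early points. Numerically tied windows resolve to
the earliest. A track with no qualifying window yields an explicit
no-estimate result, distinct from a slope of 0. Excluded tracks are
refused.

The estimator takes a max over many noisy fits, so isolated colonies with
very fast rates (few frames between appearance and the area cap) can be
overestimated by tens of percent; across the benchmark rate range
U[0.1, 0.6]/h the *median* relative error is ~1–2% (see below), and the
no-growth phenotype (true rate 0) stays below 0.01/h, an order of magnitude
under the slowest real growth.

Plate-reader (OD600) rates are the least-squares slope of
ln(OD − background) over 210–330 min, reads every 10 min. The background is
the well's first reading by default; a blank-well mean or explicit value
can be supplied instead (required for exact recovery when the inoculum
itself contributes to the first reading). Non-positive subtracted readings
are dropped; fewer than three surviving points is an error.

Group comparisons are standard one-way ANOVA (scipy) followed by Tukey's
HSD adjusted pairwise p-values (statsmodels); a definitional
sums-of-squares oracle cross-checks the F statistic in the tests.

## Stage 2 — promoter conserved regions and PAM sites

For each annotated gene the promoter window is the `window_bp = 1000` bases
immediately upstream, strand-aware ([start−1000, start−1] for `+` genes,
[end+1, end+1000] for `−`), truncated at chromosome ends and *not* trimmed
when it overlaps a neighboring gene (overlap is reported, not removed).
Coordinates are 1-based closed throughout; BED exports are 0-based
half-open.

A **conserved region (CR)** is a maximal run of window positions carrying
no segregating single-nucleotide variant from the panel: any SNP
disqualifies a base regardless of frequency, indels are excluded with a
logged count, and a multi-allelic SNV is one disqualified position. CRs are
computed from the sorted variant positions by interval arithmetic; an
independent per-base brute-force scan serves as the oracle in tests. Two
invariants pin the computation down exactly: per window, Σ CR lengths +
in-window variant count = window length; and for iid per-base SNPs with
probability p the expected number of maximal runs ≥ L is
`(1 − p)^L (1 + (W − L) p)`.

A CR is **targetable** when strictly longer than 30 bp (≥ 31 bp) — room
for a 20-nt protospacer plus NGG PAM with margin. The mean targetable count
divides by all analyzed promoters, including SNP-saturated ones with zero
CRs; a SNP-less promoter contributes a single full-length CR. CR positions
are summarized as the signed offset of the CR midpoint from the annotated
gene start (0 at the start, upstream negative, even-length midpoints
rounding toward the gene); the midpoint anchor is a choice — the position
histogram's anchor is not uniquely determined by the quantity being
plotted — and is recorded in output metadata.

**PAM-site enumeration** scans both strands of a window for
[20 nt][NGG]: a site is reported when the full protospacer lies inside the
window (the PAM may extend past the window edge), `inside_cr` marks
protospacers contained in a single targetable CR, and `unique_in_genome`
is exact-match uniqueness of the 20-mer over both strands of the supplied
genome — no mismatch-tolerant off-target scoring. The site-enumeration
subcommand defaults to a 400-bp window (the scale used when designing
guides against predicted transcription start sites) while the CR statistics
default to 1 kb anchored at annotated gene starts.

## Synthetic benchmarks

The generator produces the observables of both stages with ground truth
emitted atomically under the same seed.

* **Plates.** Colonies grow in *area* — exponential after a lag, saturating
  at a cap — and are rendered as disks of radius √(A/π) (a pixel belongs to
  a colony when its centre lies in the disk), so the true log-area slope
  equals the specified rate, which is exactly the pipeline's estimand.
  Frames are grayscale-in-RGB with per-pixel Gaussian noise; frame 0 is
  colony-free. Recovery studies use 260 × 400 px plates, 10 colonies on a
  jittered grid spaced beyond twice the final radius, initial area 150 px²,
  cap 3000 px², lags U[20, 120] h, background 0.1 and colony 0.6 V-units
  with noise sd 0.1 (SNR 5, the floor at which area fidelity is still
  claimed), 129 frames at 2 h. Not modeled: colony morphology, optics and
  vignetting, plate circularity, radial growth physics.
* **OD curves.** Logistic wells over a constant instrument background with
  Gaussian read noise. The recovery study places wells far below carrying
  capacity at the end of the fit interval (initial OD 0.03, K = 20 in the
  generator's OD units, rates 0.007–0.010/min → OD(330)/K < 0.04, read
  noise 0.002): an a-priori error budget — logistic-curvature bias
  `≈ (x(330) − x(210))/(120 r)` with `x = OD/K`, plus the unweighted-OLS
  noise SE — keeps every well's total error under 5% at three noise SDs.
  Closer to capacity, or with a dim inoculum against the same read noise,
  the unweighted semilog slope is *not* a 5%-accurate estimator, which is
  why the estimator's validity clause ("capacity not yet approached")
  matters.
* **Genomes.** Random uniform sequence; gene lengths drawn uniformly, then
  placed exactly uniformly among non-overlapping configurations by order
  statistics over the free space (an error is raised precisely when the
  genes cannot fit); per-base Bernoulli SNPs (single-nucleotide only),
  which makes the closed-form run-count expectation exact. Not modeled:
  linkage among SNPs, indels/SVs, realistic base composition, nested or
  overlapping genes.

Passing the recovery studies therefore shows the *algorithms* are correct
and well-calibrated on data obeying the stated models; it does not certify
performance on real scanner artifacts (vignetting, drift, condensation) or
real variant panels (call errors, linkage, annotation-version sensitivity
of gene starts).

## Numerical choices and degenerate inputs

* Smoothing kernels are truncated and renormalized, so constants are
  preserved exactly; thresholding is strict (`>`).
* Watershed components containing no seed keep label 0 (they contribute to
  no track); seeds off the foreground in a given frame are dropped for that
  frame only.
* Windows with `< min_points` positive areas are skipped; all-zero tracks
  give a no-estimate result. Degenerate OLS (single distinct abscissa) is
  an error; r² of a perfectly constant fit is defined as 1.
* Zero-length promoter windows (gene at a chromosome's first base) are
  emitted with a warning and skipped downstream; adjacent variants produce
  no zero-length CR; a variant on the first/last window base counts as
  inside the window.
* All simulations are deterministic given spec + seed; derived child seeds
  stay below 2³¹.

## Validation studies (what the package itself recomputes)

`ptascreen.simstudies` regenerates synthetic inputs from a seed and runs
the production paths end to end: oracle equivalence and length conservation
of the CR scan on random windows, the closed-form run-count check on
10,000 windows (W = 1000, p = 0.02, L = 31), growth-rate recovery for 100
rendered colonies plus a zero-rate plate, exact watershed partition
conservation including forced merges, OD slope recovery, the constructed
exclusion fixtures, and the worked ANOVA example. `scripts/acceptance.py`
reports these numbers; `tests/test_acceptance.py` asserts them at their
stated tolerances. Study sizes (e.g. 10 plates × 10 colonies, 10,000
windows) are chosen so the full suite completes in a few minutes on one
core.
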