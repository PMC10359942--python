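# Methods

This note documents the models, parameter choices and numerical conventions
behind `cyclefate`: what the synthetic cohort generator emulates, how the
phase and fate callers operationalize the reporter-logic rules, how the
inheritance parameters were calibrated, and what the passing tests do and do
not demonstrate about real microscope data.

## 1. The synthetic cohort generator

### Study conditions

The generator emulates a 48-h time-lapse experiment sampled every 15 min
(0.25 h). Each *mother* cell is captured mid-cycle at t = 0 (treatment
onset), completes its cycle, and divides into two daughters whose
proliferation/quiescence fate depends on the mother's stage at t = 0.

Phase durations are drawn per cell from truncated normal distributions
(truncation at 0.25 h, one sampling interval) with these targets (mean ± SD,
hours):

| condition | G1 | S | G2 | M |
| --- | --- | --- | --- | --- |
| control | 4.92 ± 2.09 | 5.59 ± 1.52 | 2.19 ± 0.93 | 0.81 ± 0.13 |
| glucose depletion | 7.39 ± 4.38 | 6.23 ± 2.05 | 3.74 ± 1.42 | 0.84 ± 0.23 |

Truncating a normal at a lower bound raises its mean (by ≈0.5 h for the
broad depletion G1), so the *location* of each truncated normal is solved
numerically so that the realized (truncated) mean equals the target; the
scale is kept at the target SD (`truncnorm_for_mean`). The realized SD is
therefore slightly below the nominal SD — an accepted consequence of
matching the first moment exactly. All phase boundaries are snapped to the
sampling grid (rounding is unbiased at the grid scale).

Mother stage-at-treatment is Bernoulli with P(G1) = 0.3881 by default. This
is not free-handed: given the stage-conditional daughter quiescence
probabilities (86.54% / 51.22%), it is the unique mixture weight that
reproduces the observed marginal quiescent fraction of 64.93%, i.e.
w = (0.6493 − 0.5122)/(0.8654 − 0.5122). The elapsed cycle position at
capture is uniform within the captured stage. The capture proportion is an
exposed parameter (`p_stage_g1`), since unsynchronized capture proportions
are population- and density-dependent in real experiments.

### Reporter waveforms

Only qualitative shapes are constrained by reporter biology, so waveforms
are piecewise analytic with one deliberate numerical property: **every peak
used for boundary detection is locally symmetric** (equal rise and fall
slopes near the apex). A moving-average smoother, or symmetric measurement
noise, then perturbs the detected argmax symmetrically and the *mean*
detected boundary stays unbiased — an asymmetric peak would bias the argmax
toward its shallow side by up to half the smoothing window.

- **Cdt1** rises linearly through G1 from 0.10 to 1.00 (relative units),
  then falls in S at the same slope to a floor of 0.05.
- **Geminin** sits at 0.02 in G1, rises linearly from the G1/S boundary to
  its peak at mitotic entry, and collapses during M.
- **SLBP** is a symmetric triangle peaking at the S/G2 boundary (half-width
  0.9 × min(d_S, d_G2), floor 0.15).
- **H1** is constant with a step to 1.8× during M (chromatin condensation),
  giving a sharp mitotic signature.
- **CDK2 ratio**: proliferating cells rise linearly from the quiescent
  baseline 0.6 at birth to a mitotic peak of 2.0 at division; quiescent
  daughters stay flat at 0.6. The sensor is emulated as a constant nuclear
  signal with cytoplasmic signal = ratio × nuclear.
- A per-cell brightness factor (log-normal, CV 0.15) multiplies the Fucci
  channels; measurement noise is multiplicative log-normal per channel with
  unit mean (fluorescence is positive and heteroscedastic), default σ = 0.10
  for Fucci channels, 0.05 for H1 and p21, 0.03 for the CDK2 signals.

### p21 dynamics, inheritance and fate

**G1-group mothers** (in G1 at treatment onset) follow the three-part p21
program: a modest rise in G1 (to 0.15 L), suppression in S (to 0.05 L), and
a robust G2/M ramp to a per-cell plateau L at division, with per-cell ramp
curvature ((t−t_G2)/τ)^κ. Across cells L is log-normal (mean 100 a.u., CV
0.5) and κ is log-normal (median 1, log-SD 0.55). At division the plateau
is split conservatively between daughters: fractions f = ½(1 ± δ) with
δ ~ N(0, 0.0626). A G1-group daughter commits to quiescence when its
inherited level exceeds a threshold θ, solved (by quadrature + root
finding) so the marginal P(quiescent) equals the configured 0.8654.

**S-group mothers** and control cells carry only baseline p21 (2 a.u.);
their daughters accumulate de novo at independent per-daughter log-normal
rates (median 4 a.u./h, CV 0.6), and commit to quiescence when the rate
exceeds the quantile matching the configured probability (0.5122 under
depletion, 0.0714 in control).

This threshold mechanism (instead of a bare Bernoulli draw) is what makes
the lineage statistics emerge mechanistically: as split noise σ_δ → 0,
G1-group siblings inherit identical p21 and are *forced* into concordant
fates, while S-group siblings decide independently and the discordant
fraction converges to 2p(1−p) ≈ 0.50.

**Calibration of the inheritance parameters.** Two of the constants above
were fixed analytically — before any test was run — so the generator's
defaults constitute the study conditions:

- σ_δ = 0.0626 solves, in closed form from the moments of L and the
  per-frame measurement noise, pooled sibling discrepancy D = 0.10 over 5-h
  post-mitosis window series, i.e. a resemblance 1 − D = 0.90 for G1 sibling
  pairs.
- The ramp-curvature spread (log-SD 0.55) sets how much the mother's 5-h
  pre-mitosis window mean (which averages over the partial G2/M ramp)
  decouples from the plateau the daughters inherit. With L's CV, the G2+M
  duration variability, and σ_δ already fixed, a log-SD of 0.55 predicts a
  mother–daughter window-mean Pearson r of 0.79; values 0.5/0.6 bracket it
  at 0.80/0.78.

**p21-degradation scenario** (optional, `condition="p21_degradation"` with
`iaa_time` set): after the induction time the p21 reporter decays to
undetectable within ~2 h; quiescent daughters' CDK2 ratio then rises but
plateaus at 75% of the mitotic peak (cycle re-entry without completed
mitosis). No quantitative target is attached to this scenario.

### Determinism

Every cell draws from its own `SeedSequence(entropy=seed, spawn_key=(i,))`
(daughters: `(i, 1+j)`) substream, so identical (config, seed) gives a
bit-identical cohort and enlarging `n_mothers` leaves existing cells
untouched. Serialization fixes float formats (times %.4f h, intensities
%.6g), making reruns byte-identical.

## 2. Phase caller

Per-cell normalization uses a robust maximum (98th percentile) to resist
single-frame spikes. "Increasing/decreasing" is operationalized as the sign
of a least-squares slope over a rolling 5-frame window on the smoothed
trace; "low Geminin" is < 20% of the cell's Geminin maximum. Intervals are
half-open [start, end): a boundary frame belongs to the later phase.

Boundary placement:

1. **G1/S** — argmax of the smoothed Cdt1 (the Cdt1 apex coincides with
   Geminin onset). If the smoothed argmax collapses to the first frame but
   the raw trace has a genuine interior apex (a 1–2-frame G1), the raw
   argmax is used: the shrinking end-window of the smoother otherwise
   swallows very short G1 phases.
2. **S/G2** — argmax of the smoothed SLBP.
3. **G2/M** — the histone signature (first frame after the SLBP peak whose
   raw H1 exceeds 1.4× the pre-mitotic median) is preferred; the Geminin
   peak is the fallback, and both candidate times are reported
   (`t_G2M_h1`, `t_G2M_geminin`) because the two can disagree.
4. **Division** — a recorded lineage event is authoritative; otherwise a
   track that ends mid-H1-signature before the observation window closes is
   inferred to have divided one frame after its last sample.

A silent Geminin channel (no dynamic range) means the cell never left G1
within the window: frames in a G1-like reporter state are labelled G1 and
everything downstream is flagged truncated. Phases cut by the observation
window are excluded from duration summaries; G1-duration means over cells
with unobserved births would otherwise be biased low.

## 3. Fate caller

CDK2 activity is elementwise cytoplasm/nucleus; frames with nuclear signal
below 1e-6 a.u. are masked rather than divided. The binary rule — "mean
CDK2 activity below 0.8 for more than 10 h" — is ambiguous about what is
averaged; it is implemented as *a contiguous interval longer than 10 h in
which the 5-frame-smoothed ratio stays below the threshold*, evaluated from
cell birth. This weakest consistent reading classifies both flat-quiescent
and late-rising cells correctly; the whole-track-mean alternative is
available via `mean_mode="global"`. Tracks spanning less than the minimum
window are returned indeterminate (censored), and daughters only partially
observed at the horizon are classified on the observed span.

The three-state scheme calls *quiescent* when the smoothed ratio never
shows a sustained increase (rolling slope > 0.01 h⁻¹ for ≥ 2 h), *G1
arrest* when it rises but Cdt1 never completes its peak, and
*proliferative* otherwise. "Cdt1 reached its peak" compares the trace
maximum against 90% of an external reference level when one is supplied;
without a reference it requires an interior maximum followed by a sustained
decline, since any trace trivially attains 100% of its own maximum.

Quiescent fractions are reported with Clopper–Pearson binomial CIs;
quiescent + proliferative = 1 exactly per group by construction.

## 4. Lineage statistics

Alignment anchors every lineage at the first division (mothers at negative
time). Window means use [−w, 0) before and (0, +w] after mitosis, w = 5 h
by default; with 0.25-h sampling each window holds 20 samples, and the
mitosis frame itself belongs to neither window. Mother–daughter correlation
is a standard two-sided Pearson test on the window means; each daughter
forms one pair with its mother.

The sibling discrepancy D is computed exactly as defined above. Although
the quantity is described as a coefficient of determination, the printed
formula is a *discrepancy* — 0 for identical siblings — while the
interpretation ("closer to 1 the more similar") matches its complement, so
both D and R² = 1 − D are returned. Group-level values pool all pair
samples (concatenating the unordered pairs into two long vectors); per-pair
values are also available. Pair series with both sides constant are
undefined (zero denominator) and flagged.

Proliferation-vs-time binning uses right-open 1.3-h bins from 0; bins with
fewer than 2 mothers are dropped from the Pearson correlation across bin
centers. The generator couples daughter fate to the mother's stage (and
thus to her time-to-mitosis), producing a strongly negative r (slower
mothers → fewer proliferating daughters); the *signed* value is reported
and interpretation is left to the caller.

## 5. Image quantification

Pixel conventions: 0-based (row, col), integer pixel centers, 0.55 µm/px.
The nuclear region is a radius-5-px disk; the cytoplasmic region is the
annulus of width 2 px immediately outside it (a literal "ring of diameter
2 px" would be degenerate). Disk and ring are disjoint by construction.

Background flattening estimates the illumination surface from the 25th
percentile of 32-px tiles (cells occupy a minority of any tile), pads the
tile grid by one odd-reflected ring, interpolates with a quadratic spline
(so image borders — where plane/vignette bias is strongest — are
interpolated rather than extrapolated), divides the unit-mean surface out,
and subtracts the median of sub-Otsu (non-cell) pixels, clamping at 0.

Nuclear detection is scale-matched LoG (σ = r/√2) on the histone channel
with Otsu-thresholded local maxima separated by ≥ 2r. Tracking is greedy
mutual-nearest-neighbour linking under a displacement gate, with a division
recorded when a linked endpoint has a second otherwise-unmatched successor
within the gate — a deliberate simplification of LAP-style trackers that is
adequate at the rendered densities (link purity ≥ 99% at the default drift)
but would not survive dense or fast-moving fields.

The renderer composites nuclear disks and cytoplasmic annuli over a smooth
plane+vignette bias and a constant background, records exact ground truth
per frame, and places daughters ±(r+2) px from the mother's final drifted
position so divisions are geometrically linkable.

## 6. Problem sizes and what the tests show

The test suite and the acceptance script run cohorts of 500–1300 mothers
(1500–4000 tracks), rendered fields of ≤ 256² px with ≤ 6 mothers over 193
frames; the full suite completes in under two minutes on one CPU. These
sizes were chosen so every recovery check has sampling error comfortably
inside its tolerance (e.g. SEM of the depletion G1 mean at n ≈ 850 is
0.15 h against a ±0.5 h band).

What passing tests show: the callers are unbiased against the generator's
ground truth at the configured noise; the pipeline's statistics recover the
configured study conditions end to end; and the statistics themselves obey
their exact invariants. What they do not show: robustness to real-data
pathologies the generator deliberately omits — segmentation errors, focus
drift, photobleaching, apoptosis, cell–cell contact, reporter silencing,
and mechanistic AMPK/p53/p21 signaling (the p21 program here is
phenomenological, not an ODE model). The S-group mother–daughter window
correlation is near zero under this generator (no mother-side accumulation
and independent de-novo rates); a weak negative dependence seen in real
data would require a mother→daughter coupling the generator does not
posit.

## 7. Known limitations

- The H1 mitotic signature is a step; real chromatin-condensation
  signatures are textured, and M-phase onset from intensity alone is ±1
  frame at best.
- The truncated-normal duration model matches means exactly but shrinks
  SDs slightly; heavy-tailed cycle-time distributions are not modelled.
- Division detection in the tracker requires the two daughters to appear
  within the displacement gate of the mother's last position.
- `phase_duration_summary` treats each cell independently; mother/daughter
  duration correlations (if any) are not modelled, so SDs pool both roles.
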