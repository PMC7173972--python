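# Methods

## Data model and units

All computation is in millimetres, seconds, and radians; frames are
0-based and bout intervals half-open `[start, end)`, so a bout's duration
is exactly `(end − start) / fps`. Trajectory files carry one row per fly
per frame (`frame, role, x_mm, y_mm, heading_rad`); pixel-unit files are
converted at read time via `mm_per_px`, never downstream. Heading is head
direction in mathematical convention (0 = +x, counterclockwise positive),
wrapped to (−π, π]; head/tail disambiguation is assumed resolved by the
upstream tracker. Bout tables are kept sorted with same-behavior,
same-fly overlaps merged at construction, which makes merging idempotent
and downstream accounting unambiguous.

## Speed

Tester speed is the backward finite difference of centroid positions
scaled by the frame rate, with `speed[0]` copying `speed[1]` so the series
has full length. An optional centered boxcar (odd window, default 1 = no
smoothing) is exposed because no smoothing scheme is canonical for the
0.1 mm/s gate; the default applies the gate to raw frame-to-frame
displacements.

## Time orienting

Frame *t* qualifies when (1) the bearing from tester to target centroid is
within ±`max_angle` (default 60°, inclusive) of the tester heading, (2)
centroid distance ≤ `max_dist` (default 5 mm, inclusive), and (3) tester
speed > `min_speed` (default 0.1 mm/s, strict). The inclusive/strict
split follows the wording of the respective thresholds ("within" vs
"above"). Bearing uses centroid-to-centroid geometry; at coincident
centroids the bearing is undefined and the angle condition is treated as
satisfied (the distance condition already holds) with a logged warning.
Maximal runs of qualifying frames become bouts; runs strictly shorter
than `min_bout` (default 200 ms — exactly 200 ms survives) are discarded
to suppress heading-flip artifacts. Per-minute attribution splits bouts
across minute boundaries by frame membership so per-minute values
conserve the total.

## Bout filtering and binning

Duration floors are per behavior (lunge/headbutt 50 ms, wing extension
100 ms) with strict `<` discards, so boundary-equal bouts survive. A
behavior without a configured floor is a configuration error rather than
a silent pass-through. Counted behaviors (lunges, headbutts) are
attributed to the minute/window containing their start frame — a lunge is
momentary (~0.05–0.2 s), so this avoids double counting; duration
behaviors (wing extension, orienting) are split across bin boundaries by
frame membership, conserving total seconds. Filtering requires a `raw`
table and stamps the output `filtered`, so the filter is applied exactly
once per pipeline run.

## Stimulation windows

The paradigm is parameterized (defaults: 60 s pre, 3 × 60 s on, 120 s
ISI, 600 s total, consistency enforced) and anchored on the first frame
whose indicator-LED intensity exceeds the configured threshold. Window 1
is the pre-stimulation minute, window 2 the union of LED-on blocks.
Window 4 has no canonical definition, so two modes are provided and
stamped into every output: `isi_split` (default; window 3 = first half of
each ISI, window 4 = second half — the only four-window partition of the
paradigm that separates early from late post-stimulation behavior; under
the standard 2-min ISI the halves are the first and second ISI minutes)
and `isi_pooled` (window 3 = entire ISIs, window 4 empty). Under
`isi_split` the four windows exactly partition the 10-minute recording
(1 + 3 + 3 + 3 minutes). Per-window amounts are normalized to per-minute
rates so windows of unequal pooled duration are comparable; a window with
zero pooled minutes reports NaN rather than a value.

## Statistics

Behavior rates are zero-inflated and non-normal, so the scheme is
nonparametric: a Kruskal–Wallis omnibus (tie-corrected H, χ² reference
with k−1 df) gates all post-hoc testing at p < 0.05. Within-fly window
comparisons use the Wilcoxon signed-rank test on paired rates (zero
differences dropped; exact sign-assignment distribution when the
effective n is below 26 and absolute differences are tie-free, otherwise
a tie-corrected normal approximation without continuity correction);
genotype comparisons use the Mann–Whitney U-test (exact below n = 20 per
group for untied data, tie-corrected normal approximation otherwise).
The switchover sizes keep exact computation sub-second; both paths are
verified against full enumeration in the test suite, and scipy provides
the underlying distributions. Bonferroni correction uses m = the number
of post-hoc comparisons actually performed within one behavior's family
(all window pairs, or the test genotype against each control); m is
recorded on every result. A raw p < 0.05 that fails correction is
flagged `marginal` (conventionally displayed in parentheses). Degenerate
inputs — all values identical, all paired differences zero, a zero
Fisher margin — return p = 1 with an explicit flag instead of an error or
an undefined statistic; all-zero groups in zero-inflated lunge data thus
surface visibly rather than producing silent p-values. Fisher's exact
test is two-sided by summing hypergeometric probabilities no larger than
the observed table's. A plain two-sample t-test is exposed for cell-count
comparisons, where normality is defensible.

Null simulation with the default generator (12 flies, flat
5 bouts/min wing extension, 2,000 cohorts) puts the omnibus rejection
rate at ≈ 0.05–0.06: window 1 pools one minute against three for windows
2–3, so its rate estimate has higher variance, and this mild
heteroscedasticity makes the χ² approximation slightly liberal at
n = 12. The gated, corrected post-hoc familywise rate stays well below
0.05.

## Responder classification

A fly is a window-2 responder if either (a) its window-2 rate exceeds a
*strictly positive* reference (window 1 or 3 — either suffices, reading
"relative to window 1 or 3" as a disjunction; a conjunctive reading is a
one-line change in `ResponderRules`) by more than `relative_increase`
(default 50%), or (b) both references are zero and window 2 exceeds an
absolute floor (1 lunge/min or 0.5 s/min wing extension, strict >). The
relative branch requires a nonzero reference deliberately: against a zero
reference any positive rate is an infinite relative increase, which would
make the floor branch unreachable and label arbitrarily small window-2
rates as responses. Classification is monotone in the window-2 rate.

## Classifier evaluation

A true (annotated) bout is detected when a predicted bout overlaps at
least `min_overlap` of its frames; the default is any overlap (≥ 1
frame), the weakest defensible criterion, and the fraction is
configurable. A predicted bout overlapping no true bout by even one frame
is a false positive. Recall is tp/n_true. Precision is reported in two
forms: the FP-augmented `tp / (n_detected + fp)` — the primary output,
kept verbatim because it is the definition used with the evaluation data
this package targets — and the conventional `tp / n_detected`; the former
never exceeds the latter.

## Voxel morphometry

Registered stacks are averaged together with their mirror images across
the left–right axis (axis 0); because each output voxel and its mirror
receive the same summands in the same order, the result is bitwise
flip-symmetric and the operation is idempotent. Structure volume counts
voxels ≥ threshold (default 800, interpreted on the stack's native
intensity scale) inside an optional label mask, times the voxel volume in
µm³. Interactive segmentation is out of scope; masks arrive as label
NRRDs. NRRD I/O is a small built-in reader/writer covering the subset
this package produces (NRRD0004, raw/gzip encodings, 3-D scalar grids,
spacings or diagonal space directions, first-axis-fastest data order);
anything outside that subset raises an explicit error rather than
guessing, and axis metadata is never silently transposed.

## Synthetic data

All randomness flows through NumPy's PCG64 `Generator` with explicit seed
plumbing, so a fixed seed reproduces identical bytes across platforms.

*Dyads* are correlated random walks: per-frame step ~ max(0, N(0.085,
0.05)) mm (≈ 5 mm/s at 60 fps), heading diffusion SD 0.25 rad/frame,
reflective walls (arena walls are slip-coated, so flies stay on the
floor), and intermittent approach epochs during which the tester's
heading is steered toward the target — enough to produce realistic
orienting episodes. The generator returns the per-frame orienting truth
computed with scalar arithmetic during generation, independent of the
vectorized analysis path. *Scripted dyads* translate both flies rigidly
along the tester heading within each segment, making the predicate's
truth per segment analytic — this is how exact recovery (e.g. 37.5 s of
orienting) is constructed. *Bouts* are homogeneous Poisson onsets within
each window at that window's rate with i.i.d. log-normal durations
(medians: lunge 120 ms, wing extension 800 ms — above the duration floors
so filtering is exercised only by dedicated sub-threshold scenarios;
log-SD 0.35), truncated at the recording end, with overlaps merged.
*Image stacks* are rasterized spheres of known voxel count plus optional
clipped Gaussian noise.

What the generator does not emulate: body posture and wing kinematics,
tracker identity swaps and heading flips (the artifacts the 200 ms rule
guards against arise here only in scripted scenarios), behavior-state
autocorrelation beyond window-piecewise rates, and social feedback
between the flies' behaviors. Passing tests therefore establish the
correctness of the measurement chain on data whose ground truth is known,
not the robustness of upstream tracking or classification.

## Problem sizes and numerics

The test suite and the acceptance script run simulations sized for a
single CPU: oracle equivalence on ~10⁶ random frames, 2,000 null cohorts
and 100 effect cohorts of 12 flies for calibration and power, enumeration
checks over all small-sample sizes in the exact regimes, and 4-pair
cohorts for byte-level determinism. Conservation identities are asserted
to 1e−9; exact-test agreement to 1e−12; mirror symmetry and scripted
recovery are exact by construction. Statistical calibration bands
(rejection rate 0.05 ± 0.01, power ≥ 90%) include Monte-Carlo error at
these sizes.

## Known limitations

- The orienting predicate uses centroids only; a head-position-based
  bearing would differ for strongly bent postures.
- Bonferroni families are defined per behavior and comparison design;
  analyses pooling many behaviors into one family need the `m` values
  recomputed (every result carries its m for exactly this reason).
- The manual curation step for zero-inflated lunge data (removing
  tracking-artifact false positives before testing) is intentionally not
  automated; the degenerate-data flags mark where it would apply.
- `isi_split` halves ISIs by time; paradigms with ISIs that are not a
  multiple of two minutes yield windows 3/4 that are not whole minutes.
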