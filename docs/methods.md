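# Methods

## Connectivity model

The phase lag index between two signals x and y over a window of T
samples is

    PLI = | (1/T) Σ_t sign(Δφ(t)) |,   Δφ = φ_x − φ_y wrapped to (−π, π],

with φ the analytic-signal (Hilbert) phase, computed **within each
window independently** after band filtering.  sign(0) contributes zero
mass, so identical signals score exactly 0; a consistent nonzero lag
scores 1; and zero-lag common signals (volume-conduction-like) are
invisible by construction.  The sign of the wrapped difference is
evaluated as sign(sin Δφ), which is identical almost everywhere; the
only divergence is exact antiphase (Δφ = ±π), a branch-cut point where
*any* convention is numerically unstable — the phase jitter of a real
computation flips the sign arbitrarily.  Accordingly the calibration
suite pins PLI = 1 at quarter-cycle and other sub-antiphase lags and
treats antiphase as undefined-in-practice.

Windows are 4 s with a 2-s step.  Under the null (independent signals)
the per-window PLI is the absolute mean of T fair ±1 signs, so it
concentrates as O(1/√T): at T = 800 samples the null 95th percentile is
comfortably below 0.12, which is the calibration bound used in the
tests.

The per-window inner loop is a numba kernel (interval tests on the phase
difference, no trigonometry); a pure-numpy reference path exists and the
two are asserted bit-equal in the unit tests.

## Graph metrics

Networks are weighted and undirected; path length is the sum of
reciprocal weights along the path (Dijkstra on 1/w).  At sparsity s the
round-half-up k = round(s·1770) strongest edges survive with their
weights; ties at the cutoff break toward the smaller flat edge index so
thresholding is deterministic.

* `Lw`: mean shortest path over ordered pairs.  On a disconnected graph
  this diverges; the implementation restricts the mean to the largest
  connected component and reports a per-level disconnection flag in the
  sparsity profile.  This is an explicit convention choice — harmonic
  substitution would be equally defensible — and the flag lets users
  detect when it was exercised.
* `Cw`: mean over nodes of 2 t_i / (k_i (k_i − 1)), with t_i the
  geometric-mean triangle intensity ½ Σ (w_ij w_ih w_jh)^{1/3}; nodes of
  degree < 2 contribute 0.
* `Eglobal`: mean of 1/l_ij with 1/∞ = 0.
* `Elocal`: for each node of degree ≥ 2, the mean over ordered neighbor
  pairs of (w_ij w_ih [l_jh(N_i)]^{−1})^{1/3}, where l_jh(N_i) is the
  shortest path *inside the neighbor subgraph*; this is the standard
  weighted local-efficiency form.

All four are validated against exhaustive brute-force enumeration
(simple-path search, direct triple loops) on random graphs of ≤ 8 nodes
to 1e−10.  Each metric profile over the default grid 0.15–0.30 (16
levels) is summarized by the trapezoidal AUC, whose constant-function
identity (AUC of c = 0.15·c) is asserted exactly.

## Statistics

Conditions are compared as independent groups by classical one-way
ANOVA; the per-subject unit is the window-averaged AUC or PLI value
(one number per recording).  Degenerate inputs are defined rather than
NaN: identical groups give (F = 0, p = 1), zero within-group variance
with distinct means gives (F = ∞, p = 0).  The implementation is the
sums-of-squares formula with the F tail from scipy; equivalence with
`scipy.stats.f_oneway` and with the squared pooled t statistic is
unit-tested, and the null rejection rate is calibrated to 0.05 ± 0.01
at 10,000 replicates.

Edge screening is *uncorrected* p < 0.05 across the 1770 edges per band
— deliberately, because the screen is a filter in front of the
multivariate ranking step, not an inferential endpoint.  Under the null
it passes ≈ 88 edges per band; a Benjamini–Hochberg option exists for
users who want a corrected screen.  Since subjects are the same people
in both conditions in the emulated design, an independent-groups ANOVA
is conservative in one sense and anticonservative in another; a
repeated-measures variant is a known omission.

## Consensus SVM-RFE

Single-run RFE trains an SVM (C = 1), scores every remaining feature,
removes the lowest-scoring one and retrains until none remain; the
reversed elimination order is the ranking.  With a linear kernel the
score is w_j².  With the default RBF kernel (γ = 1/(p · var), i.e.
scikit-learn's "scale" on standardized features), w does not exist
explicitly, so the score is the kernel generalization: the change in
the squared margin term W²(α) = Σ α_a α_b y_a y_b K(x_a, x_b) when
feature j is struck from the kernel matrix with the dual coefficients
frozen — for an RBF kernel a cheap elementwise update
K_(−j) = K ⊙ exp(γ d_j) over support vectors.  Ties break toward the
lower column index, which then survives longer and ranks better.

Consensus: the ranking is repeated on n_runs class-stratified row
subsamples (90% without replacement; stratification guarantees both
classes in every draw), and aggregated positionally — consensus rank r
is the feature most often found within the first r positions across
runs, excluding features already placed, vote ties again toward the
lower column index.  With n_runs = 1 the consensus equals the single
run.  The library default is n_runs = 1000; the acceptance checks use
n_runs = 50, which is already far past the point where the top of the
consensus stabilizes for cohorts of this size.

## Synthetic cohorts

Each channel carries 1/f-shaped noise (amplitude slope −1, unit SD).  A
planted edge in band b adds, to both channels, a narrowband-filtered
shared source of amplitude 2 (in background-SD units), one copy delayed
by a constant π/4 phase via the analytic signal; each channel's
narrowband component is c·shared + (1−c)·independent band noise, so the
pair's PLI grows monotonically with the coupling fraction c (verified
at c ∈ {0, 0.25, 0.5, 0.75, 1}).  The π/4 lag is essential: PLI is
blind to zero-lag coupling, and a lag near π would sit on the
antiphase branch cut.  Per-subject Gaussian jitter (SD 0.05) on c,
drawn once per subject and shared by both of that subject's recordings,
supplies between-subject variance.  Defaults emulate the target study
design: 20 subjects per condition, 400-s recordings at 200 Hz, four
rhythms.

What the generator does **not** emulate: volume conduction and a
realistic leadfield, ocular/muscle artifacts, nonstationarity, and
spatially correlated background activity.  Two consequences matter for
interpreting green tests.  First, average re-referencing injects a
scaled copy of the planted source into every channel, so pairs that
share a planted channel show elevated, condition-dependent PLI — the
significant-edge sets around a strong planted edge are therefore larger
than the null ≈ 88 and the consensus runner-ups cluster around the
planted channels, as in the worked example.  Second, adjacent bands
share a filter edge (alpha and beta meet at 13 Hz), so a planted beta
coupling leaks into alpha; cross-band isolation is asserted only
between spectrally disjoint bands (delta vs beta).  Passing tests
demonstrate that the chain recovers planted effects of realistic size
under these idealized conditions, not that it is robust to artifacts it
never sees.

## Problem sizes

The verification suite and `scripts/acceptance.py` use scaled-down
cohorts chosen to exercise every stage at full channel count: 20
subjects per condition with 60-s recordings (29 windows) for the
planted-edge recovery check, repeated over 20 independent cohorts with
consensus n_runs = 50; one four-band cohort of the same size for the
classification check (7080 features, 10-fold CV, 10 label-shuffle
replicates); 1000 trials for the PLI null; 10,000 replicates for ANOVA
calibration; 100 random graphs for the brute-force metric check.  The
recovery criterion (planted edge in the consensus top 5 in ≥ 80% of
cohorts) is met with margin — in practice the planted edge ranks first
in nearly every cohort at the 0.2 vs 0.8 contrast.

## Other numerical conventions

Band filters are 4th-order Butterworth applied forward–backward
(`sosfiltfilt`, default padding), giving zero phase and an effective
8th-order magnitude response; filter family and order are conventions,
as is the reflect-padding length.  Phases are computed per window, not
once per recording.  All randomness flows from explicit integer seeds
through `numpy.random.SeedSequence` spawning, so cohorts, subsampled
RFE runs and CV folds are reproducible bit-for-bit; the pipeline writes
a sha256 manifest so reruns can be verified byte-for-byte.
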