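# Methods

This note documents the models, estimators and numerical choices behind
`musclenet`, and what the synthetic fixtures do and do not establish.

## Signal model and preprocessing

Surface EMG is treated as an amplitude-modulated broadband carrier: the
interference signal of a motor-unit pool whose envelope carries the common
synaptic drive. The coherence branch therefore high-pass filters raw EMG at
20 Hz (4th-order Butterworth, applied forward–backward so the filter is
zero-phase) and takes the magnitude of the analytic signal as the envelope,
at the native sampling rate (2 kHz by default). The Hilbert magnitude is
used instead of full-wave rectification; for a pure sinusoid it returns the
exact amplitude, and for amplitude-modulated carriers it tracks the
modulator.

The MVAR branch conditions that envelope further: band-pass 0.5–70 Hz
(4th-order zero-phase Butterworth), polyphase downsampling to 200 Hz, and
per-channel z-scoring so that no muscle dominates the multivariate fit.
The decimator's anti-aliasing FIR is cut at 1.03× the band edge (801 taps
at 2 kHz) rather than at the output Nyquist: with the default filter the
Butterworth transition band (70–100 Hz) survives decimation and holds a few
percent of a broadband envelope's power, whereas the package guarantees
< 1% of output power above 70 Hz. Sharper designs (a second Butterworth
pass, or a brick-wall FIR) were rejected: their passband shaping or hard
spectral null measurably distorts finite-order autoregressive fits of the
conditioned signal. Zero-variance channels are rejected with an explicit
error rather than propagating NaNs.

## Undirected connectivity (Welch coherence)

Complex coherency per trial uses Hamming-tapered 1-s windows with 0.75-s
overlap; the frequency resolution is therefore 1 Hz and analyses are
reported on 0–60 Hz. Each trial is demeaned by its whole-trial channel mean
(not per segment): this removes the trivial shared-DC coherence of
nonnegative envelopes while keeping the coherency of identical channels
exactly 1 at every bin, including 0 Hz, where per-segment demeaning would
leave 0/0. Coherency is averaged *as a complex quantity* across the trials
of a condition and then squared — phase-inconsistent coupling cancels, so
pooled coherence is a stricter estimate than averaged magnitude, and
convexity guarantees it never exceeds the mean or max single-trial
magnitude.

Confidence limits come from phase-randomization surrogates: every channel's
envelope gets independent uniform Fourier phases (amplitude spectrum
preserved, conjugate symmetry maintained so surrogates are real), the full
pooling pipeline is re-run, and the per-pair, per-frequency 95th percentile
over 200 surrogates is the threshold. The default randomizes envelopes;
`mode="raw"` randomizes raw EMG and re-runs envelope extraction through a
user-supplied callable, since either reading of "phase randomization of the
EMG signals" is defensible. On independent-noise studies the per-bin
exceedance of the 95% threshold is ~5% (calibration is asserted within
three binomial standard errors over all pair × frequency bins).

## Directed connectivity (MVAR / PDC)

Each conditioned trial is fitted by ordinary least squares on the stacked
strictly-causal regression; the residual covariance is the MLE
(divide by N − p). The order is chosen per trial by
`AIC(p) = ln det Σ̂_p + 2 p M² / N` over p = 1..30. Rank-deficient designs
raise an error naming exactly-collinear or constant channels.

From `Ā(f) = I − Σ_k A_k e^{−i2πfk/fs}` follow the transfer function
`H = Ā⁻¹`, the model spectrum `S = H Σ Hᴴ` (used for model-based coherence,
the standard check that the model reproduces the data's coherence spectra),
and PDC `π_ij(f) = Ā_ij / sqrt(Σ_k |Ā_kj|²)` — column-normalized so each
source's squared outflow, diagonal included, sums to exactly 1 at every
frequency. Complex PDC is averaged across trials and squared, mirroring the
coherence pooling. The default PDC uses the strictly causal coefficients;
`extended=True` first absorbs instantaneous correlations by an LDL
factorization of Σ under a declared channel ordering (`B0 = I − L⁻¹`,
lagged coefficients re-expressed as `L⁻¹A_k`, diagonal innovations). The
ordering changes `B0` but never the model-implied spectrum; it defaults to
the acquisition order and is recorded in outputs. Gaussian-identifiable
instantaneous models only — non-Gaussian identification is out of scope.

PDC is not invariant to per-channel rescaling. Because the pipeline
z-scores channels, planted ground truth is expressed in standardized units:
the generator solves the companion-form Lyapunov equation for the
stationary covariance and returns `D⁻¹A_k D`, `D⁻¹ΣD⁻¹` with
`D = diag(stationary sd)`. Zero-coefficient patterns are preserved.

## NMF spectral unmixing

Spectra of all pairs, conditions and subjects are stacked subject-major
into a nonnegative frequency × observation matrix on 0–60 Hz and
factorized by projected alternating least squares: each half-step solves
the unconstrained least-squares problem and clips negatives to zero.
Initialization is uniform random from the seed; 10 restarts, relative
tolerance 1e-6, at most 500 iterations, best final error wins. Projected
ALS does not guarantee monotone error, so an iteration that would increase
the Frobenius error terminates the run and reverts to the previous factors
— the recorded error curve is non-increasing by construction. Convergence
to an exact factorization of exactly low-rank matrices is init-dependent;
with enough restarts some initialization reaches machine precision, which
the tests exploit. K defaults to 4 (the component count that captures
postural coherence spectra well: < 5 Hz, 6–10 Hz, ~16 Hz, 30–45 Hz bands);
no automatic selection rule is imposed, but `scree()` reports error versus
K. The factorization is run separately for coherence and PDC stacks.

Scale/permutation ambiguity is resolved by normalizing basis columns to
unit Euclidean norm (compensated in the loadings; the product is unchanged
to 1e-12) and sorting components by ascending basis-peak frequency.
Loadings reshape to adjacency matrices — symmetric fill for undirected,
(source, target) fill for directed — with zero diagonals.

## Graph metrics

All metrics operate on the weighted matrices; thresholding is for
visualization only. The clustering coefficient is the Onnela geometric-mean
form on weights normalized by the network maximum, and its directed
(Fagiolo) generalization counting all triangle orientations with the
bilateral-edge degree correction; nodes with fewer than two neighbours get
0. Global efficiency and betweenness use edge length `1/weight`; zero
weights are absent edges (infinite length, no epsilon flooring), and
disconnected pairs contribute 0 to efficiency. Betweenness accumulates
fractional counts over equal-length shortest-path multiplicities and is
reported unnormalized, then averaged over nodes. These conventions are
pinned by brute-force triple/path-enumeration oracles on all tested ≤6-node
graphs to 1e-12. Proportional thresholding keeps the
`ceil(fraction × candidates)` strongest edges (45 unordered or 90 ordered
candidates for 10 muscles, so top 30% undirected and top 15% directed both
keep 14); ties resolve deterministically by pair-index order and
zero-weight edges are never retained.

## Group statistics

The condition × frequency-component repeated-measures ANOVA uses the
standard within-subject sum-of-squares partitioning; each effect is tested
against its own subject-interaction error term. Sphericity is assessed per
effect with Mauchly's test on orthonormal-contrast scores; when Mauchly
p < 0.05 the Huynh-Feldt epsilon rescales both degrees of freedom (both the
corrected and uncorrected p are always reported, and Greenhouse-Geisser
epsilon is reported alongside; HF ≥ GG and both are clipped at 1). A factor
with two levels trivially satisfies sphericity (ε = 1, test skipped). When
the contrast covariance is singular — unavoidable for a (a−1)(b−1)-dimen-
sional interaction with few subjects — Mauchly's W is 0 and the correction
is applied; epsilon remains computable. F-statistics and uncorrected p
match statsmodels' AnovaRM and main-effect epsilons match pingouin to
better than 1e-6 on seeded fixtures. Post-hoc paired t-tests are
uncorrected by default (a Holm/Bonferroni flag exists); identical pairs
return t = 0, p = 1 rather than NaN.

## Muscle synergies (comparison method)

Envelopes are low-pass filtered at 10 Hz and downsampled to 100 Hz before
factorization — standard conditioning for time-domain synergy work, exposed
in the configuration. The synergy count is the smallest number of principal
components explaining 90% of envelope variance; extraction reuses the ALS
engine on the muscle × time matrix per participant and condition.
"Procrustes" alignment is operationalized as the correlation-maximizing
*permutation* (optimal assignment on the pairwise correlation matrix):
nonnegativity forbids general rotations, so reordering is the faithful
reading. Consistency per synergy is the mean correlation between aligned
basis vectors over all set pairs. Exact NMF factorizations are unique only
up to the nonnegative cone's ambiguity, so cross-set consistency is a
property of the data, not of the algorithm.

## Synthetic fixtures: what they emulate and what they do not

The generator reproduces the recording geometry of a standing-posture
study: 10 bilateral leg muscles (RF/VM/GM/TA/ED, right then left), 2 kHz
sampling in a 5–400 Hz acquisition band, four 60-s trials in each of four
conditions, any number of subjects. One master seed yields per-trial
substreams via `SeedSequence(master, spawn_key=(subject, condition_index,
trial_index, salt))`, so studies are bit-reproducible and trials can be
regenerated independently.

*Common-drive studies* multiply independent exact-band-limited Gaussian
carriers (Fourier-masked white noise, ≥ 99.9% of power in band) by
`max(1 + Σ_d gain_d s_d(t), 0.05)`, where each drive signal is unit-variance
Gaussian noise band-passed to the drive band and shared by the drive's
targets. Summed gains ≥ 1 per channel are rejected because they would
routinely drive the envelope scale negative; the 0.05 floor handles
residual excursions.

*VAR-envelope studies* simulate a stable VAR at 200 Hz — the analysis
branch's own rate — and apply its upsampled trace as a multiplicative
log-envelope modulation `exp(g·x)`, default depth g = 0.6, to
constant-envelope carriers: unit-amplitude cosines whose instantaneous
frequency sweeps 30–390 Hz triangularly with random period and phase per
channel. A Gaussian carrier's Rayleigh envelope fluctuates by ~52% and acts
as multiplicative measurement noise that biases fitted MVAR coefficients
irreducibly; the flat-envelope carrier hands the modulator to the
preprocessing chain almost untouched, which is what makes the analytic PDC
ground truth recoverable (20-seed median maximum deviation of fitted from
true squared PDC ≈ 0.09 on 60-s trials). Fixture VARs use low-frequency
poles (~0.45–0.5 at 200 Hz) so the planted process carries negligible power
near the 0.5-Hz and 70-Hz conditioning edges. Channel-identical filtering
cancels from PDC's column normalization only in the infinite-order limit,
which is why order selection up to p_max = 30 matters here.

None of this is a physiological claim: there is no motoneuron-pool or
biomechanical model, no force output, and the conditions are labels only.
Passing tests establish that the estimators recover planted linear
structure under realistic recording geometry and noise — not that real
postural EMG satisfies the generative assumptions.

## Problem sizes

Default test and reproduction runs use 3-channel directed fixtures and
10-channel undirected fixtures with 60-s trials (the native trial length),
studies of 1–3 subjects × 1–2 conditions × 4 trials, 200 surrogates, 20
Monte-Carlo seeds for recovery medians, and 100 random ≤ 6-node graphs for
the metric oracles. These sizes give stable medians and calibration
estimates while keeping a full reproduction run to a few minutes on one
CPU; subject counts at the full study scale (18) change only the statistics
stage, which is exercised on seeded fixtures of that shape.
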