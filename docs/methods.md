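# Methods

`ecgid` implements an identification pipeline for single-lead ECG: a subject
is recognized from the shape of their heartbeat rather than from a password or
fingerprint. The pipeline has five stages — wavelet feature-band extraction,
adaptive R-peak detection, R-R-R segmentation, sparse representation over a
learned dictionary, and coordinate-wise gallery matching with open-set
rejection. This note records the model assumptions, the parameters that
matter, and the design decisions taken where the design was genuinely open.

## Signal model and preprocessing

Surface-lead ECG amplitudes span roughly 10 µV–4 mV (R wave typically ~1 mV)
and the diagnostic band is ~0.05–100 Hz, with ~90% of QRS energy between
0.25 and 45 Hz. The signal is decomposed with an 8-level db4 discrete wavelet
transform (Mallat cascade). At fs = 250 Hz the detail bands are dyadic:
d1 ≈ 62.5–125 Hz down to d8 ≈ 0.49–0.98 Hz, with the approximation a8 below
0.49 Hz.

Defaults: drop d1 (high-frequency noise) and a8 (baseline wander), keep
d2–d8 — the tightest dyadic cover of the QRS band at this rate — and
soft-threshold the retained detail coefficients with the universal threshold
λ = σ̂·√(2 ln N), σ̂ = median(|d1|)/0.6745. Which sub-bands to keep and which
shrinkage rule to use are configurable (`drop_bands`, `threshold_rule`);
the retained-band choice is this package's decision, since a dyadic cover of
0.25–45 Hz admits no exact realization.

Numerical choices: symmetric boundary extension (minimal edge artifacts for
arbitrary-length records); signals are not padded to powers of two — standard
per-level length bookkeeping is used instead. Strict coefficient-domain
energy identities hold only for the orthogonal variant
(`mode="periodization"` on dyadic lengths), which is what the energy and
shrinkage-monotonicity property tests use. Note that db4's length-8 filters
have soft transition bands: zeroing d1 removes the bulk, not all, of the
62.5–125 Hz energy (measured residual ≈ 10% on white noise), and a
mid-band sine is recovered with correlation ≈ 0.93, not 1.0. Tests assert
these measured behaviors.

## R-peak detection

A Pan–Tompkins-style detector: zero-phase 5–15 Hz band-pass (2nd-order
Butterworth, forward-backward), 5-point derivative, squaring, 150 ms
moving-window integration, then adaptive dual thresholds over integration
peaks. Running estimates update as SPK ← 0.125·p + 0.875·SPK (signal) and
NPK ← 0.125·p + 0.875·NPK (noise), T1 = NPK + 0.25·(SPK − NPK), T2 = T1/2.
When no peak exceeds T1 within 1.66× the running RR mean (last 8 intervals),
the largest skipped candidate above T2 is accepted (search-back, SPK update
0.25/0.75). The squaring stage is configurable (`square`) since polarity
invariance can also come from the absolute derivative.

Every accepted detection is refined in two steps: argmax of the band-passed
magnitude within ±50 ms, then snap to the argmax of the signal magnitude
within ±16 ms. The second step defines the canonical R index used by
segmentation; on noise-free synthetic beats it lands exactly on the true R
sample while remaining robust to inverted QRS. A 200 ms refractory period is
enforced after refinement. All thresholds are relative, so detection is
invariant to positive rescaling of the input. By default detection runs on
the denoised, band-selected signal.

## Segmentation and standardization

Windows span three consecutive R peaks (two full cardiac cycles), expanded by
`expand = 20` samples at each end so the edge R waves are complete, and
clipped to the record; windows advance one peak at a time (overlap of one
cycle), giving P − 2 windows for P detected peaks. Each window is resampled
to `segment_length = 400` samples by linear interpolation and divided by its
L2 norm; resampling to a fixed length normalizes heart rate out of the
representation while preserving within-beat shape ratios, and the unit norm
removes gain. Three consecutive standardized windows form one 400×3 segment
matrix — the unit the sparse coder consumes. An alternative mode
(`group_mode="thirds"`) instead splits one long window into three equal
parts; the default grouping of three overlapping two-cycle windows is used
throughout.

## Sparse representation

The dictionary D ∈ R^{d×K} (unit-norm columns, overcomplete for K > d) is
learned by KSVD with orthogonal matching pursuit as the coding step.

OMP: greedily select the atom with maximal absolute correlation with the
residual, re-solve the least squares fit on the selected support, repeat
until `sparsity = 10` atoms or residual ≤ `tol = 1e-6`. The implementation
works in the Gram domain (D^T D and D^T x precomputed), so the per-iteration
cost is independent of the segment length. The ℓ0 constraint is realized
greedily; no ℓ1 weight appears anywhere.

KSVD: alternate (i) OMP coding of all training columns and (ii) for each atom
k, restrict to the columns using it, add atom k's contribution back into the
residual, and replace (d_k, x_k-row) by the best rank-1 approximation (first
singular pair) of that restricted residual. Design choices:

- **Code caching.** Plain OMP re-coding carries no monotonicity guarantee, so
  the coding step keeps a column's previous code whenever it has a smaller
  residual than the fresh OMP code. With that guard, both half-steps are
  exact or non-worsening, and the objective ‖Y − DX‖²_F is non-increasing on
  every iteration — a property the tests assert on seeded runs.
- **Initialization** samples K distinct training columns (seeded, re-normalized).
- **Dead atoms** (used by no column) are replaced by the currently
  worst-represented training column; since their coefficient row is zero this
  leaves the objective unchanged. Near-duplicate atoms
  (|⟨d_i,d_j⟩| > 1 − 1e−6) are resolved at the end of training by
  transferring the duplicate's coefficient row to its partner.
- **Sign convention**: the largest-magnitude entry of each updated atom is
  made positive, which fixes the SVD sign ambiguity and makes runs
  reproducible.
- The single printed tolerance 1e-6 serves as both the OMP residual bound and
  the objective-improvement stopping rule; both are individually configurable.

Defaults are K = 1000 atoms, sparsity 10, up to 300 iterations. The identity
signature of a segment matrix is max-abs pooling of its K×3 code:
β_k = max_i |α_ik|, a nonnegative K-vector with at most 3·T0 nonzeros.

## Enrollment and classification

Enrollment stores the first 30 pooled feature vectors per subject (the
standard set). A query β is matched coordinate-wise: for every nonzero β_i,
the distances |β_i − β^(z)_i| to all enrolled entries are computed.

Two decision rules are provided. The default, `decision_rule="distance"`,
predicts the subject minimizing the mean over the query's support of its
per-coordinate minimum distance (aggregated-distance argmin). The
alternative, `"votes"`, lets each coordinate vote for the label of its single
nearest entry and predicts the top-voted label. Measured on the 20-subject
synthetic desk cohort with identical features, the distance rule reaches
~97% rank-1 accuracy while the entry-level vote reaches only ~60–72%; a
whole-vector nearest-neighbor probe on the same features (~95%) confirms the
features carry the information and the per-entry vote is the lossy step —
single-coordinate comparisons against 600 individual entries are dominated by
ties and near-ties at weakly informative coordinates. Votes are computed and
reported under both rules. Vote weighting is uniform by default;
`weight_rule="inv_rank"` (the r-th most confident coordinate gets weight 1/r)
is provided as a documented alternative since distance-dependent weighting is
described only qualitatively in the source method.

Open-set rejection: the query is rejected when its mean matched distance to
the winning subject exceeds R_t (`reject_mode="total"` uses the sum instead).
R_t defaults to the 99th percentile of within-subject leave-one-out mean
matched distances over the standard set — a calibration from enrollment data
only, since no numeric threshold is published. Ties anywhere are broken
deterministically (smaller distance, then lexicographically smaller label;
earliest-enrolled entry at equal coordinate distance).

## Synthetic data

Real Holter archives cannot ship with the package, so every stage is
exercised on synthetic ECG. Each beat is the sum of five Gaussian waves
(P, Q, R, S, T) with per-subject amplitudes, centers and widths; beats are
spaced by rr_mean + N(0, rr_sd²); a sub-0.5 Hz sine models baseline wander
and white Gaussian noise models the acquisition chain. Cohort draws use
typical adult ranges (R 0.8–1.5 mV; P, T 0.1–0.3 mV; Q, S −0.3 to −0.05 mV;
RR 0.6–1.0 s) with rr_sd = 0.02 s and noise 0.02 mV, so inter-subject
morphology differences dominate intra-subject jitter. The generator returns
ground-truth R indices, which is what makes detector F1 exactly measurable.

What the generator does *not* emulate: ectopic beats and arrhythmia,
electrode motion artifacts, respiratory amplitude modulation, T-wave
alternans, drift of morphology over hours, and pathology (the real archive
this method targets contains ST/T abnormalities). Passing the synthetic
acceptance experiment therefore demonstrates that the pipeline separates
morphologically distinct subjects under mild noise — not that it attains any
particular accuracy on clinical recordings. `scripts/replicate_stt.py` runs
the identical pipeline on a locally supplied copy of the real database.

## Problem sizes used in tests and acceptance

The desk-scale experiment uses 20 subjects, 300 s of training signal and a
110 s disjoint test recording per subject, a dictionary scaled to K = 200
atoms and 60 KSVD iterations over 2500 subsampled training segments, 30
enrolled and 30 test feature vectors per subject (600 queries). Oracle-style
checks use their standard sizes: 100 random signals for the transform round
trip, 100 planted 3-sparse trials on a 20×50 dictionary for OMP, and a
20×40 planted dictionary with 1500 training signals and 80 iterations for
KSVD recovery. These sizes are the package's chosen operating points for
reproducible, deterministic runs; the full-scale defaults (K = 1000, 300
iterations) remain the configured defaults.

## Known limitations

- The WFDB reader supports only single-file format-212 record pairs (the
  dialect of the targeted archive), not the full header grammar.
- Dictionary learning is batch-mode and single-threaded; K = 3000-scale
  sweeps are possible but slow.
- The rejection threshold is calibrated from enrollment data only; with a
  single enrollment session it underestimates cross-session variability.
- Linear-interpolation resampling assumes the wavelet stage has already
  removed energy near the Nyquist band of the downsampled grid.
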