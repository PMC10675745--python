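# ecgid

Biometric identification from single-lead ECG. The heartbeat's shape is
stable within a person and distinctive between people; `ecgid` turns a raw
ECG recording into a compact identity signature and matches it against an
enrolled gallery, for researchers and engineers prototyping ECG-based
authentication.

## Method

1. **Feature-band extraction.** 8-level db4 discrete wavelet transform;
   the finest detail band (≈62.5–125 Hz noise) and the approximation
   (<0.49 Hz baseline wander) are dropped, retained detail coefficients are
   soft-thresholded (`sign(x)·max(|x|−λ, 0)`, universal λ), and the signal
   is reconstructed — keeping the band that carries QRS morphology.
2. **R-peak detection.** Pan–Tompkins-style adaptive dual-threshold
   detector: band-pass → derivative → squaring → moving-window integration,
   thresholds T1 = NPK + 0.25·(SPK − NPK) and T2 = T1/2 with search-back.
3. **Segmentation.** Windows over three consecutive R peaks (two cardiac
   cycles), expanded 20 samples at both ends, resampled to D = 400 points
   and L2-normalized; three consecutive windows form one D×3 matrix.
4. **Sparse representation.** A KSVD-learned overcomplete dictionary
   D ∈ R^{d×K}; each segment is coded by orthogonal matching pursuit with
   ‖α‖₀ ≤ 10, and the K×3 code is max-abs pooled: β_k = max_i |α_ik|.
5. **Identification.** Each enrolled subject contributes 30 pooled feature
   vectors (the standard set). A query matches coordinate-wise by
   d_{i,z} = |β_i − β^(z)_i|; the predicted subject minimizes the mean
   per-coordinate minimum distance (per-coordinate nearest-entry votes are
   also computed and reported), and queries whose matched distance exceeds
   the calibrated threshold R_t are rejected as unknown (open-set).

Real WFDB format-212 records are supported; a Gaussian-wave synthetic ECG
generator with per-subject morphology provides fully controlled test data
with exact ground-truth R positions.

## Worked example

```python
import numpy as np
from ecgid import make_cohort, synthesize_ecg, detect_rpeaks, rpeak_f1
from ecgid.pipeline import PipelineConfig, run_identification_experiment

# detector accuracy against ground truth on one synthetic subject
morph = make_cohort(1, seed=0)[0]
rec, truth = synthesize_ecg(morph, duration=60, fs=250, seed=7)
stats = rpeak_f1(detect_rpeaks(rec), truth, tol=0.05)
print(f"R-peak F1: {stats.f1:.3f} ({stats.n_matched}/{stats.n_truth} beats)")

# end-to-end identification on a 20-subject synthetic cohort
cfg = PipelineConfig(atoms=200, iterations=60)   # desk-scale dictionary
res = run_identification_experiment(n_subjects=20, seed=1, cfg=cfg,
                                    with_shuffled_control=True)
print(f"rank-1 recognition: {res['recognition_rate']:.1%} "
      f"over {res['n_queries']} queries")
print(f"rejection rate: {res['rejection_rate']:.1%}  "
      f"shuffled-label control: {res['shuffled_recognition_rate']:.1%}")
```

Output:

```
R-peak F1: 1.000 (68/68 beats)
rank-1 recognition: 97.1% over 600 queries
rejection rate: 1.0%  shuffled-label control: 5.4%
```

The F1 line says every true beat was found within 50 ms with no false
alarms. The experiment trains a shared 200-atom dictionary on 20 subjects'
training recordings, enrolls 30 feature vectors each, and identifies 600
disjoint test windows: 97% are attributed to the right person, 1% are
rejected as unknown, and scrambling the gallery labels collapses accuracy
to the 1-in-20 chance level — the signal is in the morphology, not the
protocol.

## Command line

```
ecgid synth --n-subjects 5 --duration 60 --out cohort/
ecgid train cohort/S*.txt --atoms 200 --iterations 60 --out dict.json
ecgid enroll cohort/S*.txt --dictionary dict.json --out gallery.json
ecgid identify cohort/S000.txt --dictionary dict.json --standard-set gallery.json
ecgid evaluate --n-subjects 20 --seed 1 --atoms 200 --iterations 60
ecgid sweep --parameter expand --values 0,10,20,30 --out sweep.csv
```

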