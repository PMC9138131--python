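# emgrasp

Object-grasp classification from surface EMG and inertial sensors under
limb-position change.

## The problem

Myoelectric hand control classifies a user's intended grasp from surface
electromyography (EMG). Classifiers trained with the arm in one position
degrade badly when the same grasp is performed elsewhere in the workspace:
muscles adjust their contractile strength to stabilise the limb, so the
EMG feature distribution of each grasp class drifts with arm position (the
*limb-position effect*). `emgrasp` implements, end to end, a pipeline for
studying this effect and the feature-projection techniques that mitigate
it, for researchers in EMG pattern recognition and myoelectric prosthesis
control.

The study design is five object grasps (sphere, cylinder, keycard, eraser,
pen) performed at nine object placement positions (three azimuths × three
reach distances), recorded with six EMG channels at 1024 Hz and a 6-channel
IMU (3-axis accelerometer + gyroscope) at 60 Hz. Because no public recording
of this design exists, the package ships a synthetic-data generator that
reproduces the design and its feature-space structure — distinct per-grasp
clusters, per-position cluster drift, raw-space overlap, and
position-informative IMU channels — so every downstream stage is testable
without any download.

## Pipeline

1. **Preprocessing** — 5th-order Butterworth band-pass 20–450 Hz plus a
   50 Hz notch on EMG; moving-average smoothing on IMU; segmentation into
   150 ms windows with 50 ms increments (100 ms overlap), EMG and IMU
   aligned.
2. **Features** — per EMG channel and window: mean absolute value (MAV),
   zero crossings (ZC), waveform length (WL), slope sign changes (SSC) and
   AR(6) coefficients; per IMU channel: window RMS. Together a 66-D vector,
   min-max normalised to [−1, 1] on training statistics.
3. **Projection to k = 4** (classes − 1) by one of
   - **PCA** — top-k eigenvectors of the sample covariance;
   - **LDA** — top-k eigenvectors of S_w⁻¹S_b;
   - **SRELM** — spectral-regression extreme learning machine: a random
     sigmoid hidden layer H (L nodes), orthonormalised class-indicator
     responses Z, and the ridge solution U = (HᵀH + αI)⁻¹HᵀZ, projecting
     via Y = HU;
   - **t-SNE** — exact (non-approximated) t-distributed stochastic
     neighbor embedding: per-point bandwidths calibrated to a target
     perplexity, joint probabilities p_ij, Student-t similarities q_ij,
     and gradient descent on KL(P‖Q). Transductive: train and test rows
     are embedded jointly with labels withheld.
4. **Classification** — LDA, Gaussian naive Bayes, 3-NN, linear/RBF/
   polynomial SVM, and a 4-14-5 tan-sigmoid neural network, under
   five-fold cross-validation with all fitting confined to training folds.
5. **Cluster metrics** — separability index
   SI = (1/c) Σᵢ minⱼ ½√((μᵢ−μⱼ)ᵀS⁻¹(μᵢ−μⱼ)) with S = (Sᵢ+Sⱼ)/2;
   mean semi-principal axis MSA = (1/c) Σᵢ (Πⱼ √λᵢⱼ)^{1/k}; repeatability
   index RI = (1/c) Σᵢ ½√((μ_Tr,i−μ_Ts,i)ᵀS_Tr,i⁻¹(μ_Tr,i−μ_Ts,i)).

Two orchestrated experiments: the full projection × classifier error grid,
and a training-position-reduction study (train on 1…9 positions, test
across all nine) tracking error, SI and RI.

## Worked example

```python
from emgrasp import (GeneratorConfig, generate_dataset, extract,
                     separability_index, mean_semi_principal_axis)
from emgrasp.preprocess import preprocess_and_segment
from emgrasp.features import SymmetricMinMaxScaler
from emgrasp.projection import SRELMProjector, PCAProjector

config = GeneratorConfig(n_reps=2, seed=42)          # 5 grasps x 9 positions
recordings = generate_dataset(config)                 # 90 trials
windows = preprocess_and_segment(recordings, window_stride=8)
data = extract(windows)                               # 450 x 66 features

X = SymmetricMinMaxScaler().fit(data.X).transform(data.X)
y = data.grasp
print(f"raw-space SI: {separability_index(X, y):.2f}")

for name, model in [("PCA", PCAProjector(k=4)),
                    ("SRELM", SRELMProjector(L=1000, alpha=1.0, seed=42))]:
    Y = (model.fit(X, y) if name == "SRELM" else model.fit(X)).transform(X)
    print(f"{name:6s} SI={separability_index(Y, y):6.2f}  "
          f"MSA={mean_semi_principal_axis(Y, y):.4f}")
```

prints

```
raw-space SI: 7.36
PCA    SI=  2.81  MSA=0.4763
SRELM  SI= 23.57  MSA=0.0023
```

Read: in the raw 66-D space the grasp clusters are moderately separated
(SI ≈ 7) but drift with position; unsupervised PCA keeps that overlap
(SI ≈ 2.8, large cluster ellipsoids), while the supervised SRELM
projection both separates the grasps far better (SI ≈ 24) and compacts
each cluster (MSA ≈ 0.002) — the behaviour that makes it nearly
classifier-agnostic downstream.

The same stages are scriptable from a shell:

```sh
emgrasp simulate --subjects 1 --reps 2 --seed 42 --out data/
emgrasp extract-features --manifest data/manifest.csv --out features.csv --stride 8
emgrasp project --features features.csv --method SRELM --out projected.csv
emgrasp metrics --features projected.csv
emgrasp experiment --seed 42 --mode both --out run/
```

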