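# emgait

Locomotion-mode recognition from multichannel surface EMG (sEMG): a
fully synthetic, tested re-implementation of a 12-class gait-phase ×
terrain classification pipeline.

## The problem

Powered lower-limb prostheses and exoskeletons need to know both *where
in the gait cycle* the wearer is and *what terrain* they are on. One way
to get both is to classify short sEMG segments into joint phase–terrain
classes. This package implements that analysis end to end for five
muscles (tibialis anterior, medial gastrocnemius, rectus femoris, vastus
lateralis, erector spinalis), three terrains (level ground, stair
ascent, stair descent) and four 200-ms analysis windows per gait cycle,
anchored at heel strike (HS) and toe off (TO): Post_HC, Pre_TO, Post_TO,
Pre_HC — 4 × 3 = 12 classes.

Because no public recordings exist for this protocol, the package ships
a first-class synthetic generator: band-limited Gaussian carriers
amplitude-modulated by terrain- and phase-dependent muscle-activation
envelopes, plus 50 Hz powerline interference and low-frequency motion
artifact, with matching heel/toe pressure traces and ground-truth gait
events. Every downstream stage is exercised against this known truth.

## The method

1. **Preprocess** (`emgait.preprocess`): resample to 500 Hz, zero-phase
   band-pass 10–150 Hz, notch 50/100/150 Hz, wavelet denoising (db4),
   HS/TO detection from foot pressure, cycle segmentation, and the four
   200-ms windows (100 samples × 5 channels each).
2. **Features** (`emgait.features`): 35 per channel — 12 time-domain
   (MAV, WAMP, ZC, WL, SSC, LogVAR, RMS, Q3, AR1–AR4), 5 spectral (MDF,
   MNF, PR, PKF, MNP), and 18 wavelet (db1/db4/db7 × cD1/cD2 ×
   MAV/WAMP/WL) — 175 columns in the full matrix.
3. **Selection** (`emgait.selection`): class-separability scoring with
   the Davies-Bouldin index

   DB = (1/L) Σᵢ maxⱼ≠ᵢ (Dᵢᵢ + Dⱼⱼ)/Dᵢⱼ,

   the scattering index J = tr(S_W)/tr(S_B), and the inverse
   distance-to-spread ratio invRES = 1/RES with
   RES = (1/(L(L−1))) Σᵢ≠ⱼ Dᵢⱼ / (½(δᵢᵢ+δⱼⱼ)); robustness is the
   across-subject standard deviation of each index (STN). Features are
   ranked by mean invRES.
4. **Classification** (`emgait.ensemble`): six single-feature base
   classifiers (LDA or RBF-SVM) fused by plurality voting or by weighted
   majority voting, where the (6 × 12) weight matrix W holds each
   classifier's per-class recall estimated by nested stratified
   cross-training; a multiclass LightGBM model on the concatenated
   30-column matrix is the comparator.
5. **Evaluation** (`emgait.evaluation`): stratified 5-fold
   cross-validation, pooled confusion matrices, per-class recall,
   overall accuracy, and the macro-F1 score

   macro-F1 = 2 · macro-P · macro-R / (macro-P + macro-R),

   the harmonic mean of macro-averaged precision and recall.

## Worked example

```python
from emgait import synth, pipeline
from emgait import evaluation as ev

cfg = synth.SimulationConfig(n_cycles_per_terrain=30, seed=42)
df = pipeline.subject_feature_matrix(cfg, subject_id="S1")
print(f"windows: {len(df)}, feature columns: {df.shape[1] - 4}")

reports = ev.evaluate_all(df, ("mv-svm", "wv-svm", "lgbm"), k=5, seed=42)
for method, rep in reports.items():
    print(f"{method:7s} overall={rep.overall_accuracy:.3f} macroF1={rep.macro_f1:.3f}")
```

prints

```
windows: 348, feature columns: 175
mv-svm  overall=0.940 macroF1=0.941
wv-svm  overall=0.948 macroF1=0.950
lgbm    overall=0.954 macroF1=0.954
```

i.e. one simulated subject yields 348 labeled analysis windows
(~29 usable cycles × 4 windows × 3 terrains); plurality-voting SVM
fusion classifies 94.0% of held-out windows correctly, weighted voting
nudges that to 94.8%, and gradient boosting leads at 95.4% — the same
ordering the method was designed to demonstrate.

The same steps are available from a shell:

```bash
emgait simulate --cycles 30 --seed 42 --out session/
emgait preprocess --in session/ --out windows.csv
emgait extract --in windows.csv --out features.csv
emgait evaluate --features features.csv --out report/
```

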