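# hcmecg

ECG morphology phenotyping and mechanism simulation for hypertrophic
cardiomyopathy (HCM).

HCM is a genetic thickening of the left-ventricular wall and a leading
cause of sudden cardiac death in the young; its clinical presentation is
heterogeneous, and risk stratification from conventional markers is
imperfect. This package implements, end to end and at desk scale, a
computational phenotyping approach for the 12-lead ECG of HCM cohorts,
aimed at researchers in computational cardiology and biomedical signal
processing:

1. **Morphology pipeline** — each subject's per-lead median beat is
   delineated and its QRS complex compressed into the first four Hermite
   functions φₙ(t; σ) = (σ·2ⁿ·n!·√π)^(−½)·Hₙ(t/σ)·e^(−t²/2σ²), giving a
   width σ and coefficients c₀..c₃ per lead. Together with T-wave polarity
   and amplitude these form subject feature vectors that are z-scored,
   filtered by unsupervised feature selection (variance, redundancy, and a
   permutation-calibrated Laplacian relevance score), and clustered by Ward
   agglomeration with the silhouette criterion choosing the number of
   clusters — all blinded to any labels. The structural finding this
   reproduces: QRS morphology alone resolves **three** subgroups; adding
   T-wave polarity splits the normal-QRS group into T-inverted and
   T-upright halves, giving **four**.
2. **Mechanism simulation** — a monodomain cable
   ∂Vm/∂t = ∂ₓ(D ∂ₓVm) − I_ion/C_m + I_stim with a Mitchell–Schaeffer
   membrane and a virtual electrode recording the pseudo-ECG
   φ(t) = −K∫(∂Vm/∂x)·∂ₓ(1/r) dx. Scenario presets show the dissociation of
   the two high-risk signatures: a fast endocardial layer resistively
   decoupled from a myocardial patch produces late activation and a deep
   terminal S wave, while regional ionic remodeling (↑late Na⁺, ↑Ca_L,
   ↓K⁺ → longer action potentials) inverts the T wave with the QRS
   untouched.

Because the original Holter cohort is not public, a synthetic-data module
generates 12-lead cohorts from four phenotype archetypes with known ground
truth (exact Hermite QRS shapes, controllable T polarity, parameter jitter,
noise), so every stage can be scored against truth.

## Worked example

```python
import pandas as pd
from hcmecg import RunConfig, run_phenotyping, compare_partitions

cfg = RunConfig(feature_mode="qrs_plus_t", seed=7)   # default 4 x 30 cohort
out = run_phenotyping(cfg, "run_qt")

validity = pd.read_csv(out / "validity_by_k.csv")
labels = pd.read_csv(out / "labels.csv")
print(validity.round(3).to_string(index=False))
print("ARI vs generator labels:",
      round(compare_partitions(labels["cluster"], labels["true_label"]), 3))
```

prints

```
 k  silhouette
 2       0.556
 3       0.558
 4       0.571
 5       0.507
 6       0.385
ARI vs generator labels: 1.0
```

The silhouette peaks at k = 4 — the four phenotypes — and the recovered
partition matches the generator's labels exactly (adjusted Rand index 1.0;
each cluster is one archetype). Rerunning with
`feature_mode="qrs_only"` removes the T-wave features: the silhouette then
peaks at k = 3, with the 1A and 1B archetypes merged into a single
normal-QRS cluster — T-wave polarity is what separates them.

The same is available from the shell:

```sh
hcmecg synth --groups 1A=30,1B=30,2=30,3=30 --seed 7 --out data/
hcmecg phenotype --mode qrs_plus_t --seed 7 --out run_qt/
hcmecg simulate --out mech/          # all five mechanism scenarios
hcmecg report --run mech/
```

The mechanism comparison table (`mech/comparison.csv`) shows that of the
five scenarios only `ionic_remodeling` inverts the T-like deflection
(with < 10% change in QRS-like duration) and only `purkinje_decoupled`
produces the deep terminal S wave together with a strictly later latest
activation than baseline.

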