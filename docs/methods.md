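# Methods

`hcmecg` re-implements, at desk scale, a two-stage computational phenotyping
study of hypertrophic cardiomyopathy (HCM): an unsupervised ECG-morphology
pipeline that partitions a cohort into phenotype subgroups, and a 1D
mechanistic tissue simulation that reproduces the two electrophysiological
mechanisms behind the high-risk ECG signatures. This note records the
models, the parameter choices that matter, and what the synthetic data do
and do not establish.

## Hermite QRS descriptor

The QRS complex of each lead is represented by the first *N* Hermite
functions

φₙ(t; σ) = (σ·2ⁿ·n!·√π)^(−1/2) · Hₙ(t/σ) · exp(−t²/(2σ²)),

with Hₙ the physicists' Hermite polynomial, σ a time width in ms, and
continuous-time unit L2 norm, so coefficients carry mV·ms^½. *N* = 4 by
default — four functions suffice to span the R/S morphology variation of
interest (monophasic R, R/S asymmetry, notching). Coefficients are obtained
by least squares against the sampled basis (robust at ordinary sampling
rates, unlike Riemann-sum projections), and σ minimizes the normalized RMS
error (NRMSE) over a bracket (default 2–40 ms) by a coarse log-spaced scan
plus bounded refinement to 0.1 ms.

**Alignment.** The basis centre is placed at the energy centroid
(Σ i·v²/Σ v²) of the QRS window rather than at the R peak. The R peak of a
deep-S complex sits far from the envelope centre; anchoring there absorbs
the R/S asymmetry — the very feature the descriptor must carry — into the
alignment, and compresses inter-phenotype contrast. The energy centroid
tracks the Gaussian envelope centre, is insensitive to onset/offset jitter,
and preserves the asymmetry in c₁. An optional joint centre search
(`center_search`) exists but is off by default: the discrete centre choice
adds alignment variance that outweighs its bias reduction.

**Baseline.** Before fitting, a linear isoelectric baseline anchored just
outside the QRS window is removed. The zero-phase 0.5 Hz high-pass leaves a
small T-polarity-dependent offset under the QRS; without this correction,
T-wave morphology leaks into the QRS coefficients (measurably separating
groups that have identical QRS shapes).

## Delineation and wave biomarkers

Delineation is threshold-based on the median beat, with all thresholds
relative to the beat's own peak (gain invariance): QRS on/offset at the
outermost samples above 2% of the QRS peak (16 ms sustained-run criterion,
peak-to-edge capped at 90 ms), T end at 5% of the T peak. R and S durations
use zero-crossing lobe widths clipped to the QRS; T polarity is the sign of
the signed area from QRS offset to T end (+1 for an exactly zero area), so
biphasic T waves are judged by net area rather than peak sign. Waves below
the noise floor are reported absent, never fabricated.

## Synthetic cohorts

The study's Holter cohort is not deposited, so the generator emulates it
with four archetypes matching the reported contrasts: 1A (normal QRS,
inverted T in V4–V6), 1B (same QRS, upright T), 2 (shorter R and deep S in
V3–V5, V6 and limb leads spared), 3 (low, short R with long, deep S in II
and V4–V6, wider QRS). QRS shapes are exact Hermite combinations — so a
noiseless fit must recover the generating coefficients, anchoring the whole
chain to known truth. The T wave is an asymmetric Gaussian (upstroke σ 45 ms,
downstroke σ 30 ms), lifted and truncated at ±3σ so the ST segment and
baseline are exactly flat; T peak 170 ms after QRS offset. Beats occupy a
600 ms window (QRS centre at 200 ms, fs 500 Hz); rhythm strips tile beats at
60 bpm with fresh additive noise (SD 0.02 mV) per beat. Inter-subject
variability is a coefficient of variation (default 0.05) applied log-normally
to widths and amplitudes and as a multiplicative normal factor to Hermite
coefficients.

**Archetype separation is a declared study condition.** The source study
does not quantify inter-group effect sizes, and the cluster-count result
depends on them. Coefficient values were therefore calibrated once so that
the three QRS-morphology groups are mutually resolvable by an unsupervised
validity criterion — concretely, so that group 2's contrast (confined to
V3–V5) is not dwarfed by group 3's (II plus V4–V6). After z-scoring, the
separation contributed by a feature saturates with the group-split fraction
rather than the raw contrast, so balance requires group 2 to approach that
saturation on its few altered features. Realized centroid separations on the
default cohort are ≈4–5 (1 vs 2), ≈8 (1 vs 3), ≈7.5 (2 vs 3) and √12 ≈ 3.5
(1A vs 1B, from three ±1 polarity features), against a within-group spread
of ≈1.2. Cluster-recovery results reported by the acceptance suite hold
under these conditions; cohorts with weaker separation will degrade
gracefully toward fewer resolved clusters.

## Feature assembly, selection, clustering

Per requested lead (default II, V4, V5, V6): c₀..c₃ and σ, plus — in
`qrs_plus_t` mode — T polarity (kept at ±1, unscaled, weight 1.0) and T
amplitude. Continuous features are z-scored; centres and scales are stored
for exact de-normalization.

Selection is strictly unsupervised: a variance filter, pairwise-redundancy
removal (|r| > 0.95 drops the later column; applied to continuous features
only, since Pearson r between ±1 indicator columns overstates their
exchangeability and would collapse the polarity block), and a
Laplacian-score relevance test: each feature is scored on a 5-NN graph built
from the *other* features (a noise column must not validate itself through
its own neighbourhood distortion) and kept only if its score beats the 5th
percentile of its own permutation null (50 permutations, seeded). This
removes columns that carry cohort variance but no neighbourhood structure —
e.g. T amplitude, which jitters independently of group.

Clustering is agglomerative with Ward linkage (deterministic); k is chosen
by the silhouette maximum over 2–6, ties toward smaller k. A seeded
PAM-style k-medoids is available as configuration. No stage reads ground
truth; labels live only in the synthetic cohort object and in the explicit
ARI evaluation.

## Monodomain cable and pseudo-ECG

Tissue is a 50 mm strand, ∂u/∂t = ∂ₓ(D ∂ₓu) + I_ion + I_stim with no-flux
ends, solved by explicit Euler (dx 0.25 mm, dt 0.02 ms; the solver raises an
error naming the bound dt ≤ dx²/2D when violated; convergence: halving dx
with dt/4 changes conduction velocity by < 1%). The membrane is the
two-variable Mitchell–Schaeffer model (τ_in 0.3, τ_out 6, τ_open 120,
τ_close 150 ms, u_gate 0.13), mapped to mV as Vm = −84 + 104·u. It was
chosen as the package's cell model because it exposes APD directly through
τ_close, which is what every mechanism contract here depends on; the
conductance multipliers of ionic remodeling (late Na⁺, L-type Ca²⁺,
aggregate K⁺) enter through the documented monotone map

τ_close ← τ_close · s_NaL^0.15 · s_CaL^0.3 / s_K,

so more inward plateau current or less repolarizing current prolongs APD.
The exponents are configuration; contracts test direction, not magnitude.

Repolarization heterogeneity has two ingredients. A static transmural
gradient scales τ_close linearly from 1.25 (proximal) to 0.75 (distal) —
the earliest-activated tissue keeps the longest APD, as transmurally
observed. On top, activation–repolarization coupling shortens APD where
activation is late — τ_close × clip(1 − t_act/450 ms, 0.05, 1), fixed per
node at its upstroke (`AR_SLOPE_MS`, `AR_FLOOR`). Together
they keep the repolarization sequence opposite to the activation sequence —
a concordant upright T — even when conduction is slowed or delayed, so that
only a genuine APD-prolonging intervention can invert the T. This is the
1D surrogate of why secondary T changes differ from primary ones.

The virtual electrode sits on the cable axis 20 mm beyond the distal end
(precordial surrogate) and records
φ(t) = −K ∫ (∂Vm/∂x)·(∂/∂x)(1/r) dx with K = 1 (arbitrary units): a
depolarization front approaching the electrode writes a positive
deflection.

### Scenario presets

All presets share the baseline geometry (D 0.3 mm²/ms, CV ≈ 0.59 mm/ms,
stimulus at the proximal end, 900 ms horizon).

- **slow_conduction**: D × 0.3 in 15–35 mm — broader QRS-like complex, no
  deep terminal S.
- **activation_block**: D × 0.02 in a 22–26 mm band — strong delay, again
  no deep S.
- **purkinje_decoupled**: fast layer (D × 4) over 15–50 mm stimulated
  internally, joined to a slow myocardial patch (0–13 mm, D × 0.3) through
  a 2.5 mm resistive junction with coupling factor 0.006 (conduction block
  occurs below ≈0.004; the finite junction width makes the delay graded
  rather than all-or-none). The patch activates ~30 ms after everything
  else and its retrograde front — moving away from the electrode — writes
  the deep terminal S; the T wave is not inverted.
- **ionic_remodeling**: CellScaling(2.0, 1.1, 0.65) over 30–50 mm with
  severity increasing toward the tip (s_K × 0.8 beyond 37 mm and again
  beyond 44 mm), the 1D analogue of hypertrophy that is most severe
  apically. The region repolarizes last and tip-last, inverting the T-like
  wave while the QRS-like complex is untouched. A distally increasing
  profile matters: under a uniform scaling the region's internal
  repolarization still runs tipward and its positive fronts can outweigh
  the negative boundary shelf.

APD90 is measured per node from the stored field; nodes within a few space
constants of a remodeling border inherit their neighbours' plateau
electrotonically, so regional APD comparisons exclude a ~5 mm boundary
layer.

## Problem sizes and determinism

Default cohort: 4 × 30 subjects, 8-beat strips at 500 Hz — the full
two-mode phenotyping chain runs in well under a minute; the five-scenario
suite in ~10 s. Every stochastic step (cohort jitter, noise, k-medoids
restarts, permutation nulls) flows from a single integer seed; Ward +
silhouette is fully deterministic, so reruns are bit-identical.

## What passing tests do and do not show

The synthetic cohort has exactly-Hermite QRS shapes, stationary rhythm, no
ectopy, no baseline wander or muscle artifact, and group-pure archetypes.
Passing recovery and cluster tests therefore validates the machinery —
descriptor correctness, blindness, determinism, and the structural
finding that T-wave polarity splits the normal-QRS group — not clinical
performance on real Holter data. The 1D simulation reproduces mechanism
signs and orderings, not patient-specific ECG morphology; wall-thickness
effects, fiber-disarray tensors and torso geometry are outside its scope.
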