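# Methods

This note records the model, the numerical choices, and the limits of the
synthetic data, at the level of detail a maintainer needs to change any
of them safely.

## Feature battery

All 23 features are functions of the standard 21-point hand skeleton
(wrist = 0; thumb CMC/MCP/IP/TIP = 1–4; each finger MCP/PIP/DIP/TIP =
5–8, 9–12, 13–16, 17–20). Three primitives are used throughout:

* **Angle between vectors** — computed as `atan2(|v₁×v₂|, v₁·v₂)` in
  degrees. This is mathematically identical to the arccos of the clamped
  normalized dot product but stays well-conditioned near 0° and 180°,
  which matters because straight-finger joint angles sit at the arccos
  singularity (plain arccos loses ~1e-7 degrees there; the atan2 form is
  exact to machine precision).
* **Euclidean distance** between two landmarks.
* **Standardized distance** — any distance divided by the thumb TIP–IP
  segment length, making it dimensionless and camera-invariant.

**Joint angles** are taken between the proximal segment direction
(previous landmark → joint) and the distal segment direction (joint →
next landmark); a straight chain reads 0°. The skeleton has no
metacarpal-base landmarks, so the proximal segment of every finger MCP is
wrist → MCP. This is the only construction the 21-point skeleton admits,
and it is why fully extended real hands measure small but nonzero MCP
angles (the published non-target MCP means of 5–14° reflect the same
effect).

**Webspace angles** (third: middle/ring; fourth: ring/little) are taken
between whole-finger rays (MCP → fingertip) rather than single phalanges,
so they capture whole-finger adduction deficit (the Wartenberg sign).

**Thumb palmar abduction** is the elevation of the thumb ray (thumb MCP →
thumb tip) out of the palm plane spanned by the wrist and the
index/little MCPs, *negated*: a normally abducted thumb reads ≈ −20°, a
flattened (ape-hand) thumb rises toward 0. The palm-plane normal is
oriented by the cross product (index−wrist) × (little−wrist), which for a
right-chirality hand always points dorsally; all records are first
canonicalized to right-hand convention (left hands mirrored about x), so
the sign is well-defined and every feature — including this signed one —
is invariant under translation, rotation and reflection of the input.

The starred Gesture-3 angle features are negated raw angles, making
"greater = more abnormal" uniform across the battery; sums (features 08,
11, 17, 21) are computed from their components and are exact by
construction. Feature-name collisions between gestures (`ag_thumb_MCP`,
`ag_index_MCP` appear in both G1 and G3, the G3 versions negated) are
resolved by gesture context: analyses are always per-gesture, and mixed
tables carry a `gesture` column that must be filtered first.

## Calibration and the rule model

ROC curves use the fixed orientation "score > cutoff ⇒ abnormal".
Candidate cutoffs sit midway between adjacent distinct scores (half-step
extensions beyond the extremes), one operating point per distinct score
plus both endpoints. Ties therefore share a cutoff and contribute a
diagonal segment, so the trapezoidal area equals the Mann–Whitney
concordance fraction with half-credit ties exactly (property-tested to
1e-12 against an all-pairs oracle). Selection keeps features with
AUC ≥ 0.8 and backfills to a minimum of two per gesture by descending
AUC, ties broken by ascending battery number — on the published AUC
column this reproduces the published eight selected features, including
the Gesture-3 fallback choice of `dis_tip` (0.66) over `ag_thumb_MCP`
(0.65).

Two threshold criteria are provided because the reference procedure
specifies only "from the ROC curve": the Youden point (ties resolved
toward higher specificity, then the higher cutoff), and an FPR-floor mode
(highest sensitivity with training FPR ≤ 0.02 per feature). The floor
mode is the default for end-to-end demos: an OR-ensemble's false-positive
rate accumulates across members, so per-feature specificity must be
conservative for the ensemble to stay specific. Values exactly at a
threshold predict *normal* (the rule is strict exceedance); since cutoffs
are midpoints between observed scores, exact ties occur only for
degenerate inputs.

The ML baselines deliberately use small conventional grids (logistic
regression: C ∈ {0.01…100}; SVM: {linear, rbf} × C ∈ {0.1, 1, 10};
random forest: 100/300 trees × depth {∞, 5, 10}), stratified seeded
5-fold CV, and standardization inside the pipeline (fit on training folds
only, no leakage). The grids are config-overridable and recorded on the
fitted handle; they are *not* claimed to match any external study's
hyperparameters. Importance is |coefficient| for linear models and
impurity importance for forests; an RBF-kernel SVM has no per-feature
coefficients and says so rather than improvising one.

## Statistics

Group summaries report mean, SD (n−1), and a 95% CI as mean ± 1.96·SD/√n
(a t-quantile mode exists). Group comparisons default to Welch's t-test —
the battery's group SDs differ several-fold, so the pooled-variance
assumption is untenable — with the pooled form selectable. The
double-zero-variance edge case returns t = 0, p = 1, flagged. No
multiple-testing correction is applied (marginal tests at α = 0.05),
matching common practice for descriptive feature tables; this is recorded
here rather than silently assumed.

## Synthetic data

### Forward kinematics

Fingers are planar three-segment chains hanging from fixed MCP positions;
flexion rotates successive segments in the finger's vertical plane, so
PIP/DIP angles are interior angles and exact by construction. The
measured MCP angle depends on the fixed wrist→MCP direction; when a
finger's plane is rotated by an abduction offset δ, the in-plane rotation
is compensated (φ₁ = arccos(cos θ / cos δ)) so the measured MCP angle
still equals the requested θ exactly (requires θ ≥ |δ|).

Webspace targets are met by solving δ for the ring (against the middle
ray) and then the little finger (against the solved ring ray) with
Brent's method on the exact 3-D objective (xtol 1e-12). A 3-D webspace
angle is floored by any elevation mismatch between the flanking rays, so
the Gesture-2 pose inversion first matches ray inclinations: the middle
finger mirrors the drawn ring curl, and the ring/little MCP angles are
chosen so all rays share the middle ray's palmar inclination, with the
θ(δ) coupling applied *inside* the solve objective — this keeps
arbitrarily small webspace targets reachable.

The thumb is a three-segment chain on a column with four orientation
freedoms: azimuth, column pitch below the palm plane, proximal
flexion-plane roll, and an axial **twist** of the MCP flexion axis about
the proximal segment (modeling the pronation component of opposition).
All three thumb joint angles are interior angles, hence exact for any
orientation. A palmar-abduction target is solved in the twist (monotone
bracket + Brent); a tip-distance target is then solved in the azimuth,
sweeping the pitch over [0°, 60°] until a bracket exists. Tip-pinch
feasibility requires the thumb-tip and index-tip wrist radii to be
compatible — both are pinned by the drawn joint angles — so segment
lengths were chosen to make typical pinches reachable (thumb CMC radius
0.50, thumb segments 0.38/0.30/0.26, palm length ≈ 1; all lengths in
arbitrary model units, features being scale-free). Landmark jitter, when
enabled, is isotropic Gaussian per landmark, seeded.

With zero jitter, every requested joint angle, webspace angle and
palmar-abduction elevation is reproduced to well below 1e-6 degrees
(property-tested over 1,000 random poses), and the tip distance to solver
precision for accepted draws.

### Samplers and the cohort

`sample_features` draws feature vectors directly from per-group Gaussians
at the published group means/SDs — untruncated, so large-sample AUC
simulations match the closed-form binormal value Φ(Δμ/√(σ₀²+σ₁²)).
Features are independent given the group by default; a uniform
equicorrelation ρ is available via a shared latent factor. Sum features
are drawn from their own published moments in this mode (they do not
satisfy the additive identity; the kinematic path computes them exactly).

`sample_gesture` inverts drawn feature values into poses and renders
landmarks. Draws are truncated at geometric feasibility (angles
realizable as joint rotations, webspace > 0, tip distance reachable), and
kinematically inconsistent combinations are redrawn (bounded retries,
counted). Consequently the kinematic sampler's moments match the
*truncated* Gaussians, not the raw ones: e.g. the non-target ring-DIP
group (mean 4.74, SD 6.28, truncated at 0) gains ≈ +2.4° of mean, and
tip-distance rejection biases its mean upward by ≈ +0.1. Tests compare
kinematic means against truncated-normal expectations with explicit
rejection slack.

The study-shaped cohort defaults to 34 volunteers plus 22 unilateral
patients (10 radial, 5 ulnar, 1 median, 6 combined ulnar+median), two
hands each, three gestures, four repetitions — 1,344 records, 448 per
gesture, with per-gesture target groups of 40/44/28 records. The four
repetitions of a hand share a latent severity draw with repetition noise
at 25% of the group SD (components scaled so the marginal keeps the
configured moments); in kinematic mode, a hand whose latent draw is
unrealizable has it redrawn after a few failed repetition attempts.
Splitting is stratified by target/non-target within each gesture at the
image level, test fraction 1/4 with per-stratum rounding (448 → 336/112);
a leakage-safe hand-level split mode exists but is not the default, since
the image-level arithmetic is what the per-gesture test-set size of 112
implies.

### What the synthetic data does and does not show

The moment-based cohort reproduces the *marginal* group distributions of
the features, under Gaussianity and (by default) conditional
independence. Real landmark data differ in at least three ways: feature
distributions are skewed and long-tailed (the published group SDs as
Gaussians cannot reproduce the published test-set operating points for
Gesture 3 — the real non-target palmar-abduction distribution is
evidently not a Normal with SD 8.3°); features within a hand are
correlated through shared severity and pose; and tracker noise is
structured, not isotropic. Passing the end-to-end tests therefore
demonstrates that the pipeline is correct and well-calibrated under the
stated generative model — it does not certify clinical performance on
real images.

## Numerical and interface choices

* Degrees everywhere; `dis_tip` dimensionless.
* All scalar solves use Brent's method (xtol ≤ 1e-10) after a grid scan
  for a sign change, taking the first bracket from the low end.
* CSV landmark IO writes shortest-round-trip floats and reads with
  pandas' `round_trip` parser, so write→read is bit-exact.
* Random streams: every public generator takes a seed; the cohort builder
  and CLI fan a single seed out to all stages. The acceptance script
  spawns independent child streams per reported quantity.
* CLI configuration is JSON (one resolved-config file per stage next to
  its outputs); the library API accepts plain dataclasses.
* Problem sizes in tests: 1,000 kinematic round-trip poses, 200,000
  samples per group for AUC recovery, the 1,344-record default cohort for
  end-to-end runs — each chosen as the smallest size at which the checked
  statistic is stable at the stated tolerance.

## Known limitations

* The kinematic generator is a geometric, not biomechanical, model: no
  tendon coupling, no soft-tissue surface offsets (goniometry on skin
  would read differently), no photorealistic imaging.
* The tracker adapter is a contract only; no neural hand tracker is
  bundled, and recognition-rate accounting is exercised with stubs.
* Combined injuries are handled as independent per-gesture tasks; no
  cross-gesture differential logic is attempted.
* Printed AUCs of two unselected Gesture-3 index features are
  inconsistent with their printed group moments under the battery's sign
  convention (plausibly computed pre-negation in the source); they are
  carried as data but never used numerically.
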