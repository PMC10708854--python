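# Methods

`msitvc` predicts the total viable count (TVC, log10 cfu cm⁻²) of bacteria on
meat surfaces from 18-band multispectral signatures. This note records the
models, the numerical choices, and what the synthetic data generator does and
does not emulate.

## Data model

Each specimen carries 36 first-order-statistics (FOS) features: the mean
reflectance of the region of interest and the standard deviation of the pixel
intensities, one of each per waveband (405–970 nm, coded 1–18). Columns are
labelled `Mean.01..Mean.18` / `StdDev.01..StdDev.18`; the target column `tvc`
may be empty for prediction-only rows. Files are plain CSV (tab accepted via a
dialect flag); ranking tables are long-format CSV (`method,band_index,rank`);
models and reports are JSON.

## Synthetic spoilage data

The original 84-sample beef-fillet dataset is not deposited, so the package
ships a generator with the same statistical structure, used as the default
workload for every downstream stage.

**Growth.** TVC trajectories follow the Baranyi–Roberts model in log10 units,

y(t) = y₀ + μA(t) − log₁₀(1 + (10^{μA(t)} − 1)/10^{y_max−y₀}),
A(t) = t + (1/ν)·ln(e^{−νt} + e^{−h₀} − e^{−νt−h₀}), ν = μ·ln 10,

so y(0) = y₀ exactly, y is non-decreasing and approaches y_max. The
temperature dependence of μ uses the Ratkowsky square-root secondary model
√μ = b(T − T_min) — the standard companion model in predictive microbiology.
Defaults: y₀ = 3.0, y_max = 9.9 (the observed TVC working range),
μ_ref = 0.038 log10 h⁻¹ at T_ref = 8 °C, h₀ = 1.5, T_min = −5 °C (typical of
psychrotrophic spoilage flora). With these values spoilage completes in ~3
days at 16 °C while the 0 °C curve does not reach its asymptote within the
434 h storage horizon — the qualitative behaviour of chilled beef. The default
design is 17 sampling times at each of 0/4/8/12/16 °C (85 samples), times
spaced evenly from 0 to the time the curve nears its asymptote, capped at
434 h.

**Spectral coupling.** Band features are affine in TVC plus Gaussian noise:
`baseline[j] + slope[j]·tvc (+ quad[j]·tvc²) + N(0, σ)`. This is the simplest
structure preserving the premise that FOS features predict TVC; the optional
quadratic term injects nonlinearity when a linear-vs-TSK contrast is wanted.
By default the near-infrared bands 13–18 get zero slope, so feature selection
has genuinely irrelevant bands to reject. Noise scales (2.0 reflectance units
for the mean block, 0.5 for the sd block, against slopes of roughly 1.5–3.6
and 0.4–1.0 per log10 unit) are chosen so that a well-tuned regressor reaches
an out-of-fold RMSE of roughly 0.2–0.3 log10 units — the accuracy regime
reported for instruments of this class.

**What the generator does not emulate:** pixel-level image structure,
temperature-dependent spectral shape, band–band noise correlation,
biological replicate variability, and sensor drift. Passing tests on this
generator therefore demonstrate correctness and sane statistical behaviour
of the pipeline, not field performance on measured spectra.

A second generator draws data from an explicit ground-truth
Takagi–Sugeno–Kang (TSK) system and exists purely for parameter-recovery
testing of the network.

## Feature-selection fusion

Seven rankers each emit dense ranks 1..m over the bands they retain: a
Boruta-style shadow-feature random-forest screen, recursive feature
elimination over a random forest, a genetic search (crossover 0.8, mutation
0.1 per gene), forward stepwise-AIC regression with backward checks, LASSO at
the CV-minimal penalty, LMG relative importance (approximated by seeded
permutation averaging of incremental R², 120 permutations by default), and a
PLSR-coefficient filter retaining bands with above-average |coefficient|.
Fusion is plain majority voting: with K methods the default threshold is the
strict majority ⌊K/2⌋+1; a band is selected iff at least that many methods
retained it, ordered by (votes desc, mean rank asc, band index asc). The
tie-break is recorded in the result for transparency. On the published rank
tables of the 84-sample beef-fillet study this rule reproduces the published
selections exactly (8 mean-block bands, 6 sd-block bands). An unsupervised
principal-component baseline is provided for comparison.

## The neuro-fuzzy regressor (CAGFINN)

A five-layer TSK network. Rule i, input j has an asymmetric Gaussian
membership with one center c_ij and separate left/right spreads; the forward
pass uses the total spread b_ij = σ_left + σ_right:

A_ij(x) = exp(−(x − c_ij)² / (2 b_ij²)),   R_i = ∏_j A_ij(x_j),
R̄_i = R_i / Σ_j R_j,   O = Σ_i R̄_i (w_i·x + w_i0).

Each evaluation records which side of the center the input fell on; the
left/right indicator has zero derivative almost everywhere and is treated as
locally constant in all gradients.

**Initialization.** The rule count is self-determined by a supervised
prototype stage: working in the z-scored joint (input ⊕ target) space, a
sample farther than `radius_frac` × (bounding-box diagonal) from every
prototype spawns a new one, otherwise the nearest prototype moves toward it
by `lvq_rate`. The bounding-box diagonal upper-bounds all pairwise distances,
so `radius_frac = 1` always yields one cluster. Presentation order is the
dataset order (a seed only controls optional shuffling, off by default), so
the stage is reproducible. Classic fuzzy c-means (fuzzifier m = 2) then
refines the prototype input-coordinates; initial spreads are the
membership-weighted second moments, σ_ij = √(Σ_k u_ik (x_kj − c_ij)² / Σ_k
u_ik), split evenly: σ_left = σ_right = σ_init/2. Spreads are floored at
10⁻³ × the coordinate-wise data range throughout, so degenerate clusters can
never produce a zero denominator.

**Hybrid training.** Per epoch, samples are visited in order; for each
sample the consequent weights are updated by recursive least squares on the
regressor vector (R̄_1·[x,1], …, R̄_c·[x,1]) and the premise by one
gradient-descent step: centers by the chain rule, and the total spread via
b_new = b − η ∂E/∂b, after which only the recorded side is set to b_new/2
(the other side keeps its value, so the next forward pass uses the adjusted
total). Per-sample updates are what make the side-index bookkeeping
meaningful. Defaults: η = 0.01 on internally z-scored inputs, RLS forgetting
λ = 1, initial covariance 10⁴·I reset at each epoch (persisting it across
epochs is a flag), squared-error loss, stop at 500 epochs or when the epoch
RMSE improves by less than 10⁻⁶. With λ = 1 and the premise frozen,
epoch-wise RLS converges to the batch least-squares solution of the
linearized system; the premise gradients are validated against central
finite differences rather than against any published constants (none exist
for this architecture). If every rule strength underflows at some input, the
normalized strengths fall back to uniform 1/c and the event is counted, not
raised. The rule count never changes after initialization; the network is
MISO by design.

## Stacking

The mean-block and sd-block models are combined three ways: elementwise
averaging; a linear partial-least-squares meta-model on (X_mean, X_sd); and a
degree-4 polynomial meta-model Y = b₀ + Σ_d (b_m,d X_mean^d + b_s,d X_sd^d)
fit by NIPALS component extraction on the z-scored power basis (the powers
are strongly collinear; coefficients are mapped back to raw units for
reporting). The component count is chosen by inner k-fold cross-validation,
capped at 4 by default. Meta-training inputs are out-of-fold base
predictions — the leakage-free choice; in-sample stacking is possible by
fitting the meta-model on resubstitution predictions but is not the default.
Published degree-4 coefficients from the original study are shipped only as
a documented example, never as defaults — they are specific to data this
package cannot access.

## Validation metrics and protocols

Bf = 10^(Σ log₁₀(ŷᵢ/yᵢ)/n) and Af = 10^(Σ |log₁₀(ŷᵢ/yᵢ)|/n) (Ross's bias and
accuracy factors; the absolute-log form for Af is required for its stated
semantics — Af ≥ 1 with equality only at perfect agreement). Also RMSE, MAE,
MAPE% = (100/n)Σ|eᵢ|/yᵢ, APE = Σ100|eᵢ|/yᵢ (the un-averaged sum, i.e.
n×MAPE), SEP% = 100·RMSE/ȳ (bias-uncorrected), RPD = σ_y/RMSE (sample sd,
ddof 1), RER = range(y)/RMSE, RPIQ = (Q₃−Q₁)/RMSE with type-7
linear-interpolation quartiles (recorded in the report), the standardized
mean difference θ = (ȳ − ȳ_pred)/σ_y, and Cohen's d with the pooled sd. R² is
the squared Pearson correlation by default; 1 − SSE/SST is available by flag
(the two differ for biased predictions). Zero RMSE sets the ratio metrics to
+inf with a flag; a non-positive observation flags Bf/Af as undefined (NaN)
without failing the rest of the report.

Protocols: leave-one-out cross-validation (per-fold failures are recorded
and excluded, the report marks incompleteness), and a temperature-stratified
hold-out with test size round(n·frac), at least 1, allocated across
temperature groups by largest-remainder rounding — 84 samples at 10% gives
exactly 8 test samples.

## Pipeline

`run_pipeline` executes simulate → select/fuse (per block) → train →
stack → evaluate, writing every artifact plus a manifest with stage seeds
and SHA-256 hashes. One pipeline seed fans out to per-stage seeds by stable
CRC-32 hashing of the stage name, so any stage can be re-run in isolation.
Base-model generalization is measured by 5-fold out-of-fold prediction and
the stacking combiners by meta-level out-of-fold prediction (nothing scores
its own training fit). Default problem sizes — 85 simulated samples, 5-fold
stacking, 200-epoch training cap with early stopping — keep a full run
around half a minute on one CPU while leaving the base models in the
0.2–0.3 log10 RMSE regime.

## Known limitations

* The supervised prototype stage is order-dependent by construction; two
  datasets differing only in row order can yield different rule counts.
* The asymmetric-spread update changes only one side per visit; spreads
  adapt more slowly than centers and strongly asymmetric optima require many
  epochs.
* The LMG ranker is a sampled approximation; exact averaging over all
  orderings is combinatorial in the band count.
* Af/Bf require strictly positive values on both sides; they are meaningful
  for log-scale TVC but undefined for centred residual-like quantities.
* The genetic and Boruta-style rankers are stochastic screening tools; their
  retained sets are reproducible under a seed but not across seeds.
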