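# Methods

This note documents the models implemented in `sensortune`, the
defaults and their rationale, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Dose-response model and Bayesian fitting

The dose-response of a sensor variant is the Hill curve
`G(L) = G0 + (Ginf − G0)/(1 + (EC50/L)^n)`; `L = 0` is always handled
as the analytic limit `G0`.  An *inverted* variant has `Ginf < G0`.
Parameters live on the scales used by the landscape tables: base-10
logarithms of G0, Ginf (MEF) and EC50 (µmol/L), linear Hill
coefficient.

`fit_hill` pools the non-outlier replicate curves of a variant and
samples the posterior with an affine-invariant ensemble sampler
(emcee, 32 walkers, differential-evolution moves, 800 burn-in + 600
retained steps thinned to ~1200 draws; deterministic per seed).
Cytometry geometric means carry multiplicative noise, so the
likelihood is lognormal with per-point relative scale
`max(geo_mean_err/geo_mean, 0.02)`; the 2 % floor prevents a single
over-confident point from dominating a 12-point curve.  Priors are
weakly informative: lognormal on G0 and Ginf centered on the low/high
end of the observed data (SD one decade), log-uniform EC50 over
0.1–10⁴ µmol/L (covering every phenotype class the landscape
contains), and a normal(1.5, 1) prior on `n` truncated to (0, 6].
Convergence is diagnosed with a per-walker split R-hat (arviz) and
flagged — not silently rejected — above 1.05; ensemble walkers are not
independent chains, so this is a deliberately stringent heuristic.
On clean 12-point curves the fit recovers all four parameters within
1 % (posterior median); over 50 curves with 5 % lognormal noise the
95 % central intervals cover the generating values ~97 % of the time.

Replicate outliers are removed before fitting: a replicate is dropped
when its saturating output differs from the consensus (median of log
Ginf, the 1-D geometric median) by more than 1.25-fold; dropping and
re-computing iterates to a fixed point, which makes the filter
idempotent, and at least one replicate is always kept.  Whether the
per-replicate Ginf estimate comes from a quick fit or from the
top-ligand signal is left to the caller; the CLI uses the top-ligand
signal.

## Landscape data model

A landscape row holds a variant's genotype (comma-separated canonical
codes like `V136E`, 1-based protein coordinates, empty string = wild
type), the posterior summary (means and one-SD uncertainties on the
log scales above), a posterior-sample sidecar (identical draw count
per variant, enforced), and a `quality` column — a dimensionless
relative evidence weight standing in for barcode-read depth.  Queries
evaluate predicates on posterior medians; `load ∘ save` is lossless.

## Synthetic-data generator

The generator produces landscapes with the structure of a large
deep-mutational-scanning study of an allosteric repressor:

* **Library.**  Missense counts per variant are Poisson(4.4); each
  variant draws its mutations without replacement from a vocabulary of
  substitutions at distinct positions (default 100), so some variants
  are wild-type duplicates, as in real error-prone-PCR libraries.
* **Effects.**  Each mutation carries a K=3 latent vector; a
  genotype's latent coordinate is the exact sum of its mutations'
  vectors (wild type = 0).  The axes perturb the MWC parameters:
  (1) operator binding energy Δε_RA (kT), (2) a ligand-binding-pocket
  axis moving log₁₀ K_A down and log₁₀ K_I up at 0.5 decade/decade,
  (3) the allosteric constant Δε_AI (kT).  Most effects are
  near-neutral and heavy-tailed (Student-t, df 3, scales 0.6 kT /
  0.12 decades / 0.5 kT); 5 % of mutations are strongly deleterious
  (+3–7 kT on Δε_RA, yielding flat high-output curves) and 3 % are
  inversion-prone (−0.9–1.4 decades on K_A, −3.5–6.5 kT on Δε_AI).  A
  single inversion-prone mutation is an intermediate with reduced
  dynamic range; two or more flip the curve into the rare
  high-basal inverted tail.  These fractions and scales were chosen
  once to reproduce the qualitative structure of the real landscape —
  EC50 spanning ≥3 decades, a dense non-inverted mode near the wild
  type, a sparse inverted tail — and are not tuned per experiment.
* **Wild-type anchor.**  Δε_RA = −14.4 kT, Δε_AI = 4.5 kT,
  K_A = 139 µmol/L, K_I = 0.53 µmol/L, R = 500, N_NS = 4.6×10⁶,
  G_max = 30.6 kMEF, giving G0 ≈ 158 MEF, Ginf ≈ 24.4 kMEF,
  EC50 ≈ 96 µmol/L, n ≈ 1.41 — a strongly repressing, ~150-fold
  dynamic-range induction curve.  Ligand constants follow the
  canonical in-vivo induction literature; R, N_NS and G_max are free
  anchors set to reproduce the basal output and dynamic range.
* **Measurement.**  The emitted posterior is Gaussian on the landscape
  scales: the center is the truth plus measurement error and draws
  scatter around the center with the same widths (0.04 decades for
  log G0/log Ginf, 0.06 decades for log EC50 — about a 1.15-fold
  replicate-level geometric SD — and 0.10 for n).  Flat curves get an
  EC50 width of a full decade (unidentified).  A FACS pre-screen
  retains records with probability following a falling logistic in
  log₁₀ G0 (midpoint 5 kMEF, width 0.3 decades); survivors keep
  `quality = P(retain)` and all widths scale as `1/sqrt(quality)`, so
  inverted (high-basal) variants are both rare and noisy.
* **Planting.**  `simulate_landscape(..., planted=[...])` appends
  variants with exactly specified true Hill parameters (quality 1),
  bypassing the latent map — used to place known-in-spec sequences for
  recovery experiments.

What the generator does **not** emulate: DNA-level mutations, barcode
or read-count noise (quality is a smooth proxy), non-monotonic
("band-stop") phenotypes, epistasis beyond what the smooth MWC map
induces from additive latent effects, and correlations between a
mutation's effects across axes other than the built-in K_A/K_I
coupling.  Passing tests therefore demonstrate that the methods work
when the landscape's generative assumptions hold approximately; they
do not certify performance on phenotypes whose genetic architecture is
strongly non-additive in any low-dimensional latent space.

## MWC allostery

The repressor switches between an active (operator-binding) and an
inactive state with two ligand sites:
`p_act(c) = (1+c/K_A)² / [(1+c/K_A)² + e^(−Δε_AI)(1+c/K_I)²]` and
`fold_change(c) = [1 + p_act(c)(R/N_NS)e^(−Δε_RA)]⁻¹`, output
`G(c) = G_max · fold_change(c)`.  For this form `G(c)` is monotone,
with direction set by the sign of `K_A − K_I`.  The Hill conversion
uses closed forms for `G0` and `Ginf`; the midpoint equation reduces
to a Möbius equation in `c`, so EC50 is computed exactly in closed
form (cross-checked against Brent root-finding in the tests) rather
than by bisection, and `n` is the Hill-equivalent log-slope at EC50.
Flat curves (K_A ≈ K_I or saturated repression, dynamic range below
10⁻³ decades) have no defined EC50 and raise an error (the vectorized
generator path flags them instead).  The inverted-regime mechanism —
decreasing K_A decreases both EC50 and Ginf — holds exactly on the
clearly inverted grid (K_A ≤ K_I/4); near the weak-inversion boundary
(K_A → K_I/2 at strongly negative Δε_AI) the EC50 derivative changes
sign, which is why the tested grid stops at K_I/4.

## In silico selection

A specification combines fold-bands around EC50/Ginf targets, absolute
G0/Ginf limits, and a phenotype class.  The two presets mirror
standard practice: *multiobjective* (EC50 within 1.2-fold, Ginf within
1.1-fold, G0 < 2 kMEF) and *inverted* (EC50 within 1.5-fold,
Ginf < 12.5 kMEF, 19.2 < G0 < 32.5 kMEF, inverted class).  Selection
pre-filters on posterior medians, then ranks by the joint
success probability over posterior draws.  The EC50 correction
(OLS of ln measured on ln landscape values) is applied to *every*
draw, not just the median, so band membership and probability stay
coherent; ranking probability includes all active criteria (G0
included).  Ties break toward fewer mutations, then lexicographic
genotype, for deterministic output.

The recovery experiment used by the acceptance suite places targets at
the extremes of the landscape's EC50 span (3 and 1000 µmol/L, Ginf 4,
8 and 16 kMEF) and plants five true-in-spec sequences per target.
Targets sit in sparse regions deliberately: near the wild type the
landscape naturally contains many true in-spec variants, so a
non-planted winner is a correct selection rather than a ranking
failure, and the planted-recovery metric is only informative where the
planted sequences are the unique true matches — which is also the
engineering-relevant case of requesting phenotypes the library barely
reaches.

## Latent landscape model

`y = f(Wx)` with `W ∈ R^(K×p)` (default K=3) and, per phenotype, a
polynomial basis expansion (total degree 3) over the standardized
latent coordinates fitted by Bayesian ridge regression.  This surface
meets the contract the method needs — differentiable mean, samplable
Gaussian coefficient posterior plus noise variance for Monte Carlo
predictive draws, minutes-scale training on 10⁴ variants on one CPU —
with far less machinery than a sparse Gaussian process, at the price
of a global polynomial's limited flexibility (adequate here because
the MWC-induced surfaces are smooth and gently saturating; raise
`degree` for wigglier landscapes).  Training alternates surface refits
with L-BFGS updates of `W` (analytic gradients through the basis)
from a ridge-regression initialization until the training loss stops
improving (relative tolerance 1e-7, max 20 rounds — a fixed small
round count was observed to leave systematic bias in recovered
effects).  Latent dimensions are ordered by drop-one contribution to
the training fit.  Records with inverted medians or effectively
unidentified EC50 (dynamic range < 0.2 decades or EC50 posterior SD
> 0.3 decades) are excluded from training, because inverted examples
are too rare for the model to learn.

Per-mutation effect uncertainties come from the full `Kp × Kp`
Gauss–Newton information of the residuals at the optimum (the
diagonal approximation underestimates them several-fold under
regressor collinearity).  A mutation is flagged significant on a
dimension when `|effect| > 2 SE` *and* the dimension is informative
(its drop-one MSE contribution exceeds half the summed surface noise
variance); the gate suppresses post-selection artifacts on null
dimensions, where a jointly optimized `W` can appear precise while
explaining nothing but noise.  Predictive draws sample surface
coefficients and observation noise but not `W`; the resulting
intervals are mildly conservative in practice (empirical 2-SD
coverage ~97 % on held-out synthetic variants) because observation
noise dominates.

`propose_improvement_mutations` is deliberately thin: the user asserts
which latent dimension corresponds to which biophysical parameter
(e.g. by correlating learned effects with an external hypothesis);
the model does not label its own axes.

## Evaluation

Fold-accuracy is `exp[RMSE(ln actual − ln predicted)]`, computed in
natural logs, symmetric and scale-free; `within_fold_fraction`
counts pairs with ratio ≤ k; systematic bias is the slope of the
ln-ln regression of actual on predicted.  When measurements are
posteriors, point values are posterior medians.

## Problem sizes and known limitations

The acceptance studies use 10⁴-variant landscapes, 20 selection
replicates, 50 MCMC recovery fits and 800 held-out predictions —
sizes at which every estimate above is stable run-to-run while the
whole suite stays in the minutes range on a single CPU.  Known
limitations: inverted variants are excluded from (and unpredictable
by) the latent model, mirroring their sparsity; significance flags on
`W` are approximate (Gauss–Newton + information gate, no full
posterior over `W`); the emcee split R-hat over walkers is a
heuristic, not a proof of convergence; and the latent→biophysics
correspondence used for forward engineering is a user-supplied
hypothesis, not a learned mapping.
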