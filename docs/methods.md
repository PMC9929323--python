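# Methods

`uvpool` analyzes dose-resolved survival of a randomized oligonucleotide
pool under 266 nm UV irradiation, read out by high-throughput sequencing.
This note records the models, the estimation choices, and what the
synthetic benchmark does and does not establish.

## The assay being modeled

Strands of layout `ACAC + N8 + ACAC` are irradiated; aliquots extracted at
doses D (absorbed photons per base, up to ~500) are library-prepped with a
polymerase that stops at dimeric photolesions, so only lesion-free strands
are sequenced.  The per-sequence read frequency versus dose is therefore a
survival curve.  Classes of k central bases (k ≤ 8) with randomized
neighbors are obtained by summing octamer counts over the outer positions
("marginalization" at the central window; only symmetric windows are
defined).  Sequences are numbered in alphabetical base-4 order (A=0, C=1,
G=2, T=3), e.g. hexamer TCGGTA = 3500, TTTTTT = 4095.

## Damage model

**Dimeric hazards.**  Excitation is shared between nearest neighbors, so
damage is attributed to ordered base pairs: pair XY forms a lesion with
the dimeric quantum yield phi_XY (damages per photon absorbed in the
dimer).  A strand's hazard h (per photon/base) is the sum of effective
yields over every adjacent pair touching the randomized octamer — a lesion
at a tail junction also stops the polymerase, which is why an i-mer with
randomized flanks has i+1 damageable pairs and a total yield
phi = mu/(i+1).

**Charge-transfer quenching.**  A guanine immediately adjacent to a
pyrimidine-pyrimidine pair donates an electron to the excited dimer and
deactivates lesion formation.  We parametrize this as a factor (1-q) per
adjacent G (so (1-q)^g with g in {0,1,2}), one global q in [0,1].  A
single symmetric q is a modeling choice; context-dependent quench strengths
are not identifiable from tetramer data at realistic depth.

**Secondary kinetics.**  The lesion state L can photorevert to the intact
state (coefficient rho per photon/base) or decay irreversibly (sigma):

    dI/dD = -h I + rho L,     dL/dD = h I - (rho + sigma) L

with I(0)=1.  The closed-form eigen-solution is bi-exponential in D and
reduces to exp(-h D) at rho=0; this is what produces the fast phase +
plateau shape of poly-T classes.  Defaults rho = 0.004, sigma = 0.001
per photon/base are the package's own choice (no published values exist),
set so that poly-T-like classes show a clear fast phase and TTTT crosses
50% survival near ~10 photons/base.

**Leak-through.**  Library preparation suppresses damaged strands by about
three orders of magnitude but not perfectly; a damaged strand is still
read with probability epsilon (default 1e-3).

**Canonical yield table.**  The four dimers the assay resolves:
phi_TT = 0.021, phi_CT = phi_TC = 0.011, phi_CC = 0.006, phi_AA = 0.0019;
all other dimers sit below the ~0.5e-3 sensitivity floor and default to
zero.  These values, with q = 0.5, are the synthetic generator's ground
truth.

## Synthetic data generator

`synthetic_pool.simulate_counts` draws, per dose, one multinomial of the
configured depth over the 65,536 octamers with probabilities proportional
to `b_i * (I_i(D) + epsilon (1 - I_i(D)))`.  The per-octamer weight b_i is
log-normal; sigma_log = 1.0 reproduces the observed max/mean count ratio
of ~40 in unirradiated pools.  `emit_fastq` writes one Phred+33 read per
count (`tail + octamer + tail`, constant quality, optional random
low-quality demotions) so the read-counting stage can be exercised
round-trip.

What the generator does **not** emulate: sequencing substitution errors,
adapter artifacts, PCR duplicate structure, batch effects between dose
aliquots, double-strand formation, and lesion-type heterogeneity (all
lesions block readout identically).  Passing the recovery benchmark
therefore shows the estimation chain is correct and well-calibrated for
Poisson/multinomial counting noise, synthesis bias and the modeled
photophysics — not that it is robust to every artifact of a real
sequencing run.

## Read counting

A read is counted iff both `ACAC` framing tags match exactly at their
expected positions and every central-octamer base has Phred quality
strictly above 20 (the threshold and tag are configurable; tail qualities
are ignored since the tails are discarded).  Reads whose octamer contains
non-ACGT symbols count as layout failures, keeping
passed + failed_tag + failed_quality = total exact.

## Normalization

The double ratio

    r_i(D_j) = [n_i(D_j)/n_ref(D_j)] * [n_ref(0)/n_i(0)] * exp(-mu_ref D_j)

cancels any per-class multiplicative synthesis/readout bias exactly and
anchors r_i(0) = 1.  The reference is the poly-G class (weakest dose
dependence).  The restore factor reinstates the reference's own slow
decay; mu_ref is either a fixed value (the literature-scale poly-G
tetramer coefficient 0.00077 base/photon; in fixed mode the configured
value is applied at every k) or estimated self-consistently: normalize,
fit the complete damage model, predict the reference's nearest-neighbor
hazard from the fitted yields, iterate.  The loop converges in two
iterations because the restore factor cancels between data and model.
Per-point errors are first-order Poisson; classes with a zero unirradiated
count are excluded; zero counts elsewhere get a one-pseudo-count floor so
weights stay finite.

## Per-class decay fits

Every class is fitted with `exp(-mu D)` and, when at least 5 dose points
exist, with `a exp(-mu1 D) + (1-a) exp(-mu2 D)` (bounds a in [0,1],
mu1 >= mu2 >= 0 via mu2 = f mu1, five deterministic multi-starts).  Model
choice uses AICc with a margin of 2 in favor of the simpler model.  The
damage coefficient is the fitted initial slope mu_init = a mu1 + (1-a) mu2
— the quantity that equals the class hazard regardless of photoreversal —
and phi = mu_init/(k+1), D50 from ln2/mu (mono) or bracketed root finding
(bi; censored as "> D_max" when survival stays above one half).  Reported
mu uncertainties combine the fit covariance with the systematic ~16%
dose-scale error in quadrature (`mu_init_se_total`); the statistical part
is kept separate because the dose-scale error is common-mode.

## Dimer-yield estimation

**Linear design rows.**  `design_row` expresses a class's expected hazard
as a linear form in the 16 phi_XY: internal pair counts plus
flank-averaged boundary terms, quench factors entering as polynomials in
(1-q) (each adjacent position contributes a factor that is linear in 1-q;
random neighbors contribute (3 + (1-q))/4).  Two conventions exist:
`nearest` (only pairs touching the window — the classic i+1-dimer picture)
and `pool` (every pair touching the randomized octamer, flanks
marginalized — the exact expectation under the forward model, including
quenching that window-edge guanines exert on flank-flank pairs).

**Identifiability.**  The no-quench linear model has a genuine gauge null
space: phi_XY -> phi_XY + c_X - c_Y telescopes to zero over internal pairs
and both boundary averages (rank 13 of 16 over all 256 tetramers).  Tying
XY with YX (10 parameters, the convention in which results are reported)
removes it.  `invert_naive` therefore raises on rank-deficient designs,
naming the unidentifiable combinations; the tied unconstrained inversion
is exact on noiseless composed coefficients.  Fitted to quench-generated
data, the naive model returns *negative* G-pyrimidine yields — the
diagnostic that motivates the quench extension.  `invert_quench` profiles
q on a 0.01 grid with a non-negative inner solve (each inner problem is
convex) and a bounded local refinement.

**Why the pipeline fits curves, not coefficients.**  A marginalized class
is a mixture over flank completions.  Over a finite dose range the fitted
coefficient of a mixture settles toward its slowest components, so for
slowly decaying classes mu_init is not estimable at realistic depth and a
linear inversion of fitted coefficients inherits large structured biases.
The pipeline therefore estimates yields with `fit_pool_model`: one
weighted nonlinear least squares of the complete model — tied yields, q,
and the global nuisances rho, sigma, epsilon — against *all* normalized
class curves simultaneously.  Model curves are flank mixtures of the
two-state kinetics, weighted by the unirradiated octamer counts (which
measure the synthesis bias directly), divided by the reference class's
model curve, so the reference's own decay is part of the model and the
overall yield scale stays identified.

**Correlated reference noise.**  Every class is divided by the same
reference column, so the reference's Poisson fluctuations are a per-dose
*common* disturbance, not independent point noise; plain weighted least
squares funnels that disturbance into the kinetic nuisances and the small
yields.  When the count table is available, the fit profiles one
multiplicative nuisance factor per nonzero dose, Gaussian-penalized by the
reference count's known variance, and the per-point errors then carry only
class-specific Poisson terms.  This generalized-least-squares treatment is
what makes yields near the sensitivity floor stable.

**Numerical choices.**  Bounds phi in [0, 0.2], q in [0, 1]; trust-region
reflective least squares with fixed x_scale; a single deterministic start
(small uniform yields) plus warm starts across the self-consistency loop;
no stochastic elements anywhere in estimation, so identical inputs give
identical outputs.  Covariance is taken from the Gauss-Newton normal
equations at the optimum (approximate where non-negativity binds).

## Validation benchmark and problem sizes

The standard recovery benchmark simulates depth 1e6 reads per dose at 12
doses (0 plus 11 log-spaced from 2 to 250 photons/base — dense early
sampling mirrors the many low-dose extractions and pins fast decays),
mild bias (sigma_log = 0.5), canonical yields with q = 0.5 as ground
truth, writes and re-counts FASTQ, and runs the full chain.  Across seeds
the recovered TT, CT, CC and AA yields land within ±0.003, ±0.002,
±0.001 and ±0.0003 of truth respectively — the uncertainties the assay
itself attains — with q recovered to ±0.1 and purine-dimer yields staying
below the 0.5e-3 sensitivity floor.  Unit and property tests use depths
of 3e4 to 3e5 and tetramer or shorter pools so the whole suite stays
within a desktop budget.

## Known limitations

- Yields below ~0.5e-3 are reported as small positive numbers (half-normal
  noise against the non-negativity bound), not as zeros with signs.
- epsilon (leak-through) is weakly identified when no class is driven deep
  into its plateau within the dose range.
- The quench form (1-q)^g with one global q is a concretization; the data
  cannot distinguish per-context quench strengths at tetramer depth.
- Fixed-mode mu_ref applies one value at every k although the printed
  anchor is tetramer-scale.
- Real-data artifacts outside the generator's scope (see above) are
  untested by construction.
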