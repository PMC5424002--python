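# Methods

`niacffa` implements a coupled exposure–response model of nicotinic acid
(NiAc), insulin and free fatty acids (FFA) in lean Sprague-Dawley and
obese Zucker rats, together with the population-statistical machinery to
fit it to long-format observation tables and the dosing mathematics to
optimize infusion regimens for 24 h FFA lowering.

Units are fixed package-wide: time in hours, NiAc in µM, insulin in nM,
FFA in mM, drug amounts in µmol/kg. The studies' reference infusion of
170 nmol·min⁻¹·kg⁻¹ is 10.2 µmol·kg⁻¹·h⁻¹.

## Structural model

**NiAc disposition.** Lean rats: two compartments (plasma volume `Vp`,
tissue volume `Vt`, inter-compartmental distribution `Cld`) with two
parallel Michaelis–Menten elimination pathways (`Vmax1/Km1`,
`Vmax2/Km2`) and endogenous synthesis `Synt`. Obese rats: one
compartment, single pathway. The drug-free baseline `Cp0` solves
`Synt = Σ Vmaxᵢ·Cp0/(Kmᵢ+Cp0)` (closed form for one pathway, bracketed
root otherwise). Subcutaneous dosing feeds a depot with first-order
absorption `ka`; the implanted mini-pump's effective output ramps up as
`erf(t·δ/√t0)` from first activation (`t0 = 168 h`, the implantation
lead time): interstitial fluid dilutes the catheter dead volume before
the pump starts, so early delivery lags the programmed rate. The ramp
applies only to pump administration and its clock is anchored at the
first activation, which for the pretreated groups is 120 h before the
acute experiment. δ is used exactly as estimated, with time in hours;
its printed unit (h^1/2) makes the erf argument formally dimensioned,
and no correction is attempted. Subcutaneous bioavailability is 1.

**Insulin turnover.** Insulin `I` has release `kinI` inhibited by plasma
NiAc through `H_NI = 1 − E_NI·Cpⁿ/(IC50NIⁿ+Cpⁿ)`. Two moderator
compartments in cascade (rate `ktolI`) feed back on release and on
fractional turnover (`koutI`), producing acute tolerance and
post-infusion rebound. A regulator `RI` with `dRI/dt = kinRI − koutRI·I`
multiplies release: an integral feedback controller whose set point is
the baseline `I0` (`kinRI = koutRI·I0`), so the only equilibrium under
any sustained exposure has `I = I0` (complete adaptation). In obese rats
the efficacy `E_NI` is itself down-regulated by a slow "NiAc action"
compartment `NI` (first-order tracking of `Cp` with rate `kNI`):
`E_NI = ImaxNI·(1 − SNI·NIᵞ/(N50Iᵞ+NIᵞ))` — drug resistance. Lean rats
have constant efficacy and no action compartment (the loss term was
estimated to be ~0 in that population).

**FFA turnover.** Same architecture with a single moderator (`ktolF`),
dynamic efficacy in both species (`kNF`, `N50F`, `SNF`, Hill `phi`), and
the regulator `RF` driven by *insulin* with set point `I0`
(`kinRF = koutRF·I0`): insulin below baseline stimulates FFA release
(reduced antilipolysis) and vice versa.

**Derived baseline rates.** `kinI`, `kinRI`, `kinF`, `kinRF` are not
free: stationarity of the drug-free baseline (at the endogenous `Cp0`)
gives `kinRI = koutRI·I0`, `kinRF = koutRF·I0`,
`kinI = koutI·I0/H_NI(Cp0)` and `kinF = koutF·F0/H_NF(Cp0)`. Zero drift
at the initial condition is machine-verified in the tests.

## Numerics

The coupled system spans time scales from seconds (FFA fractional
turnover, half-life ≈ 6 s in lean rats) to days (NiAc action, ≈ 106 h),
so integration uses LSODA at `rtol 1e-8 / atol 1e-10` for simulation,
restarted at every infusion on/off/step boundary so rate discontinuities
never cross a solver step. Estimation uses `rtol 1e-6 / atol 1e-8`
(residual errors are 5–50 % of signal, so 1e-6 trajectories are far
inside the noise floor). Sequential runs (each sub-model driven by exact
interpolants of the upstream solution) and fully coupled runs agree to
well under 0.1 %, which is tested. Moderator states are protected by
solver tolerances, not floors: a floor would distort the ratio terms in
the release equations, so a non-positive moderator raises instead.

Dense solver output backs all quadrature (`AUC_T = F0·T − ∫F dt`,
Gauss–Kronrod per continuous span); a trapezoid oracle on a fine grid
agrees to < 0.01 %.

**Periodic steady state.** A dosing cycle is iterated until the maximum
relative change of the state at the cycle start falls below 1e-6 (cap
500 cycles), with an Aitken-style geometric projection of the remaining
change so that short cycles (weak per-cycle contraction of the slow NiAc
action state) terminate correctly. For the regimen scans the periodic
value of the action compartment is pre-solved in closed form from the
converged exposure cycle (it is a linear low-pass of `Cp`), which
removes the days-long transient; pinned and plain iteration agree and
both are tested, and the whole construction was verified against a
brute-force 1500 h integration.

## Steady-state predictions and the regulator's memory

The FFA regulator integrates the insulin deviation over the *entire*
history: its long-run level is `1 + koutRF·∫(I0−I)dt`, which depends on
the transient taken to reach steady state, not only on the steady state
itself. Simulated from a drug-naïve baseline, a 0.5 µM clamp in obese
rats parks `RF ≈ 1.53` and cuts the apparent 24 h AUC reduction to
~2.6 mM·h. The steady-state predictions in this package (concentration–
response curves, regimen grids, the reported AUC numbers) therefore take
the insulin system at its adapted set point — `I ≡ I0`, regulator at
baseline — which is the regime the source model's own steady-state
statements describe ("all actions back at baseline at equilibrium") and
the convention under which the published prediction figures reproduce.
The fully coupled alternative is available via `insulin="dynamic"` and
its history dependence is unit-tested, including the closed-form
relation `F_dyn = F_setpoint·√RF`.

Under the set-point convention the clamped equilibrium has the closed
form `F_eq = F0·√(H_NF(Cp)/H_NF(Cp0))` (the moderator splits the
inhibition between release and response), used as the algebraic route
and cross-checked against the ODE route. Two consequences worth
flagging: clamping *below* the endogenous `Cp0` raises FFA slightly
above `F0` (the baseline already carries ~9 % endogenous inhibition in
obese rats), and complete adaptation at high exposure lands ~2–5 %
*above* baseline rather than exactly on it, because the collapsed
efficacy removes the endogenous inhibition too. The 120 h adaptation
checks in the test suite run at the experimental infusion rate, where
insulin is back within 2 % of baseline at 120 h; at a 1.0 µM clamp the
obese efficacy collapse falls near t ≈ 94 h and leaves a transient
~10 % insulin overshoot at exactly 120 h that settles by 200 h.

**Regimen grid.** Cells are (infusion, washout) cycles of constant-rate
i.v. infusion whose rate gives a 1 µM plateau through the
Michaelis–Menten balance (≈ 8.07 µmol·kg⁻¹·h⁻¹ in obese rats); the route
and exact packing behind the published figure are unstated, and this is
the documented choice. AUC24 is 24·(F0 − cycle-mean F) at the converged
periodic state — phase-independent and equal to any whole-window
construction. The surface has a nearly flat ridge along a duty cycle of
~0.6–0.65, set by the NiAc-action threshold `N50F`: more on-time loses
efficacy, more off-time wastes suppression. Its maximum reproduces the
published maximal reduction to ~1 %, but sits at a washout *shorter*
than the infusion, not the published "washout ≈ infusion + 2 h"; this
discrepancy survived every alternative convention we tried (fully
coupled insulin, regulator-normalized cycles, the experimental infusion
rate, first-day AUC) and is reported as computed. Ties prefer the
shortest infusion; local refinement hill-climbs on a 0.25 h lattice from
the coarse argmax.

## Population model and estimation

Between-subject variability is log-normal on {`ka`, `Vmax1`, `Synt`
(lean only)}, {`I0`, `ktolI`, `IC50NI`}, {`F0`, `ktolF`, `IC50NF`}, with
diagonal covariance throughout; the published BSV CV% equals 100·ω on
the log scale and this convention is kept (for ω near 1 it is not the
exact lognormal CV). Fixed-study effects are group-specific multipliers
on {`I0`, `ktolI`, `F0`, `ktolF`} applied to both the mean and the
individual draws; cross-group summaries use sample-size weighting.
Residual error is proportional on NiAc and additive on insulin and FFA.
Efficacies fixed in the source analysis stay fixed here (`ImaxNF = 1`
both species; obese `ImaxNI = SNI = SNF = 1`; lean `phi = 1`).

The marginal likelihood per stage is FOCE with interaction: per subject
the random-effect mode is found by damped Gauss–Newton (Levenberg–
Marquardt fallback, warm-started, gradient tolerance 1e-5) and the
Laplace correction uses the Gauss–Newton inner Hessian. Fitting is
sequential (exposure → insulin → FFA) with random effects frozen at
their EBEs between stages; operationally the frozen upstream sub-models
are co-integrated with the stage being fitted in one smooth compiled
state vector, which is exactly the "fixed covariate" semantics without
interpolated forcings (whose kinks throttle the stiff solver's step
size). Subjects without exposure samples (the chronically infused obese
group) keep zero exposure random effects, i.e. follow the estimated
median individual.

Fixed effects, omegas and sigmas are estimated on log scale (logit for
efficacies). Because near-flat inner posteriors make the exact FOCE
objective slightly path-dependent (0.01–0.1 nats between evaluations),
naive finite differences of it are noise; the outer optimizer instead
alternates full mode refreshes with trust-region minimization of the
frozen-mode objective, which is smooth and deterministic, accepting a
move only if the exact objective improves. At a fixed point the frozen
gradient vanishes, which by the envelope property of the inner optimum
is FOCE stationarity. Standard errors, when requested, come from a
central finite-difference Hessian of the objective (delta method back to
natural scale).

FOCE itself is cross-checked two ways: against the pooled likelihood in
the ω→0 limit, and against the exact conjugate-Gaussian marginal on a
linear toy model, where Laplace with a Gauss–Newton Hessian is exact.

## Synthetic data

No animal time courses were deposited, so the estimation layer is
exercised on synthetic populations with the statistical structure the
model assumes. The generator reproduces the seven study protocols
(including the printed step-down rate ladders, applied as seven equal
0.5 h steps between infusion end and the printed final switch-off — the
per-step timing was not published), the 120 h pretreatment histories,
the group sizes of the published design, the missing exposure sampling
in the chronic obese arm, and the residual-error models. Sampling clock
times were not published either; the defaults place 2–3 basal samples
before dosing and geometrically densifying samples after each rate
change (16–18 per animal), matching the published sampling densities,
and are configurable per protocol.

What the generator does *not* emulate: assay-specific artifacts,
correlated random effects (the source analysis also used diagonal
covariance), circadian or feeding effects on FFA, and model
misspecification of any kind — the fitted model is the generating model.
Passing recovery tests therefore demonstrate that the estimator is
consistent with its own assumptions at realistic design sizes, not that
the model is correct for real rats.

**Parameter recovery study.** The dedicated recovery check uses obese
rats on six protocols at their published group sizes (acute naïve 7+2,
continuous 8+1, 1 h i.v. 5, 1 h step-down 5, 12 h s.c. 4, 12 h
step-down 4; 36 animals — only the intermittent arm is dropped), no
study effects, and estimates per stage the fixed effects the source
analysis reported with RSE% < 30 plus the stage's omegas and residual
sigma, the weakly determined remainder staying at its generating values
(the source analysis likewise fixed poorly identified parameters).
Initial values are the truths perturbed by ±25 % (seeded). A pilot at
n = 4 per group showed the 25 % recovery band is unattainable regardless
of estimator — the *sample median* of `ka` among 13 animals was already
27 % off by the draw (ω = 0.80) — which motivated the published-size
design; the step-down arms matter because their taper ladders trace the
sub-IC50 exposure range that identifies the potencies and Hill
coefficients. The exposure and FFA stages recover their well-determined
fixed effects within 25 % at the pinned seed; the insulin potency block
(`IC50NI`, `n`, `koutRI`, `N50I`) does not — the insulin likelihood
given EBE-frozen exposures prefers a correlated potency/Hill/gain ridge,
and substituting the true exposures restores the preference for truth,
so the shortfall is exposure error propagated by the sequential scheme
itself under the 48 % proportional exposure noise, not the optimizer.
The corresponding check is asserted as stated and fails informatively.
The full two-species design is outside the intended single-CPU test
budget; problem sizes here (36 subjects, ~1600 observations, three
stages, a 12-cycle cap per stage) run in roughly ten minutes.

## Known limitations

* The regimen-grid optimum location and two narrow quantitative bands
  (FFA within 2 % of baseline at exactly 120 h; see above) do not
  reproduce the published statements under the published median
  parameters; the corresponding checks are kept as written and fail
  loudly rather than being relaxed.
* The steady-state predictions' set-point convention is a modeling
  choice forced by the regulator's history dependence; regimens that
  never let insulin adapt would need the dynamic variant.
* FOCE with very large omegas (ω up to 3.1 as published) is known to be
  biased and the inner posteriors are nearly flat in those directions;
  omega estimates should be read as order-of-magnitude at these design
  sizes.
* The lean "NiAc action" half-life (≈ 106 h) exceeds any published
  protocol duration, so lean efficacy-loss parameters are practically
  driven by the prior design, as their published standard errors
  (RSE% ≈ 160–190) already indicate.
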