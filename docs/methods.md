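# Methods

## Physical model

The construct is a tandem repeat of N identical two-state domains pulled
at constant velocity between a surface and a Hookean cantilever.  Three
ingredients define the mechanics:

1. **Entropic elasticity.** The unfolded polypeptide is a worm-like chain
   (WLC) in the Bustamante/Marko–Siggia interpolation,
   F(x) = (k_BT/p)[¼(1 − x/L_c)⁻² − ¼ + x/L_c].  The chain contour length
   is a state variable: it starts at the folded construct's end-to-end
   contribution (N × 1.5 nm folded N–C spans by default) and grows by
   ΔL_c per unfolding event.

2. **Series compliance.** The cantilever (stiffness k_c) and the chain
   share the base displacement: base = x + F/k_c with F = F_WLC(x).  The
   equilibrium force is re-solved at every step.  Compliance can be
   switched off (`compliant_cantilever=False`), which recovers the
   textbook situation where force follows the WLC of the base position;
   a zero-contour construct (`initial_Lc=0`, single domain) instead gives
   a pure force ramp F = k_c·v·t, the limit with an exact closed-form
   rupture-force distribution used as the simulator's oracle.

3. **Bell kinetics.** Each folded domain escapes with rate
   k_u(F) = k_u⁰·exp(F·Δx_u/k_BT).  Unfolding is all-or-none (no
   intermediates) and refolding is neglected — under continuous loading a
   re-folding event is vastly slower than the pulling time scale, and the
   procedure runs until every domain has unfolded.

Per step the hazard is first-order: P_u = N_f·k_u(F)·Δt, one domain at
most unfolds per step (the step policy keeps P_u small enough that
multiple ruptures per step have negligible probability), and the unfold
decision is u < P_u with u ~ Uniform(0,1).

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| persistence length p | 0.4 | nm | standard value for unfolded polyprotein chains in AFM work; not independently measurable from per-peak fits, so held fixed everywhere |
| ΔL_c | 29.1 | nm | 85 aa × 0.36 nm/aa − 1.5 nm folded N–C span |
| N (domains) | 8 | — | the engineered octamer |
| initial L_c | 12 | nm | N × 1.5 nm folded spans; the folded construct is otherwise rigid |
| cantilever k_c | 40 | pN/nm | typical soft AFM lever for this force range |
| temperature | 298 | K | room temperature; k_BT = 4.114 pN·nm, RT = 0.592 kcal/mol |
| apo kinetics | k_u⁰ = 1.05×10⁻³ s⁻¹, Δx_u = 0.55 nm | | k_u⁰ is the geometric mean of the calibrated range 1.0×10⁻⁴–1.1×10⁻² s⁻¹ (log-scale parameter → geometric mean is the natural representative) |
| holo kinetics | k_u⁰ = 2.35×10⁻³ s⁻¹, Δx_u = 0.38 nm | | geometric mean of 5.0×10⁻⁴–1.1×10⁻² s⁻¹ |
| attempt frequency k_A | 10⁹ | s⁻¹ | conventional pre-exponential for protein (un)folding barriers; ΔG‡ shifts by RT·ln(ratio) if overridden |
| Ca²⁺ sites (octamer) | K_d = 31 µM / 166 µM; ΔH = −8.5 / −3.2 kcal/mol | | sequential two-site convention K₁ ≥ K₂ |

## Time-step policy

The base step is min(10⁻⁴ s, 0.1 nm of base travel).  Because the Bell
rate grows exponentially with force, a fixed step would violate the
first-order hazard approximation near rupture; the step is therefore
shrunk adaptively so that P_u stays below `max_pu` (default 0.05, with a
0.5 safety factor against within-step rate growth).  Halving `max_pu`
moves mean rupture forces by well under 1 pN, and the single-domain
constant-loading-rate ensemble passes a Kolmogorov–Smirnov test against
the exact survival function S(F) = exp(−(k_u⁰k_BT)/(νΔx_u)·(e^{FΔx_u/k_BT}−1))
at n = 2000 (KS < 0.05).

All traces of an ensemble run in lock-step on a shared base-position
schedule (vectorized across traces); the step adapts to the
fastest-unfolding trace.  Ensembles are deterministic under a fixed seed.

## Trace analysis

Peaks are local maxima of a moving-average-smoothed force (window 5
samples) that reach 30 pN and are followed by a ≥20 pN drop.  The
thresholds are ours: 30 pN sits ~3 SD below the apo force scale and
rejects σ ≤ 8 pN noise.  Each rising edge — from the preceding force
minimum to the peak, restricted to F > 5 pN — is least-squares fitted
with the WLC with p fixed and only L_c free; ΔL_c is the difference of
consecutive fitted contour lengths, with increments outside 15–45 nm
discarded (missed/split peaks).  Only traces with ≥4 events enter pooled
statistics.  The ΔL_c histogram is additionally summarized by a
least-squares Gaussian fit.

Simulated traces include a short (2 nm of base travel) tail past the
final rupture so the last peak's force drop is visible to the detector;
the sample recorded at a rupture step is the pre-rupture apex.

## Landscape extraction

Two routes recover (k_u⁰, Δx_u) from speed-dependent mean forces:

- **Monte Carlo grid calibration** (`fit_landscape_mc`): re-simulate at
  each grid pair with common random numbers and minimize the squared
  mean-force mismatch; an optimum on the grid edge is flagged.
- **BER regression** (`fit_ber`): OLS of mean force on ln ν with
  ν = speed × k_c; slope = k_BT/Δx_u, intercept fixes k_u⁰; standard
  errors by the delta method.  Fitting is done on per-speed means,
  unweighted by default (inverse-variance weighting available through
  the returned covariance pieces if needed).

The two routes deliberately disagree in a known way: reducing an
8-domain ensemble with compliance-dependent loading to the single-barrier
closed form compresses Δx_u (0.55 → ~0.48 nm apo; 0.38 → ~0.33 nm holo)
and inflates k_u⁰ by one to two orders of magnitude.  Both behaviours are
asserted in the tests.

ΔG‡ = RT·ln(k_A/k_u⁰) uses the representative (geometric-mean) k_u⁰;
k_s = 2ΔG‡/Δx_u² converts kcal/mol → J (× 6.9477×10⁻²¹) and nm → m.

## ITC model

"Sequential two-site" means stepwise association constants K₁ = 1/K_d1,
K₂ = 1/K_d2 and binding polynomial 1 + K₁L + K₁K₂L² in the free ligand L
(the standard meaning in ITC software; the formalism is re-derived here
rather than imported).  L solves the mass balance by bracketed
root-finding on [0, L_t] to 10⁻¹² relative residual.  Cell concentrations
after cumulative injection volume dV use the displaced-volume
expressions P = P₀(1 − dV/2V₀)/(1 + dV/2V₀), L = L_s(dV/V₀)/(1 + dV/2V₀),
and per-injection heats carry the matching correction
dQ_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2.  The default synthetic
design (1.4 mL cell, 180 µM protein, 5 mM CaCl₂, 25 × 10 µL injections)
reaches molar ratio ~5.5, past first-site saturation.

The fitter runs Levenberg–Marquardt over (ln K₁, ln K₂, ΔH₁, ΔH₂),
enforces K₁ ≥ K₂ by refitting from the swapped start when violated, and
flags site II unidentifiable when the standard error of ln K₂ exceeds 10
(the noise scale used for this diagnostic is floored at 1% of the largest
heat so that flat directions are caught even on noiseless input).

## Synthetic data: what it does and does not emulate

Generators add i.i.d. Gaussian force noise (default σ = 5 pN, typical AFM
thermal noise at these stiffnesses), optional linear baseline drift and
an exponential adhesion bump to simulated traces, and proportional
Gaussian noise (default 2% of the largest heat) to model thermograms.
The default pulling replica uses speeds {100, 300, 1000, 2000, 4000} nm/s
with 50 traces per speed — a desk-scale stand-in for event counts of a
few hundred per condition.  Not emulated: 1/f and correlated instrument
noise, piezo hysteresis, non-specific multi-molecule pickups, and
detachment peaks.  Passing round-trip tests therefore demonstrates that
the analysis is unbiased under idealized noise, not that it is robust to
every artifact of real AFM data.

## Numerical choices

- WLC inversion and the free-ligand solve use bracketed Brent root-finding
  (guaranteed bracket; force law and mass balance are strictly monotone).
- The in-simulator force balance uses a safeguarded, warm-started Newton
  iteration clamped to [0, L_c); its derivative 1 + k_WLC/k_c > 1 makes
  the iteration contractive.
- The Bell exponent is capped at 700; a capped evaluation flags the trace.
- Per-peak contour fits seed curve_fit from a coarse 1-D scan and bound
  L_c above the largest extension in the fit window.
- Degenerate inputs fail loudly: extensions at/over L_c, non-positive
  rates or speeds, empty traces, fewer than 3 speeds for the BER fit,
  fewer than 10 injections for the two-site fit.

## Problem sizes

Reference runs use 500 traces per condition at 1000 nm/s for pooled
rupture forces and 200 traces per speed over 100–4000 nm/s for the speed
dependence; noisy round-trip and recovery studies use 20–200 replicates.
These sizes put Monte Carlo standard errors on mean forces well below
1 pN, far inside the quoted tolerances.

## Known limitations

- No refolding, no unfolding intermediates, no force-clamp protocols.
- The apo–holo mean-force gap narrows at low speed (~22 pN at 100 nm/s vs
  ~30–35 pN at ≥1000 nm/s): with a smaller Δx_u the holo force–ln ν slope
  is steeper, so the curves converge as speed drops.  The ~30–35 pN
  characterization holds for the 500–4000 nm/s range.
- Persistence length is an assumption (0.4 nm), not a fitted quantity;
  mean rupture forces move by a few pN across p = 0.3–0.5 nm.
- The two-phase force-vs-[Ca²⁺] titration regime is out of scope: the
  package links binding and mechanics only through the apo/holo parameter
  sets, not through a fractional-occupancy model.
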