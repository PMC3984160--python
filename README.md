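# polypull

Single-molecule force spectroscopy (SMFS) of tandem polyproteins, built
around the mechanics of M-crystallin — a Ca²⁺-binding β-sandwich protein
from *Methanosarcina acetivorans* studied as an engineered octamer,
(M-crystallin)₈.  The package is for force-spectroscopists and modellers
who want a tested, scriptable pipeline for:

- **Monte Carlo pulling simulation** of an N-domain construct at constant
  velocity, with two-state Bell kinetics under worm-like-chain (WLC) +
  cantilever compliance;
- **sawtooth trace analysis**: peak detection, per-peak WLC contour-length
  fits, ΔL_c and rupture-force statistics with the ≥4-event trace filter;
- **energy-landscape extraction** by the Bell–Evans–Ritchie (BER) model,
  the Arrhenius barrier height, and the harmonic-well spring constant;
- **sequential two-site Ca²⁺-binding thermodynamics** (ITC): the binding
  polynomial, per-injection heats, and nonlinear isotherm fitting;
- **synthetic data generators** that emulate noisy AFM traces and ITC
  thermograms with exact ground-truth manifests.

## The model

The unfolded chain pulls back with the WLC interpolation force at
extension *x*, persistence length *p* and contour length *L_c*:

    F(x) = (k_BT/p) · [ ¼(1 − x/L_c)⁻² − ¼ + x/L_c ]

Each folded domain unfolds over a single barrier with the force-activated
Bell rate k_u(F) = k_u⁰·exp(F·Δx_u/k_BT), where Δx_u is the distance to
the transition state.  During a simulated pull the per-step unfolding
probability P_u = N_f·k_u(F)·Δt (N_f = folded domains) is compared with a
uniform random number; each event adds ΔL_c = 29.1 nm of contour (85
residues × 0.36 nm/aa − 1.5 nm folded N–C span).  The speed dependence of
the mean rupture force is inverted with the BER relation

    F(ν) = (k_BT/Δx_u) · ln( ν·Δx_u / (k_u⁰·k_BT) ),   ν = speed × k_c,

and the landscape is completed by ΔG‡ = RT·ln(k_A/k_u⁰) (k_A = 10⁹ s⁻¹)
and k_s = 2ΔG‡/Δx_u².  Ca²⁺ binding follows the sequential two-site
formalism with binding polynomial 1 + K₁L + K₁K₂L².

## Worked example

```python
from polypull import PullingProtocol, simulate_ensemble, fit_ber, \
    summarize_landscape, mean_force_vs_speed
from polypull.presets import apo_kinetics, holo_kinetics, octamer_construct

construct = octamer_construct()                 # 8 domains, dLc = 29.1 nm
protocol = PullingProtocol(speed=1000.0, cantilever_k=40.0)

apo = simulate_ensemble(construct, apo_kinetics(), protocol,
                        n_traces=200, rng_seed=0)
holo = simulate_ensemble(construct, holo_kinetics(), protocol,
                         n_traces=200, rng_seed=0)
print(apo.datum.mean_force, holo.datum.mean_force)

series = mean_force_vs_speed(construct, apo_kinetics(), protocol,
                             [100, 200, 500, 1000, 2000, 4000],
                             n_traces=100, rng_seed=0)
fit = fit_ber(series)
print(fit.kinetics.dx_u, fit.kinetics.k_u0)
```

prints (to the digits shown):

```
apo  mean rupture force: 87.8 +/- 11.3 pN  (n=1600)
holo mean rupture force: 117.7 +/- 16.8 pN  (n=1600)
BER fit: dx_u = 0.478 +/- 0.007 nm, k_u0 = 1.75e-01 1/s
apo landscape: barrier 16.3 kcal/mol, k_s 0.75 N/m
holo landscape: barrier 15.9 kcal/mol, k_s 1.53 N/m
```

Reading: the apo octamer ruptures near 88 pN at 1000 nm/s and Ca²⁺
binding raises that by ~30 pN; re-fitting the simulated speed dependence
with the BER model compresses Δx_u from the 0.55 nm simulation input to an
effective ~0.48 nm, as is typical when a multi-domain ensemble is reduced
to a single-barrier closed form.  The apo barrier of ~16.3 kcal/mol with
Δx_u = 0.55 nm gives a well stiffness of 0.75 N/m; the holo well
(Δx_u = 0.38 nm) is twice as stiff at ~1.5 N/m.

The same pipeline is scriptable from the shell:

```bash
polypull simulate --params apo --speed 1000 --n-traces 200 --seed 0 --out runs/apo
polypull synthesize --params apo --speeds 100,1000,4000 --n-traces 50 --out runs/synth
polypull analyze runs/synth --out runs/report.json
polypull landscape runs/speeds.csv
polypull itc --simulate --out runs/gram.csv && polypull itc runs/gram.csv
```

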