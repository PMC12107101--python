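# mantchase

Simulation and analysis tools for **mantATP chasing experiments** on skinned
muscle fibers — the fluorescence-decay assay used to quantify the resting
biochemical states of myosin: the slow-turnover **super-relaxed state (SRX)**
and its faster counterpart, the **disordered relaxed state (DRX)**.

In a chase, a permeabilized fiber is equilibrated in 250 µM mantATP (a
fluorescent ATP analogue), then switched to dark ATP; the decay of
fluorescence F(t)/F₀ encodes how fast each myosin population hydrolyzes and
releases its nucleotide.  In practice the decay also contains a large
*nonspecific* component (NSP): free mantATP diffusing out of the fiber plus
mantATP bound to non-myosin targets.  `mantchase` packages the computational
machinery needed to understand — and correct for — how that nonspecific
signal distorts SRX/DRX population estimates.

## What is in the box

- **`mantchase.montecarlo`** — stochastic simulation of a half-thick filament
  of 147 myosin dimers.  Heads interconvert between SRX and DRX
  (k<sub>SRX-DRX</sub>, k<sub>DRX-SRX</sub>) and hydrolyze bound mant
  nucleotide at h<sub>DRX</sub> = 0.05 s⁻¹ or h<sub>SRX</sub> = 0.005 s⁻¹,
  under five cooperativity hypotheses (M0 equilibrated, M0A frozen, M1
  two motor sets, M2 intradimer gating with a forbidden blocked-DRX/free-SRX
  configuration, M3 adding intermolecular SRX stabilization by a factor γ
  from the neighboring dimer toward the M-line).  Exact event-driven
  (Gillespie) and fixed-step backends.
- **`mantchase.fiber`** — deterministic reaction–diffusion model of the whole
  fiber: nine concentric 4-µm shells (72 µm diameter) plus bath annuli,
  radial diffusion of mantATP/ATP (D = 600 µm² s⁻¹ in solution, one fifth
  inside the fiber), mass-action nonspecific binding
  d[SmATP]/dt = k_ON·[mATP]ⁿ·[S] − k_OFF·[SmATP]
  (k_ON = 10⁷ M⁻¹s⁻¹, K_A = 5.6·10⁴ M⁻¹), and a 105 µM myosin pool split
  between SRX and DRX turnover times (defaults 200 s / 20 s) with ATP
  competing for empty heads.  Includes the myosin-extracted ("ghost") fiber
  used to calibrate the nonspecific signal.
- **`mantchase.fitting`** — the three population-estimation methods used in
  the field, as bounded multi-start least squares:
  1. `two_exp`: F/F₀ = 1 − P_SRX(1 − e^(−t/T_SRX)) − P_DRX(1 − e^(−t/T_DRX))
  2. `three_exp`: adds − P_NSP(1 − e^(−t/T_NSP)); relative populations from
     SRX = P_SRX/(P_SRX + P_DRX)
  3. `three_exp_nsp`: the same fit, with populations corrected by an
     independent NSP estimate: SRX = P_SRX/(1 − NSP), DRX = 1 − SRX
  plus the reconciliation of chasing-derived turnover
  (P_DRX/T_DRX + P_SRX/T_SRX) with a measured ATPase rate,
  error % = 100·(estimated − measured)/estimated.
- **`mantchase.experiments`** — synthetic-trace generation (2-s cadence,
  800 s, like the acquisition), population scans (relative SRX scanned at
  fixed NSP and vice versa), the crossover point where the NSP-corrected
  method beats the plain three-exponential fit, and Table-style rate
  reconciliation reports.
- **`mantchase.cli`** — `mantchase simulate-mc | simulate-fiber |
  simulate-ghost | make-synthetic | fit | scan | reconcile`, reading YAML/JSON
  configs and writing CSV/JSON plus a reproducibility manifest.

## Worked example

Fit a noisy synthetic chase trace built from the schematic decomposition
(NSP 50% at 3 s, DRX and SRX 25% each at 20 s and 200 s), then derive
populations both ways and reconcile the implied turnover rate:

```python
import mantchase as mc

trace = mc.make_synthetic_trace(p_nsp=0.5, t_nsp=3.0, p_drx=0.25, t_drx=20.0,
                                p_srx=0.25, t_srx=200.0, noise_sd=0.005, seed=42)
fit = mc.fit_three_exp(trace)
rel2 = mc.relative_from_fit(fit)                       # method 2
rel3 = mc.relative_with_nsp(fit, mc.NspEstimate(0.60)) # method 3
rate = mc.estimate_rate(rel2.drx_rel, fit.t_drx, rel2.srx_rel, fit.t_srx)
```

This prints (formatted):

```
P_NSP = 0.512  T_NSP =  3.05 s
P_DRX = 0.238  T_DRX = 20.95 s
P_SRX = 0.249  T_SRX = 198.0 s
method 2 relative SRX = 51.1%
method 3 relative SRX = 62.3%
estimated turnover rate = 0.0259 1/s
error vs a measured 0.0208 1/s: +19.8%
```

All six generator parameters are recovered to a few percent at this noise
level.  Method 2's relative SRX (51.1%) is the amplitude ratio; method 3
trusts the independent 60% NSP estimate instead, so it assigns everything
outside NSP to myosin (62.3% here — on a *closed-form* trace whose
amplitudes already sum to one, method 2 is the consistent choice; the two
methods genuinely diverge on reaction–diffusion decays, where part of the
nonspecific signal masquerades as DRX).

The same scan that quantifies this distortion runs from the shell:

```bash
mantchase scan --variable srx_rel --nsp 0.6 --source fiber_rd --out out/
```

which writes a tidy per-grid-point/per-method table (`scan.csv`) and a
crossover report (`crossover.json`).

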