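# Methods

This note documents the models implemented in `mantchase`, the defaults and
their rationale, the numerical choices, and what the synthetic benchmarks do
and do not establish about real chasing data.

## 1. Thick-filament Monte-Carlo model (`mantchase.montecarlo`)

A half-thick filament carries `n_dimers` = 147 myosin dimers (294 heads).
Heads are indexed 1..294; odd indices are the *free* heads and even indices
the *blocked* heads of the interacting-heads-motif dimer.  Each head is in
one of two resting biochemical states — SRX or DRX — and hydrolyzes its bound
fluorescent nucleotide at

| parameter | meaning | default | unit |
|---|---|---|---|
| `h_drx` | DRX mantATPase rate | 0.05 | s⁻¹ |
| `h_srx` | SRX mantATPase rate | 0.005 | s⁻¹ |
| `k_sd`, `k_ds` | SRX→DRX / DRX→SRX interconversion | 0.01 | s⁻¹ |
| `gamma` | intermolecular SRX stabilization (M3) | 5 | – |
| `dt` | fixed-step size | 0.01 | s |

During a chase the bath contains a large excess of dark ATP, so a hydrolyzed
head never reloads fluorescent nucleotide: hydrolysis is modeled as permanent
signal loss, with mantADP-release kinetics lumped into the hydrolysis rate.
The ensemble-mean loaded fraction, sampled every 2 s and normalized to t = 0,
is the simulated decay.

The five cooperativity hypotheses:

- **M0** — all heads share `k_sd`/`k_ds` (thermodynamic equilibrium, no
  coupling).
- **M0A** — no interconversion at all; populations frozen at an imposed
  initial SRX fraction.  The decay is exactly the two-exponential mixture of
  the imposed amplitudes, which makes M0A the closed-form oracle for the
  fitting round-trip benchmarks.
- **M1** — two motor sets with different state stabilities; defaults are two
  equal sets with (`k_sd`, `k_ds`) = (0.05, 0.005) and (0.005, 0.05) s⁻¹, each
  strongly biased to one state.  Changing set-internal stabilities moves the
  fitted time constants but the fitted amplitudes track the set sizes.
- **M2** — intradimer gating: a blocked SRX head may switch to DRX only if
  its free head is already DRX, and a free DRX head may switch to SRX only if
  its blocked head is already SRX.  The configuration (blocked DRX, free SRX)
  is therefore unreachable, and both backends preserve that invariant
  exactly.
- **M3** — M2 plus intermolecular coupling: the free head of dimer *i* has
  its SRX state stabilized (`k_sd`/γ, `k_ds`·γ) whenever dimer *i − 1* holds
  at least one SRX head.  Dimer 1 is taken nearest the M-line and has no
  upstream neighbor; the indexing direction is a convention, since the model
  is statistically homogeneous along the filament.

**Defaults that are genuinely open.**  The interconversion rates and γ are
not fixed by the measurements this model abstracts; `k_sd = k_ds = 0.01 s⁻¹`
puts equal stationary occupancy and an interconversion timescale (100 s)
between the two hydrolysis timescales (20 s and 200 s), and γ = 5 is a strong
but finite bias.  Both are plain configuration fields.  Note that with
interconversion this slow, the equilibrated model M0 is only approximately
single-exponential: its survival function is a phase-type mixture whose best
single-exponential time constant (≈ 55 s) lies strictly between the two
hydrolysis timescales, and the collapse to a true single exponential sharpens
as `k_sd`, `k_ds` grow.

**Backends.**  The reference backend is an exact event-driven (Gillespie)
simulation of the whole filament with all per-head rates re-evaluated after
every event, so the cooperative couplings are honored without time-step
error.  A fixed-step backend tests every head once per step (transition with
probability k·dt, then hydrolysis with the post-transition rate), requires
dt·max(rate) < 0.01, and ships with a dt-halving convergence helper.  Its one
subtlety: a synchronous step can flip both heads of a dimer at once into the
forbidden M2/M3 configuration with probability O((k·dt)²); such double flips
are resolved by reverting the free head.  The event-driven backend is
order-free and the two agree within Monte-Carlo error.

**Initialization.**  Pre-chase, every head is nucleotide-loaded (saturating
mantATP).  Biochemical states are drawn by burning in the transition-only
dynamics for 10/min(positive rate) from an all-SRX start (a configuration
every model allows); M0A assigns its imposed fraction exactly.

**Reproducibility.**  One root seed spawns per-repeat child streams
(`numpy.random.SeedSequence`), so ensembles are bit-reproducible; the
vectorized fixed-step chase uses one dedicated child stream for its hot loop.

## 2. Fiber reaction–diffusion model (`mantchase.fiber`)

The fiber is a radially symmetric cylinder: nine concentric shells of 4 µm
(72 µm diameter), surrounded by `n_bath_shells` = 3 well-mixed bath annuli
with the outermost clamped to the well composition (chase: 0 mantATP, 4 mM
ATP).  The bath annuli approximate the unstirred layer around the fiber
without free parameters.  Free mantATP and ATP diffuse by a conservative
finite-volume scheme (interface diffusivity = distance-weighted harmonic
mean; D = 600 µm² s⁻¹ in solution, D/5 inside the fiber); bound species do
not move.

Reactions inside the fiber (concentrations µM, rates converted from molar):

- nonspecific sites: d[SmATP]/dt = k_ON·[mATP]ⁿ·[S] − k_OFF·[SmATP] with
  k_ON = 10⁷ M⁻¹s⁻¹, k_OFF = k_ON/K_A, K_A = 5.6·10⁴ M⁻¹, n = 1 (the
  cooperativity exponent is configurable), site total `s_tot_nsp` = 200 µM by
  default — the one nonspecific parameter that is *not* experimentally
  pinned; see §5;
- myosin (105 µM of heads, fraction `f_srx` in SRX): empty heads bind free
  mant at `k_on_mant_myo` = 10⁶ M⁻¹s⁻¹ (pseudo-first-order 250 s⁻¹ at the
  loading concentration, so heads start saturated) and lose bound mant at
  1/T_SRX or 1/T_DRX (hydrolysis + release, returned to the free pool); ATP
  competes for empty heads with on- and off-rates 10× those of mantATP.

At t = 0 the fiber is in binding equilibrium against 250 µM free mantATP
(nonspecific occupancy K_A·C/(1 + K_A·C) = 0.9333) and the bath is switched
to the chase composition.  The fluorescence observable is the
volume-weighted mant content of the fiber: every species at weight 1
(`amount` mode) or with myosin-bound mant up-weighted by the ~10-fold
binding enhancement (`weighted` mode).  Both observables are exposed because
the bound-enhancement is real but the raw amount is the cleaner model
quantity; results that depend on the choice are reported under both.

**Integration.**  The production integrator is LSODA on the full coupled
reaction–diffusion system (84 states).  The kinetics are stiff — the
nonspecific pseudo-rates reach ~2.5·10³ s⁻¹ at the loading concentration and
ATP binding ~4·10⁴ s⁻¹ during the chase — so an explicit operator-split
integrator at the diffusion-limited step is not viable for the full model;
the explicit finite-volume step is retained (with a stability check) for
pure-diffusion and conservation tests.  Tolerances default to rtol 10⁻⁸ /
atol 10⁻¹⁰.  Structural properties: sealed boundaries conserve total
nucleotide to better than 10⁻⁸ relative; a uniformly loaded cylinder with an
absorbing surface reproduces the analytic Bessel-series efflux
Σ (4/α_k²)·e^(−D α_k² t/R²) to 0.02% on a refined grid and to ~0.9% on the
default nine-shell grid.

**Imposing signal fractions.**  The in-silico scans fix the t = 0 signal
fractions rather than concentrations: NSP (free intra-fiber mant plus
nonspecifically bound mant) as a fraction of F₀, and the relative SRX share
of the myosin-bound signal.  The SRX share is met exactly by solving the
pool split for the (slightly state-dependent) head occupancies.  The NSP
share needs one more degree of freedom, and the two observables use
different ones: in `amount` mode the site total stays at its configured
value and the myosin fluorescence weight is solved (a raw-amount observable
cannot reach NSP = 60% by site scaling — free mantATP alone is already 70%
of the unweighted signal); in `weighted` mode the myosin weight stays at the
physical enhancement (10) and the site total is solved (≈ 1.4 mM at
NSP = 60%).  Both constructions hold the imposed fractions exactly at t = 0
and correspond to different free/bound mixes inside the nonspecific pool —
which is precisely the quantity the available measurements leave open.

## 3. Decay fitting (`mantchase.fitting`)

All three methods are bounded trust-region least squares
(`scipy.optimize.least_squares`) on the stated functional forms, with eight
multi-starts over log-spaced time-constant guesses around (3, 20, 200) s,
amplitudes bounded to [0, 1], and components relabeled by sorting time
constants after convergence (T_NSP < T_DRX < T_SRX), which removes label
switching.  The t = 0 sample is included; the forms force F(0)/F₀ = 1.

The amplitude-sum constraint ΣP ≤ 1 is enforced by a penalty residual that
engages only beyond a 5·10⁻³ slack.  A hard penalty at exactly 1 one-sidedly
squeezes fits whose true amplitudes sum to 1 (the fully decaying case),
biasing every parameter; with the slack the recovery study in the test suite
is unbiased and the overshoot stays within the noise floor.

Diagnostics carried on every fit: residual sum of squares, convergence flag,
Jacobian-based standard errors, and identifiability flags — relative
standard error above 50%, amplitudes below 10⁻⁴ (their time constants are
meaningless), near-coincident time constants (within 5%, where the amplitude
split is arbitrary), and sampling intervals too coarse to resolve the
nonspecific guess.  Failures are flagged, never silent.

Population derivation follows the three conventions exactly; the
NSP-corrected method clips P_SRX marginally above 1 − NSP (flagged) and
raises beyond a 5% tolerance.  Rate reconciliation uses per-trace
contributions P/T averaged across traces (mean ± SEM) — the per-fiber
convention, which is why aggregated contributions differ from the ratio of
the aggregated means — and the percent error convention
100·(estimated − measured)/estimated.

## 4. Synthetic data and what the benchmarks show

The closed-form generator evaluates the three-component model on the
acquisition grid (every 2 s for 800 s), optionally adds i.i.d. Gaussian
noise (σ = 0.005 in the recovery studies, a realistic normalized-camera
noise scale), and renormalizes to the first frame exactly as an experiment
is normalized.  It emulates the *kinetic* content of a chase: it does not
model photobleaching, baseline drift, motion artifacts, correlated camera
noise, or fiber-to-fiber parameter variability.  Passing the recovery
benchmarks therefore shows the fitting pipeline is correct and well
calibrated on its own model class — not that three exponentials are the true
model of a fiber, which is exactly the question the reaction–diffusion scans
address.

Scan defaults are the study conditions: relative SRX scanned 5–95% in 5%
steps at NSP fixed to 60% (the ghost-fiber calibration value), NSP scanned
20–80% in 10% steps at relative SRX 50%, T_DRX = 20 s, T_SRX = 200 s,
noise-free decays (scan curves are smooth; a seeded noisy replicate mode
exists).  Scans are deterministic given the spec and seed.

## 5. Known limitations

- **The nonspecific site concentration dominates the quantitative scan
  results and is not pinned by the available measurements.**  The fitted
  nonspecific kinetics (k_ON, K_A) come from ghost-fiber decays, but the site
  total `s_tot_nsp` does not; 200 µM is a stand-in.  Its value sets how much
  of the nonspecific signal decays slowly (the buffered tail has an
  effective time constant near T_DRX, which is why the plain three-exp fit
  over-assigns signal to DRX).  The crossover where the NSP-corrected method
  overtakes the plain fit moves by tens of percentage points across
  plausible site concentrations, and the two fluorescence observables differ
  in the same way; `scripts/acceptance.py` reports the value computed at the
  defaults (amount mode), which should be read with that sensitivity in
  mind.
- Only biochemical-state kinetics are modeled: no mechanics, cross-bridge
  cycling, calcium activation, or structural (IHM-orientation) layer in the
  filament model; no 3D or sarcomere-scale (A-band/I-band) structure, no
  photobleaching, and no SERCA or other ATPase kinetics in the fiber model.
- mantADP released by myosin is lumped with mantATP into one diffusible
  fluorescent species (it may rebind, though 4 mM dark ATP outcompetes it
  during the chase); sequential ADP-release states are not modeled.
- The event-driven backend recomputes all per-head rates after each event;
  at 147 dimers this is fast, but very large filaments would want
  incremental rate updates.
- Test-suite and acceptance problem sizes (ensembles of 100–300 filaments,
  400-point traces, 19-point scans) were chosen so the full statistical
  checks complete in a few minutes; all are plain parameters.
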