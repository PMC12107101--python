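"""Stochastic simulation of mantATP turnover in a half-thick filament.

The filament carries ``n_dimers`` myosin dimers (294 heads at the default
147).  Heads are indexed 1..2*n_dimers with odd indices the free heads and
even indices the blocked heads of each interacting-heads-motif dimer.  Every
head is in one of two resting biochemical states, SRX (slow nucleotide
turnover) or DRX (fast turnover), hydrolyzing its bound fluorescent
nucleotide at ``h_srx`` or ``h_drx`` per second.  During a chase the excess
dark ATP prevents fluorescent rebinding, so a hydrolyzed head goes dark
permanently and the ensemble-mean loaded fraction is the simulated decay.

Five cooperativity hypotheses are supported:

``M0``
    No cooperativity: every head interconverts with the same ``k_sd``
    (SRX->DRX) and ``k_ds`` (DRX->SRX) rates (thermodynamic equilibrium).
``M0A``
    Frozen populations: no interconversion at all; each head stays in the
    state assigned at t = 0 (``initial_srx_fraction``).
``M1``
    Two motor sets with different state stabilities: a fraction
    ``set_split`` of dimers uses (``k_sd``, ``k_ds``), the rest uses
    (``k_sd_b``, ``k_ds_b``).  No coupling between heads.
``M2``
    Intradimer cooperativity: a blocked SRX head cannot switch to DRX unless
    its free head is already DRX, and a free DRX head cannot switch to SRX
    unless its blocked head is already SRX, so the configuration
    (blocked DRX, free SRX) is forbidden.
``M3``
    M2 plus intermolecular cooperativity: the free head of dimer i has its
    SRX state stabilized by a factor ``gamma`` (k_sd/gamma, k_ds*gamma)
    whenever the adjacent dimer toward the M-line (dimer i-1, dimer 1 being
    nearest the M-line) has at least one SRX head.

Two backends produce ensemble decay traces: an exact event-driven
(Gillespie) simulation with rate re-evaluation after every event, and a
fixed-step scheme in which each head is tested once per step for a state
transition (probability k_eff*dt) and then, if still nucleotide-loaded, for
hydrolysis (probability h*dt with the post-transition rate).
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .trace import DecayTrace

__all__ = [
    "MODELS",
    "McParams",
    "FilamentState",
    "stationary_srx_fraction",
    "init_filament",
    "effective_rates",
    "effective_rate_arrays",
    "step",
    "simulate_chase",
    "fixed_step_converged_trace",
]

MODELS = ("M0", "M0A", "M1", "M2", "M3")

ModelId = Literal["M0", "M0A", "M1", "M2", "M3"]


class ConfigurationError(ValueError):
    """Invalid or inconsistent simulation parameters."""


@dataclass
class McParams:
    """Kinetic parameters of the filament Monte-Carlo model.

    Rates are per second.  ``dt`` only constrains the fixed-step backend,
    which requires ``dt * max(rate) < 0.01`` so per-step probabilities stay
    in the linear regime.
    """

    model_id: ModelId = "M0"
    h_drx: float = 0.05
    h_srx: float = 0.005
    k_sd: float = 0.01
    k_ds: float = 0.01
    gamma: float = 5.0
    n_dimers: int = 147
    dt: float = 0.01
    set_split: float = 0.5
    k_sd_b: float | None = None
    k_ds_b: float | None = None
    initial_srx_fraction: float | None = None
    n_repeats: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODELS:
            raise ConfigurationError(f"unknown model_id {self.model_id!r}; expected one of {MODELS}")
        if self.model_id == "M0A":
            # frozen populations: no interconversion by definition
            self.k_sd = 0.0
            self.k_ds = 0.0
            if self.initial_srx_fraction is None:
                raise ConfigurationError("model M0A requires initial_srx_fraction")
            if not 0.0 <= self.initial_srx_fraction <= 1.0:
                raise ConfigurationError("initial_srx_fraction must be in [0, 1]")
        if self.model_id == "M1":
            if self.k_sd_b is None or self.k_ds_b is None:
                raise ConfigurationError("model M1 requires k_sd_b and k_ds_b for the second motor set")
            if not 0.0 < self.set_split < 1.0:
                raise ConfigurationError("set_split must be in (0, 1) for model M1")
        for name in ("h_drx", "h_srx", "k_sd", "k_ds"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.k_sd_b is not None and self.k_sd_b < 0:
            raise ConfigurationError("k_sd_b must be >= 0")
        if self.k_ds_b is not None and self.k_ds_b < 0:
            raise ConfigurationError("k_ds_b must be >= 0")
        if self.gamma < 1.0:
            raise ConfigurationError("gamma must be >= 1")
        if self.n_dimers < 1:
            raise ConfigurationError("n_dimers must be >= 1")
        if self.n_repeats < 1:
            raise ConfigurationError("n_repeats must be >= 1")
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")

    @classmethod
    def for_model(cls, model_id: ModelId, **overrides) -> "McParams":
        """Parameters with the per-model defaults.

        M1 defaults to two equal-size sets strongly biased to opposite
        states ((0.05, 0.005) and (0.005, 0.05)); M0A defaults to a 50/50
        initial split.
        """
        defaults: dict = {}
        if model_id == "M1":
            defaults.update(k_sd=0.05, k_ds=0.005, k_sd_b=0.005, k_ds_b=0.05)
        elif model_id == "M0A":
            defaults.update(initial_srx_fraction=0.5)
        defaults.update(overrides)
        return cls(model_id=model_id, **defaults)

    @property
    def n_heads(self) -> int:
        return 2 * self.n_dimers

    @property
    def max_rate(self) -> float:
        rates = [self.h_drx, self.h_srx, self.k_sd, self.k_ds]
        if self.k_sd_b is not None:
            rates.append(self.k_sd_b)
        if self.k_ds_b is not None:
            rates.append(self.k_ds_b)
        if self.model_id == "M3":
            rates.append(self.k_ds * self.gamma)
            if self.k_ds_b is not None:
                rates.append(self.k_ds_b * self.gamma)
        return max(rates)

    def validate_fixed_step(self) -> None:
        if self.dt * self.max_rate >= 0.01:
            raise ConfigurationError(
                f"fixed-step backend requires dt*max_rate < 0.01 "
                f"(got {self.dt * self.max_rate:.3g}); reduce dt or use the event backend"
            )


@dataclass
class FilamentState:
    """Biochemical state of one filament.

    ``srx`` and ``loaded`` are boolean arrays over heads in index order
    (0-based array position j holds head j+1, so even positions are free
    heads and odd positions are blocked heads).  Dimer i (0-based, dimer 0
    nearest the M-line) is the head pair (2i, 2i+1).
    """

    srx: np.ndarray
    loaded: np.ndarray

    def __post_init__(self) -> None:
        self.srx = np.asarray(self.srx, dtype=bool)
        self.loaded = np.asarray(self.loaded, dtype=bool)
        if self.srx.shape != self.loaded.shape or self.srx.ndim != 1:
            raise ValueError("srx and loaded must be 1-D arrays of equal length")
        if self.srx.size % 2:
            raise ValueError("head count must be even (dimers)")

    @property
    def n_dimers(self) -> int:
        return self.srx.size // 2

    @property
    def free_srx(self) -> np.ndarray:
        return self.srx[0::2]

    @property
    def blocked_srx(self) -> np.ndarray:
        return self.srx[1::2]

    def forbidden_dimers(self) -> np.ndarray:
        """Mask of dimers in the (blocked DRX, free SRX) configuration."""
        return self.free_srx & ~self.blocked_srx

    def copy(self) -> "FilamentState":
        return FilamentState(self.srx.copy(), self.loaded.copy())


def stationary_srx_fraction(k_sd: float, k_ds: float) -> float:
    """Equilibrium SRX occupancy of an isolated two-state head.

    For a head hopping SRX -> DRX at ``k_sd`` and DRX -> SRX at ``k_ds``,
    the stationary SRX probability is ``k_ds / (k_sd + k_ds)``.
    """
    if k_sd < 0 or k_ds < 0:
        raise ValueError("rates must be >= 0")
    total = k_sd + k_ds
    if total == 0:
        raise ZeroDivisionError("undefined equilibrium: both interconversion rates are zero")
    return k_ds / total


def _set_a_mask(params: McParams, n_dimers: int) -> np.ndarray:
    """Per-head mask: True where the head belongs to motor set A (model M1)."""
    n_a = int(round(params.set_split * n_dimers))
    dimer_in_a = np.arange(n_dimers) < n_a
    return np.repeat(dimer_in_a, 2)


def _base_rates(params: McParams, n_heads: int) -> tuple[np.ndarray, np.ndarray]:
    if params.model_id == "M1":
        in_a = _set_a_mask(params, n_heads // 2)
        k_sd = np.where(in_a, params.k_sd, params.k_sd_b)
        k_ds = np.where(in_a, params.k_ds, params.k_ds_b)
        return k_sd.astype(float), k_ds.astype(float)
    return np.full(n_heads, params.k_sd), np.full(n_heads, params.k_ds)


def effective_rate_arrays(srx: np.ndarray, params: McParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-head effective (k_sd_eff, k_ds_eff) given the filament configuration.

    ``srx`` may be 1-D (heads) or 2-D (repeats, heads); cooperative rules act
    along the last axis.  Rates are sized from the state, so a filament
    smaller than ``params.n_dimers`` is handled consistently.
    """
    base_sd, base_ds = _base_rates(params, srx.shape[-1])
    k_sd = np.broadcast_to(base_sd, srx.shape).copy()
    k_ds = np.broadcast_to(base_ds, srx.shape).copy()
    if params.model_id not in ("M2", "M3"):
        return k_sd, k_ds

    free = srx[..., 0::2]
    blocked = srx[..., 1::2]

    if params.model_id == "M3" and params.gamma != 1.0:
        # SRX stabilization of the free head when the neighbor dimer toward
        # the M-line (i-1) holds at least one SRX head; dimer 0 has no neighbor.
        neigh_srx = free | blocked
        stabilized = np.zeros_like(free)
        stabilized[..., 1:] = neigh_srx[..., :-1]
        k_sd_free = k_sd[..., 0::2]
        k_ds_free = k_ds[..., 0::2]
        k_sd[..., 0::2] = np.where(stabilized, k_sd_free / params.gamma, k_sd_free)
        k_ds[..., 0::2] = np.where(stabilized, k_ds_free * params.gamma, k_ds_free)

    # Intradimer gating: forbid creating (blocked DRX, free SRX).
    k_sd[..., 1::2] = np.where(free, 0.0, k_sd[..., 1::2])     # blocked SRX->DRX needs free DRX
    k_ds[..., 0::2] = np.where(blocked, k_ds[..., 0::2], 0.0)  # free DRX->SRX needs blocked SRX
    return k_sd, k_ds


def effective_rates(
    dimer_index: int,
    head_role: Literal["blocked", "free"],
    filament: FilamentState,
    params: McParams,
) -> tuple[float, float]:
    """Effective transition rates of one head in the current configuration."""
    if not 0 <= dimer_index < filament.n_dimers:
        raise IndexError(f"dimer_index {dimer_index} out of range")
    if head_role not in ("blocked", "free"):
        raise ValueError("head_role must be 'blocked' or 'free'")
    k_sd, k_ds = effective_rate_arrays(filament.srx, params)
    j = 2 * dimer_index + (1 if head_role == "blocked" else 0)
    return float(k_sd[j]), float(k_ds[j])


def _transition_rate_per_head(srx: np.ndarray, params: McParams) -> np.ndarray:
    k_sd, k_ds = effective_rate_arrays(srx, params)
    return np.where(srx, k_sd, k_ds)


def _hydrolysis_rate_per_head(srx: np.ndarray, loaded: np.ndarray, params: McParams) -> np.ndarray:
    return np.where(loaded, np.where(srx, params.h_srx, params.h_drx), 0.0)


def init_filament(params: McParams, rng: np.random.Generator) -> FilamentState:
    """Pre-chase filament: every head mant-loaded, states equilibrated.

    For M0A the configured ``initial_srx_fraction`` is assigned exactly
    (rounded head count, random placement).  All other models start all-SRX
    (a configuration every model allows) and burn in with transition-only
    dynamics for at least 10 / min(positive interconversion rate).
    """
    n = params.n_heads
    loaded = np.ones(n, dtype=bool)
    if params.model_id == "M0A":
        n_srx = int(round(params.initial_srx_fraction * n))
        srx = np.zeros(n, dtype=bool)
        srx[rng.permutation(n)[:n_srx]] = True
        return FilamentState(srx, loaded)

    rates = [r for r in (params.k_sd, params.k_ds, params.k_sd_b, params.k_ds_b) if r]
    if not rates:
        raise ConfigurationError(
            "no positive interconversion rate to equilibrate; use M0A with initial_srx_fraction"
        )
    t_burn = 10.0 / min(rates)
    state = FilamentState(np.ones(n, dtype=bool), loaded)
    _gillespie(state, params, rng, duration=t_burn, hydrolysis=False)
    return state


def step(filament: FilamentState, params: McParams, rng: np.random.Generator) -> FilamentState:
    """One fixed-step update of every head (transition then hydrolysis)."""
    params.validate_fixed_step()
    srx = filament.srx[np.newaxis, :].copy()
    loaded = filament.loaded[np.newaxis, :].copy()
    _fixed_step_inplace(srx, loaded, params, rng)
    return FilamentState(srx[0], loaded[0])


def _fixed_step_inplace(
    srx: np.ndarray, loaded: np.ndarray, params: McParams, rng: np.random.Generator
) -> None:
    """Advance (repeats, heads) state arrays by one dt, in place."""
    dt = params.dt
    k = _transition_rate_per_head(srx, params)
    flip = rng.random(srx.shape) < k * dt
    old_free_srx = srx[..., 0::2].copy()
    srx ^= flip
    if params.model_id in ("M2", "M3"):
        # A synchronous double flip within a dimer can land in the forbidden
        # configuration; revert the free head there (O((k dt)^2) tie-break,
        # absent by construction in the event-driven backend).
        bad = srx[..., 0::2] & ~srx[..., 1::2]
        srx[..., 0::2] = np.where(bad, old_free_srx, srx[..., 0::2])
    h = np.where(srx, params.h_srx, params.h_drx)
    hydro = loaded & (rng.random(srx.shape) < h * dt)
    loaded &= ~hydro


def _gillespie(
    state: FilamentState,
    params: McParams,
    rng: np.random.Generator,
    duration: float,
    hydrolysis: bool = True,
    sample_times: np.ndarray | None = None,
) -> np.ndarray | None:
    """Exact event-driven simulation of one filament, in place.

    With ``sample_times`` given, returns the loaded-head count at each
    sample time; rates are re-evaluated after every event so cooperative
    couplings are honored exactly.
    """
    srx, loaded = state.srx, state.loaded
    t = 0.0
    out = None
    i_sample = 0
    if sample_times is not None:
        out = np.empty(sample_times.size, dtype=np.int64)

    while True:
        trans = _transition_rate_per_head(srx, params)
        hyd = (
            _hydrolysis_rate_per_head(srx, loaded, params)
            if hydrolysis
            else np.zeros_like(trans)
        )
        r_trans = trans.sum()
        r_total = r_trans + hyd.sum()
        if r_total <= 0.0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / r_total)
        if sample_times is not None:
            while i_sample < sample_times.size and sample_times[i_sample] < min(t_next, duration) + 1e-12:
                out[i_sample] = int(loaded.sum())
                i_sample += 1
        if t_next >= duration:
            break
        t = t_next
        u = rng.random() * r_total
        if u < r_trans:
            j = int(np.searchsorted(np.cumsum(trans), u, side="right"))
            j = min(j, srx.size - 1)
            srx[j] = ~srx[j]
        else:
            u -= r_trans
            j = int(np.searchsorted(np.cumsum(hyd), u, side="right"))
            j = min(j, srx.size - 1)
            loaded[j] = False
    return out


def _sample_grid(duration: float, sample_dt: float) -> np.ndarray:
    n = int(np.floor(duration / sample_dt + 1e-9)) + 1
    return np.arange(n) * sample_dt


def simulate_chase(
    params: McParams,
    duration: float = 800.0,
    sample_dt: float = 2.0,
    backend: Literal["event", "fixed"] = "event",
) -> DecayTrace:
    """Ensemble-mean fraction of still-loaded heads during a chase.

    Each of ``params.n_repeats`` filaments is equilibrated (burn-in), fully
    loaded, then chased for ``duration`` seconds; the trace is the ensemble
    mean sampled every ``sample_dt`` and normalized to 1 at t = 0.  The
    ensemble standard error per sample is stored in ``meta['se']``.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be > 0")
    times = _sample_grid(duration, sample_dt)
    ss = np.random.SeedSequence(params.seed)
    children = ss.spawn(params.n_repeats)
    n = params.n_heads

    if backend == "event":
        counts = np.empty((params.n_repeats, times.size))
        for r, child in enumerate(children):
            rng = np.random.default_rng(child)
            state = init_filament(params, rng)
            counts[r] = _gillespie(state, params, rng, duration, sample_times=times)
        frac = counts / n
    elif backend == "fixed":
        params.validate_fixed_step()
        srx = np.empty((params.n_repeats, n), dtype=bool)
        loaded = np.ones((params.n_repeats, n), dtype=bool)
        rngs = [np.random.default_rng(c) for c in children]
        for r, rng in enumerate(rngs):
            srx[r] = init_filament(params, rng).srx
        # one shared stream for the chase keeps the hot loop vectorized
        chase_rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(params.n_repeats + 1)[-1])
        n_steps = int(round(duration / params.dt))
        stride = max(1, int(round(sample_dt / params.dt)))
        frac = np.empty((params.n_repeats, times.size))
        frac[:, 0] = loaded.mean(axis=1)
        i_sample = 1
        for s in range(1, n_steps + 1):
            _fixed_step_inplace(srx, loaded, params, chase_rng)
            if s % stride == 0 and i_sample < times.size:
                frac[:, i_sample] = loaded.mean(axis=1)
                i_sample += 1
        frac = frac[:, :i_sample]
        times = times[:i_sample]
    else:
        raise ConfigurationError(f"unknown backend {backend!r}")

    mean = frac.mean(axis=0)
    se = frac.std(axis=0, ddof=1) / np.sqrt(params.n_repeats) if params.n_repeats > 1 else np.zeros_like(mean)
    values = mean / mean[0]
    meta = {
        "model": params.model_id,
        "backend": backend,
        "seed": params.seed,
        "n_repeats": params.n_repeats,
        "n_dimers": params.n_dimers,
        "se": se / mean[0],
    }
    return DecayTrace(times, values, meta)


def fixed_step_converged_trace(
    params: McParams,
    duration: float = 800.0,
    sample_dt: float = 2.0,
    tol: float = 0.01,
    max_halvings: int = 5,
) -> DecayTrace:
    """Fixed-step trace with dt halved until the sup-norm change is < tol."""
    p = params
    prev = simulate_chase(p, duration, sample_dt, backend="fixed")
    for _ in range(max_halvings):
        p = replace(p, dt=p.dt / 2)
        cur = simulate_chase(p, duration, sample_dt, backend="fixed")
        if np.max(np.abs(cur.values - prev.values)) < tol:
            cur.meta["dt_converged"] = p.dt
            return cur
        prev = cur
    raise RuntimeError(f"fixed-step trace did not converge within {max_halvings} dt halvings")
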