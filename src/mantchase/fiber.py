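"""Reaction-diffusion model of a mantATP chase in a skinned fiber.

The fiber is a radially symmetric cylinder discretized into concentric
annular shells (nine shells of 4 um at defaults, 72 um diameter), surrounded
by well-mixed bath annuli whose outermost cell is clamped to the composition
of the fresh well.  Free mantATP and ATP diffuse between shells (conservative
finite-volume fluxes, diffusivity D_fiber inside and D_sol outside); bound
species do not move.  Inside the fiber the nucleotides react with

* a nonspecific buffer of ``s_tot_nsp`` sites binding mantATP by mass action,
  d[SmATP]/dt = k_on [mATP]^n [S] - k_off [SmATP], with k_off = k_on / K_A;
* the myosin pool (``myosin_total``, split ``f_srx`` : 1 - f_srx between SRX
  and DRX heads).  Heads bind free mantATP at ``k_on_mant_myo`` and lose the
  bound nucleotide at 1/T_srx or 1/T_drx (hydrolysis + release, returned to
  the free pool, where during the chase the 4 mM dark ATP outcompetes any
  rebinding).  ATP competes for empty heads with both on- and off-rates
  scaled by ``atp_rate_factor``.

The fluorescence observable is the volume-weighted mant content of the fiber,
either raw (``amount`` mode) or with myosin-bound mant up-weighted by the
``enhancement`` factor (``weighted`` mode, ~10-fold brighter when bound).

Concentrations are in uM, lengths in um, times in s; bimolecular rate
constants are accepted in M^-1 s^-1 and converted internally.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .trace import DecayTrace

__all__ = [
    "FiberGeometry",
    "RdParams",
    "FiberState",
    "binding_rhs",
    "diffusion_step",
    "init_equilibrium",
    "simulate_chase",
    "simulate_ghost",
    "fluorescence",
    "fluorescence_components",
    "impose_signal_fractions",
]

M_TO_UM = 1e-6  # uM -> M conversion for rate constants given per molar


class ConfigurationError(ValueError):
    """Invalid or inconsistent fiber-model configuration."""


@dataclass(frozen=True)
class FiberGeometry:
    """Radial discretization of the fiber and its bath.

    ``n_shells`` annuli of thickness ``dr`` make up the fiber
    (radius = n_shells * dr); ``n_bath_shells`` additional annuli of
    thickness ``bath_dr`` (defaults to ``dr``) represent the surrounding
    solution, the outermost being clamped to the well composition when
    ``outer_bc == 'bath'``.  ``outer_bc`` may instead seal the boundary
    (zero flux) or make it absorbing (zero concentration at the surface),
    both only meaningful with ``n_bath_shells == 0``.
    """

    n_shells: int = 9
    dr: float = 4.0
    n_bath_shells: int = 3
    bath_dr: float | None = None
    outer_bc: Literal["bath", "sealed", "absorbing"] = "bath"

    def __post_init__(self) -> None:
        if self.n_shells < 1 or self.dr <= 0:
            raise ConfigurationError("need n_shells >= 1 and dr > 0")
        if self.outer_bc == "bath" and self.n_bath_shells < 1:
            raise ConfigurationError("outer_bc='bath' requires n_bath_shells >= 1")
        if self.outer_bc != "bath" and self.n_bath_shells != 0:
            raise ConfigurationError("sealed/absorbing boundaries apply to the fiber surface (n_bath_shells=0)")

    @property
    def fiber_radius(self) -> float:
        return self.n_shells * self.dr

    @property
    def n_cells(self) -> int:
        return self.n_shells + self.n_bath_shells

    @property
    def edges(self) -> np.ndarray:
        bdr = self.dr if self.bath_dr is None else self.bath_dr
        fiber = np.arange(self.n_shells + 1) * self.dr
        bath = self.fiber_radius + np.arange(1, self.n_bath_shells + 1) * bdr
        return np.concatenate([fiber, bath])

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def volumes(self) -> np.ndarray:
        """Cell volumes per unit fiber length (pi r_out^2 - pi r_in^2)."""
        e = self.edges
        return np.pi * (e[1:] ** 2 - e[:-1] ** 2)


@dataclass
class RdParams:
    """Physical parameters of the fiber reaction-diffusion model."""

    d_sol: float = 600.0                 # um^2/s, nucleotide diffusivity in solution
    d_fiber: float | None = None         # defaults to d_sol / 5
    myosin_total: float = 105.0          # uM of myosin heads in the fiber
    f_srx: float = 0.5                   # fraction of the myosin pool in SRX
    t_drx: float = 20.0                  # s, DRX nucleotide turnover time
    t_srx: float = 200.0                 # s, SRX nucleotide turnover time
    mant_free_0: float = 250.0           # uM free mantATP at equilibration
    atp_bath: float = 4000.0             # uM ATP clamped in the chase well (4 mM)
    k_on_nsp: float = 1e7                # M^-1 s^-1, nonspecific association
    k_a_nsp: float = 5.6e4               # M^-1, nonspecific association constant
    s_tot_nsp: float = 200.0             # uM of nonspecific sites
    n_coop: float = 1.0                  # cooperativity exponent of the nonspecific binding
    k_on_mant_myo: float = 1e6           # M^-1 s^-1, mant-myosin association
    atp_rate_factor: float = 10.0        # ATP on/off rates relative to mantATP
    enhancement: float = 10.0            # myosin-bound fluorescence weight (weighted mode)
    fluorescence_mode: Literal["amount", "weighted"] = "amount"
    w_myo: float | None = None           # explicit myosin weight override
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.d_fiber is None:
            self.d_fiber = self.d_sol / 5.0
        if self.d_sol <= 0 or self.d_fiber <= 0:
            raise ConfigurationError("diffusivities must be > 0")
        for name in ("myosin_total", "mant_free_0", "atp_bath", "s_tot_nsp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.f_srx <= 1.0:
            raise ConfigurationError("f_srx must be in [0, 1]")
        if self.t_drx <= 0 or self.t_srx <= 0:
            raise ConfigurationError("turnover times must be > 0")
        if self.enhancement < 1.0:
            raise ConfigurationError("enhancement must be >= 1")
        if self.fluorescence_mode not in ("amount", "weighted"):
            raise ConfigurationError(f"unknown fluorescence_mode {self.fluorescence_mode!r}")

    @property
    def k_off_nsp(self) -> float:
        return self.k_on_nsp / self.k_a_nsp

    @property
    def myosin_weight(self) -> float:
        if self.w_myo is not None:
            return self.w_myo
        return self.enhancement if self.fluorescence_mode == "weighted" else 1.0


@dataclass
class FiberState:
    """Per-cell concentrations (uM).

    Free species span fiber + bath cells; bound species exist only in the
    ``n_fiber`` fiber cells.
    """

    mant_free: np.ndarray
    atp_free: np.ndarray
    nsp_mant: np.ndarray
    drx_mant: np.ndarray
    srx_mant: np.ndarray
    drx_atp: np.ndarray
    srx_atp: np.ndarray

    _FREE = ("mant_free", "atp_free")
    _BOUND = ("nsp_mant", "drx_mant", "srx_mant", "drx_atp", "srx_atp")

    def __post_init__(self) -> None:
        for name in self._FREE + self._BOUND:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def n_fiber(self) -> int:
        return self.nsp_mant.size

    def copy(self) -> "FiberState":
        return FiberState(*(getattr(self, n).copy() for n in self._FREE + self._BOUND))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([getattr(self, n) for n in self._FREE + self._BOUND])

    @classmethod
    def from_vector(cls, vec: np.ndarray, n_cells: int, n_fiber: int) -> "FiberState":
        sizes = [n_cells, n_cells] + [n_fiber] * 5
        parts, start = [], 0
        for s in sizes:
            parts.append(vec[start : start + s])
            start += s
        return cls(*parts)

    def total_mant_moles(self, geom: FiberGeometry) -> float:
        """Total mant content (free + bound) over all cells, in uM*um^2."""
        v = geom.volumes
        nf = self.n_fiber
        total = float(np.sum(self.mant_free * v))
        total += float(np.sum((self.nsp_mant + self.drx_mant + self.srx_mant) * v[:nf]))
        return total


def _check_nonnegative(state: FiberState) -> None:
    for name in state._FREE + state._BOUND:
        if np.any(getattr(state, name) < -1e-12):
            raise ValueError(f"negative concentration in {name}")


def _binding_derivs(state: FiberState, params: RdParams) -> FiberState:
    """Mass-action reaction derivatives (no validation; used by integrators)."""
    nf = state.n_fiber
    mant = np.maximum(state.mant_free[:nf], 0.0)
    atp = np.maximum(state.atp_free[:nf], 0.0)

    # nonspecific buffer (mant only)
    s_free = params.s_tot_nsp - state.nsp_mant
    on_nsp = params.k_on_nsp * (mant * M_TO_UM) ** params.n_coop * s_free
    d_nsp = on_nsp - params.k_off_nsp * state.nsp_mant

    # myosin pools; empty heads are the pool total minus both bound species
    kon = params.k_on_mant_myo * M_TO_UM  # uM^-1 s^-1
    f_atp = params.atp_rate_factor
    m_drx = (1.0 - params.f_srx) * params.myosin_total
    m_srx = params.f_srx * params.myosin_total

    empty_d = m_drx - state.drx_mant - state.drx_atp
    empty_s = m_srx - state.srx_mant - state.srx_atp
    bind_md = kon * mant * empty_d
    bind_ms = kon * mant * empty_s
    rel_md = state.drx_mant / params.t_drx
    rel_ms = state.srx_mant / params.t_srx
    bind_ad = kon * f_atp * atp * empty_d
    bind_as = kon * f_atp * atp * empty_s
    rel_ad = f_atp * state.drx_atp / params.t_drx
    rel_as = f_atp * state.srx_atp / params.t_srx

    d_mant = np.zeros_like(state.mant_free)
    d_atp = np.zeros_like(state.atp_free)
    d_mant[:nf] = -(on_nsp - params.k_off_nsp * state.nsp_mant) - (bind_md + bind_ms) + (rel_md + rel_ms)
    d_atp[:nf] = -(bind_ad + bind_as) + (rel_ad + rel_as)
    return FiberState(
        d_mant,
        d_atp,
        d_nsp,
        bind_md - rel_md,
        bind_ms - rel_ms,
        bind_ad - rel_ad,
        bind_as - rel_as,
    )


def binding_rhs(state: FiberState, params: RdParams) -> FiberState:
    """Reaction (binding/turnover) derivatives for every species, per shell.

    Pure mass action; the returned derivatives conserve total mant and total
    ATP (bound + free) in every shell.
    """
    _check_nonnegative(state)
    return _binding_derivs(state, params)


def diffusion_matrix(geom: FiberGeometry, params: RdParams) -> np.ndarray:
    """Conservative finite-volume radial diffusion operator for free species.

    dc/dt = L @ c.  Interface diffusivity is the distance-weighted harmonic
    mean of the two cell diffusivities (D_fiber inside, D_sol in the bath).
    """
    n = geom.n_cells
    e = geom.edges
    c = geom.centers
    v = geom.volumes
    d_cell = np.where(np.arange(n) < geom.n_shells, params.d_fiber, params.d_sol)
    L = np.zeros((n, n))
    for i in range(n - 1):
        r_if = e[i + 1]
        h1 = r_if - c[i]
        h2 = c[i + 1] - r_if
        d_if = (h1 + h2) / (h1 / d_cell[i] + h2 / d_cell[i + 1])
        g = d_if * 2.0 * np.pi * r_if / (c[i + 1] - c[i])  # conductance per unit length
        L[i, i] -= g / v[i]
        L[i, i + 1] += g / v[i]
        L[i + 1, i + 1] -= g / v[i + 1]
        L[i + 1, i] += g / v[i + 1]
    if geom.outer_bc == "absorbing":
        # zero concentration at the fiber surface, half-cell distance
        g = d_cell[-1] * 2.0 * np.pi * e[-1] / (e[-1] - c[-1])
        L[-1, -1] -= g / v[-1]
    return L


def diffusion_step(state: FiberState, geom: FiberGeometry, params: RdParams, dt: float) -> FiberState:
    """One explicit finite-volume diffusion step of the free species.

    Bound species do not move.  Raises if ``dt`` violates the explicit
    stability bound; use a smaller step or the implicit (LSODA) integrator.
    """
    L = diffusion_matrix(geom, params)
    dt_max = 1.0 / np.max(-np.diag(L))
    if dt > dt_max:
        raise ValueError(
            f"explicit diffusion step unstable: dt={dt:g} exceeds {dt_max:g}; "
            "reduce dt or integrate with method='lsoda'"
        )
    new = state.copy()
    clamp = geom.n_cells - 1 if geom.outer_bc == "bath" else None
    for name in state._FREE:
        c = getattr(state, name)
        dc = L @ c
        if clamp is not None:
            dc[clamp] = 0.0
        setattr(new, name, c + dt * dc)
    return new


def init_equilibrium(params: RdParams, geom: FiberGeometry | None = None) -> FiberState:
    """Pre-chase state: free mantATP uniform at ``mant_free_0`` everywhere,
    nonspecific and myosin pools at their binding steady state, no ATP."""
    geom = geom or FiberGeometry()
    n, nf = geom.n_cells, geom.n_shells
    c0 = params.mant_free_0
    mant = np.full(n, c0)
    atp = np.zeros(n)

    occ_nsp = _nsp_occupancy(params, c0)
    kon = params.k_on_mant_myo * M_TO_UM
    occ_d = kon * c0 / (kon * c0 + 1.0 / params.t_drx) if c0 > 0 else 0.0
    occ_s = kon * c0 / (kon * c0 + 1.0 / params.t_srx) if c0 > 0 else 0.0
    m_drx = (1.0 - params.f_srx) * params.myosin_total
    m_srx = params.f_srx * params.myosin_total
    return FiberState(
        mant,
        atp,
        np.full(nf, occ_nsp * params.s_tot_nsp),
        np.full(nf, occ_d * m_drx),
        np.full(nf, occ_s * m_srx),
        np.zeros(nf),
        np.zeros(nf),
    )


def _nsp_occupancy(params: RdParams, conc_um: float) -> float:
    if conc_um <= 0:
        return 0.0
    on = params.k_on_nsp * (conc_um * M_TO_UM) ** params.n_coop
    return on / (on + params.k_off_nsp)


def fluorescence(state: FiberState, params: RdParams, geom: FiberGeometry | None = None) -> float:
    """Scalar fluorescence signal of the fiber interior.

    ``amount`` mode: volume-weighted sum of every mant species inside the
    fiber.  ``weighted`` mode: myosin-bound mant scaled by ``enhancement``
    (free and nonspecifically bound weigh 1).  An explicit ``w_myo`` on the
    parameters overrides either mode's myosin weight.
    """
    comps = fluorescence_components(state, params, geom)
    return comps["free"] + comps["nsp"] + comps["drx"] + comps["srx"]


def fluorescence_components(
    state: FiberState, params: RdParams, geom: FiberGeometry | None = None
) -> dict[str, float]:
    """The four signal components (free, nonspecific, DRX- and SRX-bound)."""
    geom = geom or FiberGeometry()
    v = geom.volumes
    nf = geom.n_shells
    w = params.myosin_weight
    return {
        "free": float(np.sum(state.mant_free[:nf] * v[:nf])),
        "nsp": float(np.sum(state.nsp_mant * v[:nf])),
        "drx": w * float(np.sum(state.drx_mant * v[:nf])),
        "srx": w * float(np.sum(state.srx_mant * v[:nf])),
    }


def _chase_initial_state(params: RdParams, geom: FiberGeometry) -> FiberState:
    state = init_equilibrium(params, geom)
    if geom.n_bath_shells:
        state.mant_free[geom.n_shells :] = 0.0
        state.atp_free[geom.n_shells :] = params.atp_bath
    return state


def _rhs(t, y, params: RdParams, geom: FiberGeometry, L: np.ndarray, clamp: int | None):
    state = FiberState.from_vector(y, geom.n_cells, geom.n_shells)
    d = _binding_derivs(state, params)
    d.mant_free += L @ state.mant_free
    d.atp_free += L @ state.atp_free
    if clamp is not None:
        d.mant_free[clamp] = 0.0
        d.atp_free[clamp] = 0.0
    return d.to_vector()


def _integrate(
    params: RdParams,
    geom: FiberGeometry,
    state0: FiberState,
    times: np.ndarray,
    method: str = "lsoda",
) -> np.ndarray:
    L = diffusion_matrix(geom, params)
    clamp = geom.n_cells - 1 if geom.outer_bc == "bath" else None
    sol = solve_ivp(
        _rhs,
        (times[0], times[-1]),
        state0.to_vector(),
        t_eval=times,
        method="LSODA" if method == "lsoda" else method,
        rtol=params.rtol,
        atol=params.atol,
        args=(params, geom, L, clamp),
    )
    if not sol.success:
        raise RuntimeError(f"fiber integration failed: {sol.message}")
    return sol.y


def simulate_chase(
    params: RdParams,
    geom: FiberGeometry | None = None,
    sample_dt: float = 2.0,
    duration: float = 800.0,
    method: str = "lsoda",
    return_components: bool = False,
):
    """Simulate a chase: at t = 0 the bath is switched to 0 mantATP / 4 mM ATP.

    Returns the t0-normalized fluorescence sampled every ``sample_dt``.  With
    ``return_components=True`` also returns a dict of the four normalized
    component trajectories (free, nsp, drx, srx).
    """
    geom = geom or FiberGeometry()
    times = np.arange(int(np.floor(duration / sample_dt + 1e-9)) + 1) * sample_dt
    state0 = _chase_initial_state(params, geom)
    ys = _integrate(params, geom, state0, times, method=method)

    comps = {k: np.empty(times.size) for k in ("free", "nsp", "drx", "srx")}
    for i in range(times.size):
        st = FiberState.from_vector(ys[:, i], geom.n_cells, geom.n_shells)
        c = fluorescence_components(st, params, geom)
        for k in comps:
            comps[k][i] = c[k]
    f = comps["free"] + comps["nsp"] + comps["drx"] + comps["srx"]
    f0 = f[0]
    if f0 <= 0:
        raise ConfigurationError("zero initial fluorescence; nothing to chase")
    meta = {
        "source": "fiber_rd",
        "fluorescence_mode": params.fluorescence_mode,
        "f_srx": params.f_srx,
        "s_tot_nsp": params.s_tot_nsp,
        "w_myo": params.myosin_weight,
    }
    trace = DecayTrace(times, f / f0, meta)
    if return_components:
        return trace, {k: v / f0 for k, v in comps.items()}
    return trace


def simulate_ghost(
    params: RdParams,
    geom: FiberGeometry | None = None,
    sample_dt: float = 2.0,
    duration: float = 800.0,
    method: str = "lsoda",
) -> DecayTrace:
    """Chase of a myosin-extracted (ghosted) fiber.

    Pure diffusion when ``s_tot_nsp == 0``; otherwise diffusion retarded by
    the nonspecific buffer, which slows the normalized decay at late times.
    """
    ghost = replace(params, myosin_total=0.0)
    trace = simulate_chase(ghost, geom, sample_dt, duration, method=method)
    trace.meta["ghost"] = True
    return trace


def impose_signal_fractions(
    params: RdParams,
    nsp_frac: float,
    srx_rel: float,
    geom: FiberGeometry | None = None,
) -> RdParams:
    """Return parameters whose t = 0 signal fractions match the targets exactly.

    ``nsp_frac`` is the nonspecific share of the initial fluorescence (free
    intra-fiber mant plus nonspecifically bound mant); ``srx_rel`` is the SRX
    share of the myosin-bound signal.  In ``amount`` mode the nonspecific
    site concentration stays at its configured value and the myosin
    fluorescence weight is solved; in ``weighted`` mode the weight stays at
    ``enhancement`` and ``s_tot_nsp`` is solved.  Raises a configuration
    error, with the feasible range, when the targets cannot be reached.
    """
    if not 0.0 < nsp_frac < 1.0:
        raise ConfigurationError("nsp_frac must be in (0, 1)")
    if not 0.0 <= srx_rel <= 1.0:
        raise ConfigurationError("srx_rel must be in [0, 1]")
    if params.myosin_total <= 0:
        raise ConfigurationError("imposing populations requires myosin_total > 0")
    c0 = params.mant_free_0
    kon = params.k_on_mant_myo * M_TO_UM
    occ_d = kon * c0 / (kon * c0 + 1.0 / params.t_drx)
    occ_s = kon * c0 / (kon * c0 + 1.0 / params.t_srx)
    # pool split giving the target share of the bound signal at t = 0
    f_srx = srx_rel * occ_d / (occ_s * (1.0 - srx_rel) + srx_rel * occ_d)
    bound_myo = params.myosin_total * (f_srx * occ_s + (1.0 - f_srx) * occ_d)  # uM equivalent

    sig_free = c0
    if params.fluorescence_mode == "amount":
        sig_nsp = _nsp_occupancy(params, c0) * params.s_tot_nsp
        w_myo = (sig_free + sig_nsp) * (1.0 - nsp_frac) / (nsp_frac * bound_myo)
        return replace(params, f_srx=f_srx, w_myo=w_myo)
    # weighted mode: solve the site concentration at fixed enhancement
    w_myo = params.enhancement
    sig_myo = w_myo * bound_myo
    sig_nsp_needed = sig_myo * nsp_frac / (1.0 - nsp_frac) - sig_free
    if sig_nsp_needed < 0:
        nsp_min = sig_free / (sig_free + sig_myo)
        raise ConfigurationError(
            f"imposed NSP={nsp_frac:.3g} below the free-nucleotide floor; "
            f"feasible NSP range is [{nsp_min:.3f}, 1) in weighted mode"
        )
    occ = _nsp_occupancy(params, c0)
    s_tot = sig_nsp_needed / occ
    return replace(params, f_srx=f_srx, s_tot_nsp=s_tot, w_myo=w_myo)
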