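"""Two-compartment Hodgkin-Huxley neurons embedded in the extracellular field.

Each cell has a soma and a dendrite carrying fast sodium (naf, m^3*h),
delayed-rectifier potassium (kdr, n^4), persistent sodium (nap, instantaneous
activation), a potassium leak and a non-specific leak.  The K+ and Na+
reversal potentials are recomputed every membrane sub-step from the local
extracellular concentrations via the Nernst equation, and the net K+/Na+
membrane currents are returned as molar fluxes deposited into the cell's
containing voxel.  This closes the positive-feedback loop that drives
spreading depression: elevated extracellular K+ depolarizes cells, their
open K+ channels release more K+ into the shrinking gradient.

The Na/K-ATPase is deliberately omitted: restoration of gradients is left to
the phenomenological astrocyte buffer reaction in the field.  Intracellular
concentrations are fixed by default ("open books"); an optional closed-books
mode tracks per-cell interior amounts so total substance is exactly
conserved for conservation audits.

Channel kinetics are Traub-style rate functions (time constants in ms at
body temperature); the default conductance set is calibrated so the resting
state is stable at the 3.5 mM potassium baseline and sustained
depolarization sets in for extracellular K+ around 15-20 mM.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .solver import FARADAY

try:  # optional acceleration; the numpy path is the reference
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["MembraneParameters", "NeuronPopulation", "nernst", "resting_state"]

#: Gas constant, J/(mol K).
R_GAS = 8.314462618


def nernst(conc_in, conc_out, z, T=310.15):
    """Nernst equilibrium potential (mV): (R T / z F) * ln(out / in).

    Concentrations in mM (any consistent unit), ``z`` the signed valence,
    ``T`` in kelvin (default body temperature 37 C).
    """
    ci = np.asarray(conc_in, dtype=float)
    co = np.asarray(conc_out, dtype=float)
    if np.any(ci <= 0) or np.any(co <= 0):
        raise ValueError("Nernst potential requires positive concentrations")
    if z == 0:
        raise ValueError("Nernst potential undefined for neutral species")
    out = (R_GAS * T) / (z * FARADAY) * np.log(co / ci) * 1e3
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MembraneParameters:
    """Named default membrane parameter set ("traub2c").

    Conductance densities in mS/cm^2, areas in um^2, capacitance in uF/cm^2.
    ``g_couple`` is the soma-referred axial coupling density; the dendrite
    receives the equal-and-opposite absolute current.  Intracellular
    concentrations (mM) are fixed; reversal potentials follow the local
    extracellular field.
    """

    name: str = "traub2c"
    cm: float = 1.0
    gnaf: float = 30.0
    gkdr: float = 30.0
    gnap: float = 0.15
    gkleak: float = 0.06
    gleak: float = 0.3
    e_leak: float = -70.0
    soma_area: float = 1000.0
    dend_area: float = 2000.0
    g_couple: float = 1.0
    k_in: float = 125.0
    na_in: float = 15.0
    temperature: float = 310.15
    dt_membrane: float = 0.05
    # persistent-sodium activation: p_inf = 1/(1 + exp(-(V - v_half)/k))
    nap_v_half: float = -52.5
    nap_k: float = 5.0

    def with_(self, **kw) -> "MembraneParameters":
        return replace(self, **kw)


# Traub-style voltage-dependent rate functions (1/ms, V in mV); the
# singularities at the breakpoints are removed with a series limit.

def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity handled."""
    x = np.asarray(x, dtype=float)
    r = x / y
    small = np.abs(r) < 1e-6
    safe = np.where(small, 1.0, np.expm1(r))
    return np.where(small, y - x / 2.0, x / safe)


def rates_m(v):
    am = 0.32 * _vtrap(-(v + 54.0), 4.0)
    bm = 0.28 * _vtrap(v + 27.0, 5.0)
    return am, bm


def rates_h(v):
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    return ah, bh


def rates_n(v):
    an = 0.032 * _vtrap(-(v + 52.0), 5.0)
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return an, bn


def nap_inf(v, p: MembraneParameters):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v, dtype=float) - p.nap_v_half) / p.nap_k))


def _gate_inf(rates, v):
    a, b = rates(v)
    return a / (a + b)


_REST_CACHE: dict = {}


def resting_state(params: MembraneParameters, k_out=3.5, na_out=144.0,
                  settle_ms=1000.0):
    """Settle a single cell at a uniform field and return its state arrays
    ``(v, m, h, n)``, each of shape (2, 1): soma row 0, dendrite row 1."""
    key = (params, float(k_out), float(na_out), float(settle_ms))
    if key in _REST_CACHE:
        return tuple(a.copy() for a in _REST_CACHE[key])
    pop = NeuronPopulation.__new__(NeuronPopulation)
    pop.params = params
    pop.n_cells = 1
    pop._init_state(np.full((2, 1), -70.0))
    ek = np.array([nernst(params.k_in, k_out, 1, params.temperature)])
    ena = np.array([nernst(params.na_in, na_out, 1, params.temperature)])
    if _HAVE_NUMBA:
        pop._advance_numba(ek, ena, settle_ms)
    else:
        pop._advance_numpy(ek, ena, settle_ms)
    state = (pop.v.copy(), pop.m.copy(), pop.h.copy(), pop.n.copy())
    _REST_CACHE[key] = state
    return tuple(a.copy() for a in state)


class NeuronPopulation:
    """A set of point-located two-compartment cells coupled to the field.

    Implements the coupler interface used by
    :class:`~ecsrd.solver.Simulation`: each field step, the membrane
    dynamics are sub-stepped at ``params.dt_membrane`` with reversal
    potentials frozen to the local field, and the accumulated K+/Na+ molar
    fluxes are deposited into each cell's voxel.
    """

    def __init__(
        self,
        grid,
        positions: np.ndarray,
        params: MembraneParameters | None = None,
        k_name: str = "k",
        na_name: str = "na",
        closed_books: bool = False,
        initial_state=None,
    ):
        self.grid = grid
        self.params = params or MembraneParameters()
        self.positions = np.atleast_2d(np.asarray(positions, dtype=float))
        if self.positions.size and self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array of um coordinates")
        self.n_cells = len(self.positions)
        self.k_name = k_name
        self.na_name = na_name
        self.closed_books = closed_books
        self._intracellular = {k_name: 0.0, na_name: 0.0}  # mM*um^3, change
        self.voxels = np.array(
            [grid.voxel_of(*p) for p in self.positions], dtype=np.int64
        ).reshape(self.n_cells, 3)
        if initial_state is None:
            initial_state = resting_state(self.params)
        v, m, h, n = initial_state
        self._init_state(np.broadcast_to(v, (2, self.n_cells)).copy())
        self.m = np.broadcast_to(m, (2, self.n_cells)).copy()
        self.h = np.broadcast_to(h, (2, self.n_cells)).copy()
        self.n = np.broadcast_to(n, (2, self.n_cells)).copy()
        self.use_numba = _HAVE_NUMBA

    @classmethod
    def place(
        cls,
        grid,
        density_per_mm3: float,
        rng,
        bounds=None,
        **kw,
    ) -> "NeuronPopulation":
        """Place cells uniformly at a density (cells/mm^3) within ``bounds``
        (defaults to the whole domain); realized count is round(density *
        volume)."""
        if bounds is None:
            bounds = (grid.xlo, grid.ylo, grid.zlo, grid.xhi, grid.yhi, grid.zhi)
        xlo, ylo, zlo, xhi, yhi, zhi = bounds
        volume_mm3 = (xhi - xlo) * (yhi - ylo) * (zhi - zlo) * 1e-9
        count = int(round(density_per_mm3 * volume_mm3))
        rng = np.random.default_rng(rng)
        pos = rng.uniform([xlo, ylo, zlo], [xhi, yhi, zhi], size=(count, 3))
        # keep strictly inside the half-open domain
        hi = np.array([xhi, yhi, zhi])
        pos = np.minimum(pos, np.nextafter(hi, -np.inf))
        return cls(grid, pos, **kw)

    def _init_state(self, v):
        self.v = np.asarray(v, dtype=float)
        self.m = _gate_inf(rates_m, self.v)
        self.h = _gate_inf(rates_h, self.v)
        self.n = _gate_inf(rates_n, self.v)

    # -- membrane dynamics -------------------------------------------------
    def advance(self, k_out: np.ndarray, na_out: np.ndarray, dt: float):
        """Advance all cells by ``dt`` ms (internally sub-stepped) with the
        given per-cell extracellular concentrations; returns per-cell net
        (k_flux, na_flux) in mmol over the interval, positive = into the
        ECS."""
        p = self.params
        ek = nernst(p.k_in, np.maximum(k_out, 1e-6), 1, p.temperature)
        ena = nernst(p.na_in, np.maximum(na_out, 1e-6), 1, p.temperature)
        ek = np.atleast_1d(ek)
        ena = np.atleast_1d(ena)
        if self.use_numba:
            qk, qna = self._advance_numba(ek, ena, dt)
        else:
            qk, qna = self._advance_numpy(ek, ena, dt)
        # q in uA*ms = nC; mmol = q * 1e-6 / F
        return qk * 1e-6 / FARADAY, qna * 1e-6 / FARADAY

    def _advance_numpy(self, ek, ena, dt):
        p = self.params
        nsub = max(1, int(np.ceil(dt / p.dt_membrane - 1e-9)))
        h_dt = dt / nsub
        areas = np.array([p.soma_area, p.dend_area])[:, None]  # um^2
        gc = np.array([p.g_couple, p.g_couple * p.soma_area / p.dend_area])[:, None]
        qk = np.zeros(self.v.shape[1])
        qna = np.zeros(self.v.shape[1])
        v, m, h, n = self.v, self.m, self.h, self.n
        for _ in range(nsub):
            am, bm = rates_m(v)
            ah, bh = rates_h(v)
            an, bn = rates_n(v)
            m += (am / (am + bm) - m) * -np.expm1(-h_dt * (am + bm))
            h += (ah / (ah + bh) - h) * -np.expm1(-h_dt * (ah + bh))
            n += (an / (an + bn) - n) * -np.expm1(-h_dt * (an + bn))
            gna = p.gnaf * m**3 * h + p.gnap * nap_inf(v, p)
            gk = p.gkdr * n**4 + p.gkleak
            ik = gk * (v - ek)      # uA/cm^2, outward positive
            ina = gna * (v - ena)
            qk += np.sum(ik * areas, axis=0) * 1e-8 * h_dt
            qna += np.sum(ina * areas, axis=0) * 1e-8 * h_dt
            v_other = v[::-1]
            g_tot = gna + gk + p.gleak + gc
            e_tot = gna * ena + gk * ek + p.gleak * p.e_leak + gc * v_other
            safe_g = np.where(g_tot > 0, g_tot, 1.0)
            dv = (e_tot / safe_g - v) * -np.expm1(-h_dt * safe_g / p.cm)
            v += np.where(g_tot > 0, dv, 0.0)
            if not np.all(np.isfinite(v)):
                raise FloatingPointError(
                    "membrane potential became non-finite; reduce dt_membrane"
                )
        return qk, qna

    def _advance_numba(self, ek, ena, dt):
        p = self.params
        nsub = max(1, int(np.ceil(dt / p.dt_membrane - 1e-9)))
        qk = np.zeros(self.v.shape[1])
        qna = np.zeros(self.v.shape[1])
        _membrane_kernel(
            self.v, self.m, self.h, self.n, ek, ena, qk, qna,
            dt / nsub, nsub,
            p.cm, p.gnaf, p.gkdr, p.gnap, p.gkleak, p.gleak, p.e_leak,
            p.soma_area, p.dend_area, p.g_couple, p.nap_v_half, p.nap_k,
        )
        if not np.all(np.isfinite(self.v)):
            raise FloatingPointError(
                "membrane potential became non-finite; reduce dt_membrane"
            )
        return qk, qna

    # -- coupler interface -------------------------------------------------
    def apply(self, sim, dt):
        """Read the local field, advance the membranes, deposit fluxes."""
        if self.n_cells == 0:
            return
        i, j, k = self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]
        k_out = np.maximum(sim.by_name[self.k_name].conc[i, j, k], 1e-3)
        na_out = np.maximum(sim.by_name[self.na_name].conc[i, j, k], 1e-3)
        k_flux, na_flux = self.advance(k_out, na_out, dt)  # mmol
        vol = sim.grid.voxel_volume
        for name, flux in ((self.k_name, k_flux), (self.na_name, na_flux)):
            amount = flux / 1e-15  # mmol -> mM*um^3
            per_voxel = np.zeros(sim.grid.shape)
            np.add.at(per_voxel, (i, j, k), amount)
            sim.by_name[name].conc += per_voxel / (sim.grid.alpha * vol)
            if self.closed_books:
                self._intracellular[name] -= float(amount.sum())
            else:
                sim.injected_mass[name] += float(amount.sum())

    def tracked_amount(self, name: str) -> float:
        """Closed-books intracellular ledger (change since t=0, mM*um^3)."""
        if not self.closed_books:
            return 0.0
        return self._intracellular.get(name, 0.0)


if _HAVE_NUMBA:

    @numba.njit(cache=False, fastmath=False)
    def _membrane_kernel(v, m, h, n, ek, ena, qk, qna, hdt, nsub,
                         cm, gnaf, gkdr, gnap, gkleak, gleak, eleak,
                         a_s, a_d, g_couple, nap_vh, nap_k):
        ncell = v.shape[1]
        for c in range(ncell):
            for _ in range(nsub):
                vs0 = v[0, c]
                vd0 = v[1, c]
                for comp in range(2):
                    vv = v[comp, c]
                    # gate rates (same expressions as the numpy path)
                    x = -(vv + 54.0)
                    am = 0.32 * (4.0 * (1.0 - x / 8.0) if abs(x / 4.0) < 1e-6
                                 else x / (np.expm1(x / 4.0)))
                    x = vv + 27.0
                    bm = 0.28 * (5.0 * (1.0 - x / 10.0) if abs(x / 5.0) < 1e-6
                                 else x / (np.expm1(x / 5.0)))
                    ah = 0.128 * np.exp(-(vv + 50.0) / 18.0)
                    bh = 4.0 / (1.0 + np.exp(-(vv + 27.0) / 5.0))
                    x = -(vv + 52.0)
                    an = 0.032 * (5.0 * (1.0 - x / 10.0) if abs(x / 5.0) < 1e-6
                                  else x / (np.expm1(x / 5.0)))
                    bn = 0.5 * np.exp(-(vv + 57.0) / 40.0)
                    sm = am + bm
                    sh = ah + bh
                    sn = an + bn
                    m[comp, c] += (am / sm - m[comp, c]) * -np.expm1(-hdt * sm)
                    h[comp, c] += (ah / sh - h[comp, c]) * -np.expm1(-hdt * sh)
                    n[comp, c] += (an / sn - n[comp, c]) * -np.expm1(-hdt * sn)
                    pinf = 1.0 / (1.0 + np.exp(-(vv - nap_vh) / nap_k))
                    gna = gnaf * m[comp, c] ** 3 * h[comp, c] + gnap * pinf
                    gk = gkdr * n[comp, c] ** 4 + gkleak
                    area = a_s if comp == 0 else a_d
                    gc = g_couple if comp == 0 else g_couple * a_s / a_d
                    vother = vd0 if comp == 0 else vs0
                    ik = gk * (vv - ek[c])
                    ina = gna * (vv - ena[c])
                    qk[c] += ik * area * 1e-8 * hdt
                    qna[c] += ina * area * 1e-8 * hdt
                    gtot = gna + gk + gleak + gc
                    etot = (gna * ena[c] + gk * ek[c] + gleak * eleak
                            + gc * vother)
                    if gtot > 0.0:
                        v[comp, c] += (etot / gtot - vv) * -np.expm1(
                            -hdt * gtot / cm
                        )
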