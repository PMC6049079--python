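"""Verification procedures for the field solver.

Three independent checks:

1. **Analytic cube-in-box.**  An initial cube of elevated concentration
   diffusing in a closed (zero-flux) box has a closed-form solution: the
   free-space Green's function integrated over the initial condition, with
   the Neumann walls satisfied by the method of images.  Because both the
   initial condition and the box factorize per axis, the 3D solution is a
   product of three 1D image series, and the average over any voxel is
   available in closed form through the antiderivative of erf.  The solver's
   central-voxel trace is compared against this series.

2. **Brute-force oracle.**  A deliberately simple forward-Euler,
   central-difference, flux-form explicit solver (sharing no code with the
   ADI implementation, same face harmonic-mean and boundary semantics) run
   at small dt.  Two consistent discretizations of the same PDE must agree
   as dt, dx -> 0.

3. **Conservation audit.**  Total amount per species (concentration x free
   volume fraction x voxel volume, plus any coupler-tracked intracellular
   books) minus injected source mass minus Dirichlet boundary exchange must
   stay constant to floating-point accuracy; the audit emits a per-step
   ledger and the maximum relative drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import erf

from .grid import ECSGrid, build_grid
from .kinetics import Species
from .solver import MM_UM3_TO_MMOL, Simulation

__all__ = [
    "AnalyticBoxProblem",
    "analytic_center_voxel",
    "brute_force_oracle",
    "convergence_study",
    "conservation_audit",
]


@dataclass
class AnalyticBoxProblem:
    """A cube of side ``a`` (concentration ``c1``) concentric in a closed
    box of side ``L`` (background ``c0``), diffusing with coefficient ``D``.

    The steady state is ``c0 + (c1 - c0) * (a/L)**3`` (the excess mass
    spread uniformly).
    """

    L: float = 21.0   # box side, um
    a: float = 9.0    # cube side, um
    c1: float = 1.0   # mM inside the cube
    c0: float = 0.0   # mM outside
    D: float = 1.0    # um^2/ms
    tol: float = 1e-14

    @property
    def steady_state(self) -> float:
        return self.c0 + (self.c1 - self.c0) * (self.a / self.L) ** 3


def _erf_antideriv(u):
    """Antiderivative of erf: u*erf(u) + exp(-u^2)/sqrt(pi)."""
    return u * erf(u) + np.exp(-(u**2)) / np.sqrt(np.pi)


def _factor_1d(problem: AnalyticBoxProblem, xl: float, xr: float, t: float) -> float:
    """Average over [xl, xr] of the 1D image-series solution for an initial
    unit indicator on [-a/2, a/2] inside walls at +-L/2.

    Reflections of the centered symmetric interval about both walls tile
    the line with image intervals centered at every integer multiple of L,
    so the series adds image pairs at +-m*L until a pair's contribution
    falls below ``problem.tol`` relative (at least 3 pairs).
    """
    a, L, D = problem.a, problem.L, problem.D
    if t <= 0 or D == 0:
        lo, hi = max(xl, -a / 2.0), min(xr, a / 2.0)
        return max(0.0, hi - lo) / (xr - xl)
    s = 2.0 * np.sqrt(D * t)

    def term(center):
        up = _erf_antideriv((xr - center + a / 2.0) / s)
        um = _erf_antideriv((xl - center + a / 2.0) / s)
        lp = _erf_antideriv((xr - center - a / 2.0) / s)
        lm = _erf_antideriv((xl - center - a / 2.0) / s)
        return 0.5 * s * ((up - um) - (lp - lm)) / (xr - xl)

    total = term(0.0)
    m = 1
    while True:
        pair = term(m * L) + term(-m * L)
        total += pair
        if m >= 3 and abs(pair) < problem.tol * max(abs(total), 1e-300):
            break
        m += 1
        if m > 10_000:  # pragma: no cover - series always converges fast
            raise RuntimeError("image series failed to converge")
    return total


def _profile_voxel_average(edges, values, L, D, xl, xr, t, tol=1e-14):
    """Average over [xl, xr] of the 1D closed-box solution for an arbitrary
    piecewise-constant initial profile.

    ``edges``/``values``: the initial profile is ``values[i]`` on
    ``[edges[i], edges[i+1]]`` inside walls at +-L/2.  Each source interval
    [p, q] contributes its direct copies [p, q] + 2mL and the wall
    reflections [L - q, L - p] + 2mL; image pairs are added until their
    contribution is negligible."""
    if t <= 0 or D == 0:
        lo = np.maximum(edges[:-1], xl)
        hi = np.minimum(edges[1:], xr)
        w = np.clip(hi - lo, 0.0, None)
        return float(np.sum(np.asarray(values) * w) / (xr - xl))
    s = 2.0 * np.sqrt(D * t)
    p = np.asarray(edges[:-1], dtype=float)
    q = np.asarray(edges[1:], dtype=float)
    v = np.asarray(values, dtype=float)

    def block(pp, qq):
        # sum_i v_i * avg over [xl, xr] of 1/2 [erf((x-p_i)/s) - erf((x-q_i)/s)]
        w = (
            _erf_antideriv((xr - pp) / s)
            - _erf_antideriv((xl - pp) / s)
            - _erf_antideriv((xr - qq) / s)
            + _erf_antideriv((xl - qq) / s)
        )
        return 0.5 * s * float(np.sum(v * w)) / (xr - xl)

    def images(m):
        out = block(p + 2 * m * L, q + 2 * m * L)
        out += block(L - q + 2 * m * L, L - p + 2 * m * L)
        return out

    total = images(0)
    m = 1
    while True:
        pair = images(m) + images(-m)
        total += pair
        if m >= 3 and abs(pair) < tol * max(abs(total), 1e-300):
            break
        m += 1
        if m > 10_000:  # pragma: no cover
            raise RuntimeError("image series failed to converge")
    return total


def analytic_center_voxel(problem: AnalyticBoxProblem, voxel_size: float,
                          t: float) -> float:
    """Average concentration over the central voxel at time ``t`` (ms).

    The central voxel is the one containing the origin on a grid of edge
    ``voxel_size`` aligned to the box corner at ``-L/2``.  The 3D solution
    factorizes into the cube of the 1D voxel-averaged image series (the
    geometry is identical per axis)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    i = int(np.floor((problem.L / 2.0) / voxel_size))
    xl = -problem.L / 2.0 + i * voxel_size
    xr = xl + voxel_size
    f = _factor_1d(problem, xl, xr, t)
    return problem.c0 + (problem.c1 - problem.c0) * f**3


def brute_force_oracle(grid: ECSGrid, species, t_stop: float, dt: float,
                       sources=(), record_every=None):
    """Forward-Euler central-difference explicit reference solver.

    Flux-form update with harmonic-mean face conductances and the same
    boundary semantics as the main solver, but sharing none of its code.
    ``dt`` must satisfy the explicit stability bound
    ``dt < min(dx,dy,dz)^2 / (6 * max(D_eff))``.

    Returns ``(fields, trajectory)``: final per-species arrays, and a list
    of ``(t, {name: array})`` snapshots if ``record_every`` (ms) is given.
    """
    hs = (grid.dx, grid.dy, grid.dz)
    dmax = 0.0
    for sp in species:
        for ax, d in enumerate(sp.d_tuple):
            if d > 0:
                dmax = max(dmax, float(np.max(d / grid.lam[ax] ** 2)))
    if dmax > 0 and dt >= min(hs) ** 2 / (6.0 * dmax):
        raise ValueError(
            f"dt={dt} violates the explicit stability bound "
            f"{min(hs)**2 / (6.0 * dmax):.4g} ms"
        )

    from .grid import materialize_field

    conc = {
        sp.name: (np.array(sp.conc, dtype=float) if sp.conc is not None
                  else materialize_field(sp.initial, grid, sp.name))
        for sp in species
    }
    vol = grid.voxel_volume

    # per-species, per-axis face conductances (independent construction)
    faces = {}
    for sp in species:
        gg = []
        for ax, d in enumerate(sp.d_tuple):
            w = grid.alpha * d / grid.lam[ax] ** 2
            wm = np.moveaxis(w, ax, 0)
            g = np.zeros((wm.shape[0] + 1,) + wm.shape[1:])
            num = 2.0 * wm[:-1] * wm[1:]
            den = wm[:-1] + wm[1:]
            g[1:-1] = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
            if sp.boundary != "neumann" and d > 0:
                g[0] = wm[0]
                g[-1] = wm[-1]
            gg.append(g)
        faces[sp.name] = gg

    src_vox = [grid.voxel_of(s.x, s.y, s.z) for s in sources]
    traj = []
    t = 0.0
    nstep = int(round(t_stop / dt))
    rec_stride = None if record_every is None else max(1, int(round(record_every / dt)))
    for step in range(nstep):
        for s, (i, j, k) in zip(sources, src_vox):
            rate = s.rate_at(t)
            conc[s.species][i, j, k] += (
                rate * dt / MM_UM3_TO_MMOL / (grid.alpha[i, j, k] * vol)
            )
        for sp in species:
            c = conc[sp.name]
            dc = np.zeros_like(c)
            for ax, d in enumerate(sp.d_tuple):
                if d == 0:
                    continue
                g = faces[sp.name][ax]
                cm = np.moveaxis(c, ax, 0)
                F = np.zeros_like(g)
                F[1:-1] = g[1:-1] * (cm[1:] - cm[:-1]) / hs[ax]
                if sp.boundary != "neumann":
                    b = float(sp.boundary)
                    F[0] = g[0] * (cm[0] - b) / hs[ax]
                    F[-1] = g[-1] * (b - cm[-1]) / hs[ax]
                dcm = (F[1:] - F[:-1]) / hs[ax]
                dc += np.moveaxis(dcm, 0, ax) / grid.alpha
            conc[sp.name] = c + dt * dc
        t += dt
        if rec_stride and (step + 1) % rec_stride == 0:
            traj.append((t, {k: v.copy() for k, v in conc.items()}))
    return conc, traj


def box_initial_field(problem: AnalyticBoxProblem, grid: ECSGrid) -> np.ndarray:
    """Exact voxel averages of the cube-in-box initial condition.

    Finite-volume unknowns are voxel averages, so voxels straddling the
    cube face carry the overlap fraction (product of per-axis overlaps)."""
    half = problem.a / 2.0

    def frac(lo_edges, h):
        lo = np.maximum(lo_edges, -half)
        hi = np.minimum(lo_edges + h, half)
        return np.clip(hi - lo, 0.0, None) / h

    fx = frac(grid.xlo + np.arange(grid.nx) * grid.dx, grid.dx)
    fy = frac(grid.ylo + np.arange(grid.ny) * grid.dy, grid.dy)
    fz = frac(grid.zlo + np.arange(grid.nz) * grid.dz, grid.dz)
    f = fx[:, None, None] * fy[None, :, None] * fz[None, None, :]
    return problem.c0 + (problem.c1 - problem.c0) * f


def _box_grid_and_sim(problem: AnalyticBoxProblem, dx: float, dt: float) -> Simulation:
    L2 = problem.L / 2.0
    grid = build_grid(-L2, -L2, -L2, L2, L2, L2, dx, 1.0, 1.0)
    sp = Species("c", d=problem.D, initial=box_initial_field(problem, grid))
    return Simulation(grid, [sp], dt=dt)


def adi_center_trace(problem: AnalyticBoxProblem, dx: float, dt: float,
                     t_stop: float, sample_every: float):
    """Run the ADI solver on the cube-in-box problem; return (times,
    central-voxel concentrations)."""
    sim = _box_grid_and_sim(problem, dx, dt)
    i, j, k = sim.grid.voxel_of(0.0, 0.0, 0.0)
    times, vals = [0.0], [float(sim.by_name["c"].conc[i, j, k])]
    every = max(1, int(round(sample_every / dt)))

    def cb(s):
        times.append(s.t)
        vals.append(float(s.by_name["c"].conc[i, j, k]))

    sim.run(t_stop, callback=cb, callback_every=every)
    return np.asarray(times), np.asarray(vals)


def convergence_study(problem: AnalyticBoxProblem, dx_list,
                      t_stop: float = 100.0, sample_every: float = 5.0,
                      dt_at_dx1: float = 0.1):
    """Relative error of the ADI central-voxel trace vs the analytic series
    for each spatial resolution.

    The time step is refined with the grid (``dt = dt_at_dx1 * dx**2``) and
    each run is compared against the exact closed-box evolution of its own
    voxel-averaged initial data, so the measured slope isolates the spatial
    order of the scheme from the representation of the cube on incommensurate
    grids.  Returns a DataFrame with columns dx, dt, max_rel_error, plus the
    fitted log-log order as ``df.attrs["order"]``.
    """
    rows = []
    for dx in dx_list:
        dt = dt_at_dx1 * dx**2
        times, vals = adi_center_trace(problem, dx, dt, t_stop, sample_every)
        L2 = problem.L / 2.0
        grid = build_grid(-L2, -L2, -L2, L2, L2, L2, dx, 1.0, 1.0)
        i = int(np.floor(L2 / dx))
        xl = -L2 + i * dx
        half = problem.a / 2.0
        edges = -L2 + np.arange(grid.nx + 1) * dx
        lo = np.maximum(edges[:-1], -half)
        hi = np.minimum(edges[1:], half)
        fx = np.clip(hi - lo, 0.0, None) / dx
        exact = np.array(
            [
                problem.c0
                + (problem.c1 - problem.c0)
                * _profile_voxel_average(
                    edges, fx, problem.L, problem.D, xl, xl + dx, t, problem.tol
                )
                ** 3
                for t in times
            ]
        )
        sel = times > 0
        err = float(np.max(np.abs(vals[sel] - exact[sel]) / np.abs(exact[sel])))
        rows.append({"dx": float(dx), "dt": float(dt), "max_rel_error": err})
    df = pd.DataFrame(rows).sort_values("dx", ascending=False, ignore_index=True)
    if len(df) >= 2:
        slope = np.polyfit(np.log(df["dx"]), np.log(df["max_rel_error"]), 1)[0]
        df.attrs["order"] = float(slope)
    return df


def conservation_audit(sim: Simulation, n_steps: int, record_every: int = 1):
    """Step the simulation, keeping per-step books for every species.

    The audited quantity per species is::

        Q = tracked mass (ECS + coupler books) - injected - boundary exchange

    which is exactly constant for a correct solver when the species takes
    part in no reaction; reactions move mass between species, in which case
    the caller audits the reaction-invariant sums from the per-species
    ``mass_*`` ledger columns instead.  Returns ``(ledger,
    max_rel_drift)`` where the ledger is a DataFrame with one row per
    recorded step and columns ``t, mass_<s>, injected_<s>, boundary_<s>,
    drift_<s>``; drift is relative to the initial audited quantity.
    """
    names = [s.name for s in sim.species]
    q0 = {
        n: sim.tracked_mass(n) - sim.injected_mass[n] - sim.boundary_exchange[n]
        for n in names
    }
    rows = []

    def record():
        row = {"t": sim.t}
        for n in names:
            q = sim.tracked_mass(n) - sim.injected_mass[n] - sim.boundary_exchange[n]
            row[f"mass_{n}"] = sim.total_mass(n)
            row[f"injected_{n}"] = sim.injected_mass[n]
            row[f"boundary_{n}"] = sim.boundary_exchange[n]
            scale = abs(q0[n]) if q0[n] != 0 else 1.0
            row[f"drift_{n}"] = (q - q0[n]) / scale
        rows.append(row)

    record()
    for i in range(n_steps):
        sim.step()
        if (i + 1) % record_every == 0 or i == n_steps - 1:
            record()
    ledger = pd.DataFrame(rows)
    drift_cols = [c for c in ledger.columns if c.startswith("drift_")]
    max_drift = float(ledger[drift_cols].abs().to_numpy().max())
    return ledger, max_drift
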