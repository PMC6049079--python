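"""Spreading depression: the coupled neuron-field scenario.

A spherical bolus of elevated potassium triggers a slowly propagating wave
of near-complete depolarization: extracellular K+ depolarizes embedded
cells, whose open K+ channels release more K+, which diffuses outward and
recruits neighbors.  A phenomenological astrocyte buffer

    K + A  <->  AK,   kf = kb / (1 + exp(-([K] - kth)/1.15)),  kb = 0.0008/ms

with total capacity Amax (mM of immobile uptake sites) opposes the wave;
high capacity abolishes it, intermediate capacity slows it.  Cytotoxic
edema (reduced free volume fraction, raised tortuosity around an ischemic
core) speeds the wave: less free volume means less K+ is needed to raise
the concentration ahead of the front.

The wave front is quantified as the maximum distance from the bolus center
at which extracellular K+ exceeds a threshold (15 mM); the wave speed is
the slope of a linear fit to front radius vs time over the first 10 s,
reported in mm/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import build_grid, edema_alpha, edema_tortuosity
from .kinetics import Reaction, Species
from .neurons import MembraneParameters, NeuronPopulation
from .solver import Simulation

__all__ = ["SDScenario", "SDResult", "run_sd", "wave_front_radius", "wave_speed"]


@dataclass
class SDScenario:
    """Configuration of a spreading-depression run.

    Defaults are the full-scale conditions: a 1 mm^3 ECS at dx = 10 um,
    alpha = 0.2, lambda = 1.6, 90,000 cells/mm^3, a 40 mM K+ bolus of
    radius 100 um, 3.5 mM K+ / 144 mM Na+ baseline, astrocyte kinetics
    kb = 0.0008/ms with threshold 15 mM and slope 1.15 mM.
    """

    bounds: tuple = (-500.0, -500.0, -500.0, 500.0, 500.0, 500.0)
    dx: float = 10.0
    alpha: float = 0.2
    tortuosity: float = 1.6
    density_per_mm3: float = 90_000.0
    bolus_radius: float = 100.0
    bolus_concentration: float = 40.0
    bolus_center: tuple | None = None  # defaults to the domain center
    baseline_k: float = 3.5
    baseline_na: float = 144.0
    d_k: float = 2.62
    d_na: float = 1.78
    amax: float = 0.0
    kb: float = 0.0008
    kth: float = 15.0
    kslope: float = 1.15
    edema: bool = False
    edema_alpha0: float = 0.07
    edema_tort0: float = 1.8
    edema_r0: float = 100.0
    boundary: object = "neumann"
    dt: float = 1.0
    t_stop: float = 10_000.0
    record_every: float = 100.0
    front_threshold: float = 15.0
    membrane: MembraneParameters = field(default_factory=MembraneParameters)
    closed_books: bool = False
    seed: int = 0

    @classmethod
    def slab(cls, **kw) -> "SDScenario":
        """Thin-slab desk-scale variant: 1000 x 200 x 200 um with the bolus
        centered on one end face, otherwise full-scale densities."""
        base = dict(
            bounds=(0.0, 0.0, 0.0, 1000.0, 200.0, 200.0),
            bolus_center=(0.0, 100.0, 100.0),
        )
        base.update(kw)
        return cls(**base)

    def center(self) -> tuple:
        if self.bolus_center is not None:
            return tuple(self.bolus_center)
        xlo, ylo, zlo, xhi, yhi, zhi = self.bounds
        return ((xlo + xhi) / 2.0, (ylo + yhi) / 2.0, (zlo + zhi) / 2.0)

    def replace(self, **kw) -> "SDScenario":
        return replace(self, **kw)


@dataclass
class SDResult:
    times: np.ndarray  # ms
    radii: np.ndarray  # um
    speed_mm_min: float
    simulation: Simulation
    population: NeuronPopulation
    scenario: SDScenario


def wave_front_radius(conc, grid, threshold=15.0, center=None):
    """Maximum Euclidean distance from ``center`` (um; default: domain
    center) among voxel centers whose concentration exceeds ``threshold``;
    0 if none do."""
    if center is None:
        center = (
            (grid.xlo + grid.xhi) / 2.0,
            (grid.ylo + grid.yhi) / 2.0,
            (grid.zlo + grid.zhi) / 2.0,
        )
    mask = np.asarray(conc) > threshold
    if not mask.any():
        return 0.0
    X, Y, Z = grid.center_mesh()
    r2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
    return float(np.sqrt(r2[mask].max()))


def wave_speed(times_ms, radii_um, t_max=10_000.0):
    """Wave speed in mm/min: slope of a linear fit of front radius vs time
    over ``t <= t_max`` (1 um/ms = 60 mm/min)."""
    t = np.asarray(times_ms, dtype=float)
    r = np.asarray(radii_um, dtype=float)
    sel = t <= t_max + 1e-9
    if sel.sum() < 2:
        raise ValueError("need at least two recorded front radii")
    slope = np.polyfit(t[sel], r[sel], 1)[0]  # um/ms
    return float(slope * 60.0)


def build_sd_simulation(scenario: SDScenario, seed=None):
    """Assemble the grid, species, buffer reaction, and neuron population
    for a scenario; returns ``(sim, population)`` without running."""
    sc = scenario
    cx, cy, cz = sc.center()
    xlo, ylo, zlo, xhi, yhi, zhi = sc.bounds
    L = xhi - xlo

    if sc.edema:
        alpha_spec = edema_alpha(
            sc.edema_alpha0, sc.alpha, sc.edema_r0, L, (cx, cy, cz)
        )
        tort_spec = edema_tortuosity(
            sc.edema_tort0, sc.tortuosity, sc.edema_r0, L, (cx, cy, cz)
        )
    else:
        alpha_spec = sc.alpha
        tort_spec = sc.tortuosity
    grid = build_grid(*sc.bounds, sc.dx, alpha_spec, tort_spec)

    r2 = sc.bolus_radius**2

    def k_init(x, y, z):
        inside = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 < r2
        return np.where(inside, sc.bolus_concentration, sc.baseline_k)

    species = [
        Species("k", d=sc.d_k, charge=1, initial=k_init, boundary=sc.boundary),
        Species("na", d=sc.d_na, charge=1, initial=sc.baseline_na,
                boundary=(sc.boundary if sc.boundary == "neumann"
                          else sc.baseline_na)),
    ]
    reactions = []
    if sc.amax > 0:
        species.append(Species("A", d=0.0, initial=sc.amax))
        species.append(Species("AK", d=0.0, initial=0.0))
        kf = f"{sc.kb!r}/(1.0 + exp(-(k - {sc.kth!r})/{sc.kslope!r}))"
        reactions.append(Reaction("k + A", "AK", kf, sc.kb))

    rng_seed = sc.seed if seed is None else seed
    pop = NeuronPopulation.place(
        grid, sc.density_per_mm3, rng=rng_seed, params=sc.membrane,
        closed_books=sc.closed_books,
    )
    sim = Simulation(
        grid, species, reactions=reactions, couplers=[pop], dt=sc.dt
    )
    return sim, pop


def run_sd(scenario: SDScenario, seed=None, progress=None) -> SDResult:
    """Run the coupled loop and return the front-radius time series and the
    wave speed fitted over the first 10 s.

    ``seed`` overrides the scenario's placement seed.  The run is
    deterministic for a fixed seed.
    """
    sc = scenario
    sim, pop = build_sd_simulation(sc, seed=seed)
    center = sc.center()
    times = [0.0]
    radii = [wave_front_radius(sim.concentration("k"), sim.grid,
                               sc.front_threshold, center)]
    every = max(1, int(round(sc.record_every / sc.dt)))

    def record(s):
        times.append(s.t)
        radii.append(wave_front_radius(s.concentration("k"), s.grid,
                                       sc.front_threshold, center))
        if progress is not None:
            progress(s.t, radii[-1])

    sim.run(sc.t_stop, callback=record, callback_every=every)
    times_a = np.asarray(times)
    radii_a = np.asarray(radii)
    speed = wave_speed(times_a, radii_a, t_max=10_000.0)
    return SDResult(times_a, radii_a, speed, sim, pop, sc)
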