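"""Annealed Langevin sampling of the chromatin polymer model.

Each replicate starts from a chain folded at random inside the confinement
sphere, is linearly cooled from ``T_start`` to ``T_end`` over the annealing
phase, then run at constant ``T_end`` during production; conformations are
saved from production only.  Integration uses the BAOAB splitting of
Langevin dynamics (mass = 1, kB = 1), with Gaussian noise pre-generated in
chunks by a seeded numpy Generator so trajectories are reproducible per
(seed, replicate) on one platform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .errors import InvalidArgumentError, SimulationError
from .michrom import LoopList, MiChroMParams, confinement_radius, energy, types_to_indices
from .structures import Structure3D
from .units import UNIT_REDUCED


@dataclass
class SimulationSchedule:
    """Annealing + production protocol in reduced time units (tau).

    Defaults are the full-scale protocol (3.0 -> 1.0 eps/kB over 5e6 steps at
    dt = 0.002, then 20e6 production steps at dt = 0.001, friction 1/tau,
    40 replicates, a saved frame every 125000 production steps).  Use
    :meth:`scaled` for desk-scale runs.
    """

    T_start: float = 3.0
    T_end: float = 1.0
    anneal_steps: int = 5_000_000
    dt_anneal: float = 0.002
    prod_steps: int = 20_000_000
    dt_prod: float = 0.001
    friction: float = 1.0
    n_replicates: int = 40
    save_every: int = 125_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T_end > self.T_start:
            raise InvalidArgumentError("T_end must not exceed T_start")
        if min(self.anneal_steps, self.prod_steps, self.save_every,
               self.n_replicates) <= 0 and self.prod_steps > 0:
            raise InvalidArgumentError("schedule counts must be positive")
        if self.dt_anneal <= 0 or self.dt_prod <= 0 or self.friction <= 0:
            raise InvalidArgumentError("time steps and friction must be positive")

    def scaled(self, steps_scale: float) -> "SimulationSchedule":
        """Uniformly shorten the protocol by ``steps_scale`` (< 1)."""
        if steps_scale <= 0:
            raise InvalidArgumentError("steps_scale must be positive")
        return replace(self,
                       anneal_steps=max(1, int(self.anneal_steps * steps_scale)),
                       prod_steps=max(1, int(self.prod_steps * steps_scale)),
                       save_every=max(1, int(self.save_every * steps_scale)))


@dataclass
class SimEnsemble:
    """Saved production frames plus bookkeeping."""

    frames: list[Structure3D]
    replicate_ids: list[int]
    type_labels: np.ndarray
    loops: LoopList
    confinement_radius: float
    energies: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_loci(self) -> int:
        return self.frames[0].n_loci if self.frames else 0

    @property
    def units(self) -> str:
        return UNIT_REDUCED

    def coords_array(self) -> np.ndarray:
        return np.stack([f.coords for f in self.frames])


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _compute_forces(x, coeff, loop_pairs, chi, mu, rc, cutoff,
                    bond_k, bond_r0, angle_k, rep_e, rep_r0,
                    wall_k, wall_r, F):
    n = x.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    # bonds
    for i in range(n - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        dz = x[i + 1, 2] - x[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        g = bond_k * (r - bond_r0) / r
        F[i, 0] += g * dx
        F[i, 1] += g * dy
        F[i, 2] += g * dz
        F[i + 1, 0] -= g * dx
        F[i + 1, 1] -= g * dy
        F[i + 1, 2] -= g * dz
    # angles: U = angle_k * (1 - cos(phi)) between successive bond vectors
    for i in range(n - 2):
        b1x = x[i + 1, 0] - x[i, 0]
        b1y = x[i + 1, 1] - x[i, 1]
        b1z = x[i + 1, 2] - x[i, 2]
        b2x = x[i + 2, 0] - x[i + 1, 0]
        b2y = x[i + 2, 1] - x[i + 1, 1]
        b2z = x[i + 2, 2] - x[i + 1, 2]
        n1 = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        c = (b1x * b2x + b1y * b2y + b1z * b2z) / (n1 * n2)
        # dc/db1 and dc/db2
        d1x = b2x / (n1 * n2) - c * b1x / (n1 * n1)
        d1y = b2y / (n1 * n2) - c * b1y / (n1 * n1)
        d1z = b2z / (n1 * n2) - c * b1z / (n1 * n1)
        d2x = b1x / (n1 * n2) - c * b2x / (n2 * n2)
        d2y = b1y / (n1 * n2) - c * b2y / (n2 * n2)
        d2z = b1z / (n1 * n2) - c * b2z / (n2 * n2)
        # F = -dU/dx = angle_k * dc/dx
        F[i, 0] -= angle_k * d1x
        F[i, 1] -= angle_k * d1y
        F[i, 2] -= angle_k * d1z
        F[i + 1, 0] += angle_k * (d1x - d2x)
        F[i + 1, 1] += angle_k * (d1y - d2y)
        F[i + 1, 2] += angle_k * (d1z - d2z)
        F[i + 2, 0] += angle_k * d2x
        F[i + 2, 1] += angle_k * d2y
        F[i + 2, 2] += angle_k * d2z
    # non-bonded pairs: soft-core repulsion + coefficiented contact term
    for i in range(n):
        for j in range(i + 2, n):
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            dz = x[j, 2] - x[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            r = math.sqrt(r2)
            g = 0.0  # -dU/dr / r  (force on j = g * (xj - xi))
            if r < rep_r0:
                g += 2.0 * rep_e * (1.0 - r / rep_r0) / (rep_r0 * r)
            c = coeff[i, j]
            if c != 0.0 and r <= cutoff:
                t = math.tanh(mu * (rc - r))
                g += c * 0.5 * mu * (1.0 - t * t) / r
            if g != 0.0:
                F[j, 0] += g * dx
                F[j, 1] += g * dy
                F[j, 2] += g * dz
                F[i, 0] -= g * dx
                F[i, 1] -= g * dy
                F[i, 2] -= g * dz
    # loop anchors (no cutoff; f' is negligible far away anyway)
    for p in range(loop_pairs.shape[0]):
        i = loop_pairs[p, 0]
        j = loop_pairs[p, 1]
        dx = x[j, 0] - x[i, 0]
        dy = x[j, 1] - x[i, 1]
        dz = x[j, 2] - x[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 0:
            t = math.tanh(mu * (rc - r))
            g = chi * 0.5 * mu * (1.0 - t * t) / r
            F[j, 0] += g * dx
            F[j, 1] += g * dy
            F[j, 2] += g * dz
            F[i, 0] -= g * dx
            F[i, 1] -= g * dy
            F[i, 2] -= g * dz
    # confinement wall
    if wall_r > 0.0:
        for i in range(n):
            rad = math.sqrt(x[i, 0] ** 2 + x[i, 1] ** 2 + x[i, 2] ** 2)
            if rad > wall_r:
                g = -wall_k * (rad - wall_r) / rad
                F[i, 0] += g * x[i, 0]
                F[i, 1] += g * x[i, 1]
                F[i, 2] += g * x[i, 2]


@njit(cache=True)
def _run_chunk(x, v, F, noise, temps, dt, friction,
               coeff, loop_pairs, chi, mu, rc, cutoff,
               bond_k, bond_r0, angle_k, rep_e, rep_r0, wall_k, wall_r):
    """Advance noise.shape[0] BAOAB steps in place; F holds current forces."""
    n = x.shape[0]
    c1 = math.exp(-friction * dt)
    amp = math.sqrt(1.0 - c1 * c1)
    half = 0.5 * dt
    for s in range(noise.shape[0]):
        c2 = amp * math.sqrt(temps[s])
        for i in range(n):
            for k in range(3):
                v[i, k] += half * F[i, k]
                x[i, k] += half * v[i, k]
                v[i, k] = c1 * v[i, k] + c2 * noise[s, i, k]
                x[i, k] += half * v[i, k]
        _compute_forces(x, coeff, loop_pairs, chi, mu, rc, cutoff,
                        bond_k, bond_r0, angle_k, rep_e, rep_r0,
                        wall_k, wall_r, F)
        for i in range(n):
            for k in range(3):
                v[i, k] += half * F[i, k]


# ---------------------------------------------------------------------------
# driver


def pair_coefficients(type_labels, params: MiChroMParams) -> np.ndarray:
    """(n, n) matrix of alpha + gamma coefficients for the f(r) pair term."""
    tidx = types_to_indices(type_labels)
    n = len(tidx)
    amat = params.alpha_matrix()
    gam = params.gamma_table()
    coeff = np.zeros((n, n))
    for i in range(n):
        for j in range(i + params.d_min, n):
            c = 0.0
            if tidx[i] >= 0 and tidx[j] >= 0:
                c += amat[tidx[i], tidx[j]]
            d = j - i
            if d <= params.d_max:
                c += gam[d]
            coeff[i, j] = coeff[j, i] = c
    return coeff


def _initial_chain(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Fold a unit-bond chain at random inside the confinement sphere."""
    limit = max(radius - 0.5, 1.0) if radius > 0 else np.inf
    x = np.zeros((n, 3))
    pos = np.zeros(3)
    for i in range(1, n):
        for _ in range(200):
            step = rng.normal(size=3)
            step /= np.linalg.norm(step)
            cand = pos + step
            if np.linalg.norm(cand) <= limit:
                pos = cand
                break
        else:  # pragma: no cover - pathological confinement
            pos = pos * (limit / (np.linalg.norm(pos) + 1e-12))
        x[i] = pos
    return x - x.mean(axis=0)


def simulate(type_labels, loops: LoopList | None, params: MiChroMParams,
             schedule: SimulationSchedule,
             confinement_radius_sigma: float | None = None,
             volume_fraction: float = 0.1,
             chunk_steps: int = 4000,
             compute_energies: bool = True,
             initial_coords: np.ndarray | None = None) -> SimEnsemble:
    """Run the annealed Langevin protocol and collect production frames.

    ``confinement_radius_sigma=None`` derives the territory radius from the
    locus count and ``volume_fraction``; pass ``0`` to disable the wall.
    """
    type_labels = np.asarray(type_labels, dtype=object)
    n = len(type_labels)
    loops = loops or LoopList()
    if len(loops) and loops.as_array().max() >= n:
        raise InvalidArgumentError("loop index out of range")
    if confinement_radius_sigma is None:
        confinement_radius_sigma = confinement_radius(n, volume_fraction)
    coeff = pair_coefficients(type_labels, params)
    loop_arr = (loops.as_array() if params.include_loops
                else np.empty((0, 2), dtype=np.int64))
    kernel_args = (coeff, loop_arr, params.chi, params.mu, params.rc,
                   params.cutoff, params.bond_k, params.bond_r0,
                   params.angle_k, params.rep_e, params.rep_r0,
                   params.wall_k, float(confinement_radius_sigma))

    frames: list[Structure3D] = []
    replicate_ids: list[int] = []
    ke_samples: list[float] = []
    for rep in range(schedule.n_replicates):
        rng = np.random.default_rng([schedule.seed, rep])
        x = (np.array(initial_coords, dtype=float) if initial_coords is not None
             else _initial_chain(n, confinement_radius_sigma, rng))
        v = rng.normal(scale=math.sqrt(schedule.T_start), size=(n, 3)) \
            if schedule.T_start > 0 else np.zeros((n, 3))
        F = np.zeros((n, 3))
        _compute_forces(x, *kernel_args, F)

        def run_phase(n_steps, dt, temps_of, save_every=None, offset=0):
            done = 0
            while done < n_steps:
                m = min(chunk_steps, n_steps - done)
                if save_every is not None:
                    # stop chunks on save boundaries
                    next_save = ((offset + done) // save_every + 1) * save_every
                    m = min(m, next_save - (offset + done))
                noise = rng.standard_normal((m, n, 3))
                temps = temps_of(offset + done + np.arange(m))
                _run_chunk(x, v, F, noise, temps, dt, schedule.friction,
                           *kernel_args)
                done += m
                if not np.all(np.isfinite(x)):
                    raise SimulationError(
                        f"replicate {rep}: non-finite coordinates after "
                        f"{offset + done} steps (dt={dt})")
                if save_every is not None and (offset + done) % save_every == 0:
                    frames.append(Structure3D(
                        coords=x.copy(), units=UNIT_REDUCED,
                        structure_id=f"r{rep:02d}s{offset + done}"))
                    replicate_ids.append(rep)
                    ke_samples.append(float(0.5 * (v ** 2).sum() / n))

        # annealing: linear ramp T_start -> T_end
        ramp = schedule.T_start - schedule.T_end
        run_phase(schedule.anneal_steps, schedule.dt_anneal,
                  lambda s: schedule.T_start -
                  ramp * (s + 1) / schedule.anneal_steps)
        # production at T_end, saving frames
        run_phase(schedule.prod_steps, schedule.dt_prod,
                  lambda s: np.full(len(s), schedule.T_end),
                  save_every=schedule.save_every)

    energies = pd.DataFrame()
    if compute_energies and frames:
        rows = [energy(f, type_labels, loops, params,
                       confinement_radius_sigma or None) for f in frames]
        energies = pd.DataFrame(rows)
        energies.insert(0, "replicate", replicate_ids)
    diagnostics = {
        "mean_kinetic_per_particle": float(np.mean(ke_samples)) if ke_samples else np.nan,
        "kinetic_per_particle": np.asarray(ke_samples),
        "n_replicates": schedule.n_replicates,
        "seed": schedule.seed,
    }
    return SimEnsemble(frames=frames, replicate_ids=replicate_ids,
                       type_labels=type_labels, loops=loops,
                       confinement_radius=float(confinement_radius_sigma),
                       energies=energies, diagnostics=diagnostics)
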