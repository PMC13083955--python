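"""Langevin dynamics for residue-bead chains.

A BAOAB-discretised Langevin integrator over the coarse-grained force field
defined in :mod:`stigroove.cg_model`: harmonic backbone bonds, elastic-network
restraints for folded domains, the hydropathy-scaled 12-6 pair potential and
Debye–Hückel electrostatics.  Pairs covered by bonds or restraints are
excluded from the nonbonded sum.  Forces are evaluated with a dense O(n^2)
pair list, which is the right trade-off for single chains of a few hundred
beads.

Frame convention: frame k of a trajectory records the coordinates at time
``k * save_interval`` counted from the start of the run, so a run of
duration T at save interval d yields ``floor(T/d)`` frames covering
[0, T).  Equilibration trimming removes frames with time < cut, which makes
the production frame count ``floor((T - cut)/d)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .cg_model import (
    KB,
    COULOMB_KJ_NM,
    ChainTopology,
    SimulationConfig,
    ValidationError,
    debye_kappa,
    dielectric_constant,
)


class SimulationError(RuntimeError):
    """Raised when integration produces non-finite coordinates or energies."""


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Ordered frames of bead coordinates (nm) at fixed spacing (ps)."""

    xyz: np.ndarray                      # (n_frames, n_beads, 3) nm
    dt_ps: float                         # frame spacing
    replica_id: int = 0
    config_hash: str = ""
    time_origin_ps: float = 0.0
    velocities: np.ndarray | None = None  # (n_frames, n_beads, 3) nm/ps

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 3 or self.xyz.shape[-1] != 3:
            raise ValidationError("trajectory xyz must be (frames, beads, 3)")
        if not np.all(np.isfinite(self.xyz)):
            raise ValidationError("trajectory contains non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def n_beads(self) -> int:
        return self.xyz.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return self.time_origin_ps + self.dt_ps * np.arange(self.n_frames)

    @property
    def duration_ps(self) -> float:
        return self.dt_ps * self.n_frames


def production_frame_count(duration_ns: float, equilibration_ns: float,
                           save_interval_ps: float) -> int:
    """Closed-form frame count after equilibration trimming."""
    span_ps = (duration_ns - equilibration_ns) * 1000.0
    return int(math.floor(round(span_ps / save_interval_ps, 9)))


def trim_equilibration(trajectory: Trajectory, cut_ns: float) -> Trajectory:
    """Drop frames with time < cut; spacing is preserved."""
    cut_ps = cut_ns * 1000.0
    if cut_ps >= trajectory.duration_ps:
        raise ValidationError(
            f"equilibration cut {cut_ns} ns >= trajectory duration "
            f"{trajectory.duration_ps / 1000.0} ns")
    keep = trajectory.times_ps >= cut_ps - 1e-9 * trajectory.dt_ps
    first = int(np.argmax(keep))
    return replace(
        trajectory,
        xyz=trajectory.xyz[first:],
        time_origin_ps=trajectory.time_origin_ps + first * trajectory.dt_ps,
        velocities=None if trajectory.velocities is None else trajectory.velocities[first:],
    )


# ---------------------------------------------------------------------------
# Force field precomputation
# ---------------------------------------------------------------------------

@dataclass
class _ForceField:
    bond_i: np.ndarray
    bond_j: np.ndarray
    bond_r0: np.ndarray
    bond_k: np.ndarray
    rest_i: np.ndarray
    rest_j: np.ndarray
    rest_r0: np.ndarray
    rest_k: np.ndarray
    pair_i: np.ndarray
    pair_j: np.ndarray
    sigma_ij: np.ndarray
    lambda_ij: np.ndarray
    qq_ij: np.ndarray
    epsilon: float
    ah_cutoff: float
    dh_cutoff: float
    dh_prefactor: float        # Coulomb const / eps_r, kJ nm/mol
    kappa: float               # 1/nm
    masses: np.ndarray = field(default=None)


def _build_forcefield(topology: ChainTopology, config: SimulationConfig) -> _ForceField:
    n = topology.n_beads
    excluded = topology.excluded_pairs
    ii, jj = np.triu_indices(n, k=2)
    keep = np.fromiter(((int(a), int(b)) not in excluded for a, b in zip(ii, jj)),
                       dtype=bool, count=len(ii))
    ii, jj = ii[keep], jj[keep]
    eps_r = dielectric_constant(config.temperature)
    rests = topology.restraints or []
    return _ForceField(
        bond_i=np.array([b[0] for b in topology.bonds], dtype=int),
        bond_j=np.array([b[1] for b in topology.bonds], dtype=int),
        bond_r0=np.array([b[2] for b in topology.bonds], dtype=float),
        bond_k=np.array([b[3] for b in topology.bonds], dtype=float),
        rest_i=np.array([r[0] for r in rests], dtype=int),
        rest_j=np.array([r[1] for r in rests], dtype=int),
        rest_r0=np.array([r[2] for r in rests], dtype=float),
        rest_k=np.array([r[3] for r in rests], dtype=float),
        pair_i=ii,
        pair_j=jj,
        sigma_ij=0.5 * (topology.sigmas[ii] + topology.sigmas[jj]),
        lambda_ij=0.5 * (topology.lambdas[ii] + topology.lambdas[jj]),
        qq_ij=topology.charges[ii] * topology.charges[jj],
        epsilon=topology.epsilon,
        ah_cutoff=topology.ah_cutoff,
        dh_cutoff=topology.dh_cutoff,
        dh_prefactor=COULOMB_KJ_NM / eps_r,
        kappa=debye_kappa(config.ionic_strength, config.temperature, dielectric=eps_r),
        masses=np.asarray(topology.masses, dtype=float),
    )


def _accumulate(f: np.ndarray, fi: np.ndarray, fj: np.ndarray, fvec: np.ndarray) -> None:
    n = f.shape[0]
    for d in range(3):
        f[:, d] += np.bincount(fi, weights=fvec[:, d], minlength=n)
        f[:, d] -= np.bincount(fj, weights=fvec[:, d], minlength=n)


def _harmonic_forces(x, fi, fj, r0, k, f):
    if len(fi) == 0:
        return 0.0
    dx = x[fj] - x[fi]
    d = np.sqrt(np.einsum("ij,ij->i", dx, dx))
    fmag = k * (d - r0)                      # dU/dd
    fvec = (fmag / d)[:, None] * dx          # force on i along +dx
    _accumulate(f, fi, fj, fvec)
    return float(np.sum(0.5 * k * (d - r0) ** 2))


def _forces(x: np.ndarray, ff: _ForceField) -> tuple[np.ndarray, float]:
    """Total force (kJ/mol/nm) and potential energy (kJ/mol)."""
    f = np.zeros_like(x)
    energy = _harmonic_forces(x, ff.bond_i, ff.bond_j, ff.bond_r0, ff.bond_k, f)
    energy += _harmonic_forces(x, ff.rest_i, ff.rest_j, ff.rest_r0, ff.rest_k, f)

    if len(ff.pair_i):
        dx = x[ff.pair_j] - x[ff.pair_i]
        r = np.sqrt(np.einsum("ij,ij->i", dx, dx))
        dudr = np.zeros_like(r)
        # hydropathy-scaled 12-6
        within = r <= ff.ah_cutoff
        if np.any(within):
            rr = r[within]
            sig = ff.sigma_ij[within]
            lam = ff.lambda_ij[within]
            s6 = (sig / rr) ** 6
            lj = 4.0 * ff.epsilon * (s6 * s6 - s6)
            dlj = -24.0 * ff.epsilon * (2.0 * s6 * s6 - s6) / rr
            rmin = 2.0 ** (1.0 / 6.0) * sig
            rep = rr <= rmin
            e_ah = np.where(rep, lj + (1.0 - lam) * ff.epsilon, lam * lj)
            d_ah = np.where(rep, dlj, lam * dlj)
            energy += float(np.sum(e_ah))
            dudr[within] += d_ah
        # Debye-Hückel
        charged = (ff.qq_ij != 0.0) & (r <= ff.dh_cutoff)
        if np.any(charged):
            rr = r[charged]
            qq = ff.qq_ij[charged]
            screen = np.exp(-ff.kappa * rr)
            e_dh = ff.dh_prefactor * qq * screen / rr
            d_dh = -ff.dh_prefactor * qq * screen * (ff.kappa * rr + 1.0) / rr ** 2
            energy += float(np.sum(e_dh))
            dudr[charged] += d_dh
        fvec = (dudr / r)[:, None] * dx
        _accumulate(f, ff.pair_i, ff.pair_j, fvec)
    return f, energy


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def extended_coords(n: int, bond_r0: float = 0.38, zig: float = 0.19) -> np.ndarray:
    """Planar zigzag starting coordinates with exact bond lengths (nm)."""
    dx = math.sqrt(bond_r0 ** 2 - zig ** 2)
    x = np.zeros((n, 3))
    x[:, 0] = dx * np.arange(n)
    x[:, 1] = zig * (np.arange(n) % 2)
    return x


def perturb_linkers(coords: np.ndarray, topology: ChainTopology,
                    rng: np.random.Generator, scale: float = 0.02) -> np.ndarray:
    """Jitter linker (non-domain) beads to vary replica starting conformations.

    Folded-domain beads are left untouched so the elastic network starts at
    its reference geometry; disordered beads receive isotropic Gaussian
    displacements of width ``scale`` nm.
    """
    out = np.asarray(coords, float).copy()
    in_domain = np.zeros(topology.n_beads, dtype=bool)
    for d in topology.domains:
        in_domain[d.indices] = True
    linkers = ~in_domain
    out[linkers] += rng.normal(0.0, scale, size=(int(linkers.sum()), 3))
    return out


def run_langevin(
    topology: ChainTopology,
    config: SimulationConfig,
    seed: int,
    initial_coords: np.ndarray | None = None,
    replica_id: int = 0,
    record_velocities: bool = False,
    out_dir: str | Path | None = None,
) -> Trajectory:
    """Integrate Langevin dynamics and return the saved trajectory.

    Uses the BAOAB splitting with friction ``config.friction_per_ps`` and
    timestep ``config.timestep_fs``; initial velocities are drawn from the
    Maxwell–Boltzmann distribution at the target temperature from ``seed``.
    Frames are saved every ``config.save_interval_ps`` starting at time 0
    (frame k holds time k*save_interval), so the run produces
    ``floor(duration/save_interval)`` frames.  A YAML run manifest is written
    when ``out_dir`` is given.  Raises :class:`SimulationError` with the
    offending frame index if coordinates or energy become non-finite.
    """
    topology.validate()
    rng = np.random.default_rng(seed)
    ff = _build_forcefield(topology, config)
    n = topology.n_beads
    m = ff.masses[:, None]

    if initial_coords is None:
        if topology.reference_coords is not None:
            x = topology.reference_coords.copy()
        else:
            x = extended_coords(n)
    else:
        x = np.asarray(initial_coords, dtype=float).copy()
        if x.shape != (n, 3):
            raise ValidationError(f"initial coords shape {x.shape} != ({n}, 3)")

    kt = KB * config.temperature
    v = rng.normal(0.0, 1.0, size=(n, 3)) * np.sqrt(kt / m)

    dt = config.timestep_fs * 1e-3                   # ps
    gamma = config.friction_per_ps
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma_v = np.sqrt(kt / m)

    steps = int(round(config.duration_ns * 1000.0 / dt))
    stride = max(1, int(round(config.save_interval_ps / dt)))
    n_save = math.floor(steps / stride) if steps > 0 else 0

    frames = np.empty((max(1, n_save), n, 3))
    vels = np.empty_like(frames) if record_velocities else None
    f, energy = _forces(x, ff)
    saved = 0
    for step in range(steps):
        if step % stride == 0:
            frames[saved] = x
            if record_velocities:
                vels[saved] = v
            saved += 1
        # BAOAB
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        v = c1 * v + c2 * sigma_v * rng.normal(0.0, 1.0, size=(n, 3))
        x += 0.5 * dt * v
        f, energy = _forces(x, ff)
        if not (np.all(np.isfinite(x)) and np.isfinite(energy)):
            raise SimulationError(
                f"non-finite coordinates/energy at step {step} (frame {saved})")
        v += 0.5 * dt * f / m
    if steps == 0:
        frames[0] = x
        if record_velocities:
            vels[0] = v
        saved = 1

    traj = Trajectory(
        xyz=frames[:saved],
        dt_ps=config.save_interval_ps if steps > 0 else 0.0,
        replica_id=replica_id,
        config_hash=topology.config_hash(),
        velocities=None if vels is None else vels[:saved],
    )
    if out_dir is not None:
        write_manifest(Path(out_dir), topology, config, seed, replica_id)
    return traj


def run_replicas(
    topology: ChainTopology,
    config: SimulationConfig,
    seed_base: int,
    initial_coords: np.ndarray | None = None,
    perturb_scale: float = 0.02,
) -> list[Trajectory]:
    """Run ``config.n_replicas`` independent trajectories.

    Replica r uses seed ``seed_base + r`` (or ``config.seeds`` when set) for
    both its starting-conformation jitter and its thermal noise, then trims
    the configured equilibration span.
    """
    seeds = config.seeds or tuple(seed_base + r for r in range(config.n_replicas))
    base = initial_coords
    if base is None:
        base = (topology.reference_coords if topology.reference_coords is not None
                else extended_coords(topology.n_beads))
    out = []
    for r, s in enumerate(seeds):
        rng = np.random.default_rng(int(s) * 2 + 1)
        x0 = perturb_linkers(base, topology, rng, scale=perturb_scale)
        traj = run_langevin(topology, config, seed=int(s), initial_coords=x0, replica_id=r)
        if config.equilibration_ns > 0:
            traj = trim_equilibration(traj, config.equilibration_ns)
        out.append(traj)
    return out


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> tuple[float, float]:
    """Equipartition temperature estimate (K) with standard error.

    ``velocities`` is (n_samples, n_beads, 3) in nm/ps; requires >= 100
    samples for a meaningful standard error.
    """
    v = np.asarray(velocities, dtype=float)
    if v.ndim != 3 or v.shape[0] < 100:
        raise ValidationError("need >= 100 velocity samples of shape (S, N, 3)")
    m = np.asarray(masses, dtype=float)
    ke = 0.5 * np.sum(m[None, :, None] * v ** 2, axis=(1, 2))   # kJ/mol per sample
    t_samples = 2.0 * ke / (3.0 * v.shape[1] * KB)
    return float(t_samples.mean()), float(t_samples.std(ddof=1) / math.sqrt(len(t_samples)))


def potential_energy(x: np.ndarray, topology: ChainTopology,
                     config: SimulationConfig) -> float:
    """Potential energy of a single frame (kJ/mol)."""
    ff = _build_forcefield(topology, config)
    _, e = _forces(np.asarray(x, float), ff)
    return e


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _mdtraj_topology(n_beads: int, sequence: str | None = None):
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    carbon = md.element.carbon
    for i in range(n_beads):
        res = top.add_residue("GLY", chain, resSeq=i + 1)
        top.add_atom("CA", carbon, res)
    for i in range(n_beads - 1):
        top.add_bond(top.atom(i), top.atom(i + 1))
    return top


def write_trajectory(trajectory: Trajectory, path: str | Path,
                     topology_pdb: str | Path | None = None,
                     sequence: str | None = None) -> None:
    """Save frames as DCD or XTC (by extension), optionally with a PDB frame."""
    import mdtraj as md

    top = _mdtraj_topology(trajectory.n_beads, sequence)
    t = md.Trajectory(trajectory.xyz, top,
                      time=trajectory.times_ps)
    path = Path(path)
    t.save(str(path))
    if topology_pdb is not None:
        t[0].save_pdb(str(topology_pdb))


def read_trajectory(path: str | Path, topology_pdb: str | Path,
                    dt_ps: float | None = None, replica_id: int = 0) -> Trajectory:
    """Load a DCD/XTC trajectory (with PDB topology) into a Trajectory."""
    import mdtraj as md

    t = md.load(str(path), top=str(topology_pdb))
    if dt_ps is None:
        dt_ps = float(t.timestep) if t.n_frames > 1 else 0.0
    return Trajectory(xyz=t.xyz.astype(float), dt_ps=dt_ps, replica_id=replica_id,
                      time_origin_ps=float(t.time[0]) if t.n_frames else 0.0)


def write_manifest(out_dir: Path, topology: ChainTopology,
                   config: SimulationConfig, seed: int, replica_id: int) -> Path:
    from . import __version__

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software_version": __version__,
        "topology_hash": topology.config_hash(),
        "replica_id": replica_id,
        "seed": seed,
        "config": {
            "temperature_K": config.temperature,
            "ph": config.ph,
            "ionic_strength_M": config.ionic_strength,
            "duration_ns": config.duration_ns,
            "equilibration_ns": config.equilibration_ns,
            "friction_per_ps": config.friction_per_ps,
            "timestep_fs": config.timestep_fs,
            "save_interval_ps": config.save_interval_ps,
            "n_replicas": config.n_replicas,
        },
    }
    path = out_dir / f"manifest_replica{replica_id}.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path
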