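"""Coarse-grained chain model: one bead per residue.

Builds the residue-bead representation used throughout the package: a
per-residue parameter table (stickiness lambda, size sigma, charge, mass),
harmonic backbone bonds, an elastic network restraining folded domains, and
the two nonbonded pair energies — a hydropathy-scaled short-range potential
(Ashbaugh–Hatch form) and Debye–Hückel screened electrostatics.  Variant
builders produce the excluded-volume null model (all stickiness and charge
zeroed) and the bound-domain topology in which two folded domains are held
together by a shared elastic network.

Units follow the GROMACS convention: lengths in nm, energies in kJ/mol,
masses in Da, charges in elementary charges, temperature in K.  Residue
numbering is 1-based inclusive, matching the UniProt sequence; bead indices
in code are 0-based.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

# --- physical constants (GROMACS units) ---
KB = 0.00831446261815324          # kJ/(mol K)
COULOMB_KJ_NM = 138.935458        # kJ nm / (mol e^2) == e^2/(4 pi eps0) * N_A
AVOGADRO = 6.02214076e23

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# model defaults (overridable everywhere they are used)
DEFAULT_EPSILON = 0.8368          # kJ/mol pair-interaction strength
DEFAULT_BOND_R0 = 0.38            # nm
DEFAULT_BOND_K = 8033.0           # kJ/(mol nm^2)
DEFAULT_ENM_CUTOFF = 0.9          # nm
DEFAULT_ENM_K = 700.0             # kJ/(mol nm^2)
DEFAULT_AH_CUTOFF = 2.0           # nm
DEFAULT_DH_CUTOFF = 4.0           # nm
DEFAULT_HIS_PKA = 6.0


class ValidationError(ValueError):
    """Raised when an input table, topology or config violates an invariant."""


# ---------------------------------------------------------------------------
# Parameter table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueParameterTable:
    """Per-amino-acid bead parameters.

    ``table`` is indexed by one-letter residue code with columns
    ``lambda`` (stickiness, 0–1), ``sigma`` (nm), ``charge`` (e) and
    ``mass`` (Da); exactly the 20 standard amino acids.
    """

    table: pd.DataFrame
    version: str = "1"

    def __post_init__(self) -> None:
        t = self.table
        missing = sorted(set(STANDARD_AA) - set(t.index))
        if missing:
            raise ValidationError(f"parameter table missing residues: {missing}")
        extra = sorted(set(t.index) - set(STANDARD_AA))
        if extra:
            raise ValidationError(f"parameter table has unknown residues: {extra}")
        for aa in STANDARD_AA:
            row = t.loc[aa]
            if not 0.0 <= row["lambda"] <= 1.0:
                raise ValidationError(f"residue {aa}: lambda {row['lambda']} outside [0, 1]")
            if row["sigma"] <= 0:
                raise ValidationError(f"residue {aa}: sigma {row['sigma']} must be > 0")
            if row["mass"] <= 0:
                raise ValidationError(f"residue {aa}: mass {row['mass']} must be > 0")

    def lookup(self, sequence: str, column: str) -> np.ndarray:
        return self.table[column].reindex(list(sequence)).to_numpy(float)


def load_parameter_table(source: str | Path | None = None) -> ResidueParameterTable:
    """Load a residue parameter CSV; ``None`` loads the bundled default table.

    The CSV must have a header row ``residue,lambda,sigma,charge,mass``
    (comment lines starting with ``#`` are skipped).
    """
    if source is None:
        ref = importlib.resources.files("stigroove").joinpath("data/residue_params.csv")
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, comment="#")
    else:
        df = pd.read_csv(source, comment="#")
    required = {"residue", "lambda", "sigma", "charge", "mass"}
    if not required.issubset(df.columns):
        raise ValidationError(f"parameter CSV must have columns {sorted(required)}")
    return ResidueParameterTable(df.set_index("residue"))


# ---------------------------------------------------------------------------
# Domain annotations and simulation config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainAnnotation:
    """A folded domain: 1-based inclusive residue span and its restraint group."""

    name: str
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    restraint_group: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"domain {self.name}: bad span {self.start}-{self.end}")
        if self.restraint_group is None:
            object.__setattr__(self, "restraint_group", self.name)

    @property
    def indices(self) -> np.ndarray:
        """0-based bead indices covered by this domain."""
        return np.arange(self.start - 1, self.end)


@dataclass
class SimulationConfig:
    """Langevin run parameters (temperature K, pH, ionic strength M, times)."""

    temperature: float = 298.15
    ph: float = 6.8
    ionic_strength: float = 0.22
    duration_ns: float = 70.0
    equilibration_ns: float = 3.5
    friction_per_ps: float = 0.01
    timestep_fs: float = 10.0
    save_interval_ps: float = 0.5
    n_replicas: int = 10
    seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValidationError("timestep must be > 0")
        if self.equilibration_ns >= self.duration_ns:
            raise ValidationError("equilibration cut must be < duration")
        if self.n_replicas < 1:
            raise ValidationError("replica count must be >= 1")
        if self.ionic_strength < 0:
            raise ValidationError("ionic strength must be >= 0")


# ---------------------------------------------------------------------------
# Charges
# ---------------------------------------------------------------------------

def assign_charges(
    sequence: str,
    ph: float,
    his_pka: float = DEFAULT_HIS_PKA,
    include_termini: bool = True,
) -> np.ndarray:
    """Per-residue charges in elementary charges.

    Asp/Glu are -1, Lys/Arg +1, His carries the Henderson–Hasselbalch
    fractional charge ``1/(1 + 10^(pH - pKa))``; when ``include_termini``
    the first bead gains +1 (amino terminus) and the last -1 (carboxyl).
    """
    if not sequence:
        raise ValidationError("empty sequence")
    bad = sorted(set(sequence) - set(STANDARD_AA))
    if bad:
        raise ValidationError(f"non-standard residue codes: {bad}")
    his_q = 1.0 / (1.0 + 10.0 ** (ph - his_pka))
    base = {aa: 0.0 for aa in STANDARD_AA}
    base.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": his_q})
    q = np.array([base[aa] for aa in sequence], dtype=float)
    if include_termini:
        q[0] += 1.0
        q[-1] -= 1.0
    return q


# ---------------------------------------------------------------------------
# Pair energies
# ---------------------------------------------------------------------------

def ah_energy(
    r,
    sigma_ij: float,
    lambda_ij: float,
    epsilon: float = DEFAULT_EPSILON,
    cutoff: float = DEFAULT_AH_CUTOFF,
    shift: bool = False,
):
    """Hydropathy-scaled 12-6 pair energy (Ashbaugh–Hatch form), kJ/mol.

    With ``L(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6]`` the energy is
    ``L(r) + (1 - lambda) eps`` for ``r <= 2^(1/6) sigma`` and
    ``lambda L(r)`` beyond, truncated to zero past ``cutoff``.  The two
    branches meet at ``-lambda eps`` at the minimum, so the potential is
    continuous for every (lambda, sigma, eps).  ``shift=True`` subtracts the
    value at the cutoff from the attractive branch (truncate-and-shift).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("ah_energy requires r > 0")
    rmin = 2.0 ** (1.0 / 6.0) * sigma_ij
    sr6 = (sigma_ij / r) ** 6
    lj = 4.0 * epsilon * (sr6 * sr6 - sr6)
    lj_cut = 0.0
    if shift:
        src6 = (sigma_ij / cutoff) ** 6
        lj_cut = 4.0 * epsilon * (src6 * src6 - src6)
    e = np.where(
        r <= rmin,
        lj - lambda_ij * lj_cut + (1.0 - lambda_ij) * epsilon,
        lambda_ij * (lj - lj_cut),
    )
    e = np.where(r > cutoff, 0.0, e)
    return float(e) if e.ndim == 0 else e


def dielectric_constant(temperature: float) -> float:
    """Temperature-dependent relative permittivity of water (empirical fit)."""
    t = temperature
    return 5321.0 / t + 233.76 - 0.9297 * t + 1.417e-3 * t * t - 8.292e-7 * t ** 3


def debye_kappa(ionic_strength: float, temperature: float, dielectric: float | None = None) -> float:
    """Inverse Debye screening length in 1/nm for a 1:1 electrolyte."""
    if ionic_strength < 0:
        raise ValidationError("ionic strength must be >= 0")
    eps_r = dielectric_constant(temperature) if dielectric is None else dielectric
    bjerrum = COULOMB_KJ_NM / (eps_r * KB * temperature)        # nm
    n_per_nm3 = ionic_strength * AVOGADRO * 1e-24               # ions/nm^3 per species
    return math.sqrt(8.0 * math.pi * bjerrum * n_per_nm3)


def dh_energy(
    r,
    qi: float,
    qj: float,
    ionic_strength: float,
    temperature: float,
    cutoff: float = DEFAULT_DH_CUTOFF,
    dielectric: float | None = None,
):
    """Debye–Hückel screened Coulomb energy, kJ/mol.

    ``B(eps_r) qi qj exp(-kappa r)/r`` with the Coulomb prefactor
    ``B = 138.935 / eps_r`` kJ nm/mol/e^2 and kappa from the ionic strength;
    zero beyond ``cutoff``.  ``dielectric`` overrides the temperature-
    dependent water permittivity.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("dh_energy requires r > 0")
    eps_r = dielectric_constant(temperature) if dielectric is None else dielectric
    kappa = debye_kappa(ionic_strength, temperature, dielectric=eps_r)
    e = COULOMB_KJ_NM / eps_r * qi * qj * np.exp(-kappa * r) / r
    e = np.where(r > cutoff, 0.0, e)
    return float(e) if e.ndim == 0 else e


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass
class ChainTopology:
    """Beads, bonds, elastic-network restraints and per-bead parameters.

    ``bonds`` are (i, j, r0 nm, k) over consecutive beads only; ``restraints``
    are (i, j, r0 nm, k) elastic-network pairs within one restraint group.
    Pairs appearing in bonds or restraints are excluded from nonbonded
    interactions.
    """

    sequence: str
    masses: np.ndarray
    charges: np.ndarray
    lambdas: np.ndarray
    sigmas: np.ndarray
    bonds: list[tuple[int, int, float, float]]
    restraints: list[tuple[int, int, float, float]]
    domains: list[DomainAnnotation] = field(default_factory=list)
    reference_coords: np.ndarray | None = None   # (n, 3) nm
    epsilon: float = DEFAULT_EPSILON
    ah_cutoff: float = DEFAULT_AH_CUTOFF
    dh_cutoff: float = DEFAULT_DH_CUTOFF

    @property
    def n_beads(self) -> int:
        return len(self.sequence)

    @property
    def excluded_pairs(self) -> set[tuple[int, int]]:
        ex = {(i, j) for i, j, _, _ in self.bonds}
        ex |= {(i, j) for i, j, _, _ in self.restraints}
        return ex

    def validate(self) -> None:
        n = self.n_beads
        for arr, name in ((self.masses, "masses"), (self.charges, "charges"),
                          (self.lambdas, "lambdas"), (self.sigmas, "sigmas")):
            if len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != sequence length {n}")
        for i, j, r0, _ in self.bonds:
            if j != i + 1:
                raise ValidationError(f"bond ({i},{j}) does not connect consecutive beads")
            if r0 <= 0:
                raise ValidationError(f"bond ({i},{j}) has non-positive r0")
        bond_set = {(i, j) for i, j, _, _ in self.bonds}
        for i, j, r0, _ in self.restraints:
            if (i, j) in bond_set:
                raise ValidationError(f"pair ({i},{j}) in both bonds and restraints")
            if r0 <= 0:
                raise ValidationError(f"restraint ({i},{j}) has non-positive reference distance")
        for d in self.domains:
            if d.end > n:
                raise ValidationError(f"domain {d.name} span exceeds sequence length {n}")

    def config_hash(self) -> str:
        h = hashlib.sha256()
        h.update(self.sequence.encode())
        for arr in (self.masses, self.charges, self.lambdas, self.sigmas):
            h.update(np.asarray(arr, float).tobytes())
        h.update(repr(sorted(self.bonds)).encode())
        h.update(repr(sorted(self.restraints)).encode())
        return h.hexdigest()[:16]


def _enm_pairs(
    coords: np.ndarray,
    groups: dict[str, np.ndarray],
    cutoff: float,
    k: float,
    bonded: set[tuple[int, int]],
) -> list[tuple[int, int, float, float]]:
    """All non-bonded pairs |i-j| >= 2 within one group closer than cutoff."""
    restraints = []
    for indices in groups.values():
        idx = np.asarray(indices)
        sub = coords[idx]
        d = np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = int(idx[a]), int(idx[b])
                if j - i < 2 or (i, j) in bonded:
                    continue
                if d[a, b] < cutoff:
                    restraints.append((i, j, float(d[a, b]), k))
    return restraints


def build_topology(
    sequence: str,
    params: ResidueParameterTable,
    reference_coords: np.ndarray | None = None,
    domains: Sequence[DomainAnnotation] = (),
    enm_cutoff: float = DEFAULT_ENM_CUTOFF,
    enm_k: float = DEFAULT_ENM_K,
    bond_r0: float = DEFAULT_BOND_R0,
    bond_k: float = DEFAULT_BOND_K,
    ph: float = 6.8,
    his_pka: float = DEFAULT_HIS_PKA,
    include_termini: bool = True,
    lambda_override: np.ndarray | None = None,
) -> ChainTopology:
    """Assemble a ChainTopology from sequence, parameters and reference coords.

    Consecutive beads are bonded harmonically; every non-bonded pair
    (|i-j| >= 2) inside one restraint group whose reference distance is
    below ``enm_cutoff`` gets an elastic-network restraint at ``enm_k`` with
    the reference distance as equilibrium length.  Restrained pairs are
    excluded from nonbonded interactions.  ``lambda_override`` replaces the
    table stickiness per bead (used for buried-residue rescaling).
    """
    domains = list(domains)
    n = len(sequence)
    if reference_coords is not None:
        reference_coords = np.asarray(reference_coords, dtype=float)
        if reference_coords.shape != (n, 3):
            raise ValidationError(
                f"reference_coords shape {reference_coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(reference_coords)):
            raise ValidationError("reference_coords contain non-finite values")
    for d in domains:
        if d.end > n:
            raise ValidationError(f"domain {d.name} span {d.start}-{d.end} exceeds sequence")

    charges = assign_charges(sequence, ph, his_pka, include_termini)
    lambdas = params.lookup(sequence, "lambda")
    if lambda_override is not None:
        lambdas = np.asarray(lambda_override, dtype=float)
        if len(lambdas) != n:
            raise ValidationError("lambda_override length mismatch")

    bonds = [(i, i + 1, bond_r0, bond_k) for i in range(n - 1)]
    restraints: list[tuple[int, int, float, float]] = []
    if domains and reference_coords is not None and enm_cutoff > 0:
        groups: dict[str, list[int]] = {}
        for d in domains:
            groups.setdefault(d.restraint_group, []).extend(d.indices.tolist())
        bonded = {(i, j) for i, j, _, _ in bonds}
        restraints = _enm_pairs(
            reference_coords,
            {g: np.array(sorted(set(v))) for g, v in groups.items()},
            enm_cutoff, enm_k, bonded,
        )

    topo = ChainTopology(
        sequence=sequence,
        masses=params.lookup(sequence, "mass"),
        charges=charges,
        lambdas=lambdas,
        sigmas=params.lookup(sequence, "sigma"),
        bonds=bonds,
        restraints=restraints,
        domains=domains,
        reference_coords=reference_coords,
    )
    topo.validate()
    return topo


def excluded_volume_variant(topology: ChainTopology, keep_charges: bool = False) -> ChainTopology:
    """Null-model copy: all stickiness zeroed (and charges, unless kept).

    Bonds and elastic restraints are untouched, so the variant measures what
    chain connectivity and sterics alone produce.
    """
    new = replace(
        topology,
        lambdas=np.zeros_like(topology.lambdas),
        charges=topology.charges.copy() if keep_charges else np.zeros_like(topology.charges),
        bonds=list(topology.bonds),
        restraints=list(topology.restraints),
    )
    new.validate()
    return new


def bound_complex_variant(
    topology: ChainTopology,
    groups_to_merge: Sequence[str],
    merged_reference_coords: np.ndarray,
    enm_cutoff: float = DEFAULT_ENM_CUTOFF,
    enm_k: float = DEFAULT_ENM_K,
) -> ChainTopology:
    """Topology variant with two (or more) restraint groups elastically fused.

    The elastic network over the merged groups is rebuilt from the bound-pose
    coordinates, so pairs across the group boundary that are within
    ``enm_cutoff`` in the bound pose become restrained; groups not being
    merged keep their original restraints.  ``merged_reference_coords`` is a
    full-length (n, 3) array that must be finite for every bead of the
    merged groups.
    """
    merged_reference_coords = np.asarray(merged_reference_coords, dtype=float)
    if merged_reference_coords.shape != (topology.n_beads, 3):
        raise ValidationError("merged_reference_coords must be (n_beads, 3)")
    merge_set = set(groups_to_merge)
    merged_idx: list[int] = []
    for d in topology.domains:
        if d.restraint_group in merge_set:
            merged_idx.extend(d.indices.tolist())
    merged_idx = sorted(set(merged_idx))
    if not merged_idx:
        raise ValidationError(f"no domain belongs to groups {sorted(merge_set)}")
    if not np.all(np.isfinite(merged_reference_coords[merged_idx])):
        raise ValidationError("missing (non-finite) coordinates for merged-group beads")

    kept = [r for r in topology.restraints
            if not _pair_in(r, merged_idx)]
    bonded = {(i, j) for i, j, _, _ in topology.bonds}
    new_restraints = _enm_pairs(
        merged_reference_coords,
        {"merged": np.array(merged_idx)},
        enm_cutoff, enm_k, bonded,
    )
    new = replace(topology, restraints=kept + new_restraints)
    new.validate()
    return new


def _pair_in(restraint: tuple[int, int, float, float], indices: Sequence[int]) -> bool:
    s = set(indices)
    return restraint[0] in s and restraint[1] in s


def rescale_buried_lambda(
    lambdas: np.ndarray,
    relative_sasa: np.ndarray,
    domain_indices: np.ndarray,
    buried_rsasa: float = 0.2,
    buried_scale: float = 0.7,
) -> np.ndarray:
    """Scale the stickiness of buried folded-domain residues.

    Residues of a folded domain whose relative solvent accessibility falls
    below ``buried_rsasa`` have lambda multiplied by ``buried_scale``: buried
    side chains should not contribute full hydropathy to surface contacts.
    Only indices in ``domain_indices`` are touched.
    """
    out = np.asarray(lambdas, dtype=float).copy()
    rs = np.asarray(relative_sasa, dtype=float)
    for i in np.asarray(domain_indices, dtype=int):
        if rs[i] < buried_rsasa:
            out[i] *= buried_scale
    return out


# ---------------------------------------------------------------------------
# Structure / sequence I/O
# ---------------------------------------------------------------------------

def read_fasta_sequence(path: str | Path) -> str:
    """First record of a FASTA file as an upper-case one-letter string."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def residue_com_from_structure(path: str | Path, chain: str | None = None) -> tuple[str, np.ndarray]:
    """Sequence and heavy-atom center-of-mass bead coordinates from PDB/mmCIF.

    Each residue becomes one bead placed at the mass-weighted center of its
    heavy atoms (hydrogens excluded).  Returns (sequence, coords) with
    coordinates in nm.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = [c for c in model if chain is None or c.name == chain]
    if not chains:
        raise ValidationError(f"chain {chain!r} not found in {path}")
    seq = []
    coords = []
    for res in chains[0]:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        one = gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
        total_mass = 0.0
        com = np.zeros(3)
        for atom in res:
            if atom.element.name == "H":
                continue
            m = atom.element.weight
            com += m * np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            total_mass += m
        if total_mass == 0:
            continue
        seq.append(one)
        coords.append(com / total_mass / 10.0)   # A -> nm
    return "".join(seq), np.array(coords)


def topology_to_yaml(topology: ChainTopology, path: str | Path) -> None:
    """Serialize a topology as self-describing YAML (lengths in nm)."""
    data = {
        "units": {"length": "nm", "energy": "kJ/mol", "mass": "Da", "charge": "e"},
        "sequence": topology.sequence,
        "masses": topology.masses.tolist(),
        "charges": topology.charges.tolist(),
        "lambdas": topology.lambdas.tolist(),
        "sigmas": topology.sigmas.tolist(),
        "bonds": [list(b) for b in topology.bonds],
        "restraints": [list(r) for r in topology.restraints],
        "domains": [
            {"name": d.name, "start": d.start, "end": d.end, "group": d.restraint_group}
            for d in topology.domains
        ],
        "reference_coords": (
            None if topology.reference_coords is None else topology.reference_coords.tolist()
        ),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def topology_from_yaml(path: str | Path) -> ChainTopology:
    data = yaml.safe_load(Path(path).read_text())
    topo = ChainTopology(
        sequence=data["sequence"],
        masses=np.array(data["masses"], float),
        charges=np.array(data["charges"], float),
        lambdas=np.array(data["lambdas"], float),
        sigmas=np.array(data["sigmas"], float),
        bonds=[tuple(b) for b in data["bonds"]],
        restraints=[tuple(r) for r in data["restraints"]],
        domains=[
            DomainAnnotation(d["name"], d["start"], d["end"], d.get("group"))
            for d in data.get("domains", [])
        ],
        reference_coords=(
            None if data.get("reference_coords") is None
            else np.array(data["reference_coords"], float)
        ),
    )
    topo.validate()
    return topo
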