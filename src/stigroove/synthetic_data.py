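"""Synthetic fixtures with analytically known ground truth.

Every downstream stage has a generator here whose output obeys a stated
closed form, so tests never depend on downloads:

* toy groove systems — beads on a hemicylindrical arc (interior on the
  concave face, exterior on the convex back) giving an unambiguous
  interior/exterior labeling and a well-defined principal axis;
* planted-occupancy trajectories — probes placed at the groove centroid
  with a chosen Bernoulli probability, else far outside (3× the
  furthest-interior radius guarantees the first groove test fails), with
  the per-frame truth recorded;
* mono-exponential relaxation decays with Gaussian noise;
* ideal Guinier scattering profiles I(q) = I0 exp(-q² Rg²/3);
* random peak lists plus a perturbation helper for CSP/intensity tests;
* a small multidomain chain (two folded helical domains, disordered
  linkers, one sticky aromatic segment) for fast simulator and pipeline
  runs.

All generators take an explicit seed and use a single private RNG stream
per call; no global RNG state is touched.  Noise-free outputs are exact
evaluations of the stated closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cg_model import DomainAnnotation, ValidationError
from .ensemble_metrics import ScatteringProfile
from .groove_analysis import GrooveDefinition
from .nmr_observables import PeakList, RelaxationSeries
from .simulator import Trajectory


# ---------------------------------------------------------------------------
# Toy groove systems
# ---------------------------------------------------------------------------

@dataclass
class ToyGrooveSystem:
    """A rigid toy groove with optional probe beads and per-frame truth flags.

    ``truth`` has shape (n_probes, n_frames); ``probe_indices`` are the bead
    indices of the probes inside ``frames``.
    """

    groove: GrooveDefinition
    frames: Trajectory
    truth: np.ndarray = field(default_factory=lambda: np.zeros((0, 1), dtype=bool))
    probe_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        if self.truth.shape[0] != len(self.probe_indices):
            raise ValidationError("one truth row per probe residue required")
        if self.truth.size and self.truth.shape[1] != self.frames.n_frames:
            raise ValidationError("one truth flag per (probe, frame) required")

    @property
    def n_groove_beads(self) -> int:
        return self.groove.interior.size + self.groove.exterior.size

    def groove_centroid(self) -> np.ndarray:
        return self.frames.xyz[0][self.groove.interior].mean(axis=0)

    def furthest_interior_radius(self) -> float:
        center = self.groove_centroid()
        return float(np.linalg.norm(
            self.frames.xyz[0][self.groove.interior] - center, axis=1).max())

    def outside_position(self) -> np.ndarray:
        """A point > 3x the furthest-interior radius from the groove center."""
        return self.groove_centroid() + np.array([0.0, 3.5, 0.0]) * self.furthest_interior_radius()


def make_toy_groove_system(
    n_interior: int,
    n_exterior: int,
    groove_radius: float,
    seed: int,
    jitter: float = 0.02,
) -> ToyGrooveSystem:
    """Rigid hemicylindrical toy groove (radius in the caller's length unit).

    Interior beads sit on the concave half-arc (polar angle 0..π at
    ``groove_radius``), spread along the cylinder axis over 4 radii;
    exterior beads sit on the convex back half-arc at 1.1× the radius.
    A small seeded jitter (``jitter`` × radius) breaks exact symmetry while
    keeping the classification unambiguous.  The geometry is rigid: one
    reference frame is stored.
    """
    if n_interior < 4:
        raise ValidationError("n_interior must be >= 4 (principal axis undefined)")
    if n_exterior < 1:
        raise ValidationError("n_exterior must be >= 1")
    if groove_radius <= 0:
        raise ValidationError("groove_radius must be > 0")
    rng = np.random.default_rng(seed)
    length = 4.0 * groove_radius

    def arc(n: int, theta0: float, radius: float) -> np.ndarray:
        theta = theta0 + math.pi * (np.arange(n) + 0.5) / n
        z = length * (np.arange(n) / max(n - 1, 1) - 0.5)
        return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])

    interior = arc(n_interior, 0.0, groove_radius)
    exterior = arc(n_exterior, math.pi, 1.1 * groove_radius)
    xyz = np.vstack([interior, exterior])
    xyz = xyz + rng.normal(0.0, jitter * groove_radius, size=xyz.shape)

    groove = GrooveDefinition(
        interior=np.arange(n_interior),
        exterior=np.arange(n_interior, n_interior + n_exterior),
    )
    frames = Trajectory(xyz=xyz[None, :, :], dt_ps=1.0)
    return ToyGrooveSystem(groove=groove, frames=frames)


def make_planted_occupancy_trajectory(
    system: ToyGrooveSystem,
    probe_residues: Sequence[int],
    target_occupancy: float,
    n_frames: int,
    seed: int,
) -> ToyGrooveSystem:
    """Plant probes in/out of the groove at a chosen Bernoulli probability.

    In each frame every probe is placed at the groove centroid with
    probability ``target_occupancy`` and otherwise at 3.5× the furthest-
    interior radius from the center (guaranteed non-occupied).  Returns a
    new system whose ``frames`` hold the planted trajectory and whose
    ``truth`` records the per-(probe, frame) flags.
    """
    if not 0.0 <= target_occupancy <= 1.0:
        raise ValidationError("target occupancy must lie in [0, 1]")
    if n_frames < 1:
        raise ValidationError("need at least one frame")
    probes = np.asarray(probe_residues, dtype=int)
    n_groove = system.n_groove_beads
    if probes.size == 0 or len(np.unique(probes)) != probes.size:
        raise ValidationError("probe indices must be non-empty and unique")
    if probes.min() < n_groove:
        raise ValidationError("probe indices must come after the groove beads")

    rng = np.random.default_rng(seed)
    n_beads = int(probes.max()) + 1
    base = system.frames.xyz[0]
    inside = system.groove_centroid()
    outside = system.outside_position()

    xyz = np.empty((n_frames, n_beads, 3))
    xyz[:, :n_groove] = base[None, :n_groove]
    xyz[:, n_groove:] = outside[None, None, :]      # gap beads stay far outside
    truth = rng.random((probes.size, n_frames)) < target_occupancy
    for p, idx in enumerate(probes):
        xyz[:, idx] = np.where(truth[p][:, None], inside[None, :], outside[None, :])

    frames = Trajectory(xyz=xyz, dt_ps=system.frames.dt_ps)
    return ToyGrooveSystem(groove=system.groove, frames=frames,
                           truth=truth, probe_indices=probes)


# ---------------------------------------------------------------------------
# Relaxation decays and scattering profiles
# ---------------------------------------------------------------------------

def make_relaxation_series(
    rate: float,
    amplitude: float,
    delays_s: Sequence[float],
    noise_sd: float,
    seed: int,
) -> RelaxationSeries:
    """Mono-exponential decay ``A exp(-R t)`` with additive Gaussian noise."""
    if rate <= 0:
        raise ValidationError("relaxation rate must be > 0")
    delays = np.asarray(delays_s, dtype=float)
    if len(np.unique(delays)) < 2:
        raise ValidationError("need >= 2 distinct delays")
    intensities = amplitude * np.exp(-rate * delays)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, noise_sd, size=len(delays))
    return RelaxationSeries(delays_s=delays, intensities=intensities, noise_sd=noise_sd)


def make_guinier_profile(
    rg: float,
    i0: float,
    q_grid: Sequence[float],
    noise_sd: float,
    seed: int,
) -> ScatteringProfile:
    """Ideal Guinier profile ``I(q) = I0 exp(-q² Rg²/3)`` (+ optional noise).

    ``rg`` in Å, ``q_grid`` in 1/Å, strictly increasing and positive.  The
    σI column is set to ``noise_sd`` (or a tiny floor when noiseless so that
    weighted fits remain defined).
    """
    if rg <= 0:
        raise ValidationError("rg must be > 0")
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0) or np.any(np.diff(q) <= 0):
        raise ValidationError("q grid must be positive and strictly increasing")
    i = i0 * np.exp(-(q ** 2) * rg ** 2 / 3.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd, size=len(q))
    sigma = np.full_like(q, noise_sd if noise_sd > 0 else 1e-12)
    return ScatteringProfile(q=q, i=i, sigma=sigma)


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

def make_peak_list(
    residues: Sequence[int],
    seed: int,
    concentration_uM: float = 50.0,
    intensity: float = 100.0,
) -> PeakList:
    """Random but reproducible amide peak list over the given residues."""
    rng = np.random.default_rng(seed)
    res = np.asarray(residues, dtype=int)
    records = [
        (int(r),
         float(rng.uniform(7.5, 9.5)),
         float(rng.uniform(105.0, 130.0)),
         float(intensity * rng.uniform(0.5, 1.5)))
        for r in res
    ]
    return PeakList.from_records(records, concentration_uM=concentration_uM)


def perturb_peak_list(
    peaks: PeakList,
    shifts: dict[int, tuple[float, float]] | None = None,
    intensity_scale: float | dict[int, float] = 1.0,
    drop: Sequence[int] = (),
    concentration_uM: float | None = None,
) -> PeakList:
    """Copy of a peak list with chosen shift changes, scaling, and dropped peaks.

    ``shifts`` maps residue -> (ΔδH, ΔδN) in ppm; ``drop`` residues are
    removed entirely (the absent-peak state).
    """
    df = peaks.data.copy()
    for residue, (dh, dn) in (shifts or {}).items():
        df.loc[residue, "h_ppm"] += dh
        df.loc[residue, "n_ppm"] += dn
    if isinstance(intensity_scale, dict):
        for residue, s in intensity_scale.items():
            df.loc[residue, "intensity"] *= s
    else:
        df["intensity"] *= intensity_scale
    df = df.drop(index=list(drop), errors="ignore")
    return PeakList(df, concentration_uM=concentration_uM
                    if concentration_uM is not None else peaks.concentration_uM)


# ---------------------------------------------------------------------------
# Toy multidomain chain
# ---------------------------------------------------------------------------

@dataclass
class ToyChain:
    """A 60-residue two-domain chain for fast simulator and pipeline runs."""

    sequence: str
    reference_coords: np.ndarray              # (n, 3) nm
    domains: list[DomainAnnotation]
    groove: GrooveDefinition
    sticky_span: tuple[int, int]              # 1-based inclusive
    regions: dict[str, tuple[int, int]]
    enm_cutoff: float = 1.6                   # nm, spans the hairpin channel


def _helix(n: int, start: np.ndarray, radius: float = 0.5,
           rise: float = 0.165, dtheta_deg: float = 40.0) -> np.ndarray:
    """Helical bead arrangement with ~0.38 nm consecutive-bead spacing."""
    theta = np.deg2rad(dtheta_deg) * np.arange(n)
    pts = np.column_stack([radius * np.cos(theta), radius * np.sin(theta),
                           rise * np.arange(n)])
    return pts - pts[0] + start


def _zigzag(n: int, start: np.ndarray, bond: float = 0.38, zig: float = 0.19,
            direction: float = 1.0) -> np.ndarray:
    dx = math.sqrt(bond ** 2 - zig ** 2)
    pts = np.zeros((n, 3))
    pts[:, 0] = direction * dx * (np.arange(n) + 1)
    pts[:, 1] = zig * ((np.arange(n) + 1) % 2)
    return pts + start


def _hairpin_groove(bond: float = 0.38, gap: float = 1.4) -> np.ndarray:
    """A 21-bead hairpin: two parallel 8-bead strands joined by a 5-bead turn.

    The open channel between the strands (width ``gap``) is the toy groove:
    a probe bead in the channel sits near the pair-potential minimum of both
    strands at once.
    """
    strand1 = np.column_stack([bond * np.arange(8), np.zeros(8), np.zeros(8)])
    radius = gap / 2.0
    center = np.array([strand1[-1, 0], radius, 0.0])
    angles = np.deg2rad([-60.0, -30.0, 0.0, 30.0, 60.0])
    turn = center + radius * np.column_stack(
        [np.cos(angles), np.sin(angles), np.zeros(5)])
    strand2 = np.column_stack([bond * np.arange(7, -1, -1), np.full(8, gap), np.zeros(8)])
    return np.vstack([strand1, turn, strand2])


def make_toy_multidomain_chain(seed: int = 0) -> ToyChain:
    """Two folded domains joined by disordered linkers with one sticky segment.

    Layout (1-based): domain A 1–21 is a hydrophobic hairpin whose open
    channel is the toy groove (strand beads interior, turn beads exterior);
    linker 22–34 (Ala/Ser) leads to a sticky aromatic segment 35–40
    (Trp/Phe — the transient-helix stand-in), a second linker 41–48, and a
    helical partner domain B 49–60.  The reference geometry is bondable
    (consecutive beads ≈ 0.38 nm apart) so the elastic network and backbone
    bonds do not fight; restraining the hairpin channel needs an elastic-
    network cutoff spanning the 1.4 nm channel width (``enm_cutoff``).
    """
    seq_a = "ILVFILVF" + "GSGSG" + "FVLIFVLI"   # 21: strands hydrophobic, turn polar
    linker1 = "ASASASASASASA"                   # 13
    sticky = "WFWFWF"                           # 6
    linker2 = "ASASASAS"                        # 8
    seq_b = "ILVAFMILVAFM"                      # 12
    sequence = seq_a + linker1 + sticky + linker2 + seq_b

    # linker leaves the channel mouth in -x, away from the hairpin body
    coords_a = _hairpin_groove()
    coords_l = _zigzag(27, coords_a[-1], direction=-1.0)
    coords_b = _helix(12, coords_l[-1] + np.array([-0.33, 0.19, 0.0]))
    coords = np.vstack([coords_a, coords_l, coords_b])

    domains = [
        DomainAnnotation("groove_domain", 1, 21, "A"),
        DomainAnnotation("partner_domain", 49, 60, "B"),
    ]
    groove = GrooveDefinition(
        interior=np.concatenate([np.arange(0, 8), np.arange(13, 21)]),  # strands
        exterior=np.arange(8, 13),                                      # turn
    )
    return ToyChain(
        sequence=sequence,
        reference_coords=coords,
        domains=domains,
        groove=groove,
        sticky_span=(35, 40),
        regions={"TH": (35, 40)},
    )
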