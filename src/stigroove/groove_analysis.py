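"""Geometric groove-occupancy classification and excess-probability profiles.

A chaperone-binding STI1 domain presents a hydrophobic groove; disordered
residues of the same chain can transiently occupy it.  Occupancy of a
candidate residue in one frame is decided by three tests against a fixed
interior/exterior labeling of the groove-domain residues:

1. the candidate is closer to the groove center (the mean of the interior
   bead positions, recomputed per frame) than the furthest interior residue
   is to that center;
2. the candidate is closer to some interior residue than to any exterior
   residue;
3. the candidate lies within the groove's own envelope around its dominant
   axis: its perpendicular distance to the first principal axis of the
   interior beads (a line through the groove center) does not exceed the
   maximum perpendicular distance of the interior beads themselves, scaled
   by a configurable alignment threshold (default 1.0).

Per-residue occupancy probabilities are averaged over replica trajectories,
and an excess profile divides them by the matching probabilities from an
excluded-volume baseline ensemble, isolating enrichment due to chemical
interactions from what chain connectivity and sterics alone produce.

All tests use strict inequalities in steps 1–2 (a tie is not occupancy) and
distances between bead centers in nm.  Residue indices here are 0-based bead
indices; region spans in :func:`region_enrichment` are 1-based inclusive to
match sequence numbering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cg_model import ValidationError
from .simulator import Trajectory


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrooveDefinition:
    """Interior/exterior labeling of groove-domain residues (0-based indices)."""

    interior: np.ndarray
    exterior: np.ndarray
    axis_threshold: float = 1.0

    def __post_init__(self) -> None:
        interior = np.asarray(self.interior, dtype=int)
        exterior = np.asarray(self.exterior, dtype=int)
        object.__setattr__(self, "interior", interior)
        object.__setattr__(self, "exterior", exterior)
        if interior.size < 4:
            raise ValidationError(
                "need >= 4 interior residues (principal axis undefined below 4)")
        if exterior.size == 0:
            raise ValidationError("exterior residue set must be non-empty")
        if np.intersect1d(interior, exterior).size:
            raise ValidationError("interior and exterior sets must be disjoint")
        if self.axis_threshold <= 0:
            raise ValidationError("axis-alignment threshold must be > 0")


@dataclass
class OccupancyProfile:
    """Per-residue occupancy probability with across-replica spread."""

    residues: np.ndarray          # 0-based bead indices
    probability: np.ndarray       # in [0, 1]
    spread: np.ndarray            # SD across replicas
    n_frames: int
    n_replicas: int

    def __post_init__(self) -> None:
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValidationError("occupancy probabilities must lie in [0, 1]")
        if np.any(self.spread < 0):
            raise ValidationError("replicate spread must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": self.residues + 1,     # 1-based for output
            "probability": self.probability,
            "spread": self.spread,
        })


@dataclass
class ExcessProfile:
    """Per-residue fold enrichment observed/baseline with undefined flags."""

    residues: np.ndarray
    enrichment: np.ndarray        # >= 0 where defined; inf where baseline == 0 < observed
    undefined: np.ndarray         # True where 0/0
    infinite: np.ndarray          # True where observed > 0 over baseline 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": self.residues + 1,
            "enrichment": self.enrichment,
            "undefined": self.undefined,
            "infinite": self.infinite,
        })


# ---------------------------------------------------------------------------
# Per-frame classification
# ---------------------------------------------------------------------------

def groove_center(frame: np.ndarray, interior: Sequence[int]) -> np.ndarray:
    """Arithmetic mean of the interior bead positions of one frame."""
    interior = np.asarray(interior, dtype=int)
    if interior.size == 0:
        raise ValidationError("empty interior set")
    return np.asarray(frame, float)[interior].mean(axis=0)


def _dominant_axis(interior_xyz: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest principal component of the interior beads."""
    centered = interior_xyz - center
    cov = centered.T @ centered / len(centered)
    w, v = np.linalg.eigh(cov)
    return v[:, -1]


def _perp_distance(points: np.ndarray, center: np.ndarray, axis: np.ndarray) -> np.ndarray:
    rel = points - center
    along = rel @ axis
    return np.linalg.norm(rel - np.outer(along, axis), axis=-1)


def classify_frame(
    frame: np.ndarray,
    groove: GrooveDefinition,
    candidates: Sequence[int],
) -> np.ndarray:
    """Occupancy flags for candidate residues in a single frame.

    Applies the three groove tests (center distance, interior-vs-exterior
    proximity, principal-axis envelope) described in the module docstring.
    Returns a boolean array aligned with ``candidates``.
    """
    frame = np.asarray(frame, dtype=float)
    cand = np.asarray(candidates, dtype=int)
    interior_xyz = frame[groove.interior]
    exterior_xyz = frame[groove.exterior]
    cand_xyz = frame[cand]

    center = interior_xyz.mean(axis=0)
    interior_radii = np.linalg.norm(interior_xyz - center, axis=1)
    r_max = interior_radii.max()

    # step 1: strictly inside the furthest-interior radius
    inside = np.linalg.norm(cand_xyz - center, axis=1) < r_max

    # step 2: strictly closer to an interior residue than any exterior one
    d_int = np.linalg.norm(cand_xyz[:, None, :] - interior_xyz[None, :, :], axis=-1).min(axis=1)
    d_ext = np.linalg.norm(cand_xyz[:, None, :] - exterior_xyz[None, :, :], axis=-1).min(axis=1)
    inside &= d_int < d_ext

    # step 3: within the interior group's envelope around its dominant axis
    axis = _dominant_axis(interior_xyz, center)
    perp_max = _perp_distance(interior_xyz, center, axis).max()
    inside &= _perp_distance(cand_xyz, center, axis) <= groove.axis_threshold * perp_max
    return inside


# ---------------------------------------------------------------------------
# Profiles over trajectories
# ---------------------------------------------------------------------------

def occupancy_profile(
    trajectories: Sequence[Trajectory],
    groove: GrooveDefinition,
    residues: Sequence[int],
) -> OccupancyProfile:
    """Per-residue occupancy probability averaged over replica trajectories.

    Each replica contributes its fraction of occupied frames per residue;
    the profile reports the mean over replicas and the across-replica
    standard deviation as spread.
    """
    trajectories = list(trajectories)
    if not trajectories:
        raise ValidationError("need at least one trajectory")
    residues = np.asarray(residues, dtype=int)
    per_replica = []
    for traj in trajectories:
        if traj.n_frames == 0:
            raise ValidationError("empty trajectory")
        counts = np.zeros(len(residues))
        for f in range(traj.n_frames):
            counts += classify_frame(traj.xyz[f], groove, residues)
        per_replica.append(counts / traj.n_frames)
    per_replica = np.array(per_replica)
    return OccupancyProfile(
        residues=residues,
        probability=per_replica.mean(axis=0),
        spread=per_replica.std(axis=0),
        n_frames=sum(t.n_frames for t in trajectories),
        n_replicas=len(trajectories),
    )


def excess_occupancy(observed: OccupancyProfile, baseline: OccupancyProfile) -> ExcessProfile:
    """Fold enrichment of observed occupancy over the excluded-volume baseline.

    Residues where both profiles are zero are flagged undefined; residues
    where only the baseline is zero are flagged infinite.  No pseudo-count
    is applied.
    """
    if not np.array_equal(observed.residues, baseline.residues):
        raise ValidationError("profiles cover different residue sets")
    obs = observed.probability
    base = baseline.probability
    undefined = (base == 0) & (obs == 0)
    infinite = (base == 0) & (obs > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = obs / base
    ratio = np.where(undefined, np.nan, ratio)
    ratio = np.where(infinite, np.inf, ratio)
    return ExcessProfile(
        residues=observed.residues.copy(),
        enrichment=ratio,
        undefined=undefined,
        infinite=infinite,
    )


def region_enrichment(
    excess: ExcessProfile,
    regions: Mapping[str, tuple[int, int]],
) -> dict[str, float]:
    """Mean defined fold enrichment per named region (1-based inclusive spans).

    Undefined (0/0) residues are excluded from the mean; a region with no
    defined residue is reported as NaN.
    """
    index = {int(r): i for i, r in enumerate(excess.residues)}
    out: dict[str, float] = {}
    for name, (start, end) in regions.items():
        rows = [index[r] for r in range(start - 1, end) if r in index]
        if not rows:
            raise ValidationError(f"region {name} [{start}, {end}] outside profile range")
        vals = excess.enrichment[rows]
        defined = ~excess.undefined[rows]
        out[name] = float(vals[defined].mean()) if defined.any() else float("nan")
    return out


# ---------------------------------------------------------------------------
# Helpers and I/O
# ---------------------------------------------------------------------------

def propose_interior_residues(
    coords: np.ndarray,
    domain_indices: Sequence[int],
    n_neighbors: int = 6,
) -> np.ndarray:
    """Advisory concave-face heuristic for interior residues of a groove domain.

    A bead is proposed as interior when its outward local normal — the vector
    from the centroid of its ``n_neighbors`` nearest domain beads to the bead
    itself — points back toward the domain centroid (their dot product is
    negative would mean convex; interior means the bead faces the concave
    side, i.e. its vector to the domain centroid aligns with the local
    normal).  The returned list is advisory; an explicit residue list remains
    the source of truth for analyses.
    """
    idx = np.asarray(domain_indices, dtype=int)
    xyz = np.asarray(coords, float)[idx]
    centroid = xyz.mean(axis=0)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    proposed = []
    for a in range(len(idx)):
        order = np.argsort(d[a])[1:n_neighbors + 1]
        normal = xyz[a] - xyz[order].mean(axis=0)
        to_centroid = centroid - xyz[a]
        if np.dot(normal, to_centroid) > 0:
            proposed.append(int(idx[a]))
    return np.array(proposed, dtype=int)


def read_groove_definition(path: str | Path) -> GrooveDefinition:
    """Load a groove definition YAML: 1-based interior/exterior lists."""
    data = yaml.safe_load(Path(path).read_text())
    return GrooveDefinition(
        interior=np.array(data["interior"], dtype=int) - 1,
        exterior=np.array(data["exterior"], dtype=int) - 1,
        axis_threshold=float(data.get("threshold", 1.0)),
    )


def write_profile_tsv(profile: OccupancyProfile | ExcessProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def plot_occupancy(
    profiles: Mapping[str, OccupancyProfile],
    path: str | Path,
    regions: Mapping[str, tuple[int, int]] | None = None,
    log: bool = True,
) -> None:
    """Log-probability occupancy plot with replicate-spread shading."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3))
    for label, prof in profiles.items():
        x = prof.residues + 1
        ax.plot(x, prof.probability, label=label)
        ax.fill_between(x, np.maximum(prof.probability - prof.spread, 1e-12),
                        prof.probability + prof.spread, alpha=0.3)
    if regions:
        for name, (start, end) in regions.items():
            ax.axvspan(start, end, color="orange", alpha=0.2)
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("residue")
    ax.set_ylabel("groove occupancy probability")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
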