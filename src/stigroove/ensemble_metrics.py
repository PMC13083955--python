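"""Ensemble observables: radius of gyration, effective concentration, Guinier.

These are the quantities used to confront a simulated single-chain ensemble
with experiment: the mass-weighted radius of gyration (Rg) distribution and
its replica statistics, the effective concentration one tethered domain
presents to another (a shell-density estimate at contact range), and the
Guinier fit that extracts Rg from a small-angle scattering profile.

Simulation coordinates are in nm; Rg values and scattering vectors are
reported in Å and 1/Å respectively, with conversion at the reporting
boundary only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cg_model import AVOGADRO, ValidationError
from .simulator import Trajectory

NM_TO_A = 10.0
# 1 molecule / nm^3 expressed in mol/L
_MOLECULE_PER_NM3_TO_M = 1e24 / AVOGADRO


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------

def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> np.ndarray | float:
    """Mass-weighted Rg about the center of mass, in the units of ``coords``.

    Accepts a single frame (n, 3) or a stack (frames, n, 3).
    """
    coords = np.asarray(coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    if coords.shape[-2] < 2:
        raise ValidationError("radius of gyration needs >= 2 beads")
    total = m.sum()
    if total <= 0:
        raise ValidationError("total mass must be > 0")
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    com = (m[None, :, None] * coords).sum(axis=1) / total
    d2 = ((coords - com[:, None, :]) ** 2).sum(axis=-1)
    rg = np.sqrt((m[None, :] * d2).sum(axis=1) / total)
    return float(rg[0]) if single else rg


@dataclass
class RgSummary:
    """Per-frame Rg series (Å) with replica means, grand mean ± SEM, histogram."""

    per_frame: list[np.ndarray]        # one array per replica, Å
    replica_means: np.ndarray          # Å
    grand_mean: float                  # Å
    sem: float                         # Å, across replicas
    hist_edges: np.ndarray             # Å
    hist_density: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replica": np.arange(len(self.replica_means)),
            "mean_rg_A": self.replica_means,
        })


def rg_summary(
    trajectories: Sequence[Trajectory],
    masses: np.ndarray,
    bins: int = 50,
) -> RgSummary:
    """Rg statistics for a replica ensemble (input nm, reported Å)."""
    trajectories = list(trajectories)
    if not trajectories:
        raise ValidationError("need at least one replica")
    per_frame = []
    for traj in trajectories:
        if traj.n_frames == 0:
            raise ValidationError("empty replica trajectory")
        per_frame.append(np.asarray(radius_of_gyration(traj.xyz, masses)) * NM_TO_A)
    means = np.array([f.mean() for f in per_frame])
    grand = float(means.mean())
    sem = float(means.std(ddof=1) / math.sqrt(len(means))) if len(means) > 1 else 0.0
    pooled = np.concatenate(per_frame)
    density, edges = np.histogram(pooled, bins=bins, density=True)
    return RgSummary(per_frame, means, grand, sem, edges, density)


# ---------------------------------------------------------------------------
# Effective concentration of tethered domains
# ---------------------------------------------------------------------------

@dataclass
class EffectiveConcentration:
    """Shell-density effective concentration in µM with replica SEM."""

    value_uM: float
    sem_uM: float
    per_replica_uM: np.ndarray
    contact_distance_nm: float
    shell_width_nm: float
    empty_shell: bool                  # no frame fell inside the shell


def _group_com_distance(xyz: np.ndarray, masses: np.ndarray,
                        idx_a: np.ndarray, idx_b: np.ndarray,
                        distance: str) -> np.ndarray:
    if distance == "com":
        ma = masses[idx_a]
        mb = masses[idx_b]
        com_a = (ma[None, :, None] * xyz[:, idx_a]).sum(axis=1) / ma.sum()
        com_b = (mb[None, :, None] * xyz[:, idx_b]).sum(axis=1) / mb.sum()
        return np.linalg.norm(com_a - com_b, axis=1)
    if distance == "min":
        d = np.linalg.norm(
            xyz[:, idx_a, None, :] - xyz[:, None, idx_b, :], axis=-1)
        return d.min(axis=(1, 2))
    raise ValidationError(f"unknown distance definition {distance!r}")


def effective_concentration(
    trajectories: Sequence[Trajectory],
    masses: np.ndarray,
    group_a: tuple[int, int],
    group_b: tuple[int, int],
    contact_distance_nm: float,
    shell_width_nm: float = 0.2,
    distance: str = "com",
) -> EffectiveConcentration:
    """Effective concentration of one tethered domain at the other, in µM.

    ``group_a``/``group_b`` are 1-based inclusive residue spans.  For each
    replica the fraction of frames whose inter-group distance falls in the
    shell (contact ± width/2) is divided by the shell volume
    ``4 pi d^2 w`` and converted to molar units; the reported value is the
    replica mean with SEM.  An all-empty shell is reported as 0 with the
    ``empty_shell`` flag set.
    """
    if contact_distance_nm <= 0 or shell_width_nm <= 0:
        raise ValidationError("contact distance and shell width must be > 0")
    a0, a1 = group_a
    b0, b1 = group_b
    if not (a1 < b0 or b1 < a0):
        raise ValidationError("group spans must be disjoint")
    idx_a = np.arange(a0 - 1, a1)
    idx_b = np.arange(b0 - 1, b1)
    m = np.asarray(masses, dtype=float)
    shell_volume = 4.0 * math.pi * contact_distance_nm ** 2 * shell_width_nm
    lo = contact_distance_nm - shell_width_nm / 2.0
    hi = contact_distance_nm + shell_width_nm / 2.0

    per_replica = []
    for traj in trajectories:
        d = _group_com_distance(traj.xyz, m, idx_a, idx_b, distance)
        frac = float(np.mean((d >= lo) & (d < hi)))
        conc_M = frac / shell_volume * _MOLECULE_PER_NM3_TO_M
        per_replica.append(conc_M * 1e6)
    per_replica = np.array(per_replica)
    sem = (float(per_replica.std(ddof=1) / math.sqrt(len(per_replica)))
           if len(per_replica) > 1 else 0.0)
    return EffectiveConcentration(
        value_uM=float(per_replica.mean()),
        sem_uM=sem,
        per_replica_uM=per_replica,
        contact_distance_nm=contact_distance_nm,
        shell_width_nm=shell_width_nm,
        empty_shell=bool(np.all(per_replica == 0.0)),
    )


# ---------------------------------------------------------------------------
# Scattering profiles and Guinier analysis
# ---------------------------------------------------------------------------

@dataclass
class ScatteringProfile:
    """Small-angle scattering profile: q (1/Å), I(q), optional σI."""

    q: np.ndarray
    i: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or len(self.q) != len(self.i):
            raise ValidationError("q and I must be 1-D and equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValidationError("q grid must be strictly increasing")
        if not np.all(np.isfinite(self.i)):
            raise ValidationError("intensities must be finite")


@dataclass
class GuinierResult:
    """Guinier fit output: Rg (Å) and I0 with fit errors, window, residuals."""

    rg_A: float
    rg_err_A: float
    i0: float
    i0_err: float
    q_window: tuple[float, float]
    n_points: int
    residuals: np.ndarray
    qrg_max: float


def guinier_fit(profile: ScatteringProfile, qrg_max: float = 1.3,
                max_iter: int = 20) -> GuinierResult:
    """Self-consistent Guinier fit: ln I linear in q², slope = -Rg²/3.

    Starting from all positive-intensity points, the low-q window is
    iteratively restricted to q·Rg <= ``qrg_max`` until stable (capped at
    ``max_iter`` rounds, ties resolved toward the smaller window).  The fit
    is weighted by σI when available.  Requires >= 5 points in the final
    window; a non-decaying profile (positive slope) is rejected.
    """
    positive = profile.i > 0
    if positive.sum() < 5:
        raise ValidationError("need >= 5 positive-intensity points")
    q = profile.q[positive]
    lni = np.log(profile.i[positive])
    w = None
    if profile.sigma is not None:
        sig = profile.sigma[positive]
        with np.errstate(divide="ignore"):
            w = np.where(sig > 0, profile.i[positive] / sig, 0.0)   # 1/sigma_lnI

    n_window = len(q)
    slope = intercept = cov = None
    for _ in range(max_iter):
        qq = q[:n_window] ** 2
        yy = lni[:n_window]
        ww = None if w is None else w[:n_window]
        coeffs, cov = np.polyfit(qq, yy, 1, w=ww, cov="unscaled" if ww is not None else True)
        slope, intercept = coeffs
        if slope >= 0:
            raise ValidationError("non-decaying profile: Guinier slope >= 0")
        rg = math.sqrt(-3.0 * slope)
        new_n = int(np.searchsorted(q, qrg_max / rg, side="right"))
        new_n = max(new_n, 5)
        if new_n >= n_window:
            break
        n_window = new_n
    if n_window < 5:
        raise ValidationError("fewer than 5 points in the Guinier window")

    rg = math.sqrt(-3.0 * slope)
    slope_err = math.sqrt(cov[0, 0])
    rg_err = 3.0 * slope_err / (2.0 * rg)
    i0 = math.exp(intercept)
    i0_err = i0 * math.sqrt(cov[1, 1])
    resid = lni[:n_window] - (slope * q[:n_window] ** 2 + intercept)
    return GuinierResult(
        rg_A=rg, rg_err_A=rg_err, i0=i0, i0_err=i0_err,
        q_window=(float(q[0]), float(q[n_window - 1])),
        n_points=n_window, residuals=resid, qrg_max=qrg_max,
    )


def read_scattering_dat(path: str | Path) -> ScatteringProfile:
    """Read a 3-column whitespace q/I/σ file ('#' comments, SASBDB dialect).

    Lines that do not parse as three numbers (headers, footers) are skipped.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            continue
        try:
            vals = [float(p) for p in parts[:3]]
        except ValueError:
            continue
        if len(vals) == 2:
            vals.append(float("nan"))
        rows.append(vals)
    if not rows:
        raise ValidationError(f"no numeric rows in {path}")
    arr = np.array(rows)
    sigma = arr[:, 2] if np.all(np.isfinite(arr[:, 2])) else None
    return ScatteringProfile(q=arr[:, 0], i=arr[:, 1], sigma=sigma)


def write_scattering_dat(profile: ScatteringProfile, path: str | Path,
                         header: str = "q(1/A) I(q) sigma") -> None:
    sigma = profile.sigma if profile.sigma is not None else np.zeros_like(profile.q)
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for q, i, s in zip(profile.q, profile.i, sigma):
            fh.write(f"{q:.8g} {i:.8g} {s:.8g}\n")
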