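"""Backbone-NMR observable calculators.

Implements the residue-level quantities used to characterise a multidomain
protein with disordered regions from picked peak lists and relaxation
tables:

* chemical-shift perturbation (CSP): the weighted combined amide shift
  difference ``sqrt(dH^2 + (dN/w)^2)`` with nitrogen weight w = 5;
* concentration-normalised peak intensity ratios I/I0, with peak
  disappearance carried as an explicit absent state (never zero intensity);
* secondary chemical shifts ``(Ca_obs - Ca_rc) - (Cb_obs - Cb_rc)`` against
  a user-supplied random-coil table (positive: α-helix, negative: β-sheet);
* mono-exponential relaxation fits ``I(t) = I0 exp(-R t)`` with rate
  uncertainties from Monte-Carlo resampling at the spectral noise level
  (default 500 trials);
* steady-state heteronuclear NOE as the saturated/reference peak-height
  ratio with propagated uncertainty.

Peak lists and relaxation tables are plain CSV with documented headers;
an optional reader extracts chemical-shift loops from NMR-STAR files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .cg_model import ValidationError

DEFAULT_NITROGEN_WEIGHT = 5.0
DEFAULT_MC_TRIALS = 500


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class PeakList:
    """Per-residue 2D amide peaks: 1H/15N shifts (ppm) and intensity.

    ``data`` is indexed by residue number with columns ``h_ppm``, ``n_ppm``,
    ``intensity``.  A residue simply missing from the index is an absent
    peak (the "no observable peak" state).
    """

    data: pd.DataFrame
    concentration_uM: float | None = None

    def __post_init__(self) -> None:
        required = {"h_ppm", "n_ppm", "intensity"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"peak list needs columns {sorted(required)}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate residue indices in peak list")
        if (self.data["intensity"] < 0).any():
            raise ValidationError("peak intensities must be >= 0")

    @classmethod
    def from_records(cls, records: Sequence[tuple[int, float, float, float]],
                     concentration_uM: float | None = None) -> "PeakList":
        df = pd.DataFrame(records, columns=["residue", "h_ppm", "n_ppm", "intensity"])
        return cls(df.set_index("residue"), concentration_uM)

    @classmethod
    def from_csv(cls, path: str | Path,
                 concentration_uM: float | None = None) -> "PeakList":
        df = pd.read_csv(path, comment="#").set_index("residue")
        return cls(df, concentration_uM)

    @property
    def residues(self) -> np.ndarray:
        return self.data.index.to_numpy()


@dataclass
class RelaxationSeries:
    """Delay–intensity series for one residue with its spectral noise level."""

    delays_s: np.ndarray
    intensities: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.delays_s) != len(self.intensities):
            raise ValidationError("delays and intensities must have equal length")
        if len(np.unique(self.delays_s)) < 2:
            raise ValidationError("need >= 2 distinct relaxation delays")
        if self.noise_sd < 0:
            raise ValidationError("noise level must be >= 0")


@dataclass
class AssignmentTable:
    """Observed and random-coil Cα/Cβ shifts per residue.

    ``data`` indexed by residue with columns ``ca_obs``, ``cb_obs``,
    ``ca_rc``, ``cb_rc``; NaN in ``cb_obs``/``cb_rc`` marks residues
    without a Cβ (glycine).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"ca_obs", "cb_obs", "ca_rc", "cb_rc"}
        if not required.issubset(self.data.columns):
            raise ValidationError(f"assignment table needs columns {sorted(required)}")


# ---------------------------------------------------------------------------
# Chemical shift perturbation and intensity ratios
# ---------------------------------------------------------------------------

def csp(reference: PeakList, perturbed: PeakList,
        nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT) -> pd.DataFrame:
    """Combined amide chemical-shift perturbation per residue, in ppm.

    ``delta = sqrt(dH^2 + (dN/w)^2)`` over residues present in both lists;
    residues present in only one list are returned with NaN and
    ``absent=True``.
    """
    shared = reference.data.index.intersection(perturbed.data.index)
    if shared.empty:
        raise ValidationError("no residues shared between peak lists")
    all_res = reference.data.index.union(perturbed.data.index)
    dh = perturbed.data["h_ppm"].reindex(all_res) - reference.data["h_ppm"].reindex(all_res)
    dn = perturbed.data["n_ppm"].reindex(all_res) - reference.data["n_ppm"].reindex(all_res)
    delta = np.sqrt(dh ** 2 + (dn / nitrogen_weight) ** 2)
    return pd.DataFrame({
        "delta_ppm": delta,
        "absent": ~all_res.isin(shared),
    }, index=all_res.rename("residue"))


def intensity_ratio(reference: PeakList, test: PeakList,
                    normalize: bool = True) -> pd.DataFrame:
    """Per-residue I/I0 between two peak lists, concentration-normalised.

    When ``normalize`` each intensity is divided by its list's sample
    concentration before the ratio.  A residue missing from the test list is
    an absent peak (NaN ratio, ``absent=True``); a zero reference intensity
    is flagged per residue rather than fatal.
    """
    if normalize:
        if not reference.concentration_uM or not test.concentration_uM:
            raise ValidationError("both peak lists need a positive concentration")
        if reference.concentration_uM <= 0 or test.concentration_uM <= 0:
            raise ValidationError("concentrations must be > 0")
    res = reference.data.index
    i0 = reference.data["intensity"].astype(float).copy()
    i1 = test.data["intensity"].reindex(res).astype(float)
    if normalize:
        i0 = i0 / reference.concentration_uM
        i1 = i1 / test.concentration_uM
    zero_ref = i0 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = i1 / i0
    ratio[zero_ref] = np.nan
    return pd.DataFrame({
        "ratio": ratio,
        "absent": i1.isna(),
        "zero_reference": zero_ref,
    }, index=res.rename("residue"))


# ---------------------------------------------------------------------------
# Secondary chemical shifts
# ---------------------------------------------------------------------------

def secondary_shift(assignments: AssignmentTable) -> pd.DataFrame:
    """Δδ(Cα−Cβ) secondary shifts per residue, in ppm.

    ``(Ca_obs - Ca_rc) - (Cb_obs - Cb_rc)``; residues without a Cβ
    (glycine) use the Cα term alone and are flagged ``ca_only``.  Missing
    random-coil entries are flagged ``missing_rc`` with NaN.
    """
    d = assignments.data
    ca_sec = d["ca_obs"] - d["ca_rc"]
    cb_sec = d["cb_obs"] - d["cb_rc"]
    ca_only = d["cb_obs"].isna() & d["ca_obs"].notna()
    value = np.where(ca_only, ca_sec, ca_sec - cb_sec)
    missing_rc = d["ca_rc"].isna() | (~ca_only & d["cb_rc"].isna() & d["cb_obs"].notna())
    return pd.DataFrame({
        "delta_ca_cb_ppm": value,
        "ca_only": ca_only,
        "missing_rc": missing_rc,
    }, index=d.index.rename("residue"))


# ---------------------------------------------------------------------------
# Relaxation fitting
# ---------------------------------------------------------------------------

@dataclass
class RelaxationFit:
    """Mono-exponential fit result: rate (1/s), amplitude, Monte-Carlo rate SD."""

    rate: float
    amplitude: float
    rate_sd: float
    converged: bool = True
    message: str = ""


def _monoexp(t, amplitude, rate):
    return amplitude * np.exp(-rate * t)


def fit_monoexponential(series: RelaxationSeries,
                        mc_trials: int = DEFAULT_MC_TRIALS,
                        seed: int = 0) -> RelaxationFit:
    """Least-squares mono-exponential fit with Monte-Carlo rate uncertainty.

    Fits ``I(t) = I0 exp(-R t)`` by untransformed nonlinear least squares
    (noise stays additive), starting from the two-point log slope.  The rate
    SD is the standard deviation of rates refit on ``mc_trials`` replicas of
    the best-fit curve perturbed with Gaussian noise at the stored spectral
    noise level.  Duplicate delays are retained as independent points.
    """
    t = series.delays_s
    y = series.intensities
    order = np.argsort(t)
    t0, t1 = t[order[0]], t[order[-1]]
    y0, y1 = y[order[0]], y[order[-1]]
    if y0 <= 0:
        raise ValidationError("intensity at the smallest delay must be > 0")
    if y1 > 0 and t1 > t0:
        rate0 = max(1e-6, math.log(y0 / y1) / (t1 - t0))
    else:
        rate0 = 1.0 / max(t1, 1e-6)
    try:
        popt, _ = curve_fit(_monoexp, t, y, p0=(y0, rate0), maxfev=10000)
    except RuntimeError as err:
        return RelaxationFit(math.nan, math.nan, math.nan, False, str(err))
    amplitude, rate = float(popt[0]), float(popt[1])

    rate_sd = 0.0
    if series.noise_sd > 0 and mc_trials > 0:
        rng = np.random.default_rng(seed)
        model = _monoexp(t, amplitude, rate)
        rates = []
        for _ in range(mc_trials):
            perturbed = model + rng.normal(0.0, series.noise_sd, size=len(t))
            try:
                p, _ = curve_fit(_monoexp, t, perturbed,
                                 p0=(amplitude, rate), maxfev=10000)
                rates.append(p[1])
            except RuntimeError:
                continue
        if len(rates) >= 2:
            rate_sd = float(np.std(rates, ddof=1))
    return RelaxationFit(rate=rate, amplitude=amplitude, rate_sd=rate_sd)


def fit_relaxation_table(table: pd.DataFrame, noise_sd: float,
                         mc_trials: int = DEFAULT_MC_TRIALS,
                         seed: int = 0) -> pd.DataFrame:
    """Fit every residue of a long-format relaxation table.

    ``table`` has columns ``residue``, ``delay_s``, ``intensity``.  Returns
    per-residue rate, amplitude, rate SD and a convergence flag; residues
    whose fit fails are flagged, not fatal.
    """
    out = []
    for i, (residue, grp) in enumerate(table.groupby("residue")):
        series = RelaxationSeries(grp["delay_s"].to_numpy(),
                                  grp["intensity"].to_numpy(), noise_sd)
        fit = fit_monoexponential(series, mc_trials=mc_trials, seed=seed + i)
        out.append({
            "residue": residue, "rate_per_s": fit.rate,
            "amplitude": fit.amplitude, "rate_sd": fit.rate_sd,
            "converged": fit.converged,
        })
    return pd.DataFrame(out).set_index("residue")


# ---------------------------------------------------------------------------
# Heteronuclear NOE
# ---------------------------------------------------------------------------

def hetnoe(saturated: PeakList, reference: PeakList,
           noise_sat: float, noise_ref: float) -> pd.DataFrame:
    """Steady-state heteronuclear NOE with propagated uncertainty.

    ``value = I_sat / I_ref``; the error is
    ``|value| sqrt((noise_sat/I_sat)^2 + (noise_ref/I_ref)^2)``.  Residues
    with zero reference intensity are flagged per residue.  A zero saturated
    intensity gives value 0 with error ``noise_sat/I_ref``.
    """
    shared = saturated.data.index.intersection(reference.data.index)
    if shared.empty:
        raise ValidationError("no residues shared between experiments")
    i_sat = saturated.data["intensity"].reindex(shared).to_numpy(float)
    i_ref = reference.data["intensity"].reindex(shared).to_numpy(float)
    zero_ref = i_ref == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        value = np.where(zero_ref, np.nan, i_sat / i_ref)
        rel_sat = np.where(i_sat != 0, noise_sat / i_sat, 0.0)
        rel_ref = np.where(zero_ref, 0.0, noise_ref / i_ref)
        err = np.abs(value) * np.sqrt(rel_sat ** 2 + rel_ref ** 2)
        err = np.where((i_sat == 0) & ~zero_ref, noise_sat / np.abs(i_ref), err)
        err = np.where(zero_ref, np.nan, err)
    return pd.DataFrame({
        "hetnoe": value,
        "error": err,
        "zero_reference": zero_ref,
    }, index=shared.rename("residue"))


# ---------------------------------------------------------------------------
# NMR-STAR chemical-shift loop reader
# ---------------------------------------------------------------------------

def read_nmr_star_shifts(path: str | Path) -> pd.DataFrame:
    """Minimal reader for the Atom_chem_shift loop of an NMR-STAR file.

    Returns a long-format table with columns ``residue``, ``atom``,
    ``shift_ppm``.  Only the columns needed for secondary-shift analysis are
    extracted; this is a targeted parser for the standard
    ``_Atom_chem_shift`` loop layout, not a general STAR reader.
    """
    lines = Path(path).read_text().splitlines()
    rows: list[tuple[int, str, float]] = []
    in_loop = False
    tags: list[str] = []
    reading_data = False
    for raw in lines:
        line = raw.strip()
        if line == "loop_":
            in_loop, tags, reading_data = True, [], False
            continue
        if not in_loop:
            continue
        if line.startswith("_"):
            tags.append(line.split(".")[-1] if "." in line else line.lstrip("_"))
            continue
        if line.startswith("stop_"):
            in_loop = reading_data = False
            continue
        if not tags or not line or line.startswith("#"):
            continue
        if "Atom_ID" not in tags or "Val" not in tags:
            continue
        reading_data = True
        parts = line.split()
        if len(parts) != len(tags):
            continue
        rec = dict(zip(tags, parts))
        seq_key = "Seq_ID" if "Seq_ID" in rec else "Comp_index_ID"
        try:
            rows.append((int(rec[seq_key]), rec["Atom_ID"], float(rec["Val"])))
        except (KeyError, ValueError):
            continue
    if not rows:
        raise ValidationError(f"no Atom_chem_shift rows found in {path}")
    return pd.DataFrame(rows, columns=["residue", "atom", "shift_ppm"])


def assignment_table_from_shifts(shifts: pd.DataFrame,
                                 random_coil: pd.DataFrame) -> AssignmentTable:
    """Join observed CA/CB shifts with a random-coil table.

    ``shifts`` is long-format (residue, atom, shift_ppm); ``random_coil``
    is indexed by residue with columns ``ca_rc`` and ``cb_rc``.
    """
    ca = shifts[shifts["atom"] == "CA"].set_index("residue")["shift_ppm"]
    cb = shifts[shifts["atom"] == "CB"].set_index("residue")["shift_ppm"]
    df = pd.DataFrame({"ca_obs": ca, "cb_obs": cb})
    df = df.join(random_coil[["ca_rc", "cb_rc"]], how="left")
    return AssignmentTable(df)
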