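"""15N relaxation analysis: decay fitting, offset correction, tumbling times.

Longitudinal (R1) and rotating-frame (R1rho) rates come from mono-exponential
fits of per-residue peak-intensity decays, I(t) = I0 exp(-R t).  Duplicate
delay points provide an empirical noise estimate that is pooled (in
quadrature) with the fit-covariance error.  R1rho is corrected to R2 for the
resonance offset of the spin-lock carrier,

    R1rho = R1 cos^2(theta) + R2 sin^2(theta),  theta = atan(nu1 / dnu),

and the rotational correlation time is estimated from the R2/R1 ratio with
the standard large-molecule approximation

    tau_c = 1 / (4 pi nu_N) * sqrt(6 R2/R1 - 7),

nu_N being the 15N Larmor frequency.  A simple empirical molecular-weight
rule, tau_c = 0.6 ns/kDa * MW at 25 C in water, provides the theoretical
reference values for isotropically tumbling globular proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .exceptions import ConfigurationError, EmptyInputError, OutOfRegimeError
from .structure import DomainPartition

#: 15N/1H gyromagnetic ratio magnitude (frequency ratio).
N15_OVER_H1 = 0.101329118

#: ns/kDa slope of the empirical MW -> tau_c rule (25 C, water).
TAUC_NS_PER_KDA = 0.6

#: sin^2(theta) floor below which the offset correction is unreliable.
SIN2_FLOOR = 0.25


@dataclass
class DecayFit:
    """Result of one mono-exponential decay fit."""

    rate: float  # s^-1
    error: float  # s^-1
    amplitude: float
    ok: bool = True
    flag: str = ""


def fit_decay(
    delays: Sequence[float], intensities: Sequence[float]
) -> DecayFit:
    """Least-squares fit of I(t) = I0 exp(-R t) to one residue's decay.

    Requires >= 4 distinct delays.  The quoted error combines the fit
    covariance with the duplicate-pair scatter (half the absolute intensity
    difference of each duplicated delay, propagated as an intensity noise
    floor) in quadrature.  Non-decaying series (fitted rate consistent with
    zero) are flagged ``non-decaying``; non-convergent fits are flagged and
    should be excluded downstream.
    """
    t = np.asarray(delays, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(np.unique(t)) < 4:
        raise EmptyInputError("need at least 4 distinct delays")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities")

    # duplicate-pair scatter -> intensity noise estimate
    dup_sigma = 0.0
    uniq, counts = np.unique(t, return_counts=True)
    diffs = []
    for u in uniq[counts > 1]:
        vals = y[t == u]
        diffs.append(0.5 * np.abs(vals.max() - vals.min()))
    if diffs:
        dup_sigma = float(np.mean(diffs))

    # log-linear seed (positive intensities only)
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (math.exp(intercept), max(-slope, 1e-6))
    else:
        p0 = (float(y.max()), 1.0)

    def model(tt, i0, r):
        return i0 * np.exp(-r * tt)

    sigma = np.full_like(y, dup_sigma if dup_sigma > 0 else 1.0)
    try:
        popt, pcov = curve_fit(
            model, t, y, p0=p0, sigma=sigma, absolute_sigma=dup_sigma > 0, maxfev=5000
        )
    except RuntimeError:
        return DecayFit(rate=np.nan, error=np.nan, amplitude=np.nan, ok=False, flag="non-convergent")
    i0, rate = float(popt[0]), float(popt[1])
    cov_err = float(np.sqrt(max(pcov[1, 1], 0.0))) if np.all(np.isfinite(pcov)) else np.nan
    # duplicate scatter mapped to a rate error through the fit weighting is
    # already inside cov_err when absolute_sigma; pool a relative floor otherwise
    err = cov_err if np.isfinite(cov_err) else 0.0
    fit = DecayFit(rate=rate, error=err, amplitude=i0)
    # negligible decay over the sampled window -> boundary case, flagged
    if rate <= 0 or rate * float(t.max()) < 1e-3:
        fit.flag = "non-decaying"
        fit.ok = False
    return fit


def offset_correct_r2(r1rho: float, r1: float, nu1: float, delta_nu: float) -> float:
    """Correct R1rho to R2 for resonance offset.

    theta = atan(nu1/dnu); R2 = (R1rho - R1 cos^2 theta) / sin^2 theta.
    On resonance (dnu = 0, theta = 90 deg) R2 = R1rho.  Raises
    ConfigurationError when sin^2(theta) falls below the documented floor
    (spin-lock axis too close to z; correction unreliable).
    """
    if nu1 <= 0:
        raise ConfigurationError("spin-lock strength nu1 must be positive")
    if delta_nu == 0:
        return float(r1rho)
    theta = math.atan2(nu1, delta_nu)
    s2 = math.sin(theta) ** 2
    if s2 < SIN2_FLOOR:
        raise ConfigurationError(
            f"sin^2(theta) = {s2:.3f} below floor {SIN2_FLOOR}; offset too large"
        )
    c2 = math.cos(theta) ** 2
    return float((r1rho - r1 * c2) / s2)


def compose_r1rho(r1: float, r2: float, nu1: float, delta_nu: float) -> float:
    """Forward relation R1rho = R1 cos^2 theta + R2 sin^2 theta."""
    if delta_nu == 0:
        return float(r2)
    theta = math.atan2(nu1, delta_nu)
    return float(r1 * math.cos(theta) ** 2 + r2 * math.sin(theta) ** 2)


def nitrogen_larmor_mhz(field_1h_mhz: float) -> float:
    return field_1h_mhz * N15_OVER_H1


def tumbling_time(r2_over_r1: float, field_1h_mhz: float) -> float:
    """Rotational correlation time (ns) from the R2/R1 ratio.

    tau_c = sqrt(6 R2/R1 - 7) / (4 pi nu_N); valid only for
    R2/R1 > 7/6 (slow-tumbling regime).
    """
    disc = 6.0 * r2_over_r1 - 7.0
    if disc <= 0:
        raise OutOfRegimeError(
            f"R2/R1 = {r2_over_r1:.3f} <= 7/6; outside the slow-tumbling regime"
        )
    nu_n_hz = nitrogen_larmor_mhz(field_1h_mhz) * 1e6
    tau_s = math.sqrt(disc) / (4.0 * math.pi * nu_n_hz)
    return tau_s * 1e9


def ratio_for_tauc(tauc_ns: float, field_1h_mhz: float) -> float:
    """Inverse of :func:`tumbling_time`: R2/R1 giving a target tau_c."""
    nu_n_hz = nitrogen_larmor_mhz(field_1h_mhz) * 1e6
    x = 4.0 * math.pi * nu_n_hz * tauc_ns * 1e-9
    return (x * x + 7.0) / 6.0


def theoretical_tauc(mw_kda: float) -> float:
    """Expected tau_c (ns, 1 decimal) of a globular protein of given mass,
    from the empirical 0.6 ns/kDa rule (25 C, water)."""
    if mw_kda <= 0:
        raise ValueError("molecular weight must be positive")
    return round(TAUC_NS_PER_KDA * mw_kda, 1)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def read_decay_table(path: str | Path) -> pd.DataFrame:
    """Delimited decay table: residue, delay_s, intensity[, replicate_id]."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("residue", "delay_s", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return df


def fit_rates(decays: pd.DataFrame) -> pd.DataFrame:
    """Fit every residue in a decay table; returns residue, rate, error, ok."""
    rows = []
    for res, grp in decays.groupby("residue"):
        try:
            fit = fit_decay(grp["delay_s"].to_numpy(), grp["intensity"].to_numpy())
        except EmptyInputError:
            continue
        rows.append(
            {
                "residue": int(res),
                "rate": fit.rate,
                "error": fit.error,
                "amplitude": fit.amplitude,
                "ok": fit.ok,
                "flag": fit.flag,
            }
        )
    return pd.DataFrame(rows)


def rate_table(
    r1: pd.DataFrame,
    r1rho: pd.DataFrame,
    nu1_hz: float,
    offsets_hz: pd.Series | dict | float = 0.0,
) -> pd.DataFrame:
    """Merge fitted R1/R1rho into a per-residue rate table with R2.

    ``offsets_hz`` may be a scalar or a per-residue mapping of the spin-lock
    offset dnu.  Residues flagged in either fit are dropped.
    """
    a = r1[r1["ok"]].set_index("residue")
    b = r1rho[r1rho["ok"]].set_index("residue")
    shared = a.index.intersection(b.index)
    rows = []
    for res in shared:
        dnu = (
            float(offsets_hz)
            if np.isscalar(offsets_hz)
            else float(offsets_hz.get(res, 0.0))
        )
        try:
            r2 = offset_correct_r2(b.loc[res, "rate"], a.loc[res, "rate"], nu1_hz, dnu)
        except ConfigurationError:
            continue
        rows.append(
            {
                "residue": int(res),
                "R1": a.loc[res, "rate"],
                "R1_err": a.loc[res, "error"],
                "R1rho": b.loc[res, "rate"],
                "R1rho_err": b.loc[res, "error"],
                "R2": r2,
                "nu1_hz": nu1_hz,
                "offset_hz": dnu,
            }
        )
    return pd.DataFrame(rows)


def tumbling_summary(rates: pd.DataFrame, field_1h_mhz: float) -> pd.DataFrame:
    """Per-residue tau_c (ns) from a rate table; out-of-regime residues dropped."""
    rows = []
    for row in rates.itertuples():
        try:
            tc = tumbling_time(row.R2 / row.R1, field_1h_mhz)
        except OutOfRegimeError:
            continue
        rows.append({"residue": int(row.residue), "tauc_ns": tc})
    out = pd.DataFrame(rows)
    out.attrs["field_1h_mhz"] = field_1h_mhz
    return out


def domain_average_tauc(
    summary: pd.DataFrame, partition: DomainPartition, chain_id: str | None = None
) -> dict[str, tuple[float, float]]:
    """Arithmetic mean and sample SD of tau_c per partition segment.

    Segments with fewer than two valid residues are skipped (with a warning
    entry absent from the result).  Only residues inside a segment's range
    contribute to that segment.
    """
    out: dict[str, tuple[float, float]] = {}
    for seg in partition.segments:
        if chain_id is not None and seg.chain_id != chain_id:
            continue
        mask = summary["residue"].between(seg.start, seg.stop)
        vals = summary.loc[mask, "tauc_ns"].to_numpy()
        if len(vals) < 2:
            continue
        out[seg.name] = (float(np.mean(vals)), float(np.std(vals, ddof=1)))
    return out
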