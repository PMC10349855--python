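"""Paramagnetic relaxation enhancement: ratios -> Gamma2 -> distances.

A nitroxide spin label (e.g. PROXYL on an engineered cysteine) broadens the
amide resonances of nearby residues.  The observable is the ratio of peak
intensities with the label oxidized (paramagnetic) and reduced
(diamagnetic),

    I_para / I_dia = R2 exp(-Gamma2 t) / (R2 + Gamma2),

where R2 is the diamagnetic transverse rate and t the total transverse
evolution period of the HSQC.  Gamma2 relates to the electron-amide distance
through the Solomon-Bloembergen equation

    Gamma2 = K / r^6 * (4 tau_c + 3 tau_c / (1 + omega_H^2 tau_c^2)),

with K = 1.23e-32 cm^6 s^-2 for a nitroxide.  Ratios in an intermediate
window (default 0.15-0.85) convert quantitatively to distances with
flat-bottom bounds; ratios below/above that window carry only an upper/lower
distance bound.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigurationError, EmptyOverlapError, OutOfRegimeError
from .structure import Conformer

logger = logging.getLogger(__name__)

#: Solomon-Bloembergen prefactor for a nitroxide-amide proton pair, cm^6 s^-2.
K_SB_CM6 = 1.23e-32

#: cm -> Angstrom
_CM_TO_ANG = 1e8

#: Default reach of the effective label position from CA along CA->CB, Angstrom.
LABEL_OFFSET = 6.0


@dataclass(frozen=True)
class SpinLabelSite:
    """Nitroxide label attachment: the effective unpaired-electron position is
    a fixed-length offset from CA along the CA->CB direction (side-chain
    proxy), falling back to CA when no CB exists."""

    residue_number: int
    chain_id: str = "A"
    label: str = "PROXYL"
    offset: float = LABEL_OFFSET

    def effective_position(self, conf: Conformer) -> np.ndarray:
        ca = conf.get(self.chain_id, self.residue_number, "CA")
        try:
            cb = conf.get(self.chain_id, self.residue_number, "CB")
        except KeyError:
            return np.asarray(ca, dtype=float)
        direction = cb - ca
        norm = np.linalg.norm(direction)
        if norm == 0:
            return np.asarray(ca, dtype=float)
        return ca + direction / norm * self.offset


@dataclass(frozen=True)
class PREParams:
    """Everything needed to turn intensity ratios into distance restraints."""

    tauc_ns: float
    field_1h_mhz: float
    t_evol_s: float
    r2_dia: float  # s^-1
    low_cut: float = 0.15
    high_cut: float = 0.85
    quantitative_tol: float = 4.0  # Angstrom, +/- around the converted distance

    def __post_init__(self) -> None:
        for name in ("tauc_ns", "field_1h_mhz", "t_evol_s", "r2_dia"):
            if getattr(self, name) is None or getattr(self, name) <= 0:
                raise ConfigurationError(f"PREParams.{name} must be positive")
        if not 0 < self.low_cut < self.high_cut < 1:
            raise ConfigurationError("need 0 < low_cut < high_cut < 1")


@dataclass(frozen=True)
class DistanceRestraint:
    """Flat-bottom distance restraint between an amide and a label site.

    ``klass`` is 'upper' (strong broadening: distance below bound), 'lower'
    (no broadening: distance above bound) or 'quantitative' (two-sided).
    """

    chain_id: str
    residue_number: int
    atom_name: str
    site: SpinLabelSite
    klass: str
    target: float
    lower: float
    upper: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (self.lower <= self.target <= self.upper):
            raise ValueError("need lower <= target <= upper")
        if self.weight <= 0:
            raise ValueError("weight must be positive")


# ---------------------------------------------------------------------------
# Ratio arithmetic
# ---------------------------------------------------------------------------


def intensity_ratio(para: pd.DataFrame, dia: pd.DataFrame) -> pd.DataFrame:
    """Per-residue I_para/I_dia over residues shared by both peak tables.

    Residues with non-positive diamagnetic intensity are skipped with a
    warning.  Errors propagate from optional ``intensity_err`` columns.
    Ratios above 1.2 are flagged anomalous.
    """
    p = para.set_index("residue_number")
    d = dia.set_index("residue_number")
    shared = p.index.intersection(d.index)
    if len(shared) == 0:
        raise EmptyOverlapError("paramagnetic and diamagnetic tables share no residues")
    rows = []
    for res in shared:
        i_d = float(d.loc[res, "intensity"])
        if i_d <= 0:
            logger.warning("PRE: residue %d has non-positive diamagnetic intensity; skipped", res)
            continue
        i_p = float(p.loc[res, "intensity"])
        ratio = i_p / i_d
        err = np.nan
        if "intensity_err" in p.columns and "intensity_err" in d.columns:
            ep = float(p.loc[res, "intensity_err"])
            ed = float(d.loc[res, "intensity_err"])
            err = abs(ratio) * math.sqrt((ep / i_p) ** 2 + (ed / i_d) ** 2) if i_p != 0 else ed / i_d
        rows.append(
            {
                "residue": int(res),
                "ratio": ratio,
                "error": err,
                "anomalous": ratio > 1.2,
            }
        )
    return pd.DataFrame(rows).sort_values("residue", ignore_index=True)


def forward_ratio(gamma2: float, r2_dia: float, t_evol_s: float) -> float:
    """I_para/I_dia predicted for a given Gamma2."""
    return r2_dia * math.exp(-gamma2 * t_evol_s) / (r2_dia + gamma2)


def ratio_to_gamma2(ratio: float, r2_dia: float, t_evol_s: float) -> tuple[float, str]:
    """Invert the intensity-ratio relation for Gamma2 (s^-1) by bisection.

    The right-hand side is strictly decreasing in Gamma2, so the root is
    unique; solved to 1e-8 relative.  Returns (gamma2, flag):
    flag '' for a clean inversion, 'no-effect' for ratio >= 1 (Gamma2 = 0),
    'lower-bound-only' for ratio = 0 (Gamma2 unbounded; inf returned).
    """
    if r2_dia <= 0 or t_evol_s <= 0:
        raise ConfigurationError("r2_dia and t_evol must be positive")
    if ratio < 0:
        raise ValueError("ratio must be non-negative")
    if ratio >= 1.0:
        return 0.0, "no-effect"
    if ratio == 0.0:
        return math.inf, "lower-bound-only"
    hi = 1.0
    while forward_ratio(hi, r2_dia, t_evol_s) > ratio:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover
            return math.inf, "lower-bound-only"
    g = brentq(
        lambda g2: forward_ratio(g2, r2_dia, t_evol_s) - ratio,
        0.0,
        hi,
        xtol=1e-12,
        rtol=1e-10,
    )
    return float(g), ""


def _sb_spectral(tauc_ns: float, field_1h_mhz: float) -> float:
    """4 tau_c + 3 tau_c / (1 + omega_H^2 tau_c^2), in seconds."""
    tau = tauc_ns * 1e-9
    omega_h = 2.0 * math.pi * field_1h_mhz * 1e6
    return 4.0 * tau + 3.0 * tau / (1.0 + (omega_h * tau) ** 2)


def gamma2_to_distance(gamma2: float, tauc_ns: float, field_1h_mhz: float) -> float:
    """Electron-proton distance (Angstrom) from Gamma2 via Solomon-Bloembergen."""
    if gamma2 <= 0:
        raise OutOfRegimeError("Gamma2 must be positive for a defined distance")
    r6_cm6 = K_SB_CM6 / gamma2 * _sb_spectral(tauc_ns, field_1h_mhz)
    return (r6_cm6 ** (1.0 / 6.0)) * _CM_TO_ANG


def distance_to_gamma2(r_ang: float, tauc_ns: float, field_1h_mhz: float) -> float:
    """Inverse of :func:`gamma2_to_distance`."""
    if r_ang <= 0:
        raise ValueError("distance must be positive")
    r_cm = r_ang / _CM_TO_ANG
    return K_SB_CM6 / (r_cm**6) * _sb_spectral(tauc_ns, field_1h_mhz)


# ---------------------------------------------------------------------------
# Restraint construction and back-calculation
# ---------------------------------------------------------------------------


def classify_and_build_restraints(
    profile: pd.DataFrame,
    site: SpinLabelSite,
    params: PREParams,
    chain_id: str = "A",
) -> list[DistanceRestraint]:
    """One flat-bottom restraint per profiled residue, classified by ratio.

    ratio < low_cut         -> 'upper': distance below r(low_cut)
    low_cut..high_cut       -> 'quantitative': target +/- quantitative_tol
    ratio > high_cut        -> 'lower': distance above r(high_cut)

    The classification is exhaustive and mutually exclusive over ratio >= 0.
    Restraints attach the amide nitrogen proxy (atom N) of each residue to
    the site's effective label position.
    """
    if len(profile) == 0:
        raise EmptyOverlapError("empty PRE profile")
    g_low, _ = ratio_to_gamma2(params.low_cut, params.r2_dia, params.t_evol_s)
    g_high, _ = ratio_to_gamma2(params.high_cut, params.r2_dia, params.t_evol_s)
    r_low = gamma2_to_distance(g_low, params.tauc_ns, params.field_1h_mhz)
    r_high = gamma2_to_distance(g_high, params.tauc_ns, params.field_1h_mhz)
    out: list[DistanceRestraint] = []
    for row in profile.itertuples():
        ratio = float(row.ratio)
        res = int(row.residue)
        if ratio < params.low_cut:
            out.append(
                DistanceRestraint(
                    chain_id=chain_id,
                    residue_number=res,
                    atom_name="N",
                    site=site,
                    klass="upper",
                    target=r_low,
                    lower=0.0,
                    upper=r_low,
                )
            )
        elif ratio <= params.high_cut:
            g2, flag = ratio_to_gamma2(ratio, params.r2_dia, params.t_evol_s)
            r = gamma2_to_distance(g2, params.tauc_ns, params.field_1h_mhz)
            out.append(
                DistanceRestraint(
                    chain_id=chain_id,
                    residue_number=res,
                    atom_name="N",
                    site=site,
                    klass="quantitative",
                    target=r,
                    lower=max(r - params.quantitative_tol, 0.0),
                    upper=r + params.quantitative_tol,
                )
            )
        else:
            out.append(
                DistanceRestraint(
                    chain_id=chain_id,
                    residue_number=res,
                    atom_name="N",
                    site=site,
                    klass="lower",
                    target=r_high,
                    lower=r_high,
                    upper=math.inf,
                )
            )
    return out


def backcalculate_pre(
    conformer: Conformer,
    site: SpinLabelSite,
    tauc_ns: float,
    field_1h_mhz: float,
    t_evol_s: float,
    r2_dia: float,
    chain_id: str = "A",
) -> pd.DataFrame:
    """Predicted I_para/I_dia profile of a conformer for one label site.

    Uses the amide nitrogen (atom N) as the proton-position proxy for each
    residue; residues without one are skipped with a warning.
    """
    label_pos = site.effective_position(conformer)
    rows = []
    for res in conformer.residues(chain_id):
        try:
            n_pos = conformer.get(chain_id, res, "N")
        except KeyError:
            logger.warning("PRE back-calculation: residue %s:%d has no N; skipped", chain_id, res)
            continue
        r = float(np.linalg.norm(n_pos - label_pos))
        g2 = distance_to_gamma2(r, tauc_ns, field_1h_mhz)
        rows.append(
            {
                "residue": int(res),
                "ratio": forward_ratio(g2, r2_dia, t_evol_s),
                "distance": r,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_pre_profile(path: str | Path) -> pd.DataFrame:
    """Delimited PRE profile: residue, ratio[, error]."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("residue", "ratio"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col}")
    return df


def write_pre_profile(profile: pd.DataFrame, path: str | Path) -> None:
    profile.to_csv(path, sep="\t", index=False)


def write_restraints_table(
    restraints: Sequence[DistanceRestraint], path: str | Path
) -> None:
    rows = [
        {
            "chain": r.chain_id,
            "residue": r.residue_number,
            "atom": r.atom_name,
            "site_residue": r.site.residue_number,
            "site_chain": r.site.chain_id,
            "class": r.klass,
            "target": r.target,
            "lower": r.lower,
            "upper": r.upper,
            "weight": r.weight,
        }
        for r in restraints
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_restraints_table(path: str | Path) -> list[DistanceRestraint]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.to_dict("records"):
        out.append(
            DistanceRestraint(
                chain_id=str(row["chain"]),
                residue_number=int(row["residue"]),
                atom_name=str(row["atom"]),
                site=SpinLabelSite(
                    residue_number=int(row["site_residue"]),
                    chain_id=str(row["site_chain"]),
                ),
                klass=str(row["class"]),
                target=float(row["target"]),
                lower=float(row["lower"]),
                upper=float(row["upper"]),
                weight=float(row["weight"]),
            )
        )
    return out


def write_assign_format(
    restraints: Sequence[DistanceRestraint], path: str | Path
) -> None:
    """Simple assign-style export for external refinement programs:
    one line per restraint, ``assign (chain resid atom) (site resid) target dminus dplus``."""
    with open(path, "w") as fh:
        for r in restraints:
            dminus = r.target - r.lower if math.isfinite(r.lower) else r.target
            dplus = r.upper - r.target if math.isfinite(r.upper) else 99.0
            fh.write(
                f"assign (segid {r.chain_id} and resid {r.residue_number} and name {r.atom_name}) "
                f"(segid {r.site.chain_id} and resid {r.site.residue_number} and name NO) "
                f"{r.target:.2f} {dminus:.2f} {dplus:.2f} ! class {r.klass}\n"
            )
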