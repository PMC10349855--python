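"""Isothermal titration calorimetry: one-site isotherms and thermodynamics.

The one-site (Wiseman) model links injection heats to the dissociation
constant KD, the molar binding enthalpy dH and the stoichiometry N.  With
cell (macromolecule) concentration M_t, titrant concentration X_t and site
concentration N*M_t, the bound complex after each injection follows the
binding quadratic

    [MX] = ((S + X + KD) - sqrt((S + X + KD)^2 - 4 S X)) / 2,   S = N M_t,

and the measured heat of injection i is the change in cell bound-heat,
corrected for the complex displaced by the injected volume.  Displacement is
modeled as perfect-mixing overflow: each injection of volume v dilutes all
cell species by exp(-v/V0) and delivers titrant at the same rate, which
conserves mass exactly at every step.  Thermodynamics follow
dG = RT ln KD and -TdS = dG - dH with R = 1.987e-3 kcal/(mol K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import ConfigurationError, FitError

#: Gas constant, kcal mol^-1 K^-1.
R_KCAL = 1.987e-3

#: c-value window commonly considered fittable.
C_WINDOW = (1.0, 1000.0)


@dataclass
class Isotherm:
    """Injection protocol plus measured (or simulated) heats.

    Heats are total kcal per injection (negative = exothermic); volumes in
    liters, concentrations molar, temperature Kelvin.
    """

    cell_volume_l: float
    cell_conc_m: float
    syringe_conc_m: float
    injection_volumes_l: np.ndarray
    heats_kcal: np.ndarray
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        self.injection_volumes_l = np.asarray(self.injection_volumes_l, dtype=float)
        self.heats_kcal = np.asarray(self.heats_kcal, dtype=float)
        if self.cell_volume_l <= 0 or self.cell_conc_m <= 0 or self.syringe_conc_m <= 0:
            raise ConfigurationError("volumes and concentrations must be positive")
        if len(self.injection_volumes_l) != len(self.heats_kcal):
            raise ConfigurationError("injection/heat length mismatch")
        if not np.all(np.isfinite(self.heats_kcal)):
            raise ConfigurationError("non-finite heats")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_l)

    def moles_injected(self) -> np.ndarray:
        """Moles of titrant delivered per injection."""
        return self.syringe_conc_m * self.injection_volumes_l

    def normalized_heats(self) -> np.ndarray:
        """kcal per mole of injectant."""
        return self.heats_kcal / self.moles_injected()


@dataclass
class BindingFit:
    kd_m: float
    kd_err: float
    dh_kcal: float
    dh_err: float
    n: float
    n_err: float
    residuals: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    n_fixed: bool = False

    @property
    def ka_m(self) -> float:
        return 1.0 / self.kd_m


def c_value(kd_m: float, cell_conc_m: float, n: float = 1.0) -> float:
    """Wiseman c parameter, N [M]_cell / KD (sigmoidality diagnostic)."""
    return n * cell_conc_m / kd_m


def _bound_concentration(sites: np.ndarray, xt: np.ndarray, kd: float) -> np.ndarray:
    s = sites + xt + kd
    return 0.5 * (s - np.sqrt(np.clip(s * s - 4.0 * sites * xt, 0.0, None)))


def _model_heats(
    kd: float,
    dh: float,
    n: float,
    cell_volume_l: float,
    cell_conc_m: float,
    syringe_conc_m: float,
    injection_volumes_l: np.ndarray,
) -> np.ndarray:
    """Per-injection heats (kcal) of the one-site model with overflow dilution."""
    v0 = cell_volume_l
    mt = cell_conc_m
    xt = 0.0
    mx_prev = 0.0
    heats = np.empty(len(injection_volumes_l))
    for i, dv in enumerate(injection_volumes_l):
        f = math.exp(-dv / v0)
        mt = mt * f
        xt = xt * f + syringe_conc_m * (1.0 - f)
        mx = float(_bound_concentration(np.array(n * mt), np.array(xt), kd))
        heats[i] = v0 * dh * (mx - mx_prev * f)
        mx_prev = mx
    return heats


def simulate_isotherm(
    kd_m: float,
    dh_kcal: float,
    n: float,
    cell_volume_l: float = 200e-6,
    cell_conc_m: float = 10e-6,
    syringe_conc_m: float = 150e-6,
    injection_volumes_l: Sequence[float] | None = None,
    temperature_k: float = 298.15,
    noise_kcal: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Isotherm:
    """Forward-simulate a one-site titration (default: 26 x 1.5 uL injections).

    Gaussian noise of the given standard deviation (kcal) is added to each
    injection heat.  A c-value outside the fittable window triggers a
    warning-style flag in the returned object's attrs-free diagnostics via
    :func:`c_value`; callers are expected to check it.
    """
    if injection_volumes_l is None:
        injection_volumes_l = np.full(26, 1.5e-6)
    injection_volumes_l = np.asarray(injection_volumes_l, dtype=float)
    heats = _model_heats(
        kd_m, dh_kcal, n, cell_volume_l, cell_conc_m, syringe_conc_m, injection_volumes_l
    )
    if noise_kcal > 0:
        rng = rng or np.random.default_rng()
        heats = heats + rng.normal(0.0, noise_kcal, size=len(heats))
    return Isotherm(
        cell_volume_l=cell_volume_l,
        cell_conc_m=cell_conc_m,
        syringe_conc_m=syringe_conc_m,
        injection_volumes_l=injection_volumes_l,
        heats_kcal=heats,
        temperature_k=temperature_k,
    )


def fit_one_site(
    isotherm: Isotherm,
    fix_n: float | None = None,
    skip_first: bool = False,
) -> BindingFit:
    """Weighted nonlinear least squares of the one-site model.

    Parameters are (log10 KD, dH, N); N may be fixed (``fix_n``), as is
    common for weak binders where the stoichiometry is not determined by the
    data.  Initialization scans a log-spaced KD grid, solving dH linearly at
    each node.  Requires >= 10 informative injections.  Errors come from the
    Jacobian-based covariance at the solution.
    """
    use = np.ones(isotherm.n_injections, dtype=bool)
    if skip_first:
        use[0] = False
    if int(use.sum()) < 10:
        raise ConfigurationError("need at least 10 informative injections")

    vols = isotherm.injection_volumes_l
    y = isotherm.heats_kcal

    def heats_for(kd: float, dh: float, n: float) -> np.ndarray:
        return _model_heats(
            kd,
            dh,
            n,
            isotherm.cell_volume_l,
            isotherm.cell_conc_m,
            isotherm.syringe_conc_m,
            vols,
        )

    # --- initialization: KD grid with linear dH solve (shape is linear in dH)
    best = None
    n0 = fix_n if fix_n is not None else 1.0
    for log_kd in np.linspace(-9.5, -2.5, 29):
        shape = heats_for(10.0**log_kd, 1.0, n0)
        denom = float(shape[use] @ shape[use])
        if denom == 0:
            continue
        dh0 = float(shape[use] @ y[use]) / denom
        sse = float(np.sum((dh0 * shape[use] - y[use]) ** 2))
        if best is None or sse < best[0]:
            best = (sse, log_kd, dh0)
    if best is None:
        raise FitError("degenerate isotherm")
    _, log_kd0, dh0 = best

    if fix_n is not None:
        x0 = np.array([log_kd0, dh0])

        def resid(x):
            return heats_for(10.0 ** x[0], x[1], fix_n)[use] - y[use]

    else:
        x0 = np.array([log_kd0, dh0, 1.0])

        def resid(x):
            return heats_for(10.0 ** x[0], x[1], x[2])[use] - y[use]

    sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=20000)
    if not sol.success and sol.status <= 0:
        raise FitError(f"one-site fit did not converge: {sol.message}")

    dof = max(int(use.sum()) - len(sol.x), 1)
    s2 = float(sol.fun @ sol.fun) / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        perr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        perr = np.full(len(sol.x), np.nan)

    kd = 10.0 ** sol.x[0]
    kd_err = kd * math.log(10.0) * perr[0]
    if fix_n is not None:
        return BindingFit(
            kd_m=kd,
            kd_err=kd_err,
            dh_kcal=float(sol.x[1]),
            dh_err=float(perr[1]),
            n=float(fix_n),
            n_err=0.0,
            residuals=sol.fun,
            n_fixed=True,
        )
    return BindingFit(
        kd_m=kd,
        kd_err=kd_err,
        dh_kcal=float(sol.x[1]),
        dh_err=float(perr[1]),
        n=float(sol.x[2]),
        n_err=float(perr[2]),
        residuals=sol.fun,
    )


def thermodynamics(
    kd_m: float, dh_kcal: float, temperature_k: float = 298.15
) -> tuple[float, float]:
    """(dG, -TdS) in kcal/mol at the stated temperature.

    dG = RT ln KD (KD in M; dG = 0 at the 1 M reference state) and
    -TdS = dG - dH, so dG = dH + (-TdS) closes exactly.
    """
    if kd_m <= 0:
        raise ValueError("KD must be positive")
    dg = R_KCAL * temperature_k * math.log(kd_m)
    return dg, dg - dh_kcal


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_isotherm(path: str | Path) -> Isotherm:
    """Delimited isotherm: header block of ``# key value`` lines (cell_volume_ul,
    cell_conc_um, syringe_conc_um, temperature_k) then columns
    injection_index, volume_ul, heat_ucal."""
    meta: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2:
                    meta[parts[0]] = float(parts[1])
                continue
            parts = line.split()
            if parts[0] == "injection_index":
                continue
            rows.append([float(p) for p in parts])
    required = {"cell_volume_ul", "cell_conc_um", "syringe_conc_um"}
    if not required <= set(meta):
        raise ConfigurationError(f"{path}: missing header keys {required - set(meta)}")
    arr = np.asarray(rows)
    return Isotherm(
        cell_volume_l=meta["cell_volume_ul"] * 1e-6,
        cell_conc_m=meta["cell_conc_um"] * 1e-6,
        syringe_conc_m=meta["syringe_conc_um"] * 1e-6,
        injection_volumes_l=arr[:, 1] * 1e-6,
        heats_kcal=arr[:, 2] * 1e-9,  # ucal -> kcal
        temperature_k=meta.get("temperature_k", 298.15),
    )


def write_isotherm(isotherm: Isotherm, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# cell_volume_ul {isotherm.cell_volume_l * 1e6:.6g}\n")
        fh.write(f"# cell_conc_um {isotherm.cell_conc_m * 1e6:.6g}\n")
        fh.write(f"# syringe_conc_um {isotherm.syringe_conc_m * 1e6:.6g}\n")
        fh.write(f"# temperature_k {isotherm.temperature_k:.6g}\n")
        fh.write("injection_index volume_ul heat_ucal\n")
        for i, (v, h) in enumerate(
            zip(isotherm.injection_volumes_l, isotherm.heats_kcal), start=1
        ):
            fh.write(f"{i} {v * 1e6:.6g} {h * 1e9:.8g}\n")


def fit_report(fit: BindingFit, temperature_k: float = 298.15) -> dict:
    dg, mtds = thermodynamics(fit.kd_m, fit.dh_kcal, temperature_k)
    return {
        "KD_M": fit.kd_m,
        "KD_err_M": fit.kd_err,
        "dH_kcal_mol": fit.dh_kcal,
        "dH_err_kcal_mol": fit.dh_err,
        "N": fit.n,
        "N_err": fit.n_err,
        "N_fixed": fit.n_fixed,
        "dG_kcal_mol": dg,
        "minus_TdS_kcal_mol": mtds,
        "temperature_K": temperature_k,
    }
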