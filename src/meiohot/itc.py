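"""Isothermal titration calorimetry: one-set-of-sites forward model, fit, and
thermodynamic derivations.

Model: a macromolecule M with N identical independent sites binds ligand X
with dissociation constant K_D and molar enthalpy dH. After injection i the
cell holds dilution-corrected totals M_i, X_i; the bound fraction of sites
Theta_i is the root in [0, 1] of

    Theta^2 - Theta * (1 + X/(N M) + K_D/(N M)) + X/(N M) = 0,

the cumulative heat is Q_i = N Theta_i M_i dH V0 (converted to ucal), and the
per-injection heat corrects for the displaced-volume average:

    dQ_i = Q_i - Q_{i-1} + (v_i/V0) * (Q_i + Q_{i-1}) / 2 + baseline.

Units are fixed: concentrations uM, volumes uL, dH kcal/mol, heats ucal;
convert at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationSchedule",
    "BindingParams",
    "InjectionHeats",
    "ThermoDerived",
    "forward_one_set_of_sites",
    "fit_one_set_of_sites",
    "derive_thermo",
]

R_KCAL = 1.98720425864083e-3  # gas constant, kcal / (mol K)
_UCAL_PER_UM_UL_KCAL = 1e-3  # uM * uL * kcal/mol -> ucal


@dataclass
class TitrationSchedule:
    """Cell volume V0 (uL), cell macromolecule M0 (uM), syringe ligand X0
    (uM), per-injection volumes (uL), temperature (K)."""

    cell_volume: float  # uL
    cell_conc: float  # uM macromolecule
    syringe_conc: float  # uM ligand
    injection_volumes: Sequence[float]  # uL each
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if min(self.cell_volume, self.cell_conc, self.syringe_conc, self.temperature) <= 0:
            raise ValueError("volumes, concentrations and temperature must be positive")
        if (self.injection_volumes <= 0).any():
            raise ValueError("injection volumes must be positive")
        if len(self.injection_volumes) < 5:
            raise ValueError("need at least 5 injections")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def dilution_corrected_totals(self):
        """Totals in the cell after each injection, with the standard
        perfusion-cell correction for displaced volume."""
        dV = np.cumsum(self.injection_volumes)
        V0 = self.cell_volume
        factor = 1.0 + dV / (2.0 * V0)
        M = self.cell_conc * (1.0 - dV / (2.0 * V0)) / factor
        X = self.syringe_conc * (dV / V0) / factor
        return M, X

    @classmethod
    def uniform(cls, n: int = 16, volume: float = 2.5, cell_volume: float = 200.0,
                cell_conc: float = 25.0, syringe_conc: float = 343.0,
                temperature: float = 298.15) -> "TitrationSchedule":
        return cls(cell_volume, cell_conc, syringe_conc, [volume] * n, temperature)


@dataclass
class BindingParams:
    """One-set-of-sites parameters: K_D (uM), dH (kcal/mol), N (sites per
    macromolecule), optional per-injection baseline offset (ucal)."""

    kd: float  # uM
    dh: float  # kcal/mol
    n: float = 1.0
    baseline: float = 0.0  # ucal / injection

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("K_D must be positive")
        if self.n <= 0:
            raise ValueError("N must be positive")


@dataclass
class InjectionHeats:
    heats: np.ndarray  # ucal per injection
    molar_ratio: np.ndarray  # cumulative X/M per injection

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        if len(self.heats) != len(self.molar_ratio):
            raise ValueError("heats and molar_ratio must align")
        if not np.isfinite(self.heats).all():
            raise ValueError("non-finite heats")


@dataclass
class ThermoDerived:
    dg: float  # kcal/mol
    dh: float  # kcal/mol
    ds: float  # cal / (mol K)
    temperature: float  # K


def forward_one_set_of_sites(
    params: BindingParams, schedule: TitrationSchedule
) -> InjectionHeats:
    """Per-injection heats predicted by the one-set-of-sites model."""
    M, X = schedule.dilution_corrected_totals()
    NM = params.n * M
    b = 1.0 + X / NM + params.kd / NM
    disc = b * b - 4.0 * X / NM
    if (disc < 0).any():
        raise FloatingPointError("negative discriminant in binding quadratic")
    theta = (b - np.sqrt(disc)) / 2.0
    Q = params.n * theta * M * params.dh * schedule.cell_volume * _UCAL_PER_UM_UL_KCAL
    Qprev = np.concatenate([[0.0], Q[:-1]])
    v = schedule.injection_volumes
    dQ = Q - Qprev + (v / schedule.cell_volume) * (Q + Qprev) / 2.0 + params.baseline
    return InjectionHeats(dQ, X / M)


def _init_params(heats: np.ndarray, schedule: TitrationSchedule) -> BindingParams:
    """Initialization: N = 1; dH from the mean of the first three heats
    (assumed near-saturating binding of injected ligand); K_D from a
    steepest-slope heuristic on the isotherm sigmoid."""
    v = np.asarray(schedule.injection_volumes, float)
    # moles of ligand per early injection, in the units of Q (ucal per kcal/mol)
    inj_mol = schedule.syringe_conc * v[:3] * _UCAL_PER_UM_UL_KCAL
    dh0 = float(np.mean(heats[:3] / inj_mol))
    if dh0 == 0:
        dh0 = -1.0
    ratio = forward_one_set_of_sites(
        BindingParams(1.0, dh0 if dh0 else -1.0, 1.0), schedule
    ).molar_ratio
    slopes = np.abs(np.diff(heats))
    k = int(np.argmax(slopes))
    # sharper transition => larger c = N M0 / K_D; crude but only a start point
    width = max(ratio[min(k + 2, len(ratio) - 1)] - ratio[max(k - 2, 0)], 1e-3)
    c0 = float(np.clip(4.0 / width, 1.0, 1e4))
    kd0 = schedule.cell_conc / c0
    return BindingParams(kd=kd0, dh=dh0, n=1.0, baseline=0.0)


@dataclass
class FitResult:
    params: BindingParams
    residual_norm: float
    converged: bool
    message: str = ""
    n_injections: int = 0


def fit_one_set_of_sites(
    heats: np.ndarray,
    schedule: TitrationSchedule,
    init: Optional[BindingParams] = None,
) -> FitResult:
    """Nonlinear least squares over (log K_D, dH, N, baseline).

    K_D is fitted on a log scale for stability. Non-convergence is flagged in
    the result rather than raising.
    """
    heats = np.asarray(heats, dtype=float)
    if len(heats) != schedule.n_injections:
        raise ValueError("heats length must match the schedule")
    if len(heats) < 5:
        raise ValueError("need at least 5 injections to fit")
    p0 = init if init is not None else _init_params(heats, schedule)

    def residuals(x):
        logkd, dh, n, base = x
        p = BindingParams(np.exp(logkd), dh, max(n, 1e-9), base)
        return forward_one_set_of_sites(p, schedule).heats - heats

    x0 = np.array([np.log(p0.kd), p0.dh, p0.n, p0.baseline])
    res = least_squares(
        residuals,
        x0,
        bounds=([-30.0, -1e4, 1e-6, -np.inf], [30.0, 1e4, 1e3, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    params = BindingParams(
        kd=float(np.exp(res.x[0])), dh=float(res.x[1]),
        n=float(res.x[2]), baseline=float(res.x[3]),
    )
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
        message=res.message,
        n_injections=len(heats),
    )


def derive_thermo(params: BindingParams, temperature: float = 298.15) -> ThermoDerived:
    """Gibbs energy and entropy from the fitted affinity:
    dG = R T ln(K_D in molar), dS = (dH - dG) / T (cal/mol/K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kd_molar = params.kd * 1e-6
    dg = R_KCAL * temperature * np.log(kd_molar)
    ds = (params.dh - dg) / temperature * 1e3
    return ThermoDerived(dg=float(dg), dh=params.dh, ds=float(ds), temperature=temperature)
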