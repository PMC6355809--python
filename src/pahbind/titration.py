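"""Single-site fluorescence-titration binding analysis.

A PAH ligand partitions into one of the (equivalent, independent) interior
cavities of the RHCC-NT tetramer.  The observable is the change in ligand
fluorescence with increasing protein concentration; the normalized change

    y = (F - F0) / (Finf - F0) = Bmax * S_free / (Kd + S_free),   Bmax = 1

is the fraction of ligand bound, with ``S_free`` the concentration of
unoccupied binding sites.  Because ligand and protein concentrations are
comparable in a titration, ``S_free`` is obtained self-consistently from
the mass balance rather than approximated by the total protein.

All concentrations are mol/L, temperatures K, energies kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import lmfit

from .constants import R_KJ_PER_MOL_K, T_KD_DEFAULT
from .exceptions import DomainError, FitFailureError, InsufficientDataError, ValidationError

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "CapacityModel",
    "FitMode",
    "solve_free_sites",
    "fraction_bound",
    "fit_binding",
    "gibbs_from_kd",
    "binding_capacity",
]

_MAX_NFEV = 200  # per-start iteration cap for the least-squares optimizer


class FitMode(str, Enum):
    """Abscissa convention for the binding isotherm.

    ``free_sites``
        Free-site concentration from the self-consistent mass balance
        (follows the binding equation as written).
    ``total_protein``
        Total site concentration, valid when protein is in large excess.
    """

    free_sites = "free_sites"
    total_protein = "total_protein"


@dataclass(frozen=True)
class TitrationSeries:
    """One ligand's fluorescence intensities across protein concentrations.

    ``protein_total`` is the tetramer concentration; the number of binding
    sites per tetramer is supplied at fit time.  Exactly one zero-protein
    point is required — it defines the free-ligand intensity F0.
    """

    ligand_name: str
    ligand_total: float
    protein_total: np.ndarray
    intensity: np.ndarray
    emission_wavelength: float
    excitation_wavelength: float
    temperature: float = 293.15

    def __post_init__(self):
        p = np.asarray(self.protein_total, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "protein_total", p)
        object.__setattr__(self, "intensity", f)
        if p.ndim != 1 or f.ndim != 1 or p.size != f.size:
            raise ValidationError("protein_total and intensity must be 1-D and equal length")
        if p.size < 5:
            raise ValidationError(f"need at least 5 titration points, got {p.size}")
        if np.any(p < 0) or self.ligand_total < 0:
            raise ValidationError("concentrations must be non-negative")
        if np.count_nonzero(p == 0.0) != 1:
            raise ValidationError("exactly one zero-protein point is required (defines F0)")
        if np.unique(p).size != p.size:
            raise ValidationError("duplicate protein concentrations are not allowed")

    def sorted(self) -> "TitrationSeries":
        """Return a copy with points ordered by protein concentration."""
        order = np.argsort(self.protein_total)
        return TitrationSeries(
            self.ligand_name, self.ligand_total,
            self.protein_total[order], self.intensity[order],
            self.emission_wavelength, self.excitation_wavelength, self.temperature,
        )

    @property
    def f0(self) -> float:
        """Fluorescence of the free ligand (zero-protein point)."""
        return float(self.intensity[self.protein_total == 0.0][0])


@dataclass
class BindingFit:
    """Result of a single-site isotherm fit (Bmax fixed at 1)."""

    kd: float
    kd_se: float
    f0: float
    f_inf: float
    f_inf_se: float
    r_squared: float
    mode: FitMode
    sites_per_tetramer: int
    converged: bool
    n_iterations: int
    b_max: float = 1.0
    residual_ss: float = field(default=float("nan"))

    def gibbs(self, temperature: float = T_KD_DEFAULT) -> float:
        """Molar Gibbs energy RT ln Kd at ``temperature`` (kJ/mol)."""
        return gibbs_from_kd(self.kd, temperature)

    def kd_ci95(self) -> tuple[float, float]:
        """Normal-approximation 95% confidence interval for Kd."""
        half = 1.959964 * self.kd_se
        return (self.kd - half, self.kd + half)


@dataclass(frozen=True)
class CapacityModel:
    """Sorbent capacity bookkeeping: moles of ligand bound per mass of protein."""

    tetramer_molar_mass: float  # kg/mol
    sites_per_tetramer: int = 2
    occupancy: float = 1.0

    def __post_init__(self):
        if self.tetramer_molar_mass <= 0:
            raise ValidationError("molar mass must be positive")
        if self.sites_per_tetramer < 1:
            raise ValidationError("at least one site per tetramer")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValidationError("occupancy must lie in [0, 1]")


def solve_free_sites(protein_total, ligand_total: float, kd: float,
                     sites_per_tetramer: int = 2):
    """Concentration of unoccupied binding sites at equilibrium.

    Solves the mass balance for a single-site model with total site
    concentration ``S_tot = sites_per_tetramer * protein_total``:

        S_free^2 + S_free (Kd + L_tot - S_tot) - Kd S_tot = 0

    taking the positive root.  Accepts scalars or arrays for
    ``protein_total``; the result satisfies ``0 <= S_free <= S_tot``.
    """
    p = np.asarray(protein_total, dtype=float)
    if np.any(p < 0) or ligand_total < 0:
        raise DomainError("concentrations must be non-negative")
    if kd <= 0:
        raise DomainError("kd must be positive")
    if sites_per_tetramer < 1:
        raise DomainError("sites_per_tetramer must be >= 1")
    s_tot = sites_per_tetramer * p
    b = kd + ligand_total - s_tot
    disc = np.sqrt(b * b + 4.0 * kd * s_tot)
    # Cancellation-safe positive root of x^2 + b x - kd*s_tot = 0.
    root = np.where(b >= 0, 2.0 * kd * s_tot / (b + disc), 0.5 * (disc - b))
    root = np.clip(root, 0.0, s_tot)
    if p.ndim == 0:
        return float(root)
    return root


def fraction_bound(s_free, kd: float, b_max: float = 1.0):
    """Langmuir fraction bound y = Bmax s / (Kd + s)."""
    if kd <= 0:
        raise DomainError("kd must be positive")
    s = np.asarray(s_free, dtype=float)
    y = b_max * s / (kd + s)
    return float(y) if s.ndim == 0 else y


def _model_y(p_nonzero, kd, ligand_total, sites, mode: FitMode):
    if mode is FitMode.free_sites:
        s = solve_free_sites(p_nonzero, ligand_total, kd, sites)
    else:
        s = sites * p_nonzero
    return s / (kd + s)


def fit_binding(series: TitrationSeries, sites_per_tetramer: int = 2,
                mode: FitMode | str = FitMode.free_sites) -> BindingFit:
    """Fit (Kd, Finf) to a fluorescence titration by nonlinear least squares.

    F0 is pinned to the measured zero-protein intensity.  Residuals are
    minimized on the intensity scale, F - [F0 + (Finf - F0) y_model]; up
    to the amplitude normalization this equals the fraction-bound
    mismatch y_obs - y_model, but unlike a literal fraction-scale
    objective it is not degenerate in the joint (Kd, Finf) limit (a
    fraction-scale objective can be driven to zero by inflating both).
    R^2 is reported on the fraction-bound scale.  Five log-spaced Kd
    starts guard against local minima; the start with the lowest residual
    sum of squares wins.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 nonzero-protein points.
    FitFailureError
        No sign-consistent intensity trend versus protein concentration.
    """
    mode = FitMode(mode)
    s = series.sorted()
    f0 = s.f0
    nz = s.protein_total > 0
    p_nz, f_nz = s.protein_total[nz], s.intensity[nz]
    if p_nz.size < 4:
        raise InsufficientDataError(
            f"need >= 4 nonzero-protein points, got {p_nz.size}")

    # Direction check: the intensity must move consistently with protein.
    r_trend = float(np.corrcoef(p_nz, f_nz)[0, 1])
    if not np.isfinite(r_trend) or abs(r_trend) < 0.3:
        raise FitFailureError(
            "intensity has no sign-consistent trend with protein concentration",
            diagnostics={"pearson_r": r_trend, "f0": f0,
                         "intensity_range": (float(f_nz.min()), float(f_nz.max()))})

    amplitude_guess = f_nz[-1] - f0  # may be negative (quenching)

    def residual(params):
        kd = params["kd"].value
        f_inf = params["f_inf"].value
        y_model = _model_y(p_nz, kd, s.ligand_total, sites_per_tetramer, mode)
        return f_nz - (f0 + (f_inf - f0) * y_model)

    s_lo = sites_per_tetramer * p_nz.min()
    s_hi = sites_per_tetramer * p_nz.max()
    best = None
    for kd0 in np.geomspace(s_lo, s_hi, 5):
        params = lmfit.Parameters()
        params.add("kd", value=float(kd0), min=1e-300)
        params.add("f_inf", value=float(f0 + 1.2 * amplitude_guess))
        try:
            res = lmfit.minimize(residual, params, method="leastsq",
                                 max_nfev=_MAX_NFEV)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitFailureError("all optimizer starts failed",
                              diagnostics={"starts": 5, "mode": mode.value})

    kd_hat = float(best.params["kd"].value)
    f_inf_hat = float(best.params["f_inf"].value)
    kd_se = float(best.params["kd"].stderr or np.nan)
    f_inf_se = float(best.params["f_inf"].stderr or np.nan)

    y_obs = (f_nz - f0) / (f_inf_hat - f0)
    y_fit = _model_y(p_nz, kd_hat, s.ligand_total, sites_per_tetramer, mode)
    ss_res = float(np.sum((y_obs - y_fit) ** 2))
    ss_tot = float(np.sum((y_obs - y_obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    return BindingFit(
        kd=kd_hat, kd_se=kd_se, f0=f0, f_inf=f_inf_hat, f_inf_se=f_inf_se,
        r_squared=r2, mode=mode, sites_per_tetramer=sites_per_tetramer,
        converged=bool(best.success) and best.nfev < _MAX_NFEV,
        n_iterations=int(best.nfev), residual_ss=ss_res,
    )


def gibbs_from_kd(kd: float, temperature: float = T_KD_DEFAULT) -> float:
    """Molar Gibbs energy of binding, RT ln Kd, in kJ/mol.

    ``kd`` must be expressed in mol/L; negative results correspond to
    sub-molar dissociation constants (favorable binding).
    """
    if kd <= 0:
        raise DomainError("kd must be positive")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    return R_KJ_PER_MOL_K * temperature * float(np.log(kd))


def binding_capacity(model: CapacityModel, mass_mg: float) -> float:
    """Moles of ligand a given mass of sorbent can hold at full occupancy.

    ``mass_mg`` is milligrams of protein; the result is in mol:
    occupancy * sites * (mass / molar mass).
    """
    if mass_mg < 0:
        raise DomainError("mass must be non-negative")
    mass_kg = mass_mg * 1e-6
    return model.occupancy * model.sites_per_tetramer * mass_kg / model.tetramer_molar_mass
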