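"""Pyrene polarity probe (Py-value) and uptake kinetics.

Pyrene's vibronic band I (~373 nm) dominates in polar environments and
band III (~384 nm) in hydrophobic ones; their intensity ratio (the
Py-value) therefore reports on the microenvironment of the probe.  When
pyrene is taken up into a hydrophobic protein cavity the Py-value falls
below 1, and the band-III emission traced over time gives the uptake
kinetics.  The time course is modelled as a single-exponential approach
to equilibrium — pseudo-first-order, appropriate for the large protein
excess used in the uptake assay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import lmfit

from .exceptions import DomainError, FitFailureError, ValidationError

__all__ = [
    "EmissionSpectrum",
    "PyResult",
    "UptakeTimeCourse",
    "UptakeFit",
    "py_value",
    "fit_uptake",
    "BAND1_WINDOW",
    "BAND3_WINDOW",
]

#: Default extraction windows (nm) for pyrene bands I and III; the peak is
#: located by maximum within the window, tolerating small calibration shifts.
BAND1_WINDOW = (368.0, 378.0)
BAND3_WINDOW = (379.0, 390.0)


@dataclass(frozen=True)
class EmissionSpectrum:
    """A fluorescence emission spectrum on a strictly increasing nm grid."""

    wavelength: np.ndarray
    intensity: np.ndarray
    excitation_wavelength: float = 334.0

    def __post_init__(self):
        wl = np.asarray(self.wavelength, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", it)
        if wl.size != it.size or wl.ndim != 1:
            raise ValidationError("wavelength and intensity must be 1-D, equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if np.any(it < 0):
            raise ValidationError("intensities must be non-negative")


@dataclass(frozen=True)
class PyResult:
    """Band-I and band-III intensities and their ratio."""

    i_band1: float
    i_band3: float

    @property
    def py(self) -> float:
        return self.i_band1 / self.i_band3


@dataclass(frozen=True)
class UptakeTimeCourse:
    """Band-III emission intensity versus time during ligand uptake."""

    time: np.ndarray          # hours, strictly increasing from 0
    intensity: np.ndarray     # counts at the band-III emission wavelength
    ligand_total: float       # mol/L
    protein_total: float      # mol/L
    temperature: float = 283.15

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "intensity", f)
        if t.size != f.size or t.ndim != 1:
            raise ValidationError("time and intensity must be 1-D, equal length")
        if t[0] != 0.0:
            raise ValidationError("time course must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")


@dataclass
class UptakeFit:
    """Exponential uptake fit: rate, equilibration time, average rate.

    ``t_eq`` is the 99%-of-amplitude equilibration time ln(100)/k.
    ``avg_uptake_rate`` is mol ligand per (hour x mol protein), assuming
    complete uptake over t_eq.
    """

    rate_constant: float       # 1/h
    rate_constant_se: float
    f0: float
    f_inf: float
    t_eq: float                # h
    avg_uptake_rate: float     # mol ligand / (h * mol protein)
    plateau_reached: bool
    r_squared: float


def py_value(spectrum: EmissionSpectrum,
             band1_window: tuple[float, float] = BAND1_WINDOW,
             band3_window: tuple[float, float] = BAND3_WINDOW) -> PyResult:
    """Compute the Py-value (band I / band III intensity ratio).

    Each band intensity is the maximum within its wavelength window, so a
    spectrometer calibration shift of a nanometre or two does not change
    the result.  The windows must be disjoint and each contain at least
    one sample point.
    """
    lo1, hi1 = band1_window
    lo3, hi3 = band3_window
    if not (hi1 <= lo3 or hi3 <= lo1):
        raise DomainError("band windows must be disjoint")
    wl, it = spectrum.wavelength, spectrum.intensity
    m1 = (wl >= lo1) & (wl <= hi1)
    m3 = (wl >= lo3) & (wl <= hi3)
    if not m1.any() or not m3.any():
        raise DomainError("each band window must contain at least one sample point")
    i1 = float(it[m1].max())
    i3 = float(it[m3].max())
    if i3 <= 0:
        raise DomainError("band-III intensity is zero; Py-value undefined")
    return PyResult(i_band1=i1, i_band3=i3)


def fit_uptake(tc: UptakeTimeCourse) -> UptakeFit:
    """Fit F(t) = Finf - (Finf - F0) exp(-k t) to an uptake time course.

    Returns the rate constant with its standard error, the 99% equilibration
    time t_eq = ln(100)/k, and the average uptake rate
    (ligand_total/protein_total)/t_eq.  If the last three points do not
    agree within 2% the plateau flag is set false (fit still returned).
    """
    t, f = tc.time, tc.intensity
    if t.size < 6:
        raise DomainError("need at least 6 time points for a kinetic fit")

    tail = f[-3:]
    plateau = float(np.ptp(tail)) <= 0.02 * abs(float(np.mean(tail)))

    direction = np.corrcoef(t, f)[0, 1]
    if not np.isfinite(direction) or abs(direction) < 0.2:
        raise FitFailureError(
            "time course shows no consistent approach to a plateau",
            diagnostics={"pearson_r": float(direction), "plateau": plateau})

    def residual(params):
        k = params["k"].value
        f0 = params["f0"].value
        f_inf = params["f_inf"].value
        return f - (f_inf - (f_inf - f0) * np.exp(-k * t))

    span = float(t[-1] - t[0])
    params = lmfit.Parameters()
    params.add("k", value=3.0 / span, min=1e-12)
    params.add("f0", value=float(f[0]))
    params.add("f_inf", value=float(f[-1]))
    res = lmfit.minimize(residual, params, method="leastsq")
    if not res.success:
        raise FitFailureError("kinetic fit failed to converge",
                              diagnostics={"message": res.message})

    k = float(res.params["k"].value)
    k_se = float(res.params["k"].stderr or np.nan)
    f0_hat = float(res.params["f0"].value)
    f_inf_hat = float(res.params["f_inf"].value)
    t_eq = float(np.log(100.0)) / k
    rate = (tc.ligand_total / tc.protein_total) / t_eq

    fitted = f_inf_hat - (f_inf_hat - f0_hat) * np.exp(-k * t)
    ss_res = float(np.sum((f - fitted) ** 2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    return UptakeFit(rate_constant=k, rate_constant_se=k_se, f0=f0_hat,
                     f_inf=f_inf_hat, t_eq=t_eq, avg_uptake_rate=rate,
                     plateau_reached=plateau, r_squared=r2)
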