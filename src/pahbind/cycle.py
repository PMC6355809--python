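"""Double-decoupling transfer free energy: TI post-processing and corrections.

The absolute standard-state free energy of transferring a ligand from bulk
solvent into a protein cavity is assembled from a thermodynamic cycle with
three legs:

* dG1 — alchemical decoupling of the ligand inside the cavity while a
  flat-bottom harmonic well (FBHW) restrains its centre of mass,
* dG2 — the analytic cost of removing the restraint, including the
  standard-concentration correction, dG2 = +RT ln(V_FBHW / V0),
* dG3 — alchemical decoupling of the free ligand in solvent
  (dG3 = -dG_solv),

combined as  dG0_transfer = -dG1 - dG2 + dG3.  A rotational-symmetry term
-RT ln(sigma) applies when orientational restraints are imposed; it is off
by default since a pure translational restraint leaves the ligand free to
rotate.

dG1 and dG3 come from thermodynamic integration of per-lambda dG/dlambda
averages; window uncertainties come from block averaging of the correlated
MD sample series, and propagate through the quadrature weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import integrate as _sciint

from .constants import R_KJ_PER_MOL_K, T_CYCLE_DEFAULT, V0_NM3
from .exceptions import DomainError, ValidationError

__all__ = [
    "LambdaWindow",
    "TIProfile",
    "FBHWRestraint",
    "CycleComponents",
    "TransferResult",
    "ErrorRule",
    "VolumeMethod",
    "block_average",
    "integrate_ti",
    "fbhw_volume",
    "restraint_correction",
    "symmetry_correction",
    "assemble_cycle",
    "kd_from_dg",
]


class ErrorRule(str, Enum):
    """How leg uncertainties combine into the transfer-energy uncertainty."""

    rss_over_sqrt2 = "rss_over_sqrt2"   # sqrt(s1^2 + s3^2) / sqrt(2)
    rss = "rss"                         # sqrt(s1^2 + s3^2)


class VolumeMethod(str, Enum):
    numeric = "numeric"
    printed_formula = "printed_formula"


@dataclass
class LambdaWindow:
    """One coupling-parameter window: mean dG/dlambda and its uncertainty.

    If a raw sample series is attached, the mean must equal its average
    (the constructor recomputes and checks).
    """

    lam: float
    mean: float
    sigma: float = 0.0
    samples: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValidationError("lambda must lie in [0, 1]")
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")
        if self.samples is not None:
            s = np.asarray(self.samples, dtype=float)
            object.__setattr__(self, "samples", s)
            if not np.isclose(self.mean, s.mean(), rtol=1e-9, atol=1e-12):
                raise ValidationError("window mean must equal the sample average")

    @classmethod
    def from_samples(cls, lam: float, samples, n_blocks: int = 10) -> "LambdaWindow":
        """Build a window from a raw dG/dlambda series via block averaging."""
        s = np.asarray(samples, dtype=float)
        mean, sigma = block_average(s, n_blocks)
        return cls(lam=lam, mean=mean, sigma=sigma, samples=s)


@dataclass
class TIProfile:
    """A full decoupling leg: lambda windows from 0 to 1, sorted and unique."""

    windows: list[LambdaWindow]

    def __post_init__(self):
        if len(self.windows) < 3:
            raise ValidationError("need at least 3 lambda windows")
        lams = np.array([w.lam for w in self.windows])
        order = np.argsort(lams)
        self.windows = [self.windows[i] for i in order]
        lams = lams[order]
        if np.unique(lams).size != lams.size:
            raise ValidationError("duplicate lambda values")
        if lams[0] != 0.0 or lams[-1] != 1.0:
            raise DomainError("endpoint windows at lambda = 0 and 1 are required; "
                              "no extrapolation is performed")

    @property
    def lam(self) -> np.ndarray:
        return np.array([w.lam for w in self.windows])

    @property
    def mean(self) -> np.ndarray:
        return np.array([w.mean for w in self.windows])

    @property
    def sigma(self) -> np.ndarray:
        return np.array([w.sigma for w in self.windows])


@dataclass(frozen=True)
class FBHWRestraint:
    """Flat-bottom harmonic well: U = 0 for r < r0, k (r - r0)^2 beyond."""

    k: float = 1000.0   # kJ mol^-1 nm^-2
    r0: float = 0.55    # nm

    def __post_init__(self):
        if self.k <= 0 or self.r0 <= 0:
            raise ValidationError("k and r0 must be positive")

    def energy(self, r):
        r = np.asarray(r, dtype=float)
        return np.where(r < self.r0, 0.0, self.k * (r - self.r0) ** 2)


@dataclass
class CycleComponents:
    """The three cycle legs plus symmetry bookkeeping and temperature."""

    dg1: float
    dg2: float
    dg3: float
    sigma1: float = 0.0
    sigma3: float = 0.0
    symmetry_number: int = 1
    temperature: float = T_CYCLE_DEFAULT
    include_symmetry: bool = False

    def __post_init__(self):
        if self.sigma1 < 0 or self.sigma3 < 0:
            raise ValidationError("uncertainties must be non-negative")
        if self.symmetry_number < 1:
            raise ValidationError("symmetry number must be >= 1")

    @property
    def dg_solv(self) -> float:
        """Solvation free energy, the negative of the solvent decoupling leg."""
        return -self.dg3


@dataclass(frozen=True)
class TransferResult:
    """Assembled standard-state transfer free energy with uncertainty."""

    dg_transfer: float
    sigma: float
    error_rule: ErrorRule

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")


def block_average(samples, n_blocks: int = 10) -> tuple[float, float]:
    """Mean and standard error of a correlated series by block averaging.

    The series is cut into ``n_blocks`` contiguous equal blocks (trailing
    remainder dropped); the reported uncertainty is the standard deviation
    of the block means divided by sqrt(n_blocks).  For block lengths well
    beyond the correlation time this is an unbiased standard error of the
    overall mean.
    """
    s = np.asarray(samples, dtype=float)
    if n_blocks < 2:
        raise DomainError("need at least 2 blocks")
    if s.size < 2 * n_blocks:
        raise DomainError(f"series too short: {s.size} samples for {n_blocks} blocks")
    block_len = s.size // n_blocks
    trimmed = s[: n_blocks * block_len].reshape(n_blocks, block_len)
    means = trimmed.mean(axis=1)
    sigma = float(means.std(ddof=1) / np.sqrt(n_blocks))
    return float(s.mean()), sigma


def _trapezoid_weights(lam: np.ndarray) -> np.ndarray:
    w = np.zeros_like(lam)
    d = np.diff(lam)
    w[0] = d[0] / 2
    w[-1] = d[-1] / 2
    w[1:-1] = (d[:-1] + d[1:]) / 2
    return w


def integrate_ti(profile: TIProfile, rule: str = "trapezoid") -> tuple[float, float]:
    """Integrate mean dG/dlambda over lambda with propagated uncertainty.

    Trapezoidal quadrature by default; Simpson's rule is available for
    uniform grids with an odd number of points.  The uncertainty is
    sqrt(sum w_i^2 sigma_i^2) with the quadrature weights w_i, treating
    windows as independent.
    """
    lam, mean, sig = profile.lam, profile.mean, profile.sigma
    if rule == "trapezoid":
        w = _trapezoid_weights(lam)
    elif rule == "simpson":
        if lam.size % 2 == 0 or not np.allclose(np.diff(lam), lam[1] - lam[0]):
            raise DomainError("Simpson's rule needs a uniform grid with odd length")
        h = lam[1] - lam[0]
        w = np.ones_like(lam)
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        w *= h / 3.0
    else:
        raise DomainError(f"unknown quadrature rule {rule!r}")
    value = float(np.dot(w, mean))
    sigma = float(np.sqrt(np.dot(w * w, sig * sig)))
    return value, sigma


def fbhw_volume(restraint: FBHWRestraint, temperature: float = T_CYCLE_DEFAULT,
                method: VolumeMethod | str = VolumeMethod.numeric) -> float:
    """Effective volume sampled under a flat-bottom harmonic restraint, nm^3.

    numeric (default)
        Adaptive quadrature of 4 pi int r^2 exp(-U(r)/RT) dr.  The hard
        core contributes (4/3) pi r0^3 exactly; the harmonic tail is
        integrated in units of the thermal width sqrt(RT/k) so the
        quadrature stays well-conditioned for arbitrarily stiff springs.
    printed_formula
        A commonly quoted closed-form expansion,
        (4/3) pi r0^3 + 4 pi r0^2 (pi RT/k)^1/2 + 2 pi r0 (pi RT/k)
        + (pi RT/k)^3/2, evaluated verbatim for comparison.  It overstates
        the Gaussian-tail terms (each is missing a factor accounting for
        the half-Gaussian) and is provided for reporting only; the numeric
        integral is authoritative.
    """
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    method = VolumeMethod(method)
    rt = R_KJ_PER_MOL_K * temperature
    r0, k = restraint.r0, restraint.k
    if method is VolumeMethod.printed_formula:
        x = np.pi * rt / k
        return float((4.0 / 3.0) * np.pi * r0 ** 3
                     + 4.0 * np.pi * r0 ** 2 * np.sqrt(x)
                     + 2.0 * np.pi * r0 * x
                     + x ** 1.5)
    width = np.sqrt(rt / k)

    def tail(u):  # r = r0 + width*u, u >= 0
        return (r0 + width * u) ** 2 * np.exp(-u * u)

    integral, _ = _sciint.quad(tail, 0.0, np.inf, epsrel=1e-10, epsabs=0.0)
    return float((4.0 / 3.0) * np.pi * r0 ** 3 + 4.0 * np.pi * width * integral)


def restraint_correction(v_fbhw: float, v0: float = V0_NM3,
                         temperature: float = T_CYCLE_DEFAULT) -> float:
    """Standard-state restraint-release free energy, +RT ln(V_FBHW/V0), kJ/mol."""
    if v_fbhw <= 0 or v0 <= 0:
        raise DomainError("volumes must be positive")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    return R_KJ_PER_MOL_K * temperature * float(np.log(v_fbhw / v0))


def symmetry_correction(symmetry_number: int, temperature: float = T_CYCLE_DEFAULT) -> float:
    """Rotational-symmetry free energy, -RT ln(sigma), kJ/mol."""
    if symmetry_number < 1:
        raise DomainError("symmetry number must be >= 1")
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    return -R_KJ_PER_MOL_K * temperature * float(np.log(symmetry_number))


def assemble_cycle(c: CycleComponents,
                   error_rule: ErrorRule | str = ErrorRule.rss_over_sqrt2) -> TransferResult:
    """Assemble dG0_transfer = -dG1 - dG2 + dG3 with combined uncertainty.

    dG2 is analytic and carries no uncertainty.  The default combination
    rule divides the root-sum-square of the two stochastic legs by
    sqrt(2); plain root-sum-square is available as the conventional
    alternative.  With ``include_symmetry`` the -RT ln(sigma) term is
    added as well.
    """
    error_rule = ErrorRule(error_rule)
    dg = -c.dg1 - c.dg2 + c.dg3
    if c.include_symmetry:
        dg += symmetry_correction(c.symmetry_number, c.temperature)
    rss = float(np.hypot(c.sigma1, c.sigma3))
    sigma = rss / np.sqrt(2.0) if error_rule is ErrorRule.rss_over_sqrt2 else rss
    return TransferResult(dg_transfer=dg, sigma=sigma, error_rule=error_rule)


def kd_from_dg(dg: float, temperature: float = T_CYCLE_DEFAULT) -> float:
    """Dissociation constant implied by a binding free energy, mol/L.

    Inverse of dG = RT ln Kd; round-trips with the titration module's
    Gibbs conversion.
    """
    if temperature <= 0:
        raise DomainError("temperature must be positive")
    return float(np.exp(dg / (R_KJ_PER_MOL_K * temperature)))
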