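"""Pathogen inactivation: germicidal spectral weighting and dose-response models.

Disinfection effectiveness depends on wavelength.  A source's *average
germicidal power ratio* (AGPR) is the germicidal-factor-weighted fraction of
its optical output, ``P_avg/P_o = int GF(lam) G(lam) dlam / int G(lam) dlam``,
which collapses to ``GF(lam0)`` for a monochromatic source at ``lam0`` (e.g.
1.0 for an ideal low-pressure mercury lamp at 253.7 nm with GF normalized
there).

Fluence maps to log10 microbial reduction through either a two-parameter
Weibull survival curve, ``log10(N/N0) = -(F/alpha)**beta`` (shoulder and
tailing shapes), or the log-linear Chick-Watson model,
``log10(N/N0) = -k*F``.  Reciprocity is assumed: reduction depends on the
received fluence only, not on how it accumulated in time.  Fluences are in
mJ/cm^2 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitError, ValidationError


# ---------------------------------------------------------------------------
# Spectra and germicidal weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionSpectrum:
    """Source emission: wavelengths (nm, ascending) and spectral power
    (relative or W/nm).  A single wavelength denotes a monochromatic line."""

    wavelengths: np.ndarray
    spectral_power: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths, float).reshape(-1)
        p = np.asarray(self.spectral_power, float).reshape(-1)
        if w.size == 0 or w.size != p.size:
            raise ValidationError("spectrum needs matching non-empty arrays")
        if np.any(np.diff(w) <= 0):
            raise ValidationError("spectrum wavelengths must be strictly ascending")
        if np.any(p < 0):
            raise ValidationError("spectral power must be >= 0")
        if p.sum() <= 0:
            raise ValidationError("spectrum total power must be > 0")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "spectral_power", p)

    @classmethod
    def monochromatic(cls, wavelength_nm: float, power: float = 1.0) -> "EmissionSpectrum":
        return cls(np.array([wavelength_nm]), np.array([power]))

    @classmethod
    def from_csv(cls, path) -> "EmissionSpectrum":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


@dataclass(frozen=True)
class GermicidalFactorCurve:
    """Pathogen-specific wavelength weighting GF(lam) >= 0; zero outside its
    tabulated support.  ``anchor_nm`` records the normalization wavelength."""

    wavelengths: np.ndarray
    gf: np.ndarray
    anchor_nm: Optional[float] = None

    def __post_init__(self):
        w = np.asarray(self.wavelengths, float).reshape(-1)
        g = np.asarray(self.gf, float).reshape(-1)
        if w.size == 0 or w.size != g.size:
            raise ValidationError("GF curve needs matching non-empty arrays")
        if np.any(np.diff(w) <= 0):
            raise ValidationError("GF wavelengths must be strictly ascending")
        if np.any(g < 0):
            raise ValidationError("GF values must be >= 0")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "gf", g)

    def __call__(self, wavelength_nm):
        lam = np.asarray(wavelength_nm, float)
        out = np.interp(lam, self.wavelengths, self.gf)
        outside = (lam < self.wavelengths[0]) | (lam > self.wavelengths[-1])
        return np.where(outside, 0.0, out)

    @classmethod
    def normalized_at(cls, wavelengths, gf, anchor_nm: float) -> "GermicidalFactorCurve":
        """Scale so GF(anchor_nm) = 1."""
        base = cls(wavelengths, gf)
        ref = float(base(anchor_nm))
        if ref <= 0:
            raise ValidationError("GF is zero at the requested anchor wavelength")
        return cls(base.wavelengths, base.gf / ref, anchor_nm=anchor_nm)

    @classmethod
    def from_csv(cls, path) -> "GermicidalFactorCurve":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def germicidal_power_ratio(spectrum: EmissionSpectrum,
                           gf: GermicidalFactorCurve) -> float:
    """AGPR ``P_avg/P_o``: GF-weighted fraction of the source's output.

    Trapezoidal quadrature on the union of the two wavelength grids, with
    linear interpolation of both curves; a monochromatic line bypasses
    quadrature and returns GF at the line.
    """
    if spectrum.wavelengths.size == 1:
        return float(gf(spectrum.wavelengths[0]))
    grid = np.union1d(spectrum.wavelengths, gf.wavelengths)
    grid = grid[(grid >= spectrum.wavelengths[0]) & (grid <= spectrum.wavelengths[-1])]
    g = np.interp(grid, spectrum.wavelengths, spectrum.spectral_power)
    total = np.trapezoid(g, grid)
    if total <= 0:
        raise ValidationError("spectrum has zero integrated power")
    weighted = np.trapezoid(gf(grid) * g, grid)
    return float(weighted / total)


# ---------------------------------------------------------------------------
# Dose-response models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeibullModel:
    """``log10(N/N0) = -(F/alpha)**beta`` (alpha mJ/cm^2, beta dimensionless)."""

    alpha: float
    beta: float
    parameterization: str = "scale-shape-log10"

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValidationError("Weibull alpha and beta must be > 0")


@dataclass(frozen=True)
class ChickWatsonModel:
    """``log10(N/N0) = -k*F`` (k in cm^2/mJ)."""

    k: float

    def __post_init__(self):
        if self.k < 0:
            raise ValidationError("Chick-Watson k must be >= 0")


InactivationModel = Union[WeibullModel, ChickWatsonModel]


def log_reduction(model: InactivationModel, fluence):
    """log10(N/N0) <= 0 at the given fluence(s) (mJ/cm^2)."""
    f = np.asarray(fluence, float)
    if np.any(f < 0):
        raise ValidationError("fluence must be >= 0")
    if isinstance(model, WeibullModel):
        out = -np.power(f / model.alpha, model.beta)
    elif isinstance(model, ChickWatsonModel):
        out = -model.k * f
    else:
        raise ValidationError(f"unknown inactivation model {type(model).__name__}")
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    model: InactivationModel
    rmse: float
    r_squared: float
    stderr: Tuple[float, ...]    # per-parameter standard errors

    def __iter__(self):  # allow (model, rmse, r2) unpacking
        return iter((self.model, self.rmse, self.r_squared))


def _goodness(observed: np.ndarray, predicted: np.ndarray, n_params: int):
    resid = observed - predicted
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((observed - observed.mean())**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return rmse, r2, resid


def fit_inactivation_model(data, family: str) -> FitResult:
    """Least-squares fit of a dose-response curve to (fluence, log10 reduction).

    Chick-Watson uses the closed-form regression through the origin; Weibull
    uses nonlinear least squares in (log alpha, log beta) with a multi-start
    over beta in {0.25, 0.5, 1, 2} and alpha at the median fluence.  R^2 may
    be negative when the model underperforms the mean.
    """
    arr = np.asarray(list(data), float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("data must be (fluence, log10 reduction) pairs")
    f, y = arr[:, 0], arr[:, 1]
    if np.any(f < 0):
        raise ValidationError("fluences must be >= 0")
    if np.allclose(f, f[0]):
        raise ValidationError("fluences must not all be equal")

    if family == "chick_watson":
        if len(f) < 2:
            raise ValidationError("Chick-Watson fit needs >= 2 points")
        sxx = float(np.sum(f**2))
        k = float(-np.sum(f * y) / sxx)
        model = ChickWatsonModel(k=max(k, 0.0))
        pred = log_reduction(model, f)
        rmse, r2, resid = _goodness(y, pred, 1)
        dof = max(len(f) - 1, 1)
        se_k = float(np.sqrt(np.sum(resid**2) / dof / sxx))
        return FitResult(model, rmse, r2, (se_k,))

    if family == "weibull":
        if len(f) < 3:
            raise ValidationError("Weibull fit needs >= 3 points")
        pos = f > 0

        def residuals(p):
            alpha, beta = np.exp(p)
            pred = np.zeros_like(f)
            with np.errstate(over="ignore"):   # wild interim steps are fine for LM
                pred[pos] = -np.power(f[pos] / alpha, beta)
            return np.nan_to_num(pred - y, nan=1e6, posinf=1e6, neginf=-1e6)

        alpha0 = float(np.median(f[pos]))
        best = None
        for beta0 in (0.25, 0.5, 1.0, 2.0):
            try:
                sol = least_squares(residuals, x0=np.log([alpha0, beta0]),
                                    method="lm", xtol=1e-14, ftol=1e-14)
            except Exception:  # noqa: BLE001 - try the remaining starts
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitError("Weibull fit did not converge from any start "
                           f"(n={len(f)}, fluence range {f.min():.3g}-{f.max():.3g})")
        alpha, beta = np.exp(best.x)
        model = WeibullModel(alpha=float(alpha), beta=float(beta))
        pred = log_reduction(model, f)
        rmse, r2, resid = _goodness(y, pred, 2)
        # delta-method standard errors from the log-parameter Jacobian
        dof = max(len(f) - 2, 1)
        s2 = float(np.sum(resid**2)) / dof
        jac = best.jac
        try:
            cov_log = s2 * np.linalg.inv(jac.T @ jac)
            se = np.sqrt(np.diag(cov_log)) * np.array([alpha, beta])
        except np.linalg.LinAlgError:
            se = np.array([np.inf, np.inf])
        return FitResult(model, rmse, r2, (float(se[0]), float(se[1])))

    raise ValidationError(f"unknown model family {family!r}")


# ---------------------------------------------------------------------------
# Surface threshold maps
# ---------------------------------------------------------------------------

@dataclass
class InactivationMap:
    element_ids: np.ndarray
    log_reduction: np.ndarray     # (N,) log10, <= 0
    passed: np.ndarray            # (N,) bool
    pass_fraction: float          # element-count fraction
    pass_fraction_area: float     # area-weighted fraction


def inactivation_map(fld, model: InactivationModel,
                     threshold: float = -2.0) -> InactivationMap:
    """Per-element log reduction over an :class:`~uvfield.evaluate.ExposureField`.

    An element passes when its signed log10 reduction is at or below the
    threshold (e.g. -2.3 passes a -2.0 / 99% threshold).
    """
    lr = log_reduction(model, fld.fluence)
    passed = lr <= threshold
    frac = float(np.mean(passed)) if passed.size else 0.0
    frac_area = float(np.average(passed, weights=fld.areas)) if passed.size else 0.0
    return InactivationMap(element_ids=fld.element_ids, log_reduction=lr,
                           passed=passed, pass_fraction=frac,
                           pass_fraction_area=frac_area)


# ---------------------------------------------------------------------------
# Published reference parameters (data, not ground truth for any specific
# parameterization; the low-pressure-mercury Weibull rows are near-singular
# under the scale-shape form and are retained verbatim for comparison only)
# ---------------------------------------------------------------------------

TABLE1 = pd.DataFrame(
    [("Salmonella", "LPM", 1.000, 0.02, 0.14, 0.41, 0.64, 4.82e-4, 1.04, 0.18),
     ("Salmonella", "LED", 0.676, 290.48, 0.58, 0.10, 0.98, 2.39e-4, 0.23, 0.89),
     ("E. coli", "LPM", 1.000, 0.00, 0.09, 0.31, 0.75, 6.51e-4, 0.90, -0.15),
     ("E. coli", "LED", 0.645, 209.59, 0.56, 0.05, 1.00, 2.71e-4, 0.25, 0.90),
     ("L. monocytogenes", "LPM", 1.000, 0.00, 0.07, 0.47, 0.41, 7.47e-4, 1.09, -0.17),
     ("L. monocytogenes", "LED", 0.640, 466.90, 0.76, 0.05, 1.00, 2.56e-4, 0.13, 0.97)],
    columns=["pathogen", "source", "agpr", "weibull_alpha", "weibull_beta",
             "weibull_rmse", "weibull_r2", "cw_k", "cw_rmse", "cw_r2"])
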