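"""Spectrophotometric assays: spectral unmixing, pKa fits and initial rates.

UV/Vis spectra of a nucleobase recorded across a pH titration are linear
combinations of the spectra of its protonated and deprotonated states.
Unmixing each spectrum against endpoint references gives the deprotonated
fraction

    alpha = x_deprot / (x_deprot + x_prot) = 10^(pH - pKa) / (1 + 10^(pH - pKa)),

and a one-parameter nonlinear fit of alpha(pH) yields the pKa.  The same
unmixing applied to substrate/product references turns enzymatic progress
curves into concentrations, from which initial rates and specific activities
(U/mg, with 1 U = 1 umol/min) follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, nnls

__all__ = [
    "Spectrum",
    "ReferenceSet",
    "UnmixResult",
    "TitrationSeries",
    "PkaFit",
    "ActivityResult",
    "IllConditionedError",
    "NoTransitionError",
    "InsufficientDataError",
    "unmix",
    "fit_pka",
    "henderson_alpha",
    "progress_to_concentration",
    "specific_activity",
]

COND_GUARD = 1e8  # reference matrix condition number beyond which unmixing is refused


class IllConditionedError(ValueError):
    """Reference spectra are (nearly) collinear; fractions are not identifiable."""


class NoTransitionError(ValueError):
    """The titration shows no protonation transition inside the sampled pH range."""


class InsufficientDataError(ValueError):
    """Too few points in the initial-rate window."""


@dataclass(frozen=True)
class Spectrum:
    """A UV/Vis absorption spectrum on a strictly increasing wavelength grid
    (nm, absorbance in AU)."""

    wavelengths: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        if wl.shape != ab.shape or wl.ndim != 1:
            raise ValueError("wavelengths and absorbances must be 1-D and equal length")
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbances", ab)


@dataclass(frozen=True)
class ReferenceSet:
    """Named endpoint spectra sharing one wavelength grid.

    For a pKa titration the two references are the fully protonated (low pH)
    and fully deprotonated (high pH) spectra; for an enzymatic assay they are
    substrate and product.
    """

    names: tuple
    wavelengths: np.ndarray
    matrix: np.ndarray  # (n_wavelengths, n_refs)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        m = np.asarray(self.matrix, dtype=float)
        if len(self.names) < 2:
            raise ValueError("need at least two reference spectra")
        if m.shape != (wl.size, len(self.names)):
            raise ValueError("matrix shape must be (n_wavelengths, n_refs)")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "matrix", m)
        # collinearity guard on column-normalized references
        norms = np.linalg.norm(m, axis=0)
        if np.any(norms == 0):
            raise IllConditionedError("a reference spectrum is identically zero")
        if np.linalg.cond(m / norms) > COND_GUARD:
            raise IllConditionedError("reference spectra are nearly collinear")

    @classmethod
    def from_spectra(cls, **spectra: Spectrum) -> "ReferenceSet":
        names = tuple(spectra)
        first = spectra[names[0]]
        for s in spectra.values():
            if not np.array_equal(s.wavelengths, first.wavelengths):
                raise ValueError("reference spectra must share one wavelength grid")
        matrix = np.column_stack([spectra[n].absorbances for n in names])
        return cls(names=names, wavelengths=first.wavelengths, matrix=matrix)

    def spectrum(self, name: str) -> Spectrum:
        return Spectrum(self.wavelengths, self.matrix[:, self.names.index(name)])


@dataclass(frozen=True)
class UnmixResult:
    """Nonnegative reference fractions (normalized to sum 1) with the raw
    least-squares coefficients and residual norm."""

    names: tuple
    fractions: np.ndarray
    coefficients: np.ndarray
    residual_norm: float
    resampled: bool = False

    def fraction(self, name: str) -> float:
        return float(self.fractions[self.names.index(name)])


@dataclass(frozen=True)
class TitrationSeries:
    """pH-resolved spectra of a titratable chromophore."""

    pH: np.ndarray
    spectra: tuple  # of Spectrum, parallel to pH

    def __post_init__(self) -> None:
        ph = np.asarray(self.pH, dtype=float)
        if len(self.spectra) != ph.size:
            raise ValueError("one spectrum per pH value required")
        if np.unique(ph).size < 5:
            raise ValueError("need at least 5 distinct pH values")
        object.__setattr__(self, "pH", ph)
        object.__setattr__(self, "spectra", tuple(self.spectra))


@dataclass(frozen=True)
class PkaFit:
    """Fitted acid dissociation constant with its asymptotic standard error
    and the observed/fitted deprotonation fractions per pH."""

    pKa: float
    stderr: float
    pH: np.ndarray
    alpha_observed: np.ndarray
    alpha_fitted: np.ndarray
    warning: str | None = None


@dataclass(frozen=True)
class ActivityResult:
    """Initial-rate analysis of an enzymatic progress curve."""

    initial_rate: float  # mM/min
    units: float  # U = umol/min
    specific_activity: float  # U/mg
    window: tuple  # (t_min, t_max) of the fitted initial-linear region
    n_points: int


def henderson_alpha(pH, pKa):
    """Deprotonated fraction of a monoprotic acid at the given pH."""
    return 10.0 ** (np.asarray(pH, dtype=float) - pKa) / (
        1.0 + 10.0 ** (np.asarray(pH, dtype=float) - pKa)
    )


def unmix(spectrum: Spectrum, refs: ReferenceSet) -> UnmixResult:
    """Decompose a spectrum into nonnegative fractions of reference states.

    Solves min ||R c - y|| subject to c >= 0 and normalizes the coefficients
    to fractions summing to 1.  Nonnegativity is imposed because the
    coefficients are physical state populations.  If the spectrum's grid
    differs from the references' it is linearly resampled, with a warning.
    """
    y = spectrum.absorbances
    resampled = False
    if not np.array_equal(spectrum.wavelengths, refs.wavelengths):
        y = np.interp(refs.wavelengths, spectrum.wavelengths, spectrum.absorbances)
        resampled = True
        warnings.warn(
            "spectrum resampled onto the reference wavelength grid", stacklevel=2
        )
    coef, rnorm = nnls(refs.matrix, y)
    total = coef.sum()
    if total <= 0:
        fractions = np.full(coef.size, np.nan)
    else:
        fractions = coef / total
    return UnmixResult(
        names=refs.names,
        fractions=fractions,
        coefficients=coef,
        residual_norm=float(rnorm),
        resampled=resampled,
    )


def fit_pka(
    series: TitrationSeries,
    refs: ReferenceSet,
    deprotonated: str | None = None,
) -> PkaFit:
    """Fit the pKa from a pH titration by spectral unmixing.

    Each spectrum is unmixed against the protonated/deprotonated references;
    the deprotonated fraction alpha is then fitted to the monoprotic
    protonation model with pKa as the only parameter.  The standard error is
    the asymptotic one from the least-squares curvature.
    """
    if len(refs.names) != 2:
        raise ValueError("pKa fitting needs exactly two references")
    if deprotonated is None:
        deprotonated = refs.names[1]
    alpha = np.array(
        [unmix(s, refs).fraction(deprotonated) for s in series.spectra]
    )
    if np.all(alpha < 0.05) or np.all(alpha > 0.95):
        raise NoTransitionError(
            "deprotonated fraction never crosses the transition; "
            "pKa is outside the sampled pH range"
        )
    ph = series.pH
    p0 = float(ph[np.argmin(np.abs(alpha - 0.5))])
    popt, pcov = curve_fit(henderson_alpha, ph, alpha, p0=[p0])
    pka = float(popt[0])
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    warning = None
    if ph.min() > pka - 1.0 or ph.max() < pka + 1.0:
        warning = (
            "titration spans less than one pH unit on one side of the midpoint; "
            "standard error may be unreliable"
        )
    return PkaFit(
        pKa=pka,
        stderr=stderr,
        pH=ph,
        alpha_observed=alpha,
        alpha_fitted=henderson_alpha(ph, pka),
        warning=warning,
    )


def progress_to_concentration(
    course, substrate_0: float, product: str | None = None
):
    """Convert an unmixed progress curve to product concentrations.

    ``course`` is an iterable of (time_min, UnmixResult); the product
    concentration at each time is the product fraction times the initial
    substrate concentration (closed mass balance, two states).
    """
    times, concs = [], []
    for t, res in course:
        name = product if product is not None else res.names[1]
        times.append(float(t))
        concs.append(res.fraction(name) * substrate_0)
    return np.array(times), np.array(concs)


def specific_activity(
    times,
    product_conc,
    substrate_0: float,
    enzyme_conc: float,
    volume: float = 1.0,
    linear_fraction_max: float = 0.15,
) -> ActivityResult:
    """Initial rate, units and specific activity from a progress curve.

    The rate is the ordinary least-squares slope (free intercept) through the
    initial-linear window, defined as the points where product has not
    exceeded ``linear_fraction_max`` of the initial substrate.  Units follow
    from rate [mM/min = umol/mL/min] times volume [mL]; specific activity is
    units per mg enzyme and is volume-invariant at fixed enzyme
    concentration (mg/mL).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(product_conc, dtype=float)
    if enzyme_conc <= 0 or volume <= 0 or substrate_0 <= 0:
        raise ValueError("substrate_0, enzyme_conc and volume must be > 0")
    mask = c <= linear_fraction_max * substrate_0
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} points with conversion <= "
            f"{linear_fraction_max:.0%} of substrate; need >= 3"
        )
    tw, cw = t[mask], c[mask]
    slope = float(np.polyfit(tw, cw, 1)[0])
    units = slope * volume  # umol/min
    return ActivityResult(
        initial_rate=slope,
        units=units,
        specific_activity=units / (enzyme_conc * volume),
        window=(float(tw.min()), float(tw.max())),
        n_points=int(mask.sum()),
    )
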