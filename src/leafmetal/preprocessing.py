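"""Spectral pre-processing: band trimming, Savitzky-Golay smoothing and the
seven transforms FD, SD, AT, AFD, ASD, MSC, SNV (plus the identity R).

Pipeline order is fixed: trim -> smooth -> transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .cohort import SpectraSet

__all__ = [
    "TRANSFORM_NAMES",
    "MSCReference",
    "trim_low_bands",
    "sg_smooth",
    "absorbance",
    "derivative",
    "msc_fit",
    "msc_apply",
    "snv",
    "apply_transform",
    "preprocess",
    "PreprocessingError",
]

TRANSFORM_NAMES = ("R", "FD", "SD", "AT", "AFD", "ASD", "MSC", "SNV")

DEFAULT_TRIM_NM = 380.0
DEFAULT_SG_WINDOW = 11
DEFAULT_SG_POLYORDER = 2


class PreprocessingError(ValueError):
    pass


@dataclass
class MSCReference:
    """Stored reference spectrum (calibration-set mean) for scatter correction."""

    wavelengths_nm: np.ndarray
    reference_spectrum: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, float)
        self.reference_spectrum = np.asarray(self.reference_spectrum, float)
        if self.wavelengths_nm.shape != self.reference_spectrum.shape:
            raise PreprocessingError("reference grid/spectrum length mismatch")


def trim_low_bands(spectra: SpectraSet, cutoff_nm: float = DEFAULT_TRIM_NM) -> SpectraSet:
    """Drop noisy edge channels below ``cutoff_nm`` (boundary inclusive at >=)."""
    keep = spectra.wavelengths_nm >= cutoff_nm
    if not keep.any():
        raise PreprocessingError(f"no channel at or above {cutoff_nm} nm")
    return spectra.replace(
        reflectance=spectra.reflectance[:, keep],
        wavelengths_nm=spectra.wavelengths_nm[keep],
    )


def sg_smooth(spectra: SpectraSet, window: int = DEFAULT_SG_WINDOW,
              polyorder: int = DEFAULT_SG_POLYORDER) -> SpectraSet:
    """Savitzky-Golay least-squares smoothing of each row.

    Edges are handled by evaluating the polynomial fitted to the last full
    window (scipy mode='interp'), so the grid is unchanged.
    """
    if window % 2 == 0:
        raise PreprocessingError("window must be odd")
    if polyorder >= window:
        raise PreprocessingError("polyorder must be smaller than window")
    if window > spectra.n_channels:
        raise PreprocessingError("window larger than channel count")
    smoothed = savgol_filter(spectra.reflectance, window, polyorder,
                             axis=1, mode="interp")
    return spectra.replace(reflectance=smoothed)


def absorbance(spectra: SpectraSet) -> SpectraSet:
    """AT: elementwise log10(1/R)."""
    r = spectra.reflectance
    if np.any(r <= 0):
        raise PreprocessingError("absorbance requires strictly positive reflectance")
    return spectra.replace(reflectance=np.log10(1.0 / r))


def derivative(spectra: SpectraSet, order: int) -> SpectraSet:
    """FD/SD: finite-difference derivative with respect to wavelength.

    Central differences on interior channels, one-sided (quadratic) stencils
    at the two edges, so the output keeps the full grid.  Units are per nm
    (order 1) or per nm^2 (order 2); the actual, possibly non-uniform, grid
    spacing is used.
    """
    if order not in (1, 2):
        raise PreprocessingError("derivative order must be 1 or 2")
    if spectra.n_channels < 3:
        raise PreprocessingError("derivative needs at least 3 channels")
    wl = spectra.wavelengths_nm
    x = spectra.reflectance
    if order == 1:
        out = np.gradient(x, wl, axis=1)
    else:
        out = _second_derivative(x, wl)
    return spectra.replace(reflectance=out)


def _second_derivative(x: np.ndarray, wl: np.ndarray) -> np.ndarray:
    """Three-point second derivative on a possibly non-uniform grid."""
    hb = wl[1:-1] - wl[:-2]   # backward steps
    hf = wl[2:] - wl[1:-1]    # forward steps
    out = np.empty_like(x)
    out[:, 1:-1] = 2.0 * (
        hb * x[:, 2:] - (hb + hf) * x[:, 1:-1] + hf * x[:, :-2]
    ) / (hb * hf * (hb + hf))
    # edge values from the quadratic through the three nearest channels,
    # whose second derivative is constant over that triple
    out[:, 0] = out[:, 1]
    out[:, -1] = out[:, -2]
    return out


def msc_fit(calibration_spectra: SpectraSet) -> MSCReference:
    """Fit the MSC reference: channelwise mean of the calibration set."""
    if calibration_spectra.n_sites < 2:
        raise PreprocessingError("MSC needs at least 2 calibration spectra")
    return MSCReference(
        wavelengths_nm=calibration_spectra.wavelengths_nm.copy(),
        reference_spectrum=calibration_spectra.reflectance.mean(axis=0),
    )


def msc_apply(spectra: SpectraSet, ref: MSCReference) -> SpectraSet:
    """Regress each spectrum on (1, reference) and invert the affine fit."""
    if not np.array_equal(spectra.wavelengths_nm, ref.wavelengths_nm):
        raise PreprocessingError("MSC reference grid does not match spectra grid")
    r = ref.reference_spectrum
    x = spectra.reflectance
    r_c = r - r.mean()
    denom = float(r_c @ r_c)
    if denom < 1e-24:
        raise PreprocessingError("MSC reference spectrum is constant")
    b = (x - x.mean(axis=1, keepdims=True)) @ r_c / denom
    a = x.mean(axis=1) - b * r.mean()
    bad = np.abs(b) < 1e-12
    if bad.any():
        idx = np.flatnonzero(bad)
        names = ", ".join(spectra.site_ids[idx])
        raise PreprocessingError(f"MSC slope numerically zero for sample(s): {names}")
    corrected = (x - a[:, None]) / b[:, None]
    return spectra.replace(reflectance=corrected)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-row standardization (ddof=1)."""
    x = spectra.reflectance
    sd = x.std(axis=1, ddof=1)
    if np.any(sd < 1e-15):
        idx = np.flatnonzero(sd < 1e-15)
        names = ", ".join(spectra.site_ids[idx])
        raise PreprocessingError(f"SNV undefined for constant spectrum: {names}")
    return spectra.replace(reflectance=(x - x.mean(axis=1, keepdims=True)) / sd[:, None])


def apply_transform(spectra: SpectraSet, name: str,
                    msc_ref: MSCReference | None = None) -> SpectraSet:
    """Dispatch one of the eight transforms on trimmed+smoothed spectra.

    For MSC, ``msc_ref`` must be supplied when ``spectra`` are not the
    calibration set (e.g. validation samples), to avoid leakage.
    """
    if name == "R":
        return spectra.replace()
    if name == "FD":
        return derivative(spectra, 1)
    if name == "SD":
        return derivative(spectra, 2)
    if name == "AT":
        return absorbance(spectra)
    if name == "AFD":
        return derivative(absorbance(spectra), 1)
    if name == "ASD":
        return derivative(absorbance(spectra), 2)
    if name == "MSC":
        ref = msc_ref if msc_ref is not None else msc_fit(spectra)
        return msc_apply(spectra, ref)
    if name == "SNV":
        return snv(spectra)
    raise PreprocessingError(
        f"unknown transform {name!r}; expected one of {TRANSFORM_NAMES}"
    )


def preprocess(spectra: SpectraSet, transform: str = "R",
               trim_cutoff_nm: float = DEFAULT_TRIM_NM,
               sg_window: int = DEFAULT_SG_WINDOW,
               sg_polyorder: int = DEFAULT_SG_POLYORDER,
               msc_ref: MSCReference | None = None) -> SpectraSet:
    """Full fixed-order pipeline: trim -> Savitzky-Golay smooth -> transform."""
    trimmed = trim_low_bands(spectra, trim_cutoff_nm)
    smoothed = sg_smooth(trimmed, sg_window, sg_polyorder)
    return apply_transform(smoothed, transform, msc_ref=msc_ref)
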