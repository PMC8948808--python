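"""End-to-end workflows: normalization strategies, calibration, segmentation.

Three reusable pipelines built on the EMSC core:

* :func:`run_case1_preprocessing` — the two lipid-normalization strategies
  for broadband FTIR of oleaginous biomass: normalize the full spectra first
  and then cut the lipid regions (strategy A, biomass standardization), or
  cut the C-H stretch region first and run the EMSC inside it (strategy B,
  lipid standardization). The output matrices feed any downstream regression.
* :func:`run_case2` — univariate solute calibration on ATR spectra: fit an
  EMSC with a solute analyte spectrum (supplied, or estimated from residual
  PCA after choosing a solvent-like reference) and regress the relative
  content f/b against the known concentrations.
* :func:`run_case3` — two-class segmentation of a hyperspectral image by the
  sign of the analyte parameter of a residual-PCA loading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constituent_tools import (
    ConstituentSpectrum,
    estimate_analyte_from_residuals,
    refit_with_estimated_analyte,
)
from .emsc_model import EMSCModelSpec
from .emsc_solver import fit, fit_correct
from .errors import ValidationError
from .spectra_core import HyperspectralImage, SpectraSet, select_region

__all__ = [
    "CalibrationResult",
    "SegmentationMask",
    "select_reference_by_peak_ratio",
    "univariate_calibration",
    "run_case1_preprocessing",
    "run_case2",
    "run_case3",
]


@dataclass
class CalibrationResult:
    """Ordinary least squares line y = slope * x + intercept with fit metrics."""

    slope: float
    intercept: float
    rmse: float
    r2: float
    predictions: np.ndarray

    def __post_init__(self) -> None:
        if self.rmse < 0:
            raise ValidationError("rmse cannot be negative")


@dataclass
class SegmentationMask:
    """Binary per-pixel labels with the threshold that produced them."""

    width: int
    height: int
    labels: np.ndarray
    threshold: float = 0.0

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=bool).reshape(-1)
        if labels.size != self.width * self.height:
            raise ValidationError(
                f"{labels.size} labels for a {self.width}x{self.height} image"
            )
        self.labels = labels

    def plane(self) -> np.ndarray:
        return self.labels.reshape(self.height, self.width)

    def agreement(self, truth: np.ndarray) -> float:
        """Fraction of matching pixels, invariant to a global label swap."""
        truth = np.asarray(truth, dtype=bool).reshape(-1)
        frac = float(np.mean(self.labels == truth))
        return max(frac, 1.0 - frac)


def select_reference_by_peak_ratio(
    spectra: SpectraSet,
    marker_wn: float = 1080.0,
    baseline_wn: float = 1200.0,
) -> tuple[np.ndarray, str]:
    """Pick the spectrum closest to the pure solvent by a marker-band contrast.

    Returns the spectrum minimizing absorbance(marker) - absorbance(baseline)
    (nearest channels); with the defaults this selects the spectrum with the
    smallest 1080 cm^-1 solute signal relative to the flat 1200 cm^-1 region,
    i.e. the most water-like spectrum. Ties break to the first id.
    """
    if spectra.n_spectra < 1:
        raise ValidationError("empty spectra set")
    i_marker = spectra.axis.nearest_index(marker_wn)
    i_base = spectra.axis.nearest_index(baseline_wn)
    contrast = spectra.absorbance[:, i_marker] - spectra.absorbance[:, i_base]
    best = int(np.argmin(contrast))  # argmin takes the first on ties
    return spectra.absorbance[best].copy(), spectra.ids[best]


def univariate_calibration(x: np.ndarray, y: np.ndarray) -> CalibrationResult:
    """OLS line of y on x with apparent RMSE and R^2 on the same samples."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("x and y must have the same length")
    if x.size < 3:
        raise ValidationError("calibration needs at least 3 samples")
    if np.ptp(x) == 0:
        raise ValidationError("x is constant; the calibration line is undefined")
    xc = x - x.mean()
    slope = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    intercept = float(y.mean() - slope * x.mean())
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / x.size))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationResult(slope, intercept, rmse, r2, pred)


LIPID_ESTER_REGION = (1727.0, 1765.0)
LIPID_CH_REGION = (2800.0, 3050.0)


def run_case1_preprocessing(spectra: SpectraSet, strategy: str) -> SpectraSet:
    """Lipid-region normalization, strategy "A" or "B".

    A: order-2 EMSC with the dataset mean as reference on the full axis
    (biomass standardization), then cut the ester (1727-1765 cm^-1) and C-H
    stretch (2800-3050 cm^-1) regions.

    B: cut the C-H stretch region first, then an order-1 EMSC with the
    sub-region mean as reference (lipid standardization). The narrow regions
    are preprocessed separately; correcting them jointly across the wide gap
    creates extra baseline variation.
    """
    if strategy == "A":
        spec = EMSCModelSpec(reference=spectra.mean_spectrum(), polynomial_order=2)
        corrected = fit_correct(spec, spectra).spectra
        return select_region(corrected, [LIPID_ESTER_REGION, LIPID_CH_REGION])
    if strategy == "B":
        sub = select_region(spectra, [LIPID_CH_REGION])
        spec = EMSCModelSpec(reference=sub.mean_spectrum(), polynomial_order=1)
        return fit_correct(spec, sub).spectra
    raise ValidationError(f"unknown strategy {strategy!r}; use 'A' or 'B'")


#: region carrying most chemical (solute) variation in the ATR case; zero
#: weights here keep the first-pass fit from chasing the solute signal
CASE2_ZERO_WEIGHT_REGION = (950.0, 1200.0)


@dataclass
class Case2Result:
    """Calibration outcome plus the model pieces used to obtain it."""

    calibration: CalibrationResult
    f_over_b: np.ndarray
    analyte: ConstituentSpectrum
    reference_id: str | None = None


def run_case2(
    spectra: SpectraSet,
    y: np.ndarray,
    mode: str,
    solvent: np.ndarray | None = None,
    solute: np.ndarray | None = None,
    marker_wn: float = 1080.0,
    baseline_wn: float = 1200.0,
    divide_by_b: bool = True,
) -> Case2Result:
    """Univariate solute calibration from EMSC analyte parameters.

    mode "known_analyte": constant-baseline EMSC (order 0) with the supplied
    solvent reference and the supplied solute spectrum as analyte.

    mode "estimated_analyte": pick the most solvent-like spectrum by
    :func:`select_reference_by_peak_ratio`, run a first order-0 EMSC with
    zero weights on the chemically active 950-1200 cm^-1 region, estimate the
    analyte as the first PCA loading of the residuals, then refit without
    weights with the loading appended.

    Either way the analyte parameter (divided by b when ``divide_by_b``) is
    regressed against ``y``.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size != spectra.n_spectra:
        raise ValidationError("responses are not aligned with the spectra")
    if mode == "known_analyte":
        if solvent is None or solute is None:
            raise ValidationError(
                "known_analyte mode needs solvent (reference) and solute spectra"
            )
        analyte = ConstituentSpectrum(
            np.asarray(solute, dtype=float), kind="analyte", provenance="supplied"
        )
        spec = EMSCModelSpec(
            reference=np.asarray(solvent, dtype=float),
            polynomial_order=0,
            analytes=[analyte.values],
        )
        params = fit(spec, spectra)
        ref_id = None
    elif mode == "estimated_analyte":
        reference, ref_id = select_reference_by_peak_ratio(
            spectra, marker_wn, baseline_wn
        )
        wn = spectra.axis.values
        weights = np.ones_like(wn)
        lo, hi = CASE2_ZERO_WEIGHT_REGION
        weights[(wn >= lo) & (wn <= hi)] = 0.0
        first = EMSCModelSpec(
            reference=reference, polynomial_order=0, weights=weights
        )
        analyte = estimate_analyte_from_residuals(spectra, first, n_components=1)[0]
        _, params = refit_with_estimated_analyte(
            spectra, first.without_weights(), analyte
        )
    else:
        raise ValidationError(
            f"unknown mode {mode!r}; use 'known_analyte' or 'estimated_analyte'"
        )
    f = np.array([p.f[-1] for p in params])
    b = np.array([p.b for p in params])
    x = f / b if divide_by_b else f
    calibration = univariate_calibration(x, y)
    return Case2Result(calibration, x, analyte, ref_id)


@dataclass
class Case3Result:
    """Segmentation outcome with the loading and parameters behind it."""

    mask: SegmentationMask
    analyte: ConstituentSpectrum
    f_values: np.ndarray
    scores: np.ndarray


def run_case3(image: HyperspectralImage, threshold: float = 0.0) -> Case3Result:
    """Two-class segmentation of a hyperspectral image via EMSC parameters.

    An EMSC with the image mean as reference and a constant + linear baseline
    is fitted; the first residual-PCA loading is appended as an analyte and
    the image refitted. Pixels with analyte parameter above ``threshold``
    (default 0, a sign test) form class 1. The same labels are obtained by
    thresholding the PCA scores directly; both are returned.
    """
    spectra = image.to_spectra()
    spec = EMSCModelSpec(reference=spectra.mean_spectrum(), polynomial_order=1)
    analyte = estimate_analyte_from_residuals(spectra, spec, n_components=1)[0]
    _, params = refit_with_estimated_analyte(spectra, spec, analyte)
    f = np.array([p.f[-1] for p in params])
    # score of each pixel on the loading: because the loading is orthogonal
    # to the basic design, this projection equals the refit's f parameter
    resid = np.vstack([p.residual for p in fit(spec, spectra)])
    scores = resid @ analyte.values
    mask = SegmentationMask(
        image.width, image.height, f > threshold, threshold
    )
    return Case3Result(mask, analyte, f, scores)
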