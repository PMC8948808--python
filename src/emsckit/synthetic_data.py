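"""Synthetic spectra generators for the three study designs.

Three scenarios are provided, each deterministic for a fixed seed and each
emitting the ground truth needed to score recovery without re-deriving it:

* :func:`make_two_group` — two chemically different groups of protein-like
  transmission FTIR spectra built from a Lorentzian band template. Only the
  amide I (1653 cm^-1) and amide II (1545 cm^-1) peak heights differ between
  groups: group 1 amide heights are scaled uniformly in [0.85, 1.0] of the
  template, group 2 in [0.40, 0.55], 20 spectra per group. Optional random
  constant/linear/quadratic baselines with coefficients uniform in
  [-0.1, 0.1] emulate physical disturbances.
* :func:`make_mixture_series` — ATR-like solvent + solute mixtures emulating
  glucose in aqueous growth media: water-like solvent template, glucose-like
  solute with a marker band near 1080 cm^-1 (solvent flat near 1200 cm^-1),
  solute amplitude proportional to concentration in g/L, multiplicative
  thickness draw, small constant offset, Gaussian noise.
* :func:`make_two_class_image` — a 64 x 64 hyperspectral image with two
  spatially contiguous tissue classes; class B adds a collagen-like contrast
  spectrum to the class A template.

The Lorentzian band tables are this package's own, chosen to reproduce the
qualitative shape of protein FTIR absorbance spectra; tests depend on the
statistical structure of the scenarios, not on any particular waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .emsc_model import centered_polynomials
from .errors import DegenerateScenarioError, ValidationError
from .spectra_core import HyperspectralImage, SpectraSet, WavenumberAxis

__all__ = [
    "Band",
    "BandModel",
    "TwoGroupScenario",
    "MixtureScenario",
    "ImageScenario",
    "lorentzian_spectrum",
    "protein_band_model",
    "make_two_group",
    "make_mixture_series",
    "make_two_class_image",
]


@dataclass(frozen=True)
class Band:
    """One Lorentzian band: center (cm^-1), HWHM gamma (cm^-1), height h."""

    center: float
    gamma: float
    height: float


@dataclass
class BandModel:
    """A sum of Lorentzian bands evaluated on a wavenumber axis."""

    bands: list[Band]
    axis: WavenumberAxis

    def __post_init__(self) -> None:
        for b in self.bands:
            if b.gamma <= 0:
                raise ValidationError(f"band at {b.center:g}: gamma must be > 0")
            if b.height < 0:
                raise ValidationError(f"band at {b.center:g}: height must be >= 0")


def lorentzian_spectrum(model: BandModel) -> np.ndarray:
    """Evaluate L(v) = sum_bands h * gamma^2 / ((v - v0)^2 + gamma^2).

    With the half-width-at-half-maximum parameterization the value at the
    center of an isolated band is h, and at v0 +/- gamma it is h/2.
    """
    v = model.axis.values
    out = np.zeros_like(v)
    for b in model.bands:
        out += b.height * b.gamma**2 / ((v - b.center) ** 2 + b.gamma**2)
    return out


# ---------------------------------------------------------------------------
# Protein-like template (two-group scenario and image scenario)
# ---------------------------------------------------------------------------

AMIDE_I = 1653.0
AMIDE_II = 1545.0

#: amide bands: the chemically varying part of the two-group template
_AMIDE_BANDS = [
    Band(AMIDE_I, 22.0, 0.85),
    Band(AMIDE_II, 20.0, 0.50),
]

#: fixed bands shared by every spectrum: the broad O-H/N-H stretch envelope
#: (hydrated biomaterial), amide A shoulder, C-H stretches, CH bends, amide
#: III and the carbohydrate C-O region. The broad envelope dominates the
#: spectrum norm, so the two group means are highly dependent even though
#: the amide peaks differ strongly.
_FIXED_BANDS = [
    Band(3300.0, 300.0, 0.90),
    Band(3075.0, 60.0, 0.22),
    Band(2955.0, 18.0, 0.12),
    Band(2925.0, 16.0, 0.18),
    Band(2855.0, 16.0, 0.10),
    Band(1450.0, 18.0, 0.20),
    Band(1390.0, 18.0, 0.14),
    Band(1240.0, 28.0, 0.20),
    Band(1160.0, 40.0, 0.15),
    Band(1080.0, 60.0, 0.30),
    Band(985.0, 50.0, 0.12),
]


def default_broadband_axis() -> WavenumberAxis:
    """500-4000 cm^-1 at 2 cm^-1 spacing (1751 channels)."""
    return WavenumberAxis(np.arange(500.0, 4000.0 + 1, 2.0))


def protein_band_model(axis: WavenumberAxis, amide_scale: float = 1.0) -> BandModel:
    """Protein-like template with amide I/II heights scaled by ``amide_scale``."""
    amide = [Band(b.center, b.gamma, b.height * amide_scale) for b in _AMIDE_BANDS]
    return BandModel(amide + list(_FIXED_BANDS), axis)


@dataclass
class TwoGroupScenario:
    """Configuration for the two-group protein simulation."""

    seed: int = 0
    n_per_group: int = 20
    group1_scale: tuple[float, float] = (0.85, 1.0)
    group2_scale: tuple[float, float] = (0.40, 0.55)
    add_baselines: bool = False
    baseline_range: tuple[float, float] = (-0.1, 0.1)
    noise_sigma: float = 1e-3
    independent_amide_draws: bool = False
    axis: WavenumberAxis = field(default_factory=default_broadband_axis)


def make_two_group(scenario: TwoGroupScenario):
    """Generate the two-group dataset.

    Returns ``(SpectraSet, labels, truth)`` where ``labels`` is an integer
    array (0 = group 1 "red", 1 = group 2 "blue") and ``truth`` records the
    per-spectrum amide scalings and baseline coefficients (on the centered
    polynomial basis), plus the fixed/amide template parts.
    """
    rng = np.random.default_rng(scenario.seed)
    axis = scenario.axis
    fixed = lorentzian_spectrum(BandModel(list(_FIXED_BANDS), axis))
    amide = lorentzian_spectrum(BandModel(list(_AMIDE_BANDS), axis))
    amide_parts = [
        lorentzian_spectrum(BandModel([b], axis)) for b in _AMIDE_BANDS
    ]
    n = scenario.n_per_group
    spectra, scales = [], []
    for lo, hi in (scenario.group1_scale, scenario.group2_scale):
        if scenario.independent_amide_draws:
            draws = rng.uniform(lo, hi, size=(n, len(_AMIDE_BANDS)))
            for row in draws:
                spectra.append(fixed + sum(s * p for s, p in zip(row, amide_parts)))
            scales.append(draws)
        else:
            draws = rng.uniform(lo, hi, size=n)
            for s in draws:
                spectra.append(fixed + s * amide)
            scales.append(draws[:, None] * np.ones(len(_AMIDE_BANDS)))
    data = np.vstack(spectra)
    poly = centered_polynomials(axis, 2)
    if scenario.add_baselines:
        lo, hi = scenario.baseline_range
        base_coef = rng.uniform(lo, hi, size=(2 * n, 3))
        data = data + base_coef @ poly.T
    else:
        base_coef = np.zeros((2 * n, 3))
    if scenario.noise_sigma > 0:
        data = data + rng.normal(0.0, scenario.noise_sigma, size=data.shape)
    labels = np.repeat([0, 1], n)
    ids = [f"red_{i:02d}" for i in range(n)] + [f"blue_{i:02d}" for i in range(n)]
    truth = {
        "amide_scales": np.vstack(scales),
        "baseline_coeffs": base_coef,
        "fixed_spectrum": fixed,
        "amide_spectrum": amide,
        "poly_basis": poly,
        "labels": labels,
    }
    return SpectraSet(axis, data, ids), labels, truth


# ---------------------------------------------------------------------------
# Solvent + solute mixture series (ATR-like glucose-in-media emulation)
# ---------------------------------------------------------------------------

#: water-like solvent: broad O-H stretch, H-O-H bend, weak association band;
#: essentially flat through 950-1250 cm^-1
_SOLVENT_BANDS = [
    Band(3350.0, 220.0, 0.90),
    Band(2120.0, 120.0, 0.05),
    Band(1640.0, 40.0, 0.45),
]

#: glucose-like solute: C-O/C-C fingerprint cluster with the 1080 cm^-1 marker
_SOLUTE_BANDS = [
    Band(990.0, 10.0, 0.30),
    Band(1030.0, 14.0, 0.90),
    Band(1080.0, 14.0, 1.00),
    Band(1150.0, 12.0, 0.45),
]

#: absorbance of the solute template per g/L of solute
SOLUTE_ABS_PER_GL = 1e-3


def default_atr_axis() -> WavenumberAxis:
    """800-3700 cm^-1 at 2 cm^-1 spacing (covers the O-H stretch envelope)."""
    return WavenumberAxis(np.arange(800.0, 3700.0 + 1, 2.0))


@dataclass
class MixtureScenario:
    """Configuration for the solvent + solute mixture series."""

    seed: int = 0
    n_samples: int = 40
    conc_range: tuple[float, float] = (0.55, 80.0)  # g/L
    concentrations: Sequence[float] | None = None  # overrides conc_range
    thickness_range: tuple[float, float] = (0.9, 1.1)
    offset_range: tuple[float, float] = (-0.005, 0.005)
    noise_sigma: float = 5e-4
    axis: WavenumberAxis = field(default_factory=default_atr_axis)


def make_mixture_series(scenario: MixtureScenario):
    """Generate the mixture series.

    Each spectrum is ``thickness * (solvent + c * SOLUTE_ABS_PER_GL * solute)
    + offset + noise`` with concentration c in g/L. Returns
    ``(SpectraSet, concentrations, truth)`` where truth carries the solvent
    and solute templates and the thickness/offset draws.
    """
    rng = np.random.default_rng(scenario.seed)
    axis = scenario.axis
    solvent = lorentzian_spectrum(BandModel(list(_SOLVENT_BANDS), axis))
    solute = lorentzian_spectrum(BandModel(list(_SOLUTE_BANDS), axis))
    if scenario.concentrations is not None:
        conc = np.asarray(scenario.concentrations, dtype=float)
        n = conc.size
    else:
        n = scenario.n_samples
        conc = rng.uniform(*scenario.conc_range, size=n)
    thickness = rng.uniform(*scenario.thickness_range, size=n)
    offset = rng.uniform(*scenario.offset_range, size=n)
    data = (
        thickness[:, None]
        * (solvent[None, :] + (conc * SOLUTE_ABS_PER_GL)[:, None] * solute[None, :])
        + offset[:, None]
    )
    if scenario.noise_sigma > 0:
        data = data + rng.normal(0.0, scenario.noise_sigma, size=data.shape)
    ids = [f"mix_{i:02d}" for i in range(n)]
    truth = {
        "solvent_spectrum": solvent,
        "solute_spectrum": solute,
        "thickness": thickness,
        "offset": offset,
        "abs_per_gl": SOLUTE_ABS_PER_GL,
    }
    return SpectraSet(axis, data, ids), conc, truth


# ---------------------------------------------------------------------------
# Two-class hyperspectral image (tissue-section emulation)
# ---------------------------------------------------------------------------

#: collagen-like contrast added to class-B pixels: amide III region gains,
#: slight amide I deficit
_CONTRAST_BANDS = [
    Band(1338.0, 12.0, 0.50),
    Band(1284.0, 12.0, 0.35),
    Band(1235.0, 14.0, 0.80),
    Band(1204.0, 10.0, 0.40),
]


def default_microscopy_axis() -> WavenumberAxis:
    """900-1800 cm^-1 at 4 cm^-1 spacing (fingerprint + amide region)."""
    return WavenumberAxis(np.arange(900.0, 1800.0 + 1, 4.0))


@dataclass
class ImageScenario:
    """Configuration for the two-class hyperspectral image."""

    seed: int = 0
    width: int = 64
    height: int = 64
    contrast_amplitude: float = 0.05
    thickness_range: tuple[float, float] = (0.8, 1.2)
    baseline_range: tuple[float, float] = (-0.05, 0.05)
    noise_sigma: float = 2e-3
    axis: WavenumberAxis = field(default_factory=default_microscopy_axis)


def contrast_spectrum(axis: WavenumberAxis) -> np.ndarray:
    """Unit-norm class-contrast spectrum (collagen-like difference).

    The raw collagen gains (amide III region) minus an amide I deficit are
    projected off the span of the class-A template and the constant/linear
    baselines: a chemical difference spectrum is exactly the part of the
    class difference that scaling and baseline terms cannot absorb, which is
    what makes it recoverable from model residuals.
    """
    gain = lorentzian_spectrum(BandModel(list(_CONTRAST_BANDS), axis))
    deficit = lorentzian_spectrum(BandModel([Band(AMIDE_I, 25.0, 0.30)], axis))
    raw = gain - deficit
    template = lorentzian_spectrum(protein_band_model(axis))
    basis = np.column_stack([template, *centered_polynomials(axis, 1).T])
    coef, *_ = np.linalg.lstsq(basis, raw, rcond=None)
    c = raw - basis @ coef
    return c / np.linalg.norm(c)


def make_two_class_image(scenario: ImageScenario):
    """Generate the two-class image.

    Class B occupies a contiguous wavy region on the right of the frame;
    class B spectra = class A template + amplitude * contrast. Per-pixel
    multiplicative thickness and constant + linear baselines are drawn, then
    Gaussian noise added. Returns ``(HyperspectralImage, mask, truth)`` with
    ``mask[i] = True`` for class-B pixels (row-major order).
    """
    if scenario.contrast_amplitude == 0:
        raise DegenerateScenarioError(
            "contrast amplitude is zero: the two classes are identical and "
            "segmentation is impossible"
        )
    rng = np.random.default_rng(scenario.seed)
    axis = scenario.axis
    template = lorentzian_spectrum(protein_band_model(axis))
    contrast = contrast_spectrum(axis)
    w, h = scenario.width, scenario.height
    x = np.arange(w)[None, :].repeat(h, axis=0)
    y = np.arange(h)[:, None].repeat(w, axis=1)
    boundary = w / 2 + 0.15 * w * np.sin(2 * np.pi * y / h)
    mask = (x > boundary).reshape(-1)  # row-major: y outer, x inner
    n_px = w * h
    thickness = rng.uniform(*scenario.thickness_range, size=n_px)
    base_coef = rng.uniform(*scenario.baseline_range, size=(n_px, 2))
    poly = centered_polynomials(axis, 1)
    pure = template[None, :] + (
        scenario.contrast_amplitude * mask[:, None] * contrast[None, :]
    )
    cube = thickness[:, None] * pure + base_coef @ poly.T
    if scenario.noise_sigma > 0:
        cube = cube + rng.normal(0.0, scenario.noise_sigma, size=cube.shape)
    image = HyperspectralImage(w, h, axis, cube)
    truth = {
        "template": template,
        "contrast_spectrum": contrast,
        "thickness": thickness,
        "baseline_coeffs": base_coef,
        "mask": mask,
    }
    return image, mask, truth
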