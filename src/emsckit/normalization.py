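"""Filtering-style normalizations for comparison with EMSC.

Vector and peak normalization are the classical filtering alternatives to a
model-based correction. Both require baseline-free spectra; EMSC performs
baseline correction and normalization in one step. A weighted EMSC with low
weights on the chemically active regions reproduces vector normalization up
to a global affine factor.
"""

from __future__ import annotations

import numpy as np

from .errors import NormalizationError
from .spectra_core import SpectraSet

__all__ = ["vector_normalize", "peak_normalize"]


def vector_normalize(spectra: SpectraSet, match_mean: bool = True) -> SpectraSet:
    """Scale each spectrum to unit Euclidean norm.

    With ``match_mean`` (default) every spectrum is then multiplied by the
    norm of the dataset mean spectrum, so the output lives on the scale of
    the raw data — the convention of normalizing "according to the mean
    spectrum" of the dataset.
    """
    norms = np.linalg.norm(spectra.absorbance, axis=1)
    if np.any(norms == 0):
        bad = spectra.ids[int(np.argmin(norms))]
        raise NormalizationError(f"spectrum {bad!r} has zero norm")
    out = spectra.absorbance / norms[:, None]
    if match_mean:
        out = out * np.linalg.norm(spectra.mean_spectrum())
    return SpectraSet(spectra.axis, out, list(spectra.ids))


def peak_normalize(spectra: SpectraSet, wavenumber: float) -> SpectraSet:
    """Scale each spectrum so the peak nearest ``wavenumber`` equals 1.

    Standardizes the spectra to the amount of one compound, e.g. proteins via
    the amide I band at 1653 cm^-1. The nearest channel is used without
    interpolation; an exact tie picks the lower wavenumber.
    """
    idx = spectra.axis.nearest_index(wavenumber)
    peaks = spectra.absorbance[:, idx]
    if np.any(peaks <= 0):
        bad = spectra.ids[int(np.argmin(peaks))]
        raise NormalizationError(
            f"spectrum {bad!r} has non-positive absorbance "
            f"({peaks.min():g}) at {spectra.axis.values[idx]:g} cm^-1"
        )
    return SpectraSet(
        spectra.axis, spectra.absorbance / peaks[:, None], list(spectra.ids)
    )
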