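"""Constituent (difference) spectra and residual-PCA analyte estimation.

A constituent added to an EMSC should represent a chemical *difference* from
the reference spectrum, not a raw compound spectrum: using the full compound
spectrum makes the design nearly collinear with the reference and the least
squares problem ill-posed. Two constructors are provided:

* :func:`difference_spectrum` — the classical k - Zref difference.
* :func:`estimate_analyte_from_residuals` — data-driven: fit a basic EMSC,
  take a PCA of the residuals (or, equivalently in practice, of the corrected
  spectra) and use the leading loadings. Such loadings are exactly orthogonal
  to the model spectra that produced the residuals, so adding them back as
  analytes parameterizes chemical variation without changing the corrected
  spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .emsc_model import EMSCModelSpec
from .emsc_solver import correct, fit, residual_matrix
from .errors import (
    DegenerateConstituentError,
    NoVariationError,
    ParseError,
    ValidationError,
)
from .spectra_core import SpectraSet

__all__ = [
    "ConstituentSpectrum",
    "difference_spectrum",
    "estimate_analyte_from_residuals",
    "refit_with_estimated_analyte",
    "save_constituent",
    "load_constituent",
]


@dataclass
class ConstituentSpectrum:
    """Unit-norm constituent spectrum with its role and origin."""

    values: np.ndarray
    kind: Literal["analyte", "interferent"] = "analyte"
    provenance: Literal["supplied", "difference", "pca_loading"] = "supplied"
    source_note: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(v)):
            raise ValidationError("constituent spectrum must be finite")
        norm = np.linalg.norm(v)
        if norm < 1e-300:
            raise DegenerateConstituentError("constituent spectrum is zero")
        self.values = v / norm
        if self.kind not in ("analyte", "interferent"):
            raise ValidationError(f"unknown constituent kind {self.kind!r}")


def difference_spectrum(
    k: np.ndarray,
    ref: np.ndarray,
    kind: Literal["analyte", "interferent"] = "analyte",
    source_note: str = "",
) -> ConstituentSpectrum:
    """Unit-norm difference spectrum (k - ref).

    Raises if k is numerically indistinguishable from the reference.
    """
    k = np.asarray(k, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if k.size != ref.size:
        raise ValidationError("spectra must share the model axis")
    diff = k - ref
    if np.linalg.norm(diff) < 1e-12 * max(np.linalg.norm(ref), 1e-300):
        raise DegenerateConstituentError(
            "constituent equals the reference; difference spectrum is degenerate"
        )
    return ConstituentSpectrum(diff, kind=kind, provenance="difference",
                               source_note=source_note)


def _fix_sign(loading: np.ndarray) -> np.ndarray:
    """Deterministic orientation: largest-magnitude element made positive."""
    idx = int(np.argmax(np.abs(loading)))
    return -loading if loading[idx] < 0 else loading


def _pca_loadings(matrix: np.ndarray, n_components: int, center: bool) -> np.ndarray:
    if center:
        matrix = matrix - matrix.mean(axis=0)
    _, s, vt = np.linalg.svd(matrix, full_matrices=False)
    return np.vstack([_fix_sign(vt[i]) for i in range(n_components)])


def estimate_analyte_from_residuals(
    data: SpectraSet,
    spec: EMSCModelSpec,
    n_components: int = 1,
    center: bool = True,
    on: Literal["residuals", "corrected"] = "residuals",
) -> list[ConstituentSpectrum]:
    """Estimate analyte spectra as leading PCA loadings of the EMSC residuals.

    Fits ``spec`` to ``data``, forms the residual matrix (or the corrected
    spectra when ``on="corrected"``; the two give practically the same
    loadings), mean-centers it across spectra and extracts the top
    ``n_components`` right singular vectors. Loadings are unit-norm with a
    deterministic sign (largest-magnitude element positive).
    """
    if n_components < 1:
        raise ValidationError("n_components must be >= 1")
    if n_components >= min(data.n_spectra, data.n_channels):
        raise ValidationError(
            f"n_components={n_components} must be < "
            f"min(n_spectra={data.n_spectra}, n_channels={data.n_channels})"
        )
    params = fit(spec, data)
    if on == "residuals":
        matrix = residual_matrix(data, spec, params)
    elif on == "corrected":
        matrix = correct(spec, data, params).spectra.absorbance
        if np.any(~np.isfinite(matrix)):
            raise ValidationError(
                "corrected spectra contain missing values; cannot run PCA"
            )
    else:
        raise ValidationError(f"unknown PCA input {on!r}")
    scale = max(1.0, float(np.max(np.abs(data.absorbance))))
    resid = residual_matrix(data, spec, params)
    if np.linalg.norm(resid) < 1e-10 * scale:
        raise NoVariationError(
            "residuals are numerically zero; the model explains the data "
            "exactly and no analyte direction can be estimated"
        )
    loadings = _pca_loadings(matrix, n_components, center)
    return [
        ConstituentSpectrum(
            loadings[i],
            kind="analyte",
            provenance="pca_loading",
            source_note=f"PC{i + 1} of EMSC {on}",
        )
        for i in range(n_components)
    ]


def refit_with_estimated_analyte(
    data: SpectraSet, spec: EMSCModelSpec, loading: ConstituentSpectrum
):
    """Refit with the estimated loading appended as an analyte.

    Because a residual-PCA loading is orthogonal to every column of the
    generating design, the corrected spectra are unchanged; the loading's f
    parameter simply captures the variation that previously sat in eps.
    Returns ``(CorrectedSet, list[EMSCParameters])``.
    """
    v = np.asarray(loading.values, dtype=float).ravel()
    if v.size != data.n_channels:
        raise ValidationError("loading is not on the data axis")
    if np.linalg.norm(v) < 1e-300:
        raise DegenerateConstituentError("zero loading")
    extended = spec.with_analyte(v)
    params = fit(extended, data)
    corrected = correct(extended, data, params)
    return corrected, params


def save_constituent(c: ConstituentSpectrum, wavenumbers: np.ndarray, path: str | Path) -> None:
    """Write a constituent in the matrix dialect with one metadata line."""
    lines = [
        f"# kind={c.kind} provenance={c.provenance} note={c.source_note}",
        "wavenumber,constituent",
    ]
    for w, v in zip(np.asarray(wavenumbers).ravel(), c.values):
        lines.append(f"{w:.12g},{v:.12g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_constituent(path: str | Path) -> tuple[ConstituentSpectrum, np.ndarray]:
    """Read a constituent file; returns (constituent, wavenumbers)."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    if not text or not text[0].startswith("#"):
        raise ParseError(f"{path}: missing metadata header line")
    meta = dict(
        kv.split("=", 1) for kv in text[0].lstrip("# ").split() if "=" in kv
    )
    wn, vals = [], []
    for line in text[2:]:
        if not line.strip():
            continue
        w, v = line.split(",")
        wn.append(float(w))
        vals.append(float(v))
    return (
        ConstituentSpectrum(
            np.array(vals),
            kind=meta.get("kind", "analyte"),  # type: ignore[arg-type]
            provenance=meta.get("provenance", "supplied"),  # type: ignore[arg-type]
            source_note=meta.get("note", ""),
        ),
        np.array(wn),
    )
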