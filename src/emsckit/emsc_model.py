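"""EMSC design-matrix construction, weighting, and collinearity diagnostics.

The EMSC models each apparent-absorbance spectrum as

    Zapp = b * Zref + sum_k p_k * T_k + sum_j f_j * Zana_j + sum_j g_j * Zint_j + eps

where T_k are polynomial baseline spectra centered around the midpoint of the
wavenumber region (T_0 is the all-ones column, so p_0 is the constant baseline
a), Zana_j are analyte constituent spectra (kept in the corrected spectrum) and
Zint_j are interferent constituent spectra (removed). Constituent columns are
rescaled to unit Euclidean norm inside the design so the fitted f and g are
comparable across runs; the original norms are recorded so parameters can be
reported on the caller's scale.

Weighting multiplies the model spectra — and by default also the measured
spectrum — element-wise with a non-negative weight spectrum before the least
squares step, which makes zero-weight channels exactly inert. See
``EMSCModelSpec.weight_mode`` for the design-only alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .errors import DegenerateConstituentError, ModelError, ValidationError
from .spectra_core import WavenumberAxis

__all__ = [
    "EMSCModelSpec",
    "DesignMatrix",
    "CollinearityReport",
    "centered_polynomials",
    "build_design",
    "apply_weights",
    "collinearity_diagnostics",
    "orthogonalize_constituent",
]

MAX_POLY_ORDER = 7
#: broadband FTIR caution: high orders start modeling the broad O-H region
BROADBAND_SAFE_ORDER = 2

CORRELATION_FLAG = 0.95
CONDITION_FLAG = 1e6


@dataclass
class EMSCModelSpec:
    """Specification of an EMSC model on a fixed wavenumber axis.

    Parameters
    ----------
    reference : ndarray
        Reference spectrum Zref, typically the dataset mean. Must not be
        identically zero.
    polynomial_order : int
        Highest polynomial baseline degree P (0 = constant only, i.e. MSC).
    analytes, interferents : sequences of ndarray
        Constituent spectra on the model axis. Analytes are kept in the
        corrected spectra; interferents are removed.
    weights : ndarray, optional
        Non-negative per-channel weights; ``None`` means all ones.
    weight_mode : {"both", "design_only"}
        Whether the measured spectrum is multiplied by the weights along with
        the model spectra ("both", default) or only the model spectra are
        ("design_only"). The two coincide for binary weights.
    """

    reference: np.ndarray
    polynomial_order: int = 2
    analytes: Sequence[np.ndarray] = field(default_factory=list)
    interferents: Sequence[np.ndarray] = field(default_factory=list)
    weights: np.ndarray | None = None
    weight_mode: Literal["both", "design_only"] = "both"

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float).ravel()
        n = self.reference.size
        if n < 3:
            raise ModelError("reference spectrum needs at least 3 channels")
        if not np.all(np.isfinite(self.reference)):
            raise ModelError("reference spectrum contains non-finite values")
        if not np.any(self.reference != 0):
            raise ModelError("reference spectrum is identically zero")
        if not (0 <= int(self.polynomial_order) <= MAX_POLY_ORDER):
            raise ModelError(
                f"polynomial order must be in [0, {MAX_POLY_ORDER}], "
                f"got {self.polynomial_order}"
            )
        self.polynomial_order = int(self.polynomial_order)
        if self.polynomial_order > BROADBAND_SAFE_ORDER:
            warnings.warn(
                f"polynomial order {self.polynomial_order} > "
                f"{BROADBAND_SAFE_ORDER}: high orders can model broad chemical "
                "features (e.g. the O-H stretching region) in broadband FTIR",
                stacklevel=2,
            )
        self.analytes = [self._check_spectrum(s, "analyte", n) for s in self.analytes]
        self.interferents = [
            self._check_spectrum(s, "interferent", n) for s in self.interferents
        ]
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float).ravel()
            if w.size != n:
                raise ModelError(
                    f"weights length {w.size} != channel count {n}"
                )
            if np.any(w < 0) or not np.all(np.isfinite(w)):
                raise ModelError("weights must be finite and non-negative")
            if not np.any(w > 0):
                raise ModelError("weights must have at least one positive entry")
            self.weights = w
        if self.weight_mode not in ("both", "design_only"):
            raise ModelError(f"unknown weight_mode {self.weight_mode!r}")

    @staticmethod
    def _check_spectrum(s: np.ndarray, what: str, n: int) -> np.ndarray:
        s = np.asarray(s, dtype=float).ravel()
        if s.size != n:
            raise ModelError(
                f"{what} spectrum has {s.size} channels, model axis has {n}"
            )
        if not np.all(np.isfinite(s)):
            raise ModelError(f"{what} spectrum contains non-finite values")
        return s

    @property
    def n_channels(self) -> int:
        return self.reference.size

    def with_analyte(self, spectrum: np.ndarray) -> "EMSCModelSpec":
        """A copy of this spec with one more analyte appended."""
        return replace(self, analytes=[*self.analytes, np.asarray(spectrum)])

    def without_weights(self) -> "EMSCModelSpec":
        return replace(self, weights=None)


@dataclass
class DesignMatrix:
    """Column matrix of EMSC model spectra with role labels.

    Column order is always ``reference, poly_0..poly_P, analyte_j...,
    interferent_j...``. ``constituent_scales`` maps constituent roles to the
    Euclidean norm the input spectrum was divided by, so fitted parameters can
    be converted back to the caller's scale (divide f by the scale).
    """

    columns: np.ndarray
    roles: list[str]
    constituent_scales: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if cols.shape[1] != len(self.roles):
            raise ModelError("role labels do not match column count")
        if self.roles.count("reference") != 1:
            raise ModelError("design must contain exactly one reference column")
        norms = np.linalg.norm(cols, axis=0)
        if np.any(norms == 0):
            bad = self.roles[int(np.argmin(norms))]
            raise ModelError(f"design column {bad!r} is identically zero")
        self.columns = cols

    @property
    def n_terms(self) -> int:
        return self.columns.shape[1]

    def column(self, role: str) -> np.ndarray:
        return self.columns[:, self.roles.index(role)]


def centered_polynomials(axis: WavenumberAxis, order: int) -> np.ndarray:
    """Polynomial baseline spectra t^0 ... t^order on the centered axis.

    The wavenumber axis is affinely mapped to t in [-1, 1] around the region
    midpoint, so even-degree columns are symmetric and odd-degree columns
    antisymmetric about the midpoint.
    """
    if order < 0:
        raise ValidationError(f"polynomial order must be >= 0, got {order}")
    v = axis.values
    mid = 0.5 * (v[0] + v[-1])
    half = 0.5 * (v[-1] - v[0])
    t = (v - mid) / half
    return np.vander(t, N=order + 1, increasing=True)


def build_design(spec: EMSCModelSpec, axis: WavenumberAxis) -> DesignMatrix:
    """Assemble the EMSC design matrix for ``spec`` on ``axis``."""
    if spec.n_channels != len(axis):
        raise ModelError(
            f"model spectra have {spec.n_channels} channels but axis has "
            f"{len(axis)}"
        )
    poly = centered_polynomials(axis, spec.polynomial_order)
    cols = [spec.reference[:, None], poly]
    roles = ["reference"] + [f"poly_{k}" for k in range(spec.polynomial_order + 1)]
    scales: dict[str, float] = {}
    for kind, spectra in (("analyte", spec.analytes), ("interferent", spec.interferents)):
        for j, s in enumerate(spectra):
            norm = float(np.linalg.norm(s))
            if norm < 1e-300:
                raise ModelError(f"{kind}_{j} has zero norm")
            role = f"{kind}_{j}"
            roles.append(role)
            scales[role] = norm
            cols.append((s / norm)[:, None])
    return DesignMatrix(np.hstack(cols), roles, scales)


def apply_weights(
    design: DesignMatrix,
    spectrum: np.ndarray,
    weights: np.ndarray,
    mode: Literal["both", "design_only"] = "both",
) -> tuple[np.ndarray, np.ndarray]:
    """Multiply design columns (and, by default, the spectrum) by weights.

    Returns the weighted column matrix and the (possibly) weighted spectrum.
    Zero-weight channels then exert no influence on the least-squares fit.
    """
    w = np.asarray(weights, dtype=float).ravel()
    if w.size != design.columns.shape[0]:
        raise ValidationError(
            f"weights length {w.size} != channel count {design.columns.shape[0]}"
        )
    if np.any(w < 0):
        raise ValidationError("weights must be non-negative")
    spectrum = np.asarray(spectrum, dtype=float).ravel()
    wd = design.columns * w[:, None]
    ws = spectrum * w if mode == "both" else spectrum.copy()
    return wd, ws


@dataclass
class CollinearityReport:
    """Conditioning summary for an EMSC design."""

    condition_number: float
    max_abs_correlation: float
    pairs: list[tuple[str, str, float]]
    collinear: bool
    ill_conditioned: bool

    @property
    def flagged(self) -> bool:
        return self.collinear or self.ill_conditioned

    def __str__(self) -> str:  # CLI-facing report
        lines = [
            f"condition number (column-normalized design): {self.condition_number:.6g}",
            f"max pairwise |correlation|: {self.max_abs_correlation:.6g}",
            "pairwise |correlation| table:",
        ]
        for a, b, c in sorted(self.pairs, key=lambda p: -abs(p[2])):
            lines.append(f"  {a:>14s} ~ {b:<14s} {c: .6f}")
        if self.collinear:
            lines.append(
                f"WARNING: near-collinear model spectra "
                f"(|correlation| > {CORRELATION_FLAG}); parameter estimates "
                "may be unstable"
            )
        if self.ill_conditioned:
            lines.append(
                f"WARNING: condition number > {CONDITION_FLAG:g}; the least "
                "squares problem is (nearly) ill-posed"
            )
        if not self.flagged:
            lines.append("no conditioning problems detected")
        return "\n".join(lines)


def collinearity_diagnostics(design: DesignMatrix) -> CollinearityReport:
    """Condition number and pairwise column correlations of the design.

    Columns are normalized to unit Euclidean norm before the singular value
    decomposition, so the condition number measures angular dependence rather
    than raw scale differences. The correlation reported for a column pair is
    the cosine of the angle between the unit-normalized columns.
    """
    if design.n_terms < 2:
        raise ValidationError("need at least 2 design columns to diagnose")
    cols = design.columns / np.linalg.norm(design.columns, axis=0)
    s = np.linalg.svd(cols, compute_uv=False)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else float("inf")
    gram = cols.T @ cols
    pairs = []
    max_corr = 0.0
    for i in range(design.n_terms):
        for j in range(i + 1, design.n_terms):
            c = float(gram[i, j])
            pairs.append((design.roles[i], design.roles[j], c))
            max_corr = max(max_corr, abs(c))
    return CollinearityReport(
        condition_number=cond,
        max_abs_correlation=max_corr,
        pairs=pairs,
        collinear=max_corr > CORRELATION_FLAG,
        ill_conditioned=cond > CONDITION_FLAG,
    )


def orthogonalize_constituent(
    constituent: np.ndarray, against: DesignMatrix
) -> np.ndarray:
    """Project a constituent onto the orthogonal complement of the design span.

    Returns the unit-norm residual of the projection (one Gram-Schmidt step);
    its dot product with every design column is numerically zero. Raises if
    the constituent lies entirely in the span.
    """
    c = np.asarray(constituent, dtype=float).ravel()
    if c.size != against.columns.shape[0]:
        raise ValidationError("constituent length does not match design")
    coef, *_ = np.linalg.lstsq(against.columns, c, rcond=None)
    resid = c - against.columns @ coef
    norm_c = np.linalg.norm(c)
    norm_r = np.linalg.norm(resid)
    if norm_r < 1e-10 * max(norm_c, 1e-300):
        raise DegenerateConstituentError(
            "constituent lies in the span of the design columns"
        )
    return resid / norm_r
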