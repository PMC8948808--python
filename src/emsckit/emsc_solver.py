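"""Least-squares EMSC fitting, correction, residuals and relative content.

Each spectrum is fitted independently by (weighted) least squares over the
design of :func:`emsckit.emsc_model.build_design`. The corrected spectrum
inverts the physical terms:

    Zcorr = (Zapp - sum_k p_k * T_k - sum_j g_j * Zint_j) / b
          = Zref + (sum_j f_j * Zana_j + eps) / b

so interferent contributions and polynomial baselines are removed while
analyte contributions and the chemical residual eps are kept. Residuals are
always reported in the unweighted metric: weights only steer the parameter
estimation, never the definition of eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .emsc_model import DesignMatrix, EMSCModelSpec, build_design
from .errors import IllPosedError, NearZeroScalingError, ValidationError
from .spectra_core import SpectraSet

__all__ = [
    "EMSCParameters",
    "CorrectedSet",
    "fit",
    "correct",
    "fit_correct",
    "residual_matrix",
    "relative_content",
    "write_parameters",
]

#: |b| below this fraction of max|Zref| is treated as a vanishing scaling
B_NEAR_ZERO_REL = 1e-8


@dataclass
class EMSCParameters:
    """Fitted EMSC parameters for one spectrum.

    ``a`` is the constant baseline (identical to ``poly[0]``); ``poly`` holds
    the full polynomial coefficient vector p_0..p_P; ``f`` and ``g`` are the
    analyte and interferent coefficients on the unit-norm design scale.
    """

    id: str
    a: float
    b: float
    poly: np.ndarray
    f: np.ndarray
    g: np.ndarray
    residual: np.ndarray
    b_near_zero: bool = False
    ill_conditioned: bool = False

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficients in design-column order (reference, polys, f, g)."""
        return np.concatenate(([self.b], self.poly, self.f, self.g))


@dataclass
class CorrectedSet:
    """Corrected spectra paired with the parameters that produced them."""

    spectra: SpectraSet
    params: list[EMSCParameters]
    dropped_ids: list[str] = field(default_factory=list)


def _solve(
    design: DesignMatrix, spec: EMSCModelSpec, data: SpectraSet, force: bool
) -> tuple[np.ndarray, bool]:
    """Solve the per-spectrum least-squares problems; returns (coef, illcond).

    coef has shape (n_spectra, n_terms). Raises IllPosedError on a rank
    deficient design unless ``force``; forcing returns the minimum-norm
    solution and marks the result ill-conditioned.
    """
    X = design.columns
    Y = data.absorbance.T  # (n_channels, n_spectra)
    if spec.weights is not None:
        w = spec.weights
        Xw = X * w[:, None]
        Yw = Y * w[:, None] if spec.weight_mode == "both" else Y
    else:
        Xw, Yw = X, Y
    s = np.linalg.svd(Xw, compute_uv=False)
    tol = s[0] * max(Xw.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    deficient = rank < design.n_terms
    if deficient and not force:
        raise IllPosedError(
            f"design is rank deficient (rank {rank} of {design.n_terms}); "
            "the model spectra are linearly dependent — revise the model or "
            "pass force=True for the minimum-norm solution"
        )
    coef, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
    return coef.T, deficient


def _unpack(
    coef: np.ndarray,
    design: DesignMatrix,
    spec: EMSCModelSpec,
    data: SpectraSet,
    ill: bool,
) -> list[EMSCParameters]:
    n_poly = spec.polynomial_order + 1
    n_ana = len(spec.analytes)
    recon = (design.columns @ coef.T).T
    residuals = data.absorbance - recon  # unweighted metric
    b_thresh = B_NEAR_ZERO_REL * np.max(np.abs(spec.reference))
    out = []
    for i, id_ in enumerate(data.ids):
        c = coef[i]
        b = float(c[0])
        poly = c[1 : 1 + n_poly].copy()
        f = c[1 + n_poly : 1 + n_poly + n_ana].copy()
        g = c[1 + n_poly + n_ana :].copy()
        out.append(
            EMSCParameters(
                id=id_,
                a=float(poly[0]),
                b=b,
                poly=poly,
                f=f,
                g=g,
                residual=residuals[i],
                b_near_zero=abs(b) < b_thresh,
                ill_conditioned=ill,
            )
        )
    return out


def fit(
    spec: EMSCModelSpec, data: SpectraSet, force: bool = False
) -> list[EMSCParameters]:
    """Estimate EMSC parameters for every spectrum in ``data``.

    Each spectrum is fitted independently; the output order matches
    ``data.ids``. With weights present, the model spectra (and by default the
    measured spectrum) are multiplied by the weight spectrum before the least
    squares step.
    """
    design = build_design(spec, data.axis)
    coef, deficient = _solve(design, spec, data, force)
    return _unpack(coef, design, spec, data, deficient)


def correct(
    spec: EMSCModelSpec,
    data: SpectraSet,
    params: list[EMSCParameters],
    force: bool = False,
) -> CorrectedSet:
    """Compute corrected spectra from fitted parameters.

    Polynomial baselines and interferent contributions are subtracted and the
    result divided by b; analyte contributions and the residual are kept.
    Spectra whose scaling is flagged near zero are emitted as missing values
    (NaN rows) and listed in ``dropped_ids``; an exactly zero b raises unless
    ``force``.
    """
    if len(params) != data.n_spectra:
        raise ValidationError(
            f"{len(params)} parameter sets for {data.n_spectra} spectra"
        )
    design = build_design(spec, data.axis)
    n_poly = spec.polynomial_order + 1
    poly_cols = design.columns[:, 1 : 1 + n_poly]
    int_cols = design.columns[:, 1 + n_poly + len(spec.analytes) :]
    out = np.empty_like(data.absorbance)
    dropped = []
    for i, (p, id_) in enumerate(zip(params, data.ids)):
        if p.id != id_:
            raise ValidationError(
                f"parameter row {p.id!r} does not align with spectrum {id_!r}"
            )
        if p.b == 0.0 and not force:
            raise NearZeroScalingError(
                f"spectrum {id_!r}: scaling parameter b is exactly zero; "
                "correction undefined (pass force=True to emit missing values)"
            )
        if p.b_near_zero:
            out[i] = np.nan
            dropped.append(id_)
            continue
        numer = data.absorbance[i] - poly_cols @ p.poly - int_cols @ p.g
        out[i] = numer / p.b
    corrected = SpectraSet.__new__(SpectraSet)
    # NaN rows are deliberate for dropped spectra; bypass the finite check
    corrected.axis = data.axis
    corrected.absorbance = out
    corrected.ids = list(data.ids)
    return CorrectedSet(corrected, list(params), dropped)


def fit_correct(
    spec: EMSCModelSpec, data: SpectraSet, force: bool = False
) -> CorrectedSet:
    """Convenience: :func:`fit` then :func:`correct`."""
    return correct(spec, data, fit(spec, data, force=force), force=force)


def residual_matrix(
    data: SpectraSet, spec: EMSCModelSpec, params: list[EMSCParameters]
) -> np.ndarray:
    """Residuals eps per spectrum as rows: Zapp = reconstruction + eps.

    The identity holds in the unweighted metric regardless of the weights
    used in fitting.
    """
    if len(params) != data.n_spectra:
        raise ValidationError(
            f"{len(params)} parameter sets for {data.n_spectra} spectra"
        )
    return np.vstack([p.residual for p in params])


def relative_content(params: EMSCParameters) -> dict[str, np.ndarray]:
    """Relative constituent content: f/b per analyte, g/b per interferent.

    The ratio removes the thickness/scaling effect, so it is proportional to
    constituent concentration per unit of reference material.
    """
    if params.b_near_zero:
        raise NearZeroScalingError(
            f"spectrum {params.id!r}: b is near zero; relative content undefined"
        )
    return {
        "f_over_b": params.f / params.b,
        "g_over_b": params.g / params.b,
    }


def write_parameters(params: list[EMSCParameters], path: str | Path) -> None:
    """Write a delimited parameter table: one row per spectrum."""
    if not params:
        raise ValidationError("no parameters to write")
    n_poly = params[0].poly.size
    n_f = params[0].f.size
    n_g = params[0].g.size
    header = (
        ["id", "a", "b"]
        + [f"p_{k}" for k in range(1, n_poly)]
        + [f"f_{j}" for j in range(n_f)]
        + [f"g_{j}" for j in range(n_g)]
        + ["b_near_zero", "ill_conditioned"]
    )
    lines = [",".join(header)]
    for p in params:
        row = [p.id, f"{p.a:.12g}", f"{p.b:.12g}"]
        row += [f"{v:.12g}" for v in p.poly[1:]]
        row += [f"{v:.12g}" for v in p.f]
        row += [f"{v:.12g}" for v in p.g]
        row += [str(int(p.b_near_zero)), str(int(p.ill_conditioned))]
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
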