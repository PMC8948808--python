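import numpy as np

from emsckit import EMSCModelSpec, SpectraSet


def make_basic_spec(spectra: SpectraSet, order: int = 2, **kw) -> EMSCModelSpec:
    """EMSC spec with the dataset mean as reference."""
    return EMSCModelSpec(
        reference=spectra.mean_spectrum(), polynomial_order=order, **kw
    )


def group_edge_gap(corrected: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Between-group mean gap at the last channel and its standard error."""
    v = corrected[:, -1]
    a, b = v[labels == 0], v[labels == 1]
    gap = abs(a.mean() - b.mean())
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    return gap, se
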