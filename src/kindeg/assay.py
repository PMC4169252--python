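"""Cleavage-extent quantification and half-cleavage (E50) estimation.

Extent of hydrolysis is measured as product signal over product-plus-
precursor signal, from either chromatographic peak intensities (peptide
assays, with the product peaks averaged since the two fragments are
equimolar) or densitometric band intensities (autoradiographs of in-vitro
translated substrates). A progression curve — fraction cleaved vs enzyme
concentration over a serial 2-fold dilution series — yields E50, the enzyme
concentration cleaving half the substrate under fixed incubation; ratios of
E50s express relative cleavage efficiency (e.g. a 25-fold higher E50 means a
25-fold less efficient cleavage).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares


@dataclass(frozen=True)
class HydrolysisAssay:
    precursor_signal: float
    product_signals: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.product_signals:
            raise ValueError("need at least one product signal slot")
        if self.precursor_signal < 0 or any(s < 0 for s in self.product_signals):
            raise ValueError("signals must be nonnegative")
        if self.precursor_signal == 0 and all(s == 0 for s in self.product_signals):
            raise ValueError("all signals are zero")


@dataclass(frozen=True)
class ProgressionCurve:
    enzyme_conc: tuple[float, ...]
    fraction_cleaved: tuple[float, ...]

    def __post_init__(self) -> None:
        c, f = self.enzyme_conc, self.fraction_cleaved
        if len(c) != len(f):
            raise ValueError("concentration and fraction series differ in length")
        if any(x <= 0 for x in c):
            raise ValueError("enzyme concentrations must be positive")
        if any(not 0 <= y <= 1 for y in f):
            raise ValueError("fractions must lie in [0, 1]")
        if any(c[i] >= c[i + 1] for i in range(len(c) - 1)):
            raise ValueError("enzyme concentrations must be strictly increasing")


class E50Method(str, enum.Enum):
    INTERPOLATION = "interpolation"
    EXPONENTIAL_FIT = "exponential_fit"


@dataclass(frozen=True)
class E50Fit:
    e50: float
    method: E50Method
    converged: bool


def hydrolysis_extent(assay: HydrolysisAssay) -> float:
    """Fraction cleaved from peak intensities: mean(product) / (mean(product) + precursor)."""
    product = float(np.mean(assay.product_signals))
    return product / (product + assay.precursor_signal)


def densitometry_fraction(cleaved_band: float, precursor_band: float) -> float:
    """Percent cleavage from band densitometry: 100 * cleaved / (cleaved + precursor)."""
    if cleaved_band < 0 or precursor_band < 0:
        raise ValueError("band intensities must be nonnegative")
    if cleaved_band == 0 and precursor_band == 0:
        raise ValueError("both band intensities are zero")
    return 100.0 * cleaved_band / (cleaved_band + precursor_band)


def exponential_fraction(conc: float | np.ndarray, e50: float) -> float | np.ndarray:
    """Saturating single-parameter model f([E]) = 1 - 2^(-[E]/e50); f(e50) = 1/2."""
    return 1.0 - np.exp2(-np.asarray(conc, dtype=float) / e50)


def fit_e50(
    curve: ProgressionCurve,
    method: E50Method | str = E50Method.INTERPOLATION,
) -> E50Fit:
    """Estimate the half-cleavage enzyme concentration from a progression curve.

    ``interpolation`` (default): linear interpolation of fraction against
    log2 concentration between the pair of consecutive points bracketing 0.5
    — assumption-free and matched to serial 2-fold dilution designs; raises
    if the curve never crosses 0.5 (no extrapolation). ``exponential_fit``:
    least squares on f([E]) = 1 - 2^(-[E]/e50); needs >= 3 points.
    """
    method = E50Method(method)
    c = np.asarray(curve.enzyme_conc, dtype=float)
    f = np.asarray(curve.fraction_cleaved, dtype=float)

    if method is E50Method.INTERPOLATION:
        if any(f[i] > f[i + 1] for i in range(len(f) - 1)):
            raise ValueError("fractions must be non-decreasing with enzyme concentration")
        exact = np.nonzero(f == 0.5)[0]
        if exact.size:
            return E50Fit(float(c[exact[0]]), method, True)
        below = np.nonzero(f < 0.5)[0]
        above = np.nonzero(f > 0.5)[0]
        if below.size == 0 or above.size == 0:
            raise ValueError("E50 outside measured range: curve never crosses 0.5")
        i, j = below[-1], above[0]
        lc_i, lc_j = math.log2(c[i]), math.log2(c[j])
        lc50 = lc_i + (0.5 - f[i]) * (lc_j - lc_i) / (f[j] - f[i])
        return E50Fit(2.0**lc50, method, True)

    if len(c) < 3:
        raise ValueError("exponential fit needs >= 3 points")
    # solve in log-space so e50 stays positive
    crude = c[np.argmin(np.abs(f - 0.5))]
    res = least_squares(
        lambda p: exponential_fraction(c, math.exp(p[0])) - f,
        x0=[math.log(crude)],
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return E50Fit(float(math.exp(res.x[0])), method, bool(res.success))


def efficiency_ratio(fit_a: E50Fit, fit_b: E50Fit) -> float:
    """Fold difference in cleavage efficiency: e50_b / e50_a.

    A ratio of 25 means substrate/enzyme pair *a* needs 25-fold less
    protease to reach half cleavage than pair *b*. Swapping the arguments
    gives the reciprocal.
    """
    if fit_a.e50 <= 0 or fit_b.e50 <= 0:
        raise ValueError("e50 values must be positive")
    return fit_b.e50 / fit_a.e50


def dilution_series(
    top: float, n_points: int, fold: float = 2.0
) -> tuple[float, ...]:
    """Ascending serial dilution series ending at ``top`` (e.g. 3.9 nM–1 uM at fold 2)."""
    if top <= 0 or n_points < 1 or fold <= 1:
        raise ValueError("need top > 0, n_points >= 1, fold > 1")
    return tuple(top / fold**k for k in reversed(range(n_points)))
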