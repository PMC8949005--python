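"""Random-matrix-theory selection of the correlation threshold.

The correlation cutoff that separates non-random associations from noise
is chosen by the transition of the eigenvalue nearest-neighbour spacing
distribution (NNSD). A dense correlated-noise matrix has GOE
(Wigner–Dyson) spacing statistics; once the threshold removes the noise,
the surviving matrix decouples into independent blocks and the spacings
follow the Poisson form P(s) = e^{−s}. The scan walks a threshold grid,
unfolds the spectrum of each thresholded matrix with a cubic smoothing
spline of the cumulative spectral density, and chi-square-tests the
spacings against the exponential; the selected threshold t* is the
smallest grid value whose NNSD is consistent with Poisson (p > alpha) and
remains consistent for every larger grid value.

Degenerate scans (too few non-isolated OTUs or too few spacings to test)
are treated as Poisson-consistent: an (almost) diagonal matrix carries no
level repulsion by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .exceptions import NoTransitionError
from .network import AssociationMatrix

logger = logging.getLogger(__name__)

__all__ = ["ThresholdScan", "rmt_threshold", "nnsd_poisson_pvalue",
           "default_grid"]

#: below this many surviving OTUs (or spacings) the NNSD test is
#: meaningless and the matrix is treated as Poisson-degenerate
MIN_SPECTRUM_SIZE = 10


def default_grid(start: float = 0.30, stop: float = 0.99,
                 step: float = 0.01) -> np.ndarray:
    """Threshold grid bracketing typical ecological-network cutoffs."""
    n = int(round((stop - start) / step)) + 1
    return np.round(np.linspace(start, stop, n), 10)


@dataclass
class ThresholdScan:
    """Per-threshold NNSD test results and the selected threshold."""

    scan: pd.DataFrame  # columns: t, n_surviving, n_spacings, chi2, p_value
    selected: float
    alpha: float


def _unfolded_spacings(eigs: np.ndarray) -> np.ndarray:
    """Unfold a spectrum and return nearest-neighbour spacings (mean 1).

    The cumulative spectral density N(λ) = #{eigenvalues ≤ λ} is smoothed
    with a cubic spline; spacings are differences of the smoothed density
    evaluated at consecutive eigenvalues. Non-monotone spline wiggles are
    clipped at zero.
    """
    eigs = np.sort(eigs)
    n = eigs.size
    # collapse exact degeneracies: spline abscissae must strictly increase
    uniq, counts = np.unique(eigs, return_counts=True)
    cum = np.cumsum(counts).astype(float)
    if uniq.size < 4:
        return np.array([])
    # smoothing grows faster than n so the spline tracks the global density
    # shape, not the level fluctuations the NNSD is meant to expose
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        spline = UnivariateSpline(uniq, cum, k=3, s=float(n) ** 1.25)
    unfolded = spline(eigs)
    spacings = np.clip(np.diff(unfolded), 0.0, None)
    mean = spacings.mean()
    if mean <= 0:
        return np.array([])
    return spacings / mean


def nnsd_poisson_pvalue(eigs: np.ndarray) -> tuple[float, float, float, int]:
    """Chi-square fits of the NNSD to the Poisson and GOE spacing forms.

    Returns ``(chi2_poisson, p_poisson, chi2_wigner, n_spacings)``.
    Spacings are binned into ⌈√m⌉ equal-probability bins of the unit
    exponential e^{−s}; the same bins are scored against the Wigner
    surmise (π/2)·s·e^{−πs²/4} for the Poisson-vs-GOE comparison.
    Degenerate spectra return p = 1 (no evidence of level repulsion).
    """
    s = _unfolded_spacings(np.asarray(eigs, dtype=float))
    m = s.size
    if m < MIN_SPECTRUM_SIZE:
        return 0.0, 1.0, np.inf, m
    k = int(np.ceil(np.sqrt(m)))
    k = max(k, 3)
    # equal-probability bin edges of Exp(1); last edge open
    qs = np.arange(1, k) / k
    edges = np.concatenate(([0.0], -np.log1p(-qs), [np.inf]))
    observed, _ = np.histogram(s, bins=edges)
    expected = m / k
    chi2_p = float(((observed - expected) ** 2 / expected).sum())
    p_p = float(stats.chi2.sf(chi2_p, df=k - 1))
    # Wigner CDF 1 − e^{−πs²/4} on the same bins
    cdf_w = 1.0 - np.exp(-np.pi * edges ** 2 / 4.0)
    cdf_w[-1] = 1.0
    exp_w = m * np.diff(cdf_w)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_w = float((((observed - exp_w) ** 2) / exp_w).sum())
    return chi2_p, p_p, chi2_w, m


def _surviving_spectrum(values: np.ndarray, t: float) -> np.ndarray:
    """Eigenvalues of the thresholded matrix over non-isolated rows."""
    a = values.copy()
    mask = np.abs(a) >= t
    np.fill_diagonal(mask, False)
    a[~mask] = 0.0
    keep = mask.any(axis=0)
    if keep.sum() < MIN_SPECTRUM_SIZE:
        return np.array([])
    sub = a[np.ix_(keep, keep)]
    np.fill_diagonal(sub, 1.0)
    return np.linalg.eigvalsh(sub)


def rmt_threshold(matrix: AssociationMatrix,
                  t_grid: np.ndarray | None = None,
                  alpha: float = 0.05) -> ThresholdScan:
    """Scan the threshold grid and select the GOE→Poisson transition.

    Parameters
    ----------
    matrix
        Association matrix over at least 20 OTUs (spacing statistics are
        meaningless below that).
    t_grid
        Strictly increasing candidate thresholds in (0, 1); defaults to
        0.30…0.99 in steps of 0.01.
    alpha
        Significance level of the chi-square Poisson test.

    Raises
    ------
    NoTransitionError
        If no grid value is Poisson-consistent through the end of the grid.
    """
    if matrix.n_otus < 20:
        raise ValueError(
            f"RMT scan needs >= 20 OTUs, got {matrix.n_otus}"
        )
    if t_grid is None:
        t_grid = default_grid()
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0) or t_grid.min() <= 0 or t_grid.max() >= 1:
        raise ValueError("t_grid must be strictly increasing within (0, 1)")
    rows = []
    for t in t_grid:
        eigs = _surviving_spectrum(matrix.values, t)
        if eigs.size == 0:
            rows.append({"t": t, "n_surviving": 0, "n_spacings": 0,
                         "chi2_poisson": 0.0, "p_value": 1.0,
                         "chi2_wigner": np.inf, "poisson_consistent": True})
            continue
        chi2_p, p, chi2_w, m = nnsd_poisson_pvalue(eigs)
        # consistent when the exponential fits acceptably, or at least
        # strictly better than the GOE surmise (Poisson-vs-GOE comparison)
        rows.append({"t": t, "n_surviving": eigs.size, "n_spacings": m,
                     "chi2_poisson": chi2_p, "p_value": p,
                     "chi2_wigner": chi2_w,
                     "poisson_consistent": p > alpha or chi2_p < chi2_w})
    scan = pd.DataFrame(rows)
    ok = scan["poisson_consistent"].to_numpy()
    # smallest t that is Poisson-consistent and stays so for the rest
    consistent_tail = np.logical_and.accumulate(ok[::-1])[::-1]
    if not consistent_tail.any():
        raise NoTransitionError(
            "no threshold on the grid reaches Poisson-consistent NNSD; "
            "widen the grid or check the matrix"
        )
    selected = float(scan["t"].iloc[int(np.argmax(consistent_tail))])
    logger.info("rmt_threshold: selected t* = %.2f (alpha=%.2f)",
                selected, alpha)
    return ThresholdScan(scan, selected, alpha)
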