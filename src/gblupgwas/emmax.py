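"""Frequentist EMMAX association tests derived from a SNP-BLUP fit.

Dividing a SNP-BLUP marker-effect estimate by its frequentist standard
error is numerically identical to fitting that marker as a fixed
regression in a mixed model whose polygenic term absorbs relatedness
(the EMMAX test), so a single SNP-BLUP fit yields the whole genome scan.
The frequentist variance of the estimator is

    Var(a_hat_i) = sigma2_a - Var(a_i | y),

prior minus posterior variance, and t = a_hat_i / sd(a_hat_i) is N(0, 1)
under the null.  For a window of n markers the quadratic form

    x = a_hat_w' (I sigma2_a - Caa_w)^{-1} a_hat_w

is chi-square with n degrees of freedom under the joint null that all n
effects are zero (a Hotelling-type test on correlated estimates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import GenotypePanel, SnpBlupFit

__all__ = [
    "Window",
    "MarkerTest",
    "freq_variance",
    "single_marker_emmax",
    "multi_marker_emmax",
    "scan_emmax",
    "bonferroni_threshold",
    "emmax_results_table",
    "iter_windows",
]

#: relative eigenvalue cutoff below which a window covariance is treated as singular
SINGULARITY_RTOL = 1e-10


@dataclass(frozen=True)
class Window:
    """A run of ``size`` consecutive markers starting at 0-based ``start``."""

    start: int
    size: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("window start must be >= 0")
        if self.size < 1:
            raise ValueError("window size must be >= 1")

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.start + self.size)


@dataclass
class MarkerTest:
    """One EMMAX test: a single marker (df = 1) or a marker window (df = n)."""

    window: Window
    estimates: np.ndarray
    statistic: float
    df: int
    p_value: float
    degenerate: bool = False
    chrom: str | None = None
    start_id: str | None = None
    start_bp: int | None = None

    @property
    def neg_log10_p(self) -> float:
        with np.errstate(divide="ignore"):
            return float(-np.log10(self.p_value))


def freq_variance(fit: SnpBlupFit, idx: int) -> float:
    """Frequentist (sampling) variance of a_hat_idx: sigma2_a - Var(a_idx|y).

    Tiny negative values from round-off are clamped to zero with a warning.
    """
    v = fit.sigma2_a - float(fit.caa([idx])[0, 0])
    if v < 0.0:
        warnings.warn(
            f"negative frequentist variance {v:.3e} at marker {idx} clamped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        v = 0.0
    return v


def single_marker_emmax(fit: SnpBlupFit, idx: int) -> MarkerTest:
    """Normal test t = a_hat / sqrt(sigma2_a - Var(a|y)), two-sided p-value."""
    window = Window(int(idx), 1)
    a = float(fit.a_hat[idx])
    v = freq_variance(fit, idx)
    if v <= 0.0:
        # no frequentist information on this marker (e.g. dropped/monomorphic)
        return MarkerTest(window, np.array([a]), 0.0, 1, 1.0, degenerate=True)
    t = a / np.sqrt(v)
    p = 2.0 * stats.norm.sf(abs(t))
    return MarkerTest(window, np.array([a]), float(t), 1, float(min(p, 1.0)))


def _active_indices(fit: SnpBlupFit, window: Window) -> np.ndarray:
    """Window indices that carry frequentist information (not dropped/degenerate)."""
    idx = window.indices
    if idx[-1] >= fit.n_markers:
        raise IndexError("window extends past the last marker")
    diag = np.diag(fit.caa_matrix)[idx]
    active = ~fit.dropped[idx] & (fit.sigma2_a - diag > 0.0)
    if not np.all(active):
        warnings.warn(
            f"window at {window.start} (size {window.size}): excluding "
            f"{int((~active).sum())} degenerate marker(s) from the quadratic form",
            RuntimeWarning,
            stacklevel=3,
        )
    return idx[active]


def multi_marker_emmax(fit: SnpBlupFit, window: Window) -> MarkerTest:
    """Joint chi-square test of a window of consecutive markers.

    Degenerate (dropped) markers inside the window are excluded and the
    degrees of freedom reduced accordingly; a window with no informative
    marker returns x = 0, p = 1.
    """
    idx = _active_indices(fit, window)
    n = idx.size
    a = fit.a_hat[window.indices]
    if n == 0:
        return MarkerTest(window, a, 0.0, 0, 1.0, degenerate=True)
    if n == 1:
        # exact reduction: chi-square(1) statistic is the squared normal t
        single = single_marker_emmax(fit, int(idx[0]))
        return MarkerTest(
            window, a, single.statistic**2, 1, single.p_value, single.degenerate
        )
    aw = fit.a_hat[idx]
    sigma = fit.sigma2_a * np.eye(n) - fit.caa(idx)
    w, Q = np.linalg.eigh(sigma)
    if w[0] <= SINGULARITY_RTOL * w[-1] or w[-1] <= 0.0:
        raise np.linalg.LinAlgError(
            f"frequentist covariance of window start={window.start}, "
            f"size={window.size} is numerically singular; try a smaller window"
        )
    z = Q.T @ aw
    x = float(np.sum(z * z / w))
    p = float(stats.chi2.sf(x, df=n))
    return MarkerTest(window, a, x, n, max(p, np.finfo(float).tiny))


def iter_windows(chromosome: np.ndarray, size: int, stride: int):
    """Yield global start indices of windows of ``size`` consecutive markers.

    Windows never span a chromosome boundary; chromosomes are taken as runs
    of equal labels in marker order.  A chromosome shorter than ``size``
    emits no windows (with a warning).
    """
    if size < 1 or stride < 1:
        raise ValueError("window size and stride must be >= 1")
    chromosome = np.asarray(chromosome).astype(str)
    boundaries = np.flatnonzero(chromosome[1:] != chromosome[:-1]) + 1
    starts = np.concatenate(([0], boundaries, [chromosome.size]))
    for lo, hi in zip(starts[:-1], starts[1:]):
        if hi - lo < size:
            warnings.warn(
                f"chromosome {chromosome[lo]} has {hi - lo} markers "
                f"(< window size {size}); no windows emitted",
                RuntimeWarning,
                stacklevel=3,
            )
            continue
        yield from range(lo, hi - size + 1, stride)


def _as_map(marker_map) -> pd.DataFrame:
    if isinstance(marker_map, GenotypePanel):
        return marker_map.marker_map
    mp = pd.DataFrame(marker_map)
    missing = {"chrom", "id", "bp"} - set(mp.columns)
    if missing:
        raise ValueError(f"marker map is missing column(s): {sorted(missing)}")
    return mp


def scan_emmax(
    fit: SnpBlupFit,
    marker_map,
    window_size: int = 1,
    stride: int = 1,
) -> list[MarkerTest]:
    """Sliding-window EMMAX scan; window_size = 1 is the single-marker scan."""
    mp = _as_map(marker_map)
    if len(mp) != fit.n_markers:
        raise ValueError("marker map length does not match the fit")
    chrom = mp["chrom"].to_numpy()
    out: list[MarkerTest] = []
    for start in iter_windows(chrom, window_size, stride):
        w = Window(start, window_size)
        test = single_marker_emmax(fit, start) if window_size == 1 else multi_marker_emmax(fit, w)
        test.chrom = str(chrom[start])
        test.start_id = str(mp["id"].iloc[start])
        test.start_bp = int(mp["bp"].iloc[start])
        out.append(test)
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """-log10 of the Bonferroni-corrected per-test rejection level alpha/n."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return float(-np.log10(alpha / n_tests))


def emmax_results_table(tests: list[MarkerTest]) -> pd.DataFrame:
    """Tabulate a scan: one row per window, single markers being size-1 windows."""
    return pd.DataFrame(
        {
            "chrom": [t.chrom for t in tests],
            "window_start_id": [t.start_id for t in tests],
            "window_start_bp": [t.start_bp for t in tests],
            "n_markers": [t.window.size for t in tests],
            "statistic": [t.statistic for t in tests],
            "df": [t.df for t in tests],
            "p_value": [t.p_value for t in tests],
            "neg_log10_p": [t.neg_log10_p for t in tests],
        }
    )
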