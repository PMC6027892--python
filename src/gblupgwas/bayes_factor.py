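"""Closed-form Bayes factors from a SNP-BLUP fit (Savage-Dickey ratios).

Under multivariate normality with known variances, the Bayes factor for
"marker i has an effect" against "a_i = 0" reduces to a ratio of two
normal densities evaluated at zero — prior over posterior:

    BF = N(0 | 0, sigma2_a) / N(0 | a_hat_i, Var(a_i | y)).

This is the Savage-Dickey density ratio: it equals the ratio of marginal
likelihoods of the data with marker i in versus out of the model, but
needs only the SNP-BLUP posterior summaries.  For a window of n markers
the ratio is of multivariate normal densities at the zero vector,

    BF = MVN(0 | 0, I sigma2_a) / MVN(0 | a_hat_w, Caa_w),

testing that all n effects are simultaneously zero against "some of them
are not".  The same algebra with a general prior covariance K0 handles
several traits jointly.  All densities are evaluated in log space: a
posterior tightly concentrated away from zero makes the denominator
underflow in linear space long before the log10 BF is large.

BF < 1 (log10 BF < 0) is meaningful evidence *against* an effect and is
reported as such — nothing is floored at 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .emmax import Window, _as_map, iter_windows
from .model_core import SnpBlupFit

__all__ = [
    "BayesFactorResult",
    "single_marker_bf",
    "multi_marker_bf",
    "multi_trait_bf",
    "scan_bf",
    "bf_results_table",
    "evidence_category",
    "LOG10_BF_DECISIVE_150",
    "LOG10_BF_SUGGESTIVE_3",
]

#: log10 of the conservative detection threshold BF > 150 proposed for QTL scans
LOG10_BF_DECISIVE_150 = math.log10(150.0)
#: log10 of the "suggestive" threshold BF > 3
LOG10_BF_SUGGESTIVE_3 = math.log10(3.0)

_LN10 = math.log(10.0)
_LN_2PI = math.log(2.0 * math.pi)


@dataclass
class BayesFactorResult:
    """log10 Bayes factor for one marker, window or marker-by-trait block."""

    window: Window | None
    log10_bf: float
    evidence_label: str
    n_markers: int = 1
    chrom: str | None = None
    start_id: str | None = None
    start_bp: int | None = None


def evidence_category(log10_bf: float) -> str:
    """Kass-Raftery verbal grading of a log10 Bayes factor."""
    if not np.isfinite(log10_bf):
        raise ValueError("log10 BF must be finite")
    if log10_bf < 0.0:
        return "against"
    if log10_bf < 0.5:
        return "barely worth mentioning"
    if log10_bf < 1.0:
        return "substantial"
    if log10_bf < 1.5:
        return "strong"
    if log10_bf < 2.0:
        return "very strong"
    return "decisive"


def _log10_mvn_at_zero(mean: np.ndarray, cov: np.ndarray, what: str) -> float:
    """log10 MVN(0 | mean, cov) via Cholesky, stable for tiny covariances."""
    n = mean.size
    try:
        L = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"{what}: covariance block is singular") from exc
    half = linalg.solve_triangular(L, mean, lower=True)
    log_det = 2.0 * np.sum(np.log(np.diag(L)))
    ln_pdf = -0.5 * (n * _LN_2PI + log_det + float(half @ half))
    return ln_pdf / _LN10


def single_marker_bf(fit: SnpBlupFit, idx: int) -> BayesFactorResult:
    """Savage-Dickey BF for one marker from its posterior mean and variance."""
    v = float(fit.caa([idx])[0, 0])
    if v <= 0.0:
        raise ValueError(f"marker {idx} has non-positive posterior variance {v}")
    a = np.array([fit.a_hat[idx]], dtype=float)
    log10_prior = _log10_mvn_at_zero(
        np.zeros(1), np.array([[fit.sigma2_a]]), "prior"
    )
    log10_post = _log10_mvn_at_zero(a, np.array([[v]]), f"marker {idx}")
    lbf = log10_prior - log10_post
    return BayesFactorResult(Window(int(idx), 1), lbf, evidence_category(lbf))


def multi_marker_bf(fit: SnpBlupFit, window: Window) -> BayesFactorResult:
    """Joint BF that all markers in the window have zero effect.

    Markers dropped from the fit carry the prior as posterior and zero
    cross-covariance, so they contribute exactly nothing; they are excluded
    from the density ratio (an all-dropped window gives log10 BF = 0).
    """
    idx = window.indices
    if idx[-1] >= fit.n_markers:
        raise IndexError("window extends past the last marker")
    idx = idx[~fit.dropped[idx]]
    n = idx.size
    if n == 0:
        return BayesFactorResult(window, 0.0, evidence_category(0.0), window.size)
    if n == 1:
        # exact reduction to the scalar normal-density ratio
        single = single_marker_bf(fit, int(idx[0]))
        return BayesFactorResult(
            window, single.log10_bf, single.evidence_label, window.size
        )
    aw = fit.a_hat[idx]
    caa = fit.caa(idx)
    log10_prior = _log10_mvn_at_zero(
        np.zeros(n), fit.sigma2_a * np.eye(n), "prior"
    )
    log10_post = _log10_mvn_at_zero(
        aw, caa, f"window start={window.start}, size={window.size}"
    )
    lbf = log10_prior - log10_post
    return BayesFactorResult(window, lbf, evidence_category(lbf), window.size)


def multi_trait_bf(a_hat_block, K0_block, caa_block) -> BayesFactorResult:
    """BF for a stacked block of marker-by-trait effects.

    ``a_hat_block`` stacks the estimates of one or more markers across one
    or more traits; ``K0_block`` is the matching prior covariance (for a
    single trait, I sigma2_a) and ``caa_block`` the joint posterior
    covariance.  With one trait this reduces exactly to the single-trait
    window BF.
    """
    a = np.atleast_1d(np.asarray(a_hat_block, dtype=float)).ravel()
    K0 = np.atleast_2d(np.asarray(K0_block, dtype=float))
    caa = np.atleast_2d(np.asarray(caa_block, dtype=float))
    d = a.size
    if K0.shape != (d, d) or caa.shape != (d, d):
        raise ValueError(
            f"dimension mismatch: a_hat has {d} entries, K0 is {K0.shape}, "
            f"caa is {caa.shape}"
        )
    log10_prior = _log10_mvn_at_zero(np.zeros(d), K0, "prior K0 block")
    log10_post = _log10_mvn_at_zero(a, caa, "posterior block")
    lbf = log10_prior - log10_post
    return BayesFactorResult(None, lbf, evidence_category(lbf), d)


def scan_bf(
    fit: SnpBlupFit,
    marker_map,
    window_size: int = 1,
    stride: int = 1,
) -> list[BayesFactorResult]:
    """Sliding-window BF scan reusing one SNP-BLUP fit for every window."""
    mp = _as_map(marker_map)
    if len(mp) != fit.n_markers:
        raise ValueError("marker map length does not match the fit")
    chrom = mp["chrom"].to_numpy()
    out: list[BayesFactorResult] = []
    for start in iter_windows(chrom, window_size, stride):
        res = multi_marker_bf(fit, Window(start, window_size))
        res.chrom = str(chrom[start])
        res.start_id = str(mp["id"].iloc[start])
        res.start_bp = int(mp["bp"].iloc[start])
        out.append(res)
    return out


def bf_results_table(results: list[BayesFactorResult]) -> pd.DataFrame:
    """Tabulate a BF scan; schema is join-compatible with the EMMAX table."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in results],
            "window_start_id": [r.start_id for r in results],
            "window_start_bp": [r.start_bp for r in results],
            "n_markers": [r.n_markers for r in results],
            "log10_bf": [r.log10_bf for r in results],
            "evidence_label": [r.evidence_label for r in results],
        }
    )
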