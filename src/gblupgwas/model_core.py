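"""SNP-BLUP mixed model with known variance components.

The model is

    y = W b + Z a + e,     a ~ N(0, I sigma2_a),   e ~ N(0, I sigma2_e),

where ``Z`` holds genotype dosages centered by twice the allele frequency
and ``W`` holds the intercept plus any fixed covariates.  With variance
components taken as known, the marker effects ``a`` have a closed-form
posterior N(a_hat, Caa): solving Henderson's mixed-model equations gives
``a_hat`` and the inverse coefficient matrix (times sigma2_e) gives the
posterior covariance Caa.  Everything downstream — EMMAX tests and Bayes
factors — is a function of (a_hat, Caa, sigma2_a) only, so the model is fit
once per data set.

Caa is obtained by exact dense inversion of the coefficient matrix; this
package targets desk-scale panels (up to a few thousand markers), not
biobank-scale data, and exact inversion removes any Monte-Carlo noise from
the posterior covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

__all__ = [
    "GenotypePanel",
    "VarianceComponents",
    "ModelSpec",
    "SnpBlupFit",
    "center_genotypes",
    "fit_snpblup",
    "backsolve_from_gblup",
    "marker_variance_from_h2",
    "read_genotypes_tsv",
    "read_plink_raw",
    "read_map_tsv",
    "read_phenotypes_tsv",
    "join_phenotypes",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenotypePanel:
    """Individuals x markers dosage matrix with its marker map.

    Dosages are allele counts in {0, 1, 2}; missing values are ``nan``.
    Allele frequencies are computed from the non-missing dosages
    (p_j = column mean / 2) and kept consistent with the matrix.
    """

    dosages: np.ndarray
    marker_ids: list[str]
    chromosome: np.ndarray
    position_bp: np.ndarray
    individual_ids: list[str] | None = None
    allele_freq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x markers matrix")
        n, m = self.dosages.shape
        self.marker_ids = list(map(str, self.marker_ids))
        self.chromosome = np.asarray(self.chromosome).astype(str)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        if not (len(self.marker_ids) == len(self.chromosome) == len(self.position_bp) == m):
            raise ValueError("marker map length does not match the number of dosage columns")
        if np.any(self.position_bp < 1):
            raise ValueError("positions are 1-based; position_bp must be >= 1")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
            raise ValueError("dosage entries must be 0, 1, 2 or missing (nan)")
        if self.individual_ids is not None:
            self.individual_ids = list(map(str, self.individual_ids))
            if len(self.individual_ids) != n:
                raise ValueError("individual_ids length does not match dosage rows")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-nan columns
            self.allele_freq = np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def monomorphic(self) -> np.ndarray:
        """Boolean mask of markers with no observed variation (p = 0 or 1)."""
        p = self.allele_freq
        with np.errstate(invalid="ignore"):
            return (p <= 0.0) | (p >= 1.0)

    @property
    def marker_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chromosome, "id": self.marker_ids, "bp": self.position_bp}
        )


@dataclass(frozen=True)
class VarianceComponents:
    """Known variance components of the SNP-BLUP model.

    ``sigma2_a`` is the prior variance of a single marker effect (trait
    units squared), ``sigma2_e`` the residual variance.  For multi-trait
    Bayes factors, ``K0`` is the t x t prior covariance of one marker's
    effects across traits and ``R0`` the residual covariance; both must be
    symmetric positive definite when supplied.
    """

    sigma2_a: float
    sigma2_e: float
    K0: np.ndarray | None = None
    R0: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.sigma2_a > 0.0):
            raise ValueError(f"sigma2_a must be positive, got {self.sigma2_a}")
        if not (self.sigma2_e > 0.0):
            raise ValueError(f"sigma2_e must be positive, got {self.sigma2_e}")
        for name in ("K0", "R0"):
            mat = getattr(self, name)
            if mat is not None:
                mat = np.asarray(mat, dtype=float)
                _require_spd(mat, name)
                object.__setattr__(self, name, mat)

    @property
    def ratio(self) -> float:
        """Shrinkage ratio lambda = sigma2_e / sigma2_a of the ridge system."""
        return self.sigma2_e / self.sigma2_a


@dataclass
class ModelSpec:
    """Construction rules for the fixed-effect design and genotype matrix."""

    covariates: np.ndarray | None = None
    include_intercept: bool = True
    center_genotypes: bool = True
    drop_monomorphic: bool = True
    missing_policy: str = "mean"

    def __post_init__(self) -> None:
        if self.missing_policy != "mean":
            raise ValueError("only mean imputation of missing dosages is supported")
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.ndim != 2:
                raise ValueError("covariates must be a 2-D matrix")

    def fixed_design(self, n: int) -> np.ndarray | None:
        """Return W = [intercept | covariates], or None for a pure random model."""
        cols = []
        if self.include_intercept:
            cols.append(np.ones((n, 1)))
        if self.covariates is not None:
            if self.covariates.shape[0] != n:
                raise ValueError("covariate rows do not match the number of individuals")
            cols.append(self.covariates)
        if not cols:
            return None
        W = np.hstack(cols)
        if np.linalg.matrix_rank(W) < W.shape[1]:
            raise np.linalg.LinAlgError("fixed-effect design W is rank deficient")
        return W


@dataclass
class SnpBlupFit:
    """Solutions and exact posterior covariance of a SNP-BLUP fit.

    ``a_hat`` is indexed by the original marker order.  Markers dropped from
    the fit (monomorphic) carry a_hat = 0 and, by convention, a posterior
    variance equal to the prior ``sigma2_a`` with zero posterior covariance
    with every other marker: an uninformative marker.  That convention makes
    downstream statistics degenerate in the intended way (EMMAX p = 1,
    log10 BF = 0).
    """

    a_hat: np.ndarray
    b_hat: np.ndarray
    sigma2_a: float
    caa_matrix: np.ndarray
    n_individuals: int
    sigma2_e: float | None = None
    dropped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.a_hat = np.asarray(self.a_hat, dtype=float).ravel()
        self.b_hat = np.asarray(self.b_hat, dtype=float).ravel()
        self.caa_matrix = np.asarray(self.caa_matrix, dtype=float)
        m = self.a_hat.size
        if self.caa_matrix.shape != (m, m):
            raise ValueError("caa_matrix must be m x m for m = len(a_hat)")
        if self.dropped is None:
            self.dropped = np.zeros(m, dtype=bool)
        else:
            self.dropped = np.asarray(self.dropped, dtype=bool)
            if self.dropped.size != m:
                raise ValueError("dropped mask length must equal the number of markers")
        if not (self.sigma2_a > 0.0):
            raise ValueError("sigma2_a must be positive")

    @property
    def n_markers(self) -> int:
        return self.a_hat.size

    def caa(self, indices) -> np.ndarray:
        """Posterior covariance block Var(a_S | y) for a marker index set S."""
        idx = np.atleast_1d(np.asarray(indices, dtype=int))
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_markers):
            raise IndexError("marker index out of range")
        return self.caa_matrix[np.ix_(idx, idx)]

    @classmethod
    def from_posterior(
        cls,
        a_hat,
        caa,
        sigma2_a: float,
        *,
        n_individuals: int = 0,
        sigma2_e: float | None = None,
    ) -> "SnpBlupFit":
        """Build a fit object from summary statistics (a_hat, Caa, sigma2_a).

        Useful when the posterior summaries come from an external GBLUP run
        or from a worked example rather than from :func:`fit_snpblup`.
        """
        a_hat = np.atleast_1d(np.asarray(a_hat, dtype=float))
        caa = np.atleast_2d(np.asarray(caa, dtype=float))
        return cls(
            a_hat=a_hat,
            b_hat=np.empty(0),
            sigma2_a=float(sigma2_a),
            caa_matrix=caa,
            n_individuals=n_individuals,
            sigma2_e=sigma2_e,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _require_spd(mat: np.ndarray, name: str) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(mat, mat.T, rtol=0, atol=1e-10 * max(1.0, np.abs(mat).max())):
        raise ValueError(f"{name} must be symmetric")
    try:
        linalg.cholesky(mat, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"{name} must be positive definite") from exc


def center_genotypes(panel: GenotypePanel) -> np.ndarray:
    """Return Z with column j equal to dosage - 2 p_j; missing entries -> 0.

    Mean imputation of a missing dosage to 2p is exactly a zero after
    centering, which is neutral under the linear model.  Raises if any
    marker has no observed dosages at all.
    """
    p = panel.allele_freq
    all_missing = np.isnan(p)
    if np.any(all_missing):
        names = [panel.marker_ids[j] for j in np.flatnonzero(all_missing)]
        raise ValueError(f"all dosages missing for marker(s): {', '.join(names)}")
    Z = panel.dosages - 2.0 * p
    Z[np.isnan(Z)] = 0.0
    return Z


def _design_matrices(panel: GenotypePanel, spec: ModelSpec):
    """Shared construction of (W, Z restricted to kept markers, keep mask)."""
    if spec.center_genotypes:
        Z = center_genotypes(panel)
    else:
        Z = panel.dosages.copy()
        p = panel.allele_freq
        if np.any(np.isnan(p)):
            names = [panel.marker_ids[j] for j in np.flatnonzero(np.isnan(p))]
            raise ValueError(f"all dosages missing for marker(s): {', '.join(names)}")
        miss = np.isnan(Z)
        Z[miss] = (2.0 * p)[np.nonzero(miss)[1]]
    keep = ~panel.monomorphic if spec.drop_monomorphic else np.ones(panel.n_markers, bool)
    W = spec.fixed_design(panel.n_individuals)
    return W, Z[:, keep], keep


def fit_snpblup(
    panel: GenotypePanel,
    phenotypes,
    spec: ModelSpec | None,
    vc: VarianceComponents,
) -> SnpBlupFit:
    """Solve the mixed-model equations and return solutions plus exact Caa.

    The coefficient matrix is ``[[W'W, W'Z], [Z'W, Z'Z + I lambda]]`` with
    lambda = sigma2_e / sigma2_a and right-hand side ``[W'y, Z'y]``.  The
    posterior covariance of the marker effects is the marker block of the
    inverse coefficient matrix times sigma2_e.
    """
    if spec is None:
        spec = ModelSpec()
    y = np.asarray(phenotypes, dtype=float).ravel()
    if y.size != panel.n_individuals:
        raise ValueError(
            f"phenotype length {y.size} != number of individuals {panel.n_individuals}"
        )
    W, Zk, keep = _design_matrices(panel, spec)
    mk = Zk.shape[1]
    k = 0 if W is None else W.shape[1]
    lam = vc.ratio

    C = np.empty((k + mk, k + mk))
    rhs = np.empty(k + mk)
    if W is not None:
        C[:k, :k] = W.T @ W
        C[:k, k:] = W.T @ Zk
        C[k:, :k] = C[:k, k:].T
        rhs[:k] = W.T @ y
    C[k:, k:] = Zk.T @ Zk + lam * np.eye(mk)
    rhs[k:] = Zk.T @ y

    try:
        cf = linalg.cho_factor(C, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "mixed-model coefficient matrix is singular (rank-deficient "
            "fixed-effect block?)"
        ) from exc
    sol = linalg.cho_solve(cf, rhs)
    Cinv = linalg.cho_solve(cf, np.eye(k + mk))

    m = panel.n_markers
    a_hat = np.zeros(m)
    a_hat[keep] = sol[k:]
    # dropped markers: uninformative posterior = prior, no cross-covariance
    caa = np.zeros((m, m))
    caa[np.ix_(keep, keep)] = Cinv[k:, k:] * vc.sigma2_e
    drop_idx = np.flatnonzero(~keep)
    caa[drop_idx, drop_idx] = vc.sigma2_a

    return SnpBlupFit(
        a_hat=a_hat,
        b_hat=sol[:k],
        sigma2_a=vc.sigma2_a,
        caa_matrix=caa,
        n_individuals=panel.n_individuals,
        sigma2_e=vc.sigma2_e,
        dropped=~keep,
    )


def backsolve_from_gblup(
    gblup_breeding_values,
    panel: GenotypePanel,
    vc: VarianceComponents,
) -> np.ndarray:
    """Recover marker effects a_hat = sigma2_a Z' G^{-1} u from GBLUP output.

    ``G = Z Z' sigma2_a`` is the (unscaled) genomic covariance of breeding
    values ``u = Z a``.  Because Z is column-centered, G always has the
    vector of ones in its null space, so the system is solved by least
    squares (minimum-norm); that is exact whenever ``u`` lies in the range
    of G, which any genuine vector of genomic breeding values u = Z a does.
    Breeding values outside the range of G (a rank-deficient panel and an
    inconsistent u) raise.
    """
    u = np.asarray(gblup_breeding_values, dtype=float).ravel()
    if u.size != panel.n_individuals:
        raise ValueError("breeding-value vector length != number of individuals")
    Z = center_genotypes(panel)
    G = (Z @ Z.T) * vc.sigma2_a
    x, _, _, _ = np.linalg.lstsq(G, u, rcond=None)
    if np.linalg.norm(G @ x - u) > 1e-8 * max(np.linalg.norm(u), 1.0):
        raise np.linalg.LinAlgError(
            "breeding values are not in the range of ZZ'sigma2_a (G is rank "
            "deficient for this panel); blending/regularization of G is out "
            "of scope"
        )
    return vc.sigma2_a * (Z.T @ x)


def marker_variance_from_h2(
    h2: float,
    phenotypic_variance: float,
    allele_freqs,
) -> VarianceComponents:
    """Convert heritability to per-marker and residual variances.

    sigma2_u = h2 * Vp is the total additive-genetic variance; spreading it
    over the markers gives sigma2_a = sigma2_u / (2 sum p_j (1 - p_j)), the
    standard conversion used to turn a prior estimate of genetic variance
    into the SNP-BLUP marker-effect variance.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError(f"h2 must be in (0, 1), got {h2}")
    if not (phenotypic_variance > 0.0):
        raise ValueError("phenotypic variance must be positive")
    p = np.asarray(allele_freqs, dtype=float)
    het = 2.0 * np.sum(p * (1.0 - p))
    if het <= 0.0:
        raise ValueError("all markers are monomorphic: sum 2p(1-p) = 0")
    sigma2_u = h2 * phenotypic_variance
    return VarianceComponents(
        sigma2_a=sigma2_u / het,
        sigma2_e=(1.0 - h2) * phenotypic_variance,
    )


# ---------------------------------------------------------------------------
# File input: genotype, map and phenotype tables
# ---------------------------------------------------------------------------

def read_map_tsv(path) -> pd.DataFrame:
    """Read a marker map TSV with columns chrom, id, bp (1-based positions)."""
    mp = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str}, comment="#")
    missing = {"chrom", "id", "bp"} - set(mp.columns)
    if missing:
        raise ValueError(f"marker map is missing column(s): {sorted(missing)}")
    return mp


def _panel_from_frame(geno: pd.DataFrame, map_path=None) -> GenotypePanel:
    ids = geno.index.astype(str).tolist()
    marker_ids = [str(c) for c in geno.columns]
    if map_path is not None:
        mp = read_map_tsv(map_path).set_index("id")
        absent = [m for m in marker_ids if m not in mp.index]
        if absent:
            raise ValueError(f"markers missing from map: {absent[:10]}")
        mp = mp.loc[marker_ids]
        chrom = mp["chrom"].to_numpy()
        bp = mp["bp"].to_numpy()
    else:
        chrom = np.repeat("1", len(marker_ids))
        bp = np.arange(1, len(marker_ids) + 1)
    return GenotypePanel(
        dosages=geno.to_numpy(dtype=float),
        marker_ids=marker_ids,
        chromosome=chrom,
        position_bp=bp,
        individual_ids=ids,
    )


def read_genotypes_tsv(path, map_path=None) -> GenotypePanel:
    """Read a plain genotype TSV: id column, then one 0/1/2/NA column per marker."""
    geno = pd.read_csv(path, sep="\t", comment="#")
    geno = geno.set_index(geno.columns[0])
    return _panel_from_frame(geno, map_path)


def read_plink_raw(path, map_path=None) -> GenotypePanel:
    """Read a PLINK .raw additive-dosage file (header FID IID PAT MAT SEX PHENOTYPE).

    Marker columns are named ``<id>_<counted allele>``; the allele suffix is
    stripped.  Individual id is IID.  A chrom/id/bp map TSV supplies positions.
    """
    raw = pd.read_csv(path, sep=r"\s+", comment="#")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    missing = [c for c in meta if c not in raw.columns]
    if missing:
        raise ValueError(f"not a PLINK .raw file, missing column(s): {missing}")
    geno = raw.drop(columns=meta[:1] + meta[2:]).set_index("IID")
    geno.columns = [c.rsplit("_", 1)[0] for c in geno.columns]
    return _panel_from_frame(geno, map_path)


def read_phenotypes_tsv(path) -> pd.DataFrame:
    """Read a phenotype/covariate TSV; the first column is the individual id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.set_index(df.columns[0])


def join_phenotypes(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    trait: str,
    covariates: tuple[str, ...] = (),
):
    """Align a phenotype table to the panel's individuals by id.

    Returns (y, covariate matrix or None) in panel row order.  The join is
    order-independent; ids present on one side only raise with the offending
    ids listed.
    """
    if panel.individual_ids is None:
        raise ValueError("genotype panel carries no individual ids to join on")
    pheno = pheno.copy()
    pheno.index = pheno.index.astype(str)
    gset, pset = set(panel.individual_ids), set(pheno.index)
    only_g = sorted(gset - pset)
    if only_g:
        raise ValueError(f"ids genotyped but not phenotyped: {only_g[:20]}")
    aligned = pheno.loc[panel.individual_ids]
    if trait not in aligned.columns:
        raise ValueError(f"trait column {trait!r} not in phenotype table")
    y = aligned[trait].to_numpy(dtype=float)
    X = aligned[list(covariates)].to_numpy(dtype=float) if covariates else None
    return y, X
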