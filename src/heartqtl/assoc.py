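"""Mixed-model association of recombination blocks with heart-rate phenotypes.

The scan fits a single-variance-component linear mixed model

    y = mu + u + e,   u ~ N(0, sg^2 K),   e ~ N(0, se^2 I)

in the EMMA/EMMAX style: K is eigendecomposed once, the heritability ratio
h^2 = sg^2/(sg^2+se^2) is estimated by restricted maximum likelihood on a
grid with local refinement, and every block's additive dosage term is then
tested by generalized least squares under the fitted covariance (variance
components held fixed across blocks). Genome-wide significance thresholds at
1% and 5% FDR come from phenotype permutations: the empirical FDR at a
candidate p cutoff is the mean number of permuted-scan discoveries divided
by the observed discovery count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .blocks import GenotypeMatrix
from .errors import DegenerateInputError, InvalidSpecError
from .simulate import TEMPERATURES

_TINY_P = 1e-300


def variance_phenotype(
    table: pd.DataFrame, mode: str = "mean_abs_pairwise"
) -> pd.Series:
    """Dispersion of the repeated heart-rate measurements per individual.

    Default is the mean absolute pairwise difference of the three
    temperature measurements, (|x21-x28| + |x21-x35| + |x28-x35|) / 3;
    ``range`` and ``variance`` are available alternatives. Individuals with
    any missing measurement are excluded.
    """
    cols = list(TEMPERATURES)
    complete = table.dropna(subset=cols)
    x = complete[cols].to_numpy(dtype=float)
    if mode == "mean_abs_pairwise":
        v = (
            np.abs(x[:, 0] - x[:, 1])
            + np.abs(x[:, 0] - x[:, 2])
            + np.abs(x[:, 1] - x[:, 2])
        ) / 3.0
    elif mode == "range":
        v = x.max(axis=1) - x.min(axis=1)
    elif mode == "variance":
        v = x.var(axis=1, ddof=1)
    else:
        raise InvalidSpecError(f"unknown variance-phenotype mode: {mode}")
    return pd.Series(v, index=complete["sample"].to_numpy(), name="variance")


def estimate_kinship(matrix: GenotypeMatrix) -> np.ndarray:
    """Realized relatedness K = Z Z^T / m from column-standardized dosages.

    Monomorphic (zero-variance) blocks carry no relatedness information and
    are skipped.
    """
    if matrix.n < 2 or matrix.n_blocks < 1:
        raise InvalidSpecError("need >= 2 individuals and >= 1 block")
    z = matrix.dosage.T.astype(float)  # (n, m)
    sd = z.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise DegenerateInputError("all blocks are monomorphic")
    z = (z[:, keep] - z[:, keep].mean(axis=0)) / sd[keep]
    k = z @ z.T / keep.sum()
    return (k + k.T) / 2.0


@dataclass
class NullModelFit:
    """REML fit of the no-marker mixed model, reused across the scan."""

    h2: float
    loglik: float
    eigvals: np.ndarray
    eigvecs: np.ndarray
    n: int

    def whitening_weights(self) -> np.ndarray:
        d = self.h2 * self.eigvals + (1.0 - self.h2)
        return 1.0 / np.sqrt(np.maximum(d, 1e-12))


def _reml_loglik(h2: float, y_star: np.ndarray, x_star: np.ndarray,
                 s: np.ndarray) -> float:
    n, p = x_star.shape
    d = h2 * s + (1.0 - h2)
    d = np.maximum(d, 1e-12)
    w = 1.0 / np.sqrt(d)
    yw = y_star * w
    xw = x_star * w[:, None]
    xtx = xw.T @ xw
    beta = np.linalg.solve(xtx, xw.T @ yw)
    rss = float(((yw - xw @ beta) ** 2).sum())
    sigma2 = rss / (n - p)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    return -0.5 * ((n - p) * np.log(sigma2) + np.log(d).sum() + logdet_xtx)


def fit_null_model(
    y: np.ndarray, kinship: np.ndarray, grid_points: int = 100
) -> NullModelFit:
    """Estimate h^2 by REML: coarse grid over [0, 0.99] plus local refinement."""
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise InvalidSpecError("phenotype contains non-finite values")
    n = len(y)
    s, u = np.linalg.eigh(kinship)
    s = np.maximum(s, 0.0)
    y_star = u.T @ y
    x_star = u.T @ np.ones((n, 1))
    grid = np.linspace(0.0, 0.99, grid_points)
    ll = np.array([_reml_loglik(h, y_star, x_star, s) for h in grid])
    best = int(ll.argmax())
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda h: -_reml_loglik(h, y_star, x_star, s),
            bounds=(lo, hi),
            method="bounded",
        )
        h2, loglik = float(res.x), float(-res.fun)
        if loglik < ll[best]:
            h2, loglik = float(grid[best]), float(ll[best])
    else:
        h2, loglik = float(grid[best]), float(ll[best])
    return NullModelFit(h2=h2, loglik=loglik, eigvals=s, eigvecs=u, n=n)


def _gls_block_tests(
    gw: np.ndarray, x0w: np.ndarray, yw: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-block slope, SE and p for whitened genotypes (n, B) vs phenotype(s).

    ``yw`` may be (n,) for the observed scan or (n, P) for permutations; in
    the latter case only the p-values are returned (beta/se arrays are 2-D).
    """
    a00 = float(x0w @ x0w)
    a01 = gw.T @ x0w                      # (B,)
    a11 = (gw * gw).sum(axis=0)           # (B,)
    det = a00 * a11 - a01**2
    ok = det > 1e-12 * max(a00, 1.0)
    det_safe = np.where(ok, det, 1.0)
    y2 = yw if yw.ndim == 2 else yw[:, None]
    a0y = x0w @ y2                        # (P,)
    a1y = gw.T @ y2                       # (B, P)
    syy = (y2 * y2).sum(axis=0)           # (P,)
    beta1 = (a00 * a1y - a01[:, None] * a0y[None, :]) / det_safe[:, None]
    beta0 = (a11[:, None] * a0y[None, :] - a01[:, None] * a1y) / det_safe[:, None]
    rss = syy[None, :] - beta0 * a0y[None, :] - beta1 * a1y
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / (n - 2)
    var_b1 = sigma2 * (a00 / det_safe[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta1 / np.sqrt(var_b1)
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.clip(p, _TINY_P, 1.0)
    p[~ok, :] = 1.0
    beta1[~ok, :] = 0.0
    se = np.sqrt(var_b1)
    se[~ok, :] = np.nan
    if yw.ndim == 1:
        return beta1[:, 0], se[:, 0], p[:, 0]
    return beta1, se, p


@dataclass
class AssociationScan:
    """Per-block association results for one phenotype."""

    table: pd.DataFrame  # block_id, chrom, start, end, phenotype, beta, se, p, neg_log10_p
    phenotype: str
    h2: float
    n: int


def lmm_scan(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    kinship: np.ndarray,
    phenotype_name: str = "phenotype",
    null_fit: NullModelFit | None = None,
) -> AssociationScan:
    """Score every block by GLS under the REML-fitted polygenic covariance."""
    y = np.asarray(phenotype, dtype=float)
    if len(y) != matrix.n:
        raise InvalidSpecError("phenotype length does not match cohort size")
    if not np.isfinite(y).all():
        raise InvalidSpecError("phenotype contains non-finite values")
    fit = null_fit or fit_null_model(y, kinship)
    w = fit.whitening_weights()
    ut = fit.eigvecs.T
    yw = (ut @ y) * w
    x0w = (ut @ np.ones(matrix.n)) * w
    gw = (ut @ matrix.dosage.T.astype(float)) * w[:, None]
    beta, se, p = _gls_block_tests(gw, x0w, yw, matrix.n)
    table = matrix.block_table.copy()
    table["phenotype"] = phenotype_name
    table["beta"] = beta
    table["se"] = se
    table["p"] = p
    table["neg_log10_p"] = -np.log10(p)
    return AssociationScan(table=table, phenotype=phenotype_name, h2=fit.h2, n=matrix.n)


@dataclass
class FdrThresholds:
    """Permutation-FDR significance thresholds on the -log10 p scale."""

    phenotype: str
    thresholds: dict[float, float]
    n_perm: int
    seed: int

    def passes(self, neg_log10_p: np.ndarray, level: float = 0.05) -> np.ndarray:
        return np.asarray(neg_log10_p) >= self.thresholds[level]


def permutation_thresholds(
    matrix: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    kinship: np.ndarray,
    n_perm: int = 100,
    levels: tuple[float, ...] = (0.01, 0.05),
    seed: int = 0,
    phenotype_name: str = "phenotype",
    null_fit: NullModelFit | None = None,
    observed: AssociationScan | None = None,
) -> FdrThresholds:
    """Empirical-FDR thresholds from phenotype permutations.

    The phenotype vector is permuted across individuals ``n_perm`` times with
    the variance components of the unpermuted null fit reused. For a
    candidate cutoff t, FDR(t) = (mean permuted discoveries at t) /
    max(1, observed discoveries at t); the reported threshold per level is
    the most permissive observed p with FDR <= level. When no cutoff
    qualifies the threshold is set strictly above every observed statistic.
    """
    if n_perm < 1:
        raise InvalidSpecError("n_perm must be >= 1")
    y = np.asarray(phenotype, dtype=float)
    fit = null_fit or fit_null_model(y, kinship)
    obs = observed or lmm_scan(
        matrix, y, kinship, phenotype_name=phenotype_name, null_fit=fit
    )
    rng = np.random.default_rng(seed)
    perm_y = np.stack([y[rng.permutation(len(y))] for _ in range(n_perm)], axis=1)
    w = fit.whitening_weights()
    ut = fit.eigvecs.T
    yw = (ut @ perm_y) * w[:, None]
    x0w = (ut @ np.ones(matrix.n)) * w
    gw = (ut @ matrix.dosage.T.astype(float)) * w[:, None]
    _, _, perm_p = _gls_block_tests(gw, x0w, yw, matrix.n)
    p_obs = np.sort(obs.table["p"].to_numpy())
    perm_sorted = np.sort(perm_p.ravel())
    obs_count = np.arange(1, len(p_obs) + 1)
    perm_count = np.searchsorted(perm_sorted, p_obs, side="right") / n_perm
    fdr = perm_count / np.maximum(obs_count, 1)
    thresholds: dict[float, float] = {}
    fallback = float(-np.log10(p_obs[0])) + 1.0 if len(p_obs) else np.inf
    for level in levels:
        qualifying = np.nonzero(fdr <= level)[0]
        if len(qualifying):
            thresholds[level] = float(-np.log10(p_obs[qualifying[-1]]))
        else:
            thresholds[level] = fallback
    return FdrThresholds(
        phenotype=phenotype_name, thresholds=thresholds, n_perm=n_perm, seed=seed
    )


def scan_all_phenotypes(
    matrix: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    kinship: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
    levels: tuple[float, ...] = (0.01, 0.05),
    phenotype_names: tuple[str, ...] = (*TEMPERATURES, "variance"),
) -> tuple[pd.DataFrame, dict[str, FdrThresholds], dict[str, float]]:
    """Scan heart rate at each temperature plus the variance phenotype.

    Returns the stacked scan table, per-phenotype FDR thresholds and the
    per-phenotype REML heritability estimates. Phenotype rows must align
    with the genotype-matrix sample order.
    """
    if list(phenotypes["sample"]) != list(matrix.samples):
        phenotypes = (
            phenotypes.set_index("sample").loc[matrix.samples].reset_index()
        )
    values = {name: phenotypes[name].to_numpy(float) for name in TEMPERATURES
              if name in phenotype_names}
    if "variance" in phenotype_names:
        values["variance"] = variance_phenotype(phenotypes).to_numpy()
    scans, thresholds, h2 = [], {}, {}
    for k, (name, y) in enumerate(values.items()):
        fit = fit_null_model(y, kinship)
        scan = lmm_scan(matrix, y, kinship, phenotype_name=name, null_fit=fit)
        thr = permutation_thresholds(
            matrix, y, kinship, n_perm=n_perm, levels=levels,
            seed=seed + k, phenotype_name=name, null_fit=fit, observed=scan,
        )
        scans.append(scan.table)
        thresholds[name] = thr
        h2[name] = scan.h2
    return pd.concat(scans, ignore_index=True), thresholds, h2
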