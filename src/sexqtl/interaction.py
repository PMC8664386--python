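"""Sex x genotype interaction scan (ΔLOD) with matched permutations.

Two nested linear models are fit at every locus of a cohort of outbred
animals:

* additive model: phenotype ~ covariates + sex + genotype
* interaction model: additive terms + genotype x sex

Each model's LOD is measured against the covariates-only null using the
residual-sum-of-squares form ``LOD = (n/2) * log10(RSS_null / RSS_alt)``.
ΔLOD = LOD(interaction) - LOD(additive) estimates how differently the
locus acts in the two sexes; it is non-negative because the models nest.

The significance threshold is empirical: genotype rows are permuted (the
same shuffle feeding both models, so the two LOD columns stay matched),
the genome-wide maximum ΔLOD is recorded per permutation, and the
(1 - alpha) quantile of those maxima is the genome-wide threshold.  Loci
whose observed ΔLOD reaches the threshold are flagged robust.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class Cohort:
    """Design matrices for one cohort.

    ``covariates`` excludes the intercept and sex; both are added
    internally.  ``sex`` is coded 0/1.
    """

    phenotype: np.ndarray          # (n,)
    sex: np.ndarray                # (n,) in {0,1}
    genotypes: np.ndarray          # (n, n_loci) dosages
    covariates: np.ndarray         # (n, k)
    locus_names: Sequence[str] = ()

    def __post_init__(self) -> None:
        n = self.phenotype.shape[0]
        if self.genotypes.ndim == 1:
            self.genotypes = self.genotypes[:, None]
        if self.covariates.ndim == 1:
            self.covariates = self.covariates[:, None]
        if not (self.sex.shape[0] == n == self.genotypes.shape[0]
                == self.covariates.shape[0]):
            raise ValueError("cohort arrays must share the sample dimension")
        if not self.locus_names:
            self.locus_names = [f"locus_{i}" for i in range(self.genotypes.shape[1])]

    @property
    def n(self) -> int:
        return self.phenotype.shape[0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, phenotype: str = "phenotype",
                   sex: str = "sex",
                   covariate_cols: Sequence[str] = (),
                   locus_prefix: str = "locus_") -> "Cohort":
        locus_cols = [c for c in df.columns if c.startswith(locus_prefix)]
        sex_vals = df[sex]
        if sex_vals.dtype == object:
            sex_vals = sex_vals.map({"F": 0, "female": 0, "M": 1, "male": 1})
        return cls(
            phenotype=df[phenotype].to_numpy(float),
            sex=sex_vals.to_numpy(float),
            genotypes=df[locus_cols].to_numpy(float),
            covariates=df[list(covariate_cols)].to_numpy(float)
            if covariate_cols else np.empty((len(df), 0)),
            locus_names=locus_cols,
        )


def lod_from_fit(rss_null: float, rss_alt: float, n: int) -> float:
    """Linear-model LOD: ``(n/2) * log10(rss_null / rss_alt)``."""
    if rss_null <= 0 or rss_alt <= 0:
        raise ValueError("RSS values must be positive")
    return (n / 2.0) * np.log10(rss_null / rss_alt)


def _base_design(cohort: Cohort) -> np.ndarray:
    X = np.column_stack([np.ones(cohort.n), cohort.sex, cohort.covariates])
    names = ["intercept", "sex"] + [f"covariate_{i}"
                                    for i in range(cohort.covariates.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient covariate design; collinear: {bad}")
    return X


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    bad, kept = [], np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept = cand
        else:
            bad.append(names[j])
    return bad


def _residualizer(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis Q of col(X); residualize v as v - Q (Q^T v)."""
    q, _ = np.linalg.qr(X)
    return q


def _scan_residualized(y_res: np.ndarray, g_res: np.ndarray,
                       gs_res: np.ndarray, n: int) -> pd.DataFrame:
    """ΔLOD per locus from covariate-residualized responses.

    Columns of ``g_res`` / ``gs_res`` are the residualized genotype and
    genotype-x-sex vectors; fits reduce to 1- and 2-predictor least
    squares in the residual space.
    """
    rss0 = float(y_res @ y_res)
    gy = g_res.T @ y_res                       # (L,)
    gg = np.einsum("ij,ij->j", g_res, g_res)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss_add = rss0 - np.where(gg > 0, gy ** 2 / np.where(gg > 0, gg, 1), 0.0)

    sy = gs_res.T @ y_res
    ss = np.einsum("ij,ij->j", gs_res, gs_res)
    gs = np.einsum("ij,ij->j", g_res, gs_res)
    det = gg * ss - gs ** 2
    ok = det > 1e-12 * np.maximum(gg * ss, 1e-300)
    b_g = np.where(ok, (ss * gy - gs * sy) / np.where(ok, det, 1), 0.0)
    b_s = np.where(ok, (gg * sy - gs * gy) / np.where(ok, det, 1), 0.0)
    explained = np.where(ok, b_g * gy + b_s * sy,
                         np.where(gg > 0, gy ** 2 / np.where(gg > 0, gg, 1), 0.0))
    rss_int = rss0 - explained

    rss_add = np.maximum(rss_add, 1e-300)
    rss_int = np.maximum(rss_int, 1e-300)
    lod_add = (n / 2.0) * np.log10(rss0 / rss_add)
    lod_int = (n / 2.0) * np.log10(rss0 / rss_int)
    return pd.DataFrame({"lod_additive": lod_add, "lod_interaction": lod_int,
                         "delta_lod": lod_int - lod_add})


def delta_lod_scan(cohort: Cohort) -> pd.DataFrame:
    """Per-locus additive LOD, interaction LOD and ΔLOD."""
    X = _base_design(cohort)
    q = _residualizer(X)

    def res(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    y_res = res(cohort.phenotype)
    g_res = res(cohort.genotypes)
    gs_res = res(cohort.genotypes * cohort.sex[:, None])
    out = _scan_residualized(y_res, g_res, gs_res, cohort.n)
    out.insert(0, "locus", list(cohort.locus_names))
    return out


@dataclass
class PermutationResult:
    threshold: float
    null_maxima: np.ndarray
    n_perm: int
    alpha: float
    seed: int
    scan: pd.DataFrame          # observed scan with a 'robust' column


def permutation_threshold(cohort: Cohort, n_perm: int = 1000,
                          alpha: float = 0.05,
                          seed: int = 0) -> PermutationResult:
    """Genome-wide ΔLOD threshold from matched genotype permutations.

    One row permutation per iteration is applied to the genotype matrix
    and feeds both nested models, so their LODs stay matched.  The
    threshold is the empirical (1 - alpha) quantile (linear
    interpolation) of the per-permutation maximum ΔLOD.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} < 100: unstable quantile estimate",
                      stacklevel=2)
    X = _base_design(cohort)
    q = _residualizer(X)

    def res(v: np.ndarray) -> np.ndarray:
        return v - q @ (q.T @ v)

    y_res = res(cohort.phenotype)
    observed = delta_lod_scan(cohort)

    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(cohort.n)
        g_perm = cohort.genotypes[perm]
        g_res = res(g_perm)
        gs_res = res(g_perm * cohort.sex[:, None])
        null = _scan_residualized(y_res, g_res, gs_res, cohort.n)
        maxima[p] = null["delta_lod"].max()

    threshold = float(np.quantile(maxima, 1.0 - alpha, method="linear"))
    scan = observed.copy()
    scan["robust"] = scan["delta_lod"] >= threshold
    return PermutationResult(threshold=threshold, null_maxima=maxima,
                             n_perm=n_perm, alpha=alpha, seed=seed, scan=scan)
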