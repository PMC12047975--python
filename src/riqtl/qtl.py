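"""Single-marker genome scans for inbred strain panels.

Implements least-squares (Haley-Knott) marker regression reporting the
likelihood-ratio statistic LRS = n*ln(RSS0/RSS1), permutation-based
genome-wide thresholds, an EMMA-style mixed-model scan with a kinship
matrix, and LOD-drop support intervals.

Scans run at genotyped markers only. The regression kernel is vectorized
over (permutations x markers) with per-marker complete-case handling of
missing genotype calls, so 10^4-10^6 permutations reduce to a few matrix
products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix

__all__ = [
    "LOD_SCALE",
    "QtlScanResult",
    "SupportInterval",
    "hk_scan",
    "permutation_threshold",
    "lmm_scan",
    "support_interval",
]

# LRS = 2*ln(10) * LOD = 4.605... * LOD; a 2-LOD drop is a 9.21-LRS drop
LOD_SCALE = 2.0 * np.log(10.0)

_TINY = 1e-300


@dataclass
class QtlScanResult:
    """Per-marker association table plus thresholds and peak bookkeeping.

    ``table`` columns: marker, chromosome, position_mb, n, lrs, lod,
    neg_log10_p, flag.
    """

    table: pd.DataFrame
    method: str
    trait: str = ""
    thresholds: dict[float, float] = field(default_factory=dict)

    def peak(self, chromosome: str | None = None) -> pd.Series:
        t = self.table if chromosome is None else self.table[
            self.table["chromosome"] == chromosome
        ]
        if t.empty:
            raise ValueError(f"no markers on chromosome {chromosome!r}")
        return t.loc[t["lod"].idxmax()]

    def significant(self, threshold: float) -> pd.DataFrame:
        return self.table[self.table["lrs"] >= threshold]


@dataclass(frozen=True)
class SupportInterval:
    """LOD-drop support interval around a scan peak."""

    chromosome: str
    start_mb: float
    end_mb: float
    peak_mb: float
    peak_lod: float
    drop: float
    one_sided: bool = False

    def __post_init__(self) -> None:
        if not self.start_mb <= self.peak_mb <= self.end_mb:
            raise ValueError("peak must lie inside the interval")

    def contains(self, position_mb: float) -> bool:
        return self.start_mb <= position_mb <= self.end_mb

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "start_mb": self.start_mb,
            "end_mb": self.end_mb,
            "peak_mb": self.peak_mb,
            "peak_lod": self.peak_lod,
            "drop": self.drop,
            "one_sided": self.one_sided,
        }


def _align(genotypes: GenotypeMatrix, trait: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Restrict to strains having both a genotype row and a trait value."""
    trait = trait.dropna()
    shared = [s for s in genotypes.strains if s in trait.index]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} strains shared between genotypes and trait")
    idx = [genotypes.strains.index(s) for s in shared]
    return genotypes.dosages[idx], trait.loc[shared].to_numpy(float)


def _marker_moments(X: np.ndarray):
    """Precompute per-marker masked moments of the genotype matrix."""
    mask = ~np.isnan(X)
    X0 = np.where(mask, X, 0.0)
    n = mask.sum(axis=0).astype(float)
    sx = X0.sum(axis=0)
    sxx = (X0 * X0).sum(axis=0)
    return mask, X0, n, sx, sxx


def _lrs_matrix(Y: np.ndarray, mask, X0, n, sx, sxx):
    """LRS for every (row of Y) x marker pair under complete-case OLS.

    Y is (n_perm x n_strains); returns (lrs, rss0, rss1, n) arrays of shape
    (n_perm x n_markers). Monomorphic markers get LRS 0.
    """
    sy = Y @ mask
    syy = (Y * Y) @ mask
    sxy = Y @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        syy_c = syy - sy * sy / n
        sxx_c = sxx - sx * sx / n
        sxy_c = sxy - sx * sy / n
        rss0 = syy_c
        explained = np.where(sxx_c > 0, sxy_c**2 / np.where(sxx_c > 0, sxx_c, 1.0), 0.0)
        rss1 = np.maximum(rss0 - explained, 0.0)
        ratio = np.where(rss0 > 0, rss0 / np.maximum(rss1, _TINY), 1.0)
        lrs = n * np.log(ratio)
    return lrs, rss0, rss1, np.broadcast_to(n, lrs.shape)


def hk_scan(genotypes: GenotypeMatrix, trait: pd.Series, trait_name: str = "") -> QtlScanResult:
    """Haley-Knott single-marker regression scan.

    Per marker, the strain trait is regressed on the genotype dosage
    (0 / 0.5 / 1; unknown calls dropped marker-wise) and
    ``LRS = n * ln(RSS0 / RSS1)`` compares against the intercept-only
    model. LOD = LRS / (2 ln 10); p-values are from the exact F(1, n-2)
    test of the marker coefficient.
    """
    X, y = _align(genotypes, trait)
    mask, X0, n, sx, sxx = _marker_moments(X)
    lrs, rss0, rss1, n_used = _lrs_matrix(y[None, :], mask, X0, n, sx, sxx)
    lrs, rss0, rss1, n_used = lrs[0], rss0[0], rss1[0], n_used[0]

    sxx_c = sxx - sx * sx / n
    mono = sxx_c <= 1e-12
    perfect = (rss1 <= 1e-12 * np.maximum(rss0, 1.0)) & ~mono & (rss0 > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        df2 = n_used - 2.0
        fstat = np.where(rss1 > 0, (rss0 - rss1) * df2 / np.maximum(rss1, _TINY), np.inf)
        pval = stats.f.sf(fstat, 1.0, df2)
    pval = np.where(mono | (rss0 <= 0), 1.0, pval)
    lrs = np.where(mono, 0.0, lrs)
    lrs = np.where(perfect, np.inf, lrs)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(np.maximum(pval, 0.0))

    flag = np.where(mono, "monomorphic", "")
    flag = np.where(perfect, "perfect_fit", flag)
    fm = genotypes.founder_map
    table = pd.DataFrame(
        {
            "marker": list(fm.marker_names),
            "chromosome": list(fm.chromosomes),
            "position_mb": np.asarray(fm.positions_mb, float),
            "n": n_used.astype(int),
            "lrs": lrs,
            "lod": lrs / LOD_SCALE,
            "neg_log10_p": nlp,
            "flag": flag,
        }
    )
    return QtlScanResult(table, method="hk", trait=trait_name)


def permutation_threshold(
    genotypes: GenotypeMatrix,
    trait: pd.Series,
    n_perm: int = 10_000,
    alpha: float | tuple[float, ...] = 0.05,
    seed: int | np.random.Generator = 0,
    batch_size: int = 2_000,
) -> float | dict[float, float]:
    """Genome-wide LRS threshold from trait permutations.

    Shuffles the trait across strains ``n_perm`` times, records the
    genome-wide maximum LRS of each shuffle, and returns the empirical
    (1 - alpha) quantile of the maxima. Pass a tuple of alphas to get a
    dict (e.g. 0.05 "significant" and 0.37 "suggestive").
    """
    alphas = (alpha,) if np.isscalar(alpha) else tuple(alpha)
    for a in alphas:
        if not 0.0 < a <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {a}")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    X, y = _align(genotypes, trait)
    mask, X0, n, sx, sxx = _marker_moments(X)
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        Y = np.empty((b, len(y)))
        for i in range(b):
            Y[i] = rng.permutation(y)
        lrs, _, _, _ = _lrs_matrix(Y, mask, X0, n, sx, sxx)
        maxima[done : done + b] = np.nanmax(lrs, axis=1)
        done += b
    out = {a: float(np.quantile(maxima, 1.0 - a)) for a in alphas}
    return out[alphas[0]] if np.isscalar(alpha) else out


def kinship_matrix(genotypes: GenotypeMatrix, exclude_chromosome: str | None = None) -> np.ndarray:
    """Centered genotype cross-product kinship, K = Zc Zc' / m.

    Unknown calls are mean-imputed per marker. ``exclude_chromosome``
    implements leave-one-chromosome-out.
    """
    X = genotypes.dosages
    if exclude_chromosome is not None:
        keep = np.asarray(genotypes.founder_map.chromosomes) != exclude_chromosome
        X = X[:, keep]
    col_mean = np.nanmean(X, axis=0)
    Z = np.where(np.isnan(X), col_mean, X) - col_mean
    return Z @ Z.T / Z.shape[1]


def _reml_null(eigvals: np.ndarray, yr: np.ndarray, xr: np.ndarray):
    """Profile the variance ratio delta = sigma_e^2/sigma_g^2 by REML on the
    rotated null (intercept-only) model; returns (delta, sigma_g^2)."""
    n = len(yr)

    def neg_reml(log_delta: float) -> float:
        d = eigvals + np.exp(log_delta)
        w = 1.0 / d
        xtx = np.sum(xr * xr * w)
        beta = np.sum(xr * yr * w) / xtx
        resid = yr - xr * beta
        rss_w = np.sum(resid * resid * w)
        sg2 = rss_w / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(2.0 * np.pi * sg2)
            + np.sum(np.log(d))
            + np.log(xtx)
            + (n - 1)
        )
        return -ll

    grid = np.arange(-10.0, 10.1, 0.5)
    best = grid[np.argmin([neg_reml(g) for g in grid])]
    res = optimize.minimize_scalar(
        neg_reml, bounds=(best - 1.0, best + 1.0), method="bounded"
    )
    log_delta = res.x if res.fun <= neg_reml(best) else best
    delta = float(np.exp(log_delta))
    d = eigvals + delta
    w = 1.0 / d
    xtx = np.sum(xr * xr * w)
    beta = np.sum(xr * yr * w) / xtx
    rss_w = np.sum((yr - xr * beta) ** 2 * w)
    return delta, float(rss_w / (n - 1))


def lmm_scan(
    genotypes: GenotypeMatrix,
    trait: pd.Series,
    trait_name: str = "",
    kinship: np.ndarray | None = None,
) -> QtlScanResult:
    """Mixed-model scan with a polygenic random effect (EMMA-style).

    Variance components are fit once under the null by REML on the
    eigendecomposed model, then every marker is tested by generalized
    least squares with the null variance structure held fixed. The
    estimated narrow-sense heritability is exposed as
    ``result.h2_estimate``.
    """
    X, y = _align(genotypes, trait)
    n = len(y)
    if n < 4:
        raise ValueError("mixed-model scan needs at least four strains")
    if kinship is None:
        kinship = kinship_matrix(genotypes)
        keep = [s in trait.dropna().index for s in genotypes.strains]
        kinship = kinship[np.ix_(keep, keep)] if not all(keep) else kinship
    # scale to unit mean diagonal so 1/(1+delta) reads as a heritability
    mean_diag = float(np.mean(np.diag(kinship)))
    if mean_diag > 0:
        kinship = kinship / mean_diag

    eigvals, U = np.linalg.eigh(kinship)
    # a centered kinship is always rank-deficient by one; flag anything worse
    if np.sum(eigvals > 1e-10 * eigvals.max()) < kinship.shape[0] - 1:
        warnings.warn("near-singular kinship matrix; adding ridge 1e-6 to diagonal",
                      stacklevel=2)
        eigvals = eigvals + 1e-6
    eigvals = np.maximum(eigvals, 0.0)
    yr = U.T @ y
    onesr = U.T @ np.ones(n)
    delta, _ = _reml_null(eigvals, yr, onesr)
    w = 1.0 / (eigvals + delta)

    col_mean = np.nanmean(X, axis=0)
    Xi = np.where(np.isnan(X), col_mean, X)
    Xr = U.T @ Xi

    # per-marker GLS of y on [1, x] with weights w, vectorized over markers;
    # in rotated coordinates the intercept column is onesr, not a constant
    so2 = np.sum(w * onesr * onesr)
    soy = np.sum(w * onesr * yr)
    sox = (w * onesr) @ Xr
    swxx = w @ (Xr * Xr)
    swxy = (w * yr) @ Xr
    sxx_c = swxx - sox * sox / so2
    sxy_c = swxy - sox * soy / so2
    syy_c = np.sum(w * yr * yr) - soy * soy / so2
    zero_var = sxx_c <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(zero_var, 0.0, sxy_c / np.where(zero_var, 1.0, sxx_c))
        rss_w = np.maximum(syy_c - beta * sxy_c, 0.0)
        sigma2 = rss_w / (n - 2)
        se = np.sqrt(sigma2 / np.where(zero_var, 1.0, sxx_c))
        tstat = np.where(zero_var, 0.0, beta / np.maximum(se, _TINY))
        pval = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    pval = np.where(zero_var, 1.0, pval)
    with np.errstate(divide="ignore"):
        nlp = -np.log10(np.maximum(pval, 0.0))
        lrs = n * np.log(np.where(pval < 1.0, syy_c / np.maximum(rss_w, _TINY), 1.0))
        lrs = np.maximum(lrs, 0.0)

    fm = genotypes.founder_map
    table = pd.DataFrame(
        {
            "marker": list(fm.marker_names),
            "chromosome": list(fm.chromosomes),
            "position_mb": np.asarray(fm.positions_mb, float),
            "n": n,
            "lrs": lrs,
            "lod": lrs / LOD_SCALE,
            "neg_log10_p": nlp,
            "flag": np.where(zero_var, "monomorphic", ""),
        }
    )
    result = QtlScanResult(table, method="lmm", trait=trait_name)
    result.h2_estimate = 1.0 / (1.0 + delta)
    result.delta = delta
    return result


def support_interval(
    scan: QtlScanResult, chromosome: str, drop: float = 2.0
) -> SupportInterval:
    """LOD-drop support interval: walk outward from the chromosome peak to
    the outermost contiguous markers with LOD >= peak - drop."""
    sub = scan.table[scan.table["chromosome"].astype(str) == str(chromosome)]
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chromosome!r}")
    sub = sub.sort_values("position_mb").reset_index(drop=True)
    lod = sub["lod"].to_numpy(float)
    pos = sub["position_mb"].to_numpy(float)
    peak = int(np.argmax(lod))
    floor = lod[peak] - drop
    lo = peak
    while lo > 0 and lod[lo - 1] >= floor:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= floor:
        hi += 1
    one_sided = peak == 0 or peak == len(lod) - 1
    if one_sided:
        warnings.warn(
            f"peak at edge of chromosome {chromosome}; one-sided interval", stacklevel=2
        )
    return SupportInterval(
        chromosome=chromosome,
        start_mb=float(pos[lo]),
        end_mb=float(pos[hi]),
        peak_mb=float(pos[peak]),
        peak_lod=float(lod[peak]),
        drop=float(drop),
        one_sided=one_sided,
    )
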