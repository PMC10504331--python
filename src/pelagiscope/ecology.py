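"""Environmental association statistics for recruitment-based abundances.

Latitude banding (Polar / Temperate / Tropical on absolute latitude),
prevalence filtering (a genome must recruit in enough samples to support any
claim), per-genome abundance ~ covariate ordinary least squares with
Benjamini-Hochberg correction across the genome x covariate grid, and
bootstrap difference-of-medians effect sizes between genomes.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BANDS = ("Polar", "Temperate", "Tropical")

#: absolute-latitude band edges: Polar [66, 90], Temperate [33, 66),
#: Tropical [0, 33) — boundaries belong to the higher band
POLAR_EDGE = 66.0
TEMPERATE_EDGE = 33.0

METADATA_COVARIATES = ("temperature", "oxygen", "salinity", "chlorophyll",
                       "nutrients")


def latitude_band(latitude: float) -> str:
    """Band a latitude by its absolute value (boundary -> higher band)."""
    a = abs(latitude)
    if a > 90.0:
        raise ValueError(f"|latitude| must be <= 90, got {latitude}")
    if a >= POLAR_EDGE:
        return "Polar"
    if a >= TEMPERATE_EDGE:
        return "Temperate"
    return "Tropical"


def prevalence_filter(rpkm: pd.DataFrame,
                      min_samples_nonzero: int = 5) -> set[str]:
    """Genomes with non-zero RPKM in at least ``min_samples_nonzero`` samples.

    ``rpkm`` is a sample x genome matrix. Genomes below the floor carry too
    little signal for distribution claims and are treated as seed-bank
    residents.
    """
    counts = (rpkm > 0).sum(axis=0)
    return set(counts.index[counts >= min_samples_nonzero])


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.slope)


def fit_env_regression(rpkm: Sequence[float],
                       covariate: Sequence[float]) -> RegressionResult:
    """OLS of abundance on one environmental covariate.

    Pairs with a missing value on either side are dropped. A covariate with
    zero variance has no defined slope; the result is flagged with NaNs
    rather than raising, so a grid over many covariates degrades gracefully.
    """
    y = np.asarray(rpkm, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("rpkm and covariate must have equal length")
    ok = ~(np.isnan(y) | np.isnan(x))
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise ValueError(f"need >= 3 complete pairs, got {y.size}")
    if np.ptp(x) == 0:
        logger.warning("covariate has zero variance; slope undefined")
        return RegressionResult(float("nan"), float("nan"), float("nan"),
                                float("nan"), int(y.size))
    if np.ptp(y) == 0:
        # a constant response is fit exactly by a flat line
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, int(y.size))
    fit = stats.linregress(x, y)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2),
                            p_value=float(fit.pvalue), n=int(y.size))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted q-values; NaN p-values propagate to NaN q."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


def regression_grid(rpkm: pd.DataFrame, metadata: pd.DataFrame,
                    covariates: Iterable[str] = METADATA_COVARIATES,
                    ) -> pd.DataFrame:
    """Fit every genome x covariate regression; BH-adjust across the grid.

    ``rpkm`` is sample x genome; ``metadata`` is indexed by sample_id (or
    carries a sample_id column) with one column per covariate. Returns a
    long table: genome_id, covariate, slope, r_squared, p_value, q_value, n.
    """
    if "sample_id" in metadata.columns:
        metadata = metadata.set_index("sample_id")
    common = rpkm.index.intersection(metadata.index)
    missing = rpkm.index.difference(metadata.index)
    if len(missing):
        logger.warning("samples without metadata dropped: %s",
                       sorted(missing))
    rpkm = rpkm.loc[common]
    metadata = metadata.loc[common]
    rows = []
    for genome in rpkm.columns:
        for cov in covariates:
            res = fit_env_regression(rpkm[genome].to_numpy(),
                                     metadata[cov].to_numpy(dtype=float))
            rows.append((genome, cov, res.slope, res.r_squared,
                         res.p_value, res.n))
    grid = pd.DataFrame(rows, columns=["genome_id", "covariate", "slope",
                                       "r_squared", "p_value", "n"])
    grid["q_value"] = benjamini_hochberg(grid["p_value"].to_numpy())
    return grid[["genome_id", "covariate", "slope", "r_squared",
                 "p_value", "q_value", "n"]]


@dataclass(frozen=True)
class EffectSize:
    """Difference of medians with a percentile bootstrap interval."""

    statistic: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def bootstrap_median_difference(group_a: Sequence[float],
                                group_b: Sequence[float],
                                n_boot: int = 5000, seed: int = 0,
                                ci: float = 0.95) -> EffectSize:
    """median(a) - median(b) with a seeded percentile bootstrap CI.

    Both groups are resampled with replacement independently in each of
    ``n_boot`` replicates; the CI is the percentile interval of the
    replicate differences. Deterministic given the seed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    stat = float(np.median(a) - np.median(b))
    ra = rng.integers(0, a.size, size=(n_boot, a.size))
    rb = rng.integers(0, b.size, size=(n_boot, b.size))
    diffs = np.median(a[ra], axis=1) - np.median(b[rb], axis=1)
    alpha = (1.0 - ci) / 2
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return EffectSize(statistic=stat, ci_low=float(lo), ci_high=float(hi),
                      n_boot=n_boot, seed=seed)


def summarise_by_band(rpkm: pd.DataFrame,
                      metadata: pd.DataFrame) -> pd.DataFrame:
    """Per genome x latitude band: n, median, quartiles, non-zero fraction."""
    if "sample_id" in metadata.columns:
        metadata = metadata.set_index("sample_id")
    unmatched = rpkm.index.difference(metadata.index)
    if len(unmatched):
        logger.warning("samples without metadata excluded from band summary:"
                       " %s", sorted(unmatched))
    common = rpkm.index.intersection(metadata.index)
    bands = metadata.loc[common, "latitude"].map(latitude_band)
    rows = []
    for genome in rpkm.columns:
        for band in BANDS:
            vals = rpkm.loc[common[bands == band], genome].to_numpy(dtype=float)
            if vals.size:
                q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
                nonzero = float((vals > 0).mean())
            else:
                q1 = med = q3 = float("nan")
                nonzero = float("nan")
            rows.append((genome, band, vals.size, med, q1, q3, nonzero))
    return pd.DataFrame(rows, columns=["genome_id", "band", "n", "median",
                                       "q1", "q3", "nonzero_fraction"])
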