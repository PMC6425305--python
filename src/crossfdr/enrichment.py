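"""Conditional QQ-plot data and genomic inflation correction.

A conditional QQ-plot shows the p-value distribution of the primary trait
within nested strata defined by the conditioning trait's significance
(p2 <= 1, 0.1, 0.01, 0.001 by default).  Progressive leftward shift of the
stricter strata away from the null line indicates pleiotropic enrichment.
Empirical CDFs are averaged over the random-pruning ensemble so LD does
not inflate the curves; the genomic inflation factor lambda is estimated
from LD-independent intergenic SNPs (depleted of true associations) and
applied to all test statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .ld import PruningEnsemble
from .sumstats import p_from_z

logger = logging.getLogger(__name__)

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = float(chi2.median(1))

DEFAULT_STRATA = (1.0, 0.1, 0.01, 0.001)


class InflationEstimationError(ValueError):
    """Too few SNPs to estimate the inflation factor."""


def inflation_factor(z, min_snps: int = 100) -> float:
    """Genomic inflation factor: lambda = median(z^2) / median(chi^2_1).

    ``z`` should be the z-scores of a putatively null SNP set
    (LD-independent intergenic SNPs)."""
    z = np.asarray(z, dtype=float)
    if z.size < min_snps:
        raise InflationEstimationError(
            f"need >= {min_snps} SNPs to estimate lambda, got {z.size}")
    return float(np.median(z ** 2) / CHI2_1_MEDIAN)


def apply_inflation(pairs: pd.DataFrame, lambda1: float, lambda2: float,
                    clamp: bool = False) -> pd.DataFrame:
    """Divide both traits' test statistics by their inflation factors.

    z <- z / sqrt(lambda) per trait and p recomputed as 2*Phi(-|z|).  With
    ``clamp=True`` lambda below 1 is raised to 1 (never inflates the
    statistics upward); the default applies the division unconditionally.
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("inflation factors must be positive")
    if clamp:
        lambda1, lambda2 = max(lambda1, 1.0), max(lambda2, 1.0)
    out = pairs.copy()
    out["z1"] = pairs["z1"] / np.sqrt(lambda1)
    out["z2"] = pairs["z2"] / np.sqrt(lambda2)
    out["p1"] = p_from_z(out["z1"])
    out["p2"] = p_from_z(out["z2"])
    return out


class InflationCorrector(BaseEstimator, TransformerMixin):
    """Genomic-control corrector with a scikit-learn transformer surface.

    fit(X) estimates ``lambda_`` from a null z-score vector; transform(X)
    rescales arbitrary z-scores by 1/sqrt(lambda_).

    Parameters
    ----------
    min_snps : minimum null-set size accepted by fit.
    clamp : if True, lambda is floored at 1 (no upward inflation).
    """

    def __init__(self, min_snps: int = 100, clamp: bool = False):
        self.min_snps = min_snps
        self.clamp = clamp

    def fit(self, X, y=None):
        lam = inflation_factor(np.ravel(X), min_snps=self.min_snps)
        self.lambda_ = max(lam, 1.0) if self.clamp else lam
        return self

    def transform(self, X):
        check_is_fitted(self, "lambda_")
        return np.asarray(X, dtype=float) / np.sqrt(self.lambda_)


@dataclass(frozen=True)
class QqConfig:
    """Settings for conditional QQ curves.

    ``strata_thresholds`` are conditioning cutoffs on p2, strictly
    decreasing with the first equal to 1 (the unconditional stratum);
    ``grid`` is the nominal -log10 p axis the curves are evaluated on.
    """

    strata_thresholds: tuple = DEFAULT_STRATA
    grid_max: float = 10.0
    grid_step: float = 0.1
    min_stratum_count: int = 100

    def __post_init__(self):
        t = self.strata_thresholds
        if not t or t[0] != 1.0:
            raise ValueError("first stratum threshold must be 1")
        if any(a <= b for a, b in zip(t, t[1:])):
            raise ValueError("strata thresholds must be strictly decreasing")

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.grid_max / self.grid_step))
        return np.round(np.arange(n + 1) * self.grid_step, 10)


@dataclass
class EnrichmentReport:
    """Averaged conditional QQ curves plus the inflation factors used.

    ``curves`` maps each stratum threshold to the empirical -log10
    exceedance quantile on the nominal grid (NaN where the averaged
    exceedance is zero); ``counts`` holds the ensemble-averaged stratum
    sizes."""

    grid: np.ndarray
    curves: dict
    counts: dict
    lambda1: float = 1.0
    lambda2: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, emp in self.curves.items():
            rows.append(pd.DataFrame({
                "stratum_p2": t, "nominal_neglog10p": self.grid,
                "empirical_neglog10q": emp, "stratum_count": self.counts[t],
            }))
        return pd.concat(rows, ignore_index=True)

    def plot(self, ax=None):
        """Render the conditional QQ plot (empirical quantile on x,
        nominal p on y, both on the -log10 scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lim = float(self.grid[-1])
        ax.plot([0, lim], [0, lim], "k--", lw=0.8, label="null")
        for t, emp in self.curves.items():
            ax.plot(emp, self.grid, label=f"p2 <= {t:g}")
        ax.set_xlabel(r"empirical $-\log_{10}(q)$")
        ax.set_ylabel(r"nominal $-\log_{10}(p)$")
        ax.legend()
        return ax


def _stratum_exceedance(neglog_p1, in_stratum, masks, weights, grid):
    """Ensemble-averaged exceedance G(q) = P(-log10 p1 >= q | stratum) and
    the averaged stratum size."""
    total_w = weights.sum()
    g = np.zeros(len(grid))
    size = 0.0
    for mask, w in zip(masks, weights):
        sel = neglog_p1[mask & in_stratum]
        if sel.size == 0:
            continue
        sel.sort()
        # count of values >= q, with a tiny nudge so grid-node values count
        n_ge = sel.size - np.searchsorted(sel, grid - 1e-9, side="left")
        g += w * (n_ge / sel.size)
        size += w * sel.size
    return g / total_w, size / total_w


def conditional_qq(pairs: pd.DataFrame, config: QqConfig,
                   ensemble: PruningEnsemble, direction: int = 1) -> EnrichmentReport:
    """Averaged conditional QQ curves of trait ``direction`` stratified by
    the other trait's p-values.

    For each stratum {p2 <= t} the empirical exceedance of p1 is computed
    within every pruning mask, averaged over the ensemble, and reported as
    -log10 of the averaged quantile on the nominal grid.  Strata with
    fewer (ensemble-averaged) SNPs than ``min_stratum_count`` are omitted
    with a warning.
    """
    if direction == 1:
        p_primary = pairs["p1"].to_numpy()
        p_cond = pairs["p2"].to_numpy()
    elif direction == 2:
        p_primary = pairs["p2"].to_numpy()
        p_cond = pairs["p1"].to_numpy()
    else:
        raise ValueError("direction must be 1 or 2")

    order = pd.Index(pairs["snp_id"]).get_indexer(ensemble.panel)
    if np.any(order < 0):
        raise ValueError("ensemble panel contains SNPs absent from pairs")
    neglog_p1 = -np.log10(p_primary[order])
    p_cond = p_cond[order]

    grid = config.grid
    curves, counts = {}, {}
    for t in config.strata_thresholds:
        in_stratum = p_cond <= t
        g, size = _stratum_exceedance(neglog_p1, in_stratum, ensemble.masks,
                                      ensemble.weights, grid)
        if size < config.min_stratum_count:
            logger.warning("conditional_qq: stratum p2<=%g has %.1f SNPs "
                           "(< %d), omitted", t, size, config.min_stratum_count)
            continue
        with np.errstate(divide="ignore"):
            curves[t] = np.where(g > 0, -np.log10(np.maximum(g, 1e-320)), np.nan)
        counts[t] = size
    return EnrichmentReport(grid=grid, curves=curves, counts=counts)
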