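"""Conditional and conjunctional false discovery rate estimation.

The conditional FDR of trait 1 given trait 2 at a SNP with observed
p-values (p1, p2) is the posterior probability that the SNP is null for
trait 1 given that both traits' p-values are at least as small as
observed.  With the null fraction pi0 held at its conservative upper
bound of 1 it is estimated as

    condFDR(p1 | p2) = pi0 * p1 / F(p1 | p2 <= t)|_{t = p2}

where F is the stratified empirical CDF of p1 among SNPs whose
conditioning p-value falls below t.  F is tabulated on a 2-D grid in
-log10 coordinates, averaged over the random-pruning ensemble so LD does
not distort the empirical distribution, and queried by bilinear
interpolation.  The conjunctional FDR — the posterior probability that a
SNP is null for either trait — is the maximum of the two conditional
FDRs, a conservative joint-association criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.utils.validation import check_is_fitted

from .ld import PruningEnsemble

#: nudge in -log10 p units so values at a grid node count as <= the node's
#: p-value despite round-trip floating error
_GRID_EPS = 1e-9


class LookupError_(ValueError):
    """The CDF lookup cannot be built or evaluated."""


@dataclass(frozen=True)
class CfdrConfig:
    """Estimator settings.

    pi0 is the assumed null fraction (1 = conservative upper bound).
    The lookup grid spans -log10 p1 in [0, p1_grid_max] and conditioning
    thresholds -log10 p2 in [0, p2_grid_max], both at ``grid_step``;
    queries beyond the grid are clamped to the boundary.  Cells whose
    averaged SNP count falls below ``min_stratum_count`` inherit the value
    of the nearest less-stringent conditioning stratum.
    """

    pi0: float = 1.0
    p1_grid_max: float = 20.0
    p2_grid_max: float = 10.0
    grid_step: float = 0.1
    min_stratum_count: int = 100

    def __post_init__(self):
        if not 0 < self.pi0 <= 1:
            raise ValueError("pi0 must lie in (0, 1]")

    def _axis(self, hi: float) -> np.ndarray:
        n = int(round(hi / self.grid_step))
        return np.round(np.arange(n + 1) * self.grid_step, 10)

    @property
    def p1_grid(self) -> np.ndarray:
        return self._axis(self.p1_grid_max)

    @property
    def p2_grid(self) -> np.ndarray:
        return self._axis(self.p2_grid_max)


@dataclass
class CdfLookup:
    """Averaged stratified empirical CDF table F(p1 | p2 <= t).

    ``cdf[j, i]`` is the ensemble-averaged empirical probability that
    p1 <= 10^-p1_grid[i] among SNPs with p2 <= 10^-p2_grid[j];
    ``counts[j, i]`` the averaged numerator SNP count per cell and
    ``base_counts[j]`` the averaged stratum size.
    """

    p1_grid: np.ndarray
    p2_grid: np.ndarray
    cdf: np.ndarray
    counts: np.ndarray
    base_counts: np.ndarray

    def __post_init__(self):
        self._interp = RegularGridInterpolator(
            (self.p2_grid, self.p1_grid), self.cdf, method="linear",
            bounds_error=False, fill_value=None)

    def evaluate(self, neglog_p1, neglog_p2) -> np.ndarray:
        """Bilinear interpolation in -log10 coordinates, clamped to the
        grid on both axes."""
        q1 = np.clip(np.asarray(neglog_p1, float), 0.0, self.p1_grid[-1])
        q2 = np.clip(np.asarray(neglog_p2, float), 0.0, self.p2_grid[-1])
        return self._interp(np.column_stack([np.ravel(q2), np.ravel(q1)])
                            ).reshape(np.shape(q1))

    def save(self, path) -> None:
        np.savez(path, p1_grid=self.p1_grid, p2_grid=self.p2_grid,
                 cdf=self.cdf, counts=self.counts,
                 base_counts=self.base_counts)

    @classmethod
    def load(cls, path) -> "CdfLookup":
        d = np.load(path)
        return cls(p1_grid=d["p1_grid"], p2_grid=d["p2_grid"], cdf=d["cdf"],
                   counts=d["counts"], base_counts=d["base_counts"])


def _mask_cdf(neglog_p1, neglog_p2, p1_grid, p2_grid):
    """Exact stratified empirical CDF of one pruning mask.

    Returns (cdf, numerator counts, stratum sizes).  Counting uses a 2-D
    histogram on node indices followed by reverse cumulative sums, which
    reproduces direct threshold counting exactly.
    """
    i_idx = np.searchsorted(p1_grid, neglog_p1 + _GRID_EPS, side="right")
    j_idx = np.searchsorted(p2_grid, neglog_p2 + _GRID_EPS, side="right")
    hist = np.zeros((len(p2_grid) + 1, len(p1_grid) + 1))
    np.add.at(hist, (j_idx, i_idx), 1.0)
    # S[j, i] = #{snp: j_idx > j, i_idx > i} = #{p2 <= t_j, p1 <= 10^-q_i}
    rc = np.cumsum(np.cumsum(hist[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
    counts = rc[1:, 1:]
    base = counts[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        cdf = counts / base[:, None]
    return cdf, counts, base


def build_lookup(pairs, ensemble: PruningEnsemble | None = None,
                 config: CfdrConfig = CfdrConfig(),
                 direction: int = 1) -> CdfLookup:
    """Build the averaged conditional ECDF lookup for one direction.

    ``pairs`` is a harmonized table (or any frame with p1/p2 columns);
    ``direction=1`` estimates F(p1 | p2), ``direction=2`` the reverse.
    Per pruning mask the exact stratified ECDF is computed and the tables
    are weight-averaged over unique masks.  Strata that are empty in a
    mask inherit the next-less-stringent stratum; sparse cells (averaged
    count below the configured minimum) do the same after averaging, and
    a final isotonic pass enforces monotonicity along the p1 axis.
    """
    if direction == 1:
        p_primary, p_cond = pairs["p1"].to_numpy(), pairs["p2"].to_numpy()
    elif direction == 2:
        p_primary, p_cond = pairs["p2"].to_numpy(), pairs["p1"].to_numpy()
    else:
        raise ValueError("direction must be 1 or 2")

    q1 = -np.log10(p_primary)
    q2 = -np.log10(p_cond)
    p1_grid, p2_grid = config.p1_grid, config.p2_grid

    if ensemble is None:
        masks = [np.ones(len(pairs), dtype=bool)]
        weights = np.array([1.0])
    else:
        order = pd.Index(pairs["snp_id"]).get_indexer(ensemble.panel)
        if np.any(order < 0):
            raise LookupError_("ensemble panel contains SNPs absent from pairs")
        q1, q2 = q1[order], q2[order]
        masks, weights = ensemble.masks, ensemble.weights

    total_w = float(np.sum(weights))
    cdf_sum = np.zeros((len(p2_grid), len(p1_grid)))
    cnt_sum = np.zeros_like(cdf_sum)
    base_sum = np.zeros(len(p2_grid))
    for mask, w in zip(masks, weights):
        cdf, counts, base = _mask_cdf(q1[mask], q2[mask], p1_grid, p2_grid)
        if base[0] == 0:
            raise LookupError_("base stratum (p2 <= 1) is empty in a mask")
        # empty strata take the nearest less-stringent stratum's CDF
        for j in range(1, len(p2_grid)):
            if base[j] == 0:
                cdf[j] = cdf[j - 1]
        cdf_sum += w * cdf
        cnt_sum += w * counts
        base_sum += w * base
    cdf = cdf_sum / total_w
    counts = cnt_sum / total_w
    base = base_sum / total_w

    # sparse-cell fallback toward less stringent conditioning
    for j in range(1, len(p2_grid)):
        sparse = counts[j] < config.min_stratum_count
        cdf[j, sparse] = cdf[j - 1, sparse]

    # isotonic pass: F is non-increasing in -log10 p1 (non-decreasing in p1)
    iso = IsotonicRegression(increasing=False)
    x = np.arange(len(p1_grid), dtype=float)
    for j in range(len(p2_grid)):
        if not np.all(np.diff(cdf[j]) <= 0):
            cdf[j] = iso.fit_transform(x, cdf[j])

    return CdfLookup(p1_grid=p1_grid, p2_grid=p2_grid,
                     cdf=np.clip(cdf, 0.0, 1.0), counts=counts,
                     base_counts=base)


def cond_fdr(p1, p2, lookup: CdfLookup, config: CfdrConfig = CfdrConfig()):
    """Per-SNP conditional FDR: min(1, pi0 * p1 / F(p1 | p2)).

    Accepts scalars or arrays; p-values must lie in (0, 1].  Where the
    interpolated CDF is zero the estimate saturates at 1.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 <= 0) | (p1 > 1)) or np.any((p2 <= 0) | (p2 > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    f = lookup.evaluate(-np.log10(p1), -np.log10(p2))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = config.pi0 * p1 / f
    out = np.where(f <= 0, 1.0, out)
    return np.minimum(out, 1.0)[()] if out.ndim == 0 else np.minimum(out, 1.0)


def conj_fdr(c12, c21):
    """Conjunctional FDR: the maximum of the two conditional FDRs."""
    c12 = np.asarray(c12, dtype=float)
    c21 = np.asarray(c21, dtype=float)
    if np.any((c12 < 0) | (c12 > 1)) or np.any((c21 < 0) | (c21 > 1)):
        raise ValueError("conditional FDRs must lie in [0, 1]")
    out = np.maximum(c12, c21)
    return out[()] if out.ndim == 0 else out


FDR_COLUMNS = ["snp_id", "chrom", "pos", "p1", "p2", "z1", "z2",
               "condfdr_1given2", "condfdr_2given1", "conjfdr"]


def score_panel(pairs: pd.DataFrame, lookup12: CdfLookup, lookup21: CdfLookup,
                config: CfdrConfig = CfdrConfig()) -> pd.DataFrame:
    """Score every SNP of a harmonized panel in both directions.

    Returns the per-SNP table with condFDR(1|2), condFDR(2|1) and their
    maximum (conjFDR).  Deterministic given the inputs and lookups.
    """
    if len(pairs) < 2:
        raise LookupError_("panel too small to score (need >= 2 SNPs)")
    p1 = pairs["p1"].to_numpy()
    p2 = pairs["p2"].to_numpy()
    c12 = cond_fdr(p1, p2, lookup12, config)
    c21 = cond_fdr(p2, p1, lookup21, config)
    out = pairs[["snp_id", "chrom", "pos", "p1", "p2", "z1", "z2"]].copy()
    out["condfdr_1given2"] = c12
    out["condfdr_2given1"] = c21
    out["conjfdr"] = conj_fdr(c12, c21)
    return out


class ConditionalFdr(BaseEstimator):
    """Conditional FDR estimator with a scikit-learn surface.

    fit(X) tabulates the stratified averaged empirical CDF from an
    (n, 2) array of p-value pairs ``[p_primary, p_conditioning]``;
    predict(X) returns condFDR for arbitrary p-value pairs.

    Parameters
    ----------
    pi0 : assumed null fraction (conservative default 1).
    p1_grid_max, p2_grid_max, grid_step : lookup grid in -log10 p units.
    min_stratum_count : sparse-cell fallback threshold.

    Attributes
    ----------
    lookup_ : CdfLookup
        The fitted conditional ECDF table.
    n_snps_ : int
        Panel size used for fitting.
    """

    def __init__(self, pi0: float = 1.0, p1_grid_max: float = 20.0,
                 p2_grid_max: float = 10.0, grid_step: float = 0.1,
                 min_stratum_count: int = 100):
        self.pi0 = pi0
        self.p1_grid_max = p1_grid_max
        self.p2_grid_max = p2_grid_max
        self.grid_step = grid_step
        self.min_stratum_count = min_stratum_count

    def _config(self) -> CfdrConfig:
        return CfdrConfig(pi0=self.pi0, p1_grid_max=self.p1_grid_max,
                          p2_grid_max=self.p2_grid_max,
                          grid_step=self.grid_step,
                          min_stratum_count=self.min_stratum_count)

    def fit(self, X, y=None, ensemble: PruningEnsemble | None = None):
        X = self._validate_p(X)
        frame = pd.DataFrame({"p1": X[:, 0], "p2": X[:, 1],
                              "snp_id": np.arange(len(X)).astype(str)})
        if ensemble is not None:
            frame["snp_id"] = ensemble.panel
        self.lookup_ = build_lookup(frame, ensemble, self._config())
        self.n_snps_ = len(X)
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "lookup_")
        X = self._validate_p(X)
        return cond_fdr(X[:, 0], X[:, 1], self.lookup_, self._config())

    @staticmethod
    def _validate_p(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of p-value pairs")
        if np.any((X <= 0) | (X > 1)):
            raise ValueError("p-values must lie in (0, 1]")
        return X


class ConjunctionalFdr(BaseEstimator):
    """Joint-association scorer: maximum of both conditional FDRs.

    fit(X) fits one ConditionalFdr per direction on the (n, 2) p-value
    array; predict(X) returns the per-row conjunctional FDR.

    Attributes
    ----------
    fdr12_ , fdr21_ : the fitted directional estimators.
    """

    def __init__(self, pi0: float = 1.0, p1_grid_max: float = 20.0,
                 p2_grid_max: float = 10.0, grid_step: float = 0.1,
                 min_stratum_count: int = 100):
        self.pi0 = pi0
        self.p1_grid_max = p1_grid_max
        self.p2_grid_max = p2_grid_max
        self.grid_step = grid_step
        self.min_stratum_count = min_stratum_count

    def fit(self, X, y=None, ensemble: PruningEnsemble | None = None):
        params = self.get_params()
        X = ConditionalFdr._validate_p(X)
        self.fdr12_ = ConditionalFdr(**params).fit(X, ensemble=ensemble)
        self.fdr21_ = ConditionalFdr(**params).fit(X[:, ::-1], ensemble=ensemble)
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        check_is_fitted(self, "fdr12_")
        X = ConditionalFdr._validate_p(X)
        return conj_fdr(self.fdr12_.predict(X), self.fdr21_.predict(X[:, ::-1]))
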