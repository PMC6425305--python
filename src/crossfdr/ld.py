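"""Pairwise LD representation, random pruning and region exclusion.

LD enters the analysis three ways: repeated random selection of one SNP per
LD cluster (r^2 > 0.1) before estimating empirical CDFs, propagation of
region exclusions to LD partners, and clumping of significant SNPs into
independent loci.  All three operate on a sparse symmetric r^2 graph; SNP
pairs absent from the table are treated as r^2 = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_R2_THRESHOLD = 0.1

#: long-range-LD / known-association regions excluded by default:
#: the MHC and the APOE gene (1-based inclusive bounds)
DEFAULT_EXCLUSION_REGIONS = ("6:25652429-33368333", "19:44909039-45912650")


class LdFormatError(ValueError):
    """A malformed row in an LD pair table."""


class LdGraph:
    """Sparse symmetric mapping (snp_i, snp_j) -> r^2.

    r^2 must lie in [0, 1]; self-edges are rejected; duplicate pairs keep
    the maximum r^2.
    """

    def __init__(self, r2_threshold: float = DEFAULT_R2_THRESHOLD):
        self.r2_threshold = float(r2_threshold)
        self._adj: dict[str, dict[str, float]] = {}

    def add_pair(self, a: str, b: str, r2: float) -> None:
        if a == b:
            raise LdFormatError(f"self-edge for SNP {a!r}")
        if not (0.0 <= r2 <= 1.0):
            raise LdFormatError(f"r^2={r2} outside [0, 1] for pair ({a}, {b})")
        cur = self._adj.get(a, {}).get(b)
        if cur is not None:
            if cur != r2:
                logger.info("duplicate LD pair (%s, %s): keeping max(%g, %g)",
                            a, b, cur, r2)
            r2 = max(cur, r2)
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float:
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, snp: str, min_r2: float | None = None) -> dict[str, float]:
        nbrs = self._adj.get(snp, {})
        if min_r2 is None:
            return dict(nbrs)
        return {s: r for s, r in nbrs.items() if r > min_r2}

    def degree(self, snp: str) -> int:
        return len(self._adj.get(snp, {}))

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    def edges(self):
        seen = set()
        for a, nbrs in self._adj.items():
            for b, r2 in nbrs.items():
                key = (a, b) if a < b else (b, a)
                if key not in seen:
                    seen.add(key)
                    yield key[0], key[1], r2

    def nodes(self):
        return self._adj.keys()


def load_ld_pairs(path, storage_floor: float = 0.0,
                  r2_threshold: float = DEFAULT_R2_THRESHOLD) -> LdGraph:
    """Load a PLINK-.ld-style whitespace table (SNP_A, SNP_B, R2 columns).

    Pairs with r^2 <= ``storage_floor`` are not stored.  Rows with r^2
    outside [0, 1] or unparseable fields are rejected with their line
    number logged.
    """
    df = pd.read_csv(path, sep=r"\s+")
    for col in ("SNP_A", "SNP_B", "R2"):
        if col not in df.columns:
            raise LdFormatError(f"missing column {col!r} in {path}")
    graph = LdGraph(r2_threshold=r2_threshold)
    n_bad = 0
    r2s = pd.to_numeric(df["R2"], errors="coerce")
    for i, (a, b, r2) in enumerate(zip(df["SNP_A"].astype(str),
                                       df["SNP_B"].astype(str), r2s)):
        if not np.isfinite(r2) or not (0.0 <= r2 <= 1.0) or a == b:
            n_bad += 1
            logger.warning("%s line %d: rejected LD row (%s, %s, r2=%s)",
                           path, i + 2, a, b, r2)
            continue
        if r2 > storage_floor:
            graph.add_pair(a, b, float(r2))
    if n_bad:
        logger.info("load_ld_pairs(%s): rejected %d malformed rows", path, n_bad)
    return graph


def write_ld_pairs(graph: LdGraph, panel: pd.DataFrame, path) -> None:
    """Write the graph as a PLINK-.ld-like table using panel coordinates."""
    loc = panel.set_index("snp_id")[["chrom", "pos"]]
    rows = []
    for a, b, r2 in graph.edges():
        ca, pa = loc.loc[a]
        cb, pb = loc.loc[b]
        rows.append((ca, pa, a, cb, pb, b, r2))
    out = pd.DataFrame(rows, columns=["CHR_A", "BP_A", "SNP_A",
                                      "CHR_B", "BP_B", "SNP_B", "R2"])
    out.to_csv(path, sep=" ", index=False)


@dataclass(frozen=True)
class ExclusionRegion:
    """A genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    @classmethod
    def from_string(cls, s: str) -> "ExclusionRegion":
        chrom, span = s.replace("chr", "").split(":")
        lo, hi = span.replace("–", "-").split("-")
        return cls(chrom=chrom, start=int(lo), end=int(hi))

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


@dataclass
class PruningEnsemble:
    """Keep-masks from repeated random LD pruning.

    Masks are stored deduplicated with multiplicity ``weights`` (summing to
    ``n_iter``); every average over the ensemble is weighted accordingly,
    which is identical to storing each iteration's mask separately.
    """

    panel: np.ndarray              # snp ids, fixed order
    masks: list                    # list of boolean arrays over panel
    weights: np.ndarray            # multiplicity of each unique mask
    n_iter: int
    seed: int
    r2_threshold: float = DEFAULT_R2_THRESHOLD

    def __post_init__(self):
        assert int(np.sum(self.weights)) == self.n_iter

    @property
    def n_unique(self) -> int:
        return len(self.masks)

    def keep_frequency(self) -> np.ndarray:
        """Per-SNP fraction of iterations in which it was retained."""
        freq = np.zeros(len(self.panel))
        for mask, w in zip(self.masks, self.weights):
            freq += w * mask
        return freq / self.n_iter


def _greedy_mis(order: np.ndarray, nbr_idx: list[np.ndarray], n: int) -> np.ndarray:
    """Random maximal independent set: visit SNPs in random order, keep any
    not-yet-excluded SNP and exclude its r^2-linked neighbours."""
    keep = np.zeros(n, dtype=bool)
    decided = np.zeros(n, dtype=bool)
    for i in order:
        if decided[i]:
            continue
        keep[i] = True
        decided[i] = True
        nb = nbr_idx[i]
        if nb.size:
            decided[nb] = True
    return keep


def _panel_neighbor_index(panel: np.ndarray, graph: LdGraph,
                          threshold: float) -> list[np.ndarray]:
    pos = {s: i for i, s in enumerate(panel)}
    nbr_idx = []
    for s in panel:
        nbrs = graph.neighbors(s, min_r2=threshold)
        nbr_idx.append(np.array([pos[t] for t in nbrs if t in pos],
                                dtype=np.intp))
    return nbr_idx


def random_prune(graph: LdGraph, panel, n_iter: int = 200, seed: int = 0,
                 r2_threshold: float | None = None) -> PruningEnsemble:
    """Repeated random selection of one SNP per LD cluster (r^2 > threshold).

    Each iteration draws an independent random maximal independent set of
    the r^2 > threshold graph restricted to ``panel``: repeatedly pick a
    uniformly random undecided SNP, keep it, and discard all its linked
    neighbours.  Isolated SNPs appear in every mask.  Iteration ``k`` uses
    an RNG stream derived from ``(seed, k)``, so iterations are
    order-independent and the ensemble is fully reproducible.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    thr = graph.r2_threshold if r2_threshold is None else r2_threshold
    panel = np.asarray(list(panel), dtype=object)
    n = len(panel)
    nbr_idx = _panel_neighbor_index(panel, graph, thr)

    has_edges = any(nb.size for nb in nbr_idx)
    unique: dict[bytes, int] = {}
    masks: list[np.ndarray] = []
    weights: list[int] = []
    if not has_edges:
        masks.append(np.ones(n, dtype=bool))
        weights.append(n_iter)
    else:
        for k in range(n_iter):
            rng = np.random.default_rng([seed, k])
            order = rng.permutation(n)
            keep = _greedy_mis(order, nbr_idx, n)
            key = keep.tobytes()
            if key in unique:
                weights[unique[key]] += 1
            else:
                unique[key] = len(masks)
                masks.append(keep)
                weights.append(1)
    return PruningEnsemble(panel=panel, masks=masks,
                           weights=np.asarray(weights, dtype=np.int64),
                           n_iter=n_iter, seed=seed, r2_threshold=thr)


def apply_exclusions(panel: pd.DataFrame, regions, graph: LdGraph,
                     r2_threshold: float | None = None) -> pd.DataFrame:
    """Remove SNPs inside any exclusion region plus their LD partners.

    A SNP is removed if ``start <= pos <= end`` in any region on the same
    chromosome (both bounds inclusive), or if it is linked with
    r^2 > threshold to such a SNP.  The panel must carry ``snp_id``,
    ``chrom`` and ``pos`` columns.
    """
    regions = [ExclusionRegion.from_string(r) if isinstance(r, str) else r
               for r in regions]
    if not regions:
        return panel
    thr = graph.r2_threshold if r2_threshold is None else r2_threshold

    chrom = panel["chrom"].astype(str).to_numpy()
    pos = panel["pos"].to_numpy()
    inside = np.zeros(len(panel), dtype=bool)
    for reg in regions:
        inside |= (chrom == reg.chrom) & (pos >= reg.start) & (pos <= reg.end)

    excluded = set(panel["snp_id"].to_numpy()[inside])
    partners = set()
    for s in excluded:
        partners.update(graph.neighbors(s, min_r2=thr))
    removed = excluded | partners
    keep = ~panel["snp_id"].isin(removed)
    logger.info("apply_exclusions: removed %d in-region SNPs plus %d LD "
                "partners", len(excluded), len(removed) - len(excluded))
    return panel.loc[keep].reset_index(drop=True)


def intergenic_independent(panel: pd.DataFrame, genes: pd.DataFrame,
                           graph: LdGraph, seed: int = 0,
                           r2_threshold: float | None = None) -> set:
    """LD-independent intergenic SNP ids for inflation estimation.

    Keeps SNPs strictly outside every gene interval (1-based inclusive
    coordinates), then thins to one SNP per LD cluster with a single seeded
    random pruning pass.
    """
    thr = graph.r2_threshold if r2_threshold is None else r2_threshold
    chrom = panel["chrom"].astype(str).to_numpy()
    pos = panel["pos"].to_numpy()
    genic = np.zeros(len(panel), dtype=bool)
    for c, sub in genes.groupby(genes["chrom"].astype(str)):
        on_c = chrom == c
        if not on_c.any():
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        # merge overlapping intervals so searchsorted is valid
        m_starts, m_ends = [], []
        for s, e in zip(starts, ends):
            if m_ends and s <= m_ends[-1]:
                m_ends[-1] = max(m_ends[-1], e)
            else:
                m_starts.append(s)
                m_ends.append(e)
        m_starts = np.asarray(m_starts)
        m_ends = np.asarray(m_ends)
        idx = np.searchsorted(m_starts, pos[on_c], side="right") - 1
        hit = (idx >= 0) & (pos[on_c] <= m_ends[np.clip(idx, 0, None)])
        genic[on_c] = hit
    inter = panel.loc[~genic, "snp_id"].to_numpy()
    ens = random_prune(graph, inter, n_iter=1, seed=seed, r2_threshold=thr)
    return set(ens.panel[ens.masks[0]])


def read_bed(path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open) into 1-based
    inclusive internal coordinates.  Columns beyond the first six ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    out = pd.DataFrame({
        "chrom": df[0].astype(str).str.replace("chr", "", regex=False),
        "start": df[1].astype(np.int64) + 1,
        "end": df[2].astype(np.int64),
        "name": df[3].astype(str) if ncol > 3 else "",
        "strand": df[5].astype(str) if ncol > 5 else "+",
    })
    return out


def write_bed(genes: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    out = pd.DataFrame({
        0: genes["chrom"], 1: genes["start"] - 1, 2: genes["end"],
        3: genes.get("name", ""), 4: 0, 5: genes.get("strand", "+"),
    })
    out.to_csv(path, sep="\t", header=False, index=False)
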