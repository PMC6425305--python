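"""Synthetic paired GWAS summary statistics with known ground truth.

The generator emulates the statistical structure the cross-trait analysis
assumes: a four-class causal mixture (null / trait-1-specific /
trait-2-specific / shared), block LD with compound-symmetric correlation,
and configurable sign concordance of shared effects.  With concordance at
0.5 the shared component contributes no genome-wide z-score correlation —
the mixed-direction overlap regime — while each shared SNP still carries a
real effect in both traits.

Effects enter directly on the z-score axis: a causal SNP k has offset
delta_k and the observed z is z_i = sum_k R_ik delta_k + eps_i, with R the
within-block correlation matrix (r = sqrt(r^2), compound symmetric) and
eps ~ N(0, R), so null blocks are exchangeable correlated standard
normals.  Sample-size columns are carried for I/O realism only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ld import LdGraph, write_bed, write_ld_pairs
from .sumstats import Dialect, DEFAULT_DIALECT, p_from_z, write_sumstats

LABELS = ("null", "spec1", "spec2", "shared")

# unordered allele pairs that survive strand checks (no A/T, C/G)
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the paired-GWAS generator.

    Fractions are class probabilities of the causal mixture; the null
    fraction is the complement.  ``effect_sd1/2`` scale the causal z-score
    offsets; ``sign_concordance`` is the probability that a shared SNP has
    same-sign effects in both traits.  LD is block-diagonal with all
    within-block pairs at ``within_block_r2``.
    """

    n_snps: int = 10_000
    frac_shared: float = 0.0
    frac_spec1: float = 0.0
    frac_spec2: float = 0.0
    effect_sd1: float = 3.0
    effect_sd2: float = 3.0
    sign_concordance: float = 0.5
    ld_block_size: int = 1
    within_block_r2: float = 0.0
    n_chromosomes: int = 2
    intergenic_fraction: float = 0.3
    n_samples1: int = 50_000
    n_samples2: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1:
            raise SimConfigError("n_snps must be positive")
        fracs = (self.frac_shared, self.frac_spec1, self.frac_spec2)
        if any(f < 0 or f > 1 for f in fracs):
            raise SimConfigError("class fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise SimConfigError("class fractions sum to > 1")
        if self.effect_sd1 <= 0 or self.effect_sd2 <= 0:
            raise SimConfigError("effect scales must be positive")
        if not 0 <= self.sign_concordance <= 1:
            raise SimConfigError("sign_concordance must lie in [0, 1]")
        if not 0 <= self.within_block_r2 < 1:
            raise SimConfigError("within_block_r2 must lie in [0, 1)")
        if self.ld_block_size < 1:
            raise SimConfigError("ld_block_size must be positive")
        if self.ld_block_size > 1 and self.n_snps < 2 * self.ld_block_size:
            raise SimConfigError("n_snps must be >= 2 * ld_block_size")
        if not 0 <= self.intergenic_fraction <= 1:
            raise SimConfigError("intergenic_fraction must lie in [0, 1]")

    @property
    def frac_null(self) -> float:
        return 1.0 - self.frac_shared - self.frac_spec1 - self.frac_spec2


TRUTH_COLUMNS = ["snp_id", "label", "delta1", "delta2", "concordant"]


@dataclass
class PanelSim:
    """Outputs of one simulation: two sumstats tables, the LD graph, gene
    intervals and the ground-truth table, all index-aligned."""

    sumstats1: pd.DataFrame
    sumstats2: pd.DataFrame
    ld: LdGraph
    genes: pd.DataFrame
    truth: pd.DataFrame


def _draw_effects(rng, labels, cfg: SimConfig):
    n = len(labels)
    delta1 = np.zeros(n)
    delta2 = np.zeros(n)
    concordant = np.full(n, np.nan)

    has1 = (labels == "shared") | (labels == "spec1")
    has2 = (labels == "shared") | (labels == "spec2")
    delta1[has1] = rng.normal(0.0, cfg.effect_sd1, has1.sum())
    delta2[has2] = rng.normal(0.0, cfg.effect_sd2, has2.sum())

    # Bernoulli flip of delta2's sign per shared SNP toward/away from delta1
    sh = labels == "shared"
    if sh.any():
        conc = rng.random(sh.sum()) < cfg.sign_concordance
        sign1 = np.where(delta1[sh] >= 0, 1.0, -1.0)
        mag2 = np.abs(delta2[sh])
        delta2[sh] = np.where(conc, sign1, -sign1) * mag2
        concordant[sh] = conc
    return delta1, delta2, concordant


def _block_slices(n, block_size, chrom_of):
    """Consecutive runs of ``block_size`` SNPs, never crossing a chromosome."""
    slices = []
    start = 0
    while start < n:
        end = min(start + block_size, n)
        while end > start + 1 and chrom_of[end - 1] != chrom_of[start]:
            end -= 1
        slices.append((start, end))
        start = end
    return slices


def _correlated_z(rng, delta, blocks, r):
    """z = R delta + eps with eps ~ N(0, R), R compound symmetric at r."""
    n = len(delta)
    e = rng.normal(size=n)
    z = np.empty(n)
    for (s, t) in blocks:
        d = delta[s:t]
        b = t - s
        if b == 1 or r == 0.0:
            z[s:t] = d + e[s:t]
            continue
        mu = d + r * (d.sum() - d)
        u = rng.normal()
        z[s:t] = mu + np.sqrt(r) * u + np.sqrt(1.0 - r) * e[s:t]
    return z


def _make_genes(rng, chrom, pos, intergenic_fraction):
    """Intervals covering ~(1 - intergenic_fraction) of SNPs.

    Each SNP is genic with that probability; consecutive genic SNPs on a
    chromosome merge into one interval spanning their positions, so
    intergenic SNPs sit strictly outside every interval."""
    n = len(pos)
    genic = rng.random(n) < (1.0 - intergenic_fraction)
    rows = []
    k = 0
    i = 0
    while i < n:
        if genic[i]:
            j = i
            while j + 1 < n and genic[j + 1] and chrom[j + 1] == chrom[i]:
                j += 1
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom[i], int(pos[i]), int(pos[j]),
                         f"GENE{k:05d}", strand))
            k += 1
            i = j + 1
        else:
            i += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                       "strand"])


def simulate_panel(config: SimConfig) -> PanelSim:
    """Generate one paired-GWAS panel under the causal-mixture model.

    Identical ``(config, seed)`` gives byte-identical outputs.  Two-sided
    p-values satisfy p = 2*Phi(-|z|) at every SNP.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps

    snp_id = np.array([f"rs{i:08d}" for i in range(n)], dtype=object)
    per_chrom = int(np.ceil(n / cfg.n_chromosomes))
    chrom = np.array([str(1 + i // per_chrom) for i in range(n)], dtype=object)
    gaps = rng.integers(500, 5000, size=n)
    pos = np.empty(n, dtype=np.int64)
    for c in pd.unique(chrom):
        m = chrom == c
        pos[m] = np.cumsum(gaps[m]) + 10_000

    labels = np.asarray(rng.choice(
        ["null", "shared", "spec1", "spec2"], size=n,
        p=[cfg.frac_null, cfg.frac_shared, cfg.frac_spec1, cfg.frac_spec2]),
        dtype=object)
    delta1, delta2, concordant = _draw_effects(rng, labels, cfg)

    blocks = (_block_slices(n, cfg.ld_block_size, chrom)
              if cfg.ld_block_size > 1 else [(i, i + 1) for i in range(n)])
    r = float(np.sqrt(cfg.within_block_r2))
    z1 = _correlated_z(rng, delta1, blocks, r)
    z2 = _correlated_z(rng, delta2, blocks, r)
    p1 = p_from_z(z1)
    p2 = p_from_z(z2)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx], dtype=object)
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx], dtype=object)

    ld = LdGraph()
    if cfg.within_block_r2 > 0 and cfg.ld_block_size > 1:
        for (s, t) in blocks:
            for i in range(s, t):
                for j in range(i + 1, t):
                    ld.add_pair(snp_id[i], snp_id[j], cfg.within_block_r2)

    genes = _make_genes(rng, chrom, pos, cfg.intergenic_fraction)

    def table(z, p, n_samples):
        return pd.DataFrame({
            "snp_id": snp_id, "chrom": chrom, "pos": pos,
            "a1": a1, "a2": a2, "p": p, "z": z,
            "n": np.full(n, n_samples, dtype=np.int64),
        })

    truth = pd.DataFrame({
        "snp_id": snp_id, "label": labels,
        "delta1": delta1, "delta2": delta2, "concordant": concordant,
    })
    return PanelSim(sumstats1=table(z1, p1, cfg.n_samples1),
                    sumstats2=table(z2, p2, cfg.n_samples2),
                    ld=ld, genes=genes, truth=truth)


def truth_fdp(discovery_calls, truth: pd.DataFrame, target_class) -> float:
    """Empirical false-discovery proportion of a call set.

    Fraction of called SNPs whose true label is outside ``target_class``;
    0 for an empty call set.  Unknown SNP ids raise ``KeyError``.
    """
    calls = list(discovery_calls)
    if not calls:
        return 0.0
    target = {target_class} if isinstance(target_class, str) else set(target_class)
    label_of = dict(zip(truth["snp_id"], truth["label"]))
    unknown = [s for s in calls if s not in label_of]
    if unknown:
        raise KeyError(f"unknown SNP id(s) in call set: {unknown[:5]}")
    n_false = sum(label_of[s] not in target for s in calls)
    return n_false / len(calls)


def write_panel(sim: PanelSim, outdir, dialect: Dialect = DEFAULT_DIALECT) -> dict:
    """Write all five artifacts (TSV sumstats x2, .ld pairs, BED genes,
    truth TSV) and return the path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sumstats1": outdir / "trait1.sumstats.tsv",
        "sumstats2": outdir / "trait2.sumstats.tsv",
        "ld": outdir / "panel.ld",
        "genes": outdir / "genes.bed",
        "truth": outdir / "truth.tsv",
    }
    write_sumstats(sim.sumstats1, paths["sumstats1"], dialect)
    write_sumstats(sim.sumstats2, paths["sumstats2"], dialect)
    write_ld_pairs(sim.ld, sim.sumstats1, paths["ld"])
    write_bed(sim.genes, paths["genes"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
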