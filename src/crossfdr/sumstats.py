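"""Reading, validation and harmonization of GWAS summary statistics.

Two per-trait association tables are brought onto a shared, allele-aligned
SNP panel so that the signed z-scores of both traits refer to the same
effect allele.  Strand-ambiguous variants (A/T, C/G) are dropped because
their orientation cannot be resolved from summary data alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

#: smallest p-value carried through the pipeline; avoids infinite -log10 p
P_FLOOR = 1e-300

#: tolerance on |z_reported - z_from_p| before the p-value wins
Z_CONSISTENCY_TOL = 0.05

VALID_ALLELES = frozenset("ACGT")
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

CANONICAL_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2", "p", "z", "n"]


class SumstatsFormatError(ValueError):
    """A required column is missing or the file is unusable."""


class EmptyPanelError(ValueError):
    """No valid rows survived validation, or an empty intersection."""


def signed_z_from_p(p, direction):
    """Two-sided p-value and effect direction to a signed z-score.

    z = sign(direction) * Phi^-1(1 - p/2).  ``p`` must lie in (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    z = norm.isf(p / 2.0)
    return z * np.sign(direction)


def p_from_z(z):
    """Two-sided p-value of a signed z-score: p = 2 * Phi(-|z|)."""
    p = 2.0 * norm.sf(np.abs(np.asarray(z, dtype=float)))
    return np.clip(p, P_FLOOR, 1.0)


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for a summary-statistics file.

    ``z`` may be absent if ``beta`` and ``se`` are given (z = beta / se),
    or if only ``p`` is present (z is then recovered from p with + sign).
    """

    snp_id: str = "SNP"
    chrom: str = "CHR"
    pos: str = "BP"
    a1: str = "A1"
    a2: str = "A2"
    p: str = "P"
    z: str | None = "Z"
    beta: str | None = None
    se: str | None = None
    n: str | None = "N"
    sep: str = "\t"


DEFAULT_DIALECT = Dialect()


@dataclass
class SumStatRecord:
    """One SNP's association summary for one trait."""

    snp_id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    p: float
    z: float
    n: int


def read_sumstats(path, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read one trait's summary statistics into the canonical table.

    Returns a DataFrame with columns ``snp_id, chrom, pos, a1, a2, p, z, n``.
    Rows with p outside (0, 1], missing/invalid alleles, or unparseable
    numeric fields are dropped and the counts logged.  Duplicate ``snp_id``
    keeps the record with the larger sample size.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    required = [dialect.snp_id, dialect.chrom, dialect.pos, dialect.a1,
                dialect.a2, dialect.p]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"missing required column(s) {missing} in {path}")

    out = pd.DataFrame({
        "snp_id": df[dialect.snp_id].astype(str),
        "chrom": df[dialect.chrom].astype(str),
        "pos": pd.to_numeric(df[dialect.pos], errors="coerce"),
        "a1": df[dialect.a1].astype(str).str.upper(),
        "a2": df[dialect.a2].astype(str).str.upper(),
        "p": pd.to_numeric(df[dialect.p], errors="coerce"),
    })

    if dialect.z is not None and dialect.z in df.columns:
        out["z"] = pd.to_numeric(df[dialect.z], errors="coerce")
    elif dialect.beta and dialect.se and dialect.beta in df.columns:
        beta = pd.to_numeric(df[dialect.beta], errors="coerce")
        se = pd.to_numeric(df[dialect.se], errors="coerce")
        out["z"] = beta / se
    else:
        out["z"] = np.nan

    if dialect.n is not None and dialect.n in df.columns:
        out["n"] = pd.to_numeric(df[dialect.n], errors="coerce")
    else:
        out["n"] = 0

    n_raw = len(out)
    valid_allele = (out["a1"].isin(VALID_ALLELES) & out["a2"].isin(VALID_ALLELES)
                    & (out["a1"] != out["a2"]))
    valid_p = out["p"].notna() & (out["p"] > 0) & (out["p"] <= 1)
    valid_pos = out["pos"].notna() & (out["pos"] > 0)
    keep = valid_allele & valid_p & valid_pos
    n_dropped = int(n_raw - keep.sum())
    if n_dropped:
        logger.info("read_sumstats(%s): dropped %d/%d invalid rows",
                    path, n_dropped, n_raw)
    out = out.loc[keep].copy()
    if out.empty:
        raise EmptyPanelError(f"no valid rows in {path}")

    out["pos"] = out["pos"].astype(np.int64)
    out["n"] = out["n"].fillna(0).astype(np.int64)
    out["p"] = out["p"].clip(lower=P_FLOOR)

    # fill/reconcile z against p; p wins when the two disagree materially
    z_from_p = signed_z_from_p(out["p"].to_numpy(), 1.0)
    have_z = out["z"].notna().to_numpy()
    z = out["z"].to_numpy(dtype=float)
    sign = np.where(np.signbit(z) & have_z, -1.0, 1.0)
    inconsistent = have_z & (np.abs(np.abs(z) - z_from_p) > Z_CONSISTENCY_TOL)
    n_inc = int(inconsistent.sum())
    if n_inc:
        logger.info("read_sumstats(%s): %d rows with |z| inconsistent with p; "
                    "recomputed z from p keeping the reported sign", path, n_inc)
    z = np.where(have_z & ~inconsistent, z, sign * z_from_p)
    out["z"] = z

    # duplicate ids: keep largest n
    if out["snp_id"].duplicated().any():
        n_dup = int(out["snp_id"].duplicated().sum())
        logger.info("read_sumstats(%s): %d duplicated snp_id rows, keeping "
                    "largest n", path, n_dup)
        out = (out.sort_values("n", kind="stable")
                  .drop_duplicates("snp_id", keep="last"))

    return out.reset_index(drop=True)[CANONICAL_COLUMNS]


def write_sumstats(df: pd.DataFrame, path, dialect: Dialect = DEFAULT_DIALECT):
    """Write a canonical table back to disk under the dialect's headers."""
    cols = {
        dialect.snp_id: df["snp_id"], dialect.chrom: df["chrom"],
        dialect.pos: df["pos"], dialect.a1: df["a1"], dialect.a2: df["a2"],
        dialect.p: df["p"],
    }
    if dialect.z is not None:
        cols[dialect.z] = df["z"]
    if dialect.n is not None:
        cols[dialect.n] = df["n"]
    pd.DataFrame(cols).to_csv(path, sep=dialect.sep, index=False)


HARMONIZED_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2",
                      "p1", "z1", "p2", "z2", "n1", "n2", "flag"]


def harmonize(t1: pd.DataFrame, t2: pd.DataFrame) -> pd.DataFrame:
    """Align two canonical tables onto a shared allele-matched panel.

    Intersects on ``snp_id``; when trait 2 reports swapped alleles the sign
    of z2 is flipped (flag ``allele_flipped``); strand-ambiguous pairs and
    irreconcilable allele sets are dropped.  Chromosome/position are taken
    from trait 1.
    """
    if t1.empty or t2.empty:
        raise EmptyPanelError("cannot harmonize an empty panel")
    m = t1.merge(t2, on="snp_id", suffixes=("_1", "_2"), how="inner")
    if m.empty:
        raise EmptyPanelError("no SNPs shared between the two panels")

    a1_1, a2_1 = m["a1_1"].to_numpy(), m["a2_1"].to_numpy()
    a1_2, a2_2 = m["a1_2"].to_numpy(), m["a2_2"].to_numpy()

    ambiguous = np.array([(a, b) in AMBIGUOUS_PAIRS for a, b in zip(a1_1, a2_1)])
    direct = (a1_1 == a1_2) & (a2_1 == a2_2)
    swapped = (a1_1 == a2_2) & (a2_1 == a1_2)

    flag = np.where(ambiguous, "dropped_ambiguous",
                    np.where(direct, "direct",
                             np.where(swapped, "allele_flipped",
                                      "dropped_mismatch")))
    keep = (flag == "direct") | (flag == "allele_flipped")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("harmonize: dropped %d SNPs (ambiguous or mismatched "
                    "alleles)", n_drop)

    z2 = np.where(flag == "allele_flipped", -m["z_2"].to_numpy(),
                  m["z_2"].to_numpy())
    out = pd.DataFrame({
        "snp_id": m["snp_id"], "chrom": m["chrom_1"], "pos": m["pos_1"],
        "a1": a1_1, "a2": a2_1,
        "p1": m["p_1"], "z1": m["z_1"], "p2": m["p_2"], "z2": z2,
        "n1": m["n_1"], "n2": m["n_2"], "flag": flag,
    })
    out = out.loc[keep].reset_index(drop=True)
    if out.empty:
        raise EmptyPanelError("all shared SNPs dropped during harmonization")
    return out[HARMONIZED_COLUMNS]


def split_harmonized(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project a harmonized panel back into two canonical per-trait tables."""
    def view(k):
        return pd.DataFrame({
            "snp_id": pairs["snp_id"], "chrom": pairs["chrom"],
            "pos": pairs["pos"], "a1": pairs["a1"], "a2": pairs["a2"],
            "p": pairs[f"p{k}"], "z": pairs[f"z{k}"], "n": pairs[f"n{k}"],
        })
    return view(1), view(2)


def write_harmonized(pairs: pd.DataFrame, path):
    pairs.to_csv(path, sep="\t", index=False)


def read_harmonized(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
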