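"""Thresholding, LD clumping into independent loci, and annotation.

Significant SNPs (condFDR < 0.01 per direction, conjFDR < 0.05 for joint
association, strict inequalities) are grouped into independent loci as
connected components of the r^2 > 0.1 subgraph induced on the call set;
the lead SNP is the member with the smallest FDR (ties broken by smaller
p, then smaller position).  Loci are annotated with allelic direction of
effect in both traits, the nearest gene, and a flag for variants already
genome-wide significant (p < 5e-8) in the original scan — such variants
are not novel by this criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .ld import LdGraph


@dataclass(frozen=True)
class DiscoveryConfig:
    cond_threshold: float = 0.01
    conj_threshold: float = 0.05
    clump_r2: float = 0.1
    gws_p: float = 5e-8

    def __post_init__(self):
        for v in (self.cond_threshold, self.conj_threshold, self.clump_r2,
                  self.gws_p):
            if not 0 < v < 1:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class Locus:
    """One independent locus from clumping."""

    lead: str
    members: list
    chrom: str
    start: int
    end: int
    lead_fdr: float
    direction: str = ""
    gene: str = ""
    gene_relation: str = ""


@dataclass
class CallSets:
    """SNP ids passing each threshold (sets may overlap)."""

    cond_1given2: set
    cond_2given1: set
    conjunction: set


def threshold_calls(results: pd.DataFrame,
                    config: DiscoveryConfig = DiscoveryConfig()) -> CallSets:
    """Strict-inequality calls at the conditional and conjunctional
    thresholds."""
    ids = results["snp_id"]
    return CallSets(
        cond_1given2=set(ids[results["condfdr_1given2"] < config.cond_threshold]),
        cond_2given1=set(ids[results["condfdr_2given1"] < config.cond_threshold]),
        conjunction=set(ids[results["conjfdr"] < config.conj_threshold]),
    )


def clump_loci(calls, graph: LdGraph, results: pd.DataFrame,
               config: DiscoveryConfig = DiscoveryConfig(),
               fdr_col: str = "conjfdr") -> list[Locus]:
    """Group called SNPs into independent loci.

    Loci are the connected components of the r^2 > ``clump_r2`` subgraph
    induced on the call set; each SNP belongs to exactly one locus.  The
    lead SNP minimises (fdr, p1, pos) within the locus.
    """
    calls = set(calls)
    if not calls:
        return []
    sub = results.set_index("snp_id").loc[sorted(calls)]
    g = nx.Graph()
    g.add_nodes_from(calls)
    for s in calls:
        for t, r2 in graph.neighbors(s, min_r2=config.clump_r2).items():
            if t in calls:
                g.add_edge(s, t)
    loci = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        rows = sub.loc[members]
        key = list(zip(rows[fdr_col], rows["p1"], rows["pos"]))
        lead = members[int(np.lexsort(([r[2] for r in key],
                                       [r[1] for r in key],
                                       [r[0] for r in key]))[0])]
        loci.append(Locus(
            lead=lead, members=members,
            chrom=str(rows["chrom"].iloc[0]),
            start=int(rows["pos"].min()), end=int(rows["pos"].max()),
            lead_fdr=float(sub.loc[lead, fdr_col]),
        ))
    loci.sort(key=lambda l: (l.chrom, l.start))
    return loci


def annotate_direction(z1: float, z2: float) -> str:
    """Allelic direction of effect in both traits, e.g. '+/+' or '-/+'."""
    def s(z):
        return "0" if z == 0 else ("+" if z > 0 else "-")
    return f"{s(z1)}/{s(z2)}"


def nearest_gene(chrom, pos, genes: pd.DataFrame) -> tuple[str, str]:
    """Nearest gene to a position and the positional relation to it.

    Returns ``(name, relation)`` with relation 'intronic' when the
    position lies inside the gene body, otherwise 'upstream'/'downstream'
    relative to the gene's strand; ('', 'intergenic') when the chromosome
    carries no genes.  Ties go to the gene with the smaller start.
    """
    sub = genes[genes["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        return "", "intergenic"
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    dist = np.maximum(start - pos, 0) + np.maximum(pos - end, 0)
    order = np.lexsort((start, dist))
    k = order[0]
    row = sub.iloc[k]
    if dist[k] == 0:
        return row["name"], "intronic"
    plus = row.get("strand", "+") == "+"
    before = pos < row["start"]
    relation = "upstream" if before == plus else "downstream"
    return row["name"], relation


def flag_gws(p_original: float,
             config: DiscoveryConfig = DiscoveryConfig()) -> bool:
    """True when the variant was already genome-wide significant
    (p < 5e-8, strict) in the original scan."""
    if not 0 < p_original <= 1:
        raise ValueError("p must lie in (0, 1]")
    return p_original < config.gws_p


def manhattan_data(results: pd.DataFrame, loci: list[Locus],
                   fdr_col: str = "conjfdr") -> pd.DataFrame:
    """Per-SNP plot table: chrom, pos, -log10 FDR, locus id, lead flag."""
    locus_of = {}
    lead_of = {}
    for k, loc in enumerate(loci):
        for s in loc.members:
            locus_of[s] = k
        lead_of[loc.lead] = True
    out = results[["snp_id", "chrom", "pos"]].copy()
    out["neglog10_fdr"] = -np.log10(results[fdr_col].clip(lower=1e-300))
    out["locus"] = results["snp_id"].map(lambda s: locus_of.get(s, -1)).astype(int)
    out["is_lead"] = results["snp_id"].isin(lead_of).to_numpy()
    return out


LOCI_COLUMNS = ["snp_id", "chrom", "pos", "closest_gene", "gene_relation",
                "p1", "p2", "fdr", "alleles", "direction",
                "gws_trait1", "gws_trait2", "ldlink_check", "pubmed_check"]


def loci_table(loci: list[Locus], results: pd.DataFrame, genes: pd.DataFrame,
               pairs: pd.DataFrame,
               config: DiscoveryConfig = DiscoveryConfig(),
               fdr_col: str = "conjfdr") -> pd.DataFrame:
    """Per-locus summary table (lead SNP per row) with gene annotation,
    allele pair, direction of effect and novelty flags.

    LDlink and PubMed cross-checks are manual follow-up steps; the columns
    carry a placeholder, never an automated query result.
    """
    res = results.set_index("snp_id")
    alle = pairs.set_index("snp_id")[["a1", "a2"]]
    rows = []
    for loc in loci:
        r = res.loc[loc.lead]
        gene, relation = nearest_gene(loc.chrom, int(r["pos"]), genes)
        rows.append({
            "snp_id": loc.lead, "chrom": loc.chrom, "pos": int(r["pos"]),
            "closest_gene": gene, "gene_relation": relation,
            "p1": float(r["p1"]), "p2": float(r["p2"]),
            "fdr": float(r[fdr_col]),
            "alleles": f"{alle.loc[loc.lead, 'a1']}/{alle.loc[loc.lead, 'a2']}",
            "direction": annotate_direction(float(r["z1"]), float(r["z2"])),
            "gws_trait1": flag_gws(float(r["p1"]), config),
            "gws_trait2": flag_gws(float(r["p2"]), config),
            "ldlink_check": "manual", "pubmed_check": "manual",
        })
    return pd.DataFrame(rows, columns=LOCI_COLUMNS)
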