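"""End-to-end orchestration of the cross-trait FDR analysis.

read -> harmonize -> exclude regions -> prune -> genomic-control correct
-> conditional QQ -> ECDF lookups -> condFDR both directions -> conjFDR
-> threshold -> clump -> annotate -> write, all driven by one
configuration with a recorded seed and per-stage row counts in the output
manifest.  Settings that stand in for choices the method leaves open
(strata cutoffs, grid resolution, pi0, sparse-cell minimum) are marked
"decision" in the manifest so their provenance is explicit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cfdr import CfdrConfig, build_lookup, score_panel
from .discovery import (DiscoveryConfig, clump_loci, loci_table,
                        manhattan_data, threshold_calls)
from .enrichment import (QqConfig, apply_inflation, conditional_qq,
                         inflation_factor)
from .ld import (DEFAULT_EXCLUSION_REGIONS, apply_exclusions,
                 intergenic_independent, load_ld_pairs, random_prune,
                 read_bed)
from .simulate import SimConfig, simulate_panel, write_panel
from .sumstats import (DEFAULT_DIALECT, Dialect, harmonize, read_sumstats,
                       split_harmonized, write_harmonized)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything one analysis run needs."""

    sumstats1: str = ""
    sumstats2: str = ""
    ld_table: str = ""
    gene_bed: str = ""
    outdir: str = "crossfdr_out"
    dialect1: Dialect = field(default_factory=Dialect)
    dialect2: Dialect = field(default_factory=Dialect)
    exclusion_regions: tuple = DEFAULT_EXCLUSION_REGIONS
    qq: QqConfig = field(default_factory=QqConfig)
    cfdr: CfdrConfig = field(default_factory=CfdrConfig)
    discovery: DiscoveryConfig = field(default_factory=DiscoveryConfig)
    n_iter: int = 200
    seed: int = 0
    clamp_lambda: bool = False
    min_intergenic: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub in (("dialect1", Dialect), ("dialect2", Dialect),
                         ("qq", QqConfig), ("cfdr", CfdrConfig),
                         ("discovery", DiscoveryConfig)):
            if key in raw:
                val = raw.pop(key)
                if key == "qq" and "strata_thresholds" in val:
                    val["strata_thresholds"] = tuple(val["strata_thresholds"])
                kwargs[key] = sub(**val)
        if "exclusion_regions" in raw:
            raw["exclusion_regions"] = tuple(raw["exclusion_regions"])
        kwargs.update(raw)
        return cls(**kwargs)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns (and writes) the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}

    t1 = _stage("read_trait1")(read_sumstats)(config.sumstats1, config.dialect1)
    t2 = _stage("read_trait2")(read_sumstats)(config.sumstats2, config.dialect2)
    counts["trait1_rows"] = len(t1)
    counts["trait2_rows"] = len(t2)

    pairs = _stage("harmonize")(harmonize)(t1, t2)
    counts["harmonized"] = len(pairs)

    graph = _stage("load_ld")(load_ld_pairs)(config.ld_table)
    genes = _stage("load_genes")(read_bed)(config.gene_bed)

    pairs = _stage("exclusions")(apply_exclusions)(
        pairs, config.exclusion_regions, graph)
    counts["after_exclusions"] = len(pairs)

    ensemble = _stage("pruning")(random_prune)(
        graph, pairs["snp_id"], n_iter=config.n_iter, seed=config.seed)
    counts["pruning_masks_unique"] = ensemble.n_unique
    counts["mean_mask_size"] = float(np.mean(
        [m.sum() for m in ensemble.masks]))

    inter = _stage("intergenic")(intergenic_independent)(
        pairs, genes, graph, seed=config.seed)
    counts["intergenic_independent"] = len(inter)
    sel = pairs["snp_id"].isin(inter)
    lam1 = inflation_factor(pairs.loc[sel, "z1"], min_snps=config.min_intergenic)
    lam2 = inflation_factor(pairs.loc[sel, "z2"], min_snps=config.min_intergenic)
    pairs = _stage("inflation")(apply_inflation)(
        pairs, lam1, lam2, clamp=config.clamp_lambda)

    write_harmonized(pairs, out / "harmonized.tsv")

    rep1 = _stage("qq")(conditional_qq)(pairs, config.qq, ensemble, direction=1)
    rep2 = _stage("qq")(conditional_qq)(pairs, config.qq, ensemble, direction=2)
    rep1.lambda1, rep1.lambda2 = lam1, lam2
    rep1.to_frame().to_csv(out / "qq_trait1.tsv", sep="\t", index=False)
    rep2.to_frame().to_csv(out / "qq_trait2.tsv", sep="\t", index=False)

    lookup12 = _stage("lookup")(build_lookup)(pairs, ensemble, config.cfdr, 1)
    lookup21 = _stage("lookup")(build_lookup)(pairs, ensemble, config.cfdr, 2)
    lookup12.save(out / "lookup_1given2.npz")
    lookup21.save(out / "lookup_2given1.npz")

    results = _stage("score")(score_panel)(pairs, lookup12, lookup21,
                                           config.cfdr)
    results.to_csv(out / "fdr_results.tsv", sep="\t", index=False)

    calls = threshold_calls(results, config.discovery)
    counts["calls_cond_1given2"] = len(calls.cond_1given2)
    counts["calls_cond_2given1"] = len(calls.cond_2given1)
    counts["calls_conjunction"] = len(calls.conjunction)
    for name, ids in (("cond_1given2", calls.cond_1given2),
                      ("cond_2given1", calls.cond_2given1),
                      ("conjunction", calls.conjunction)):
        pd.Series(sorted(ids), name="snp_id").to_csv(
            out / f"calls_{name}.tsv", sep="\t", index=False)

    tables = {}
    for name, ids, col in (("cond_1given2", calls.cond_1given2, "condfdr_1given2"),
                           ("cond_2given1", calls.cond_2given1, "condfdr_2given1"),
                           ("conjunction", calls.conjunction, "conjfdr")):
        loci = _stage("clump")(clump_loci)(ids, graph, results,
                                           config.discovery, fdr_col=col)
        counts[f"loci_{name}"] = len(loci)
        tab = loci_table(loci, results, genes, pairs, config.discovery,
                         fdr_col=col)
        tab.to_csv(out / f"loci_{name}.tsv", sep="\t", index=False)
        manhattan_data(results, loci, fdr_col=col).to_csv(
            out / f"manhattan_{name}.tsv", sep="\t", index=False)
        tables[name] = tab

    decision_settings = {
        "qq_strata": list(config.qq.strata_thresholds),
        "cfdr_grid_step": config.cfdr.grid_step,
        "cfdr_pi0": config.cfdr.pi0,
        "min_stratum_count": config.cfdr.min_stratum_count,
        "clump_rule": "connected components at r2 > "
                      f"{config.discovery.clump_r2}",
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_iter": config.n_iter,
        "lambda1": lam1, "lambda2": lam2,
        "counts": counts,
        "settings_decision": decision_settings,
        "exclusion_regions": list(config.exclusion_regions),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %s", counts)
    return manifest


def simulate_command(sim_config: SimConfig, outdir) -> dict:
    """Generate a synthetic panel and write all five artifacts."""
    sim = simulate_panel(sim_config)
    paths = write_panel(sim, outdir)
    paths["n_snps"] = sim_config.n_snps
    return paths
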