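"""LD graph, random pruning, region exclusion and intergenic selection."""

import numpy as np
import pandas as pd
import pytest

from crossfdr.ld import (ExclusionRegion, LdFormatError, LdGraph,
                         apply_exclusions, intergenic_independent,
                         load_ld_pairs, random_prune, read_bed, write_bed)


class TestLdGraph:
    def test_load_pairs(self, tmp_path):
        f = tmp_path / "p.ld"
        f.write_text("CHR_A BP_A SNP_A CHR_B BP_B SNP_B R2\n"
                     "1 100 a 1 200 b 0.5\n"
                     "1 100 a 1 300 c 0.2\n"
                     "1 200 b 1 300 c 0.15\n")
        g = load_ld_pairs(f)
        assert g.n_edges == 3
        assert g.degree("a") == 2
        assert g.r2("b", "a") == 0.5  # symmetric access
        assert g.r2("a", "zzz") == 0.0

    def test_duplicate_keeps_max(self, tmp_path):
        f = tmp_path / "p.ld"
        f.write_text("SNP_A SNP_B R2\na b 0.3\na b 0.6\nb a 0.4\n")
        g = load_ld_pairs(f)
        assert g.r2("a", "b") == 0.6

    def test_invalid_r2_rejected(self, tmp_path):
        f = tmp_path / "p.ld"
        f.write_text("SNP_A SNP_B R2\na b 1.2\nb c 0.5\n")
        g = load_ld_pairs(f)
        assert g.n_edges == 1

    def test_self_edge_rejected(self):
        g = LdGraph()
        with pytest.raises(LdFormatError):
            g.add_pair("a", "a", 0.5)


class TestRandomPrune:
    def test_isolated_snp_always_kept(self, toy_graph):
        panel = ["a", "b", "c", "d", "e"]
        ens = random_prune(toy_graph, panel, n_iter=200, seed=1)
        freq = dict(zip(ens.panel, ens.keep_frequency()))
        assert freq["e"] == 1.0
        assert freq["d"] == 1.0  # only link is r2=0.05, below threshold

    def test_pair_above_threshold_exactly_one_kept(self):
        g = LdGraph()
        g.add_pair("a", "b", 0.2)
        ens = random_prune(g, ["a", "b"], n_iter=100, seed=0)
        for mask in ens.masks:
            assert mask.sum() == 1

    def test_masks_are_independent_and_maximal(self, toy_graph):
        panel = ["a", "b", "c", "d", "e"]
        ens = random_prune(toy_graph, panel, n_iter=50, seed=3)
        idx = {s: i for i, s in enumerate(ens.panel)}
        for mask in ens.masks:
            kept = {s for s in panel if mask[idx[s]]}
            for u, v, r2 in toy_graph.edges():
                if r2 > 0.1:
                    assert not ({u, v} <= kept)
            # maximality: every excluded SNP has a kept neighbour above thr
            for s in set(panel) - kept:
                nbrs = toy_graph.neighbors(s, min_r2=0.1)
                assert any(t in kept for t in nbrs)

    def test_three_clique_symmetric_frequencies(self):
        g = LdGraph()
        for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
            g.add_pair(u, v, 0.5)
        ens = random_prune(g, ["a", "b", "c"], n_iter=200, seed=7)
        freq = ens.keep_frequency()
        sd = np.sqrt((1 / 3) * (2 / 3) / 200)
        assert np.all(np.abs(freq - 1 / 3) < 3 * sd)

    def test_reproducible_and_seed_sensitive(self, toy_graph):
        panel = ["a", "b", "c", "d", "e"]
        e1 = random_prune(toy_graph, panel, n_iter=20, seed=9)
        e2 = random_prune(toy_graph, panel, n_iter=20, seed=9)
        e3 = random_prune(toy_graph, panel, n_iter=20, seed=10)
        assert all((a == b).all() for a, b in zip(e1.masks, e2.masks))
        assert (e1.weights != e3.weights).any() or any(
            (a != b).any() for a, b in zip(e1.masks, e3.masks))

    def test_mask_sizes_stable_on_block_panel(self, shared_panel,
                                              shared_pairs):
        ens = random_prune(shared_panel.ld, shared_pairs["snp_id"],
                           n_iter=30, seed=0)
        sizes = np.repeat([m.sum() for m in ens.masks], ens.weights)
        assert sizes.std() / sizes.mean() < 0.05

    def test_n_iter_validation(self, toy_graph):
        with pytest.raises(ValueError):
            random_prune(toy_graph, ["a"], n_iter=0, seed=0)


class TestExclusions:
    PANEL = pd.DataFrame({
        "snp_id": ["in_lo", "out_lo", "partner", "far", "in_apoe"],
        "chrom": ["6", "6", "6", "7", "19"],
        "pos": [25652429, 25652428, 40000000, 100, 44909039],
    })

    def test_boundary_and_ld_propagation(self):
        g = LdGraph()
        g.add_pair("in_lo", "partner", 0.3)   # LD partner of an excluded SNP
        regions = ["6:25652429-33368333", "19:44909039-45912650"]
        out = apply_exclusions(self.PANEL, regions, g)
        kept = set(out["snp_id"])
        assert kept == {"out_lo", "far"}

    def test_partner_below_threshold_survives(self):
        g = LdGraph()
        g.add_pair("in_lo", "partner", 0.05)
        out = apply_exclusions(self.PANEL, ["6:25652429-33368333"], g)
        assert "partner" in set(out["snp_id"])

    def test_empty_region_list_is_identity(self, toy_graph):
        out = apply_exclusions(self.PANEL, [], toy_graph)
        assert len(out) == len(self.PANEL)

    def test_region_parse(self):
        r = ExclusionRegion.from_string("chr19:44909039-45912650")
        assert (r.chrom, r.start, r.end) == ("19", 44909039, 45912650)
        with pytest.raises(ValueError):
            ExclusionRegion("1", 10, 5)

    def test_excluded_disjoint_from_region_neighbourhood(self, shared_panel,
                                                         shared_pairs):
        pos = shared_pairs["pos"]
        lo, hi = int(pos.quantile(0.4)), int(pos.quantile(0.5))
        region = f"1:{lo}-{hi}"
        out = apply_exclusions(shared_pairs, [region], shared_panel.ld)
        inside = (out["chrom"] == "1") & (out["pos"] >= lo) & (out["pos"] <= hi)
        assert not inside.any()
        removed_in = shared_pairs.loc[
            (shared_pairs["chrom"] == "1")
            & (shared_pairs["pos"].between(lo, hi)), "snp_id"]
        kept = set(out["snp_id"])
        for s in removed_in:
            for t in shared_panel.ld.neighbors(s, min_r2=0.1):
                assert t not in kept


class TestIntergenic:
    def test_gene_members_excluded_and_ld_thinned(self):
        panel = pd.DataFrame({
            "snp_id": ["g1", "i1", "i2", "i3"],
            "chrom": ["1"] * 4,
            "pos": [150, 500, 600, 900],
        })
        genes = pd.DataFrame({"chrom": ["1"], "start": [100], "end": [200],
                              "name": ["G"], "strand": ["+"]})
        g = LdGraph()
        g.add_pair("i1", "i2", 0.5)
        g.add_pair("i2", "i3", 0.05)
        sel = intergenic_independent(panel, genes, g, seed=0)
        assert "g1" not in sel
        assert "i3" in sel
        assert len({"i1", "i2"} & sel) == 1

    def test_bed_roundtrip(self, tmp_path, shared_panel):
        p = tmp_path / "genes.bed"
        write_bed(shared_panel.genes, p)
        back = read_bed(p)
        np.testing.assert_array_equal(back["start"], shared_panel.genes["start"])
        np.testing.assert_array_equal(back["end"], shared_panel.genes["end"])
        assert list(back["strand"]) == list(shared_panel.genes["strand"])
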