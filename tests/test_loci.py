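"""GWAS locus grouping, ranking, power matching and concordance."""

import numpy as np
import pandas as pd
import pytest

from specdrift.loci import (
    BURDEN_SIG_LOG10P,
    assign_genes,
    burden_gwas_overlap,
    filter_hits_by_maf,
    group_hits_into_loci,
    ld_block_compare,
    rank_loci,
    select_power_matched_top_loci,
)

MB = 1_000_000


def hits_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "log10p", "beta", "maf"])


def closure_oracle(positions, window):
    """Brute-force transitive closure: grow each locus from the most
    significant unassigned hit by repeatedly adding any hit within the
    window of any member."""
    order = np.argsort(positions["log10p"].to_numpy(), kind="stable")
    pos = positions["pos"].to_numpy()
    assigned = np.zeros(len(positions), dtype=bool)
    out = []
    for i in order:
        if assigned[i]:
            continue
        members = {i}
        assigned[i] = True
        changed = True
        while changed:
            changed = False
            for j in range(len(positions)):
                if assigned[j]:
                    continue
                if any(abs(pos[j] - pos[m]) <= window for m in members):
                    members.add(j)
                    assigned[j] = True
                    changed = True
        out.append(frozenset(pos[m] for m in members))
    return set(out)


class TestGrouping:
    def test_single_hit_span(self):
        loci = group_hits_into_loci(hits_df([("chr1", 10 * MB, -20.0, 0.1, 0.3)]))
        (loc,) = loci
        assert (loc.start, loc.end) == (9_500_000, 10_500_001)

    def test_two_loci_hand_trace(self):
        hits = hits_df(
            [
                ("chr1", 1 * MB, -20.0, 0.1, 0.3),
                ("chr1", int(1.5 * MB), -10.0, 0.1, 0.3),
                ("chr1", 3 * MB, -9.0, 0.1, 0.3),
            ]
        )
        loci = group_hits_into_loci(hits)
        spans = sorted(frozenset(l.hit_rows["pos"]) for l in loci)
        assert spans == [{1 * MB, int(1.5 * MB)}, {3 * MB}]

    def test_transitive_expansion_joins_chain(self):
        hits = hits_df(
            [
                ("chr1", 0, -30.0, 0.1, 0.3),
                ("chr1", int(0.9 * MB), -8.0, 0.1, 0.3),
                ("chr1", int(1.8 * MB), -12.0, 0.1, 0.3),
            ]
        )
        loci = group_hits_into_loci(hits)
        assert len(loci) == 1
        assert loci[0].n_hits == 3

    def test_matches_bruteforce_closure_on_random_configurations(self, rng):
        for _ in range(120):
            n = rng.integers(1, 25)
            hits = hits_df(
                [
                    ("chr1", int(p), float(lp), 0.1, 0.3)
                    for p, lp in zip(
                        rng.choice(20 * MB, size=n, replace=False),
                        -rng.uniform(8, 40, size=n),
                    )
                ]
            )
            got = {frozenset(l.hit_rows["pos"]) for l in group_hits_into_loci(hits)}
            assert got == closure_oracle(hits, MB)

    def test_order_invariance(self, rng):
        hits = hits_df(
            [
                ("chr1", int(p), float(lp), 0.1, 0.3)
                for p, lp in zip(
                    rng.choice(30 * MB, size=40, replace=False),
                    -rng.uniform(8, 40, size=40),
                )
            ]
        )
        base = {frozenset(l.hit_rows["pos"]) for l in group_hits_into_loci(hits)}
        for _ in range(5):
            shuf = hits.sample(frac=1.0, random_state=int(rng.integers(1e6)))
            assert {
                frozenset(l.hit_rows["pos"]) for l in group_hits_into_loci(shuf)
            } == base

    def test_no_cross_locus_proximity(self, rng):
        hits = hits_df(
            [
                ("chr2", int(p), float(lp), 0.1, 0.3)
                for p, lp in zip(
                    rng.choice(50 * MB, size=60, replace=False),
                    -rng.uniform(8, 30, size=60),
                )
            ]
        )
        loci = group_hits_into_loci(hits)
        for i, a in enumerate(loci):
            for b in loci[i + 1 :]:
                pa = a.hit_rows["pos"].to_numpy()[:, None]
                pb = b.hit_rows["pos"].to_numpy()[None, :]
                assert np.abs(pa - pb).min() > MB

    def test_duplicate_positions_rejected(self):
        hits = hits_df(
            [("chr1", 5, -9.0, 0.1, 0.3), ("chr1", 5, -10.0, 0.1, 0.3)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            group_hits_into_loci(hits)

    def test_empty_input_gives_empty_output(self):
        assert group_hits_into_loci(hits_df([])) == []


class TestGeneAssignment:
    def make_locus(self):
        return group_hits_into_loci(hits_df([("chr1", 10 * MB, -20.0, 0.1, 0.3)]))

    def test_contained_gene_assigned_and_boundary_excluded(self):
        loci = self.make_locus()
        genes = pd.DataFrame(
            {
                "gene_id": ["inside", "touching_start", "outside"],
                "chrom": ["chr1"] * 3,
                "start": [10 * MB, 9_400_000, 12 * MB],
                "end": [10 * MB + 1000, 9_500_000, 12 * MB + 1000],
            }
        )
        assign_genes(loci, genes)
        # half-open: a gene ending exactly at the span start does not overlap
        assert loci[0].genes == ["inside"]

    def test_matches_allpairs_overlap_oracle(self, rng):
        hits = hits_df(
            [
                ("chr1", int(p), float(lp), 0.1, 0.3)
                for p, lp in zip(
                    rng.choice(40 * MB, size=15, replace=False),
                    -rng.uniform(8, 30, size=15),
                )
            ]
        )
        loci = group_hits_into_loci(hits)
        starts = rng.choice(45 * MB, size=200, replace=False)
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(200)],
                "chrom": "chr1",
                "start": starts,
                "end": starts + rng.integers(1000, 200_000, size=200),
            }
        )
        assign_genes(loci, genes)
        for loc in loci:
            expect = [
                g.gene_id
                for g in genes.itertuples()
                if g.start < loc.end and g.end > loc.start
            ]
            assert sorted(loc.genes) == sorted(expect)


class TestRanking:
    def two_loci(self):
        hits = hits_df(
            [
                ("chr1", 1 * MB, -20.0, 0.05, 0.3),
                ("chr1", 10 * MB, -10.0, 0.50, 0.3),
            ]
        )
        return group_hits_into_loci(hits)

    def test_min_p_ranking(self):
        ranked = rank_loci(self.two_loci(), mode="min_p")
        assert [l.min_log10p for l in ranked] == [-20.0, -10.0]
        assert [l.rank for l in ranked] == [1, 2]

    def test_effect_mode_reverses_order(self):
        ranked = rank_loci(self.two_loci(), mode="max_abs_beta_significant")
        assert [l.min_log10p for l in ranked] == [-10.0, -20.0]

    def test_effect_mode_drops_loci_without_significant_members(self):
        hits = hits_df(
            [("chr1", 1 * MB, -20.0, 0.05, 0.3), ("chr1", 10 * MB, -6.0, 0.5, 0.3)]
        )
        ranked = rank_loci(group_hits_into_loci(hits), mode="max_abs_beta_significant")
        assert len(ranked) == 1

    def test_matches_sort_oracle(self, rng):
        hits = hits_df(
            [
                ("chr1", int(p), float(lp), float(b), 0.3)
                for p, lp, b in zip(
                    rng.choice(80 * MB, size=30, replace=False),
                    -rng.uniform(8, 30, size=30),
                    rng.normal(size=30),
                )
            ]
        )
        ranked = rank_loci(group_hits_into_loci(hits), mode="min_p")
        keys = [(l.min_log10p, l.chrom, l.start) for l in ranked]
        assert keys == sorted(keys)


class TestPowerMatching:
    def build(self, rng, n_hits=40, n_genes=120):
        hits = hits_df(
            [
                ("chr1", int(p), float(lp), 0.1, 0.3)
                for p, lp in zip(
                    rng.choice(100 * MB, size=n_hits, replace=False),
                    -rng.uniform(8, 40, size=n_hits),
                )
            ]
        )
        loci = rank_loci(group_hits_into_loci(hits))
        starts = rng.choice(100 * MB, size=n_genes, replace=False)
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n_genes)],
                "chrom": "chr1",
                "start": starts,
                "end": starts + 50_000,
            }
        )
        assign_genes(loci, genes)
        burden = pd.DataFrame(
            {
                "gene_id": genes["gene_id"],
                "log10p": -rng.uniform(0, 12, size=n_genes),
            }
        )
        return loci, burden

    def test_zero_target_selects_nothing(self):
        burden = pd.DataFrame({"gene_id": ["a"], "log10p": [-1.0]})
        assert select_power_matched_top_loci([], burden) == ([], [])

    def test_first_loci_supply_significant_genes(self, rng):
        loci, _ = self.build(rng)
        with_genes = [loc for loc in loci if loc.genes][:3]
        assert len(with_genes) >= 2
        sig_genes = [loc.genes[0] for loc in with_genes[:2]]
        burden = pd.DataFrame(
            {"gene_id": sig_genes, "log10p": [BURDEN_SIG_LOG10P - 1.0] * 2}
        )
        chosen_loci, chosen_genes = select_power_matched_top_loci(loci, burden)
        assert set(sig_genes) <= set(chosen_genes)
        assert len(chosen_genes) >= 2

    def test_matches_literal_procedural_oracle(self, rng):
        for _ in range(25):
            loci, burden = self.build(rng)
            got_loci, got_genes = select_power_matched_top_loci(loci, burden)
            # literal re-execution of the selection walk
            btab = burden.set_index("gene_id")["log10p"]
            target = int((btab < BURDEN_SIG_LOG10P).sum())
            exp_genes, seen = [], set()
            exp_loci = []
            for loc in got_loci + [l for l in loci if l not in got_loci]:
                if len(exp_genes) >= target:
                    break
                members = [g for g in loc.genes if g not in seen]
                if not members:
                    continue
                sig = [g for g in members if btab.get(g, 0.0) < BURDEN_SIG_LOG10P]
                take = sig if sig else [min(members, key=lambda g: (btab.get(g, 0.0), g))]
                exp_loci.append(loc)
                for g in take:
                    seen.add(g)
                    exp_genes.append(g)
            assert got_genes == exp_genes
            # selection never takes more loci than targets plus a terminal one
            assert len(got_loci) <= target + 1


class TestOverlapAndBlocks:
    def test_concordant_world_gives_full_overlap(self):
        hits = hits_df([("chr1", 10 * MB, -30.0, 0.1, 0.3)])
        loci = rank_loci(group_hits_into_loci(hits))
        genes = pd.DataFrame(
            {"gene_id": ["g0"], "chrom": ["chr1"], "start": [10 * MB], "end": [10 * MB + 10]}
        )
        assign_genes(loci, genes)
        res = burden_gwas_overlap(["g0"], loci, top_loci=loci)
        assert res["fraction_in_any_locus"] == 1.0
        assert res["fraction_in_top_loci"] == 1.0

    def test_disjoint_world_gives_zero_overlap(self):
        hits = hits_df([("chr1", 10 * MB, -30.0, 0.1, 0.3)])
        loci = rank_loci(group_hits_into_loci(hits))
        assign_genes(
            loci,
            pd.DataFrame(
                {"gene_id": ["g0"], "chrom": ["chr2"], "start": [0], "end": [10]}
            ),
        )
        res = burden_gwas_overlap(["g0"], loci, top_loci=[])
        assert res["fraction_in_any_locus"] == 0.0
        assert res["rank_pairs"]["locus_rank"].isna().all()

    def test_planted_fraction_recovered(self, rng):
        inside = [f"in{i}" for i in range(60)]
        outside = [f"out{i}" for i in range(40)]
        hits = hits_df([("chr1", 10 * MB, -30.0, 0.1, 0.3)])
        loci = rank_loci(group_hits_into_loci(hits))
        loci[0].genes = inside
        res = burden_gwas_overlap(inside + outside, loci)
        assert res["fraction_in_any_locus"] == pytest.approx(0.6)

    def test_block_minima_and_shared_gene_drop(self):
        blocks = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "start": [0, MB, 2 * MB], "end": [MB, 2 * MB, 3 * MB]}
        )
        hits = hits_df(
            [("chr1", 100, -9.0, 0.1, 0.3), ("chr1", MB + 5, -22.0, 0.1, 0.3)]
        )
        genes = pd.DataFrame(
            {
                "gene_id": ["span01", "only2"],
                "chrom": ["chr1"] * 2,
                "start": [MB - 10, 2 * MB + 5],
                "end": [MB + 10, 2 * MB + 500],
            }
        )
        burden = pd.DataFrame(
            {"gene_id": ["span01", "only2"], "log10p": [-15.0, -3.0]}
        )
        out = ld_block_compare(blocks, hits, burden, genes)
        # the gene spanning blocks 0 and 1 minimizes both -> both dropped
        assert out["dropped"].tolist() == [True, True, False]
        assert out.loc[0, "min_gwas_log10p"] == -9.0
        assert out.loc[1, "min_gwas_log10p"] == -22.0

    def test_overlapping_blocks_rejected(self):
        blocks = pd.DataFrame(
            {"chrom": ["chr1"] * 2, "start": [0, MB - 10], "end": [MB, 2 * MB]}
        )
        with pytest.raises(ValueError, match="overlap"):
            ld_block_compare(blocks, hits_df([]), pd.DataFrame({"gene_id": [], "log10p": []}), pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]))


class TestMafFilter:
    def test_threshold_inclusive_and_full_range(self, rng):
        hits = hits_df(
            [
                ("chr1", i, -9.0, 0.1, m)
                for i, m in enumerate([0.005, 0.01, 0.1, 0.49, 0.5])
            ]
        )
        assert len(filter_hits_by_maf(hits, 0.5)) == 5  # keeps everything
        kept = filter_hits_by_maf(hits, 0.01)
        assert kept["maf"].tolist() == [0.005, 0.01]  # boundary kept

    def test_matches_predicate_scan(self, rng):
        mafs = rng.uniform(0, 0.5, size=300)
        hits = hits_df(
            [("chr1", i, -9.0, 0.1, float(m)) for i, m in enumerate(mafs)]
        )
        thr = 0.123
        assert set(filter_hits_by_maf(hits, thr)["pos"]) == {
            i for i, m in enumerate(mafs) if m <= thr
        }

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            filter_hits_by_maf(hits_df([]), 0.6)
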