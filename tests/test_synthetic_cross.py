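"""The F2-cross simulator and the deterministic packaged fixture."""

import numpy as np
import pytest

from vdmap import CrossConfig, build_packaged_fixture, simulate_haplotype
from vdmap.effect_annotation import CODON_TABLE
from vdmap.synthetic_cross import (
    MUTAGENIZED,
    _draw_embryo,
    _stream,
    simulate_pools,
    simulate_variant_table,
    snp_panel,
)
from vdmap.zygosity_mapping import assign_zygosity


@pytest.fixture()
def single_chrom_config():
    return CrossConfig(seed=11, chrom_lengths={"chr14": 54_000_000})


class TestHaplotypes:
    def test_segments_tile_chromosome(self, default_config):
        rng = _stream(3, 1)
        for _ in range(50):
            h = simulate_haplotype("chr14", default_config, rng)
            assert h.segments[0][0] == 1
            assert h.length == default_config.chrom_lengths["chr14"]
            # gap-free tiling and alternating parents are enforced by the
            # constructor; re-check the boundary arithmetic explicitly
            for (s1, e1, _), (s2, _, _) in zip(h.segments, h.segments[1:]):
                assert s2 == e1 + 1

    def test_zero_map_length_gives_single_segment(self):
        cfg = CrossConfig(seed=5, map_length=0.0)
        rng = _stream(5, 1)
        h = simulate_haplotype("chr14", cfg, rng)
        assert len(h.segments) == 1

    def test_poisson_crossover_mean(self, default_config):
        # Monte-Carlo check of the Poisson(map_length) crossover count
        rng = _stream(17, 1)
        counts = [
            len(simulate_haplotype("chr14", default_config, rng).segments) - 1
            for _ in range(10_000)
        ]
        assert np.mean(counts) == pytest.approx(1.0, abs=0.03)


class TestPools:
    def test_mendelian_mutant_fraction(self, single_chrom_config):
        # recessive segregation: 1/4 mutants, 2/3 of siblings heterozygous
        rng = _stream(11, 9)
        chrom, pos = single_chrom_config.causal_locus
        n_mut = n_het = n_non = 0
        for _ in range(10_000):
            e = _draw_embryo(single_chrom_config, rng)
            h1, h2 = e.haplotypes[chrom]
            a = h1.parent_at(pos) == MUTAGENIZED
            b = h2.parent_at(pos) == MUTAGENIZED
            if a and b:
                n_mut += 1
            else:
                n_non += 1
                n_het += a or b
        assert n_mut / 10_000 == pytest.approx(0.25, abs=0.02)
        assert n_het / n_non == pytest.approx(2 / 3, abs=0.02)

    def test_mutant_pool_homozygous_at_causal_locus(self, default_config):
        mutants, siblings = simulate_pools(default_config)
        assert len(mutants) == len(siblings) == default_config.pool_size
        for e in mutants:
            assert e.is_mutant(default_config.causal_locus)
        for e in siblings:
            assert not e.is_mutant(default_config.causal_locus)


class TestVariantTables:
    def test_snp_panel_deterministic_and_within_bounds(self, default_config):
        p1 = snp_panel(default_config)
        p2 = snp_panel(default_config)
        for chrom in default_config.chrom_lengths:
            pos1, ref1, alt1 = p1[chrom]
            pos2, _, _ = p2[chrom]
            assert np.array_equal(pos1, pos2)
            assert pos1.min() >= 1
            assert pos1.max() <= default_config.chrom_lengths[chrom]
            assert not np.any(ref1 == alt1)

    def test_unlinked_chromosome_alt_fraction_near_half(self):
        fracs = []
        for seed in (1, 2, 3):
            cfg = CrossConfig(seed=seed)
            mutants, _ = simulate_pools(cfg)
            table = simulate_variant_table(mutants, cfg, "mutant_pool")
            fracs += [v.alt_fraction for v in table if v.chrom == "chr15"]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.05)

    def test_alt_fraction_decays_as_one_minus_r(self):
        # selected gametes carry the mapping allele with probability r, so
        # the mutant-pool alt fraction follows 1 - r (Haldane)
        allr, allf = [], []
        for seed in range(1, 6):
            cfg = CrossConfig(seed=seed)
            mutants, _ = simulate_pools(cfg)
            table = simulate_variant_table(mutants, cfg, "mutant_pool")
            length = cfg.chrom_lengths["chr14"]
            _, causal_pos = cfg.causal_locus
            for v in table:
                if v.chrom != "chr14":
                    continue
                d = cfg.map_length * abs(v.pos - causal_pos) / length
                allr.append(0.5 * (1.0 - np.exp(-2.0 * d)))
                allf.append(v.alt_fraction)
        allr, allf = np.array(allr), np.array(allf)
        edges = np.quantile(allr, np.linspace(0, 1, 51))
        idx = np.clip(np.digitize(allr, edges[1:-1]), 0, 49)
        dev = [
            abs(allf[idx == b].mean() - (1.0 - allr[idx == b].mean()))
            for b in range(50)
        ]
        assert max(dev) < 0.05

    def test_sibling_hom_rate_lower_than_mutant_near_locus(self):
        # the subtraction scheme relies on sibling pools not fixing the
        # mutagenized allele where the mutant pool does
        cfg = CrossConfig(seed=4)
        mutants, siblings = simulate_pools(cfg)
        mut = assign_zygosity(simulate_variant_table(mutants, cfg, "mutant_pool"))
        sib = assign_zygosity(simulate_variant_table(siblings, cfg, "sibling_pool"))
        _, causal_pos = cfg.causal_locus

        def hom_rate(table, chrom, near):
            recs = [
                v
                for v in table
                if v.chrom == chrom
                and (abs(v.pos - causal_pos) < 2_000_000) == near
            ]
            return sum(v.zygosity == "hom_alt" for v in recs) / len(recs)

        assert hom_rate(sib, "chr15", near=False) < hom_rate(mut, "chr14", near=True)

    def test_causal_locus_alt_fraction_near_one_in_mutant_pool(self, default_config):
        mutants, _ = simulate_pools(default_config)
        table = simulate_variant_table(mutants, default_config, "mutant_pool")
        chrom, causal_pos = default_config.causal_locus
        nearby = [
            v.alt_fraction
            for v in table
            if v.chrom == chrom and abs(v.pos - causal_pos) < 250_000
        ]
        assert nearby and np.mean(nearby) > 0.97


class TestPackagedFixture:
    def test_same_seed_identical_bundles(self, packaged_bundle):
        assert build_packaged_fixture(seed=1) == packaged_bundle

    def test_different_seed_differs(self, packaged_bundle):
        assert build_packaged_fixture(seed=2) != packaged_bundle

    def test_stop_variant_identity(self, packaged_bundle):
        assert ("chr14", 14_800_000, "C", "A") in packaged_bundle.mutant_table.keys()

    def test_codon_180_is_tyrosine_tac_in_reference(self, packaged_bundle):
        slbp = next(g for g in packaged_bundle.genome.genes if g.gene_id == "slbp")
        ref = packaged_bundle.genome.reference["chr14"]
        cds = "".join(ref[s - 1 : e] for s, e in slbp.cds)
        codon = cds[537:540]
        assert codon == "TAC"
        assert CODON_TABLE[codon] == "Y"
        # third base of codon 180 sits at the causal position, and C->A
        # turns TAC into the TAA stop codon
        assert CODON_TABLE["TAA"] == "*"
        assert ref[14_800_000 - 1] == "C"

    def test_markers_match_printed_coordinates(self, packaged_bundle):
        assert packaged_bundle.markers.interval("z4896", "z6847") == (
            "chr14",
            10_750_000,
            17_260_000,
        )

    def test_amplicons_are_445_bp_and_differ_by_one_base(self, packaged_bundle):
        wt, mut = packaged_bundle.amplicon_wt, packaged_bundle.amplicon_mut
        assert len(wt) == len(mut) == 445
        diffs = [(i, a, b) for i, (a, b) in enumerate(zip(wt, mut)) if a != b]
        assert len(diffs) == 1
        _, wt_base, mut_base = diffs[0]
        assert (wt_base, mut_base) == ("C", "A")
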