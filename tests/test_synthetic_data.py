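import numpy as np
import pandas as pd
import pytest

from karyocourt import synthetic_data as syn
from karyocourt.sexchrom import classify_sex_qpcr


def cfg(**kw):
    return syn.desk_scale_config(**kw)


class TestConfig:
    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            cfg(beta=1.5)

    def test_too_short_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="10 \\* s_min"):
            syn.SimulationConfig(n_chrom=2, chrom_lengths=(5000, 5000))

    def test_default_lengths_span_desk_scale(self):
        c = cfg()
        assert min(c.chrom_lengths) == 3_000_000
        assert max(c.chrom_lengths) == 10_000_000


class TestGenome:
    def test_baseline_masked_fraction(self):
        g = syn.simulate_genome(cfg(seed=5, n_chrom=4,
                                    chrom_lengths=(3e6, 4e6, 5e6, 6e6)))
        mean = np.mean(np.concatenate(list(g.density.values())))
        assert mean == pytest.approx(0.67, abs=0.02)

    def test_extreme_junction_is_nearly_fully_masked(self):
        c = cfg(seed=2, planned_splits=(("chr2", 2_000_000, 0.999),))
        g = syn.simulate_genome(c)
        lo, hi = (2_000_000 - 100_000) // 1000, (2_000_000 + 100_000) // 1000
        assert g.density["chr2"][lo:hi].mean() >= 0.99

    def test_seed_determinism(self):
        c = cfg(seed=7, planned_splits=(("chr3", 2_500_000),))
        g1, g2 = syn.simulate_genome(c), syn.simulate_genome(c)
        for chrom in g1.density:
            np.testing.assert_array_equal(g1.density[chrom], g2.density[chrom])
        pd.testing.assert_frame_equal(g1.repeats.table, g2.repeats.table)

    def test_split_near_end_rejected(self):
        with pytest.raises(ValueError, match="chromosome end"):
            syn.simulate_genome(cfg(planned_splits=(("chr1", 500),)))


class TestDerivation:
    def test_scaffold_counts(self):
        g = syn.simulate_genome(cfg(seed=1))
        s1, _ = syn.derive_assembly(g, [("chr1", 1_500_000)], "A")
        assert len(s1) == 9
        s3, _ = syn.derive_assembly(
            g, [("chr2", 2_000_000), ("chr3", 2_500_000), ("chr4", 3_000_000)], "B")
        assert len(s3) == 11

    def test_karyotype_scale_counts(self):
        """One split on a 46-chromosome genome gives 47 scaffolds; three give 49."""
        c = syn.karyotype_scale_config(seed=0)
        g = syn.simulate_genome(c)
        names = c.chrom_names()
        mids = {n: (c.chrom_lengths[i] // 2000) * 1000 for i, n in enumerate(names)}
        s47, _ = syn.derive_assembly(g, [(names[0], mids[names[0]])], "A")
        assert len(s47) == 47
        s49, _ = syn.derive_assembly(
            g, [(n, mids[n]) for n in names[1:4]], "B")
        assert len(s49) == 49

    def test_empty_plan_is_identity(self):
        g = syn.simulate_genome(cfg(seed=1))
        sset, deriv = syn.derive_assembly(g, [], "X")
        assert len(sset) == 8
        for name, (chrom, start, end, strand) in deriv.liftover.items():
            assert start == 0 and end == g.chrom_length(chrom) and strand == "+"

    def test_close_splits_rejected(self):
        g = syn.simulate_genome(cfg(seed=1))
        with pytest.raises(ValueError, match="closer than"):
            syn.derive_assembly(g, [("chr8", 4_000_000), ("chr8", 4_100_000)], "X")

    def test_liftover_invertibility(self, rng):
        g = syn.simulate_genome(cfg(seed=1))
        _, deriv = syn.derive_assembly(
            g, [("chr1", 1_500_000), ("chr5", 3_000_000)], "X")
        for _ in range(200):
            chrom = g.chromosomes.names[rng.integers(0, 8)]
            pos = int(rng.integers(0, g.chrom_length(chrom)))
            scaf, p = deriv.to_assembly(chrom, pos)
            assert deriv.to_genome(scaf, p) == (chrom, pos)


class TestPairs:
    def test_beta_zero_no_splits_has_no_trans(self):
        c = cfg(seed=1, beta=0.0, n_pairs=20_000)
        g = syn.simulate_genome(c)
        sset, deriv = syn.derive_assembly(g, [], "X")
        pairs = syn.simulate_hic_pairs(g, deriv, c)
        assert (pairs["scaffold1"] == pairs["scaffold2"]).all()

    def test_beta_zero_with_split_trans_joins_only_split_scaffolds(self):
        c = cfg(seed=1, beta=0.0, n_pairs=20_000)
        study = syn.simulate_study(c, [("chr1", 1_500_000)], [])
        trans = study.pairs_a[study.pairs_a["scaffold1"] != study.pairs_a["scaffold2"]]
        assert len(trans) > 0
        assert set(zip(trans["scaffold1"], trans["scaffold2"])) == {("A_s1", "A_s2")}

    def test_trans_fraction_matches_beta(self):
        c = cfg(seed=3)
        tp = syn.simulate_true_pairs(syn.simulate_genome(c), c)
        assert tp.trans_fraction() == pytest.approx(0.10, abs=0.01)

    def test_seed_determinism(self):
        c = cfg(seed=9, n_pairs=50_000)
        g = syn.simulate_genome(c)
        sset, deriv = syn.derive_assembly(g, [], "X")
        pd.testing.assert_frame_equal(
            syn.simulate_hic_pairs(g, deriv, c), syn.simulate_hic_pairs(g, deriv, c))

    def test_cis_decay_exponent_recovered(self):
        c = cfg(seed=3)
        tp = syn.simulate_true_pairs(syn.simulate_genome(c), c)
        s = np.abs(tp.pos2[~tp.is_trans] - tp.pos1[~tp.is_trans])
        edges = np.geomspace(2e3, 2e5, 21)
        h, _ = np.histogram(s, bins=edges)
        dens = h / np.diff(edges)
        slope = np.polyfit(np.log(np.sqrt(edges[:-1] * edges[1:])), np.log(dens), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_liftover_invertibility_of_pair_ends(self):
        c = cfg(seed=4, n_pairs=5_000)
        study = syn.simulate_study(c, [("chr1", 1_500_000)], [])
        names = study.genome.chromosomes.names
        tp, deriv = study.true_pairs, study.deriv_a
        for i in range(0, len(tp), 100):
            chrom, pos = names[tp.chrom1[i]], int(tp.pos1[i])
            scaf, p = deriv.to_assembly(chrom, pos)
            assert deriv.to_genome(scaf, p) == (chrom, pos)


class TestDepth:
    def test_mean_depth_without_mappability_loss(self):
        c = cfg(seed=2, gamma=0.0)
        g = syn.simulate_genome(c)
        _, deriv = syn.derive_assembly(g, [], "X")
        fine, _ = syn.simulate_depth(g, deriv, c)
        assert fine.table["depth"].mean() == pytest.approx(23.0, rel=0.01)

    def test_z0_half_depth_on_z(self):
        c = cfg(seed=2, gamma=0.0, sex="Z0", z_chrom="chr8")
        g = syn.simulate_genome(c)
        _, deriv = syn.derive_assembly(g, [], "X")
        fine, _ = syn.simulate_depth(g, deriv, c)
        z = fine.table[fine.table["scaffold"] == "X_s8"]["depth"].mean()
        assert z == pytest.approx(11.5, rel=0.02)

    def test_junction_depth_ratio_five_fold(self):
        """gamma=0.8 with a fully-masked junction over zero-repeat flanks gives ~0.2x."""
        c = cfg(seed=2, gamma=0.8, repeat_base_mean=0.0,
                planned_splits=(("chr4", 3_000_000, 1.0),))
        g = syn.simulate_genome(c)
        _, deriv = syn.derive_assembly(g, [], "X")
        fine, _ = syn.simulate_depth(g, deriv, c)
        d = fine.table[fine.table["scaffold"] == "X_s4"]["depth"].to_numpy()
        junction = d[2950:3050].mean()
        flank = np.concatenate([d[2500:2800], d[3200:3500]]).mean()
        assert junction / flank == pytest.approx(0.2, abs=0.02)

    def test_coarse_windows_average_fine_bins(self):
        c = cfg(seed=2)
        g = syn.simulate_genome(c)
        _, deriv = syn.derive_assembly(g, [], "X")
        fine, coarse = syn.simulate_depth(g, deriv, c)
        d = fine.table[fine.table["scaffold"] == "X_s1"]["depth"].to_numpy()
        first = coarse.table[coarse.table["scaffold"] == "X_s1"].iloc[0]
        assert first["depth"] == pytest.approx(d[:500].mean())


class TestQpcr:
    def test_noiseless_delta_is_exact(self):
        for sex, expect in (("male", 1.0), ("female", -1.0)):
            a, s = syn.simulate_qpcr(sex, seed=0, noise_sd=0.0)
            assert classify_sex_qpcr(a, s).delta_cq == pytest.approx(expect)

    def test_sign_is_stable_under_replicate_noise(self):
        signs = [classify_sex_qpcr(*syn.simulate_qpcr("ZZ", seed=i, noise_sd=0.1)).delta_cq > 0
                 for i in range(200)]
        assert np.mean(signs) > 0.99

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_qpcr("XY", seed=0)
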