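import numpy as np
import pandas as pd
import pytest

from clipmaps import simulate as sim
from clipmaps.crosslink import filter_high_confidence, snp_filter
from clipmaps.metagene import eligible_transcripts
from clipmaps.translation import STOP_CODONS


class TestGenome:
    def test_base_frequencies_match_configuration(self):
        cfg = sim.SimulationConfig(seed=0, chrom_sizes={"c": 100_000})
        g = sim.simulate_genome(cfg)
        t_frac = g.chroms["c"].count("T") / 100_000
        assert abs(t_frac - 0.31) <= 0.01

    def test_seed_determinism(self):
        cfg = sim.SimulationConfig(seed=5, chrom_sizes={"c": 5000})
        g1 = sim.simulate_genome(cfg)
        g2 = sim.simulate_genome(cfg)
        assert g1.chroms == g2.chroms

    def test_zero_size_rejected(self):
        cfg = sim.SimulationConfig(chrom_sizes={"c": 0})
        with pytest.raises(sim.SimulationError):
            sim.simulate_genome(cfg)


class TestAnnotations:
    def test_isolated_mrnas_pass_metagene_filters(self, small_simulation):
        cfg, genome, ann, features, control, _ = small_simulation
        n_mrna = len(ann.mrnas)
        for align in ("TSS", "pA"):
            eligible = eligible_transcripts(ann, align, "sense",
                                            min_length=0)
            assert len(eligible) == n_mrna

    def test_identity_copula_gives_uncorrelated_features(self):
        cfg = sim.SimulationConfig(
            seed=3, chrom_sizes={f"c{i}": 500_000 for i in range(5)},
            class_counts={"mRNA": 600}, isolated_fraction=0.0,
            crowded_gap=80, cds_codon_range=(150, 250),
            utr5_range=(20, 40), utr3_range=(20, 40))
        rng = np.random.default_rng(3)
        g = sim.simulate_genome(cfg, rng)
        ann, feats = sim.simulate_annotations(g, cfg, rng)
        corr = feats[["optimality", "expression", "halflife"]].corr()
        off_diag = corr.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.abs(off_diag).max() < 0.1

    def test_correlated_copula_respected(self):
        corr = [[1.0, 0.6, 0.0], [0.6, 1.0, 0.0], [0.0, 0.0, 1.0]]
        cfg = sim.SimulationConfig(
            seed=4, chrom_sizes={f"c{i}": 500_000 for i in range(5)},
            class_counts={"mRNA": 600}, isolated_fraction=0.0,
            crowded_gap=80, cds_codon_range=(150, 250),
            utr5_range=(20, 40), utr3_range=(20, 40),
            feature_correlation=corr)
        rng = np.random.default_rng(4)
        g = sim.simulate_genome(cfg, rng)
        ann, feats = sim.simulate_annotations(g, cfg, rng)
        r = np.corrcoef(feats["optimality"],
                        np.log(feats["expression"]))[0, 1]
        assert 0.4 < r < 0.75

    def test_mrna_only_configuration(self):
        cfg = sim.SimulationConfig(seed=1, chrom_sizes={"c": 60_000},
                                   class_counts={"mRNA": 8},
                                   isolated_fraction=0.0, crowded_gap=100)
        rng = np.random.default_rng(1)
        g = sim.simulate_genome(cfg, rng)
        ann, _ = sim.simulate_annotations(g, cfg, rng)
        assert {t.class_label for t in ann.transcripts} == {"mRNA"}

    def test_infeasible_packing_rejected(self):
        cfg = sim.SimulationConfig(seed=1, chrom_sizes={"c": 10_000},
                                   class_counts={"mRNA": 50})
        rng = np.random.default_rng(1)
        g = sim.simulate_genome(cfg, rng)
        with pytest.raises(sim.SimulationError, match="genome"):
            sim.simulate_annotations(g, cfg, rng)

    def test_cds_reading_frames_are_clean_orfs(self, small_simulation):
        cfg, genome, ann, features, control, _ = small_simulation
        seqs = sim.cds_sequences(ann, genome)
        for tid, seq in seqs.items():
            assert len(seq) % 3 == 0
            codons = {seq[i:i + 3] for i in range(0, len(seq), 3)}
            if not any(s.kind == "intron" for s in ann[tid].segments):
                assert not codons & set(STOP_CODONS)


class TestControl:
    def test_planted_snps_have_high_transition_fraction(self, small_simulation):
        cfg, genome, ann, features, control, snps = small_simulation
        merged = snps.merge(control.track, on=["chrom", "pos", "strand"])
        assert len(merged) == len(snps) == cfg.n_snps
        assert (merged["transition_fraction"] >= 0.75).all()
        others = control.track.drop(
            control.track.reset_index().merge(
                snps, on=["chrom", "pos", "strand"])["index"])
        assert (others["transition_fraction"] < 0.75).all()

    def test_coverage_tracks_expression(self, small_simulation):
        cfg, genome, ann, features, control, _ = small_simulation
        idx = control.track.set_index(["chrom", "pos", "strand"])["coverage"]
        ratios = []
        for t in ann.mrnas:
            mean_cov = idx.loc[t.chrom].loc[
                slice(t.start, t.end - 1), t.strand].mean()
            ratios.append(mean_cov / features.loc[t.id, "expression"])
        ratios = np.array(ratios)
        assert ratios.std() / ratios.mean() < 0.2

    def test_depth_scaling_linear(self):
        base = sim.SimulationConfig(seed=2, chrom_sizes={"c": 40_000},
                                    class_counts={"mRNA": 5},
                                    isolated_fraction=0.0, crowded_gap=100)
        rng = np.random.default_rng(2)
        g = sim.simulate_genome(base, rng)
        ann, feats = sim.simulate_annotations(g, base, rng)
        c1, _ = sim.simulate_input_control(ann, feats, base,
                                           np.random.default_rng(9))
        deep = sim.SimulationConfig(**{**base.__dict__,
                                       "control_depth": base.control_depth * 10})
        c2, _ = sim.simulate_input_control(ann, feats, deep,
                                           np.random.default_rng(9))
        ratio = c2.track["coverage"].mean() / c1.track["coverage"].mean()
        assert ratio == pytest.approx(10.0, rel=0.05)


class TestFactor:
    def test_class_preference_shapes_site_distribution(self, small_simulation):
        cfg, genome, ann, features, control, _ = small_simulation
        spec = sim.FactorSpec("F", n_sites=1200, decoy_fraction=0.0,
                              class_preference={"mRNA": 1.0, "snoRNA": 10.0})
        ds, _ = sim.simulate_factor(spec, ann, genome, control, seed=11,
                                    features=features)
        codes = ann.assign_site_classes(ds.sites["chrom"].to_numpy(),
                                        ds.sites["pos"].to_numpy(),
                                        ds.sites["strand"].to_numpy())
        from clipmaps.annotations import DETAILED_LABELS
        labels = np.array([DETAILED_LABELS[c] if c >= 0 else "none"
                           for c in codes])
        # short snoRNAs saturate in unique positions, so weight by reads
        # (duplicate draws merge into coverage), matching read counting
        cov = ds.sites["coverage"].to_numpy(dtype=float)
        frac = cov[labels == "snoRNA"].sum() / cov.sum()
        assert frac >= 0.6

    def test_decoy_fraction_removed_by_filter(self, small_simulation):
        cfg, genome, ann, features, control, snps = small_simulation
        spec = sim.FactorSpec("F", n_sites=1000, decoy_fraction=0.3)
        ds, truth = sim.simulate_factor(spec, ann, genome, control, seed=12,
                                        features=features, snp_sites=snps)
        hc = filter_high_confidence(ds)
        removed = len(ds) - len(hc)
        assert removed == truth["n_decoys"]
        frac = removed / len(ds)
        assert 0.2 <= frac <= 0.4

    def test_snp_filter_removes_exactly_planted_snps(self, small_simulation):
        cfg, genome, ann, features, control, snps = small_simulation
        spec = sim.FactorSpec("F", n_sites=800, decoy_fraction=0.0)
        ds, truth = sim.simulate_factor(spec, ann, genome, control, seed=13,
                                        features=features, snp_sites=snps)
        out = snp_filter(ds, control)
        removed = set(map(tuple,
                          ds.sites[["chrom", "pos", "strand"]]
                          .itertuples(index=False))) - \
            set(map(tuple, out.sites[["chrom", "pos", "strand"]]
                    .itertuples(index=False)))
        assert removed == {tuple(k) for k in truth["snp_sites"]}

    def test_determinism_byte_identical(self, small_simulation, tmp_path):
        cfg, genome, ann, features, control, snps = small_simulation
        spec = sim.FactorSpec("F", n_sites=300)
        d1, _ = sim.simulate_factor(spec, ann, genome, control, seed=14,
                                    features=features, snp_sites=snps)
        d2, _ = sim.simulate_factor(spec, ann, genome, control, seed=14,
                                    features=features, snp_sites=snps)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        d1.to_tsv(p1)
        d2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_spec_rejected(self):
        with pytest.raises(sim.SimulationError):
            sim.FactorSpec("F", n_sites=0)
        with pytest.raises(sim.SimulationError):
            sim.FactorSpec("F", class_preference={"mRNA": 0.0})
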