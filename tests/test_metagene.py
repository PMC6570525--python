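import numpy as np
import pandas as pd
import pytest

from clipmaps.annotations import AnnotationSet, Transcript
from clipmaps.crosslink import FactorDataset
from clipmaps.metagene import (average_profile, eligible_transcripts,
                               exclude_sites_in_regions, moving_average)
from conftest import make_sites


class TestMovingAverage:
    def test_impulse_spreads_over_window(self):
        x = np.zeros(101)
        x[50] = 1.0
        sm = moving_average(x, 41)
        assert sm[50] == sm.max() == pytest.approx(1 / 41)
        assert np.count_nonzero(sm) == 41

    def test_interior_sum_conserved(self):
        rng = np.random.default_rng(0)
        x = rng.random(500)
        sm = moving_average(x, 21)
        # away from edges the average of averages equals the average
        assert sm[50:450].mean() == pytest.approx(x[40:460].mean(), rel=0.05)

    def test_window_one_is_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_edges_use_truncated_windows(self):
        x = np.ones(50)
        sm = moving_average(x, 41)
        np.testing.assert_allclose(sm, 1.0)  # no padding artifacts


def _ann(transcripts):
    return AnnotationSet(transcripts)


class TestEligibility:
    def test_short_transcript_excluded(self):
        ann = _ann([Transcript("m", "c", "+", 1000, 2499, "mRNA")])
        assert eligible_transcripts(ann, "TSS") == []

    def test_isolated_long_transcript_passes_all_modes(self):
        ann = _ann([Transcript("m", "c", "+", 1000, 3000, "mRNA")])
        for align in ("TSS", "pA"):
            for mode in ("sense", "antisense"):
                got = eligible_transcripts(ann, align, mode)
                assert [t.id for t in got] == ["m"]

    def test_upstream_neighbor_blocks_tss_mode(self):
        # neighbor ends 500 nt upstream of the TSS of m
        ann = _ann([Transcript("m", "c", "+", 3000, 5000, "mRNA"),
                    Transcript("n", "c", "+", 500, 2500, "mRNA")])
        got = [t.id for t in eligible_transcripts(ann, "TSS")]
        assert got == ["n"]

    def test_downstream_neighbor_blocks_pa_mode(self):
        ann = _ann([Transcript("m", "c", "+", 1000, 3000, "mRNA"),
                    Transcript("n", "c", "+", 3200, 5000, "mRNA")])
        got = [t.id for t in eligible_transcripts(ann, "pA")]
        assert got == ["n"]

    def test_opposite_strand_neighbor_only_blocks_antisense_mode(self):
        ann = _ann([Transcript("m", "c", "+", 3000, 5000, "mRNA"),
                    Transcript("n", "c", "-", 500, 2500, "mRNA")])
        assert [t.id for t in eligible_transcripts(ann, "TSS", "sense")] == \
            ["m", "n"]
        anti = [t.id for t in eligible_transcripts(ann, "TSS", "antisense")]
        assert "m" not in anti


class TestRegionExclusion:
    def test_trna_sites_removed_by_default(self, tiny_annotations):
        d = FactorDataset("F", make_sites([("chrA", 420, "-", 1, 2, 0.001),
                                           ("chrA", 150, "+", 1, 2, 0.001)]))
        out = exclude_sites_in_regions(d, tiny_annotations)
        assert list(out.sites["pos"]) == [150]

    def test_explicit_intervals_removed(self, tiny_annotations):
        d = FactorDataset("F", make_sites([("chrB", 150, "-", 1, 2, 0.001)]))
        out = exclude_sites_in_regions(
            d, tiny_annotations, intervals=[("chrB", 100, 300, "-")])
        assert len(out) == 0

    def test_plain_cds_site_retained(self, tiny_annotations):
        d = FactorDataset("F", make_sites([("chrA", 120, "+", 1, 2, 0.001)]))
        out = exclude_sites_in_regions(d, tiny_annotations)
        assert len(out) == 1


def _occ_dataset(rows):
    df = make_sites([r[:6] for r in rows])
    df["input_coverage"] = 1.0
    df["occupancy"] = [r[6] for r in rows]
    return FactorDataset("F", df)


class TestAverageProfile:
    lengths = {"c": 10_000}

    def test_single_spike_normalizes_to_one(self):
        t = Transcript("m", "c", "+", 3000, 6000, "mRNA")
        d = _occ_dataset([("c", 3005, "+", 2, 4, 0.001, 4.0)])
        prof = average_profile(d, [t], self.lengths, "TSS", smooth=1,
                               n_boot=0)
        assert prof.mean_occ[prof.offsets == 5] == pytest.approx(1.0)
        assert prof.mean_occ.sum() == pytest.approx(1.0)

    def test_minus_strand_offsets_follow_transcript_orientation(self):
        t = Transcript("m", "c", "-", 3000, 6000, "mRNA")
        # TSS of a minus-strand transcript is at end-1 = 5999; a site 5 nt
        # into the transcript sits at genomic 5994
        d = _occ_dataset([("c", 5994, "-", 2, 4, 0.001, 4.0)])
        prof = average_profile(d, [t], self.lengths, "TSS", smooth=1,
                               n_boot=0)
        assert prof.offsets[np.argmax(prof.mean_occ)] == 5

    def test_constant_profile_emitted_as_zeros_with_warning(self, caplog):
        t = Transcript("m", "c", "+", 3000, 6000, "mRNA")
        d = _occ_dataset([])
        with caplog.at_level("WARNING"):
            prof = average_profile(d, [t], self.lengths, "TSS", n_boot=0)
        assert (prof.mean_occ == 0).all()

    def test_smoothed_spike_peaks_at_site_spread_over_window(self):
        t = Transcript("m", "c", "+", 3000, 6000, "mRNA")
        d = _occ_dataset([("c", 3005, "+", 2, 4, 0.001, 4.0)])
        prof = average_profile(d, [t], self.lengths, "TSS", smooth=41,
                               n_boot=0, normalize=False)
        at_site = prof.raw_mean[prof.offsets == 5][0]
        assert at_site == prof.raw_mean.max() == pytest.approx(4.0 / 41)
        assert np.count_nonzero(prof.raw_mean) == 41

    def test_bootstrap_band_contains_mean(self):
        rng = np.random.default_rng(3)
        ts = [Transcript(f"m{i}", "c", "+", 2000 + 100 * i, 8000, "mRNA")
              for i in range(5)]
        d = _occ_dataset([("c", int(p), "+", 1, 2, 0.001, float(o))
                          for p, o in zip(rng.choice(np.arange(2500, 7500),
                                                     40, replace=False),
                                          rng.random(40) * 5)])
        prof = average_profile(d, ts, self.lengths, "TSS", n_boot=300,
                               rng=rng)
        assert (prof.ci_low <= prof.mean_occ + 1e-12).all()
        assert (prof.ci_high >= prof.mean_occ - 1e-12).all()

    def test_empty_transcript_list_rejected(self):
        with pytest.raises(ValueError):
            average_profile(_occ_dataset([]), [], self.lengths, "TSS")

    def test_antisense_mode_reads_opposite_strand_track(self):
        t = Transcript("m", "c", "+", 3000, 6000, "mRNA")
        d = _occ_dataset([("c", 3010, "-", 2, 4, 0.001, 4.0)])
        prof = average_profile(d, [t], self.lengths, "TSS",
                               strand_mode="antisense", smooth=1, n_boot=0)
        assert prof.offsets[np.argmax(prof.mean_occ)] == 10


def test_planted_gaussian_peak_recovered(small_simulation):
    from clipmaps import simulate as sim
    from clipmaps.crosslink import (compute_occupancy,
                                    filter_high_confidence)
    cfg, genome, ann, features, control, _ = small_simulation
    spec = sim.FactorSpec(
        "peak", n_sites=2200, decoy_fraction=0.1,
        positional_profile=sim.PositionalProfile("gaussian", "pa", -100, 30))
    ds, _ = sim.simulate_factor(spec, ann, genome, control, seed=77,
                                features=features)
    occ = compute_occupancy(filter_high_confidence(ds), control)
    transcripts = eligible_transcripts(ann, "pA", "sense")
    prof = average_profile(occ, transcripts, genome.lengths, "pA",
                           n_boot=100, rng=np.random.default_rng(0))
    peak = prof.offsets[np.argmax(prof.mean_occ)]
    assert abs(peak - (-100)) <= 20
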