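import numpy as np
import pandas as pd
import pytest

from clipmaps.crosslink import (CrosslinkError, FactorDataset, InputControl,
                                compute_occupancy, filter_high_confidence,
                                merge_replicates, replicate_correlation,
                                snp_filter)
from conftest import make_sites


def _control(rows):
    return InputControl(pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "coverage",
                       "transition_fraction"]))


class TestMerge:
    def test_union_keeps_singleton_sites(self):
        a = FactorDataset("F", make_sites([("c", 5, "+", 3, 5, 0.001)]), "1")
        b = FactorDataset("F", make_sites([("c", 9, "+", 2, 4, 0.002)]), "2")
        merged = merge_replicates([a, b])
        assert len(merged) == 2
        row = merged.sites.set_index("pos").loc[5]
        assert (row["transitions"], row["coverage"]) == (3, 5)

    def test_shared_site_counts_add(self):
        a = FactorDataset("F", make_sites([("c", 5, "+", 3, 5, 0.004)]), "1")
        b = FactorDataset("F", make_sites([("c", 5, "+", 2, 4, 0.001)]), "2")
        merged = merge_replicates([a, b])
        row = merged.sites.iloc[0]
        assert (row["transitions"], row["coverage"]) == (5, 9)
        assert row["p_value"] == 0.001  # min over replicates

    def test_empty_replicates_merge_empty(self):
        merged = merge_replicates([FactorDataset("F"), FactorDataset("F")])
        assert len(merged) == 0

    def test_factor_mismatch_rejected(self):
        with pytest.raises(CrosslinkError):
            merge_replicates([FactorDataset("F"), FactorDataset("G")])

    def test_self_merge_doubles_counts_same_positions(self):
        sites = make_sites([("c", 5, "+", 3, 6, 0.001),
                            ("c", 9, "-", 1, 2, 0.002)])
        d = FactorDataset("F", sites)
        merged = merge_replicates([d, FactorDataset("F", sites.copy(), "2")])
        assert set(merged.sites["pos"]) == set(sites["pos"])
        assert (merged.sites.sort_values("pos")["transitions"].to_numpy()
                == 2 * sites.sort_values("pos")["transitions"].to_numpy()).all()


class TestHighConfidenceFilter:
    @pytest.mark.parametrize("p,cov,kept", [
        (0.004, 2, True),    # passes both bounds
        (0.005, 2, True),    # boundary p is inclusive
        (0.004, 1, False),   # fails coverage
        (0.006, 10, False),  # fails p
    ])
    def test_bounds(self, p, cov, kept):
        d = FactorDataset("F", make_sites([("c", 1, "+", 1, cov, p)]))
        assert len(filter_high_confidence(d)) == (1 if kept else 0)


class TestSnpFilter:
    @pytest.mark.parametrize("frac,kept", [(0.80, False), (0.75, False),
                                           (0.74, True)])
    def test_threshold(self, frac, kept):
        d = FactorDataset("F", make_sites([("c", 1, "+", 1, 2, 0.001)]))
        ctrl = _control([("c", 1, "+", 10.0, frac)])
        assert len(snp_filter(d, ctrl)) == (1 if kept else 0)

    def test_uncovered_position_untouched(self):
        d = FactorDataset("F", make_sites([("c", 1, "+", 1, 2, 0.001)]))
        ctrl = _control([("c", 99, "+", 10.0, 0.9)])
        assert len(snp_filter(d, ctrl)) == 1


class TestOccupancy:
    def test_ratio_before_capping(self):
        d = FactorDataset("F", make_sites([("c", 1, "+", 10, 20, 0.001)]))
        ctrl = _control([("c", 1, "+", 5.0, 0.0)])
        out = compute_occupancy(d, ctrl, cap_quantile=1.0)
        assert out.sites["occupancy"].iloc[0] == pytest.approx(2.0)

    def test_cap_at_95th_percentile_of_1_to_100(self):
        # transitions 1..100 over unit control coverage -> occupancies 1..100;
        # 0.95 quantile with linear interpolation is 95.05
        rows = [("c", i, "+", i, i, 0.001) for i in range(1, 101)]
        ctrl = _control([("c", i, "+", 1.0, 0.0) for i in range(1, 101)])
        out = compute_occupancy(FactorDataset("F", make_sites(rows)), ctrl)
        occ = np.sort(out.sites["occupancy"].to_numpy())
        expected_cap = np.quantile(np.arange(1.0, 101.0), 0.95)
        assert expected_cap == pytest.approx(95.05)
        assert occ.max() == pytest.approx(expected_cap)
        # order statistics below the cap unchanged
        assert (occ[:94] == np.arange(1.0, 95.0)).all()

    def test_constant_occupancies_unchanged_by_cap(self):
        rows = [("c", i, "+", 3, 6, 0.001) for i in range(10)]
        ctrl = _control([("c", i, "+", 1.0, 0.0) for i in range(10)])
        out = compute_occupancy(FactorDataset("F", make_sites(rows)), ctrl)
        assert (out.sites["occupancy"] == 3.0).all()

    def test_zero_control_coverage_sites_dropped(self):
        d = FactorDataset("F", make_sites([("c", 1, "+", 2, 4, 0.001),
                                           ("c", 2, "+", 2, 4, 0.001)]))
        ctrl = _control([("c", 1, "+", 4.0, 0.0), ("c", 2, "+", 0.0, 0.0)])
        out = compute_occupancy(d, ctrl)
        assert list(out.sites["pos"]) == [1]

    def test_empty_dataset_stays_empty(self):
        out = compute_occupancy(FactorDataset("F"), _control([]))
        assert len(out) == 0 and out.has_occupancy


def test_filters_commute(small_simulation):
    from clipmaps import simulate as sim
    cfg, genome, ann, features, control, snps = small_simulation
    spec = sim.FactorSpec("F", n_sites=400, decoy_fraction=0.3)
    ds, _ = sim.simulate_factor(spec, ann, genome, control, seed=5,
                                features=features, snp_sites=snps)
    ab = snp_filter(filter_high_confidence(ds), control)
    ba = filter_high_confidence(snp_filter(ds, control))
    pd.testing.assert_frame_equal(ab.sites, ba.sites)


class TestReplicateCorrelation:
    """Spearman of per-transcript totals over a 3-transcript annotation."""

    def _setup(self, occs_a, occs_b):
        from clipmaps.annotations import AnnotationSet, Transcript
        transcripts = [Transcript(f"m{i}", "c", "+", 100 * i, 100 * i + 80,
                                  "mRNA") for i in range(max(len(occs_a), 3))]
        ann = AnnotationSet(transcripts)
        ctrl = _control([("c", 100 * i + 10, "+", 1.0, 0.0)
                         for i in range(len(transcripts))])

        def build(occs):
            rows = [("c", 100 * i + 10, "+", int(o), int(o) + 1, 0.001)
                    for i, o in enumerate(occs)]
            d = FactorDataset("F", make_sites(rows))
            return compute_occupancy(d, ctrl, cap_quantile=1.0)

        return build(occs_a), build(occs_b), ann

    def test_monotone_maps_give_unit_correlation(self):
        a, b, ann = self._setup([1, 2, 3], [10, 20, 30])
        assert replicate_correlation(a, b, ann) == pytest.approx(1.0)
        assert replicate_correlation(a, a, ann) == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        a, b, ann = self._setup([1, 2, 3], [3, 2, 1])
        assert replicate_correlation(a, b, ann) == pytest.approx(-1.0)

    def test_too_few_nonzero_transcripts_rejected(self):
        a, b, ann = self._setup([1, 2], [2, 1])
        with pytest.raises(CrosslinkError):
            replicate_correlation(a, b, ann)
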