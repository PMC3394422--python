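import pytest

from phytomir.datamodel import PredictionSet, ReferenceSet, Region, annotate_region
from phytomir.evaluate import (
    BenchmarkReport,
    additional_prediction,
    column_average,
    count_pm_vm_cm,
    filter_power,
    pairwise_agreement,
    region_share,
    region_summary,
    true_positive,
)
from tests.conftest import make_interval_site


def _pred(*sites):
    return PredictionSet(tuple(sites))


class TestCounting:
    def test_groups_matched_against_reference(self):
        sites = []
        # 10 well-separated groups on TX1; m1..m4 pairs, m1 has 3 sites
        for k in range(3):
            sites.append(make_interval_site(400 * k, 400 * k + 22, mirna_id="m1"))
        for k, mirna in enumerate(("m2", "m3", "m4", "m5", "m6", "m7", "m8")):
            sites.append(
                make_interval_site(1300 + 400 * k, 1322 + 400 * k, mirna_id=mirna)
            )
        ref = ReferenceSet.from_pairs(
            [("m1", "TX1"), ("m2", "TX1"), ("m3", "TX1"), ("m9", "TX9")]
        )
        pm, vm, cm = count_pm_vm_cm(_pred(*sites), ref)
        assert (pm, vm, cm) == (10, 5, 3)  # 3+1+1 validated groups, 3 pairs

    def test_disjoint_prediction(self):
        pred = _pred(make_interval_site(0, 22, mirna_id="mX"))
        ref = ReferenceSet.from_pairs([("m1", "TX1")])
        assert count_pm_vm_cm(pred, ref) == (1, 0, 0)

    def test_one_site_per_reference_pair(self):
        pairs = [(f"m{k}", "TX1") for k in range(5)]
        sites = [
            make_interval_site(100 * k, 100 * k + 22, mirna_id=m)
            for k, (m, _) in enumerate(pairs)
        ]
        ref = ReferenceSet.from_pairs(pairs)
        assert count_pm_vm_cm(_pred(*sites), ref) == (5, 5, 5)

    def test_multiple_sites_per_pair_inflate_vm_not_cm(self):
        sites = [
            make_interval_site(400 * k, 400 * k + 22, mirna_id="m1") for k in range(4)
        ]
        ref = ReferenceSet.from_pairs([("m1", "TX1")])
        pm, vm, cm = count_pm_vm_cm(_pred(*sites), ref)
        assert vm == 4 > cm == 1


class TestPercentages:
    @pytest.mark.parametrize(
        "pm,vm,expected",
        [
            (541, 366, 32.35),
            (622, 411, 33.92),
            (362, 269, 25.69),
            (615, 411, 33.17),
            (362, 362, 0.00),
        ],
    )
    def test_additional_prediction(self, pm, vm, expected):
        assert additional_prediction(pm, vm) == expected

    @pytest.mark.parametrize(
        "cm,n_ref,expected",
        [
            (100, 142, 70.42),
            (116, 142, 81.69),
            (110, 142, 77.46),
            (98, 142, 69.01),
            (125, 142, 88.03),
            (0, 142, 0.00),
        ],
    )
    def test_true_positive(self, cm, n_ref, expected):
        assert true_positive(cm, n_ref) == expected

    def test_zero_pm_rejected(self):
        with pytest.raises(ValueError, match="PM"):
            additional_prediction(0, 0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            true_positive(0, 0)

    def test_ap_complements_validated_fraction(self):
        for pm, vm in [(541, 366), (622, 411), (7, 3)]:
            assert 100 * (pm - vm) / pm + 100 * vm / pm == pytest.approx(100.0)

    @pytest.mark.parametrize(
        "ratio,ap,expected", [(0.0, 0.5, 0.0), (1.0, 1.0, 1.0), (0.5, 0.32, 0.4)]
    )
    def test_filter_power_geometric_mean(self, ratio, ap, expected):
        assert filter_power(ratio, ap) == pytest.approx(expected)

    def test_filter_power_domain_checked(self):
        with pytest.raises(ValueError):
            filter_power(1.5, 0.2)


class TestPairwiseAgreement:
    def _set(self, starts, mirna="m1"):
        return _pred(
            *[make_interval_site(s, s + 22, mirna_id=mirna) for s in starts]
        )

    def test_identical_sets_agree_fully(self):
        a = self._set([0, 400, 800])
        matrix = pairwise_agreement({"A": a, "B": a})
        assert matrix.loc["A", "B"] == 100.0
        assert matrix.loc["A", "A"] == 100.0

    def test_disjoint_sets_agree_zero(self):
        matrix = pairwise_agreement(
            {"A": self._set([0, 400]), "B": self._set([2000, 2400])}
        )
        assert matrix.loc["A", "B"] == 0.0

    def test_denominator_is_smaller_set(self):
        a = self._set([0, 400, 800, 1200])
        b_sub = self._set([0, 400])
        matrix = pairwise_agreement({"A": a, "B": b_sub})
        assert matrix.loc["A", "B"] == 100.0
        b_half = self._set([0, 5000])
        matrix = pairwise_agreement({"A": a, "B": b_half})
        assert matrix.loc["A", "B"] == 50.0

    def test_mrna_level_uses_pair_intersection(self):
        a = _pred(
            make_interval_site(0, 22, mirna_id="m1"),
            make_interval_site(0, 22, mirna_id="m2"),
        )
        b = _pred(make_interval_site(900, 922, mirna_id="m1"))
        matrix = pairwise_agreement({"A": a, "B": b}, level="mrna")
        assert matrix.loc["A", "B"] == 100.0  # shared pair despite distant sites

    def test_symmetry(self):
        a = self._set([0, 400, 800])
        b = self._set([0, 2000])
        matrix = pairwise_agreement({"A": a, "B": b})
        assert matrix.loc["A", "B"] == matrix.loc["B", "A"]


class TestRegionSummary:
    def _regional_pred(self, counts):
        sites = []
        k = 0
        for label, n in counts.items():
            for _ in range(n):
                sites.append(
                    annotate_region(
                        make_interval_site(40 * k, 40 * k + 22, transcript_id=f"T{k}"),
                        label,
                    )
                )
                k += 1
        return _pred(*sites)

    def test_region_rows_and_cds_share(self):
        pred = self._regional_pred({"5UTR": 52, "CDS": 897, "3UTR": 253})
        summary = region_summary(pred)
        assert list(summary.loc["predicted"]) == [52, 897, 253]
        assert region_share(summary, Region.CDS) == 74.63

    def test_single_region_is_everything(self):
        pred = self._regional_pred({"CDS": 7})
        summary = region_summary(pred)
        assert region_share(summary, "CDS") == 100.0

    def test_mirna_level_share_arithmetic(self):
        # 32 of 207 miRNAs with 3'UTR sites
        from phytomir.evaluate import round_pct

        assert round_pct(100 * 32 / 207) == 15.46

    def test_reference_matching_rows(self):
        pred = _pred(
            annotate_region(make_interval_site(0, 22, mirna_id="m1"), "CDS"),
            annotate_region(make_interval_site(400, 422, mirna_id="m1"), "CDS"),
            annotate_region(make_interval_site(800, 822, mirna_id="m2"), "3UTR"),
        )
        ref = ReferenceSet.from_pairs([("m1", "TX1")])
        summary = region_summary(pred, ref)
        assert summary.loc["validated", "CDS"] == 2
        assert summary.loc["collapsed", "CDS"] == 1
        assert summary.loc["validated", "3UTR"] == 0


class TestColumnAverage:
    def _table2_reports(self):
        rows = [
            (541, 366, 100, 32.35, 70.42),
            (622, 411, 116, 33.92, 81.69),
            (362, 269, 110, 25.69, 77.46),
            (615, 411, 98, 33.17, 69.01),
        ]
        return [
            BenchmarkReport(pm=pm, vm=vm, cm=cm, ap=ap, tp=tp)
            for pm, vm, cm, ap, tp in rows
        ]

    def test_count_and_percentage_means(self):
        avg = column_average(self._table2_reports())
        assert avg.pm == 535
        assert avg.vm == 364
        assert avg.cm == 106
        assert avg.ap == 31.28
        # plain arithmetic mean of the TP column
        assert avg.tp == 74.65

    def test_average_of_identical_reports_is_the_report(self):
        rep = BenchmarkReport(pm=100, vm=60, cm=40, ap=40.0, tp=28.17)
        avg = column_average([rep, rep, rep])
        assert avg == rep

    def test_union_recovers_at_least_the_best_part(self):
        part_a = _pred(
            make_interval_site(0, 22, mirna_id="m1"),
            make_interval_site(400, 422, mirna_id="m2"),
        )
        part_b = _pred(make_interval_site(800, 822, mirna_id="m3"))
        ref = ReferenceSet.from_pairs(
            [("m1", "TX1"), ("m2", "TX1"), ("m3", "TX1")]
        )
        union = _pred(*(part_a.sites + part_b.sites))
        cm_union = count_pm_vm_cm(union, ref)[2]
        assert cm_union >= max(
            count_pm_vm_cm(part_a, ref)[2], count_pm_vm_cm(part_b, ref)[2]
        )
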