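import random
from dataclasses import replace

import pytest

from phytomir.datamodel import DegradomeRecord, DegradomeTable, PredictionSet
from phytomir.energy import AccessibilityResult
from phytomir.engines import ENGINE_ORDER, TAPIRLIKE, UEALIKE, WMD3LIKE
from phytomir.filters import (
    DEFAULT_ACCESSIBILITY_CUTOFF,
    DEFAULT_DEGRADOME_CUTOFF,
    filter_accessibility,
    filter_degradome,
    filter_multi_method,
    filter_multiplicity,
    group_sites,
    overlap_fraction,
)
from tests.conftest import make_interval_site


def _pred(*sites):
    return PredictionSet(tuple(sites))


class TestOverlapFraction:
    def test_identical_intervals(self):
        a = make_interval_site(100, 122)
        assert overlap_fraction(a, a) == 1.0

    def test_one_base_shift(self):
        a = make_interval_site(100, 122)
        b = make_interval_site(101, 123)
        assert overlap_fraction(a, b) == pytest.approx(21 / 22)

    def test_disjoint(self):
        assert overlap_fraction(
            make_interval_site(100, 122), make_interval_site(130, 152)
        ) == 0.0

    def test_cross_pair_comparison_rejected(self):
        with pytest.raises(ValueError, match="pair"):
            overlap_fraction(
                make_interval_site(0, 22, mirna_id="a"),
                make_interval_site(0, 22, mirna_id="b"),
            )


class TestGrouping:
    def test_shifted_sites_group_together(self):
        a = make_interval_site(100, 122, engine=WMD3LIKE)
        b = make_interval_site(101, 123, engine=TAPIRLIKE)
        groups = group_sites([a, b])
        assert len(groups) == 1
        assert groups[0].engines == {WMD3LIKE, TAPIRLIKE}

    def test_partial_overlap_stays_apart(self):
        a = make_interval_site(100, 122)
        b = make_interval_site(110, 132)  # 12/22 shared
        assert len(group_sites([a, b])) == 2

    def test_singleton(self):
        groups = group_sites([make_interval_site(5, 27)])
        assert len(groups) == 1 and len(groups[0].sites) == 1

    def test_every_site_in_exactly_one_group(self, rng):
        sites = [
            make_interval_site(start, start + 22, engine=rng.choice(ENGINE_ORDER))
            for start in rng.sample(range(0, 2000, 7), 40)
        ]
        groups = group_sites(sites)
        assert sum(len(g.sites) for g in groups) == len(sites)

    def test_representative_is_best_scoring_member(self):
        worse = make_interval_site(100, 122, score=2.0, engine=WMD3LIKE)
        better = make_interval_site(101, 123, score=0.5, engine=UEALIKE)
        group = group_sites([worse, better])[0]
        assert group.representative is better


def _four_group_fixture():
    """Groups supported by exactly 1, 2, 3 and 4 engines on one transcript."""
    sites = []
    for k, n_engines in enumerate((1, 2, 3, 4)):
        start = 200 * k
        for engine in ENGINE_ORDER[:n_engines]:
            sites.append(
                make_interval_site(start, start + 22, engine=engine, score=float(k))
            )
    return _pred(*sites)


class TestMultiMethod:
    def test_cutoff_counts_distinct_engines(self):
        outcome = filter_multi_method(_four_group_fixture(), cutoff=3)
        assert len(outcome.kept) == 2
        assert all(len(s.support) >= 3 for s in outcome.kept)

    def test_cutoff_one_keeps_all_groups(self):
        outcome = filter_multi_method(_four_group_fixture(), cutoff=1)
        assert len(outcome.kept) == 4

    def test_cutoff_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            filter_multi_method(_four_group_fixture(), cutoff=5)

    def test_bookkeeping_exact(self):
        pred = _four_group_fixture()
        outcome = filter_multi_method(pred, cutoff=2)
        assert outcome.removed == len(pred) - len(outcome.kept)
        assert outcome.filter_ratio * len(pred) == pytest.approx(outcome.removed)

    def test_monotone_in_cutoff(self):
        pred = _four_group_fixture()
        previous = None
        for cutoff in (1, 2, 3, 4):
            kept = {
                (s.pair, s.start, s.end)
                for s in filter_multi_method(pred, cutoff).kept
            }
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_idempotent(self):
        once = filter_multi_method(_four_group_fixture(), cutoff=2).kept
        twice = filter_multi_method(once, cutoff=2).kept
        assert {(s.pair, s.start, s.end, s.support) for s in twice} == {
            (s.pair, s.start, s.end, s.support) for s in once
        }


class TestMultiplicity:
    def _multi_group_fixture(self):
        sites = []
        # pair m1/TX1: 1 group; m2/TX1: 2 groups; m3/TX1: 3 groups
        for k, mirna in enumerate(("m1", "m2", "m3"), start=1):
            for g in range(k):
                sites.append(
                    make_interval_site(300 * g, 300 * g + 22, mirna_id=mirna)
                )
        return _pred(*sites)

    def test_default_cutoff_two_inclusive(self):
        outcome = filter_multiplicity(self._multi_group_fixture(), cutoff=2)
        kept_mirnas = {s.mirna_id for s in outcome.kept}
        assert kept_mirnas == {"m2", "m3"}
        assert {s.multiplicity for s in outcome.kept} == {2, 3}

    def test_cutoff_one_keeps_single_site_pairs(self):
        outcome = filter_multiplicity(self._multi_group_fixture(), cutoff=1)
        assert len(outcome.kept) == 6

    def test_engine_duplicates_count_once(self):
        # one physical site seen by all four engines is multiplicity 1
        sites = [
            make_interval_site(100, 122, engine=e) for e in ENGINE_ORDER
        ]
        outcome = filter_multiplicity(_pred(*sites), cutoff=2)
        assert len(outcome.kept) == 0

    def test_contraction_and_idempotence(self):
        pred = self._multi_group_fixture()
        once = filter_multiplicity(pred, cutoff=2).kept
        assert set(s.pair for s in once) <= set(s.pair for s in pred)
        twice = filter_multiplicity(once, cutoff=2).kept
        assert len(twice) == len(once)


def _with_access(site, total):
    return replace(
        site, accessibility=AccessibilityResult(opening=0.0, duplex=total, total=total)
    )


class TestAccessibilityFilter:
    def test_default_cutoff_boundaries(self):
        strong = _with_access(make_interval_site(0, 22), -26.0)
        exact = _with_access(make_interval_site(100, 122), -15.87)
        weak = _with_access(make_interval_site(200, 222), -14.0)
        outcome = filter_accessibility(_pred(strong, exact, weak))
        kept_totals = {s.accessibility.total for s in outcome.kept}
        assert kept_totals == {-26.0, -15.87}  # boundary is inclusive

    def test_uncomputed_sites_removed_and_counted(self):
        ok = _with_access(make_interval_site(0, 22), -26.0)
        broken = replace(
            make_interval_site(100, 122), accessibility=AccessibilityResult.uncomputed()
        )
        outcome = filter_accessibility(_pred(ok, broken))
        assert len(outcome.kept) == 1
        assert outcome.uncomputed == 1

    def test_unannotated_site_rejected(self):
        with pytest.raises(ValueError, match="accessibility"):
            filter_accessibility(_pred(make_interval_site(0, 22)))


class TestDegradomeFilter:
    def _table(self):
        return DegradomeTable.from_records(
            [
                DegradomeRecord("m1", "TX1", 4.5),
                DegradomeRecord("m2", "TX1", 6.0),
            ]
        )

    def test_boundary_score_kept(self):
        site = make_interval_site(0, 22, mirna_id="m1")
        outcome = filter_degradome(_pred(site), self._table())
        assert len(outcome.kept) == 1
        assert outcome.kept.sites[0].degradome_score == 4.5

    def test_weak_support_removed(self):
        site = make_interval_site(0, 22, mirna_id="m2")
        assert len(filter_degradome(_pred(site), self._table()).kept) == 0

    def test_absent_pair_removed(self):
        site = make_interval_site(0, 22, mirna_id="m9")
        assert len(filter_degradome(_pred(site), self._table()).kept) == 0

    def test_commutes_with_multiplicity(self):
        sites = [
            make_interval_site(0, 22, mirna_id="m1"),
            make_interval_site(300, 322, mirna_id="m1"),
            make_interval_site(0, 22, mirna_id="m2"),
        ]
        pred = _pred(*sites)
        table = self._table()
        ab = filter_degradome(filter_multiplicity(pred, 2).kept, table).kept
        ba = filter_multiplicity(filter_degradome(pred, table).kept, 2).kept
        assert {(s.pair, s.start) for s in ab} == {(s.pair, s.start) for s in ba}


class TestFilterLaws:
    """Randomized law checks across all four filters."""

    def _random_pred(self, rng: random.Random):
        sites = []
        for _ in range(rng.randint(0, 25)):
            start = rng.randrange(0, 3000)
            site = make_interval_site(
                start,
                start + 22,
                mirna_id=f"m{rng.randint(1, 4)}",
                transcript_id=f"TX{rng.randint(1, 3)}",
                engine=rng.choice(ENGINE_ORDER),
                score=round(rng.uniform(0, 5), 2),
            )
            sites.append(
                _with_access(site, round(rng.uniform(-40.0, 0.0), 2))
            )
        return _pred(*sites)

    def _random_table(self, rng: random.Random):
        records = [
            DegradomeRecord(f"m{m}", f"TX{t}", round(rng.uniform(0, 9), 2))
            for m in range(1, 5)
            for t in range(1, 4)
            if rng.random() < 0.7
        ]
        return DegradomeTable.from_records(records)

    def test_contraction_idempotence_and_bookkeeping(self):
        rng = random.Random(515)
        for trial in range(40):
            pred = self._random_pred(rng)
            table = self._random_table(rng)
            applications = [
                lambda p: filter_multi_method(p, rng.randint(1, 4)),
                lambda p: filter_multiplicity(p, rng.randint(1, 3)),
                lambda p: filter_accessibility(p, DEFAULT_ACCESSIBILITY_CUTOFF),
                lambda p: filter_degradome(p, table, DEFAULT_DEGRADOME_CUTOFF),
            ]
            for apply_filter in applications:
                state = rng.getstate()
                outcome = apply_filter(pred)
                # bookkeeping: kept + removed = total, ratio exact
                assert len(outcome.kept) + outcome.removed == len(pred)
                if len(pred):
                    assert outcome.filter_ratio == pytest.approx(
                        outcome.removed / len(pred)
                    )
                else:
                    assert outcome.filter_ratio == 0.0
                # idempotence (re-seed so cutoffs repeat)
                rng.setstate(state)
                again = apply_filter(outcome.kept)
                assert {(s.pair, s.start, s.end) for s in again.kept} == {
                    (s.pair, s.start, s.end) for s in outcome.kept
                }
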