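"""Post-prediction filters: multi-method consensus, multiplicity,
accessibility and degradome support.

Every filter is a pure PredictionSet -> FilterOutcome transform. The
outcome records how many sites were removed and the filter ratio
(removed / total), the bookkeeping used when comparing filter power.

Putative sites on the same (miRNA, transcript) pair that overlap by at
least 90% of their positions are grouped into one common interaction;
groups are the connected components of the >= 90%-overlap graph, which
makes grouping deterministic and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

from .datamodel import (
    ACCESSIBILITY_OK,
    DegradomeTable,
    PredictionSet,
    TargetSite,
)
from .align import interval_overlap_fraction
from .engines import ENGINE_ORDER

__all__ = [
    "FilterOutcome",
    "SiteGroup",
    "overlap_fraction",
    "group_sites",
    "filter_multi_method",
    "filter_multiplicity",
    "filter_accessibility",
    "filter_degradome",
    "DEFAULT_OVERLAP_THRESHOLD",
    "DEFAULT_MULTIPLICITY_CUTOFF",
    "DEFAULT_ACCESSIBILITY_CUTOFF",
    "DEFAULT_DEGRADOME_CUTOFF",
]

DEFAULT_OVERLAP_THRESHOLD = 0.90
DEFAULT_MULTIPLICITY_CUTOFF = 2
DEFAULT_ACCESSIBILITY_CUTOFF = -15.87  # kcal/mol
DEFAULT_DEGRADOME_CUTOFF = 4.5

_ENGINE_RANK = {label: k for k, label in enumerate(ENGINE_ORDER)}


@dataclass(frozen=True)
class FilterOutcome:
    """Result of one filter application with exact bookkeeping."""

    kept: PredictionSet
    removed: int
    filter_ratio: float
    uncomputed: int = 0  # sites dropped because accessibility was uncomputable

    @classmethod
    def build(
        cls, kept: Iterable[TargetSite], total: int, uncomputed: int = 0
    ) -> "FilterOutcome":
        kept_set = PredictionSet(tuple(kept))
        removed = total - len(kept_set)
        ratio = removed / total if total else 0.0
        return cls(kept=kept_set, removed=removed, filter_ratio=ratio, uncomputed=uncomputed)


def overlap_fraction(a: TargetSite, b: TargetSite) -> float:
    """Shared positional fraction of two sites of the same interaction.

    The denominator is the shorter site, so the measure is symmetric
    and equals 1.0 for identical intervals, 0.0 for disjoint ones.
    """
    if a.pair != b.pair:
        raise ValueError(
            f"overlap is defined within one (miRNA, transcript) pair; "
            f"got {a.pair} vs {b.pair}"
        )
    return interval_overlap_fraction(a.start, a.end, b.start, b.end)


def _provenance(site: TargetSite) -> frozenset[str]:
    return frozenset(site.engines)


def _rep_key(site: TargetSite) -> tuple:
    engine_rank = min(
        (_ENGINE_RANK.get(e, len(_ENGINE_RANK)) for e in site.engines),
        default=len(_ENGINE_RANK),
    )
    return (site.score, site.start, engine_rank, site.end, site.mirna_id)


@dataclass(frozen=True)
class SiteGroup:
    """Sites collapsed into one common interaction by >= 90% overlap."""

    sites: tuple[TargetSite, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("a site group needs at least one member")

    @property
    def representative(self) -> TargetSite:
        """Lowest weighted score; ties by leftmost start, then engine order."""
        return min(self.sites, key=_rep_key)

    @property
    def engines(self) -> frozenset[str]:
        out: set[str] = set()
        for site in self.sites:
            out.update(site.engines)
        return frozenset(out)

    @property
    def engine_count(self) -> int:
        return len(self.engines)

    @property
    def pair(self) -> tuple[str, str]:
        return self.sites[0].pair


def group_sites(
    sites: PredictionSet | Iterable[TargetSite],
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> list[SiteGroup]:
    """Connected components of the pairwise >= threshold overlap graph.

    Grouping is per (miRNA, transcript) pair; every site lands in
    exactly one group. Output order: (transcript, representative
    start, miRNA).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    all_sites = tuple(sites.sites if isinstance(sites, PredictionSet) else sites)
    buckets: dict[tuple[str, str], list[TargetSite]] = {}
    for site in all_sites:
        buckets.setdefault(site.pair, []).append(site)
    groups: list[SiteGroup] = []
    for members in buckets.values():
        parent = list(range(len(members)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if overlap_fraction(members[i], members[j]) >= threshold:
                    parent[find(i)] = find(j)
        comp: dict[int, list[TargetSite]] = {}
        for i, site in enumerate(members):
            comp.setdefault(find(i), []).append(site)
        for member_sites in comp.values():
            member_sites.sort(key=_rep_key)
            groups.append(SiteGroup(tuple(member_sites)))
    groups.sort(
        key=lambda g: (
            g.representative.transcript_id,
            g.representative.start,
            g.representative.mirna_id,
        )
    )
    return groups


def filter_multi_method(
    pred: PredictionSet,
    cutoff: int = 2,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> FilterOutcome:
    """Keep site groups supported by at least ``cutoff`` distinct engines.

    Each surviving group is represented by its best-scoring member,
    annotated with the full supporting-engine set. Cutoff 1 keeps all
    groups (but still collapses near-duplicates onto representatives).
    """
    if not 1 <= cutoff <= len(ENGINE_ORDER):
        raise ValueError(f"multi-method cutoff must be in 1..{len(ENGINE_ORDER)}")
    total = len(pred)
    kept = [
        replace(g.representative, support=tuple(sorted(g.engines)))
        for g in group_sites(pred, threshold)
        if g.engine_count >= cutoff
    ]
    return FilterOutcome.build(kept, total)


def filter_multiplicity(
    pred: PredictionSet,
    cutoff: int = DEFAULT_MULTIPLICITY_CUTOFF,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> FilterOutcome:
    """Keep sites of pairs with at least ``cutoff`` distinct site groups.

    Multiplicity counts grouped sites, so one physical site supported
    by several engines counts once. Kept sites are annotated with
    their pair's multiplicity.
    """
    if cutoff < 1:
        raise ValueError("multiplicity cutoff must be >= 1")
    total = len(pred)
    counts: dict[tuple[str, str], int] = {}
    for group in group_sites(pred, threshold):
        counts[group.pair] = counts.get(group.pair, 0) + 1
    kept = [
        replace(site, multiplicity=counts[site.pair])
        for site in pred
        if counts[site.pair] >= cutoff
    ]
    return FilterOutcome.build(kept, total)


def filter_accessibility(
    pred: PredictionSet,
    cutoff: float = DEFAULT_ACCESSIBILITY_CUTOFF,
) -> FilterOutcome:
    """Keep sites whose total accessibility energy is <= cutoff (kcal/mol).

    Sites whose accessibility could not be computed are removed and
    counted separately in ``uncomputed``. Sites must have been
    annotated (see :func:`phytomir.energy.annotate_accessibility`).
    """
    total = len(pred)
    kept: list[TargetSite] = []
    uncomputed = 0
    for site in pred:
        result = site.accessibility
        if result is None:
            raise ValueError(
                f"site {site.mirna_id}/{site.transcript_id} [{site.start},{site.end}) "
                "has no accessibility annotation"
            )
        if result.status != ACCESSIBILITY_OK:
            uncomputed += 1
            continue
        if result.total <= cutoff:
            kept.append(site)
    return FilterOutcome.build(kept, total, uncomputed=uncomputed)


def filter_degradome(
    pred: PredictionSet,
    records: DegradomeTable,
    cutoff: float = DEFAULT_DEGRADOME_CUTOFF,
) -> FilterOutcome:
    """Keep sites whose (miRNA, transcript) pair has degradome support.

    mRNA-level join: the pair must appear in the table with a
    (min-collapsed) score <= cutoff; lower degradome category scores
    mean stronger cleavage support. Kept sites are annotated with the
    supporting score.
    """
    total = len(pred)
    kept = [
        replace(site, degradome_score=records.score(site.pair))
        for site in pred
        if site.pair in records and records.score(site.pair) <= cutoff
    ]
    return FilterOutcome.build(kept, total)
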