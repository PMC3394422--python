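"""Benchmark metrics for target prediction against a validated reference.

Definitions (all comparisons at the target-site level unless noted):

* PM - predicted interactions: site groups after >= 90% overlap
  collapsing, one count per group.
* VM - validated predictions: groups whose (miRNA, transcript) pair is
  in the reference set. The reference is mRNA-level, so a validated
  pair predicted at three distinct sites contributes 3 to VM but 1 to
  CM; VM can therefore exceed the reference size.
* CM - coverage: distinct reference pairs recovered after collapsing
  predictions to mRNA level.
* AP - additional prediction, 100 x (PM - VM) / PM. Smaller is better.
* TP - true positive rate, 100 x CM / N_ref. Larger is better.
* filter power - geometric mean of a filter's filter ratio and the
  post-filter AP (as fractions). Smaller is better.

Percentages are reported to two decimals with half-away-from-zero
rounding.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .datamodel import PredictionSet, ReferenceSet, Region
from .filters import DEFAULT_OVERLAP_THRESHOLD, group_sites

__all__ = [
    "BenchmarkReport",
    "round_pct",
    "count_pm_vm_cm",
    "additional_prediction",
    "true_positive",
    "filter_power",
    "benchmark",
    "pairwise_agreement",
    "region_summary",
    "region_share",
    "column_average",
    "report_to_tsv",
    "report_to_json",
]


def round_pct(x: float) -> float:
    """Two-decimal percentage, rounded half away from zero."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _round_count(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BenchmarkReport:
    """PM/VM/CM counts plus the derived percentages for one predictor."""

    pm: int
    vm: int
    cm: int
    ap: float
    tp: float
    filter_ratio: Optional[float] = None
    filter_power: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.vm <= self.pm:
            raise ValueError(f"need 0 <= VM <= PM, got VM={self.vm}, PM={self.pm}")
        if self.cm > self.vm:
            raise ValueError(f"CM ({self.cm}) cannot exceed VM ({self.vm})")
        for name in ("ap", "tp"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")


def count_pm_vm_cm(
    pred: PredictionSet,
    ref: ReferenceSet,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> tuple[int, int, int]:
    """(PM, VM, CM) of a prediction set against the reference."""
    groups = group_sites(pred, threshold)
    pm = len(groups)
    vm = sum(1 for g in groups if g.pair in ref)
    cm = len({g.pair for g in groups} & set(ref.pairs))
    return pm, vm, cm


def additional_prediction(pm: int, vm: int) -> float:
    """AP percentage, 100 x (PM - VM) / PM, two decimals."""
    if pm <= 0:
        raise ValueError("additional prediction is undefined for PM = 0")
    if not 0 <= vm <= pm:
        raise ValueError(f"need 0 <= VM <= PM, got VM={vm}, PM={pm}")
    return round_pct(100.0 * (pm - vm) / pm)


def true_positive(cm: int, n_ref: int) -> float:
    """TP percentage, 100 x CM / N_ref, two decimals."""
    if n_ref <= 0:
        raise ValueError("true positive rate needs a non-empty reference set")
    if not 0 <= cm <= n_ref:
        raise ValueError(f"need 0 <= CM <= N_ref, got CM={cm}, N_ref={n_ref}")
    return round_pct(100.0 * cm / n_ref)


def filter_power(filter_ratio: float, ap_fraction: float) -> float:
    """Geometric mean of filter ratio and additional prediction (fractions)."""
    for name, v in (("filter_ratio", filter_ratio), ("ap_fraction", ap_fraction)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return math.sqrt(filter_ratio * ap_fraction)


def benchmark(
    pred: PredictionSet,
    ref: ReferenceSet,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> BenchmarkReport:
    """Full report for one prediction set against the reference."""
    pm, vm, cm = count_pm_vm_cm(pred, ref, threshold)
    return BenchmarkReport(
        pm=pm,
        vm=vm,
        cm=cm,
        ap=additional_prediction(pm, vm),
        tp=true_positive(cm, ref.n_ref),
    )


def pairwise_agreement(
    engine_sets: Mapping[str, PredictionSet],
    level: str = "site",
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> pd.DataFrame:
    """Common-interaction percentages between every pair of predictors.

    At site level, the two sets' sites are pooled and grouped by
    >= 90% overlap; a group found by both predictors is common. At
    mRNA level, common means the intersection of collapsed pairs. The
    denominator is the smaller set, the matrix is symmetric with a
    diagonal of 100.
    """
    if level not in ("site", "mrna"):
        raise ValueError("level must be 'site' or 'mrna'")
    labels = list(engine_sets)
    if len(labels) < 2:
        raise ValueError("pairwise agreement needs at least two prediction sets")
    if level == "site":
        sizes = {lab: len(group_sites(s, threshold)) for lab, s in engine_sets.items()}
    else:
        sizes = {lab: len(s.mrna_pairs()) for lab, s in engine_sets.items()}
    matrix = pd.DataFrame(100.0, index=labels, columns=labels)
    for ia, la in enumerate(labels):
        for lb in labels[ia + 1 :]:
            denom = min(sizes[la], sizes[lb])
            if denom == 0:
                pct = 0.0
            elif level == "mrna":
                common = len(
                    engine_sets[la].mrna_pairs() & engine_sets[lb].mrna_pairs()
                )
                pct = round_pct(100.0 * common / denom)
            else:
                # fresh copies so shared site objects keep distinct provenance
                tagged = [(replace(site), la) for site in engine_sets[la]] + [
                    (replace(site), lb) for site in engine_sets[lb]
                ]
                origin = {id(site): lab for site, lab in tagged}
                pooled = [site for site, _ in tagged]
                common = 0
                for group in group_sites(pooled, threshold):
                    found = {origin[id(site)] for site in group.sites}
                    if len(found) == 2:
                        common += 1
                pct = round_pct(100.0 * common / denom)
            matrix.loc[la, lb] = matrix.loc[lb, la] = pct
    return matrix


_REGION_ORDER = (Region.FIVE_UTR, Region.CDS, Region.THREE_UTR, Region.UNSPLIT)


def region_summary(
    pred: PredictionSet,
    ref: Optional[ReferenceSet] = None,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> pd.DataFrame:
    """Per-region attribution table (rows: predicted / validated / collapsed).

    ``predicted`` counts site groups per region, ``validated`` those
    whose pair is in the reference, ``collapsed`` the distinct
    reference pairs recovered in that region. Columns cover the
    regions present in the input, in 5'UTR, CDS, 3'UTR order.
    """
    groups = group_sites(pred, threshold)
    regions = [r for r in _REGION_ORDER if any(g.representative.region is r for g in groups)]
    data: dict[str, list[int]] = {}
    for region in regions:
        in_region = [g for g in groups if g.representative.region is region]
        predicted = len(in_region)
        if ref is None:
            validated = 0
            collapsed = 0
        else:
            validated = sum(1 for g in in_region if g.pair in ref)
            collapsed = len({g.pair for g in in_region} & set(ref.pairs))
        data[region.value] = [predicted, validated, collapsed]
    return pd.DataFrame(data, index=["predicted", "validated", "collapsed"])


def region_share(
    summary: pd.DataFrame, region: Region | str, row: str = "predicted"
) -> float:
    """Percentage of one region's count over the row total, two decimals."""
    label = Region.from_label(region).value
    total = int(summary.loc[row].sum())
    if total == 0:
        raise ValueError(f"row {row!r} has no counts")
    value = int(summary.loc[row, label]) if label in summary.columns else 0
    return round_pct(100.0 * value / total)


def column_average(reports: Sequence[BenchmarkReport]) -> BenchmarkReport:
    """Arithmetic column mean: counts to the nearest integer,
    percentages to two decimals."""
    if not reports:
        raise ValueError("column_average needs at least one report")
    n = len(reports)
    mean = lambda xs: sum(xs) / n  # noqa: E731
    kwargs = {}
    for optional in ("filter_ratio", "filter_power"):
        values = [getattr(r, optional) for r in reports]
        if all(v is not None for v in values):
            kwargs[optional] = mean(values)
    return BenchmarkReport(
        pm=_round_count(mean([r.pm for r in reports])),
        vm=_round_count(mean([r.vm for r in reports])),
        cm=_round_count(mean([r.cm for r in reports])),
        ap=round_pct(mean([r.ap for r in reports])),
        tp=round_pct(mean([r.tp for r in reports])),
        **kwargs,
    )


_REPORT_COLUMNS = ["method", "PM", "VM", "CM", "AP", "TP", "filter_ratio", "filter_power"]


def report_to_tsv(reports: Mapping[str, BenchmarkReport], path) -> None:
    """Write a table of per-method reports mirroring the benchmark layout."""
    rows = []
    for method, rep in reports.items():
        rows.append(
            [method, rep.pm, rep.vm, rep.cm, rep.ap, rep.tp, rep.filter_ratio, rep.filter_power]
        )
    pd.DataFrame(rows, columns=_REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def report_to_json(reports: Mapping[str, BenchmarkReport], path) -> None:
    payload = {method: asdict(rep) for method, rep in reports.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
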