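"""Readers and writers for FASTA inputs, evidence tables and result rows.

Result files are plain TSV with one row per site (or per surviving
site group after filtering) and a fixed, documented column set, so
they round-trip losslessly and are easy to post-process.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO

from .datamodel import (
    ACCESSIBILITY_OK,
    ACCESSIBILITY_UNCOMPUTED,
    DegradomeRecord,
    DegradomeTable,
    FunctionalType,
    MatureMiRNA,
    PredictionSet,
    ReferenceSet,
    Region,
    TargetSite,
    TranscriptRegion,
)
from .energy import AccessibilityResult

__all__ = [
    "read_fasta",
    "read_mirnas",
    "read_transcripts",
    "write_fasta",
    "read_reference",
    "read_degradome",
    "RESULT_COLUMNS",
    "results_frame",
    "write_results",
    "read_results",
    "extract_rows",
    "sort_sites",
]

logger = logging.getLogger("phytomir")

#: Stable column set of site-level result files.
RESULT_COLUMNS = [
    "mirna_id",
    "transcript_id",
    "region",
    "start",
    "end",
    "engines",
    "score",
    "energy_ratio",
    "functional_type",
    "multiplicity",
    "accessibility",
    "degradome_score",
    "filters_passed",
]

_NA = "NA"


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records; duplicate ids or empty sequences
    are rejected naming the offending record."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def read_mirnas(path: str | Path) -> list[MatureMiRNA]:
    return [MatureMiRNA(id=rid, seq=seq) for rid, seq in read_fasta(path)]


def read_transcripts(
    path: str | Path, region: Region | str = Region.UNSPLIT
) -> list[TranscriptRegion]:
    reg = Region.from_label(region)
    return [
        TranscriptRegion(transcript_id=rid, seq=seq, region=reg)
        for rid, seq in read_fasta(path)
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [col for col in required if col not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return frame


def read_reference(path: str | Path) -> ReferenceSet:
    """Validated-pair TSV: columns mirna_id, transcript_id; header required."""
    frame = _read_tsv(path, ["mirna_id", "transcript_id"])
    return ReferenceSet.from_pairs(
        zip(frame["mirna_id"].astype(str), frame["transcript_id"].astype(str))
    )


def read_degradome(path: str | Path) -> DegradomeTable:
    """Degradome TSV: mirna_id, transcript_id, score; duplicates are
    collapsed to the minimum (strongest-support) score."""
    frame = _read_tsv(path, ["mirna_id", "transcript_id", "score"])
    records = []
    for idx, row in frame.iterrows():
        try:
            score = float(row["score"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: non-numeric degradome score {row['score']!r} on data row {idx + 1}"
            ) from None
        records.append(DegradomeRecord(str(row["mirna_id"]), str(row["transcript_id"]), score))
    return DegradomeTable.from_records(records)


def _fmt(value, digits: int = 4) -> str:
    if value is None:
        return _NA
    if isinstance(value, float):
        if math.isnan(value):
            return _NA
        return f"{value:.{digits}g}" if abs(value) >= 1e-3 or value == 0 else repr(value)
    return str(value)


def results_frame(pred: PredictionSet) -> pd.DataFrame:
    """Site rows in deterministic (transcript, start, miRNA) order."""
    rows = []
    for site in sort_sites(pred):
        if site.accessibility is None:
            access = _NA
        elif site.accessibility.status != ACCESSIBILITY_OK:
            access = ACCESSIBILITY_UNCOMPUTED
        else:
            access = _fmt(site.accessibility.total, 6)
        rows.append(
            {
                "mirna_id": site.mirna_id,
                "transcript_id": site.transcript_id,
                "region": site.region.value,
                "start": site.start,
                "end": site.end,
                "engines": ",".join(site.engines) or _NA,
                "score": _fmt(site.score, 6),
                "energy_ratio": _fmt(site.energy_ratio, 6),
                "functional_type": site.functional_type.value,
                "multiplicity": _fmt(site.multiplicity),
                "accessibility": access,
                "degradome_score": _fmt(site.degradome_score, 6),
                "filters_passed": ",".join(site.filters_passed) or _NA,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(pred: PredictionSet, path: str | Path) -> None:
    results_frame(pred).to_csv(path, sep="\t", index=False)


def _parse_optional_float(text: str) -> Optional[float]:
    return None if text == _NA else float(text)


def read_results(path: str | Path) -> PredictionSet:
    """Read a result TSV back into a PredictionSet.

    Duplex alignments are not serialized, so restored sites carry
    ``duplex=None``; accessibility totals are restored as opaque
    totals (components unavailable after serialization).
    """
    frame = _read_tsv(path, RESULT_COLUMNS)
    sites = []
    for _, row in frame.iterrows():
        engines = tuple(e for e in str(row["engines"]).split(",") if e and e != _NA)
        access_text = str(row["accessibility"])
        if access_text == _NA:
            access = None
        elif access_text == ACCESSIBILITY_UNCOMPUTED:
            access = AccessibilityResult.uncomputed()
        else:
            total = float(access_text)
            access = AccessibilityResult(opening=0.0, duplex=total, total=total)
        multiplicity = row["multiplicity"]
        filters_passed = tuple(
            f for f in str(row["filters_passed"]).split(",") if f and f != _NA
        )
        sites.append(
            TargetSite(
                mirna_id=str(row["mirna_id"]),
                transcript_id=str(row["transcript_id"]),
                region=Region.from_label(row["region"]),
                start=int(row["start"]),
                end=int(row["end"]),
                engine=engines[0] if len(engines) == 1 else None,
                support=engines if len(engines) > 1 else (),
                score=float(row["score"]),
                energy_ratio=_parse_optional_float(str(row["energy_ratio"])),
                functional_type=FunctionalType(str(row["functional_type"])),
                multiplicity=None if multiplicity == _NA else int(multiplicity),
                accessibility=access,
                degradome_score=_parse_optional_float(str(row["degradome_score"])),
                filters_passed=filters_passed,
            )
        )
    return PredictionSet(tuple(sites))


def extract_rows(
    pred: PredictionSet, by: str, identifier: str
) -> PredictionSet:
    """All rows for one miRNA or transcript; unknown ids yield an empty
    subset with a warning, not an error."""
    if by not in ("mirna", "transcript"):
        raise ValueError("extract 'by' must be 'mirna' or 'transcript'")
    key = (lambda s: s.mirna_id) if by == "mirna" else (lambda s: s.transcript_id)
    subset = [site for site in pred if key(site) == identifier]
    if not subset:
        logger.warning("no result rows for %s %r", by, identifier)
    return PredictionSet(tuple(sort_sites(PredictionSet(tuple(subset)))))


def sort_sites(pred: PredictionSet, by: str = "position") -> list[TargetSite]:
    """Stable, documented orders: 'position' (transcript, start, miRNA)
    or 'score' (score, then position)."""
    position_key = lambda s: (s.transcript_id, s.start, s.end, s.mirna_id, s.engine or "")  # noqa: E731
    if by == "position":
        return sorted(pred, key=position_key)
    if by == "score":
        return sorted(pred, key=lambda s: (s.score,) + position_key(s))
    raise ValueError("sort 'by' must be 'position' or 'score'")
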