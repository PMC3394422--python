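"""Core data types and coordinate conventions.

Conventions used throughout the toolkit:

* miRNA positions are 1-based, counted from the miRNA 5' end. The seed
  region is positions 2-8, the central region 9-11, and the core region
  2-12. Plant miRNAs pair near-perfectly with their targets and the
  central region is where cleavage-competent duplexes must pair.
* Transcript coordinates are 0-based half-open intervals on the sense
  strand of the supplied sequence; interval arithmetic (overlap
  fractions, flank extraction) is exact under this convention.
* All sequences are normalised to the RNA alphabet ``ACGU``: ``T`` is
  rewritten to ``U`` and lowercase is uppercased on input.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Iterator, Optional

RNA_ALPHABET = frozenset("ACGU")

WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: miRNA position windows (1-based, inclusive) used by the rule engines.
SEED_WINDOW = (2, 8)
CENTRAL_WINDOW = (9, 11)
CORE_WINDOW = (2, 12)


def normalize_rna(seq: str, *, what: str = "sequence") -> str:
    """Uppercase, rewrite T->U and validate against the RNA alphabet."""
    norm = seq.strip().upper().replace("T", "U")
    bad = set(norm) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"{what} contains non-ACGU characters after normalization: "
            f"{sorted(bad)!r}"
        )
    return norm


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string."""
    return "".join(WC_PARTNER[b] for b in reversed(seq))


class PairState(enum.Enum):
    """State of one aligned miRNA:target position."""

    WC_MATCH = "WC"
    GU_WOBBLE = "GU"
    MISMATCH = "MM"
    GAP_MIRNA = "GAP_MIRNA"  # bulged target base, no miRNA base opposite
    GAP_TARGET = "GAP_TARGET"  # bulged miRNA base, no target base opposite


GAP_STATES = frozenset({PairState.GAP_MIRNA, PairState.GAP_TARGET})
PAIRED_STATES = frozenset({PairState.WC_MATCH, PairState.GU_WOBBLE})


class Region(enum.Enum):
    """Transcript region a site falls in (for Table-style attribution)."""

    FIVE_UTR = "5UTR"
    CDS = "CDS"
    THREE_UTR = "3UTR"
    UNSPLIT = "UNSPLIT"

    @classmethod
    def from_label(cls, label: "Region | str") -> "Region":
        if isinstance(label, Region):
            return label
        text = str(label).strip().upper()
        aliases = {
            "5UTR": cls.FIVE_UTR,
            "5'UTR": cls.FIVE_UTR,
            "FIVE_UTR": cls.FIVE_UTR,
            "UTR5": cls.FIVE_UTR,
            "CDS": cls.CDS,
            "3UTR": cls.THREE_UTR,
            "3'UTR": cls.THREE_UTR,
            "THREE_UTR": cls.THREE_UTR,
            "UTR3": cls.THREE_UTR,
            "UNSPLIT": cls.UNSPLIT,
        }
        if text not in aliases:
            raise ValueError(f"unknown transcript region label: {label!r}")
        return aliases[text]


class FunctionalType(enum.Enum):
    """Predicted mode of action: cleavage vs translational repression."""

    CLEAVAGE = "CLEAVAGE"
    TRANSLATION = "TRANSLATION"
    UNSET = "UNSET"


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA guide strand, positions 1..L from the 5' end."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("miRNA id must be non-empty")
        object.__setattr__(self, "seq", normalize_rna(self.seq, what=f"miRNA {self.id!r}"))
        if not 15 <= len(self.seq) <= 30:
            raise ValueError(
                f"miRNA {self.id!r} length {len(self.seq)} outside accepted range 15-30 nt"
            )
        if not 20 <= len(self.seq) <= 24:
            warnings.warn(
                f"miRNA {self.id!r} length {len(self.seq)} is outside the typical "
                "20-24 nt range for plant mature miRNAs",
                stacklevel=2,
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TranscriptRegion:
    """A transcript (or one region of it) to be scanned for target sites."""

    transcript_id: str
    seq: str
    region: Region = Region.UNSPLIT

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript id must be non-empty")
        object.__setattr__(
            self,
            "seq",
            normalize_rna(self.seq, what=f"transcript {self.transcript_id!r}"),
        )
        object.__setattr__(self, "region", Region.from_label(self.region))
        if not self.seq:
            raise ValueError(f"transcript {self.transcript_id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DuplexAlignment:
    """An antiparallel miRNA:target alignment.

    ``pair_states`` runs along the miRNA from position 1 (miRNA 5' end,
    opposite the 3'-most target base of the site) to position L, with
    GAP_MIRNA states interleaved where the target bulges. ``pairs``
    carries the aligned (miRNA base, target base) letters, ``None`` on
    the gapped side.
    """

    mirna_length: int
    pair_states: tuple[PairState, ...]
    pairs: tuple[tuple[Optional[str], Optional[str]], ...]

    def __post_init__(self) -> None:
        n_gap_mirna = sum(1 for s in self.pair_states if s is PairState.GAP_MIRNA)
        if len(self.pair_states) != self.mirna_length + n_gap_mirna:
            raise ValueError(
                "pair_states length must equal miRNA length plus GAP_MIRNA count: "
                f"{len(self.pair_states)} != {self.mirna_length} + {n_gap_mirna}"
            )
        if len(self.pairs) != len(self.pair_states):
            raise ValueError("pairs and pair_states must have the same length")
        for state, (mb, tb) in zip(self.pair_states, self.pairs):
            if state is PairState.GAP_MIRNA and mb is not None:
                raise ValueError("GAP_MIRNA states carry no miRNA base")
            if state is PairState.GAP_TARGET and tb is not None:
                raise ValueError("GAP_TARGET states carry no target base")
            if state not in GAP_STATES and (mb is None or tb is None):
                raise ValueError(f"{state.name} states need both bases")

    def mirna_positions(self) -> tuple[int, ...]:
        """1-based miRNA position of every state.

        GAP_MIRNA states sit between miRNA bases and are assigned the
        position of the next miRNA base (clamped to L) for window
        bookkeeping.
        """
        positions = []
        consumed = 0
        for state in self.pair_states:
            if state is PairState.GAP_MIRNA:
                positions.append(min(consumed + 1, self.mirna_length))
            else:
                consumed += 1
                positions.append(consumed)
        return tuple(positions)

    def count(
        self,
        *states: PairState,
        window: Optional[tuple[int, int]] = None,
    ) -> int:
        """Number of states of the given kinds, optionally restricted to a
        1-based inclusive miRNA-position window such as the seed (2, 8)."""
        wanted = set(states) if states else set(PairState)
        total = 0
        for state, pos in zip(self.pair_states, self.mirna_positions()):
            if state in wanted and (window is None or window[0] <= pos <= window[1]):
                total += 1
        return total

    @property
    def n_mismatches(self) -> int:
        return self.count(PairState.MISMATCH)

    @property
    def n_gu(self) -> int:
        return self.count(PairState.GU_WOBBLE)

    @property
    def n_gaps(self) -> int:
        return self.count(*GAP_STATES)

    @property
    def target_span(self) -> int:
        """Number of target bases covered (non-GAP_TARGET states)."""
        return sum(1 for s in self.pair_states if s is not PairState.GAP_TARGET)


ACCESSIBILITY_OK = "OK"
ACCESSIBILITY_UNCOMPUTED = "UNCOMPUTED"


@dataclass(frozen=True)
class TargetSite:
    """A located candidate site plus its duplex and per-engine annotation."""

    mirna_id: str
    transcript_id: str
    start: int
    end: int
    duplex: Optional[DuplexAlignment] = None
    region: Region = Region.UNSPLIT
    engine: Optional[str] = None
    score: float = 0.0
    energy_ratio: Optional[float] = None
    functional_type: FunctionalType = FunctionalType.UNSET
    accessibility: Optional[Any] = None  # energy.AccessibilityResult
    support: tuple[str, ...] = ()
    degradome_score: Optional[float] = None
    multiplicity: Optional[int] = None
    filters_passed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid site interval [{self.start}, {self.end}) for "
                f"{self.mirna_id}/{self.transcript_id}"
            )
        if self.energy_ratio is not None and not 0.0 <= self.energy_ratio <= 1.0:
            raise ValueError(f"energy_ratio {self.energy_ratio} outside [0, 1]")
        if self.duplex is not None and self.end - self.start != self.duplex.target_span:
            raise ValueError(
                "site span must equal the duplex target span: "
                f"{self.end - self.start} != {self.duplex.target_span}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna_id, self.transcript_id)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def engines(self) -> tuple[str, ...]:
        """Provenance labels: the support set if grouped, else the engine."""
        if self.support:
            return self.support
        return (self.engine,) if self.engine else ()


def _site_sort_key(site: TargetSite) -> tuple:
    return (site.transcript_id, site.start, site.end, site.mirna_id, site.engine or "")


@dataclass(frozen=True)
class PredictionSet:
    """A collection of TargetSites with engine provenance."""

    sites: tuple[TargetSite, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", tuple(self.sites))

    @classmethod
    def empty(cls) -> "PredictionSet":
        return cls(())

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[TargetSite]:
        return iter(self.sites)

    def __bool__(self) -> bool:
        return bool(self.sites)

    def mrna_pairs(self) -> set[tuple[str, str]]:
        return {site.pair for site in self.sites}

    def sorted(self) -> "PredictionSet":
        return PredictionSet(tuple(sorted(self.sites, key=_site_sort_key)))


def collapse_to_mrna(pred: PredictionSet | Iterable[TargetSite]) -> set[tuple[str, str]]:
    """Collapse site-level predictions to unique (miRNA, transcript) pairs.

    Idempotent projection; an empty input yields an empty set.
    """
    sites = pred.sites if isinstance(pred, PredictionSet) else tuple(pred)
    return {site.pair for site in sites}


def annotate_region(site: TargetSite, region_label: Region | str) -> TargetSite:
    """Return the site carrying the given region label.

    Raises ``ValueError`` for labels outside the four known regions.
    """
    return replace(site, region=Region.from_label(region_label))


@dataclass(frozen=True)
class ReferenceSet:
    """Experimentally validated (miRNA, transcript) pairs, mRNA level."""

    pairs: frozenset[tuple[str, str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "ReferenceSet":
        return cls(frozenset((str(m), str(t)) for m, t in pairs))

    @property
    def n_ref(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)


@dataclass(frozen=True)
class DegradomeRecord:
    """One degradome-supported interaction; lower score = stronger support."""

    mirna_id: str
    transcript_id: str
    degradome_score: float

    def __post_init__(self) -> None:
        score = float(self.degradome_score)
        if score != score or score in (float("inf"), float("-inf")):
            raise ValueError(
                f"degradome score for {self.mirna_id}/{self.transcript_id} must be finite"
            )
        object.__setattr__(self, "degradome_score", score)


@dataclass(frozen=True)
class DegradomeTable:
    """Degradome evidence keyed by mRNA-level pair, min-collapsed."""

    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: Iterable[DegradomeRecord]) -> "DegradomeTable":
        scores: dict[tuple[str, str], float] = {}
        for rec in records:
            key = (rec.mirna_id, rec.transcript_id)
            prev = scores.get(key)
            if prev is None or rec.degradome_score < prev:
                scores[key] = rec.degradome_score
        return cls(scores)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.scores

    def __len__(self) -> int:
        return len(self.scores)

    def score(self, pair: tuple[str, str]) -> float:
        return self.scores[pair]
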