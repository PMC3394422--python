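"""Hybridization energy, energy ratio and target-site accessibility.

The energy layer is deliberately a simplified, fully deterministic
model so the whole pipeline runs with no external folding binary:

* duplex hybridization energy is a per-pair sum (G:C -3, A:U -2,
  G:U -1 kcal/mol; mismatches and gaps contribute nothing),
* the reference energy is the same sum for the miRNA paired with its
  perfect reverse complement, giving the energy ratio
  ``duplex / perfect`` in [0, 1] (>= 0.70 is the classic acceptance
  threshold),
* target-site accessibility is the free energy needed to open the
  site within its local secondary structure plus the hybridization
  energy. Opening energy is computed with a Nussinov-style minimum
  energy pairing DP (minimum hairpin loop 3 nt) on a window of at
  most 100 nt of flanking sequence on each side of the site.

A thermodynamically rigorous engine (e.g. an RNAup-style partition
function tool) can be plugged in through the ``backend`` contract of
:func:`accessibility`: any replacement must return an opening energy
>= 0 and a duplex energy <= 0 for the same window and site.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Optional

import numpy as np

from .datamodel import (
    ACCESSIBILITY_OK,
    ACCESSIBILITY_UNCOMPUTED,
    PAIRED_STATES,
    DuplexAlignment,
    MatureMiRNA,
    PredictionSet,
    TargetSite,
    TranscriptRegion,
    normalize_rna,
)

__all__ = [
    "EnergyParams",
    "AccessibilityResult",
    "duplex_energy",
    "perfect_energy",
    "energy_ratio",
    "extract_flanks",
    "fold_energy",
    "opening_energy",
    "accessibility",
    "annotate_accessibility",
]


@dataclass(frozen=True)
class EnergyParams:
    """Per-pair energy contributions (kcal/mol) and folding settings."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    min_loop: int = 3  # minimum hairpin loop length, nt
    flank: int = 100  # flanking sequence taken on each side of a site

    def __post_init__(self) -> None:
        if self.gc > 0 or self.au > 0 or self.gu > 0:
            raise ValueError("pair energy contributions must be <= 0")
        if self.flank < 0:
            raise ValueError("flank length must be >= 0")


DEFAULT_ENERGY_PARAMS = EnergyParams()


def _pair_contribution(a: str, b: str, params: EnergyParams) -> float:
    key = frozenset((a, b))
    if key == frozenset("GC"):
        return params.gc
    if key == frozenset("AU"):
        return params.au
    if key == frozenset("GU"):
        return params.gu
    return 0.0


def duplex_energy(
    duplex: DuplexAlignment, params: EnergyParams = DEFAULT_ENERGY_PARAMS
) -> float:
    """Hybridization energy of a duplex: per-pair sum over paired positions."""
    total = 0.0
    for state, (mb, tb) in zip(duplex.pair_states, duplex.pairs):
        if state in PAIRED_STATES:
            total += _pair_contribution(mb, tb, params)
    return total


def perfect_energy(
    mirna: MatureMiRNA | str, params: EnergyParams = DEFAULT_ENERGY_PARAMS
) -> float:
    """Energy of the miRNA against its exact reverse complement."""
    seq = mirna.seq if isinstance(mirna, MatureMiRNA) else normalize_rna(mirna)
    return sum(params.gc if b in "GC" else params.au for b in seq)


def energy_ratio(
    duplex: DuplexAlignment,
    mirna: MatureMiRNA | str,
    params: EnergyParams = DEFAULT_ENERGY_PARAMS,
) -> float:
    """Duplex energy over perfect-complement energy, clamped to [0, 1]."""
    perfect = perfect_energy(mirna, params)
    if perfect >= 0:
        raise ValueError("perfect-complement energy must be negative")
    ratio = duplex_energy(duplex, params) / perfect
    return min(1.0, max(0.0, ratio))


def extract_flanks(
    transcript: TranscriptRegion | str,
    site: TargetSite,
    flank: Optional[int] = None,
) -> tuple[str, int]:
    """Window of at most ``flank`` nt on each side of the site.

    Returns ``(window sequence, window offset on the transcript)``;
    the window always contains the site and is clamped at transcript
    boundaries.
    """
    seq = transcript.seq if isinstance(transcript, TranscriptRegion) else transcript
    if flank is None:
        flank = DEFAULT_ENERGY_PARAMS.flank
    if not 0 <= site.start < site.end <= len(seq):
        raise ValueError(
            f"site [{site.start}, {site.end}) outside transcript of length {len(seq)}"
        )
    lo = max(0, site.start - flank)
    hi = min(len(seq), site.end + flank)
    return seq[lo:hi], lo


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


def _pair_energy_matrix(seq: str, params: EnergyParams) -> np.ndarray:
    table = np.full((4, 4), np.inf)
    table[0, 3] = table[3, 0] = params.au
    table[2, 1] = table[1, 2] = params.gc
    table[2, 3] = table[3, 2] = params.gu
    codes = np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.intp, count=len(seq))
    return table[codes[:, None], codes[None, :]]


def fold_energy(
    seq: str,
    params: EnergyParams = DEFAULT_ENERGY_PARAMS,
    forbidden: Iterable[int] = (),
) -> float:
    """Minimum energy over nested secondary structures (Nussinov-style DP).

    Positions listed in ``forbidden`` (0-based) may not pair; pairs
    must enclose at least ``min_loop`` unpaired bases. Returns 0.0 for
    sequences that cannot form any pair.
    """
    s = normalize_rna(seq, what="fold window")
    n = len(s)
    if n == 0:
        return 0.0
    P = _pair_energy_matrix(s, params)
    banned = list(forbidden)
    if banned:
        P[banned, :] = np.inf
        P[:, banned] = np.inf
    E = np.zeros((n, n))
    for l in range(1, n):
        i = np.arange(0, n - l)
        j = i + l
        best = np.minimum(E[i + 1, j], E[i, j - 1])
        if l >= params.min_loop + 1:
            best = np.minimum(best, E[i + 1, j - 1] + P[i, j])
        for split in range(1, l - 1):
            best = np.minimum(best, E[i, i + split] + E[i + split + 1, j])
        E[i, j] = best
    return float(E[0, n - 1])


def opening_energy(
    window: str,
    site_span_in_window: tuple[int, int],
    params: EnergyParams = DEFAULT_ENERGY_PARAMS,
) -> float:
    """Free energy needed to open (unpair) the site within the window.

    ``E_open = E_fold(window, site forced unpaired) - E_fold(window)``;
    always >= 0 because constraining the fold cannot improve it.
    """
    lo, hi = site_span_in_window
    if not 0 <= lo < hi <= len(window):
        raise ValueError(
            f"site span [{lo}, {hi}) outside window of length {len(window)}"
        )
    constrained = fold_energy(window, params, forbidden=range(lo, hi))
    unconstrained = fold_energy(window, params)
    return constrained - unconstrained


@dataclass(frozen=True)
class AccessibilityResult:
    """Opening + hybridization energy of one target site (kcal/mol)."""

    opening: float
    duplex: float
    total: float
    status: str = ACCESSIBILITY_OK

    @classmethod
    def ok(cls, opening: float, duplex: float) -> "AccessibilityResult":
        return cls(opening=opening, duplex=duplex, total=opening + duplex)

    @classmethod
    def uncomputed(cls) -> "AccessibilityResult":
        nan = float("nan")
        return cls(opening=nan, duplex=nan, total=nan, status=ACCESSIBILITY_UNCOMPUTED)

    @property
    def is_ok(self) -> bool:
        return self.status == ACCESSIBILITY_OK


#: Backend contract: (window sequence, site span within window, site) ->
#: (opening energy >= 0, duplex energy <= 0). Raising marks the site
#: UNCOMPUTED; it never aborts a batch.
AccessibilityBackend = Callable[[str, tuple[int, int], TargetSite], tuple[float, float]]


def accessibility(
    mirna: MatureMiRNA,
    transcript: TranscriptRegion,
    site: TargetSite,
    params: EnergyParams = DEFAULT_ENERGY_PARAMS,
    backend: Optional[AccessibilityBackend] = None,
) -> AccessibilityResult:
    """Real accessibility of a site: opening energy plus duplex energy.

    The window is the site plus at most ``params.flank`` nt on each
    side. A failing backend yields an UNCOMPUTED result rather than an
    exception, so batch runs never abort.
    """
    try:
        window, offset = extract_flanks(transcript, site, params.flank)
        span = (site.start - offset, site.end - offset)
        if backend is not None:
            opening, duplex = backend(window, span, site)
        else:
            if site.duplex is None:
                raise ValueError("site carries no duplex alignment")
            opening = opening_energy(window, span, params)
            duplex = duplex_energy(site.duplex, params)
        if opening < 0 or duplex > 0:
            raise ValueError(
                f"backend returned opening={opening}, duplex={duplex}; "
                "contract requires opening >= 0 and duplex <= 0"
            )
    except Exception:
        return AccessibilityResult.uncomputed()
    return AccessibilityResult.ok(opening, duplex)


def annotate_accessibility(
    pred: PredictionSet,
    mirnas: Iterable[MatureMiRNA],
    transcripts: Iterable[TranscriptRegion],
    params: EnergyParams = DEFAULT_ENERGY_PARAMS,
    backend: Optional[AccessibilityBackend] = None,
) -> PredictionSet:
    """Attach an AccessibilityResult to every site of a prediction set."""
    mirna_by_id = {m.id: m for m in mirnas}
    tx_by_id = {t.transcript_id: t for t in transcripts}
    out = []
    for site in pred:
        mi = mirna_by_id.get(site.mirna_id)
        tx = tx_by_id.get(site.transcript_id)
        if mi is None or tx is None:
            result = AccessibilityResult.uncomputed()
        else:
            result = accessibility(mi, tx, site, params, backend)
        out.append(replace(site, accessibility=result))
    return PredictionSet(tuple(out))
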