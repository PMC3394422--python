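"""Candidate site discovery by antiparallel complementarity alignment.

A miRNA binds its target antiparallel: miRNA position 1 (the 5' end)
pairs with the 3'-most base of the target site. Candidate windows on
the transcript are aligned against the miRNA under a weighted penalty
scheme in the Allen-score tradition used by plant target predictors:
mismatches cost 1.0, G:U wobbles 0.5 and gaps 2.0, with every penalty
doubled inside the core region (miRNA positions 2-12, covering both the
seed 2-8 and the central region 9-11). Lower scores mean better
complementarity; a perfect reverse-complement site scores 0.

The search is a correctness-first sliding scan: every window whose
minimum-penalty gapped alignment passes the cutoff is emitted, then
near-duplicate hits (>= 90% positional overlap) are collapsed onto the
best-scoring one.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from .datamodel import (
    WC_PARTNER,
    CENTRAL_WINDOW,
    CORE_WINDOW,
    SEED_WINDOW,
    DuplexAlignment,
    MatureMiRNA,
    PairState,
    RNA_ALPHABET,
    TargetSite,
    TranscriptRegion,
    normalize_rna,
)

__all__ = [
    "ScanParams",
    "pair_state",
    "align_window",
    "weighted_score",
    "scan_transcript",
    "interval_overlap_fraction",
]

_GU_PAIRS = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class ScanParams:
    """Weights, windows and search-space limits for the sliding scan.

    Defaults follow the plant-predictor convention: mismatch 1.0,
    G:U 0.5, gap 2.0, all doubled inside the core (2-12); at most one
    bulge of length one per duplex.
    """

    mismatch_weight: float = 1.0
    gu_weight: float = 0.5
    gap_weight: float = 2.0
    core_multiplier: float = 2.0
    core: tuple[int, int] = CORE_WINDOW
    seed: tuple[int, int] = SEED_WINDOW
    central: tuple[int, int] = CENTRAL_WINDOW
    max_gaps: int = 1
    max_gap_len: int = 1
    max_penalty_score: float = 4.0
    overlap_threshold: float = 0.90

    def __post_init__(self) -> None:
        for name in ("mismatch_weight", "gu_weight", "gap_weight", "core_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_gaps < 0 or self.max_gap_len < 0:
            raise ValueError("gap limits must be non-negative")
        if not 0 < self.overlap_threshold <= 1:
            raise ValueError("overlap_threshold must be in (0, 1]")

    @property
    def max_indel(self) -> int:
        """Largest net length difference between miRNA and window."""
        return self.max_gaps * self.max_gap_len


DEFAULT_SCAN_PARAMS = ScanParams()


def pair_state(mirna_base: str, target_base: str) -> PairState:
    """Classify one miRNA:target base pair.

    Watson-Crick pairs (A:U, U:A, G:C, C:G) are WC_MATCH, G:U and U:G
    are GU_WOBBLE, everything else is MISMATCH.
    """
    m, t = mirna_base.upper(), target_base.upper()
    if m not in RNA_ALPHABET or t not in RNA_ALPHABET:
        raise ValueError(f"bases must be in ACGU, got {mirna_base!r}:{target_base!r}")
    if WC_PARTNER[m] == t:
        return PairState.WC_MATCH
    if (m, t) in _GU_PAIRS:
        return PairState.GU_WOBBLE
    return PairState.MISMATCH


def _state_penalty(state: PairState, pos: int, params: ScanParams) -> float:
    if state is PairState.WC_MATCH:
        return 0.0
    if state is PairState.GU_WOBBLE:
        base = params.gu_weight
    elif state is PairState.MISMATCH:
        base = params.mismatch_weight
    else:
        base = params.gap_weight
    if params.core[0] <= pos <= params.core[1]:
        base *= params.core_multiplier
    return base


def weighted_score(duplex: DuplexAlignment, params: ScanParams = DEFAULT_SCAN_PARAMS) -> float:
    """Weighted complementarity penalty of a duplex; 0 for a perfect site."""
    return sum(
        _state_penalty(state, pos, params)
        for state, pos in zip(duplex.pair_states, duplex.mirna_positions())
    )


def _mirna_seq(mirna: MatureMiRNA | str) -> str:
    if isinstance(mirna, MatureMiRNA):
        return mirna.seq
    return normalize_rna(mirna, what="miRNA")


def align_window(
    mirna: MatureMiRNA | str,
    window_seq: str,
    params: ScanParams = DEFAULT_SCAN_PARAMS,
    bound: Optional[float] = None,
) -> Optional[DuplexAlignment]:
    """Minimum-penalty gapped antiparallel alignment of miRNA vs window.

    miRNA position 1 is placed opposite the window's 3'-most aligned
    base. Ties break deterministically: fewer gaps first, then the
    leftmost gap placement. When ``bound`` is given, returns ``None``
    if no alignment scores <= bound (used for pruning during scans).
    """
    m = _mirna_seq(mirna)
    w = normalize_rna(window_seq, what="window")
    L, M = len(m), len(w)
    if not L - params.max_indel <= M <= L + params.max_indel:
        raise ValueError(
            f"window length {M} outside [{L - params.max_indel}, {L + params.max_indel}] "
            f"for a {L} nt miRNA"
        )
    if L < params.core[1]:
        warnings.warn(
            f"miRNA length {L} is shorter than the core window end "
            f"{params.core[1]}; windows are truncated at L",
            stacklevel=2,
        )
    t = w[::-1]  # target read 3'->5': t[j] opposes miRNA position j+1 ungapped

    best: Optional[tuple] = None  # (penalty, n_gap_runs, gap_starts, states, pairs)
    limit = math.inf if bound is None else bound
    max_gaps, max_gap_len = params.max_gaps, params.max_gap_len

    states: list[PairState] = []
    pairs: list[tuple[Optional[str], Optional[str]]] = []

    def admissible(penalty: float) -> bool:
        if penalty > limit:
            return False
        if best is not None and penalty > best[0]:
            return False
        return True

    def record(penalty: float, gaps_used: int, gap_starts: tuple[int, ...]) -> None:
        nonlocal best
        key = (penalty, gaps_used, gap_starts)
        if best is None or key < best[:3]:
            best = (penalty, gaps_used, gap_starts, tuple(states), tuple(pairs))

    def dfs(
        i: int,
        j: int,
        penalty: float,
        gaps_used: int,
        last_was_gap: bool,
        gap_starts: tuple[int, ...],
    ) -> None:
        if not admissible(penalty):
            return
        # feasibility: remaining length difference must be bridgeable
        if abs((L - i) - (M - j)) > (max_gaps - gaps_used) * max_gap_len:
            return
        if i == L and j == M:
            record(penalty, gaps_used, gap_starts)
            return
        if i < L and j < M:
            st = pair_state(m[i], t[j])
            states.append(st)
            pairs.append((m[i], t[j]))
            dfs(i + 1, j + 1, penalty + _state_penalty(st, i + 1, params),
                gaps_used, False, gap_starts)
            states.pop()
            pairs.pop()
        if gaps_used < max_gaps and not last_was_gap:
            here = gap_starts + (len(states),)
            for run in range(1, max_gap_len + 1):
                if i + run <= L:  # bulge miRNA bases (GAP_TARGET states)
                    extra = sum(
                        _state_penalty(PairState.GAP_TARGET, i + k + 1, params)
                        for k in range(run)
                    )
                    for k in range(run):
                        states.append(PairState.GAP_TARGET)
                        pairs.append((m[i + k], None))
                    dfs(i + run, j, penalty + extra, gaps_used + 1, True, here)
                    del states[-run:]
                    del pairs[-run:]
                if j + run <= M:  # bulge target bases (GAP_MIRNA states)
                    pos = min(i + 1, L)
                    extra = run * _state_penalty(PairState.GAP_MIRNA, pos, params)
                    for k in range(run):
                        states.append(PairState.GAP_MIRNA)
                        pairs.append((None, t[j + k]))
                    dfs(i, j + run, penalty + extra, gaps_used + 1, True, here)
                    del states[-run:]
                    del pairs[-run:]

    dfs(0, 0, 0.0, 0, False, ())
    if best is None:
        return None
    return DuplexAlignment(mirna_length=L, pair_states=best[3], pairs=best[4])


def interval_overlap_fraction(s1: int, e1: int, s2: int, e2: int) -> float:
    """Shared fraction of two half-open intervals, relative to the shorter."""
    inter = max(0, min(e1, e2) - max(s1, s2))
    return inter / min(e1 - s1, e2 - s2)


def scan_transcript(
    mirna: MatureMiRNA,
    transcript: TranscriptRegion,
    params: ScanParams = DEFAULT_SCAN_PARAMS,
) -> list[TargetSite]:
    """Slide over every window of the transcript and emit passing sites.

    A window passes when its minimum alignment penalty is <= the
    inclusive ``max_penalty_score`` cutoff. Overlapping hits sharing
    >= 90% of their positions are suppressed, keeping the lowest score
    (ties: leftmost start, then shortest). Sites carry 0-based
    half-open transcript coordinates of the aligned interval.
    """
    seq = transcript.seq
    L = mirna.length
    lengths = range(max(1, L - params.max_indel), L + params.max_indel + 1)
    candidates: list[TargetSite] = []
    for start in range(0, len(seq)):
        for wlen in lengths:
            end = start + wlen
            if end > len(seq):
                continue
            duplex = align_window(
                mirna, seq[start:end], params, bound=params.max_penalty_score
            )
            if duplex is None:
                continue
            candidates.append(
                TargetSite(
                    mirna_id=mirna.id,
                    transcript_id=transcript.transcript_id,
                    start=start,
                    end=end,
                    duplex=duplex,
                    region=transcript.region,
                    score=weighted_score(duplex, params),
                )
            )
    kept: list[TargetSite] = []
    for cand in sorted(candidates, key=lambda s: (s.score, s.start, s.end)):
        if all(
            interval_overlap_fraction(cand.start, cand.end, k.start, k.end)
            < params.overlap_threshold
            for k in kept
        ):
            kept.append(cand)
    kept.sort(key=lambda s: (s.start, s.end))
    return kept
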