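"""Independent brute-force oracles used to pin expected values.

These deliberately share no code paths with the package internals:
the alignment oracle enumerates every monotone gapped alignment by
naive recursion over index pairs, and the folding oracle enumerates
every nested secondary structure explicitly.
"""

from __future__ import annotations

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GU = {("G", "U"), ("U", "G")}

PAIR_ENERGY = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}


def penalty_of(kind: str, mirna_pos: int, core=(2, 12), weights=(1.0, 0.5, 2.0), mult=2.0):
    mismatch_w, gu_w, gap_w = weights
    base = {"MM": mismatch_w, "GU": gu_w, "GAP": gap_w, "WC": 0.0}[kind]
    if core[0] <= mirna_pos <= core[1]:
        base *= mult
    return base


def brute_force_min_penalty(
    mirna: str,
    window: str,
    max_gaps: int = 1,
    max_gap_len: int = 1,
    core=(2, 12),
    weights=(1.0, 0.5, 2.0),
    mult=2.0,
) -> float:
    """Minimum penalty over all monotone alignments with run-limited gaps.

    Pure recursion over (miRNA index, target index); a gap is a
    maximal run of consecutive single-side steps, at most ``max_gaps``
    runs of length <= ``max_gap_len`` each.
    """
    t = window[::-1]  # 3'->5'; t[j] opposes miRNA position j+1 ungapped
    L, M = len(mirna), len(t)
    best = [float("inf")]

    def kind_of(m, b):
        if (m, b) in WC:
            return "WC"
        if (m, b) in GU:
            return "GU"
        return "MM"

    def rec(i, j, pen, runs, run_type, run_len):
        if pen >= best[0]:
            return
        if i == L and j == M:
            best[0] = pen
            return
        if i < L and j < M:
            k = kind_of(mirna[i], t[j])
            rec(i + 1, j + 1, pen + penalty_of(k, i + 1, core, weights, mult),
                runs, None, 0)
        # single-side steps; opening a new run costs one of max_gaps
        if i < L:  # unopposed miRNA base
            new_runs = runs if run_type == "T" else runs + 1
            new_len = run_len + 1 if run_type == "T" else 1
            if new_runs <= max_gaps and new_len <= max_gap_len:
                rec(i + 1, j, pen + penalty_of("GAP", i + 1, core, weights, mult),
                    new_runs, "T", new_len)
        if j < M:  # unopposed target base
            new_runs = runs if run_type == "M" else runs + 1
            new_len = run_len + 1 if run_type == "M" else 1
            if new_runs <= max_gaps and new_len <= max_gap_len:
                pos = min(i + 1, L)
                rec(i, j + 1, pen + penalty_of("GAP", pos, core, weights, mult),
                    new_runs, "M", new_len)

    rec(0, 0, 0.0, 0, None, 0)
    return best[0]


def pairable(a: str, b: str) -> bool:
    return frozenset((a, b)) in PAIR_ENERGY


def enumerate_structures(seq: str, min_loop: int = 3):
    """Yield every nested structure as a frozenset of (i, j) pairs."""
    n = len(seq)

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield frozenset()
            return
        first, rest = positions[0], positions[1:]
        # first unpaired
        for structure in rec(rest):
            yield structure
        # first paired with some j
        for idx, j in enumerate(rest):
            if j - first <= min_loop:
                continue
            if not pairable(seq[first], seq[j]):
                continue
            inside = tuple(p for p in rest[:idx] if first < p < j)
            outside = tuple(p for p in rest if p > j)
            for s_in in rec(inside):
                for s_out in rec(outside):
                    yield s_in | s_out | {(first, j)}

    yield from rec(tuple(range(n)))


def brute_force_fold_energy(seq: str, min_loop: int = 3, forbidden=frozenset()) -> float:
    """Minimum energy over explicitly enumerated nested structures."""
    forbidden = set(forbidden)
    best = 0.0
    for structure in enumerate_structures(seq, min_loop):
        if any(i in forbidden or j in forbidden for i, j in structure):
            continue
        energy = sum(PAIR_ENERGY[frozenset((seq[i], seq[j]))] for i, j in structure)
        if energy < best:
            best = energy
    return best
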