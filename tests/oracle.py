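"""Independent brute-force oracles used only by the test suite.

The stem oracle enumerates every admissible single-hairpin pairing by
explicit path recursion (no memoization, no shared code with the
scanner's search) and returns the maximum weighted stem score.
"""

from __future__ import annotations

from riddkit.endomotif_scanner import HEPTAMER_LEN, LoopMatch, ScannerConfig

_WC = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")}
_GU = {("G", "U"), ("U", "G")}


def _weight(a: str, b: str, allow_gu: bool) -> int:
    if (a, b) in _WC:
        return 3 if {a, b} == {"G", "C"} else 2
    if allow_gu and (a, b) in _GU:
        return 1
    return 0


def brute_force_best_stem_score(seq: str, match: LoopMatch, config: ScannerConfig) -> int:
    """Maximum stem score over all loop candidates and admissible pairings.

    A pairing is a sequence of steps outward from the loop closing
    position: pair (i, j), skip one base on the 5′ side, or skip one on
    the 3′ side, honoring the consecutive-bulge and total-unpaired
    budgets and the flanking window. Returns 0 when nothing can pair.
    """
    hept_start = match.start
    hept_end = match.start + HEPTAMER_LEN
    lo = max(0, hept_start - config.flank_window)
    hi = min(len(seq), hept_end + config.flank_window)
    allow_gu = config.allow_gu_wobble

    best = 0

    def explore(i: int, j: int, run_l: int, run_r: int, skips: int, score: int) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < lo and j >= hi:
            return
        if i >= lo and j < hi:
            w = _weight(seq[i], seq[j], allow_gu)
            if w:
                explore(i - 1, j + 1, 0, 0, skips, score + w)
        if skips < config.max_unpaired:
            if i >= lo and run_l < config.max_bulge_run:
                explore(i - 1, j, run_l + 1, run_r, skips + 1, score)
            if j < hi and run_r < config.max_bulge_run:
                explore(i, j + 1, run_l, run_r + 1, skips + 1, score)

    for loop_len in range(HEPTAMER_LEN, config.max_loop_len + 1):
        for ls in range(hept_end - loop_len, hept_start + 1):
            le = ls + loop_len
            if ls < 1 or le >= len(seq):
                continue
            explore(ls - 1, le, 0, 0, 0, 0)
    return best


def step_up_fdr(pvals):
    """Plain-python Benjamini–Hochberg step-up, for cross-checking."""
    m = len(pvals)
    order = sorted(range(m), key=lambda k: pvals[k])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        k = order[rank - 1]
        running = min(running, pvals[k] * m / rank)
        q[k] = running
    return q
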