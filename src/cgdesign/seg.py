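"""Two-pass low-complexity-region (LCR) detection (SEG-style).

Pass one slides a window (default 12 residues) along the sequence and flags
windows whose compositional Shannon entropy falls at or below a low cutoff
(default 2.2 bits). Overlapping flagged regions, extended through windows
at or below a high cutoff (default 2.5 bits), form candidate contigs. Pass
two refines each contig to the subsequence with the smallest probability of
its composition,

    P0 = (L! / prod_i n_i!) * (20! / prod_k r_k!) / 20^L,

where n_i are the residue-type counts of the subsequence and r_k is the
number of residue types occurring exactly k times (including k = 0).
Ties prefer the longer, then the left-most, subsequence. Positions outside
the 20-letter alphabet (e.g. 'X') split the sequence; reported coordinates
refer to the full input sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np

from .constants import AA_INDEX

DEFAULT_WINDOW = 12
DEFAULT_LOCUT = 2.2
DEFAULT_HICUT = 2.5

_LN20 = log(20.0)
_LGAMMA21 = lgamma(21.0)


@dataclass(frozen=True)
class Segment:
    start: int  # inclusive, 0-based, in full-sequence coordinates
    end: int    # inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def window_entropy(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a composition count vector."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def composition_logprob(counts: np.ndarray) -> float:
    """ln P0 of a composition: multinomial permutations times the number of
    distinct compositions with the same count multiset, over 20^L."""
    L = int(counts.sum())
    ln_m = lgamma(L + 1) - sum(lgamma(int(n) + 1) for n in counts)
    values, reps = np.unique(counts, return_counts=True)
    ln_f = _LGAMMA21 - sum(lgamma(int(r) + 1) for r in reps)
    del values
    return ln_m + ln_f - L * _LN20


def _refine(codes: np.ndarray, a: int, b: int) -> tuple[int, int]:
    """Pass two: the (i, j) within [a, b] minimizing ln P0; ties prefer the
    longer then left-most subsequence."""
    prefix = np.zeros((b - a + 2, 20), dtype=int)
    for pos in range(a, b + 1):
        prefix[pos - a + 1] = prefix[pos - a]
        prefix[pos - a + 1, codes[pos]] += 1
    best = (np.inf, 0, 0)  # (lnP0, -length, start)
    for i in range(a, b + 1):
        for j in range(i, b + 1):
            counts = prefix[j - a + 1] - prefix[i - a]
            key = (composition_logprob(counts), -(j - i + 1), i)
            if key < best:
                best = key
    return best[2], best[2] - best[1] - 1


def _find_in_run(codes: np.ndarray, offset: int, window: int,
                 locut: float, hicut: float) -> list[Segment]:
    n = len(codes)
    if n < window:
        return []
    n_windows = n - window + 1
    counts = np.zeros(20, dtype=int)
    for c in codes[:window]:
        counts[c] += 1
    entropies = np.empty(n_windows)
    entropies[0] = window_entropy(counts)
    for w in range(1, n_windows):
        counts[codes[w - 1]] -= 1
        counts[codes[w + window - 1]] += 1
        entropies[w] = window_entropy(counts)

    trigger = entropies <= locut
    if not trigger.any():
        return []
    extend = entropies <= hicut
    # contiguous runs of extendable windows that contain a trigger window
    spans: list[tuple[int, int]] = []
    w = 0
    while w < n_windows:
        if not extend[w]:
            w += 1
            continue
        start = w
        while w < n_windows and extend[w]:
            w += 1
        if trigger[start:w].any():
            spans.append((start, w - 1 + window - 1))  # residue coordinates
    if not spans:
        return []
    # merge candidate regions whose residue spans overlap
    merged = [spans[0]]
    for a, b in spans[1:]:
        if a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    segments = []
    for a, b in merged:
        i, j = _refine(codes, a, b)
        segments.append(Segment(start=offset + i, end=offset + j))
    return segments


def find_low_complexity(sequence: str, window: int = DEFAULT_WINDOW,
                        locut: float = DEFAULT_LOCUT,
                        hicut: float = DEFAULT_HICUT) -> list[Segment]:
    """Low-complexity segments of ``sequence`` (full-sequence coordinates)."""
    segments: list[Segment] = []
    run_start = None
    codes: list[int] = []
    for pos, letter in enumerate(sequence + "!"):  # sentinel flush
        code = AA_INDEX.get(letter)
        if code is None:
            if run_start is not None:
                segments.extend(_find_in_run(
                    np.array(codes, dtype=int), run_start,
                    window, locut, hicut))
            run_start, codes = None, []
        else:
            if run_start is None:
                run_start = pos
            codes.append(code)
    return segments


def lcr_fraction(sequence: str, window: int = DEFAULT_WINDOW,
                 locut: float = DEFAULT_LOCUT,
                 hicut: float = DEFAULT_HICUT) -> float:
    """Percentage of residues inside low-complexity segments."""
    if not sequence:
        return 0.0
    segments = find_low_complexity(sequence, window, locut, hicut)
    covered = np.zeros(len(sequence), dtype=bool)
    for seg in segments:
        covered[seg.start:seg.end + 1] = True
    return 100.0 * covered.sum() / len(sequence)
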