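"""Independent oracles used by the test suite.

These deliberately re-derive expected behaviour by brute force or from
first principles (cut chemistry, exact rational arithmetic, naive scans),
sharing no code path with the implementation they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def naive_find_motif(seq: str, motif: str = "CCCGGG") -> list[int]:
    """All-offsets 6-mer comparison (strict equality, so N never matches)."""
    seq = seq.upper()
    return [i for i in range(len(seq) - len(motif) + 1) if seq[i : i + len(motif)] == motif]


def digestion_reads(
    seq: str, site_states: dict[int, str], read_length: int
) -> list[tuple[int, str, str, int, str]]:
    """In-silico sequential SmaI/XmaI digestion with fill-in.

    ``site_states`` maps each CCCGGG site position (first C) to
    'methylated' or 'unmethylated'.  The sequence is fragmented by the cut
    chemistry: SmaI cuts unmethylated sites blunt between the third C and
    first G (both strands severed at p+3); XmaI cuts methylated sites
    between the first and second C on the top strand and symmetrically on
    the bottom strand, leaving 5'-CCGG overhangs that fill-in converts to
    blunt ends — so the downstream fragment starts at p+1 and the upstream
    fragment extends through p+4.  Each internal fragment end yields one
    read: a plus-strand read from the fragment's left end and a
    minus-strand read whose 5' end is the fragment's right end.

    Returns (start, strand, forward-orientation sequence, source site pos,
    state) per read; ends at the sequence boundaries produce no read.
    """
    seq = seq.upper()
    # per site: (right_start, left_end) = genomic boundaries the cut creates
    cuts = []
    for pos in sorted(site_states):
        state = site_states[pos]
        if state == "unmethylated":
            cuts.append((pos, state, pos + 3, pos + 3))
        elif state == "methylated":
            cuts.append((pos, state, pos + 1, pos + 5))
        else:
            raise ValueError(state)
    reads = []
    for pos, state, right_start, left_end in cuts:
        # plus-strand read from the start of the downstream fragment
        plus_seq = seq[right_start : right_start + read_length]
        reads.append((right_start, "+", plus_seq, pos, state))
        # minus-strand read from the end of the upstream fragment
        start = max(0, left_end - read_length)
        minus_fwd = seq[start:left_end]
        reads.append((start, "-", minus_fwd, pos, state))
    return reads


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full enumeration with exact rationals.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability is <= the observed table's (exact integer
    comparison of numerators at common denominator).
    """
    r1, r2, m = a + b, c + d, a + c
    lo, hi = max(0, m - r2), min(r1, m)
    nums = {x: comb(r1, x) * comb(r2, m - x) for x in range(lo, hi + 1)}
    denom = comb(r1 + r2, m)
    obs = nums[a]
    return Fraction(sum(v for v in nums.values() if v <= obs), denom)


def bh_step_up(p_values: list[float]) -> list[float]:
    """Hand Benjamini-Hochberg: q_(i) = min_{j >= i} p_(j) * m / j."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), by exact enumeration."""
    denom = comb(N, n)
    total = sum(comb(K, x) * comb(N - K, n - x)
                for x in range(k, min(K, n) + 1))
    return Fraction(total, denom)
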