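"""Differential methylation between two conditions at SmaI/XmaI sites.

Each site passing coverage in both conditions is tested with a two-sided
Fisher exact test on the 2x2 table of (methylated, unmethylated) signature
counts, pooled across replicates.  P-values are adjusted genome-wide by
Benjamini-Hochberg, and sites are classified hyper-/hypomethylated when the
methylation change (condition B minus condition A, knockdown minus control
in the motivating design) clears both an absolute effect-size floor and the
FDR threshold.  The genome-wide summary reports the percentage of tested
sites in each class — the statistic behind statements such as an N% gain in
hypermethylated CpG sites after knockdown.

``fisher_site`` is an exact implementation over integer hypergeometric
weights: the two-sided p-value sums, over the table support at fixed
margins, every table whose probability does not exceed the observed one,
with ties resolved by exact integer comparison rather than floating-point
tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, log10
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .meth_call import MethylationCall
from .signature_count import SampleCounts

LOG10P_CEILING = 320.0


@dataclass(frozen=True)
class DifferentialSite:
    site_id: str
    level_a: float
    level_b: float
    delta: float  # level_b - level_a
    p_value: float
    q_value: float
    klass: str  # hyper | hypo | unchanged


@dataclass(frozen=True)
class DiffSummary:
    n_tested: int
    pct_hyper: float
    pct_hypo: float
    pct_unchanged: float

    def to_dict(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "pct_hyper": self.pct_hyper,
            "pct_hypo": self.pct_hypo,
            "pct_unchanged": self.pct_unchanged,
        }


def fisher_site(
    counts_a: tuple[int, int], counts_b: tuple[int, int]
) -> float:
    """Two-sided Fisher exact p-value for one site's 2x2 signature table.

    Rows are conditions, columns (n_meth, n_unmeth).  Computed exactly:
    table probabilities at fixed margins are proportional to
    C(r1, a) * C(r2, m - a), integers compared without rounding, so
    equal-probability tables are always included in the tail.
    """
    a, b = counts_a
    c, d = counts_b
    if min(a, b, c, d) < 0:
        raise ValueError("negative count in contingency table")
    r1, r2 = a + b, c + d
    if r1 == 0 or r2 == 0:
        raise ValueError("a condition has zero coverage; site should be skipped")
    m = a + c  # methylated-column margin
    lo, hi = max(0, m - r2), min(r1, m)
    weights = [comb(r1, x) * comb(r2, m - x) for x in range(lo, hi + 1)]
    observed = weights[a - lo]
    tail = sum(wt for wt in weights if wt <= observed)
    return tail / comb(r1 + r2, m)


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def classify_sites(
    calls_a: Mapping[str, MethylationCall],
    calls_b: Mapping[str, MethylationCall],
    counts_a: SampleCounts,
    counts_b: SampleCounts,
    alpha: float = 0.05,
    min_delta: float = 0.10,
) -> tuple[list[DifferentialSite], DiffSummary]:
    """Test and classify every site called in both conditions.

    hyper:  delta >= +min_delta and q <= alpha
    hypo:   delta <= -min_delta and q <= alpha
    else unchanged.  Summary percentages use tested sites as denominator.
    """
    common = sorted(set(calls_a) & set(calls_b))
    if not common:
        raise ValueError("no sites pass coverage in both conditions")
    p_values = []
    for sid in common:
        ca, cb = counts_a.counts[sid], counts_b.counts[sid]
        p_values.append(fisher_site((ca.n_meth, ca.n_unmeth), (cb.n_meth, cb.n_unmeth)))
    q_values = bh_adjust(p_values)
    sites: list[DifferentialSite] = []
    n_hyper = n_hypo = 0
    for sid, p, q in zip(common, p_values, q_values):
        la, lb = calls_a[sid].level, calls_b[sid].level
        delta = lb - la
        if q <= alpha and delta >= min_delta:
            klass = "hyper"
            n_hyper += 1
        elif q <= alpha and delta <= -min_delta:
            klass = "hypo"
            n_hypo += 1
        else:
            klass = "unchanged"
        sites.append(DifferentialSite(sid, la, lb, delta, p, q, klass))
    n = len(sites)
    summary = DiffSummary(
        n_tested=n,
        pct_hyper=100.0 * n_hyper / n,
        pct_hypo=100.0 * n_hypo / n,
        pct_unchanged=100.0 * (n - n_hyper - n_hypo) / n,
    )
    return sites, summary


def volcano_table(sites: Sequence[DifferentialSite]) -> pd.DataFrame:
    """Export table for a volcano plot; -log10 p capped at 320 (presentation only)."""
    rows = []
    for s in sites:
        if s.p_value > 0:
            mlp = min(-log10(s.p_value), LOG10P_CEILING)
            capped = mlp >= LOG10P_CEILING
        else:  # floating-point underflow; Fisher p is mathematically > 0
            mlp, capped = LOG10P_CEILING, True
        rows.append(
            {
                "site_id": s.site_id,
                "delta": s.delta,
                "minus_log10_p": mlp,
                "p_capped": capped,
                "q": s.q_value,
                "klass": s.klass,
            }
        )
    return pd.DataFrame(rows, columns=["site_id", "delta", "minus_log10_p",
                                       "p_capped", "q", "klass"])
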