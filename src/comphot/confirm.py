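"""Exact-test confirmation of candidate comparative hotspots.

Each candidate is reduced to a 2x2 table of integration counts

    (n_in_A, n_out_A; n_in_B, n_out_B)

where ``n_in`` counts the vector's sites on the hotspot's strand inside
its genomic interval and ``n_out`` is that vector's genome-wide total
(all units, both strands) minus ``n_in`` — one genome-wide integration
propensity per vector, so the table margins are constant across
candidates.  The cross-product odds ratio is oriented to be >= 1 (the
vector on top is the winner; infinite when the loser has no inside
sites), the null OR = 1 is tested with the two-sided Fisher exact test,
and raw p-values from ALL candidates of one genome-wide run (both
strands, both winners) form a single Bonferroni-Holm family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, norm
from scipy.stats.contingency import odds_ratio as _exact_or
from statsmodels.stats.multitest import multipletests

from .detect import CandidateHotspot

logger = logging.getLogger("comphot.confirm")

DEFAULT_ALPHA = 0.05


@dataclass
class HotspotTest:
    """Confirmation record for one candidate hotspot."""

    hotspot: CandidateHotspot
    n_in_win: int
    n_out_win: int
    n_in_lose: int
    n_out_lose: int
    or_value: float  # oriented >= 1, may be inf
    ci95: tuple[float, float]
    p_raw: float
    p_adj: float = np.nan
    significant: bool = False

    @property
    def winner(self) -> str:
        return self.hotspot.winner


def count_sites(hotspot: CandidateHotspot, sites: pd.DataFrame,
                vector: str) -> tuple[int, int]:
    """Inside/outside counts for ``vector`` at a genomic hotspot.

    ``sites`` holds genomic records with columns chrom, pos, strand,
    vector.  ``n_in`` counts sites on the hotspot's chromosome and strand
    with ``start <= pos < end``; ``n_out`` is the vector's genome-wide
    total minus ``n_in``.
    """
    if hotspot.unit is None or hotspot.start is None or hotspot.end is None:
        raise ValueError("hotspot must carry a unit and genomic coordinates")
    v = sites[sites["vector"] == vector]
    total = len(v)
    inside = ((v["chrom"] == hotspot.unit.chrom)
              & (v["strand"] == hotspot.unit.strand)
              & (v["pos"] >= hotspot.start)
              & (v["pos"] < hotspot.end))
    n_in = int(inside.sum())
    return n_in, total - n_in


def _wald_ci(table: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    t = table.astype(float)
    if (t == 0).any():
        t = t + 0.5  # Haldane-Anscombe continuity correction
    lo = np.log(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))
    se = np.sqrt((1.0 / t).sum())
    z = norm.ppf(0.5 + level / 2.0)
    return float(np.exp(lo - z * se)), float(np.exp(lo + z * se))


def odds_ratio_test(n_in_a: int, n_out_a: int, n_in_b: int, n_out_b: int,
                    labels: tuple[str, str] = ("A", "B")):
    """Oriented odds ratio, winner, 95% CI and Fisher exact two-sided p.

    OR = (n_in_A/n_out_A)/(n_in_B/n_out_B), inverted (winner = B) when
    below 1.  CI: conditional exact when any cell <= 5, else logit-Wald
    with 0.5 continuity on zero cells; reporting-only (significance uses
    the p-value).
    """
    counts = (n_in_a, n_out_a, n_in_b, n_out_b)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    if n_in_a + n_out_a == 0 or n_in_b + n_out_b == 0:
        raise ValueError("both row totals must be positive")
    flip = n_in_a * n_out_b < n_in_b * n_out_a
    if flip:
        n_in_a, n_out_a, n_in_b, n_out_b = n_in_b, n_out_b, n_in_a, n_out_a
    winner = labels[1] if flip else labels[0]
    table = np.array([[n_in_a, n_out_a], [n_in_b, n_out_b]], dtype=np.int64)
    if n_in_b == 0:
        or_value = np.inf if n_in_a > 0 else 1.0
    else:
        or_value = (n_in_a / n_out_a) / (n_in_b / n_out_b) if n_out_a > 0 else np.inf
    p_raw = float(fisher_exact(table, alternative="two-sided")[1])
    if (table <= 5).any():
        ci = _exact_or(table, kind="conditional").confidence_interval(0.95)
        ci95 = (float(ci.low), float(ci.high))
    else:
        ci95 = _wald_ci(table)
    return float(or_value), winner, ci95, p_raw


def holm_adjust(p_values) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def confirm(candidates: list[CandidateHotspot], sites: pd.DataFrame,
            alpha: float = DEFAULT_ALPHA) -> list[HotspotTest]:
    """Test every candidate of one genome-wide run in a single Holm family.

    The winner label from band detection fixes the OR orientation; the
    returned list is sorted by adjusted then raw p-value (table order).
    """
    if not candidates:
        return []
    vectors = sorted(sites["vector"].unique())
    if len(vectors) != 2:
        raise ValueError(f"need exactly two vector labels, got {vectors}")
    tests: list[HotspotTest] = []
    for cand in candidates:
        loser = vectors[0] if cand.winner == vectors[1] else vectors[1]
        n_in_w, n_out_w = count_sites(cand, sites, cand.winner)
        n_in_l, n_out_l = count_sites(cand, sites, loser)
        or_value, _, ci95, p_raw = odds_ratio_test(
            n_in_w, n_out_w, n_in_l, n_out_l, labels=(cand.winner, loser))
        tests.append(HotspotTest(hotspot=cand, n_in_win=n_in_w,
                                 n_out_win=n_out_w, n_in_lose=n_in_l,
                                 n_out_lose=n_out_l, or_value=or_value,
                                 ci95=ci95, p_raw=p_raw))
    adj = holm_adjust([t.p_raw for t in tests])
    for t, pa in zip(tests, adj):
        t.p_adj = float(pa)
        t.significant = bool(pa <= alpha)
    tests.sort(key=lambda t: (t.p_adj, t.p_raw, t.hotspot.id))
    return tests


_FRAME_COLUMNS = ["id", "virus", "chr", "arm", "strand", "start", "end",
                  "length", "n_in_win", "n_out_win", "n_in_lose", "n_out_lose",
                  "OR", "ci_low", "ci_high", "p_raw", "p_adj", "significant"]


def tests_to_frame(tests: list[HotspotTest]) -> pd.DataFrame:
    """Result table: one row per candidate, ordered by adjusted p."""
    if not tests:
        return pd.DataFrame(columns=_FRAME_COLUMNS)
    rows = []
    for t in tests:
        h = t.hotspot
        rows.append({
            "id": h.id,
            "virus": h.winner,
            "chr": h.unit.chrom if h.unit else "",
            "arm": h.unit.arm if h.unit else "",
            "strand": h.unit.strand if h.unit else "",
            "start": h.start, "end": h.end,
            "length": h.genomic_length,
            "n_in_win": t.n_in_win, "n_out_win": t.n_out_win,
            "n_in_lose": t.n_in_lose, "n_out_lose": t.n_out_lose,
            "OR": t.or_value, "ci_low": t.ci95[0], "ci_high": t.ci95[1],
            "p_raw": t.p_raw, "p_adj": t.p_adj,
            "significant": t.significant,
        })
    return pd.DataFrame(rows)
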