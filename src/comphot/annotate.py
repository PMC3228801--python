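"""Annotation of confirmed hotspots against interval/position tracks.

Gene counting is strand-agnostic (a gene overlapping the hotspot by at
least 1 bp counts once, whatever its strand), unlike integration-site
counting which is strand-aware.  Expression enrichment compares
present/absent flags of genes inside one hotspot against genes outside
all confirmed hotspots (Fisher exact, Holm across hotspots).  Chromatin
track densities (reads per bp of hotspot) are compared between
HIV-preferred and MLV-preferred hotspot groups with a Welch or
Mann-Whitney statistic whose p-value is computed by label permutation,
Holm-adjusted across tracks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, rankdata

from .confirm import holm_adjust
from .detect import CandidateHotspot

logger = logging.getLogger("comphot.annotate")

DEFAULT_N_PERM = 100_000


@dataclass
class GroupComparison:
    """Two-group comparison of per-hotspot track densities."""

    track: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    statistic: str  # "welch" | "mannwhitney"
    observed: float
    p_perm: float
    p_adj: float = np.nan
    n_perm: int = 0


def _intervals(df: pd.DataFrame) -> pd.DataFrame:
    need = {"chrom", "start", "end"}
    if not need.issubset(df.columns):
        raise ValueError(f"track needs columns {sorted(need)}")
    return df


def overlapping_genes(hotspot: CandidateHotspot, genes: pd.DataFrame) -> pd.DataFrame:
    """Genes with >= 1 bp overlap with the hotspot, regardless of strand."""
    _intervals(genes)
    if hotspot.unit is None or hotspot.start is None:
        raise ValueError("hotspot must carry genomic coordinates")
    m = ((genes["chrom"] == hotspot.unit.chrom)
         & (genes["start"] < hotspot.end)
         & (genes["end"] > hotspot.start))
    return genes[m]


def overlap_stats(hotspots: list[CandidateHotspot],
                  genes: pd.DataFrame) -> pd.DataFrame:
    """Per-hotspot gene count and length-normalised gene density (genes/bp)."""
    rows = []
    for h in hotspots:
        count = len(overlapping_genes(h, genes))
        rows.append({"id": h.id, "winner": h.winner, "length": h.genomic_length,
                     "n_genes": count,
                     "gene_density": count / h.genomic_length})
    return pd.DataFrame(rows)


def expression_enrichment(hotspots: list[CandidateHotspot],
                          genes: pd.DataFrame) -> pd.DataFrame:
    """Per-hotspot enrichment of expressed genes vs the genomic background.

    ``genes`` needs a ``flag`` column in {"present", "absent"}.  The
    background for every hotspot is the set of genes outside ALL supplied
    hotspots.  Hotspots containing zero genes are reported with NA and
    excluded from the Holm family.
    """
    if "flag" not in genes.columns:
        raise ValueError("genes track needs a present/absent 'flag' column")
    bad = set(genes["flag"].unique()) - {"present", "absent"}
    if bad:
        raise ValueError(f"unknown expression flags: {sorted(bad)}")
    in_any = np.zeros(len(genes), dtype=bool)
    per_hotspot_mask = {}
    for h in hotspots:
        m = ((genes["chrom"] == h.unit.chrom)
             & (genes["start"] < h.end) & (genes["end"] > h.start)).to_numpy()
        per_hotspot_mask[h.id] = m
        in_any |= m
    bg = genes[~in_any]
    bg_present = int((bg["flag"] == "present").sum())
    bg_absent = int((bg["flag"] == "absent").sum())
    rows = []
    for h in hotspots:
        sub = genes[per_hotspot_mask[h.id]]
        n_p = int((sub["flag"] == "present").sum())
        n_a = int((sub["flag"] == "absent").sum())
        if n_p + n_a == 0:
            rows.append({"id": h.id, "winner": h.winner, "n_present": 0,
                         "n_absent": 0, "OR": np.nan, "p_raw": np.nan})
            continue
        table = np.array([[n_p, n_a], [bg_present, bg_absent]])
        orv, p = fisher_exact(table, alternative="two-sided")
        rows.append({"id": h.id, "winner": h.winner, "n_present": n_p,
                     "n_absent": n_a, "OR": float(orv), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    ok = out["p_raw"].notna()
    if ok.any():
        out.loc[ok, "p_adj"] = holm_adjust(out.loc[ok, "p_raw"].to_numpy())
    return out


def track_density(hotspot: CandidateHotspot, reads: pd.DataFrame) -> float:
    """Read positions inside the hotspot divided by its genomic length."""
    if "pos" in reads.columns:
        m = ((reads["chrom"] == hotspot.unit.chrom)
             & (reads["pos"] >= hotspot.start) & (reads["pos"] < hotspot.end))
    else:
        m = ((reads["chrom"] == hotspot.unit.chrom)
             & (reads["start"] >= hotspot.start) & (reads["start"] < hotspot.end))
    return float(m.sum()) / hotspot.genomic_length


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    va = a.var(ddof=1) / a.size
    vb = b.var(ddof=1) / b.size
    denom = np.sqrt(va + vb)
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / denom)


def _mw_u_centered(ranks_a_sum: float, n1: int, n2: int) -> float:
    # U statistic centred at its null mean so |.| orders two-sidedly
    u = ranks_a_sum - n1 * (n1 + 1) / 2.0
    return u - n1 * n2 / 2.0


def compare_group_densities(values_a, values_b, statistic: str = "welch",
                            n_perm: int = DEFAULT_N_PERM,
                            seed: int | None = None,
                            track: str = "") -> GroupComparison:
    """Permutation test for equal group means/locations of track densities.

    The observed Welch t (or centred Mann-Whitney U) is compared with its
    distribution under random relabelling; two-sided p is
    ``(1 + #{|T*| >= |T|}) / (n_perm + 1)``, or the exact proportion when
    all label partitions can be enumerated (``C(n, n1) <= n_perm``).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    if statistic not in ("welch", "mannwhitney"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if statistic == "welch" and (a.size < 2 or b.size < 2):
        logger.warning("group of size 1: falling back to mannwhitney")
        statistic = "mannwhitney"
    pool = np.concatenate([a, b])
    n, n1 = pool.size, a.size
    n2 = n - n1

    if statistic == "mannwhitney":
        ranks = rankdata(pool)
        def stat_from_idx(idx_a):
            return _mw_u_centered(float(ranks[list(idx_a)].sum()), n1, n2)
        observed = stat_from_idx(range(n1))
    else:
        def stat_from_idx(idx_a):
            idx_a = np.asarray(list(idx_a))
            mask = np.zeros(n, dtype=bool)
            mask[idx_a] = True
            return _welch_t(pool[mask], pool[~mask])
        observed = _welch_t(a, b)

    n_part = comb(n, n1)
    if n_part <= n_perm:
        count = sum(abs(stat_from_idx(c)) >= abs(observed) - 1e-12
                    for c in combinations(range(n), n1))
        p = count / n_part
        used = n_part
    else:
        rng = np.random.default_rng(seed)
        count = 0
        chunk = 2000
        done = 0
        if statistic == "mannwhitney":
            base = rankdata(pool)
        while done < n_perm:
            k = min(chunk, n_perm - done)
            if statistic == "mannwhitney":
                mat = np.tile(base, (k, 1))
                rng.permuted(mat, axis=1, out=mat)
                ga = mat[:, :n1]
                stats = (ga.sum(axis=1) - n1 * (n1 + 1) / 2.0) - n1 * n2 / 2.0
            else:
                mat = np.tile(pool, (k, 1))
                rng.permuted(mat, axis=1, out=mat)
                ga, gb = mat[:, :n1], mat[:, n1:]
                va = ga.var(axis=1, ddof=1) / n1
                vb = gb.var(axis=1, ddof=1) / n2
                denom = np.sqrt(va + vb)
                denom[denom == 0] = np.inf
                stats = (ga.mean(axis=1) - gb.mean(axis=1)) / denom
            count += int((np.abs(stats) >= abs(observed) - 1e-12).sum())
            done += k
        p = (1 + count) / (n_perm + 1)
        used = n_perm
    return GroupComparison(track=track, mean_a=float(a.mean()),
                           sd_a=float(a.std(ddof=1)) if a.size > 1 else np.nan,
                           mean_b=float(b.mean()),
                           sd_b=float(b.std(ddof=1)) if b.size > 1 else np.nan,
                           statistic=statistic, observed=float(observed),
                           p_perm=float(p), n_perm=used)


def compare_tracks(track_values: dict[str, tuple[np.ndarray, np.ndarray]],
                   statistic: str = "welch", n_perm: int = DEFAULT_N_PERM,
                   seed: int | None = None) -> pd.DataFrame:
    """Group comparison per track, Holm-adjusted across all tracks."""
    seeds = np.random.SeedSequence(seed).spawn(len(track_values))
    comps = []
    for (name, (va, vb)), ss in zip(track_values.items(), seeds):
        comps.append(compare_group_densities(
            va, vb, statistic=statistic, n_perm=n_perm,
            seed=int(ss.generate_state(1)[0] % (2 ** 31)), track=name))
    adj = holm_adjust([c.p_perm for c in comps])
    for c, pa in zip(comps, adj):
        c.p_adj = float(pa)
    return pd.DataFrame([{
        "track": c.track, "mean_A": c.mean_a, "sd_A": c.sd_a,
        "mean_B": c.mean_b, "sd_B": c.sd_b, "statistic": c.statistic,
        "p": c.p_perm, "p_adj": c.p_adj} for c in comps])


def length_stats(hotspots: list[CandidateHotspot],
                 n_perm: int = DEFAULT_N_PERM,
                 seed: int | None = None) -> dict:
    """Per-winner hotspot length summaries and a permutation Mann-Whitney p.

    Medians follow the usual convention (mean of the middle pair for an
    even-sized group).  With a single winner group present, medians are
    reported and the p-value is NA.
    """
    lengths: dict[str, np.ndarray] = {}
    for h in hotspots:
        lengths.setdefault(h.winner, [])
        lengths[h.winner].append(h.genomic_length)
    summary = {}
    for winner, vals in lengths.items():
        v = np.asarray(vals, dtype=float)
        summary[winner] = {"n": int(v.size), "median": float(np.median(v)),
                           "min": float(v.min()), "max": float(v.max())}
    out = {"per_winner": summary, "p_perm": np.nan}
    if len(lengths) == 2:
        (la, lb) = (np.asarray(v, float) for v in lengths.values())
        cmp = compare_group_densities(la, lb, statistic="mannwhitney",
                                      n_perm=n_perm, seed=seed, track="length")
        out["p_perm"] = cmp.p_perm
    return out
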