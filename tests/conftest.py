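"""Shared fixtures: small coordinate maps, planted-signal scenarios, oracles."""

from __future__ import annotations

import numpy as np
import pytest

from comphot.blindmap import AnalysisUnit, BlindMap
from comphot.simulate import Bump, ScenarioSpec, simulate_sites


def identity_map(length: int, chrom: str = "chrS", strand: str = "+") -> BlindMap:
    unit = AnalysisUnit(chrom, "p", strand, 0, length)
    return BlindMap(unit=unit, blind=np.empty((0, 2), dtype=np.int64))


def draw_pair(length: int, n: int, bumps=(), seed: int = 0,
              labels=("A", "B")):
    """Two i.i.d. site samples on a blind-free unit: uniform background
    plus the given planted bumps; returns (sets, genomic_df, truth_df)."""
    bmap = identity_map(length)
    spec = ScenarioSpec(unit_length=length, n_sites={labels[0]: n, labels[1]: n},
                        bumps=tuple(bumps), strands=("+",), chrom=bmap.unit.chrom,
                        seed=seed)
    sets, genomic, truth = simulate_sites(spec, bmap, seed=seed,
                                          grid_points=2 ** 14)
    return sets, genomic, truth, bmap


def per_base_blind_oracle(sites: np.ndarray, unit: AnalysisUnit,
                          min_read: int, max_frag: int) -> np.ndarray:
    """Brute-force per-base detectability: a base is detectable iff it lies
    in a gap between consecutive restriction sites and its distance to the
    gap's reference site (5' site on +, 3' site on -) is in the admissible
    window ([min_read, max_frag) on +, its mirror image (min_read, max_frag]
    on -, the half-open boundary mirroring with the rule)."""
    blind = np.ones(unit.length, dtype=bool)
    s = np.sort(np.asarray(sites))
    for p, q in zip(s[:-1], s[1:]):
        for x in range(int(p), int(q)):
            if unit.strand == "+":
                ok = min_read <= x - p < max_frag
            else:
                ok = min_read < q - x <= max_frag
            if ok:
                blind[x - unit.start] = False
    return blind


def intervals_to_mask(intervals: np.ndarray, unit: AnalysisUnit) -> np.ndarray:
    mask = np.zeros(unit.length, dtype=bool)
    for a, b in np.asarray(intervals).reshape(-1, 2):
        mask[a - unit.start:b - unit.start] = True
    return mask


def hypergeom_fisher_oracle(table: np.ndarray) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration of all tables
    with the observed margins (sum of probabilities <= observed's)."""
    from scipy.stats import hypergeom

    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def holm_stepdown_oracle(p: np.ndarray) -> np.ndarray:
    """Hand execution of Holm's step-down procedure."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, (m - k) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


@pytest.fixture(scope="session")
def planted_pair():
    """One strong planted bump for vector A: OR 8 over 2% of a 10 Mb unit,
    n = 2,000 sites per vector."""
    L = 10_000_000
    bump = Bump(center=3_000_000, width=200_000, vector="A", odds_ratio=8.0)
    sets, genomic, truth, bmap = draw_pair(L, 2000, bumps=[bump], seed=42)
    return {"sets": sets, "genomic": genomic, "truth": truth, "bmap": bmap,
            "bump": bump, "L": L}


@pytest.fixture(scope="session")
def genome_run():
    """Small genome-wide run with three planted bumps (two for HIV, one for
    MLV) on one (arm, strand) unit, detection and confirmation executed."""
    from comphot.confirm import confirm
    from comphot.pipeline import detect_genome

    L = 10_000_000
    bumps = (Bump(2_000_000, 200_000, "HIV", 8.0),
             Bump(5_000_000, 200_000, "MLV", 8.0),
             Bump(8_000_000, 200_000, "HIV", 8.0))
    bmap = identity_map(L)
    spec = ScenarioSpec(unit_length=L, n_sites={"HIV": 1500, "MLV": 1500},
                        bumps=bumps, strands=("+",), chrom="chrS", seed=11)
    sets, genomic, truth = simulate_sites(spec, bmap, seed=11,
                                          grid_points=2 ** 14)
    site_sets = {bmap.unit.id: sets}
    candidates = detect_genome(site_sets, {bmap.unit.id: bmap},
                               grid_size=4096, ucv_grid=48)
    tests = confirm(candidates, genomic)
    return {"bmap": bmap, "sets": sets, "genomic": genomic, "truth": truth,
            "candidates": candidates, "tests": tests}
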