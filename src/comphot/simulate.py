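"""Seeded synthetic data with the statistical structure the method assumes.

The generator emulates the study design: a chromosome-arm-sized sequence
with restriction motifs at geometric spacings (hence restriction-digest
blind regions), and two vectors' integration sites drawn i.i.d. from a
mixture of a uniform background over detectable positions plus localised
Gaussian-shaped intensity bumps assigned to one vector, each bump sized
by the odds ratio it should induce between the two vectors inside its
half-maximum window.  Truth intervals are emitted so detection can be
scored against known signal.

Defaults mirror the real study's regime: a 1e8 bp unit, ~30% blind, and
~1,500 sites per vector per (arm, strand) unit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .blindmap import (DEFAULT_MAX_FRAG, DEFAULT_MIN_READ, DEFAULT_MOTIF,
                       AnalysisUnit, BlindMap, blind_map_from_sequence)
from .density import IntegrationSiteSet

logger = logging.getLogger("comphot.simulate")

_FILLER = np.frombuffer(b"ACG", dtype=np.uint8)
_MOTIF_BYTES = np.frombuffer(b"TTAA", dtype=np.uint8)


@dataclass(frozen=True)
class Bump:
    """Localised integration-intensity excess for one vector.

    ``width`` is the full width at half maximum of the Gaussian-shaped
    multiplier; the truth interval is ``[center - width/2, center + width/2)``.
    ``odds_ratio`` is the in-window vs out-of-window integration odds of
    the bumped vector relative to a uniform one.
    """

    center: int
    width: int
    vector: str
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("bump width must be positive")
        if self.odds_ratio <= 1:
            raise ValueError("bump odds ratio must exceed 1")

    @property
    def sigma(self) -> float:
        return self.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))

    @property
    def truth(self) -> tuple[int, int]:
        return (self.center - self.width // 2, self.center + self.width // 2)


@dataclass(frozen=True)
class ScenarioSpec:
    """Full description of one synthetic study."""

    unit_length: int = 100_000_000
    mean_motif_gap: float = 350.0       # bp; ~30% blind under the 20/500 rule
    n_sites: dict = field(default_factory=lambda: {"HIV": 1500, "MLV": 1500})
    bumps: tuple = ()
    strands: tuple = ("+", "-")
    chrom: str = "chr1"
    arm: str = "p"
    min_read: int = DEFAULT_MIN_READ
    max_frag: int = DEFAULT_MAX_FRAG
    motif: str = DEFAULT_MOTIF
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.bumps:
            if not (0 <= b.center < self.unit_length):
                raise ValueError("bump outside the unit")


def default_scenario(seed: int = 0) -> ScenarioSpec:
    """The packaged default: three planted bumps (two HIV, one MLV), OR 8,
    each 2% of the unit wide."""
    L = 100_000_000
    w = int(0.02 * L)
    bumps = (Bump(int(0.20 * L), w, "HIV", 8.0),
             Bump(int(0.50 * L), w, "MLV", 8.0),
             Bump(int(0.80 * L), w, "HIV", 8.0))
    return ScenarioSpec(unit_length=L, bumps=bumps, seed=seed)


def simulate_motif_genome(length: int, mean_gap: float = 350.0,
                          seed: int | None = None) -> bytes:
    """Random ACG filler with TTAA motifs at geometric gaps.

    The filler alphabet contains no T, so the only TTAA occurrences are
    the planted ones; consecutive motif starts differ by
    ``4 + Geometric(1/(mean_gap - 4))`` with mean ``mean_gap``.
    """
    if mean_gap < 24:
        raise ValueError("mean_gap must be >= 24")
    rng = np.random.default_rng(seed)
    seq = _FILLER[rng.integers(0, 3, size=length)]
    n_est = int(length / mean_gap * 1.3) + 16
    gaps = 4 + rng.geometric(1.0 / (mean_gap - 4.0), size=n_est)
    starts = np.cumsum(gaps)
    while starts[-1] < length:
        extra = 4 + rng.geometric(1.0 / (mean_gap - 4.0), size=n_est)
        starts = np.concatenate([starts, starts[-1] + np.cumsum(extra)])
    starts = starts[starts <= length - 4]
    for j in range(4):
        seq[starts + j] = _MOTIF_BYTES[j]
    return seq.tobytes()


def _amplitude_for_or(bump: Bump, grid_g: np.ndarray, target: float) -> float:
    """Solve the bump amplitude so the in-truth-window odds ratio vs a
    uniform vector equals ``target``; grid_g are the genomic positions of
    equally spaced collapsed grid points (uniform measure on detectables)."""
    lo, hi = bump.truth
    g = np.exp(-0.5 * ((grid_g - bump.center) / bump.sigma) ** 2)
    win = (grid_g >= lo) & (grid_g < hi)
    m = grid_g.size
    q0 = win.sum() / m
    if q0 == 0 or q0 == 1:
        raise ValueError("bump truth window not resolvable on the unit")
    odds_target = target * q0 / (1 - q0)

    def gap(a):
        mass_in = win.sum() + a * g[win].sum()
        mass_tot = m + a * g.sum()
        q1 = mass_in / mass_tot
        return q1 / (1 - q1) - odds_target

    return float(brentq(gap, 0.0, 1e6))


def simulate_sites(spec: ScenarioSpec, bmap: BlindMap,
                   seed: int | None = None,
                   grid_points: int = 2 ** 16):
    """Draw both vectors' site samples restricted to detectable positions.

    Sampling inverts the mixture CDF on a fine grid of collapsed
    coordinates (uniform over detectable bases by construction), then
    expands to genomic positions — every site is detectable.  Returns
    ``(site_sets, genomic_df, truth_df)`` where ``site_sets`` maps vector
    label to an :class:`IntegrationSiteSet` on the collapsed axis.
    """
    if bmap.is_degenerate:
        raise ValueError("fully blind unit: no detectable positions")
    Lc = bmap.collapsed_length
    for label, n in spec.n_sites.items():
        if n > 10 * Lc:
            raise ValueError(f"requested n for {label} exceeds 10x detectable length")
    rng = np.random.default_rng(seed if seed is not None else spec.seed)
    cgrid = (np.arange(grid_points, dtype=float) + 0.5) * (Lc / grid_points)
    ggrid = bmap.expand(np.minimum(cgrid.astype(np.int64), Lc - 1)).astype(float)
    site_sets: dict[str, IntegrationSiteSet] = {}
    genomic_rows = []
    truth_rows = []
    for vector, n in spec.n_sites.items():
        intensity = np.ones(grid_points)
        for b in spec.bumps:
            if b.vector != vector:
                continue
            amp = _amplitude_for_or(b, ggrid, b.odds_ratio)
            intensity += amp * np.exp(-0.5 * ((ggrid - b.center) / b.sigma) ** 2)
        cdf = np.cumsum(intensity)
        cdf /= cdf[-1]
        u = rng.random(n)
        idx = np.searchsorted(cdf, u)
        # uniform jitter within the chosen grid cell, still detectable
        frac = rng.random(n)
        cpos = (idx + frac) * (Lc / grid_points)
        cpos = np.clip(cpos, 0, Lc - 1e-9)
        gpos = bmap.expand(cpos.astype(np.int64))
        order = np.argsort(cpos)
        site_sets[vector] = IntegrationSiteSet(
            positions=cpos[order], domain_length=float(Lc),
            vector=vector, unit=bmap.unit)
        genomic_rows.append(pd.DataFrame({
            "chrom": bmap.unit.chrom, "pos": np.sort(gpos),
            "strand": bmap.unit.strand, "vector": vector}))
    for b in spec.bumps:
        lo, hi = b.truth
        truth_rows.append({"chrom": bmap.unit.chrom, "start": lo, "end": hi,
                           "vector": b.vector, "odds_ratio": b.odds_ratio,
                           "strand": bmap.unit.strand})
    genomic = pd.concat(genomic_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows,
                         columns=["chrom", "start", "end", "vector",
                                  "odds_ratio", "strand"])
    return site_sets, genomic, truth


def simulate_annotation_tracks(spec: ScenarioSpec, seed: int | None = None,
                               n_genes: int = 2000, gene_width: int = 50_000,
                               p_present: float = 0.75,
                               read_tracks: tuple = ("H3K4me3", "H2AZ"),
                               reads_per_track: int = 20_000):
    """Uniform gene intervals with expression flags and uniform read tracks."""
    rng = np.random.default_rng(seed if seed is not None else spec.seed + 1)
    starts = np.sort(rng.integers(0, spec.unit_length - gene_width, size=n_genes))
    genes = pd.DataFrame({
        "chrom": spec.chrom, "start": starts, "end": starts + gene_width,
        "name": [f"gene_{i}" for i in range(n_genes)],
        "flag": np.where(rng.random(n_genes) < p_present, "present", "absent"),
    })
    reads = {}
    for t in read_tracks:
        pos = np.sort(rng.integers(0, spec.unit_length, size=reads_per_track))
        reads[t] = pd.DataFrame({"chrom": spec.chrom, "pos": pos})
    return genes, reads


def _write_fasta(path: Path, chrom: str, seq: bytes, width: int = 80) -> None:
    with open(path, "wb") as fh:
        fh.write(f">{chrom}\n".encode())
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + b"\n")


def make_scenario(spec: ScenarioSpec, outdir) -> dict:
    """Materialise a scenario as a self-consistent fixture directory.

    Writes genome.fa, arms.bed, sites.bed (BED6, name = vector), gene /
    expression-flag / read tracks and truth.tsv, all consumable by the
    package's readers and the CLI end-to-end.  Deterministic given the
    spec (including its seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(spec.seed)
    genome_seed, tracks_seed, *strand_seeds = [
        int(s.generate_state(1)[0] % (2 ** 31))
        for s in root.spawn(2 + len(spec.strands))]
    seq = simulate_motif_genome(spec.unit_length, spec.mean_motif_gap,
                                seed=genome_seed)
    _write_fasta(outdir / "genome.fa", spec.chrom, seq)
    pd.DataFrame([{"chrom": spec.chrom, "start": 0, "end": spec.unit_length,
                   "name": spec.arm}]).to_csv(
        outdir / "arms.bed", sep="\t", header=False, index=False)
    all_sites, all_truth = [], []
    for strand, sseed in zip(spec.strands, strand_seeds):
        unit = AnalysisUnit(spec.chrom, spec.arm, strand, 0, spec.unit_length)
        bmap = blind_map_from_sequence(seq, unit, motif=spec.motif,
                                       min_read=spec.min_read,
                                       max_frag=spec.max_frag)
        _, genomic, truth = simulate_sites(spec, bmap, seed=sseed)
        all_sites.append(genomic)
        all_truth.append(truth)
    sites = pd.concat(all_sites, ignore_index=True)
    bed = pd.DataFrame({"chrom": sites["chrom"], "start": sites["pos"],
                        "end": sites["pos"] + 1, "name": sites["vector"],
                        "score": 0, "strand": sites["strand"]})
    bed.to_csv(outdir / "sites.bed", sep="\t", header=False, index=False)
    truth = pd.concat(all_truth, ignore_index=True)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    genes, reads = simulate_annotation_tracks(spec, seed=tracks_seed)
    genes[["chrom", "start", "end", "name"]].assign(score=0, strand="+").to_csv(
        outdir / "genes.bed", sep="\t", header=False, index=False)
    genes[["name", "flag"]].to_csv(outdir / "expression.tsv", sep="\t",
                                   index=False, header=["gene", "flag"])
    for name, df in reads.items():
        pd.DataFrame({"chrom": df["chrom"], "start": df["pos"],
                      "end": df["pos"] + 1, "name": name, "score": 0,
                      "strand": "+"}).to_csv(
            outdir / f"reads_{name}.bed", sep="\t", header=False, index=False)
    meta = {"spec": {**asdict(spec), "bumps": [asdict(b) for b in spec.bumps]},
            "files": ["genome.fa", "arms.bed", "sites.bed", "truth.tsv",
                      "genes.bed", "expression.tsv"]
            + [f"reads_{n}.bed" for n in reads]}
    meta["spec_hash"] = hashlib.sha256(
        json.dumps(meta["spec"], sort_keys=True).encode()).hexdigest()[:12]
    (outdir / "scenario.json").write_text(json.dumps(meta, indent=2) + "\n")
    return meta
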