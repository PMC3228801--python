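"""Whole-genome orchestration: blindmap -> density -> detect -> confirm -> annotate.

`detect_genome` runs band detection on every analysis unit with enough
data and assigns stable candidate ids (winner label lowercased + discovery
order over the genome scan, e.g. ``hiv_3``).  `run_pipeline` is the file
-level driver behind the CLI: it reads the standard inputs, executes the
stages in order and writes the output tables with metadata headers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blindmap import (DEFAULT_MAX_FRAG, DEFAULT_MIN_READ, DEFAULT_MOTIF,
                       AnalysisUnit, BlindMap, blind_map_from_sequence)
from .confirm import DEFAULT_ALPHA, confirm, tests_to_frame
from .density import (DEFAULT_GRID_SIZE, DEFAULT_LEVEL, MIN_SITES,
                      IntegrationSiteSet)
from .detect import (CandidateHotspot, bands_for_unit, find_candidates,
                     sensitivity_scan, to_genomic)
from . import annotate as _annotate
from . import io as _io

logger = logging.getLogger("comphot.pipeline")


class ConfigError(ValueError):
    """Inconsistent or unreadable pipeline configuration."""


@dataclass
class RunConfig:
    """Everything one pipeline run depends on (hashable for provenance)."""

    fasta: str = ""
    arms: str = ""
    sites: str = ""
    genes: str = ""
    expression: str = ""
    reads: dict = field(default_factory=dict)  # track name -> BED path
    motif: str = DEFAULT_MOTIF
    include_reverse_complement: bool = False
    min_read: int = DEFAULT_MIN_READ
    max_frag: int = DEFAULT_MAX_FRAG
    level: float = DEFAULT_LEVEL
    grid_size: int = DEFAULT_GRID_SIZE
    ucv_grid: int = 200
    s_grid: tuple = ()
    alpha: float = DEFAULT_ALPHA
    n_perm: int = 100_000
    min_sites: int = MIN_SITES
    seed: int = 0
    outdir: str = "comphot_out"

    def __post_init__(self) -> None:
        if not 0 < self.level < 1:
            raise ConfigError("level must be in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_read >= self.max_frag:
            raise ConfigError("min_read must be < max_frag")

    _PATH_FIELDS = ("fasta", "arms", "sites", "genes", "expression", "reads",
                    "outdir")

    def hash(self) -> str:
        # analysis parameters only: identical settings give an identical
        # hash wherever the inputs live, so re-runs are byte-comparable
        d = {k: v for k, v in dataclasses.asdict(self).items()
             if k not in self._PATH_FIELDS}
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def meta(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed,
                "level": self.level, "alpha": self.alpha}


def build_blind_maps(fasta, units: list[AnalysisUnit], motif: str = DEFAULT_MOTIF,
                     min_read: int = DEFAULT_MIN_READ,
                     max_frag: int = DEFAULT_MAX_FRAG,
                     include_reverse_complement: bool = False) -> dict[str, BlindMap]:
    """One blind map per analysis unit from an indexed FASTA."""
    maps: dict[str, BlindMap] = {}
    for unit in units:
        seq = fasta[unit.chrom][unit.start:unit.end].seq
        maps[unit.id] = blind_map_from_sequence(
            seq, unit, motif=motif, min_read=min_read, max_frag=max_frag,
            include_reverse_complement=include_reverse_complement)
        logger.info("unit %s: blind fraction %.3f", unit.id,
                    maps[unit.id].blind_fraction())
    return maps


def collapse_sites(sites: pd.DataFrame, bmaps: dict[str, BlindMap],
                   units: list[AnalysisUnit]) -> dict[str, dict[str, IntegrationSiteSet]]:
    """Assign genomic sites to units and collapse their coordinates.

    Sites at blind positions (possible with real mapping artefacts) are
    dropped with a warning.  Returns unit id -> vector -> site set.
    """
    out: dict[str, dict[str, IntegrationSiteSet]] = {}
    vectors = sorted(sites["vector"].unique())
    for unit in units:
        bmap = bmaps[unit.id]
        if bmap.is_degenerate:
            logger.warning("unit %s fully blind; skipped", unit.id)
            continue
        sub = sites[(sites["chrom"] == unit.chrom)
                    & (sites["strand"] == unit.strand)
                    & (sites["pos"] >= unit.start)
                    & (sites["pos"] < unit.end)]
        per_vec = {}
        for vec in vectors:
            pos = sub.loc[sub["vector"] == vec, "pos"].to_numpy(np.int64)
            blind = bmap.is_blind(pos)
            if blind.any():
                logger.warning("unit %s: dropped %d blind-position sites (%s)",
                               unit.id, int(blind.sum()), vec)
                pos = pos[~blind]
            per_vec[vec] = IntegrationSiteSet(
                positions=bmap.collapse(pos).astype(float),
                domain_length=float(bmap.collapsed_length),
                vector=vec, unit=unit)
        out[unit.id] = per_vec
    return out


def assign_ids(candidates: list[CandidateHotspot]) -> list[CandidateHotspot]:
    """Stable ids: winner label lowercased + discovery order per genome scan."""
    counters: dict[str, int] = {}
    out = []
    for c in candidates:
        key = c.winner.lower()
        counters[key] = counters.get(key, 0) + 1
        out.append(dataclasses.replace(c, id=f"{key}_{counters[key]}"))
    return out


def detect_genome(site_sets: dict[str, dict[str, IntegrationSiteSet]],
                  bmaps: dict[str, BlindMap], level: float = DEFAULT_LEVEL,
                  grid_size: int = DEFAULT_GRID_SIZE, ucv_grid: int = 200,
                  min_sites: int = MIN_SITES) -> list[CandidateHotspot]:
    """Band detection on every unit with enough data, ids assigned."""
    all_cands: list[CandidateHotspot] = []
    for uid in sorted(site_sets):
        per_vec = site_sets[uid]
        vecs = sorted(per_vec)
        if len(vecs) != 2:
            raise ConfigError(f"unit {uid}: need exactly two vectors, got {vecs}")
        sa, sb = per_vec[vecs[0]], per_vec[vecs[1]]
        if sa.n < min_sites or sb.n < min_sites:
            logger.warning("unit %s skipped: n=%d/%d below %d sites",
                           uid, sa.n, sb.n, min_sites)
            continue
        band_a, band_b, h_opt = bands_for_unit(sa, sb, level=level,
                                               grid_size=grid_size,
                                               ucv_grid=ucv_grid)
        cands = find_candidates(band_a, band_b, labels=(vecs[0], vecs[1]),
                                unit=sa.unit)
        cands = to_genomic(cands, bmaps[uid])
        logger.info("unit %s: n=%d/%d h_opt=%.4g/%.4g candidates=%d",
                    uid, sa.n, sb.n, h_opt[vecs[0]], h_opt[vecs[1]], len(cands))
        all_cands.extend(cands)
    return assign_ids(all_cands)


def candidates_to_frame(candidates: list[CandidateHotspot]) -> pd.DataFrame:
    return pd.DataFrame([{
        "id": c.id, "chrom": c.unit.chrom if c.unit else "",
        "arm": c.unit.arm if c.unit else "",
        "strand": c.unit.strand if c.unit else "",
        "start": c.start, "end": c.end, "winner": c.winner}
        for c in candidates],
        columns=["id", "chrom", "arm", "strand", "start", "end", "winner"])


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages from files and write the result directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = config.meta()
    fasta = _io.read_fasta(config.fasta)
    arms = _io.read_arms_bed(config.arms)
    sites = _io.read_sites_bed(config.sites)
    fasta_chroms = set(fasta.keys())
    missing = sorted({a["chrom"] for a in arms} - fasta_chroms)
    missing += sorted(set(sites["chrom"].unique()) - {a["chrom"] for a in arms})
    if missing:
        raise ConfigError(f"chromosome names not consistent across inputs: {missing}")
    units = _io.units_from_arms(arms)
    bmaps = build_blind_maps(fasta, units, motif=config.motif,
                             min_read=config.min_read, max_frag=config.max_frag,
                             include_reverse_complement=config.include_reverse_complement)
    _io.write_blind_bed(outdir / "blind.bed", bmaps)
    _io.write_table(outdir / "blind_fractions.tsv", pd.DataFrame(
        [{"unit": uid, "blind_fraction": m.blind_fraction(),
          "collapsed_length": m.collapsed_length} for uid, m in bmaps.items()]),
        meta)
    summary: dict = {"version": __version__, **meta, "units": len(units)}
    if sites.empty:
        logger.warning("empty sites file: writing empty outputs")
        _io.write_table(outdir / "candidates.tsv", candidates_to_frame([]), meta)
        _io.write_table(outdir / "hotspots.tsv", tests_to_frame([]), meta)
        summary.update(candidates=0, confirmed=0)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        return outdir
    site_sets = collapse_sites(sites, bmaps, units)
    candidates = detect_genome(site_sets, bmaps, level=config.level,
                               grid_size=config.grid_size,
                               ucv_grid=config.ucv_grid,
                               min_sites=config.min_sites)
    _io.write_table(outdir / "candidates.tsv", candidates_to_frame(candidates),
                    meta)
    tests = confirm(candidates, sites, alpha=config.alpha)
    _io.write_table(outdir / "hotspots.tsv", tests_to_frame(tests), meta)
    confirmed = [t.hotspot for t in tests if t.significant]
    summary.update(candidates=len(candidates), confirmed=len(confirmed))
    if config.s_grid:
        rows = []
        for uid in sorted(site_sets):
            per_vec = site_sets[uid]
            vecs = sorted(per_vec)
            sa, sb = per_vec[vecs[0]], per_vec[vecs[1]]
            if sa.n < config.min_sites or sb.n < config.min_sites:
                continue
            scan = sensitivity_scan(sa, sb, s_grid=config.s_grid,
                                    level=config.level,
                                    grid_size=config.grid_size,
                                    bmap=bmaps[uid], ucv_grid=config.ucv_grid)
            rows.append(scan.to_frame())
        robustness = (pd.concat(rows, ignore_index=True) if rows
                      else pd.DataFrame(columns=["s", "unit", "start", "end",
                                                 "winner"]))
        _io.write_table(outdir / "robustness.tsv", robustness, meta)
    if confirmed and config.genes:
        genes = _io.read_genes_bed(config.genes)
        _io.write_table(outdir / "gene_density.tsv",
                        _annotate.overlap_stats(confirmed, genes), meta)
        if config.expression:
            flags = _io.read_expression_flags(config.expression)
            genes_f = genes.merge(flags, left_on="name", right_on="gene",
                                  how="inner")
            _io.write_table(outdir / "expression_enrichment.tsv",
                            _annotate.expression_enrichment(confirmed, genes_f),
                            meta)
        ls = _annotate.length_stats(confirmed, n_perm=config.n_perm,
                                    seed=config.seed)
        summary["length_stats"] = ls
    if confirmed and config.reads:
        winners = sorted({c.winner for c in confirmed})
        if len(winners) == 2:
            track_values = {}
            for name, path in config.reads.items():
                reads = _io.read_reads_bed(path)
                dens = {w: np.array([_annotate.track_density(c, reads)
                                     for c in confirmed if c.winner == w])
                        for w in winners}
                track_values[name] = (dens[winners[0]], dens[winners[1]])
            _io.write_table(outdir / "track_densities.tsv",
                            _annotate.compare_tracks(track_values,
                                                     n_perm=config.n_perm,
                                                     seed=config.seed), meta)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float) + "\n")
    return outdir
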