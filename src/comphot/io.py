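"""Readers and writers for the package's file formats.

Coordinates are 0-based half-open everywhere (BED convention).  Sites,
blind regions, genes and read tracks travel as BED6; hotspot/test/
annotation tables as TSV with ``#``-prefixed metadata header lines
(version, config hash, seed) so outputs are self-describing and
re-runs are byte-identical.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .blindmap import AnalysisUnit, BlindMap

_BED6 = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path):
    """Indexed FASTA access by chromosome name (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(path), sequence_always_upper=True)


_EMPTY_SITES = pd.DataFrame(columns=["chrom", "pos", "strand", "vector"])


def read_sites_bed(path) -> pd.DataFrame:
    """Integration sites from BED6: start = position, name = vector label."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return _EMPTY_SITES.copy()
    if df.shape[1] < 6:
        raise ValueError("sites BED must have 6 columns (BED6)")
    df = df.iloc[:, :6]
    df.columns = _BED6
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("sites BED strand column must be + or -")
    return pd.DataFrame({"chrom": df["chrom"].astype(str), "pos": df["start"],
                         "strand": df["strand"], "vector": df["name"].astype(str)})


def read_arms_bed(path) -> list[dict]:
    """Chromosome-arm definitions from BED3+ (name column = p|q)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("arms BED must have at least 4 columns (chrom,start,end,arm)")
    out = []
    for _, r in df.iterrows():
        arm = str(r[3])
        if arm not in ("p", "q"):
            raise ValueError(f"arm name must be p or q, got {arm!r}")
        out.append({"chrom": str(r[0]), "start": int(r[1]), "end": int(r[2]),
                    "arm": arm})
    return out


def read_genes_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = min(df.shape[1], 6)
    df = df.iloc[:, :ncol]
    df.columns = _BED6[:ncol]
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_reads_bed(path) -> pd.DataFrame:
    df = read_genes_bed(path)
    return pd.DataFrame({"chrom": df["chrom"], "pos": df["start"]})


def read_expression_flags(path) -> pd.DataFrame:
    """TSV of (gene id, present|absent)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["gene", "flag"] + list(df.columns[2:])
    bad = set(df["flag"].unique()) - {"present", "absent"}
    if bad:
        raise ValueError(f"unknown expression flags: {sorted(bad)}")
    return df[["gene", "flag"]]


def write_blind_bed(path, bmaps: dict[str, BlindMap]) -> None:
    """Blind intervals of every unit as BED6 (name = unit id)."""
    rows = []
    for uid, bmap in bmaps.items():
        for s, e in bmap.blind:
            rows.append((bmap.unit.chrom, int(s), int(e), uid, 0,
                         bmap.unit.strand))
    pd.DataFrame(rows, columns=_BED6).to_csv(path, sep="\t", header=False,
                                             index=False)


def write_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """TSV with '#'-prefixed metadata lines followed by a header row."""
    buf = _io.StringIO()
    buf.write(f"# comphot {__version__}\n")
    for k, v in (meta or {}).items():
        buf.write(f"# {k}: {v}\n")
    df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def units_from_arms(arms: list[dict]) -> list[AnalysisUnit]:
    """Expand arm records into per-strand analysis units."""
    units = []
    for a in arms:
        for strand in ("+", "-"):
            units.append(AnalysisUnit(a["chrom"], a["arm"], strand,
                                      a["start"], a["end"]))
    return units
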