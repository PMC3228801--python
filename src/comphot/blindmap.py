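"""Restriction-digest blind regions and the collapsed coordinate system.

Integration-site libraries built by restriction digestion plus size
selection cannot detect an integration whose distance to the relevant
restriction site falls outside the window ``[min_read, max_frag)``: shorter
fragments produce unalignably short junction reads, longer ones are removed
by size fractionation.  The stretches of the genome that are undetectable
for this reason are *blind regions*; they are strand specific and must be
excised before any density comparison, otherwise a blind stretch mimics a
real integration desert.

This module scans a sequence for the restriction motif (TTAA / MseI by
default), derives the blind intervals per analysis unit (one chromosome
arm on one strand), and provides an invertible map between genomic
coordinates and the *collapsed* coordinate obtained by deleting the blind
intervals and concatenating the detectable segments.

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("comphot.blindmap")

#: minimum alignable junction-read length in bp
DEFAULT_MIN_READ = 20
#: maximum sequenced fragment length in bp (size-selection cut-off)
DEFAULT_MAX_FRAG = 500
#: MseI recognition sequence (its own reverse complement)
DEFAULT_MOTIF = "TTAA"
#: assembly-gap N runs at least this long are treated as blind
DEFAULT_N_RUN = 1000

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class BlindPositionError(ValueError):
    """Raised when a genomic position inside a blind interval is collapsed."""


@dataclass(frozen=True)
class AnalysisUnit:
    """One (chromosome, arm, strand) triple with its genomic extent.

    Densities, bands and candidate hotspots are computed independently per
    unit: arms are separated because the centromere is a giant blind
    region, strands because blind regions are strand specific.
    """

    chrom: str
    arm: str  # "p" or "q"
    strand: str  # "+" or "-"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty unit [{self.start}, {self.end})")
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be p or q, got {self.arm!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        return f"{self.chrom}_{self.arm}_{self.strand}"


@dataclass(frozen=True)
class MotifSites:
    """Sorted 0-based start coordinates of motif occurrences."""

    positions: np.ndarray
    motif: str = DEFAULT_MOTIF

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if pos.size and np.any(np.diff(pos) <= 0):
            raise ValueError("motif positions must be strictly increasing")

    def __len__(self) -> int:
        return int(self.positions.size)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_motif(sequence, motif: str = DEFAULT_MOTIF,
               include_reverse_complement: bool = False) -> MotifSites:
    """Find every (possibly overlapping) motif occurrence in ``sequence``.

    Matching is exact and case-insensitive; ambiguous bases (N) never
    match.  ``include_reverse_complement`` additionally scans for the
    reverse complement of the motif, for non-palindromic enzymes; TTAA is
    its own reverse complement so the default scan serves both strands.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if isinstance(sequence, (bytes, bytearray)):
        buf = bytes(sequence).upper()
    else:
        buf = str(sequence).upper().encode("ascii")
    motifs = {motif.upper()}
    if include_reverse_complement:
        motifs.add(reverse_complement(motif.upper()))
    arr = np.frombuffer(buf, dtype=np.uint8)
    hits: list[np.ndarray] = []
    for m in motifs:
        mb = m.encode("ascii")
        k = len(mb)
        if arr.size < k:
            continue
        match = arr[: arr.size - k + 1] == mb[0]
        for j in range(1, k):
            match &= arr[j: arr.size - k + 1 + j] == mb[j]
        hits.append(np.flatnonzero(match))
    pos = (np.unique(np.concatenate(hits)) if hits
           else np.empty(0, dtype=np.int64))
    return MotifSites(positions=pos.astype(np.int64), motif=motif.upper())


def find_n_runs(sequence, min_len: int = DEFAULT_N_RUN) -> np.ndarray:
    """Half-open intervals of N runs of length >= ``min_len`` (assembly gaps)."""
    if isinstance(sequence, (bytes, bytearray)):
        arr = np.frombuffer(bytes(sequence).upper(), dtype=np.uint8)
    else:
        arr = np.frombuffer(str(sequence).upper().encode("ascii"), dtype=np.uint8)
    is_n = (arr == ord("N")).astype(np.int8)
    if not is_n.any():
        return np.empty((0, 2), dtype=np.int64)
    d = np.diff(np.concatenate(([0], is_n, [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    keep = (ends - starts) >= min_len
    return np.column_stack([starts[keep], ends[keep]]).astype(np.int64)


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent half-open intervals."""
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    iv = iv[iv[:, 1] > iv[:, 0]]
    if iv.shape[0] == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], int(e))
        else:
            out.append([int(s), int(e)])
    return np.asarray(out, dtype=np.int64)


def derive_blind_intervals(sites: MotifSites | np.ndarray, unit: AnalysisUnit,
                           min_read: int = DEFAULT_MIN_READ,
                           max_frag: int = DEFAULT_MAX_FRAG) -> np.ndarray:
    """Blind intervals of ``unit`` implied by restriction-site positions.

    Within each gap between consecutive sites ``(p, q)``:

    * ``+`` strand: detectable positions lie ``[min_read, max_frag)``
      downstream of the 5' site, so ``[p, min(p+min_read, q))`` and
      ``[min(p+max_frag, q), q)`` are blind;
    * ``-`` strand: the mirror image, measured upstream from ``q``.

    The spans of the unit before the first site and after the last site
    have no usable flanking site and are blind on both strands, as is a
    unit with no site at all.  Returned intervals are merged, disjoint,
    sorted and clipped to the unit.
    """
    if min_read >= max_frag:
        raise ValueError("min_read must be < max_frag")
    pos = sites.positions if isinstance(sites, MotifSites) else np.asarray(sites, np.int64)
    if pos.size and np.any(np.diff(pos) <= 0):
        raise ValueError("restriction sites must be strictly increasing")
    # allow a site touching the closed end of the unit (it bounds the last gap)
    if pos.size and (pos[0] < unit.start or pos[-1] > unit.end):
        raise ValueError("restriction sites outside the analysis unit")
    if pos.size < 2:
        return np.array([[unit.start, unit.end]], dtype=np.int64)

    p, q = pos[:-1], pos[1:]
    if unit.strand == "+":
        b1 = np.column_stack([p, np.minimum(p + min_read, q)])
        b2 = np.column_stack([np.minimum(p + max_frag, q), q])
    else:
        b1 = np.column_stack([np.maximum(q - min_read, p), q])
        b2 = np.column_stack([p, np.maximum(q - max_frag, p)])
    pieces = [b1, b2]
    if pos[0] > unit.start:
        pieces.append(np.array([[unit.start, pos[0]]]))
    if pos[-1] < unit.end:
        pieces.append(np.array([[pos[-1], unit.end]]))
    return merge_intervals(np.vstack(pieces))


@dataclass
class BlindMap:
    """Invertible genomic <-> collapsed coordinate map for one unit.

    The collapsed coordinate deletes blind intervals and concatenates the
    detectable segments, so densities can be estimated on a gap-free axis
    and found hotspots expanded back into the original topology.
    """

    unit: AnalysisUnit
    blind: np.ndarray  # (k, 2) sorted disjoint half-open, within unit
    # non-blind segments, derived
    seg_gstart: np.ndarray = field(init=False, repr=False)
    seg_gend: np.ndarray = field(init=False, repr=False)
    seg_cstart: np.ndarray = field(init=False, repr=False)
    collapsed_length: int = field(init=False)

    def __post_init__(self) -> None:
        blind = np.asarray(self.blind, dtype=np.int64).reshape(-1, 2)
        if blind.size:
            if np.any(blind[:, 0] >= blind[:, 1]):
                raise ValueError("blind intervals must be non-empty half-open")
            if np.any(np.diff(blind.ravel()) < 0):
                raise ValueError("blind intervals must be sorted and disjoint")
            if blind[0, 0] < self.unit.start or blind[-1, 1] > self.unit.end:
                raise ValueError("blind intervals outside the unit")
        self.blind = blind
        bounds = np.concatenate(([self.unit.start], blind.ravel(), [self.unit.end]))
        gs, ge = bounds[0::2], bounds[1::2]
        keep = ge > gs
        self.seg_gstart, self.seg_gend = gs[keep], ge[keep]
        lens = self.seg_gend - self.seg_gstart
        self.seg_cstart = np.concatenate(([0], np.cumsum(lens)[:-1])).astype(np.int64)
        self.collapsed_length = int(lens.sum())
        if self.collapsed_length == 0:
            logger.warning("unit %s is fully blind (degenerate map)", self.unit.id)

    @property
    def is_degenerate(self) -> bool:
        return self.collapsed_length == 0

    def blind_fraction(self) -> float:
        return 1.0 - self.collapsed_length / self.unit.length

    def is_blind(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=np.int64)
        i = np.searchsorted(self.seg_gstart, x, side="right") - 1
        ok = (i >= 0) & (x < self.seg_gend[np.clip(i, 0, None)])
        return ~ok

    def collapse(self, x):
        """Map genomic position(s) to collapsed coordinate(s).

        Raises :class:`BlindPositionError` for blind positions and
        ``ValueError`` for positions outside the unit.
        """
        xa = np.asarray(x, dtype=np.int64)
        if np.any((xa < self.unit.start) | (xa >= self.unit.end)):
            raise ValueError("position outside the analysis unit")
        i = np.searchsorted(self.seg_gstart, xa, side="right") - 1
        bad = (i < 0) | (xa >= self.seg_gend[np.clip(i, 0, None)])
        if np.any(bad):
            raise BlindPositionError("cannot collapse a blind position")
        out = self.seg_cstart[i] + (xa - self.seg_gstart[i])
        return out if isinstance(x, np.ndarray) else int(out)

    def expand(self, c):
        """Map collapsed coordinate(s) back to genomic position(s)."""
        ca = np.asarray(c, dtype=np.int64)
        if np.any((ca < 0) | (ca >= self.collapsed_length)):
            raise ValueError("collapsed coordinate out of range")
        i = np.searchsorted(self.seg_cstart, ca, side="right") - 1
        out = self.seg_gstart[i] + (ca - self.seg_cstart[i])
        return out if isinstance(c, np.ndarray) else int(out)

    def expand_interval(self, a: int, b: int) -> tuple[int, int]:
        """Expand a collapsed half-open interval ``[a, b)`` to genomic scale.

        The genomic interval covers every detectable base of the collapsed
        one plus any blind stretches interior to it, so its length is at
        least ``b - a``.
        """
        if not (0 <= a < b <= self.collapsed_length):
            raise ValueError("collapsed interval out of range")
        gstart = self.expand(int(a))
        gend = self.expand(int(b) - 1) + 1
        return int(gstart), int(gend)


def build_blind_map(blind_intervals, unit: AnalysisUnit) -> BlindMap:
    """Construct a :class:`BlindMap` from disjoint sorted blind intervals."""
    return BlindMap(unit=unit, blind=np.asarray(blind_intervals, np.int64).reshape(-1, 2))


def blind_map_from_sequence(sequence, unit: AnalysisUnit,
                            motif: str = DEFAULT_MOTIF,
                            min_read: int = DEFAULT_MIN_READ,
                            max_frag: int = DEFAULT_MAX_FRAG,
                            include_reverse_complement: bool = False,
                            n_run: int = DEFAULT_N_RUN) -> BlindMap:
    """Scan ``sequence`` (covering ``unit.region``, index 0 = unit.start)
    and build the unit's blind map, including long assembly-gap N runs."""
    sites = scan_motif(sequence, motif, include_reverse_complement)
    pos = sites.positions + unit.start
    pos = pos[(pos >= unit.start) & (pos <= unit.end)]
    blind = derive_blind_intervals(MotifSites(pos, sites.motif), unit,
                                   min_read=min_read, max_frag=max_frag)
    runs = find_n_runs(sequence, min_len=n_run)
    if runs.size:
        blind = merge_intervals(np.vstack([blind, runs + unit.start]))
    return build_blind_map(blind, unit)


def blind_fraction(bmap: BlindMap) -> float:
    """Fraction of the unit that is blind, in ``[0, 1]``."""
    return bmap.blind_fraction()
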