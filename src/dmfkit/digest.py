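"""In-silico MspI digestion of a reference genome into RRBS fragments.

Reduced-representation bisulphite sequencing (RRBS) libraries are built from
MspI-digested DNA.  The enzyme recognises CCGG and cleaves between the first
and second base (C^CGG), so every occurrence of the motif contributes one cut
on the plus strand.  Size selection then retains doubly-cut fragments in a
narrow window (conventionally 40-220 bp), which enriches CpG-dense genome
fractions.  This module reproduces that process on a FASTA reference:

* :func:`find_mspi_cuts` scans a sequence for CCGG motifs,
* :func:`digest` turns cut positions into a :class:`FragmentCatalog`,
* :func:`size_select` applies the library size window,
* :func:`locate_cpgs` records the plus-strand CpG positions of each fragment.

All coordinates are 0-based half-open internally; the BED writer keeps that
convention (BED is itself 0-based half-open).

The cut model is single-stranded: one cut per recognition site at C^CGG on
the plus strand.  MspI in fact leaves 2-nt 5' overhangs, but fragment
methylation is interval-based, so overhang bookkeeping would not change CpG
membership; fragment intervals simply abut.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "FragmentCatalog",
    "find_mspi_cuts",
    "digest",
    "size_select",
    "locate_cpgs",
]

MSPI_SITE = "CCGG"
#: Offset of the cut within the recognition site (C^CGG).
MSPI_CUT_OFFSET = 1

_MSPI_RE = re.compile(r"(?=CCGG)")  # lookahead so overlapping motifs all match
_VALID = set("ACGTN")


class Genome(Mapping):
    """A reference genome held in memory as per-chromosome strings.

    Sequences are stored upper-case; any non-ACGTN IUPAC character is
    masked to N.  Chromosome order is preserved from the input.
    """

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one chromosome")
        cleaned: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            s = str(seq).upper()
            if not set(s) <= _VALID:
                s = re.sub(r"[^ACGTN]", "N", s)
            cleaned[name] = s
        self._seqs = cleaned

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self._seqs.items()
        ]
        SeqIO.write(records, str(path), "fasta")


@dataclass
class FragmentCatalog:
    """In-silico MspI fragments with coordinates and CpG positions.

    ``frame`` holds one row per fragment with columns ``chrom``, ``start``,
    ``end`` (0-based half-open), ``fragment_id``, ``length``, ``terminal``
    (abuts a chromosome end, i.e. singly cut) and ``n_cpg`` (-1 until
    :func:`locate_cpgs` has run).  ``cpg_positions`` is aligned with the
    rows of ``frame`` and gives the 0-based plus-strand C coordinate of
    every CpG whose C lies inside the fragment interval.
    """

    frame: pd.DataFrame
    cpg_positions: list[np.ndarray] | None = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frame)

    def __post_init__(self) -> None:
        if self.cpg_positions is not None and len(self.cpg_positions) != len(self.frame):
            raise ValueError("cpg_positions must align with catalog rows")

    def sequences(self, genome: Genome) -> list[str]:
        return [
            genome[row.chrom][row.start : row.end]
            for row in self.frame.itertuples(index=False)
        ]

    def to_bed(self, path: str | Path) -> None:
        """Write a BED6-like TSV: chrom, start, end, fragment_id, length, n_CpG."""
        out = self.frame[["chrom", "start", "end", "fragment_id", "length", "n_cpg"]]
        out.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path, **provenance) -> "FragmentCatalog":
        frame = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "fragment_id", "length", "n_cpg"],
            dtype={"chrom": str},
        )
        frame["terminal"] = False  # not persisted in BED; terminal fragments are
        # normally excluded before writing
        return cls(frame=frame.reset_index(drop=True), provenance=dict(provenance))


def _fragment_id(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def find_mspi_cuts(seq: str) -> list[int]:
    """Return ascending between-base cut coordinates for MspI on ``seq``.

    A cut at coordinate ``i + 1`` is produced for every index ``i`` where
    ``seq[i:i+4] == "CCGG"`` (case-insensitive).  Overlapping occurrences
    each yield a cut.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    return [m.start() + MSPI_CUT_OFFSET for m in _MSPI_RE.finditer(seq.upper())]


def digest(genome: Genome, locate: bool = True) -> FragmentCatalog:
    """Digest every chromosome of ``genome`` at MspI sites.

    For a chromosome of length L with cuts c1 < ... < ck the fragments are
    [0,c1), [c1,c2), ..., [ck,L); the two outermost fragments are flagged
    terminal.  A chromosome with no site yields a single terminal fragment.
    Concatenating fragment sequences in order reconstructs the chromosome.

    When ``locate`` is true (default) CpG positions are filled in directly.
    """
    rows = []
    for chrom, seq in genome.items():
        cuts = find_mspi_cuts(seq)
        bounds = [0, *cuts, len(seq)]
        n = len(bounds) - 1
        for i in range(n):
            start, end = bounds[i], bounds[i + 1]
            rows.append(
                (chrom, start, end, _fragment_id(chrom, start, end), end - start,
                 i == 0 or i == n - 1)
            )
    frame = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "fragment_id", "length", "terminal"]
    )
    frame["n_cpg"] = -1
    catalog = FragmentCatalog(
        frame=frame, provenance={"genome_lengths": genome.lengths}
    )
    if locate:
        catalog = locate_cpgs(catalog, genome)
    return catalog


def size_select(
    catalog: FragmentCatalog,
    min_len: int = 40,
    max_len: int = 220,
    keep_terminal: bool = False,
) -> FragmentCatalog:
    """Retain fragments with ``min_len <= length <= max_len`` (inclusive).

    Terminal (singly-cut) fragments are dropped unless ``keep_terminal``:
    RRBS library construction requires MspI ends on both sides.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) must not exceed max_len ({max_len})")
    keep = (catalog.frame["length"] >= min_len) & (catalog.frame["length"] <= max_len)
    if not keep_terminal:
        keep &= ~catalog.frame["terminal"]
    idx = np.flatnonzero(keep.to_numpy())
    frame = catalog.frame.iloc[idx].reset_index(drop=True)
    cpgs = None
    if catalog.cpg_positions is not None:
        cpgs = [catalog.cpg_positions[i] for i in idx]
    provenance = dict(catalog.provenance)
    provenance.update(min_len=min_len, max_len=max_len, keep_terminal=keep_terminal)
    return FragmentCatalog(frame=frame, cpg_positions=cpgs, provenance=provenance)


def _cpg_sites(seq: str) -> np.ndarray:
    """0-based positions p with seq[p] == 'C' and seq[p+1] == 'G'."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def locate_cpgs(catalog: FragmentCatalog, genome: Genome) -> FragmentCatalog:
    """Fill in the plus-strand CpG positions of every fragment.

    A CpG is assigned to the fragment whose half-open interval contains its
    C; the CG inside each boundary CCGG therefore belongs to the downstream
    fragment, which starts at that C.  Assignment is a partition of the
    genomic CpGs lying inside fragment intervals.
    """
    per_chrom = {chrom: _cpg_sites(seq) for chrom, seq in genome.items()}
    lengths = genome.lengths
    positions: list[np.ndarray] = []
    counts = np.empty(len(catalog), dtype=int)
    for i, row in enumerate(catalog.frame.itertuples(index=False)):
        if row.chrom not in lengths:
            raise ValueError(f"chromosome {row.chrom!r} not in genome")
        if row.start < 0 or row.end > lengths[row.chrom] or row.start >= row.end:
            raise ValueError(
                f"fragment {row.fragment_id} out of range for {row.chrom}"
            )
        sites = per_chrom[row.chrom]
        lo, hi = np.searchsorted(sites, [row.start, row.end])
        pos = sites[lo:hi]
        positions.append(pos)
        counts[i] = len(pos)
    frame = catalog.frame.copy()
    frame["n_cpg"] = counts
    return FragmentCatalog(
        frame=frame, cpg_positions=positions, provenance=dict(catalog.provenance)
    )
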