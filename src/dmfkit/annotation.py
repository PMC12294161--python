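"""Genomic-feature classification of RRBS fragments.

Fragments are assigned exactly one of five labels relative to a set of gene
models: ``promoter`` (overlap with the strand-oriented window from 1 kb
upstream to 5 kb downstream of the TSS), ``exon_intron_boundary`` (overlap
with both an exon and an adjacent intron of the same gene), ``exon``,
``intron``, or ``intergenic`` (no overlap with any gene span or promoter
window).  Precedence is promoter > boundary > exon > intron; ties across
genes are broken by smaller absolute TSS distance, then lexicographic gene
id.  Intergenic fragments carry no gene id, matching the convention of
reporting gene linkages only for fragments inside defined gene features.

One representative transcript is kept per gene (the longest); introns are
the gene-body complement of the exons, so a fragment that overlaps an exon
and intron of the same gene necessarily crosses an exon/intron junction.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from intervaltree import IntervalTree

from .digest import FragmentCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "AnnotationLabel",
    "GeneIndex",
    "load_gene_models",
    "classify_fragment",
    "annotate_catalog",
    "PROMOTER_UPSTREAM",
    "PROMOTER_DOWNSTREAM",
]

#: Promoter window relative to the TSS, in transcription direction (bp).
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 5000

_RANK = {"promoter": 0, "exon_intron_boundary": 1, "exon": 2, "intron": 3}


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to one representative transcript.

    Coordinates are 0-based half-open; ``exons`` are sorted and
    non-overlapping.  The TSS is the span start on the plus strand and
    ``end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene has no exons")
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside span")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def promoter_window(self) -> tuple[int, int]:
        """Genomic half-open interval of [TSS-1kb, TSS+5kb] (strand-aware)."""
        if self.strand == "+":
            return self.tss - PROMOTER_UPSTREAM, self.tss + PROMOTER_DOWNSTREAM + 1
        return self.tss - PROMOTER_DOWNSTREAM, self.tss + PROMOTER_UPSTREAM + 1

    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gene-body complement of the exons (includes any span flanks)."""
        out = []
        prev = self.start
        for s, e in self.exons:
            if s > prev:
                out.append((prev, s))
            prev = max(prev, e)
        if prev < self.end:
            out.append((prev, self.end))
        return tuple(out)

    def tss_distance(self, start: int, end: int) -> int:
        """Signed transcription-oriented distance from fragment midpoint to TSS."""
        mid = (start + end) // 2
        d = mid - self.tss
        return d if self.strand == "+" else -d


@dataclass(frozen=True)
class AnnotationLabel:
    """Classification of one fragment: label, associated gene, TSS distance."""

    location: str
    gene_id: str | None = None
    tss_distance: int | None = None

    def __post_init__(self) -> None:
        if (self.location == "intergenic") == (self.gene_id is not None):
            raise ValueError("gene id present iff label is not intergenic")


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _parse_bed12(path: Path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}: line {lineno}: BED12 needs 12 columns")
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5]
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + sz) for off, sz in zip(offsets, sizes)
            )
            try:
                models.append(
                    GeneModel(name, chrom, strand, start, end, exons)
                )
            except ValueError as exc:
                logger.warning("skipping %s: %s", name, exc)
    return models


def _parse_gff(path: Path, gene_key: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    # group exons by (gene, transcript) straight from attributes; works for
    # GTF (gene_id/transcript_id) and attribute-rich GFF3 alike
    tx_exons: dict[tuple[str, str], list] = {}
    tx_meta: dict[tuple[str, str], tuple[str, str]] = {}
    for exon in db.features_of_type("exon"):
        gene = exon.attributes.get(gene_key, [None])[0]
        tx = exon.attributes.get("transcript_id", exon.attributes.get("Parent", [None]))[0]
        if gene is None and tx is not None:
            # GFF3: walk up Parent chain for the gene id
            try:
                parent = db[tx]
                gene = parent.attributes.get(gene_key, parent.attributes.get("Parent", [tx]))[0]
            except Exception:
                gene = tx
        if gene is None or tx is None:
            continue
        key = (gene, tx)
        tx_exons.setdefault(key, []).append((exon.start - 1, exon.end))
        tx_meta[key] = (exon.seqid, exon.strand)
    best: dict[str, GeneModel] = {}
    for (gene, _tx), exons in tx_exons.items():
        chrom, strand = tx_meta[(gene, _tx)]
        exons = tuple(sorted(exons))
        span = (exons[0][0], exons[-1][1])
        try:
            model = GeneModel(gene, chrom, strand, span[0], span[1], exons)
        except ValueError as exc:
            logger.warning("skipping %s: %s", gene, exc)
            continue
        prev = best.get(gene)
        if prev is None or (model.end - model.start) > (prev.end - prev.start):
            best[gene] = model
    return list(best.values())


def load_gene_models(
    path: str | Path, fmt: str | None = None, gene_key: str = "gene_id"
) -> list[GeneModel]:
    """Load gene models from BED12 or GTF/GFF3, one longest transcript per gene.

    ``fmt`` ('bed12' or 'gff') is sniffed from the extension when omitted.
    Records that fail validation (no exons, exon outside span) are skipped
    with a warning.  Models are returned sorted by chromosome then start.
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed12" if path.suffix.lower() in {".bed", ".bed12"} else "gff"
    if fmt == "bed12":
        models = _parse_bed12(path)
    elif fmt == "gff":
        models = _parse_gff(path, gene_key)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return sorted(models, key=lambda m: (m.chrom, m.start, m.gene_id))


class GeneIndex:
    """Interval index over gene spans and promoter windows for fast lookup."""

    def __init__(self, models: list[GeneModel]):
        self.trees: dict[str, IntervalTree] = {}
        self.tss: dict[str, list[tuple[int, GeneModel]]] = {}
        for m in models:
            tree = self.trees.setdefault(m.chrom, IntervalTree())
            ps, pe = m.promoter_window()
            lo = min(m.start, ps)
            hi = max(m.end, pe)
            tree.addi(lo, hi, m)
            self.tss.setdefault(m.chrom, []).append((m.tss, m))
        for chrom in self.tss:
            self.tss[chrom].sort(key=lambda t: t[0])

    def candidates(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self.trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def nearest_tss(self, chrom: str, start: int, end: int) -> GeneModel | None:
        entries = self.tss.get(chrom)
        if not entries:
            return None
        mid = (start + end) // 2
        positions = [t for t, _ in entries]
        i = bisect_left(positions, mid)
        best = None
        for j in (i - 1, i):
            if 0 <= j < len(entries):
                t, m = entries[j]
                d = abs(mid - t)
                if best is None or d < best[0]:
                    best = (d, m)
        return best[1] if best else None


def _gene_label(start: int, end: int, m: GeneModel) -> str | None:
    ps, pe = m.promoter_window()
    if _overlaps(start, end, ps, pe):
        return "promoter"
    if not _overlaps(start, end, m.start, m.end):
        return None
    in_exon = any(_overlaps(start, end, s, e) for s, e in m.exons)
    in_intron = any(_overlaps(start, end, s, e) for s, e in m.introns())
    if in_exon and in_intron:
        return "exon_intron_boundary"
    if in_exon:
        return "exon"
    if in_intron:
        return "intron"
    return None


def classify_fragment(
    chrom: str, start: int, end: int, index: GeneIndex
) -> AnnotationLabel:
    """Classify one fragment interval against the indexed gene models."""
    best: tuple[int, int, str, str, GeneModel] | None = None
    for m in index.candidates(chrom, start, end):
        label = _gene_label(start, end, m)
        if label is None:
            continue
        key = (_RANK[label], abs(m.tss_distance(start, end)), m.gene_id)
        if best is None or key < best[:3]:
            best = (*key, label, m)
    if best is None:
        near = index.nearest_tss(chrom, start, end)
        dist = near.tss_distance(start, end) if near is not None else None
        return AnnotationLabel("intergenic", None, dist)
    _, _, _, label, model = best
    return AnnotationLabel(label, model.gene_id, model.tss_distance(start, end))


def annotate_catalog(
    catalog: FragmentCatalog, models: list[GeneModel]
) -> pd.DataFrame:
    """Label every catalog fragment; returns a frame indexed by fragment id.

    Columns: ``location``, ``gene_id`` (NA for intergenic), ``tss_distance``.
    Deterministic and invariant to the input order of ``models``.
    """
    index = GeneIndex(models)
    rows = []
    for row in catalog.frame.itertuples(index=False):
        lab = classify_fragment(row.chrom, row.start, row.end, index)
        rows.append((row.fragment_id, lab.location, lab.gene_id, lab.tss_distance))
    out = pd.DataFrame(
        rows, columns=["fragment_id", "location", "gene_id", "tss_distance"]
    )
    return out.set_index("fragment_id")
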