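"""Reference sequences, transcript models, and genome<->mRNA coordinate maps.

All internal coordinates are 0-based half-open. GTF input (1-based inclusive)
is converted at the boundary; bedGraph positions are already 0-based.
"""

from __future__ import annotations

import bisect
import json
import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")

NOT_EXONIC = -1
"""Sentinel returned by :meth:`TranscriptModel.genomic_to_mrna` for intronic
or out-of-transcript positions."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GenomeSeq:
    """Uppercase nucleotide sequences keyed by contig name."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} has empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(f"contig {name!r} contains non-ACGTN characters: {sorted(bad)}")

    @classmethod
    def from_fasta(cls, path) -> "GenomeSeq":
        contigs = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in contigs:
                raise ValueError(f"duplicate contig name {rec.id!r}")
            contigs[rec.id] = str(rec.seq).upper()
        if not contigs:
            raise ValueError(f"no FASTA records in {path}")
        return cls(contigs)

    def to_fasta(self, path) -> None:
        recs = [SeqRecord(Seq(s), id=name, description="") for name, s in self.contigs.items()]
        SeqIO.write(recs, str(path), "fasta")

    def base(self, contig: str, pos0: int) -> str:
        return self.contigs[contig][pos0]


@dataclass
class TranscriptModel:
    """One transcript: ordered exons plus an optional CDS span.

    ``exons`` are 0-based half-open genomic intervals, non-overlapping and
    sorted by genomic start. ``cds_span`` is the genomic min/max of the CDS.
    On the minus strand, mRNA position 0 is the 3'-most genomic exon end.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int] | None = None

    # cumulative exon lengths, filled lazily
    _cum: list[int] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for (a, b), (c, d) in zip(self.exons, self.exons[1:]):
            if b > c:
                raise ValueError(f"transcript {self.transcript_id} has overlapping exons")
        if any(b <= a for a, b in self.exons):
            raise ValueError(f"transcript {self.transcript_id} has an empty exon")
        self._cum = [0]
        for a, b in self.exons:
            self._cum.append(self._cum[-1] + (b - a))

    @property
    def mrna_length(self) -> int:
        return self._cum[-1]

    @property
    def is_coding(self) -> bool:
        return self.cds_span is not None

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def _left_offset(self, gpos: int) -> int:
        """Exonic nucleotides strictly left of gpos, or NOT_EXONIC."""
        i = bisect.bisect_right([a for a, _ in self.exons], gpos) - 1
        if i < 0:
            return NOT_EXONIC
        a, b = self.exons[i]
        if gpos >= b:
            return NOT_EXONIC
        return self._cum[i] + (gpos - a)

    def genomic_to_mrna(self, gpos: int) -> int:
        """0-based mRNA coordinate of a genomic position, or NOT_EXONIC."""
        off = self._left_offset(gpos)
        if off == NOT_EXONIC:
            return NOT_EXONIC
        return off if self.strand == "+" else self.mrna_length - 1 - off

    def mrna_to_genomic(self, mpos: int) -> int:
        if not 0 <= mpos < self.mrna_length:
            raise IndexError(f"mRNA position {mpos} outside transcript of length {self.mrna_length}")
        off = mpos if self.strand == "+" else self.mrna_length - 1 - mpos
        i = bisect.bisect_right(self._cum, off) - 1
        a, _ = self.exons[i]
        return a + (off - self._cum[i])

    def _exonic_count_below(self, gpos: int) -> int:
        """Number of exonic positions with genomic coordinate < gpos."""
        n = 0
        for a, b in self.exons:
            if gpos <= a:
                break
            n += min(gpos, b) - a
        return n

    def utr_cds_segments(self) -> tuple[int, int, int]:
        """(5'UTR, CDS, 3'UTR) lengths in mRNA nucleotides; strand-aware."""
        if self.cds_span is None:
            raise ValueError(f"non-coding transcript {self.transcript_id}")
        cs, ce = self.cds_span
        before = self._exonic_count_below(cs)
        upto = self._exonic_count_below(ce)
        inside = upto - before
        after = self.mrna_length - upto
        if self.strand == "+":
            return before, inside, after
        return after, inside, before

    def spliced_seq(self, genome: GenomeSeq) -> str:
        """The mature mRNA sequence (DNA alphabet, 5'->3')."""
        s = "".join(genome.contigs[self.contig][a:b] for a, b in self.exons)
        return s if self.strand == "+" else revcomp(s)

    def to_dict(self) -> dict:
        return {
            "transcript_id": self.transcript_id,
            "gene_id": self.gene_id,
            "contig": self.contig,
            "strand": self.strand,
            "exons": [list(e) for e in self.exons],
            "cds_span": list(self.cds_span) if self.cds_span else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TranscriptModel":
        return cls(
            transcript_id=d["transcript_id"],
            gene_id=d["gene_id"],
            contig=d["contig"],
            strand=d["strand"],
            exons=[tuple(e) for e in d["exons"]],
            cds_span=tuple(d["cds_span"]) if d.get("cds_span") else None,
        )


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attrs(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def load_annotation(gtf_path) -> list[TranscriptModel]:
    """Parse a GTF into transcript models.

    Only ``exon`` and ``CDS`` features are consumed; both must carry
    ``gene_id`` and ``transcript_id`` attributes. 1-based inclusive
    coordinates are converted to 0-based half-open. Transcripts lacking
    exon features are dropped with a warning.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{gtf_path}: unparseable GTF line {lineno}: expected 9 fields")
            _, _, feature, start, end, _, strand, _, attrs = parts
            if feature not in ("exon", "CDS"):
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"{gtf_path}: line {lineno}: strand must be + or -, got {strand!r}")
            try:
                iv = (int(start) - 1, int(end))
            except ValueError as e:
                raise ValueError(f"{gtf_path}: unparseable GTF line {lineno}: {e}") from None
            a = _parse_attrs(attrs)
            if "gene_id" not in a or "transcript_id" not in a:
                raise ValueError(f"{gtf_path}: line {lineno}: missing gene_id/transcript_id")
            tid = a["transcript_id"]
            meta.setdefault(tid, (a["gene_id"], parts[0], strand))
            (exons if feature == "exon" else cds).setdefault(tid, []).append(iv)

    models = []
    for tid, (gene_id, contig, strand) in meta.items():
        if tid not in exons:
            log.warning("transcript %s has CDS but no exon features; dropped", tid)
            continue
        cspan = None
        if tid in cds:
            cspan = (min(a for a, _ in cds[tid]), max(b for _, b in cds[tid]))
        models.append(
            TranscriptModel(
                transcript_id=tid, gene_id=gene_id, contig=contig,
                strand=strand, exons=exons[tid], cds_span=cspan,
            )
        )
    return models


def write_gtf(models: list[TranscriptModel], path) -> None:
    """Serialize models to GTF (exon + CDS features, 1-based inclusive)."""
    with open(path, "w") as fh:
        for t in models:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for a, b in t.exons:
                fh.write(f"{t.contig}\teditscope\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n")
            if t.cds_span:
                cs, ce = t.cds_span
                for a, b in t.exons:
                    lo, hi = max(a, cs), min(b, ce)
                    if lo < hi:
                        fh.write(f"{t.contig}\teditscope\tCDS\t{lo + 1}\t{hi}\t.\t{t.strand}\t.\t{attrs}\n")


def save_models_json(models: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_dict() for t in models], fh, indent=1)


def load_models_json(path) -> list[TranscriptModel]:
    with open(path) as fh:
        return [TranscriptModel.from_dict(d) for d in json.load(fh)]


def representative_transcripts(models: list[TranscriptModel]) -> dict[str, TranscriptModel]:
    """One transcript per gene: longest mRNA, ties to the lexicographically
    smallest transcript_id."""
    best: dict[str, TranscriptModel] = {}
    for t in models:
        cur = best.get(t.gene_id)
        if cur is None or (t.mrna_length, _neg_id(t)) > (cur.mrna_length, _neg_id(cur)):
            best[t.gene_id] = t
    return best


class _neg_id:
    """Orders transcript ids so that *smaller* id wins under max()."""

    __slots__ = ("tid",)

    def __init__(self, t: TranscriptModel):
        self.tid = t.transcript_id

    def __gt__(self, other):  # a > b  <=>  a.tid < b.tid
        return self.tid < other.tid


class GeneModelIndex:
    """Representative transcript per gene plus interval indexes for lookup."""

    def __init__(self, models: list[TranscriptModel]):
        self.representatives = representative_transcripts(models)
        self.exon_trees: dict[str, IntervalTree] = {}
        self.span_trees: dict[str, IntervalTree] = {}
        for gid, t in self.representatives.items():
            et = self.exon_trees.setdefault(t.contig, IntervalTree())
            for a, b in t.exons:
                et.addi(a, b, gid)
            st = self.span_trees.setdefault(t.contig, IntervalTree())
            st.addi(t.span[0], t.span[1], gid)

    def genes_with_exon_at(self, contig: str, pos0: int) -> list[str]:
        tree = self.exon_trees.get(contig)
        return sorted({iv.data for iv in tree[pos0]}) if tree is not None else []

    def genes_spanning(self, contig: str, pos0: int) -> list[str]:
        tree = self.span_trees.get(contig)
        return sorted({iv.data for iv in tree[pos0]}) if tree is not None else []
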