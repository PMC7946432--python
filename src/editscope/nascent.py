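"""Intron-read analysis: nascent-transcription control for stability changes.

Reads wholly inside introns report on transcription rather than mRNA decay,
so a knockdown that lowers exonic counts while intron counts stay flat is a
posttranscriptional effect. Intron intervals are each gene's span minus the
exon union of *all* transcripts of *all* genes, so no intron interval can
overlap any annotated exon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .refmodel import TranscriptModel
from .stability import classify_de

log = logging.getLogger(__name__)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [tuple(x) for x in out]


def _subtract(span: tuple[int, int], blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """span minus a sorted, merged block list."""
    s, e = span
    out = []
    cur = s
    for a, b in blocks:
        if b <= cur or a >= e:
            continue
        if a > cur:
            out.append((cur, min(a, e)))
        cur = max(cur, b)
        if cur >= e:
            break
    if cur < e:
        out.append((cur, e))
    return out


@dataclass
class IntronAnnotation:
    """gene_id -> (contig, strand, disjoint intron intervals)."""

    introns: dict[str, tuple[str, str, list[tuple[int, int]]]]

    def to_saf(self, path) -> None:
        """SAF-like TSV (GeneID, Chr, Start, End, Strand), 1-based inclusive."""
        with open(path, "w") as fh:
            fh.write("GeneID\tChr\tStart\tEnd\tStrand\n")
            for gid in sorted(self.introns):
                contig, strand, ivs = self.introns[gid]
                for a, b in ivs:
                    fh.write(f"{gid}\t{contig}\t{a + 1}\t{b}\t{strand}\n")

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for gid in sorted(self.introns):
                contig, strand, ivs = self.introns[gid]
                for a, b in ivs:
                    fh.write(f"{contig}\t{a}\t{b}\t{gid}\t0\t{strand}\n")


def build_intron_annotation(models: list[TranscriptModel]) -> IntronAnnotation:
    """Per-gene intron intervals purged of every annotated exon.

    Introns = gene span (over all of its transcripts) minus the global exon
    union on that contig; intronless genes are absent.
    """
    exons_by_contig: dict[str, list[tuple[int, int]]] = {}
    genes: dict[str, tuple[str, str, int, int]] = {}
    for t in models:
        exons_by_contig.setdefault(t.contig, []).extend(t.exons)
        s, e = t.span
        if t.gene_id in genes:
            c, strand, gs, ge = genes[t.gene_id]
            genes[t.gene_id] = (c, strand, min(gs, s), max(ge, e))
        else:
            genes[t.gene_id] = (t.contig, t.strand, s, e)
    union = {c: _merge(ivs) for c, ivs in exons_by_contig.items()}

    out = {}
    for gid, (contig, strand, s, e) in genes.items():
        ivs = _subtract((s, e), union[contig])
        if ivs:
            out[gid] = (contig, strand, ivs)
    ann = IntronAnnotation(out)
    _assert_no_exon_overlap(ann, union)
    return ann


def _assert_no_exon_overlap(ann: IntronAnnotation, union: dict) -> None:
    for gid, (contig, _, ivs) in ann.introns.items():
        for a, b in ivs:
            for ea, eb in union[contig]:
                assert min(b, eb) <= max(a, ea), (
                    f"intron {contig}:{a}-{b} of {gid} overlaps exon {ea}-{eb}"
                )


def count_reads_in_introns(bam_path, ann: IntronAnnotation, sample_id: str = "") -> pd.Series:
    """Per-gene counts of reads whose aligned blocks all lie inside one
    intron interval of that gene; junction- or exon-touching reads excluded."""
    import pysam

    counts = {gid: 0 for gid in ann.introns}
    with pysam.AlignmentFile(str(bam_path)) as af:
        for gid, (contig, _, ivs) in ann.introns.items():
            if contig not in af.references:
                continue
            seen = set()
            for a, b in ivs:
                for read in af.fetch(contig, a, b):
                    if read.is_unmapped or read.query_name in seen:
                        continue
                    blocks = read.get_blocks()
                    if blocks and all(a <= s and e <= b for s, e in blocks):
                        counts[gid] += 1
                        seen.add(read.query_name)
    return pd.Series(counts, name=sample_id)


def nascent_class_fractions(
    intron_counts: pd.DataFrame, labels: list[str], targets, alpha: float = 0.05, seed: int = 0,
    **classify_kwargs,
) -> dict:
    """Knockdown-response class fractions of targets on the intron signal.

    Normalization and classification run on the full intron matrix (size
    factors need all genes); fractions are reported among targets.
    """
    targets = set(targets)
    if not targets:
        raise ValueError("empty target list")
    present = targets & set(intron_counts.index)
    with_signal = [g for g in present if intron_counts.loc[g].sum() > 0]
    if len(with_signal) < 5:
        raise ValueError(f"need >= 5 targets with intronic counts, got {len(with_signal)}")
    de = classify_de(intron_counts, labels, alpha=alpha, seed=seed, **classify_kwargs)
    sub = de[de["gene_id"].isin(with_signal)]
    n = len(sub)
    return {
        "fractions": {c: float((sub["cls"] == c).sum()) / n for c in ("down", "unchanged", "up")},
        "n_targets": n,
        "de": sub,
    }


def nascent_fraction_unchanged(intron_counts, labels, targets, alpha: float = 0.05, seed: int = 0) -> float:
    """Convenience wrapper: fraction of targets 'unchanged' on intron reads."""
    return nascent_class_fractions(intron_counts, labels, targets, alpha, seed)["fractions"]["unchanged"]
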