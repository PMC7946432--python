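"""Assigning edit sites to genes, transcript regions, and metagene coordinates.

Metagene coordinates rescale each mRNA region to unit length: 5'UTR maps to
[0,1), CDS to [1,2), 3'UTR to [2,3), so positional preferences aggregate
across genes of different lengths. Raw fractional positions are emitted;
binning is left to plotting.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .refmodel import NOT_EXONIC, GeneModelIndex

log = logging.getLogger(__name__)

MRNA_REGIONS = ("5UTR", "CDS", "3UTR")


def _region_of(t, mpos: int) -> tuple[str, float | None]:
    if not t.is_coding:
        return "noncoding_exon", None
    u5, cds, u3 = t.utr_cds_segments()
    if mpos < u5:
        return "5UTR", mpos / u5
    if mpos < u5 + cds:
        return "CDS", 1.0 + (mpos - u5) / cds
    return "3UTR", 2.0 + (mpos - u5 - cds) / u3


def assign_edit(edit: pd.Series, index: GeneModelIndex) -> dict:
    """Annotate one edit site with gene, region, and metagene coordinate.

    Gene choice: a gene whose exon union contains the site; ties prefer
    strand agreement, then a UTR placement, then the lexicographically
    smaller gene_id. Sites inside a gene span but not exonic are introns;
    outside any gene, intergenic.
    """
    contig, pos = edit["contig"], int(edit["pos0"])
    exonic = index.genes_with_exon_at(contig, pos)
    if exonic:
        cands = []
        for gid in exonic:
            t = index.representatives[gid]
            mpos = t.genomic_to_mrna(pos)
            region, mx = _region_of(t, mpos)
            strand_match = ("strand" not in edit) or edit["strand"] in (".", t.strand)
            in_utr = region in ("5UTR", "3UTR")
            cands.append((not strand_match, not in_utr, gid, region, mx, mpos, t))
        if len(cands) > 1:
            log.info("site %s:%d overlaps exons of genes %s", contig, pos, exonic)
        cands.sort(key=lambda c: c[:3])
        _, _, gid, region, mx, mpos, t = cands[0]
        return {"contig": contig, "pos0": pos, "gene_id": gid, "region": region,
                "metagene_x": mx, "mrna_pos": mpos, "strand": t.strand}
    spanning = index.genes_spanning(contig, pos)
    if spanning:
        gid = spanning[0]
        return {"contig": contig, "pos0": pos, "gene_id": gid, "region": "intron",
                "metagene_x": None, "mrna_pos": NOT_EXONIC,
                "strand": index.representatives[gid].strand}
    return {"contig": contig, "pos0": pos, "gene_id": "", "region": "intergenic",
            "metagene_x": None, "mrna_pos": NOT_EXONIC, "strand": "."}


def annotate_edits(edits: pd.DataFrame, index: GeneModelIndex) -> pd.DataFrame:
    return pd.DataFrame([assign_edit(r, index) for _, r in edits.iterrows()])


@dataclass
class RegionSummary:
    fractions: dict  # over mRNA regions (5UTR/CDS/3UTR)
    other_counts: dict  # noncoding_exon/intron/intergenic tallies
    edits_per_gene: dict
    single_site_gene_count: int
    n_edits: int


def region_fractions(annots: pd.DataFrame) -> RegionSummary:
    """Distribution of edits over mRNA regions plus per-gene edit counts."""
    if annots.empty:
        raise ValueError("no edits to summarize")
    counts = Counter(annots["region"])
    mrna_total = sum(counts.get(r, 0) for r in MRNA_REGIONS)
    if mrna_total == 0:
        log.warning("no edits fall in mRNA regions; fractions reported as 0")
        fractions = {r: 0.0 for r in MRNA_REGIONS}
    else:
        fractions = {r: counts.get(r, 0) / mrna_total for r in MRNA_REGIONS}
    per_gene = Counter(g for g in annots["gene_id"] if g)
    return RegionSummary(
        fractions=fractions,
        other_counts={r: counts.get(r, 0) for r in ("noncoding_exon", "intron", "intergenic")},
        edits_per_gene=dict(per_gene),
        single_site_gene_count=sum(1 for v in per_gene.values() if v == 1),
        n_edits=len(annots),
    )


def expression_independence(annots: pd.DataFrame, expression: dict) -> tuple[pd.DataFrame, float | None]:
    """Per-gene expression vs. edit status, with a rank correlation.

    Returns a table of (gene, expression, edited flag, n_edits) over all
    genes in the expression map, and the Spearman correlation between
    expression and edit count among edited genes (None when fewer than two
    edited genes have expression values).
    """
    if not expression:
        raise ValueError("empty expression map")
    per_gene = Counter(g for g in annots["gene_id"] if g)
    covered = sum(1 for g in per_gene if g in expression)
    if per_gene and covered / len(per_gene) < 0.9:
        log.warning("expression map covers only %d/%d edited genes", covered, len(per_gene))
    table = pd.DataFrame(
        {
            "gene_id": list(expression),
            "expression": [expression[g] for g in expression],
            "n_edits": [per_gene.get(g, 0) for g in expression],
        }
    )
    table["edited"] = table["n_edits"] > 0
    sub = table[table["edited"]]
    rho = None
    if len(sub) >= 2 and sub["expression"].nunique() > 1 and sub["n_edits"].nunique() > 1:
        rho = float(stats.spearmanr(sub["expression"], sub["n_edits"]).statistic)
        if np.isnan(rho):
            rho = None
    return table, rho
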