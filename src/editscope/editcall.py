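"""Calling A->I(G) edit sites from experiment-vs-control nucleotide tallies.

The caller compares per-position tallies between a fusion-expressing sample
and an unedited control and reports sites passing coverage and edit-fraction
thresholds (inclusive, >= 20 reads and >= 15% by default). Only A->G on the
gene's sense strand is considered (ADAR chemistry): genomic A with G reads
under + genes, genomic T with C reads under - genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

KEY = ["contig", "pos0", "strand"]


@dataclass
class EditCallConfig:
    min_coverage: int = 20
    min_edit_frac: float = 0.15
    ctrl_min_coverage: int = 20
    ctrl_max_alt_frac: float = 0.02
    strand_specific: bool = True

    def validate(self) -> None:
        for f in (self.min_edit_frac, self.ctrl_max_alt_frac):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0,1]")
        if self.min_coverage < 1 or self.ctrl_min_coverage < 1:
            raise ValueError("coverages must be >= 1")


@dataclass
class EditCallResult:
    """Called sites plus the funnel diagnostics around the control filter."""

    sites: pd.DataFrame  # contig,pos0,strand,coverage,edit_fraction,sample_id
    n_exp_pass: int  # sites passing experiment thresholds
    n_no_control: int  # of those, excluded for absent/under-covered control
    n_control_edited: int  # of those, excluded for edited control


def _edited_and_coverage(df: pd.DataFrame) -> pd.DataFrame:
    """Append coverage and sense-strand edited-base count columns."""
    df = df.copy()
    df["coverage"] = df[["nA", "nC", "nG", "nT"]].sum(axis=1)
    plus = df["strand"] == "+"
    ok = (plus & (df["ref"] == "A")) | (~plus & (df["ref"] == "T"))
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("dropping %d rows whose sense-strand reference base is not A", n_bad)
        df = df[ok]
        plus = df["strand"] == "+"
    df["edited"] = np.where(plus, df["nG"], df["nC"])
    return df


def call_edits(exp: pd.DataFrame, ctrl: pd.DataFrame, cfg: EditCallConfig) -> EditCallResult:
    """Report sites where the experiment is edited and the control is not.

    A site is called iff experiment coverage >= min_coverage, experiment
    edited fraction >= min_edit_frac (both inclusive), control coverage >=
    ctrl_min_coverage, and control edited fraction <= ctrl_max_alt_frac.
    Sites without qualifying control coverage are excluded and tallied, not
    raised.
    """
    cfg.validate()
    e = _edited_and_coverage(exp)
    c = _edited_and_coverage(ctrl)

    e = e[e["coverage"] >= cfg.min_coverage]
    e = e[e["edited"] / e["coverage"] >= cfg.min_edit_frac]
    n_exp_pass = len(e)

    m = e.merge(
        c[KEY + ["coverage", "edited"]], on=KEY, how="left", suffixes=("", "_ctrl")
    )
    has_ctrl = m["coverage_ctrl"].notna() & (m["coverage_ctrl"] >= cfg.ctrl_min_coverage)
    n_no_control = int((~has_ctrl).sum())
    m = m[has_ctrl]
    ctrl_clean = m["edited_ctrl"] / m["coverage_ctrl"] <= cfg.ctrl_max_alt_frac
    n_control_edited = int((~ctrl_clean).sum())
    m = m[ctrl_clean]

    sites = m[KEY + ["coverage"]].copy()
    sites["edit_fraction"] = (m["edited"] / m["coverage"]).to_numpy()
    sites["sample_id"] = m["sample_id"].to_numpy() if "sample_id" in m else ""
    sites = sites.sort_values(KEY, kind="mergesort").reset_index(drop=True)

    assert (sites["coverage"] >= cfg.min_coverage).all()
    assert (sites["edit_fraction"] >= cfg.min_edit_frac).all()
    return EditCallResult(sites, n_exp_pass, n_no_control, n_control_edited)


def intersect_replicates(replicate_sites: list[pd.DataFrame]) -> pd.DataFrame:
    """Sites called in every replicate, with per-replicate edit fractions.

    Keyed by (contig, pos0, strand); output columns frac_rep1..frac_repN and
    cov_rep1..cov_repN feed the per-replicate edit-percentage heatmap.
    """
    if len(replicate_sites) < 2:
        raise ValueError("replication required: need >= 2 replicate edit sets")
    out = None
    for i, df in enumerate(replicate_sites, start=1):
        cur = df[KEY].copy()
        cur[f"frac_rep{i}"] = df["edit_fraction"].to_numpy()
        cur[f"cov_rep{i}"] = df["coverage"].to_numpy()
        out = cur if out is None else out.merge(cur, on=KEY, how="inner")
    if out.empty:
        log.warning("no edit sites common to all %d replicates", len(replicate_sites))
    return out.sort_values(KEY, kind="mergesort").reset_index(drop=True)


def write_bedgraph(sites: pd.DataFrame, path, frac_col: str = "edit_fraction", header: str = "") -> None:
    """bedGraph of edit percentages: contig, pos0, pos0+1, percent (2 dp)."""
    with open(path, "w") as fh:
        fh.write(f"# editscope edit sites; value = edit percentage{(' ' + header) if header else ''}\n")
        for _, r in sites.iterrows():
            fh.write(f"{r['contig']}\t{int(r['pos0'])}\t{int(r['pos0']) + 1}\t{100 * r[frac_col]:.2f}\n")


def read_bedgraph(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3]) / 100.0))
            except ValueError:
                raise ValueError(f"{path}: malformed bedGraph line {lineno}") from None
    return pd.DataFrame(rows, columns=["contig", "pos0", "end0", "edit_fraction"])


def pileup_from_alignments(
    bam_path, genome, index, min_mapq: int = 10, min_baseq: int = 20, sample_id: str = ""
) -> pd.DataFrame:
    """SiteCount table from a sorted+indexed BAM, restricted to sense-A sites.

    Positions are kept only where an annotated gene determines the strand and
    the sense-strand reference base is A (genomic A under + genes, genomic T
    under - genes). Reads below MAPQ 10 and bases below Q20 are excluded;
    the MAPQ filter stands in for a unique-mapping requirement.
    """
    import pysam

    af = pysam.AlignmentFile(str(bam_path))
    if not af.has_index():
        raise ValueError(f"{bam_path}: alignment file must be coordinate-sorted and indexed "
                         "(samtools sort && samtools index)")
    rows = []
    for contig in af.references:
        if contig not in genome.contigs:
            raise ValueError(f"contig {contig!r} in alignments but absent from genome")
        for col in af.pileup(
            contig, min_base_quality=min_baseq, min_mapping_quality=min_mapq,
            stepper="samtools", truncate=True,
        ):
            pos = col.reference_pos
            gids = index.genes_spanning(contig, pos)
            strands = {index.representatives[g].strand for g in gids}
            if len(strands) != 1:
                continue  # no gene, or ambiguous strand
            strand = strands.pop()
            ref = genome.base(contig, pos)
            if (strand == "+" and ref != "A") or (strand == "-" and ref != "T"):
                continue
            tally = {"A": 0, "C": 0, "G": 0, "T": 0}
            for pr in col.pileups:
                if pr.is_del or pr.is_refskip or pr.query_position is None:
                    continue
                b = pr.alignment.query_sequence[pr.query_position].upper()
                if b in tally:
                    tally[b] += 1
            if sum(tally.values()) == 0:
                continue
            rows.append((contig, pos, ref, strand, tally["A"], tally["C"], tally["G"], tally["T"], sample_id))
    return pd.DataFrame(rows, columns=["contig", "pos0", "ref", "strand", "nA", "nC", "nG", "nT", "sample_id"])
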