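"""Synthetic genomes, edit-bearing pileups, and count matrices with planted truth.

The generator emulates the structure of an RBP-ADARcd editing experiment:
duplicate fusion-expressing RNA samples plus one unedited control, and
control-vs-knockdown count matrices for the stability arm. Every random
stream derives from ``numpy.random.default_rng([seed, stream_id])`` (PCG64
seeded through SeedSequence) so outputs are byte-identical across runs;
stream ids are 0 for the reference, 100+i for pileup sample i, and 200 for
count matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .refmodel import GenomeSeq, TranscriptModel, revcomp

REF_STREAM = 0
PILEUP_STREAM = 100
COUNT_STREAM = 200

MOTIF_DNA = "TATATATA"  # UAUAUAUA on the RNA strand

SITECOUNT_COLUMNS = ["contig", "pos0", "ref", "strand", "nA", "nC", "nG", "nT", "sample_id"]


@dataclass
class SimConfig:
    """Parameters of the synthetic reference + pileup experiment.

    Defaults describe a small transcriptome with duplicate editing
    replicates: ~150x mean coverage (negative-binomial, size 10, mimicking
    RNA-seq overdispersion), planted edit fractions of 0.3-0.7, a 0.1%
    per-base sequencing error (post base-quality filtering), and edits
    placed across 5'UTR/CDS/3'UTR in the proportions observed for a
    3'UTR-biased RBP.
    """

    n_genes: int = 60
    utr5_range: tuple[int, int] = (50, 150)
    cds_range: tuple[int, int] = (300, 900)
    utr3_range: tuple[int, int] = (100, 300)
    intron_prob: float = 0.5
    intron_len_range: tuple[int, int] = (60, 200)
    n_target_genes: int = 12
    edits_per_target: int = 3
    edit_fraction_range: tuple[float, float] = (0.3, 0.7)
    coverage_mean: float = 150.0
    coverage_nb_size: float = 10.0
    seq_error_rate: float = 0.001
    motif_planting_rate: float = 0.8
    n_replicates: int = 2
    seed: int = 0
    region_weights: dict = field(
        default_factory=lambda: {"utr5": 0.04, "cds": 0.267, "utr3": 0.693}
    )
    spacer_len: int = 100
    contig_name: str = "synth1"

    def validate(self) -> None:
        if not 0 <= self.motif_planting_rate <= 1:
            raise ValueError("motif_planting_rate must be in [0,1]")
        if not 0 <= self.seq_error_rate <= 1:
            raise ValueError("seq_error_rate must be in [0,1]")
        lo, hi = self.edit_fraction_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("edit_fraction_range must lie in (0,1]")
        if self.n_target_genes > self.n_genes:
            raise ValueError("more target genes than genes")
        if self.utr3_range[0] < len(MOTIF_DNA):
            raise ValueError(
                f"utr3 range shorter than planted motif ({len(MOTIF_DNA)} nt)"
            )
        if self.coverage_mean <= 0 or self.coverage_nb_size <= 0:
            raise ValueError("coverage parameters must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least one experiment replicate")
        w = sum(self.region_weights.values())
        if w <= 0 or any(v < 0 for v in self.region_weights.values()):
            raise ValueError("region_weights must be non-negative and sum > 0")


@dataclass
class PlantedEdit:
    contig: str
    pos0: int
    gene_id: str
    strand: str
    true_fraction: float
    region: str
    mrna_pos: int


@dataclass
class PlantedTruth:
    """Ground truth of a simulation run."""

    edits: list[PlantedEdit]
    target_genes: list[str]
    motif_positions: list[dict]  # gene_id, mrna_start (3'UTR-relative abs mRNA coord)
    stab_log2fc: dict[str, float] = field(default_factory=dict)

    @property
    def edit_positions(self) -> set[tuple[str, int]]:
        return {(e.contig, e.pos0) for e in self.edits}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "edits": [asdict(e) for e in self.edits],
                    "target_genes": self.target_genes,
                    "motif_positions": self.motif_positions,
                    "stab_log2fc": self.stab_log2fc,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            edits=[PlantedEdit(**e) for e in d["edits"]],
            target_genes=d["target_genes"],
            motif_positions=d["motif_positions"],
            stab_log2fc=d.get("stab_log2fc", {}),
        )


def _rand_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def simulate_reference(cfg: SimConfig):
    """Build a synthetic genome, one transcript per gene, and planted truth.

    Returns (GenomeSeq, list[TranscriptModel], PlantedTruth). Deterministic
    under cfg.seed.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, REF_STREAM])

    target_idx = set(
        rng.choice(cfg.n_genes, size=cfg.n_target_genes, replace=False).tolist()
    )
    region_names = sorted(cfg.region_weights)
    wsum = sum(cfg.region_weights.values())
    region_p = [cfg.region_weights[r] / wsum for r in region_names]

    pieces: list[str] = []
    offset = 0
    models: list[TranscriptModel] = []
    edits: list[PlantedEdit] = []
    motif_positions: list[dict] = []

    for gi in range(cfg.n_genes):
        gid = f"g{gi:04d}"
        u5 = int(rng.integers(cfg.utr5_range[0], cfg.utr5_range[1] + 1))
        cds = int(rng.integers(cfg.cds_range[0], cfg.cds_range[1] + 1))
        utr3 = int(rng.integers(cfg.utr3_range[0], cfg.utr3_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        mrna = list(_rand_seq(rng, u5 + cds + utr3))
        L = len(mrna)

        is_target = gi in target_idx
        motif_mpos = None
        if is_target and rng.random() < cfg.motif_planting_rate:
            m0 = u5 + cds
            motif_mpos = m0 + int(rng.integers(0, utr3 - len(MOTIF_DNA) + 1))
            mrna[motif_mpos : motif_mpos + len(MOTIF_DNA)] = MOTIF_DNA
            motif_positions.append({"gene_id": gid, "mrna_start": motif_mpos})
        mrna = "".join(mrna)

        # optional single intron inside the CDS
        has_intron = rng.random() < cfg.intron_prob and cds > 40
        if has_intron:
            split = u5 + int(rng.integers(10, cds - 10))
            intron = _rand_seq(rng, int(rng.integers(*cfg.intron_len_range)))
            pre_exons = [(0, split), (split + len(intron), split + len(intron) + (L - split))]
            pre_seq = mrna[:split] + intron + mrna[split:]
        else:
            pre_exons = [(0, L)]
            pre_seq = mrna

        plen = len(pre_seq)
        if strand == "+":
            gseq = pre_seq
            exons = pre_exons
        else:
            gseq = revcomp(pre_seq)
            exons = sorted((plen - b, plen - a) for a, b in pre_exons)

        exons_abs = [(a + offset, b + offset) for a, b in exons]
        t = TranscriptModel(
            transcript_id=f"{gid}.t1", gene_id=gid, contig=cfg.contig_name,
            strand=strand, exons=exons_abs, cds_span=None,
        )
        g1 = t.mrna_to_genomic(u5)
        g2 = t.mrna_to_genomic(u5 + cds - 1)
        t.cds_span = (min(g1, g2), max(g1, g2) + 1)
        models.append(t)

        if is_target:
            bounds = {"utr5": (0, u5), "cds": (u5, u5 + cds), "utr3": (u5 + cds, L)}
            used: set[int] = set()
            for _ in range(cfg.edits_per_target):
                region = region_names[int(rng.choice(len(region_names), p=region_p))]
                lo, hi = bounds[region]
                if region == "utr3" and motif_mpos is not None:
                    wlo = max(lo, motif_mpos - 40)
                    whi = min(hi, motif_mpos + len(MOTIF_DNA) + 40)
                    cand = [i for i in range(wlo, whi) if mrna[i] == "A" and i not in used]
                    if not cand:
                        cand = [i for i in range(lo, hi) if mrna[i] == "A" and i not in used]
                else:
                    cand = [i for i in range(lo, hi) if mrna[i] == "A" and i not in used]
                if not cand:
                    continue
                mpos = int(cand[rng.integers(len(cand))])
                used.add(mpos)
                frac = float(rng.uniform(*cfg.edit_fraction_range))
                edits.append(
                    PlantedEdit(
                        contig=cfg.contig_name, pos0=t.mrna_to_genomic(mpos),
                        gene_id=gid, strand=strand, true_fraction=frac,
                        region={"utr5": "5UTR", "cds": "CDS", "utr3": "3UTR"}[region],
                        mrna_pos=mpos,
                    )
                )

        pieces.append(gseq)
        pieces.append(_rand_seq(rng, cfg.spacer_len))
        offset += plen + cfg.spacer_len

    genome = GenomeSeq({cfg.contig_name: "".join(pieces)})
    truth = PlantedTruth(
        edits=edits,
        target_genes=sorted(f"g{i:04d}" for i in target_idx),
        motif_positions=motif_positions,
    )
    return genome, models, truth


def sense_a_positions(genome: GenomeSeq, models: list[TranscriptModel]) -> pd.DataFrame:
    """All exonic positions whose sense-strand base is A, one row each.

    Columns: contig, pos0, ref (genomic base: A on +, T on -), strand,
    gene_id, mrna_pos. Sorted by (contig, pos0).
    """
    rows = []
    for t in models:
        seq = t.spliced_seq(genome)
        for mpos, base in enumerate(seq):
            if base == "A":
                g = t.mrna_to_genomic(mpos)
                rows.append(
                    (t.contig, g, "A" if t.strand == "+" else "T", t.strand, t.gene_id, mpos)
                )
    df = pd.DataFrame(rows, columns=["contig", "pos0", "ref", "strand", "gene_id", "mrna_pos"])
    return df.sort_values(["contig", "pos0"], kind="mergesort").reset_index(drop=True)


def simulate_tribe_pileups(
    genome: GenomeSeq, models: list[TranscriptModel], truth: PlantedTruth, cfg: SimConfig
) -> dict[str, pd.DataFrame]:
    """Per-sample SiteCount tables for n_replicates experiments + a control.

    At a planted site with fraction f and drawn coverage n, the edited-base
    count is Binomial(n, f); the remaining reads acquire errors at
    seq_error_rate, split over the three non-reference bases in alphabetical
    order. The control carries no planted edits. Per-sample draws come from
    stream PILEUP_STREAM + sample_index, positions in (contig, pos0) order:
    coverage first, then edited counts, then the three error binomials.
    """
    cfg.validate()
    pos = sense_a_positions(genome, models)
    n = len(pos)
    planted = {(e.contig, e.pos0): e.true_fraction for e in truth.edits}
    frac = pos.apply(lambda r: planted.get((r.contig, r.pos0), 0.0), axis=1).to_numpy()

    r = cfg.coverage_nb_size
    p_nb = r / (r + cfg.coverage_mean)
    e3 = cfg.seq_error_rate / 3.0

    samples = [f"rep{i + 1}" for i in range(cfg.n_replicates)] + ["control"]
    out: dict[str, pd.DataFrame] = {}
    for k, sample in enumerate(samples):
        rng = np.random.default_rng([cfg.seed, PILEUP_STREAM + k])
        cov = rng.negative_binomial(r, p_nb, n)
        f = frac if sample != "control" else np.zeros(n)
        edited = rng.binomial(cov, f)
        rem = cov - edited
        err = np.zeros((3, n), dtype=np.int64)
        for j in range(3):
            # per-base error rate e/3 for each alternative base
            pj = e3 / (1.0 - j * e3) if e3 > 0 else 0.0
            err[j] = rng.binomial(rem, min(pj, 1.0))
            rem = rem - err[j]
        # tallies: ref base gets the remainder; the edited base (G on +,
        # C on -) gets `edited` on top of its error share
        df = pos[["contig", "pos0", "ref", "strand"]].copy()
        plus = (pos["strand"] == "+").to_numpy()
        counts = {b: np.zeros(n, dtype=np.int64) for b in "ACGT"}
        # alternative bases in alphabetical order per strand
        for idx, strand_mask, ref_b in ((0, plus, "A"), (1, ~plus, "T")):
            alts = [b for b in "ACGT" if b != ref_b]
            for j, b in enumerate(alts):
                counts[b][strand_mask] += err[j][strand_mask]
            counts[ref_b][strand_mask] += rem[strand_mask]
        counts["G"][plus] += edited[plus]
        counts["C"][~plus] += edited[~plus]
        for b in "ACGT":
            df[f"n{b}"] = counts[b]
        df["sample_id"] = sample
        out[sample] = df
    return out


@dataclass
class CountSimConfig:
    """Control-vs-knockdown count matrix simulation.

    Exonic counts are negative-binomial with per-gene means spread
    lognormally around ``mean_expression``; the knockdown effect
    (``kd_log2fc``, negative = target destabilized without the RBP) scales
    target genes' exonic means only, unless ``intron_log2fc`` models a
    transcriptional change. Intronic means are ``intron_mean_fraction`` of
    exonic means.
    """

    mean_expression: float = 300.0
    mean_lognorm_sigma: float = 0.8
    dispersion: float = 0.05
    n_per_condition: int = 3
    kd_log2fc: float = -1.0
    intron_log2fc: float = 0.0
    intron_mean_fraction: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.mean_expression <= 0:
            raise ValueError("mean expression must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_per_condition < 1:
            raise ValueError("need at least one sample per condition")
        if self.intron_mean_fraction <= 0:
            raise ValueError("intron mean fraction must be positive")


def _nb_draw(rng, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def simulate_counts(
    gene_ids: list[str], target_genes: list[str], cfg: CountSimConfig, truth: PlantedTruth | None = None
):
    """Exonic + intronic count matrices for control vs. knockdown.

    Returns (exonic DataFrame, intronic DataFrame, condition labels);
    matrices are genes x samples with columns ctrl_1.. then kd_1.. .
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, COUNT_STREAM])
    g = len(gene_ids)
    targets = set(target_genes)
    base = cfg.mean_expression * rng.lognormal(
        -0.5 * cfg.mean_lognorm_sigma**2, cfg.mean_lognorm_sigma, g
    )
    is_t = np.array([gid in targets for gid in gene_ids])
    exo_kd = base * np.where(is_t, 2.0**cfg.kd_log2fc, 1.0)
    intron_base = base * cfg.intron_mean_fraction
    intron_kd = intron_base * np.where(is_t, 2.0**cfg.intron_log2fc, 1.0)

    cols, labels = [], []
    exo, intr = {}, {}
    for i in range(cfg.n_per_condition):
        c = f"ctrl_{i + 1}"
        exo[c] = _nb_draw(rng, base, cfg.dispersion)
        intr[c] = _nb_draw(rng, intron_base, cfg.dispersion)
        cols.append(c)
        labels.append("control")
    for i in range(cfg.n_per_condition):
        c = f"kd_{i + 1}"
        exo[c] = _nb_draw(rng, exo_kd, cfg.dispersion)
        intr[c] = _nb_draw(rng, intron_kd, cfg.dispersion)
        cols.append(c)
        labels.append("knockdown")

    exo_df = pd.DataFrame(exo, index=gene_ids)[cols]
    intr_df = pd.DataFrame(intr, index=gene_ids)[cols]
    if truth is not None:
        truth.stab_log2fc = {gid: (cfg.kd_log2fc if gid in targets else 0.0) for gid in gene_ids}
    return exo_df, intr_df, labels


def write_sitecounts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_sitecounts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sam(
    path, genome: GenomeSeq, models: list[TranscriptModel], truth: PlantedTruth,
    depth: int = 30, read_len: int = 50, edited: bool = True,
) -> None:
    """Emit a minimal SAM of exon-tiling, ungapped reads.

    Reads tile each exon at uniform depth; at planted edit sites a
    deterministic round(f*depth) of overlapping reads carry the edited base
    (G on the + genomic strand, C on -). Intended for integration tests of
    the alignment-pileup path, not as a read-level simulator.
    """
    planted = {(e.contig, e.pos0): e for e in truth.edits} if edited else {}
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        qn = 0
        for t in models:
            contig_seq = genome.contigs[t.contig]
            for a, b in t.exons:
                if b - a < read_len:
                    continue
                step = max(1, read_len // depth)
                starts = list(range(a, b - read_len + 1, step))
                for si, s in enumerate(starts):
                    bases = list(contig_seq[s : s + read_len])
                    for off in range(read_len):
                        e = planted.get((t.contig, s + off))
                        if e is None:
                            continue
                        # stripe edited reads deterministically by tiling rank
                        n_over = sum(1 for x in starts if x <= s + off < x + read_len)
                        rank = sum(1 for x in starts[:si] if x <= s + off < x + read_len)
                        if rank < round(e.true_fraction * n_over):
                            bases[off] = "G" if e.strand == "+" else "C"
                    qn += 1
                    fh.write(
                        f"r{qn}\t0\t{t.contig}\t{s + 1}\t60\t{read_len}M\t*\t0\t0\t"
                        f"{''.join(bases)}\t{'I' * read_len}\n"
                    )
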