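"""Edit-window extraction, k-mer enrichment, and AU-rich-element scoring.

Windows around edit sites are taken in mRNA coordinates, so they are
intronless by construction and truncated at transcript ends. The k-mer
enrichment statistic replaces external motif discovery with a self-contained
z-score against a dinucleotide-preserving shuffle null. The ARE score is a
pentamer-based AU-richness measure of a 3'UTR: one point per AUUUA
occurrence (overlaps counted), clustering bonuses for nearby pentamer pairs,
and a context bonus for pentamers flanked by A/U on both sides.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .refmodel import NOT_EXONIC, GenomeSeq, GeneModelIndex, TranscriptModel

log = logging.getLogger(__name__)

PENTAMER = "AUUUA"
AU = {"A", "U"}


@dataclass
class MotifWindow:
    gene_id: str
    mrna_pos: int  # edit position, mRNA coordinates
    seq: str  # RNA alphabet, <= 2*flank+1 nt


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def extract_edit_windows(
    annots: pd.DataFrame, index: GeneModelIndex, genome: GenomeSeq, flank: int = 100
) -> list[MotifWindow]:
    """mRNA-coordinate windows of +-flank nt around exonic edits.

    Windows are spliced (exon junctions concatenated) and truncated at
    transcript ends without padding; non-exonic edits are skipped with a
    warning. DNA T is transliterated to U.
    """
    seqs: dict[str, str] = {}
    out = []
    n_skipped = 0
    for _, r in annots.iterrows():
        mpos = int(r["mrna_pos"])
        gid = r["gene_id"]
        if mpos == NOT_EXONIC or not gid:
            n_skipped += 1
            continue
        if gid not in seqs:
            seqs[gid] = _to_rna(index.representatives[gid].spliced_seq(genome))
        s = seqs[gid]
        lo, hi = max(0, mpos - flank), min(len(s), mpos + flank + 1)
        out.append(MotifWindow(gene_id=gid, mrna_pos=mpos, seq=s[lo:hi]))
    if n_skipped:
        log.warning("skipped %d non-exonic edits during window extraction", n_skipped)
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle preserving exact dinucleotide composition."""
    if len(seq) <= 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    first, last = seq[0], seq[-1]
    vertices = list(edges)
    # choose one outgoing "last edge" per vertex (except the sink) such that
    # following last edges always reaches the sink: an arborescence into `last`
    while True:
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        ok = True
        for v in last_edge:
            seen, u = set(), v
            while u != last and u not in seen:
                seen.add(u)
                u = last_edge[u]
            if u != last:
                ok = False
                break
        if ok:
            break
    walk_lists: dict[str, list[str]] = {}
    for v in vertices:
        lst = list(edges[v])
        if v != last:
            lst.remove(last_edge[v])
        lst = [lst[i] for i in rng.permutation(len(lst))]
        if v != last:
            lst.append(last_edge[v])
        walk_lists[v] = lst
    res, ptr, u = [first], defaultdict(int), first
    while True:
        lst = walk_lists.get(u)
        if lst is None or ptr[u] >= len(lst):
            break
        nxt = lst[ptr[u]]
        ptr[u] += 1
        res.append(nxt)
        u = nxt
    return "".join(res)


def _count_kmers(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def kmer_enrichment(
    windows: list[MotifWindow], k: int = 8, n_shuffles: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Rank k-mers against a per-window dinucleotide-shuffle null.

    Only k-mers observed in the real windows are scored. For each, z =
    (obs - null mean)/sd with a Poisson-style variance floor of
    (mean + 1)/n_shuffles so that k-mers never regenerated by the shuffle
    cannot reach infinite scores, plus an add-one empirical p. The ranking
    is by empirical p, ties broken by observed count then lexicographically
    (the empirical p is floor-limited, so the count decides among clear
    hits; this keeps one-off k-mers with degenerate null variance from
    outranking abundant motifs). The returned frame carries a family-wise
    empirical p for the top statistic in ``df.attrs["top_fwer_p"]``,
    computed by comparing the observed maximum z against the per-round
    maxima (Westfall-Young style), which is the number to consult before
    trusting the top hit.
    """
    if n_shuffles == 0:
        raise ValueError("null model required: n_shuffles must be >= 1")
    if len(windows) < 5:
        raise ValueError(f"need >= 5 windows for enrichment, got {len(windows)}")
    usable = [w.seq for w in windows if len(w.seq) >= k]
    if not usable:
        raise ValueError(f"all windows shorter than k={k}")

    obs = Counter()
    for s in usable:
        obs.update(_count_kmers(s, k))
    kmers = sorted(obs)
    kidx = {m: i for i, m in enumerate(kmers)}

    # pass 1: accumulate null moments over the full k-mer universe (kmers
    # the shuffle generates count too, else the max statistic is biased)
    rng = np.random.default_rng(seed)
    sum_c: dict[str, float] = defaultdict(float)
    sum_sq: dict[str, float] = defaultdict(float)
    for _ in range(n_shuffles):
        round_counts = Counter()
        for s in usable:
            round_counts.update(_count_kmers(dinucleotide_shuffle(s, rng), k))
        for m, c in round_counts.items():
            sum_c[m] += c
            sum_sq[m] += c * c

    def _mean_sd(m: str) -> tuple[float, float]:
        mu = sum_c[m] / n_shuffles
        if n_shuffles > 1:
            var = max(0.0, (sum_sq[m] - n_shuffles * mu * mu) / (n_shuffles - 1))
        else:
            var = 0.0
        return mu, np.sqrt(max(var, (mu + 1.0) / n_shuffles))

    def _loo_z(m: str, c: float) -> float:
        """z of count c in one round against the other rounds (the observed
        data are scored against all rounds, so rounds must leave themselves
        out to be exchangeable with it)."""
        n1 = n_shuffles - 1
        if n1 == 0:
            mu, sd = _mean_sd(m)
            return (c - mu) / sd
        mu = (sum_c[m] - c) / n1
        if n1 > 1:
            var = max(0.0, (sum_sq[m] - c * c - n1 * mu * mu) / (n1 - 1))
        else:
            var = 0.0
        return (c - mu) / np.sqrt(max(var, (mu + 1.0) / n1))

    # pass 2: identical shuffles (same seed) give per-round counts for the
    # observed k-mers and the per-round maximum z for the family-wise p
    rng = np.random.default_rng(seed)
    null = np.zeros((n_shuffles, len(kmers)))
    null_max_z = np.full(n_shuffles, -np.inf)
    for r in range(n_shuffles):
        round_counts = Counter()
        for s in usable:
            round_counts.update(_count_kmers(dinucleotide_shuffle(s, rng), k))
        for m, c in round_counts.items():
            i = kidx.get(m)
            if i is not None:
                null[r, i] = c
            null_max_z[r] = max(null_max_z[r], _loo_z(m, c))

    stats = [_mean_sd(m) for m in kmers]
    mean = np.array([s[0] for s in stats])
    sd_eff = np.array([s[1] for s in stats])
    obs_v = np.array([obs[m] for m in kmers], dtype=float)
    z = (obs_v - mean) / sd_eff
    emp_p = (1 + (null >= obs_v[None, :]).sum(axis=0)) / (n_shuffles + 1)
    top_fwer_p = (1 + (null_max_z >= z.max()).sum()) / (n_shuffles + 1)
    df = pd.DataFrame(
        {"kmer": kmers, "observed": obs_v.astype(int), "expected": mean, "z": z, "emp_p": emp_p}
    )
    df = df.sort_values(
        ["emp_p", "observed", "kmer"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.attrs["top_fwer_p"] = float(top_fwer_p)
    return df


@dataclass
class AREScoreParams:
    """Weights of the pentamer-based AU-richness score."""

    pentamer_point: float = 1.0  # per AUUUA occurrence, overlaps counted
    doublet_bonus_near: float = 1.5  # consecutive pentamer starts <= 10 nt apart
    doublet_bonus_far: float = 0.75  # 11-20 nt apart
    au_block_bonus: float = 0.5  # pentamer flanked by A/U on both sides
    min_utr_len: int = 10  # sequences <= this length are not scored

    def validate(self) -> None:
        if min(self.pentamer_point, self.doublet_bonus_near, self.doublet_bonus_far,
               self.au_block_bonus) < 0:
            raise ValueError("ARE score weights must be >= 0")


@dataclass
class AREScoreResult:
    gene_id: str
    transcript_id: str
    score: float
    n_pentamers: int
    n_near_doublets: int
    n_far_doublets: int
    n_au_flanked: int


def are_score(
    seq: str, params: AREScoreParams | None = None, gene_id: str = "", transcript_id: str = ""
) -> AREScoreResult | None:
    """Score a 3'UTR for AU-rich elements; None when too short to score.

    Pentamer starts are found by positional scan (overlaps counted);
    consecutive start pairs within 10 nt earn the near bonus, within 11-20 nt
    the far bonus; a pentamer whose immediate neighbors on both sides exist
    and are A/U earns the context bonus.
    """
    params = params or AREScoreParams()
    params.validate()
    s = _to_rna(seq)
    if set(s) - set("ACGUN"):
        raise ValueError("sequence must be ACGU/T (N allowed)")
    if len(s) <= params.min_utr_len:
        return None
    starts = [i for i in range(len(s) - 4) if s[i : i + 5] == PENTAMER]
    n_near = sum(1 for a, b in zip(starts, starts[1:]) if b - a <= 10)
    n_far = sum(1 for a, b in zip(starts, starts[1:]) if 11 <= b - a <= 20)
    n_flanked = sum(
        1 for i in starts if i > 0 and i + 5 < len(s) and s[i - 1] in AU and s[i + 5] in AU
    )
    score = (
        params.pentamer_point * len(starts)
        + params.doublet_bonus_near * n_near
        + params.doublet_bonus_far * n_far
        + params.au_block_bonus * n_flanked
    )
    return AREScoreResult(
        gene_id=gene_id, transcript_id=transcript_id, score=score,
        n_pentamers=len(starts), n_near_doublets=n_near, n_far_doublets=n_far,
        n_au_flanked=n_flanked,
    )


def utr3_seq(t: TranscriptModel, genome: GenomeSeq) -> str | None:
    """The 3'UTR sequence (RNA alphabet) of a coding transcript, else None."""
    if not t.is_coding:
        return None
    u5, cds, u3 = t.utr_cds_segments()
    if u3 == 0:
        return None
    return _to_rna(t.spliced_seq(genome)[u5 + cds :])


def gene_are_scores(
    models: list[TranscriptModel], genome: GenomeSeq, params: AREScoreParams | None = None
) -> dict[str, AREScoreResult]:
    """Per-gene ARE score: the highest-scoring isoform's 3'UTR.

    Only 3'UTRs longer than min_utr_len are scored; genes with no qualifying
    3'UTR are absent from the result. Score ties break to the smaller
    transcript_id.
    """
    params = params or AREScoreParams()
    best: dict[str, AREScoreResult] = {}
    for t in models:
        seq = utr3_seq(t, genome)
        if seq is None:
            continue
        res = are_score(seq, params, gene_id=t.gene_id, transcript_id=t.transcript_id)
        if res is None:
            continue
        cur = best.get(t.gene_id)
        if cur is None or (res.score, cur.transcript_id) > (cur.score, res.transcript_id):
            best[t.gene_id] = res
    return best
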