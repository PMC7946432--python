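"""Normalization, differential classification, and target-stratified stability statistics.

Counts are normalized by median-of-ratios size factors. Per-gene p-values
come from a two-sample permutation test on normalized log counts —
exhaustive over group assignments when few, Monte Carlo otherwise — with an
inclusive threshold (padj <= alpha), the calibrated convention for discrete
permutation p-values. Target-vs-background class proportions are compared
with a Pearson chi-square, bootstrapped with replacement, and per-bootstrap
p-values combined by Fisher's method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CLASSES = ("down", "unchanged", "up")


def median_of_ratios(counts: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Size factors and normalized matrix via the median-of-ratios method.

    The reference is the per-gene geometric mean across samples, using only
    genes with nonzero counts in every sample; each sample's size factor is
    the median ratio of its counts to the reference.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("cannot form reference: no gene has nonzero counts in every sample")
    logc = np.log(counts[allpos].astype(float))
    loggeo = logc.mean(axis=1)
    sf = np.exp(logc.sub(loggeo, axis=0).median(axis=0))
    norm = counts / sf
    # by construction: per-sample median ratio of normalized counts to the
    # reference (geometric means of the raw counts) is exactly 1
    check = np.log(norm[allpos]).sub(loggeo, axis=0).median(axis=0)
    assert np.allclose(check, 0.0, atol=1e-9), "median-of-ratios self-check failed"
    return sf, norm


def _mean_diff(L: np.ndarray, kd, ctrl) -> np.ndarray:
    """Group mean difference of log counts, vectorized over genes."""
    kd, ctrl = np.asarray(kd), np.asarray(ctrl)
    return L[:, kd].mean(axis=1) - L[:, ctrl].mean(axis=1)


def classify_de(
    counts: pd.DataFrame,
    labels: list[str],
    alpha: float = 0.05,
    lfc_floor: float = 0.0,
    seed: int = 0,
    padj_mode: str = "raw",
    max_exhaustive: int = 1000,
    n_mc: int = 10_000,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene knockdown-vs-control classification into down/unchanged/up.

    log2fc = log2 of the ratio of mean normalized counts (knockdown over
    control, with a pseudocount). The test statistic is the group mean
    difference of log2(normalized + pseudocount); its null distribution is
    built from group-label permutations (exhaustive when few arrangements,
    Monte Carlo otherwise) and pooled across genes, excluding the observed
    assignment and its mirror, which do not break the group structure.
    Pooling is what makes small designs testable: with 3v3 replicates a
    per-gene exhaustive two-sided permutation p can never fall below
    2/20 = 0.1, whereas the pooled null has genes x permutations
    resolution; the log transform is variance-stabilizing for
    overdispersed counts, which is what makes the statistic comparable
    across genes. padj_mode is "raw" (padj = p, mirroring a plain p<alpha
    report) or "bh".
    """
    lab = np.asarray(labels)
    conds = sorted(set(lab))
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions, got {conds}")
    ctrl_name = "control" if "control" in conds else conds[0]
    kd_name = [c for c in conds if c != ctrl_name][0]
    kd_idx = np.where(lab == kd_name)[0]
    ctrl_idx = np.where(lab == ctrl_name)[0]
    if min(len(kd_idx), len(ctrl_idx)) < 2:
        raise ValueError("no within-condition variance: need >= 2 replicates per condition")
    if padj_mode not in ("raw", "bh"):
        raise ValueError("padj_mode must be 'raw' or 'bh'")

    sf, norm = median_of_ratios(counts)
    L = np.log2(norm.to_numpy(dtype=float) + pseudocount)
    rng = np.random.default_rng(seed)
    n_samples, n_kd = counts.shape[1], len(kd_idx)
    from math import comb

    t_obs = _mean_diff(L, kd_idx, ctrl_idx)
    obs_set, obs_mirror = set(kd_idx.tolist()), set(ctrl_idx.tolist())
    null_parts = []
    if comb(n_samples, n_kd) <= max_exhaustive:
        for kd in combinations(range(n_samples), n_kd):
            if set(kd) in (obs_set, obs_mirror):
                continue
            ctrl = np.setdiff1d(np.arange(n_samples), kd)
            null_parts.append(_mean_diff(L, np.array(kd), ctrl))
    else:
        # enough label permutations for >= n_mc pooled null values
        n_perms = max(100, -(-n_mc // len(L)))
        while len(null_parts) < n_perms:
            perm = rng.permutation(n_samples)
            if set(perm[:n_kd].tolist()) in (obs_set, obs_mirror):
                continue
            null_parts.append(_mean_diff(L, perm[:n_kd], perm[n_kd:]))
    if not null_parts:
        raise ValueError("no permutations distinct from the observed assignment")
    null = np.abs(np.concatenate(null_parts))
    null.sort()
    # pooled empirical p with add-one correction
    ge = len(null) - np.searchsorted(null, np.abs(t_obs) - 1e-12, side="left")
    p = (1 + ge) / (1 + len(null))

    padj = p if padj_mode == "raw" else stats.false_discovery_control(p, method="bh")
    mean_kd = norm.iloc[:, kd_idx].mean(axis=1).to_numpy()
    mean_ctrl = norm.iloc[:, ctrl_idx].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_kd + pseudocount) / (mean_ctrl + pseudocount))
    cls = np.where(
        (padj <= alpha) & (log2fc < -lfc_floor), "down",
        np.where((padj <= alpha) & (log2fc > lfc_floor), "up", "unchanged"),
    )
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "base_mean": norm.mean(axis=1).to_numpy(),
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "cls": cls,
        }
    ).set_index("gene_id", drop=False)


def _contingency(de: pd.DataFrame, targets: set) -> pd.DataFrame:
    is_t = de["gene_id"].isin(targets)
    tab = pd.DataFrame(
        {
            "target": [int(((de["cls"] == c) & is_t).sum()) for c in CLASSES],
            "background": [int(((de["cls"] == c) & ~is_t).sum()) for c in CLASSES],
        },
        index=list(CLASSES),
    )
    return tab


def _chi2_on_table(tab: pd.DataFrame) -> tuple[float, float, bool]:
    """Pearson chi-square dropping all-zero class rows; (stat, p, low_expected)."""
    t = tab.loc[tab.sum(axis=1) > 0]
    if t.shape[0] < 2 or (t.sum(axis=0) == 0).any():
        return 0.0, 1.0, True
    chi2, p, _, exp = stats.chi2_contingency(t.to_numpy(), correction=False)
    return float(chi2), float(p), bool((exp < 5).any())


@dataclass
class StabilityReport:
    contingency: pd.DataFrame  # classes x {target, background}
    chi2: float
    chi2_p: float
    low_expected: bool
    target_fractions: dict
    background_fractions: dict
    bootstrap_ci: dict | None = None
    combined_p: float | None = None
    n_boot: int = 0
    seed: int = 0
    n_dropped_targets: int = 0


def stability_contingency(de: pd.DataFrame, targets) -> StabilityReport:
    """Class-by-group contingency and Pearson chi-square (df = 2)."""
    targets = set(targets)
    if not targets:
        raise ValueError("empty target set")
    known = targets & set(de["gene_id"])
    dropped = len(targets) - len(known)
    if dropped:
        log.warning("%d target genes absent from DE results; dropped", dropped)
    if not known:
        raise ValueError("no target genes among tested genes")
    tab = _contingency(de, known)
    chi2, p, low = _chi2_on_table(tab)
    nt, nb = tab["target"].sum(), tab["background"].sum()
    return StabilityReport(
        contingency=tab, chi2=chi2, chi2_p=p, low_expected=low,
        target_fractions={c: tab.loc[c, "target"] / nt for c in CLASSES},
        background_fractions={c: tab.loc[c, "background"] / max(nb, 1) for c in CLASSES},
        n_dropped_targets=dropped,
    )


def bootstrap_class_fractions(
    de: pd.DataFrame, targets, n_boot: int = 1000, seed: int = 0
) -> dict:
    """Bootstrap (with replacement) of class fractions and chi-square p-values.

    Targets and background are resampled independently at their observed
    sizes, n_boot times; per-class/per-group fraction CIs are the 2.5/97.5
    percentiles, and per-bootstrap chi-square p-values are combined with
    Fisher's method (global combination).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    targets = set(targets) & set(de["gene_id"])
    cls = de["cls"]
    t_cls = cls[de["gene_id"].isin(targets)].to_numpy()
    b_cls = cls[~de["gene_id"].isin(targets)].to_numpy()
    rng = np.random.default_rng(seed)
    fracs = {g: {c: np.empty(n_boot) for c in CLASSES} for g in ("target", "background")}
    ps = np.empty(n_boot)
    for i in range(n_boot):
        ts = t_cls[rng.integers(len(t_cls), size=len(t_cls))]
        bs = b_cls[rng.integers(len(b_cls), size=len(b_cls))]
        tab = pd.DataFrame(
            {
                "target": [(ts == c).sum() for c in CLASSES],
                "background": [(bs == c).sum() for c in CLASSES],
            },
            index=list(CLASSES),
        )
        for c in CLASSES:
            fracs["target"][c][i] = tab.loc[c, "target"] / len(ts)
            fracs["background"][c][i] = tab.loc[c, "background"] / len(bs)
        _, ps[i], _ = _chi2_on_table(tab)
    ci = {
        g: {c: tuple(np.percentile(fracs[g][c], [2.5, 97.5])) for c in CLASSES}
        for g in fracs
    }
    return {
        "ci": ci,
        "fractions": fracs,
        "chi2_ps": ps,
        "combined_p": fisher_combine(np.clip(ps, 1e-300, 1.0).tolist()),
        "n_boot": n_boot,
        "seed": seed,
    }


def fisher_combine(ps: list[float]) -> float:
    """Fisher's method: -2*sum(ln p) vs chi-square with 2k df."""
    if not len(ps):
        raise ValueError("empty p-value list")
    ps = np.asarray(ps, dtype=float)
    if (ps <= 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    X = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(X, 2 * len(ps)))


@dataclass
class AREStratification:
    target_vs_all_p: float | None
    target_median: float
    all_median: float
    down_vs_notdown_p: float | None
    down_median: float | None
    notdown_median: float | None
    score_lfc_rho: float | None
    n_targets_scored: int


def _ranksum(a, b) -> float | None:
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        return None
    if np.unique(np.concatenate([a, b])).size == 1:
        return 1.0  # constant scores: uninformative
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def are_vs_change(scores: dict, de: pd.DataFrame, targets) -> AREStratification:
    """Stratify ARE scores by target status and knockdown response.

    (a) targets vs. all tested genes (rank-sum); (b) among targets, down vs.
    not-down (rank-sum) plus the Spearman correlation between score and
    -log2fc. ``scores`` maps gene -> AREScoreResult or a bare number.
    """
    val = {g: (s.score if hasattr(s, "score") else float(s)) for g, s in scores.items()}
    de_scored = de[de["gene_id"].isin(val)]
    targets = set(targets)
    t_rows = de_scored[de_scored["gene_id"].isin(targets)]
    if len(t_rows) < 5:
        raise ValueError(f"need >= 5 targets with ARE scores, got {len(t_rows)}")
    t_scores = t_rows["gene_id"].map(val).to_numpy(float)
    all_scores = de_scored["gene_id"].map(val).to_numpy(float)

    if len(t_rows) == len(de_scored):
        log.warning("targets cover all tested genes; target-vs-transcriptome comparison skipped")
        p_all = None
    else:
        p_all = _ranksum(t_scores, all_scores)

    down = t_rows[t_rows["cls"] == "down"]
    notdown = t_rows[t_rows["cls"] != "down"]
    d_scores = down["gene_id"].map(val).to_numpy(float)
    n_scores = notdown["gene_id"].map(val).to_numpy(float)
    p_down = _ranksum(d_scores, n_scores)

    rho = None
    if t_rows["log2fc"].nunique() > 1 and len(set(t_scores)) > 1:
        rho = float(stats.spearmanr(t_scores, -t_rows["log2fc"]).statistic)
    elif len(set(t_scores)) == 1:
        rho = 0.0
    return AREStratification(
        target_vs_all_p=p_all,
        target_median=float(np.median(t_scores)),
        all_median=float(np.median(all_scores)),
        down_vs_notdown_p=p_down,
        down_median=float(np.median(d_scores)) if len(d_scores) else None,
        notdown_median=float(np.median(n_scores)) if len(n_scores) else None,
        score_lfc_rho=rho,
        n_targets_scored=len(t_rows),
    )
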