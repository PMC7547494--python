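"""Bicluster evaluation and interpretation metrics.

Recovery against planted ground truth:

* IoU — cell-set intersection over union of two rectangular blocks.
* SoBC — score of biclustering: each obtained block takes its best-matching
  truth block (max IoU); SoBC = (r / max(s, n)) * mean(best IoU), where r is
  the number of distinct truth blocks matched, s the number of truth blocks
  and n the number of obtained blocks.  SoBC = 1 only for a perfect recovery.

Internal quality, used by the threshold auto-tuner:

* SDwC — sqrt of the summed per-block mean squared deviation of the weighted
  levels w*p, divided by the block count N.  Larger SDwC means looser,
  information-richer blocks and is maximised.
* ASwC — sqrt of the summed per-block average pairwise Pearson correlation of
  weighted condition profiles (ordered pairs, factor 2/(n_k(n_k-1))), divided
  by N.  Smaller ASwC is preferred.  The inner sum can be negative for
  anti-correlated blocks, in which case the score is undefined and returned
  as NaN; callers (the tuner) must exclude such threshold pairs.  Note the
  printed form can exceed 1 (a single perfectly correlated block gives
  sqrt(2)).

Biological interpretation:

* Fisher's exact test + Benjamini-Hochberg FDR for gene-set enrichment.
* WE_score — gene-count-weighted mean of -log10 p over a block's enriched
  terms, discounted by the fraction of the block's genes in no enriched term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MatchResult",
    "EnrichmentTerm",
    "iou",
    "sobc",
    "sdwc",
    "aswc",
    "we_score",
    "fisher_enrichment",
    "bh_adjust",
    "enrichment_table",
]


def _block_axes(block):
    """Accept an LFB-like object or a (sites, conditions) pair."""
    if hasattr(block, "sites"):
        return set(block.sites), set(block.conditions)
    sites, conds = block
    return set(sites), set(conds)


def iou(obtained, truth) -> float:
    """Intersection-over-union of two rectangular blocks' cell sets."""
    u1, v1 = _block_axes(obtained)
    u2, v2 = _block_axes(truth)
    inter = len(u1 & u2) * len(v1 & v2)
    a1 = len(u1) * len(v1)
    a2 = len(u2) * len(v2)
    union = a1 + a2 - inter
    return inter / union if union else 0.0


@dataclass(frozen=True)
class MatchResult:
    """Obtained-vs-truth block matching underlying a SoBC score."""

    G: np.ndarray                 # g_d = 1 iff truth block d was matched
    best_iou: np.ndarray          # best IoU per obtained block
    matched_truth: np.ndarray     # index d of the best truth block per obtained
    iou_mean: float
    r: int                        # number of ones in G
    s: int                        # truth block count
    n: int                        # obtained block count
    sobc: float


def sobc(obtained: Sequence, truth: Sequence) -> MatchResult:
    """Score a set of obtained blocks against planted ground truth.

    Each obtained block independently takes its maximum-IoU truth block
    (ties resolve to the lower truth index); matching the same truth block
    twice does not increase r.  An empty obtained list scores 0.
    """
    truth = list(truth)
    obtained = list(obtained)
    s = len(truth)
    if s == 0:
        raise ValueError("SoBC needs at least one ground-truth block")
    n = len(obtained)
    G = np.zeros(s, dtype=int)
    best = np.zeros(n)
    matched = np.full(n, -1, dtype=int)
    for i, blk in enumerate(obtained):
        scores = np.array([iou(blk, t) for t in truth])
        d = int(np.argmax(scores))          # first (lowest-index) maximum
        best[i] = scores[d]
        matched[i] = d
        G[d] = 1
    r = int(G.sum())
    iou_mean = float(best.mean()) if n else 0.0
    score = (r / max(s, n)) * iou_mean if n else 0.0
    return MatchResult(G=G, best_iou=best, matched_truth=matched,
                       iou_mean=iou_mean, r=r, s=s, n=n, sobc=score)


def _extract(block, P, W):
    u, v = _block_axes(block)
    if not u or not v:
        raise ValueError("metric undefined for an empty block")
    ui = np.asarray(sorted(u), dtype=int)
    vi = np.asarray(sorted(v), dtype=int)
    return (W[np.ix_(ui, vi)] * P[np.ix_(ui, vi)])


def sdwc(lfbs: Sequence, P: np.ndarray, W: np.ndarray) -> float:
    """Standard deviation of weighted methylation levels within clusters."""
    lfbs = list(lfbs)
    if not lfbs:
        raise ValueError("SDwC needs at least one block")
    total = 0.0
    for blk in lfbs:
        wp = _extract(blk, P, W)
        total += np.mean((wp - wp.mean()) ** 2)
    return float(np.sqrt(total) / len(lfbs))


def aswc(lfbs: Sequence, P: np.ndarray, W: np.ndarray) -> float:
    """Average similarity (pairwise correlation of weighted columns) within clusters.

    Returns NaN when any block's correlation is undefined (a zero-variance
    weighted column, or fewer than 2 sites) or when the summed average
    correlations are negative, making the square root undefined.
    """
    lfbs = list(lfbs)
    if not lfbs:
        raise ValueError("ASwC needs at least one block")
    total = 0.0
    for blk in lfbs:
        wp = _extract(blk, P, W)
        m_k, n_k = wp.shape
        if n_k < 2:
            raise ValueError("ASwC undefined for a single-condition block")
        if m_k < 2:
            return float("nan")
        centered = wp - wp.mean(axis=0, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=0))
        if np.any(norms == 0):
            return float("nan")
        corr = (centered.T @ centered) / np.outer(norms, norms)
        off_sum = corr.sum() - np.trace(corr)     # ordered pairs a != b
        total += (2.0 / (n_k * (n_k - 1))) * off_sum
    if total < 0:
        return float("nan")
    return float(np.sqrt(total) / len(lfbs))


@dataclass(frozen=True)
class EnrichmentTerm:
    """One enriched term for a block: its p-value and in-block gene count."""

    term_id: str
    p: float
    m: int

    def score(self, base: float = 10.0) -> float:
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.term_id}: p-value {self.p} outside (0, 1]")
        return float(-np.log(self.p) / np.log(base))


def we_score(terms: Sequence[EnrichmentTerm], M: int, m_non: int, *,
             log_base: float = 10.0) -> float:
    """Weighted enrichment score of a block's enriched terms.

    Each term's -log p score is weighted by the fraction m_i / M of the
    block's M genes it covers; the denominator adds m_non / M for genes in no
    enriched term, so blocks whose genes mostly escape annotation score low.
    Scale-consistent: doubling (m_i, M, m_non) together changes nothing.
    """
    if M <= 0:
        raise ValueError(f"M must be positive, got {M}")
    terms = list(terms)
    if not terms:
        return 0.0
    for t in terms:
        if t.m > M:
            raise ValueError(f"{t.term_id}: m={t.m} exceeds block gene count M={M}")
    num = sum(t.score(log_base) * t.m / M for t in terms)
    den = sum(t.m / M for t in terms) + m_non / M
    return float(num / den)


def fisher_enrichment(lfb_genes: set, target_genes: set, universe: set):
    """Fisher's exact test of a block's genes against one target gene set.

    Returns ``(odds_ratio, p_value)`` from the 2x2 membership table over the
    universe.  The odds ratio is the sample (cross-product) estimate ad/bc; a
    0.5 continuity correction is applied to all cells only when a zero in b
    or c would make it undefined.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    lfb_genes = set(lfb_genes) & universe
    target_genes = set(target_genes) & universe
    a = len(lfb_genes & target_genes)
    b = len(lfb_genes - target_genes)
    c = len(target_genes - lfb_genes)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b == 0 or c == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), float(p)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values for a batch of tests."""
    pvalues = np.asarray(list(pvalues), dtype=float)
    if pvalues.size == 0:
        return pvalues
    return multipletests(pvalues, method="fdr_bh")[1]


def enrichment_table(lfb_gene_sets: dict, target_sets: dict, universe: set):
    """All-pairs Fisher enrichment with one BH correction across the batch.

    Returns a pandas DataFrame with columns (lfb, target, OR, p_value, FDR),
    mirroring the usual pathway-enrichment table layout.
    """
    import pandas as pd

    rows = []
    for lfb_id, genes in lfb_gene_sets.items():
        for target_id, targets in target_sets.items():
            odds, p = fisher_enrichment(genes, targets, universe)
            rows.append({"lfb": lfb_id, "target": target_id, "OR": odds, "p_value": p})
    df = pd.DataFrame(rows)
    df["FDR"] = bh_adjust(df["p_value"]) if len(df) else []
    return df
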