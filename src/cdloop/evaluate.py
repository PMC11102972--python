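"""Loop-set evaluation: one-to-one matching, Venn overlap and APA pileups.

Matching is greedy and one-to-one: predictions are visited in descending
score order and consume at most one reference pair each; a prediction and a
reference match when both anchor midpoints lie within the tolerance (in bp,
inclusive).  The APA (aggregate peak analysis) score is the pileup centre
divided by the mean of its lower-left corner; values above one indicate
focal enrichment at the called loops.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import BedpePair, ContactMatrix

__all__ = ["MatchResult", "match_loops", "venn_overlap", "apa"]


@dataclasses.dataclass
class MatchResult:
    n_pred: int
    n_ref: int
    n_matched: int
    precision: float
    recall: float
    f1: float


def _midpoints(pairs: list[BedpePair]) -> np.ndarray:
    out = np.empty((len(pairs), 2))
    for k, p in enumerate(pairs):
        p = p.sorted_anchors()
        out[k] = (p.mid1, p.mid2)
    return out


def _greedy_match(pred: list[BedpePair], ref: list[BedpePair], tol_bp: float) -> int:
    """Count one-to-one matches; predictions visit in descending score order."""
    if not pred or not ref:
        return 0
    order = sorted(range(len(pred)),
                   key=lambda k: -(pred[k].score if pred[k].score is not None else 0.0))
    pm = _midpoints(pred)
    rm = _midpoints(ref)
    ref_chrom = np.array([(r.sorted_anchors().chrom1, r.sorted_anchors().chrom2) for r in ref])
    used = np.zeros(len(ref), dtype=bool)
    matched = 0
    for k in order:
        p = pred[k].sorted_anchors()
        ok = (~used
              & (ref_chrom[:, 0] == p.chrom1) & (ref_chrom[:, 1] == p.chrom2)
              & (np.abs(rm[:, 0] - pm[k, 0]) <= tol_bp)
              & (np.abs(rm[:, 1] - pm[k, 1]) <= tol_bp))
        hits = np.flatnonzero(ok)
        if hits.size:
            # consume the closest available reference
            d = np.maximum(np.abs(rm[hits, 0] - pm[k, 0]), np.abs(rm[hits, 1] - pm[k, 1]))
            used[hits[np.argmin(d)]] = True
            matched += 1
    return matched


def match_loops(pred: list[BedpePair], ref: list[BedpePair], tol_bp: float = 0) -> MatchResult:
    """Precision / recall / F1 of predicted loops against reference pairs."""
    if tol_bp < 0:
        raise ValueError("tolerance must be non-negative")
    n_matched = _greedy_match(pred, ref, tol_bp)
    n_pred, n_ref = len(pred), len(ref)
    precision = n_matched / n_pred if n_pred else 0.0
    recall = n_matched / n_ref if n_ref else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MatchResult(n_pred=n_pred, n_ref=n_ref, n_matched=n_matched,
                       precision=precision, recall=recall, f1=f1)


def venn_overlap(a: list[BedpePair], b: list[BedpePair], tol_bp: float = 0):
    """(only_a, shared, only_b) with shared counted from a's perspective,
    each b loop consumed at most once."""
    shared = _greedy_match(a, b, tol_bp)
    return len(a) - shared, shared, len(b) - shared


def apa(m: ContactMatrix, loops: list[BedpePair], flank_bins: int = 10,
        corner: int = 6, top_k: int = 2000, layer: str = "raw"):
    """Aggregate peak analysis over the ``top_k`` highest-scoring loops.

    Averages the (2*flank+1)^2 windows centred on each loop pixel (windows
    clipped by the matrix edge are skipped) and scores the pileup as
    centre value / mean of the ``corner`` x ``corner`` lower-left submatrix.
    Returns (apa_score, pileup); the score is NaN when the corner mean is 0.
    """
    vals = m.layer(layer)
    res = m.resolution
    ranked = sorted(loops, key=lambda p: -(p.score if p.score is not None else 0.0))[:top_k]
    side = 2 * flank_bins + 1
    pileup = np.zeros((side, side))
    n_used = 0
    for p in ranked:
        p = p.sorted_anchors()
        i = int(p.mid1 // res)
        j = int(p.mid2 // res)
        if i - flank_bins < 0 or j - flank_bins < 0 \
                or i + flank_bins >= m.n_bins or j + flank_bins >= m.n_bins:
            continue
        pileup += vals[i - flank_bins:i + flank_bins + 1, j - flank_bins:j + flank_bins + 1]
        n_used += 1
    if n_used == 0:
        return float("nan"), pileup
    pileup /= n_used
    corner_block = pileup[-corner:, :corner]  # lower-left: large i, small j
    corner_mean = corner_block.mean()
    center = pileup[flank_bins, flank_bins]
    score = float("nan") if corner_mean == 0 else float(center / corner_mean)
    return score, pileup
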