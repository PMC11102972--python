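"""Genome-wide loop calling: candidate scan, diffusion scoring, isolation
filtering and density-peaks clustering.

Candidates are bin pairs inside the 30 kb - 3 Mb band whose contact value is
at least ``min_if`` and whose 28x28 window contains fewer than 200 zero
entries.  After scoring, pairs with score > 0.5 survive, isolated
predictions (fewer than 15 candidates in the 5x5 square) are dropped in one
simultaneous pass, and density-peaks clustering (local density rho within
Chebyshev radius 2; delta = distance to the nearest strictly denser
candidate) keeps peaks with delta >= 5 as the final loops.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .diffusion import DiffusionSchedule, EpsNet, reverse_classify_batch
from .io import BedpePair, ContactMatrix
from .prior import PriorNet

__all__ = [
    "CandidateLoop",
    "scan_candidates",
    "score_candidates",
    "filter_score",
    "remove_isolated",
    "density_delta",
    "select_final",
    "loops_to_bedpe",
    "call_loops",
]

MIN_DIST_BP = 30_000
MAX_DIST_BP = 3_000_000


@dataclasses.dataclass
class CandidateLoop:
    i: int
    j: int
    score: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    t_pvalue: float = np.nan
    rho: int = 0
    delta: float = np.nan


def _box_zero_counts(layer: np.ndarray, w: int) -> np.ndarray:
    """Number of zero entries in the 2w x 2w window at every centre, via a
    summed-area table; entries for centres whose window crosses the boundary
    are set to a sentinel larger than any real count."""
    n = layer.shape[0]
    side = 2 * w
    zeros = (layer == 0).astype(np.int64)
    sat = np.zeros((n + 1, n + 1), dtype=np.int64)
    sat[1:, 1:] = zeros.cumsum(axis=0).cumsum(axis=1)
    out = np.full((n, n), side * side + 1, dtype=np.int64)
    lo = w - 1
    hi_excl = n - w  # last valid centre index + 1
    if hi_excl > lo:
        r0 = np.arange(lo, hi_excl)
        a = r0 - (w - 1)
        b = r0 + w + 1  # exclusive
        block = (sat[np.ix_(b, b)] - sat[np.ix_(a, b)] - sat[np.ix_(b, a)]
                 + sat[np.ix_(a, a)])
        out[np.ix_(r0, r0)] = block
    return out


def scan_candidates(m: ContactMatrix, w: int = 14, min_d: int = MIN_DIST_BP,
                    max_d: int = MAX_DIST_BP, min_if: float = 1.0,
                    max_zeros: int = 200, layer: str = "balanced") -> list[tuple[int, int]]:
    """Enumerate prefiltered candidate bin pairs (i < j)."""
    vals = m.layer(layer)
    res = m.resolution
    n = m.n_bins
    lo_bins = int(np.ceil(min_d / res))
    hi_bins = min(int(max_d // res), n - 1)
    zero_counts = _box_zero_counts(vals, w)
    ii, jj = np.triu_indices(n, k=lo_bins)
    keep = (((jj - ii) <= hi_bins)
            & (ii >= w - 1) & (jj >= w - 1)
            & (ii <= n - 1 - w) & (jj <= n - 1 - w))
    ii, jj = ii[keep], jj[keep]
    keep = vals[ii, jj] >= min_if
    ii, jj = ii[keep], jj[keep]
    keep = zero_counts[ii, jj] < max_zeros
    ii, jj = ii[keep], jj[keep]
    return list(zip(ii.tolist(), jj.tolist()))


def score_candidates(cands: list[tuple[int, int]], m: ContactMatrix,
                     prior_net: PriorNet, eps_net: EpsNet, sched: DiffusionSchedule,
                     n_draws: int = 10, seed: int = 0, w: int = 14,
                     layer: str = "balanced", batch: int = 4096) -> list[CandidateLoop]:
    """Score every candidate window with the reverse diffusion chain."""
    if not cands:
        return []
    vals = m.layer(layer)
    out: list[CandidateLoop] = []
    for k in range(0, len(cands), batch):
        chunk = cands[k:k + batch]
        wins = np.stack([
            vals[i - (w - 1):i + w + 1, j - (w - 1):j + w + 1] for i, j in chunk
        ]).astype(np.float32)
        preds = reverse_classify_batch(wins, prior_net, eps_net, sched,
                                       n_draws=n_draws, seed=seed + k)
        for (i, j), p in zip(chunk, preds):
            out.append(CandidateLoop(i=i, j=j, score=p.score, ci_low=p.ci_low,
                                     ci_high=p.ci_high, t_pvalue=p.t_pvalue))
    return out


def filter_score(cands: list[CandidateLoop], cutoff: float = 0.5) -> list[CandidateLoop]:
    """Keep candidates with score strictly greater than the cutoff."""
    return [c for c in cands if c.score > cutoff]


def remove_isolated(cands: list[CandidateLoop], square: int = 5,
                    min_count: int = 15) -> list[CandidateLoop]:
    """Drop isolated predictions in a single simultaneous pass.

    A candidate survives iff at least ``min_count`` candidates of the input
    set (itself included) fall in the ``square`` x ``square`` Chebyshev
    neighbourhood centred on it.
    """
    if square % 2 == 0:
        raise ValueError("square size must be odd")
    if not cands:
        return []
    radius = square // 2
    pts = np.array([[c.i, c.j] for c in cands], dtype=float)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius, p=np.inf, return_length=True)
    return [c for c, n in zip(cands, counts) if n >= min_count]


def _density_order_key(c: CandidateLoop) -> tuple:
    """Total order on 'density': rho, then score, then (i, j)."""
    return (c.rho, c.score, c.i, c.j)


def density_delta(cands: list[CandidateLoop], d_c: float = 2.0) -> list[CandidateLoop]:
    """Attach local density rho and separation delta to every candidate.

    rho counts candidates within Chebyshev radius ``d_c`` (the 5x5 square for
    the default).  delta is the Chebyshev distance to the nearest candidate
    that is strictly denser under the (rho, score, index) total order, found
    with expanding-radius K-D-tree queries; the global density maximum gets
    ``max(other deltas) + 1``.
    """
    if not cands:
        raise ValueError("need at least one candidate")
    pts = np.array([[c.i, c.j] for c in cands], dtype=float)
    tree = cKDTree(pts)
    rho = tree.query_ball_point(pts, r=d_c, p=np.inf, return_length=True)
    for c, r in zip(cands, rho):
        c.rho = int(r)
    keys = [_density_order_key(c) for c in cands]
    n = len(cands)
    deltas = np.full(n, np.nan)
    top = max(range(n), key=lambda k: keys[k])
    span = float(np.abs(pts - pts[top]).max()) if n > 1 else 1.0
    for idx in range(n):
        if idx == top:
            continue
        radius = max(d_c, 1.0)
        best = np.inf
        while True:
            neigh = tree.query_ball_point(pts[idx], r=radius, p=np.inf)
            for nb in neigh:
                if keys[nb] > keys[idx]:
                    d = max(abs(pts[nb][0] - pts[idx][0]), abs(pts[nb][1] - pts[idx][1]))
                    best = min(best, d)
            if np.isfinite(best) and best <= radius:
                break
            if radius > span:
                break
            radius *= 2.0
        deltas[idx] = best if np.isfinite(best) else span
    max_other = np.nanmax(deltas[np.arange(n) != top]) if n > 1 else 0.0
    deltas[top] = max_other + 1.0
    for c, d in zip(cands, deltas):
        c.delta = float(d)
    return cands


def select_final(cands: list[CandidateLoop], delta_min: float = 5.0) -> list[CandidateLoop]:
    """Keep density peaks: candidates with delta >= delta_min, sorted by
    (i, j).  Candidates with smaller delta sit close to a denser candidate
    and are redundant predictions."""
    kept = [c for c in cands if c.delta >= delta_min]
    return sorted(kept, key=lambda c: (c.i, c.j))


def shuffle_scores(scored: list[CandidateLoop], seed: int) -> list[CandidateLoop]:
    """Permute scores across candidates (a null caller: spatial structure of
    the score field destroyed, marginal score distribution preserved)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(scored))
    return [dataclasses.replace(c, score=scored[k].score)
            for c, k in zip(scored, perm)]


def cluster_scored(scored: list[CandidateLoop], score_cutoff: float = 0.5,
                   square: int = 5, min_neighbors: int = 15,
                   delta_min: float = 5.0) -> list[CandidateLoop]:
    """The post-scoring half of the pipeline: cutoff, isolation removal,
    density-peaks selection."""
    kept = filter_score(scored, cutoff=score_cutoff)
    kept = remove_isolated(kept, square=square, min_count=min_neighbors)
    if not kept:
        return []
    kept = density_delta(kept, d_c=square // 2)
    return select_final(kept, delta_min=delta_min)


def loops_to_bedpe(loops: list[CandidateLoop], chrom: str, resolution: int) -> list[BedpePair]:
    """Loop pixels -> BEDPE records with bin-interval anchors."""
    return [
        BedpePair(chrom, c.i * resolution, (c.i + 1) * resolution,
                  chrom, c.j * resolution, (c.j + 1) * resolution,
                  name=f"loop_{k}", score=round(float(c.score), 6))
        for k, c in enumerate(loops)
    ]


def call_loops(m: ContactMatrix, prior_net: PriorNet, eps_net: EpsNet,
               sched: DiffusionSchedule, w: int = 14, min_d: int = MIN_DIST_BP,
               max_d: int = MAX_DIST_BP, min_if: float = 1.0, max_zeros: int = 200,
               score_cutoff: float = 0.5, square: int = 5, min_neighbors: int = 15,
               delta_min: float = 5.0, n_draws: int = 10, seed: int = 0,
               layer: str = "balanced", log=None):
    """Run the full calling pipeline on one contact matrix.

    Returns ``(final_loops, stage_counts, scored)`` where ``scored`` is the
    full pre-cutoff score table (useful for audits and null comparisons).
    """
    counts = {}
    cands = scan_candidates(m, w=w, min_d=min_d, max_d=max_d, min_if=min_if,
                            max_zeros=max_zeros, layer=layer)
    counts["prefiltered"] = len(cands)
    scored = score_candidates(cands, m, prior_net, eps_net, sched,
                              n_draws=n_draws, seed=seed, w=w, layer=layer)
    counts["scored"] = len(scored)
    kept = filter_score(scored, cutoff=score_cutoff)
    counts["score_cutoff"] = len(kept)
    kept = remove_isolated(kept, square=square, min_count=min_neighbors)
    counts["non_isolated"] = len(kept)
    if kept:
        kept = density_delta(kept, d_c=square // 2)
        final = select_final(kept, delta_min=delta_min)
    else:
        final = []
    counts["final"] = len(final)  # same steps as cluster_scored, with audit
    if log is not None:
        for k, v in counts.items():
            log(f"{k}: {v}")
    return final, counts, scored
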