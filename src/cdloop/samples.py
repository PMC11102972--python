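"""Build labelled training samples from a contact map plus BEDPE loop labels.

Positives are label anchor pairs inside the 30 kb - 3 Mb separation band,
expanded to every pixel the anchors overlap (an anchor spanning two bins
contributes two bin rows/columns).  Negatives come from three sampling
schemes keyed to the positive distance distribution, all-zero negative
windows are dropped, and positives are augmented by matrix flips.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import BedpePair, ContactMatrix, Window, extract_window

__all__ = [
    "LabeledSample",
    "anchor_bins",
    "collect_positives",
    "sample_negatives",
    "build_samples",
    "drop_allzero",
    "augment_flips",
    "split_by_chromosome",
    "DEFAULT_VAL_CHROMS",
    "DEFAULT_TEST_CHROMS",
]

MIN_DIST_BP = 30_000
MAX_DIST_BP = 3_000_000

DEFAULT_VAL_CHROMS = ("chr11", "chr12")
DEFAULT_TEST_CHROMS = ("chr15", "chr16", "chr17")


@dataclasses.dataclass
class LabeledSample:
    window: Window
    label: int  # 1 = loop, 0 = background
    origin: str  # positive | neg_scheme1 | neg_scheme2 | neg_scheme3
    distance: int  # genomic separation in bp
    chrom: str = "chrN"

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if (self.label == 1) != (self.origin == "positive"):
            raise ValueError("label 1 iff origin is 'positive'")


def anchor_bins(start: int, end: int, resolution: int) -> range:
    """All bins overlapped by the half-open interval [start, end)."""
    return range(start // resolution, (end - 1) // resolution + 1)


def collect_positives(labels: list[BedpePair], m: ContactMatrix,
                      min_d: int = MIN_DIST_BP, max_d: int = MAX_DIST_BP) -> list[tuple[int, int]]:
    """Map intra-chromosomal label pairs in the distance band to pixel
    coordinates; a label spanning several pixels yields one positive per
    pixel, duplicates collapsed."""
    res = m.resolution
    out: set[tuple[int, int]] = set()
    for p in labels:
        if p.chrom1 != p.chrom2 or p.chrom1 != m.chrom:
            continue
        p = p.sorted_anchors()
        d = abs(p.mid2 - p.mid1)
        if not (min_d <= d <= max_d):
            continue
        for bi in anchor_bins(p.start1, p.end1, res):
            for bj in anchor_bins(p.start2, p.end2, res):
                i, j = (bi, bj) if bi <= bj else (bj, bi)
                if 0 <= i < m.n_bins and 0 <= j < m.n_bins and min_d <= (j - i) * res <= max_d:
                    out.add((i, j))
    return sorted(out)


def sample_negatives(positives: list[tuple[int, int]], m: ContactMatrix,
                     seed: int) -> list[tuple[int, int, str]]:
    """Draw negatives with the three distance-matched schemes.

    1. per positive, two random pairs at the same bin distance;
    2. |positives| pairs at distances resampled from the positive multiset;
    3. |positives| pairs at distances strictly greater than the largest
       positive distance (capped at the chromosome span).

    No sampled pair may coincide with a positive; duplicates between
    negatives are allowed.
    """
    if not positives:
        raise ValueError("need at least one positive to sample negatives")
    rng = np.random.default_rng(seed)
    n_bins = m.n_bins
    pos_set = set(positives)
    distances = np.array([j - i for i, j in positives])
    d_max = int(distances.max())
    if d_max + 1 > n_bins - 1:
        raise RuntimeError(
            f"chromosome with {n_bins} bins too short for scheme-3 distances > {d_max}"
        )
    out: list[tuple[int, int, str]] = []

    def draw_at(d: int, tag: str) -> tuple[int, int, str]:
        for _ in range(10_000):
            i = int(rng.integers(0, n_bins - d))
            pair = (i, i + d)
            if pair not in pos_set:
                return (pair[0], pair[1], tag)
        raise RuntimeError(f"could not sample a negative at distance {d}")

    for i, j in positives:  # scheme 1
        d = j - i
        out.append(draw_at(d, "neg_scheme1"))
        out.append(draw_at(d, "neg_scheme1"))
    for _ in positives:  # scheme 2
        d = int(rng.choice(distances))
        out.append(draw_at(d, "neg_scheme2"))
    for _ in positives:  # scheme 3
        d = int(rng.integers(d_max + 1, n_bins))
        out.append(draw_at(d, "neg_scheme3"))
    return out


def build_samples(positives: list[tuple[int, int]],
                  negatives: list[tuple[int, int, str]],
                  m: ContactMatrix, w: int = 14, layer: str = "balanced") -> list[LabeledSample]:
    """Extract windows for every pair; pairs whose window would cross the
    chromosome boundary are skipped."""
    res = m.resolution
    out: list[LabeledSample] = []
    for i, j in positives:
        try:
            win = extract_window(m, i, j, w=w, layer=layer)
        except ValueError:
            continue
        out.append(LabeledSample(win, 1, "positive", (j - i) * res, m.chrom))
    for i, j, tag in negatives:
        try:
            win = extract_window(m, i, j, w=w, layer=layer)
        except ValueError:
            continue
        out.append(LabeledSample(win, 0, tag, (j - i) * res, m.chrom))
    return out


def drop_allzero(samples: list[LabeledSample]) -> list[LabeledSample]:
    """Remove negative samples whose window is entirely zero (they carry no
    signal); positives are never removed here."""
    return [s for s in samples
            if s.label == 1 or np.any(s.window.values != 0)]


def augment_flips(samples: list[LabeledSample], mode: str = "hv+both") -> list[LabeledSample]:
    """Flip-augment positive windows; negatives pass through unchanged.

    mode 'hv+both': identity, horizontal, vertical and double flip (4
    variants per positive); mode 'hv': identity, horizontal, vertical.
    """
    if mode == "hv+both":
        ops = [lambda v: v, np.fliplr, np.flipud, lambda v: np.flipud(np.fliplr(v))]
    elif mode == "hv":
        ops = [lambda v: v, np.fliplr, np.flipud]
    else:
        raise ValueError(f"unknown flip mode {mode!r}")
    out: list[LabeledSample] = []
    for s in samples:
        if s.label == 0:
            out.append(s)
            continue
        for op in ops:
            win = Window(center=s.window.center, values=np.ascontiguousarray(op(s.window.values)),
                         w=s.window.w)
            out.append(dataclasses.replace(s, window=win))
    return out


def split_by_chromosome(samples: list[LabeledSample],
                        val_chroms=DEFAULT_VAL_CHROMS,
                        test_chroms=DEFAULT_TEST_CHROMS):
    """Partition samples into (train, val, test) by chromosome; chromosomes
    in neither list default to training."""
    val = set(val_chroms)
    test = set(test_chroms)
    if val & test:
        raise ValueError(f"validation/test chromosome lists overlap: {sorted(val & test)}")
    train_s, val_s, test_s = [], [], []
    for s in samples:
        if s.chrom in val:
            val_s.append(s)
        elif s.chrom in test:
            test_s.append(s)
        else:
            train_s.append(s)
    return train_s, val_s, test_s


def samples_to_arrays(samples: list[LabeledSample]):
    """Stack windows into an (N, 2w, 2w) float array plus label vector."""
    x = np.stack([s.window.values for s in samples]).astype(np.float32)
    y = np.array([s.label for s in samples], dtype=np.int64)
    return x, y
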