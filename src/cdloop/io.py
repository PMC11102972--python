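"""Contact-matrix and BEDPE input/output, balancing, windows, downsampling.

A :class:`ContactMatrix` holds one chromosome's symmetric contact counts at a
fixed bin resolution (default 5 kb), plus an optional Knight-Ruiz-balanced
layer.  Matrices come from single-resolution ``.cool`` files (read with h5py),
3-column sparse text (``bin_i  bin_j  count``) or dense square text.  Loop
labels and loop calls travel as BEDPE records.

Bin convention: 0-based indices; bin ``k`` covers the half-open genomic
interval ``[k*res, (k+1)*res)``.
"""

from __future__ import annotations

import dataclasses
import io as _stdio
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "ContactMatrix",
    "Window",
    "BedpePair",
    "load_contacts",
    "kr_normalize",
    "extract_window",
    "downsample",
    "read_bedpe",
    "write_bedpe",
    "write_sparse_text",
]


@dataclasses.dataclass
class ContactMatrix:
    """Symmetric per-chromosome contact counts, raw and optionally balanced."""

    chrom: str
    resolution: int
    raw: np.ndarray
    balanced: np.ndarray | None = None
    mask: np.ndarray | None = None  # True for bins excluded from balancing

    def __post_init__(self):
        self.raw = np.asarray(self.raw)
        if self.raw.ndim != 2 or self.raw.shape[0] != self.raw.shape[1]:
            raise ValueError("contact matrix must be square")
        if (self.raw < 0).any():
            raise ValueError("negative contact counts")
        if not np.allclose(self.raw, self.raw.T):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.raw.shape[0]

    def layer(self, name: str) -> np.ndarray:
        if name == "raw":
            return self.raw
        if name == "balanced":
            if self.balanced is None:
                raise ValueError("balanced layer not computed; run kr_normalize first")
            return self.balanced
        raise ValueError(f"unknown layer {name!r}")


@dataclasses.dataclass
class Window:
    """A 2w x 2w submatrix centred on a bin pair; the model input."""

    center: tuple[int, int]
    values: np.ndarray
    w: int = 14

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (2 * self.w, 2 * self.w):
            raise ValueError(f"window must be {2*self.w}x{2*self.w}, got {self.values.shape}")
        if not np.isfinite(self.values).all() or (self.values < 0).any():
            raise ValueError("window values must be finite and non-negative")


@dataclasses.dataclass(frozen=True)
class BedpePair:
    """One BEDPE record: two half-open 0-based genomic intervals."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    name: str = "."
    score: float | None = None

    def __post_init__(self):
        if self.start1 >= self.end1 or self.start2 >= self.end2:
            raise ValueError("BEDPE interval must have start < end")

    @property
    def mid1(self) -> float:
        return 0.5 * (self.start1 + self.end1)

    @property
    def mid2(self) -> float:
        return 0.5 * (self.start2 + self.end2)

    def sorted_anchors(self) -> "BedpePair":
        if (self.chrom2, self.start2) < (self.chrom1, self.start1):
            return dataclasses.replace(
                self, chrom1=self.chrom2, start1=self.start2, end1=self.end2,
                chrom2=self.chrom1, start2=self.start1, end2=self.end1,
            )
        return self


# ---------------------------------------------------------------------------
# loading

def _load_cool(path: Path, chrom: str, resolution: int) -> np.ndarray:
    with h5py.File(path, "r") as f:
        binsize = int(f["bins/start"][1] - f["bins/start"][0]) if f["bins/start"].shape[0] > 1 else resolution
        if "bin-size" in f.attrs:
            binsize = int(f.attrs["bin-size"])
        if binsize != resolution:
            raise ValueError(f"cool file resolution {binsize} != requested {resolution}")
        chrom_names = [c.decode() if isinstance(c, bytes) else str(c) for c in f["chroms/name"][:]]
        if chrom not in chrom_names:
            raise ValueError(f"chromosome {chrom!r} not in cool file (has {chrom_names})")
        cid = chrom_names.index(chrom)
        bin_chrom = f["bins/chrom"][:]
        sel = np.flatnonzero(bin_chrom == cid)
        lo, hi = int(sel[0]), int(sel[-1]) + 1
        n = hi - lo
        b1 = f["pixels/bin1_id"][:]
        b2 = f["pixels/bin2_id"][:]
        cnt = f["pixels/count"][:]
        keep = (b1 >= lo) & (b1 < hi) & (b2 >= lo) & (b2 < hi)
        mat = np.zeros((n, n), dtype=float)
        i = b1[keep] - lo
        j = b2[keep] - lo
        np.add.at(mat, (i, j), cnt[keep])
        mat = np.triu(mat) + np.triu(mat, 1).T  # mirror upper triangle
        return mat


def _strip_comments(path: Path) -> _stdio.StringIO:
    lines = [ln for ln in Path(path).read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    return _stdio.StringIO("\n".join(lines))


def load_contacts(path, chrom: str, resolution: int = 5000,
                  n_bins: int | None = None) -> ContactMatrix:
    """Load one chromosome's contact matrix.

    Accepts a single-resolution ``.cool`` file, 3-column sparse text
    (``bin_i bin_j count``, whitespace- or tab-separated, ``#`` comments) or a
    dense square text matrix.  Counts from the upper triangle are mirrored so
    the result is exactly symmetric.
    """
    path = Path(path)
    if path.suffix == ".cool" or h5py.is_hdf5(path):
        raw = _load_cool(path, chrom, resolution)
        return ContactMatrix(chrom=chrom, resolution=resolution, raw=raw)

    arr = np.loadtxt(_strip_comments(path), ndmin=2)
    if arr.size == 0:
        raise ValueError(f"{path}: empty contact file")
    if arr.shape[1] == 3 and (n_bins is not None or arr.shape[0] != 3):
        i = arr[:, 0].astype(int)
        j = arr[:, 1].astype(int)
        c = arr[:, 2]
        if (c < 0).any():
            raise ValueError(f"{path}: negative contact count")
        n = n_bins if n_bins is not None else int(max(i.max(), j.max())) + 1
        mat = np.zeros((n, n), dtype=float)
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        np.add.at(mat, (lo, hi), c)
        mat = np.triu(mat) + np.triu(mat, 1).T
        return ContactMatrix(chrom=chrom, resolution=resolution, raw=mat)

    if arr.shape[0] != arr.shape[1]:
        raise ValueError(f"{path}: dense matrix must be square, got {arr.shape}")
    if (arr < 0).any():
        raise ValueError(f"{path}: negative contact count")
    if not np.allclose(arr, arr.T, rtol=1e-6, atol=1e-8):
        raise ValueError(f"{path}: dense matrix asymmetric beyond tolerance")
    sym = np.triu(arr) + np.triu(arr, 1).T
    return ContactMatrix(chrom=chrom, resolution=resolution, raw=sym)


def write_sparse_text(m: ContactMatrix, path, header: str | None = None) -> None:
    """Write the upper triangle as 3-column text (``bin_i bin_j count``)."""
    i, j = np.nonzero(np.triu(m.raw))
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write(f"# chrom={m.chrom} resolution={m.resolution} n_bins={m.n_bins}\n")
        for a, b in zip(i, j):
            v = m.raw[a, b]
            fh.write(f"{a}\t{b}\t{v:g}\n")


# ---------------------------------------------------------------------------
# balancing

def kr_normalize(m: ContactMatrix, tol: float = 1e-6, max_iter: int = 3000) -> ContactMatrix:
    """Knight-Ruiz balancing: find positive diagonal D with D*raw*D having
    equal row sums over unmasked bins.

    All-zero rows are masked (balancing is undefined there).  The balanced
    layer is rescaled to preserve the total raw count mass, so entries remain
    on the count scale.  Raises if the residual has not dropped below ``tol``
    within ``max_iter`` fixed-point iterations.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    raw = m.raw.astype(float)
    rowsum = raw.sum(axis=1)
    mask = rowsum == 0
    active = ~mask
    sub = raw[np.ix_(active, active)]
    n_act = sub.shape[0]
    if n_act == 0:
        m.balanced = np.zeros_like(raw)
        m.mask = mask
        return m
    d = np.ones(n_act)
    residual = np.inf
    for it in range(1, max_iter + 1):
        r = d * (sub @ d)  # current row sums of diag(d) sub diag(d)
        mean_r = r.mean()
        residual = np.abs(r / mean_r - 1.0).max()
        if residual <= tol:
            break
        d /= np.sqrt(r / mean_r)
    else:
        raise RuntimeError(
            f"KR balancing did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} > tol {tol:.3e})"
        )
    bal_sub = sub * np.outer(d, d)
    total = sub.sum()
    if bal_sub.sum() > 0:
        bal_sub *= total / bal_sub.sum()  # keep count scale
    balanced = np.zeros_like(raw)
    balanced[np.ix_(active, active)] = bal_sub
    m.balanced = balanced
    m.mask = mask
    return m


# ---------------------------------------------------------------------------
# windows

def extract_window(m: ContactMatrix, i: int, j: int, w: int = 14,
                   layer: str = "balanced") -> Window:
    """Extract the 2w x 2w window around bin pair (i, j).

    Rows ``i-(w-1) .. i+w`` and columns ``j-(w-1) .. j+w`` inclusive, so the
    centre pixel sits at index ``(w-1, w-1)`` of the window (13 bins upward /
    leftward and 14 downward / rightward for w=14).
    """
    lo_i, hi_i = i - (w - 1), i + w
    lo_j, hi_j = j - (w - 1), j + w
    if lo_i < 0 or lo_j < 0 or hi_i >= m.n_bins or hi_j >= m.n_bins:
        raise ValueError(
            f"window at ({i},{j}) with w={w} crosses the chromosome boundary "
            f"(n_bins={m.n_bins})"
        )
    vals = m.layer(layer)[lo_i:hi_i + 1, lo_j:hi_j + 1].copy()
    return Window(center=(i, j), values=vals, w=w)


# ---------------------------------------------------------------------------
# downsampling

def downsample(m: ContactMatrix, fraction: float, seed: int) -> ContactMatrix:
    """Binomially thin every contact count, emulating sequencing-depth
    reduction: each read pair is kept independently with probability
    ``fraction`` (so the expected total is fraction x original total)."""
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    counts = m.raw
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("downsampling requires integer counts")
    if fraction == 1.0:
        return ContactMatrix(chrom=m.chrom, resolution=m.resolution, raw=counts.copy())
    rng = np.random.default_rng(seed)
    upper = np.triu(counts).astype(np.int64)
    thinned = rng.binomial(upper, fraction)
    sym = np.triu(thinned) + np.triu(thinned, 1).T
    return ContactMatrix(chrom=m.chrom, resolution=m.resolution, raw=sym.astype(float))


# ---------------------------------------------------------------------------
# BEDPE

def read_bedpe(path) -> list[BedpePair]:
    """Read tab/whitespace-separated BEDPE; ``#`` lines are comments."""
    pairs: list[BedpePair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: expected >= 6 BEDPE fields, got {len(fields)}")
            try:
                rec = BedpePair(
                    chrom1=fields[0], start1=int(fields[1]), end1=int(fields[2]),
                    chrom2=fields[3], start2=int(fields[4]), end2=int(fields[5]),
                    name=fields[6] if len(fields) > 6 else ".",
                    score=float(fields[7]) if len(fields) > 7 else None,
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BEDPE line ({exc})") from exc
            pairs.append(rec)
    return pairs


def write_bedpe(pairs, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for p in pairs:
            score = "" if p.score is None else f"\t{p.score:.6g}"
            fh.write(f"{p.chrom1}\t{p.start1}\t{p.end1}\t{p.chrom2}\t{p.start2}\t{p.end2}"
                     f"\t{p.name}{score}\n")
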