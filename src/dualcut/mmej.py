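"""Microhomology statistics for small-deletion formation at Cas9 cuts.

MMEJ repairs a double-strand break by annealing short direct repeats that
flank the cut, deleting the sequence between them.  For a deletion-sized
region of ``n`` nucleotides centred on the cleavage site, let ``M`` be the
length of the longest common (contiguous) sequence shared by the two
flanks.  ``M`` behaves like the longest head run in a coin-tossing record:
the Arratia-Waterman extreme-value theory gives, for per-position match
probability ``p`` (1/4 for uniform random DNA),

    P(M <= L)  <=  (1+p)/(1-p) * (1 - (2/n) log_{1/p} n)^{-2}
                   * p^{2 log_{1/p} n - L - 1}
    P(M <= L)  >=  1 - p^{L - 2 log_{1/p} n + 1}

and ``M / log_{1/p}(n)`` converges to 2 almost surely as ``n`` grows.  The
probability that a region offers at least ``L+1`` bases of microhomology is
then bounded below by one minus the upper bound, which is the conservative
MMEJ-probability curve: it climbs to 99.7% for L = 2 by n = 100, the
rationale for treating deletions under 100 bp as the MMEJ-dominated size
range.

The raw bound formulas leave [0, 1] at small ``n``; all returned
probabilities are clamped.  The region of length ``n`` is split evenly
into two flanks of n/2 (remainder to the upstream flank).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "longest_flanking_match",
    "p_upper_bound_M_le_L",
    "p_lower_bound_M_le_L",
    "mmej_probability_lower_bound",
    "mmej_curve",
    "simulate_M_ratio",
    "MRatioResult",
]

_CODE = {c: i for i, c in enumerate("ACGT")}


def _log_inv_p(n: float, p: float) -> float:
    return math.log(n) / math.log(1.0 / p)


def _to_codes(seq) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq.astype(np.int64)
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"non-ACGT symbol {exc} in flank") from exc


def _kmer_codes(codes: np.ndarray, k: int, bits: int) -> np.ndarray:
    """Bit-packed k-mers of a coded sequence."""
    n = codes.size
    out = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        out = (out << bits) | codes[j : j + n - k + 1]
    return out


def _has_common_kmer(a: np.ndarray, b: np.ndarray, k: int) -> bool:
    if k == 0:
        return True
    if k > min(a.size, b.size):
        return False
    bits = max(2, int(max(a.max(initial=0), b.max(initial=0))).bit_length())
    if k * bits <= 62:
        return np.intersect1d(_kmer_codes(a, k, bits), _kmer_codes(b, k, bits)).size > 0
    # rare long-match path: exact substring sets
    sa = {a[i : i + k].tobytes() for i in range(a.size - k + 1)}
    return any(b[i : i + k].tobytes() in sa for i in range(b.size - k + 1))


def longest_flanking_match(left_flank, right_flank) -> int:
    """Length M of the longest common substring of the two flanks.

    Accepts DNA strings (ACGT) or integer code arrays.  Exact: binary
    search over the match length with packed k-mer set intersection.
    """
    a = _to_codes(left_flank)
    b = _to_codes(right_flank)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty window")
    cap = min(a.size, b.size)
    # exponential bracket (typical M ~ 2 log n, far below the flank length)
    hi = 1
    while hi < cap and _has_common_kmer(a, b, hi):
        hi = min(cap, hi * 2)
    if hi == cap and _has_common_kmer(a, b, cap):
        return cap
    lo = hi // 2  # largest probed success
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _has_common_kmer(a, b, mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def _check_bound_args(n: float, L: int, p: float) -> float:
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if n < 2:
        raise ValueError("bound undefined for n")
    lg = _log_inv_p(n, p)
    if (2.0 / n) * lg >= 1.0:
        raise ValueError("bound undefined for n")
    return lg


def p_upper_bound_M_le_L(n: float, L: int, p: float = 0.25) -> float:
    """Arratia-Waterman upper bound on P(M <= L), clamped to [0, 1]."""
    lg = _check_bound_args(n, L, p)
    raw = (
        (1.0 + p)
        / (1.0 - p)
        * (1.0 - (2.0 / n) * lg) ** -2
        * p ** (2.0 * lg - L - 1.0)
    )
    return min(1.0, max(0.0, raw))


def p_lower_bound_M_le_L(n: float, L: int, p: float = 0.25) -> float:
    """Arratia-Waterman lower bound on P(M <= L), clamped to [0, 1]."""
    lg = _check_bound_args(n, L, p)
    raw = 1.0 - p ** (L - 2.0 * lg + 1.0)
    return min(1.0, max(0.0, raw))


def mmej_probability_lower_bound(n: float, L: int = 2, p: float = 0.25) -> float:
    """Conservative lower bound on P(M >= L): 1 - upper bound of P(M <= L-1).

    With the defaults this is the probability that a deletion-sized region
    of ``n`` bp offers at least 2 bp of flanking microhomology.
    """
    return min(1.0, max(0.0, 1.0 - p_upper_bound_M_le_L(n, L - 1, p)))


def mmej_curve(n_values, L: int = 2, p: float = 0.25):
    """MMEJ-probability lower bound over a grid of region sizes.

    Returns a pandas DataFrame with columns ``n`` and ``p_mmej_lower``.
    """
    import pandas as pd

    rows = [(int(n), mmej_probability_lower_bound(n, L, p)) for n in n_values]
    return pd.DataFrame(rows, columns=["n", "p_mmej_lower"])


def plot_mmej_curve(curve, path) -> None:
    """Save the curve to an image file (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve["n"], curve["p_mmej_lower"], lw=1.5)
    ax.set_xlabel("deletion size n (bp)")
    ax.set_ylabel("P(M >= 2), lower bound")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass(frozen=True)
class MRatioResult:
    """Monte-Carlo summary of the ratio M / log_{1/p}(n)."""

    n: int
    reps: int
    p: float
    mean_M: float
    ratio_mean: float
    ratio_se: float


def simulate_M_ratio(n: int, reps: int, seed: int, p: float = 0.25) -> MRatioResult:
    """Monte-Carlo estimate of mean M / log_{1/p}(n) on random flank pairs.

    Draws ``reps`` independent pairs of uniform random flanks of ``n // 2``
    symbols each over an alphabet of ``1/p`` letters, computes the longest
    common substring length M for each, and returns the mean ratio with its
    standard error.  The theory predicts the ratio approaches 2 from below
    as ``n`` grows.  ``p`` must be the reciprocal of an integer alphabet
    size; ``p = 1`` degenerates to a single-letter alphabet where M is
    always the full flank length.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    sigma = round(1.0 / p)
    if abs(1.0 / p - sigma) > 1e-9:
        raise ValueError("p must be the reciprocal of an integer alphabet size")
    half = n // 2
    if half < 1:
        raise ValueError("n too small")
    rng = np.random.default_rng(seed)
    if sigma == 1:
        ms = np.full(reps, half, dtype=float)
        ratio = math.inf
        return MRatioResult(n, reps, p, float(half), ratio, 0.0)
    ms = np.empty(reps, dtype=float)
    for r in range(reps):
        a = rng.integers(0, sigma, half, dtype=np.int64)
        b = rng.integers(0, sigma, half, dtype=np.int64)
        ms[r] = longest_flanking_match(a, b)
    lg = _log_inv_p(n, p)
    ratios = ms / lg
    return MRatioResult(
        n=n,
        reps=reps,
        p=p,
        mean_M=float(ms.mean()),
        ratio_mean=float(ratios.mean()),
        ratio_se=float(ratios.std(ddof=1) / math.sqrt(reps)),
    )
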