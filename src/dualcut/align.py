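"""Staggered-cleavage-aware alignment of amplicon reads to a junctional reference.

Each read is decomposed into three parts: a left part aligned to the
upstream arm, an optional unmapped middle insertion, and a right part
aligned to the downstream arm.  Two levels of optimisation are involved:
per-part affine-gap alignments with free outer ends (the lower level) and
the choice of split indices (the upper level).  The junction-proximal ends
of the two part alignments are free within their arms; their distances to
the junction are reported as ``del_up`` / ``del_down`` -- the deleted bases
at the cleavage site, which are the editing outcome being measured and are
therefore never charged as alignment gaps.  The left and right read
intervals may overlap by up to ``max_overlap`` bases so that junction
sequence matching both arms (as left by staggered Cas9 cleavage ends) is
captured rather than arbitrarily attributed to one arm.

``brute_force_align`` provides an independent oracle for the same search
space, built on :class:`Bio.Align.PairwiseAligner`; it is intended for
small instances and testing only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .reference import JunctionReference, revcomp

__all__ = [
    "ScoringScheme",
    "PartAlignment",
    "JunctionAlignment",
    "align_junction",
    "align_both_strands",
    "brute_force_align",
    "alignment_table_row",
]

_NEG = -1e18

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("invalid alphabet")
    return codes


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment parameters.

    A gap of length g costs ``gap_open + (g - 1) * gap_extend``.  Each
    unmapped middle-insertion base costs ``insertion_base_penalty``.  ``N``
    bases always score as mismatches.  ``mapped_frac`` sets the mapping
    threshold: a read is mapped when its total score reaches
    ``mapped_frac * match * len(read)``.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    insertion_base_penalty: float = -1.0
    max_overlap: int = 6
    min_anchor: int = 15
    mapped_frac: float = 0.6

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.max_overlap < 0:
            raise ValueError("max_overlap must be >= 0")
        if self.min_anchor < 1:
            raise ValueError("min_anchor must be >= 1")

    def mapped_threshold(self, read_len: int) -> float:
        return self.mapped_frac * self.match * read_len


@dataclass(frozen=True)
class PartAlignment:
    """One aligned read part: read interval, arm interval, CIGAR, score."""

    read_start: int
    read_end: int
    arm_start: int
    arm_end: int
    cigar: str
    score: float


@dataclass(frozen=True)
class JunctionAlignment:
    """Optimal three-part decomposition of one read against a junction."""

    read_id: str
    read: str
    strand: str
    left: PartAlignment | None
    right: PartAlignment | None
    middle_insertion: str
    overlap_len: int
    del_up: int
    del_down: int
    score: float
    mapped: bool

    @property
    def split(self) -> tuple[int, int]:
        return (self.left.read_end, self.right.read_start)


def _part_matrices(part: np.ndarray, arm: np.ndarray, scheme: ScoringScheme):
    """Affine-gap DP of every read-part prefix against the arm.

    Returns state matrices ``M`` (diagonal), ``X`` (arm base deleted) and
    ``Y`` (read base inserted), each of shape (len(part)+1, len(arm)+1).
    Row 0 of ``M`` is zero: the alignment may start anywhere in the arm for
    free.  ``max(M, X, Y)[i, u]`` is the best score of aligning the prefix
    of length ``i`` with the alignment ending at arm position ``u``.
    """
    m, a = len(part), len(arm)
    op, ex = scheme.gap_open, scheme.gap_extend
    M = np.full((m + 1, a + 1), _NEG)
    X = np.full((m + 1, a + 1), _NEG)
    Y = np.full((m + 1, a + 1), _NEG)
    M[0, :] = 0.0
    idx = np.arange(a)
    for i in range(1, m + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        p = part[i - 1]
        srow = np.where((arm == p) & (p < 4), scheme.match, scheme.mismatch)
        M[i, 1:] = best_prev[:-1] + srow
        Y[i] = np.maximum(M[i - 1] + op, Y[i - 1] + ex)
        # X[i, u] = max(M[i, u-1] + op, X[i, u-1] + ex): prefix-scan closed form
        run = np.maximum.accumulate(M[i, :-1] - idx * ex)
        X[i, 1:] = op + run + idx * ex
    return M, X, Y


def _prefix_profile(M, X, Y):
    """Per prefix length: best score over arm end positions, and the largest
    end position achieving it (ties resolved toward the junction)."""
    best_state = np.maximum(np.maximum(M, X), Y)
    best = best_state.max(axis=1)
    a = best_state.shape[1] - 1
    ends = a - np.argmax(best_state[:, ::-1], axis=1)
    return best, ends


def _traceback(M, X, Y, part, arm, scheme, i, u):
    """Walk back from state-max cell (i, u); returns (arm_start, cigar)."""
    op_, ex = scheme.gap_open, scheme.gap_extend
    vals = (M[i, u], X[i, u], Y[i, u])
    state = "MXY"[int(np.argmax(vals))]
    ops: list[str] = []
    tol = 1e-9

    def close(x, y):
        return abs(x - y) < tol

    while i > 0:
        if state == "M":
            ops.append("M")
            prev = (M[i - 1, u - 1], X[i - 1, u - 1], Y[i - 1, u - 1])
            state = "MXY"[int(np.argmax(prev))]
            i, u = i - 1, u - 1
        elif state == "X":
            ops.append("D")
            state = "M" if close(X[i, u], M[i, u - 1] + op_) else "X"
            u -= 1
        else:  # Y
            ops.append("I")
            state = "M" if close(Y[i, u], M[i - 1, u] + op_) else "Y"
            i -= 1
    # trailing arm-deletion ops at the alignment start are an artefact of a
    # penalised X-ending; trim leading free arm positions
    cigar_ops = ops[::-1]
    while cigar_ops and cigar_ops[0] == "D":
        cigar_ops.pop(0)
        u += 1
    runs = ["%d%s" % (len(list(g)), k) for k, g in itertools.groupby(cigar_ops)]
    return u, "".join(runs)


def _validate_read(read: str, scheme: ScoringScheme) -> np.ndarray:
    if len(read) < 2 * scheme.min_anchor:
        raise ValueError("read too short")
    return _encode(read)


def _choose_split(totals, mids, delsums, overlaps, ii, jj):
    """Deterministic tie-breaking: max score, then smallest middle insertion,
    smallest del_up+del_down, largest overlap, leftmost split."""
    order = np.lexsort((jj, ii, -overlaps, delsums, mids, -totals))
    return order[0]


def align_junction(
    read: str,
    ref: JunctionReference,
    scheme: ScoringScheme | None = None,
    read_id: str = "",
    strand: str = "+",
) -> JunctionAlignment:
    """Maximum-score three-part decomposition of ``read`` against ``ref``.

    Ties between equal-scoring decompositions are broken toward precise
    ligation: smaller middle insertion first, then smaller
    ``del_up + del_down``, then larger overlap, then the leftmost split.
    ``mapped`` is ``False`` when the optimum falls below the scheme's
    mapping threshold.
    """
    scheme = scheme or ScoringScheme()
    codes = _validate_read(read, scheme)
    m = len(read)
    up = _encode(ref.upstream_arm)
    down = _encode(ref.downstream_arm)
    a, b = len(up), len(down)

    ML, XL, YL = _part_matrices(codes, up, scheme)
    MRr, XRr, YRr = _part_matrices(codes[::-1], down[::-1], scheme)
    bl, bl_end = _prefix_profile(ML, XL, YL)
    br_rev, br_rev_end = _prefix_profile(MRr, XRr, YRr)
    # suffix R[j:] corresponds to reversed prefix of length m - j
    br = br_rev[::-1]
    del_down_at = (b - br_rev_end)[::-1]  # forward arm start of right part
    del_up_at = a - bl_end

    anchor = scheme.min_anchor
    i_vals = np.arange(anchor, min(m, m - anchor + scheme.max_overlap) + 1)
    j_vals = np.arange(0, m - anchor + 1)
    ii, jj = np.meshgrid(i_vals, j_vals, indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    ok = jj >= ii - scheme.max_overlap
    ii, jj = ii[ok], jj[ok]
    mids = np.maximum(0, jj - ii)
    overlaps = np.maximum(0, ii - jj)
    totals = bl[ii] + br[jj] + scheme.insertion_base_penalty * mids
    delsums = del_up_at[ii] + del_down_at[jj]
    k = _choose_split(totals, mids, delsums, overlaps, ii, jj)
    i, j, score = int(ii[k]), int(jj[k]), float(totals[k])

    lu = int(bl_end[i])
    arm_start_l, cigar_l = _traceback(ML, XL, YL, codes, up, scheme, i, lu)
    t = m - j
    ru = int(br_rev_end[t])
    rev_start, cigar_r_rev = _traceback(
        MRr, XRr, YRr, codes[::-1], down[::-1], scheme, t, ru
    )
    # map reversed-arm interval [rev_start, ru) back to forward coordinates
    r_arm_start, r_arm_end = b - ru, b - rev_start
    cigar_r = "".join(
        "%d%s" % (n, o)
        for n, o in reversed(
            [(int(x[:-1]), x[-1]) for x in _split_cigar(cigar_r_rev)]
        )
    )

    left = PartAlignment(0, i, arm_start_l, lu, cigar_l, float(bl[i]))
    right = PartAlignment(j, m, r_arm_start, r_arm_end, cigar_r, float(br[j]))
    overlap = max(0, i - j)
    middle = read[i:j] if j > i else ""
    return JunctionAlignment(
        read_id=read_id,
        read=read,
        strand=strand,
        left=left,
        right=right,
        middle_insertion=middle,
        overlap_len=overlap,
        del_up=a - lu,
        del_down=r_arm_start,
        score=score,
        mapped=score >= scheme.mapped_threshold(m),
    )


def _split_cigar(cigar: str) -> list[str]:
    out, num = [], ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append(num + ch)
            num = ""
    return out


def align_both_strands(
    read: str,
    ref: JunctionReference,
    scheme: ScoringScheme | None = None,
    read_id: str = "",
) -> JunctionAlignment:
    """Align ``read`` and its reverse complement; keep the higher score.

    On ties the forward orientation is reported.  The returned alignment's
    ``read`` field holds the oriented (possibly reverse-complemented)
    sequence actually aligned.
    """
    fwd = align_junction(read, ref, scheme, read_id=read_id, strand="+")
    rev = align_junction(revcomp(read), ref, scheme, read_id=read_id, strand="-")
    return fwd if fwd.score >= rev.score else rev


def _oracle_aligner(scheme: ScoringScheme):
    from Bio import Align
    from Bio.Align import substitution_matrices

    mat = np.full((5, 5), scheme.mismatch)
    for i in range(4):
        mat[i, i] = scheme.match
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.Array(
        "ACGTN", dims=2, data=mat
    )
    aligner.mode = "global"
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    aligner.end_deletion_score = 0  # unaligned arm (target) ends are free
    return aligner


def brute_force_align(
    read: str,
    ref: JunctionReference,
    scheme: ScoringScheme | None = None,
    read_id: str = "",
    max_len: int = 60,
) -> JunctionAlignment:
    """Exhaustive oracle over all split pairs; small instances only.

    Enumerates every (i, j) with ``j <= i <= j + max_overlap`` or ``i <= j``
    and scores each part with an independently implemented pairwise aligner
    (Biopython), then applies the same tie rules as :func:`align_junction`.
    Scores agree exactly with :func:`align_junction` by construction of the
    search space; this is the contract the tests enforce.
    """
    scheme = scheme or ScoringScheme()
    if len(read) > max_len:
        raise ValueError("oracle size exceeded")
    _validate_read(read, scheme)
    m = len(read)
    aligner = _oracle_aligner(scheme)
    U, D = ref.upstream_arm, ref.downstream_arm
    a, b = len(U), len(D)
    anchor = scheme.min_anchor

    left_scores = {
        i: aligner.score(U, read[:i])
        for i in range(anchor, min(m, m - anchor + scheme.max_overlap) + 1)
    }
    right_scores = {j: aligner.score(D, read[j:]) for j in range(0, m - anchor + 1)}

    rows = []
    for i, ls in left_scores.items():
        for j, rs in right_scores.items():
            if j < i - scheme.max_overlap:
                continue
            mid = max(0, j - i)
            rows.append(
                (ls + rs + scheme.insertion_base_penalty * mid, mid, max(0, i - j), i, j)
            )
    totals = np.array([r[0] for r in rows])
    best_total = totals.max()

    del_cache: dict[tuple[str, int], tuple[int, tuple[int, int]]] = {}

    def min_del(arm_seq, part, side, cap=64):
        """Smallest junction distance among co-optimal part alignments."""
        key = (side, len(part))
        if key in del_cache:
            return del_cache[key]
        best = None
        for aln in itertools.islice(aligner.align(arm_seq, part), cap):
            blocks = aln.aligned[0]
            start, end = int(blocks[0][0]), int(blocks[-1][1])
            d = (len(arm_seq) - end) if side == "up" else start
            if best is None or d < best[0]:
                best = (d, (start, end))
        del_cache[key] = best
        return best

    # tie-break only among maximum-score splits
    cands = [r for r, tot in zip(rows, totals) if tot == best_total]
    mids = np.array([r[1] for r in cands])
    overlaps = np.array([r[2] for r in cands])
    ii = np.array([r[3] for r in cands])
    jj = np.array([r[4] for r in cands])
    dels = np.array(
        [
            min_del(U, read[:i], "up")[0] + min_del(D, read[j:], "down")[0]
            for i, j in zip(ii, jj)
        ]
    )
    k = _choose_split(np.zeros(len(cands)), mids, dels, overlaps, ii, jj)
    i, j = int(ii[k]), int(jj[k])
    du, (lus, lue) = min_del(U, read[:i], "up")
    dd, (rus, rue) = min_del(D, read[j:], "down")
    score = float(best_total)
    return JunctionAlignment(
        read_id=read_id,
        read=read,
        strand="+",
        left=PartAlignment(0, i, lus, lue, "", float(left_scores[i])),
        right=PartAlignment(j, m, rus, rue, "", float(right_scores[j])),
        middle_insertion=read[i:j] if j > i else "",
        overlap_len=max(0, i - j),
        del_up=du,
        del_down=dd,
        score=score,
        mapped=score >= scheme.mapped_threshold(m),
    )


def alignment_table_row(aln: JunctionAlignment) -> dict:
    """Flat record for the per-read alignment TSV."""
    return {
        "read_id": aln.read_id,
        "strand": aln.strand,
        "i": aln.left.read_end,
        "j": aln.right.read_start,
        "overlap_len": aln.overlap_len,
        "del_up": aln.del_up,
        "del_down": aln.del_down,
        "insertion": aln.middle_insertion,
        "score": aln.score,
        "mapped": aln.mapped,
    }
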