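"""Large-resection calling from bait-prey junction reads.

Linear-amplification junction capture (LAM-HTGTS-style) produces reads
whose 5' end anchors at a bait primer upstream of the first cut and whose
remainder reports where the broken end was rejoined.  Each read is mapped
as two segments against a user-supplied locus window on both strands.  A
read is a deletion-type junction when the second segment maps strictly
downstream of the first with both on the forward strand, and an
inversion-type junction when the second segment maps to the reverse
strand.  The resected length is the total distance between the expected
cut positions and the observed mapped boundaries; junctions losing more
than the large-resection cutoff (100 nt by default, shared with the
outcome classifier) count as large resections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import ScoringScheme, _encode, _part_matrices, _prefix_profile, _traceback
from .classify import LARGE_RESECTION_CUTOFF
from .reference import revcomp

__all__ = [
    "Segment",
    "SegmentMapping",
    "map_read_segments",
    "classify_resection",
    "resection_fraction",
]


@dataclass(frozen=True)
class Segment:
    """One mapped read segment on the locus window (forward coordinates)."""

    reference_id: str
    strand: str
    start: int
    end: int
    score: float


@dataclass(frozen=True)
class SegmentMapping:
    """Two-segment decomposition of one read; seg1 is the more 5' segment."""

    read_id: str
    seg1: Segment | None
    seg2: Segment | None
    resection_class: str = "unclassified"
    resected_nt: int = 0


def map_read_segments(
    read: str,
    reference: str,
    reference_id: str = "ref",
    scheme: ScoringScheme | None = None,
    read_id: str = "",
) -> SegmentMapping:
    """Split ``read`` into two segments mapped against ``reference``.

    The first segment is aligned to the forward strand (the bait strand);
    the second to whichever strand scores higher.  Each segment's outer and
    inner reference ends are free; splits leaving either part below the
    anchor length are not considered.  Segments failing the per-part
    mapping threshold are reported as ``None``.
    """
    scheme = scheme or ScoringScheme()
    m = len(read)
    if m < 2 * scheme.min_anchor:
        raise ValueError("read too short")
    codes = _encode(read)
    fwd = _encode(reference.upper())
    rev = _encode(revcomp(reference.upper()))
    b = len(fwd)

    M1, X1, Y1 = _part_matrices(codes, fwd, scheme)
    p1, e1 = _prefix_profile(M1, X1, Y1)
    mats = {}
    profs = {}
    for name, arm in (("+", fwd), ("-", rev)):
        mats[name] = _part_matrices(codes[::-1], arm[::-1], scheme)
        profs[name] = _prefix_profile(*mats[name])

    best = None
    for s in range(scheme.min_anchor, m - scheme.min_anchor + 1):
        t = m - s
        for strand in "+-":
            p2, _ = profs[strand]
            total = p1[s] + p2[t]
            # ties: forward strand, then the leftmost split
            key = (-total, 0 if strand == "+" else 1, s)
            if best is None or key < best[0]:
                best = (key, s, strand)
    _, s, strand = best
    t = m - s

    u1 = int(e1[s])
    start1, _ = _traceback(M1, X1, Y1, codes, fwd, scheme, s, u1)
    seg1 = Segment(reference_id, "+", start1, u1, float(p1[s]))

    p2, e2 = profs[strand]
    u2r = int(e2[t])
    Mr, Xr, Yr = mats[strand]
    arm_rev = (fwd if strand == "+" else rev)[::-1]
    start2r, _ = _traceback(Mr, Xr, Yr, codes[::-1], arm_rev, scheme, t, u2r)
    # reversed-arm interval -> arm coordinates
    a_start, a_end = b - u2r, b - start2r
    if strand == "-":
        a_start, a_end = b - a_end, b - a_start  # '-' arm coords -> forward
    seg2 = Segment(reference_id, strand, a_start, a_end, float(p2[t]))

    thr = scheme.mapped_frac * scheme.match
    if seg1.score < thr * s:
        seg1 = None
    if seg2.score < thr * t:
        seg2 = None
    return SegmentMapping(read_id=read_id, seg1=seg1, seg2=seg2)


def classify_resection(
    mapping: SegmentMapping,
    expected_cuts: tuple[int, int] | None = None,
) -> SegmentMapping:
    """Assign the joining type and, given the expected cuts, the resected length.

    Deletion-type: both segments forward and the second strictly downstream
    of the first.  Inversion-type: the second segment on the reverse
    strand.  Anything else is unclassified.
    """
    if mapping.seg1 is None or mapping.seg2 is None:
        raise ValueError("incomplete mapping")
    s1, s2 = mapping.seg1, mapping.seg2
    if s1.strand == "+" and s2.strand == "+" and s2.start > s1.end:
        cls = "deletion_type"
    elif s1.strand == "+" and s2.strand == "-":
        cls = "inversion_type"
    else:
        cls = "unclassified"
    resected = 0
    if cls != "unclassified" and expected_cuts is not None:
        c1, c2 = expected_cuts
        resected = max(0, c1 - s1.end)
        if cls == "deletion_type":
            resected += max(0, s2.start - c2)
        else:
            resected += max(0, c2 - s2.end)
    return SegmentMapping(
        read_id=mapping.read_id,
        seg1=s1,
        seg2=s2,
        resection_class=cls,
        resected_nt=resected,
    )


def resection_fraction(
    classified: list[SegmentMapping],
    total_reads: int,
    large_threshold: int = LARGE_RESECTION_CUTOFF,
) -> float:
    """Ratio of large-resection reads to the total number of reads."""
    if total_reads <= 0:
        raise ValueError("empty library")
    if total_reads < len(classified):
        raise ValueError("inconsistent totals")
    n = sum(
        1
        for mobj in classified
        if mobj.resection_class in ("deletion_type", "inversion_type")
        and mobj.resected_nt > large_threshold
    )
    return n / total_reads
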