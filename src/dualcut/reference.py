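"""Guide sites and junctional references for dual-sgRNA DNA-fragment editing.

A pair of Cas9 cuts programmed with two sgRNAs rearranges the intervening
DNA fragment.  Each rearrangement type (deletion, inversion, duplication)
creates a novel junction whose predicted sequence -- the *junctional
reference* -- is the concatenation of two cut arms.  SpCas9 cleaves
predominantly bluntly between protospacer positions -3 and -4 (counted
upstream from the NGG PAM), but a sizeable fraction of cleavages are
staggered, leaving 1-3 nt 5' overhangs over positions -4 to -6.  Cellular
fill-in of such an overhang duplicates those bases at the junction, which
is why the overhang sequence of each guide is carried on the reference.

Coordinates are 0-based and half-open throughout; cut sites are inter-base
integers on the forward strand of the supplied segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "revcomp",
    "GuideSite",
    "JunctionReference",
    "blunt_cut_position",
    "predicted_overhang",
    "build_junction_reference",
    "JUNCTION_KINDS",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: rearrangement junction types supported by :func:`build_junction_reference`
JUNCTION_KINDS = ("deletion", "inversion_up", "inversion_down", "duplication", "single_cut")

#: minimum retained arm length (nt); shorter arms cannot anchor an alignment
MIN_ARM = 15

#: default arm window (nt); 150 + 150 keeps junctional amplicons under 290 bp
DEFAULT_ARM_WINDOW = 150


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return hits
        hits.append(i)
        start = i + 1


def _check_pam(pam: str) -> None:
    if len(pam) != 3 or pam[1:].upper() != "GG":
        raise ValueError(f"unsupported PAM {pam!r}: only the SpCas9 NGG dialect is accepted")


def blunt_cut_position(segment: str, protospacer: str, pam: str, strand: str) -> int:
    """Locate a guide on ``segment`` and return its blunt-cut coordinate.

    The blunt cut falls between protospacer positions -3 and -4 counted from
    the PAM, expressed as an inter-base coordinate on the forward strand of
    ``segment``.  The protospacer immediately followed by its PAM must occur
    exactly once on the stated strand.

    Raises
    ------
    ValueError
        ``"guide not found"`` if there is no occurrence, ``"ambiguous guide
        placement"`` if there are several.
    """
    _check_pam(pam)
    segment = segment.upper()
    site = (protospacer + pam).upper()
    if strand == "+":
        hits = _find_all(segment, site)
    elif strand == "-":
        hits = _find_all(segment, revcomp(site))
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if not hits:
        raise ValueError("guide not found")
    if len(hits) > 1:
        raise ValueError("ambiguous guide placement")
    s = hits[0]
    if strand == "+":
        # PAM starts at s + len(protospacer); cut 3 nt upstream of the PAM
        return s + len(protospacer) - 3
    # on '-' the reverse-complement PAM occupies [s, s+3); position -1 of the
    # protospacer sits at forward coordinate s+3, so the -3/-4 boundary is s+6
    return s + 6


@dataclass(frozen=True)
class GuideSite:
    """A protospacer + PAM placed on a reference segment, with cut geometry.

    ``cut_blunt`` is the inter-base blunt-cut coordinate on the segment's
    forward strand.  ``max_overhang`` bounds the staggered-cleavage 5'
    overhang (0-3 nt) this guide is modelled to produce.
    """

    label: str
    protospacer: str
    pam: str
    strand: str
    cut_blunt: int
    max_overhang: int = 3

    def __post_init__(self) -> None:
        _check_pam(self.pam)
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.max_overhang <= 3:
            raise ValueError("max_overhang must be between 0 and 3")
        if len(self.protospacer) < 17:
            raise ValueError("protospacer too short to carry a -4..-6 overhang window")

    @classmethod
    def place(
        cls,
        label: str,
        segment: str,
        protospacer: str,
        pam: str,
        strand: str,
        max_overhang: int = 3,
    ) -> "GuideSite":
        """Locate the guide on ``segment`` and return a validated site."""
        cut = blunt_cut_position(segment, protospacer, pam, strand)
        site = cls(label, protospacer.upper(), pam.upper(), strand, cut, max_overhang)
        if not site.max_overhang <= cut <= len(segment) - site.max_overhang:
            raise ValueError("cut site too close to the segment boundary")
        return site


def predicted_overhang(guide: GuideSite, k: int) -> str:
    """Sequence duplicated by fill-in of a ``k``-nt 5' overhang (k = 1..3).

    Returns the bases at PAM-relative positions -4 .. -(3+k) of the
    protospacer strand, PAM-proximal first (-4, -5, -6).  A staggered cut
    with a ``k``-nt overhang, once filled in, duplicates exactly these bases
    at the junction.
    """
    if not 1 <= k <= guide.max_overhang:
        raise ValueError("overhang length unsupported")
    proto = guide.protospacer
    # position -i from the PAM is proto[len(proto) - i]
    return "".join(proto[len(proto) - i] for i in range(4, 4 + k))


def _flank_frame(strand: str, side: str) -> tuple[int, int]:
    """PAM frame of a cut flank: (junction-adjacent position, step away from it).

    The flank on the PAM-distal side of the cut carries positions -4, -5, -6
    walking away from the junction; the PAM-proximal flank carries -3, -2,
    -1 and then the PAM itself (+1, +2, ...; 0 is skipped).
    """
    distal = (side == "left") == (strand == "+")
    return (-4, -1) if distal else (-3, +1)


@dataclass(frozen=True)
class JunctionReference:
    """Predicted post-rearrangement sequence: upstream arm + downstream arm.

    The junction sits at the inter-base coordinate ``len(upstream_arm)`` of
    the concatenated sequence.  ``pam_frames`` maps each arm (``"up"`` /
    ``"down"``) to its PAM frame, used to express deleted bases in
    PAM-relative coordinates.
    """

    kind: str
    upstream_arm: str
    downstream_arm: str
    guides: tuple[GuideSite, ...]
    pam_frames: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in JUNCTION_KINDS:
            raise ValueError(f"unknown junction kind {self.kind!r}")
        if not self.upstream_arm or not self.downstream_arm:
            raise ValueError("both arms must be non-empty")

    @property
    def junction(self) -> int:
        return len(self.upstream_arm)

    @property
    def sequence(self) -> str:
        return self.upstream_arm + self.downstream_arm

    def pam_positions(self, arm: str, n_deleted: int) -> list[int]:
        """PAM-relative positions removed by deleting ``n_deleted``
        junction-proximal bases from ``arm`` ("up" or "down")."""
        frame = self.pam_frames.get(arm)
        if frame is None or n_deleted <= 0:
            return []
        pos, step = frame
        out = []
        for _ in range(n_deleted):
            out.append(pos)
            pos += step
            if pos == 0:  # no position zero: -1 is adjacent to +1 (first PAM base)
                pos += step
        return out


def build_junction_reference(
    upstream_segment: str,
    downstream_segment: str | None,
    guide_up: GuideSite,
    guide_down: GuideSite | None,
    kind: str,
    arm_window: int = DEFAULT_ARM_WINDOW,
    min_arm: int = MIN_ARM,
    label: str = "",
) -> JunctionReference:
    """Assemble the junctional reference for one rearrangement type.

    ``upstream_segment`` / ``downstream_segment`` carry ``guide_up`` /
    ``guide_down`` respectively (for ``single_cut`` the downstream segment
    and guide are ignored and may be ``None``).  Arms are trimmed to
    ``arm_window`` nt so that amplicon-sized reads stay within the
    reference.

    Junction geometry:

    - ``deletion``       -- up[..cut_up] + down[cut_down..]
    - ``inversion_up``   -- up[..cut_up] + revcomp(down[..cut_down])
    - ``inversion_down`` -- revcomp(up[cut_up..]) + down[cut_down..]
    - ``duplication``    -- down[..cut_down] + up[cut_up..]  (head-to-tail)
    - ``single_cut``     -- up[..cut_up] + up[cut_up..]
    """
    upstream_segment = upstream_segment.upper()
    cut_up = guide_up.cut_blunt
    if kind == "single_cut":
        up_arm = upstream_segment[:cut_up]
        down_arm = upstream_segment[cut_up:]
        frames = {
            "up": _flank_frame(guide_up.strand, "left"),
            "down": _flank_frame(guide_up.strand, "right"),
        }
        guides = (guide_up,)
    else:
        if downstream_segment is None or guide_down is None:
            raise ValueError(f"kind {kind!r} needs a downstream segment and guide")
        downstream_segment = downstream_segment.upper()
        cut_down = guide_down.cut_blunt
        if kind == "deletion":
            up_arm = upstream_segment[:cut_up]
            down_arm = downstream_segment[cut_down:]
            frames = {
                "up": _flank_frame(guide_up.strand, "left"),
                "down": _flank_frame(guide_down.strand, "right"),
            }
        elif kind == "inversion_up":
            up_arm = upstream_segment[:cut_up]
            down_arm = revcomp(downstream_segment[:cut_down])
            frames = {
                "up": _flank_frame(guide_up.strand, "left"),
                "down": _flank_frame(guide_down.strand, "left"),
            }
        elif kind == "inversion_down":
            up_arm = revcomp(upstream_segment[cut_up:])
            down_arm = downstream_segment[cut_down:]
            frames = {
                "up": _flank_frame(guide_up.strand, "right"),
                "down": _flank_frame(guide_down.strand, "right"),
            }
        elif kind == "duplication":
            up_arm = downstream_segment[:cut_down]
            down_arm = upstream_segment[cut_up:]
            frames = {
                "up": _flank_frame(guide_down.strand, "left"),
                "down": _flank_frame(guide_up.strand, "right"),
            }
        else:
            raise ValueError(f"unknown junction kind {kind!r}")
        guides = (guide_up, guide_down)

    up_arm = up_arm[-arm_window:] if arm_window else up_arm
    down_arm = down_arm[:arm_window] if arm_window else down_arm
    if len(up_arm) < min_arm or len(down_arm) < min_arm:
        raise ValueError("arm too short")
    return JunctionReference(
        kind=kind,
        upstream_arm=up_arm,
        downstream_arm=down_arm,
        guides=guides,
        pam_frames=frames,
        label=label or f"{guide_up.label}:{kind}",
    )
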