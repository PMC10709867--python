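"""Editing-outcome classification and per-library tallies.

Each mapped junction alignment is assigned to one of four mutually
exclusive outcome groups -- precise ligation, deletion, insertion, indel --
with deletion sizes binned as 1 bp, 2-20 bp, 21-100 bp and >100 bp (the
last labelled a large resection).  Insertions of 1-3 bp that reproduce a
flanking guide's predicted 5'-overhang sequence are flagged as templated:
they are the signature of polymerase fill-in of staggered Cas9 cleavage
ends.  Deleted bases are additionally reported in PAM-relative coordinates
so that the characteristic bias of 1-3 bp deletions toward positions -4,
-5 and -6 can be profiled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import JunctionAlignment
from .reference import JunctionReference, predicted_overhang

__all__ = [
    "JunctionOutcome",
    "OutcomeTally",
    "classify",
    "is_templated_insertion",
    "deletion_position_profile",
    "tally",
    "CATEGORIES",
    "DEL_BINS",
    "LARGE_RESECTION_CUTOFF",
]

CATEGORIES = ("precise", "deletion", "insertion", "indel", "unmapped")
DEL_BINS = ("1", "2-20", "21-100", ">100")

#: deletions beyond this size (nt) are counted as large resections; the
#: small-deletion analyses consider deletions under 100 bp
LARGE_RESECTION_CUTOFF = 100


def del_bin(del_total: int, cutoff: int = LARGE_RESECTION_CUTOFF) -> str | None:
    if del_total <= 0:
        return None
    if del_total == 1:
        return "1"
    if del_total <= 20:
        return "2-20"
    if del_total <= cutoff:
        return "21-100"
    return ">100"


@dataclass(frozen=True)
class JunctionOutcome:
    """Per-read classification of a junction alignment."""

    read_id: str
    category: str
    del_up: int = 0
    del_down: int = 0
    ins_len: int = 0
    insertion: str = ""
    templated: bool = False
    templated_k: int = 0
    templated_source: str = ""
    del_positions: tuple[int, ...] = ()
    strand: str = "+"

    @property
    def del_total(self) -> int:
        return self.del_up + self.del_down

    @property
    def bin(self) -> str | None:
        return del_bin(self.del_total)


def is_templated_insertion(
    insertion: str, ref: JunctionReference
) -> tuple[bool, int, str]:
    """Does ``insertion`` match a flanking guide's predicted fill-in product?

    True iff the insertion is 1-3 nt long and equals the predicted overhang
    of either junction-side guide, read PAM-proximal-first or
    PAM-distal-first (the orientation in which a duplicated overhang lands
    at a junction depends on the rearrangement geometry, so both are
    accepted).  Returns ``(flag, k, source)`` where ``source`` records which
    guide and order matched.
    """
    k = len(insertion)
    if not 1 <= k <= 3:
        return False, 0, ""
    insertion = insertion.upper()
    for guide in ref.guides:
        if k > guide.max_overhang:
            continue
        ov = predicted_overhang(guide, k)
        if insertion == ov:
            return True, k, f"{guide.label}:proximal-first"
        if insertion == ov[::-1]:
            return True, k, f"{guide.label}:distal-first"
    return False, 0, ""


def classify(alignment: JunctionAlignment, ref: JunctionReference) -> JunctionOutcome:
    """Convert one alignment into its outcome record.

    Unmapped alignments yield ``category="unmapped"``.  Otherwise the four
    groups are determined by the deleted and inserted base counts at the
    junction: precise (0, 0), deletion (>0, 0), insertion (0, >0) and indel
    (>0, >0).
    """
    if not alignment.mapped:
        return JunctionOutcome(read_id=alignment.read_id, category="unmapped",
                               strand=alignment.strand)
    du, dd = alignment.del_up, alignment.del_down
    ins = alignment.middle_insertion
    if du + dd == 0 and not ins:
        category = "precise"
    elif ins and du + dd == 0:
        category = "insertion"
    elif du + dd > 0 and not ins:
        category = "deletion"
    else:
        category = "indel"
    templated, k, source = (False, 0, "")
    if ins:
        templated, k, source = is_templated_insertion(ins, ref)
    positions = tuple(ref.pam_positions("up", du) + ref.pam_positions("down", dd))
    return JunctionOutcome(
        read_id=alignment.read_id,
        category=category,
        del_up=du,
        del_down=dd,
        ins_len=len(ins),
        insertion=ins,
        templated=templated,
        templated_k=k,
        templated_source=source,
        del_positions=positions,
        strand=alignment.strand,
    )


def deletion_position_profile(outcomes: list[JunctionOutcome]) -> dict[int, int]:
    """Counts of deleted PAM-relative positions among 1-3 bp deletions.

    Staggered Cas9 cleavage predicts that small junction deletions
    concentrate on positions -4, -5 and -6; this profile makes that bias
    measurable for one library.
    """
    counts: Counter[int] = Counter()
    for o in outcomes:
        if o.category == "deletion" and 1 <= o.del_total <= 3:
            counts.update(o.del_positions)
    return dict(counts)


@dataclass(frozen=True)
class OutcomeTally:
    """Per-library counts and frequencies.

    ``repaired_fraction`` is the ratio of reads with junctions (mapped
    reads) to the total number of reads; ``large_resection_fraction`` is
    the ratio of >100 bp deletion reads to the total number of reads.
    Category frequencies are taken over junction reads and sum to one.
    """

    total_reads: int
    junction_reads: int
    category_counts: dict = field(default_factory=dict)
    bin_counts: dict = field(default_factory=dict)
    templated_insertions: int = 0

    @property
    def repaired_fraction(self) -> float:
        return self.junction_reads / self.total_reads if self.total_reads else 0.0

    @property
    def large_resection_fraction(self) -> float:
        if not self.total_reads:
            return 0.0
        return self.bin_counts.get(">100", 0) / self.total_reads

    @property
    def category_frequencies(self) -> dict[str, float]:
        if not self.junction_reads:
            return {c: 0.0 for c in self.category_counts}
        return {c: n / self.junction_reads for c, n in self.category_counts.items()}

    @property
    def bin_frequencies(self) -> dict[str, float]:
        if not self.junction_reads:
            return {b: 0.0 for b in self.bin_counts}
        return {b: n / self.junction_reads for b, n in self.bin_counts.items()}

    def to_records(self) -> list[dict]:
        rows = []
        for cat in CATEGORIES:
            if cat == "unmapped":
                continue
            rows.append(
                {
                    "kind": "category",
                    "name": cat,
                    "count": self.category_counts.get(cat, 0),
                    "frequency": self.category_frequencies.get(cat, 0.0),
                }
            )
        for b in DEL_BINS:
            rows.append(
                {
                    "kind": "del_bin",
                    "name": b,
                    "count": self.bin_counts.get(b, 0),
                    "frequency": self.bin_frequencies.get(b, 0.0),
                }
            )
        rows.append(
            {
                "kind": "summary",
                "name": "repaired_fraction",
                "count": self.junction_reads,
                "frequency": self.repaired_fraction,
            }
        )
        rows.append(
            {
                "kind": "summary",
                "name": "large_resection_fraction",
                "count": self.bin_counts.get(">100", 0),
                "frequency": self.large_resection_fraction,
            }
        )
        return rows


def tally(outcomes: list[JunctionOutcome], total_reads: int) -> OutcomeTally:
    """Aggregate per-read outcomes into library-level counts and fractions."""
    mapped = [o for o in outcomes if o.category != "unmapped"]
    if total_reads < len(mapped):
        raise ValueError("inconsistent totals")
    cat_counts = Counter(o.category for o in mapped)
    bin_counts = Counter(o.bin for o in mapped if o.bin is not None)
    templated = sum(1 for o in mapped if o.templated)
    return OutcomeTally(
        total_reads=total_reads,
        junction_reads=len(mapped),
        category_counts={c: cat_counts.get(c, 0) for c in CATEGORIES if c != "unmapped"},
        bin_counts={b: bin_counts.get(b, 0) for b in DEL_BINS},
        templated_insertions=templated,
    )
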