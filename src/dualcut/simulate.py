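"""Ground-truth amplicon library simulator.

Synthesises junctional amplicon reads with a configured mixture of repair
outcomes -- precise ligations, cNHEJ-style 1 bp deletions, staggered-end
1-3 bp deletions, MMEJ deletions spanning embedded microhomologies,
templated fill-in insertions, untemplated insertions and large resections
-- plus uniform substitution sequencing errors, together with a truth table
for every emitted read.  Amplicons stay under 290 bp, the product-size
ceiling of junctional amplicon libraries sequenced on short-read
platforms.

Truth identifiability
---------------------
A deletion whose boundary bases coincidentally resemble the opposite arm
is genuinely ambiguous: a read lacking one base next to a junction whose
flanks share that base is indistinguishable from a molecule with a
smaller deletion, and the aligner (correctly) absorbs such shared
sequence into an overlap.  So that the truth table is exact, event
sampling rejects events whose clean read does not decode back to the
intended outcome: a fast boundary-base screen first, then a full
align-and-classify verification of the error-free read.  Untemplated
insertions are likewise redrawn if they happen to reproduce a guide's
overhang sequence.  Real libraries contain such ambiguous molecules;
simulated ones deliberately do not, which is what makes count-level
round-trip checks meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference import JunctionReference, predicted_overhang, revcomp

__all__ = [
    "SimConfig",
    "TruthRecord",
    "SimRead",
    "simulate_library",
    "simulate_mmej_deletion",
    "simulate_resection_library",
    "DEFAULT_MIXTURE",
    "random_junction_reference",
]

#: outcome-class mixture used when none is configured
DEFAULT_MIXTURE = {
    "precise": 0.35,
    "del1": 0.15,
    "del_mmej": 0.20,
    "ins_templated": 0.15,
    "ins_random": 0.10,
    "large_resection": 0.05,
}

#: classifier category each simulated class must map to
EXPECTED_CATEGORY = {
    "precise": "precise",
    "del1": "deletion",
    "del_stagger": "deletion",
    "del_mmej": "deletion",
    "ins_templated": "insertion",
    "ins_random": "insertion",
    "large_resection": "deletion",
}

_BASES = "ACGT"


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions for one junctional amplicon library."""

    ref: JunctionReference
    n_reads: int = 5000
    mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    error_rate: float = 0.0
    read_len: int = 280
    seed: int = 1
    #: staggered-overhang length distribution shared by templated insertions
    #: and staggered 1-3 bp deletions
    k_probs: dict = field(default_factory=lambda: {1: 0.5, 2: 0.3, 3: 0.2})
    mmej_mh_lens: tuple = (1, 2, 3, 4)
    mmej_offset_max: int = 7
    ins_random_max: int = 8
    resection_range: tuple = (101, 220)
    min_anchor: int = 15

    def __post_init__(self) -> None:
        if abs(sum(self.mixture.values()) - 1.0) > 1e-9:
            raise ValueError("invalid mixture")
        unknown = set(self.mixture) - set(EXPECTED_CATEGORY)
        if unknown:
            raise ValueError(f"unknown outcome classes {sorted(unknown)}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.read_len < 2 * self.min_anchor:
            raise ValueError("read_len below twice the anchor length")
        if self.read_len > 290:
            raise ValueError("amplicons must stay under 290 bp")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read."""

    read_id: str
    sim_class: str
    expected_category: str
    del_total: int = 0
    insertion: str = ""
    templated_k: int = 0
    resected_nt: int = 0


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    quality: str


def _windows(ref: JunctionReference, read_len: int) -> tuple[str, str]:
    half = read_len // 2
    return ref.upstream_arm[-half:], ref.downstream_arm[:half]


def _deletion_ok(U: str, D: str, du: int, dd: int) -> bool:
    """Reject junction-boundary coincidences that would shrink or shift the
    apparent deletion (see module docstring)."""
    a = len(U)
    if du > 0:
        if dd < len(D) and D[dd] == U[a - du]:
            return False
    if dd > 0:
        if a - du - 1 >= 0 and U[a - du - 1] == D[dd - 1]:
            return False
    return True


def _sample_k(rng: np.random.Generator, k_probs: dict) -> int:
    ks = sorted(k_probs)
    probs = np.array([k_probs[k] for k in ks], dtype=float)
    return int(rng.choice(ks, p=probs / probs.sum()))


def _overhang_candidates(ref: JunctionReference, k: int) -> set[str]:
    cands = set()
    for g in ref.guides:
        if k <= g.max_overhang:
            ov = predicted_overhang(g, k)
            cands.update({ov, ov[::-1]})
    return cands


def simulate_mmej_deletion(
    ref: JunctionReference,
    mh_len: int,
    up_offset: int,
    down_offset: int,
    read_len: int = 280,
) -> str:
    """One MMEJ-deletion read: microhomology copies ``up_offset`` /
    ``down_offset`` nt away from the junction anneal, deleting the sequence
    between them and one copy; the surviving copy is attributed to the
    upstream arm (the deletion is reported left-aligned).  The resulting
    deletion size is ``up_offset + down_offset + mh_len``.
    """
    U, D = _windows(ref, read_len)
    if up_offset + mh_len > len(U) or down_offset + mh_len > len(D):
        raise ValueError("offset out of range")
    if min(up_offset, down_offset) < 0 or mh_len < 0:
        raise ValueError("offset out of range")
    return U[: len(U) - up_offset] + D[down_offset + mh_len :]


def _build_event(
    cls: str, cfg: SimConfig, rng: np.random.Generator, U: str, D: str
) -> tuple[str, dict]:
    """Return (read sequence, truth fields) for one sampled outcome class."""
    a = len(U)
    if cls == "precise":
        return U + D, {}
    if cls in ("del1", "del_stagger"):
        k = 1 if cls == "del1" else _sample_k(rng, cfg.k_probs)
        for _ in range(20):
            up_first = rng.random() < 0.5
            du, dd = (k, 0) if up_first else (0, k)
            if _deletion_ok(U, D, du, dd):
                return U[: a - du] + D[dd:], {"del_total": k}
            du, dd = (0, k) if up_first else (k, 0)
            if _deletion_ok(U, D, du, dd):
                return U[: a - du] + D[dd:], {"del_total": k}
            k = 1 if cls == "del1" else _sample_k(rng, cfg.k_probs)
        raise RuntimeError("could not place an identifiable staggered deletion")
    if cls == "del_mmej":
        for _ in range(100):
            mh = int(rng.choice(cfg.mmej_mh_lens))
            uo = int(rng.integers(0, cfg.mmej_offset_max + 1))
            do = int(rng.integers(0, cfg.mmej_offset_max + 1))
            du, dd = uo, do + mh
            if du + dd >= 2 and _deletion_ok(U, D, du, dd):
                read = U[: a - du] + D[dd:]
                return read, {"del_total": du + dd}
        raise RuntimeError("could not place an identifiable MMEJ deletion")
    if cls == "ins_templated":
        for _ in range(20):
            k = _sample_k(rng, cfg.k_probs)
            eligible = [g for g in cfg.ref.guides if k <= g.max_overhang]
            if eligible:
                g = eligible[int(rng.integers(0, len(eligible)))]
                # fill-in duplication lands PAM-distal-first at the junction
                ins = predicted_overhang(g, k)[::-1]
                return U + ins + D, {"insertion": ins, "templated_k": k}
        raise RuntimeError("no guide supports the sampled overhang length")
    if cls == "ins_random":
        for _ in range(100):
            length = int(rng.integers(1, cfg.ins_random_max + 1))
            ins = "".join(_BASES[i] for i in rng.integers(0, 4, length))
            if length <= 3 and ins in _overhang_candidates(cfg.ref, length):
                continue
            return U + ins + D, {"insertion": ins}
        raise RuntimeError("could not draw an untemplated insertion")
    if cls == "large_resection":
        lo, hi = cfg.resection_range
        du_max = a - cfg.min_anchor - 5
        dd_max = len(D) - cfg.min_anchor - 5
        for _ in range(200):
            total = int(rng.integers(lo, hi + 1))
            du = int(rng.integers(max(0, total - dd_max), min(du_max, total) + 1))
            dd = total - du
            if _deletion_ok(U, D, du, dd):
                return U[: a - du] + D[dd:], {
                    "del_total": total,
                    "resected_nt": total,
                }
        raise RuntimeError("could not place an identifiable large resection")
    raise ValueError(f"unknown outcome class {cls!r}")


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode("ascii")


def _identifiable(seq: str, cls: str, fields: dict, ref: JunctionReference) -> bool:
    """Does the clean read decode back to the intended event?

    Rejects events rendered ambiguous by coincidental junction-boundary
    homology (the aligner would legitimately prefer another decomposition).
    """
    from .align import align_junction
    from .classify import classify

    aln = align_junction(seq, ref)
    o = classify(aln, ref)
    return (
        o.category == EXPECTED_CATEGORY[cls]
        and o.del_total == fields.get("del_total", 0)
        and o.insertion == fields.get("insertion", "")
        and o.templated_k == fields.get("templated_k", 0)
    )


def simulate_library(config: SimConfig) -> tuple[list[SimRead], list[TruthRecord]]:
    """Simulate one junctional amplicon library.

    Deterministic for a given config (including seed).  Returns the reads
    (constant quality Q40) and a parallel truth table.
    """
    rng = np.random.default_rng(config.seed)
    U, D = _windows(config.ref, config.read_len)
    classes = sorted(config.mixture)
    probs = np.array([config.mixture[c] for c in classes], dtype=float)
    drawn = rng.choice(len(classes), size=config.n_reads, p=probs / probs.sum())
    reads, truths = [], []
    for idx, ci in enumerate(drawn):
        cls = classes[int(ci)]
        for _ in range(50):
            seq, fields = _build_event(cls, config, rng, U, D)
            if cls == "precise" or _identifiable(seq, cls, fields, config.ref):
                break
        else:
            raise RuntimeError(f"could not draw an identifiable {cls} event")
        if len(seq) > 290:
            raise AssertionError("amplicon exceeded 290 nt")
        seq = _apply_errors(seq, config.error_rate, rng)
        rid = f"sim_{idx:06d}"
        reads.append(SimRead(rid, seq, "I" * len(seq)))
        truths.append(
            TruthRecord(
                read_id=rid,
                sim_class=cls,
                expected_category=EXPECTED_CATEGORY[cls],
                del_total=fields.get("del_total", 0),
                insertion=fields.get("insertion", ""),
                templated_k=fields.get("templated_k", 0),
                resected_nt=fields.get("resected_nt", 0),
            )
        )
    return reads, truths


# ---------------------------------------------------------------------------
# LAM-HTGTS-style resection libraries (two-segment reads on one locus window)


def simulate_resection_library(
    reference: str,
    cuts: tuple[int, int],
    n_reads: int,
    resection_rate: float = 0.02,
    inversion_fraction: float = 0.5,
    resected_range: tuple[int, int] = (101, 200),
    bait_len: int = 60,
    prey_len: int = 60,
    seed: int = 0,
) -> tuple[list[SimRead], list[dict]]:
    """Simulate bait-prey junction reads around two cuts on one locus window.

    Non-resected reads join the bait flank of the first cut directly to the
    sequence beyond the second cut (deletion junctions) or to the reverse
    complement of the fragment end (inversion junctions).  A
    ``resection_rate`` fraction of reads lose additional sequence from the
    cut ends before joining; their total loss is drawn from
    ``resected_range``.  Truth records carry the joining type and the
    resected length.
    """
    rng = np.random.default_rng(seed)
    c1, c2 = cuts
    W = reference.upper()
    if not (bait_len <= c1 < c2 <= len(W) - prey_len):
        raise ValueError("cuts too close to the window boundary")
    reads, truth = [], []
    for idx in range(n_reads):
        resected = rng.random() < resection_rate
        inversion = rng.random() < inversion_fraction
        for _ in range(200):
            if resected:
                r_total = int(rng.integers(*resected_range))
                r_up = int(rng.integers(0, min(r_total, c1 - bait_len) + 1))
                r_down = r_total - r_up
            else:
                r_up = r_down = r_total = 0
            bait = W[c1 - r_up - bait_len : c1 - r_up]
            if inversion:
                if c2 - r_down - prey_len < c1:
                    continue
                prey_src = W[c2 - r_down - prey_len : c2 - r_down]
                prey = revcomp(prey_src)
                prev_base = revcomp(W[c2 - r_down])  # base preceding prey on '-'
            else:
                if c2 + r_down + prey_len > len(W):
                    continue
                prey = W[c2 + r_down : c2 + r_down + prey_len]
                prev_base = W[c2 + r_down - 1]
            nxt = W[c1 - r_up]  # first unused bait-side base
            if prey[0] == nxt or bait[-1] == prev_base:
                if not resected:
                    break  # boundary clash is a property of the cuts themselves
                continue
            break
        rid = f"res_{idx:06d}"
        reads.append(SimRead(rid, bait + prey, "I" * (bait_len + prey_len)))
        truth.append(
            {
                "read_id": rid,
                "type": "inversion" if inversion else "deletion",
                "resected_nt": r_total,
            }
        )
    return reads, truth


# ---------------------------------------------------------------------------
# convenience: a reproducible synthetic locus with two guides


def random_junction_reference(
    seed: int = 0,
    kind: str = "deletion",
    segment_len: int = 400,
    arm_window: int = 150,
):
    """A random two-guide locus and its junctional reference.

    The upstream guide is placed on '+' and the downstream guide on '-' so
    that both junction-adjacent flanks carry the -4/-5/-6 overhang window
    (the PAM-out configuration).  Segments are redrawn until every 1-3 bp
    junction-adjacent deletion is identifiable (no boundary base clashes).
    Returns ``(ref, up_segment, down_segment)``.
    """
    from .reference import GuideSite, build_junction_reference

    rng = np.random.default_rng(seed)

    def _draw_segment(strand: str):
        q = segment_len // 2 - 11  # guide site anchor
        while True:
            bases = list(_BASES[i] for i in rng.integers(0, 4, segment_len))
            if strand == "+":
                bases[q + 21 : q + 23] = ["G", "G"]  # PAM = NGG at q+20
                seg = "".join(bases)
                proto, pam = seg[q : q + 20], seg[q + 20 : q + 23]
            else:
                bases[q : q + 2] = ["C", "C"]  # forward CCN = revcomp NGG
                seg = "".join(bases)
                proto = revcomp(seg[q + 3 : q + 23])
                pam = revcomp(seg[q : q + 3])
            try:
                g = GuideSite.place("g" + strand, seg, proto, pam, strand)
            except ValueError:
                continue  # redrawn on duplicate placement
            return seg, g

    for _ in range(100):
        up_seg, g_up = _draw_segment("+")
        down_seg, g_down = _draw_segment("-")
        ref = build_junction_reference(
            up_seg, down_seg, g_up, g_down, kind, arm_window=arm_window
        )
        U, D = ref.upstream_arm, ref.downstream_arm
        ok = all(
            _deletion_ok(U, D, k, 0) and _deletion_ok(U, D, 0, k) for k in (1, 2, 3)
        )
        if ok:
            return ref, up_seg, down_seg
    raise RuntimeError("could not draw an identifiable locus")
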