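"""I/O, demultiplexing, pair merging and pipeline orchestration.

File formats go through Biopython (FASTQ/FASTA, gzip transparently by
suffix).  The pipeline stages are: demultiplex by exact (or Hamming-1)
barcode prefix, optionally merge read pairs by their best ungapped
overlap, align each read to its junctional reference on both strands,
classify the outcome, and tally the library.
"""

from __future__ import annotations

import gzip
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import ScoringScheme, align_both_strands, alignment_table_row
from .classify import classify, tally
from .reference import GuideSite, JunctionReference, build_junction_reference

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "LibraryManifest",
    "ManifestEntry",
    "demultiplex",
    "merge_pairs",
    "load_guide_table",
    "run_pipeline",
]

logger = logging.getLogger("dualcut")


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path):
    """Yield (read_id, sequence, quality string) from FASTQ (.gz ok)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq), quals


def write_fastq(path, reads) -> int:
    """Write (read_id, sequence, quality) triples to FASTQ (.gz ok)."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
            SeqIO.write(rec, fh, "fastq")
            n += 1
    return n


def read_fasta(path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


@dataclass(frozen=True)
class ManifestEntry:
    sample: str
    barcode: str
    reference_label: str
    fastq: str = ""
    index: str = ""
    replicate: str = ""


@dataclass
class LibraryManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        barcodes = [e.barcode for e in self.entries]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("manifest conflict")
        if len({len(b) for b in barcodes}) > 1:
            raise ValueError("manifest conflict")

    @classmethod
    def from_tsv(cls, path) -> "LibraryManifest":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        entries = [
            ManifestEntry(
                sample=row["sample"],
                barcode=row["barcode"].upper(),
                reference_label=row.get("reference_label", ""),
                fastq=row.get("fastq", ""),
                index=row.get("index", ""),
                replicate=row.get("replicate", ""),
            )
            for _, row in df.iterrows()
        ]
        return cls(entries)


def demultiplex(reads, manifest: LibraryManifest, max_mismatch: int = 0):
    """Partition reads by barcode prefix; the barcode is trimmed on output.

    With ``max_mismatch=1`` a read is assigned to the unique barcode within
    Hamming distance 1; ambiguous or unmatched reads go to the
    ``"undetermined"`` bin (untrimmed).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    by_barcode = {e.barcode: e.sample for e in manifest.entries}
    blen = len(next(iter(by_barcode))) if by_barcode else 0
    out = {e.sample: [] for e in manifest.entries}
    out["undetermined"] = []
    for rid, seq, qual in reads:
        prefix = seq[:blen].upper()
        sample = by_barcode.get(prefix)
        if sample is None and max_mismatch == 1:
            near = [
                s
                for bc, s in by_barcode.items()
                if sum(a != b for a, b in zip(bc, prefix)) <= 1
            ]
            sample = near[0] if len(near) == 1 else None
        if sample is None:
            out["undetermined"].append((rid, seq, qual))
        else:
            out[sample].append((rid, seq[blen:], qual[blen:]))
    return out


def merge_pairs(
    read1: tuple[str, str],
    read2_revcomp: tuple[str, str],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
):
    """Merge a read pair (read2 already reverse-complemented) by their best
    ungapped overlap; base disagreements resolve to the higher quality.

    Returns ``(sequence, quality)`` or ``None`` when no acceptable overlap
    exists (failure is a value, not an error).
    """
    s1, q1 = read1
    s2, q2 = read2_revcomp
    best = None
    for o in range(min(len(s1), len(s2)), min_overlap - 1, -1):
        tail, head = s1[-o:], s2[:o]
        matches = sum(a == b for a, b in zip(tail, head))
        if (o - matches) / o <= max_mismatch_frac:
            if best is None or matches > best[1]:
                best = (o, matches)
    if best is None:
        return None
    o = best[0]
    merged_seq, merged_q = list(s1[:-o]), list(q1[:-o])
    for k in range(o):
        b1, b2 = s1[len(s1) - o + k], s2[k]
        c1, c2 = q1[len(s1) - o + k], q2[k]
        if b1 == b2 or c1 >= c2:
            merged_seq.append(b1)
            merged_q.append(max(c1, c2) if b1 == b2 else c1)
        else:
            merged_seq.append(b2)
            merged_q.append(c2)
    merged_seq += list(s2[o:])
    merged_q += list(q2[o:])
    return "".join(merged_seq), "".join(merged_q)


def load_guide_table(table_path, fasta_path, arm_window: int = 150):
    """Build junctional references from a guide table and segment FASTA.

    The TSV needs columns ``label, segment_fasta_id, protospacer, pam,
    strand, kind``; one row defines a single-cut reference, two rows with
    the same label (upstream first) define a two-guide junction.
    """
    segments = read_fasta(fasta_path)
    df = pd.read_csv(table_path, sep="\t", dtype=str)
    refs: dict[str, JunctionReference] = {}
    for label, group in df.groupby("label", sort=False):
        rows = group.to_dict("records")
        kinds = {r["kind"] for r in rows}
        if len(kinds) != 1:
            raise ValueError(f"conflicting kinds for junction {label!r}")
        kind = kinds.pop()
        sites = []
        for r in rows:
            seg = segments.get(r["segment_fasta_id"])
            if seg is None:
                raise ValueError(f"segment {r['segment_fasta_id']!r} missing from FASTA")
            sites.append(
                (seg, GuideSite.place(r["label"], seg, r["protospacer"], r["pam"], r["strand"]))
            )
        if kind == "single_cut":
            seg, g = sites[0]
            refs[label] = build_junction_reference(
                seg, None, g, None, kind, arm_window=arm_window, label=label
            )
        else:
            if len(sites) != 2:
                raise ValueError(f"junction {label!r} needs exactly two guide rows")
            (seg_u, g_u), (seg_d, g_d) = sites
            refs[label] = build_junction_reference(
                seg_u, seg_d, g_u, g_d, kind, arm_window=arm_window, label=label
            )
    return refs


def _tally_frame(t) -> pd.DataFrame:
    return pd.DataFrame(t.to_records())


def run_pipeline(
    manifest: LibraryManifest,
    references: dict[str, JunctionReference],
    reads=None,
    scheme: ScoringScheme | None = None,
    out_dir=None,
    max_barcode_mismatch: int = 0,
):
    """Demultiplex, align, classify and tally a run.

    ``reads`` is an iterable of (id, seq, qual); if omitted, each manifest
    entry's FASTQ is read separately (no demultiplexing).  Writes per-sample
    alignment and outcome TSVs plus a JSON report when ``out_dir`` is set.
    Returns ``{sample: (tally, outcomes)}``.
    """
    scheme = scheme or ScoringScheme()
    for e in manifest.entries:
        if e.reference_label not in references:
            raise ValueError(f"manifest references unknown junction {e.reference_label!r}")

    if reads is not None:
        pools = demultiplex(reads, manifest, max_barcode_mismatch)
    else:
        pools = {}
        for e in manifest.entries:
            pools[e.sample] = list(read_fastq(e.fastq)) if e.fastq else []
    results = {}
    report = {}
    for e in manifest.entries:
        pool = pools.get(e.sample, [])
        ref = references[e.reference_label]
        outcomes, rows = [], []
        n_short = 0
        for rid, seq, _ in pool:
            try:
                aln = align_both_strands(seq, ref, scheme, read_id=rid)
            except ValueError:
                n_short += 1
                continue
            rows.append(alignment_table_row(aln))
            outcomes.append(classify(aln, ref))
        t = tally(outcomes, total_reads=len(pool))
        results[e.sample] = (t, outcomes)
        report[e.sample] = {
            "input_reads": len(pool),
            "skipped_short": n_short,
            "junction_reads": t.junction_reads,
            "repaired_fraction": t.repaired_fraction,
            "large_resection_fraction": t.large_resection_fraction,
            "category_frequencies": t.category_frequencies,
        }
        logger.info(
            "sample %s: %d reads, %d with junctions (%.3f repaired)",
            e.sample,
            len(pool),
            t.junction_reads,
            t.repaired_fraction,
        )
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(rows).to_csv(out / f"{e.sample}.alignments.tsv", sep="\t", index=False)
            _tally_frame(t).to_csv(out / f"{e.sample}.tally.tsv", sep="\t", index=False)
    if out_dir is not None:
        with open(Path(out_dir) / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    if "undetermined" in pools:
        report["undetermined"] = {"input_reads": len(pools["undetermined"])}
    return results


def setup_logging(verbose: bool = False, log_file=None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def scheme_from_config(cfg: dict) -> ScoringScheme:
    fields = {
        k: cfg[k]
        for k in (
            "match",
            "mismatch",
            "gap_open",
            "gap_extend",
            "insertion_base_penalty",
            "max_overlap",
            "min_anchor",
            "mapped_frac",
        )
        if k in cfg
    }
    return ScoringScheme(**fields)
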