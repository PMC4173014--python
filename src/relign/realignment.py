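"""Non-gapped realignment of reads against the alternate reference.

Each read is scored ungapped against every seeded placement in the
alternate reference; a read is moved only when it unambiguously aligns
more closely to the alternate than to the original reference, and the
accepted hit is projected back to original-reference coordinates through
the contig's alignment blocks.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import time
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pysam

from relign import __version__
from relign.assembly import assemble_region
from relign.contig_processing import (
    AlternateReference,
    ContigAlignment,
    WindowIndex,
    build_alternate_reference,
    deduplicate,
    left_align_indels,
    place_contig,
)
from relign.io_formats import (
    CIGAR_OPS,
    Cigar,
    Config,
    ReadRecord,
    Reference,
    Region,
    _seq_array,
    add_program_record,
    cigar_to_string,
    fetch_region_reads,
    split_regions,
    write_realigned_bam,
)

log = logging.getLogger("relign")

#: auxiliary tag recording the original alignment of a moved read
ORIG_ALIGNMENT_TAG = "YO"


@dataclasses.dataclass(frozen=True)
class UngappedHit:
    """A read placed gaplessly inside one alternate-reference entry."""

    entry_index: int
    offset: int  # 0-based start of the read within the entry sequence
    mismatches: int


@dataclasses.dataclass
class RealignmentDecision:
    """Outcome for one read: keep its original alignment, or move it."""

    action: str  # "keep" | "move"
    chrom: Optional[str] = None
    pos: int = -1
    cigar: Optional[Cigar] = None
    orig_mismatches: float = 0.0
    best_alt_mismatches: Optional[int] = None


def count_mismatches(
    read_seq: str,
    ref_seq_slice: str,
    quals: np.ndarray,
    min_base_quality: int,
) -> int:
    """Mismatching positions where the read base quality passes the
    threshold; N in either sequence counts as a mismatch."""
    if len(read_seq) != len(ref_seq_slice):
        raise ValueError(
            f"length mismatch: read {len(read_seq)} vs ref {len(ref_seq_slice)}"
        )
    r = _seq_array(read_seq)
    s = _seq_array(ref_seq_slice)
    diff = (r != s) | (r == ord("N")) | (s == ord("N"))
    return int(np.count_nonzero(diff & (np.asarray(quals) >= min_base_quality)))


def ungapped_best_hits(
    read: ReadRecord, alt_reference: AlternateReference, config: Config
) -> List[UngappedHit]:
    """All minimal-mismatch gapless placements of the read in the alternate
    reference, found by k-mer seeding."""
    k = alt_reference.k_seed
    L = len(read.seq)
    if L < k or len(alt_reference) == 0:
        return []
    seq = read.seq
    positions = list(range(0, L - k + 1, k))
    if positions[-1] != L - k:
        positions.append(L - k)
    candidates: Set[int] = set()
    for i in positions:
        for gpos in alt_reference.lookup(seq[i : i + k]):
            candidates.add(gpos - i)
    if not candidates:
        return []
    starts = alt_reference.starts
    buf = alt_reference.buf
    rarr = read.seq_array
    qual_ok = read.quals >= config.min_base_quality
    n_mask = rarr == ord("N")
    valid: List[Tuple[int, int]] = []  # (entry, offset-in-entry) per candidate
    glob: List[int] = []
    for g in sorted(candidates):
        ei = alt_reference.entry_of(g)
        if ei < 0 or ei >= len(alt_reference):
            continue
        lo, hi = int(starts[ei]), int(starts[ei + 1])
        if g < lo or g + L > hi:
            continue
        valid.append((ei, g - lo))
        glob.append(g)
    if not glob:
        return []
    idx = np.asarray(glob, dtype=np.int64)[:, None] + np.arange(L)
    slices = buf[idx]
    diff = (slices != rarr) | n_mask
    mm = (diff & qual_ok).sum(axis=1)
    best = int(mm.min())
    return [
        UngappedHit(ei, off, best)
        for (ei, off), m in zip(valid, mm)
        if int(m) == best
    ]


def score_original(read: ReadRecord, reference: Reference, config: Config) -> float:
    """Quality-masked mismatches of the read's current alignment plus one
    penalty per soft-clipped, inserted or deleted base.  Unmapped reads
    score +inf so any finite alternate hit can win."""
    if read.is_unmapped or read.chrom is None:
        return math.inf
    ref = reference.get(read.chrom)
    score = 0
    r = read.pos
    q = 0
    for op, n in read.cigar:
        if op in "M=X":
            seg = ref[r : r + n]
            if len(seg) < n:
                seg = seg + "N" * (n - len(seg))  # read overhangs chromosome
            score += count_mismatches(
                read.seq[q : q + n], seg, read.quals[q : q + n], config.min_base_quality
            )
            r += n
            q += n
        elif op == "S":
            score += n
            q += n
        elif op == "I":
            score += n
            q += n
        elif op in "DN":
            score += n
            r += n
        elif op == "H":
            pass
    return float(score)


def project_to_reference(
    hit: UngappedHit, contig_alignment: ContigAlignment, read_length: int
) -> Optional[Tuple[str, int, Cigar]]:
    """Project a gapless alternate-reference hit back onto the original
    reference by walking the contig's alignment blocks.

    Insertion overlap truncated at a read edge becomes a soft clip;
    deletions strictly inside the read's span are kept.  Returns None if
    the read span touches no M block.
    """
    span_start = hit.offset
    span_end = hit.offset + read_length
    cig: Cigar = []
    pos: Optional[int] = None
    r = contig_alignment.ref_start
    q = 0
    pending_d = 0  # deletion seen after some M, emitted only if M follows
    for op, n in contig_alignment.blocks:
        if op == "D":
            if pos is not None and q > span_start:
                pending_d += n
            r += n
            continue
        lo = max(q, span_start)
        hi = min(q + n, span_end)
        if hi > lo:
            if op == "M":
                if pos is None:
                    pos = r + (lo - q)
                if pending_d:
                    cig.append(("D", pending_d))
                    pending_d = 0
                cig.append(("M", hi - lo))
            else:  # I
                # insertion truncated by a read edge projects as a soft clip
                if pos is None or (lo == span_start and lo > q) or (hi == span_end and hi < q + n):
                    cig.append(("S", hi - lo))
                else:
                    cig.append(("I", hi - lo))
        if op == "M":
            r += n
        q += n
        if q >= span_end:
            break
    if pos is None:
        return None
    # merge and tidy: trailing I becomes S, collapse repeats
    merged: Cigar = []
    for op, n in cig:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    if merged and merged[-1][0] == "I":
        merged[-1] = ("S", merged[-1][1])
    if merged and merged[0][0] == "I":
        merged[0] = ("S", merged[0][1])
    qlen = sum(n for op, n in merged if op in "MIS")
    if qlen != read_length:
        return None
    if not any(op == "M" for op, _ in merged):
        return None
    return (contig_alignment.chrom, pos, merged)


def decide(
    read: ReadRecord,
    hits: Sequence[UngappedHit],
    orig_score: float,
    alt_reference: AlternateReference,
    config: Config,
) -> RealignmentDecision:
    """Move the read iff its best hits project to a single alignment that
    beats the original by at least ``min_improvement`` quality-masked
    mismatches."""
    if not hits:
        return RealignmentDecision("keep", orig_mismatches=orig_score)
    projections: Set[Tuple[str, int, Tuple[Tuple[str, int], ...]]] = set()
    for hit in hits:
        proj = project_to_reference(
            hit, alt_reference.entries[hit.entry_index], len(read.seq)
        )
        if proj is not None:
            projections.add((proj[0], proj[1], tuple(proj[2])))
    best_mm = hits[0].mismatches
    if len(projections) != 1:
        return RealignmentDecision(
            "keep", orig_mismatches=orig_score, best_alt_mismatches=best_mm
        )
    chrom, pos, cigar_t = next(iter(projections))
    if best_mm + config.min_improvement > orig_score:
        return RealignmentDecision(
            "keep", orig_mismatches=orig_score, best_alt_mismatches=best_mm
        )
    cigar = list(cigar_t)
    if (
        not read.is_unmapped
        and read.chrom == chrom
        and read.pos == pos
        and read.cigar == cigar
    ):
        # already there: nothing to change
        return RealignmentDecision(
            "keep", orig_mismatches=orig_score, best_alt_mismatches=best_mm
        )
    return RealignmentDecision(
        "move",
        chrom=chrom,
        pos=pos,
        cigar=cigar,
        orig_mismatches=orig_score,
        best_alt_mismatches=best_mm,
    )


def _nm_for(read_seq: str, quals: np.ndarray, chrom: str, pos: int, cigar: Cigar,
            reference: Reference) -> int:
    """Edit distance (NM tag): all mismatching M bases plus I/D lengths."""
    ref = reference.get(chrom)
    nm = 0
    r = pos
    q = 0
    for op, n in cigar:
        if op in "M=X":
            seg = ref[r : r + n]
            a = _seq_array(read_seq[q : q + n])
            b = _seq_array(seg + "N" * (n - len(seg)))
            nm += int(np.count_nonzero((a != b) | (a == ord("N")) | (b == ord("N"))))
            r += n
            q += n
        elif op == "I":
            nm += n
            q += n
        elif op in "DN":
            nm += n
            r += n
        elif op == "S":
            q += n
    return nm


@dataclasses.dataclass
class _Proposal:
    mismatches: int
    chrom: str
    pos: int
    cigar: Tuple[Tuple[str, int], ...]
    ambiguous: bool = False


def _region_pipeline(
    bam: "pysam.AlignmentFile",
    reference: Reference,
    region: Region,
    config: Config,
    proposals: Dict[Tuple[str, int], _Proposal],
    examined: Set[Tuple[str, int]],
    stats: Dict[str, int],
    decision_rows: Optional[List[Tuple]] = None,
) -> None:
    reads = fetch_region_reads(bam, region, config.region_pad)
    if not reads:
        return
    for r in reads:
        examined.add(r.read_id)
    contigs = assemble_region(reads, config, region, stats)
    if not contigs:
        return
    chrom_len = reference.length(region.chrom)
    # contigs spanning a deletion cover up to max_deletion_length more
    # reference than the read-fetch window; the alignment window must
    # accommodate both flanks
    pad = config.region_pad + config.max_deletion_length + 200
    ws = max(0, region.start - pad)
    we = min(chrom_len, region.end + pad)
    window = reference.fetch(region.chrom, ws, we)
    index = WindowIndex(window, config.k_seed)
    placed: List[ContigAlignment] = []
    for contig in contigs:
        aln = place_contig(contig, region.chrom, window, ws, config, index)
        if aln is not None:
            placed.append(left_align_indels(aln, reference))
    retained = deduplicate(placed, reference)
    if not retained:
        return
    altref = build_alternate_reference(retained, config.k_seed)
    for read in reads:
        orig = score_original(read, reference, config)
        hits = ungapped_best_hits(read, altref, config)
        dec = decide(read, hits, orig, altref, config)
        if decision_rows is not None:
            dec_new = (
                (dec.chrom, dec.pos, cigar_to_string(dec.cigar))
                if dec.action == "move"
                else ("", -1, "")
            )
            decision_rows.append(
                (
                    read.name,
                    f"{region.chrom}:{region.start}-{region.end}",
                    dec.action,
                    orig,
                    dec.best_alt_mismatches,
                    read.chrom,
                    read.pos,
                    cigar_to_string(read.cigar),
                    *dec_new,
                )
            )
        if dec.action != "move":
            continue
        key = read.read_id
        new = _Proposal(
            int(dec.best_alt_mismatches or 0),
            dec.chrom,
            dec.pos,
            tuple(dec.cigar),
        )
        old = proposals.get(key)
        if old is None or new.mismatches < old.mismatches:
            proposals[key] = new
        elif new.mismatches == old.mismatches and (
            (new.chrom, new.pos, new.cigar) != (old.chrom, old.pos, old.cigar)
        ):
            old.ambiguous = True  # conflicting equal-score proposals: keep


def realign(
    bam_path: str,
    reference: Reference,
    regions: Sequence[Region],
    config: Config,
    out_path: str,
    decisions_path: Optional[str] = None,
    command_line: str = "relign",
) -> Dict:
    """Run the full pipeline and write a realigned, sorted, indexed BAM.

    Returns a run manifest with configuration, input paths and counters.
    Failures inside a region degrade to pass-through for that region.
    """
    t0 = time.time()
    chunks = split_regions(
        regions, config.max_region_length, config.split_overlap
    )
    proposals: Dict[Tuple[str, int], _Proposal] = {}
    examined: Set[Tuple[str, int]] = set()
    stats: Dict[str, int] = {"regions_abandoned": 0}
    decision_rows: Optional[List[Tuple]] = [] if decisions_path else None
    n_regions = 0
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for region in chunks:
            if region.chrom not in reference:
                log.warning("region %s not in reference; skipped", region)
                continue
            if region.chrom not in bam.references:
                log.warning("region %s not in BAM header; skipped", region)
                continue
            n_regions += 1
            try:
                _region_pipeline(
                    bam, reference, region, config, proposals, examined,
                    stats, decision_rows,
                )
            except Exception:
                log.exception("region %s failed; passing reads through", region)

    # application pass (fresh handle: until_eof iteration must start at the
    # first record, not wherever the last random-access fetch left off)
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        header = add_program_record(bam.header.to_dict(), command_line)
        records: List[pysam.AlignedSegment] = []
        moved: Dict[Tuple[str, int], Tuple[int, int, Cigar]] = {}
        tid_of = {name: i for i, name in enumerate(bam.references)}
        for rec in bam.fetch(until_eof=True):
            if not (rec.is_secondary or rec.is_supplementary or rec.is_duplicate):
                key = (rec.query_name, rec.flag & 0xC0)
                prop = proposals.get(key)
                if prop is not None and not prop.ambiguous:
                    _apply_move(rec, prop, reference, config, tid_of)
                    moved[key] = (tid_of[prop.chrom], prop.pos, list(prop.cigar))
            records.append(rec)
    _fix_mates(records, moved)
    write_realigned_bam(header, records, out_path)
    manifest = {
        "version": __version__,
        "config": {
            k: v for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {"bam": bam_path, "out": out_path},
        "counts": {
            "regions_processed": n_regions,
            "regions_abandoned": stats.get("regions_abandoned", 0),
            "reads_examined": len(examined),
            "reads_moved": len(moved),
        },
        "wall_time_sec": round(time.time() - t0, 3),
    }
    if decisions_path and decision_rows is not None:
        with open(decisions_path, "w") as fh:
            fh.write(
                "name\tregion\taction\torig_score\talt_mismatches\t"
                "old_chrom\told_pos\told_cigar\tnew_chrom\tnew_pos\tnew_cigar\n"
            )
            for row in decision_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
    return manifest


def _apply_move(
    rec: "pysam.AlignedSegment",
    prop: _Proposal,
    reference: Reference,
    config: Config,
    tid_of: Dict[str, int],
) -> None:
    was_unmapped = rec.is_unmapped
    old = (
        "unmapped"
        if was_unmapped
        else f"{rec.reference_name}:{rec.reference_start}:{rec.cigarstring}"
    )
    cigar = list(prop.cigar)
    if (
        not was_unmapped
        and rec.reference_name == prop.chrom
        and rec.reference_start == prop.pos
        and rec.cigartuples == [(CIGAR_OPS.index(op), n) for op, n in cigar]
    ):
        return
    seq = rec.query_sequence
    quals = rec.query_qualities
    rec.reference_id = tid_of[prop.chrom]
    rec.reference_start = prop.pos
    rec.cigartuples = [(CIGAR_OPS.index(op), n) for op, n in cigar]
    rec.query_sequence = seq  # setting cigar can clear seq/qual in pysam
    rec.query_qualities = quals
    rec.flag &= ~0x4
    if was_unmapped:
        rec.mapping_quality = config.mapq_default
    rec.set_tag(ORIG_ALIGNMENT_TAG, old, value_type="Z")
    nm = _nm_for(
        rec.query_sequence,
        np.asarray(rec.query_qualities, dtype=np.uint8),
        prop.chrom,
        prop.pos,
        cigar,
        reference,
    )
    rec.set_tag("NM", nm, value_type="i")


def _ref_span_end(pos: int, cigar: Sequence[Tuple[int, int]]) -> int:
    return pos + sum(n for op, n in cigar if CIGAR_OPS[op] in "MDN=X")


def _fix_mates(
    records: Sequence["pysam.AlignedSegment"],
    moved: Dict[Tuple[str, int], Tuple[int, int, Cigar]],
) -> None:
    """Refresh mate position and TLEN fields for pairs with a moved end."""
    if not moved:
        return
    moved_names = {name for name, _ in moved}
    primary: Dict[Tuple[str, int], pysam.AlignedSegment] = {}
    for rec in records:
        if rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
            continue
        if rec.is_paired and rec.query_name in moved_names:
            primary[(rec.query_name, rec.flag & 0xC0)] = rec
    for (name, bit), rec in primary.items():
        mate = primary.get((name, bit ^ 0xC0))
        if mate is None:
            continue
        if mate.is_unmapped:
            rec.mate_is_unmapped = True
            continue
        rec.next_reference_id = mate.reference_id
        rec.next_reference_start = mate.reference_start
        rec.mate_is_unmapped = False
        if (
            not rec.is_unmapped
            and rec.reference_id == mate.reference_id
        ):
            lo = min(rec.reference_start, mate.reference_start)
            hi = max(
                _ref_span_end(rec.reference_start, rec.cigartuples or []),
                _ref_span_end(mate.reference_start, mate.cigartuples or []),
            )
            tlen = hi - lo
            if rec.reference_start < mate.reference_start or (
                rec.reference_start == mate.reference_start and not rec.is_reverse
            ):
                rec.template_length = tlen
            else:
                rec.template_length = -tlen
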