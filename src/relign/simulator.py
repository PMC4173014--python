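"""Synthetic references, truth variants, reads and an indel-blind baseline
alignment, so the realigner is testable without external data.

The baseline aligner (:func:`naive_align`) places each read at its best
ungapped reference position and represents indel-spanning reads as
mismatch-laden or end-soft-clipped records — never with I/D ops — standing
in for a production mapper's output.  Read names encode the source
haplotype and sampling position so truth recovery can be measured exactly.
"""

from __future__ import annotations

import dataclasses
import os
from collections import Counter
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pysam

from relign.io_formats import (
    CIGAR_OPS,
    Cigar,
    ReadRecord,
    Region,
    _seq_array,
    write_bed,
    write_realigned_bam,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass
class TruthVariant:
    """Ground-truth record for one injected variant (reference coords)."""

    kind: str  # SNV | INS | DEL
    chrom: str
    pos: int
    length: int
    alt_seq: str = ""  # INS: inserted bases; SNV: the alternate base
    vaf: float = 1.0

    def ref_span(self) -> Tuple[int, int]:
        if self.kind == "DEL":
            return (self.pos, self.pos + self.length)
        if self.kind == "SNV":
            return (self.pos, self.pos + 1)
        return (self.pos, self.pos)


@dataclasses.dataclass
class SimRead:
    name: str
    seq: str
    quals: np.ndarray
    hap_id: str
    hap_start: int


def simulate_reference(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. random DNA at the given GC fraction; deterministic per seed."""
    if length <= 0:
        return ""
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]  # A C G T
    arr = rng.choice(_BASES, size=length, p=probs)
    return arr.tobytes().decode("ascii")


def _left_normalize(ref: str, v: TruthVariant) -> TruthVariant:
    """Shift an indel to its leftmost equivalent placement so truth
    positions are canonical."""
    if v.kind == "DEL":
        p, L = v.pos, v.length
        while p > 0 and ref[p - 1] == ref[p + L - 1]:
            p -= 1
        return dataclasses.replace(v, pos=p)
    if v.kind == "INS":
        p, s = v.pos, v.alt_seq
        while p > 0 and s and s[-1] == ref[p - 1]:
            s = ref[p - 1] + s[:-1]
            p -= 1
        return dataclasses.replace(v, pos=p, alt_seq=s)
    return v


def normalize_variants(
    ref: str,
    variants: Sequence[TruthVariant],
    seed: int = 0,
    min_spacing: Optional[int] = None,
    max_deletion: int = 2000,
    max_insertion: Optional[int] = None,
) -> List[TruthVariant]:
    """Fill in random alt sequences where missing, left-normalize indels,
    and validate bounds and spacing."""
    rng = np.random.default_rng(seed + 104729)
    out: List[TruthVariant] = []
    for v in sorted(variants, key=lambda x: x.pos):
        if v.kind not in ("SNV", "INS", "DEL"):
            raise ValueError(f"unknown variant kind {v.kind!r}")
        if v.kind == "DEL":
            if not (1 <= v.length <= max_deletion):
                raise ValueError(
                    f"DEL length {v.length} outside supported range 1..{max_deletion}"
                )
            if v.pos + v.length > len(ref):
                raise ValueError("DEL extends past reference end")
        if v.kind == "INS":
            if v.length < 1:
                raise ValueError("INS length must be >= 1")
            if max_insertion is not None and v.length >= max_insertion:
                raise ValueError(
                    f"INS length {v.length} must be < {max_insertion}"
                )
            if not v.alt_seq:
                alt = rng.choice(_BASES, size=v.length).tobytes().decode("ascii")
                v = dataclasses.replace(v, alt_seq=alt)
        if v.kind == "SNV":
            v = dataclasses.replace(v, length=1)
            if not v.alt_seq:
                choices = [b for b in "ACGT" if b != ref[v.pos]]
                v = dataclasses.replace(
                    v, alt_seq=choices[int(rng.integers(0, 3))]
                )
        out.append(_left_normalize(ref, v))
    out.sort(key=lambda x: x.pos)
    if min_spacing is not None:
        for a, b in zip(out, out[1:]):
            if b.ref_span()[0] - a.ref_span()[1] < min_spacing:
                raise ValueError(
                    f"variants at {a.pos} and {b.pos} closer than {min_spacing} bp"
                )
    return out


def apply_variants(ref: str, variants: Sequence[TruthVariant]) -> str:
    """Apply normalized variants (descending position) to the reference."""
    hap = ref
    for v in sorted(variants, key=lambda x: -x.pos):
        if v.kind == "DEL":
            hap = hap[: v.pos] + hap[v.pos + v.length :]
        elif v.kind == "INS":
            hap = hap[: v.pos] + v.alt_seq + hap[v.pos :]
        else:
            hap = hap[: v.pos] + v.alt_seq + hap[v.pos + 1 :]
    return hap


def inject_variants(
    ref: str, variant_spec: Sequence[TruthVariant], seed: int = 0
) -> Tuple[str, List[TruthVariant]]:
    """One haplotype carrying every variant in the spec, plus the
    normalized truth list in reference coordinates."""
    truth = normalize_variants(ref, variant_spec, seed)
    return apply_variants(ref, truth), truth


def build_haplotypes(
    ref: str, truth: Sequence[TruthVariant]
) -> List[Tuple[str, str, float]]:
    """Diploid haplotypes: hap "a" carries all variants, hap "b" only the
    homozygous (vaf >= 1) ones.  Returns (hap_id, sequence, weight)."""
    het = [v for v in truth if v.vaf < 1.0]
    hom = [v for v in truth if v.vaf >= 1.0]
    hap_a = apply_variants(ref, list(truth))
    if not het:
        return [("a", hap_a, 1.0)]
    hap_b = apply_variants(ref, hom)
    return [("a", hap_a, 0.5), ("b", hap_b, 0.5)]


def hap_variants(truth: Sequence[TruthVariant], hap_id: str) -> List[TruthVariant]:
    if hap_id == "a":
        return list(truth)
    return [v for v in truth if v.vaf >= 1.0]


def ref_to_hap(variants: Sequence[TruthVariant], ref_pos: int) -> int:
    """Haplotype coordinate of a reference position lying outside every
    variant span (also the junction coordinate of a variant at ref_pos)."""
    shift = 0
    for v in variants:
        if v.pos >= ref_pos:
            break
        if v.kind == "DEL" and v.pos + v.length <= ref_pos:
            shift -= v.length
        elif v.kind == "INS":
            shift += v.length
    return ref_pos + shift


def simulate_reads(
    haplotypes: Sequence[Tuple[str, str, float]],
    depth: float,
    read_length: int,
    error_rate: float = 0.005,
    seed: int = 0,
    base_quality: int = 36,
    error_quality: int = 11,
) -> List[SimRead]:
    """Uniformly sampled reads with substitution errors at low quality."""
    rng = np.random.default_rng(seed)
    reads: List[SimRead] = []
    idx = 0
    for hap_id, hap, weight in haplotypes:
        if len(hap) < read_length:
            continue
        n = int(round(depth * weight * len(hap) / read_length))
        starts = rng.integers(0, len(hap) - read_length + 1, size=n)
        for s in starts:
            s = int(s)
            arr = _seq_array(hap[s : s + read_length]).copy()
            quals = np.full(read_length, base_quality, dtype=np.uint8)
            if error_rate > 0:
                err = rng.random(read_length) < error_rate
                for i in np.flatnonzero(err):
                    cur = arr[i]
                    alt = _BASES[_BASES != cur]
                    arr[i] = alt[int(rng.integers(0, len(alt)))]
                    quals[i] = error_quality
            reads.append(
                SimRead(
                    name=f"sim{idx:06d}_{hap_id}_{s}",
                    seq=arr.tobytes().decode("ascii"),
                    quals=quals,
                    hap_id=hap_id,
                    hap_start=s,
                )
            )
            idx += 1
    return reads


class _RefIndex:
    def __init__(self, ref: str, k: int):
        self.k = k
        self.index: Dict[str, List[int]] = {}
        for i in range(len(ref) - k + 1):
            self.index.setdefault(ref[i : i + k], []).append(i)

    def lookup(self, kmer: str) -> List[int]:
        return self.index.get(kmer, [])


def naive_align(
    reads: Sequence[SimRead],
    ref: str,
    chrom: str = "chr1",
    seed_length: int = 20,
    min_clip: int = 10,
    match: int = 1,
    mismatch: int = -4,
    clip_penalty: int = 1,
    ref_index: Optional[_RefIndex] = None,
) -> List[ReadRecord]:
    """Best ungapped placement of each read against the reference.

    The representation per placement is either all-M or a single terminal
    soft clip of at least ``min_clip`` bases, whichever scores better.  No
    I or D ops are ever emitted; reads with no seed hit come out unmapped.
    """
    if ref_index is None:
        ref_index = _RefIndex(ref, seed_length)
    rarr_ref = _seq_array(ref)
    rlen = len(ref)
    out: List[ReadRecord] = []
    for read in reads:
        L = len(read.seq)
        placements: Set[int] = set()
        if L >= seed_length:
            for off in (0, (L - seed_length) // 2, L - seed_length):
                for hit in ref_index.lookup(read.seq[off : off + seed_length])[:8]:
                    p = hit - off
                    if 0 <= p <= rlen - L:
                        placements.add(p)
        best: Optional[Tuple[float, int, int, int]] = None  # score, p, clipL, clipR
        arr = _seq_array(read.seq)
        for p in sorted(placements):
            m = np.where(arr == rarr_ref[p : p + L], match, mismatch)
            pre = np.concatenate(([0], np.cumsum(m)))
            total = int(pre[L])
            cands = [(total, 0, 0)]
            max_clip = L - seed_length
            if max_clip >= min_clip:
                a = np.arange(min_clip, max_clip + 1)
                left = total - pre[a] - clip_penalty * a
                ia = int(np.argmax(left))
                cands.append((int(left[ia]), int(a[ia]), 0))
                right = pre[L - a] - clip_penalty * a
                ib = int(np.argmax(right))
                cands.append((int(right[ib]), 0, int(a[ib])))
            score, cl, cr = max(cands)
            if best is None or score > best[0]:
                best = (score, p, cl, cr)
        if best is None:
            out.append(
                ReadRecord(
                    name=read.name,
                    seq=read.seq,
                    quals=read.quals,
                    chrom=None,
                    pos=-1,
                    cigar=[],
                    mapq=0,
                    flags=0x4,
                )
            )
            continue
        _, p, cl, cr = best
        cigar: Cigar = []
        if cl:
            cigar.append(("S", cl))
        cigar.append(("M", L - cl - cr))
        if cr:
            cigar.append(("S", cr))
        out.append(
            ReadRecord(
                name=read.name,
                seq=read.seq,
                quals=read.quals,
                chrom=chrom,
                pos=p + cl,
                cigar=cigar,
                mapq=60,
                flags=0,
            )
        )
    return out


def records_to_bam(
    records: Sequence[ReadRecord], ref: str, chrom: str, out_path: str
) -> None:
    """Write ReadRecords as a coordinate-sorted, indexed BAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chrom, "LN": len(ref)}],
    }
    hdr = pysam.AlignmentHeader.from_dict(header)
    segs = []
    for r in records:
        seg = pysam.AlignedSegment(hdr)
        seg.query_name = r.name
        seg.query_sequence = r.seq
        seg.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in r.quals)
        )
        seg.flag = r.flags
        if r.chrom is not None:
            seg.reference_id = 0
            seg.reference_start = r.pos
            seg.cigartuples = [(CIGAR_OPS.index(op), n) for op, n in r.cigar]
        else:
            seg.reference_id = -1
            seg.reference_start = -1
        seg.mapping_quality = r.mapq
        seg.next_reference_id = -1
        seg.next_reference_start = -1
        segs.append(seg)
    write_realigned_bam(header, segs, out_path)


TRUTH_COLUMNS = ["chrom", "pos", "kind", "length", "alt_seq", "vaf"]


def write_truth(truth: Sequence[TruthVariant], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for v in truth:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.kind}\t{v.length}\t{v.alt_seq or '.'}\t{v.vaf}\n"
            )


def read_truth(path: str) -> List[TruthVariant]:
    out: List[TruthVariant] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == TRUTH_COLUMNS, f"unexpected truth header {header}"
        for line in fh:
            chrom, pos, kind, length, alt, vaf = line.rstrip("\n").split("\t")
            out.append(
                TruthVariant(
                    kind=kind,
                    chrom=chrom,
                    pos=int(pos),
                    length=int(length),
                    alt_seq="" if alt == "." else alt,
                    vaf=float(vaf),
                )
            )
    return out


@dataclasses.dataclass
class Simulation:
    """Paths and in-memory products of one simulated dataset."""

    ref: str
    chrom: str
    truth: List[TruthVariant]
    read_length: int
    fasta_path: str
    bam_path: str
    truth_path: str
    targets_path: str


def simulate_dataset(
    out_dir: str,
    ref_length: int,
    variants: Sequence[TruthVariant],
    depth: float = 50.0,
    read_length: int = 100,
    error_rate: float = 0.005,
    gc: float = 0.5,
    seed: int = 0,
    chrom: str = "chr1",
) -> Simulation:
    """End-to-end fixture generation: reference FASTA, naive BAM, truth TSV
    and a whole-reference targets BED."""
    os.makedirs(out_dir, exist_ok=True)
    ref = simulate_reference(ref_length, gc=gc, seed=seed)
    spec = [dataclasses.replace(v, chrom=chrom) for v in variants]
    truth = normalize_variants(
        ref, spec, seed=seed, min_spacing=read_length, max_insertion=read_length
    )
    haps = build_haplotypes(ref, truth)
    reads = simulate_reads(
        haps, depth=depth, read_length=read_length, error_rate=error_rate, seed=seed
    )
    records = naive_align(reads, ref, chrom=chrom)
    fasta_path = os.path.join(out_dir, "ref.fasta")
    with open(fasta_path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(ref), 80):
            fh.write(ref[i : i + 80] + "\n")
    pysam.faidx(fasta_path)
    bam_path = os.path.join(out_dir, "reads.bam")
    records_to_bam(records, ref, chrom, bam_path)
    truth_path = os.path.join(out_dir, "truth.tsv")
    write_truth(truth, truth_path)
    targets_path = os.path.join(out_dir, "targets.bed")
    if len(ref) > 0:
        write_bed([Region(chrom, 0, len(ref))], targets_path)
    else:
        open(targets_path, "w").close()
    return Simulation(
        ref=ref,
        chrom=chrom,
        truth=truth,
        read_length=read_length,
        fasta_path=fasta_path,
        bam_path=bam_path,
        truth_path=truth_path,
        targets_path=targets_path,
    )


def spanning_read_names(
    bam_path: str,
    variant: TruthVariant,
    truth: Sequence[TruthVariant],
    read_length: int,
    min_flank: int = 1,
) -> Set[str]:
    """Names of reads that, by construction, span the variant's junction
    with at least ``min_flank`` haplotype bases on each side."""
    carriers = {"a", "b"} if variant.vaf >= 1.0 else {"a"}
    names: Set[str] = set()
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name
            try:
                _, hap_id, start = name.rsplit("_", 2)
                s = int(start)
            except ValueError:
                continue
            if hap_id not in carriers:
                continue
            hvars = hap_variants(truth, hap_id)
            j = ref_to_hap(hvars, variant.pos)
            if variant.kind == "DEL":
                lo, hi = j, j
            elif variant.kind == "INS":
                lo, hi = j, j + variant.length
            else:
                lo, hi = j, j + 1
            if s + min_flank <= lo and s + read_length >= hi + min_flank:
                names.add(name)
    return names


def reads_carrying_indel(bam_path: str, variant: TruthVariant) -> Set[str]:
    """Names of primary reads whose CIGAR contains the exact indel op at
    the variant's (left-normalized) reference position."""
    want_op = "D" if variant.kind == "DEL" else "I"
    names: Set[str] = set()
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            if not rec.cigartuples:
                continue
            r = rec.reference_start
            for op, n in rec.cigartuples:
                opc = CIGAR_OPS[op]
                if opc == want_op and r == variant.pos and n == variant.length:
                    names.add(rec.query_name)
                    break
                if opc in "MDN=X":
                    r += n
    return names


def variant_read_recall(
    bam_path: str,
    variant: TruthVariant,
    truth: Sequence[TruthVariant],
    read_length: int,
    min_flank: int = 1,
) -> Tuple[int, int]:
    """(junction-spanning reads, those carrying the exact indel op)."""
    spanning = spanning_read_names(bam_path, variant, truth, read_length, min_flank)
    carrying = reads_carrying_indel(bam_path, variant)
    return len(spanning), len(spanning & carrying)


def pileup_base_counts(
    bam_path: str, chrom: str, positions: Iterable[int]
) -> Dict[int, Counter]:
    """Per-position Counter of aligned read bases at the given 0-based
    reference positions."""
    wanted = set(positions)
    counts: Dict[int, Counter] = {p: Counter() for p in wanted}
    if not wanted:
        return counts
    lo, hi = min(wanted), max(wanted) + 1
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        for col in bam.pileup(
            chrom, lo, hi, truncate=True, min_base_quality=0, max_depth=100000
        ):
            if col.reference_pos not in wanted:
                continue
            c = counts[col.reference_pos]
            for pread in col.pileups:
                if pread.is_del or pread.is_refskip or pread.query_position is None:
                    continue
                c[pread.alignment.query_sequence[pread.query_position]] += 1
    return counts
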