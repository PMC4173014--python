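"""Reference, target-region, and alignment-file handling.

All coordinates are 0-based half-open throughout the package; conversion to
SAM's 1-based convention happens inside pysam at the file boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pysam

log = logging.getLogger("relign")

#: CIGAR as a list of (op, length) pairs, ops drawn from MIDNSHP=X.
Cigar = List[Tuple[str, int]]

CIGAR_OPS = "MIDNSHP=X"
#: ops that consume query bases
QUERY_OPS = frozenset("MIS=X")
#: ops that consume reference bases
REF_OPS = frozenset("MDN=X")

_DEFAULT_SPLIT_OVERLAP = 200


class MissingChromosomeError(KeyError):
    """A chromosome was requested that the reference does not contain."""


class BedFormatError(ValueError):
    """A BED line could not be parsed; message cites the line number."""


@dataclasses.dataclass(frozen=True, order=True)
class Region:
    """A genomic interval targeted for assembly (0-based, half-open)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def padded(self, pad: int, chrom_length: Optional[int] = None) -> "Region":
        """Expand by ``pad`` on both sides, clamped to chromosome bounds."""
        start = max(0, self.start - pad)
        end = self.end + pad
        if chrom_length is not None:
            end = min(end, chrom_length)
        return Region(self.chrom, start, end)


@dataclasses.dataclass
class Config:
    """Tunable parameters for assembly, contig alignment and realignment.

    ``k_max=None`` resolves per region to (max read length - 1) so at least
    two k-mer windows fit in every read.
    """

    k_initial: int = 25
    k_step: int = 10
    k_max: Optional[int] = None
    min_base_quality: int = 20
    min_distinct_reads: int = 2
    max_region_length: int = 2000
    split_overlap: int = _DEFAULT_SPLIT_OVERLAP
    region_pad: int = 2000
    max_paths_per_region: int = 5000
    min_improvement: int = 1
    k_seed: int = 20
    match_score: int = 1
    mismatch_score: int = -4
    gap_open: int = 6
    gap_extend: int = 1
    min_score_fraction: float = 0.8
    max_deletion_length: int = 2000
    chimera_max_overlap: int = 10
    mapq_default: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_initial < 3 or self.k_initial % 2 == 0:
            raise ValueError("k_initial must be odd and >= 3")
        if self.min_distinct_reads < 1:
            raise ValueError("min_distinct_reads must be >= 1")
        if self.k_max is not None and self.k_max < self.k_initial:
            raise ValueError("k_max must be >= k_initial")
        if self.split_overlap >= self.max_region_length:
            raise ValueError("split_overlap must be < max_region_length")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes (non-negative)")


_ENC = "ascii"


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(_ENC), dtype=np.uint8)


@dataclasses.dataclass
class ReadRecord:
    """In-memory carrier for one sequencing read being (re)aligned.

    ``seq`` is stored in the orientation of the source BAM record, i.e.
    reference orientation for mapped reads.
    """

    name: str
    seq: str
    quals: np.ndarray  # uint8 Phred scores, len == len(seq)
    chrom: Optional[str]  # None when unmapped and unplaced
    pos: int  # 0-based; -1 when unmapped
    cigar: Cigar
    mapq: int = 0
    flags: int = 0
    mate_chrom: Optional[str] = None
    mate_pos: int = -1

    _seq_arr: Optional[np.ndarray] = dataclasses.field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.uint8)
        if len(self.quals) != len(self.seq):
            raise ValueError(f"read {self.name}: len(quals) != len(seq)")
        if self.cigar and not self.is_unmapped:
            qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
            if qlen != len(self.seq):
                raise ValueError(
                    f"read {self.name}: CIGAR query length {qlen} != "
                    f"sequence length {len(self.seq)}"
                )

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & 0x4)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flags & 0x10)

    @property
    def is_paired(self) -> bool:
        return bool(self.flags & 0x1)

    @property
    def mate_bit(self) -> int:
        """0xC0 slice of the flags: distinguishes R1 from R2."""
        return self.flags & 0xC0

    @property
    def read_id(self) -> Tuple[str, int]:
        """Identity of this sequencing read: (name, first/second-of-pair)."""
        return (self.name, self.mate_bit)

    @property
    def seq_array(self) -> np.ndarray:
        if self._seq_arr is None:
            self._seq_arr = _seq_array(self.seq)
        return self._seq_arr

    @classmethod
    def from_pysam(cls, rec: "pysam.AlignedSegment") -> "ReadRecord":
        seq = rec.query_sequence or ""
        quals = rec.query_qualities
        quals = np.asarray(quals, dtype=np.uint8) if quals is not None else np.zeros(
            len(seq), dtype=np.uint8
        )
        cigar: Cigar = []
        if rec.cigartuples:
            cigar = [(CIGAR_OPS[op], n) for op, n in rec.cigartuples]
        return cls(
            name=rec.query_name or "",
            seq=seq.upper(),
            quals=quals,
            chrom=rec.reference_name if rec.reference_id >= 0 else None,
            pos=rec.reference_start if rec.reference_id >= 0 else -1,
            cigar=cigar,
            mapq=rec.mapping_quality,
            flags=rec.flag,
            mate_chrom=rec.next_reference_name if rec.next_reference_id >= 0 else None,
            mate_pos=rec.next_reference_start if rec.next_reference_id >= 0 else -1,
        )


def cigar_to_string(cigar: Cigar) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def cigar_from_string(s: str) -> Cigar:
    out: Cigar = []
    n = ""
    for ch in s:
        if ch.isdigit():
            n += ch
        elif ch in CIGAR_OPS:
            if not n:
                raise ValueError(f"bad CIGAR string {s!r}")
            out.append((ch, int(n)))
            n = ""
        else:
            raise ValueError(f"bad CIGAR string {s!r}")
    if n:
        raise ValueError(f"bad CIGAR string {s!r}")
    return out


class Reference:
    """Whole-genome reference held in memory, sliceable by 0-based half-open
    coordinates."""

    def __init__(self, seqs: Dict[str, str]):
        self._seqs = {name: s.upper() for name, s in seqs.items()}
        self._arrays: Dict[str, np.ndarray] = {}

    @property
    def names(self) -> List[str]:
        return list(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def length(self, chrom: str) -> int:
        return len(self.get(chrom))

    def get(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise MissingChromosomeError(
                f"chromosome {chrom!r} not present in reference"
            ) from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self.get(chrom)[start:end]

    def array(self, chrom: str) -> np.ndarray:
        if chrom not in self._arrays:
            self._arrays[chrom] = _seq_array(self.get(chrom))
        return self._arrays[chrom]


def load_reference(fasta_path: str) -> Reference:
    """Load a FASTA into memory (uppercased), creating a .fai if absent."""
    if not os.path.exists(fasta_path):
        raise FileNotFoundError(fasta_path)
    if not os.path.exists(fasta_path + ".fai"):
        pysam.faidx(fasta_path)
    seqs: Dict[str, str] = {}
    with pysam.FastaFile(fasta_path) as fa:
        for name in fa.references:
            seqs[name] = fa.fetch(name)
    return Reference(seqs)


def read_target_regions(bed_path: str) -> List[Region]:
    """Parse a 3+ column BED into merged, sorted regions."""
    raw: List[Region] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(
                    f"{bed_path}:{lineno}: expected >=3 tab-separated fields"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError:
                raise BedFormatError(
                    f"{bed_path}:{lineno}: non-integer coordinates"
                ) from None
            try:
                raw.append(Region(chrom, start, end))
            except ValueError as exc:
                raise BedFormatError(f"{bed_path}:{lineno}: {exc}") from None
    return merge_regions(raw)


def merge_regions(regions: Iterable[Region]) -> List[Region]:
    """Sort by (chrom, start) and merge overlapping or abutting intervals."""
    merged: List[Region] = []
    for r in sorted(regions):
        if merged and merged[-1].chrom == r.chrom and r.start <= merged[-1].end:
            if r.end > merged[-1].end:
                merged[-1] = Region(r.chrom, merged[-1].start, r.end)
        else:
            merged.append(r)
    return merged


def write_bed(regions: Sequence[Region], path: str) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


def split_regions(
    regions: Sequence[Region],
    max_region_length: int = 2000,
    split_overlap: int = _DEFAULT_SPLIT_OVERLAP,
) -> List[Region]:
    """Chop oversized regions into chunks of at most ``max_region_length``.

    Consecutive chunks of one input overlap by ``split_overlap`` bp so that
    indels near a chunk boundary remain assemblable from one chunk or the
    other.  The union of the output equals the union of the input.
    """
    if split_overlap >= max_region_length:
        raise ValueError("split_overlap must be < max_region_length")
    out: List[Region] = []
    for r in regions:
        if r.length <= max_region_length:
            out.append(r)
            continue
        step = max_region_length - split_overlap
        pos = r.start
        while True:
            end = min(pos + max_region_length, r.end)
            out.append(Region(r.chrom, pos, end))
            if end >= r.end:
                break
            pos += step
    return out


def fetch_region_reads(
    bam: "pysam.AlignmentFile", region: Region, region_pad: int
) -> List[ReadRecord]:
    """Fetch assembly input reads for one region from an indexed BAM.

    Returns primary, non-duplicate reads overlapping the padded window.
    Placed-unmapped mates (unmapped reads carrying their mate's coordinate)
    are included so they can be rescued; secondary and supplementary
    records never are.
    """
    if not bam.has_index():
        raise ValueError(f"BAM {bam.filename!r} has no index; sort and index first")
    start = max(0, region.start - region_pad)
    end = region.end + region_pad
    out: List[ReadRecord] = []
    for rec in bam.fetch(region.chrom, start, end):
        if rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
            continue
        if not rec.query_sequence:
            continue
        out.append(ReadRecord.from_pysam(rec))
    return out


def add_program_record(header: Dict, command_line: str) -> Dict:
    """Append a @PG line describing this run to a pysam header dict."""
    from relign import __version__

    header = dict(header)
    pg = list(header.get("PG", []))
    entry = {
        "ID": "relign",
        "PN": "relign",
        "VN": __version__,
        "CL": command_line,
    }
    ids = {p.get("ID") for p in pg}
    i = 1
    while entry["ID"] in ids:
        entry["ID"] = f"relign.{i}"
        i += 1
    if pg:
        entry["PP"] = pg[-1].get("ID")
    pg.append(entry)
    header["PG"] = pg
    return header


def write_realigned_bam(
    header: Dict, records: Sequence["pysam.AlignedSegment"], out_path: str
) -> None:
    """Write records to a coordinate-sorted, indexed BAM.

    ``header`` is a pysam header dict (typically the input header with a
    program line appended via :func:`add_program_record`).
    """
    tmp = out_path + ".unsorted.tmp.bam"
    try:
        with pysam.AlignmentFile(tmp, "wb", header=header) as out:
            for rec in records:
                try:
                    out.write(rec)
                except (ValueError, TypeError) as exc:
                    raise ValueError(
                        f"cannot write record for read {rec.query_name!r}: {exc}"
                    ) from exc
        pysam.sort("-O", "bam", "-o", out_path, tmp)
    finally:
        if os.path.exists(tmp):
            os.remove(tmp)
    pysam.index(out_path)
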