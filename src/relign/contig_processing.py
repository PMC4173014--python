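"""Contig-to-reference alignment and alternate-reference construction.

Contigs are aligned into the padded local reference window with a glocal
affine-gap aligner (whole contig aligned, free reference overhangs).  For
speed, cheap exact/near-exact placements are attempted first:

* seed-anchored ungapped (substitutions-only) placement,
* seed-anchored single-indel placement (one D or I block, found in O(n)),

falling back to full dynamic programming and, for long deletions that an
affine gap cannot pay for, to a split (chimeric) alignment whose two
segments are merged into one long-deletion alignment.

Alignments that do not vary from the reference, duplicate contigs, and
contigs contained in longer retained contigs are removed; the survivors
form the alternate reference against which reads are realigned ungapped.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import Align

from relign.assembly import Contig
from relign.io_formats import Config, Reference, _seq_array

log = logging.getLogger("relign")

# Do not attempt full DP beyond this many cells; such contigs are either
# handled by the fast paths or dropped.
_MAX_DP_CELLS = 60_000_000

# Deletions longer than this are scored as split (chimeric) alignments:
# the affine gap penalty no longer applies, mirroring how a mapper would
# report two local hits.
_SPLIT_DELETION_MIN = 100


@dataclasses.dataclass
class ContigAlignment:
    """A contig's gapped alignment to the original reference.

    ``blocks`` cover the entire contig: M consumes contig and reference,
    I contig only, D reference only.  Blocks start and end with M and no
    two adjacent blocks share an op.
    """

    contig: Contig
    chrom: str
    ref_start: int
    blocks: Tuple[Tuple[str, int], ...]
    score: float

    def __post_init__(self) -> None:
        self.blocks = tuple(self.blocks)
        if not self.blocks:
            raise ValueError("empty block list")
        if self.blocks[0][0] != "M" or self.blocks[-1][0] != "M":
            raise ValueError(f"blocks must start and end with M: {self.blocks}")
        for (op1, _), (op2, _) in zip(self.blocks, self.blocks[1:]):
            if op1 == op2:
                raise ValueError(f"adjacent blocks share op: {self.blocks}")
        for op, n in self.blocks:
            if op not in "MID" or n <= 0:
                raise ValueError(f"bad block ({op},{n})")
        qlen = sum(n for op, n in self.blocks if op in "MI")
        if qlen != len(self.contig.seq):
            raise ValueError(
                f"blocks consume {qlen} contig bases, contig has "
                f"{len(self.contig.seq)}"
            )

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.blocks if op in "MD")

    @property
    def has_indel(self) -> bool:
        return any(op in "ID" for op, _ in self.blocks)

    def key(self) -> Tuple:
        return (self.chrom, self.ref_start, self.blocks, self.contig.seq)


def _merge_blocks(blocks: Sequence[Tuple[str, int]]) -> List[Tuple[str, int]]:
    out: List[Tuple[str, int]] = []
    for op, n in blocks:
        if n <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return out


def reconstruct_contig(aln: ContigAlignment, reference: Reference) -> str:
    """Rebuild the contig from the reference and the alignment blocks,
    copying reference bases under M.  Differences from ``contig.seq`` are
    exactly the substitution mismatches of the alignment."""
    ref = reference.get(aln.chrom)
    out: List[str] = []
    r = aln.ref_start
    q = 0
    for op, n in aln.blocks:
        if op == "M":
            out.append(ref[r : r + n])
            r += n
            q += n
        elif op == "I":
            out.append(aln.contig.seq[q : q + n])
            q += n
        else:  # D
            r += n
    return "".join(out)


def alignment_mismatches(aln: ContigAlignment, reference: Reference) -> int:
    """Substitution count of the alignment (M blocks only)."""
    ref_arr = reference.array(aln.chrom)
    contig_arr = _seq_array(aln.contig.seq)
    mism = 0
    r = aln.ref_start
    q = 0
    for op, n in aln.blocks:
        if op == "M":
            mism += int(np.count_nonzero(contig_arr[q : q + n] != ref_arr[r : r + n]))
            r += n
            q += n
        elif op == "I":
            q += n
        else:
            r += n
    return mism


def _make_glocal_aligner(config: Config) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = config.match_score
    a.mismatch_score = config.mismatch_score
    # First gap position costs open+extend so a length-L gap scores
    # -(open + L*extend).
    a.open_gap_score = -(config.gap_open + config.gap_extend)
    a.extend_gap_score = -config.gap_extend
    # target (reference window) overhangs at the ends are free ...
    a.end_deletion_score = 0
    # ... but the contig must be aligned end to end.
    a.end_insertion_score = -1e9
    return a


def _make_local_aligner(config: Config) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = config.match_score
    a.mismatch_score = config.mismatch_score
    a.open_gap_score = -(config.gap_open + config.gap_extend)
    a.extend_gap_score = -config.gap_extend
    return a


def _blocks_from_alignment(aln: "Align.Alignment") -> Tuple[List[Tuple[str, int]], int, int, int]:
    """Convert a biopython alignment to (blocks, ref_start, q_start, q_end)."""
    t_segs, q_segs = aln.aligned
    blocks: List[Tuple[str, int]] = []
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(t_segs, q_segs):
        if prev_t is not None:
            dt = t0 - prev_t
            dq = q0 - prev_q
            if dt > 0:
                blocks.append(("D", int(dt)))
            if dq > 0:
                blocks.append(("I", int(dq)))
        blocks.append(("M", int(t1 - t0)))
        prev_t, prev_q = t1, q1
    if not blocks:
        return [], 0, 0, 0
    return (
        _merge_blocks(blocks),
        int(t_segs[0][0]),
        int(q_segs[0][0]),
        int(q_segs[-1][1]),
    )


def align_contig(
    contig: Contig,
    ref_window_seq: str,
    ref_window_start: int,
    config: Config,
    chrom: str = "",
) -> Optional[ContigAlignment]:
    """Glocal affine-gap alignment of the full contig into the window.

    Returns None when the contig cannot be placed with score of at least
    ``min_score_fraction * len(contig)`` (or when the DP would be too
    large).
    """
    c = len(contig.seq)
    if c == 0 or c > len(ref_window_seq):
        return None
    if c * len(ref_window_seq) > _MAX_DP_CELLS:
        log.debug("contig of length %d too large for DP, skipping", c)
        return None
    aligner = _make_glocal_aligner(config)
    alns = aligner.align(ref_window_seq, contig.seq)
    score = alns.score
    if score < config.min_score_fraction * c:
        return None
    blocks, t0, q0, q1 = _blocks_from_alignment(alns[0])
    if not blocks or q0 != 0 or q1 != c:
        return None  # contig end fell in an end gap; treat as unalignable
    if blocks[0][0] != "M" or blocks[-1][0] != "M":
        return None
    for op, n in blocks:
        if op == "D" and n > config.max_deletion_length:
            return None
    return ContigAlignment(contig, chrom, ref_window_start + t0, tuple(blocks), score)


@dataclasses.dataclass
class SplitSegment:
    """One local alignment of a contig slice, input to chimeric merging."""

    chrom: str
    q_start: int
    q_end: int
    ref_start: int
    blocks: Tuple[Tuple[str, int], ...]
    score: float

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.blocks if op in "MD")


def _trim_query_prefix(
    blocks: Sequence[Tuple[str, int]], n_trim: int
) -> Tuple[List[Tuple[str, int]], int]:
    """Drop the first ``n_trim`` query bases from a block list; returns the
    trimmed blocks and the number of reference bases consumed."""
    out = list(blocks)
    ref_adv = 0
    remaining = n_trim
    while remaining > 0 and out:
        op, n = out[0]
        if op == "D":
            ref_adv += n
            out.pop(0)
            continue
        take = min(n, remaining)
        if op == "M":
            ref_adv += take
        remaining -= take
        if take == n:
            out.pop(0)
        else:
            out[0] = (op, n - take)
    while out and out[0][0] == "D":
        ref_adv += out[0][1]
        out.pop(0)
    return out, ref_adv


def combine_chimeric(
    split_alignments: Sequence[SplitSegment],
    contig: Contig,
    config: Config,
) -> Optional[ContigAlignment]:
    """Merge a prefix and a suffix local alignment of one contig into a
    single long-deletion alignment.

    Requirements: two segments on the same chromosome, ordered consistently
    on contig and reference, jointly covering the contig with overlap of at
    most ``chimera_max_overlap`` (trimmed from the suffix) or a gap of at
    most the same slack (emitted as an insertion at the junction), and an
    implied deletion of 1..max_deletion_length bp.  Returns None otherwise.
    """
    if len(split_alignments) != 2:
        return None
    a, b = split_alignments
    if a.q_start > b.q_start:
        a, b = b, a
    if a.chrom != b.chrom:
        return None
    if a.q_start != 0 or b.q_end != len(contig.seq):
        return None
    overlap = a.q_end - b.q_start  # >0: segments overlap on the contig
    if overlap > config.chimera_max_overlap:
        return None
    gap = -overlap
    if gap > config.chimera_max_overlap:
        return None
    b_blocks: List[Tuple[str, int]] = list(b.blocks)
    b_ref_start = b.ref_start
    if overlap > 0:
        b_blocks, ref_adv = _trim_query_prefix(b_blocks, overlap)
        b_ref_start += ref_adv
        if not b_blocks:
            return None
    deletion = b_ref_start - a.ref_end
    if deletion <= 0 or deletion > config.max_deletion_length:
        return None
    middle: List[Tuple[str, int]] = []
    if gap > 0:
        middle.append(("I", gap))
    middle.append(("D", deletion))
    blocks = _merge_blocks(list(a.blocks) + middle + b_blocks)
    if blocks[0][0] != "M" or blocks[-1][0] != "M":
        return None
    try:
        return ContigAlignment(
            contig, a.chrom, a.ref_start, tuple(blocks), a.score + b.score
        )
    except ValueError:
        return None


def _chimeric_align(
    contig: Contig,
    window: str,
    window_start: int,
    config: Config,
    chrom: str,
) -> Optional[ContigAlignment]:
    """Split-alignment fallback: anchor the contig with its best local hit,
    align the remainder beyond it, and merge the two segments."""
    c = len(contig.seq)
    if c * len(window) > _MAX_DP_CELLS:
        return None
    local = _make_local_aligner(config)
    alns = local.align(window, contig.seq)
    if alns.score <= 0:
        return None
    blocks, t0, q0, q1 = _blocks_from_alignment(alns[0])
    if not blocks:
        return None
    slack = config.chimera_max_overlap
    if q0 == 0 and q1 < c:
        # prefix anchored; align the remaining suffix downstream
        seg_a = SplitSegment(chrom, 0, q1, window_start + t0, tuple(blocks), alns.score)
        rest = contig.seq[q1:]
        t_end = t0 + sum(n for op, n in blocks if op in "MD")
        tail_window = window[t_end:]
        if len(rest) < 1 or len(rest) > len(tail_window):
            return None
        alns2 = local.align(tail_window, rest)
        if alns2.score <= 0:
            return None
        blocks2, t02, q02, q12 = _blocks_from_alignment(alns2[0])
        if not blocks2 or q02 > 0 or q12 < len(rest):
            return None
        seg_b = SplitSegment(
            chrom,
            q1 + q02,
            q1 + q12,
            window_start + t_end + t02,
            tuple(blocks2),
            alns2.score,
        )
        return combine_chimeric([seg_a, seg_b], contig, config)
    if q1 == c and q0 > 0:
        # suffix anchored; align the remaining prefix upstream
        seg_b = SplitSegment(chrom, q0, c, window_start + t0, tuple(blocks), alns.score)
        rest = contig.seq[:q0]
        head_window = window[:t0]
        if len(rest) < 1 or len(rest) > len(head_window):
            return None
        alns2 = local.align(head_window, rest)
        if alns2.score <= 0:
            return None
        blocks2, t02, q02, q12 = _blocks_from_alignment(alns2[0])
        if not blocks2 or q02 > 0 or q12 < len(rest):
            return None
        seg_a = SplitSegment(
            chrom, 0, q12, window_start + t02, tuple(blocks2), alns2.score
        )
        return combine_chimeric([seg_a, seg_b], contig, config)
    return None


class WindowIndex:
    """Exact-match k-mer positions of a reference window, for seeding."""

    def __init__(self, window: str, k: int):
        self.k = k
        self.window = window
        index: Dict[str, List[int]] = {}
        for i in range(len(window) - k + 1):
            index.setdefault(window[i : i + k], []).append(i)
        self.index = index

    def lookup(self, kmer: str) -> List[int]:
        return self.index.get(kmer, [])


def _candidate_frames(
    contig_seq: str, index: WindowIndex, from_end: bool, max_frames: int = 8
) -> List[int]:
    """Candidate window offsets for contig position 0, extrapolated from
    seed hits near the contig's start (or end)."""
    k = index.k
    c = len(contig_seq)
    if c < k:
        return []
    frames: List[int] = []
    seen: Set[int] = set()
    offsets = range(c - k, max(-1, c - k - 3 * k), -k) if from_end else range(0, min(c - k + 1, 3 * k), k)
    for off in offsets:
        for hit in index.lookup(contig_seq[off : off + k])[:4]:
            f = hit - off
            if f not in seen:
                seen.add(f)
                frames.append(f)
        if frames and len(frames) >= max_frames:
            break
    return frames[:max_frames]


def _frame_slice(warr: np.ndarray, origin: int, length: int) -> np.ndarray:
    """Window bytes at [origin, origin+length); out-of-bounds positions are
    zero-filled (never match a base)."""
    out = np.zeros(length, dtype=np.uint8)
    lo = max(0, origin)
    hi = min(len(warr), origin + length)
    if hi > lo:
        out[lo - origin : hi - origin] = warr[lo:hi]
    return out


def place_contig(
    contig: Contig,
    chrom: str,
    window: str,
    window_start: int,
    config: Config,
    window_index: Optional[WindowIndex] = None,
) -> Optional[ContigAlignment]:
    """Best placement of a contig into the window.

    Tries seed-anchored ungapped and single-indel placements before falling
    back to full glocal DP and finally to a chimeric split alignment.
    """
    c = len(contig.seq)
    if c == 0:
        return None
    if window_index is None:
        window_index = WindowIndex(window, config.k_seed)
    carr = _seq_array(contig.seq)
    warr = _seq_array(window)
    wlen = len(window)
    match, mism_pen = config.match_score, -config.mismatch_score
    threshold = config.min_score_fraction * c

    head = _candidate_frames(contig.seq, window_index, from_end=False)
    tail = _candidate_frames(contig.seq, window_index, from_end=True)

    best: Optional[Tuple[float, ContigAlignment]] = None

    def consider(score: float, aln: ContigAlignment) -> None:
        nonlocal best
        if best is None or score > best[0]:
            best = (score, aln)

    # 1) ungapped placement (substitutions only)
    for f in {*head, *tail}:
        if f < 0 or f + c > wlen:
            continue
        mm = int(np.count_nonzero(carr != warr[f : f + c]))
        score = (c - mm) * match - mm * mism_pen
        if score >= threshold:
            consider(
                score,
                ContigAlignment(
                    contig, chrom, window_start + f, (("M", c),), score
                ),
            )

    # 2) single-indel placement from a head/tail frame pair
    if True:
        gap_open, gap_ext = config.gap_open, config.gap_extend
        for f1 in head:
            for f2 in tail:
                d = f2 - f1
                if d == 0:
                    continue
                if d > 0:  # deletion of d reference bases
                    if d > config.max_deletion_length:
                        continue
                    if f1 < 0 or f2 + c > wlen:
                        continue
                    arr1 = _frame_slice(warr, f1, c)
                    arr2 = _frame_slice(warr, f2, c)
                    mm1 = np.concatenate(
                        ([0], np.cumsum((carr != arr1).astype(np.int32)))
                    )
                    mm2 = np.concatenate(
                        ([0], np.cumsum((carr != arr2).astype(np.int32)))
                    )
                    tot = mm1[1:c] + (mm2[c] - mm2[1:c])  # split after s bases
                    s = int(np.argmin(tot)) + 1
                    mm = int(tot[s - 1])
                    base = (c - mm) * match - mm * mism_pen
                    if d <= _SPLIT_DELETION_MIN:
                        score = base - (gap_open + gap_ext * d)
                    else:
                        # split-alignment semantics: no affine charge, but
                        # both sides must be solidly anchored
                        if min(s, c - s) < config.k_seed:
                            continue
                        score = base
                    if score < threshold:
                        continue
                    blocks = (("M", s), ("D", d), ("M", c - s))
                    consider(
                        score,
                        ContigAlignment(
                            contig, chrom, window_start + f1, blocks, score
                        ),
                    )
                else:  # insertion of -d contig bases
                    ins = -d
                    if ins >= c - 1:
                        continue
                    if f1 < 0 or f1 + (c - ins) > wlen:
                        continue
                    arr1 = _frame_slice(warr, f1, c)
                    arr2 = _frame_slice(warr, f2, c)
                    mm1 = np.concatenate(
                        ([0], np.cumsum((carr != arr1).astype(np.int32)))
                    )
                    mm2 = np.concatenate(
                        ([0], np.cumsum((carr != arr2).astype(np.int32)))
                    )
                    # insertion occupies contig [s, s+ins)
                    s_vals = np.arange(1, c - ins)
                    tot = mm1[s_vals] + (mm2[c] - mm2[s_vals + ins])
                    s = int(s_vals[int(np.argmin(tot))])
                    mm = int(tot[s - 1])
                    score = (
                        (c - ins - mm) * match
                        - mm * mism_pen
                        - (gap_open + gap_ext * ins)
                    )
                    if score < threshold:
                        continue
                    blocks = (("M", s), ("I", ins), ("M", c - s - ins))
                    consider(
                        score,
                        ContigAlignment(
                            contig, chrom, window_start + f1, blocks, score
                        ),
                    )

    if best is not None:
        return best[1]

    aln = align_contig(contig, window, window_start, config, chrom)
    if aln is not None:
        return aln
    return _chimeric_align(contig, window, window_start, config, chrom)


def left_align_indels(aln: ContigAlignment, reference: Reference) -> ContigAlignment:
    """Shift each I/D block to its leftmost equivalent placement (canonical,
    VCF-style) without changing the alignment's match structure."""
    ref = reference.get(aln.chrom)
    seq = aln.contig.seq
    blocks = [list(b) for b in aln.blocks]
    changed = False
    # absolute ref / contig offsets at each block start
    for i in range(1, len(blocks) - 1):
        op, n = blocks[i]
        if op not in "ID":
            continue
        r = aln.ref_start
        q = 0
        for bop, bn in blocks[:i]:
            if bop == "M":
                r += bn
                q += bn
            elif bop == "I":
                q += bn
            else:
                r += bn
        prev = blocks[i - 1]
        nxt = blocks[i + 1]
        if prev[0] != "M" or nxt[0] != "M":
            continue
        shift = 0
        if op == "D":
            while (
                prev[1] - shift > 1
                and r - shift - 1 >= 0
                and ref[r - shift - 1] == ref[r + n - shift - 1]
            ):
                shift += 1
        else:  # I
            while (
                prev[1] - shift > 1
                and q - shift - 1 >= 0
                and seq[q - shift - 1] == seq[q + n - shift - 1]
            ):
                shift += 1
        if shift:
            changed = True
            prev[1] -= shift
            nxt[1] += shift
    if not changed:
        return aln
    return ContigAlignment(
        aln.contig,
        aln.chrom,
        aln.ref_start,
        tuple((op, n) for op, n in blocks),
        aln.score,
    )


def deduplicate(
    alignments: Sequence[ContigAlignment], reference: Reference
) -> List[ContigAlignment]:
    """Remove reference-identical, duplicate and contained contigs."""
    varying: List[ContigAlignment] = []
    for aln in sorted(alignments, key=lambda a: (a.chrom, a.ref_start, a.contig.seq)):
        if not aln.has_indel and alignment_mismatches(aln, reference) == 0:
            continue
        varying.append(aln)
    seen: Set[str] = set()
    unique: List[ContigAlignment] = []
    for aln in varying:
        if aln.contig.seq in seen:
            continue
        seen.add(aln.contig.seq)
        unique.append(aln)
    retained: List[ContigAlignment] = []
    for aln in unique:
        contained = any(
            aln.contig.seq in other.contig.seq
            for other in unique
            if len(other.contig.seq) > len(aln.contig.seq)
        )
        if not contained:
            retained.append(aln)
    return retained


class AlternateReference:
    """Contig-derived alternate sequences plus a k-mer seed index.

    Entries are stored in one contiguous byte buffer; the index maps every
    ``k_seed``-mer of every entry to its global buffer offsets, and
    candidate read placements are validated against entry boundaries.
    """

    def __init__(self, entries: Sequence[ContigAlignment], k_seed: int):
        self.entries: List[ContigAlignment] = list(entries)
        self.k_seed = k_seed
        seqs = [e.contig.seq for e in self.entries]
        starts = [0]
        for s in seqs:
            starts.append(starts[-1] + len(s))
        self.starts = np.asarray(starts, dtype=np.int64)  # len == n_entries+1
        self.buf = (
            _seq_array("".join(seqs)) if seqs else np.zeros(0, dtype=np.uint8)
        )
        index: Dict[str, List[int]] = {}
        for ei, s in enumerate(seqs):
            base = int(self.starts[ei])
            for i in range(len(s) - k_seed + 1):
                index.setdefault(s[i : i + k_seed], []).append(base + i)
        self.index = index

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, kmer: str) -> List[int]:
        return self.index.get(kmer, [])

    def entry_of(self, global_pos: int) -> int:
        return int(np.searchsorted(self.starts, global_pos, side="right")) - 1

    def entry_bounds(self, entry_index: int) -> Tuple[int, int]:
        return int(self.starts[entry_index]), int(self.starts[entry_index + 1])


def build_alternate_reference(
    retained_alignments: Sequence[ContigAlignment], k_seed: int
) -> AlternateReference:
    """Package deduplicated alignments into an indexed alternate reference."""
    return AlternateReference(retained_alignments, k_seed)
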