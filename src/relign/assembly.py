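"""Per-region De Bruijn graph construction, pruning and contig traversal.

The graph is built from quality-filtered k-mer windows of the region's
reads.  Node support counts distinct sequencing reads (R1 and R2 of a pair
count separately).  Nodes below the support threshold are pruned, and every
remaining source-to-sink path is spelled into a contig — low-frequency
branches are deliberately kept, since they may be the variant of interest.
When the graph at the current k contains a cycle, assembly is retried at
larger k until the cycle disappears or the configured maximum k is reached.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Dict, Iterator, List, Optional, Sequence, Set, Tuple

import numpy as np

from relign.io_formats import Config, ReadRecord, Region

log = logging.getLogger("relign")

_ACGT = frozenset(b"ACGT")
_ACGT_LUT = np.zeros(256, dtype=bool)
for _b in b"ACGT":
    _ACGT_LUT[_b] = True

_COMPLEMENT = str.maketrans("ACGTN", "TACGN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PathBudgetExceeded(Exception):
    """Raised when a region's path count exceeds the traversal cap."""


@dataclasses.dataclass
class Contig:
    """A sequence spelled from one maximal path through the k-mer graph."""

    seq: str
    region: Optional[Region]
    k_used: int


class KmerGraph:
    """Directed De Bruijn graph over k-mers with distinct-read support.

    ``support`` maps each k-mer to the number of distinct sequencing reads
    containing it; ``edges`` holds the observed (k-1)-overlap successor
    links.
    """

    __slots__ = ("k", "support", "edges")

    def __init__(
        self,
        k: int,
        support: Optional[Dict[str, int]] = None,
        edges: Optional[Dict[str, Set[str]]] = None,
    ):
        self.k = k
        self.support: Dict[str, int] = support or {}
        self.edges: Dict[str, Set[str]] = edges or {}

    def __len__(self) -> int:
        return len(self.support)

    def successors(self, node: str) -> Set[str]:
        return self.edges.get(node, set())

    def in_degrees(self) -> Dict[str, int]:
        indeg = {n: 0 for n in self.support}
        for node, succs in self.edges.items():
            for s in succs:
                indeg[s] += 1
        return indeg

    def sources(self) -> List[str]:
        return sorted(n for n, d in self.in_degrees().items() if d == 0)


def _window_ok(read: ReadRecord, k: int, min_base_quality: int) -> np.ndarray:
    """Boolean per-position array: window [i, i+k) has no low-quality or
    non-ACGT base."""
    n = len(read.seq)
    if n < k:
        return np.zeros(0, dtype=bool)
    base_ok = _ACGT_LUT[read.seq_array] & (read.quals >= min_base_quality)
    # window ok iff all k bases ok: prefix-sum trick
    cs = np.concatenate(([0], np.cumsum(base_ok.astype(np.int32))))
    return (cs[k:] - cs[:-k]) == k


def _kmer_windows(
    read: ReadRecord, k: int, min_base_quality: int
) -> Iterator[Tuple[int, str]]:
    ok = _window_ok(read, k, min_base_quality)
    seq = read.seq
    for i in np.flatnonzero(ok):
        yield int(i), seq[i : i + k]


def extract_kmers(read: ReadRecord, k: int, min_base_quality: int) -> List[str]:
    """The read's k-length windows, excluding any window containing a base
    below ``min_base_quality`` or a non-ACGT character."""
    if k < 3:
        raise ValueError("k must be >= 3")
    return [kmer for _, kmer in _kmer_windows(read, k, min_base_quality)]


def build_graph(
    reads: Sequence[ReadRecord], k: int, min_base_quality: int
) -> KmerGraph:
    """Assemble the k-mer graph from reads.

    A k-mer occurring several times within one read contributes a single
    unit of support; edges link windows that were adjacent in at least one
    read.
    """
    seen: Dict[str, Set[Tuple[str, int]]] = {}
    edges: Dict[str, Set[str]] = {}
    for read in reads:
        rid = read.read_id
        prev_pos = -2
        prev_kmer = ""
        for pos, kmer in _kmer_windows(read, k, min_base_quality):
            seen.setdefault(kmer, set()).add(rid)
            if pos == prev_pos + 1:
                edges.setdefault(prev_kmer, set()).add(kmer)
            prev_pos, prev_kmer = pos, kmer
    support = {kmer: len(ids) for kmer, ids in seen.items()}
    return KmerGraph(k, support, edges)


def prune_graph(graph: KmerGraph, min_distinct_reads: int) -> KmerGraph:
    """Drop k-mers supported by fewer than ``min_distinct_reads`` distinct
    reads, along with their incident edges."""
    support = {
        kmer: n for kmer, n in graph.support.items() if n >= min_distinct_reads
    }
    edges: Dict[str, Set[str]] = {}
    for node, succs in graph.edges.items():
        if node not in support:
            continue
        kept = {s for s in succs if s in support}
        if kept:
            edges[node] = kept
    return KmerGraph(graph.k, support, edges)


def has_cycle(graph: KmerGraph) -> bool:
    """Iterative three-colour DFS cycle check."""
    WHITE, GREY, BLACK = 0, 1, 2
    color = dict.fromkeys(graph.support, WHITE)
    for root in graph.support:
        if color[root] != WHITE:
            continue
        stack: List[Tuple[str, Iterator[str]]] = [(root, iter(graph.successors(root)))]
        color[root] = GREY
        while stack:
            node, it = stack[-1]
            nxt = next(it, None)
            if nxt is None:
                color[node] = BLACK
                stack.pop()
                continue
            c = color.get(nxt, BLACK)
            if c == GREY:
                return True
            if c == WHITE:
                color[nxt] = GREY
                stack.append((nxt, iter(graph.successors(nxt))))
    return False


def enumerate_contigs(
    graph: KmerGraph,
    min_contig_length: int,
    max_paths: int,
    region: Optional[Region] = None,
) -> List[Contig]:
    """Spell every maximal source-to-sink path into a contig.

    The graph must be acyclic.  Traversal order is lexicographic over node
    strings so output is deterministic.  Raises :class:`PathBudgetExceeded`
    once more than ``max_paths`` maximal paths have been seen (the caller
    abandons the region).
    """
    contigs: List[Contig] = []
    n_paths = 0
    for source in graph.sources():
        # path spelled as: source + one base per traversed edge
        tail: List[str] = []
        stack: List[Iterator[str]] = [iter(sorted(graph.successors(source)))]
        if not graph.successors(source):
            n_paths += 1
            if len(source) >= min_contig_length:
                contigs.append(Contig(source, region, graph.k))
            continue
        while stack:
            nxt = next(stack[-1], None)
            if nxt is None:
                stack.pop()
                if tail:
                    tail.pop()
                continue
            tail.append(nxt[-1])
            succs = graph.successors(nxt)
            if succs:
                stack.append(iter(sorted(succs)))
            else:
                n_paths += 1
                if n_paths > max_paths:
                    raise PathBudgetExceeded(
                        f"more than {max_paths} paths in region {region}"
                    )
                seq = source + "".join(tail)
                if len(seq) >= min_contig_length:
                    contigs.append(Contig(seq, region, graph.k))
                tail.pop()
    return contigs


def _orient_unmapped(
    reads: Sequence[ReadRecord], k: int, min_base_quality: int
) -> List[ReadRecord]:
    """Choose the orientation of each unmapped read that shares more
    surviving k-mers with the mapped reads; mapped reads pass through in
    their aligned orientation."""
    mapped = [r for r in reads if not r.is_unmapped]
    unmapped = [r for r in reads if r.is_unmapped]
    if not unmapped:
        return list(reads)
    mapped_kmers: Set[str] = set()
    for r in mapped:
        mapped_kmers.update(extract_kmers(r, k, min_base_quality))
    out = list(mapped)
    for r in unmapped:
        fwd = extract_kmers(r, k, min_base_quality)
        rc_read = dataclasses.replace(
            r,
            seq=reverse_complement(r.seq),
            quals=r.quals[::-1].copy(),
            _seq_arr=None,
        )
        rev = extract_kmers(rc_read, k, min_base_quality)
        n_fwd = sum(km in mapped_kmers for km in fwd)
        n_rev = sum(km in mapped_kmers for km in rev)
        out.append(rc_read if n_rev > n_fwd else r)
    return out


def assemble_region(
    reads: Sequence[ReadRecord],
    config: Config,
    region: Optional[Region] = None,
    stats: Optional[Dict[str, int]] = None,
) -> List[Contig]:
    """Run extract -> build -> prune -> traverse for one region.

    Escalates k by ``k_step`` while the pruned graph is cyclic.  Failures
    (persistent cycle at k_max, path budget exceeded, empty graph) yield an
    empty contig list; the region's reads then keep their original
    alignments.
    """
    if stats is None:
        stats = {}
    if not reads:
        return []
    max_read_len = max(len(r.seq) for r in reads)
    k_max = config.k_max if config.k_max is not None else max_read_len - 1
    k = min(config.k_initial, k_max)
    if k < 3:
        return []
    oriented = _orient_unmapped(reads, k, config.min_base_quality)
    while True:
        graph = prune_graph(
            build_graph(oriented, k, config.min_base_quality),
            config.min_distinct_reads,
        )
        if not graph.support:
            return []
        if not has_cycle(graph):
            break
        if k + config.k_step > k_max:
            log.info("region %s: cycle persists at k_max=%d, abandoning", region, k)
            stats["regions_abandoned"] = stats.get("regions_abandoned", 0) + 1
            return []
        k += config.k_step
        log.debug("region %s: cycle at k=%d, retrying at k=%d", region, k - config.k_step, k)
    try:
        contigs = enumerate_contigs(
            graph, max_read_len + 1, config.max_paths_per_region, region
        )
    except PathBudgetExceeded as exc:
        log.info("region %s: %s, abandoning", region, exc)
        stats["regions_abandoned"] = stats.get("regions_abandoned", 0) + 1
        return []
    contigs.sort(key=lambda c: c.seq)
    return contigs
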