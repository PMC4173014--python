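import math
from collections import Counter

import numpy as np
import pysam
import pytest

from relign.assembly import Contig
from relign.contig_processing import ContigAlignment, build_alternate_reference
from relign.io_formats import (
    Config,
    Reference,
    cigar_to_string,
    load_reference,
    read_target_regions,
)
from relign.realignment import (
    RealignmentDecision,
    UngappedHit,
    _fix_mates,
    count_mismatches,
    decide,
    project_to_reference,
    realign,
    score_original,
    ungapped_best_hits,
)
from relign.simulator import (
    TruthVariant,
    variant_read_recall,
)

from conftest import make_read, run_pipeline


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _alt_from_seqs(seqs, k_seed=20, ref_start=0):
    alns = []
    for s in seqs:
        alns.append(
            ContigAlignment(Contig(s, None, 25), "chr1", ref_start, (("M", len(s)),), len(s))
        )
    return build_alternate_reference(alns, k_seed)


# ------------------------------------------------------------ count_mismatches


def test_count_mismatches_identical():
    q = np.full(4, 30, dtype=np.uint8)
    assert count_mismatches("ACGT", "ACGT", q, 20) == 0


def test_count_mismatches_high_quality_difference():
    q = np.full(4, 30, dtype=np.uint8)
    assert count_mismatches("ACGT", "AGGT", q, 20) == 1


def test_count_mismatches_low_quality_masked():
    q = np.array([30, 10, 30, 30], dtype=np.uint8)
    assert count_mismatches("ACGT", "AGGT", q, 20) == 0


def test_count_mismatches_n_counts():
    q = np.full(4, 30, dtype=np.uint8)
    assert count_mismatches("ANGT", "ANGT", q, 20) == 1  # N vs N still mismatch


def test_count_mismatches_length_error():
    with pytest.raises(ValueError):
        count_mismatches("ACG", "ACGT", np.full(3, 30, dtype=np.uint8), 20)


# ------------------------------------------------------------ ungapped hits


def test_ungapped_verbatim_read_single_hit():
    rng = np.random.default_rng(0)
    entry = _rand_seq(rng, 200)
    alt = _alt_from_seqs([entry])
    read = make_read("r", entry[50:150])
    hits = ungapped_best_hits(read, alt, Config())
    assert len(hits) == 1
    assert hits[0] == UngappedHit(0, 50, 0)


def test_ungapped_equidistant_tie_returned():
    rng = np.random.default_rng(1)
    core = _rand_seq(rng, 60)
    entry = core + _rand_seq(rng, 30) + core
    alt = _alt_from_seqs([entry])
    read = make_read("r", core[:40])
    hits = ungapped_best_hits(read, alt, Config())
    assert {h.offset for h in hits} == {0, 90}
    assert all(h.mismatches == 0 for h in hits)


def test_ungapped_no_shared_kmer_empty():
    rng = np.random.default_rng(2)
    alt = _alt_from_seqs([_rand_seq(rng, 200)])
    read = make_read("r", _rand_seq(np.random.default_rng(77), 100))
    assert ungapped_best_hits(read, alt, Config()) == []


def test_ungapped_short_read_empty():
    rng = np.random.default_rng(3)
    alt = _alt_from_seqs([_rand_seq(rng, 200)])
    read = make_read("r", "ACGTACGTAC")  # shorter than k_seed
    assert ungapped_best_hits(read, alt, Config()) == []


# ------------------------------------------------------------ score_original


def test_score_original_perfect_match():
    rng = np.random.default_rng(4)
    chrom = _rand_seq(rng, 300)
    ref = Reference({"chr1": chrom})
    read = make_read("r", chrom[100:200], pos=100)
    assert score_original(read, ref, Config()) == 0


def test_score_original_softclip_penalty():
    rng = np.random.default_rng(5)
    chrom = _rand_seq(rng, 300)
    ref = Reference({"chr1": chrom})
    seq = _rand_seq(np.random.default_rng(88), 20) + chrom[100:180]
    read = make_read("r", seq, pos=100, cigar=[("S", 20), ("M", 80)])
    assert score_original(read, ref, Config()) == 20


def test_score_original_unmapped_infinite():
    ref = Reference({"chr1": "ACGT" * 100})
    read = make_read("r", "ACGT" * 25, flags=0x4)
    assert math.isinf(score_original(read, ref, Config()))


# ------------------------------------------------------------ projection


def test_project_read_inside_m_block():
    rng = np.random.default_rng(6)
    contig_seq = _rand_seq(rng, 300)
    aln = ContigAlignment(
        Contig(contig_seq, None, 25), "chr1", 1000, (("M", 300),), 300
    )
    proj = project_to_reference(UngappedHit(0, 40, 0), aln, 100)
    assert proj == ("chr1", 1040, [("M", 100)])


def test_project_offset_shifts_through_prior_indels():
    rng = np.random.default_rng(7)
    contig_seq = _rand_seq(rng, 300)
    # blocks: 100M 8I 192M -> read at contig offset 150 sits 42 into 2nd M
    aln = ContigAlignment(
        Contig(contig_seq, None, 25), "chr1", 1000,
        (("M", 100), ("I", 8), ("M", 192)), 0,
    )
    proj = project_to_reference(UngappedHit(0, 150, 0), aln, 100)
    assert proj == ("chr1", 1000 + 100 + 42, [("M", 100)])


def test_project_read_spanning_long_deletion():
    rng = np.random.default_rng(8)
    chrom = _rand_seq(rng, 5000)
    ref = Reference({"chr1": chrom})
    contig_seq = chrom[500:1000] + chrom[3000:3500]
    aln = ContigAlignment(
        Contig(contig_seq, None, 25), "chr1", 500,
        (("M", 500), ("D", 2000), ("M", 500)), 0,
    )
    proj = project_to_reference(UngappedHit(0, 460, 0), aln, 100)
    assert proj == ("chr1", 960, [("M", 40), ("D", 2000), ("M", 60)])
    # reconstruction oracle: reference bases consumed by the CIGAR equal
    # the read (= contig slice) bases under every M op
    chrom_pos = proj[1]
    read = contig_seq[460:560]
    q = 0
    r = chrom_pos
    for op, n in proj[2]:
        if op == "M":
            assert chrom[r : r + n] == read[q : q + n]
            r += n
            q += n
        elif op == "D":
            r += n
    assert q == 100


def test_project_read_starting_inside_insertion_clips():
    rng = np.random.default_rng(9)
    chrom = _rand_seq(rng, 1000)
    ins = _rand_seq(np.random.default_rng(10), 8)
    contig_seq = chrom[100:200] + ins + chrom[200:300]
    aln = ContigAlignment(
        Contig(contig_seq, None, 25), "chr1", 100,
        (("M", 100), ("I", 8), ("M", 100)), 0,
    )
    # read starts 5 bases into the insertion: 3 insertion bases remain at
    # the read's head and become a soft clip
    proj = project_to_reference(UngappedHit(0, 105, 0), aln, 50)
    assert proj is not None
    chrom_out, pos, cigar = proj
    assert cigar[0] == ("S", 3)
    assert pos == 200
    assert cigar == [("S", 3), ("M", 47)]


def test_project_read_ending_inside_insertion_clips():
    rng = np.random.default_rng(11)
    chrom = _rand_seq(rng, 1000)
    ins = _rand_seq(np.random.default_rng(12), 8)
    contig_seq = chrom[100:200] + ins + chrom[200:300]
    aln = ContigAlignment(
        Contig(contig_seq, None, 25), "chr1", 100,
        (("M", 100), ("I", 8), ("M", 100)), 0,
    )
    proj = project_to_reference(UngappedHit(0, 55, 0), aln, 50)
    assert proj == ("chr1", 155, [("M", 45), ("S", 5)])


def test_project_fully_inside_insertion_rejected():
    rng = np.random.default_rng(13)
    chrom = _rand_seq(rng, 1000)
    ins = _rand_seq(np.random.default_rng(14), 60)
    contig_seq = chrom[100:200] + ins + chrom[200:300]
    aln = ContigAlignment(
        Contig(contig_seq, None, 25), "chr1", 100,
        (("M", 100), ("I", 60), ("M", 100)), 0,
    )
    assert project_to_reference(UngappedHit(0, 105, 0), aln, 50) is None


# ------------------------------------------------------------ decide


def _simple_alt(chrom_seq, contig_seq, blocks, ref_start, k_seed=20):
    aln = ContigAlignment(Contig(contig_seq, None, 25), "chr1", ref_start, blocks, 0)
    return build_alternate_reference([aln], k_seed)


def test_decide_clear_win_moves():
    rng = np.random.default_rng(15)
    chrom = _rand_seq(rng, 600)
    contig_seq = chrom[100:250] + chrom[300:450]  # 50 bp deletion
    alt = _simple_alt(chrom, contig_seq, (("M", 150), ("D", 50), ("M", 150)), 100)
    read = make_read("r", contig_seq[100:200], pos=150)
    hits = ungapped_best_hits(read, alt, Config())
    ref = Reference({"chr1": chrom})
    orig = score_original(read, ref, Config())
    assert orig >= 5  # frame-shifted tail mismatches
    dec = decide(read, hits, orig, alt, Config())
    assert dec.action == "move"
    assert dec.pos == 200
    assert dec.cigar == [("M", 50), ("D", 50), ("M", 50)]


def test_decide_ambiguous_tie_keeps():
    rng = np.random.default_rng(16)
    core = _rand_seq(rng, 80)
    entry = core + _rand_seq(rng, 40) + core
    alt = _alt_from_seqs([entry])
    read = make_read("r", core[10:70], pos=0)
    hits = ungapped_best_hits(read, alt, Config())
    assert len(hits) == 2
    dec = decide(read, hits, 10.0, alt, Config())
    assert dec.action == "keep"


def test_decide_no_strict_improvement_keeps():
    rng = np.random.default_rng(17)
    entry = _rand_seq(rng, 200)
    alt = _alt_from_seqs([entry])
    # read matches the entry with 3 high-quality mismatches
    seq = list(entry[50:150])
    for i in (10, 30, 60):
        seq[i] = "A" if seq[i] != "A" else "C"
    read = make_read("r", "".join(seq), pos=123)
    hits = ungapped_best_hits(read, alt, Config())
    assert hits and hits[0].mismatches == 3
    dec = decide(read, hits, 3.0, alt, Config())
    assert dec.action == "keep"


def test_decide_same_alignment_is_keep():
    rng = np.random.default_rng(18)
    entry = _rand_seq(rng, 200)
    alt = _alt_from_seqs([entry], ref_start=0)
    read = make_read("r", entry[50:150], pos=50)
    hits = ungapped_best_hits(read, alt, Config())
    dec = decide(read, hits, 5.0, alt, Config())
    assert dec.action == "keep"  # projection equals current alignment


def test_decide_unmapped_read_rescued():
    rng = np.random.default_rng(19)
    chrom = _rand_seq(rng, 600)
    contig_seq = chrom[100:250] + chrom[300:450]
    alt = _simple_alt(chrom, contig_seq, (("M", 150), ("D", 50), ("M", 150)), 100)
    read = make_read("um", contig_seq[120:220], flags=0x4)
    ref = Reference({"chr1": chrom})
    hits = ungapped_best_hits(read, alt, Config())
    dec = decide(read, hits, score_original(read, ref, Config()), alt, Config())
    assert dec.action == "move"
    assert dec.pos == 220


# ------------------------------------------------------------ end to end


def test_del50_read_recall(del50_run):
    v = del50_run.sim.truth[0]
    n_span, n_carry = variant_read_recall(
        del50_run.out_bam, v, del50_run.sim.truth, del50_run.sim.read_length
    )
    assert n_span > 0
    assert n_carry / n_span >= 0.9


def test_ins25_read_recall(ins25_run):
    v = ins25_run.sim.truth[0]
    n_span, n_carry = variant_read_recall(
        ins25_run.out_bam, v, ins25_run.sim.truth, ins25_run.sim.read_length
    )
    assert n_span > 0
    assert n_carry / n_span >= 0.8


def _bam_payloads(path):
    out = {}
    with pysam.AlignmentFile(path) as bam:
        for rec in bam.fetch(until_eof=True):
            key = (rec.query_name, rec.flag & 0xC0)
            out[key] = (rec.query_sequence, tuple(rec.query_qualities))
    return out


def test_conservation_names_seq_quals(del50_run):
    pre = _bam_payloads(del50_run.sim.bam_path)
    post = _bam_payloads(del50_run.out_bam)
    assert set(pre) == set(post)
    for key in pre:
        assert pre[key] == post[key]
    # name multiset equality (record counts)
    with pysam.AlignmentFile(del50_run.sim.bam_path) as b1, pysam.AlignmentFile(
        del50_run.out_bam
    ) as b2:
        names1 = Counter(r.query_name for r in b1.fetch(until_eof=True))
        names2 = Counter(r.query_name for r in b2.fetch(until_eof=True))
    assert names1 == names2


def test_cigar_query_arithmetic_every_record(del50_run):
    with pysam.AlignmentFile(del50_run.out_bam) as bam:
        n = 0
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            qlen = sum(
                ln for op, ln in rec.cigartuples if op in (0, 1, 4, 7, 8)
            )
            assert qlen == len(rec.query_sequence)
            assert rec.reference_end <= 8000
            n += 1
        assert n > 0


def test_non_degradation_of_moved_reads(del50_run):
    """For every moved read, the quality-masked mismatch count of its new
    alignment (M bases vs the reference) is strictly lower than the score
    of its original alignment."""
    from relign.io_formats import ReadRecord, cigar_from_string

    ref = load_reference(del50_run.sim.fasta_path)
    cfg = del50_run.config
    chrom_seq = ref.get("chr1")
    moved = 0
    with pysam.AlignmentFile(del50_run.out_bam) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or not rec.has_tag("YO"):
                continue
            moved += 1
            quals = np.asarray(rec.query_qualities, dtype=np.uint8)
            new_mism = 0
            r = rec.reference_start
            q = 0
            for op, n in rec.cigartuples:
                opc = "MIDNSHP=X"[op]
                if opc == "M":
                    new_mism += count_mismatches(
                        rec.query_sequence[q : q + n],
                        chrom_seq[r : r + n],
                        quals[q : q + n],
                        cfg.min_base_quality,
                    )
                    r += n
                    q += n
                elif opc in "IS":
                    q += n
                elif opc in "DN":
                    r += n
            tag = rec.get_tag("YO")
            if tag == "unmapped":
                continue  # original score is +inf: trivially improved
            chrom, pos, cigstr = tag.split(":")
            orig = ReadRecord(
                name=rec.query_name,
                seq=rec.query_sequence,
                quals=quals,
                chrom=chrom,
                pos=int(pos),
                cigar=cigar_from_string(cigstr),
                flags=0,
            )
            assert new_mism < score_original(orig, ref, cfg)
    assert moved > 0


def test_idempotence_second_pass_moves_nothing(del50_run, tmp_path):
    ref = load_reference(del50_run.sim.fasta_path)
    regions = read_target_regions(del50_run.sim.targets_path)
    out2 = str(tmp_path / "second.bam")
    manifest = realign(del50_run.out_bam, ref, regions, del50_run.config, out2)
    assert manifest["counts"]["reads_moved"] == 0


def test_no_target_reads_passthrough(tmp_path, del50_run):
    """Regions far from any read leave the BAM unchanged."""
    ref = load_reference(del50_run.sim.fasta_path)
    from relign.io_formats import Region

    out = str(tmp_path / "pt.bam")
    manifest = realign(
        del50_run.sim.bam_path, ref, [Region("chr1", 7900, 7999)],
        del50_run.config, out,
    )
    assert manifest["counts"]["reads_moved"] == 0
    assert _bam_payloads(out) == _bam_payloads(del50_run.sim.bam_path)


# ------------------------------------------------------------ sweep

DEL_LENGTHS = [1, 10, 50, 500, 2000]
INS_LENGTHS = [1, 10, 25]


@pytest.mark.parametrize("length", DEL_LENGTHS)
def test_parameter_recovery_deletions(tmp_path, length):
    run = run_pipeline(
        tmp_path, [TruthVariant("DEL", "chr1", 4000, length)], seed=21 + length
    )
    v = run.sim.truth[0]
    n_span, n_carry = variant_read_recall(run.out_bam, v, run.sim.truth, 100)
    assert n_span > 0
    assert n_carry >= 1
    if length >= 10:
        assert n_carry / n_span >= 0.8


@pytest.mark.parametrize("length", INS_LENGTHS)
def test_parameter_recovery_insertions(tmp_path, length):
    run = run_pipeline(
        tmp_path, [TruthVariant("INS", "chr1", 4000, length)], seed=43 + length
    )
    v = run.sim.truth[0]
    n_span, n_carry = variant_read_recall(run.out_bam, v, run.sim.truth, 100)
    assert n_span > 0
    assert n_carry >= 1
    if length >= 10:
        assert n_carry / n_span >= 0.8


# ------------------------------------------------------------ mates


def test_fix_mates_updates_pnext_and_tlen():
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10000}]}
    )

    def seg(name, flag, pos):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.query_sequence = "A" * 50
        a.query_qualities = pysam.qualitystring_to_array("I" * 50)
        a.flag = flag
        a.reference_id = 0
        a.reference_start = pos
        a.cigartuples = [(0, 50)]
        a.next_reference_id = 0
        return a

    r1 = seg("p", 0x1 | 0x40, 150)  # moved from 100 to 150 already
    r2 = seg("p", 0x1 | 0x80 | 0x10, 300)
    r1.next_reference_start = 300
    r2.next_reference_start = 100  # stale
    _fix_mates([r1, r2], {("p", 0x40): (0, 150, [("M", 50)])})
    assert r2.next_reference_start == 150
    assert r1.next_reference_start == 300
    assert r1.template_length == 200
    assert r2.template_length == -200
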