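import numpy as np
import pytest

from plastidflip import ir_assembly
from plastidflip.genome import build_genome
from plastidflip.reads import LongRead, simulate_reads
from plastidflip.sequtil import revcomp


def test_pseudoref_lengths_full():
    g = build_genome(seed=1)
    ira, irb = ir_assembly.build_ir_pseudorefs(g, 2000)
    assert len(ira.seq) == 21_552 + 4000 == 25_552
    assert len(irb.seq) == 21_553 + 4000 == 25_553


def test_pseudoref_flank_zero(mid_genome):
    ira, irb = ir_assembly.build_ir_pseudorefs(mid_genome, 0)
    assert ira.seq == mid_genome.region_seq("IRa")
    assert irb.seq == mid_genome.region_seq("IRb")


def test_pseudoref_toy_lengths():
    g = build_genome(3000, 500, 2500, 500, n_ir_diffs=0, seed=0)
    ira, _ = ir_assembly.build_ir_pseudorefs(g, 2000)
    assert len(ira.seq) == 4500


def test_pseudoref_flank_too_large(small_genome):
    with pytest.raises(ValueError):
        ir_assembly.build_ir_pseudorefs(small_genome, 1600)  # SSC is 1500


def test_pseudoref_irb_wraps_origin(mid_genome):
    _, irb = ir_assembly.build_ir_pseudorefs(mid_genome, 2000)
    assert irb.seq.endswith(mid_genome.seq[:2000])


def test_assign_junction_read(mid_genome):
    ira_s, _ = mid_genome.regions["IRa"]
    read = mid_genome.seq[ira_s - 1000 : ira_s + 1000]  # spans LSC->IRa
    prs = ir_assembly.build_ir_pseudorefs(mid_genome, 2000)
    assert ir_assembly.assign_ir(read, prs, 500) == "IRa"
    irb_s, _ = mid_genome.regions["IRb"]
    read_b = mid_genome.seq[irb_s - 1000 : irb_s + 1000]  # spans SSC->IRb
    assert ir_assembly.assign_ir(read_b, prs, 500) == "IRb"


def test_assign_interior_ambiguous(mid_genome):
    ira_s, ira_e = mid_genome.regions["IRa"]
    read = mid_genome.seq[ira_s + 500 : ira_e - 500]
    prs = ir_assembly.build_ir_pseudorefs(mid_genome, 2000)
    assert ir_assembly.assign_ir(read, prs, 500) == "ambiguous"


def test_assign_symmetry_under_label_swap(mid_genome):
    prs = ir_assembly.build_ir_pseudorefs(mid_genome, 2000)
    a, b = prs
    swapped = (
        ir_assembly.IrPseudoRef("IRa", b.seq, b.flank, b.ir_len),
        ir_assembly.IrPseudoRef("IRb", a.seq, a.flank, a.ir_len),
    )
    rs = simulate_reads(mid_genome, depth=6, read_len_mean=2500, read_len_sd=200,
                        isomer_ratio=0.5, seed=8)
    asg1 = ir_assembly.IrAssigner(prs)
    asg2 = ir_assembly.IrAssigner(swapped)
    flip = {"IRa": "IRb", "IRb": "IRa", "ambiguous": "ambiguous"}
    for r in rs.reads:
        assert asg2.assign(r, 500) == flip[asg1.assign(r, 500)]


def test_assignment_balance(mid_genome):
    """|IRa| ~ |IRb| in expectation for any isomer mixture (3 SE)."""
    for ratio in (0.0, 0.5, 1.0):
        rs = simulate_reads(mid_genome, depth=40, read_len_mean=1500,
                            read_len_sd=100, isomer_ratio=ratio, seed=int(ratio * 10))
        asg = ir_assembly.IrAssigner(ir_assembly.build_ir_pseudorefs(mid_genome, 2000))
        counts = {"IRa": 0, "IRb": 0, "ambiguous": 0}
        for r in rs.reads:
            counts[asg.assign(r, 500)] += 1
        n = counts["IRa"] + counts["IRb"]
        assert n > 100
        assert abs(counts["IRa"] - n / 2) <= 3 * np.sqrt(n * 0.25)


def test_consensus_error_free_equals_pseudoref(mid_genome):
    prs = ir_assembly.build_ir_pseudorefs(mid_genome, 2000)
    asg = ir_assembly.IrAssigner(prs)
    rs = simulate_reads(mid_genome, depth=50, read_len_mean=4000, read_len_sd=300,
                        isomer_ratio=0.0, seed=9)
    ira_reads = [r for r in rs.reads if asg.assign(r, 500) == "IRa"]
    cons, support = ir_assembly.consensus_assembly(ira_reads, prs[0])
    assert cons == prs[0].seq
    assert support.sum() > 0


def test_consensus_with_errors_equals_truth(mid_genome):
    prs = ir_assembly.build_ir_pseudorefs(mid_genome, 2000)
    asg = ir_assembly.IrAssigner(prs)
    rs = simulate_reads(mid_genome, depth=80, read_len_mean=4000, read_len_sd=300,
                        isomer_ratio=0.0, error_rate=0.02, seed=10)
    ira_reads = [r for r in rs.reads if asg.assign(r, 500) == "IRa"]
    cons, _ = ir_assembly.consensus_assembly(ira_reads, prs[0])
    assert cons == prs[0].seq


def test_consensus_zero_coverage_is_n(mid_genome):
    prs = ir_assembly.build_ir_pseudorefs(mid_genome, 2000)
    # single read covering only the middle of the pseudoref
    read = LongRead(id="r", seq=prs[0].seq[3000:6000])
    cons, support = ir_assembly.consensus_assembly([read], prs[0])
    assert cons[:2900].count("N") > 2800
    assert "N" not in cons[3100:5900]
    assert support[:2990].sum() == 0


def test_consensus_no_reads_errors(mid_genome):
    prs = ir_assembly.build_ir_pseudorefs(mid_genome, 2000)
    with pytest.raises(ValueError):
        ir_assembly.consensus_assembly([], prs[0])


def test_consensus_idempotent(mid_genome):
    """Reads simulated from the consensus reproduce the consensus."""
    prs = ir_assembly.build_ir_pseudorefs(mid_genome, 1000)
    src = prs[0].seq
    starts = list(range(0, len(src) - 2000, 400)) + [len(src) - 2000]
    reads = [LongRead(id=f"c{i}", seq=src[s : s + 2000]) for i, s in enumerate(starts)]
    cons, _ = ir_assembly.consensus_assembly(reads, prs[0])
    reads2 = [LongRead(id=f"d{i}", seq=cons[s : s + 2000]) for i, s in enumerate(starts)]
    cons2, _ = ir_assembly.consensus_assembly(reads2, cons)
    assert cons2 == cons


def test_compare_identical_irs():
    g = build_genome(8000, 2000, 1200, 2000, n_ir_diffs=0, seed=2)
    diffs, summary = ir_assembly.compare_irs(g.region_seq("IRa"), g.region_seq("IRb"))
    assert diffs == [] and summary == {}


def test_compare_single_1bp_indel():
    ira = build_genome(8000, 2000, 1200, 2000, n_ir_diffs=0, seed=3).region_seq("IRa")
    irb_rc = ira[:1000] + ira[1001:]  # 1 bp deletion in IRb frame
    diffs, _ = ir_assembly.compare_irs(ira, revcomp(irb_rc))
    assert len(diffs) == 1
    assert diffs[0].kind == "indel" and diffs[0].length == 1


@pytest.mark.parametrize("k", [1, 3, 5, 10])
def test_compare_irs_recovers_k_injected_diffs(k):
    g = build_genome(12000, 6000, 3000, 6000, n_ir_diffs=k, seed=100 + k)
    diffs, _ = ir_assembly.compare_irs(g.region_seq("IRa"), g.region_seq("IRb"))
    assert len(diffs) == k
    truth_kinds = sorted(
        ("SNP" if d.kind == "SNP" else "indel") for d in g.ir_diffs
    )
    got_kinds = sorted(d.kind for d in diffs)
    assert got_kinds == truth_kinds
    # positions match up to left-alignment ambiguity through repeats
    for got, truth in zip(sorted(d.pos for d in diffs), sorted(d.pos for d in g.ir_diffs)):
        assert abs(got - truth) <= 4


def test_reconstruct_roundtrip(mid_genome):
    r = mid_genome.regions
    lsc = mid_genome.seq[r["LSC"][0] : r["LSC"][1] + 100]
    ira = mid_genome.seq[r["IRa"][0] : r["IRa"][1] + 100]
    ssc = mid_genome.seq[r["SSC"][0] : r["SSC"][1] + 100]
    irb = mid_genome.seq[r["IRb"][0] :] + mid_genome.seq[:100]
    rec = ir_assembly.reconstruct_quadripartite(lsc, ira, ssc, irb)
    assert rec.seq == mid_genome.seq


def test_reconstruct_zero_overlap_errors(mid_genome, rng):
    from plastidflip.sequtil import random_seq

    with pytest.raises(ValueError, match="junction"):
        ir_assembly.reconstruct_quadripartite(
            random_seq(2000, 0.4, rng),
            random_seq(1000, 0.4, rng),
            random_seq(800, 0.4, rng),
            random_seq(1000, 0.4, rng),
        )


def test_end_to_end_sample_recovery(mid_population, mid_genome):
    """Consensus segments from a sample's reads stitch back into that
    sample's truth genome."""
    sid = mid_population.sample_ids[0]
    sample = mid_population.samples[sid]
    rs = simulate_reads(sample, depth=45, read_len_mean=4000, read_len_sd=300,
                        isomer_ratio=0.0, seed=12)
    prs = ir_assembly.build_ir_pseudorefs(mid_genome, 2000)
    assigner = ir_assembly.IrAssigner(prs)
    by_label = {"IRa": [], "IRb": [], "ambiguous": []}
    for read in rs.reads:
        by_label[assigner.assign(read, 500)].append(read)
    r = mid_genome.regions  # guides come from the reference, not the sample
    segs = {}
    for label, pad in (("LSC", 100), ("IRa", 100), ("SSC", 100), ("IRb", 100)):
        s, e = r[label]
        if label == "IRb":
            guide = mid_genome.seq[s:] + mid_genome.seq[:pad]
        else:
            guide = mid_genome.seq[s : e + pad]
        # IR consensus uses only the reads classified to that copy
        reads = by_label.get(label) if label in ("IRa", "IRb") else rs.reads
        cons, _ = ir_assembly.consensus_assembly(reads, guide)
        segs[label] = cons
    rec = ir_assembly.reconstruct_quadripartite(
        segs["LSC"], segs["IRa"], segs["SSC"], segs["IRb"]
    )
    assert rec.seq == sample.seq
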