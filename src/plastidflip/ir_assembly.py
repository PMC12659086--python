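"""IR-centered pseudo-references, IRa/IRb read classification,
reference-guided consensus and quadripartite stitching.

The two inverted repeats are near-identical, so reads are attributed to a
copy by the single-copy flank they carry, in consistent orientation.  De
novo assembly is replaced by per-column majority consensus over anchored
read alignments against the pseudo-reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from plastidflip.anchors import KmerIndex, chain_anchors, segment_align
from plastidflip.genome import QuadripartiteGenome
from plastidflip.reads import LongRead
from plastidflip.sequtil import circular_slice, revcomp


@dataclass
class IrPseudoRef:
    label: str  # "IRa" | "IRb"
    seq: str
    flank: int
    ir_len: int
    provenance: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def ir_interval(self) -> tuple[int, int]:
        return self.flank, self.flank + self.ir_len


@dataclass
class IrDiff:
    kind: str  # "SNP" | "indel"
    pos: int  # IRa-frame position
    ref: str
    alt: str

    @property
    def length(self) -> int:
        return max(len(self.ref), len(self.alt), 1) if self.kind == "indel" else 1


def build_ir_pseudorefs(
    genome: QuadripartiteGenome, flank: int = 2000
) -> tuple[IrPseudoRef, IrPseudoRef]:
    """IRa and IRb each extended by ``flank`` bp of single-copy sequence.

    Flanks are taken in the genome's reference orientation; the IRb right
    flank wraps the circular origin into the LSC start.
    """
    lsc_len = genome.region_len("LSC")
    ssc_len = genome.region_len("SSC")
    if flank > min(lsc_len, ssc_len):
        raise ValueError(
            f"flank {flank} exceeds an adjacent single-copy region "
            f"(LSC {lsc_len}, SSC {ssc_len})"
        )
    lsc_s, lsc_e = genome.regions["LSC"]
    ira_s, ira_e = genome.regions["IRa"]
    ssc_s, ssc_e = genome.regions["SSC"]
    irb_s, irb_e = genome.regions["IRb"]
    ira = IrPseudoRef(
        "IRa",
        genome.seq[ira_s - flank : ira_e + flank],
        flank,
        ira_e - ira_s,
        provenance=[(ira_s - flank, ira_e + flank, "+")],
    )
    irb_seq = circular_slice(genome.seq, irb_s - flank, (irb_e - irb_s) + 2 * flank)
    irb = IrPseudoRef(
        "IRb",
        irb_seq,
        flank,
        irb_e - irb_s,
        provenance=[(irb_s - flank, irb_e, "+"), (0, flank, "+")],
    )
    return ira, irb


class IrAssigner:
    """Flank-anchored IRa/IRb classifier (build once, assign many reads)."""

    def __init__(
        self,
        pseudorefs: tuple[IrPseudoRef, IrPseudoRef],
        k: int = 21,
        stride: int = 16,
    ):
        self.k = k
        self.stride = stride
        self.flank_kmers: dict[str, set[tuple[str, int]]] = {}
        kmers: dict[str, set[tuple[str, str]]] = {}
        for pr in pseudorefs:
            for fseq in (pr.seq[: pr.flank], pr.seq[pr.flank + pr.ir_len :]):
                for strand, s in (("+", fseq), ("-", revcomp(fseq))):
                    for i in range(len(s) - k + 1):
                        kmers.setdefault(s[i : i + k], set()).add((pr.label, strand))
        # k-mers shared between the two labels are uninformative
        self.lookup = {km: labs for km, labs in kmers.items() if len({l for l, _ in labs}) == 1}

    def assign(self, read: LongRead | str, min_flank_overlap: int = 500) -> str:
        seq = read.seq if isinstance(read, LongRead) else read
        tally: dict[tuple[str, str], int] = {}
        for off in range(0, max(1, len(seq) - self.k + 1), self.stride):
            labs = self.lookup.get(seq[off : off + self.k])
            if labs:
                for key in labs:
                    tally[key] = tally.get(key, 0) + 1
        if not tally:
            return "ambiguous"
        # anchored bases approximated by hits x stride; orientation must be
        # consistent: take the best (label, strand) cell
        best_key = max(tally, key=lambda kk: (tally[kk], kk))
        need = max(1, (min_flank_overlap - self.k + 1) // self.stride)
        by_label: dict[str, int] = {}
        for (lab, _strand), n in tally.items():
            by_label[lab] = max(by_label.get(lab, 0), n)
        top = tally[best_key]
        if top < need:
            return "ambiguous"
        other = [v for lab, v in by_label.items() if lab != best_key[0]]
        if other and max(other) == top:
            return "ambiguous"
        return best_key[0]


def assign_ir(
    read: LongRead | str,
    pseudorefs: tuple[IrPseudoRef, IrPseudoRef],
    min_flank_overlap: int = 500,
) -> str:
    """One-shot flank-orientation assignment: {IRa, IRb, ambiguous}."""
    return IrAssigner(pseudorefs).assign(read, min_flank_overlap)


def _orient_read(seq: str, index: KmerIndex, stride: int = 20) -> tuple[str, int]:
    """Pick read orientation by anchor hit count against the reference."""
    k = index.k
    counts = {}
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        c = 0
        for off in range(0, max(1, len(s) - k + 1), stride):
            if index.positions(s[off : off + k]):
                c += 1
        counts[strand] = c
    if counts["+"] >= counts["-"]:
        return seq, counts["+"]
    return revcomp(seq), counts["-"]


def consensus_assembly(
    assigned_reads: Iterable[LongRead],
    pseudoref: IrPseudoRef | str,
    k: int = 21,
    min_anchored_span: int = 300,
) -> tuple[str, np.ndarray]:
    """Per-column majority consensus over anchored read alignments.

    Reads are oriented and anchored to the pseudo-reference with unique
    k-mer chains; the short stretches between anchors are aligned with
    Needleman-Wunsch, contributing substitution, deletion and insertion
    votes.  Returns the consensus sequence and per-base support (coverage);
    zero-support positions are emitted as N.
    """
    from plastidflip.anchors import alignment_to_ops
    from plastidflip.variants import normalize_variant

    ref = pseudoref.seq if isinstance(pseudoref, IrPseudoRef) else pseudoref
    reads = list(assigned_reads)
    if not reads:
        raise ValueError("no assigned reads to build a consensus from")
    L = len(ref)
    index = KmerIndex(ref, k)
    # votes per canonical event (pos, ref allele, alt allele); placement
    # ambiguity inside repeats is removed by left normalization against the
    # full reference so equivalent observations pool into one key
    event_votes: dict[tuple[int, str, str], int] = {}
    coverage = np.zeros(L, dtype=np.int64)

    for read in reads:
        seq, hits = _orient_read(read.seq, index)
        if hits == 0:
            continue
        chain = chain_anchors(seq, index, stride=5)
        if not chain:
            continue
        if chain[-1][1] + k - chain[0][1] < min_anchored_span:
            continue  # read only grazes the reference (e.g. via a short pad)
        segments: list[tuple[int, int, str]] = []  # (ref_start, ref_end, read segment)
        (qa, ra), rest = chain[0], chain[1:]
        seg_q, seg_r = qa, ra
        prev_q, prev_r = qa, ra
        for nq, nr in rest:
            dq, dr = nq - prev_q, nr - prev_r
            if dq == dr:
                prev_q, prev_r = nq, nr
                continue
            segments.append((seg_r, prev_r + k, seq[seg_q : prev_q + k]))
            segments.append((prev_r + k, nr, seq[prev_q + k : nq]))
            seg_q, seg_r = nq, nr
            prev_q, prev_r = nq, nr
        segments.append((seg_r, prev_r + k, seq[seg_q : prev_q + k]))

        for rs, re_, rseq in segments:
            ref_seg = ref[rs:re_]
            coverage[rs:re_] += 1
            if rseq == ref_seg:
                continue
            a_aln, b_aln = segment_align(ref_seg, rseq)
            smp = rseq
            for op in alignment_to_ops(a_aln, b_aln):
                if op.op == "M":
                    for i in range(op.length):
                        x = ref_seg[op.a_pos + i]
                        y = smp[op.b_pos + i]
                        if x != y:
                            event_votes[(rs + op.a_pos + i, x, y)] = (
                                event_votes.get((rs + op.a_pos + i, x, y), 0) + 1
                            )
                    continue
                if op.op == "D":
                    p = rs + op.a_pos
                    if p == 0:
                        continue  # cannot anchor a deletion at the very start
                    ev = normalize_variant(
                        p - 1, ref[p - 1 : p + op.length], ref[p - 1], ref
                    )
                else:
                    p = rs + op.a_pos
                    ins = smp[op.b_pos : op.b_pos + op.length]
                    if p == 0:
                        continue
                    ev = normalize_variant(p - 1, ref[p - 1], ref[p - 1] + ins, ref)
                event_votes[ev] = event_votes.get(ev, 0) + 1

    accepted: list[tuple[int, str, str]] = []
    for (pos, ref_a, alt_a), n in sorted(event_votes.items()):
        cov = int(coverage[pos]) if pos < L else 0
        if cov > 0 and 2 * n > cov:
            accepted.append((pos, ref_a, alt_a))
    # splice non-overlapping accepted events into the reference left to
    # right; zero-coverage reference positions are emitted as N
    masked = np.frombuffer(ref.encode(), dtype=np.uint8).copy()
    masked[coverage == 0] = ord("N")
    ref_n = masked.tobytes().decode()
    pieces: list[str] = []
    cursor = 0
    for pos, ref_a, alt_a in accepted:
        if pos < cursor:
            continue
        pieces.append(ref_n[cursor:pos])
        pieces.append(alt_a)
        cursor = pos + len(ref_a)
    pieces.append(ref_n[cursor:])
    return "".join(pieces), coverage


def compare_irs(ira_seq: str, irb_seq: str) -> tuple[list[IrDiff], dict[int, int]]:
    """Diffs between IRa and reverse-complemented IRb, binned by length."""
    if not ira_seq or not irb_seq:
        raise ValueError("IR sequences must be non-empty")
    from plastidflip.anchors import align_pair, alignment_to_ops

    b = revcomp(irb_seq)
    a_aln, b_aln = align_pair(ira_seq, b)
    diffs: list[IrDiff] = []
    for op in alignment_to_ops(a_aln, b_aln):
        if op.op == "M":
            a_seg = ira_seq[op.a_pos : op.a_pos + op.length]
            b_seg = b[op.b_pos : op.b_pos + op.length]
            for i, (x, y) in enumerate(zip(a_seg, b_seg)):
                if x != y:
                    diffs.append(IrDiff("SNP", op.a_pos + i, x, y))
        elif op.op == "D":
            diffs.append(
                IrDiff("indel", op.a_pos, ira_seq[op.a_pos : op.a_pos + op.length], "")
            )
        else:
            diffs.append(
                IrDiff("indel", op.a_pos, "", b[op.b_pos : op.b_pos + op.length])
            )
    summary: dict[int, int] = {}
    for d in diffs:
        summary[d.length] = summary.get(d.length, 0) + 1
    return diffs, summary


def _junction_overlap(a: str, b: str, min_overlap: int = 50) -> int:
    """Largest o >= min_overlap with a[-o:] == b[:o]; 0 when none."""
    seed = a[-min_overlap:]
    best = 0
    start = 0
    while True:
        j = b.find(seed, start)
        if j < 0:
            break
        o = j + min_overlap
        if o <= len(a) and a[-o:] == b[:o]:
            best = max(best, o)
        start = j + 1
    return best


def reconstruct_quadripartite(
    lsc: str, ira: str, ssc: str, irb: str, min_overlap: int = 50
) -> QuadripartiteGenome:
    """Stitch four segments by exact junction overlaps into a circle.

    Consecutive segments (and the IRb->LSC wrap) must share >= min_overlap
    identical bases; region boundaries are placed at the end of each
    segment's contribution (junction placement within the overlap is
    conventional).
    """
    segs = [("LSC", lsc), ("IRa", ira), ("SSC", ssc), ("IRb", irb)]
    pieces: list[str] = [lsc]
    for (la, a), (lb, b) in zip(segs, segs[1:]):
        o = _junction_overlap(a, b, min_overlap)
        if o == 0:
            raise ValueError(f"missing junction overlap between {la} and {lb}")
        pieces.append(b[o:])
    o = _junction_overlap(irb, lsc, min_overlap)
    if o == 0:
        raise ValueError("missing junction overlap between IRb and LSC (circular closure)")
    pieces[-1] = pieces[-1][: len(pieces[-1]) - o] if o <= len(pieces[-1]) else ""
    lengths = [len(p) for p in pieces]
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    seq = "".join(pieces)
    regions = {
        "LSC": (int(bounds[0]), int(bounds[1])),
        "IRa": (int(bounds[1]), int(bounds[2])),
        "SSC": (int(bounds[2]), int(bounds[3])),
        "IRb": (int(bounds[3]), int(bounds[4])),
    }
    return QuadripartiteGenome(seq=seq, regions=regions)
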