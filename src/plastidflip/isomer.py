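"""Flip-flop inversion isomer detection from junction-spanning long reads.

A read votes for an isomer only under stringent span criteria: it must
contain the complete IR plus at least ``min_flank`` single-copy bases on
both sides.  The two junction references share the LSC-side flank and the
IR; the SSC-side flank is the discriminating segment, so the isomer call
is made from anchored identity on that side alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from scipy.stats import binomtest

from plastidflip.genome import QuadripartiteGenome
from plastidflip.reads import LongRead
from plastidflip.sequtil import revcomp


@dataclass
class IsomerRefs:
    ref_seq: str  # junction reference for the reference isomer
    inv_seq: str  # junction reference for the inverted isomer
    flank: int
    ir_len: int

    def __post_init__(self) -> None:
        if len(self.ref_seq) != len(self.inv_seq):
            raise ValueError("junction references must have equal length")


@dataclass
class IsomerCounts:
    n_ref: int
    n_inv: int
    n_disqualified: int
    p_value: float | None = None
    ci: tuple[float, float] | None = None

    @property
    def ratio(self) -> float:
        if self.n_inv == 0:
            return float("nan")
        return self.n_ref / self.n_inv

    @property
    def proportion(self) -> float:
        tot = self.n_ref + self.n_inv
        return self.n_ref / tot if tot else float("nan")


@dataclass
class ContigIsomerCall:
    contig_id: str
    call: str  # reference_only | inversion_only | both | undetermined


def build_isomer_refs(
    genome: QuadripartiteGenome, flank: int = 2000, invert: str = "ssc"
) -> IsomerRefs:
    """Junction references centered on IRa for the two isomers.

    Both are LSC-flank + IRa + SSC-side flank; the inverted reference
    carries the reverse-complemented distal SSC end, matching the polarity
    change produced by flip-flop recombination of the segment named by
    ``invert``.
    """
    if invert.lower() != "ssc":
        raise ValueError("only the SSC flip-flop convention is supported here")
    lsc_len = genome.region_len("LSC")
    ssc_len = genome.region_len("SSC")
    if flank > min(lsc_len, ssc_len):
        raise ValueError("flank exceeds an adjacent single-copy region")
    ira_s, ira_e = genome.regions["IRa"]
    ssc_s, ssc_e = genome.regions["SSC"]
    left = genome.seq[ira_s - flank : ira_s]
    ira = genome.seq[ira_s:ira_e]
    right_ref = genome.seq[ssc_s : ssc_s + flank]
    right_inv = revcomp(genome.seq[ssc_e - flank : ssc_e])
    return IsomerRefs(
        ref_seq=left + ira + right_ref,
        inv_seq=left + ira + right_inv,
        flank=flank,
        ir_len=ira_e - ira_s,
    )


class _JunctionMatcher:
    """Anchored matcher for the two junction references."""

    def __init__(self, refs: IsomerRefs, k: int = 21, stride: int = 8):
        self.refs = refs
        self.k = k
        self.stride = stride
        self.lookup: dict[str, list[tuple[str, int]]] = {}
        for name, seq in (("ref", refs.ref_seq), ("inv", refs.inv_seq)):
            for i in range(len(seq) - k + 1):
                self.lookup.setdefault(seq[i : i + k], []).append((name, i))

    def evaluate(self, seq: str, min_flank: int, require_full_ir: bool) -> str | None:
        """Return 'ref', 'inv' or None (disqualified) for one oriented read."""
        k, stride = self.k, self.stride
        refs = self.refs
        best: tuple[int, str] | None = None
        for q in (seq, revcomp(seq)):
            cov: dict[str, list[int]] = {"ref": [], "inv": []}
            disc: dict[str, int] = {"ref": 0, "inv": 0}
            ssc_side = refs.flank + refs.ir_len
            for off in range(0, max(1, len(q) - k + 1), stride):
                hits = self.lookup.get(q[off : off + k])
                if not hits:
                    continue
                for name, pos in hits:
                    cov[name].append(pos)
                    if pos >= ssc_side:
                        disc[name] += 1
            lo_need = refs.flank - min_flank
            hi_need = refs.flank + refs.ir_len + min_flank
            slack = stride + k
            qualified = {}
            for name in ("ref", "inv"):
                if not cov[name]:
                    qualified[name] = False
                    continue
                lo, hi = min(cov[name]), max(cov[name]) + k
                span_ok = lo <= lo_need + slack and hi >= hi_need - slack
                if require_full_ir:
                    span_ok = span_ok and lo <= refs.flank and hi >= refs.flank + refs.ir_len
                qualified[name] = span_ok
            for name in ("ref", "inv"):
                if not qualified[name]:
                    continue
                other = "inv" if name == "ref" else "ref"
                score = disc[name]
                if score >= 8 and score >= 2 * max(disc[other], 1):
                    if best is None or score > best[0]:
                        best = (score, name)
        return best[1] if best else None


def count_isomer_support(
    reads: Iterable[LongRead],
    isomer_refs: IsomerRefs,
    min_flank: int = 2000,
    require_full_ir: bool = True,
    k: int = 21,
    stride: int = 8,
) -> IsomerCounts:
    """Tally junction-spanning reads per isomer under the stringent rule.

    Every read is examined; reads failing the complete-IR-plus-flanks
    criterion, or matching both references equally, are disqualified.
    """
    if min_flank > isomer_refs.flank:
        raise ValueError("min_flank cannot exceed the junction reference flank")
    matcher = _JunctionMatcher(isomer_refs, k=k, stride=stride)
    n_ref = n_inv = n_dis = 0
    for read in reads:
        seq = read.seq if isinstance(read, LongRead) else read
        verdict = matcher.evaluate(seq, min_flank, require_full_ir)
        if verdict == "ref":
            n_ref += 1
        elif verdict == "inv":
            n_inv += 1
        else:
            n_dis += 1
    counts = IsomerCounts(n_ref, n_inv, n_dis)
    if n_ref + n_inv > 0:
        counts.p_value, counts.ci = test_equimolar(n_ref, n_inv)
    return counts


def classify_contigs(
    contigs: dict[str, str] | list[tuple[str, str]],
    isomer_refs: IsomerRefs,
    min_flank: int | None = None,
) -> list[ContigIsomerCall]:
    """Per-contig isomer call by the same stringent span rule."""
    if isinstance(contigs, dict):
        items = list(contigs.items())
    else:
        items = list(contigs)
    mf = min_flank if min_flank is not None else isomer_refs.flank
    matcher = _JunctionMatcher(isomer_refs)
    calls: list[ContigIsomerCall] = []
    for cid, seq in items:
        verdict = matcher.evaluate(seq, mf, require_full_ir=True)
        if verdict == "ref":
            call = "reference_only"
        elif verdict == "inv":
            call = "inversion_only"
        else:
            call = "undetermined"
        calls.append(ContigIsomerCall(cid, call))
    return calls


def aggregate_sample_calls(calls: list[ContigIsomerCall]) -> str:
    """UpSet-style per-sample aggregation of contig calls."""
    kinds = {c.call for c in calls}
    has_ref = "reference_only" in kinds or "both" in kinds
    has_inv = "inversion_only" in kinds or "both" in kinds
    if has_ref and has_inv:
        return "both"
    if has_ref:
        return "reference_only"
    if has_inv:
        return "inversion_only"
    return "undetermined"


def test_equimolar(n_ref: int, n_inv: int) -> tuple[float, tuple[float, float]]:
    """Exact two-sided binomial test of proportion 0.5 plus 95% CP interval."""
    total = n_ref + n_inv
    if total == 0:
        raise ValueError("no qualifying reads: equimolarity test undefined")
    res = binomtest(n_ref, total, 0.5, alternative="two-sided")
    ci = res.proportion_ci(confidence_level=0.95, method="exact")
    return float(res.pvalue), (float(ci.low), float(ci.high))
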