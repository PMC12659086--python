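"""Anchor-based sequence matching and alignment primitives.

Exact k-mer anchors plus short Needleman-Wunsch fills give deterministic,
dependency-free pairwise alignment for near-identical sequences (the
organelle intra-species regime), and diagonal voting gives fast placement
of low-error long reads on a reference.  No external aligner is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plastidflip.sequtil import revcomp

DEFAULT_K = 21

# NW scoring (linear gap)
_MATCH = 2
_MISMATCH = -3
_GAP = -4

_MAX_NW_CELLS = 30_000_000


class KmerIndex:
    """Exact k-mer -> start positions lookup over one sequence."""

    def __init__(self, seq: str, k: int = DEFAULT_K):
        if k < 4:
            raise ValueError("k too small")
        self.seq = seq
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        self.index = index

    def positions(self, kmer: str) -> list[int]:
        return self.index.get(kmer, [])


def best_diagonal(
    query: str, index: KmerIndex, stride: int = 50, diag_bucket: int = 16
) -> tuple[int | None, int, str]:
    """Best (ref_start, votes, strand) placement of query by diagonal voting.

    Both orientations of the query are tried; ref_start is where the query
    5' end would sit on the reference (may be negative for queries hanging
    off the left edge).
    """
    k = index.k
    best: tuple[int | None, int, str] = (None, 0, "+")
    for strand, q in (("+", query), ("-", revcomp(query))):
        votes: dict[int, int] = {}
        for off in range(0, max(1, len(q) - k + 1), stride):
            for pos in index.positions(q[off : off + k]):
                d = (pos - off) // diag_bucket
                votes[d] = votes.get(d, 0) + 1
        if votes:
            d, n = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
            if n > best[1]:
                best = (d * diag_bucket, n, strand)
    return best


def chain_anchors(query: str, index: KmerIndex, stride: int = 1) -> list[tuple[int, int]]:
    """Collinear chain of exact anchor matches (query_pos, ref_pos).

    Anchors are k-mers of the query that occur exactly once in the
    reference; the longest strictly increasing chain (classic LIS on the
    reference coordinate) is returned.
    """
    k = index.k
    cand: list[tuple[int, int]] = []
    for off in range(0, max(1, len(query) - k + 1), stride):
        hits = index.positions(query[off : off + k])
        if len(hits) == 1:
            cand.append((off, hits[0]))
    if not cand:
        return []
    # LIS on ref positions (candidates already sorted by query position)
    refs = [c[1] for c in cand]
    n = len(refs)
    tails: list[int] = []  # indices into cand
    prev = [-1] * n
    import bisect

    tvals: list[int] = []
    for i, r in enumerate(refs):
        j = bisect.bisect_left(tvals, r)
        if j == len(tvals):
            tvals.append(r)
            tails.append(i)
        else:
            tvals[j] = r
            tails[j] = i
        prev[i] = tails[j - 1] if j > 0 else -1
    chain = []
    i = tails[len(tvals) - 1]
    while i >= 0:
        chain.append(cand[i])
        i = prev[i]
    chain.reverse()
    # enforce non-negative inter-anchor gaps (drop conflicting anchors)
    filtered: list[tuple[int, int]] = []
    for qa, ra in chain:
        if filtered:
            pq, pr = filtered[-1]
            dq, dr = qa - pq, ra - pr
            if dq == dr:  # same diagonal: always compatible
                filtered.append((qa, ra))
                continue
            if dq < k or dr < k:
                continue
        filtered.append((qa, ra))
    return filtered


def _common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def fast_segment_align(a: str, b: str) -> tuple[str, str] | None:
    """Cheap alignment for the common inter-anchor cases.

    Equal lengths align column-wise; a single clean indel is located by
    prefix/suffix matching.  Returns None when the segment needs real DP.
    """
    if len(a) == len(b):
        mism = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
        # a locally dense mismatch run is the signature of compensating
        # indels (shifted sequence); those need DP, sparse substitutions not
        dense = any(mism[i + 4] - mism[i] < 8 for i in range(len(mism) - 4))
        if not dense:
            return a, b
        return None
    p = _common_prefix(a, b)
    s = _common_prefix(a[::-1], b[::-1])
    if len(a) > len(b):
        d = len(a) - len(b)
        if p + s >= len(b):
            c = min(p, len(b) - s)
            return a, b[:c] + "-" * d + b[c:]
    else:
        d = len(b) - len(a)
        if p + s >= len(a):
            c = min(p, len(a) - s)
            return a[:c] + "-" * d + a[c:], b
    return None


def needleman_wunsch(a: str, b: str) -> tuple[str, str]:
    """Global alignment of two (short) sequences; returns gapped strings."""
    n, m = len(a), len(b)
    if n == 0:
        return "-" * m, b
    if m == 0:
        return a, "-" * n
    if a == b:
        return a, b
    if (n + 1) * (m + 1) > _MAX_NW_CELLS:
        raise ValueError(
            f"alignment problem too large ({n} x {m}); sequences likely below "
            "the identity regime — supply an external MSA instead"
        )
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    score = np.zeros((n + 1, m + 1), dtype=np.int32)
    tb = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 diag, 1 up (gap in b), 2 left
    score[:, 0] = np.arange(n + 1) * _GAP
    score[0, :] = np.arange(m + 1) * _GAP
    tb[1:, 0] = 1
    tb[0, 1:] = 2
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], _MATCH, _MISMATCH)
        diag = score[i - 1, :-1] + sub
        up = score[i - 1, 1:] + _GAP
        row = score[i]
        prev_best = np.maximum(diag, up)
        choice = np.where(diag >= up, 0, 1).astype(np.uint8)
        # left moves depend on the row itself: sequential pass
        acc = row[0]
        for j in range(1, m + 1):
            left = acc + _GAP
            if prev_best[j - 1] >= left:
                acc = prev_best[j - 1]
                tb[i, j] = choice[j - 1]
            else:
                acc = left
                tb[i, j] = 2
            row[j] = acc
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        t = tb[i, j]
        if t == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif t == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def banded_needleman_wunsch(a: str, b: str, band: int = 16) -> tuple[str, str]:
    """Global alignment restricted to a diagonal band.

    Adequate when the optimal path stays within ``band`` of the main
    diagonal (near-identical sequences with small indels); falls back on
    the full DP for tiny problems.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0 or (n + 1) * (m + 1) <= 4096:
        return needleman_wunsch(a, b)
    lo = min(0, m - n) - band
    hi = max(0, m - n) + band
    width = hi - lo + 1
    NEG = -(10 ** 9)
    score = np.full((n + 1, width), NEG, dtype=np.int64)
    tb = np.zeros((n + 1, width), dtype=np.uint8)  # 0 diag, 1 up, 2 left

    def col(i: int, j: int) -> int:
        return j - i - lo

    score[0, col(0, 0)] = 0
    for j in range(1, min(m, hi) + 1):
        score[0, col(0, j)] = j * _GAP
        tb[0, col(0, j)] = 2
    for i in range(1, n + 1):
        jmin = max(0, i + lo)
        jmax = min(m, i + hi)
        for j in range(jmin, jmax + 1):
            c = col(i, j)
            best_s, best_t = NEG, 0
            if j > 0 and 0 <= col(i - 1, j - 1) < width:
                d = score[i - 1, col(i - 1, j - 1)]
                if d > NEG:
                    d += _MATCH if a[i - 1] == b[j - 1] else _MISMATCH
                    if d > best_s:
                        best_s, best_t = d, 0
            if 0 <= col(i - 1, j) < width:
                u = score[i - 1, col(i - 1, j)]
                if u > NEG and u + _GAP > best_s:
                    best_s, best_t = u + _GAP, 1
            if j > 0 and 0 <= col(i, j - 1) < width:
                l = score[i, col(i, j - 1)]
                if l > NEG and l + _GAP > best_s:
                    best_s, best_t = l + _GAP, 2
            score[i, c] = best_s
            tb[i, c] = best_t
    if score[n, col(n, m)] <= NEG:
        return needleman_wunsch(a, b)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        t = tb[i, col(i, j)]
        if t == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif t == 1 and i > 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def segment_align(a: str, b: str) -> tuple[str, str]:
    """fast_segment_align when possible, DP on the divergent core otherwise."""
    quick = fast_segment_align(a, b)
    if quick is not None:
        return quick
    # peel the exact prefix/suffix so DP only sees the divergent core
    p = _common_prefix(a, b)
    p = max(0, p - 4)  # keep slack so the core can left-shift indels
    s = _common_prefix(a[::-1], b[::-1])
    s = min(s, min(len(a), len(b)) - p)
    core_a, core_b = a[p : len(a) - s], b[p : len(b) - s]
    band = abs(len(core_a) - len(core_b)) + 12
    ca, cb = banded_needleman_wunsch(core_a, core_b, band)
    return a[:p] + ca + a[len(a) - s :], b[:p] + cb + b[len(b) - s :]


@dataclass
class AlignOp:
    op: str  # 'M' (both), 'D' (consumes a only), 'I' (consumes b only)
    length: int
    a_pos: int
    b_pos: int


def alignment_to_ops(a_aln: str, b_aln: str) -> list[AlignOp]:
    ops: list[AlignOp] = []
    ai = bi = 0
    for ca, cb in zip(a_aln, b_aln):
        if ca == "-" and cb == "-":
            continue
        op = "M" if (ca != "-" and cb != "-") else ("D" if cb == "-" else "I")
        if ops and ops[-1].op == op:
            ops[-1].length += 1
        else:
            ops.append(AlignOp(op, 1, ai, bi))
        if ca != "-":
            ai += 1
        if cb != "-":
            bi += 1
    return ops


def merge_split_gaps(ops: list[AlignOp], a: str, b: str) -> list[AlignOp]:
    """Collapse D-M-D (or I-M-I) runs into one contiguous gap when the
    intervening match block is sequence-equivalent at the other placement
    (linear gap scoring ties; the merged form is the canonical one)."""
    changed = True
    while changed:
        changed = False
        out: list[AlignOp] = []
        i = 0
        while i < len(ops):
            if i + 2 < len(ops):
                o1, om, o2 = ops[i], ops[i + 1], ops[i + 2]
                if o1.op == "D" and om.op == "M" and o2.op == "D":
                    m = om.length
                    if a[o1.a_pos : o1.a_pos + m] == b[om.b_pos : om.b_pos + m]:
                        out.append(AlignOp("M", m, o1.a_pos, o1.b_pos))
                        out.append(
                            AlignOp("D", o1.length + o2.length, o1.a_pos + m, o1.b_pos + m)
                        )
                        i += 3
                        changed = True
                        continue
                if o1.op == "I" and om.op == "M" and o2.op == "I":
                    m = om.length
                    if b[o1.b_pos : o1.b_pos + m] == a[om.a_pos : om.a_pos + m]:
                        out.append(AlignOp("M", m, o1.a_pos, o1.b_pos))
                        out.append(
                            AlignOp("I", o1.length + o2.length, o1.a_pos + m, o1.b_pos + m)
                        )
                        i += 3
                        changed = True
                        continue
            out.append(ops[i])
            i += 1
        # coalesce adjacent same-type ops created by the rewrite
        ops = []
        for op in out:
            if ops and ops[-1].op == op.op:
                prev = ops[-1]
                a_end = prev.a_pos + (prev.length if prev.op != "I" else 0)
                b_end = prev.b_pos + (prev.length if prev.op != "D" else 0)
                if (a_end, b_end) == (op.a_pos, op.b_pos):
                    prev.length += op.length
                    continue
            ops.append(AlignOp(op.op, op.length, op.a_pos, op.b_pos))
    return ops


def left_shift_ops(ops: list[AlignOp], a: str, b: str) -> list[AlignOp]:
    """Shift indel ops to their leftmost equivalent placement."""
    shifted: list[AlignOp] = []
    limit_a = limit_b = 0  # end of the previous indel op; M runs may shrink
    for op in ops:
        if op.op == "D":
            p, d = op.a_pos, op.length
            shift = 0
            while p > limit_a and p - op.a_pos + op.b_pos > limit_b and a[p - 1] == a[p + d - 1]:
                p -= 1
                shift += 1
            op = AlignOp("D", d, p, op.b_pos - shift)
            limit_a, limit_b = op.a_pos + d, op.b_pos
        elif op.op == "I":
            p, d = op.b_pos, op.length
            shift = 0
            while p > limit_b and p - op.b_pos + op.a_pos > limit_a and b[p - 1] == b[p + d - 1]:
                p -= 1
                shift += 1
            op = AlignOp("I", d, op.a_pos - shift, p)
            limit_a, limit_b = op.a_pos, op.b_pos + d
        shifted.append(op)
    # re-sort M ops around moved indels is unnecessary: a shifted indel only
    # slides within the preceding M run; rebuild fixes the M spans.
    return shifted


def ops_to_alignment(ops: list[AlignOp], a: str, b: str) -> tuple[str, str]:
    """Rebuild gapped strings from (possibly left-shifted) indel ops."""
    indels = sorted(
        (o for o in ops if o.op != "M"), key=lambda o: (o.a_pos, o.b_pos)
    )
    out_a: list[str] = []
    out_b: list[str] = []
    ai = bi = 0
    for o in indels:
        take = o.a_pos - ai
        out_a.append(a[ai : ai + take])
        out_b.append(b[bi : bi + take])
        ai += take
        bi += take
        if o.op == "D":
            out_a.append(a[ai : ai + o.length])
            out_b.append("-" * o.length)
            ai += o.length
        else:
            out_a.append("-" * o.length)
            out_b.append(b[bi : bi + o.length])
            bi += o.length
    out_a.append(a[ai:])
    out_b.append(b[bi:])
    return "".join(out_a), "".join(out_b)


def align_pair(a: str, b: str, k: int = 25, left_align: bool = True) -> tuple[str, str]:
    """Global alignment of two near-identical sequences.

    Unique shared k-mer anchors are chained; the short stretches between
    anchors are aligned with Needleman-Wunsch.  Indels are left-aligned.
    """
    if not a or not b:
        return needleman_wunsch(a, b)
    if a == b:
        return a, b
    index = KmerIndex(b, k)
    chain = chain_anchors(a, index)
    if not chain:
        return _finish(needleman_wunsch(a, b), a, b, left_align)
    parts_a: list[str] = []
    parts_b: list[str] = []
    fa, fb = chain[0]
    ha, hb = segment_align(a[:fa], b[:fb])
    parts_a.append(ha)
    parts_b.append(hb)
    prev_a, prev_b = fa, fb
    for qa, ra in chain[1:]:
        dq, dr = qa - prev_a, ra - prev_b
        if dq == dr:
            # same diagonal: usually clean columns, but compensating indels
            # keep the diagonal too — let segment_align arbitrate
            sa, sb = segment_align(a[prev_a:qa], b[prev_b:ra])
            parts_a.append(sa)
            parts_b.append(sb)
        else:
            parts_a.append(a[prev_a : prev_a + k])
            parts_b.append(b[prev_b : prev_b + k])
            sa, sb = segment_align(a[prev_a + k : qa], b[prev_b + k : ra])
            parts_a.append(sa)
            parts_b.append(sb)
        prev_a, prev_b = qa, ra
    ta, tb_ = segment_align(a[prev_a:], b[prev_b:])
    parts_a.append(ta)
    parts_b.append(tb_)
    a_aln, b_aln = "".join(parts_a), "".join(parts_b)
    return _finish((a_aln, b_aln), a, b, left_align)


def _finish(
    aln: tuple[str, str], a: str, b: str, left_align: bool
) -> tuple[str, str]:
    a_aln, b_aln = aln
    assert a_aln.replace("-", "") == a and b_aln.replace("-", "") == b
    if not left_align:
        return a_aln, b_aln
    ops = alignment_to_ops(a_aln, b_aln)
    ops = merge_split_gaps(ops, a, b)
    ops = left_shift_ops(ops, a, b)
    return ops_to_alignment(ops, a, b)


def kmer_identity(a: str, b: str, k: int = DEFAULT_K) -> float:
    """Fraction of a's k-mers present in b (cheap identity proxy)."""
    if len(a) < k:
        return 1.0 if a in b else 0.0
    kms = {b[i : i + k] for i in range(len(b) - k + 1)}
    total = len(a) - k + 1
    return sum(1 for i in range(total) if a[i : i + k] in kms) / total
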