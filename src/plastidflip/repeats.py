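"""Short direct-repeat discovery and repeat/variant association.

Repeats are found by a sliding k-mer census from the longest unit length
down: at each k, non-overlapping occurrences of every k-mer are counted
(leftmost-greedy placement), units occurring at least twice are retained,
and their occurrences are masked before smaller k are processed so that
shorter units nested inside longer retained repeats are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from plastidflip.variants import VariantRecord


@dataclass
class RepeatOccurrence:
    k: int
    unit: str
    positions: list[int]  # 0-based starts, non-overlapping
    count: int


@dataclass
class MirrorTrack:
    bin_size: int
    ira_density: np.ndarray
    irb_density: np.ndarray  # reverse-complement-mapped into the IRa frame
    correlation: float  # Pearson; NaN when undefined


def find_direct_repeats(
    sequence: str, k_min: int = 3, k_max: int = 30
) -> list[RepeatOccurrence]:
    """All retained direct repeats of unit length k_min..k_max.

    Deterministic: units are processed in order of first occurrence;
    placement of occurrences is leftmost-greedy; longer units are handled
    first and mask the sequence for shorter ones (nested removal).
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    n = len(sequence)
    k_max = min(k_max, n)
    mask = np.zeros(n, dtype=bool)
    results: list[RepeatOccurrence] = []
    for k in range(k_max, k_min - 1, -1):
        if k > n:
            continue
        cum = np.concatenate(([0], np.cumsum(mask)))
        occ: dict[str, list[int]] = {}
        for i in range(n - k + 1):
            if cum[i + k] - cum[i]:
                continue
            occ.setdefault(sequence[i : i + k], []).append(i)
        retained: list[RepeatOccurrence] = []
        for unit, positions in occ.items():
            if len(positions) < 2:
                continue
            sel: list[int] = []
            last = -k
            for p in positions:
                if p >= last + k:
                    sel.append(p)
                    last = p
            if len(sel) >= 2:
                retained.append(RepeatOccurrence(k, unit, sel, len(sel)))
        for r in retained:
            for p in r.positions:
                mask[p : p + r.k] = True
        results.extend(retained)
    return results


def repeat_length_histogram(repeats: list[RepeatOccurrence]) -> dict[int, int]:
    """Occurrences per unit length (distributional summary)."""
    hist: dict[int, int] = {}
    for r in repeats:
        hist[r.k] = hist.get(r.k, 0) + r.count
    return hist


def variant_repeat_overlap(
    variants: list[VariantRecord],
    repeats: list[RepeatOccurrence],
    k_select: tuple[int, int] = (5, 8),
) -> dict[str, float]:
    """Fraction of indels and SNPs intersecting retained k_select repeats.

    A variant intersects a repeat when its reference span [pos, pos+|ref|)
    overlaps any retained occurrence of a unit with k in the inclusive
    ``k_select`` range.  Returns fractions plus their ratio; fractions are
    NaN when the corresponding variant class is empty.
    """
    lo, hi = k_select
    intervals = sorted(
        (p, p + r.k) for r in repeats if lo <= r.k <= hi for p in r.positions
    )
    starts = np.array([iv[0] for iv in intervals], dtype=np.int64)
    ends = np.array([iv[1] for iv in intervals], dtype=np.int64)

    def hits(v: VariantRecord) -> bool:
        if len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, v.end))
        return bool((ends[:i] > v.pos).any())

    tallies = {"indel": [0, 0], "SNP": [0, 0], "SV": [0, 0]}
    for v in variants:
        cls = v.vtype if v.vtype in tallies else "indel"
        tallies[cls][1] += 1
        if hits(v):
            tallies[cls][0] += 1
    out: dict[str, float] = {}
    for cls, (inside, total) in tallies.items():
        out[f"{cls.lower()}_fraction"] = inside / total if total else float("nan")
    i_f, s_f = out["indel_fraction"], out["snp_fraction"]
    out["indel_to_snp_ratio"] = i_f / s_f if s_f and s_f > 0 else float("nan")
    return out


def indel_mirroring(
    variants: list[VariantRecord],
    regions: dict[str, tuple[int, int]],
    bin_size: int = 50,
) -> MirrorTrack:
    """Binned IRa vs reverse-complement-mapped IRb indel density tracks.

    Position x in the IRa frame corresponds to position ir_len-1-x in the
    IRb frame; IRb indel anchors are mapped through that involution before
    binning, so perfectly mirrored indels produce identical tracks.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    ira_s, ira_e = regions["IRa"]
    irb_s, irb_e = regions["IRb"]
    ira_len, irb_len = ira_e - ira_s, irb_e - irb_s
    frame = max(ira_len, irb_len)
    n_bins = (frame + bin_size - 1) // bin_size
    ta = np.zeros(n_bins)
    tb = np.zeros(n_bins)
    na = nb = 0
    for v in variants:
        if v.vtype not in ("indel", "SV") or len(v.ref) == len(v.alts[0]):
            continue
        if ira_s <= v.pos < ira_e:
            ta[(v.pos - ira_s) // bin_size] += 1
            na += 1
        elif irb_s <= v.pos < irb_e:
            # map the ref-span start through the reverse-complement involution
            mapped = irb_len - (v.pos - irb_s) - len(v.ref)
            tb[min(max(mapped, 0), frame - 1) // bin_size] += 1
            nb += 1
    if na == 0 or nb == 0 or ta.std() == 0 or tb.std() == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(ta, tb)[0, 1])
    return MirrorTrack(bin_size, ta, tb, corr)
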