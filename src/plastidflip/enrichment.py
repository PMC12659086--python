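"""Chloroplast read enrichment, copy-number estimation and depth profiles.

Enrichment replaces a BLAST homology filter with exact k-mer sharing
against a bait set of conserved windows; read placement for depth uses
diagonal voting of k-mer anchors per read chunk (no full mapper).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from plastidflip.anchors import KmerIndex
from plastidflip.genome import QuadripartiteGenome
from plastidflip.reads import LongRead


@dataclass
class Bait:
    start: int
    end: int
    seq: str
    score: float


@dataclass
class BaitSet:
    baits: list[Bait]
    k: int = 21
    min_match_fraction: float = 0.08
    dropped: list[tuple[int, float]] = field(default_factory=list)  # (start, best score)

    def __post_init__(self) -> None:
        self.baits.sort(key=lambda b: b.start)
        for a, b in zip(self.baits, self.baits[1:]):
            if b.start < a.end:
                raise ValueError("baits must be non-overlapping")
        for b in self.baits:
            if not 0.0 <= b.score <= 1.0:
                raise ValueError("bait conservation score must be in [0, 1]")

    def kmer_set(self) -> set[str]:
        """Strand-symmetric bait k-mers (reads may come in either
        orientation, and flip-flop inversion reverses the SSC)."""
        from plastidflip.sequtil import revcomp

        kms: set[str] = set()
        for b in self.baits:
            for s in (b.seq, revcomp(b.seq)):
                for i in range(len(s) - self.k + 1):
                    kms.add(s[i : i + self.k])
        return kms


@dataclass
class ReadPartition:
    chloroplast: list[LongRead]
    background: list[LongRead]
    stats: list[dict[str, Any]]
    skipped: int = 0


@dataclass
class DepthProfile:
    coverage: np.ndarray  # per-base int coverage on the one-IR reference
    regions: dict[str, tuple[int, int]]
    placed_bases: int = 0
    unplaced_chunks: int = 0

    def mean_depth(self, label: str) -> float:
        s, e = self.regions[label]
        return float(self.coverage[s:e].mean())

    def ir_sc_ratio(self) -> float:
        sc = np.concatenate(
            [self.coverage[slice(*self.regions[lab])] for lab in ("LSC", "SSC")]
        )
        if sc.mean() == 0:
            return float("nan")
        return self.mean_depth("IR") / float(sc.mean())


def _conservation_track(panel: list[str], k: int) -> np.ndarray:
    """Per-position min fraction (0/1) of reference k-mers present in each
    other panel genome; cross-panel identity proxy for window scoring."""
    ref = panel[0]
    n = len(ref) - k + 1
    track = np.ones(n, dtype=float)
    for other in panel[1:]:
        kms = {other[i : i + k] for i in range(len(other) - k + 1)}
        pres = np.fromiter(
            (ref[i : i + k] in kms for i in range(n)), dtype=bool, count=n
        )
        track = np.minimum(track, pres.astype(float))
    return track


def build_bait_set(
    panel: list[str],
    n_regions: int = 40,
    region_len: int = 500,
    min_identity: float = 0.9,
    k: int = 21,
    min_match_fraction: float = 0.08,
) -> BaitSet:
    """Evenly spaced conserved windows on the first panel genome.

    Window conservation is the mean of a per-position cross-panel k-mer
    presence track; windows under ``min_identity`` are shifted to the
    nearest passing offset within half a spacing, else dropped (recorded
    in ``BaitSet.dropped``).
    """
    if len(panel) < 2:
        raise ValueError("panel must contain at least 2 genomes")
    ref = panel[0]
    if n_regions * region_len > len(ref):
        raise ValueError("n_regions x region_len exceeds the reference length")
    track = _conservation_track(panel, k)
    csum = np.concatenate(([0.0], np.cumsum(track)))
    n_win_pos = len(track) - (region_len - k)  # valid window starts

    def win_score(s: int) -> float:
        e = s + region_len - k + 1
        return float(csum[e] - csum[s]) / (region_len - k + 1)

    if n_win_pos <= 0:
        raise ValueError("region_len too large for the reference")

    baits: list[Bait] = []
    dropped: list[tuple[int, float]] = []
    if n_regions == 1:
        scores = (csum[region_len - k + 1 :] - csum[: n_win_pos]) / (region_len - k + 1)
        best = int(np.argmax(scores))
        if scores[best] < min_identity:
            raise ValueError(
                f"no window reaches identity {min_identity}; best achievable "
                f"{scores[best]:.3f} at {best}"
            )
        baits.append(Bait(best, best + region_len, ref[best : best + region_len], float(scores[best])))
    else:
        spacing = len(ref) // n_regions
        half = spacing // 2
        taken_end = -1
        for i in range(n_regions):
            centre = i * spacing + (spacing - region_len) // 2
            centre = max(0, min(centre, n_win_pos - 1))
            candidates = [centre]
            stride = max(1, region_len // 4)
            for d in range(stride, half, stride):
                candidates.extend([centre + d, centre - d])
            placed = False
            best_seen = (centre, -1.0)
            for s in candidates:
                if s < 0 or s >= n_win_pos or s <= taken_end:
                    continue
                sc = win_score(s)
                if sc > best_seen[1]:
                    best_seen = (s, sc)
                if sc >= min_identity:
                    baits.append(Bait(s, s + region_len, ref[s : s + region_len], sc))
                    taken_end = s + region_len
                    placed = True
                    break
            if not placed:
                dropped.append(best_seen)
        if not baits:
            best = max(dropped, key=lambda t: t[1])
            raise ValueError(
                f"no window passes identity {min_identity}; best achievable "
                f"{best[1]:.3f} at {best[0]}"
            )
    return BaitSet(baits=baits, k=k, min_match_fraction=min_match_fraction, dropped=dropped)


def classify_reads(
    reads: list[LongRead], baits: BaitSet, stride: int = 4
) -> ReadPartition:
    """Partition reads into chloroplast vs background by bait k-mer sharing.

    A read is chloroplast iff the fraction of its sampled k-mers present in
    the bait k-mer set reaches ``baits.min_match_fraction``.  Reads shorter
    than k are skipped (counted).
    """
    kms = baits.kmer_set()
    k = baits.k
    chloro: list[LongRead] = []
    background: list[LongRead] = []
    stats: list[dict[str, Any]] = []
    skipped = 0
    for read in reads:
        if len(read.seq) < k:
            skipped += 1
            continue
        offs = range(0, len(read.seq) - k + 1, stride)
        n = 0
        hits = 0
        for off in offs:
            n += 1
            if read.seq[off : off + k] in kms:
                hits += 1
        frac = hits / n if n else 0.0
        is_cp = frac >= baits.min_match_fraction
        (chloro if is_cp else background).append(read)
        stats.append({"id": read.id, "match_fraction": frac, "kmers": n, "chloroplast": is_cp})
    return ReadPartition(chloro, background, stats, skipped)


def estimate_copy_number(
    cp_depth: float, nuclear_depth: float, nuclear_copies_per_cell: float = 2.0
) -> float:
    """Chloroplast genome copies per cell from the depth ratio."""
    if nuclear_depth <= 0:
        raise ValueError("nuclear_depth must be > 0")
    return cp_depth * nuclear_copies_per_cell / nuclear_depth


def one_ir_reference(genome: QuadripartiteGenome) -> tuple[str, dict[str, tuple[int, int]]]:
    """Linear reference with the second IR copy removed (IRb dropped)."""
    irb_s, _ = genome.regions["IRb"]
    seq = genome.seq[:irb_s]
    regions = {
        "LSC": genome.regions["LSC"],
        "IR": genome.regions["IRa"],
        "SSC": genome.regions["SSC"],
    }
    return seq, regions


def compute_depth_profile(
    reads: list[LongRead],
    reference: str,
    regions: dict[str, tuple[int, int]],
    k: int = 21,
    chunk: int = 500,
    stride: int = 50,
) -> DepthProfile:
    """Per-base depth from best-diagonal placement of read chunks.

    Each read is cut into ``chunk``-sized pieces placed independently at
    their best diagonal (forward or reverse complement); chunks from the
    collapsed IR copy therefore pile onto the single retained copy.
    """
    from plastidflip.sequtil import revcomp

    index = KmerIndex(reference, k)
    L = len(reference)
    diff = np.zeros(L + 1, dtype=np.int64)
    placed_bases = 0
    unplaced = 0
    bucket = 16
    for read in reads:
        seq = read.seq
        for off in range(0, len(seq), chunk):
            piece = seq[off : off + chunk]
            if len(piece) < k:
                continue
            # diagonal voting per strand; cover only the anchored span so
            # junction-spanning chunks do not bleed across regions
            best: tuple[int, int, int] | None = None  # (votes, span_start, span_end)
            for q in (piece, revcomp(piece)):
                votes: dict[int, list[int]] = {}
                for qoff in range(0, max(1, len(q) - k + 1), stride):
                    for pos in index.positions(q[qoff : qoff + k]):
                        votes.setdefault((pos - qoff) // bucket, []).append(pos)
                if not votes:
                    continue
                d, hits = max(votes.items(), key=lambda kv: (len(kv[1]), -kv[0]))
                # absorb bucket-edge jitter from the adjacent diagonals
                hits = hits + votes.get(d - 1, []) + votes.get(d + 1, [])
                span = (len(hits), min(hits), max(hits) + k)
                if best is None or span[0] > best[0]:
                    best = span
            if best is None or best[0] < 2:
                unplaced += 1
                continue
            s, e = max(0, best[1]), min(L, best[2])
            if e <= s:
                unplaced += 1
                continue
            diff[s] += 1
            diff[e] -= 1
            placed_bases += e - s
    coverage = np.cumsum(diff[:-1])
    return DepthProfile(coverage, regions, placed_bases, unplaced)
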