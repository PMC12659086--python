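"""Population simulator with region-structured variation and truth tables.

Generates per-sample genomes from a quadripartite reference by injecting
SNPs and small indels at region-specific densities, optionally placing a
stated fraction of LSC indels inside 5-8 bp direct repeats, mirroring IRa
indels to the reverse-complement-mapped IRb coordinate, and adding large
(>= 50 bp) structural variants.  Every sample is exactly reconstructable
from the emitted truth variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from plastidflip.genome import REGION_ORDER, QuadripartiteGenome
from plastidflip.repeats import find_direct_repeats
from plastidflip.sequtil import BASES, random_seq
from plastidflip.variants import VariantRecord, normalize_variant

_MARGIN = 5  # blocked bases around every event and region boundary

RateSpec = dict[str, float] | float


@dataclass
class PopulationTruth:
    reference: QuadripartiteGenome
    sample_ids: list[str]
    samples: dict[str, QuadripartiteGenome]
    variants: list[VariantRecord]
    params: dict[str, Any] = field(default_factory=dict)


def mirror_offset(x_off: int, ref_len: int, ir_len: int) -> int:
    """IRb-frame anchor offset of the reverse-complement image of an
    IRa-frame event anchored at ``x_off`` spanning ``ref_len`` bases."""
    return ir_len - x_off - ref_len


def _rate(spec: RateSpec, region: str) -> float:
    if isinstance(spec, dict):
        return float(spec.get(region, 0.0))
    return float(spec)


def apply_variants(reference: str, variants: list[VariantRecord], sample_id: str) -> str:
    """Splice a sample's carried variants into the reference sequence."""
    carried = sorted(
        (v for v in variants if v.genotypes.get(sample_id, 0) > 0),
        key=lambda v: v.pos,
    )
    out: list[str] = []
    cursor = 0
    for v in carried:
        if v.pos < cursor:
            raise ValueError("overlapping variants cannot be applied")
        alt = v.alts[v.genotypes[sample_id] - 1]
        out.append(reference[cursor : v.pos])
        out.append(alt)
        cursor = v.end
    out.append(reference[cursor:])
    return "".join(out)


def _shifted_regions(
    regions: dict[str, tuple[int, int]], variants: list[VariantRecord], sample_id: str
) -> dict[str, tuple[int, int]]:
    carried = [v for v in variants if v.genotypes.get(sample_id, 0) > 0]
    deltas = sorted(
        (v.pos, len(v.alts[v.genotypes[sample_id] - 1]) - len(v.ref)) for v in carried
    )

    def shift(b: int) -> int:
        return b + sum(d for p, d in deltas if p < b)

    return {lab: (shift(s), shift(e)) for lab, (s, e) in regions.items()}


class _Placer:
    """Tracks blocked intervals so injected events never overlap."""

    def __init__(self, length: int, boundaries: list[int]):
        self.blocked = np.zeros(length, dtype=bool)
        for b in boundaries:
            lo, hi = max(0, b - _MARGIN - 3), min(length, b + _MARGIN + 3)
            self.blocked[lo:hi] = True
        self.blocked[: _MARGIN + 1] = True
        self.blocked[-(_MARGIN + 1) :] = True

    def ok(self, start: int, span: int) -> bool:
        lo, hi = max(0, start - _MARGIN), min(len(self.blocked), start + span + _MARGIN)
        return not self.blocked[lo:hi].any()

    def take(self, start: int, span: int) -> None:
        lo, hi = max(0, start - _MARGIN), min(len(self.blocked), start + span + _MARGIN)
        self.blocked[lo:hi] = True


def _draw_carriers(n_samples: int, rng: np.random.Generator) -> list[int]:
    c = int(rng.integers(1, n_samples + 1))
    return sorted(rng.choice(n_samples, size=c, replace=False).tolist())


def mutate_population(
    reference: QuadripartiteGenome,
    n_samples: int,
    snp_rate_by_region: RateSpec,
    indel_rate_by_region: RateSpec,
    indel_in_repeat_fraction: float = 0.0,
    ir_mirror_prob: float = 0.0,
    sv_spec: list[dict[str, Any]] | None = None,
    seed: int | None = None,
) -> PopulationTruth:
    """Sample a population of genomes plus an exact truth variant table.

    Rates are per-site probabilities that a segregating site of that type
    exists in the population within the region.  ``indel_in_repeat_fraction``
    applies to LSC indels (placed inside 5-8 bp direct repeats of the
    reference LSC); ``ir_mirror_prob`` is the probability that an IRa indel
    has a mirrored partner at the reverse-complement-mapped IRb coordinate,
    carried by the same samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not 0.0 <= indel_in_repeat_fraction <= 1.0:
        raise ValueError("indel_in_repeat_fraction must be in [0, 1]")
    if not 0.0 <= ir_mirror_prob <= 1.0:
        raise ValueError("ir_mirror_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = reference.seq
    L = len(seq)
    boundaries = [reference.regions[lab][0] for lab in REGION_ORDER] + [L]
    placer = _Placer(L, boundaries)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    variants: list[VariantRecord] = []

    lsc_start, lsc_end = reference.regions["LSC"]
    lsc_seq = seq[lsc_start:lsc_end]
    repeat_cov = np.zeros(len(lsc_seq), dtype=bool)
    repeat_starts: list[tuple[int, int]] = []  # (genome_pos, k)
    if indel_in_repeat_fraction > 0:
        for occ in find_direct_repeats(lsc_seq, 3, 30):
            if not 5 <= occ.k <= 8:
                continue
            for p in occ.positions:
                repeat_cov[p : p + occ.k] = True
                repeat_starts.append((lsc_start + p, occ.k))
        repeat_starts.sort()

    def genotypes_for(carriers: list[int]) -> dict[str, int]:
        g = {sid: 0 for sid in sample_ids}
        for ci in carriers:
            g[sample_ids[ci]] = 1
        return g

    def is_canonical(pos: int, ref_a: str, alt_a: str) -> bool:
        """True when the event is already in left-aligned canonical form,
        so the truth table matches what any normalizing caller reports."""
        return normalize_variant(pos, ref_a, alt_a, seq) == (pos, ref_a, alt_a)

    def add_variant(pos: int, ref_a: str, alt_a: str, carriers: list[int]) -> VariantRecord:
        v = VariantRecord(pos, ref_a, (alt_a,), genotypes=genotypes_for(carriers))
        v.region = reference.region_of(pos)
        variants.append(v)
        placer.take(pos, len(ref_a))
        return v

    def place_snp(r_start: int, r_end: int) -> None:
        for _ in range(2000):
            p = int(rng.integers(r_start, r_end))
            if placer.ok(p, 1):
                ref_a = seq[p]
                alt_a = str(rng.choice([b for b in BASES if b != ref_a]))
                add_variant(p, ref_a, alt_a, _draw_carriers(n_samples, rng))
                return
        raise ValueError("could not place SNP: region saturated")

    def draft_indel(p: int) -> tuple[int, str, str] | None:
        """Candidate canonical indel anchored at p, or None to retry."""
        d = int(rng.choice([1, 2, 3], p=[0.6, 0.25, 0.15]))
        if rng.random() < 0.5 and p + 1 + d < L:  # deletion
            cand = (p, seq[p : p + 1 + d], seq[p])
        else:
            cand = (p, seq[p], seq[p] + random_seq(d, 0.4, rng))
        return cand if is_canonical(*cand) else None

    def draft_mirror(pos: int, ref_a: str, alt_a: str) -> tuple[int, str, str] | None:
        """Reverse-complement-mapped IRb partner of an IRa indel candidate."""
        ira_s, _ira_e = reference.regions["IRa"]
        irb_s, irb_e = reference.regions["IRb"]
        q = irb_s + mirror_offset(pos - ira_s, len(ref_a), irb_e - irb_s)
        span = len(ref_a)
        if q < irb_s or q + span > irb_e or not placer.ok(q, span + 1):
            return None
        delta = len(alt_a) - len(ref_a)
        if delta < 0:
            cand = (q, seq[q : q + 1 - delta], seq[q])
        else:
            cand = (q, seq[q], seq[q] + random_seq(delta, 0.4, rng))
        return cand if is_canonical(*cand) else None

    def place_indel(
        r_start: int, r_end: int, in_repeat: bool | None = None, mirror: bool = False
    ) -> None:
        for _ in range(8000):
            if in_repeat is True:
                if not repeat_starts:
                    raise ValueError("no 5-8 bp LSC repeats available for placement")
                p, _k = repeat_starts[int(rng.integers(0, len(repeat_starts)))]
            else:
                p = int(rng.integers(r_start, r_end))
                if in_repeat is False:
                    off = p - lsc_start
                    lo, hi = max(0, off - 1), min(len(lsc_seq), off + 6)
                    if repeat_cov[lo:hi].any():
                        continue
            if not placer.ok(p, 4):
                continue
            cand = draft_indel(p)
            if cand is None:
                continue
            partner = None
            if mirror and rng.random() < ir_mirror_prob:
                partner = draft_mirror(*cand)
                if partner is None:
                    continue  # mirrored pair must be placeable atomically
            carriers = _draw_carriers(n_samples, rng)
            add_variant(*cand, carriers)
            if partner is not None:
                add_variant(*partner, carriers)
            return
        raise ValueError("could not place indel: region saturated or rates too high")

    for label in REGION_ORDER:
        r_start, r_end = reference.regions[label]
        r_len = r_end - r_start
        n_snp = int(rng.binomial(r_len, min(1.0, _rate(snp_rate_by_region, label))))
        n_indel = int(rng.binomial(r_len, min(1.0, _rate(indel_rate_by_region, label))))
        if (n_snp + n_indel) * (2 * _MARGIN + 4) > r_len:
            raise ValueError(
                f"requested rates imply more variants than region {label} can host"
            )
        for _ in range(n_snp):
            place_snp(r_start, r_end)
        if label == "LSC" and indel_in_repeat_fraction > 0:
            n_in = int(round(indel_in_repeat_fraction * n_indel))
            for _ in range(n_in):
                place_indel(r_start, r_end, in_repeat=True)
            for _ in range(n_indel - n_in):
                place_indel(r_start, r_end, in_repeat=False)
        else:
            mirror = label == "IRa" and ir_mirror_prob > 0
            for _ in range(n_indel):
                place_indel(r_start, r_end, mirror=mirror)

    for sv in sv_spec or []:
        label = sv.get("region", "LSC")
        kind = sv.get("kind", "ins")
        length = int(sv.get("length", 60))
        if length < 50:
            raise ValueError("sv_spec length must be >= 50")
        r_start, r_end = reference.regions[label]
        placed = False
        for _ in range(4000):
            p = int(rng.integers(r_start, r_end - length - 2))
            span = 1 + (length if kind == "del" else 0)
            if not placer.ok(p, span):
                continue
            if kind == "del":
                cand = (p, seq[p : p + 1 + length], seq[p])
            else:
                cand = (p, seq[p], seq[p] + random_seq(length, 0.4, rng))
            if not is_canonical(*cand):
                continue
            carriers = sv.get("carriers")
            carriers = (
                sorted(rng.choice(n_samples, size=int(carriers), replace=False).tolist())
                if carriers
                else _draw_carriers(n_samples, rng)
            )
            add_variant(*cand, carriers)
            placed = True
            break
        if not placed:
            raise ValueError(f"could not place SV in {label}")

    variants.sort(key=lambda v: (v.pos, v.ref, v.alts))
    samples = {}
    for sid in sample_ids:
        smp_seq = apply_variants(seq, variants, sid)
        samples[sid] = QuadripartiteGenome(
            seq=smp_seq, regions=_shifted_regions(reference.regions, variants, sid)
        )
    params = {
        "n_samples": n_samples,
        "snp_rate_by_region": snp_rate_by_region,
        "indel_rate_by_region": indel_rate_by_region,
        "indel_in_repeat_fraction": indel_in_repeat_fraction,
        "ir_mirror_prob": ir_mirror_prob,
        "sv_spec": sv_spec,
        "seed": seed,
    }
    return PopulationTruth(reference, sample_ids, samples, variants, params)
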