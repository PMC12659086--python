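"""Pangenome variant map: pairwise/MSA variant extraction and annotation.

Variants are reference-projected, VCF-style anchored and left-aligned.
Events whose allele length difference is >= 50 bp are classified as SV;
length-changing events below that are indels; single-base substitutions
are SNPs.  Genotypes are haploid (homoplasmic chloroplast model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plastidflip.anchors import align_pair, alignment_to_ops, kmer_identity
from plastidflip.genome import Gene, QuadripartiteGenome

SV_MIN_LENGTH = 50


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if abs(len(ref) - len(alt)) >= SV_MIN_LENGTH:
        return "SV"
    if len(ref) != len(alt):
        return "indel"
    return "SNP"  # equal-length multi-base substitution: treated per-column upstream


@dataclass
class VariantRecord:
    """One reference-projected variant site (0-based anchor position)."""

    pos: int
    ref: str
    alts: tuple[str, ...]
    vtype: str = ""
    region: str = ""
    context: str = ""
    genotypes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref or any(not a for a in self.alts):
            raise ValueError("alleles must be non-empty")
        if not self.vtype:
            self.vtype = classify_alleles(self.ref, self.alts[0])

    @property
    def end(self) -> int:
        """Half-open end of the reference span."""
        return self.pos + len(self.ref)

    def carriers(self) -> set[str]:
        return {s for s, g in self.genotypes.items() if g > 0}


def normalize_variant(pos: int, ref: str, alt: str, reference: str) -> tuple[int, str, str]:
    """Left-align and parsimony-trim an anchored variant against the reference."""
    # trim identical trailing bases (keeping at least one base per allele),
    # shifting left through repeats as we go
    while True:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        if len(ref) > 1 and len(alt) > 1:
            break
        if ref[-1] == alt[-1] and pos > 0:
            base = reference[pos - 1]
            ref, alt = base + ref[:-1], base + alt[:-1]
            pos -= 1
            continue
        break
    # trim identical leading bases (keep anchor for indels)
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def align_sample(
    sample_seq: str, reference: str, min_identity: float = 0.9
) -> tuple[str, str]:
    """Global pairwise alignment (reference row first), indels left-aligned."""
    ident = kmer_identity(sample_seq, reference)
    if ident < min_identity:
        raise ValueError(
            f"sequences too divergent (k-mer identity {ident:.2f} < "
            f"{min_identity}); supply an external MSA instead"
        )
    ref_aln, smp_aln = align_pair(reference, sample_seq)
    return ref_aln, smp_aln


def _events_from_pair(ref_aln: str, smp_aln: str, reference: str) -> list[tuple[int, str, str]]:
    """(pos, ref, alt) events from one pairwise alignment, normalized."""
    events: list[tuple[int, str, str]] = []
    ops = alignment_to_ops(ref_aln, smp_aln)
    smp = smp_aln.replace("-", "")
    for op in ops:
        if op.op == "M":
            a_seg = reference[op.a_pos : op.a_pos + op.length]
            b_seg = smp[op.b_pos : op.b_pos + op.length]
            for i, (x, y) in enumerate(zip(a_seg, b_seg)):
                if x != y:
                    events.append((op.a_pos + i, x, y))
        elif op.op == "D":  # deletion in sample
            if op.a_pos > 0:
                anchor = op.a_pos - 1
                ref_a = reference[anchor : op.a_pos + op.length]
                alt_a = reference[anchor]
            else:  # right-anchor at sequence start
                anchor = 0
                ref_a = reference[: op.length + 1]
                alt_a = reference[op.length]
            events.append(normalize_variant(anchor, ref_a, alt_a, reference))
        else:  # insertion in sample
            ins = smp[op.b_pos : op.b_pos + op.length]
            if op.a_pos > 0:
                anchor = op.a_pos - 1
                ref_a = reference[anchor]
                alt_a = ref_a + ins
            else:
                anchor = 0
                ref_a = reference[0]
                alt_a = ins + ref_a
            events.append(normalize_variant(anchor, ref_a, alt_a, reference))
    return events


def _events_from_msa_row(
    ref_row: str, smp_row: str, reference: str
) -> list[tuple[int, str, str]]:
    """Events for one sample row of an MSA against the reference row.

    Columns gapped in both rows are skipped; maximal contiguous gap runs
    are merged into single indel events.
    """
    # project MSA columns down to a pairwise alignment of the two rows
    pair_ref: list[str] = []
    pair_smp: list[str] = []
    for cr, cs in zip(ref_row, smp_row):
        if cr == "-" and cs == "-":
            continue
        pair_ref.append(cr)
        pair_smp.append(cs)
    return _events_from_pair("".join(pair_ref), "".join(pair_smp), reference)


def call_variants(
    alignments: dict[str, tuple[str, str]] | None = None,
    msa: dict[str, str] | None = None,
    reference_id: str | None = None,
    reference: str | None = None,
) -> list[VariantRecord]:
    """Merge per-sample events into a sorted list of variant records.

    Either ``alignments`` (sample_id -> (ref_row, sample_row) pairwise
    alignments) or ``msa`` (sample_id -> aligned row, with ``reference_id``
    naming the reference row) must be given.
    """
    per_sample: dict[str, list[tuple[int, str, str]]] = {}
    if msa is not None:
        if reference_id is None or reference_id not in msa:
            raise ValueError("msa input requires reference_id present in the MSA")
        widths = {len(r) for r in msa.values()}
        if len(widths) != 1:
            raise ValueError("ragged alignment: rows differ in length")
        ref_row = msa[reference_id]
        reference = ref_row.replace("-", "")
        for sid, row in msa.items():
            if sid == reference_id:
                continue
            per_sample[sid] = _events_from_msa_row(ref_row, row, reference)
    elif alignments is not None:
        if reference is None:
            first = next(iter(alignments.values()))
            reference = first[0].replace("-", "")
        for sid, (ref_aln, smp_aln) in alignments.items():
            if ref_aln.replace("-", "") != reference:
                raise ValueError(f"alignment for {sid} does not match the reference")
            per_sample[sid] = _events_from_pair(ref_aln, smp_aln, reference)
    else:
        raise ValueError("either alignments or msa must be provided")

    sample_ids = sorted(per_sample)
    # merge: SNPs grouped by (pos, ref) with multiple alts; indels/SV by allele
    snp_sites: dict[tuple[int, str], dict[str, list[str]]] = {}
    indel_sites: dict[tuple[int, str, str], list[str]] = {}
    for sid in sample_ids:
        for pos, ref_a, alt_a in per_sample[sid]:
            if len(ref_a) == 1 and len(alt_a) == 1:
                snp_sites.setdefault((pos, ref_a), {}).setdefault(alt_a, []).append(sid)
            else:
                indel_sites.setdefault((pos, ref_a, alt_a), []).append(sid)

    records: list[VariantRecord] = []
    for (pos, ref_a), alts in sorted(snp_sites.items()):
        alt_list = sorted(alts)
        genotypes = {sid: 0 for sid in sample_ids}
        for ai, alt_a in enumerate(alt_list, start=1):
            for sid in alts[alt_a]:
                genotypes[sid] = ai
        records.append(
            VariantRecord(pos, ref_a, tuple(alt_list), genotypes=genotypes)
        )
    for (pos, ref_a, alt_a), carriers in sorted(indel_sites.items()):
        genotypes = {sid: (1 if sid in carriers else 0) for sid in sample_ids}
        records.append(VariantRecord(pos, ref_a, (alt_a,), genotypes=genotypes))
    records.sort(key=lambda r: (r.pos, r.ref, r.alts))
    return records


def annotate_variants(
    variants: list[VariantRecord],
    genome: QuadripartiteGenome,
    genes: list[Gene] | None = None,
    introns: list[Gene] | None = None,
) -> dict[tuple[str, str], int]:
    """Label variants with region and genic context; returns count table.

    A variant is exonic if its reference span intersects a gene and no
    intron, intronic if it intersects an intron, intergenic otherwise.
    The returned table maps (region, vtype) -> count.
    """
    genes = genes if genes is not None else genome.genes
    introns = introns or []
    counts: dict[tuple[str, str], int] = {}
    for v in variants:
        if not 0 <= v.pos < len(genome.seq):
            raise ValueError(f"variant position {v.pos} outside reference")
        v.region = genome.region_of(v.pos)
        span = (v.pos, v.end)
        in_gene = any(g.start < span[1] and span[0] < g.end for g in genes)
        in_intron = any(g.start < span[1] and span[0] < g.end for g in introns)
        if in_intron:
            v.context = "intronic"
        elif in_gene:
            v.context = "exonic"
        else:
            v.context = "intergenic"
        key = (v.region, v.vtype)
        counts[key] = counts.get(key, 0) + 1
    return counts


def _event_length(ref: str, alt: str) -> int:
    d = abs(len(ref) - len(alt))
    return d if d > 0 else len(ref)


def pan_unique_curve(
    variants: list[VariantRecord],
    reference_len: int,
    n_values: list[int],
    n_perm: int = 100,
    seed: int | None = None,
    mode: str = "private",
    sample_ids: list[str] | None = None,
) -> list[tuple[int, float]]:
    """Pan-genome unique-sequence curve over random sample combinations.

    The reference genome is always the first member of every combination,
    anchoring the n=1 column to the reference length.  A combination's
    unique sequence is the summed length of variant events carried by at
    least one member and, in ``private`` mode, by no sample outside the
    combination; ``union`` mode drops the privacy requirement.  Per n the
    maximum over ``n_perm`` sampled combinations is reported.
    """
    if mode not in ("private", "union"):
        raise ValueError("mode must be 'private' or 'union'")
    if sample_ids is None:
        sample_ids = sorted({s for v in variants for s in v.genotypes})
    n_samples = len(sample_ids) + 1  # reference counts as a sample
    rng = np.random.default_rng(seed)
    events = [
        (frozenset(v.carriers()), _event_length(v.ref, v.alts[0]))
        for v in variants
        if v.carriers()
    ]
    curve: list[tuple[int, float]] = []
    for n in n_values:
        if not 1 <= n <= n_samples:
            raise ValueError(f"n={n} outside 1..{n_samples}")
        best = 0
        for _ in range(n_perm):
            chosen = set(
                rng.choice(sample_ids, size=n - 1, replace=False)
            ) if n > 1 else set()
            total = 0
            for carriers, length in events:
                if not carriers & chosen:
                    continue
                if mode == "private" and not carriers <= chosen:
                    continue
                total += length
            best = max(best, total)
        curve.append((n, float(reference_len + best)))
    return curve
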