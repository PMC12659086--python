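"""Quadripartite chloroplast genome model and synthetic genome builder.

A chloroplast genome is modelled as a circular sequence linearized at the
start of the large single-copy region (LSC), tiled by the four canonical
regions in fixed order LSC-IRa-SSC-IRb.  The two inverted repeats are
near-perfect reverse complements of each other; the builder can inject a
configurable number of small (1-3 bp indel or SNP) differences between
them, mimicking the indel-dominated IR divergence seen in real plastomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from plastidflip.sequtil import BASES, random_seq, revcomp

REGION_ORDER = ("LSC", "IRa", "SSC", "IRb")

# default region lengths for the synthetic plastome (total 135,900 bp)
DEFAULT_LSC = 80_004
DEFAULT_IRA = 21_552
DEFAULT_SSC = 12_791
DEFAULT_IRB = 21_553


@dataclass
class Gene:
    name: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"


@dataclass
class IrDifference:
    """A single injected IRa/IRb difference, in IRa-frame coordinates."""

    kind: str  # "SNP" | "ins" | "del"
    pos: int  # 0-based offset within IRa
    ref: str  # IRa-frame allele
    alt: str  # IRb-frame (reverse-complement-mapped) allele


@dataclass
class QuadripartiteGenome:
    """Circular genome with LSC/IRa/SSC/IRb partition.

    ``regions`` maps region label to 0-based half-open intervals on the
    linearized sequence; the four intervals tile the sequence exactly.
    """

    seq: str
    regions: dict[str, tuple[int, int]]
    genes: list[Gene] = field(default_factory=list)
    is_circular: bool = True
    ir_diffs: list[IrDifference] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if set(self.regions) != set(REGION_ORDER):
            raise ValueError(f"regions must be exactly {REGION_ORDER}")
        cursor = 0
        for label in REGION_ORDER:
            start, end = self.regions[label]
            if start != cursor or end <= start:
                raise ValueError(
                    f"region {label} [{start},{end}) does not tile contiguously"
                )
            cursor = end
        if cursor != len(self.seq):
            raise ValueError("region intervals do not cover the full sequence")
        for gene in self.genes:
            if not (0 <= gene.start < gene.end <= len(self.seq)):
                raise ValueError(f"gene {gene.name} out of bounds")

    def __len__(self) -> int:
        return len(self.seq)

    def region_seq(self, label: str) -> str:
        start, end = self.regions[label]
        return self.seq[start:end]

    def region_len(self, label: str) -> int:
        start, end = self.regions[label]
        return end - start

    def region_of(self, pos: int) -> str:
        for label in REGION_ORDER:
            start, end = self.regions[label]
            if start <= pos < end:
                return label
        raise ValueError(f"position {pos} outside genome of length {len(self.seq)}")

    def boundary_description(self) -> str:
        """Compact region encoding used in FASTA descriptions."""
        return ";".join(
            f"{label}={self.regions[label][0]}-{self.regions[label][1]}"
            for label in REGION_ORDER
        )

    @staticmethod
    def parse_boundary_description(seq: str, desc: str) -> "QuadripartiteGenome":
        regions: dict[str, tuple[int, int]] = {}
        for token in desc.strip().split(";"):
            label, span = token.split("=")
            a, b = span.split("-")
            regions[label] = (int(a), int(b))
        return QuadripartiteGenome(seq=seq, regions=regions)


def _edit_deltas(n_diffs: int, need: int, rng: np.random.Generator) -> list[int]:
    """Per-edit length deltas in [-3,3] summing to ``need`` (0 delta = SNP)."""
    if abs(need) > 3 * n_diffs:
        raise ValueError(
            f"cannot realize IR length difference {need} with {n_diffs} 1-3 bp edits"
        )
    deltas = [int(d) for d in rng.integers(-3, 4, size=n_diffs)]
    gap = need - sum(deltas)
    i = 0
    while gap != 0:
        step = 1 if gap > 0 else -1
        new = deltas[i % n_diffs] + step
        if -3 <= new <= 3:
            deltas[i % n_diffs] = new
            gap -= step
        i += 1
    return deltas


def _apply_ir_edits(
    ira: str, positions: list[int], deltas: list[int], rng: np.random.Generator
) -> tuple[str, list[IrDifference]]:
    """Apply SNP/indel edits to the IRa-frame sequence; returns edited copy."""
    diffs: list[IrDifference] = []
    out: list[str] = []
    prev = 0
    for pos, delta in sorted(zip(positions, deltas)):
        out.append(ira[prev:pos])
        if delta == 0:
            ref = ira[pos]
            alt = rng.choice([b for b in BASES if b != ref])
            out.append(alt)
            prev = pos + 1
            diffs.append(IrDifference("SNP", pos, ref, alt))
        elif delta > 0:
            ins = random_seq(delta, 0.5, rng)
            out.append(ins)
            prev = pos
            diffs.append(IrDifference("ins", pos, "", ins))
        else:
            d = -delta
            out.append("")
            prev = pos + d
            diffs.append(IrDifference("del", pos, ira[pos : pos + d], ""))
    out.append(ira[prev:])
    return "".join(out), diffs


def build_genome(
    lsc_len: int = DEFAULT_LSC,
    ira_len: int = DEFAULT_IRA,
    ssc_len: int = DEFAULT_SSC,
    irb_len: int = DEFAULT_IRB,
    gc_overall: float = 0.38,
    gc_ir: float = 0.44,
    n_ir_diffs: int = 1,
    seed: int | None = None,
) -> QuadripartiteGenome:
    """Build a random quadripartite genome.

    IRb is the reverse complement of IRa except for exactly ``n_ir_diffs``
    injected 1-3 bp differences (SNPs and indels).  The net indel length
    difference is constrained to reconcile ``ira_len`` with ``irb_len``.
    Single-copy GC is derived so that the overall GC hits ``gc_overall``
    given ``gc_ir`` in the repeats.
    """
    for name, v in (("lsc_len", lsc_len), ("ira_len", ira_len),
                    ("ssc_len", ssc_len), ("irb_len", irb_len)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    if not (0 <= gc_overall <= 1 and 0 <= gc_ir <= 1):
        raise ValueError("gc values must be in [0, 1]")
    if n_ir_diffs < 0:
        raise ValueError("n_ir_diffs must be >= 0")
    if n_ir_diffs == 0 and ira_len != irb_len:
        raise ValueError("n_ir_diffs=0 requires equal IR lengths")
    if n_ir_diffs > 0 and ira_len < 8 * n_ir_diffs + 20:
        raise ValueError("IR too short to host the requested number of differences")

    rng = np.random.default_rng(seed)
    total = lsc_len + ira_len + ssc_len + irb_len
    sc_len = lsc_len + ssc_len
    gc_sc = (gc_overall * total - gc_ir * (ira_len + irb_len)) / sc_len
    if not 0.0 <= gc_sc <= 1.0:
        raise ValueError(
            f"gc_overall={gc_overall} with gc_ir={gc_ir} implies single-copy "
            f"GC {gc_sc:.3f} outside [0, 1]"
        )

    lsc = random_seq(lsc_len, gc_sc, rng)
    ira = random_seq(ira_len, gc_ir, rng)
    ssc = random_seq(ssc_len, gc_sc, rng)

    if n_ir_diffs == 0:
        irb_rc, diffs = ira, []
    else:
        deltas = _edit_deltas(n_ir_diffs, irb_len - ira_len, rng)
        lo, hi = 10, ira_len - 10
        step = (hi - lo) // n_ir_diffs
        positions = [
            lo + i * step + int(rng.integers(0, max(1, step - 8)))
            for i in range(n_ir_diffs)
        ]
        irb_rc, diffs = _apply_ir_edits(ira, positions, deltas, rng)
    irb = revcomp(irb_rc)
    assert len(irb) == irb_len

    seq = lsc + ira + ssc + irb
    regions = {
        "LSC": (0, lsc_len),
        "IRa": (lsc_len, lsc_len + ira_len),
        "SSC": (lsc_len + ira_len, lsc_len + ira_len + ssc_len),
        "IRb": (lsc_len + ira_len + ssc_len, total),
    }
    return QuadripartiteGenome(seq=seq, regions=regions, ir_diffs=diffs)


def generate_isomer(
    genome: QuadripartiteGenome, orientation: str, invert: str = "ssc"
) -> str:
    """Sequence of one of the two flip-flop inversion isomers.

    ``reference`` returns the genome sequence unchanged; ``inverted``
    reverse-complements the single-copy segment named by ``invert``
    (``ssc`` by default), the canonical flip-flop product of
    intramolecular IR recombination.
    """
    if orientation == "reference":
        return genome.seq
    if orientation != "inverted":
        raise ValueError(f"unknown orientation {orientation!r}")
    label = {"ssc": "SSC", "lsc": "LSC"}.get(invert.lower())
    if label is None:
        raise ValueError(f"invert must be 'ssc' or 'lsc', got {invert!r}")
    start, end = genome.regions[label]
    return genome.seq[:start] + revcomp(genome.seq[start:end]) + genome.seq[end:]


def make_synthetic_genes(
    genome: QuadripartiteGenome,
    genes_per_region: int = 5,
    gene_len: int = 900,
    seed: int | None = None,
) -> list[Gene]:
    """Evenly spaced placeholder genes per region (for context annotation)."""
    rng = np.random.default_rng(seed)
    genes: list[Gene] = []
    for label in REGION_ORDER:
        start, end = genome.regions[label]
        span = end - start
        n = min(genes_per_region, max(0, span // (2 * gene_len)))
        if n == 0:
            continue
        step = span // (n + 1)
        for i in range(n):
            gstart = start + (i + 1) * step - gene_len // 2
            gstart = max(start, min(gstart, end - gene_len))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"{label.lower()}_g{i + 1}", gstart, gstart + gene_len, strand))
    return genes
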