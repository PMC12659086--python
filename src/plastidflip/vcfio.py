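"""VCF 4.2 emission and parsing for haploid variant records.

Records are written with 1-based positions, anchored left-aligned alleles
and haploid GT fields; the header carries the contig line so files parse
under standard VCF tooling.
"""

from __future__ import annotations

from pathlib import Path

from plastidflip.variants import VariantRecord

_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##source=plastidflip',
    '##INFO=<ID=VT,Number=1,Type=String,Description="Variant type: SNP, indel or SV">',
    '##INFO=<ID=REGION,Number=1,Type=String,Description="Quadripartite region">',
    '##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Genic context">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
]


def write_vcf(
    path: str | Path,
    variants: list[VariantRecord],
    contig: str,
    contig_length: int,
    sample_ids: list[str] | None = None,
) -> None:
    for a, b in zip(variants, variants[1:]):
        if b.pos < a.pos:
            raise ValueError("variants must be sorted by position")
    if sample_ids is None:
        ids: set[str] = set()
        for v in variants:
            ids.update(v.genotypes)
        sample_ids = sorted(ids)
    with open(path, "w") as fh:
        for line in _HEADER_LINES:
            fh.write(line + "\n")
        fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + sample_ids) + "\n")
        for v in variants:
            info = f"VT={v.vtype}"
            if v.region:
                info += f";REGION={v.region}"
            if v.context:
                info += f";CONTEXT={v.context}"
            gts = [str(v.genotypes.get(s, 0)) for s in sample_ids]
            fh.write(
                f"{contig}\t{v.pos + 1}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t"
                f"{info}\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    variants: list[VariantRecord] = []
    sample_ids: list[str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                sample_ids = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{path}:{ln}: malformed VCF record")
            pos = int(parts[1]) - 1
            ref = parts[3]
            alts = tuple(parts[4].split(","))
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, "")
                for kv in parts[7].split(";")
            )
            genotypes = {}
            for sid, gt in zip(sample_ids, parts[9:]):
                genotypes[sid] = int(gt.split(":")[0].replace("|", "/").split("/")[0])
            v = VariantRecord(
                pos,
                ref,
                alts,
                vtype=info.get("VT", ""),
                region=info.get("REGION", ""),
                context=info.get("CONTEXT", ""),
                genotypes=genotypes,
            )
            variants.append(v)
    return variants, sample_ids
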