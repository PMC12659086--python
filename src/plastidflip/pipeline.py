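"""End-to-end pipeline driver: simulate -> enrich -> classify-ir ->
consensus -> detect-isomers -> call-variants -> popgen -> repeats.

Every run writes the resolved configuration next to its outputs and a
machine-readable summary JSON; with a fixed seed all outputs are
byte-identical across runs.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from plastidflip import enrichment, ir_assembly, isomer, popgen, repeats as rp
from plastidflip.genome import build_genome
from plastidflip.population import mutate_population
from plastidflip.reads import simulate_reads
from plastidflip.seqio import (
    write_bed,
    write_bedgraph,
    write_fastq,
    write_genome_fasta,
    write_tsv,
)
from plastidflip.variants import align_sample, annotate_variants, call_variants, pan_unique_curve
from plastidflip.vcfio import write_vcf

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "plastidflip_out",
    "stages": [
        "simulate",
        "enrich",
        "classify-ir",
        "consensus",
        "detect-isomers",
        "call-variants",
        "popgen",
        "repeats",
    ],
    "genome": {
        "lsc_len": 20000,
        "ira_len": 6000,
        "ssc_len": 5000,
        "irb_len": 6000,
        "gc_overall": 0.38,
        "gc_ir": 0.44,
        "n_ir_diffs": 1,
    },
    "population": {
        "n_samples": 6,
        "snp_rate": {"LSC": 0.002, "IRa": 0.001, "SSC": 0.002, "IRb": 0.001},
        "indel_rate": {"LSC": 0.001, "IRa": 0.002, "SSC": 0.001, "IRb": 0.0},
        "indel_in_repeat_fraction": 0.63,
        "ir_mirror_prob": 0.8,
        "sv_spec": [{"region": "LSC", "kind": "ins", "length": 60}],
    },
    "reads": {
        "depth": 20,
        "isomer_ratio": 0.5,
        "read_len_mean": 5000,
        "read_len_sd": 500,
        "error_rate": 0.0,
        "nuclear_background_fraction": 0.1,
    },
    "enrichment": {
        "n_baits": 20,
        "bait_len": 400,
        "min_identity": 0.8,
        "min_match_fraction": 0.08,
    },
    "ir": {"flank": 2000, "min_flank_overlap": 500},
    "isomer": {"min_flank": 2000, "target_qualifying": 300},
    "popgen": {"window": 1000, "step": 500},
    "repeats": {"k_min": 3, "k_max": 30, "bin_size": 50},
}


def _merge_validate(base: dict[str, Any], override: dict[str, Any], path: str = "") -> dict[str, Any]:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise ValueError(f"unknown config key: {path}{key}")
        if isinstance(base[key], dict) and not path.startswith("population"):
            if not isinstance(val, dict):
                raise ValueError(f"config key {path}{key} must be a mapping")
            out[key] = _merge_validate(base[key], val, f"{path}{key}.")
        else:
            out[key] = copy.deepcopy(val)
    return out


@dataclass
class PipelineConfig:
    values: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    @classmethod
    def from_dict(cls, overrides: dict[str, Any]) -> "PipelineConfig":
        return cls(values=_merge_validate(DEFAULT_CONFIG, overrides))

    def __getitem__(self, key: str) -> Any:
        return self.values[key]


def run_pipeline(config: PipelineConfig | dict[str, Any], outdir: str | Path | None = None) -> dict[str, Any]:
    """Execute the configured stages; returns the summary dict."""
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    cfg = config.values
    outdir = Path(outdir or cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.resolved.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    seed = int(cfg["seed"])
    stages = cfg["stages"]
    summary: dict[str, Any] = {"seed": seed}

    gcfg = cfg["genome"]
    genome = build_genome(
        gcfg["lsc_len"], gcfg["ira_len"], gcfg["ssc_len"], gcfg["irb_len"],
        gcfg["gc_overall"], gcfg["gc_ir"], gcfg["n_ir_diffs"], seed=seed,
    )
    contig = "plastome"
    pcfg = cfg["population"]
    pop = mutate_population(
        genome,
        pcfg["n_samples"],
        pcfg["snp_rate"],
        pcfg["indel_rate"],
        pcfg["indel_in_repeat_fraction"],
        pcfg["ir_mirror_prob"],
        pcfg["sv_spec"],
        seed=seed + 1,
    )
    rcfg = cfg["reads"]
    readset = simulate_reads(
        genome,
        depth=rcfg["depth"],
        isomer_ratio=rcfg["isomer_ratio"],
        read_len_mean=rcfg["read_len_mean"],
        read_len_sd=rcfg["read_len_sd"],
        error_rate=rcfg["error_rate"],
        nuclear_background_fraction=rcfg["nuclear_background_fraction"],
        seed=seed + 2,
    )

    if "simulate" in stages:
        write_genome_fasta(outdir / "reference.fasta", {contig: genome})
        write_genome_fasta(outdir / "samples.fasta", pop.samples)
        write_fastq(outdir / "reads.fastq", readset.reads)
        write_bed(
            outdir / "regions.bed",
            [(contig, s, e, lab) for lab, (s, e) in genome.regions.items()],
        )
        write_vcf(outdir / "truth.vcf", pop.variants, contig, len(genome.seq), pop.sample_ids)
        write_tsv(
            outdir / "truth_variants.tsv",
            ["pos", "ref", "alt", "type", "region", "carriers"],
            [
                (v.pos, v.ref, v.alts[0], v.vtype, v.region, ",".join(sorted(v.carriers())))
                for v in pop.variants
            ],
        )
        summary["simulate"] = {
            "genome_length": len(genome.seq),
            "n_samples": len(pop.sample_ids),
            "n_truth_variants": len(pop.variants),
            "n_reads": len(readset.reads),
        }

    if "enrich" in stages:
        ecfg = cfg["enrichment"]
        panel = [genome.seq] + [pop.samples[s].seq for s in pop.sample_ids[:2]]
        baits = enrichment.build_bait_set(
            panel, ecfg["n_baits"], ecfg["bait_len"], ecfg["min_identity"],
            min_match_fraction=ecfg["min_match_fraction"],
        )
        part = enrichment.classify_reads(readset.reads, baits)
        truth_cp = {r.id for r in readset.chloroplast()}
        called_cp = {r.id for r in part.chloroplast}
        tp = len(truth_cp & called_cp)
        precision = tp / len(called_cp) if called_cp else float("nan")
        recall = tp / len(truth_cp) if truth_cp else float("nan")
        one_ir_seq, one_ir_regions = enrichment.one_ir_reference(genome)
        profile = enrichment.compute_depth_profile(
            part.chloroplast, one_ir_seq, one_ir_regions
        )
        write_bedgraph(outdir / "depth.bedgraph", contig, profile.coverage.tolist())
        write_bed(
            outdir / "baits.bed",
            [(contig, b.start, b.end, f"bait_{i}") for i, b in enumerate(baits.baits)],
        )
        nuclear_depth = 1.0
        cp_depth = float(profile.coverage.mean())
        summary["enrich"] = {
            "n_baits": len(baits.baits),
            "precision": precision,
            "recall": recall,
            "ir_sc_depth_ratio": profile.ir_sc_ratio(),
            "copy_number_at_unit_nuclear_depth": enrichment.estimate_copy_number(
                cp_depth, nuclear_depth
            ),
        }

    ircfg = cfg["ir"]
    pseudorefs = ir_assembly.build_ir_pseudorefs(genome, ircfg["flank"])
    if "classify-ir" in stages:
        assigner = ir_assembly.IrAssigner(pseudorefs)
        tallies = {"IRa": 0, "IRb": 0, "ambiguous": 0}
        for read in readset.chloroplast():
            tallies[assigner.assign(read, ircfg["min_flank_overlap"])] += 1
        write_tsv(
            outdir / "ir_assignments.tsv",
            ["label", "count"],
            sorted(tallies.items()),
        )
        summary["classify_ir"] = tallies

    if "consensus" in stages:
        assigner = ir_assembly.IrAssigner(pseudorefs)
        ira_reads = [
            r for r in readset.chloroplast()
            if assigner.assign(r, ircfg["min_flank_overlap"]) == "IRa"
        ]
        if ira_reads:
            cons, support = ir_assembly.consensus_assembly(ira_reads[:60], pseudorefs[0])
            n_count = cons.count("N")
            match = cons == pseudorefs[0].seq
            summary["consensus"] = {
                "length": len(cons),
                "n_positions": n_count,
                "matches_pseudoref": bool(match),
                "mean_support": float(support.mean()),
            }
        else:
            summary["consensus"] = {"length": 0, "note": "no IRa-assigned reads"}

    if "detect-isomers" in stages:
        icfg = cfg["isomer"]
        refs = isomer.build_isomer_refs(genome, ircfg["flank"])
        ira_s, ira_e = genome.regions["IRa"]
        span = (ira_e - ira_s) + 2 * icfg["min_flank"]
        read_len = span + 2000
        lo = ira_e + icfg["min_flank"] - read_len
        hi = ira_s - icfg["min_flank"]
        n_target = icfg["target_qualifying"]
        depth = n_target * read_len / len(genome.seq)
        junction_reads = simulate_reads(
            genome,
            depth=depth,
            isomer_ratio=rcfg["isomer_ratio"],
            read_len_mean=read_len,
            read_len_sd=200,
            error_rate=rcfg["error_rate"],
            seed=seed + 3,
            start_interval=(lo, hi),
        )
        counts = isomer.count_isomer_support(
            junction_reads.reads, refs, min_flank=icfg["min_flank"]
        )
        summary["detect_isomers"] = {
            "n_ref": counts.n_ref,
            "n_inv": counts.n_inv,
            "n_disqualified": counts.n_disqualified,
            "ratio": counts.ratio,
            "p_value": counts.p_value,
            "ci": counts.ci,
        }
        (outdir / "isomer_counts.json").write_text(
            json.dumps(summary["detect_isomers"], indent=2)
        )

    called = None
    if "call-variants" in stages or "popgen" in stages or "repeats" in stages:
        alignments = {
            sid: align_sample(pop.samples[sid].seq, genome.seq)
            for sid in pop.sample_ids
        }
        called = call_variants(alignments=alignments, reference=genome.seq)
        counts_table = annotate_variants(called, genome)
        if "call-variants" in stages:
            write_vcf(outdir / "called.vcf", called, contig, len(genome.seq), pop.sample_ids)
            write_tsv(
                outdir / "variant_counts.tsv",
                ["region", "type", "count"],
                [(r, t, c) for (r, t), c in sorted(counts_table.items())],
            )
            curve = pan_unique_curve(
                called, len(genome.seq),
                n_values=list(range(1, len(pop.sample_ids) + 2)),
                n_perm=50, seed=seed + 4, sample_ids=pop.sample_ids,
            )
            write_tsv(outdir / "pan_curve.tsv", ["n", "max_length"], curve)
            by_type: dict[str, int] = {}
            for v in called:
                by_type[v.vtype] = by_type.get(v.vtype, 0) + 1
            summary["call_variants"] = {
                "n_variants": len(called),
                "by_type": by_type,
                "pan_curve_first": curve[0][1],
                "pan_curve_last": curve[-1][1],
            }

    if "popgen" in stages and called is not None:
        n = len(pop.sample_ids)
        if called:
            gmat = np.array(
                [[v.genotypes.get(s, 0) for s in pop.sample_ids] for v in called]
            )
            gmat = (gmat > 0).astype(int)
        else:
            gmat = np.zeros((0, n), dtype=int)
        positions = np.array([v.pos for v in called])
        region_stats = []
        for lab, (s, e) in genome.regions.items():
            sel = (positions >= s) & (positions < e)
            sub = gmat[sel]
            c = sub.sum(axis=1)
            D_tot = float((c * (n - c)).sum())
            L = e - s
            pi = D_tot / L / (n * (n - 1) / 2)
            td = popgen.tajimas_d(sub) if len(sub) else None
            region_stats.append(
                (lab, pi, td.D if td is not None and td.defined else float("nan"))
            )
        half = n // 2
        labels = ["pop1"] * half + ["pop2"] * (n - half)
        fst_sites, fst_mean = (
            popgen.fst_weir_cockerham(gmat, labels) if len(gmat) else (np.array([]), float("nan"))
        )
        sfs = popgen.allele_frequency_spectrum(gmat) if len(gmat) else np.array([])
        gc = popgen.gc_content(genome.seq, regions=genome.regions)
        write_tsv(
            outdir / "popgen_regions.tsv",
            ["region", "pi", "tajimas_d", "gc"],
            [(lab, pi, d, gc[lab]) for lab, pi, d in region_stats],
        )
        summary["popgen"] = {
            "per_region": {lab: {"pi": pi, "tajimas_d": d} for lab, pi, d in region_stats},
            "fst_mean": fst_mean,
            "sfs": sfs.tolist(),
            "gc": gc,
        }

    if "repeats" in stages and called is not None:
        kcfg = cfg["repeats"]
        lsc_s, lsc_e = genome.regions["LSC"]
        lsc_repeats = rp.find_direct_repeats(
            genome.seq[lsc_s:lsc_e], kcfg["k_min"], kcfg["k_max"]
        )
        lsc_variants = [v for v in pop.variants if v.region == "LSC"]
        shifted = []
        for v in lsc_variants:
            w = copy.copy(v)
            w.pos = v.pos - lsc_s
            shifted.append(w)
        overlap = rp.variant_repeat_overlap(shifted, lsc_repeats)
        mirror = rp.indel_mirroring(pop.variants, genome.regions, kcfg["bin_size"])
        write_bed(
            outdir / "repeats.bed",
            [
                (contig, lsc_s + p, lsc_s + p + r.k, f"rep{r.k}")
                for r in lsc_repeats for p in r.positions
            ],
        )
        summary["repeats"] = {
            "n_repeat_units": len(lsc_repeats),
            "indel_in_repeat_fraction": overlap["indel_fraction"],
            "snp_in_repeat_fraction": overlap["snp_fraction"],
            "mirror_correlation": mirror.correlation,
        }

    def _clean(obj: Any) -> Any:
        if isinstance(obj, float) and not np.isfinite(obj):
            return None
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return _clean(float(obj))
        return obj

    summary = _clean(summary)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
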