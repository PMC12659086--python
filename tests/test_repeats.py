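import copy
import math

import numpy as np
import pytest

from plastidflip.repeats import (
    MirrorTrack,
    RepeatOccurrence,
    find_direct_repeats,
    indel_mirroring,
    repeat_length_histogram,
    variant_repeat_overlap,
)
from plastidflip.sequtil import random_seq
from plastidflip.variants import VariantRecord


# ------------------------------------------------------------------ oracle
def oracle_repeats(sequence, k_min, k_max):
    """Exhaustive enumeration: same masking semantics, naive data flow."""
    n = len(sequence)
    masked = [False] * n
    out = []
    for k in range(min(k_max, n), k_min - 1, -1):
        units = {}
        for i in range(n - k + 1):
            if any(masked[i : i + k]):
                continue
            units.setdefault(sequence[i : i + k], []).append(i)
        level = []
        for unit, poss in units.items():
            sel = []
            last = -k
            for p in poss:
                if p >= last + k:
                    sel.append(p)
                    last = p
            if len(sel) >= 2:
                level.append((k, unit, tuple(sel)))
        for k_, _u, sel in level:
            for p in sel:
                for q in range(p, p + k_):
                    masked[q] = True
        out.extend(level)
    return sorted(out)


def as_tuples(repeats):
    return sorted((r.k, r.unit, tuple(r.positions)) for r in repeats)


def test_example_acgtacgt():
    found = find_direct_repeats("ACGTACGT", 3, 8)
    assert as_tuples(found) == [(4, "ACGT", (0, 4))]


def test_example_aaaaaa():
    found = find_direct_repeats("AAAAAA", 3, 8)
    assert as_tuples(found) == [(3, "AAA", (0, 3))]


def test_matches_oracle_on_random_strings():
    rng = np.random.default_rng(1)
    for trial in range(30):
        n = int(rng.integers(20, 200))
        gc = float(rng.uniform(0.2, 0.8))
        s = random_seq(n, gc, rng)
        assert as_tuples(find_direct_repeats(s, 3, 10)) == oracle_repeats(s, 3, 10)


def test_matches_oracle_low_complexity():
    rng = np.random.default_rng(2)
    for trial in range(10):
        n = int(rng.integers(20, 120))
        s = "".join(rng.choice(list("AT"), size=n))
        assert as_tuples(find_direct_repeats(s, 3, 10)) == oracle_repeats(s, 3, 10)


def test_invariants_on_output():
    rng = np.random.default_rng(3)
    s = random_seq(2000, 0.4, rng)
    found = find_direct_repeats(s, 3, 30)
    for r in found:
        assert r.count == len(r.positions) >= 2
        for a, b in zip(r.positions, r.positions[1:]):
            assert b - a >= r.k  # non-overlapping
        for p in r.positions:
            assert s[p : p + r.k] == r.unit


def test_nested_removal_idempotence():
    rng = np.random.default_rng(4)
    s = random_seq(1500, 0.4, rng)
    found = find_direct_repeats(s, 3, 30)
    masked = list(s)
    for r in found:
        for p in r.positions:
            for q in range(p, p + r.k):
                masked[q] = "N"
    again = find_direct_repeats("".join(masked), 3, 30)
    retained_units = {r.unit for r in found}
    assert not any(r.unit in retained_units and "N" not in r.unit for r in again)


def test_5_to_8_bp_class_dominates_on_synthetic_lsc():
    """GC-matched random LSC: the 5-8 bp unit class carries most retained
    repeat occurrences."""
    rng = np.random.default_rng(5)
    s = random_seq(10_000, 0.36, rng)
    hist = repeat_length_histogram(find_direct_repeats(s, 3, 30))
    in_class = sum(c for k, c in hist.items() if 5 <= k <= 8)
    assert in_class > 0.5 * sum(hist.values())


def test_k_min_validation():
    with pytest.raises(ValueError):
        find_direct_repeats("ACGT", 1, 8)


# -------------------------------------------------------- variant overlap
def _mk_variant(pos, ref, alt):
    return VariantRecord(pos, ref, (alt,), genotypes={"s": 1})


def test_overlap_all_indels_inside():
    reps = [RepeatOccurrence(6, "ACGTAC", [10, 40], 2)]
    vs = [_mk_variant(11, "CG", "C"), _mk_variant(41, "C", "CT")]
    out = variant_repeat_overlap(vs, reps)
    assert out["indel_fraction"] == 1.0


def test_overlap_disjoint_zero():
    reps = [RepeatOccurrence(6, "ACGTAC", [100], 2)]
    vs = [_mk_variant(10, "AG", "A"), _mk_variant(20, "A", "T")]
    out = variant_repeat_overlap(vs, reps)
    assert out["indel_fraction"] == 0.0 and out["snp_fraction"] == 0.0


def test_overlap_empty_flagged():
    out = variant_repeat_overlap([], [])
    assert math.isnan(out["indel_fraction"])


def test_overlap_monotone_in_k_select():
    rng = np.random.default_rng(6)
    s = random_seq(5000, 0.4, rng)
    reps = find_direct_repeats(s, 3, 30)
    vs = [
        _mk_variant(int(p), s[int(p)], s[int(p)] + "A")
        for p in rng.integers(0, 4990, size=200)
    ]
    prev = -1.0
    for hi in (5, 6, 7, 8, 10, 14):
        frac = variant_repeat_overlap(vs, reps, k_select=(5, hi))["indel_fraction"]
        assert frac >= prev
        prev = frac


# ------------------------------------------------------------- mirroring
def test_mirror_coordinate_identity():
    regions = {"IRa": (100, 200), "IRb": (300, 400)}
    # one IRa indel at offset 0, one IRb indel mapping to offset 0
    ira_v = _mk_variant(100, "AT", "A")
    irb_v = _mk_variant(300 + 100 - 0 - 2, "CG", "C")  # maps to offset 0
    track = indel_mirroring([ira_v, irb_v], regions, bin_size=10)
    assert track.ira_density[0] == 1
    assert track.irb_density[0] == 1


def test_mirror_perfect_correlation(mid_genome):
    """With mirroring certain and no independent IRb indels the two binned
    tracks are identical."""
    from plastidflip.population import mutate_population

    pop = mutate_population(
        mid_genome, 4, 0.0, {"IRa": 0.004, "IRb": 0.0}, ir_mirror_prob=1.0, seed=9
    )
    track = indel_mirroring(pop.variants, mid_genome.regions, bin_size=50)
    assert track.correlation == pytest.approx(1.0)
    np.testing.assert_array_equal(track.ira_density, track.irb_density)


def test_mirror_independent_near_zero():
    """ir_mirror_prob=0: correlation ~ 0 over seeds."""
    from plastidflip.genome import build_genome
    from plastidflip.population import mutate_population

    g = build_genome(8000, 6000, 4000, 6000, seed=30)
    corrs = []
    for seed in range(10):
        pop = mutate_population(
            g, 3, 0.0, {"IRa": 0.004, "IRb": 0.004}, ir_mirror_prob=0.0, seed=seed
        )
        track = indel_mirroring(pop.variants, g.regions, bin_size=200)
        if np.isfinite(track.correlation):
            corrs.append(track.correlation)
    assert len(corrs) >= 8
    assert abs(np.mean(corrs)) < 0.25


def test_mirror_zero_indels_flagged(mid_genome):
    track = indel_mirroring([], mid_genome.regions, bin_size=50)
    assert math.isnan(track.correlation)
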