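"""Population-genetics statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastidflip import popgen
from plastidflip.sequtil import random_seq


# ---------------------------------------------------------------- oracles
def oracle_pi(seqs):
    """Mean pairwise Hamming distance / L (gap-free alignments)."""
    n = len(seqs)
    L = len(seqs[0])
    total = 0
    for a, b in itertools.combinations(seqs, 2):
        total += sum(x != y for x, y in zip(a, b))
    return total / L / (n * (n - 1) / 2)


def oracle_tajima(genotypes):
    """First-principles Tajima's D for a 0/1 haploid matrix."""
    g = np.asarray(genotypes)
    n = g.shape[1]
    derived = g.sum(axis=1)
    seg = (derived > 0) & (derived < n)
    S = int(seg.sum())
    pairs = n * (n - 1) / 2
    pi = sum(
        sum(1 for i in range(n) for j in range(i + 1, n) if g[s, i] != g[s, j])
        for s in range(g.shape[0])
    ) / pairs
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    if S == 0:
        return float("nan")
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def oracle_wc_fst(p1, n1, p2, n2):
    """Haploid Weir-Cockerham theta from allele frequencies, by algebra."""
    n_tot = n1 + n2
    nc = (n_tot - (n1 ** 2 + n2 ** 2) / n_tot) / 1
    p_bar = (n1 * p1 + n2 * p2) / n_tot
    msp = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / 1
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n1 - 1 + n2 - 1)
    return (msp - msg) / (msp + (nc - 1) * msg)


def oracle_r2(h1, h2):
    pa = h1.mean()
    pb = h2.mean()
    pab = (h1 * h2).mean()
    d = pab - pa * pb
    return d ** 2 / (pa * (1 - pa) * pb * (1 - pb))


# -------------------------------------------------------------------- pi
def test_pi_identical_is_zero():
    r = popgen.nucleotide_diversity(["ACGTACGT", "ACGTACGT"])
    assert r.pi == 0.0 and r.D == 0


def test_pi_two_seqs_one_diff():
    a = "A" * 100
    b = "A" * 50 + "C" + "A" * 49
    r = popgen.nucleotide_diversity([a, b])
    assert r.pi == pytest.approx(0.01)
    assert (r.D, r.L, r.N) == (1, 100, 2)


def test_pi_three_seqs_brute_force_example():
    base = "A" * 100
    s2 = "C" + base[1:99] + "G"  # 2 diffs vs base
    seqs = [base, s2, base]
    r = popgen.nucleotide_diversity(seqs)
    assert r.pi == pytest.approx(4 / 300)


def test_pi_requires_two(rng):
    with pytest.raises(ValueError):
        popgen.nucleotide_diversity(["ACGT"])


@settings(max_examples=40, deadline=None)
@given(
    st.integers(2, 8),
    st.integers(10, 200),
    st.integers(0, 10 ** 6),
)
def test_pi_matches_oracle_random_instances(n, L, seed):
    rng = np.random.default_rng(seed)
    base = random_seq(L, 0.4, rng)
    seqs = []
    for _ in range(n):
        s = list(base)
        for _ in range(int(rng.integers(0, 6))):
            p = int(rng.integers(0, L))
            s[p] = "ACGT"[int(rng.integers(0, 4))]
        seqs.append("".join(s))
    r = popgen.nucleotide_diversity(seqs)
    assert r.pi == pytest.approx(oracle_pi(seqs))


def test_pi_gap_columns_excluded_pairwise():
    a = "ACGTACGTAC"
    b = "ACG-ACGTAC"  # gap column excluded for this pair
    r = popgen.nucleotide_diversity([a, b])
    assert r.D == 0 and r.L == 9 and r.pi == 0.0


# ------------------------------------------------------------- sliding pi
def test_sliding_identical_all_zero():
    seqs = ["ACGT" * 500] * 4
    stats = popgen.sliding_diversity(seqs, window=200, step=200)
    assert all(w.value == 0.0 for w in stats)
    assert stats[0].start == 0 and stats[-1].end == 2000


def test_sliding_divergent_block_localized(rng):
    base = random_seq(5000, 0.4, rng)
    divergent = base[:2000] + random_seq(1000, 0.4, rng) + base[3000:]
    stats = popgen.sliding_diversity([base, divergent], window=1000, step=500)
    hot = [w for w in stats if w.start >= 1500 and w.end <= 3500]
    cold = [w for w in stats if w.end <= 1500 or w.start >= 3500]
    assert max(w.value for w in cold) < min(0.1, max(w.value for w in hot))


def test_sliding_near_uniform_rate(rng):
    base = random_seq(20000, 0.4, rng)
    other = list(base)
    idx = rng.choice(20000, size=400, replace=False)
    for p in idx:
        other[p] = "ACGT"[(ord(base[p]) + 1) % 4]
    stats = popgen.sliding_diversity([base, "".join(other)], window=2000, step=2000)
    vals = np.array([w.value for w in stats])
    assert vals.std() / vals.mean() < 0.5  # near flat for a uniform rate


# --------------------------------------------------------------- tajima d
def test_tajima_d_zero_when_pi_equals_theta():
    # n=4: 8 singleton + 3 doubleton sites give pi = theta_w = 6 exactly
    rows = [[1, 0, 0, 0]] * 8 + [[1, 1, 0, 0]] * 3
    r = popgen.tajimas_d(np.array(rows))
    assert r.pi == pytest.approx(6.0)
    assert r.theta_w == pytest.approx(6.0)
    assert r.D == pytest.approx(0.0)


def test_tajima_singletons_negative():
    n = 10
    g = np.zeros((5, n), dtype=int)
    for s in range(5):
        g[s, s] = 1  # five singleton variants
    r = popgen.tajimas_d(g)
    assert r.D < 0


def test_tajima_matches_oracle_toy_matrices():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(4, 9))
        S = int(rng.integers(1, 12))
        g = (rng.random((S, n)) < rng.random()).astype(int)
        got = popgen.tajimas_d(g)
        want = oracle_tajima(g)
        if math.isnan(want):
            assert not got.defined
        else:
            assert got.D == pytest.approx(want)


def test_tajima_undefined_when_no_segregating():
    r = popgen.tajimas_d(np.zeros((3, 6), dtype=int))
    assert not r.defined


def test_tajima_relabeling_invariance():
    rng = np.random.default_rng(5)
    g = (rng.random((8, 6)) < 0.3).astype(int)
    perm = rng.permutation(6)
    assert popgen.tajimas_d(g).D == pytest.approx(popgen.tajimas_d(g[:, perm]).D)


def test_tajima_alignment_route():
    seqs = ["AAAA", "AAAT", "AAAA", "CAAA"]
    r = popgen.tajimas_d(seqs)
    g = np.array([[0, 0, 0, 1], [0, 1, 0, 0]]).T  # sites x samples transposed
    want = oracle_tajima(np.array([[0, 0, 0, 1], [0, 1, 0, 0]]).T.T)
    assert r.S == 2
    assert r.D == pytest.approx(oracle_tajima(np.array([[0, 0, 0, 1], [0, 1, 0, 0]])))


# -------------------------------------------------------------------- fst
def test_fst_hand_computed_value():
    g = np.zeros((1, 20), dtype=int)
    g[0, :8] = 1  # pop1: p=0.8 over n=10
    g[0, 10:12] = 1  # pop2: p=0.2 over n=10
    labels = ["p1"] * 10 + ["p2"] * 10
    per_site, mean = popgen.fst_weir_cockerham(g, labels)
    assert per_site[0] == pytest.approx(oracle_wc_fst(0.8, 10, 0.2, 10))
    assert mean == pytest.approx(per_site[0])


def test_fst_fixed_difference_is_one():
    g = np.zeros((1, 12), dtype=int)
    g[0, :6] = 1
    labels = ["a"] * 6 + ["b"] * 6
    per_site, mean = popgen.fst_weir_cockerham(g, labels)
    assert per_site[0] == pytest.approx(1.0)


def test_fst_identical_frequencies_near_zero():
    rng = np.random.default_rng(7)
    g = (rng.random((400, 40)) < 0.3).astype(int)  # same freq both pops
    labels = ["a"] * 20 + ["b"] * 20
    _, mean = popgen.fst_weir_cockerham(g, labels)
    assert abs(mean) < 0.05


def test_fst_label_swap_symmetry():
    rng = np.random.default_rng(8)
    g = (rng.random((50, 20)) < 0.4).astype(int)
    labels = np.array(["a"] * 10 + ["b"] * 10)
    f1, m1 = popgen.fst_weir_cockerham(g, labels)
    swapped = np.where(labels == "a", "b", "a")
    f2, m2 = popgen.fst_weir_cockerham(g, swapped)
    np.testing.assert_allclose(f1, f2)


def test_fst_monomorphic_excluded():
    g = np.zeros((2, 8), dtype=int)
    g[1, :2] = 1
    labels = ["a"] * 4 + ["b"] * 4
    per_site, mean = popgen.fst_weir_cockerham(g, labels)
    assert math.isnan(per_site[0]) and np.isfinite(per_site[1])
    assert mean == pytest.approx(per_site[1])


def test_fst_requires_two_pops():
    with pytest.raises(ValueError):
        popgen.fst_weir_cockerham(np.zeros((1, 4)), ["a"] * 4)


# --------------------------------------------------------------------- ld
def test_ld_duplicated_marker_r2_one():
    rng = np.random.default_rng(9)
    h = (rng.random(30) < 0.5).astype(int)
    g = np.vstack([h, h])
    pairs, curve = popgen.ld_r2(g, [100, 200])
    assert pairs[0][2] == pytest.approx(1.0)


def test_ld_independent_markers_null():
    rng = np.random.default_rng(10)
    n = 50
    g = (rng.random((80, n)) < 0.5).astype(int)
    pairs, _ = popgen.ld_r2(g, list(range(0, 8000, 100)))
    mean = np.mean([r for _, _, r in pairs])
    assert 0.3 / n < mean < 3.0 / n  # E[r2] ~ 1/N for unlinked markers


def test_ld_r2_in_unit_interval_and_oracle():
    rng = np.random.default_rng(11)
    g = (rng.random((12, 40)) < 0.4).astype(int)
    pairs, _ = popgen.ld_r2(g, list(range(12)))
    poly = [i for i in range(12) if 0 < g[i].mean() < 1]
    for pi_, pj, r2 in pairs:
        assert 0.0 <= r2 <= 1.0 + 1e-12
        assert r2 == pytest.approx(oracle_r2(g[poly[pi_ - 0] if False else pi_], g[pj]))


def test_ld_decay_curve_monotone_under_block_structure():
    """Markers in tight blocks have higher r2 at short range."""
    rng = np.random.default_rng(12)
    n = 60
    blocks = []
    positions = []
    for b in range(10):
        anchor = (rng.random(n) < 0.5).astype(int)
        for j in range(4):
            noisy = anchor.copy()
            flips = rng.random(n) < 0.05 * j
            noisy[flips] = 1 - noisy[flips]
            blocks.append(noisy)
            positions.append(b * 10_000 + j * 100)
    g = np.vstack(blocks)
    pairs, curve = popgen.ld_r2(g, positions, max_dist=50_000, bins=10)
    short = [r for a, b, r in pairs if abs(b - a) < 1000]
    long = [r for a, b, r in pairs if abs(b - a) > 5000]
    assert np.mean(short) > np.mean(long) + 0.3


# -------------------------------------------------------------------- sfs
def test_sfs_singleton():
    g = np.zeros((1, 28), dtype=int)
    g[0, 3] = 1
    sfs = popgen.allele_frequency_spectrum(g)
    assert sfs[0] == 1 and sfs.sum() == 1


def test_sfs_sums_to_segregating_sites():
    rng = np.random.default_rng(13)
    g = (rng.random((300, 28)) < rng.random((300, 1))).astype(int)
    derived = g.sum(axis=1)
    S = int(((derived > 0) & (derived < 28)).sum())
    sfs = popgen.allele_frequency_spectrum(g)
    assert sfs.sum() == S


def test_sfs_matches_generator_tallies():
    rng = np.random.default_rng(14)
    n = 20
    counts = rng.integers(1, n, size=500)
    g = np.zeros((500, n), dtype=int)
    for s, c in enumerate(counts):
        g[s, rng.choice(n, size=c, replace=False)] = 1
    sfs = popgen.allele_frequency_spectrum(g)
    want = np.bincount(counts, minlength=n)[1:n]
    np.testing.assert_array_equal(sfs, want)


def test_sfs_folded():
    g = np.zeros((2, 10), dtype=int)
    g[0, :1] = 1  # count 1
    g[1, :9] = 1  # count 9 -> folds to 1
    sfs = popgen.allele_frequency_spectrum(g, folded=True)
    assert sfs[0] == 2


# --------------------------------------------------------------------- gc
def test_gc_examples():
    assert popgen.gc_content("GGCC")["all"] == 1.0
    assert popgen.gc_content("ATAT")["all"] == 0.0


def test_gc_windows_flag_ambiguous():
    stats = popgen.gc_content("ACGT" + "N" * 4, window=4)
    assert stats[0].value == 0.5
    assert not stats[1].defined


def test_gc_recovers_generator_parameter():
    from plastidflip.genome import build_genome

    g = build_genome(20000, 6000, 5000, 6000, gc_overall=0.40, gc_ir=0.52, seed=15)
    gc = popgen.gc_content(g.seq, regions=g.regions)
    assert abs(gc["IRa"] - 0.52) < 0.02
    assert abs(gc["IRb"] - 0.52) < 0.02


def test_gc_empty_rejected():
    with pytest.raises(ValueError):
        popgen.gc_content("")


# ------------------------------------------------------- sliding tajima d
def test_sliding_tajima_window_grid(rng):
    base = random_seq(4000, 0.4, rng)
    seqs = [base]
    for i in range(5):
        s = list(base)
        for p in rng.integers(0, 4000, size=8):
            s[int(p)] = "ACGT"[int(rng.integers(0, 4))]
        seqs.append("".join(s))
    stats = popgen.sliding_tajimas_d(seqs, window=1000, step=500)
    assert stats[0].start == 0 and stats[0].end == 1000
    assert stats[1].start == 500
    assert any(w.defined for w in stats)
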