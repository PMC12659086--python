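"""Region-partitioned population statistics for haploid organelle data.

Nucleotide diversity follows pi = D / L / (N*(N-1)/2) with D the total
pairwise difference count over comparable columns and L the mean pairwise
comparable length (columns gapped in either member of a pair are excluded
from that pair).  Tajima's D uses the standard 1989 variance constants;
FST is the Weir-Cockerham variance-components estimator in haploid form;
LD r^2 comes directly from haplotype frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np


@dataclass
class DiversityResult:
    D: float  # total pairwise difference count
    L: float  # (mean pairwise) comparable alignment length
    N: int
    pi: float


@dataclass
class TajimaResult:
    pi: float  # mean pairwise differences (count per sequence pair)
    theta_w: float  # Watterson's estimate from S and a1
    S: int
    variance: float
    D: float  # NaN when undefined (S == 0)

    @property
    def defined(self) -> bool:
        return np.isfinite(self.D)


@dataclass
class WindowStat:
    start: int  # 0-based half-open internally
    end: int
    region: str
    name: str
    value: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


_GAP_CHARS = frozenset("-.Nn")


def _to_matrix(seqs: list[str]) -> np.ndarray:
    widths = {len(s) for s in seqs}
    if len(widths) != 1:
        raise ValueError("sequences must be aligned (equal lengths)")
    return np.array([np.frombuffer(s.upper().encode(), dtype=np.uint8) for s in seqs])


def nucleotide_diversity(
    seqs: list[str], interval: tuple[int, int] | None = None
) -> DiversityResult:
    """Per-site diversity over all unordered sequence pairs."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    mat = _to_matrix(seqs)
    if interval is not None:
        mat = mat[:, interval[0] : interval[1]]
    valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
    n_pairs = n * (n - 1) // 2
    D = 0
    L_sum = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            L_sum += int(both.sum())
            D += int(((mat[i] != mat[j]) & both).sum())
    L = L_sum / n_pairs if n_pairs else 0.0
    pi = D / L / n_pairs if L > 0 else (0.0 if D == 0 else float("nan"))
    return DiversityResult(float(D), float(L), n, float(pi))


def sliding_diversity(
    seqs: list[str],
    window: int = 1000,
    step: int | None = None,
    partition: dict[str, tuple[int, int]] | None = None,
) -> list[WindowStat]:
    """Windowed pi on the alignment frame, tagged by quadripartite region."""
    return _sliding(
        seqs, window, step, partition, "pi",
        lambda sub, iv: nucleotide_diversity(sub, iv).pi,
    )


def _region_at(partition: dict[str, tuple[int, int]] | None, pos: int) -> str:
    if partition is None:
        return ""
    for lab, (s, e) in partition.items():
        if s <= pos < e:
            return lab
    return ""


def _sliding(seqs, window, step, partition, name, fn) -> list[WindowStat]:
    aln_len = len(seqs[0])
    if window > aln_len:
        window = aln_len
    step = step or window
    out: list[WindowStat] = []
    start = 0
    while start < aln_len:
        end = min(start + window, aln_len)
        value = fn(seqs, (start, end))
        mid = (start + end) // 2
        out.append(WindowStat(start, end, _region_at(partition, mid), name, value))
        if end == aln_len:
            break
        start += step
    return out


def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) a1,a2,b1,b2,c1,c2,e1,e2 for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def _pairwise_diff_mean(mat: np.ndarray, valid: np.ndarray) -> float:
    n = mat.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(((mat[i] != mat[j]) & valid[i] & valid[j]).sum())
    return total / (n * (n - 1) / 2)


def tajimas_d(
    seqs_or_genotypes: list[str] | np.ndarray,
    interval: tuple[int, int] | None = None,
) -> TajimaResult:
    """Tajima's D from an alignment or a (sites x samples) 0/1 matrix.

    Excess rare variants drive D negative.  With S = 0 the statistic is
    undefined and reported as NaN (``defined`` is False), not zero.
    """
    if isinstance(seqs_or_genotypes, np.ndarray):
        g = np.asarray(seqs_or_genotypes)
        if interval is not None:
            g = g[interval[0] : interval[1]]
        n = g.shape[1]
        if n < 2:
            raise ValueError("need at least 2 samples")
        derived = g.sum(axis=1)
        seg = (derived > 0) & (derived < n)
        S = int(seg.sum())
        d = derived[seg].astype(float)
        pi = float((d * (n - d)).sum() / (n * (n - 1) / 2))
    else:
        mat = _to_matrix(seqs_or_genotypes)
        if interval is not None:
            mat = mat[:, interval[0] : interval[1]]
        n = mat.shape[0]
        if n < 2:
            raise ValueError("need at least 2 sequences")
        valid = np.isin(mat, np.frombuffer(b"ACGT", dtype=np.uint8))
        all_valid = valid.all(axis=0)
        S = 0
        for col in np.nonzero(all_valid)[0]:
            alleles = np.unique(mat[:, col])
            if len(alleles) == 2:  # biallelic segregating sites only
                S += 1
        pi = _pairwise_diff_mean(mat, valid)
    c = tajima_constants(n)
    theta_w = S / c["a1"]
    if S == 0:
        return TajimaResult(pi, theta_w, S, 0.0, float("nan"))
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:  # degenerate (e.g. n = 2): statistic undefined
        return TajimaResult(pi, theta_w, S, var, float("nan"))
    D = (pi - theta_w) / sqrt(var)
    return TajimaResult(pi, theta_w, S, var, D)


def sliding_tajimas_d(
    seqs: list[str],
    window: int = 1000,
    step: int = 500,
    partition: dict[str, tuple[int, int]] | None = None,
) -> list[WindowStat]:
    """1 kb / 0.5 kb step sliding Tajima's D reported at window midpoints."""
    return _sliding(
        seqs, window, step, partition, "tajimas_d",
        lambda sub, iv: tajimas_d(sub, iv).D,
    )


def fst_weir_cockerham(
    genotypes: np.ndarray, pop_labels: list[str] | np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-site Weir-Cockerham FST (haploid variance components) and mean.

    ``genotypes`` is (sites x samples) with 0/1 haploid alleles; exactly
    two populations are required.  Sites monomorphic across the pooled
    sample are undefined (NaN) and excluded from the mean.
    """
    g = np.asarray(genotypes, dtype=float)
    labels = np.asarray(pop_labels)
    pops = sorted(set(labels.tolist()))
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    masks = [labels == p for p in pops]
    n_i = np.array([m.sum() for m in masks], dtype=float)
    if (n_i < 2).any():
        raise ValueError("each population needs at least 2 samples")
    r = 2.0
    n_tot = n_i.sum()
    nc = (n_tot - (n_i**2).sum() / n_tot) / (r - 1)
    p_i = np.stack([g[:, m].mean(axis=1) for m in masks], axis=1)  # sites x 2
    p_bar = (p_i * n_i).sum(axis=1) / n_tot
    msp = (n_i * (p_i - p_bar[:, None]) ** 2).sum(axis=1) / (r - 1)
    msg = (n_i * p_i * (1 - p_i)).sum(axis=1) / (n_i - 1).sum()
    denom = msp + (nc - 1) * msg
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = (msp - msg) / denom
    poly = (p_bar > 0) & (p_bar < 1)
    theta = np.where(poly & (denom != 0), theta, np.nan)
    defined = theta[np.isfinite(theta)]
    mean = float(defined.mean()) if len(defined) else float("nan")
    return theta, mean


def ld_r2(
    genotypes: np.ndarray,
    positions: np.ndarray | list[int],
    max_dist: int | None = None,
    bins: int = 20,
) -> tuple[list[tuple[int, int, float]], list[tuple[float, float]]]:
    """Pairwise haplotype r^2 plus a distance-binned mean decay curve.

    Returns (pairs, curve): pairs as (pos_i, pos_j, r2); curve as
    (bin upper edge midpoint distance, mean r2).  Monomorphic markers are
    excluded.
    """
    g = np.asarray(genotypes, dtype=float)
    pos = np.asarray(positions)
    freq = g.mean(axis=1)
    keep = (freq > 0) & (freq < 1)
    g, pos, freq = g[keep], pos[keep], freq[keep]
    m = len(pos)
    pairs: list[tuple[int, int, float]] = []
    for i in range(m):
        for j in range(i + 1, m):
            dist = abs(int(pos[j]) - int(pos[i]))
            if max_dist is not None and dist > max_dist:
                continue
            pa, pb = freq[i], freq[j]
            pab = float((g[i] * g[j]).mean())
            d_ld = pab - pa * pb
            denom = pa * (1 - pa) * pb * (1 - pb)
            r2 = d_ld**2 / denom
            pairs.append((int(pos[i]), int(pos[j]), float(r2)))
    if not pairs:
        return pairs, []
    dists = np.array([abs(b - a) for a, b, _ in pairs], dtype=float)
    vals = np.array([v for _, _, v in pairs])
    top = max_dist if max_dist is not None else float(dists.max()) or 1.0
    edges = np.linspace(0, top, bins + 1)
    curve: list[tuple[float, float]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (dists > lo) & (dists <= hi) if lo > 0 else (dists >= lo) & (dists <= hi)
        if sel.any():
            curve.append((float((lo + hi) / 2), float(vals[sel].mean())))
    return pairs, curve


def allele_frequency_spectrum(
    genotypes: np.ndarray, folded: bool = False
) -> np.ndarray:
    """Site-frequency spectrum of derived allele counts.

    Unfolded: index c (1..N-1) holds the number of sites with derived
    count c.  Folded: index is the minor allele count (1..N//2).  Sites
    monomorphic in the sample are excluded, so the spectrum sums to the
    number of segregating sites.
    """
    g = np.asarray(genotypes)
    n = g.shape[1]
    derived = g.sum(axis=1)
    seg = derived[(derived > 0) & (derived < n)]
    if folded:
        counts = np.minimum(seg, n - seg)
        sfs = np.bincount(counts.astype(int), minlength=n // 2 + 1)
        return sfs[1 : n // 2 + 1]
    sfs = np.bincount(seg.astype(int), minlength=n)
    return sfs[1:n]


def gc_content(
    sequence: str,
    window: int | None = None,
    regions: dict[str, tuple[int, int]] | None = None,
) -> dict[str, float] | list[WindowStat]:
    """GC fraction per region (dict) or per window (list of WindowStat)."""
    from plastidflip.sequtil import gc_fraction

    if not sequence:
        raise ValueError("sequence must be non-empty")
    if regions is not None:
        return {lab: gc_fraction(sequence[s:e]) for lab, (s, e) in regions.items()}
    if window is None:
        return {"all": gc_fraction(sequence)}
    out: list[WindowStat] = []
    for start in range(0, len(sequence), window):
        end = min(start + window, len(sequence))
        out.append(WindowStat(start, end, "", "gc", gc_fraction(sequence[start:end])))
    return out
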