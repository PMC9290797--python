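"""Windowed diversity and differentiation statistics.

Implements per-window nucleotide diversity, the Hudson F_ST estimator
(ratio-of-averages form with finite-sample corrections), the population
branch statistic, and a joint site-frequency spectrum with outgroup
polarization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MISSING, HaplotypeMatrix, PopulationMap, WindowSpec

FST_CLAMP_HI = 1.0 - 1e-9


@dataclass
class AlleleFrequencyTable:
    """Per-site derived-allele frequency and called-haplotype count per population."""

    scaffold: str
    positions: np.ndarray
    populations: list[str]
    p: np.ndarray  # (n_pops, n_sites); NaN where n == 0
    n: np.ndarray  # (n_pops, n_sites) int

    def pop_index(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"population {population!r} not in table") from None

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class JointSFS:
    """Unfolded joint SFS over one or more populations.

    ``entries[d1, ..., dk]`` counts sites with derived-allele count ``di`` in
    population i; shape is ``(2*n1 + 1, ..., 2*nk + 1)``.
    """

    populations: list[str]
    haplotype_counts: list[int]
    entries: np.ndarray
    outgroup: str
    excluded_sites: int

    @property
    def total_sites(self) -> int:
        return int(self.entries.sum()) + self.excluded_sites

    def write(self, path) -> None:
        """Write coordinate->count TSV plus a flattened single-line variant.

        The flattened line lists entries in C (row-major) order over
        dimensions given in the header comment, i.e. the last population's
        derived count varies fastest.
        """
        with open(path, "w") as fh:
            dims = "x".join(str(d) for d in self.entries.shape)
            fh.write(
                f"# joint SFS; populations={','.join(self.populations)}; "
                f"dims={dims}; outgroup={self.outgroup}; "
                f"excluded_sites={self.excluded_sites}; "
                "flattened line is C-order (last dimension fastest)\n"
            )
            fh.write(
                "\t".join(f"d_{p}" for p in self.populations) + "\tcount\n"
            )
            for coord in np.ndindex(self.entries.shape):
                c = int(self.entries[coord])
                if c:
                    fh.write(
                        "\t".join(str(x) for x in coord) + f"\t{c}\n"
                    )
            flat = " ".join(str(int(x)) for x in self.entries.ravel(order="C"))
            fh.write(f"#flat\t{flat}\n")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(
    hm: HaplotypeMatrix,
    popmap: PopulationMap,
    populations: Sequence[str],
) -> AlleleFrequencyTable:
    """Derived-allele frequency and called count per site per population.

    Frequencies are computed over non-missing haplotypes only; sites where a
    population has zero called haplotypes carry ``p = NaN``, ``n = 0``.
    """
    if not populations:
        raise ValueError("populations must be non-empty")
    n_sites = hm.n_sites
    p = np.full((len(populations), n_sites), np.nan)
    n = np.zeros((len(populations), n_sites), dtype=np.int64)
    for k, pop in enumerate(populations):
        samples = [s for s in popmap.samples(pop) if s in hm.samples]
        if not samples:
            raise ValueError(f"population {pop!r} has no samples in the matrix")
        rows = hm.haplotype_rows(samples)
        block = hm.alleles[rows]
        called = block != MISSING
        cnt = called.sum(axis=0)
        ones = ((block == 1) & called).sum(axis=0)
        n[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(cnt > 0, ones / np.maximum(cnt, 1), np.nan)
    return AlleleFrequencyTable(
        scaffold=hm.scaffold,
        positions=hm.positions.copy(),
        populations=list(populations),
        p=p,
        n=n,
    )


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------


def _pi_site_terms(hm: HaplotypeMatrix, rows: Sequence[int]) -> np.ndarray:
    block = hm.alleles[list(rows)]
    called = block != MISSING
    n = called.sum(axis=0)
    c1 = ((block == 1) & called).sum(axis=0)
    c0 = n - c1
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(n >= 2, 2.0 * c0 * c1 / (n * np.maximum(n - 1, 1)), 0.0)
    return terms


def window_pi(
    hm: HaplotypeMatrix,
    window: WindowSpec,
    popmap: PopulationMap,
    population: str,
) -> float:
    """Per-site nucleotide diversity of one population in a coordinate window.

    pi = sum over SNPs of 2*c0*c1 / (n*(n-1)), divided by the window length
    in bp (invariant sites count as monomorphic).  Sites with fewer than two
    called haplotypes are skipped.
    """
    if window.length <= 0:
        raise ValueError("window length must be positive")
    samples = [s for s in popmap.samples(population) if s in hm.samples]
    if not samples:
        raise ValueError(f"population {population!r} has no samples in the matrix")
    rows = hm.haplotype_rows(samples)
    terms = _pi_site_terms(hm, rows)
    sl = hm.site_slice(window.start, window.end)
    return float(terms[sl].sum() / window.length)


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------


def hudson_components(
    freqs: AlleleFrequencyTable, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site Hudson numerator/denominator and a usable-site mask.

    N_s = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)
    D_s = pA(1-pB) + pB(1-pA)

    Sites with fewer than two called haplotypes in either population are
    masked out (N and D set to 0).
    """
    ia, ib = freqs.pop_index(pop_a), freqs.pop_index(pop_b)
    pa, pb = freqs.p[ia], freqs.p[ib]
    na, nb = freqs.n[ia], freqs.n[ib]
    usable = (na >= 2) & (nb >= 2) & ~np.isnan(pa) & ~np.isnan(pb)
    pa = np.where(usable, pa, 0.0)
    pb = np.where(usable, pb, 0.0)
    # grouped so every term is commutative in (A, B): exact symmetry
    with np.errstate(invalid="ignore", divide="ignore"):
        corr_a = pa * (1 - pa) / np.maximum(na - 1, 1)
        corr_b = pb * (1 - pb) / np.maximum(nb - 1, 1)
        num = (pa - pb) ** 2 - (corr_a + corr_b)
    den = (pa + pb) - 2 * (pa * pb)
    num = np.where(usable, num, 0.0)
    den = np.where(usable, den, 0.0)
    return num, den, usable


def _ratio_fst(num_sum: float, den_sum: float) -> tuple[float, float]:
    if den_sum == 0:
        return float("nan"), float("nan")
    raw = num_sum / den_sum
    return raw, min(max(raw, 0.0), FST_CLAMP_HI)


def window_fst_hudson(
    freqs: AlleleFrequencyTable,
    pop_a: str,
    pop_b: str,
    window: WindowSpec | None = None,
) -> tuple[float, float, int]:
    """Hudson F_ST (ratio of averages) for one window (or all sites).

    Returns ``(raw, clamped, n_usable_sites)``.  With no usable sites both
    estimates are NaN (undefined), never silently 0.  Symmetric in A and B.
    """
    num, den, usable = hudson_components(freqs, pop_a, pop_b)
    if window is not None:
        lo, hi = np.searchsorted(freqs.positions, (window.start, window.end))
        num, den, usable = num[lo:hi], den[lo:hi], usable[lo:hi]
    n_used = int(usable.sum())
    if n_used == 0:
        return float("nan"), float("nan"), 0
    raw, clamped = _ratio_fst(float(num.sum()), float(den.sum()))
    return raw, clamped, n_used


def fst_hudson_windows(
    freqs: AlleleFrequencyTable,
    pop_a: str,
    pop_b: str,
    windows: Sequence[WindowSpec],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-window Hudson F_ST over sorted non-overlapping windows.

    Returns arrays ``(raw, clamped, n_usable)`` aligned with *windows*;
    windows with no usable sites get NaN.
    """
    num, den, usable = hudson_components(freqs, pop_a, pop_b)
    raw = np.full(len(windows), np.nan)
    clamped = np.full(len(windows), np.nan)
    n_used = np.zeros(len(windows), dtype=np.int64)
    starts = np.array([w.start for w in windows])
    ends = np.array([w.end for w in windows])
    lo = np.searchsorted(freqs.positions, starts)
    hi = np.searchsorted(freqs.positions, ends)
    cn = np.concatenate([[0.0], np.cumsum(num)])
    cd = np.concatenate([[0.0], np.cumsum(den)])
    cu = np.concatenate([[0], np.cumsum(usable)])
    ns = cn[hi] - cn[lo]
    ds = cd[hi] - cd[lo]
    n_used = (cu[hi] - cu[lo]).astype(np.int64)
    ok = (n_used > 0) & (ds != 0)
    raw[ok] = ns[ok] / ds[ok]
    clamped[ok] = np.clip(raw[ok], 0.0, FST_CLAMP_HI)
    return raw, clamped, n_used


# ---------------------------------------------------------------------------
# Population branch statistic
# ---------------------------------------------------------------------------


def pbs(fst_ab, fst_ac, fst_bc):
    """Population branch statistic for focal population A.

    T_xy = -ln(1 - F_ST,xy); PBS_A = (T_AB + T_AC - T_BC) / 2.  Inputs must
    be clamped F_ST values in [0, 1); NaN inputs propagate to NaN output.
    May be negative.
    """
    arrs = [np.asarray(f, dtype=float) for f in (fst_ab, fst_ac, fst_bc)]
    for a in arrs:
        finite = a[~np.isnan(a)]
        if finite.size and (np.any(finite < 0) or np.any(finite >= 1)):
            raise ValueError("F_ST inputs must lie in [0, 1); clamp upstream")
    t = [-np.log1p(-a) for a in arrs]
    out = (t[0] + t[1] - t[2]) / 2.0
    if all(np.isscalar(f) or np.ndim(f) == 0 for f in (fst_ab, fst_ac, fst_bc)):
        return float(out)
    return out


# ---------------------------------------------------------------------------
# Window statistic table
# ---------------------------------------------------------------------------


def window_stat_table(
    hm: HaplotypeMatrix,
    popmap: PopulationMap,
    windows: Sequence[WindowSpec],
    pi_populations: Sequence[str] = (),
    fst_pairs: Sequence[tuple[str, str]] = (),
    pbs_triplets: Sequence[tuple[str, str, str, str]] = (),
) -> pd.DataFrame:
    """Assemble the per-window statistic table.

    *pbs_triplets* entries are ``(name, focal, ref1, ref2)``; the F_ST pairs
    they need are computed automatically.  Output columns: scaffold, start,
    end, chrom_class, n_snps, ``pi_<pop>``, ``fst_<A>_<B>`` (clamped) with
    ``fst_raw_<A>_<B>``, and ``pbs_<name>``.
    """
    need_pairs: list[tuple[str, str]] = [tuple(p) for p in fst_pairs]
    for _, focal, r1, r2 in pbs_triplets:
        for pair in ((focal, r1), (focal, r2), (r1, r2)):
            pair = tuple(pair)
            if pair not in need_pairs and (pair[1], pair[0]) not in need_pairs:
                need_pairs.append(pair)
    pops: list[str] = []
    for p in list(pi_populations) + [x for pair in need_pairs for x in pair]:
        if p not in pops:
            pops.append(p)

    df = pd.DataFrame(
        {
            "scaffold": [w.scaffold for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "chrom_class": [w.chrom_class for w in windows],
            "n_snps": [w.n_snps for w in windows],
        }
    )
    if not pops:
        return df
    freqs = allele_frequencies(hm, popmap, pops)

    for pop in pi_populations:
        rows = hm.haplotype_rows(
            [s for s in popmap.samples(pop) if s in hm.samples]
        )
        terms = _pi_site_terms(hm, rows)
        ct = np.concatenate([[0.0], np.cumsum(terms)])
        starts = np.array([w.start for w in windows])
        ends = np.array([w.end for w in windows])
        lo = np.searchsorted(hm.positions, starts)
        hi = np.searchsorted(hm.positions, ends)
        lengths = ends - starts
        df[f"pi_{pop}"] = (ct[hi] - ct[lo]) / lengths

    clamped_of: dict[frozenset, np.ndarray] = {}
    for a, b in need_pairs:
        raw, clamped, n_used = fst_hudson_windows(freqs, a, b, windows)
        clamped_of[frozenset((a, b))] = clamped
        df[f"fst_raw_{a}_{b}"] = raw
        df[f"fst_{a}_{b}"] = clamped
        df[f"fst_nsites_{a}_{b}"] = n_used

    for name, focal, r1, r2 in pbs_triplets:
        df[f"pbs_{name}"] = pbs(
            clamped_of[frozenset((focal, r1))],
            clamped_of[frozenset((focal, r2))],
            clamped_of[frozenset((r1, r2))],
        )
    return df


# ---------------------------------------------------------------------------
# Joint SFS
# ---------------------------------------------------------------------------


def joint_sfs(
    hm: HaplotypeMatrix,
    popmap: PopulationMap,
    populations: Sequence[str],
    outgroup: str,
) -> JointSFS:
    """Unfolded joint SFS polarized by a fixed outgroup allele.

    A site contributes iff the outgroup is fixed there (its allele defines
    the ancestral state) and every focal population is fully called;
    otherwise it is counted as excluded.
    """
    if outgroup in populations:
        raise ValueError("outgroup must be disjoint from focal populations")
    out_rows = hm.haplotype_rows(
        [s for s in popmap.samples(outgroup) if s in hm.samples]
    )
    if not out_rows:
        raise ValueError(f"outgroup {outgroup!r} has no samples in the matrix")
    out_block = hm.alleles[out_rows]
    out_called = out_block != MISSING
    out_n = out_called.sum(axis=0)
    if hm.n_sites and not out_n.any():
        raise ValueError("outgroup has zero called haplotypes at every site")
    out_ones = ((out_block == 1) & out_called).sum(axis=0)
    fixed = (out_n > 0) & ((out_ones == 0) | (out_ones == out_n))
    ancestral = np.where(out_ones == out_n, 1, 0)

    hap_counts = []
    derived = []
    full = fixed.copy()
    for pop in populations:
        samples = [s for s in popmap.samples(pop) if s in hm.samples]
        if not samples:
            raise ValueError(f"population {pop!r} has no samples in the matrix")
        rows = hm.haplotype_rows(samples)
        block = hm.alleles[rows]
        called = block != MISSING
        hap_counts.append(len(rows))
        full &= called.sum(axis=0) == len(rows)
        derived.append(((block != MISSING) & (block != ancestral[None, :])).sum(axis=0))

    shape = tuple(h + 1 for h in hap_counts)
    entries = np.zeros(shape, dtype=np.int64)
    idx = tuple(d[full] for d in derived)
    if idx[0].size:
        np.add.at(entries, idx, 1)
    excluded = int(hm.n_sites - full.sum())
    return JointSFS(
        populations=list(populations),
        haplotype_counts=hap_counts,
        entries=entries,
        outgroup=outgroup,
        excluded_sites=excluded,
    )
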