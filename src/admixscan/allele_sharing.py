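"""Four-population f4 tests with block-jackknife standard errors.

f4(A,B;C,D) is the mean over usable SNPs of (pA - pB)(pC - pD); under a
strict population tree of the form ([A,B],[C,D]) its expectation is zero,
and a significantly negative value indicates excess allele sharing between
B and C (positive: between B and D).  Standard errors come from a
delete-one block jackknife over consecutive-SNP blocks that never span
scaffolds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .popstats import AlleleFrequencyTable


@dataclass
class F4Result:
    a: str
    b: str
    c: str
    d: str
    f4: float
    se: float
    z: float  # NaN when undefined (SE == 0)
    z_defined: bool
    n_sites: int
    n_blocks: int


@dataclass
class JackknifeResult:
    estimate: float
    se: float
    z: float
    z_defined: bool
    n_blocks: int


def f4_statistic(
    freqs: AlleleFrequencyTable | Sequence[AlleleFrequencyTable],
    a: str,
    b: str,
    c: str,
    d: str,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Per-site f4 products and their mean.

    Sites missing (fewer than two called haplotypes) in any of the four
    populations are skipped.  Accepts one frequency table or a sequence of
    per-scaffold tables; returns ``(products, f4_mean, scaffold_index)``
    where ``scaffold_index`` labels each retained site with the index of its
    source table (all zeros for a single table).
    """
    tables = [freqs] if isinstance(freqs, AlleleFrequencyTable) else list(freqs)
    if not tables:
        raise ValueError("no frequency tables given")
    prods: list[np.ndarray] = []
    scafs: list[np.ndarray] = []
    for t_i, ft in enumerate(tables):
        ia, ib, ic, id_ = (ft.pop_index(x) for x in (a, b, c, d))
        usable = np.ones(ft.n_sites, dtype=bool)
        for k in (ia, ib, ic, id_):
            usable &= (ft.n[k] >= 2) & ~np.isnan(ft.p[k])
        prod = (ft.p[ia] - ft.p[ib]) * (ft.p[ic] - ft.p[id_])
        prods.append(prod[usable])
        scafs.append(np.full(int(usable.sum()), t_i, dtype=np.int64))
    products = np.concatenate(prods) if prods else np.empty(0)
    if products.size == 0:
        raise ValueError("zero usable sites for f4")
    return products, float(products.mean()), np.concatenate(scafs)


def _block_slices(
    n: int, block_size: int, scaffolds: np.ndarray | None
) -> list[tuple[int, int]]:
    """Contiguous block bounds; trailing runt blocks (< block_size/10) merge
    into the previous block of the same scaffold."""
    if scaffolds is None:
        runs = [(0, n)]
    else:
        runs = []
        start = 0
        for i in range(1, n + 1):
            if i == n or scaffolds[i] != scaffolds[start]:
                runs.append((start, i))
                start = i
    out: list[tuple[int, int]] = []
    min_tail = block_size / 10.0
    for lo, hi in runs:
        bounds = list(range(lo, hi, block_size)) + [hi]
        blocks = [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]
        if len(blocks) >= 2 and (blocks[-1][1] - blocks[-1][0]) < min_tail:
            last = blocks.pop()
            prev = blocks.pop()
            blocks.append((prev[0], last[1]))
        out.extend(blocks)
    return out


def block_jackknife(
    per_site_values,
    block_size_snps: int = 500,
    scaffolds: np.ndarray | None = None,
) -> JackknifeResult:
    """Delete-one-block jackknife SE and Z for the mean of per-site values.

    Consecutive sites are grouped into blocks of *block_size_snps*
    (equal-weight delete-one; a trailing block keeps its own slot when it
    holds at least block_size/10 sites, otherwise it merges into the
    previous block).  Blocks never span scaffold boundaries when
    *scaffolds* labels are given.  When all values are identical the SE is 0
    and Z is reported as undefined (NaN with ``z_defined=False``).
    """
    v = np.asarray(per_site_values, dtype=float)
    if v.ndim != 1:
        raise ValueError("per_site_values must be 1-D")
    blocks = _block_slices(v.size, block_size_snps, scaffolds)
    m = len(blocks)
    if m < 2:
        raise ValueError(f"need at least 2 jackknife blocks, got {m}")
    total = v.sum()
    n = v.size
    loo = np.array([(total - v[lo:hi].sum()) / (n - (hi - lo)) for lo, hi in blocks])
    se = float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))
    est = float(total / n)
    if se == 0.0:
        return JackknifeResult(est, 0.0, float("nan"), False, m)
    return JackknifeResult(est, se, est / se, True, m)


def f4_test(
    freqs: AlleleFrequencyTable | Sequence[AlleleFrequencyTable],
    a: str,
    b: str,
    c: str,
    d: str,
    block_size_snps: int = 500,
) -> F4Result:
    """f4 with block-jackknife SE and Z-score for quartet ([a, b],[c, d])."""
    products, f4, scaf = f4_statistic(freqs, a, b, c, d)
    jk = block_jackknife(products, block_size_snps=block_size_snps, scaffolds=scaf)
    return F4Result(
        a=a,
        b=b,
        c=c,
        d=d,
        f4=f4,
        se=jk.se,
        z=jk.z,
        z_defined=jk.z_defined,
        n_sites=int(products.size),
        n_blocks=jk.n_blocks,
    )
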