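"""Genotype, population-map and window I/O primitives.

All coordinates are 0-based half-open internally.  VCF input is 1-based and
is converted on read; every table written by this package uses 0-based
half-open ``start``/``end`` columns (BED-compatible).

The central container is :class:`HaplotypeMatrix`: phased 0/1 alleles for
every haplotype at ordered SNP positions of one scaffold.  Diploid samples
contribute exactly two consecutive rows (sample-major order).
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

VALID_SEXES = ("male", "female", "unknown")

_SEX_TOKENS = {
    "male": "male",
    "m": "male",
    "female": "female",
    "f": "female",
    "unknown": "unknown",
    "u": "unknown",
    "na": "unknown",
}


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed."""


class PopmapError(ValueError):
    """Raised on malformed population-map input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeMatrix:
    """Phased alleles for one scaffold.

    Parameters
    ----------
    scaffold
        Scaffold identifier.
    positions
        0-based SNP coordinates, strictly increasing.
    alleles
        ``int8`` matrix of shape ``(2 * n_samples, n_sites)`` with values in
        ``{0, 1, MISSING}``.  Rows ``2*i`` and ``2*i + 1`` are the two
        haplotypes of ``samples[i]``.
    samples
        Sample identifiers, one per diploid individual.
    unphased_het
        Optional boolean ``(n_samples, n_sites)`` mask flagging genotypes
        that were heterozygous but unphased in the source VCF.  Phase-free
        statistics may use such sites; tree building must not.
    """

    scaffold: str
    positions: np.ndarray
    alleles: np.ndarray
    samples: list[str]
    unphased_het: np.ndarray | None = None
    n_skipped_records: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape != (2 * len(self.samples), len(self.positions)):
            raise ValueError(
                f"alleles shape {self.alleles.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.positions)} sites"
            )
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"positions not strictly increasing on {self.scaffold}")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele values must be 0, 1 or missing (-1)")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{s}__{k}" for s in self.samples for k in (1, 2)]

    def sample_of_haplotype(self, row: int) -> str:
        return self.samples[row // 2]

    def haplotype_rows(self, samples: Iterable[str]) -> list[int]:
        """Row indices of the haplotypes belonging to *samples*."""
        index = {s: i for i, s in enumerate(self.samples)}
        rows: list[int] = []
        for s in samples:
            if s not in index:
                raise KeyError(f"sample {s!r} not present in matrix")
            rows.extend((2 * index[s], 2 * index[s] + 1))
        return rows

    @property
    def has_unphased_hets(self) -> bool:
        return self.unphased_het is not None and bool(self.unphased_het.any())

    def subset_sites(self, selector) -> "HaplotypeMatrix":
        """New matrix restricted to the selected site indices/mask."""
        return HaplotypeMatrix(
            scaffold=self.scaffold,
            positions=self.positions[selector],
            alleles=self.alleles[:, selector],
            samples=list(self.samples),
            unphased_het=None
            if self.unphased_het is None
            else self.unphased_het[:, selector],
        )

    def site_slice(self, start: int, end: int) -> slice:
        """Index slice of the SNPs falling in ``[start, end)`` (0-based bp)."""
        lo, hi = np.searchsorted(self.positions, (start, end))
        return slice(int(lo), int(hi))


@dataclass
class PopulationMap:
    """Mapping sample -> (population label, sex)."""

    entries: dict[str, tuple[str, str]]

    def __post_init__(self) -> None:
        for s, (pop, sex) in self.entries.items():
            if not pop:
                raise PopmapError(f"empty population label for sample {s!r}")
            if sex not in VALID_SEXES:
                raise PopmapError(f"unknown sex token {sex!r} for sample {s!r}")

    def __contains__(self, sample: str) -> bool:
        return sample in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def population_of(self, sample: str) -> str:
        return self.entries[sample][0]

    def sex_of(self, sample: str) -> str:
        return self.entries[sample][1]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for pop, _ in self.entries.values():
            seen.setdefault(pop, None)
        return list(seen)

    def samples(self, population: str | None = None) -> list[str]:
        if population is None:
            return list(self.entries)
        return [s for s, (p, _) in self.entries.items() if p == population]

    def males(self) -> list[str]:
        return [s for s, (_, x) in self.entries.items() if x == "male"]

    def females(self) -> list[str]:
        return [s for s, (_, x) in self.entries.items() if x == "female"]


@dataclass(frozen=True)
class WindowSpec:
    """A genomic analysis window.

    ``start``/``end`` are 0-based half-open base-pair bounds; ``snp_start``/
    ``snp_stop`` delimit (half-open) the indices of the scaffold's SNPs that
    belong to the window.
    """

    scaffold: str
    start: int
    end: int
    snp_start: int
    snp_stop: int
    mode: str  # "coordinate" | "snp_count"
    chrom_class: str = "unassigned"  # "autosome" | "X" | "unassigned"
    partial: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")
        if self.snp_stop < self.snp_start:
            raise ValueError("invalid SNP index range")
        if self.mode not in ("coordinate", "snp_count"):
            raise ValueError(f"unknown window mode {self.mode!r}")

    @property
    def n_snps(self) -> int:
        return self.snp_stop - self.snp_start

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------


def _parse_vcf(path, region=None):
    """Yield (chrom, pos0, genotypes) for biallelic SNP records.

    Returns a tuple ``(samples, iterator, counter)`` via generator protocol;
    implemented as an internal helper for :func:`read_vcf`.
    """
    from cyvcf2 import VCF

    try:
        reader = VCF(str(path))
    except Exception as exc:  # htslib raises plain Exceptions
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    return reader


def read_vcf(
    path,
    region: str | None = None,
    random_phase_seed: int | None = None,
) -> HaplotypeMatrix:
    """Read a (possibly gzip-compressed) VCF into a :class:`HaplotypeMatrix`.

    Only biallelic SNP records are used; multiallelic or non-SNP records are
    skipped and counted (``n_skipped_records``).  A *region* (scaffold name)
    with no records yields an empty matrix.  If *region* is ``None`` the file
    must contain records for at most one scaffold (use :func:`read_vcf_multi`
    otherwise).

    Unphased heterozygous genotypes are kept but flagged in
    ``unphased_het``; passing *random_phase_seed* instead assigns each such
    genotype a random phase under that seed and clears the flags.
    """
    reader = _parse_vcf(path)
    samples = list(reader.samples)
    n = len(samples)
    positions: list[int] = []
    columns: list[np.ndarray] = []
    unphased_cols: list[np.ndarray] = []
    skipped = 0
    chrom_seen: str | None = None
    record_no = 0
    try:
        for var in reader:
            record_no += 1
            if region is not None and var.CHROM != region:
                continue
            if len(var.ALT) != 1 or not var.is_snp:
                skipped += 1
                continue
            if region is None:
                if chrom_seen is None:
                    chrom_seen = var.CHROM
                elif var.CHROM != chrom_seen:
                    raise VcfParseError(
                        f"{path}: multiple scaffolds present "
                        f"({chrom_seen!r}, {var.CHROM!r}); pass region= or "
                        "use read_vcf_multi()"
                    )
            col = np.full(2 * n, MISSING, dtype=np.int8)
            unph = np.zeros(n, dtype=bool)
            for i, g in enumerate(var.genotypes):
                a0, a1, phased = g[0], g[1], bool(g[-1])
                if a0 >= 0:
                    col[2 * i] = a0
                if a1 >= 0:
                    col[2 * i + 1] = a1
                if a0 >= 0 and a1 >= 0 and a0 != a1 and not phased:
                    unph[i] = True
            pos0 = var.POS - 1
            if positions and pos0 <= positions[-1]:
                raise VcfParseError(
                    f"{path}: positions not strictly increasing at record "
                    f"{record_no} ({var.CHROM}:{var.POS})"
                )
            positions.append(pos0)
            columns.append(col)
            unphased_cols.append(unph)
    except VcfParseError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"{path}: malformed VCF at or near record {record_no}: {exc}"
        ) from exc
    if skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNP records", path, skipped)

    scaffold = region if region is not None else (chrom_seen or "")
    if columns:
        alleles = np.stack(columns, axis=1)
        unphased = np.stack(unphased_cols, axis=1)
    else:
        alleles = np.zeros((2 * n, 0), dtype=np.int8)
        unphased = np.zeros((n, 0), dtype=bool)

    if random_phase_seed is not None and unphased.any():
        rng = np.random.default_rng(random_phase_seed)
        si, vi = np.nonzero(unphased)
        flip = rng.random(si.size) < 0.5
        for s, v, fl in zip(si, vi, flip):
            if fl:
                alleles[2 * s, v], alleles[2 * s + 1, v] = (
                    alleles[2 * s + 1, v],
                    alleles[2 * s, v],
                )
        unphased = np.zeros_like(unphased)

    return HaplotypeMatrix(
        scaffold=scaffold,
        positions=np.asarray(positions, dtype=np.int64),
        alleles=alleles,
        samples=samples,
        unphased_het=unphased,
        n_skipped_records=skipped,
    )


def read_vcf_multi(path, random_phase_seed=None) -> dict[str, HaplotypeMatrix]:
    """Read every scaffold of a VCF, returning ``{scaffold: HaplotypeMatrix}``."""
    reader = _parse_vcf(path)
    chroms: list[str] = []
    seen = set()
    try:
        for var in reader:
            if var.CHROM not in seen:
                seen.add(var.CHROM)
                chroms.append(var.CHROM)
    except Exception as exc:
        raise VcfParseError(f"{path}: malformed VCF: {exc}") from exc
    return {
        c: read_vcf(path, region=c, random_phase_seed=random_phase_seed)
        for c in chroms
    }


def write_vcf(
    matrices: Mapping[str, HaplotypeMatrix] | HaplotypeMatrix,
    path,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write one or more HaplotypeMatrix objects as a VCF v4.2 text file.

    Alleles are emitted as phased GT fields (REF=A, ALT=T placeholders);
    missing haplotype calls become ``.``.
    """
    if isinstance(matrices, HaplotypeMatrix):
        matrices = {matrices.scaffold: matrices}
    mats = list(matrices.values())
    if not mats:
        raise ValueError("no matrices to write")
    samples = mats[0].samples
    for m in mats:
        if m.samples != samples:
            raise ValueError("all matrices must share the same sample list")

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=admixscan\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for scaf, m in matrices.items():
            length = None
            if scaffold_lengths is not None:
                length = scaffold_lengths.get(scaf)
            if length is None:
                length = int(m.positions[-1] + 1) if m.n_sites else 1
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for scaf, m in matrices.items():
            A = m.alleles
            for j in range(m.n_sites):
                gts = []
                for i in range(len(samples)):
                    a0, a1 = A[2 * i, j], A[2 * i + 1, j]
                    gts.append(
                        f"{a0 if a0 >= 0 else '.'}|{a1 if a1 >= 0 else '.'}"
                    )
                fh.write(
                    f"{scaf}\t{m.positions[j] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                    + "\t".join(gts)
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_variants(
    hm: HaplotypeMatrix, max_missing_frac: float = 0.5, min_mac: int = 2
) -> HaplotypeMatrix:
    """Apply hard site filters: call-rate and minor-allele-count.

    A site is retained when the fraction of non-missing haplotype calls is
    ``>= max_missing_frac`` (vcftools ``--max-missing`` semantics) and the
    minor-allele count among non-missing calls is ``>= min_mac``.
    Idempotent; site order preserved.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    if min_mac < 0:
        raise ValueError("min_mac must be >= 0")
    if hm.n_sites == 0:
        return hm.subset_sites(slice(0, 0))
    called = hm.alleles != MISSING
    call_frac = called.mean(axis=0)
    ones = np.sum((hm.alleles == 1) & called, axis=0)
    n = called.sum(axis=0)
    mac = np.minimum(ones, n - ones)
    keep = (call_frac >= max_missing_frac) & (mac >= min_mac)
    return hm.subset_sites(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------


def read_popmap(path) -> PopulationMap:
    """Read a whitespace/tab-separated popmap: sample, population[, sex]."""
    entries: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise PopmapError(f"{path}:{lineno}: expected 2-3 columns")
            sample, pop = fields[0], fields[1]
            if sample in entries:
                raise PopmapError(f"{path}:{lineno}: duplicate sample {sample!r}")
            if len(fields) == 3:
                token = fields[2]
                sex = _SEX_TOKENS.get(token.lower())
                if sex is None:
                    raise PopmapError(
                        f"{path}:{lineno}: unknown sex token {token!r}"
                    )
            else:
                sex = "unknown"
            entries[sample] = (pop, sex)
    return PopulationMap(entries)


def write_popmap(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for s, (pop, sex) in popmap.entries.items():
            fh.write(f"{s}\t{pop}\t{sex}\n")


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def build_windows(
    hm: HaplotypeMatrix,
    mode: str,
    size: int,
    scaffold_length: int | None = None,
    chrom_class: str = "unassigned",
) -> list[WindowSpec]:
    """Build non-overlapping analysis windows over one scaffold.

    ``snp_count`` mode emits ``floor(n_snps / size)`` full windows of *size*
    SNPs each, dropping the trailing remainder.  ``coordinate`` mode tiles
    ``[0, scaffold_length)`` with *size*-bp windows, keeping a final partial
    window flagged ``partial=True``.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    windows: list[WindowSpec] = []
    if mode == "snp_count":
        n_full = hm.n_sites // size
        for w in range(n_full):
            lo, hi = w * size, (w + 1) * size
            windows.append(
                WindowSpec(
                    scaffold=hm.scaffold,
                    start=int(hm.positions[lo]),
                    end=int(hm.positions[hi - 1]) + 1,
                    snp_start=lo,
                    snp_stop=hi,
                    mode="snp_count",
                    chrom_class=chrom_class,
                )
            )
    elif mode == "coordinate":
        if scaffold_length is None:
            raise ValueError("coordinate mode requires scaffold_length")
        if hm.n_sites and scaffold_length < int(hm.positions[-1]) + 1:
            raise ValueError("scaffold_length smaller than last SNP position")
        start = 0
        while start < scaffold_length:
            end = min(start + size, scaffold_length)
            lo, hi = np.searchsorted(hm.positions, (start, end))
            windows.append(
                WindowSpec(
                    scaffold=hm.scaffold,
                    start=start,
                    end=int(end),
                    snp_start=int(lo),
                    snp_stop=int(hi),
                    mode="coordinate",
                    chrom_class=chrom_class,
                    partial=(end - start) < size,
                )
            )
            start += size
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    return windows


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

_LEAD_COLS = ["scaffold", "start", "end"]


def write_window_table(rows, path) -> None:
    """Write per-window rows as TSV with scaffold/start/end leading columns.

    *rows* may be a DataFrame or a list of dicts sharing one schema.  Floats
    are rendered with 10 significant digits so a round-trip re-parses equal
    within 1e-9.  An empty row list yields a header-only file (requires a
    DataFrame to know the schema, else the three lead columns only).
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows))
    if df.empty and not len(df.columns):
        df = pd.DataFrame(columns=_LEAD_COLS)
    missing = [c for c in _LEAD_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"rows lack required columns: {missing}")
    ordered = _LEAD_COLS + [c for c in df.columns if c not in _LEAD_COLS]
    df[ordered].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_window_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_scaffold_lengths(path) -> dict[str, int]:
    """Read a scaffold<TAB>length table."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("scaffold\t"):
                continue
            scaf, length = line.split("\t")[:2]
            out[scaf] = int(length)
    return out


def write_scaffold_lengths(lengths: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for scaf, length in lengths.items():
            fh.write(f"{scaf}\t{length}\n")


def read_depth_table(path) -> pd.DataFrame:
    """Read a raw depth TSV (scaffold, sample, mean_depth), with or without header."""
    df = pd.read_csv(path, sep="\t")
    expected = {"scaffold", "sample", "mean_depth"}
    if not expected.issubset(df.columns):
        df = pd.read_csv(
            path, sep="\t", header=None, names=["scaffold", "sample", "mean_depth"]
        )
    return df
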