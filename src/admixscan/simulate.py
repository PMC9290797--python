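"""Synthetic genotype / popmap / depth / truth generator.

The generative model is a hierarchical Balding-Nichols construction: an
ancestral allele frequency per SNP, two differentiated source lineages
("west", "east") drifted from it with ``f_split``, terminal populations
drifted from their lineage with ``f_pop``, and introduced populations whose
per-window source lineage is west with probability ``alpha`` (one draw per
window shared by all introduced populations in ``shared`` mode, independent
draws in ``independent`` mode), followed by post-colonization drift
``f_intro``.  X-linked scaffolds inflate every F as
``F_X = 1 - (1 - F)**x_exponent`` (default exponent 4/3, mimicking the
reduced effective size of the X).  A configurable minority of autosomal
windows carries a directional derived-frequency shift ``p + delta*(1 - p)``
in every introduced population.  Haplotypes are independent draws at the
population frequency; the outgroup is fixed ancestral except at a
configurable fraction of fixed-derived sites.

Everything is deterministic given the seed, and the emitted VCF round-trips
through :mod:`admixscan.core_io` exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core_io import (
    HaplotypeMatrix,
    PopulationMap,
    write_popmap,
    write_scaffold_lengths,
    write_vcf,
    write_window_table,
)

ROLES = ("outgroup", "west", "east", "introduced")
ADMIX_MODES = ("shared", "independent", "none")


@dataclass
class PopSpec:
    name: str
    role: str
    n_diploid: int

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.n_diploid < 0:
            raise ValueError("n_diploid must be >= 0")


def _default_populations() -> list[PopSpec]:
    return [
        PopSpec("OUT", "outgroup", 4),
        PopSpec("W1", "west", 6),
        PopSpec("W2", "west", 6),
        PopSpec("E1", "east", 6),
        PopSpec("E2", "east", 6),
        PopSpec("I1", "introduced", 6),
        PopSpec("I2", "introduced", 6),
        PopSpec("I3", "introduced", 6),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Scaffolds are named ``A01.. / X01.. / R01.. / S01..`` for autosome, X,
    repeat (depth-only) and small (depth-only) classes.  Autosome and X
    scaffolds carry ``windows_per_scaffold`` windows of ``snps_per_window``
    SNPs, each window spanning ``window_bp`` base pairs.
    """

    seed: int = 0
    n_autosome_scaffolds: int = 2
    n_x_scaffolds: int = 1
    n_repeat_scaffolds: int = 0
    n_small_scaffolds: int = 0
    small_scaffold_len: int = 80_000
    windows_per_scaffold: int = 40
    snps_per_window: int = 20
    window_bp: int = 5000
    populations: list[PopSpec] = field(default_factory=_default_populations)
    f_split: float = 0.2
    f_pop: float = 0.05
    f_intro: float = 0.1
    alpha: float = 0.5
    admix_mode: str = "shared"
    x_exponent: float = 4.0 / 3.0
    n_selected_windows: int = 0
    selection_delta: float = 0.0
    anc_freq_range: tuple[float, float] = (0.05, 0.95)
    outgroup_derived_p: float = 0.05
    n_males: int = 5
    n_females: int = 4

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        for f, label in (
            (self.f_split, "f_split"),
            (self.f_pop, "f_pop"),
            (self.f_intro, "f_intro"),
        ):
            if not 0 <= f < 1:
                raise ValueError(f"{label} must be in [0, 1)")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if not 0 <= self.selection_delta <= 1:
            raise ValueError("selection_delta must be in [0, 1]")
        if self.admix_mode not in ADMIX_MODES:
            raise ValueError(f"admix_mode must be one of {ADMIX_MODES}")
        if self.admix_mode == "none" and self.alpha not in (0.0, 1.0):
            raise ValueError("admix_mode='none' requires alpha of exactly 0 or 1")
        if self.snps_per_window > self.window_bp:
            raise ValueError("snps_per_window cannot exceed window_bp")
        if self.snps_per_window <= 0 or self.windows_per_scaffold <= 0:
            raise ValueError("window plan must be positive")
        lo, hi = self.anc_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("anc_freq_range must satisfy 0 < lo <= hi < 1")
        n_auto_windows = self.n_autosome_scaffolds * self.windows_per_scaffold
        if self.n_selected_windows > n_auto_windows:
            raise ValueError("more planted windows than autosomal windows")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        if not any(p.role == "west" and p.n_diploid > 0 for p in self.populations):
            raise ValueError("need at least one west population with samples")
        if not any(p.role == "east" and p.n_diploid > 0 for p in self.populations):
            raise ValueError("need at least one east population with samples")

    # -- derived layout -------------------------------------------------------

    def scaffold_plan(self) -> list[tuple[str, str, int]]:
        """Ordered (name, class, length) triples for every scaffold."""
        snp_len = self.windows_per_scaffold * self.window_bp
        plan = []
        for i in range(self.n_autosome_scaffolds):
            plan.append((f"A{i + 1:02d}", "autosome", snp_len))
        for i in range(self.n_x_scaffolds):
            plan.append((f"X{i + 1:02d}", "X", snp_len))
        for i in range(self.n_repeat_scaffolds):
            plan.append((f"R{i + 1:02d}", "repeat", snp_len))
        for i in range(self.n_small_scaffolds):
            plan.append((f"S{i + 1:02d}", "unassigned_small", self.small_scaffold_len))
        return plan

    def sample_names(self) -> list[str]:
        return [
            f"{p.name}_{i + 1}"
            for p in self.populations
            for i in range(p.n_diploid)
        ]

    def popmap(self) -> PopulationMap:
        """Population map with the first ``n_males``/``n_females`` samples
        (in overall order) carrying known sexes, the rest unknown."""
        entries: dict[str, tuple[str, str]] = {}
        sexes: list[str] = (
            ["male"] * self.n_males + ["female"] * self.n_females
        )
        k = 0
        for p in self.populations:
            for i in range(p.n_diploid):
                sex = sexes[k] if k < len(sexes) else "unknown"
                entries[f"{p.name}_{i + 1}"] = (p.name, sex)
                k += 1
        return PopulationMap(entries)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        if "populations" in data:
            data["populations"] = [
                p if isinstance(p, PopSpec) else PopSpec(**p)
                for p in data["populations"]
            ]
        if "anc_freq_range" in data:
            data["anc_freq_range"] = tuple(data["anc_freq_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["anc_freq_range"] = list(self.anc_freq_range)
        return d


@dataclass
class SimResult:
    """In-memory simulated dataset plus its ground truth."""

    config: SimulationConfig
    matrices: dict[str, HaplotypeMatrix]
    popmap: PopulationMap
    scaffold_lengths: dict[str, int]
    truth: pd.DataFrame  # one row per window: scaffold/start/end/ancestry/selected

    def write_all(self, out_dir) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": str(out / "sim.vcf"),
            "popmap": str(out / "popmap.tsv"),
            "scaffold_lengths": str(out / "scaffold_lengths.tsv"),
            "truth": str(out / "truth.tsv"),
            "config": str(out / "sim_config.yaml"),
        }
        write_vcf(self.matrices, paths["vcf"], self.scaffold_lengths)
        write_popmap(self.popmap, paths["popmap"])
        write_scaffold_lengths(self.scaffold_lengths, paths["scaffold_lengths"])
        write_window_table(self.truth, paths["truth"])
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------
# Drift
# ---------------------------------------------------------------------------


def balding_nichols(
    rng: np.random.Generator, p: np.ndarray, f: float
) -> np.ndarray:
    """Draw descendant frequencies: Beta with mean p, variance f*p*(1-p)."""
    if f <= 0:
        return np.array(p, dtype=float, copy=True)
    p = np.clip(np.asarray(p, dtype=float), 1e-9, 1 - 1e-9)
    scale = (1.0 - f) / f
    return rng.beta(p * scale, (1.0 - p) * scale)


def _x_inflate(f: float, exponent: float) -> float:
    return 1.0 - (1.0 - f) ** exponent


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------


def _snp_positions(cfg: SimulationConfig) -> np.ndarray:
    """0-based SNP positions for one scaffold: evenly spread inside windows."""
    nw, ns, bp = cfg.windows_per_scaffold, cfg.snps_per_window, cfg.window_bp
    offsets = ((np.arange(ns) + 0.5) * bp / ns).astype(np.int64)
    offsets = np.unique(offsets)[:ns]
    assert offsets.size == ns
    return (np.arange(nw)[:, None] * bp + offsets[None, :]).ravel()


def simulate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> SimResult:
    """Generate the full synthetic dataset for *config*.

    The optional *seed* overrides ``config.seed``.  Returns an in-memory
    :class:`SimResult`; use ``write_all`` for the file surface.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    plan = [(n, c, l) for n, c, l in cfg.scaffold_plan() if c in ("autosome", "X")]
    nw, ns = cfg.windows_per_scaffold, cfg.snps_per_window
    lo, hi = cfg.anc_freq_range

    # plant selected windows among autosomal windows, chosen globally
    auto_windows = [
        (name, w) for name, c, _ in plan if c == "autosome" for w in range(nw)
    ]
    selected: set[tuple[str, int]] = set()
    if cfg.n_selected_windows:
        picks = rng.choice(
            len(auto_windows), size=cfg.n_selected_windows, replace=False
        )
        selected = {auto_windows[i] for i in picks}

    intro_pops = [p for p in cfg.populations if p.role == "introduced"]
    matrices: dict[str, HaplotypeMatrix] = {}
    truth_rows: list[dict] = []
    samples = cfg.sample_names()

    for scaf, cls, length in plan:
        n_sites = nw * ns
        fs = _x_inflate(cfg.f_split, cfg.x_exponent) if cls == "X" else cfg.f_split
        fp = _x_inflate(cfg.f_pop, cfg.x_exponent) if cls == "X" else cfg.f_pop
        fi = _x_inflate(cfg.f_intro, cfg.x_exponent) if cls == "X" else cfg.f_intro

        p_anc = rng.uniform(lo, hi, size=n_sites)
        p_west = balding_nichols(rng, p_anc, fs)
        p_east = balding_nichols(rng, p_anc, fs)

        # window ancestry of the introduced source lineage
        if cfg.admix_mode == "independent":
            anc = {
                p.name: rng.random(nw) < cfg.alpha for p in intro_pops
            }
        else:  # shared / none: one draw per window
            shared_draw = rng.random(nw) < cfg.alpha
            anc = {p.name: shared_draw for p in intro_pops}

        sel_mask_w = np.array([(scaf, w) in selected for w in range(nw)])
        sel_sites = np.repeat(sel_mask_w, ns)

        blocks: list[np.ndarray] = []
        for pop in cfg.populations:
            if pop.role == "outgroup":
                derived = rng.random(n_sites) < cfg.outgroup_derived_p
                hap = np.tile(
                    derived.astype(np.int8), (2 * pop.n_diploid, 1)
                )
                blocks.append(hap)
                continue
            if pop.role == "west":
                p_pop = balding_nichols(rng, p_west, fp)
            elif pop.role == "east":
                p_pop = balding_nichols(rng, p_east, fp)
            else:  # introduced
                west_sites = np.repeat(anc[pop.name], ns)
                source = np.where(west_sites, p_west, p_east)
                p_pop = balding_nichols(rng, source, fi)
                if cfg.selection_delta > 0:
                    p_pop = np.where(
                        sel_sites,
                        p_pop + cfg.selection_delta * (1.0 - p_pop),
                        p_pop,
                    )
            hap = (
                rng.random((2 * pop.n_diploid, n_sites)) < p_pop[None, :]
            ).astype(np.int8)
            blocks.append(hap)

        alleles = (
            np.vstack(blocks)
            if blocks
            else np.zeros((0, n_sites), dtype=np.int8)
        )
        matrices[scaf] = HaplotypeMatrix(
            scaffold=scaf,
            positions=_snp_positions(cfg),
            alleles=alleles,
            samples=samples,
        )

        for w in range(nw):
            origins = {p.name: ("west" if anc[p.name][w] else "east") for p in intro_pops}
            vals = set(origins.values())
            row = {
                "scaffold": scaf,
                "start": w * cfg.window_bp,
                "end": (w + 1) * cfg.window_bp,
                "window_index": w,
                "chrom_class": cls,
                "ancestry": vals.pop() if len(vals) == 1 else "mixed",
                "selected": bool(sel_mask_w[w]),
            }
            for name, origin in origins.items():
                row[f"ancestry_{name}"] = origin
            truth_rows.append(row)

    lengths = {name: length for name, _, length in cfg.scaffold_plan()}
    return SimResult(
        config=cfg,
        matrices=matrices,
        popmap=cfg.popmap(),
        scaffold_lengths=lengths,
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Depth simulation
# ---------------------------------------------------------------------------

_DEPTH_FACTORS = {"autosome": 1.0, "X": None, "repeat": 1.8, "unassigned_small": 1.0}


def simulate_depth_table(
    config: SimulationConfig,
    seed: int | None = None,
    sigma: float = 0.05,
) -> pd.DataFrame:
    """Raw per-scaffold per-sample mean-depth table (long format).

    Autosomal scaffolds sit at the sample baseline, X scaffolds at half the
    baseline in males, repeat scaffolds at 1.8x in everyone; multiplicative
    Gaussian noise with relative standard deviation *sigma*, truncated at 0.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 7_919 if seed is None else seed)
    popmap = cfg.popmap()
    samples = cfg.sample_names()
    baselines = rng.uniform(25.0, 35.0, size=len(samples))
    rows = []
    for scaf, cls, _length in cfg.scaffold_plan():
        for s, base in zip(samples, baselines):
            factor = _DEPTH_FACTORS[cls]
            if factor is None:  # X
                factor = 0.5 if popmap.sex_of(s) == "male" else 1.0
            noise = rng.normal(0.0, sigma) if sigma > 0 else 0.0
            depth = max(0.0, base * factor * (1.0 + noise))
            rows.append({"scaffold": scaf, "sample": s, "mean_depth": depth})
    return pd.DataFrame(rows)
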