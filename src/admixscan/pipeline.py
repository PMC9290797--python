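"""End-to-end pipeline orchestration.

A single YAML config drives the stages
``simulate -> filter -> sexlink -> windows -> popstats -> topoweights ->
f4 -> scan``; any stage can be skipped via the ``stages`` list.  One global
seed is declared; each stage derives its own generator by stable hashing of
``(seed, stage name)``, so enabling or disabling one stage never shifts
another stage's draws.  A JSON run manifest records config, seed, per-stage
outputs, row counts and wall-clock times.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import allele_sharing, core_io, popstats, selection_scan, sexlink, topoweights
from .simulate import SimulationConfig, simulate_dataset, simulate_depth_table

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "filter",
    "sexlink",
    "windows",
    "popstats",
    "topoweights",
    "f4",
    "scan",
)


class ConfigError(ValueError):
    """Raised when the run configuration is incomplete or inconsistent."""


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed derived from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:8], "little")


def _pkg_version() -> str:
    try:
        return version("admixscan")
    except PackageNotFoundError:
        return "unknown"


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, Mapping):
        return dict(path_or_dict)
    with open(path_or_dict) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _require(cfg: Mapping, key: str, context: str) -> Any:
    if key not in cfg:
        raise ConfigError(f"missing required config key {key!r} ({context})")
    return cfg[key]


def validate_config(cfg: Mapping) -> list[str]:
    """Check stage requirements up front; returns the enabled stage list."""
    stages = list(cfg.get("stages", ALL_STAGES))
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    if "simulate" not in stages:
        inputs = _require(cfg, "inputs", "stage list omits 'simulate'")
        for key in ("vcf", "popmap"):
            _require(inputs, key, "inputs")
    if "topoweights" in stages:
        tw = _require(cfg, "topoweights", "topoweights stage enabled")
        groups = _require(tw, "groups", "topoweights stage enabled")
        for role in ("outgroup", "west", "east", "focal"):
            _require(groups, role, "topoweights.groups")
    if "f4" in stages:
        _require(_require(cfg, "f4", "f4 stage enabled"), "quartets", "f4")
    if "popstats" in stages:
        _require(cfg, "popstats", "popstats stage enabled")
    if "scan" in stages:
        sc = _require(cfg, "scan", "scan stage enabled")
        _require(sc, "comparisons", "scan")
    return stages


def default_config(seed: int = 0) -> dict:
    """A small self-contained config exercising every stage via simulation."""
    return {
        "seed": seed,
        "stages": list(ALL_STAGES),
        "simulate": {
            "n_autosome_scaffolds": 2,
            "n_x_scaffolds": 1,
            "windows_per_scaffold": 20,
            "snps_per_window": 25,
            "f_split": 0.25,
            "f_pop": 0.05,
            "f_intro": 0.1,
            "alpha": 0.5,
            "admix_mode": "shared",
            "n_selected_windows": 2,
            "selection_delta": 0.6,
        },
        "filter": {"max_missing": 0.5, "min_mac": 2},
        "windows": {"coordinate_size": 5000, "snp_size": 25},
        "popstats": {
            "pi_pops": ["W1", "E1", "I1"],
            "fst_pairs": [["I1", "W1"], ["I1", "E1"]],
            "pbs": [
                {"name": "I1_between", "focal": "I1", "ref1": "W1", "ref2": "E1"},
                {"name": "I2_between", "focal": "I2", "ref1": "W1", "ref2": "E1"},
                {"name": "I3_between", "focal": "I3", "ref1": "W1", "ref2": "E1"},
                {"name": "I1_within_intro", "focal": "I1", "ref1": "I2", "ref2": "I3"},
                {"name": "W1_within_native", "focal": "W1", "ref1": "E1", "ref2": "E2"},
            ],
        },
        "topoweights": {
            "groups": {
                "outgroup": "OUT",
                "west": "W1",
                "east": "E1",
                "focal": "I1",
            },
            "n_subtrees": 200,
        },
        "f4": {
            "quartets": [["OUT", "E1", "I1", "W1"], ["OUT", "W1", "I1", "E1"]],
            "block_size": 100,
        },
        "scan": {
            "quantile": 0.99,
            "reps": 2000,
            "comparisons": {
                "I1_between": "between_range",
                "I2_between": "between_range",
                "I3_between": "between_range",
                "I1_within_intro": "within_introduced",
                "W1_within_native": "within_native",
            },
        },
    }


def run_pipeline(config, out_dir, seed: int | None = None) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    cfg = load_config(config)
    stages = validate_config(cfg)
    if seed is None:
        seed = int(cfg.get("seed", 0))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "config": cfg,
        "seed": seed,
        "version": _pkg_version(),
        "stages": {},
    }

    matrices: dict[str, core_io.HaplotypeMatrix] = {}
    popmap: core_io.PopulationMap | None = None
    lengths: dict[str, int] = {}
    depth_df: pd.DataFrame | None = None
    scaffold_classes: dict[str, str] = {}
    coord_windows: list[core_io.WindowSpec] = []
    snp_windows: list[core_io.WindowSpec] = []
    stat_table: pd.DataFrame | None = None
    weights_table: pd.DataFrame | None = None

    def record(stage: str, t0: float, outputs: dict[str, Any]) -> None:
        manifest["stages"][stage] = {
            "wall_seconds": round(time.monotonic() - t0, 3),
            **outputs,
        }

    # ---- simulate / load ----------------------------------------------------
    t0 = time.monotonic()
    if "simulate" in stages:
        sim_cfg = SimulationConfig.from_dict(
            {**cfg.get("simulate", {}), "seed": stage_seed(seed, "simulate")}
        )
        sim = simulate_dataset(sim_cfg)
        paths = sim.write_all(out / "sim")
        depth_df = simulate_depth_table(sim_cfg)
        depth_path = out / "sim" / "depth.tsv"
        depth_df.to_csv(depth_path, sep="\t", index=False)
        paths["depth"] = str(depth_path)
        matrices = sim.matrices
        popmap = sim.popmap
        lengths = sim.scaffold_lengths
        record(
            "simulate",
            t0,
            {
                "outputs": paths,
                "n_scaffolds": len(matrices),
                "n_sites": int(sum(m.n_sites for m in matrices.values())),
            },
        )
    else:
        inputs = cfg["inputs"]
        matrices = core_io.read_vcf_multi(
            inputs["vcf"],
            random_phase_seed=stage_seed(seed, "phase")
            if inputs.get("force_random_phase")
            else None,
        )
        popmap = core_io.read_popmap(inputs["popmap"])
        if "scaffold_lengths" in inputs:
            lengths = core_io.read_scaffold_lengths(inputs["scaffold_lengths"])
        else:
            lengths = {
                s: int(m.positions[-1] + 1) if m.n_sites else 1
                for s, m in matrices.items()
            }
        if "depths" in inputs:
            depth_df = core_io.read_depth_table(inputs["depths"])

    # ---- filter -------------------------------------------------------------
    if "filter" in stages:
        t0 = time.monotonic()
        fcfg = cfg.get("filter", {})
        before = sum(m.n_sites for m in matrices.values())
        matrices = {
            s: core_io.filter_variants(
                m,
                max_missing_frac=fcfg.get("max_missing", 0.5),
                min_mac=fcfg.get("min_mac", 2),
            )
            for s, m in matrices.items()
        }
        after = sum(m.n_sites for m in matrices.values())
        record("filter", t0, {"sites_before": int(before), "sites_after": int(after)})

    # ---- sexlink ------------------------------------------------------------
    if "sexlink" in stages:
        t0 = time.monotonic()
        if depth_df is None:
            raise ConfigError("sexlink stage requires a depth table")
        profile = sexlink.normalize_depths(depth_df, lengths)
        assignment = sexlink.assign_scaffolds(profile, popmap)
        scaffold_classes = assignment.classes
        path = out / "scaffold_assignment.tsv"
        assignment.as_frame(lengths).to_csv(path, sep="\t", index=False)
        record(
            "sexlink",
            t0,
            {
                "outputs": {"assignment": str(path)},
                "n_scaffolds": len(scaffold_classes),
            },
        )

    def class_of(scaf: str) -> str:
        cls = scaffold_classes.get(scaf, "unassigned")
        return cls if cls in ("autosome", "X") else "unassigned"

    # ---- windows ------------------------------------------------------------
    if "windows" in stages:
        t0 = time.monotonic()
        wcfg = cfg.get("windows", {})
        coord_size = wcfg.get("coordinate_size", 5000)
        snp_size = wcfg.get("snp_size", 500)
        for scaf, m in matrices.items():
            coord_windows.extend(
                core_io.build_windows(
                    m,
                    "coordinate",
                    coord_size,
                    scaffold_length=lengths.get(
                        scaf, int(m.positions[-1] + 1) if m.n_sites else 1
                    ),
                    chrom_class=class_of(scaf),
                )
            )
            snp_windows.extend(
                core_io.build_windows(
                    m, "snp_count", snp_size, chrom_class=class_of(scaf)
                )
            )
        record(
            "windows",
            t0,
            {"n_coordinate": len(coord_windows), "n_snp": len(snp_windows)},
        )

    # ---- popstats -----------------------------------------------------------
    if "popstats" in stages:
        t0 = time.monotonic()
        pcfg = cfg["popstats"]
        pbs_defs = [
            (d["name"], d["focal"], d["ref1"], d["ref2"])
            for d in pcfg.get("pbs", [])
        ]
        frames = []
        for scaf, m in matrices.items():
            wins = [w for w in coord_windows if w.scaffold == scaf]
            if not wins:
                continue
            frames.append(
                popstats.window_stat_table(
                    m,
                    popmap,
                    wins,
                    pi_populations=pcfg.get("pi_pops", []),
                    fst_pairs=[tuple(p) for p in pcfg.get("fst_pairs", [])],
                    pbs_triplets=pbs_defs,
                )
            )
        stat_table = pd.concat(frames, ignore_index=True)
        path = out / "window_stats.tsv"
        core_io.write_window_table(stat_table, path)
        record(
            "popstats",
            t0,
            {"outputs": {"window_stats": str(path)}, "n_rows": len(stat_table)},
        )

    # ---- topoweights --------------------------------------------------------
    if "topoweights" in stages:
        t0 = time.monotonic()
        tcfg = cfg["topoweights"]
        g = tcfg["groups"]
        focal_list = g["focal"] if isinstance(g["focal"], list) else [g["focal"]]
        frames = []
        for focal in focal_list:
            for scaf, m in matrices.items():
                wins = [w for w in snp_windows if w.scaffold == scaf]
                if not wins:
                    continue
                groups = topoweights.GroupAssignment.from_popmap(
                    popmap, m, g["outgroup"], g["west"], g["east"], focal
                )
                df = topoweights.windows_topology_weights(
                    m,
                    wins,
                    groups,
                    n_subtrees=tcfg.get("n_subtrees", 600),
                    seed=stage_seed(seed, f"topoweights:{focal}:{scaf}"),
                )
                df.insert(0, "focal", focal)
                frames.append(df)
        weights_table = pd.concat(frames, ignore_index=True)
        path = out / "topology_weights.tsv"
        weights_table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        record(
            "topoweights",
            t0,
            {
                "outputs": {"weights": str(path)},
                "n_rows": len(weights_table),
            },
        )

    # ---- f4 -----------------------------------------------------------------
    if "f4" in stages:
        t0 = time.monotonic()
        fcfg = cfg["f4"]
        pops_needed: list[str] = []
        for q in fcfg["quartets"]:
            for p in q:
                if p not in pops_needed:
                    pops_needed.append(p)
        tables = [
            popstats.allele_frequencies(m, popmap, pops_needed)
            for m in matrices.values()
            if m.n_sites
        ]
        rows = []
        for q in fcfg["quartets"]:
            res = allele_sharing.f4_test(
                tables, *q, block_size_snps=fcfg.get("block_size", 500)
            )
            rows.append(asdict(res))
        f4_table = pd.DataFrame(rows)
        path = out / "f4_results.tsv"
        f4_table.to_csv(path, sep="\t", index=False, float_format="%.10g")
        record(
            "f4", t0, {"outputs": {"f4": str(path)}, "n_quartets": len(rows)}
        )

    # ---- scan ---------------------------------------------------------------
    if "scan" in stages:
        t0 = time.monotonic()
        scfg = cfg["scan"]
        if stat_table is None:
            raise ConfigError("scan stage requires popstats output")
        comparisons: dict[str, str] = scfg["comparisons"]
        quantile = scfg.get("quantile", 0.99)
        classes = stat_table["chrom_class"].values
        flags: dict[str, np.ndarray] = {}
        for comp in comparisons:
            col = f"pbs_{comp}"
            if col not in stat_table.columns:
                raise ConfigError(f"scan comparison {comp!r} has no column {col!r}")
            with_warnings = stat_table[col].values
            flags[comp] = selection_scan.call_outliers(
                with_warnings, classes, quantile=quantile
            )
        cat_df, counts = selection_scan.overlap_categories(flags, comparisons)
        outlier_table = stat_table[["scaffold", "start", "end", "chrom_class"]].copy()
        for comp in comparisons:
            outlier_table[f"pbs_{comp}"] = stat_table[f"pbs_{comp}"].values
            outlier_table[f"outlier_{comp}"] = flags[comp]
        outlier_table = pd.concat([outlier_table, cat_df], axis=1)
        path = out / "outliers.tsv"
        core_io.write_window_table(outlier_table, path)

        rand_report: dict[str, Any] = {"counts": counts}
        reps = scfg.get("reps", 100_000)
        for cls in ("autosome", "X"):
            cls_mask = classes == cls
            n_cls = int(cls_mask.sum())
            if n_cls == 0:
                continue
            cls_flags = {c: f[cls_mask] for c, f in flags.items()}
            _, cls_counts = selection_scan.overlap_categories(cls_flags, comparisons)
            observed = {
                s: cls_counts[s]
                for s in ("shared_two", "shared_three", "plus_native", "plus_introduced")
                if s in cls_counts
            }
            results = selection_scan.overlap_randomization(
                n_cls,
                {c: int(f.sum()) for c, f in cls_flags.items()},
                observed,
                comparisons,
                reps=reps,
                seed=stage_seed(seed, f"scan:{cls}"),
            )
            rand_report[cls] = {s: asdict(r) for s, r in results.items()}
        rpath = out / "randomization.json"
        with open(rpath, "w") as fh:
            json.dump(rand_report, fh, indent=2)
        record(
            "scan",
            t0,
            {
                "outputs": {"outliers": str(path), "randomization": str(rpath)},
                "counts": counts,
            },
        )

    manifest_path = out / "run_manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
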