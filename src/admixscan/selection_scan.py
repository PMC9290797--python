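"""Percentile outlier calling, overlap categories, and randomization nulls.

Windows whose PBS reaches the top 1% within their chromosome class
(autosome / X handled separately) are outliers; overlap of outlier sets
across comparisons is categorized and tested against a uniform
without-replacement randomization null.  An ancestry-composition chi-squared
test compares topology classes at outlier windows with the genomic
background.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

COMPARISON_GROUPS = ("between_range", "within_native", "within_introduced")
OVERLAP_STATS = ("shared_two", "shared_three", "plus_native", "plus_introduced")


@dataclass
class RandomizationResult:
    statistic: str
    observed: int
    reps: int
    null_mean: float
    null_max: int
    p_raw: float
    p_corrected: float
    seed: int | None


def call_outliers(
    values,
    classes,
    quantile: float = 0.99,
) -> np.ndarray:
    """Flag windows in the top (1 - quantile) of values within their class.

    Uses the nearest-rank rule: with n windows in a class the threshold is
    the k-th largest value, k = ceil((1 - quantile) * n); every window with a
    value >= threshold is flagged (ties at the threshold all included, with a
    warning when ties inflate the set past k).  NaN values are never
    outliers.  A class with fewer than 10 windows is skipped with a warning.
    """
    v = np.asarray(values, dtype=float)
    cls = np.asarray(classes)
    if v.shape != cls.shape:
        raise ValueError("values and classes must align")
    flags = np.zeros(v.shape, dtype=bool)
    for c in pd.unique(cls):
        mask = (cls == c) & ~np.isnan(v)
        n = int(mask.sum())
        if n < 10:
            warnings.warn(
                f"class {c!r} has {n} windows (<10); skipped", stacklevel=2
            )
            continue
        # epsilon guards against e.g. 0.01 * 1000 landing a hair above 10
        k = max(1, math.ceil((1.0 - quantile) * n - 1e-9))
        threshold = np.sort(v[mask])[n - k]
        hit = mask & (v >= threshold)
        if int(hit.sum()) > k:
            warnings.warn(
                f"class {c!r}: ties at the outlier threshold inflate the set "
                f"to {int(hit.sum())} (> {k})",
                stacklevel=2,
            )
        flags |= hit
    return flags


def overlap_categories(
    flags: Mapping[str, np.ndarray],
    comparison_groups: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Categorize per-window outlier overlap across comparisons.

    *flags* maps comparison name -> boolean per-window outlier vector;
    *comparison_groups* maps each comparison to one of ``between_range``,
    ``within_native``, ``within_introduced``.  Categories (not mutually
    exclusive, except ``unique``):

    - ``shared_two``: outlier in >= 2 between-range comparisons
    - ``shared_three``: outlier in all between-range comparisons
    - ``plus_native``: outlier in >= 1 between-range and >= 1 within-native
    - ``plus_introduced``: outlier in >= 1 between-range and >= 1
      within-introduced
    - ``unique``: outlier in exactly one between-range comparison
    """
    for name, group in comparison_groups.items():
        if group not in COMPARISON_GROUPS:
            raise ValueError(f"unknown comparison group {group!r} for {name!r}")
    between = [n for n, g in comparison_groups.items() if g == "between_range"]
    native = [n for n, g in comparison_groups.items() if g == "within_native"]
    intro = [n for n, g in comparison_groups.items() if g == "within_introduced"]
    if len(between) < 2:
        raise ValueError("need at least 2 between-range comparisons")
    missing = [n for n in comparison_groups if n not in flags]
    if missing:
        raise ValueError(f"flags missing for comparisons: {missing}")

    between_count = np.sum([np.asarray(flags[n], bool) for n in between], axis=0)
    native_any = (
        np.any([np.asarray(flags[n], bool) for n in native], axis=0)
        if native
        else np.zeros_like(between_count, dtype=bool)
    )
    intro_any = (
        np.any([np.asarray(flags[n], bool) for n in intro], axis=0)
        if intro
        else np.zeros_like(between_count, dtype=bool)
    )

    df = pd.DataFrame(
        {
            "shared_two": between_count >= 2,
            "shared_three": between_count == len(between),
            "plus_native": (between_count >= 1) & native_any,
            "plus_introduced": (between_count >= 1) & intro_any,
            "unique": between_count == 1,
        }
    )
    counts = {c: int(df[c].sum()) for c in df.columns}
    return df, counts


def _null_overlaps(
    rng: np.random.Generator,
    n_windows: int,
    outlier_counts: Mapping[str, int],
    comparison_groups: Mapping[str, str],
    reps: int,
    stats_wanted: Sequence[str],
) -> dict[str, np.ndarray]:
    between = [n for n, g in comparison_groups.items() if g == "between_range"]
    native = [n for n, g in comparison_groups.items() if g == "within_native"]
    intro = [n for n, g in comparison_groups.items() if g == "within_introduced"]
    out = {s: np.empty(reps, dtype=np.int64) for s in stats_wanted}
    chunk = max(1, int(2e7 // max(n_windows, 1)))
    done = 0
    while done < reps:
        c = min(chunk, reps - done)
        masks: dict[str, np.ndarray] = {}
        for name, k in outlier_counts.items():
            keys = rng.random((c, n_windows))
            top = np.argpartition(keys, k - 1, axis=1)[:, :k] if k > 0 else None
            m = np.zeros((c, n_windows), dtype=bool)
            if top is not None:
                np.put_along_axis(m, top, True, axis=1)
            masks[name] = m
        b_count = np.sum([masks[n].astype(np.int8) for n in between], axis=0)
        n_any = (
            np.any([masks[n] for n in native], axis=0)
            if native
            else np.zeros((c, n_windows), dtype=bool)
        )
        i_any = (
            np.any([masks[n] for n in intro], axis=0)
            if intro
            else np.zeros((c, n_windows), dtype=bool)
        )
        sl = slice(done, done + c)
        if "shared_two" in out:
            out["shared_two"][sl] = (b_count >= 2).sum(axis=1)
        if "shared_three" in out:
            out["shared_three"][sl] = (b_count == len(between)).sum(axis=1)
        if "plus_native" in out:
            out["plus_native"][sl] = ((b_count >= 1) & n_any).sum(axis=1)
        if "plus_introduced" in out:
            out["plus_introduced"][sl] = ((b_count >= 1) & i_any).sum(axis=1)
        done += c
    return out


def overlap_randomization(
    n_windows: int,
    outlier_counts: Mapping[str, int],
    observed: Mapping[str, int],
    comparison_groups: Mapping[str, str],
    reps: int = 100_000,
    seed: int | None = None,
) -> dict[str, RandomizationResult]:
    """Randomization null for outlier-overlap statistics within one class.

    Each replicate draws, for every comparison, a uniform
    without-replacement sample of windows matching the observed outlier
    count, then recomputes the overlap statistics named in *observed*.
    The empirical p is ``#(null >= observed) / reps``; the
    ``(count + 1) / (reps + 1)`` corrected value is reported alongside.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for name, k in outlier_counts.items():
        if k > n_windows:
            raise ValueError(f"outlier count for {name!r} exceeds window count")
        if name not in comparison_groups:
            raise ValueError(f"comparison {name!r} lacks a group label")
    between_ks = [
        k for n, k in outlier_counts.items()
        if comparison_groups[n] == "between_range"
    ]
    for stat, obs in observed.items():
        if stat not in OVERLAP_STATS:
            raise ValueError(f"unknown overlap statistic {stat!r}")
        if stat in ("shared_two", "shared_three") and between_ks:
            if obs > min(between_ks):
                raise ValueError(
                    f"observed {stat} ({obs}) exceeds the smallest "
                    "between-range outlier count"
                )
    rng = np.random.default_rng(seed)
    nulls = _null_overlaps(
        rng, n_windows, outlier_counts, comparison_groups, reps, list(observed)
    )
    results: dict[str, RandomizationResult] = {}
    for stat, obs in observed.items():
        null = nulls[stat]
        count = int((null >= obs).sum())
        results[stat] = RandomizationResult(
            statistic=stat,
            observed=int(obs),
            reps=reps,
            null_mean=float(null.mean()),
            null_max=int(null.max()),
            p_raw=count / reps,
            p_corrected=(count + 1) / (reps + 1),
            seed=seed,
        )
    return results


def ancestry_enrichment(
    outlier_counts,
    background_counts,
) -> tuple[float, int, float]:
    """Pearson chi-squared test of topology-class composition at outliers.

    *outlier_counts* are observed counts over the four topology categories
    (topo1, topo2, topo3, ambiguous); expected counts are background
    proportions times the outlier total.  Returns (statistic, df, p).
    """
    obs = np.asarray(outlier_counts, dtype=float)
    bg = np.asarray(background_counts, dtype=float)
    if obs.shape != bg.shape or obs.ndim != 1:
        raise ValueError("outlier and background counts must be 1-D and aligned")
    total = obs.sum()
    if total == 0:
        raise ValueError("zero outlier windows")
    if bg.sum() == 0 or (bg < 0).any():
        raise ValueError("invalid background counts")
    props = bg / bg.sum()
    if (props == 0).any():
        raise ValueError("background category with zero mass")
    expected = props * total
    if (expected < 1).any():
        warnings.warn("expected count below 1 in at least one category", stacklevel=2)
    statistic = float(np.sum((obs - expected) ** 2 / expected))
    df = obs.size - 1
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p
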