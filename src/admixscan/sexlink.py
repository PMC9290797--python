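"""Coverage-based scaffold classification (X / autosome / Y / repeat).

Male flies are hemizygous for the X, so X-linked scaffolds sit near half the
normalized depth of autosomes in males while staying near 1 in females.
Classification applies threshold rules on normalized per-sample depth, with
absolute vote counts generalized to ceil-of-fraction rules so the operation
works for any cohort size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import PopulationMap

CLASSES = ("X", "autosome", "Y", "repeat", "unassigned_small", "unassigned")


@dataclass
class DepthProfile:
    """Normalized mean depth per scaffold per sample.

    ``normalized`` is indexed by scaffold (rows) with one column per sample;
    each cell is the scaffold's mean depth divided by that sample's
    length-weighted genome-wide mean depth, so a sample's length-weighted
    mean of normalized values is 1.
    """

    normalized: pd.DataFrame
    sample_mean_depth: pd.Series
    lengths: pd.Series

    def __post_init__(self) -> None:
        if (self.normalized.values < 0).any():
            raise ValueError("normalized depths must be >= 0")
        w = self.lengths.loc[self.normalized.index].values.astype(float)
        w = w / w.sum()
        means = self.normalized.values.T @ w
        if not np.allclose(means, 1.0, atol=1e-6):
            raise ValueError("length-weighted mean of normalized depths != 1")


@dataclass
class AssignmentParams:
    """Cutoffs and required sample fractions for scaffold classification.

    Defaults reproduce the absolute counts of the original 5-male / 4-female /
    9-sample design: ceil(0.8*5)=4 males, ceil(0.75*4)=3 females,
    ceil(7/9*9)=7 samples.
    """

    x_cut: float = 0.85
    y_cut: float = 0.25
    repeat_cut: float = 1.5
    min_len: int = 100_000
    male_frac: float = 0.8
    female_frac: float = 0.75
    all_frac: float = 7.0 / 9.0


@dataclass
class ScaffoldAssignment:
    classes: dict[str, str]
    params: AssignmentParams
    votes: pd.DataFrame

    def as_frame(self, lengths: Mapping[str, int] | None = None) -> pd.DataFrame:
        df = self.votes.copy()
        df.insert(0, "scaffold", df.index)
        df.insert(1, "class", [self.classes[s] for s in df.index])
        if lengths is not None:
            df.insert(2, "length", [lengths[s] for s in df.index])
        return df.reset_index(drop=True)


def normalize_depths(
    raw_depth: pd.DataFrame, scaffold_lengths: Mapping[str, int]
) -> DepthProfile:
    """Normalize a long-format (scaffold, sample, mean_depth) table.

    Each cell is divided by the sample's length-weighted genome-wide mean
    depth (mean depth across all sequenced sites).
    """
    wide = raw_depth.pivot(index="scaffold", columns="sample", values="mean_depth")
    if wide.isna().any().any():
        missing = wide.isna().stack()
        pair = missing[missing].index[0]
        raise ValueError(f"missing depth for scaffold/sample pair {tuple(pair)}")
    if (wide.values < 0).any():
        raise ValueError("raw depths must be >= 0")
    lengths = pd.Series({s: scaffold_lengths[s] for s in wide.index}, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("scaffold lengths must be positive")
    w = lengths.values / lengths.values.sum()
    gw_mean = pd.Series(wide.values.T @ w, index=wide.columns)
    zero = gw_mean[gw_mean == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero genome-wide depth")
    return DepthProfile(
        normalized=wide / gw_mean,
        sample_mean_depth=gw_mean,
        lengths=lengths.astype(int),
    )


def _required(frac: float, n: int) -> int:
    # epsilon guards against e.g. (7/9)*9 landing a hair above 7.0
    return max(1, math.ceil(frac * n - 1e-9))


def assign_scaffolds(
    profile: DepthProfile,
    popmap: PopulationMap,
    params: AssignmentParams | None = None,
) -> ScaffoldAssignment:
    """Classify every scaffold from normalized depth.

    Precedence (first matching rule wins):

    1. ``unassigned_small`` — length below ``min_len``.
    2. ``repeat`` — normalized depth > ``repeat_cut`` in the required
       fraction of all samples (sex-independent; unknown-sex samples count
       only here).
    3. ``X`` — depth < ``x_cut`` in the required male fraction AND
       > ``x_cut`` in the required female fraction.
    4. ``Y`` — depth > ``y_cut`` in males AND < ``y_cut`` in females.
    5. ``autosome`` otherwise.
    """
    if params is None:
        params = AssignmentParams()
    samples = list(profile.normalized.columns)
    males = [s for s in popmap.males() if s in samples]
    females = [s for s in popmap.females() if s in samples]
    if not males or not females:
        raise ValueError("need at least one male and one female with known sex")

    req_m = _required(params.male_frac, len(males))
    req_f = _required(params.female_frac, len(females))
    req_all = _required(params.all_frac, len(samples))

    norm = profile.normalized
    M = norm[males].values
    F = norm[females].values
    ALL = norm[samples].values

    repeat_votes = (ALL > params.repeat_cut).sum(axis=1)
    x_m = (M < params.x_cut).sum(axis=1)
    x_f = (F > params.x_cut).sum(axis=1)
    y_m = (M > params.y_cut).sum(axis=1)
    y_f = (F < params.y_cut).sum(axis=1)

    classes: dict[str, str] = {}
    for i, scaf in enumerate(norm.index):
        if profile.lengths.loc[scaf] < params.min_len:
            cls = "unassigned_small"
        elif repeat_votes[i] >= req_all:
            cls = "repeat"
        elif x_m[i] >= req_m and x_f[i] >= req_f:
            cls = "X"
        elif y_m[i] >= req_m and y_f[i] >= req_f:
            cls = "Y"
        else:
            cls = "autosome"
        classes[scaf] = cls

    votes = pd.DataFrame(
        {
            "repeat_votes": repeat_votes,
            "x_male_votes": x_m,
            "x_female_votes": x_f,
            "y_male_votes": y_m,
            "y_female_votes": y_f,
        },
        index=norm.index,
    )
    for key, value in asdict(params).items():
        votes[f"param_{key}"] = value
    return ScaffoldAssignment(classes=classes, params=params, votes=votes)
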