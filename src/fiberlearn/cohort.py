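"""Cohort assembly: stratified grouped splitting, train-only normalization, masks.

Fibers dissected from the same muscle bundle are near-replicates; the split
therefore allocates whole bundles (groups) to train/dev/test so no bundle
leaks across sets. Stratification keys come from the labels, with continuous
tasks median-dichotomized for stratification only. Labels and priors are
z-scored with statistics fitted on the train set alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

SPLIT_NAMES = ("train", "dev", "test")
DEFAULT_FRACTIONS = (0.5, 0.25, 0.25)


@dataclass
class SplitAssignment:
    """sample_id -> set name, with the group map that produced it."""

    assignment: dict[str, str]
    group_assignment: dict[str, str]
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int | None = None

    def members(self, name: str) -> list[str]:
        return [s for s, v in self.assignment.items() if v == name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.assignment), "set": list(self.assignment.values())}
        )


def dichotomize_for_stratification(
    labels: pd.DataFrame, task_kinds: dict[str, str]
) -> pd.Series:
    """Per-sample stratification key from the labels.

    Continuous tasks are median-dichotomized to high/low (values equal to the
    median count as low, deterministically); binary tasks pass through;
    missing values form an "NA" stratum. These keys steer the split only and
    never become learning tasks.
    """
    keys = pd.DataFrame(index=labels.index)
    for task, kind in task_kinds.items():
        if task not in labels.columns:
            continue
        col = labels[task]
        if kind == "continuous":
            valid = col.dropna()
            if len(valid) >= 2:
                med = valid.median()
                keys[task] = np.where(col.isna(), "NA",
                                      np.where(col <= med, "low", "high"))
            else:
                keys[task] = "NA"
        else:
            keys[task] = np.where(col.isna(), "NA", col.astype(str))
    if keys.empty:
        return pd.Series("all", index=labels.index)
    return keys.astype(str).agg("|".join, axis=1)


def stratified_group_split(
    manifest: pd.DataFrame,
    task_kinds: dict[str, str],
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitAssignment:
    """Allocate whole groups to train/dev/test targeting the given fractions.

    Greedy deficit allocation: strata are processed largest-first, groups are
    shuffled by the seed, and each group goes to the set with the largest
    remaining deficit for that stratum (ties resolved train > dev > test).
    Groups never straddle sets. Strata with < 3 groups are allocated
    best-effort.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    if "group_id" not in manifest.columns:
        raise ValueError("manifest must carry a group_id column")
    groups = manifest["group_id"].astype(str)
    unique_groups = groups.unique()
    if len(unique_groups) < 4:
        raise ValueError("need at least 4 groups to split")

    keys = dichotomize_for_stratification(manifest, task_kinds)
    # one stratum per group: the most common key among its samples
    group_key: dict[str, str] = {}
    for g in unique_groups:
        sel = keys[groups == g]
        group_key[g] = sel.mode().iloc[0]

    strata: dict[str, list[str]] = {}
    for g, k in group_key.items():
        strata.setdefault(k, []).append(g)

    rng = np.random.default_rng(seed)
    group_assignment: dict[str, str] = {}
    for key in sorted(strata, key=lambda k: (-len(strata[k]), k)):
        members = sorted(strata[key])
        rng.shuffle(members)
        n = len(members)
        counts = [0, 0, 0]
        for g in members:
            deficits = [fractions[i] * n - counts[i] for i in range(3)]
            i = int(np.argmax(deficits))  # ties -> lowest index (train, dev, test)
            group_assignment[g] = SPLIT_NAMES[i]
            counts[i] += 1

    assignment = {
        str(row.sample_id): group_assignment[str(row.group_id)]
        for row in manifest.itertuples()
    }
    return SplitAssignment(assignment=assignment, group_assignment=group_assignment,
                           fractions=fractions, seed=seed)


@dataclass
class NormalizationStats:
    """Train-set mean/sd per normalized quantity (population sd, ddof=0)."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, mu in self.mean.items():
            if col in out.columns:
                out[col] = (out[col] - mu) / self.sd[col]
        return out


def fit_apply_normalization(
    table: pd.DataFrame,
    split: SplitAssignment,
    columns: Iterable[str],
    id_column: str = "sample_id",
) -> tuple[pd.DataFrame, NormalizationStats]:
    """Z-score ``columns`` using train-only statistics; missing stays missing.

    Columns whose train sd is zero (or with an empty train set) are left
    unnormalized and recorded in ``stats.skipped``.
    """
    import warnings

    train_ids = set(split.members("train"))
    in_train = table[id_column].astype(str).isin(train_ids)
    stats = NormalizationStats()
    for col in columns:
        vals = pd.to_numeric(table.loc[in_train, col], errors="coerce").dropna()
        if len(vals) == 0:
            stats.skipped.append(col)
            warnings.warn(f"no train values for {col!r}; left unnormalized")
            continue
        mu = float(vals.mean())
        sd = float(vals.std(ddof=0))
        if sd <= 0:
            stats.skipped.append(col)
            warnings.warn(f"zero train sd for {col!r}; left unnormalized")
            continue
        stats.mean[col] = mu
        stats.sd[col] = sd
    return stats.transform(table), stats


def build_masks(
    table: pd.DataFrame,
    task_names: list[str],
    prior_names: list[str] = (),
) -> np.ndarray:
    """Per-sample boolean presence mask over model outputs (tasks then priors).

    True where a target value exists: missing labels and unavailable priors
    are masked, so no loss or gradient is attributed to those outputs.
    """
    cols = list(task_names) + list(prior_names)
    mask = np.zeros((len(table), len(cols)), dtype=bool)
    for j, col in enumerate(cols):
        if col in table.columns:
            mask[:, j] = pd.to_numeric(table[col], errors="coerce").notna().to_numpy()
    return mask
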