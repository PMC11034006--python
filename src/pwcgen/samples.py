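"""Training/test sample assembly: age-matching, holdout splits, compounds.

Three operations mirror the study design: (i) within each dataset,
females and males are 1:1 age-matched (greedy nearest-age, caliper-
limited) so training samples are sex-balanced; (ii) each matched sample
is split 75/25 into train and held-out subsets, stratified by sex and
age quartile, with the train size taken as floor(fraction * n) — the
rounding that reproduces held-out counts 220/214/48/250 from matched
sample sizes 878/854/190/1000; (iii) compound training samples pool the
per-dataset train subsets at a target size while preserving dataset,
sex and age composition via largest-remainder apportionment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError

logger = logging.getLogger(__name__)


@dataclass
class SampleDefinition:
    """An ordered, duplicate-free list of subject ids with a role."""

    name: str
    role: str  # {"train", "test"}
    subject_ids: tuple[str, ...]
    source_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.subject_ids = tuple(self.subject_ids)
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ConfigurationError(f"sample {self.name}: duplicate subject ids")
        if self.role not in ("train", "test"):
            raise ConfigurationError(f"sample {self.name}: bad role {self.role!r}")

    def __len__(self) -> int:
        return len(self.subject_ids)


def largest_remainder(target_n: int, weights) -> np.ndarray:
    """Integer quotas proportional to ``weights`` summing exactly to ``target_n``.

    Each quota is floor(share) plus at most one unit, handed out in order
    of decreasing fractional remainder (ties broken by position). Every
    quota is within 1 of its unrounded share.
    """
    weights = np.asarray(weights, dtype=float)
    if target_n < 0:
        raise ConfigurationError("target_n must be >= 0")
    if weights.size == 0 or weights.sum() <= 0:
        raise ConfigurationError("weights must be non-empty with positive sum")
    shares = target_n * weights / weights.sum()
    quotas = np.floor(shares).astype(int)
    remainder = int(target_n - quotas.sum())
    if remainder > 0:
        frac = shares - quotas
        order = np.lexsort((np.arange(weights.size), -frac))
        quotas[order[:remainder]] += 1
    return quotas


def match_sexes_by_age(
    demo: pd.DataFrame, caliper: float, name: str = "matched", role: str = "train"
) -> SampleDefinition:
    """Greedy 1:1 nearest-age pairing of females and males.

    All admissible female-male pairs (age difference <= caliper) are
    ranked by age difference (ties by original row order) and accepted
    greedily without replacement; unmatched subjects are dropped. The
    result has equal sex counts.
    """
    females = demo[demo["sex"] == "F"].reset_index(drop=True)
    males = demo[demo["sex"] == "M"].reset_index(drop=True)
    if len(females) == 0 or len(males) == 0:
        raise DegenerateDataError("both sexes must be present for matching")

    fa = females["age"].to_numpy()
    ma = males["age"].to_numpy()
    diff = np.abs(fa[:, None] - ma[None, :])
    fi, mi = np.nonzero(diff <= caliper)
    if fi.size == 0:
        raise DegenerateDataError(
            f"no admissible female-male pairs within caliper {caliper}"
        )
    order = np.lexsort((mi, fi, diff[fi, mi]))
    used_f = np.zeros(len(females), dtype=bool)
    used_m = np.zeros(len(males), dtype=bool)
    ids: list[str] = []
    counts: dict[str, int] = {}
    for k in order:
        i, j = fi[k], mi[k]
        if used_f[i] or used_m[j]:
            continue
        used_f[i] = used_m[j] = True
        for row in (females.iloc[i], males.iloc[j]):
            ids.append(row["subject_id"])
            counts[row["dataset"]] = counts.get(row["dataset"], 0) + 1
    return SampleDefinition(name=name, role=role, subject_ids=tuple(ids),
                            source_counts=counts)


def _strata(group: pd.DataFrame) -> pd.Series:
    """Sex x age-quartile strata; degrades to sex-only when too sparse."""
    quart = pd.qcut(group["age"], 4, labels=False, duplicates="drop")
    strata = group["sex"].astype(str) + "/" + quart.astype(str)
    if strata.value_counts().min() < 2:
        msg = "stratum smaller than 2; degrading to sex-only stratification"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=3)
        strata = group["sex"].astype(str)
    return strata


def _stratified_take(
    group: pd.DataFrame, n_take: int, rng: np.random.Generator
) -> list[str]:
    """Seeded stratified subsample of ``n_take`` subject ids from a group."""
    if n_take >= len(group):
        return list(group["subject_id"])
    if n_take == 0:
        return []
    strata = _strata(group)
    keys = sorted(strata.unique())
    sizes = [int((strata == k).sum()) for k in keys]
    quotas = largest_remainder(n_take, sizes)
    taken: list[str] = []
    for key, quota in zip(keys, quotas):
        members = group.loc[strata == key, "subject_id"].to_numpy()
        picked = rng.permutation(len(members))[:quota]
        taken.extend(members[np.sort(picked)])
    return taken


def split_holdout(
    demo: pd.DataFrame,
    train_fraction: float,
    seed: int,
    name_prefix: str = "sample",
) -> tuple[SampleDefinition, SampleDefinition]:
    """Per-dataset stratified holdout split.

    The train set takes floor(train_fraction * n) subjects from each
    dataset, stratified by sex and age quartile; the rest form the test
    set. Deterministic under ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list[str] = []
    test_ids: list[str] = []
    train_counts: dict[str, int] = {}
    test_counts: dict[str, int] = {}
    for ds in sorted(demo["dataset"].unique()):
        group = demo[demo["dataset"] == ds].reset_index(drop=True)
        n_train = int(np.floor(train_fraction * len(group)))
        picked = set(_stratified_take(group, n_train, rng))
        for sid in group["subject_id"]:
            (train_ids if sid in picked else test_ids).append(sid)
        train_counts[ds] = n_train
        test_counts[ds] = len(group) - n_train
    train = SampleDefinition(
        f"{name_prefix}_train", "train", tuple(train_ids), train_counts
    )
    test = SampleDefinition(
        f"{name_prefix}_test", "test", tuple(test_ids), test_counts
    )
    return train, test


def build_compound(
    splits: dict[str, SampleDefinition],
    demo: pd.DataFrame,
    target_n: int,
    seed: int,
    name: str = "compound",
) -> SampleDefinition:
    """Pool per-dataset train samples into one compound training sample.

    Per-dataset quotas follow largest-remainder apportionment of
    ``target_n`` over the available train sizes (so quotas sum exactly to
    ``target_n``); within each quota the subsample is stratified by sex
    and age quartile. Deterministic under ``seed``.
    """
    names = sorted(splits)
    avail = np.array([len(splits[k]) for k in names])
    if target_n > avail.sum():
        raise ConfigurationError(
            f"target_n={target_n} exceeds available {avail.sum()} train subjects"
        )
    if target_n == 0:
        return SampleDefinition(name, "train", (), {})
    quotas = largest_remainder(target_n, avail)
    rng = np.random.default_rng(seed)
    demo_idx = demo.set_index("subject_id")
    ids: list[str] = []
    counts: dict[str, int] = {}
    for ds, quota in zip(names, quotas):
        members = list(splits[ds].subject_ids)
        group = demo_idx.loc[members].reset_index()
        ids.extend(_stratified_take(group, int(quota), rng))
        counts[ds] = int(quota)
    return SampleDefinition(name, "train", tuple(ids), counts)
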