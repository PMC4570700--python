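"""Reproducible train/test splits and cross-validation fold assignment.

One base seed governs a whole run.  Split ``i`` uses ``base_seed + i``;
fold assignment inside a split uses a documented hash of
(base seed, split index, method name, salt) so that every
(method, split, repeat) task gets an independent, scheduling-order-free
stream.  Identical inputs always give bit-identical plans.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np


class ResamplingError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    """One random train/test partition of the case ids."""

    split_index: int  # 1-based
    seed: int
    train_ids: np.ndarray
    test_ids: np.ndarray
    train_fraction: float


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: repeated k-fold or leave-one-out."""

    kind: str  # repeated_kfold | loo
    folds: int = 10
    repeats: int = 10

    def __post_init__(self) -> None:
        if self.kind not in ("repeated_kfold", "loo"):
            raise ResamplingError(f"unknown CV kind {self.kind!r}")
        if self.kind == "repeated_kfold" and self.folds < 2:
            raise ResamplingError("repeated_kfold needs at least 2 folds")


REPEATED_CV = CVScheme("repeated_kfold", folds=10, repeats=10)
LOO = CVScheme("loo")


def derive_seed(base_seed: int, split_index: int, method: str = "", salt: int = 0) -> int:
    """Stable, documented seed derivation for per-task RNG streams.

    CRC32 of the task identity string mixed with the base seed; result is
    kept below 2**31 so downstream RNGs accept it.
    """
    tag = f"{base_seed}:{split_index}:{method}:{salt}".encode()
    return (base_seed * 1_000_003 + zlib.crc32(tag)) % (2**31)


def make_splits(
    n_cases: int, n_splits: int, train_fraction: float = 0.75, base_seed: int = 1
) -> list[SplitPlan]:
    """Repeated random train/test splits over case ids 0..n_cases-1.

    |train| = round(train_fraction · n); split i is seeded with
    base_seed + i, so plans are reproducible independent of each other.
    """
    if n_splits < 1:
        raise ResamplingError("n_splits must be >= 1")
    if not 0 < train_fraction < 1:
        raise ResamplingError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n_cases))
    if n_train < 1 or n_train >= n_cases:
        raise ResamplingError(
            f"train_fraction {train_fraction} leaves an empty partition for n={n_cases}"
        )
    plans = []
    for i in range(1, n_splits + 1):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n_cases)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
        plans.append(
            SplitPlan(
                split_index=i,
                seed=seed,
                train_ids=train,
                test_ids=test,
                train_fraction=train_fraction,
            )
        )
    return plans


def make_cv_folds(train_ids, scheme: CVScheme, seed: int = 0) -> list[list[np.ndarray]]:
    """Fold assignment: a partition of train_ids per repeat.

    repeated_kfold: per repeat r (seeded seed + r) the ids are shuffled and
    dealt into ``folds`` blocks whose sizes differ by at most one.
    loo: n singleton blocks in case order, one repeat.
    """
    train_ids = np.asarray(train_ids)
    n = len(train_ids)
    if scheme.kind == "loo":
        return [[np.array([i]) for i in train_ids]]
    if scheme.folds > n:
        raise ResamplingError(f"{scheme.folds} folds but only {n} training cases")
    repeats = []
    for r in range(scheme.repeats):
        rng = np.random.default_rng((seed + r) % (2**31))
        perm = rng.permutation(train_ids)
        # block sizes differ by <= 1: the first n % folds blocks get the extra
        repeats.append([np.sort(block) for block in np.array_split(perm, scheme.folds)])
    return repeats


def iter_resamples(train_ids, folds_per_repeat):
    """Yield (held_out_ids, kept_ids) for every fold of every repeat."""
    train_ids = np.asarray(train_ids)
    for repeat in folds_per_repeat:
        for block in repeat:
            mask = np.isin(train_ids, block)
            yield train_ids[mask], train_ids[~mask]
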