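"""Curation of a binary DR dataset from 5-grade manifests.

The grading scheme is the clinical 0-4 scale (0 no DR, 1 mild, 2 moderate,
3 severe, 4 proliferative DR).  Curation binarizes by dropping grades 1-2
(ambiguous middle) and merging 3-4 into a single DR class, balances the two
pools by seeded uniform down-sampling of the larger one, and splits 1:9
test:train stratified by class.  All randomness is governed by an explicit
recorded seed.

Manifests are CSV with header ``image_id,grade``; the EyePACS
``trainLabels.csv`` dialect (``image,level``) is accepted on read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GradeRecord",
    "CuratedDataset",
    "binarize_grades",
    "balance_pools",
    "split_dataset",
    "curate",
    "read_manifest",
    "write_curated_manifest",
]

NO_DR = 0
DR = 1


@dataclass(frozen=True)
class GradeRecord:
    image_id: str
    grade: int

    def __post_init__(self):
        if self.grade not in (0, 1, 2, 3, 4):
            raise ValueError(f"grade must be 0-4, got {self.grade!r}")


@dataclass
class CuratedDataset:
    """Balanced, binarized, split manifest with per-step provenance counts."""

    train: list[tuple[str, int]]
    test: list[tuple[str, int]]
    seed: int
    provenance: dict = field(default_factory=dict)

    def split_of(self, image_id: str) -> str:
        """Split assignment by image_id; device-simulated variants of an
        image share the id and hence the assignment."""
        if any(i == image_id for i, _ in self.train):
            return "train"
        if any(i == image_id for i, _ in self.test):
            return "test"
        raise KeyError(image_id)


def binarize_grades(records: list[GradeRecord]
                    ) -> tuple[list[GradeRecord], list[GradeRecord]]:
    """Partition into (no_dr_pool, dr_pool): grade 0 is No DR, grades 3 and 4
    merge into DR, grades 1-2 are discarded."""
    no_dr = [r for r in records if r.grade == 0]
    dr = [r for r in records if r.grade in (3, 4)]
    return no_dr, dr


def balance_pools(no_dr_pool: list[GradeRecord], dr_pool: list[GradeRecord],
                  seed: int) -> list[tuple[str, int]]:
    """Down-sample the larger pool uniformly at random (seeded) to the size
    of the smaller, removing class imbalance.  Returns labelled records,
    No DR first, each pool in its original order."""
    if not no_dr_pool or not dr_pool:
        raise ValueError("both pools must be non-empty to balance")
    rng = np.random.default_rng(seed)
    n = min(len(no_dr_pool), len(dr_pool))

    def _take(pool: list[GradeRecord]) -> list[GradeRecord]:
        if len(pool) == n:
            return list(pool)
        idx = np.sort(rng.choice(len(pool), size=n, replace=False))
        return [pool[i] for i in idx]

    kept_no = _take(no_dr_pool)
    kept_dr = _take(dr_pool)
    return ([(r.image_id, NO_DR) for r in kept_no]
            + [(r.image_id, DR) for r in kept_dr])


def split_dataset(balanced: list[tuple[str, int]], seed: int,
                  test_denominator: int = 10) -> CuratedDataset:
    """Stratified 1:9 test:train split.

    Per class, the test count is ``ceil(class_size / test_denominator)``,
    drawn uniformly (seeded); the remainder is training.  With the balanced
    686 + 686 pool this yields 69 + 69 = 138 test and 1234 training images.
    """
    by_class: dict[int, list[tuple[str, int]]] = {}
    for item in balanced:
        by_class.setdefault(item[1], []).append(item)
    sizes = {c: len(v) for c, v in by_class.items()}
    if len(sizes) != 2 or len(set(sizes.values())) != 1:
        raise ValueError("balanced input must contain two equally-sized classes")
    if min(sizes.values()) < 2:
        raise ValueError("each class needs at least 2 records to split")
    rng = np.random.default_rng(seed)
    train: list[tuple[str, int]] = []
    test: list[tuple[str, int]] = []
    for cls in sorted(by_class):
        pool = by_class[cls]
        n_test = math.ceil(len(pool) / test_denominator)
        idx = set(rng.choice(len(pool), size=n_test, replace=False).tolist())
        test.extend(p for i, p in enumerate(pool) if i in idx)
        train.extend(p for i, p in enumerate(pool) if i not in idx)
    return CuratedDataset(train=train, test=test, seed=seed)


def curate(records: list[GradeRecord], seed: int) -> CuratedDataset:
    """Full curation: binarize, balance, split; provenance counts recorded."""
    no_dr, dr = binarize_grades(records)
    balanced = balance_pools(no_dr, dr, seed)
    ds = split_dataset(balanced, seed)
    ds.provenance = {
        "input": len(records),
        "no_dr_pool": len(no_dr),
        "dr_pool": len(dr),
        "dropped_grades_1_2": len(records) - len(no_dr) - len(dr),
        "balanced": len(balanced),
        "train": len(ds.train),
        "test": len(ds.test),
    }
    return ds


def read_manifest(path: str | Path) -> list[GradeRecord]:
    """Read an ``image_id,grade`` CSV (or EyePACS ``image,level``)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("image_id") or cols.get("image")
    grade_col = cols.get("grade") or cols.get("level")
    if id_col is None or grade_col is None:
        raise ValueError("manifest needs columns image_id,grade (or image,level)")
    return [GradeRecord(str(i), int(g)) for i, g in zip(df[id_col], df[grade_col])]


def write_curated_manifest(ds: CuratedDataset, path: str | Path) -> None:
    """Write ``image_id,label,split`` CSV plus a ``.provenance.json`` block."""
    path = Path(path)
    rows = ([(i, l, "train") for i, l in ds.train]
            + [(i, l, "test") for i, l in ds.test])
    pd.DataFrame(rows, columns=["image_id", "label", "split"]).to_csv(
        path, index=False)
    prov = {"seed": ds.seed, **ds.provenance}
    path.with_suffix(".provenance.json").write_text(json.dumps(prov, indent=1))
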