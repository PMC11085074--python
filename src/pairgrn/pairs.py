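"""Labeled TF-target pair sets: parsing, negative sampling, splitting.

A :class:`GenePairLabelSet` is the training currency of the whole pipeline:
records of (tf_id, target_id, label) with label 1 meaning "TF regulates
target" and 0 meaning "no interaction". Gold standards supply the
positives; negatives are uniform (TF, gene) pairs disjoint from the
positives, the standard convention when a curated negative set does not
exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


class PairSetError(ValueError):
    """Raised for malformed pair inputs or infeasible sampling requests."""


@dataclass
class GenePairLabelSet:
    """Ordered set of labeled (tf_id, target_id) records."""

    records: pd.DataFrame  # columns: tf_id, target_id, label
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        df = self.records
        required = ["tf_id", "target_id", "label"]
        if list(df.columns) != required:
            df = df[required]
        df = df.astype({"tf_id": str, "target_id": str, "label": np.int64})
        bad = ~df["label"].isin((0, 1))
        if bad.any():
            raise PairSetError(
                f"labels must be 0 or 1; offending rows: {list(df.index[bad][:5])}"
            )
        dup = df.duplicated(subset=["tf_id", "target_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["tf_id", "target_id"]].tolist()
            raise PairSetError(f"duplicate pair {tuple(pair)}")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str, int]]:
        return iter(self.records.itertuples(index=False, name=None))

    @property
    def labels(self) -> np.ndarray:
        return self.records["label"].to_numpy()

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((self.labels == 0).sum())

    @classmethod
    def from_tuples(
        cls,
        tuples: Iterable[tuple[str, str, int]],
        provenance: str = "unspecified",
    ) -> "GenePairLabelSet":
        df = pd.DataFrame(list(tuples), columns=["tf_id", "target_id", "label"])
        return cls(df, provenance)

    def subset(self, indices: Sequence[int], provenance: str | None = None) -> "GenePairLabelSet":
        df = self.records.iloc[list(indices)].reset_index(drop=True)
        return GenePairLabelSet(df, provenance or self.provenance)

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(
    path: str | Path,
    tf_list: Sequence[str] | None = None,
) -> GenePairLabelSet:
    """Parse a 3-column (tf_id, target_id, label) TSV.

    ``#``-prefixed comment lines are ignored; a header row is optional and
    detected by a non-numeric third field. Duplicates and labels outside
    {0,1} are rejected with line numbers.
    """
    path = Path(path)
    rows: list[tuple[str, str, int]] = []
    line_nos: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PairSetError(
                    f"{path.name}:{lineno}: expected 3 tab-separated columns"
                )
            tf, target, label_str = parts[0].strip(), parts[1].strip(), parts[2].strip()
            if lineno == 1 or not rows:
                # allow a header row anywhere before the first data row
                try:
                    int(label_str)
                except ValueError:
                    continue
            try:
                label = int(label_str)
            except ValueError:
                raise PairSetError(
                    f"{path.name}:{lineno}: non-integer label {label_str!r}"
                ) from None
            if label not in (0, 1):
                raise PairSetError(
                    f"{path.name}:{lineno}: label must be 0 or 1, got {label}"
                )
            rows.append((tf, target, label))
            line_nos.append(lineno)
    seen: dict[tuple[str, str], int] = {}
    for (tf, target, _), lineno in zip(rows, line_nos):
        key = (tf, target)
        if key in seen:
            raise PairSetError(
                f"{path.name}: duplicate pair {key} at lines {seen[key]} and {lineno}"
            )
        seen[key] = lineno
    if tf_list is not None:
        allowed = set(tf_list)
        for (tf, _, _), lineno in zip(rows, line_nos):
            if tf not in allowed:
                raise PairSetError(
                    f"{path.name}:{lineno}: tf_id {tf!r} not in the declared TF list"
                )
    return GenePairLabelSet.from_tuples(rows, provenance=str(path))


def sample_negatives(
    positives: GenePairLabelSet,
    tf_ids: Sequence[str],
    gene_universe: Sequence[str],
    ratio: float = 1.0,
    seed: int = 0,
) -> GenePairLabelSet:
    """Add uniformly sampled non-interacting (tf, gene) pairs.

    Candidates are TF x universe minus self-pairs minus the positives;
    ``ceil(ratio * n_positives)`` of them are drawn without replacement.
    """
    if ratio < 0:
        raise PairSetError("ratio must be non-negative")
    n_needed = int(np.ceil(ratio * len(positives)))
    if n_needed == 0:
        return positives
    pos_keys = {(tf, t) for tf, t, _ in positives}
    candidates = [
        (tf, g)
        for tf in tf_ids
        for g in gene_universe
        if tf != g and (tf, g) not in pos_keys
    ]
    if len(candidates) < n_needed:
        raise PairSetError(
            f"need {n_needed} negative pairs but only {len(candidates)} candidates"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_needed, replace=False)
    negatives = [(candidates[i][0], candidates[i][1], 0) for i in sorted(chosen)]
    all_rows = list(positives) + negatives
    return GenePairLabelSet.from_tuples(all_rows, provenance=positives.provenance)


def split_train_test(
    pair_set: GenePairLabelSet,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[GenePairLabelSet, GenePairLabelSet]:
    """Disjoint, exhaustive train/test split, stratified by label by default."""
    n = len(pair_set)
    if n < 2:
        raise PairSetError("need at least 2 records to split")
    if not 0 < train_fraction < 1:
        raise PairSetError("train_fraction must be in (0, 1)")
    labels = pair_set.labels
    if stratified and len(np.unique(labels)) < 2:
        raise PairSetError("stratified split requires both classes present")
    from sklearn.model_selection import train_test_split as _tts

    train_idx, test_idx = _tts(
        np.arange(n),
        train_size=train_fraction,
        random_state=seed,
        shuffle=True,
        stratify=labels if stratified else None,
    )
    train_idx = sorted(train_idx.tolist())
    test_idx = sorted(test_idx.tolist())
    return (
        pair_set.subset(train_idx, provenance=f"{pair_set.provenance}[train]"),
        pair_set.subset(test_idx, provenance=f"{pair_set.provenance}[test]"),
    )


def kfold_partitions(
    pair_set: GenePairLabelSet,
    k: int = 10,
    repeats: int = 20,
    seed: int = 0,
) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """Repeated k-fold partitions as (repeat, fold, train_idx, test_idx).

    Each repeat shuffles once with its own child seed and slices the
    permutation into k contiguous folds whose sizes differ by at most one.
    """
    n = len(pair_set)
    if k < 2:
        raise PairSetError("k must be at least 2")
    if k > n:
        raise PairSetError(f"k={k} exceeds the {n} available records")
    child_seeds = np.random.SeedSequence(seed).spawn(repeats)
    partitions: list[tuple[int, int, np.ndarray, np.ndarray]] = []
    for rep, child in enumerate(child_seeds):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        for fold_i, test in enumerate(folds):
            train = np.concatenate([f for j, f in enumerate(folds) if j != fold_i])
            partitions.append((rep, fold_i, np.sort(train), np.sort(test)))
    return partitions
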