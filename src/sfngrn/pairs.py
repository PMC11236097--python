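"""Labeled gene-pair construction and TF-disjoint cross-validation folds.

Two supervised tasks are supported. For the *interaction* task each true
TF-target pair (a, x1) is matched with one negative pair (a, x2), x2 drawn
uniformly without replacement from the non-targets of a, giving a 1:1 class
ratio per TF. For the *causality* task every true directed edge (a, x1)
yields the reversed pair (x1, a) as its negative, so the classifier must
learn direction, not mere association.

Folds are assigned to transcription factors, never to individual pairs: all
pairs anchored on one TF share a fold, which is what makes the
cross-validation leakage-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import EdgeList

logger = logging.getLogger(__name__)

__all__ = [
    "GenePair",
    "PairDataset",
    "build_interaction_pairs",
    "build_causality_pairs",
    "split_by_tf",
    "shuffle_labels_within_tf",
]


@dataclass(frozen=True)
class GenePair:
    """One labeled (regulator, target) example anchored on a TF for grouping."""

    regulator: str
    target: str
    label: int
    tf_group: str
    task: str  # "interaction" | "causality"

    def __post_init__(self) -> None:
        if self.regulator.casefold() == self.target.casefold():
            raise ValueError(f"self-pair not allowed: {self.regulator}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.task not in ("interaction", "causality"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class PairDataset:
    """A balanced set of labeled gene pairs with optional TF->fold assignment."""

    pairs: list[GenePair]
    fold_of: dict[str, int] | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def tf_groups(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for p in self.pairs:
            if p.tf_group not in seen:
                seen.add(p.tf_group)
                out.append(p.tf_group)
        return out

    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs], dtype=int)

    def pair_array(self) -> np.ndarray:
        """(n_pairs, 2) object array of (regulator, target) names."""
        return np.array([(p.regulator, p.target) for p in self.pairs], dtype=object)

    def groups(self) -> np.ndarray:
        return np.array([p.tf_group for p in self.pairs], dtype=object)

    def subset_folds(self, folds: set[int] | list[int]) -> "PairDataset":
        if self.fold_of is None:
            raise ValueError("dataset has no fold assignment; call split_by_tf first")
        folds = set(folds)
        kept = [p for p in self.pairs if self.fold_of[p.tf_group] in folds]
        fold_of = {t: f for t, f in self.fold_of.items() if f in folds}
        return PairDataset(kept, fold_of=fold_of, seed=self.seed)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "regulator": p.regulator,
                "target": p.target,
                "label": p.label,
                "tf_group": p.tf_group,
                "task": p.task,
                "fold": self.fold_of.get(p.tf_group, -1) if self.fold_of else -1,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(
            rows, columns=["regulator", "target", "label", "tf_group", "task", "fold"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairDataset":
        frame = pd.read_csv(path, sep="\t")
        pairs = [
            GenePair(
                str(r.regulator), str(r.target), int(r.label), str(r.tf_group), str(r.task)
            )
            for r in frame.itertuples()
        ]
        fold_of: dict[str, int] | None = None
        if "fold" in frame.columns and (frame["fold"] >= 0).all():
            fold_of = {
                str(t): int(f)
                for t, f in zip(frame["tf_group"], frame["fold"])
            }
        return cls(pairs, fold_of=fold_of)

    def check_balance(self) -> None:
        """Assert the 1:1 label ratio, globally and per TF."""
        frame = self.to_frame()
        global_counts = frame["label"].value_counts()
        if global_counts.get(0, 0) != global_counts.get(1, 0):
            raise AssertionError("global label counts are not balanced")
        per_tf = frame.groupby("tf_group")["label"].agg(["sum", "count"])
        bad = per_tf[per_tf["sum"] * 2 != per_tf["count"]]
        if len(bad):
            raise AssertionError(f"unbalanced TFs: {list(bad.index)}")


def _canonicalize(names: list[str]) -> dict[str, str]:
    return {n.casefold(): n for n in names}


def build_interaction_pairs(
    truth: EdgeList,
    gene_universe: list[str],
    tf_list: list[str] | None = None,
    seed: int = 0,
) -> PairDataset:
    """Balanced positive/negative pairs for the interaction task.

    For each TF ``a`` with m in-universe targets, emits the m positives
    (a, target) and m negatives (a, non-target) sampled uniformly without
    replacement from ``gene_universe`` minus ``a`` and its targets.
    """
    canon = _canonicalize(gene_universe)
    truth = truth.restrict_to(gene_universe)
    if tf_list is None:
        tf_list = truth.regulators()
    rng = np.random.default_rng(seed)
    pairs: list[GenePair] = []
    skipped: list[str] = []
    for tf in tf_list:
        targets = truth.targets_of(tf)
        if not targets:
            skipped.append(tf)
            continue
        tf_name = canon.get(tf.casefold(), tf)
        excluded = {tf.casefold()} | {t.casefold() for t in targets}
        pool = sorted(k for k in canon if k not in excluded)
        if len(pool) < len(targets):
            raise ValueError(
                f"TF {tf!r} has {len(targets)} targets but only {len(pool)} "
                "candidate non-targets in the gene universe"
            )
        negatives = rng.choice(len(pool), size=len(targets), replace=False)
        for tgt, neg in zip(targets, negatives):
            pairs.append(GenePair(tf_name, canon[tgt.casefold()], 1, tf_name, "interaction"))
            pairs.append(GenePair(tf_name, canon[pool[neg]], 0, tf_name, "interaction"))
    if skipped:
        logger.warning(
            "excluded %d TF(s) with no in-universe targets: %s",
            len(skipped),
            ", ".join(skipped),
        )
    return PairDataset(pairs, seed=seed)


def build_causality_pairs(
    truth: EdgeList, tf_list: list[str] | None = None
) -> PairDataset:
    """Direction-labeled pairs: each true edge (a, x1) with label 1 is
    mirrored by (x1, a) with label 0; both carry ``tf_group = a`` so they
    travel together across folds.

    Reciprocal edges (both a->b and b->a in the truth) would receive
    contradictory labels and are removed with a logged count.
    """
    if not truth.directed:
        raise ValueError("causality pairs require a directed ground truth")
    keys = {(a.casefold(), b.casefold()) for a, b in truth.edges}
    reciprocal = {(a, b) for a, b in keys if (b, a) in keys}
    if reciprocal:
        logger.warning(
            "removed %d reciprocal edge(s) from causality ground truth",
            len(reciprocal) // 2,
        )
    pairs: list[GenePair] = []
    allowed = (
        None if tf_list is None else {t.casefold() for t in tf_list}
    )
    for a, b in truth.edges:
        if (a.casefold(), b.casefold()) in reciprocal:
            continue
        if allowed is not None and a.casefold() not in allowed:
            continue
        pairs.append(GenePair(a, b, 1, a, "causality"))
        pairs.append(GenePair(b, a, 0, a, "causality"))
    return PairDataset(pairs)


def split_by_tf(ds: PairDataset, n_folds: int = 3, seed: int = 0) -> PairDataset:
    """Assign TFs (and hence their pairs) to folds, round-robin after a shuffle.

    Fold sizes differ by at most one TF; fold TF sets are pairwise disjoint
    and cover all TFs, so no pair's anchor TF can appear on both sides of a
    train/test split.
    """
    tfs = sorted(ds.tf_groups)
    if n_folds > len(tfs):
        raise ValueError(
            f"cannot split {len(tfs)} TF(s) into {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tfs))
    fold_of = {tfs[j]: i % n_folds for i, j in enumerate(order)}
    return PairDataset(list(ds.pairs), fold_of=fold_of, seed=seed)


def shuffle_labels_within_tf(ds: PairDataset, seed: int = 0) -> PairDataset:
    """Permute labels within each TF group — the null control.

    Shuffling within groups preserves the per-TF 1:1 class balance while
    destroying any association between pair identity and label.
    """
    rng = np.random.default_rng(seed)
    by_tf: dict[str, list[int]] = {}
    for i, p in enumerate(ds.pairs):
        by_tf.setdefault(p.tf_group, []).append(i)
    new_labels = [p.label for p in ds.pairs]
    for idx in by_tf.values():
        labels = [ds.pairs[i].label for i in idx]
        perm = rng.permutation(len(idx))
        for slot, j in zip(idx, perm):
            new_labels[slot] = labels[j]
    pairs = [
        GenePair(p.regulator, p.target, new_labels[i], p.tf_group, p.task)
        for i, p in enumerate(ds.pairs)
    ]
    return PairDataset(pairs, fold_of=ds.fold_of, seed=ds.seed)
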