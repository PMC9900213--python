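"""Build positive / hard-negative / easy-negative pools and the dataset split.

The negative taxonomy is per kinase: a *hard negative* for kinase ``k`` is a
peptide with phosphorylation evidence for some other kinase but not for
``k``; an *easy negative* is an S/TY-centered peptide with no evidence of
phosphorylation by any kinase. A site annotated for several kinases is a
positive for each of them and a hard negative for none of them.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .records import (
    LabeledPair,
    PairLabel,
    PeptideWindow,
    PhosphoAnnotationTable,
    PHOSPHOACCEPTORS,
    SubstrateRecord,
    WINDOW_FLANK,
    WINDOW_SIZE,
)

logger = logging.getLogger(__name__)

DEFAULT_SPLIT_RATIO = (0.70, 0.15, 0.15)
#: kinases with at most this many positives contribute to training only
DEFAULT_MIN_POSITIVES = 50


def window_at(substrate: SubstrateRecord, position: int) -> PeptideWindow:
    """The 11-mer around ``position``, '-'-padded when near a terminus."""
    seq = substrate.sequence
    if not (0 <= position < len(seq)):
        raise ValueError(f"position {position} outside substrate {substrate.substrate_id}")
    lo, hi = position - WINDOW_FLANK, position + WINDOW_FLANK + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    residues = "-" * left_pad + seq[max(0, lo) : min(len(seq), hi)] + "-" * right_pad
    assert len(residues) == WINDOW_SIZE
    return PeptideWindow(
        residues=residues, source_substrate_id=substrate.substrate_id, site_position=position
    )


def extract_windows(substrate: SubstrateRecord) -> list[PeptideWindow]:
    """All unique 11-mer windows centered on S/T/Y within one substrate.

    De-duplication is per substrate by residue string (the first occurrence
    is kept); identical windows in different substrates remain distinct.
    """
    seen: set[str] = set()
    windows = []
    for pos, aa in enumerate(substrate.sequence):
        if aa in PHOSPHOACCEPTORS:
            w = window_at(substrate, pos)
            if w.residues not in seen:
                seen.add(w.residues)
                windows.append(w)
    return windows


@dataclass
class NegativePools:
    """Per-kinase hard negatives and the shared easy-negative pool."""

    hard: dict[str, list[PeptideWindow]]
    easy: list[PeptideWindow]

    def hard_union(self) -> list[PeptideWindow]:
        seen: set[tuple[str, int]] = set()
        union = []
        for windows in self.hard.values():
            for w in windows:
                key = (w.source_substrate_id, w.site_position)
                if key not in seen:
                    seen.add(key)
                    union.append(w)
        return union


def build_pools(
    annotations: PhosphoAnnotationTable, substrates: Sequence[SubstrateRecord]
) -> tuple[dict[str, list[PeptideWindow]], NegativePools]:
    """Derive per-kinase positive sets and the negative pools.

    Returns ``(positives, pools)`` where ``positives[k]`` are the annotated
    windows of kinase ``k``. Every annotated site becomes a hard negative
    for exactly the kinases that are *not* annotated on it; unannotated
    S/T/Y windows form the global easy-negative pool.
    """
    by_id = {s.substrate_id: s for s in substrates}
    site_kinases: dict[tuple[str, int], set[str]] = {}
    for row in annotations.rows:
        site_kinases.setdefault((row.substrate_id, row.site_position), set()).add(row.kinase_id)

    site_window = {
        (sid, pos): window_at(by_id[sid], pos) for (sid, pos) in site_kinases if sid in by_id
    }
    annotated_strings: dict[str, set[str]] = {}
    for (sid, pos), w in site_window.items():
        annotated_strings.setdefault(sid, set()).add(w.residues)

    kinase_ids = annotations.kinase_ids()
    positives: dict[str, list[PeptideWindow]] = {k: [] for k in kinase_ids}
    hard: dict[str, list[PeptideWindow]] = {k: [] for k in kinase_ids}
    for site, kinases in site_kinases.items():
        w = site_window.get(site)
        if w is None:
            continue
        for k in kinase_ids:
            (positives if k in kinases else hard)[k].append(w)

    easy = []
    for sub in substrates:
        annotated = annotated_strings.get(sub.substrate_id, set())
        easy.extend(w for w in extract_windows(sub) if w.residues not in annotated)
    return positives, NegativePools(hard=hard, easy=easy)


@dataclass
class DatasetSplit:
    train: list[LabeledPair] = field(default_factory=list)
    validation: list[LabeledPair] = field(default_factory=list)
    test: list[LabeledPair] = field(default_factory=list)
    positive_counts: dict[str, int] = field(default_factory=dict)
    #: hard negatives consumed by validation/test pairing, per kinase,
    #: keyed by (substrate_id, site_position); excluded from train sampling
    used_hard: dict[str, set[tuple[str, int]]] = field(default_factory=dict)
    seed: int | None = None

    def partition(self, name: str) -> list[LabeledPair]:
        return {"train": self.train, "validation": self.validation, "test": self.test}[name]


def _partition_sizes(n: int, ratio: tuple[float, float, float]) -> tuple[int, int, int]:
    """Floor the validation/test shares; the remainder goes to train."""
    n_val = math.floor(ratio[1] * n)
    n_test = math.floor(ratio[2] * n)
    return n - n_val - n_test, n_val, n_test


def split_dataset(
    positives: Mapping[str, Sequence[PeptideWindow]],
    pools: NegativePools,
    ratio: tuple[float, float, float] = DEFAULT_SPLIT_RATIO,
    min_positives: int = DEFAULT_MIN_POSITIVES,
    seed: int = 0,
) -> DatasetSplit:
    """Split positives 70:15:15 and pair one hard negative per held-out positive.

    Kinases with at most ``min_positives`` positives go to training only.
    Hard negatives for validation/test are drawn without replacement from
    the kinase's own pool (falling back to the global union, with a log
    line, if the pool runs dry) and are never reused for training.
    """
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError(f"split ratio {ratio} does not sum to 1")
    rng = np.random.default_rng(seed)
    split = DatasetSplit(seed=seed)
    global_hard = pools.hard_union()

    for kinase_id in sorted(positives):
        pos = list(positives[kinase_id])
        split.positive_counts[kinase_id] = len(pos)
        split.used_hard.setdefault(kinase_id, set())
        if len(pos) <= min_positives:
            split.train.extend(
                LabeledPair(kinase_id, w, PairLabel.POSITIVE) for w in pos
            )
            continue
        order = rng.permutation(len(pos))
        n_train, n_val, n_test = _partition_sizes(len(pos), ratio)
        parts = {
            "train": [pos[i] for i in order[:n_train]],
            "validation": [pos[i] for i in order[n_train : n_train + n_val]],
            "test": [pos[i] for i in order[n_train + n_val :]],
        }
        split.train.extend(
            LabeledPair(kinase_id, w, PairLabel.POSITIVE) for w in parts["train"]
        )

        pool = list(pools.hard.get(kinase_id, []))
        pool_order = list(rng.permutation(len(pool)))
        pos_keys = {(w.source_substrate_id, w.site_position) for w in pos}
        borrowable: list[PeptideWindow] | None = None  # built lazily on exhaustion
        for name in ("validation", "test"):
            target = split.partition(name)
            for w in parts[name]:
                target.append(LabeledPair(kinase_id, w, PairLabel.POSITIVE))
                if pool_order:
                    neg = pool[pool_order.pop()]
                else:
                    logger.warning(
                        "hard-negative pool exhausted for kinase %s; borrowing from global union",
                        kinase_id,
                    )
                    if borrowable is None:
                        used = split.used_hard[kinase_id]
                        borrowable = [
                            g
                            for g in global_hard
                            if (g.source_substrate_id, g.site_position) not in pos_keys
                            and (g.source_substrate_id, g.site_position) not in used
                        ]
                        rng.shuffle(borrowable)  # type: ignore[arg-type]
                    if not borrowable:
                        raise ValueError(
                            f"no hard negatives available anywhere for kinase {kinase_id}"
                        )
                    neg = borrowable.pop()
                target.append(LabeledPair(kinase_id, neg, PairLabel.HARD_NEGATIVE))
                split.used_hard[kinase_id].add((neg.source_substrate_id, neg.site_position))
    return split


def sample_easy_test(
    pools: NegativePools,
    kinase_ids: Sequence[str],
    size: int,
    seed: int = 0,
) -> list[LabeledPair]:
    """A separate all-negative test set: easy negatives paired with random
    kinases, for false-positive-rate benchmarking only."""
    if not pools.easy:
        raise ValueError("easy-negative pool is empty")
    if not kinase_ids:
        raise ValueError("no kinases to pair with")
    rng = np.random.default_rng(seed)
    kids = sorted(kinase_ids)
    return [
        LabeledPair(
            kids[int(rng.integers(len(kids)))],
            pools.easy[int(rng.integers(len(pools.easy)))],
            PairLabel.EASY_NEGATIVE,
        )
        for _ in range(size)
    ]


def sample_training_negatives(
    split: DatasetSplit,
    pools: NegativePools,
    n_easy: int,
    m_hard: int,
    seed: int = 0,
) -> list[LabeledPair]:
    """Augment the training partition with (n_easy + m_hard) negatives per positive.

    Easy negatives pair the positive's kinase with a random unannotated
    window; hard negatives come from the kinase's own pool, excluding any
    already consumed by validation/test pairing. The returned list has a
    positive:negative ratio of exactly 1:(n_easy + m_hard).
    """
    if n_easy < 0 or m_hard < 0:
        raise ValueError("negative counts must be non-negative")
    if n_easy > 0 and not pools.easy:
        raise ValueError("easy-negative pool is empty but n_easy > 0")
    rng = np.random.default_rng(seed)

    avail_hard: dict[str, list[PeptideWindow]] = {}
    for kinase_id, pool in pools.hard.items():
        used = split.used_hard.get(kinase_id, set())
        avail_hard[kinase_id] = [
            w for w in pool if (w.source_substrate_id, w.site_position) not in used
        ]
    # fallback pool per kinase: unused hard negatives of any other kinase
    # that are not themselves positives of this kinase
    fallback_cache: dict[str, list[PeptideWindow]] = {}

    def _fallback(kinase_id: str) -> list[PeptideWindow]:
        if kinase_id not in fallback_cache:
            used = split.used_hard.get(kinase_id, set())
            pos_keys = {
                (p.peptide.source_substrate_id, p.peptide.site_position)
                for part in (split.train, split.validation, split.test)
                for p in part
                if p.kinase_id == kinase_id and p.label is PairLabel.POSITIVE
            }
            fallback_cache[kinase_id] = [
                w
                for w in pools.hard_union()
                if (w.source_substrate_id, w.site_position) not in used
                and (w.source_substrate_id, w.site_position) not in pos_keys
            ]
        return fallback_cache[kinase_id]

    out = list(split.train)
    for pair in split.train:
        if pair.label is not PairLabel.POSITIVE:
            continue
        for _ in range(n_easy):
            w = pools.easy[int(rng.integers(len(pools.easy)))]
            out.append(LabeledPair(pair.kinase_id, w, PairLabel.EASY_NEGATIVE))
        pool = avail_hard.get(pair.kinase_id) or []
        for _ in range(m_hard):
            if not pool:
                logger.warning(
                    "no unused hard negatives for kinase %s; borrowing from global union",
                    pair.kinase_id,
                )
                pool = _fallback(pair.kinase_id)
                if not pool:
                    raise ValueError(
                        f"no hard negatives available anywhere for kinase {pair.kinase_id}"
                    )
            w = pool[int(rng.integers(len(pool)))]
            out.append(LabeledPair(pair.kinase_id, w, PairLabel.HARD_NEGATIVE))
    return out
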