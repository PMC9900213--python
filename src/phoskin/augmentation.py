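"""Protein-specific training-time augmentations.

Four strategies, all acting on the kinase side of a (kinase, peptide) pair:

* resampling under-represented kinases up to fixed targets,
* shifting the kinase-domain boundaries by up to ``max_shift`` residues
  independently at each terminus,
* masking a fraction of kinase-domain residues with a mask marker,
* (negatives share shifting and masking but are never resampled).

Peptide windows are never modified. Augmentation applies to the training
partition only and is meant to be re-drawn every epoch.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .records import KinaseRecord, LabeledPair, MASK_CHAR, PairLabel


@dataclass
class AugmentationConfig:
    resample_target_large: int = 1118
    resample_target_small: int = 50
    resample_threshold: int = 50
    max_shift: int = 5
    kinase_mask_rate: float = 0.05
    enable_resample: bool = True
    enable_shift: bool = True
    enable_mask: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.kinase_mask_rate < 1.0):
            raise ValueError("kinase_mask_rate must be in [0, 1)")
        if self.max_shift < 0:
            raise ValueError("max_shift must be non-negative")


@dataclass(frozen=True)
class AugmentedExample:
    """A labeled pair together with the (possibly perturbed) kinase domain."""

    pair: LabeledPair
    kinase_domain: str


def resample_positives(
    positives: Sequence[LabeledPair], cfg: AugmentationConfig, rng: np.random.Generator
) -> list[LabeledPair]:
    """Upsample each kinase's training positives to its fixed target count.

    Kinases with more than ``resample_threshold`` positives are brought to
    ``resample_target_large``; the rest to ``resample_target_small``.
    Kinases already at or above their target are left unchanged — never
    downsampled. Extra copies are drawn with replacement; downstream
    shifting/masking makes the repeats non-identical.
    """
    by_kinase: dict[str, list[LabeledPair]] = {}
    for p in positives:
        if p.label is not PairLabel.POSITIVE:
            raise ValueError("resample_positives accepts positive pairs only")
        by_kinase.setdefault(p.kinase_id, []).append(p)

    out: list[LabeledPair] = []
    for kinase_id in sorted(by_kinase):
        pool = by_kinase[kinase_id]
        target = (
            cfg.resample_target_large
            if len(pool) > cfg.resample_threshold
            else cfg.resample_target_small
        )
        out.extend(pool)
        if len(pool) < target:
            extra = rng.integers(len(pool), size=target - len(pool))
            out.extend(pool[i] for i in extra)
    return out


def shift_domain(
    kinase: KinaseRecord, cfg: AugmentationConfig, rng: np.random.Generator
) -> str:
    """Kinase domain with both boundaries independently shifted by up to
    ``max_shift`` residues, clamped to the full-length sequence.

    A draw that would leave an empty interval is redrawn.
    """
    n = len(kinase.full_sequence)
    if cfg.max_shift == 0:
        return kinase.domain_sequence
    while True:
        d_n = int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))
        d_c = int(rng.integers(-cfg.max_shift, cfg.max_shift + 1))
        start = min(max(kinase.domain_start + d_n, 0), n)
        end = min(max(kinase.domain_end + d_c, 0), n)
        if end - start > 0:
            return kinase.full_sequence[start:end]


def mask_kinase(domain: str, cfg: AugmentationConfig, rng: np.random.Generator) -> str:
    """Replace each domain position independently with the mask marker with
    probability ``kinase_mask_rate``."""
    if not domain:
        raise ValueError("cannot mask an empty domain")
    if cfg.kinase_mask_rate == 0.0:
        return domain
    hits = rng.random(len(domain)) < cfg.kinase_mask_rate
    return "".join(MASK_CHAR if hit else aa for aa, hit in zip(domain, hits))


def augment_batch(
    pairs: Sequence[LabeledPair],
    kinome: Mapping[str, KinaseRecord],
    cfg: AugmentationConfig,
    rng: np.random.Generator,
    partition: str = "train",
) -> list[AugmentedExample]:
    """Apply resample (positives only) -> shift -> mask to a training batch.

    Negatives keep their count but still receive shifting and masking.
    Refuses non-training partitions: augmentation would contaminate
    evaluation.
    """
    if partition != "train":
        raise ValueError(f"augmentation applies to the training partition only, got {partition!r}")
    positives = [p for p in pairs if p.label is PairLabel.POSITIVE]
    negatives = [p for p in pairs if p.label is not PairLabel.POSITIVE]
    if cfg.enable_resample and positives:
        positives = resample_positives(positives, cfg, rng)
    out = []
    for pair in positives + negatives:
        kin = kinome[pair.kinase_id]
        domain = shift_domain(kin, cfg, rng) if cfg.enable_shift else kin.domain_sequence
        if cfg.enable_mask:
            domain = mask_kinase(domain, cfg, rng)
        out.append(AugmentedExample(pair=pair, kinase_domain=domain))
    return out
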