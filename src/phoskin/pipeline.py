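"""End-to-end desk-scale experiment: synthesize → curate → train → evaluate.

This is the programmatic equivalent of chaining the CLI subcommands; the
defaults here are the desk-scale study conditions (tiny encoder, synthetic
kinome) under which the pipeline provably recovers planted specificity
motifs on one CPU in minutes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augmentation import AugmentationConfig
from .curation import (
    NegativePools,
    build_pools,
    sample_easy_test,
    sample_training_negatives,
    split_dataset,
)
from .encoding import Vocabulary
from .evaluation import MetricReport, stratified_report
from .nn.transformer import ModelConfig, TransformerEncoder
from .records import LabeledPair
from .synthetic import SyntheticDataset, SyntheticKinomeConfig, generate_dataset
from .training import FinetuneLog, TrainConfig, finetune, pretrain, score_examples


@dataclass
class ExperimentConfig:
    """Desk-scale defaults for the full synthetic-kinome experiment."""

    synth: SyntheticKinomeConfig = field(default_factory=SyntheticKinomeConfig)
    model: ModelConfig = field(default_factory=ModelConfig.tiny)
    # negative sampling for training (positive:negative = 1:(n_easy+m_hard));
    # one easy plus one hard per positive keeps the grammar-matching core of
    # the task balanced, which a desk-scale encoder needs to escape the
    # peptide-only shortcut
    n_easy: int = 1
    m_hard: int = 1
    easy_test_size: int = 400
    #: redraw the (n+m) training negatives every epoch, so the model sees
    #: fresh easy-negative windows throughout training (augmentation in
    #: spirit: positives are fixed, negative pairings vary)
    online_negatives: bool = True
    pretrain_epochs: int = 6
    batch_size: int = 64
    pretrain_lr: float = 1e-3
    finetune_lr: float = 1.5e-3
    gamma: float = 2.0
    # the joint kinase-motif feature emerges at a seed-dependent epoch and
    # the validation loss is noisy before it does; the desk pipeline holds
    # the peak rate until validation clears ``breakout_val`` (capped at
    # ``hold_max_epochs``), then runs a short decay tail, keeping the
    # best-validation checkpoint throughout
    breakout_val: float = 0.15
    hold_min_epochs: int = 9
    hold_max_epochs: int = 16
    decay_epochs: int = 8
    patience: int = 99
    pretrain_corpus_size: int = 120  # sequences drawn from kinome + substrates
    # shift + mask keep resampled-free epochs cheap while still breaking
    # kinase-sequence memorization; family imbalance is mild (~3x) so
    # resampling is off in the desk-scale pipeline
    augment: AugmentationConfig | None = field(
        default_factory=lambda: AugmentationConfig(enable_resample=False)
    )
    seed: int = 0


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    dataset: SyntheticDataset
    pools: NegativePools
    vocab: Vocabulary
    model: TransformerEncoder
    pretrained_state: dict
    finetune_log: FinetuneLog
    pretrain_trace: list[float]
    test_pairs: list[LabeledPair]
    test_scores: np.ndarray
    easy_pairs: list[LabeledPair]
    easy_scores: np.ndarray
    report: MetricReport

    def pretrained_model(self) -> TransformerEncoder:
        """A copy of the encoder as it stood after pre-training."""
        model = TransformerEncoder(self.model.config, seed=0)
        model.load_state_dict(self.pretrained_state)
        return model


def build_pretrain_corpus(
    dataset: SyntheticDataset, size: int, rng: np.random.Generator
) -> list[str]:
    """Kinase domains plus a sample of substrate sequences."""
    corpus = [k.domain_sequence for k in dataset.kinome]
    n_sub = max(0, size - len(corpus))
    if n_sub and dataset.substrates:
        idx = rng.choice(len(dataset.substrates), size=min(n_sub, len(dataset.substrates)), replace=False)
        corpus.extend(dataset.substrates[i].sequence for i in idx)
    return corpus


def run_experiment(cfg: ExperimentConfig | None = None, seed: int | None = None) -> ExperimentResult:
    cfg = cfg if cfg is not None else ExperimentConfig()
    if seed is not None:
        cfg.seed = seed
        cfg.synth.seed = seed

    dataset = generate_dataset(cfg.synth)
    positives, pools = build_pools(dataset.annotations, dataset.substrates)
    split = split_dataset(positives, pools, seed=cfg.seed)
    train_pairs = sample_training_negatives(split, pools, cfg.n_easy, cfg.m_hard, seed=cfg.seed)

    aug = cfg.augment
    if aug is not None and aug.resample_target_large <= 0:
        # "auto": track the observed maximum per-kinase training positive count
        from dataclasses import replace as _replace

        from .records import PairLabel

        counts: dict[str, int] = {}
        for p in split.train:
            if p.label is PairLabel.POSITIVE:
                counts[p.kinase_id] = counts.get(p.kinase_id, 0) + 1
        aug = _replace(aug, resample_target_large=max(counts.values()))

    vocab = Vocabulary()
    model = TransformerEncoder(cfg.model, seed=cfg.seed)

    corpus = build_pretrain_corpus(
        dataset, cfg.pretrain_corpus_size, np.random.default_rng(cfg.seed + 7)
    )
    pre_cfg = TrainConfig(
        stage="pretrain",
        learning_rate=cfg.pretrain_lr,
        epochs=cfg.pretrain_epochs,
        batch_size=cfg.batch_size,
        seed=cfg.seed,
    )
    pretrain_trace = pretrain(model, corpus, pre_cfg, vocab)
    pretrained_state = model.state_dict()

    fit_cfg = TrainConfig(
        stage="finetune",
        learning_rate=cfg.finetune_lr,
        gamma=cfg.gamma,
        epochs=cfg.hold_max_epochs + cfg.decay_epochs,
        batch_size=cfg.batch_size,
        patience=cfg.patience,
        seed=cfg.seed,
        n_easy=cfg.n_easy,
        m_hard=cfg.m_hard,
        breakout_val=cfg.breakout_val,
        hold_min_epochs=cfg.hold_min_epochs,
        hold_max_epochs=cfg.hold_max_epochs,
        decay_epochs=cfg.decay_epochs,
    )
    provider = None
    if cfg.online_negatives:
        def provider(epoch: int):
            return sample_training_negatives(
                split, pools, cfg.n_easy, cfg.m_hard, seed=(cfg.seed * 1009 + epoch) % (2**31)
            )

    log = finetune(
        model,
        train_pairs,
        split.validation,
        dataset.kinome_map,
        fit_cfg,
        aug,
        vocab,
        train_provider=provider,
    )

    test_pairs = list(split.test)
    test_scores = score_examples(model, test_pairs, dataset.kinome_map, vocab)
    easy_pairs = sample_easy_test(
        pools, [k.kinase_id for k in dataset.kinome], cfg.easy_test_size, seed=cfg.seed + 13
    )
    easy_scores = score_examples(model, easy_pairs, dataset.kinome_map, vocab)
    report = stratified_report(
        test_scores, test_pairs, dataset.kinome_map, easy_scores=easy_scores
    )
    return ExperimentResult(
        config=cfg,
        dataset=dataset,
        pools=pools,
        vocab=vocab,
        model=model,
        pretrained_state=pretrained_state,
        finetune_log=log,
        pretrain_trace=pretrain_trace,
        test_pairs=test_pairs,
        test_scores=test_scores,
        easy_pairs=easy_pairs,
        easy_scores=easy_scores,
        report=report,
    )
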