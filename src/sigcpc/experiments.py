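"""Label-efficiency study: pretrained vs from-scratch classifiers under label budgets.

For each labeled fraction (the canonical grid is 10%, 30%, 50%, 70%, 100%),
each seed and each mode, the harness pretrains the contrastive pretext task
on the unlabeled training epochs (pretrained mode only), fine-tunes the
classifier on a class-stratified labeled subset, and evaluates on held-out
data.  "Scratch" mode uses the identical architecture with a freshly
initialized encoder — plain supervised training — so the accuracy gap
isolates what the self-supervised pretraining contributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import TrainConfig, build_classifier, predict, train_classifier
from .data import EpochDataset, label_mask, split_dataset
from .metrics import confusion_matrix, report_metrics
from .pretext import Encoder, PretextConfig, train_pretext

__all__ = ["ExperimentConfig", "label_fraction_experiment", "evaluate_classifier"]

CANONICAL_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 1.0)


@dataclass
class ExperimentConfig:
    test_fraction: float = 0.1  # the 9:1 train/test convention
    val_fraction: float = 0.2  # of the labeled subset, for the plateau monitor
    pretext: PretextConfig = field(default_factory=PretextConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    evaluation_scope: str = "heldout"  # "heldout", "full", or "both"


def evaluate_classifier(model, dataset: EpochDataset):
    """EvalReport of a trained classifier on a dataset."""
    pred, _ = predict(model, dataset)
    m = confusion_matrix(dataset.labels, pred, model.n_classes)
    return report_metrics(m, dataset.class_names)


def _run_one(
    mode: str,
    encoder_template: tuple[int, tuple[int, ...], int],
    pretrained_encoder_state,
    labeled: EpochDataset,
    test: EpochDataset,
    config: ExperimentConfig,
    seed: int,
):
    input_length, hidden, d_z = encoder_template
    enc = Encoder(input_length, hidden, d_z, rng=np.random.default_rng(seed))
    if mode == "pretrained":
        enc.load_state_dict(pretrained_encoder_state)
    fit, val = split_dataset(labeled, config.val_fraction, seed)
    model = build_classifier(enc, labeled.n_classes, seed=seed)
    tc = TrainConfig(**{**config.train.__dict__, "seed": seed})
    model, _ = train_classifier(model, fit, val, tc)
    return model


def label_fraction_experiment(
    dataset: EpochDataset,
    fractions=CANONICAL_FRACTIONS,
    seeds=(0, 1, 2),
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Run the full label-fraction grid; returns a tidy results table.

    Columns: fraction, mode ("pretrained"/"scratch"), seed, scope,
    accuracy, macro_f1 (percent).  The pretext task is trained once per
    seed and its encoder reused across fractions.
    """
    config = config or ExperimentConfig()
    if any(not 0.0 < f <= 1.0 for f in fractions):
        raise ValueError(f"fractions must lie in (0, 1], got {list(fractions)}")
    rows = []
    for seed in seeds:
        train, test = split_dataset(dataset, config.test_fraction, seed)
        pc = PretextConfig(**{**config.pretext.__dict__, "seed": seed})
        pretext_model, _ = train_pretext(train, test, pc)
        enc_state = pretext_model.encoder.state_dict()
        template = (
            pretext_model.encoder.input_length,
            pretext_model.encoder.hidden,
            pretext_model.encoder.d_z,
        )
        for fraction in fractions:
            idx = label_mask(train, fraction, seed)
            labeled = train.subset(idx)
            for mode in ("pretrained", "scratch"):
                model = _run_one(
                    mode, template, enc_state, labeled, test, config, seed
                )
                scopes = (
                    ["heldout", "full"]
                    if config.evaluation_scope == "both"
                    else [config.evaluation_scope]
                )
                for scope in scopes:
                    target = test if scope == "heldout" else dataset
                    rep = evaluate_classifier(model, target)
                    rows.append(
                        {
                            "fraction": fraction,
                            "mode": mode,
                            "seed": seed,
                            "scope": scope,
                            "accuracy": rep.accuracy,
                            "macro_f1": rep.macro_f1,
                        }
                    )
    return pd.DataFrame(rows)
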