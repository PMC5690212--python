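"""Leave-one-subject-out evaluation and the step-size sweep.

The classifier must generalize to unseen anatomy, so evaluation holds out
all solutions of one subject per fold and trains on the remaining subjects
(with an internal 80/20 train/validation split for early stopping).  The
positive class is the *unsuccessful* registration: sensitivity is the
fraction of truly failed solutions flagged, specificity the fraction of good
solutions passed.  Metrics with an empty denominator are reported as NaN and
flagged, never coerced to 0 or 1.

The sampling step size of the feature profiles is a hyperparameter; the
sweep retrains and re-evaluates the classifier for each step in the grid and
selects the step maximizing the mean balanced accuracy across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from regiq.classifier import TrainConfig, predict, scg_train
from regiq.mvd import UNSUCCESSFUL

__all__ = ["FoldResult", "FEATURE_COLUMNS", "leave_one_out", "step_size_sweep",
           "sweep_table", "select_step", "plot_feature_scatter", "plot_sweep"]

FEATURE_COLUMNS = ["do_trans", "do_rot", "ms_trans", "ms_rot"]


@dataclass
class FoldResult:
    """Held-out-subject confusion counts and derived metrics."""

    subject_id: str
    tp: int
    fp: int
    tn: int
    fn: int
    step_size: float
    seed: int
    undefined: tuple = ()

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0


def _fold_seed(base_seed: int, step_size: float, fold_index: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(round(step_size * 1000)),
                                 int(fold_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def leave_one_out(dataset: pd.DataFrame, config: TrainConfig = TrainConfig(),
                  threshold: float = 0.5):
    """One fold per subject: train on the others, test on the held-out one.

    ``dataset`` needs columns ``subject`` and ``label`` plus the four feature
    columns; rows of one step size only.  Returns a list of
    :class:`FoldResult` in subject order.
    """
    subjects = sorted(dataset["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-out needs >= 2 subjects")
    step = float(dataset["step_size"].iloc[0]) if "step_size" in dataset else float("nan")
    results = []
    for i, held in enumerate(subjects):
        train_df = dataset[dataset["subject"] != held]
        test_df = dataset[dataset["subject"] == held]
        seed = _fold_seed(config.seed, 0.0 if np.isnan(step) else step, i)
        fold_config = TrainConfig(**{**config.__dict__, "seed": seed})
        model, _ = scg_train(train_df[FEATURE_COLUMNS].to_numpy(),
                             train_df["label"].tolist(), fold_config)
        scores = model.forward(test_df[FEATURE_COLUMNS].to_numpy())
        pred_pos = scores > threshold
        true_pos = (test_df["label"] == UNSUCCESSFUL).to_numpy()
        tp = int(np.sum(pred_pos & true_pos))
        fp = int(np.sum(pred_pos & ~true_pos))
        tn = int(np.sum(~pred_pos & ~true_pos))
        fn = int(np.sum(~pred_pos & true_pos))
        undefined = []
        if tp + fn == 0:
            undefined.append("sensitivity")
        if tn + fp == 0:
            undefined.append("specificity")
        results.append(FoldResult(subject_id=held, tp=tp, fp=fp, tn=tn, fn=fn,
                                  step_size=step, seed=seed,
                                  undefined=tuple(undefined)))
    return results


def sweep_table(folds_by_step: dict) -> pd.DataFrame:
    """Tidy table: one row per (step size, held-out subject)."""
    rows = []
    for step, folds in sorted(folds_by_step.items()):
        for f in folds:
            rows.append({"step_size": step, "subject": f.subject_id,
                         "tp": f.tp, "fp": f.fp, "tn": f.tn, "fn": f.fn,
                         "sensitivity": f.sensitivity,
                         "specificity": f.specificity,
                         "balanced_accuracy": f.balanced_accuracy,
                         "undefined": ",".join(f.undefined)})
    return pd.DataFrame(rows)


def select_step(folds_by_step: dict) -> float:
    """Operating step: maximal mean balanced accuracy (ties -> smaller step)."""
    best_step, best_score = None, -np.inf
    for step in sorted(folds_by_step):
        score = np.nanmean([f.balanced_accuracy for f in folds_by_step[step]])
        if score > best_score + 1e-12:
            best_step, best_score = step, score
    return best_step


def step_size_sweep(datasets_by_step: dict, config: TrainConfig = TrainConfig(),
                    threshold: float = 0.5):
    """Leave-one-out evaluation at every step size in the grid.

    ``datasets_by_step`` maps step size (mm) to a labeled feature table.
    Returns ``(folds_by_step, table, selected_step)``.
    """
    folds_by_step = {float(s): leave_one_out(df, config, threshold)
                     for s, df in datasets_by_step.items()}
    return folds_by_step, sweep_table(folds_by_step), select_step(folds_by_step)


def plot_feature_scatter(dataset: pd.DataFrame, path) -> None:
    """DO and MS scatter plots, successes vs failures (one step size)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    fail = dataset["label"] == UNSUCCESSFUL
    for ax, (x, y) in zip(axes, [("do_trans", "do_rot"), ("ms_trans", "ms_rot")]):
        ax.plot(dataset.loc[~fail, x], dataset.loc[~fail, y], "o", ms=4,
                mfc="none", color="tab:blue", label="successful")
        ax.plot(dataset.loc[fail, x], dataset.loc[fail, y], "x", ms=5,
                color="tab:red", label="unsuccessful")
        ax.set_xlabel(x)
        ax.set_ylabel(y)
    axes[0].legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sweep(table: pd.DataFrame, path) -> None:
    """Sensitivity and specificity per held-out subject vs step size."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True, sharey=True)
    for ax, metric in zip(axes, ["sensitivity", "specificity"]):
        for subject, g in table.groupby("subject"):
            ax.plot(g["step_size"], g[metric], "o-", ms=4, label=subject)
        ax.set_xlabel("step size (mm)")
        ax.set_ylabel(metric)
        ax.set_ylim(-0.02, 1.02)
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
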