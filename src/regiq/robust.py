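"""The integrated robust registration loop and its acceptance bookkeeping.

A registration attempt is run from a random initial pose; the trained
quality evaluator scores the solution's cost-profile features, and a score
above the threshold rejects the solution and triggers a fresh attempt from a
new random start, up to ``max_trials`` (default 5).  Exhausting the budget
marks the case as a final rejection (in the clinic: falling back to manual
registration).

Two campaign-level efficiency figures summarize the loop:

* TAR (trial-to-acceptance ratio): total trials / accepted solutions —
  the computational overhead of the retry machinery;
* FAR (final acceptance ratio): accepted / (accepted + finally rejected)
  cases, as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from regiq.classifier import MlpModel, predict
from regiq.features import compute_features, sample_profiles
from regiq.geometry import RigidTransform
from regiq.mvd import NormalizationFactors
from regiq.register import (PerturbationRange, RegisterConfig,
                            RegistrationFailedError, random_inits, register)
from regiq.similarity import CostFunction

__all__ = ["CaseOutcome", "CampaignSummary", "robust_register", "summarize",
           "summarize_counts", "share_of_final_rejections"]


@dataclass
class CaseOutcome:
    """Result of the accept/reject loop on one registration case."""

    case_id: str
    n_trials: int
    accepted: bool
    final_pose: RigidTransform
    trial_scores: list
    trial_poses: list
    threshold: float = 0.5


@dataclass
class CampaignSummary:
    n_acceptances: int
    n_trials_total: int
    n_final_rejections: int

    @property
    def tar(self) -> float:
        """Trial-to-acceptance ratio: total trials / acceptances."""
        if self.n_acceptances == 0:
            return float("nan")
        return self.n_trials_total / self.n_acceptances

    @property
    def far_percent(self) -> float:
        """Final acceptance ratio: accepted / (accepted + finally rejected), %."""
        denom = self.n_acceptances + self.n_final_rejections
        if denom == 0:
            return float("nan")
        return 100.0 * self.n_acceptances / denom


def robust_register(volume, case, model: MlpModel, nf: NormalizationFactors,
                    step_size: float, max_trials: int = 5,
                    init_range: PerturbationRange = PerturbationRange(20.0, 8.0),
                    seed=0, config: RegisterConfig = RegisterConfig(),
                    n_per_side: int = 3, threshold: float = 0.5) -> CaseOutcome:
    """Register with quality gating: retry from fresh random starts until the
    evaluator accepts the solution or ``max_trials`` is exhausted.

    Retry initial poses are drawn within ``init_range`` around the
    isocenter-aligned pose, matching the distribution the evaluator was
    trained on.  A registration failure (degenerate cost at the start)
    counts as a rejected trial.  Deterministic per seed.
    """
    if max_trials < 1:
        raise ValueError("max_trials must be >= 1")
    # the gate must be able to score wherever the optimizer lands, so
    # zero-overlap DRR panels take the zero-information NMI limit (1.0)
    # rather than aborting the trial
    cost_fn = CostFunction(volume, case, bins=config.bins, step=config.ray_step,
                           degenerate_nmi=1.0)
    inits = random_inits(RigidTransform.identity(), init_range, max_trials, seed)
    scores, poses = [], []
    for trial, init in enumerate(inits, start=1):
        try:
            sol = register(volume, case, init, config, cost_fn=cost_fn)
            profiles = sample_profiles(volume, case, sol.pose, nf, step_size,
                                       n_per_side=n_per_side, cost_fn=cost_fn)
        except RegistrationFailedError:
            scores.append(float("inf"))
            poses.append(init)
            continue
        score = predict(model, compute_features(profiles))
        scores.append(score)
        poses.append(sol.pose)
        if score <= threshold:
            return CaseOutcome(case_id=case.case_id, n_trials=trial,
                               accepted=True, final_pose=sol.pose,
                               trial_scores=scores, trial_poses=poses,
                               threshold=threshold)
    return CaseOutcome(case_id=case.case_id, n_trials=max_trials, accepted=False,
                       final_pose=poses[-1], trial_scores=scores,
                       trial_poses=poses, threshold=threshold)


def summarize(outcomes) -> CampaignSummary:
    """Exact integer bookkeeping over a collection of case outcomes."""
    outcomes = list(outcomes)
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    n_acc = sum(1 for o in outcomes if o.accepted)
    n_trials = sum(o.n_trials for o in outcomes)
    n_rej = sum(1 for o in outcomes if not o.accepted)
    return CampaignSummary(n_acceptances=n_acc, n_trials_total=n_trials,
                           n_final_rejections=n_rej)


def summarize_counts(acceptances, trials, final_rejections) -> CampaignSummary:
    """Summary from per-group count tables (scalars or sequences)."""
    return CampaignSummary(
        n_acceptances=int(np.sum(acceptances)),
        n_trials_total=int(np.sum(trials)),
        n_final_rejections=int(np.sum(final_rejections)),
    )


def share_of_final_rejections(final_rejections, group_index: int) -> float:
    """One group's percentage share of all final rejections."""
    counts = np.asarray(final_rejections, dtype=float)
    total = counts.sum()
    if total == 0:
        return float("nan")
    return 100.0 * counts[group_index] / total
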