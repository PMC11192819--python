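"""Trial-level predictors of willingness-to-pay for the candidate models.

Three quantities can predict a trial's bid: the mean of the presented values
(the sequence's true value), the mean of the recalled values (intrusions
included, missing when nothing was recalled), and a temporal-difference (TD)
value — a recency-weighted running average of the presented values governed by
a learning rate alpha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .task import N_ITEMS, RecallSet, Sequence, TrialRecord


def presented_predictor(sequence: Sequence) -> float:
    """Arithmetic mean of the seven presented values."""
    return float(np.mean(sequence.values))


def recalled_predictor(recall: RecallSet) -> float:
    """Mean of all reported values, intrusions and duplicates included;
    ``nan`` when nothing was recalled."""
    if len(recall) == 0:
        return float("nan")
    return float(np.mean(recall.reports))


def td_value(sequence_values, alpha: float) -> float:
    """Temporal-difference value of a sequence after its last item.

    The estimate starts at the first presented value and is updated by
    ``V <- V + alpha * (x_t - V)`` for each subsequent item, yielding an
    exponentially recency-weighted average: alpha=0 returns the first value,
    alpha=1 the last.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    values = sequence_values.values if isinstance(sequence_values, Sequence) else sequence_values
    v = float(values[0])
    for x in values[1:]:
        v += alpha * (float(x) - v)
    return v


def td_weights(alpha, n_items: int = N_ITEMS) -> np.ndarray:
    """Closed-form item weights of the TD value.

    ``w_1 = (1-alpha)^(n-1)`` and ``w_t = alpha * (1-alpha)^(n-t)`` for
    ``t >= 2``; the weights sum to one, so the TD value is the corresponding
    weighted mean of the presented values.  ``alpha`` may be an array, giving
    one weight row per learning rate.
    """
    a = np.atleast_1d(np.asarray(alpha, dtype=float))
    t = np.arange(1, n_items + 1)
    w = a[:, None] * (1.0 - a[:, None]) ** (n_items - t)[None, :]
    w[:, 0] = (1.0 - a) ** (n_items - 1)
    return w if np.ndim(alpha) else w[0]


def build_design(records: list[TrialRecord], dropna: bool = True) -> pd.DataFrame:
    """One row per usable trial with the response and every model's predictor.

    So that marginal likelihoods are comparable across models, the same trial
    set is used for all of them: trials with an empty recall set (where the
    recalled-items predictor is undefined) are dropped for every model.  The
    raw stimulus columns x1..x7 are kept so the TD predictor can be recomputed
    inside the sampler as a function of alpha.
    """
    rows = []
    for r in records:
        if r.bid is None or np.isnan(r.bid):
            continue
        row = {
            "participant_id": r.participant_id,
            "trial_index": r.trial_index,
            "task_order": r.task_order,
            "bid": float(r.bid),
            "predictor_presented": presented_predictor(r.sequence),
            "predictor_recalled": recalled_predictor(r.recall),
        }
        for k, v in enumerate(r.sequence.values, start=1):
            row[f"x{k}"] = float(v)
        rows.append(row)
    design = pd.DataFrame(rows)
    if design.empty:
        raise ValueError("no bid-bearing trials: dataset unusable")
    if dropna:
        design = design.dropna(subset=["predictor_recalled"]).reset_index(drop=True)
        if design.empty:
            raise ValueError("every trial has an empty recall set: dataset unusable")
    return design
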