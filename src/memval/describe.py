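"""Pre-registered exclusions and behavioural summaries.

Participants are excluded when they completed fewer than 80% of the 32 trials,
recalled on average less than one item correctly per attempted recall trial,
or completed fewer than 80% of the evaluation trials; participants with any
bid outside the allowed 0-100 range are flagged for exclusion from the
evaluation analyses.  The joint model-comparison subset keeps only
participants who completed every trial.

Summaries: serial-position curves (mean proportion recalled per position, with
Morey-corrected within-subject standard errors) and per-participant RMSE of
the bid against the sequence's true value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import N_ITEMS, N_TRIALS, TrialRecord, to_frame

EXCLUSION_REASONS = ("incomplete_trials", "low_recall", "incomplete_eval")
COMPLETION_THRESHOLD = 0.8
BID_RANGE = (0.0, 100.0)


@dataclass
class ExclusionReport:
    excluded: dict = field(default_factory=dict)  # participant_id -> [reason, ...]
    flagged_bid_out_of_range: list = field(default_factory=list)
    n_total: int = 0
    n_included: int = 0
    n_complete_all_trials: int = 0

    @property
    def excluded_ids(self):
        return sorted(self.excluded)


def _as_frame(dataset) -> pd.DataFrame:
    if isinstance(dataset, pd.DataFrame):
        return dataset.copy()
    return to_frame(dataset)


def _reports_from_row(row) -> list[int]:
    raw = row["recalls"]
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    raw = str(raw)
    return [int(float(v)) for v in raw.split(";") if v != ""]


def _recall_attempted(row) -> bool:
    raw = row["recalls"]
    return not (raw is None or (isinstance(raw, float) and np.isnan(raw)))


def score_recall(trial) -> tuple[np.ndarray, int]:
    """Score one trial's recall against its presented values.

    Each report is greedily matched to the earliest not-yet-matched presented
    position holding that value; matched positions count as correct, unmatched
    reports (including duplicates beyond the available tokens) as intrusions.

    Returns ``(correct, n_intrusions)`` with ``correct`` a length-7 boolean
    vector.
    """
    if isinstance(trial, TrialRecord):
        values = list(trial.sequence.values)
        reports = list(trial.recall.reports)
    else:
        values = [int(trial[f"v{k}"]) for k in range(1, N_ITEMS + 1)]
        reports = _reports_from_row(trial)
    correct = np.zeros(N_ITEMS, dtype=bool)
    intrusions = 0
    for rep in reports:
        for pos, v in enumerate(values):
            if v == rep and not correct[pos]:
                correct[pos] = True
                break
        else:
            intrusions += 1
    return correct, intrusions


def apply_exclusions(dataset) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the pre-registered filters to a long-format trial table.

    A trial counts as completed when both its bid and its recall field are
    present.  All filters are computed from the raw table, so the exclusion
    set does not depend on the order of application.  Returns the cleaned
    table (excluded participants removed; bid-range-flagged participants kept
    but listed in the report) and the :class:`ExclusionReport`.
    """
    df = _as_frame(dataset)
    report = ExclusionReport(n_total=df["participant_id"].nunique())

    for pid, grp in df.groupby("participant_id"):
        reasons = []
        bid_ok = grp["bid"].notna()
        recall_ok = grp.apply(_recall_attempted, axis=1)
        n_completed = int((bid_ok & recall_ok).sum())
        if n_completed < COMPLETION_THRESHOLD * N_TRIALS:
            reasons.append("incomplete_trials")

        attempted = grp[recall_ok]
        if len(attempted):
            n_correct = attempted.apply(lambda r: int(score_recall(r)[0].sum()), axis=1)
            if n_correct.mean() < 1.0:
                reasons.append("low_recall")
        else:
            reasons.append("low_recall")

        if int(bid_ok.sum()) < COMPLETION_THRESHOLD * N_TRIALS:
            reasons.append("incomplete_eval")

        bids = grp.loc[bid_ok, "bid"]
        if ((bids < BID_RANGE[0]) | (bids > BID_RANGE[1])).any():
            report.flagged_bid_out_of_range.append(pid)

        if reasons:
            report.excluded[pid] = reasons

    clean = df[~df["participant_id"].isin(report.excluded)].reset_index(drop=True)
    report.n_included = clean["participant_id"].nunique()

    complete = [
        pid
        for pid, grp in clean.groupby("participant_id")
        if int((grp["bid"].notna() & grp.apply(_recall_attempted, axis=1)).sum()) == N_TRIALS
    ]
    report.n_complete_all_trials = len(complete)
    return clean, report


def complete_trials_subset(clean: pd.DataFrame) -> pd.DataFrame:
    """Participants who completed all 32 trials (joint model-comparison set)."""
    keep = [
        pid
        for pid, grp in clean.groupby("participant_id")
        if int((grp["bid"].notna() & grp.apply(_recall_attempted, axis=1)).sum()) == N_TRIALS
    ]
    return clean[clean["participant_id"].isin(keep)].reset_index(drop=True)


def evaluation_subset(clean: pd.DataFrame, report: ExclusionReport) -> pd.DataFrame:
    """Drop participants flagged for out-of-range bids (evaluation analyses)."""
    return clean[~clean["participant_id"].isin(report.flagged_bid_out_of_range)].reset_index(
        drop=True
    )


def spc(dataset, task_order: str | None = None) -> pd.DataFrame:
    """Serial-position curve: per-position mean proportion recalled with the
    Cousineau-Morey within-subject SEM.

    Participant-level position scores are centred (participant mean replaced
    by the grand mean) before the between-participant SEM is taken, and the
    result is inflated by the Morey factor ``sqrt(K / (K - 1))`` for K=7
    positions.
    """
    df = _as_frame(dataset)
    if task_order is not None:
        df = df[df["task_order"] == task_order]
    df = df[df.apply(_recall_attempted, axis=1)]

    per_participant = []
    for pid, grp in df.groupby("participant_id"):
        scores = np.stack([score_recall(row)[0] for _, row in grp.iterrows()])
        per_participant.append(scores.mean(axis=0))
    P = np.stack(per_participant)  # (J, 7)
    if len(P) < 2:
        raise ValueError("within-subject SEM needs at least 2 participants")

    centered = P - P.mean(axis=1, keepdims=True) + P.mean()
    morey = np.sqrt(N_ITEMS / (N_ITEMS - 1))
    sem = centered.std(axis=0, ddof=1) / np.sqrt(len(P)) * morey
    return pd.DataFrame(
        {
            "position": np.arange(1, N_ITEMS + 1),
            "prop_recalled": P.mean(axis=0),
            "sem": sem,
        }
    )


def wtp_rmse(dataset, by_order: bool = False) -> pd.DataFrame:
    """Per-participant root-mean-square error of bids against true values."""
    df = _as_frame(dataset)
    df = df[df["bid"].notna()].copy()
    values = df[[f"v{k}" for k in range(1, N_ITEMS + 1)]].to_numpy(dtype=float)
    df["true_value"] = values.mean(axis=1)
    df["sqerr"] = (df["bid"] - df["true_value"]) ** 2
    keys = ["participant_id"] + (["task_order"] if by_order else [])
    out = df.groupby(keys)["sqerr"].mean().pow(0.5).rename("rmse").reset_index()
    return out


# ---------------------------------------------------------------------------
# figures


def plot_spc(dataset, path=None):
    """Serial-position curves per task order with within-subject error bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for order, marker in [("RE", "o"), ("ER", "s")]:
        curve = spc(dataset, task_order=order)
        ax.errorbar(
            curve["position"], curve["prop_recalled"], yerr=curve["sem"],
            marker=marker, capsize=3, label=order,
        )
    ax.set_xlabel("Serial position")
    ax.set_ylabel("Proportion recalled")
    ax.set_ylim(0, 1)
    ax.legend(title="Task order")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_wtp_rmse(dataset, path=None):
    """Mean WTP accuracy (RMSE, GC) per task order with between-subject SEM."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rmse = wtp_rmse(dataset, by_order=True)
    agg = rmse.groupby("task_order")["rmse"].agg(["mean", "sem"])
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(agg.index, agg["mean"], yerr=agg["sem"], capsize=4)
    ax.set_ylabel("WTP RMSE (GC)")
    ax.set_xlabel("Task order")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
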