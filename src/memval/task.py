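"""Synthetic number-sequence / free-recall / willingness-to-pay experiments.

Each trial shows seven two-digit Galactic Credit (GC) values drawn from a
per-sequence uniform distribution, elicits free recall and a bid for another
draw from the sequence, and resolves the bid with a Becker-DeGroot-Marschak
(BDM) auction.  The generator produces long-format trial tables with the
statistical structure the downstream model comparison assumes: serial-position
structured recall (primacy, recency, reduced recency under delayed recall) and
bids generated by one of the candidate evaluation models plus participant
intercepts and Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: fictitious-currency conversion used for participant bonuses
GC_PER_POUND = 200

#: endowment handed out on every auction trial, in GC
ENDOWMENT = 100.0

#: bounds of the per-sequence mean distribution (uniform over integers)
MEAN_LO, MEAN_HI = 40, 70

#: half-width of each sequence's generating distribution
HALF_RANGE = 29

N_ITEMS = 7
N_TRIALS = 32

MODEL_IDS = ("recalled", "presented", "both", "td")
TASK_ORDERS = ("RE", "ER")  # recall-first / evaluation-first


@dataclass(frozen=True)
class Sequence:
    """Seven stimulus values plus their generating distribution.

    ``dist_mean`` is drawn uniformly from the integers 40..70 and the seven
    values uniformly (with replacement) from ``dist_mean ± 29``, so every
    stimulus is a two-digit number in [11, 99] and every sequence distribution
    spans exactly 58 GC.  ``true_value`` is the arithmetic mean of the values,
    which is also the sequence's currency value in the auction.
    """

    values: tuple[int, ...]
    dist_mean: int
    true_value: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if len(self.values) != N_ITEMS:
            raise ValueError(f"a sequence holds exactly {N_ITEMS} values")
        if self.true_value is None:
            object.__setattr__(self, "true_value", float(np.mean(self.values)))

    @property
    def dist_lo(self) -> int:
        return self.dist_mean - HALF_RANGE

    @property
    def dist_hi(self) -> int:
        return self.dist_mean + HALF_RANGE


@dataclass(frozen=True)
class RecallSet:
    """Recalled values in output order; intrusions (values never shown) allowed."""

    reports: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.reports)


@dataclass(frozen=True)
class TrialRecord:
    participant_id: int
    trial_index: int  # 1..32
    task_order: str  # "RE" or "ER"
    sequence: Sequence
    recall: RecallSet
    bid: float
    selling_price: float
    earnings: float


@dataclass(frozen=True)
class SpcParams:
    """Serial-position recall profile for the recall simulator.

    ``p_recall`` gives the per-position recall probability for immediate
    (recall-first) trials; under evaluation-first order the last two positions
    are attenuated by ``recency_attenuation_ER``, emulating the loss of recency
    with delayed recall.  Intrusions are Poisson with mean ``intrusion_rate``
    per trial, drawn from the sequence's generating range but excluding
    presented values.  Total outputs are capped at ``max_outputs`` (standing in
    for the bounded response window of the task).
    """

    p_recall: tuple[float, ...] = (0.75, 0.60, 0.50, 0.45, 0.45, 0.55, 0.70)
    recency_attenuation_ER: float = 0.6
    intrusion_rate: float = 0.3
    max_outputs: int = 8

    def __post_init__(self):
        p = np.asarray(self.p_recall, dtype=float)
        if p.shape != (N_ITEMS,) or np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"p_recall must be {N_ITEMS} probabilities in [0, 1]")
        if not 0.0 <= self.recency_attenuation_ER <= 1.0:
            raise ValueError("recency_attenuation_ER must lie in [0, 1]")
        if self.intrusion_rate < 0:
            raise ValueError("intrusion_rate must be non-negative")


@dataclass(frozen=True)
class GenerativeModelParams:
    """Parameters of a bid-generating evaluation model.

    ``bid = b0 + u_j + <linear term in the model's predictor(s)> + eps`` with
    ``u_j ~ N(0, tau)`` per participant and ``eps ~ N(0, sigma)`` per trial,
    clipped to the response range [0, 100].
    """

    model_id: str = "presented"
    b0: float = 3.5
    tau: float = 3.0
    beta_recall: float = 0.541
    beta_presented: float = 0.936
    alpha: float = 0.6
    sigma: float = 3.0

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"model_id must be one of {MODEL_IDS}")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def default_generator_params(model_id: str) -> GenerativeModelParams:
    """Default generating parameters per model, intercepts placed so that mean
    bids sit mid-scale given the fitted slopes."""
    presets = {
        "recalled": dict(b0=25.2, beta_recall=0.541),
        "presented": dict(b0=3.5, beta_presented=0.936),
        "both": dict(b0=2.75, beta_recall=0.41, beta_presented=0.54),
        "td": dict(b0=5.5, beta_presented=0.9, alpha=0.6),
    }
    return GenerativeModelParams(model_id=model_id, **presets[model_id])


def generate_sequence(rng: np.random.Generator) -> Sequence:
    """Draw one stimulus sequence: integer mean uniform on {40..70}, then seven
    values uniform with replacement on {mean-29..mean+29}."""
    dist_mean = int(rng.integers(MEAN_LO, MEAN_HI + 1))
    values = rng.integers(dist_mean - HALF_RANGE, dist_mean + HALF_RANGE + 1, size=N_ITEMS)
    return Sequence(values=tuple(int(v) for v in values), dist_mean=dist_mean)


def simulate_recall(
    sequence: Sequence,
    spc: SpcParams,
    order: str,
    rng: np.random.Generator,
) -> RecallSet:
    """Simulate one free-recall report from a serial-position profile.

    Each position is recalled independently with its ``p_recall`` probability
    (last two positions attenuated under ER order); Poisson intrusions are
    drawn uniformly from the sequence's generating range excluding presented
    values; output order is randomized and capped at ``spc.max_outputs``.
    """
    if order not in TASK_ORDERS:
        raise ValueError(f"order must be one of {TASK_ORDERS}")
    p = np.asarray(spc.p_recall, dtype=float).copy()
    if order == "ER":
        p[-2:] *= spc.recency_attenuation_ER
    recalled_positions = np.flatnonzero(rng.random(N_ITEMS) < p)
    outputs = [sequence.values[i] for i in recalled_positions]

    n_intrusions = rng.poisson(spc.intrusion_rate)
    candidates = np.setdiff1d(
        np.arange(sequence.dist_lo, sequence.dist_hi + 1), np.asarray(sequence.values)
    )
    if n_intrusions > 0 and candidates.size > 0:
        n_intrusions = min(n_intrusions, candidates.size)
        outputs.extend(int(v) for v in rng.choice(candidates, size=n_intrusions, replace=False))

    outputs = [outputs[i] for i in rng.permutation(len(outputs))]
    return RecallSet(reports=tuple(outputs[: spc.max_outputs]))


def simulate_bid(
    sequence: Sequence,
    recall: RecallSet,
    params: GenerativeModelParams,
    participant_intercept: float,
    rng: np.random.Generator,
) -> float:
    """Generate a bid from one of the candidate evaluation models.

    Raises ``ValueError`` for recall-dependent models on an empty recall set
    (the caller regenerates the trial).
    """
    from .design import presented_predictor, recalled_predictor, td_value

    mu = params.b0 + participant_intercept
    if params.model_id in ("recalled", "both"):
        if len(recall) == 0:
            raise ValueError("recall-dependent bid generator needs a non-empty recall set")
        mu += params.beta_recall * recalled_predictor(recall)
    if params.model_id in ("presented", "both"):
        mu += params.beta_presented * presented_predictor(sequence)
    if params.model_id == "td":
        mu += params.beta_presented * td_value(sequence, params.alpha)
    bid = mu + params.sigma * rng.standard_normal()
    return float(np.clip(bid, 0.0, ENDOWMENT))


def draw_selling_price(rng: np.random.Generator) -> float:
    """Selling price ~ continuous Uniform(40, 70), the range of sequence means."""
    return float(rng.uniform(MEAN_LO, MEAN_HI))


def bdm_payoff(
    bid: float,
    selling_price: float,
    sequence_true_value: float,
    endowment: float = ENDOWMENT,
) -> float:
    """BDM auction earnings for one trial.

    Below the selling price the participant keeps the endowment; at or above
    it they buy the sequence at the selling price and additionally receive the
    sequence's currency value (its mean).  Under this rule expected earnings
    are maximized by bidding the believed true value.
    """
    if not 0.0 <= bid <= endowment:
        raise ValueError(f"bid {bid} outside the allowed range [0, {endowment}]")
    if bid < selling_price:
        return float(endowment)
    return float(endowment - selling_price + sequence_true_value)


def generate_dataset(
    n_participants: int,
    gen_params: GenerativeModelParams | None = None,
    spc: SpcParams | None = None,
    seed: int | np.random.Generator = 0,
) -> list[TrialRecord]:
    """Simulate a full experiment: 32 trials per participant, 16 per task order
    in a random balanced order, fully determined by ``seed``."""
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    gen_params = gen_params or GenerativeModelParams()
    spc = spc or SpcParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    records: list[TrialRecord] = []
    for j in range(1, n_participants + 1):
        u_j = gen_params.tau * rng.standard_normal()
        orders = np.array(["RE"] * (N_TRIALS // 2) + ["ER"] * (N_TRIALS // 2))
        orders = orders[rng.permutation(N_TRIALS)]
        for t in range(1, N_TRIALS + 1):
            order = str(orders[t - 1])
            # recall-dependent generators need >=1 recalled item; regenerate the
            # trial's recall/noise if the simulated report comes back empty
            for _ in range(1000):
                sequence = generate_sequence(rng)
                recall = simulate_recall(sequence, spc, order, rng)
                try:
                    bid = simulate_bid(sequence, recall, gen_params, u_j, rng)
                except ValueError:
                    continue
                break
            else:  # pragma: no cover - would need pathological SpcParams
                raise RuntimeError("could not generate a usable trial in 1000 attempts")
            price = draw_selling_price(rng)
            earnings = bdm_payoff(bid, price, sequence.true_value)
            records.append(
                TrialRecord(
                    participant_id=j,
                    trial_index=t,
                    task_order=order,
                    sequence=sequence,
                    recall=recall,
                    bid=bid,
                    selling_price=price,
                    earnings=earnings,
                )
            )
    return records


# ---------------------------------------------------------------------------
# long-format trial table I/O


def to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Long-format trial table: one row per trial, stimulus values in v1..v7,
    recalls as a semicolon-delimited string in output order."""
    rows = []
    for r in records:
        row = {
            "participant_id": r.participant_id,
            "trial_index": r.trial_index,
            "task_order": r.task_order,
        }
        for k, v in enumerate(r.sequence.values, start=1):
            row[f"v{k}"] = v
        row["recalls"] = ";".join(str(v) for v in r.recall.reports)
        row["bid"] = r.bid
        row["selling_price"] = r.selling_price
        row["earnings"] = r.earnings
        rows.append(row)
    return pd.DataFrame(rows)


def from_frame(df: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for _, row in df.iterrows():
        values = tuple(int(row[f"v{k}"]) for k in range(1, N_ITEMS + 1))
        seq = Sequence(values=values, dist_mean=int(round(np.mean(values))))
        raw = row.get("recalls", "")
        raw = "" if (raw is None or (isinstance(raw, float) and np.isnan(raw))) else str(raw)
        reports = tuple(int(float(v)) for v in raw.split(";") if v != "")
        records.append(
            TrialRecord(
                participant_id=int(row["participant_id"]),
                trial_index=int(row["trial_index"]),
                task_order=str(row["task_order"]),
                sequence=seq,
                recall=RecallSet(reports=reports),
                bid=float(row["bid"]),
                selling_price=float(row.get("selling_price", np.nan)),
                earnings=float(row.get("earnings", np.nan)),
            )
        )
    return records


def write_csv(records: list[TrialRecord], path) -> None:
    to_frame(records).to_csv(path, index=False)


def read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"recalls": "string"})
    df["recalls"] = df["recalls"].fillna("")
    return df


def sequence_from_row(row) -> Sequence:
    """Rebuild the Sequence for a trial-table row; the generating mean is not
    stored in the table, so it is reconstructed as the rounded sample mean
    (used only for bookkeeping, never by the evaluation models)."""
    values = tuple(int(row[f"v{k}"]) for k in range(1, N_ITEMS + 1))
    return Sequence(values=values, dist_mean=int(round(np.mean(values))))
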