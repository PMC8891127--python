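"""Outcome measures and schedule arithmetic for the classification task.

The listening experiment is a 6-alternative forced choice: on each trial
a listener hears one sonified STS pattern (rendered with one of the six
parameter combinations) and names the pattern.  This module provides the
outcome measures — accuracy (% correct), per-class precision/recall/
F-score, confusion matrices — and the Latin-square trial schedule builder
(6 blocks x 6 patterns x 3 repetitions = 108 trials per participant),
usable on any response log with the TrialRecord columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import COMBOS
from .simulate import PATTERN_IDS

TRIAL_COLUMNS = ("participant", "block", "combo", "true_pattern",
                 "predicted_pattern", "confidence", "response_time")


@dataclass
class TrialRecord:
    participant: int
    block: int
    combo: str
    true_pattern: str
    predicted_pattern: str
    confidence: int = 50
    response_time: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.confidence <= 100):
            raise ValueError("confidence must lie in [0, 100]")
        if self.response_time <= 0:
            raise ValueError("response_time must be positive")


def records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])


def accuracy_percent(records) -> float:
    """Percentage of correct responses: correct / total x 100."""
    df = records_to_frame(records)
    if len(df) == 0:
        raise ValueError("no records")
    correct = (df["true_pattern"] == df["predicted_pattern"]).sum()
    return 100.0 * correct / len(df)


def confusion_matrix(records, classes=PATTERN_IDS) -> pd.DataFrame:
    """6x6 count matrix; rows = true class, columns = predicted class."""
    df = records_to_frame(records)
    cm = pd.DataFrame(0, index=list(classes), columns=list(classes),
                      dtype=int)
    grouped = df.groupby(["true_pattern", "predicted_pattern"]).size()
    for (t, p), n in grouped.items():
        cm.loc[t, p] = n
    return cm


def f_score(cm: pd.DataFrame, cls: str) -> tuple:
    """(precision, recall, F) for one class of a confusion matrix.

    F = 2PR/(P+R), with the guarded convention F = 0 when P + R = 0.
    """
    if cm.loc[cls].sum() < 1:
        raise ValueError(f"class {cls} has no true instances")
    tp = cm.loc[cls, cls]
    fp = cm[cls].sum() - tp
    fn = cm.loc[cls].sum() - tp
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn)
    f = (2 * precision * recall / (precision + recall)
         if (precision + recall) > 0 else 0.0)
    return float(precision), float(recall), float(f)


def f_score_table(records, by: str = "combo") -> pd.DataFrame:
    """Per-(pattern, group) F-scores, mirroring a heatmap layout."""
    df = records_to_frame(records)
    rows = {}
    for key, sub in df.groupby(by):
        cm = confusion_matrix(sub)
        rows[key] = {
            cls: f_score(cm, cls)[2]
            for cls in PATTERN_IDS if cm.loc[cls].sum() > 0
        }
    return pd.DataFrame(rows)


def _latin_square(items, row: int):
    """Row of the standard cyclic Latin square over ``items``."""
    n = len(items)
    return [items[(row + j) % n] for j in range(n)]


def _pattern_order(patterns, reps: int, rng: np.random.Generator,
                   max_tries: int = 1000):
    """Random order with each pattern ``reps`` times, no two consecutive
    trials sharing a pattern."""
    pool = list(patterns) * reps
    for _ in range(max_tries):
        order = list(rng.permutation(pool))
        if all(a != b for a, b in zip(order, order[1:])):
            return order
    raise RuntimeError("could not satisfy the non-identical-consecutive "
                       "constraint; check counts")


def build_schedule(participant: int = 0, combos=COMBOS,
                   patterns=PATTERN_IDS, reps: int = 3,
                   seed: int = 0) -> pd.DataFrame:
    """Testing-phase schedule for one participant.

    Block order follows the cyclic Latin-square row selected by the
    participant index (counterbalancing combos across participants);
    within each block, every pattern appears exactly ``reps`` times with
    no two consecutive trials sharing a pattern.  The default design
    yields 6 x 6 x 3 = 108 trials.
    """
    if reps < 1 or len(patterns) < 2:
        raise ValueError("need reps >= 1 and at least two patterns")
    rng = np.random.default_rng(np.random.SeedSequence([seed, participant]))
    block_combos = _latin_square(list(combos), participant % len(combos))
    rows = []
    for b, combo in enumerate(block_combos, start=1):
        for pat in _pattern_order(patterns, reps, rng):
            rows.append(
                {"participant": participant, "block": b, "combo": combo,
                 "true_pattern": pat}
            )
    return pd.DataFrame(rows)


def simulate_responses(schedule: pd.DataFrame, strategy: str = "uniform",
                       seed: int = 0, classes=PATTERN_IDS) -> pd.DataFrame:
    """Attach simulated predictions to a schedule.

    ``uniform`` draws uniformly over the six classes (chance-level
    responder); ``ideal`` always answers the true pattern.
    """
    rng = np.random.default_rng(seed)
    df = schedule.copy()
    if strategy == "uniform":
        df["predicted_pattern"] = rng.choice(list(classes), size=len(df))
    elif strategy == "ideal":
        df["predicted_pattern"] = df["true_pattern"]
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    df["confidence"] = 50
    df["response_time"] = 1.0
    return df
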