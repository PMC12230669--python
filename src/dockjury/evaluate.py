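"""Assessor-style evaluation of quality predictions against observed scores.

Given per-model predicted and observed quality values (and optionally
per-residue tracks), this module computes the standard assessor
statistics — Pearson and Spearman correlations, ROC AUC of local
interface scoring, and the top-1 selection loss — and combines them into
three composite totals:

* LOCAL_TOTAL  = sum over {PatchDockQ, PatchQS, CAD, lDDT} of
                 0.5*Pearson + 0.5*Spearman + AUC            (max 8)
* QSCORE_TOTAL = sum over {DockQ-wave, QS} of
                 0.5*Pearson + 0.5*Spearman + AUC + (1-Loss) (max 6)
* SCORE_TOTAL  = sum over {GDT_TS, TM} of the same four terms (max 6)

Loss is the observed quality of the best available model minus that of
the model the predictor ranked first.  The AUC is computed by explicit
pair counting after binarizing the observed track at a threshold
(default 0.5): AUC = P(pred_pos > pred_neg) + 0.5 * P(tie).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ConfigError
from .structure import LocalScoreTrack

LOCAL_TOTAL_METRICS = ("PatchDockQ", "PatchQS", "CAD", "lDDT")
QSCORE_TOTAL_METRICS = ("DockQ-wave", "QS")
SCORE_TOTAL_METRICS = ("GDT_TS", "TM")


@dataclass
class EvalPair:
    predicted: list[float]
    observed: list[float]

    def __post_init__(self):
        if len(self.predicted) != len(self.observed):
            raise ConfigError("predicted and observed lengths differ")


@dataclass
class CompositeTotal:
    name: str
    value: float
    breakdown: dict = field(default_factory=dict)


def correlations(e: EvalPair) -> tuple[float | None, float | None]:
    """(Pearson, Spearman with average-rank ties); None if zero variance."""
    pred = np.asarray(e.predicted, dtype=float)
    obs = np.asarray(e.observed, dtype=float)
    if len(pred) < 2 or np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return None, None
    pearson = float(stats.pearsonr(pred, obs).statistic)
    spearman = float(stats.spearmanr(pred, obs).statistic)
    return pearson, spearman


def _track_values(predicted, observed):
    if isinstance(predicted, LocalScoreTrack):
        keys = [
            k
            for k in predicted
            if predicted.get(k) is not None
            and isinstance(observed, LocalScoreTrack)
            and observed.get(k) is not None
        ]
        pred = np.array([predicted[k] for k in keys], dtype=float)
        obs = np.array([observed[k] for k in keys], dtype=float)
        return pred, obs
    return (
        np.asarray(predicted, dtype=float),
        np.asarray(observed, dtype=float),
    )


def auc(predicted, observed, binarize_at: float = 0.5) -> float | None:
    """ROC AUC by pair counting; observed binarized at ``binarize_at``.

    Accepts LocalScoreTracks (UNSCORED residues in either track are
    excluded) or plain sequences.  Returns None when only one class
    remains after binarization.
    """
    pred, obs = _track_values(predicted, observed)
    labels = obs >= binarize_at
    pos = pred[labels]
    neg = pred[~labels]
    if len(pos) == 0 or len(neg) == 0:
        return None
    diffs = pos[:, None] - neg[None, :]
    wins = np.count_nonzero(diffs > 0)
    ties = np.count_nonzero(diffs == 0)
    return float((wins + 0.5 * ties) / (len(pos) * len(neg)))


def loss(e: EvalPair) -> float:
    """Observed quality gap between best and predictor-selected model.

    Predicted ties resolve to the first index.
    """
    pred = np.asarray(e.predicted, dtype=float)
    obs = np.asarray(e.observed, dtype=float)
    if len(pred) == 0:
        raise ConfigError("loss needs at least one model")
    selected = int(np.argmax(pred))  # argmax returns the first maximum
    return float(obs.max() - obs[selected])


@dataclass
class MetricEval:
    """Assessor terms for one observed metric."""

    pearson: float | None = None
    spearman: float | None = None
    auc: float | None = None
    loss: float | None = None


def evaluate_metric(
    e: EvalPair,
    predicted_track=None,
    observed_track=None,
    binarize_at: float = 0.5,
    with_loss: bool = True,
) -> MetricEval:
    """All assessor terms for one metric from global (and local) data."""
    p, s = correlations(e)
    if predicted_track is not None and observed_track is not None:
        a = auc(predicted_track, observed_track, binarize_at)
    else:
        a = auc(e.predicted, e.observed, binarize_at)
    return MetricEval(p, s, a, loss(e) if with_loss else None)


def _term(ev: MetricEval, with_loss: bool) -> tuple[float, dict]:
    pearson = ev.pearson if ev.pearson is not None else 0.0
    spearman = ev.spearman if ev.spearman is not None else 0.0
    aucv = ev.auc if ev.auc is not None else 0.0
    parts = {
        "0.5*Pearson": 0.5 * pearson,
        "0.5*Spearman": 0.5 * spearman,
        "AUC": aucv,
    }
    if with_loss:
        lossv = ev.loss if ev.loss is not None else 0.0
        parts["1-Loss"] = 1.0 - lossv
    return sum(parts.values()), parts


def composite_totals(
    evals: dict[str, MetricEval], strict: bool = True
) -> dict[str, CompositeTotal]:
    """The three assessor composite totals from per-metric terms.

    ``evals`` maps metric names to their MetricEval; each total requires
    its full metric set and raises ConfigError naming absent components
    (unless ``strict=False``, in which case absent metrics simply drop
    their term).
    """
    totals = {}
    for name, metrics, with_loss in (
        ("LOCAL_TOTAL", LOCAL_TOTAL_METRICS, False),
        ("QSCORE_TOTAL", QSCORE_TOTAL_METRICS, True),
        ("SCORE_TOTAL", SCORE_TOTAL_METRICS, True),
    ):
        missing = [m for m in metrics if m not in evals]
        if missing and strict:
            raise ConfigError(
                f"{name} missing components: {', '.join(missing)}"
            )
        metrics = [m for m in metrics if m in evals]
        value = 0.0
        breakdown = {}
        for m in metrics:
            term, parts = _term(evals[m], with_loss)
            value += term
            breakdown[m] = parts
        totals[name] = CompositeTotal(name, value, breakdown)
    return totals
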