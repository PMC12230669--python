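"""Consensus ("jury") quality estimation over a pool of assembly models.

The idea: without a native structure, a model's quality can be estimated
by how structurally similar it is to the other models of the same target
— each pool member takes a turn as a pseudo-reference, and a model's
jury score for a metric is the aggregate (mean, or mean of top-k) of
that metric over all its comparisons.  Eight jury metrics are computed
(QS-best, DockQ-wave, TM, oligo-GDT, lDDT, CAD, PatchQS, PatchDockQ);
four of them also yield per-residue jury tracks (lDDT, CAD, PatchQS,
PatchDockQ) whose unweighted mean is the combined local score.

Three variants mirror common server modes:

* D2  — globals are weighted means of jury scores (linear combination);
* D2R — globals are mean reciprocal ranks across metrics (rank-optimized);
* D2S — a single model scored against an external reference pool, with
        the combined local track computed directly as the mean of the
        four local jury tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import group_chains, map_chains
from .errors import ConfigError, MappingError
from .global_scores import lddt
from .interface_scores import (
    cad_score,
    dockq_wave,
    patch_scores,
    qs_score,
)
from .structure import LocalScoreTrack, Structure

ALL_METRICS = (
    "QSbest", "DockQwave", "TM", "OligoGDT", "lDDT", "CAD",
    "PatchQS", "PatchDockQ",
)
ASSEMBLY_METRICS = ("lDDT", "TM", "OligoGDT", "CAD")
INTERFACE_METRICS = ("QSbest", "DockQwave", "PatchQS", "PatchDockQ")
LOCAL_METRICS = ("lDDT", "CAD", "PatchQS", "PatchDockQ")


@dataclass
class JuryConfig:
    metrics: tuple = ALL_METRICS
    aggregation: str = "mean"  # "mean" or "top-k"
    top_k: int = 3
    variant: str = "D2"  # D2 | D2R | D2S
    weights: dict | None = None  # per-metric weights; None = equal

    def __post_init__(self):
        if self.variant not in ("D2", "D2R", "D2S"):
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.aggregation not in ("mean", "top-k"):
            raise ConfigError(f"unknown aggregation {self.aggregation!r}")
        missing_a = [m for m in ASSEMBLY_METRICS if m not in self.metrics]
        missing_i = [m for m in INTERFACE_METRICS if m not in self.metrics]
        if missing_a or missing_i:
            raise ConfigError(
                "jury configuration missing required metrics: "
                + ", ".join(missing_a + missing_i)
            )
        if self.weights is not None:
            for m, w in self.weights.items():
                if w < 0:
                    raise ConfigError(f"negative weight for {m}")


@dataclass
class QAResult:
    label: str
    global_score: float | None  # assembly quality
    interface_score: float | None
    local_track: LocalScoreTrack = field(default_factory=LocalScoreTrack)
    per_metric: dict = field(default_factory=dict)
    rank: int = 0


@dataclass
class PairwiseScoreMatrix:
    metric: str
    values: np.ndarray  # n x n, NaN = undefined (diagonal, unmappable pairs)


# ---------------------------------------------------------------------------
# single pairwise comparison


def compare_pair(model: Structure, reference: Structure,
                 metrics=ALL_METRICS) -> dict:
    """All requested metrics of one model against one reference.

    Returns global values (None where UNSCORED) and, for the four local
    metrics, per-residue tracks keyed on model residues.  An unmappable
    pair yields all-None.
    """
    out: dict = {m: None for m in metrics}
    try:
        groups = group_chains(model, reference)
        mapping = map_chains(model, reference, groups)
    except MappingError:
        return out

    if "lDDT" in metrics:
        g, track = lddt(model, reference, mapping)
        out["lDDT"] = g.value
        out["lDDT_local"] = track
    if "TM" in metrics or "OligoGDT" in metrics:
        from .global_scores import GDT_CUTOFFS, mapped_ca_coords, superposition_scan

        P, Q, _ = mapped_ca_coords(model, reference, mapping)
        if len(P) >= 3:
            gdt_best, tm_best = superposition_scan(P, Q)
            if "TM" in metrics:
                out["TM"] = tm_best
            if "OligoGDT" in metrics:
                out["OligoGDT"] = float(
                    np.mean([gdt_best[c] / len(P) for c in GDT_CUTOFFS])
                )
    if "CAD" in metrics:
        g, track = cad_score(model, reference, mapping)
        out["CAD"] = g.value
        out["CAD_local"] = track
    if "QSbest" in metrics:
        qs = qs_score(model, reference, mapping)
        out["QSbest"] = qs.breakdown.get("QSbest")
        out["QSglobal"] = qs.breakdown.get("QSglobal")
    if "DockQwave" in metrics:
        out["DockQwave"] = dockq_wave(model, reference, mapping).value
    if "PatchQS" in metrics or "PatchDockQ" in metrics:
        tqs, tdq = patch_scores(model, reference, mapping)
        if "PatchQS" in metrics:
            out["PatchQS"] = tqs.mean()
            out["PatchQS_local"] = tqs
        if "PatchDockQ" in metrics:
            out["PatchDockQ"] = tdq.mean()
            out["PatchDockQ_local"] = tdq
    return out


# ---------------------------------------------------------------------------
# pairwise matrices


def pairwise_scores(pool: list[Structure], metrics=ALL_METRICS):
    """Score matrices over a model pool; entry (i, j) uses model_j as reference.

    Returns (matrices, local_tracks): matrices maps metric name to a
    PairwiseScoreMatrix; local_tracks maps metric name to a dict
    {(i, j): LocalScoreTrack on model_i residues}.
    """
    n = len(pool)
    if n < 2:
        raise ConfigError("pairwise jury needs a pool of at least 2 models")
    matrices = {m: np.full((n, n), np.nan) for m in metrics}
    local_tracks: dict = {m: {} for m in LOCAL_METRICS if m in metrics}
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            result = compare_pair(pool[i], pool[j], metrics)
            for m in metrics:
                v = result.get(m)
                if v is not None:
                    matrices[m][i, j] = v
                t = result.get(f"{m}_local")
                if m in local_tracks and t is not None:
                    local_tracks[m][(i, j)] = t
    return (
        {m: PairwiseScoreMatrix(m, matrices[m]) for m in metrics},
        local_tracks,
    )


def jury_global(matrix: PairwiseScoreMatrix, aggregation: str = "mean",
                top_k: int = 3) -> list[float | None]:
    """Per-model jury score: aggregate of the defined entries in each row."""
    out = []
    for row in matrix.values:
        vals = row[~np.isnan(row)]
        if len(vals) == 0:
            out.append(None)
        elif aggregation == "mean":
            out.append(float(vals.mean()))
        else:  # top-k mean
            k = min(top_k, len(vals))
            out.append(float(np.sort(vals)[::-1][:k].mean()))
    return out


def jury_local(pool: list[Structure], metric: str,
               local_tracks: dict | None = None) -> list[LocalScoreTrack]:
    """Per-model local jury track: mean over pseudo-references per residue."""
    if local_tracks is None:
        _, all_tracks = pairwise_scores(pool, metrics=(metric,))
        local_tracks = all_tracks[metric]
    n = len(pool)
    out = []
    for i in range(n):
        sums: dict = {}
        counts: dict = {}
        for j in range(n):
            if i == j or (i, j) not in local_tracks:
                continue
            for key, v in local_tracks[(i, j)].items():
                if v is None:
                    continue
                sums[key] = sums.get(key, 0.0) + v
                counts[key] = counts.get(key, 0) + 1
        track = LocalScoreTrack()
        for key in pool[i].residue_keys():
            track[key] = (
                sums[key] / counts[key] if counts.get(key) else None
            )
        out.append(track)
    return out


def combined_local_tracks(pool, local_tracks_by_metric) -> list[LocalScoreTrack]:
    """Unweighted mean of the four local jury tracks, per model."""
    per_metric = {
        m: jury_local(pool, m, local_tracks_by_metric[m])
        for m in local_tracks_by_metric
    }
    out = []
    for i, model in enumerate(pool):
        track = LocalScoreTrack()
        for key in model.residue_keys():
            vals = [
                per_metric[m][i].get(key)
                for m in per_metric
                if per_metric[m][i].get(key) is not None
            ]
            track[key] = float(np.mean(vals)) if vals else None
        out.append(track)
    return out


# ---------------------------------------------------------------------------
# variant combiners


def _weighted_mean(scores: dict, metrics, weights=None) -> float | None:
    vals, ws = [], []
    for m in metrics:
        v = scores.get(m)
        if v is None:
            continue
        vals.append(v)
        ws.append(1.0 if weights is None else weights.get(m, 1.0))
    if not vals or sum(ws) == 0:
        return None
    return float(np.average(vals, weights=ws))


def _competition_ranks(scores: list[float | None]) -> list[int]:
    """Rank 1 = best; ties share the best rank; None ranks last."""
    sentinel = [-np.inf if s is None else s for s in scores]
    return [1 + sum(1 for t in sentinel if t > s) for s in sentinel]


def combine_variant(
    jury_scores: dict[str, list[float | None]],
    local_tracks: list[LocalScoreTrack],
    cfg: JuryConfig,
    labels: list[str],
) -> list[QAResult]:
    """Combine per-metric jury scores into ranked QA results.

    D2: weighted means of the assembly and interface metric groups.
    D2R: mean reciprocal rank across each metric group, already in (0,1].
    The ranking is by global interface score, ties broken by assembly
    score and then by label.
    """
    for m in ASSEMBLY_METRICS + INTERFACE_METRICS:
        if m not in jury_scores:
            raise ConfigError(f"missing jury metric {m}")
    n = len(labels)
    results = []
    if cfg.variant in ("D2", "D2S"):
        for i in range(n):
            per_model = {m: jury_scores[m][i] for m in jury_scores}
            assembly = _weighted_mean(per_model, ASSEMBLY_METRICS, cfg.weights)
            interface = _weighted_mean(per_model, INTERFACE_METRICS, cfg.weights)
            results.append(
                QAResult(labels[i], assembly, interface,
                         local_tracks[i] if local_tracks else LocalScoreTrack(),
                         per_model)
            )
    else:  # D2R: mean reciprocal rank per metric group
        ranks = {m: _competition_ranks(jury_scores[m]) for m in jury_scores}
        for i in range(n):
            per_model = {m: jury_scores[m][i] for m in jury_scores}
            fully_unscored = all(per_model[m] is None for m in per_model)
            if fully_unscored:
                assembly = interface = None
            else:
                assembly = float(
                    np.mean([1.0 / ranks[m][i] for m in ASSEMBLY_METRICS])
                )
                interface = float(
                    np.mean([1.0 / ranks[m][i] for m in INTERFACE_METRICS])
                )
            results.append(
                QAResult(labels[i], assembly, interface,
                         local_tracks[i] if local_tracks else LocalScoreTrack(),
                         per_model)
            )
    order = sorted(
        range(n),
        key=lambda i: (
            -(results[i].interface_score
              if results[i].interface_score is not None else -np.inf),
            -(results[i].global_score
              if results[i].global_score is not None else -np.inf),
            results[i].label,
        ),
    )
    for rank, i in enumerate(order, start=1):
        results[i].rank = rank
    return results


# ---------------------------------------------------------------------------
# top-level drivers


def run_jury(pool: list[Structure], cfg: JuryConfig | None = None) -> list[QAResult]:
    """Full consensus run on a model pool (variants D2 / D2R)."""
    cfg = cfg or JuryConfig()
    matrices, local_tracks = pairwise_scores(pool, cfg.metrics)
    jury_scores = {
        m: jury_global(matrices[m], cfg.aggregation, cfg.top_k)
        for m in cfg.metrics
    }
    combined = combined_local_tracks(pool, local_tracks)
    labels = [s.label for s in pool]
    return combine_variant(jury_scores, combined, cfg, labels)


def score_single(
    model: Structure,
    reference_pool: list[Structure],
    cfg: JuryConfig | None = None,
) -> QAResult:
    """Score one model against an external reference pool (variant D2S).

    The model is compared against every reference-pool member; global
    jury scores are the row aggregates and the combined local track is
    the direct mean of the four local jury tracks.
    """
    if not reference_pool:
        raise ConfigError("reference pool must contain at least 1 model")
    cfg = cfg or JuryConfig(variant="D2S")
    rows: dict = {m: [] for m in cfg.metrics}
    local_accum: dict = {m: [] for m in LOCAL_METRICS if m in cfg.metrics}
    for ref in reference_pool:
        result = compare_pair(model, ref, cfg.metrics)
        for m in cfg.metrics:
            rows[m].append(result.get(m))
        for m in local_accum:
            t = result.get(f"{m}_local")
            if t is not None:
                local_accum[m].append(t)

    def aggregate(vals):
        vals = [v for v in vals if v is not None]
        if not vals:
            return None
        if cfg.aggregation == "mean":
            return float(np.mean(vals))
        k = min(cfg.top_k, len(vals))
        return float(np.mean(sorted(vals, reverse=True)[:k]))

    jury_scores = {m: [aggregate(rows[m])] for m in cfg.metrics}

    combined = LocalScoreTrack()
    for key in model.residue_keys():
        metric_means = []
        for m in local_accum:
            vals = [
                t.get(key) for t in local_accum[m] if t.get(key) is not None
            ]
            if vals:
                metric_means.append(float(np.mean(vals)))
        combined[key] = float(np.mean(metric_means)) if metric_means else None

    result = combine_variant(jury_scores, [combined], cfg, [model.label])[0]
    result.rank = 1
    return result
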