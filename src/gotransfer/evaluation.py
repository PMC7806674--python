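"""CAFA-style assessment: precision/recall/F1, the F_max sweep, bootstrap CIs.

Predictions carry a reliability score in (0, 1]; evaluation sweeps a
threshold τ over a grid (default 0.00–1.00, step 0.01), keeps predictions
with score ≥ τ, and computes per namespace

    P = TP / (TP + FP),   R = TP / (TP + FN),   F1 = 2·P·R / (P + R)

where TP are predicted-and-annotated terms, FP predicted-only and FN
annotated-only, on root-free propagation-closed sets.  F_max is the maximum
F1 over the grid.  Two averaging modes are supported:

* ``protein_centric`` (default, the CAFA protocol): precision is averaged
  over proteins with ≥1 prediction at τ, recall over *all* benchmark
  proteins — the "full evaluation", penalising queries with no prediction;
* ``micro``: the equations applied to counts pooled over proteins.

Confidence intervals follow the CAFA convention: resample the benchmark
protein set with replacement, recompute the metric, and report a symmetric
95% interval of ±1.96 bootstrap standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotations import AnnotationSet
from .errors import ValidationError
from .ontology import NAMESPACE_ROOTS
from .transfer import Prediction

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
MODES = ("protein_centric", "micro")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int


def confusion(predicted: Iterable[str], truth: Iterable[str]) -> ConfusionCounts:
    """Set-wise confusion counts for one protein at one threshold.

    Both sets must be root-free and propagation-closed term sets from the
    same namespace (the caller groups per namespace).
    """
    p, t = set(predicted), set(truth)
    return ConfusionCounts(tp=len(p & t), fp=len(p - t), fn=len(t - p))


def precision_recall_f1(
    counts: Sequence[ConfusionCounts], mode: str = "protein_centric"
) -> tuple[float, float, float]:
    """Aggregate per-protein confusion counts into (P, R, F1).

    ``protein_centric`` averages precision over proteins that made ≥1
    prediction and recall over all proteins (full evaluation); ``micro``
    pools the counts first.  F1 is defined as 0 when P + R = 0.
    """
    if not counts:
        raise ValidationError("need at least one benchmark protein")
    if mode == "protein_centric":
        precisions = [c.tp / (c.tp + c.fp) for c in counts if c.tp + c.fp > 0]
        recalls = [c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else 0.0 for c in counts]
        p = float(np.mean(precisions)) if precisions else 0.0
        r = float(np.mean(recalls))
    elif mode == "micro":
        tp = sum(c.tp for c in counts)
        fp = sum(c.fp for c in counts)
        fn = sum(c.fn for c in counts)
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
    else:
        raise ValidationError(f"unknown mode {mode!r} (expected {MODES})")
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


@dataclass
class NamespaceEval:
    """Threshold sweep result for one namespace."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    fmax: float
    tau_star: float
    n_benchmark: int
    ci_halfwidth: float | None = None


def _per_protein_tables(
    predictions: Iterable[Prediction],
    truth: AnnotationSet,
    grid: np.ndarray,
    namespace: str,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Per-(protein, τ) precision values, prediction flags and recalls.

    Benchmark = truth proteins with ≥1 term in the namespace.  Predictions
    for proteins outside the benchmark are ignored.
    """
    benchmark = [p for p in truth.proteins() if truth.terms(p, namespace)]
    by_query: dict[str, dict[str, float]] = {p: {} for p in benchmark}
    for pred in predictions:
        if pred.namespace != namespace or pred.query not in by_query:
            continue
        cur = by_query[pred.query].get(pred.term)
        if cur is None or pred.ri > cur:
            by_query[pred.query][pred.term] = pred.ri

    n, t = len(benchmark), len(grid)
    prec = np.zeros((n, t))
    has_pred = np.zeros((n, t), dtype=bool)
    rec = np.zeros((n, t))
    for i, protein in enumerate(benchmark):
        truth_terms = truth.terms(protein, namespace)
        scored = by_query[protein]
        if not scored:
            continue
        ris = np.array(list(scored.values()))
        in_truth = np.array([term in truth_terms for term in scored], dtype=bool)
        above = ris[None, :] >= grid[:, None]  # (t, m)
        tp = (above & in_truth[None, :]).sum(axis=1)
        npred = above.sum(axis=1)
        has_pred[i] = npred > 0
        with np.errstate(invalid="ignore"):
            prec[i] = np.where(npred > 0, tp / np.maximum(npred, 1), 0.0)
        rec[i] = tp / len(truth_terms)
    return benchmark, prec, has_pred, rec


def _curves(
    prec: np.ndarray, has_pred: np.ndarray, rec: np.ndarray, mode_protein: bool,
    counts_tp: np.ndarray | None = None, counts_pred: np.ndarray | None = None,
    counts_truth: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode_protein:
            n_predicting = has_pred.sum(axis=0)
            p = np.where(
                n_predicting > 0,
                (prec * has_pred).sum(axis=0) / np.maximum(n_predicting, 1),
                0.0,
            )
            r = rec.mean(axis=0)
        else:
            tp = counts_tp.sum(axis=0)
            p = np.where(counts_pred.sum(axis=0) > 0,
                         tp / np.maximum(counts_pred.sum(axis=0), 1), 0.0)
            r = np.where(counts_truth.sum() > 0, tp / counts_truth.sum(), 0.0)
        f1 = np.where(p + r > 0, 2 * p * r / np.maximum(p + r, 1e-300), 0.0)
    return p, r, f1


def fmax(
    predictions: Iterable[Prediction],
    truth: AnnotationSet,
    grid: np.ndarray | Sequence[float] | None = None,
    mode: str = "protein_centric",
    bootstrap: int = 0,
    seed: int | None = None,
) -> dict[str, NamespaceEval]:
    """Threshold sweep and F_max per namespace, optionally with bootstrap CIs.

    Ties in F1 across thresholds resolve toward the larger τ.  Namespaces
    without benchmark proteins are omitted from the result.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r} (expected {MODES})")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=np.float64)
    preds = list(predictions)
    out: dict[str, NamespaceEval] = {}
    for ns in NAMESPACE_ROOTS:
        benchmark, prec, has_pred, rec = _per_protein_tables(preds, truth, grid, ns)
        if not benchmark:
            continue
        if mode == "micro":
            tp_m, pred_m, truth_v = _micro_counts(preds, truth, grid, ns, benchmark)

            def _sample_curves(sample: np.ndarray):
                return _curves(None, None, None, False,
                               tp_m[sample], pred_m[sample], truth_v[sample])

            p, r, f1 = _curves(prec, has_pred, rec, False, tp_m, pred_m, truth_v)
        else:

            def _sample_curves(sample: np.ndarray):
                return _curves(prec[sample], has_pred[sample], rec[sample], True)

            p, r, f1 = _curves(prec, has_pred, rec, True)
        best = int(np.flatnonzero(f1 >= f1.max() - 1e-12).max())
        ci = None
        if bootstrap:
            ci = _bootstrap_fmax_ci(len(benchmark), _sample_curves, bootstrap, seed)
        out[ns] = NamespaceEval(
            thresholds=grid.copy(), precision=p, recall=r, f1=f1,
            fmax=float(f1[best]), tau_star=float(grid[best]),
            n_benchmark=len(benchmark), ci_halfwidth=ci,
        )
    return out


def _micro_counts(preds, truth, grid, ns, benchmark):
    by_query: dict[str, dict[str, float]] = {p: {} for p in benchmark}
    for pred in preds:
        if pred.namespace != ns or pred.query not in by_query:
            continue
        cur = by_query[pred.query].get(pred.term)
        if cur is None or pred.ri > cur:
            by_query[pred.query][pred.term] = pred.ri
    n, t = len(benchmark), len(grid)
    tp = np.zeros((n, t))
    npred = np.zeros((n, t))
    truth_sizes = np.zeros(n)
    for i, protein in enumerate(benchmark):
        truth_terms = truth.terms(protein, ns)
        truth_sizes[i] = len(truth_terms)
        scored = by_query[protein]
        if not scored:
            continue
        ris = np.array(list(scored.values()))
        in_truth = np.array([term in truth_terms for term in scored], dtype=bool)
        above = ris[None, :] >= grid[:, None]
        tp[i] = (above & in_truth[None, :]).sum(axis=1)
        npred[i] = above.sum(axis=1)
    return tp, npred, truth_sizes


def _bootstrap_fmax_ci(
    n: int,
    sample_curves: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]],
    b: int,
    seed: int | None,
) -> float:
    """95% CI half-width of F_max by resampling benchmark proteins."""
    if n < 2:
        raise ValidationError("bootstrap requires >= 2 benchmark proteins")
    rng = np.random.default_rng(seed)
    maxima = np.empty(b)
    for j in range(b):
        sample = rng.integers(0, n, size=n)
        _, _, f1 = sample_curves(sample)
        maxima[j] = f1.max()
    return float(1.96 * maxima.std(ddof=1))


def bootstrap_ci(
    values: Sequence[float],
    b: int = 10_000,
    seed: int | None = None,
    statistic: Callable[[np.ndarray], float] | None = None,
) -> float:
    """95% CI half-width (±1.96·SD) of a statistic under resampling.

    Resamples the value vector with replacement ``b`` times; the default
    statistic is the mean (vectorised).
    """
    vals = np.asarray(values, dtype=np.float64)
    if b < 1:
        raise ValidationError("bootstrap sample count must be >= 1")
    if vals.size < 2:
        raise ValidationError("bootstrap requires n >= 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, vals.size, size=(b, vals.size))
    if statistic is None:
        boot = vals[idx].mean(axis=1)
    else:
        boot = np.array([statistic(vals[row]) for row in idx])
    return float(1.96 * boot.std(ddof=1))


# -- set similarity and correlation ---------------------------------------


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Jaccard index |A∩B| / |A∪B| between two GO term sets.

    Two empty sets are defined as identical (J = 1, logged).
    """
    sa, sb = set(a), set(b)
    if not sa and not sb:
        logger.debug("jaccard of two empty sets defined as 1.0")
        return 1.0
    return len(sa & sb) / len(sa | sb)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Returns NaN for constant columns (rank correlation undefined).
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("spearman requires two equal-length vectors")
    if xa.size < 3:
        raise ValidationError("spearman requires at least 3 pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return float("nan")
    rho = stats.spearmanr(xa, ya).statistic
    return float(rho)
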