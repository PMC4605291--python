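"""Per-residue assessment: ROC/AUC, TP-rate at a fixed FP-rate,
subset-resampling significance, and FP-rate on matched control regions.

Positives are the residues annotated with the target function; negatives
are all other residues, including other disordered residues and all
ordered residues. ROC curves sweep every distinct score threshold; tied
scores earn half credit, so the AUC equals the Mann-Whitney pair statistic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from idrbind.annotations import AnnotatedProtein, RegionRecord, true_runs

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    function: str
    auc: float
    roc_points: list[tuple[float, float]]  # (fp_rate, tp_rate)
    tp_at_fp: dict[float, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)  # TP/FP/TN/FN at a threshold


@dataclass
class SignificanceResult:
    label: str
    auc_a: np.ndarray
    auc_b: np.ndarray
    test_used: str  # "t" or "wilcoxon"
    p_value: float
    significant: bool


def roc_auc(scores: np.ndarray, labels: np.ndarray, function: str = "") -> EvaluationReport:
    """ROC over all distinct thresholds plus trapezoidal AUC."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return EvaluationReport(function, auc, list(zip(fpr.tolist(), tpr.tolist())))


def counts_at_threshold(scores, labels, threshold: float) -> dict[str, int]:
    labels = np.asarray(labels, dtype=bool)
    pred = np.asarray(scores, dtype=float) >= threshold
    return {
        "TP": int(np.sum(pred & labels)),
        "FP": int(np.sum(pred & ~labels)),
        "TN": int(np.sum(~pred & ~labels)),
        "FN": int(np.sum(~pred & labels)),
    }


def tp_rate_at_fp(report: EvaluationReport, fp_level: float = 0.1) -> float:
    """TP-rate linearly interpolated on the ROC polyline at ``fp_level``.

    Vertical ROC segments (several TP-rates at one FP-rate) resolve to the
    highest TP-rate at that FP-rate.
    """
    if not (0.0 <= fp_level <= 1.0):
        raise ValueError(f"fp_level {fp_level} outside [0, 1]")
    pts = np.asarray(report.roc_points)
    # np.interp walks the polyline; at an exactly duplicated FP-rate
    # (vertical segment) it returns the last, i.e. highest, TP-rate
    return float(np.interp(fp_level, pts[:, 0], pts[:, 1]))


def _anderson_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    """Anderson-Darling normality check at the given significance level."""
    if np.std(x) == 0:
        return False  # degenerate vector: route to the rank-based test
    with warnings.catch_warnings():
        # scipy >= 1.17 deprecation chatter about the p-value method; the
        # critical-value table comparison used here is unaffected
        warnings.simplefilter("ignore", FutureWarning)
        res = stats.anderson(x, dist="norm")
    levels = np.asarray(res.significance_level, dtype=float) / 100.0
    idx = int(np.argmin(np.abs(levels - alpha)))
    return bool(res.statistic < res.critical_values[idx])


def compare_auc_vectors(auc_a: np.ndarray, auc_b: np.ndarray,
                        label: str = "", alpha: float = 0.05) -> SignificanceResult:
    """t-test iff both vectors pass Anderson-Darling normality at 0.05,
    otherwise the Wilcoxon rank-sum test; significant iff p < alpha."""
    auc_a = np.asarray(auc_a, dtype=float)
    auc_b = np.asarray(auc_b, dtype=float)
    if np.allclose(auc_a, auc_b):
        return SignificanceResult(label, auc_a, auc_b, "t", 1.0, False)
    if _anderson_normal(auc_a) and _anderson_normal(auc_b):
        test_used = "t"
        p = float(stats.ttest_ind(auc_a, auc_b).pvalue)
    else:
        test_used = "wilcoxon"
        p = float(stats.ranksums(auc_a, auc_b).pvalue)
    if not np.isfinite(p) or p <= 0:
        p = 1.0
    return SignificanceResult(label, auc_a, auc_b, test_used,
                              min(p, 1.0), p < alpha)


def subset_significance(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    protein_ids: np.ndarray,
    n_rep: int = 10,
    frac: float = 0.5,
    alpha: float = 0.05,
    seed: int = 0,
    label: str = "A-vs-B",
) -> SignificanceResult:
    """Resample random protein subsets and compare the two predictors' AUCs.

    Each repetition samples floor(frac * N) proteins without replacement and
    computes both AUCs over their pooled residues; repetitions whose labels
    collapse to one class are redrawn (logged).
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels, dtype=bool)
    protein_ids = np.asarray(protein_ids)
    proteins = np.unique(protein_ids)
    k = int(np.floor(frac * proteins.size))
    if k < 1:
        raise ValueError("subset too small")
    auc_a, auc_b = [], []
    for _ in range(n_rep):
        for _attempt in range(100):
            chosen = rng.choice(proteins, size=k, replace=False)
            mask = np.isin(protein_ids, chosen)
            y = labels[mask]
            if y.any() and not y.all():
                break
            logger.info("resampling repetition with single-class labels")
        else:
            raise ValueError("could not draw a two-class protein subset")
        auc_a.append(roc_auc(np.asarray(scores_a)[mask], y).auc)
        auc_b.append(roc_auc(np.asarray(scores_b)[mask], y).auc)
    return compare_auc_vectors(np.array(auc_a), np.array(auc_b), label, alpha)


def _disorder_complement_regions(protein: AnnotatedProtein) -> list[tuple[int, int]]:
    """Maximal runs (0-based inclusive) outside annotated disorder."""
    return true_runs(~protein.track("disorder"))


def _other_function_regions(protein: AnnotatedProtein, function: str) -> list[tuple[int, int]]:
    """Disordered runs annotated with some function other than ``function``
    and free of the target function."""
    other = np.zeros(len(protein), dtype=bool)
    for f in ("rna", "dna", "protein"):
        if f != function:
            other |= protein.track(f)
    mask = protein.track("disorder") & other & ~protein.track(function)
    return true_runs(mask)


def control_region_fp_rate(
    predictions: dict[str, np.ndarray],
    proteins: list[AnnotatedProtein],
    function: str,
    control_kind: str = "non-disordered",
    cutoff: float = 0.5,
    seed: int = 0,
) -> float:
    """FP-rate on sampled control regions matched in count and length to the
    annotated positive regions of ``function``.

    ``control_kind``: "non-disordered" (segments outside annotated disorder)
    or "other-function" (disordered segments annotated with other functions
    only). Controls are sampled uniformly; a positive-region length with no
    control segment long enough raises an error reporting the shortfall.
    """
    if control_kind not in ("non-disordered", "other-function"):
        raise ValueError(f"unknown control kind {control_kind!r}")
    rng = np.random.default_rng(seed)
    positive_lengths: list[int] = []
    pool: list[tuple[str, int, int]] = []  # (protein_id, start, end) 0-based
    for p in proteins:
        for s, e in true_runs(p.track(function)):
            positive_lengths.append(e - s + 1)
        runs = (_disorder_complement_regions(p) if control_kind == "non-disordered"
                else _other_function_regions(p, function))
        pool.extend((p.id, s, e) for s, e in runs)
    if not positive_lengths:
        raise ValueError(f"no positive regions for function {function!r}")
    fp = tn = 0
    for L in positive_lengths:
        fitting = [(pid, s, e) for pid, s, e in pool if e - s + 1 >= L]
        if not fitting:
            raise ValueError(
                f"insufficient control regions of length >= {L} "
                f"for kind {control_kind!r}"
            )
        pid, s, e = fitting[rng.integers(len(fitting))]
        offset = int(rng.integers(e - s + 1 - L + 1))
        start = s + offset
        pred = np.asarray(predictions[pid], dtype=float)[start : start + L] >= cutoff
        fp += int(pred.sum())
        tn += int(L - pred.sum())
    return fp / (fp + tn)


def sampled_control_lengths(
    proteins: list[AnnotatedProtein], function: str
) -> list[int]:
    """Length multiset of the positive regions, i.e. the lengths the control
    sampler matches."""
    lengths = []
    for p in proteins:
        for s, e in true_runs(p.track(function)):
            lengths.append(e - s + 1)
    return lengths


def evaluate_predictions(
    scores_by_protein: dict[str, np.ndarray],
    proteins: list[AnnotatedProtein],
    function: str,
    fp_levels: tuple[float, ...] = (0.1,),
    threshold: float = 0.5,
) -> EvaluationReport:
    """Corpus-level per-residue evaluation of one function."""
    scores, labels = [], []
    for p in proteins:
        scores.append(np.asarray(scores_by_protein[p.id], dtype=float))
        labels.append(p.track(function))
    s = np.concatenate(scores)
    y = np.concatenate(labels)
    report = roc_auc(s, y, function)
    for level in fp_levels:
        report.tp_at_fp[level] = tp_rate_at_fp(report, level)
    report.counts = counts_at_threshold(s, y, threshold)
    return report


def pooled_labels(proteins: list[AnnotatedProtein], function: str) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-residue labels and protein-id grouping vector."""
    labels = np.concatenate([p.track(function) for p in proteins])
    ids = np.concatenate([np.repeat(p.id, len(p)) for p in proteins])
    return labels, ids
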