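"""Near-vs-remote contrast features and the two-stage feature selection.

Each binding function uses its own sliding-window geometry: a window of odd
size ``ws`` centered at the predicted residue, the (ws-1)/2 "near" residues
in the middle of the window, and floor((ws-1)/4) "remote" residues at each
end of the window. The contrast feature is mean(near) - mean(remote pooled
over both ends). Windows are truncated at the termini.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from idrbind.profiles import ProfileMatrix

logger = logging.getLogger(__name__)

DEFAULT_WS = {"rna": 55, "dna": 21, "protein": 33}
AGGREGATIONS = ("contrast", "window_mean")


@dataclass(frozen=True)
class WindowSpec:
    """Function-specific sliding-window geometry."""

    function: str
    ws: int

    def __post_init__(self) -> None:
        if self.ws < 5 or self.ws % 2 == 0:
            raise ValueError(f"ws must be odd and >= 5, got {self.ws}")

    @property
    def half(self) -> int:
        return (self.ws - 1) // 2

    @property
    def near_count(self) -> int:
        return (self.ws - 1) // 2

    @property
    def remote_count_per_side(self) -> int:
        # (ws-1)/4 is non-integral for e.g. ws=55; floored per side so the
        # remote pool stays inside the window.
        return (self.ws - 1) // 4

    @classmethod
    def default(cls, function: str) -> "WindowSpec":
        return cls(function, DEFAULT_WS[function])


def derive_window_size(region_lengths: list[int], centile: float = 0.20) -> int:
    """Window size = nearest-rank centile of the region lengths.

    Nearest-rank: the value at position ceil(centile * n) of the ascending
    sort. The result is decremented by 1 if even, then clamped to >= 5.
    """
    if not region_lengths:
        raise ValueError("cannot derive a window size from an empty length list")
    lengths = sorted(region_lengths)
    rank = max(1, math.ceil(centile * len(lengths)))
    ws = int(lengths[rank - 1])
    if ws % 2 == 0:
        ws -= 1
    return max(ws, 5)


def _near_bounds(pos: int, spec: WindowSpec) -> tuple[int, int]:
    """0-based inclusive bounds of the near region: the middle near_count
    positions of the window, right-biased by one when near_count is even."""
    m = spec.near_count
    lo = pos - m // 2 if m % 2 == 1 else pos - (m // 2 - 1)
    return lo, lo + m - 1


def contrast_feature(values: np.ndarray, position: int, spec: WindowSpec) -> float:
    """Contrast at one 0-based position: mean over the near residues minus
    mean over the pooled remote residues at the two window ends.

    The window is truncated at the termini; remote residues falling outside
    the chain are dropped, and the value is 0 when the remote pool is empty.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if not (0 <= position < n):
        raise IndexError(f"position {position} outside vector of length {n}")
    h, r = spec.half, spec.remote_count_per_side
    nlo, nhi = _near_bounds(position, spec)
    near = v[max(nlo, 0): min(nhi, n - 1) + 1]
    # remote: first r and last r positions of the (untruncated) window,
    # clipped to the chain
    llo, lhi = position - h, position - h + r - 1
    rlo, rhi = position + h - r + 1, position + h
    pool = np.concatenate([
        v[max(llo, 0): min(lhi, n - 1) + 1] if lhi >= 0 else v[:0],
        v[max(rlo, 0): min(rhi, n - 1) + 1] if rlo <= n - 1 else v[:0],
    ])
    if pool.size == 0:
        return 0.0
    return float(near.mean() - pool.mean())


def _interval_sums(cs: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum and count of v over [lo, hi] clipped to [0, n-1]; empty -> (0, 0)."""
    n = cs.size - 1
    lo_c = np.clip(lo, 0, n)
    hi_c = np.clip(hi + 1, 0, n)
    cnt = np.maximum(hi_c - lo_c, 0)
    s = np.where(cnt > 0, cs[hi_c] - cs[lo_c], 0.0)
    return s, cnt


def contrast_vector(values: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Vectorized contrast_feature over every position."""
    v = np.asarray(values, dtype=float)
    n = v.size
    cs = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    m, h, r = spec.near_count, spec.half, spec.remote_count_per_side
    nlo = idx - m // 2 if m % 2 == 1 else idx - (m // 2 - 1)
    nhi = nlo + m - 1
    ns, nc = _interval_sums(cs, nlo, nhi)
    ls, lc = _interval_sums(cs, idx - h, idx - h + r - 1)
    rs, rc = _interval_sums(cs, idx + h - r + 1, idx + h)
    pool_cnt = lc + rc
    near_mean = ns / np.maximum(nc, 1)
    pool_mean = (ls + rs) / np.maximum(pool_cnt, 1)
    return np.where(pool_cnt > 0, near_mean - pool_mean, 0.0)


def window_mean_vector(values: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Mean of the channel over the truncated ws-window at every position."""
    v = np.asarray(values, dtype=float)
    cs = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(v.size)
    s, c = _interval_sums(cs, idx - spec.half, idx + spec.half)
    return s / np.maximum(c, 1)


@dataclass
class FeatureVectorSet:
    """Per-residue feature rows for one or many proteins."""

    feature_ids: list[str]
    matrix: np.ndarray  # (n_residues, n_features)
    labels: np.ndarray  # boolean, len n_residues
    protein_ids: np.ndarray  # str array, len n_residues (grouping key)
    positions: np.ndarray  # 1-based residue positions

    def __post_init__(self) -> None:
        n, k = self.matrix.shape
        if len(self.feature_ids) != k:
            raise ValueError("feature id count != column count")
        if len(set(self.feature_ids)) != k:
            raise ValueError("duplicate feature ids")
        if self.labels.shape != (n,):
            raise ValueError("label length != row count")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")

    def select(self, feature_ids: list[str]) -> "FeatureVectorSet":
        idx = []
        for fid in feature_ids:
            if fid not in self.feature_ids:
                raise KeyError(f"missing feature column {fid!r}")
            idx.append(self.feature_ids.index(fid))
        return FeatureVectorSet(
            list(feature_ids), self.matrix[:, idx], self.labels,
            self.protein_ids, self.positions,
        )

    @classmethod
    def concatenate(cls, parts: list["FeatureVectorSet"]) -> "FeatureVectorSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        ids = parts[0].feature_ids
        for p in parts[1:]:
            if p.feature_ids != ids:
                raise ValueError("feature id mismatch between parts")
        return cls(
            ids,
            np.vstack([p.matrix for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.protein_ids for p in parts]),
            np.concatenate([p.positions for p in parts]),
        )


def build_features(
    profiles: ProfileMatrix,
    spec: WindowSpec,
    channel_list: list[str] | None = None,
    aggregations: tuple[str, ...] = AGGREGATIONS,
    labels: np.ndarray | None = None,
) -> FeatureVectorSet:
    """One feature column per (channel, aggregation); one row per residue."""
    channels = channel_list if channel_list is not None else sorted(profiles.channels)
    for agg in aggregations:
        if agg not in AGGREGATIONS:
            raise ValueError(f"unknown aggregation {agg!r}")
    cols, ids = [], []
    for cid in channels:
        vec = profiles[cid]
        for agg in aggregations:
            ids.append(f"{cid}:{agg}")
            if agg == "contrast":
                cols.append(contrast_vector(vec, spec))
            else:
                cols.append(window_mean_vector(vec, spec))
    n = profiles.length
    if labels is None:
        labels = np.zeros(n, dtype=bool)
    logger.debug("built %d feature columns for %s", len(ids), profiles.protein_id)
    return FeatureVectorSet(
        ids,
        np.column_stack(cols) if cols else np.empty((n, 0)),
        np.asarray(labels, dtype=bool),
        np.repeat(profiles.protein_id, n),
        np.arange(1, n + 1),
    )


def single_feature_relevance(column: np.ndarray, labels: np.ndarray) -> float:
    """max(AUC, 1-AUC) of one feature against the labels."""
    auc = roc_auc_score(labels, column)
    return float(max(auc, 1.0 - auc))


def select_features(
    candidates: FeatureVectorSet,
    relevance_min_auc: float = 0.55,
    redundancy_max_abs_corr: float = 0.7,
) -> list[str]:
    """Two-stage relevance/redundancy selection.

    Stage 1 keeps features whose single-feature AUC (the better of AUC and
    1-AUC) reaches ``relevance_min_auc``. Stage 2 scans survivors by
    descending relevance (ties broken by feature id) and drops any feature
    whose absolute Pearson correlation with an already-kept feature exceeds
    ``redundancy_max_abs_corr``.
    """
    y = candidates.labels
    if y.all() or not y.any():
        raise ValueError("feature selection requires both classes in the labels")
    relevances = {}
    for j, fid in enumerate(candidates.feature_ids):
        relevances[fid] = single_feature_relevance(candidates.matrix[:, j], y)
    survivors = [f for f, r in relevances.items() if r >= relevance_min_auc]
    if not survivors:
        logger.warning("no feature passed the relevance threshold %.3f", relevance_min_auc)
        return []
    survivors.sort(key=lambda f: (-relevances[f], f))
    col = {f: candidates.matrix[:, candidates.feature_ids.index(f)] for f in survivors}
    kept: list[str] = []
    for f in survivors:
        redundant = False
        for g in kept:
            a, b = col[f], col[g]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                corr = 1.0 if sa == sb else 0.0
            else:
                corr = float(np.corrcoef(a, b)[0, 1])
            if abs(corr) > redundancy_max_abs_corr:
                redundant = True
                break
        if not redundant:
            kept.append(f)
    return kept


def export_feature_table(fvs: FeatureVectorSet, path) -> None:
    """Audit export: protein_id, position, feature columns, label."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\t" + "\t".join(fvs.feature_ids) + "\tlabel\n")
        for i in range(fvs.matrix.shape[0]):
            vals = "\t".join(repr(float(x)) for x in fvs.matrix[i])
            fh.write(f"{fvs.protein_ids[i]}\t{fvs.positions[i]}\t{vals}\t{int(fvs.labels[i])}\n")
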