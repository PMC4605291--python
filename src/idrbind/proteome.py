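"""Proteome-level validation analyses.

All analyses compare an observed statistic computed on random halves of the
proteins of interest against the same statistic on random draws from the
whole proteome, using the shared Anderson-Darling-gated t / Wilcoxon
procedure. Reference binder sets, interaction degrees and localization
terms are consumed as user-supplied plain tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from idrbind.annotations import RegionRecord
from idrbind.evaluate import SignificanceResult, compare_auc_vectors

logger = logging.getLogger(__name__)


@dataclass
class ReferenceSet:
    name: str
    ids: set[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError(f"reference set {self.name!r} is empty")

    @classmethod
    def from_file(cls, path: str | Path, name: str | None = None) -> "ReferenceSet":
        ids = set()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    ids.add(line)
        return cls(name or Path(path).stem, ids)


@dataclass
class OverlapResult:
    actual_overlaps: np.ndarray
    random_overlaps: np.ndarray
    ratio: float
    p_value: float
    significant: bool
    test_used: str


@dataclass
class PromiscuityResult:
    pcc: float
    per_k_table: dict[int, tuple[float, int]]  # k -> (mean degree, protein count)
    ratio_to_random: float
    p_value: float
    significant: bool


@dataclass
class EnrichmentResult:
    enriched_terms: list[str]
    overlap_fraction: float | None
    ratio: float | None
    p_value: float | None
    significant: bool


def _half_sample(rng: np.random.Generator, items: list[str]) -> set[str]:
    k = len(items) // 2
    return set(rng.choice(items, size=k, replace=False))


def overlap_significance(
    predicted_ids: set[str],
    reference: ReferenceSet,
    proteome_ids: set[str],
    n_rep: int = 10,
    seed: int = 0,
) -> OverlapResult:
    """Overlap of predicted binders with a reference set versus random draws.

    Actual vector: overlaps of ``n_rep`` random halves of the predictions
    with the reference. Random vector: overlaps of equal-sized random
    proteome draws. Ratio = median(actual) / median(random).
    """
    if not predicted_ids <= proteome_ids:
        raise ValueError("predicted ids must be a subset of the proteome")
    if not (reference.ids & proteome_ids):
        raise ValueError(
            f"reference set {reference.name!r} is disjoint from the proteome"
        )
    rng = np.random.default_rng(seed)
    pred = sorted(predicted_ids)
    prot = sorted(proteome_ids)
    k = len(pred) // 2
    actual = np.array([
        len(_half_sample(rng, pred) & reference.ids) for _ in range(n_rep)
    ], dtype=float)
    random = np.array([
        len(set(rng.choice(prot, size=k, replace=False)) & reference.ids)
        for _ in range(n_rep)
    ], dtype=float)
    med_rand = float(np.median(random))
    ratio = float(np.median(actual)) / med_rand if med_rand > 0 else float("inf")
    if float(np.median(actual)) == 0.0:
        ratio = 0.0
    sig = compare_auc_vectors(actual, random, label=f"overlap:{reference.name}")
    return OverlapResult(actual, random, ratio, sig.p_value,
                         sig.significant and float(np.mean(actual)) > float(np.mean(random)),
                         sig.test_used)


def _term_fractions(ids: set[str], loc: dict[str, set[str]], terms: list[str]) -> np.ndarray:
    """Fraction of proteins in ``ids`` annotated with each term."""
    n = max(len(ids), 1)
    return np.array([
        sum(1 for pid in ids if t in loc.get(pid, set())) / n for t in terms
    ])


def localization_enrichment(
    novel_ids: set[str],
    known_ids: set[str],
    localizations: dict[str, set[str]],
    proteome_ids: set[str],
    min_frac: float = 0.02,
    n_rep: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
) -> EnrichmentResult:
    """Two-step localization analysis.

    Step 1 finds terms significantly enriched among known binders versus
    random proteome draws, after removing terms carrying less than
    ``min_frac`` of the known binders' total annotation count. Step 2
    computes the fraction of novel-binder localization annotations falling
    in those terms, and compares random halves of the novel set against
    random proteome draws of the same size.
    """
    if not localizations:
        raise ValueError("empty localization table")
    rng = np.random.default_rng(seed)
    covered = sum(1 for pid in proteome_ids if localizations.get(pid))
    logger.info("localization table covers %d/%d proteome ids", covered, len(proteome_ids))

    term_counts: dict[str, int] = {}
    for pid in known_ids:
        for t in localizations.get(pid, set()):
            term_counts[t] = term_counts.get(t, 0) + 1
    total = sum(term_counts.values())
    terms = sorted(t for t, c in term_counts.items() if total and c / total >= min_frac)
    if not terms:
        logger.warning("no localization term passes the %.0f%% low-count filter",
                       100 * min_frac)
        return EnrichmentResult([], None, None, None, False)

    known = sorted(known_ids)
    prot = sorted(proteome_ids)
    k = len(known) // 2
    enriched: list[str] = []
    for j, term in enumerate(terms):
        actual = np.array([
            _term_fractions(_half_sample(rng, known), localizations, [term])[0]
            for _ in range(n_rep)
        ])
        random = np.array([
            _term_fractions(set(rng.choice(prot, size=k, replace=False)),
                            localizations, [term])[0]
            for _ in range(n_rep)
        ])
        sig = compare_auc_vectors(actual, random, label=f"loc:{term}", alpha=alpha)
        if sig.significant and actual.mean() > random.mean():
            enriched.append(term)
    if not enriched:
        return EnrichmentResult([], None, None, None, False)

    enriched_set = set(enriched)

    def annot_fraction(ids: set[str]) -> float:
        in_terms = tot = 0
        for pid in ids:
            for t in localizations.get(pid, set()):
                tot += 1
                if t in enriched_set:
                    in_terms += 1
        return in_terms / tot if tot else 0.0

    novel = sorted(novel_ids)
    kn = max(len(novel) // 2, 1)
    actual = np.array([annot_fraction(_half_sample(rng, novel)) for _ in range(n_rep)])
    random = np.array([
        annot_fraction(set(rng.choice(prot, size=kn, replace=False)))
        for _ in range(n_rep)
    ])
    sig = compare_auc_vectors(actual, random, label="loc-overlap", alpha=alpha)
    med_rand = float(np.median(random))
    ratio = float(np.median(actual)) / med_rand if med_rand > 0 else float("inf")
    return EnrichmentResult(
        enriched, annot_fraction(novel_ids), ratio, sig.p_value,
        sig.significant and actual.mean() > random.mean(),
    )


def _per_k_means(ks: np.ndarray, degrees: np.ndarray) -> dict[int, tuple[float, int]]:
    table: dict[int, tuple[float, int]] = {}
    for k in np.unique(ks):
        mask = ks == k
        table[int(k)] = (float(degrees[mask].mean()), int(mask.sum()))
    return table


def _table_pcc(table: dict[int, tuple[float, int]]) -> float:
    ks = np.array(sorted(table))
    means = np.array([table[int(k)][0] for k in ks])
    if ks.size < 2 or means.std() == 0:
        return float("nan")
    return float(np.corrcoef(ks, means)[0, 1])


def promiscuity_correlation(
    region_counts: dict[str, int],
    degrees: dict[str, float],
    n_rep: int = 10,
    seed: int = 0,
) -> PromiscuityResult:
    """Correlation between predicted protein-binding region counts and the
    mean interaction-partner count at each region count.

    Observed PCC vector: computed on ``n_rep`` random halves of the shared
    proteins. Random vector: PCC after shuffling region counts across
    proteins. Ratio = median(observed) / median(|random|).
    """
    shared = sorted(set(region_counts) & set(degrees))
    if not shared:
        raise ValueError("no shared protein ids between tables")
    ks = np.array([region_counts[p] for p in shared])
    deg = np.array([degrees[p] for p in shared], dtype=float)
    if np.unique(ks).size < 3:
        raise ValueError("need >= 3 distinct region-count values for a PCC")
    table = _per_k_means(ks, deg)
    pcc = _table_pcc(table)

    rng = np.random.default_rng(seed)
    half = len(shared) // 2
    observed = []
    for _ in range(n_rep):
        idx = rng.choice(len(shared), size=half, replace=False)
        sub = _per_k_means(ks[idx], deg[idx])
        v = _table_pcc(sub)
        if np.isfinite(v):
            observed.append(v)
    randomized = []
    for _ in range(n_rep):
        perm = rng.permutation(len(shared))
        sub = _per_k_means(ks[perm], deg)
        v = _table_pcc(sub)
        if np.isfinite(v):
            randomized.append(v)
    observed_v = np.array(observed if observed else [0.0])
    random_v = np.array(randomized if randomized else [0.0])
    med_rand = float(np.median(np.abs(random_v)))
    ratio = float(np.median(observed_v)) / med_rand if med_rand > 0 else float("inf")
    sig = compare_auc_vectors(observed_v, random_v, label="promiscuity")
    return PromiscuityResult(pcc, table, ratio, sig.p_value, sig.significant)


def elm_overlap(
    predicted_regions: list[RegionRecord],
    elm_regions: list[RegionRecord],
    disorder_regions: list[RegionRecord],
) -> tuple[float | None, int]:
    """Among motif regions overlapping annotated disorder by >= 1 residue,
    the fraction also overlapping >= 1 predicted protein-binding region.

    Returns (fraction or None when no motif lies in disorder, count of
    motifs in disorder).
    """
    def overlaps(a: RegionRecord, b: RegionRecord) -> bool:
        return a.protein_id == b.protein_id and a.start <= b.end and b.start <= a.end

    in_disorder = [
        e for e in elm_regions if any(overlaps(e, d) for d in disorder_regions)
    ]
    if not in_disorder:
        return None, 0
    hit = sum(
        1 for e in in_disorder if any(overlaps(e, r) for r in predicted_regions)
    )
    return hit / len(in_disorder), len(in_disorder)


def read_degree_table(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("protein_id"):
                continue
            pid, deg = line.split("\t")
            out[pid] = float(deg)
    return out


def read_localization_table(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("protein_id"):
                continue
            pid, term = line.split("\t")
            out.setdefault(pid, set()).add(term)
    return out
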