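"""Annotation transfer from the training library by local alignment.

The builtin engine runs Smith-Waterman with BLOSUM62 and affine gaps
(open -11 / extend -1) via Biopython and converts raw scores to
Karlin-Altschul-style E-values over the total library size. The
external-tabular engine instead parses a standard 12-column tabular
alignment file produced by any local-alignment tool.

Only the best hit under the E-value cutoff contributes; transferred
annotations are binary and are merged with the regression propensity p as
(1 + p) / 2 on transferred residues.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from math import exp, log
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from idrbind.annotations import AnnotatedProtein, FUNCTIONS

logger = logging.getLogger(__name__)

# gapped BLOSUM62 (open 11 / extend 1) Karlin-Altschul parameters
KA_LAMBDA = 0.267
KA_K = 0.041

DEFAULT_E_CUTOFF = 0.1


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    e_value: float
    position_map: list[tuple[int, int]] = field(default_factory=list)  # 1-based
    bitscore: float = 0.0
    pident: float = 0.0
    aln_length: int = 0
    mismatch: int = 0
    gapopen: int = 0

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")
        q_prev = s_prev = 0
        for q, s in self.position_map:
            if q <= q_prev or s <= s_prev:
                raise ValueError("position_map must be strictly increasing")
            q_prev, s_prev = q, s


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def _evalue(score: float, query_len: int, library_len: int) -> float:
    e = KA_K * query_len * library_len * exp(-KA_LAMBDA * score)
    return max(e, 1e-300)


def _position_map(alignment) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    q_blocks, s_blocks = alignment.aligned
    for (qs, qe), (ss, se) in zip(q_blocks, s_blocks):
        for k in range(qe - qs):
            pairs.append((qs + k + 1, ss + k + 1))
    return pairs


def search(
    query: AnnotatedProtein,
    library: list[AnnotatedProtein],
    engine: str = "builtin",
) -> list[AlignmentHit]:
    """Align the query to every library sequence; hits sorted by ascending
    E-value, ties broken by subject_id. Only the best hit carries a full
    position map (the transfer layer uses nothing else); the remaining hits
    report score and E-value only.

    ``engine`` is "builtin" or "external-tabular:<path>".
    """
    if engine.startswith("external-tabular:"):
        hits = [h for h in read_tabular(engine.split(":", 1)[1]) if h.query_id == query.id]
        return sorted(hits, key=lambda h: (h.e_value, h.subject_id))
    if engine != "builtin":
        raise ValueError(f"unknown alignment engine {engine!r}")
    if not library:
        return []
    aligner = _make_aligner()
    total = sum(len(p) for p in library)
    scored: list[tuple[float, str, AnnotatedProtein]] = []
    for subject in library:
        score = aligner.score(query.sequence, subject.sequence)
        scored.append((score, subject.id, subject))
    hits = [
        AlignmentHit(query.id, sid, _evalue(score, len(query), total),
                     bitscore=float(score))
        for score, sid, _ in scored
    ]
    hits.sort(key=lambda h: (h.e_value, h.subject_id))
    if hits:
        best = hits[0]
        subject = next(s for _, sid, s in scored if sid == best.subject_id)
        alignment = aligner.align(query.sequence, subject.sequence)[0]
        best.position_map = _position_map(alignment)
        matches = sum(
            1 for q, s in best.position_map
            if query.sequence[q - 1] == subject.sequence[s - 1]
        )
        best.aln_length = len(best.position_map)
        best.mismatch = best.aln_length - matches
        best.pident = 100.0 * matches / best.aln_length if best.aln_length else 0.0
        best.gapopen = max(len(alignment.aligned[0]) - 1, 0)
    return hits


def transfer(
    query: AnnotatedProtein,
    hits: list[AlignmentHit],
    library_tracks: dict[str, dict[str, np.ndarray]],
    e_cutoff: float = DEFAULT_E_CUTOFF,
) -> dict[str, np.ndarray]:
    """Binary per-function transfer vectors from the best hit only.

    If the best hit satisfies e_value < e_cutoff, query positions aligned
    to binding-True subject positions get 1; everything else is 0.
    """
    out = {f: np.zeros(len(query), dtype=bool) for f in FUNCTIONS}
    if not hits or hits[0].e_value >= e_cutoff:
        return out
    best = hits[0]
    tracks = library_tracks.get(best.subject_id)
    if tracks is None:
        raise KeyError(f"no library tracks for subject {best.subject_id!r}")
    for f in FUNCTIONS:
        track = tracks.get(f)
        if track is None:
            continue
        for q, s in best.position_map:
            if track[s - 1]:
                out[f][q - 1] = True
    n = {f: int(out[f].sum()) for f in FUNCTIONS}
    logger.debug("transfer to %s from %s (e=%.3g): %s", query.id, best.subject_id,
                 best.e_value, n)
    return out


def merge(p: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Merged propensity: (1 + p) / 2 where transferred, p elsewhere."""
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=bool)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    return np.where(t, (1.0 + p) / 2.0, p)


def write_tabular(hits: list[AlignmentHit], path: str | Path) -> None:
    """Write hits in the standard 12-column tabular alignment format."""
    with open(path, "w") as fh:
        for h in hits:
            if h.position_map:
                qstart, qend = h.position_map[0][0], h.position_map[-1][0]
                sstart, send = h.position_map[0][1], h.position_map[-1][1]
            else:
                qstart = qend = sstart = send = 0
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.2f}\t{h.aln_length}\t"
                f"{h.mismatch}\t{h.gapopen}\t{qstart}\t{qend}\t{sstart}\t{send}\t"
                f"{h.e_value:.3g}\t{h.bitscore:.1f}\n"
            )


def read_tabular(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column tabular alignment file. The position map is built
    by collinear mapping of the query span onto the subject span (tabular
    output carries no per-column gap structure)."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns")
            (qid, sid, pident, length, mismatch, gapopen,
             qstart, qend, sstart, send, evalue, bitscore) = parts
            qstart, qend, sstart, send = map(int, (qstart, qend, sstart, send))
            span = min(qend - qstart, send - sstart) + 1 if qstart > 0 else 0
            pmap = [(qstart + k, sstart + k) for k in range(max(span, 0))]
            hits.append(AlignmentHit(
                qid, sid, float(evalue), pmap,
                bitscore=float(bitscore), pident=float(pident),
                aln_length=int(length), mismatch=int(mismatch),
                gapopen=int(gapopen),
            ))
    return hits


def calibrate_e_cutoff(
    proteins: list[AnnotatedProtein],
    candidates: tuple[float, ...] = (1e-6, 1e-3, 0.01, 0.1, 1.0, 10.0),
    n_folds: int = 4,
    seed: int = 0,
) -> float:
    """Choose the E-value cutoff by k-fold cross-validated transfer,
    maximizing the mean (over functions) TP-rate / FP-rate ratio; ties go
    to the lowest cutoff."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(proteins))
    folds = np.array_split(order, n_folds)
    # precompute per-protein hits against its training folds
    per_protein_hits: dict[str, list[AlignmentHit]] = {}
    tracks = {p.id: {f: p.track(f) for f in FUNCTIONS} for p in proteins}
    for fold in folds:
        held = [proteins[i] for i in fold]
        lib = [p for p in proteins if p.id not in {q.id for q in held}]
        for q in held:
            per_protein_hits[q.id] = search(q, lib)
    best_cut, best_ratio = candidates[0], -1.0
    for cut in sorted(candidates):
        tp = {f: 0 for f in FUNCTIONS}
        fn = {f: 0 for f in FUNCTIONS}
        fp = {f: 0 for f in FUNCTIONS}
        tn = {f: 0 for f in FUNCTIONS}
        for p in proteins:
            t = transfer(p, per_protein_hits[p.id], tracks, e_cutoff=cut)
            for f in FUNCTIONS:
                truth = p.track(f)
                tp[f] += int(np.sum(t[f] & truth))
                fn[f] += int(np.sum(~t[f] & truth))
                fp[f] += int(np.sum(t[f] & ~truth))
                tn[f] += int(np.sum(~t[f] & ~truth))
        ratios = []
        for f in FUNCTIONS:
            tpr = tp[f] / (tp[f] + fn[f]) if (tp[f] + fn[f]) else 0.0
            fpr = fp[f] / (fp[f] + tn[f]) if (fp[f] + tn[f]) else 0.0
            if fpr == 0.0:
                ratios.append(tpr / 1e-6 if tpr > 0 else 0.0)
            else:
                ratios.append(tpr / fpr)
        mean_ratio = float(np.mean(ratios))
        if mean_ratio > best_ratio:
            best_ratio, best_cut = mean_ratio, cut
    return best_cut
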