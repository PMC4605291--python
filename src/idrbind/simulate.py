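"""Seeded synthetic corpora with planted, tunable binding signal.

Proteins are built from alternating ordered and disordered segments with a
composition bias in the disordered state. Binding regions (length >= 4,
log-uniform lengths) are placed inside disordered segments; residues inside
a binding region are sampled from an exponentially tilted composition so
that the expectation of a designated amino-acid scale shifts by
``effect_size`` scale standard deviations. Homolog proteins (10% point
mutations, annotations preserved) exercise the alignment-transfer layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from idrbind.annotations import (
    FUNCTIONS,
    AnnotatedProtein,
    RegionRecord,
    tracks_to_regions,
    write_fasta,
    write_regions,
)
from idrbind.features import derive_window_size
from idrbind.scales import CANONICAL_AA, _RAW_SCALES, normalize_scale

# background composition (ordered segments), roughly UniProt-like
_ORDERED_COMP = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039, "G": 0.071,
    "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097, "M": 0.024, "N": 0.040,
    "P": 0.047, "Q": 0.039, "R": 0.055, "S": 0.066, "T": 0.053, "V": 0.069,
    "W": 0.011, "Y": 0.029,
}

# disorder bias: promote disorder-enriched residues, deplete order-promoting ones
_DISORDER_MULTIPLIER = {
    "P": 2.2, "E": 1.8, "S": 1.7, "K": 1.6, "Q": 1.6, "G": 1.5,
    "W": 0.25, "C": 0.3, "F": 0.35, "I": 0.4, "Y": 0.4, "V": 0.5,
}

DEFAULT_SIGNAL_SCALES = {
    "rna": "HOPT810101",
    "dna": "ZIMJ680102",
    "protein": "DAYM780201",
}


@dataclass
class SimConfig:
    n_proteins: int = 200
    length_min: int = 100
    length_max: int = 400
    disorder_content: float = 0.45
    binding_prevalence: dict[str, float] = field(
        default_factory=lambda: {"rna": 0.25, "dna": 0.15, "protein": 0.20}
    )
    region_max_len: dict[str, int] = field(
        default_factory=lambda: {"rna": 80, "dna": 30, "protein": 50}
    )
    effect_size: float = 1.0
    signal_scales: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_SCALES)
    )
    homolog_fraction: float = 0.0
    mutation_rate: float = 0.10
    # multiplicative composition bias applied in disordered segments;
    # None -> the documented default table, {} -> no bias (fully
    # exchangeable null corpus)
    disorder_bias: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.disorder_content <= 1.0):
            raise ValueError("disorder_content must lie in [0, 1]")
        for f, q in self.binding_prevalence.items():
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"binding prevalence for {f} outside [0, 1]")
        for f, m in self.region_max_len.items():
            if m < 4:
                raise ValueError("region lengths must allow >= 4 residues")
        if not (0.0 <= self.homolog_fraction <= 1.0):
            raise ValueError("homolog_fraction must lie in [0, 1]")


def _base_comps(bias: dict[str, float] | None) -> tuple[np.ndarray, np.ndarray]:
    if bias is None:
        bias = _DISORDER_MULTIPLIER
    ordered = np.array([_ORDERED_COMP[a] for a in CANONICAL_AA])
    ordered = ordered / ordered.sum()
    dis = ordered * np.array([bias.get(a, 1.0) for a in CANONICAL_AA])
    dis = dis / dis.sum()
    return ordered, dis


def _z_scale(scale_id: str) -> np.ndarray:
    v = normalize_scale(_RAW_SCALES[scale_id])
    return (v - v.mean()) / v.std()


def _solve_tilt(base: np.ndarray, z: np.ndarray, shift: float) -> float:
    """Tilt eta with E_{base*e^{eta z}}[z] - E_base[z] = shift."""
    if shift == 0.0:
        return 0.0
    base_mean = float(base @ z)
    # as eta -> +/-inf the tilted mean approaches the extreme z value with
    # positive base mass; clamp unattainable shifts just inside that range
    reachable = z[base > 0]
    max_shift = float(reachable.max()) - base_mean
    min_shift = float(reachable.min()) - base_mean
    shift = float(np.clip(shift, 0.95 * min_shift, 0.95 * max_shift))

    def gap(eta: float) -> float:
        w = base * np.exp(eta * z)
        w = w / w.sum()
        return float(w @ z) - base_mean - shift

    hi = 1.0
    while gap(hi) < 0 and hi < 64:
        hi *= 2.0
    lo = -1.0
    while gap(lo) > 0 and lo > -64:
        lo *= 2.0
    return float(brentq(gap, lo, hi))


def _segment_plan(rng: np.random.Generator, length: int, disorder_content: float) -> np.ndarray:
    """Boolean disorder mask built from alternating random-length segments."""
    mask = np.zeros(length, dtype=bool)
    pos = 0
    while pos < length:
        disordered = rng.random() < disorder_content
        seg = int(rng.integers(8, 61))
        seg = min(seg, length - pos)
        if disordered and seg >= 4:
            mask[pos : pos + seg] = True
        pos += seg
    return mask


def _place_regions(
    rng: np.random.Generator,
    disorder_mask: np.ndarray,
    prevalence: float,
    max_len: int,
) -> np.ndarray:
    """Binding mask inside disordered runs, log-uniform lengths in [4, max]."""
    from idrbind.annotations import true_runs

    out = np.zeros(disorder_mask.size, dtype=bool)
    if prevalence <= 0:
        return out
    for s, e in true_runs(disorder_mask):
        seg_len = e - s + 1
        if seg_len < 4:
            continue
        cap = min(max_len, seg_len)
        target = prevalence * seg_len
        # draw log-uniform lengths until the target budget is met; the last
        # draw is accepted with probability proportional to the shortfall so
        # the expected planted count matches the target
        lengths: list[int] = []
        budget = 0.0
        while budget < target:
            L = int(round(math.exp(rng.uniform(math.log(4), math.log(cap))))) if cap > 4 else 4
            L = max(4, min(L, cap))
            if budget + L > target and rng.random() >= (target - budget) / L:
                break
            lengths.append(L)
            budget += L
        while lengths and sum(lengths) + 2 * (len(lengths) - 1) > seg_len:
            lengths.pop()  # infeasible placement: drop regions, keep >=2 gaps
        if not lengths:
            continue
        # scatter the regions with >= 1 residue between them so separate
        # placements stay separate maximal runs
        k = len(lengths)
        free = seg_len - sum(lengths) - (k - 1)
        cuts = np.sort(rng.integers(0, free + 1, size=k))
        pos = s
        prev_cut = 0
        for j, (L, cut) in enumerate(zip(lengths, cuts)):
            pos += int(cut - prev_cut) + (1 if j else 0)
            out[pos : pos + L] = True
            pos += L
            prev_cut = int(cut)
    return out


def simulate_corpus(
    config: SimConfig,
) -> tuple[list[AnnotatedProtein], list[RegionRecord], dict]:
    """Generate a corpus; returns (proteins, region records, metadata)."""
    rng = np.random.default_rng(config.seed)
    ordered_comp, disorder_comp = _base_comps(config.disorder_bias)
    z = {f: _z_scale(sid) for f, sid in config.signal_scales.items()}
    tilt = {
        f: {
            "ordered": _solve_tilt(ordered_comp, z[f], config.effect_size),
            "disordered": _solve_tilt(disorder_comp, z[f], config.effect_size),
        }
        for f in FUNCTIONS
    }
    aa_array = np.array(list(CANONICAL_AA))
    proteins: list[AnnotatedProtein] = []
    for i in range(config.n_proteins):
        L = int(rng.integers(config.length_min, config.length_max + 1))
        dis = _segment_plan(rng, L, config.disorder_content)
        binding = {
            f: _place_regions(rng, dis, config.binding_prevalence.get(f, 0.0),
                              config.region_max_len.get(f, 50))
            for f in FUNCTIONS
        }
        seq_idx = np.empty(L, dtype=int)
        for pos in range(L):
            base = disorder_comp if dis[pos] else ordered_comp
            state = "disordered" if dis[pos] else "ordered"
            active = [f for f in FUNCTIONS if binding[f][pos]]
            if active:
                logw = np.log(base)
                for f in active:
                    logw = logw + tilt[f][state] * z[f]
                w = np.exp(logw - logw.max())
                w = w / w.sum()
            else:
                w = base
            seq_idx[pos] = rng.choice(20, p=w)
        seq = "".join(aa_array[seq_idx])
        tracks = {"disorder": dis}
        tracks.update(binding)
        proteins.append(AnnotatedProtein(id=f"sim{i:04d}", sequence=seq, tracks=tracks))

    n_hom = int(math.floor(config.homolog_fraction * config.n_proteins))
    for i in range(n_hom):
        parent = proteins[i]
        seq = list(parent.sequence)
        n_mut = int(round(config.mutation_rate * len(seq)))
        pos = rng.choice(len(seq), size=n_mut, replace=False)
        for p in pos:
            seq[p] = aa_array[rng.integers(20)]
        proteins.append(AnnotatedProtein(
            id=parent.id + "_h",
            sequence="".join(seq),
            tracks={k: v.copy() for k, v in parent.tracks.items()},
        ))

    records: list[RegionRecord] = []
    for p in proteins:
        records.extend(tracks_to_regions(p))
    meta = {
        "config": asdict(config),
        "n_proteins_total": len(proteins),
        "stats": corpus_stats(proteins),
    }
    return proteins, records, meta


def corpus_stats(proteins: list[AnnotatedProtein]) -> dict:
    """Bookkeeping: disorder content, per-function counts, region-length
    20th centiles (the input to window-size derivation)."""
    total = sum(len(p) for p in proteins)
    n_dis = sum(int(p.track("disorder").sum()) for p in proteins)
    stats: dict = {
        "n_proteins": len(proteins),
        "n_residues": total,
        "disorder_content": n_dis / total if total else 0.0,
    }
    for f in FUNCTIONS:
        n = sum(int(p.track(f).sum()) for p in proteins)
        lengths = []
        for p in proteins:
            lengths.extend(r.length for r in tracks_to_regions(p) if r.function == f)
        stats[f] = {
            "n_binding_residues": n,
            "n_regions": len(lengths),
            "region_length_centile20": (
                derive_window_size(lengths) if lengths else None
            ),
        }
    return stats


def write_corpus(
    proteins: list[AnnotatedProtein],
    records: list[RegionRecord],
    meta: dict,
    out_dir: str | Path,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(proteins, out / "corpus.fasta")
    write_regions(records, out / "regions.tsv")
    with open(out / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
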