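"""Per-residue real-valued channels computed from the sequence.

Channels are the raw material for the windowed contrast features: scale
profiles, window amino-acid composition, windowed Shannon-entropy sequence
complexity, and pluggable putative disorder / secondary-structure scores.
All windows are truncated at the termini (the window shrinks on one side so
it never extends outside the chain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from idrbind.annotations import AnnotatedProtein
from idrbind.scales import (
    CANONICAL_AA,
    COIL_SCALE_ID,
    DISORDER_SCALE_ID,
    HELIX_SCALE_ID,
    STRAND_SCALE_ID,
    ScaleSet,
    _RAW_SCALES,
    normalize_scale,
)

AA_TO_IDX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

DISORDER_CHANNELS = ("disorder_long", "disorder_short", "disorder_glob")
SECSTRUCT_CHANNELS = ("helix", "strand", "coil")

# smoothing spans for the bundled surrogate providers
DISORDER_SMOOTH_WS = {"disorder_long": 21, "disorder_short": 9, "disorder_glob": 41}
SECSTRUCT_SMOOTH_WS = 7


@dataclass
class ProfileMatrix:
    """Per-residue channels for one protein, prior to windowing."""

    protein_id: str
    length: int
    channels: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, channel_id: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.length,):
            raise ValueError(
                f"channel {channel_id!r}: length {values.shape} != {self.length}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"channel {channel_id!r} contains non-finite values")
        self.channels[channel_id] = values

    def __getitem__(self, channel_id: str) -> np.ndarray:
        if channel_id not in self.channels:
            raise KeyError(f"unknown channel {channel_id!r}")
        return self.channels[channel_id]


def _check_ws(ws: int) -> None:
    if ws < 3 or ws % 2 == 0:
        raise ValueError(f"window size must be odd and >= 3, got {ws}")


def moving_average(values: np.ndarray, ws: int) -> np.ndarray:
    """Truncated-window moving average: at each position the mean over the
    window of size ``ws`` clipped to the vector bounds."""
    _check_ws(ws)
    v = np.asarray(values, dtype=float)
    n = v.size
    h = ws // 2
    cs = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, n - 1)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def scale_profile(protein: AnnotatedProtein, scale: np.ndarray) -> np.ndarray:
    """Per-position lookup of a normalized 20-value scale; 'X' maps to 0.5."""
    scale = np.asarray(scale, dtype=float)
    if scale.shape != (20,):
        raise ValueError("scale must have exactly 20 values")
    out = np.empty(len(protein.sequence))
    for i, aa in enumerate(protein.sequence):
        out[i] = scale[AA_TO_IDX[aa]] if aa in AA_TO_IDX else 0.5
    return out


def _aa_indicator(protein: AnnotatedProtein) -> np.ndarray:
    """(20, L) one-hot matrix; 'X' columns are all zero."""
    L = len(protein.sequence)
    ind = np.zeros((20, L))
    for i, aa in enumerate(protein.sequence):
        j = AA_TO_IDX.get(aa)
        if j is not None:
            ind[j, i] = 1.0
    return ind


def window_composition(protein: AnnotatedProtein, ws: int) -> dict[str, np.ndarray]:
    """Frequency of each amino acid in the truncated window centered at each
    position. 'X' counts toward the window size but toward no channel, so
    the 20 frequencies sum to 1 exactly when the window has no 'X'."""
    _check_ws(ws)
    ind = _aa_indicator(protein)
    return {
        f"comp_{aa}": moving_average(ind[j], ws)
        for aa, j in AA_TO_IDX.items()
    }


def complexity_profile(protein: AnnotatedProtein, ws: int) -> np.ndarray:
    """Shannon entropy (bits) of the window amino-acid composition, divided
    by log2(20) so values lie in [0, 1]. 'X' residues are excluded from the
    composition; an all-'X' window scores 0."""
    _check_ws(ws)
    L = len(protein.sequence)
    ind = _aa_indicator(protein)
    h = ws // 2
    cs = np.concatenate((np.zeros((20, 1)), np.cumsum(ind, axis=1)), axis=1)
    idx = np.arange(L)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, L - 1)
    counts = cs[:, hi + 1] - cs[:, lo]  # (20, L)
    totals = counts.sum(axis=0)
    out = np.zeros(L)
    nz = totals > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(nz, counts / np.where(nz, totals, 1.0), 0.0)
        terms = np.where(freq > 0, -freq * np.log2(np.where(freq > 0, freq, 1.0)), 0.0)
    out[nz] = terms.sum(axis=0)[nz] / np.log2(20.0)
    return out


def _read_score_file(path: str | Path, protein_id: str, length: int,
                     wanted: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Read an external per-residue score TSV: protein_id, position (1-based),
    channel, score in [0,1]. Every position of every wanted channel must be
    covered."""
    vals: dict[str, np.ndarray] = {c: np.full(length, np.nan) for c in wanted}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "protein_id":
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            pid, pos, channel, score = parts
            if pid != protein_id or channel not in vals:
                continue
            p = int(pos)
            if not (1 <= p <= length):
                raise ValueError(f"{path}:{lineno}: position {p} out of range")
            s = float(score)
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"{path}:{lineno}: score {s} outside [0, 1]")
            vals[channel][p - 1] = s
    for channel, arr in vals.items():
        gaps = np.flatnonzero(np.isnan(arr)) + 1
        if gaps.size:
            raise ValueError(
                f"score file {path} misses channel {channel!r} of protein "
                f"{protein_id!r} at positions {gaps[:10].tolist()}"
                + ("..." if gaps.size > 10 else "")
            )
    return vals


def disorder_channels(protein: AnnotatedProtein, provider: str = "bundled") -> dict[str, np.ndarray]:
    """Three putative-disorder channels in [0, 1].

    The bundled provider smooths a normalized disorder-propensity scale
    profile over windows of 21 (long), 9 (short) and 41 (globular
    surrogate). ``file:<path>`` reads externally computed scores instead.
    """
    if provider == "bundled":
        raw = scale_profile(protein, normalize_scale(_RAW_SCALES[DISORDER_SCALE_ID]))
        return {
            name: moving_average(raw, ws)
            for name, ws in DISORDER_SMOOTH_WS.items()
        }
    if provider.startswith("file:"):
        return _read_score_file(provider[5:], protein.id, len(protein.sequence),
                                DISORDER_CHANNELS)
    raise ValueError(f"unknown disorder provider {provider!r}")


def secstruct_channels(protein: AnnotatedProtein, provider: str = "bundled") -> dict[str, np.ndarray]:
    """Helix/strand/coil channels in [0, 1] summing to 1 per position.

    The bundled provider smooths normalized Chou-Fasman-style propensity
    profiles over a window of 7 and renormalizes the three channels.
    """
    if provider == "bundled":
        chans = {}
        for name, sid in zip(SECSTRUCT_CHANNELS,
                             (HELIX_SCALE_ID, STRAND_SCALE_ID, COIL_SCALE_ID)):
            raw = scale_profile(protein, normalize_scale(_RAW_SCALES[sid]))
            chans[name] = moving_average(raw, SECSTRUCT_SMOOTH_WS)
        total = sum(chans.values())
        total = np.where(total > 0, total, 1.0)
        return {name: v / total for name, v in chans.items()}
    if provider.startswith("file:"):
        return _read_score_file(provider[5:], protein.id, len(protein.sequence),
                                SECSTRUCT_CHANNELS)
    raise ValueError(f"unknown secondary-structure provider {provider!r}")


def build_profile_matrix(
    protein: AnnotatedProtein,
    scale_set: ScaleSet | None = None,
    comp_ws: int = 15,
    complexity_ws: int = 15,
    disorder_provider: str = "bundled",
    secstruct_provider: str = "bundled",
) -> ProfileMatrix:
    """Assemble the full channel matrix for one protein.

    Channel ids: ``scale_<id>``, ``comp_<AA>``, ``complexity``,
    the three disorder channels and the three secondary-structure channels.
    """
    if scale_set is None:
        scale_set = ScaleSet.bundled()
    pm = ProfileMatrix(protein_id=protein.id, length=len(protein.sequence))
    for sid in scale_set.ids():
        pm.add(f"scale_{sid}", scale_profile(protein, scale_set[sid]))
    for cid, vec in window_composition(protein, comp_ws).items():
        pm.add(cid, vec)
    pm.add("complexity", complexity_profile(protein, complexity_ws))
    for cid, vec in disorder_channels(protein, disorder_provider).items():
        pm.add(cid, vec)
    for cid, vec in secstruct_channels(protein, secstruct_provider).items():
        pm.add(cid, vec)
    return pm
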