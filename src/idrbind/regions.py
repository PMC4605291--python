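"""Binarization of propensities and binding-region / binder calls."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from idrbind.annotations import FUNCTIONS, true_runs

DEFAULT_CUTOFF = 0.5
MIN_REGION_LEN = 4


@dataclass(frozen=True)
class BindingRegion:
    """A called binding region, 1-based inclusive."""

    protein_id: str
    function: str
    start: int
    end: int
    mean_propensity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def binarize(p: np.ndarray, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """True iff propensity >= cutoff."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    p = np.asarray(p, dtype=float)
    return p >= cutoff


def call_regions(
    binary: np.ndarray,
    protein_id: str,
    function: str,
    propensities: np.ndarray | None = None,
    min_len: int = MIN_REGION_LEN,
) -> list[BindingRegion]:
    """Maximal True runs of length >= min_len, in position order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    binary = np.asarray(binary, dtype=bool)
    regions = []
    for s, e in true_runs(binary):
        if e - s + 1 < min_len:
            continue
        mean_p = float(propensities[s : e + 1].mean()) if propensities is not None else float("nan")
        regions.append(BindingRegion(protein_id, function, s + 1, e + 1, mean_p))
    return regions


def protein_level_call(regions_by_function: dict[str, list[BindingRegion]]) -> dict[str, bool]:
    """A protein is a binder for a function iff it has >= 1 called region."""
    return {f: bool(regions_by_function.get(f)) for f in FUNCTIONS}


def write_region_table(regions: list[BindingRegion], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfunction\tstart\tend\tmean_propensity\n")
        for r in regions:
            fh.write(f"{r.protein_id}\t{r.function}\t{r.start}\t{r.end}\t{r.mean_propensity:.6f}\n")
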