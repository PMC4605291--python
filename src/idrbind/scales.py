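"""Amino-acid scale tables (20 values per scale) and their normalization.

The bundled library ships 18 classical physicochemical scales keyed by
AAindex-style ids. Membership of the active scale set is configurable; the
bundled list is a documented default, not a claim about any particular
published feature set. Values are indexed by the canonical amino-acid order
``ACDEFGHIKLMNPQRSTVWY``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}

#            A      C      D      E      F      G      H      I      K      L      M      N      P      Q      R      S      T      V      W      Y
_RAW_SCALES: dict[str, list[float]] = {
    # Kyte-Doolittle hydropathy
    "KYTJ820101": [1.8, 2.5, -3.5, -3.5, 2.8, -0.4, -3.2, 4.5, -3.9, 3.8, 1.9, -3.5, -1.6, -3.5, -4.5, -0.8, -0.7, 4.2, -0.9, -1.3],
    # Hopp-Woods hydrophilicity
    "HOPT810101": [-0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0, -1.8, -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5, -3.4, -2.3],
    # Eisenberg consensus hydrophobicity
    "EISD840101": [0.62, 0.29, -0.90, -0.74, 1.19, 0.48, -0.40, 1.38, -1.50, 1.06, 0.64, -0.78, 0.12, -0.85, -2.53, -0.18, -0.05, 1.08, 0.81, 0.26],
    # Grantham polarity
    "GRAR740102": [8.1, 5.5, 13.0, 12.3, 5.2, 9.0, 10.4, 5.2, 11.3, 4.9, 5.7, 11.6, 8.0, 10.5, 10.5, 9.2, 8.6, 5.9, 5.4, 6.2],
    # Isoelectric point
    "ZIMJ680104": [6.00, 5.05, 2.77, 3.22, 5.48, 5.97, 7.59, 6.02, 9.74, 5.98, 5.74, 5.41, 6.30, 5.65, 10.76, 5.68, 5.66, 5.96, 5.89, 5.66],
    # Average flexibility index
    "BHAR880101": [0.357, 0.346, 0.511, 0.497, 0.314, 0.544, 0.323, 0.462, 0.466, 0.365, 0.295, 0.463, 0.509, 0.493, 0.529, 0.507, 0.444, 0.386, 0.305, 0.420],
    # Residue accessible surface area
    "CHOC760101": [115.0, 135.0, 150.0, 190.0, 210.0, 75.0, 195.0, 175.0, 200.0, 170.0, 185.0, 160.0, 145.0, 180.0, 225.0, 115.0, 140.0, 155.0, 255.0, 230.0],
    # Molecular weight
    "FASG760101": [89.09, 121.15, 133.10, 147.13, 165.19, 75.07, 155.16, 131.17, 146.19, 131.17, 149.21, 132.12, 115.13, 146.15, 174.20, 105.09, 119.12, 117.15, 204.24, 181.19],
    # Relative mutability
    "DAYM780201": [100.0, 20.0, 106.0, 102.0, 41.0, 49.0, 66.0, 96.0, 56.0, 40.0, 94.0, 134.0, 56.0, 93.0, 65.0, 120.0, 97.0, 74.0, 18.0, 41.0],
    # Chou-Fasman helix propensity
    "CHOP780201": [1.42, 0.70, 1.01, 1.51, 1.13, 0.57, 1.00, 1.08, 1.16, 1.21, 1.45, 0.67, 0.57, 1.11, 0.98, 0.77, 0.83, 1.06, 1.08, 0.69],
    # Chou-Fasman sheet propensity
    "CHOP780202": [0.83, 1.19, 0.54, 0.37, 1.38, 0.75, 0.87, 1.60, 0.74, 1.30, 1.05, 0.89, 0.55, 1.10, 0.93, 0.75, 1.19, 1.70, 1.37, 1.47],
    # Chou-Fasman turn propensity
    "CHOP780203": [0.66, 1.19, 1.46, 0.74, 0.60, 1.56, 0.95, 0.47, 1.01, 0.59, 0.60, 1.56, 1.52, 0.98, 0.95, 1.43, 0.96, 0.50, 0.96, 1.14],
    # Positive charge indicator
    "FAUJ880111": [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    # Negative charge indicator
    "FAUJ880112": [0.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
    # Disorder propensity (TOP-IDP style)
    "TOPIDP0101": [0.060, 0.020, 0.192, 0.736, -0.697, 0.166, 0.303, -0.486, 0.586, -0.326, -0.397, 0.007, 0.987, 0.318, 0.180, 0.341, 0.059, -0.121, -0.884, -0.510],
    # Surrounding hydrophobicity
    "PONP800101": [12.97, 14.63, 10.85, 11.89, 14.00, 12.43, 12.16, 15.67, 11.36, 14.90, 14.39, 11.42, 11.37, 11.76, 11.72, 11.23, 11.69, 15.71, 13.93, 13.42],
    # Normalized B-factor flexibility
    "VINM940101": [0.984, 0.906, 1.068, 1.094, 0.915, 1.031, 0.950, 0.927, 1.102, 0.935, 0.952, 1.048, 1.049, 1.037, 1.008, 1.046, 0.997, 0.931, 0.904, 0.929],
    # Bulkiness
    "ZIMJ680102": [11.50, 13.46, 11.68, 13.57, 19.80, 3.40, 13.69, 21.40, 15.71, 21.40, 16.25, 12.82, 17.43, 14.45, 14.28, 9.47, 15.77, 21.57, 21.67, 18.03],
}

DEFAULT_SCALE_IDS: tuple[str, ...] = tuple(sorted(_RAW_SCALES))

DISORDER_SCALE_ID = "TOPIDP0101"
HELIX_SCALE_ID = "CHOP780201"
STRAND_SCALE_ID = "CHOP780202"
COIL_SCALE_ID = "CHOP780203"


def normalize_scale(values) -> np.ndarray:
    """Linearly rescale a 20-vector to [0, 1]; a constant scale becomes 0.5."""
    v = np.asarray(values, dtype=float)
    if v.shape != (20,):
        raise ValueError(f"a scale must have exactly 20 values, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("scale contains non-finite values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full(20, 0.5)
    return (v - lo) / (hi - lo)


class ScaleSet:
    """A normalized library of amino-acid scales keyed by scale id."""

    def __init__(self, raw_scales: dict[str, list[float] | np.ndarray]):
        if not raw_scales:
            raise ValueError("empty scale set")
        self.scales: dict[str, np.ndarray] = {
            sid: normalize_scale(vals) for sid, vals in raw_scales.items()
        }

    @classmethod
    def bundled(cls, scale_ids: list[str] | None = None) -> "ScaleSet":
        """The bundled default library, optionally restricted to ``scale_ids``."""
        ids = scale_ids if scale_ids is not None else list(DEFAULT_SCALE_IDS)
        missing = [s for s in ids if s not in _RAW_SCALES]
        if missing:
            raise KeyError(f"unknown bundled scale id(s): {missing}")
        return cls({sid: _RAW_SCALES[sid] for sid in ids})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScaleSet":
        """Read a scale table: scale_id followed by 20 values in canonical order."""
        raw: dict[str, list[float]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "scale_id":
                    continue
                if len(parts) != 21:
                    raise ValueError(f"{path}:{lineno}: expected scale_id + 20 values")
                raw[parts[0]] = [float(x) for x in parts[1:]]
        return cls(raw)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("scale_id\t" + "\t".join(CANONICAL_AA) + "\n")
            for sid in sorted(self.scales):
                fh.write(sid + "\t" + "\t".join(repr(float(x)) for x in self.scales[sid]) + "\n")

    def __contains__(self, sid: str) -> bool:
        return sid in self.scales

    def __getitem__(self, sid: str) -> np.ndarray:
        if sid not in self.scales:
            raise KeyError(f"unknown scale_id {sid!r}")
        return self.scales[sid]

    def ids(self) -> list[str]:
        return sorted(self.scales)
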