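"""Sequences and functional-region annotations.

Coordinates in all files are 1-based inclusive. Internally, tracks are
0-based numpy boolean arrays of length ``len(sequence)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

FUNCTIONS = ("rna", "dna", "protein")
TRACKS = ("disorder", "rna", "dna", "protein")

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = CANONICAL_AA + "X"


@dataclass
class AnnotatedProtein:
    """A protein sequence plus per-residue boolean annotation tracks.

    Tracks cover intrinsic disorder and the three disorder-mediated binding
    functions (rna, dna, protein). Track arrays always have the same length
    as the sequence.
    """

    id: str
    sequence: str
    tracks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, track in self.tracks.items():
            if len(track) != len(self.sequence):
                raise ValueError(
                    f"track {name!r} of protein {self.id!r} has length "
                    f"{len(track)} != sequence length {len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def track(self, name: str) -> np.ndarray:
        """Return the named track, defaulting to all-False if absent."""
        if name not in TRACKS:
            raise KeyError(f"unknown track {name!r}; expected one of {TRACKS}")
        if name not in self.tracks:
            self.tracks[name] = np.zeros(len(self.sequence), dtype=bool)
        return self.tracks[name]

    def ensure_tracks(self) -> None:
        for name in TRACKS:
            self.track(name)


@dataclass(frozen=True)
class RegionRecord:
    """A 1-based inclusive annotated region on one protein."""

    protein_id: str
    function: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.function not in TRACKS:
            raise ValueError(
                f"function {self.function!r} not in vocabulary {TRACKS}"
            )
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid region coordinates ({self.start}, {self.end}) "
                f"on protein {self.protein_id!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _clean_sequence(seq: str, pid: str) -> str:
    seq = seq.upper().replace(" ", "").replace("\t", "")
    cleaned = []
    n_mapped = 0
    for ch in seq:
        if ch in CANONICAL_AA:
            cleaned.append(ch)
        else:
            cleaned.append("X")
            n_mapped += 1
    if n_mapped:
        logger.warning(
            "protein %s: %d residue(s) outside the 20-letter alphabet mapped to 'X'",
            pid, n_mapped,
        )
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[AnnotatedProtein]:
    """Read a FASTA file into AnnotatedProtein records with empty tracks.

    Sequences are uppercased; characters outside the 20 canonical amino
    acids are mapped to 'X' with a logged warning. Duplicate ids and empty
    files raise ValueError.
    """
    path = Path(path)
    proteins: list[AnnotatedProtein] = []
    seen: set[str] = set()
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            pid = header.split()[0]
            if pid in seen:
                raise ValueError(f"duplicate FASTA id {pid!r} in {path}")
            seen.add(pid)
            proteins.append(AnnotatedProtein(id=pid, sequence=_clean_sequence(seq, pid)))
    if not proteins:
        raise ValueError(f"no FASTA records found in {path}")
    return proteins


def write_fasta(proteins: Iterable[AnnotatedProtein], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def read_regions(path: str | Path) -> list[RegionRecord]:
    """Read a 4-column region TSV (protein_id, function, start, end).

    Lines starting with '#' are comments; a header line with the literal
    column names is tolerated.
    """
    records: list[RegionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            if parts[0] == "protein_id" and parts[1] == "function":
                continue
            records.append(
                RegionRecord(parts[0], parts[1], int(parts[2]), int(parts[3]))
            )
    return records


def write_regions(records: Iterable[RegionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tfunction\tstart\tend\n")
        for r in records:
            fh.write(f"{r.protein_id}\t{r.function}\t{r.start}\t{r.end}\n")


def regions_to_tracks(
    records: Iterable[RegionRecord], proteins: list[AnnotatedProtein]
) -> list[AnnotatedProtein]:
    """Fill per-residue boolean tracks from region records (in place).

    Residue i (1-based) is True for function f iff some record of f covers
    i; overlapping records of the same function are unioned.
    """
    index = {p.id: p for p in proteins}
    for p in proteins:
        p.ensure_tracks()
    for rec in records:
        if rec.protein_id not in index:
            raise ValueError(f"region references unknown protein {rec.protein_id!r}")
        prot = index[rec.protein_id]
        if rec.end > len(prot):
            raise ValueError(
                f"region ({rec.start}, {rec.end}) of function {rec.function!r} "
                f"out of range for protein {rec.protein_id!r} of length {len(prot)}"
            )
        prot.track(rec.function)[rec.start - 1 : rec.end] = True
    return proteins


def tracks_to_regions(protein: AnnotatedProtein) -> list[RegionRecord]:
    """Extract maximal True runs of every present track as 1-based regions."""
    records: list[RegionRecord] = []
    for name in TRACKS:
        if name not in protein.tracks:
            continue
        for start, end in true_runs(protein.tracks[name]):
            records.append(RegionRecord(protein.id, name, start + 1, end + 1))
    return records


def true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector as 0-based inclusive (start, end)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def write_label_table(proteins: Iterable[AnnotatedProtein], path: str | Path) -> None:
    """Export per-residue 0/1 labels for all four tracks as TSV."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tresidue\tdisorder\trna\tdna\tprotein\n")
        for p in proteins:
            p.ensure_tracks()
            for i, aa in enumerate(p.sequence):
                flags = "\t".join(
                    str(int(p.tracks[t][i])) for t in TRACKS
                )
                fh.write(f"{p.id}\t{i + 1}\t{aa}\t{flags}\n")
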