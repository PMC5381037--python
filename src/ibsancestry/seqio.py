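"""Sequence and interval I/O for pseudo-haploid genome data.

The universal input unit is a *pseudo-haploid* sequence: one FASTA record per
scaffold per individual, in which every base was randomly sampled from one of
the two homologous chromosomes. All characters outside A/C/G/T
(case-insensitive) are treated as missing data and normalized to N before any
computation.

Coordinates are 0-based half-open everywhere, matching the BED standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "PseudoHaploidSeq",
    "GenomeWindow",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "pseudo_haploidize",
    "tile_windows",
    "write_bed",
    "read_bed",
    "filter_scaffolds",
]

_N = ord("N")

# any byte outside acgtACGT maps to 'N'; lowercase maps to uppercase
_NORM_TABLE = np.full(256, _N, dtype=np.uint8)
for _c in "ACGT":
    _NORM_TABLE[ord(_c)] = ord(_c)
    _NORM_TABLE[ord(_c.lower())] = ord(_c)


class FastaFormatError(ValueError):
    """Raised for malformed or empty FASTA input."""


def _normalize(raw: bytes | np.ndarray) -> np.ndarray:
    arr = np.frombuffer(raw, dtype=np.uint8) if isinstance(raw, bytes) else np.asarray(raw, dtype=np.uint8)
    return _NORM_TABLE[arr]


@dataclass
class PseudoHaploidSeq:
    """A named pseudo-haploid sequence over the alphabet {A,C,G,T,N}.

    ``bases`` is a numpy uint8 array of ASCII codes, normalized on
    construction via :meth:`from_string`.
    """

    name: str
    bases: np.ndarray

    @classmethod
    def from_string(cls, name: str, seq: str) -> "PseudoHaploidSeq":
        return cls(name=name, bases=_normalize(seq.encode("ascii")))

    @property
    def length(self) -> int:
        return int(self.bases.size)

    def __len__(self) -> int:
        return self.length

    def to_string(self) -> str:
        return self.bases.tobytes().decode("ascii")

    def n_mask(self) -> np.ndarray:
        """Boolean mask of missing (N) positions."""
        return self.bases == _N


@dataclass(frozen=True)
class GenomeWindow:
    """A window [start, end) on a scaffold with its missing-data fraction."""

    scaffold: str
    start: int
    end: int
    n_fraction: float

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad window coordinates [{self.start}, {self.end})")
        if not (0.0 <= self.n_fraction <= 1.0):
            raise ValueError(f"n_fraction {self.n_fraction} outside [0, 1]")

    @property
    def size(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> dict[str, PseudoHaploidSeq]:
    """Read a (multi-record) FASTA file into normalized pseudo-haploid sequences.

    Record order is preserved (insertion order of the returned dict). Raises
    :class:`FastaFormatError` on an empty file, on text before the first
    header, or on duplicate record names.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno} is not FASTA (expected '>' header first): {stripped[:40]!r}"
                )
            break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file")

    out: dict[str, PseudoHaploidSeq] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise FastaFormatError(f"{path}: duplicate record name {rec.id!r}")
            out[rec.id] = PseudoHaploidSeq.from_string(rec.id, str(rec.seq))
    if not out:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return out


def write_fasta(seqs: Mapping[str, PseudoHaploidSeq] | Iterable[PseudoHaploidSeq], path: str | Path, width: int = 80) -> None:
    """Write sequences to FASTA, wrapping lines at ``width`` columns."""
    if isinstance(seqs, Mapping):
        seqs = seqs.values()
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.name}\n")
            text = s.to_string()
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


def pseudo_haploidize(hap1: PseudoHaploidSeq, hap2: PseudoHaploidSeq, seed: int) -> PseudoHaploidSeq:
    """Sample a pseudo-haploid sequence from two haplotypes.

    At each position the output base is hap1's or hap2's with probability 1/2.
    If exactly one is N the non-N base is taken; if both are N the output is N.
    Deterministic for a fixed seed.
    """
    if hap1.length != hap2.length:
        raise ValueError(f"haplotype lengths differ: {hap1.length} != {hap2.length}")
    rng = np.random.default_rng(seed)
    take1 = rng.integers(0, 2, size=hap1.length, dtype=np.uint8).astype(bool)
    out = np.where(take1, hap1.bases, hap2.bases)
    n1 = hap1.bases == _N
    n2 = hap2.bases == _N
    out[n1 & ~n2] = hap2.bases[n1 & ~n2]
    out[~n1 & n2] = hap1.bases[~n1 & n2]
    out[n1 & n2] = _N
    return PseudoHaploidSeq(name=hap1.name, bases=out)


def tile_windows(seq: PseudoHaploidSeq, w: int) -> list[GenomeWindow]:
    """Tile a scaffold into consecutive non-overlapping windows of size ``w``.

    Windows are [0,w), [w,2w), ...; a trailing segment shorter than ``w`` is
    dropped. Returns an empty list if the scaffold is shorter than ``w``.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    n_win = seq.length // w
    if n_win == 0:
        return []
    is_n = (seq.bases[: n_win * w] == _N).reshape(n_win, w)
    n_frac = is_n.mean(axis=1)
    return [
        GenomeWindow(scaffold=seq.name, start=k * w, end=(k + 1) * w, n_fraction=float(n_frac[k]))
        for k in range(n_win)
    ]


def write_bed(tracks: Sequence[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write labeled intervals as BED3+1 (tab-separated, no header).

    Intervals must be sorted and non-overlapping per scaffold; adjacent
    intervals on the same scaffold with the same label are merged.
    """
    merged: list[list] = []
    last_end: dict[str, int] = {}
    for scaf, start, end, label in tracks:
        if start >= end:
            raise ValueError(f"empty or inverted interval {scaf}:{start}-{end}")
        if scaf in last_end and start < last_end[scaf]:
            raise ValueError(f"overlapping/unsorted intervals on {scaf} at {start}")
        last_end[scaf] = end
        if merged and merged[-1][0] == scaf and merged[-1][2] == start and merged[-1][3] == label:
            merged[-1][2] = end
        else:
            merged.append([scaf, start, end, label])
    with open(path, "w") as fh:
        for scaf, start, end, label in merged:
            fh.write(f"{scaf}\t{start}\t{end}\t{label}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a BED3+1 file written by :func:`write_bed`."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"expected >=4 BED columns, got {line!r}")
            out.append((fields[0], int(fields[1]), int(fields[2]), fields[3]))
    return out


def filter_scaffolds(
    seqs: Mapping[str, PseudoHaploidSeq], min_len: int = 500_000
) -> dict[str, PseudoHaploidSeq]:
    """Keep scaffolds of length >= ``min_len`` (default 500 kb)."""
    kept = {name: s for name, s in seqs.items() if s.length >= min_len}
    if not kept and seqs:
        logger.warning("all %d scaffolds are below the %d bp minimum length", len(seqs), min_len)
    return kept
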