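"""Genome assembly I/O: sanitising, windowing and one-hot encoding.

DNA is handled over the five-letter alphabet {A, C, G, T, N}.  The one-hot
row order is fixed as (A, C, T, G, N) — ``ROW_ORDER`` — and every component
that builds or consumes 5xn matrices (the k-mer filter bank, the detector
network) depends on this constant.

Coordinates are 0-based half-open internally; every emitted file uses
1-based inclusive coordinates.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

#: Fixed row order of the one-hot matrix.
ROW_ORDER = "ACTGN"

#: Default window size in bases for genome sectioning.
WINDOW_SIZE = 50_000

#: Default name of the tabular predictions output.
PREDICTIONS_FILENAME = "ltrnet_predictions.tab"

# byte translation table: uppercase, then anything outside {A,C,G,T,N} -> N
_CLEAN_TABLE = bytearray(ord("N") for _ in range(256))
for _b in b"ACGTN":
    _CLEAN_TABLE[_b] = _b
    _CLEAN_TABLE[_b + 32] = _b  # lowercase
_CLEAN_TABLE = bytes(_CLEAN_TABLE)

# base byte -> one-hot row index
_ROW_OF_BYTE = np.full(256, ROW_ORDER.index("N"), dtype=np.int64)
for _i, _c in enumerate(ROW_ORDER):
    _ROW_OF_BYTE[ord(_c)] = _i


@dataclass
class GenomeSequence:
    """A sanitised assembly sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class WindowSpec:
    """How one analysis cycle sections a sequence into windows.

    Cycle ``c`` of ``total_cycles`` shifts the tiling by
    ``floor(window_size * c / total_cycles)`` bases so that elements split
    by one cycle's window boundary fall inside a window of another cycle.
    """

    window_size: int = WINDOW_SIZE
    cycle_index: int = 0
    total_cycles: int = 1

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if not 1 <= self.total_cycles <= 5:
            raise ValueError("total_cycles must be in [1, 5]")
        if not 0 <= self.cycle_index < self.total_cycles:
            raise ValueError("cycle_index must be in [0, total_cycles)")

    @property
    def offset(self) -> int:
        return self.window_size * self.cycle_index // self.total_cycles


@dataclass
class OneHotWindow:
    """One genomic window as a 5xn binary matrix (rows ``ROW_ORDER``).

    Columns beyond ``end - start`` are padding, encoded as N so that every
    column still sums to exactly 1.
    """

    source_id: str
    start: int
    end: int
    matrix: np.ndarray  # (5, n) float32

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    @property
    def seq_len(self) -> int:
        return self.end - self.start


def clean_sequence(raw: str, seq_id: str = "") -> GenomeSequence:
    """Sanitise a raw sequence: uppercase, map non-ACGTN characters to N.

    Replacement (rather than deletion) keeps a 1:1 coordinate mapping
    between the cleaned sequence and the input assembly.
    """
    if not raw:
        raise ValueError("empty sequence")
    cleaned = raw.encode("ascii", errors="replace").translate(_CLEAN_TABLE)
    return GenomeSequence(id=seq_id, seq=cleaned.decode("ascii"))


def drop_non_nucleotides(raw: str) -> str:
    """Strictly delete non-ACGTN characters (post-processing utility).

    Unlike :func:`clean_sequence` this shifts coordinates and must never be
    used upstream of candidate detection.
    """
    up = raw.upper()
    return "".join(c for c in up if c in "ACGTN")


def split_windows(g: GenomeSequence, spec: WindowSpec) -> list[tuple[int, int]]:
    """Tile ``[0, g.length)`` with non-overlapping windows for one cycle.

    For cycle offset ``o > 0`` the first window is the partial ``[0, o)``;
    full windows follow; a final partial window absorbs the tail.  The
    returned intervals exactly cover the sequence with no overlap.
    """
    length = g.length
    if length == 0:
        return []
    w, off = spec.window_size, spec.offset
    cuts = [0]
    b = off if off > 0 else w
    while b < length:
        cuts.append(b)
        b += w
    cuts.append(length)
    return list(zip(cuts[:-1], cuts[1:]))


def encode_sequence(seq: str) -> np.ndarray:
    """One-hot encode a string over {A,C,G,T,N} into a (5, len) matrix."""
    codes = _ROW_OF_BYTE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    m = np.zeros((5, len(seq)), dtype=np.float32)
    m[codes, np.arange(len(seq))] = 1.0
    return m


def one_hot_encode(g: GenomeSequence, start: int, end: int, n: int | None = None) -> OneHotWindow:
    """Encode ``g.seq[start:end]`` into a 5xn one-hot window.

    ``n`` defaults to ``end - start``; if larger, trailing columns are
    N-padded so each column still sums to 1.
    """
    if not (0 <= start < end <= g.length):
        raise ValueError(f"window [{start}, {end}) outside sequence of length {g.length}")
    if n is None:
        n = end - start
    if end - start > n:
        raise ValueError("window longer than matrix width n")
    m = np.zeros((5, n), dtype=np.float32)
    m[:, : end - start] = encode_sequence(g.seq[start:end])
    if n > end - start:
        m[ROW_ORDER.index("N"), end - start :] = 1.0
    return OneHotWindow(source_id=g.id, start=start, end=end, matrix=m)


def decode_one_hot(matrix: np.ndarray, length: int | None = None) -> str:
    """Inverse of encoding: 5xn matrix back to a string (padding excluded)."""
    rows = np.argmax(matrix, axis=0)
    if length is None:
        length = matrix.shape[1]
    return "".join(ROW_ORDER[r] for r in rows[:length])


def _open_maybe_gzip(path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_genome(path, clean: bool = True) -> list[GenomeSequence]:
    """Read a (possibly gzipped) multi-FASTA assembly.

    With ``clean=True`` (the default) every sequence is passed through
    :func:`clean_sequence`.
    """
    out: list[GenomeSequence] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            s = str(rec.seq)
            out.append(clean_sequence(s, seq_id=rec.id) if clean else GenomeSequence(rec.id, s))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_library(preds: Sequence, genome: Iterable[GenomeSequence], path) -> None:
    """Write retained predictions as a RepeatMasker-style FASTA library.

    Headers are ``{source_id}_{start1}_{end1}#LTR/{lineage}`` with 1-based
    inclusive coordinates; each record's sequence is the exact genome
    substring of the prediction.
    """
    by_id = {g.id: g for g in genome}
    with open(path, "w") as fh:
        for p in preds:
            src, start, end = p.source_id, p.start, p.end
            g = by_id.get(src)
            if g is None:
                raise ValueError(f"unknown source sequence {src!r}")
            if not (0 <= start < end <= g.length):
                raise ValueError(f"prediction [{start}, {end}) outside {src!r}")
            fh.write(f">{src}_{start + 1}_{end}#LTR/{p.lineage}\n")
            sub = g.seq[start:end]
            for i in range(0, len(sub), 60):
                fh.write(sub[i : i + 60] + "\n")


def write_predictions_table(preds: Sequence, path) -> None:
    """Write the tabular predictions file (TSV, one row per prediction).

    Columns: source_id, start, end (1-based inclusive), lineage, the three
    network probabilities and their mean (the combined prediction score).
    """
    cols = [
        "source_id", "start", "end", "lineage",
        "detect_prob", "intact_prob", "lineage_prob", "combined_score",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for p in preds:
            fh.write(
                f"{p.source_id}\t{p.start + 1}\t{p.end}\t{p.lineage}\t"
                f"{p.detect_prob:.6f}\t{p.intact_prob:.6f}\t{p.lineage_prob:.6f}\t"
                f"{p.combined_score:.6f}\n"
            )
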