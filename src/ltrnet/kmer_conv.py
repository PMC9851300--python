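"""Exact k-mer counting (1 <= k <= 6) on one-hot DNA via fixed convolutions.

The feature space is the 5460 k-mers of length 1..6 over {A,C,G,T} in
lexicographic order (alphabet A < C < G < T), k ascending.  Each k-mer m is
realised as a convolution filter equal to the 5xk one-hot matrix of m (zero
weight in the N row) with bias 1 - k: at a matching position the
cross-correlation scores k, the bias brings it to 1; any mismatch or
N-overlap scores <= k - 1, the bias makes it <= 0 and rectification clamps
it.  Summing the rectified feature map therefore yields the exact
occurrence count.

Three routes are provided:

* :func:`count_kmers_conv` — the convolutional mechanism itself, operating
  on 5xn matrices (the route used on extracted candidate elements);
* :func:`count_kmers_fast` — a vectorised integer rolling-code counter used
  for bulk training corpora;
* :func:`count_kmers_oracle` — a naive sliding-window substring counter
  kept as an independent verification oracle.

All three agree exactly; k-mers overlapping an N never count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .genome_io import ROW_ORDER, OneHotWindow

#: Lexicographic alphabet for k-mer enumeration.
KMER_ALPHABET = "ACGT"

MAX_K = 6

#: Total number of filters: 4^1 + ... + 4^6.
N_KMERS = sum(4**k for k in range(1, MAX_K + 1))  # 5460

# lexicographic base code (A=0, C=1, G=2, T=3); N and anything else -> 4
_LEX_CODE = np.full(256, 4, dtype=np.int64)
for _i, _c in enumerate(KMER_ALPHABET):
    _LEX_CODE[ord(_c)] = _i


def _enumerate_kmers(k: int) -> list[str]:
    return ["".join(t) for t in product(KMER_ALPHABET, repeat=k)]


@dataclass
class KmerFilterBank:
    """The 5460 fixed convolution filters and biases, lexicographic order.

    ``weights[k]`` stacks the 4^k filters of width k as a (4^k, 5*k) float32
    matrix (filter rows follow :data:`ltrnet.genome_io.ROW_ORDER`, flattened
    row-major over (row, column)); the bias of every width-k filter is
    ``1 - k``.  ``offsets[k]`` is the index of the first width-k k-mer in
    the global 5460-vector.
    """

    kmers: list[str]
    weights: dict[int, np.ndarray]
    offsets: dict[int, int]
    index: dict[str, int]

    @property
    def n_filters(self) -> int:
        return len(self.kmers)

    def bias(self, kmer: str) -> int:
        return 1 - len(kmer)

    def index_of(self, kmer: str) -> int:
        return self.index[kmer]

    def filter_matrix(self, kmer: str) -> np.ndarray:
        """The 5xk one-hot weight matrix of one k-mer."""
        k = len(kmer)
        row = self.index_of(kmer) - self.offsets[k]
        return self.weights[k][row].reshape(5, k)


def build_filter_bank() -> KmerFilterBank:
    """Construct the deterministic 5460-filter bank."""
    kmers: list[str] = []
    weights: dict[int, np.ndarray] = {}
    offsets: dict[int, int] = {}
    for k in range(1, MAX_K + 1):
        offsets[k] = len(kmers)
        kms = _enumerate_kmers(k)
        w = np.zeros((len(kms), 5, k), dtype=np.float32)
        for i, m in enumerate(kms):
            for j, c in enumerate(m):
                w[i, ROW_ORDER.index(c), j] = 1.0
        weights[k] = w.reshape(len(kms), 5 * k)
        kmers.extend(kms)
    index = {m: i for i, m in enumerate(kmers)}
    return KmerFilterBank(kmers=kmers, weights=weights, offsets=offsets, index=index)


@dataclass
class KmerVector:
    """Counts of all 5460 k-mers of a sequence of length ``n``."""

    counts: np.ndarray  # (5460,) int64
    n: int

    def count(self, kmer: str, bank: KmerFilterBank) -> int:
        return int(self.counts[bank.index_of(kmer)])


def _as_matrix(w) -> tuple[np.ndarray, int]:
    if isinstance(w, OneHotWindow):
        return w.matrix[:, : w.seq_len], w.seq_len
    m = np.asarray(w, dtype=np.float32)
    if m.ndim != 2 or m.shape[0] != 5:
        raise ValueError("expected a 5xn one-hot matrix")
    return m, m.shape[1]


def count_kmers_conv(
    w, bank: KmerFilterBank, position_chunk: int = 8192
) -> KmerVector:
    """Count k-mers of a one-hot matrix by rectified cross-correlation.

    For each filter width k, every valid position of the matrix is scored
    against all 4^k filters (a single matrix product), the bias ``1 - k``
    is added, negatives are clamped to zero and the rectified scores are
    summed over positions.  Scores are small integers, exact in float32.
    """
    m, n = _as_matrix(w)
    counts = np.zeros(N_KMERS, dtype=np.int64)
    for k in range(1, MAX_K + 1):
        npos = n - k + 1
        if npos < 1:
            continue
        wk = bank.weights[k]  # (4^k, 5k)
        o = bank.offsets[k]
        acc = np.zeros(wk.shape[0], dtype=np.float64)
        # patches: (npos, 5, k) view -> (chunk, 5k) contiguous per chunk
        sl = np.lib.stride_tricks.sliding_window_view(m, k, axis=1)  # (5, npos, k)
        for lo in range(0, npos, position_chunk):
            hi = min(lo + position_chunk, npos)
            patch = np.ascontiguousarray(sl[:, lo:hi].transpose(1, 0, 2)).reshape(hi - lo, 5 * k)
            scores = patch @ wk.T
            scores += np.float32(1 - k)
            np.maximum(scores, 0.0, out=scores)
            acc += scores.sum(axis=0, dtype=np.float64)
        counts[o : o + wk.shape[0]] = np.rint(acc).astype(np.int64)
    return KmerVector(counts=counts, n=n)


def count_kmers_fast(seq: str, bank: KmerFilterBank) -> KmerVector:
    """Vectorised rolling-code counter (production bulk route).

    Encodes bases as integers 0..3 (N = 4), forms the base-4 code of every
    window by summing shifted arrays, masks windows touching an N and
    tallies with ``bincount``.
    """
    codes = _LEX_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    is_n = codes == 4
    counts = np.zeros(N_KMERS, dtype=np.int64)
    for k in range(1, MAX_K + 1):
        npos = n - k + 1
        if npos < 1:
            continue
        code = np.zeros(npos, dtype=np.int64)
        bad = np.zeros(npos, dtype=bool)
        for j in range(k):
            code = code * 4 + codes[j : j + npos]
            bad |= is_n[j : j + npos]
        valid = code[~bad]
        o = bank.offsets[k]
        counts[o : o + 4**k] = np.bincount(valid, minlength=4**k)
    return KmerVector(counts=counts, n=n)


def count_kmers_oracle(seq: str, bank: KmerFilterBank) -> KmerVector:
    """Naive sliding-window substring counter (verification oracle).

    Tallies every length-k substring with a Counter; substrings containing
    characters outside {A,C,G,T} are simply absent from the bank's index
    and ignored.
    """
    from collections import Counter

    counts = np.zeros(N_KMERS, dtype=np.int64)
    n = len(seq)
    idx = bank.index
    for k in range(1, MAX_K + 1):
        tally = Counter(seq[i : i + k] for i in range(n - k + 1))
        for sub, c in tally.items():
            j = idx.get(sub)
            if j is not None:
                counts[j] += c
    return KmerVector(counts=counts, n=n)


def batch_count(
    elements, bank: KmerFilterBank, batch_size: int = 32
) -> list[KmerVector]:
    """Convolutional counts for a list of one-hot matrices.

    ``batch_size`` only controls grouping of the work; the result is
    independent of it and preserves input order.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out: list[KmerVector] = []
    for lo in range(0, len(elements), batch_size):
        for el in elements[lo : lo + batch_size]:
            out.append(count_kmers_conv(el, bank))
    return out


def kmer_matrix(seqs: list[str], bank: KmerFilterBank) -> np.ndarray:
    """Stack fast-route count vectors of many sequences into (n, 5460)."""
    return np.stack([count_kmers_fast(s, bank).counts for s in seqs]).astype(np.float64)
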