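"""q-gram bins, binary bin signatures, and FIR word-density filtering.

A *bin* is one q-gram word over {A, C, G, T}; the 4^q bins are kept in
lexicographic order.  The *bin signature* S_j of a sequence marks every
start position where bin b_j occurs (a bit vector of length n - q + 1).
Passing a signature through a causal FIR filter

    y[n] = sum_{i=0..k} b_i * x[n - i],     x[m] = 0 for m < 0,

yields the local word density.  With a uniform unit window of width W the
filter is literally a trailing occurrence counter: y[i] is the number of
occurrences of the bin starting in the last W signature positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from qgramfir.sequence_io import SequenceRecord

NUCLEOTIDES = "ACGT"

#: Practical guard: 4^12 ≈ 16.8M bins is the largest alphabet we will enumerate.
MAX_Q = 12


@dataclass(frozen=True)
class QGramAlphabet:
    """The 4^q q-gram bins in lexicographic order (A < C < G < T)."""

    q: int
    bins: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.bins)

    def index(self, bin_word: str) -> int:
        """Lexicographic rank of a bin, computed positionally in O(q)."""
        if len(bin_word) != self.q or any(c not in NUCLEOTIDES for c in bin_word):
            raise ValueError(f"{bin_word!r} is not a {self.q}-gram over ACGT")
        rank = 0
        for c in bin_word:
            rank = rank * 4 + NUCLEOTIDES.index(c)
        return rank


def enumerate_bins(q: int) -> QGramAlphabet:
    """All 4^q bins of word length q, lexicographically ordered."""
    if not isinstance(q, (int, np.integer)) or q < 1:
        raise ValueError(f"word length q must be a positive integer, got {q!r}")
    if q > MAX_Q:
        raise ValueError(f"q={q} exceeds the supported maximum {MAX_Q} (4^q bins)")
    bins = tuple("".join(p) for p in product(NUCLEOTIDES, repeat=q))
    return QGramAlphabet(q=int(q), bins=bins)


@dataclass(frozen=True)
class BinSignature:
    """Presence/absence bit vector of one bin along a sequence."""

    bin: str
    values: np.ndarray  # uint8, length |seq| - q + 1

    def __len__(self) -> int:
        return len(self.values)


def bin_signature(seq: str, bin_word: str) -> BinSignature:
    """Scan ``seq`` for exact occurrences of ``bin_word``.

    Position α (0-based here, 1-based in messages) is 1 iff
    seq[α : α + q] == bin_word.  Windows overlapping an 'N' are 0 for every
    bin, so column sums across bins may drop below 1 at those positions.
    """
    q = len(bin_word)
    if q < 1:
        raise ValueError("bin must be non-empty")
    if q > len(seq):
        raise ValueError(
            f"bin length {q} exceeds sequence length {len(seq)}; "
            f"no signature positions exist"
        )
    if any(c not in NUCLEOTIDES for c in bin_word):
        raise ValueError(f"bin {bin_word!r} contains characters outside ACGT")
    n_pos = len(seq) - q + 1
    values = np.zeros(n_pos, dtype=np.uint8)
    for alpha in range(n_pos):
        if seq[alpha : alpha + q] == bin_word:
            values[alpha] = 1
    return BinSignature(bin=bin_word, values=values)


@dataclass(frozen=True)
class FilterCoefficients:
    """Weights b_0..b_k of a causal FIR filter of order k (k + 1 taps)."""

    b: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.b, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("filter needs at least one tap in a 1-D coefficient vector")
        if not np.all(np.isfinite(arr)):
            raise ValueError("filter coefficients must be finite")
        object.__setattr__(self, "b", arr)

    @property
    def order(self) -> int:
        return len(self.b) - 1

    def __len__(self) -> int:
        return len(self.b)


def uniform_window(W: int, normalize: bool = False) -> FilterCoefficients:
    """A uniform sliding window of width W: unit taps, or 1/W taps if normalized."""
    if not isinstance(W, (int, np.integer)) or W < 1:
        raise ValueError(f"window width W must be a positive integer, got {W!r}")
    taps = np.full(int(W), 1.0 / W if normalize else 1.0)
    return FilterCoefficients(taps)


def fir_filter(x: Sequence[float] | np.ndarray, coeffs: FilterCoefficients) -> np.ndarray:
    """Causal FIR convolution with zero initial conditions, truncated to len(x)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("input signal must be a non-empty 1-D vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("input signal contains non-finite values")
    return lfilter(coeffs.b, [1.0], x)


@dataclass
class DensityProfile:
    """FIR-filtered density rows for every bin of one sequence, in alphabet order."""

    seq_id: str
    q: int
    rows: np.ndarray  # shape (4^q, n - q + 1)
    window: FilterCoefficients = field(repr=False)

    @property
    def n_positions(self) -> int:
        return self.rows.shape[1]

    def flatten(self) -> np.ndarray:
        """Bin-major concatenation: all positions of bin 1, then bin 2, ..."""
        return self.rows.reshape(-1)


def density_profile(record: SequenceRecord, q: int, coeffs: FilterCoefficients) -> DensityProfile:
    """Compute the full 4^q-row density profile of one sequence.

    Row j is fir_filter(bin_signature(seq, bin_j), coeffs); rows follow the
    lexicographic bin order of :func:`enumerate_bins`.
    """
    alphabet = enumerate_bins(q)
    if len(record.seq) < q:
        raise ValueError(
            f"record {record.id!r}: length {len(record.seq)} is shorter than q={q}"
        )
    n_pos = len(record.seq) - q + 1
    rows = np.empty((len(alphabet), n_pos), dtype=float)
    # One pass over the sequence instead of 4^q scans: rank each window.
    sig = np.zeros((len(alphabet), n_pos), dtype=np.uint8)
    seq = record.seq
    for alpha in range(n_pos):
        word = seq[alpha : alpha + q]
        if "N" in word:
            continue
        sig[alphabet.index(word), alpha] = 1
    for j in range(len(alphabet)):
        rows[j] = fir_filter(sig[j], coeffs)
    return DensityProfile(seq_id=record.id, q=q, rows=rows, window=coeffs)
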