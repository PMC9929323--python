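"""Sequence-space bookkeeping for randomized oligonucleotide pools.

The survival assay reads 16-mers of layout ``tail + N_8 + tail`` (default
tail ``ACAC``).  All downstream analysis works on k-mer *classes*: the k
bases occupying the central window of the randomized octamer, with the
remaining random positions summed out ("marginalized").  A class therefore
always has fully randomized neighbors on both sides, which is what makes
flank-averaged damage models applicable.

Sequences are enumerated in alphabetical base-4 order (A=0 < C=1 < G=2 <
T=3, leftmost base most significant), so ``AAAAAA`` is hexamer 0 and
``TTTTTT`` is hexamer 4095.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

BASES = "ACGT"
PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
G_DIGIT = BASES.index("G")

_BASE_TO_DIGIT = {b: i for i, b in enumerate(BASES)}

MAX_K = 8


def index_of(sequence: str) -> int:
    """Base-4 index of a k-mer (A=0, C=1, G=2, T=3, leftmost most significant).

    >>> index_of("TCGGTA")
    3500
    """
    k = len(sequence)
    if not 1 <= k <= MAX_K:
        raise ValueError(f"sequence length must be in 1..{MAX_K}, got {k}")
    idx = 0
    for ch in sequence:
        try:
            idx = idx * 4 + _BASE_TO_DIGIT[ch]
        except KeyError:
            raise ValueError(
                f"non-ACGT character {ch!r} in sequence {sequence!r}"
            ) from None
    return idx


def seq_of(index: int, k: int) -> str:
    """Inverse of :func:`index_of`: the k-mer with the given base-4 index."""
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in 1..{MAX_K}, got {k}")
    if not 0 <= index < 4**k:
        raise ValueError(f"index {index} out of range for k={k}")
    out = []
    for _ in range(k):
        out.append(BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


@functools.lru_cache(maxsize=None)
def all_kmers(k: int) -> tuple[str, ...]:
    """All 4**k k-mers in index order."""
    return tuple(seq_of(i, k) for i in range(4**k))


def digits_of(sequence: str) -> np.ndarray:
    """Sequence as an int8 digit array (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_BASE_TO_DIGIT[b] for b in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in {sequence!r}") from exc


@functools.lru_cache(maxsize=None)
def digit_matrix(k: int) -> np.ndarray:
    """(4**k, k) digit matrix of all k-mers in index order (read-only)."""
    idx = np.arange(4**k)
    mat = (idx[:, None] // 4 ** np.arange(k - 1, -1, -1)[None, :]) % 4
    mat = mat.astype(np.int8)
    mat.setflags(write=False)
    return mat


def central_window(k: int, parent_length: int) -> tuple[int, int]:
    """1-based inclusive positions of the centered k-window in a parent mer.

    Only symmetric trimming is defined: ``parent_length - k`` must be even,
    so that the window keeps randomized neighbors on both sides.
    """
    if k < 1 or parent_length < 1:
        raise ValueError("lengths must be positive")
    if k > parent_length:
        raise ValueError(f"window k={k} exceeds parent length {parent_length}")
    if (parent_length - k) % 2:
        raise ValueError(
            f"no central window: parent {parent_length} minus k={k} is odd"
        )
    start = (parent_length - k) // 2 + 1
    return (start, start + k - 1)


@dataclass
class CountTable:
    """Read counts per sequence class per dose level.

    Attributes
    ----------
    counts:
        Integer array of shape ``(4**k, n_doses)``; row order is the base-4
        sequence index.
    doses:
        Absorbed photons per base, strictly increasing, first entry 0.
    k:
        Class length in bases (8 for the raw octamer table).
    tail:
        Fixed flanking sequence of the construct the counts came from.
    """

    counts: np.ndarray
    doses: np.ndarray
    k: int
    tail: str = "ACAC"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4**self.k:
            raise ValueError(
                f"counts must have shape (4**{self.k}, n_doses), "
                f"got {self.counts.shape}"
            )
        if self.counts.shape[1] != self.doses.size:
            raise ValueError("counts and doses disagree on the number of dose levels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.doses.size == 0 or self.doses[0] != 0.0:
            raise ValueError("dose schedule must start at 0")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")

    @property
    def n_doses(self) -> int:
        return self.doses.size

    @property
    def sequences(self) -> tuple[str, ...]:
        return all_kmers(self.k)

    @property
    def totals(self) -> np.ndarray:
        """Total reads per dose level."""
        return self.counts.sum(axis=0)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(self.sequences, name="sequence"),
            columns=[f"{d:.10g}" for d in self.doses],
        )
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, tail: str = "ACAC") -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="sequence")
        k = len(str(df.index[0]))
        if len(df) != 4**k:
            raise ValueError(
                f"expected a complete table of 4**{k} sequences, got {len(df)} rows"
            )
        order = np.argsort([index_of(s) for s in df.index])
        counts = df.to_numpy()[order]
        doses = np.array([float(c) for c in df.columns])
        return cls(counts=counts, doses=doses, k=k, tail=tail)


def marginalize(table: CountTable, k: int) -> CountTable:
    """Sum octamer (or longer-mer) counts down to central k-mer class counts.

    The count of class ``s`` is the sum over all parent sequences carrying
    ``s`` at the central window.  Per-dose totals are conserved exactly.
    """
    parent = table.k
    central_window(k, parent)  # validates k (symmetric, k <= parent)
    m = (parent - k) // 2
    if m == 0:
        return replace(table, counts=table.counts.copy())
    shaped = table.counts.reshape(4**m, 4**k, 4**m, table.n_doses)
    out = shaped.sum(axis=(0, 2))
    return CountTable(counts=out, doses=table.doses.copy(), k=k, tail=table.tail)
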