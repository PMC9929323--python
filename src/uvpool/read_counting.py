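"""FASTQ to count-table conversion by framing-tag and quality filtering.

A read is counted iff both copies of the framing tag match exactly at their
expected positions (layout ``tag + random + tag``, anchored at the first
base) and every base of the central randomer has a Phred quality strictly
greater than the threshold.  Tail-base qualities are not checked — the
tails are discarded anyway.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .sequence_space import BASES, CountTable, _BASE_TO_DIGIT


@dataclass
class ReadFilterConfig:
    """Framing-tag layout and quality threshold of the read filter."""

    tag: str = "ACAC"
    min_quality: int = 20  # octamer bases must have Phred strictly above this
    random_length: int = 8

    def __post_init__(self) -> None:
        if any(b not in BASES for b in self.tag):
            raise ValueError("tag must be over ACGT")
        if self.min_quality < 0:
            raise ValueError("min_quality must be non-negative")
        if not 1 <= self.random_length <= 8:
            raise ValueError("random_length must be in 1..8")

    @property
    def read_length(self) -> int:
        return 2 * len(self.tag) + self.random_length


@dataclass
class FilterReport:
    """Per-file accounting; passed + failed_tag + failed_quality == total."""

    path: str
    total: int = 0
    passed: int = 0
    failed_tag: int = 0
    failed_quality: int = 0

    def as_dict(self) -> dict:
        return {
            "path": self.path,
            "total": self.total,
            "passed": self.passed,
            "failed_tag": self.failed_tag,
            "failed_quality": self.failed_quality,
        }


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_reads(
    fastq_path, config: ReadFilterConfig | None = None
) -> tuple[np.ndarray, FilterReport]:
    """Count central randomers of one FASTQ file (one dose level).

    Returns the dense per-class count column (length ``4**random_length``)
    and a :class:`FilterReport`.  Reads whose randomer contains a non-ACGT
    base are rejected as layout (tag) failures.  An empty file yields an
    all-zero column.
    """
    config = config or ReadFilterConfig()
    tag = config.tag
    t = len(tag)
    L = config.random_length
    need = config.read_length
    # Phred+33: octamer passes iff its worst quality char sorts above this one
    min_q_char = chr(33 + config.min_quality)
    counts = np.zeros(4**L, dtype=np.int64)
    report = FilterReport(path=str(fastq_path))
    base_digit = _BASE_TO_DIGIT
    with _open_maybe_gzip(fastq_path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                report.total += 1
                if len(seq) < need:
                    report.failed_tag += 1
                    continue
                if seq[:t] != tag or seq[t + L : need] != tag:
                    report.failed_tag += 1
                    continue
                if min(qual[t : t + L]) <= min_q_char:
                    report.failed_quality += 1
                    continue
                idx = 0
                try:
                    for ch in seq[t : t + L]:
                        idx = idx * 4 + base_digit[ch]
                except KeyError:
                    report.failed_tag += 1
                    continue
                counts[idx] += 1
                report.passed += 1
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ in {fastq_path} near record {report.total + 1}: {exc}"
            ) from exc
    return counts, report


def count_files(
    fastq_paths: Sequence, doses: Iterable[float], config: ReadFilterConfig | None = None
) -> tuple[CountTable, list[FilterReport]]:
    """Count a dose series of FASTQ files into a :class:`CountTable`.

    ``fastq_paths`` and ``doses`` must align; doses must be ascending from 0.
    """
    config = config or ReadFilterConfig()
    doses = np.asarray(list(doses), dtype=float)
    fastq_paths = list(fastq_paths)
    if len(fastq_paths) != doses.size:
        raise ValueError("one FASTQ file per dose level required")
    columns = []
    reports = []
    for path in fastq_paths:
        col, rep = count_reads(path, config)
        columns.append(col)
        reports.append(rep)
    table = CountTable(
        counts=np.stack(columns, axis=1),
        doses=doses,
        k=config.random_length,
        tail=config.tag,
    )
    return table, reports
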