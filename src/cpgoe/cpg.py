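"""Nucleotide/dinucleotide content and the CpG observed/expected statistic.

For a region of effective length N (unambiguous A/C/G/T bases) with C
cytosines, G guanines and CpG occurrences of the CpG dinucleotide,

    CpG[o/e] = N * CpG / (C * G)

Values well below 1 indicate historical CpG depletion, the sequence footprint
of germ-line cytosine methylation (methyl-C deaminates to T over evolutionary
time, eroding CpG sites). Dinucleotides are counted with an overlapping scan
of width 2 and step 1; any window touching an ambiguous base is skipped, and
ambiguous bases do not count toward N, C or G.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_io import SequenceRecord

logger = logging.getLogger(__name__)

_BASES = "ACGT"
# byte -> code; A,C,G,T -> 0..3, everything else (ambiguity codes) -> -1
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES.encode()):
    _CODE[_b] = _i

A, C, G, T = 0, 1, 2, 3


class NoUsableSequencesError(ValueError):
    """Raised when every input sequence is excluded from a batch computation."""


def _encode(residues: str) -> np.ndarray:
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def count_dinucleotides(seq: SequenceRecord) -> dict[str, int]:
    """Count the 4 nucleotides and 16 dinucleotides of a sequence.

    Returns a dict keyed by one-letter (nucleotide) and two-letter
    (dinucleotide) strings. Windows containing an ambiguous base are skipped;
    nucleotide counts cover unambiguous bases only. Empty input gives all
    zeros.
    """
    codes = _encode(seq.residues)
    counts: dict[str, int] = {}
    nuc = np.bincount(codes[codes >= 0], minlength=4)
    for i, base in enumerate(_BASES):
        counts[base] = int(nuc[i])
    if len(codes) >= 2:
        left, right = codes[:-1], codes[1:]
        valid = (left >= 0) & (right >= 0)
        pair_idx = left[valid].astype(np.int64) * 4 + right[valid]
        dinuc = np.bincount(pair_idx, minlength=16)
    else:
        dinuc = np.zeros(16, dtype=np.int64)
    for i, b1 in enumerate(_BASES):
        for j, b2 in enumerate(_BASES):
            counts[b1 + b2] = int(dinuc[i * 4 + j])
    return counts


@dataclass(frozen=True)
class CpGStats:
    """Per-sequence counts and the CpG[o/e] value.

    ``cpg_oe`` is NaN when undefined (C == 0 or G == 0), with the reason
    recorded in ``undefined_reason``.
    """

    seq_id: str
    n: int
    c: int
    g: int
    cpg: int
    cpg_oe: float
    undefined_reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.undefined_reason is None


def cpg_oe(seq: SequenceRecord) -> CpGStats:
    """Compute CpG[o/e] = N*CpG/(C*G) for one sequence.

    N is the count of unambiguous bases; CpG comes from the overlapping
    two-base scan. When C or G is zero the value is undefined (NaN) and the
    reason is recorded; no exception is raised.
    """
    codes = _encode(seq.residues)
    mask = codes >= 0
    n = int(mask.sum())
    counts = np.bincount(codes[mask], minlength=4)
    c, g = int(counts[C]), int(counts[G])
    if len(codes) >= 2:
        cpg = int(np.count_nonzero((codes[:-1] == C) & (codes[1:] == G)))
    else:
        cpg = 0
    if c == 0 or g == 0:
        missing = "C" if c == 0 else "G"
        return CpGStats(seq.id, n, c, g, cpg, math.nan, f"no {missing} bases")
    return CpGStats(seq.id, n, c, g, cpg, n * cpg / (c * g))


@dataclass(frozen=True)
class ExclusionSummary:
    too_short: int
    undefined: int
    kept: int

    def as_dict(self) -> dict[str, int]:
        return {
            "too_short": self.too_short,
            "undefined": self.undefined,
            "kept": self.kept,
        }


def cpg_oe_table(
    seqs: Sequence[SequenceRecord], min_length: int = 200
) -> tuple[list[CpGStats], ExclusionSummary]:
    """Compute CpG[o/e] for a batch, excluding unusable sequences.

    Sequences with effective length N < ``min_length`` are excluded as too
    short; sequences with undefined o/e are excluded as undefined. Output
    order matches input order. Raises :class:`NoUsableSequencesError` when
    nothing survives (including empty input).
    """
    kept: list[CpGStats] = []
    too_short = 0
    undefined = 0
    for seq in seqs:
        stats = cpg_oe(seq)
        if stats.n < min_length:
            too_short += 1
        elif not stats.defined:
            undefined += 1
        else:
            kept.append(stats)
    summary = ExclusionSummary(too_short, undefined, len(kept))
    if not kept:
        raise NoUsableSequencesError(
            f"no usable sequences (too_short={too_short}, undefined={undefined})"
        )
    if too_short or undefined:
        logger.info(
            "cpg_oe_table: kept %d, excluded %d too-short and %d undefined",
            len(kept),
            too_short,
            undefined,
        )
    return kept, summary


def stats_frame(stats: Iterable[CpGStats]) -> pd.DataFrame:
    """Tabulate CpGStats as a 6-column DataFrame (seq_id, N, C, G, CpG, cpg_oe)."""
    rows = [(s.seq_id, s.n, s.c, s.g, s.cpg, s.cpg_oe) for s in stats]
    return pd.DataFrame(rows, columns=["seq_id", "N", "C", "G", "CpG", "cpg_oe"])


def write_stats_tsv(stats: Iterable[CpGStats], path: str | Path) -> None:
    """Write the per-sequence statistic table as TSV ('NA' for undefined values)."""
    frame = stats_frame(stats)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_values_tsv(path: str | Path, column: str = "cpg_oe") -> np.ndarray:
    """Read a numeric value column from a TSV (header optional).

    Uses ``column`` when a header is present and names it, otherwise the first
    column. 'NA' entries are dropped with a logged count; any other
    non-numeric entry raises ValueError listing the offending rows (1-based,
    excluding the header).
    """
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty values table")
    token = first.split("\t")[0].strip()
    try:
        float(token)
        header = None
    except ValueError:
        header = 0
    table = pd.read_csv(path, sep="\t", header=header, dtype=str, keep_default_na=False)
    if header is not None and column in table.columns:
        raw = table[column]
    else:
        raw = table.iloc[:, 0]
    raw = raw.str.strip()
    is_na = raw.isin({"NA", "NaN", "nan", ""})
    values = pd.to_numeric(raw.where(~is_na), errors="coerce")
    bad = values.isna() & ~is_na
    if bad.any():
        rows = [int(i) + 1 for i in np.flatnonzero(bad.to_numpy())][:20]
        raise ValueError(f"{path}: non-numeric entries at data row(s) {rows}")
    if int(is_na.sum()):
        logger.info("%s: dropped %d NA value(s)", path, int(is_na.sum()))
    return values.dropna().to_numpy(dtype=float)
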