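"""Read quality control: three whole-read removal rules on FASTQ input.

A read is removed if any of the following holds, tested in order (the first
failing rule is the one credited in the report):

1. at least 10% of its bases are N;
2. more than 50% of its bases have phred quality below 5;
3. more than 10 nt align ungapped to the adapter with at most 10% mismatches.

Reads are removed whole, never trimmed. Phred encoding is fixed at +33.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

N_FRAC_MAX = 0.10          # rule 1, inclusive (>= removes)
PHRED_MIN = 5              # rule 2 quality floor
LOWQ_FRAC_MAX = 0.50       # rule 2, strict (> removes)
ADAPTER_MATCH_MAX = 10     # rule 3, strict (> removes)
ADAPTER_MISMATCH_FRAC = 0.10

_BASE_CODE = {c: i for i, c in enumerate("ACGTN")}


@dataclass
class ReadRecord:
    identifier: str
    bases: str
    quals: np.ndarray  # integer phred scores, same length as bases

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"record {self.identifier!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )


@dataclass
class QCReport:
    total_in: int = 0
    removed_n_rule: int = 0
    removed_quality_rule: int = 0
    removed_adapter_rule: int = 0

    @property
    def kept(self) -> int:
        return (
            self.total_in
            - self.removed_n_rule
            - self.removed_quality_rule
            - self.removed_adapter_rule
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            fh.write(f"total_in\t{self.total_in}\n")
            fh.write(f"removed_n_rule\t{self.removed_n_rule}\n")
            fh.write(f"removed_quality_rule\t{self.removed_quality_rule}\n")
            fh.write(f"removed_adapter_rule\t{self.removed_adapter_rule}\n")
            fh.write(f"kept\t{self.kept}\n")


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_CODE.get(c, 4) for c in seq), dtype=np.int8, count=len(seq))


def adapter_match_len(
    read_bases: str, adapter: str, max_mismatch_frac: float = ADAPTER_MISMATCH_FRAC
) -> int:
    """Longest ungapped alignment between any adapter substring and any read
    position with mismatches <= floor(max_mismatch_frac * length).

    Every diagonal (relative offset of adapter against read) is scanned; on a
    diagonal, cumulative mismatch counts give the mismatch total of every
    (start, length) window, and the longest window within budget wins.
    Returns 0 for an empty read or when no alignment qualifies.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not read_bases:
        return 0
    r = _encode(read_bases)
    a = _encode(adapter)
    n, m = len(r), len(a)
    best = 0
    # offset d: adapter position j aligns with read position j + d
    for d in range(-(m - 1), n):
        j0 = max(0, -d)
        j1 = min(m, n - d)
        L = j1 - j0
        if L <= best:
            continue
        mism = (r[j0 + d : j1 + d] != a[j0:j1]).astype(np.int32)
        cs = np.concatenate(([0], np.cumsum(mism)))
        # windows [s, s+k) on this diagonal
        for k in range(L, best, -1):
            budget = int(max_mismatch_frac * k)  # floor
            window = cs[k:] - cs[: L - k + 1]
            if window.min() <= budget:
                best = k
                break
    return best


def _fails_rule(read: ReadRecord, adapter: Optional[str]) -> Optional[str]:
    n = len(read.bases)
    if read.bases.count("N") / n >= N_FRAC_MAX:
        return "n"
    if (read.quals < PHRED_MIN).sum() / n > LOWQ_FRAC_MAX:
        return "quality"
    if adapter and adapter_match_len(read.bases, adapter) > ADAPTER_MATCH_MAX:
        return "adapter"
    return None


def parse_fastq(path) -> Iterator[ReadRecord]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            quals = np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int32) - 33
            yield ReadRecord(title.split()[0], seq, quals)


def filter_reads(
    reads: Iterable[ReadRecord], adapter: Optional[str] = None
) -> tuple[list[ReadRecord], QCReport]:
    """Apply the three removal rules; returns surviving reads and the report."""
    report = QCReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.total_in += 1
        rule = _fails_rule(read, adapter)
        if rule is None:
            kept.append(read)
        elif rule == "n":
            report.removed_n_rule += 1
        elif rule == "quality":
            report.removed_quality_rule += 1
        else:
            report.removed_adapter_rule += 1
    return kept, report


def filter_fastq_file(
    fastq_in, fastq_out, adapter: Optional[str] = None
) -> QCReport:
    """Stream a FASTQ file through the filters, writing survivors."""
    kept, report = filter_reads(parse_fastq(fastq_in), adapter)
    with open(fastq_out, "w") as fh:
        for read in kept:
            qual = "".join(chr(int(q) + 33) for q in read.quals)
            fh.write(f"@{read.identifier}\n{read.bases}\n+\n{qual}\n")
    return report
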