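"""Read-level preprocessing for UID-tagged sequencing data.

Molecule tagging attaches a short random oligonucleotide (a UID, elsewhere
called a UMI) to each input DNA molecule before amplification, so every
sequenced read descending from one molecule carries the same tag.  Before
reads can be grouped by molecule the tag bases have to be located, removed
from the sequence line and preserved in the read header, and reads that
would corrupt grouping (low quality, mostly-N, tag containing N) have to be
discarded.  This module implements that preprocessing as a stream over
paired FASTQ files:

    filter -> adapter trim -> UID extraction -> tagged FASTQ

The UID placement is declarative (:class:`UIDConfig`): tagging protocols
put tag bases at the 5' and/or 3' end of either mate, so each of the four
read ends carries an independently configurable number of tag bases.  The
extracted UID is the concatenation, in fixed order, of mate1 5', mate1 3',
mate2 5', mate2 3' bases, and is appended to the read id with a single
reserved delimiter so it survives FASTQ -> SAM -> grouping round trips.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pysam

UID_DELIMITER = ":"

_VALID_ADAPTER_CHARS = set("ACGTN")


class DropReason(str, Enum):
    """Why a read pair was removed from the stream."""

    N_RUN = "N_RUN"
    LOW_QUALITY = "LOW_QUALITY"
    TOO_SHORT = "TOO_SHORT"
    UID_AMBIGUOUS = "UID_AMBIGUOUS"


@dataclass(frozen=True)
class UIDConfig:
    """Declarative description of where UID bases sit on each mate.

    Parameters
    ----------
    mate1_five_prime_len, mate1_three_prime_len,
    mate2_five_prime_len, mate2_three_prime_len
        Number of UID bases at each read end.  At least one must be > 0.
        The common dual-tag protocol (five bases ligated to each end of
        the fragment) is ``mate1_five_prime_len=5, mate2_five_prime_len=5``
        because mate2's 5' end reads the fragment's 3' end.
    adapters
        Adapter sequences to trim before UID extraction (adapter
        read-through would otherwise contaminate the tag bases).
    min_mean_quality
        Pairs where either mate's mean Phred quality falls below this are
        dropped (inclusive boundary: equal passes).
    max_n_fraction
        Pairs where either mate's fraction of N calls exceeds this are
        dropped.
    min_adapter_overlap
        Minimum bases of adapter prefix that must overlap the read 3' end
        for a partial (end-overlap) adapter match.
    """

    mate1_five_prime_len: int = 5
    mate2_five_prime_len: int = 5
    mate1_three_prime_len: int = 0
    mate2_three_prime_len: int = 0
    adapters: tuple[str, ...] = ()
    min_mean_quality: float = 20.0
    max_n_fraction: float = 0.5
    min_adapter_overlap: int = 5

    def __post_init__(self) -> None:
        lens = (
            self.mate1_five_prime_len,
            self.mate2_five_prime_len,
            self.mate1_three_prime_len,
            self.mate2_three_prime_len,
        )
        if any(n < 0 for n in lens):
            raise ValueError("UID length fields must be >= 0")
        if sum(lens) == 0:
            raise ValueError("at least one UID length field must be > 0")
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must lie in [0, 1]")
        object.__setattr__(
            self, "adapters", tuple(a.upper() for a in self.adapters)
        )
        for a in self.adapters:
            if not a or not set(a) <= _VALID_ADAPTER_CHARS:
                raise ValueError(f"adapter {a!r} contains non-ACGTN characters")

    @property
    def total_uid_len(self) -> int:
        return (
            self.mate1_five_prime_len
            + self.mate2_five_prime_len
            + self.mate1_three_prime_len
            + self.mate2_three_prime_len
        )


@dataclass(frozen=True)
class ReadPair:
    """One raw paired-end record (sequence + Phred+33 quality per mate)."""

    read_id: str
    mate1_seq: str
    mate1_qual: str
    mate2_seq: str
    mate2_qual: str

    def validate(self) -> None:
        if len(self.mate1_seq) != len(self.mate1_qual) or len(
            self.mate2_seq
        ) != len(self.mate2_qual):
            raise ValueError(
                f"read {self.read_id!r}: sequence/quality length mismatch"
            )


@dataclass(frozen=True)
class TaggedReadPair:
    """A read pair after UID extraction.

    ``read_id`` is the original id (first whitespace token) with the UID
    appended after :data:`UID_DELIMITER`; the mate sequences have the UID
    bases removed, qualities trimmed in lockstep.
    """

    read_id: str
    uid: str
    mate1_seq: str
    mate1_qual: str
    mate2_seq: str
    mate2_qual: str


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: DropReason | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.keep


KEEP = FilterDecision(True)


def mean_phred(qual: str) -> float:
    """Mean Phred score of a Phred+33 quality string."""
    if not qual:
        return 0.0
    return sum(ord(c) - 33 for c in qual) / len(qual)


def n_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return seq.upper().count("N") / len(seq)


def filter_read_pair(pair: ReadPair, cfg: UIDConfig) -> FilterDecision:
    """Keep/drop decision for one pair; mates are always dropped together.

    A pair is dropped with reason ``N_RUN`` if either mate's N fraction
    exceeds ``cfg.max_n_fraction``, with reason ``LOW_QUALITY`` if either
    mate's mean Phred is below ``cfg.min_mean_quality`` (a mean exactly at
    the threshold passes).
    """
    pair.validate()
    if (
        n_fraction(pair.mate1_seq) > cfg.max_n_fraction
        or n_fraction(pair.mate2_seq) > cfg.max_n_fraction
    ):
        return FilterDecision(False, DropReason.N_RUN)
    if (
        mean_phred(pair.mate1_qual) < cfg.min_mean_quality
        or mean_phred(pair.mate2_qual) < cfg.min_mean_quality
    ):
        return FilterDecision(False, DropReason.LOW_QUALITY)
    return KEEP


def trim_adapters(
    seq: str,
    qual: str,
    adapters: Iterable[str],
    min_overlap: int = 5,
) -> tuple[str, str]:
    """Remove the leftmost adapter occurrence and everything 3' of it.

    Two match modes: an exact full-adapter substring anywhere in the read,
    or a read 3'-end suffix equal to an adapter prefix of at least
    ``min_overlap`` bases (adapter running off the end of the read).
    No mismatches are tolerated; adapter-free reads pass unchanged, which
    makes the operation idempotent.
    """
    cut = len(seq)
    useq = seq.upper()
    for adapter in adapters:
        if not adapter:
            continue
        pos = useq.find(adapter)
        if pos != -1:
            cut = min(cut, pos)
        # adapter prefix overlapping the read's 3' end
        max_ov = min(len(adapter) - 1, len(useq))
        for ov in range(max_ov, min_overlap - 1, -1):
            if useq.endswith(adapter[:ov]):
                cut = min(cut, len(useq) - ov)
                break
    return seq[:cut], qual[:cut]


def extract_uid(
    pair: ReadPair, cfg: UIDConfig
) -> TaggedReadPair | FilterDecision:
    """Move UID bases from the sequence lines into the read id.

    The UID is assembled in fixed order (mate1 5', mate1 3', mate2 5',
    mate2 3'); the corresponding bases and qualities are removed from each
    mate.  Pairs where a mate is shorter than its configured UID allotment
    plus one insert base are dropped (``TOO_SHORT``); pairs whose UID
    contains an N are dropped (``UID_AMBIGUOUS``) rather than forming
    ambiguous groups.
    """
    pair.validate()
    f1, t1 = cfg.mate1_five_prime_len, cfg.mate1_three_prime_len
    f2, t2 = cfg.mate2_five_prime_len, cfg.mate2_three_prime_len
    if len(pair.mate1_seq) < f1 + t1 + 1 or len(pair.mate2_seq) < f2 + t2 + 1:
        return FilterDecision(False, DropReason.TOO_SHORT)

    m1, q1 = pair.mate1_seq, pair.mate1_qual
    m2, q2 = pair.mate2_seq, pair.mate2_qual
    uid = (
        m1[:f1]
        + (m1[len(m1) - t1 :] if t1 else "")
        + m2[:f2]
        + (m2[len(m2) - t2 :] if t2 else "")
    )
    if "N" in uid.upper():
        return FilterDecision(False, DropReason.UID_AMBIGUOUS)

    m1_trim = m1[f1 : len(m1) - t1 or None]
    q1_trim = q1[f1 : len(q1) - t1 or None]
    m2_trim = m2[f2 : len(m2) - t2 or None]
    q2_trim = q2[f2 : len(q2) - t2 or None]
    base_id = pair.read_id.split()[0]
    return TaggedReadPair(
        read_id=f"{base_id}{UID_DELIMITER}{uid}",
        uid=uid,
        mate1_seq=m1_trim,
        mate1_qual=q1_trim,
        mate2_seq=m2_trim,
        mate2_qual=q2_trim,
    )


@dataclass
class ProcessStats:
    """Bookkeeping for one preprocessing run; counts are in read pairs."""

    pairs_in: int = 0
    pairs_kept: int = 0
    dropped: Counter = field(default_factory=Counter)

    def check_conservation(self) -> None:
        if self.pairs_in != self.pairs_kept + sum(self.dropped.values()):
            raise AssertionError("pair accounting does not balance")

    def to_tsv(self) -> str:
        lines = ["metric\tcount", f"pairs_in\t{self.pairs_in}",
                 f"pairs_kept\t{self.pairs_kept}"]
        for reason in DropReason:
            lines.append(f"dropped.{reason.value}\t{self.dropped[reason.value]}")
        return "\n".join(lines) + "\n"


def _open_text_write(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def read_fastq_pairs(
    fastq1: str | Path, fastq2: str | Path
) -> Iterator[ReadPair]:
    """Stream matched records from a paired FASTQ (plain or gzip).

    Raises ``ValueError`` on a record-count mismatch between the mates.
    """
    with pysam.FastxFile(str(fastq1)) as fq1, pysam.FastxFile(
        str(fastq2)
    ) as fq2:
        it1, it2 = iter(fq1), iter(fq2)
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if r1 is None or r2 is None:
                raise ValueError(
                    "record-count mismatch between mate FASTQ files"
                )
            yield ReadPair(
                read_id=r1.name,
                mate1_seq=r1.sequence,
                mate1_qual=r1.quality or "",
                mate2_seq=r2.sequence,
                mate2_qual=r2.quality or "",
            )


def format_fastq_record(read_id: str, seq: str, qual: str) -> str:
    return f"@{read_id}\n{seq}\n+\n{qual}\n"


def process_pairs(
    pairs: Iterable[ReadPair], cfg: UIDConfig
) -> Iterator[TaggedReadPair | tuple[None, DropReason]]:
    """Core streaming composition: filter, trim adapters, extract UID.

    Yields a :class:`TaggedReadPair` for kept pairs and ``(None, reason)``
    for dropped ones, preserving input order.
    """
    for pair in pairs:
        decision = filter_read_pair(pair, cfg)
        if not decision.keep:
            yield None, decision.reason
            continue
        if cfg.adapters:
            s1, q1 = trim_adapters(
                pair.mate1_seq, pair.mate1_qual, cfg.adapters,
                cfg.min_adapter_overlap,
            )
            s2, q2 = trim_adapters(
                pair.mate2_seq, pair.mate2_qual, cfg.adapters,
                cfg.min_adapter_overlap,
            )
            pair = ReadPair(pair.read_id, s1, q1, s2, q2)
        tagged = extract_uid(pair, cfg)
        if isinstance(tagged, FilterDecision):
            yield None, tagged.reason
            continue
        yield tagged


def process_fastq(
    fastq1: str | Path,
    fastq2: str | Path,
    cfg: UIDConfig,
    out1: str | Path,
    out2: str | Path,
) -> ProcessStats:
    """Run the full preprocessing stream over a FASTQ pair.

    Writes tagged FASTQ files (UID in the header, UID bases removed from
    the sequence lines) and returns per-reason statistics whose counts sum
    to the input pair count.
    """
    stats = ProcessStats()
    with _open_text_write(out1) as o1, _open_text_write(out2) as o2:
        for result in process_pairs(read_fastq_pairs(fastq1, fastq2), cfg):
            stats.pairs_in += 1
            if isinstance(result, tuple):
                _, reason = result
                stats.dropped[reason.value] += 1
                continue
            stats.pairs_kept += 1
            o1.write(
                format_fastq_record(
                    result.read_id, result.mate1_seq, result.mate1_qual
                )
            )
            o2.write(
                format_fastq_record(
                    result.read_id, result.mate2_seq, result.mate2_qual
                )
            )
    stats.check_conservation()
    return stats
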