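"""Alignment and per-read variant extraction within BED targets.

This stage turns UID-tagged reads into :class:`PerReadVariant`
observations: each mismatch or small indel seen in one read, with the
read's UID attached, restricted to user-specified target regions.

Two alignment routes are supported.  The built-in aligner
(:class:`BuiltinAligner`) is ungapped (match +1, mismatch -1, gaps
effectively infinitely penalised), which realises the contract that
alignment should be permissive of mismatches but averse to opening gaps;
it exists so the whole pipeline runs on synthetic and test data without
external binaries.  Externally aligned reads (e.g. BWA output) are
ingested from SAM with :func:`ingest_sam`, the UID being carried as the
final delimited token of the read name.

Variant identification is a direct base-by-base comparison of each
aligned read against the reference, walking the CIGAR string — the same
information a samtools-calmd MD-tag round trip would yield, computed
in-process.  Indels are reported left-anchored with one reference base of
context (VCF style); N read bases and soft-clipped bases never yield
observations.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pysam
from pyfaidx import Fasta

from .uid_io import UID_DELIMITER

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Targets


@dataclass(frozen=True, order=True)
class TargetRegion:
    """A target interval, 0-based half-open as in BED."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"target {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, chrom: str, pos1: int) -> bool:
        """Membership of a 1-based position."""
        return chrom == self.chrom and self.start < pos1 <= self.end


def load_targets(bed_source: str | Path | Iterable[str]) -> list[TargetRegion]:
    """Parse BED (>= 3 columns) into merged, sorted target regions.

    Overlapping or abutting regions on one chromosome are merged.  Raises
    ``ValueError`` with the offending line number on malformed input.
    """
    if isinstance(bed_source, (str, Path)):
        with open(bed_source) as fh:
            lines = fh.readlines()
    else:
        lines = list(bed_source)

    raw: list[TargetRegion] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        chrom = cols[0]
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError as exc:
            raise ValueError(f"BED line {lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ValueError(f"BED line {lineno}: start >= end")
        name = cols[3] if len(cols) > 3 else None
        raw.append(TargetRegion(chrom, start, end, name))

    raw.sort(key=lambda r: (r.chrom, r.start, r.end))
    merged: list[TargetRegion] = []
    for region in raw:
        if (
            merged
            and merged[-1].chrom == region.chrom
            and region.start <= merged[-1].end
        ):
            prev = merged[-1]
            merged[-1] = TargetRegion(
                prev.chrom, prev.start, max(prev.end, region.end), prev.name
            )
        else:
            merged.append(region)
    return merged


class TargetLookup:
    """Fast point/interval membership against a merged target list."""

    def __init__(self, targets: Iterable[TargetRegion]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for t in sorted(targets):
            starts, ends = self._by_chrom.setdefault(t.chrom, ([], []))
            starts.append(t.start)
            ends.append(t.end)

    def contains(self, chrom: str, pos1: int) -> bool:
        """True if 1-based position ``pos1`` lies in any target."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect.bisect_right(starts, pos1 - 1) - 1
        return i >= 0 and pos1 - 1 < ends[i]

    def overlaps(self, chrom: str, start0: int, end0: int) -> bool:
        """True if the 0-based half-open interval overlaps any target."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = bisect.bisect_right(starts, end0 - 1) - 1
        return i >= 0 and start0 < ends[i]


# ---------------------------------------------------------------------------
# Reference


class Reference:
    """In-memory reference sequences keyed by chromosome name.

    Accepts a FASTA path (loaded via pyfaidx), a dict of name -> sequence,
    or a bare sequence string (single chromosome named ``ref``).
    """

    def __init__(self, source: str | Path | Mapping[str, str]):
        if isinstance(source, Mapping):
            self._seqs = {k: str(v).upper() for k, v in source.items()}
        else:
            p = Path(source)
            if p.exists():
                fasta = Fasta(str(p))
                self._seqs = {name: str(fasta[name][:]).upper() for name in fasta.keys()}
            else:
                self._seqs = {"ref": str(source).upper()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def seq(self, chrom: str) -> str:
        return self._seqs[chrom]

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        return self._seqs[chrom][start0:end0]


# ---------------------------------------------------------------------------
# Aligned reads


@dataclass
class AlignedRead:
    """One mapped (or unmapped) read in reference orientation.

    ``seq`` is stored as aligned to the reference strand (reverse
    complemented for minus-strand placements), matching SAM convention;
    ``pos`` is the 1-based leftmost mapping coordinate.
    """

    read_id: str
    uid: str
    chrom: str
    pos: int
    strand: str
    cigar: str
    seq: str
    mapped: bool
    qual: str | None = None
    n_mismatches: int | None = None


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


# ---------------------------------------------------------------------------
# Built-in aligner


def _score_placement(read: str, ref: str) -> int:
    """Ungapped score (+1 match, -1 mismatch); strings of equal length."""
    mism = sum(a != b for a, b in zip(read, ref))
    return len(read) - 2 * mism


class BuiltinAligner:
    """Ungapped seed-and-extend aligner over a small reference.

    Candidate placements come from exact k-mer seeds taken at ``n_seeds``
    evenly spaced read offsets (both strands); each candidate is scored
    ungapped and the best placement wins, ties broken by (chrom, leftmost
    coordinate, then + strand).  Any placement with fewer mismatches than
    the number of seeds is guaranteed to be found; ``exhaustive=True``
    scores every offset on both strands instead (the literal best-placement
    contract, quadratic and intended for small references and tests).

    Reads scoring below ``min_score_fraction * len(read)`` are reported
    unmapped.  Gapped placements are never produced: the gap penalty is
    maximal by construction.
    """

    def __init__(
        self,
        reference: Reference,
        seed_len: int = 20,
        n_seeds: int = 4,
        min_score_fraction: float = 0.6,
    ):
        self.reference = reference
        self.seed_len = seed_len
        self.n_seeds = n_seeds
        self.min_score_fraction = min_score_fraction
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom in reference.chroms():
            seq = reference.seq(chrom)
            for i in range(len(seq) - seed_len + 1):
                self._index.setdefault(seq[i : i + seed_len], []).append(
                    (chrom, i)
                )
        self._ref_arrays = {
            chrom: np.frombuffer(
                reference.seq(chrom).encode("ascii"), dtype=np.uint8
            )
            for chrom in reference.chroms()
        }

    def _seed_offsets(self, read_len: int) -> list[int]:
        k = self.seed_len
        if read_len <= k:
            return [0]
        n = self.n_seeds
        span = read_len - k
        return sorted({round(i * span / max(n - 1, 1)) for i in range(n)})

    def _candidates(self, oriented: str) -> set[tuple[str, int]]:
        cands: set[tuple[str, int]] = set()
        L = len(oriented)
        for off in self._seed_offsets(L):
            seed = oriented[off : off + self.seed_len]
            for chrom, i in self._index.get(seed, ()):
                start = i - off
                if 0 <= start <= self.reference.length(chrom) - L:
                    cands.add((chrom, start))
        return cands

    def _exhaustive_best(
        self, oriented: str
    ) -> tuple[int, str, int] | None:
        """Best (score, chrom, start) over all offsets via numpy."""
        L = len(oriented)
        arr = np.frombuffer(oriented.encode("ascii"), dtype=np.uint8)
        best: tuple[int, str, int] | None = None
        for chrom, ref_arr in self._ref_arrays.items():
            if len(ref_arr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(ref_arr, L)
            mism = (windows != arr).sum(axis=1)
            start = int(mism.argmin())
            score = L - 2 * int(mism[start])
            if best is None or score > best[0]:
                best = (score, chrom, start)
        return best

    def align(
        self,
        seq: str,
        read_id: str = "",
        uid: str = "",
        qual: str | None = None,
        exhaustive: bool = False,
    ) -> AlignedRead:
        """Place one read; returns an unmapped record below the score floor."""
        if not seq:
            raise ValueError(f"read {read_id!r}: empty sequence")
        seq = seq.upper()
        L = len(seq)
        rc = reverse_complement(seq)
        best: tuple[int, str, int, str] | None = None  # score, chrom, start, strand

        def consider(score: int, chrom: str, start: int, strand: str) -> None:
            nonlocal best
            if best is None:
                best = (score, chrom, start, strand)
                return
            b_score, b_chrom, b_start, b_strand = best
            if score > b_score:
                best = (score, chrom, start, strand)
            elif score == b_score:
                # leftmost coordinate, then + strand
                if (chrom, start, strand != "+") < (
                    b_chrom,
                    b_start,
                    b_strand != "+",
                ):
                    best = (score, chrom, start, strand)

        if exhaustive:
            for oriented, strand in ((seq, "+"), (rc, "-")):
                hit = self._exhaustive_best(oriented)
                if hit is None:
                    continue
                score, chrom, start = hit
                consider(score, chrom, start, strand)
                # argmin returns leftmost minimum per chrom; tie resolution
                # across strands handled by consider()
        else:
            for oriented, strand in ((seq, "+"), (rc, "-")):
                for chrom, start in self._candidates(oriented):
                    ref_sub = self.reference.fetch(chrom, start, start + L)
                    consider(
                        _score_placement(oriented, ref_sub), chrom, start, strand
                    )

        floor = self.min_score_fraction * L
        if best is None or best[0] < floor:
            return AlignedRead(
                read_id=read_id, uid=uid, chrom="", pos=0, strand="+",
                cigar="", seq=seq, mapped=False, qual=qual,
            )
        score, chrom, start, strand = best
        oriented = seq if strand == "+" else rc
        oriented_qual = qual if (qual is None or strand == "+") else qual[::-1]
        return AlignedRead(
            read_id=read_id,
            uid=uid,
            chrom=chrom,
            pos=start + 1,
            strand=strand,
            cigar=f"{L}M",
            seq=oriented,
            mapped=True,
            qual=oriented_qual,
            n_mismatches=(L - score) // 2,
        )


def builtin_align(
    seq: str,
    reference: Reference,
    read_id: str = "",
    uid: str = "",
    **kwargs,
) -> AlignedRead:
    """One-shot convenience wrapper; builds a fresh index each call."""
    exhaustive = kwargs.pop("exhaustive", False)
    return BuiltinAligner(reference, **kwargs).align(
        seq, read_id=read_id, uid=uid, exhaustive=exhaustive
    )


# ---------------------------------------------------------------------------
# SAM ingestion


@dataclass
class IngestStats:
    records: int = 0
    mapped: int = 0
    unmapped: int = 0
    uid_missing: int = 0


def parse_uid_from_name(name: str, delimiter: str = UID_DELIMITER) -> str | None:
    """UID = final delimited token of the read name; None if absent."""
    if delimiter not in name:
        return None
    uid = name.rsplit(delimiter, 1)[1]
    if not uid or not set(uid.upper()) <= set("ACGT"):
        return None
    return uid


def ingest_sam(
    sam_source: str | Path,
    uid_delimiter: str = UID_DELIMITER,
    stats: IngestStats | None = None,
) -> Iterator[AlignedRead]:
    """Stream mapped reads (with parsed UIDs) from a SAM file.

    Unmapped records and records whose name lacks a UID token are skipped
    and counted in ``stats``.
    """
    if stats is None:
        stats = IngestStats()
    with pysam.AlignmentFile(str(sam_source), "r", check_sq=False) as sam:
        for rec in sam:
            stats.records += 1
            if rec.is_unmapped:
                stats.unmapped += 1
                continue
            uid = parse_uid_from_name(rec.query_name or "", uid_delimiter)
            if uid is None:
                stats.uid_missing += 1
                continue
            stats.mapped += 1
            yield AlignedRead(
                read_id=rec.query_name,
                uid=uid,
                chrom=rec.reference_name,
                pos=rec.reference_start + 1,
                strand="-" if rec.is_reverse else "+",
                cigar=rec.cigarstring or "",
                seq=(rec.query_sequence or "").upper(),
                mapped=True,
                qual=(
                    "".join(chr(q + 33) for q in rec.query_qualities)
                    if rec.query_qualities is not None
                    else None
                ),
            )


# ---------------------------------------------------------------------------
# Variant extraction (calmd-equivalent)


@dataclass(frozen=True)
class PerReadVariant:
    """One mismatch or indel observed in one read.

    SNVs have two single, differing bases; insertions and deletions are
    left-anchored with one reference base of context, so an insertion has
    ``len(ref_allele) == 1 < len(alt_allele)`` and a deletion the reverse.
    ``pos`` is the 1-based coordinate of the first reference base of
    ``ref_allele``.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    var_type: str  # SNV / INS / DEL
    uid: str
    read_id: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def extract_variants(
    read: AlignedRead,
    reference: Reference,
    targets: TargetLookup | None = None,
    min_base_quality: int = 0,
) -> list[PerReadVariant]:
    """Base-by-base comparison of one aligned read against the reference.

    Walks the CIGAR; every aligned base differing from the reference
    yields an SNV observation, insertion/deletion operations yield
    left-anchored indel observations.  Observations outside the targets
    are discarded; N read bases and soft-clipped bases never yield
    observations.  ``min_base_quality`` (default 0, i.e. no filtering)
    suppresses mismatch observations whose base quality is lower.
    """
    if not read.mapped:
        return []
    ops = parse_cigar(read.cigar)
    ref_len = reference.length(read.chrom)
    consumed_ref = sum(n for n, op in ops if op in "MDN=X")
    if read.pos - 1 + consumed_ref > ref_len:
        raise ValueError(
            f"read {read.read_id!r}: alignment runs past the reference end"
        )

    out: list[PerReadVariant] = []
    ref_seq = reference.seq(read.chrom)
    rpos = read.pos - 1  # 0-based reference cursor
    qpos = 0  # query cursor

    def in_targets(pos1: int) -> bool:
        return targets is None or targets.contains(read.chrom, pos1)

    def qual_ok(qi: int) -> bool:
        if min_base_quality <= 0 or read.qual is None:
            return True
        return ord(read.qual[qi]) - 33 >= min_base_quality

    for n, op in ops:
        if op in "M=X":
            block_read = read.seq[qpos : qpos + n]
            block_ref = ref_seq[rpos : rpos + n]
            if block_read != block_ref:
                for i in range(n):
                    rb = block_read[i]
                    fb = block_ref[i]
                    if rb == fb or rb == "N":
                        continue
                    pos1 = rpos + i + 1
                    if in_targets(pos1) and qual_ok(qpos + i):
                        out.append(
                            PerReadVariant(
                                read.chrom, pos1, fb, rb, "SNV",
                                read.uid, read.read_id,
                            )
                        )
            rpos += n
            qpos += n
        elif op == "I":
            inserted = read.seq[qpos : qpos + n]
            if rpos > 0 and "N" not in inserted:
                anchor = ref_seq[rpos - 1]
                pos1 = rpos  # 1-based coordinate of the anchor base
                if in_targets(pos1):
                    out.append(
                        PerReadVariant(
                            read.chrom, pos1, anchor, anchor + inserted,
                            "INS", read.uid, read.read_id,
                        )
                    )
            qpos += n
        elif op in "DN":
            if op == "D" and rpos > 0:
                anchor = ref_seq[rpos - 1]
                deleted = ref_seq[rpos : rpos + n]
                pos1 = rpos
                if in_targets(pos1):
                    out.append(
                        PerReadVariant(
                            read.chrom, pos1, anchor + deleted, anchor,
                            "DEL", read.uid, read.read_id,
                        )
                    )
            rpos += n
        elif op == "S":
            qpos += n
        # H and P consume nothing we track
    return out


def read_overlaps_targets(read: AlignedRead, targets: TargetLookup) -> bool:
    """Does the read's reference footprint intersect any target region?"""
    if not read.mapped:
        return False
    ref_span = sum(n for n, op in parse_cigar(read.cigar) if op in "MDN=X")
    return targets.overlaps(read.chrom, read.pos - 1, read.pos - 1 + ref_span)
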