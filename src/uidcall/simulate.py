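"""Synthetic dilution-series data and caller evaluation.

The benchmark this module reproduces mixes two read pools derived from
one reference sequence: a wild-type pool with no variants, and a variant
pool in which each molecule carries one random SNV and is PCR-duplicated
a random 1-50 times (wild-type molecules are unique, duplication 1).
Reads are 100 bp paired-end with a random 10 bp UID attached to the
molecule — realised as five leading bases on each mate, i.e. tags ligated
to both fragment ends.  Mixing the pools at levels from 0% to 99.9999%
wild-type emulates hunting for one variant molecule in up to a million
input molecules.

Dilution is enforced at the molecule level: a variant molecule is either
included whole (all its duplicates) or not at all, because the biological
claim under test concerns input molecules.  When the variant-read budget
at an extreme dilution is smaller than one molecule's duplicates, exactly
one whole molecule is included and the realised dilution recorded in the
truth-set metadata.

Sequencing error is an optional uniform per-base substitution rate,
default 0 (the benchmark design injects no machine error; the errors the
caller must suppress are the simulated PCR duplications of variant reads
versus the singleton wild-type background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import AlignedRead, PerReadVariant, Reference, parse_cigar, reverse_complement
from .caller import SuperMutant
from .uid_io import ReadPair, UIDConfig, format_fastq_record

DILUTION_LEVELS = (0.0, 0.5, 0.9, 0.99, 0.999, 0.9999, 0.99999, 0.999999)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_reference(length: int, seed: int, chrom: str = "synth1") -> Reference:
    """A uniform-random DNA reference sequence (synthetic stand-in)."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    return Reference({chrom: seq})


def write_fasta(reference: Reference, path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for chrom in reference.chroms():
            fh.write(f">{chrom}\n")
            seq = reference.seq(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the dilution-series generator.

    Defaults mirror the benchmark design: 100 bp paired-end reads, 10 bp
    UIDs (5 per mate), variant molecules duplicated uniformly in [1, 50].
    ``reference`` may be a FASTA path, a dict, or a bare sequence string.
    """

    reference: Reference
    read_len: int = 100
    uid_len: int = 10
    n_total_pairs: int = 10_000
    dilution_levels: tuple[float, ...] = DILUTION_LEVELS
    dup_min: int = 1
    dup_max: int = 50
    n_variant_molecules: int = 100
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.dup_min <= self.dup_max:
            raise ValueError("need 1 <= dup_min <= dup_max")
        if any(not 0.0 <= d < 1.0 for d in self.dilution_levels):
            raise ValueError("dilution levels must lie in [0, 1)")
        if self.uid_len % 2 != 0:
            raise ValueError("uid_len must be even (split across both mates)")
        for chrom in self.reference.chroms():
            if self.read_len > self.reference.length(chrom):
                raise ValueError("read_len exceeds reference length")

    @property
    def uid_config(self) -> UIDConfig:
        half = self.uid_len // 2
        return UIDConfig(
            mate1_five_prime_len=half, mate2_five_prime_len=half
        )

    @property
    def insert_len(self) -> int:
        """Usable bases per mate after the UID allotment."""
        return self.read_len - self.uid_len // 2

    @property
    def fragment_len(self) -> int:
        # mates abut: every fragment base is read by exactly one mate
        return 2 * self.insert_len


@dataclass(frozen=True)
class TruthRecord:
    """One simulated variant molecule."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    molecule_uid: str
    duplication_count: int

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_allele)


@dataclass
class TruthSet:
    """Simulated variant molecules plus generation metadata."""

    records: list[TruthRecord]
    seed: int
    metadata: dict = field(default_factory=dict)

    def sites(self) -> set[tuple[str, int, str]]:
        return {r.site for r in self.records}

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            for k in sorted(self.metadata):
                fh.write(f"# {k}={self.metadata[k]}\n")
            fh.write(
                "chrom\tpos\tref_allele\talt_allele\tmolecule_uid\t"
                "duplication_count\n"
            )
            for r in self.records:
                fh.write(
                    f"{r.chrom}\t{r.pos}\t{r.ref_allele}\t{r.alt_allele}\t"
                    f"{r.molecule_uid}\t{r.duplication_count}\n"
                )
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthSet":
        records: list[TruthRecord] = []
        meta: dict = {}
        seed = 0
        with open(path) as fh:
            header_seen = False
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    if key == "seed":
                        seed = int(value)
                    else:
                        meta[key] = value
                    continue
                if not header_seen:
                    header_seen = True
                    continue
                if not line:
                    continue
                c, p, ref, alt, uid, dup = line.split("\t")
                records.append(
                    TruthRecord(c, int(p), ref, alt, uid, int(dup))
                )
        return cls(records=records, seed=seed, metadata=meta)


@dataclass(frozen=True)
class Molecule:
    """One simulated input molecule: its truth (None for wild type) and
    the raw read pairs (UID bases still embedded) it produced."""

    uid: str
    pairs: tuple[ReadPair, ...]
    truth: TruthRecord | None = None


def _random_uid(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _make_pair(
    cfg: SimConfig,
    chrom: str,
    fragment: str,
    uid: str,
    read_id: str,
    rng: np.random.Generator,
) -> ReadPair:
    """Assemble one raw read pair from a fragment with the UID embedded.

    Mate1 reads the fragment 5' end on the forward strand, mate2 the 3'
    end on the reverse strand; each mate starts with its half of the UID.
    """
    half = cfg.uid_len // 2
    insert1 = fragment[: cfg.insert_len]
    insert2 = reverse_complement(fragment[cfg.insert_len :])
    m1 = uid[:half] + _apply_errors(insert1, cfg.error_rate, rng)
    m2 = uid[half:] + _apply_errors(insert2, cfg.error_rate, rng)
    qual = "I" * cfg.read_len  # Q40 throughout: the benchmark injects no
    return ReadPair(read_id, m1, qual, m2, qual)  # base-quality signal


def generate_wildtype_pool(
    cfg: SimConfig, n_pairs: int, rng: np.random.Generator | None = None
) -> list[Molecule]:
    """Variant-free molecules, one read pair each (duplication 1)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out: list[Molecule] = []
    for i in range(n_pairs):
        chrom = cfg.reference.chroms()[0]
        start = int(rng.integers(0, cfg.reference.length(chrom) - cfg.fragment_len + 1))
        fragment = cfg.reference.fetch(chrom, start, start + cfg.fragment_len)
        uid = _random_uid(rng, cfg.uid_len)
        pair = _make_pair(cfg, chrom, fragment, uid, f"wt{i}", rng)
        out.append(Molecule(uid=uid, pairs=(pair,)))
    return out


def generate_variant_pool(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    targets: Sequence[tuple[str, int, int]] | None = None,
) -> tuple[list[Molecule], TruthSet]:
    """Variant molecules: one random SNV each, duplicated 1-50 times.

    Each molecule gets a fresh random UID and a duplication count drawn
    uniformly from ``[dup_min, dup_max]``; every duplicate is a read pair
    carrying the molecule's SNV and UID.  ``targets`` (0-based half-open
    triples) restricts variant placement; default is the whole reference.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chrom = cfg.reference.chroms()[0]
    if targets is None:
        targets = [(chrom, 0, cfg.reference.length(chrom))]

    molecules: list[Molecule] = []
    records: list[TruthRecord] = []
    for m in range(cfg.n_variant_molecules):
        t_chrom, t_start, t_end = targets[int(rng.integers(0, len(targets)))]
        # place the fragment so the variant site is inside it
        var_pos0 = int(rng.integers(t_start, t_end))
        lo = max(0, var_pos0 - cfg.fragment_len + 1)
        hi = min(
            cfg.reference.length(t_chrom) - cfg.fragment_len, var_pos0
        )
        frag_start = int(rng.integers(lo, hi + 1))
        fragment = cfg.reference.fetch(
            t_chrom, frag_start, frag_start + cfg.fragment_len
        )
        offset = var_pos0 - frag_start
        ref_base = fragment[offset]
        alt_base = ref_base
        while alt_base == ref_base:  # rejection-sample a differing allele
            alt_base = chr(_BASES[int(rng.integers(0, 4))])
        fragment = fragment[:offset] + alt_base + fragment[offset + 1 :]

        uid = _random_uid(rng, cfg.uid_len)
        dup = int(rng.integers(cfg.dup_min, cfg.dup_max + 1))
        record = TruthRecord(
            chrom=t_chrom, pos=var_pos0 + 1, ref_allele=ref_base,
            alt_allele=alt_base, molecule_uid=uid, duplication_count=dup,
        )
        pairs = tuple(
            _make_pair(cfg, t_chrom, fragment, uid, f"var{m}.{d}", rng)
            for d in range(dup)
        )
        molecules.append(Molecule(uid=uid, pairs=pairs, truth=record))
        records.append(record)
    return molecules, TruthSet(records=records, seed=cfg.seed)


@dataclass
class DilutionDataset:
    """One mixed dataset: shuffled raw read pairs plus restricted truth."""

    pairs: list[ReadPair]
    truth: TruthSet
    level: float

    @property
    def realized_level(self) -> float:
        return float(self.truth.metadata["realized_level"])


def mix_dilution(
    wildtype: Sequence[Molecule],
    variants: Sequence[Molecule],
    level: float,
    n_total_pairs: int,
    seed: int,
) -> DilutionDataset:
    """Mix pools at a wild-type fraction ``level``, molecule-wise.

    The variant-read budget is ``round(n_total_pairs * (1 - level))``;
    variant molecules are drawn in seeded random order and included whole
    while they fit the budget.  A budget smaller than the first molecule's
    duplicates admits exactly one whole molecule (the realised level is
    recorded either way).  Remaining capacity is filled by wild-type pairs
    sampled without replacement; the combined records are shuffled
    deterministically.
    """
    rng = np.random.default_rng(seed)
    budget = round(n_total_pairs * (1.0 - level))
    order = rng.permutation(len(variants))

    chosen: list[Molecule] = []
    n_var = 0
    for idx in order:
        mol = variants[int(idx)]
        if n_var + len(mol.pairs) <= budget:
            chosen.append(mol)
            n_var += len(mol.pairs)
    if not chosen and variants:
        mol = variants[int(order[0])]
        chosen.append(mol)
        n_var = len(mol.pairs)

    n_wt = n_total_pairs - n_var
    if n_wt < 0:
        n_wt = 0
    if n_wt > len(wildtype):
        raise ValueError(
            f"wild-type pool of {len(wildtype)} molecules cannot supply "
            f"{n_wt} pairs"
        )
    wt_idx = rng.choice(len(wildtype), size=n_wt, replace=False)

    pairs: list[ReadPair] = []
    for mol in chosen:
        pairs.extend(mol.pairs)
    for i in wt_idx:
        pairs.extend(wildtype[int(i)].pairs)
    perm = rng.permutation(len(pairs))
    pairs = [pairs[int(i)] for i in perm]

    total = len(pairs)
    truth = TruthSet(
        records=[m.truth for m in chosen if m.truth is not None],
        seed=seed,
        metadata={
            "requested_level": level,
            "n_total_pairs": total,
            "n_variant_pairs": n_var,
            "realized_level": (total - n_var) / total if total else 0.0,
        },
    )
    return DilutionDataset(pairs=pairs, truth=truth, level=level)


def write_fastq_pairs(
    pairs: Iterable[ReadPair], fastq1: str | Path, fastq2: str | Path
) -> None:
    with open(fastq1, "w") as f1, open(fastq2, "w") as f2:
        for p in pairs:
            f1.write(format_fastq_record(p.read_id, p.mate1_seq, p.mate1_qual))
            f2.write(format_fastq_record(p.read_id, p.mate2_seq, p.mate2_qual))


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class Evaluation:
    """Confusion counts over distinct (chrom, pos, alt) call sites.

    ``fn_rate`` = FN / (TP + FN); ``fp_rate`` = FP / total distinct calls
    (0 when nothing was called).
    """

    tp: int
    fp: int
    fn: int

    @property
    def fn_rate(self) -> float:
        denom = self.tp + self.fn
        return self.fn / denom if denom else 0.0

    @property
    def fp_rate(self) -> float:
        denom = self.tp + self.fp
        return self.fp / denom if denom else 0.0

    def to_tsv(self) -> str:
        return (
            "tp\tfp\tfn\tfp_rate\tfn_rate\n"
            f"{self.tp}\t{self.fp}\t{self.fn}\t"
            f"{self.fp_rate:.6f}\t{self.fn_rate:.6f}\n"
        )


def evaluate_calls(
    supermutants: Iterable[SuperMutant], truth: TruthSet
) -> Evaluation:
    """Exact-match comparison of called sites against the truth set.

    A truth variant is a TP if any super mutant matches its (chrom, pos,
    alt allele); truth variants never called are FNs; called sites absent
    from the truth are FPs.
    """
    called = {(m.chrom, m.pos, m.alt_allele) for m in supermutants}
    truth_sites = truth.sites()
    tp = len(called & truth_sites)
    fp = len(called - truth_sites)
    fn = len(truth_sites - called)
    return Evaluation(tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Naive pooled baseline


def depth_from_alignments(
    reads: Iterable[AlignedRead], reference: Reference
) -> dict[str, np.ndarray]:
    """Per-position aligned depth via interval difference arrays."""
    diffs = {
        chrom: np.zeros(reference.length(chrom) + 1, dtype=np.int64)
        for chrom in reference.chroms()
    }
    for read in reads:
        if not read.mapped:
            continue
        span = sum(n for n, op in parse_cigar(read.cigar) if op in "MDN=X")
        d = diffs[read.chrom]
        d[read.pos - 1] += 1
        d[read.pos - 1 + span] -= 1
    return {chrom: np.cumsum(d[:-1]) for chrom, d in diffs.items()}


def naive_pooled_caller(
    observations: Iterable[PerReadVariant],
    depth: Mapping[str, np.ndarray],
    min_allele_fraction: float = 0.2,
    min_depth: int = 1,
) -> list[tuple[str, int, str, str]]:
    """Call on aggregate allele fraction, ignoring UID structure.

    This is the failure mode conventional callers share at high dilution:
    a variant confined to one molecule's read family vanishes into the
    pooled background fraction.  Returns (chrom, pos, ref, alt) keys whose
    pooled read fraction reaches ``min_allele_fraction`` at depth
    ``min_depth``.
    """
    counts: dict[tuple[str, int, str, str], int] = {}
    counted: set[tuple[str, tuple[str, int, str, str]]] = set()
    for obs in observations:
        dedup = (obs.read_id, obs.key)
        if dedup in counted:
            continue
        counted.add(dedup)
        counts[obs.key] = counts.get(obs.key, 0) + 1

    out = []
    for key in sorted(counts):
        chrom, pos, _, _ = key
        d = int(depth[chrom][pos - 1]) if chrom in depth else 0
        if d >= min_depth and d > 0 and counts[key] / d >= min_allele_fraction:
            out.append(key)
    return out
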