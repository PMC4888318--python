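"""UID-group variant calling: super mutants and super groups.

The error-suppression logic of molecule tagging lives here.  All aligned
on-target reads sharing one UID form a *UID group* — the read family of
one input DNA molecule.  A variant seen concordantly within a group is
evidence it existed in the original molecule rather than arising during
PCR: by default a group of at least 5 reads in which at least 40% of the
reads observe the same variant yields a *super mutant*.  A variant
supported by super mutants from two or more distinct UIDs (molecules) is
further classified as a *super group*.

The 40% default (rather than a strict majority) tolerates UID collisions,
where one tag is attached to two distinct molecules and a true variant is
present in only part of the read family; for the same reason multiple
alleles passing the threshold within one group are all reported.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .align import PerReadVariant

VariantKey = tuple[str, int, str, str]  # chrom, pos, ref_allele, alt_allele

_FRACTION_EPS = 1e-9  # inclusive threshold robust to float division

SUPERMUTANT_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele", "uid",
    "n_variant_reads", "n_group_reads", "fraction",
]
SUPERGROUP_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele",
    "n_supermutants", "total_reads",
]


@dataclass(frozen=True)
class CallerParams:
    """Thresholds for super-mutant / super-group classification.

    ``min_group_size``: minimum reads in a UID group (default 5).
    ``min_variant_fraction``: minimum fraction of the group's reads that
    must observe the variant (default 0.40).  Both are inclusive.
    ``min_supermutants_per_group``: distinct molecules required for a
    super group (default 2).
    """

    min_group_size: int = 5
    min_variant_fraction: float = 0.40
    min_supermutants_per_group: int = 2

    def __post_init__(self) -> None:
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if not 0.0 < self.min_variant_fraction <= 1.0:
            raise ValueError("min_variant_fraction must lie in (0, 1]")
        if self.min_supermutants_per_group < 1:
            raise ValueError("min_supermutants_per_group must be >= 1")


@dataclass
class UIDGroup:
    """All reads sharing one UID, with per-variant read tallies.

    ``n_reads`` counts every aligned on-target read carrying the UID,
    variant-bearing or not — it is the denominator of the variant
    fraction.  ``tallies`` counts, per variant key, the number of distinct
    reads in the group observing that variant (a read counts at most once
    per key).
    """

    uid: str
    n_reads: int = 0
    tallies: dict[VariantKey, int] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_reads < 1:
            raise ValueError(f"group {self.uid}: n_reads must be >= 1")
        for key, count in self.tallies.items():
            if count > self.n_reads:
                raise ValueError(
                    f"group {self.uid}: tally {key} exceeds group size"
                )


@dataclass(frozen=True)
class SuperMutant:
    """A variant passing the within-group thresholds for one UID."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    uid: str
    n_variant_reads: int
    n_group_reads: int

    @property
    def fraction(self) -> float:
        return self.n_variant_reads / self.n_group_reads

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class SuperGroup:
    """A variant supported by super mutants from >= 2 distinct molecules."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    members: tuple[SuperMutant, ...]

    @property
    def n_supermutants(self) -> int:
        return len(self.members)

    @property
    def total_reads(self) -> int:
        return sum(m.n_group_reads for m in self.members)

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


def build_groups(
    observations: Iterable[PerReadVariant],
    read_index: Mapping[str, str],
) -> dict[str, UIDGroup]:
    """Group variant observations by UID.

    ``read_index`` maps read_id -> uid for *all* aligned on-target reads
    (each mate is one read), so groups include variant-free reads in their
    size.  Each read contributes at most once to a given variant tally.
    Raises ``ValueError`` for an observation whose UID has no reads in the
    index (an upstream consistency failure).
    """
    groups: dict[str, UIDGroup] = {}
    for uid in read_index.values():
        group = groups.get(uid)
        if group is None:
            groups[uid] = UIDGroup(uid=uid, n_reads=1)
        else:
            group.n_reads += 1

    seen: set[tuple[str, VariantKey]] = set()
    for obs in observations:
        group = groups.get(obs.uid)
        if group is None:
            raise ValueError(
                f"observation for UID {obs.uid} has no reads in the index"
            )
        dedup = (obs.read_id, obs.key)
        if dedup in seen:
            continue
        seen.add(dedup)
        group.tallies[obs.key] = group.tallies.get(obs.key, 0) + 1
    return groups


def call_super_mutants(
    group: UIDGroup, params: CallerParams
) -> list[SuperMutant]:
    """Classify a group's tallies under the size and fraction thresholds.

    Thresholds are inclusive; every passing allele is emitted (no
    winner-take-all).
    """
    group.validate()
    if group.n_reads < params.min_group_size:
        return []
    out = []
    for key in sorted(group.tallies):
        count = group.tallies[key]
        if count / group.n_reads >= params.min_variant_fraction - _FRACTION_EPS:
            chrom, pos, ref, alt = key
            out.append(
                SuperMutant(
                    chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                    uid=group.uid, n_variant_reads=count,
                    n_group_reads=group.n_reads,
                )
            )
    return out


def call_all_super_mutants(
    groups: Mapping[str, UIDGroup] | Iterable[UIDGroup],
    params: CallerParams,
) -> list[SuperMutant]:
    if isinstance(groups, Mapping):
        groups = groups.values()
    out: list[SuperMutant] = []
    for group in sorted(groups, key=lambda g: g.uid):
        out.extend(call_super_mutants(group, params))
    out.sort(key=lambda m: (m.chrom, m.pos, m.ref_allele, m.alt_allele, m.uid))
    return out


def call_super_groups(
    supermutants: Iterable[SuperMutant], params: CallerParams
) -> list[SuperGroup]:
    """Aggregate super mutants recurring at one (chrom, pos, alleles) key.

    Keys supported by at least ``min_supermutants_per_group`` distinct
    UIDs become super groups, sorted by position.  Duplicate (uid, key)
    emissions upstream raise ``ValueError``.
    """
    by_key: dict[VariantKey, list[SuperMutant]] = {}
    seen: set[tuple[str, VariantKey]] = set()
    for sm in supermutants:
        ident = (sm.uid, sm.key)
        if ident in seen:
            raise ValueError(
                f"duplicate super mutant for UID {sm.uid} at {sm.key}"
            )
        seen.add(ident)
        by_key.setdefault(sm.key, []).append(sm)

    out = []
    for key in sorted(by_key):
        members = sorted(by_key[key], key=lambda m: m.uid)
        if len(members) >= params.min_supermutants_per_group:
            chrom, pos, ref, alt = key
            out.append(
                SuperGroup(
                    chrom=chrom, pos=pos, ref_allele=ref, alt_allele=alt,
                    members=tuple(members),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Reports

def supermutants_frame(supermutants: Iterable[SuperMutant]) -> pd.DataFrame:
    rows = [
        {
            "chrom": m.chrom, "pos": m.pos, "ref_allele": m.ref_allele,
            "alt_allele": m.alt_allele, "uid": m.uid,
            "n_variant_reads": m.n_variant_reads,
            "n_group_reads": m.n_group_reads,
            "fraction": f"{m.fraction:.4f}",
        }
        for m in supermutants
    ]
    return pd.DataFrame(rows, columns=SUPERMUTANT_COLUMNS)


def supergroups_frame(supergroups: Iterable[SuperGroup]) -> pd.DataFrame:
    rows = [
        {
            "chrom": g.chrom, "pos": g.pos, "ref_allele": g.ref_allele,
            "alt_allele": g.alt_allele,
            "n_supermutants": g.n_supermutants,
            "total_reads": g.total_reads,
        }
        for g in supergroups
    ]
    return pd.DataFrame(rows, columns=SUPERGROUP_COLUMNS)


def _atomic_write_tsv(frame: pd.DataFrame, path: Path) -> None:
    # write to a temporary then rename, so a present file is a complete file
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    frame.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def write_reports(
    supermutants: Iterable[SuperMutant],
    supergroups: Iterable[SuperGroup],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write the two tab-separated reports.

    ``<prefix>.supermutants.tsv`` has one row per super mutant (fraction
    printed to 4 decimals); ``<prefix>.supergroups.tsv`` one row per
    recurrent variant.  Both are deterministic in content and ordering and
    round-trip parseable with :func:`read_supermutants_report`.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    sm_path = out_prefix.with_name(out_prefix.name + ".supermutants.tsv")
    sg_path = out_prefix.with_name(out_prefix.name + ".supergroups.tsv")
    sms = sorted(
        supermutants,
        key=lambda m: (m.chrom, m.pos, m.ref_allele, m.alt_allele, m.uid),
    )
    sgs = sorted(supergroups, key=lambda g: (g.chrom, g.pos))
    _atomic_write_tsv(supermutants_frame(sms), sm_path)
    _atomic_write_tsv(supergroups_frame(sgs), sg_path)
    return sm_path, sg_path


def read_supermutants_report(path: str | Path) -> list[SuperMutant]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "uid": str})
    return [
        SuperMutant(
            chrom=row.chrom, pos=int(row.pos), ref_allele=row.ref_allele,
            alt_allele=row.alt_allele, uid=row.uid,
            n_variant_reads=int(row.n_variant_reads),
            n_group_reads=int(row.n_group_reads),
        )
        for row in df.itertuples()
    ]


def read_supergroups_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
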