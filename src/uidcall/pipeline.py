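"""End-to-end workflow driver with logging and resume.

The workflow runs seven file-to-file steps, mirroring the stages of a
UID-tagged variant-detection analysis:

1. ``uid_definition``   — validate the run configuration, freeze it to disk
2. ``sequence_qc``      — quality / N filtering and adapter trimming
3. ``uid_processing``   — UID extraction into the read headers
4. ``alignment``        — built-in aligner (or an external command template)
5. ``variant_detection``— per-read variant extraction within BED targets
6. ``report_generation``— UID grouping, super-mutant / super-group calling
7. ``summary``          — per-variant tabular summary (plot-ready TSV)

Every step is logged (parameters, input/output SHA-256 checksums,
timestamps, status) to a JSON-lines run log, outputs are written to
temporaries and renamed on completion, and a run can be resumed from any
step after verifying that the prerequisite outputs still match their
logged checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import shlex
import subprocess
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import pysam

from . import align as align_mod
from . import caller as caller_mod
from . import uid_io
from .align import Reference, TargetLookup, load_targets
from .caller import CallerParams
from .uid_io import UIDConfig

STEPS = [
    "uid_definition",
    "sequence_qc",
    "uid_processing",
    "alignment",
    "variant_detection",
    "report_generation",
    "summary",
]

READ_INDEX_COLUMNS = ["read_id", "uid"]
VARIANT_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele", "var_type", "uid", "read_id",
]


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    fastq1: Path
    fastq2: Path
    bed: Path
    reference: Path
    out_dir: Path
    uid_config: UIDConfig = field(default_factory=UIDConfig)
    caller_params: CallerParams = field(default_factory=CallerParams)
    aligner: str = "builtin"  # builtin | external
    aligner_cmd: str | None = None  # template with {fastq1} {fastq2} {reference} {out_sam}
    min_base_quality: int = 0
    min_score_fraction: float = 0.6
    count_fragments: bool = False  # dedup mates: count each fragment once
    group_per_target: bool = False  # group by (UID, target) instead of UID
    run_id: str = "run"

    def __post_init__(self) -> None:
        for name in ("fastq1", "fastq2", "bed", "reference", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))

    def validate(self) -> None:
        for name in ("fastq1", "fastq2", "bed", "reference"):
            p: Path = getattr(self, name)
            if not p.exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.aligner not in ("builtin", "external"):
            raise ValueError(f"unknown aligner {self.aligner!r}")
        if self.aligner == "external" and not self.aligner_cmd:
            raise ValueError("external aligner requires aligner_cmd")
        self.out_dir.mkdir(parents=True, exist_ok=True)
        probe = self.out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, Path):
                d[k] = str(v)
        return json.dumps(d, indent=2, sort_keys=True, default=str)

    @classmethod
    def from_json_file(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        uid_cfg = d.pop("uid_config", {})
        if isinstance(uid_cfg.get("adapters"), list):
            uid_cfg["adapters"] = tuple(uid_cfg["adapters"])
        params = d.pop("caller_params", {})
        return cls(
            uid_config=UIDConfig(**uid_cfg),
            caller_params=CallerParams(**params),
            **d,
        )


@dataclass
class StepRecord:
    step: str
    status: str  # OK | FAILED
    params: dict
    inputs: dict
    outputs: dict
    started: float
    finished: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)


@dataclass
class RunLog:
    path: Path
    records: list[StepRecord] = field(default_factory=list)

    def append(self, record: StepRecord) -> None:
        self.records.append(record)
        with open(self.path, "a") as fh:
            fh.write(record.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunLog":
        path = Path(path)
        records = []
        if path.exists():
            for line in path.read_text().splitlines():
                if line.strip():
                    records.append(StepRecord(**json.loads(line)))
        return cls(path=path, records=records)

    def latest(self, step: str) -> StepRecord | None:
        for rec in reversed(self.records):
            if rec.step == step and rec.status == "OK":
                return rec
        return None


class _Paths:
    """Canonical output locations for one run directory."""

    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.config = out_dir / "config.json"
        self.qc1 = out_dir / "qc_R1.fastq"
        self.qc2 = out_dir / "qc_R2.fastq"
        self.qc_stats = out_dir / "qc_stats.tsv"
        self.tagged1 = out_dir / "tagged_R1.fastq"
        self.tagged2 = out_dir / "tagged_R2.fastq"
        self.uid_stats = out_dir / "uid_stats.tsv"
        self.sam = out_dir / "alignments.sam"
        self.variants = out_dir / "variants.tsv"
        self.read_index = out_dir / "read_index.tsv"
        self.supermutants = out_dir / "calls.supermutants.tsv"
        self.supergroups = out_dir / "calls.supergroups.tsv"
        self.summary = out_dir / "summary.tsv"
        self.log = out_dir / "run_log.jsonl"
        self.text_log = out_dir / "run.log"


def _atomic_writer(path: Path):
    """Open a temp file beside ``path``; rename into place on success."""

    class _Ctx:
        def __enter__(self):
            fd, self.tmp = tempfile.mkstemp(
                dir=path.parent, suffix=".tmp", text=True
            )
            self.fh = os.fdopen(fd, "w")
            return self.fh

        def __exit__(self, exc_type, exc, tb):
            self.fh.close()
            if exc_type is None:
                os.replace(self.tmp, path)
            else:
                os.unlink(self.tmp)
            return False

    return _Ctx()


# ---------------------------------------------------------------------------
# Steps


def _step_uid_definition(cfg: RunConfig, paths: _Paths) -> dict[str, Path]:
    cfg.validate()
    load_targets(cfg.bed)  # fail early on malformed BED
    with _atomic_writer(paths.config) as fh:
        fh.write(cfg.to_json() + "\n")
    return {"config": paths.config}


def _step_sequence_qc(cfg: RunConfig, paths: _Paths) -> dict[str, Path]:
    stats = uid_io.ProcessStats()
    ucfg = cfg.uid_config
    with _atomic_writer(paths.qc1) as o1, _atomic_writer(paths.qc2) as o2:
        for pair in uid_io.read_fastq_pairs(cfg.fastq1, cfg.fastq2):
            stats.pairs_in += 1
            decision = uid_io.filter_read_pair(pair, ucfg)
            if not decision.keep:
                stats.dropped[decision.reason.value] += 1
                continue
            if ucfg.adapters:
                s1, q1 = uid_io.trim_adapters(
                    pair.mate1_seq, pair.mate1_qual, ucfg.adapters,
                    ucfg.min_adapter_overlap,
                )
                s2, q2 = uid_io.trim_adapters(
                    pair.mate2_seq, pair.mate2_qual, ucfg.adapters,
                    ucfg.min_adapter_overlap,
                )
                pair = uid_io.ReadPair(pair.read_id, s1, q1, s2, q2)
            stats.pairs_kept += 1
            o1.write(uid_io.format_fastq_record(
                pair.read_id, pair.mate1_seq, pair.mate1_qual))
            o2.write(uid_io.format_fastq_record(
                pair.read_id, pair.mate2_seq, pair.mate2_qual))
    stats.check_conservation()
    with _atomic_writer(paths.qc_stats) as fh:
        fh.write(stats.to_tsv())
    return {"qc1": paths.qc1, "qc2": paths.qc2, "qc_stats": paths.qc_stats}


def _step_uid_processing(cfg: RunConfig, paths: _Paths) -> dict[str, Path]:
    stats = uid_io.ProcessStats()
    with _atomic_writer(paths.tagged1) as o1, _atomic_writer(paths.tagged2) as o2:
        for pair in uid_io.read_fastq_pairs(paths.qc1, paths.qc2):
            stats.pairs_in += 1
            tagged = uid_io.extract_uid(pair, cfg.uid_config)
            if isinstance(tagged, uid_io.FilterDecision):
                stats.dropped[tagged.reason.value] += 1
                continue
            stats.pairs_kept += 1
            o1.write(uid_io.format_fastq_record(
                tagged.read_id, tagged.mate1_seq, tagged.mate1_qual))
            o2.write(uid_io.format_fastq_record(
                tagged.read_id, tagged.mate2_seq, tagged.mate2_qual))
    stats.check_conservation()
    with _atomic_writer(paths.uid_stats) as fh:
        fh.write(stats.to_tsv())
    return {
        "tagged1": paths.tagged1, "tagged2": paths.tagged2,
        "uid_stats": paths.uid_stats,
    }


def _sam_header(reference: Reference) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": chrom, "LN": reference.length(chrom)}
                for chrom in reference.chroms()
            ],
        }
    )


def _step_alignment(cfg: RunConfig, paths: _Paths) -> dict[str, Path]:
    if cfg.aligner == "external":
        cmd = cfg.aligner_cmd.format(
            fastq1=paths.tagged1, fastq2=paths.tagged2,
            reference=cfg.reference, out_sam=paths.sam,
        )
        subprocess.run(shlex.split(cmd), check=True)
        return {"sam": paths.sam}

    reference = Reference(cfg.reference)
    aligner = align_mod.BuiltinAligner(
        reference, min_score_fraction=cfg.min_score_fraction
    )
    header = _sam_header(reference)
    tid = {chrom: i for i, chrom in enumerate(reference.chroms())}

    tmp_fd, tmp_sam = tempfile.mkstemp(dir=paths.out_dir, suffix=".sam.tmp")
    os.close(tmp_fd)
    with pysam.AlignmentFile(tmp_sam, "wh", header=header) as out:
        for pair in uid_io.read_fastq_pairs(paths.tagged1, paths.tagged2):
            for mate_flag, seq, qual in (
                (0x40, pair.mate1_seq, pair.mate1_qual),
                (0x80, pair.mate2_seq, pair.mate2_qual),
            ):
                uid = align_mod.parse_uid_from_name(pair.read_id) or ""
                hit = aligner.align(seq, read_id=pair.read_id, uid=uid,
                                    qual=qual)
                rec = pysam.AlignedSegment(header)
                rec.query_name = pair.read_id
                rec.flag = 0x1 | mate_flag
                if not hit.mapped:
                    rec.flag |= 0x4
                    rec.query_sequence = seq
                    rec.query_qualities = pysam.qualitystring_to_array(qual)
                    rec.reference_id = -1
                    rec.reference_start = -1
                else:
                    if hit.strand == "-":
                        rec.flag |= 0x10
                    rec.reference_id = tid[hit.chrom]
                    rec.reference_start = hit.pos - 1
                    rec.mapping_quality = 60
                    rec.cigarstring = hit.cigar
                    rec.query_sequence = hit.seq
                    rec.query_qualities = pysam.qualitystring_to_array(
                        hit.qual or "I" * len(hit.seq)
                    )
                out.write(rec)
    os.replace(tmp_sam, paths.sam)
    return {"sam": paths.sam}


def _step_variant_detection(cfg: RunConfig, paths: _Paths) -> dict[str, Path]:
    reference = Reference(cfg.reference)
    targets = TargetLookup(load_targets(cfg.bed))
    stats = align_mod.IngestStats()

    with _atomic_writer(paths.variants) as vf, _atomic_writer(
        paths.read_index
    ) as rf:
        vf.write("\t".join(VARIANT_COLUMNS) + "\n")
        rf.write("\t".join(READ_INDEX_COLUMNS) + "\n")
        with pysam.AlignmentFile(str(paths.sam), "r", check_sq=False) as sam:
            for rec in sam:
                stats.records += 1
                if rec.is_unmapped:
                    stats.unmapped += 1
                    continue
                uid = align_mod.parse_uid_from_name(rec.query_name or "")
                if uid is None:
                    stats.uid_missing += 1
                    continue
                stats.mapped += 1
                if cfg.count_fragments or not rec.is_paired:
                    read_id = rec.query_name
                else:
                    read_id = rec.query_name + ("/1" if rec.is_read1 else "/2")
                read = align_mod.AlignedRead(
                    read_id=read_id, uid=uid,
                    chrom=rec.reference_name,
                    pos=rec.reference_start + 1,
                    strand="-" if rec.is_reverse else "+",
                    cigar=rec.cigarstring or "",
                    seq=(rec.query_sequence or "").upper(),
                    mapped=True,
                    qual=(
                        "".join(chr(q + 33) for q in rec.query_qualities)
                        if rec.query_qualities is not None else None
                    ),
                )
                if not align_mod.read_overlaps_targets(read, targets):
                    continue
                group_uid = uid
                if cfg.group_per_target:
                    group_uid = f"{uid}@{read.chrom}"
                rf.write(f"{read_id}\t{group_uid}\n")
                for v in align_mod.extract_variants(
                    read, reference, targets, cfg.min_base_quality
                ):
                    vf.write(
                        f"{v.chrom}\t{v.pos}\t{v.ref_allele}\t{v.alt_allele}"
                        f"\t{v.var_type}\t{group_uid}\t{read_id}\n"
                    )
    return {"variants": paths.variants, "read_index": paths.read_index}


def load_variants_tsv(path: str | Path) -> list[align_mod.PerReadVariant]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            chrom, pos, ref, alt, vtype, uid, read_id = line.rstrip("\n").split("\t")
            out.append(
                align_mod.PerReadVariant(
                    chrom, int(pos), ref, alt, vtype, uid, read_id
                )
            )
    return out


def load_read_index_tsv(path: str | Path) -> dict[str, str]:
    index: dict[str, str] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            read_id, uid = line.rstrip("\n").split("\t")
            index[read_id] = uid
    return index


def _step_report_generation(cfg: RunConfig, paths: _Paths) -> dict[str, Path]:
    observations = load_variants_tsv(paths.variants)
    read_index = load_read_index_tsv(paths.read_index)
    groups = caller_mod.build_groups(observations, read_index)
    sms = caller_mod.call_all_super_mutants(groups, cfg.caller_params)
    sgs = caller_mod.call_super_groups(sms, cfg.caller_params)
    sm_path, sg_path = caller_mod.write_reports(
        sms, sgs, paths.out_dir / "calls"
    )
    return {"supermutants": sm_path, "supergroups": sg_path}


def _step_summary(cfg: RunConfig, paths: _Paths) -> dict[str, Path]:
    sms = caller_mod.read_supermutants_report(paths.supermutants)
    agg: dict[tuple, list[int]] = {}
    for m in sms:
        entry = agg.setdefault(m.key, [0, 0, 0])
        entry[0] += 1
        entry[1] += m.n_variant_reads
        entry[2] += m.n_group_reads
    with _atomic_writer(paths.summary) as fh:
        fh.write(
            "chrom\tpos\tref_allele\talt_allele\tn_supermutants\t"
            "n_variant_reads\tn_group_reads\n"
        )
        for key in sorted(agg):
            chrom, pos, ref, alt = key
            n_sm, n_var, n_grp = agg[key]
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{n_sm}\t{n_var}\t{n_grp}\n")
    return {"summary": paths.summary}


_STEP_FUNCS: dict[str, Callable[[RunConfig, _Paths], dict[str, Path]]] = {
    "uid_definition": _step_uid_definition,
    "sequence_qc": _step_sequence_qc,
    "uid_processing": _step_uid_processing,
    "alignment": _step_alignment,
    "variant_detection": _step_variant_detection,
    "report_generation": _step_report_generation,
    "summary": _step_summary,
}

_STEP_INPUTS: dict[str, list[str]] = {
    "uid_definition": [],
    "sequence_qc": ["fastq1", "fastq2"],
    "uid_processing": ["qc1", "qc2"],
    "alignment": ["tagged1", "tagged2"],
    "variant_detection": ["sam"],
    "report_generation": ["variants", "read_index"],
    "summary": ["supermutants"],
}


def _input_paths(cfg: RunConfig, paths: _Paths, step: str) -> dict[str, Path]:
    mapping = {
        "fastq1": cfg.fastq1, "fastq2": cfg.fastq2,
        "qc1": paths.qc1, "qc2": paths.qc2,
        "tagged1": paths.tagged1, "tagged2": paths.tagged2,
        "sam": paths.sam, "variants": paths.variants,
        "read_index": paths.read_index, "supermutants": paths.supermutants,
    }
    return {k: mapping[k] for k in _STEP_INPUTS[step]}


def _run_steps(
    cfg: RunConfig, paths: _Paths, log: RunLog, steps: list[str]
) -> RunLog:
    with open(paths.text_log, "a") as tlog:
        for step in steps:
            started = time.time()
            inputs = {
                str(p): sha256_file(p)
                for p in _input_paths(cfg, paths, step).values()
                if Path(p).exists()
            }
            tlog.write(f"[{cfg.run_id}] step {step} started\n")
            try:
                outputs = _STEP_FUNCS[step](cfg, paths)
            except Exception:
                log.append(
                    StepRecord(
                        step=step, status="FAILED",
                        params=_step_params(cfg, step),
                        inputs=inputs, outputs={},
                        started=started, finished=time.time(),
                    )
                )
                tlog.write(f"[{cfg.run_id}] step {step} FAILED\n")
                raise
            out_sums = {str(p): sha256_file(p) for p in outputs.values()}
            log.append(
                StepRecord(
                    step=step, status="OK", params=_step_params(cfg, step),
                    inputs=inputs, outputs=out_sums,
                    started=started, finished=time.time(),
                )
            )
            tlog.write(f"[{cfg.run_id}] step {step} OK\n")
    return log


def _step_params(cfg: RunConfig, step: str) -> dict:
    if step in ("sequence_qc", "uid_processing"):
        return dataclasses.asdict(cfg.uid_config)
    if step == "alignment":
        return {"aligner": cfg.aligner, "min_score_fraction": cfg.min_score_fraction}
    if step in ("variant_detection",):
        return {
            "min_base_quality": cfg.min_base_quality,
            "count_fragments": cfg.count_fragments,
            "group_per_target": cfg.group_per_target,
        }
    if step in ("report_generation", "summary"):
        return dataclasses.asdict(cfg.caller_params)
    return {}


def run_pipeline(cfg: RunConfig) -> RunLog:
    """Execute all seven steps; any failure halts the run, leaves completed
    outputs in place, and is recorded FAILED in the log."""
    cfg.validate()
    paths = _Paths(cfg.out_dir)
    log = RunLog(path=paths.log)
    if paths.log.exists():
        paths.log.unlink()
    return _run_steps(cfg, paths, log, STEPS)


def resume_pipeline(cfg: RunConfig, from_step: str) -> RunLog:
    """Re-run from ``from_step`` onward after verifying prerequisites.

    Every completed step before ``from_step`` must have its logged outputs
    present with matching checksums; a mismatch refuses the resume and
    names the stale step.
    """
    if from_step not in STEPS:
        raise ValueError(f"unknown step {from_step!r}")
    cfg.validate()
    paths = _Paths(cfg.out_dir)
    prior = RunLog.load(paths.log)
    idx = STEPS.index(from_step)
    if idx == 0:
        return run_pipeline(cfg)

    for step in STEPS[:idx]:
        rec = prior.latest(step)
        if rec is None:
            raise ValueError(f"cannot resume: step {step!r} has not completed")
        for path_str, checksum in rec.outputs.items():
            p = Path(path_str)
            if not p.exists() or sha256_file(p) != checksum:
                raise ValueError(
                    f"cannot resume: output of step {step!r} is stale or "
                    f"missing ({path_str})"
                )

    kept = [r for r in prior.records if r.step in STEPS[:idx] and r.status == "OK"]
    if paths.log.exists():
        paths.log.unlink()
    log = RunLog(path=paths.log)
    for rec in kept:
        log.append(rec)
    return _run_steps(cfg, paths, log, STEPS[idx:])
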