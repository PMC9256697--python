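"""Domain types and on-disk format readers/writers.

Conventions
-----------
All genomic *intervals* (windows, segments, gene intervals) are 0-based
half-open, BED style.  All *point* mutations are 1-based, VCF style.  The two
coordinate systems meet only in :func:`point_to_interval`.

Calls are the pipeline entry point: upstream alignment and variant calling
are consumed through either VCF 4.2 (with ``AD`` and ``DP`` FORMAT fields) or
a TSV dialect that additionally carries uncalled sites with their read
support, which is what the read-level rescue and coverage analyses need.
"""

from __future__ import annotations

import enum
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ctc_concord")

VALID_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


class ValidationError(ValueError):
    """Raised when domain invariants are violated (e.g. sample sheet)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class SampleClass(str, enum.Enum):
    BULK_TUMOR = "bulk_tumor"
    GERMLINE_BLOOD = "germline_blood"
    WBC_POOL = "wbc_pool"
    CTC_SINGLE = "ctc_single"
    CTC_POOL = "ctc_pool"

    @property
    def is_ctc(self) -> bool:
        return self in (SampleClass.CTC_SINGLE, SampleClass.CTC_POOL)


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample: a bulk biopsy, control, or CTC sample."""

    sample_id: str
    patient_id: str
    sample_class: SampleClass
    n_cells: int = 1

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: n_cells must be >= 1, got {self.n_cells}"
            )


class MutationKey(NamedTuple):
    """Identity of a single-base substitution, shared across samples/patients."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def validate(self) -> "MutationKey":
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValidationError(f"non-ACGT ref/alt in {self}")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt in {self}")
        if self.pos < 1:
            raise ValidationError(f"non-positive position in {self}")
        return self


@dataclass
class VariantCall:
    """One substitution observed in one sample with read support.

    ``vaf`` is ``alt_reads / depth`` and is ``None`` (missing) when
    ``depth == 0``.  ``called`` is the upstream caller's decision; rows with
    ``called=False`` carry read support at sites called in other samples.
    """

    key: MutationKey
    sample_id: str
    depth: int
    alt_reads: int
    called: bool
    gene: Optional[str] = None
    effect: Optional[str] = None
    protein_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.alt_reads > self.depth:
            raise ValidationError(
                f"{self.key}: alt_reads {self.alt_reads} > depth {self.depth}"
            )
        if self.depth < 0 or self.alt_reads < 0:
            raise ValidationError(f"{self.key}: negative read counts")

    @property
    def vaf(self) -> Optional[float]:
        if self.depth == 0:
            return None
        return self.alt_reads / self.depth


@dataclass
class RunConfig:
    """Pipeline constants.

    Defaults encode the analysis rules: calls below a 20% VAF floor are
    dropped unless present in the matched bulk; bulk mutations need 20x
    coverage in at least one CTC to count as "selected"; sites covered by
    fewer than 5 reads are "low coverage"; calls whose flanking reference
    sequence contains the blacklist k-mer are amplification artifacts;
    copy number is assessed in 10 kb windows, segmented by circular binary
    segmentation and categorized on a ploidy-2 scale (amp > 4, gain > 2.5,
    del < 1.5, deep del < 0.8).
    """

    vaf_floor: float = 0.20
    min_select_depth: int = 20
    low_cov_depth: int = 5
    artifact_kmer: str = "TTAACTGACAGC"
    artifact_flank: int = 12
    window_size: int = 10_000
    cn_thresholds: dict = field(
        default_factory=lambda: {"amp": 4.0, "gain": 2.5, "del": 1.5, "deep_del": 0.8}
    )
    min_control_count: int = 10
    spectrum_pseudocount: float = 0.01
    cbs_alpha: float = 0.01
    cbs_nperm: int = 1000
    cbs_min_width: int = 2
    cbs_undo_z: float = 5.0
    max_exhaustive_subsets: int = 10_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        t = self.cn_thresholds
        if not (t["deep_del"] < t["del"] < 2 < t["gain"] < t["amp"]):
            raise ValidationError(f"CN thresholds not ordered: {t}")
        for name in ("min_select_depth", "low_cov_depth", "window_size",
                     "artifact_flank", "cbs_nperm", "max_exhaustive_subsets"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.artifact_flank < len(self.artifact_kmer):
            raise ValidationError("artifact_flank must be >= len(artifact_kmer)")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class WindowCounts:
    """Read counts in a fixed-width, sorted, non-overlapping window grid.

    ``df`` columns: chrom, start, end (0-based half-open), count.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "count"]
        if list(self.df.columns[:4]) != required:
            raise FormatError(f"window table must have columns {required}")
        if (self.df["count"] < 0).any():
            raise FormatError("negative window count")
        self._check_sorted()

    def _check_sorted(self) -> None:
        df = self.df
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (ends <= starts).any():
                raise FormatError(f"{chrom}: empty or inverted window")
            if len(starts) > 1 and not (starts[1:] >= ends[:-1]).all():
                raise FormatError(f"{chrom}: windows overlapping or unsorted")

    def same_grid(self, other: "WindowCounts") -> bool:
        a = self.df[["chrom", "start", "end"]].reset_index(drop=True)
        b = other.df[["chrom", "start", "end"]].reset_index(drop=True)
        return a.equals(b)

    def __len__(self) -> int:
        return len(self.df)


def point_to_interval(pos: int) -> tuple[int, int]:
    """Convert a 1-based point position to a 0-based half-open interval.

    The only sanctioned bridge between the two coordinate conventions.
    """
    if pos < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos}")
    return pos - 1, pos


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read and validate the run's sample sheet (TSV).

    Columns: sample_id, patient_id, sample_class, n_cells.  Every patient
    must have exactly one bulk tumor, one germline blood, one WBC pool, and
    at least one CTC sample; sample ids must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "patient_id", "sample_class", "n_cells"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
    metas: list[SampleMeta] = []
    for _, row in df.iterrows():
        try:
            cls = SampleClass(row["sample_class"])
        except ValueError:
            raise ValidationError(
                f"unknown sample_class {row['sample_class']!r} "
                f"for sample {row['sample_id']!r}"
            ) from None
        metas.append(
            SampleMeta(
                sample_id=row["sample_id"],
                patient_id=row["patient_id"],
                sample_class=cls,
                n_cells=int(row["n_cells"]),
            )
        )
    validate_sample_set(metas)
    return metas


def validate_sample_set(metas: Sequence[SampleMeta]) -> None:
    ids = [m.sample_id for m in metas]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValidationError(f"duplicate sample_id(s): {sorted(dupes)}")
    for patient_id, group in group_by_patient(metas).items():
        classes = [m.sample_class for m in group]
        for needed in (SampleClass.BULK_TUMOR, SampleClass.GERMLINE_BLOOD,
                       SampleClass.WBC_POOL):
            n = classes.count(needed)
            if n != 1:
                raise ValidationError(
                    f"patient {patient_id!r}: expected exactly one "
                    f"{needed.value} sample, found {n}"
                )
        if not any(c.is_ctc for c in classes):
            raise ValidationError(f"patient {patient_id!r}: no CTC sample")


def group_by_patient(metas: Iterable[SampleMeta]) -> dict[str, list[SampleMeta]]:
    out: dict[str, list[SampleMeta]] = {}
    for m in metas:
        out.setdefault(m.patient_id, []).append(m)
    return out


def write_sample_sheet(metas: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "patient_id": m.patient_id,
                "sample_class": m.sample_class.value,
                "n_cells": m.n_cells,
            }
            for m in metas
        ]
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant calls: VCF 4.2 and TSV dialect
# ---------------------------------------------------------------------------

CALLS_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "alt_reads", "called"]
CALLS_TSV_OPTIONAL = ["gene", "effect", "protein_change"]


def read_calls(path: str | Path, sample: SampleMeta | str) -> list[VariantCall]:
    """Read variant calls for one sample from VCF 4.2 or the TSV dialect.

    Indels are skipped with a logged count; multi-allelic VCF records are
    split into one :class:`VariantCall` per alternate allele.
    """
    sample_id = sample.sample_id if isinstance(sample, SampleMeta) else sample
    path = Path(path)
    if path.suffix == ".tsv":
        return _read_calls_tsv(path, sample_id)
    return _read_calls_vcf(path, sample_id)


def _read_calls_tsv(path: Path, sample_id: str) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(CALLS_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    calls: list[VariantCall] = []
    n_indels = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ref, alt = str(row.ref), str(row.alt)
        if len(ref) != 1 or len(alt) != 1:
            n_indels += 1
            continue
        try:
            key = MutationKey(str(row.chrom), int(row.pos), ref, alt).validate()
            call = VariantCall(
                key=key,
                sample_id=sample_id,
                depth=int(row.depth),
                alt_reads=int(row.alt_reads),
                called=_parse_bool(row.called),
                gene=_opt_str(getattr(row, "gene", None)),
                effect=_opt_str(getattr(row, "effect", None)),
                protein_change=_opt_str(getattr(row, "protein_change", None)),
            )
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}: malformed row at line {i}: {exc}") from exc
        calls.append(call)
    if n_indels:
        logger.info("%s: skipped %d indel rows", path, n_indels)
    return calls


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean {v!r}")


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v)
    return s if s and s.lower() != "nan" else None


def _read_calls_vcf(path: Path, sample_id: str) -> list[VariantCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if "AD" not in [f["ID"] for f in _vcf_format_headers(vcf)]:
        raise FormatError(f"{path}: FORMAT field AD absent")
    if "DP" not in [f["ID"] for f in _vcf_format_headers(vcf)]:
        raise FormatError(f"{path}: FORMAT field DP absent")
    calls: list[VariantCall] = []
    n_indels = 0
    for var in vcf:
        ref = var.REF
        ad = var.format("AD")
        dp = var.format("DP")
        if ad is None or dp is None:
            raise FormatError(f"{path}: record {var.CHROM}:{var.POS} lacks AD/DP")
        depth = int(dp[0][0])
        gene = var.INFO.get("GENE")
        effect = var.INFO.get("EFFECT")
        pchange = var.INFO.get("PCHANGE")
        for ai, alt in enumerate(var.ALT):
            if len(ref) != 1 or len(alt) != 1:
                n_indels += 1
                continue
            alt_reads = int(ad[0][ai + 1])
            key = MutationKey(var.CHROM, var.POS, ref, alt).validate()
            calls.append(
                VariantCall(
                    key=key,
                    sample_id=sample_id,
                    depth=depth,
                    alt_reads=min(alt_reads, depth),
                    called=var.FILTER is None,  # PASS or '.'
                    gene=gene,
                    effect=effect,
                    protein_change=pchange,
                )
            )
    if n_indels:
        logger.info("%s: skipped %d indel alleles", path, n_indels)
    return calls


def _vcf_format_headers(vcf) -> list[dict]:
    out = []
    for h in vcf.header_iter():
        try:
            if h["HeaderType"] == "FORMAT":
                out.append(h)
        except KeyError:
            continue
    return out


def write_calls_tsv(calls: Sequence[VariantCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.key.chrom,
                "pos": c.key.pos,
                "ref": c.key.ref,
                "alt": c.key.alt,
                "depth": c.depth,
                "alt_reads": c.alt_reads,
                "called": c.called,
                "gene": c.gene or "",
                "effect": c.effect or "",
                "protein_change": c.protein_change or "",
            }
        )
    df = pd.DataFrame(rows, columns=CALLS_TSV_COLUMNS + CALLS_TSV_OPTIONAL)
    df.to_csv(path, sep="\t", index=False)


def write_calls_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    contigs: Mapping[str, int],
    sample_id: str,
) -> None:
    """Write called variants as a minimal VCF 4.2 with AD/DP FORMAT fields."""
    lines = ["##fileformat=VCFv4.2"]
    for chrom, length in contigs.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    lines.append('##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">')
    lines.append('##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">'
    )
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for c in sorted(calls, key=lambda c: (c.key.chrom, c.key.pos, c.key.alt)):
        info_parts = []
        if c.gene:
            info_parts.append(f"GENE={c.gene}")
        if c.effect:
            info_parts.append(f"EFFECT={c.effect}")
        if c.protein_change:
            info_parts.append(f"PCHANGE={c.protein_change}")
        info = ";".join(info_parts) or "."
        ad = f"{c.depth - c.alt_reads},{c.alt_reads}"
        lines.append(
            f"{c.key.chrom}\t{c.key.pos}\t.\t{c.key.ref}\t{c.key.alt}\t.\tPASS\t"
            f"{info}\tAD:DP\t{ad}:{c.depth}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Window counts (BED-like) and segments (SEG-like)
# ---------------------------------------------------------------------------


def read_window_counts(path: str | Path) -> WindowCounts:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "count": np.int64},
    )
    missing = {"chrom", "start", "end", "count"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return WindowCounts(df[["chrom", "start", "end", "count"]])


def write_window_counts(wc: WindowCounts, path: str | Path) -> None:
    wc.df.to_csv(path, sep="\t", index=False)


SEG_COLUMNS = [
    "sample", "chrom", "start", "end", "n_windows", "mean_log2", "cn", "category",
]


def write_segments(segments: pd.DataFrame, path: str | Path) -> None:
    """Write a SEG-like TSV; expects the columns in :data:`SEG_COLUMNS`."""
    missing = set(SEG_COLUMNS) - set(segments.columns)
    if missing:
        raise FormatError(f"segment table missing columns: {sorted(missing)}")
    segments[SEG_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# COSMIC counts and gene intervals
# ---------------------------------------------------------------------------


def read_cosmic_counts(path: str | Path) -> "CosmicCounts":
    from ctc_concord.drivers import CosmicCounts

    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "protein_change": str})
    missing = {"gene", "protein_change", "count"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return CosmicCounts.from_frame(df)


def read_gene_intervals(path: str | Path) -> pd.DataFrame:
    """BED-like gene interval table: chrom, start, end, gene (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str},
    )
    return df


# ---------------------------------------------------------------------------
# Run log
# ---------------------------------------------------------------------------


@dataclass
class RunLog:
    """Records seed, config hash, and per-stage record counts for a run."""

    seed: int
    config_hash: str
    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, **counts})
        logger.info("stage %s: %s", stage, counts)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"seed": self.seed, "config_hash": self.config_hash,
                 "stages": self.stages},
                fh,
                indent=2,
            )
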