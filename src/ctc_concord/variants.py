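"""Somatic-call filtering and the bulk/CTC mutation taxonomy.

Three filters are applied to the raw caller output before any concordance
statistic is computed:

* **blacklist k-mer** — calls whose flanking reference sequence contains a
  known amplification-artifact motif (either strand) are removed;
* **cross-patient** — substitutions called in more than one patient are
  removed everywhere (recurrent artifacts rather than biology);
* **VAF floor** — calls below the VAF floor (default 20%) are removed unless
  the same substitution is called in the patient's bulk sample.

The filters act on disjoint predicates (reference context, cross-patient
recurrence, within-sample read support), so they are idempotent and commute.

After filtering, every mutation of a patient is assigned exactly one
category: ``bulk_only`` (bulk but never in a CTC), ``ctc_bulk`` (CTC and
bulk), ``ctc_shared`` (>= 2 CTC samples, absent from bulk), ``ctc_private``
(exactly one CTC sample, absent from bulk), or ``excluded`` (e.g. present in
the WBC pool or germline, hence not attributable to the tumor).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ctc_concord.io_core import (
    MutationKey,
    RunConfig,
    SampleClass,
    SampleMeta,
    ValidationError,
    VariantCall,
    logger,
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CallStatus(str, enum.Enum):
    """Per-(mutation, sample) evidence level used by the oncoplot rescue."""

    CALLED = "called"
    SUPPORTED = "supported"      # >=1 alt read but not called ("recovered")
    COVERED_REF = "covered_ref"  # reads present, none supporting the alt
    NO_COVERAGE = "no_coverage"  # zero reads ("stricken cell")


def rescue_status(depth: int, alt_reads: int, called: bool) -> CallStatus:
    """Evidence status at one site in one sample.

    The caller flag takes precedence; otherwise a single alternate-supporting
    read suffices to mark the mutation as recoverable.
    """
    if called:
        return CallStatus.CALLED
    if alt_reads >= 1:
        return CallStatus.SUPPORTED
    if depth >= 1:
        return CallStatus.COVERED_REF
    return CallStatus.NO_COVERAGE


@dataclass
class CallMatrix:
    """Mutations x samples grid of depth, alt reads, caller flag and status."""

    patient_id: str
    mutations: list[MutationKey]
    samples: list[str]
    depth: pd.DataFrame      # mutations x samples, int
    alt_reads: pd.DataFrame  # mutations x samples, int
    called: pd.DataFrame     # mutations x samples, bool

    @classmethod
    def from_calls(
        cls,
        patient_id: str,
        calls_by_sample: Mapping[str, Sequence[VariantCall]],
        mutations: Sequence[MutationKey] | None = None,
    ) -> "CallMatrix":
        samples = sorted(calls_by_sample)
        if mutations is None:
            keys = sorted({c.key for calls in calls_by_sample.values() for c in calls})
        else:
            keys = list(mutations)
        index = pd.Index(keys)
        depth = pd.DataFrame(0, index=index, columns=samples, dtype=int)
        alt = pd.DataFrame(0, index=index, columns=samples, dtype=int)
        called = pd.DataFrame(False, index=index, columns=samples, dtype=bool)
        keyset = set(keys)
        for sid, calls in calls_by_sample.items():
            for c in calls:
                if c.key not in keyset:
                    continue
                depth.at[c.key, sid] = c.depth
                alt.at[c.key, sid] = c.alt_reads
                called.at[c.key, sid] = c.called
        return cls(patient_id, keys, samples, depth, alt, called)

    def status(self, key: MutationKey, sample_id: str) -> CallStatus:
        return rescue_status(
            int(self.depth.at[key, sample_id]),
            int(self.alt_reads.at[key, sample_id]),
            bool(self.called.at[key, sample_id]),
        )

    def status_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.depth.index, columns=self.samples, dtype=object)
        for sid in self.samples:
            d = self.depth[sid].to_numpy()
            a = self.alt_reads[sid].to_numpy()
            c = self.called[sid].to_numpy()
            col = np.where(
                c, CallStatus.CALLED.value,
                np.where(a >= 1, CallStatus.SUPPORTED.value,
                         np.where(d >= 1, CallStatus.COVERED_REF.value,
                                  CallStatus.NO_COVERAGE.value)),
            )
            out[sid] = col
        return out


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def filter_artifact_kmer(
    calls: Sequence[VariantCall],
    reference,
    cfg: RunConfig,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Remove calls whose flanking reference contains the blacklist k-mer.

    A call is removed iff the k-mer or its reverse complement occurs anywhere
    in the reference window ``pos +- artifact_flank`` (window clipped at
    contig ends).  ``reference`` is a mapping of contig name to sequence
    (e.g. a ``pyfaidx.Fasta``).
    """
    kmer = cfg.artifact_kmer.upper()
    rc = reverse_complement(kmer)
    kept: list[VariantCall] = []
    removed: list[VariantCall] = []
    cache: dict[MutationKey, bool] = {}
    for c in calls:
        hit = cache.get(c.key)
        if hit is None:
            contig = reference[c.key.chrom]
            contig_len = len(contig)
            if not (1 <= c.key.pos <= contig_len):
                raise ValidationError(
                    f"{c.key}: position outside reference contig "
                    f"{c.key.chrom} (length {contig_len})"
                )
            lo = max(0, c.key.pos - 1 - cfg.artifact_flank)
            hi = min(contig_len, c.key.pos + cfg.artifact_flank)
            window = str(contig[lo:hi]).upper()
            hit = kmer in window or rc in window
            cache[c.key] = hit
        (removed if hit else kept).append(c)
    return kept, removed


def filter_cross_patient(
    calls_by_patient: Mapping[str, Sequence[VariantCall]],
    presence_from: Optional[Mapping[str, Sequence[VariantCall]]] = None,
) -> tuple[dict[str, list[VariantCall]], dict[str, list[VariantCall]]]:
    """Remove substitutions called in more than one patient, everywhere.

    Only *called* occurrences establish presence in a patient; uncalled
    read-support rows do not.  Removal applies to all rows of a recurrent
    key, called or not.  ``presence_from`` optionally fixes the callset used
    to determine recurrence (e.g. the unfiltered calls, so that the filters
    act as independent predicates and commute); it defaults to the input.
    """
    if len(calls_by_patient) < 2:
        logger.warning("cross-patient filter: single patient, no-op")
        return (
            {p: list(v) for p, v in calls_by_patient.items()},
            {p: [] for p in calls_by_patient},
        )
    patients_per_key: dict[MutationKey, set[str]] = {}
    for patient, calls in (presence_from or calls_by_patient).items():
        for c in calls:
            if c.called:
                patients_per_key.setdefault(c.key, set()).add(patient)
    recurrent = {k for k, ps in patients_per_key.items() if len(ps) >= 2}
    kept: dict[str, list[VariantCall]] = {}
    removed: dict[str, list[VariantCall]] = {}
    for patient, calls in calls_by_patient.items():
        kept[patient] = [c for c in calls if c.key not in recurrent]
        removed[patient] = [c for c in calls if c.key in recurrent]
    return kept, removed


def filter_vaf(
    calls: Sequence[VariantCall],
    bulk_called_keys: Iterable[MutationKey],
    cfg: RunConfig,
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Drop called variants below the VAF floor unless called in the bulk.

    A call at exactly the floor is kept.  Uncalled read-support rows pass
    through untouched (they carry coverage information, not assertions).
    """
    if bulk_called_keys is None:
        raise ValidationError("VAF filter requires the patient's bulk callset")
    bulk_keys = set(bulk_called_keys)
    kept: list[VariantCall] = []
    removed: list[VariantCall] = []
    for c in calls:
        if not c.called:
            kept.append(c)
            continue
        vaf = c.vaf
        low = vaf is None or vaf < cfg.vaf_floor
        if low and c.key not in bulk_keys:
            removed.append(c)
        else:
            kept.append(c)
    return kept, removed


# ---------------------------------------------------------------------------
# Categorization
# ---------------------------------------------------------------------------

CATEGORIES = ["bulk_only", "ctc_bulk", "ctc_shared", "ctc_private", "excluded"]


@dataclass
class MutationCategories:
    """Per-mutation category labels for one patient, plus summary counts."""

    patient_id: str
    labels: dict[MutationKey, str]
    per_sample_counts: pd.DataFrame  # samples x categories

    def count(self, category: str) -> int:
        return sum(1 for v in self.labels.values() if v == category)

    def keys_in(self, category: str) -> set[MutationKey]:
        return {k for k, v in self.labels.items() if v == category}


def categorize(
    called_keys_by_sample: Mapping[str, set[MutationKey]],
    metas: Sequence[SampleMeta],
) -> MutationCategories:
    """Assign each filtered mutation of a patient to exactly one category.

    Bulk mutations are those called in the bulk but absent from both the
    germline blood and the amplified WBC pool.  CTC mutations are those
    called in at least one CTC sample but absent from the WBC pool.  CTC
    mutations are split by bulk overlap and by how many CTC samples share
    them.  Mutations attributable to neither (e.g. WBC-pool calls) are
    ``excluded``.
    """
    by_class: dict[SampleClass, list[SampleMeta]] = {}
    for m in metas:
        by_class.setdefault(m.sample_class, []).append(m)
    patient_ids = {m.patient_id for m in metas}
    if len(patient_ids) != 1:
        raise ValidationError(f"categorize expects one patient, got {patient_ids}")
    patient_id = patient_ids.pop()

    bulk_id = by_class[SampleClass.BULK_TUMOR][0].sample_id
    germ_id = by_class[SampleClass.GERMLINE_BLOOD][0].sample_id
    wbc_id = by_class[SampleClass.WBC_POOL][0].sample_id
    ctc_ids = sorted(
        m.sample_id for m in metas if m.sample_class.is_ctc
    )

    get = lambda sid: called_keys_by_sample.get(sid, set())
    bulk_set = get(bulk_id) - get(germ_id) - get(wbc_id)
    ctc_union: set[MutationKey] = set()
    for sid in ctc_ids:
        ctc_union |= get(sid)
    ctc_set = ctc_union - get(wbc_id)

    n_ctc_samples = {
        k: sum(1 for sid in ctc_ids if k in get(sid)) for k in ctc_set
    }

    universe: set[MutationKey] = set()
    for sid in called_keys_by_sample:
        universe |= get(sid)

    labels: dict[MutationKey, str] = {}
    for k in universe:
        if k in ctc_set:
            if k in bulk_set:
                labels[k] = "ctc_bulk"
            else:
                labels[k] = "ctc_shared" if n_ctc_samples[k] >= 2 else "ctc_private"
        elif k in bulk_set:
            labels[k] = "bulk_only"
        else:
            labels[k] = "excluded"

    # Partition sanity: the three CTC categories must tile the CTC set.
    n_ctc_cat = sum(
        1 for v in labels.values() if v in ("ctc_bulk", "ctc_shared", "ctc_private")
    )
    assert n_ctc_cat == len(ctc_set)

    counts = pd.DataFrame(
        0, index=sorted(called_keys_by_sample), columns=CATEGORIES, dtype=int
    )
    for sid in counts.index:
        for k in get(sid):
            counts.at[sid, labels[k]] += 1
    return MutationCategories(patient_id, labels, counts)


def called_key_sets(
    calls_by_sample: Mapping[str, Sequence[VariantCall]],
) -> dict[str, set[MutationKey]]:
    """Collapse per-sample call lists to sets of called MutationKeys."""
    return {
        sid: {c.key for c in calls if c.called}
        for sid, calls in calls_by_sample.items()
    }


def categories_frame(cats: MutationCategories) -> pd.DataFrame:
    rows = [
        {"chrom": k.chrom, "pos": k.pos, "ref": k.ref, "alt": k.alt, "category": v}
        for k, v in sorted(cats.labels.items())
    ]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "category"])
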