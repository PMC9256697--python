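"""Driver-centric oncoplot summary.

Genes are selected for display by recurrence (at least two mutation events
across all samples whose variant appears at least 20 times in the COSMIC
catalogue), plus an always-show list (ESR1 by default) and the configured
driver-CNA genes.  Individual variants are shown when their COSMIC count is
at least 20, with a relaxed cutoff of 5 for TP53.  Each (feature, sample)
cell carries either the mutation evidence status — called, recovered (at
least one alternate-supporting read without a call), absent, or no
coverage — or the copy-number category of the segment overlapping the gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from ctc_concord.io_core import MutationKey, RunConfig
from ctc_concord.variants import CallMatrix, CallStatus
from ctc_concord.cna import CNProfile

DEFAULT_EXTRA_GENES = ("ESR1",)
#: genes whose copy-number state is displayed as oncoplot rows by default
DRIVER_CNA_GENES = ("MYC", "ERBB2", "CCND1", "PTEN", "RB1")
DEFAULT_GENE_COSMIC_MIN = 20
DEFAULT_VARIANT_COSMIC_MIN = 20
TP53_VARIANT_COSMIC_MIN = 5


@dataclass
class CosmicCounts:
    """Occurrence counts from a static COSMIC-style table."""

    variant_counts: dict[tuple[str, str], int]
    gene_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_counts:
            agg: dict[str, int] = {}
            for (gene, _), n in self.variant_counts.items():
                agg[gene] = agg.get(gene, 0) + n
            self.gene_counts = agg
        for gene, total in self.gene_counts.items():
            per_variant = [
                n for (g, _), n in self.variant_counts.items() if g == gene
            ]
            if per_variant and total < max(per_variant):
                raise ValueError(
                    f"gene {gene!r}: aggregate count below a per-variant count"
                )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CosmicCounts":
        counts = {
            (str(r.gene), str(r.protein_change)): int(r.count)
            for r in df.itertuples(index=False)
        }
        return cls(counts)

    def variant_count(self, gene: str, protein_change: Optional[str]) -> int:
        if protein_change is None:
            return 0
        return self.variant_counts.get((gene, protein_change), 0)


@dataclass
class AnnotatedMutation:
    """One mutation event with its gene annotation, as seen in one sample."""

    key: MutationKey
    sample_id: str
    gene: Optional[str]
    protein_change: Optional[str]


def select_oncoplot_genes(
    mutations: Sequence[AnnotatedMutation],
    cosmic: CosmicCounts,
    extra_genes: Sequence[str] = DEFAULT_EXTRA_GENES,
    driver_cna_genes: Sequence[str] = (),
    min_events: int = 2,
    min_cosmic: int = DEFAULT_GENE_COSMIC_MIN,
) -> list[str]:
    """Genes with >= 2 COSMIC-recurrent mutation events, plus forced genes.

    An "event" is one qualifying mutation occurrence in one sample (the same
    variant in two samples counts twice).  A mutation qualifies when its
    COSMIC count is >= ``min_cosmic``.
    """
    if any(m.gene is None for m in mutations):
        raise ValueError("mutation lacking gene annotation")
    events: dict[str, int] = {}
    for m in mutations:
        if cosmic.variant_count(m.gene, m.protein_change) >= min_cosmic:
            events[m.gene] = events.get(m.gene, 0) + 1
    selected = {g for g, n in events.items() if n >= min_events}
    selected |= set(extra_genes) | set(driver_cna_genes)
    return sorted(selected)


def select_oncoplot_variants(
    mutations: Sequence[AnnotatedMutation],
    cosmic: CosmicCounts,
    min_cosmic: int = DEFAULT_VARIANT_COSMIC_MIN,
    tp53_min_cosmic: int = TP53_VARIANT_COSMIC_MIN,
) -> list[tuple[str, str]]:
    """Distinct (gene, protein_change) variants passing the display cutoff.

    The cutoff is ``min_cosmic`` occurrences in COSMIC, relaxed to
    ``tp53_min_cosmic`` for TP53 variants.
    """
    shown: set[tuple[str, str]] = set()
    for m in mutations:
        if m.gene is None or m.protein_change is None:
            continue
        n = cosmic.variant_count(m.gene, m.protein_change)
        cutoff = tp53_min_cosmic if m.gene == "TP53" else min_cosmic
        if n >= cutoff:
            shown.add((m.gene, m.protein_change))
    return sorted(shown)


# ---------------------------------------------------------------------------
# Oncoplot grid
# ---------------------------------------------------------------------------

MUTATION_CELL = {
    CallStatus.CALLED: "called",
    CallStatus.SUPPORTED: "recovered",
    CallStatus.COVERED_REF: "absent",
    CallStatus.NO_COVERAGE: "no_coverage",
}


def gene_cn_category(
    profile: CNProfile, chrom: str, start: int, end: int
) -> str:
    """CN category at a gene interval: the longest-overlap segment wins."""
    segs = profile.segments
    if segs is None:
        raise ValueError("profile has no segments")
    same = segs[segs["chrom"] == chrom]
    overlaps = (
        same.assign(
            ov=(same[["end"]].to_numpy().ravel().clip(max=end)
                - same[["start"]].to_numpy().ravel().clip(min=start))
        )
        .query("ov > 0")
        .sort_values(["ov", "start"], ascending=[False, True])
    )
    if overlaps.empty:
        raise ValueError(
            f"gene interval {chrom}:{start}-{end} overlaps no segment "
            f"in {profile.sample_id!r}"
        )
    return str(overlaps["category"].iloc[0])


def oncoplot_table(
    variants_shown: Sequence[tuple[str, str]],
    variant_keys: Mapping[tuple[str, str], MutationKey],
    matrix: CallMatrix,
    cn_genes: Sequence[str],
    gene_intervals: pd.DataFrame,
    profiles: Mapping[str, CNProfile],
) -> pd.DataFrame:
    """Per-(feature, sample) status grid.

    Mutation rows are labelled ``GENE p.CHANGE`` and carry evidence status;
    CNA rows are labelled ``GENE (CN)`` and carry the copy-number category
    of the longest-overlap segment at the gene.
    """
    interval_map = {
        str(r.gene): (str(r.chrom), int(r.start), int(r.end))
        for r in gene_intervals.itertuples(index=False)
    }
    samples = matrix.samples
    rows = {}
    status = matrix.status_frame()
    cell_of = {s.value: MUTATION_CELL[s] for s in CallStatus}
    for gene, pchange in variants_shown:
        key = variant_keys[(gene, pchange)]
        label = f"{gene} {pchange}"
        if key in status.index:
            rows[label] = [cell_of[status.at[key, sid]] for sid in samples]
        else:
            rows[label] = ["no_coverage"] * len(samples)
    for gene in cn_genes:
        if gene not in interval_map:
            raise ValueError(f"gene {gene!r} absent from the interval map")
        chrom, start, end = interval_map[gene]
        row = []
        for sid in samples:
            if sid in profiles:
                row.append(gene_cn_category(profiles[sid], chrom, start, end))
            else:
                row.append("")
        rows[f"{gene} (CN)"] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)
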