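"""End-to-end orchestration: load a dataset, filter, and run every analysis.

The on-disk layout consumed here is the one the simulator emits (and that
real data must be converted to): a sample sheet, per-sample site tables
(read support at every candidate site, called or not), per-sample window
counts, a reference FASTA, a gene interval BED and a COSMIC-count TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ctc_concord import cna as cna_mod
from ctc_concord import concordance as conc_mod
from ctc_concord import drivers as drivers_mod
from ctc_concord import spectra as spectra_mod
from ctc_concord import variants as variants_mod
from ctc_concord.io_core import (
    MutationKey,
    RunConfig,
    RunLog,
    SampleClass,
    SampleMeta,
    VariantCall,
    WindowCounts,
    group_by_patient,
    read_calls,
    read_cosmic_counts,
    read_gene_intervals,
    read_sample_sheet,
    read_window_counts,
    write_segments,
)


@dataclass
class Dataset:
    root: Path
    metas: list[SampleMeta]
    calls: dict                    # sample_id -> list[VariantCall], all rows
    windows: dict                  # sample_id -> WindowCounts
    reference: Mapping             # contig -> sequence
    genes: pd.DataFrame
    cosmic: "drivers_mod.CosmicCounts"

    def patients(self) -> dict[str, list[SampleMeta]]:
        return group_by_patient(self.metas)

    def meta(self, sample_id: str) -> SampleMeta:
        return next(m for m in self.metas if m.sample_id == sample_id)


def load_dataset(root: str | Path, reference: Optional[Mapping] = None) -> Dataset:
    root = Path(root)
    metas = read_sample_sheet(root / "sample_sheet.tsv")
    calls = {}
    windows = {}
    for m in metas:
        calls[m.sample_id] = read_calls(
            root / "samples" / f"{m.sample_id}.sites.tsv", m
        )
        windows[m.sample_id] = read_window_counts(
            root / "samples" / f"{m.sample_id}.windows.tsv"
        )
    if reference is None:
        from pyfaidx import Fasta

        reference = Fasta(str(root / "reference.fa"))
    genes = read_gene_intervals(root / "genes.bed")
    cosmic = read_cosmic_counts(root / "cosmic_counts.tsv")
    return Dataset(root, metas, calls, windows, reference, genes, cosmic)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    removed_kmer: int = 0
    removed_cross_patient: int = 0
    removed_vaf: int = 0


def apply_filters(
    ds: Dataset, cfg: RunConfig, log: Optional[RunLog] = None
) -> tuple[dict, FilterReport]:
    """Blacklist k-mer, cross-patient, then VAF filter; returns filtered calls.

    The three filters operate on disjoint predicates and commute; this order
    is fixed only for reporting.  The VAF rescue uses the patient bulk's
    called keys *after* the first two filters.
    """
    report = FilterReport()
    filtered: dict[str, list[VariantCall]] = {}
    for sid, calls in ds.calls.items():
        kept, removed = variants_mod.filter_artifact_kmer(calls, ds.reference, cfg)
        filtered[sid] = kept
        report.removed_kmer += sum(1 for c in removed if c.called)

    by_patient: dict[str, list[VariantCall]] = {}
    for m in ds.metas:
        by_patient.setdefault(m.patient_id, []).extend(filtered[m.sample_id])
    kept_by_patient, removed_by_patient = variants_mod.filter_cross_patient(
        by_patient
    )
    report.removed_cross_patient = sum(
        sum(1 for c in v if c.called) for v in removed_by_patient.values()
    )
    filtered = _split_by_sample(kept_by_patient, ds.metas)

    for pid, metas in ds.patients().items():
        bulk = next(m for m in metas if m.sample_class == SampleClass.BULK_TUMOR)
        bulk_keys = {c.key for c in filtered[bulk.sample_id] if c.called}
        for m in metas:
            kept, removed = variants_mod.filter_vaf(
                filtered[m.sample_id], bulk_keys, cfg
            )
            filtered[m.sample_id] = kept
            report.removed_vaf += len(removed)
    if log is not None:
        log.record(
            "filters",
            removed_kmer=report.removed_kmer,
            removed_cross_patient=report.removed_cross_patient,
            removed_vaf=report.removed_vaf,
        )
    return filtered, report


def _split_by_sample(by_patient: dict, metas) -> dict:
    out: dict[str, list[VariantCall]] = {m.sample_id: [] for m in metas}
    for calls in by_patient.values():
        for c in calls:
            out[c.sample_id].append(c)
    return out


# ---------------------------------------------------------------------------
# Per-patient analyses
# ---------------------------------------------------------------------------


@dataclass
class PatientResults:
    patient_id: str
    categories: variants_mod.MutationCategories
    bulk_keys: set
    recovery: dict = field(default_factory=dict)  # (mutation_set, selection)
    low_cov_pooled: float = float("nan")
    low_cov_per_sample: Optional[pd.Series] = None
    vaf_comparison: Optional[conc_mod.GroupComparison] = None
    vaf_corr_per_sample: Optional[pd.DataFrame] = None
    vaf_corr_pooled: Optional[conc_mod.VafCorrelation] = None
    selected_keys: set = field(default_factory=set)


def analyze_patient_mutations(
    pid: str,
    metas: list[SampleMeta],
    filtered: dict,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> PatientResults:
    called_sets = variants_mod.called_key_sets(
        {m.sample_id: filtered[m.sample_id] for m in metas}
    )
    cats = variants_mod.categorize(called_sets, metas)
    bulk_keys = cats.keys_in("bulk_only") | cats.keys_in("ctc_bulk")
    res = PatientResults(pid, cats, bulk_keys)

    ctc_metas = [m for m in metas if m.sample_class.is_ctc]
    ctc_ids = [m.sample_id for m in ctc_metas]
    depth_tables = {
        sid: {c.key: c.depth for c in filtered[sid]} for sid in ctc_ids
    }
    ctc_called = {sid: called_sets[sid] for sid in ctc_ids}
    if not bulk_keys or not ctc_ids:
        return res

    bulk_meta = next(m for m in metas if m.sample_class == SampleClass.BULK_TUMOR)
    bulk_rows = {c.key: c for c in filtered[bulk_meta.sample_id] if c.called}
    nonsyn = {
        k for k in bulk_keys
        if bulk_rows.get(k) is not None
        and bulk_rows[k].effect in ("nonsynonymous", "nonsense")
    }
    selected = conc_mod.select_covered(bulk_keys, depth_tables, cfg)
    res.selected_keys = selected

    for mset_name, mset in (("all", bulk_keys), ("nonsyn_nonsense", nonsyn)):
        for sel_name, sel in (("all_bulk", mset), ("covered_20x", mset & selected)):
            if not sel:
                continue
            res.recovery[(mset_name, sel_name)] = conc_mod.recovery_curve(
                sorted(sel), ctc_called, cfg, rng,
                mutation_set=mset_name, selection=sel_name,
            )

    res.low_cov_pooled, res.low_cov_per_sample = conc_mod.low_coverage_fraction(
        sorted(bulk_keys), depth_tables, cfg
    )

    bulk_vafs = {
        k: bulk_rows[k].vaf
        for k in selected
        if k in bulk_rows and bulk_rows[k].vaf is not None
    }
    called_any = {
        k: any(k in ctc_called[sid] for sid in ctc_ids) for k in bulk_vafs
    }
    res.vaf_comparison = conc_mod.vaf_called_vs_notcalled(bulk_vafs, called_any)

    ctc_vafs = {
        sid: {
            c.key: c.vaf
            for c in filtered[sid]
            if c.called and c.key in bulk_vafs and c.vaf is not None
        }
        for sid in ctc_ids
    }
    res.vaf_corr_per_sample, res.vaf_corr_pooled = (
        conc_mod.vaf_correlations_per_sample(bulk_vafs, ctc_vafs)
    )
    return res


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


def sample_spectra(
    ds: Dataset,
    filtered: dict,
    cfg: RunConfig,
    include_classes: tuple = (
        SampleClass.CTC_SINGLE, SampleClass.CTC_POOL, SampleClass.WBC_POOL,
    ),
    private_only: bool = False,
    categories: Optional[dict] = None,
) -> list[spectra_mod.Spectrum]:
    """Context spectra of CTC/WBC samples from filtered calls.

    Germline-called keys are excluded.  With ``private_only`` the spectrum
    uses only mutations categorized ``ctc_private`` (requires
    ``categories``, patient_id -> MutationCategories).
    """
    out = []
    germline_keys: dict[str, set] = {}
    for pid, metas in ds.patients().items():
        germ = next(
            m for m in metas if m.sample_class == SampleClass.GERMLINE_BLOOD
        )
        germline_keys[pid] = {c.key for c in filtered[germ.sample_id] if c.called}
    for m in ds.metas:
        if m.sample_class not in include_classes:
            continue
        keys = {c.key for c in filtered[m.sample_id] if c.called}
        keys -= germline_keys[m.patient_id]
        if private_only:
            keys &= categories[m.patient_id].keys_in("ctc_private")
        out.append(
            spectra_mod.context_spectrum(sorted(keys), ds.reference, m.sample_id)
        )
    return out


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------


def build_cn_profiles(
    ds: Dataset, cfg: RunConfig, rng: np.random.Generator
) -> dict[str, cna_mod.CNProfile]:
    """CN profiles for bulk and CTC samples, normalized to matched controls.

    Bulk samples are normalized to germline blood and purity-corrected; CTC
    samples are normalized to the patient's WBC pool and taken as pure.
    """
    profiles: dict[str, cna_mod.CNProfile] = {}
    for pid, metas in ds.patients().items():
        germ = next(m for m in metas if m.sample_class == SampleClass.GERMLINE_BLOOD)
        wbc = next(m for m in metas if m.sample_class == SampleClass.WBC_POOL)
        for m in metas:
            if m.sample_class == SampleClass.BULK_TUMOR:
                control, correct = germ, True
            elif m.sample_class.is_ctc:
                control, correct = wbc, False
            else:
                continue
            profiles[m.sample_id] = cna_mod.build_profile(
                m.sample_id,
                ds.windows[m.sample_id],
                ds.windows[control.sample_id],
                cfg,
                correct_purity=correct,
                rng=rng,
            )
    return profiles


# ---------------------------------------------------------------------------
# Drivers / oncoplot
# ---------------------------------------------------------------------------


def oncoplot_for_patient(
    ds: Dataset,
    pid: str,
    filtered: dict,
    profiles: dict,
    cfg: RunConfig,
    driver_cna_genes=drivers_mod.DRIVER_CNA_GENES,
) -> pd.DataFrame:
    metas = [m for m in ds.patients()[pid]
             if m.sample_class == SampleClass.BULK_TUMOR or m.sample_class.is_ctc]
    events = [
        drivers_mod.AnnotatedMutation(c.key, c.sample_id, c.gene, c.protein_change)
        for m in metas
        for c in filtered[m.sample_id]
        if c.called and c.gene
    ]
    variants_shown = drivers_mod.select_oncoplot_variants(events, ds.cosmic)
    variant_keys = {
        (m.gene, m.protein_change): m.key
        for m in events
        if m.protein_change
    }
    variants_shown = [v for v in variants_shown if v in variant_keys]
    keys = sorted({variant_keys[v] for v in variants_shown})
    matrix = variants_mod.CallMatrix.from_calls(
        pid, {m.sample_id: filtered[m.sample_id] for m in metas}, mutations=keys
    )
    cn_genes = [
        g for g in driver_cna_genes if g in set(ds.genes["gene"])
    ]
    sample_profiles = {
        m.sample_id: profiles[m.sample_id]
        for m in metas if m.sample_id in profiles
    }
    return drivers_mod.oncoplot_table(
        variants_shown, variant_keys, matrix, cn_genes, ds.genes, sample_profiles
    )


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_all(
    root: str | Path,
    cfg: RunConfig,
    outdir: str | Path,
    reference: Optional[Mapping] = None,
) -> dict:
    """Run the complete analysis on a dataset directory; write all reports.

    Returns a summary dict (also written as ``summary.json``).
    """
    root = Path(root)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog(cfg.rng_seed, cfg.config_hash())
    rng = np.random.default_rng(cfg.rng_seed)
    ds = load_dataset(root, reference=reference)
    log.record("load", n_samples=len(ds.metas))

    filtered, _rep = apply_filters(ds, cfg, log)

    summary: dict = {"patients": {}}
    cat_frames = []
    count_frames = []
    recovery_frames = []
    vaf_rows = []
    corr_frames = []
    patient_results: dict[str, PatientResults] = {}
    for pid, metas in sorted(ds.patients().items()):
        res = analyze_patient_mutations(pid, metas, filtered, cfg, rng)
        patient_results[pid] = res
        cf = variants_mod.categories_frame(res.categories)
        cf.insert(0, "patient_id", pid)
        cat_frames.append(cf)
        counts = res.categories.per_sample_counts.copy()
        counts.insert(0, "patient_id", pid)
        count_frames.append(counts)
        for (mset, sel), curve in res.recovery.items():
            t = curve.table.copy()
            t.insert(0, "patient_id", pid)
            t.insert(1, "mutation_set", mset)
            t.insert(2, "selection", sel)
            recovery_frames.append(t)
        if res.vaf_comparison is not None and res.vaf_comparison.applicable:
            vaf_rows.append(
                {"patient_id": pid, "p_value": res.vaf_comparison.p_value,
                 "method": res.vaf_comparison.method}
            )
        if res.vaf_corr_per_sample is not None:
            t = res.vaf_corr_per_sample.copy()
            t.insert(0, "patient_id", pid)
            corr_frames.append(t)
        summary["patients"][pid] = {
            "n_bulk_mutations": len(res.bulk_keys),
            "category_counts": {
                c: res.categories.count(c) for c in variants_mod.CATEGORIES
            },
            "low_coverage_fraction": res.low_cov_pooled,
            "union_recovery_all": (
                res.recovery[("all", "all_bulk")].table["median"].iloc[-1]
                if ("all", "all_bulk") in res.recovery else None
            ),
        }
    pd.concat(cat_frames, ignore_index=True).to_csv(
        outdir / "categories.tsv", sep="\t", index=False
    )
    pd.concat(count_frames).to_csv(outdir / "category_counts.tsv", sep="\t")
    if recovery_frames:
        pd.concat(recovery_frames, ignore_index=True).to_csv(
            outdir / "recovery_curve.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
    pd.DataFrame(vaf_rows).to_csv(
        outdir / "vaf_comparison.tsv", sep="\t", index=False
    )
    if corr_frames:
        pd.concat(corr_frames, ignore_index=True).to_csv(
            outdir / "vaf_correlation.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
    log.record("mutations", n_patients=len(patient_results))

    # spectra
    spectra = sample_spectra(ds, filtered, cfg)
    clustering = spectra_mod.cluster_spectra(
        [s for s in spectra if s.total > 0], cfg.spectrum_pseudocount
    )
    spectra_mod.spectra_frame(spectra).to_csv(outdir / "spectra.tsv", sep="\t")
    clustering.distance_matrix.to_csv(
        outdir / "distance_matrix.tsv", sep="\t", float_format="%.6g"
    )
    (outdir / "dendrogram.nwk").write_text(clustering.newick + "\n")
    n_patients = len(ds.patients())
    clusters = clustering.flat_labels(n_patients)
    clusters.to_frame().to_csv(outdir / "clusters.tsv", sep="\t")
    log.record("spectra", n_spectra=len(spectra))

    # copy number
    profiles = build_cn_profiles(ds, cfg, rng)
    seg_frames = []
    cn_window_cols = {}
    for sid in sorted(profiles):
        p = profiles[sid]
        segs = p.segments.copy()
        segs.insert(0, "sample", sid)
        seg_frames.append(segs)
        cn_window_cols[sid] = p.window_cn()
        summary["patients"].setdefault(ds.meta(sid).patient_id, {})
    all_segs = pd.concat(seg_frames, ignore_index=True)
    write_segments(all_segs, outdir / "segments.tsv")
    grid = next(iter(profiles.values())).windows[["chrom", "start", "end"]]
    cn_windows = pd.concat([grid.reset_index(drop=True),
                            pd.DataFrame(cn_window_cols)], axis=1)
    cn_windows.to_csv(outdir / "cn_windows.tsv", sep="\t", index=False,
                      float_format="%.4f")
    rho_df, _Z, newick = cna_mod.cna_concordance(list(profiles.values()))
    rho_df.to_csv(outdir / "concordance_matrix.tsv", sep="\t",
                  float_format="%.4f")
    (outdir / "cna_dendrogram.nwk").write_text(newick + "\n")
    for pid in ds.patients():
        bulk = next(m for m in ds.patients()[pid]
                    if m.sample_class == SampleClass.BULK_TUMOR)
        prof = profiles[bulk.sample_id]
        summary["patients"][pid]["n_cnas_bulk"] = cna_mod.count_cnas(prof.segments)
        if prof.purity_fit is not None:
            summary["patients"][pid]["purity_estimate"] = prof.purity_fit.rho
    log.record("cna", n_profiles=len(profiles))

    # oncoplot per patient
    for pid in sorted(ds.patients()):
        table = oncoplot_for_patient(ds, pid, filtered, profiles, cfg)
        table.to_csv(outdir / f"oncoplot_{pid}.tsv", sep="\t")
    log.record("drivers", n_patients=len(ds.patients()))

    log.write(outdir / "run_log.json")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return {
        "summary": summary,
        "patient_results": patient_results,
        "profiles": profiles,
        "clustering": clustering,
        "concordance": rho_df,
        "filtered": filtered,
        "dataset": ds,
    }
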