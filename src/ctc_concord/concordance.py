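"""Recovery of bulk mutations in CTC samples and VAF concordance.

The central question: what fraction of the mutations called in a bulk tumor
biopsy is recovered by sequencing k of the patient's CTC samples?  Recovery
is computed over subsets of CTC samples of each size k (exhaustively when
feasible, otherwise by seeded Monte-Carlo subset sampling), for all bulk
mutations and for the subset with adequate CTC coverage, and the VAF of
recovered versus missed bulk mutations is compared with a two-sided
Wilcoxon rank-sum test.  VAF agreement between bulk and CTCs is summarized
by Spearman correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ctc_concord.io_core import MutationKey, RunConfig


# ---------------------------------------------------------------------------
# Coverage-conditioned selection
# ---------------------------------------------------------------------------


def select_covered(
    bulk_keys: Iterable[MutationKey],
    ctc_depths: Mapping[str, Mapping[MutationKey, int]],
    cfg: RunConfig,
) -> set[MutationKey]:
    """Bulk mutations with >= ``min_select_depth`` coverage in >= 1 CTC sample.

    Missing depth entries count as zero coverage.
    """
    selected = set()
    for key in bulk_keys:
        best = max(
            (depths.get(key, 0) for depths in ctc_depths.values()), default=0
        )
        if best >= cfg.min_select_depth:
            selected.add(key)
    return selected


def low_coverage_fraction(
    bulk_keys: Sequence[MutationKey],
    ctc_depths: Mapping[str, Mapping[MutationKey, int]],
    cfg: RunConfig,
) -> tuple[float, pd.Series]:
    """Fraction of (bulk mutation, CTC sample) pairs with depth < threshold.

    Returns the pooled fraction over all pairs (the headline number) and a
    per-sample Series of fractions.
    """
    if not bulk_keys or not ctc_depths:
        raise ValueError("need at least one bulk mutation and one CTC sample")
    per_sample = {}
    total_low = 0
    for sid in sorted(ctc_depths):
        depths = ctc_depths[sid]
        n_low = sum(1 for k in bulk_keys if depths.get(k, 0) < cfg.low_cov_depth)
        per_sample[sid] = n_low / len(bulk_keys)
        total_low += n_low
    pooled = total_low / (len(bulk_keys) * len(ctc_depths))
    return pooled, pd.Series(per_sample, name="low_coverage_fraction")


# ---------------------------------------------------------------------------
# Recovery curves
# ---------------------------------------------------------------------------


@dataclass
class RecoveryCurve:
    """Median/min/max recovered fraction of bulk mutations per subset size k."""

    table: pd.DataFrame  # columns: k, median, min, max, n_subsets, mode
    mutation_set: str = "all"       # or "nonsyn_nonsense"
    selection: str = "all_bulk"     # or "covered_20x"

    def median(self, k: int) -> float:
        row = self.table.loc[self.table["k"] == k]
        return float(row["median"].iloc[0])


def _subsets(
    n: int, k: int, max_exhaustive: int, rng: np.random.Generator
) -> tuple[list[tuple[int, ...]], str]:
    """All k-subsets of range(n), or seeded distinct uniform draws."""
    total = math.comb(n, k)
    if total <= max_exhaustive:
        return list(itertools.combinations(range(n), k)), "exhaustive"
    seen: set[tuple[int, ...]] = set()
    # distinct-subset sampling; collision probability is negligible when
    # total >> max_exhaustive, so the attempt bound is generous
    attempts = 0
    while len(seen) < max_exhaustive and attempts < 20 * max_exhaustive:
        s = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        seen.add(s)
        attempts += 1
    return sorted(seen), "monte_carlo"


def recovery_curve(
    bulk_keys: Sequence[MutationKey],
    ctc_called: Mapping[str, set[MutationKey]],
    cfg: RunConfig,
    rng: Optional[np.random.Generator] = None,
    mutation_set: str = "all",
    selection: str = "all_bulk",
) -> RecoveryCurve:
    """Recovered fraction of ``bulk_keys`` versus number of CTC samples used.

    For each k, the recovered fraction of a subset S of CTC samples is the
    fraction of bulk mutations called in at least one sample of S.  Subsets
    are enumerated exhaustively when C(n, k) <= ``max_exhaustive_subsets``,
    otherwise sampled uniformly (distinct subsets, seeded).
    """
    if not bulk_keys:
        raise ValueError("empty bulk mutation set")
    if not ctc_called:
        raise ValueError("need at least one CTC sample")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    bulk = set(bulk_keys)
    sids = sorted(ctc_called)
    hits = [bulk & ctc_called[s] for s in sids]
    rows = []
    for k in range(1, len(sids) + 1):
        subs, mode = _subsets(len(sids), k, cfg.max_exhaustive_subsets, rng)
        fracs = np.empty(len(subs))
        for i, sub in enumerate(subs):
            union: set[MutationKey] = set()
            for j in sub:
                union |= hits[j]
            fracs[i] = len(union) / len(bulk)
        rows.append(
            {
                "k": k,
                "median": float(np.median(fracs)),
                "min": float(fracs.min()),
                "max": float(fracs.max()),
                "n_subsets": len(subs),
                "mode": mode,
            }
        )
    table = pd.DataFrame(rows)
    _check_curve(table)
    return RecoveryCurve(table, mutation_set=mutation_set, selection=selection)


def _check_curve(table: pd.DataFrame) -> None:
    if not ((table["min"] <= table["median"]) & (table["median"] <= table["max"])).all():
        raise AssertionError("recovery curve: min <= median <= max violated")
    exhaustive = table[table["mode"] == "exhaustive"]
    med = exhaustive["median"].to_numpy()
    if len(med) > 1 and not (np.diff(med) >= -1e-12).all():
        raise AssertionError("exhaustive recovery median must be non-decreasing in k")


# ---------------------------------------------------------------------------
# VAF statistics
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    applicable: bool
    p_value: Optional[float] = None
    method: str = ""
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def vaf_called_vs_notcalled(
    bulk_vafs: Mapping[MutationKey, float],
    called_in_ctc: Mapping[MutationKey, bool],
    exact_max_n: int = 25,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test of bulk VAFs: recovered vs missed.

    Uses exact enumeration when both groups have <= ``exact_max_n``
    observations and there are no ties, otherwise the normal approximation
    with tie and continuity correction.
    """
    called = [v for k, v in bulk_vafs.items() if called_in_ctc.get(k, False)]
    missed = [v for k, v in bulk_vafs.items() if not called_in_ctc.get(k, False)]
    summary = pd.DataFrame(
        {
            "group": ["called", "not_called"],
            "n": [len(called), len(missed)],
            "median_vaf": [
                float(np.median(called)) if called else np.nan,
                float(np.median(missed)) if missed else np.nan,
            ],
        }
    )
    if not called or not missed:
        return GroupComparison(False, None, "not_applicable", summary)
    pooled = called + missed
    has_ties = len(set(pooled)) < len(pooled)
    if len(called) <= exact_max_n and len(missed) <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        called, missed, alternative="two-sided", method=method, use_continuity=True
    )
    return GroupComparison(True, float(res.pvalue), method, summary)


@dataclass
class VafCorrelation:
    applicable: bool
    rho: Optional[float] = None
    p_value: Optional[float] = None
    n: int = 0


def vaf_correlation(
    pairs: Sequence[tuple[float, float]],
) -> VafCorrelation:
    """Spearman correlation between bulk VAF and CTC VAF over common mutations.

    Average ranks on ties; the p-value comes from the t approximation.
    Requires at least 3 pairs.
    """
    if len(pairs) < 3:
        return VafCorrelation(False, n=len(pairs))
    x, y = zip(*pairs)
    rho, p = stats.spearmanr(x, y)
    return VafCorrelation(True, float(rho), float(p), len(pairs))


def vaf_correlations_per_sample(
    bulk_vafs: Mapping[MutationKey, float],
    ctc_vafs: Mapping[str, Mapping[MutationKey, float]],
) -> tuple[pd.DataFrame, VafCorrelation]:
    """Per-CTC-sample and pooled Spearman correlation of bulk vs CTC VAFs.

    Only mutations with a defined VAF in both the bulk and the CTC sample
    enter; the pooled correlation uses all (mutation, sample) pairs.
    """
    rows = []
    pooled_pairs: list[tuple[float, float]] = []
    for sid in sorted(ctc_vafs):
        pairs = [
            (bulk_vafs[k], v)
            for k, v in ctc_vafs[sid].items()
            if k in bulk_vafs
        ]
        pooled_pairs.extend(pairs)
        corr = vaf_correlation(pairs)
        rows.append(
            {
                "sample_id": sid,
                "n": corr.n,
                "rho": corr.rho if corr.applicable else np.nan,
                "p_value": corr.p_value if corr.applicable else np.nan,
            }
        )
    pooled = vaf_correlation(pooled_pairs)
    return pd.DataFrame(rows), pooled


# ---------------------------------------------------------------------------
# Allele-dropout read-through
# ---------------------------------------------------------------------------


def implied_ado(recovery_k1: float, locus_dropout_rate: float) -> float:
    """Allele-dropout rate implied by single-sample recovery of het mutations.

    With deep coverage, a heterozygous truncal mutation is recovered in a
    single whole-genome-amplified sample iff the site is amplified
    (probability ``1 - locus_dropout_rate``) and the alternate allele
    survived dropout (probability ``1 - ado``), so
    ``recovery = (1 - d) * (1 - ado)``.
    """
    if not 0 <= locus_dropout_rate < 1:
        raise ValueError("locus_dropout_rate must be in [0, 1)")
    detect_given_amplified = recovery_k1 / (1.0 - locus_dropout_rate)
    return float(np.clip(1.0 - detect_given_amplified, 0.0, 1.0))
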