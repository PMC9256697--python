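"""Window-based copy-number pipeline.

Read counts in fixed 10 kb windows are normalized against a matched control
(the WBC pool for CTC samples, germline blood for the bulk), segmented per
chromosome by circular binary segmentation (CBS) with a permutation test,
converted to absolute copy number — via a grid-search purity/ploidy
corrector for the impure bulk, directly for CTC samples which are taken as
pure — rescaled to a ploidy of 2, categorized (amp / gain / neutral / del /
deep del), and compared across samples by Spearman correlation of the
per-window copy-number vectors.

The purity model: a bulk sample with tumor purity ``rho`` and tumor ploidy
``tau`` produces, in a region of tumor copy number ``q``, a library-scaled
count ratio ``R = (rho*q + 2*(1-rho)) / (rho*tau + 2*(1-rho))`` against a
diploid control.  The corrector grid-searches (rho, tau), scoring each pair
by how close the implied ``q`` values of all segments are to integers
(window-weighted), with a penalty for the unidentifiable solution in which
every segment lands on the same integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ctc_concord.io_core import RunConfig, WindowCounts
from ctc_concord.spectra import linkage_to_newick

CN_CATEGORIES = ["amp", "gain", "neutral", "del", "deep_del"]


@dataclass
class PurityFit:
    rho: float
    tau: float
    objective: float
    degenerate: bool = False
    corrected: bool = True
    alternatives: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class CNProfile:
    """Per-window log2 ratios plus segmentation and absolute copy number."""

    sample_id: str
    windows: pd.DataFrame          # chrom, start, end, log2, masked
    segments: Optional[pd.DataFrame] = None
    window_segment: Optional[np.ndarray] = None  # segment row index, -1 = masked
    purity_fit: Optional[PurityFit] = None

    def window_cn(self) -> np.ndarray:
        """Ploidy-normalized segment-mean CN per window (NaN where masked)."""
        if self.segments is None or "cn" not in self.segments.columns:
            raise ValueError("profile not yet assigned copy numbers")
        cn = np.full(len(self.windows), np.nan)
        seg_cn = self.segments["cn"].to_numpy()
        ok = self.window_segment >= 0
        cn[ok] = seg_cn[self.window_segment[ok]]
        return cn


# ---------------------------------------------------------------------------
# Control normalization
# ---------------------------------------------------------------------------


def normalize_to_control(
    sample: WindowCounts, control: WindowCounts, cfg: RunConfig
) -> pd.DataFrame:
    """Library-size-scaled log2 ratio of sample vs control per window.

    ``ratio_i = (s_i / sum(s)) / (c_i / sum(c))``.  Windows whose control
    count is below ``min_control_count`` are masked and excluded downstream.
    Returns a frame with columns chrom, start, end, log2, masked.
    """
    if not sample.same_grid(control):
        raise ValueError("sample and control window grids differ")
    s = sample.df["count"].to_numpy(dtype=float)
    c = control.df["count"].to_numpy(dtype=float)
    masked = c < cfg.min_control_count
    ratio = np.full(len(s), np.nan)
    ok = ~masked
    ratio[ok] = (s[ok] / s.sum()) / (c[ok] / c.sum())
    log2 = np.full(len(s), np.nan)
    pos = ok & (ratio > 0)
    log2[pos] = np.log2(ratio[pos])
    masked = masked | (ok & ~(ratio > 0))
    out = sample.df[["chrom", "start", "end"]].copy()
    out["log2"] = log2
    out["masked"] = masked
    return out


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------


def _max_arc_tsq(x: np.ndarray, min_width: int) -> float:
    """Max two-sample t^2 over all circular arc/complement partitions of x."""
    batch = _batch_max_arc_tsq(x[None, :], min_width)
    return float(batch[0])


def _batch_max_arc_tsq(X: np.ndarray, min_width: int) -> np.ndarray:
    """Row-wise max arc-vs-complement t^2 for a batch of stretches.

    Arcs are contiguous runs x[i:j]; complements of contiguous arcs cover the
    wrapped arcs, so all circular partitions are scanned.  Pooled-variance
    two-sample t statistic, maximized as t^2 (monotone in |t|).

    For an arc with sum A and length k out of (n, T, T2): the mean difference
    is ``A/k - (T-A)/(n-k)`` and the within-groups sum of squares reduces to
    ``T2 - A^2/k - (T-A)^2/(n-k)``, so only prefix sums of x are needed.
    """
    B, n = X.shape
    if n < 2 * min_width:
        return np.zeros(B)
    S = np.concatenate([np.zeros((B, 1)), np.cumsum(X, axis=1)], axis=1)
    total = S[:, -1:]
    total2 = (X * X).sum(axis=1, keepdims=True)
    best = np.zeros(B)
    f = n - 2
    eps = 1e-12 * float(np.max(total2)) + 1e-300
    for k in range(min_width, n - min_width + 1):
        c1 = 1.0 / k
        c2 = 1.0 / (n - k)
        c3 = c1 + c2
        A = S[:, k:] - S[:, :-k]          # arc sums, shape (B, n-k+1)
        diff = A * c3 - total * c2
        ss = total2 - total * total * c2 + A * (2.0 * c2) * total - A * A * c3
        denom = ss * (c3 / f)
        tsq = diff * diff
        # ss == 0 with a nonzero mean difference is a perfect separation
        perfect = (ss < eps) & (tsq > eps)
        np.maximum(denom, eps, out=denom)
        tsq /= denom
        tsq[perfect] = np.inf
        best = np.maximum(best, tsq.max(axis=1))
    return best


def _best_arc(x: np.ndarray, min_width: int) -> tuple[int, int, float]:
    """Arg-max arc boundaries (i, j) and the max t^2 for one stretch."""
    n = len(x)
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    total2 = float(np.dot(x, x))
    best = (0, n, 0.0)
    f = n - 2
    eps = 1e-12 * total2 + 1e-300
    for k in range(min_width, n - min_width + 1):
        c1 = 1.0 / k
        c2 = 1.0 / (n - k)
        c3 = c1 + c2
        A = S[k:] - S[:-k]
        diff = A * c3 - total * c2
        ss = total2 - total * total * c2 + A * (2.0 * c2) * total - A * A * c3
        denom = np.maximum(ss * (c3 / f), eps)
        tsq = diff * diff / denom
        perfect = (ss < eps) & (tsq > eps)
        tsq = np.where(perfect, np.inf, tsq)
        i = int(np.argmax(tsq))
        if tsq[i] > best[2]:
            best = (i, i + k, float(tsq[i]))
    return best


def _split_significant(
    x: np.ndarray, cfg: RunConfig, rng: np.random.Generator
) -> Optional[tuple[int, int]]:
    """Permutation test for the best arc split; None if not significant.

    The p-value is ``(1 + #{perm max-t^2 >= observed}) / (1 + nperm)``.
    Permutations are drawn in growing blocks and stop early once enough
    exceedances guarantee p >= alpha (early stopping can only *fail to
    reject*, so calibration is preserved).
    """
    n = len(x)
    if n < 2 * cfg.cbs_min_width:
        return None
    i, j, obs = _best_arc(x, cfg.cbs_min_width)
    if obs <= 0:
        return None
    nperm = cfg.cbs_nperm
    reject_at = int(np.floor(cfg.cbs_alpha * (nperm + 1)))  # stop if cnt >= this
    count = 0
    done = 0
    block = 25
    while done < nperm:
        b = min(block, nperm - done)
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        stats_b = _batch_max_arc_tsq(perms, cfg.cbs_min_width)
        count += int((stats_b >= obs).sum())
        done += b
        if count >= reject_at:
            return None
        block = min(block * 2, 400)
    p = (1 + count) / (1 + nperm)
    if p < cfg.cbs_alpha:
        return (i, j)
    return None


def cbs_segment(
    windows: pd.DataFrame,
    cfg: RunConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Segment per-window log2 ratios chromosome by chromosome.

    ``windows`` needs columns chrom, start, end, log2, masked.  Returns the
    segment table (chrom, start, end, n_windows, mean_log2) and the
    per-window segment assignment (-1 for masked windows).  Degenerate
    stretches (too few unmasked windows) become single segments.

    After the recursive splitting, adjacent segments whose two-sample t
    statistic falls below ``cfg.cbs_undo_z`` are re-merged (weakest boundary
    first).  Permutation false rejections land just above the acceptance
    threshold (|t| around 4-5) whereas genuine copy-number boundaries in
    window-count data sit far higher, so this prunes the spurious interior
    splits that a maximizing arc test otherwise scatters over long null
    stretches.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    window_segment = np.full(len(windows), -1, dtype=int)
    seg_rows: list[dict] = []
    for chrom in windows["chrom"].unique():
        chrom_mask = (windows["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(chrom_mask & ~windows["masked"].to_numpy())
        if len(idx) == 0:
            continue
        x = windows["log2"].to_numpy()[idx]
        boundaries = _segment_recursive(x, cfg, rng)
        boundaries = _undo_weak_splits(x, boundaries, cfg.cbs_undo_z)
        for lo, hi in boundaries:
            rows = idx[lo:hi]
            seg_id = len(seg_rows)
            window_segment[rows] = seg_id
            seg_rows.append(
                {
                    "chrom": chrom,
                    "start": int(windows["start"].iloc[rows[0]]),
                    "end": int(windows["end"].iloc[rows[-1]]),
                    "n_windows": int(hi - lo),
                    "mean_log2": float(x[lo:hi].mean()),
                }
            )
    segments = pd.DataFrame(
        seg_rows, columns=["chrom", "start", "end", "n_windows", "mean_log2"]
    )
    return segments, window_segment


def _undo_weak_splits(
    x: np.ndarray, boundaries: list, z: float
) -> list:
    """Merge adjacent segments whose two-sample t falls below ``z``.

    Boundaries are (lo, hi) runs tiling ``x``.  The weakest boundary is
    merged first and statistics recomputed, until every remaining neighbor
    pair differs by at least ``z`` standard errors (pooled within-segment
    variance).
    """
    if z <= 0:
        return boundaries
    runs = sorted(boundaries)
    while len(runs) > 1:
        t_vals = []
        for (lo1, hi1), (lo2, hi2) in zip(runs[:-1], runs[1:]):
            a, b = x[lo1:hi1], x[lo2:hi2]
            n1, n2 = len(a), len(b)
            if n1 + n2 < 3:
                t_vals.append(0.0)
                continue
            ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            var = ss / (n1 + n2 - 2)
            if var <= 0:
                t_vals.append(np.inf if a.mean() != b.mean() else 0.0)
                continue
            t_vals.append(
                abs(a.mean() - b.mean()) / np.sqrt(var * (1 / n1 + 1 / n2))
            )
        weakest = int(np.argmin(t_vals))
        if t_vals[weakest] >= z:
            break
        lo1, _hi1 = runs[weakest]
        _lo2, hi2 = runs[weakest + 1]
        runs[weakest : weakest + 2] = [(lo1, hi2)]
    return runs


def _segment_recursive(
    x: np.ndarray, cfg: RunConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome's unmasked values; returns (lo, hi) runs."""
    out: list[tuple[int, int]] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        split = _split_significant(x[lo:hi], cfg, rng)
        if split is None:
            out.append((lo, hi))
            continue
        i, j = split
        pieces = [(lo, lo + i), (lo + i, lo + j), (lo + j, hi)]
        for piece in pieces:
            if piece[1] > piece[0]:
                stack.append(piece)
    return sorted(out)


# ---------------------------------------------------------------------------
# Purity / ploidy correction
# ---------------------------------------------------------------------------

RHO_GRID = np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 2)
TAU_GRID = np.round(np.arange(1.2, 5.0 + 1e-9, 0.05), 2)


def fit_purity_ploidy(
    segments: pd.DataFrame,
    cfg: RunConfig,
    objective_threshold: float = 0.01,
    degenerate_penalty: float = 1.0,
    ploidy_penalty: float = 5e-4,
    cn_prior_weight: float = 3e-4,
    outlier_cap: float = 4.0,
    max_cn: int = 8,
    n_alternatives: int = 5,
    window_log2: Optional[np.ndarray] = None,
    window_segment: Optional[np.ndarray] = None,
) -> tuple[PurityFit, np.ndarray]:
    """Grid-search purity/ploidy corrector for impure bulk profiles.

    A bulk segment with tumor copy number ``q`` has expected count ratio
    ``R = (rho*q + 2*(1-rho)) / (rho*tau + 2*(1-rho))`` against a diploid
    control.  For each grid pair (rho, tau) the implied
    ``q = (R*(rho*tau + 2*(1-rho)) - 2*(1-rho)) / rho`` of every segment is
    snapped to the nearest integer in [0, ``max_cn``] and the segment is
    scored by the squared residual, *on the ratio scale*, between its
    observed mean ratio and the ratio the integer implies.  Scoring in
    observation space keeps segment-mean noise from being amplified by
    1/rho (which biases naive q-space least squares toward rho = 1), and
    the capped integer comb rules out low-purity solutions that explain
    everything with an arbitrarily fine comb.  Three refinements make the
    objective robust at realistic purities:

    * each segment's residual is capped at ``(outlier_cap * sigma_s)^2``
      (sigma_s = its mean-ratio standard error from within-segment window
      scatter), so genuinely non-integer segments — subclonal events —
      cost the same under every candidate instead of rewarding dense combs;
    * the expected noise floor ``min(sigma_s^2, spacing^2/12)`` is
      subtracted per segment, so neither dense nor wide combs are rewarded
      merely for absorbing noise;
    * a karyotype-style prior ``cn_prior_weight * |k - 2|`` penalizes
      extreme integer assignments, breaking coincidental combs that map
      ordinary segments to CN 0 or to high amplifications.

    A mild near-diploid parsimony penalty on tau is added — depth data
    alone cannot break the integer-shift degeneracy of the comb, so
    polyploid genomes are reported at their most parsimonious equivalent —
    plus a large penalty when every segment lands on the same integer (a
    flat profile is unidentifiable).  If no grid point beats
    ``objective_threshold`` the profile is left uncorrected (rho = 1).
    Returns the fit and the per-segment absolute CN (continuous q under the
    chosen fit, clipped at 0).
    """
    if len(segments) < 3:
        raise ValueError("need >= 3 segments to fit purity/ploidy")
    R = np.power(2.0, segments["mean_log2"].to_numpy())
    n_win = segments["n_windows"].to_numpy(dtype=float)
    w = n_win / n_win.sum()
    var_mean = _segment_mean_variance(segments, window_log2, window_segment, R)
    sig2 = np.clip(var_mean, 2.5e-5, None)

    rho = RHO_GRID[:, None]
    tau = TAU_GRID[None, :]
    D = rho * tau + 2.0 * (1.0 - rho)                      # (nr, nt)
    q = (R[:, None, None] * D[None] - 2.0 * (1.0 - rho[None])) / rho[None]
    rounded = np.clip(np.round(q), 0, max_cn)
    model_R = (rho[None] * rounded + 2.0 * (1.0 - rho[None])) / D[None]
    dev2 = (R[:, None, None] - model_R) ** 2
    spacing_var = (rho / D) ** 2 / 12.0
    floor = np.minimum(sig2[:, None, None], spacing_var[None])
    loss = np.minimum(dev2, (outlier_cap ** 2) * sig2[:, None, None]) - floor
    loss = loss + cn_prior_weight * np.abs(rounded - 2.0)
    obj = np.tensordot(w, loss, axes=(0, 0))               # (nr, nt)

    all_same = (rounded == rounded[0]).all(axis=0)
    obj = obj + degenerate_penalty * all_same
    obj = obj + ploidy_penalty * (tau - 2.0) ** 2

    flat = obj.ravel()
    order = np.argsort(flat, kind="stable")
    # among ties at the optimum prefer higher purity, then lower ploidy
    best_val = flat[order[0]]
    tied = np.flatnonzero(flat <= best_val + 1e-12)
    ri, ti = np.unravel_index(tied, obj.shape)
    pick = np.lexsort((ti, -ri))[0]
    bi, bj = int(ri[pick]), int(ti[pick])

    alts = []
    for o in order[:n_alternatives]:
        r_, t_ = np.unravel_index(o, obj.shape)
        alts.append(
            {"rho": float(RHO_GRID[r_]), "tau": float(TAU_GRID[t_]),
             "objective": float(obj[r_, t_])}
        )
    alternatives = pd.DataFrame(alts)

    if obj[bi, bj] >= objective_threshold:
        fit = PurityFit(
            rho=1.0, tau=float(np.sum(w * 2.0 * R)), objective=float(obj[bi, bj]),
            degenerate=bool(all_same[bi, bj]), corrected=False,
            alternatives=alternatives,
        )
        cn = np.clip(2.0 * R, 0.0, None)
        return fit, cn
    fit = PurityFit(
        rho=float(RHO_GRID[bi]), tau=float(TAU_GRID[bj]),
        objective=float(obj[bi, bj]), degenerate=False, corrected=True,
        alternatives=alternatives,
    )
    cn = np.clip(q[:, bi, bj], 0.0, None)
    return fit, cn


def _segment_mean_variance(
    segments: pd.DataFrame,
    window_log2: Optional[np.ndarray],
    window_segment: Optional[np.ndarray],
    R: np.ndarray,
) -> np.ndarray:
    """Sampling variance of each segment's mean ratio.

    Estimated from within-segment window scatter where there are enough
    windows; short segments fall back to the global per-window variance.
    """
    n_win = segments["n_windows"].to_numpy(dtype=float)
    if window_log2 is None or window_segment is None:
        # crude fallback: assume 5% per-window ratio noise
        return (0.05 * R) ** 2 / n_win
    ratios = np.power(2.0, window_log2)
    resid = []
    per_seg = np.full(len(segments), np.nan)
    for s in range(len(segments)):
        vals = ratios[window_segment == s]
        if len(vals) >= 5:
            per_seg[s] = vals.var(ddof=1)
        resid.extend((vals - vals.mean()).tolist())
    global_var = float(np.var(resid)) if len(resid) > 2 else 0.0025
    per_seg = np.where(np.isnan(per_seg), global_var, per_seg)
    return per_seg / n_win


# ---------------------------------------------------------------------------
# Ploidy normalization and categorization
# ---------------------------------------------------------------------------


def normalize_ploidy(
    segments: pd.DataFrame,
    purity_fit: Optional[PurityFit] = None,
    absolute_cn: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Rescale copy number so the window-weighted mean CN is 2.

    Purity-corrected bulk profiles use ``CN' = q * 2 / tau_hat``.  Profiles
    taken as pure (CTCs, pools) use the recentred count ratio directly:
    ``CN' = 2 * R / weighted_mean(R)``.
    """
    w = segments["n_windows"].to_numpy(dtype=float)
    w = w / w.sum()
    if purity_fit is not None and purity_fit.corrected and absolute_cn is not None:
        return absolute_cn * 2.0 / purity_fit.tau
    R = np.power(2.0, segments["mean_log2"].to_numpy())
    center = float(np.sum(w * R))
    return 2.0 * R / center


def categorize_cn(cn: float, cfg: RunConfig) -> str:
    """Category of one ploidy-2-scale CN value (strict-inequality thresholds)."""
    t = cfg.cn_thresholds
    if cn > t["amp"]:
        return "amp"
    if cn > t["gain"]:
        return "gain"
    if cn < t["deep_del"]:
        return "deep_del"
    if cn < t["del"]:
        return "del"
    return "neutral"


def count_cnas(segments: pd.DataFrame) -> int:
    """Number of segments in a non-neutral copy-number category."""
    if "category" not in segments.columns:
        raise ValueError("segments not categorized")
    return int((segments["category"] != "neutral").sum())


# ---------------------------------------------------------------------------
# Full per-sample profile construction
# ---------------------------------------------------------------------------


def build_profile(
    sample_id: str,
    sample_counts: WindowCounts,
    control_counts: WindowCounts,
    cfg: RunConfig,
    correct_purity: bool,
    rng: Optional[np.random.Generator] = None,
) -> CNProfile:
    """Normalize, segment, purity-correct (bulk only), normalize, categorize."""
    windows = normalize_to_control(sample_counts, control_counts, cfg)
    segments, window_segment = cbs_segment(windows, cfg, rng)
    fit: Optional[PurityFit] = None
    absolute: Optional[np.ndarray] = None
    if correct_purity and len(segments) >= 3:
        fit, absolute = fit_purity_ploidy(
            segments, cfg,
            window_log2=windows["log2"].to_numpy(),
            window_segment=window_segment,
        )
    cn = normalize_ploidy(segments, fit, absolute)
    segments = segments.copy()
    segments["cn"] = cn
    segments["category"] = [categorize_cn(v, cfg) for v in cn]
    return CNProfile(sample_id, windows, segments, window_segment, fit)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------


def cna_concordance(
    profiles: Sequence[CNProfile], min_shared_windows: int = 10
):
    """Pairwise Spearman correlation of per-window CN plus sample clustering.

    Correlations use the segment-mean CN assigned to each window, over
    windows unmasked in both profiles.  Samples are then clustered by
    complete linkage on ``1 - rho``.  Returns (rho matrix DataFrame,
    linkage matrix, newick string).
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    ordered = sorted(profiles, key=lambda p: p.sample_id)
    ids = [p.sample_id for p in ordered]
    grid = ordered[0].windows[["chrom", "start", "end"]]
    for p in ordered[1:]:
        if not grid.equals(p.windows[["chrom", "start", "end"]]):
            raise ValueError(f"window grid mismatch for {p.sample_id!r}")
    vectors = [p.window_cn() for p in ordered]
    n = len(ordered)
    rho = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~np.isnan(vectors[i]) & ~np.isnan(vectors[j])
            if ok.sum() < min_shared_windows:
                raise ValueError(
                    f"<{min_shared_windows} shared windows between "
                    f"{ids[i]!r} and {ids[j]!r}"
                )
            r = stats.spearmanr(vectors[i][ok], vectors[j][ok]).statistic
            if np.isnan(r):  # zero variance (e.g. two flat profiles): treat as 0
                r = 0.0
            rho[i, j] = rho[j, i] = r
    rho_df = pd.DataFrame(rho, index=ids, columns=ids)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import squareform

    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    newick = linkage_to_newick(Z, ids)
    return rho_df, Z, newick
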