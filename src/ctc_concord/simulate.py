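"""Synthetic multi-patient CTC/bulk datasets with ground truth.

The generator emulates the statistical structure of whole-exome data from
matched bulk biopsies and whole-genome-amplified (WGA) CTC samples:

* a small synthetic genome (10 chromosomes x 1 Mb by default) with a
  blacklist k-mer planted at known sites;
* per patient, a clone tree with truncal and subclonal mutations, per-clone
  copy-number segments, and planted driver mutations in named genes;
* a bulk sample as an impure mixture of tumor clones and diploid normal
  cells (purity drawn in [0.2, 0.35] by default);
* CTC singles/pools as cells drawn from clone proportions that may diverge
  from the bulk clone fractions, read out through a WGA noise model with
  per-allele dropout (ADO), per-site locus dropout, overdispersed depth, and
  Poisson-count artifact mutations whose trinucleotide contexts follow a
  patient-specific spectrum;
* a WBC pool processed through the same WGA model but carrying no tumor
  mutations (artifact control);
* an emulated caller (minimum depth / alt reads / VAF) producing the called
  flags, so the pipeline's filters see realistic false negatives.

ADO is modeled per allele, independently across sites and samples — a
simplification of the spatially correlated amplification bias of real WGA.

Every randomized step draws from a single seeded generator, so a run is
byte-reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ctc_concord.io_core import (
    MutationKey,
    SampleClass,
    SampleMeta,
    ValidationError,
    VariantCall,
    WindowCounts,
    write_calls_vcf,
    write_sample_sheet,
    write_window_counts,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G on 0..3 codes

EFFECTS = ("nonsynonymous", "nonsense", "synonymous")
EFFECT_PROBS = (0.35, 0.05, 0.60)


# ---------------------------------------------------------------------------
# Configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass
class WGAModel:
    """Whole-genome-amplification noise model for one sample class."""

    ado_rate: float = 0.3            # per-allele dropout probability
    fp_rate: float = 800.0           # expected artifact SNVs per sample
    locus_dropout_rate: float = 0.4  # P(zero coverage at a site)
    coverage_mean: float = 60.0      # negative-binomial depth mean
    coverage_dispersion: float = 2.0  # NB shape r; var = mu + mu^2/r
    artifact_spectrum: Optional[np.ndarray] = None  # 96 context probs
    kmer_artifact_fraction: float = 0.05  # artifacts placed in blacklist k-mer

    def __post_init__(self) -> None:
        for name in ("ado_rate", "locus_dropout_rate", "kmer_artifact_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.fp_rate < 0 or self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValidationError("fp_rate must be >= 0; coverage params positive")
        if self.artifact_spectrum is not None:
            s = np.asarray(self.artifact_spectrum, dtype=float)
            if s.shape != (96,) or (s < 0).any() or not np.isclose(s.sum(), 1.0):
                raise ValidationError("artifact_spectrum must be 96 probs summing to 1")
            self.artifact_spectrum = s


@dataclass
class DriverSpec:
    gene: str
    protein_change: str
    cosmic_count: int
    effect: str = "nonsynonymous"


@dataclass
class CloneSpec:
    """One clone: tree position, bulk CCF, CTC sampling weight, CN events."""

    clone_id: str
    parent: Optional[str]
    ccf_bulk: float
    ctc_fraction: float = 0.0
    n_private_mutations: int = 0
    cn_events: list = field(default_factory=list)  # (chrom, start, end, cn)
    drivers: list = field(default_factory=list)    # DriverSpec


@dataclass
class PatientScenario:
    patient_id: str
    clones: list = field(default_factory=list)
    bulk_purity: Optional[float] = None          # None: sample from range
    bulk_purity_range: tuple = (0.2, 0.35)
    n_ctc_singles: int = 3
    ctc_pool_sizes: tuple = ()
    single_clone_assignment: Optional[list] = None  # force clone per single
    wga_ctc: WGAModel = field(default_factory=WGAModel)
    wga_wbc: WGAModel = field(
        default_factory=lambda: WGAModel(fp_rate=60.0)
    )


@dataclass
class SimConfig:
    n_chroms: int = 10
    chrom_length: int = 1_000_000
    window_size: int = 10_000
    patients: list = field(default_factory=list)
    # bulk / germline sequencing (no WGA)
    bulk_coverage_mean: float = 150.0
    bulk_coverage_dispersion: float = 20.0
    germline_coverage_mean: float = 100.0
    # window read counts
    reads_per_window: float = 2000.0
    window_dispersion_bulk: float = 150.0
    window_dispersion_wga: float = 30.0
    # emulated caller
    caller_min_depth: int = 8
    caller_min_alt: int = 3
    caller_min_vaf: float = 0.05
    # blacklist k-mer planting
    artifact_kmer: str = "TTAACTGACAGC"
    n_kmer_sites: int = 150
    # artifact allele fraction ~ Uniform(lo, hi)
    artifact_vaf_range: tuple = (0.3, 0.9)

    @property
    def n_windows_per_chrom(self) -> int:
        return self.chrom_length // self.window_size


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------


@dataclass
class Genome:
    codes: dict            # chrom -> np.ndarray of uint8 in 0..3
    kmer_sites: list       # (chrom, start0) of planted blacklist k-mer

    @property
    def chroms(self) -> list[str]:
        return list(self.codes)

    def contig_lengths(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.codes.items()}

    def sequences(self) -> dict[str, str]:
        return {
            c: BASES[a].tobytes().decode() for c, a in self.codes.items()
        }

    def base(self, chrom: str, pos: int) -> str:
        return "ACGT"[self.codes[chrom][pos - 1]]

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences().items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def generate_genome(cfg: SimConfig, rng: np.random.Generator) -> Genome:
    kmer_codes = np.array([_BASE_INDEX[b] for b in cfg.artifact_kmer], dtype=np.uint8)
    codes: dict[str, np.ndarray] = {}
    sites: list[tuple[str, int]] = []
    per_chrom = max(1, cfg.n_kmer_sites // cfg.n_chroms)
    for i in range(cfg.n_chroms):
        chrom = f"chr{i + 1}"
        arr = rng.integers(0, 4, size=cfg.chrom_length, dtype=np.uint8)
        starts = rng.choice(
            np.arange(100, cfg.chrom_length - 100 - len(kmer_codes)),
            size=per_chrom, replace=False,
        )
        for s in sorted(starts.tolist()):
            arr[s : s + len(kmer_codes)] = kmer_codes
            sites.append((chrom, int(s)))
        codes[chrom] = arr
    return Genome(codes, sites)


# ---------------------------------------------------------------------------
# Read sampling at a site
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mean, dispersion, size=None):
    r = dispersion
    p = r / (r + np.asarray(mean, dtype=float))
    return rng.negative_binomial(r, p, size=size)


def sample_reads_at_site(
    true_vaf: float, wga: WGAModel, rng: np.random.Generator
) -> tuple[int, int]:
    """Draw (depth, alt_reads) at one site under the WGA noise model.

    The site fails amplification entirely with probability
    ``locus_dropout_rate``.  Otherwise each of the two alleles drops out
    independently with probability ``ado_rate``: losing the alternate allele
    zeroes the read-level allele fraction, losing the reference allele
    doubles it (renormalization of the surviving material).  Depth is
    negative binomial; alt reads are binomial in the post-dropout fraction.
    """
    if not 0.0 <= true_vaf <= 1.0:
        raise ValidationError(f"true_vaf {true_vaf} outside [0, 1]")
    if rng.random() < wga.locus_dropout_rate:
        return 0, 0
    f_alt = true_vaf * (1.0 - (rng.random() < wga.ado_rate if true_vaf > 0 else 0.0))
    f_ref = (1.0 - true_vaf) * (
        1.0 - (rng.random() < wga.ado_rate if true_vaf < 1 else 0.0)
    )
    if f_alt + f_ref == 0:
        return 0, 0
    post = f_alt / (f_alt + f_ref)
    depth = int(_nb_draw(rng, wga.coverage_mean, wga.coverage_dispersion))
    if depth == 0:
        return 0, 0
    alt = int(rng.binomial(depth, post))
    return depth, alt


def _sample_reads_copies(
    n_alt_copies: np.ndarray,
    n_ref_copies: np.ndarray,
    wga: WGAModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized WGA read sampling given allele copy counts per site.

    Used for single cells (1 alt copy, q-1 ref copies) and pools (summed
    over member cells); each template copy survives amplification with
    probability ``1 - ado_rate``.
    """
    n = len(n_alt_copies)
    dropped = rng.random(n) < wga.locus_dropout_rate
    kept_alt = rng.binomial(n_alt_copies, 1.0 - wga.ado_rate)
    kept_ref = rng.binomial(n_ref_copies, 1.0 - wga.ado_rate)
    total = kept_alt + kept_ref
    ok = ~dropped & (total > 0)
    depth = np.zeros(n, dtype=int)
    depth[ok] = _nb_draw(
        rng, wga.coverage_mean, wga.coverage_dispersion, size=int(ok.sum())
    )
    post = np.zeros(n)
    post[ok] = kept_alt[ok] / total[ok]
    alt = rng.binomial(depth, post)
    return depth, alt


# ---------------------------------------------------------------------------
# Artifact spectra and context-aware position sampling
# ---------------------------------------------------------------------------


def disjoint_artifact_spectra(
    n_patients: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Patient-specific 96-class spectra with disjoint supports.

    The 96 context classes are partitioned round-robin; each patient's
    probability mass lives on its own classes with Dirichlet weights.
    """
    out = []
    for p in range(n_patients):
        support = np.arange(96)[np.arange(96) % n_patients == p]
        weights = rng.dirichlet(np.full(len(support), 2.0))
        spec = np.zeros(96)
        spec[support] = weights
        out.append(spec)
    return out


def _class_decomposition(k: int) -> tuple[int, int, int, int]:
    """96-class index -> (ref_code, alt_code, five_code, three_code), pyr strand."""
    sub = k // 16
    five = (k % 16) // 4
    three = k % 4
    ref = 1 if sub < 3 else 3  # C or T
    alts = {0: 0, 1: 2, 2: 3, 3: 0, 4: 1, 5: 2}  # C>A,C>G,C>T,T>A,T>C,T>G
    return ref, alts[sub], five, three


def _context32(k: int) -> int:
    ref, _alt, five, three = _class_decomposition(k)
    return (0 if ref == 1 else 16) + five * 4 + three


class _ContextPool:
    """Per-sample pools of genome positions grouped by pyrimidine context."""

    def __init__(self, genome: Genome, rng: np.random.Generator, n_candidates: int):
        chroms = genome.chroms
        lengths = np.array([len(genome.codes[c]) for c in chroms])
        ci = rng.integers(0, len(chroms), size=n_candidates)
        pos = rng.integers(2, lengths[ci] - 1)  # 1-based, flanks guaranteed
        ctx = np.empty(n_candidates, dtype=int)
        pyr = np.empty(n_candidates, dtype=bool)
        for i_c, chrom in enumerate(chroms):
            sel = ci == i_c
            if not sel.any():
                continue
            codes = genome.codes[chrom]
            p = pos[sel]
            c5, cr, c3 = codes[p - 2], codes[p - 1], codes[p]
            is_pyr = (cr == 1) | (cr == 3)
            rr = np.where(is_pyr, cr, _COMP[cr])
            f5 = np.where(is_pyr, c5, _COMP[c3])
            f3 = np.where(is_pyr, c3, _COMP[c5])
            ctx[sel] = np.where(rr == 1, 0, 16) + f5 * 4 + f3
            pyr[sel] = is_pyr
        self._pools: dict[int, list] = {}
        order = rng.permutation(n_candidates)
        for i in order:
            self._pools.setdefault(int(ctx[i]), []).append(
                (chroms[ci[i]], int(pos[i]), bool(pyr[i]))
            )

    def draw(self, context32: int):
        pool = self._pools.get(context32)
        if not pool:
            return None
        return pool.pop()


# ---------------------------------------------------------------------------
# Clone resolution
# ---------------------------------------------------------------------------


@dataclass
class Clone:
    clone_id: str
    parent: Optional[str]
    ccf_bulk: float
    ctc_fraction: float
    exact_fraction: float          # fraction of bulk tumor cells exactly here
    mutation_rows: np.ndarray      # indices into the patient site table
    cn_windows: np.ndarray         # per-window integer CN (genome order)


@dataclass
class PatientTruth:
    patient_id: str
    bulk_purity: float
    clones: dict                  # clone_id -> Clone
    sites: pd.DataFrame           # chrom,pos,ref,alt,origin,clone,owner,gene,...
    carriers: np.ndarray          # n_clones x n_sites bool (clonal inheritance)
    clone_order: list
    samples: list                 # SampleMeta
    cells_per_sample: dict        # sample_id -> list of clone indices
    tumor_ploidy: float


def _resolve_clones(
    scenario: PatientScenario, n_windows_total: int, window_index
) -> tuple[list[CloneSpec], dict[str, np.ndarray], dict[str, float]]:
    specs = {c.clone_id: c for c in scenario.clones}
    order: list[CloneSpec] = []
    resolved_cn: dict[str, np.ndarray] = {}
    exact: dict[str, float] = {}

    def visit(spec: CloneSpec, parent_cn: np.ndarray) -> None:
        if spec.parent is not None:
            parent = specs[spec.parent]
            if spec.ccf_bulk > parent.ccf_bulk + 1e-12:
                raise ValidationError(
                    f"clone {spec.clone_id}: ccf {spec.ccf_bulk} exceeds "
                    f"parent {spec.parent} ccf {parent.ccf_bulk}"
                )
        cn = parent_cn.copy()
        for chrom, start, end, value in spec.cn_events:
            cn[window_index(chrom, start, end)] = value
        resolved_cn[spec.clone_id] = cn
        order.append(spec)
        for child in scenario.clones:
            if child.parent == spec.clone_id:
                visit(child, cn)

    roots = [c for c in scenario.clones if c.parent is None]
    if len(roots) != 1:
        raise ValidationError("clone tree must have exactly one root")
    if abs(roots[0].ccf_bulk - 1.0) > 1e-9:
        raise ValidationError("truncal clone must have ccf_bulk = 1")
    visit(roots[0], np.full(n_windows_total, 2, dtype=int))

    for spec in order:
        child_sum = sum(
            c.ccf_bulk for c in scenario.clones if c.parent == spec.clone_id
        )
        exact[spec.clone_id] = spec.ccf_bulk - child_sum
        if exact[spec.clone_id] < -1e-9:
            raise ValidationError(
                f"clone {spec.clone_id}: children CCFs exceed own CCF"
            )
    return order, resolved_cn, exact


# ---------------------------------------------------------------------------
# Default three-patient scenario bundle
# ---------------------------------------------------------------------------

#: named genes placed on the synthetic genome (window-aligned, 20 kb each)
DEFAULT_GENES = [
    ("TP53", "chr1", 200_000, 220_000),
    ("MYC", "chr2", 400_000, 420_000),
    ("ERBB2", "chr3", 600_000, 620_000),
    ("AKT1", "chr4", 300_000, 320_000),
    ("CCND1", "chr5", 500_000, 520_000),
    ("ESR1", "chr6", 700_000, 720_000),
    ("PTEN", "chr7", 200_000, 220_000),
    ("RB1", "chr8", 400_000, 420_000),
    ("PER3", "chr9", 600_000, 620_000),
    ("GATA3", "chr10", 300_000, 320_000),
] + [
    (f"GENE{i}", f"chr{i}", 800_000, 820_000) for i in range(1, 11)
]

def default_sim_config(n_truncal: int = 120, n_subclonal: int = 60) -> SimConfig:
    """Three patients mirroring the study's structure.

    Patient P1 (triple-negative-like): CTCs concordant with bulk; truncal
    TP53 mutation and MYC amplification.  Patient P2 (HER2-like): uniform
    ERBB2 amplification in every sample.  Patient P3 (ER-like): a divergent
    CTC-only clone carrying an ESR1 mutation and an ERBB2 amplification,
    absent from the bulk, while the bulk-dominant lineage carries TP53 and a
    PTEN loss that the CTCs lack.
    """
    p1 = PatientScenario(
        patient_id="P1",
        n_ctc_singles=4,
        ctc_pool_sizes=(5, 5, 5),
        clones=[
            CloneSpec(
                "A", None, 1.0, ctc_fraction=0.6,
                n_private_mutations=n_truncal,
                cn_events=[
                    ("chr1", 0, 300_000, 3),
                    ("chr2", 350_000, 500_000, 6),   # MYC amp
                    ("chr3", 500_000, 1_000_000, 1),
                    ("chr5", 600_000, 1_000_000, 3),
                    ("chr7", 0, 250_000, 1),
                    ("chr9", 300_000, 500_000, 4),
                ],
                drivers=[DriverSpec("TP53", "M237K", cosmic_count=30)],
            ),
            CloneSpec(
                "B", "A", 0.25, ctc_fraction=0.4,
                n_private_mutations=n_subclonal,
                cn_events=[("chr6", 0, 200_000, 1)],
            ),
        ],
    )
    p2 = PatientScenario(
        patient_id="P2",
        n_ctc_singles=4,
        ctc_pool_sizes=(10,) * 7,
        clones=[
            CloneSpec(
                "A", None, 1.0, ctc_fraction=0.65,
                n_private_mutations=n_truncal,
                cn_events=[
                    ("chr3", 550_000, 700_000, 6),   # ERBB2 amp, all samples
                    ("chr2", 350_000, 500_000, 5),   # MYC amp
                    ("chr5", 0, 400_000, 3),
                    ("chr8", 600_000, 1_000_000, 1),
                    ("chr4", 500_000, 800_000, 1),
                    ("chr7", 600_000, 900_000, 3),
                    ("chr10", 0, 200_000, 4),
                ],
                drivers=[DriverSpec("TP53", "H193L", cosmic_count=7)],
            ),
            CloneSpec(
                "B", "A", 0.25, ctc_fraction=0.35,
                n_private_mutations=n_subclonal,
                cn_events=[("chr9", 0, 300_000, 3)],
            ),
        ],
    )
    p3 = PatientScenario(
        patient_id="P3",
        n_ctc_singles=3,
        ctc_pool_sizes=(),
        single_clone_assignment=["D", "D", "C"],
        clones=[
            CloneSpec(
                "A", None, 1.0, ctc_fraction=0.0,
                n_private_mutations=n_truncal,
                cn_events=[
                    ("chr5", 450_000, 600_000, 5),   # CCND1 amp
                    ("chr8", 0, 400_000, 3),
                    ("chr10", 600_000, 1_000_000, 1),
                    ("chr4", 0, 150_000, 4),
                    ("chr9", 0, 200_000, 1),
                ],
                drivers=[DriverSpec("AKT1", "E17K", cosmic_count=4000)],
            ),
            CloneSpec(
                # near-clonal TP53 lineage: in the bulk and in most CTCs
                "B", "A", 0.95, ctc_fraction=0.0,
                n_private_mutations=max(n_subclonal // 6, 5),
                cn_events=[("chr2", 0, 200_000, 1)],
                drivers=[DriverSpec("TP53", "R175H", cosmic_count=900)],
            ),
            CloneSpec(
                # bulk-dominant terminal clone: PTEN loss never seen in CTCs
                "B1", "B", 0.85, ctc_fraction=0.0,
                n_private_mutations=n_subclonal,
                cn_events=[("chr7", 150_000, 350_000, 1)],
            ),
            CloneSpec(
                # CTC lineage diverged from the TP53 clone: barely present in
                # the bulk, so its mutations surface as CTC-shared
                "D", "B", 0.05, ctc_fraction=0.7,
                n_private_mutations=n_subclonal,
            ),
            CloneSpec(
                # CTC-only divergent clone: ESR1 driver + ERBB2 amp, absent
                # from the bulk (ccf 0)
                "C", "A", 0.0, ctc_fraction=0.3,
                n_private_mutations=n_subclonal,
                cn_events=[("chr3", 550_000, 700_000, 6)],
                drivers=[DriverSpec("ESR1", "Y537N", cosmic_count=120)],
            ),
        ],
    )
    return SimConfig(patients=[p1, p2, p3])


# ---------------------------------------------------------------------------
# Patient simulation
# ---------------------------------------------------------------------------


def _window_grid(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_chroms):
        chrom = f"chr{i + 1}"
        for w in range(cfg.n_windows_per_chrom):
            rows.append(
                (chrom, w * cfg.window_size, (w + 1) * cfg.window_size)
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _window_indexer(cfg: SimConfig):
    nw = cfg.n_windows_per_chrom

    def index(chrom: str, start: int, end: int) -> np.ndarray:
        ci = int(chrom[3:]) - 1
        w0 = start // cfg.window_size
        w1 = (end + cfg.window_size - 1) // cfg.window_size
        return np.arange(ci * nw + w0, ci * nw + min(w1, nw))

    return index


def _window_of_position(cfg: SimConfig, chrom: str, pos: int) -> int:
    ci = int(chrom[3:]) - 1
    return ci * cfg.n_windows_per_chrom + (pos - 1) // cfg.window_size


def _stable_offset(text: str, modulo: int) -> int:
    return sum(ord(ch) * (i + 7) for i, ch in enumerate(text)) % modulo


def _draw_clonal_positions(
    genome: Genome, n: int, rng: np.random.Generator,
    taken: set, kmer_exclusion: int = 30,
) -> list[tuple[str, int]]:
    """Distinct random positions avoiding planted k-mer neighborhoods."""
    chroms = genome.chroms
    lengths = {c: len(genome.codes[c]) for c in chroms}
    kmer_by_chrom: dict[str, np.ndarray] = {}
    for chrom, s in genome.kmer_sites:
        kmer_by_chrom.setdefault(chrom, [])
    for chrom, s in genome.kmer_sites:
        kmer_by_chrom[chrom].append(s)
    kmer_by_chrom = {c: np.array(sorted(v)) for c, v in kmer_by_chrom.items()}
    out: list[tuple[str, int]] = []
    while len(out) < n:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(2, lengths[chrom] - 1))  # 1-based with flanks
        if (chrom, pos) in taken:
            continue
        sites = kmer_by_chrom.get(chrom)
        if sites is not None and len(sites):
            j = np.searchsorted(sites, pos)
            near = []
            if j > 0:
                near.append(sites[j - 1])
            if j < len(sites):
                near.append(sites[j])
            if any(abs(pos - 1 - s) <= kmer_exclusion for s in near):
                continue
        taken.add((chrom, pos))
        out.append((chrom, pos))
    return out


def simulate_patient(
    scenario: PatientScenario,
    cfg: SimConfig,
    genome: Genome,
    rng: np.random.Generator,
    taken_positions: set,
) -> PatientTruth:
    """Build one patient's ground truth: clones, mutations, samples, cells."""
    n_windows_total = cfg.n_chroms * cfg.n_windows_per_chrom
    windex = _window_indexer(cfg)
    order, resolved_cn, exact = _resolve_clones(scenario, n_windows_total, windex)

    gene_map = {g: (c, s, e) for g, c, s, e in DEFAULT_GENES}
    site_rows: list[dict] = []
    clone_sites: dict[str, list[int]] = {c.clone_id: [] for c in order}
    for spec in order:
        for drv in spec.drivers:
            chrom, gs, ge = gene_map[drv.gene]
            pos = gs + 1 + _stable_offset(drv.gene + drv.protein_change, ge - gs - 2)
            ref = genome.base(chrom, pos)
            alt = "ACGT"[( _BASE_INDEX[ref] + 1 + _stable_offset(drv.protein_change, 3)) % 4]
            if alt == ref:
                alt = "ACGT"[(_BASE_INDEX[ref] + 1) % 4]
            clone_sites[spec.clone_id].append(len(site_rows))
            taken_positions.add((chrom, pos))
            site_rows.append(
                {
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "origin": "truncal" if spec.parent is None else "subclonal",
                    "clone": spec.clone_id, "owner": "",
                    "gene": drv.gene, "effect": drv.effect,
                    "protein_change": drv.protein_change,
                }
            )
        positions = _draw_clonal_positions(
            genome, spec.n_private_mutations, rng, taken_positions
        )
        effects = rng.choice(EFFECTS, size=len(positions), p=EFFECT_PROBS)
        for (chrom, pos), eff in zip(positions, effects):
            ref = genome.base(chrom, pos)
            alt = "ACGT"[(_BASE_INDEX[ref] + int(rng.integers(1, 4))) % 4]
            gene = _gene_at(chrom, pos)
            clone_sites[spec.clone_id].append(len(site_rows))
            site_rows.append(
                {
                    "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                    "origin": "truncal" if spec.parent is None else "subclonal",
                    "clone": spec.clone_id, "owner": "",
                    "gene": gene, "effect": str(eff), "protein_change": "",
                }
            )

    # sample roster
    pid = scenario.patient_id
    samples = [
        SampleMeta(f"{pid}_BULK", pid, SampleClass.BULK_TUMOR),
        SampleMeta(f"{pid}_GERM", pid, SampleClass.GERMLINE_BLOOD),
        SampleMeta(f"{pid}_WBC", pid, SampleClass.WBC_POOL),
    ]
    for i in range(scenario.n_ctc_singles):
        samples.append(SampleMeta(f"{pid}_CTC{i + 1}", pid, SampleClass.CTC_SINGLE))
    for i, size in enumerate(scenario.ctc_pool_sizes):
        samples.append(
            SampleMeta(f"{pid}_POOL{i + 1}", pid, SampleClass.CTC_POOL, n_cells=size)
        )

    # clone membership of every CTC cell
    clone_ids = [c.clone_id for c in order]
    weights = np.array([c.ctc_fraction for c in order], dtype=float)
    if weights.sum() <= 0:
        raise ValidationError("no clone has a positive ctc_fraction")
    weights = weights / weights.sum()
    cells_per_sample: dict[str, list[int]] = {}
    forced = list(scenario.single_clone_assignment or [])
    single_i = 0
    for meta in samples:
        if meta.sample_class == SampleClass.CTC_SINGLE:
            if single_i < len(forced):
                cells = [clone_ids.index(forced[single_i])]
            else:
                cells = [int(rng.choice(len(order), p=weights))]
            single_i += 1
        elif meta.sample_class == SampleClass.CTC_POOL:
            cells = rng.choice(len(order), size=meta.n_cells, p=weights).tolist()
        else:
            cells = []
        cells_per_sample[meta.sample_id] = cells

    # artifact injection per WGA sample
    for meta in samples:
        wga = _wga_for(meta, scenario)
        if wga is None:
            continue
        artifacts = inject_artifacts(meta.sample_id, wga, genome, cfg, rng,
                                     taken_positions)
        site_rows.extend(artifacts)

    sites = pd.DataFrame(
        site_rows,
        columns=["chrom", "pos", "ref", "alt", "origin", "clone", "owner",
                 "gene", "effect", "protein_change"],
    )

    # clonal carrier matrix: a cell of clone c carries mutations of c and
    # all its ancestors
    carriers = np.zeros((len(order), len(sites)), dtype=bool)
    ancestors: dict[str, list[str]] = {}
    for spec in order:
        chain = [spec.clone_id]
        p = spec.parent
        while p is not None:
            chain.append(p)
            p = next(c for c in order if c.clone_id == p).parent
        ancestors[spec.clone_id] = chain
    for ci, spec in enumerate(order):
        for anc in ancestors[spec.clone_id]:
            carriers[ci, clone_sites[anc]] = True

    if scenario.bulk_purity is not None:
        purity = float(scenario.bulk_purity)
    else:
        lo, hi = scenario.bulk_purity_range
        purity = float(rng.uniform(lo, hi))
    if not 0 < purity <= 1:
        raise ValidationError(f"purity {purity} outside (0, 1]")

    clones = {}
    for ci, spec in enumerate(order):
        clones[spec.clone_id] = Clone(
            clone_id=spec.clone_id,
            parent=spec.parent,
            ccf_bulk=spec.ccf_bulk,
            ctc_fraction=spec.ctc_fraction,
            exact_fraction=exact[spec.clone_id],
            mutation_rows=np.array(clone_sites[spec.clone_id], dtype=int),
            cn_windows=resolved_cn[spec.clone_id],
        )
    fracs = np.array([exact[c.clone_id] for c in order])
    cn_matrix = np.stack([resolved_cn[c.clone_id] for c in order])
    tumor_ploidy = float((fracs @ cn_matrix).mean())

    return PatientTruth(
        patient_id=pid,
        bulk_purity=purity,
        clones=clones,
        sites=sites,
        carriers=carriers,
        clone_order=clone_ids,
        samples=samples,
        cells_per_sample=cells_per_sample,
        tumor_ploidy=tumor_ploidy,
    )


def _gene_at(chrom: str, pos: int) -> str:
    for g, c, s, e in DEFAULT_GENES:
        if c == chrom and s < pos <= e:
            return g
    return ""


def _wga_for(meta: SampleMeta, scenario: PatientScenario) -> Optional[WGAModel]:
    if meta.sample_class.is_ctc:
        return scenario.wga_ctc
    if meta.sample_class == SampleClass.WBC_POOL:
        return scenario.wga_wbc
    return None


def inject_artifacts(
    sample_id: str,
    wga: WGAModel,
    genome: Genome,
    cfg: SimConfig,
    rng: np.random.Generator,
    taken_positions: set,
) -> list[dict]:
    """Draw Poisson-count WGA artifact site rows for one sample.

    Contexts follow the sample's patient-specific ``artifact_spectrum``; a
    fixed fraction is planted inside blacklist k-mer occurrences so the
    k-mer filter has true positives to remove.
    """
    n = int(rng.poisson(wga.fp_rate))
    if n == 0:
        return []
    spectrum = wga.artifact_spectrum
    if spectrum is None:
        spectrum = np.full(96, 1.0 / 96)
    n_kmer = int(round(wga.kmer_artifact_fraction * n))
    rows: list[dict] = []
    klen = len(cfg.artifact_kmer)
    for _ in range(n_kmer):
        for _attempt in range(100):
            chrom, s = genome.kmer_sites[int(rng.integers(0, len(genome.kmer_sites)))]
            pos = s + 1 + int(rng.integers(0, klen))  # 1-based, inside the k-mer
            if (chrom, pos) not in taken_positions:
                break
        taken_positions.add((chrom, pos))
        ref = genome.base(chrom, pos)
        alt = "ACGT"[(_BASE_INDEX[ref] + int(rng.integers(1, 4))) % 4]
        rows.append(_artifact_row(chrom, pos, ref, alt, sample_id, rng))
    n_ctx = n - n_kmer
    pool = _ContextPool(genome, rng, n_candidates=max(20_000, 40 * n_ctx))
    classes = rng.choice(96, size=n_ctx, p=spectrum)
    for k in classes:
        drawn = None
        for _attempt in range(50):
            drawn = pool.draw(_context32(int(k)))
            if drawn is None:
                break
            if (drawn[0], drawn[1]) not in taken_positions:
                break
            drawn = None
        if drawn is None:
            continue  # context exhausted; Poisson count shrinks by one
        chrom, pos, is_pyr = drawn
        taken_positions.add((chrom, pos))
        ref_code, alt_code, _f5, _f3 = _class_decomposition(int(k))
        if not is_pyr:
            ref_code, alt_code = _COMP[ref_code], _COMP[alt_code]
        rows.append(
            _artifact_row(chrom, pos, "ACGT"[ref_code], "ACGT"[alt_code],
                          sample_id, rng)
        )
    return rows


def _artifact_row(chrom, pos, ref, alt, sample_id, rng) -> dict:
    effect = str(rng.choice(EFFECTS, p=EFFECT_PROBS))
    return {
        "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
        "origin": "artifact", "clone": "", "owner": sample_id,
        "gene": _gene_at(chrom, pos), "effect": effect, "protein_change": "",
    }


# ---------------------------------------------------------------------------
# Read-level realization of one sample
# ---------------------------------------------------------------------------


def _realize_sample(
    meta: SampleMeta,
    truth: PatientTruth,
    scenario: PatientScenario,
    cfg: SimConfig,
    rng: np.random.Generator,
    site_windows: np.ndarray,
) -> pd.DataFrame:
    """Simulate depth/alt_reads/called at every patient site for one sample."""
    sites = truth.sites
    n = len(sites)
    clone_cn = np.stack([truth.clones[c].cn_windows for c in truth.clone_order])
    is_artifact = (sites["origin"] == "artifact").to_numpy()
    own_artifact = (sites["owner"] == meta.sample_id).to_numpy()

    if meta.sample_class == SampleClass.BULK_TUMOR:
        fracs = np.array(
            [truth.clones[c].exact_fraction for c in truth.clone_order]
        )
        qbar = fracs @ clone_cn[:, site_windows]  # mean tumor CN per site
        rho = truth.bulk_purity
        # CCF of each clonal site = CCF of its clone
        ccf = np.zeros(n)
        for ci, cid in enumerate(truth.clone_order):
            rows = truth.clones[cid].mutation_rows
            ccf[rows] = truth.clones[cid].ccf_bulk
        denom = rho * qbar + 2.0 * (1.0 - rho)
        v = np.where(is_artifact, 0.0, rho * ccf / denom)
        depth = _nb_draw(rng, cfg.bulk_coverage_mean,
                         cfg.bulk_coverage_dispersion, size=n)
        alt = rng.binomial(depth, v)
    elif meta.sample_class == SampleClass.GERMLINE_BLOOD:
        depth = _nb_draw(rng, cfg.germline_coverage_mean,
                         cfg.bulk_coverage_dispersion, size=n)
        alt = np.zeros(n, dtype=int)
    else:
        wga = _wga_for(meta, scenario)
        cells = truth.cells_per_sample[meta.sample_id]
        n_alt = np.zeros(n, dtype=int)
        n_ref = np.zeros(n, dtype=int)
        if meta.sample_class == SampleClass.WBC_POOL:
            n_ref[:] = 2 * meta.n_cells
        else:
            for ci in cells:
                q = clone_cn[ci, site_windows]
                carry = truth.carriers[ci] & (q > 0) & ~is_artifact
                n_alt += carry.astype(int)
                n_ref += np.maximum(q - carry.astype(int), 0)
        depth, alt = _sample_reads_copies(n_alt, n_ref, wga, rng)
        # Driver loci carried by this sample are conditioned on successful
        # amplification and adequate depth: the default scenarios emulate a
        # study in which every carrier sample's driver aberration was in
        # fact observed, so the bundle reproduces that outcome instead of
        # re-rolling the WGA lottery at the handful of sites that define
        # the scenario's qualitative structure.
        is_driver = (sites["protein_change"].to_numpy() != "") & ~is_artifact
        carrier_driver = is_driver & (n_alt > 0)
        kd = int(carrier_driver.sum())
        if kd:
            d_depth = np.maximum(
                _nb_draw(rng, wga.coverage_mean, wga.coverage_dispersion,
                         size=kd),
                cfg.caller_min_depth + cfg.caller_min_alt,
            )
            frac = n_alt[carrier_driver] / (
                n_alt[carrier_driver] + n_ref[carrier_driver]
            )
            depth[carrier_driver] = d_depth
            alt[carrier_driver] = np.maximum(
                rng.binomial(d_depth, frac), cfg.caller_min_alt
            )
        # the sample's own artifacts exist in the amplified material: depth
        # without locus dropout, allele fraction uniform in the config range
        k = int(own_artifact.sum())
        if k:
            a_depth = _nb_draw(rng, wga.coverage_mean,
                               wga.coverage_dispersion, size=k)
            lo, hi = cfg.artifact_vaf_range
            f = rng.uniform(lo, hi, size=k)
            a_alt = rng.binomial(a_depth, f)
            depth[own_artifact] = a_depth
            alt[own_artifact] = a_alt

    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    called = (
        (depth >= cfg.caller_min_depth)
        & (alt >= cfg.caller_min_alt)
        & (vaf >= cfg.caller_min_vaf)
    )
    out = sites[["chrom", "pos", "ref", "alt", "gene", "effect",
                 "protein_change"]].copy()
    out.insert(4, "depth", depth)
    out.insert(5, "alt_reads", alt)
    out.insert(6, "called", called)
    return out


def _window_counts_for_sample(
    meta: SampleMeta,
    truth: PatientTruth,
    scenario: PatientScenario,
    cfg: SimConfig,
    grid: pd.DataFrame,
    rng: np.random.Generator,
) -> WindowCounts:
    clone_cn = np.stack([truth.clones[c].cn_windows for c in truth.clone_order])
    nwin = len(grid)
    if meta.sample_class == SampleClass.BULK_TUMOR:
        fracs = np.array(
            [truth.clones[c].exact_fraction for c in truth.clone_order]
        )
        rho = truth.bulk_purity
        expected = rho * (fracs @ clone_cn) + 2.0 * (1.0 - rho)
        dispersion = cfg.window_dispersion_bulk
    elif meta.sample_class in (SampleClass.GERMLINE_BLOOD, SampleClass.WBC_POOL):
        expected = np.full(nwin, 2.0)
        dispersion = (
            cfg.window_dispersion_bulk
            if meta.sample_class == SampleClass.GERMLINE_BLOOD
            else cfg.window_dispersion_wga
        )
    else:
        cells = truth.cells_per_sample[meta.sample_id]
        expected = clone_cn[cells].mean(axis=0)
        dispersion = cfg.window_dispersion_wga
    mu = cfg.reads_per_window * expected / 2.0
    counts = _nb_draw(rng, np.maximum(mu, 1e-9), dispersion, size=nwin)
    df = grid.copy()
    df["count"] = counts.astype(np.int64)
    return WindowCounts(df)


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def _cosmic_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    seen = set()
    for scenario in config.patients:
        for clone in scenario.clones:
            for drv in clone.drivers:
                key = (drv.gene, drv.protein_change)
                if key not in seen:
                    seen.add(key)
                    rows.append(
                        {"gene": drv.gene, "protein_change": drv.protein_change,
                         "count": drv.cosmic_count}
                    )
    # filler entries with low counts, below every display threshold
    for g, _c, _s, _e in DEFAULT_GENES:
        pc = f"A{100 + _stable_offset(g, 400)}V"
        if (g, pc) not in seen:
            rows.append({"gene": g, "protein_change": pc,
                         "count": int(rng.integers(1, 4))})
    return pd.DataFrame(rows, columns=["gene", "protein_change", "count"])


def simulate_run(
    config: SimConfig, seed: int, outdir: str | Path
) -> tuple[list[PatientTruth], Genome]:
    """Generate the full on-disk dataset for all configured patients.

    Writes, under ``outdir``: ``reference.fa``, ``sample_sheet.tsv``,
    ``genes.bed``, ``cosmic_counts.tsv``, per-sample ``<id>.vcf`` (called
    variants), ``<id>.sites.tsv`` (read support at every patient site) and
    ``<id>.windows.tsv`` (window read counts), plus truth tables under
    ``truth/``.  Deterministic given the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "samples").mkdir(exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    rng = np.random.default_rng(seed)
    genome = generate_genome(config, rng)
    genome.write_fasta(outdir / "reference.fa")
    grid = _window_grid(config)

    # assign disjoint patient-specific artifact spectra where none configured
    spectra = disjoint_artifact_spectra(len(config.patients), rng)
    patients = []
    for scenario, spec in zip(config.patients, spectra):
        if scenario.wga_ctc.artifact_spectrum is None:
            scenario = replace(
                scenario,
                wga_ctc=replace(scenario.wga_ctc, artifact_spectrum=spec),
                wga_wbc=replace(scenario.wga_wbc, artifact_spectrum=spec),
            )
        patients.append(scenario)

    taken: set[tuple[str, int]] = set()
    truths: list[PatientTruth] = []
    all_meta: list[SampleMeta] = []
    truth_mut_rows = []
    truth_cn_rows = []
    truth_sample_rows = []
    contigs = genome.contig_lengths()

    for scenario in patients:
        truth = simulate_patient(scenario, config, genome, rng, taken)
        truths.append(truth)
        all_meta.extend(truth.samples)
        site_windows = np.array(
            [
                _window_of_position(config, c, p)
                for c, p in zip(truth.sites["chrom"], truth.sites["pos"])
            ],
            dtype=int,
        )
        for meta in truth.samples:
            table = _realize_sample(meta, truth, scenario, config, rng,
                                    site_windows)
            table.to_csv(
                outdir / "samples" / f"{meta.sample_id}.sites.tsv",
                sep="\t", index=False,
            )
            called_rows = table[table["called"]]
            calls = [
                VariantCall(
                    key=MutationKey(r.chrom, int(r.pos), r.ref, r.alt),
                    sample_id=meta.sample_id,
                    depth=int(r.depth), alt_reads=int(r.alt_reads), called=True,
                    gene=r.gene or None, effect=r.effect or None,
                    protein_change=r.protein_change or None,
                )
                for r in called_rows.itertuples(index=False)
            ]
            write_calls_vcf(
                calls, outdir / "samples" / f"{meta.sample_id}.vcf",
                contigs, meta.sample_id,
            )
            wc = _window_counts_for_sample(meta, truth, scenario, config,
                                           grid, rng)
            write_window_counts(
                wc, outdir / "samples" / f"{meta.sample_id}.windows.tsv"
            )
        # truth tables
        t = truth.sites.copy()
        t.insert(0, "patient_id", truth.patient_id)
        truth_mut_rows.append(t)
        for cid in truth.clone_order:
            clone = truth.clones[cid]
            for chrom, start, end, cn in _cn_runs(clone.cn_windows, grid):
                truth_cn_rows.append(
                    {"patient_id": truth.patient_id, "clone": cid,
                     "chrom": chrom, "start": start, "end": end, "cn": cn}
                )
        for meta in truth.samples:
            cells = truth.cells_per_sample[meta.sample_id]
            truth_sample_rows.append(
                {
                    "sample_id": meta.sample_id,
                    "patient_id": truth.patient_id,
                    "sample_class": meta.sample_class.value,
                    "cells": ",".join(truth.clone_order[c] for c in cells),
                    "bulk_purity": truth.bulk_purity,
                    "tumor_ploidy": truth.tumor_ploidy,
                }
            )

    write_sample_sheet(all_meta, outdir / "sample_sheet.tsv")
    genes = pd.DataFrame(DEFAULT_GENES, columns=["gene", "chrom", "start", "end"])
    genes[["chrom", "start", "end", "gene"]].to_csv(
        outdir / "genes.bed", sep="\t", header=False, index=False
    )
    _cosmic_table(config, rng).to_csv(
        outdir / "cosmic_counts.tsv", sep="\t", index=False
    )
    pd.concat(truth_mut_rows, ignore_index=True).to_csv(
        outdir / "truth" / "mutations.tsv", sep="\t", index=False
    )
    pd.DataFrame(truth_cn_rows).to_csv(
        outdir / "truth" / "clone_cn.tsv", sep="\t", index=False
    )
    pd.DataFrame(truth_sample_rows).to_csv(
        outdir / "truth" / "samples.tsv", sep="\t", index=False, float_format="%.6f"
    )
    with open(outdir / "truth" / "params.json", "w") as fh:
        json.dump(
            {"seed": seed, "n_patients": len(patients),
             "n_chroms": config.n_chroms, "chrom_length": config.chrom_length,
             "window_size": config.window_size},
            fh, indent=2,
        )
    return truths, genome


def _cn_runs(cn: np.ndarray, grid: pd.DataFrame):
    """Compress a per-window CN vector into (chrom, start, end, cn) runs."""
    chroms = grid["chrom"].to_numpy()
    starts = grid["start"].to_numpy()
    ends = grid["end"].to_numpy()
    boundary = np.flatnonzero(
        (cn[1:] != cn[:-1]) | (chroms[1:] != chroms[:-1])
    )
    edges = np.concatenate([[0], boundary + 1, [len(cn)]])
    for lo, hi in zip(edges[:-1], edges[1:]):
        yield chroms[lo], int(starts[lo]), int(ends[hi - 1]), int(cn[lo])
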