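"""Trinucleotide-context mutation spectra and sample clustering.

Each sample's substitutions are tabulated into the standard 96 trinucleotide
classes: the six pyrimidine-strand substitution types (C>A, C>G, C>T, T>A,
T>C, T>G) crossed with the 5' and 3' flanking reference bases.  Mutations
whose reference base is a purine are reverse-complemented into the
pyrimidine-strand class.  Samples are compared with the distance
``1 - cor(log(pseudocount + f))`` over the 96 context frequencies ``f`` and
clustered by complete-linkage agglomeration, the rationale being that
samples whose private mutations arise from the same mutational processes
show correlated context spectra even when the mutations themselves are
disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ctc_concord.io_core import MutationKey, logger

SUBSTITUTION_CLASSES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = ["A", "C", "G", "T"]
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: canonical order of the 96 context classes: substitution-major,
#: then 5' flank, then 3' flank (e.g. A[C>A]A, A[C>A]C, ...)
CONTEXT_LABELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
]


def context_index(five: str, ref: str, alt: str, three: str) -> int:
    """Index of a substitution-with-flanks in the 96-class vector.

    Purine-reference substitutions are collapsed to the pyrimidine strand by
    reverse complement (which also swaps and complements the flanks).
    """
    five, ref, alt, three = five.upper(), ref.upper(), alt.upper(), three.upper()
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    sub = f"{ref}>{alt}"
    return (
        SUBSTITUTION_CLASSES.index(sub) * 16
        + BASES.index(five) * 4
        + BASES.index(three)
    )


@dataclass
class Spectrum:
    """96-dimensional trinucleotide-context count vector for one sample."""

    sample_id: str
    counts: np.ndarray  # shape (96,), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 bins")
        if (self.counts < 0).any():
            raise ValueError("negative spectrum counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        t = self.counts.sum()
        if t == 0:
            return np.zeros(96)
        return self.counts / t


def context_spectrum(
    mutations: Sequence[MutationKey],
    reference,
    sample_id: str = "",
) -> Spectrum:
    """Tabulate substitutions into the 96 trinucleotide classes.

    ``reference`` maps contig name to sequence (e.g. ``pyfaidx.Fasta``).
    Sites lacking a 1 bp flank on either side (contig edges) are skipped
    with a logged count.
    """
    counts = np.zeros(96, dtype=int)
    n_edge = 0
    for key in mutations:
        contig = reference[key.chrom]
        if key.pos < 2 or key.pos > len(contig) - 1:
            n_edge += 1
            continue
        # pos is 1-based; flanks at pos-1 and pos+1
        tri = str(contig[key.pos - 2 : key.pos + 1]).upper()
        if tri[1] != key.ref:
            raise ValueError(
                f"{key}: reference base mismatch (genome has {tri[1]!r})"
            )
        counts[context_index(tri[0], key.ref, key.alt, tri[2])] += 1
    if n_edge:
        logger.info("context_spectrum(%s): skipped %d edge sites", sample_id, n_edge)
    return Spectrum(sample_id, counts)


def spectrum_distance(a: Spectrum, b: Spectrum, pseudocount: float = 0.01) -> float:
    """Distance ``1 - cor(log(pseudocount + f_a), log(pseudocount + f_b))``.

    Frequencies (not counts) enter the log; the log base cancels in the
    correlation.  Ranges over [0, 2].  Raises on zero-variance log-vectors
    (e.g. an empty spectrum), for which correlation is undefined.
    """
    la = np.log(pseudocount + a.frequencies)
    lb = np.log(pseudocount + b.frequencies)
    if np.ptp(la) == 0 or np.ptp(lb) == 0:
        raise ValueError(
            f"spectrum distance undefined for zero-variance spectrum "
            f"({a.sample_id!r} vs {b.sample_id!r})"
        )
    r = np.corrcoef(la, lb)[0, 1]
    return float(1.0 - r)


@dataclass
class SpectrumClustering:
    sample_ids: list[str]
    distance_matrix: pd.DataFrame
    linkage: np.ndarray
    newick: str

    def flat_labels(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")


def cluster_spectra(
    spectra: Sequence[Spectrum],
    pseudocount: float = 0.01,
) -> SpectrumClustering:
    """Complete-linkage hierarchical clustering on pairwise spectrum distances.

    Samples are sorted lexicographically by sample id before agglomeration so
    that equal-distance merges are broken deterministically, making the
    result invariant to input order.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to cluster")
    ordered = sorted(spectra, key=lambda s: s.sample_id)
    ids = [s.sample_id for s in ordered]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in spectra")
    n = len(ordered)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = spectrum_distance(ordered[i], ordered[j], pseudocount)
            except ValueError as exc:
                raise ValueError(
                    f"undefined distance between {ids[i]!r} and {ids[j]!r}"
                ) from exc
            dm[i, j] = dm[j, i] = d
    Z = hierarchy.linkage(squareform(dm, checks=False), method="complete")
    newick = linkage_to_newick(Z, ids)
    return SpectrumClustering(
        ids, pd.DataFrame(dm, index=ids, columns=ids), Z, newick
    )


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            length = parent_height
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{parent_height - node.dist:.6g}"

    root = tree
    left = walk(root.left, root.dist)
    right = walk(root.right, root.dist)
    return f"({left},{right});"


def spectra_frame(spectra: Sequence[Spectrum]) -> pd.DataFrame:
    """96 x samples count table with canonical context row labels."""
    data = {s.sample_id: s.counts for s in sorted(spectra, key=lambda s: s.sample_id)}
    return pd.DataFrame(data, index=CONTEXT_LABELS)
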