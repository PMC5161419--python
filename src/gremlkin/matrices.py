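"""Genomic (G, K) and environmental (F, S, C) relationship matrices.

G is the per-SNP-standardized genomic relationship matrix

    G_ik = (1/m) sum_j (x_ij - 2 p_j)(x_kj - 2 p_j) / (2 p_j (1 - p_j)),

with allele frequencies estimated from the sample.  K zeroes G's
off-diagonal entries below a relatedness threshold (default 0.05),
isolating close relatives; fitted together, G and K split additive
genetic variance into a common-variant part and an additional
pedigree-associated part.  F, S and C are 0/1 indicator matrices of
shared nuclear family, full sibship and couple status, with unit
diagonal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree

__all__ = [
    "RelationshipMatrix",
    "compute_grm",
    "threshold_kinship",
    "build_erm",
    "compute_pcs",
    "matrix_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Symmetric n x n similarity matrix with sample labels.

    ``kind`` is one of G, K, F, S, C or "other"; ``pair_counts`` (G only)
    holds per-pair non-missing SNP counts.
    """

    sample_ids: list[str]
    values: np.ndarray
    kind: str = "other"
    pair_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"{len(self.sample_ids)} ids vs matrix shape {self.values.shape}"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def reorder(self, sample_ids: list[str]) -> "RelationshipMatrix":
        """Restrict/permute to the given sample order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids])
        pc = None
        if self.pair_counts is not None:
            pc = self.pair_counts[np.ix_(idx, idx)]
        return RelationshipMatrix(
            list(sample_ids), self.values[np.ix_(idx, idx)], self.kind, pc
        )


def compute_grm(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    missing_policy: str = "mean_impute",
) -> RelationshipMatrix:
    """Build the standardized-dosage GRM from filtered SNPs.

    Monomorphic SNPs and SNPs with minor-allele frequency below
    ``maf_min`` are dropped.  Missing dosages contribute zero after
    centering ("mean_impute"); with ``missing_policy="pairwise"`` each
    pair's sum is instead divided by its own non-missing SNP count.
    """
    if genotypes.n_samples < 2:
        raise ValueError("GRM needs at least 2 samples")
    p = genotypes.allele_freq
    maf = np.minimum(p, 1 - p)
    keep = (p > 0) & (p < 1) & (maf >= maf_min)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("compute_grm: dropped %d monomorphic/low-MAF SNPs", n_dropped)
    if not keep.any():
        raise ValueError("no informative SNPs after MAF/monomorphic filtering")
    x = genotypes.dosages[:, keep]
    p = p[keep]
    z = (x - 2 * p) / np.sqrt(2 * p * (1 - p))
    miss = np.isnan(z)
    z[miss] = 0.0  # mean imputation: centered missing entries drop out
    obs = (~miss).astype(float)
    pair_counts = obs @ obs.T
    if missing_policy == "mean_impute":
        values = (z @ z.T) / z.shape[1]
    elif missing_policy == "pairwise":
        with np.errstate(invalid="ignore", divide="ignore"):
            values = (z @ z.T) / pair_counts
        values[pair_counts == 0] = 0.0
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    values = (values + values.T) / 2
    return RelationshipMatrix(
        list(genotypes.sample_ids), values, kind="G", pair_counts=pair_counts
    )


def threshold_kinship(G: RelationshipMatrix, threshold: float = 0.05) -> RelationshipMatrix:
    """Zero off-diagonal entries of G strictly below ``threshold``.

    The diagonal is copied unchanged; entries >= threshold are retained
    as-is, so K's non-zero off-diagonals equal the corresponding G
    entries.
    """
    if threshold < 0 and not np.isneginf(threshold):
        raise ValueError(f"threshold must be >= 0 (got {threshold})")
    values = np.where(G.values >= threshold, G.values, 0.0)
    np.fill_diagonal(values, np.diag(G.values))
    return RelationshipMatrix(list(G.sample_ids), values, kind="K")


def build_erm(
    pedigree: Pedigree, kind: str, sample_ids: list[str] | None = None
) -> RelationshipMatrix:
    """Indicator matrix for shared couple (C), sibship (S) or family (F) status."""
    if kind not in ("F", "S", "C"):
        raise ValueError(f"ERM kind must be F, S or C (got {kind!r})")
    if sample_ids is None:
        sample_ids = pedigree.individual_ids
    pairs = pedigree.pair_set(kind)
    if kind == "C" and not pairs:
        warnings.warn(
            "no couple pairs derivable; C is the identity and its component "
            "will be inestimable"
        )
    pos = {s: i for i, s in enumerate(sample_ids)}
    values = np.eye(len(sample_ids))
    for pair in pairs:
        ab = [pos[x] for x in pair if x in pos]
        if len(ab) == 2:
            values[ab[0], ab[1]] = values[ab[1], ab[0]] = 1.0
    return RelationshipMatrix(list(sample_ids), values, kind=kind)


def compute_pcs(G: RelationshipMatrix, k: int = 20) -> np.ndarray:
    """Top-k unit-norm eigenvectors of G, by descending eigenvalue.

    Sign is fixed so each vector's largest-magnitude loading is
    positive; eigenvalue ties resolve to ascending sample-id order via
    the symmetric eigensolver's deterministic output.
    """
    if k >= G.n:
        raise ValueError(f"k={k} must be smaller than n={G.n}")
    w, v = np.linalg.eigh(G.values)
    if w[0] < -1e-6 * max(1.0, abs(w[-1])):
        warnings.warn(f"G has negative eigenvalue {w[0]:.3g}; not PSD")
    order = np.argsort(w)[::-1][:k]
    scores = v[:, order]
    for j in range(k):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def matrix_correlation(A: RelationshipMatrix, B: RelationshipMatrix) -> float:
    """Pearson correlation of off-diagonal upper-triangle entries.

    A collinearity diagnostic: high values between e.g. F and the
    combination of C and K warn that their variance components will be
    hard to separate.
    """
    if A.sample_ids != B.sample_ids:
        raise ValueError("matrices must share the same sample set and order")
    if A.n < 3:
        raise ValueError("need at least 3 samples for an off-diagonal correlation")
    iu = np.triu_indices(A.n, k=1)
    a, b = A.values[iu], B.values[iu]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("degenerate (constant) off-diagonal entries")
    return float(np.corrcoef(a, b)[0, 1])
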