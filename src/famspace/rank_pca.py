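"""Sequence-space PCA of protein families via per-column occurrence ranks.

The method turns an alignment into a numeric matrix by replacing each
residue with the rank of its symbol's occurrence count within its column
(most frequent symbol = rank 1, ties broken by alphabetical order of the
one-letter code), then runs an ordinary covariance PCA on the mean-centred
rank matrix. Scores separate protein families; the per-column loadings of
the discriminating components point at the alignment positions — typically
the variable N-terminal region in Cdc48-family ATPases — that drive the
separation, while conserved AAA-module positions carry near-zero weight.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import silhouette_score

from .msa_io import GAP, Alignment


class DegenerateInputError(ValueError):
    """Input carries no usable variance."""


@dataclass(frozen=True)
class RankMatrix:
    """Numeric encoding of an alignment: one occurrence rank per residue."""

    values: np.ndarray  # (n_seqs, n_cols), positive integers
    row_ids: tuple[str, ...]
    gap_policy: str
    rank_direction: str = "most_frequent_first"

    @property
    def n_seqs(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PCAResult:
    """Scores, unit-norm loadings and explained-variance fractions."""

    scores: np.ndarray  # (n_seqs, k)
    loadings: np.ndarray  # (n_cols, k), columns unit-norm
    explained_variance_fraction: np.ndarray  # (k,)
    column_means: np.ndarray  # (n_cols,)
    k: int
    row_ids: tuple[str, ...] = ()

    def component_loadings(self, component: int) -> np.ndarray:
        """Loadings of 1-based ``component``."""
        if not 1 <= component <= self.k:
            raise ValueError(f"component {component} out of range 1..{self.k}")
        return self.loadings[:, component - 1]


def _column_ranks(residues: str, gap_policy: str) -> dict[str, int]:
    """Map each symbol in a column to its occurrence rank.

    Symbols are sorted by descending count, ties by ascending alphabetical
    order; the gap character sorts after every letter within a tie so that
    amino acids keep their alphabetical tie-break. Under ``gap_worst_rank``
    the gap always receives (max observed rank) + 1.
    """
    counts = Counter(residues)
    gap_present = GAP in counts
    if gap_policy == "gap_worst_rank":
        counts.pop(GAP, None)
    # '~' > 'Z': gap loses alphabetical ties against any amino acid
    order = sorted(counts, key=lambda s: (-counts[s], s if s != GAP else "~"))
    ranks = {sym: i + 1 for i, sym in enumerate(order)}
    if gap_policy == "gap_worst_rank" and gap_present:
        ranks[GAP] = len(order) + 1
    return ranks


def rank_encode(aln: Alignment, gap_policy: str = "gap_as_symbol") -> RankMatrix:
    """Replace every residue by its symbol's per-column occurrence rank.

    Rank 1 is the most frequent symbol in the column; equally frequent
    symbols are ranked alphabetically by one-letter code. Columns that are
    identical across all sequences become constant (and therefore carry no
    PCA weight) but are retained so column indices stay aligned with the
    alignment.
    """
    if gap_policy not in ("gap_as_symbol", "gap_worst_rank"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    if aln.n_seqs < 2:
        raise ValueError("rank encoding requires at least 2 sequences")
    values = np.empty((aln.n_seqs, aln.n_cols), dtype=np.int64)
    for j in range(aln.n_cols):
        col = aln.column(j + 1)
        ranks = _column_ranks(col, gap_policy)
        values[:, j] = [ranks[sym] for sym in col]
    return RankMatrix(values=values, row_ids=aln.ids, gap_policy=gap_policy)


def run_pca(rm: RankMatrix, k: int) -> PCAResult:
    """Covariance PCA (centering only, no variance scaling) of a rank matrix.

    Components are the top-``k`` right singular vectors of the centred
    matrix; each component's sign is fixed so its largest-magnitude loading
    entry is positive, making results deterministic.
    """
    n, p = rm.values.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} out of range 1..{min(n - 1, p)}")
    X = rm.values.astype(float)
    means = X.mean(axis=0)
    Xc = X - means
    if not np.any(Xc):
        raise DegenerateInputError("rank matrix is constant in every column")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    # sign convention: largest-|loading| entry of each component positive
    for i in range(k):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    evf = s[:k] ** 2 / total_var
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=evf,
        column_means=means,
        k=k,
        row_ids=rm.row_ids,
    )


def family_separation(
    res: PCAResult,
    labels: Mapping[str, str],
    components: Sequence[int] = (1, 2),
) -> float:
    """Mean silhouette width of labeled families in a component subspace.

    Uses Euclidean distance over the selected 1-based components. Families
    with a single member are excluded (with a warning); at least two
    usable families are required. Values near 1 mean tight, well-separated
    family clusters; values near 0 mean no structure.
    """
    comp_idx = [c - 1 for c in components]
    if any(not 0 <= i < res.k for i in comp_idx):
        raise ValueError(f"components {components} out of range 1..{res.k}")
    ids = res.row_ids
    fam_members: dict[str, list[int]] = {}
    for i, sid in enumerate(ids):
        if sid in labels:
            fam_members.setdefault(labels[sid], []).append(i)
    singletons = [f for f, m in fam_members.items() if len(m) < 2]
    if singletons:
        warnings.warn(
            f"excluding single-member families: {sorted(singletons)}",
            stacklevel=2,
        )
    usable = {f: m for f, m in fam_members.items() if len(m) >= 2}
    if len(usable) < 2:
        raise ValueError("need at least 2 families with >= 2 members each")
    rows = [i for members in usable.values() for i in members]
    X = res.scores[np.ix_(rows, comp_idx)]
    y = [labels[ids[i]] for i in rows]
    if np.allclose(X, X[0]):
        raise DegenerateInputError("all points identical; distances undefined")
    return float(silhouette_score(X, y, metric="euclidean"))
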