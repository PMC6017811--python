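"""Gene presence/absence co-occurrence across genomes.

Quantifies phylogenetic-profile claims of the form "gene A occurs only in
genomes that also carry gene B" (e.g. the Cdc48-like ATPase gene co-occurs
with the 20S proteasome subunit genes prcA/prcB in actinobacteria): builds
the 2x2 contingency table over genomes, reports whether A is nested within
B (no genome has A without B), and attaches a one-sided Fisher exact
p-value for positive association.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PresenceAbsenceMatrix:
    """Boolean genomes x genes presence matrix with unique name lists."""

    genomes: tuple[str, ...]
    genes: tuple[str, ...]
    present: np.ndarray  # bool, (n_genomes, n_genes)

    def __post_init__(self) -> None:
        if len(set(self.genomes)) != len(self.genomes):
            raise ValueError("duplicate genome names")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names")
        if self.present.shape != (len(self.genomes), len(self.genes)):
            raise ValueError(
                f"matrix shape {self.present.shape} does not match "
                f"{len(self.genomes)} genomes x {len(self.genes)} genes"
            )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PresenceAbsenceMatrix":
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("presence/absence cells must be 0 or 1")
        return cls(
            genomes=tuple(str(g) for g in df.index),
            genes=tuple(str(g) for g in df.columns),
            present=values.astype(bool),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        """Read a genomes-by-genes 0/1 table (first column = genome name)."""
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))

    def gene_vector(self, gene: str) -> np.ndarray:
        if gene not in self.genes:
            raise KeyError(f"unknown gene {gene!r}")
        return self.present[:, self.genes.index(gene)]


@dataclass(frozen=True)
class ContingencyTable:
    """Joint presence counts of two genes over genomes."""

    both: int  # a AND b
    a_only: int  # a AND NOT b
    b_only: int  # NOT a AND b
    neither: int

    def as_array(self) -> np.ndarray:
        return np.array([[self.both, self.a_only], [self.b_only, self.neither]])

    @property
    def total(self) -> int:
        return self.both + self.a_only + self.b_only + self.neither


def contingency(
    pam: PresenceAbsenceMatrix, gene_a: str, gene_b: str
) -> ContingencyTable:
    """2x2 table of joint presence of ``gene_a`` and ``gene_b``."""
    if not pam.genomes:
        raise ValueError("empty presence/absence matrix")
    a = pam.gene_vector(gene_a)
    b = pam.gene_vector(gene_b)
    return ContingencyTable(
        both=int(np.sum(a & b)),
        a_only=int(np.sum(a & ~b)),
        b_only=int(np.sum(~a & b)),
        neither=int(np.sum(~a & ~b)),
    )


def nestedness_and_test(
    table: ContingencyTable, alternative: str = "greater"
) -> dict:
    """Nestedness flag plus Fisher exact p-value for the 2x2 table.

    ``is_nested`` is true iff gene A never occurs without gene B (the
    a-only cell is zero). ``fisher_p`` defaults to the one-sided
    (positive-association) hypergeometric tail; pass
    ``alternative="two-sided"`` for the symmetric test.
    """
    if table.total < 1:
        raise ValueError("contingency table is empty")
    _, p = stats.fisher_exact(table.as_array(), alternative=alternative)
    return {"is_nested": table.a_only == 0, "fisher_p": float(p)}
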