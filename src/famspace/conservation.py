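"""Conservation mapping: loading thresholds, logo information content,
motif windows and per-residue structure annotation.

Positions are classified by the magnitude of their loading on a chosen
principal component relative to the maximum over all columns: above 30% of
the maximum the position is *variable* (family-discriminating), below 10%
it is *conserved*, in between *intermediate*. Per-column conservation is
also quantified as sequence-logo information content in bits,
IC = log2(A) - H with A the alphabet size (20 for proteins) and H the
Shannon entropy of the observed residue frequencies, optionally reduced by
the small-sample correction e_n = (A - 1) / (2 ln 2 n).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .msa_io import GAP, Alignment, SymbolCounts, column_counts

logger = logging.getLogger(__name__)

VARIABLE = "variable"
CONSERVED = "conserved"
INTERMEDIATE = "intermediate"

#: The loading-percentage thresholds used for structure colouring.
DEFAULT_UPPER = 0.30
DEFAULT_LOWER = 0.10


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class PositionClassification:
    column: int  # 1-based alignment column
    loading_abs: float
    pct_of_max: float
    category: str


@dataclass(frozen=True)
class LogoColumn:
    """Residue frequencies and information content of one column."""

    column: int
    frequencies: Mapping[str, float]
    entropy_bits: float
    information_content_bits: float
    correction: float


def classify_positions(
    loadings: Sequence[float],
    upper: float = DEFAULT_UPPER,
    lower: float = DEFAULT_LOWER,
) -> list[PositionClassification]:
    """Classify alignment columns by |loading| relative to the maximum.

    Strictly above ``upper`` (fraction of the maximal |loading|) is
    *variable*, strictly below ``lower`` is *conserved*, everything else —
    including values exactly at a threshold — is *intermediate*. The
    classification is invariant to rescaling (and sign flips) of the
    loading vector.
    """
    if not 0 <= lower < upper <= 1:
        raise ValueError(f"need 0 <= lower < upper <= 1, got {lower}, {upper}")
    mags = np.abs(np.asarray(loadings, dtype=float))
    if mags.size == 0:
        raise ValueError("empty loadings")
    max_mag = mags.max()
    if max_mag == 0:
        raise DegenerateInputError("all loadings are zero")
    out = []
    for j, mag in enumerate(mags):
        pct = float(mag / max_mag)
        if pct > upper:
            cat = VARIABLE
        elif pct < lower:
            cat = CONSERVED
        else:
            cat = INTERMEDIATE
        out.append(
            PositionClassification(
                column=j + 1, loading_abs=float(mag), pct_of_max=pct, category=cat
            )
        )
    return out


def information_content(
    counts: SymbolCounts,
    alphabet_size: int = 20,
    apply_correction: bool = False,
) -> LogoColumn:
    """Shannon entropy and logo information content of a column, in bits.

    IC = log2(alphabet_size) - H - e_n, clamped at zero, with the
    small-sample correction e_n = (alphabet_size - 1) / (2 ln 2 n_observed)
    applied only when requested. Gaps are expected to have been excluded
    from ``counts`` already (standard logo convention, ``skip_gap``).
    """
    n = counts.n_observed
    if n == 0:
        raise DegenerateInputError(
            f"column {counts.column_index} has no observed residues"
        )
    freqs = {sym: c / n for sym, c in counts.counts.items() if c > 0}
    H = -sum(p * math.log2(p) for p in freqs.values())
    e_n = (alphabet_size - 1) / (2 * math.log(2) * n) if apply_correction else 0.0
    ic = max(0.0, math.log2(alphabet_size) - H - e_n)
    return LogoColumn(
        column=counts.column_index,
        frequencies=freqs,
        entropy_bits=H,
        information_content_bits=ic,
        correction=e_n,
    )


def reference_column_map(aln: Alignment, reference_id: str) -> list[int]:
    """1-based alignment column of each ungapped residue of the reference."""
    if reference_id not in aln.ids:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    seq = aln.seqs[aln.ids.index(reference_id)]
    return [j + 1 for j, sym in enumerate(seq) if sym != GAP]


def motif_window(
    aln: Alignment,
    reference_id: str,
    ref_start: int,
    ref_end: int,
    alphabet_size: int = 20,
    apply_correction: bool = False,
) -> list[LogoColumn]:
    """Logo columns for a window given in ungapped reference coordinates.

    Used to profile conserved motifs (e.g. the Walker A/B boxes of AAA
    modules) around residues of a chosen reference sequence: residue
    coordinates are mapped through the reference's gaps onto alignment
    columns, and each column's frequencies/IC computed with gaps excluded.
    """
    colmap = reference_column_map(aln, reference_id)
    if not 1 <= ref_start <= ref_end <= len(colmap):
        raise ValueError(
            f"window {ref_start}..{ref_end} outside ungapped reference "
            f"length {len(colmap)}"
        )
    out = []
    for r in range(ref_start, ref_end + 1):
        col = colmap[r - 1]
        counts = column_counts(aln, col, gap_policy="skip_gap")
        out.append(information_content(counts, alphabet_size, apply_correction))
    return out


def map_to_structure(
    classification: Sequence[PositionClassification],
    column_to_residue: Mapping[int, tuple[str, int]],
) -> list[dict]:
    """Project a position classification onto structure residues.

    ``column_to_residue`` maps 1-based alignment columns to
    (chain, residue number) pairs; columns without a mapping are omitted.
    If two columns target the same residue the last one wins (logged).
    The resulting rows can be written as a generic per-residue attribute
    table for structure colouring.
    """
    by_column = {c.column: c for c in classification}
    missing = sorted(set(column_to_residue) - set(by_column))
    if missing:
        raise KeyError(f"mapping refers to unclassified column(s): {missing}")
    rows: dict[tuple[str, int], dict] = {}
    for col in sorted(column_to_residue):
        chain, resnum = column_to_residue[col]
        cls = by_column[col]
        key = (chain, resnum)
        if key in rows:
            logger.warning(
                "residue %s%d mapped from multiple columns; keeping column %d",
                chain, resnum, col,
            )
        rows[key] = {
            "chain": chain,
            "residue": resnum,
            "category": cls.category,
            "pct_of_max": cls.pct_of_max,
        }
    return [rows[k] for k in sorted(rows)]
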