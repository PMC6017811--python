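"""Differential label-free quantification (LFQ) proteomics.

Compares replicate protein intensities between two conditions (e.g. a
wild-type and a knockout strain, five biological replicates each), computes
per-protein log2 fold changes and two-sided t-test p-values on log2
intensities, classifies proteins on the volcano plot at a fold-change
threshold of 1.5 (inclusive) and p < 0.05 (strict), and summarises the
significantly changed proteins by COG functional class, excluding class S
(function unknown) and unannotated proteins.

The fold-change direction convention is positive = higher in the knockout
(second) group, so "accumulated" means accumulating in the knockout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ACCUMULATED = "accumulated"
DEPLETED = "depleted"
UNCHANGED = "unchanged"

DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_P_THRESHOLD = 0.05

COG_UNKNOWN_CLASS = "S"


@dataclass(frozen=True)
class LFQTable:
    """Replicate protein intensities for a two-group comparison.

    Intensities are non-negative; zeros mark missing quantifications.
    ``group`` maps each sample (column) name to its condition label; the
    reference condition (e.g. wild type) is named by ``reference`` and the
    other condition is the comparison (knockout) group.
    """

    proteins: tuple[str, ...]
    intensities: np.ndarray  # (n_proteins, n_samples)
    samples: tuple[str, ...]
    group: Mapping[str, str]
    reference: str

    def __post_init__(self) -> None:
        if len(set(self.proteins)) != len(self.proteins):
            raise ValueError("duplicate protein ids")
        if self.intensities.shape != (len(self.proteins), len(self.samples)):
            raise ValueError("intensity matrix shape mismatch")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        conditions = {self.group[s] for s in self.samples}
        if len(conditions) != 2 or self.reference not in conditions:
            raise ValueError(
                f"need exactly 2 conditions including reference "
                f"{self.reference!r}, got {sorted(conditions)}"
            )
        for cond in conditions:
            n = sum(self.group[s] == cond for s in self.samples)
            if n < 2:
                raise ValueError(f"condition {cond!r} has {n} < 2 samples")

    def group_columns(self) -> tuple[list[int], list[int]]:
        """(reference column indices, comparison column indices)."""
        ref = [i for i, s in enumerate(self.samples) if self.group[s] == self.reference]
        other = [i for i, s in enumerate(self.samples) if self.group[s] != self.reference]
        return ref, other

    @classmethod
    def from_tsv(
        cls, lfq_path: str | Path, design_path: str | Path, reference: str
    ) -> "LFQTable":
        """Load intensities (protein id + one column per sample) and a
        two-column sample-to-group design table."""
        df = pd.read_csv(lfq_path, sep="\t", index_col=0)
        design = pd.read_csv(design_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(
            proteins=tuple(str(p) for p in df.index),
            intensities=df.to_numpy(dtype=float),
            samples=tuple(str(s) for s in df.columns),
            group={str(s): str(g) for s, g in design.items()},
            reference=reference,
        )


@dataclass(frozen=True)
class LFQResult:
    protein: str
    log2_fc: float
    p_value: float  # NaN when not computable
    category: str
    cog_class: str | None = None


def _welch_or_student(
    a: np.ndarray, b: np.ndarray, test: str
) -> float:
    res = stats.ttest_ind(b, a, equal_var=(test == "student_t"))
    return float(res.pvalue)


def differential(
    tab: LFQTable,
    test: str = "welch_t",
    log_transform: bool = True,
    missing_policy: str = "drop",
) -> list[LFQResult]:
    """Per-protein log2 fold change and two-sided t-test p-value.

    The t-test always runs on log2-transformed intensities (intensity
    noise is multiplicative); ``log_transform`` additionally controls
    whether the fold change is the difference of log2 group means (True)
    or the log2 ratio of raw group means (False). Zeros are missing
    values: ``drop`` removes them per protein, ``impute_min`` replaces
    them with half the smallest positive intensity in the table. Proteins
    with fewer than two usable values in either group get ``p = NaN`` and
    category *unchanged*.
    """
    if test not in ("welch_t", "student_t"):
        raise ValueError(f"unknown test {test!r}")
    if missing_policy not in ("drop", "impute_min"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")

    X = tab.intensities.astype(float)
    if missing_policy == "impute_min":
        positive = X[X > 0]
        if positive.size:
            X = np.where(X == 0, positive.min() / 2.0, X)
    ref_cols, cmp_cols = tab.group_columns()
    A, B = X[:, ref_cols], X[:, cmp_cols]

    results: list[LFQResult] = []
    complete = (A > 0).all(axis=1) & (B > 0).all(axis=1)
    # vectorised fast path for complete rows, per-protein handling otherwise
    logA = np.log2(np.where(A > 0, A, np.nan))
    logB = np.log2(np.where(B > 0, B, np.nan))
    p_fast = np.full(len(tab.proteins), np.nan)
    if complete.any():
        res = stats.ttest_ind(
            logB[complete], logA[complete], axis=1,
            equal_var=(test == "student_t"),
        )
        p_fast[complete] = res.pvalue
    for i, prot in enumerate(tab.proteins):
        a = A[i][A[i] > 0]
        b = B[i][B[i] > 0]
        if len(a) < 2 or len(b) < 2:
            results.append(LFQResult(prot, math.nan, math.nan, UNCHANGED))
            continue
        if log_transform:
            fc = float(np.mean(np.log2(b)) - np.mean(np.log2(a)))
        else:
            fc = float(np.log2(np.mean(b) / np.mean(a)))
        if complete[i]:
            p = float(p_fast[i])
        else:
            p = _welch_or_student(np.log2(a), np.log2(b), test)
        results.append(
            LFQResult(prot, fc, p, _categorize(fc, p))
        )
    return results


def _categorize(
    log2_fc: float,
    p: float,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> str:
    if math.isnan(p):
        return UNCHANGED
    cut = math.log2(fc_threshold)
    if log2_fc >= cut and p < p_threshold:
        return ACCUMULATED
    if log2_fc <= -cut and p < p_threshold:
        return DEPLETED
    return UNCHANGED


def volcano_classify(
    results: Sequence[LFQResult],
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> dict:
    """Re-classify at the given thresholds and count volcano categories.

    The fold-change cut is inclusive (|log2 fc| >= log2(threshold)), the
    p-value cut strict (p < threshold). Proteins whose p-value could not
    be computed count as unchanged. Returns the relabelled results and the
    category counts, which always partition the input.
    """
    if not results:
        raise ValueError("no results to classify")
    if fc_threshold < 1:
        raise ValueError("fold-change threshold must be >= 1")
    relabelled = [
        LFQResult(
            r.protein,
            r.log2_fc,
            r.p_value,
            _categorize(r.log2_fc, r.p_value, fc_threshold, p_threshold),
            r.cog_class,
        )
        for r in results
    ]
    counts = {ACCUMULATED: 0, DEPLETED: 0, UNCHANGED: 0}
    for r in relabelled:
        counts[r.category] += 1
    return {"results": relabelled, "counts": counts}


def adjust_benjamini_hochberg(results: Sequence[LFQResult]) -> list[LFQResult]:
    """Replace p-values by Benjamini-Hochberg adjusted values (optional;
    the default volcano filter uses raw p-values)."""
    ps = np.array([r.p_value for r in results])
    ok = ~np.isnan(ps)
    adj = ps.copy()
    if ok.any():
        adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    return [
        LFQResult(r.protein, r.log2_fc, float(p), _categorize(r.log2_fc, float(p)),
                  r.cog_class)
        for r, p in zip(results, adj)
    ]


def cog_summary(
    results: Sequence[LFQResult],
    cog_map: Mapping[str, str],
) -> dict[str, tuple[int, int]]:
    """Count accumulated/depleted proteins per COG class.

    Proteins without a class assignment and proteins in class S (function
    unknown) are excluded; classes are returned in alphabetical order as
    {class: (n_accumulated, n_depleted)}.
    """
    tally: dict[str, list[int]] = {}
    for r in results:
        if r.category == UNCHANGED:
            continue
        cls = cog_map.get(r.protein, r.cog_class)
        if cls is None:
            logger.info("protein %s has no COG class; excluded", r.protein)
            continue
        if cls == COG_UNKNOWN_CLASS:
            continue
        slot = tally.setdefault(cls, [0, 0])
        slot[0 if r.category == ACCUMULATED else 1] += 1
    return {cls: (a, d) for cls, (a, d) in sorted(tally.items())}
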