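"""Alignment input/output and per-column bookkeeping.

Reads aligned FASTA/Clustal files into a validated :class:`Alignment`,
attaches protein-family labels, counts residues per column, and writes
per-position result tables. Alignment columns are 1-based in every public
interface, matching the way alignments are read by biologists; gaps are
normalised to ``'-'`` and residues to uppercase at read time.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: 20 canonical amino acids, gap, and 'X' for unknown residues.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = frozenset(AMINO_ACIDS) | {GAP, UNKNOWN}

UNLABELED = "unlabeled"


class AlignmentShapeError(ValueError):
    """Sequences in an alignment do not share a common length."""


class AlignmentIdentityError(ValueError):
    """Duplicate or empty sequence identifiers."""


class AlphabetError(ValueError):
    """A sequence contains a character outside the supported alphabet."""


class InputError(ValueError):
    """Empty or unparseable input file."""


@dataclass(frozen=True)
class Alignment:
    """A validated multiple sequence alignment with optional family labels.

    Parameters
    ----------
    ids :
        Unique, non-empty sequence identifiers.
    seqs :
        Equal-length uppercase strings over the 20 amino acids, ``'-'``
        (gap) and ``'X'`` (unknown).
    labels :
        Optional map from sequence id to family name. Ids without an entry
        are reported as ``"unlabeled"``.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentShapeError(
                f"{len(self.ids)} ids but {len(self.seqs)} sequences"
            )
        if not self.seqs:
            raise InputError("alignment contains no sequences")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"sequences have unequal lengths {sorted(lengths)}"
            )
        if lengths == {0}:
            raise AlignmentShapeError("sequences have zero length")
        if any(not i for i in self.ids):
            raise AlignmentIdentityError("empty sequence identifier")
        if len(set(self.ids)) != len(self.ids):
            dupes = [i for i, c in Counter(self.ids).items() if c > 1]
            raise AlignmentIdentityError(f"duplicate ids: {dupes}")
        for sid, seq in zip(self.ids, self.seqs):
            bad = set(seq) - ALPHABET
            if bad:
                raise AlphabetError(
                    f"record {sid!r} contains unsupported symbol(s) "
                    f"{sorted(bad)}"
                )

    @property
    def n_seqs(self) -> int:
        return len(self.seqs)

    @property
    def n_cols(self) -> int:
        return len(self.seqs[0])

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, top to bottom."""
        if not 1 <= col <= self.n_cols:
            raise IndexError(f"column {col} out of range 1..{self.n_cols}")
        return "".join(seq[col - 1] for seq in self.seqs)

    def family_of(self, seq_id: str) -> str:
        return self.labels.get(seq_id, UNLABELED)


@dataclass(frozen=True)
class SymbolCounts:
    """Residue counts for one alignment column (1-based ``column_index``)."""

    column_index: int
    counts: Mapping[str, int]
    n_observed: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_observed:
            raise ValueError("counts do not sum to n_observed")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`.

    Lowercase residues are uppercased and ``'.'`` gaps converted to ``'-'``.
    Raises the specific validation error (shape, identity, alphabet) for
    malformed alignments and :class:`InputError` for empty files.
    """
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise InputError(f"empty alignment file: {path}")
    try:
        records = list(AlignIO.parse(io.StringIO(text), format))
    except ValueError as exc:
        # Biopython's AlignIO refuses ragged records before we can; map its
        # complaint onto the shape error the contract promises.
        if "same length" in str(exc).lower():
            raise AlignmentShapeError(str(exc)) from exc
        raise InputError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records or not len(records[0]):
        raise InputError(f"no alignment records in {path}")
    msa = records[0]
    ids = tuple(rec.id for rec in msa)
    seqs = tuple(_normalize(str(rec.seq)) for rec in msa)
    return Alignment(ids=ids, seqs=seqs)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write an alignment in FASTA or Clustal format."""
    if format not in ("fasta", "clustal"):
        raise ValueError(f"unsupported format {format!r}")
    msa = MultipleSeqAlignment(
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ids, aln.seqs)
    )
    with open(path, "w") as handle:
        AlignIO.write(msa, handle, format)


def attach_labels(aln: Alignment, label_map: Mapping[str, str]) -> Alignment:
    """Return a copy of ``aln`` carrying family labels.

    Every key of ``label_map`` must name a sequence in the alignment;
    sequences without a label remain and are reported as ``"unlabeled"``.
    """
    known = set(aln.ids)
    unknown = sorted(set(label_map) - known)
    if unknown:
        raise KeyError(f"labels refer to unknown id(s): {unknown}")
    return replace(aln, labels=dict(label_map))


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (id <tab> family) label table, header optional."""
    labels: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"label line has no family column: {line!r}")
        if parts[0] in ("id", "sequence_id") and not labels:
            continue
        labels[parts[0]] = parts[1]
    return labels


def column_counts(
    aln: Alignment, col: int, gap_policy: str = "count_gap"
) -> SymbolCounts:
    """Count residues in 1-based column ``col``.

    Under ``skip_gap`` gaps are excluded from both the counts and
    ``n_observed``; ``'X'`` is always counted as its own symbol so rows
    stay synchronised.
    """
    if gap_policy not in ("count_gap", "skip_gap"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    residues = aln.column(col)
    if gap_policy == "skip_gap":
        residues = residues.replace(GAP, "")
    counts = dict(Counter(residues))
    return SymbolCounts(column_index=col, counts=counts, n_observed=len(residues))


def write_position_table(
    rows: Iterable[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] = ("column", "score", "pct_of_max", "category"),
) -> None:
    """Write per-position records as a TSV sorted by 1-based column index.

    ``rows`` must be non-empty mappings each containing at least the fields
    in ``columns``; the first field is the column index used for ordering.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no rows to write")
    key = columns[0]
    rows.sort(key=lambda r: int(r[key]))  # deterministic order by column
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
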