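"""Sliding-window mean pairwise similarity along a protein alignment.

The profile emulates EMBOSS ``plotcon``: for every alignment column the
mean substitution-matrix score over all unordered residue pairs is taken
(a pair involving a gap ``-`` or the mask symbol ``X`` contributes 0 and
stays in the denominator), and the profile value at window start ``j`` is
the mean column score over columns ``j .. j+W-1`` (1-based starts,
``L - W + 1`` windows). BLOSUM62 is the default matrix; any flat-file
matrix readable by Biopython can be substituted.

Stretches of missing sequence are conventionally written as poly-glycine
runs; :func:`mask_missing` turns runs of >= ``min_run`` glycines into mask
symbols so they score like gaps instead of inflating G/G identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import substitution_matrices

from .errors import ParameterError

#: characters whose pairs contribute nothing to a column score
NON_SCORING = frozenset("-.X*")

DEFAULT_WINDOW = 50
MASK_CHAR = "X"


def load_matrix(name_or_path: str | Path = "BLOSUM62"):
    """Load a substitution matrix by name (Biopython's bundled set) or from
    a flat file in NCBI/EMBOSS format."""
    name = str(name_or_path)
    if name.upper() in substitution_matrices.load():
        return substitution_matrices.load(name.upper())
    return substitution_matrices.read(str(name_or_path))


@dataclass(frozen=True)
class Alignment:
    """A protein multiple alignment: equal-length rows over AAs plus '-'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ParameterError("alignment needs at least 2 rows")
        if len(self.ids) != len(self.rows):
            raise ParameterError("ids and rows differ in number")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ParameterError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        msa = AlignIO.read(str(path), "fasta")
        return cls(
            ids=tuple(rec.id for rec in msa),
            rows=tuple(str(rec.seq).upper() for rec in msa),
        )

    def to_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n{row}\n")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-window mean pairwise similarity (one value per window start)."""

    window: int
    scores: tuple[float, ...]
    matrix_id: str = "BLOSUM62"

    def __len__(self) -> int:
        return len(self.scores)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("window_start\tscore\n")
            for j, s in enumerate(self.scores, start=1):
                fh.write(f"{j}\t{s:.6f}\n")

    def plot(self, ax=None):
        """Plot score against window start (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(1, len(self.scores) + 1), self.scores)
        ax.set_xlabel("window start (aa)")
        ax.set_ylabel(f"mean pairwise similarity ({self.matrix_id}, W={self.window})")
        return ax


def _pair_score(a: str, b: str, matrix) -> float:
    if a in NON_SCORING or b in NON_SCORING:
        return 0.0
    try:
        return float(matrix[a, b])
    except (KeyError, IndexError):
        return 0.0  # residue outside the matrix alphabet scores like a mask


def column_similarity(column, matrix=None) -> float:
    """Mean matrix score over all unordered residue pairs of one column."""
    if matrix is None:
        matrix = load_matrix()
    residues = [c.upper() for c in column]
    if len(residues) < 2:
        raise ParameterError("column similarity needs >= 2 rows")
    pairs = list(combinations(residues, 2))
    return sum(_pair_score(a, b, matrix) for a, b in pairs) / len(pairs)


def _column_scores(aln: Alignment, matrix) -> np.ndarray:
    """Vectorized per-column mean pair score via residue counting."""
    n = len(aln.rows)
    n_pairs = n * (n - 1) / 2
    scores = np.empty(aln.length)
    for j in range(aln.length):
        counts: dict[str, int] = {}
        for row in aln.rows:
            c = row[j].upper()
            counts[c] = counts.get(c, 0) + 1
        total = 0.0
        items = list(counts.items())
        for i, (a, ca) in enumerate(items):
            total += ca * (ca - 1) / 2 * _pair_score(a, a, matrix)
            for b, cb in items[i + 1:]:
                total += ca * cb * _pair_score(a, b, matrix)
        scores[j] = total / n_pairs
    return scores


def windowed_similarity(aln: Alignment, window: int = DEFAULT_WINDOW, matrix=None,
                        matrix_id: str | None = None) -> ConservationProfile:
    """Sliding-window conservation profile of an alignment.

    ``window`` must satisfy ``1 <= window <= alignment length``; the result
    has ``L - W + 1`` scores indexed by window start.
    """
    if matrix is None:
        matrix = load_matrix()
        matrix_id = matrix_id or "BLOSUM62"
    if window < 1:
        raise ParameterError(f"window must be >= 1, got {window}")
    if window > aln.length:
        raise ParameterError(
            f"window ({window}) exceeds alignment length ({aln.length})"
        )
    col = _column_scores(aln, matrix)
    kernel = np.ones(window) / window
    scores = np.convolve(col, kernel, mode="valid")
    return ConservationProfile(
        window=window,
        scores=tuple(float(s) for s in scores),
        matrix_id=matrix_id or "custom",
    )


def mask_missing(seq: str, min_run: int = 15, mask_char: str = MASK_CHAR) -> str:
    """Replace poly-glycine runs of length >= ``min_run`` by mask symbols.

    Shorter glycine runs are genuine sequence and stay untouched.
    """
    if min_run < 1:
        raise ParameterError(f"min_run must be >= 1, got {min_run}")
    return re.sub(
        f"G{{{min_run},}}", lambda m: mask_char * len(m.group(0)), seq, flags=re.IGNORECASE
    )
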