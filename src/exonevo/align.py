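"""Global protein alignment with affine gaps and identity/similarity statistics.

The aligner is Needleman–Wunsch with an affine gap model: an aligned pair of
residues scores its substitution-matrix value, and a gap of length L costs
``gap_open + (L-1) * gap_extend``.  End gaps are free by default, the
convention of the widely used pairwise global alignment web services, so a
short region aligned inside a longer one is not penalised for the overhangs.

Percentage conventions (which matter — MSA tools define identity
differently): *identity* is the fraction of alignment columns with identical
residues, *similarity* the fraction with identical or positively scoring
residues, and *gaps* the fraction of columns containing a gap — all with the
**total number of alignment columns, gap columns included,** as denominator.

The dynamic programming itself is delegated to :class:`Bio.Align.PairwiseAligner`,
configured to exactly this scoring model.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .seq_io import ProteinRecord

__all__ = [
    "ScoringScheme",
    "PairwiseAlignment",
    "AlignmentStats",
    "load_scoring_scheme",
    "align_global",
    "alignment_stats",
    "format_pair",
]

GAP = "-"


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    Attributes
    ----------
    matrix_name:
        Name of the substitution matrix (default ``"blosum62"``).
    gap_open:
        Non-negative penalty charged once per gap (default 10.0).
    gap_extend:
        Non-negative penalty per gap position after the first (default 0.5).
    penalize_end_gaps:
        If false (default), terminal gaps cost nothing.
    """

    matrix_name: str = "blosum62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    penalize_end_gaps: bool = False

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def pair_score(self, a: str, b: str) -> float:
        """Substitution score for an (unordered) residue pair."""
        return float(self.matrix[a, b])


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name.upper())
    except FileNotFoundError:
        available = ", ".join(sorted(substitution_matrices.load()))
        raise ValueError(
            f"unknown substitution matrix {name!r}; available: {available}"
        ) from None


def load_scoring_scheme(
    name: str = "blosum62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    penalize_end_gaps: bool = False,
) -> ScoringScheme:
    """Build a :class:`ScoringScheme`, validating the matrix name eagerly."""
    if gap_open < 0 or gap_extend < 0:
        raise ValueError("gap penalties must be non-negative")
    scheme = ScoringScheme(name, float(gap_open), float(gap_extend), penalize_end_gaps)
    scheme.matrix  # noqa: B018 -- force matrix lookup so bad names fail here
    return scheme


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped sequence pair with its alignment score.

    ``gapped_a`` and ``gapped_b`` have equal length, no column holds two
    gaps, and stripping gaps recovers the input sequences.
    """

    gapped_a: str
    gapped_b: str
    score: float
    id_a: str = ""
    id_b: str = ""

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped sequences differ in length")
        for ca, cb in zip(self.gapped_a, self.gapped_b):
            if ca == GAP and cb == GAP:
                raise ValueError("alignment column with two gaps")

    def __len__(self) -> int:
        return len(self.gapped_a)


@dataclass(frozen=True)
class AlignmentStats:
    """Column counts and percentages for one pairwise alignment.

    All percentages use total alignment columns (gaps included) as the
    denominator.  ``max_window_identity`` is the highest percentage of
    identical columns in any contiguous window of the configured width
    (one full-length window if the alignment is shorter).
    """

    length: int
    n_identical: int
    n_similar: int
    n_gap_columns: int
    identity_pct: float
    similarity_pct: float
    gaps_pct: float
    max_window_identity: float
    window: int


def _residues(seq: ProteinRecord | str) -> str:
    return seq.residues if isinstance(seq, ProteinRecord) else str(seq)


def _record_id(seq: ProteinRecord | str, default: str) -> str:
    return seq.record_id if isinstance(seq, ProteinRecord) else default


def _make_aligner(scheme: ScoringScheme) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -scheme.gap_open
    aligner.extend_gap_score = -scheme.gap_extend
    if not scheme.penalize_end_gaps:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    return aligner


def align_global(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    scheme: ScoringScheme | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    The returned alignment maximises the affine-gap score; the traceback is
    the aligner's first optimal path and is deterministic for fixed inputs.
    """
    scheme = scheme or load_scoring_scheme()
    seq_a, seq_b = _residues(a), _residues(b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(scheme)
    alignment = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(
        gapped_a=alignment[0],
        gapped_b=alignment[1],
        score=float(alignment.score),
        id_a=_record_id(a, "a"),
        id_b=_record_id(b, "b"),
    )


def _column_flags(
    aln: PairwiseAlignment, scheme: ScoringScheme
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (identical, similar, gap) boolean arrays."""
    n = len(aln)
    identical = np.zeros(n, dtype=bool)
    similar = np.zeros(n, dtype=bool)
    gap = np.zeros(n, dtype=bool)
    for k, (ca, cb) in enumerate(zip(aln.gapped_a, aln.gapped_b)):
        if ca == GAP or cb == GAP:
            gap[k] = True
        elif ca == cb:
            identical[k] = True
            similar[k] = True
        elif scheme.pair_score(ca, cb) > 0:
            similar[k] = True
    return identical, similar, gap


def alignment_stats(
    aln: PairwiseAlignment,
    scheme: ScoringScheme | None = None,
    window: int = 30,
) -> AlignmentStats:
    """Identity/similarity/gap statistics for an alignment.

    ``window`` sets the width (in columns) over which the maximum local
    identity is scanned; it feeds the "scattered vs contiguous" homology
    call downstream.
    """
    scheme = scheme or load_scoring_scheme()
    if window < 1:
        raise ValueError("window must be positive")
    identical, similar, gap = _column_flags(aln, scheme)
    length = len(aln)
    w = min(window, length)
    window_sums = np.convolve(identical.astype(int), np.ones(w, dtype=int), "valid")
    max_window = 100.0 * window_sums.max() / w
    return AlignmentStats(
        length=length,
        n_identical=int(identical.sum()),
        n_similar=int(similar.sum()),
        n_gap_columns=int(gap.sum()),
        identity_pct=100.0 * identical.sum() / length,
        similarity_pct=100.0 * similar.sum() / length,
        gaps_pct=100.0 * gap.sum() / length,
        max_window_identity=float(max_window),
        window=window,
    )


def format_pair(
    aln: PairwiseAlignment,
    stats: AlignmentStats | None = None,
    scheme: ScoringScheme | None = None,
    width: int = 60,
) -> str:
    """Human-readable blocked pair view with a match line.

    ``|`` marks identical columns, ``:`` similar (positively scoring)
    columns, and a space anything else, including gap columns.
    """
    scheme = scheme or load_scoring_scheme()
    if stats is None:
        stats = alignment_stats(aln, scheme)
    identical, similar, _ = _column_flags(aln, scheme)
    match_line = "".join(
        "|" if ident else ":" if sim else " "
        for ident, sim in zip(identical, similar)
    )
    lines = [
        f"# {aln.id_a} vs {aln.id_b}",
        f"# Length: {stats.length}  Score: {aln.score:.1f}",
        f"# Identity: {stats.n_identical}/{stats.length} ({stats.identity_pct:.1f}%)",
        f"# Similarity: {stats.n_similar}/{stats.length} ({stats.similarity_pct:.1f}%)",
        f"# Gaps: {stats.n_gap_columns}/{stats.length} ({stats.gaps_pct:.1f}%)",
        "",
    ]
    for start in range(0, len(aln), width):
        stop = start + width
        lines.append(aln.gapped_a[start:stop])
        lines.append(match_line[start:stop])
        lines.append(aln.gapped_b[start:stop])
        lines.append("")
    return "\n".join(lines)
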