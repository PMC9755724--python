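"""Region homology tables, identity matrices, significance calls, and scans.

This module produces the cross-species summaries of an exon-resolved
conservation analysis: per-region identity/similarity rows against a
reference species, all-vs-all percent-identity matrices, a two-criterion
homology significance call (overall identity above a noise floor *and* at
least one contiguous well-matching window, to reject "scattered" identity),
conservation ratios between regions, and a desk-scale similarity scan that
ranks database sequences (and their annotated exons) against a query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import (
    AlignmentStats,
    ScoringScheme,
    align_global,
    alignment_stats,
    load_scoring_scheme,
)
from .regions import RegionSpec, extract_region
from .seq_io import ExonMap, ProteinRecord

logger = logging.getLogger(__name__)

__all__ = [
    "RegionHomologyRow",
    "IdentityMatrix",
    "HomologyCall",
    "SimilarityHit",
    "region_homology_table",
    "identity_matrix",
    "classify_homology",
    "conservation_ratio",
    "rank_by_similarity",
]


@dataclass(frozen=True)
class RegionHomologyRow:
    """One (target species, region) row of a region-homology table."""

    species_label: str
    region_name: str
    identity_pct: float
    similarity_pct: float
    ref_region_len: int
    target_region_len: int


@dataclass(frozen=True)
class IdentityMatrix:
    """Square percent-identity matrix over an ordered species list.

    The diagonal is 100 by definition; off-diagonal entries come from
    pairwise global alignment of the extracted regions (each unordered pair
    aligned once, so the matrix is exactly symmetric).
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class HomologyCall:
    """Significance call for one alignment's statistics."""

    status: str  # "significant" | "nonsignificant"
    identity_pct: float
    max_window_identity: float
    reason: str


@dataclass(frozen=True)
class SimilarityHit:
    """One ranked hit of a similarity scan."""

    record_id: str
    region: str  # "full" or an exon label
    score: float
    identity_pct: float
    target_start: int
    target_end: int


Annotated = tuple[ProteinRecord, ExonMap | None]


def _label(record: ProteinRecord) -> str:
    return record.species_label or record.record_id


def region_homology_table(
    reference: Annotated,
    targets: Iterable[Annotated],
    regions: Sequence[RegionSpec],
    scheme: ScoringScheme | None = None,
    window: int = 30,
) -> list[RegionHomologyRow]:
    """Per-region identity/similarity of each target against the reference.

    Regions that cannot be resolved in a target (missing exon labels — e.g.
    a species without a 4a-L exon) are skipped with a log entry rather than
    zero-filled.  Raises if no row at all can be produced.
    """
    scheme = scheme or load_scoring_scheme()
    ref_record, ref_map = reference
    rows: list[RegionHomologyRow] = []
    for target_record, target_map in targets:
        for spec in regions:
            try:
                ref_seq, ref_len = extract_region(ref_record, ref_map, spec)
                tgt_seq, tgt_len = extract_region(target_record, target_map, spec)
            except (KeyError, ValueError) as exc:
                logger.info(
                    "skipping %s / %s: %s", target_record.record_id, spec.name, exc
                )
                continue
            stats = alignment_stats(
                align_global(ref_seq, tgt_seq, scheme), scheme, window
            )
            rows.append(
                RegionHomologyRow(
                    species_label=_label(target_record),
                    region_name=spec.name,
                    identity_pct=stats.identity_pct,
                    similarity_pct=stats.similarity_pct,
                    ref_region_len=ref_len,
                    target_region_len=tgt_len,
                )
            )
    if not rows:
        raise ValueError("no resolvable (target, region) pairs")
    return rows


def homology_rows_to_frame(rows: Iterable[RegionHomologyRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def identity_matrix(
    records: Sequence[Annotated],
    region: RegionSpec,
    scheme: ScoringScheme | None = None,
) -> IdentityMatrix:
    """All-vs-all percent-identity matrix on an extracted region."""
    scheme = scheme or load_scoring_scheme()
    usable: list[tuple[str, str]] = []
    for record, exon_map in records:
        try:
            seq, _ = extract_region(record, exon_map, region)
        except (KeyError, ValueError) as exc:
            logger.info("matrix: skipping %s: %s", record.record_id, exc)
            continue
        usable.append((_label(record), seq))
    if len(usable) < 2:
        raise ValueError(
            f"need at least 2 records with region {region.name!r}, have {len(usable)}"
        )
    n = len(usable)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            stats = alignment_stats(
                align_global(usable[i][1], usable[j][1], scheme), scheme
            )
            values[i, j] = values[j, i] = stats.identity_pct
    return IdentityMatrix(tuple(lab for lab, _ in usable), values)


def classify_homology(
    stats: AlignmentStats,
    min_identity: float = 20.0,
    window_min: float = 40.0,
) -> HomologyCall:
    """Two-criterion homology significance call.

    ``significant`` requires overall identity at or above ``min_identity``
    percent *and* a maximum windowed identity at or above ``window_min``
    percent — low identity scattered along the alignment, with no
    contiguous well-matching stretch, is classified as lacking homology.
    The call is monotone: raising either statistic never flips a
    significant call to nonsignificant.
    """
    failures = []
    if stats.identity_pct < min_identity:
        failures.append(
            f"identity {stats.identity_pct:.1f}% < {min_identity:g}%"
        )
    if stats.max_window_identity < window_min:
        failures.append(
            f"max {stats.window}-column window identity "
            f"{stats.max_window_identity:.1f}% < {window_min:g}% (scattered)"
        )
    if failures:
        return HomologyCall(
            "nonsignificant",
            stats.identity_pct,
            stats.max_window_identity,
            "; ".join(failures),
        )
    return HomologyCall(
        "significant",
        stats.identity_pct,
        stats.max_window_identity,
        "identity and window criteria met",
    )


@dataclass(frozen=True)
class ConservationRatio:
    """Relative conservation of one region versus another, in percent."""

    value: float
    rounded: int


def conservation_ratio(
    numerator_values: Sequence[float],
    denominator_values: Sequence[float],
) -> ConservationRatio:
    """100 x mean(numerator) / mean(denominator).

    Used to express, e.g., how conserved the 4a insert is relative to the
    microtubule-binding domain across a clade.  Scale-invariant: scaling
    both lists by a common factor leaves the ratio unchanged.
    """
    if not len(numerator_values) or not len(denominator_values):
        raise ValueError("both value lists must be nonempty")
    num = float(np.mean(numerator_values))
    den = float(np.mean(denominator_values))
    if den == 0:
        raise ZeroDivisionError("denominator mean is zero")
    value = 100.0 * num / den
    return ConservationRatio(value=value, rounded=int(round(value)))


def rank_by_similarity(
    query: ProteinRecord | str,
    database: Sequence[Annotated | ProteinRecord],
    scheme: ScoringScheme | None = None,
    include_exons: bool = True,
) -> list[SimilarityHit]:
    """Rank database sequences (and annotated exons) by alignment to a query.

    A desk-scale presence/absence scan: the query is globally aligned (end
    gaps free) against every record, and against each annotated exon when
    exon maps are available, then hits are sorted by score descending, ties
    broken by identity then record id.  The matched interval is the target
    span covered by the query (first to last column where the query has a
    residue).
    """
    scheme = scheme or load_scoring_scheme()
    if not database:
        raise ValueError("database is empty")
    hits: list[SimilarityHit] = []

    def scan(record_id: str, region: str, seq: str, offset: int) -> None:
        aln = align_global(query, seq, scheme)
        stats = alignment_stats(aln, scheme)
        # Target span covered by the query's residues.
        t = 0
        start = end = 0
        started = False
        for ca, cb in zip(aln.gapped_a, aln.gapped_b):
            if cb != "-":
                t += 1
            if ca != "-":
                if not started:
                    start = t - 1 if cb != "-" else t
                    started = True
                end = t
        hits.append(
            SimilarityHit(
                record_id=record_id,
                region=region,
                score=aln.score,
                identity_pct=stats.identity_pct,
                target_start=offset + max(start, 0),
                target_end=offset + end,
            )
        )

    for entry in database:
        record, exon_map = entry if isinstance(entry, tuple) else (entry, None)
        scan(record.record_id, "full", record.residues, 0)
        if include_exons and exon_map is not None:
            for iv in exon_map.intervals:
                scan(
                    record.record_id,
                    iv.label,
                    record.residues[iv.start : iv.end],
                    iv.start,
                )
    hits.sort(key=lambda h: (-h.score, -h.identity_pct, h.record_id, h.region))
    return hits
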