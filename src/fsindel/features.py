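"""The four selected features of a frameshifting coding indel.

* ``f14`` fraction of the gene's conserved DNA bases that are affected (%)
* ``f5``  indel location relative to the coding sequence, max over transcripts (%)
* ``f18`` fraction of conserved amino acids lost, max over transcripts (%)
* ``f15`` minimum distance of the indel to an exon boundary (bp)

"Affected" is everything from the first frameshifted coding base to the end
of the transcript's coding sequence: a frameshift scrambles every downstream
codon, so deleted bases plus all downstream bases count.  Features that
cannot be computed (no conservation data, no coding overlap) are flagged
rather than silently zeroed.

An open registry (:func:`register_feature`) allows plugging additional
named feature functions into :func:`extract_features`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .genome_model import (
    ConservationTrack,
    CoordinateError,
    Indel,
    ProteinConservationTrack,
    TranscriptModel,
)

FEATURE_NAMES = ("f14", "f5", "f18", "f15")

F14 = "f14"
F5 = "f5"
F18 = "f18"
F15 = "f15"


@dataclass
class FeatureVector:
    """Feature values for one indel; ``None`` + entry in ``uncomputable`` marks
    a feature that could not be derived from the available inputs."""

    frac_conserved_dna_affected: Optional[float] = None   # f14, percent
    max_relative_location: Optional[float] = None         # f5, percent
    max_frac_conserved_aa_lost: Optional[float] = None    # f18, percent
    min_dist_exon_boundary: Optional[int] = None          # f15, bp
    extras: dict[str, float] = field(default_factory=dict)
    uncomputable: set[str] = field(default_factory=set)
    indel_id: Optional[str] = None
    gene_id: Optional[str] = None

    _ALIASES = {
        F14: "frac_conserved_dna_affected",
        F5: "max_relative_location",
        F18: "max_frac_conserved_aa_lost",
        F15: "min_dist_exon_boundary",
    }

    def __post_init__(self) -> None:
        for pct in (
            self.frac_conserved_dna_affected,
            self.max_relative_location,
            self.max_frac_conserved_aa_lost,
        ):
            if pct is not None and not (0.0 <= pct <= 100.0):
                raise ValueError(f"percentage feature {pct} outside [0,100]")
        if self.min_dist_exon_boundary is not None and self.min_dist_exon_boundary < 0:
            raise ValueError("min_dist_exon_boundary must be >= 0")

    def value(self, name: str) -> Optional[float]:
        if name in self._ALIASES:
            return getattr(self, self._ALIASES[name])
        return self.extras.get(name)

    def is_computable(self, name: str) -> bool:
        return name not in self.uncomputable and self.value(name) is not None

    @classmethod
    def from_values(cls, f14: float, f5: float, f18: float, f15: float,
                    **extras: float) -> "FeatureVector":
        return cls(
            frac_conserved_dna_affected=f14,
            max_relative_location=f5,
            max_frac_conserved_aa_lost=f18,
            min_dist_exon_boundary=int(f15),
            extras=dict(extras),
        )


# registry for additional named features ------------------------------------

ExtraFeatureFn = Callable[[Indel, list[TranscriptModel]], float]
_EXTRA_FEATURES: dict[str, ExtraFeatureFn] = {}


def register_feature(name: str, fn: ExtraFeatureFn) -> None:
    if name in FEATURE_NAMES:
        raise ValueError(f"{name} is a built-in feature")
    _EXTRA_FEATURES[name] = fn


def registered_features() -> dict[str, ExtraFeatureFn]:
    return dict(_EXTRA_FEATURES)


# ---------------------------------------------------------------------------
# core geometry
# ---------------------------------------------------------------------------

def first_affected_cds_offset(indel: Indel, t: TranscriptModel) -> Optional[int]:
    """CDS offset of the first coding base touched or shifted by the indel.

    Deletions: the smallest CDS offset among deleted coding bases.
    Insertions: the offset of the coding base at the insertion point (the
    base the inserted sequence lands before, in transcript orientation).
    Returns None when the indel touches no coding base of ``t``.
    """
    lo, hi = t.span
    if indel.chrom != t.chrom:
        return None
    if indel.is_deletion:
        candidates = range(indel.start, indel.end)
    elif t.strand == "+":
        candidates = range(indel.start, indel.start + 1)
    else:
        candidates = range(indel.start - 1, indel.start)
    best: Optional[int] = None
    for pos in candidates:
        if not (lo <= pos < hi):
            continue
        off = t.genomic_to_cds(pos)
        if off is not None and (best is None or off < best):
            best = off
    return best


def affected_cds_region(indel: Indel, t: TranscriptModel) -> tuple[int, int]:
    """[first affected CDS base, coding_length) — empty when non-coding."""
    off = first_affected_cds_offset(indel, t)
    if off is None:
        return (0, 0)
    return (off, t.coding_length)


# ---------------------------------------------------------------------------
# the four features
# ---------------------------------------------------------------------------

def frac_conserved_dna_affected(
    indel: Indel,
    transcripts: list[TranscriptModel],
    dna_track: Optional[ConservationTrack],
) -> Optional[float]:
    """Percent of the gene's conserved coding DNA bases that are affected.

    Denominator: conserved bases within the union of all (valid) transcripts'
    coding bases.  Numerator: conserved bases within the union over
    transcripts of the genomic image of the affected CDS region.  Returns
    0.0 (by convention, the gene has nothing conserved to lose) when the
    denominator is 0 and None (uncomputable) without a track.
    """
    if dna_track is None:
        return None
    valid = [t for t in transcripts if t.is_valid]
    if not valid:
        return None
    gene_coding: set[int] = set()
    affected: set[int] = set()
    for t in valid:
        positions = t.coding_positions()
        gene_coding.update(int(p) for p in positions)
        lo, hi = affected_cds_region(indel, t)
        if hi > lo:
            affected.update(int(p) for p in positions[lo:hi])
    chrom = valid[0].chrom
    conserved_all = {p for p in gene_coding if dna_track.is_conserved(chrom, p)}
    if not conserved_all:
        return 0.0
    conserved_affected = conserved_all & affected
    return 100.0 * len(conserved_affected) / len(conserved_all)


def max_relative_location(
    indel: Indel, transcripts: list[TranscriptModel]
) -> Optional[float]:
    """Max over transcripts of 100 * first_affected_offset / coding_length."""
    best: Optional[float] = None
    for t in transcripts:
        if not t.is_valid:
            continue
        off = first_affected_cds_offset(indel, t)
        if off is None:
            continue
        rel = 100.0 * off / t.coding_length
        if best is None or rel > best:
            best = rel
    return best


def max_frac_conserved_aa_lost(
    indel: Indel,
    transcripts: list[TranscriptModel],
    protein_track: Optional[ProteinConservationTrack],
) -> Optional[float]:
    """Max over transcripts of percent conserved residues at/after the
    frameshift codon (residues of the original protein, index >=
    floor(cds_offset / 3))."""
    if protein_track is None:
        return None
    best: Optional[float] = None
    for t in transcripts:
        if not t.is_valid or not protein_track.has_transcript(t.transcript_id):
            continue
        off = first_affected_cds_offset(indel, t)
        if off is None:
            continue
        mask = protein_track.conserved_mask(t.transcript_id)
        n_conserved = int(mask.sum())
        if n_conserved == 0:
            value = 0.0
        else:
            first_codon = off // 3
            value = 100.0 * int(mask[first_codon:].sum()) / n_conserved
        if best is None or value > best:
            best = value
    return best


def min_dist_exon_boundary(
    indel: Indel, transcripts: list[TranscriptModel]
) -> Optional[int]:
    """Min over affected transcripts of the distance (bp) from the indel's
    leftmost affected base to the nearer edge of its containing exon."""
    best: Optional[int] = None
    pos = indel.start
    for t in transcripts:
        if not t.is_valid or t.chrom != indel.chrom:
            continue
        exon = t.containing_exon(pos)
        if exon is None:
            continue
        a, b = exon
        d = min(pos - a, b - 1 - pos)
        if best is None or d < best:
            best = d
    return best


def extract_features(
    indel: Indel,
    transcripts: list[TranscriptModel],
    dna_track: Optional[ConservationTrack] = None,
    protein_track: Optional[ProteinConservationTrack] = None,
) -> FeatureVector:
    """Compute the selected features for a frameshifting coding indel.

    Non-frameshifting indels are rejected: this tool's scope is FS indels.
    """
    if not indel.is_frameshifting():
        raise ValueError(
            f"indel {indel.id or indel.allele_key()} is not frameshifting "
            f"(net length {indel.net_length})"
        )
    uncomputable: set[str] = set()

    f14 = frac_conserved_dna_affected(indel, transcripts, dna_track)
    if f14 is None:
        uncomputable.add(F14)
    f5 = max_relative_location(indel, transcripts)
    if f5 is None:
        uncomputable.add(F5)
    f18 = max_frac_conserved_aa_lost(indel, transcripts, protein_track)
    if f18 is None:
        uncomputable.add(F18)
    f15 = min_dist_exon_boundary(indel, transcripts)
    if f15 is None:
        uncomputable.add(F15)

    extras: dict[str, float] = {}
    for name, fn in _EXTRA_FEATURES.items():
        try:
            extras[name] = float(fn(indel, transcripts))
        except Exception:
            uncomputable.add(name)

    gene_ids = {t.gene_id for t in transcripts}
    return FeatureVector(
        frac_conserved_dna_affected=f14,
        max_relative_location=f5,
        max_frac_conserved_aa_lost=f18,
        min_dist_exon_boundary=f15,
        extras=extras,
        uncomputable=uncomputable,
        indel_id=indel.id,
        gene_id=gene_ids.pop() if len(gene_ids) == 1 else None,
    )


# ---------------------------------------------------------------------------
# feature table I/O
# ---------------------------------------------------------------------------

TABLE_COLUMNS = [
    "indel_id",
    "gene_id",
    "f14_frac_cons_dna",
    "f5_max_rel_loc",
    "f18_max_frac_cons_aa_lost",
    "f15_min_dist_exon",
]


def write_feature_table(vectors: list[FeatureVector], path) -> None:
    extra_names = sorted({k for v in vectors for k in v.extras})
    with open(path, "w") as fh:
        fh.write("\t".join(TABLE_COLUMNS + extra_names) + "\n")
        for v in vectors:
            row = [
                v.indel_id or "",
                v.gene_id or "",
                _fmt(v.frac_conserved_dna_affected),
                _fmt(v.max_relative_location),
                _fmt(v.max_frac_conserved_aa_lost),
                _fmt(v.min_dist_exon_boundary),
            ]
            row += [_fmt(v.extras.get(name)) for name in extra_names]
            fh.write("\t".join(row) + "\n")


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{x:g}"
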