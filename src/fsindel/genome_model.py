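"""Domain types and I/O for indel calls, transcript models and conservation tracks.

Single source of truth for coordinate conventions:

* internal coordinates are 0-based, half-open;
* VCF and the tab-separated indel interchange format are 1-based on input
  and output, converted exactly once at the I/O boundary;
* exon lists are stored in ascending genomic order regardless of strand;
  CDS offsets are strand-aware (offset 0 is the first coding base in
  transcript orientation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

LABEL_DAMAGING = "gene-damaging"
LABEL_NEUTRAL = "neutral"


class IndelError(ValueError):
    """Raised for records that cannot be interpreted as a pure indel."""


class CoordinateError(ValueError):
    """Raised for positions outside the queried transcript."""


# ---------------------------------------------------------------------------
# Indel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Indel:
    """One insertion or deletion call.

    ``pos`` is the 0-based position of the first base of ``ref_allele``
    (i.e. VCF POS - 1; for anchored representations this is the shared
    anchor base).  Use :attr:`start` for the leftmost genomic base actually
    affected after trimming the shared prefix.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    id: Optional[str] = None
    allele_frequency: Optional[float] = None

    def __post_init__(self) -> None:
        ref, alt = self.ref_allele.upper(), self.alt_allele.upper()
        if not ref or not alt:
            raise IndelError(f"empty allele in {ref!r}>{alt!r}")
        if any(c not in "ACGTN" for c in ref + alt):
            raise IndelError(f"non-nucleotide characters in {ref!r}>{alt!r}")
        tref, talt, _ = _trim_alleles(ref, alt)
        if tref and talt:
            raise IndelError(
                f"{ref!r}>{alt!r} is not a pure insertion or deletion"
            )
        if not tref and not talt:
            raise IndelError(f"{ref!r}>{alt!r} has no length change")
        if self.allele_frequency is not None and not (
            0.0 <= self.allele_frequency <= 1.0
        ):
            raise IndelError(
                f"allele frequency {self.allele_frequency} outside [0,1]"
            )

    @property
    def net_length(self) -> int:
        """Signed length change in bp (len(alt) - len(ref))."""
        return len(self.alt_allele) - len(self.ref_allele)

    def is_frameshifting(self) -> bool:
        return abs(self.net_length) % 3 != 0

    @property
    def is_deletion(self) -> bool:
        return self.net_length < 0

    @property
    def _trimmed(self) -> tuple[str, str, int]:
        return _trim_alleles(self.ref_allele.upper(), self.alt_allele.upper())

    @property
    def start(self) -> int:
        """0-based leftmost affected base.

        For deletions: first deleted base.  For insertions: the base before
        which the new sequence lands (the insertion point).
        """
        _, _, n = self._trimmed
        return self.pos + n

    @property
    def end(self) -> int:
        """0-based exclusive end of the deleted reference span.

        Insertions occupy zero reference bases, so ``end == start``.
        """
        tref, _, _ = self._trimmed
        return self.start + len(tref)

    def allele_key(self) -> tuple[str, int, str, str]:
        """Canonical identity (chrom, start, trimmed ref, trimmed alt)."""
        tref, talt, _ = self._trimmed
        return (self.chrom, self.start, tref, talt)

    def left_normalized(self, sequence: str, seq_offset: int = 0) -> "Indel":
        """Shift this indel to its leftmost equivalent position.

        ``sequence`` is reference sequence for this chromosome (or a slice
        of it starting at genomic coordinate ``seq_offset``).
        """
        tref, talt, _ = self._trimmed
        moving = tref or talt
        start = self.start
        i = start - seq_offset
        while i > 0 and moving and sequence[i - 1].upper() == moving[-1].upper():
            moving = sequence[i - 1].upper() + moving[:-1]
            i -= 1
        new_start = i + seq_offset
        if new_start == start:
            return self
        anchor = sequence[new_start - 1 - seq_offset].upper() if new_start > 0 else "N"
        if self.is_deletion:
            ref, alt = anchor + moving, anchor
        else:
            ref, alt = anchor, anchor + moving
        return Indel(
            chrom=self.chrom,
            pos=new_start - 1,
            ref_allele=ref,
            alt_allele=alt,
            id=self.id,
            allele_frequency=self.allele_frequency,
        )


def _trim_alleles(ref: str, alt: str) -> tuple[str, str, int]:
    """Strip the shared suffix then the shared prefix; returns the trimmed
    alleles plus the number of prefix bases removed (the position shift)."""
    i, j = len(ref), len(alt)
    while i > 0 and j > 0 and ref[i - 1] == alt[j - 1]:
        i -= 1
        j -= 1
    k = 0
    while k < i and k < j and ref[k] == alt[k]:
        k += 1
    return ref[k:i], alt[k:j], k


# ---------------------------------------------------------------------------
# TranscriptModel
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` are 0-based half-open genomic intervals in ascending genomic
    order; ``cds_start``/``cds_end`` bound the coding region genomically
    (half-open).  A transcript is *valid* iff it has a CDS whose total
    length is a positive multiple of 3.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    invalid_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.transcript_id}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"empty exon [{a},{b}) in {self.transcript_id}")
        for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        if self.invalid_reason is None:
            if self.cds_start is None or self.cds_end is None:
                self.invalid_reason = "missing-cds"
            elif self.coding_length == 0:
                self.invalid_reason = "empty-cds"
            elif self.coding_length % 3 != 0:
                self.invalid_reason = "cds-length-not-multiple-of-3"

    @property
    def is_valid(self) -> bool:
        return self.invalid_reason is None

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def coding_length(self) -> int:
        if self.cds_start is None or self.cds_end is None:
            return 0
        total = 0
        for a, b in self.exons:
            total += max(0, min(b, self.cds_end) - max(a, self.cds_start))
        return total

    def coding_intervals(self) -> list[tuple[int, int]]:
        """CDS-overlapping exon pieces, ascending genomic order."""
        if self.cds_start is None or self.cds_end is None:
            return []
        out = []
        for a, b in self.exons:
            lo, hi = max(a, self.cds_start), min(b, self.cds_end)
            if hi > lo:
                out.append((lo, hi))
        return out

    def coding_positions(self) -> np.ndarray:
        """All coding genomic positions in transcript (5'->3') order."""
        pieces = self.coding_intervals()
        if self.strand == "-":
            arrays = [np.arange(b - 1, a - 1, -1) for a, b in reversed(pieces)]
        else:
            arrays = [np.arange(a, b) for a, b in pieces]
        if not arrays:
            return np.array([], dtype=int)
        return np.concatenate(arrays)

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """0-based offset into the coding sequence, or None if non-coding.

        Raises :class:`CoordinateError` when ``pos`` lies outside the
        transcript span.
        """
        lo, hi = self.span
        if not (lo <= pos < hi):
            raise CoordinateError(
                f"position {pos} outside transcript {self.transcript_id} span [{lo},{hi})"
            )
        offset = 0
        for a, b in self.coding_intervals():
            if a <= pos < b:
                if self.strand == "+":
                    return offset + (pos - a)
                # minus strand: count from the genomic high end
                return self.coding_length - 1 - (offset + (pos - a))
            offset += b - a
        return None

    def cds_to_genomic(self, offset: int) -> int:
        """Inverse of :meth:`genomic_to_cds` for coding offsets."""
        if not (0 <= offset < self.coding_length):
            raise CoordinateError(
                f"CDS offset {offset} outside [0,{self.coding_length}) for {self.transcript_id}"
            )
        if self.strand == "-":
            offset = self.coding_length - 1 - offset
        for a, b in self.coding_intervals():
            if offset < b - a:
                return a + offset
            offset -= b - a
        raise AssertionError("unreachable")

    def containing_exon(self, pos: int) -> Optional[tuple[int, int]]:
        for a, b in self.exons:
            if a <= pos < b:
                return (a, b)
        return None

    def distance_to_nearest_exon_edge(self, pos: int) -> int:
        """bp from ``pos`` to the nearest exon boundary (0 at an edge).

        For exonic positions: distance to the closer edge of the containing
        exon.  For intronic positions: distance to the nearest flanking exon.
        """
        exon = self.containing_exon(pos)
        if exon is not None:
            a, b = exon
            return min(pos - a, b - 1 - pos)
        best = None
        for a, b in self.exons:
            d = a - pos if pos < a else pos - b + 1
            best = d if best is None else min(best, d)
        if best is None:
            raise CoordinateError("transcript has no exons")
        return best


def genomic_to_cds(transcript: TranscriptModel, pos: int) -> Optional[int]:
    """Module-level convenience wrapper around the method of the same name."""
    return transcript.genomic_to_cds(pos)


def cds_to_genomic(transcript: TranscriptModel, offset: int) -> int:
    return transcript.cds_to_genomic(offset)


# ---------------------------------------------------------------------------
# Conservation tracks
# ---------------------------------------------------------------------------

@dataclass
class ConservationTrack:
    """Per-base DNA conservation scores (PhyloP-style).

    Sparse mapping chrom -> {position -> score}.  Positions without a score
    are *missing*, which is distinct from a score of 0: :meth:`score`
    returns ``None`` for them and :meth:`is_conserved` counts them.
    """

    scores: dict[str, dict[int, float]] = field(default_factory=dict)
    conservation_threshold: float = 1.5
    missing_queries: int = 0

    def set_score(self, chrom: str, pos: int, value: float) -> None:
        self.scores.setdefault(chrom, {})[int(pos)] = float(value)

    def score(self, chrom: str, pos: int) -> Optional[float]:
        return self.scores.get(chrom, {}).get(pos)

    def is_conserved(self, chrom: str, pos: int) -> bool:
        """Missing scores count as not conserved (logged via missing_queries)."""
        s = self.score(chrom, pos)
        if s is None:
            self.missing_queries += 1
            return False
        return s >= self.conservation_threshold


@dataclass
class ProteinConservationTrack:
    """Per-residue conservation scores keyed by transcript id.

    A residue is conserved when its score reaches ``threshold``; if no
    explicit threshold is given the per-protein upper quartile is used.
    """

    scores: dict[str, np.ndarray] = field(default_factory=dict)
    threshold: Optional[float] = None
    percentile: float = 75.0

    def set_scores(self, transcript_id: str, values: Sequence[float]) -> None:
        self.scores[transcript_id] = np.asarray(values, dtype=float)

    def has_transcript(self, transcript_id: str) -> bool:
        return transcript_id in self.scores

    def conserved_mask(self, transcript_id: str) -> np.ndarray:
        values = self.scores[transcript_id]
        if self.threshold is not None:
            thr = self.threshold
        else:
            thr = float(np.percentile(values, self.percentile))
        return values >= thr


@dataclass
class GeneIndelSet:
    """Indels of one gene (optionally one species), plus call qualities.

    ``quality_scores`` maps an indel id to the per-base quality values of
    the window surrounding that indel's start.
    """

    gene_id: str
    indels: list[Indel]
    species: Optional[str] = None
    quality_scores: dict[str, Sequence[int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Indel I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "id", "allele_frequency"]


def read_indels(path: str | Path) -> list[Indel]:
    """Read indel calls from a VCF (``.vcf``) or tab-separated file.

    Positions in both formats are 1-based and are converted to the internal
    0-based convention.  Non-indel records (substitutions, MNPs) are
    skipped; the count is logged.  Malformed records raise
    :class:`IndelError` naming the offending line.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        return _read_vcf(path)
    return _read_indel_tsv(path)


def _read_vcf(path: Path) -> list[Indel]:
    import warnings

    import pysam

    out: list[Indel] = []
    n_skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vf = pysam.VariantFile(str(path))
        for rec in vf:
            for alt in rec.alts or ():
                try:
                    indel = Indel(
                        chrom=rec.chrom,
                        pos=rec.pos - 1,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        id=rec.id,
                        allele_frequency=_vcf_af(rec),
                    )
                except IndelError:
                    n_skipped += 1
                    continue
                out.append(indel)
    if n_skipped:
        logger.info("read_indels(%s): skipped %d non-indel record(s)", path, n_skipped)
    return out


def _vcf_af(rec) -> Optional[float]:
    af = rec.info.get("AF") if "AF" in rec.info else None
    if af is None:
        return None
    if isinstance(af, (tuple, list)):
        af = af[0]
    return float(af)


def _read_indel_tsv(path: Path) -> list[Indel]:
    out: list[Indel] = []
    n_skipped = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            idx = {name: header.index(name) for name in ("chrom", "pos", "ref", "alt")}
        except ValueError as exc:
            raise IndelError(f"{path}: missing required column: {exc}") from exc
        opt = {name: header.index(name) for name in ("id", "allele_frequency")
               if name in header}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                af_raw = fields[opt["allele_frequency"]] if "allele_frequency" in opt else ""
                ind_id = fields[opt["id"]] if "id" in opt else ""
                indel = Indel(
                    chrom=fields[idx["chrom"]],
                    pos=int(fields[idx["pos"]]) - 1,
                    ref_allele=fields[idx["ref"]],
                    alt_allele=fields[idx["alt"]],
                    id=ind_id or None,
                    allele_frequency=float(af_raw) if af_raw not in ("", "NA") else None,
                )
            except IndelError as exc:
                if "not a pure insertion" in str(exc) or "no length change" in str(exc):
                    n_skipped += 1
                    continue
                raise IndelError(f"{path}:{lineno}: {exc}") from exc
            except (ValueError, IndexError) as exc:
                raise IndelError(f"{path}:{lineno}: malformed record: {exc}") from exc
            out.append(indel)
    if n_skipped:
        logger.info("read_indels(%s): skipped %d non-indel record(s)", path, n_skipped)
    return out


def write_indels(indels: Iterable[Indel], path: str | Path, fmt: str = "tsv") -> None:
    """Write indels as TSV (default) or minimal VCF; positions back to 1-based."""
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for ind in indels:
                af = "" if ind.allele_frequency is None else repr(ind.allele_frequency)
                fh.write(
                    f"{ind.chrom}\t{ind.pos + 1}\t{ind.ref_allele}\t{ind.alt_allele}\t"
                    f"{ind.id or ''}\t{af}\n"
                )
    elif fmt == "vcf":
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
            chroms = sorted({ind.chrom for ind in indels_list} if (indels_list := list(indels)) else set())
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
            for ind in indels_list:
                info = "." if ind.allele_frequency is None else f"AF={ind.allele_frequency}"
                fh.write(
                    f"{ind.chrom}\t{ind.pos + 1}\t{ind.id or '.'}\t{ind.ref_allele}\t"
                    f"{ind.alt_allele}\t.\t.\t{info}\n"
                )
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Transcript I/O
# ---------------------------------------------------------------------------

def read_transcripts(path: str | Path) -> dict[str, list[TranscriptModel]]:
    """Read transcript models from GTF/GFF3 into a gene_id -> transcripts map.

    Transcripts that fail validation (no CDS, CDS length not a multiple of
    3) are kept but flagged via ``invalid_reason``, never silently dropped.
    """
    import gffutils

    path = Path(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id") or _gff3_parent(feat)
        gene = (feat.attributes.get("gene_id") or ["?"])[0]
        for tid in tids:
            prev = meta.get(tid)
            if prev is not None and prev[2] != feat.strand:
                raise ValueError(f"inconsistent strand for transcript {tid}")
            meta[tid] = (gene, feat.seqid, feat.strand)
            interval = (feat.start - 1, feat.end)  # GFF is 1-based inclusive
            target = exons if feat.featuretype == "exon" else cds
            target.setdefault(tid, []).append(interval)

    genes: dict[str, list[TranscriptModel]] = {}
    for tid, (gene, chrom, strand) in meta.items():
        if strand not in ("+", "-"):
            raise ValueError(f"unknown strand {strand!r} for transcript {tid}")
        cds_iv = cds.get(tid, [])
        cds_start = min(a for a, _ in cds_iv) if cds_iv else None
        cds_end = max(b for _, b in cds_iv) if cds_iv else None
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gene,
            chrom=chrom,
            strand=strand,
            exons=exons.get(tid, cds_iv),
            cds_start=cds_start,
            cds_end=cds_end,
        )
        genes.setdefault(gene, []).append(t)
    return genes


def _gff3_parent(feat) -> list[str]:
    return list(feat.attributes.get("Parent", []))


def write_transcripts_gtf(
    transcripts: Iterable[TranscriptModel], path: str | Path, source: str = "fsindel"
) -> None:
    with open(Path(path), "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for a, b in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                )
            for a, b in t.coding_intervals():
                fh.write(
                    f"{t.chrom}\t{source}\tCDS\t{a + 1}\t{b}\t.\t{t.strand}\t0\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Conservation I/O
# ---------------------------------------------------------------------------

def read_dna_conservation(
    path: str | Path, conservation_threshold: float = 1.5
) -> ConservationTrack:
    """Read a fixed-step/variable-step wiggle or bedGraph DNA score track."""
    path = Path(path)
    track = ConservationTrack(conservation_threshold=conservation_threshold)
    mode: Optional[str] = None
    chrom = ""
    pos = 0
    step = 1
    span = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("fixedStep"):
                params = dict(kv.split("=") for kv in line.split()[1:])
                mode = "fixed"
                chrom = params["chrom"]
                pos = int(params["start"]) - 1  # wig is 1-based
                step = int(params.get("step", 1))
                span = int(params.get("span", 1))
                continue
            if line.startswith("variableStep"):
                params = dict(kv.split("=") for kv in line.split()[1:])
                mode = "variable"
                chrom = params["chrom"]
                span = int(params.get("span", 1))
                continue
            fields = line.split()
            if len(fields) == 4:  # bedGraph: chrom start end value (0-based half-open)
                c, a, b, v = fields
                for p in range(int(a), int(b)):
                    track.set_score(c, p, float(v))
            elif mode == "fixed" and len(fields) == 1:
                for k in range(span):
                    track.set_score(chrom, pos + k, float(fields[0]))
                pos += step
            elif mode == "variable" and len(fields) == 2:
                start = int(fields[0]) - 1
                for k in range(span):
                    track.set_score(chrom, start + k, float(fields[1]))
            else:
                raise ValueError(f"{path}:{lineno}: unparseable wig/bedGraph line")
    return track


def write_dna_conservation_wig(track: ConservationTrack, path: str | Path) -> None:
    """Write as variableStep wig (sparse positions, 1-based)."""
    with open(Path(path), "w") as fh:
        for chrom in sorted(track.scores):
            fh.write(f"variableStep chrom={chrom}\n")
            for pos in sorted(track.scores[chrom]):
                fh.write(f"{pos + 1}\t{track.scores[chrom][pos]:g}\n")


def read_protein_conservation(
    path: str | Path,
    threshold: Optional[float] = None,
    percentile: float = 75.0,
) -> ProteinConservationTrack:
    """Read per-residue scores from TSV: transcript_id, position (1-based), score."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "position", "score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    track = ProteinConservationTrack(threshold=threshold, percentile=percentile)
    for tid, grp in df.groupby("transcript_id"):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, len(positions) + 1)):
            raise ValueError(f"{path}: positions for {tid} must be contiguous from 1")
        track.set_scores(str(tid), grp["score"].to_numpy())
    return track


def write_protein_conservation(
    track: ProteinConservationTrack, path: str | Path
) -> None:
    with open(Path(path), "w") as fh:
        fh.write("transcript_id\tposition\tscore\n")
        for tid in sorted(track.scores):
            for i, s in enumerate(track.scores[tid], start=1):
                fh.write(f"{tid}\t{i}\t{s:g}\n")


def group_by_gene(
    indels: Iterable[Indel],
    genes: Mapping[str, list[TranscriptModel]],
    species: Optional[str] = None,
) -> list[GeneIndelSet]:
    """Assign each indel to every gene whose transcript span contains it."""
    out: dict[str, GeneIndelSet] = {}
    for ind in indels:
        for gene_id, transcripts in genes.items():
            for t in transcripts:
                lo, hi = t.span
                if t.chrom == ind.chrom and lo <= ind.start < hi:
                    out.setdefault(
                        gene_id, GeneIndelSet(gene_id=gene_id, indels=[], species=species)
                    ).indels.append(ind)
                    break
    return list(out.values())
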