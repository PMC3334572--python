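"""Compensatory-indel analysis.

A frameshifting indel knocks out a gene, but a second nearby frameshifting
indel can restore the reading frame when the pair's net length change is
divisible by three.  This module clusters frameshifting indels by proximity
(single-linkage chaining within a window), computes the fraction of
clusters whose net size restores the frame as a function of window size,
and compares that fraction between exonic and intronic indel pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .genome_model import Indel, TranscriptModel
from .rules import round_half_up


@dataclass
class IndelCluster:
    """Two or more individually-frameshifting indels within one window."""

    region_id: str
    members: list[Indel]
    max_pairwise_gap: int  # bp between first and last member start
    net_size: int
    frame_restored: bool

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")
        for m in self.members:
            if not m.is_frameshifting():
                raise ValueError("cluster members must be frameshifting indels")
        if self.net_size != sum(m.net_length for m in self.members):
            raise ValueError("net_size must equal the sum of member net lengths")
        if self.frame_restored != (self.net_size % 3 == 0):
            raise ValueError("frame_restored inconsistent with net_size")

    @classmethod
    def from_members(cls, region_id: str, members: Sequence[Indel],
                     positions: Optional[Sequence[int]] = None) -> "IndelCluster":
        pos = list(positions) if positions is not None else [m.start for m in members]
        net = sum(m.net_length for m in members)
        return cls(
            region_id=region_id,
            members=list(members),
            max_pairwise_gap=max(pos) - min(pos),
            net_size=net,
            frame_restored=net % 3 == 0,
        )


def cluster_indels(
    indels: Sequence[Indel],
    window: int,
    region_id: str = "",
    transcript: Optional[TranscriptModel] = None,
) -> list[IndelCluster]:
    """Single-linkage chaining: consecutive indels at most ``window`` bp
    apart (start-to-start) join the same cluster; singletons are dropped.

    When ``transcript`` is given, distances are measured on the transcript
    (cDNA) coordinate; indels outside its coding bases are excluded.
    """
    fs = [i for i in indels if i.is_frameshifting()]
    if transcript is not None:
        located = []
        for ind in fs:
            try:
                off = transcript.genomic_to_cds(ind.start)
            except Exception:
                off = None
            if off is not None:
                located.append((off, ind))
        located.sort(key=lambda t: t[0])
    else:
        located = sorted(((ind.start, ind) for ind in fs), key=lambda t: t[0])

    clusters: list[IndelCluster] = []
    chain: list[tuple[int, Indel]] = []

    def flush() -> None:
        if len(chain) >= 2:
            clusters.append(IndelCluster.from_members(
                region_id, [ind for _, ind in chain], [p for p, _ in chain]))

    for pos, ind in located:
        if chain and pos - chain[-1][0] <= window:
            chain.append((pos, ind))
        else:
            flush()
            chain = [(pos, ind)]
    flush()
    return clusters


@dataclass(frozen=True)
class RestorationPoint:
    n_clusters: int
    n_restored: int

    @property
    def fraction(self) -> Optional[float]:
        if self.n_clusters == 0:
            return None  # undefined, flagged
        return self.n_restored / self.n_clusters


def restoration_curve(
    indels_by_region: Mapping[str, Sequence[Indel]],
    windows: Sequence[int],
    transcripts: Optional[Mapping[str, TranscriptModel]] = None,
) -> dict[int, RestorationPoint]:
    """For each window size, the fraction of clusters (over all regions)
    whose net size is divisible by three."""
    out: dict[int, RestorationPoint] = {}
    for w in windows:
        n = restored = 0
        for region_id, indels in indels_by_region.items():
            t = transcripts.get(region_id) if transcripts else None
            for c in cluster_indels(indels, w, region_id=region_id, transcript=t):
                n += 1
                restored += int(c.frame_restored)
        out[w] = RestorationPoint(n_clusters=n, n_restored=restored)
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    exon_fraction: float
    intron_fraction: float
    n_exon_pairs: int
    n_intron_pairs: int

    @property
    def enrichment(self) -> Optional[float]:
        if self.intron_fraction == 0:
            return None  # undefined, flagged
        return round_half_up(self.exon_fraction / self.intron_fraction, 2)


def exon_intron_enrichment(
    exon_pairs: Sequence[IndelCluster],
    intron_pairs: Sequence[IndelCluster],
) -> EnrichmentResult:
    """Fraction of frame-restoring two-indel clusters in exons vs introns,
    and their ratio (2 decimals)."""
    for name, pairs in (("exon", exon_pairs), ("intron", intron_pairs)):
        for c in pairs:
            if len(c.members) != 2:
                raise ValueError(f"{name} cluster {c.region_id} is not a pair")
        if not pairs:
            raise ValueError(f"no {name} pairs")
    exon_frac = sum(c.frame_restored for c in exon_pairs) / len(exon_pairs)
    intron_frac = sum(c.frame_restored for c in intron_pairs) / len(intron_pairs)
    return EnrichmentResult(
        exon_fraction=exon_frac,
        intron_fraction=intron_frac,
        n_exon_pairs=len(exon_pairs),
        n_intron_pairs=len(intron_pairs),
    )


def write_restoration_curve(curve: Mapping[int, RestorationPoint], path) -> None:
    with open(path, "w") as fh:
        fh.write("window\tn_clusters\tn_restored\tfraction_restored\n")
        for w in sorted(curve):
            p = curve[w]
            frac = "NA" if p.fraction is None else f"{p.fraction:.4f}"
            fh.write(f"{w}\t{p.n_clusters}\t{p.n_restored}\t{frac}\n")


def write_enrichment(result: EnrichmentResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("region_class\tn_pairs\tfraction_restored\n")
        fh.write(f"exon\t{result.n_exon_pairs}\t{result.exon_fraction:.4f}\n")
        fh.write(f"intron\t{result.n_intron_pairs}\t{result.intron_fraction:.4f}\n")
        enr = "NA" if result.enrichment is None else f"{result.enrichment:.2f}"
        fh.write(f"enrichment\t\t{enr}\n")
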