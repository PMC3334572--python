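"""Dataset-construction filters for indel call sets.

All filters are idempotent and return a :class:`FilterReport` accounting
for every removal (n_in == n_out + len(removed)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .genome_model import GeneIndelSet, Indel


@dataclass
class FilterReport:
    n_in: int
    n_out: int
    removed: list[tuple[str, str]] = field(default_factory=list)  # (indel_id, reason)

    def __post_init__(self) -> None:
        if self.n_in - self.n_out != len(self.removed):
            raise ValueError("FilterReport conservation violated")


def _ind_id(ind: Indel) -> str:
    return ind.id or f"{ind.chrom}:{ind.start}:{ind.ref_allele}>{ind.alt_allele}"


def one_per_gene(
    sets: Sequence[GeneIndelSet], mode: str, seed: int = 0
) -> tuple[list[GeneIndelSet], FilterReport]:
    """Disease mode: keep one uniformly-random indel per gene.  Neutral mode:
    a gene x species set holding more than one frameshifting indel is assumed
    to be a pseudogene and dropped entirely."""
    if mode not in ("disease", "neutral"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out: list[GeneIndelSet] = []
    removed: list[tuple[str, str]] = []
    n_in = sum(len(s.indels) for s in sets)
    for s in sets:
        if mode == "disease":
            if len(s.indels) <= 1:
                out.append(s)
                continue
            keep = int(rng.integers(len(s.indels)))
            for i, ind in enumerate(s.indels):
                if i != keep:
                    removed.append((_ind_id(ind), "one-per-gene"))
            out.append(GeneIndelSet(s.gene_id, [s.indels[keep]], s.species,
                                    s.quality_scores))
        else:
            n_fs = sum(1 for ind in s.indels if ind.is_frameshifting())
            if n_fs > 1:
                for ind in s.indels:
                    removed.append((_ind_id(ind), "pseudogene"))
            else:
                out.append(s)
    n_out = sum(len(s.indels) for s in out)
    return out, FilterReport(n_in=n_in, n_out=n_out, removed=removed)


def quality_window_filter(
    s: GeneIndelSet, window: int = 10, min_q: int = 9
) -> tuple[GeneIndelSet, FilterReport]:
    """Keep an indel only when every base of the surrounding window (default
    10 bp total, i.e. 5 each side) has quality >= min_q.  The window values
    are taken from ``s.quality_scores[indel_id]``; an indel without quality
    data is removed."""
    kept: list[Indel] = []
    removed: list[tuple[str, str]] = []
    for ind in s.indels:
        key = _ind_id(ind)
        quals = s.quality_scores.get(key)
        if quals is None and ind.id is not None:
            quals = s.quality_scores.get(ind.id)
        if quals is None or len(quals) == 0:
            removed.append((key, "no-quality-data"))
            continue
        qs = list(quals)[:window]
        if all(q >= min_q for q in qs):
            kept.append(ind)
        else:
            removed.append((key, f"quality<{min_q}-in-window"))
    out = GeneIndelSet(s.gene_id, kept, s.species, s.quality_scores)
    return out, FilterReport(len(s.indels), len(kept), removed)


def neighbor_distance_filter(
    indels: Sequence[Indel], min_gap: int
) -> tuple[list[Indel], FilterReport]:
    """Remove every indel whose nearest neighbor on the same chromosome is
    closer than ``min_gap`` bp (edge-to-edge); removal takes both members of
    a close pair."""
    order = sorted(range(len(indels)), key=lambda i: (indels[i].chrom, indels[i].start))
    drop = set()
    for k, a in enumerate(order):
        ia = indels[a]
        for b in order[k + 1:]:
            ib = indels[b]
            if ib.chrom != ia.chrom or ib.start - ia.end >= min_gap:
                # sorted by start, but a long deletion span can still reach a
                # later indel, so only stop once starts are out of range
                if ib.chrom != ia.chrom or ib.start - ia.start >= min_gap + (ia.end - ia.start):
                    break
                continue
            drop.add(a)
            drop.add(b)
    kept = [ind for i, ind in enumerate(indels) if i not in drop]
    removed = [(_ind_id(indels[i]), f"neighbor<{min_gap}bp") for i in sorted(drop)]
    return kept, FilterReport(len(indels), len(kept), removed)


def multispecies_concordance_filter(
    calls: Mapping[str, Sequence[Indel]],
    lineages: Mapping[str, str],
) -> list[Indel]:
    """Keep indels identically observed (same position and alleles after
    trimming) in at least two species of the same lineage.  Returns one
    representative per surviving call."""
    for species in calls:
        if species not in lineages:
            raise ValueError(f"unknown species {species!r}: no lineage assigned")
    by_key: dict[tuple, dict[str, Indel]] = {}
    for species, indels in calls.items():
        for ind in indels:
            by_key.setdefault(ind.allele_key(), {})[species] = ind
    survivors: list[Indel] = []
    for key in sorted(by_key):
        species_map = by_key[key]
        lineage_counts: dict[str, int] = {}
        for species in species_map:
            lin = lineages[species]
            lineage_counts[lin] = lineage_counts.get(lin, 0) + 1
        if any(c >= 2 for c in lineage_counts.values()):
            first_species = sorted(species_map)[0]
            survivors.append(species_map[first_species])
    return survivors


def write_filter_report(report: FilterReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("indel_id\treason\n")
        for indel_id, reason in report.removed:
            fh.write(f"{indel_id}\t{reason}\n")
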