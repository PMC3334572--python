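"""Synthetic-data generators for every fixture the other modules consume.

Three generators:

* :func:`generate_labeled_features` — feature vectors with rule-structured
  class boundaries planted at the published thresholds.  Values are drawn
  uniformly from each rule's region, excluding a margin band around every
  threshold so that planted boundaries stay identifiable; labels follow the
  rules (the uncovered gaps are gene-damaging and flagged), then flip with
  probability ``noise_rate``.
* :func:`generate_selection_dataset` — 4 informative + n noise features
  where the damaging class satisfies all four threshold conditions and each
  neutral row violates exactly one, so every informative feature is
  necessary for separation (used by feature-selection tests).
* :func:`generate_toy_gene` / :func:`generate_indel_clusters` — toy
  transcripts with conservation tracks, and clustered frameshifting indel
  sets with a controlled frame-restoration probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    LABEL_DAMAGING,
    LABEL_NEUTRAL,
    ConservationTrack,
    Indel,
    ProteinConservationTrack,
    TranscriptModel,
    write_dna_conservation_wig,
    write_protein_conservation,
    write_transcripts_gtf,
)
from .training import LabeledDataset

PUBLISHED_THRESHOLDS = {
    "f14_low": 1.2,
    "f14_mid": 4.3,
    "f14_high": 6.2,
    "f5_low": 8.7,
    "f5_high": 85.5,
    "f18": 0.9,
    "f15": 6.0,
}

# published per-rule training coverage, used as default sampling weights
PUBLISHED_RULE_COUNTS = {"R1": 687, "R2": 129, "R3": 102, "R4": 1193}

_DOMAINS = {"f14": (0.0, 100.0), "f5": (0.0, 100.0), "f18": (0.0, 100.0),
            "f15": (0.0, 60.0)}
_FEATURE_THRESHOLDS = {
    "f14": ("f14_low", "f14_mid", "f14_high"),
    "f5": ("f5_low", "f5_high"),
    "f18": ("f18",),
    "f15": ("f15",),
}


@dataclass
class GeneratorConfig:
    n_per_class: int = 1000
    noise_rate: float = 0.0
    thresholds: dict = field(default_factory=lambda: dict(PUBLISHED_THRESHOLDS))
    margin_rel: float = 0.2  # band half-width = margin_rel * distance to domain edge
    n_noise_features: int = 0
    rule_weights: dict = field(default_factory=lambda: dict(PUBLISHED_RULE_COUNTS))
    fallback_weight: float = 0.0  # share of the damaging class from uncovered gaps
    compensation_p: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.margin_rel <= 0:
            raise ValueError("margin_rel must be > 0")
        if not (0 <= self.fallback_weight <= 1):
            raise ValueError("fallback_weight must be in [0,1]")

    def margin(self, name: str) -> float:
        """Half-width of the excluded band around threshold ``name``."""
        thr = self.thresholds[name]
        feature = next(f for f, keys in _FEATURE_THRESHOLDS.items() if name in keys)
        lo, hi = _DOMAINS[feature]
        return self.margin_rel * min(thr - lo, hi - thr)

    def band(self, name: str) -> tuple[float, float]:
        thr, m = self.thresholds[name], self.margin(name)
        return (thr - m, thr + m)

    def bands_for(self, feature: str) -> list[tuple[float, float]]:
        return [self.band(k) for k in _FEATURE_THRESHOLDS[feature]]


def _allowed_segments(lo: float, hi: float,
                      bands: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    segs = [(lo, hi)]
    for blo, bhi in bands:
        nxt = []
        for a, b in segs:
            if bhi <= a or blo >= b:
                nxt.append((a, b))
            else:
                if a < blo:
                    nxt.append((a, blo))
                if bhi < b:
                    nxt.append((bhi, b))
        segs = nxt
    return [(a, b) for a, b in segs if b > a]


def _sample_outside(rng: np.random.Generator, n: int, lo: float, hi: float,
                    bands: Sequence[tuple[float, float]],
                    resolution: float = 0.1) -> np.ndarray:
    """Uniform draw from the grid of multiples of ``resolution`` inside
    [lo, hi] and outside every band.

    The features are ratio- or count-valued in reality, so the generator
    emits them on a grid; this also guarantees ties at the support edges,
    keeping planted thresholds identifiable under label noise (a single
    flipped row at a support edge cannot be isolated by a split).
    """
    segs = _allowed_segments(lo, hi, bands)
    if not segs:
        raise ValueError(f"no admissible values in [{lo},{hi}] outside margin bands")
    values = np.concatenate([
        np.arange(int(np.ceil(round(a / resolution, 9))),
                  int(np.floor(round(b / resolution, 9))) + 1)
        for a, b in segs
    ]) * resolution
    values = values[(values >= lo) & (values <= hi)]
    # keep strictly clear of band edges (grid points may coincide with them)
    for blo, bhi in bands:
        values = values[(values <= blo + 1e-9) | (values >= bhi - 1e-9)]
    if len(values) == 0:
        raise ValueError("no admissible grid values")
    return rng.choice(values, size=n).astype(float)


def _rule_region_sampler(cfg: GeneratorConfig, rng: np.random.Generator):
    """Returns sample(rule_id, n) -> (n,4) array of (f14, f5, f18, f15)."""
    t = cfg.thresholds

    def feat(name: str, n: int, lo: float = None, hi: float = None) -> np.ndarray:
        dlo, dhi = _DOMAINS[name]
        res = 1.0 if name == "f15" else 0.1
        return _sample_outside(rng, n, dlo if lo is None else lo,
                               dhi if hi is None else hi,
                               cfg.bands_for(name), resolution=res)

    def sample(rule_id: str, n: int) -> np.ndarray:
        if rule_id == "R1":
            f14 = feat("f14", n, hi=t["f14_low"])
            f5 = feat("f5", n)
            f18 = feat("f18", n)
            f15 = feat("f15", n)
        elif rule_id == "R2":
            f14 = feat("f14", n, lo=t["f14_low"], hi=t["f14_mid"])
            f5 = feat("f5", n, hi=t["f5_high"])
            f18 = feat("f18", n)
            f15 = feat("f15", n)
        elif rule_id == "R3":
            f14 = feat("f14", n, lo=t["f14_low"], hi=t["f14_mid"])
            f5 = feat("f5", n, lo=t["f5_high"])
            f18 = feat("f18", n, hi=t["f18"])
            f15 = feat("f15", n)
        elif rule_id == "R4":
            f14 = feat("f14", n, lo=t["f14_high"])
            f5 = feat("f5", n, lo=t["f5_low"])
            f18 = feat("f18", n, lo=t["f18"])
            f15 = feat("f15", n, lo=t["f15"])
        elif rule_id == "gapA":
            # uncovered: low conserved-DNA fraction but C-terminal location
            # with conserved residues lost
            f14 = feat("f14", n, lo=t["f14_low"], hi=t["f14_mid"])
            f5 = feat("f5", n, lo=t["f5_high"])
            f18 = feat("f18", n, lo=t["f18"])
            f15 = feat("f15", n)
        elif rule_id == "gapC":
            # uncovered: f14 above 6.2 but one R4 condition violated
            f14 = feat("f14", n, lo=t["f14_high"])
            f5 = feat("f5", n, lo=t["f5_low"])
            f18 = feat("f18", n, lo=t["f18"])
            f15 = feat("f15", n, lo=t["f15"])
            which = rng.integers(3, size=n)
            f5[which == 0] = feat("f5", int((which == 0).sum()), hi=t["f5_low"])
            f18[which == 1] = feat("f18", int((which == 1).sum()), hi=t["f18"])
            f15[which == 2] = feat("f15", int((which == 2).sum()), hi=t["f15"])
        else:
            raise ValueError(f"unknown region {rule_id!r}")
        return np.column_stack([f14, f5, f18, f15])

    return sample


def generate_labeled_features(cfg: GeneratorConfig) -> LabeledDataset:
    """Labeled feature vectors with the published rule structure planted.

    Neutral rows are drawn from the R1/R2/R3 regions (weights
    ``cfg.rule_weights``); gene-damaging rows from R4 and, with share
    ``cfg.fallback_weight``, from the uncovered gap regions (flagged via
    ``meta.fallback``).  Labels flip with probability ``noise_rate``
    (``meta.flipped``); ``n_noise_features`` independent uniform features
    are appended.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    sampler = _rule_region_sampler(cfg, rng)
    n = cfg.n_per_class

    w = cfg.rule_weights
    neutral_w = np.array([w["R1"], w["R2"], w["R3"]], dtype=float)
    counts = rng.multinomial(n, neutral_w / neutral_w.sum())
    neutral_parts, neutral_rules = [], []
    for rule_id, cnt in zip(("R1", "R2", "R3"), counts):
        if cnt:
            neutral_parts.append(sampler(rule_id, int(cnt)))
            neutral_rules += [rule_id] * int(cnt)

    n_fallback = int(round(cfg.fallback_weight * n))
    n_r4 = n - n_fallback
    damaging_parts, damaging_rules = [], []
    if n_r4:
        damaging_parts.append(sampler("R4", n_r4))
        damaging_rules += ["R4"] * n_r4
    if n_fallback:
        n_gap_a = int(rng.binomial(n_fallback, 0.5))
        for gap_id, cnt in (("gapA", n_gap_a), ("gapC", n_fallback - n_gap_a)):
            if cnt:
                damaging_parts.append(sampler(gap_id, cnt))
                damaging_rules += [gap_id] * cnt

    X = np.vstack(neutral_parts + damaging_parts)
    y = np.array([LABEL_NEUTRAL] * n + [LABEL_DAMAGING] * n, dtype=object)
    rule_ids = np.array(neutral_rules + damaging_rules, dtype=object)

    flipped = rng.uniform(size=2 * n) < cfg.noise_rate
    y = np.where(flipped,
                 np.where(y == LABEL_NEUTRAL, LABEL_DAMAGING, LABEL_NEUTRAL),
                 y).astype(object)

    names = ["f14", "f5", "f18", "f15"]
    if cfg.n_noise_features:
        noise = rng.uniform(0, 100, size=(2 * n, cfg.n_noise_features))
        X = np.hstack([X, noise])
        names += [f"noise_{i + 1}" for i in range(cfg.n_noise_features)]

    order = rng.permutation(2 * n)
    meta = pd.DataFrame({
        "rule_id": rule_ids[order],
        "fallback": np.isin(rule_ids, ("gapA", "gapC"))[order],
        "flipped": flipped[order],
    })
    return LabeledDataset(X[order], y[order], names,
                          provenance=f"generate_labeled_features(seed={cfg.seed})",
                          meta=meta)


def generate_selection_dataset(
    n_per_class: int,
    n_noise_features: int = 16,
    seed: int = 0,
    margin_rel: float = 0.2,
) -> LabeledDataset:
    """Conjunction-structured data where all four informative features are
    necessary: damaging rows satisfy every R4 condition, each neutral row
    violates exactly one (chosen uniformly).  A tree restricted to any
    proper feature subset misclassifies the neutral rows violating the
    held-out condition, so greedy selection must pick all four before noise
    features add anything."""
    cfg = GeneratorConfig(margin_rel=margin_rel, seed=seed)
    rng = np.random.default_rng(seed)
    t = cfg.thresholds

    def feat(name, n, lo=None, hi=None):
        dlo, dhi = _DOMAINS[name]
        res = 1.0 if name == "f15" else 0.1
        return _sample_outside(rng, n, dlo if lo is None else lo,
                               dhi if hi is None else hi,
                               cfg.bands_for(name), resolution=res)

    def satisfying(n):
        return [feat("f14", n, lo=t["f14_high"]),
                feat("f5", n, lo=t["f5_low"]),
                feat("f18", n, lo=t["f18"]),
                feat("f15", n, lo=t["f15"])]

    damaging = np.column_stack(satisfying(n_per_class))
    cols = satisfying(n_per_class)
    violate = rng.integers(4, size=n_per_class)
    lows = [("f14", t["f14_high"]), ("f5", t["f5_low"]), ("f18", t["f18"]),
            ("f15", t["f15"])]
    for j, (name, thr) in enumerate(lows):
        mask = violate == j
        cnt = int(mask.sum())
        if cnt:
            cols[j][mask] = feat(name, cnt, hi=thr)
    neutral = np.column_stack(cols)

    X = np.vstack([damaging, neutral])
    y = np.array([LABEL_DAMAGING] * n_per_class + [LABEL_NEUTRAL] * n_per_class,
                 dtype=object)
    names = ["f14", "f5", "f18", "f15"]
    if n_noise_features:
        X = np.hstack([X, rng.uniform(0, 100, size=(len(X), n_noise_features))])
        names += [f"noise_{i + 1}" for i in range(n_noise_features)]
    order = rng.permutation(len(X))
    return LabeledDataset(X[order], y[order], names,
                          provenance=f"generate_selection_dataset(seed={seed})")


# ---------------------------------------------------------------------------
# toy genes
# ---------------------------------------------------------------------------

@dataclass
class ToyGene:
    transcripts: list[TranscriptModel]
    genome: dict[str, str]
    dna_track: ConservationTrack
    protein_track: ProteinConservationTrack
    conserved_dna: set[int]
    conserved_residues: dict[str, set[int]]

    @property
    def transcript(self) -> TranscriptModel:
        return self.transcripts[0]

    def write(self, out_dir: str | Path, stem: str = "toygene") -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "gtf": out / f"{stem}.gtf",
            "fasta": out / f"{stem}.fa",
            "wig": out / f"{stem}.wig",
            "protein_tsv": out / f"{stem}.protein_scores.tsv",
        }
        write_transcripts_gtf(self.transcripts, paths["gtf"])
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        write_dna_conservation_wig(self.dna_track, paths["wig"])
        write_protein_conservation(self.protein_track, paths["protein_tsv"])
        return paths


def generate_toy_gene(
    n_exons: int,
    cds_length: int,
    conserved_fraction: float,
    seed: int = 0,
    strand: str = "+",
    chrom: str = "chrT",
    gene_id: str = "toy_gene",
    transcript_id: str = "toy_tx",
    dna_threshold: float = 1.5,
    protein_threshold: float = 1.5,
    conserved_aa_fraction: Optional[float] = None,
) -> ToyGene:
    """One valid transcript with exactly round(fraction * cds_length)
    conserved coding bases; every coding base gets a score (no missing
    data), conserved bases score above the threshold."""
    if cds_length % 3 != 0:
        raise ValueError("cds_length must be a multiple of 3")
    if cds_length < 3 * n_exons:
        raise ValueError("cds_length too short for the requested exon count")
    rng = np.random.default_rng(seed)

    # split the CDS over exons (each at least 3 bp)
    cuts = np.sort(rng.choice(np.arange(1, cds_length // 3), size=n_exons - 1,
                              replace=False)) * 3 if n_exons > 1 else np.array([], int)
    sizes = np.diff(np.concatenate([[0], cuts, [cds_length]]))
    pos = int(rng.integers(100, 200))
    exons = []
    for size in sizes:
        exons.append((pos, pos + int(size)))
        pos += int(size) + int(rng.integers(30, 120))  # intron

    t = TranscriptModel(
        transcript_id=transcript_id, gene_id=gene_id, chrom=chrom, strand=strand,
        exons=exons, cds_start=exons[0][0], cds_end=exons[-1][1],
    )
    assert t.is_valid and t.coding_length == cds_length

    seq_len = exons[-1][1] + 200
    genome = {chrom: "".join(rng.choice(list("ACGT"), size=seq_len))}

    coding = [int(p) for p in t.coding_positions()]
    n_conserved = int(round(conserved_fraction * cds_length))
    conserved_dna = set(rng.choice(coding, size=n_conserved, replace=False).tolist())
    dna_track = ConservationTrack(conservation_threshold=dna_threshold)
    for p in coding:
        dna_track.set_score(chrom, p, dna_threshold + 1.0 if p in conserved_dna
                            else dna_threshold - 1.5)

    n_res = cds_length // 3
    frac_aa = conserved_fraction if conserved_aa_fraction is None else conserved_aa_fraction
    n_cons_res = int(round(frac_aa * n_res))
    cons_res = set(rng.choice(n_res, size=n_cons_res, replace=False).tolist())
    protein_track = ProteinConservationTrack(threshold=protein_threshold)
    protein_track.set_scores(
        transcript_id,
        [protein_threshold + 1.0 if i in cons_res else protein_threshold - 1.0
         for i in range(n_res)],
    )
    return ToyGene(
        transcripts=[t], genome=genome, dna_track=dna_track,
        protein_track=protein_track, conserved_dna=conserved_dna,
        conserved_residues={transcript_id: cons_res},
    )


# ---------------------------------------------------------------------------
# clustered indel sets
# ---------------------------------------------------------------------------

_COMPENSATING_PAIRS = [(-1, -2), (-2, -1), (1, 2), (2, 1),
                       (-1, 1), (1, -1), (-2, 2), (2, -2)]
_NON_COMPENSATING_PAIRS = [(-1, -1), (1, 1), (-2, -2), (2, 2),
                           (-1, 2), (2, -1), (1, -2), (-2, 1)]


def generate_indel_clusters(
    n_regions: int,
    compensation_p: float,
    window: int,
    indels_per_region: int = 2,
    min_gap: int = 5,
    seed: int = 0,
) -> dict[str, list[Indel]]:
    """Frameshifting indel pairs placed within ``window`` bp of each other;
    with probability ``compensation_p`` a pair's net size is divisible by 3.
    Regions hold ``indels_per_region`` indels (pairs; must be even), pairs
    separated by well over the window so they never chain together."""
    if not (0 <= compensation_p <= 1):
        raise ValueError("compensation_p must be in [0,1]")
    if indels_per_region % 2 != 0:
        raise ValueError("indels_per_region must be even (pairs)")
    if min_gap > window:
        raise ValueError("min_gap must be <= window")
    rng = np.random.default_rng(seed)
    out: dict[str, list[Indel]] = {}
    for r in range(n_regions):
        region_id = f"region_{r:05d}"
        indels: list[Indel] = []
        cursor = 100
        for _ in range(indels_per_region // 2):
            start = cursor + int(rng.integers(0, 50))
            gap = int(rng.integers(min_gap, window + 1))
            if rng.uniform() < compensation_p:
                s1, s2 = _COMPENSATING_PAIRS[rng.integers(len(_COMPENSATING_PAIRS))]
            else:
                s1, s2 = _NON_COMPENSATING_PAIRS[rng.integers(len(_NON_COMPENSATING_PAIRS))]
            for offset, size in ((0, s1), (gap, s2)):
                p = start + offset
                if size < 0:
                    ref, alt = "A" + "C" * (-size), "A"
                else:
                    ref, alt = "A", "A" + "C" * size
                indels.append(Indel(chrom=region_id, pos=p - 1, ref_allele=ref,
                                    alt_allele=alt,
                                    id=f"{region_id}_i{len(indels)}"))
            cursor = start + gap + 3 * window + 10
        out[region_id] = indels
    return out
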