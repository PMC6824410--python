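"""Runs of homozygosity, per-SNP incidence, and ROH islands.

A run of homozygosity (ROH) is called per animal under strict rules: no
missing and no heterozygous genotype inside, at least ``min_snps`` SNPs,
span at least ``min_length_bp``, no gap between consecutive SNPs above
``max_gap_bp``, and SNP density of at least one SNP per ``density_bp``.
Because no heterozygote/missing allowance is granted, ROH are found by exact
maximal-run enumeration (no scanning-window heuristic is needed).

Per-SNP incidence is the fraction of animals whose ROH cover the SNP;
islands are maximal runs of map-consecutive SNPs whose incidence reaches the
breed's nearest-rank 99.9th-percentile threshold (single-SNP islands are
legal).  Islands are intersected across breeds to find shared autozygosity
hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset, SnpMap
from .local_ancestry import nearest_rank_quantile

__all__ = [
    "RohSegment",
    "IslandTrack",
    "detect_roh",
    "snp_roh_incidence",
    "call_islands",
    "cross_breed_island_overlaps",
]

MIN_SNPS = 25
MIN_LENGTH_BP = 500_000
MAX_GAP_BP = 250_000
DENSITY_BP = 100_000


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run in one animal; closed 1-based coordinates."""

    sample_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def covers(self, chromosome: int, position_bp: int) -> bool:
        return (chromosome == self.chromosome
                and self.start_bp <= position_bp <= self.end_bp)


@dataclass
class IslandTrack:
    """Per-breed ROH incidence with percentile threshold and island intervals.

    ``islands`` rows: (chromosome, start_bp, end_bp, n_snps).
    """

    breed: str
    snp_map: SnpMap
    incidence: np.ndarray
    threshold: float
    islands: list[tuple[int, int, int, int]]

    def islands_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.islands,
                            columns=["chromosome", "start_bp", "end_bp", "n_snps"])


def detect_roh(dataset: GenotypeDataset, min_snps: int = MIN_SNPS,
               min_length_bp: int = MIN_LENGTH_BP, max_gap_bp: int = MAX_GAP_BP,
               density_bp: int = DENSITY_BP) -> list[RohSegment]:
    """Enumerate every qualifying ROH of every sample.

    Per sample and chromosome, maximal runs of consecutive non-missing
    homozygous SNPs are found, split wherever the inter-SNP gap exceeds
    ``max_gap_bp``, and kept iff they hold >= ``min_snps`` SNPs, span
    >= ``min_length_bp``, and satisfy n_snps / length >= 1 / ``density_bp``.
    Segment coordinates are the first and last member SNP positions.
    """
    segments: list[RohSegment] = []
    sm = dataset.snp_map
    for c in np.unique(sm.chromosome):
        idx = np.flatnonzero(sm.chromosome == c)
        pos = sm.position_bp[idx]
        gap_break = np.diff(pos) > max_gap_bp
        d = dataset.dosages[:, idx]
        hom = (d == 0) | (d == 2)            # excludes het and missing
        for i in range(dataset.n_samples):
            h = hom[i]
            j = 0
            Lc = len(idx)
            while j < Lc:
                if not h[j]:
                    j += 1
                    continue
                k = j
                while k + 1 < Lc and h[k + 1] and not gap_break[k]:
                    k += 1
                n = k - j + 1
                length = int(pos[k] - pos[j])
                if (n >= min_snps and length >= min_length_bp
                        and n * density_bp >= length):
                    segments.append(RohSegment(str(dataset.sample_id[i]),
                                               int(c), int(pos[j]),
                                               int(pos[k]), n))
                j = k + 1
    return segments


def snp_roh_incidence(segments: list[RohSegment], snp_map: SnpMap,
                      n_animals: int, sample_ids=None) -> np.ndarray:
    """Fraction of animals whose ROH cover each SNP.

    A SNP covered by several segments of the same animal counts once.  When
    ``sample_ids`` is given, segments referencing unknown samples raise.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    known = set(sample_ids) if sample_ids is not None else None
    per_sample: dict[str, np.ndarray] = {}
    for seg in segments:
        if known is not None and seg.sample_id not in known:
            raise KeyError(f"segment references unknown sample {seg.sample_id!r}")
        cov = per_sample.setdefault(seg.sample_id,
                                    np.zeros(snp_map.n_snps, dtype=bool))
        cov |= ((snp_map.chromosome == seg.chromosome)
                & (snp_map.position_bp >= seg.start_bp)
                & (snp_map.position_bp <= seg.end_bp))
    counts = np.zeros(snp_map.n_snps, dtype=np.int64)
    for cov in per_sample.values():
        counts += cov
    return counts / n_animals


def call_islands(incidence: np.ndarray, snp_map: SnpMap, breed: str = "",
                 percentile: float = 0.999) -> IslandTrack:
    """Call ROH islands at the breed's incidence-percentile threshold.

    The threshold is the nearest-rank ``percentile`` quantile of the per-SNP
    incidence distribution (zeros included; ties at the threshold kept).  A
    SNP that appears in no ROH at all is never flagged, even when sparse
    incidence drives the percentile threshold to zero.  Islands are maximal
    runs of map-consecutive flagged SNPs on one chromosome; single-SNP
    islands are permitted.
    """
    incidence = np.asarray(incidence, dtype=float)
    if incidence.size == 0:
        raise ValueError("empty incidence vector")
    if np.ptp(incidence) == 0:
        import warnings
        warnings.warn(f"degenerate (constant) incidence for breed {breed!r}",
                      stacklevel=2)
    thr = nearest_rank_quantile(incidence, percentile)
    flagged = (incidence >= thr) & (incidence > 0)
    islands: list[tuple[int, int, int, int]] = []
    for c in np.unique(snp_map.chromosome):
        on_c = snp_map.chromosome == c
        idx = np.flatnonzero(on_c)
        f = flagged[idx]
        j = 0
        while j < len(idx):
            if not f[j]:
                j += 1
                continue
            k = j
            while k + 1 < len(idx) and f[k + 1]:
                k += 1
            islands.append((int(c), int(snp_map.position_bp[idx[j]]),
                            int(snp_map.position_bp[idx[k]]), k - j + 1))
            j = k + 1
    return IslandTrack(breed, snp_map, incidence, float(thr), islands)


def long_island_fraction(track: IslandTrack,
                         min_length_bp: int = 5_000_000) -> float:
    """Fraction of a breed's islands longer than ``min_length_bp`` (end - start)."""
    if not track.islands:
        raise ValueError(f"no islands in track for breed {track.breed!r}")
    long = sum(1 for _, s, e, _n in track.islands if e - s > min_length_bp)
    return long / len(track.islands)


def cross_breed_island_overlaps(island_tracks: list[IslandTrack],
                                ) -> list[tuple[tuple[str, str], int, tuple[int, int]]]:
    """Intersect islands across every unordered breed pair.

    Each pair of islands from two different breeds sharing >= 1 bp on the
    same chromosome yields ((breed1, breed2), chromosome,
    (max(starts), min(ends))) -- the closed-interval intersection.
    """
    if len(island_tracks) < 2:
        raise ValueError("need at least two island tracks")
    records = []
    for x in range(len(island_tracks)):
        for y in range(x + 1, len(island_tracks)):
            ta, tb = island_tracks[x], island_tracks[y]
            for ca, sa, ea, _ in ta.islands:
                for cb, sb, eb, _ in tb.islands:
                    if ca == cb and sa <= eb and sb <= ea:
                        records.append(((ta.breed, tb.breed), ca,
                                        (max(sa, sb), min(ea, eb))))
    return records
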