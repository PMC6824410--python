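"""Synthetic SNP cohorts with ground truth for every pipeline stage.

The generators emulate the statistical structure each scan assumes:

* two ancestral breed panels whose allele frequencies drifted apart under the
  Balding-Nichols model with differentiation parameter F;
* an admixed cohort formed g generations ago with global Merino proportion
  alpha, whose haplotypes are ancestry mosaics broken by a Poisson
  recombination process of rate g*r per bp, optionally with loci carrying a
  planted excess delta of Merino ancestry;
* pairs of differentiated populations with planted high-F_ST outlier loci;
* cohorts whose individuals carry planted autozygous (fully homozygous)
  tracts against a heterozygous background.

All generators are deterministic given their seed, and every planted feature
is returned as an explicit truth object so recovery tests can score calls
against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import AlleleFrequencyPanel, GenotypeDataset, SnpMap

__all__ = [
    "AncestralPanelSpec",
    "AdmixtureTruth",
    "OutlierTruth",
    "RohTruth",
    "simulate_ancestral_panels",
    "simulate_admixed_cohort",
    "simulate_differentiated_pair",
    "simulate_roh_cohort",
]


@dataclass(frozen=True)
class AncestralPanelSpec:
    """Layout and drift parameters of the two ancestral proxy panels.

    ``fst`` is the Balding-Nichols differentiation F of each derived panel
    from their common ancestor; ancestral frequencies are drawn uniformly
    from ``p_range`` (default avoids near-monomorphic SNPs).
    """

    n_snps_per_chrom: int = 1000
    n_chromosomes: int = 1
    spacing_bp: int = 50_000
    fst: float = 0.1
    p_range: tuple[float, float] = (0.05, 0.95)

    def __post_init__(self):
        if not 0.0 < self.fst < 1.0:
            raise ValueError("differentiation F must lie in (0, 1)")
        if self.spacing_bp <= 0:
            raise ValueError("spacing_bp must be positive")

    @property
    def n_snps(self) -> int:
        return self.n_snps_per_chrom * self.n_chromosomes

    @property
    def chrom_length_bp(self) -> int:
        return self.spacing_bp * self.n_snps_per_chrom


@dataclass
class AdmixtureTruth:
    """Per-individual truth of an admixed cohort.

    ``mosaics[i]`` holds the two haplotype mosaics of sample i, each a list of
    (chromosome, start_bp, end_bp, ancestry) blocks tiling every chromosome,
    ancestry in {"A", "B"}.  ``merino_dosage`` is the true per-SNP count of
    A-ancestry allele copies.
    """

    alpha_true: np.ndarray                       # (n,)
    mosaics: list[list[list[tuple[int, int, int, str]]]]
    merino_dosage: np.ndarray                    # (n, L) ints 0/1/2
    excess_loci: np.ndarray = field(default_factory=lambda: np.array([], int))
    delta: float = 0.0

    @property
    def mean_merino_fraction(self) -> float:
        return float(self.merino_dosage.mean() / 2.0)


@dataclass
class OutlierTruth:
    """Planted high-differentiation loci of a two-population cohort."""

    outlier_indices: np.ndarray
    neutral_fst: float
    outlier_fst: float

    def __post_init__(self):
        self.outlier_indices = np.asarray(self.outlier_indices, dtype=int)
        if self.outlier_indices.size and not self.outlier_fst > self.neutral_fst:
            raise ValueError("outlier F must exceed neutral F")


@dataclass
class RohTruth:
    """Planted autozygous tracts per sample: lists of (chrom, start, end)."""

    tracts: dict[str, list[tuple[int, int, int]]]


def _uniform_map(spec: AncestralPanelSpec) -> SnpMap:
    ids, chroms, poss = [], [], []
    for c in range(1, spec.n_chromosomes + 1):
        for k in range(spec.n_snps_per_chrom):
            ids.append(f"sim{c}_{k + 1}")
            chroms.append(c)
            poss.append((k + 1) * spec.spacing_bp)
    return SnpMap(np.array(ids, dtype=object), np.array(chroms), np.array(poss))


def simulate_ancestral_panels(spec: AncestralPanelSpec, seed: int,
                              ) -> tuple[AlleleFrequencyPanel, SnpMap]:
    """Draw drift-differentiated allele frequencies for the two proxies.

    Per SNP an ancestral frequency p ~ Uniform(p_range) is drawn, then each
    panel's frequency independently from Beta(p(1-F)/F, (1-p)(1-F)/F) -- the
    Balding-Nichols model, under which the expected Weir-Cockerham F_ST
    between large samples from the two panels is close to F.
    """
    rng = np.random.default_rng(seed)
    snp_map = _uniform_map(spec)
    p = rng.uniform(*spec.p_range, size=spec.n_snps)
    scale = (1.0 - spec.fst) / spec.fst
    freq_a = rng.beta(p * scale, (1 - p) * scale)
    freq_b = rng.beta(p * scale, (1 - p) * scale)
    return AlleleFrequencyPanel(snp_map, freq_a, freq_b), snp_map


def _chrom_bounds(snp_map: SnpMap) -> dict[int, tuple[int, int]]:
    out = {}
    for c in np.unique(snp_map.chromosome):
        pos = snp_map.position_bp[snp_map.chromosome == c]
        out[int(c)] = (1, int(pos.max()))
    return out


def simulate_admixed_cohort(panels: AlleleFrequencyPanel, n: int, alpha: float,
                            g: float = 7.0, r: float = 1e-8,
                            excess_loci=None, delta: float = 0.0,
                            seed: int = 0) -> tuple[GenotypeDataset, AdmixtureTruth]:
    """Simulate an admixed cohort of ``n`` diploids with known ancestry.

    Each haplotype is an ancestry mosaic: breakpoints fall as a Poisson
    process of rate g*r per bp, and each block's ancestry is A with
    probability alpha.  At planted ``excess_loci`` (SNP indices) the marginal
    probability of A is raised to alpha + delta by re-drawing the ancestry of
    the covering block with the boosted probability.  Alleles are drawn from
    the block panel's frequency; only unphased genotypes are exposed.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if delta < 0 or alpha + delta > 1.0:
        raise ValueError("need delta >= 0 and alpha + delta <= 1")
    excess = np.asarray(excess_loci if excess_loci is not None else [], dtype=int)
    rng = np.random.default_rng(seed)
    snp_map = panels.snp_map
    L = snp_map.n_snps
    chroms = np.unique(snp_map.chromosome)
    bounds = _chrom_bounds(snp_map)
    rate = g * r
    excess_set = set(excess.tolist())

    hap_dosage = np.zeros((n, L), dtype=np.int8)       # A-ancestry copies
    geno = np.zeros((n, L), dtype=float)
    mosaics: list[list[list[tuple[int, int, int, str]]]] = []
    for i in range(n):
        sample_mosaics = []
        for _hap in range(2):
            hap_blocks: list[tuple[int, int, int, str]] = []
            hap_anc = np.empty(L, dtype=bool)           # True = ancestry A
            for c in chroms:
                cmask = snp_map.chromosome == c
                pos = snp_map.position_bp[cmask]
                idx = np.flatnonzero(cmask)
                lo, hi = bounds[int(c)]
                length = hi - lo + 1
                n_bp = rng.poisson(rate * length)
                cuts = np.sort(rng.integers(lo + 1, hi + 1, size=n_bp)) if n_bp else \
                    np.array([], dtype=int)
                starts = np.concatenate(([lo], cuts))
                ends = np.concatenate((cuts - 1, [hi]))
                for s, e in zip(starts, ends):
                    if s > e:
                        continue
                    in_blk = (pos >= s) & (pos <= e)
                    blk_idx = idx[in_blk]
                    p_a = alpha
                    if delta > 0 and any(int(j) in excess_set for j in blk_idx):
                        p_a = alpha + delta
                    anc_a = rng.random() < p_a
                    hap_blocks.append((int(c), int(s), int(e), "A" if anc_a else "B"))
                    hap_anc[blk_idx] = anc_a
            pf = np.where(hap_anc, panels.freq_a, panels.freq_b)
            allele = rng.random(L) < pf
            geno[i] += allele
            hap_dosage[i] += hap_anc
            sample_mosaics.append(hap_blocks)
        mosaics.append(sample_mosaics)

    alpha_true = hap_dosage.mean(axis=1) / 2.0
    ds = GenotypeDataset(
        np.array([f"adm{i + 1}" for i in range(n)], dtype=object),
        np.array(["Admixed"] * n, dtype=object), snp_map, geno)
    truth = AdmixtureTruth(alpha_true, mosaics, hap_dosage.astype(np.int16),
                           excess, delta)
    return ds, truth


def simulate_differentiated_pair(panels_spec: AncestralPanelSpec, n_per_pop: int,
                                 outlier_indices=None, outlier_fst: float = 0.5,
                                 seed: int = 0,
                                 ) -> tuple[GenotypeDataset, OutlierTruth]:
    """Two drift-differentiated breeds with planted high-F_ST outlier loci.

    Neutral loci drift with the spec's F.  At each outlier locus the two
    population frequencies are set divergently, displaced symmetrically
    about an ancestral frequency p by +-sqrt(outlier_fst * p * (1 - p))
    (random sign), so the parametric two-population differentiation
    Var(p_j) / (p (1 - p)) equals ``outlier_fst`` exactly -- mimicking
    divergent selection pushing the breeds toward opposite alleles.  (An
    independent Balding-Nichols redraw at high F would leave many planted
    loci undifferentiated by chance, making them useless as ground truth.)
    """
    out_idx = np.asarray(outlier_indices if outlier_indices is not None else [],
                         dtype=int)
    if out_idx.size and (out_idx.min() < 0 or out_idx.max() >= panels_spec.n_snps):
        raise IndexError("outlier index out of range")
    if out_idx.size and not outlier_fst > panels_spec.fst:
        raise ValueError("outlier F must exceed the neutral F")
    rng = np.random.default_rng(seed)
    panel, snp_map = simulate_ancestral_panels(
        panels_spec, int(rng.integers(0, 2**31 - 1)))
    freq = np.stack([panel.freq_a, panel.freq_b])       # (2, L)
    if out_idx.size:
        # ancestral p restricted so both displaced frequencies stay in (0,1)
        p = rng.uniform(0.25, 0.75, size=out_idx.size)
        half_d = np.sqrt(outlier_fst * p * (1 - p))
        sign = np.where(rng.random(out_idx.size) < 0.5, 1.0, -1.0)
        freq[0, out_idx] = np.clip(p + sign * half_d, 0.01, 0.99)
        freq[1, out_idx] = np.clip(p - sign * half_d, 0.01, 0.99)
    L = snp_map.n_snps
    geno = np.empty((2 * n_per_pop, L), dtype=float)
    for pop in range(2):
        geno[pop * n_per_pop:(pop + 1) * n_per_pop] = rng.binomial(
            2, freq[pop], size=(n_per_pop, L))
    ids = np.array([f"p{pop + 1}_{i + 1}" for pop in range(2)
                    for i in range(n_per_pop)], dtype=object)
    breeds = np.array(["PopA"] * n_per_pop + ["PopB"] * n_per_pop, dtype=object)
    ds = GenotypeDataset(ids, breeds, snp_map, geno)
    return ds, OutlierTruth(out_idx, panels_spec.fst, outlier_fst)


def simulate_roh_cohort(snp_map: SnpMap, n: int,
                        tract_specs: dict[str, list[tuple[int, int, int]]] | None = None,
                        background_het: float = 0.4, seed: int = 0,
                        ) -> tuple[GenotypeDataset, RohTruth]:
    """Cohort with planted autozygous tracts on a heterozygous background.

    ``tract_specs`` maps sample id (``"roh<i>"``, 1-based) to closed bp
    intervals (chrom, start, end) forced fully homozygous; they must not
    overlap within a sample.  Background genotypes are heterozygous with
    probability ``background_het`` so chance homozygous runs beyond a
    realistic ROH minimum are vanishingly rare (geometric run lengths).
    """
    tract_specs = tract_specs or {}
    rng = np.random.default_rng(seed)
    L = snp_map.n_snps
    bounds = _chrom_bounds(snp_map)
    sample_ids = [f"roh{i + 1}" for i in range(n)]
    for sid, tracts in tract_specs.items():
        if sid not in sample_ids:
            raise KeyError(f"tract spec for unknown sample {sid!r}")
        by_chrom: dict[int, list[tuple[int, int]]] = {}
        for c, s, e in tracts:
            lo, hi = bounds[int(c)]
            if s < lo or e > hi or s > e:
                raise ValueError(f"tract ({c},{s},{e}) outside chromosome bounds")
            by_chrom.setdefault(int(c), []).append((s, e))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping tracts in sample {sid}")

    u = rng.random((n, L))
    geno = np.where(u < background_het, 1.0,
                    np.where(rng.random((n, L)) < 0.5, 0.0, 2.0))
    for sid, tracts in tract_specs.items():
        i = sample_ids.index(sid)
        for c, s, e in tracts:
            inside = (snp_map.chromosome == c) & (snp_map.position_bp >= s) \
                & (snp_map.position_bp <= e)
            geno[i, inside] = np.where(rng.random(int(inside.sum())) < 0.5, 0.0, 2.0)
    ds = GenotypeDataset(np.array(sample_ids, dtype=object),
                         np.array(["RohSim"] * n, dtype=object), snp_map, geno)
    return ds, RohTruth({sid: [(int(c), int(s), int(e)) for c, s, e in tr]
                         for sid, tr in tract_specs.items()})
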