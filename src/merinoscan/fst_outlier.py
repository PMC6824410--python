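"""Bayesian F_ST-outlier scanning between breed pairs.

The model follows the classical Bayesian genome-scan decomposition: for locus
i in population j the population allele frequency drifts from an ancestral
frequency q_i under a beta model whose intensity is F_ij, with

    logit(F_ij) = a_i + b_j

where b_j is a population-wide drift effect shared by all loci and a_i is a
locus-specific selection effect.  Divergent selection inflates a_i > 0.  A
spike-and-slab prior is placed on a_i: with prior odds ``prior_odds`` for
neutrality the effect is exactly zero, otherwise it follows the slab normal.
Integrating the unknown population frequency out of the binomial sampling
layer yields a beta-binomial likelihood for the observed allele counts.

The posterior is explored by MCMC with Gibbs variable selection on the
inclusion indicator; the posterior inclusion probability (pip) of each locus
feeds a posterior-based FDR: q-values are running means of (1 - pip) down
the pip ranking.

Downstream, per-SNP significance indicators from several breed-pair
comparisons are combined into consensus counts, and consensus regions are
built by the seed-and-extend rule: seed at SNPs significant in at least
``seed_min`` comparisons, then chain outward over SNPs significant in at
least one comparison while consecutive chained SNPs lie within
``link_dist_bp``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .genotype_io import GenotypeDataset, SnpMap
from .local_ancestry import SignalRegion

__all__ = [
    "AlleleCountTable",
    "LocusFstResult",
    "ConsensusTrack",
    "McmcConfig",
    "DESK_MCMC",
    "DEFAULT_MCMC",
    "wc_fst",
    "bayescan_scan",
    "qvalues_from_posteriors",
    "consensus_counts",
    "build_outlier_regions",
]

log = logging.getLogger(__name__)


@dataclass
class AlleleCountTable:
    """Per-SNP reference/alternate allele counts in two populations."""

    snp_map: SnpMap
    ref: np.ndarray   # (L, 2) reference-allele counts per population
    alt: np.ndarray   # (L, 2)

    def __post_init__(self):
        self.ref = np.asarray(self.ref, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        L = self.snp_map.n_snps
        if self.ref.shape != (L, 2) or self.alt.shape != (L, 2):
            raise ValueError("count arrays must be (n_snps, 2)")
        if (self.ref < 0).any() or (self.alt < 0).any():
            raise ValueError("allele counts must be non-negative")

    @property
    def totals(self) -> np.ndarray:
        return self.ref + self.alt

    @classmethod
    def from_dataset(cls, dataset: GenotypeDataset, breed1: str, breed2: str,
                     ) -> "AlleleCountTable":
        """Tally allele counts for two labelled breeds, missing excluded."""
        ref = np.empty((dataset.n_snps, 2), dtype=np.int64)
        alt = np.empty_like(ref)
        for k, breed in enumerate((breed1, breed2)):
            d = dataset.dosages[dataset.samples_of(breed)]
            called = (~np.isnan(d)).sum(axis=0)
            r = np.nansum(d, axis=0).astype(np.int64)
            ref[:, k] = r
            alt[:, k] = 2 * called - r
        return cls(dataset.snp_map, ref, alt)


@dataclass
class LocusFstResult:
    """Posterior summary for one locus in one pair-wise comparison."""

    snp_id: str
    fst_posterior_mean: float
    a_effect: float            # posterior mean locus effect (log-odds scale)
    pip: float                 # posterior inclusion probability of selection
    q_value: float = np.nan
    converged: bool = True


@dataclass
class ConsensusTrack:
    """Per-SNP count N of pair-wise comparisons significant at q < threshold."""

    snp_map: SnpMap
    n_significant: np.ndarray
    n_comparisons: int

    def __post_init__(self):
        self.n_significant = np.asarray(self.n_significant, dtype=np.int64)
        if self.n_significant.shape != (self.snp_map.n_snps,):
            raise ValueError("consensus counts must align with the SNP map")
        if (self.n_significant < 0).any() or \
                (self.n_significant > self.n_comparisons).any():
            raise ValueError("counts must lie in [0, n_comparisons]")

    def to_frame(self) -> pd.DataFrame:
        df = self.snp_map.to_frame()
        df["n_significant"] = self.n_significant
        return df


# ---------------------------------------------------------------------------
# Moment estimator (oracle for the Bayesian scan)


def wc_fst(counts: AlleleCountTable) -> np.ndarray:
    """Weir-Cockerham variance-components F_ST per SNP from allele counts.

    Two-level ANOVA (populations / alleles within populations) on the allele
    counts; SNPs monomorphic for the same allele in both populations are
    undefined (NaN).  Estimates may be slightly negative by sampling noise.
    """
    n = counts.totals.astype(float)              # (L, 2) allele sample sizes
    if (n == 0).any():
        raise ValueError("zero observed alleles in a population")
    p = counts.ref / n
    N = n.sum(axis=1)
    r = 2
    pbar = (n * p).sum(axis=1) / N
    nc = (N - (n ** 2).sum(axis=1) / N) / (r - 1)
    msp = (n * (p - pbar[:, None]) ** 2).sum(axis=1) / (r - 1)
    msg = (n * p * (1 - p)).sum(axis=1) / (n - 1).sum(axis=1)
    denom = msp + (nc - 1) * msg
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = (msp - msg) / denom
    theta[denom == 0] = np.nan                   # monomorphic in both
    return theta


# ---------------------------------------------------------------------------
# Bayesian scan


@dataclass(frozen=True)
class McmcConfig:
    """Chain sizes and priors for the Bayesian scan.

    ``prior_odds`` is the prior odds in favour of the neutral model (no
    locus effect); the slab is Normal(0, slab_sd^2), and b_j has a
    Normal(b_mean, b_sd^2) prior reflecting weak genome-wide drift.
    """

    n_pilot: int = 10
    pilot_iters: int = 1000
    burn_in: int = 5000
    n_iter: int = 50_000
    thin: int = 10
    prior_odds: float = 10.0
    slab_sd: float = 3.0
    b_mean: float = -2.0
    b_sd: float = 1.8
    rhat_tol: float = 0.1


#: long default chain
DEFAULT_MCMC = McmcConfig()
#: short chain for interactive/desk use; adequate for two-population scans
DESK_MCMC = McmcConfig(n_pilot=3, pilot_iters=300, burn_in=1500,
                       n_iter=10_000, thin=5)

MCMC_PRESETS = {"desk": DESK_MCMC, "default": DEFAULT_MCMC}


def _beta_binom_ll(ref, tot, q, theta):
    """log P(ref | q, theta) under beta-binomial, up to the count constant.

    theta = (1 - F)/F is the precision of the beta drift distribution.
    Shapes broadcast over (L, 2).
    """
    aq = theta * q
    bq = theta * (1.0 - q)
    return (gammaln(ref + aq) + gammaln(tot - ref + bq) - gammaln(tot + theta)
            - gammaln(aq) - gammaln(bq) + gammaln(theta))


def _loglik(ref, tot, q, a, b):
    """Total beta-binomial log-likelihood per locus, (L,)."""
    f = expit(a[:, None] + b[None, :])
    f = np.clip(f, 1e-6, 1 - 1e-6)
    theta = (1.0 - f) / f
    return _beta_binom_ll(ref, tot, q[:, None], theta).sum(axis=1)


def bayescan_scan(counts: AlleleCountTable, mcmc: McmcConfig = DESK_MCMC,
                  seed: int = 0) -> list[LocusFstResult]:
    """Bayesian F_ST-outlier scan of one two-population comparison.

    Samples the posterior of (q_i, a_i, gamma_i, b_j) by Metropolis-within-
    Gibbs: per-locus parameters update independently given the b_j
    (vectorised element-wise accept/reject).  Inclusion indicators use Gibbs
    variable selection with a data-informed linking density: while a locus is
    excluded its dormant effect a_i is refreshed from a pseudo-prior centred
    on the moment-estimator logit F_ST, so flips into the selection model
    propose effects that already fit the data (the pseudo-prior cancels from
    the posterior over included states).  Proposal scales are tuned during
    pilot runs toward mid-range acceptance.

    Returns per-locus posterior mean F_ST (averaged over the two populations),
    posterior mean locus effect, pip, and a q-value; results are flagged
    non-converged when the split-chain R-hat of the population effects
    exceeds the configured tolerance.
    """
    L = counts.snp_map.n_snps
    if L < 100:
        warnings.warn("fewer than 100 loci: posterior FDR calibration may be "
                      "unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    ref = counts.ref.astype(float)
    tot = counts.totals.astype(float)
    pincl = 1.0 / (1.0 + mcmc.prior_odds)
    log_prior_incl = np.log(pincl) - np.log1p(-pincl)
    slab_var = mcmc.slab_sd ** 2

    # pseudo-prior for dormant locus effects: centred on the moment estimate
    with np.errstate(invalid="ignore"):
        wc = wc_fst(counts)
    wc = np.clip(np.where(np.isfinite(wc), wc, 0.01), 0.003, 0.97)
    a_hat = logit(wc) - np.median(logit(wc))
    psi_sd = 1.0

    def log_slab(x):
        return -x ** 2 / (2 * slab_var) - np.log(mcmc.slab_sd)

    def log_psi(x):
        return -(x - a_hat) ** 2 / (2 * psi_sd ** 2) - np.log(psi_sd)

    # initial state: empirical pooled frequency, neutral effects
    q = np.clip(ref.sum(axis=1) / np.maximum(tot.sum(axis=1), 1), 0.02, 0.98)
    a = a_hat + rng.normal(0, psi_sd, L)
    gamma = np.zeros(L, dtype=bool)
    b = np.full(2, mcmc.b_mean)
    ll = _loglik(ref, tot, q, a * gamma, b)

    step_q, step_a, step_b = 0.3, 0.5, 0.1
    sweep_no = 0

    def sweep(step_q, step_a, step_b):
        nonlocal q, a, gamma, b, ll, sweep_no
        sweep_no += 1
        acc = np.zeros(3)
        # --- ancestral frequencies (logit random walk, element-wise MH)
        zq = logit(q) + rng.normal(0, step_q, L)
        q_new = expit(zq)
        ll_new = _loglik(ref, tot, q_new, a * gamma, b)
        # Jacobian of the logit transform under a uniform prior on q
        lr = ll_new - ll + (np.log(q_new) + np.log1p(-q_new)
                            - np.log(q) - np.log1p(-q))
        keep = np.log(rng.random(L)) < lr
        q = np.where(keep, q_new, q)
        ll = np.where(keep, ll_new, ll)
        acc[0] = keep.mean()
        # --- locus effects: random walk on the included subset
        inc = np.flatnonzero(gamma)
        if inc.size:
            a_prop = a[inc] + rng.normal(0, step_a, inc.size)
            ll_prop = _loglik(ref[inc], tot[inc], q[inc], a_prop, b)
            lr = (ll_prop - ll[inc]) + log_slab(a_prop) - log_slab(a[inc])
            keep = np.log(rng.random(inc.size)) < lr
            a[inc[keep]] = a_prop[keep]
            ll[inc[keep]] = ll_prop[keep]
            acc[1] = keep.mean()
        else:
            acc[1] = 0.25
        # --- inclusion flips (Gibbs variable selection with pseudo-prior)
        a_dorm = a_hat + rng.normal(0, psi_sd, L)     # fresh dormant effects
        a_flip = np.where(gamma, a, a_dorm)           # effect if state flips
        ll_flip = _loglik(ref, tot, q, np.where(gamma, 0.0, a_flip), b)
        lr = np.where(
            gamma,
            ll_flip - ll + log_psi(a) - log_slab(a) - log_prior_incl,
            ll_flip - ll + log_slab(a_flip) - log_psi(a_flip) + log_prior_incl)
        keep = np.log(rng.random(L)) < lr
        a = np.where(keep & ~gamma, a_flip, a)
        a = np.where(~gamma & ~keep, a_dorm, a)       # dormant refresh is free
        gamma = np.where(keep, ~gamma, gamma)
        ll = np.where(keep, ll_flip, ll)
        # --- population effects (scalar MH, alternating populations)
        j = sweep_no % 2
        b_new = b.copy()
        b_new[j] += rng.normal(0, step_b)
        ll_new = _loglik(ref, tot, q, a * gamma, b_new)
        lr = (ll_new.sum() - ll.sum()
              + ((b[j] - mcmc.b_mean) ** 2
                 - (b_new[j] - mcmc.b_mean) ** 2) / (2 * mcmc.b_sd ** 2))
        if np.log(rng.random()) < lr:
            b, ll = b_new, ll_new
            acc[2] = 1.0
        return acc

    # pilot tuning toward mid-range acceptance rates
    for _ in range(mcmc.n_pilot):
        rates = np.zeros(3)
        for _ in range(mcmc.pilot_iters):
            rates += sweep(step_q, step_a, step_b)
        rates /= mcmc.pilot_iters
        for k, target in enumerate((0.35, 0.35, 0.3)):
            factor = np.clip(rates[k] / target, 0.5, 2.0)
            if k == 0:
                step_q *= factor
            elif k == 1:
                step_a *= factor
            else:
                step_b *= factor

    for _ in range(mcmc.burn_in):
        sweep(step_q, step_a, step_b)

    n_kept = mcmc.n_iter // mcmc.thin
    gamma_sum = np.zeros(L)
    a_sum = np.zeros(L)
    fst_sum = np.zeros(L)
    b_trace = np.empty((n_kept, 2))
    k = 0
    for it in range(mcmc.n_iter):
        sweep(step_q, step_a, step_b)
        if (it + 1) % mcmc.thin == 0:
            gamma_sum += gamma
            a_sum += a * gamma
            # realized locus differentiation: draw the population frequencies
            # from their exact conditional posterior and measure their spread
            f = np.clip(expit((a * gamma)[:, None] + b[None, :]), 1e-6, 1 - 1e-6)
            th = (1.0 - f) / f
            p_pop = rng.beta(th * q[:, None] + ref, th * (1 - q[:, None])
                             + tot - ref)
            pbar = p_pop.mean(axis=1)
            denom = 4.0 * pbar * (1.0 - pbar)
            with np.errstate(invalid="ignore", divide="ignore"):
                realized = (p_pop[:, 0] - p_pop[:, 1]) ** 2 / denom
            fst_sum += np.where(denom > 0, realized, 0.0)
            b_trace[k] = b
            k += 1

    pip = gamma_sum / n_kept
    a_mean = a_sum / n_kept
    fst_mean = fst_sum / n_kept
    converged = _split_rhat(b_trace) <= 1.0 + mcmc.rhat_tol
    if not converged:
        log.warning("population-effect chain failed split-half R-hat check")
    qvals = qvalues_from_posteriors(pip)
    return [LocusFstResult(str(counts.snp_map.snp_id[i]), float(fst_mean[i]),
                           float(a_mean[i]), float(pip[i]), float(qvals[i]),
                           bool(converged))
            for i in range(L)]


def _split_rhat(trace: np.ndarray) -> float:
    """Max split-half potential-scale-reduction over traced scalars."""
    m = trace.shape[0] // 2
    if m < 2:
        return 1.0
    halves = np.stack([trace[:m], trace[m:2 * m]])      # (2, m, k)
    w = halves.var(axis=1, ddof=1).mean(axis=0)
    bvar = m * halves.mean(axis=1).var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rhat = np.sqrt((w * (m - 1) / m + bvar / m) / w)
    return float(np.nanmax(np.where(w > 0, rhat, 1.0)))


def qvalues_from_posteriors(pips: np.ndarray) -> np.ndarray:
    """Posterior-probability FDR: q = running mean of (1 - pip) down the ranking.

    Loci are sorted by decreasing pip; q(i) is the mean of (1 - pip) over the
    i highest-pip loci, then monotonicity is enforced by a cumulative minimum
    from the bottom of the ranking.
    """
    pips = np.asarray(pips, dtype=float)
    if pips.size == 0:
        raise ValueError("empty input")
    if pips.min() < 0 or pips.max() > 1:
        raise ValueError("pips must lie in [0, 1]")
    order = np.argsort(-pips, kind="stable")
    cummean = np.cumsum(1.0 - pips[order]) / np.arange(1, pips.size + 1)
    cummean = np.minimum.accumulate(cummean[::-1])[::-1]
    out = np.empty_like(cummean)
    out[order] = cummean
    return out


# ---------------------------------------------------------------------------
# Consensus across comparisons and region construction


def consensus_counts(result_sets: list[list[LocusFstResult]], snp_map: SnpMap,
                     q_threshold: float = 0.05) -> ConsensusTrack:
    """Count, per SNP, the comparisons where it is significant (q < threshold)."""
    if not result_sets:
        raise ValueError("need at least one result set")
    N = np.zeros(snp_map.n_snps, dtype=np.int64)
    ids = list(snp_map.snp_id)
    for results in result_sets:
        if len(results) != snp_map.n_snps or \
                any(r.snp_id != s for r, s in zip(results, ids)):
            raise ValueError("result set does not match the SNP map")
        N += np.array([r.q_value < q_threshold for r in results], dtype=np.int64)
    return ConsensusTrack(snp_map, N, len(result_sets))


def build_outlier_regions(track: ConsensusTrack, snp_map: SnpMap | None = None,
                          seed_min: int = 4, link_dist_bp: int = 200_000,
                          ) -> list[SignalRegion]:
    """Seed-and-extend consensus regions from a per-SNP significance-count track.

    Seeds are SNPs significant in >= ``seed_min`` comparisons.  From each
    seed the region extends outward over SNPs significant in >= 1 comparison
    while consecutive chained SNPs are <= ``link_dist_bp`` apart; chains from
    different seeds that touch merge into one region.  The region interval is
    [first, last] chained SNP; the score is the maximum count inside.
    """
    snp_map = snp_map or track.snp_map
    N = track.n_significant
    regions: list[SignalRegion] = []
    for c in np.unique(snp_map.chromosome):
        idx = np.flatnonzero((snp_map.chromosome == c) & (N >= 1))
        if idx.size == 0:
            continue
        pos = snp_map.position_bp[idx]
        # chains: maximal runs of N>=1 SNPs with consecutive gaps <= link_dist
        breaks = np.flatnonzero(np.diff(pos) > link_dist_bp)
        start = 0
        for b in list(breaks) + [idx.size - 1]:
            members = idx[start:b + 1]
            start = b + 1
            if N[members].max() < seed_min:        # chain holds no seed
                continue
            regions.append(SignalRegion(
                chromosome=int(c),
                start_bp=int(snp_map.position_bp[members[0]]),
                end_bp=int(snp_map.position_bp[members[-1]]),
                start_snp_id=str(snp_map.snp_id[members[0]]),
                end_snp_id=str(snp_map.snp_id[members[-1]]),
                score=float(N[members].max()),
                n_snps=len(members)))
    return regions
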