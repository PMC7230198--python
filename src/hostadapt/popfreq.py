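"""Bayesian population allele-frequency estimation from genotype likelihoods.

At ~2X coverage individual genotypes are uncertain, so population allele
frequencies are estimated with a hierarchical model that integrates over
genotypes instead of calling them: genotypes g_ij in {0, 1, 2} carry a
Hardy-Weinberg Binomial(2, p_i) prior, the data enter through per-individual
genotype likelihoods, and p_i carries a Beta(a, b) prior.  A Gibbs sampler
alternates sampling genotypes from their categorical full conditional and
p from its conjugate Beta full conditional.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["GenotypeLikelihoods", "AlleleFreqEstimate", "estimate_allele_frequencies"]


@dataclass
class GenotypeLikelihoods:
    """Per-site x per-individual likelihoods of the three diploid genotypes.

    ``likelihoods`` has shape (n_sites, n_individuals, 3), linear scale.
    ``missing`` is a boolean (n_sites, n_individuals) mask; missing cells are
    treated as flat (no data).  ``sites`` is a pandas DataFrame with columns
    scaffold, position (1-based) and chrom_class in {autosome, X, other}.
    """

    sites: "object"  # pandas.DataFrame
    likelihoods: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        if self.likelihoods.ndim != 3 or self.likelihoods.shape[2] != 3:
            raise ValueError("likelihoods must have shape (sites, individuals, 3)")
        if np.any(self.likelihoods < 0):
            raise ValueError("likelihoods must be non-negative")
        if self.missing is None:
            self.missing = np.zeros(self.likelihoods.shape[:2], dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        zero = self.likelihoods.sum(axis=2) <= 0
        if np.any(zero & ~self.missing):
            raise ValueError(
                "all-zero likelihood triple for a non-missing cell; "
                "mask it as missing or fix the input"
            )

    @property
    def n_sites(self) -> int:
        return self.likelihoods.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.likelihoods.shape[1]


@dataclass
class AlleleFreqEstimate:
    """Posterior summary of per-site allele frequencies."""

    posterior_mean: np.ndarray
    posterior_sd: np.ndarray
    n_called: np.ndarray
    all_missing: np.ndarray
    mcmc_settings: dict


def estimate_allele_frequencies(
    gl: GenotypeLikelihoods,
    burn_in: int = 1000,
    n_iter: int = 10000,
    thin: int = 5,
    seed: int = 1,
    prior_a: float = 1.0,
    prior_b: float = 1.0,
) -> AlleleFreqEstimate:
    """Gibbs sampler for population allele frequencies at every site.

    Each sweep samples (i) every genotype from the categorical distribution
    proportional to likelihood(g) x Binomial(2, p) prior mass at g, and
    (ii) p per site from Beta(prior_a + sum g, prior_b + sum(2 - g)) over
    non-missing individuals.  All sites are updated in parallel
    (vectorized); the chain is reproducible bit-for-bit given the seed.

    Sites where every individual is missing keep the Beta prior and are
    flagged in ``all_missing`` (warning, not an error).
    """
    if n_iter <= 0 or burn_in < 0 or thin <= 0:
        raise ValueError("need n_iter > 0, burn_in >= 0, thin > 0")
    if prior_a <= 0 or prior_b <= 0:
        raise ValueError("Beta prior parameters must be > 0")
    rng = np.random.default_rng(seed)

    lik = gl.likelihoods.copy()
    lik[gl.missing] = 1.0  # flat likelihood contributes nothing
    # Guard against underflow: scale each triple to max 1.
    lik /= lik.max(axis=2, keepdims=True)
    n_sites, n_ind, _ = lik.shape
    obs = ~gl.missing
    n_called = obs.sum(axis=1)
    all_missing = n_called == 0
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} site(s) have no called individuals; "
            "their posterior equals the Beta prior",
            stacklevel=2,
        )

    p = np.full(n_sites, 0.5)
    g_support = np.array([0.0, 1.0, 2.0])
    sum_p = np.zeros(n_sites)
    sum_p2 = np.zeros(n_sites)
    n_kept = 0

    total = burn_in + n_iter
    for it in range(total):
        # genotype full conditional: lik * HWE prior at current p
        prior = np.stack(
            [(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1
        )  # (n_sites, 3)
        w = lik * prior[:, None, :]
        w_cum = np.cumsum(w, axis=2)
        u = rng.random((n_sites, n_ind, 1)) * w_cum[:, :, -1:]
        g = (u > w_cum).sum(axis=2)  # index of sampled genotype
        g_sum = np.where(obs, g_support[g], 0.0).sum(axis=1)
        # p full conditional (conjugate Beta)
        a_post = prior_a + g_sum
        b_post = prior_b + 2.0 * n_called - g_sum
        p = rng.beta(a_post, b_post)
        if it >= burn_in and (it - burn_in) % thin == 0:
            sum_p += p
            sum_p2 += p * p
            n_kept += 1

    mean = sum_p / n_kept
    var = np.maximum(sum_p2 / n_kept - mean**2, 0.0)
    return AlleleFreqEstimate(
        posterior_mean=mean,
        posterior_sd=np.sqrt(var),
        n_called=n_called,
        all_missing=all_missing,
        mcmc_settings={
            "burn_in": burn_in,
            "n_iter": n_iter,
            "thin": thin,
            "seed": seed,
            "prior_a": prior_a,
            "prior_b": prior_b,
        },
    )
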