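"""Synthetic data generators for every stage of the host-adaptation analysis.

The generators emulate the statistical structure of an evolve-and-resequence
(E&R) host-shift experiment in a seed beetle-like system: replicate
Wright-Fisher lines passed through a severe founding bottleneck with strong
selection at a minority of loci, shallow (~2X) genotyping-by-sequencing
genotype likelihoods, backcross mapping families with a polygenic and
negatively correlated two-trait architecture, and negative-binomial
expression counts with differential expression concentrated in labelled
gene classes.  Each simulator returns the ground truth alongside the data so
downstream estimators have a recovery target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SimTruth",
    "simulate_er_lines",
    "simulate_read_likelihoods",
    "simulate_backcross",
    "simulate_expression",
]


@dataclass
class SimTruth:
    """Ground truth shared by the simulators.

    Parameters
    ----------
    selected_loci
        Indices of loci under selection in the E&R simulation.
    s
        Per-locus selection coefficient (unitless, genic selection).
    Ne
        Effective population size (diploid individuals) after recovery.
    generations
        Number of Wright-Fisher generations simulated.
    bottleneck_n
        Number of founding individuals surviving the initial host shift
        (the first generation is sampled with ``2 * bottleneck_n`` gametes).
    qtl_effects
        (n_loci, 2) additive effects on (weight, development time); rows of
        zeros at non-QTL loci.  A negative correlation between the two
        columns yields negatively correlated breeding values.
    target_pve
        Proportion of trait variance that is additive-genetic, in [0, 1].
    de_genes
        Indices of truly differentially expressed genes.
    de_lfc
        log2 fold changes for ``de_genes`` (same length).
    """

    selected_loci: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    s: float = 0.0
    Ne: int = 1000
    generations: int = 16
    bottleneck_n: int | None = None
    qtl_effects: np.ndarray | None = None
    target_pve: float = 0.3
    de_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    de_lfc: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))

    def __post_init__(self) -> None:
        self.selected_loci = np.asarray(self.selected_loci, dtype=int)
        self.de_genes = np.asarray(self.de_genes, dtype=int)
        self.de_lfc = np.asarray(self.de_lfc, dtype=float)
        if not (0.0 <= self.target_pve <= 1.0):
            raise ValueError("target_pve must lie in [0, 1]")
        if self.Ne < 1:
            raise ValueError("Ne must be >= 1")
        if self.bottleneck_n is None:
            self.bottleneck_n = self.Ne
        if self.bottleneck_n > self.Ne:
            raise ValueError("bottleneck_n must be <= Ne")
        if self.de_genes.size != self.de_lfc.size:
            raise ValueError("de_genes and de_lfc must have equal length")


def _selection_update(p: np.ndarray, s_vec: np.ndarray) -> np.ndarray:
    """Deterministic genic-selection recursion p' = p(1+s) / (1+s p)."""
    return p * (1.0 + s_vec) / (1.0 + s_vec * p)


def simulate_er_lines(
    n_loci: int,
    n_replicate_lines: int,
    Ne: int,
    generations: int,
    truth: SimTruth,
    seed: int,
    p0: np.ndarray | float = 0.5,
) -> dict:
    """Simulate replicate Wright-Fisher E&R lines with a founding bottleneck.

    Each generation applies the deterministic selection update
    ``p' = p(1+s)/(1+sp)`` at selected loci and then binomial sampling of
    ``2*Ne`` gametes (``2*bottleneck_n`` in the first generation, modelling
    the 1-2% survival of the initial host shift).

    Returns a dict with ``founder_freqs`` (n_loci,), ``trajectories``
    (n_lines, generations+1, n_loci) and the truth object.
    """
    rng = np.random.default_rng(seed)
    p0 = np.broadcast_to(np.asarray(p0, dtype=float), (n_loci,)).copy()
    if not np.all(np.isfinite(p0)) or np.any(p0 <= 0.0) or np.any(p0 >= 1.0):
        raise ValueError("starting frequencies must be finite and in (0, 1)")
    s_vec = np.zeros(n_loci)
    sel = truth.selected_loci
    if sel.size and (sel.min() < 0 or sel.max() >= n_loci):
        raise ValueError("selected_loci out of range")
    s_vec[sel] = truth.s

    traj = np.empty((n_replicate_lines, generations + 1, n_loci))
    for line in range(n_replicate_lines):
        p = p0.copy()
        traj[line, 0] = p
        for t in range(1, generations + 1):
            p = _selection_update(p, s_vec)
            n_gametes = 2 * (truth.bottleneck_n if t == 1 else Ne)
            p = rng.binomial(n_gametes, p) / n_gametes
            traj[line, t] = p
    return {"founder_freqs": p0, "trajectories": traj, "truth": truth}


def simulate_read_likelihoods(
    true_genotypes: np.ndarray,
    mean_depth: float,
    error_rate: float,
    seed: int,
) -> dict:
    """Simulate shallow-coverage genotype likelihoods from true genotypes.

    Per site x individual the read depth is Poisson(``mean_depth``); reads
    carrying the non-reference allele are Binomial(depth, q) with
    q = epsilon, 1/2 or 1-epsilon for genotypes 0, 1, 2.  The likelihood of
    each genotype is the binomial probability of the observed non-reference
    read count under that genotype's q.  Zero depth gives three equal
    likelihoods (no data).

    ``true_genotypes`` is (n_sites, n_individuals) with values in {0, 1, 2}.
    Returns a dict with ``likelihoods`` (n_sites, n_individuals, 3),
    ``depths``, ``alt_reads``.
    """
    g = np.asarray(true_genotypes)
    if not np.isin(g, [0, 1, 2]).all():
        raise ValueError("genotypes must be in {0, 1, 2}")
    if mean_depth < 0:
        raise ValueError("mean depth must be >= 0")
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, size=g.shape)
    q_true = np.array([error_rate, 0.5, 1.0 - error_rate])[g]
    alt = rng.binomial(depth, q_true)
    q_geno = np.array([error_rate, 0.5, 1.0 - error_rate])
    # Binomial pmf of alt reads under each candidate genotype.
    lik = stats.binom.pmf(alt[..., None], depth[..., None], q_geno[None, None, :])
    return {"likelihoods": lik, "depths": depth, "alt_reads": alt}


def simulate_backcross(
    n_families: int,
    per_family_n: int,
    n_loci: int,
    truth: SimTruth,
    env_sd: float = 1.0,
    seed: int = 0,
    family_icc: float = 0.0,
) -> dict:
    """Simulate a backcross (BC) mapping population with two traits.

    At loci fixed for alternative alleles between the parental lines, BC
    genotypes (counted as copies of the backcross-parent allele) are 1
    (heterozygous) or 2 (parental homozygote) with probability 1/2 each.
    Trait = additive genetic value + family effect + normal noise.  Noise is
    scaled so the realized additive fraction of trait variance matches
    ``truth.target_pve``; ``family_icc`` sets the fraction of non-genetic
    variance that is among families.  With ``target_pve == 0`` the genetic
    effects are dropped and ``env_sd`` sets the noise scale directly.

    Returns a dict with ``genotypes`` (n, n_loci) in {1, 2}, ``traits``
    (n, 2) columns (weight, dev_time), ``family`` labels, ``breeding_values``
    (n, 2) and the truth object.
    """
    pve = truth.target_pve
    if pve == 1.0 and env_sd > 0:
        raise ValueError("target_pve=1 is incompatible with env_sd > 0")
    if not (0.0 <= family_icc <= 1.0):
        raise ValueError("family_icc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_families * per_family_n
    geno = 1 + rng.binomial(1, 0.5, size=(n, n_loci))
    fam = np.repeat(np.arange(n_families), per_family_n)

    effects = truth.qtl_effects
    if effects is None:
        effects = np.zeros((n_loci, 2))
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (n_loci, 2):
        raise ValueError("qtl_effects must have shape (n_loci, 2)")

    bv = (geno - 1.5) @ effects  # centered additive values, (n, 2)
    traits = np.empty((n, 2))
    for k in range(2):
        v_g = bv[:, k].var()
        if pve == 0.0 or v_g == 0.0:
            bv[:, k] = 0.0
            v_ng = env_sd**2 if env_sd > 0 else 1.0
        else:
            v_ng = v_g * (1.0 - pve) / pve
        fam_sd = np.sqrt(family_icc * v_ng)
        res_sd = np.sqrt((1.0 - family_icc) * v_ng)
        fam_eff = rng.normal(0.0, fam_sd, size=n_families)[fam]
        noise = rng.normal(0.0, res_sd, size=n) if res_sd > 0 else 0.0
        traits[:, k] = bv[:, k] + fam_eff + noise
    return {
        "genotypes": geno,
        "traits": traits,
        "family": fam,
        "breeding_values": bv,
        "truth": truth,
    }


def simulate_expression(
    n_genes: int,
    n_samples_per_group: int,
    lib_size: float,
    dispersion: float,
    truth: SimTruth,
    class_labels: dict[str, np.ndarray] | None = None,
    seed: int = 0,
) -> dict:
    """Simulate a two-group negative-binomial expression count matrix.

    Baseline relative expression per gene is log-normal and renormalized per
    group so each library's expected total equals ``lib_size``.  Genes in
    ``truth.de_genes`` have their group-2 mean multiplied by
    ``2**truth.de_lfc``.  Counts are NB with var = mu + dispersion * mu^2
    (Poisson when dispersion == 0).

    Returns a dict with ``counts`` (n_genes, 2*n_samples_per_group),
    ``groups`` labels, optional ``class_labels`` and a per-gene truth table.
    """
    if lib_size <= 0:
        raise ValueError("lib_size must be > 0")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    fold = np.ones(n_genes)
    if truth.de_genes.size:
        if truth.de_genes.max() >= n_genes:
            raise ValueError("de_genes out of range")
        fold[truth.de_genes] = 2.0 ** truth.de_lfc
    mu1 = base / base.sum() * lib_size
    g2 = base * fold
    mu2 = g2 / g2.sum() * lib_size

    def _draw(mu, n_samples):
        mu_mat = np.tile(mu[:, None], (1, n_samples))
        if dispersion == 0.0:
            return rng.poisson(mu_mat)
        r = 1.0 / dispersion
        return rng.negative_binomial(r, r / (r + mu_mat))

    counts = np.hstack(
        [_draw(mu1, n_samples_per_group), _draw(mu2, n_samples_per_group)]
    )
    groups = np.array([0] * n_samples_per_group + [1] * n_samples_per_group)
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[truth.de_genes] = True
    return {
        "counts": counts,
        "groups": groups,
        "is_de": is_de,
        "class_labels": class_labels or {},
        "truth": truth,
    }
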