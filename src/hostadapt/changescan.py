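"""Genome scan for SNPs with exceptional standardized allele-frequency change.

The scan standardizes allele-frequency change between an ancestral and a
derived sample by the ancestral expected heterozygosity,

    delta_i = |p1_i - p0_i| / (2 p0_i (1 - p0_i)),

then classifies SNPs into an *average change* and an *exceptional change*
hidden state with a two-state Gaussian HMM whose emission means are fixed at
the median and an upper quantile (default 99.5th percentile) of delta and
whose shared emission s.d. is the empirical s.d.; only the transition matrix
is re-estimated (Baum-Welch).  Viterbi decoding yields per-SNP states; runs
of consecutive exceptional SNPs within a scaffold form regions.  An
autocorrelation-preserving circular-shift randomization tests for an excess
(or deficit) of exceptional SNPs on the X chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM

from .integrate import OverlapTestResult, circular_shift

__all__ = [
    "ChangeProfile",
    "HmmFit",
    "RegionSet",
    "standardized_change",
    "make_change_profile",
    "fit_change_hmm",
    "summarize_regions",
    "x_excess_test",
    "hmm_loglik",
    "viterbi_decode",
    "AVERAGE",
    "EXCEPTIONAL",
]

AVERAGE = 0
EXCEPTIONAL = 1


def standardized_change(
    p0: np.ndarray,
    p1: np.ndarray,
    mode: str = "absolute",
    sqrt_denominator: bool = False,
) -> np.ndarray:
    """Standardized allele-frequency change delta per SNP.

    delta = (p1 - p0) / (2 p0 (1 - p0)); ``mode="absolute"`` (default)
    takes the magnitude, ``mode="signed"`` keeps the numerator's sign.
    ``sqrt_denominator=True`` divides by sqrt(2 p0 (1-p0)) instead, for
    sensitivity analysis.  SNPs with p0 in {0, 1} yield NaN with a warning;
    they should have been removed by the minor-allele-frequency filter.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError("mode must be 'absolute' or 'signed'")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    het = 2.0 * p0 * (1.0 - p0)
    if sqrt_denominator:
        het = np.sqrt(het)
    bad = het <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} SNP(s) with ancestral frequency 0 or 1; "
            "delta undefined (NaN), drop them upstream",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (p1 - p0) / het
    delta = np.where(bad, np.nan, delta)
    if mode == "absolute":
        delta = np.abs(delta)
    return delta


@dataclass
class ChangeProfile:
    """Per-SNP standardized change with genome coordinates.

    ``table`` columns: scaffold, position, chrom_class, p0, p1, delta;
    rows sorted by (scaffold, position), delta finite.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"scaffold", "position", "chrom_class", "p0", "p1", "delta"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"ChangeProfile table needs columns {sorted(req)}")
        if not np.all(np.isfinite(self.table["delta"].to_numpy())):
            raise ValueError("delta must be finite for all retained SNPs")
        pos_ok = (
            self.table.groupby("scaffold", sort=False)["position"]
            .apply(lambda s: s.is_monotonic_increasing)
            .all()
        )
        if not pos_ok:
            raise ValueError("positions must increase within each scaffold")


def make_change_profile(
    anc: pd.DataFrame,
    der: pd.DataFrame,
    mode: str = "absolute",
    sqrt_denominator: bool = False,
) -> ChangeProfile:
    """Join ancestral and derived allele-frequency tables and compute delta.

    Both inputs need columns scaffold, position, chrom_class, p_mean (as
    written by the popfreq table writer); the join is on (scaffold,
    position).  SNPs with undefined delta (ancestral p of 0 or 1) are
    dropped with a warning.
    """
    merged = anc.merge(
        der,
        on=["scaffold", "position"],
        suffixes=("_anc", "_der"),
    )
    chrom = (
        merged["chrom_class_anc"]
        if "chrom_class_anc" in merged.columns
        else merged["chrom_class"]
    )
    delta = standardized_change(
        merged["p_mean_anc"].to_numpy(),
        merged["p_mean_der"].to_numpy(),
        mode=mode,
        sqrt_denominator=sqrt_denominator,
    )
    out = pd.DataFrame(
        {
            "scaffold": merged["scaffold"],
            "position": merged["position"],
            "chrom_class": chrom,
            "p0": merged["p_mean_anc"],
            "p1": merged["p_mean_der"],
            "delta": delta,
        }
    )
    out = out[np.isfinite(out["delta"])].reset_index(drop=True)
    out = out.sort_values(["scaffold", "position"], kind="stable").reset_index(
        drop=True
    )
    return ChangeProfile(out)


@dataclass
class HmmFit:
    """Fixed-emission two-state HMM fit for a change profile."""

    mu_avg: float
    mu_exc: float
    sigma: float
    transmat: np.ndarray
    startprob: np.ndarray
    states: np.ndarray  # 0 = average, 1 = exceptional, genome order
    loglik_trace: list = field(default_factory=list)
    converged: bool = True
    degenerate: bool = False


def fit_change_hmm(
    profile: ChangeProfile,
    exc_quantile: float = 0.995,
    max_iter: int = 500,
    tol: float = 1e-4,
    per_scaffold: bool = True,
    startprob: tuple[float, float] | None = None,
) -> HmmFit:
    """Fit the constrained two-state Gaussian HMM and Viterbi-decode states.

    Emission means are fixed at the median (average state) and the
    ``exc_quantile`` (exceptional state) of delta; the shared emission s.d.
    is the empirical s.d. of delta.  Baum-Welch re-estimates only the
    transition matrix, for at most ``max_iter`` iterations or until the
    log-likelihood improves by less than ``tol``.  With
    ``per_scaffold=True`` chains restart at scaffold boundaries;
    ``per_scaffold=False`` treats the genome-ordered SNPs as one chain.
    The fit has no random initialization, so repeated runs are identical.
    """
    delta = profile.table["delta"].to_numpy(dtype=float)
    if delta.size < 2:
        raise ValueError("need at least 2 SNPs to fit the HMM")
    mu_avg = float(np.median(delta))
    mu_exc = float(np.quantile(delta, exc_quantile))
    sigma = float(np.std(delta))
    if startprob is None:
        startprob = (exc_quantile, 1.0 - exc_quantile)
    if mu_exc - mu_avg < 1e-12 or sigma <= 0:
        warnings.warn(
            "degenerate delta distribution (median == upper quantile); "
            "all SNPs decoded as average change",
            stacklevel=2,
        )
        return HmmFit(
            mu_avg=mu_avg,
            mu_exc=mu_exc,
            sigma=sigma,
            transmat=np.array([[1.0, 0.0], [1.0, 0.0]]),
            startprob=np.array([1.0, 0.0]),
            states=np.zeros(delta.size, dtype=int),
            degenerate=True,
        )

    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        n_iter=max_iter,
        tol=tol,
        init_params="",
        params="t",  # only the transition matrix is re-estimated
    )
    model.startprob_ = np.asarray(startprob, dtype=float)
    model.transmat_ = np.array([[0.99, 0.01], [0.5, 0.5]])
    model.means_ = np.array([[mu_avg], [mu_exc]])
    model.covars_ = np.array([[sigma**2], [sigma**2]])

    X = delta.reshape(-1, 1)
    if per_scaffold:
        lengths = (
            profile.table.groupby("scaffold", sort=False).size().to_numpy().tolist()
        )
    else:
        lengths = [delta.size]
    with warnings.catch_warnings():
        # hmmlearn warns that startprob_ will not be re-estimated; intended.
        warnings.simplefilter("ignore")
        model.fit(X, lengths)
        _, states = model.decode(X, lengths, algorithm="viterbi")
    return HmmFit(
        mu_avg=mu_avg,
        mu_exc=mu_exc,
        sigma=sigma,
        transmat=model.transmat_.copy(),
        startprob=model.startprob_.copy(),
        states=states.astype(int),
        loglik_trace=list(model.monitor_.history),
        converged=bool(model.monitor_.converged),
    )


def _model_from_fit(fit: HmmFit) -> GaussianHMM:
    model = GaussianHMM(n_components=2, covariance_type="diag", init_params="")
    model.startprob_ = fit.startprob
    model.transmat_ = fit.transmat
    model.means_ = np.array([[fit.mu_avg], [fit.mu_exc]])
    model.covars_ = np.array([[fit.sigma**2], [fit.sigma**2]])
    return model


def hmm_loglik(delta: np.ndarray, fit: HmmFit) -> float:
    """Forward-algorithm log-likelihood of a delta sequence under a fit."""
    return float(_model_from_fit(fit).score(np.asarray(delta).reshape(-1, 1)))


def viterbi_decode(delta: np.ndarray, fit: HmmFit) -> np.ndarray:
    """Most probable state path for a delta sequence under a fit."""
    _, states = _model_from_fit(fit).decode(
        np.asarray(delta).reshape(-1, 1), algorithm="viterbi"
    )
    return states.astype(int)


@dataclass
class RegionSet:
    """Contiguous exceptional-change regions (maximal runs within scaffolds)."""

    regions: pd.DataFrame  # scaffold, start, end (1-based inclusive), n_snps
    n_regions: int
    mean_snps_per_region: float


def summarize_regions(fit: HmmFit, profile: ChangeProfile) -> RegionSet:
    """Collapse runs of consecutive exceptional SNPs into regions.

    Runs never span scaffold boundaries.  With no exceptional SNPs the
    region set is empty and the mean is reported as 0.
    """
    tab = profile.table
    states = fit.states
    rows = []
    for scaf, idx in tab.groupby("scaffold", sort=False).indices.items():
        st = states[idx]
        pos = tab["position"].to_numpy()[idx]
        in_run = False
        for i, s in enumerate(st):
            if s == EXCEPTIONAL and not in_run:
                start = pos[i]
                n = 1
                in_run = True
            elif s == EXCEPTIONAL:
                n += 1
            elif in_run:
                rows.append((scaf, start, pos[i - 1], n))
                in_run = False
        if in_run:
            rows.append((scaf, start, pos[len(st) - 1], n))
    reg = pd.DataFrame(rows, columns=["scaffold", "start", "end", "n_snps"])
    n_regions = len(reg)
    mean_n = float(reg["n_snps"].mean()) if n_regions else 0.0
    return RegionSet(regions=reg, n_regions=n_regions, mean_snps_per_region=mean_n)


def x_excess_test(
    fit: HmmFit,
    profile: ChangeProfile,
    n_rand: int = 1000,
    seed: int = 1,
) -> OverlapTestResult:
    """Randomization test for X-chromosome excess of exceptional SNPs.

    Observed statistic: number of exceptional-change SNPs labelled X.  Null:
    the decoded state vector is circularly shifted along the genome-ordered
    SNP list (preserving run structure) and the count recomputed.  The
    headline p is the upper (excess) tail with add-one correction; the
    deficit tail is reported alongside.
    """
    is_x = (profile.table["chrom_class"].to_numpy() == "X").astype(float)
    states = fit.states
    if not np.any(is_x):
        warnings.warn("no X-labelled SNPs; observed = 0, p = 1", stacklevel=2)
    if states.sum() == 0:
        obs = 0.0
        null = np.zeros(n_rand)
    else:
        rng = np.random.default_rng(seed)
        obs = float(np.sum(is_x * (states == EXCEPTIONAL)))
        offsets = rng.integers(0, states.size, size=n_rand)
        null = np.array(
            [
                np.sum(is_x * (circular_shift(states, off) == EXCEPTIONAL))
                for off in offsets
            ],
            dtype=float,
        )
    p_excess = (1.0 + np.sum(null >= obs)) / (1.0 + n_rand)
    p_deficit = (1.0 + np.sum(null <= obs)) / (1.0 + n_rand)
    return OverlapTestResult(
        observed=obs,
        null=null,
        expected=float(null.mean()),
        p=p_excess,
        p_lower=p_deficit,
        n_rand=n_rand,
        seed=seed,
        tail="upper",
    )
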