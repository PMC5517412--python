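"""Admixture-model Bayesian clustering of binary marker data.

Each sample i carries membership proportions q_i over K clusters, and
each cluster k has allele frequencies p_kl per locus.  Markers are
treated as haploid biallelic loci (dominant presence/absence scores
cannot be decomposed into diploid genotypes without an error model).
Inference is by Gibbs sampling:

* z_il | q, p  ~ Categorical(q_ik p_kl^x (1-p_kl)^(1-x))
* p_kl | z     ~ Beta(lambda + n1_kl, lambda + n0_kl)
* q_i  | z     ~ Dirichlet(alpha + counts_i)

with fixed priors lambda (allele frequencies) and alpha (admixture).
The data-probability estimate per run is lnPD = mean(lnL) - var(lnL)/2
over the post-burnin trace, and the number of clusters is chosen by the
second-order rate of change of lnPD across K normalised by its
between-run standard deviation (Delta K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StructureConfig", "StructureRun", "DeltaKTable",
           "fit", "run_k_range", "evanno", "align_labels", "assign"]


@dataclass
class StructureConfig:
    """MCMC settings; defaults follow common practice for germplasm scans
    (burnin 10,000 then 20,000 reps, five runs per K, K from 1 to 3)."""

    k_range: tuple[int, int] = (1, 3)
    n_runs: int = 5
    burnin: int = 10_000
    reps: int = 20_000
    freq_prior: float = 1.0   # Beta prior lambda on allele frequencies
    admix_prior: float = 1.0  # Dirichlet prior alpha on memberships (fixed)
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burnin < 0 or self.reps < 1:
            raise ValueError("burnin must be >= 0 and reps >= 1")
        if self.k_range[0] < 1 or self.k_range[1] < self.k_range[0]:
            raise ValueError("invalid k_range")
        if self.freq_prior <= 0 or self.admix_prior <= 0:
            raise ValueError("priors must be positive")


@dataclass
class StructureRun:
    """Posterior summaries of one MCMC run at a fixed K."""

    K: int
    Q: np.ndarray       # (n_samples, K) posterior-mean memberships
    P: np.ndarray       # (K, n_loci) posterior-mean allele frequencies
    lnPD: float         # data-probability estimate
    loglik_trace: np.ndarray
    sample_ids: list[str]
    seed: int

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")


@dataclass
class DeltaKTable:
    """Per-K mean/sd of lnPD over runs and Delta K for interior K."""

    table: pd.DataFrame  # index K; columns mean_lnPD, sd_lnPD, delta_k

    @property
    def selected_k(self) -> int:
        dk = self.table["delta_k"].dropna()
        if dk.empty:
            return int(self.table["mean_lnPD"].idxmax())
        return int(dk.idxmax())


def _as_genotype_array(genotypes) -> tuple[np.ndarray, list[str]]:
    """Accepts a samples-as-columns DataFrame (markers x samples) or an
    (n_samples, n_loci) array; returns (matrix with NaN missing, ids)."""
    if isinstance(genotypes, pd.DataFrame):
        ids = list(genotypes.columns)
        X = genotypes.to_numpy(dtype=float).T
    else:
        X = np.asarray(genotypes, dtype=float)
        ids = [f"S{i}" for i in range(X.shape[0])]
    return X, ids


def fit(genotypes, K: int, config: StructureConfig | None = None,
        seed: int | None = None) -> StructureRun:
    """One Gibbs-sampling run of the admixture model at a fixed K.

    ``genotypes`` is a binary matrix with missing values allowed
    (missing loci are skipped in both the updates and the likelihood):
    either a markers-by-samples DataFrame or an (n_samples, n_loci)
    array.  Deterministic given the seed.
    """
    config = config or StructureConfig()
    if seed is None:
        seed = config.seed
    X, ids = _as_genotype_array(genotypes)
    n, L = X.shape
    if K > n:
        raise ValueError("K cannot exceed the number of samples")
    if K < 1:
        raise ValueError("K must be >= 1")
    obs = ~np.isnan(X)
    x1 = np.nan_to_num(X) * obs          # observed presence indicator
    x0 = (1.0 - np.nan_to_num(X)) * obs  # observed absence indicator
    rng = np.random.default_rng(seed)
    lam, alpha = config.freq_prior, config.admix_prior

    Q = np.full((n, K), 1.0 / K)
    P = rng.uniform(0.1, 0.9, size=(K, L))
    Q_sum = np.zeros_like(Q)
    P_sum = np.zeros_like(P)
    logliks = []
    n_sweeps = config.burnin + config.reps
    kept = 0
    for sweep in range(n_sweeps):
        # z_il proportional to q_ik * p^x * (1-p)^(1-x); missing loci get
        # the prior q alone (their z draw does not touch the data)
        lik = np.where(X[:, :, None] == 1.0, P.T[None, :, :],
                       1.0 - P.T[None, :, :])
        lik = np.where(obs[:, :, None], lik, 1.0)
        w = Q[:, None, :] * lik
        w_sum = w.sum(axis=2, keepdims=True)
        w /= w_sum
        u = rng.random((n, L, 1))
        z = (w.cumsum(axis=2) < u).sum(axis=2)  # (n, L) in 0..K-1
        zoh = np.eye(K, dtype=bool)[z]          # one-hot (n, L, K)
        n1 = np.einsum("nl,nlk->kl", x1, zoh)
        n0 = np.einsum("nl,nlk->kl", x0, zoh)
        P = np.clip(rng.beta(lam + n1, lam + n0), 1e-12, 1.0 - 1e-12)
        counts = (zoh & obs[:, :, None]).sum(axis=1)
        Q = rng.gamma(alpha + counts)
        Q /= Q.sum(axis=1, keepdims=True)
        if sweep >= config.burnin and (sweep - config.burnin) % config.thin == 0:
            Q_sum += Q
            P_sum += P
            # observed-data log-likelihood, z marginalised
            mix = (Q[:, None, :] * lik).sum(axis=2)
            logliks.append(float(np.log(np.where(obs, mix, 1.0)).sum()))
            kept += 1
    Qm = Q_sum / kept
    Pm = P_sum / kept
    ll = np.array(logliks)
    lnPD = float(ll.mean() - ll.var() / 2.0)
    if K == 1:
        Qm = np.ones((n, 1))
    return StructureRun(K=K, Q=Qm, P=Pm, lnPD=lnPD, loglik_trace=ll,
                        sample_ids=ids, seed=seed)


def run_k_range(genotypes, config: StructureConfig | None = None
                ) -> dict[int, list[StructureRun]]:
    """Replicated runs for every K in the configured range; each run gets
    a distinct seed derived from the config seed."""
    config = config or StructureConfig()
    runs: dict[int, list[StructureRun]] = {}
    lo, hi = config.k_range
    for K in range(lo, hi + 1):
        runs[K] = [
            fit(genotypes, K, config,
                seed=config.seed + 1009 * K + 7919 * r)
            for r in range(config.n_runs)
        ]
    return runs


def evanno(runs: dict[int, list[StructureRun]]) -> DeltaKTable:
    """Delta K model choice across a contiguous K range.

    Delta K(K) = |mean L(K-1) - 2 mean L(K) + mean L(K+1)| / sd(L(K)),
    defined only for interior K with sd > 0 (flagged NaN otherwise).
    Requires >= 2 runs per K and a contiguous range of length >= 3.
    """
    ks = sorted(runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range of length >= 3")
    if any(len(runs[k]) < 2 for k in ks):
        raise ValueError("need >= 2 runs per K")
    if len(ks) == 3:
        warnings.warn(
            "Delta K is defined only at the single interior K of a "
            "3-value range; widen the K range for a meaningful argmax")
    mean = {k: float(np.mean([r.lnPD for r in runs[k]])) for k in ks}
    sd = {k: float(np.std([r.lnPD for r in runs[k]], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        if ks[0] < k < ks[-1] and sd[k] > 0:
            dk = abs(mean[k - 1] - 2 * mean[k] + mean[k + 1]) / sd[k]
        else:
            dk = np.nan
        rows.append({"K": k, "mean_lnPD": mean[k], "sd_lnPD": sd[k],
                     "delta_k": dk})
    return DeltaKTable(table=pd.DataFrame(rows).set_index("K"))


def align_labels(runs: list[StructureRun]) -> list[StructureRun]:
    """Repair label switching across replicated runs of one K.

    Each run's Q columns are permuted to match the first run, greedily
    pairing the most-correlated column pair first.  Returns new runs;
    the first is unchanged.
    """
    if not runs:
        return runs
    K = runs[0].K
    if any(r.K != K for r in runs):
        raise ValueError("all runs must share the same K")
    ref = runs[0].Q
    out = [runs[0]]
    for run in runs[1:]:
        if K == 1:
            out.append(run)
            continue
        C = np.zeros((K, K))
        for a in range(K):
            for b in range(K):
                ra = ref[:, a] - ref[:, a].mean()
                rb = run.Q[:, b] - run.Q[:, b].mean()
                denom = np.sqrt((ra ** 2).sum() * (rb ** 2).sum())
                C[a, b] = (ra * rb).sum() / denom if denom > 0 else 0.0
        perm = np.full(K, -1)
        used_a, used_b = set(), set()
        for _ in range(K):
            best = max(((C[a, b], a, b) for a in range(K) for b in range(K)
                        if a not in used_a and b not in used_b),
                       key=lambda t: t[0])
            _, a, b = best
            perm[a] = b
            used_a.add(a)
            used_b.add(b)
        out.append(StructureRun(
            K=K, Q=run.Q[:, perm], P=run.P[perm], lnPD=run.lnPD,
            loglik_trace=run.loglik_trace, sample_ids=run.sample_ids,
            seed=run.seed))
    return out


def assign(Q: np.ndarray, threshold: float = 0.8,
           sample_ids: list[str] | None = None) -> pd.DataFrame:
    """Threshold-based cluster assignment from a membership matrix.

    A sample is assigned to argmax_k q_ik when that maximum reaches the
    threshold, otherwise labelled ``admixed``.  The returned frame also
    records the max membership; cluster mean-membership proportions (in
    percent) are attached as ``df.attrs['cluster_mean_pct']``.
    """
    Q = np.asarray(Q, dtype=float)
    ids = sample_ids or [f"S{i}" for i in range(Q.shape[0])]
    top = Q.argmax(axis=1)
    mx = Q.max(axis=1)
    labels = [str(k + 1) if m >= threshold else "admixed"
              for k, m in zip(top, mx)]
    df = pd.DataFrame({"label": labels, "max_membership": mx}, index=ids)
    df.attrs["cluster_mean_pct"] = 100.0 * Q.mean(axis=0)
    return df
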