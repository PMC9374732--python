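"""Ancestry estimation and the variant/probe filters feeding it.

The estimation core is the binomial admixture likelihood: for sample *i*
with ancestry proportions ``q_i`` over K populations whose alternate-
allele frequencies at SNP *m* are ``f_km``, the dosage ``g_im`` is
Binomial(2, p_im) with ``p_im = sum_k q_ik f_km``. Supervised fits hold F
fixed at panel estimates and maximize over q by EM; unsupervised fits
block-relax q and F. Model order K is chosen by held-out-entry
cross-validation repeated over re-randomized fold assignments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, is_autosome

#: frequency clamp keeping the likelihood finite
EPS = 1e-6


@dataclass
class AdmixtureModel:
    """Population allele frequencies F (K x M) with population names."""

    pops: list[str]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[0] != len(self.pops):
            raise ValueError("freqs must be (n_pops x n_snps)")

    @property
    def n_pops(self) -> int:
        return len(self.pops)

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[1]


# ---------------------------------------------------------------------------
# variant filtering / sampling / LD pruning
# ---------------------------------------------------------------------------

def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.05,
    require_complete: bool = True,
    autosomes_only: bool = True,
) -> GenotypeMatrix:
    """Retain biallelic SNPs passing completeness, MAF and autosome filters.

    The MAF cut is inclusive (MAF exactly equal to ``maf_min`` is kept),
    matching the usual ">= 5% minor allele frequency" convention.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    keep = gm.is_biallelic()
    if autosomes_only:
        keep &= gm.variants["chrom"].map(is_autosome).to_numpy()
    if require_complete:
        keep &= ~gm.has_missing()
    with np.errstate(invalid="ignore"):
        maf = gm.maf()
    keep &= np.nan_to_num(maf, nan=-1.0) >= maf_min
    if not keep.any():
        warnings.warn("variant filter retained no SNPs", stacklevel=2)
    return gm.take_variants(keep)


def sample_variants(gm: GenotypeMatrix, n: int, seed: int) -> GenotypeMatrix:
    """Uniform sample of ``n`` SNPs without replacement, coordinate order kept."""
    if n < 0 or n > gm.n_variants:
        raise ValueError(f"cannot sample {n} of {gm.n_variants} variants")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(gm.n_variants, size=n, replace=False))
    return gm.take_variants(idx)


def _centered(dosages: np.ndarray) -> np.ndarray:
    """Mean-impute missing calls and center columns (composite-LD scale)."""
    d = dosages.astype(float)
    miss = dosages == MISSING
    if miss.any():
        obs = ~miss
        col_mean = np.where(obs, d, 0).sum(0) / np.maximum(obs.sum(0), 1)
        d = np.where(miss, col_mean, d)
    return d - d.mean(axis=0)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
    corr_samples: list[str] | None = None,
) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on squared dosage correlation.

    Windows of ``window_snps`` SNPs advance by ``step_snps`` within each
    chromosome. While any retained pair inside a window exceeds
    ``r2_max``, the member with the lower MAF is removed (ties: the later
    coordinate), so re-scanning the output finds no offending pair.

    ``corr_samples`` restricts the correlation and MAF computation to a
    subset (e.g. the reference panel); the pruning decision then does not
    condition on the remaining samples' genotypes, which would otherwise
    bias their downstream ancestry fits. All samples are retained in the
    output either way.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must lie in (0, 1]")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")

    stat_gm = gm if corr_samples is None else gm.take_samples(corr_samples)
    maf = stat_gm.maf()
    centered = _centered(stat_gm.dosages)
    keep = np.ones(gm.n_variants, dtype=bool)

    # single sweep with windows anchored on the input coordinates; since
    # SNPs are only ever removed, every window is still pairwise clean
    # among the survivors when the sweep ends
    chrom_col = gm.variants["chrom"].to_numpy()
    for chrom in pd.unique(gm.variants["chrom"]):
        cols = np.flatnonzero(chrom_col == chrom)
        m = len(cols)
        for start in range(0, max(m - 1, 1), step_snps):
            window = cols[start : start + window_snps]
            _prune_window(window, centered, maf, keep, r2_max)
    return gm.take_variants(keep)


def max_window_r2(
    pruned: GenotypeMatrix,
    original: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 10,
    corr_samples: list[str] | None = None,
) -> float:
    """Largest surviving pairwise r-squared under the pruning sweep's
    window geometry (windows anchored on the ORIGINAL coordinates).

    This is the re-scan companion to :func:`ld_prune`: by construction
    the returned value never exceeds the ``r2_max`` the pruning used.
    """
    stat_gm = pruned if corr_samples is None else pruned.take_samples(corr_samples)
    centered = _centered(stat_gm.dosages)
    norms = np.linalg.norm(centered, axis=0)
    kept_keys = set(
        zip(pruned.variants["chrom"], pruned.variants["pos"])
    )
    col_of = {
        key: j
        for j, key in enumerate(zip(pruned.variants["chrom"], pruned.variants["pos"]))
    }
    orig_keys = list(zip(original.variants["chrom"], original.variants["pos"]))
    worst = 0.0
    chrom_col = original.variants["chrom"].to_numpy()
    for chrom in pd.unique(original.variants["chrom"]):
        cols = np.flatnonzero(chrom_col == chrom)
        for start in range(0, max(len(cols) - 1, 1), step_snps):
            window = cols[start : start + window_snps]
            surv = [col_of[orig_keys[j]] for j in window if orig_keys[j] in kept_keys]
            if len(surv) < 2:
                continue
            sub = centered[:, surv]
            n = norms[surv]
            safe = np.where(n > 0, n, 1.0)
            r2 = (sub.T @ sub / np.outer(safe, safe)) ** 2
            np.fill_diagonal(r2, 0.0)
            r2[n == 0, :] = 0.0
            r2[:, n == 0] = 0.0
            worst = max(worst, float(r2.max()))
    return worst


def _prune_window(window, centered, maf, keep, r2_max) -> bool:
    """Prune one window in place; returns True if anything was removed."""
    active = window[keep[window]]
    if len(active) < 2:
        return False
    sub = centered[:, active]
    norms = np.linalg.norm(sub, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    corr = (sub.T @ sub) / np.outer(safe, safe)
    r2 = corr**2
    np.fill_diagonal(r2, 0.0)
    r2[norms == 0, :] = 0.0
    r2[:, norms == 0] = 0.0
    alive = np.ones(len(active), dtype=bool)
    removed = False
    while True:
        masked = np.where(np.outer(alive, alive), r2, 0.0)
        i, j = divmod(int(masked.argmax()), len(active))
        if masked[i, j] <= r2_max:
            break
        a, b = active[i], active[j]
        # drop lower MAF; on a tie drop the later coordinate (larger index)
        if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
            drop_local = i
        else:
            drop_local = j
        alive[drop_local] = False
        keep[active[drop_local]] = False
        removed = True
    return removed


# ---------------------------------------------------------------------------
# admixture fits
# ---------------------------------------------------------------------------

def panel_freqs(gm: GenotypeMatrix, labels: dict[str, str]) -> AdmixtureModel:
    """Per-population alternate-allele frequencies from a labeled panel.

    Uses a half-count pseudocount, ``f = (alt + 0.5) / (2 n_obs + 1)``,
    so no frequency is exactly 0 or 1 even for monomorphic panels, and
    clamps to [EPS, 1-EPS].
    """
    pops = sorted(set(labels.values()))
    freqs = np.empty((len(pops), gm.n_variants))
    for k, pop in enumerate(pops):
        members = [s for s in gm.samples if labels.get(s) == pop]
        if not members:
            raise ValueError(f"population {pop!r} has no panel samples")
        d = gm.take_samples(members).dosages
        obs = d != MISSING
        alt = np.where(obs, d, 0).sum(0)
        n_obs = obs.sum(0)
        freqs[k] = (alt + 0.5) / (2 * n_obs + 1)
    return AdmixtureModel(pops=pops, freqs=np.clip(freqs, EPS, 1 - EPS))


def _loglik(G: np.ndarray, Q: np.ndarray, F: np.ndarray) -> float:
    P = np.clip(Q @ F, EPS, 1 - EPS)
    return float(np.sum(G * np.log(P) + (2 - G) * np.log1p(-P)))


def _loglik_masked(G, Q, F, W) -> float:
    P = np.clip(Q @ F, EPS, 1 - EPS)
    return float(np.sum(W * (G * np.log(P) + (2 - G) * np.log1p(-P))))


def _em_q_update(G, Q, F, W=None):
    """One EM ascent step in Q with F fixed; returns the row-normalized Q."""
    P = np.clip(Q @ F, EPS, 1 - EPS)
    Gm = G if W is None else G * W
    Cm = (2 - G) if W is None else (2 - G) * W
    A = Q * ((Gm / P) @ F.T)
    B = Q * ((Cm / (1 - P)) @ (1 - F).T)
    Qn = A + B
    denom = Qn.sum(axis=1, keepdims=True)
    return np.where(denom > 0, Qn / denom, 1.0 / Q.shape[1])


def supervised_q(
    g: np.ndarray,
    model: AdmixtureModel,
    tol: float = 1e-6,
    max_iter: int = 1000,
    return_trace: bool = False,
):
    """Maximum-likelihood ancestry proportions with F held fixed (EM).

    ``g`` is one complete dosage vector. Returns the K-vector q (and the
    log-likelihood trajectory if requested); the trajectory is
    non-decreasing, a property the tests assert.
    """
    Q, trace = supervised_q_batch(
        np.asarray(g, dtype=float)[None, :], model, tol=tol, max_iter=max_iter
    )
    return (Q[0], trace) if return_trace else Q[0]


def supervised_q_batch(
    G: np.ndarray,
    model: AdmixtureModel,
    tol: float = 1e-6,
    max_iter: int = 1000,
):
    """Vectorized :func:`supervised_q` over the rows of ``G``.

    Returns ``(Q, trace)`` where trace is the summed log-likelihood per
    iteration (non-decreasing).
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[1] != model.n_snps:
        raise ValueError("G must be (n_samples x n_snps) matching the model")
    if (G < 0).any():
        raise ValueError("supervised_q requires complete genotypes (no missing)")
    F = model.freqs
    K = model.n_pops
    Q = np.full((G.shape[0], K), 1.0 / K)
    trace = [_loglik(G, Q, F)]
    if K == 1:
        return Q, np.asarray(trace)
    for _ in range(max_iter):
        Q = _em_q_update(G, Q, F)
        trace.append(_loglik(G, Q, F))
        if trace[-1] - trace[-2] < tol:
            break
    if not np.all(np.isfinite(trace)):
        raise ValueError("non-finite likelihood; check frequency clamping")
    return Q, np.asarray(trace)


def supervised_admixture(
    G_panel: np.ndarray,
    panel_pops: Sequence[str],
    G_query: np.ndarray,
    tol: float = 1e-5,
    max_iter: int = 2000,
    return_trace: bool = False,
):
    """Supervised admixture with jointly re-estimated frequencies.

    Panel rows have their ancestry pinned to the labeled population;
    query rows get free ancestry vectors; F is re-estimated each
    iteration from panel *and* query genotypes. With few reference
    individuals per population this is markedly less biased than fitting
    queries against plug-in panel frequencies, because the frequency
    noise is averaged over all samples rather than baked into a fixed F.

    Returns ``(Q_query, model)`` (plus the non-decreasing log-likelihood
    trace if requested), with ``model`` holding the final frequencies.
    """
    G_panel = np.asarray(G_panel, dtype=float)
    G_query = np.asarray(G_query, dtype=float)
    if len(panel_pops) != G_panel.shape[0]:
        raise ValueError("one population label per panel row required")
    if G_query.shape[1] != G_panel.shape[1]:
        raise ValueError("panel and query SNP columns differ")
    if (G_panel < 0).any() or (G_query < 0).any():
        raise ValueError("supervised fits require complete genotypes")
    pops = sorted(set(panel_pops))
    K = len(pops)
    n_p = G_panel.shape[0]
    Q = np.vstack(
        [
            np.eye(K)[[pops.index(p) for p in panel_pops]],
            np.full((G_query.shape[0], K), 1.0 / K),
        ]
    )
    G = np.vstack([G_panel, G_query])
    # init F from panel allele counts (pseudocounted)
    F = np.empty((K, G.shape[1]))
    for k, pop in enumerate(pops):
        rows = [i for i, p in enumerate(panel_pops) if p == pop]
        F[k] = (G_panel[rows].sum(0) + 0.5) / (2 * len(rows) + 1)
    F = np.clip(F, EPS, 1 - EPS)

    trace = [_loglik(G, Q, F)]
    for _ in range(max_iter):
        Qn = _em_q_update(G, Q, F)
        Q[n_p:] = Qn[n_p:]  # panel rows stay pinned
        P = np.clip(Q @ F, EPS, 1 - EPS)
        A = F * (Q.T @ (G / P))
        B = (1 - F) * (Q.T @ ((2 - G) / (1 - P)))
        with np.errstate(invalid="ignore"):
            F = np.clip(np.where(A + B > 0, A / (A + B), F), EPS, 1 - EPS)
        trace.append(_loglik(G, Q, F))
        if trace[-1] - trace[-2] < tol:
            break
    model = AdmixtureModel(pops=pops, freqs=F)
    out = (Q[n_p:], model)
    return out + (np.asarray(trace),) if return_trace else out


def unsupervised_admixture(
    G: np.ndarray | GenotypeMatrix,
    K: int,
    seed: int,
    tol: float = 1e-5,
    max_iter: int = 500,
    weights: np.ndarray | None = None,
    return_trace: bool = False,
):
    """Joint EM over ancestry proportions Q and frequencies F.

    Block relaxation: the q-rows and the f-rows are each updated by their
    EM step, which never decreases the (optionally cell-weighted)
    binomial log-likelihood. Population labels are unidentifiable: any
    permutation of the K components gives the same likelihood, so
    comparisons against a truth must search over label orders.
    """
    if isinstance(G, GenotypeMatrix):
        G = G.dosages
    G = np.asarray(G, dtype=float)
    n, M = G.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    if weights is None and (G < 0).any():
        raise ValueError("missing genotypes require an explicit weight mask")
    W = None if weights is None else np.asarray(weights, dtype=float)
    if W is not None:
        G = np.where(W > 0, G, 0.0)  # masked cells never touch the likelihood

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    pooled = (G if W is None else G * W).sum(0) / np.maximum(
        2 * (n if W is None else W.sum(0)), 1
    )
    F = np.clip(pooled[None, :] + rng.normal(0, 0.05, size=(K, M)), EPS, 1 - EPS)

    ll = _loglik(G, Q, F) if W is None else _loglik_masked(G, Q, F, W)
    trace = [ll]
    for _ in range(max_iter):
        Q = _em_q_update(G, Q, F, W)
        P = np.clip(Q @ F, EPS, 1 - EPS)
        Gm = G if W is None else G * W
        Cm = (2 - G) if W is None else (2 - G) * W
        A = F * (Q.T @ (Gm / P))
        B = (1 - F) * (Q.T @ (Cm / (1 - P)))
        with np.errstate(invalid="ignore"):
            F = np.clip(np.where(A + B > 0, A / (A + B), F), EPS, 1 - EPS)
        ll = _loglik(G, Q, F) if W is None else _loglik_masked(G, Q, F, W)
        trace.append(ll)
        if trace[-1] - trace[-2] < tol:
            break
    out = (Q, F)
    return out + (np.asarray(trace),) if return_trace else out


def cv_error(
    G: np.ndarray | GenotypeMatrix,
    K: int,
    n_folds: int = 5,
    n_boot: int = 1,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 300,
) -> tuple[float, float]:
    """Held-out-entry cross-validation error for model order K.

    Genotype cells are partitioned into ``n_folds`` random folds; each
    fold is masked in turn, the model refit on the remaining cells, and
    the masked cells scored by squared deviation between observed dosage
    and its fitted expectation ``2 sum_k q f``. The whole procedure is
    repeated over ``n_boot`` re-randomized fold assignments; returns the
    mean error and the SD across repetitions.
    """
    if isinstance(G, GenotypeMatrix):
        G = G.dosages
    G = np.asarray(G, dtype=float)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    n, M = G.shape
    rng = np.random.default_rng(seed)
    boot_means = []
    for _ in range(n_boot):
        folds = _draw_folds(rng, n, M, n_folds)
        errs = []
        for f in range(n_folds):
            held = folds == f
            if not held.any():
                raise ValueError("a fold masked no genotype entries")
            W = (~held).astype(float)
            Q, F = unsupervised_admixture(
                G, K, seed=int(rng.integers(2**31)), tol=tol,
                max_iter=max_iter, weights=W,
            )
            pred = 2 * np.clip(Q @ F, EPS, 1 - EPS)
            errs.append(float(np.mean((G[held] - pred[held]) ** 2)))
        boot_means.append(float(np.mean(errs)))
    mean = float(np.mean(boot_means))
    sd = float(np.std(boot_means, ddof=1)) if n_boot > 1 else 0.0
    return mean, sd


def _draw_folds(rng, n, M, n_folds, max_tries: int = 20) -> np.ndarray:
    """Random cell-fold assignment; redraw if any SNP column falls wholly
    into one fold (that column would have no training data in that fit)."""
    for _ in range(max_tries):
        folds = rng.integers(0, n_folds, size=(n, M))
        if not (folds == folds[0]).all(axis=0).any():
            return folds
        warnings.warn("fold assignment left a SNP column fully masked; redrawing",
                      stacklevel=3)
    raise RuntimeError("could not draw a valid fold assignment")


def classify_species(
    q: np.ndarray, pop_names: list[str], major_min: float = 0.85
) -> str:
    """Assign the majority population if its proportion reaches ``major_min``,
    otherwise report "admixed"."""
    if not 0.5 < major_min <= 1:
        raise ValueError("major_min must lie in (0.5, 1]")
    q = np.asarray(q, dtype=float)
    k = int(q.argmax())
    return pop_names[k] if q[k] >= major_min else "admixed"


# ---------------------------------------------------------------------------
# microarray probe QC
# ---------------------------------------------------------------------------

#: each predicate is an EXCLUSION rule; a probe is kept only if none fires.
PROBE_EXCLUSION_RULES: dict[str, callable] = {
    "meanR_AB < 0.2": lambda s: s["meanR_AB"] < 0.2,
    "meanR_AA < 0.2": lambda s: s["meanR_AA"] < 0.2,
    "meanR_BB < 0.2": lambda s: s["meanR_BB"] < 0.2,
    "Cluster_Sep < 0.35": lambda s: s["Cluster_Sep"] < 0.35,
    "meanTHETA_AA > 0.3": lambda s: s["meanTHETA_AA"] > 0.3,
    "meanTHETA_BB < 0.7": lambda s: s["meanTHETA_BB"] < 0.7,
    "meanTHETA_AB outside [0.3, 0.7]": lambda s: (
        s["meanTHETA_AB"] < 0.3 or s["meanTHETA_AB"] > 0.7
    ),
    "devTHETA_AA > 0.025": lambda s: s["devTHETA_AA"] > 0.025,
    "devTHETA_AB >= 0.07": lambda s: s["devTHETA_AB"] >= 0.07,
    "devTHETA_BB > 0.025": lambda s: s["devTHETA_BB"] > 0.025,
    "GenTrain_Score < 0.7": lambda s: s["GenTrain_Score"] < 0.7,
}

PROBE_STAT_COLUMNS = (
    "meanR_AA", "meanR_AB", "meanR_BB", "Cluster_Sep",
    "meanTHETA_AA", "meanTHETA_AB", "meanTHETA_BB",
    "devTHETA_AA", "devTHETA_AB", "devTHETA_BB", "GenTrain_Score",
)


def filter_probes(
    stats: pd.DataFrame, with_reasons: bool = False
):
    """Microarray probe QC by cluster-geometry exclusion rules.

    ``stats`` needs a ``probe_id`` column plus the GenomeStudio cluster
    statistics in :data:`PROBE_STAT_COLUMNS`. A probe with any missing
    statistic is excluded with reason "incomplete". Returns the retained
    probe ids (and, optionally, a reasons mapping for exclusions).
    """
    retained: list[str] = []
    reasons: dict[str, list[str]] = {}
    for _, row in stats.iterrows():
        pid = row["probe_id"]
        if any(pd.isna(row.get(c)) for c in PROBE_STAT_COLUMNS):
            reasons[pid] = ["incomplete"]
            continue
        fired = [name for name, rule in PROBE_EXCLUSION_RULES.items() if rule(row)]
        if fired:
            reasons[pid] = fired
        else:
            retained.append(pid)
    return (retained, reasons) if with_reasons else retained
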