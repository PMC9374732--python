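"""Ancestry-adjusted kinship estimation and exact pedigree expectations.

Genotype-based estimates follow the individual-specific allele-frequency
construction: each sample's per-SNP expected frequency is
``mu_im = sum_k q_ik f_km`` from its ancestry vector, and the kinship
moment estimator

    phi_hat = sum_m (g_im - 2 mu_im)(g_jm - 2 mu_jm)
              / (4 sum_m sqrt(mu_im (1-mu_im) mu_jm (1-mu_jm)))

stays centered at the pedigree kinship even when the pair spans diverged
populations. IBD-sharing proportions (delta0, delta1, delta2) are fit by
simplex-constrained least squares on the 3x3 joint-genotype table.
Pedigree-expected values come from the classical recursive kinship
algorithm and from exact enumeration of inheritance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from .ancestry import EPS, AdmixtureModel

# ---------------------------------------------------------------------------
# genotype-based estimators
# ---------------------------------------------------------------------------

def individual_freqs(q: np.ndarray, model: AdmixtureModel) -> np.ndarray:
    """Individual-specific allele frequencies ``mu_m = sum_k q_k f_km``."""
    q = np.asarray(q, dtype=float)
    if q.shape != (model.n_pops,):
        raise ValueError(f"q has shape {q.shape}, expected ({model.n_pops},)")
    return np.clip(q @ model.freqs, EPS, 1 - EPS)


def individual_freqs_batch(Q: np.ndarray, model: AdmixtureModel) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != model.n_pops:
        raise ValueError("Q must be (n_samples x n_pops)")
    return np.clip(Q @ model.freqs, EPS, 1 - EPS)


def kinship_phi(g_i, g_j, mu_i, mu_j) -> float:
    """Pairwise kinship from dosages and individual-specific frequencies."""
    g_i, g_j, mu_i, mu_j = map(np.asarray, (g_i, g_j, mu_i, mu_j))
    if not g_i.shape == g_j.shape == mu_i.shape == mu_j.shape:
        raise ValueError("dosage and frequency vectors must be aligned")
    num = float(((g_i - 2 * mu_i) * (g_j - 2 * mu_j)).sum())
    den = 4.0 * float(np.sqrt(mu_i * (1 - mu_i) * mu_j * (1 - mu_j)).sum())
    if den <= 0:
        raise ValueError("degenerate denominator: all frequencies at bounds")
    return num / den


def pairwise_phi(G_a, Mu_a, G_b, Mu_b) -> np.ndarray:
    """Kinship matrix between two sample sets (rows of a vs rows of b)."""
    G_a, Mu_a, G_b, Mu_b = (np.asarray(x, dtype=float) for x in (G_a, Mu_a, G_b, Mu_b))
    num = (G_a - 2 * Mu_a) @ (G_b - 2 * Mu_b).T
    sd_a = np.sqrt(Mu_a * (1 - Mu_a))
    sd_b = np.sqrt(Mu_b * (1 - Mu_b))
    den = 4.0 * (sd_a @ sd_b.T)
    return num / den


def _binom2(p: np.ndarray) -> np.ndarray:
    """P(dosage = 0,1,2) under Binomial(2, p); shape (3, M)."""
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2])


def _bern(p: np.ndarray) -> np.ndarray:
    """P(allele = 0,1); shape (2, M)."""
    return np.stack([1 - p, p])


def ibd_deltas(g_i, g_j, mu_i, mu_j) -> tuple[float, float, float]:
    """IBD-sharing proportions from the 3x3 joint-genotype table.

    Expected joint-genotype probabilities are computed per SNP under each
    IBD state (sharing 0, 1 or 2 alleles), with the shared allele drawn
    at the pair-average frequency ``(mu_i + mu_j)/2`` and the non-shared
    alleles at each individual's own frequency; the observed table is
    projected onto the simplex of state mixtures by least squares.
    """
    g_i, g_j = np.asarray(g_i), np.asarray(g_j)
    mu_i, mu_j = np.asarray(mu_i, dtype=float), np.asarray(mu_j, dtype=float)
    if not g_i.shape == g_j.shape == mu_i.shape == mu_j.shape:
        raise ValueError("dosage and frequency vectors must be aligned")
    M = g_i.size
    obs = np.zeros((3, 3))
    np.add.at(obs, (g_i.astype(int), g_j.astype(int)), 1.0)
    obs /= M

    mubar = (mu_i + mu_j) / 2
    bi, bj = _binom2(mu_i), _binom2(mu_j)
    # state 0: fully independent genotypes
    e0 = np.einsum("am,bm->ab", bi, bj) / M
    # state 1: one shared allele (freq mubar) + one private allele each
    s = _bern(mubar)
    ai, aj = _bern(mu_i), _bern(mu_j)
    e1 = np.zeros((3, 3))
    for shared in (0, 1):
        for x in (0, 1):
            for y in (0, 1):
                e1[shared + x, shared + y] += float(
                    (s[shared] * ai[x] * aj[y]).sum()
                )
    e1 /= M
    # state 2: identical genotypes at the pair-average frequency
    e2 = np.zeros((3, 3))
    e2[np.diag_indices(3)] = _binom2(mubar).sum(axis=1) / M

    A = np.column_stack([e0.ravel(), e1.ravel(), e2.ravel()])
    if np.linalg.matrix_rank(A, tol=1e-10) < 3:
        raise ValueError("IBD state tables are collinear; deltas unidentifiable")
    d = _simplex_lstsq(A, obs.ravel())
    return tuple(float(x) for x in d)


def _simplex_lstsq(A: np.ndarray, o: np.ndarray) -> np.ndarray:
    """Exact minimizer of ||A d - o||^2 over the probability simplex.

    With three variables the QP is solved by enumerating the active sets
    of the positivity constraints: for every nonempty support, solve the
    sum-to-one equality-constrained least squares via its KKT system and
    keep the best feasible candidate. Exact and deterministic.
    """
    k = A.shape[1]
    best, best_obj = None, np.inf
    for mask in range(1, 1 << k):
        support = [i for i in range(k) if mask >> i & 1]
        As = A[:, support]
        m = len(support)
        kkt = np.zeros((m + 1, m + 1))
        kkt[:m, :m] = 2 * As.T @ As
        kkt[:m, m] = 1.0
        kkt[m, :m] = 1.0
        rhs = np.concatenate([2 * As.T @ o, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            continue
        ds = sol[:m]
        if (ds < -1e-12).any():
            continue
        d = np.zeros(k)
        d[support] = np.clip(ds, 0, None)
        d /= d.sum()
        r = A @ d - o
        obj = float(r @ r)
        if obj < best_obj - 1e-15:
            best, best_obj = d, obj
    return best


@dataclass(frozen=True)
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi_hat: float
    deltas: tuple[float, float, float]
    n_snps: int


def estimate_kinship(sample_i, sample_j, g_i, g_j, mu_i, mu_j) -> KinshipEstimate:
    return KinshipEstimate(
        sample_i=sample_i,
        sample_j=sample_j,
        phi_hat=kinship_phi(g_i, g_j, mu_i, mu_j),
        deltas=ibd_deltas(g_i, g_j, mu_i, mu_j),
        n_snps=int(np.asarray(g_i).size),
    )


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

class Pedigree:
    """Acyclic parent graph; parents are either both recorded or both absent."""

    def __init__(self, records: Iterable[tuple]) -> None:
        self.parents: dict[str, tuple[str | None, str | None]] = {}
        self.sex: dict[str, str | None] = {}
        for rec in records:
            iid, sire, dam = rec[0], rec[1], rec[2]
            sx = rec[3] if len(rec) > 3 else None
            if iid in self.parents:
                raise ValueError(f"duplicate individual {iid!r}")
            if (sire is None) != (dam is None):
                raise ValueError(
                    f"individual {iid!r} has exactly one recorded parent; "
                    "record both or neither"
                )
            self.parents[iid] = (sire, dam)
            self.sex[iid] = sx
        for iid, (sire, dam) in self.parents.items():
            for p in (sire, dam):
                if p is not None and p not in self.parents:
                    raise ValueError(f"parent {p!r} of {iid!r} is not in the pedigree")
        self.topo_order = self._toposort()
        self._topo_index = {iid: i for i, iid in enumerate(self.topo_order)}
        self._phi_cache: dict[tuple[str, str], float] = {}

    def _toposort(self) -> list[str]:
        order, state = [], {}

        def visit(node, stack):
            if state.get(node) == 2:
                return
            if state.get(node) == 1:
                cycle = stack[stack.index(node):] + [node]
                raise ValueError(f"pedigree contains a cycle: {' -> '.join(cycle)}")
            state[node] = 1
            stack.append(node)
            for p in self.parents[node]:
                if p is not None:
                    visit(p, stack)
            stack.pop()
            state[node] = 2
            order.append(node)

        for iid in self.parents:
            visit(iid, [])
        return order

    def __contains__(self, iid: str) -> bool:
        return iid in self.parents

    @property
    def members(self) -> list[str]:
        return list(self.topo_order)

    def is_founder(self, iid: str) -> bool:
        return self.parents[iid][0] is None

    def founders(self) -> list[str]:
        return [i for i in self.topo_order if self.is_founder(i)]

    def ancestors_closure(self, ids: Sequence[str]) -> list[str]:
        """ids plus all their ancestors, in topological order."""
        seen: set[str] = set()
        stack = list(ids)
        while stack:
            iid = stack.pop()
            if iid in seen:
                continue
            seen.add(iid)
            stack.extend(p for p in self.parents[iid] if p is not None)
        return [i for i in self.topo_order if i in seen]

    def _check(self, iid: str) -> None:
        if iid not in self.parents:
            raise KeyError(f"unknown individual {iid!r}")


def pedigree_phi(ped: Pedigree, a: str, b: str) -> float:
    """Exact kinship coefficient by the classical recursion.

    Founders are taken unrelated and non-inbred. phi(a, a) =
    (1 + phi(sire, dam)) / 2; for distinct individuals the one appearing
    later in topological order is expanded onto its parents.
    """
    ped._check(a)
    ped._check(b)

    def phi(x: str | None, y: str | None) -> float:
        if x is None or y is None:
            return 0.0
        key = (x, y) if ped._topo_index[x] <= ped._topo_index[y] else (y, x)
        if key in ped._phi_cache:
            return ped._phi_cache[key]
        if x == y:
            sire, dam = ped.parents[x]
            val = 0.5 * (1 + phi(sire, dam))
        else:
            # expand the later (younger) individual first
            lo, hi = key
            if ped.is_founder(hi):
                val = 0.0 if ped.is_founder(lo) else _expand(lo, hi)
            else:
                val = _expand(hi, lo)
        ped._phi_cache[key] = val
        return val

    def _expand(child: str, other: str) -> float:
        sire, dam = ped.parents[child]
        return 0.5 * (phi(sire, other) + phi(dam, other))

    return phi(a, b)


def is_inbred(ped: Pedigree, iid: str, tol: float = 0.0) -> bool:
    sire, dam = ped.parents[iid]
    if sire is None:
        return False
    return pedigree_phi(ped, sire, dam) > tol


def _transmission_bits(ped, closure):
    """Non-founder list and total transmission count for a closure."""
    nonfounders = [i for i in closure if not ped.is_founder(i)]
    return nonfounders, 2 * len(nonfounders)


def _propagate_alleles(ped, closure, bits):
    """Drop founder allele labels through the closure for each bit vector.

    ``bits`` has shape (N, T) with two columns per non-founder (sire pick,
    dam pick). Returns {individual: (N, 2) allele-label array}.
    """
    nonfounders, _ = _transmission_bits(ped, closure)
    col = {iid: 2 * t for t, iid in enumerate(nonfounders)}
    N = bits.shape[0]
    alleles: dict[str, np.ndarray] = {}
    label = 0
    rows = np.arange(N)
    for iid in closure:
        if ped.is_founder(iid):
            arr = np.empty((N, 2), dtype=np.int32)
            arr[:, 0] = label
            arr[:, 1] = label + 1
            label += 2
        else:
            sire, dam = ped.parents[iid]
            c = col[iid]
            arr = np.empty((N, 2), dtype=np.int32)
            arr[:, 0] = alleles[sire][rows, bits[:, c]]
            arr[:, 1] = alleles[dam][rows, bits[:, c + 1]]
        alleles[iid] = arr
    return alleles


def _deltas_from_alleles(alleles, a, b) -> tuple[float, float, float]:
    aa, bb = alleles[a], alleles[b]
    shared = (
        (aa[:, 0] == bb[:, 0]).astype(np.int8)
        + (aa[:, 0] == bb[:, 1])
        + (aa[:, 1] == bb[:, 0])
        + (aa[:, 1] == bb[:, 1])
    )
    counts = np.bincount(shared, minlength=3)
    d = counts / counts.sum()
    return float(d[0]), float(d[1]), float(d[2])


def pedigree_deltas(
    ped: Pedigree,
    a: str,
    b: str,
    method: str = "auto",
    max_transmissions: int = 20,
    n_draws: int = 500_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Exact IBD-sharing probabilities by inheritance-vector enumeration.

    Every parent-to-child transmission in the joint ancestor closure of
    ``{a, b}`` is a fair coin; enumerating all 2^T vectors and counting
    how many of a's alleles are identical by descent to b's gives
    (delta0, delta1, delta2) exactly. Pedigrees with more than
    ``max_transmissions`` transmissions fall back to seeded Monte Carlo
    (``method="monte_carlo"`` forces it). Inbred endpoints are rejected:
    condensed identity coefficients are out of scope.
    """
    ped._check(a)
    ped._check(b)
    for iid in (a, b):
        if is_inbred(ped, iid):
            raise ValueError(
                f"individual {iid!r} is inbred; only the nine-state condensed "
                "coefficients would be exact, and those are not supported"
            )
    closure = ped.ancestors_closure([a, b])
    _, T = _transmission_bits(ped, closure)
    if method not in ("auto", "exact", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    use_exact = method == "exact" or (method == "auto" and T <= max_transmissions)
    if method == "exact" and T > max_transmissions:
        raise ValueError(
            f"{T} transmissions exceed the enumeration cap "
            f"({max_transmissions}); use method='monte_carlo'"
        )
    if use_exact:
        if T == 0:
            bits = np.zeros((1, 0), dtype=np.int8)
        else:
            n = 1 << T
            bits = ((np.arange(n, dtype=np.int64)[:, None] >> np.arange(T)) & 1).astype(
                np.int8
            )
    else:
        rng = np.random.default_rng(seed)
        bits = rng.integers(0, 2, size=(n_draws, max(T, 1)), dtype=np.int8)
        if T == 0:
            bits = bits[:, :0]
    alleles = _propagate_alleles(ped, closure, bits)
    return _deltas_from_alleles(alleles, a, b)


def expected_table(ped: Pedigree, pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """Pedigree-expected kinship, IBD deltas and relationship degree per pair.

    Degree is ``round(-log2(2 phi))`` (1 = parent/offspring or full sib,
    2 = grandparent/half-sib, ...), or "unrelated" when phi is zero.
    """
    rows = []
    for a, b in pairs:
        phi = pedigree_phi(ped, a, b)
        d0, d1, d2 = pedigree_deltas(ped, a, b)
        degree = str(int(round(-np.log2(2 * phi)))) if phi > 0 else "unrelated"
        rows.append(
            {"id_a": a, "id_b": b, "phi_exp": phi,
             "delta0": d0, "delta1": d1, "delta2": d2, "degree": degree}
        )
    return pd.DataFrame(rows)
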