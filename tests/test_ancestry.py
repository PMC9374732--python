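import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from identikin.containers import MISSING, GenotypeMatrix
from identikin.ancestry import (
    AdmixtureModel,
    classify_species,
    cv_error,
    filter_probes,
    filter_variants,
    ld_prune,
    panel_freqs,
    sample_variants,
    supervised_admixture,
    supervised_q,
    unsupervised_admixture,
)
from identikin.synthdata import simulate_genotypes


def _gm(dosages, chroms=None, alts=None):
    d = np.asarray(dosages, dtype=np.int16)
    n, m = d.shape
    variants = pd.DataFrame(
        {
            "chrom": chroms or ["1"] * m,
            "pos": np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": alts or ["G"] * m,
        }
    )
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)], variants=variants,
                          dosages=d)


# ---------------------------------------------------------------------------
# variant filtering
# ---------------------------------------------------------------------------

def test_filter_drops_monomorphic_sites():
    gm = _gm(np.zeros((10, 1)))
    assert filter_variants(gm, maf_min=0.05).n_variants == 0


def test_maf_threshold_is_inclusive():
    # 19 alt / 1 ref alleles in 10 diploids -> MAF exactly 0.05
    col = np.full(10, 2)
    col[0] = 1
    gm = _gm(col[:, None])
    assert filter_variants(gm, maf_min=0.05).n_variants == 1
    assert filter_variants(gm, maf_min=0.051).n_variants == 0


def test_filter_completeness_multiallelic_and_autosomes():
    d = np.array([[1, 1, 1, 1], [MISSING, 1, 1, 1], [1, 1, 1, 1]])
    gm = _gm(d, chroms=["1", "1", "X", "1"], alts=["G", "G,T", "G", "G"])
    out = filter_variants(gm, maf_min=0.0)
    # col0: missing call; col1: multi-allelic; col2: X chromosome
    assert out.n_variants == 1
    out2 = filter_variants(gm, maf_min=0.0, require_complete=False,
                           autosomes_only=False)
    assert out2.n_variants == 3


def test_sample_variants_identity_empty_and_determinism(small_gm):
    assert sample_variants(small_gm, small_gm.n_variants, seed=1).n_variants == (
        small_gm.n_variants
    )
    assert sample_variants(small_gm, 0, seed=1).n_variants == 0
    a = sample_variants(small_gm, 10, seed=2)
    b = sample_variants(small_gm, 10, seed=2)
    assert a.variants.equals(b.variants)
    with pytest.raises(ValueError):
        sample_variants(small_gm, small_gm.n_variants + 1, seed=1)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def test_duplicated_snp_keeps_exactly_one_copy():
    rng = np.random.default_rng(0)
    col = rng.integers(0, 3, size=20)
    gm = _gm(np.column_stack([col, col]))
    out = ld_prune(gm, window_snps=10, step_snps=5, r2_max=0.1)
    assert out.n_variants == 1


def test_independent_snps_are_all_retained():
    rng = np.random.default_rng(1)
    # enough samples that chance r2 stays below the threshold
    d = rng.binomial(2, 0.5, size=(400, 30))
    gm = _gm(d)
    centered = d - d.mean(0)
    corr = np.corrcoef(centered.T) ** 2
    np.fill_diagonal(corr, 0)
    assert corr.max() < 0.1  # precondition for the check
    out = ld_prune(gm, window_snps=30, step_snps=5, r2_max=0.1)
    assert out.n_variants == 30


def test_three_snps_one_correlated_pair_keeps_two():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 3, size=50)
    b = rng.permutation(a)  # independent of a, same margin
    gm = _gm(np.column_stack([a, a, b]))
    out = ld_prune(gm, window_snps=3, step_snps=1, r2_max=0.1)
    assert out.n_variants == 2


def test_pruned_output_rescans_clean():
    """Re-scanning the pruned output with the pruning sweep's own window
    geometry finds no pair above the threshold."""
    from identikin.ancestry import max_window_r2
    from identikin.synthdata import add_ld_duplicates

    rng = np.random.default_rng(33)
    base = _gm(rng.binomial(2, 0.4, size=(30, 40)))
    gm = add_ld_duplicates(base, n_dup=8, flip_rate=0.05, seed=3)
    out = ld_prune(gm, window_snps=10, step_snps=3, r2_max=0.5)
    assert max_window_r2(out, gm, window_snps=10, step_snps=3) <= 0.5 + 1e-9


def test_prune_parameter_validation(small_gm):
    with pytest.raises(ValueError):
        ld_prune(small_gm, window_snps=1)
    with pytest.raises(ValueError):
        ld_prune(small_gm, r2_max=0.0)


# ---------------------------------------------------------------------------
# panel frequencies
# ---------------------------------------------------------------------------

def test_panel_freqs_pseudocount_arithmetic():
    gm = _gm(np.array([[2, 2], [2, 0]]))
    model = panel_freqs(gm, {"s0": "p", "s1": "p"})
    # alt counts 4 and 2 over 4 alleles: (4+0.5)/5, (2+0.5)/5
    assert model.freqs[0, 0] == pytest.approx(0.9)
    assert model.freqs[0, 1] == pytest.approx(0.5)


def test_panel_freqs_clamps_and_rejects_empty_pop():
    gm = _gm(np.zeros((50, 1)))
    model = panel_freqs(gm, {f"s{i}": "p" for i in range(50)})
    assert 0 < model.freqs[0, 0] < 0.01
    with pytest.raises(ValueError, match="no panel samples"):
        panel_freqs(gm, {f"s{i}": "p" for i in range(50)} | {"ghost": "q"})


# ---------------------------------------------------------------------------
# supervised fits
# ---------------------------------------------------------------------------

def test_supervised_q_k1_is_trivial():
    model = AdmixtureModel(pops=["p"], freqs=np.full((1, 10), 0.5))
    q = supervised_q(np.ones(10), model)
    assert q == pytest.approx([1.0])


def test_supervised_q_recovers_pure_ancestry(three_pop_freqs):
    gm = simulate_genotypes(three_pop_freqs, np.array([[1.0, 0, 0]]), seed=30)
    model = AdmixtureModel(pops=list("abc"), freqs=three_pop_freqs)
    q, trace = supervised_q(
        gm.dosages[0].astype(float), model, tol=1e-8, max_iter=3000,
        return_trace=True,
    )
    assert q[0] > 0.95
    assert np.all(np.diff(trace) >= -1e-8)  # EM never decreases the loglik


def test_supervised_q_recovers_admixture(three_pop_freqs):
    errs = []
    for seed in range(3):
        gm = simulate_genotypes(
            three_pop_freqs, np.array([[0.5, 0.5, 0.0]]), seed=40 + seed
        )
        model = AdmixtureModel(pops=list("abc"), freqs=three_pop_freqs)
        q = supervised_q(gm.dosages[0].astype(float), model, tol=1e-8,
                         max_iter=3000)
        errs.append(np.abs(q - [0.5, 0.5, 0.0]).max())
    assert np.mean(errs) < 0.05


def test_supervised_q_rejects_missing_genotypes(three_pop_freqs):
    model = AdmixtureModel(pops=list("abc"), freqs=three_pop_freqs)
    g = np.zeros(three_pop_freqs.shape[1])
    g[0] = MISSING
    with pytest.raises(ValueError, match="complete"):
        supervised_q(g, model)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_ancestry_vectors_lie_on_the_simplex(seed):
    rng = np.random.default_rng(seed)
    F = np.clip(rng.random((3, 120)), 1e-6, 1 - 1e-6)
    g = rng.binomial(2, F[rng.integers(3)]).astype(float)
    model = AdmixtureModel(pops=list("abc"), freqs=F)
    q = supervised_q(g, model, max_iter=150)
    assert np.all(q >= -1e-12)
    assert np.isclose(q.sum(), 1.0, atol=1e-9)


def test_joint_supervised_fit_is_monotone_and_accurate(three_pop_freqs):
    rng_q = np.repeat(np.eye(3), 5, axis=0)
    panel = simulate_genotypes(three_pop_freqs, rng_q, seed=50)
    queries = simulate_genotypes(
        three_pop_freqs, np.array([[1, 0, 0], [0.5, 0.5, 0]]), seed=51
    )
    Q, model, trace = supervised_admixture(
        panel.dosages.astype(float),
        ["a"] * 5 + ["b"] * 5 + ["c"] * 5,
        queries.dosages.astype(float),
        tol=1e-7, max_iter=4000, return_trace=True,
    )
    assert np.all(np.diff(trace) >= -1e-6)
    assert Q[0, 0] > 0.9
    assert abs(Q[1, 0] - 0.5) < 0.1 and abs(Q[1, 1] - 0.5) < 0.1


# ---------------------------------------------------------------------------
# unsupervised fits + CV
# ---------------------------------------------------------------------------

def test_unsupervised_k1_closed_form(small_gm):
    Q, F = unsupervised_admixture(small_gm, K=1, seed=1, max_iter=50)
    assert np.allclose(Q, 1.0)
    pooled = small_gm.dosages.mean(0) / 2
    assert np.abs(F[0] - np.clip(pooled, 1e-6, 1 - 1e-6)).max() < 1e-6


def test_unsupervised_recovers_two_populations():
    from identikin.synthdata import balding_nichols_freqs, sample_ancestral_freqs

    # well-separated populations: strong divergence, 10 samples each
    anc = sample_ancestral_freqs(2000, seed=61)
    F2 = balding_nichols_freqs(anc, 0.3, 2, seed=62)
    Q_true = np.repeat(np.eye(2), 10, axis=0)
    gm = simulate_genotypes(F2, Q_true, seed=60)
    Q, F, trace = unsupervised_admixture(
        gm, K=2, seed=3, tol=1e-6, max_iter=3000, return_trace=True
    )
    assert np.all(np.diff(trace) >= -1e-6)
    err_direct = np.abs(Q - Q_true).max()
    err_swapped = np.abs(Q - Q_true[:, ::-1]).max()
    assert min(err_direct, err_swapped) < 0.05  # labels are unidentifiable


def test_unsupervised_rejects_k_above_n(small_gm):
    with pytest.raises(ValueError):
        unsupervised_admixture(small_gm, K=small_gm.n_samples + 1, seed=1)


def test_cv_error_is_deterministic_and_validates(three_pop_freqs):
    gm = simulate_genotypes(
        three_pop_freqs[:, :300], np.repeat(np.eye(3), 4, axis=0), seed=70
    )
    a = cv_error(gm, K=2, n_folds=3, n_boot=1, seed=9, max_iter=60)
    b = cv_error(gm, K=2, n_folds=3, n_boot=1, seed=9, max_iter=60)
    assert a == b
    assert a[1] == 0.0  # single repetition has no spread
    with pytest.raises(ValueError):
        cv_error(gm, K=2, n_folds=1, seed=9)


# ---------------------------------------------------------------------------
# species calls + probe QC
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "q,expected",
    [([1, 0, 0], "a"), ([0.5, 0.5, 0], "admixed"), ([0.86, 0.1, 0.04], "a")],
)
def test_classify_species(q, expected):
    assert classify_species(np.array(q), ["a", "b", "c"]) == expected


def _probe(pid="p1", **overrides):
    base = {
        "probe_id": pid, "meanR_AA": 0.5, "meanR_AB": 0.5, "meanR_BB": 0.5,
        "Cluster_Sep": 0.5, "meanTHETA_AA": 0.05, "meanTHETA_AB": 0.5,
        "meanTHETA_BB": 0.95, "devTHETA_AA": 0.01, "devTHETA_AB": 0.05,
        "devTHETA_BB": 0.01, "GenTrain_Score": 0.8,
    }
    base.update(overrides)
    return base


def test_probe_filter_exclusion_semantics():
    stats = pd.DataFrame(
        [
            _probe("good"),
            _probe("dim_het", meanR_AB=0.1),  # low het intensity
            _probe("boundary", GenTrain_Score=0.69),
            _probe("theta_shift", meanTHETA_AB=0.8),
        ]
    )
    retained, reasons = filter_probes(stats, with_reasons=True)
    assert retained == ["good"]
    assert "meanR_AB < 0.2" in reasons["dim_het"]
    assert "GenTrain_Score < 0.7" in reasons["boundary"]
    assert any("meanTHETA_AB" in r for r in reasons["theta_shift"])


def test_probe_with_missing_stat_is_excluded_as_incomplete():
    row = _probe("nan_probe")
    row["Cluster_Sep"] = np.nan
    retained, reasons = filter_probes(pd.DataFrame([row]), with_reasons=True)
    assert retained == []
    assert reasons["nan_probe"] == ["incomplete"]
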