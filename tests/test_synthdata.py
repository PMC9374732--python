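import numpy as np
import pytest

from identikin.containers import GenotypeMatrix
from identikin.kinship import Pedigree, kinship_phi
from identikin.synthdata import (
    PopulationModel,
    make_variant_table,
    ScenarioConfig,
    add_ld_duplicates,
    balding_nichols_freqs,
    drop_genes,
    make_scenario,
    sample_ancestral_freqs,
    simulate_chrom_counts,
    simulate_genotypes,
)


# ---------------------------------------------------------------------------
# ancestral / population frequencies
# ---------------------------------------------------------------------------

def test_ancestral_freqs_edge_cases_and_lln():
    assert sample_ancestral_freqs(0, 0.1, 0.9, seed=1).size == 0
    assert np.all(sample_ancestral_freqs(5, 0.5, 0.5, seed=1) == 0.5)
    p = sample_ancestral_freqs(10_000, 0.05, 0.95, seed=1)
    se = np.sqrt((0.95 - 0.05) ** 2 / 12 / 10_000)
    assert abs(p.mean() - 0.5) < 3 * se
    with pytest.raises(ValueError):
        sample_ancestral_freqs(-1, 0.1, 0.9, seed=1)


def test_balding_nichols_mean_and_zero_divergence_limit():
    anc = sample_ancestral_freqs(20_000, 0.2, 0.8, seed=2)
    F = balding_nichols_freqs(anc, 1e-6, 2, seed=3)
    assert np.abs(F - anc).max() < 0.01  # fst -> 0 pins f at p
    F2 = balding_nichols_freqs(anc, 0.1, 2, seed=4)
    # Beta mean is the ancestral frequency
    assert abs((F2[0] - anc).mean()) < 0.005
    with pytest.raises(ValueError):
        balding_nichols_freqs(anc, 1.5, 2, seed=5)


def _hudson_fst(F, counts_per_pop, seed):
    """Independent oracle: Hudson estimator from simulated genotype counts."""
    rng = np.random.default_rng(seed)
    n = counts_per_pop
    p1 = rng.binomial(2 * n, F[0]) / (2 * n)
    p2 = rng.binomial(2 * n, F[1]) / (2 * n)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n - 1) - p2 * (1 - p2) / (2 * n - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num.sum() / den.sum()


def test_generated_freqs_recover_target_fst():
    """Hudson Fst over 10^4 SNPs matches the divergence parameter."""
    anc = sample_ancestral_freqs(10_000, 0.1, 0.9, seed=6)
    F = balding_nichols_freqs(anc, 0.1, 2, seed=7)
    fst_hat = _hudson_fst(F, counts_per_pop=500, seed=8)
    assert abs(fst_hat - 0.1) < 0.02


def test_population_model_validation():
    with pytest.raises(ValueError):
        PopulationModel(n_pops=0, n_snps=1, ancestral_freqs=np.array([0.5]), fst=0.1)
    with pytest.raises(ValueError):
        PopulationModel(n_pops=2, n_snps=1, ancestral_freqs=np.array([0.0]), fst=0.1)


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------

def test_simulate_genotypes_fixed_allele_and_mean():
    F = np.full((1, 10_000), 0.999999)
    gm = simulate_genotypes(F, np.array([[1.0]]), seed=1)
    assert np.all(gm.dosages == 2)
    F2 = np.vstack([np.full(10_000, 0.2), np.full(10_000, 0.6)])
    gm2 = simulate_genotypes(F2, np.array([[0.5, 0.5]]), seed=2)
    # binomial mean: 2 * (0.5*0.2 + 0.5*0.6) = 0.8
    assert abs(gm2.dosages.mean() - 0.8) < 0.03


def test_simulate_genotypes_determinism_and_dim_check():
    F = np.full((2, 50), 0.5)
    Q = np.tile([0.5, 0.5], (3, 1))
    a = simulate_genotypes(F, Q, seed=9)
    b = simulate_genotypes(F, Q, seed=9)
    assert np.array_equal(a.dosages, b.dosages)
    with pytest.raises(ValueError):
        simulate_genotypes(F, np.ones((3, 3)) / 3, seed=9)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def test_drop_genes_forced_transmission():
    ped = Pedigree([("P1", None, None), ("P2", None, None), ("C", "P1", "P2")])
    founders = GenotypeMatrix(
        samples=["P1", "P2"],
        variants=make_variant_table(4),
        dosages=np.full((2, 4), 2, dtype=np.int16),
    )
    out = drop_genes(ped, founders, seed=0)
    assert np.all(out.row("C") == 2)


def test_drop_genes_empirical_kinship_matches_pedigree():
    """Parent-offspring and grandparent kinship from dropped genes."""
    M = 100_000
    anc = sample_ancestral_freqs(M, 0.1, 0.9, seed=20)
    F = balding_nichols_freqs(anc, 0.1, 1, seed=21)
    ped = Pedigree(
        [("A", None, None), ("Am", None, None), ("B", "A", "Am"),
         ("Bm", None, None), ("C", "B", "Bm")]
    )
    founders = simulate_genotypes(
        F, np.ones((3, 1)), seed=22, sample_ids=["A", "Am", "Bm"]
    )
    gm = drop_genes(ped, founders, seed=23)
    mu = np.clip(F[0], 1e-6, 1 - 1e-6)
    po = kinship_phi(gm.row("A").astype(float), gm.row("B").astype(float), mu, mu)
    gp = kinship_phi(gm.row("A").astype(float), gm.row("C").astype(float), mu, mu)
    assert abs(po - 0.25) < 0.02
    assert abs(gp - 0.125) < 0.02


def test_drop_genes_rejects_missing_founders_and_half_parents():
    ped = Pedigree([("P1", None, None), ("P2", None, None), ("C", "P1", "P2")])
    founders = GenotypeMatrix(
        samples=["P1"],
        variants=make_variant_table(2),
        dosages=np.zeros((1, 2), dtype=np.int16),
    )
    with pytest.raises(ValueError, match="founders lack genotypes"):
        drop_genes(ped, founders, seed=0)
    with pytest.raises(ValueError, match="one recorded parent"):
        Pedigree([("P1", None, None), ("C", "P1", None)])


# ---------------------------------------------------------------------------
# chromosome counts
# ---------------------------------------------------------------------------

def test_chrom_counts_sex_structure():
    f0 = simulate_chrom_counts("female", 2.0, 0.0, seed=1)
    assert f0.get("Y")["mapped"] == 0  # no mismapping, no Y reads
    m = simulate_chrom_counts("male", 2.0, 0.01, seed=2)
    x, y = m.get("X"), m.get("Y")
    ratio = (x["mapped"] / x["length"]) / (y["mapped"] / y["length"])
    assert 0.9 < ratio < 1.1  # one copy each, length-normalized
    f = simulate_chrom_counts("female", 2.0, 0.01, seed=3)
    xf, yf = f.get("X"), f.get("Y")
    ratio_f = (xf["mapped"] / xf["length"]) / (yf["mapped"] / yf["length"])
    assert ratio_f > 5 * ratio
    with pytest.raises(ValueError, match="unknown sex"):
        simulate_chrom_counts("other", 2.0, 0.01, seed=4)


# ---------------------------------------------------------------------------
# LD duplicates
# ---------------------------------------------------------------------------

def test_ld_duplicates_create_high_r2_pairs(small_gm):
    out = add_ld_duplicates(small_gm, n_dup=5, flip_rate=0.0, seed=1)
    assert out.n_variants == small_gm.n_variants + 5
    # a zero-noise duplicate is a perfectly correlated column
    pos = out.variants["pos"].to_numpy()
    dup_idx = np.flatnonzero(np.diff(pos) == 1)
    assert len(dup_idx) >= 5


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def _small_config(**kw):
    kw.setdefault("n_snps", 800)
    return ScenarioConfig(**kw)


def test_zero_swaps_reported_metadata_equals_truth():
    sc = make_scenario(_small_config(n_swaps=0), seed=3)
    for rec in sc.reported:
        assert rec.name == sc.truth.planted_permutation[rec.biosample]


def test_default_scenario_mirrors_study_layout():
    sc = make_scenario(_small_config(), seed=4)
    assert len(sc.query_samples) == 10
    assert len(sc.panel_samples) == 27
    assert len(sc.relative_samples) == 8
    mislabeled = sum(
        rec.name != sc.truth.planted_permutation[rec.biosample]
        for rec in sc.reported
    )
    assert mislabeled == 9
    # relatives cover seven of the ten queries; records cover the rest
    assert len(sc.records) == 3


def test_planted_permutation_is_a_bijection_and_round_trips():
    sc = make_scenario(_small_config(), seed=5)
    reported_names = [r.name for r in sc.reported]
    true_names = [sc.truth.planted_permutation[r.biosample] for r in sc.reported]
    assert sorted(reported_names) == sorted(true_names)
    # reported metadata is exactly the reported individual's registry data
    for rec in sc.reported:
        ind = sc.registry[rec.name]
        assert (rec.species, rec.sex) == (ind.species, ind.sex)


def test_scenario_is_deterministic_given_seed():
    a = make_scenario(_small_config(), seed=6)
    b = make_scenario(_small_config(), seed=6)
    assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
    assert a.truth.planted_permutation == b.truth.planted_permutation
    assert [r.name for r in a.reported] == [r.name for r in b.reported]
    ca = a.chrom_counts[a.query_samples[0]].table["mapped"].to_numpy()
    cb = b.chrom_counts[b.query_samples[0]].table["mapped"].to_numpy()
    assert np.array_equal(ca, cb)


def test_infeasible_swap_count_is_rejected():
    with pytest.raises(ValueError, match="swaps"):
        make_scenario(_small_config(n_swaps=11), seed=1)


def test_true_q_vectors_lie_on_the_simplex():
    sc = make_scenario(_small_config(), seed=7)
    for q in sc.truth.true_q.values():
        assert np.all(np.asarray(q) >= 0)
        assert np.isclose(np.sum(q), 1.0)
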