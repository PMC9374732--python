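"""Synthetic study scenarios for the identity-verification pipeline.

Emulates the structure of the real study: three diverged source
populations (Bornean / Sumatran / Tapanuli analogues under a
Balding-Nichols divergence model), a labeled reference panel, ten query
samples whose reported metadata carries a planted label permutation,
genotyped relatives connected to most queries through small pedigrees,
and per-chromosome mapped-read counts that separate the sexes. Every
downstream stage of the pipeline is therefore testable against a known
ground truth without any external data.

All randomness flows from one scenario seed through named substreams, so
each generation stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ChromCounts, GenotypeMatrix, MISSING
from .kinship import Pedigree, pedigree_phi
from .resolve import Individual, Registry, RelativeLink, SampleRecord

# named substreams off the scenario seed
_STREAMS = {
    "ancestral": 11, "bn": 12, "panel": 13, "founders": 14, "drop": 15,
    "counts": 16, "perm": 17, "variants": 18, "ld": 19, "sexflip": 20,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from the scenario seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


# ---------------------------------------------------------------------------
# population model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """K diverged populations around shared ancestral frequencies."""

    n_pops: int
    n_snps: int
    ancestral_freqs: np.ndarray
    fst: float

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        p = np.asarray(self.ancestral_freqs)
        if p.size != self.n_snps or ((p <= 0) | (p >= 1)).any():
            raise ValueError("ancestral_freqs must be length n_snps, strictly in (0,1)")
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie strictly in (0, 1)")


def sample_ancestral_freqs(
    n_snps: int, lo: float = 0.05, hi: float = 0.95, seed: int = 0
) -> np.ndarray:
    """i.i.d. uniform ancestral allele frequencies on [lo, hi]."""
    if n_snps < 0:
        raise ValueError("n_snps must be non-negative")
    if not 0 < lo <= hi < 1:
        raise ValueError("need 0 < lo <= hi < 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(lo, hi, size=n_snps)


def balding_nichols_freqs(
    ancestral: np.ndarray, fst: float, n_pops: int, seed: int = 0
) -> np.ndarray:
    """Population frequencies drifted around the ancestral values.

    Each ``f_km`` is Beta(p(1-fst)/fst, (1-p)(1-fst)/fst), which has mean
    p and variance ``fst * p(1-p)``; entries are clamped away from the
    boundary so downstream likelihoods stay finite.
    """
    if not 0 < fst < 1:
        raise ValueError("fst must lie strictly in (0, 1)")
    p = np.asarray(ancestral, dtype=float)
    rng = np.random.default_rng(seed)
    scale = (1 - fst) / fst
    F = rng.beta(p * scale, (1 - p) * scale, size=(n_pops, p.size))
    return np.clip(F, 1e-6, 1 - 1e-6)


def make_variant_table(n_snps: int, n_chroms: int = 22, spacing: int = 5000) -> pd.DataFrame:
    """Evenly spaced synthetic autosomal SNP coordinates (A>G throughout)."""
    per = int(np.ceil(n_snps / n_chroms))
    chroms, pos = [], []
    for c in range(1, n_chroms + 1):
        take = min(per, n_snps - len(chroms))
        chroms += [str(c)] * take
        pos += [spacing * (i + 1) for i in range(take)]
        if len(chroms) >= n_snps:
            break
    return pd.DataFrame(
        {"chrom": chroms, "pos": pos, "ref": "A", "alt": "G"}
    )


def simulate_genotypes(
    F: np.ndarray,
    Q: np.ndarray,
    seed: int,
    sample_ids: list[str] | None = None,
    variants: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Binomial genotypes under the admixture model: g ~ Bin(2, q_i . f_m)."""
    F = np.asarray(F, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or F.ndim != 2 or Q.shape[1] != F.shape[0]:
        raise ValueError(
            f"Q {Q.shape} and F {F.shape} are dimension-incompatible"
        )
    if not np.allclose(Q.sum(axis=1), 1):
        raise ValueError("rows of Q must lie on the simplex")
    rng = np.random.default_rng(seed)
    P = Q @ F
    G = rng.binomial(2, P).astype(np.int16)
    n, M = G.shape
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n)]
    if variants is None:
        variants = make_variant_table(M)
    return GenotypeMatrix(samples=sample_ids, variants=variants, dosages=G)


# ---------------------------------------------------------------------------
# gene dropping
# ---------------------------------------------------------------------------

def drop_genes(
    pedigree: Pedigree, founder_genotypes: GenotypeMatrix, seed: int
) -> GenotypeMatrix:
    """Mendelian gene dropping: each non-founder receives one uniformly chosen
    allele from each parent, independently per SNP; founders pass through.

    Founder dosages are split into unordered allele pairs (a het is one
    ref plus one alt allele), then transmissions are simulated down the
    topological order. Returns genotypes for every pedigree member.
    """
    rng = np.random.default_rng(seed)
    missing_founders = set(pedigree.founders()) - set(founder_genotypes.samples)
    if missing_founders:
        raise ValueError(f"founders lack genotypes: {sorted(missing_founders)}")
    M = founder_genotypes.n_variants
    alleles: dict[str, np.ndarray] = {}  # id -> (2, M) int8 of 0/1 alleles
    for iid in pedigree.topo_order:
        if pedigree.is_founder(iid):
            g = founder_genotypes.row(iid)
            if (g == MISSING).any():
                raise ValueError(f"founder {iid!r} has missing genotypes")
            a = np.zeros((2, M), dtype=np.int8)
            a[0] = g >= 1
            a[1] = g == 2
            alleles[iid] = a
        else:
            sire, dam = pedigree.parents[iid]
            picks = rng.integers(0, 2, size=(2, M))
            a = np.empty((2, M), dtype=np.int8)
            cols = np.arange(M)
            a[0] = alleles[sire][picks[0], cols]
            a[1] = alleles[dam][picks[1], cols]
            alleles[iid] = a
    members = pedigree.topo_order
    dosages = np.vstack([alleles[i].sum(axis=0, dtype=np.int16) for i in members])
    return GenotypeMatrix(
        samples=list(members),
        variants=founder_genotypes.variants.copy(),
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# chromosome read counts
# ---------------------------------------------------------------------------

def default_chrom_lengths() -> dict[str, int]:
    """Chromosome length table with great-ape-like magnitudes (bp)."""
    lengths = {
        str(i + 1): int(l)
        for i, l in enumerate(
            np.linspace(230e6, 50e6, 22)
        )
    }
    lengths["X"] = 140_000_000
    lengths["Y"] = 26_000_000
    return lengths


#: nominal read length used to convert depth x length into read counts
READ_LENGTH = 100


def simulate_chrom_counts(
    sex: str,
    mean_depth: float,
    mismap_rate: float,
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
    sample: str = "sample",
) -> ChromCounts:
    """Poisson per-chromosome mapped-read counts for one individual.

    Expected counts are proportional to chromosome length, sequencing
    depth, and copy number (2 for autosomes; X: 2 female / 1 male; Y: 1
    male, ``2 * mismap_rate`` female, modelling reads mismapped onto Y).
    """
    if sex not in ("male", "female"):
        raise ValueError(f"unknown sex label {sex!r}")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not 0 <= mismap_rate < 0.1:
        raise ValueError("mismap_rate must lie in [0, 0.1)")
    if chrom_lengths is None:
        chrom_lengths = default_chrom_lengths()
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in chrom_lengths.items():
        if chrom == "X":
            copies = 2.0 if sex == "female" else 1.0
        elif chrom == "Y":
            copies = 1.0 if sex == "male" else 2.0 * mismap_rate
        else:
            copies = 2.0
        lam = mean_depth * length * copies / (2 * READ_LENGTH)
        rows.append(
            {"chrom": chrom, "length": int(length),
             "mapped": int(rng.poisson(lam)), "unmapped": 0}
        )
    return ChromCounts(sample=sample, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# LD block synthesis (pruning exercise)
# ---------------------------------------------------------------------------

def add_ld_duplicates(
    gm: GenotypeMatrix, n_dup: int, flip_rate: float = 0.02, seed: int = 0
) -> GenotypeMatrix:
    """Insert near-duplicate SNP columns to create high-LD pairs.

    ``n_dup`` randomly chosen SNPs are copied next to their source with a
    small per-genotype copy noise (each dosage resampled with probability
    ``flip_rate``), producing pairs with r-squared near 1 for LD-pruning
    tests. SNPs are unlinked by construction otherwise.
    """
    rng = np.random.default_rng(seed)
    src = np.sort(rng.choice(gm.n_variants, size=n_dup, replace=False))
    var = gm.variants
    new_cols, new_vars, order_keys = [], [], []
    for j in range(gm.n_variants):
        new_cols.append(gm.dosages[:, j])
        new_vars.append(var.iloc[j])
        order_keys.append((var.iloc[j]["chrom"], var.iloc[j]["pos"], 0))
    for j in src:
        col = gm.dosages[:, j].copy()
        flip = rng.random(gm.n_samples) < flip_rate
        col[flip] = rng.integers(0, 3, size=int(flip.sum()))
        rec = var.iloc[j].copy()
        rec["pos"] = int(rec["pos"]) + 1
        new_cols.append(col)
        new_vars.append(rec)
        order_keys.append((rec["chrom"], rec["pos"], 1))
    order = np.argsort(
        pd.Series(order_keys).map(lambda t: (str(t[0]).zfill(4), t[1], t[2]))
    ).to_numpy()
    return GenotypeMatrix(
        samples=list(gm.samples),
        variants=pd.DataFrame([new_vars[i] for i in order]).reset_index(drop=True),
        dosages=np.column_stack([new_cols[i] for i in order]),
    )


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

#: the ten query individuals mirror the study's mix: five Bornean, four
#: Sumatran and one Tapanuli analogue, five of each sex.
QUERY_TEMPLATE = (
    ("I01", "bornean", "F"),
    ("I02", "bornean", "M"),
    ("I03", "bornean", "F"),
    ("I04", "bornean", "M"),
    ("I05", "bornean", "M"),
    ("I06", "sumatran", "M"),
    ("I07", "sumatran", "M"),
    ("I08", "sumatran", "F"),
    ("I09", "sumatran", "F"),
    ("I10", "tapanuli", "F"),
)

#: pedigree templates linking genotyped relatives to query individuals,
#: mirroring the degrees in the study's genogram: one grandchild, one
#: child shared by two queries, one grandchild, one great-grandchild,
#: one child, and a child + child + grandchild trio for the last query.
RELATIVE_TEMPLATES = (
    ("R1", "grandchild", ("I02",)),
    ("R2", "child", ("I03", "I04")),
    ("R3", "grandchild", ("I05",)),
    ("R4", "great_grandchild", ("I06",)),
    ("R5", "child", ("I09",)),
    ("R6", "child", ("I10",)),
    ("R7", "child", ("I10",)),
    ("R8", "grandchild", ("I10",)),
)


@dataclass
class ScenarioConfig:
    """Generation parameters; defaults reproduce the study's layout."""

    n_snps: int = 40_000
    fst: float = 0.1
    pop_names: tuple[str, ...] = ("bornean", "sumatran", "tapanuli")
    n_panel_per_pop: int = 9
    n_swaps: int = 9  # queries whose reported label is wrong
    n_sex_flips: int = 0  # additional reported-sex corruptions
    mean_depth: float = 5.0
    mismap_rate: float = 0.01
    freq_lo: float = 0.05
    freq_hi: float = 0.95
    queries: tuple = QUERY_TEMPLATE
    relatives: tuple = RELATIVE_TEMPLATES


@dataclass(frozen=True)
class ScenarioTruth:
    planted_permutation: dict[str, str]  # biosample -> true individual name
    true_sex: dict[str, str]  # individual -> M/F
    true_species: dict[str, str]
    true_q: dict[str, np.ndarray]  # sample/individual -> ancestry vector


@dataclass
class Scenario:
    config: ScenarioConfig
    seed: int
    model: PopulationModel
    pop_freqs: np.ndarray  # (K, M)
    genotypes: GenotypeMatrix  # panel + queries (by biosample) + relatives
    panel_samples: list[str]
    panel_labels: dict[str, str]
    panel_sexes: dict[str, str]  # M/F, known for calibration
    query_samples: list[str]  # biosample ids
    relative_samples: list[str]
    pedigree: Pedigree
    chrom_counts: dict[str, ChromCounts]  # biosample/panel id -> counts
    reported: list[SampleRecord]
    registry: Registry
    records: dict[str, str] = field(default_factory=dict)  # biosample -> candidate
    truth: ScenarioTruth = None

    def query_genotypes(self) -> GenotypeMatrix:
        return self.genotypes.take_samples(self.query_samples)


_KIND_DEPTH = {"child": 1, "grandchild": 2, "great_grandchild": 3}


def _relationship_pedigree(config: ScenarioConfig):
    """Pedigree records + founder roster implied by the relative templates."""
    species_of = {iid: sp for iid, sp, _ in config.queries}
    sex_of = {iid: sx for iid, _, sx in config.queries}
    records = [(iid, None, None, sex_of[iid]) for iid, _, _ in config.queries]
    founders: list[tuple[str, str]] = [
        (iid, species_of[iid]) for iid, _, _ in config.queries
    ]
    aux = 0
    for rel_id, kind, anchors in config.relatives:
        for a in anchors:
            if a not in species_of:
                raise ValueError(f"relative template anchors unknown query {a!r}")
        # mates introduce the other lineage: Sumatran for the Tapanuli
        # query (the captive hybrids), the query's own species otherwise
        mate_species = (
            "sumatran"
            if species_of[anchors[0]] == "tapanuli" and "sumatran" in config.pop_names
            else species_of[anchors[0]]
        )
        if kind == "child" and len(anchors) == 2:
            records.append((rel_id, anchors[0], anchors[1], None))
            continue
        depth = _KIND_DEPTH[kind]
        parent = anchors[0]
        for step in range(depth):
            last = step == depth - 1
            child = rel_id if last else f"U{aux:02d}"
            mate = f"M{aux:02d}"
            aux += 1
            records.append((mate, None, None, None))
            founders.append((mate, mate_species))
            records.append((child, parent, mate, None))
            parent = child
    return records, founders


def make_scenario(config: ScenarioConfig | None = None, seed: int = 0) -> Scenario:
    """Generate one complete synthetic study scenario.

    The reported metadata differs from the truth exactly by the planted
    permutation: ``n_swaps`` query samples are relabelled along a single
    cycle (so none of them keeps its own label), the rest are fixed
    points. All genotypes derive from one Balding-Nichols population
    model; relatives are produced by gene dropping on the template
    pedigrees.
    """
    config = config or ScenarioConfig()
    n_query = len(config.queries)
    if config.n_swaps > n_query:
        raise ValueError(
            f"cannot plant {config.n_swaps} swaps among {n_query} samples"
        )
    if config.n_swaps == 1:
        raise ValueError("a single relabelled sample is not a permutation")
    K = len(config.pop_names)

    ancestral = sample_ancestral_freqs(
        config.n_snps, config.freq_lo, config.freq_hi,
        seed=substream(seed, "ancestral").integers(2**31),
    )
    F = balding_nichols_freqs(
        ancestral, config.fst, K, seed=substream(seed, "bn").integers(2**31)
    )
    model = PopulationModel(
        n_pops=K, n_snps=config.n_snps, ancestral_freqs=ancestral, fst=config.fst
    )
    variants = make_variant_table(config.n_snps)
    pop_index = {p: k for k, p in enumerate(config.pop_names)}

    # labeled reference panel, pure ancestry
    panel_ids, panel_labels, panel_q = [], {}, []
    for pop in config.pop_names:
        for i in range(config.n_panel_per_pop):
            sid = f"P_{pop}_{i:02d}"
            panel_ids.append(sid)
            panel_labels[sid] = pop
            q = np.zeros(K)
            q[pop_index[pop]] = 1.0
            panel_q.append(q)
    panel_gm = simulate_genotypes(
        F, np.array(panel_q), seed=substream(seed, "panel").integers(2**31),
        sample_ids=panel_ids, variants=variants,
    )
    panel_sexes = {sid: ("M" if i % 2 == 0 else "F") for i, sid in enumerate(panel_ids)}

    # pedigree founders (queries + mates), gene dropping for relatives
    ped_records, founder_roster = _relationship_pedigree(config)
    pedigree = Pedigree(ped_records)
    founder_ids = [f for f, _ in founder_roster]
    founder_q = []
    for _, sp in founder_roster:
        q = np.zeros(K)
        q[pop_index[sp]] = 1.0
        founder_q.append(q)
    founder_gm = simulate_genotypes(
        F, np.array(founder_q), seed=substream(seed, "founders").integers(2**31),
        sample_ids=founder_ids, variants=variants,
    )
    family_gm = drop_genes(
        pedigree, founder_gm, seed=substream(seed, "drop").integers(2**31)
    )

    query_names = [iid for iid, _, _ in config.queries]
    relative_ids = [r for r, _, _ in config.relatives]
    species_of = {iid: sp for iid, sp, _ in config.queries}
    sex_of = {iid: sx for iid, _, sx in config.queries}

    # true ancestry vectors for everyone we genotype
    true_q: dict[str, np.ndarray] = {}
    q_founder = {f: np.array(q) for (f, _), q in zip(founder_roster, founder_q)}
    for iid in pedigree.topo_order:
        if pedigree.is_founder(iid):
            true_q[iid] = q_founder[iid]
        else:
            sire, dam = pedigree.parents[iid]
            true_q[iid] = 0.5 * (true_q[sire] + true_q[dam])
    for sid in panel_ids:
        true_q[sid] = np.eye(K)[pop_index[panel_labels[sid]]]

    # planted permutation over the query labels
    rng_perm = substream(seed, "perm")
    biosamples = [f"SAMP{i + 1:03d}" for i in range(n_query)]
    perm = list(range(n_query))
    if config.n_swaps >= 2:
        moved = sorted(rng_perm.choice(n_query, size=config.n_swaps, replace=False))
        cycle = list(moved)
        rng_perm.shuffle(cycle)
        for src, dst in zip(cycle, cycle[1:] + cycle[:1]):
            perm[src] = dst  # sample of query[src] is reported as query[dst]

    flip_sex = set()
    if config.n_sex_flips:
        rng_flip = substream(seed, "sexflip")
        flip_sex = set(
            rng_flip.choice(n_query, size=config.n_sex_flips, replace=False)
        )

    reported, truth_perm = [], {}
    for i, b in enumerate(biosamples):
        true_ind = query_names[i]
        rep_ind = query_names[perm[i]]
        truth_perm[b] = true_ind
        rep_sex = sex_of[rep_ind]
        if i in flip_sex:
            rep_sex = "F" if rep_sex == "M" else "M"
        reported.append(
            SampleRecord(
                biosample=b,
                lab_id=f"KB{1000 + i}",
                studbook=str(100 + query_names.index(rep_ind)),
                name=rep_ind,
                species=species_of[rep_ind],
                sex=rep_sex,
            )
        )

    # registry with relative links and pedigree-expected kinship
    individuals = []
    for i, iid in enumerate(query_names):
        links = []
        for rel_id, _, anchors in config.relatives:
            if iid in anchors:
                links.append(
                    RelativeLink(
                        relative_id=rel_id,
                        phi_exp=pedigree_phi(pedigree, iid, rel_id),
                    )
                )
        individuals.append(
            Individual(
                name=iid, studbook=str(100 + i), sex=sex_of[iid],
                species=species_of[iid], relatives=tuple(links),
            )
        )
    registry = Registry(individuals)

    # archival-records channel covers queries without genotyped relatives
    covered = {a for _, _, anchors in config.relatives for a in anchors}
    records = {
        biosamples[i]: query_names[i]
        for i in range(n_query)
        if query_names[i] not in covered
    }

    # read counts: queries (true sex) + panel (known sex)
    rng_counts = substream(seed, "counts")
    lengths = default_chrom_lengths()
    chrom_counts: dict[str, ChromCounts] = {}
    sexname = {"M": "male", "F": "female"}
    for i, b in enumerate(biosamples):
        chrom_counts[b] = simulate_chrom_counts(
            sexname[sex_of[query_names[i]]], config.mean_depth, config.mismap_rate,
            lengths, seed=int(rng_counts.integers(2**31)), sample=b,
        )
    for sid in panel_ids:
        chrom_counts[sid] = simulate_chrom_counts(
            sexname[panel_sexes[sid]], config.mean_depth, config.mismap_rate,
            lengths, seed=int(rng_counts.integers(2**31)), sample=sid,
        )

    # assemble one genotype matrix: panel + queries(by biosample) + relatives
    query_gm = family_gm.take_samples(query_names)
    query_gm = GenotypeMatrix(
        samples=biosamples, variants=query_gm.variants, dosages=query_gm.dosages
    )
    rel_gm = family_gm.take_samples(relative_ids)
    genotypes = panel_gm.concat_samples(query_gm).concat_samples(rel_gm)

    truth = ScenarioTruth(
        planted_permutation=truth_perm,
        true_sex=dict(sex_of),
        true_species=dict(species_of),
        true_q={**{biosamples[i]: true_q[query_names[i]] for i in range(n_query)},
                **{r: true_q[r] for r in relative_ids},
                **{s: true_q[s] for s in panel_ids}},
    )
    return Scenario(
        config=config, seed=seed, model=model, pop_freqs=F, genotypes=genotypes,
        panel_samples=panel_ids, panel_labels=panel_labels, panel_sexes=panel_sexes,
        query_samples=biosamples, relative_samples=relative_ids,
        pedigree=pedigree, chrom_counts=chrom_counts, reported=reported,
        registry=registry, records=records, truth=truth,
    )
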