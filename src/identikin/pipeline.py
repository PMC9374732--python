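"""End-to-end orchestration: sexing -> ancestry -> kinship -> resolve.

The in-memory entry point is :func:`analyze_scenario`, which runs the
full identity-verification analysis on a :class:`~identikin.synthdata.Scenario`
(or equivalently structured inputs loaded from disk). ``run_table1``
replays the packaged worked example. File-based runs go through
``write_scenario`` / ``load_scenario`` / ``run_pipeline`` for the CLI.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as iokit
from .ancestry import (
    classify_species,
    filter_variants,
    ld_prune,
    sample_variants,
    supervised_admixture,
)
from .fixtures import table1_evidence, table1_registry, table1_reported
from .kinship import ibd_deltas, individual_freqs_batch, pairwise_phi
from .resolve import (
    DiscrepancySummary,
    IdentityAssignment,
    KinshipHit,
    SampleEvidence,
    corrected_lab_id,
    resolve_identities,
    summarize,
)
from .sexing import calibrate_thresholds, classify_sex, xy_ratio
from .synthdata import Scenario

_SEX_LETTER = {"male": "M", "female": "F", "undetermined": "U"}


@dataclass
class PipelineParams:
    """Analysis thresholds, with the defaults used throughout the package."""

    maf_min: float = 0.05
    n_snps: int | None = 35_000  # SNPs sampled after the MAF/completeness
    # filter and before LD pruning (None = keep all)
    window_snps: int = 50
    step_snps: int = 10
    r2_max: float = 0.1
    margin: float = 0.25
    major_min: float = 0.85
    tau: float = 0.1
    floor: float = 0.02
    em_tol: float = 1e-5
    em_max_iter: int = 2000
    compute_deltas: bool = True

    def validate(self) -> None:
        checks = [
            0 <= self.maf_min <= 0.5, 0 < self.r2_max <= 1,
            self.window_snps >= 2, self.step_snps >= 1,
            self.margin >= 0, 0.5 < self.major_min <= 1,
            self.tau > 0, self.floor >= 0,
        ]
        if not all(checks):
            raise ValueError("pipeline parameter outside its documented domain")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class PipelineResult:
    assignment: IdentityAssignment
    summary: DiscrepancySummary
    evidence: list[SampleEvidence]
    sex_calls: dict[str, str]
    q_hat: pd.DataFrame  # sample x population ancestry proportions
    kinship: pd.DataFrame  # query x relative phi estimates
    n_snps_used: int
    provenance: dict = field(default_factory=dict)

    def recovered_permutation(self) -> dict[str, str]:
        return self.assignment.assigned()


def analyze_scenario(
    scenario: Scenario,
    params: PipelineParams | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full identity analysis against a scenario's ground inputs.

    Stages: calibrate sex thresholds on the known-sex panel and classify
    the query samples; filter, subsample and LD-prune the genotypes;
    estimate panel allele frequencies and supervised ancestry for queries
    and relatives; compute ancestry-adjusted kinship between every query
    and every genotyped relative; resolve identities and summarize the
    discrepancies against the reported metadata.
    """
    params = params or PipelineParams()
    params.validate()

    # --- sex ---------------------------------------------------------
    labeled = [
        (xy_ratio(scenario.chrom_counts[s]), sex)
        for s, letter in scenario.panel_sexes.items()
        for sex in [{"M": "male", "F": "female"}[letter]]
    ]
    thresholds = calibrate_thresholds(labeled, margin=params.margin)
    sex_calls = {
        b: classify_sex(xy_ratio(scenario.chrom_counts[b]), thresholds, b).call
        for b in scenario.query_samples
    }

    # --- variants ----------------------------------------------------
    gm = filter_variants(scenario.genotypes, maf_min=params.maf_min)
    if params.n_snps is not None and params.n_snps < gm.n_variants:
        gm = sample_variants(gm, params.n_snps, seed=seed)
    gm = ld_prune(
        gm, params.window_snps, params.step_snps, params.r2_max,
        corr_samples=scenario.panel_samples,
    )

    # --- ancestry ----------------------------------------------------
    # queries and relatives are fit together: every genotyped sample
    # sharpens the jointly re-estimated population frequencies
    panel = gm.take_samples(scenario.panel_samples)
    target_ids = scenario.query_samples + scenario.relative_samples
    G = gm.take_samples(target_ids).dosages.astype(float)
    Q, model = supervised_admixture(
        panel.dosages.astype(float),
        [scenario.panel_labels[s] for s in panel.samples],
        G, tol=params.em_tol, max_iter=params.em_max_iter,
    )
    q_hat = pd.DataFrame(Q, index=target_ids, columns=model.pops)
    species_calls = {
        b: classify_species(q_hat.loc[b].to_numpy(), model.pops, params.major_min)
        for b in scenario.query_samples
    }

    # --- kinship ------------------------------------------------------
    Mu = individual_freqs_batch(Q, model)
    nq = len(scenario.query_samples)
    phi = pairwise_phi(G[:nq], Mu[:nq], G[nq:], Mu[nq:])
    kin_rows = []
    hits_by_sample: dict[str, list[KinshipHit]] = {b: [] for b in scenario.query_samples}
    for i, b in enumerate(scenario.query_samples):
        for j, r in enumerate(scenario.relative_samples):
            kin_rows.append({"biosample": b, "relative": r,
                             "phi_hat": float(phi[i, j])})
            if phi[i, j] > params.floor:
                deltas = (
                    ibd_deltas(G[i], G[nq + j], Mu[i], Mu[nq + j])
                    if params.compute_deltas
                    else None
                )
                hits_by_sample[b].append(
                    KinshipHit(relative_id=r, phi_hat=float(phi[i, j]),
                               deltas=deltas, n_snps=gm.n_variants)
                )
    kinship_df = pd.DataFrame(kin_rows)

    # --- resolve ------------------------------------------------------
    evidence = [
        SampleEvidence(
            biosample=b,
            sex_call=sex_calls[b],
            species_call=species_calls[b],
            xy_ratio=xy_ratio(scenario.chrom_counts[b]),
            kinship_hits=hits_by_sample[b],
            records_candidate=scenario.records.get(b),
        )
        for b in scenario.query_samples
    ]
    assignment = resolve_identities(
        evidence, scenario.registry, tau=params.tau, floor=params.floor
    )
    summary = summarize(assignment, scenario.reported, scenario.registry)
    provenance = {
        "seed": seed, "scenario_seed": scenario.seed,
        "params": asdict(params), "params_digest": params.digest(),
        "n_snps_used": gm.n_variants,
        "sex_thresholds": {"male_upper": thresholds.male_upper,
                           "female_lower": thresholds.female_lower},
    }
    return PipelineResult(
        assignment=assignment, summary=summary, evidence=evidence,
        sex_calls=sex_calls, q_hat=q_hat, kinship=kinship_df,
        n_snps_used=gm.n_variants, provenance=provenance,
    )


# ---------------------------------------------------------------------------
# the packaged worked example
# ---------------------------------------------------------------------------

def run_table1(tau: float = 0.1, floor: float = 0.02):
    """Resolve the packaged correction-table fixture.

    Returns ``(corrected, assignment, summary)`` where ``corrected`` is a
    DataFrame mirroring the corrected-metadata block (lab id, studbook,
    name, species, sex per BioSample).
    """
    registry = table1_registry()
    evidence = table1_evidence()
    reported = table1_reported()
    assignment = resolve_identities(evidence, registry, tau=tau, floor=floor)
    summary = summarize(assignment, reported, registry)
    rep_by_id = {r.biosample: r for r in reported}
    rows = []
    for b in sorted(assignment.assignments):
        a = assignment.assignments[b]
        ind = registry[a.individual] if a.individual else None
        rows.append(
            {
                "biosample": b,
                "cor_lab_id": corrected_lab_id(a, rep_by_id[b].lab_id),
                "cor_isb": ind.studbook if ind else None,
                "cor_name": a.individual,
                "cor_species": ind.species if ind else None,
                "cor_sex": _SEX_LETTER.get(a.sex_call),
                "flag": a.flag,
            }
        )
    return pd.DataFrame(rows), assignment, summary


# ---------------------------------------------------------------------------
# file-based runs (CLI surface)
# ---------------------------------------------------------------------------

def write_scenario(scenario: Scenario, outdir) -> None:
    """Serialize a scenario to the standard interchange formats."""
    out = Path(outdir)
    (out / "idxstats").mkdir(parents=True, exist_ok=True)
    iokit.write_vcf(scenario.genotypes, out / "genotypes.vcf")
    iokit.write_labels(scenario.panel_labels, out / "panel_labels.tsv")
    iokit.write_metadata(scenario.reported, out / "metadata.tsv")
    iokit.write_registry(scenario.registry, out / "registry.json")
    iokit.write_pedigree(scenario.pedigree, out / "pedigree.ped")
    for sid, counts in scenario.chrom_counts.items():
        iokit.write_idxstats(counts, out / "idxstats" / f"{sid}.tsv")
    (out / "panel_sexes.tsv").write_text(
        "".join(f"{s}\t{x}\n" for s, x in sorted(scenario.panel_sexes.items()))
    )
    (out / "records.tsv").write_text(
        "".join(f"{b}\t{c}\n" for b, c in sorted(scenario.records.items()))
    )
    truth = {
        "planted_permutation": scenario.truth.planted_permutation,
        "true_sex": scenario.truth.true_sex,
        "true_species": scenario.truth.true_species,
        "true_q": {k: list(map(float, v)) for k, v in scenario.truth.true_q.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    roles = {
        "panel": scenario.panel_samples,
        "queries": scenario.query_samples,
        "relatives": scenario.relative_samples,
        "seed": scenario.seed,
    }
    (out / "roles.json").write_text(json.dumps(roles, indent=1))


def load_scenario(indir) -> Scenario:
    """Rebuild an analyzable scenario from a simulated directory."""
    from .synthdata import ScenarioTruth

    ind = Path(indir)
    roles = json.loads((ind / "roles.json").read_text())
    genotypes = iokit.read_vcf(ind / "genotypes.vcf")
    panel_labels = iokit.read_labels(ind / "panel_labels.tsv")
    reported = iokit.read_metadata(ind / "metadata.tsv")
    registry = iokit.read_registry(ind / "registry.json")
    pedigree = iokit.read_pedigree(ind / "pedigree.ped")
    panel_sexes = dict(
        line.split("\t")
        for line in (ind / "panel_sexes.tsv").read_text().splitlines()
    )
    records = dict(
        line.split("\t")
        for line in (ind / "records.tsv").read_text().splitlines()
        if line
    )
    counts = {
        p.stem: iokit.read_idxstats(p) for p in sorted((ind / "idxstats").glob("*.tsv"))
    }
    truth_raw = json.loads((ind / "truth.json").read_text())
    truth = ScenarioTruth(
        planted_permutation=truth_raw["planted_permutation"],
        true_sex=truth_raw["true_sex"],
        true_species=truth_raw["true_species"],
        true_q={k: np.asarray(v) for k, v in truth_raw["true_q"].items()},
    )
    return Scenario(
        config=None, seed=roles.get("seed", 0), model=None, pop_freqs=None,
        genotypes=genotypes, panel_samples=roles["panel"],
        panel_labels=panel_labels, panel_sexes=panel_sexes,
        query_samples=roles["queries"], relative_samples=roles["relatives"],
        pedigree=pedigree, chrom_counts=counts, reported=reported,
        registry=registry, records=records, truth=truth,
    )


def run_pipeline(indir, outdir, params: PipelineParams | None = None, seed: int = 0):
    """File-based end-to-end run: load a scenario directory, analyze it,
    write per-stage outputs plus a machine-readable report."""
    scenario = load_scenario(indir)
    result = analyze_scenario(scenario, params=params, seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.q_hat.to_csv(out / "ancestry_q.tsv", sep="\t")
    result.kinship.to_csv(out / "kinship.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"sample": s, "sex_call": c} for s, c in sorted(result.sex_calls.items())]
    ).to_csv(out / "sex_calls.tsv", sep="\t", index=False)
    rep_by_id = {r.biosample: r for r in scenario.reported}
    assign_rows = [
        {
            "biosample": b,
            "assigned": a.individual,
            "lab_id": corrected_lab_id(a, rep_by_id[b].lab_id),
            "flag": a.flag,
            "sex_call": a.sex_call,
            "species_call": a.species_call,
        }
        for b, a in sorted(result.assignment.assignments.items())
    ]
    pd.DataFrame(assign_rows).to_csv(out / "assignment.tsv", sep="\t", index=False)
    report = {
        "summary": asdict(result.summary),
        "provenance": result.provenance,
        "assignments": {r["biosample"]: r["assigned"] for r in assign_rows},
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return result
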