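"""The packaged worked example: ten re-sequenced orang-utan genomes.

The fixture transcribes the published correction table for the ten
genomes re-sequenced alongside the Sumatran orang-utan reference
assembly: reported vs corrected/validated metadata per BioSample, the
X:Y read-mapping ratio of each genome, and the observed-vs-expected
kinship links to genotyped relatives. The printed values are stored
verbatim (including one delta row that does not sum to 1 as printed);
registry links and the archival-records channel are reconstructed from
the same publication's prose.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files

import pandas as pd

from .resolve import (
    LAB_ID_UNKNOWN,
    Individual,
    KinshipHit,
    Registry,
    RelativeLink,
    SampleEvidence,
    SampleRecord,
)
from .sexing import FEMALE, MALE, SexThresholds, calibrate_thresholds, classify_sex

#: X:Y ratio ranges observed in known-sex individuals in the source study
PAPER_MALE_RATIO_RANGE = (0.369, 0.569)
PAPER_FEMALE_RATIO_RANGE = (4.114, 5.827)

_SPECIES = {"B", "S", "T"}


@dataclass(frozen=True)
class Table1Fixture:
    samples: pd.DataFrame  # one row per BioSample, reported + corrected blocks
    kinship: pd.DataFrame  # one row per kinship link


def _data_path(name: str):
    return files("identikin").joinpath("data", name)


def load_table1() -> Table1Fixture:
    """Load the packaged correction-table fixture (verbatim values)."""
    samples = pd.read_csv(
        _data_path("table1_samples.tsv"), sep="\t",
        dtype={"rep_isb": str, "cor_isb": str},
    )
    kinship = pd.read_csv(
        _data_path("table1_kinship.tsv"), sep="\t", dtype={"relative_isb": str}
    )
    assert len(samples) == 10, "fixture must hold the ten BioSample rows"
    assert set(samples["rep_species"]) | set(samples["cor_species"]) <= _SPECIES
    assert len(kinship) == 9, "fixture holds the nine printed kinship links"
    return Table1Fixture(samples=samples, kinship=kinship)


def paper_sex_thresholds(margin: float = 0.25) -> SexThresholds:
    """Thresholds calibrated from the published known-sex ratio ranges."""
    labeled = [(r, MALE) for r in PAPER_MALE_RATIO_RANGE] + [
        (r, FEMALE) for r in PAPER_FEMALE_RATIO_RANGE
    ]
    return calibrate_thresholds(labeled, margin=margin)


def table1_registry() -> Registry:
    """The candidate individuals with their genotyped-relative links.

    Expected kinship coefficients are the pedigree values for the stated
    relationship degrees (printed to three decimals in the source).
    """
    def ind(name, isb, sex, species, *links):
        return Individual(
            name=name, studbook=isb, sex=sex, species=species,
            relatives=tuple(
                RelativeLink(relative_id=r, phi_exp=phi, relationship=rel)
                for r, phi, rel in links
            ),
        )

    return Registry(
        [
            ind("Dinah", "356", "F", "B"),
            ind("Billy", "590", "M", "B", ("3572", 0.125, "granddaughter")),
            ind("Dolly", "364", "F", "B", ("1387", 0.25, "daughter")),
            ind("Dennis", "360", "M", "B", ("1387", 0.25, "daughter")),
            ind("Louis", "990", "M", "B", ("3619", 0.125, "grandson")),
            ind("Likoe", "1600", "M", "S", ("3351", 0.063, "great-granddaughter")),
            ind("Baldy", "732", "M", "S"),
            ind("Doris", "53", "F", "S"),
            ind("Sibu", "550", "F", "S", ("2069", 0.25, "son")),
            ind("Bubbles", "695", "F", "T",
                ("1980", 0.25, "daughter"), ("1773", 0.25, "son"),
                ("3450", 0.125, "granddaughter")),
        ]
    )


#: samples the archival-records review tied directly to an individual
#: (the three genomes without genotyped relatives)
TABLE1_RECORDS_CANDIDATES = {
    "SAMN00007164": "Dinah",
    "SAMN00007171": "Baldy",
    "SAMN00007172": "Doris",
}

#: validated lab ids from the records review (sentinel = invalidated)
TABLE1_RECORDS_LAB_IDS = {
    "SAMN00007168": LAB_ID_UNKNOWN,  # reported id absent from the repository
    "SAMN00007170": "KB9258",  # digit-swapped in the original report
    "SAMN00007173": LAB_ID_UNKNOWN,  # reported id was a studbook number
}

_SPECIES_CALL = {"B": "B", "S": "S", "T": "T"}


def table1_reported() -> list[SampleRecord]:
    fx = load_table1()
    return [
        SampleRecord(
            biosample=r.biosample, lab_id=None if r.rep_lab_id == "." else r.rep_lab_id,
            studbook=r.rep_isb, name=r.rep_name, species=r.rep_species, sex=r.rep_sex,
        )
        for r in fx.samples.itertuples(index=False)
    ]


def table1_evidence(margin: float = 0.25) -> list[SampleEvidence]:
    """Evidence channels for the fixture, ready for the resolver.

    Sex calls classify the printed X:Y ratios against thresholds
    calibrated from the published known-sex ranges; species calls use the
    corrected species column (standing in for the supervised-ancestry
    figure); kinship hits are the printed links; the records channel
    carries the archival candidates and validated lab ids.
    """
    fx = load_table1()
    thresholds = paper_sex_thresholds(margin=margin)
    evidence = []
    for r in fx.samples.itertuples(index=False):
        hits = [
            KinshipHit(
                relative_id=k.relative_isb, phi_hat=k.phi_hat,
                deltas=(k.delta0, k.delta1, k.delta2),
            )
            for k in fx.kinship.itertuples(index=False)
            if k.biosample == r.biosample
        ]
        evidence.append(
            SampleEvidence(
                biosample=r.biosample,
                sex_call=classify_sex(r.xy_ratio, thresholds, r.biosample).call,
                species_call=_SPECIES_CALL[r.cor_species],
                xy_ratio=r.xy_ratio,
                kinship_hits=hits,
                records_candidate=TABLE1_RECORDS_CANDIDATES.get(r.biosample),
                records_lab_id=TABLE1_RECORDS_LAB_IDS.get(r.biosample),
            )
        )
    return evidence
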