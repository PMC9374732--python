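"""Readers and writers for the standard interchange formats.

Coordinates follow the VCF convention (1-based, inclusive) throughout;
idxstats lengths are base pairs. VCF reading goes through cyvcf2; the
writer emits the minimal GT-only subset the pipeline round-trips.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, ChromCounts, GenotypeMatrix
from .kinship import Pedigree
from .resolve import Individual, Registry, RelativeLink, SampleRecord

# ---------------------------------------------------------------------------
# idxstats
# ---------------------------------------------------------------------------

def read_idxstats(path, sample: str | None = None) -> ChromCounts:
    """Parse a 4-column idxstats TSV (ref name, length, mapped, unmapped).

    The catch-all ``*`` row (unplaced reads) is dropped if present.
    Chromosome aliases ("X" vs "chrX") are resolved lazily at lookup time.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 tab-separated fields, "
                    f"got {len(parts)}"
                )
            name, length, mapped, unmapped = parts
            if name == "*":
                continue
            try:
                rows.append(
                    {"chrom": name, "length": int(length),
                     "mapped": int(mapped), "unmapped": int(unmapped)}
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer count field") from exc
    return ChromCounts(sample=sample or path.stem, table=pd.DataFrame(rows))


def write_idxstats(counts: ChromCounts, path) -> None:
    counts.table[["chrom", "length", "mapped", "unmapped"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path) -> GenotypeMatrix:
    """Load GT fields from a VCF into a dosage matrix.

    Unphased and phased calls are treated alike; any genotype with a
    missing allele becomes a missing dosage. Multi-allelic records are
    kept (alt alleles comma-joined) and left for ``filter_variants`` to
    drop; their dosage counts any non-reference allele.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms, pos, refs, alts, cols = [], [], [], [], []
    saw_gt = False
    for v in vcf:
        if "GT" in (v.FORMAT or []):
            saw_gt = True
        chroms.append(v.CHROM)
        pos.append(v.POS)
        refs.append(v.REF)
        alts.append(",".join(v.ALT) if v.ALT else ".")
        col = np.empty(len(samples), dtype=np.int16)
        for i, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            col[i] = MISSING if a < 0 or b < 0 else (a > 0) + (b > 0)
        cols.append(col)
    if cols and not saw_gt:
        raise ValueError(f"{path}: no GT field in any record")
    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0), dtype=np.int16)
    )
    variants = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": refs, "alt": alts})
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the minimal GT-only VCF the reader round-trips."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=identikin\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, var in enumerate(gm.variants.itertuples(index=False)):
            gts = "\t".join(_GT[int(d)] for d in gm.dosages[:, j])
            fh.write(
                f"{var.chrom}\t{var.pos}\t.\t{var.ref}\t{var.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# pedigree (PED-style)
# ---------------------------------------------------------------------------

_PED_SEX = {"1": "M", "2": "F", "0": None}
_PED_SEX_OUT = {"M": "1", "F": "2", None: "0"}


def read_pedigree(path) -> Pedigree:
    """Parse a PED-style TSV (family, id, sire, dam, sex; 0 = unknown)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 columns")
            _fam, iid, sire, dam, sex = parts[:5]
            records.append(
                (
                    iid,
                    None if sire == "0" else sire,
                    None if dam == "0" else dam,
                    _PED_SEX.get(sex, None),
                )
            )
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path, family: str = "FAM1") -> None:
    with open(path, "w") as fh:
        for iid in ped.topo_order:
            sire, dam = ped.parents[iid]
            fh.write(
                f"{family}\t{iid}\t{sire or 0}\t{dam or 0}\t"
                f"{_PED_SEX_OUT.get(ped.sex.get(iid), '0')}\n"
            )


# ---------------------------------------------------------------------------
# metadata / registry / labels
# ---------------------------------------------------------------------------

def write_metadata(records: list[SampleRecord], path) -> None:
    pd.DataFrame(
        [
            {"biosample": r.biosample, "lab_id": r.lab_id or ".",
             "studbook": r.studbook or ".", "name": r.name,
             "species": r.species, "sex": r.sex}
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        SampleRecord(
            biosample=row["biosample"],
            lab_id=None if row["lab_id"] == "." else row["lab_id"],
            studbook=None if row["studbook"] == "." else row["studbook"],
            name=row["name"], species=row["species"], sex=row["sex"],
        )
        for _, row in df.iterrows()
    ]


def write_registry(registry: Registry, path) -> None:
    payload = [
        {
            "name": ind.name, "studbook": ind.studbook, "sex": ind.sex,
            "species": ind.species,
            "relatives": [
                {"relative_id": l.relative_id, "phi_exp": l.phi_exp,
                 "relationship": l.relationship}
                for l in ind.relatives
            ],
        }
        for ind in registry.individuals.values()
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_registry(path) -> Registry:
    payload = json.loads(Path(path).read_text())
    return Registry(
        [
            Individual(
                name=d["name"], studbook=d["studbook"], sex=d["sex"],
                species=d["species"],
                relatives=tuple(
                    RelativeLink(
                        relative_id=l["relative_id"], phi_exp=l["phi_exp"],
                        relationship=l.get("relationship", ""),
                    )
                    for l in d.get("relatives", [])
                ),
            )
            for d in payload
        ]
    )


def write_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(labels.items()), columns=["sample", "population"]
    ).to_csv(path, sep="\t", index=False)


def read_labels(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["population"]))
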