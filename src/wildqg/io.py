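"""Plain-text file formats for pedigrees, genotypes and phenotypes.

Conventions: tab-separated pedigree (id, sire, dam, sex, cohort, population,
nest) with "0" for an unknown parent; PLINK-style .ped/.map genotype text
plus a compact dosage-matrix dialect; phenotype and truth tables as CSV with
header.  Chromosome names are strings, cM positions floating point, "NA"
codes a missing phenotype or dosage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthpop import GenotypePanel, Pedigree, TraitDataset, UNKNOWN


class ValidationError(ValueError):
    """Carries the full list of validation failures."""

    def __init__(self, errors: list[str]):
        super().__init__("; ".join(errors))
        self.errors = errors


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def write_pedigree(path, pedigree: Pedigree) -> None:
    tab = pedigree.table.copy()
    for col in ("sire", "dam"):
        tab[col] = tab[col].fillna(UNKNOWN)
    tab["nest"] = tab["nest"].fillna("NA")
    tab.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    tab = pd.read_csv(path, sep="\t", dtype={"id": str, "sire": str, "dam": str,
                                             "population": str, "nest": str})
    errors = []
    for col in ("sire", "dam"):
        tab[col] = tab[col].where(tab[col] != UNKNOWN, None)
        tab[col] = tab[col].where(pd.notna(tab[col]), None)
    tab["nest"] = tab["nest"].where(tab["nest"] != "NA", None)
    tab["nest"] = tab["nest"].where(pd.notna(tab["nest"]), None)
    known = set(tab["id"])
    for col in ("sire", "dam"):
        bad = sorted(set(p for p in tab[col] if p is not None and p not in known))
        if bad:
            errors.append(f"unknown {col} ids: {bad[:5]}")
    # cycle check via Pedigree constructor, collected rather than raised raw
    try:
        ped = Pedigree(tab)
    except ValueError as e:
        errors.append(str(e))
        raise ValidationError(errors)
    if errors:
        raise ValidationError(errors)
    return ped


# ---------------------------------------------------------------------------
# genotypes: PLINK-style .ped/.map and compact matrix text
# ---------------------------------------------------------------------------

def write_plink(prefix, panel: GenotypePanel) -> None:
    """.map: chrom, snp, cM, bp(0); .ped: id fields then two alleles per SNP
    (1 = reference, 2 = counted allele, 0 = missing)."""
    m = panel.snp_map
    with open(f"{prefix}.map", "w") as fh:
        for _, row in m.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp']}\t{row['cM']}\t0\n")
    pops = panel.populations or {}
    with open(f"{prefix}.ped", "w") as fh:
        for k, ind in enumerate(panel.ids):
            fields = [pops.get(ind, "0"), ind, "0", "0", "0", "-9"]
            d = panel.dosages[k]
            for g in d:
                if np.isnan(g):
                    fields.extend(["0", "0"])
                else:
                    g = int(g)
                    fields.extend([["1", "1"], ["1", "2"], ["2", "2"]][g])
            fh.write("\t".join(fields) + "\n")


def read_plink(prefix, chrom_meta: pd.DataFrame | None = None) -> GenotypePanel:
    snp_map = pd.read_csv(f"{prefix}.map", sep="\t", header=None,
                          names=["chrom", "snp", "cM", "bp"],
                          dtype={"chrom": str, "snp": str})
    snp_map = snp_map[["snp", "chrom", "cM"]]
    ids, rows, pops = [], [], {}
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            fam, ind = fields[0], fields[1]
            ids.append(ind)
            if fam != "0":
                pops[ind] = fam
            alleles = fields[6:]
            d = np.empty(len(snp_map))
            for j in range(len(snp_map)):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a == "0" or b == "0":
                    d[j] = np.nan
                else:
                    d[j] = (a == "2") + (b == "2")
            rows.append(d)
    if chrom_meta is None:
        chroms = list(dict.fromkeys(snp_map["chrom"]))
        chrom_meta = pd.DataFrame({"chrom": chroms,
                                   "size_mbp": np.nan, "gene_count": np.nan})
    return GenotypePanel(ids=ids, dosages=np.array(rows), snp_map=snp_map,
                         chrom_meta=chrom_meta, populations=pops or None)


def write_dosage_matrix(path, panel: GenotypePanel) -> None:
    """Compact dialect: header row of SNP names, one row per individual."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(panel.snp_map["snp"]) + "\n")
        for k, ind in enumerate(panel.ids):
            vals = ["NA" if np.isnan(v) else str(int(v))
                    for v in panel.dosages[k]]
            fh.write(ind + "\t" + "\t".join(vals) + "\n")


def read_dosage_matrix(path, snp_map: pd.DataFrame,
                       chrom_meta: pd.DataFrame) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"])
    ids = list(df["id"])
    dos = df.drop(columns="id").to_numpy(dtype=float)
    return GenotypePanel(ids=ids, dosages=dos, snp_map=snp_map,
                         chrom_meta=chrom_meta)


# ---------------------------------------------------------------------------
# phenotypes and truth
# ---------------------------------------------------------------------------

def write_phenotypes(path, dataset: TraitDataset) -> None:
    dataset.records.to_csv(path, index=False, na_rep="NA")


def read_phenotypes(path, pedigree: Pedigree | None = None) -> TraitDataset:
    rec = pd.read_csv(path, dtype={"individual_id": str, "nest": str},
                      na_values=["NA"], keep_default_na=True)
    errors = []
    if pedigree is not None:
        known = set(pedigree.ids)
        orphans = sorted(set(rec["individual_id"]) - known)
        if orphans:
            errors.append(f"phenotype records for unknown individuals: {orphans[:5]}")
    if errors:
        raise ValidationError(errors)
    return TraitDataset(records=rec)


def write_truth(path, dataset: TraitDataset) -> None:
    bv = dataset.truth.get("breeding_values", {})
    rows = [{"individual_id": k, "breeding_value": v} for k, v in bv.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# combined validated read
# ---------------------------------------------------------------------------

def read_inputs(pedigree_path, plink_prefix, phenotype_path):
    """Read and cross-validate the three input files, collecting all
    validation failures into a single error."""
    errors = []
    ped = panel = data = None
    try:
        ped = read_pedigree(pedigree_path)
    except (ValidationError, ValueError) as e:
        errors.append(f"pedigree: {e}")
    try:
        panel = read_plink(plink_prefix)
    except Exception as e:  # noqa: BLE001 - collect and report
        errors.append(f"genotypes: {e}")
    try:
        data = read_phenotypes(phenotype_path, pedigree=ped)
    except (ValidationError, ValueError) as e:
        errors.append(f"phenotypes: {e}")
    if ped is not None and panel is not None:
        unknown = sorted(set(panel.ids) - set(ped.ids))
        if unknown:
            errors.append(f"genotyped individuals missing from pedigree: {unknown[:5]}")
    if errors:
        raise ValidationError(errors)
    return ped, panel, data
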