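"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel either as a VCF with per-sample GT fields (read back with
cyvcf2) or as a plain TSV dosage matrix (rows = samples, columns = SNP ids,
cells in {0, 1, 2, NA}); weights as a TSV (snp_id, effect_allele,
other_allele, beta); phenotypes as a TSV; simulation configs as YAML.
In the VCF, ALT is the effect allele and REF the other allele, so the ALT
dosage equals the effect-allele dosage.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .genotypes import GenotypeMatrix
from .simulate import CovariateSpec, SimulationConfig

__all__ = [
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_weights_tsv",
    "read_weights_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_vcf",
    "read_vcf",
    "save_config",
    "load_config",
]


# -- dosage TSV -------------------------------------------------------------


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(genotypes.dosages, index=genotypes.sample_ids, columns=genotypes.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_dosage_tsv(path, weights: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a TSV dosage matrix; allele labels come from ``weights`` if given."""
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    snp_ids = np.array(df.columns, dtype=object)
    if weights is not None:
        wt = weights.set_index("snp_id")
        ea = np.array([wt.at[s, "effect_allele"] if s in wt.index else "N" for s in snp_ids],
                      dtype=object)
        oa = np.array(
            [wt.at[s, "other_allele"] if s in wt.index and "other_allele" in wt.columns else "N"
             for s in snp_ids], dtype=object)
    else:
        ea = np.full(len(snp_ids), "N", dtype=object)
        oa = np.full(len(snp_ids), "N", dtype=object)
    return GenotypeMatrix(
        sample_ids=np.array(df.index, dtype=object),
        snp_ids=snp_ids,
        dosages=df.to_numpy(dtype=float),
        effect_allele=ea,
        other_allele=oa,
    )


# -- weights / phenotypes ---------------------------------------------------


def write_weights_tsv(weights: pd.DataFrame, path) -> None:
    cols = [c for c in ("snp_id", "effect_allele", "other_allele", "beta") if c in weights.columns]
    weights[cols].to_csv(path, sep="\t", index=False)


def read_weights_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"snp_id", "effect_allele", "beta"} <= set(df.columns):
        raise InvalidInputError("weights TSV needs snp_id, effect_allele and beta columns")
    return df


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


# -- VCF --------------------------------------------------------------------

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path, chrom: str = "1") -> None:
    """Write dosages as a minimal VCFv4.2 with GT fields (ALT = effect allele)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=IMPSCORE,Number=1,Type=Float,Description="Imputation accuracy score">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in genotypes.sample_ids) + "\n")
        for j, snp in enumerate(genotypes.snp_ids):
            score = genotypes.imputation_score[j]
            info = "." if np.isnan(score) else f"IMPSCORE={score:.4f}"
            gts = "\t".join(
                _GT.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosages[:, j]
            )
            fh.write(
                f"{chrom}\t{j + 1}\t{snp}\t{genotypes.other_allele[j]}\t"
                f"{genotypes.effect_allele[j]}\t.\t.\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read GT dosages from a VCF via cyvcf2 (dosage counts the ALT allele)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    snp_ids, eas, oas, scores, rows = [], [], [], [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    gt_map = np.array([0.0, 1.0, np.nan, 2.0])
    for v in vcf:
        snp_ids.append(v.ID or f"{v.CHROM}:{v.POS}")
        oas.append(v.REF)
        eas.append(v.ALT[0] if v.ALT else "N")
        score = v.INFO.get("IMPSCORE")
        scores.append(float(score) if score is not None else np.nan)
        rows.append(gt_map[np.asarray(v.gt_types)])
    if not rows:
        raise InvalidInputError(f"no variants in {path}")
    return GenotypeMatrix(
        sample_ids=samples,
        snp_ids=np.array(snp_ids, dtype=object),
        dosages=np.column_stack(rows) if rows else np.empty((len(samples), 0)),
        effect_allele=np.array(eas, dtype=object),
        other_allele=np.array(oas, dtype=object),
        imputation_score=np.array(scores, dtype=float),
    )


# -- config YAML ------------------------------------------------------------


def save_config(config: SimulationConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["allele_freq_range"] = list(d["allele_freq_range"])
    d["covariate_specs"] = [dataclasses.asdict(s) for s in config.covariate_specs]
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path) -> SimulationConfig:
    d = yaml.safe_load(Path(path).read_text())
    if "allele_freq_range" in d:
        d["allele_freq_range"] = tuple(d["allele_freq_range"])
    if "covariate_specs" in d and d["covariate_specs"] is not None:
        d["covariate_specs"] = [CovariateSpec(**s) for s in d["covariate_specs"]]
    return SimulationConfig(**d)
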