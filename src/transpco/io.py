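"""Readers and writers for the on-disk formats the pipeline consumes.

Conventions: TSV with UTF-8 and '.' for missing values; genomic coordinates
are 1-based inclusive everywhere (matching VCF).  Output files carry a
header comment with the tool version and a hash of the resolved
configuration so results are traceable to their run.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from . import __version__
from .preprocess import ExpressionMatrix, GeneAnnotation
from .scan import ZPanel

__all__ = [
    "read_genotypes",
    "read_expression",
    "read_covariates",
    "read_annotation",
    "read_crossmap",
    "read_zpanel",
    "write_zpanel",
    "write_results",
    "read_results",
    "write_dosages",
    "write_expression",
    "write_annotation",
    "write_gmt",
]

MISSING = "."


def _config_hash(config) -> str:
    blob = json.dumps(config, sort_keys=True, default=str) if config else ""
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _header_comment(config=None) -> str:
    return f"# transpco {__version__} config={_config_hash(config)}\n"


# --------------------------------------------------------------------------
# genotypes


def read_genotypes(path):
    """Dosage matrix (samples x SNPs) and positions from VCF or dosage TSV.

    VCF: the DS FORMAT field is preferred; GT hard calls otherwise.
    Dosage TSV: columns snp, chrom, pos, then one column per sample.
    Missing values ('.') become NaN.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING])
    required = {"snp", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: dosage TSV missing columns {sorted(required - set(df.columns))}"
        )
    positions = df[["snp", "chrom", "pos"]].rename(columns={"snp": "snp_id"}) \
                                           .set_index("snp_id")
    sample_cols = [c for c in df.columns if c not in required]
    dosages = df[sample_cols].T
    dosages.columns = df["snp"]
    dosages = dosages.astype(float)
    _check_dosage_range(dosages, path)
    return dosages, positions


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    snp_ids, chroms, pos, rows = [], [], [], []
    for i, var in enumerate(vcf):
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        try:
            if "DS" in (var.FORMAT or []):
                d = np.asarray(var.format("DS"), dtype=float).ravel()
            else:
                gt = np.asarray(var.genotype.array())[:, :2].astype(float)
                gt[gt < 0] = np.nan
                d = gt.sum(axis=1)
        except Exception as err:
            raise ValueError(f"{path}: malformed record at {var.CHROM}:{var.POS}") from err
        snp_ids.append(vid)
        chroms.append(var.CHROM)
        pos.append(var.POS)
        rows.append(d)
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=snp_ids)
    _check_dosage_range(dosages, path)
    positions = pd.DataFrame({"snp_id": snp_ids, "chrom": chroms, "pos": pos}) \
        .set_index("snp_id")
    return dosages, positions


def _check_dosage_range(dosages: pd.DataFrame, path):
    vals = dosages.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError(f"{path}: dosages outside [0, 2]")


def write_dosages(path, dosages: pd.DataFrame, positions: pd.DataFrame,
                  config=None):
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        cols = ["snp", "chrom", "pos"] + list(dosages.index)
        fh.write("\t".join(cols) + "\n")
        for snp in dosages.columns:
            row = [snp, str(positions.loc[snp, "chrom"]),
                   str(int(positions.loc[snp, "pos"]))]
            row += [MISSING if np.isnan(v) else f"{v:.6g}"
                    for v in dosages[snp].to_numpy(dtype=float)]
            fh.write("\t".join(row) + "\n")


# --------------------------------------------------------------------------
# expression / covariates


def read_expression(path, stage: str = "normalized") -> ExpressionMatrix:
    """Samples x genes TSV: header row of gene ids, first column sample ids."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ExpressionMatrix(list(df.index), list(df.columns),
                            df.to_numpy(dtype=float), stage)


def write_expression(path, x: ExpressionMatrix, config=None):
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        x.to_frame().to_csv(fh, sep="\t", index_label="sample_id")


def read_covariates(path):
    from .preprocess import CovariateMatrix

    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return CovariateMatrix(list(df.index), list(df.columns),
                           df.to_numpy(dtype=float))


# --------------------------------------------------------------------------
# annotation / cross-mappability


def read_annotation(path) -> dict:
    """TSV with columns gene_id, chrom, start, end, biotype, mappability."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene_id", "chrom", "start", "end", "biotype"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    out = {}
    for _, r in df.iterrows():
        out[r["gene_id"]] = GeneAnnotation(
            gene_id=str(r["gene_id"]), chromosome=str(r["chrom"]),
            start=int(r["start"]), end=int(r["end"]), biotype=str(r["biotype"]),
            mappability=float(r.get("mappability", 1.0))
            if "mappability" in df.columns else 1.0,
        )
    return out


def write_annotation(path, annotation: dict, config=None):
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        fh.write("gene_id\tchrom\tstart\tend\tbiotype\tmappability\n")
        for a in annotation.values():
            fh.write(f"{a.gene_id}\t{a.chromosome}\t{a.start}\t{a.end}\t"
                     f"{a.biotype}\t{a.mappability:g}\n")


def read_crossmap(path) -> set:
    """Two-column TSV gene_a TAB gene_b; symmetric closure is applied."""
    pairs = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_a"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            a, b = parts[0], parts[1]
            if a != b:
                pairs.add((a, b))
                pairs.add((b, a))
    return pairs


def write_gmt(path, modules, config=None):
    with open(path, "w") as fh:
        for m in modules:
            fh.write("\t".join([m.module_id, m.provenance, *m.gene_ids]) + "\n")


# --------------------------------------------------------------------------
# Z panels


def read_zpanel(path, n_samples=None) -> ZPanel:
    """SNP x gene Z-score panel, wide or long dialect.

    Wide: columns snp_id, chrom, pos, then one column per gene.
    Long: columns snp, gene, z (optionally chrom, pos).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = set(df.columns)
    if {"snp", "gene", "z"}.issubset(cols):
        chrom = (df.groupby("snp")["chrom"].first().to_dict()
                 if "chrom" in cols else {})
        pos = (df.groupby("snp")["pos"].first().to_dict()
               if "pos" in cols else {})
        wide = df.pivot(index="snp", columns="gene", values="z")
        if wide.isna().any().any():
            raise ValueError(f"{path}: long Z panel is not a complete SNP x gene grid")
        snps = list(wide.index)
        return ZPanel(snps,
                      {s: chrom.get(s, "NA") for s in snps},
                      {s: int(pos.get(s, 0)) for s in snps},
                      list(wide.columns), wide.to_numpy(dtype=float),
                      n_samples=n_samples)
    if {"snp_id", "chrom", "pos"}.issubset(cols):
        genes = [c for c in df.columns if c not in ("snp_id", "chrom", "pos")]
        snps = list(df["snp_id"])
        return ZPanel(snps, dict(zip(snps, df["chrom"].astype(str))),
                      dict(zip(snps, df["pos"].astype(int))),
                      genes, df[genes].to_numpy(dtype=float),
                      n_samples=n_samples)
    raise ValueError(
        f"{path}: not a recognised Z panel (need snp/gene/z or snp_id/chrom/pos columns)"
    )


def write_zpanel(path, zpanel: ZPanel, config=None):
    with open(path, "w") as fh:
        fh.write(_header_comment(config))
        fh.write("\t".join(["snp_id", "chrom", "pos", *zpanel.gene_ids]) + "\n")
        for i, s in enumerate(zpanel.snp_ids):
            vals = "\t".join(f"{v:.10g}" for v in zpanel.z[i])
            fh.write(f"{s}\t{zpanel.snp_chrom[s]}\t{zpanel.snp_pos[s]}\t{vals}\n")


# --------------------------------------------------------------------------
# scan results


def write_results(path, result, config=None):
    """Scan records sorted by (module, p_pco), with a provenance header."""
    df = result.records.sort_values(["module", "p_pco"], kind="stable")
    with open(path, "w") as fh:
        fh.write(_header_comment(config if config is not None else vars(result.config)))
        df.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
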