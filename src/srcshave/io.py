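"""Tabular input/output for the selection pipeline.

Formats (all TSV, UTF-8):

* expression / genotype matrix — header ``id<TAB>sample1...sampleN``, one row
  per variable, first column the variable ID.  Genotypes use additive coding
  (minor-allele count 0/1/2); empty cells or ``NA`` are missing and are
  imputed to the per-variable mode (ties toward the smaller code).
* phenotype — ``sample_id<TAB>status`` with status 0 (control) / 1 (case).
* gene map — ``variable_id<TAB>gene<TAB>type`` with type ``expression`` or
  ``snp``.

An optional VCF reader converts GT fields to additive codes; multi-allelic
sites are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "GeneMap",
    "read_dataset",
    "write_dataset",
    "read_phenotype",
    "read_gene_map",
    "write_gene_map",
    "read_vcf_dataset",
    "subset_variables",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan", ".", "N/A"}


@dataclass(frozen=True)
class LabeledDataset:
    """One data type's variables x samples matrix with case/control labels."""

    data_type: str  # "expression" or "snp"
    values: np.ndarray
    variable_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    status: np.ndarray  # per-sample, 0 = control, 1 = case

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "variable_ids", tuple(self.variable_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "status", np.asarray(self.status, dtype=int))
        if self.data_type not in ("expression", "snp"):
            raise ValueError(f"unknown data type {self.data_type!r}")
        p, n = self.values.shape
        if p != len(self.variable_ids):
            raise ValueError("row count must equal the number of variable IDs")
        if n != len(self.sample_ids) or n != len(self.status):
            raise ValueError("column count must equal the number of samples and labels")
        if len(set(self.variable_ids)) != p:
            raise ValueError("variable IDs must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample IDs must be unique")
        if not set(np.unique(self.status)).issubset({0, 1}):
            raise ValueError("status labels must be 0 (control) or 1 (case)")
        if (self.status == 0).sum() < 2 or (self.status == 1).sum() < 2:
            raise ValueError("need at least 2 controls and 2 cases")
        if self.data_type == "snp":
            bad = ~np.isin(self.values, (0.0, 1.0, 2.0))
            if np.any(bad):
                i, j = np.argwhere(bad)[0]
                raise ValueError(
                    f"genotype value {self.values[i, j]!r} for variable "
                    f"{self.variable_ids[i]!r}, sample {self.sample_ids[j]!r} "
                    "is not in {0, 1, 2}"
                )

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class GeneMap:
    """gene symbol -> (expression variable IDs, SNP variable IDs)."""

    entries: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=dict)

    def joint_genes(self) -> list[str]:
        """Genes with at least one probe and one SNP, in file order."""
        return [g for g, (e, s) in self.entries.items() if e and s]

    def variable_to_gene(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for gene, (expr_ids, snp_ids) in self.entries.items():
            for v in (*expr_ids, *snp_ids):
                out[v] = gene
        return out

    def validate_against(self, expr: LabeledDataset | None = None,
                         snp: LabeledDataset | None = None) -> None:
        if expr is not None:
            have = set(expr.variable_ids)
            for gene, (expr_ids, _) in self.entries.items():
                for v in expr_ids:
                    if v not in have:
                        raise KeyError(f"expression ID {v!r} (gene {gene!r}) "
                                       "is absent from the expression dataset")
        if snp is not None:
            have = set(snp.variable_ids)
            for gene, (_, snp_ids) in self.entries.items():
                for v in snp_ids:
                    if v not in have:
                        raise KeyError(f"SNP ID {v!r} (gene {gene!r}) "
                                       "is absent from the SNP dataset")


def read_phenotype(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"phenotype file {path} needs columns sample_id and status")
    out: dict[str, int] = {}
    for sample, status in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if status not in ("0", "1"):
            raise ValueError(f"phenotype status for sample {sample!r} must be 0 or 1, "
                             f"got {status!r}")
        if sample in out:
            raise ValueError(f"duplicate sample {sample!r} in phenotype file")
        out[sample] = int(status)
    return out


def _impute_mode(row: np.ndarray) -> np.ndarray:
    """Fill missing genotypes with the per-variable mode (ties -> smaller code)."""
    miss = np.isnan(row)
    if not miss.any():
        return row
    present = row[~miss].astype(int)
    # bincount argmax returns the smallest code on ties
    mode = int(np.bincount(present, minlength=3).argmax()) if present.size else 0
    out = row.copy()
    out[miss] = mode
    return out


def read_dataset(path, kind: str, phenotype_path) -> LabeledDataset:
    """Read a variables x samples TSV plus its phenotype file.

    The phenotype file must cover exactly the matrix's samples; genotype
    matrices may contain missing cells, which are imputed to the per-variable
    mode before validation.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    pheno = read_phenotype(phenotype_path)
    sample_ids = [str(s) for s in df.columns]
    unknown = set(pheno) - set(sample_ids)
    if unknown:
        raise ValueError(f"phenotype file lists unknown sample(s): {sorted(unknown)}")
    missing = [s for s in sample_ids if s not in pheno]
    if missing:
        raise ValueError(f"samples missing from phenotype file: {missing}")
    variable_ids = [str(v) for v in df.index]

    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            txt = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if txt in _MISSING_TOKENS:
                if kind != "snp":
                    raise ValueError(
                        f"missing value for variable {variable_ids[i]!r}, "
                        f"sample {sample_ids[j]!r} in expression matrix"
                    )
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(txt)
            except ValueError:
                raise ValueError(
                    f"non-numeric value {txt!r} for variable {variable_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}"
                ) from None
    if kind == "snp":
        finite = values[~np.isnan(values)]
        bad = ~np.isin(finite, (0.0, 1.0, 2.0))
        if np.any(bad):
            ij = np.argwhere(~np.isnan(values) & ~np.isin(values, (0.0, 1.0, 2.0)))[0]
            raise ValueError(
                f"genotype value {values[ij[0], ij[1]]!r} for variable "
                f"{variable_ids[ij[0]]!r}, sample {sample_ids[ij[1]]!r} is not in {{0, 1, 2}}"
            )
        values = np.apply_along_axis(_impute_mode, 1, values)
    status = np.array([pheno[s] for s in sample_ids], dtype=int)
    return LabeledDataset(data_type=kind, values=values, variable_ids=variable_ids,
                          sample_ids=sample_ids, status=status)


def write_dataset(ds: LabeledDataset, matrix_path, phenotype_path=None) -> None:
    """Write the matrix (and optionally the phenotype) back as TSV.

    Values are printed with ``repr`` so finite floats round-trip bit-exactly.
    """
    with open(matrix_path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(ds.sample_ids) + "\n")
        fmt = (lambda v: str(int(v))) if ds.data_type == "snp" else (lambda v: repr(float(v)))
        for vid, row in zip(ds.variable_ids, ds.values):
            fh.write(vid + "\t" + "\t".join(fmt(v) for v in row) + "\n")
    if phenotype_path is not None:
        with open(phenotype_path, "w", encoding="utf-8") as fh:
            fh.write("sample_id\tstatus\n")
            for s, st in zip(ds.sample_ids, ds.status):
                fh.write(f"{s}\t{st}\n")


def read_gene_map(path) -> GeneMap:
    """Read ``variable_id<TAB>gene<TAB>type`` rows into a GeneMap.

    Duplicate rows collapse; a variable mapped to two different genes is a
    hard error (one-to-one variable-to-gene assignment is assumed).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[0] == 0:
        return GeneMap(entries={})
    if df.shape[1] < 3:
        raise ValueError("gene map needs columns variable_id, gene, type")
    seen_gene: dict[str, str] = {}
    entries: dict[str, tuple[list[str], list[str]]] = {}
    for vid, gene, typ in zip(df.iloc[:, 0], df.iloc[:, 1], df.iloc[:, 2]):
        vid, gene, typ = str(vid), str(gene), str(typ)
        if typ not in ("expression", "snp"):
            raise ValueError(f"unknown variable type {typ!r} for {vid!r}")
        if vid in seen_gene and seen_gene[vid] != gene:
            raise ValueError(f"variable {vid!r} is mapped to two genes: "
                             f"{seen_gene[vid]!r} and {gene!r}")
        seen_gene[vid] = gene
        expr_ids, snp_ids = entries.setdefault(gene, ([], []))
        target = expr_ids if typ == "expression" else snp_ids
        if vid not in target:
            target.append(vid)
    return GeneMap(entries={g: (tuple(e), tuple(s)) for g, (e, s) in entries.items()})


def write_gene_map(gmap: GeneMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variable_id\tgene\ttype\n")
        for gene, (expr_ids, snp_ids) in gmap.entries.items():
            for v in expr_ids:
                fh.write(f"{v}\t{gene}\texpression\n")
            for v in snp_ids:
                fh.write(f"{v}\t{gene}\tsnp\n")


def read_vcf_dataset(vcf_path, phenotype_path) -> LabeledDataset:
    """Read genotypes from a VCF (GT field) into additive 0/1/2 coding.

    Requires cyvcf2.  Multi-allelic sites are rejected; missing genotypes are
    imputed to the per-variant mode like the TSV reader.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading VCF requires the optional cyvcf2 dependency") from exc
    pheno = read_phenotype(phenotype_path)
    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    unknown = set(pheno) - set(sample_ids)
    if unknown:
        raise ValueError(f"phenotype file lists unknown sample(s): {sorted(unknown)}")
    missing = [s for s in sample_ids if s not in pheno]
    if missing:
        raise ValueError(f"samples missing from phenotype file: {missing}")
    rows, ids = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic site at {v.CHROM}:{v.POS} is not supported")
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        row = np.empty(len(sample_ids))
        for j, gt in enumerate(v.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            row[j] = float(sum(alleles)) if len(alleles) == 2 else np.nan
        rows.append(_impute_mode(row))
        ids.append(vid)
    status = np.array([pheno[s] for s in sample_ids], dtype=int)
    return LabeledDataset(data_type="snp", values=np.array(rows), variable_ids=ids,
                          sample_ids=sample_ids, status=status)


def subset_variables(ds: LabeledDataset, keys) -> LabeledDataset:
    """Restrict a dataset to the given variable IDs (order preserved)."""
    index = {v: i for i, v in enumerate(ds.variable_ids)}
    missing = [k for k in keys if k not in index]
    if missing:
        raise KeyError(f"variable(s) absent from dataset: {missing}")
    rows = [index[k] for k in keys]
    return LabeledDataset(data_type=ds.data_type, values=ds.values[rows],
                          variable_ids=[ds.variable_ids[i] for i in rows],
                          sample_ids=ds.sample_ids, status=ds.status)
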