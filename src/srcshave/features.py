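"""Per-variable feature extraction and the cross-combined feature matrix.

Every variable (an expression probe or a SNP under additive 0/1/2 coding)
is summarized by five statistics computed against the case/control labels:

    [ sd_control, sd_case, |mean_case - mean_control|, |corr|, amplitude ]

where ``corr`` is the Pearson (point-biserial) correlation between the
variable's values and the 0/1 status, and ``amplitude`` is the L2 norm of
the variable's value vector over all samples.  Standard deviations use the
n-1 denominator.  The correlation is stored as an absolute value because the
sign only reflects arbitrary probe/allele polarity.

Rows of the resulting feature matrix are min-max scaled to [0, 1] so that
features with different natural ranges become comparable, and then
*oriented*: the two spread entries are flipped (x -> 1 - x) so that after
orientation "larger" uniformly means "more significant" in every entry.

For the integrative analysis, every expression probe of a gene is paired
with every SNP of that gene ("cross combination"): each pair contributes one
10-row column stacking the probe's oriented block over the SNP's.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import GeneMap, LabeledDataset

__all__ = [
    "FeatureMatrix",
    "extract_features",
    "scale_rows",
    "orient_significance",
    "combine_features",
    "subset_columns",
    "write_feature_matrix",
]

BLOCK = 5
COMBINED_KEY_SEP = "|"


@dataclass(frozen=True)
class FeatureMatrix:
    """``r x p`` matrix of per-variable feature vectors.

    ``r`` is 5 for a single data type and 10 for the combined analysis.
    ``variable_keys`` holds one key per column: a variable ID, or
    ``"<expr_id>|<snp_id>"`` for a combined column.  ``genes[j]`` is the gene
    symbol attributed to column ``j`` (``None`` when unknown).
    """

    features: np.ndarray
    variable_keys: tuple[str, ...]
    genes: tuple[str | None, ...]
    scaled: bool = False
    oriented: bool = False

    @property
    def r(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        object.__setattr__(self, "variable_keys", tuple(self.variable_keys))
        object.__setattr__(self, "genes", tuple(self.genes))
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.r % BLOCK != 0:
            raise ValueError(f"feature count must be a multiple of {BLOCK}")
        if len(self.variable_keys) != self.p or len(self.genes) != self.p:
            raise ValueError("one key and one gene per column required")


def extract_features(dataset: LabeledDataset, gmap: GeneMap | None = None) -> FeatureMatrix:
    """Compute the unscaled 5-feature vector for every variable.

    A constant variable gets correlation 0 (not NaN).  When ``gmap`` is
    given, each column is annotated with its gene symbol.
    """
    X = np.asarray(dataset.values, dtype=float)
    status = np.asarray(dataset.status)
    ctrl = X[:, status == 0]
    case = X[:, status == 1]
    if ctrl.shape[1] < 2 or case.shape[1] < 2:
        raise ValueError("need at least 2 samples per class")
    sd_ctrl = ctrl.std(axis=1, ddof=1)
    sd_case = case.std(axis=1, ddof=1)
    dmu = np.abs(case.mean(axis=1) - ctrl.mean(axis=1))
    # point-biserial correlation with the 0/1 status; 0 for constant variables
    s = status.astype(float)
    sc = s - s.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc**2).sum(axis=1) * (sc**2).sum())
    num = Xc @ sc
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, np.abs(num) / np.where(denom > 0, denom, 1.0), 0.0)
    amp = np.linalg.norm(X, axis=1)
    F = np.vstack([sd_ctrl, sd_case, dmu, corr, amp])
    genes: tuple[str | None, ...]
    if gmap is not None:
        lookup = gmap.variable_to_gene()
        genes = tuple(lookup.get(v) for v in dataset.variable_ids)
    else:
        genes = tuple([None] * len(dataset.variable_ids))
    return FeatureMatrix(features=F, variable_keys=tuple(dataset.variable_ids),
                         genes=genes, scaled=False, oriented=False)


def minmax_rows(M: np.ndarray) -> np.ndarray:
    """Min-max scale each row to [0, 1]; a constant row maps to all-0.5."""
    M = np.asarray(M, dtype=float)
    lo = M.min(axis=1, keepdims=True)
    hi = M.max(axis=1, keepdims=True)
    rng = hi - lo
    out = np.where(rng > 0, (M - lo) / np.where(rng > 0, rng, 1.0), 0.5)
    return out


def scale_rows(fm: FeatureMatrix) -> FeatureMatrix:
    """Scale every feature row to [0, 1] across variables."""
    if fm.p < 1:
        raise ValueError("cannot scale an empty feature matrix")
    return replace(fm, features=minmax_rows(fm.features), scaled=True)


def orient_significance(fm: FeatureMatrix) -> FeatureMatrix:
    """Flip the two spread entries of each 5-block so larger = more significant."""
    if not fm.scaled:
        raise ValueError("orient_significance requires a scaled matrix")
    F = fm.features.copy()
    for b in range(0, fm.r, BLOCK):
        F[b:b + 2] = 1.0 - F[b:b + 2]
    return replace(fm, features=F, oriented=True)


def combine_features(expr_fm: FeatureMatrix, snp_fm: FeatureMatrix,
                     gmap: GeneMap) -> FeatureMatrix:
    """Cross-combine expression and SNP feature blocks per joint gene.

    For gene ``i`` with ``n_e`` probes and ``n_s`` SNPs, all ``n_e * n_s``
    pairs are emitted; each column stacks the probe's 5 oriented features
    over the SNP's.  Genes present in only one data type are omitted.
    """
    for fm, name in ((expr_fm, "expression"), (snp_fm, "snp")):
        if not (fm.scaled and fm.oriented):
            raise ValueError(f"{name} features must be scaled and oriented before combining")
        if fm.r != BLOCK:
            raise ValueError(f"{name} features must have r={BLOCK}")
    e_idx = {k: j for j, k in enumerate(expr_fm.variable_keys)}
    s_idx = {k: j for j, k in enumerate(snp_fm.variable_keys)}
    cols: list[np.ndarray] = []
    keys: list[str] = []
    genes: list[str | None] = []
    for gene in gmap.joint_genes():
        expr_ids, snp_ids = gmap.entries[gene]
        for e in expr_ids:
            if e not in e_idx:
                raise KeyError(f"expression ID {e!r} of gene {gene!r} missing from feature matrix")
            for s in snp_ids:
                if s not in s_idx:
                    raise KeyError(f"SNP ID {s!r} of gene {gene!r} missing from feature matrix")
                cols.append(np.concatenate([expr_fm.features[:, e_idx[e]],
                                            snp_fm.features[:, s_idx[s]]]))
                keys.append(f"{e}{COMBINED_KEY_SEP}{s}")
                genes.append(gene)
    F = np.column_stack(cols) if cols else np.empty((2 * BLOCK, 0))
    return FeatureMatrix(features=F, variable_keys=tuple(keys), genes=tuple(genes),
                         scaled=True, oriented=True)


def subset_columns(fm: FeatureMatrix, indices: np.ndarray) -> FeatureMatrix:
    indices = np.asarray(indices, dtype=int)
    return replace(
        fm,
        features=fm.features[:, indices],
        variable_keys=tuple(fm.variable_keys[i] for i in indices),
        genes=tuple(fm.genes[i] for i in indices),
    )


def write_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Write a feature matrix as TSV with a 2-line header (key, gene)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("key\t" + "\t".join(fm.variable_keys) + "\n")
        fh.write("gene\t" + "\t".join(g if g is not None else "." for g in fm.genes) + "\n")
        for i in range(fm.r):
            fh.write(f"f{i + 1}\t" + "\t".join(repr(float(v)) for v in fm.features[i]) + "\n")
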