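"""Validation layer: SRC classification with LOO cross-validation, and
classical single-variable baselines (Welch t-test, Fisher exact test).

The classifier is the sample-dictionary sparse-representation classifier:
training sample vectors (restricted to the selected variables) form the
dictionary columns, grouped by class; a test vector is sparse-coded and
assigned to the class whose columns reconstruct it with the smallest
residual.  Accuracy is reported as the classification ratio (CR), the
percentage of correctly classified samples.

Variable selection is performed once on the full data set before LOO; the
folds re-fit only the classifier.  This mirrors the common (optimistic)
validation design and its selection bias is documented in the README.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import LabeledDataset, subset_variables
from .src_core import _bpdn_columns

__all__ = [
    "ClassificationResult",
    "src_classify",
    "centroid_classify",
    "loo_cv",
    "evaluate_independent",
    "ttest_pvalues",
    "ttest_select",
    "allele_table",
    "fisher_table_pvalue",
    "fisher_pvalues",
    "fisher_select",
    "random_select",
    "overlap_report",
]


@dataclass(frozen=True)
class ClassificationResult:
    """CR (percent correct), per-sample predictions and fold bookkeeping."""

    cr: float
    predictions: np.ndarray
    sample_ids: tuple[str, ...]
    n_variables_used: int
    folds: tuple[str, ...] = ()


def src_classify(train_values: np.ndarray, train_status: np.ndarray,
                 test_vector: np.ndarray, epsilon_scale: float = 0.05) -> int:
    """Predict 0/1 for one test vector from a training sample dictionary.

    ``train_values`` is variables x samples; the samples become dictionary
    columns (unit-normalized), grouped by class.  All-zero training vectors
    carry no reconstruction power and are dropped from the dictionary; a
    class left without columns is scored by the bare residual ``||y||``.
    Class residual ties break toward class 0 (controls).
    """
    train_values = np.asarray(train_values, dtype=float)
    train_status = np.asarray(train_status, dtype=int)
    y = np.asarray(test_vector, dtype=float).ravel()
    if y.shape[0] != train_values.shape[0]:
        raise ValueError("test vector length must equal the number of variables")
    if (train_status == 0).sum() < 2 or (train_status == 1).sum() < 2:
        raise ValueError("need at least 2 training samples per class")
    norms = np.linalg.norm(train_values, axis=0)
    if not np.any(norms > 0.0):
        raise ValueError("degenerate dictionary: every training sample is all-zero "
                         "on the selected variables")
    keep = norms > 0.0
    D = train_values[:, keep] / norms[keep]
    st = train_status[keep]
    ny = float(np.linalg.norm(y))
    if ny == 0.0:
        x = np.zeros(D.shape[1])
    else:
        floor = float(_ls_residual(D, y))
        eps = max(epsilon_scale * ny, floor * (1.0 + 1e-9) + 1e-12)
        # residual comparison tolerates a coarser solve than objective checks
        x = _bpdn_columns(D, y[:, None], np.array([eps]),
                          n_bisect=28, inner_tol=1e-9, inner_iter=400)[:, 0]
    resid = []
    for cls in (0, 1):
        cols = st == cls
        if cols.any():
            resid.append(float(np.linalg.norm(y - D[:, cols] @ x[cols])))
        else:
            resid.append(ny)
    return 0 if resid[0] <= resid[1] else 1


def _ls_residual(A: np.ndarray, y: np.ndarray) -> float:
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.linalg.norm(A @ x - y))


def centroid_classify(train_values: np.ndarray, train_status: np.ndarray,
                      test_vector: np.ndarray) -> int:
    """Nearest class-centroid ablation classifier; ties go to class 0."""
    train_status = np.asarray(train_status)
    d = []
    for cls in (0, 1):
        mu = train_values[:, train_status == cls].mean(axis=1)
        d.append(np.linalg.norm(test_vector - mu))
    return 0 if d[0] <= d[1] else 1


_CLASSIFIERS = {"src": src_classify, "centroid": centroid_classify}


def loo_cv(dataset: LabeledDataset, selected, classifier: str = "src") -> ClassificationResult:
    """Leave-one-out cross-validation of the classifier on selected variables.

    Selection is not re-run inside folds.  CR is computed over all samples.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("need at least one selected variable")
    ds = subset_variables(dataset, selected)
    clf = _CLASSIFIERS[classifier]
    n = ds.n_samples
    preds = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        preds[i] = clf(ds.values[:, keep], ds.status[keep], ds.values[:, i])
    cr = 100.0 * float((preds == ds.status).sum()) / n
    return ClassificationResult(cr=cr, predictions=preds, sample_ids=ds.sample_ids,
                                n_variables_used=len(selected), folds=ds.sample_ids)


def evaluate_independent(train: LabeledDataset, test: LabeledDataset, selected,
                         classifier: str = "src") -> ClassificationResult:
    """Train the classifier on one cohort and score it on an independent one."""
    selected = list(selected)
    if not selected:
        raise ValueError("need at least one selected variable")
    tr = subset_variables(train, selected)
    te = subset_variables(test, selected)
    clf = _CLASSIFIERS[classifier]
    preds = np.array([clf(tr.values, tr.status, te.values[:, i])
                      for i in range(te.n_samples)], dtype=int)
    cr = 100.0 * float((preds == te.status).sum()) / te.n_samples
    return ClassificationResult(cr=cr, predictions=preds, sample_ids=te.sample_ids,
                                n_variables_used=len(selected))


# ---------------------------------------------------------------------------
# baseline selectors
# ---------------------------------------------------------------------------


def ttest_pvalues(dataset: LabeledDataset) -> np.ndarray:
    """Welch two-sample t-test p-value per variable; constants get p = 1."""
    case = dataset.values[:, dataset.status == 1]
    ctrl = dataset.values[:, dataset.status == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def ttest_select(dataset: LabeledDataset, k: int) -> list[str]:
    """Top-k variables by ascending Welch p-value (stable in input order)."""
    p = ttest_pvalues(dataset)
    order = np.argsort(p, kind="stable")
    return [dataset.variable_ids[i] for i in order[:k]]


def allele_table(genotypes: np.ndarray, status: np.ndarray) -> np.ndarray:
    """2x2 allele-count table [[case minor, case major], [ctrl minor, ctrl major]].

    Each sample contributes two alleles; a genotype coded 2 contributes two
    minor alleles.
    """
    g = np.asarray(genotypes)
    case = status == 1
    case_minor = int(g[case].sum())
    ctrl_minor = int(g[~case].sum())
    case_major = 2 * int(case.sum()) - case_minor
    ctrl_major = 2 * int((~case).sum()) - ctrl_minor
    return np.array([[case_minor, case_major], [ctrl_minor, ctrl_major]])


def fisher_table_pvalue(table: np.ndarray) -> float:
    """Two-sided Fisher exact p-value of a 2x2 count table.

    A table with an empty column margin (monomorphic SNP) is defined to have
    p = 1.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a nonnegative 2x2 table")
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def fisher_pvalues(dataset: LabeledDataset) -> np.ndarray:
    """Two-sided Fisher exact p-value per SNP from allele-count tables."""
    if dataset.data_type != "snp":
        raise ValueError("Fisher exact selection applies to genotype data")
    p = np.empty(dataset.n_variables)
    for i in range(dataset.n_variables):
        p[i] = fisher_table_pvalue(allele_table(dataset.values[i], dataset.status))
    return p


def fisher_select(dataset: LabeledDataset, k: int) -> list[str]:
    """Top-k SNPs by ascending two-sided Fisher exact p-value."""
    p = fisher_pvalues(dataset)
    order = np.argsort(p, kind="stable")
    return [dataset.variable_ids[i] for i in order[:k]]


def random_select(dataset: LabeledDataset, k: int, rng: np.random.Generator) -> list[str]:
    """Uniformly random k-variable panel (control for selection comparisons)."""
    idx = rng.choice(dataset.n_variables, size=min(k, dataset.n_variables), replace=False)
    return [dataset.variable_ids[i] for i in sorted(idx)]


def overlap_report(list_a, list_b, list_c) -> dict[str, int]:
    """All 7 exclusive Venn region sizes for three duplicate-free lists."""
    a, b, c = set(list_a), set(list_b), set(list_c)
    for name, lst, s in (("a", list_a, a), ("b", list_b, b), ("c", list_c, c)):
        if len(lst) != len(s):
            raise ValueError(f"list {name} contains duplicates")
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(a & b & c),
    }
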