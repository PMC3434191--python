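"""Sliding-window gene shaving driven by sparse-representation clustering.

One iteration slides a window across the (possibly permuted) columns of the
feature matrix; within each window the columns are sparse-coded against the
characteristic matrix, and every column assigned to a significant cluster
earns one selection.  Between iterations the column order is reshuffled with
a Fisher-Yates permutation so that window boundaries do not systematically
favor any variable.  The loop stops once the cumulative top-k gene list
stabilizes: the percentage similarity (PS) between the lists of successive
iterations reaches a preset threshold.

Variables selected with the highest frequencies are the most significant.
A combined column's selection is attributed to its gene; a gene's frequency
is the maximum over its combination columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix, minmax_rows, subset_columns
from .src_core import CharacteristicMatrix, assign_clusters

__all__ = [
    "ShavingConfig",
    "SelectionResult",
    "percentage_similarity",
    "fisher_yates",
    "shave",
    "shave_rounds",
]


def percentage_similarity(list_a, list_b) -> float:
    """Overlap between two duplicate-free key lists, as a percentage.

    PS = 100 * |a intersect b| / max(|a|, |b|), in [0, 100].
    """
    a, b = list(list_a), list(list_b)
    if not a or not b:
        raise ValueError("percentage similarity is undefined for an empty list")
    sa, sb = set(a), set(b)
    if len(sa) != len(a) or len(sb) != len(b):
        raise ValueError("lists must be duplicate-free")
    return 100.0 * len(sa & sb) / max(len(a), len(b))


def fisher_yates(items, rng: np.random.Generator) -> list:
    """Uniform random permutation via in-place Fisher-Yates swaps.

    Walks i = n-1 .. 1, drawing j uniformly from {0, ..., i} and swapping.
    """
    out = list(items)
    for i in range(len(out) - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        out[i], out[j] = out[j], out[i]
    return out


@dataclass(frozen=True)
class ShavingConfig:
    """Knobs of the sliding-window selection loop.

    ``window_length``/``step`` are in variables (50% overlap by default so
    boundary variables get two looks per sweep); ``ps_threshold`` is the PS
    percentage at which the cumulative top-k gene list is considered
    converged; ``clusters_kept`` are the 1-based cluster indices counted as
    significant (cluster 1 is the all-significant template by construction).
    """

    window_length: int = 500
    step: int = 250
    ps_threshold: float = 90.0
    max_iterations: int = 50
    top_k: int = 10
    seed: int = 0
    epsilon_scale: float = 0.05
    clusters_kept: tuple[int, ...] = (1,)
    windowed_rescale: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.step <= self.window_length):
            raise ValueError("need 1 <= step <= window_length")
        if not (0.0 < self.ps_threshold <= 100.0):
            raise ValueError("ps_threshold must be in (0, 100]")
        if self.max_iterations < 1 or self.top_k < 1:
            raise ValueError("max_iterations and top_k must be positive")


@dataclass(frozen=True)
class SelectionResult:
    """Selection frequencies and the ranked lists they induce.

    ``ranked`` orders variable keys by frequency (descending), ties broken
    by oriented-feature sum (descending) then key; ``ranked_genes`` applies
    the same ordering to per-gene frequencies (max over the gene's columns).
    """

    frequency: dict[str, int]
    gene_frequency: dict[str, int]
    ranked: tuple[str, ...]
    ranked_genes: tuple[str, ...]
    iterations_run: int
    ps_trajectory: tuple[float, ...]
    n_window_slots: int


def _window_starts(p: int, window: int, step: int) -> list[int]:
    starts = list(range(0, p - window + 1, step))
    if starts[-1] != p - window:  # anchor a tail window so every column is covered
        starts.append(p - window)
    return starts


def _rank(order_keys: np.ndarray, freq: np.ndarray, feat_sum: np.ndarray) -> np.ndarray:
    """Indices sorted by (-frequency, -feature sum, key)."""
    idx = np.arange(len(freq))
    return np.array(sorted(idx, key=lambda i: (-freq[i], -feat_sum[i], order_keys[i])))


def shave(fm: FeatureMatrix, cm: CharacteristicMatrix, cfg: ShavingConfig) -> SelectionResult:
    """Run the sliding-window SRC selection loop over a feature matrix.

    The matrix must be scaled and oriented and at least one window long.
    The first iteration sweeps the columns in input order; every later
    iteration sweeps a fresh Fisher-Yates permutation.
    """
    if not (fm.scaled and fm.oriented):
        raise ValueError("shave requires a scaled and oriented feature matrix")
    p = fm.p
    if p == 0:
        return SelectionResult(frequency={}, gene_frequency={}, ranked=(),
                               ranked_genes=(), iterations_run=0,
                               ps_trajectory=(), n_window_slots=0)
    if cfg.window_length > p:
        raise ValueError(f"window length {cfg.window_length} exceeds the "
                         f"number of columns ({p})")
    if cm.m != fm.r:
        raise ValueError(f"characteristic matrix has {cm.m} rows but the "
                         f"feature matrix has {fm.r} features")
    if any(k < 1 or k > cm.c for k in cfg.clusters_kept):
        raise ValueError("clusters_kept must be valid 1-based cluster indices")

    rng = np.random.default_rng(cfg.seed)
    keys = np.array(fm.variable_keys)
    genes = np.array([g if g is not None else k
                      for g, k in zip(fm.genes, fm.variable_keys)])
    feat_sum = fm.features.sum(axis=0)
    freq = np.zeros(p, dtype=int)
    order = np.arange(p)
    starts = _window_starts(p, cfg.window_length, cfg.step)
    kept = np.asarray(cfg.clusters_kept)

    ps_traj: list[float] = []
    prev_top: list[str] | None = None
    iterations = 0
    while iterations < cfg.max_iterations:
        iterations += 1
        if iterations > 1:
            order = np.array(fisher_yates(order.tolist(), rng))
        selected = np.zeros(p, dtype=bool)
        for s in starts:
            cols = order[s:s + cfg.window_length]
            block = fm.features[:, cols]
            if cfg.windowed_rescale:
                block = minmax_rows(block)
            labels, _ = assign_clusters(cm, block, epsilon_scale=cfg.epsilon_scale)
            selected[cols[np.isin(labels, kept)]] = True
        # one count per sweep, not per window: a column near the sweep's edge
        # sits in fewer windows, and per-window counts would encode position
        # rather than significance
        freq[selected] += 1
        top = _top_genes(keys, genes, freq, feat_sum, cfg.top_k)
        if prev_top is not None:
            ps = percentage_similarity(top, prev_top)
            ps_traj.append(ps)
            if ps >= cfg.ps_threshold:
                break
        prev_top = top

    ranked_idx = _rank(keys, freq, feat_sum)
    gene_freq, gene_rank = _gene_level(keys, genes, freq, feat_sum)
    return SelectionResult(
        frequency={k: int(f) for k, f in zip(keys, freq)},
        gene_frequency=gene_freq,
        ranked=tuple(keys[ranked_idx]),
        ranked_genes=tuple(gene_rank),
        iterations_run=iterations,
        ps_trajectory=tuple(ps_traj),
        n_window_slots=len(starts),
    )


def _gene_level(keys, genes, freq, feat_sum) -> tuple[dict[str, int], list[str]]:
    gene_freq: dict[str, int] = {}
    gene_sum: dict[str, float] = {}
    for g, f, s in zip(genes, freq, feat_sum):
        if g not in gene_freq or f > gene_freq[g] or (f == gene_freq[g] and s > gene_sum[g]):
            gene_freq[g] = int(f)
            gene_sum[g] = float(s)
    ranked = sorted(gene_freq, key=lambda g: (-gene_freq[g], -gene_sum[g], g))
    return gene_freq, ranked


def _top_genes(keys, genes, freq, feat_sum, k: int) -> list[str]:
    _, ranked = _gene_level(keys, genes, freq, feat_sum)
    return ranked[:k]


def shave_rounds(fm: FeatureMatrix, cm: CharacteristicMatrix, cfg: ShavingConfig,
                 floor: int) -> tuple[SelectionResult, list[SelectionResult]]:
    """Multi-round shaving: re-run on survivors until at most ``floor`` remain.

    Each round keeps the columns selected at least once; the matrix is
    restricted to them and shaved again (with a window no longer than the
    survivor count).  Stops when the survivor set stops shrinking or the
    floor is reached.  Returns the final round's result and the full history.
    """
    history: list[SelectionResult] = []
    current = fm
    while True:
        cfg_round = cfg if cfg.window_length <= current.p else \
            ShavingConfig(**{**cfg.__dict__, "window_length": current.p,
                             "step": min(cfg.step, current.p)})
        res = shave(current, cm, cfg_round)
        history.append(res)
        keys = np.array(current.variable_keys)
        surv = np.array([res.frequency[k] > 0 for k in keys])
        if surv.sum() <= floor or surv.sum() == current.p or surv.sum() == 0:
            return res, history
        current = subset_columns(current, np.flatnonzero(surv))
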