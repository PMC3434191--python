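"""Sparse-representation clustering engine.

The engine clusters feature vectors against a *designed* dictionary, the
characteristic matrix ``A``.  Each cluster owns a template direction in
feature space (a significance pattern in ``[0, 1]^m``) replicated at several
amplitudes, so cluster membership is determined jointly by vector angle and
by magnitude.  A query vector ``y`` is sparse-coded against ``A`` by basis
pursuit denoising,

    minimize ||x||_1   subject to   ||A x - y||_2 <= epsilon,

and assigned to the cluster whose coefficients alone reconstruct ``y`` with
the smallest residual (the SRC rule).  Columns of ``A`` are deliberately not
L2-normalized: amplitude carries information.

The default template set is built from two per-block patterns over oriented
5-feature blocks (see :mod:`srcshave.features`):

* significant block ``[1, 1, 1, 1, 1]`` — low within-group spread, large
  between-group shift, high correlation with status, high amplitude;
* background block ``[1, 1, 0.05, 0.05, 0.05]`` — negligible between-group
  signal (a 0.05 floor keeps the column nonzero).

For a stacked matrix of ``b`` blocks (``b = 2`` in the integrative analysis)
every combination of per-block patterns becomes a cluster, ``c = 2**b``, with
the all-significant cluster first.  This lets the integrative analysis keep
only genes whose expression *and* SNP sub-vectors look significant at once.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "CharacteristicMatrix",
    "SparseCode",
    "vector_angle",
    "design_characteristic_matrix",
    "sparse_code",
    "assign_clusters",
    "write_characteristic_matrix",
    "read_characteristic_matrix",
    "SIGNIFICANT_BLOCK",
    "BACKGROUND_BLOCK",
    "DEFAULT_AMPLITUDES",
]

BLOCK = 5
# Per-block cluster prototypes in oriented feature space.  Only the
# between-group entries (mean difference, correlation with status) separate
# signal from noise: within-group spreads and amplitudes of null variables
# are signal-free and scatter around mid-range after min-max scaling, so the
# templates pin those entries at the null centroid 0.5 and discriminate on
# the two association entries (1 for significant, a 0.05 floor for
# background so no column is zero).
SIGNIFICANT_BLOCK = np.array([0.5, 0.5, 1.0, 1.0, 0.5])
BACKGROUND_BLOCK = np.array([0.5, 0.5, 0.05, 0.05, 0.5])
DEFAULT_AMPLITUDES = (0.25, 0.5, 0.75, 1.0)

_PARALLEL_TOL_DEG = 1e-3  # arccos loses ~1e-6 deg of precision near 0


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two nonzero vectors, in degrees, clamped to [0, 180]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("vector_angle is undefined for a zero vector")
    cos = float(np.clip(u @ v / (nu * nv), -1.0, 1.0))
    return float(np.degrees(np.arccos(cos)))


@dataclass(frozen=True)
class CharacteristicMatrix:
    """Designed dictionary whose column groups encode cluster prototypes.

    ``A`` is ``m x n`` with ``n = c * len(amplitudes)`` when built from
    templates; ``cluster_of`` gives the 1-based cluster index of every
    column.  ``templates`` is ``None`` for sample dictionaries (classifier
    use), where columns are training samples rather than designed patterns.
    """

    A: np.ndarray
    cluster_of: np.ndarray
    c: int
    templates: np.ndarray | None = None
    amplitudes: tuple[float, ...] = ()

    @property
    def m(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "cluster_of", np.asarray(self.cluster_of, dtype=int))
        if A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        if self.cluster_of.shape != (A.shape[1],):
            raise ValueError("cluster_of must label every column of A")
        if self.cluster_of.min(initial=1) < 1 or self.cluster_of.max(initial=self.c) > self.c:
            raise ValueError("cluster indices must lie in 1..c")
        norms = np.linalg.norm(A, axis=0)
        if np.any(norms == 0.0):
            raise ValueError("characteristic matrix must not contain zero columns")
        for k in range(1, self.c + 1):
            if not np.any(self.cluster_of == k):
                raise ValueError(f"cluster {k} owns no column")


@dataclass(frozen=True)
class SparseCode:
    """Result of sparse-coding one feature vector against a dictionary."""

    x: np.ndarray
    residuals: np.ndarray
    assigned_cluster: int
    objective: float


def _default_templates(m: int) -> np.ndarray:
    if m % BLOCK != 0 or m < BLOCK:
        raise ValueError(
            f"default templates need a feature count that is a multiple of {BLOCK}; got m={m}. "
            "Pass explicit templates for other layouts."
        )
    n_blocks = m // BLOCK
    rows = []
    for combo in itertools.product((SIGNIFICANT_BLOCK, BACKGROUND_BLOCK), repeat=n_blocks):
        rows.append(np.concatenate(combo))
    return np.array(rows)


def design_characteristic_matrix(
    m: int,
    c: int | None = None,
    amplitudes: tuple[float, ...] = DEFAULT_AMPLITUDES,
    templates: np.ndarray | None = None,
) -> CharacteristicMatrix:
    """Build the designed dictionary from cluster templates and an amplitude grid.

    Columns are emitted cluster-major: for cluster ``k`` the columns
    ``template_k * amp`` for every amplitude level.  With default templates
    the number of clusters is ``2**(m/5)`` (one per combination of
    significant / background 5-feature blocks) and the all-significant
    cluster has index 1.
    """
    if m < 2:
        raise ValueError("need at least 2 features")
    amplitudes = tuple(float(a) for a in amplitudes)
    if not amplitudes or any(a <= 0.0 or a > 1.0 for a in amplitudes):
        raise ValueError("amplitudes must lie in (0, 1]")
    if templates is None:
        templates = _default_templates(m)
    templates = np.asarray(templates, dtype=float)
    if templates.ndim != 2 or templates.shape[1] != m:
        raise ValueError(f"templates must be (c, {m})")
    if c is None:
        c = templates.shape[0]
    if c != templates.shape[0]:
        raise ValueError("c must match the number of templates")
    if c < 2:
        raise ValueError("need at least 2 clusters")
    for i in range(c):
        for j in range(i + 1, c):
            if vector_angle(templates[i], templates[j]) < _PARALLEL_TOL_DEG:
                raise ValueError(
                    f"templates {i} and {j} are parallel; clusters would be "
                    "indistinguishable by angle"
                )
    cols = []
    cluster_of = []
    for k in range(c):
        for a in amplitudes:
            cols.append(a * templates[k])
            cluster_of.append(k + 1)
    A = np.column_stack(cols)
    return CharacteristicMatrix(A=A, cluster_of=np.array(cluster_of), c=c,
                                templates=templates, amplitudes=amplitudes)


def write_characteristic_matrix(cm: CharacteristicMatrix, path) -> None:
    """Export the dictionary as TSV: a cluster-label header row, then A."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cluster\t" + "\t".join(str(int(k)) for k in cm.cluster_of) + "\n")
        for row in cm.A:
            fh.write("\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_characteristic_matrix(path) -> CharacteristicMatrix:
    """Read a dictionary written by :func:`write_characteristic_matrix`.

    Templates and amplitudes are not stored; the imported matrix carries
    only columns and cluster labels, which is all coding and assignment use.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "cluster":
            raise ValueError("expected a 'cluster' header row")
        cluster_of = np.array([int(t) for t in header[1:]])
        rows = [[float(t) for t in line.rstrip("\n").split("\t")[1:]]
                for line in fh if line.strip()]
    A = np.array(rows)
    return CharacteristicMatrix(A=A, cluster_of=cluster_of, c=int(cluster_of.max()))


# ---------------------------------------------------------------------------
# basis pursuit denoising
#
# For epsilon > 0 the constrained problem is solved through its penalized
# (lasso) form  0.5||Ax-y||^2 + lam*||x||_1 : the residual norm of the lasso
# path is nondecreasing in lam, so a bisection on lam finds the point where
# the constraint ||Ax-y|| = epsilon is active, which is the BPDN solution.
# The inner solves use FISTA, vectorized over columns with a per-column lam.
# For epsilon = 0 the problem is the basis pursuit linear program, solved
# exactly with the HiGHS LP solver on the split x = u - v.
# ---------------------------------------------------------------------------


def _fista(A: np.ndarray, Y: np.ndarray, lam: np.ndarray, X0: np.ndarray,
           tol: float = 1e-11, max_iter: int = 1500) -> np.ndarray:
    """Columnwise lasso  min 0.5||A x_j - y_j||^2 + lam_j ||x_j||_1  via FISTA."""
    L = np.linalg.norm(A, 2) ** 2
    if L == 0.0:
        return np.zeros_like(X0)
    step = 1.0 / L
    thr = lam * step  # per-column soft threshold
    X = X0.copy()
    Z = X0.copy()
    t = 1.0
    AtA = A.T @ A
    AtY = A.T @ Y
    for _ in range(max_iter):
        G = AtA @ Z - AtY
        W = Z - step * G
        Xn = np.sign(W) * np.maximum(np.abs(W) - thr, 0.0)
        tn = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        Z = Xn + ((t - 1.0) / tn) * (Xn - X)
        delta = np.max(np.abs(Xn - X)) if Xn.size else 0.0
        X, t = Xn, tn
        if delta <= tol * max(1.0, np.max(np.abs(X)) if X.size else 0.0):
            break
    return X


def _bpdn_columns(A: np.ndarray, Y: np.ndarray, eps: np.ndarray,
                  n_bisect: int = 55, inner_tol: float = 1e-11,
                  inner_iter: int = 1500) -> np.ndarray:
    """Solve BPDN for every column of Y with its own epsilon (> 0).

    Returns the coefficient matrix X (n_atoms x n_columns).  Columns whose
    epsilon already exceeds ||y|| get x = 0.  Raises if some epsilon is
    smaller than the best residual the dictionary can reach.
    """
    m, p = Y.shape
    n = A.shape[1]
    X = np.zeros((n, p))
    norms = np.linalg.norm(Y, axis=0)
    active = eps < norms * (1.0 - 1e-12)
    if not np.any(active):
        return X
    Ya = Y[:, active]
    eps_a = eps[active]
    pa = Ya.shape[1]
    lam_hi = np.max(np.abs(A.T @ Ya), axis=0)
    lam_hi = np.maximum(lam_hi, 1e-300)
    lo = np.zeros(pa)
    hi = lam_hi.copy()
    Xa = np.zeros((n, pa))
    X_feas = np.zeros((n, pa))
    feas_found = np.zeros(pa, dtype=bool)
    for _ in range(n_bisect):
        lam = 0.5 * (lo + hi)
        Xa = _fista(A, Ya, lam, Xa, tol=inner_tol, max_iter=inner_iter)
        res = np.linalg.norm(A @ Xa - Ya, axis=0)
        feas = res <= eps_a
        X_feas[:, feas] = Xa[:, feas]
        feas_found |= feas
        lo = np.where(feas, lam, lo)
        hi = np.where(feas, hi, lam)
    if not np.all(feas_found):
        # the constraint may be unreachable: check the (near) least-squares end
        bad = ~feas_found
        Xls = _fista(A, Ya[:, bad], np.full(bad.sum(), 1e-12 * lam_hi[bad].max()),
                     Xa[:, bad], tol=inner_tol, max_iter=4 * inner_iter)
        res = np.linalg.norm(A @ Xls - Ya[:, bad], axis=0)
        ok = res <= eps_a[bad] + 1e-6
        if not np.all(ok):
            worst = float(np.max(res - eps_a[bad]))
            raise RuntimeError(
                "sparse coding did not reach feasibility: the noise tolerance is "
                f"below the attainable residual (violation {worst:.3e} after "
                f"{n_bisect} bisections x {inner_iter} FISTA iterations)"
            )
        X_feas[:, np.flatnonzero(bad)] = Xls
    X[:, active] = X_feas
    return X


def _basis_pursuit_exact(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Equality-constrained basis pursuit min ||x||_1 s.t. Ax = y (LP, HiGHS)."""
    m, n = A.shape
    c = np.ones(2 * n)
    A_eq = np.hstack([A, -A])
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(
            f"basis pursuit LP failed (status {res.status}: {res.message}); "
            "y may lie outside the span of the dictionary"
        )
    x = res.x[:n] - res.x[n:]
    return x


def _cluster_residuals(cm: CharacteristicMatrix, Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-cluster masked reconstruction residuals, shape (c, n_columns)."""
    c = cm.c
    R = np.empty((c, Y.shape[1]))
    for k in range(1, c + 1):
        mask = cm.cluster_of == k
        recon = cm.A[:, mask] @ X[mask, :]
        R[k - 1] = np.linalg.norm(Y - recon, axis=0)
    return R


def _attainable_residuals(A: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares residual norm per column: the best any code can do.

    A designed dictionary spans only ``c`` template directions, so a generic
    feature vector cannot be reconstructed to arbitrary accuracy; the
    attainable floor is the distance to the dictionary's column space.
    """
    X_ls, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return np.linalg.norm(A @ X_ls - Y, axis=0)


def sparse_code(cm: CharacteristicMatrix, y: np.ndarray,
                epsilon: float | None = None,
                epsilon_scale: float = 0.05) -> SparseCode:
    """Sparse-code ``y`` against the dictionary and assign it to a cluster.

    ``epsilon`` is the noise tolerance of basis pursuit denoising.  With
    ``epsilon=None`` the automatic rule ``epsilon_scale * ||y||_2`` is used,
    clipped from below at the attainable (least-squares) residual so the
    program is always feasible.  An explicit ``epsilon`` is strict:
    ``epsilon = 0`` demands exact reconstruction (solved as a linear
    program) and an unreachable tolerance is an error.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != cm.m:
        raise ValueError(f"feature vector has length {y.shape[0]}, expected {cm.m}")
    ny = float(np.linalg.norm(y))
    if epsilon is None:
        floor = float(_attainable_residuals(cm.A, y[:, None])[0])
        epsilon = max(epsilon_scale * ny, floor * (1.0 + 1e-9) + 1e-12)
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if ny == 0.0:
        x = np.zeros(cm.n)
    elif epsilon == 0.0:
        x = _basis_pursuit_exact(cm.A, y)
    else:
        x = _bpdn_columns(cm.A, y[:, None], np.array([epsilon]))[:, 0]
    R = _cluster_residuals(cm, y[:, None], x[:, None])[:, 0]
    assigned = int(np.argmin(R)) + 1  # argmin breaks ties toward the lower index
    return SparseCode(x=x, residuals=R, assigned_cluster=assigned,
                      objective=float(np.sum(np.abs(x))))


def assign_clusters(cm: CharacteristicMatrix, Y: np.ndarray,
                    epsilon: float | None = None,
                    epsilon_scale: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Cluster every column of ``Y`` by the SRC rule.

    Returns ``(labels, margins)``: 1-based cluster labels and the residual
    margin (second-best minus best cluster residual) per column.  With
    ``epsilon=None`` each column uses the tolerance
    ``epsilon_scale * ||y||_2``, clipped from below at the attainable
    least-squares residual.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != cm.m:
        raise ValueError(f"Y must be ({cm.m}, p)")
    p = Y.shape[1]
    norms = np.linalg.norm(Y, axis=0)
    if epsilon is None:
        floor = _attainable_residuals(cm.A, Y)
        eps = np.maximum(epsilon_scale * norms, floor * (1.0 + 1e-9) + 1e-12)
    else:
        eps = np.full(p, float(epsilon))
    if np.any(eps < 0):
        raise ValueError("epsilon must be nonnegative")
    if np.all(eps > 0) or np.all(norms == 0):
        X = _bpdn_columns(cm.A, Y, np.maximum(eps, 1e-300))
    else:
        X = np.zeros((cm.n, p))
        for j in range(p):
            if norms[j] == 0.0:
                continue
            if eps[j] == 0.0:
                X[:, j] = _basis_pursuit_exact(cm.A, Y[:, j])
            else:
                X[:, j] = _bpdn_columns(cm.A, Y[:, [j]], eps[[j]])[:, 0]
    R = _cluster_residuals(cm, Y, X)
    labels = np.argmin(R, axis=0) + 1
    Rs = np.sort(R, axis=0)
    margins = Rs[1] - Rs[0] if cm.c > 1 else np.zeros(p)
    return labels, margins
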