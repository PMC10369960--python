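"""Potent/null subspace analysis of recurrent and inter-areal weights.

For a weight matrix W, the m-dimensional "potent space" is the span of the
right singular vectors belonging to the m largest singular values; the null
space is its orthogonal complement.  Activity components in the null space
are not transmitted through W.  A task axis (a unit vector over the source
population) is compared against these spaces by the squared L2 norm of its
orthogonal projection; for a random unit vector in d dimensions the expected
squared projection onto an m-dimensional subspace is m / d, which serves as
the chance baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkParams

__all__ = [
    "SubspaceDecomposition",
    "svd_spaces",
    "potent_projection",
    "random_baseline",
    "projection_profile",
    "projection_sweep",
    "restrict_axis",
]


@dataclass
class SubspaceDecomposition:
    """Right singular vectors and singular values of one weight matrix."""

    matrix_id: str
    right_singular_vectors: np.ndarray  # (d, d), columns sorted by singular value
    singular_values: np.ndarray         # (min(shape),) descending

    @property
    def d(self) -> int:
        return self.right_singular_vectors.shape[0]

    def potent_basis(self, m: int) -> np.ndarray:
        """Orthonormal basis (d, m) of the rank-m potent space."""
        if not 1 <= m <= self.d:
            raise ValueError("m out of range")
        return self.right_singular_vectors[:, :m]


def svd_spaces(W: np.ndarray, matrix_id: str = "") -> SubspaceDecomposition:
    """Full SVD of W; the potent space of dimension m is spanned by the top-m
    right singular vectors."""
    W = np.asarray(W, dtype=float)
    _, s, Vt = np.linalg.svd(W, full_matrices=True)
    return SubspaceDecomposition(matrix_id, Vt.T, s)


def potent_projection(axis: np.ndarray, decomp: SubspaceDecomposition, m: int) -> float:
    """Squared norm of the projection of a unit axis onto the m-dim potent
    space (the null-space projection is its complement to 1)."""
    axis = np.asarray(axis, dtype=float)
    if axis.shape != (decomp.d,):
        raise ValueError("axis dimension does not match the matrix")
    nrm = np.linalg.norm(axis)
    if not np.isclose(nrm, 1.0, atol=1e-6):
        raise ValueError("axis must be unit-norm")
    V = decomp.potent_basis(m)
    return float(((V.T @ axis) ** 2).sum())


def restrict_axis(axis: np.ndarray, indices: np.ndarray) -> np.ndarray:
    """Restrict a population axis to a unit subset and re-normalize.

    dPCA axes span a whole population; projections through an inter-areal
    block require support on the source units only.
    """
    sub = np.asarray(axis, dtype=float)[indices]
    nrm = np.linalg.norm(sub)
    if nrm == 0:
        raise ValueError("axis has no support on the requested units")
    return sub / nrm


def random_baseline(
    decomp: SubspaceDecomposition,
    ms: np.ndarray,
    rng: np.random.Generator,
    n_vectors: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD over random unit vectors of the potent projection at each
    m (empirical counterpart of the m/d chance line)."""
    d = decomp.d
    vecs = rng.normal(size=(n_vectors, d))
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    coords = vecs @ decomp.right_singular_vectors  # (n, d)
    cums = np.cumsum(coords ** 2, axis=1)
    sel = cums[:, np.asarray(ms) - 1]
    return sel.mean(axis=0), sel.std(axis=0, ddof=1)


def projection_profile(
    axis: np.ndarray,
    decomp: SubspaceDecomposition,
    ms: np.ndarray | None = None,
) -> np.ndarray:
    """Potent squared projection of one axis for every m (vectorized)."""
    coords = decomp.right_singular_vectors.T @ np.asarray(axis, dtype=float)
    cums = np.cumsum(coords ** 2)
    if ms is None:
        return cums
    return cums[np.asarray(ms) - 1]


def projection_sweep(
    params: NetworkParams,
    axes: dict[str, np.ndarray],
    rng: np.random.Generator,
    n_random: int = 100,
):
    """Potent-projection profiles of task axes for every analysis matrix.

    Matrices analyzed: each area's recurrent block (over all its units) and
    the inter-areal feedforward E->E blocks W21, W32, ...  Task ``axes`` map
    an area-scoped name like ``"area1:direction"`` (axes over that area's
    units for recurrent blocks, or over its excitatory units for feedforward
    blocks, already restricted and unit-norm) to a vector.  A 100-draw
    random-vector baseline is included per matrix.  Returns a tidy pandas
    DataFrame (matrix, axis, m, potent_sq_norm).
    """
    import pandas as pd

    arch = params.arch
    rows = []

    def add(matrix_id: str, W: np.ndarray, scope: str):
        dec = svd_spaces(W, matrix_id)
        ms = np.arange(1, dec.d + 1)
        for name, vec in axes.items():
            area_tag, axis_name = name.split(":")
            if area_tag != scope:
                continue
            prof = projection_profile(vec, dec)
            rows.extend(
                {"matrix": matrix_id, "axis": axis_name, "m": int(m),
                 "potent_sq_norm": float(p)}
                for m, p in zip(ms, prof)
            )
        mean, sd = random_baseline(dec, ms, rng, n_random)
        rows.extend(
            {"matrix": matrix_id, "axis": "random", "m": int(m),
             "potent_sq_norm": float(mu), "random_sd": float(s)}
            for m, mu, s in zip(ms, mean, sd)
        )

    for k in range(arch.n_areas):
        sl = arch.area_slice(k)
        add(f"W_rec_area{k + 1}", params.W_rec[sl, sl], f"area{k + 1}")
    for k in range(arch.n_areas - 1):
        src = arch.exc_indices(k)
        dst = arch.exc_indices(k + 1)
        # feedforward E->E block; rows = target units, columns = source units
        add(f"W{k + 2}{k + 1}", params.W_rec[np.ix_(dst, src)], f"area{k + 1}_exc")
    return pd.DataFrame(rows)
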