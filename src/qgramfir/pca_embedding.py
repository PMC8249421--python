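"""Data-matrix assembly and covariance PCA of density profiles.

Each sequence contributes one row: its 4^q density rows concatenated
bin-major, so the matrix is m x p with p = 4^q * (n - q + 1).  PCA is
covariance PCA — columns are mean-centered but not variance-scaled, since
all density columns share units and the method is not scale invariant.
The decomposition runs on singular values of the centered matrix rather
than an explicit p x p covariance, which is the stable route when p >> m.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from qgramfir.qgram_density import DensityProfile, enumerate_bins


class DegenerateDataError(ValueError):
    """Raised when the centered data matrix has zero total variance."""


@dataclass
class DataMatrix:
    """m x p matrix of concatenated per-sequence density rows."""

    values: np.ndarray
    row_ids: list[str]
    block_order: tuple[str, ...]
    q: int

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class ScoreMatrix:
    """m x k PCA scores with per-component explained-variance fractions."""

    scores: np.ndarray
    explained_fraction: np.ndarray
    row_ids: list[str]

    @property
    def m(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def build_data_matrix(profiles: Sequence[DensityProfile]) -> DataMatrix:
    """Stack density profiles into the data matrix, one sequence per row.

    All profiles must share q, the number of positions, and the filter.
    """
    if len(profiles) < 2:
        raise ValueError(f"need at least 2 profiles to compare, got {len(profiles)}")
    qs = {p.q for p in profiles}
    if len(qs) > 1:
        raise ValueError(f"profiles mix different q values: {sorted(qs)}")
    n_pos = {p.n_positions for p in profiles}
    if len(n_pos) > 1:
        raise ValueError(f"profiles mix different sequence lengths: positions {sorted(n_pos)}")
    windows = {tuple(p.window.b) for p in profiles}
    if len(windows) > 1:
        raise ValueError("profiles were computed with different filter windows")
    q = profiles[0].q
    values = np.vstack([p.flatten() for p in profiles])
    return DataMatrix(
        values=values,
        row_ids=[p.seq_id for p in profiles],
        block_order=enumerate_bins(q).bins,
        q=q,
    )


def pca_scores(D: DataMatrix, k: int = 3) -> ScoreMatrix:
    """Project the centered data matrix onto its top-k principal components.

    Scores are the projections onto the top-k right singular vectors of the
    centered matrix.  ``explained_fraction[c]`` is the variance of component
    c divided by the total variance of the centered matrix (all components,
    not only the retained ones).  Sign convention: each loading vector is
    flipped so its largest-magnitude entry is positive, making runs
    bit-reproducible; Euclidean distances downstream are sign-invariant.
    """
    X = np.asarray(D.values, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("data matrix contains non-finite values")
    m, p = X.shape
    k_max = min(m - 1, p)
    if not 1 <= k <= k_max:
        raise ValueError(f"k={k} out of range; need 1 <= k <= min(m-1, p) = {k_max}")
    Xc = X - X.mean(axis=0, keepdims=True)
    total_var = float(np.sum(Xc**2))
    if total_var <= 0.0:
        raise DegenerateDataError(
            "degenerate data: all rows identical after centering (zero total variance)"
        )
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # Deterministic sign: largest-|loading| entry of each component positive.
    for c in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[c]))
        if Vt[c, pivot] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    scores = U[:, :k] * s[:k]
    explained = (s[:k] ** 2) / total_var
    return ScoreMatrix(scores=scores, explained_fraction=explained, row_ids=list(D.row_ids))


def write_scores_tsv(S: ScoreMatrix, path) -> None:
    """Write scores as TSV with columns seq_id, PC1..PCk (12 sig. digits)."""
    with open(path, "w") as out:
        out.write("seq_id\t" + "\t".join(f"PC{c + 1}" for c in range(S.k)) + "\n")
        for rid, row in zip(S.row_ids, S.scores):
            out.write(rid + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_scores_tsv(path) -> ScoreMatrix:
    """Read a scores TSV back; explained fractions are not stored there."""
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    scores = np.asarray(rows, dtype=float)
    return ScoreMatrix(scores=scores, explained_fraction=np.full(scores.shape[1], np.nan), row_ids=ids)
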