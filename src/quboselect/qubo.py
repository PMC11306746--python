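"""QUBO and Ising objective representations for feature selection.

The selection problem is encoded as a binary quadratic model
``f(x) = sum_i Q_ii x_i + sum_{i<j} Q_ij x_i x_j = x^T Q x`` over bit
vectors x, with Q an upper-triangular real matrix.  Diagonal entries
reward relevance (negated information with the target, so minimization
selects informative items) and off-diagonal entries penalize redundancy
(mutual information between items).  The equivalent Ising form over spins
s in {-1,+1} is provided because annealing hardware is specified in that
representation; the two are related by the affine map x = (1+s)/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .info_theory import (
    BinningRule,
    conditional_mutual_information,
    discretize,
    mutual_information,
)
from .synthetic import SurveyTable

__all__ = [
    "QuboMatrix",
    "IsingModel",
    "Assignment",
    "evaluate",
    "build_qubo",
    "add_cardinality_penalty",
    "lambda_auto",
    "ising_from_qubo",
    "qubo_from_ising",
]

CONSTRUCTION_MODES = ("literal", "miqubo", "conditional_diag")


@dataclass
class QuboMatrix:
    """Upper-triangular coefficient matrix Q of the selection objective.

    ``metadata`` records how Q was built (construction mode, penalty
    strength and cardinality if constrained, additive constant).
    """

    Q: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2 or self.Q.shape[0] != self.Q.shape[1]:
            raise ValueError(f"Q must be square, got shape {self.Q.shape}")
        if not np.all(np.isfinite(self.Q)):
            raise ValueError("Q contains non-finite entries")
        if np.any(np.tril(self.Q, k=-1) != 0.0):
            raise ValueError("Q must be upper-triangular (zero below the diagonal)")

    @property
    def p(self) -> int:
        return self.Q.shape[0]

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.Q).copy()

    @property
    def constant(self) -> float:
        """Additive constant tracked alongside Q (e.g. lambda*k^2)."""
        return float(self.metadata.get("constant", 0.0))

    def symmetric_offdiag(self) -> np.ndarray:
        """Symmetrized off-diagonal couplings with zero diagonal."""
        off = self.Q - np.diag(np.diag(self.Q))
        return off + off.T

    def to_files(self, tsv_path, json_path=None) -> None:
        """Serialize as (i, j, value) triplets plus a JSON metadata block."""
        tsv_path = Path(tsv_path)
        iu = np.triu_indices(self.p)
        with tsv_path.open("w") as fh:
            fh.write("i\tj\tvalue\n")
            for i, j in zip(*iu):
                v = float(self.Q[i, j])
                if v != 0.0 or i == j:
                    fh.write(f"{i}\t{j}\t{v!r}\n")
        meta = dict(self.metadata, p=self.p)
        json_path = Path(json_path) if json_path else tsv_path.with_suffix(".json")
        json_path.write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_files(cls, tsv_path, json_path=None) -> "QuboMatrix":
        tsv_path = Path(tsv_path)
        json_path = Path(json_path) if json_path else tsv_path.with_suffix(".json")
        meta = json.loads(json_path.read_text())
        p = int(meta.pop("p"))
        Q = np.zeros((p, p))
        with tsv_path.open() as fh:
            next(fh)  # header
            for line in fh:
                i, j, v = line.split("\t")
                Q[int(i), int(j)] = float(v)
        return cls(Q=Q, metadata=meta)


@dataclass
class IsingModel:
    """Spin-model biases h_i and couplings J_ij equivalent to a QUBO.

    Energy of a spin configuration s in {-1,+1}^N is
    ``sum_i h_i s_i + sum_{i<j} J_ij s_i s_j + offset``.
    """

    h: np.ndarray
    J: np.ndarray
    offset: float = 0.0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        if self.J.shape != (self.h.size, self.h.size):
            raise ValueError("J shape must be (N, N) matching h")
        if np.any(np.tril(self.J) != 0.0):
            raise ValueError("J must be strictly upper-triangular")

    @property
    def n_spins(self) -> int:
        return self.h.size

    def energy(self, s) -> float:
        s = np.asarray(s, dtype=float)
        return float(self.h @ s + s @ self.J @ s + self.offset)


@dataclass
class Assignment:
    """A candidate bit vector with its objective value."""

    x: np.ndarray
    energy: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int8)

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.x)


def evaluate(qubo: QuboMatrix, x) -> float:
    """Objective value f(x) = sum_i Q_ii x_i + sum_{i<j} Q_ij x_i x_j."""
    x = np.asarray(x)
    if x.shape != (qubo.p,):
        raise ValueError(f"x has shape {x.shape}, expected ({qubo.p},)")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("x entries must be 0 or 1")
    xf = x.astype(float)
    return float(xf @ qubo.Q @ xf)


def _relevance(X: np.ndarray, yb: np.ndarray) -> np.ndarray:
    return np.array([mutual_information(X[:, i], yb) for i in range(X.shape[1])])


def build_qubo(
    table: SurveyTable,
    mode: str = "literal",
    binning: BinningRule | None = None,
) -> QuboMatrix:
    """Build the selection QUBO from a preprocessed survey table.

    The continuous target is discretized with ``binning`` (equal-frequency,
    10 bins by default) before any information estimate.  Three
    constructions are available:

    ``literal`` (default)
        ``Q_ii = -I(X_i; Y)`` and ``Q_ij = +I(X_i; X_j)`` for i<j —
        relevance on the diagonal, pairwise redundancy off it.
    ``miqubo``
        ``Q_ii = -I(X_i; Y)`` and
        ``Q_ij = -[I(X_i;Y|X_j) + I(X_j;Y|X_i)]/2`` — the
        mutual-information QUBO in which off-diagonals reward
        complementary (conditionally informative) pairs.
    ``conditional_diag``
        ``Q_ii = -mean_{j!=i} I(X_i; Y | X_j)`` with the literal
        off-diagonal — diagonal relevance measured conditionally on each
        other item in turn.
    """
    if mode not in CONSTRUCTION_MODES:
        raise ValueError(f"unknown construction mode {mode!r}; choose from {CONSTRUCTION_MODES}")
    if table.p < 2:
        raise ValueError("need at least 2 features to build a selection QUBO")
    binning = binning or BinningRule()
    X = table.X
    yb = discretize(table.y, binning)
    p = table.p

    Q = np.zeros((p, p))
    if mode in ("literal", "miqubo"):
        np.fill_diagonal(Q, -_relevance(X, yb))
    else:  # conditional_diag
        for i in range(p):
            cmis = [
                conditional_mutual_information(X[:, i], yb, X[:, j])
                for j in range(p)
                if j != i
            ]
            Q[i, i] = -float(np.mean(cmis))

    for i in range(p):
        for j in range(i + 1, p):
            if mode == "miqubo":
                Q[i, j] = -0.5 * (
                    conditional_mutual_information(X[:, i], yb, X[:, j])
                    + conditional_mutual_information(X[:, j], yb, X[:, i])
                )
            else:
                Q[i, j] = mutual_information(X[:, i], X[:, j])

    return QuboMatrix(Q=Q, metadata={"mode": mode, "n_bins": binning.n_bins, "n": table.n})


def lambda_auto(qubo: QuboMatrix, eps: float = 1e-6) -> float:
    """Penalty weight 2 * p * max|Q entry| + eps.

    This upper-bounds the largest objective improvement obtainable by
    violating the cardinality constraint by one unit, so with this weight
    every exact minimizer of the penalized problem is feasible.
    """
    return 2.0 * qubo.p * float(np.abs(qubo.Q).max()) + eps


def add_cardinality_penalty(qubo: QuboMatrix, k: int, lam: float) -> QuboMatrix:
    """Add the quadratic penalty ``lam * (sum_i x_i - k)^2`` to the QUBO.

    On binary variables the expansion adds ``lam * (1 - 2k)`` to every
    diagonal entry and ``2 * lam`` to every upper off-diagonal entry; the
    remaining constant ``lam * k^2`` is tracked in metadata so reported
    energies can be made comparable across k.
    """
    if not 1 <= k <= qubo.p:
        raise ValueError(f"k={k} outside valid range 1..{qubo.p}")
    if lam <= 0:
        raise ValueError(f"penalty weight must be positive, got {lam}")
    Q = qubo.Q.copy()
    Q[np.triu_indices(qubo.p, k=1)] += 2.0 * lam
    Q[np.diag_indices(qubo.p)] += lam * (1.0 - 2.0 * k)
    meta = dict(qubo.metadata)
    meta.update(
        penalty_lambda=lam,
        penalty_k=int(k),
        constant=qubo.constant + lam * float(k) ** 2,
    )
    return QuboMatrix(Q=Q, metadata=meta)


def ising_from_qubo(qubo: QuboMatrix) -> IsingModel:
    """Convert a QUBO to its Ising form via the substitution x = (1+s)/2.

    Energies satisfy ``f(x) = E_ising(s) + offset`` exactly, so the full
    state-energy ordering (and in particular the argmin) is preserved.
    """
    Qu = np.triu(qubo.Q, k=1)
    diag = np.diag(qubo.Q)
    qsym = Qu + Qu.T
    h = diag / 2.0 + qsym.sum(axis=1) / 4.0
    J = Qu / 4.0
    offset = float(diag.sum() / 2.0 + Qu.sum() / 4.0)
    return IsingModel(h=h, J=J, offset=offset)


def qubo_from_ising(model: IsingModel) -> QuboMatrix:
    """Inverse conversion; round-trips exactly up to the stored offset."""
    Jsym = model.J + model.J.T
    diag = 2.0 * (model.h - Jsym.sum(axis=1))
    Q = 4.0 * np.triu(model.J, k=1) + np.diag(diag)
    constant = model.offset - float(diag.sum() / 2.0 + np.triu(Q, k=1).sum() / 4.0)
    return QuboMatrix(Q=Q, metadata={"constant": constant})
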