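"""Plug-in (maximum-likelihood) information estimators for discrete variables.

Entropy, mutual information and conditional mutual information are computed
from contingency counts with empirical cell probabilities, in nats.  These
are the quantities that populate the feature-selection QUBO: mutual
information between features measures redundancy, (conditional) mutual
information with the dependent variable measures relevance.

No small-sample bias correction (Miller–Madow, shrinkage, ...) is applied;
the raw plug-in estimator keeps every value exactly reproducible from the
contingency table and is the documented extension point if correction is
ever wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _count_entropy

__all__ = [
    "BinningRule",
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "discretize",
]

#: negative values of this magnitude are rounding noise and are clamped to 0
_NEG_TOL = 1e-12


@dataclass(frozen=True)
class BinningRule:
    """Equal-frequency discretization rule for continuous variables.

    The continuous dependent variable (a summed score) must be discretized
    before it can enter the contingency-table estimators.  Equal-frequency
    (quantile) bins are robust to skewed score distributions.
    """

    n_bins: int = 10
    strategy: str = "equal-frequency"

    def __post_init__(self) -> None:
        if self.strategy != "equal-frequency":
            raise ValueError(f"unknown binning strategy: {self.strategy!r}")
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")


def _codes(x, name: str = "x") -> np.ndarray:
    """Map an arbitrary discrete sample to dense integer codes 0..L-1."""
    x = np.asarray(x)
    if x.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {x.shape}")
    if x.size == 0:
        raise ValueError(f"{name} is empty")
    _, codes = np.unique(x, return_inverse=True)
    return codes.astype(np.intp)


def entropy(x) -> float:
    """Shannon entropy H(X) in nats of a discrete sample, plug-in estimate.

    H = -sum_l p_l log p_l with p_l = count_l / n over the observed levels.
    """
    codes = _codes(x)
    counts = np.bincount(codes)
    return float(_count_entropy(counts))


def _joint_counts(cx: np.ndarray, cy: np.ndarray) -> np.ndarray:
    nx = int(cx.max()) + 1
    ny = int(cy.max()) + 1
    return np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny)


def _mi_from_joint(joint: np.ndarray) -> float:
    """I(X;Y) = H(X) - H(X|Y) from a joint count table."""
    n = joint.sum()
    col = joint.sum(axis=0)  # counts of Y
    h_x = _count_entropy(joint.sum(axis=1))
    # H(X|Y) = sum_y p(y) H(X | Y=y)
    h_x_given_y = 0.0
    for j in range(joint.shape[1]):
        if col[j] > 0:
            h_x_given_y += (col[j] / n) * _count_entropy(joint[:, j])
    mi = float(h_x - h_x_given_y)
    if mi < 0.0:
        if mi < -_NEG_TOL:  # pragma: no cover - analytically impossible
            raise FloatingPointError(f"plug-in MI came out {mi}")
        mi = 0.0
    return mi


def mutual_information(x, y) -> float:
    """Plug-in mutual information I(X;Y) = H(X) - H(X|Y), in nats.

    Symmetric in its arguments; tiny negatives from floating-point
    cancellation (< 1e-12) are clamped to zero.
    """
    cx, cy = _codes(x, "x"), _codes(y, "y")
    if cx.shape != cy.shape:
        raise ValueError(f"length mismatch: {cx.size} vs {cy.size}")
    return _mi_from_joint(_joint_counts(cx, cy))


def conditional_mutual_information(x, y, z) -> float:
    """Plug-in conditional mutual information I(X;Y|Z), in nats.

    Computed by stratification: sum_z p(z) I(X;Y | Z=z), which equals
    H(X|Z) - H(X|Y,Z) for plug-in estimates.  Strata with no observations
    carry zero weight.
    """
    cx, cy, cz = _codes(x, "x"), _codes(y, "y"), _codes(z, "z")
    if not (cx.shape == cy.shape == cz.shape):
        raise ValueError(
            f"length mismatch: {cx.size}, {cy.size}, {cz.size}"
        )
    n = cx.size
    cmi = 0.0
    for zv in range(int(cz.max()) + 1):
        mask = cz == zv
        nz = int(mask.sum())
        if nz == 0:
            continue
        cmi += (nz / n) * _mi_from_joint(_joint_counts(cx[mask], cy[mask]))
    return float(cmi)


def discretize(y, rule: BinningRule | None = None) -> np.ndarray:
    """Discretize a continuous sample into equal-frequency bins.

    Bin codes run 0..n_bins-1 in increasing order of value.  Tied values are
    assigned as a block to the lowest bin any of them would fall in, so
    equal inputs always receive equal codes.  Without ties, bin populations
    differ by at most one.

    A degenerate all-equal sample collapses to a single code and emits a
    ``UserWarning``.
    """
    if rule is None:
        rule = BinningRule()
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError(f"y must be one-dimensional, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    n = y.size
    if n < rule.n_bins:
        raise ValueError(f"n={n} is smaller than n_bins={rule.n_bins}")

    order = np.argsort(y, kind="stable")
    codes = np.empty(n, dtype=np.intp)
    codes[order] = (np.arange(n) * rule.n_bins) // n
    # collapse ties to the lower bin
    uniq, inv = np.unique(y, return_inverse=True)
    lowest = np.full(uniq.size, rule.n_bins, dtype=np.intp)
    np.minimum.at(lowest, inv, codes)
    codes = lowest[inv]
    if uniq.size == 1:
        warnings.warn(
            "discretize: sample is constant; all observations share one bin",
            UserWarning,
            stacklevel=2,
        )
    return codes
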