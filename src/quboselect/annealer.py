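"""QUBO minimizers: exhaustive enumeration and simulated annealing.

The exact solver is the ground truth for small problems (it enumerates all
2^p states).  Simulated annealing is the desk-scale stand-in for the
quantum-annealing hardware: Metropolis sampling over a geometric
inverse-temperature ladder with independent seeded restarts ("reads").
Proposals mix single-bit flips with pair exchanges; the exchanges matter
under a cardinality penalty, where they move between same-weight subsets
without climbing the penalty barrier that separates them.

An external binary-quadratic-model sampler (e.g. a hardware annealer's
client) can be plugged in wherever a ``solve`` callable taking a
:class:`~quboselect.qubo.QuboMatrix` and returning an
:class:`~quboselect.qubo.Assignment` is accepted; nothing in this package
depends on one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .qubo import Assignment, QuboMatrix, evaluate

__all__ = ["AnnealSchedule", "solve_exact", "solve_sa", "EXACT_GUARD"]

#: largest dimension the exhaustive solver will enumerate (2^22 states)
EXACT_GUARD = 22


@dataclass(frozen=True)
class AnnealSchedule:
    """Simulated-annealing schedule.

    ``beta_start`` and ``beta_end`` are inverse temperatures interpolated
    geometrically across ``n_sweeps`` sweeps (one sweep = p flip
    proposals); ``n_reads`` independent restarts are run, each on its own
    random substream derived from ``(seed, read_index)`` so results do not
    depend on how many reads run.
    """

    n_sweeps: int = 2000
    beta_start: float = 0.1
    beta_end: float = 100.0
    n_reads: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValueError(f"n_sweeps must be >= 1, got {self.n_sweeps}")
        if self.n_reads < 1:
            raise ValueError(f"n_reads must be >= 1, got {self.n_reads}")
        if not 0.0 < self.beta_start < self.beta_end:
            raise ValueError(
                f"need 0 < beta_start < beta_end, got {self.beta_start}, {self.beta_end}"
            )


def solve_exact(qubo: QuboMatrix) -> Assignment:
    """Global minimizer by full enumeration of all 2^p bit vectors.

    Ties are broken toward the lexicographically smallest bit vector
    (leading bits compared first).  Refuses p > 22; use :func:`solve_sa`
    beyond that.
    """
    p = qubo.p
    if p > EXACT_GUARD:
        raise ValueError(
            f"p={p} exceeds the enumeration guard ({EXACT_GUARD}); use solve_sa"
        )
    shifts = np.arange(p - 1, -1, -1, dtype=np.uint32)  # bit 0 = leading
    best_energy = np.inf
    best_state = None
    chunk = 1 << 16
    for start in range(0, 1 << p, chunk):
        m = np.arange(start, min(start + chunk, 1 << p), dtype=np.uint32)
        X = ((m[:, None] >> shifts) & 1).astype(float)
        energies = np.einsum("ni,ij,nj->n", X, qubo.Q, X)
        idx = int(np.argmin(energies))  # first occurrence = lexicographic
        if energies[idx] < best_energy:
            best_energy = float(energies[idx])
            best_state = X[idx].astype(np.int8)
    return Assignment(x=best_state, energy=best_energy)


@njit(cache=False)
def _sa_read(diag, qsym, betas, idx_a, idx_b, moves, unifs, x):  # pragma: no cover - jitted
    """One annealing read; mutates x, returns (best_energy, best_x).

    ``moves[t] == 0`` proposes a single-bit flip of ``idx_a[t]``;
    ``moves[t] == 1`` proposes exchanging the unequal pair
    ``(idx_a[t], idx_b[t])`` (a no-op when the two bits agree).  The pair
    proposal is symmetric, so plain Metropolis acceptance applies.
    ``field[i]`` caches ``Q_ii + sum_j qsym_ij x_j``, the flip cost of i.
    """
    p = diag.shape[0]
    field = diag.copy()
    energy = 0.0
    for i in range(p):
        if x[i] == 1:
            energy += diag[i]
            for j in range(i + 1, p):
                if x[j] == 1:
                    energy += qsym[i, j]
    for i in range(p):
        if x[i] == 1:
            for j in range(p):
                field[j] += qsym[j, i]
    best_energy = energy
    best_x = x.copy()
    for t in range(idx_a.shape[0]):
        i = idx_a[t]
        if moves[t] == 0:  # single-bit flip
            s = 1 - 2 * x[i]
            d_e = s * field[i]
            if d_e <= 0.0 or unifs[t] < np.exp(-betas[t] * d_e):
                x[i] += s
                energy += d_e
                for j in range(p):  # qsym diagonal is zero: field[i] untouched
                    field[j] += s * qsym[j, i]
                if energy < best_energy:
                    best_energy = energy
                    best_x = x.copy()
        else:  # pair exchange; crosses no cardinality-penalty barrier
            j = idx_b[t]
            if x[i] == x[j]:
                continue
            s_i = 1 - 2 * x[i]
            s_j = 1 - 2 * x[j]
            d_e = s_i * field[i] + s_j * (field[j] + s_i * qsym[j, i])
            if d_e <= 0.0 or unifs[t] < np.exp(-betas[t] * d_e):
                x[i] += s_i
                x[j] += s_j
                energy += d_e
                for m in range(p):
                    field[m] += s_i * qsym[m, i] + s_j * qsym[m, j]
                if energy < best_energy:
                    best_energy = energy
                    best_x = x.copy()
    return best_energy, best_x


def _beta_ladder(schedule: AnnealSchedule, p: int) -> np.ndarray:
    betas = np.geomspace(schedule.beta_start, schedule.beta_end, schedule.n_sweeps)
    return np.repeat(betas, p)


def solve_sa(qubo: QuboMatrix, schedule: AnnealSchedule | None = None) -> list[Assignment]:
    """Simulated annealing; returns one assignment per read, best first.

    Deterministic given ``schedule.seed``; the returned list is sorted by
    energy ascending with a stable sort, so equal-energy reads keep their
    read order.  Each assignment's energy is re-evaluated from Q before
    returning.
    """
    schedule = schedule or AnnealSchedule()
    p = qubo.p
    diag = qubo.diagonal
    qsym = np.ascontiguousarray(qubo.symmetric_offdiag())
    betas = _beta_ladder(schedule, p)
    n_steps = betas.shape[0]

    results: list[Assignment] = []
    for read in range(schedule.n_reads):
        rng = np.random.default_rng(np.random.SeedSequence([schedule.seed, read]))
        x0 = rng.integers(0, 2, size=p).astype(np.int8)
        idx_a = rng.integers(0, p, size=n_steps).astype(np.int64)
        idx_b = rng.integers(0, p - 1, size=n_steps).astype(np.int64)
        idx_b[idx_b >= idx_a] += 1  # uniform over j != i
        moves = (rng.random(n_steps) < 0.5).astype(np.int8)
        unifs = rng.random(n_steps)
        _, best_x = _sa_read(diag, qsym, betas, idx_a, idx_b, moves, unifs, x0)
        results.append(Assignment(x=best_x, energy=evaluate(qubo, best_x)))
    results.sort(key=lambda a: a.energy)  # stable
    return results
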