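"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

import cyclekin as ck


def rational_left_nullspace(S) -> list[tuple[Fraction, ...]]:
    """Independent left-null-space oracle: exact Fraction Gaussian elimination.

    Solves w @ S == 0 (i.e. S.T w = 0) without sympy, returning a basis of
    Fraction vectors via the free-variable construction on the RREF of S.T.
    """
    A = [[Fraction(int(x)) for x in row] for row in np.asarray(S).T]
    n_rows = len(A)
    n_cols = len(A[0]) if n_rows else 0
    pivots: list[int] = []
    r = 0
    for c in range(n_cols):
        piv = next((i for i in range(r, n_rows) if A[i][c] != 0), None)
        if piv is None:
            continue
        A[r], A[piv] = A[piv], A[r]
        A[r] = [x / A[r][c] for x in A[r]]
        for i in range(n_rows):
            if i != r and A[i][c] != 0:
                f = A[i][c]
                A[i] = [a - f * b for a, b in zip(A[i], A[r])]
        pivots.append(c)
        r += 1
        if r == n_rows:
            break
    basis = []
    free = [c for c in range(n_cols) if c not in pivots]
    for fc in free:
        w = [Fraction(0)] * n_cols
        w[fc] = Fraction(1)
        for i, pc in enumerate(pivots):
            w[pc] = -A[i][fc]
        basis.append(tuple(w))
    return basis


def rational_rref(vectors) -> tuple[tuple[Fraction, ...], ...]:
    """Canonical RREF of a set of rational row vectors (for span comparison)."""
    A = [[Fraction(x) for x in v] for v in vectors]
    if not A:
        return ()
    n_cols = len(A[0])
    r = 0
    for c in range(n_cols):
        piv = next((i for i in range(r, len(A)) if A[i][c] != 0), None)
        if piv is None:
            continue
        A[r], A[piv] = A[piv], A[r]
        A[r] = [x / A[r][c] for x in A[r]]
        for i in range(len(A)):
            if i != r and A[i][c] != 0:
                f = A[i][c]
                A[i] = [a - f * b for a, b in zip(A[i], A[r])]
        r += 1
        if r == len(A):
            break
    return tuple(tuple(row) for row in A[:r])


def spans_equal(vs1, vs2) -> bool:
    return rational_rref(vs1) == rational_rref(vs2)


def max_conservation_drift(network, trajectory) -> float:
    """Worst relative drift of any conserved moiety along a trajectory."""
    scale = float(trajectory.concentrations.max())
    worst = 0.0
    for w in ck.conservation_laws(network):
        q = trajectory.concentrations @ w
        worst = max(
            worst, float(np.max(np.abs(q - q[0]))) / (float(np.abs(w).sum()) * scale)
        )
    return worst


@pytest.fixture(scope="session")
def landolt_net():
    """Landolt core with the reference parameters k1=1e-6, k2=1e-2, k3=1e7."""
    return ck.landolt(1e-6, 1e-2, 1e7)


@pytest.fixture(scope="session")
def hypercycle_base_net():
    """Hypercycle with the base competition parameters (cross k9 = 3e-7)."""
    return ck.preset("fig5_optionA").network


@pytest.fixture(scope="session")
def hypercycle_init(hypercycle_base_net):
    return hypercycle_base_net.state({"A": 1.0, "B": 1.0, "X": 1.0, "Y": 1.0})
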