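"""Four-component synthesis: Y ~ a*S(n-nd) + b*A(n) + c*H1(n) + d*H2(n).

The amplification factors are solved in closed form by linear least squares
for each candidate sEJP delay ``nd``; the delay itself is found by an
exhaustive scan of the integers in [n1, n2] (onset to peak of the target
AP).  The objective in ``nd`` is not unimodal in general, so no golden
section or gradient shortcut is taken — the interval is short (tens of
samples) and the scan is cheap.

The normal-equations form ``X = (C'C)^-1 C'Y`` is solved with an
orthogonal-decomposition least-squares routine with the identical solution
contract but better behaviour when the S and A feet are nearly collinear;
the design condition number is reported with every fit.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import lsq_linear

from apdecomp.core import Decomposition, FitError, TemplateSet

#: columns of the component matrix, in order
COMPONENT_NAMES = ("S", "A", "H1", "H2")

#: designs with a condition number above this raise a singular-design error
MAX_CONDITION = 1e10


def component_matrix(templates: TemplateSet, nd: int, n: int) -> np.ndarray:
    """Build the N x 4 component matrix for sEJP delay ``nd``.

    Column 1 is S delayed by ``nd`` samples (zeros before its onset and
    after it ends); column 2 is A starting at row 0; columns 3-4 are H1 and
    H2 starting at A's peak row plus ``h_offset``.  All columns are
    zero-padded/truncated to ``n`` rows.  Absent H templates give all-zero
    columns (the fit then runs on the remaining components).
    """
    if nd < 0:
        raise FitError(f"nd must be non-negative, got {nd}")
    if nd >= n:
        raise FitError(f"nd={nd} does not fit in {n} output rows")
    C = np.zeros((n, 4))
    _paste(C, 0, templates.S, nd)
    _paste(C, 1, templates.A, 0)
    h_start = int(np.argmax(templates.A)) + templates.h_offset
    if templates.H1 is not None:
        _paste(C, 2, templates.H1, h_start)
    if templates.H2 is not None:
        _paste(C, 3, templates.H2, h_start)
    return C


def _paste(C: np.ndarray, col: int, vec: np.ndarray, start: int) -> None:
    n = C.shape[0]
    lo = max(0, start)
    hi = min(n, start + len(vec))
    if hi > lo:
        C[lo:hi, col] = vec[lo - start:hi - start]


def active_columns(C: np.ndarray) -> np.ndarray:
    """Indices of columns that carry any signal (non-zero norm)."""
    return np.flatnonzero(np.linalg.norm(C, axis=0) > 0)


def solve_amplification(C: np.ndarray, Y: np.ndarray,
                        nonnegative_ahp: bool = False
                        ) -> tuple[np.ndarray, float]:
    """Least-squares amplification factors X minimizing ||C X - Y||.

    Returns ``(X, condition_number)``.  All-zero columns (absent templates)
    are excluded from the solve and get coefficient 0.  A rank-deficient or
    badly conditioned design raises a :class:`FitError` naming the
    collinear columns.  With ``nonnegative_ahp`` the H1/H2 coefficients are
    constrained to be >= 0 (bounded least squares); a and b stay free.
    """
    C = np.asarray(C, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if C.ndim != 2 or C.shape[0] != Y.shape[0]:
        raise FitError("component matrix and target lengths differ")
    cols = active_columns(C)
    if cols.size == 0:
        raise FitError("all component columns are zero")
    Cw = C[:, cols]
    sv = np.linalg.svd(Cw, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")
    if not np.isfinite(cond) or cond > MAX_CONDITION:
        raise FitError(
            "singular component design; collinear columns: "
            + ", ".join(_collinear_columns(Cw, cols)))
    if nonnegative_ahp:
        lo = np.full(cols.size, -np.inf)
        hi = np.full(cols.size, np.inf)
        lo[np.isin(cols, (2, 3))] = 0.0
        sol = lsq_linear(Cw, Y, bounds=(lo, hi))
        x_active = sol.x
    else:
        x_active, *_ = np.linalg.lstsq(Cw, Y, rcond=None)
    X = np.zeros(4)
    X[cols] = x_active
    return X, cond


def _collinear_columns(Cw: np.ndarray, cols: np.ndarray) -> list[str]:
    names = [COMPONENT_NAMES[i] for i in cols]
    unit = Cw / np.linalg.norm(Cw, axis=0)
    gram = np.abs(unit.T @ unit)
    flagged: set[str] = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if gram[i, j] > 1 - 1e-9:
                flagged.update((names[i], names[j]))
    return sorted(flagged) if flagged else names


def synthesize(C: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Composite signal ``Y_hat = C X``."""
    return np.asarray(C, dtype=float) @ np.asarray(X, dtype=float)


def fit_decomposition(Y: np.ndarray, templates: TemplateSet,
                      n1: int, n2: int, *, ap_id: str = "ap",
                      nd_step: int = 1, nonnegative_ahp: bool = False,
                      threshold: float = float("nan")) -> Decomposition:
    """Fit the four-component model to a baseline-subtracted AP vector.

    The sEJP delay is scanned exhaustively over ``range(n1, n2 + 1,
    nd_step)`` (``n1``/``n2`` are the onset and peak indices of ``Y``); at
    each delay the amplifications are solved by least squares and the delay
    with the smallest Euclidean residual wins (ties go to the smaller
    delay).  The stored ``rmse`` is the residual RMS over the fitted window.
    """
    Y = np.asarray(Y, dtype=float)
    if n1 > n2:
        raise FitError(f"empty delay interval [{n1}, {n2}]")
    if n2 >= Y.size:
        raise FitError("delay interval extends past the target vector")
    best: tuple[float, int, np.ndarray, float] | None = None
    for nd in range(n1, n2 + 1, max(1, nd_step)):
        C = component_matrix(templates, nd, Y.size)
        try:
            X, cond = solve_amplification(C, Y, nonnegative_ahp)
        except FitError:
            continue
        dist = float(np.linalg.norm(C @ X - Y))
        if best is None or dist < best[0]:
            best = (dist, nd, X, cond)
    if best is None:
        raise FitError("all candidate delays gave singular designs")
    dist, nd, X, cond = best
    return Decomposition(
        ap_id=ap_id, a=float(X[0]), b=float(X[1]), c=float(X[2]),
        d=float(X[3]), nd=nd, rmse=dist / np.sqrt(Y.size),
        threshold_used=threshold, condition_number=cond, n1=n1, n2=n2)
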