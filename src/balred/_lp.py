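"""Thin deterministic wrapper around scipy's HiGHS linear programming."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

__all__ = ["LPResult", "LPError", "solve_lp"]


class LPError(RuntimeError):
    """LP solver failure (anything other than optimal/unbounded/infeasible)."""


@dataclass(frozen=True)
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective: float | None
    x: np.ndarray | None


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    c: np.ndarray,
    A_eq: np.ndarray | None,
    b_eq: np.ndarray | None,
    bounds: list[tuple[float | None, float | None]],
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    sense: str = "min",
) -> LPResult:
    """Optimize ``c @ v`` subject to ``A_eq v = b_eq``, ``A_ub v <= b_ub`` and bounds."""
    if sense not in ("min", "max"):
        raise ValueError(f"unknown sense {sense!r}")
    sign = 1.0 if sense == "min" else -1.0
    res = linprog(
        sign * np.asarray(c, dtype=float),
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    status = _STATUS.get(res.status)
    if status is None:
        raise LPError(f"LP solver failed: {res.message}")
    if status != "optimal":
        return LPResult(status=status, objective=None, x=None)
    return LPResult(status="optimal", objective=sign * res.fun, x=res.x)


def clean_bounds(lo: np.ndarray, hi: np.ndarray) -> list[tuple[float | None, float | None]]:
    return [
        (None if math.isinf(l) else float(l), None if math.isinf(h) else float(h))
        for l, h in zip(lo, hi)
    ]
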