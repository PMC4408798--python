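"""Shared statistics: 2x2 chi-square tests and type-I calibration utilities.

All significance tests in this pipeline are Pearson chi-square tests on 2x2
contingency tables without continuity correction, with the p-value taken as
the right-tailed probability of the chi-square distribution with one degree
of freedom.  For df = 1 that tail probability has the closed form
``erfc(sqrt(x / 2))``, which is what :func:`chi2_2x2` uses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Tuple

import numpy as np

__all__ = ["ContingencyTable", "chi2_2x2", "chi2_right_tail_p", "typeI_calibration"]


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table of non-negative counts ``[[a, b], [c, d]]``."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency table counts must be non-negative")
        if self.a + self.b + self.c + self.d <= 0:
            raise ValueError("contingency table total must be positive")


def chi2_right_tail_p(chi2: float) -> float:
    """Right-tailed probability of chi-square(df=1) at ``chi2``."""
    if chi2 < 0:
        raise ValueError("chi-square statistic must be non-negative")
    return math.erfc(math.sqrt(chi2 / 2.0))


def chi2_2x2(table: ContingencyTable | tuple) -> Tuple[float, float]:
    """Pearson chi-square (no continuity correction) for a 2x2 table.

    Returns ``(chi2, p)`` where ``p`` is the right tail of chi-square(1).
    Raises :class:`ValueError` on a zero row or column margin (an expected
    cell of zero); warns when any expected count drops below 5.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(*table)
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) <= 0:
        raise ValueError("zero row or column margin: expected cell count is 0")
    expected_min = min(r1 * c1, r1 * c2, r2 * c1, r2 * c2) / n
    if expected_min < 5:
        warnings.warn(
            f"minimum expected cell count {expected_min:.2f} < 5; "
            "chi-square approximation may be poor",
            stacklevel=2,
        )
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return chi2, chi2_right_tail_p(chi2)


def typeI_calibration(
    null_simulator: Callable[[np.random.Generator], ContingencyTable | tuple],
    alpha: float,
    n_reps: int,
    seed: int = 0,
) -> float:
    """Fraction of null replicates rejected at level ``alpha``.

    ``null_simulator`` draws a 2x2 table under independence from the supplied
    generator; replicates whose table degenerates (zero margin) are redrawn.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if n_reps < 50:
        warnings.warn("fewer than 50 replicates: calibration estimate is noisy", stacklevel=2)
    rng = np.random.default_rng(seed)
    rejected = 0
    for _ in range(n_reps):
        while True:
            table = null_simulator(rng)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, p = chi2_2x2(table)
                break
            except ValueError:
                continue
        if p < alpha or alpha >= 1.0:  # alpha = 1 rejects everything, incl. p = 1
            rejected += 1
    return rejected / n_reps
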