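"""Closed-form fixation probabilities used as analytic oracles.

Well-mixed populations (the complete graph) and the cycle admit exact
expressions because the number of mutants performs a birth-death chain
on 0..N.  For any such chain with gain/loss probabilities T_j+/T_j- the
fixation probability of a single mutant is

    phi = 1 / (1 + sum_{k=1}^{N-1} prod_{j=1}^{k} T_j- / T_j+).

For the well-mixed population this yields (1 - 1/r) / (1 - 1/r^N) under
Bd and ((N-1)/N) (1 - 1/r) / (1 - 1/r^{N-1}) under dB; both reduce to
1/N at neutrality (r = 1), which is special-cased rather than left to
floating-point cancellation.

The cycle under dB is the canonical graph that is neither an amplifier
nor a suppressor: its fixation probability sits below the well-mixed
reference on both sides of r = 1.  Starting from a single mutant the
mutant set remains one contiguous arc, so the 2^N-state chain reduces
exactly to a birth-death chain on the arc length; the reduction is gated
in the tests by the full-matrix solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChainRates",
    "phi_chain",
    "phi_wellmixed_bd",
    "phi_wellmixed_db",
    "wellmixed_bd_rates",
    "cycle_db_rates",
    "phi_cycle_db",
    "cycle_db_deficit",
]


@dataclass(frozen=True)
class ChainRates:
    """Gain and loss probabilities T_j+ / T_j- of a birth-death chain on
    the mutant count j = 1 .. N-1 (absorbing at 0 and N)."""

    t_plus: tuple[float, ...]
    t_minus: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.t_plus) != len(self.t_minus):
            raise ValueError("t_plus and t_minus must have equal length")
        for tp, tm in zip(self.t_plus, self.t_minus):
            if not (0.0 < tp <= 1.0) or not (0.0 < tm <= 1.0):
                raise ValueError("all transition probabilities must lie in (0, 1]")
            if tp + tm > 1.0 + 1e-12:
                raise ValueError("T_j+ + T_j- must not exceed 1")

    @property
    def n(self) -> int:
        return len(self.t_plus) + 1


def phi_chain(rates: ChainRates) -> float:
    """Single-mutant fixation probability of a tri-diagonal chain with two
    absorbing boundaries."""
    gammas = np.asarray(rates.t_minus) / np.asarray(rates.t_plus)
    return float(1.0 / (1.0 + np.cumprod(gammas).sum()))


def phi_wellmixed_bd(r: float, n: int) -> float:
    """Well-mixed (complete-graph) fixation probability under Bd:
    (1 - 1/r) / (1 - 1/r^N), with the neutral limit 1/N at r = 1."""
    if r <= 0:
        raise ValueError("fitness must be positive")
    if n < 2:
        raise ValueError("population size must be >= 2")
    if r == 1.0:
        return 1.0 / n
    return (1.0 - 1.0 / r) / (1.0 - r ** (-n))


def phi_wellmixed_db(r: float, n: int) -> float:
    """Well-mixed fixation probability under dB:
    ((N-1)/N) (1 - 1/r) / (1 - 1/r^{N-1}), neutral limit 1/N.

    The (N-1)/N prefactor is the price of local selection: the initial
    mutant is lost outright with probability 1/N x (certainty of being
    replaced by a wild-type neighbor) more often than under Bd.
    """
    if r <= 0:
        raise ValueError("fitness must be positive")
    if n < 3:
        raise ValueError("population size must be >= 3 for dB")
    if r == 1.0:
        return 1.0 / n
    return (n - 1) / n * (1.0 - 1.0 / r) / (1.0 - r ** (-(n - 1)))


def wellmixed_bd_rates(r: float, n: int) -> ChainRates:
    """Bd transition probabilities on the complete graph without
    self-replacement:

        T_j+ = jr/(jr + N - j) x (N - j)/(N - 1),
        T_j- = (N - j)/(jr + N - j) x j/(N - 1).

    Their ratio is 1/r for every j, which is what makes the well-mixed
    Bd fixation probability independent of the self-replacement
    convention.
    """
    if r <= 0:
        raise ValueError("fitness must be positive")
    if n < 2:
        raise ValueError("population size must be >= 2")
    tp, tm = [], []
    for j in range(1, n):
        denom = j * r + n - j
        tp.append(j * r / denom * (n - j) / (n - 1))
        tm.append((n - j) / denom * j / (n - 1))
    return ChainRates(tuple(tp), tuple(tm))


def cycle_db_rates(r: float, n: int) -> ChainRates:
    """dB transition probabilities on the cycle of size n >= 3.

    The mutants always form one contiguous arc.  For an arc of length j:

    * gain (generic): one of the two wild-types flanking the arc dies
      (probability 2/N) and the adjacent mutant wins the vacancy against
      the wild-type on the other side, probability r/(r+1);
    * loss (generic): one of the two mutants at the arc ends dies (2/N)
      and the flanking wild-type wins, probability 1/(r+1);
    * j = 1: the lone mutant has two wild-type neighbors, so its death
      (1/N) is followed by certain wild-type replacement, T_1- = 1/N;
    * j = N-1: the last wild-type's death (1/N) is followed by certain
      mutant replacement, T_{N-1}+ = 1/N.

    Deaths interior to the arc (or to its complement) change nothing.
    """
    if n < 3:
        raise ValueError("the cycle reduction needs n >= 3")
    if r <= 0:
        raise ValueError("fitness must be positive")
    gain = 2.0 / n * r / (r + 1.0)
    loss = 2.0 / n / (r + 1.0)
    tp = [gain] * (n - 1)
    tm = [loss] * (n - 1)
    tm[0] = 1.0 / n
    tp[-1] = 1.0 / n
    return ChainRates(tuple(tp), tuple(tm))


def phi_cycle_db(r: float, n: int) -> float:
    """Fixation probability of a single mutant on the cycle under dB.

    At n = 4 this equals 2 r^2 / (3 r^2 + 2 r + 3) exactly.
    """
    return phi_chain(cycle_db_rates(r, n))


def cycle_db_deficit(r: float, n: int = 4) -> float:
    """Signed difference phi_cycle_dB - phi_wellmixed_dB.

    Nonpositive for every r > 0, zero only at r = 1: the cycle under dB
    depresses fixation for advantageous and disadvantageous mutants
    alike, which is what makes it neither an amplifier nor a suppressor.
    At n = 4 the difference equals
    -r^2 (r-1)^2 / (4 (r^2 + r + 1)(3 r^2 + 2 r + 3)).
    """
    return phi_cycle_db(r, n) - phi_wellmixed_db(r, n)
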