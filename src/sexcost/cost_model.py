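"""Deterministic theory of asexual-frequency change under a net cost of sex.

An obligately asexual lineage segregating in a dioecious sexual population
changes in frequency over one generation according to standard single-locus
selection arithmetic.  Writing ``q_t`` for the asexual frequency among
parents, ``W_asex`` for the asexual per-capita birth rate and
``W_sex = W_asex / c`` for the sexual one (``c`` is the *net cost of sex*),

    q_{t+1} = q_t W_asex / W_bar,   W_bar = q_t W_asex + (1 - q_t) W_sex,

which simplifies to the one-parameter recursion

    q_{t+1} = c q_t / (1 + q_t (c - 1)).

The net cost decomposes as ``c = r / s``: ``1/s`` is the cost of males
(``s`` the primary sex ratio, i.e. the proportion of sexual females'
offspring that are daughters) and ``r`` is the fecundity-survival ratio
(mean surviving offspring of asexual females over that of sexual females).
``r = 1`` is the classic all-else-equal assumption, under which the whole
cost of sex is the cost of producing sons.

All operations accept scalars or array-likes and apply elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CostParams",
    "FrequencyPair",
    "next_frequency",
    "fold_increase",
    "estimate_cost",
    "decompose_cost",
    "cost_of_males",
]


@dataclass(frozen=True)
class CostParams:
    """Net cost of sex ``c``, primary sex ratio ``s`` and their ratio ``r``.

    The three are linked exactly by ``c = r / s``; construct via
    :meth:`from_cost_and_sex_ratio` to keep the identity.
    """

    c: float
    s: float
    r: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"net cost of sex c must be > 0, got {self.c}")
        if not 0 < self.s <= 1:
            raise ValueError(f"primary sex ratio s must be in (0, 1], got {self.s}")
        if not self.r > 0:
            raise ValueError(f"fecundity-survival ratio r must be > 0, got {self.r}")
        if not np.isclose(self.c, self.r / self.s, rtol=1e-12, atol=1e-12):
            raise ValueError(
                f"inconsistent parameters: c={self.c} but r/s={self.r / self.s}"
            )

    @classmethod
    def from_cost_and_sex_ratio(cls, c: float, s: float) -> "CostParams":
        return cls(c=c, s=s, r=c * s)


@dataclass(frozen=True)
class FrequencyPair:
    """Asexual frequencies in the parental (``q_t``) and offspring (``q_t1``) generations."""

    q_t: float
    q_t1: float

    def __post_init__(self) -> None:
        for name, value in (("q_t", self.q_t), ("q_t1", self.q_t1)):
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")


def _validate_frequency(q, name: str = "q_t", open_interval: bool = False):
    q = np.asarray(q, dtype=float)
    if open_interval:
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError(f"{name} must lie strictly in (0, 1)")
    elif np.any((q < 0) | (q > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return q


def _validate_cost(c):
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("net cost of sex c must be > 0")
    return c


def next_frequency(q_t, c):
    """Asexual frequency in the offspring generation.

    Evaluates ``c q_t / (1 + q_t (c - 1))``.  With ``c = 1`` (no net cost)
    this is the identity map; with ``c > 1`` asexuals increase every
    generation and fix in the limit.

    Parameters
    ----------
    q_t : float or array-like
        Parental asexual frequency, in [0, 1].
    c : float or array-like
        Net cost of sex, > 0.
    """
    q_t = _validate_frequency(q_t)
    c = _validate_cost(c)
    out = c * q_t / (1.0 + q_t * (c - 1.0))
    return out if out.ndim else float(out)


def fold_increase(q_t, c):
    """Proportional one-generation increase in asexual frequency.

    Evaluates ``c / (1 + q_t (c - 1)) = next_frequency(q_t, c) / q_t``.
    Declines from ``c`` (the rare-mutant limit as ``q_t -> 0``, not an
    admissible input here) to 1 at fixation: a two-fold cost doubles a rare
    asexual lineage but yields far less than doubling once asexuals are
    common.

    Raises
    ------
    ValueError
        If ``q_t`` is 0 (the ratio is undefined; its limit is ``c``).
    """
    q_t = _validate_frequency(q_t)
    if np.any(q_t == 0):
        raise ValueError(
            "fold_increase is undefined at q_t = 0; the rare-mutant limit is c"
        )
    c = _validate_cost(c)
    out = c / (1.0 + q_t * (c - 1.0))
    return out if out.ndim else float(out)


def estimate_cost(q_t, q_t1):
    """Net cost of sex implied by one observed frequency change.

    Inverts the recursion: ``c = q_t1 (1 - q_t) / (q_t (1 - q_t1))``, the
    odds ratio of the offspring versus parental asexual frequencies.  Exact
    inverse of :func:`next_frequency` in ``c``.

    Raises
    ------
    ValueError
        If either frequency is 0 or 1: the odds ratio
        ``odds(q_t1)/odds(q_t)`` is undefined at the boundaries.
    """
    q_t = _validate_frequency(q_t, "q_t", open_interval=True)
    q_t1 = _validate_frequency(q_t1, "q_t1", open_interval=True)
    out = q_t1 * (1.0 - q_t) / (q_t * (1.0 - q_t1))
    return out if out.ndim else float(out)


def decompose_cost(c, s):
    """Fecundity-survival ratio ``r = c * s`` implied by a net cost and sex ratio.

    ``r`` is the mean number of surviving offspring of asexual females
    divided by that of sexual females; ``r = 1`` is consistent with the
    all-else-equal assumption (the entire net cost is the cost of males).
    """
    c = _validate_cost(c)
    s = np.asarray(s, dtype=float)
    if np.any((s <= 0) | (s > 1)):
        raise ValueError("primary sex ratio s must be in (0, 1]")
    out = c * s
    return out if out.ndim else float(out)


def cost_of_males(s):
    """Cost of producing sons, ``1/s``, for primary sex ratio ``s`` in (0, 1].

    Two-fold when broods are half sons (s = 0.5); 1 for all-daughter broods.
    """
    s = np.asarray(s, dtype=float)
    if np.any((s <= 0) | (s > 1)):
        raise ValueError("primary sex ratio s must be in (0, 1]")
    out = 1.0 / s
    return out if out.ndim else float(out)
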