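"""Monte Carlo permutation engine and p-value conventions shared by all detectors.

Significance of a hotspot statistic is judged against its permutation null:
the observed cell values are randomly reassigned to units N times
(conditional on the observed multiset of counts), the statistic is
recomputed on each rearrangement, and the rank of the observed value gives
the p-value with the usual (1 + r) / (1 + N) convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .lattice import CellField

__all__ = ["NullDistribution", "permute_field", "rescatter_field",
           "mc_pvalue", "build_null"]


@dataclass(frozen=True)
class NullDistribution:
    """Statistic values recomputed on permuted fields."""

    draws: np.ndarray
    n_sim: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.draws) != self.n_sim:
            raise ValueError("draws must hold exactly n_sim entries")


def permute_field(field: CellField, rng: np.random.Generator) -> CellField:
    """Uniformly random relabeling of cell values across units.

    The multiset of counts (and hence the total) is preserved; only the
    assignment of values to units changes.
    """
    if len(field) == 0:
        raise ValueError("cannot permute an empty field")
    return CellField(rng.permutation(field.values))


def rescatter_field(field: CellField, rng: np.random.Generator) -> CellField:
    """Re-scatter individual cases uniformly over units (multinomial null).

    Alternative null for count data: the N cases are dropped independently
    and uniformly on the lattice, so per-cell values are multinomial rather
    than a permutation of the observed ones.  Requires integer totals.
    """
    total = field.total
    if not float(total).is_integer():
        raise ValueError("case re-scattering requires an integer total count")
    n = len(field)
    return CellField(rng.multinomial(int(total), np.full(n, 1.0 / n)).astype(float))


def mc_pvalue(observed: float, null: NullDistribution) -> float:
    """Permutation p-value: (1 + #{draws >= observed}) / (1 + n_sim).

    Ties count toward the numerator (conservative); the observed statistic
    itself contributes the +1, so p lies in (0, 1].
    """
    if null.n_sim == 0:
        raise ValueError("empty null distribution")
    r = int(np.count_nonzero(null.draws >= observed))
    return (1 + r) / (1 + null.n_sim)


def build_null(statistic: Callable[[CellField], float], field: CellField,
               n_sim: int, seed: int | None = None,
               scheme: str = "permute") -> NullDistribution:
    """Null distribution of ``statistic`` over ``n_sim`` rearranged fields."""
    rng = np.random.default_rng(seed)
    draw = permute_field if scheme == "permute" else rescatter_field
    draws = np.array([statistic(draw(field, rng)) for _ in range(n_sim)])
    return NullDistribution(draws=draws, n_sim=n_sim, seed=seed)
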