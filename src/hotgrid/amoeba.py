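"""AMOEBA: multidirectional optimal ecotope-based hotspot growth.

From every seed unit an irregular "ecotope" is grown: at each round the
first-order neighbours of the current ecotope are considered and the
subset whose inclusion maximizes the seed's standardized G* is adopted;
rejected frontier units are excluded from all later rounds, and growth
stops when no addition improves the statistic.

The statistic optimized is the randomization z-score of G* for the member
set S treated as the neighbourhood of the seed,

    z(S) = (sum_S x - |S| xbar) / sqrt(|S| (n - |S|) sigma^2 / (n - 1)),

a monotone transform of G* at fixed |S|.  (Raw G* is non-decreasing under
any addition of non-negative values, so the size-penalized z-form is what
makes growth terminate.)  Because z at fixed |S| is monotone in the added
mass, the optimal frontier subset of each cardinality is a prefix of the
value-sorted frontier, so scanning prefixes evaluates "each possible
combination" exactly; this is verified against exhaustive connected-subset
search in the test suite.

Significance of an ecotope is Monte Carlo: the field is permuted and an
ecotope regrown from the same seed position; the rank of the observed z
among the null z's gives the p-value.  Significant ecotopes from different
seeds are resolved greedily by descending z, discarding overlapping
competitors, and the survivors' union forms the hotspot labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .lattice import CellField, GridLattice, contiguity_weights
from .lisa import HotspotLabeling
from .significance import NullDistribution, mc_pvalue

__all__ = ["Ecotope", "grow_ecotope", "amoeba_detect", "AMOEBA",
           "AmoebaResults"]


@dataclass(frozen=True)
class Ecotope:
    """A grown neighbourhood: connected member set containing the seed."""

    seed: int
    members: frozenset
    gstar: float
    z: float
    generation: int
    p: float | None = None


@njit(cache=True)
def _grow(indptr, indices, values, xbar, sq, seed, state, frontier, adopted,
          touched):
    """Grow one ecotope from ``seed``.  Returns (z, total, size, generation).

    ``state``: 0 untouched, 1 member, 2 excluded, 3 frontier.  ``sq`` is
    sigma^2 / (n - 1).  The caller resets ``state`` via ``touched``.
    """
    n = values.shape[0]
    n_touched = 0
    state[seed] = 1
    touched[n_touched] = seed
    n_touched += 1
    total = values[seed]
    size = 1
    cur_z = (total - xbar) / np.sqrt((n - 1.0) * sq) if sq > 0 else 0.0
    gen = 0

    # frontier holds candidate ids; rebuilt incrementally from new members
    nf = 0
    for e in range(indptr[seed], indptr[seed + 1]):
        j = indices[e]
        if state[j] == 0:
            state[j] = 3
            frontier[nf] = j
            nf += 1
            touched[n_touched] = j
            n_touched += 1

    while nf > 0:
        # insertion sort of frontier by (value desc, id asc) for determinism
        for a in range(1, nf):
            key = frontier[a]
            kv = values[key]
            b = a - 1
            while b >= 0 and (values[frontier[b]] < kv or
                              (values[frontier[b]] == kv and frontier[b] > key)):
                frontier[b + 1] = frontier[b]
                b -= 1
            frontier[b + 1] = key
        # best value-sorted prefix
        best_z = cur_z
        best_k = 0
        acc = total
        for k in range(1, nf + 1):
            acc += values[frontier[k - 1]]
            csize = size + k
            if csize >= n:
                break
            zk = (acc - csize * xbar) / np.sqrt(csize * (n - csize) * sq)
            if zk > best_z:
                best_z = zk
                best_k = k
        if best_k == 0:
            break
        # adopt the prefix, exclude the rest of this round's frontier
        for k in range(best_k):
            adopted[k] = frontier[k]
            state[frontier[k]] = 1
            total += values[frontier[k]]
        for k in range(best_k, nf):
            state[frontier[k]] = 2
        size += best_k
        cur_z = best_z
        gen += 1
        # next frontier: untouched neighbours of the newly adopted members
        # (adopted is a separate buffer: frontier is about to be overwritten)
        new_nf = 0
        for k in range(best_k):
            m = adopted[k]
            for e in range(indptr[m], indptr[m + 1]):
                j = indices[e]
                if state[j] == 0:
                    state[j] = 3
                    frontier[new_nf] = j
                    new_nf += 1
                    touched[n_touched] = j
                    n_touched += 1
        nf = new_nf

    return cur_z, total, size, gen, n_touched


@njit(cache=True)
def _grow_all_z(indptr, indices, values, xbar, sq):
    """z of the grown ecotope for every seed (used for the permutation null)."""
    n = values.shape[0]
    out = np.empty(n)
    state = np.zeros(n, dtype=np.int8)
    frontier = np.empty(n, dtype=np.int64)
    adopted = np.empty(n, dtype=np.int64)
    touched = np.empty(n, dtype=np.int64)
    for seed in range(n):
        z, _, _, _, n_touched = _grow(indptr, indices, values, xbar, sq,
                                      seed, state, frontier, adopted, touched)
        out[seed] = z
        for t in range(n_touched):
            state[touched[t]] = 0
    return out


def _field_params(values: np.ndarray) -> tuple[float, float]:
    xbar = float(values.mean())
    sigma2 = float(values.var())
    if sigma2 == 0:
        raise ValueError("ecotope growth is undefined on a constant field")
    return xbar, sigma2 / (len(values) - 1)


def grow_ecotope(seed: int, lattice: GridLattice, field: CellField,
                 rule: str = "queen") -> Ecotope:
    """Grow the G*-optimal ecotope from one seed unit."""
    if len(field) != lattice.n_units:
        raise ValueError("field and lattice are misaligned")
    w = contiguity_weights(lattice, rule=rule).matrix
    values = field.values
    xbar, sq = _field_params(values)
    n = len(values)
    state = np.zeros(n, dtype=np.int8)
    frontier = np.empty(n, dtype=np.int64)
    adopted = np.empty(n, dtype=np.int64)
    touched = np.empty(n, dtype=np.int64)
    z, total, size, gen, _ = _grow(w.indptr, w.indices.astype(np.int64),
                                   values, xbar, sq, int(seed), state,
                                   frontier, adopted, touched)
    members = frozenset(int(i) for i in np.flatnonzero(state == 1))
    return Ecotope(seed=int(seed), members=members,
                   gstar=total / values.sum(), z=float(z), generation=gen)


@dataclass(frozen=True)
class AmoebaResults:
    """Fitted AMOEBA detector: surviving ecotopes and the hotspot labeling."""

    model: "AMOEBA"
    ecotopes: tuple
    z: np.ndarray
    p: np.ndarray
    labeling: HotspotLabeling
    alpha: float
    n_sim: int

    @property
    def hotspot_mask(self) -> np.ndarray:
        return self.labeling.mask

    def summary(self) -> str:
        lines = [
            "AMOEBA ecotope detection",
            "-" * 40,
            f"units                 {self.model.lattice.n_units}",
            f"permutations          {self.n_sim}",
            f"alpha                 {self.alpha}",
            f"surviving ecotopes    {len(self.ecotopes)}",
            f"hotspot cells         {int(self.labeling.mask.sum())}",
        ]
        for k, eco in enumerate(self.ecotopes):
            lines.append(f"  ecotope {k}: seed {eco.seed}, "
                         f"{len(eco.members)} cells, z = {eco.z:.2f}, "
                         f"p = {eco.p:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_unit_values

        return plot_unit_values(self.model.lattice, self.model.field.values,
                                mask=self.labeling.mask, ax=ax,
                                title="AMOEBA ecotopes")


class AMOEBA:
    """AMOEBA hotspot model over a lattice count field (queen contiguity
    by default, matching the other detectors)."""

    def __init__(self, field: CellField, lattice: GridLattice,
                 rule: str = "queen"):
        if len(field) != lattice.n_units:
            raise ValueError("field and lattice are misaligned")
        if field.total <= 0:
            raise ValueError("AMOEBA requires a positive total case count")
        self.field = field
        self.lattice = lattice
        self.rule = rule
        w = contiguity_weights(lattice, rule=rule).matrix
        self._indptr = w.indptr
        self._indices = w.indices.astype(np.int64)

    @classmethod
    def from_dataframe(cls, df, lattice: GridLattice, value_col: str = "value",
                       **kw):
        return cls(CellField(df[value_col].to_numpy(dtype=float)), lattice, **kw)

    def _grow_all(self, values: np.ndarray) -> np.ndarray:
        xbar, sq = _field_params(values)
        return _grow_all_z(self._indptr, self._indices, values, xbar, sq)

    def fit(self, n_sim: int = 999, alpha: float = 0.05,
            seed: int | None = None) -> AmoebaResults:
        """Grow every seed, test against same-seed permutation nulls, and
        resolve overlaps keeping the highest-z ecotopes."""
        values = self.field.values
        n = len(values)
        z_obs = self._grow_all(values)

        rng = np.random.default_rng(seed)
        exceed = np.zeros(n, dtype=np.int64)
        for _ in range(n_sim):
            z_null = self._grow_all(rng.permutation(values))
            exceed += z_null >= z_obs
        p = (1 + exceed) / (1 + n_sim)

        # significant, upward ecotopes; greedy overlap resolution by z
        cand = np.flatnonzero((p <= alpha) & (z_obs > 0))
        ecotopes = []
        taken = np.zeros(n, dtype=bool)
        cluster_id = np.full(n, -1, dtype=int)
        if cand.size:
            grown = {int(s): grow_ecotope(int(s), self.lattice, self.field,
                                          rule=self.rule) for s in cand}
            order = sorted(cand, key=lambda s: (-z_obs[s],
                                                len(grown[int(s)].members), s))
            for s in order:
                eco = grown[int(s)]
                mem = np.fromiter(eco.members, dtype=int)
                if taken[mem].any():
                    continue
                taken[mem] = True
                cluster_id[mem] = len(ecotopes)
                ecotopes.append(Ecotope(seed=eco.seed, members=eco.members,
                                        gstar=eco.gstar, z=eco.z,
                                        generation=eco.generation,
                                        p=float(p[s])))
        labeling = HotspotLabeling(mask=taken, cluster_id=cluster_id)
        return AmoebaResults(model=self, ecotopes=tuple(ecotopes), z=z_obs,
                             p=p, labeling=labeling, alpha=alpha, n_sim=n_sim)


def amoeba_detect(lattice: GridLattice, field: CellField, n_sim: int = 999,
                  alpha: float = 0.05, seed: int | None = None,
                  rule: str = "queen") -> HotspotLabeling:
    """Functional wrapper: fit :class:`AMOEBA` and return the labeling."""
    model = AMOEBA(field, lattice, rule=rule)
    return model.fit(n_sim=n_sim, alpha=alpha, seed=seed).labeling
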