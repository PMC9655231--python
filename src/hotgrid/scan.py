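"""Poisson circular spatial scan statistic.

Variable-radius circular windows are centred on every unit; a window's
member set is the units whose centroids lie within the radius of the
centre's centroid.  Under the uniform-risk Poisson model the expected
count inside a window is mu = C * (window population share), with per-unit
population 1 by default so that mu is proportional to the number of member
cells.  Each window is scored with the one-sided likelihood ratio

    LR = (c / mu)^c * ((C - c) / (C - mu))^(C - c)   for c > mu, else 1,

and the most likely cluster is the window maximizing LR.  Its significance
comes from the permutation null of *maximum* LR over rearranged fields,
which accounts for the multiplicity of windows; secondary clusters are
reported greedily in descending LR, skipping windows that overlap an
already-reported cluster, each tested against the same max-LR null.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .lattice import CellField, GridLattice
from .lisa import HotspotLabeling
from .significance import NullDistribution, mc_pvalue

__all__ = ["ScanWindow", "Cluster", "ClusterSet", "poisson_lr",
           "enumerate_windows", "scan_detect", "SpatialScan", "ScanResults"]


@dataclass(frozen=True)
class ScanWindow:
    """One circular window: centre, radius, members and Poisson quantities."""

    center_unit: int
    radius: float
    members: frozenset
    c: float
    mu: float


@dataclass(frozen=True)
class Cluster:
    members: np.ndarray
    log_lr: float
    p: float

    @property
    def lr(self) -> float:
        with np.errstate(over="ignore"):
            return float(np.exp(self.log_lr))


@dataclass(frozen=True)
class ClusterSet:
    """Disjoint significant clusters, ordered by descending likelihood ratio."""

    clusters: tuple
    alpha: float

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def mask(self, n_units: int) -> np.ndarray:
        out = np.zeros(n_units, dtype=bool)
        for cl in self.clusters:
            out[cl.members] = True
        return out

    def labeling(self, n_units: int) -> HotspotLabeling:
        cluster_id = np.full(n_units, -1, dtype=int)
        for k, cl in enumerate(self.clusters):
            cluster_id[cl.members] = k
        return HotspotLabeling(mask=self.mask(n_units), cluster_id=cluster_id)


def log_poisson_lr(c, mu, C):
    """log LR of the one-sided Poisson scan statistic (vectorized).

    0 for c <= mu (a deficit is not a hotspot).  The boundary c = C is the
    limit of the second factor, which tends to 1.
    """
    c = np.asarray(c, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or np.any(mu >= C):
        raise ValueError("need 0 < mu < C for a strict window subset")
    if np.any(c < 0) or np.any(c > C):
        raise ValueError("need 0 <= c <= C")
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = np.where(c > 0, c * np.log(c / mu), 0.0)
        rest = C - c
        outside = np.where(rest > 0, rest * np.log(rest / (C - mu)), 0.0)
    llr = inside + outside
    return np.where(c > mu, llr, 0.0)


def poisson_lr(c: float, mu: float, C: float) -> float:
    """Likelihood ratio of Poisson counts inside vs outside a window."""
    return float(np.exp(log_poisson_lr(c, mu, C)))


class _WindowTable:
    """Precomputed window geometry shared by the observed scan and the null.

    For each centre, units sorted by centroid distance with prefix windows
    marked at distinct-radius boundaries and truncated at the population cap.
    """

    def __init__(self, lattice: GridLattice, max_fraction: float,
                 population: np.ndarray | None = None):
        if not (0 < max_fraction <= 1):
            raise ValueError("max_fraction must lie in (0, 1]")
        n = lattice.n_units
        pop = (np.ones(n) if population is None
               else np.asarray(population, dtype=float))
        if pop.shape != (n,) or np.any(pop < 0) or pop.sum() <= 0:
            raise ValueError("invalid population vector")
        xy = lattice.centroids
        d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        order = np.argsort(d2, axis=1, kind="stable")
        dsort = np.take_along_axis(d2, order, axis=1)
        cum_pop = np.cumsum(pop[order], axis=1)
        share = cum_pop / pop.sum()
        # prefix k (0-based) closes a window iff the next distance is strictly
        # larger (or it is the last unit) and the population cap is respected
        boundary = np.ones((n, n), dtype=bool)
        boundary[:, :-1] = dsort[:, 1:] > dsort[:, :-1] + 1e-12
        boundary &= share <= max_fraction + 1e-12
        kmax = int(np.max(np.count_nonzero(share <= max_fraction + 1e-12, axis=1)))
        kmax = max(kmax, 1)
        self.order = order[:, :kmax]
        self.boundary = boundary[:, :kmax]
        self.boundary[:, 0] |= ~self.boundary.any(axis=1)  # singleton fallback
        self.share = share[:, :kmax]
        self.radius = np.sqrt(dsort[:, :kmax])
        self.n = n

    def log_lr(self, values: np.ndarray) -> np.ndarray:
        """(n, kmax) log-LR matrix; -inf where no window closes."""
        C = values.sum()
        c = np.cumsum(values[self.order], axis=1)
        mu = C * self.share
        with np.errstate(divide="ignore", invalid="ignore"):
            inside = np.where(c > 0, c * np.log(c / mu), 0.0)
            rest = C - c
            outside = np.where(rest > 0, rest * np.log(rest / (C - mu)), 0.0)
        llr = np.where(c > mu, inside + outside, 0.0)
        # windows covering everything (mu == C) are not strict subsets
        llr = np.where(mu >= C, -np.inf, llr)
        return np.where(self.boundary, llr, -np.inf)

    def members(self, i: int, k: int) -> np.ndarray:
        return np.sort(self.order[i, :k + 1])


def enumerate_windows(lattice: GridLattice, field: CellField,
                      max_fraction: float = 0.5,
                      population: np.ndarray | None = None) -> list[ScanWindow]:
    """All distinct circular windows up to the population cap.

    Windows with identical member sets (reached from different centres or
    radii) are reported once, keeping the lowest centre id.
    """
    table = _WindowTable(lattice, max_fraction, population)
    values = field.values
    C = values.sum()
    pop = np.ones(lattice.n_units) if population is None else population
    seen = set()
    out = []
    for i in range(table.n):
        for k in np.flatnonzero(table.boundary[i]):
            mem = frozenset(int(u) for u in table.order[i, :k + 1])
            if mem in seen:
                continue
            seen.add(mem)
            idx = table.order[i, :k + 1]
            out.append(ScanWindow(center_unit=i,
                                  radius=float(table.radius[i, k]),
                                  members=mem,
                                  c=float(values[idx].sum()),
                                  mu=float(C * table.share[i, k])))
    return out


@dataclass(frozen=True)
class ScanResults:
    """Fitted scan: significant clusters plus the max-LR permutation null."""

    model: "SpatialScan"
    clusters: ClusterSet
    max_log_lr: float
    null: NullDistribution
    p_primary: float

    @property
    def hotspot_mask(self) -> np.ndarray:
        return self.clusters.mask(self.model.lattice.n_units)

    @property
    def labeling(self) -> HotspotLabeling:
        return self.clusters.labeling(self.model.lattice.n_units)

    def summary(self) -> str:
        lines = [
            "Poisson spatial scan",
            "-" * 40,
            f"units / total cases   {self.model.lattice.n_units} / "
            f"{self.model.field.total:.0f}",
            f"max window fraction   {self.model.max_fraction}",
            f"permutations          {self.null.n_sim}",
            f"max log LR            {self.max_log_lr:.3f} (p = {self.p_primary:.4g})",
            f"significant clusters  {len(self.clusters)} at alpha = "
            f"{self.clusters.alpha}",
        ]
        for k, cl in enumerate(self.clusters):
            lines.append(f"  cluster {k}: {len(cl.members)} cells, "
                         f"log LR {cl.log_lr:.3f}, p = {cl.p:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        from .plotting import plot_unit_values

        lab = self.labeling
        return plot_unit_values(self.model.lattice, self.model.field.values,
                                mask=lab.mask, ax=ax, title="scan clusters")


class SpatialScan:
    """Poisson circular scan model over a lattice count field.

    Parameters
    ----------
    field, lattice
        Case counts and study-region geometry.
    max_fraction : float
        Upper size limit of a window as a share of the background
        population (0.5 by default, i.e. half the study region).
    population : ndarray, optional
        Per-unit background population; uniform (1 per cell) when omitted,
        which makes mu proportional to the window's cell count.
    """

    def __init__(self, field: CellField, lattice: GridLattice,
                 max_fraction: float = 0.5,
                 population: np.ndarray | None = None):
        if len(field) != lattice.n_units:
            raise ValueError("field and lattice are misaligned")
        if field.total <= 0:
            raise ValueError("scan requires a positive total case count")
        self.field = field
        self.lattice = lattice
        self.max_fraction = max_fraction
        self.population = population
        self._table = _WindowTable(lattice, max_fraction, population)

    @classmethod
    def from_dataframe(cls, df, lattice: GridLattice, value_col: str = "value",
                       **kw):
        return cls(CellField(df[value_col].to_numpy(dtype=float)), lattice, **kw)

    def fit(self, n_sim: int = 999, alpha: float = 0.05,
            seed: int | None = None) -> ScanResults:
        """Scan all windows and test them against the max-LR permutation null."""
        table = self._table
        values = self.field.values
        llr = table.log_lr(values)
        t_obs = float(llr.max())

        rng = np.random.default_rng(seed)
        draws = np.empty(n_sim)
        for s in range(n_sim):
            draws[s] = table.log_lr(rng.permutation(values)).max()
        null = NullDistribution(draws=draws, n_sim=n_sim, seed=seed)
        p_primary = mc_pvalue(t_obs, null)

        clusters = self._extract_clusters(llr, null, alpha)
        return ScanResults(model=self, clusters=clusters, max_log_lr=t_obs,
                           null=null, p_primary=p_primary)

    def _extract_clusters(self, llr: np.ndarray, null: NullDistribution,
                          alpha: float) -> ClusterSet:
        # greedy non-overlapping report in descending LR; ties prefer the
        # smaller window, then the lower centre id (determinism)
        table = self._table
        cand_i, cand_k = np.nonzero(llr > 0)
        if cand_i.size == 0:
            return ClusterSet(clusters=(), alpha=alpha)
        vals = llr[cand_i, cand_k]
        # significance threshold on the shared null: smallest LR still at p<=alpha
        order = np.lexsort((cand_i, cand_k, -vals))
        taken = np.zeros(table.n, dtype=bool)
        found = []
        for idx in order:
            i, k = int(cand_i[idx]), int(cand_k[idx])
            p = mc_pvalue(float(vals[idx]), null)
            if p > alpha:
                break  # LR only decreases from here on
            members = table.members(i, k)
            if taken[members].any():
                continue
            taken[members] = True
            found.append(Cluster(members=members, log_lr=float(vals[idx]), p=p))
        return ClusterSet(clusters=tuple(found), alpha=alpha)


def scan_detect(lattice: GridLattice, field: CellField,
                max_fraction: float = 0.5, n_sim: int = 999,
                alpha: float = 0.05, seed: int | None = None,
                population: np.ndarray | None = None) -> ClusterSet:
    """Functional wrapper: fit a :class:`SpatialScan` and return its clusters."""
    model = SpatialScan(field, lattice, max_fraction=max_fraction,
                        population=population)
    return model.fit(n_sim=n_sim, alpha=alpha, seed=seed).clusters
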