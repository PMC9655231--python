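"""Local autocorrelation detectors: Getis-Ord G* and local Moran's I.

Both statistics compare a unit's neighbourhood with the study area:

* G*_i = sum_j w_ij x_j / sum_j x_j with the self weight included — the
  share of the total attribute mass lying in the neighbourhood of unit i;
* I_i = ((x_i - xbar) / S^2) * sum_j w_ij (x_j - xbar), self excluded,
  with S^2 the population (divide-by-n) variance — positive when a unit
  and its neighbours deviate from the mean in the same direction.

Significance uses the analytic z-score under the randomization hypothesis
(values permuted over units, moments verified against exhaustive
enumeration), one-sided in the upper tail; a Monte Carlo permutation test
is available as an alternative.  Hotspot extraction keeps, for G*, units
with positive z and p below the level, and, for Moran, significant
positive I_i whose own value is above the mean (high-high clusters only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .lattice import CellField, GridLattice, WeightsMatrix, contiguity_weights
from .significance import mc_pvalue, NullDistribution, permute_field

__all__ = [
    "LocalStatResult",
    "HotspotLabeling",
    "getis_ord_gstar",
    "local_morans_i",
    "extract_hotspots",
    "bh_adjust",
    "GetisOrdGStar",
    "LocalMoran",
]


@dataclass(frozen=True)
class LocalStatResult:
    """Per-unit statistic, z-score and one-sided upper p-value."""

    stat: np.ndarray
    z: np.ndarray
    p: np.ndarray
    method: str
    mean_x: float
    var_x: float


@dataclass(frozen=True)
class HotspotLabeling:
    """Boolean hotspot mask plus contiguous-cluster ids (-1 = background)."""

    mask: np.ndarray
    cluster_id: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max()) + 1 if self.mask.any() else 0

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_id == k)


def _check(field: CellField, weights: WeightsMatrix) -> None:
    if weights.n != len(field):
        raise ValueError("field and weights are misaligned")
    if len(field) < 2:
        raise ValueError("need at least 2 units")


def getis_ord_gstar(field: CellField, weights: WeightsMatrix) -> LocalStatResult:
    """Getis-Ord G* with analytic randomization z-scores.

    ``weights`` must include the self weight (w_ii = 1).  On a constant
    field the variance is zero and z / p are flagged NaN per unit.
    """
    _check(field, weights)
    if not weights.include_self:
        raise ValueError("G* requires weights with include_self=True")
    x = field.values
    n = len(x)
    xbar = x.mean()
    sigma2 = x.var()  # population variance
    num = weights.matrix @ x
    stat = num / x.sum()
    wi = weights.row_sums().astype(float)
    ez = wi / n
    var = wi * (n - wi) * sigma2 / ((n - 1) * n ** 2 * xbar ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (stat - ez) / np.sqrt(var), np.nan)
    p = stats.norm.sf(z)
    return LocalStatResult(stat=stat, z=z, p=p, method="gstar",
                           mean_x=float(xbar), var_x=float(sigma2))


def local_morans_i(field: CellField, weights: WeightsMatrix) -> LocalStatResult:
    """Local Moran's I with analytic randomization z-scores (self excluded)."""
    _check(field, weights)
    if weights.include_self:
        raise ValueError("local Moran requires weights with include_self=False")
    x = field.values
    n = len(x)
    xbar = x.mean()
    m2 = x.var()  # population variance S^2
    zdev = x - xbar
    if m2 == 0:
        nanv = np.full(n, np.nan)
        return LocalStatResult(stat=nanv, z=nanv, p=nanv, method="moran",
                               mean_x=float(xbar), var_x=0.0)
    lag = weights.matrix @ zdev
    stat = zdev / m2 * lag
    wi = weights.row_sums().astype(float)
    wi2 = wi  # binary weights: sum of squares equals the row sum
    b2 = (zdev ** 4).mean() / m2 ** 2
    ei = -wi / (n - 1)
    var = (wi2 * (n - b2) / (n - 1)
           + (wi ** 2 - wi2) * (2 * b2 - n) / ((n - 1) * (n - 2))
           - wi ** 2 / (n - 1) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(var > 0, (stat - ei) / np.sqrt(var), np.nan)
    p = stats.norm.sf(z)
    return LocalStatResult(stat=stat, z=z, p=p, method="moran",
                           mean_x=float(xbar), var_x=float(m2))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def _label_components(flags: np.ndarray, weights: WeightsMatrix) -> np.ndarray:
    """Group contiguous flagged units; -1 for background units."""
    from scipy.sparse.csgraph import connected_components

    cluster_id = np.full(flags.size, -1, dtype=int)
    members = np.flatnonzero(flags)
    if members.size == 0:
        return cluster_id
    sub = weights.matrix[members][:, members]
    _, labels = connected_components(sub, directed=False)
    # renumber by first occurrence for determinism
    _, labels = np.unique(labels, return_inverse=True)
    cluster_id[members] = labels
    return cluster_id


def extract_hotspots(result: LocalStatResult, field: CellField,
                     weights: WeightsMatrix, alpha: float = 0.05,
                     correction: str = "none",
                     cold: bool = False) -> HotspotLabeling:
    """Threshold a local-statistic result into a hotspot labeling.

    G*: units with p <= alpha and z > 0.  Moran: additionally requires the
    statistic positive and the unit's own value above the mean, so only
    high-high clusters are kept (low-low clusters are also significant
    positive-I configurations but are not hotspots).  ``correction='bh'``
    applies Benjamini-Hochberg before thresholding.  ``cold=True`` flips
    the direction to extract cold spots instead.
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    p = result.p if not cold else 1.0 - result.p
    if correction == "bh":
        p = bh_adjust(p)
    sign = -1.0 if cold else 1.0
    with np.errstate(invalid="ignore"):
        flags = (p <= alpha) & (sign * result.z > 0)
        if result.method == "moran":
            flags &= (result.stat > 0) & (sign * (field.values - result.mean_x) > 0)
    flags = np.where(np.isnan(result.z), False, flags)
    cluster_id = _label_components(flags, weights)
    return HotspotLabeling(mask=flags, cluster_id=cluster_id)


def _mc_pvalues(field: CellField, weights: WeightsMatrix, method: str,
                observed: np.ndarray, n_sim: int, seed) -> np.ndarray:
    """Per-unit permutation p-values against the relabeling null."""
    fn = getis_ord_gstar if method == "gstar" else local_morans_i
    rng = np.random.default_rng(seed)
    count = np.zeros(len(field), dtype=int)
    for _ in range(n_sim):
        perm = fn(permute_field(field, rng), weights)
        count += perm.stat >= observed
    return (1 + count) / (1 + n_sim)


class _LocalModel:
    """Shared scaffolding for the two local-statistic models."""

    method: str

    def __init__(self, field: CellField, lattice: GridLattice,
                 weights: WeightsMatrix | None = None, rule: str = "queen",
                 threshold: float | None = None):
        include_self = self.method == "gstar"
        if weights is None:
            weights = contiguity_weights(lattice, rule=rule, threshold=threshold,
                                         include_self=include_self)
        if weights.include_self != include_self:
            raise ValueError(f"{self.method} weights must have "
                             f"include_self={include_self}")
        self.field = field
        self.lattice = lattice
        self.weights = weights

    @classmethod
    def from_dataframe(cls, df, lattice: GridLattice, value_col: str = "value",
                       **kw):
        """Build from a per-unit dataframe aligned with the lattice order."""
        return cls(CellField(df[value_col].to_numpy(dtype=float)), lattice, **kw)

    def _stat(self, field: CellField) -> LocalStatResult:
        fn = getis_ord_gstar if self.method == "gstar" else local_morans_i
        return fn(field, self.weights)

    def fit(self, alpha: float = 0.05, correction: str = "none",
            inference: str = "analytic", n_sim: int = 999,
            seed: int | None = None) -> "LocalResults":
        """Compute the statistic and extract significant hotspots.

        ``inference='analytic'`` uses the normal z-test (default);
        ``'permutation'`` replaces the p-values with Monte Carlo ones from
        ``n_sim`` relabelings of the field.
        """
        res = self._stat(self.field)
        if inference == "permutation":
            p = _mc_pvalues(self.field, self.weights, self.method,
                            res.stat, n_sim, seed)
            res = LocalStatResult(stat=res.stat, z=res.z, p=p,
                                  method=res.method, mean_x=res.mean_x,
                                  var_x=res.var_x)
        elif inference != "analytic":
            raise ValueError(f"unknown inference {inference!r}")
        labeling = extract_hotspots(res, self.field, self.weights,
                                    alpha=alpha, correction=correction)
        return LocalResults(model=self, result=res, labeling=labeling,
                            alpha=alpha, correction=correction)


class GetisOrdGStar(_LocalModel):
    """Getis-Ord G* hotspot model over a lattice count field."""

    method = "gstar"


class LocalMoran(_LocalModel):
    """Local Moran's I (LISA) hotspot model over a lattice count field."""

    method = "moran"


@dataclass
class LocalResults:
    """Fitted local-statistic detector: per-unit scores and the labeling."""

    model: _LocalModel
    result: LocalStatResult
    labeling: HotspotLabeling
    alpha: float
    correction: str

    @property
    def hotspot_mask(self) -> np.ndarray:
        return self.labeling.mask

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "unit": np.arange(len(self.result.stat)),
            "stat": self.result.stat,
            "z": self.result.z,
            "p_value": self.result.p,
            "hotspot": self.labeling.mask.astype(int),
            "cluster_id": self.labeling.cluster_id,
        })

    def summary(self) -> str:
        r = self.result
        k = int(self.labeling.mask.sum())
        name = {"gstar": "Getis-Ord G*", "moran": "local Moran's I"}[r.method]
        lines = [
            f"{name} hotspot detection",
            "-" * 40,
            f"units                 {len(r.stat)}",
            f"mean / variance       {r.mean_x:.4f} / {r.var_x:.4f}",
            f"alpha                 {self.alpha} ({self.correction} correction)",
            f"hotspot cells         {k}",
            f"clusters              {self.labeling.n_clusters}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Map of z-scores with hotspot cells outlined (regular grids)."""
        from .plotting import plot_unit_values

        return plot_unit_values(self.model.lattice, self.result.z,
                                mask=self.labeling.mask, ax=ax,
                                title=f"{self.result.method} z-score")
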