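"""k-nearest-neighbour spatial weights and Lee's L bivariate spatial
association.

Lee's L couples the Pearson correlation between two variables with the
spatial autocorrelation of each: it is the cross-product of the spatially
lagged, centred variables, scaled so that under row-standardised weights
L lies in [-1, 1]. Positive L means high values of one variable sit near
high values of the other (spatial dependency); negative L means they
spatially repel (spatial discrepancy). Inference is by Monte-Carlo
permutation: the (x_i, y_i) pairs are relocated jointly across sites,
which preserves the aspatial correlation while destroying the spatial
arrangement, so the null is "no *spatial* association".

Global statistic (with spatial lag ~x_i = sum_j w_ij (x_j - xbar)):

    L = n / sum_i (sum_j w_ij)^2 * sum_i ~x_i ~y_i / (||x - xbar|| ||y - ybar||)

Local decomposition:

    L_i = n * ~x_i ~y_i / (||x - xbar|| ||y - ybar||)

so mean(L_i) = L exactly under row standardisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

from .errors import ConfigurationError, DataError
from .geo import pairwise_haversine

WEIGHT_STYLES = ("binary", "row_standardized")


@dataclass
class SpatialWeights:
    """Sparse k-NN neighbour structure.

    ``neighbors[i]`` holds the k neighbour indices of observation i in
    ascending-distance order; ``weights[i]`` the matching weights. No
    self-neighbours. k-NN weights are in general asymmetric (i being j's
    neighbour does not make j i's neighbour) and are kept that way.
    """

    neighbors: np.ndarray  # (n, k) int
    weights: np.ndarray  # (n, k) float
    style: str
    k: int

    def __post_init__(self):
        if self.style not in WEIGHT_STYLES:
            raise ConfigurationError(f"unknown weight style {self.style!r}")
        self.neighbors = np.asarray(self.neighbors, dtype=np.intp)
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.n
        if np.any(self.neighbors == np.arange(n)[:, None]):
            raise DataError("self-neighbour found in weights structure")

    @property
    def n(self) -> int:
        return self.neighbors.shape[0]

    def lag(self, x: np.ndarray) -> np.ndarray:
        """Spatial lag W x (row-wise weighted sums over neighbours)."""
        return np.einsum("ij,ij->i", self.weights, x[self.neighbors])

    def row_sums(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def to_dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        np.put_along_axis(W, self.neighbors, self.weights, axis=1)
        return W

    # --- GAL neighbour-list serialization -------------------------------
    def to_gal(self, fh: TextIO, ids: Iterable | None = None) -> None:
        """Write the neighbour lists in GAL text format (ids default 0..n-1).

        GAL stores adjacency only; weights are reconstructed from ``style``
        on read.
        """
        ids = list(ids) if ids is not None else list(range(self.n))
        fh.write(f"{self.n}\n")
        for i in range(self.n):
            fh.write(f"{ids[i]} {self.k}\n")
            fh.write(" ".join(str(ids[j]) for j in self.neighbors[i]) + "\n")

    @classmethod
    def from_gal(cls, fh: TextIO, style: str = "row_standardized") -> "SpatialWeights":
        header = fh.readline().split()
        n = int(header[0])
        neigh = {}
        for _ in range(n):
            ident, kk = fh.readline().split()
            neigh[ident] = fh.readline().split()
        ids = list(neigh)
        pos = {ident: i for i, ident in enumerate(ids)}
        k = len(next(iter(neigh.values())))
        neighbors = np.array([[pos[j] for j in neigh[i]] for i in ids], dtype=np.intp)
        w = np.ones((n, k)) / (k if style == "row_standardized" else 1.0)
        return cls(neighbors, w, style, k)


def knn_weights(coords, k: int = 4, style: str = "row_standardized") -> SpatialWeights:
    """k nearest neighbours by haversine distance.

    Distance ties are broken by ascending record index, so the structure is
    deterministic even with duplicated coordinates. Row-standardised style
    gives every neighbour weight 1/k.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n <= k:
        raise DataError(f"need more than k={k} observations, got n={n}")
    if not np.all(np.isfinite(coords)):
        raise DataError("non-finite coordinates")
    D = pairwise_haversine(coords)
    np.fill_diagonal(D, np.inf)
    # lexsort: primary key distance, secondary key index (ascending) — stable
    order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), D), axis=1)
    neighbors = order[:, :k]
    w = np.full((n, k), 1.0 / k if style == "row_standardized" else 1.0)
    return SpatialWeights(neighbors, w, style, k)


def _centered_lags(x, y, W: SpatialWeights):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.shape[0] != W.n:
        raise DataError("x, y and weights must agree in length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("x and y must be complete (substitute censored values upstream)")
    xc = x - x.mean()
    yc = y - y.mean()
    ssx = float(np.sqrt(np.sum(xc**2)))
    ssy = float(np.sqrt(np.sum(yc**2)))
    if ssx == 0.0 or ssy == 0.0:
        raise DataError("zero variance in x or y")
    return W.lag(xc), W.lag(yc), ssx, ssy


def lee_global(x, y, W: SpatialWeights) -> float:
    """Global Lee's L bivariate spatial association statistic."""
    lx, ly, ssx, ssy = _centered_lags(x, y, W)
    denom_w = float(np.sum(W.row_sums() ** 2))
    return float(W.n / denom_w * np.sum(lx * ly) / (ssx * ssy))


def lee_local(x, y, W: SpatialWeights) -> np.ndarray:
    """Local decomposition L_i; mean(L_i) equals global L under
    row-standardised weights."""
    lx, ly, ssx, ssy = _centered_lags(x, y, W)
    return W.n * lx * ly / (ssx * ssy)


@dataclass
class LeeResult:
    """Lee's L with permutation inference.

    ``null_sample`` holds the permuted global L values; ``local_null`` (if
    kept) the per-permutation local vectors, used by :func:`classify_local`.
    ``substitution_scheme`` records how censored inputs were made numeric.
    """

    L: float
    local: np.ndarray
    p_value: float
    null_sample: np.ndarray
    n_perm: int
    alternative: str
    seed: int | None
    local_null: np.ndarray | None = None
    substitution_scheme: str | None = None
    pair: tuple[str, str] | None = None


ALTERNATIVES = ("two_sided", "greater", "less")


def lee_mc(
    x,
    y,
    W: SpatialWeights,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "two_sided",
    keep_local_null: bool = False,
) -> LeeResult:
    """Monte-Carlo permutation test for Lee's L.

    Each permutation applies one shared random relocation of the
    (x_i, y_i) *pairs* across sites. p = (1 + #extreme) / (1 + n_perm);
    the two-sided p doubles the smaller tail, capped at 1, and is never 0.
    Deterministic for a fixed seed.
    """
    if alternative not in ALTERNATIVES:
        raise ConfigurationError(f"alternative must be one of {ALTERNATIVES}")
    if n_perm < 99:
        raise ConfigurationError("n_perm must be >= 99 for meaningful inference")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    L_obs = lee_global(x, y, W)
    local_obs = lee_local(x, y, W)

    rng = np.random.default_rng(seed)
    n = W.n
    null = np.empty(n_perm)
    local_null = np.empty((n_perm, n)) if keep_local_null else None
    for b in range(n_perm):
        perm = rng.permutation(n)
        if keep_local_null:
            loc = lee_local(x[perm], y[perm], W)
            local_null[b] = loc
            null[b] = loc.mean() if W.style == "row_standardized" else lee_global(
                x[perm], y[perm], W
            )
        else:
            null[b] = lee_global(x[perm], y[perm], W)

    ge = int(np.sum(null >= L_obs))
    le = int(np.sum(null <= L_obs))
    p_greater = (1 + ge) / (1 + n_perm)
    p_less = (1 + le) / (1 + n_perm)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return LeeResult(
        L=L_obs,
        local=local_obs,
        p_value=float(p),
        null_sample=null,
        n_perm=n_perm,
        alternative=alternative,
        seed=seed,
        local_null=local_null,
    )


def classify_local(
    local: np.ndarray,
    local_null: np.ndarray,
    alpha: float = 0.05,
    alternative: str = "two_sided",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site permutation p-values and significant / nonsignificant labels.

    Each site's observed L_i is ranked within its own permutation null
    column; the two-sided p doubles the smaller tail with the +1
    correction. Returns ``(p_values, significant)`` with ``significant``
    boolean; the two labels partition all sites.
    """
    local = np.asarray(local, dtype=float)
    local_null = np.asarray(local_null, dtype=float)
    if local_null.ndim != 2 or local_null.shape[1] != local.size:
        raise DataError("local_null must be (n_perm, n) matching local")
    n_perm = local_null.shape[0]
    ge = np.sum(local_null >= local[None, :], axis=0)
    le = np.sum(local_null <= local[None, :], axis=0)
    p_greater = (1 + ge) / (1 + n_perm)
    p_less = (1 + le) / (1 + n_perm)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    else:
        p = np.minimum(1.0, 2.0 * np.minimum(p_greater, p_less))
    return p, p < alpha


def local_results_geojson(coords, local, p_values, significant) -> dict:
    """GeoJSON FeatureCollection of per-site local association results."""
    coords = np.asarray(coords, dtype=float)
    feats = []
    for i in range(coords.shape[0]):
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(coords[i, 0]), float(coords[i, 1])]},
                "properties": {
                    "L_i": float(local[i]),
                    "p_i": float(p_values[i]),
                    "significant": bool(significant[i]),
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
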