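"""Distance matrices and the three-model comparison of genetic against
landscape distances.

The question: does genetic differentiation between habitat patches track
straight-line geography (isolation by distance, IBD — the null model), the
cost-weighted least-cost path through the land-use mosaic (LCP), or the
circuit-theory resistance / random-walk commute distance (IBR)? Each model
is scored by a Mantel permutation test between the γ_ST matrix and the
model's distance matrix: r is the Pearson correlation of the lower
triangles, the null distribution permutes patch labels jointly over rows
and columns. For k = 5 patches all 5! = 120 relabelings (identity + 119
permutations) are enumerable, so the exhaustive test is exact and
seed-independent; Monte-Carlo permutation is used for larger k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as iter_permutations

import numpy as np
import pandas as pd

from .geo import haversine

__all__ = [
    "great_circle_matrix", "mantel_test", "compare_models",
    "MantelResult", "ModelComparison",
    "read_distance_tsv", "write_distance_tsv",
]


class InferenceError(ValueError):
    pass


def _as_matrix(M) -> tuple[np.ndarray, list | None]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), list(M.index)
    return np.asarray(M, dtype=float), None


def _validate_square(A: np.ndarray, name: str, strict: bool = True) -> None:
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InferenceError(f"{name} must be square")
    if not np.allclose(A, A.T, equal_nan=True):
        raise InferenceError(f"{name} must be symmetric")
    if strict and not np.isfinite(A).all():
        raise InferenceError(f"{name} has non-finite entries")


def great_circle_matrix(patches) -> pd.DataFrame:
    """Patch-pair haversine distances in km.

    ``patches`` is a :class:`~landgen.seqio.PatchTable` or a DataFrame with
    ``lon``/``lat`` columns indexed by patch label. Duplicate coordinates
    give an off-diagonal 0 with a warning, not an error.
    """
    table = patches.table if hasattr(patches, "table") else patches
    if len(table) < 2:
        raise InferenceError("need >= 2 patches")
    lon = table["lon"].to_numpy()
    lat = table["lat"].to_numpy()
    D = haversine(lon[:, None], lat[:, None], lon[None, :], lat[None, :]) / 1000.0
    np.fill_diagonal(D, 0.0)
    if (D[np.triu_indices_from(D, 1)] == 0).any():
        import warnings
        warnings.warn("duplicate patch coordinates: off-diagonal zero distance")
    df = pd.DataFrame(D, index=table.index, columns=table.index)
    df.attrs["units"] = "km"
    return df


@dataclass
class MantelResult:
    """Mantel permutation test between two distance matrices."""

    r: float
    p_value: float
    permutations: int       # permutations beyond the identity
    method: str             # "exhaustive" | "montecarlo"
    alternative: str
    seed: int | None
    perm_mean: float
    perm_max: float
    undefined: bool = False


def _lower(A: np.ndarray) -> np.ndarray:
    return A[np.tril_indices_from(A, -1)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / math.sqrt((xc @ xc) * (yc @ yc)))


def mantel_test(A, B, permutations: int = 119, seed: int | None = None,
                alternative: str = "greater",
                method: str = "auto") -> MantelResult:
    """Mantel test: Pearson r over lower triangles, label-permutation null.

    ``method="auto"`` enumerates all k! relabelings when k <= 5 (for k = 5
    that is the identity plus 119 permutations, the maximum a 5 x 5 matrix
    allows), giving an exact, seed-independent p; otherwise ``permutations``
    random relabelings with the add-one rule p = (1 + #{r* >= r})/(B + 1).
    ``alternative`` is ``greater`` (the landscape-genetics prediction),
    ``less``, or ``two-sided``.
    """
    Am, la = _as_matrix(A)
    Bm, lb = _as_matrix(B)
    if la is not None and lb is not None and la != lb:
        raise InferenceError(f"label mismatch: {la} vs {lb}")
    _validate_square(Am, "A")
    _validate_square(Bm, "B")
    k = Am.shape[0]
    if k < 3:
        raise InferenceError("Mantel test needs k >= 3")
    if alternative not in ("greater", "less", "two-sided"):
        raise InferenceError(f"unknown alternative {alternative!r}")
    x = _lower(Am)
    if x.std() == 0 or _lower(Bm).std() == 0:
        return MantelResult(float("nan"), float("nan"), 0, "none",
                            alternative, seed, float("nan"), float("nan"),
                            undefined=True)
    if method == "auto":
        method = "exhaustive" if k <= 5 else "montecarlo"

    def tail_stat(r):
        if alternative == "greater":
            return r
        if alternative == "less":
            return -r
        return abs(r)

    r_obs = _pearson(x, _lower(Bm))
    if method == "exhaustive":
        rs = []
        for perm in iter_permutations(range(k)):
            p = np.asarray(perm)
            rs.append(_pearson(x, _lower(Bm[np.ix_(p, p)])))
        rs = np.asarray(rs)
        extreme = tail_stat(rs) >= tail_stat(r_obs) - 1e-12
        p_value = float(extreme.mean())  # identity term is the +1
        n_perm = len(rs) - 1
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        rs = np.empty(permutations)
        for b in range(permutations):
            p = rng.permutation(k)
            rs[b] = _pearson(x, _lower(Bm[np.ix_(p, p)]))
        count = int(np.sum(tail_stat(rs) >= tail_stat(r_obs) - 1e-12))
        p_value = (1.0 + count) / (permutations + 1.0)
        n_perm = permutations
    else:
        raise InferenceError(f"unknown method {method!r}")
    return MantelResult(r_obs, p_value, n_perm, method, alternative, seed,
                        float(np.mean(rs)), float(np.max(rs)))


@dataclass
class ModelComparison:
    """IBD vs LCP vs IBR Mantel results with a best-supported flag.

    ``best`` is the model with the highest r among those with p <= alpha,
    or None when no model is significant.
    """

    results: dict[str, MantelResult]
    alpha: float
    best: str | None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"model": m, "r": res.r, "p": res.p_value,
                 "permutations": res.permutations, "method": res.method,
                 "best": m == self.best}
                for m, res in self.results.items()]
        df = pd.DataFrame(rows).set_index("model")
        df.attrs["alpha"] = self.alpha
        return df


def compare_models(gst, geo, lcp, ibr, permutations: int = 119,
                   seed: int | None = None, alpha: float = 0.05,
                   alternative: str = "greater") -> ModelComparison:
    """Score IBD, LCP and IBR against the γ_ST matrix by Mantel tests."""
    results = {}
    for name, M in (("IBD", geo), ("LCP", lcp), ("IBR", ibr)):
        results[name] = mantel_test(gst, M, permutations=permutations,
                                    seed=seed, alternative=alternative)
    significant = {m: r for m, r in results.items()
                   if not r.undefined and r.p_value <= alpha}
    best = max(significant, key=lambda m: significant[m].r) if significant else None
    return ModelComparison(results, alpha, best)


def write_distance_tsv(df: pd.DataFrame, path) -> None:
    """Labelled square matrix as TSV (header row + labelled rows)."""
    df.to_csv(path, sep="\t", index_label="")


def read_distance_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df
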