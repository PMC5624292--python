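"""Diversity and differentiation statistics for patch-structured haplotype
data.

Per-patch descriptors
---------------------
* ``S`` — segregating sites: retained columns with >= 2 distinct bases.
* ``Nh`` — number of distinct haplotypes.
* ``Hd`` — haplotype diversity with Nei's unbiased n/(n-1) correction,
  Hd = n(1 - sum p_i^2)/(n - 1); its standard deviation uses the
  sampling-variance formula of Nei (1987, eq. 8.12).
* ``π`` — nucleotide diversity, the mean over all sequence pairs of the
  per-site proportion of differing retained sites. Two standard deviations
  are offered: the analytic *total* (stochastic + sampling) variance of
  Nei (1987, eq. 10.7), and a seeded bootstrap-over-sequences *sampling*
  standard deviation (the default, matching the much tighter SDs that
  standard diversity software prints for sample-level tables).

Differentiation
---------------
* ``γ_ST`` — Nei's haplotype-frequency analogue of F_ST:
  γ_ST = (H_T - H_S)/H_T, with H_S the unweighted mean of the two
  populations' unbiased haplotype diversities and H_T the unbiased
  diversity of the pooled sample (pooling counts, correcting by the pooled
  n/(n-1)). Negative estimates from the corrections are reported as
  computed, flagged, never clamped.
* ``Snn`` — Hudson's nearest-neighbour statistic: the mean over sequences
  of the fraction of each sequence's nearest neighbours (minimum Hamming
  distance on retained sites; equidistant ties share weight equally, self
  excluded) that belong to its own patch. Significance by permuting patch
  labels; the add-one rule p = (1 + #{Snn_perm >= Snn_obs})/(B + 1) keeps
  p away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .seqio import Alignment, HaplotypeAssignment, PatchTable, collapse_haplotypes

__all__ = [
    "segregating_sites", "haplotype_diversity", "nucleotide_diversity",
    "gamma_st", "pairwise_gamma_st", "snn_statistic", "snn_permutation_test",
    "pairwise_snn_tests", "diversity_summary", "hamming_matrix",
    "GammaST", "SnnResult",
]


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------- diversity

def segregating_sites(aln: Alignment) -> int:
    """Number of retained columns with at least two distinct bases."""
    if aln.n < 2:
        raise StatsError("segregating sites need >= 2 sequences")
    m = aln.matrix
    return int(np.sum((m != m[0]).any(axis=0)))


def haplotype_diversity(hap_counts) -> tuple[float, float]:
    """Unbiased haplotype diversity and its standard deviation.

    Hd = n(1 - sum p_i^2)/(n-1);  V(Hd) per Nei (1987, eq. 8.12):
    V = 2/(n(n-1)) * [2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2].
    """
    counts = np.asarray(hap_counts, dtype=float)
    counts = counts[counts > 0]
    n = counts.sum()
    if n < 2:
        raise StatsError("haplotype diversity needs n >= 2")
    p = counts / n
    sum2 = float(np.sum(p ** 2))
    sum3 = float(np.sum(p ** 3))
    hd = n * (1.0 - sum2) / (n - 1.0)
    var = (2.0 / (n * (n - 1.0))) * (
        2.0 * (n - 2.0) * (sum3 - sum2 ** 2) + sum2 - sum2 ** 2)
    return hd, float(np.sqrt(max(var, 0.0)))


def _pairwise_prop_diff(matrix: np.ndarray, deletion: str) -> np.ndarray:
    """Condensed vector of per-site difference proportions over all pairs."""
    n, L = matrix.shape
    out = np.empty(n * (n - 1) // 2)
    if deletion == "pairwise":
        valid = np.isin(matrix, list("ACGT"))
    for k, (i, j) in enumerate(combinations(range(n), 2)):
        if deletion == "pairwise":
            ok = valid[i] & valid[j]
            nsites = int(ok.sum())
            if nsites == 0:
                raise StatsError(f"no comparable sites between records {i} and {j}")
            out[k] = np.sum(matrix[i, ok] != matrix[j, ok]) / nsites
        else:
            out[k] = np.sum(matrix[i] != matrix[j]) / L
    return out


def nucleotide_diversity(aln: Alignment, sd_method: str = "sampling",
                         deletion: str = "complete",
                         bootstrap: int = 1000, seed: int = 0
                         ) -> tuple[float, float]:
    """Nucleotide diversity π and its standard deviation.

    ``sd_method="total"`` uses Nei (1987, eq. 10.7),
    V = (n+1)/(3(n-1)L) π + 2(n^2+n+3)/(9n(n-1)) π², which includes the
    evolutionary (stochastic) variance; ``"sampling"`` (default) is a
    seeded bootstrap over sequences, estimating only the sampling spread of
    the observed sample. ``deletion="pairwise"`` scores each pair on the
    sites where both records carry an unambiguous base (use with an
    unfiltered alignment).
    """
    if aln.n < 2:
        raise StatsError("nucleotide diversity needs >= 2 sequences")
    if aln.length < 1:
        raise StatsError("nucleotide diversity needs >= 1 retained site")
    diffs = _pairwise_prop_diff(aln.matrix, deletion)
    pi = float(diffs.mean())
    n, L = aln.n, aln.length
    if sd_method == "total":
        var = ((n + 1.0) / (3.0 * (n - 1.0) * L) * pi
               + 2.0 * (n ** 2 + n + 3.0) / (9.0 * n * (n - 1.0)) * pi ** 2)
        return pi, float(np.sqrt(max(var, 0.0)))
    if sd_method != "sampling":
        raise StatsError(f"unknown sd_method {sd_method!r}")
    rng = np.random.default_rng(seed)
    reps = np.empty(bootstrap)
    for b in range(bootstrap):
        idx = rng.integers(0, n, size=n)
        sub = aln.matrix[idx]
        reps[b] = _pairwise_prop_diff(sub, deletion).mean()
    return pi, float(reps.std(ddof=1))


def hamming_matrix(aln: Alignment) -> np.ndarray:
    """Pairwise Hamming distances (site counts) on retained sites."""
    m = aln.matrix.view(np.uint32).reshape(aln.n, aln.length)
    return np.sum(m[:, None, :] != m[None, :, :], axis=2)


# ----------------------------------------------------------- differentiation

@dataclass
class GammaST:
    """γ_ST between two populations; flags, never silent clamping."""

    value: float
    h_t: float
    h_s: float
    no_variation: bool = False
    negative: bool = False


def _unbiased_h(counts: np.ndarray) -> float:
    counts = counts[counts > 0].astype(float)
    n = counts.sum()
    p = counts / n
    return n * (1.0 - float(np.sum(p ** 2))) / (n - 1.0)


def gamma_st(hap_counts_1, hap_counts_2) -> GammaST:
    """Nei's γ_ST from two haplotype count vectors on a shared index space.

    Both populations need n >= 2. When both are monomorphic for the same
    haplotype, H_T = 0 and γ_ST is undefined: the result is flagged
    ``no_variation`` with value NaN rather than 0.
    """
    c1 = np.asarray(hap_counts_1, dtype=float)
    c2 = np.asarray(hap_counts_2, dtype=float)
    if c1.shape != c2.shape:
        raise StatsError("count vectors must share a haplotype index space")
    if c1.sum() < 2 or c2.sum() < 2:
        raise StatsError("gamma_st needs n >= 2 in each population")
    h_s = 0.5 * (_unbiased_h(c1) + _unbiased_h(c2))
    h_t = _unbiased_h(c1 + c2)
    if h_t <= 0.0:
        return GammaST(float("nan"), h_t, h_s, no_variation=True)
    g = (h_t - h_s) / h_t
    return GammaST(float(g), h_t, h_s, negative=bool(g < 0))


def pairwise_gamma_st(aln: Alignment, patches: PatchTable,
                      haplotypes: HaplotypeAssignment | None = None
                      ) -> pd.DataFrame:
    """Symmetric patch x patch γ_ST matrix (zero diagonal).

    Undefined (no-variation) pairs come back as NaN; negative corrected
    estimates are kept as computed.
    """
    haps = haplotypes if haplotypes is not None else collapse_haplotypes(aln)
    labels = patches.labels
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        g = gamma_st(haps.counts[a].to_numpy(), haps.counts[b].to_numpy())
        out.loc[a, b] = out.loc[b, a] = g.value
    return out


def _snn_from_distance(D: np.ndarray, groups: np.ndarray) -> float:
    n = D.shape[0]
    D = D.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    mins = D.min(axis=1)
    x = np.empty(n)
    for j in range(n):
        nn = D[j] == mins[j]
        x[j] = np.mean(groups[nn] == groups[j])
    return float(x.mean())


def snn_statistic(aln: Alignment, labels=None) -> float:
    """Hudson's Snn on retained-site Hamming distances.

    ``labels`` defaults to the alignment's patch labels; groups of size 1
    are allowed (the singleton still contributes through its own nearest
    neighbours' groups).
    """
    groups = np.asarray(labels if labels is not None else aln.patches)
    if len(set(groups.tolist())) < 2:
        raise StatsError("Snn needs >= 2 groups")
    return _snn_from_distance(hamming_matrix(aln), groups)


@dataclass
class SnnResult:
    observed: float
    permutations: int
    p_value: float
    seed: int


def snn_permutation_test(aln: Alignment, labels=None, permutations: int = 1000,
                         seed: int = 0) -> SnnResult:
    """Label-permutation test for Snn; p = (1 + #{>= obs})/(B + 1)."""
    if permutations < 1:
        raise StatsError("need at least one permutation")
    groups = np.asarray(labels if labels is not None else aln.patches)
    D = hamming_matrix(aln)
    obs = _snn_from_distance(D, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(groups)
        if _snn_from_distance(D, perm) >= obs - 1e-12:
            count += 1
    p = (1.0 + count) / (permutations + 1.0)
    return SnnResult(obs, permutations, p, seed)


def pairwise_snn_tests(aln: Alignment, patches: PatchTable,
                       permutations: int = 1000, seed: int = 0
                       ) -> pd.DataFrame:
    """Patch-pair Snn permutation p-values (symmetric, NaN diagonal).

    Each pair is tested on the subset of sequences sampled in those two
    patches, mirroring a pairwise differentiation table with γ_ST below and
    Snn significance above the diagonal.
    """
    labels = patches.labels
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    patch_arr = np.asarray(aln.patches)
    for i, (a, b) in enumerate(combinations(labels, 2)):
        idx = np.flatnonzero((patch_arr == a) | (patch_arr == b))
        sub = aln.subset(idx)
        res = snn_permutation_test(sub, permutations=permutations,
                                   seed=seed + i)
        out.loc[a, b] = out.loc[b, a] = res.p_value
    return out


# ------------------------------------------------------------------ summary

def diversity_summary(aln: Alignment, patches: PatchTable,
                      sd_method: str = "sampling", seed: int = 0
                      ) -> pd.DataFrame:
    """Per-patch and pooled N, S, Nh, Hd±SD, π±SD (a Table-1-style frame).

    Statistics per patch are computed on that patch's sequences over the
    alignment's retained sites; the ``Total`` row pools all sequences.
    """
    rows = []
    patch_arr = np.asarray(aln.patches)
    groups = [(label, np.flatnonzero(patch_arr == label))
              for label in patches.labels]
    groups.append(("Total", np.arange(aln.n)))
    for label, idx in groups:
        sub = aln.subset(idx)
        haps = collapse_haplotypes(sub)
        hd, hd_sd = haplotype_diversity(haps.pooled_counts())
        pi, pi_sd = nucleotide_diversity(sub, sd_method=sd_method, seed=seed)
        rows.append({"patch": label, "N": sub.n,
                     "S": segregating_sites(sub), "Nh": haps.n_haplotypes,
                     "Hd": hd, "Hd_sd": hd_sd, "pi": pi, "pi_sd": pi_sd})
    df = pd.DataFrame(rows).set_index("patch")
    df.attrs["pi_sd_method"] = sd_method
    return df
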