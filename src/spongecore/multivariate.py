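"""Permutation-based multivariate statistics: PERMANOVA, PERMDISP, IndVal.

These are implemented from first principles on a distance matrix / abundance
table rather than delegated, because the exact conventions matter:

* **PERMANOVA** — one-way partitioning of the squared-distance sum of
  squares (SS_total = N⁻¹ Σ_{i<j} d²ᵢⱼ; SS_within from within-group pairs
  weighted 1/n_g), pseudo-F = (SS_between/(a−1)) / (SS_within/(N−a)),
  R² = SS_between/SS_total, and an add-one permutation p-value from free
  relabelling of samples.

* **PERMDISP** — homogeneity of multivariate dispersions: samples are
  embedded by principal-coordinates analysis; distances to group centroids
  subtract the squared contribution of negative-eigenvalue axes (clamped at
  zero); an optional small-sample bias adjustment multiplies each group's
  distances by sqrt(n_g/(n_g−1)); the classical one-way ANOVA F on those
  distances is compared against relabelled recomputations.  Centroids (not
  spatial medians) are used.

* **IndVal** — the Dufrêne–Legendre indicator value: specificity
  A_ij = mean abundance in group j / Σ_k mean abundance in group k, fidelity
  B_ij = occurrence fraction within group j, IndVal_ij = A·B, reported as
  the max over groups with a permutation p-value on that max.

All permutation schemes are free (unstratified) label permutations; seeded
runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "PermanovaResult",
    "DispersionResult",
    "IndvalResult",
    "permanova",
    "permdisp",
    "indval",
]


@dataclass
class PermanovaResult:
    factor: str
    r2: float
    pseudo_f: float
    p: float
    n_permutations: int
    n_samples: int
    n_groups: int


@dataclass
class DispersionResult:
    factor: str
    group_mean_distance: dict[str, float]
    f: float
    p: float
    n_permutations: int
    bias_adjusted: bool


@dataclass
class IndvalResult:
    taxon: str
    group: str
    indval: float
    p: float
    is_indicator: bool


def _group_codes(dm_ids, grouping) -> tuple[np.ndarray, list[str]]:
    labels = pd.Series(grouping)
    missing = [i for i in dm_ids if i not in labels.index]
    if missing:
        raise ValueError(f"grouping does not cover sample(s): {missing}")
    lab = labels.loc[list(dm_ids)]
    names = sorted(set(lab))
    codes = np.array([names.index(v) for v in lab], dtype=np.intp)
    return codes, names


def _permanova_stats(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """pseudo-F and R² from the squared-distance matrix and group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        return np.inf, ss_between / ss_total if ss_total > 0 else 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    factor: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA with a free label-permutation p-value.

    ``grouping`` maps every id of ``dm`` to a group label (dict or Series).
    The p-value follows the add-one rule, p = (1 + #{F* ≥ F}) / (B + 1),
    and therefore never reaches 0.
    """
    codes, names = _group_codes(dm.ids, grouping)
    n = len(codes)
    a = len(names)
    if a < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if a >= n:
        raise ValueError("every group would absorb a single sample; no residual df")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    f_obs, r2 = _permanova_stats(d2, codes, a)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_perm, _ = _permanova_stats(d2, perm, a)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return PermanovaResult(factor=factor, r2=float(r2), pseudo_f=float(f_obs), p=float(p),
                           n_permutations=n_permutations, n_samples=n, n_groups=a)


def _pcoa_axes(dm: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding, keeping negative axes separately.

    Returns (pos, neg): sample coordinates on positive-eigenvalue axes and
    on negative-eigenvalue axes (scaled by sqrt(|λ|)).
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    tol = np.abs(eigval).max() * 1e-10 if eigval.size else 0.0
    pos = eigval > tol
    neg = eigval < -tol
    pos_axes = eigvec[:, pos] * np.sqrt(eigval[pos])
    neg_axes = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return pos_axes, neg_axes


def _dispersion_f(
    pos: np.ndarray, neg: np.ndarray, codes: np.ndarray, n_groups: int,
    bias_adjust: bool,
) -> tuple[float, np.ndarray]:
    """One-way ANOVA F on distances-to-centroid for a given labelling."""
    n = pos.shape[0]
    dist = np.empty(n)
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        cp = pos[idx].mean(axis=0)
        d2 = ((pos[idx] - cp) ** 2).sum(axis=1)
        if neg.shape[1]:
            cn = neg[idx].mean(axis=0)
            d2 = d2 - ((neg[idx] - cn) ** 2).sum(axis=1)
        d = np.sqrt(np.clip(d2, 0.0, None))
        if bias_adjust:
            d = d * np.sqrt(len(idx) / (len(idx) - 1))
        dist[idx] = d
    grand = dist.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        m = dist[idx].mean()
        ss_between += len(idx) * (m - grand) ** 2
        ss_within += ((dist[idx] - m) ** 2).sum()
    df_b = n_groups - 1
    df_w = n - n_groups
    if ss_within <= 0:
        return np.inf, dist
    return (ss_between / df_b) / (ss_within / df_w), dist


def permdisp(
    dm: DistanceMatrix,
    grouping,
    bias_adjust: bool = True,
    n_permutations: int = 999,
    seed: int = 0,
    factor: str = "group",
) -> DispersionResult:
    """Permutation test for homogeneity of multivariate dispersions.

    Group labels are freely permuted and centroids, distances and F are
    recomputed for every relabelling; the add-one rule gives the p-value.
    ``bias_adjust`` applies the sqrt(n/(n−1)) small-sample correction, which
    matters when group sizes are very unequal.
    """
    codes, names = _group_codes(dm.ids, grouping)
    a = len(names)
    if a < 2:
        raise ValueError("PERMDISP needs at least two groups")
    counts = np.bincount(codes, minlength=a)
    if counts.min() < 2:
        small = [names[i] for i in np.flatnonzero(counts < 2)]
        raise ValueError(f"every group needs ≥ 2 samples; too small: {small}")
    pos, neg = _pcoa_axes(dm)
    f_obs, dist = _dispersion_f(pos, neg, codes, a, bias_adjust)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_perm, _ = _dispersion_f(pos, neg, perm, a, bias_adjust)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    means = {names[g]: float(dist[codes == g].mean()) for g in range(a)}
    return DispersionResult(factor=factor, group_mean_distance=means, f=float(f_obs),
                            p=float(p), n_permutations=n_permutations,
                            bias_adjusted=bias_adjust)


def _indval_matrix(mat: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """max-over-groups IndVal per taxon (columns of ``mat``)."""
    means = np.empty((n_groups, mat.shape[1]))
    occ = np.empty((n_groups, mat.shape[1]))
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        means[g] = mat[idx].mean(axis=0)
        occ[g] = (mat[idx] > 0).mean(axis=0)
    total = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(total > 0, means / total, 0.0)
    return (a * occ).max(axis=0)


def indval(
    table: pd.DataFrame,
    grouping,
    threshold: float = 0.6,
    alpha: float = 0.01,
    n_permutations: int = 999,
    seed: int = 0,
) -> list[IndvalResult]:
    """Dufrêne–Legendre indicator-value analysis per taxon.

    ``table`` holds samples × taxa abundances (relative abundances, possibly
    rank-aggregated).  A taxon is an indicator of its best group when
    IndVal ≥ ``threshold`` and the permutation p-value is below ``alpha``.
    Taxa absent from every sample are excluded.
    """
    labels = pd.Series(grouping)
    codes, names = _group_codes(table.index, labels)
    if len(names) < 2:
        raise ValueError("IndVal needs at least two groups")
    mat = table.to_numpy(dtype=float)
    present = mat.sum(axis=0) > 0
    taxa = list(table.columns[present])
    mat = mat[:, present]
    n_groups = len(names)

    # observed per-taxon best group and value
    means = np.stack([mat[codes == g].mean(axis=0) for g in range(n_groups)])
    occ = np.stack([(mat[codes == g] > 0).mean(axis=0) for g in range(n_groups)])
    total = means.sum(axis=0)
    a = np.where(total > 0, means / total, 0.0)
    iv = a * occ
    best = iv.argmax(axis=0)
    obs = iv.max(axis=0)

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(taxa))
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        hits += _indval_matrix(mat, perm, n_groups) >= obs
    p = (1 + hits) / (n_permutations + 1)
    return [
        IndvalResult(
            taxon=t,
            group=names[best[i]],
            indval=float(obs[i]),
            p=float(p[i]),
            is_indicator=bool(obs[i] >= threshold and p[i] < alpha),
        )
        for i, t in enumerate(taxa)
    ]
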