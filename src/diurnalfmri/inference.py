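"""Family-aware permutation inference and regression controls.

Participants from the same family are not exchangeable with unrelated
participants (shared genetics and environment induce dependence), so all
permutation tests here shuffle within exchangeability blocks: members of a
family may be permuted among themselves, and whole families of identical
size may be swapped.  p-values use the add-one estimator
``(1 + #{|null| >= |obs|}) / (1 + n_perm)``, which is valid for any finite
number of permutations.

Also provided: Benjamini-Hochberg FDR, the network-based statistic (NBS)
for cluster-level inference on connectivity graphs, single-covariate
residualisation, a paired run test with sign-flip nulls, and OLS / robust
(Huber) / median-quantile line fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import t as t_dist

__all__ = [
    "PermutationScheme",
    "CorrelationResult",
    "NBSResult",
    "build_permutation_scheme",
    "perm_pvalue",
    "between_participant_corr",
    "within_participant_corr",
    "fdr_correct",
    "network_based_statistic",
    "regress_covariate",
    "paired_run_test",
    "fit_lines",
]


@dataclass
class PermutationScheme:
    """Family-block exchangeability scheme.

    ``blocks`` partition participant indices by family; only blocks of
    identical size are exchanged with each other, and members are freely
    reordered within a block.  A drawn permutation ``perm`` relabels data
    as ``y[perm]``.
    """

    families: np.ndarray
    blocks: list
    seed: int = 0

    @property
    def n(self) -> int:
        return int(self.families.size)

    def draw_matrix(self, n_perm: int, seed: int | None = None) -> np.ndarray:
        """Draw ``n_perm`` permutations as an ``(n_perm, n)`` index array.

        Each draw independently shuffles whole blocks within every
        size class and reorders members within each block (vectorised
        over draws).
        """
        rng = np.random.default_rng(self.seed if seed is None else seed)
        perm = np.empty((n_perm, self.n), dtype=np.intp)
        sizes = np.array([b.size for b in self.blocks])
        for size in np.unique(sizes):
            ids = np.flatnonzero(sizes == size)
            pos = np.stack([self.blocks[i] for i in ids])      # (k, size)
            k = ids.size
            block_order = np.argsort(rng.random((n_perm, k)), axis=1)
            src = pos[block_order]                             # (P, k, size)
            within = np.argsort(rng.random((n_perm, k, int(size))), axis=2)
            shuffled = np.take_along_axis(src, within, axis=2)
            perm[:, pos.ravel()] = shuffled.reshape(n_perm, -1)
        return perm

    def is_valid_permutation(self, perm: np.ndarray) -> bool:
        """Check that ``perm`` maps every family onto a family of equal size."""
        fam_of = {i: f for i, f in enumerate(self.families)}
        for block in self.blocks:
            sources = {fam_of[int(j)] for j in perm[block]}
            if len(sources) != 1:
                return False
            src_fam = next(iter(sources))
            if np.sum(self.families == src_fam) != block.size:
                return False
        return True


def build_permutation_scheme(
    families: Sequence,
    seed: int = 0,
) -> PermutationScheme:
    """Group participants into family exchangeability blocks."""
    fams = np.asarray(families)
    if fams.size == 0:
        raise ValueError("empty family assignment")
    order: dict = {}
    for i, f in enumerate(fams):
        order.setdefault(f, []).append(i)
    blocks = [np.asarray(v, dtype=np.intp) for v in order.values()]
    return PermutationScheme(families=fams, blocks=blocks, seed=seed)


def perm_pvalue(observed: float, nulls: np.ndarray,
                alternative: Literal["two-sided", "greater", "less"] = "two-sided") -> float:
    """Add-one permutation p-value."""
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("need at least one null draw")
    if alternative == "two-sided":
        count = np.sum(np.abs(nulls) >= abs(observed))
    elif alternative == "greater":
        count = np.sum(nulls >= observed)
    elif alternative == "less":
        count = np.sum(nulls <= observed)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float((1 + count) / (1 + nulls.size))


@dataclass
class CorrelationResult:
    """Pearson correlation with a family-permutation p-value."""

    r: float
    n: int
    p: float
    level: Literal["between", "within"]
    n_perm: int


def _standardized(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant input")
    return (x - x.mean()) / sd


def between_participant_corr(
    metric: np.ndarray,
    tod: np.ndarray,
    families: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> CorrelationResult:
    """Between-participant Pearson correlation of a (session-averaged)
    metric with time of day, with a family-permutation p-value."""
    metric = np.asarray(metric, dtype=float)
    tod = np.asarray(tod, dtype=float)
    if metric.size != tod.size or metric.size != len(families):
        raise ValueError("metric, tod and families must have equal length")
    n = metric.size
    if n < 4:
        raise ValueError("need at least 4 participants")
    zm, zt = _standardized(metric), _standardized(tod)
    r = float(zm @ zt / n)
    scheme = build_permutation_scheme(families, seed=seed)
    P = scheme.draw_matrix(n_perm)
    nulls = zm[P] @ zt / n
    return CorrelationResult(r=r, n=n, p=perm_pvalue(r, nulls),
                             level="between", n_perm=n_perm)


def within_participant_corr(
    delta_metric: np.ndarray,
    delta_tod: np.ndarray,
    families: Sequence,
    n_perm: int = 999,
    seed: int = 0,
    sign_flips: bool = True,
) -> CorrelationResult:
    """Within-participant correlation of session differences.

    Inputs are per-participant session-2 minus session-1 differences
    (participants with both sessions only).  The null relabels rows with
    the family scheme and additionally flips the sign of each family's
    metric deltas (session order is exchangeable under the null).
    """
    dm = np.asarray(delta_metric, dtype=float)
    dt = np.asarray(delta_tod, dtype=float)
    if dm.size != dt.size or dm.size != len(families):
        raise ValueError("inputs must have equal length")
    if dm.size < 4:
        raise ValueError("need at least 4 complete participants")
    zm, zt = _standardized(dm), _standardized(dt)
    n = dm.size
    r = float(zm @ zt / n)

    scheme = build_permutation_scheme(families, seed=seed)
    P = scheme.draw_matrix(n_perm)
    permuted = zm[P]
    if sign_flips:
        rng = np.random.default_rng(seed + 1)
        fams = np.asarray(families)
        uniq, fam_idx = np.unique(fams, return_inverse=True)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, uniq.size))
        permuted = permuted * signs[:, fam_idx]
    # re-centre/scale each permuted row so nulls are correlations
    permuted = permuted - permuted.mean(axis=1, keepdims=True)
    sds = permuted.std(axis=1, keepdims=True)
    sds[sds == 0] = np.inf
    nulls = (permuted / sds) @ zt / n
    return CorrelationResult(r=r, n=n, p=perm_pvalue(r, nulls),
                             level="within", n_perm=n_perm)


def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(reject, threshold)`` where ``threshold`` is the largest
    ordered p-value satisfying ``p_(i) <= i q / m`` (0 if none do) and
    ``reject`` marks all p-values at or below it.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    ok = ranked <= (np.arange(1, m + 1) * q / m)
    if not ok.any():
        return np.zeros(m, dtype=bool), 0.0
    thresh = float(ranked[np.flatnonzero(ok)[-1]])
    return p <= thresh, thresh


def regress_covariate(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residuals of the least-squares fit of y on [intercept, x]."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need matched vectors with n >= 3")
    design = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def paired_run_test(
    metric_run1: np.ndarray,
    metric_run2: np.ndarray,
    families: Sequence,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Paired t statistic for the run-2 minus run-1 difference with a
    family-respecting sign-flip permutation p-value."""
    d = np.asarray(metric_run2, dtype=float) - np.asarray(metric_run1, dtype=float)
    n = d.size
    if n < 3 or len(families) != n:
        raise ValueError("need matched runs for at least 3 participants")
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0 if d.mean() == 0 else np.inf, 1.0 / (1.0 + n_perm)
    t_obs = float(d.mean() / (sd / np.sqrt(n)))

    rng = np.random.default_rng(seed)
    fams = np.asarray(families)
    uniq, fam_idx = np.unique(fams, return_inverse=True)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, uniq.size))[:, fam_idx]
    D = signs * d
    means = D.mean(axis=1)
    sds = D.std(axis=1, ddof=1)
    sds[sds == 0] = np.inf
    nulls = means / (sds / np.sqrt(n))
    return t_obs, perm_pvalue(t_obs, nulls)


def fit_lines(
    y: np.ndarray,
    x: np.ndarray,
    method: Literal["ols", "robust_huber", "quantile_median"] = "ols",
) -> tuple[float, float]:
    """Line of best fit under OLS, Huber (tuning constant 1.345) or median
    quantile loss.  Returns ``(slope, intercept)``."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 3:
        raise ValueError("need matched vectors with n >= 3")
    X = sm.add_constant(x)
    if method == "ols":
        res = sm.OLS(y, X).fit()
    elif method == "robust_huber":
        res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit()
    elif method == "quantile_median":
        res = sm.QuantReg(y, X).fit(q=0.5)
    else:
        raise ValueError(f"unknown method {method!r}")
    intercept, slope = res.params
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# network-based statistic

@dataclass
class NBSResult:
    """Suprathreshold components of an edgewise association test."""

    components: list                 # list of (k, 2) arrays of region-index pairs
    sizes: np.ndarray                # component statistic (extent or intensity)
    p_values: np.ndarray             # max-statistic permutation p per component
    q_reject: np.ndarray             # BH rejection per component (fdr mode)
    null_max: np.ndarray             # null distribution of the max statistic
    edge_r: np.ndarray               # observed edge-covariate r (regions x regions)
    r_crit: float                    # |r| screening threshold implied by edge p
    n_suprathreshold: int

    @property
    def any_significant(self) -> bool:
        return bool(self.q_reject.any())


def _components_from_mask(mask: np.ndarray, iu: tuple, n_regions: int):
    """Connected components of the suprathreshold edge graph.

    Returns (labels per region, extent per component label) with -1 for
    regions carrying no suprathreshold edge.
    """
    rows, cols = iu[0][mask], iu[1][mask]
    adj = sparse.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_regions, n_regions))
    n_comp, labels = connected_components(adj, directed=False)
    extent = np.bincount(labels[rows], minlength=n_comp)
    return labels, extent, rows, cols


def network_based_statistic(
    rsfc_stack: np.ndarray,
    covariate: np.ndarray,
    families: Sequence | None = None,
    n_perm: int = 999,
    seed: int = 0,
    edge_p_thresh: float = 0.001,
    component_stat: Literal["extent", "intensity"] = "extent",
    q: float = 0.05,
    correction: Literal["fdr", "fwer"] = "fdr",
) -> NBSResult:
    """Cluster-level inference on edgewise covariate associations.

    Edges whose parametric (t-approximation) p-value for the Pearson
    correlation with the covariate falls below ``edge_p_thresh`` form a
    graph; its connected components are scored by edge count ("extent",
    default) or summed suprathreshold |r| excess ("intensity") and compared
    with the permutation null of the maximum component statistic, with the
    covariate relabelled under the family scheme (unrestricted when
    ``families`` is None).  Component p-values are then passed through
    BH-FDR at ``q`` (``correction="fdr"``); with ``correction="fwer"`` the
    max-statistic p-values are used directly.
    """
    stack = np.asarray(rsfc_stack, dtype=float)
    cov = np.asarray(covariate, dtype=float).ravel()
    n, R = stack.shape[0], stack.shape[1]
    if cov.size != n:
        raise ValueError("covariate length must match the stack")
    if np.std(cov) == 0:
        raise ValueError("covariate is constant")
    iu = np.triu_indices(R, k=1)
    edges = stack[:, iu[0], iu[1]]
    ez = edges - edges.mean(axis=0)
    esd = ez.std(axis=0)
    esd[esd == 0] = np.inf
    ezn = ez / esd                                     # n x E, unit SD columns
    zc = (cov - cov.mean()) / cov.std()
    r_obs = ezn.T @ zc / n

    t_crit = float(t_dist.isf(edge_p_thresh / 2.0, n - 2))
    r_crit = float(t_crit / np.sqrt(n - 2 + t_crit**2))

    def comp_stats(r_vec: np.ndarray):
        mask = np.abs(r_vec) > r_crit
        if not mask.any():
            return [], np.zeros(0), 0
        labels, extent, rows, cols = _components_from_mask(mask, iu, R)
        comp_ids = np.flatnonzero(extent > 0)
        comps, stats = [], []
        for cid in comp_ids:
            sel = labels[rows] == cid
            comps.append(np.column_stack([rows[sel], cols[sel]]))
            if component_stat == "extent":
                stats.append(float(sel.sum()))
            else:
                e_idx = np.flatnonzero(mask)[sel]
                stats.append(float(np.sum(np.abs(r_vec[e_idx]) - r_crit)))
        return comps, np.asarray(stats), int(mask.sum())

    comps, stats, n_supra = comp_stats(r_obs)

    if families is not None:
        scheme = build_permutation_scheme(families, seed=seed)
        P = scheme.draw_matrix(n_perm)
    else:
        rng = np.random.default_rng(seed)
        P = np.stack([rng.permutation(n) for _ in range(n_perm)])
    null_r = ezn.T @ (zc[P].T) / n                     # E x n_perm
    null_max = np.zeros(n_perm)
    for j in range(n_perm):
        _, s, _ = comp_stats(null_r[:, j])
        null_max[j] = s.max() if s.size else 0.0

    if stats.size:
        pvals = np.array([perm_pvalue(s, null_max, alternative="greater")
                          for s in stats])
        if correction == "fdr":
            reject, _ = fdr_correct(pvals, q=q)
        else:
            reject = pvals <= q
    else:
        pvals = np.zeros(0)
        reject = np.zeros(0, dtype=bool)

    edge_r = np.zeros((R, R))
    edge_r[iu] = r_obs
    edge_r += edge_r.T
    return NBSResult(components=comps, sizes=stats, p_values=pvals,
                     q_reject=reject, null_max=null_max, edge_r=edge_r,
                     r_crit=r_crit, n_suprathreshold=n_supra)
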