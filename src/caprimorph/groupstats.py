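"""Group-comparison statistics for superimposed shapes and centroid sizes.

Covers the comparisons run between modern and archaeological sheep and
goat: permutation Procrustes ANOVA (residual randomization), morphological
disparity (per-group Procrustes variance with pairwise permutation tests),
Fligner-Killeen and pairwise Wilcoxon rank-sum tests on log centroid size,
a classical two-way ANOVA on size, Mahalanobis distances between group
means in PC-score space, a neighbor-joining summary tree, and group mean
shapes.

Standard tests are delegated (scipy for Fligner and rank-sum, statsmodels
for the size ANOVA, scikit-bio for neighbor joining); the shape-specific
permutation machinery is implemented here.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

logger = logging.getLogger(__name__)


def _as_flat_shapes(shapes: np.ndarray) -> np.ndarray:
    shapes = np.asarray(shapes, dtype=float)
    if shapes.ndim == 3:
        shapes = shapes.reshape(shapes.shape[0], -1)
    return shapes


# ---------------------------------------------------------------------------
# Procrustes ANOVA via residual randomization (RRPP)
# ---------------------------------------------------------------------------

def _design_blocks(factors: dict[str, np.ndarray], interaction: bool):
    """Sequential design blocks (term name, dummy matrix) after an intercept."""
    names = list(factors)
    blocks: list[tuple[str, np.ndarray]] = []
    dummies = {}
    for name in names:
        f = pd.Categorical(np.asarray(factors[name]))
        if len(f.categories) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
        d = pd.get_dummies(f, drop_first=True).to_numpy(dtype=float)
        dummies[name] = d
        blocks.append((name, d))
    if interaction:
        if len(names) != 2:
            raise ValueError("interaction requires exactly two factors")
        a, b = dummies[names[0]], dummies[names[1]]
        inter = np.einsum("ni,nj->nij", a, b).reshape(len(a), -1)
        blocks.append((f"{names[0]}:{names[1]}", inter))
    return blocks


def procrustes_anova(
    shapes: np.ndarray,
    factors: dict[str, np.ndarray] | np.ndarray,
    interaction: bool = False,
    n_perm: int = 999,
    seed: int | None = None,
    _perm_chunk: int = 100,
) -> pd.DataFrame:
    """Permutation ANOVA on the shape matrix with sequential (type-I) SS.

    Sums of squares come from nested least-squares fits on the flattened
    aligned coordinates; significance is assessed by residual randomization
    under the reduced model (RRPP): for each term, the reduced-model
    residuals are permuted, added back to the reduced-model fit, and the
    term's pseudo-F recomputed.  p = rank of the observed F among the
    n_perm + 1 values.  Deterministic under a fixed seed.
    """
    y = _as_flat_shapes(shapes)
    n = y.shape[0]
    if isinstance(factors, (np.ndarray, list, pd.Series)):
        factors = {"group": np.asarray(factors)}
    for name, f in factors.items():
        levels, counts = np.unique(np.asarray(f), return_counts=True)
        if n <= len(levels):
            raise ValueError("more factor levels than specimens")
    if interaction:
        combo = pd.MultiIndex.from_arrays([np.asarray(v) for v in factors.values()])
        _, cell_counts = np.unique(combo.to_numpy(), return_counts=True)
        if (cell_counts < 2).any():
            raise ValueError("a factor-level cell has a single specimen under interaction")

    blocks = _design_blocks(factors, interaction)
    intercept = np.ones((n, 1))
    # orthonormal bases of the nested design sequence
    designs = [intercept]
    for _, d in blocks:
        designs.append(np.hstack([designs[-1], d]))
    qs = [np.linalg.qr(d)[0] for d in designs]
    ranks = [q.shape[1] for q in qs]

    y0 = y - y.mean(axis=0)
    ss_total = float(np.sum(y0**2))
    proj_ss = [float(np.sum((q.T @ y) ** 2)) for q in qs]
    ss_terms = np.diff(proj_ss)
    df_terms = np.diff(ranks)
    ss_resid = float(np.sum(y**2)) - proj_ss[-1]
    df_resid = n - ranks[-1]
    ms_terms = ss_terms / df_terms
    ms_resid = ss_resid / df_resid
    f_obs = ms_terms / ms_resid

    rng = np.random.default_rng(seed)
    n_terms = len(blocks)
    exceed = np.zeros(n_terms)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
    for j in range(n_terms):
        q_red, q_full = qs[j], qs[j + 1]
        fitted = q_red @ (q_red.T @ y)
        resid = y - fitted
        df_j = df_terms[j]
        for start in range(0, n_perm, _perm_chunk):
            p_idx = perms[start : start + _perm_chunk]
            y_star = fitted[None] + resid[p_idx]  # (chunk, n, d)
            proj_full = np.einsum("nr,cnd->crd", q_full, y_star)
            proj_red = np.einsum("nr,cnd->crd", q_red, y_star)
            proj_all = np.einsum("nr,cnd->crd", qs[-1], y_star)
            ss_full = np.einsum("crd,crd->c", proj_full, proj_full)
            ss_red = np.einsum("crd,crd->c", proj_red, proj_red)
            ss_res_star = np.einsum("cnd,cnd->c", y_star, y_star) - np.einsum(
                "crd,crd->c", proj_all, proj_all
            )
            f_star = ((ss_full - ss_red) / df_j) / (ss_res_star / df_resid)
            exceed[j] += np.sum(f_star >= f_obs[j] - 1e-12)
    p_perm = (1.0 + exceed) / (n_perm + 1.0)

    rows = []
    for j, (name, _) in enumerate(blocks):
        rows.append(
            {
                "term": name,
                "df": int(df_terms[j]),
                "SS": ss_terms[j],
                "MS": ms_terms[j],
                "R2": ss_terms[j] / ss_total,
                "F": f_obs[j],
                "p_perm": p_perm[j],
            }
        )
    rows.append(
        {
            "term": "Residuals",
            "df": int(df_resid),
            "SS": ss_resid,
            "MS": ms_resid,
            "R2": ss_resid / ss_total,
            "F": np.nan,
            "p_perm": np.nan,
        }
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Morphological disparity (Procrustes variance)
# ---------------------------------------------------------------------------

def procrustes_variance(shapes: np.ndarray) -> float:
    """Per-group disparity: mean squared deviation from the group mean shape."""
    y = _as_flat_shapes(shapes)
    c = y - y.mean(axis=0)
    return float(np.sum(c**2)) / len(y)


def morphological_disparity(
    shapes: np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> dict:
    """Group Procrustes variances with pairwise permutation tests.

    The pairwise statistic is the absolute difference of the two group
    variances; its null distribution comes from permuting the group labels
    of the specimens in that pair.  Groups of size 1 are excluded with a
    warning.
    """
    y = _as_flat_shapes(shapes)
    g = pd.Series(np.asarray(groups)).astype(str)
    sizes = g.value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        logger.warning("excluding single-specimen groups from disparity: %s", singletons)
        keep = ~g.isin(singletons)
        y, g = y[keep.to_numpy()], g[keep].reset_index(drop=True)
    labels = sorted(g.unique())
    if len(labels) < 2:
        raise ValueError("disparity needs >= 2 groups of >= 2 specimens")
    variances = {lab: procrustes_variance(y[(g == lab).to_numpy()]) for lab in labels}

    rng = np.random.default_rng(seed)
    dist = pd.DataFrame(0.0, index=labels, columns=labels)
    pvals = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        mask = (g == a) | (g == b)
        sub = y[mask.to_numpy()]
        lab = (g[mask] == a).to_numpy()
        obs = abs(
            procrustes_variance(sub[lab]) - procrustes_variance(sub[~lab])
        )
        count = 1
        for _ in range(n_perm):
            perm = rng.permutation(lab)
            stat = abs(
                procrustes_variance(sub[perm]) - procrustes_variance(sub[~perm])
            )
            if stat >= obs - 1e-15:
                count += 1
        dist.loc[a, b] = dist.loc[b, a] = obs
        p = count / (n_perm + 1)
        pvals.loc[a, b] = pvals.loc[b, a] = p
    return {
        "variances": pd.Series(variances),
        "pairwise_distance": dist,
        "pairwise_p": pvals,
    }


# ---------------------------------------------------------------------------
# Size tests
# ---------------------------------------------------------------------------

def fligner_test(values, groups) -> tuple[float, int, float]:
    """Fligner-Killeen homogeneity-of-variance test (chi-square statistic).

    Returns (statistic, df, p) with df = number of groups - 1.  Constant
    data yield statistic 0, p 1.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    samples = [v[g == lab] for lab in labels]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("Fligner test needs >= 2 groups with >= 2 values each")
    if np.ptp(v) == 0:
        return 0.0, len(samples) - 1, 1.0
    stat, p = scipy.stats.fligner(*samples)
    return float(stat), len(samples) - 1, float(p)


def wilcoxon_pairwise(
    values, groups, correction: str = "bonferroni", exact_max_n: int = 50
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests with Bonferroni correction.

    Exact p-values for pairs where both groups have at most ``exact_max_n``
    observations and no ties, the tie-corrected normal approximation (with
    continuity correction) otherwise.  Adjusted p = raw p times the number
    of pairs, capped at 1.  Pairs involving a group with < 2 values are
    skipped with a warning (NaN entry).
    """
    v = np.asarray(values, dtype=float)
    g = pd.Series(np.asarray(groups)).astype(str)
    labels = sorted(g.unique())
    pairs = list(combinations(labels, 2))
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    np.fill_diagonal(out.values, 1.0)
    n_pairs = len(pairs)
    for a, b in pairs:
        xa, xb = v[(g == a).to_numpy()], v[(g == b).to_numpy()]
        if len(xa) < 2 or len(xb) < 2:
            logger.warning("skipping pair (%s, %s): group with < 2 values", a, b)
            continue
        has_ties = len(np.unique(np.concatenate([xa, xb]))) < len(xa) + len(xb)
        if max(len(xa), len(xb)) <= exact_max_n and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        p = float(res.pvalue)
        if correction == "bonferroni":
            p = min(1.0, p * n_pairs)
        out.loc[a, b] = out.loc[b, a] = p
    return out


def anova_size_twoway(log_cs, species, cohort) -> pd.DataFrame:
    """Two-way ANOVA with interaction on log centroid size (classical F tests).

    Sequential (type-I) sums of squares, matching the default of the usual
    R workflow for balanced-ish designs.  Every species x cohort cell must
    be non-empty.
    """
    df = pd.DataFrame(
        {"logcs": np.asarray(log_cs, float), "species": species, "cohort": cohort}
    )
    cells = df.groupby(["species", "cohort"], observed=True).size()
    n_sp = df["species"].nunique()
    n_co = df["cohort"].nunique()
    if n_sp < 2 or n_co < 2 or len(cells) < n_sp * n_co:
        raise ValueError(
            "two-way size ANOVA needs 2 levels per factor and no empty "
            "species x cohort cell"
        )
    model = smf.ols("logcs ~ C(species) * C(cohort)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    if np.ptp(df["logcs"].to_numpy()) == 0:
        # degenerate constant response: report zero F rather than a 0/0 ratio
        table.loc[table["F"].notna(), "F"] = 0.0
        table.loc[table["PR(>F)"].notna(), "PR(>F)"] = 1.0
    table = table.rename(
        index={
            "C(species)": "species",
            "C(cohort)": "cohort",
            "C(species):C(cohort)": "species:cohort",
            "Residual": "Residuals",
        }
    )
    return table


# ---------------------------------------------------------------------------
# Mahalanobis distances and neighbor joining
# ---------------------------------------------------------------------------

def mahalanobis_group_distances(scores: np.ndarray, groups) -> pd.DataFrame:
    """Mahalanobis distances between group means under pooled covariance.

    D(g, h) = sqrt((m_g - m_h)' S^{-1} (m_g - m_h)) with S the pooled
    within-group covariance of the scores.  Raises if S is singular on the
    chosen components.
    """
    x = np.asarray(scores, dtype=float)
    g = pd.Series(np.asarray(groups)).astype(str)
    labels = sorted(g.unique())
    n, p = x.shape
    means = {}
    scatter = np.zeros((p, p))
    for lab in labels:
        xi = x[(g == lab).to_numpy()]
        means[lab] = xi.mean(axis=0)
        d = xi - means[lab]
        scatter += d.T @ d
    pooled = scatter / (n - len(labels))
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        raise ValueError("singular pooled covariance: reduce the number of components")
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        d = means[a] - means[b]
        out.loc[a, b] = out.loc[b, a] = float(np.sqrt(d @ inv @ d))
    return out


def neighbor_joining(dist: pd.DataFrame | np.ndarray, labels=None) -> str:
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix, as newick.

    On an additive matrix the true topology and branch lengths are
    recovered exactly; negative branch lengths are clamped to zero (the
    scikit-bio convention), with a log note when clamping occurred.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"g{i}" for i in range(len(d))]
    if len(d) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    dm = DistanceMatrix(d, ids=[str(l) for l in labels])
    raw = _skbio_nj(dm, neg_as_zero=False)
    if any(
        node.length is not None and node.length < 0 for node in raw.traverse()
    ):
        logger.info("negative NJ branch lengths clamped to 0")
    tree = _skbio_nj(dm, neg_as_zero=True)
    return str(tree).strip()


def mean_shape(shapes: np.ndarray, groups=None) -> dict | np.ndarray:
    """Per-group mean shapes (coordinate-wise means, re-centered).

    With ``groups`` None, the single overall mean configuration is
    returned.
    """
    arr = np.asarray(shapes, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected (n, k, 2) aligned shapes")

    def _mean(sub: np.ndarray) -> np.ndarray:
        m = sub.mean(axis=0)
        return m - m.mean(axis=0)

    if groups is None:
        return _mean(arr)
    g = pd.Series(np.asarray(groups)).astype(str)
    out = {}
    for lab in sorted(g.unique()):
        mask = (g == lab).to_numpy()
        if not mask.any():
            raise ValueError(f"empty group {lab!r}")
        out[lab] = _mean(arr[mask])
    return out
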