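"""Shape PCA and the balanced-resampling ensemble of predictive LDAs.

The identification procedure mirrors standard practice for two-species
discrimination from superimposed landmark data with a strongly unbalanced
reference collection:

1. the Procrustes residuals of all specimens (reference and unknowns,
   superimposed together) enter a PCA;
2. each of ``n_iter`` iterations draws a without-replacement subsample of
   the majority species equal in size to the minority species, fits a
   two-class linear discriminant (pooled within-class covariance, equal
   priors) on the first ``n_pcs`` scores, records its leave-one-out
   cross-validation percentage (CVP) and its prediction for every unknown;
3. only iterations whose CVP reaches the third quartile of all CVPs are
   retained, and each unknown is labeled by the majority vote of the
   retained discriminants, reported as a percentage.

The discriminant is written out explicitly (class means, pooled covariance,
Mahalanobis rule) rather than delegated, because the leave-one-out loop
uses rank-one downdates of the pooled scatter for speed and the ensemble
bookkeeping needs the internals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gpa import AlignedDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# PCA of Procrustes residuals
# ---------------------------------------------------------------------------

@dataclass
class ShapePCA:
    """Principal components of centered, flattened aligned coordinates."""

    eigenvalues: np.ndarray  # descending, one per retained component
    components: np.ndarray  # (p, 2k) orthonormal rows
    scores: np.ndarray  # (n, p)
    variance_fractions: np.ndarray
    mean: np.ndarray  # (2k,) grand mean of the flattened coordinates

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def transform(self, flat_coords: np.ndarray) -> np.ndarray:
        """Project flattened (m, 2k) coordinates into the PC basis."""
        return (np.atleast_2d(flat_coords) - self.mean) @ self.components.T


def pca_shape(aligned: AlignedDataset | np.ndarray, drop_tol: float = 1e-12) -> ShapePCA:
    """PCA of the Procrustes residuals (SVD of the centered data matrix).

    Components with eigenvalue below ``drop_tol`` times the largest are
    dropped; eigenvalues use the n-1 denominator so that their sum equals
    the total variance of the centered coordinates.
    """
    x = aligned.flat() if isinstance(aligned, AlignedDataset) else np.asarray(aligned, float)
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"PCA needs at least 3 specimens, got {n}")
    mean = x.mean(axis=0)
    centered = x - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / (n - 1)
    keep = eig > drop_tol * eig[0] if eig[0] > 0 else np.zeros_like(eig, bool)
    eig, vt, s, u = eig[keep], vt[keep], s[keep], u[:, keep]
    scores = u * s
    total_var = float(np.sum(centered**2)) / (n - 1)
    return ShapePCA(
        eigenvalues=eig,
        components=vt,
        scores=scores,
        variance_fractions=eig / total_var if total_var > 0 else eig,
        mean=mean,
    )


# ---------------------------------------------------------------------------
# Two-class linear discriminant, pooled covariance, equal priors
# ---------------------------------------------------------------------------

@dataclass
class LinearDiscriminant:
    classes: tuple
    means: np.ndarray  # (2, p)
    pooled_cov: np.ndarray  # (p, p)
    _solve: np.ndarray = field(repr=False, default=None)  # cov^{-1}

    def decision(self, x: np.ndarray) -> np.ndarray:
        """Signed score: positive favors classes[0], negative classes[1].

        Equal-prior Mahalanobis rule: half the difference of squared
        Mahalanobis distances to the two class means.
        """
        x = np.atleast_2d(x)
        d0 = x - self.means[0]
        d1 = x - self.means[1]
        q0 = np.einsum("ij,jk,ik->i", d0, self._solve, d0)
        q1 = np.einsum("ij,jk,ik->i", d1, self._solve, d1)
        return 0.5 * (q1 - q0)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted class labels; an exact tie goes to classes[0] (documented)."""
        s = self.decision(x)
        return np.where(s >= 0, self.classes[0], self.classes[1])

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Posterior probability of classes[0] under the Gaussian model."""
        return 1.0 / (1.0 + np.exp(-self.decision(x)))


def fit_lda(scores: np.ndarray, labels: np.ndarray) -> LinearDiscriminant:
    """Fit the pooled-covariance two-class discriminant.

    Requires both classes present and m > p + 2 so the pooled covariance
    has positive degrees of freedom; a singular pooled covariance raises
    with the advice to use fewer components.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = tuple(pd.unique(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    m, p = x.shape
    if m <= p + 2:
        raise ValueError(f"m={m} samples insufficient for p={p} predictors (need m > p+2)")
    means = np.stack([x[y == c].mean(axis=0) for c in classes])
    scatter = np.zeros((p, p))
    for ci, c in enumerate(classes):
        d = x[y == c] - means[ci]
        scatter += d.T @ d
    pooled = scatter / (m - 2)
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular pooled within-class covariance: reduce the number of PCs"
        )
    return LinearDiscriminant(classes=classes, means=means, pooled_cov=pooled, _solve=inv)


def _loo_correct(x: np.ndarray, y01: np.ndarray, classes: tuple) -> int:
    """Count leave-one-out correct classifications of the pooled-cov LDA.

    Uses exact rank-one downdates of per-class sums and scatters, so each
    left-out case costs one p x p solve instead of a full refit.
    """
    m, p = x.shape
    masks = [y01 == 0, y01 == 1]
    ns = np.array([masks[0].sum(), masks[1].sum()])
    sums = np.stack([x[masks[0]].sum(axis=0), x[masks[1]].sum(axis=0)])
    means = sums / ns[:, None]
    scatters = []
    for ci in range(2):
        d = x[masks[ci]] - means[ci]
        scatters.append(d.T @ d)
    correct = 0
    for i in range(m):
        g = y01[i]
        ng = ns[g]
        if ng < 2:
            continue  # class would vanish; skip (cannot happen for balanced m>=4)
        mean_g = (sums[g] - x[i]) / (ng - 1)
        d = x[i] - sums[g] / ng
        scat_g = scatters[g] - np.outer(d, d) * (ng / (ng - 1))
        other = 1 - g
        pooled = (scat_g + scatters[other]) / (m - 3)
        mm = [None, None]
        mm[g] = mean_g
        mm[other] = means[other]
        d0 = x[i] - mm[0]
        d1 = x[i] - mm[1]
        try:
            sol = np.linalg.solve(pooled, np.stack([d0, d1], axis=1))
        except np.linalg.LinAlgError:
            raise ValueError("singular pooled covariance in LOO: reduce the number of PCs")
        q0 = d0 @ sol[:, 0]
        q1 = d1 @ sol[:, 1]
        pred = 0 if q1 - q0 >= 0 else 1
        if pred == g:
            correct += 1
    return correct


def cross_validation_percentage(scores: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-out cross-validation percentage of the two-class LDA.

    Each specimen is predicted by a discriminant refit without it; the CVP
    is 100 times the fraction predicted correctly.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = tuple(pd.unique(y))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    m, p = x.shape
    if m <= p + 2:
        raise ValueError(f"m={m} samples insufficient for p={p} predictors")
    y01 = np.where(y == classes[0], 0, 1)
    return 100.0 * _loo_correct(x, y01, classes) / m


# ---------------------------------------------------------------------------
# Balanced-resampling ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleIdentification:
    """Votes, CVP distribution and retention bookkeeping of the ensemble."""

    table: pd.DataFrame  # per-specimen votes/percentages/final label
    cvps: np.ndarray  # (n_iter,)
    q3_threshold: float
    retained_ids: np.ndarray  # indices (0-based) of retained iterations
    n_pcs: int
    n_per_class: int
    n_iter: int
    seed: int | None
    classes: tuple
    retention_rule: str

    @property
    def final_labels(self) -> pd.Series:
        return self.table["final_label"]


def ensemble_identify(
    reference_scores: np.ndarray,
    reference_labels: np.ndarray,
    unknown_scores: np.ndarray,
    n_iter: int = 100,
    n_pcs: int = 20,
    retention_rule: str = ">=",
    seed: int | None = None,
    unknown_ids=None,
    force_call: bool = False,
) -> EnsembleIdentification:
    """Identify unknowns by a CVP-filtered ensemble of balanced pLDAs.

    Each iteration down-samples the majority species (without replacement)
    to the minority count, fits the discriminant on the first ``n_pcs``
    scores, and records its leave-one-out CVP and predictions.  Iterations
    with CVP at or above the third quartile (type-7 linear interpolation)
    of all CVPs are retained — the strict ``">"`` rule is available but
    falls back to ``">="`` (logged) if it would retain nothing.  A specimen
    tied 50/50 over the retained iterations is labeled ``"unresolved"``
    unless ``force_call`` is set, in which case the first class wins.
    """
    rng = np.random.default_rng(seed)
    ref = np.asarray(reference_scores, dtype=float)[:, :n_pcs]
    unk = np.asarray(unknown_scores, dtype=float)[:, :n_pcs]
    y = np.asarray(reference_labels)
    classes = tuple(pd.unique(y))
    if len(classes) != 2:
        raise ValueError(f"reference must contain exactly 2 species, got {classes}")
    if retention_rule not in (">=", ">"):
        raise ValueError("retention_rule must be '>=' or '>'")
    counts = {c: int((y == c).sum()) for c in classes}
    if counts[classes[0]] <= counts[classes[1]]:
        minority, majority = classes
    else:
        majority, minority = classes
    n_minor = counts[minority]
    idx_minor = np.flatnonzero(y == minority)
    idx_major = np.flatnonzero(y == majority)

    n_unknown = unk.shape[0]
    cvps = np.empty(n_iter)
    votes = np.zeros((n_unknown, 2), dtype=int)  # per-iteration predictions later
    predictions = np.empty((n_iter, n_unknown), dtype=int)  # 0 -> classes[0]
    for it in range(n_iter):
        sub_major = rng.choice(idx_major, size=n_minor, replace=False)
        train_idx = np.concatenate([idx_minor, sub_major])
        xt, yt = ref[train_idx], y[train_idx]
        lda = fit_lda(xt, yt)
        y01 = np.where(yt == lda.classes[0], 0, 1)
        cvps[it] = 100.0 * _loo_correct(xt, y01, lda.classes) / len(yt)
        pred = lda.predict(unk)
        predictions[it] = np.where(pred == classes[0], 0, 1)

    q3 = float(np.percentile(cvps, 75))  # type-7 linear interpolation
    if np.ptp(cvps) == 0:
        logger.info("all CVPs identical (%.2f): quartile filter vacuous, retaining all", q3)
        retained = np.arange(n_iter)
    elif retention_rule == ">":
        retained = np.flatnonzero(cvps > q3)
        if retained.size == 0:
            logger.warning("strict '>' retention empty: falling back to '>='")
            retained = np.flatnonzero(cvps >= q3)
    else:
        retained = np.flatnonzero(cvps >= q3)

    kept = predictions[retained]  # (r, n_unknown)
    votes[:, 1] = kept.sum(axis=0)
    votes[:, 0] = len(retained) - votes[:, 1]
    pct0 = 100.0 * votes[:, 0] / len(retained)
    tie = votes[:, 0] == votes[:, 1]
    final = np.where(votes[:, 0] > votes[:, 1], classes[0], classes[1]).astype(object)
    if force_call:
        final[tie] = classes[0]
    else:
        final[tie] = "unresolved"
    if unknown_ids is None:
        unknown_ids = [str(i) for i in range(n_unknown)]
    table = pd.DataFrame(
        {
            "specimen_id": list(unknown_ids),
            f"votes_{classes[0]}": votes[:, 0],
            f"votes_{classes[1]}": votes[:, 1],
            f"percent_{classes[0]}": pct0,
            f"percent_{classes[1]}": 100.0 - pct0,
            "percent_majority": np.maximum(pct0, 100.0 - pct0),
            "final_label": final,
            "tie_flag": tie,
        }
    )
    return EnsembleIdentification(
        table=table,
        cvps=cvps,
        q3_threshold=q3,
        retained_ids=retained,
        n_pcs=n_pcs,
        n_per_class=n_minor,
        n_iter=n_iter,
        seed=seed,
        classes=classes,
        retention_rule=retention_rule,
    )


def congruence_report(
    ensemble: EnsembleIdentification, molecular_labels
) -> tuple[pd.DataFrame, dict]:
    """Compare ensemble identifications with molecular (ZooMS-style) labels.

    Returns the per-specimen table with agreement flags plus a summary with
    counts, percent agreement, the cross-tabulation of morphometric against
    molecular labels, and the mismatches with their vote percentages.
    Specimens lacking a molecular label are excluded and reported.
    """
    mol = pd.Series(molecular_labels).reset_index(drop=True)
    table = ensemble.table.copy().reset_index(drop=True)
    if len(mol) != len(table):
        raise ValueError("molecular label vector length mismatch")
    table["molecular_label"] = mol
    missing = mol.isna() | (mol.astype(str).isin(["", "none"]))
    if missing.any():
        logger.warning("%d specimens lack a molecular label: excluded", int(missing.sum()))
    scored = table[~missing].copy()
    scored["agreement"] = scored["final_label"] == scored["molecular_label"]
    n = len(scored)
    n_agree = int(scored["agreement"].sum())
    mismatches = scored[~scored["agreement"]][
        ["specimen_id", "final_label", "molecular_label", "percent_majority"]
    ]
    crosstab = pd.crosstab(scored["final_label"], scored["molecular_label"])
    summary = {
        "n_scored": n,
        "n_excluded_missing_label": int(missing.sum()),
        "n_agree": n_agree,
        "n_disagree": n - n_agree,
        "percent_congruent": 100.0 * n_agree / n if n else float("nan"),
        "crosstab": crosstab,
        "mismatches": mismatches,
    }
    return table, summary
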