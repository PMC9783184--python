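"""Two-group differential feature analysis: per-feature tests, volcano
gating, top-K selection, PCA scores, and set overlaps.

The same machinery serves lipid species tables (differential lipids at a
2-fold gate) and expression matrices (differentially expressed genes at the
same 2-fold gate).  Effect size is always the log2 ratio of group means of
the raw abundances; p-values come from a configurable two-sided test on the
per-sample values (log2-transformed for the t-family tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import FeatureMatrix

TESTS = ("t", "welch", "wilcoxon", "ks")


@dataclass
class DifferentialResult:
    feature_id: str
    log2_fold_change: float
    p_value: float
    test_used: str
    significant: bool
    direction: str  # "up" | "down" | "ns"


def default_pseudocount(values: pd.DataFrame) -> float:
    """Half the smallest nonzero value in the matrix (0 if all-zero)."""
    arr = values.to_numpy(dtype=float)
    nz = arr[arr > 0]
    return float(nz.min()) / 2.0 if nz.size else 0.0


def differential_test(matrix: FeatureMatrix, group_a: str, group_b: str,
                      test: str = "t", pseudocount: float | None = None,
                      log2fc_threshold: float = 1.0, alpha: float = 0.05,
                      log_scale: bool = False) -> list[DifferentialResult]:
    """Per-feature two-group comparison (group A over group B).

    For raw abundances (the default) log2 fold change =
    log2(mean_A + pc) - log2(mean_B + pc) and the t-family tests act on
    log2(value + pc).  With ``log_scale=True`` the matrix is taken to be
    on the log2 scale already (e.g. log-transformed expression): the fold
    change is the plain mean difference and no pseudocount is applied.
    ``test`` selects the p-value: "t" (Student's two-tailed, pooled
    variance), "welch" (unequal variance t), "wilcoxon" (rank-sum), or
    "ks" (two-sample Kolmogorov-Smirnov).  Zero-variance features under
    the t-family tests get p = 1 with a warning.  Significance:
    |log2FC| > threshold and p < alpha.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; expected one of {TESTS}")
    A = matrix.group_values(group_a).to_numpy(dtype=float)
    B = matrix.group_values(group_b).to_numpy(dtype=float)
    for label, arr in ((group_a, A), (group_b, B)):
        if arr.shape[1] < 2:
            raise ValueError(f"group {label!r} has {arr.shape[1]} sample(s); need >= 2")
    pc = default_pseudocount(matrix.values) if pseudocount is None else float(pseudocount)
    if pc < 0:
        raise ValueError("pseudocount must be >= 0")

    if log_scale:
        la, lb = A, B
        l2fc = A.mean(axis=1) - B.mean(axis=1)
    else:
        la, lb = np.log2(A + pc), np.log2(B + pc)
        l2fc = np.log2(A.mean(axis=1) + pc) - np.log2(B.mean(axis=1) + pc)

    if test in ("t", "welch"):
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = stats.ttest_ind(la, lb, axis=1, equal_var=(test == "t"))
        degenerate = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
        p = np.where(np.isnan(p), 1.0, p)
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} zero-variance feature(s) under the "
                f"{test}-test; reporting p = 1"
            )
            p = np.where(degenerate, 1.0, p)
    elif test == "wilcoxon":
        _, p = stats.mannwhitneyu(A, B, axis=1, alternative="two-sided")
    else:  # ks
        p = np.array([stats.ks_2samp(a, b).pvalue for a, b in zip(A, B)])

    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    sig = (np.abs(l2fc) > log2fc_threshold) & (p < alpha)
    return [
        DifferentialResult(
            feature_id=fid,
            log2_fold_change=float(fc),
            p_value=float(pv),
            test_used=test,
            significant=bool(s),
            direction=("up" if fc > 0 else "down") if s else "ns",
        )
        for fid, fc, pv, s in zip(matrix.feature_ids, l2fc, p, sig)
    ]


def results_table(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "test_used": [r.test_used for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
        }
    ).set_index("feature_id")


def volcano_gate(results: list[DifferentialResult], log2fc_threshold: float = 1.0,
                 alpha: float = 0.05) -> tuple[int, int, list[DifferentialResult]]:
    """Apply the volcano gate |log2FC| > threshold and p < alpha.

    Returns (n_up, n_down, gated results with re-evaluated calls).  The
    default threshold of 1 is the 2-fold gate used for both lipids and
    genes.
    """
    if log2fc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    gated = []
    n_up = n_down = 0
    for r in results:
        s = abs(r.log2_fold_change) > log2fc_threshold and r.p_value < alpha
        d = ("up" if r.log2_fold_change > 0 else "down") if s else "ns"
        if d == "up":
            n_up += 1
        elif d == "down":
            n_down += 1
        gated.append(
            DifferentialResult(r.feature_id, r.log2_fold_change, r.p_value,
                               r.test_used, s, d)
        )
    return n_up, n_down, gated


def top_k_by_significance(results: list[DifferentialResult], k: int) -> list[str]:
    """The k most significant features, for heatmap display.

    Among significant features: smallest p first; ties broken by larger
    |log2FC|, then lexical feature id.  If fewer than k are significant,
    all of them are returned with a warning.
    """
    if k > len(results):
        raise ValueError(f"k={k} exceeds the number of features ({len(results)})")
    sig = [r for r in results if r.significant]
    sig.sort(key=lambda r: (r.p_value, -abs(r.log2_fold_change), r.feature_id))
    if len(sig) < k:
        warnings.warn(f"only {len(sig)} significant features for top-{k} selection")
        return [r.feature_id for r in sig]
    return [r.feature_id for r in sig[:k]]


def pca_scores(matrix: FeatureMatrix, n_components: int = 2,
               scaling: str = "center") -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample principal-component scores and explained-variance fractions.

    Samples are observations, features variables.  ``scaling="center"``
    (default for abundance data) mean-centers each feature;
    ``scaling="autoscale"`` additionally divides by the feature standard
    deviation (constant features are left centered).
    """
    from sklearn.decomposition import PCA

    if scaling not in ("center", "autoscale"):
        raise ValueError(f"unknown scaling {scaling!r}")
    X = matrix.values.to_numpy(dtype=float).T  # samples x features
    if n_components > min(X.shape):
        raise ValueError("n_components exceeds min(features, samples)")
    Xc = X - X.mean(axis=0)
    if not np.any(Xc != 0):
        raise ValueError("constant matrix: no variance to decompose")
    if scaling == "autoscale":
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(Xc)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
        pca.explained_variance_ratio_,
    )


def set_overlap(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Venn partition sizes for two or more feature-id sets.

    Keys are the sorted tuples of set labels an element belongs to
    exclusively; values are partition sizes.  Partition sizes sum to the
    size of the union.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    labels = sorted(sets)
    union = set().union(*sets.values())
    out: dict[tuple[str, ...], int] = {}
    for el in union:
        key = tuple(l for l in labels if el in sets[l])
        out[key] = out.get(key, 0) + 1
    return out
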