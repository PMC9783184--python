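"""Parametric empirical-Bayes batch-effect correction (ComBat).

Location-scale model per gene g, sample j in batch i::

    Y_gij = alpha_g + gamma_ig + delta_ig * eps_gij,   eps ~ N(0, sigma_g^2)

After standardizing each gene by its grand mean and pooled variance, the
per-batch additive effects gamma and multiplicative effects delta^2 are
shrunk across genes with conjugate priors — normal for gamma, inverse-gamma
for delta^2 — whose hyperparameters are set by method of moments from the
per-batch empirical distributions.  Conditional posterior means are
iterated to convergence, and corrected data are the back-transformed
standardized residuals with the shrunken batch effects removed.

Expression inputs are expected on a log scale (log2(x+1) upstream of
correction for count-derived expression).  Cross-species merging of human
tumor and mouse culture matrices is by case-insensitive symbol
intersection (:func:`merge_by_symbol`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import BATCH_COL, GROUP_COL, FeatureMatrix


@dataclass
class BatchModel:
    batches: list[str]
    gene_ids: list[str]
    batch_sizes: dict[str, int]
    grand_mean: np.ndarray          # per gene, batch-size-weighted (alpha_g)
    var_pooled: np.ndarray          # per gene, residual variance about batch means
    gamma_hat: pd.DataFrame         # batches x genes, standardized scale
    delta_hat: pd.DataFrame
    gamma_star: pd.DataFrame        # EB-shrunken
    delta_star: pd.DataFrame
    gamma_bar: dict[str, float]     # normal-prior means per batch
    t2: dict[str, float]            # normal-prior variances per batch
    a_prior: dict[str, float]       # inverse-gamma shape per batch
    b_prior: dict[str, float]       # inverse-gamma scale per batch
    passthrough_genes: list[str] = field(default_factory=list)
    n_iterations: dict[str, int] = field(default_factory=dict)
    # per-sample standardization means when covariates are protected
    # (genes x fitted samples); None for the covariate-free model
    stand_mean_per_sample: pd.DataFrame | None = None

    def batch_effects_data_scale(self) -> pd.DataFrame:
        """Shrunken batch effects back on the data scale.

        Rows = batches; ``additive`` is the mean over genes of
        gamma_star * sqrt(var_pooled) (the additive offset each batch
        carries relative to the grand mean), ``scale`` the mean of
        sqrt(delta_star) (the batch's noise-scale multiplier relative to
        the pooled noise level).
        """
        sd = np.sqrt(self.var_pooled)
        rows = {
            b: {
                "additive": float((self.gamma_star.loc[b].to_numpy() * sd).mean()),
                "scale": float(np.sqrt(self.delta_star.loc[b].to_numpy()).mean()),
            }
            for b in self.batches
        }
        return pd.DataFrame.from_dict(rows, orient="index")


def _moments_priors(gamma_hat: np.ndarray, delta_hat: np.ndarray):
    gamma_bar = float(gamma_hat.mean())
    t2 = float(gamma_hat.var(ddof=1))
    m = float(delta_hat.mean())
    s2 = float(delta_hat.var(ddof=1))
    if s2 <= 0:
        # zero spread across genes: the prior degenerates to a point mass
        # at the common value m (continuous limit of the moment equations)
        a = 1e8
        b = m * (a - 1.0)
    else:
        a = (2 * s2 + m ** 2) / s2
        b = (m * s2 + m ** 3) / s2
    return gamma_bar, t2, a, b


def _it_solve(Z_b: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
              gamma_bar: float, t2: float, a: float, b: float,
              tol: float, max_iter: int):
    """Iterate the conditional posterior means for one batch."""
    n = Z_b.shape[1]
    g_old, d_old = gamma_hat.copy(), delta_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (n * t2 * gamma_hat + d_old * gamma_bar) / (n * t2 + d_old)
        sum2 = ((Z_b - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old, it


def fit_combat(matrix: FeatureMatrix, batch_col: str = BATCH_COL,
               covariate_cols: list[str] | None = None,
               tol: float = 1e-4, max_iter: int = 100) -> BatchModel:
    """Fit the parametric empirical-Bayes batch model.

    Requires >= 2 batches with >= 2 samples each.  Genes with zero
    variance within every batch are flagged and passed through
    uncorrected.  A batch nested 1:1 within a biological group triggers a
    warning (correction may remove signal) but proceeds, since the
    tissue-vs-culture design of a tumor/SVF comparison is confounded by
    construction.

    ``covariate_cols`` names categorical metadata columns (e.g.
    ``["group"]``) whose effects are protected: they enter the
    standardization design, are kept out of the batch-effect estimates,
    and are restored on back-transformation.  A covariate level nested
    entirely within one batch makes the design singular and is rejected.
    """
    if batch_col not in matrix.samples.columns:
        raise ValueError(f"no {batch_col!r} column in sample metadata")
    batch_series = matrix.samples[batch_col].astype(str)
    batches = sorted(batch_series.unique().tolist())
    if len(batches) < 2:
        raise ValueError("need >= 2 batches")
    sizes = {b: int((batch_series == b).sum()) for b in batches}
    for b, n in sizes.items():
        if n < 2:
            raise ValueError(f"batch {b!r} has a single sample")
    if GROUP_COL in matrix.samples.columns:
        crossed = matrix.samples.groupby(GROUP_COL)[batch_col].nunique()
        if (crossed == 1).all() and len(batches) > 1:
            warnings.warn(
                "every group sits in exactly one batch; batch correction may "
                "remove biological signal"
            )

    X = matrix.values.to_numpy(dtype=float)
    genes = matrix.values.index
    masks = {b: (batch_series == b).to_numpy() for b in batches}

    within_var = np.column_stack([X[:, masks[b]].var(axis=1) for b in batches])
    passthrough = (within_var == 0).all(axis=1)

    N = X.shape[1]
    k = len(batches)
    batch_design = np.column_stack([masks[b].astype(float) for b in batches])
    cov_design = _covariate_design(matrix.samples, covariate_cols)
    design = np.hstack([batch_design, cov_design])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate confounded with batch: design is singular")
    # least-squares gene-wise fit of batch means + protected covariates
    B_hat, *_ = np.linalg.lstsq(design, X.T, rcond=None)  # (p, genes)
    w = np.array([sizes[b] / N for b in batches])
    grand_mean = (w @ B_hat[:k]).ravel()
    fitted = (design @ B_hat).T
    # unbiased residual variance about the fitted design; makes delta
    # exactly 1 for effect-free equal-size batches, and only rescales the
    # standardized coordinates relative to the biased-variance convention
    # (the corrected output is invariant to that choice)
    var_pooled = ((X - fitted) ** 2).sum(axis=1) / (N - design.shape[1])
    var_safe = np.where(var_pooled > 0, var_pooled, 1.0)

    stand_mean = grand_mean[:, None] + (cov_design @ B_hat[k:]).T
    Z = (X - stand_mean) / np.sqrt(var_safe)[:, None]

    gamma_hat, delta_hat, gamma_star, delta_star = {}, {}, {}, {}
    gamma_bar, t2, a_prior, b_prior, n_iter = {}, {}, {}, {}, {}
    for b in batches:
        Zb = Z[:, masks[b]]
        gh = Zb.mean(axis=1)
        dh = Zb.var(axis=1, ddof=1)
        dh = np.maximum(dh, 1e-12)  # delta must stay strictly positive
        gb, tt2, ap, bp = _moments_priors(gh, dh)
        gs, ds, it = _it_solve(Zb, gh, dh, gb, tt2, ap, bp, tol, max_iter)
        gamma_hat[b], delta_hat[b] = gh, dh
        gamma_star[b], delta_star[b] = gs, ds
        gamma_bar[b], t2[b], a_prior[b], b_prior[b], n_iter[b] = gb, tt2, ap, bp, it

    def _frame(d):
        return pd.DataFrame(d, index=genes).T.loc[batches]

    stand_df = None
    if cov_design.shape[1] > 0:
        stand_df = pd.DataFrame(stand_mean, index=genes,
                                columns=matrix.values.columns)
    return BatchModel(
        batches=batches,
        gene_ids=genes.tolist(),
        batch_sizes=sizes,
        grand_mean=grand_mean,
        var_pooled=var_pooled,
        gamma_hat=_frame(gamma_hat),
        delta_hat=_frame(delta_hat),
        gamma_star=_frame(gamma_star),
        delta_star=_frame(delta_star),
        gamma_bar=gamma_bar,
        t2=t2,
        a_prior=a_prior,
        b_prior=b_prior,
        passthrough_genes=genes[passthrough].tolist(),
        n_iterations=n_iter,
        stand_mean_per_sample=stand_df,
    )


def _covariate_design(samples: pd.DataFrame,
                      covariate_cols: list[str] | None) -> np.ndarray:
    """Dummy-coded covariate columns (first level dropped per covariate)."""
    if not covariate_cols:
        return np.empty((len(samples), 0))
    blocks = []
    for col in covariate_cols:
        if col not in samples.columns:
            raise ValueError(f"no {col!r} column in sample metadata")
        levels = sorted(samples[col].astype(str).unique())
        if len(levels) < 2:
            continue
        for lev in levels[1:]:
            blocks.append((samples[col].astype(str) == lev).to_numpy(float))
    if not blocks:
        return np.empty((len(samples), 0))
    return np.column_stack(blocks)


def apply_combat(matrix: FeatureMatrix, model: BatchModel,
                 batch_col: str = BATCH_COL) -> FeatureMatrix:
    """Remove the fitted batch effects from a matrix.

    Every batch present in the matrix must be in the model; genes flagged
    as zero-variance-within-every-batch at fit time pass through
    unchanged.
    """
    batch_series = matrix.samples[batch_col].astype(str)
    unseen = sorted(set(batch_series) - set(model.batches))
    if unseen:
        raise ValueError(f"batch label(s) not in model: {unseen}")
    if matrix.values.index.tolist() != model.gene_ids:
        raise ValueError("feature ids differ from the fitted model")

    X = matrix.values.to_numpy(dtype=float)
    var_safe = np.where(model.var_pooled > 0, model.var_pooled, 1.0)
    sd = np.sqrt(var_safe)
    if model.stand_mean_per_sample is not None:
        missing = [s for s in matrix.sample_ids
                   if s not in model.stand_mean_per_sample.columns]
        if missing:
            raise ValueError(
                "covariate-protected model can only be applied to fitted "
                f"samples; unknown: {missing[:5]}")
        stand = model.stand_mean_per_sample[matrix.sample_ids].to_numpy()
    else:
        stand = model.grand_mean[:, None]
    Z = (X - stand) / sd[:, None]
    out = np.empty_like(Z)
    for b in model.batches:
        mask = (batch_series == b).to_numpy()
        if not mask.any():
            continue
        gs = model.gamma_star.loc[b].to_numpy()
        ds = model.delta_star.loc[b].to_numpy()
        out[:, mask] = (Z[:, mask] - gs[:, None]) / np.sqrt(ds)[:, None]
    corrected = out * sd[:, None] + stand
    if model.passthrough_genes:
        keep = matrix.values.index.isin(model.passthrough_genes)
        corrected[keep] = X[keep]
    values = pd.DataFrame(corrected, index=matrix.values.index,
                          columns=matrix.values.columns)
    return FeatureMatrix(values, matrix.samples.copy())


def correct_batches(matrix: FeatureMatrix, batch_col: str = BATCH_COL,
                    **kwargs) -> tuple[FeatureMatrix, BatchModel]:
    """Convenience: fit and apply in one call."""
    model = fit_combat(matrix, batch_col=batch_col, **kwargs)
    return apply_combat(matrix, model, batch_col=batch_col), model


def merge_by_symbol(a: FeatureMatrix, b: FeatureMatrix) -> tuple[FeatureMatrix, int]:
    """Merge two expression matrices on case-insensitive gene symbols.

    Handles human (upper-case) vs mouse (title-case) symbol conventions.
    Unmatched genes are dropped (the count is returned); when several rows
    of one matrix collapse onto one symbol, the higher-mean row wins.  The
    merged matrix uses the first matrix's casing and concatenates samples.
    """
    def dedupe(fm: FeatureMatrix) -> pd.DataFrame:
        v = fm.values.copy()
        key = v.index.str.upper()
        order = v.mean(axis=1).to_numpy()
        df = v.assign(_key=key, _mean=order)
        df = df.sort_values("_mean", ascending=False).drop_duplicates("_key")
        df.index = df.pop("_key")
        return df.drop(columns="_mean")

    da, db = dedupe(a), dedupe(b)
    shared = da.index.intersection(db.index).sort_values()
    n_dropped = (len(da) - len(shared)) + (len(db) - len(shared))
    if len(shared) == 0:
        raise ValueError("no shared gene symbols between matrices")
    # restore the first matrix's casing for display
    casing = {k.upper(): k for k in a.values.index}
    merged = pd.concat([da.loc[shared], db.loc[shared]], axis=1)
    merged.index = [casing.get(s, s) for s in shared]
    samples = pd.concat([a.samples, b.samples])
    return FeatureMatrix(merged, samples), n_dropped
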