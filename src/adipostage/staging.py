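"""Adipogenic differentiation staging of tumor transcriptomes.

A stromal-vascular-fraction (SVF) culture differentiated into mature
adipocytes over days 0-10 provides a staged reference.  For each sampled
day d the mean corrected SVF expression profile x_d is compared to the
tumor-group mean T-bar by Euclidean distance, normalized by the distance to
the normal-tissue mean N-bar::

    relative_distance(d) = ||x_d - T-bar||_2 - ||x_d - N-bar||_2
    similarity(d)        = 1 / relative_distance(d)

A day whose profile is closer to the tumor than to normal tissue has
negative relative distance (literal similarity negative with small
magnitude-inverse); the best-matching differentiation stage is the day
minimizing the relative distance, which is monotone-consistent with
reading "higher similarity = closer stage" regardless of the reciprocal's
sign.  An optional display mode reports 1/|relative_distance| for
bar-plot-style figures (flagged as non-literal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import DAY_COL, FeatureMatrix

DEFAULT_TOL = 1e-9


@dataclass
class StageSimilarityProfile:
    tumor_group: str
    days: list[int]
    d_T: dict[int, float]
    d_N: dict[int, float]
    relative_distance: dict[int, float]
    similarity: dict[int, float]        # 1/relative_distance; NaN when undefined
    undefined: dict[int, bool]
    best_day: int
    tie: bool = False
    abs_similarity: dict[int, float] = field(default_factory=dict)  # 1/|rel|, display mode


def stage_similarity(corrected: FeatureMatrix, tumor_group: str,
                     normal_group: str = "normal", svf_group: str = "SVF",
                     days: list[int] | None = None,
                     tol: float = DEFAULT_TOL) -> StageSimilarityProfile:
    """Distance-based staging of one tumor group against the SVF time course.

    ``corrected`` should already be batch-corrected; SVF samples must carry
    integer ``day`` metadata.  SVF replicates within a day are averaged
    into x_d before distances are taken.  Days requested but absent from
    the data are dropped with a warning.  When |relative_distance| falls
    below ``tol`` the reciprocal similarity is flagged undefined (NaN).
    """
    meta = corrected.samples
    svf_ids = corrected.samples_in_group(svf_group)
    if not svf_ids:
        raise ValueError(f"no samples in SVF group {svf_group!r}")
    svf_days = meta.loc[svf_ids, DAY_COL]
    if svf_days.isna().any():
        bad = svf_days.index[svf_days.isna()].tolist()
        raise ValueError(f"SVF sample(s) without day metadata: {bad[:5]}")
    available = sorted(int(d) for d in svf_days.unique())
    if days is None:
        use_days = available
    else:
        use_days = sorted(int(d) for d in days)
        missing = [d for d in use_days if d not in available]
        if missing:
            warnings.warn(f"day(s) {missing} absent from SVF samples; omitted")
            use_days = [d for d in use_days if d in available]
    if not use_days:
        raise ValueError("no usable SVF days")

    T_bar = corrected.group_values(tumor_group).mean(axis=1).to_numpy()
    N_bar = corrected.group_values(normal_group).mean(axis=1).to_numpy()

    d_T, d_N, rel, sim, undef, abs_sim = {}, {}, {}, {}, {}, {}
    for d in use_days:
        ids = [s for s in svf_ids if int(meta.at[s, DAY_COL]) == d]
        x = corrected.values[ids].mean(axis=1).to_numpy()
        dt = float(np.linalg.norm(x - T_bar))
        dn = float(np.linalg.norm(x - N_bar))
        r = dt - dn
        d_T[d], d_N[d], rel[d] = dt, dn, r
        if abs(r) > tol:
            sim[d], abs_sim[d], undef[d] = 1.0 / r, 1.0 / abs(r), False
        else:
            sim[d], abs_sim[d], undef[d] = float("nan"), float("nan"), True

    rel_vals = np.array([rel[d] for d in use_days])
    best_idx = int(np.argmin(rel_vals))  # earliest day wins exact ties
    tie = bool((np.abs(rel_vals - rel_vals[best_idx]) <= tol).sum() > 1)
    if tie:
        warnings.warn("tied relative distance between days; reporting the earliest")
    return StageSimilarityProfile(
        tumor_group=tumor_group,
        days=use_days,
        d_T=d_T,
        d_N=d_N,
        relative_distance=rel,
        similarity=sim,
        undefined=undef,
        best_day=use_days[best_idx],
        tie=tie,
        abs_similarity=abs_sim,
    )


def similarity_barplot_table(profile: StageSimilarityProfile) -> pd.DataFrame:
    """Per-day export of the staging profile, ordered by day.

    Columns: d_T, d_N, relative_distance, similarity (literal reciprocal,
    empty when undefined), abs_similarity (display mode 1/|rel|),
    undefined flag, and a best_day marker.
    """
    rows = []
    for d in profile.days:
        rows.append(
            {
                "day": d,
                "d_T": profile.d_T[d],
                "d_N": profile.d_N[d],
                "relative_distance": profile.relative_distance[d],
                "similarity": profile.similarity[d],
                "abs_similarity": profile.abs_similarity[d],
                "undefined": profile.undefined[d],
                "best_day": d == profile.best_day,
            }
        )
    return pd.DataFrame(rows).set_index("day")


def best_day_stability(corrected: FeatureMatrix, tumor_group: str,
                       normal_group: str = "normal", svf_group: str = "SVF",
                       subsample_fraction: float = 0.8, n_resamples: int = 50,
                       seed: int = 0) -> float:
    """Diagnostic: fraction of gene-subsampling resamples whose best_day
    agrees with the full-set call."""
    full = stage_similarity(corrected, tumor_group, normal_group, svf_group)
    rng = np.random.default_rng(seed)
    n = corrected.n_features
    k = max(2, int(round(subsample_fraction * n)))
    agree = 0
    for _ in range(n_resamples):
        idx = rng.choice(n, size=k, replace=False)
        sub = corrected.subset_features(np.array(corrected.feature_ids)[idx])
        prof = stage_similarity(sub, tumor_group, normal_group, svf_group)
        agree += prof.best_day == full.best_day
    return agree / n_resamples
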