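"""Preranked gene-set enrichment: ES/NES with a gene-label permutation null.

Genes are ranked by a differential statistic; a gene set's enrichment score
(ES) is the signed maximum deviation of a weighted running sum over the
ranked list.  With hit weight |s_i|^p (normalized to unit total mass over
set members) the running sum at position i is

    R(i) = sum_{hits <= i} |s|^p / N_R  -  i / N

i.e. the accumulated hit mass minus the uniform baseline.  At p = 0 this is
exactly the one-sample Kolmogorov-Smirnov statistic of the hit positions
against the uniform distribution on the list, so a set consisting of the
single top-ranked gene scores ES = 1 - 1/N.  Significance comes from
size-matched random gene-label permutations: NES normalizes ES by the mean
of same-signed null scores, and the permutation p-value counts same-signed
null scores at least as extreme.  The selection gate is
(|NES| > 1) and (p < alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .differential import DifferentialResult

RANK_METRICS = ("signed_log2fc", "signed_logp")


@dataclass
class GeneSet:
    set_id: str
    description: str
    member_genes: list[str]

    def __post_init__(self) -> None:
        seen, dedup = set(), []
        for g in self.member_genes:
            if g not in seen:
                seen.add(g)
                dedup.append(g)
        self.member_genes = dedup
        if not self.member_genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")


@dataclass
class ESResult:
    es: float
    running_sum: np.ndarray
    computable: bool = True
    reason: str = ""


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p_value: float
    n_permutations: int
    selected: bool
    computable: bool = True
    reason: str = ""


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (tab-separated: id, description,
    member genes...)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno}: need id, description, >=1 gene")
            sets.append(GeneSet(parts[0], parts[1], [g for g in parts[2:] if g]))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *s.member_genes]) + "\n")


def rank_genes(diff: list[DifferentialResult], metric: str = "signed_log2fc",
               ) -> tuple[list[str], np.ndarray]:
    """Order genes for preranked enrichment, best-scoring first.

    ``signed_log2fc`` ranks by the log2 fold change; ``signed_logp`` by
    -log10(p) carrying the fold-change sign.  Score ties break by gene
    symbol (lexical) so the ordering is strictly deterministic.  Duplicate
    symbols are an error.
    """
    if not diff:
        raise ValueError("empty differential result list")
    if metric not in RANK_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {RANK_METRICS}")
    ids = [r.feature_id for r in diff]
    dup = sorted({g for g in ids if ids.count(g) > 1})
    if dup:
        raise ValueError(f"duplicate gene symbols: {dup[:10]}")
    if metric == "signed_log2fc":
        scores = {r.feature_id: r.log2_fold_change for r in diff}
    else:
        scores = {
            r.feature_id: -np.log10(r.p_value) * np.sign(r.log2_fold_change)
            for r in diff
        }
    ordered = sorted(ids, key=lambda g: (-scores[g], g))
    return ordered, np.array([scores[g] for g in ordered], dtype=float)


def enrichment_score(ranked_genes: list[str], scores: np.ndarray,
                     gene_set: GeneSet, weight_exponent: float = 1.0) -> ESResult:
    """ES and full running-sum profile for one gene set.

    Not computable when the set does not intersect the ranked list, or
    when it spans the entire list (no outside genes to contrast against).
    """
    n = len(ranked_genes)
    members = set(gene_set.member_genes)
    hits = np.fromiter((g in members for g in ranked_genes), dtype=bool, count=n)
    n_hits = int(hits.sum())
    if n_hits == 0:
        return ESResult(float("nan"), np.zeros(n), False, "empty intersection")
    if n_hits == n:
        return ESResult(float("nan"), np.zeros(n), False,
                        "gene set spans the entire ranked list")
    running = _running_sum(scores, hits, weight_exponent)
    idx = int(np.argmax(np.abs(running)))
    return ESResult(float(running[idx]), running)


def _running_sum(scores: np.ndarray, hits: np.ndarray, p: float) -> np.ndarray:
    n = scores.size
    w = np.abs(scores) ** p if p != 0 else np.ones(n)
    hit_mass = np.where(hits, w, 0.0)
    total = hit_mass.sum()
    if total == 0:
        # all hit scores exactly zero; fall back to unweighted hit mass
        hit_mass = hits.astype(float)
        total = hit_mass.sum()
    return np.cumsum(hit_mass) / total - (np.arange(1, n + 1) / n)


def _null_es(scores: np.ndarray, n_hits: int, n_permutations: int,
             rng: np.random.Generator, p: float) -> np.ndarray:
    """ES values of size-matched random gene-label sets, vectorized."""
    n = scores.size
    w = np.abs(scores) ** p if p != 0 else np.ones(n)
    baseline = np.arange(1, n + 1) / n
    # positions of each permutation's hits: sample without replacement
    out = np.empty(n_permutations)
    block = max(1, min(n_permutations, int(2e7 / max(n, 1))))
    done = 0
    while done < n_permutations:
        m = min(block, n_permutations - done)
        mask = np.zeros((m, n), dtype=bool)
        for j in range(m):
            mask[j, rng.choice(n, size=n_hits, replace=False)] = True
        hm = np.where(mask, w[None, :], 0.0)
        totals = hm.sum(axis=1)
        totals[totals == 0] = 1.0
        running = np.cumsum(hm, axis=1) / totals[:, None] - baseline[None, :]
        idx = np.argmax(np.abs(running), axis=1)
        out[done:done + m] = running[np.arange(m), idx]
        done += m
    return out


def permutation_nes(ranked_genes: list[str], scores: np.ndarray,
                    gene_set: GeneSet, n_permutations: int = 1000,
                    seed: int = 0, weight_exponent: float = 1.0,
                    alpha: float = 0.05) -> EnrichmentResult:
    """NES and permutation p-value under a size-matched gene-label null.

    nes = es / mean(same-signed null ES);
    p = (1 + #{same-signed null with |ES| >= |es|}) / (n_same_sign + 1).
    Reproducible given ``seed``.
    """
    if n_permutations < 100:
        raise ValueError("need >= 100 permutations")
    esr = enrichment_score(ranked_genes, scores, gene_set, weight_exponent)
    if not esr.computable:
        return EnrichmentResult(gene_set.set_id, float("nan"), float("nan"), 1.0,
                                n_permutations, False, False, esr.reason)
    rng = np.random.default_rng(seed)
    n_hits = len(set(gene_set.member_genes) & set(ranked_genes))
    null = _null_es(scores, n_hits, n_permutations, rng, weight_exponent)
    es = esr.es
    same_sign = null > 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        warnings.warn(f"{gene_set.set_id}: no same-signed null scores; p = 1")
        return EnrichmentResult(gene_set.set_id, es, float("nan"), 1.0,
                                n_permutations, False)
    null_same = null[same_sign]
    nes = es / abs(float(null_same.mean()))
    p = (1 + int((np.abs(null_same) >= abs(es)).sum())) / (n_same + 1)
    selected = (abs(nes) > 1.0) and (p < alpha)
    return EnrichmentResult(gene_set.set_id, es, float(nes), float(p),
                            n_permutations, bool(selected))


def enrich_all(ranked_genes: list[str], scores: np.ndarray,
               gene_sets: list[GeneSet], n_permutations: int = 1000,
               seed: int = 0, weight_exponent: float = 1.0,
               alpha: float = 0.05) -> list[EnrichmentResult]:
    """Run the permutation test for every gene set, each with a seed
    derived deterministically from the base seed and the set's position."""
    return [
        permutation_nes(ranked_genes, scores, gs, n_permutations,
                        seed=seed + i, weight_exponent=weight_exponent,
                        alpha=alpha)
        for i, gs in enumerate(gene_sets)
    ]
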