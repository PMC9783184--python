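"""Synthetic cohorts with ground-truth bookkeeping.

Two generators emulate the statistical structure of a
well-differentiated-vs-dedifferentiated liposarcoma (WDLPS/DDLPS)
multi-omics study:

* :func:`simulate_expression` — log2-scale expression for tumor, paired
  normal, and SVF adipogenic time-course samples.  A differentiation
  program of genes follows monotone sigmoids over culture days 0-10; each
  tumor group is generated from the SVF profile of its assigned
  differentiation day plus a shared malignancy signature; normal adipose
  tissue sits at the mature (post-day-10) end of the trajectory.  Tissue
  and culture samples carry additive + multiplicative batch effects.
* :func:`simulate_lipidomics` — species-level lipid abundance tables with
  grammar-valid shorthand names and planted class-level group effects
  (neutral storage lipids TG/DG up in the WDLPS-like group; membrane
  phospholipids PC/PE/SM up in the DDLPS-like group).

Every planted perturbation is recorded in a :class:`GroundTruth` sidecar so
downstream recovery can be scored exactly.  Identical seed + config gives
bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .lipids import parse_lipid_name
from .matrix import FeatureMatrix

# -- configuration ---------------------------------------------------------


def _default_batch_effects() -> dict:
    return {"tissue": {"additive": 0.0, "scale": 1.0},
            "culture": {"additive": 2.0, "scale": 1.5}}


def _default_lipid_effects() -> dict:
    # log2 fold changes, group A (WDLPS-like) over group B (DDLPS-like)
    return {"TG": 2.0, "DG": 2.0, "PC": -2.0, "PE": -2.0, "SM": -2.0,
            "ChE": -1.0, "LPC": 0.0, "LPE": 0.0, "Cer": 0.0, "Hex1Cer": 0.0}


def _default_stages() -> dict:
    return {"WDLPS": 4, "DDLPS": 0}


@dataclass
class SimulationConfig:
    seed: int = 0
    # expression design (cohort shape mirrors the study: 6+7 tumors,
    # 13 paired normals, 3 SVF replicates per day over days 0-10)
    n_genes: int = 2000
    n_program_genes: int = 400
    days: list[int] = field(default_factory=lambda: [0, 2, 4, 6, 8, 10])
    svf_replicates: int = 3
    n_tumors: dict = field(default_factory=lambda: {"WDLPS": 6, "DDLPS": 7})
    n_normals: int = 13
    stage_assignment: dict = field(default_factory=_default_stages)
    # per-gene sigmoid timing: adipogenic programs switch on at different
    # times (early transcription factors through late lipogenic genes), so
    # each program gene draws its own midpoint/slope from these ranges
    sigmoid_midpoint_range: tuple = (0.5, 9.5)
    sigmoid_slope_range: tuple = (0.3, 0.8)
    # fraction of program genes with transient (pulse) dynamics, emulating
    # waves such as the early mitotic-clonal-expansion burst; the rest are
    # monotone sigmoids
    transient_fraction: float = 0.5
    transient_width_range: tuple = (0.8, 2.0)
    program_amplitude: tuple = (1.0, 3.0)   # |log2| range of trajectory swing
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    malignancy_genes: int = 100
    malignancy_effect: float = 1.0          # |log2| shift shared by tumors
    mature_day: float = 14.0                # where normals sit on the trajectory
    noise_sd: float = 0.5                   # per-sample log2 noise
    batch_effects: dict = field(default_factory=_default_batch_effects)
    batch_effect_gene_sd: float = 0.2       # gene-to-gene spread of the shift
    mismatch_fraction: float = 0.2          # SVF labels re-cased mouse-style
    count_mode: bool = False                # Poisson-lognormal then log2(x+1)
    # lipidomics design
    lipid_classes: dict = field(default_factory=_default_lipid_effects)
    species_per_class: int = 30
    lipid_group_sizes: dict = field(default_factory=lambda: {"WDLPS": 6, "DDLPS": 7})
    lipid_base_mean: float = 18.0           # log2 abundance of a typical species
    lipid_base_sd: float = 2.0
    lipid_noise_sd: float = 0.4

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_program_genes < 0:
            raise ValueError("gene counts must be positive")
        if self.n_program_genes > self.n_genes:
            raise ValueError("more program genes than genes")
        if sorted(self.days) != list(self.days):
            raise ValueError("days must be sorted ascending")
        for g, d in self.stage_assignment.items():
            if d not in self.days:
                raise ValueError(f"group {g!r} assigned to day {d} not in days")
        for v in (self.svf_replicates, self.n_normals, self.species_per_class):
            if v <= 0:
                raise ValueError("all replicate counts must be positive")
        for eff in self.lipid_classes.values():
            if not np.isfinite(eff):
                raise ValueError("lipid effects must be finite")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class GroundTruth:
    """Exact record of every planted perturbation (and nothing else)."""

    batch_effects: dict = field(default_factory=dict)   # batch -> gene -> {additive, scale}
    group_effects: dict = field(default_factory=dict)   # gene -> log2FC (tumor A over B)
    program_trajectory: dict = field(default_factory=dict)  # gene -> {day: value}
    malignancy_genes: dict = field(default_factory=dict)    # gene -> log2 shift
    stage_assignment: dict = field(default_factory=dict)    # group -> day
    lipid_species: dict = field(default_factory=dict)   # species -> {class, log2fc, differential}
    class_effects: dict = field(default_factory=dict)   # class -> log2fc (nonzero only)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


# -- expression ------------------------------------------------------------


def _sigmoid(day: np.ndarray | float, mid: float, slope: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(np.asarray(day, dtype=float) - mid) / slope))


def simulate_expression(config: SimulationConfig) -> tuple[FeatureMatrix, GroundTruth]:
    """Tumor + normal + SVF time-course expression with planted structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    genes = np.array([f"GENE{i + 1:05d}" for i in range(G)])
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, G)

    # differentiation program: monotone sigmoid per program gene
    prog_idx = np.arange(config.n_program_genes)
    lo, hi = config.program_amplitude
    amp = rng.uniform(lo, hi, config.n_program_genes)
    amp *= rng.choice([-1.0, 1.0], config.n_program_genes)
    mids = rng.uniform(*config.sigmoid_midpoint_range, config.n_program_genes)
    slopes = rng.uniform(*config.sigmoid_slope_range, config.n_program_genes)
    transient = rng.random(config.n_program_genes) < config.transient_fraction
    widths = rng.uniform(*config.transient_width_range, config.n_program_genes)

    def day_profile(day: float) -> np.ndarray:
        prof = baseline.copy()
        shape = np.where(
            transient,
            np.exp(-((float(day) - mids) ** 2) / (2.0 * widths ** 2)),
            _sigmoid(day, mids, slopes),
        )
        prof[prog_idx] = baseline[prog_idx] + amp * shape
        return prof

    # shared malignancy signature distinguishing tumors from the trajectory
    malig_idx = rng.choice(G, size=min(config.malignancy_genes, G), replace=False)
    malig_eff = rng.uniform(0.5, 1.0, malig_idx.size) * config.malignancy_effect
    malig_eff *= rng.choice([-1.0, 1.0], malig_idx.size)
    malig = np.zeros(G)
    malig[malig_idx] = malig_eff

    # per-batch per-gene effects
    batch_add, batch_scale = {}, {}
    for b, eff in config.batch_effects.items():
        add = float(eff.get("additive", 0.0))
        scale = float(eff.get("scale", 1.0))
        if add != 0.0:
            batch_add[b] = rng.normal(add, config.batch_effect_gene_sd, G)
        else:
            batch_add[b] = np.zeros(G)
        batch_scale[b] = scale

    cols, col_ids, meta = [], [], []

    def add_sample(sid, clean, group, batch, day=None):
        eps = rng.normal(0.0, config.noise_sd, G)
        x = clean + batch_add[batch] + batch_scale[batch] * eps
        cols.append(x)
        col_ids.append(sid)
        meta.append({"sample": sid, "group": group, "batch": batch,
                     "day": day if day is not None else ""})

    for group, n in config.n_tumors.items():
        clean = day_profile(config.stage_assignment[group]) + malig
        for j in range(n):
            add_sample(f"{group}_{j + 1:02d}", clean, group, "tissue")
    normal_clean = day_profile(config.mature_day)
    for j in range(config.n_normals):
        add_sample(f"normal_{j + 1:02d}", normal_clean, "normal", "tissue")
    for d in config.days:
        clean = day_profile(d)
        for j in range(config.svf_replicates):
            add_sample(f"SVF_d{d:02d}_{j + 1}", clean, "SVF", "culture", day=d)

    X = np.column_stack(cols)
    if config.count_mode:
        lam = np.maximum(2.0 ** X, 1e-9)
        X = np.log2(rng.poisson(lam).astype(float) + 1.0)

    values = pd.DataFrame(X, index=genes, columns=col_ids)
    # emulate mouse-style symbol casing on a fraction of SVF gene labels:
    # the matrix itself keeps one gene index, but a re-cased SVF view can be
    # produced with split_species_casing() for testing the symbol matcher
    samples = pd.DataFrame(meta).set_index("sample")
    samples["day"] = pd.to_numeric(samples["day"], errors="coerce").astype("Int64")
    fm = FeatureMatrix(values, samples)

    truth = GroundTruth(stage_assignment=dict(config.stage_assignment))
    groups = list(config.n_tumors)
    if len(groups) == 2:
        a, b = groups
        pa = day_profile(config.stage_assignment[a])
        pb = day_profile(config.stage_assignment[b])
        diff = pa - pb
        truth.group_effects = {
            genes[i]: float(diff[i]) for i in np.nonzero(diff != 0)[0]
        }
    truth.malignancy_genes = {genes[i]: float(malig[i]) for i in malig_idx}
    truth.program_trajectory = {
        genes[i]: {str(d): float(day_profile(d)[i]) for d in config.days}
        for i in prog_idx
    }
    for b in config.batch_effects:
        entries = {}
        for i in range(G):
            add = float(batch_add[b][i])
            if add != 0.0 or batch_scale[b] != 1.0:
                entries[genes[i]] = {"additive": add, "scale": batch_scale[b]}
        if entries:
            truth.batch_effects[b] = entries
    return fm, truth


def split_species_casing(fm: FeatureMatrix, config: SimulationConfig,
                         svf_group: str = "SVF") -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split into tissue and culture matrices with mouse-style casing.

    A ``mismatch_fraction`` of the culture matrix's gene symbols are
    re-cased title-style (as mouse symbols are), exercising the
    case-insensitive matcher used before joint batch correction.
    """
    rng = np.random.default_rng(config.seed + 101)
    svf_ids = fm.samples_in_group(svf_group)
    other_ids = [s for s in fm.sample_ids if s not in set(svf_ids)]
    tissue = fm.subset_samples(other_ids)
    culture = fm.subset_samples(svf_ids)
    n = culture.n_features
    k = int(round(config.mismatch_fraction * n))
    recase = set(rng.choice(n, size=k, replace=False).tolist())
    new_index = [
        (g.capitalize() if i in recase else g)
        for i, g in enumerate(culture.values.index)
    ]
    culture.values.index = pd.Index(new_index)
    return tissue, culture


def simulate_batch_study(n_genes: int = 2000, n_per_batch: int = 50,
                         additive: float = 2.0, scale: float = 1.5,
                         noise_sd: float = 0.5, gene_sd: float = 0.2,
                         seed: int = 0) -> tuple[FeatureMatrix, GroundTruth]:
    """Two-batch, one-condition benchmark for batch-effect recovery.

    Batch ``b2`` carries a per-gene additive shift drawn around
    ``additive`` and noise scaled by ``scale``; batch ``b1`` is clean.
    Batch is orthogonal to biology by construction.
    """
    rng = np.random.default_rng(seed)
    genes = np.array([f"GENE{i + 1:05d}" for i in range(n_genes)])
    baseline = rng.normal(7.0, 1.5, n_genes)
    shift = rng.normal(additive, gene_sd, n_genes)
    X1 = baseline[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_per_batch))
    X2 = (baseline[:, None] + shift[:, None]
          + scale * rng.normal(0.0, noise_sd, (n_genes, n_per_batch)))
    ids = [f"b1_{j + 1:02d}" for j in range(n_per_batch)] + \
          [f"b2_{j + 1:02d}" for j in range(n_per_batch)]
    values = pd.DataFrame(np.hstack([X1, X2]), index=genes, columns=ids)
    samples = pd.DataFrame(
        {"group": ["ctrl"] * (2 * n_per_batch),
         "batch": ["b1"] * n_per_batch + ["b2"] * n_per_batch},
        index=ids,
    )
    truth = GroundTruth(batch_effects={
        "b2": {genes[i]: {"additive": float(shift[i]), "scale": scale}
               for i in range(n_genes)}
    })
    return FeatureMatrix(values, samples), truth


# -- lipidomics ------------------------------------------------------------

_CHAIN_CARBONS = np.arange(10, 25)
_SPHINGOID_CLASSES = {"SM", "Cer", "Hex1Cer"}
_SUMMED_ONLY = {"LPC", "LPE", "ChE"}
_N_CHAINS = {"TG": 3, "DG": 2, "PC": 2, "PE": 2, "SM": 2, "Cer": 2,
             "Hex1Cer": 2, "LPC": 1, "LPE": 1, "ChE": 1}


def _make_species_name(cls: str, rng: np.random.Generator,
                       widen: int = 0) -> str:
    """One grammar-valid shorthand name of the given class.

    ``widen`` extends the chain-carbon range so classes with small name
    spaces (single-chain species) can still yield many unique names.
    """
    n_chain = _N_CHAINS.get(cls, 2)
    carbons = np.arange(10, 25 + widen)
    chains = [(int(rng.choice(carbons)), int(rng.integers(0, 7 + widen // 4)))
              for _ in range(n_chain)]
    summed = cls in _SUMMED_ONLY or (cls not in _SPHINGOID_CLASSES and rng.random() < 0.3)
    ether = cls in ("PC", "PE", "TG", "DG", "LPC", "LPE") and rng.random() < 0.4
    if cls in _SPHINGOID_CLASSES:
        prefix = "d" if rng.random() < 0.8 else "t"
        body = f"{prefix}{chains[0][0]}:{chains[0][1]}/" + \
               "/".join(f"{c}:{d}" for c, d in chains[1:])
        return f"{cls}({body})"
    if summed:
        tc = sum(c for c, _ in chains)
        td = sum(d for _, d in chains)
        return f"{cls}({tc}:{td}{'e' if ether else ''})"
    parts = [f"{c}:{d}" for c, d in chains]
    if ether:
        c, d = chains[0]
        parts[0] = f"{c}:{d}e"
    return f"{cls}({'/'.join(parts)})"


def simulate_lipidomics(config: SimulationConfig) -> tuple[FeatureMatrix, GroundTruth]:
    """Species-level lipid abundances with planted class-level group effects.

    Abundances are log-normal around class means; every species in an
    affected class carries that class's log2 group effect (group A over
    group B).  All generated names satisfy the shorthand grammar.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 7)
    groups = list(config.lipid_group_sizes)
    if len(groups) != 2:
        raise ValueError("lipidomics design needs exactly two groups")
    ga, gb = groups

    names, classes, base = [], [], []
    seen = set()
    for cls in config.lipid_classes:
        made, attempts, widen = 0, 0, 0
        while made < config.species_per_class:
            nm = _make_species_name(cls, rng, widen)
            attempts += 1
            if nm in seen:
                # widen the carbon range when the class's name space at the
                # current range is close to exhausted
                if attempts > 20 * (made + 1):
                    widen += 4
                    attempts = 0
                continue
            parse_lipid_name(nm)  # grammar conformance by construction
            seen.add(nm)
            names.append(nm)
            classes.append(cls)
            base.append(rng.normal(config.lipid_base_mean, config.lipid_base_sd))
            made += 1

    n_species = len(names)
    effects = np.array([config.lipid_classes[c] for c in classes])
    base = np.array(base)

    cols, col_ids, meta = [], [], []
    for group, n in config.lipid_group_sizes.items():
        # group A carries +effect, group B the reference level
        shift = effects if group == ga else np.zeros(n_species)
        for j in range(n):
            logv = base + shift + rng.normal(0.0, config.lipid_noise_sd, n_species)
            cols.append(2.0 ** logv)
            sid = f"{group}_L{j + 1:02d}"
            col_ids.append(sid)
            meta.append({"sample": sid, "group": group, "batch": "lipid", "day": ""})

    values = pd.DataFrame(np.column_stack(cols), index=names, columns=col_ids)
    samples = pd.DataFrame(meta).set_index("sample")
    samples["day"] = pd.to_numeric(samples["day"], errors="coerce").astype("Int64")
    fm = FeatureMatrix(values, samples)

    truth = GroundTruth()
    truth.class_effects = {c: e for c, e in config.lipid_classes.items() if e != 0.0}
    truth.lipid_species = {
        nm: {"class": c, "log2fc": float(e), "differential": bool(e != 0.0)}
        for nm, c, e in zip(names, classes, effects)
    }
    return fm, truth
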