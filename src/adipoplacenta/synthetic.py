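"""Synthetic cohort, counts and annotation generators with planted ground truth.

Emulates the study design the pipeline targets: four groups of neonates
(LELA / LEHA / OBLA / OBHA, default sizes 20/19/20/20) defined by maternal
pregravid BMI (lean vs obese) and neonatal adiposity tertile, plus middle-
tertile samples so tertile assignment is exercised.  Counts follow a
negative-binomial model, mean_gj = depth_j * baseline_g * 2^(x_j . beta_g),
variance = mu + alpha * mu^2, with adiposity effects planted in five classes:

* shared_concordant — same-sign effect in both maternal strata
* shared_discordant — opposite-sign effects across strata
* le_unique / ob_unique — effect in one stratum only
* null — no adiposity effect

Every generator is a pure function of its config (and the recorded truth), so
identical seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import (FM_BW_COEF, FM_INTERCEPT, FM_LENGTH_COEF,
                     FM_SKINFOLD_COEF, body_composition)

PLANTED_CLASSES = ("shared_concordant", "shared_discordant",
                   "le_unique", "ob_unique")

# percent-body-fat target windows per intended adiposity class; disjoint so
# the tertile split recovers the intended labels deterministically
_PFAT_WINDOWS = {"LA": (8.0, 1.2, 6.0, 9.8),
                 "MID": (12.0, 1.0, 10.2, 13.8),
                 "HA": (16.0, 1.8, 14.2, 20.0)}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Group sizes and planted effect magnitudes default to the study design the
    pipeline emulates: |log2FC| = 1.0 adiposity effects at n ~ 20 per class,
    gene-wise NB dispersion 0.1, library-size factors log-uniform on
    [0.5, 2].
    """

    n_per_group: tuple[int, int, int, int] = (20, 19, 20, 20)  # LELA/LEHA/OBLA/OBHA
    n_mid_per_stratum: tuple[int, int] = (20, 20)              # LE, OB middle tertile
    n_genes: int = 2000
    n_shared_concordant: int = 15
    n_shared_discordant: int = 15
    n_le_unique: int = 20
    n_ob_unique: int = 20
    effect_log2fc: float = 1.0
    dispersion: float = 0.1
    depth_range: tuple[float, float] = (0.5, 2.0)
    baseline_log_mean: float = math.log(150.0)
    baseline_log_sd: float = 1.0
    sex_effect_log2fc: float = 0.2
    sex_effect_fraction: float = 0.05
    annotation_fraction: float = 0.8
    n_gene_sets: int = 6
    clique_size: int = 8
    edge_density: float = 0.002
    n_cell_types: int = 8
    qpcr_slope: float = 1.0
    qpcr_intercept: float = 34.0
    qpcr_noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        n_planted = (self.n_shared_concordant + self.n_shared_discordant
                     + self.n_le_unique + self.n_ob_unique)
        if n_planted >= self.n_genes:
            raise ValueError("planted-class counts must sum to < n_genes")
        if min(self.n_shared_concordant, self.n_shared_discordant,
               self.n_le_unique, self.n_ob_unique) < 0:
            raise ValueError("planted-class counts must be non-negative")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ValueError("depth_range must be positive and ordered")
        if any(n < 0 for n in self.n_per_group):
            raise ValueError("group sizes must be non-negative")
        if not (0 < self.annotation_fraction <= 1):
            raise ValueError("annotation_fraction must lie in (0, 1]")
        return self


@dataclass
class SyntheticTruth:
    """Planted per-gene effect classes and stratum-specific true log2FCs."""

    gene_class: dict[str, str]
    log2fc_le: dict[str, float]
    log2fc_ob: dict[str, float]

    @property
    def shared_genes(self) -> list[str]:
        return [g for g, c in self.gene_class.items()
                if c in ("shared_concordant", "shared_discordant")]

    def genes_of(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]


def _truncnorm(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_anthropometrics(config: SimulationConfig) -> pd.DataFrame:
    """Generate per-sample metadata with anthropometrics and pregravid BMI.

    Birth weight, length and percent-body-fat targets are drawn per intended
    adiposity class (LA / MID / HA within each maternal stratum); the flank
    skinfold is then solved from the fat-mass equation so that the computed
    percent body fat hits its target.  HA targets occupy the top window, so
    tertile assignment within a stratum recovers the intended labels.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_lela, n_leha, n_obla, n_obha = config.n_per_group
    n_mid_le, n_mid_ob = config.n_mid_per_stratum
    plan = [("LE", "LA", n_lela), ("LE", "MID", n_mid_le), ("LE", "HA", n_leha),
            ("OB", "LA", n_obla), ("OB", "MID", n_mid_ob), ("OB", "HA", n_obha)]
    bw_params = {"LA": (2.85, 0.22), "MID": (3.3, 0.3), "HA": (3.7, 0.35)}
    len_params = {"LA": (48.0, 1.8), "MID": (49.0, 1.8), "HA": (50.0, 1.8)}
    rows = []
    idx = 0
    for stratum, cls, n in plan:
        mean, sd, lo, hi = _PFAT_WINDOWS[cls]
        pfat = _truncnorm(rng, mean, sd, lo, hi, n)
        bw = _truncnorm(rng, *bw_params[cls], 2.2, 4.8, n)
        length = _truncnorm(rng, *len_params[cls], 44.0, 55.0, n)
        if stratum == "LE":
            bmi = _truncnorm(rng, 22.3, 1.5, 18.0, 24.9, n)
        else:
            bmi = _truncnorm(rng, 34.0, 2.5, 30.0, 40.0, n)
        sex = rng.choice(["F", "M"], size=n)

        def solve_skinfold(bw_, len_):
            fm_target = pfat / 100.0 * bw_
            return (fm_target - FM_BW_COEF * bw_ - FM_LENGTH_COEF * len_
                    - FM_INTERCEPT) / FM_SKINFOLD_COEF

        # redraw weight/length where the implied skinfold leaves the
        # plausible range, so the computed %fat stays exactly on target
        skinfold = solve_skinfold(bw, length)
        for _ in range(200):
            bad = (skinfold < 0.5) | (skinfold > 20.0)
            if not bad.any():
                break
            nb = int(bad.sum())
            bw[bad] = _truncnorm(rng, *bw_params[cls], 2.2, 4.8, nb)
            length[bad] = _truncnorm(rng, *len_params[cls], 44.0, 55.0, nb)
            skinfold = solve_skinfold(bw, length)
        skinfold = np.clip(skinfold, 0.5, 20.0)
        for i in range(n):
            idx += 1
            bc = body_composition(bw[i], skinfold[i], length[i])
            rows.append({
                "sample_id": f"S{idx:03d}",
                "maternal_group": stratum,
                "adiposity_class": cls,
                "sex": sex[i],
                "birth_weight_kg": round(float(bw[i]), 4),
                "length_cm": round(float(length[i]), 2),
                "flank_skinfold_mm": round(float(skinfold[i]), 3),
                "pregravid_bmi": round(float(bmi[i]), 2),
                "pct_body_fat": bc.pct_body_fat,
            })
    return pd.DataFrame(rows)


def _plant_truth(config: SimulationConfig, gene_ids, rng) -> SyntheticTruth:
    eff = config.effect_log2fc
    gene_class = {g: "null" for g in gene_ids}
    lfc_le = {g: 0.0 for g in gene_ids}
    lfc_ob = {g: 0.0 for g in gene_ids}
    cursor = 0

    def take(n):
        nonlocal cursor
        out = gene_ids[cursor:cursor + n]
        cursor += n
        return out

    for g in take(config.n_shared_concordant):
        sign = rng.choice([-1.0, 1.0])
        gene_class[g] = "shared_concordant"
        lfc_le[g] = lfc_ob[g] = sign * eff
    for g in take(config.n_shared_discordant):
        sign = rng.choice([-1.0, 1.0])
        gene_class[g] = "shared_discordant"
        lfc_le[g], lfc_ob[g] = sign * eff, -sign * eff
    for g in take(config.n_le_unique):
        gene_class[g] = "le_unique"
        lfc_le[g] = rng.choice([-1.0, 1.0]) * eff
    for g in take(config.n_ob_unique):
        gene_class[g] = "ob_unique"
        lfc_ob[g] = rng.choice([-1.0, 1.0]) * eff
    return SyntheticTruth(gene_class, lfc_le, lfc_ob)


def simulate_counts(config: SimulationConfig,
                    metadata: pd.DataFrame | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Draw a negative-binomial count matrix with planted adiposity effects.

    Returns (counts, metadata, truth).  The adiposity covariate is 1 for HA,
    0 for LA and 0.5 for middle-tertile samples; a sex effect of
    ``sex_effect_log2fc`` is planted on a random ``sex_effect_fraction`` of
    genes so the sex covariate in downstream models is non-degenerate.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    if metadata is None:
        metadata = simulate_anthropometrics(config)
    gene_ids = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    truth = _plant_truth(config, gene_ids, rng)

    n_samples = len(metadata)
    x_adip = metadata["adiposity_class"].map(
        {"LA": 0.0, "MID": 0.5, "HA": 1.0}).to_numpy()
    x_sex = (metadata["sex"] == "M").to_numpy(float)
    is_ob = (metadata["maternal_group"] == "OB").to_numpy()

    lo, hi = config.depth_range
    depth = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))
    baseline = np.exp(rng.normal(config.baseline_log_mean,
                                 config.baseline_log_sd, size=config.n_genes))
    beta_le = np.array([truth.log2fc_le[g] for g in gene_ids])
    beta_ob = np.array([truth.log2fc_ob[g] for g in gene_ids])
    n_sex = int(round(config.sex_effect_fraction * config.n_genes))
    sex_beta = np.zeros(config.n_genes)
    if n_sex:
        sex_idx = rng.choice(config.n_genes, size=n_sex, replace=False)
        sex_beta[sex_idx] = config.sex_effect_log2fc * rng.choice(
            [-1.0, 1.0], size=n_sex)

    beta = np.where(is_ob[None, :], beta_ob[:, None], beta_le[:, None])
    log2_mu = (np.log2(baseline)[:, None] + np.log2(depth)[None, :]
               + beta * x_adip[None, :] + sex_beta[:, None] * x_sex[None, :])
    mu = np.exp2(log2_mu)

    alpha = config.dispersion
    if alpha < 1e-6:
        counts = rng.poisson(mu)
    else:
        # NB via gamma-Poisson mixture: shape 1/alpha, mean mu
        shape = 1.0 / alpha
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=gene_ids,
                             columns=metadata["sample_id"].tolist())
    counts_df.index.name = "gene_id"
    return counts_df, metadata, truth


def simulate_annotation(config: SimulationConfig, truth: SyntheticTruth,
                        ) -> dict[str, set[str]]:
    """Build a GMT-style gene-set collection with one designated set enriched
    for the planted shared genes (a stated fraction of them plus background),
    alongside random background sets."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    genes = np.array(sorted(truth.gene_class))
    shared = truth.shared_genes
    sets: dict[str, set[str]] = {}
    if shared:
        k = max(1, int(round(config.annotation_fraction * len(shared))))
        members = set(rng.choice(shared, size=k, replace=False))
        n_bg = max(5, len(shared) // 2)
        members |= set(rng.choice(genes, size=n_bg, replace=False))
        sets["PLANTED_SHARED_RESPONSE"] = members
    n_random = max(config.n_gene_sets - len(sets), 5)
    for i in range(n_random):
        size = int(rng.integers(10, 60))
        sets[f"RANDOM_SET_{i + 1:02d}"] = set(
            rng.choice(genes, size=size, replace=False))
    return sets


def simulate_network(config: SimulationConfig, truth: SyntheticTruth,
                     ) -> pd.DataFrame:
    """Interaction edge list (node1, node2, combined_score) with a planted
    clique among shared planted genes plus random background edges at the
    configured density."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes = sorted(truth.gene_class)
    shared = truth.shared_genes
    if config.clique_size > len(shared):
        raise ValueError(
            f"clique_size {config.clique_size} exceeds the "
            f"{len(shared)} shared planted genes")
    clique = list(rng.choice(shared, size=config.clique_size, replace=False))
    edges = set()
    rows = []
    for i in range(len(clique)):
        for j in range(i + 1, len(clique)):
            a, b = sorted((clique[i], clique[j]))
            edges.add((a, b))
            rows.append((a, b, int(rng.integers(850, 999))))
    n_genes = len(genes)
    n_bg = int(round(config.edge_density * n_genes * (n_genes - 1) / 2))
    while n_bg > 0:
        i, j = rng.integers(0, n_genes, size=2)
        if i == j:
            continue
        a, b = sorted((genes[int(i)], genes[int(j)]))
        if (a, b) in edges:
            continue
        edges.add((a, b))
        rows.append((a, b, int(rng.integers(400, 999))))
        n_bg -= 1
    return pd.DataFrame(rows, columns=["node1", "node2", "combined_score"])


def simulate_reference(config: SimulationConfig, truth: SyntheticTruth,
                       designated_type: str = "Neutrophil") -> pd.DataFrame:
    """Cell-type x gene reference expression matrix in which one designated
    cell type expresses the planted shared genes at a strongly elevated level."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    genes = sorted(truth.gene_class)
    base_types = ["Cytotrophoblast", "Syncytiotrophoblast",
                  "Extravillous_trophoblast", "Hofbauer_cell", "Fibroblast",
                  "Endothelial_cell", "T_cell", "Monocyte", "B_cell", "NK_cell"]
    types = base_types[:max(config.n_cell_types - 1, 1)] + [designated_type]
    expr = np.exp(rng.normal(1.0, 1.0, size=(len(types), len(genes))))
    shared_idx = [genes.index(g) for g in truth.shared_genes]
    if shared_idx:
        expr[-1, shared_idx] *= 50.0
    ref = pd.DataFrame(expr, index=types, columns=genes)
    ref.index.name = "cell_type"
    return ref


def simulate_qpcr(config: SimulationConfig, counts: pd.DataFrame,
                  target_genes: list[str] | None = None,
                  reference_gene: str = "RPL17",
                  samples: list[str] | None = None) -> pd.DataFrame:
    """Emit a long-format Ct table for target genes plus a reference gene.

    Ct for a target is ``a - b * log2(normalized count + 1)`` plus Gaussian
    noise, so lower Ct tracks higher expression; the reference gene's Ct is
    independent of adiposity.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    if target_genes is None:
        target_genes = list(counts.index[:2])
    missing = [g for g in target_genes if g not in counts.index]
    if missing:
        raise ValueError(f"target genes absent from counts: {missing}")
    samples = list(samples or counts.columns)
    # depth-normalize by library-size ratio (qPCR emulation only needs a
    # monotone link to expression, not full median-of-ratios)
    libsize = counts[samples].sum(axis=0).to_numpy(float)
    sf = libsize / np.exp(np.mean(np.log(libsize)))
    rows = []
    for g in target_genes:
        norm = counts.loc[g, samples].to_numpy(float) / sf
        ct = (config.qpcr_intercept - config.qpcr_slope * np.log2(norm + 1.0)
              + rng.normal(0.0, config.qpcr_noise_sd, size=len(samples)))
        rows += [{"sample_id": s, "gene": g, "ct": float(c)}
                 for s, c in zip(samples, ct)]
    ref_ct = 22.0 + rng.normal(0.0, config.qpcr_noise_sd, size=len(samples))
    rows += [{"sample_id": s, "gene": reference_gene, "ct": float(c)}
             for s, c in zip(samples, ref_ct)]
    return pd.DataFrame(rows)


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A reduced configuration for fast tests: same design, fewer genes."""
    base = dict(n_genes=300, n_shared_concordant=10, n_shared_discordant=10,
                n_le_unique=10, n_ob_unique=10, clique_size=6,
                edge_density=0.01, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)
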