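"""Neonatal body composition, adiposity tertiles, study groups, cohort summary.

Neonatal fat mass is predicted from birth weight, flank skinfold and length by
a validated anthropometric regression; lean mass and percent body fat follow by
identity.  Within each maternal pregravid-BMI category (lean, 18-24.9; obese,
30-40) neonates are ranked into tertiles of percent body fat, and the first
(low adiposity, LA) and third (high adiposity, HA) tertiles define the four
study groups LELA / LEHA / OBLA / OBHA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

# Coefficients of the neonatal fat-mass prediction equation (kg).
FM_BW_COEF = 0.39055      # per kg birth weight
FM_SKINFOLD_COEF = 0.0453  # per mm flank skinfold
FM_LENGTH_COEF = -0.03237  # per cm length
FM_INTERCEPT = 0.54657

LEAN_BMI_RANGE = (18.0, 24.9)
OBESE_BMI_RANGE = (30.0, 40.0)


@dataclass(frozen=True)
class BodyComposition:
    """Fat mass, lean mass and percent body fat for one neonate.

    Lean mass is birth weight minus fat mass, exactly; percent body fat is
    ``fat_mass / birth_weight * 100``.
    """

    fat_mass_kg: float
    lean_mass_kg: float
    pct_body_fat: float


@dataclass(frozen=True)
class GroupAssignment:
    sample_id: str
    bmi_category: str      # LE | OB | EXCLUDED
    adiposity_tertile: str  # T1 | T2 | T3
    study_group: str       # LELA | LEHA | OBLA | OBHA | NONE


def fat_mass(birth_weight_kg: float, flank_skinfold_mm: float,
             length_cm: float) -> float:
    """Predicted neonatal fat mass (kg) from the anthropometric equation."""
    for name, v in (("birth_weight_kg", birth_weight_kg),
                    ("flank_skinfold_mm", flank_skinfold_mm),
                    ("length_cm", length_cm)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    return (FM_BW_COEF * birth_weight_kg
            + FM_SKINFOLD_COEF * flank_skinfold_mm
            + FM_LENGTH_COEF * length_cm
            + FM_INTERCEPT)


def body_composition(birth_weight_kg: float, flank_skinfold_mm: float,
                     length_cm: float) -> BodyComposition:
    """Fat mass, lean mass and percent body fat for one neonate.

    Raises ValueError on non-finite inputs or non-positive birth weight
    (percent body fat is undefined without a positive denominator).
    """
    fm = fat_mass(birth_weight_kg, flank_skinfold_mm, length_cm)
    if birth_weight_kg <= 0:
        raise ValueError("birth_weight_kg must be positive for percent body fat")
    lbm = birth_weight_kg - fm
    pfat = fm / birth_weight_kg * 100.0
    return BodyComposition(fat_mass_kg=fm, lean_mass_kg=lbm, pct_body_fat=pfat)


def lean_mass(birth_weight_kg: float, fat_mass_kg: float) -> float:
    """Lean (fat-free) mass: birth weight minus fat mass, by definition."""
    return birth_weight_kg - fat_mass_kg


def assign_tertiles(pct_body_fat: pd.Series) -> pd.Series:
    """Rank samples of one BMI category into adiposity tertiles T1/T2/T3.

    The n samples are ranked by percent body fat (ties broken by the stable
    index order) and split into groups of sizes ceil(n/3) (T1, lowest),
    ceil((n - n1)/2) (T2), and the remainder (T3, highest).  If every value is
    identical no ordering is meaningful and all samples are labelled T2, which
    excludes them from the LA/HA contrast.

    Parameters
    ----------
    pct_body_fat : Series indexed by sample id.

    Returns
    -------
    Series of labels "T1"/"T2"/"T3" with the same index.
    """
    s = pd.Series(pct_body_fat)
    n = len(s)
    if n < 3:
        raise ValueError(f"need at least 3 samples to form tertiles, got {n}")
    if s.isna().any():
        raise ValueError("percent body fat contains missing values")
    if s.nunique() == 1:
        return pd.Series("T2", index=s.index)
    n1 = math.ceil(n / 3)
    n2 = math.ceil((n - n1) / 2)
    # mergesort is stable: ties keep input (sample-id) order
    order = np.argsort(s.to_numpy(), kind="mergesort")
    labels = np.empty(n, dtype=object)
    labels[order[:n1]] = "T1"
    labels[order[n1:n1 + n2]] = "T2"
    labels[order[n1 + n2:]] = "T3"
    return pd.Series(labels, index=s.index)


def bmi_category(pregravid_bmi: float) -> str:
    """LE for BMI in [18, 24.9], OB for [30, 40], else EXCLUDED."""
    if pregravid_bmi is None or not math.isfinite(pregravid_bmi):
        raise ValueError("pregravid BMI is missing or non-finite")
    if LEAN_BMI_RANGE[0] <= pregravid_bmi <= LEAN_BMI_RANGE[1]:
        return "LE"
    if OBESE_BMI_RANGE[0] <= pregravid_bmi <= OBESE_BMI_RANGE[1]:
        return "OB"
    return "EXCLUDED"


def assign_groups(metadata: pd.DataFrame) -> pd.DataFrame:
    """Assign BMI category, adiposity tertile and study group per sample.

    Requires columns ``sample_id``, ``pregravid_bmi`` and either
    ``pct_body_fat`` or the three anthropometrics needed to compute it.
    Tertiles are computed within each BMI category (EXCLUDED samples are not
    ranked).  Study group is the BMI label crossed with T1 -> LA / T3 -> HA;
    middle-tertile and excluded samples get study_group NONE.
    """
    md = metadata.copy()
    if "pct_body_fat" not in md.columns:
        md["pct_body_fat"] = [
            body_composition(bw, sf, ln).pct_body_fat
            for bw, sf, ln in zip(md["birth_weight_kg"],
                                  md["flank_skinfold_mm"], md["length_cm"])
        ]
    if md["pregravid_bmi"].isna().any():
        bad = md.loc[md["pregravid_bmi"].isna(), "sample_id"].tolist()
        raise ValueError(f"missing pregravid BMI for samples {bad}")
    md = md.set_index("sample_id", drop=False)
    md["bmi_category"] = md["pregravid_bmi"].map(bmi_category)
    md["adiposity_tertile"] = "T2"
    for cat in ("LE", "OB"):
        mask = md["bmi_category"] == cat
        if mask.sum() >= 3:
            md.loc[mask, "adiposity_tertile"] = assign_tertiles(
                md.loc[mask, "pct_body_fat"])
    tert_to_class = {"T1": "LA", "T3": "HA"}
    groups = []
    for cat, tert in zip(md["bmi_category"], md["adiposity_tertile"]):
        cls = tert_to_class.get(tert)
        groups.append(cat + cls if cat in ("LE", "OB") and cls else "NONE")
    md["study_group"] = groups
    md["adiposity_class"] = [tert_to_class.get(t, "MID")
                             for t in md["adiposity_tertile"]]
    return md.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Cohort summary table (two-way ANOVA, Tukey letters, Fisher exact)
# ---------------------------------------------------------------------------

def _compact_letter_display(levels, nonsig) -> dict:
    """Compact letter display: levels sharing a letter are not significantly
    different.  `nonsig` is a set of frozensets of level pairs that are NOT
    significantly different.  Insert-and-absorb algorithm."""
    groups: list[set] = []
    for lv in levels:
        placed = False
        for g in groups:
            if all(frozenset((lv, other)) in nonsig for other in g):
                g.add(lv)
                placed = True
        if not placed:
            groups.append({lv})
    # absorb subsets
    groups = [g for i, g in enumerate(groups)
              if not any(g < h for j, h in enumerate(groups) if i != j)]
    letters = {lv: "" for lv in levels}
    for letter, g in zip("ABCDEFGH", groups):
        for lv in sorted(g):
            letters[lv] += letter
    return {lv: "".join(sorted(letters[lv])) for lv in levels}


def fisher_exact_rxc(table: np.ndarray) -> float:
    """Two-sided exact test of independence for a small r x c contingency
    table (Freeman-Halton): the p-value sums the null probabilities of every
    table with the observed margins whose probability does not exceed the
    observed table's.

    Enumeration is exponential in table size; intended for the cohort-scale
    tables this module produces (2 x 4 with n < 100 or so).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a 2-D non-negative integer array")
    if table.shape[0] == 2 and table.shape[1] == 2:
        return float(stats.fisher_exact(table)[1])
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    n = int(table.sum())
    if n == 0:
        return 1.0

    from math import lgamma

    def lfact(x):
        return lgamma(x + 1)

    const = sum(lfact(r) for r in row_m) + sum(lfact(c) for c in col_m) - lfact(n)

    def log_prob(t):
        return const - sum(lfact(v) for v in t.flat)

    obs_lp = log_prob(table)
    r, c = table.shape
    p_total = 0.0

    # recursive enumeration over cells, constraining margins
    def rec(i, j, t, row_rem, col_rem):
        nonlocal p_total
        if i == r - 1:
            # last row forced by column remainders
            t[i, :] = col_rem
            if (t[i, :] >= 0).all():
                lp = log_prob(t)
                if lp <= obs_lp + 1e-9:
                    p_total += math.exp(lp)
            return
        if j == c - 1:
            v = row_rem[i]
            if 0 <= v <= col_rem[j]:
                t[i, j] = v
                col_rem2 = col_rem.copy()
                col_rem2[j] -= v
                row_rem2 = row_rem.copy()
                row_rem2[i] = 0
                rec(i + 1, 0, t, row_rem2, col_rem2)
            return
        hi = min(row_rem[i], col_rem[j])
        for v in range(hi + 1):
            t[i, j] = v
            col_rem2 = col_rem.copy()
            col_rem2[j] -= v
            row_rem2 = row_rem.copy()
            row_rem2[i] -= v
            rec(i, j + 1, t, row_rem2, col_rem2)

    rec(0, 0, np.zeros_like(table), row_m.copy(), col_m.copy())
    return float(min(1.0, p_total))


def cohort_table(metadata: pd.DataFrame, continuous: list[str],
                 categorical: list[str] | None = None) -> pd.DataFrame:
    """Summarize cohort variables over the 2 x 2 design (maternal BMI category
    x neonatal adiposity class).

    For each continuous variable: per-cell n and mean +/- SD, two-way ANOVA
    p-values for the maternal-obesity main effect, the adiposity main effect
    and their interaction (partial, type-II sums of squares — the design is
    unbalanced), and Tukey-HSD grouping letters across the four cells.  For
    each categorical variable: per-cell percentages and a Fisher exact p
    across the four groups.

    `metadata` needs columns ``maternal_group`` (LE/OB), ``adiposity_class``
    (LA/HA) and the named variables; MID samples should be dropped upstream.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    md = metadata[metadata["adiposity_class"].isin(["LA", "HA"])].copy()
    md["cell"] = md["maternal_group"] + md["adiposity_class"]
    cells = ["LELA", "LEHA", "OBLA", "OBHA"]
    for cell in cells:
        if (md["cell"] == cell).sum() == 0:
            raise ValueError(f"empty design cell {cell}")

    rows = []
    for var in continuous:
        sub = md[["cell", "maternal_group", "adiposity_class", var]].dropna()
        row: dict = {"variable": var, "kind": "continuous"}
        for cell in cells:
            vals = sub.loc[sub["cell"] == cell, var]
            row[f"{cell}_n"] = int(len(vals))
            row[f"{cell}_mean"] = float(vals.mean())
            row[f"{cell}_sd"] = float(vals.std(ddof=1))
        within_var = sub.groupby("cell")[var].var(ddof=1)
        if (within_var.fillna(0.0) == 0).all():
            raise ValueError(
                f"{var}: zero within-cell variance in every cell; "
                "ANOVA is degenerate")
        d = sub.rename(columns={var: "y"})
        model = smf.ols(
            "y ~ C(maternal_group) * C(adiposity_class)", data=d).fit()
        aov = sm.stats.anova_lm(model, typ=2)
        row["p_ob"] = float(aov.loc["C(maternal_group)", "PR(>F)"])
        row["p_ha"] = float(aov.loc["C(adiposity_class)", "PR(>F)"])
        row["p_interaction"] = float(
            aov.loc["C(maternal_group):C(adiposity_class)", "PR(>F)"])
        tuk = pairwise_tukeyhsd(sub[var].to_numpy(), sub["cell"].to_numpy())
        nonsig = set()
        res = tuk.summary().data[1:]
        for line in res:
            g1, g2, reject = str(line[0]), str(line[1]), bool(line[6])
            if not reject:
                nonsig.add(frozenset((g1, g2)))
        letters = _compact_letter_display(cells, nonsig)
        for cell in cells:
            row[f"{cell}_letter"] = letters[cell]
        rows.append(row)

    for var in (categorical or []):
        sub = md[["cell", var]].dropna()
        row = {"variable": var, "kind": "categorical"}
        ct = pd.crosstab(sub[var], sub["cell"]).reindex(columns=cells,
                                                        fill_value=0)
        for cell in cells:
            tot = ct[cell].sum()
            top = ct[cell].iloc[-1] if len(ct) else 0
            row[f"{cell}_n"] = int(tot)
            row[f"{cell}_pct"] = float(100.0 * top / tot) if tot else float("nan")
        row["p_fisher"] = fisher_exact_rxc(ct.to_numpy())
        rows.append(row)

    return pd.DataFrame(rows)
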