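"""Closed-form renal quantifications and group-comparison statistics.

Small, exactly specified formulas used downstream of the peptidome pipeline:

* Weibel stereological glomerular volume from a 2-D profile area:
  ``V = A^1.5 * 1.38 / 1.01`` (1.38 = sphere shape coefficient, 1.01 = size
  distribution coefficient);
* qPCR relative expression with genomic-DNA contamination correction:
  ``2^(Ct_GAPDH - Ct_gene) * (1 - 2^-(Ct_RT- - Ct_gene))``, the bracket
  collapsing to 1 when no RT- signal is observed;
* urinary albumin/creatinine ratio in mg/g;
* stained-area fractions in percent;
* two-way ANOVA (age x treatment, Type-II sums of squares for unbalanced
  designs) with Tukey HSD over the cell means, flagged at the conventional
  */**/*** levels;
* start/stop consistency checks for annotated peptide fragments, where a
  lowercase letter denotes one modified residue (e.g. hydroxyproline ``p``,
  oxidized methionine ``m``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import AnalysisError, ValidationError

WEIBEL_SHAPE_COEFF = 1.38
WEIBEL_SIZE_DIST_COEFF = 1.01


def glomerular_volume(area_um2):
    """Weibel estimate of glomerular volume [um^3] from profile area [um^2]."""
    area = np.asarray(area_um2, dtype=float)
    if np.any(area < 0):
        raise ValidationError(f"area must be >= 0, got {area_um2!r}")
    vol = area**1.5 * WEIBEL_SHAPE_COEFF / WEIBEL_SIZE_DIST_COEFF
    return float(vol) if np.isscalar(area_um2) else vol


def mean_glomerular_volume(areas_um2, aggregate: str = "mean_of_volumes") -> float:
    """Per-animal summary over all glomeruli measured on a slide.

    ``mean_of_volumes`` (default) averages per-glomerulus volumes;
    ``volume_of_mean`` applies the formula to the mean area instead.
    """
    areas = np.asarray(areas_um2, dtype=float)
    if areas.size == 0:
        raise ValidationError("no glomerulus areas given")
    if aggregate == "mean_of_volumes":
        return float(np.mean(glomerular_volume(areas)))
    if aggregate == "volume_of_mean":
        return float(glomerular_volume(float(areas.mean())))
    raise ValidationError(f"unknown aggregate {aggregate!r}")


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct triple for one sample; ``ct_rt_minus`` None = no contamination signal."""

    ct_gene: float
    ct_gapdh: float
    ct_rt_minus: float | None = None

    def __post_init__(self) -> None:
        if not self.ct_gene > 0 or not self.ct_gapdh > 0:
            raise ValidationError("Ct values must be > 0")
        if self.ct_rt_minus is not None:
            if not self.ct_rt_minus > 0:
                raise ValidationError("Ct values must be > 0")
            if self.ct_rt_minus < self.ct_gene:
                raise ValidationError(
                    f"ct_rt_minus ({self.ct_rt_minus}) < ct_gene ({self.ct_gene}): "
                    "contamination cannot exceed total signal"
                )


def qpcr_expression(m: QpcrMeasurement) -> float:
    """GAPDH-normalized relative expression with RT- contamination correction."""
    base = 2.0 ** (m.ct_gapdh - m.ct_gene)
    if m.ct_rt_minus is None or math.isinf(m.ct_rt_minus):
        bracket = 1.0
    else:
        bracket = 1.0 - 2.0 ** -(m.ct_rt_minus - m.ct_gene)
    return base * bracket


def qpcr_expression_table(table: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`qpcr_expression` over (ct_gene, ct_gapdh, ct_rt_minus) rows."""
    out = []
    for _, row in table.iterrows():
        rt = row.get("ct_rt_minus")
        rt = None if rt is None or (isinstance(rt, float) and math.isnan(rt)) else float(rt)
        out.append(
            qpcr_expression(
                QpcrMeasurement(float(row["ct_gene"]), float(row["ct_gapdh"]), rt)
            )
        )
    return pd.Series(out, index=table.index, name="expression")


def albumin_creatinine_ratio(albumin_mg_per_l, creatinine_g_per_l):
    """Urinary albumin/creatinine ratio [mg/g]."""
    alb = np.asarray(albumin_mg_per_l, dtype=float)
    crea = np.asarray(creatinine_g_per_l, dtype=float)
    if np.any(crea <= 0):
        raise ValidationError("creatinine must be > 0")
    if np.any(alb < 0):
        raise ValidationError("albumin must be >= 0")
    out = alb / crea
    return float(out) if np.isscalar(albumin_mg_per_l) else out


def area_fraction(stained_area, reference_area):
    """Stained area as percent of the reference compartment area."""
    s = np.asarray(stained_area, dtype=float)
    r = np.asarray(reference_area, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("reference area must be > 0")
    if np.any(s < 0) or np.any(s > r):
        raise ValidationError("stained area must satisfy 0 <= stained <= reference")
    out = 100.0 * s / r
    return float(out) if np.isscalar(stained_area) else out


# ---------------------------------------------------------------------------
# Two-way ANOVA + Tukey
# ---------------------------------------------------------------------------


@dataclass
class AnovaTable:
    """Two-way ANOVA summary plus Tukey pairwise contrasts of cell means."""

    anova: pd.DataFrame       # rows: age, treatment, age:treatment, Residual
    tukey: pd.DataFrame       # group1, group2, meandiff, p_adj, reject, stars
    alpha: float


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def two_way_anova_tukey(
    values: Sequence[float],
    age_labels: Sequence[str],
    treatment_labels: Sequence[str],
    alpha: float = 0.05,
    include_tukey: bool = True,
) -> AnovaTable:
    """Age x treatment ANOVA with interaction, then Tukey HSD on cell means.

    Uses Type-II sums of squares so unbalanced designs are handled; with a
    zero-residual fit the convention F = 0, p = 1 applies to null effects and
    F = inf, p = 0 to non-null ones.  Requires >= 2 levels per factor and a
    non-empty value in every age x treatment cell (>= 2 values per cell for
    the interaction term).
    """
    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "age": list(age_labels),
            "treatment": list(treatment_labels),
        }
    )
    if df["age"].nunique() < 2 or df["treatment"].nunique() < 2:
        raise AnalysisError("need >= 2 levels for both age and treatment")
    counts = df.groupby(["age", "treatment"], observed=True).size()
    for a in df["age"].unique():
        for t in df["treatment"].unique():
            if (a, t) not in counts.index:
                raise AnalysisError(f"empty design cell (age={a!r}, treatment={t!r})")
    model = ols("value ~ C(age) * C(treatment)", data=df).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(age)": "age",
            "C(treatment)": "treatment",
            "C(age):C(treatment)": "age:treatment",
        }
    )
    # degenerate-fit conventions: constant data is null everywhere; a
    # zero-residual fit with a real effect is maximally significant
    resid_ss = float(table.loc["Residual", "sum_sq"])
    scale = max(float(np.abs(df["value"]).max()) ** 2, 1.0)
    constant = np.ptp(df["value"].to_numpy()) == 0
    for row in table.index:
        if row == "Residual":
            continue
        if constant:
            table.loc[row, "F"], table.loc[row, "PR(>F)"] = 0.0, 1.0
            continue
        f = table.loc[row, "F"]
        if not np.isfinite(f):
            if resid_ss <= 1e-12 * scale:
                if table.loc[row, "sum_sq"] <= 1e-12 * scale:
                    table.loc[row, "F"], table.loc[row, "PR(>F)"] = 0.0, 1.0
                else:
                    table.loc[row, "F"], table.loc[row, "PR(>F)"] = np.inf, 0.0
    cell = (df["age"].astype(str) + "/" + df["treatment"].astype(str)).to_numpy()
    cells = sorted(set(cell))
    pairs = [(a, b) for i, a in enumerate(cells) for b in cells[i + 1:]]
    if not include_tukey:
        tukey = pd.DataFrame(
            columns=["group1", "group2", "meandiff", "p_adj", "reject", "stars"]
        )
        return AnovaTable(anova=table, tukey=tukey, alpha=alpha)
    if np.ptp(df["value"].to_numpy()) == 0:
        tukey = pd.DataFrame(
            {
                "group1": [p[0] for p in pairs],
                "group2": [p[1] for p in pairs],
                "meandiff": 0.0,
                "p_adj": 1.0,
                "reject": False,
            }
        )
    else:
        res = pairwise_tukeyhsd(df["value"].to_numpy(), cell, alpha=alpha)
        from itertools import combinations

        groups = [str(g) for g in res.groupsunique]
        tukey = pd.DataFrame(
            {
                "group1": [a for a, _ in combinations(groups, 2)],
                "group2": [b for _, b in combinations(groups, 2)],
                "meandiff": np.asarray(res.meandiffs, dtype=float),
                "p_adj": np.asarray(res.pvalues, dtype=float),
                "reject": np.asarray(res.reject, dtype=bool),
            }
        )
    tukey["stars"] = [significance_stars(float(p)) for p in tukey["p_adj"]]
    return AnovaTable(anova=table, tukey=tukey, alpha=alpha)


# ---------------------------------------------------------------------------
# Peptide annotation consistency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeptideAnnotation:
    """A sequenced peptide fragment mapped onto its parent protein.

    ``sequence`` uses one character per residue; lowercase marks a modified
    residue (hydroxyproline ``p``, oxidized methionine ``m``).  ``start_aa``
    and ``stop_aa`` are 1-based positions in the parent protein.
    """

    peptide_id: str
    sequence: str
    accession: str
    protein_name: str
    start_aa: int
    stop_aa: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("sequence must be non-empty")
        if self.start_aa < 1:
            raise ValidationError(f"start_aa must be >= 1, got {self.start_aa}")


def validate_annotation(ann: PeptideAnnotation) -> tuple[int, bool]:
    """Recompute the stop position from sequence length; check consistency.

    Returns ``(computed_stop, consistent)`` with
    ``computed_stop = start_aa + len(sequence) - 1``.
    """
    computed = ann.start_aa + len(ann.sequence) - 1
    return computed, computed == ann.stop_aa


def load_reference_annotations() -> list[PeptideAnnotation]:
    """The 12 sequenced peptides of the published mouse urinary aging panel."""
    text = (
        resources.files("pepage").joinpath("data/aging_panel_annotations.tsv")
        .read_text(encoding="utf-8")
    )
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    out = []
    for line in lines[1:]:
        row = dict(zip(header, line.split("\t")))
        out.append(
            PeptideAnnotation(
                peptide_id=row["peptide_id"],
                sequence=row["sequence"],
                accession=row["accession"],
                protein_name=row["protein_name"],
                start_aa=int(row["start_aa"]),
                stop_aa=int(row["stop_aa"]),
            )
        )
    return out
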