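"""Elicitor time-course analytics.

Fold changes against the 0 h control, regulation-class calls (up / down /
mixed / excluded), comparative-Ct (ddCt) quantification, RNA-seq vs qPCR
concordance, and one-way ANOVA with Tukey HSD follow-up at a configurable
alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import parse_sample_column

__all__ = [
    "FoldChangeResult",
    "fold_change",
    "classify_regulation",
    "ddct",
    "concordance",
    "anova_tukey",
    "AnovaTukeyResult",
]


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-gene, per-timepoint fold change (treatment/control) and its ln.

    ``fold`` and ``ln_fold`` are genes x timepoints; ``excluded`` lists genes
    with a missing timepoint mean or a non-positive 0 h mean (their rows are
    NaN).  The 0 h column is identically 1 (ln 0) for retained genes.
    """

    fold: pd.DataFrame
    ln_fold: pd.DataFrame
    excluded: tuple[str, ...]

    @property
    def timepoints(self) -> tuple[float, ...]:
        return tuple(self.fold.columns)


def timepoint_means(expr: pd.DataFrame) -> pd.DataFrame:
    """Average replicates: genes x timepoints arithmetic means.

    A timepoint mean is NaN if any replicate is missing (an undetectable
    signal at that timepoint disqualifies the gene downstream).
    """
    tps = [parse_sample_column(c)[0] for c in expr.columns]
    grouped = expr.T.groupby(pd.Index(tps, name="timepoint_h"))
    means = grouped.mean().T
    has_nan = grouped.apply(lambda g: g.isna().any()).T
    return means.mask(has_nan)


def fold_change(expr: pd.DataFrame) -> FoldChangeResult:
    """Fold change per gene and timepoint versus the 0 h control.

    fold(g, t) = mean abundance of g at t / mean at 0 h, replicates averaged
    arithmetically.  Genes with a zero/missing 0 h mean or any missing
    timepoint are flagged excluded rather than raising.
    """
    means = timepoint_means(expr)
    if 0.0 not in means.columns:
        raise ValueError("expression matrix has no 0 h control columns")
    control = means[0.0]
    bad = means.isna().any(axis=1) | ~(control > 0)
    fold = means.div(control, axis=0)
    fold.loc[bad] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        ln_fold = np.log(fold)
    return FoldChangeResult(
        fold=fold, ln_fold=ln_fold, excluded=tuple(means.index[bad])
    )


def classify_regulation(fc: FoldChangeResult, min_fold: float = 1.0) -> pd.Series:
    """One call per gene: excluded / up / down / mixed.

    ``up`` requires fold > min_fold at every post-treatment timepoint,
    ``down`` fold < 1/min_fold at every one; anything else (detected but
    direction-inconsistent) is ``mixed``.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    post = [t for t in fc.fold.columns if t > 0]
    if not post:
        raise ValueError("no post-treatment timepoints")
    calls = {}
    for gene, row in fc.fold.iterrows():
        if gene in fc.excluded:
            calls[gene] = "excluded"
        elif (row[post] > min_fold).all():
            calls[gene] = "up"
        elif (row[post] < 1.0 / min_fold).all():
            calls[gene] = "down"
        else:
            calls[gene] = "mixed"
    return pd.Series(calls, name="regulation")


# ---------------------------------------------------------------------------
# comparative Ct


def plot_ln_fold_heatmap(fc: FoldChangeResult, path) -> None:
    """Genes x timepoints heatmap of ln fold changes; excluded genes gray."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = fc.ln_fold.to_numpy()
    fig, ax = plt.subplots(figsize=(6, max(2, 0.12 * len(data))))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.6")  # gray = excluded / undetectable
    vmax = np.nanmax(np.abs(data)) or 1.0
    im = ax.imshow(data, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]), [f"{t:g} h" for t in fc.fold.columns])
    ax.set_yticks([])
    ax.set_xlabel("time post elicitation")
    fig.colorbar(im, ax=ax, label="ln(fold change vs 0 h)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def ddct(ct: pd.DataFrame, efficiency: float = 2.0) -> pd.DataFrame:
    """Comparative-Ct relative expression, one row per (sample, target gene).

    Technical replicates (duplicate rows per sample/gene) are averaged on the
    Ct scale first.  dCt = Ct_target - Ct_reference per sample; ddCt
    subtracts the calibrator-condition mean dCt of the same gene; relative
    expression = efficiency ** (-ddCt).
    """
    if not 1 < efficiency <= 2:
        raise ValueError("efficiency must lie in (1, 2]")
    need = {"sample_id", "gene_id", "ct", "role", "calibrator"}
    missing = need - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    mean_ct = (
        ct.groupby(["sample_id", "gene_id", "role", "calibrator"], as_index=False)["ct"].mean()
    )
    ref = mean_ct[mean_ct["role"] == "reference"]
    if ref["gene_id"].nunique() != 1:
        raise ValueError("exactly one reference gene is required")
    ref_ct = ref.set_index("sample_id")["ct"]
    targets = mean_ct[mean_ct["role"] == "target"].copy()
    missing_ref = set(targets["sample_id"]) - set(ref_ct.index)
    if missing_ref:
        raise ValueError(f"samples lacking a reference-gene Ct: {sorted(missing_ref)}")
    targets["dct"] = targets["ct"].to_numpy() - ref_ct.loc[targets["sample_id"]].to_numpy()
    cal = targets[targets["calibrator"]]
    if cal.empty:
        raise ValueError("no calibrator samples flagged")
    cal_dct = cal.groupby("gene_id")["dct"].mean()
    targets["ddct"] = targets["dct"] - cal_dct.loc[targets["gene_id"]].to_numpy()
    targets["relative_expression"] = efficiency ** (-targets["ddct"])
    return targets[["sample_id", "gene_id", "ct", "dct", "ddct", "relative_expression"]]


def relative_expression_by_timepoint(rel: pd.DataFrame) -> pd.DataFrame:
    """Average ddCt relative expression over replicates: genes x timepoints."""
    out = rel.copy()
    out["timepoint_h"] = [parse_sample_column(s)[0] for s in out["sample_id"]]
    return out.pivot_table(
        index="gene_id", columns="timepoint_h", values="relative_expression", aggfunc="mean"
    )


def concordance(fc_a: Sequence[float], fc_b: Sequence[float]) -> float:
    """Pearson correlation between two ln fold-change vectors."""
    a = np.asarray(fc_a, dtype=float)
    b = np.asarray(fc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# ANOVA + Tukey


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    alpha: float
    pairwise: pd.DataFrame  # group_a, group_b, p_value (NaN if gated), significant

    @property
    def any_significant(self) -> bool:
        return bool(self.pairwise["significant"].any())


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.01) -> AnovaTukeyResult:
    """One-way ANOVA gated Tukey HSD at the same alpha.

    Pairwise comparisons (studentized-range p-values) are only computed when
    the omnibus F test rejects; otherwise every pair is reported
    non-significant with a NaN p-value, mirroring the usual gated workflow
    for transgenic-line vs control comparisons.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for name in names:
        arr = np.asarray(groups[name], dtype=float)
        if len(arr) < 2:
            raise ValueError(f"group {name!r} needs >= 2 replicates")
        arrays.append(arr)
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("all groups constant: ANOVA undefined (zero within-group variance)")
    f_stat, p = stats.f_oneway(*arrays)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    if p < alpha:
        hsd = stats.tukey_hsd(*arrays)
        rows = [
            {
                "group_a": a,
                "group_b": b,
                "p_value": float(hsd.pvalue[names.index(a), names.index(b)]),
            }
            for a, b in pairs
        ]
        for r in rows:
            r["significant"] = r["p_value"] < alpha
    else:
        rows = [
            {"group_a": a, "group_b": b, "p_value": float("nan"), "significant": False}
            for a, b in pairs
        ]
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        alpha=alpha,
        pairwise=pd.DataFrame(rows, columns=["group_a", "group_b", "p_value", "significant"]),
    )
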