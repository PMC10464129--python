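"""Screen- and reagent-level quality control.

Covers reagent collapsing, strictly standardised mean difference (SSMD)
between control gene sets, within-gene reagent concordance, control-based
ROC AUC per cell line, gene-effect scaling to the conventional
(nonessential = 0, core-essential = -1) scale, and construction of a
composite "unbiased essential" control set from orthogonal evidence
sources (gene trap, mouse lethality, human population constraint).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score


class DegenerateInputError(ValueError):
    pass


def collapse_reagents(lfc: pd.DataFrame, reagent_map: pd.Series) -> pd.DataFrame:
    """Collapse reagent-level LFC to gene level by simple per-line average.

    ``reagent_map`` maps reagent name -> gene.  A gene whose reagents are
    all missing in a line is missing there.
    """
    unmapped = [r for r in lfc.columns if r not in reagent_map.index]
    if unmapped:
        raise KeyError(f"unmapped reagents: {unmapped[:5]}")
    return lfc.T.groupby(reagent_map.loc[lfc.columns]).mean().T


def ssmd(values_by_line: pd.DataFrame, positives: set[str], negatives: set[str]) -> pd.Series:
    """Per-line SSMD between positive and negative control genes.

    SSMD = (mean_pos - mean_neg) / sqrt(var_pos + var_neg), sample
    variances.  With depletion coded negative, more negative SSMD means
    better separation.
    """
    pos = [g for g in values_by_line.columns if g in positives]
    neg = [g for g in values_by_line.columns if g in negatives]
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateInputError("need >=2 members of each control group")
    p = values_by_line[pos]
    q = values_by_line[neg]
    denom = p.var(axis=1, ddof=1) + q.var(axis=1, ddof=1)
    if (denom == 0).any():
        raise DegenerateInputError("zero combined control variance in at least one line")
    out = (p.mean(axis=1) - q.mean(axis=1)) / np.sqrt(denom)
    out.name = "ssmd"
    return out


def center_scale_lines(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each cell line (row) — batch-effect reduction before
    reagent-correlation analysis."""
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    return matrix.sub(mu, axis=0).div(sd, axis=0)


def _percentile_of(values: np.ndarray) -> np.ndarray:
    """Fraction of entries strictly smaller, ties averaged, x100."""
    return (rankdata(values, method="average") - 1.0) / len(values) * 100.0


def reagent_concordance(lfc: pd.DataFrame, reagent_map: pd.Series) -> pd.DataFrame:
    """Per-gene median pairwise reagent correlation and variance percentile.

    The matrix is centred and scaled per cell line first.  Genes with one
    reagent get NaN concordance.  Reagent pairs with <3 shared non-missing
    lines are skipped; a gene whose pairs are all skipped is NaN.
    """
    scaled = center_scale_lines(lfc)
    genes = reagent_map.loc[lfc.columns]
    med_r: dict[str, float] = {}
    max_var: dict[str, float] = {}
    for gene, reagents in genes.groupby(genes).groups.items():
        sub = scaled[list(reagents)]
        max_var[gene] = float(np.nanmax(sub.var(axis=0, ddof=1).to_numpy()))
        if len(reagents) < 2:
            med_r[gene] = np.nan
            continue
        corr = sub.corr(min_periods=3)
        iu = np.triu_indices(len(reagents), k=1)
        pair_r = corr.to_numpy()[iu]
        pair_r = pair_r[~np.isnan(pair_r)]
        med_r[gene] = float(np.median(pair_r)) if pair_r.size else np.nan
    out = pd.DataFrame({"median_reagent_correlation": med_r, "max_reagent_variance": max_var})
    out["max_reagent_variance_percentile"] = _percentile_of(out["max_reagent_variance"].to_numpy())
    return out


def control_roc_auc(
    scores_by_line: pd.DataFrame, positives: set[str], negatives: set[str]
) -> pd.Series:
    """Per-line AUC separating positive from negative control genes.

    Lower (more depleted) scores are treated as more positive; ties are
    handled by midranks (the Mann-Whitney convention).
    """
    pos = [g for g in scores_by_line.columns if g in positives]
    neg = [g for g in scores_by_line.columns if g in negatives]
    if not pos or not neg:
        raise DegenerateInputError("both control classes must be non-empty")
    aucs = {}
    labels = np.array([1] * len(pos) + [0] * len(neg))
    for line in scores_by_line.index:
        s = scores_by_line.loc[line, pos + neg].to_numpy(dtype=float)
        ok = ~np.isnan(s)
        if len(np.unique(labels[ok])) < 2:
            raise DegenerateInputError(f"one-class input in line {line}")
        aucs[line] = roc_auc_score(labels[ok], -s[ok])
    return pd.Series(aucs, name="control_auc")


def scale_gene_effects(
    matrix: pd.DataFrame, essential: set[str], nonessential: set[str]
) -> pd.DataFrame:
    """Centre by per-line nonessential median, scale by the essential span.

    After scaling, each line has nonessential median 0 and core-essential
    median -1.  Idempotent, and invariant to per-line affine maps.
    """
    ess = [g for g in matrix.columns if g in essential]
    non = [g for g in matrix.columns if g in nonessential]
    if not ess or not non:
        raise DegenerateInputError("control sets do not intersect the gene axis")
    med_non = matrix[non].median(axis=1)
    med_ess = matrix[ess].median(axis=1)
    span = (med_ess - med_non).abs()
    if (span < 1e-12).any():
        bad = span.index[span < 1e-12][0]
        raise DegenerateInputError(f"essential and nonessential medians equal in line {bad}")
    return matrix.sub(med_non, axis=0).div(span, axis=0)


def build_unbiased_essential_set(
    population_scores: pd.DataFrame,
    gene_trap_hits: set[str],
    mouse_lethal: set[str],
    directions: dict[str, str] | None = None,
    percentile_cut: float = 85.0,
    min_metrics: int = 3,
) -> set[str]:
    """Composite essential set from orthogonal evidence.

    Population metrics (rows = genes) are converted to percentiles
    (``directions[metric]`` is ``"high"`` if larger means more essential,
    ``"low"`` otherwise); genes with a median percentile above
    ``percentile_cut`` over at least ``min_metrics`` non-missing metrics
    form the population-lethal set.  The output requires gene-trap support
    plus one other source:

        trap_hits  AND  (mouse_lethal  OR  population_lethal)
    """
    directions = directions or {}
    pct = {}
    for metric in population_scores.columns:
        col = population_scores[metric]
        vals = col.dropna()
        if vals.nunique() <= 1:
            warnings.warn(f"metric {metric} is constant; dropped", stacklevel=2)
            continue
        ranks = pd.Series(_percentile_of(vals.to_numpy()), index=vals.index)
        if directions.get(metric, "high") == "low":
            ranks = 100.0 - ranks
        pct[metric] = ranks.reindex(population_scores.index)
    population_lethal: set[str] = set()
    if pct:
        pdf = pd.DataFrame(pct)
        enough = pdf.notna().sum(axis=1) >= min_metrics
        med = pdf.median(axis=1)
        population_lethal = set(pdf.index[enough & (med > percentile_cut)])
    return gene_trap_hits & (mouse_lethal | population_lethal)


@dataclass
class ScreenQCReport:
    """Per-line and per-gene quality summary."""

    per_line: pd.DataFrame  # columns: ssmd, control_auc
    per_gene: pd.DataFrame  # reagent_concordance output


def qc_report(
    lfc: pd.DataFrame,
    reagent_map: pd.Series,
    essential: set[str],
    nonessential: set[str],
    positives: set[str] | None = None,
    negatives: set[str] | None = None,
) -> ScreenQCReport:
    """Full QC pass on one reagent-level dataset."""
    gene_lfc = collapse_reagents(lfc, reagent_map)
    per_line = pd.DataFrame(
        {
            "ssmd": ssmd(gene_lfc, essential, nonessential),
            "control_auc": control_roc_auc(
                gene_lfc, positives or essential, negatives or nonessential
            ),
        }
    )
    return ScreenQCReport(per_line=per_line, per_gene=reagent_concordance(lfc, reagent_map))
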