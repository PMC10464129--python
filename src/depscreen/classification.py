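"""Dependency classification statistics.

Implements the pipeline's core per-gene statistics on a scaled gene-effect
matrix (cell lines x genes):

* normalised within-line ranks and the 90th-percentile pan-dependency call
  with a bimodal-minimum threshold;
* posterior probability of dependency from per-line null (non-expressed
  genes) and positive (pan-dependent genes) control densities;
* skew-t likelihood-ratio selectivity;
* high-variance calling against the non-expressed-gene variance null;
* the priority-ordered five-class assignment;
* cross-dataset agreement (high-confidence set) and cross-perturbation
  class mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde, rankdata
from sklearn.isotonic import IsotonicRegression

from .containers import DEPENDENCY_CLASSES
from .skewt import LRTResult, lrt_selectivity_single


class BimodalityError(ValueError):
    """Raised when a distribution expected to be bimodal has < 2 modes."""


# ---------------------------------------------------------------- ranks


def normalized_ranks(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-line ascending rank of gene effect over the number screened.

    The most negative (most depleted) gene gets rank 1/n, the least gets
    1, with n the count of non-missing genes in that line.  Ties get
    average ranks.  Values lie in (0, 1]; missing effects stay missing.
    """
    vals = matrix.to_numpy(dtype=float)
    out = np.full_like(vals, np.nan)
    for i in range(vals.shape[0]):
        row = vals[i]
        ok = ~np.isnan(row)
        n = int(ok.sum())
        if n < 2:
            raise ValueError(f"line {matrix.index[i]} has fewer than 2 non-missing genes")
        out[i, ok] = rankdata(row[ok], method="average") / n
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ------------------------------------------------- bimodal thresholding


def bimodal_minimum(
    values: np.ndarray,
    grid_size: int = 512,
    bw_method: str | float = "silverman",
    min_prominence_frac: float = 0.01,
) -> float:
    """Density minimum separating the depleted (left) mode from the rest.

    A Gaussian KDE is evaluated on a fixed grid and its modes located
    (peaks with prominence at least ``min_prominence_frac`` of the maximum
    density, to ignore numerical wiggle).  The threshold is the grid
    argmin of the density strictly between the leftmost mode and the next
    mode to its right — for a genuinely bimodal sample this is the unique
    valley minimum, and when an intermediate subpopulation creates a
    shoulder it still isolates the depleted mode, which is the object of
    interest for pan-dependency and expression thresholds.  Raises
    :class:`BimodalityError` for unimodal input.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 10:
        raise BimodalityError("too few values for density estimation")
    kde = gaussian_kde(x, bw_method=bw_method)
    pad = 0.05 * (x.max() - x.min() + 1e-12)
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = kde(grid)
    peaks, props = find_peaks(dens, prominence=min_prominence_frac * dens.max())
    if len(peaks) < 2:
        raise BimodalityError(
            "fewer than two density modes found; supply an explicit threshold"
        )
    left, right = int(peaks[0]), int(peaks[1])
    between = slice(left + 1, right)
    return float(grid[between][np.argmin(dens[between])])


# ----------------------------------------------------- pan-dependency


@dataclass
class PanDependencyResult:
    rank90: pd.Series  # per gene, the percentile of normalised ranks
    threshold: float
    is_pan: pd.Series
    percentile: float


def pan_dependency_call(
    rank_matrix: pd.DataFrame,
    percentile: float = 90.0,
    threshold: float | None = None,
) -> PanDependencyResult:
    """Call pan-dependencies from a normalised-rank matrix.

    Per gene, the ``percentile`` quantile of its normalised ranks across
    lines is the rank of the most dependent line among the (100 -
    percentile)% least dependent — small iff the gene is depleted nearly
    everywhere.  The threshold separating the two modes of that statistic
    defaults to the bimodal density minimum.
    """
    q = rank_matrix.quantile(percentile / 100.0, axis=0)
    q.name = f"rank{percentile:g}"
    if threshold is None:
        threshold = bimodal_minimum(q.to_numpy())
    is_pan = q < threshold
    return PanDependencyResult(rank90=q, threshold=float(threshold), is_pan=is_pan, percentile=percentile)


# ------------------------------------------- probability of dependency


def _line_posterior(
    effects: np.ndarray,
    null_effects: np.ndarray,
    pos_effects: np.ndarray,
    pi1: float,
    bw_method: str | float,
) -> np.ndarray:
    if np.std(null_effects) < 1e-12 or np.std(pos_effects) < 1e-12:
        raise ValueError("degenerate (zero-variance) control distribution")
    f0 = gaussian_kde(null_effects, bw_method=bw_method)
    f1 = gaussian_kde(pos_effects, bw_method=bw_method)
    ok = ~np.isnan(effects)
    x = effects[ok]
    d0 = (1.0 - pi1) * f0(x)
    d1 = pi1 * f1(x)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = d1 / (d0 + d1)
    p = np.nan_to_num(p, nan=0.5)
    # monotone tail rule: beyond both control supports the posterior is
    # pinned (1 on the depleted side, 0 on the enriched side)
    lo = min(null_effects.min(), pos_effects.min())
    hi = max(null_effects.max(), pos_effects.max())
    p[x < lo] = 1.0
    p[x > hi] = 0.0
    # isotonic projection: nonincreasing in the gene effect
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=False)
    p = iso.fit_transform(x, p)
    out = np.full(effects.shape, np.nan)
    out[ok] = np.clip(p, 0.0, 1.0)
    return out


def probability_of_dependency(
    matrix: pd.DataFrame,
    null_sets: dict[str, set[str]] | set[str],
    positive_set: set[str],
    pi1: float = 0.5,
    bw_method: str | float = "silverman",
    min_controls: int = 20,
) -> pd.DataFrame:
    """Posterior probability that each effect is a true dependency.

    Per cell line, the effect distribution is decomposed into a null
    density (that line's non-expressed genes) and a positive-control
    density (the dataset's pan-dependent genes), both by Gaussian KDE;
    the posterior is ``pi1 f1 / (pi0 f0 + pi1 f1)``, pinned monotonically
    beyond the control supports and projected to be nonincreasing in the
    gene effect within each line.
    """
    probs = np.full(matrix.shape, np.nan)
    genes = matrix.columns
    pos_genes = [g for g in genes if g in positive_set]
    for i, line in enumerate(matrix.index):
        null_genes_line = null_sets[line] if isinstance(null_sets, dict) else null_sets
        ng = [g for g in genes if g in null_genes_line]
        row = matrix.iloc[i]
        null_eff = row[ng].dropna().to_numpy()
        pos_eff = row[pos_genes].dropna().to_numpy()
        if len(null_eff) < min_controls or len(pos_eff) < min_controls:
            raise ValueError(
                f"line {line}: need >= {min_controls} genes in each control set"
            )
        probs[i] = _line_posterior(row.to_numpy(dtype=float), null_eff, pos_eff, pi1, bw_method)
    return pd.DataFrame(probs, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------- selectivity


def lrt_selectivity(matrix: pd.DataFrame, min_n: int = 30) -> pd.DataFrame:
    """Skew-t vs Gaussian LRT per gene (columns of the effect matrix)."""
    rows = {}
    for g in matrix.columns:
        r: LRTResult = lrt_selectivity_single(matrix[g].to_numpy(dtype=float), min_n=min_n)
        rows[g] = {
            "lrt": r.lrt if r.lrt is not None else np.nan,
            "slant": r.slant if r.slant is not None else np.nan,
            "skew_sign": r.skew_sign,
            "converged": r.converged,
            "nu": r.fit.nu if r.fit is not None else np.nan,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene"
    return out


# -------------------------------------------------------- high variance


@dataclass
class HighVarianceResult:
    variance: pd.Series
    threshold: float
    is_high_variance: pd.Series


def high_variance_call(
    probabilities: pd.DataFrame, non_expressed: set[str], percentile: float = 99.0
) -> HighVarianceResult:
    """Flag genes whose dependency-probability variance exceeds the
    ``percentile`` of the variance distribution of non-expressed genes.

    The threshold is data-derived, never fixed a priori.
    """
    ne = [g for g in probabilities.columns if g in non_expressed]
    if not ne:
        raise ValueError("empty non-expressed control set")
    var = probabilities.var(axis=0, ddof=1)
    thr = float(np.nanpercentile(var[ne].to_numpy(), percentile))
    return HighVarianceResult(variance=var, threshold=thr, is_high_variance=var > thr)


# ------------------------------------------------------ classification


def classify_dependency(
    stats: pd.DataFrame,
    lrt_cutoff: float = 100.0,
    lrt_operator: str = ">=",
    order: str = "sequential_overwrite",
) -> pd.DataFrame:
    """Priority-ordered dependency class per gene.

    ``stats`` must carry per-gene columns: ``n_dependent`` (lines with
    probability > 0.5), ``lrt``, ``skew_sign``, ``is_pan``,
    ``is_high_variance``.  Rules are applied in order:

    1. non-dependent — no dependent line;
    2. weakly selective — at least one dependent line;
    3. strongly selective — LRT above the cutoff;
    4. pan-dependent;
    5. high-variance;
    6. strongly selective — LRT above the cutoff AND negative skew.

    Under ``sequential_overwrite`` (default) each later rule overwrites
    the label of any gene it fires for; ``first_match`` keeps the first
    label instead.  Genes with missing statistics are dropped with a
    warning.
    """
    required = ["n_dependent", "lrt", "skew_sign", "is_pan", "is_high_variance"]
    missing_cols = [c for c in required if c not in stats.columns]
    if missing_cols:
        raise KeyError(f"missing statistic columns: {missing_cols}")
    complete = stats[required].notna().all(axis=1)
    if not complete.all():
        warnings.warn(
            f"{(~complete).sum()} genes dropped for missing statistics", stacklevel=2
        )
    s = stats.loc[complete]

    def lrt_fires(row) -> bool:
        return row["lrt"] >= lrt_cutoff if lrt_operator == ">=" else row["lrt"] > lrt_cutoff

    rules = [
        ("non_dependent", lambda r: r["n_dependent"] == 0),
        ("weakly_selective", lambda r: r["n_dependent"] >= 1),
        ("strongly_selective", lrt_fires),
        ("pan_dependent", lambda r: bool(r["is_pan"])),
        ("high_variance", lambda r: bool(r["is_high_variance"])),
        ("strongly_selective", lambda r: lrt_fires(r) and r["skew_sign"] == "negative"),
    ]
    labels = {}
    for g, row in s.iterrows():
        label = None
        for name, rule in rules:
            if rule(row):
                if order == "sequential_overwrite":
                    label = name
                elif label is None:
                    label = name
        labels[g] = label
    out = s.copy()
    out["dependency_class"] = pd.Series(labels)
    bad = out["dependency_class"].isna()
    if bad.any():
        # rules 1 and 2 partition, so this would mean inconsistent input
        raise ValueError(f"unclassifiable genes: {list(out.index[bad])[:5]}")
    assert set(out["dependency_class"]) <= set(DEPENDENCY_CLASSES)
    return out


def dependency_statistics(
    effects: pd.DataFrame,
    probabilities: pd.DataFrame,
    pan: PanDependencyResult,
    selectivity: pd.DataFrame,
    high_var: HighVarianceResult,
) -> pd.DataFrame:
    """Assemble the per-gene statistic table classify_dependency consumes."""
    return pd.DataFrame(
        {
            "n_dependent": (probabilities > 0.5).sum(axis=0),
            "max_probability": probabilities.max(axis=0),
            "probability_variance": high_var.variance,
            "lrt": selectivity["lrt"],
            "skew_sign": selectivity["skew_sign"],
            "is_pan": pan.is_pan,
            "rank90": pan.rank90,
            "is_high_variance": high_var.is_high_variance,
            "mean_effect": effects.mean(axis=0),
        }
    )


# ----------------------------------------------- cross-dataset agreement


def _matching_gene_top_correlate(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
    """True where a gene's cross-dataset correlation with itself ranks 1
    among its correlations with every gene of the other dataset."""
    an = (a - a.mean()) / a.std(ddof=0)
    bn = (b - b.mean()) / b.std(ddof=0)
    an = an.fillna(0.0)
    bn = bn.fillna(0.0)
    corr = an.T.to_numpy() @ bn.to_numpy() / len(a)
    corr = pd.DataFrame(corr, index=a.columns, columns=b.columns)
    best = corr.idxmax(axis=1)
    return pd.Series(best.index == best.values, index=a.columns)


@dataclass
class HighConfidenceSet:
    flags: pd.DataFrame  # per gene: shared_pan_<m>, shared_nondep_<m>, top_correlate_<m>
    in_set: pd.Series


def high_confidence_set(
    datasets: dict[str, list[dict]],
) -> HighConfidenceSet:
    """Agreement-based high-confidence gene set.

    ``datasets`` maps modality -> list of exactly two dataset dicts, each
    with keys ``effects`` (lines x genes), ``classes`` (classify output)
    and ``is_pan``.  Within a modality a gene agrees if it is pan in both
    datasets, non-dependent in both, or its own top cross-dataset
    correlate.  The final set is the intersection of the per-modality
    agreement unions.
    """
    flag_cols = {}
    per_modality = {}
    genes = None
    for modality, pair in datasets.items():
        if len(pair) != 2:
            raise ValueError(f"modality {modality}: need exactly 2 datasets")
        d1, d2 = pair
        g = d1["effects"].columns
        if genes is None:
            genes = g
        shared_pan = d1["is_pan"].reindex(g) & d2["is_pan"].reindex(g)
        nd1 = d1["classes"]["dependency_class"].reindex(g) == "non_dependent"
        nd2 = d2["classes"]["dependency_class"].reindex(g) == "non_dependent"
        shared_nondep = nd1 & nd2
        top = _matching_gene_top_correlate(d1["effects"], d2["effects"])
        flag_cols[f"shared_pan_{modality}"] = shared_pan
        flag_cols[f"shared_nondep_{modality}"] = shared_nondep
        flag_cols[f"top_correlate_{modality}"] = top
        per_modality[modality] = shared_pan | shared_nondep | top
    flags = pd.DataFrame(flag_cols)
    in_set = pd.Series(True, index=genes)
    for agree in per_modality.values():
        in_set &= agree.reindex(genes).fillna(False)
    return HighConfidenceSet(flags=flags, in_set=in_set)


def map_classes_cross_perturbation(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    restrict_to: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene (class_A, class_B) pairs and the 5x5 contingency table."""
    if not table_a.index.equals(table_b.index):
        raise ValueError("class tables must share the gene axis")
    pairs = pd.DataFrame(
        {
            "class_A": table_a["dependency_class"],
            "class_B": table_b["dependency_class"],
        }
    )
    if restrict_to is not None:
        pairs = pairs.loc[restrict_to.reindex(pairs.index).fillna(False)]
    counts = (
        pd.crosstab(pairs["class_A"], pairs["class_B"])
        .reindex(index=DEPENDENCY_CLASSES, columns=DEPENDENCY_CLASSES, fill_value=0)
    )
    return pairs, counts
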