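"""Random-forest biomarker models of gene-effect profiles.

Each target gene's effect profile is regressed on omics features under two
feature-selection regimes:

* **related** — only features whose subject gene has a prior known
  relationship to the target (the target itself included), plus
  confounders and lineage annotations, which are always included;
* **unbiased** — the top 1000 features by |Pearson correlation| with the
  target, computed inside each training fold to avoid leakage.

Models are 100-tree random forests (max depth 8, >= 5 lines per leaf)
evaluated by stratified 5-fold cross-validation, where the strata are
dependent (probability > 0.5) vs non-dependent lines.  Accuracy is the
Pearson correlation between observed effects and out-of-fold predictions;
accurate models (r > 0.5) are then screened against a rule table that
assigns biomarker classes (genetic driver, expression addiction, paralog
lethality, CYCLOPS, oncogene addiction, synthetic lethality).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureMatrix

RF_PARAMS = dict(n_estimators=100, max_depth=8, min_samples_leaf=5)
MUTATION_TYPES = ("mutation_damaging", "mutation_missense", "mutation_hotspot", "fusion")
ALWAYS_INCLUDED = ("confounder", "lineage")


def assemble_feature_matrix(
    continuous: dict[str, pd.DataFrame] | None = None,
    categorical: dict[str, pd.DataFrame] | None = None,
    confounders: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Standardise continuous blocks, one-hot categoricals, zero-fill.

    ``continuous`` / ``categorical`` map source type -> (lines x features)
    tables sharing a cell-line axis.  Continuous features are z-scored
    over non-missing entries; zero-variance features are dropped with a
    warning.  ``metadata`` (feature -> subject_gene / chr_arm) is merged
    when given.
    """
    blocks: list[pd.DataFrame] = []
    meta_rows: list[tuple[str, str, str, str]] = []

    def record(name: str, source: str) -> None:
        subj, arm = "", ""
        if metadata is not None and name in metadata.index:
            subj = str(metadata.loc[name].get("subject_gene", ""))
            arm = str(metadata.loc[name].get("chr_arm", ""))
        meta_rows.append((name, source, subj, arm))

    for source, table in (continuous or {}).items():
        sd = table.std(ddof=0)
        dead = sd.index[(sd == 0) | sd.isna()]
        if len(dead):
            warnings.warn(f"{len(dead)} constant {source} features dropped", stacklevel=2)
            table = table.drop(columns=dead)
            sd = sd.drop(dead)
        z = (table - table.mean()) / sd
        blocks.append(z)
        for f in z.columns:
            record(f, source)

    for source, table in (categorical or {}).items():
        for col in table.columns:
            onehot = pd.get_dummies(table[col], prefix=col).astype(float)
            blocks.append(onehot)
            for f in onehot.columns:
                record(f, source)

    if confounders is not None:
        blocks.append(confounders)
        for f in confounders.columns:
            record(f, "confounder")

    values = pd.concat(blocks, axis=1).fillna(0.0)
    meta = pd.DataFrame(
        meta_rows, columns=["feature", "source_type", "subject_gene", "chr_arm"]
    ).set_index("feature")
    return FeatureMatrix(values, meta.loc[values.columns])


@dataclass
class PredictiveModelResult:
    target: str
    regime: str
    accuracy: float
    importances: pd.Series  # normalised, sum 1
    n_lines: int
    fold_assignment: pd.Series
    fallback_to_confounders: bool = False

    def top_features(self, k: int = 10) -> pd.Series:
        return self.importances.sort_values(ascending=False, kind="stable").head(k)

    @property
    def top_feature(self) -> str:
        # deterministic tie-break: importance desc, then feature name
        imp = self.importances
        order = sorted(imp.index, key=lambda f: (-imp[f], f))
        return order[0]


def _related_features(
    features: FeatureMatrix, target: str, priors: dict[str, set[str]]
) -> tuple[list[str], bool]:
    related_genes = set(priors.get(target, set())) | {target}
    meta = features.metadata
    by_gene = meta.index[meta["subject_gene"].isin(related_genes)]
    always = meta.index[meta["source_type"].isin(ALWAYS_INCLUDED)]
    fallback = len(by_gene) == 0
    cols = [f for f in features.values.columns if f in set(by_gene) | set(always)]
    return cols, fallback


def fit_dependency_model(
    target: str,
    effects: pd.Series,
    features: FeatureMatrix,
    regime: str,
    priors: dict[str, set[str]] | None = None,
    dependent_lines: pd.Series | None = None,
    seed: int = 0,
    n_folds: int = 5,
    top_n_unbiased: int = 1000,
) -> PredictiveModelResult:
    """Cross-validated random-forest model for one gene-effect profile."""
    if regime not in ("related", "unbiased"):
        raise ValueError(f"unknown regime {regime!r}")
    y_full = effects.dropna()
    if len(y_full) < 50:
        raise ValueError(f"target {target}: need >= 50 cell lines with effects")
    X_full = features.values.reindex(y_full.index)

    fallback = False
    if regime == "related":
        cols, fallback = _related_features(features, target, priors or {})
        if fallback:
            warnings.warn(
                f"{target}: no prior-related features; falling back to "
                "confounder + lineage only",
                stacklevel=2,
            )
        X_full = X_full[cols]

    if dependent_lines is not None:
        strata = dependent_lines.reindex(y_full.index).fillna(False).astype(int)
    else:
        strata = (y_full < -0.5).astype(int)
    if strata.nunique() < 2 or strata.value_counts().min() < n_folds:
        # stratification degenerate: fall back to balanced pseudo-strata
        strata = pd.Series(np.arange(len(y_full)) % n_folds, index=y_full.index)
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)

    y = y_full.to_numpy()
    oof = np.full(len(y), np.nan)
    fold_of = np.full(len(y), -1)
    imp_sum = pd.Series(0.0, index=features.values.columns)
    for fold, (tr, te) in enumerate(splitter.split(X_full, strata)):
        X_tr, X_te = X_full.iloc[tr], X_full.iloc[te]
        if regime == "unbiased":
            # per-fold correlation screen, leakage-safe
            xs = X_tr.to_numpy()
            ys = y[tr]
            xm = xs - xs.mean(axis=0)
            ym = ys - ys.mean()
            denom = np.sqrt((xm**2).sum(axis=0) * (ym**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.abs(xm.T @ ym) / denom
            r = np.nan_to_num(r)
            keep = np.argsort(-r, kind="stable")[:top_n_unbiased]
            cols = X_full.columns[np.sort(keep)]
            X_tr, X_te = X_tr[cols], X_te[cols]
        rf = RandomForestRegressor(random_state=seed, **RF_PARAMS)
        rf.fit(X_tr, y[tr])
        oof[te] = rf.predict(X_te)
        fold_of[te] = fold
        imp_sum[X_tr.columns] = imp_sum[X_tr.columns].to_numpy() + rf.feature_importances_
    total = imp_sum.sum()
    importances = imp_sum / total if total > 0 else imp_sum
    acc = float(pearsonr(y, oof).statistic) if np.std(oof) > 0 else 0.0
    return PredictiveModelResult(
        target=target,
        regime=regime,
        accuracy=acc,
        importances=importances,
        n_lines=len(y),
        fold_assignment=pd.Series(fold_of, index=y_full.index),
        fallback_to_confounders=fallback,
    )


def combined_accuracy(results: dict[str, PredictiveModelResult]) -> float:
    """A gene's reported accuracy is the max over the fitted regimes."""
    return max(r.accuracy for r in results.values())


@dataclass
class BiomarkerClassAssignment:
    target: str
    classes: list[str] = field(default_factory=list)
    evidence: dict[str, dict] = field(default_factory=dict)


def _corr(a: pd.Series, b: pd.Series) -> float:
    ok = a.notna() & b.notna()
    if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
        return np.nan
    return float(pearsonr(a[ok], b[ok]).statistic)


def assign_biomarker_class(
    results: dict[str, PredictiveModelResult],
    features: FeatureMatrix,
    effects: pd.Series,
    priors: dict[str, set[str]] | None = None,
    oncogenes: set[str] | None = None,
    tumor_suppressors: set[str] | None = None,
    accuracy_cutoff: float = 0.5,
    importance_cutoff: float = 0.05,
) -> BiomarkerClassAssignment:
    """Rule-table biomarker classes for one target's fitted models.

    Correlation directions are evaluated on the gene-effect scale (more
    negative = more dependent), so every "feature promotes dependency"
    rule expects a negative feature-effect correlation; the CYCLOPS rule
    expects positive correlation with the target's own copy number.
    Classes are only assigned when some model's accuracy exceeds
    ``accuracy_cutoff``.  Skewness is the sample third standardised moment
    of the effect profile.
    """
    target = next(iter(results.values())).target
    out = BiomarkerClassAssignment(target=target)
    accurate = {k: r for k, r in results.items() if r.accuracy > accuracy_cutoff}
    if not accurate:
        return out
    priors = priors or {}
    meta = features.metadata
    eff = effects.dropna()
    e = eff.to_numpy()
    skew = float(np.mean(((e - e.mean()) / e.std()) ** 3)) if e.std() > 0 else 0.0
    neg_skew = skew < 0

    def feature_corr(f: str) -> float:
        return _corr(effects, features.values[f])

    self_cn = next(iter(features.features_of(target, ("copy_number",))), None)

    for regime, res in accurate.items():
        top = res.top_feature
        top_meta = meta.loc[top]
        imp = res.importances

        # genetic driver: self mutation/fusion/CN feature, importance > 0.05,
        # feature promotes dependency, negative skew
        for f in features.features_of(target, MUTATION_TYPES + ("copy_number",)):
            if imp.get(f, 0.0) > importance_cutoff and neg_skew:
                c = feature_corr(f)
                if not np.isnan(c) and c < 0:
                    out.classes.append("genetic_driver")
                    out.evidence["genetic_driver"] = {
                        "feature": f, "importance": float(imp[f]), "correlation": c,
                        "regime": regime,
                    }

        # expression addiction: self expression is the model's top feature,
        # negatively correlated with the effect
        if top_meta["subject_gene"] == target and top_meta["source_type"] == "expression":
            c = feature_corr(top)
            if not np.isnan(c) and c < 0:
                out.classes.append("expression_addiction")
                out.evidence["expression_addiction"] = {
                    "feature": top, "correlation": c, "regime": regime,
                }

        # paralog lethality: a prior-related partner's feature is top
        if (
            top_meta["subject_gene"] not in ("", target)
            and top_meta["subject_gene"] in priors.get(target, set())
        ):
            out.classes.append("paralog_lethal")
            out.evidence["paralog_lethal"] = {
                "feature": top, "partner": top_meta["subject_gene"], "regime": regime,
            }

        # CYCLOPS: top feature is a self CN/expression feature on the
        # target's own chromosome arm with importance > 0.05, positive
        # correlation to the top feature and to self copy number,
        # negative skew
        if (
            top_meta["subject_gene"] == target
            and top_meta["source_type"] in ("copy_number", "expression")
            and imp.get(top, 0.0) > importance_cutoff
            and neg_skew
            and self_cn is not None
        ):
            own_arm = meta.loc[meta["subject_gene"] == target, "chr_arm"]
            same_arm = top_meta["chr_arm"] in set(own_arm) and top_meta["chr_arm"] != ""
            c_top = feature_corr(top)
            c_cn = feature_corr(self_cn)
            if same_arm and not np.isnan(c_top) and c_top > 0 and not np.isnan(c_cn) and c_cn > 0:
                out.classes.append("cyclops")
                out.evidence["cyclops"] = {
                    "feature": top, "corr_top": c_top, "corr_self_cn": c_cn,
                    "regime": regime,
                }

        # oncogene addiction: the target is an annotated oncogene and one
        # of its own features is in the model's top 10; negative skew
        if oncogenes and target in oncogenes and neg_skew:
            top10 = set(res.top_features(10).index)
            own = set(features.features_of(target))
            if top10 & own:
                out.classes.append("oncogene_addiction")
                out.evidence["oncogene_addiction"] = {
                    "feature": sorted(top10 & own)[0], "regime": regime,
                }

        # synthetic lethal (oncogene/TSG): an important feature belongs to
        # a different oncogene or tumor suppressor
        onco_tsg = (oncogenes or set()) | (tumor_suppressors or set())
        for f in imp.index[imp > importance_cutoff]:
            subj = meta.loc[f, "subject_gene"] if f in meta.index else ""
            if subj and subj != target and subj in onco_tsg:
                out.classes.append("synthetic_lethal_onco_tsg")
                out.evidence["synthetic_lethal_onco_tsg"] = {
                    "feature": f, "partner": subj, "regime": regime,
                }
                break

    out.classes = sorted(set(out.classes))
    return out
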