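"""Dose-level drug response vs gene dependency association.

Each dose-level drug matrix (cell lines x drugs) first has its leading
principal component removed — in large viability screens PC1 tracks a
growth-rate-like confound shared across compounds.  Missing values are
median-imputed per drug for the PC computation and re-masked afterwards.
Residual profiles are then correlated with gene-dependency profiles
(pairwise-complete Pearson), the best dose per annotated drug-target pair
is labelled, and target recovery at a rank cutoff is summarised.

Sign convention: both drug response and gene effect are "more negative =
more killing", so a drug matching its target's dependency pattern gives a
positive correlation; "best" is the most positive signed r by default,
with an absolute-value mode available.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .containers import DrugResponseTensor


def remove_first_pc(dose_matrix: pd.DataFrame) -> pd.DataFrame:
    """Residualise each drug column on the matrix's first principal component.

    Missing entries are median-imputed per drug before the SVD and
    re-masked in the output.  Raises on a constant (rank-0) matrix.
    """
    if dose_matrix.shape[0] < 3 or dose_matrix.shape[1] < 3:
        raise ValueError("need >= 3 cell lines and >= 3 drugs")
    mask = dose_matrix.isna()
    filled = dose_matrix.apply(lambda col: col.fillna(col.median()))
    X = filled.to_numpy(dtype=float)
    centered = X - X.mean(axis=0)
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError("constant dose matrix: no principal component")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    pc1 = u[:, 0] * s[0]  # per-line scores
    # per-column regression on PC1 (with intercept via prior centering)
    beta = centered.T @ pc1 / (pc1 @ pc1)
    resid = centered - np.outer(pc1, beta)
    out = pd.DataFrame(resid, index=dose_matrix.index, columns=dose_matrix.columns)
    return out.mask(mask)


def _pairwise_pearson(drug_mat: pd.DataFrame, gene_mat: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson r between drug and gene columns."""
    D = drug_mat.to_numpy(dtype=float)
    G = gene_mat.to_numpy(dtype=float)
    if not (np.isnan(D).any() or np.isnan(G).any()):
        dn = (D - D.mean(axis=0)) / D.std(axis=0)
        gn = (G - G.mean(axis=0)) / G.std(axis=0)
        r = dn.T @ gn / D.shape[0]
        return pd.DataFrame(r, index=drug_mat.columns, columns=gene_mat.columns)
    out = np.full((D.shape[1], G.shape[1]), np.nan)
    for i in range(D.shape[1]):
        d = D[:, i]
        for j in range(G.shape[1]):
            g = G[:, j]
            ok = ~(np.isnan(d) | np.isnan(g))
            if ok.sum() < min_pairs:
                continue
            dv, gv = d[ok] - d[ok].mean(), g[ok] - g[ok].mean()
            denom = np.sqrt((dv**2).sum() * (gv**2).sum())
            if denom > 0:
                out[i, j] = float(dv @ gv / denom)
    return pd.DataFrame(out, index=drug_mat.columns, columns=gene_mat.columns)


@dataclass
class DrugTargetCorrelationTable:
    long: pd.DataFrame  # drug, dose, gene, r
    best_target_per_drug: pd.DataFrame  # drug -> best correlated annotated target
    best_dose_per_pair: pd.DataFrame  # (drug, target) -> best dose and r


def correlate_drug_doses(
    tensor: DrugResponseTensor,
    dependencies: pd.DataFrame,
    gene_filter: list[str] | None = None,
    remove_pc1: bool = True,
    min_shared_lines: int = 10,
    use_absolute: bool = False,
) -> DrugTargetCorrelationTable:
    """Full (drug, dose) x gene correlation table plus best-pair labels.

    ``gene_filter`` restricts to genes passing the dependency prefilter
    (>= 3 dependent lines); when None all genes are used.
    """
    shared = [c for c in tensor.cell_lines if c in dependencies.index]
    if len(shared) < min_shared_lines:
        raise ValueError(f"only {len(shared)} shared cell lines")
    genes = list(gene_filter) if gene_filter is not None else list(dependencies.columns)
    gmat = dependencies.loc[shared, genes]

    frames = []
    for d in range(len(tensor.doses)):
        dmat = tensor.dose_matrix(d).loc[shared]
        if remove_pc1:
            dmat = remove_first_pc(dmat)
        r = _pairwise_pearson(dmat, gmat)
        longr = r.stack(future_stack=True).rename("r").reset_index()
        longr.columns = ["drug", "gene", "r"]
        longr.insert(1, "dose", tensor.doses[d])
        frames.append(longr)
    long = pd.concat(frames, ignore_index=True).dropna(subset=["r"])

    score = long["r"].abs() if use_absolute else long["r"]
    long = long.assign(_score=score)

    # best correlated annotated target per drug
    rows = []
    for drug, targets in tensor.targets.items():
        sub = long[(long["drug"] == drug) & long["gene"].isin(targets)]
        if sub.empty:
            continue
        best = sub.loc[sub["_score"].idxmax()]
        rows.append((drug, best["gene"], best["dose"], best["r"]))
    best_target = pd.DataFrame(rows, columns=["drug", "target", "dose", "r"])

    best_pair = best_dose_per_pair(long, tensor.targets)
    return DrugTargetCorrelationTable(
        long=long.drop(columns="_score"),
        best_target_per_drug=best_target,
        best_dose_per_pair=best_pair,
    )


def best_dose_per_pair(
    long: pd.DataFrame, targets: dict[str, list[str]], use_absolute: bool = False
) -> pd.DataFrame:
    """Argmax dose per annotated (drug, target) pair; ties -> lowest dose."""
    score = long["r"].abs() if use_absolute else long["r"]
    tab = long.assign(_score=score)
    rows = []
    for drug, genes in targets.items():
        for gene in genes:
            sub = tab[(tab["drug"] == drug) & (tab["gene"] == gene)].dropna(subset=["r"])
            if sub.empty:
                continue
            sub = sub.sort_values(["_score", "dose"], ascending=[False, True], kind="stable")
            top = sub.iloc[0]
            rows.append((drug, gene, top["dose"], top["r"]))
    return pd.DataFrame(rows, columns=["drug", "target", "best_dose", "r"])


def target_recovery_fraction(
    long: pd.DataFrame,
    targets: dict[str, list[str]],
    k: int = 5,
    gene_classes: pd.Series | None = None,
    use_absolute: bool = False,
) -> dict:
    """Fraction of drug-doses whose annotated target ranks in the top k.

    Returns per-dose fractions, the overall fraction, and — when
    ``gene_classes`` is given — fractions per target stratum
    (pan-dependent vs other).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    score = long["r"].abs() if use_absolute else long["r"]
    tab = long.assign(_score=score)
    hits = []
    for (drug, dose), sub in tab.groupby(["drug", "dose"], sort=True):
        tgt = targets.get(drug)
        if not tgt:
            warnings.warn(f"drug {drug} has no annotated targets; excluded", stacklevel=2)
            continue
        topk = set(
            sub.sort_values(["_score", "gene"], ascending=[False, True], kind="stable")
            .head(k)["gene"]
        )
        hit = bool(topk & set(tgt))
        stratum = None
        if gene_classes is not None:
            cls = {gene_classes.get(t) for t in tgt}
            stratum = "pan_dependent" if "pan_dependent" in cls else "other"
        hits.append((drug, dose, hit, stratum))
    hdf = pd.DataFrame(hits, columns=["drug", "dose", "hit", "stratum"])
    out = {
        "overall": float(hdf["hit"].mean()) if len(hdf) else np.nan,
        "per_dose": hdf.groupby("dose")["hit"].mean(),
        "n": len(hdf),
    }
    if gene_classes is not None:
        out["per_stratum"] = hdf.groupby("stratum")["hit"].mean()
    return out
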