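"""Planted-truth benchmarks for the pipeline's headline operations.

Each routine generates synthetic data under the package's standard study
conditions (~400-line panels, gene effects scaled to nonessential 0 /
essential -1), runs one stage of the analysis, and scores it against the
planted truth.  They power both the acceptance checks and the
reproducibility script; every quantity is recomputed from scratch at call
time.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, kstest
from scipy.optimize import brentq

from . import classification as cls
from . import drugs as drug_mod
from . import network as net_mod
from .biomarkers import assign_biomarker_class, fit_dependency_model
from .skewt import lrt_selectivity_single
from .synthetic import (
    SyntheticConfig,
    build_truth,
    generate_bundle,
    generate_drug_response,
    generate_gene_effects,
    generate_related_priors,
)


def pan_recovery_benchmark(seeds=(1, 2, 3, 4, 5), n_cell_lines=400, n_genes=1000) -> dict:
    """Pan-dependency sensitivity/FDR and percentile robustness.

    One 400 x 1000 bundle per seed with 10% planted pan genes; pan calls
    use the derived bimodal threshold at the 80th/90th/95th percentiles.
    """
    sens, fdr, jac = [], [], []
    for seed in seeds:
        cfg = SyntheticConfig(n_cell_lines=n_cell_lines, n_genes=n_genes, seed=int(seed))
        eff, truth = generate_gene_effects(cfg, "A")
        ranks = cls.normalized_ranks(eff)
        truth_pan = set(truth.genes_of("pan"))
        sets = {}
        for pct in (80, 90, 95):
            res = cls.pan_dependency_call(ranks, percentile=pct)
            sets[pct] = set(res.is_pan.index[res.is_pan])
        called = sets[90]
        tp = len(called & truth_pan)
        sens.append(tp / len(truth_pan))
        fdr.append((len(called) - tp) / max(1, len(called)))
        jac.append(
            min(
                len(sets[a] & sets[b]) / len(sets[a] | sets[b])
                for a, b in itertools.combinations(sets, 2)
            )
        )
    return {
        "sensitivity": float(np.mean(sens)),
        "fdr": float(np.mean(fdr)),
        "min_jaccard": float(min(jac)),
        "n": len(sens) * n_genes,
    }


def lrt_benchmark(
    seed: int = 1,
    n_null: int = 500,
    n_alt: int = 200,
    n_lines: int = 400,
    noise_sd: float = 0.15,
    shift: float = -1.5,
    dependent_fraction: float = 0.05,
) -> dict:
    """LRT operating characteristics on Gaussian null and planted
    selective profiles."""
    rng = np.random.default_rng(seed)
    null_lrt = []
    min_lrt = np.inf
    for _ in range(n_null):
        r = lrt_selectivity_single(rng.normal(0.0, noise_sd, n_lines))
        null_lrt.append(r.lrt)
        min_lrt = min(min_lrt, r.lrt)
    hits = 0
    n_dep = int(round(dependent_fraction * n_lines))
    for _ in range(n_alt):
        x = rng.normal(0.0, noise_sd, n_lines)
        x[rng.choice(n_lines, n_dep, replace=False)] += shift
        r = lrt_selectivity_single(x)
        hits += r.lrt >= 100.0 and r.slant < 0
        min_lrt = min(min_lrt, r.lrt)
    return {
        "null_exceed_pct": 100.0 * float(np.mean(np.asarray(null_lrt) >= 100.0)),
        "power_pct": 100.0 * hits / n_alt,
        "min_lrt": float(min_lrt),
        "n": n_null + n_alt,
    }


def probability_calibration_benchmark(
    seed: int = 1, n_controls: int = 150, sd: float = 0.15, separation: float = 1.0
) -> dict:
    """Posterior calibration with control modes >= 4 pooled SD apart."""
    rng = np.random.default_rng(seed)
    null = rng.normal(0.0, sd, n_controls)
    pos = rng.normal(-separation, sd, n_controls)
    f0 = gaussian_kde(null, bw_method="silverman")
    f1 = gaussian_kde(pos, bw_method="silverman")
    x_star = brentq(lambda x: f1(x)[0] - f0(x)[0], -separation + sd, -sd)
    genes = (
        [f"n{i}" for i in range(n_controls)]
        + [f"p{i}" for i in range(n_controls)]
        + ["mid"]
    )
    mat = pd.DataFrame([np.concatenate([null, pos, [x_star]])], index=["c"], columns=genes)
    prob = cls.probability_of_dependency(
        mat,
        {g for g in genes if g.startswith("n")},
        {g for g in genes if g.startswith("p")},
    )
    return {
        "mean_posterior_positive": float(prob.loc["c", [f"p{i}" for i in range(n_controls)]].mean()),
        "mean_posterior_null": float(prob.loc["c", [f"n{i}" for i in range(n_controls)]].mean()),
        "posterior_at_equal_density": float(prob.loc["c", "mid"]),
        "separation_pooled_sd": separation / sd,
        "n": 2 * n_controls,
    }


def classification_oracle_benchmark(seed: int = 1, n: int = 200) -> dict:
    """Agreement of classify_dependency with a literal rule-list replay."""
    rng = np.random.default_rng(seed)
    stats = pd.DataFrame(
        {
            "n_dependent": rng.integers(0, 5, n),
            "lrt": rng.choice([0.0, 50.0, 100.0, 150.0], n),
            "skew_sign": rng.choice(["negative", "nonnegative"], n),
            "is_pan": rng.random(n) < 0.3,
            "is_high_variance": rng.random(n) < 0.3,
        },
        index=[f"g{i}" for i in range(n)],
    )
    out = cls.classify_dependency(stats)["dependency_class"]

    def replay(row):
        label = "non_dependent" if row["n_dependent"] == 0 else "weakly_selective"
        if row["lrt"] >= 100.0:
            label = "strongly_selective"
        if row["is_pan"]:
            label = "pan_dependent"
        if row["is_high_variance"]:
            label = "high_variance"
        if row["lrt"] >= 100.0 and row["skew_sign"] == "negative":
            label = "strongly_selective"
        return label

    agree = sum(out[g] == replay(row) for g, row in stats.iterrows())
    return {"agreement_fraction": agree / n, "n": n}


def biomarker_config(seed: int, per_mechanism: int = 50, n_cell_lines: int = 200) -> SyntheticConfig:
    """Study design for the biomarker benchmark: enough selective and
    high-variance genes to host 50 planted genes per mechanism."""
    return SyntheticConfig(
        n_cell_lines=n_cell_lines,
        n_genes=450,
        fractions={
            "pan": 0.05,
            "strongly_selective": 0.45,
            "high_variance": 0.20,
            "weakly_selective": 0.05,
            "non_dependent": 0.25,
        },
        mechanism_counts={
            "genetic_driver": per_mechanism,
            "expression_addiction": per_mechanism,
            "paralog": per_mechanism,
            "cyclops": per_mechanism,
        },
        n_modules=2,
        module_size=5,
        n_drugs=5,
        seed=seed,
    )


EXPECTED_CLASS = {
    "genetic_driver": "genetic_driver",
    "expression_addiction": "expression_addiction",
    "paralog": "paralog_lethal",
    "cyclops": "cyclops",
}


def biomarker_benchmark(
    seed: int = 1,
    per_mechanism: int = 50,
    n_uncoupled: int = 50,
    regimes: tuple[str, ...] = ("related",),
    unbiased_spot_check: int = 0,
) -> dict:
    """Planted-mechanism recovery by cross-validated RF models.

    Fits the requested regimes for every planted-mechanism gene and for
    uncoupled control genes, then scores class assignment.  The Related
    regime carries every planted mechanism's signal (self and
    prior-partner features); ``unbiased_spot_check`` additionally runs the
    Unbiased regime for that many planted genes.
    """
    cfg = biomarker_config(seed, per_mechanism)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = generate_bundle(cfg)
    eff = bundle.gene_effects["A"]
    fm = bundle.features
    truth = bundle.truth

    def fit_and_assign(gene, use_regimes):
        dep = eff[gene] < -0.5
        res = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for regime in use_regimes:
                res[regime] = fit_dependency_model(
                    gene, eff[gene], fm, regime, bundle.priors,
                    dependent_lines=dep, seed=seed,
                )
            assign = assign_biomarker_class(res, fm, eff[gene], bundle.priors)
        return res, assign

    correct = accurate = 0
    spot_left = unbiased_spot_check
    for mech, want in EXPECTED_CLASS.items():
        for gene in truth.genes_with_mechanism(mech):
            use = tuple(regimes)
            if spot_left > 0:
                use = tuple(set(use) | {"unbiased"})
                spot_left -= 1
            res, assign = fit_and_assign(gene, use)
            if max(r.accuracy for r in res.values()) > 0.5:
                accurate += 1
                correct += want in assign.classes

    uncoupled = [
        g
        for g in truth.genes_of("strongly_selective")
        if truth.mechanism[g] == "none"
    ][:n_uncoupled]
    false_assigned = 0
    for gene in uncoupled:
        _, assign = fit_and_assign(gene, tuple(regimes))
        false_assigned += bool(assign.classes)

    return {
        "accurate_fraction": accurate / (len(EXPECTED_CLASS) * per_mechanism),
        "correct_of_accurate": correct / max(1, accurate),
        "false_assignment_rate": false_assigned / max(1, len(uncoupled)),
        "n": len(EXPECTED_CLASS) * per_mechanism + len(uncoupled),
    }


def drug_recovery_benchmark(
    seed: int = 1, n_drugs: int = 50, n_cell_lines: int = 400, n_genes: int = 1000
) -> dict:
    """Annotated-target recovery at the signal dose, before and after PC1
    removal of the shared growth-rate-like confound."""
    cfg = SyntheticConfig(
        n_cell_lines=n_cell_lines, n_genes=n_genes, n_drugs=n_drugs, seed=seed
    )
    eff, truth = generate_gene_effects(cfg, "A")
    tensor = generate_drug_response(
        truth, eff, n_doses=cfg.n_doses, seed=seed, n_drugs=n_drugs
    )
    gene_filter = [
        g
        for g, a in truth.archetype.items()
        if a in ("strongly_selective", "high_variance", "weakly_selective")
    ]
    post = drug_mod.correlate_drug_doses(tensor, eff, gene_filter, remove_pc1=True)
    pre = drug_mod.correlate_drug_doses(tensor, eff, gene_filter, remove_pc1=False)
    centre = tensor.doses[len(tensor.doses) // 2]

    centre_long = post.long[post.long["dose"] == centre]
    recovery = drug_mod.target_recovery_fraction(centre_long, tensor.targets, k=5)

    improved = 0
    for drug, targets in tensor.targets.items():
        tgt = targets[0]

        def r_of(tab):
            sub = tab.long[
                (tab.long["drug"] == drug)
                & (tab.long["gene"] == tgt)
                & (tab.long["dose"] == centre)
            ]
            return float(sub["r"].iloc[0])

        improved += r_of(post) > r_of(pre)
    return {
        "recovery_top5": float(recovery["overall"]),
        "improved_fraction": improved / len(tensor.targets),
        "n": n_drugs,
    }


def network_fusion_benchmark(
    seed: int = 1, n_cell_lines: int = 400, n_genes: int = 1000
) -> dict:
    """Module recovery through SNF and KS-p uniformity under random priors."""
    cfg = SyntheticConfig(
        n_cell_lines=n_cell_lines, n_genes=n_genes, n_modules=5, module_size=10, seed=seed
    )
    truth = build_truth(cfg)
    eff_a, _ = generate_gene_effects(cfg, "A", truth=truth)
    eff_b, _ = generate_gene_effects(cfg, "B", truth=truth)
    gene_filter = [
        g
        for g, a in truth.archetype.items()
        if a in ("strongly_selective", "high_variance")
    ]
    net_a = net_mod.correlation_similarity(eff_a, gene_filter)
    net_b = net_mod.correlation_similarity(eff_b, gene_filter)
    fused = net_mod.snf_fuse(net_a, net_b, k=7, iterations=20)

    priors = generate_related_priors(truth)
    module_genes = sorted(set().union(*truth.modules))
    enr = net_mod.related_enrichment(fused, {g: priors[g] for g in module_genes})
    within10 = float((enr.per_gene["best_related_rank"] <= 10).mean())

    rng = np.random.default_rng(seed)
    genes = list(fused.genes)
    random_priors = {
        g: set(rng.choice([h for h in genes if h != g], 5, replace=False))
        for g in genes[:150]
    }
    null_enr = net_mod.related_enrichment(fused, random_priors)
    uniform_p = float(kstest(null_enr.per_gene["ks_pvalue"], "uniform").pvalue)
    return {
        "module_best_rank10_fraction": within10,
        "ks_uniformity_pvalue": uniform_p,
        "n": len(module_genes),
    }
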