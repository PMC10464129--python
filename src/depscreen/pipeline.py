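"""Staged pipeline driver.

Stages run in dependency order (synth -> qc -> classify -> predict /
drugs / network); each stage reads its inputs from the output directory,
writes its products there, and records a manifest (stage name, config
hash, seed, per-stage timings and output row counts) so that a rerun with
the same configuration produces identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import classification as cls
from . import drugs as drug_mod
from . import io as dsio
from . import network as net_mod
from . import quality as qc_mod
from .biomarkers import assemble_feature_matrix, assign_biomarker_class, fit_dependency_model
from .synthetic import SyntheticConfig, generate_bundle

log = logging.getLogger("depscreen")

STAGE_ORDER = ["synth", "qc", "classify", "predict", "drugs", "network"]
_PREREQ = {
    "qc": ["synth"],
    "classify": ["synth"],
    "predict": ["synth", "classify"],
    "drugs": ["synth", "classify"],
    "network": ["synth", "classify"],
}


class DependencyError(RuntimeError):
    pass


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _manifest(out: Path, stage: str, cfg: dict, seed: int, t0: float, counts: dict) -> None:
    path = out / f"manifest_{stage}.json"
    payload = {
        "stage": stage,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "counts": counts,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    log.info("stage %s finished in %.1fs: %s", stage, time.time() - t0, counts)


def _require(out: Path, stage: str) -> None:
    for pre in _PREREQ.get(stage, []):
        if not (out / f"manifest_{pre}.json").exists():
            raise DependencyError(f"stage {stage!r} requires {pre!r} to have run first")


def run_pipeline(config: dict, out_dir: str | Path, stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all) against one synthetic bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = stages or STAGE_ORDER
    bad = [s for s in stages if s not in STAGE_ORDER]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    stages = [s for s in STAGE_ORDER if s in stages]
    seed = int(config.get("seed", 0))
    synth_cfg = SyntheticConfig(**{**config.get("synth", {}), "seed": seed})

    bundle = None

    def get_bundle():
        nonlocal bundle
        if bundle is None:
            bundle = generate_bundle(synth_cfg)
        return bundle

    for stage in stages:
        _require(out, stage)
        t0 = time.time()
        counts: dict = {}
        if stage == "synth":
            b = get_bundle()
            for m, df in b.gene_effects.items():
                dsio.write_matrix(df, out / f"gene_effects_{m}.csv")
            for m, df in b.reagent_lfc.items():
                dsio.write_matrix(df, out / f"reagent_lfc_{m}.csv")
                b.reagent_map[m].to_csv(out / f"reagent_map_{m}.csv")
            dsio.write_matrix(b.features.values, out / "features.csv")
            b.features.metadata.to_csv(out / "feature_metadata.csv")
            dsio.write_truth(b.truth, out / "truth.json")
            dsio.write_gene_sets(
                {f"module_{i}": m for i, m in enumerate(b.truth.modules)},
                out / "modules.gmt",
            )
            counts = {"cell_lines": synth_cfg.n_cell_lines, "genes": synth_cfg.n_genes}
        elif stage == "qc":
            b = get_bundle()
            ess = set(b.truth.genes_of("pan"))
            non = set(b.truth.genes_of("non_dependent"))
            for m in b.reagent_lfc:
                rep = qc_mod.qc_report(b.reagent_lfc[m], b.reagent_map[m], ess, non)
                rep.per_line.to_csv(out / f"qc_per_line_{m}.tsv", sep="\t")
                rep.per_gene.to_csv(out / f"qc_per_gene_{m}.tsv", sep="\t")
            counts = {"modalities": len(b.reagent_lfc)}
        elif stage == "classify":
            b = get_bundle()
            null_set = set(b.truth.non_expressed)
            for m, eff in b.gene_effects.items():
                ranks = cls.normalized_ranks(eff)
                pan = cls.pan_dependency_call(ranks)
                prob = cls.probability_of_dependency(eff, null_set, set(pan.is_pan.index[pan.is_pan]))
                sel = cls.lrt_selectivity(eff)
                hv = cls.high_variance_call(prob, null_set)
                stats = cls.dependency_statistics(eff, prob, pan, sel, hv)
                table = cls.classify_dependency(stats)
                table.to_csv(out / f"dependency_classes_{m}.tsv", sep="\t")
                dsio.write_matrix(prob, out / f"dependency_probability_{m}.csv")
                counts[m] = table["dependency_class"].value_counts().to_dict()
            ta = pd.read_csv(out / "dependency_classes_A.tsv", sep="\t", index_col=0)
            tb = pd.read_csv(out / "dependency_classes_B.tsv", sep="\t", index_col=0)
            _, contingency = cls.map_classes_cross_perturbation(ta, tb)
            contingency.to_csv(out / "class_mapping_AB.tsv", sep="\t")
        elif stage == "predict":
            b = get_bundle()
            features = b.features
            eff = b.gene_effects["A"]
            prob = dsio.read_matrix(out / "dependency_probability_A.csv")
            targets = config.get("predict", {}).get("targets") or [
                g for g, m in b.truth.mechanism.items() if m != "none"
            ]
            rows = []
            for g in targets:
                res = {
                    "related": fit_dependency_model(
                        g, eff[g], features, "related", b.priors,
                        dependent_lines=prob[g] > 0.5, seed=seed,
                    )
                }
                assign = assign_biomarker_class(res, features, eff[g], b.priors)
                rows.append(
                    {
                        "gene": g,
                        "accuracy": res["related"].accuracy,
                        "top_feature": res["related"].top_feature,
                        "classes": ";".join(assign.classes),
                    }
                )
            pd.DataFrame(rows).set_index("gene").to_csv(out / "biomarker_models.tsv", sep="\t")
            counts = {"models": len(rows)}
        elif stage == "drugs":
            b = get_bundle()
            prob = dsio.read_matrix(out / "dependency_probability_A.csv")
            gene_filter = list(prob.columns[(prob > 0.5).sum(axis=0) >= 3])
            table = drug_mod.correlate_drug_doses(b.drugs, b.gene_effects["A"], gene_filter)
            table.long.to_csv(out / "drug_gene_correlations.tsv", sep="\t", index=False)
            rec = drug_mod.target_recovery_fraction(table.long, b.drugs.targets, k=5)
            rec["per_dose"].to_csv(out / "drug_target_recovery.tsv", sep="\t")
            counts = {"drugs": len(b.drugs.drugs), "recovery_overall": rec["overall"]}
        elif stage == "network":
            b = get_bundle()
            prob = dsio.read_matrix(out / "dependency_probability_A.csv")
            gene_filter = list(prob.columns[(prob > 0.5).sum(axis=0) >= 3])
            nets = {
                m: net_mod.correlation_similarity(b.gene_effects[m], gene_filter)
                for m in ("A", "B")
            }
            fused = net_mod.snf_fuse(nets["A"], nets["B"])
            dsio.write_matrix(fused.weights, out / "network_fused.tsv")
            enr = net_mod.related_enrichment(fused, b.priors)
            enr.per_gene.to_csv(out / "network_enrichment.tsv", sep="\t")
            counts = {"genes": len(fused.genes), "rank_counts": enr.rank_counts}
        _manifest(out, stage, config, seed, t0, counts)
    return out
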