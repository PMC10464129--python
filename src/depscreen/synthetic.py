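"""Synthetic paired-modality dependency screens with planted ground truth.

The generator emulates the statistical structure of genome-scale
loss-of-function screens across a panel of cancer cell lines, scaled so the
median nonessential gene-effect is ~0 and the median core-essential effect
is ~-1.  Two modalities are produced from the same planted truth:

* modality ``A`` (knockout-like): full on-target efficacy;
* modality ``B`` (knockdown-like): attenuated — pan-dependent genes get a
  shrunken mean and inflated variance, selective effects are shallower.

Gene archetypes (pan-dependent, strongly selective, high-variance, weakly
selective, non-dependent) are planted per gene, along with biomarker
mechanisms, drug-target couplings, and correlated gene modules, so every
downstream statistic can be validated against known truth.

Randomness is organised as one root seed with per-purpose, per-gene child
streams: structural latents (which lines are dependent, high-variance
gradients, module profiles) are shared between modalities, while
measurement noise is modality-specific.  Adding genes to a configuration
does not perturb the columns of existing genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DrugResponseTensor,
    FeatureMatrix,
    SyntheticBundle,
    SyntheticTruth,
)

ARCHETYPES = (
    "pan",
    "strongly_selective",
    "high_variance",
    "weakly_selective",
    "non_dependent",
)

# stream tags: keep stable so adding purposes never reshuffles existing draws
_TAGS = {
    "structure": 0,
    "noise_A": 1,
    "noise_B": 2,
    "reagent": 3,
    "omics": 4,
    "drug": 5,
    "missing": 6,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study-design parameters for one synthetic bundle.

    Defaults mirror a ~400-line pan-cancer panel screened genome-wide,
    with gene effects on the conventional scale (nonessential ~ 0,
    core-essential ~ -1).
    """

    n_cell_lines: int = 400
    n_genes: int = 1000
    fractions: dict[str, float] = field(
        default_factory=lambda: {
            "pan": 0.10,
            "strongly_selective": 0.10,
            "high_variance": 0.10,
            "weakly_selective": 0.10,
            "non_dependent": 0.60,
        }
    )
    pan_effect_mean: float = -1.0
    noise_sd: float = 0.15
    selective_fraction_dependent: float = 0.05
    reagents_per_gene: dict[str, int] = field(default_factory=lambda: {"A": 4, "B": 8})
    reagent_noise_sd: float = 0.3
    offtarget_rate: dict[str, float] = field(default_factory=lambda: {"A": 0.02, "B": 0.10})
    n_drugs: int = 50
    n_doses: int = 16
    seed: int = 0
    # modality-B attenuation: multiplicative mean shrinkage plus additive
    # variance inflation for pan genes
    attenuation: float = 0.6
    pan_sd_inflation: float = 0.25
    # planted correlated modules (drawn from high-variance genes)
    n_modules: int = 5
    module_size: int = 10
    module_coupling: float = 0.85
    # biomarker mechanisms planted per type
    mechanism_counts: dict[str, int] = field(
        default_factory=lambda: {
            "genetic_driver": 10,
            "expression_addiction": 10,
            "paralog": 10,
            "cyclops": 10,
        }
    )
    # fraction of non-dependent genes that are transcriptionally silent
    non_expressed_fraction: float = 0.4
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"archetype fractions sum to {total}, expected 1")
        if any(not (0.0 <= f <= 1.0) for f in self.fractions.values()):
            raise ConfigurationError("archetype fractions must lie in [0, 1]")
        if self.n_cell_lines <= 0 or self.n_genes <= 0:
            raise ConfigurationError("counts must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")

    # ---- axis labels -------------------------------------------------
    @property
    def cell_lines(self) -> list[str]:
        return [f"CL{i:04d}" for i in range(self.n_cell_lines)]

    @property
    def genes(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


def _rng(seed: int, tag: str, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, _TAGS[tag], *key]))


_PHI = (np.sqrt(5.0) - 1.0) / 2.0


def _assign_archetypes(config: SyntheticConfig) -> dict[str, str]:
    """Archetype per gene via a golden-ratio (Weyl) sequence.

    Deterministic and stable under gene-axis extension (gene i keeps its
    archetype when n_genes grows), with realised proportions within one
    gene of the configured fractions by low-discrepancy.
    """
    cuts = np.cumsum([config.fractions.get(a, 0.0) for a in ARCHETYPES])
    u = (np.arange(1, config.n_genes + 1) * _PHI) % 1.0
    idx = np.digitize(u, cuts[:-1])
    return {g: ARCHETYPES[k] for g, k in zip(config.genes, idx)}


def build_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Assign archetypes, mechanisms, modules, partners — all structure."""
    genes = config.genes
    archetype = _assign_archetypes(config)
    by_arch: dict[str, list[str]] = {a: [] for a in ARCHETYPES}
    for g in genes:
        by_arch[archetype[g]].append(g)

    mechanism = {g: "none" for g in genes}
    selective_pool = list(by_arch["strongly_selective"])
    hv_pool = list(by_arch["high_variance"])
    need_sel = sum(
        config.mechanism_counts.get(m, 0)
        for m in ("genetic_driver", "expression_addiction", "paralog")
    )
    if need_sel > len(selective_pool):
        raise ConfigurationError(
            f"{need_sel} selective-coupled mechanisms requested but only "
            f"{len(selective_pool)} strongly selective genes available"
        )
    if config.mechanism_counts.get("cyclops", 0) > len(hv_pool):
        raise ConfigurationError("more cyclops mechanisms requested than high-variance genes")
    for m in ("genetic_driver", "expression_addiction", "paralog"):
        for _ in range(config.mechanism_counts.get(m, 0)):
            mechanism[selective_pool.pop(0)] = m
    for _ in range(config.mechanism_counts.get("cyclops", 0)):
        mechanism[hv_pool.pop(0)] = "cyclops"

    # paralog partners are inert (non-dependent, expressed) genes
    nd_pool = list(by_arch["non_dependent"])
    paralog_partner: dict[str, str] = {}
    paralog_genes = [g for g in genes if mechanism[g] == "paralog"]
    if len(paralog_genes) > len(nd_pool):
        raise ConfigurationError("not enough non-dependent genes to act as paralog partners")
    for g in paralog_genes:
        paralog_partner[g] = nd_pool.pop(0)

    # planted modules live among the remaining high-variance genes
    n_module_genes = config.n_modules * config.module_size
    if n_module_genes > len(hv_pool):
        raise ConfigurationError(
            f"{config.n_modules} modules of {config.module_size} genes exceed the "
            f"{len(hv_pool)} unassigned high-variance genes"
        )
    modules = [
        set(hv_pool[m * config.module_size : (m + 1) * config.module_size])
        for m in range(config.n_modules)
    ]

    # non-expressed genes: inert non-dependent genes that never sit in a
    # mechanism's path; silent in every cell line
    n_silent = int(round(config.non_expressed_fraction * len(nd_pool)))
    non_expressed = nd_pool[:n_silent]

    # dependent-line sets for selective genes (shared across modalities)
    dependent_lines: dict[str, list[str]] = {}
    lines = config.cell_lines
    n_dep = max(1, int(round(config.selective_fraction_dependent * config.n_cell_lines)))
    for gi, g in enumerate(genes):
        if archetype[g] in ("strongly_selective", "weakly_selective"):
            rng = _rng(config.seed, "structure", 0, gi)
            idx = rng.choice(config.n_cell_lines, size=n_dep, replace=False)
            dependent_lines[g] = [lines[j] for j in sorted(idx)]

    return SyntheticTruth(
        archetype=archetype,
        mechanism=mechanism,
        modules=modules,
        dependent_lines=dependent_lines,
        paralog_partner=paralog_partner,
        non_expressed=non_expressed,
    )


def _module_of(truth: SyntheticTruth) -> dict[str, int]:
    return {g: m for m, mod in enumerate(truth.modules) for g in mod}


def generate_gene_effects(
    config: SyntheticConfig, modality: str = "A", truth: SyntheticTruth | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Scaled gene-effect matrix (cell lines x genes) for one modality."""
    if modality not in ("A", "B"):
        raise ConfigurationError(f"unknown modality {modality!r}")
    if truth is None:
        truth = build_truth(config)
    n, lines, genes = config.n_cell_lines, config.cell_lines, config.genes
    mu, sd = config.pan_effect_mean, config.noise_sd
    shrink = config.attenuation if modality == "B" else 1.0
    module_of = _module_of(truth)

    # shared module gradients (structure stream, one per module)
    module_t = {
        m: _rng(config.seed, "structure", 1, m).beta(2.0, 4.0, size=n)
        for m in range(len(truth.modules))
    }

    out = np.empty((n, config.n_genes))
    noise_tag = f"noise_{modality}"
    line_pos = {c: i for i, c in enumerate(lines)}
    for gi, g in enumerate(genes):
        arch = truth.archetype[g]
        z = _rng(config.seed, noise_tag, gi).standard_normal(n)
        if arch == "pan":
            if modality == "B":
                col = shrink * mu + (sd + config.pan_sd_inflation) * z
            else:
                col = mu + sd * z
        elif arch in ("strongly_selective", "weakly_selective"):
            depth = 1.5 if arch == "strongly_selective" else 0.6
            col = sd * z
            shift = shrink * depth * mu
            for c in truth.dependent_lines[g]:
                col[line_pos[c]] += shift
        elif arch == "high_variance":
            t_own = _rng(config.seed, "structure", 2, gi).beta(2.0, 4.0, size=n)
            if g in module_of:
                w = config.module_coupling
                t = w * module_t[module_of[g]] + (1.0 - w) * t_own
                col = shrink * mu * t + 0.6 * sd * z
            else:
                col = shrink * mu * t_own + sd * z
        else:  # non_dependent
            col = sd * z
        out[:, gi] = col

    df = pd.DataFrame(out, index=lines, columns=genes)
    if config.missing_rate > 0:
        # mask drawn from the structure stream so paired matrices share it
        mask = _rng(config.seed, "missing", 0).random((n, config.n_genes)) < config.missing_rate
        df = df.mask(mask)
    return df, truth


def generate_reagent_lfc(
    gene_effects: pd.DataFrame,
    reagents_per_gene: int,
    reagent_noise_sd: float = 0.3,
    offtarget_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-reagent LFC matrix plus the reagent -> gene map.

    Each reagent is its gene's effect plus a reagent-specific bias and
    noise; a random ``offtarget_rate`` fraction of reagents instead report
    an unrelated gene's profile (total off-target failure).
    """
    if reagents_per_gene < 1:
        raise ConfigurationError("reagents_per_gene must be >= 1")
    if not (0.0 <= offtarget_rate <= 1.0):
        raise ConfigurationError("offtarget_rate must lie in [0, 1]")
    genes = list(gene_effects.columns)
    n = gene_effects.shape[0]
    cols, names, mapped = [], [], []
    for gi, g in enumerate(genes):
        rng = _rng(seed, "reagent", gi)
        for r in range(reagents_per_gene):
            bias = rng.normal(0.0, 0.1)
            noise = rng.normal(0.0, reagent_noise_sd, size=n)
            donor = g
            if rng.random() < offtarget_rate and len(genes) > 1:
                donor = genes[rng.choice([j for j in range(len(genes)) if j != gi])]
            cols.append(gene_effects[donor].to_numpy() + bias + noise)
            names.append(f"{g}_r{r}")
            mapped.append(g)
    lfc = pd.DataFrame(np.column_stack(cols), index=gene_effects.index, columns=names)
    return lfc, pd.Series(mapped, index=names, name="gene")


def generate_omics_features(
    truth: SyntheticTruth,
    gene_effects: pd.DataFrame,
    seed: int = 0,
    n_lineages: int = 4,
) -> FeatureMatrix:
    """Expression / copy-number / mutation / lineage features.

    Mechanism couplings are built from the realised gene effects:

    * ``expression_addiction`` — own expression high where the gene effect
      is negative (dependency driven by the gene's own overexpression);
    * ``cyclops`` — own copy number positively correlated with the effect
      (partial copy loss sensitises to further suppression);
    * ``paralog`` — the designated partner's expression tracks the effect
      (partner loss creates the dependency);
    * ``genetic_driver`` — a hotspot-mutation flag marks the dependent
      lines.

    Everything else is independent noise.  Expression is bimodal: planted
    non-expressed genes sit in a near-zero mode in every line.
    """
    for g in gene_effects.columns:
        if g not in truth.mechanism:
            raise ConfigurationError(f"gene {g} has no mechanism annotation in truth")
    lines = gene_effects.index
    n = len(lines)
    genes = list(gene_effects.columns)
    silent = set(truth.non_expressed)
    arms = [f"{c}{a}" for c in range(1, 23) for a in ("p", "q")]

    values: dict[str, np.ndarray] = {}
    meta_rows: list[tuple[str, str, str, str]] = []

    for gi, g in enumerate(genes):
        rng = _rng(seed, "omics", gi)
        arm = arms[gi % len(arms)]
        eff = gene_effects[g].to_numpy()
        eff0 = np.nan_to_num(eff, nan=0.0)
        mech = truth.mechanism[g]

        # expression
        if g in silent:
            expr = np.abs(rng.normal(0.05, 0.03, size=n))
        elif mech == "expression_addiction":
            expr = 4.0 - 3.0 * eff0 + rng.normal(0.0, 0.5, size=n)
        else:
            expr = rng.normal(rng.uniform(2.0, 8.0), 1.0, size=n)
        values[f"{g}_expr"] = expr
        meta_rows.append((f"{g}_expr", "expression", g, arm))

        # copy number
        if mech == "cyclops":
            cn = 1.0 + 1.2 * (eff0 - eff0.mean()) + rng.normal(0.0, 0.08, size=n)
        else:
            cn = rng.normal(1.0, 0.2, size=n)
        values[f"{g}_cn"] = cn
        meta_rows.append((f"{g}_cn", "copy_number", g, arm))

        # driver mutation flag on the dependent lines (2% label noise)
        if mech == "genetic_driver":
            dep = np.isin(lines, truth.dependent_lines.get(g, []))
            flips = rng.random(n) < 0.02
            values[f"{g}_mut"] = (dep ^ flips).astype(float)
            meta_rows.append((f"{g}_mut", "mutation_hotspot", g, arm))

    # second pass: paralog couplings overwrite the partner's noise column
    # (partners appear later in gene order, so this must run after the loop)
    for gi, g in enumerate(genes):
        if truth.mechanism[g] == "paralog":
            partner = truth.paralog_partner[g]
            eff0 = np.nan_to_num(gene_effects[g].to_numpy(), nan=0.0)
            prng = _rng(seed, "omics", len(genes) + 100 + gi)
            values[f"{partner}_expr"] = 3.0 + 3.0 * eff0 + prng.normal(0.0, 0.5, size=n)

    # lineage annotation, one-hot downstream
    lin_rng = _rng(seed, "omics", len(genes) + 1)
    lineage = lin_rng.integers(0, n_lineages, size=n)
    for lv in range(n_lineages):
        values[f"lineage_{lv}"] = (lineage == lv).astype(float)
        meta_rows.append((f"lineage_{lv}", "lineage", "", ""))

    vdf = pd.DataFrame(values, index=lines)
    meta = pd.DataFrame(
        meta_rows, columns=["feature", "source_type", "subject_gene", "chr_arm"]
    ).set_index("feature")
    meta = meta.loc[~meta.index.duplicated()]
    return FeatureMatrix(vdf, meta.loc[vdf.columns])


def generate_drug_response(
    truth: SyntheticTruth,
    gene_effects: pd.DataFrame,
    n_doses: int = 16,
    seed: int = 0,
    n_drugs: int = 50,
    confound_weight: float = 1.0,
    drug_noise_sd: float = 0.3,
) -> DrugResponseTensor:
    """Dose-level drug responses that are noisy transforms of target effects.

    Mid-range doses carry the target signal (weight peaking at the centre
    dose), the lowest quarter of doses is pure noise, and the highest
    quarter is near-uniform toxicity.  A shared growth-rate-like confound
    is added to all drugs, to be removed downstream via PC1 regression.
    """
    if n_doses < 3:
        raise ConfigurationError("n_doses must be >= 3")
    candidates = [
        g
        for g in gene_effects.columns
        if truth.archetype.get(g) in ("strongly_selective", "high_variance")
    ]
    if not candidates:
        raise ConfigurationError("no selective/high-variance genes available as drug targets")
    rng = _rng(seed, "drug", 0)
    targets = [candidates[i] for i in rng.choice(len(candidates), size=n_drugs, replace=n_drugs > len(candidates))]
    for t in targets:
        if t not in gene_effects.columns:
            raise ConfigurationError(f"drug target {t} absent from gene axis")

    n = gene_effects.shape[0]
    confound = _rng(seed, "drug", 1).standard_normal(n) * 0.5
    lo, hi = n_doses // 4, (3 * n_doses) // 4
    centre = n_doses // 2

    def signal_weight(d: int) -> float:
        if d < lo or d >= hi:
            return 0.0
        return max(0.0, 1.0 - abs(d - centre) / max(1, (hi - lo) // 2))

    drugs = [f"D{i:03d}" for i in range(n_drugs)]
    vals = np.empty((n_drugs, n_doses, n))
    for i, (drug, tgt) in enumerate(zip(drugs, targets)):
        eff = np.nan_to_num(gene_effects[tgt].to_numpy(), nan=0.0)
        drng = _rng(seed, "drug", 2, i)
        for d in range(n_doses):
            noise = drng.normal(0.0, drug_noise_sd, size=n)
            if d >= hi:  # uniform toxicity, low variance
                vals[i, d] = -2.0 + 0.05 * noise / drug_noise_sd + 0.1 * confound
            else:
                vals[i, d] = signal_weight(d) * eff + confound_weight * confound + noise
    return DrugResponseTensor(
        values=vals,
        drugs=drugs,
        doses=list(np.arange(1.0, n_doses + 1.0)),
        cell_lines=list(gene_effects.index),
        targets={d: [t] for d, t in zip(drugs, targets)},
    )


def generate_related_priors(
    truth: SyntheticTruth,
    n_modules: int | None = None,
    module_size: int | None = None,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Known-relation sets: module co-members plus paralog pairs."""
    modules = truth.modules
    if n_modules is not None:
        if n_modules > len(modules):
            raise ConfigurationError(
                f"{n_modules} modules requested but only {len(modules)} planted"
            )
        modules = modules[:n_modules]
    if module_size is not None and any(len(m) != module_size for m in modules):
        raise ConfigurationError("planted module sizes do not match requested module_size")
    priors: dict[str, set[str]] = {}
    for mod in modules:
        for g in mod:
            priors.setdefault(g, set()).update(mod - {g})
    for g, p in truth.paralog_partner.items():
        priors.setdefault(g, set()).add(p)
        priors.setdefault(p, set()).add(g)
    return priors


def generate_bundle(config: SyntheticConfig) -> SyntheticBundle:
    """The full paired study: effects, reagents, omics, drugs, priors."""
    truth = build_truth(config)
    effects = {}
    for mod in ("A", "B"):
        effects[mod], _ = generate_gene_effects(config, mod, truth=truth)
    reagent_lfc, reagent_map = {}, {}
    for mod in ("A", "B"):
        lfc, rmap = generate_reagent_lfc(
            effects[mod],
            config.reagents_per_gene[mod],
            config.reagent_noise_sd,
            config.offtarget_rate[mod],
            seed=config.seed + (1 if mod == "B" else 0),
        )
        reagent_lfc[mod], reagent_map[mod] = lfc, rmap
    features = generate_omics_features(truth, effects["A"], seed=config.seed)
    drugs = generate_drug_response(
        truth,
        effects["A"],
        n_doses=config.n_doses,
        seed=config.seed,
        n_drugs=config.n_drugs,
    )
    truth.drug_targets = drugs.targets
    priors = generate_related_priors(truth)
    return SyntheticBundle(
        gene_effects=effects,
        reagent_lfc=reagent_lfc,
        reagent_map=reagent_map,
        features=features,
        drugs=drugs,
        priors=priors,
        truth=truth,
    )
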