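"""Shared in-memory containers.

Gene-effect and reagent matrices are plain :class:`pandas.DataFrame` objects
with cell lines as rows and genes (or reagents) as columns; that convention
is used everywhere in the package.  The containers below wrap the few
objects that need metadata riding along with their values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical dependency class labels, in no particular order
DEPENDENCY_CLASSES = (
    "non_dependent",
    "weakly_selective",
    "strongly_selective",
    "pan_dependent",
    "high_variance",
)

#: biomarker mechanisms the synthetic generator can plant
MECHANISMS = ("none", "genetic_driver", "expression_addiction", "paralog", "cyclops")


@dataclass
class FeatureMatrix:
    """Cell lines x features with per-feature metadata.

    ``values`` holds the numeric payload; ``metadata`` is indexed by feature
    name with columns ``source_type`` (expression / copy_number /
    mutation_damaging / mutation_missense / mutation_hotspot / fusion /
    lineage / confounder), ``subject_gene`` (the gene the feature measures,
    empty string if none) and ``chr_arm`` (synthetic chromosome-arm tag).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"features missing metadata: {sorted(missing)[:5]}")

    @property
    def cell_lines(self) -> pd.Index:
        return self.values.index

    def features_of(self, gene: str, source_types: tuple[str, ...] | None = None) -> list[str]:
        """Names of features whose subject is ``gene``."""
        meta = self.metadata.loc[self.metadata["subject_gene"] == gene]
        if source_types is not None:
            meta = meta.loc[meta["source_type"].isin(source_types)]
        return [f for f in meta.index if f in self.values.columns]

    def subset(self, features: list[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values[features], self.metadata.loc[features])


@dataclass
class DrugResponseTensor:
    """Drug x dose x cell-line viability responses (lower = more killing)."""

    values: np.ndarray  # (n_drugs, n_doses, n_lines)
    drugs: list[str]
    doses: list[float]
    cell_lines: list[str]
    targets: dict[str, list[str]]  # drug -> annotated target genes

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.drugs), len(self.doses), len(self.cell_lines)):
            raise ValueError("tensor shape does not match axis lengths")
        if list(self.doses) != sorted(self.doses):
            raise ValueError("dose axis must be ordered low to high")

    def dose_matrix(self, dose_index: int) -> pd.DataFrame:
        """Cell lines x drugs matrix at one dose level."""
        return pd.DataFrame(
            self.values[:, dose_index, :].T, index=self.cell_lines, columns=self.drugs
        )

    def to_long(self) -> pd.DataFrame:
        recs = []
        for i, drug in enumerate(self.drugs):
            for j, dose in enumerate(self.doses):
                for k, line in enumerate(self.cell_lines):
                    recs.append((drug, dose, line, self.values[i, j, k]))
        return pd.DataFrame(recs, columns=["drug", "dose", "cell_line", "response"])


@dataclass
class SimilarityNetwork:
    """Symmetric weighted gene x gene network."""

    weights: pd.DataFrame
    kind: str  # raw_correlation | knn_sparse | fused

    def __post_init__(self) -> None:
        w = self.weights
        if not w.index.equals(w.columns):
            raise ValueError("similarity network must be square with matching axes")

    @property
    def genes(self) -> pd.Index:
        return self.weights.index


@dataclass
class SyntheticTruth:
    """Planted ground truth for a synthetic bundle."""

    archetype: dict[str, str]  # gene -> archetype label
    mechanism: dict[str, str]  # gene -> biomarker mechanism
    drug_targets: dict[str, list[str]] = field(default_factory=dict)
    modules: list[set[str]] = field(default_factory=list)
    dependent_lines: dict[str, list[str]] = field(default_factory=dict)
    paralog_partner: dict[str, str] = field(default_factory=dict)
    non_expressed: list[str] = field(default_factory=list)

    def genes_of(self, archetype: str) -> list[str]:
        return [g for g, a in self.archetype.items() if a == archetype]

    def genes_with_mechanism(self, mechanism: str) -> list[str]:
        return [g for g, m in self.mechanism.items() if m == mechanism]


@dataclass
class SyntheticBundle:
    """Everything one paired-modality study produces."""

    gene_effects: dict[str, pd.DataFrame]  # modality -> lines x genes
    reagent_lfc: dict[str, pd.DataFrame]  # modality -> lines x reagents
    reagent_map: dict[str, pd.Series]  # modality -> reagent -> gene
    features: FeatureMatrix | None
    drugs: DrugResponseTensor | None
    priors: dict[str, set[str]]  # gene -> related genes
    truth: SyntheticTruth
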