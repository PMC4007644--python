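"""Growth-phenotype matrices and model clustering.

Wildtype models are screened over a carbon-source x electron-acceptor
grid with identical medium conventions; each cell is a qualitative
growth call, and per-cell counts say how many strains in the family can
grow there.  Models are then clustered hierarchically — either on their
binary gene-content profiles (which ortholog groups are present) or on
their binary phenotype profiles (which conditions support growth) — with
euclidean distances, so that genetic similarity and functional
similarity can be contrasted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import pdist, squareform

from .fba import (
    GrowthCondition,
    MediumSpec,
    NotRepresentableError,
    is_growth,
    maximize_growth,
    set_medium,
)
from .model import MetabolicModel
from .orthologs import OrthologTable

__all__ = [
    "PhenotypeMatrix",
    "ClusterResult",
    "growth_phenotype_matrix",
    "gene_content_matrix",
    "cluster_models",
]


@dataclass
class PhenotypeMatrix:
    """Per-strain binary growth layers plus a per-cell strain count.

    ``layers[model_id]`` is a carbon x acceptor DataFrame of 0/1 growth
    calls; ``counts`` sums the layers cell-wise.
    """

    layers: Dict[str, pd.DataFrame]
    counts: pd.DataFrame
    not_representable: List[Tuple[str, str]]  # (model id, compound)

    def layer(self, model_id: str) -> pd.DataFrame:
        return self.layers[model_id]

    def to_tsv(self, directory: str) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        for model_id, layer in self.layers.items():
            layer.to_csv(os.path.join(directory, f"phenotype_{model_id}.tsv"),
                         sep="\t")
        self.counts.to_csv(os.path.join(directory, "phenotype_counts.tsv"),
                           sep="\t")


def growth_phenotype_matrix(
    models: Sequence[MetabolicModel],
    carbon_sources: Sequence[str],
    electron_acceptors: Sequence[str],
    nitrogen_source: str = "nh4",
    spec: MediumSpec = MediumSpec(),
) -> PhenotypeMatrix:
    """FBA growth calls for every model over the condition grid.

    All models see the same exchange-bound conventions.  A compound a
    model cannot exchange scores 0 (no growth) rather than missing, and
    the (model, compound) pair is recorded in ``not_representable``.
    """
    if not carbon_sources or not electron_acceptors:
        raise ValueError("carbon source and electron acceptor lists must be non-empty")
    layers: Dict[str, pd.DataFrame] = {}
    not_representable: List[Tuple[str, str]] = []
    for model in models:
        grid = np.zeros((len(carbon_sources), len(electron_acceptors)), dtype=int)
        for i, carbon in enumerate(carbon_sources):
            for j, acceptor in enumerate(electron_acceptors):
                condition = GrowthCondition(carbon, acceptor, nitrogen_source)
                try:
                    constrained = set_medium(model, condition, spec)
                except NotRepresentableError as err:
                    not_representable.append((model.id, err.compound))
                    continue
                if is_growth(maximize_growth(constrained)):
                    grid[i, j] = 1
        layers[model.id] = pd.DataFrame(
            grid, index=list(carbon_sources), columns=list(electron_acceptors)
        )
    counts = sum(layers.values())
    return PhenotypeMatrix(layers=layers, counts=counts,
                           not_representable=sorted(set(not_representable)))


def gene_content_matrix(
    models: Sequence[MetabolicModel],
    table: Optional[OrthologTable] = None,
    drop_identical_rows: bool = False,
) -> pd.DataFrame:
    """Binary presence matrix: ortholog group (rows) x model (columns).

    With a table, an entry is 1 iff the group has a functional member
    among the model's genes (model ids must match table strain ids);
    without one, gene ids themselves are the rows.  Rows identical across
    all models can be dropped for display — identical coordinates
    contribute nothing to euclidean distances, so clustering is
    unaffected.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    columns = {}
    if table is not None:
        all_groups = sorted(table.groups)
        for model in models:
            gene2group = table.gene_to_group(model.id)
            present = {gene2group[g] for g in model.genes if g in gene2group}
            columns[model.id] = [1 if gid in present else 0 for gid in all_groups]
        matrix = pd.DataFrame(columns, index=all_groups)
    else:
        all_genes = sorted(set().union(*[model.genes for model in models]))
        for model in models:
            genes = model.genes
            columns[model.id] = [1 if g in genes else 0 for g in all_genes]
        matrix = pd.DataFrame(columns, index=all_genes)
    if drop_identical_rows:
        keep = matrix.nunique(axis=1) > 1
        matrix = matrix.loc[keep]
    return matrix


@dataclass
class ClusterResult:
    """Hierarchical clustering of model profile columns."""

    labels: List[str]
    distance_matrix: pd.DataFrame
    linkage_matrix: np.ndarray
    newick: str

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def first_merge_pair(self) -> frozenset:
        """The two model ids joined at the lowest merge height."""
        left, right = int(self.linkage_matrix[0, 0]), int(self.linkage_matrix[0, 1])
        return frozenset([self.labels[left], self.labels[right]])

    def merge_order(self) -> List[frozenset]:
        """Leaf-label sets of each merge, in height order."""
        n = len(self.labels)
        clusters: Dict[int, frozenset] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        order = []
        for step, (a, b, _h, _c) in enumerate(self.linkage_matrix):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + step] = merged
            order.append(merged)
        return order


def cluster_models(
    binary_matrix: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of the matrix columns (one per model).

    Euclidean distance on the binary profile vectors, average linkage by
    default (the distance metric is the scientifically pinned choice; the
    linkage is configurable).  Columns are ordered lexicographically
    before clustering so tie-breaks are deterministic.  The dendrogram is
    also rendered as a Newick string with branch lengths.
    """
    if binary_matrix.shape[1] < 2:
        raise ValueError("need at least two model columns to cluster")
    matrix = binary_matrix[sorted(binary_matrix.columns)]
    labels = list(matrix.columns)
    profiles = matrix.to_numpy().T.astype(float)
    condensed = pdist(profiles, metric=metric)
    Z = linkage(condensed, method=method, metric=metric)
    dist = pd.DataFrame(squareform(condensed), index=labels, columns=labels)
    newick = _linkage_to_newick(Z, labels)
    return ClusterResult(
        labels=labels, distance_matrix=dist, linkage_matrix=Z, newick=newick
    )


def _linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    tree = to_tree(Z, rd=False)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(tree.get_left(), tree.dist)},{render(tree.get_right(), tree.dist)});"
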