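"""SVM-weight feature importance: ranks, percentile subsets, subnetworks.

Feature weights from the representative linear-SVM model are ordered into
an importance rank (1 = largest positive weight, associated with the
positive class; last = largest negative weight). Percentile subsets are
taken conservatively under ties: the cutoff for the Xth percentile of
positive features is the smallest weight *above* which lie X% or less of
all features, so a tie straddling the cutoff shrinks the subset rather
than inflating it (and symmetrically for negative features). Top-decile
features from multiple models are recombined into reduced feature matrices
and projected into TF-TF importance networks whose connected components
are the regulatory modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .classify import build_feature_matrix
from .enrichment import ContingencyTable2x2, fisher_exact

logger = logging.getLogger(__name__)


def percentile_threshold(weights: pd.Series, X: float,
                         side: str = "positive") -> list[str]:
    """Features in the top (or bottom) Xth percentile of weights,
    conservative under ties.

    Positive side: features with weight strictly above the smallest weight
    w* such that |{f : weight(f) > w*}| ≤ X% of all features. Negative side
    is the exact mirror (strictly below the largest qualifying weight).
    """
    if not (0 < X <= 50):
        raise ValueError("X must lie in (0, 50]")
    if side not in ("positive", "negative"):
        raise ValueError("side must be 'positive' or 'negative'")
    w = weights.astype(float)
    if w.nunique() == 1:
        logger.warning("all weights equal; percentile subset is empty")
        return []
    vals = w.to_numpy()
    if side == "negative":
        vals = -vals
    budget = X / 100.0 * len(vals)
    # smallest cutoff (in the mirrored scale) admitting ≤ budget features
    for cut in np.sort(np.unique(vals)):
        n_above = int((vals > cut).sum())
        if n_above <= budget:
            mask = vals > cut
            return [f for f, m in zip(w.index, mask) if m]
    return []


@dataclass
class ImportanceTable:
    """Weight, rank and percentile membership for every feature of a model."""

    weights: pd.Series
    ranks: pd.Series
    top10: frozenset[str]
    top25: frozenset[str]
    bottom10: frozenset[str]
    bottom25: frozenset[str]

    @classmethod
    def from_weights(cls, weights: pd.Series) -> "ImportanceTable":
        order = weights.sort_values(ascending=False, kind="mergesort")
        ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index
                          ).reindex(weights.index)
        return cls(
            weights=weights,
            ranks=ranks,
            top10=frozenset(percentile_threshold(weights, 10, "positive")),
            top25=frozenset(percentile_threshold(weights, 25, "positive")),
            bottom10=frozenset(percentile_threshold(weights, 10, "negative")),
            bottom25=frozenset(percentile_threshold(weights, 25, "negative")),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "weight": self.weights,
            "rank": self.ranks,
            "top10": [f in self.top10 for f in self.weights.index],
            "top25": [f in self.top25 for f in self.weights.index],
            "bottom10": [f in self.bottom10 for f in self.weights.index],
            "bottom25": [f in self.bottom25 for f in self.weights.index],
        })


def combine_important_features(subsets: dict[str, list[str]],
                               sources, genes=None) -> pd.DataFrame:
    """Reduced feature matrix from the union of important-feature subsets.

    ``subsets`` maps a dataset tag to the selected (already tagged) feature
    names; ``sources`` is the same (tag, GRN|FFL-set) list used to build
    the full matrices. Columns keep their dataset tags, so the same TF
    selected from two datasets stays two distinct features; gene rows are
    re-filtered to those with at least one selected feature.
    """
    keep = set()
    for tag, feats in subsets.items():
        keep.update(feats)
    if not keep:
        raise ValueError("combined important-feature set is empty")
    full = build_feature_matrix(sources, genes=genes)
    cols = [c for c in full.columns if c in keep]
    if not cols:
        raise ValueError("no selected feature exists in the given sources")
    out = full[cols]
    out = out.loc[out.sum(axis=1) > 0]
    if out.empty:
        raise ValueError("no gene retains a feature after combination")
    return out


def _feature_nodes(feature: str) -> tuple[str, ...]:
    """TF node(s) of a (possibly tagged) feature id."""
    name = feature.split(":", 1)[-1]
    if "->" in name:
        a, b = name.split("->", 1)
        return (a, b)
    return (name,)


@dataclass
class ImportanceGRN:
    """TF network of top-decile features, with per-edge phase annotation."""

    graph: nx.DiGraph
    modules: list[frozenset[str]] = field(default_factory=list)

    @property
    def isolated_nodes(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.degree(n) == 0]

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v,
             "phases": ",".join(sorted(d.get("phases", ())))}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "phases"])


def build_importance_grn(general_table: ImportanceTable,
                         phase_tables: dict[str, ImportanceTable] | None = None
                         ) -> ImportanceGRN:
    """Importance network from the general model's top-decile features.

    TF-TF pair features become directed edges; single-TF features become
    (possibly isolated) nodes. Each edge/node is annotated with the phases
    in whose model the same feature is also top-decile. Modules are the
    connected components of the undirected projection, excluding
    singletons.
    """
    phase_tables = phase_tables or {}
    g = nx.DiGraph()
    top = general_table.top10
    if not top:
        logger.warning("general model has an empty top-decile set")
    for feat in sorted(top):
        phases = frozenset(ph for ph, tab in phase_tables.items()
                           if feat in tab.top10)
        nodes = _feature_nodes(feat)
        if len(nodes) == 2:
            g.add_edge(nodes[0], nodes[1], phases=phases, feature=feat)
        else:
            g.add_node(nodes[0])
            g.nodes[nodes[0]]["phases"] = phases
            g.nodes[nodes[0]]["feature"] = feat
    comps = [frozenset(c) for c in
             nx.connected_components(g.to_undirected()) if len(c) > 1]
    return ImportanceGRN(graph=g, modules=sorted(comps, key=sorted))


def known_regulator_enrichment(top_tfs: set[str], annotated: set[str],
                               all_tfs: set[str]) -> float:
    """One-sided Fisher p for over-representation of annotated regulators
    among the top TF features."""
    if not all_tfs:
        raise ValueError("empty TF universe")
    if not annotated <= all_tfs:
        raise ValueError("annotated set must be a subset of the universe")
    a = len(top_tfs & annotated)
    b = len(top_tfs - annotated)
    c = len(annotated - top_tfs)
    d = len(all_tfs - top_tfs - annotated)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0  # a degenerate margin carries no enrichment signal
    return fisher_exact(ContingencyTable2x2(a, b, c, d), sidedness="greater")
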