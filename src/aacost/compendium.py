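"""Comparison of amino acid cost measures.

Bundles eight literature and FBA-derived cost measures for the 20 standard
amino acids, computes pairwise Spearman rank correlation matrices, clusters
cost types by complete-linkage agglomeration on distance 1 - R, and
compares cost tables across species or models.
"""
from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
from scipy import stats

from .cost_estimation import CostTable

#: Column labels of the bundled compendium, in table order.
COMPENDIUM_COLUMNS = ("abs_glc", "rel_glc", "ag_energy", "cw_energy",
                      "cw_steps", "wagner_ferm", "wagner_resp", "mol_weight")

#: The six literature measures (everything except the FBA-derived pair).
LITERATURE_COLUMNS = COMPENDIUM_COLUMNS[2:]

_UNITS = {
    "abs_glc": "unitless", "rel_glc": "mmol/gDW", "ag_energy": "~P bonds",
    "cw_energy": "~P bonds", "cw_steps": "steps", "wagner_ferm": "~P bonds",
    "wagner_resp": "~P bonds", "mol_weight": "Da",
}
_PROVENANCE = {
    "abs_glc": "FBA absolute cost, glucose limitation, S. cerevisiae iND750",
    "rel_glc": "FBA relative cost, glucose limitation, S. cerevisiae iND750",
    "ag_energy": "Akashi & Gojobori (2002) energetic cost",
    "cw_energy": "Craig & Weber (1998) energetic cost",
    "cw_steps": "Craig & Weber (1998) biosynthetic steps",
    "wagner_ferm": "Wagner (2005) fermentative cost",
    "wagner_resp": "Wagner (2005) respiratory cost",
    "mol_weight": "molecular weight (Seligmann 2003)",
}


def load_compendium() -> CostTable:
    """The bundled 20 x 8 cost compendium (printed 3-s.f. values)."""
    with importlib.resources.files("aacost.data").joinpath(
            "cost_compendium.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t", comment="#", index_col="residue")
    return CostTable(values=frame, units=dict(_UNITS), provenance=dict(_PROVENANCE))


@dataclass
class CostCorrelationMatrix:
    """Pairwise Spearman correlations (and p-values) between cost types."""

    labels: list[str]
    r: pd.DataFrame
    p: pd.DataFrame


def correlation_matrix(table: CostTable,
                       method: str = "spearman") -> CostCorrelationMatrix:
    """Pairwise correlations between cost types.

    ``method`` is ``"spearman"`` (rank correlation, average ranks for ties)
    or ``"pearson"`` (product-moment).  Pairwise-complete observations are
    used when residues are missing; a constant column yields NaN
    correlations with a warning.  p-values are two-sided via the
    t-distribution approximation.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    frame = table.values
    labels = list(frame.columns)
    if len(labels) < 2:
        raise ValueError("need at least two cost columns")
    k = len(labels)
    r = np.eye(k)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(p, 1.0)
    for a in range(k):
        for b in range(a + 1, k):
            pair = frame.iloc[:, [a, b]].dropna()
            xa, xb = pair.iloc[:, 0], pair.iloc[:, 1]
            if xa.nunique() < 2 or xb.nunique() < 2:
                warnings.warn(
                    f"constant column in pair ({labels[a]}, {labels[b]}); "
                    "correlation undefined", stacklevel=2)
                r[a, b] = r[b, a] = np.nan
                continue
            res = corr(xa, xb)
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    return CostCorrelationMatrix(
        labels=labels,
        r=pd.DataFrame(r, index=labels, columns=labels),
        p=pd.DataFrame(p, index=labels, columns=labels),
    )


def spearman_matrix(table: CostTable) -> CostCorrelationMatrix:
    """Spearman rank correlation matrix between cost types."""
    return correlation_matrix(table, method="spearman")


@dataclass
class Dendrogram:
    """Complete-linkage tree over cost types with merge heights."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def smallest_cluster_containing(self, *labels: str) -> set[str]:
        """Members of the lowest merge node containing all given labels."""
        want = set(labels)
        n = len(self.labels)
        members = {i: {self.labels[i]} for i in range(n)}
        for step, (a, b, _h, _cnt) in enumerate(self.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            if want <= merged:
                return merged
        raise ValueError(f"labels {want} not all present")  # pragma: no cover

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for step, (a, b, h, _cnt) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + step] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + step] = h
        return node[n + len(self.linkage) - 1] + ";"


def cluster_cost_types(matrix: CostCorrelationMatrix,
                       distance: str = "one_minus_r") -> Dendrogram:
    """Complete-linkage agglomeration of cost types on distance d = 1 - R.

    Anti-correlated measures are maximally dissimilar under this transform
    (``distance="one_minus_abs_r"`` treats them as similar instead).
    """
    r = matrix.r.to_numpy()
    if np.isnan(r).any():
        raise ValueError("correlation matrix contains undefined entries")
    d = 1.0 - (np.abs(r) if distance == "one_minus_abs_r" else r)
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    condensed = scipy.spatial.distance.squareform(d, checks=False)
    linkage = scipy.cluster.hierarchy.linkage(condensed, method="complete")
    return Dendrogram(labels=list(matrix.labels), linkage=linkage)


def compare_cost_tables(a: CostTable, b: CostTable) -> pd.DataFrame:
    """Per-cost-type Spearman R between two tables joined on residue.

    Returns a frame indexed by the shared cost types with columns
    ``r``, ``p`` and ``n_residues``.
    """
    shared_cols = [c for c in a.values.columns if c in b.values.columns]
    if not shared_cols:
        raise ValueError("no shared cost types")
    shared_residues = a.values.index.intersection(b.values.index)
    if len(shared_residues) < 5:
        raise ValueError(f"only {len(shared_residues)} shared residues (need >= 5)")
    rows = []
    for col in shared_cols:
        pair = pd.DataFrame({
            "a": a.values.loc[shared_residues, col],
            "b": b.values.loc[shared_residues, col],
        }).dropna()
        res = stats.spearmanr(pair["a"], pair["b"])
        rows.append((col, res.statistic, res.pvalue, len(pair)))
    return pd.DataFrame(rows, columns=["cost_type", "r", "p", "n_residues"]
                        ).set_index("cost_type")
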