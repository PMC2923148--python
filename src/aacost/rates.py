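"""Per-site amino acid substitution rates on a fixed 4-taxon tree.

Each alignment column's rate is a maximum-likelihood multiplier rho that
scales all branch lengths of the gene tree under an empirical amino acid
model (WAG by default, or a null model with identical exchange rates).
Column likelihoods are computed with Felsenstein's pruning algorithm; the
ancestral residue is the marginal reconstruction at the root.  Gene branch
lengths are fitted by ML under a rate-homogeneous model, and per-site rates
are then normalized by the gene's tree length (sum of branch lengths) to
control for gene-level rate variation.  Columns containing a gap in any
sequence are flagged and excluded from downstream aggregation, as is any
gene whose estimated tree length is zero.
"""
from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize, minimize_scalar

from .properties import ONE_TO_THREE

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {ch: i for i, ch in enumerate(AA_ORDER)}
GAP_CHARS = set("-?XxBZJU*.")

RHO_BOUNDS = (1e-6, 50.0)
RHO_XTOL = 1e-8
BRANCH_BOUNDS = (1e-8, 20.0)


# ---------------------------------------------------------------------------
# rate matrices


@dataclass
class RateMatrix:
    """Instantaneous 20-state rate matrix Q with equilibrium frequencies pi.

    Q is scaled so the expected number of substitutions per unit branch
    length at equilibrium is 1.  Time reversibility (pi_i Q_ij = pi_j Q_ji)
    holds for matrices built from symmetric exchangeabilities.
    """

    Q: np.ndarray
    pi: np.ndarray
    label: str
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_exchangeabilities(cls, s: np.ndarray, pi: np.ndarray,
                               label: str) -> "RateMatrix":
        s = np.asarray(s, dtype=float)
        pi = np.asarray(pi, dtype=float)
        pi = pi / pi.sum()
        Q = s * pi[np.newaxis, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(np.sum(pi * np.diag(Q)))
        return cls(Q=Q / scale, pi=pi, label=label)

    @classmethod
    def wag(cls) -> "RateMatrix":
        """The WAG empirical model (Whelan & Goldman 2001), bundled."""
        with importlib.resources.files("aacost.data").joinpath("wag.tsv").open() as fh:
            lines = [ln.strip() for ln in fh
                     if ln.strip() and not ln.startswith("#")]
        freq_line = lines[0].split("\t")
        assert freq_line[0] == "frequencies"
        pi = np.array([float(v) for v in freq_line[1:]])
        values = [float(v) for v in lines[1:]]
        s = np.zeros((20, 20))
        k = 0
        for j in range(20):          # column-major lower triangle
            for i in range(j + 1, 20):
                s[i, j] = s[j, i] = values[k]
                k += 1
        assert k == len(values) == 190
        return cls.from_exchangeabilities(s, pi, "WAG")

    @classmethod
    def null(cls) -> "RateMatrix":
        """Equal rates between all residues, uniform frequencies."""
        s = np.ones((20, 20))
        np.fill_diagonal(s, 0.0)
        return cls.from_exchangeabilities(s, np.full(20, 1 / 20), "null")

    def _eigendecomposition(self):
        if self._eig is None:
            sqrt_pi = np.sqrt(self.pi)
            B = self.Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
            B = (B + B.T) / 2  # symmetrize against round-off
            lam, U = np.linalg.eigh(B)
            left = U.T * sqrt_pi[None, :]
            right = U / sqrt_pi[:, None]
            self._eig = (lam, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows sum to 1, entries clipped at 0."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        lam, right, left = self._eigendecomposition()
        P = (right * np.exp(lam * t)[None, :]) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# trees


@dataclass
class PhyloTree:
    """Rooted tree in postorder arrays (the root may be multifurcating)."""

    parent: list[int]
    children: list[list[int]]
    lengths: np.ndarray
    leaf_labels: dict[int, str]
    postorder: list[int]
    root: int

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(tree.preorder_node_iter())
        index = {id(node): i for i, node in enumerate(nodes)}
        parent = [-1] * len(nodes)
        children: list[list[int]] = [[] for _ in nodes]
        lengths = np.zeros(len(nodes))
        leaf_labels = {}
        for node in nodes:
            i = index[id(node)]
            if node.parent_node is not None:
                parent[i] = index[id(node.parent_node)]
                children[parent[i]].append(i)
                lengths[i] = node.edge.length if node.edge.length is not None else 0.1
            if node.is_leaf():
                leaf_labels[i] = node.taxon.label.replace(" ", "_")
        postorder = [index[id(n)] for n in tree.postorder_node_iter()]
        return cls(parent=parent, children=children, lengths=lengths,
                   leaf_labels=leaf_labels, postorder=postorder,
                   root=index[id(tree.seed_node)])

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def branch_nodes(self) -> list[int]:
        """Nodes carrying a branch (everything but the root)."""
        return [i for i in range(len(self.parent)) if self.parent[i] != -1]

    def tree_length(self) -> float:
        return float(sum(self.lengths[i] for i in self.branch_nodes))

    def with_lengths(self, lengths_by_node: np.ndarray) -> "PhyloTree":
        out = PhyloTree(parent=list(self.parent),
                        children=[list(c) for c in self.children],
                        lengths=np.array(lengths_by_node, dtype=float),
                        leaf_labels=dict(self.leaf_labels),
                        postorder=list(self.postorder), root=self.root)
        return out


def load_species_tree() -> PhyloTree:
    """The bundled fixed 4-taxon *Saccharomyces* topology."""
    text = importlib.resources.files("aacost.data").joinpath(
        "species_tree.nwk").read_text()
    return PhyloTree.from_newick(text)


# ---------------------------------------------------------------------------
# pruning likelihood


def _encode_alignment(alignment: Mapping[str, str], tree: PhyloTree):
    """Column codes per leaf: 0..19 residue index, -1 missing/gap."""
    labels = [tree.leaf_labels[i] for i in sorted(tree.leaf_labels)]
    missing = [lab for lab in labels if lab not in alignment]
    if missing:
        raise ValueError(f"alignment lacks sequences for tree leaves {missing}")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment sequences differ in length")
    n_cols = lengths.pop()
    codes = {}
    for leaf, lab in tree.leaf_labels.items():
        seq = alignment[lab].upper()
        codes[leaf] = np.array(
            [AA_INDEX.get(ch, -1) for ch in seq], dtype=int)
    return codes, n_cols


class PruningEngine:
    """Column log-likelihoods and root posteriors by Felsenstein pruning."""

    def __init__(self, tree: PhyloTree, matrix: RateMatrix,
                 alignment: Mapping[str, str]):
        self.tree = tree
        self.matrix = matrix
        self.codes, self.n_cols = _encode_alignment(alignment, tree)
        self.has_gap = np.zeros(self.n_cols, dtype=bool)
        for leaf_codes in self.codes.values():
            self.has_gap |= leaf_codes < 0

    def _partials(self, columns: np.ndarray, lengths: np.ndarray, rho: float):
        """Conditional likelihood arrays per node, shape (n_cols, 20)."""
        tree = self.tree
        P = {i: self.matrix.transition_matrix(float(lengths[i]) * rho)
             for i in tree.branch_nodes}
        partial: dict[int, np.ndarray] = {}
        for node in tree.postorder:
            if node in tree.leaf_labels:
                codes = self.codes[node][columns]
                arr = np.ones((len(columns), 20))
                observed = codes >= 0
                arr[observed] = 0.0
                arr[observed, codes[observed]] = 1.0
                partial[node] = arr
            else:
                arr = np.ones((len(columns), 20))
                for child in tree.children[node]:
                    arr *= partial[child] @ P[child].T
                partial[node] = arr
        return partial

    def column_logliks(self, columns: np.ndarray, lengths: np.ndarray,
                       rho: float = 1.0) -> np.ndarray:
        partial = self._partials(columns, lengths, rho)
        site_lik = partial[self.tree.root] @ self.matrix.pi
        return np.log(np.maximum(site_lik, 1e-300))

    def total_loglik(self, lengths: np.ndarray) -> float:
        cols = np.arange(self.n_cols)
        return float(self.column_logliks(cols, lengths, 1.0).sum())

    def root_posterior(self, column: int, lengths: np.ndarray,
                       rho: float) -> np.ndarray:
        partial = self._partials(np.array([column]), lengths, rho)
        post = partial[self.tree.root][0] * self.matrix.pi
        total = post.sum()
        return post / total if total > 0 else np.full(20, 1 / 20)


# ---------------------------------------------------------------------------
# estimation


@dataclass
class SiteRate:
    """One alignment column's rate estimate."""

    gene: str
    column: int
    rate: float
    ancestral_residue: str | None
    has_gap: bool
    tree_length: float


def _fit_branch_lengths(engine: PruningEngine) -> np.ndarray:
    """ML branch lengths shared across columns (rate-homogeneous model)."""
    tree = engine.tree
    branch_nodes = tree.branch_nodes
    x0 = np.array([max(tree.lengths[i], 0.05) for i in branch_nodes])

    def negloglik(x):
        lengths = tree.lengths.copy()
        for value, node in zip(x, branch_nodes):
            lengths[node] = value
        return -engine.total_loglik(lengths)

    res = minimize(negloglik, x0, method="L-BFGS-B",
                   bounds=[BRANCH_BOUNDS] * len(branch_nodes))
    lengths = tree.lengths.copy()
    for value, node in zip(res.x, branch_nodes):
        lengths[node] = value
    return lengths


def estimate_site_rates(alignment: Mapping[str, str], tree: PhyloTree,
                        matrix: RateMatrix, gene: str = "gene",
                        optimize_branch_lengths: bool = True,
                        ) -> tuple[list[SiteRate], float]:
    """Per-column ML rate multipliers and ancestral residues.

    Returns the site records and the gene's estimated tree length.  Rates
    are raw multipliers (not yet normalized by tree length; see
    :func:`normalize_and_pool`).
    """
    engine = PruningEngine(tree, matrix, alignment)
    if optimize_branch_lengths:
        lengths = _fit_branch_lengths(engine)
    else:
        lengths = tree.lengths.copy()
    tree_length = float(sum(lengths[i] for i in tree.branch_nodes))

    # collapse identical columns so each unique pattern is optimized once
    pattern_key = np.stack([engine.codes[leaf]
                            for leaf in sorted(tree.leaf_labels)], axis=1)
    _, first_index, inverse = np.unique(pattern_key, axis=0,
                                        return_index=True, return_inverse=True)
    rho_by_pattern = np.empty(len(first_index))
    anc_by_pattern: list[str] = []
    for p, col in enumerate(first_index):
        col_arr = np.array([col])

        def neg(rho, _col=col_arr):
            return -float(engine.column_logliks(_col, lengths, rho)[0])

        res = minimize_scalar(neg, bounds=RHO_BOUNDS, method="bounded",
                              options={"xatol": RHO_XTOL})
        rho_by_pattern[p] = float(res.x)
        posterior = engine.root_posterior(int(col), lengths, float(res.x))
        anc_by_pattern.append(AA_ORDER[int(np.argmax(posterior))])

    records = []
    for col in range(engine.n_cols):
        p = inverse[col]
        gap = bool(engine.has_gap[col])
        records.append(SiteRate(
            gene=gene, column=col, rate=float(rho_by_pattern[p]),
            ancestral_residue=None if gap else anc_by_pattern[p],
            has_gap=gap, tree_length=tree_length))
    return records, tree_length


def column_loglik_bruteforce(alignment: Mapping[str, str], tree: PhyloTree,
                             matrix: RateMatrix, column: int,
                             rho: float = 1.0) -> float:
    """Likelihood by explicit summation over all internal-node states.

    Exponential in the number of internal nodes; an independent check of
    the pruning recursion on small trees.
    """
    codes, n_cols = _encode_alignment(alignment, tree)
    if not 0 <= column < n_cols:
        raise IndexError("column out of range")
    internal = [i for i in range(len(tree.parent))
                if i not in tree.leaf_labels]
    P = {i: matrix.transition_matrix(float(tree.lengths[i]) * rho)
         for i in tree.branch_nodes}

    def prob_given_states(states: dict[int, int]) -> float:
        prob = matrix.pi[states[tree.root]]
        for node in tree.branch_nodes:
            parent_state = states[tree.parent[node]]
            if node in tree.leaf_labels:
                code = codes[node][column]
                if code < 0:
                    continue  # missing observation: marginalized out
                prob *= P[node][parent_state, code]
            else:
                prob *= P[node][parent_state, states[node]]
        return prob

    total = 0.0
    import itertools
    for assignment in itertools.product(range(20), repeat=len(internal)):
        states = dict(zip(internal, assignment))
        total += prob_given_states(states)
    return float(np.log(total))


# ---------------------------------------------------------------------------
# filtering, parsing, pooling, aggregation


def filter_alignments(alignments: Mapping[str, Mapping[str, str]],
                      reference: Mapping[str, str],
                      reference_species: str = "Scer",
                      min_species: int = 4,
                      ) -> tuple[dict[str, Mapping[str, str]], list[tuple[str, str]]]:
    """Keep alignments with the full species set and an exact reference match.

    The reference comparison strips gap characters from the aligned
    reference-species sequence.  Returns the retained alignments and a
    ``(gene, reason)`` rejection log.
    """
    retained: dict[str, Mapping[str, str]] = {}
    log: list[tuple[str, str]] = []
    for gene, aln in alignments.items():
        if len(aln) < min_species:
            log.append((gene, f"only {len(aln)} species (need {min_species})"))
            continue
        if reference_species not in aln:
            log.append((gene, f"missing {reference_species} sequence"))
            continue
        if gene not in reference:
            log.append((gene, "no reference sequence available"))
            continue
        degapped = re.sub(r"[-.*]", "", aln[reference_species]).upper()
        if degapped != reference[gene].upper():
            log.append((gene, "reference sequence mismatch"))
            continue
        retained[gene] = aln
    return retained, log


def read_fasta_alignment(path) -> dict[str, str]:
    """Species -> aligned sequence from a FASTA file."""
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_rate_table(site_rates: Iterable[SiteRate], path) -> None:
    frame = pd.DataFrame([{
        "gene": s.gene, "column": s.column, "rate": repr(s.rate),
        "ancestral": s.ancestral_residue or "-",
        "has_gap": int(s.has_gap), "tree_length": repr(s.tree_length),
    } for s in site_rates])
    frame.to_csv(path, sep="\t", index=False)


def parse_rate_file(path, dialect: str = "tabular") -> list[SiteRate]:
    """Read per-site rates from a tabular file or an rst-style report.

    The ``codeml_rst`` dialect understands the subset of the rst report
    this package documents: a ``tree length = <x>`` line and a table headed
    ``Site Rate Ancestral`` with one row per column (1-based site index).
    """
    if dialect == "tabular":
        frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
        required = {"gene", "column", "rate", "ancestral", "has_gap", "tree_length"}
        if not required <= set(frame.columns):
            raise ValueError(f"{path}: missing columns {required - set(frame.columns)}")
        return [SiteRate(gene=str(r.gene), column=int(r.column),
                         rate=float(r.rate),
                         ancestral_residue=None if r.ancestral in ("-", None)
                         else str(r.ancestral),
                         has_gap=bool(r.has_gap),
                         tree_length=float(r.tree_length))
                for r in frame.itertuples()]
    if dialect != "codeml_rst":
        raise ValueError(f"unknown dialect {dialect!r}")
    text = open(path).read()
    m = re.search(r"tree length\s*=\s*([0-9.eE+-]+)", text)
    if m is None:
        raise ValueError(f"{path}: no 'tree length =' line")
    tree_length = float(m.group(1))
    gene = re.sub(r"\.[^.]*$", "", str(path)).split("/")[-1]
    rows = re.search(r"Site\s+Rate\s+Ancestral\s*\n(.*)", text, re.DOTALL)
    if rows is None:
        raise ValueError(f"{path}: no 'Site Rate Ancestral' table")
    records = []
    for line in rows.group(1).strip().splitlines():
        if not line.strip():
            break
        parts = line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed rate row {line!r}")
        site, rate, anc = int(parts[0]), float(parts[1]), parts[2]
        gap = anc in ("-", ".")
        records.append(SiteRate(gene=gene, column=site - 1, rate=rate,
                                ancestral_residue=None if gap else anc,
                                has_gap=gap, tree_length=tree_length))
    if not records:
        raise ValueError(f"{path}: empty rate table")
    return records


def normalize_and_pool(site_rates: Iterable[SiteRate],
                       ) -> tuple[list[SiteRate], dict[str, int]]:
    """Divide rates by gene tree length; drop gap columns and zero-length genes.

    Returns the pooled normalized records and a bookkeeping dict with counts
    of ``kept``, ``gap_columns`` and ``zero_tree_length`` columns.
    """
    pooled: list[SiteRate] = []
    log = {"kept": 0, "gap_columns": 0, "zero_tree_length": 0}
    for s in site_rates:
        if s.tree_length < 0:
            raise ValueError(f"negative tree length for gene {s.gene!r}")
        if s.tree_length == 0:
            log["zero_tree_length"] += 1
            continue
        if s.has_gap:
            log["gap_columns"] += 1
            continue
        pooled.append(SiteRate(
            gene=s.gene, column=s.column, rate=s.rate / s.tree_length,
            ancestral_residue=s.ancestral_residue, has_gap=False,
            tree_length=s.tree_length))
        log["kept"] += 1
    return pooled, log


def aggregate_by_ancestral(pooled: Sequence[SiteRate]) -> pd.DataFrame:
    """Mean normalized rate per ancestral residue with SEM and site count.

    Indexed by 3-letter residue code; residues never inferred ancestral are
    absent.
    """
    if not pooled:
        raise ValueError("empty site-rate pool")
    frame = pd.DataFrame({
        "residue": [ONE_TO_THREE[s.ancestral_residue] for s in pooled],
        "rate": [s.rate for s in pooled],
    })
    grouped = frame.groupby("residue")["rate"]
    out = pd.DataFrame({
        "mean_rate": grouped.mean(),
        "sem": grouped.apply(lambda x: x.std(ddof=1) / np.sqrt(len(x))
                             if len(x) > 1 else 0.0),
        "n_sites": grouped.size(),
    })
    return out


@dataclass
class RateCostCorrelation:
    """Rank correlation and robust linear trend of rate against cost."""

    spearman_r: float
    spearman_p: float
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    n: int


def correlate_rate_with_cost(summaries: pd.DataFrame,
                             cost: pd.Series) -> RateCostCorrelation:
    """Spearman correlation plus Huber M-estimator trend over residues.

    ``summaries`` is the output of :func:`aggregate_by_ancestral`; ``cost``
    is a residue-indexed (3-letter) cost column.
    """
    import statsmodels.api as sm

    joined = summaries.join(cost.rename("cost"), how="inner").dropna(
        subset=["mean_rate", "cost"])
    if len(joined) < 5:
        raise ValueError(f"only {len(joined)} shared residues (need >= 5)")
    res = stats.spearmanr(joined["cost"], joined["mean_rate"])
    exog = sm.add_constant(joined["cost"].to_numpy())
    rlm = sm.RLM(joined["mean_rate"].to_numpy(), exog,
                 M=sm.robust.norms.HuberT()).fit()
    slope = float(rlm.params[1])
    half_width = 1.96 * float(rlm.bse[1])
    return RateCostCorrelation(
        spearman_r=float(res.statistic), spearman_p=float(res.pvalue),
        slope=slope, intercept=float(rlm.params[0]),
        slope_ci=(slope - half_width, slope + half_width), n=len(joined))
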