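import numpy as np
import pytest
from scipy import stats
from scipy.linalg import expm

from aacost.rates import (
    AA_ORDER,
    PruningEngine,
    RateMatrix,
    SiteRate,
    aggregate_by_ancestral,
    column_loglik_bruteforce,
    correlate_rate_with_cost,
    estimate_site_rates,
    filter_alignments,
    normalize_and_pool,
    parse_rate_file,
    write_rate_table,
)
from aacost.synth import AlignmentSimSpec, simulate_alignment, validation_tree


# -- rate matrices -----------------------------------------------------------


@pytest.mark.parametrize("label", ["wag", "null"])
def test_rate_matrix_invariants(label, wag, null_matrix):
    m = wag if label == "wag" else null_matrix
    assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
    off = m.Q[~np.eye(20, dtype=bool)]
    assert np.all(off >= 0)
    # unit expected substitution rate at equilibrium
    assert -np.sum(m.pi * np.diag(m.Q)) == pytest.approx(1.0, abs=1e-12)
    # detailed balance
    flux = m.pi[:, None] * m.Q
    assert np.allclose(flux, flux.T, atol=1e-12)


def test_null_matrix_uniform(null_matrix):
    assert np.allclose(null_matrix.pi, 1 / 20)
    off = null_matrix.Q[~np.eye(20, dtype=bool)]
    assert np.allclose(off, off[0])


def test_transition_matrix_matches_expm(wag):
    for t in (0.01, 0.5, 3.0):
        assert np.allclose(wag.transition_matrix(t), expm(wag.Q * t),
                           atol=1e-10)


def test_transition_matrix_rows_stochastic(wag):
    for t in (0.0, 1e-4, 0.1, 10.0):
        P = wag.transition_matrix(t)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(P >= 0)


# -- pruning -----------------------------------------------------------------


def test_pruning_agrees_with_state_enumeration(species_tree, wag):
    spec = AlignmentSimSpec(tree=species_tree, matrix=wag, n_sites=8, seed=3)
    aln, _, _ = simulate_alignment(spec)
    engine = PruningEngine(species_tree, wag, aln)
    for rho in (0.25, 1.0, 4.0):
        for col in range(8):
            pruned = engine.column_logliks(np.array([col]),
                                           species_tree.lengths, rho)[0]
            brute = column_loglik_bruteforce(aln, species_tree, wag, col, rho)
            assert pruned == pytest.approx(brute, abs=1e-10)


def test_pruning_handles_gap_as_missing(species_tree, wag):
    spec = AlignmentSimSpec(tree=species_tree, matrix=wag, n_sites=4,
                            gap_probability=0.3, seed=5)
    aln, _, _ = simulate_alignment(spec)
    engine = PruningEngine(species_tree, wag, aln)
    brute = [column_loglik_bruteforce(aln, species_tree, wag, c, 1.0)
             for c in range(4)]
    pruned = engine.column_logliks(np.arange(4), species_tree.lengths, 1.0)
    assert np.allclose(pruned, brute, atol=1e-10)


def test_null_matrix_relabelling_symmetry(species_tree, null_matrix, rng):
    """Under equal exchange rates, permuting residue labels cannot change
    a column's likelihood profile or rate estimate."""
    aln = {"Scer": "AC", "Spar": "AC", "Smik": "RC", "Sbay": "DW"}
    perm = rng.permutation(20)
    mapping = {AA_ORDER[i]: AA_ORDER[perm[i]] for i in range(20)}
    relabelled = {k: "".join(mapping[c] for c in v) for k, v in aln.items()}
    r1, _ = estimate_site_rates(aln, species_tree, null_matrix,
                                optimize_branch_lengths=False)
    r2, _ = estimate_site_rates(relabelled, species_tree, null_matrix,
                                optimize_branch_lengths=False)
    for a, b in zip(r1, r2):
        assert a.rate == pytest.approx(b.rate, rel=1e-6)


# -- site rate estimation ----------------------------------------------------


def test_invariant_column_rate_at_lower_bound(species_tree, wag):
    aln = {lab: "AAAA" for lab in ("Scer", "Spar", "Smik", "Sbay")}
    records, _ = estimate_site_rates(aln, species_tree, wag,
                                     optimize_branch_lengths=False)
    for rec in records:
        assert rec.rate <= 1e-4


def test_simulated_rate_recovery():
    """Spearman > 0.8 between estimated and simulated per-site rates."""
    tree = validation_tree()
    wag = RateMatrix.wag()
    spec = AlignmentSimSpec(tree=tree, matrix=wag, n_sites=500, seed=11)
    aln, true_rates, _ = simulate_alignment(spec)
    records, tree_length = estimate_site_rates(aln, tree, wag)
    estimated = np.array([r.rate for r in records])
    rho = stats.spearmanr(estimated, true_rates).statistic
    assert rho > 0.8
    assert tree_length > 0


def test_gap_columns_flagged_and_stripped_of_ancestor(species_tree, wag):
    spec = AlignmentSimSpec(tree=species_tree, matrix=wag, n_sites=60,
                            gap_probability=0.15, seed=7)
    aln, _, _ = simulate_alignment(spec)
    records, _ = estimate_site_rates(aln, species_tree, wag,
                                     optimize_branch_lengths=False)
    has_gap_truth = [any(aln[lab][c] == "-" for lab in aln)
                     for c in range(60)]
    for rec, truth in zip(records, has_gap_truth):
        assert rec.has_gap == truth
        assert (rec.ancestral_residue is None) == truth


def test_ancestral_reconstruction_recovers_root_on_conserved_sites():
    tree = validation_tree()
    wag = RateMatrix.wag()
    spec = AlignmentSimSpec(tree=tree, matrix=wag, n_sites=300,
                            rate_values=(0.05,), rate_weights=(1.0,), seed=13)
    aln, _, root = simulate_alignment(spec)
    records, _ = estimate_site_rates(aln, tree, wag,
                                     optimize_branch_lengths=False)
    recovered = sum(rec.ancestral_residue == root[rec.column]
                    for rec in records)
    assert recovered / len(records) > 0.95


def test_branch_scaling_leaves_rate_estimates_invariant(wag):
    """Re-estimated branch lengths absorb a global rate scale, so per-site
    multipliers are unchanged and the tree length carries the scale."""
    tree = validation_tree()
    spec = AlignmentSimSpec(tree=tree, matrix=wag, n_sites=120, seed=17)
    aln, _, _ = simulate_alignment(spec)
    scaled_tree = tree.with_lengths(tree.lengths * 2.0)
    r1, t1 = estimate_site_rates(aln, tree, wag)
    r2, t2 = estimate_site_rates(aln, scaled_tree, wag)
    # same data, different starting lengths: ML fit converges to same optimum
    assert t2 == pytest.approx(t1, rel=1e-3)
    for a, b in zip(r1, r2):
        assert b.rate == pytest.approx(a.rate, rel=1e-3, abs=1e-6)


# -- filtering ---------------------------------------------------------------


def test_filter_rejects_few_species_and_mismatches():
    good = {"Scer": "MKV-", "Spar": "MKVL", "Smik": "MRVL", "Sbay": "MKAL"}
    three_species = {k: good[k] for k in ("Scer", "Spar", "Smik")}
    mismatch = dict(good, Scer="MKIL")
    alignments = {"g1": good, "g2": three_species, "g3": mismatch}
    reference = {"g1": "MKV", "g2": "MKV", "g3": "MKV"}
    retained, log = filter_alignments(alignments, reference)
    assert set(retained) == {"g1"}
    reasons = dict(log)
    assert "species" in reasons["g2"]
    assert "mismatch" in reasons["g3"]


# -- parsing and round trip --------------------------------------------------


def _mini_rates():
    return [
        SiteRate("gA", 0, 0.4, "A", False, 2.0),
        SiteRate("gA", 1, 1.2, "W", False, 2.0),
        SiteRate("gA", 2, 0.9, None, True, 2.0),
        SiteRate("gB", 0, 0.8, "C", False, 0.0),
    ]


def test_tabular_rate_round_trip(tmp_path):
    path = tmp_path / "rates.tsv"
    write_rate_table(_mini_rates(), path)
    back = parse_rate_file(path, "tabular")
    assert back == _mini_rates()


RST_STYLE = """\
Supplemental results

tree length =  1.75

Rates for sites, with ancestral state at the root

Site Rate Ancestral
1 0.500 M
2 1.250 K
3 0.010 V
4 2.000 -
5 0.333 A
6 0.875 W
7 1.000 C
8 0.444 D
9 0.725 E
10 1.500 F
"""


def test_rst_style_parse(tmp_path):
    path = tmp_path / "gene1.rst"
    path.write_text(RST_STYLE)
    records = parse_rate_file(path, "codeml_rst")
    assert len(records) == 10
    assert records[0].rate == pytest.approx(0.5)
    assert records[0].ancestral_residue == "M"
    assert records[3].has_gap and records[3].ancestral_residue is None
    assert all(r.tree_length == pytest.approx(1.75) for r in records)


def test_truncated_rst_rejected(tmp_path):
    path = tmp_path / "trunc.rst"
    path.write_text("tree length = 1.0\n")
    with pytest.raises(ValueError, match="Site Rate Ancestral"):
        parse_rate_file(path, "codeml_rst")


# -- pooling and aggregation -------------------------------------------------


def test_normalization_divides_by_tree_length():
    pooled, log = normalize_and_pool(_mini_rates())
    assert [s.rate for s in pooled] == pytest.approx([0.2, 0.6])
    assert log == {"kept": 2, "gap_columns": 1, "zero_tree_length": 1}


def test_bookkeeping_is_exact():
    records = _mini_rates()
    pooled, log = normalize_and_pool(records)
    assert log["kept"] + log["gap_columns"] + log["zero_tree_length"] \
        == len(records)


def test_negative_tree_length_rejected():
    with pytest.raises(ValueError, match="negative tree length"):
        normalize_and_pool([SiteRate("g", 0, 0.1, "A", False, -1.0)])


def test_aggregate_mean_and_sem():
    pool = [SiteRate("g", 0, 0.1, "A", False, 1.0),
            SiteRate("g", 1, 0.3, "A", False, 1.0),
            SiteRate("g", 2, 0.5, "W", False, 1.0)]
    summary = aggregate_by_ancestral(pool)
    assert summary.loc["ala", "mean_rate"] == pytest.approx(0.2)
    assert summary.loc["ala", "sem"] == pytest.approx(0.1)
    assert summary.loc["ala", "n_sites"] == 2
    assert "trp" in summary.index
    assert "cys" not in summary.index


def test_aggregate_recovers_generator_means(rng):
    pool = []
    means = {"A": 0.2, "L": 0.5, "S": 0.9}
    for residue, mu in means.items():
        for i in range(400):
            pool.append(SiteRate("g", i, rng.normal(mu, 0.1), residue,
                                 False, 1.0))
    summary = aggregate_by_ancestral(pool)
    from aacost.properties import ONE_TO_THREE
    for residue, mu in means.items():
        row = summary.loc[ONE_TO_THREE[residue]]
        assert abs(row["mean_rate"] - mu) <= 2 * row["sem"] + 1e-9


def test_empty_pool_rejected():
    with pytest.raises(ValueError, match="empty"):
        aggregate_by_ancestral([])


# -- correlation -------------------------------------------------------------


def test_perfect_anticorrelation(compendium_table):
    import pandas as pd
    cost = compendium_table.column("abs_glc")
    # one summary row per residue, mean rate strictly decreasing in cost
    summary = pd.DataFrame({
        "mean_rate": 10.0 - cost, "sem": 0.0, "n_sites": 1})
    result = correlate_rate_with_cost(summary, cost)
    assert result.spearman_r == pytest.approx(-1.0)
    assert result.slope < 0


def test_shuffled_cost_rarely_reaches_large_correlation(compendium_table,
                                                        rng):
    """At n=20, |R| of a random permutation is below 0.55 in >= 95% of draws."""
    import pandas as pd
    cost = compendium_table.column("abs_glc")
    summary = pd.DataFrame({"mean_rate": cost.to_numpy(), "sem": 0.0,
                            "n_sites": 1}, index=cost.index)
    extreme = 0
    n_shuffles = 1000
    for _ in range(n_shuffles):
        shuffled = pd.Series(rng.permutation(cost.to_numpy()),
                             index=cost.index)
        r = correlate_rate_with_cost(summary, shuffled).spearman_r
        extreme += abs(r) >= 0.55
    assert extreme / n_shuffles <= 0.05


def test_too_few_shared_residues_rejected(compendium_table):
    import pandas as pd
    cost = compendium_table.column("abs_glc")
    summary = pd.DataFrame({"mean_rate": [0.1, 0.2], "sem": 0.0,
                            "n_sites": 1}, index=["ala", "gly"])
    with pytest.raises(ValueError, match="shared residues"):
        correlate_rate_with_cost(summary, cost)


# -- trees -------------------------------------------------------------------


def test_species_tree_topology(species_tree):
    assert species_tree.n_leaves == 4
    labels = set(species_tree.leaf_labels.values())
    assert labels == {"Scer", "Spar", "Smik", "Sbay"}
    assert len(species_tree.children[species_tree.root]) == 3


def test_alignment_tree_mismatch_rejected(species_tree, wag):
    aln = {"Scer": "MK", "Spar": "MK", "Smik": "MK"}
    with pytest.raises(ValueError, match="lacks sequences"):
        PruningEngine(species_tree, wag, aln)
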