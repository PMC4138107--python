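"""Alignment scores vs a brute-force oracle; NJ consistency and clades."""

import io
from functools import lru_cache

import numpy as np
import pytest

from aedes_ptp.errors import ContractError, ValidationError
from aedes_ptp.phylo import (
    DistanceMatrix,
    build_distance_matrix,
    clade_check,
    global_align,
    load_matrix,
    neighbor_joining,
    percent_identity_domainpair,
    robinson_foulds,
    three_taxon_lengths,
)
from aedes_ptp.synth import make_family

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = load_matrix("BLOSUM62")


def brute_force_score(a: str, b: str, gap_open=10.0, gap_extend=1.0) -> float:
    """Exhaustive affine-gap global alignment score (independent oracle).

    A gap of length L costs open + extend * L; switching between gap types
    opens a new gap.
    """

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        res = -np.inf
        if i < len(a) and j < len(b):
            res = max(res, BLOSUM62[a[i], b[j]] + best(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open + gap_extend
            res = max(res, -cost + best(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open + gap_extend
            res = max(res, -cost + best(i, j + 1, "Y"))
        return res

    return best(0, 0, "M")


def test_global_aligner_matches_brute_force_on_random_pairs():
    rng = np.random.default_rng(7)
    for _ in range(60):
        a = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(3, 11)))
        b = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(3, 11)))
        got = global_align(a, b).score
        assert got == pytest.approx(brute_force_score(a, b), abs=1e-9), (a, b)


def test_alignment_invariants():
    r = global_align("HEAGAWGHEE", "PAWHEAE")
    assert r.aligned_query.replace("-", "") == "HEAGAWGHEE"
    assert r.aligned_subject.replace("-", "") == "PAWHEAE"
    # score symmetric under argument swap
    assert r.score == global_align("PAWHEAE", "HEAGAWGHEE").score
    with pytest.raises(ContractError):
        global_align("", "PAW")


@pytest.mark.parametrize("a,b,expected", [
    ("HCSAGIGR", "HCSAGIGR", 100.0),
    ("AAAA", "GGGG", 0.0),
])
def test_percent_identity_trivia(a, b, expected):
    assert percent_identity_domainpair(a, b) == pytest.approx(expected)


def test_identity_of_reversed_domain_below_100():
    dom = "PIIHCSAGIGRSGTLI" + "VQNVSQYRF"
    assert percent_identity_domainpair(dom, dom) == 100.0
    assert percent_identity_domainpair(dom, dom[::-1]) < 100.0


def test_distance_matrix_matches_independent_pairwise_computation():
    leaves, _ = make_family(taxa=6, seed=4)
    dm = build_distance_matrix(leaves)
    assert np.allclose(dm.d, dm.d.T) and np.all(np.diag(dm.d) == 0)
    for i, a in enumerate(dm.taxa):
        for j, b in enumerate(dm.taxa):
            if i < j:
                pid = percent_identity_domainpair(leaves[a], leaves[b])
                assert dm.d[i, j] == pytest.approx(1 - pid / 100)


def test_distance_matrix_validation():
    with pytest.raises(ValidationError):
        build_distance_matrix([("x", "AAA"), ("x", "CCC")])
    with pytest.raises(ContractError):
        build_distance_matrix({"only": "AAA"})
    with pytest.raises(ValidationError):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def test_phylip_roundtrip(tmp_path):
    dm = DistanceMatrix(list("ABC"), np.array([[0, .1, .2], [.1, 0, .3], [.2, .3, 0]]))
    p = tmp_path / "d.phylip"
    dm.to_phylip(p)
    back = DistanceMatrix.from_phylip(p)
    assert back.taxa == dm.taxa
    assert np.allclose(back.d, dm.d)


def test_three_taxon_closed_form():
    dm = DistanceMatrix(list("ABC"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    assert three_taxon_lengths(2, 4, 4) == (1.0, 1.0, 3.0)
    tree = neighbor_joining(dm)
    newick = tree.newick()
    assert "A:1" in newick and "B:1" in newick and "C:3" in newick


def _additive_matrix_from_tree(rng, n_taxa):
    """Random tree -> exact path-length distances (and the truth newick)."""
    import dendropy
    _, truth = make_family(taxa=n_taxa, seed=int(rng.integers(2**31)))
    t = dendropy.Tree.get(data=truth.family_tree, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    taxa = sorted(t.taxon_namespace, key=lambda x: x.label)
    names = [x.label for x in taxa]
    d = np.array([[pdm.distance(a, b) for b in taxa] for a in taxa])
    return DistanceMatrix(names, d), truth.family_tree


def test_nj_exact_on_additive_matrices():
    """NJ consistency: additive input reconstructs topology and total length."""
    import dendropy
    rng = np.random.default_rng(99)
    for n in (4, 5, 6, 8):
        dm, truth_newick = _additive_matrix_from_tree(rng, n)
        tree = neighbor_joining(dm)
        assert robinson_foulds(tree, truth_newick) == 0
        total = sum(e.length or 0 for e in
                    dendropy.Tree.get(data=truth_newick, schema="newick").edges())
        got = sum(e.length or 0 for e in tree.tree.edges())
        assert got == pytest.approx(total, rel=1e-9)


def test_nj_four_taxon_least_squares_choice():
    """NJ picks the (unique) topology whose least-squares fit error is zero."""
    # tree ((A:1,B:2):1,(C:3,D:4)): additive distances
    d = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)
    dm = DistanceMatrix(list("ABCD"), d)
    # enumerate the three unrooted quartets; columns: eA,eB,eC,eD,internal
    quartets = {
        "AB|CD": [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)],
    }
    paths = {
        "AB|CD": np.array([[1, 1, 0, 0, 0], [1, 0, 1, 0, 1], [1, 0, 0, 1, 1],
                           [0, 1, 1, 0, 1], [0, 1, 0, 1, 1], [0, 0, 1, 1, 0]]),
        "AC|BD": np.array([[1, 1, 0, 0, 1], [1, 0, 1, 0, 0], [1, 0, 0, 1, 1],
                           [0, 1, 1, 0, 1], [0, 1, 0, 1, 0], [0, 0, 1, 1, 1]]),
        "AD|BC": np.array([[1, 1, 0, 0, 1], [1, 0, 1, 0, 1], [1, 0, 0, 1, 0],
                           [0, 1, 1, 0, 0], [0, 1, 0, 1, 1], [0, 0, 1, 1, 1]]),
    }
    y = np.array([d[i, j] for i, j in quartets["AB|CD"]])
    errors = {}
    for topo, X in paths.items():
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        errors[topo] = np.sum((X @ beta - y) ** 2)
    assert errors["AB|CD"] == pytest.approx(0, abs=1e-18)
    assert min(errors, key=errors.get) == "AB|CD"
    assert robinson_foulds(neighbor_joining(dm), "((A:1,B:2):1,(C:3,D:4):0);") == 0


def test_nj_matches_independent_implementation():
    """Cross-check topology against scikit-bio's NJ on noisy matrices."""
    import skbio
    from skbio.tree import nj as skbio_nj
    rng = np.random.default_rng(5)
    for trial in range(5):
        leaves, _ = make_family(taxa=6, seed=trial)
        dm = build_distance_matrix(leaves)
        mine = neighbor_joining(dm)
        theirs = skbio_nj(skbio.DistanceMatrix(dm.d, ids=dm.taxa))
        buf = io.StringIO()
        theirs.write(buf)
        assert robinson_foulds(mine, buf.getvalue()) == 0


def test_nj_needs_three_taxa():
    with pytest.raises(ContractError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.array([[0, 1.], [1., 0]])))


def test_negative_branch_lengths_clamped():
    # a decidedly non-additive matrix that provokes negative estimates
    d = np.array([[0, .1, .4, .5], [.1, 0, .5, .4],
                  [.4, .5, 0, .05], [.5, .4, .05, 0]])
    tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
    assert all((e.length or 0) >= 0 for e in tree.tree.edges())


def test_clade_check():
    tree = neighbor_joining(DistanceMatrix(
        list("ABCD"),
        np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float)))
    assert clade_check(tree, "A", {"B"}, {"C", "D"})       # sibling partner
    assert not clade_check(tree, "A", {"C"}, {"B", "D"})   # partner across every split
    with pytest.raises(ContractError):
        clade_check(tree, "Z", {"B"}, {"C"})


def test_family_clade_property():
    """Trees built from generated families separate the true clades."""
    hits = 0
    for seed in range(20):
        leaves, truth = make_family(taxa=8, seed=seed)
        tree = neighbor_joining(build_distance_matrix(leaves))
        if robinson_foulds(tree, truth.family_tree) == 0:
            hits += 1
    assert hits >= 18
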