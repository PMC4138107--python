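"""Pairwise alignment, percent identity, distance matrices and NJ trees.

Distances between PTP domain sequences come from pairwise global alignments
(Needleman–Wunsch with affine gaps, BLOSUM62 scoring, gap open 10 / extend
1) rather than a progressive multiple alignment; percent identity counts
identical columns over the full alignment length, gapped columns included
in the denominator, and distance is ``1 - identity/100``.  Trees are built
with the classical Saitou–Nei neighbor-joining algorithm: at each step the
pair minimising the Q-criterion is joined, branch lengths come from the
two-point formulas, and the run finishes with the three-taxon closed form.
Ties on Q are broken by lexicographic taxon-pair order; negative branch-
length estimates are clamped to zero with the deficit moved to the sister
branch (the Kuhner–Felsenstein convention).  A flag-selectable local
(Smith–Waterman) mode exists for identity comparisons against reference
catalytic domains.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ContractError, ValidationError

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 1.0


def load_matrix(name_or_path: str = DEFAULT_MATRIX):
    """A substitution matrix by name (packaged set) or NCBI-format file."""
    try:
        return substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        return substitution_matrices.read(name_or_path)


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float
    percent_identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ContractError("aligned strings must have equal length")


def _aligner(matrix, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = matrix
    # a gap of length L costs open + extend * L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def identity_from_alignment(aligned_a: str, aligned_b: str) -> float:
    """Identical columns over all aligned columns (gaps in the denominator)."""
    if len(aligned_a) != len(aligned_b) or not aligned_a:
        raise ContractError("need two non-empty gapped strings of equal length")
    same = sum(x == y and x != "-" for x, y in zip(aligned_a, aligned_b))
    return 100.0 * same / len(aligned_a)


def global_align(a: str, b: str,
                 matrix=None,
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND,
                 query_id: str = "query", subject_id: str = "subject",
                 mode: str = "global") -> AlignmentResult:
    """Optimal affine-gap alignment of two residue strings.

    Deterministic: among co-optimal alignments the aligner's canonical
    first traceback is reported; the score is unique.
    """
    if not a or not b:
        raise ContractError("sequences must be non-empty")
    matrix = matrix if matrix is not None else load_matrix()
    aligner = _aligner(matrix, gap_open, gap_extend, mode)
    aln = aligner.align(a.upper(), b.upper())[0]
    ga, gb = str(aln[0]), str(aln[1])
    return AlignmentResult(
        query_id=query_id, subject_id=subject_id,
        aligned_query=ga, aligned_subject=gb,
        score=float(aln.score),
        percent_identity=identity_from_alignment(ga, gb),
    )


def percent_identity_domainpair(a: str, b: str, local: bool = False,
                                matrix=None,
                                gap_open: float = DEFAULT_GAP_OPEN,
                                gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Percent identity between two extracted domain sequences.

    ``local=True`` scores only the best-matching sub-region (useful when the
    provenance of a published identity value — global vs local — is
    unknown).
    """
    mode = "local" if local else "global"
    return global_align(a, b, matrix=matrix, gap_open=gap_open,
                        gap_extend=gap_extend, mode=mode).percent_identity


# --------------------------------------------------------------------------
# distance matrices

@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValidationError("matrix shape must match taxa count")
        if len(set(self.taxa)) != n:
            raise ValidationError("duplicate taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValidationError("distances must be nonnegative")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def to_phylip(self, path: str | Path | None = None) -> str:
        """PHYLIP square format."""
        lines = [f"{len(self.taxa)}"]
        for name, row in zip(self.taxa, self.d):
            lines.append(name.ljust(10) + "  ".join(f"{v:.6f}" for v in row))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_phylip(cls, source: str | Path) -> "DistanceMatrix":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        lines = [ln for ln in text.splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        taxa, rows = [], []
        for ln in lines[1:n + 1]:
            parts = ln.split()
            taxa.append(parts[0])
            rows.append([float(x) for x in parts[1:n + 1]])
        return cls(taxa, np.array(rows))


def build_distance_matrix(seqs, local: bool = False, matrix=None) -> DistanceMatrix:
    """All-pairs alignment distances, d = 1 - identity/100.

    ``seqs`` is a mapping id -> sequence or an iterable of (id, sequence)
    pairs; duplicate ids raise a validation error.
    """
    pairs = list(seqs.items()) if hasattr(seqs, "items") else list(seqs)
    ids = [p[0] for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sequence ids")
    if len(ids) < 2:
        raise ContractError("need at least two sequences")
    matrix = matrix if matrix is not None else load_matrix()
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity_domainpair(pairs[i][1], pairs[j][1],
                                              local=local, matrix=matrix)
            d[i, j] = d[j, i] = 1.0 - pid / 100.0
    return DistanceMatrix(ids, d)


# --------------------------------------------------------------------------
# neighbor joining

@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths, stored as a dendropy tree."""

    tree: dendropy.Tree

    @property
    def taxa(self) -> list[str]:
        return sorted(t.label for t in self.tree.taxon_namespace)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True).strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.newick() + "\n")


def _clamp(li: float, lj: float) -> tuple[float, float]:
    """Move a negative estimate's deficit onto the sister branch."""
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical Saitou–Nei NJ with deterministic tie-breaking.

    On an additive (tree-realisable) matrix this reconstructs the generating
    topology and branch lengths exactly.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ContractError("neighbor joining needs at least 3 taxa")
    if n == 2:  # pragma: no cover - unreachable, kept for clarity
        pass

    # working copies; each active node is (sort_key, newick_fragment)
    d = dm.d.copy()
    keys = list(dm.taxa)           # lexicographic representative per node
    frags = list(dm.taxa)          # newick fragment per node

    def join(i: int, j: int, li: float, lj: float) -> None:
        nonlocal d, keys, frags
        li, lj = _clamp(li, lj)
        frag = f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g})"
        key = min(keys[i], keys[j])
        m = d.shape[0]
        rest = [k for k in range(m) if k not in (i, j)]
        new_row = np.array([
            max((d[i, k] + d[j, k] - d[i, j]) / 2.0, 0.0) for k in rest
        ])
        d = np.vstack([
            np.hstack([d[np.ix_(rest, rest)], new_row[:, None]]),
            np.hstack([new_row, [0.0]]),
        ])
        keys = [keys[k] for k in rest] + [key]
        frags = [frags[k] for k in rest] + [frag]

    while d.shape[0] > 3:
        m = d.shape[0]
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        join(i, j, li, lj)

    # three-taxon closed form
    (a, b, c) = (0, 1, 2)
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    order = sorted(range(3), key=lambda k: keys[k])
    inner = ",".join(f"{frags[k]}:{[la, lb, lc][k]:.10g}" for k in order)
    return PhyloTree.from_newick(f"({inner});")


def three_taxon_lengths(dab: float, dac: float, dbc: float) -> tuple[float, float, float]:
    """Closed-form pendant branch lengths for a 3-taxon star."""
    la = (dab + dac - dbc) / 2.0
    lb = (dab + dbc - dac) / 2.0
    lc = (dac + dbc - dab) / 2.0
    return la, lb, lc


def robinson_foulds(t1: PhyloTree | str, t2: PhyloTree | str) -> int:
    """Unrooted symmetric (Robinson–Foulds) bipartition distance."""
    s1 = t1.newick() if isinstance(t1, PhyloTree) else t1
    s2 = t2.newick() if isinstance(t2, PhyloTree) else t2
    ns = dendropy.TaxonNamespace()
    a = dendropy.Tree.get(data=s1, schema="newick", taxon_namespace=ns,
                          preserve_underscores=True)
    b = dendropy.Tree.get(data=s2, schema="newick", taxon_namespace=ns,
                          preserve_underscores=True)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


def clade_check(tree: PhyloTree, focal: str, partners: set[str],
                outgroup: set[str]) -> bool:
    """Does some edge separate {focal} | partners from the outgroup set?"""
    labels = set(tree.taxa)
    for t in {focal} | set(partners) | set(outgroup):
        if t not in labels:
            raise ContractError(f"unknown taxon {t!r}")
    want = {focal} | set(partners)
    out = set(outgroup)
    for edge in tree.tree.preorder_edge_iter():
        head = edge.head_node
        if head is tree.tree.seed_node:
            continue
        side = {lf.taxon.label for lf in head.leaf_iter()}
        other = labels - side
        if (want <= side and not (out & side)) or (want <= other and not (out & other)):
            return True
    return False
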