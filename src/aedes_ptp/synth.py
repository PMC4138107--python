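"""Synthetic data with known ground truth for every pipeline stage.

Three generators:

* :func:`make_proteome` — proteins made of random flanks plus planted PTP
  domain cassettes.  A cassette embeds the ten motif instances at their
  canonical offsets around the P-loop cysteine; lesions (anchor-residue
  mutation, whole-motif loss) realise intended per-motif statuses.
  :func:`table1_proteome` is a packaged preset that plants the published
  ten-protein repertoire's motif strings verbatim, so its domain counts and
  motif statuses are known exactly.
* :func:`make_family` — a sequence family evolved by per-branch point
  mutation down a known (recorded) tree; used to test distance/NJ recovery.
* :func:`make_ct_table` / :func:`make_cage_table` — qPCR threshold-cycle
  tables with known fold changes and primer efficiencies, and egg-count
  cage tables with known per-female means.

All randomness flows from one named seed.  After planting, motif search
windows are sanitised: filler residues that happen to spell an unintended
pattern hit are resampled (planted residues are never touched), so the
recorded truth is exact rather than merely highly probable.  Each generated
dataset serialises together with its :class:`SyntheticTruth` sidecar (JSON).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .domains import Presence, ProteinRecord, ScanConfig, _window, write_fasta
from .errors import ValidationError
from .motifs import (
    ACTIVE_SITE_MOTIFS,
    CORE_MOTIFS,
    MotifRegistry,
    STANDARD_AA,
    Status,
    call_motif,
    default_registry,
    load_table1_fixture,
)

_FRAME_RE = re.compile(r"C.{5}R")

#: Deterministic lesioned motif instances (fail the competence pattern).
MUTATED_TEMPLATES = {
    1: "NLNENGY",        # basic/arginine anchors lost
    8: "YLAWGDHGVP",     # general-acid D -> G
    9: "PIIHCNEGGGRTG",  # C-x5-R frame intact, S-A-G context lost
    10: "TPSLAQYKF",     # position-2 glutamine missing
}
#: P-loop cysteine substituted by serine: no C-x5-R frame remains at all.
M9_CYS_TO_SER = "PIIHSSAGIGRTG"

_M1_PLANT_OFFSET = -170
_M8_PLANT_OFFSET = -38
_M10_PLANT_OFFSET = 45


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [STANDARD_AA[i] for i in rng.integers(0, len(STANDARD_AA), n)]


def _anchor_index(m9_seq: str) -> int:
    """Index of the (possibly substituted) catalytic cysteine in a P-loop string."""
    m = _FRAME_RE.search(m9_seq)
    if m:
        return m.start()
    if "C" in m9_seq:
        return m9_seq.index("C")
    return 4  # virtual anchor position of the canonical template


@dataclass(frozen=True)
class DomainSpec:
    """Build recipe for one planted domain.

    ``motif_seqs`` maps active-site motif ids to the exact string to plant;
    a value of ``None`` for motif 1 means the KNRY region is missing
    entirely (the domain then sits at the protein's N-terminus).
    ``degenerate=True`` plants only a remnant of core motifs with no P-loop.
    """

    motif_seqs: dict[int, str | None] = field(default_factory=dict)
    degenerate: bool = False
    core_ids: tuple[int, ...] = CORE_MOTIFS

    def intended_statuses(self) -> dict[int, Status]:
        if self.degenerate:
            return {m: Status.ABSENT for m in ACTIVE_SITE_MOTIFS}
        out = {}
        for mid in ACTIVE_SITE_MOTIFS:
            s = self.motif_seqs.get(mid)
            out[mid] = Status.ABSENT if s is None else call_motif(mid, s).status
        return out


def intact_domain_spec(registry: MotifRegistry | None = None) -> DomainSpec:
    registry = registry or default_registry()
    return DomainSpec(motif_seqs={m: registry[m].template for m in ACTIVE_SITE_MOTIFS})


def lesioned_domain_spec(lesions: dict[int, str],
                         registry: MotifRegistry | None = None) -> DomainSpec:
    """Apply lesions to the intact template.

    ``lesions`` maps motif id -> one of ``"mutate"`` (anchor residue lost),
    ``"absent"`` (motif 1 only: region missing), or ``"cys_to_ser"``
    (motif 9 only).
    """
    registry = registry or default_registry()
    seqs: dict[int, str | None] = {m: registry[m].template for m in ACTIVE_SITE_MOTIFS}
    for mid, kind in lesions.items():
        if mid not in ACTIVE_SITE_MOTIFS:
            raise ValidationError(f"lesion names unknown active-site motif {mid}")
        if kind == "mutate":
            seqs[mid] = MUTATED_TEMPLATES[mid]
        elif kind == "absent":
            if mid != 1:
                raise ValidationError("'absent' lesion is only defined for motif 1")
            seqs[mid] = None
        elif kind == "cys_to_ser":
            if mid != 9:
                raise ValidationError("'cys_to_ser' lesion is only defined for motif 9")
            seqs[mid] = M9_CYS_TO_SER
        else:
            raise ValidationError(f"unknown lesion kind {kind!r}")
    return DomainSpec(motif_seqs=seqs)


@dataclass
class _Planted:
    anchor: int | None          # absolute 0-based anchor (None for degenerate)
    start0: int                 # cassette bounds, 0-based half-open
    end0: int
    presence: Presence
    intended: dict[int, Status]


def _build_wellformed(rng, registry, spec: DomainSpec):
    """Return (chars, mask, anchor_rel, intended) for one cassette."""
    seqs = spec.motif_seqs
    include_m1 = seqs.get(1) is not None
    rel_min = _M1_PLANT_OFFSET - 10 if include_m1 else min(
        registry[c].offset for c in spec.core_ids) - 10
    m10 = seqs[10]
    rel_max = _M10_PLANT_OFFSET + len(m10) + 10
    n = rel_max - rel_min
    chars = _random_seq(rng, n)
    mask = [False] * n

    def put(s: str, rel: int) -> None:
        i = rel - rel_min
        chars[i:i + len(s)] = list(s)
        mask[i:i + len(s)] = [True] * len(s)

    for cid in spec.core_ids:
        put(registry[cid].template, registry[cid].offset)
    if include_m1:
        put(seqs[1], _M1_PLANT_OFFSET)
    put(seqs[8], _M8_PLANT_OFFSET)
    put(seqs[9], -_anchor_index(seqs[9]))
    put(m10, _M10_PLANT_OFFSET)
    return chars, mask, -rel_min, spec.intended_statuses()


def _build_degenerate(rng, registry, core_ids=(3, 5), spacing=45, margin=5,
                      max_tries=200):
    """A core-motif remnant guaranteed to contain no C-x5-R frame."""
    length = margin + spacing * (len(core_ids) - 1) \
        + len(registry[core_ids[-1]].template) + margin
    for _ in range(max_tries):
        chars = _random_seq(rng, length)
        mask = [False] * length
        for k, cid in enumerate(core_ids):
            t = registry[cid].template
            pos = margin + k * spacing
            chars[pos:pos + len(t)] = list(t)
            mask[pos:pos + len(t)] = [True] * len(t)
        if not _FRAME_RE.search("".join(chars)):
            return chars, mask
    raise RuntimeError("could not draw a frame-free degenerate cassette")


def _sanitize(chars: list[str], mask: list[bool], planted: list[_Planted],
              registry: MotifRegistry, rng: np.random.Generator,
              scan_cfg: ScanConfig | None = None, max_iter: int = 300) -> None:
    """Resample filler residues that contradict a domain's intended statuses."""
    cfg = scan_cfg or ScanConfig()
    seq = "".join(chars)

    def rewrite(lo: int, hi: int, pattern: re.Pattern) -> None:
        nonlocal seq
        for _ in range(max_iter):
            m = pattern.search(seq, lo, hi)
            if not m:
                return
            free = [p for p in range(m.start(), m.end()) if not mask[p]]
            if not free:
                raise RuntimeError("unintended motif hit inside planted residues")
            for p in free:
                chars[p] = STANDARD_AA[rng.integers(0, len(STANDARD_AA))]
            seq = "".join(chars)
        raise RuntimeError("window sanitisation did not converge")

    for dom in planted:
        if dom.presence is Presence.WELL_FORMED:
            for md in (registry[m] for m in ACTIVE_SITE_MOTIFS):
                if dom.intended[md.motif_id] is Status.INACTIVE:
                    w0, w1 = _window(seq, dom.anchor, md)
                    rewrite(w0, w1, md.regex)
        else:
            lo = max(dom.start0 - cfg.degenerate_pad - 2, 0)
            hi = min(dom.end0 + cfg.degenerate_pad + 2, len(seq))
            rewrite(lo, hi, _FRAME_RE)


@dataclass(frozen=True)
class ProteomeConfig:
    """Study conditions of the synthetic proteome."""

    flank_min: int = 60
    flank_max: int = 150
    p_n_domains: tuple[float, float, float] = (0.3, 0.5, 0.2)  # P(0), P(1), P(2)
    p_intact: float = 0.6        # probability a planted domain has no lesion
    max_lesions: int = 2


def _random_domain_spec(rng, registry, cfg: ProteomeConfig) -> DomainSpec:
    if rng.random() < cfg.p_intact:
        return intact_domain_spec(registry)
    k = int(rng.integers(1, cfg.max_lesions + 1))
    which = rng.choice(ACTIVE_SITE_MOTIFS, size=k, replace=False)
    return lesioned_domain_spec({int(m): "mutate" for m in which}, registry)


def _assemble_protein(rng, registry, specs: list[DomainSpec],
                      cfg: ProteomeConfig):
    chars: list[str] = []
    mask: list[bool] = []
    planted: list[_Planted] = []

    def flank(n: int) -> None:
        chars.extend(_random_seq(rng, n))
        mask.extend([False] * n)

    for i, spec in enumerate(specs):
        m1_absent = (not spec.degenerate) and spec.motif_seqs.get(1) is None
        if i == 0:
            # a domain whose KNRY region is genuinely missing must sit at the
            # N-terminus, otherwise the scanner sees an (empty) window
            flank(int(rng.integers(0, 10)) if m1_absent
                  else int(rng.integers(cfg.flank_min, cfg.flank_max + 1)))
        else:
            flank(int(rng.integers(cfg.flank_min, cfg.flank_max + 1)))
        start0 = len(chars)
        if spec.degenerate:
            c, m = _build_degenerate(rng, registry)
            chars.extend(c)
            mask.extend(m)
            planted.append(_Planted(None, start0, len(chars),
                                    Presence.DEGENERATE, spec.intended_statuses()))
        else:
            c, m, anchor_rel, intended = _build_wellformed(rng, registry, spec)
            chars.extend(c)
            mask.extend(m)
            planted.append(_Planted(start0 + anchor_rel, start0, len(chars),
                                    Presence.WELL_FORMED, intended))
    flank(int(rng.integers(cfg.flank_min, cfg.flank_max + 1)))
    _sanitize(chars, mask, planted, registry, rng)
    return "".join(chars), planted


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside every generated dataset."""

    seed: int
    planted_domains: dict[str, list[dict]] | None = None
    family_tree: str | None = None
    expression_truth: dict | None = None
    cage_truth: dict | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _truth_entry(p: _Planted) -> dict:
    return {
        "start": p.start0 + 1,
        "end": p.end0,
        "presence": p.presence.value,
        "motif_status": {str(m): p.intended[m].value for m in ACTIVE_SITE_MOTIFS},
    }


def make_proteome(n_proteins: int,
                  config: ProteomeConfig | None = None,
                  seed: int = 0,
                  registry: MotifRegistry | None = None,
                  ) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Random proteins with 0-2 planted domain cassettes each."""
    if n_proteins < 1:
        raise ValidationError("n_proteins must be >= 1")
    cfg = config or ProteomeConfig()
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    records, truth = [], {}
    for i in range(n_proteins):
        n_dom = int(rng.choice(3, p=cfg.p_n_domains))
        specs = [_random_domain_spec(rng, registry, cfg) for _ in range(n_dom)]
        seq, planted = _assemble_protein(rng, registry, specs, cfg)
        acc = f"SYN{i + 1:06d}-PA"
        records.append(ProteinRecord(accession=acc, sequence=seq,
                                     description="synthetic PTP test protein"))
        truth[acc] = [_truth_entry(p) for p in planted]
    return records, SyntheticTruth(seed=seed, planted_domains=truth)


def make_protein_with_domains(specs: list[DomainSpec], seed: int = 0,
                              accession: str = "SYN000001-PA",
                              config: ProteomeConfig | None = None,
                              registry: MotifRegistry | None = None,
                              ) -> tuple[ProteinRecord, list[dict]]:
    """One protein built from explicit domain recipes (truth returned)."""
    cfg = config or ProteomeConfig()
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    seq, planted = _assemble_protein(rng, registry, specs, cfg)
    rec = ProteinRecord(accession=accession, sequence=seq)
    return rec, [_truth_entry(p) for p in planted]


def table1_proteome(seed: int = 0,
                    registry: MotifRegistry | None = None,
                    ) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """The packaged ten-protein preset mirroring the published repertoire.

    Plants each domain's printed motif strings verbatim inside template
    scaffolds, so the scanner+classifier must reproduce the published
    per-motif statuses, domain counts (13) and repertoire counts exactly.
    """
    registry = registry or default_registry()
    fixture = load_table1_fixture()
    rng = np.random.default_rng(seed)
    specs_by_acc: dict[str, list[DomainSpec]] = {}
    for r in fixture.itertuples(index=False):
        if r.presence == "DEGENERATE":
            spec = DomainSpec(degenerate=True)
        else:
            spec = DomainSpec(motif_seqs={
                1: r.m1_seq or None,
                8: r.m8_seq,
                9: r.m9_seq,
                10: r.m10_seq,
            })
        specs_by_acc.setdefault(r.accession, []).append(spec)

    cfg = ProteomeConfig()
    records, truth = [], {}
    # splice variants of one locus share a sub-seed: their domain content
    # (indeed their whole sequence) is identical, as in the real repertoire
    from .domains import strip_splice_suffix
    gene_seed: dict[str, int] = {}
    for acc in specs_by_acc:
        gene = strip_splice_suffix(acc)
        if gene not in gene_seed:
            gene_seed[gene] = int(rng.integers(0, 2**31 - 1))
    for acc, specs in specs_by_acc.items():
        sub = gene_seed[strip_splice_suffix(acc)]
        seq, planted = _assemble_protein(
            np.random.default_rng(sub), registry, specs, cfg)
        records.append(ProteinRecord(accession=acc, sequence=seq,
                                     description="synthetic repertoire preset"))
        truth[acc] = [_truth_entry(p) for p in planted]
    return records, SyntheticTruth(seed=seed, planted_domains=truth)


# --------------------------------------------------------------------------
# sequence families on known trees

@dataclass(frozen=True)
class FamilyConfig:
    n_taxa: int = 8
    seq_length: int = 300
    mutation_rate: float = 0.08      # per site per unit branch length
    branch_length_range: tuple[float, float] = (0.6, 1.4)
    tree_newick: str | None = None   # explicit topology overrides the random one


class _TreeNode:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.label
        inner = ",".join(f"{c.newick()}:{bl:g}" for c, bl in self.children)
        return f"({inner})"


def _random_tree(rng, labels: list[str], bl_range) -> _TreeNode:
    nodes = [_TreeNode(lbl) for lbl in labels]
    bl = lambda: float(rng.uniform(*bl_range))
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        merged = _TreeNode(children=[(nodes[i], bl()), (nodes[j], bl())])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return _TreeNode(children=[(n, bl()) for n in nodes])


def _parse_newick(s: str) -> _TreeNode:
    """Minimal newick reader for explicit truth topologies (labels + lengths)."""
    pos = 0

    def parse() -> tuple[_TreeNode, float]:
        nonlocal pos
        if s[pos] == "(":
            pos += 1
            children = []
            while True:
                children.append(parse())
                if s[pos] == ",":
                    pos += 1
                    continue
                break
            assert s[pos] == ")"
            pos += 1
            node = _TreeNode(children=children)
        else:
            start = pos
            while pos < len(s) and s[pos] not in ",():;":
                pos += 1
            node = _TreeNode(label=s[start:pos])
        length = 1.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            start = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            length = float(s[start:pos])
        return node, length

    node, _ = parse()
    return node


def make_family(taxa: int | None = None,
                config: FamilyConfig | None = None,
                mutation_rate: float | None = None,
                seed: int = 0,
                ) -> tuple[dict[str, str], SyntheticTruth]:
    """Evolve a root sequence down a (random or given) tree.

    Each site on each branch substitutes with probability
    ``1 - exp(-rate * branch_length)``; the realised topology and branch
    lengths are recorded as the truth newick.
    """
    cfg = config or FamilyConfig()
    if taxa is not None:
        cfg = FamilyConfig(n_taxa=taxa, seq_length=cfg.seq_length,
                           mutation_rate=cfg.mutation_rate,
                           branch_length_range=cfg.branch_length_range,
                           tree_newick=cfg.tree_newick)
    rate = cfg.mutation_rate if mutation_rate is None else mutation_rate
    if not (0 <= rate < 1):
        raise ValidationError("mutation rate must lie in [0, 1) per site per branch")
    if cfg.n_taxa < 3:
        raise ValidationError("need at least 3 taxa")
    rng = np.random.default_rng(seed)

    if cfg.tree_newick:
        root = _parse_newick(cfg.tree_newick)
    else:
        labels = [f"T{i + 1}" for i in range(cfg.n_taxa)]
        root = _random_tree(rng, labels, cfg.branch_length_range)

    aa = np.array(list(STANDARD_AA))
    root_seq = rng.integers(0, 20, cfg.seq_length)
    leaves: dict[str, str] = {}

    def evolve(node: _TreeNode, seq: np.ndarray) -> None:
        if not node.children:
            leaves[node.label] = "".join(aa[seq])
            return
        for child, bl in node.children:
            p = 1.0 - np.exp(-rate * bl)
            child_seq = seq.copy()
            hit = rng.random(len(seq)) < p
            # substitute to one of the 19 other residues
            shift = rng.integers(1, 20, hit.sum())
            child_seq[hit] = (child_seq[hit] + shift) % 20
            evolve(child, child_seq)

    evolve(root, root_seq)
    newick = root.newick() + ";"
    return leaves, SyntheticTruth(seed=seed, family_tree=newick)


# --------------------------------------------------------------------------
# qPCR Ct tables and egg-count cage tables

def make_ct_table(fold_changes: dict[str, dict[str, float]],
                  efficiencies: dict[str, float] | None = None,
                  conditions: list[str] | None = None,
                  calibrator: str = "control",
                  reference_gene: str = "rp49",
                  noise_sd: float = 0.2,
                  n_replicates: int = 3,
                  seed: int = 0,
                  ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate threshold cycles for target genes plus the reference gene.

    ``fold_changes[gene][condition]`` is the true expression of ``gene`` in
    ``condition`` relative to the calibrator condition.  Ct values are drawn
    as ``baseline - log_E(fold) + N(0, noise_sd)``; the reference gene's fold
    is fixed at 1 in every condition.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if n_replicates < 2:
        raise ValidationError("need at least duplicate measurements")
    for g, byc in fold_changes.items():
        for c, f in byc.items():
            if f <= 0:
                raise ValidationError(f"fold change must be positive ({g}/{c}: {f})")
    rng = np.random.default_rng(seed)
    genes = list(fold_changes)
    if conditions is None:
        conditions = sorted({c for byc in fold_changes.values() for c in byc}
                            | {calibrator})
    efficiencies = dict(efficiencies or {})
    for g in genes + [reference_gene]:
        eff = efficiencies.setdefault(g, 2.0)
        if not (1.0 <= eff <= 2.0):
            raise ValidationError(f"efficiency for {g} outside [1, 2]: {eff}")

    baselines = {g: float(rng.uniform(18, 26)) for g in genes + [reference_gene]}
    rows = []
    for cond in conditions:
        for g in genes + [reference_gene]:
            fold = 1.0 if g == reference_gene or cond == calibrator \
                else fold_changes[g].get(cond, 1.0)
            eff = efficiencies[g]
            mean_ct = baselines[g] - (np.log(fold) / np.log(eff) if eff > 1 else 0.0)
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "sample_id": f"{cond}_r{rep}",
                    "condition": cond,
                    "gene": g,
                    "replicate": rep,
                    "ct": float(mean_ct + rng.normal(0, noise_sd)),
                    "efficiency": eff,
                })
    df = pd.DataFrame(rows)
    truth = SyntheticTruth(seed=seed, expression_truth={
        "calibrator": calibrator,
        "reference_gene": reference_gene,
        "fold_changes": fold_changes,
        "efficiencies": efficiencies,
        "noise_sd": noise_sd,
    })
    return df, truth


def make_cage_table(means: dict[str, float],
                    n_cages: int = 4,
                    females_range: tuple[int, int] = (10, 15),
                    seed: int = 0,
                    ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Egg-count tables: per cage, eggs ~ Poisson(mean_per_female * females)."""
    if n_cages < 1:
        raise ValidationError("n_cages must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for treatment, mean in means.items():
        if mean < 0:
            raise ValidationError("mean eggs per female must be >= 0")
        for i in range(n_cages):
            females = int(rng.integers(females_range[0], females_range[1] + 1))
            eggs = int(rng.poisson(mean * females))
            rows.append({"unit_id": f"{treatment}_cage{i + 1}",
                         "treatment": treatment,
                         "eggs": eggs, "females": females})
    df = pd.DataFrame(rows)
    return df, SyntheticTruth(seed=seed, cage_truth={"means": means})


# --------------------------------------------------------------------------
# dataset serialization

def save_proteome(records, truth: SyntheticTruth, outdir: str | Path,
                  stem: str = "proteome") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(records, outdir / f"{stem}.fasta")
    truth.to_json(outdir / f"{stem}.truth.json")


def save_family(leaves: dict[str, str], truth: SyntheticTruth,
                outdir: str | Path, stem: str = "family") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recs = [ProteinRecord(accession=k, sequence=v) for k, v in leaves.items()]
    write_fasta(recs, outdir / f"{stem}.fasta")
    truth.to_json(outdir / f"{stem}.truth.json")
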