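"""Motif-constellation search for classical PTP domains in protein sequences.

Instead of a profile-HMM, candidate domains are located by the constellation
of the ten PTP motifs around the P-loop:

1. enumerate anchor candidates — positions of the relaxed C-x5-R frame,
   plus anchors inferred by "voting" of core-motif matches (>=3 core motifs
   whose match positions agree, within tolerance, on a common P-loop
   position; this recovers domains whose catalytic cysteine is substituted);
2. for each anchor, search each motif's window (expected offset +/-
   tolerance, relative to the anchor cysteine) for its pattern;
3. anchors with >=5 of the 10 motifs located become WELL_FORMED domains;
   overlapping candidates are resolved by most-motifs-first, then leftmost;
4. clusters of >=2 core motifs outside any well-formed domain and lacking a
   P-loop frame become DEGENERATE (pseudo-phosphatase remnant) domains with
   all four active-site motifs ABSENT.

Reported coordinates are 1-based inclusive, the convention used in the
repertoire tables; :func:`to_zero_based` / :func:`to_one_based` convert to
and from Python's 0-based half-open slices.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, InvalidResidueError, ValidationError
from .motifs import (
    ACTIVE_SITE_MOTIFS,
    MotifCall,
    MotifDefinition,
    MotifRegistry,
    Status,
    VALID_RESIDUES,
    default_registry,
)

_ACCESSION_RE = re.compile(r"^(?P<gene>[A-Z0-9]+?)(?:-P(?P<variant>[A-Z]))?$")
_FRAME_RE = re.compile(r"(?=(C.{5}R))")


def strip_splice_suffix(accession: str) -> str:
    """AAEL001919-PA -> AAEL001919; accessions without a suffix pass through."""
    m = _ACCESSION_RE.match(accession)
    if not m:
        raise ValidationError(f"malformed accession: {accession!r}")
    return m.group("gene")


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein: accession, parent gene locus, and sequence."""

    accession: str
    sequence: str
    description: str = ""
    gene_id: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.accession}: empty sequence")
        seq = self.sequence.upper()
        for i, ch in enumerate(seq):
            if ch not in VALID_RESIDUES:
                raise InvalidResidueError(ch, i, f"record {self.accession}")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "gene_id", strip_splice_suffix(self.accession))

    def __len__(self) -> int:
        return len(self.sequence)


class Presence(str, enum.Enum):
    WELL_FORMED = "WELL_FORMED"
    DEGENERATE = "DEGENERATE"


@dataclass(frozen=True)
class DomainAnnotation:
    """One PTP domain call: boundaries, active-site motif calls, verdict.

    ``start``/``end`` are 1-based inclusive residue coordinates.  ``verdict``
    is filled by the repertoire classifier and stays ``None`` after a bare
    scan.
    """

    protein: str
    start: int
    end: int
    presence: Presence
    motif_calls: tuple[MotifCall, MotifCall, MotifCall, MotifCall]
    verdict: Status | None = None
    n_motifs_located: int = 0
    core_status: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= self.start < self.end):
            raise ValidationError(
                f"{self.protein}: invalid domain boundaries {self.start}..{self.end}"
            )
        ids = tuple(c.motif_id for c in self.motif_calls)
        if ids != ACTIVE_SITE_MOTIFS:
            raise ValidationError(f"motif calls must cover {ACTIVE_SITE_MOTIFS}, got {ids}")

    def call(self, motif_id: int) -> MotifCall:
        return self.motif_calls[ACTIVE_SITE_MOTIFS.index(motif_id)]


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start0 + 1, end0


@dataclass(frozen=True)
class ScanConfig:
    """Tunable knobs of the constellation search (all residue counts)."""

    min_motifs: int = 5          # located motifs required for WELL_FORMED
    min_core_votes: int = 3      # core matches needed to infer an anchor
    vote_radius: int = 12        # clustering radius for core anchor votes
    pad_left: int = 30           # boundary padding upstream of motif 1 (or 8)
    pad_right: int = 20          # boundary padding past the Q loop
    degenerate_min_core: int = 2
    degenerate_gap: int = 60     # max spacing between clustered core matches
    degenerate_pad: int = 10     # frame exclusion margin around a core cluster


def _window(seq: str, anchor: int, md: MotifDefinition) -> tuple[int, int]:
    """Search window (0-based half-open) for a motif at a given anchor."""
    w0 = anchor + md.offset - md.tolerance
    w1 = anchor + md.offset + md.tolerance + md.span
    return max(w0, 0), min(w1, len(seq))


def _evaluate_anchor(seq: str, anchor: int, registry: MotifRegistry):
    """Count located motifs at ``anchor`` and call the active-site four."""
    located = 0
    calls: list[MotifCall] = []
    core_hits: list[bool] = []
    for md in registry:
        w0, w1 = _window(seq, anchor, md)
        expected = anchor + md.offset
        in_range = 0 <= expected < len(seq) and w1 > w0
        m = md.regex.search(seq, w0, w1) if in_range else None
        if md.motif_id in ACTIVE_SITE_MOTIFS:
            if not in_range:
                calls.append(MotifCall(md.motif_id, "", None, Status.ABSENT))
            elif m:
                located += 1
                calls.append(
                    MotifCall(md.motif_id, m.group(0), m.start(), Status.ACTIVE)
                )
            else:
                calls.append(
                    MotifCall(md.motif_id, seq[w0:w1], w0, Status.INACTIVE)
                )
        else:
            hit = bool(m)
            core_hits.append(hit)
            located += hit
    return located, tuple(calls), tuple(core_hits)


def _anchor_candidates(seq: str, registry: MotifRegistry, cfg: ScanConfig) -> list[int]:
    anchors = {m.start() for m in _FRAME_RE.finditer(seq)}
    # constellation voting: each core match proposes where the P-loop should be
    votes: list[int] = []
    for md in registry.core:
        votes.extend(m.start() - md.offset for m in md.regex.finditer(seq))
    votes.sort()
    i = 0
    while i < len(votes):
        j = i
        while j + 1 < len(votes) and votes[j + 1] - votes[i] <= 2 * cfg.vote_radius:
            j += 1
        if j - i + 1 >= cfg.min_core_votes:
            anchors.add(votes[(i + j) // 2])
        i = j + 1
    return sorted(a for a in anchors if 0 <= a < len(seq))


def _boundaries(seq: str, anchor: int, calls, registry: MotifRegistry,
                cfg: ScanConfig) -> tuple[int, int]:
    m1, _, m9, m10 = calls
    left_md = registry[1] if m1.status is not Status.ABSENT else registry[8]
    left = anchor + left_md.offset - cfg.pad_left
    if m10.status is not Status.ABSENT:
        right = anchor + registry[10].offset + registry[10].span + cfg.pad_right
    else:
        right = anchor + registry[9].span + cfg.pad_right
    left0, right0 = max(left, 0), min(right, len(seq))
    return to_one_based(left0, right0)


def scan_protein(record: ProteinRecord,
                 registry: MotifRegistry | None = None,
                 config: ScanConfig | None = None) -> list[DomainAnnotation]:
    """Locate PTP domains (well-formed and degenerate) in one protein."""
    registry = registry or default_registry()
    cfg = config or ScanConfig()
    if len(registry) == 0:  # defensive; registry enforces ten on load
        raise ConfigurationError("empty motif registry")
    seq = record.sequence

    candidates = []
    for anchor in _anchor_candidates(seq, registry, cfg):
        located, calls, core_hits = _evaluate_anchor(seq, anchor, registry)
        if located >= cfg.min_motifs:
            start, end = _boundaries(seq, anchor, calls, registry, cfg)
            candidates.append((located, start, end, anchor, calls, core_hits))

    # most motifs first; ties by leftmost boundary, then leftmost anchor
    candidates.sort(key=lambda c: (-c[0], c[1], c[3]))
    kept: list[tuple] = []
    for cand in candidates:
        if all(cand[2] < k[1] or cand[1] > k[2] for k in kept):
            kept.append(cand)

    annotations = [
        DomainAnnotation(
            protein=record.accession, start=start, end=end,
            presence=Presence.WELL_FORMED, motif_calls=calls,
            n_motifs_located=located, core_status=core_hits,
        )
        for located, start, end, _anchor, calls, core_hits in kept
    ]

    kept_anchors = [k[3] for k in kept]
    annotations.extend(
        _degenerate_domains(record, registry, cfg, kept_anchors))
    annotations.sort(key=lambda a: a.start)
    return annotations


def _constellation_footprint(registry: MotifRegistry) -> tuple[int, int]:
    """Residue span, relative to an anchor, covered by any motif window."""
    lo = min(d.offset - d.tolerance for d in registry)
    hi = max(d.offset + d.tolerance + d.span for d in registry)
    return lo, hi


def _degenerate_domains(record: ProteinRecord, registry: MotifRegistry,
                        cfg: ScanConfig, kept_anchors: list[int]):
    """Core-motif clusters with no P-loop frame: pseudo-domain remnants."""
    seq = record.sequence
    flo, fhi = _constellation_footprint(registry)
    spans = [(a + flo, a + fhi) for a in kept_anchors]
    hits = []  # (pos0, end0, motif_id)
    for md in registry.core:
        for m in md.regex.finditer(seq):
            if not any(s <= m.start() < e for s, e in spans):
                hits.append((m.start(), m.end(), md.motif_id))
    hits.sort()

    out = []
    i = 0
    while i < len(hits):
        j = i
        while j + 1 < len(hits) and hits[j + 1][0] - hits[j][1] <= cfg.degenerate_gap:
            j += 1
        cluster = hits[i:j + 1]
        i = j + 1
        if len({h[2] for h in cluster}) < cfg.degenerate_min_core:
            continue
        c0 = max(cluster[0][0] - cfg.degenerate_pad, 0)
        c1 = min(cluster[-1][1] + cfg.degenerate_pad, len(seq))
        if _FRAME_RE.search(seq, c0, c1):
            continue  # a P-loop frame is present: not a bare remnant
        start, end = to_one_based(max(cluster[0][0] - cfg.pad_left, 0),
                                  min(cluster[-1][1] + cfg.pad_right, len(seq)))
        absent = tuple(
            MotifCall(mid, "", None, Status.ABSENT) for mid in ACTIVE_SITE_MOTIFS
        )
        out.append(DomainAnnotation(
            protein=record.accession, start=start, end=end,
            presence=Presence.DEGENERATE, motif_calls=absent,
            n_motifs_located=len(cluster),
            core_status=tuple(mid in {h[2] for h in cluster}
                              for mid in (2, 3, 4, 5, 6, 7)),
        ))
    return out


def scan_proteome(records: list[ProteinRecord],
                  registry: MotifRegistry | None = None,
                  config: ScanConfig | None = None) -> list[DomainAnnotation]:
    """Scan a whole proteome, preserving input order.

    Raises :class:`ValidationError` on duplicate accessions.
    """
    seen: set[str] = set()
    for r in records:
        if r.accession in seen:
            raise ValidationError(f"duplicate accession: {r.accession}")
        seen.add(r.accession)
    out: list[DomainAnnotation] = []
    for r in records:
        out.extend(scan_protein(r, registry, config))
    return out


# --------------------------------------------------------------------------
# FASTA and report I/O

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from (wrapped or unwrapped) FASTA."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(
            accession=rec.id, sequence=str(rec.seq), description=rec.description,
        ))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.accession}"
            if r.description and r.description != r.accession:
                header += f" {r.description}"
            fh.write(header + "\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")


def annotations_to_frame(annotations: list[DomainAnnotation]) -> pd.DataFrame:
    """Flatten annotations into the TSV report layout (one row per domain)."""
    rows = []
    for a in annotations:
        row = {
            "accession": a.protein,
            "gene_id": strip_splice_suffix(a.protein),
            "start": a.start,
            "end": a.end,
            "presence": a.presence.value,
        }
        for c in a.motif_calls:
            row[f"motif{c.motif_id}"] = c.status.value
        for mid, hit in zip((2, 3, 4, 5, 6, 7), a.core_status or (None,) * 6):
            row[f"motif{mid}"] = ("LOCATED" if hit else "NOT_LOCATED") if hit is not None else ""
        row["verdict"] = a.verdict.value if a.verdict else ""
        rows.append(row)
    cols = (["accession", "gene_id", "start", "end", "presence"]
            + [f"motif{i}" for i in range(1, 11)] + ["verdict"])
    return pd.DataFrame(rows, columns=cols)


def write_annotation_report(annotations: list[DomainAnnotation],
                            path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)
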