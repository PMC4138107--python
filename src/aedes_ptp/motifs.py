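"""Active-site motif grammar for classical protein tyrosine phosphatase (PTP) domains.

A classical PTP catalytic domain is described by ten conserved sequence motifs.
Four of them carry the active-site residues and decide catalytic competence:

* motif 1, the KNRY loop — recruits the substrate phosphotyrosine;
* motif 8, the WPD loop — supplies the general-acid aspartate;
* motif 9, the P-loop (HCX5R) — holds the nucleophilic cysteine;
* motif 10, the Q loop — glutamines positioning the hydrolytic water.

The remaining six motifs (2–7) form the structural core of the fold and are
used here only to anchor domain searches, never to score activity.

Competence is decided by degenerate residue patterns, one per active-site
motif, shipped as editable data (``data/motif_definitions.tsv``).  A motif
region is ACTIVE when the pattern matches anywhere inside it, INACTIVE when
it does not, and ABSENT when the region is empty.  Ambiguous residues
(B, Z, X) can fill wildcard positions but never satisfy an anchor residue
class, so an unconfirmed catalytic residue never yields ACTIVE.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, ContractError, InvalidResidueError

#: The 20 standard amino acids.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity codes accepted in input sequences (never ACTIVE at anchors).
AMBIGUOUS_AA = "BZX"
VALID_RESIDUES = frozenset(STANDARD_AA + AMBIGUOUS_AA)

ACTIVE_SITE_MOTIFS = (1, 8, 9, 10)
CORE_MOTIFS = (2, 3, 4, 5, 6, 7)


class Status(str, enum.Enum):
    """Catalytic-competence status of a single motif or whole domain."""

    ACTIVE = "ACTIVE"
    INACTIVE = "INACTIVE"
    ABSENT = "ABSENT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Role(str, enum.Enum):
    ACTIVE_SITE = "active_site"
    CORE = "core"


@dataclass(frozen=True)
class MotifDefinition:
    """Grammar of one of the ten PTP motifs.

    ``offset`` is the expected start of the motif relative to the P-loop
    catalytic cysteine (negative = upstream), ``tolerance`` the half-width of
    the search window around that offset.  ``template`` is the canonical
    (catalytically competent) instance planted by the synthetic generator.
    """

    motif_id: int
    name: str
    role: Role
    active_pattern: str
    offset: int
    tolerance: int
    template: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "_regex", re.compile(self.active_pattern))

    @property
    def regex(self) -> re.Pattern:
        return self._regex  # type: ignore[attr-defined]

    @property
    def span(self) -> int:
        """Nominal residue span of the motif (template length)."""
        return len(self.template)


@dataclass(frozen=True)
class MotifCall:
    """One motif observation: what was seen, where, and its status.

    ``start`` is a 0-based index into the parent sequence (or the isolated
    region); it is ``None`` exactly when the motif is ABSENT.
    """

    motif_id: int
    observed_sequence: str
    start: int | None
    status: Status

    def __post_init__(self) -> None:
        absent = self.status is Status.ABSENT
        if absent != (self.observed_sequence == "" and self.start is None):
            raise ContractError(
                "ABSENT status requires (and is required by) an empty "
                "observation with null start"
            )


class MotifRegistry:
    """The ten motif definitions, loadable from a TSV file."""

    def __init__(self, definitions: list[MotifDefinition]):
        ids = [d.motif_id for d in definitions]
        if sorted(ids) != list(range(1, 11)):
            raise ConfigurationError(
                f"registry must contain motifs 1..10 exactly once, got {sorted(ids)}"
            )
        for d in definitions:
            expected = Role.ACTIVE_SITE if d.motif_id in ACTIVE_SITE_MOTIFS else Role.CORE
            if d.role is not expected:
                raise ConfigurationError(
                    f"motif {d.motif_id} must have role {expected.value}"
                )
        self._by_id = {d.motif_id: d for d in definitions}

    def __getitem__(self, motif_id: int) -> MotifDefinition:
        return self._by_id[motif_id]

    def __iter__(self):
        return iter(sorted(self._by_id.values(), key=lambda d: d.motif_id))

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def active_site(self) -> list[MotifDefinition]:
        return [self._by_id[i] for i in ACTIVE_SITE_MOTIFS]

    @property
    def core(self) -> list[MotifDefinition]:
        return [self._by_id[i] for i in CORE_MOTIFS]

    @classmethod
    def load(cls, path: str | Path | None = None) -> "MotifRegistry":
        """Load a registry from TSV; with no path, the packaged default."""
        if path is None:
            with resources.as_file(
                resources.files("aedes_ptp.data") / "motif_definitions.tsv"
            ) as p:
                return cls._read(p)
        return cls._read(Path(path))

    @classmethod
    def _read(cls, path: Path) -> "MotifRegistry":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"motif_id", "name", "role", "active_pattern", "offset",
                    "tolerance", "template"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"motif file missing columns: {sorted(missing)}")
        defs = [
            MotifDefinition(
                motif_id=int(r.motif_id),
                name=r.name,
                role=Role(r.role),
                active_pattern=r.active_pattern,
                offset=int(r.offset),
                tolerance=int(r.tolerance),
                template=r.template,
            )
            for r in df.itertuples(index=False)
        ]
        return cls(defs)


_DEFAULT_REGISTRY: MotifRegistry | None = None


def default_registry() -> MotifRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = MotifRegistry.load()
    return _DEFAULT_REGISTRY


def validate_region(region: str, context: str = "motif region") -> str:
    """Uppercase ``region`` and reject characters outside the alphabet."""
    up = region.upper()
    for i, ch in enumerate(up):
        if ch not in VALID_RESIDUES:
            raise InvalidResidueError(ch, i, context)
    return up


def call_motif(motif_id: int, region: str,
               registry: MotifRegistry | None = None) -> MotifCall:
    """Decide competence of an isolated motif-region sequence.

    Empty input is ABSENT.  Regions shorter than the pattern's span are
    simply INACTIVE (truncated degenerate motifs occur in real repertoires).
    Matching is case-insensitive and deterministic.
    """
    if motif_id not in ACTIVE_SITE_MOTIFS:
        raise ContractError(f"motif {motif_id} is not an active-site motif")
    registry = registry or default_registry()
    region = validate_region(region, context=f"motif {motif_id} region")
    if region == "":
        return MotifCall(motif_id, "", None, Status.ABSENT)
    status = Status.ACTIVE if registry[motif_id].regex.search(region) else Status.INACTIVE
    return MotifCall(motif_id, region, 0, status)


def call_motif1(region: str, registry: MotifRegistry | None = None) -> MotifCall:
    """KNRY loop: basic residue, <=2 arbitrary, R, <=1 arbitrary, aromatic."""
    return call_motif(1, region, registry)


def call_motif8(region: str, registry: MotifRegistry | None = None) -> MotifCall:
    """WPD loop: the contiguous W-P-D triad (general-acid aspartate in place)."""
    return call_motif(8, region, registry)


def call_motif9(region: str, registry: MotifRegistry | None = None) -> MotifCall:
    """P-loop: H-C-S-A-G-[IVLM]-G-R, the nucleophilic Cys in its C-x5-R frame."""
    return call_motif(9, region, registry)


def call_motif10(region: str, registry: MotifRegistry | None = None) -> MotifCall:
    """Q loop: a 9-residue window with glutamine at positions 2 and 6."""
    return call_motif(10, region, registry)


def load_table1_fixture() -> pd.DataFrame:
    """The packaged worked example: per-domain motif strings and printed calls.

    One row per PTP domain of the ten-protein repertoire; empty motif cells
    denote ABSENT motifs (degenerate domains, or a missing KNRY region).
    """
    with resources.as_file(
        resources.files("aedes_ptp.data") / "table1_motifs.tsv"
    ) as p:
        df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    return df
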