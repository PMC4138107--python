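"""Domain verdicts, gene-level summaries and repertoire counts.

A PTP domain is catalytically ACTIVE when the WPD loop (motif 8), the P-loop
(motif 9) and the Q loop (motif 10) are all competent.  The KNRY loop
(motif 1) recruits substrate but does not gate the verdict: a domain lacking
the KNRY region can still be an active enzyme, and the repertoire contains
exactly such a case.  The rule ships as configuration
(:data:`REQUIRED_ACTIVE_MOTIFS`).

Gene-level calls group protein records by locus (splice suffix -PA/-PB
stripped); splice variants carrying identical domain content collapse to a
single gene verdict.  Exclusions (curated genes that are not true classical
PTPs, e.g. a MAPK-phosphatase ortholog) are explicit user input, never
inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .domains import DomainAnnotation, strip_splice_suffix
from .errors import ContractError
from .motifs import ACTIVE_SITE_MOTIFS, MotifCall, Status

#: Motifs that must all be ACTIVE for a domain to be called ACTIVE (D3 rule).
REQUIRED_ACTIVE_MOTIFS: tuple[int, ...] = (8, 9, 10)


def classify_domain(calls, required: tuple[int, ...] = REQUIRED_ACTIVE_MOTIFS) -> Status:
    """Verdict for one domain from its four active-site motif calls."""
    ids = [c.motif_id for c in calls]
    if sorted(ids) != sorted(ACTIVE_SITE_MOTIFS):
        raise ContractError(
            f"expected one call per motif in {ACTIVE_SITE_MOTIFS}, got {ids}"
        )
    by_id = {c.motif_id: c for c in calls}
    ok = all(by_id[m].status is Status.ACTIVE for m in required)
    return Status.ACTIVE if ok else Status.INACTIVE


def annotate_verdicts(annotations: list[DomainAnnotation]) -> list[DomainAnnotation]:
    """Return annotations with the domain verdict filled in."""
    return [replace(a, verdict=classify_domain(a.motif_calls)) for a in annotations]


@dataclass(frozen=True)
class GeneSummary:
    """Collapsed view of one gene locus."""

    gene_id: str
    protein_accessions: tuple[str, ...]
    n_domains_total: int
    n_domains_active: int
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def gene_active(self) -> bool:
        return self.n_domains_active >= 1 and not self.excluded


@dataclass(frozen=True)
class RepertoireReport:
    n_proteins: int
    n_genes: int
    n_proteins_with_active_domain: int
    n_active_genes: int


def load_default_exclusions() -> dict[str, str]:
    """The packaged curation list (gene_id -> reason)."""
    with resources.as_file(resources.files("aedes_ptp.data") / "exclusions.tsv") as p:
        return read_exclusions(p)


def read_exclusions(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns[:2]) != ["gene_id", "reason"]:
        raise ContractError("exclusion list needs columns: gene_id, reason")
    return dict(zip(df.gene_id, df.reason))


def summarize_repertoire(
    annotations: list[DomainAnnotation],
    exclusions: dict[str, str] | None = None,
    accessions: list[str] | None = None,
) -> tuple[list[GeneSummary], RepertoireReport]:
    """Group domain verdicts into gene summaries and headline counts.

    ``accessions`` optionally names the full protein set (so proteins with
    zero detected domains are still counted); by default it is derived from
    the annotations.  Verdicts must already be filled
    (see :func:`annotate_verdicts`).
    """
    exclusions = exclusions or {}
    for a in annotations:
        if a.verdict is None:
            raise ContractError(f"{a.protein}: annotation lacks a verdict")
    if accessions is None:
        seen: list[str] = []
        for a in annotations:
            if a.protein not in seen:
                seen.append(a.protein)
        accessions = seen
    else:
        known = set(accessions)
        for a in annotations:
            if a.protein not in known:
                raise ContractError(f"annotation references unknown protein {a.protein}")

    by_protein: dict[str, list[DomainAnnotation]] = {acc: [] for acc in accessions}
    for a in annotations:
        by_protein[a.protein].append(a)

    genes: dict[str, list[str]] = {}
    for acc in accessions:
        genes.setdefault(strip_splice_suffix(acc), []).append(acc)

    summaries = []
    for gene_id in sorted(genes):
        accs = tuple(sorted(genes[gene_id]))
        doms = [d for acc in accs for d in by_protein[acc]]
        summaries.append(GeneSummary(
            gene_id=gene_id,
            protein_accessions=accs,
            n_domains_total=len(doms),
            n_domains_active=sum(d.verdict is Status.ACTIVE for d in doms),
            excluded=gene_id in exclusions,
            exclusion_reason=exclusions.get(gene_id, ""),
        ))

    n_prot_active = sum(
        any(d.verdict is Status.ACTIVE for d in by_protein[acc])
        for acc in accessions
    )
    report = RepertoireReport(
        n_proteins=len(accessions),
        n_genes=len(summaries),
        n_proteins_with_active_domain=n_prot_active,
        n_active_genes=sum(s.gene_active for s in summaries),
    )
    return summaries, report


# --------------------------------------------------------------------------
# report I/O

def summaries_to_frame(summaries: list[GeneSummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "gene_id": s.gene_id,
            "protein_accessions": ",".join(s.protein_accessions),
            "n_domains_total": s.n_domains_total,
            "n_domains_active": s.n_domains_active,
            "gene_active": s.gene_active,
            "excluded": s.excluded,
            "exclusion_reason": s.exclusion_reason,
        }
        for s in summaries
    ])


def write_summaries(summaries: list[GeneSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, sep="\t", index=False)


def read_summaries(path: str | Path) -> list[GeneSummary]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"exclusion_reason": str})
    out = []
    for r in df.itertuples(index=False):
        out.append(GeneSummary(
            gene_id=r.gene_id,
            protein_accessions=tuple(r.protein_accessions.split(",")),
            n_domains_total=int(r.n_domains_total),
            n_domains_active=int(r.n_domains_active),
            excluded=bool(r.excluded),
            exclusion_reason=r.exclusion_reason,
        ))
    return out


def format_summary(report: RepertoireReport, summaries: list[GeneSummary]) -> str:
    """One-page plain-text repertoire summary."""
    lines = [
        "Classical PTP repertoire summary",
        "================================",
        f"proteins scanned:                 {report.n_proteins}",
        f"gene loci:                        {report.n_genes}",
        f"proteins with >=1 active domain:  {report.n_proteins_with_active_domain}",
        f"catalytically active genes:       {report.n_active_genes}",
        "",
        "Per-gene calls:",
    ]
    for s in summaries:
        flag = "ACTIVE" if s.gene_active else ("EXCLUDED" if s.excluded else "inactive")
        lines.append(
            f"  {s.gene_id}: {s.n_domains_active}/{s.n_domains_total} active domains "
            f"[{flag}]" + (f" ({s.exclusion_reason})" if s.excluded else "")
        )
    return "\n".join(lines) + "\n"
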