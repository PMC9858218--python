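"""Family membership from domain hits, subfamily assignment and naming.

Proteins enter the family through significant hits to subfamily-diagnostic
Pfam domains (default scheme: the six chaperone subfamilies SHSP, HSP40,
HSP60, HSP70, HSP90, HSP100).  Accepted members are named with the scheme's
prefix and numbered within each subfamily by chromosomal position, ascending
coordinate standing in for the short-to-long-arm convention since assembly
files carry no arm annotation.

Molecular-weight windows in the scheme are advisory only: a member whose MW
falls outside its subfamily's window is flagged, never reassigned (real
families contain such outliers, e.g. ~97 kDa proteins retained in an HSP70
subfamily).
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainHit, GeneModel, ProteinRecord
from .physchem import PhyschemStats, characterize

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_THRESHOLD = 1e-4


@dataclass(frozen=True)
class SubfamilyRule:
    """One subfamily: diagnostic domain accessions, name stem, MW window."""

    label: str
    accessions: frozenset[str]
    name_stem: str
    mw_window_kda: tuple[float, float]


@dataclass
class SubfamilyScheme:
    """Ordered subfamily rules; domain sets must be pairwise disjoint."""

    rules: list[SubfamilyRule]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.rules]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate subfamily labels")
        seen: set[str] = set()
        for r in self.rules:
            overlap = seen & r.accessions
            if overlap:
                raise ValueError(f"domain sets overlap: {sorted(overlap)}")
            seen |= r.accessions

    def rule_for_accession(self, accession: str) -> SubfamilyRule | None:
        for r in self.rules:
            if accession in r.accessions:
                return r
        return None


def default_scheme(prefix: str = "Le") -> SubfamilyScheme:
    """The six-subfamily heat-shock-protein scheme with Pfam accessions."""
    return SubfamilyScheme([
        SubfamilyRule("SHSP", frozenset({"PF00011"}), prefix + "SHSP",
                      (10.0, 45.0)),
        SubfamilyRule("HSP40", frozenset({"PF00226", "PF01556"}),
                      prefix + "HSP40", (30.0, 55.0)),
        SubfamilyRule("HSP60", frozenset({"PF00118"}), prefix + "HSP60",
                      (50.0, 65.0)),
        SubfamilyRule("HSP70", frozenset({"PF00012"}), prefix + "HSP70",
                      (60.0, 80.0)),
        SubfamilyRule("HSP90", frozenset({"PF00183"}), prefix + "HSP90",
                      (75.0, 95.0)),
        SubfamilyRule("HSP100", frozenset({"PF02861", "PF10431"}),
                      prefix + "HSP100", (80.0, 105.0)),
    ])


@dataclass
class FamilyMember:
    """A protein accepted into the family."""

    protein_id: str
    subfamily: str
    supporting_hits: list[DomainHit]
    gene: GeneModel | None = None
    assigned_name: str = ""
    stats: PhyschemStats | None = None
    mw_flag: bool = False


def filter_hits(hits: Iterable[DomainHit],
                threshold: float = DEFAULT_EVALUE_THRESHOLD) -> list[DomainHit]:
    """Keep hits with E-value strictly below the threshold, order preserved."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return [h for h in hits if h.evalue < threshold]


def assign_subfamily(hits: Sequence[DomainHit],
                     scheme: SubfamilyScheme) -> str | None:
    """Subfamily of one protein's filtered hits, or None if rejected.

    The label comes from the scheme entry containing the hit with the
    smallest E-value among hits matching any scheme domain; ties break by
    scheme order.
    """
    best_label: str | None = None
    best_e = float("inf")
    for rank, rule in enumerate(scheme.rules):
        for h in hits:
            if h.domain_accession in rule.accessions and h.evalue < best_e:
                best_e = h.evalue
                best_label = rule.label
    return best_label


def identify_members(hits: Iterable[DomainHit],
                     scheme: SubfamilyScheme | None = None,
                     threshold: float = DEFAULT_EVALUE_THRESHOLD,
                     ) -> list[FamilyMember]:
    """Group filtered hits by protein and accept proteins with a subfamily."""
    scheme = scheme or default_scheme()
    kept = filter_hits(hits, threshold)
    by_protein: dict[str, list[DomainHit]] = {}
    for h in kept:
        by_protein.setdefault(h.protein_id, []).append(h)
    members = []
    for pid in sorted(by_protein):
        label = assign_subfamily(by_protein[pid], scheme)
        if label is None:
            logger.info("protein %s rejected: no diagnostic domain", pid)
            continue
        members.append(FamilyMember(pid, label, by_protein[pid]))
    return members


_NATURAL_RE = re.compile(r"(\d+)")


def natural_key(chrom: str) -> tuple:
    """Sort key treating embedded digits numerically ('Chr2' < 'Chr10')."""
    return tuple(int(p) if p.isdigit() else p
                 for p in _NATURAL_RE.split(chrom))


def assign_names(members: Sequence[FamilyMember],
                 gene_of: Mapping[str, GeneModel],
                 scheme: SubfamilyScheme | None = None) -> list[FamilyMember]:
    """Number members within each subfamily by (chromosome, start) order.

    Ties at identical (chromosome, start) break deterministically by
    protein id and are logged.  Idempotent and independent of input order.
    """
    scheme = scheme or default_scheme()
    stem = {r.label: r.name_stem for r in scheme.rules}
    for m in members:
        if m.gene is None:
            m.gene = gene_of[m.protein_id]
    out = sorted(members, key=lambda m: m.protein_id)
    for rule in scheme.rules:
        sub = [m for m in out if m.subfamily == rule.label]
        sub.sort(key=lambda m: (natural_key(m.gene.chromosome),
                                m.gene.start, m.protein_id))
        for pos, m in enumerate(sub, 1):
            m.assigned_name = f"{stem[m.subfamily]}.{pos}"
        for a, b in zip(sub, sub[1:]):
            if (a.gene.chromosome, a.gene.start) == (b.gene.chromosome, b.gene.start):
                logger.warning("tie at %s:%d broken by protein id (%s, %s)",
                               a.gene.chromosome, a.gene.start,
                               a.protein_id, b.protein_id)
    return out


def characterize_members(members: Sequence[FamilyMember],
                         sequences: Mapping[str, str],
                         scheme: SubfamilyScheme | None = None,
                         ) -> list[FamilyMember]:
    """Attach physicochemical stats; flag MW outside the subfamily window."""
    scheme = scheme or default_scheme()
    window = {r.label: r.mw_window_kda for r in scheme.rules}
    for m in members:
        m.stats = characterize(sequences[m.protein_id])
        lo, hi = window[m.subfamily]
        m.mw_flag = not (lo <= m.stats.mw_kda <= hi)
        if m.mw_flag:
            logger.warning("%s (%s): MW %.1f kDa outside %s window [%s, %s]",
                           m.assigned_name or m.protein_id, m.subfamily,
                           m.stats.mw_kda, m.subfamily, lo, hi)
    return list(members)


def chromosome_distribution(members: Iterable[FamilyMember]) -> dict[str, int]:
    """Count members per chromosome (requires located genes)."""
    counts = Counter(m.gene.chromosome for m in members)
    return dict(sorted(counts.items(), key=lambda kv: natural_key(kv[0])))


def subfamily_tally(members: Iterable[FamilyMember]) -> dict[str, int]:
    return dict(Counter(m.subfamily for m in members))


def flag_homology_candidates(accepted: Mapping[str, str],
                             candidates: Mapping[str, str],
                             identity_min: float = 0.5,
                             coverage_min: float = 0.7) -> list[str]:
    """Flag proteins lacking a domain hit that still align well to a member.

    A candidate aligning to any accepted member at >= 50% identity over
    >= 70% coverage is returned for manual review; it is never
    auto-accepted into the family.
    """
    from .pairwise_dup import global_align

    flagged = []
    for cid in sorted(candidates):
        for aid in sorted(accepted):
            aln = global_align(candidates[cid], accepted[aid])
            if aln.identity >= identity_min and aln.coverage >= coverage_min:
                flagged.append(cid)
                break
    return flagged
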