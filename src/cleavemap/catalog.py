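"""Site-level bookkeeping across substrates and enzymes.

A cleavage site's identity is its P1 position on a given protein isoform;
two enzymes share a site when they cut the same bond of the same isoform.
Cross-isoform identity is never inferred from sequence — it requires an
explicit position map, because isoforms are numbered independently and
silent renumbering is the main error mode in this kind of catalogue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .caller import CleavageCall
from .model import CleavemapError, DomainAnnotation, ProteinRecord


@dataclass
class SiteCatalog:
    """Deduplicated cleavage calls keyed by (protein_id, p1_pos, enzyme)."""

    entries: dict[tuple[str, int, str], CleavageCall] = field(
        default_factory=dict
    )
    known_sites: list[tuple[str, int, str]] = field(default_factory=list)

    def positions(self, protein_id: str | None = None) -> set[int]:
        return {
            p1
            for (pid, p1, _enz) in self.entries
            if protein_id is None or pid == protein_id
        }

    def enzymes(self) -> set[str]:
        return {enz for (_pid, _p1, enz) in self.entries}

    def calls(self) -> list[CleavageCall]:
        return [self.entries[k] for k in sorted(self.entries)]

    def __len__(self) -> int:
        return len(self.entries)


def deduplicate(calls: list[CleavageCall]) -> SiteCatalog:
    """Merge calls into one catalog entry per (protein, P1, enzyme).

    Multiple peptides supporting the same bond pool their evidence;
    the entry keeps the best (max) z tier ordering: an ``outlier_high`` or
    ``typical`` tier wins over ``outlier_low`` when merging.
    """
    catalog = SiteCatalog()
    tier_rank = {"outlier_low": 0, "typical": 1, "outlier_high": 2}
    for call in calls:
        key = (call.protein_id, call.p1_pos, call.enzyme)
        existing = catalog.entries.get(key)
        if existing is None:
            merged = CleavageCall(
                protein_id=call.protein_id,
                p1_pos=call.p1_pos,
                p1prime_pos=call.p1prime_pos,
                enzyme=call.enzyme,
                p1_aa=call.p1_aa,
                p1prime_aa=call.p1prime_aa,
                semi_evidence=list(call.semi_evidence),
                spanning_evidence=list(call.spanning_evidence),
                domain=call.domain,
                tier=call.tier,
            )
            catalog.entries[key] = merged
        else:
            seen = {obs.key() for obs, _, _ in existing.semi_evidence}
            for item in call.semi_evidence:
                if item[0].key() not in seen:
                    existing.semi_evidence.append(item)
            seen_span = {obs.key() for obs, _ in existing.spanning_evidence}
            for item in call.spanning_evidence:
                if item[0].key() not in seen_span:
                    existing.spanning_evidence.append(item)
            if tier_rank.get(call.tier, 1) > tier_rank.get(existing.tier, 1):
                existing.tier = call.tier
    return catalog


def annotate_domains(
    catalog: SiteCatalog,
    domains: dict[str, list[DomainAnnotation]],
    proteins: dict[str, ProteinRecord] | None = None,
) -> SiteCatalog:
    """Label each entry with the first domain interval containing its P1.

    Positions in no interval are labelled ``interdomain``. If ``proteins``
    is given, P1/P1' residue letters are checked against the sequence.
    """
    for (pid, p1, _enz), call in catalog.entries.items():
        call.domain = "interdomain"
        for dom in domains.get(pid, []):
            if p1 in dom:
                call.domain = dom.name
                break
        if proteins and pid in proteins:
            protein = proteins[pid]
            if call.p1_aa and protein.residue(p1) != call.p1_aa:
                raise CleavemapError(
                    f"{pid} P1 {p1}: catalog says {call.p1_aa}, "
                    f"sequence has {protein.residue(p1)}"
                )
            if (
                call.p1prime_aa
                and call.p1prime_pos <= len(protein)
                and protein.residue(call.p1prime_pos) != call.p1prime_aa
            ):
                raise CleavemapError(
                    f"{pid} P1' {call.p1prime_pos}: catalog says "
                    f"{call.p1prime_aa}, sequence has "
                    f"{protein.residue(call.p1prime_pos)}"
                )
    return catalog


@dataclass
class SharingReport:
    """Cross-enzyme sharing of cleavage positions on one substrate."""

    protein_id: str
    by_position: dict[int, set[str]]

    @property
    def union_size(self) -> int:
        return len(self.by_position)

    @property
    def shared_positions(self) -> dict[int, set[str]]:
        return {
            pos: enzymes
            for pos, enzymes in self.by_position.items()
            if len(enzymes) > 1
        }

    @property
    def exclusive_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for enzymes in self.by_position.values():
            if len(enzymes) == 1:
                (enz,) = enzymes
                counts[enz] = counts.get(enz, 0) + 1
        return counts

    def shared_between(self, enzyme_a: str, enzyme_b: str) -> set[int]:
        return {
            pos
            for pos, enzymes in self.by_position.items()
            if enzyme_a in enzymes and enzyme_b in enzymes
        }


def compare_enzymes(catalogs: list[SiteCatalog]) -> SharingReport:
    """Sharing report over catalogs of the same substrate protein."""
    protein_ids = {
        pid for cat in catalogs for (pid, _p1, _enz) in cat.entries
    }
    if len(protein_ids) > 1:
        raise CleavemapError(
            f"catalogs mix substrates {sorted(protein_ids)}; "
            "map isoform positions first"
        )
    protein_id = protein_ids.pop() if protein_ids else ""
    by_position: dict[int, set[str]] = {}
    for cat in catalogs:
        for (_pid, p1, enz) in cat.entries:
            by_position.setdefault(p1, set()).add(enz)
    return SharingReport(protein_id, by_position)


def union_novel(
    catalogs: list[SiteCatalog],
    known_sites: list[tuple[str, int]] | None = None,
) -> dict[str, int]:
    """Union of unique P1 positions across enzymes, and how many are new.

    ``known_sites`` are (protein_id, p1_pos) pairs on the same numbering.
    """
    union: set[tuple[str, int]] = set()
    for cat in catalogs:
        for (pid, p1, _enz) in cat.entries:
            union.add((pid, p1))
    known = set(known_sites or [])
    return {
        "union": len(union),
        "known": len(union & known),
        "novel": len(union - known),
    }


def map_isoform_position(
    protein_a: str,
    pos_a: int,
    protein_b: str,
    alignment: list[tuple[str, int, int, str, int]],
) -> int:
    """Map a residue position between isoforms via an explicit block map.

    ``alignment`` rows are (protein_a, a_start, a_end, protein_b, b_start)
    linear blocks; the identity map applies when both proteins are equal.
    """
    if protein_a == protein_b:
        return pos_a
    for (pa, a_start, a_end, pb, b_start) in alignment:
        if pa == protein_a and pb == protein_b and a_start <= pos_a <= a_end:
            return b_start + (pos_a - a_start)
        # Blocks are invertible; accept the reverse orientation too.
        if pa == protein_b and pb == protein_a:
            b_end = b_start + (a_end - a_start)
            if b_start <= pos_a <= b_end:
                return a_start + (pos_a - b_start)
    raise CleavemapError(
        f"position {pos_a} of {protein_a} is not covered by the "
        f"{protein_a}/{protein_b} correspondence map"
    )
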