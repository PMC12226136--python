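"""End-to-end drivers combining classification, calling and cataloguing.

Two entry points cover the two ways evidence arrives:

* :func:`run_pipeline` — full statistics on a raw E/EQ peptide table:
  per-working-protease z-scoring, fence stratification, site calling,
  spanning-peptide corroboration, then site-level merging across the
  trypsin and GluC experiments.

* :func:`sites_from_significant` — site inference on peptides already
  established as significant (e.g. the packaged worked-example tables,
  which list only the significant rows): classify, infer, deduplicate.
"""

from __future__ import annotations

import math

from .caller import (
    CleavageCall,
    OrphanSignal,
    RatioRecord,
    abundance_fence,
    call_sites,
    compute_ratios,
    corroborate,
)
from .catalog import SiteCatalog, annotate_domains, deduplicate
from .digest import classify_peptide, rule_for
from .model import DomainAnnotation, PeptideObservation, ProteinRecord


def run_pipeline(
    observations: list[PeptideObservation],
    enzyme: str = "",
    z_threshold: float = 2.0,
    fence_k: float = 1.5,
    domains: dict[str, list[DomainAnnotation]] | None = None,
    proteins: dict[str, ProteinRecord] | None = None,
    abundance_reference: str = "enriched",
) -> tuple[SiteCatalog, list[OrphanSignal], list[RatioRecord]]:
    """Run the two-step analysis on one substrate's E/EQ peptide table.

    Trypsin and GluC preparations are z-scored as separate experiments and
    their calls merged at the site level. Returns the deduplicated catalog,
    orphan EQ-enriched spanners, and all ratio records (for plotting or
    export).
    """
    calls: list[CleavageCall] = []
    orphans: list[OrphanSignal] = []
    all_records: list[RatioRecord] = []
    proteases = sorted({o.working_protease for o in observations})
    for protease in proteases:
        group = [o for o in observations if o.working_protease == protease]
        rule = rule_for(protease)
        records = compute_ratios(group, abundance_reference)
        all_records.extend(records)
        specs = [classify_peptide(o, rule) for o in group]
        fence = abundance_fence(records, fence_k)
        group_calls = call_sites(
            records, specs, z_threshold, fence, enzyme=enzyme
        )
        fully = [
            rec
            for rec, spec in zip(records, specs)
            if spec.peptide_class == "fully"
        ]
        group_calls, group_orphans = corroborate(
            group_calls, fully, z_threshold
        )
        calls.extend(group_calls)
        orphans.extend(group_orphans)
    catalog = deduplicate(calls)
    if domains is not None:
        annotate_domains(catalog, domains, proteins)
    return catalog, orphans, all_records


def sites_from_significant(
    observations: list[PeptideObservation],
    enzyme: str = "",
    domains: dict[str, list[DomainAnnotation]] | None = None,
    proteins: dict[str, ProteinRecord] | None = None,
) -> SiteCatalog:
    """Infer and deduplicate sites from pre-selected significant peptides.

    Fully-specific rows contribute no sites (they are corroboration, not
    nomination); semi-specific positionally internal rows nominate the bond
    at their nonconforming terminus. No z-scoring happens here — the input
    is already the significant subset.
    """
    calls: list[CleavageCall] = []
    for obs in observations:
        spec = classify_peptide(obs, rule_for(obs.working_protease))
        if spec.peptide_class not in ("semi_n", "semi_c"):
            continue
        if not spec.positionally_internal:
            continue
        p1, p1p = spec.inferred_site
        p1_aa = obs.prev_aa if spec.peptide_class == "semi_n" else obs.sequence[-1]
        p1p_aa = obs.sequence[0] if spec.peptide_class == "semi_n" else obs.next_aa
        calls.append(
            CleavageCall(
                protein_id=obs.protein_id,
                p1_pos=p1,
                p1prime_pos=p1p,
                enzyme=enzyme,
                p1_aa=p1_aa,
                p1prime_aa=p1p_aa,
                semi_evidence=[(obs, float("nan"), obs.working_protease)],
            )
        )
    catalog = deduplicate(calls)
    if domains is not None:
        annotate_domains(catalog, domains, proteins)
    return catalog


def attach_spanning(
    catalog: SiteCatalog, eq_enriched: list[PeptideObservation]
) -> SiteCatalog:
    """Attach pre-selected EQ-enriched fully-specific spanners to a catalog.

    Counterpart of :func:`sites_from_significant` for corroboration rows:
    interval containment only, no z filtering.
    """
    for obs in eq_enriched:
        for (pid, p1, _enz), call in catalog.entries.items():
            if pid != obs.protein_id:
                continue
            if obs.start <= p1 and call.p1prime_pos <= obs.end:
                call.spanning_evidence.append((obs, float("nan")))
    return catalog


def site_table_rows(catalog: SiteCatalog) -> list[dict]:
    """Rows for the tab-separated site-table output schema."""
    rows = []
    for call in catalog.calls():
        zs = [z for _, z, _ in call.semi_evidence if not math.isnan(z)]
        rows.append(
            {
                "protein_id": call.protein_id,
                "enzyme": call.enzyme,
                "p1_pos": call.p1_pos,
                "p1_aa": call.p1_aa,
                "p1p_pos": call.p1prime_pos,
                "p1p_aa": call.p1prime_aa,
                "domain": call.domain,
                "n_semi_peptides": len(call.semi_evidence),
                "n_spanning_peptides": len(call.spanning_evidence),
                "max_z": f"{max(zs):.2f}" if zs else "",
                "tier": call.tier,
            }
        )
    return rows
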