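"""Two-step statistical identification of cleavage sites.

Step one: peptides quantified in both the active (E) and inactive (EQ)
digests are z-scored on their log2(E/EQ) abundance ratio against the whole
co-quantified population of the experiment; a semi-specific, positionally
internal peptide with z at or above the threshold nominates the cleavage
site implied by its nonconforming terminus. Step two: candidate sites are
stratified (not filtered) by peptide abundance using Tukey fences on the
log2 abundances of the same population, and corroborated by fully-specific
peptides that span the site and are significantly *depleted* in the active
digest (EQ-enriched), as expected when the protease under study cuts inside
them.

Peptides quantified in only one group are excluded from the z population
and reported in a side channel: the ratio population is defined over
peptides found in both groups, and one-group peptides carry no ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .digest import SpecificityCall
from .model import CleavemapError, PeptideObservation


class DegenerateRatios(CleavemapError):
    """The log-ratio population has zero spread; z-scores are undefined."""


@dataclass
class RatioRecord:
    """Per-peptide quantification summary within one experiment.

    ``log2_abundance`` is the reference intensity used for abundance
    stratification (by default the enriched group's intensity, i.e. the
    group the peptide is evidence in); ``z`` is defined only for peptides
    quantified in both groups.
    """

    observation: PeptideObservation
    log2_abundance: float
    log2_ratio: float | None
    z: float | None
    exclusive_group: str | None = None  # "E_only" | "EQ_only" | None


@dataclass(frozen=True)
class FenceResult:
    """Tukey fences on the log2-abundance distribution."""

    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    k: float

    def tier(self, log2_abundance: float) -> str:
        if log2_abundance < self.lower_fence:
            return "outlier_low"
        if log2_abundance > self.upper_fence:
            return "outlier_high"
        return "typical"


@dataclass
class CleavageCall:
    """A called cleavage site with its pooled peptide evidence."""

    protein_id: str
    p1_pos: int
    p1prime_pos: int
    enzyme: str
    p1_aa: str = ""
    p1prime_aa: str = ""
    semi_evidence: list[tuple[PeptideObservation, float, str]] = field(
        default_factory=list
    )
    spanning_evidence: list[tuple[PeptideObservation, float]] = field(
        default_factory=list
    )
    domain: str = ""
    tier: str = "typical"
    direction: str = "E_enriched"

    @property
    def max_z(self) -> float:
        zs = [z for _, z, _ in self.semi_evidence]
        return max(zs) if zs else float("nan")

    @property
    def max_semi_log2_abundance(self) -> float | None:
        values = [
            math.log2(obs.abundance_E)
            for obs, _, _ in self.semi_evidence
            if obs.abundance_E
        ]
        return max(values) if values else None


@dataclass
class OrphanSignal:
    """An EQ-enriched fully-specific peptide spanning no called site.

    Suggests a cleavage inside its interval that produced no detectable
    semi-specific peptide (e.g. products outside the length window).
    """

    observation: PeptideObservation
    z: float
    interval: tuple[int, int]


def compute_ratios(
    observations: list[PeptideObservation],
    abundance_reference: str = "enriched",
) -> list[RatioRecord]:
    """z-score log2(E/EQ) ratios over the co-quantified population.

    ``abundance_reference`` selects the intensity used as the record's
    log2_abundance: ``"enriched"`` (the larger group's intensity — the
    evidentiary one) or ``"mean_of_both"``.
    """
    if abundance_reference not in ("enriched", "mean_of_both"):
        raise CleavemapError(
            f"unknown abundance reference {abundance_reference!r}"
        )
    both = [
        o for o in observations if o.abundance_E and o.abundance_EQ
    ]
    if len(both) < 3:
        raise CleavemapError(
            f"need at least 3 peptides quantified in both groups, "
            f"got {len(both)}"
        )
    ratios = np.array(
        [math.log2(o.abundance_E / o.abundance_EQ) for o in both]
    )
    sd = float(ratios.std(ddof=1))
    if sd == 0.0:
        raise DegenerateRatios(
            "all co-quantified peptides have identical E/EQ ratios"
        )
    mean = float(ratios.mean())

    def _log2_abundance(obs: PeptideObservation) -> float:
        e = obs.abundance_E or 0.0
        eq = obs.abundance_EQ or 0.0
        if abundance_reference == "mean_of_both" and e and eq:
            return math.log2((e + eq) / 2.0)
        return math.log2(max(e, eq))

    records = []
    for obs in observations:
        if obs.abundance_E and obs.abundance_EQ:
            ratio = math.log2(obs.abundance_E / obs.abundance_EQ)
            records.append(
                RatioRecord(
                    observation=obs,
                    log2_abundance=_log2_abundance(obs),
                    log2_ratio=ratio,
                    z=(ratio - mean) / sd,
                )
            )
        else:
            records.append(
                RatioRecord(
                    observation=obs,
                    log2_abundance=_log2_abundance(obs),
                    log2_ratio=None,
                    z=None,
                    exclusive_group="E_only" if obs.abundance_E else "EQ_only",
                )
            )
    return records


def abundance_fence(records: list[RatioRecord], k: float = 1.5) -> FenceResult:
    """Tukey fences (both sides) on log2 abundances of the population.

    Quartiles use linear interpolation of order statistics (the numpy
    default), so q1 of {10,12,14,16,18} is 12.
    """
    values = np.array([r.log2_abundance for r in records], dtype=float)
    if values.size < 4:
        raise CleavemapError(
            f"need at least 4 records to place fences, got {values.size}"
        )
    q1, q3 = np.percentile(values, [25.0, 75.0])
    iqr = q3 - q1
    return FenceResult(
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_fence=float(q1 - k * iqr),
        upper_fence=float(q3 + k * iqr),
        k=k,
    )


def call_sites(
    records: list[RatioRecord],
    specificity_calls: dict | list[SpecificityCall],
    z_threshold: float = 2.0,
    fence: FenceResult | None = None,
    enzyme: str = "",
) -> list[CleavageCall]:
    """Nominate and merge cleavage sites from significant semi peptides.

    ``specificity_calls`` is aligned with ``records`` (list) or keyed by
    ``PeptideObservation.key()`` (dict). Calls sharing (protein_id, P1) are
    merged with pooled evidence; below-fence calls are retained and tiered
    ``outlier_low``, not dropped.
    """
    aligned = _align(records, specificity_calls)
    by_site: dict[tuple[str, int], CleavageCall] = {}
    for record, spec in aligned:
        if spec.peptide_class not in ("semi_n", "semi_c"):
            continue
        if not spec.positionally_internal:
            continue
        if record.z is None or record.z < z_threshold:
            continue
        obs = record.observation
        p1, p1p = spec.inferred_site
        key = (obs.protein_id, p1)
        call = by_site.get(key)
        if call is None:
            p1_aa = obs.prev_aa if spec.peptide_class == "semi_n" else obs.sequence[-1]
            p1p_aa = obs.sequence[0] if spec.peptide_class == "semi_n" else obs.next_aa
            call = CleavageCall(
                protein_id=obs.protein_id,
                p1_pos=p1,
                p1prime_pos=p1p,
                enzyme=enzyme,
                p1_aa=p1_aa,
                p1prime_aa=p1p_aa,
            )
            by_site[key] = call
        call.semi_evidence.append((obs, record.z, obs.working_protease))
    calls = [by_site[k] for k in sorted(by_site)]
    if fence is not None:
        for call in calls:
            top = call.max_semi_log2_abundance
            if top is not None:
                call.tier = fence.tier(top)
    return calls


def corroborate(
    calls: list[CleavageCall],
    fully_records: list[RatioRecord],
    z_threshold: float = 2.0,
) -> tuple[list[CleavageCall], list[OrphanSignal]]:
    """Attach EQ-enriched fully-specific spanning peptides to calls.

    A fully-specific peptide with z <= -z_threshold whose interval strictly
    contains a call's scissile bond (start <= P1 and P1' <= end) becomes
    spanning evidence; EQ-enriched spanners covering no call are returned
    as orphan signals.
    """
    orphans = []
    for record in fully_records:
        if record.z is None or record.z > -z_threshold:
            continue
        obs = record.observation
        hit = False
        for call in calls:
            if call.protein_id != obs.protein_id:
                continue
            if obs.start <= call.p1_pos and call.p1prime_pos <= obs.end:
                call.spanning_evidence.append((obs, record.z))
                hit = True
        if not hit:
            orphans.append(
                OrphanSignal(obs, record.z, (obs.start, obs.end))
            )
    return calls, orphans


def _align(records, specificity_calls):
    if isinstance(specificity_calls, dict):
        pairs = []
        for record in records:
            key = record.observation.key()
            try:
                pairs.append((record, specificity_calls[key]))
            except KeyError:
                raise CleavemapError(
                    f"no specificity call for observation {key}"
                ) from None
        return pairs
    if len(records) != len(specificity_calls):
        raise CleavemapError(
            "records and specificity calls are not aligned"
        )
    return list(zip(records, specificity_calls))
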