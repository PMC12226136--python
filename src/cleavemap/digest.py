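"""In-silico digestion and peptide terminal-specificity classification.

The working protease (trypsin or GluC) defines which peptide termini are
"expected": a terminus is *specific* when the preceding residue belongs to
the protease's P1 set and the following residue is not blocked (trypsin is
conventionally blocked by proline in P1'). A peptide with exactly one
nonconforming terminus is *semi-specific*, and that terminus marks a
candidate cleavage by the protease under study: its P1/P1' positions are
read directly off the peptide coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .model import (
    TERMINUS,
    CleavemapError,
    PeptideObservation,
    ProteinRecord,
)


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage rule of a working protease.

    ``p1_residues`` are the residues after which the protease cuts;
    ``blocked_p1prime`` suppresses cleavage when the next residue is in the
    set (classically proline for trypsin).
    """

    name: str
    p1_residues: frozenset[str]
    blocked_p1prime: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.p1_residues:
            raise CleavemapError("protease rule needs at least one P1 residue")

    def cuts_after(self, p1: str, p1prime: str) -> bool:
        """Would the protease cleave the bond ``p1``-``p1prime``?"""
        return p1 in self.p1_residues and p1prime not in self.blocked_p1prime


#: Trypsin: cleaves after K/R, blocked by proline in P1'.
TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))
#: GluC (ammonium bicarbonate conditions): cleaves after E and D.
GLUC = ProteaseRule("gluc", frozenset("DE"))

RULES = {"trypsin": TRYPSIN, "gluc": GLUC}


def rule_for(name: str) -> ProteaseRule:
    try:
        return RULES[name]
    except KeyError:
        raise CleavemapError(f"no protease rule named {name!r}") from None


@dataclass(frozen=True)
class SpecificityCall:
    """Terminal-specificity classification of one peptide observation.

    ``inferred_site`` is the (P1, P1') residue-position pair implied by the
    single nonspecific terminus of a semi-specific peptide; fully specific
    and doubly nonspecific peptides imply no site.
    """

    n_term_status: str  # specific | nonspecific | protein_terminus
    c_term_status: str
    peptide_class: str  # fully | semi_n | semi_c | nonspecific
    positionally_internal: bool
    inferred_site: tuple[int, int] | None


def classify_peptide(
    obs: PeptideObservation,
    rule: ProteaseRule,
    mature_start: int | None = None,
) -> SpecificityCall:
    """Classify a peptide's termini against the working-protease rule.

    A terminus at the protein N-/C-terminus (flank ``-``) is treated as
    specific and yields no site. If ``mature_start`` is given, a peptide
    beginning exactly there (e.g. the mature chain after signal-peptide
    removal) is likewise treated as specific on its N-terminal side.
    """
    if obs.working_protease != rule.name:
        raise CleavemapError(
            f"observation prepared with {obs.working_protease!r}, "
            f"rule is {rule.name!r}"
        )

    if obs.prev_aa == TERMINUS:
        n_status = "protein_terminus"
    elif rule.cuts_after(obs.prev_aa, obs.sequence[0]):
        n_status = "specific"
    elif mature_start is not None and obs.start == mature_start:
        n_status = "protein_terminus"
    else:
        n_status = "nonspecific"

    if obs.next_aa == TERMINUS:
        c_status = "protein_terminus"
    elif rule.cuts_after(obs.sequence[-1], obs.next_aa):
        c_status = "specific"
    else:
        c_status = "nonspecific"

    n_ok = n_status in ("specific", "protein_terminus")
    c_ok = c_status in ("specific", "protein_terminus")
    if n_ok and c_ok:
        cls = "fully"
        site = None
    elif not n_ok and c_ok:
        cls = "semi_n"
        site = (obs.start - 1, obs.start)
    elif n_ok and not c_ok:
        cls = "semi_c"
        site = (obs.end, obs.end + 1)
    else:
        cls = "nonspecific"
        site = None

    # A semi peptide's cut is positionally internal unless it abuts a
    # protein terminus. Termini themselves already classify as
    # protein_terminus, so the only remaining boundary case is a cut at the
    # very first peptide bond (P1 = residue 1), which is treated as ragged
    # rather than internal.
    internal = False
    if cls == "semi_n":
        internal = site[0] >= 2
    elif cls == "semi_c":
        internal = obs.next_aa != TERMINUS

    return SpecificityCall(n_status, c_status, cls, internal, site)


def theoretical_sites(
    protein: ProteinRecord,
    rule: ProteaseRule,
    region: tuple[int, int] | None = None,
) -> list[int]:
    """P1 positions at which ``rule`` would cleave ``protein``.

    A position ``i`` qualifies when residue ``i`` is in the P1 set, residue
    ``i+1`` is not blocked, and ``i`` is not the last residue. ``region``
    restricts the scan to a 1-based inclusive interval.
    """
    start, end = _checked_region(protein, region)
    seq = protein.sequence
    return [
        i
        for i in range(start, min(end, len(seq) - 1) + 1)
        if rule.cuts_after(seq[i - 1], seq[i])
    ]


def digest_protein(
    protein: ProteinRecord,
    rule: ProteaseRule,
    max_missed: int = 0,
    length_range: tuple[int, float] = (1, float("inf")),
) -> list[PeptideObservation]:
    """Fully specific peptides of an in-silico digest.

    Emits every peptide bounded by cleavage sites (or protein termini) with
    at most ``max_missed`` internal sites and length within
    ``length_range``. Abundances are left unset (schema skeletons): callers
    fill them in. The zero-missed-cleavage set tiles the protein exactly.
    """
    if max_missed < 0:
        raise CleavemapError("max_missed must be >= 0")
    lo, hi = length_range
    if lo > hi:
        raise CleavemapError(f"bad length range {length_range}")
    sites = theoretical_sites(protein, rule)
    # Peptide boundaries: starts follow a site (or position 1), ends are at
    # a site (or the protein C-terminus).
    bounds = [0] + sites + [len(protein)]
    out: list[PeptideObservation] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 1 + max_missed + 1, len(bounds))):
            start, end = bounds[i] + 1, bounds[j]
            if not lo <= end - start + 1 <= hi:
                continue
            out.append(_skeleton(protein, start, end, rule.name))
    return out


def _skeleton(
    protein: ProteinRecord, start: int, end: int, protease: str
) -> PeptideObservation:
    obs = PeptideObservation.__new__(PeptideObservation)
    obs.protein_id = protein.id
    obs.sequence = protein.subsequence(start, end)
    obs.start = start
    obs.end = end
    obs.prev_aa = TERMINUS if start == 1 else protein.residue(start - 1)
    obs.next_aa = TERMINUS if end == len(protein) else protein.residue(end + 1)
    obs.working_protease = protease
    obs.modifications = []
    # Digest skeletons have no quantification yet; bypass the at-least-one-
    # abundance rule that applies to observed peptides.
    obs.abundance_E = None
    obs.abundance_EQ = None
    return obs


def coverage(
    peptides: list[PeptideObservation], protein: ProteinRecord
) -> float:
    """Fraction of protein residues covered by at least one peptide."""
    covered: set[int] = set()
    for pep in peptides:
        if pep.protein_id != protein.id or pep.end > len(protein):
            raise CleavemapError(
                f"peptide {pep.sequence!r} does not map to {protein.id}"
            )
        covered.update(range(pep.start, pep.end + 1))
    return len(covered) / len(protein)


@dataclass(frozen=True)
class DensityReport:
    """Cleavage-site density statistics over a protein region.

    Gaps are distances between consecutive theoretical P1 positions inside
    the region; a region without sites reports its full length as both the
    mean and maximum gap.
    """

    region: tuple[int, int]
    n_sites: int
    mean_gap: float
    max_gap: int
    residue_counts: dict[str, int] = field(default_factory=dict)


def site_density(
    protein: ProteinRecord,
    rule: ProteaseRule,
    region: tuple[int, int] | None = None,
    count_residues: str | None = None,
) -> DensityReport:
    """Density of theoretical cleavage sites within ``region``.

    ``count_residues`` additionally tallies the named residues in the
    region (defaults to the rule's P1 residues).
    """
    start, end = _checked_region(protein, region)
    sites = theoretical_sites(protein, rule, (start, end))
    length = end - start + 1
    if len(sites) >= 2:
        gaps = [b - a for a, b in zip(sites, sites[1:])]
        mean_gap: float = sum(gaps) / len(gaps)
        max_gap = max(gaps)
    else:
        mean_gap = float(length)
        max_gap = length
    residues = count_residues or "".join(sorted(rule.p1_residues))
    segment = protein.subsequence(start, end)
    counts = {aa: segment.count(aa) for aa in residues}
    return DensityReport((start, end), len(sites), mean_gap, max_gap, counts)


def reverse_observation(obs: PeptideObservation) -> PeptideObservation:
    """Mirror an observation: reversed sequence, swapped flank roles.

    Used by symmetry checks — classification maps semi_n <-> semi_c under
    this transform (the protease rules are not themselves symmetric, so the
    check also reverses the rule; see tests).
    """
    return replace(
        obs,
        sequence=obs.sequence[::-1],
        prev_aa=obs.next_aa,
        next_aa=obs.prev_aa,
    )


def _checked_region(
    protein: ProteinRecord, region: tuple[int, int] | None
) -> tuple[int, int]:
    if region is None:
        return 1, len(protein)
    start, end = region
    if start > end:
        raise CleavemapError(f"empty region {region}")
    if not (1 <= start and end <= len(protein)):
        raise CleavemapError(
            f"region {region} outside protein 1..{len(protein)}"
        )
    return start, end
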