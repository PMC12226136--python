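"""Core domain objects shared across the pipeline.

Coordinates are 1-based and inclusive throughout, matching the residue
numbering used in the source tables (a cleavage site written ``E441-A442``
means the scissile bond lies between residues 441 and 442 of the named
protein). Conversion to 0-based slicing happens only inside methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: ``X`` is tolerated as an unknown residue in protein sequences.
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}
#: Marker used in ``prev_aa``/``next_aa`` for the protein N-/C-terminus.
TERMINUS = "-"
#: Post-translational modification labels carried on observations.
MOD_LABELS = frozenset({"acetyl", "oxidation", "pyroglu"})
#: The two working (sample-preparation) proteases supported out of the box.
WORKING_PROTEASES = ("trypsin", "gluc")


class CleavemapError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CleavemapError):
    """A file or record failed validation while being read."""


@dataclass(frozen=True)
class DomainAnnotation:
    """A named interval on a protein, 1-based inclusive.

    Intervals may nest or overlap; position lookups resolve to the first
    matching annotation in file order.
    """

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ParseError("domain annotation needs a non-empty name")
        if not (1 <= self.start <= self.end):
            raise ParseError(
                f"domain {self.name!r}: invalid interval {self.start}-{self.end}"
            )

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class ProteinRecord:
    """A protein sequence with optional domain annotations.

    ``sequence`` is uppercase and restricted to the 20 standard residues
    plus ``X``; positions are 1-based inclusive so ``residue(1)`` is the
    first residue.
    """

    id: str
    sequence: str
    description: str = ""
    domains: list[DomainAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ParseError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ParseError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)}"
            )
        for dom in self.domains:
            if dom.end > len(self.sequence):
                raise ParseError(
                    f"protein {self.id!r}: domain {dom.name!r} extends past "
                    f"sequence end ({dom.end} > {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(f"position {pos} outside 1..{len(self.sequence)}")
        return self.sequence[pos - 1]

    def subsequence(self, start: int, end: int) -> str:
        """Substring covering 1-based inclusive ``[start, end]``."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise IndexError(
                f"interval {start}-{end} outside 1..{len(self.sequence)}"
            )
        return self.sequence[start - 1 : end]

    def domain_of(self, pos: int) -> str | None:
        """Name of the first domain annotation containing ``pos``, if any."""
        for dom in self.domains:
            if pos in dom:
                return dom.name
        return None


@dataclass
class PeptideObservation:
    """One quantified peptide from an E/EQ digest pair.

    ``abundance_E``/``abundance_EQ`` are raw (linear-scale) intensities from
    the active- and inactive-protease digests; ``None`` means the peptide was
    not quantified in that group (distinct from zero). Distinct modification
    states of the same sequence are distinct observations.
    """

    protein_id: str
    sequence: str
    start: int
    end: int
    prev_aa: str
    next_aa: str
    working_protease: str
    modifications: list[tuple[int, str]] = field(default_factory=list)
    abundance_E: float | None = None
    abundance_EQ: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self, protein: ProteinRecord | None = None) -> None:
        """Check internal consistency, and against ``protein`` if given."""
        if not self.sequence or set(self.sequence) - PROTEIN_ALPHABET:
            raise ParseError(f"invalid peptide sequence {self.sequence!r}")
        if self.working_protease not in WORKING_PROTEASES:
            raise ParseError(
                f"unknown working protease {self.working_protease!r}"
            )
        if self.end - self.start + 1 != len(self.sequence):
            raise ParseError(
                f"peptide {self.sequence!r}: positions {self.start}-{self.end} "
                f"do not match length {len(self.sequence)}"
            )
        if self.start < 1:
            raise ParseError(f"peptide {self.sequence!r}: start < 1")
        for flank, name in ((self.prev_aa, "prev_aa"), (self.next_aa, "next_aa")):
            if flank != TERMINUS and flank not in PROTEIN_ALPHABET:
                raise ParseError(f"{name} must be a residue or {TERMINUS!r}")
        if (self.prev_aa == TERMINUS) != (self.start == 1):
            raise ParseError(
                f"peptide {self.sequence!r}: prev_aa {self.prev_aa!r} "
                f"inconsistent with start {self.start}"
            )
        for pos, label in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ParseError(
                    f"modification position {pos} outside peptide of length "
                    f"{len(self.sequence)}"
                )
            if label not in MOD_LABELS:
                raise ParseError(f"unknown modification label {label!r}")
        for value, name in (
            (self.abundance_E, "abundance_E"),
            (self.abundance_EQ, "abundance_EQ"),
        ):
            if value is not None and value < 0:
                raise ParseError(f"{name} must be nonnegative, got {value}")
        if self.abundance_E is None and self.abundance_EQ is None:
            raise ParseError(
                f"peptide {self.sequence!r}: at least one abundance required"
            )
        if protein is not None:
            if self.end > len(protein):
                raise ParseError(
                    f"peptide {self.sequence!r}: end {self.end} past protein "
                    f"length {len(protein)}"
                )
            observed = protein.subsequence(self.start, self.end)
            if observed != self.sequence:
                raise ParseError(
                    f"peptide {self.sequence!r} does not match "
                    f"{self.protein_id} residues {self.start}-{self.end} "
                    f"({observed!r})"
                )
            want_prev = (
                TERMINUS if self.start == 1 else protein.residue(self.start - 1)
            )
            want_next = (
                TERMINUS
                if self.end == len(protein)
                else protein.residue(self.end + 1)
            )
            if self.prev_aa != want_prev or self.next_aa != want_next:
                raise ParseError(
                    f"peptide {self.sequence!r}: flanks "
                    f"({self.prev_aa!r}, {self.next_aa!r}) disagree with "
                    f"sequence context ({want_prev!r}, {want_next!r})"
                )
            if (self.next_aa == TERMINUS) != (self.end == len(protein)):
                raise ParseError(
                    f"peptide {self.sequence!r}: next_aa inconsistent with end"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def key(self) -> tuple:
        """Identity of the observation (modification states are distinct)."""
        return (
            self.protein_id,
            self.sequence,
            self.start,
            self.end,
            self.working_protease,
            tuple(sorted(self.modifications)),
        )
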