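"""Subsite-specificity scoring around cleavage sites (iceLogo style).

Residues at the ten positions P5…P1 (unprimed, N-terminal of the scissile
bond) and P1'…P5' (primed, C-terminal) are tallied across a set of cleavage
sites and compared, position by position, against a reference proteome
composition using percentage differences. Significance per cell is a
two-sided normal test of the observed proportion against the reference
proportion with standard error sqrt(p(1-p)/n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from scipy.stats import norm

from .model import AMINO_ACIDS, CleavemapError, ProteinRecord

PAD = "-"


def position_labels(span: int = 5) -> list[str]:
    """["P5", …, "P1", "P1'", …, "P5'"] for the given half-window."""
    unprimed = [f"P{i}" for i in range(span, 0, -1)]
    primed = [f"P{i}'" for i in range(1, span + 1)]
    return unprimed + primed


@dataclass(frozen=True)
class SiteWindow:
    """Residues surrounding one scissile bond, padded at protein termini.

    ``residues`` holds 2*span characters, unprimed then primed; ``PAD``
    marks slots outside the protein.
    """

    protein_id: str
    p1_pos: int
    residues: str
    span: int = 5

    @property
    def p1(self) -> str:
        return self.residues[self.span - 1]

    @property
    def p1prime(self) -> str:
        return self.residues[self.span]

    def slot(self, label: str) -> str:
        return self.residues[position_labels(self.span).index(label)]


@dataclass
class ReferenceComposition:
    """Residue → percentage background composition (sums to 100)."""

    percentages: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if abs(total - 100.0) > 0.1:
            raise CleavemapError(
                f"reference composition sums to {total:.3f}, not 100"
            )
        missing = AMINO_ACIDS - set(self.percentages)
        if missing:
            raise CleavemapError(
                f"reference composition missing residues {sorted(missing)}"
            )
        # Renormalise exactly to 100 so per-position diffs sum to zero.
        self.percentages = {
            aa: 100.0 * pct / total for aa, pct in self.percentages.items()
        }


def load_reference_composition() -> ReferenceComposition:
    """The packaged human Swiss-Prot-style background composition."""
    path = resources.files("cleavemap").joinpath(
        "fixtures", "reference_composition.tsv"
    )
    frame = pd.read_csv(path, sep="\t")
    return ReferenceComposition(
        dict(zip(frame["residue"], frame["percentage"])),
        source="swissprot-human",
    )


def extract_windows(
    sites: list[tuple[str, int]],
    proteins: dict[str, ProteinRecord],
    span: int = 5,
) -> list[SiteWindow]:
    """P-span…P-span' windows around (protein_id, p1_pos) sites."""
    windows = []
    for protein_id, p1 in sites:
        try:
            protein = proteins[protein_id]
        except KeyError:
            raise CleavemapError(
                f"no sequence provided for {protein_id!r}"
            ) from None
        if not 1 <= p1 < len(protein):
            raise CleavemapError(
                f"{protein_id}: P1 position {p1} leaves no P1' residue"
            )
        chars = []
        for pos in range(p1 - span + 1, p1 + span + 1):
            if 1 <= pos <= len(protein):
                chars.append(protein.residue(pos))
            else:
                chars.append(PAD)
        windows.append(SiteWindow(protein_id, p1, "".join(chars), span))
    return windows


@dataclass
class LogoMatrix:
    """Per-position residue enrichment against the reference composition.

    ``frame`` columns: position, residue, observed_pct, reference_pct,
    diff, significant. Percentages at a position are computed over its
    non-padded observations, so per-position diffs sum to zero.
    """

    frame: pd.DataFrame
    n_windows: int
    p_value: float

    def cell(self, position: str, residue: str) -> pd.Series:
        mask = (self.frame["position"] == position) & (
            self.frame["residue"] == residue
        )
        return self.frame[mask].iloc[0]

    def display_frame(self) -> pd.DataFrame:
        """Copy with non-significant diffs zeroed (for rendering)."""
        out = self.frame.copy()
        out.loc[~out["significant"], "diff"] = 0.0
        return out


def logo_scores(
    windows: list[SiteWindow],
    reference: ReferenceComposition,
    p: float = 0.05,
) -> LogoMatrix:
    """Percentage-difference logo matrix over a set of site windows."""
    if not windows:
        raise CleavemapError("no site windows supplied")
    span = windows[0].span
    labels = position_labels(span)
    crit = norm.ppf(1.0 - p / 2.0)
    rows = []
    for idx, label in enumerate(labels):
        residues_here = [
            w.residues[idx] for w in windows if w.residues[idx] != PAD
        ]
        n = len(residues_here)
        for residue in sorted(AMINO_ACIDS):
            observed = (
                100.0 * residues_here.count(residue) / n if n else 0.0
            )
            ref = reference.percentages.get(residue, 0.0)
            diff = observed - ref
            significant = False
            if n:
                p0 = ref / 100.0
                se = math.sqrt(p0 * (1.0 - p0) / n)
                significant = se > 0 and abs(observed / 100.0 - p0) > crit * se
            rows.append(
                {
                    "position": label,
                    "residue": residue,
                    "observed_pct": observed,
                    "reference_pct": ref,
                    "diff": diff,
                    "significant": significant,
                }
            )
    return LogoMatrix(pd.DataFrame(rows), n_windows=len(windows), p_value=p)
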