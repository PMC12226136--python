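"""Readers and writers for the external formats the pipeline touches.

Formats are deliberately plain: FASTA for proteins (via Biopython), and
tab-separated UTF-8 tables for peptides, domain annotations, site catalogs
and reference compositions. Empty abundance cells mean "not quantified",
never zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .model import (
    TERMINUS,
    CleavemapError,
    DomainAnnotation,
    ParseError,
    PeptideObservation,
    ProteinRecord,
)

PEPTIDE_COLUMNS = [
    "protein_id",
    "peptide",
    "prev_aa",
    "next_aa",
    "start",
    "end",
    "working_protease",
    "modifications",
    "abundance_E",
    "abundance_EQ",
]

SITE_COLUMNS = [
    "protein_id",
    "enzyme",
    "p1_pos",
    "p1_aa",
    "p1p_pos",
    "p1p_aa",
    "domain",
    "n_semi_peptides",
    "n_spanning_peptides",
    "max_z",
    "tier",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein FASTA file into :class:`ProteinRecord` objects."""
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except (ValueError, FileNotFoundError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not parsed and Path(path).stat().st_size > 0:
        raise ParseError(f"{path}: not FASTA-formatted")
    for rec in parsed:
        seq = str(rec.seq).upper().replace(" ", "")
        try:
            records.append(
                ProteinRecord(id=rec.id, sequence=seq, description=rec.description)
            )
        except ParseError as exc:
            raise ParseError(f"{path}, entry {rec.id!r}: {exc}") from exc
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                if rec.description.startswith(rec.id):
                    header = f">{rec.description}"
                else:
                    header = f">{rec.id} {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Peptide tables


def _parse_mods(cell: str) -> list[tuple[int, str]]:
    if not cell:
        return []
    mods = []
    for item in cell.split(";"):
        pos, _, label = item.partition(":")
        try:
            mods.append((int(pos), label))
        except ValueError:
            raise ParseError(f"bad modification entry {item!r}") from None
    return mods


def _format_mods(mods: list[tuple[int, str]]) -> str:
    return ";".join(f"{pos}:{label}" for pos, label in mods)


def _parse_abundance(cell, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    if isinstance(cell, str):
        cell = cell.strip()
        if not cell:
            return None
    value = float(cell)
    if value < 0:
        raise ParseError(f"{column} must be nonnegative, got {value}")
    return value


def read_peptide_table(
    path: str | Path, proteins: dict[str, ProteinRecord] | None = None
) -> list[PeptideObservation]:
    """Read a tab-separated peptide quantification table.

    If ``proteins`` maps protein ids to records, each row is additionally
    validated against the protein sequence (substring and flank identity).
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PEPTIDE_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    observations = []
    for idx, row in frame.iterrows():
        try:
            obs = PeptideObservation(
                protein_id=row["protein_id"],
                sequence=row["peptide"].strip().upper(),
                start=int(row["start"]),
                end=int(row["end"]),
                prev_aa=row["prev_aa"].strip() or TERMINUS,
                next_aa=row["next_aa"].strip() or TERMINUS,
                working_protease=row["working_protease"].strip().lower(),
                modifications=_parse_mods(row["modifications"].strip()),
                abundance_E=_parse_abundance(row["abundance_E"], "abundance_E"),
                abundance_EQ=_parse_abundance(
                    row["abundance_EQ"], "abundance_EQ"
                ),
            )
            if proteins is not None and obs.protein_id in proteins:
                obs.validate(proteins[obs.protein_id])
        except (ParseError, ValueError) as exc:
            raise ParseError(f"{path}, row {idx + 2}: {exc}") from exc
        observations.append(obs)
    return observations


def write_peptide_table(
    observations: list[PeptideObservation], path: str | Path
) -> None:
    rows = []
    for obs in observations:
        rows.append(
            {
                "protein_id": obs.protein_id,
                "peptide": obs.sequence,
                "prev_aa": obs.prev_aa,
                "next_aa": obs.next_aa,
                "start": obs.start,
                "end": obs.end,
                "working_protease": obs.working_protease,
                "modifications": _format_mods(obs.modifications),
                "abundance_E": "" if obs.abundance_E is None else repr(obs.abundance_E),
                "abundance_EQ": ""
                if obs.abundance_EQ is None
                else repr(obs.abundance_EQ),
            }
        )
    pd.DataFrame(rows, columns=PEPTIDE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Domain tables


def read_domain_table(path: str | Path) -> dict[str, list[DomainAnnotation]]:
    """Read domain annotations; per-protein lists keep file order."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["protein_id", "domain_name", "start", "end"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    out: dict[str, list[DomainAnnotation]] = {}
    for idx, row in frame.iterrows():
        try:
            ann = DomainAnnotation(
                row["domain_name"], int(row["start"]), int(row["end"])
            )
        except (ParseError, ValueError) as exc:
            raise ParseError(f"{path}, row {idx + 2}: {exc}") from exc
        out.setdefault(row["protein_id"], []).append(ann)
    return out


# ---------------------------------------------------------------------------
# Configuration

CONFIG_DEFAULTS = {
    "z_threshold": 2.0,
    "fence_k": 1.5,
    "max_missed": 2,
    "min_length": 6,
    "max_length": 75,
    "trypsin_blocked_p1prime": "P",
    "gluc_blocked_p1prime": "",
    "mature_start_is_specific": False,
    "abundance_reference": "enriched",  # or "mean_of_both"
}


def read_config(path: str | Path | None) -> dict:
    """Flat key/value configuration (YAML mapping); unknown keys rejected."""
    config = dict(CONFIG_DEFAULTS)
    if path is None:
        return config
    with open(path, encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ParseError(f"{path}: config must be a flat key-value mapping")
    unknown = set(loaded) - set(CONFIG_DEFAULTS)
    if unknown:
        raise ParseError(f"{path}: unknown config key(s) {sorted(unknown)}")
    config.update(loaded)
    return config


# ---------------------------------------------------------------------------
# Packaged fixtures (worked examples transcribed from published digest tables)

FIXTURE_SOURCES = ("Table1", "Table2", "Table3", "Table4", "Table5")

FIXTURE_SUBSTRATES = {
    "Table1": "Q9P2N4-3",  # ADAMTS9 MDTCS (autolysis)
    "Table2": "P13611-2",  # versican V1
    "Table3": "P13611-3",  # versican V2, ADAMTS9
    "Table4": "P13611-3",  # versican V2, ADAMTS1/4/5
    "Table5": "P21810",  # biglycan, four enzymes
}


@dataclass
class FixtureRow:
    """One transcribed table row: the observation plus the printed metadata.

    ``published_site``/``published_domain``/``published_log2_abundance``/``published_z`` are
    regression references only — the pipeline never consumes them as inputs.
    ``spanning`` marks fully-specific peptides listed as corroborating
    evidence; ``eq_enriched`` marks rows whose printed abundance was higher
    in the inactive (EQ) digest.
    """

    observation: PeptideObservation
    enzyme: str
    published_site: str
    published_p1: int | None
    published_domain: str
    published_log2_abundance: float
    published_z: float
    eq_enriched: bool
    spanning: bool


@dataclass
class FixtureTable:
    source: str
    substrate: str
    rows: list[FixtureRow]

    def enzymes(self) -> list[str]:
        seen: list[str] = []
        for row in self.rows:
            if row.enzyme not in seen:
                seen.append(row.enzyme)
        return seen

    def select(
        self, enzyme: str | None = None, spanning: bool | None = None
    ) -> list[FixtureRow]:
        rows = self.rows
        if enzyme is not None:
            rows = [r for r in rows if r.enzyme == enzyme]
        if spanning is not None:
            rows = [r for r in rows if r.spanning == spanning]
        return rows


def _fixture_path(name: str):
    return resources.files("cleavemap").joinpath("fixtures", name)


def fixture_file(name: str):
    """Path-like handle to a packaged fixture file."""
    path = _fixture_path(name)
    if not path.is_file():
        raise CleavemapError(f"no packaged fixture named {name!r}")
    return path


def _parse_site(label: str) -> int | None:
    # "V26-G27" -> 26 ; interval labels like "1459-1480" carry no P1.
    head = label.split("-", 1)[0]
    if head and head[0].isalpha() and head[1:].isdigit():
        return int(head[1:])
    return None


def load_fixture(source: str) -> FixtureTable:
    """Load one packaged digest table (``Table1`` … ``Table5``)."""
    if source not in FIXTURE_SOURCES:
        raise CleavemapError(
            f"unknown fixture {source!r}; expected one of {FIXTURE_SOURCES}"
        )
    path = _fixture_path(f"{source.lower()}.tsv")
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rows = []
    for _, row in frame.iterrows():
        obs = PeptideObservation(
            protein_id=row["protein_id"],
            sequence=row["peptide"],
            start=int(row["start"]),
            end=int(row["end"]),
            prev_aa=row["prev_aa"],
            next_aa=row["next_aa"],
            working_protease=row["working_protease"],
            modifications=_parse_mods(row["modifications"]),
            abundance_E=_parse_abundance(row["abundance_E"], "abundance_E"),
            abundance_EQ=_parse_abundance(row["abundance_EQ"], "abundance_EQ"),
        )
        rows.append(
            FixtureRow(
                observation=obs,
                enzyme=row["enzyme"],
                published_site=row["published_site"],
                published_p1=_parse_site(row["published_site"]),
                published_domain=row["published_domain"],
                published_log2_abundance=float(row["published_log2_abundance"]),
                published_z=float(row["published_z"]),
                eq_enriched=row["eq_enriched"] == "1",
                spanning=row["spanning"] == "1",
            )
        )
    return FixtureTable(source, FIXTURE_SUBSTRATES[source], rows)


def load_fixture_domains() -> dict[str, list[DomainAnnotation]]:
    """Domain intervals for the fixture substrates.

    The source tables print domain labels but not boundaries; these
    intervals are reverse-engineered so that every printed site falls in its
    printed domain, and are editable fixture data, not code.
    """
    return read_domain_table(_fixture_path("domains.tsv"))


def load_isoform_map() -> list[tuple[str, int, int, str, int]]:
    """Block-wise position correspondences between protein isoforms.

    Rows are (protein_a, a_start, a_end, protein_b, b_start): positions in
    ``[a_start, a_end]`` of ``protein_a`` map linearly onto ``protein_b``
    starting at ``b_start``.
    """
    frame = pd.read_csv(
        _fixture_path("isoform_map.tsv"), sep="\t", dtype=str
    )
    return [
        (
            r["protein_a"],
            int(r["a_start"]),
            int(r["a_end"]),
            r["protein_b"],
            int(r["b_start"]),
        )
        for _, r in frame.iterrows()
    ]
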