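"""Synthetic E/EQ digest experiments with known ground truth.

The generator emulates the comparative degradomics design: a substrate is
incubated with an active (E) or catalytically dead (EQ) protease, then
digested with a working protease (trypsin/GluC) and quantified label-free.
Planted cleavage events leave three signatures, mirroring the physical
experiment:

* semi-specific peptides abutting the planted bond, abundant in E and at
  trace level in EQ (so they remain co-quantified);
* fully-specific peptides spanning the bond, depleted in E by the cleavage
  fraction;
* everything else symmetric between groups up to multiplicative noise.

Background (spurious) semi-specific peptides — ragged termini from in-source
fragmentation or nonspecific working-protease activity — are symmetric
between groups by construction, which makes the null z distribution of the
background approximately standard normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .caller import CleavageCall
from .digest import digest_protein, rule_for, theoretical_sites
from .logo import load_reference_composition
from .model import CleavemapError, PeptideObservation, ProteinRecord


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated E/EQ experiment pair.

    Defaults emulate a mid-size substrate digested with both working
    proteases under the standard search settings (up to two missed
    cleavages, peptide length 6–75): ten planted sites cleaved at 80%
    efficiency, log-normal base intensities around 2^18 and ~10%
    multiplicative noise per group, with roughly three ragged background
    semi peptides per detected fully-specific peptide — the semi:fully
    ratio seen in real digest searches.
    """

    seed: int = 7
    protein: ProteinRecord | None = None
    protein_length: int = 300
    planted_sites: list[tuple[int, float]] | None = None
    n_planted: int = 10
    cleavage_fraction: float = 0.8
    working_proteases: tuple[str, ...] = ("trypsin", "gluc")
    max_missed: int = 2
    length_range: tuple[int, int] = (6, 75)
    base_log2_mean: float = 18.0
    base_log2_sd: float = 2.0
    noise_cv: float = 0.1
    background_semi_rate: float = 3.0
    detect_prob: float = 0.9
    eq_trace_fraction: float = 0.01
    eq_trace_detect_prob: float = 0.6

    def validate(self) -> None:
        if self.planted_sites is not None:
            length = (
                len(self.protein) if self.protein else self.protein_length
            )
            for p1, frac in self.planted_sites:
                if not 1 <= p1 < length:
                    raise CleavemapError(
                        f"planted P1 {p1} outside protein 1..{length - 1}"
                    )
                if not 0 < frac <= 1:
                    raise CleavemapError(
                        f"cleavage fraction {frac} not in (0, 1]"
                    )
        unknown = set(self.working_proteases) - {"trypsin", "gluc"}
        if unknown:
            raise CleavemapError(f"unknown working protease(s) {unknown}")
        if not 0 < self.detect_prob <= 1:
            raise CleavemapError("detect_prob must be in (0, 1]")
        if self.background_semi_rate < 0 or self.noise_cv < 0:
            raise CleavemapError("rates must be nonnegative")


@dataclass
class GroundTruth:
    """What the generator planted, and where each observation came from."""

    protein: ProteinRecord
    planted: list[tuple[int, float]]
    provenance: dict[tuple, str] = field(default_factory=dict)

    def planted_positions(self) -> set[int]:
        return {p1 for p1, _ in self.planted}


def random_protein(
    rng: np.random.Generator, length: int, protein_id: str = "SYN1"
) -> ProteinRecord:
    """Random sequence drawn from the packaged proteome composition."""
    ref = load_reference_composition().percentages
    residues = sorted(ref)
    probs = np.array([ref[r] for r in residues])
    probs = probs / probs.sum()
    seq = "".join(rng.choice(residues, size=length, p=probs))
    return ProteinRecord(protein_id, seq, description="synthetic substrate")


def simulate_experiment(
    config: SyntheticConfig,
) -> tuple[list[PeptideObservation], GroundTruth]:
    """Simulate the peptide table of one E/EQ digest pair.

    Deterministic given ``config.seed``. Returns the observations (all
    working proteases pooled, as in a merged search output) and the ground
    truth with per-observation provenance ("planted" / "background" /
    "fully").
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    protein = config.protein or random_protein(rng, config.protein_length)

    if config.planted_sites is not None:
        planted = sorted(config.planted_sites)
    else:
        planted = _draw_planted(rng, protein, config)

    sigma = float(np.log2(1.0 + config.noise_cv))
    truth = GroundTruth(protein, planted)
    by_key: dict[tuple, PeptideObservation] = {}

    def noise() -> float:
        return float(2.0 ** rng.normal(0.0, sigma)) if sigma > 0 else 1.0

    def base() -> float:
        return float(
            2.0 ** rng.normal(config.base_log2_mean, config.base_log2_sd)
        )

    def emit(obs: PeptideObservation, provenance: str) -> None:
        key = obs.key()
        if key in by_key:
            return
        by_key[key] = obs
        truth.provenance[key] = provenance

    for protease in config.working_proteases:
        rule = rule_for(protease)
        sites = theoretical_sites(protein, rule)
        site_set = set(sites)
        clashes = [p1 for p1, _ in planted if p1 in site_set]
        if clashes:
            warnings.warn(
                f"planted site(s) {clashes} coincide with theoretical "
                f"{protease} sites and are invisible as semi evidence",
                stacklevel=2,
            )

        fully = digest_protein(
            protein, rule, config.max_missed, config.length_range
        )
        detected_fully = []
        for pep in fully:
            if rng.random() > config.detect_prob:
                continue
            b = base()
            reduction = 1.0
            for p1, frac in planted:
                if pep.start <= p1 and p1 + 1 <= pep.end:
                    reduction *= 1.0 - frac
            obs = _with_abundance(pep, b * reduction * noise(), b * noise())
            detected_fully.append(obs)
            emit(obs, "fully")

        for p1, frac in planted:
            if p1 in site_set:
                continue  # indistinguishable from the working protease
            for skel in _planted_semis(protein, rule, sites, p1, config):
                if rng.random() > config.detect_prob:
                    continue
                b = base()
                # The EQ-side trace sits at the detection limit and is
                # only sometimes quantified; an undetected trace leaves an
                # E-only exclusive, which the caller sidelines.
                eq_int = (
                    config.eq_trace_fraction * b * noise()
                    if rng.random() < config.eq_trace_detect_prob
                    else None
                )
                emit(
                    _with_abundance(skel, frac * b * noise(), eq_int),
                    "planted",
                )

        forbidden_cuts = site_set | {p1 for p1, _ in planted}
        for obs in detected_fully:
            n_bg = rng.poisson(config.background_semi_rate)
            for _ in range(n_bg):
                skel = _ragged_variant(
                    protein, obs, rng, config.length_range[0], forbidden_cuts
                )
                if skel is None:
                    continue
                b = base()
                emit(
                    _with_abundance(skel, b * noise(), b * noise()),
                    "background",
                )

    observations = [by_key[k] for k in sorted(by_key)]
    return observations, truth


def _draw_planted(
    rng: np.random.Generator,
    protein: ProteinRecord,
    config: SyntheticConfig,
) -> list[tuple[int, float]]:
    """Planted P1 positions away from termini and working-protease sites."""
    avoid: set[int] = set()
    for protease in config.working_proteases:
        avoid.update(theoretical_sites(protein, rule_for(protease)))
    margin = 5
    candidates = [
        pos
        for pos in range(1 + margin, len(protein) - margin)
        if pos not in avoid
    ]
    if len(candidates) < config.n_planted:
        raise CleavemapError(
            f"cannot place {config.n_planted} sites on this protein"
        )
    chosen = rng.choice(
        np.array(candidates), size=config.n_planted, replace=False
    )
    return sorted((int(p), config.cleavage_fraction) for p in chosen)


def _planted_semis(
    protein: ProteinRecord,
    rule,
    sites: list[int],
    p1: int,
    config: SyntheticConfig,
) -> list[PeptideObservation]:
    """Semi peptides produced by re-digesting the two cleavage products.

    Keeps the working-protease peptides of each product whose terminus is
    the planted bond: peptides ending at P1 (semi on the C side) and
    starting at P1' (semi on the N side), up to ``max_missed`` internal
    sites and within the detectable length window.
    """
    lo, hi = config.length_range
    out = []
    left_bounds = [0] + [s for s in sites if s < p1]
    for b in left_bounds[-(config.max_missed + 1) :]:
        start, end = b + 1, p1
        if lo <= end - start + 1 <= hi:
            out.append(_skeleton_obs(protein, start, end, rule.name))
    right_bounds = [s for s in sites if s > p1] + [len(protein)]
    for e in right_bounds[: config.max_missed + 1]:
        start, end = p1 + 1, e
        if lo <= end - start + 1 <= hi:
            out.append(_skeleton_obs(protein, start, end, rule.name))
    return out


def _ragged_variant(
    protein: ProteinRecord,
    obs: PeptideObservation,
    rng: np.random.Generator,
    min_len: int,
    forbidden_cuts: set[int],
) -> PeptideObservation | None:
    """A random truncation of a fully-specific peptide (background semi).

    The new terminus avoids theoretical working-protease sites (which would
    stay fully specific) and planted bonds (which would fake evidence).
    """
    side = "n" if rng.random() < 0.5 else "c"
    if side == "n":
        # New start in (start, end-min_len+1]; cut bond is start-1.
        lo, hi = obs.start + 1, obs.end - min_len + 1
        if hi < lo:
            return None
        start = int(rng.integers(lo, hi + 1))
        if start - 1 in forbidden_cuts:
            return None
        return _skeleton_obs(protein, start, obs.end, obs.working_protease)
    lo, hi = obs.start + min_len - 1, obs.end - 1
    if hi < lo:
        return None
    end = int(rng.integers(lo, hi + 1))
    if end in forbidden_cuts:
        return None
    return _skeleton_obs(protein, obs.start, end, obs.working_protease)


def _skeleton_obs(
    protein: ProteinRecord, start: int, end: int, protease: str
) -> PeptideObservation:
    from .digest import _skeleton

    return _skeleton(protein, start, end, protease)


def _with_abundance(
    skel: PeptideObservation, e: float, eq: float
) -> PeptideObservation:
    obs = _copy(skel)
    obs.abundance_E = e
    obs.abundance_EQ = eq
    return obs


def _copy(skel: PeptideObservation) -> PeptideObservation:
    obs = PeptideObservation.__new__(PeptideObservation)
    obs.protein_id = skel.protein_id
    obs.sequence = skel.sequence
    obs.start = skel.start
    obs.end = skel.end
    obs.prev_aa = skel.prev_aa
    obs.next_aa = skel.next_aa
    obs.working_protease = skel.working_protease
    obs.modifications = list(skel.modifications)
    obs.abundance_E = skel.abundance_E
    obs.abundance_EQ = skel.abundance_EQ
    return obs


@dataclass
class RecoveryReport:
    """Precision/recall of called sites against the planted truth."""

    precision: float
    recall: float
    n_calls: int
    n_planted: int
    true_positives: list[int]
    false_positives: list[int]
    missed: list[int]
    precision_defined: bool

    def __str__(self) -> str:
        return (
            f"precision={self.precision:.3f} recall={self.recall:.3f} "
            f"({self.n_calls} calls, {self.n_planted} planted)"
        )


def recovery_report(
    calls: list[CleavageCall], truth: GroundTruth
) -> RecoveryReport:
    """Score called sites: a call is a true positive iff its P1 is planted.

    With no calls at all, precision is undefined and reported as 1.0 with
    ``precision_defined=False``.
    """
    planted = truth.planted_positions()
    positions = sorted({c.p1_pos for c in calls})
    tp = [p for p in positions if p in planted]
    fp = [p for p in positions if p not in planted]
    missed = sorted(planted - set(positions))
    defined = bool(positions)
    precision = len(tp) / len(positions) if defined else 1.0
    recall = len(tp) / len(planted) if planted else 1.0
    return RecoveryReport(
        precision=precision,
        recall=recall,
        n_calls=len(positions),
        n_planted=len(planted),
        true_positives=tp,
        false_positives=fp,
        missed=missed,
        precision_defined=defined,
    )
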