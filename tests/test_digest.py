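"""In-silico digestion and terminal-specificity classification."""

import dataclasses

import pytest
from hypothesis import given, settings, strategies as st

from cleavemap.digest import (
    GLUC,
    TRYPSIN,
    ProteaseRule,
    classify_peptide,
    coverage,
    digest_protein,
    reverse_observation,
    rule_for,
    site_density,
    theoretical_sites,
)
from cleavemap.model import CleavemapError, PeptideObservation, ProteinRecord

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=60)


def scan_oracle(seq: str, p1: set, blocked: set) -> list[int]:
    """Independent character-scan for theoretical cleavage positions."""
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in p1 and seq[i + 1] not in blocked
    ]


class TestTheoreticalSites:
    def test_simple_tryptic(self):
        protein = ProteinRecord("P", "AAKAAKAA")
        assert theoretical_sites(protein, TRYPSIN) == [3, 6]

    def test_proline_rule(self):
        protein = ProteinRecord("P", "AKPA")
        assert theoretical_sites(protein, TRYPSIN) == []
        unblocked = ProteaseRule("trypsin", frozenset("KR"))
        assert theoretical_sites(protein, unblocked) == [2]

    def test_terminal_residue_yields_no_site(self):
        protein = ProteinRecord("P", "AAK")
        assert theoretical_sites(protein, TRYPSIN) == []

    def test_empty_region_rejected(self):
        protein = ProteinRecord("P", "AAKAAKAA")
        with pytest.raises(CleavemapError, match="empty region"):
            theoretical_sites(protein, TRYPSIN, (5, 4))

    @settings(derandomize=True, max_examples=50)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=200, max_size=200))
    def test_gluc_matches_scan_oracle(self, seq):
        protein = ProteinRecord("P", seq)
        assert theoretical_sites(protein, GLUC) == scan_oracle(
            seq, set("DE"), set()
        )


class TestDigest:
    def test_zero_missed(self):
        protein = ProteinRecord("P", "MKTAYR")
        peptides = digest_protein(protein, TRYPSIN, 0)
        assert [p.sequence for p in peptides] == ["MK", "TAYR"]
        assert [(p.prev_aa, p.next_aa) for p in peptides] == [
            ("-", "T"),
            ("K", "-"),
        ]

    def test_one_missed_adds_readthrough(self):
        protein = ProteinRecord("P", "MKTAYR")
        peptides = digest_protein(protein, TRYPSIN, 1)
        assert {p.sequence for p in peptides} == {"MK", "TAYR", "MKTAYR"}

    def test_length_filter(self):
        protein = ProteinRecord("P", "MKTAYR")
        peptides = digest_protein(protein, TRYPSIN, 0, (3, 75))
        assert [p.sequence for p in peptides] == ["TAYR"]

    @settings(derandomize=True, max_examples=25)
    @given(seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=500, max_size=500))
    def test_zero_missed_tiles_sequence(self, seq):
        protein = ProteinRecord("P", seq)
        for rule in (TRYPSIN, GLUC):
            peptides = digest_protein(protein, rule, 0)
            assert "".join(p.sequence for p in peptides) == seq

    @settings(derandomize=True, max_examples=25)
    @given(seq=sequences, missed=st.integers(0, 3))
    def test_digest_output_classifies_fully(self, seq, missed):
        protein = ProteinRecord("P", seq)
        for rule in (TRYPSIN, GLUC):
            for pep in digest_protein(protein, rule, missed):
                call = classify_peptide(pep, rule)
                assert call.peptide_class == "fully"
                assert call.inferred_site is None


class TestClassify:
    def obs(self, seq, prev, nxt, start, protease="trypsin"):
        return PeptideObservation(
            protein_id="X",
            sequence=seq,
            start=start,
            end=start + len(seq) - 1,
            prev_aa=prev,
            next_aa=nxt,
            working_protease=protease,
            abundance_E=1.0,
            abundance_EQ=1.0,
        )

    def test_semi_n_infers_upstream_bond(self):
        # Ragged N-terminus after E, fully tryptic C-terminus.
        call = classify_peptide(
            self.obs("YSGSETAVER", "E", "I", 829), TRYPSIN
        )
        assert call.peptide_class == "semi_n"
        assert call.inferred_site == (828, 829)
        assert call.positionally_internal

    def test_semi_c_infers_downstream_bond(self):
        call = classify_peptide(
            self.obs("GLQHLYAL", "K", "V", 112), TRYPSIN
        )
        assert call.peptide_class == "semi_c"
        assert call.inferred_site == (119, 120)

    def test_fully_tryptic_no_site(self):
        call = classify_peptide(self.obs("TAVER", "K", "I", 10), TRYPSIN)
        assert call.peptide_class == "fully"
        assert call.inferred_site is None

    def test_protein_terminus_counts_as_specific(self):
        call = classify_peptide(self.obs("MKTA", "-", "V", 1), TRYPSIN)
        assert call.n_term_status == "protein_terminus"
        assert call.peptide_class == "semi_c"

    def test_first_bond_cut_not_positionally_internal(self):
        call = classify_peptide(self.obs("TAVER", "M", "I", 2), TRYPSIN)
        assert call.peptide_class == "semi_n"
        assert call.inferred_site == (1, 2)
        assert not call.positionally_internal

    def test_mature_start_config(self):
        obs = self.obs("TAVER", "G", "I", 30)
        assert classify_peptide(obs, TRYPSIN).peptide_class == "semi_n"
        call = classify_peptide(obs, TRYPSIN, mature_start=30)
        assert call.peptide_class == "fully"

    def test_modifications_do_not_alter_specificity(self):
        obs = self.obs("TEPTGLVLSTVMDR", "S", "E", 893)
        acetylated = dataclasses.replace(
            obs, modifications=[(1, "acetyl")]
        )
        assert (
            classify_peptide(obs, TRYPSIN).peptide_class
            == classify_peptide(acetylated, TRYPSIN).peptide_class
            == "semi_n"
        )

    def test_protease_mismatch_rejected(self):
        with pytest.raises(CleavemapError, match="rule"):
            classify_peptide(self.obs("TAVER", "K", "I", 10), GLUC)

    @settings(derandomize=True, max_examples=100)
    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
        prev=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        nxt=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
    )
    def test_partition_exactly_one_class(self, seq, prev, nxt):
        for rule in (TRYPSIN, GLUC):
            obs = self.obs(seq, prev, nxt, 10, rule.name)
            call = classify_peptide(obs, rule)
            assert call.peptide_class in (
                "fully",
                "semi_n",
                "semi_c",
                "nonspecific",
            )
            assert (call.inferred_site is not None) == (
                call.peptide_class in ("semi_n", "semi_c")
            )

    @settings(derandomize=True, max_examples=100)
    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=20),
        prev=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
        nxt=st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
    )
    def test_reversal_swaps_semi_n_and_semi_c(self, seq, prev, nxt):
        """Mirroring sequence and flanks (with the rule read in the mirror
        orientation) exchanges the two semi classes."""

        class MirrorRule(ProteaseRule):
            def cuts_after(self, p1, p1prime):  # reads bonds right-to-left
                return (
                    p1prime in self.p1_residues
                    and p1 not in self.blocked_p1prime
                )

        for rule in (TRYPSIN, GLUC):
            mirror = MirrorRule(rule.name, rule.p1_residues, rule.blocked_p1prime)
            obs = self.obs(seq, prev, nxt, 10, rule.name)
            mirrored = reverse_observation(obs)
            swap = {"semi_n": "semi_c", "semi_c": "semi_n"}
            direct = classify_peptide(obs, rule).peptide_class
            reflected = classify_peptide(mirrored, mirror).peptide_class
            assert reflected == swap.get(direct, direct)


class TestCoverage:
    def test_single_peptide(self, obs_factory):
        protein = ProteinRecord("TOY1", "A" * 100)
        obs = obs_factory(protein, 1, 10)
        assert coverage([obs], protein) == pytest.approx(0.10)

    def test_overlap_counted_once(self, obs_factory):
        protein = ProteinRecord("TOY1", "A" * 100)
        peps = [obs_factory(protein, 1, 10), obs_factory(protein, 5, 20)]
        assert coverage(peps, protein) == pytest.approx(0.20)

    def test_matches_mask_oracle(self, rng):
        residues = "ACDEFGHIKLMNPQRSTVWY"
        protein = ProteinRecord(
            "TOY1", "".join(rng.choice(list(residues), size=300))
        )
        peps = []
        mask = [False] * 300
        for _ in range(50):
            start = int(rng.integers(1, 290))
            end = min(300, start + int(rng.integers(5, 30)))
            peps.append(
                PeptideObservation(
                    protein_id="TOY1",
                    sequence=protein.subsequence(start, end),
                    start=start,
                    end=end,
                    prev_aa="-" if start == 1 else protein.residue(start - 1),
                    next_aa="-" if end == 300 else protein.residue(end + 1),
                    working_protease="trypsin",
                    abundance_E=1.0,
                )
            )
            for i in range(start - 1, end):
                mask[i] = True
        assert coverage(peps, protein) == pytest.approx(sum(mask) / 300)


class TestSiteDensity:
    def test_simple(self):
        protein = ProteinRecord("P", "AAKAAKAA")
        report = site_density(protein, TRYPSIN)
        assert report.n_sites == 2
        assert report.mean_gap == 3
        assert report.max_gap == 3
        assert report.residue_counts == {"K": 2, "R": 0}

    def test_region_without_sites_reports_length(self):
        protein = ProteinRecord("P", "AAKAAKAA")
        report = site_density(protein, TRYPSIN, (4, 5))
        assert report.n_sites == 0
        assert report.mean_gap == report.max_gap == 2

    def test_matches_scan_oracle(self, rng):
        residues = "ACDEFGHIKLMNPQRSTVWY"
        seq = "".join(rng.choice(list(residues), size=400))
        protein = ProteinRecord("P", seq)
        report = site_density(protein, rule_for("gluc"), count_residues="DE")
        sites = scan_oracle(seq, set("DE"), set())
        gaps = [b - a for a, b in zip(sites, sites[1:])]
        assert report.n_sites == len(sites)
        assert report.mean_gap == pytest.approx(sum(gaps) / len(gaps))
        assert report.max_gap == max(gaps)
        assert report.residue_counts == {
            "D": seq.count("D"),
            "E": seq.count("E"),
        }
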