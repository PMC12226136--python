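#!/usr/bin/env python
"""Subsite preference of the protease under study at its proteoglycan sites.

Pools the catalogued cleavage sites of the enzyme across its proteoglycan
substrates, tallies P1/P1' residues (known from the evidence peptides'
flanks even without full-length sequences) and scores them against the
packaged proteome reference composition. Writes results/p1_enrichment.tsv.
"""

from collections import Counter
from pathlib import Path

from cleavemap.io import load_fixture
from cleavemap.logo import PAD, SiteWindow, load_reference_composition, logo_scores
from cleavemap.pipeline import sites_from_significant

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    pairs = []  # (p1_aa, p1prime_aa) per unique site
    for source in ("Table2", "Table3", "Table5"):
        table = load_fixture(source)
        rows = table.select(enzyme="ADAMTS9", spanning=False)
        catalog = sites_from_significant(
            [r.observation for r in rows], enzyme="ADAMTS9"
        )
        pairs.extend((c.p1_aa, c.p1prime_aa) for c in catalog.calls())

    p1_counts = Counter(p1 for p1, _ in pairs)
    p1p_counts = Counter(p1p for _, p1p in pairs)
    print(f"{len(pairs)} unique proteoglycan cleavage sites")
    print("P1 residues: ", dict(p1_counts.most_common()))
    print("P1' residues:", dict(p1p_counts.most_common()))

    # Score the two flanking positions against the proteome background.
    windows = [
        SiteWindow("pool", 0, PAD * 4 + p1 + p1p + PAD * 4, span=5)
        for p1, p1p in pairs
    ]
    matrix = logo_scores(windows, load_reference_composition())
    flanks = matrix.frame[matrix.frame["position"].isin(["P1", "P1'"])]
    flanks = flanks[flanks["observed_pct"] > 0].sort_values(
        ["position", "diff"], ascending=[True, False]
    )
    flanks.to_csv(RESULTS / "p1_enrichment.tsv", sep="\t", index=False)

    top_p1 = flanks[flanks["position"] == "P1"].iloc[0]
    print(
        f"\nstrongest P1 enrichment: {top_p1['residue']} "
        f"({top_p1['observed_pct']:.1f}% observed vs "
        f"{top_p1['reference_pct']:.1f}% background, "
        f"diff {top_p1['diff']:+.1f}, "
        f"significant={bool(top_p1['significant'])})"
    )
    print(f"enrichment table -> {RESULTS / 'p1_enrichment.tsv'}")


if __name__ == "__main__":
    main()
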