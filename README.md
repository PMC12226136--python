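# cleavemap

Protease cleavage-site mapping from comparative degradomics, for
biochemists characterising the substrate repertoire of a protease — here
the ADAMTS family of secreted metalloproteases acting on the proteoglycans
versican, aggrecan and biglycan.

The experimental design it analyses: a substrate is incubated with the
active protease (E) or its inactive active-site mutant (EQ), both samples
are digested with a working protease (trypsin or GluC) and quantified
label-free by LC-MS/MS. For each peptide quantified in both groups,

    r = log2(E/EQ),    z = (r − mean r) / sd r

over all co-quantified peptides of the experiment. A *semi-specific*
peptide (exactly one terminus conforming to the working protease's rule)
with z ≥ 2 nominates the cleavage site P1–P1′ at its nonconforming
terminus; a *fully specific* peptide with z ≤ −2 spanning a called bond
corroborates it (the cleavage destroys it in the E digest). Calls are
stratified by abundance with Tukey fences (Q1 − 1.5·IQR, Q3 + 1.5·IQR),
deduplicated per (protein, P1, enzyme), annotated with domains, and
compared across enzymes for shared and novel sites. Around the catalogued
sites, P5–P5′ residue frequencies are scored against a proteome reference
composition (iceLogo-style percentage differences). A kinetics layer fits
Michaelis–Menten initial rates, tight-binding active-site titrations
(x-intercept) and single-exponential progress curves for kcat/Km.

A synthetic E/EQ generator with planted cleavage sites makes the whole
pipeline testable end to end with known ground truth — no downloads
required. See `docs/methods.md` for the models and conventions.

## Worked example

The packaged evidence tables transcribe the significant peptides of the
ADAMTS digest study (five tables: ADAMTS9 autolysis, versican V1,
versican V2 by ADAMTS9 and by ADAMTS1/4/5, and biglycan by all four
enzymes). Building the site catalogues:

```python
from cleavemap.io import load_fixture, load_fixture_domains
from cleavemap.pipeline import sites_from_significant
from cleavemap.catalog import compare_enzymes, union_novel

domains = load_fixture_domains()

def catalog(source, enzyme):
    rows = load_fixture(source).select(enzyme=enzyme, spanning=False)
    return sites_from_significant([r.observation for r in rows],
                                  enzyme=enzyme, domains=domains)

v2 = [catalog("Table3", "ADAMTS9"), catalog("Table4", "ADAMTS1"),
      catalog("Table4", "ADAMTS4"), catalog("Table4", "ADAMTS5")]
print([len(c) for c in v2])
print(union_novel(v2)["union"])
print(compare_enzymes(v2).shared_between("ADAMTS5", "ADAMTS9"))
```

prints

```
[21, 12, 5, 9]
42
{1433, 1451}
```

— per-enzyme unique cleavage sites in versican V2, their cross-enzyme
union (inter-enzyme shared bonds counted once), and the two G3-domain
bonds cut by both ADAMTS5 and ADAMTS9. The analysis drivers run the full
narrative and write tables under `results/`:

```sh
python analysis/01_site_catalogs.py     # site tables, sharing, unions
python analysis/02_kinetics.py          # kcat/Km, titration, progress fits
python analysis/03_specificity.py       # P1/P1' enrichment vs proteome
python analysis/04_synthetic_benchmark.py  # recovery, null calibration, power
```

`02_kinetics.py`, for instance, prints

```
catalytic efficiency kcat/Km = 3.35e+03 1/(M s)
active-site titration x-intercept = 8.00 nM
progress-curve kcat/Km (V1) = 2.1e+04 1/(M s)
versicanase activity vs ADAMTS5: ADAMTS5: 165-fold higher
```

i.e. the enzyme's peptidolytic efficiency from its measured kcat and Km,
the active concentration from the TIMP-3 titration, the versicanase
specificity constant from the progress curve, and the fold comparison
against the related proteases.

A `cleavemap` console command wraps the same functions for shell use
(`cleavemap classify`, `call`, `catalog`, `logo`, `density`,
`kinetics mm|titration|progress`, `simulate`); run any subcommand with
`--help`.

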