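# rrnasip

Analysis toolkit for **rRNA stable isotope probing (SIP)** experiments that
trace the flow of substrate carbon into soil microbial communities.

In an rRNA-SIP experiment, a soil microcosm is amended with a
¹³C-labeled substrate (glucose, cellulose, plant litter, ...). Organisms that
assimilate substrate carbon synthesize ¹³C-labeled rRNA, which bands at a
higher buoyant density in an isopycnic CsTFA gradient. After fractionating
the gradient (12 fractions, fraction 1 the densest) and amplicon-sequencing
a representative **heavy** (~1.82 g ml⁻¹) and **light** (~1.79 g ml⁻¹)
fraction of both the ¹³C gradient and a paired ¹²C control, the
**enrichment factor** of each taxon is

```
EF = ¹³C_heavy / ¹³C_light − ¹²C_heavy / ¹²C_light
```

where each term is the taxon's relative read abundance in that fraction.
Taxa with EF > 0.5 in at least one treatment or timepoint are called
¹³C-labeled; EFs are computed for taxa exceeding 2% read abundance in a
heavy fraction (protists exempt). Alongside, a **two-pool δ¹³C mixing
model** quantifies substrate-derived carbon in CO₂, microbial biomass and
PLFA pools,

```
% substrate-derived C = (δ_sample − δ_reference) / (δ_substrate − δ_soil) × 100
```

and an **in-silico T-RF digester** predicts terminal restriction fragment
lengths from reference sequences to cross-validate labeling calls against
T-RFLP fingerprints.

Because raw SIP sequence data are experiment-specific, the package includes
a gradient **simulator** with known ground truth (two-mode Gaussian density
model, multinomial read sampling, paired controls, mixing-consistent δ¹³C
series), so every inference step is testable by parameter recovery.

## Worked example

```
$ rrnasip run --seed 4 --depth 2000 -o out/
INFO rrnasip: run complete; 8 labeled taxa: Arthrobacter, Cellvibrio, ...
```

or, stepwise, the numbered drivers:

```
$ python analysis/01_simulate_gradients.py
glucose/8d: top taxon in heavy 13C fraction = Arthrobacter (4180 of 10000 reads)
...
$ python analysis/02_enrichment_factors.py
32 records over 4 gradient pairs
called labeled: Arthrobacter, Cellvibrio, Chaetomium, Cryptococcus,
Flavobacterium, Kitasatospora, Micrococcaceae, Pythium
simulated assimilators: Arthrobacter, Cellvibrio, Chaetomium, Cryptococcus,
Flavobacterium, Kitasatospora, Micrococcaceae, Pythium
```

Every simulated assimilator — and no background taxon — is called labeled.
The labeled-taxa matrix marks each substrate × timepoint cell `+` (EF > 0.5)
or `++` (EF > 0.5 and ≥10% heavy-fraction read abundance):

```
substrate               cellulose     glucose
timepoint                     32d  8d     32d  8d
bacteria Arthrobacter                      ++  ++
         Cellvibrio            ++  ++
         Flavobacterium            ++
...
```

`analysis/03_carbon_mixing.py` prints the amendment bookkeeping
(12 mg C per 50-g microcosm = 240 µg C g⁻¹ soil, 1.752% of soil organic C)
and recovers the simulated substrate-derived carbon percentages from noisy
δ¹³C replicates (e.g. 63.2% recovered vs 60% truth at 0.5‰ noise, n = 3).
`analysis/04_trf_validation.py` cross-validates all labeled taxa by
predicted T-RFs within ±2 bp of observed fragment sizes.

The CLI also exposes each stage separately (`rrnasip simulate | ef |
mixing | trf`) for user-supplied tables in the same TSV/CSV layouts.

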