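# toxscreen

Similarity-network toxicity screening for natural-product component
libraries, paired with *Vibrio fischeri* bioluminescence dose–response
analysis. The package is aimed at researchers triaging multi-herb
formulations: it identifies which chemical components of a formulation
structurally resemble known toxicants, and quantifies whole-extract toxicity
from microplate luminescence data.

## What it computes

**Toxic reference set.** Every compound in a toxic-training library is
reduced to a 166-key MACCS fingerprint — the binary vector of substructure
keys it contains. Pairs with Tanimoto coefficient

    T(A, B) = |A ∩ B| / (|A| + |B| − |A ∩ B|) ≥ τ   (default τ = 0.5)

become edges of an undirected similarity network. Degree centrality (how
many library compounds a molecule resembles at or above τ) identifies the
structural core: nodes with degree ≥ ⌈max degree / 2⌉ form the toxic
reference set.

**Component screening.** Each query component is matched against every
reference compound; its *match degree* is the number of reference compounds
it resembles at T ≥ τ. Within each query library, components with match
degree ≥ ⌈max match degree / 2⌉ (and ≥ 1 match) are flagged as putative
toxic components. Formulations are screened as pooled, structure-deduplicated
unions of their constituent herbs' component lists.

**Bioassay.** The luminescence inhibition rate per concentration is

    inhibition% = (X̄_ctrl − X̄_sample) / X̄_ctrl × 100,

with replicate luminescence averaged first (negative values mean stimulation
and are flagged, not clipped). Inhibition against log10 concentration is
fitted with a four-parameter logistic; the reported IC50 is the
concentration where the fitted curve crosses 50% absolute inhibition.
Smaller IC50 = greater potential toxicity, so ranking series by descending
IC50 lists the least toxic first, and a formulation whose IC50 exceeds the
base herb's is called a detoxification trend.

A seeded synthetic-data module generates every input with planted ground
truth — clustered fingerprint/SMILES libraries with decoys, mimic/decoy
query libraries, and dose–response plates with known IC50 and Hill slope —
so the whole pipeline is testable without any external data.

## Worked example

The four numbered drivers under `analysis/` run the whole study on synthetic
inputs (`python analysis/01_simulate_inputs.py`, then 02–04). With the
shipped seed, building the reference from a 20-compound training library of
two scaffold families prints:

```
library: 20 compounds; 31 pairs at tau=0.5
max degree 7, cutoff 4 -> 9 reference compounds
```

i.e. 31 compound pairs reach Tanimoto ≥ 0.5, the best-connected compound
resembles 7 others, and the 9 compounds with degree ≥ 4 (all from the
denser alkane family) become the reference set. Screening two formulations
against it:

```
FORM1: 2 of 4 components flagged (max match degree 6, cutoff 3)
  A_heptanol: match degree 6, closest references alkane_1, alkane_3, alkane_6
  A_octane: match degree 5, closest references alkane_0, alkane_4, alkane_2
```

the two planted chain-family components are flagged; the polar decoys match
nothing. The bioassay stage fits the three simulated plates (true IC50s
5×10⁻⁴, 4×10⁻⁴, 2.5×10⁻⁴ g/mL, 5% multiplicative noise):

```
BASE: IC50 0.0003873 g/mL (95% CI 0.000378-0.000399), hill 1.01
FORM1: IC50 0.0005323 g/mL (95% CI 0.000516-0.000551), hill 1.24
FORM2: IC50 0.0002422 g/mL (95% CI 0.000231-0.000254), hill 1.47
ranking (least toxic first): FORM1 > BASE > FORM2
  FORM1 vs BASE: detoxification trend
```

Each fitted IC50 lands within a few percent of its true value, and the
ranking recovers the planted toxicity order.

The same stages are available as a CLI:

```bash
toxscreen simulate --kind smiles --out sim --seed 1
toxscreen build-reference --library sim/library.smi --out ref
toxscreen screen --reference-dir ref --manifest manifest.json --out screens
toxscreen bioassay plate_*.csv --out bio --base BASE
```

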