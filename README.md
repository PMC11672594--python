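# pksdecode

Motif-based decoding of type I cis-AT polyketide synthase (PKS) assembly
lines, built around the irumamycin-class architecture: a 20-membered
macrolactone with a six-membered hemiketal ring, an exchangeable
hemiketal hydroxyl, and a glycosylated, epoxidized tailored product.

The pipeline runs entirely from protein sequences plus a small layout
configuration:

1. **`domain_scanner`** — locate KS/AT/DH/ER/KR/T/TE domains with
   anchored degenerate-pattern models (1-based inclusive coordinates)
   and segment them into modules with the canonical
   `KS–AT–[DH–[ER]–KR]–T` grammar.
2. **`specificity_rules`** — classify active-site windows: AT extender
   choice (methylmalonyl `xVDVxQ/GHSQGE/xxSH` vs malonyl
   `xTxYTQ/GHSI(V)GE/xAFN`, catalytic-serine loss ⇒ inactive), KR
   stereotype (LDD/IDD/VDD ⇒ B, `YxP` ⇒ B2 / `YxA` ⇒ B1, `WxxxxQ` ⇒ A),
   DH activity (`HxxxxxxxxP` + intact `YxY`) and enoyl-isomerase
   candidacy, KS loading-vs-extension (Q vs C).
3. **`assembly_model`** — module specs (iteration, AT borrowing, KS
   gatekeeping, olefin shift), chain extension into a unit-based
   backbone with β-carbon states and stereo labels, macrolactone +
   hemiketal ring closure, tailoring (dehydration, epoxidation,
   glycosylation) down to a molecular formula.
4. **`mass_tools`** — monoisotopic masses, `[M+H]+ / [M+NH4]+ / [M+Na]+`
   adduct m/z (electron mass included), binomial heavy-oxygen
   isotopologue patterns and peak-list comparison.
5. **`energy_profile`** — telescoping free-energy profiles for the two
   hemiketal-formation mechanisms from printed stage values, barrier
   comparison and consistency checks.
6. **`synthetic_data`** — deterministic generator embedding truth-table
   motifs into screened low-complexity scaffolds, so scanner and
   classifiers can be validated against exact ground truth, plus
   targeted window corruption.

The packaged fixture (`pksdecode.iru`) encodes the 13-module assembly
line (loading module + 12 extension modules across 6 proteins) and its
layout: AT12 inactive with malonyl borrowed from AT11, M8 ketosynthase
gatekeeping, the module 11 olefin shift giving the cis C4=C5 bond,
lactonization at C19 (20-membered ring) and the C3/C7 hemiketal.
Decoding it yields aglycone C34H56O7 and tailored product C41H65NO12;
with one heavy oxygen at the exchangeable hemiketal slot the predicted
adducts are m/z 783.489 ([M+NH4]+) and 788.444 ([M+Na]+).

## CLI

```bash
pksdecode synth --fixture iru --seed 42 --out iru   # FASTA + truth JSON
pksdecode scan --fasta iru.fasta --out hits         # hit TSV + JSON
pksdecode classify --hits hits.json --out calls.json
pksdecode backbone --calls calls.json --layout layout.json --path 1
pksdecode mass --formula C41H65NO12 --adduct "[M+NH4]+" --label-slots 1 --enrichment 0.5
pksdecode energy --path both --check
pksdecode demo                                      # full packaged pipeline
```

## Layout

```
src/pksdecode/      package modules (one per pipeline stage + iru fixture, CLI)
tests/              pytest suite; tests/test_acceptance.py maps 1:1 to the
                    acceptance criteria
scripts/acceptance.py
```
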