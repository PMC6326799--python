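# nucfish

Quantitative analysis of co-transcriptional mRNA nuclear export, as studied
by multi-colour single-molecule FISH (smFISH) in trypanosomes — with a
ground-truthed simulator so every estimator in the pipeline can be validated
against known truth.

## The problem

Trypanosome genes are transcribed in long polycistrons and matured by
trans-splicing, and mRNAs can begin crossing the nuclear envelope while
still being transcribed. Quantifying this requires:

1. **A coordinate system for the nuclear border.** DAPI intensity along a
   line from the cytoplasm to the nucleolus is rescaled to 0–100%; a spot's
   position is its *%DAPI* — the percent of the peak DAPI value at that
   point, plus a flag for which flank of the peak it is on. The border is
   calibrated by (a) the %DAPI position of a nuclear-pore marker's intensity
   peak and (b) the crossing point of a cytoplasmic marker with the rising
   DAPI flank.
2. **Molecule classification.** Spots from up to three probe colours
   (red = 5′ end, infrared = internal, green = 3′ end) are detected, linked
   into molecules (probes of one molecule stay within ~0.5 µm; a fully
   extended 22,197-nt mRNA would measure 7.5 µm at 0.34 nm/nt), and
   classified by colour combination (intact / 5′ part / 3′ part /
   read-through across a gene boundary) and by location: any signal between
   10 and 66.6 %DAPI on the cytoplasmic flank ⇒ *nuclear periphery*; all
   signals below 10% ⇒ *cytoplasm*; otherwise *nucleus*.
3. **Export orientation.** Among border-straddling molecules whose
   5′–internal segment intersects the nucleus, the fraction with the 5′
   signal further toward the cytoplasm measures 5′-first (head-first)
   export.
4. **Proteome enrichment.** Two-condition triplicate LFQ proteomics is
   analysed with the standard moderated pipeline: filter decoy/contaminant/
   only-by-site rows and rows quantified in fewer than 2 of 3 replicates;
   log2; impute missing values from a down-shifted normal (width 0.3,
   downshift 1.8 column-sd units); then call enrichment with the
   S0-moderated Welch statistic d = (m₂ − m₁)/(se + S0), S0 = 0.5, with a
   250-randomization permutation FDR at 0.05.
5. **Sequence statistics.** Q-rich regions (consecutive 60-mers with ≥7
   glutamines, reported per 100 aa) and reciprocal-best-hit homology calls
   (top forward hit whose reverse top hit returns the query with e < 1e-5).

The package is aimed at microscopists and computational biologists who want
these procedures as tested, scriptable building blocks rather than manual
image-analysis steps.

## Worked example

```python
from nucfish import (
    OpticsParams, generate_cell_scene, render_image,
    detect_spots, group_spots_to_molecules,
    classify_molecule_species, localize_molecule,
)
from nucfish.profiles import dapi_centroid

counts = {("intact", "cytoplasm"): 2, ("five_prime_part", "periphery"): 2,
          ("intact", "nucleus"): 1}
scene = generate_cell_scene(counts, orientation_fraction=0.81, seed=1)
stack = render_image(scene, OpticsParams(noise_model="poisson"), seed=2)

spots = [s for ch in ("red", "ir", "green") for s in detect_spots(stack, ch)]
molecules = group_spots_to_molecules(spots, pairing_radius=0.5)
probe_map = {"red": ("geneA", "five_prime"), "ir": ("geneA", "internal"),
             "green": ("geneA", "three_prime")}
centroid = dapi_centroid(stack)
for m in molecules:
    classify_molecule_species(m, probe_map)
    localize_molecule(m, stack, centroid)
for m in molecules:
    print(m.species, m.location)
```

prints, for this seed, one line per recovered molecule:

```
intact cytoplasm
intact nucleus
five_prime_part nuclear_periphery
five_prime_part nuclear_periphery
intact cytoplasm
```

— exactly the five molecules the scene was built with: the two border
molecules land in the periphery band, the nuclear one deep in the nucleus
(>66.6 %DAPI), the cytoplasmic ones below 10 %DAPI.

The same flow is available from the shell:

```bash
nucfish run --seed 7 --out results/demo
nucfish enrich --seed 7 --out results/demo   # just one stage
```

which writes TSV tables (spots, molecules, counts, orientation, enrichment,
Q-rich scores, homology calls) plus a `manifest.json` capturing the config,
seed and file digests; re-running with the same seed reproduces the outputs
byte for byte.

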