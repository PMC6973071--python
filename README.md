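# g4kit

A toolkit for the structural analysis of G-quadruplex (G4) nucleic
acids from multi-model coordinate files:

* **Sugar pucker** — endocyclic torsions, pseudorotation phase/amplitude
  (cosine model), octant and envelope/twist classification.
* **Glycosidic conformation** — chi computation, syn / anti / high-anti
  classes, base planes, pseudo-hydrogen-bond screening to 2'-F/2'-OH
  acceptors.
* **Topology** — Hoogsteen tetrad detection as directed 4-cycles,
  stacking polarity (homopolar/heteropolar), G-column extraction with
  strand-inversion points, groove-width classes, loop classification
  (lateral / diagonal / propeller / V), and V-loop records including the
  backbone-turn locus (within the following tract vs. between the two
  linked residues).
* **Coupling inversion** — Karplus forward models of vicinal couplings
  (including ¹⁹F–¹H paths of 2'-fluoro sugars) and grid inversion of a
  coupling set to compatible (P, τm) regions.
* **Ensemble metrics** — Kabsch superposition, pairwise / to-mean
  ensemble RMSD, interproton distances (with geometric proton
  reconstruction), ring-proximity geometry, and a V-loop
  flanking-residue pucker survey.
* **Synthetic structures** — a generator that realizes declarative
  topology specifications (including zero-nucleotide V-loops) as
  coordinate files, so the entire analysis chain is testable without
  any external data. Shipped presets: `parallel`, `hybrid-ODN`,
  `vloop-ODN1415`, `vloop-typeB`.

## CLI

```sh
# generate a synthetic V-loop quadruplex (10 models, mild noise)
g4kit synth --preset vloop-ODN1415 --models 10 --noise-sd 0.2 --seed 1 \
      --out vloop.pdb --emit-spec vloop_spec.yaml

# full topology/conformer/pucker analysis (JSON report)
g4kit analyze vloop.pdb --out vloop_report.json

# invert a coupling table (TSV: path <TAB> J_Hz <TAB> sigma_Hz)
g4kit couplings couplings.tsv --k 1 --out fit.json --surface chisq.tsv

# pucker survey of V-loop flanking residues across several files
g4kit survey a.pdb b.pdb --out survey.tsv
```

Exit codes: `0` success, `1` usage or I/O error, `2` structure parsed
but no tetrad found. Geometric cutoffs (H-bond distances, base-plane
angle, groove thresholds) can be overridden with `--config cutoffs.yaml`.

## Conventions

* Endocyclic torsions: ν0 = C4'-O4'-C1'-C2' … ν4 = C3'-C4'-O4'-C1';
  forward model νj = τm·cos(P + 144°·(j−2)); dihedral signs follow
  IUPAC. Getting this indexing wrong shifts P by multiples of 72°.
* chi: O4'-C1'-N9-C4 (purines) / O4'-C1'-N1-C2 (pyrimidines);
  syn = [0°, +90°], high-anti = [−90°, 0°), anti = the rest.
* Stack orientation: "top" is the outer tetrad holding the 5'-most core
  guanine; a column runs "up" when its 5'→3' direction points from top
  to bottom.
* Groove widths use mean nearest-pair P–P distances between adjacent
  columns (core-linkage phosphates, measured perpendicular to the stack
  axis); default class thresholds are calibrated on the synthetic
  presets and configurable.
* Karplus parameter sets (coefficients + θ(ν) maps) are plain data
  files with provenance headers; see
  `src/g4kit/data/karplus_default.txt`.

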