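# sde2d

Simulation and quantification of two-dimensional strandness-dependent
electrophoresis (2D-SDE) of damaged DNA.

The first gel dimension separates native molecules by length, strandness and
damage-induced conformation; after in-gel heat denaturation the second
dimension separates single strands by length only — unless interstrand
crosslinks hold strands together. Analyzing a sample as a pair (undigested
vs. digested with a four-cutter that cleaves both ssDNA and dsDNA) turns the
resulting 2D pattern into a simultaneous readout of single- and double-strand
breaks, interstrand and intrastrand crosslinks, denatured ssDNA and
apoptotic fragmentation.

The package contains:

* **`sde2d.molecules`** — explicit DNA molecules (duplexes with per-strand
  nicks and lesions, strand segments, post-denaturation crosslink networks),
  damage operations (restriction digestion, nicking, double-strand breaks,
  crosslinker lesions, internucleosomal fragmentation), heat denaturation and
  a PCR-amplifiability oracle. FASTA input and JSON-lines serialization.
* **`sde2d.electrophoresis`** — a semi-log mobility model with limiting
  mobility, projection of populations to 2D gel coordinates, two-channel
  (stain + Cy5 marker) gel rendering with seeded noise, and ready-made
  experiment scenarios (clean, cisplatin-like crosslinking, nicking, DSB,
  apoptosis, PARP-inhibitor, heat-denaturation, interstrand-fraction sweep)
  that emit ground-truth mass fractions for every image.
* **`sde2d.quantify`** — Cy5 marker-band detection, monotone log-size
  calibration with extrapolation, the five diagnostic regions (unmigrated,
  dsDNA arc, behind-arc, front-of-arc, SSB streak) built from marker-band
  edges, background-corrected fraction percentages, region size
  distributions and prominence-based peak calling (apoptosis ladders).
* **`sde2d.comet`** — alkaline-comet image simulation with programmed tail
  fraction/length/crosslink retardation, and tail-moment scoring
  (tail moment = fraction of DNA in tail x tail length).
* **`sde2d.stats`** — classical pooled-variance two-sample t-tests,
  dose-response summaries with Spearman rank correlation, repair-experiment
  report compilation.
* **`sde2d.cli` / `sde2d.gelio`** — command line and file I/O (16-bit
  two-page TIFF gels, PNG previews and QC overlays, CSV/JSON/YAML).

## Command line

```sh
# simulate an undigested/digested gel pair with ground truth
sde2d simulate --scenario cisplatin --seed 1 --out runs/cisplatin

# quantify a rendered gel (marker detection -> calibration -> regions -> report)
sde2d quantify runs/cisplatin/digested.tif --out runs/cisplatin/quant

# simulate and score a comet batch
sde2d comet-score --n 100 --fraction 0.3 --seed 1 --out comets.csv

# repair statistics from replicate fraction percentages
sde2d report experiment.json --out report_out

# regenerate the full seeded fixture gallery
sde2d fixtures --out fixtures --seed 0
```

A YAML run configuration (`--config`) can set the scenario, seed, mobility
model overrides, ladder composition and image geometry; the effective
configuration is echoed next to the outputs for provenance. Outputs are
never overwritten without `--force`.

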