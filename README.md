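# danai

Contact-graph analysis of molecular-dynamics trajectories with
micro-interaction motif counting in the DANAI notation.

Given trajectory frames of a liquid of tagged two-carbon molecules (labels in
the DL_F style, e.g. `C180` = monohaloalkane carbon, `C182` = trihaloalkane
carbon), the package:

1. reads frames from a DL_POLY-style `HISTORY` text dialect (plain or gzip)
   or multi-frame XYZ (`danai.trajectory_io`);
2. extracts the tagged carbon interaction centers and builds, per frame, the
   global intermolecular contact graph under a minimum-image distance
   criterion (default 5 Å) (`danai.contact_graph`);
3. parses/serializes/canonicalizes DANAI statements such as
   `[J4]c182:c182(:c182):c182` — topology letter (`L` linear / `R` ring /
   `J` junction), colon = non-bonded contact, parenthesised branch species,
   uppercase = no contacts beyond those shown (`danai.notation`);
4. counts, per frame, the 20 built-in interaction modes (7 `ID_182_182`,
   7 `ID_180_180`, 6 `ID_180_182`) as a subgraph census with case semantics
   (`danai.motif_count`), cross-validated by an independent brute-force
   oracle (`danai.oracle`);
5. assembles count time series and computes means, deviations and the
   pairwise Pearson correlation matrix (`danai.stats`);
6. generates synthetic inputs — random dimer liquids at the study scale
   (1000 molecules, 53 Å cubic box) and planted-motif frames with exactly
   known census — so the whole pipeline is testable offline
   (`danai.synthetic_data`).

## CLI

```sh
# synthetic liquid in the HISTORY dialect
danai generate --n 1000 --box 53 --frames 5 --seed 1 --out HISTORY_synth

# per-frame mode counts (CSV column per DANAI statement)
danai analyze --traj HISTORY_synth --molecule-size 2 --cutoff 5.0 --out counts.csv

# means/deviations and the mode-mode correlation matrix
danai stats --counts counts.csv --summary summary.csv --correlation correlation.csv

# structured reading + canonical form of a statement
danai parse "[R3]c180:c182:c180:c180"
```

`analyze` accepts `--input-format xyz --cell-length <Å>` for XYZ input,
`--case-scope {global,macro}` and `--lowercase-mode {superset,exclusive}` for
the case-semantics variants, and `--config file` with `key = value` lines
(explicit flags win).

## Counting semantics (summary)

Counts are a subgraph census: each distinct node set / role assignment is
counted once, up to pattern automorphism (a triangle therefore also contains
three `[L3]` chains and three `[L2]` pairs). Closed forms for lowercase
single-species modes: `L2 = |E|`, `L3 = Σ C(deg,2)`, `J4 = Σ C(deg,3)`,
`J5 = Σ C(deg,4)` on the macro-class subgraph. Uppercase species require the
node's degree (full graph by default, macro subgraph with
`--case-scope macro`) to equal its in-pattern degree; lowercase species are
unconstrained by default (`superset`) or require at least one extra contact
(`exclusive`).
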