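# gpcrsel

Biophysical template selection for GPCR homology modeling.

G protein-coupled receptors (GPCRs) share a seven-transmembrane (7TM) helix
architecture but often show very low pairwise sequence identity, so picking a
homology-modeling template by identity alone is unreliable. `gpcrsel` ranks
candidate template structures for a query receptor by three biophysical
criteria instead:

- **Hydrophobicity correspondence (HC).** Each sequence gets a moving-window
  hydropathy profile on the Eisenberg consensus scale,
  `H_n = (1/w) Σ_{i=n−(w−1)/2}^{n+(w−1)/2} h_i` with window `w = 11`.
  Corresponding helices of target and template are aligned by tethering
  their Ballesteros–Weinstein X.50 center residues, and compared by the sum
  of squared profile differences over the paired positions,
  `SSD = Σ_n (H_template,n − H_target,n)²`, normalized per residue.
  A helix contributes `s_i = +2` when SSD/residue ≤ 0.1, else `−1`; the HC
  score is `S_h = Σ_{i=1}^{7} s_i ∈ {−7, −4, …, 14}`.
- **Binding-site residue similarity (BRS).** The 24 canonical class A
  orthosteric-pocket positions (3.28 … 7.42 in Ballesteros–Weinstein
  numbering) are extracted from both sequences and their residue pairs are
  scored with a substitution matrix; the sum is `S_b`. Any NCBI-format
  matrix file can be supplied (e.g. a transcription of the GPCRtm matrix,
  which is derived from GPCR transmembrane regions); the built-in default
  is BLOSUM62, and a unit (identity-count) matrix is packaged.
- **Resolution.** `S_r = 1` for structures at ≤ 2.5 Å, else 0; structures
  without a reported resolution score 0.

Candidates are combined as `S_t = S_h + S_b + S_r` and ranked by
`S_rank = S_hn + S_bn + S_r`, where `S_hn`, `S_bn` are min–max
normalizations of `S_h`, `S_b` over the candidate set. The tool also emits a
full-length target–template alignment (helices tethered at X.50, loops
joined by a deterministic centered-gap rule), global and per-TM sequence
identities, and hydrophobic moments / helical-wheel data per helix
(`μH = (1/w)·|Σ_j h_j·e^{i·j·100°}|`, maximized over 11-residue windows).

The intended users are structural bioinformaticians preparing GPCR homology
models (including for receptors with no close structural homolog, such as
olfactory receptors), who need a reproducible, scriptable way to shortlist
and document template choices.

## Inputs

- **Query**: a FASTA file plus a sidecar TSV giving the seven TM
  `(start, end, center)` triples (1-based inclusive; `center` is the X.50
  residue).
- **Registry**: a TSV with one row per PDB entry — receptor id/name/class,
  `pdb_id`, `resolution` (Å, empty when unreported), `state`
  (inactive/active/intermediate), `coverage` (%), the full sequence, and
  the 21 TM columns. `gpcrsel.write_fixture` generates a complete synthetic
  example.

## Worked example

Generate a synthetic 5-template registry (planted so that template `9T00`
matches the query's hydropathy structure and hotspot residues) and search:

```bash
python -c "from gpcrsel import FixtureSpec, write_fixture; \
           write_fixture(FixtureSpec(seed=2), 'demo')"
gpcrsel search --query demo/query.fasta --tm demo/query.tm.tsv \
               --registry demo/registry.tsv --out demo/out
```

`demo/out/ranked_top.tsv` (first columns):

```
rank  receptor_id  pdb_id  resolution  state     coverage  s_h  s_b  s_r  s_t  s_hn  s_bn      s_rank
1     R000         9T00    2.0         inactive  95.0      14   135  1    150  1.0   1.0       3.0
2     R001         9T01    2.3         inactive  92.0      11   122  1    134  0.75  0.796875  2.546875
3     R002         9T02    2.4         inactive  88.0      8    98   1    107  0.5   0.421875  1.921875
```

`9T00` attains the maximal HC score `S_h = 14` (all seven helices with
SSD/residue ≤ 0.1), the highest BRS score under the default BLOSUM62 matrix
(`S_b = 135` over 24 scored hotspot positions), and `S_r = 1` at 2.0 Å, so
it ranks first with the maximal `S_rank = 3`. Each decoy loses 3 points of
`S_h` per degraded helix. Per-pair Markdown reports
(`demo/out/report_9T00.md`, …) contain the score block, the per-helix HC
table, the hotspot comparison, hydrophobic moments, and the full-length
alignment in both annotated-text and FASTA form.

The SSD calculator compares any two sequences under user TM definitions,
with no registry:

```bash
gpcrsel ssd --target demo/query.fasta --target-tm demo/query.tm.tsv \
            --template demo/query.fasta --template-tm demo/query.tm.tsv
```

```
helix   n_paired  ssd       ssd_per_residue  s_i
TM1     30        0.000000  0.000000         +2
...
S_h     14
```

A sequence compared against itself has zero SSD on every helix and the
maximal `S_h = 14`.

`gpcrsel browse` scores every registry entry unfiltered (no per-receptor
deduplication) and adds global and per-TM identity columns for expert
inspection.

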