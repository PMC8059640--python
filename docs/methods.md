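# Methods

## Model and procedure

`gpcrsel` treats GPCR template selection as a scoring problem over
(query, candidate-structure) pairs. The method assumes that both sequences
carry a trustworthy seven-helix transmembrane (TM) annotation — seven
`(start, end, center)` triples where `center` is the residue numbered X.50
in the Ballesteros–Weinstein (BW) scheme. TM annotations are consumed as
data (e.g. from a structure-derived multiple alignment of the GPCR family);
the package performs no TM prediction.

The pipeline, in execution order:

1. **Registry load and filtering.** Candidates are rows of a TSV registry
   (one per PDB entry, sequence and TM definition inline). Search mode can
   filter by conformational state, resolution (≤ cutoff, inclusive;
   entries without a reported resolution are excluded whenever a resolution
   filter is active), and coverage (strictly greater than the cutoff — a
   structure resolving exactly 75% of its receptor fails a 75% filter).
   Search mode additionally keeps only the best PDB entry per receptor
   (lowest resolution, then highest coverage, then lexicographic PDB id);
   browse mode scores everything.
2. **Helix tethering.** For each helix k, target and template helices are
   aligned gaplessly by placing the two X.50 residues opposite each other
   and pairing outward by equal offset. The pair count is
   `min(left arms) + min(right arms) + 1`; residues beyond the shorter arm
   are overhangs and take no part in SSD scoring (SSD needs two profile
   values per position; overhang columns are gapped in the full alignment
   and flagged by their TM annotation).
3. **Hydropathy correspondence.** Profiles are window means of per-residue
   Eisenberg-consensus hydrophobicities. SSD is summed over paired
   positions and normalized per residue; each helix contributes +2
   (SSD/residue ≤ 0.1) or −1, summing to `S_h`.
4. **Hotspot similarity.** The 24 canonical class A orthosteric positions
   are resolved by BW arithmetic (`index = center_k + NN − 50`). Labels may
   legitimately resolve outside the annotated helix span (7.31 typically
   precedes the TM7 annotation) — only positions outside the sequence are
   missing. Missing positions are excluded from the sum and the count of
   scored positions is reported. The residue pairs are scored with a
   symmetric substitution matrix to give `S_b`.
5. **Combination and ranking.** `S_t = S_h + S_b + S_r` and
   `S_rank = S_hn + S_bn + S_r` with min–max normalization of `S_h`, `S_b`
   over the ranked set. Ordering is by `S_rank` descending with the
   tie-break chain (`S_b` desc, resolution asc with absent last, PDB id);
   the chain is a deterministic convention, recorded in output.
6. **Reporting.** Ranked TSV tables with a fixed column order, per-pair
   Markdown reports, a full-length FASTA alignment, and profile/wheel TSVs;
   PNG plots are optional and off by default. Everything is deterministic:
   reruns are byte-identical.

## Parameters

| parameter | default | meaning |
|---|---|---|
| window | 11 residues | hydropathy / moment window; the classic TM-detection length |
| scale | Eisenberg consensus | per-residue hydrophobicities (dimensionless consensus units) |
| SSD/residue boundary | 0.1 (units²) | helix "good correspondence" threshold; the boundary value scores +2, strictly greater scores −1 |
| resolution cutoff | 2.5 Å | inclusive boundary for `S_r = 1` |
| coverage cutoff | 75% (exclusive) | completeness shortlist rule |
| substitution matrix | BLOSUM62 | hotspot pair scoring; any NCBI-format file loadable (`--matrix`), unit matrix packaged |
| helix twist δ | 100°/residue | ideal α-helix angle for moments and wheels |
| top k | 3 | templates reported in search mode |

Two methodological details are genuinely underdetermined and are exposed as
flags, recorded in every report:

- **Edge windows** (`--edge-mode`, default `extend`): profiles are computed
  on the full-length sequence and sliced to helices, so helix-edge windows
  average over genuine flanking loop residues (standard hydropathy-plot
  practice). `truncate` computes each helix in isolation. At sequence
  termini the window truncates and the divisor is the actual window size.
- **SSD divisor** (`--ssd-divisor`, default `paired`): the per-residue
  normalization divides by the number of paired positions; "helix length"
  is ambiguous when target and template helices differ, so `target` and
  `template` helix-length divisors are also available.

Other conventions: all coordinates are 1-based inclusive; non-standard
residue codes (X, B, Z, U) take the scale mean for hydropathy (logged) and
score 0 in any substitution matrix, so engineered construct artifacts do
not abort or dominate a comparison; a degenerate normalization set
(max = min) maps every candidate to 1.0, preserving the "all equally best"
reading.

Global sequence identity (browse columns and reports) uses a global
Needleman–Wunsch alignment with BLOSUM62 and affine gaps (open 11,
extend 1), counting identities over aligned columns. This is a stand-alone
approximation of BLAST-style identity without an external binary and is
labeled as such in output; per-TM identity is counted over tethered pairs
only.

## Synthetic data

`gpcrsel.fixtures` generates GPCR-like sequences with a piecewise-constant
windowed-hydropathy target: hydrophobic helices (defaults 0.60–0.95
consensus units, the range typical of TM window means), mildly hydrophilic
loops (−0.4), geometry of 25–35-residue helices with mid-helix X.50
anchors. Residues are drawn from the scale-adjacent pair bracketing each
region's target and interleaved evenly with a seeded random phase, then
swap-repaired; every window fully inside a region lands within ±0.05 of
the target (hotspot positions are overwritten afterwards with the demanded
residues, which perturbs nearby windows equally in any two sequences built
with the same hotspot assignment, so pairwise SSDs are unaffected).
Registries plant one template sharing the query's targets and hotspots
among decoys degraded by −0.5 units on a growing number of helices and
3 mutations per step among the hotspot residues (mutations chosen
hydropathy-conservative so they change identity, not profile); a
ground-truth table records the intended `S_h` and identity-matrix `S_b`
per template.

What the generator does **not** emulate: real amino-acid composition and
correlation structure, family-conserved motifs, chimeric/fusion construct
artifacts, loop-length diversity, or any relationship between sequence and
actual 3D structure. Passing tests therefore demonstrate the correctness of
the scoring machinery and the recoverability of planted hydropathy/hotspot
structure — not that the ranking picks the template that yields the best
homology model for a real receptor.

## Numerical choices

- SSD thresholding compares the computed double against 0.1 exactly;
  profile arithmetic uses cumulative sums (error ~1e−16 per window).
- Moments evaluate `|Σ h_j e^{i·j·δ}| / w` per window; the maximal window
  resolves ties leftmost; angles are reported in [0, 360).
- Tests use absolute tolerance 1e−9 for floating comparisons.
- Degenerate inputs: single-residue helices tether to exactly one pair;
  a helix shorter than the window uses the whole helix as one moment
  window; empty filter results are a documented empty-result status
  (CLI exit code 3), not an error.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
registries of 5 templates with ~280-residue receptors; property batteries
use 200 random sequences/pairs and planted-recovery runs 20 independently
seeded registries. These sizes exercise every code path (all seven helices,
all 24 hotspot labels, both edge modes, all divisors) while keeping the
whole suite in the seconds range.

## External reference data

Reproducing published benchmark pair scores for real receptors requires
inputs that cannot be bundled: the receptor sequences, their
structure-derived TM definitions, and the GPCRtm substitution matrix
transcribed from its publication. Users with access can drop
`registry.tsv`, `pairs.tsv` (`target_receptor_id`, `template_pdb_id`,
`expected_s_t`) and `gpcrtm.txt` into `tests/data/external/`; the
acceptance test then checks agreement under every edge-mode × divisor flag
combination. Until then that test reports the missing data as a failure
rather than silently skipping.

## Known limitations

- `S_rank` depends on the normalization population; reports record which
  candidate set was used, but rankings from different filter settings are
  not comparable number-for-number. Orderings by `S_t` and `S_rank` can
  legitimately differ when candidates trade resolution points against raw
  component scores.
- BLOSUM62 is a general-purpose default; hotspot similarity is better
  served by a TM-specific matrix (supply one via `--matrix`).
- The loop/terminus centered-gap rule is a deterministic convenience;
  loop regions of a real modeling alignment should be adjusted manually.
- The method ranks structures by biophysical correspondence only; ligand
  similarity, mutagenesis data, and model validation are out of scope.
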