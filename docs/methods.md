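# Methods

## The screen

During translation initiation the assembled ribosome covers the mRNA up to
roughly nucleotide +15..+17 downstream of the start codon (the classical
toe-print position, with the A of the AUG numbered +1). A stable RNA
secondary structure beginning immediately past that edge can stall the
scanning pre-initiation complex directly over the AUG and thereby assist
start-codon selection. `startscreen` looks for coding sequences that could
use this mechanism by folding, for every CDS of a species, the 50-nt window
spanning positions +16..+65, and asking whether that window folds much more
stably than its own shuffled composition.

The per-window statistic is

    ratio = MFE_struc / mean(MFE_rand)

where `MFE_struc` is the minimum free energy (kcal/mol) of the native
window and `MFE_rand` is the MFE of a mononucleotide shuffle of the same
window, averaged over `n_shuffles = 100` independent permutations. Both
energies are ≤ 0, so the ratio is ≥ 0; values well above 1 mean the native
ordering is far more stable than its composition predicts. Selection is
two-staged:

1. **Ratio filter** — keep windows with `ratio ≥ 2` (inclusive).
2. **Quantile filter** — keep, among those, windows whose `MFE_struc` is
   equal to or below the species-level empirical 0.25 quantile (linear
   interpolation) of the `MFE_struc` distribution of all folded windows of
   that species, so that only the most stable quartile of structures
   survives.

Both boundaries are inclusive; ties at the quantile threshold are kept.
The quantile population is a genuinely open design point: restricting it to
ratio-passed windows makes the selected set, by construction, about a
quarter of the ratio survivors regardless of how many true structures exist.
We compute the quantile over **all** folded windows by default (the more
literal reading of "all structures of a given species"), which lets every
strongly structured, ratio-passing window through; the alternative
population is available as `quantile_population="ratio_passed"`.

A selected window whose structure string contains at least 8 quadruplex
`'+'` characters (two stacked G-quartets, the smallest quadruplex the
engine emits) is additionally classified as a G-quadruplex candidate and
histogrammed by its exact engaged-G count.

## Folding engines

Two engines satisfy one contract (dot-bracket string over `.()+`, energy in
kcal/mol, ≤ 0, exactly 0 for a fully unpaired quadruplex-free window):

**`thermodynamic_gquad`** wraps the ViennaRNA MFE folder (Python bindings)
with G-quadruplex prediction enabled. ViennaRNA ≥ 2.6 prints the 3′-most
quadruplex G as `~`; the adapter rewrites it to `+` so the `+` count equals
the number of engaged guanines (4 × layers for a regular quadruplex), which
is the convention the rest of the package counts on. Energies are rounded
to two decimals on ingest; one-decimal rounding happens only in report
writers, never in comparisons. The engine name and version are recorded in
every `FoldResult`; no temperature default is imposed beyond the engine's
own (37 °C).

**`nussinov_oracle`** is a built-in exact dynamic program used for hermetic
testing of every downstream stage. It minimises

    E = pair_score · n_pairs + helix_penalty · n_helices

with `pair_score = −1`, a minimum hairpin loop of 3 nt, and Watson–Crick
plus GU wobble pairs. A helix is a maximal stack of pairs; `helix_penalty`
is charged once per helix. With the default `helix_penalty = 0` this is
plain Nussinov base-pair maximization (and the energy is exactly
−max_pairs). That plain form, however, is useless for the shuffle-ratio
statistic: the attainable pair count of a 50-mer is dominated by its
nucleotide composition, which shuffling preserves, so native and shuffled
windows score within a few percent of each other even when a perfect 20-bp
stem is present (measured ratio ≈ 1.16). Real thermodynamic models
discriminate because every loop costs initiation energy. The screening
default therefore uses `helix_penalty = 2.0` — loop initiation of about
twice a pair's magnitude, the same order as the nearest-neighbor
parameters' ratio of loop penalty (≈ +3..+4 kcal/mol) to stack gain
(≈ −2 kcal/mol). Under this model a helix only pays off from three pairs
up, planted 20-bp stems score ratios of 2.2–2.7, and i.i.d. background
windows concentrate near ratio 0.9–1.0.

Traceback tie-breaks are fixed (pairing preferred over leaving the 5′ base
unpaired; smallest admissible partner; stacked continuation preferred
inside a helix), so structures are deterministic. The DP fill is
JIT-compiled with numba when available, with an identical pure-Python
fallback.

## Null model and reproducibility

Shuffles are plain Fisher–Yates permutations of the window (mononucleotide
shuffling — "mixing the nucleotides"); a dinucleotide-preserving Euler-walk
shuffle is available for sensitivity analysis but is not the default, since
the selection statistic is defined against the mononucleotide null. Each
window's RNG stream is derived from `(global seed, CRC32(window id))`, so
results are independent of processing order and fully reproducible:
identical inputs, configuration and seed give byte-identical output files.

Zero-energy corner cases: a native window with `MFE_struc = 0` gets ratio 0
and can never be selected; a structured native window whose shuffles all
score 0 gets ratio +∞ and passes any threshold.

## Synthetic species

The generator emulates an NCBI `*_cds_from_genomic.fna` download: records
named `lcl|...` with bracketed `[gene=...] [protein_id=...]` tags, an
optional number tagged `[pseudo=true]`. Background CDSs are `AUG` followed
by i.i.d. nucleotides at a target GC (default 0.5, 150 nt records); stop
codons are not excluded, since the screen is purely nucleotide-level.
Planted hairpins are a random stem S, loop, and reverse complement of S
placed at +16 (default 20 bp stem, 6 nt loop: the whole 46-nt hairpin sits
inside the window). Planted quadruplex motifs are four G-runs of
`layers` Gs joined by A/U linkers; linkers default to 1 nt because a
two-layer quadruplex is only thermodynamically competitive with loops of
1–2 nt, and A/U linkers keep the planted Gs out of competing Watson–Crick
pairs. Planting truth (kind, coordinates, expected engaged-G count) is
written to a sidecar TSV, never to FASTA headers, so the pipeline cannot
see it.

What the generator does **not** emulate: codon usage, realistic length and
GC heterogeneity, organellar contamination, isoform redundancy, or
imperfect/bulged natural stems. Passing the recovery and calibration tests
therefore shows that the statistic and plumbing behave as designed on
clean planted signal, not that any particular genome contains a given
number of structures.

## Numerical and policy choices

- Coordinates are 1-based inclusive, +1 = first CDS nucleotide; output
  files state this in their headers.
- Start-codon identity is not enforced (bacterial GUG/UUG starts); non-AUG
  starts are counted as warnings only.
- Records shorter than 65 nt, tagged pseudo, or containing non-ACGU
  characters are quarantined with reason codes (TOO_SHORT, PSEUDO,
  BAD_ALPHABET); filtering never aborts a run.
- "Non-nuclear" exclusion is provenance-based: the caller supplies nuclear
  CDS files; no sequence-based organelle detection is attempted.
- Isoforms are screened per record; `--dedupe-window` optionally collapses
  records with identical 50-nt windows and reports the duplicates.
- The empirical quantile uses linear interpolation (numpy's default).
- GO terms are ranked by the number of distinct selected CDSs carrying the
  term (reviewed Swiss-Prot annotations override unreviewed TrEMBL ones on
  conflict); no GO-graph propagation and no formal enrichment statistic is
  applied.
- Percentages are reported to two decimals, energies to one (reports only).

## Problem sizes

The bundled checks run the screen at its standard operating point
(100 shuffles per window) on synthetic species of 100 CDSs, calibrate the
null on 1,000 background windows, and verify the oracle against exhaustive
structure enumeration on 500 sequences of length ≤ 12 — sizes at which the
exact enumeration oracle and the full pipeline both complete in seconds to
a couple of minutes on one core. Genome-scale inputs (10⁴–10⁵ CDSs) are
supported through the same `screen` entry point; runtime scales linearly in
the number of windows × shuffles.

## Known limitations

- The oracle's helix penalty is a single constant; it reproduces the
  qualitative behaviour of thermodynamic folding (loop cost, stack gain)
  but not its energies. Absolute MFE values are only comparable within one
  engine.
- Windows containing any non-ACGU character are rejected rather than
  folded with wildcards; folding semantics for N are undefined here.
- The ratio statistic is insensitive for low-complexity windows (shuffling
  a repeat barely changes it); such windows can pass the filter. The screen
  deliberately favours stringency over completeness.
- G-quadruplex detection is exactly what the folding engine predicts; no
  sequence-motif scoring (G4Hunter-style) is applied.
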