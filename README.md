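# startscreen

Screen coding sequences for stable RNA secondary structures — including
G-quadruplexes — in the 50-nt window from +16 to +65 downstream of the
start codon (the A of the AUG is +1).

A ribosome positioned over the AUG covers the mRNA up to about +15..+17
(its toe-print). A stable structure that begins right past that edge can
stall the scanning pre-initiation complex on the start codon and enhance
initiation. This package finds, genome-wide, the CDSs that carry such
structures: candidates for structure-assisted start-codon selection. It is
aimed at RNA and translation researchers who have a species' CDS FASTA
(NCBI `*_cds_from_genomic.fna` dialect) and want a ranked, reproducible
candidate list.

## Method

For each CDS (pseudogene-tagged, short and non-ACGU records are filtered
out with explicit reason codes), the +16..+65 window is folded to obtain
its minimum free energy MFE_struc. The same window is then shuffled 100
times (mononucleotide permutations, composition conserved exactly) and
each shuffle is folded, giving mean MFE_rand. The selection statistic is

```
ratio = MFE_struc / mean(MFE_rand)
```

A window is selected when (1) `ratio ≥ 2` — the native ordering is at
least twice as stable as its composition predicts — and (2) its MFE_struc
lies at or below the species-level 0.25 quantile of all window MFEs, i.e.
it belongs to the most stable quartile. Guanines engaged in predicted
G-quadruplexes appear as `+` in the structure string; a selected window
with ≥ 8 engaged Gs (two stacked G-quartets) is classified as a
G-quadruplex candidate. Per-species reports include counts, percentages,
pooled GC content of the analyzed CDSs, the quantile threshold, and the
exact engaged-G histogram.

Folding engines: the ViennaRNA MFE folder with G-quadruplex prediction
(`--engine thermo`, the default), or a built-in exact dynamic-programming
folder (`--engine oracle`) that needs no external engine — useful for
hermetic testing and method studies. See `docs/methods.md` for the model
details and design choices.

## Worked example

Generate a synthetic species (60 CDSs; 6 planted 20-bp hairpins and 3
planted two-layer quadruplexes at +16; 2 pseudogene-tagged records), then
screen it:

```
$ startscreen fixture --out-fasta species.fna --out-truth truth.tsv \
      --n-cds 60 --stems 6 --gquads 3 --pseudo 2 --seed 42
$ startscreen screen --cds species.fna --species-label demo_species \
      --engine thermo --seed 7 --out out
demo_species: 58 CDS analyzed, 8 selected (13.79%), 2 with G-quadruplexes; outputs in out
$ startscreen report out/summary.json
gc_percent_cds: 50.0
gquad_histogram: {'8': 2}
mfe_quantile_threshold: -14.4
n_cds_analyzed: 58
n_gquad_selected: 2
n_selected: 8
percent_gquad: 3.45
percent_selected: 13.79
species: demo_species
top_quartile_min_mfe: -42.0
```

Reading the numbers: the two pseudogene records were filtered (58 of 60
analyzed). Eight windows passed both filters — the six planted hairpins
plus two of the three planted quadruplexes (the third scored ratio 1.68,
just under the threshold: quadruplex windows shuffle into partially
structured decoys, and the screen is deliberately stringent). The
strongest selected structure reaches −42.0 kcal/mol; the quartile
threshold for this species is −14.4 kcal/mol; both quadruplex candidates
engage exactly 8 Gs. `out/records.tsv` has the per-CDS detail (window
sequence, dot-bracket structure, MFE_struc, mean MFE_rand, ratio, flags),
`out/structures.txt` the selected structures in text form, and
`out/rejected.tsv` the filtered records with reasons.

The same run is available as a library:

```python
from startscreen import RunConfig, run_screen
result = run_screen(RunConfig(cds_paths=["species.fna"], species="demo", seed=7))
print(result.summary.n_selected)
```

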