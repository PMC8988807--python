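# ssmnet

Blank-aware MS/MS molecular networking for untargeted LC–MS/MS
metabolomics, built for "one strain, many compounds" (OSMAC) experiments in
which a microbial strain is grown under several culture media or chemical
elicitors and the question is *which compound families appear, and under
which conditions*.

## What it does

Given MS/MS spectra (MGF, one file per sample) and a sample manifest that
labels each sample as a culture sample (`SAMPLE`), a chromatographic blank
injection (`BLANK`) or an uninoculated culture-medium extract (`BED`),
`ssmnet`:

1. **Clusters** spectra into consensus nodes (single linkage over
   co-eluting spectra with matching precursor m/z and cosine ≥ 0.6), with
   per-sample MS1-area and count tables.
2. **Builds the IVAMN** (ionization-variant annotation molecular network):
   nodes that co-elute and whose m/z values are explained as ionization
   variants of one neutral mass M — `[M+H]+`, `[M+Na]+`, `[M+NH4]+`, the
   M+1 isotopologue, `[2M+H]+` — are linked, partitioning the nodes into
   per-compound variant groups.
3. **Removes contaminants**: every node detected in a BLANK sample is
   discarded *together with its first IVAMN neighbors*, so adducts and
   isotopologues of a contaminant fall with it.
4. **Selects protonated representatives**: one `[M+H]+` node per variant
   group carries the compound forward.
5. **Builds the SSMN** (spectra-similarity molecular network) over the
   representatives using the modified cosine

   cos(A, B) = Σ<sub>(i,j) ∈ 𝓜</sub> w<sub>A,i</sub> · w<sub>B,j</sub>,  w<sub>X,k</sub> = √I<sub>X,k</sub> / ‖√I<sub>X</sub>‖₂

   where the one-to-one alignment 𝓜 admits fragment pairs matching
   directly (|Δm/z| ≤ 0.025 Da) or offset by the precursor mass difference.
   Edges require cosine ≥ 0.6 and ≥ 4 matched peaks; topology filters then
   enforce a maximum node degree of 15 and a maximum connected-component
   size of 200, and media-background (BED) nodes and singletons are pruned.
   Structurally related compounds (congeners differing by e.g. 2H or C4H8)
   end up in one component.
6. **Compares conditions**: per-node areas normalised by row maximum, a
   node × node cosine matrix of detection profiles (the clustered heat-map
   input), and per-condition fold changes with up/down/unchanged flags.
7. **Extracts ion chromatograms** (EIC, ± 0.01 Da windows) for target m/z
   values from MS1 peak tables.

A seeded synthetic-experiment generator (`ssmnet.synthetic`) plants
ground-truth compound families — including an epoxyketone-peptide-like
family with congeners at m/z 401.26, 399.25, 345.20 and 343.19 and a
stereoisomer pair at 6.6/7.4 min — plus contaminants, media ions and
condition effects, so the whole pipeline is testable offline, end to end.

## Worked example

```bash
ssmn generate --seed 42 --out experiment   # synthetic bundle + ground truth
ssmn network --manifest experiment/manifest.csv --out run
```

prints the per-stage counts of the run (also in `run/run_log.json`):

```json
{
  "spectra_read": 744,
  "spectra_in_range": 744,
  "nodes_clustered": 90,
  "ivamn_edges": 97,
  "nodes_post_blank_removal": 82,
  "protonated_representatives": 28,
  "ssmn_nodes_raw": 28,
  "ssmn_edges_raw": 39,
  "ssmn_nodes_final": 25,
  "ssmn_edges_final": 39
}
```

Reading: 744 MS/MS spectra from 12 samples collapse into 90 nodes; 97
IVAMN edges group them into variant families; blank removal discards 8
contaminant-derived nodes (the 3 planted contaminants plus their adduct
and isotopologue nodes), leaving 82; one `[M+H]+` representative per
variant group gives 28 compound nodes; the SSMN connects 39 pairs with
cosine ≥ 0.6, and pruning the 3 media-background nodes leaves 25 nodes —
the 25 planted compounds, with each planted family in its own component
(`run/ssmn_components.csv`). `run/fold_change.csv` flags the
epoxyketone-like family "down" outside medium A1 and the decoy families
"up" in their preferred media, and `run/eic_401.26.csv` shows the two
stereoisomer apexes at 6.6 and 7.4 min:

```bash
ssmn recover --bundle experiment --out run2   # ground-truth recovery metrics
ssmn eic --ms1 experiment/ms1.csv --mz 401.26 --tol 0.01 --out eic.csv
```

## Layout

- `src/ssmnet/spectra_io.py` — MGF + manifest I/O, scan-range filter
- `src/ssmnet/mass_calc.py` — formula masses, adduct rules, EICs
- `src/ssmnet/similarity.py` — (modified) cosine, exhaustive oracle, library match
- `src/ssmnet/node_builder.py` — spectra clustering, consensus, count tables
- `src/ssmnet/ivamn.py` — variant network, blank removal, representatives
- `src/ssmnet/ssmn.py` — similarity network + topology filters
- `src/ssmnet/differential.py` — normalisation, profile similarity, fold changes
- `src/ssmnet/synthetic.py` — ground-truth experiment generator, recovery scoring
- `src/ssmnet/pipeline.py`, `src/ssmnet/cli.py` — orchestration and the `ssmn` CLI

See `docs/methods.md` for the model, parameter defaults and limitations.
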