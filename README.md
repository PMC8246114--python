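# enzymatic-reaction-transformer (`ert`)

Predicting the products of enzyme-catalyzed reactions — including their
stereochemistry — from the substrate structure plus a plain-text
description of the enzyme ("Candida antarctica lipase B", "ketoreductase
from Lactobacillus kefir glucose dehydrogenase", ...).

The package is aimed at cheminformatics practitioners working on
biocatalysis: it implements the full pipeline behind a multi-task
"enzymatic transformer" — corpus curation, mixed SMILES/natural-language
tokenization, transfer-learning training regimes, beam-search decoding
with confidence scores, and the complete evaluation suite — together
with a synthetic benchmark generator so every stage can be exercised and
validated on one CPU without licensed data.

## The model

A sequence-to-sequence transformer reads

```
substrate SMILES tokens  [SEP]  BPE tokens of the enzyme sentence
```

and writes product SMILES tokens. SMILES are tokenized atomically (one
token per character, except `Cl`/`Br`, bracketed atoms and `%NN` ring
closures); enzyme sentences are lowercased and byte-pair encoded with a
top-K-truncated vocabulary; both token sets share one combined
vocabulary with disjoint id ranges. Training follows the noam schedule
`lr(s) = base_lr · d^-1/2 · min(s^-1/2, s·w^-3/2)` with Adam, and one of
three regimes:

* **single** — one corpus;
* **STL** — pretrain on general chemistry, fine-tune on enzymatic data;
* **MTL** — joint training on a weighted corpus mixture (reference
  weighting 1:9 enzymatic:general; per cycle of `Σw` batches, corpus *i*
  contributes exactly `w_i`).

Decoding is beam search; each hypothesis carries the product of its
token probabilities as a confidence score. A prediction is *correct*
when its canonical SMILES equals the canonical reference exactly,
stereo annotations included. See `docs/methods.md` for the complete
account.

## Worked example

Generate a synthetic enzymatic corpus and inspect its structure:

```bash
ert synth --n-reactions 200 --seed 9 --out demo/
ert stats --corpus demo/enzymatic.tsv
```

```
{"enzymatic": 200, "general": 1000, "no_text_ceiling": 0.5}
{
  "n_records": 200,
  "ase_count_table": [
    {"ase_count": 1, "n_reactions": 166},
    {"ase_count": 2, "n_reactions": 34}
  ],
  ...
  "enantioselective_fraction": 0.5
}
```

166/200 sentences name a single enzyme and 34 add a second
(cofactor-regeneration) enzyme name; half of all records create a
stereocenter that only the sentence can disambiguate, so a text-blind
model cannot exceed 50% stereo-exact accuracy on that half
(`no_text_ceiling`).

Running the bundled benchmark matrix (about six minutes per seed on one
CPU core) trains a no-text and a full-sentence multi-task model on
~5000 enzymatic + ~25000 general reactions and evaluates the held-out
product-grouped test set:

```python
from ert.experiment import benchmark_run_config, run_experiment

result = run_experiment(benchmark_run_config(seed=11))
for cell, report in result.reports.items():
    print(cell, round(report.top1_accuracy, 3))
```

```
no_text/mtl 0.267
full_sentence/mtl 0.477
full_sentence/mtl/scrambled 0.117
```

Reading: with enzyme sentences the model writes the exact
stereo-correct product for 48% of unseen test products; without any
enzyme text it manages 27%; and feeding the *wrong* sentences
(deranged between test reactions) collapses accuracy to 12% — the
model genuinely reads the enzyme description rather than ignoring it.
`result.calibration[...]` adds equal-frequency confidence bins whose
true-prediction fraction rises from the bottom to the top bin, so the
confidence score can be used to decide which predictions are worth
taking to the bench.

The same matrix is available from the shell:

```bash
ert experiment --seed 11 --out runs/demo
```

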