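# ubilys

Window-based prediction of protein **ubiquitylation sites** — the lysines
(K) to which ubiquitin is conjugated by the E1→E2→E3 enzyme cascade.
Because substrate specificity comes from E3 ligases that contact the
substrate well away from the modified lysine, the discriminative sequence
signal is not confined to the immediate neighbourhood of the site: this
package is built around wide (−20…+20) windows, a per-feature
discrimination statistic that localises signal by window offset, and a
radial basis function network classifier solved exactly.

## What it does

Given protein sequences (FASTA), labelled lysine sites (TSV), and optional
per-residue profiles (PSSM evolutionary scores, percent solvent
accessibility, H/E/C secondary structure), `ubilys`:

* extracts (2n+1)-mer windows centred on candidate lysines (default 41-mer),
  padding past the termini with a dedicated terminal symbol;
* removes redundant training fragments: proteins with >30% local-alignment
  identity (BLOSUM62, affine gaps) are homologs, and identical windows
  between homologs keep a single representative;
* encodes windows into block-structured feature vectors —
  amino-acid composition (20), adjacent-pair composition (400),
  min–max-normalised BLOSUM62 rows with a terminal flag (21·(2n+1)),
  a pooled 400-dimensional PSSM transform, scaled accessibility (2n+1)
  and one-hot secondary structure (3·(2n+1));
* ranks features with the F-score statistic

      F = [(x̄⁺ − x̄)² + (x̄⁻ − x̄)²] / (s⁺² + s⁻²),

  the ratio of squared class-mean deviations from the grand mean to the
  sum of within-class sample variances, and aggregates it per window
  offset to map where along the window the classes differ;
* classifies with an all-centres Gaussian RBF network,

      y_j(x) = Σ_i w_ji · exp(−‖x − m_i‖² / (2σ²)),   σ = 5,

  whose output weights solve (Φ + λI)W = Y in closed form against one-hot
  class targets (λ = 1e−8 by default; λ = 0 interpolates exactly);
* evaluates by stratified k-fold cross-validation with pooled
  Pr/Sn/Sp/Acc, a window-length sweep, and feature-set comparison;
* generates a fully synthetic proteome — sequences, site labels, PSSM, ASA
  and secondary-structure profiles — with class signal planted at chosen
  window offsets, so the entire method is exercisable and testable without
  any external database.

## Worked example

```bash
python examples/01_simulate_and_scan.py
```

```
proteins: 350
sites: 300 positive / 1200 negative
top-5 discriminative offsets: [17, 13, -16, -10, -8]
planted offsets:             [-16, -10, 13, 17]
  offset +17: aggregate F-score 1.033
  offset +13: aggregate F-score 0.925
  offset -16: aggregate F-score 0.915
  offset -10: aggregate F-score 0.810
  offset  -8: aggregate F-score 0.045
```

The generator planted acidic-residue enrichment at four offsets far from
the central lysine; the positional F-score scan ranks exactly those four
at the top, an order of magnitude above the background (offset −8).

```bash
python examples/03_window_sweep.py
```

```
distant signal:
 window  n    Sn    Sp   Acc
     11  5 0.140 0.826 0.689
     21 10 0.507 0.912 0.831
     31 15 0.667 0.938 0.884
     41 20 0.837 0.978 0.950
```

With signal placed only beyond ±5 of the site, an 11-mer model cannot see
it (accuracy 69%, below the 80% majority rate); widening the window to
41-mer recovers it (95%). On the proximal-signal control the sweep is flat
(see the example output) — the improvement is attributable to the distant
positions, not to window size per se.

Other examples: `02_crossval.py` (pooled five-fold metrics of the 41-mer
BLOSUM model), `04_feature_comparison.py` (one model per encoding under
shared folds).

## Command line

Every stage is also a subcommand of the `ubilys` executable:

```bash
ubilys simulate --seed 1 --out-dir data/
ubilys featurize --data-dir data/ --blocks blosum --window 41 --out X.tsv
ubilys crossval --features X.tsv --k 5 --seed 17 --out cv.json
ubilys fscan --data-dir data/ --channel composition --window 41 --out scan.tsv
ubilys run --seed 1 --out-dir run/      # full pipeline with stage skipping
```

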