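# Methods

This note records the models, parameter choices and numerical conventions
behind chimeranet, and what the synthetic experiments do and do not show.

## Chimera construction

A chimera is `miRNA + site (+ pad)`, all written 5'→3', fixed at 110 nt.
The concatenation order (miRNA first) and the 3' placement of the pad are
conventions of this package; both are applied consistently at training and
inference so the classifier never sees a layout it was not trained on.
Over-length combinations (miRNA + site > 110 nt) are rejected, mirroring
the curation rule used for real chimera datasets.

Pads are drawn i.i.d. uniform over {A,U,G,C} and rejected wholesale until
no pad window of length ≥ 4 is the reverse complement of any miRNA window
(Watson–Crick only; G·U wobble can be included via a flag but is off by
default — the pad rule is about avoiding decoy *binding sites*, for which
the strict reading of contiguous pairing is the conservative choice). The
retry cap is 10,000 attempts; for a 21-nt miRNA the acceptance rate of
random pads is high and the cap is never approached in practice.

Pseudo-negative chimeras take sites of exactly `110 − len(miRNA)` nt from
annotated transcript regions at a 3'UTR:5'UTR:ORF ratio of 7:2:1
(largest-remainder apportionment when the requested count is not divisible),
excluding any (miRNA, gene) pair on a caller-supplied forbidden list. A
consequence faithfully reproduced from this construction: positives may
carry pads, generated negatives never do. This is a potential shortcut
feature; the pad's anti-complementarity constraint makes it weak, but
users auditing shortcut learning can shorten and pad negatives identically
through the builder API.

## One-hot encoding

Fixed column order A, U, G, C; one channel per base; DNA input (T) is
mapped to U on read. Ambiguity codes are rejected rather than encoded —
the 4-channel input has no representation for them, and silently mapping
N to a vector would inject phantom signal.

## The network

| block | layers | output length |
|---|---|---|
| 1 | conv(16, k=2, ReLU) + maxpool(2) | 110 → 55 |
| 2 | conv(32, k=3, ReLU) + maxpool(2) | 55 → 28 |
| 3 | conv(64, k=4, ReLU) + maxpool(2) | 28 → 14 |
| 4 | conv(128, k=5, ReLU) + maxpool(2) | 14 → 7 |
| head | flatten (896) → dropout(0.5) → dense(128, ReLU, L2) → dropout(0.3) → dense(1, sigmoid) | |

166,001 trainable parameters. Two conventions are forced by the parameter
and shape accounting: convolutions are length-preserving ("same" padding,
asymmetric for even kernels — extra position on the right), and pooling
uses the ceiling convention `L → ceil(L/2)` (the trailing partial window
is kept), since 55 → 28 is only consistent with ceil.

The implementation is plain NumPy: im2col convolutions, argmax-routed
pooling gradients, inverted dropout, Glorot-uniform initialization, Adam
(α = 1e-3, β₁ = 0.9, β₂ = 0.999, ε = 1e-8), mini-batches of 128,
binary cross-entropy computed on logits for numerical stability, and the
L2 penalty (coefficient 1e-3, applied as `λ‖W‖²` to the dense-128 weights)
added to the optimized loss. Dropout rates (0.5 after flatten, 0.3 after
dense-128), the L2 coefficient, batch size and optimizer constants are all
config-exposed. Training is bit-reproducible given a seed on a fixed
platform (BLAS summation order may differ across platforms).

Early stopping monitors validation loss; training stops when it has not
improved for `patience` consecutive epochs and the best-validation weights
are restored. The config default is patience 3 with up to 100 epochs. The
synthetic-data experiments below instead use patience 15 (CV: 10) and a
60-epoch cap (CV: 40): this network has a flat warm-up phase of a few
epochs at near-constant loss, and a patience of 3 frequently stops inside
it; larger patience lets the experiments measure the architecture rather
than the stopping rule.

Decision threshold: a chimera (or window) is called positive when its
score is **strictly greater** than 0.5.

## Duplex energy model

Candidate filtering needs an intermolecular miRNA:site hybridization
energy. chimeranet computes it with a transparent nearest-neighbor dynamic
program rather than an external black-box tool, so the whole pipeline is
auditable and testable: structures are chains of canonical pairs
(Watson–Crick, plus G·U wobble by default) extended by stacks, bulges or
internal loops, with a single duplex-initiation penalty; no intramolecular
pairs, multiloops, dangling ends or coaxial stacking.

Parameters ship as versioned plain text (`data/nn_duplex_params_v1.tsv`):
a Turner-style stack table (the two destabilizing GU/UG stack motifs are
clamped to 0 so every tabulated stack is stabilizing or neutral),
size-indexed bulge/internal-loop penalties, initiation +4.09 kcal/mol, and
a model-definition cap of 8 unpaired bases per side between consecutive
pairs. The table satisfies the thermodynamic symmetry
`E[p1][p2] = E[rev(p2)][rev(p1)]`, which makes `mfe(a, b) = mfe(b, a)`.

The DP is verified exhaustively against brute-force structure enumeration
on short strands (where the loop cap never binds, so the equivalence is
exact). Absolute energies differ from full hybridization programs — no
dangling ends, terminal-AU penalties or loop sequence dependence — but
over the energy range the filter discriminates the model's ranking agrees
with ViennaRNA's duplex fold at r ≈ 0.99; on *purely random* (uniformly
weak) pairs the correlation is lower (~0.84) simply because there is
little variance to explain. The −20 kcal/mol cutoff is kept as the default
and exposed as a flag; with a different energy model a user may want to
recalibrate it.

## Transcript scanning

Windows of length `110 − len(miRNA)` are enumerated at a default step of
5 nt plus a terminal window flush with the transcript end; transcripts no
longer than the window yield one whole-transcript candidate, padded to
110 nt through the same pad generator used in training. Window length is
chosen so that every scanned chimera is exactly 110 nt with no pad,
matching the negative-set construction and avoiding pad-presence bias at
inference. Aggregation is the maximum over surviving window scores; if no
window survives the MFE filter the score is 0 and the call False.

## Evaluation conventions

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), F1 2TP/(2TP+FP+FN), MCC
with its standard four-factor denominator, accuracy (TP+TN)/n. A metric
whose denominator vanishes is reported as 0 and flagged — a warning, not
an exception, because degenerate folds can legitimately occur in small
experiments. ROC/AUC delegate to scikit-learn (thresholds descending,
trapezoidal area); the test suite cross-checks AUC against a directly
enumerated Mann–Whitney statistic. Cross-validation folds are stratified
by label by default (a flag restores plain splitting); the summary reports
per-metric mean ± SE with SE = sd(ddof=1)/√k. Percentages are printed to
two decimals.

## Synthetic data: what it emulates and what it shows

The generator produces a small panel of random 21-nt miRNAs; positives
embed the reverse complement of the miRNA seed (nt 2–8) — and by default
also of a 3'-supplementary block (nt 13–18, separated by a 2-nt spacer) —
within `max_site_offset` (12) nt of the site's 5' end, in chimeras of
60–110 nt padded to 110; negatives come from the same pseudo-site sampler
used for real transcript data, over random transcripts of 1,500 nt
(5'UTR 200 / ORF 900 / 3'UTR 400). `mutation_rate` (default 0.05) mutates
the planted block base-by-base.

Two fixture choices deserve emphasis. A fixed-weight convolutional network
cannot compute sequence complementarity *as a relation* between two
arbitrary subsequences; what it can learn is a panel of (miRNA identity →
complement motif) associations. The default panel is therefore small
(8 miRNAs) and the planted match sits near the site's 5' end (bounded
positional jitter, consistent with ligation junctions flanking the bound
region). With an unbounded panel or free placement the task is provably
out of reach for this architecture and a failing test would say nothing
about the pipeline. Consequently, passing the synthetic experiments
demonstrates that dataset construction, encoding, training, evaluation and
scanning work end to end — it does **not** certify performance on real
CLASH/CLIP data, whose signal is carried by richer (and partly unknown)
sequence statistics and whose miRNA panel is far larger. The fixture also
ignores expression levels, ligation artifacts, Ago-binding context and
site accessibility.

Under the default conditions (5,000 chimeras, 4,000/500/500 split, seed
fixed), training reaches held-out accuracy ≈ 0.95 and AUC ≈ 0.99; 10-fold
cross-validation on the same 5,000 chimeras gives mean accuracy ≈ 0.93;
label-shuffled training sits at chance (0.50). A plain string search for
the exact seed complement solves the unmutated task (≥ 0.95) and degrades
monotonically with `mutation_rate` — the planted signal is real, simple,
and destroyable, which is exactly what a pipeline fixture needs.

Problem sizes used by the shipped experiments (5,000-chimera dataset,
10-fold CV at the same size, 600-nt scan transcripts) are the package's
chosen study conditions: large enough for stable estimates, small enough
to run comfortably on a single CPU.

## Known limitations

- The duplex model is deliberately simplified; its absolute MFEs are not
  interchangeable with RNAhybrid/RNAduplex values (ranking agrees, scale
  differs), so threshold recalibration is advised when substituting models.
- Scanning enumerates windows at a fixed step; a site straddling two
  coarse windows can in principle be diluted (the terminal window and
  step ≤ 5 defaults make this rare).
- Training on real chimera datasets is supported through the TSV/XLSX
  loaders but no real-data performance is claimed or reproduced here; the
  published-scale quantities recomputed by `scripts/acceptance.py` are the
  arithmetic consequences of the published gene-level confusion counts.
- Multi-site synergy, circRNA sponging and Ago-context effects are out of
  scope for the scanner's max-aggregation rule.
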