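# proteopin

Proteome-wide **protein degradation QC** for bottom-up proteomics.

In resected or stored specimens, proteases truncate proteins before and
during sample preparation. In a trypsin-digested (SWATH/DIA or DDA)
experiment those truncation products surface as **semi-tryptic
peptides**: peptides with one trypsin-conforming terminus (after K/R, or
a protein terminus) and one ragged terminus. `proteopin` turns the
intensity carried by such peptides into an objective per-sample quality
score, so degraded samples can be rejected with a statistically
calibrated cut-off instead of by eye.

## The scores

For each protein in each sample, the *individual Protein Integrity
Score*:

```
iPIS = 1 - Σ I_semi-tryptic / Σ I_all-peptides
```

with intensities square-root-normalized by default. The *Proteome
Integrity Number* of a sample is the arithmetic mean over its N
scorable proteins:

```
PIN = Σᵢ iPISᵢ / N        (0 = fully degraded, 1 = intact)
```

PIN values of the non-degraded samples of a cohort are modeled as a
Weibull(λ, k) distribution; the degradation P-value of a sample with
PIN x is the lower-tail probability

```
P = F(x; λ, k) = 1 - exp(-(x/λ)^k).
```

The null is fitted iteratively by exact maximum likelihood: fit on the
included samples and record the Kolmogorov–Smirnov distance D, exclude
samples with P < 0.02 under the current fit, refit, and stop when the
excluded set stabilizes or D stops improving (smallest D wins). All
samples are then scored with the converged parameters and flagged at
P < 0.01 by default.

The package also ships a ground-truth **degradation simulator**
(`pin simulate`): it transfers a known fraction *f* of every peptide's
intensity into a semi-tryptic truncation product, so the expected PIN
has a closed form (exactly `1 - f` under identity normalization) and
every stage of the method is testable without any external data.

## Worked example

Simulate a 10-sample cohort in which one sample (S01) has 12 % of its
peptide intensity mass degraded and the rest are nearly intact, then
score it:

```
$ pin simulate --config cohort.json --out cohort.tsv --truth cohort_truth.tsv
simulated 1088 peptides x 10 samples -> cohort.tsv (truth: cohort_truth.tsv)
$ pin compute --matrix cohort.tsv --out-dir out
scored 10 samples (PIN 0.730-0.969); 1 flagged degraded at P<0.01; ...
```

`out/sample_scores.tsv` (abridged):

```
sample  pin     n_proteins  p_value    degraded
S01     0.7303  100         4.40e-14   1
S02     0.9693  100         0.899      0
S03     0.9572  100         0.428      0
...
```

`out/null_model.json` records the fit: λ = 0.9622, k = 111.5, 2
iterations, excluded = [S01]. The degraded sample was removed from the
null and flagged at P ≈ 4×10⁻¹⁴; the intact samples score PIN ≈ 0.94–0.97
with unremarkable P-values. The other outputs are `ipis_matrix.tsv`
(protein × sample iPIS plus cohort-averaged iPIS — proteins with
averaged iPIS < 0.8 are reported as degradation-prone in
`degradation_prone.tsv`).

Two further verbs: `pin compare --scores out/sample_scores.tsv
--external mrin.tsv` correlates PIN with an external integrity score
(e.g. mRIN from adjacent RNA-Seq samples) by Spearman rank correlation,
and `pin stability --matrix cohort.tsv --remove out/degradation_prone.tsv`
reports the cophenetic correlation between sample dendrograms built with
and without the degradation-prone proteins.

Everything is also available as a library (`import proteopin`):
`read_peptide_matrix`, `annotate_from_fasta` (cleavage classification
from a FASTA), `apply_cohort_filters`, `merge_replicates`,
`compute_ipis_matrix`, `fit_null_iterative`, `score_cohort`, …

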