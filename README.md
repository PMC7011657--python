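# statefish

How much of single-cell gene-expression variability is *noise*, and how
much is *cell state*? Over-dispersed mRNA count distributions are
routinely attributed to transcriptional bursting — episodic,
allele-specific transcription — but the same over-dispersion arises when
cells simply differ in volume, cell-cycle phase, differentiation or
signaling state, because those differences are *shared* across genes and
show up as gene–gene covariance. `statefish` implements the full analysis
chain that separates the two on multiplexed-FISH data paired with
live-cell calcium imaging, and a synthetic-data generator with known
ground truth to exercise it end to end:

- **codebook** — constant-weight binary barcodes (24 bits = 8
  hybridizations × 3 colors, weight 4, minimum Hamming distance 4, with
  unassigned "blank" codewords) and the geometric pixel-classification
  threshold 2·sin(15°) = 0.5176;
- **decode** — pixel-vector decoding of multi-bit image stacks
  (pseudo-z projection, high-pass, optional Richardson–Lucy
  deconvolution, percentile normalization, nearest-normalized-barcode
  assignment with single-dropout correction), spot calling, bead-based
  registration, dropout-based sensitivity / blank-based false-positive
  estimation, and cell volume from smoothed call density;
- **calcium** — GCaMP/mCherry ratio trajectories split into wavelet
  bands and reduced to 8 response features (peak counts, first-peak decay
  and FWHM, band AUCs, maximum and its time);
- **decomposition** — the statistical core: per-gene OLS conditioning on
  the 13 cell-state features with mean add-back, staged (volume → cycle →
  all observed → 2 hidden PCA factors), judged by Fano factor / CV²
  dispersion and by gene–gene covariance against a shuffled baseline,
  plus incremental-R² category attribution and permutation tests for
  calcium-feature slopes.

The central quantitative signature: if cell state dominates, conditioning
drives the gene–gene correlations to the shuffled baseline **and** the
median Fano factor (Var/mean; 1 for a Poisson process) to ~1; if bursting
dominates, counts stay over-dispersed (Fano ≈ 1 + burst size) no matter
how much state is conditioned away.

## Worked example

```python
from statefish.simulate import (
    generate_cell_states, default_gene_models, generate_expression,
)
from statefish.decomposition import VarianceDecomposition

states = generate_cell_states(5000, seed=41)          # volume, cycle, Ca latents
models = default_gene_models(150, seed=42)            # Poisson mode (no bursting)
ds = generate_expression(states, models, seed=43)     # 5000 cells x 150 genes
results = VarianceDecomposition.from_dataset(ds, shuffle_seed=44).fit()
print(results.summary())
```

```
Variance decomposition
======================================================================
              n_features  median_r2  median_fano  pc12_explained_variance  shuffled_pc12  mean_abs_offdiag_corr
stage
raw                    0     0.0000       2.6130                   0.3008         0.0181                 0.1861
volume                 1     0.1098       1.9600                   0.2475         0.0180                 0.1648
volume+cycle           3     0.1665       1.8641                   0.2603         0.0180                 0.1697
all_observed          13     0.4660       1.0457                   0.1596         0.0182                 0.0398
hidden                15     0.6035       1.0229                   0.0329         0.0181                 0.0166
----------------------------------------------------------------------
final stage 'hidden': median Fano 1.023 (Poisson limit = 1), PC1+2 variance 3.290%
shuffled-baseline PC1+2 variance 1.807%
```

Reading it: the raw counts are strongly over-dispersed (median Fano 2.6)
and strongly covarying (first two PCs explain 30% of the variance).
Conditioning on the 13 observed state features explains a median 47% of
per-gene variance and collapses the median Fano to 1.05; adding the two
hidden PCA factors brings the shared variance down to ~3.3%, close to the
1.8% shuffled-data baseline, with median Fano 1.02 — residual,
allele-specific variability at the Poisson limit. Rerunning with
`default_gene_models(..., mode="bursting", burst_size=9.0)` leaves the
final median Fano near 10: the decomposition does not absorb true
intrinsic over-dispersion. `results.plot_fano()`, `.plot_pc_variance()`
and `.plot_cv2_vs_mean()` draw the corresponding figures.

The command line mirrors the library:

```bash
statefish simulate --n-cells 2000 --n-genes 150 --seed 1 --out sim/
statefish decompose --counts sim/expression.csv --features sim/features.csv --out dec/
statefish decode --stack fov.tif --codebook cb.csv --out decoded/ --no-deconv
statefish ca-features --trajectories sim/trajectories.csv --out ca.csv
statefish run-all --seed 1 --out run/
```

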