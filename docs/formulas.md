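# Feature formula sheet

Exact definitions of every matrix-derived feature, as implemented.  Gray
levels `i`, gradient levels `g`, run lengths `j` and zone sizes `s` are all
1-based (the discretization stores levels 1..Range so the low-gray-level
emphases, which divide by `i²`, are always defined).

## Notation

* GLCM: `p(i,j)` — symmetric normalized co-occurrence matrix at one
  (distance, direction); `μx = Σ i·p(i,j)`, `μy = Σ j·p(i,j)`,
  `σx², σy²` the matching variances; `p_{x+y}(k) = Σ_{i+j=k} p(i,j)`.
* GLGCM: `p(i,g)` — normalized joint gray/gradient histogram;
  `p_i(i)`, `p_g(g)` its marginals; `μi, μg, σi², σg²` their moments.
* GLRLM: `R(i,j)` — run counts; `Nr = Σ R`; `Np` = in-mask pixel count.
* ISZM: `Z(i,s)` — zone counts; `Nz = Σ Z`; `Np` as above.
* All logarithms are base 2.

## GLCM (10 statistics per matrix; mean and population variance over the 4 directions, at each distance 1, 2, 4, 8 → 80 features)

| feature | definition |
|---|---|
| Energy | `Σ p(i,j)²` |
| Entropy | `−Σ p(i,j) log p(i,j)` |
| Contrast | `Σ (i−j)² p(i,j)` |
| Correlation | `Σ (i−μx)(j−μy) p(i,j) / (σx σy)` (0 if either σ = 0) |
| Homogeneity | `Σ p(i,j) / (1 + |i−j|)` |
| Sum Variance | `Σ_k (k − SA)² p_{x+y}(k)`, `SA = Σ_k k·p_{x+y}(k)` |
| Cluster Shade | `Σ (i+j−μx−μy)³ p(i,j)` |
| Cluster Tendency | `Σ (i+j−μx−μy)² p(i,j)` |
| Inverse Difference Moment | `Σ p(i,j) / (1 + (i−j)²)` |
| Inverse Variance | `Σ_{i≠j} p(i,j) / (i−j)²` |

Degenerate matrix (no valid pixel pair at an offset): Energy 1, Entropy 0,
Contrast 0, Correlation 0, Homogeneity 1, Sum Variance 0, Cluster Shade 0,
Cluster Tendency 0, IDM 1, Inverse Variance 0 — the limits of a
single-cell diagonal matrix.

## GLGCM (15 features)

| feature | definition |
|---|---|
| Small Gradient Emphasis | `Σ p(i,g)/g²` |
| Large Gradient Emphasis | `Σ p(i,g)·g²` |
| Gray Inhomogeneity | `Σ_i p_i(i)²` |
| Gradient Inhomogeneity | `Σ_g p_g(g)²` |
| Gradient Energy | `Σ p(i,g)²` |
| Mean Gray | `μi` |
| Mean Gradient | `μg` |
| Gray Variance | `σi²` |
| Gradient Variance | `σg²` |
| Gradient Correlation | `Σ (i−μi)(g−μg) p(i,g) / (σi σg)` (0 if degenerate) |
| Gray Entropy | `−Σ p_i log p_i` |
| Gradient Entropy | `−Σ p_g log p_g` |
| Mixture Entropy | `−Σ p(i,g) log p(i,g)` |
| Gradient Difference Moment | `Σ (i−g)² p(i,g)` |
| Gradient Inverse Difference Moment | `Σ p(i,g) / (1 + (i−g)²)` |

The classic gray-gradient nonuniformity statistics are count-scaled; the
inhomogeneity features above use the normalized marginals so values are
comparable across ROI sizes.

## GLRLM (11 statistics, one value per direction → 44 features)

| feature | definition |
|---|---|
| SRE  | `(1/Nr) Σ R(i,j)/j²` |
| LRE  | `(1/Nr) Σ R(i,j)·j²` |
| GLN  | `(1/Nr) Σ_i (Σ_j R)²` |
| RLN  | `(1/Nr) Σ_j (Σ_i R)²` |
| LGRE | `(1/Nr) Σ R(i,j)/i²` |
| HGRE | `(1/Nr) Σ R(i,j)·i²` |
| SRLGE | `(1/Nr) Σ R(i,j)/(i²j²)` |
| SRHGE | `(1/Nr) Σ R(i,j)·i²/j²` |
| LRLGE | `(1/Nr) Σ R(i,j)·j²/i²` |
| LRHGE | `(1/Nr) Σ R(i,j)·i²j²` |
| Run Percentage | `Nr / Np` |

## ISZM (11 features)

| feature | definition |
|---|---|
| Small Zone Emphasis | `(1/Nz) Σ Z(i,s)/s²` |
| Large Zone Emphasis | `(1/Nz) Σ Z(i,s)·s²` |
| Intensity Variability | `(1/Nz) Σ_i (Σ_s Z)²` |
| Size-Zone Variability | `(1/Nz) Σ_s (Σ_i Z)²` |
| Zone Percentage | `Nz / Np` |
| Low Intensity Emphasis | `(1/Nz) Σ Z(i,s)/i²` |
| High Intensity Emphasis | `(1/Nz) Σ Z(i,s)·i²` |
| Low-Intensity Small-Zone Emphasis | `(1/Nz) Σ Z(i,s)/(i²s²)` |
| High-Intensity Small-Zone Emphasis | `(1/Nz) Σ Z(i,s)·i²/s²` |
| Low-Intensity Large-Zone Emphasis | `(1/Nz) Σ Z(i,s)·s²/i²` |
| High-Intensity Large-Zone Emphasis | `(1/Nz) Σ Z(i,s)·i²s²` |

## IHF (3 features)

Unbiased variance; skewness `m3/m2^{3/2}`; excess kurtosis `m4/m2² − 3`
(central sample moments `mk` of the in-mask intensities).  All three are
invariant to a global intensity shift.

## GWTF (80 features)

For the complex Gabor kernel at scale `ν` (center frequency `f_ν`,
geometric spacing from 0.4 cycles/pixel at ν=0 to 0.05 at ν=4) and
orientation `μπ/8`:

* `S_gabor-νμ` — mean over in-mask pixels of `|response|²`
* `A_gabor-νμ` — mean over in-mask pixels of `|response|`

with the kernel `(2πσ²)^{-1} exp(−(x'²+y'²)/2σ²) exp(2πi f x')`,
`σ = 0.56/f`, truncated at 3σ and mean-subtracted (DC-free).
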