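# seqdesc

**Fixed-length numeric descriptors for variable-length biological sequences.**

Most sequence classifiers — function prediction, subcellular localization,
promoter and methylation-site calling — consume fixed-length feature
vectors, not sequences. `seqdesc` converts DNA, RNA, protein and
user-defined-alphabet sequences into such vectors: k-tuple compositions,
type-1/type-2 pseudo-compositions (PseAAC / PseDNC / PseKNC families),
property autocorrelation descriptors (auto/cross covariance, Moran, Geary,
Moreau–Broto), distance-pair frequencies and one-hot encodings. It is
aimed at computational biologists building machine-learning predictors,
and at method developers who need a platform to prototype *new*
representation modes without rewriting the parsing, normalization and
output plumbing every time.

## The model

A sequence of length L over an alphabet 𝒜 is encoded once as internal
indices. For tuple size k, the composition is

    f_u = count(u) / (L − k + 1),   u ∈ 𝒜^k.

Physicochemical properties H⁰ over n-tuples are standardized to zero mean
and unit population standard deviation, H(a) = (H⁰(a) − mean)/σ. Two
families of sequence-order factors capture correlation at lag j = 1..λ:

    θ_j = (1/(N−j)) Σᵢ Θ(Dᵢ, Dᵢ₊ⱼ),   Θ(a,b) = (1/Γ) Σ_k [H_k(a) − H_k(b)]²
    τ_{(j−1)Γ+v} = (1/(N−j)) Σᵢ P_v(Dᵢ)·P_v(Dᵢ₊ⱼ)

with N = L − n + 1 tuples and Γ properties. The type-1 (parallel) and
type-2 (series/amphiphilic) pseudo-compositions are then

    x_u = f_u / Z,   x_{|𝒜|^k + m} = ω·t_m / Z,   Z = 1 + ω Σ t_m

with t = θ (type 1, dimension |𝒜|^k + λ) or t = τ (type 2, dimension
|𝒜|^k + λΓ); ω weights the sequence-order block against the composition.
All components sum to 1.

Because Θ and the products P_v(a)P_v(b) depend only on tuple *pairs*, they
are pre-computed once per configuration over all |𝒜|ⁿ × |𝒜|ⁿ combinations;
per-sequence work is pure table lookup. The test suite certifies this fast
path against an independent naive re-implementation to < 1e-12.

35 representation modes are built in (12 DNA, 8 RNA, 15 protein — run
`seqdesc --list-modes`), and extension files can register new sequence
types (e.g. an `M` for methyl-cytosine), new property tables, new modes
and new command-line options through a 23-function API.

## Worked example

As a scikit-learn transformer:

```python
>>> from seqdesc import SequenceVectorizer
>>> vec = SequenceVectorizer(mode="aac").fit()
>>> X = vec.transform(["MKVLIT"])
>>> X.shape
(1, 20)
```

The six residues of `MKVLIT` are all distinct, so six amino-acid
composition components are 1/6 ≈ `0.166667` (I, K, L, M, T, V — features
`aac_8, aac_9, aac_10, aac_11, aac_17, aac_18` in the alphabetical
20-letter ordering) and the rest are 0. The transformer composes with
pipelines: `make_pipeline(SequenceVectorizer(mode="pseaac1", lam=5),
LogisticRegression())`.

From the shell, the classic amphiphilic pseudo-amino-acid composition
with λ = 10 tiers and weight ω = 0.05 in libSVM format:

```sh
seqdesc -f demo.fas -m pseaac2 -l 10 -w 0.05 -F svm
```

For a 33-residue demo protein this prints one line per sequence,

```
0 1:0.0943486 2:0 3:0.0314495 4:0.0314495 5:0.0314495 6:0.0943486 ...
```

— a label (default 0) followed by 40 indexed components (20 composition
+ 2×10 correlation tiers from the hydrophobicity/hydrophilicity pair)
that sum to 1. Faulty records (non-standard letters, sequences too short
for λ) are skipped and reported to standard error, or abort the run with
`-e abort`. Output formats: `svm`, `tsv`, `csv`.

Extensions are Python files loaded with `-d`; see
`docs/methods.md` and the `seqdesc.extensions` module docstring for the
API and a complete example. **Loading an extension executes its code.**

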