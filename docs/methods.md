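# Methods

## Scope and design

`seqdesc` is a platform for representing variable-length biological
sequences as fixed-length numeric vectors. Four stages form the pipeline:
FASTA parser → sequence preprocessor (encoding to internal alphabet
indices) → computing engine (mode registry + numeric kernels) → result
writer. The user-facing surface is a scikit-learn transformer
(`SequenceVectorizer`), a batch engine with a data-fault policy
(`run_engine`), and a command-line tool (`seqdesc`).

## Sequence model

A sequence type is an ordered alphabet; a letter's internal index is its
0-based position in that ordering. Built-ins: DNA (A,C,G,T with Watson–
Crick complements), RNA (A,C,G,U), PROT (the 20 standard residues in
alphabetical order — no canonical ordering exists in the descriptor
literature, and alphabetical is reproducible; composition component *u*
is the *u*-th letter of that ordering). Users may define alphabets with
extra letters (e.g. `M` for 5-methyl-cytosine). The complement map must
be total on the alphabet but is deliberately *not* required to be
injective or an involution: a modified base legitimately shares its
complement with the unmodified one.

Input is case-folded to upper case by default (real FASTA is mixed-case);
folding can be disabled for alphabets where case is semantic. Whitespace
and digits inside sequence lines are stripped (tolerates column-formatted
FASTA). RNA and DNA are distinct types with no automatic U↔T translation:
a U under the DNA type is a data fault, because silently reinterpreting
letters would change descriptor values without warning. Ambiguity codes
(N, R, Y, …) are likewise faults unless the user defines an alphabet
containing them.

Formulas below use the literature's 1-based positions R₁..R_L; code uses
0-based indices throughout.

## Data-fault policy

Per-record problems — a non-standard letter, a sequence too short for the
requested lags, a degenerate type-2 denominator — are *data faults*,
distinct from configuration errors (unknown mode, bad parameters), which
are raised before any sequence is processed. The policy is user-chosen:
SKIP excludes the record and emits exactly one report (id + reason), so
`len(outputs) + len(reports) == len(inputs)` always holds; ABORT stops
all processing, and the CLI then exits nonzero without writing output.
Parameter validation is dataset-independent, so one short sequence can
never abort a SKIP-policy run.

## FASTA dialects

Headers from UniProt (`sp|ACC|…`/`tr|ACC|…`), NCBI legacy
(`gi|N|gb/ref/emb/dbj|ACC|`), ENA (`ENA|ACC|…`), modern RefSeq
(`XX_digits[.v]`) and GenBank/DDBJ (`1-2 letters + 5-6 digits[.v]`) are
matched in that fixed order, first match wins. GenBank and DDBJ
accessions share a namespace, so both tag as GENBANK (documented
limitation). Anything else falls back to the whole header line as the
identifier. Identifiers must be unique per file; when two *different*
header lines extract the same accession, both fall back to their whole
lines, and only truly identical headers are a hard parse error. Line
splitting is delegated to Biopython's `SimpleFastaParser`; dialect
recognition, uniqueness and the fault policy are layered on top.

## Property tables and pre-computation

A property assigns a real value to every n-tuple of the alphabet (n = 1
amino-acid/nucleotide scales, n = 2 dinucleotide, n = 3 trinucleotide
parameters); a missing tuple is a load error. Before use, raw values are
standardized to mean 0 and *population* (÷N) standard deviation 1 — the
convention of the classic pseudo-composition normalization; the sample
(N−1) denominator would silently rescale every correlation tier. A
constant table has no scale and is rejected. Normalization is idempotent
to 1e-9.

For a configured property set the engine pre-computes, over all tuple
pairs, the averaged squared difference Θ(a,b) = (1/Γ)Σ_k[H_k(a)−H_k(b)]²
and per-property products Π_v(a,b) = P_v(a)P_v(b). These matrices are
built once per mode configuration, never per sequence; every kernel then
works by table lookup. Θ divides by Γ (classic averaging); a `combine="sum"`
flag exists for user modes. Tuple index order is lexicographic by
alphabet index (dinucleotide index = 4·idx(first) + idx(second) for DNA).

Bundled defaults: the classic protein trio (hydrophobicity,
hydrophilicity, side-chain mass) with its widely reproduced published
values; for DNA/RNA, six dinucleotide helical-parameter tables (twist,
tilt, roll, shift, slide, rise) and two DNA trinucleotide tables. The
nucleotide tables are **synthetic stand-ins** — representative values,
marked `synthetic` in filename and header, not drawn from any published
supplementary compilation — suitable as structural defaults; supply your
own tables (plain-text `#name/#seqtype/#tuple` + `TUPLE value` format)
for publication-grade nucleotide work. No test or reported quantity
depends on bundled values: correctness is established exclusively on
randomly generated toy tables.

## Kernels

With N = L−n+1 tuples Dᵢ and composition tuple size k (independent of the
correlation tuple size n — general-k pseudo-compositions combine k-tuple
frequencies with dinucleotide correlations):

- composition `f_u = count(u)/(L−k+1)`; reverse-complement collapsing
  pools a k-mer with its reverse complement onto the lexicographically
  smaller (canonical) of the pair;
- parallel tiers `θ_j = (1/(N−j)) Σ Θ(Dᵢ, Dᵢ₊ⱼ)`, j = 1..λ;
- series tiers `τ_{(j−1)Γ+v} = (1/(N−j)) Σ Π_v(Dᵢ, Dᵢ₊ⱼ)`, lag-major and
  property-minor — for Γ = 2 this reproduces the classic τ_{2j−1}, τ_{2j}
  interleaving, and lag-major is the natural generalization for Γ > 2;
- type-1 / type-2 pseudo-composition with shared denominator
  Z = 1 + ωΣ(tiers); λ = 0 reduces *exactly* (bit-for-bit) to the plain
  composition. Type-2's Z can vanish; |Z| < 1e-12 is a data fault rather
  than an infinite vector;
- autocorrelation family over the per-position property profile:
  AC/CC/ACC (centred covariances, ÷(N−d)), Moran (AC over the ÷N
  variance), Geary (half mean squared difference over the ÷(N−1)
  variance), normalized Moreau–Broto (un-centred products). On
  zero-variance (homopolymer) profiles Moran and Geary are defined as 0
  instead of faulting — homopolymers are legitimate inputs and the fault
  system is reserved for structural problems;
- distance-pair frequencies per distance d = 1..d_max, each block
  normalized by L−d;
- one-hot with a mandatory target length; shorter sequences are
  zero-padded, longer ones fault (truncation would silently discard
  signal).

Frequencies (not raw counts) are used everywhere so the pseudo-composition
denominator takes the 1 + ωΣ form and composition blocks sum to 1.

## Mode catalogue and defaults

35 built-in modes: 12 DNA, 8 RNA, 15 protein (`seqdesc --list-modes`;
stable sort by seqtype then mode id). Defaults: λ = 1, ω = 0.05,
d_max = 1; psednc fixes k = 2; general-k PseKNC modes default to k = 3
(the k-tuple lineage convention); nucleotide k-mer modes default to
k = 2; one-hot has no default target length (it is data-dependent and
silently guessing it would make output dimensions irreproducible).
`pseaac1` fixes the classic trio, `pseaac2` the hydrophobicity/
hydrophilicity pair; the `-g` variants take any user property set.

## Extension system

Extensions are Python source files executed against a namespace of
exactly 23 documented callables (registration, option declaration and
re-binding, property access, per-sequence inspection, kernel helpers,
`emit_vector`/`set_label`/`skip_sequence`). Loading is transactional —
a failing file registers nothing (rollback journal) — and identifiers
must not collide with built-ins or earlier extensions. Option
re-declaration is allowed; the last-loaded extension wins with a logged
warning. A mode whose compute rule emits the wrong dimension is a data
fault at first use, not a load error, because the dimension may depend on
options unknown at load time. Extensions run arbitrary code; they are
loaded only from explicit `-d` paths and never auto-discovered.

## Output

libSVM (`label 1:v …`, 1-based strictly increasing indices, zeros emitted
so every line has a fixed column count; `--sparse` drops them), TSV and
CSV (RFC-4180 quoting) writers share one number format — shortest
positional decimal at 6 significant digits, no scientific notation below
1e6 — so the three formats are numerically identical and round-trip to
the printed precision. Skip reports and the summary line go to standard
error, never into the data stream. Exit codes: 0 success, 1 abort/parse
fault, 2 configuration error.

## Synthetic data

Test fixtures are generated, not stored: uniform-random sequences over a
registered alphabet with lengths drawn from a range (5–50 for kernel
checks, matching the short-to-medium regime where lag bounds actually
bind), random non-constant toy property tables, one synthetic header per
database dialect, and a mixed-quality FASTA with a controlled count of
clean / bad-letter / too-short records (7/2/1 in the fault-contract
check). Uniform sequences exercise everything the engine is sensitive to
— letter identity, order and length — but none of the structure of real
data (compositional bias, domains, repeats), so passing tests certify
numerical and contractual correctness, not biological performance of any
descriptor.

## Verification strategy and problem sizes

Every kernel is checked against an independent naive implementation
(`tests/reference_impl.py`: per-position Python loops over letter strings
and property dictionaries, no shared code) to within 1e-12 — in practice
agreement is at machine precision (~1e-15) — on 500 random sequences in
the acceptance checks and smaller per-kernel batches in unit tests; the
reduction/invariance sweep uses 1,000 random inputs; the worked example
and the extension round-trip use 100 sequences each. These sizes give
wide coverage of length/lag/tuple-size combinations while keeping the
full suite under a minute. Reversal invariance of θ/τ (n = 1) and
permutation invariance of compositions are asserted on random inputs;
property-based tests (hypothesis, seeded) cover encode/decode round
trips.

## Known limitations

- Bundled nucleotide property values are synthetic stand-ins (above).
- GenBank and DDBJ accessions are indistinguishable by pattern; both tag
  GENBANK.
- No FASTQ or compressed input; no ambiguity-code expansion; no
  translation or whole-record reverse complementation; no GO/domain/PSSM
  general-form modes (they require external databases); no mismatch
  kernels.
- Extension loading is not sandboxed.
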