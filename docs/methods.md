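# Methods

This note documents the models, conventions and numerical choices behind
protannot, in the order a user meets them: the data model, the file
formats, the three analyses, and the synthetic generator the test suite
uses as its oracle.

## Data model and conventions

**Coordinates.** All residue coordinates are 1-based and inclusive at both
ends, the convention of protein biology (UniProt feature tables, PDB
numbering): a domain `[start, stop]` covers `stop − start + 1` residues and
a length-L track's element *i* annotates residue *i* (1-based). No
half-open arithmetic appears anywhere, including in the files.

**Alphabet.** Sequences are validated against the 20 canonical residues on
entry; the letters `X` (unknown) and `U` (selenocysteine) are accepted only
under an explicit permissive flag. Failing loudly on unexpected characters
catches the most common class of upstream data error (nucleotide files,
gaps, `*` stop codons) at the boundary instead of deep inside an analysis.

**Duplicate identifiers.** Adding a protein under an existing unique ID is
an error by default (`strict`); a `skip` policy (first record wins) exists
for merging overlapping sources. Both are explicit modes rather than silent
behavior.

**Residue classes.** The built-in chemistry classes are polar `G S T Q N P`
(proline included, following the composition convention for polar
low-complexity domains), aromatic `F W Y`, aliphatic `A I L M V` and
charged `D E K R`. Histidine is excluded from the charged class — its side
chain is mostly neutral at physiological pH — and cysteine belongs to no
class; the three-way aliphatic/aromatic/charged split therefore does not
partition the alphabet, and composition bookkeeping carries an implicit
"other" complement so per-sequence class fractions sum to 1. The aliphatic
set is one common convention among several (some authors include G or
exclude M); it is a documented assumption, not a measurement.

**Determinism.** Every returned list follows insertion order (protein
order, then annotation order); nothing depends on hash ordering, so two
runs over the same inputs produce identical output files.

## File formats

The four annotation flavors are tab-separated, one annotation per line,
join key (the protein's unique ID) first, no header, `#` comments, with
optional trailing `key:value` attribute tokens. Attribute tokens split on
the *first* colon only, so values may contain colons; keys may not contain
`:` or tabs and must be unique per line. Numeric values are serialized with
`repr`-level (shortest round-trip) precision, so write-then-read is exact;
readers accept any parseable real. CRLF files and trailing blank lines
parse identically to LF files.

Readers are atomic per line: a fatal line contributes nothing to the
proteome, and remaining lines are still processed; every line is classified
accepted / warning / fatal with a machine-readable code in a
`ValidationReport`. Lines naming proteins absent from the proteome are
skipped with a warning by default (annotating a subset is a normal
workflow) and fatal in strict mode. `validate_file` runs exactly the same
per-line code with application disabled, so validation is side-effect free
and can never disagree with reading. Out-of-bounds domain coordinates are
fatal under `safe=true` and clipped to `[1, len]` under `safe=false`
(annotations produced against a slightly different sequence version);
inverted coordinates are always fatal.

These column layouts are this package's own specification of a
tab-separated, one-annotation-per-line schema; they are not guaranteed
byte-compatible with any other tool's files.

## PTM enrichment corrected for solvent accessibility

For a target residue *r* and site type *s*, every residue equal to *r* is
assigned to the IDR stratum (covered by ≥ 1 domain of the IDR type) or the
folded stratum. A residue is *modified* if any site of type *s* sits at its
position. The reported quantities are

    f_IDR    = modified IDR residues / all IDR residues
    f_folded = modified accessible folded residues / accessible folded residues
    ratio    = f_IDR / f_folded

where *accessible* means the residue's value in the accessibility track is
≥ the threshold (default 0.25, the conventional relative-solvent-
accessibility cutoff between buried and exposed residues). IDR residues
are **not** accessibility-filtered by default: disordered regions have no
fixed structure for a structure-derived RSA estimate to describe, and the
scientific comparison is "IDR residues versus *solvent-accessible* folded
residues". A flag applies the filter to both strata for sensitivity
analysis. Both the threshold and the filtering convention are parameters
precisely because the underlying statistic admits more than one reasonable
convention.

A stratum with zero target residues yields an undefined (None) fraction —
flagged, never an exception — and the ratio is undefined whenever its
denominator is. A two-proportion z-test p-value is provided alongside the
ratio; it is descriptive, not a multiple-testing-corrected inference.

## Percentile-based chemistry selection

Candidates are all domains of the requested type with length ≥
`min_length` (default 30 — long enough for a composition fraction to be
meaningful and a typical minimum for functional IDRs; whether a length
filter is applied, and where, is an explicit parameter rather than a fixed
rule). For each candidate the enriched-class fraction and the *summed*
depleted-class fraction (e.g. charged + aliphatic) are computed; the
selection keeps candidates in the top `enrich_percentile` % of the former
and the bottom `deplete_percentile` % of the latter (defaults 20 and 5).

Thresholds are empirical nearest-rank percentiles over the candidates,
computed on the relevant tail: the upper threshold is the k-th largest
value with k = ⌈p/100 · n⌉ (clipped to [1, n]) and values ≥ it are kept;
the lower threshold is the k-th smallest and values ≤ it are kept.
Comparisons are inclusive, so ties at a threshold enter the selection.
This definition makes the degenerate identities exact: 100 % admits every
candidate, 0 % only the tied extreme set, and the top 20 % of ten
distinct values is exactly its two largest. Fewer than 20 candidates
attaches an instability warning (an empirical 5th percentile of 7 values
is close to meaningless); zero candidates return an empty selection.

## Disorder versus abundance

Per protein, the disorder fraction is the number of residues covered by
≥ 1 IDR domain divided by the length (overlapping IDRs are not double-
counted), and the IDR charge content is the length-weighted charged
fraction over that protein's IDR domains (undefined without IDRs; such
proteins are excluded from the charge statistic only). Abundance is read
from a protein attribute; missing, non-numeric or non-positive values are
skipped and tallied. The headline statistic is the Spearman rank
correlation against log₁₀ abundance — rank-based because the relationship
of interest is a monotone trend, not a parametric model, which also makes
the statistic invariant to any strictly monotone transform of abundance
(the log matters only for the binned means). Zero rank variance in either
variable flags the correlation undefined; fewer than 3 usable proteins is
an error. Quantile bins are taken on abundance ranks (ties averaged), so
the bins partition the ranked proteins.

## Synthetic generator

The generator emulates the *structure* of an integratively annotated
proteome, with planted parameters as the ground truth that the analyses
must recover:

* **Sizes.** Default 200 proteins of uniform length 100–300. Parameter-
  recovery runs use 1 500 proteins for the enrichment check — sized so
  each stratum holds ≥ 5 000 target serines, making three binomial
  standard errors a tight band (≈ ±1.2 percentage points on the folded
  stratum) — and 2 000 for the correlation check (Spearman sampling error
  ≈ 0.022).
* **Disorder layout.** Each protein draws a target disorder fraction
  (scaled Beta(2, 2) over [0.05, 0.8]) realized as 1–2 non-overlapping
  contiguous IDR domains of ≥ 10 residues placed in equal-width blocks.
* **Composition.** Residues are drawn from a disorder-like distribution
  inside IDRs (polar/charged-rich, ~10 % serine, no cysteine) and a
  globular-like one outside (~7 % serine). Only composition is modeled —
  no residue ordering, patterning or evolutionary structure, so sequences
  are not biophysically realistic disordered sequences; they are
  composition-faithful stand-ins.
* **Modifications.** Each target residue is modified independently with
  probability `p_idr` = 0.23 inside IDRs and `p_folded` = 0.12 outside —
  independent of accessibility, so the accessible-folded subsample is an
  unbiased estimate of `p_folded`.
* **Accessibility.** Beta(2, 5) for folded residues (mostly buried,
  ~53 % above the 0.25 cutoff) and Beta(8, 3) for IDR residues (mostly
  exposed). Real RSA is spatially autocorrelated along the chain; the
  generator's values are i.i.d. within a stratum, which is irrelevant to
  the per-residue counting statistics tested but means the tracks should
  not be used to test smoothing-dependent methods.
* **Abundance.** log₁₀ abundance ~ Normal(2, 1), coupled to the disorder
  fraction through a Gaussian copula: the latent normals use Pearson
  correlation r = 2 sin(π ρ_s / 6), the exact inverse of the bivariate-
  normal rank correlation, so the planted Spearman ρ_s (default −0.5) is
  hit up to sampling and IDR-length discretization error.

Generation is bit-reproducible for a fixed seed, and the emitted file set
always passes validation with zero fatal errors; the in-memory proteome
equals the result of reading the files back. Because the generator plants
effects by construction, passing recovery tests demonstrates the
*correctness of the estimators*, not that real proteomes behave this way:
real PTM data have enzyme-specific sequence motifs, abundance spans more
orders of magnitude with heavy measurement noise, and disorder calls
disagree between predictors. Conclusions about real data require real
annotation files, which the I/O layer consumes in the same formats.

The fixed five-protein toy proteome trades realism for hand-verifiability:
every count in its documentation (5 proteins, 6 IDRs, 9 phospho sites,
6/14 IDR serines modified vs 1/3 accessible folded) can be checked by eye
against the sequences.

## Known limitations

* One annotation file flavor per call; no gzip, remote URLs, or BED/GFF
  conversion.
* The enrichment p-value is a plain two-proportion z-test; residues are
  treated as independent, which real clustered PTM data violate.
* Percentile selection is unstable below ~20 candidates (warned, not
  refused).
* The generator's sequences are composition-only; no secondary structure,
  motifs, or phylogeny.
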