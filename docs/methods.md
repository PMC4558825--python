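# Methods

This note documents the models, conventions and numerical choices behind
`uniline`, in the order the pipeline runs them.

## Reference trees and variant tokens

Haplogroup phylogenies are rooted trees whose branches carry defining
variants. The token grammar covers the forms used in the human mtDNA
haplogroup literature — `A1692G` (substitution with alleles), bare `1692`
(substitution with unspecified allele; it matches any observed allele at the
position), `8281-8289d` (range deletion), `8289.1C` (insertion,
string-matched) — plus named Y-SNP markers (`P293`, `M168`), which are
treated as opaque string-matched tokens. A trailing `!` is a back mutation:
in a cumulative root-to-node set it removes the earlier variant at that
position and does not itself enter the set (the lineage has reverted to the
ancestral state). A later variant at an already-mutated position replaces
the earlier one.

The on-disk format is a three-column TSV (node, parent, comma-separated
tokens) with `#` comments — trivially diffable, since no canonical machine
format exists for these trees. Two toy trees ship with the package: a
26-node mtDNA tree covering the H/HV European clades, the B branch carrying
the 9-bp deletion with the B4a1a1m / B4a1a1a14 sibling pair (whose cumulative
sets differ by exactly position 6905), and Oceanian/Asian alternatives
(M28, Q1, P1); and a 14-node Y skeleton with the F branch (P145/P160;
tips G, H, I1, R1b) and the rare E1b1a1 (P293) outlier. The deletion-bearing
level is named `B` rather than `B4'5` so every label is Newick-safe without
quoting.

Induced subtrees are the minimal subtree spanning a set of nodes: unary
unrequested internals (including the root) collapse, so a single requested
name yields `name;`. With annotation on, each emitted label carries a
square-bracket comment listing the defining variants accumulated along its
(possibly collapsed) branch; annotation off yields strict Newick.

## Haplogroup calling

The assignment score is the Kulczynski-style symmetric mean
`½(|M|/|E| + |M|/|O|)` with empty-denominator terms defined as 1 (so the
root scores 1 against an empty profile). It is the simplest symmetric
measure that is exactly testable and rewards both completeness (of the
expected set) and purity (of the observed set). Matching is wildcard-aware:
a bare-position token on either side matches any allele at that position;
deletions match on their exact range; opaque tokens on their string. Each
observed variant is consumed at most once, so `|M| ≤ min(|E|, |O|)` by
construction. Ties break toward the deeper (more specific) clade, then
lexicographically — deterministic output. An optional position mask (e.g.
hypervariable sites) is removed from both `E` and `O`; the default is empty.

Frequency tables collapse calls around a clade of interest: calls at or
below the ancestor pool into `<ancestor>[x]`; all others bin by their major
clade, defined as the last single-letter haplogroup label on the root path
(H1 → H, B4a1a1m → B, E1b1a1 → E), falling back to the depth-1 node.

## The 9-bp-deletion screen

The in-silico PCR anneals the forward primer on the plus strand and the
reverse-complemented reverse primer downstream, each with at most
`max_mismatch` mismatches (default 1) and none in the primer's 3'-terminal
3 bases (those abolish extension). The reported fragment length is
end-to-end including both primers — the convention under which the expected
sizes are 133 bp (no deletion) and 124 bp (deletion). Among multiple
pairings the shortest product is reported, with a warning when more than one
product falls under 2 kb. Genotype calls are exact-length: 133 → absent,
124 → present, anything else (or no product) → unknown; unknown is a value,
not an error. The search is linear; an optional circular mode appends a
configurable origin-spanning window (this amplicon does not cross the
origin, so the default is off).

Because no external sequence download can be assumed, the screen's template
is a synthetic reference: a seeded random 16,569-base sequence with the two
primer sites and the CCCCCTCTA×2 repeat implanted at the rCRS-homologous
offsets (forward site 8196–8217, repeat 8272–8289, reverse site 8307–8328),
so the 133/124 arithmetic is exactly that of the real mitochondrial genome.

## Pedigrees and lineage propagation

The file dialect is PED-like: `family id father mother sex origin`,
whitespace-delimited, `0` for missing, with the origin label (european /
polynesian / other / unknown) in the phenotype slot. Validation rejects
unresolved parent references, fathers who are not male / mothers who are not
female, and parent–child cycles, each with a distinct error.

Matrilines follow mother links to the first individual with no recorded
mother; patrilines follow father links and are defined only for males. An
individual with one recorded parent terminates the corresponding line at
themselves (partial genealogies are the norm); cohort members without
ancestral links can be modelled as founders with `origin=other`, tracked but
binned separately. Propagation is a single topological-order pass and is
invariant to input row order; every true founder must carry an mtDNA
haplotype and every male founder a Y haplotype.

Concordance between propagated haplotypes and observed calls is the fraction
of shared samples that agree after collapsing both to a chosen depth below
the root; mismatches are reported as candidate pedigree errors or new
founders.

## Admixture statistics

The default evaluation cohort is the pedigree leaves (no recorded children),
standing in for "present-day individuals"; an explicit id list overrides.
Maternal fractions are computed over the whole cohort, paternal fractions
over males with a defined patriline — and are reported as undefined, not
zero, when that set is empty. Individuals whose matriline ends in an
unknown-origin founder count in the `unknown` bin and are never
redistributed. Confidence intervals are percentile bootstrap over
individuals (default 1000 replicates, seed required). Lineage survival is
the number of distinct founders represented in the cohort's matrilines (or
patrilines), optionally restricted by founder origin. The gender-bias index
is `maternal(origin) − paternal(origin)`, in [−1, 1].

## The simulator

The generator encodes the settlement scenario as defaults: 9 European male
and 12 Polynesian female founders, 11 non-overlapping generations, a total
population cap of 1400, three additional European male settlers entering as
founders in generations 1–3, Polynesian founders drawing a B4-clade mtDNA
haplogroup with probability 0.9 (B4 tips of the bundled tree) and otherwise
an Oceanian alternative (M28/Q1/P1), European founders drawing H-clade
mtDNA, and male founders drawing an F-branch Y haplogroup with an E1b1a1
outlier probability of 1/223. Mating is monogamous random pairing within a
generation; offspring per couple are Poisson with mean 3.0 (a growth factor
of ~1.5 per generation, which reaches the cap within the 11 generations);
sex is a fair coin. Reaching the cap truncates a generation at random;
a generation that could have reproduced but did not raises an extinction
warning rather than failing silently. All randomness flows from one seed,
and identical seeds give byte-identical PED output.

Observed genotypes are modelled as the cumulative variant set of the
assigned haplogroup with per-variant dropout (probability δ) and
Poisson-mean-μ private false positives placed at positions the reference
tree never uses. Because each variant consumes one uniform draw in a fixed
order, dropout across a δ-grid with a common seed is nested, making
concordance monotone non-increasing in δ — a property the tests exploit.
Consensus-like FASTA for the deletion screen applies a clade's cumulative
variants to the synthetic reference (wildcard substitutions become the
transition partner of the reference base; deletions shift downstream
coordinates).

What the simulator does **not** emulate: overlapping generations, age
structure, non-random or polygamous mating, recombination or autosomal
genotypes, heteroplasmy, sequencing-depth-dependent error, and shared
founder matrilines (each founding woman is her own matriline; a grouping
option would be needed to mimic sisters among founders). Passing tests
therefore demonstrate the pipeline's internal correctness and its behaviour
under idealised noise — not calibration against any real cohort.

## Phylogenies

Sample trees use the Hamming set distance (size of the symmetric difference
of two masked variant sets) and neighbor joining, delegated to scikit-bio;
negative NJ branch lengths are clamped to zero with a warning, keeping the
Newick valid at the cost of slight non-additivity. The two-taxon case is a
single edge of length d. Reference-style annotated figures come instead from
induced subtrees of the haplogroup tree; both routes are exposed.

## Pipeline and reproducibility

Stages hand off through flat files (PED/TSV/FASTA/JSON) so each stage can be
re-run in isolation; every tabular output carries `#` header lines with the
seed, a configuration hash (location-independent) and the package version.
The deletion screen defaults to the first 70 female leaves, mirroring a
restriction-screen cohort size; the NJ stage defaults to 40 samples to keep
the all-pairs distance matrix small. The acceptance script scales the
end-to-end recovery experiment to 50 replicates of the default scenario
(the test suite runs 200), with 1000 bootstrap replicates per estimate; all
problem sizes are stated in its output (`n` per quantity).
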