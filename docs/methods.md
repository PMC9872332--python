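# Methods

`karyopaint` implements the comparative-cytogenetics workflow built on
Zoo-FISH (cross-species chromosome painting): whole-chromosome probes from
one species are hybridised onto metaphases of another, revealing homology at
chromosome/arm resolution. The package covers karyotype bookkeeping, algebra
over painting homology tables, detection of syntenic associations used as
cladistic markers, parsimony classification of rearrangement events against
an ancestral karyotype, change-rate estimation, and a forward simulator that
provides ground truth for the inference machinery.

## Karyotype arithmetic

A karyotype is a list of chromosome pairs with morphology classes
(metacentric, submetacentric, subtelocentric, acrocentric). The diploid
number is `2n = 2·(autosome pairs) + 2` for the single sex pair. The
fundamental number used throughout is the **autosomal** FN: twice the
per-pair arm sum, with bi-armed chromosomes contributing 2 arms and
acrocentrics 1, sex chromosomes excluded. This is the only convention that
yields FN = 92 simultaneously for the Amazonian manatee (TIN: 2n = 56, 19
bi-armed + 8 acrocentric autosome pairs) and the Florida manatee (TML:
2n = 48, 23 bi-armed pairs), which is the diagnostic fingerprint of
Robertsonian divergence: each centric fusion/fission moves 2n by 2 and
leaves FN unchanged.

Two extra morphology values encode what comparative tables actually state:
`biarmed` (bi-armed, centromere position unspecified — still contributes 2
arms) and `unknown` (FN not derivable; requesting FN raises, naming the
chromosome). Source publications only rarely print per-chromosome classes;
insisting on the four-class set would force invented data into fixtures.
Subtelocentric counts as bi-armed, standard cytogenetic practice.

Validation is finding-based, not exception-based: printed-vs-derived 2n/FN
mismatches, duplicate labels and missing morphology are returned as findings
because the literature itself disagrees in places (an older census prints
FN = 82 for TIN where the current morphology census yields 92); such
conflicts must surface without aborting an analysis.

## Segment tokens and table dialects

Painted segments are written as compact tokens — `17q-dist`, `2qhi`,
`12p-qprox`, `16p?`, `27 (24)` — with an optional arm (`p`/`q`/`pq`), an
opaque band-letter run, a positional qualifier after a hyphen, a trailing
`?` for regions not resolved by painting, and a parenthesised alternative
label whose meaning the source tables do not define (stored verbatim, never
interpreted). Tokens round-trip losslessly through parse/format; no band
coordinate system is imposed because none exists at painting resolution.

Table cells are small expressions over tokens: `, ` separates the several
chromosomes an ancestral segment split into, `/` joins reference-species
segments syntenic on one chromosome, ` + ` joins outgroup segments, and a
trailing `inv` or `inv/cr` flag marks a pericentric inversion or an
inversion/centromere-repositioning on that specific cell. Files are UTF-8
TSV with `# key: value` headers; `+` joins composite flow-peak members and
`;` separates multiple targets. The dialect was chosen to transcribe the
typeset source tables byte-faithfully, and writers reproduce the cell text
exactly so transcription errors stay visible in diffs.

The TML→TIN fixture ships in flow-peak form: 17 pure peaks, the mixed peaks
`2+4`, `3+7`, `6+X`, `11+13`, `14+19`, `17+21`, and the duplicated TML 20
peak (NOR heteromorphism), which the reader collapses with a logged notice.
Composite peaks are resolved by an assignment table derived from the
published one-to-one probe enumeration; deconvolution refuses assignments
that leave an observed signal unattributed. The typeset `17, 21` row prints
only target 18; the published prose states TML 17→TIN 12 and TML 21→TIN 18
explicitly, so the fixture row carries both targets.

## Homology algebra

All matching happens at whole-chromosome granularity: arm and region
qualifiers are carried as evidence but never create or block a match,
because whole-chromosome painting cannot support arm-level adjacency claims.
`invert_map` swaps each (probe, target-segment) link, so annotations change
sides losslessly and inversion is an involution. `compose_maps` chains
A→B and B→C through the shared species and records the (B, C) evidence
chain per produced link. The segment census sums target-list sizes per
probe; on the TML→TIN table the default convention gives 29 segments
(19 single-signal autosomes + 4 probes × 2 signals + X + Y). The source
abstract prints 31; no counting convention (mixed peaks, the duplicated NOR
peak, counting on the TIN side) yields 31 unambiguously, so 29 is reported
and the discrepancy is flagged rather than patched.

A syntenic association — the classic Zoo-FISH cladistic character — is
detected when segments of both members of a candidate pair (e.g. HSA 5 and
HSA 21) map to one target chromosome. Co-occurrence is the criterion;
absence is reported explicitly; uncertainty-flagged tokens and unresolved
cells never create hits. The HSA→TML map used to infer HSA content of TIN
is derived from the HSA column of the ancestral matrix (text-based
provenance). That column carries mostly one token per ancestral chromosome,
so associations whose evidence lives only in the graphical HSA→TML painting
figure (14/15, 16/19, and the second 12/22 block) are not reachable from
this encoding; the report layer emits a finding for every
detected-vs-published status or placement conflict (including the published
2/3 placement on TIN 12 where composition yields TIN 11).

## Event inference

Parsimony-minimal reading of painting evidence: a probe chromosome with k
targets witnesses k−1 fissions; a target receiving k probes witnesses k−1
fusions; polarity is always explicit (ancestor → descendant), never guessed.
A fusion/fission is flagged Robertsonian when the split side is all
acrocentric and the joined homolog bi-armed; missing morphology downgrades
the event to unflagged with a warning finding rather than failing.
Pericentric inversions and centromere repositionings are invisible to
painting and enter only as annotations — the structural flags of the
ancestral matrix (`inv`, `inv/cr`) or curated statements.

Lineage counting against the ancestral matrix applies the same k−1 rules to
a taxon column: a taxon chromosome homologous to k ancestral rows → k−1
fusions; an ancestral row split over k taxon chromosomes → k−1 fissions;
flags map to annotation events. Uncertainty handling: bare `?` cells are
always excluded and reported; tokens merely flagged uncertain (`16p?`)
participate in tallies by default but are reported as unresolved
(`include_uncertain=False` gives the stricter reading). On the packaged
matrix this yields TIN 1 fusion + 1 inversion + 2 repositionings (total 4)
and TML 5 fusions + 2 repositionings (total 7), matching the published
counts, and LAF 5 fusions (published) + 3 fissions where 4 are published —
the fourth would require reading the `27 (24)` parenthetical as a second
chromosome, which this package deliberately does not do — and PCA 3 fusions
+ 2 fissions against a published 4 + 2: the missing fusion is exactly the
unresolved `?` cell at ancestral chromosome 22 (28 ancestral rows against
26 hyrax autosome pairs balance only if that cell resolves to an
already-used chromosome). These two divergences are reported, not patched.

Change rates are `events / divergence_myr`, unrounded, formatted only at the
report layer. Rates are computed per lineage (56 myr ordinal divergence)
and per pairwise comparison (1.34 myr manatee split) separately; the
published 1–5 changes/myr interval is treated as a plausibility bound.
Shared-association classification marks a pair clade-shared when present in
every ingroup taxon and derived when additionally absent or unresolved in
the outgroup; untested pairs count as unresolved, which conservatively
blocks a synapomorphy call.

## Simulator

The forward simulator applies a configured number (or Poisson-drawn number,
in rate mode) of fusions, fissions, inversions and repositionings to a
synthetic ancestral karyotype, sampling eligible chromosomes uniformly
without replacement within an event and re-evaluating eligibility each
step. Chromosome content is tracked as intervals of ancestral chromosomes,
so the emitted ancestral→derived painting map is exactly what a painting
experiment would see — including the confounding that arises when one
chromosome is hit twice (a fusion followed by a fission at the fusion
boundary is invisible). Derived labels are `D1..Dn` in descending
size-proxy order, deterministic per seed; identical seeds give bit-identical
maps, karyotypes and truth logs, and replaying the log mechanically
reproduces the derived karyotype.

What the simulator does and does not emulate: it reproduces the painting
*logic* of whole-chromosome probes (merges, splits, morphology bookkeeping,
conservation laws: fusion −2/0 on 2n/FN, fission +2/0, inversion 0/±2), not
the wet-lab error modes (cross-hybridisation, weak signals, heterochromatin
artefacts) or sequence-level processes. Passing recovery tests therefore
demonstrates the correctness of the inference algebra on clean homology
maps, not robustness to noisy FISH calls. The ancestral morphology mix
(`acrocentric_fraction`, default 0.3) is a free parameter — no morphology
distribution is published for the ancestral complement — and event recovery
is scored by identifiability class read off the truth log: exact recovery is
guaranteed only in the each-chromosome-once regime; with repeated hits the
inferred total is a lower bound (asserted, never exceeded). The packaged
recovery study runs 1000 replicates at 10–30 pairs with ≤5 events, sizes at
which the identifiable regime dominates and the whole study completes in
seconds.

## Numerical and design notes

- No floating-point tolerances matter anywhere except change rates, which
  are exact divisions reported at full precision (JSON) or 2 decimals
  (text).
- Chromosome labels are opaque strings compared by exact match; display
  ordering uses natural order ("2" before "10").
- The report pipeline never re-derives a number: every block carries the
  module-level operation output plus a provenance string, and two runs are
  byte-identical.
- Strict pipeline mode aborts on structural findings (karyotype validation,
  matrix-vs-map contradictions) but not on the documented
  detected-vs-published association conflicts, which are data discrepancies
  the report exists to display.

## Known limitations

- Arm-level claims are out of reach by design; composition and association
  detection operate at whole-chromosome granularity.
- Within-chromosome marker order, breakpoint coordinates and
  breakpoint-graph (DCJ) distances are out of scope, as are phylogenetic
  tree search and hybridisation modelling.
- Event counts from painting are parsimony minima; repeated rearrangements
  on one chromosome are systematically under-counted (the simulator
  quantifies this bound).
- The ancestral matrix encodes a typeset table whose flowed rendering is
  ambiguous in places; every row was cross-anchored against the pairwise
  painting table (the packaged cross-consistency check returns no findings),
  but parentheticals and `?` cells are preserved uninterpreted.
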