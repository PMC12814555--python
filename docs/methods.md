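# Methods

## Scope and data model

`moclosim` simulates one-pot Golden Gate / MoClo reactions and the
bookkeeping around a cloning campaign. The unit of sequence data is the
`DnaMolecule`: an uppercase A/C/G/T/N string with explicit
circular/linear topology and simple stranded features. Coordinates are
0-based and end-exclusive everywhere inside the package; conversion to
GenBank's 1-based inclusive convention happens only in serialization
(via biopython). Ambiguity codes other than N are rejected at load:
Type IIS site matching over degenerate sequence has no agreed semantics,
and silently matching (or not matching) an R or Y would be worse than a
clear error. Plasmid identifiers equal the GenBank file basename,
case-sensitively. Records that do not declare a topology on the LOCUS
line are treated as circular with a warning — inputs are plasmid
databases, and circular is the only default that does not silently
truncate a part spanning the file's seam.

## Digestion

A Type IIS enzyme is `(recognition, spacer_top, spacer_bottom)` in the
usual N(a/b) notation; the overhang length is `b − a`. Cut positions are
gap indices on the top strand: a + site at `p` cuts at
`p + m + a` / `p + m + b`, a − site at `q` (where the reverse complement
of the recognition occurs on the top strand) cuts at `q − b` / `q − a`.
Since `b > a`, the top cut always lies left of the bottom cut and the
overhang is simply `seq[top_cut : bottom_cut]`, which is also the fusion
site's name (5′→3′ on the final product's top strand, the MoClo kit
convention — e.g. AATG for a start-codon junction).

Circular molecules are handled by modular arithmetic (equivalently: a
virtual rotation so no cut spans the seam); rotation invariance of the
fragment multiset is asserted by tests. Fragments between consecutive
cuts are stored as `left_fusion + payload`, the right fusion belonging
to the next fragment — this makes length conservation exact and turns
junction compatibility into string equality.

Degenerate cases, decided here and frozen:

- zero sites on a circle → `NoSitesError` ("uncut"), so a campaign row
  using a siteless plasmid fails with the plasmid named;
- exactly one cut on a circle is a nicked circle, not a digest →
  `SingleCutError`;
- two sites directing the *identical* cut (as happens when sites flank a
  junction from both sides in re-digestible products) collapse into one
  cut; *partially* overlapping overhang regions are a
  `CutCollisionError`, since such a part plasmid is malformed;
- linear molecules digest into n+1 pieces whose outer ends carry empty
  fusion strings.

The released **insert** is the unique fragment whose full duplex
(including the right overhang) contains no recognition site on either
strand. The same rule serves acceptor plasmids whose sites face outward
into the drop-out: the usable backbone piece is then itself
recognition-free. Zero or multiple recognition-free fragments are
reported as errors naming the source plasmid.

## Assembly

Fragments chain where `A.right_fusion == B.left_fusion`. With all left
and right fusion sites unique and the two multisets equal, every
fragment has exactly one successor; the reaction succeeds iff the
successor permutation is a single cycle. Failure classification follows
what a pot would actually do: duplicated left/right sites → `ambiguous`
(checked first, since a duplicate usually also strands another site);
unpartnered sites → `incomplete`; several disjoint cycles →
`multiple_circles`. An exhaustive-enumeration oracle (all circular
orderings, rotations identified) backs the classifier in tests:
success ⇔ exactly one valid ordering, ≥2 orderings ⇒ ambiguous.

Ligation is chemically orientation-agnostic, so a fragment whose forward
orientation has no partner is retried reverse-complemented
(`try_reverse_complement=True` by default), with a diagnostic recorded;
kits are designed so this never triggers, and the flag exists precisely
to surface designs that violate that.

The product's origin is fixed at the left fusion site of the
first-listed fragment, so re-running a campaign yields byte-identical
GenBank output. Feature annotations are carried with shifted
coordinates; a feature reaching past the final junction wraps across the
product's origin.

## Grammars and campaigns

A MoClo grammar is an ordered list of typed positions with optional
expected fusion-site pairs, a subpart separator (default "."), and a
naming convention (joiner between part names, id prefix, zero-pad
width). Validation checks circular coherence (right fusion of position i
= left fusion of position i+1, last wraps to first) and duplicate-free
fusion usage; templates are only generated for coherent grammars.
When expected fusions are declared, the simulator cross-checks each
digested insert against its position and records a warning diagnostic on
mismatch without failing the row — the physical reaction is governed by
the real overhangs, not the annotation.

Campaign files are comma/semicolon/tab-delimited text (delimiter
sniffed; XLSX accepted via pandas) with the output name in column 1
(blank → composed from part names with the joiner). Typed mode enforces
the grammar's arity, allows blank cells only on positions marked
optional, and splits subpart cells; raw mode accepts any arity and skips
blanks. Resolution order per token: direct plasmid-id hit, then mapping
by (name, type) with fallback to an untyped mapping row; in raw mode a
name mapped under several types is an explicit ambiguity error rather
than a guess. Cross-file mapping collisions are load errors, not
last-wins — silent precedence is how campaigns pick the wrong Venus.

Rows are simulated independently; every failure is captured per-row with
the row number and offending token in the message. Product ids are
prefix + zero-padded counter continuing past the largest counter already
in the database, so chained campaigns never collide. `DB_produced`
(part_name, part_type, plasmid_id) is directly loadable as a mapping,
closing the loop for follow-up campaigns. Provenance is a JSON record
per success (inputs, enzyme, product id, software version); a timestamp
is included only when the caller supplies one (the CLI passes wall
clock), keeping library output deterministic.

## Verification

Primer binding is exact full-length string matching — no mismatch or
3′-anchor model, because a hybridization model would add parameters the
simulation cannot justify while destroying determinism. Amplicon length
is measured 5′ start of the forward primer to 5′ start of the reverse
primer, inclusive of both primers (documented because "between 3′ ends"
is the other defensible convention). All productive pairings are
reported when a primer binds more than once, with a warning. Analytical
digests pool cut positions across enzymes (palindromic cutters EcoRI,
BamHI, HindIII, XhoI, NotI are built in alongside the Type IIS table);
circular templates with n cuts give n fragments, linear n+1, summing to
the template length. The gel image maps band position to
`a − b·log10(size)` with fixed constants; it is presentational — the
size table is the tested artifact.

## Quantitation

Equimolar dosing uses the standard 650 g·mol⁻¹·bp⁻¹ average dsDNA base
pair mass (module constant): `ng = fmol × bp × 650e−6`. Volumes below
the pipettable minimum get the smallest power-of-ten pre-dilution that
clears it (powers of ten because that is what a bench scientist actually
prepares). Master-mix totals are per-reaction volume × usage count ×
dead-volume factor, computed exactly; CSV exports round to 2 decimals
(pipettor resolution). Target molar amount, reaction volume, minimum
pipettable volume and dead-volume factor are user parameters with no
privileged defaults. Picklist wells are assigned row-major A1..H12 with
a plate index column beyond 96 reactions.

## Synthetic kits (what the generator does and does not emulate)

`make_kit(n_positions, parts_per_position, enzyme, seed)` builds a
miniature coherent kit: fusion sites drawn from non-palindromic k-mers,
excluding any k-mer whose reverse complement is already chosen
(mirroring real kit rules against self-ligation), chained into one
circle; entry plasmids laid out as
`recognition · spacer · L · payload · R · spacer · revcomp(recognition) · stuffer`,
with payloads 20–200 bp and stuffers 250–500 bp resampled until exactly
one recognition occurrence per strand remains. Everything is a pure
function of the seed, so written files are byte-identical across runs.
`make_campaign` draws random valid part combinations and can inject
defects (typo'd name, wrong type) recorded in a sidecar manifest.

What this does *not* emulate about real kits: real overhang sets with
measured ligation-fidelity profiles, methylation-sensitive or star
activity, multi-level (cassette-of-cassettes) grammars, and realistic
plasmid sizes (real entry vectors are kilobases of backbone). Passing
tests therefore demonstrate the correctness of the cut/join/bookkeeping
logic under clean MoClo design rules, not robustness to poorly designed
overhang sets — near-cognate overhang ligation is explicitly out of
scope.

## Problem sizes

The test suite and the acceptance script use small, fixed problem
sizes chosen to exercise every code path while keeping runs quick:
kits of 2–8 positions × 1–2 parts, campaigns of 2–6 rows, 500 random
circles (≈1–4 kb each) for conservation, brute-force assembly
enumeration up to 7 fragments (≤720 orderings), and 20-trial batches
for PCR/digest arithmetic. All quantities reported by
`scripts/acceptance.py` are recomputed from scratch on each run from
the seed passed on the command line.

## Known limitations

- Single-enzyme reactions only; dual-enzyme Golden Gate, PCR-based part
  homing and external database connections are out of scope.
- Exact-match primer binding means primers with SNPs against the
  template simply do not bind.
- Fragment orientation rescue flips one fragment at a time based on
  local partner availability; pathological sets where only a joint
  flip of several fragments chains are reported as failures rather
  than searched exhaustively.
- The typed mode requires a type for every part; names are never
  resolved by uniqueness alone when a grammar is active.
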