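# Methods

## Scope and model

`heliscan` annotates helitrons — rolling-circle class-II transposons —
from structure and homology alone. The model of an element is:

```
5'  T[C/G] | head/body (optionally RepHel ORF + captured genes) |
    arm (>= 6 WC pairs, <= 2 mismatches) | loop (2-4 bp) | arm' |
    spacer (5-8 bp) | terminal 4-mer in {CTAA, CTAG, CTGA, CTGG, CTTG}  3'
```

inserted between an A and a T of the host, with no target-site
duplication. The 3' structural signature (hairpin + spacer + terminus),
called a *helend*, anchors everything: it is the only part of an element
detectable without a second copy or a protein signal.

Assumptions: DNA-level hairpin pairing is strict Watson–Crick (A–T,
G–C, no G·U/G·T wobble — the structure is a DNA duplex, not RNA); family
identity is carried by the terminal 30 bp of the 3' end; copies of one
element share sequence from the 5' start to the 3' terminus while their
flanks are unrelated; autonomous elements encode Rep and PIF1-family
helicase domains on the element's forward frames upstream of the helend.

## Stage 1 — structure scan (`helend` module)

Terminal 4-mers are located on both strands (minus-strand hits reported
in plus coordinates). For each motif occurrence every (arm, loop,
spacer) combination within bounds is evaluated; a combination is valid
when the stem has no N, at most `max_stem_mismatches` non-pairing
positions, and non-negative coordinates. Among valid geometries the
scanner keeps the best under the declared tie-break:

1. maximal stem pairs, 2. minimal mismatches, 3. minimal spacer,
4. minimal loop

— prefer the strongest, most proximal structure. One candidate is kept
per (scaffold, strand, terminus end position). The production scan is
vectorised (numpy over all motif positions per geometry); the test
suite proves it equal to a plain exhaustive enumeration on random
60-mers and 10-kb genomes.

A geometric consequence worth knowing: bounds are enforced on the
*reported window*, not on whatever structure was "intended". A perfect
stem with, say, a 5-bp loop always admits a compensating in-bounds
window around the same palindrome centre with at most two extra
(possibly mismatching) pairs, so such a structure is reported with a
compliant geometry rather than rejected. Only structures needing more
than `max_stem_mismatches` extra chance pairs to compensate (e.g. a
spacer 4 bp beyond the maximum) are truly invisible. The simulator's
decoys are built accordingly.

| parameter | default | unit | rationale |
|---|---|---|---|
| `min_stem_pairs` | 6 | bp | canonical minimum stem |
| `max_stem_mismatches` | 2 | positions | canonical tolerance |
| `loop_min..loop_max` | 2..4 | bp | canonical loop range |
| `spacer_min..spacer_max` | 5..8 | bp | hairpin-to-terminus distance |
| `terminal_motifs` | CTRR + CTTG | 4-mers | CTRR expansion plus the known CTTG-terminated family |
| `max_stem_pairs` | 20 | bp | generous cap above the reported 16–20-nt hairpins |

## Stage 2 — families and boundaries (`families` module)

**Identity** is gapless (Hamming) percent identity over equal-length
30-mers; positions with N never match. At 30 bp and an 80% threshold a
gapless comparison is the simplest faithful reading of "30 bp with at
least 80% identity"; 24/30 matches joins (inclusive boundary), 23/30
does not.

**Families** are the single-linkage transitive closure of the ≥ 80%
relation on 3'-terminal 30-mers (oriented on the element strand,
terminus included). Closure makes the partition well-defined and
deterministic; it matches connected components of the thresholded
identity graph (tested against an independent graph oracle). Family ids
are assigned by descending member count, ties by leftmost genomic
coordinate. Genome-scale inputs use a block-vectorised pairwise
comparison; the scalar `end_identity` defines the semantics.

**5' boundaries.** For each member, windows up to `boundary_window`
(default 3000 bp, configurable; elements longer than the window cannot
have their start located) upstream of the 3' terminus are compared with
every sibling, end-anchored. The *conservation edge* is the farthest
distance from the terminus at which a 30-bp window still reaches the
identity threshold with at least one sibling **and** the first bases of
the window agree with every supporting sibling (a 6-base guard). The
guard matters: all copies share the host junction A immediately 5' of
their start, and without the guard chance flank matches drag edges a
few bases into the flank.

A truncation cut is itself a conservation edge, so an edge alone does
not prove a 5' end. The boundary rule is therefore *recurrence*: each
member's edge is snapped to the nearest T[C/G] within 3 bp, and a
member is intact only when its snapped depth (distance from the 3'
terminus) is shared by at least two members. Genuine element starts
recur by construction; truncation cuts are uniform per copy and
essentially never collide. Conveniently, the junction A makes the two
positions just outside a true start ineligible as T[C/G], so at low
divergence the snap is exact. Members without a recurring start are
truncated; their 5' extent is the conservation edge itself (identifiable
only to ~1–2 bp because a sibling body base equal to A is
indistinguishable from the host junction A).

**Subfamilies** re-run single linkage on the 5'-terminal 30-mers
(starting at the located T[C/G]) of intact members; truncated members
stay unassigned. **Names** are `PREFIX<family>.<subfamily>`, uppercase
iff putative autonomous.

## Stage 3 — RepHel homology (`rephel` module)

The window upstream of each helend (default 3600 bp, measured upstream
of the hairpin's 5' arm, oriented to the element strand) is translated
in the three forward frames; stops are rendered `*` and do not halt
translation. Nine degenerate amino-acid patterns are slid over each
frame: rep1–rep3 for the rolling-circle initiator (HUH metal-binding
and catalytic-tyrosine grammar) and helI–helVI for the SF1/PIF1
helicase (Walker A/B and companions). The shipped patterns
(`data/rephel_motifs.txt`) are editable approximations written from the
canonical motif grammar of these protein families; replace them with a
project-specific consensus when available. A window position hits when
at least `min_score` pattern positions match.

Default autonomy policy: ≥ 2/3 rep motifs AND ≥ 4/6 helicase motifs,
with the rep block upstream of the helicase block, all inside the
element once the 5' boundary is known. The published criterion is
domain *presence* (PF14214 + PF05970) within boundaries; the counts are
this package's operational reading, and an external tab-separated
domain table (query id `<candidate>|f<frame>`, E-value cutoff 0.01)
reproduces the domain-presence route exactly and wins over the built-in
scanner when supplied. Elements with the helicase signal but no rep
block are flagged orphan helicases, not autonomous.

The RepHel span is the hull of contributing motif hits extended to the
nearest in-frame stop codons; hulls in different frames merge when
collinear within 1 kb (introns and indels shift frames in real
elements).

## Curation (`pipeline` module)

Random ~50% GC sequence satisfies the helend geometry roughly once per
70 bp of motif occurrences (~14,000 chance candidates per Mb), so raw
structural hits need the same kind of false-positive removal the
original protocol did manually. Two automated rules:

* **Validated families** need ≥ `min_family_size` (default 2) members;
  singletons survive only via RepHel homology rescue (ORF + upstream
  T[C/G] within `rescue_tc_search` = 200 bp), and only when the rescued
  span does not overlap a family-derived element.
* **One element per locus.** Repeated copies make chance helends
  *inside* a real element cluster into genuine-looking families, and
  mirrored (+/−) copy pairs can project chance structures onto spans
  straddling two real elements. Elements are admitted by priority —
  larger family first, then longer span — and anything overlapping an
  admitted element by more than 10 bp is dropped as its shadow. A
  minimum element length (default 100 bp) removes bare-helend scraps.

Consequences to be aware of: genuinely nested helitrons are reported
only as the outer element, and tandem elements closer than 10 bp would
be collapsed.

## Annotation and expression

* **Captured genes**: full-length gene models (GFF3) inside intact
  element boundaries, excluding anything overlapping the RepHel span or
  flagged as a RepHel model.
* **Insertion site**: the A|T rule is strand-symmetric, so the check
  reads the plus strand: base before start = A, base after end = T.
  Scaffold-edge elements are indeterminate, not false.
* **Flank composition**: AT fraction of the 50-bp flanks, per element
  strand and pooled.
* **Fragment search**: exact 20-mer seeds, ungapped two-sided X-drop
  extension (match +1, mismatch −2, drop 6), per-diagonal merging;
  hits must exceed 50 bp and 95% identity (both strict). This replaces
  a BLASTN step; without BLAST statistics there is no E-value, so the
  thresholds are length/identity only — a documented deviation.
* **RPKM** = count × 10⁹ / (total mapped reads × feature length).
  Input is a placement table (read id, scaffold, start, end, placement
  count); each placement of a multi-mapped read counts fully, and the
  library size is the number of *distinct* read ids. Overlap counting
  is interval-tree backed and strand-agnostic.

## The simulator (`simulate` module)

The generator emulates the study conditions end to end: multi-scaffold
i.i.d. background at 51% GC (49% AT), three families × two subfamilies
× five copies (30 elements) by default, one RepHel-bearing subfamily
per family (half the copies autonomous by template), 20% truncation,
AT-dinucleotide insertion with 57%-AT 50-bp flanks, per-subfamily
bodies of 0.8–2.4 kb, and mandatory seeds with byte-identical reruns.

Constraints enforced at generation: family tails mutually < 80%
identical over the last 30 bp; subfamily heads of one family < 80%
identical over the first 30 bp; every copy lands between an A and a T
(the 49 drawn flank bases use an AT rate chosen so the measured 50-bp
flank, junction base included, averages exactly the configured
fraction). Truncated copies keep a uniform 35–65% 3' fraction; point
mutations (default rate 0) spare both terminal 30-mers so family
membership stays a controlled variable. The RepHel ORF is a compact
(~150 aa) concatenation of the shipped motif consensus blocks with
randomized linkers and codon usage per subfamily — protein-level
homology with DNA-level divergence, like real RepHel genes; a natural
~1400-aa RepHel would simply make elements larger without changing
what the tests exercise. Reads are placed uniformly within elements at
Poisson counts proportional to rate × length × depth, plus uniform
background.

What passing the round-trip shows — and what it does not: the pipeline
recovers exactly what the model says should be recoverable
(coordinates, partitions, autonomy, cargo) when real elements satisfy
the canonical geometry, diverge < 20% at their termini and come in ≥ 2
copies. Real genomes add repeat-rich flanks, segmental duplications,
degenerate old copies and assembly gaps, none of which the background
model contains; on real data the curation rules and thresholds should
be treated as starting points, not guarantees.

## Numerical and degenerate-input conventions

* Coordinates are 1-based inclusive everywhere outside internal numpy
  code; BED output converts at the boundary.
* N never pairs in stems (stems containing N are rejected outright),
  never matches in identity, and is excluded from AT/GC denominators;
  all-N composition queries raise rather than return 0.
* Lowercase (soft-masked) input is uppercased; masking is discarded.
* Ties everywhere break deterministically (documented orderings), so
  identical inputs and configuration give identical output bytes; every
  CLI output carries the tool version and a config hash.
* Candidates whose 30-mer is clipped by a scaffold edge are excluded
  from clustering (flagged); windows clipped at scaffold edges are
  flagged rather than silently shortened.

## Known limitations

* Elements longer than `boundary_window` cannot have conservation-based
  starts; raise the window for large-element genomes.
* Boundary recurrence needs two intact copies per subfamily; a
  subfamily with one intact copy is reported truncated unless rescued
  by homology.
* At per-copy mutation rates above a few percent the 6-base edge guard
  undershoots and boundary calls degrade before family clustering does.
* The motif patterns ship as approximations; for publication-grade
  autonomy calls run an offline CDD/HMMER search and import the hit
  table.
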