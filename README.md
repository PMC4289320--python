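# heliscan

Identification, classification and annotation of **helitrons** — class-II
transposable elements that move by rolling-circle replication — in
assembled genomes, with a synthetic-genome simulator that makes the whole
pipeline testable end to end without any downloads.

Helitrons are hard to find because they lack the usual class-II landmarks
(no terminal inverted repeats, no target-site duplication). What they do
have is a stereotyped architecture:

```
5'  T[C/G] ............ body (RepHel ORF, captured genes) ............
    [hairpin arm]  [loop 2-4 bp]  [hairpin arm']  [spacer 5-8 bp]  CTRR  3'
```

* a 5' **T[C/G]** start,
* a 3' **CTRR** terminus (R = purine; one known family ends in **CTTG**),
* a subterminal palindromic **hairpin** — at least 6 Watson–Crick stem
  pairs with up to 2 mismatches, a 2–4 bp loop, 5–8 bp between hairpin
  and terminus,
* insertion precisely **between an A and a T** of the host, and
* in autonomous copies a **RepHel** protein: a rolling-circle replication
  initiator (Rep) fused to a PIF1-family (SF1) helicase (Hel).

`heliscan` is written for people annotating repeats in fungal (or other
compact) genomes who need more than a k-mer repeat masker: it reports
family structure, element boundaries, autonomy, captured genes and
expression for this one family of elements.

## The method

1. **Structure scan (helends).** Both strands of every scaffold are
   scanned for terminal 4-mers with a compliant upstream hairpin. Among
   alternative geometries the scanner keeps the strongest, most proximal
   structure (max stem pairs, then min mismatches, min spacer, min
   loop). Detection is exhaustively verified against brute-force
   enumeration in the test suite.
2. **Family classification.** Elements whose 3'-terminal 30-mers share
   ≥ 80% identity (gapless, inclusive at the boundary) belong to one
   family; the rule is closed transitively. Families split into
   subfamilies where 5'-terminal 30-mer identity drops below 80%.
3. **5' boundaries.** Sibling copies share sequence from the 5' T[C/G]
   to the 3' terminus while their flanks are unrelated, so the boundary
   is recovered as a conservation edge that snaps to a T[C/G] at a
   depth recurring in ≥ 2 members. Elements with such a boundary are
   **intact**; elements with only the 3' helend are **truncated**.
4. **Autonomy (RepHel).** 3600 bp upstream of each helend is translated
   in the three forward frames and scanned with degenerate Rep (3) and
   helicase (6) motif patterns; ≥ 2/3 Rep plus ≥ 4/6 helicase motifs
   with Rep upstream of Hel calls the element putative autonomous. An
   external domain-hit table (offline CDD/HMMER against PF14214 +
   PF05970) can replace the built-in scanner.
5. **Annotation & expression.** Captured genes (full-length gene models
   inside boundaries, RepHel excluded), A|T insertion-site checks,
   50-bp flank AT content, a seed-and-extend search for captured-gene
   fragments (> 50 bp, > 95% identity), per-genome summary tables, and
   RPKM per element from a read-placement table.

Elements are named `PREFIX<family>.<subfamily>`, uppercase for putative
autonomous copies and lowercase otherwise (e.g. `HEL1.1` vs `hel1.3`).

## Worked example

Simulate a 200-kb two-scaffold genome with 30 planted helitrons (three
families, two subfamilies each, 20% truncated copies), then run the
full pipeline on it:

```bash
heliscan simulate --seed 11 -d sim --genome-length 200000 --scaffolds 2 --depth 20
heliscan -v pipeline sim/genome.fa --genes sim/genes.gff3 \
         --placements sim/placements.tsv -d out
# INFO 30 elements (22 intact, 7 autonomous), 17.556% of the genome
```

All 30 planted elements are recovered and nothing else. `out/summary.tsv`
holds one row per element:

```
name    scaffold    start  end    orientation  size_kb  autonomous  captured_genes  intact  rpkm
hel1.1  scaffold_1   7049   7947  +            0.9                  capA            *        2110.43
HEL2.2  scaffold_1  15098  17400  -            2.3      *           capA            *       46663.98
hel3.1  scaffold_1  20464  21570  +            1.1                  capA            *        4284.72
```

`hel1.1` is an intact, non-autonomous member of family 1, subfamily 1,
0.9 kb long, carrying one captured gene; `HEL2.2` (uppercase) also
carries the RepHel ORF and is therefore putative autonomous. The `rpkm`
column is reads per kilobase per million mapped reads computed from the
supplied placements (the simulated library is small, hence the large
values). `out/elements.gff3` carries the same calls as
`mobile_genetic_element` features with `polypeptide_motif` children for
the RepHel spans, and `out/candidates.tsv` the raw helend scan.

The same steps are available as a library (`heliscan.run_pipeline`,
`heliscan.simulate.simulate`, …); the CLI is a thin wrapper.

## Limitations

* Boundary calls need ≥ 2 copies sharing a 5' end; isolated autonomous
  elements are recovered only through the RepHel homology route, and
  single-copy non-autonomous elements are reported as truncated or not
  at all (mirroring the curation logic of structure-based annotation).
* Truncated 5' edges are identifiable only to within a couple of bases
  (the host A|T junction is shared by every copy).
* The fragment search is a deterministic seed-and-extend scan with
  length/identity thresholds; it does not compute E-values.

See `docs/methods.md` for the full model description, parameter table
and design rationale.
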