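# Methods

## Background and model

Kink-turns (k-turns) are duplex-RNA motifs in which a three-nucleotide bulge
followed by tandem G•A and A•G pairs kinks the helical axis by roughly 50°,
juxtaposing the minor grooves of the flanking canonical (C) and
non-canonical (NC) helices. Positions are named outward from the bulge:
-1b/-1n precede it on the C-helix side, L1–L3 are the bulge, 1b/1n and 2b/2n
are the conserved G•A/A•G pairs, and 3b/3n, 4b/4n continue into the NC
helix (b = bulged strand, n = non-bulged strand).

Kinked k-turns fall into two conformational classes distinguished by the
acceptor of the hydrogen bond donated by the -1n ribose O2′: either A2b N3
(the **N3** class) or A2b N1 (the **N1** class). The switch requires a
rotation of the A2b base, so in N1 structures the A2b N6 – G2n N3 pairing
bond is lost (the distance is typically > 4 Å) and the local helix widens:
the C1′–C1′ distance across 2b•2n moves from about 8.9 Å (N3) to about
10.2 Å (N1), and across 3b•3n from about 9.6 Å to about 11.3 Å, while the
Watson–Crick 4b–4n pair stays near 10.55 Å. The basepair at 3b,3n is the
principal sequence determinant of both the class and of whether the k-turn
folds in metal ions alone; this package implements the classifier, the
width statistic, the basepair-family typing, the 3b,3n rule table and a
population-scale sequence profiler around that model.

## Hydrogen-bond calling

Crystal structures in the relevant resolution range (1.7–3.3 Å) carry no
hydrogens, so bonds are called on heavy-atom donor–acceptor distance only,
with no angular term:

* `bonded_max` = 3.5 Å — at or below, *bonded*;
* `broken_min` = 4.0 Å — at or above, *not bonded* (matching the convention
  that > 4 Å distances in these cores are not hydrogen bonded);
* between the two, the verdict is explicitly *ambiguous*.

Both cutoffs are configurable (`GeometryParams`, CLI `--bonded-max` /
`--broken-min`). The classifier's decision rule: if neither O2′→N3 nor
O2′→N1 is bonded the core is not kinked (*extended*); if both are bonded
the shorter wins unless they differ by less than the `ambiguity_margin`
(0.3 Å, a safety net — observed structures never show both bonded); the
secondary N6–N3 bond must agree with the primary call (present for N3,
absent for N1), and any disagreement downgrades the call to *ambiguous*
with all distances reported. Ambiguous and extended are explicit states;
nothing defaults silently to a class.

## Width statistics

C1′–C1′ distances are measured per named pair (2b2n, 3b3n, 4b4n); values
below 4 Å are flagged implausible. Every crystallographically independent
copy is one datum, matching how multi-copy asymmetric units are counted in
the structural literature; `width_statistics(collapse=...)` (CLI-exposed
as a per-k-turn collapse) instead averages copies first, since published
means do not state which weighting they used. SD is the sample estimator
(ddof = 1), stated in the output metadata, because the source statistics do
not say which estimator was applied.

## Basepair-family typing

The 3b,3n pair is typed with a deliberately simplified Leontis–Westhof
scheme sufficient to separate the only two families observed at this
position (trans Hoogsteen/sugar-edge and cis Watson–Crick): inter-base
hydrogen bonds are enumerated over polar base atoms; each base's bonded
atoms vote for the edge(s) they belong to (a packaged base→edge→atoms
table; shared atoms such as G O6 vote for both of their edges), majority
wins with ties broken by the edge holding the shortest bond; cis/trans is
the side test of the two C1′–glycosidic-nitrogen vectors about the axis
joining the glycosidic nitrogens. Full reference-frame fitting of all
twelve LW families is out of scope; pairs with no inter-base bond are
*undetermined*.

## The rule table

Ion-induced folding is a closed-form rule: 3b = C or 3n = G confers
folding, except that a Watson–Crick 3b,3n pair (A–U, U–A, G–C, C–G —
wobbles excluded) never folds; the Watson–Crick rule dominates, so C–G does
not fold. Conformation has no closed form and ships as a 16-cell lookup
table (`data/rule_table.tsv`, human-editable, one provenance string per
cell). Cells anchored in unambiguous published statements: U•G→N1, A•G→N3
(with the ribosomal HmKt-7 copy recorded as the forced-N1 exception),
G–C→N3, U•U→N3, G•G→N1, C•A→N1, C•C→N1. The remaining determined cells are
constrained rather than individually quotable, and were fixed once from
the joint constraints that five of the six newly determined variant cells
{C•A, C–G, C•U, G•G, U–A, U•C} are N1; that A•G is the unique cell that is
both N3 and ion-folding (forcing C•U to N1 and the single N3 of the six to
lie in {C–G, U–A, U•C}); that six of the eight pyrimidine-3b cells are N1;
and that 3b = purine tends to N3 with G•G the only stated exception. The
resulting assignments (C–G, A•C, G•A, G•U → N3; U–A, U•C → N1) carry the
provenance tag "figure (graphical), transcription uncertain" and are the
natural cells for a user to override. Two cells are unknown: A–U (no
variant structure was obtained; survey data suggest it is N3-forming) and
A–A.

`build_rule_table` reconstructs a table from classified structures by
per-cell majority vote — unanimous cells take the class, split cells take
the majority with the minority recorded in `exception_notes` (modelling the
ribosomal A•G exception), exact ties become unknown with a warning — and
round-trips the packaged table from its own evidence list.

## Sequence profiling

Alignments (FASTA/Stockholm/Clustal) are upper-cased with T→U; the 3b and
3n alignment columns are explicit 1-based user inputs, since k-turn regions
are aligned manually in practice and automatic column inference would be
guesswork. Rows with a gap at either column are excluded with reason
`gap`, other non-ACGU characters with reason `ambiguous`; percentages are
over the included rows by default (`--denominator all` divides by all rows
instead — the published "percentage of the total" is ambiguous on this
point). Wobble and non-canonical combinations are never filtered: the 4×4
array is over raw base combinations. `summarize` multiplies the cell
fractions into population fractions of predicted N3/N1/unknown conformation
and folding/non-folding, which equals per-sequence classification followed
by averaging.

## Synthetic data

The structure generator emits idealized minimal cores (the classifier's
required atoms, plus full planar base-atom sets at 3b/3n so family typing
is exercised) meeting the class target distances exactly at zero jitter:
donor–acceptor 2.9 Å for bonded and 5.2 Å for non-bonded O2′ contacts,
N6–N3 2.9 Å (N3) or 4.6 Å (N1), and the class mean widths 8.93/9.59 Å (N3),
10.17/11.30 Å (N1) and 10.55 Å at 4b4n. A•G 3b,3n pairs are built as trans
Hoogsteen/sugar-edge, all other combinations as generic cis pairs with
facing Watson–Crick edges. Noise is i.i.d. per-coordinate Gaussian jitter
(default study level 0.1 Å), the simplest model that exercises cutoff
robustness. The generator does **not** model backbone connectivity, sugar
puckers, base-plane stacking, crystal packing, density quality or
correlated coordinate error, so passing tests demonstrate the correctness
of the distance logic and statistics, not performance on real
crystallographic coordinates.

The alignment generator draws 3b,3n jointly i.i.d. from a specified 4×4
distribution into a fixed synthetic scaffold (placeholder columns marked
`b`/`n`), with optional flank substitution noise. The packaged Kt-7-like
distribution fixes the two published cells (U•G 92.06%, A•G 0.29%) and
splits the remaining mass over plausible minor cells (C•A 4.0, C•C 2.0,
C•U 1.0, G•G 0.35, G–C 0.20, U•U 0.10%) such that the population
aggregates equal the published survey values (99.41% N1-conferring, 99.70%
ion-foldable); real surveys have phylogenetically correlated rows and
row-specific gaps, which the generator does not emulate.

## Numerical choices and problem sizes

Coordinates serialize at PDB fixed-point precision (3 decimals) in both
PDB and mmCIF output, so the two formats read back identically. Distance
comparisons in rigid-motion invariance tests hold to 1e-9 Å. Frequency
recovery is judged against conservative per-cell 99% binomial
(Clopper–Pearson-style) intervals. The test suite and the acceptance
script use 100 synthetic copies per class at jitter 0.1 Å, 100 replicate
alignments of n = 5000 for recovery, and n = 2722 (the bacterial Kt-7
survey size) for the population summary — sizes chosen to give stable
statistics on a desktop in seconds.

## Known limitations

* The conformation table's graphically-stated cells are reconstructed from
  textual constraints (see above) and marked as such; users with access to
  the primary structural data can edit `rule_table.tsv`.
* The basepair-family typing is distance-only and two-family; it will
  report chemically impossible "bonds" (e.g. O···O) on adversarial
  geometries, which is acceptable for the synthetic cores it is applied to
  but not a general-purpose LW annotator.
* No de-novo k-turn detection: annotations mapping nomenclature positions
  to residues are user input.
* Validation against deposited crystal structures requires downloading the
  relevant PDB entries and supplying annotations; the pipeline supports it
  (`kturnlab classify/widths/bp-family`) but the shipped tests run entirely
  on synthetic data.
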