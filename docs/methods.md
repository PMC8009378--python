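# Methods

## The engineered reference

The reference is a synthetic stand-in for yeast chromosome III carrying a
conditional dicentric. The background is i.i.d. random DNA (default GC
content 0.38, length 316,620 bp, deterministic per seed); every feature the
downstream analyses read is placed at its published coordinate, so nothing
depends on the real chromosome III sequence:

- eCEN3: a 125 bp centromere core starting at 114,300, sitting inside a
  336 bp homology block (core offset 105 within the block). The diagnostic
  eC1/eC2 primer sites are written convergently around it; their amplicon
  length is configurable (default 900 bp — the true eCEN3 product size is
  not printed anywhere, so this is a free plumbing choice).
- GALCEN3: a 932 bp cassette written over the background at the insertion
  site: GC1 site, a 200 bp GAL-promoter stub, a verbatim copy of the 336 bp
  eCEN3 homology block (with its own copy of the 125 bp core), a spacer,
  and the reverse-complemented GC2 site. The cassette core starts exactly
  at the configured insertion coordinate, so the SSA deletion equals the
  printed CEN–CEN distance, and the GC1–GC2 amplicon is exactly 932 bp.
  The bases immediately flanking the homology copy are forced to mismatch
  their eCEN3 counterparts, making the shared block exactly 336 bp long.
- Annotations: the Ty2-1 element at 84,811–90,769; essential genes RRP7
  (between the 57.7 and 46.3 kb insertion sites) and NFS1 (between 46.3 and
  18.2 kb), and the fitness gene PGS1 (between 6.5 kb and eCEN3). Exact gene
  coordinates are not published; each is a 1.5 kb interval at the midpoint
  of its flanking insertion sites, because only interval membership between
  deletion breakpoints matters to the viability audit. All three are
  configurable.

The cassette *overwrites* a window of the background rather than inserting
into it, so one coordinate frame covers both centromeres and the published
coordinates remain valid verbatim. Coordinates are 1-based inclusive
throughout the API; BED export converts to 0-based half-open.

Two printed kb labels disagree with round-half-up arithmetic on the printed
coordinates (114,300 − 96,020 = 18,280 bp, labelled 18.2; 114,300 − 56,740 =
57,560 bp, labelled 57.7). `cen_cen_distance` always reports the computed
round-half-up value; the printed labels are kept in
`genome.PAPER_KB_LABELS` and used as cohort labels only.

## The division/repair model

Each division of a cell with an active dicentric breaks the bridge with
probability `p_break` (default 0.5, the published per-division estimate).
The break coordinate is a two-component mixture over the open
inter-centromeric span: with weight `break_locality_weight` (default 0.5)
uniform over the ≤10 kb windows flanking either core (clipped to the span —
at 6.5 kb the windows cover the span and the mixture degenerates to
uniform), otherwise uniform over the whole span. This encodes the
observation that about half of dicentric breaks fall within 10 kb of a
centromere.

Repair pathway choice is *calibrated configuration, not prediction*: a
distance-labelled weight table (6.5 kb SSA-dominant; 9.8–18.2 kb
EJ-dominant; 46.3 kb crossover-dominant; 57.7 kb mixed) reproduces the
observed regime structure, because the underlying mechanism
(resection kinetics, checkpoint biology) is outside scope. Genotype
backgrounds multiply these weights: the recombination null zeroes SSA and
crossover; the ligase null zeroes end joining (so its colonies shift to
homology-based products with little viability cost, as observed); the
replication-checkpoint mutant applies ×0.1 to the homology pathways only
beyond 20 kb — a phenomenological stand-in, flagged as such. The pathway
draw renormalizes the surviving weights; if all are zero the break goes
unrepaired and the colony dies.

Because renormalization alone would let the recombination null repair
everything by end joining (flat viability, contrary to the observed decline
with distance), genotypes may also carry a per-break lethality by distance
label. The defaults for the recombination and checkpoint nulls are
monotone-increasing calibrations chosen once to reproduce the qualitative
trend; they are not fitted to the published percentages, which this
simulator does not claim to reproduce.

Product structures:

- SSA: one linear chromosome = prefix through the cassette homology block
  joined to the suffix from the end of the eCEN3 block; the deletion equals
  the CEN–CEN distance exactly and the product carries the hybrid GC1–eC2
  centromere.
- RCO: the same linear product plus a circular chromosome carrying exactly
  the inter-centromeric segment and the reciprocal eC1–GC2 centromere. The
  second exchange needed for circularization is folded into one composite
  event, since only product structures are observable downstream; the
  pipeline labels these colonies HR without claiming single-crossover vs
  two-SSA origin.
- EJ: a two-cut deletion of size uniform on 278–585 bp positioned to cover
  the whole 125 bp core while sparing the flanking primer sites; GALCEN3 is
  chosen with probability 0.7. Junction microhomology is *emergent*: the
  placement is resampled (up to 400 draws) until the realized junction
  microhomology computed from the actual flanking sequence lies in
  `ej_mh_range` (default 1–9 bp) — modelling end joining's preference for
  sealing where terminal microhomology exists. On random sequence this
  yields mostly 1–3 bp junctions; the deletion-size distribution is
  unaffected because size is drawn before placement.
- refusion: the dicentric is restored and the BFB cycle continues.

A colony is approximated by its founder lineage (one surviving lineage sets
the colony genotype, matching the single-colony PCR readout): divisions
iterate until the karyotype is stably monocentric, death, or `max_cycles`
(default 20). Nondisjunction (default 0.01/division) duplicates a
chromosome within the lineage, which is how mixed patterns such as
aneuploid colonies arise. Viability requires every essential gene on some
chromosome and a centromere on every chromosome; PGS1 loss flags
slow growth — which is why the 6.5 kb SSA derivative is viable but
slow-growing, and why the SSA linear product is lethal beyond 18.2 kb
unless the reciprocal circle is retained.

## In-silico PCR and the decision key

Amplicon prediction is exact string matching of the forward primer and the
reverse complement of the reverse primer (both orientations), reporting
every convergent pair within `max_amplicon` (default 6 kb); circular
templates are searched across the origin. No thermodynamics, mismatch
tolerance, or size-estimation error is modelled, because the synthetic
references embed exact sites. A parental band counts as wild type within
50 bp of its expected size; anything shorter is reduced (a reduced parental
band means the centromere itself was deleted).

The decision list, evaluated in order: HR (both hybrids, no parentals);
aneuploid (rearrangement plus any parental); SSA (rearrangement only);
SSA+EJ (reciprocal plus intact eCEN3 only); unrearranged (both parentals,
no hybrids); EJ (exactly one parental, no hybrids); otherwise unclassified.
The published key does not state a precedence; this order maps every listed
pattern to its stated class and sends conflicts to the more information-rich
class, with unlisted patterns (e.g. reciprocal + GALCEN3) left unclassified
rather than forced.

Circular-derivative contiguity mapping generates tiling primer pairs
(default 20-mers every 1.5 kb, 200 bp overlap) around a candidate circle
and reports whether the overlapping amplicons cover the full circumference.

## Junction analysis

For a reference/derivative allele pair, the caller takes the longest common
suffix, caps the longest common prefix so the two do not overlap, and reads
off the deletion interval and any inserted bases. Microhomology is the
matching run to the right of both cut sites plus the run to the left;
equivalent placements form a contiguous run of `mh_total + 1` positions and
the call is slid to the leftmost one. Junction mismatches are handled only
as insertions of the mismatched run; derivatives needing true realignment
(implied insertions beyond `max_insertion`) are rejected. The MMEJ label
needs ≥5 bp of junction homology, NHEJ ≤1 bp with no insertion, anything
between is ambiguous — a convention, configurable, since observed junctions
span 1–9 bp without a sharp dichotomy.

## Synthetic fixtures

`synth.fig4_cohort` emits cohort tables with exact class counts encoded as
canonical patterns; the packaged 57.7 kb panel uses the printed composition
(12/10/6/2 of 30 = 40/33.3/20/6.7%), while panels described only
approximately in the text carry `approximate=True` and are excluded from
exact checks. `synth.random_junction` plants deletions whose junction
realizes exactly the drawn microhomology by copying bases across the
junction *inside the to-be-deleted span* and forcing the bounding bases to
mismatch (so the planted homology is maximal and the planted interval is
the leftmost placement); it returns the locally adjusted reference allele
with the derivative, which is what makes round-trip recovery exact rather
than approximate. An optional zero-inflation parameter produces blunt
(0 bp) junctions, which are observed occasionally.

What passing tests show — and what they do not: the generators emulate the
*structure* of the real data (coordinates, primer geometry, homology,
deletion and microhomology envelopes, cohort compositions), not its
sequencing noise, PCR artefacts, mixed colonies, or the real chromosome III
sequence context (repeats near the Ty element could create PCR and
microhomology ambiguities the random background lacks). Observed mutant
viability percentages and non-fixture class distributions are experimental
outcomes; the simulator reproduces their qualitative trends only.

## Problem sizes and numerics

Default study sizes: 10,000 divisions for the breakage-rate estimate,
≥2,000 end-joining events for the deletion-bias estimate, 1,000 junctions
for round-trip recovery, 150–300 colonies per simulated cohort, three
100-founder replicates per plating — sizes at which the binomial standard
errors are comfortably inside the tolerances quoted with each estimate.
Per-colony RNG substreams derive from (seed, colony index), so cohorts are
order-independent and extendable. kb distances round half-up to one
decimal; viability is uncapped (plating noise can exceed 100%); the pooled
Student's t-test is the default comparison (Welch available), two
zero-variance identical groups return p = 1 by convention, and no
multiple-testing correction is applied, matching the published analysis.

## Known limitations

Telomere addition, break-induced replication, Ty-mediated interchromosomal
repair, whole-population colony dynamics, galactose/glucose induction
kinetics, and mechanistic replication-fork/checkpoint biochemistry are not
modelled. The refusion weight is a free parameter (no published rate), and
the per-break lethality tables are qualitative calibrations. The simulator
produces SSA+EJ and aneuploid colonies only via nondisjunction, so their
simulated frequencies are far below the observed 57.7 kb panel; that panel
is represented exactly by the packaged fixture instead.
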