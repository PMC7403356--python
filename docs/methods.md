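# Methods

## The model

`slbvic` implements a rule-based, event-driven model of Late Palaeozoic
(~350–250 Ma) biogeography in which the Siberian Land Bridge (SLB) — the
low-profile connection between the Siberian plate and Laurussia at the
southern end of the Uralian Seaway — alternately emerges and floods under
eustatic sea-level change.  Time is partitioned into:

* **junction intervals** — sea-level lowstands expose the SLB; eastern
  (Siberian) and western (Laurussia/Gondwana) Pangaea are terrestrially
  connected and whole biotas geodisperse;
* **disjunction intervals** — highstands flood the SLB; the two territories
  are isolated and lineages evolve endemically, splitting allopatrically.

Conventions used throughout: ages in Ma before present, larger = older;
intervals written `(older, younger)` and treated half-open
`[older, younger)`, so a boundary instant belongs to the older interval; a
level exactly equal to the exposure threshold counts as exposed (ties
resolve toward junction, since lowstands *outstripping* the reference line
are read as exposures).

### Phase-timeline synthesis

The timeline is synthesised in two regimes separated by a configurable
mode-switch age (default 273.0 Ma, the Kungurian/Roadian boundary):

* **Active era (older than the switch).**  The eustatic curve is
  authoritative.  Exposure windows are maximal sub-threshold intervals of
  the linearly interpolated curve, with a minimum duration (default 0.2 My)
  and a merge gap (default 0.1 My) — the source gives no minimum window
  size, so these are small, configurable guards against sampling blips.
  The default state is disjunction.  Crossing times are solved by linear
  interpolation between adjacent samples, which makes detection
  resolution-independent and testable against a dense-grid oracle.
* **Passive era (younger than the switch).**  Orogeny decouples the seaway
  from the global curve; the land-bridge region is predominantly
  terrestrial, so the default state is junction and each dated
  *transgression* event contributes one disjunction interval.  Ingressions
  known to have failed to break the land bridge (kind
  `failed_transgression`, e.g. Niendorf) contribute nothing.

The packaged event fixture stores printed ages where they exist (Bash 3 at
321 Ma, Bash 5 at 318, the early Roadian transgression at 273, the
Zechstein transgression at 258, P4 from 259.5 to 254.5, zone boundaries at
260.26 and 259.5) and figure-digitised positions elsewhere; every
figure-digitised row is flagged in its `notes` field.  The four
small-to-moderate Kun3–Kun3c cycles are point events: they mark troughs of
the curve but never breach the exposure threshold, and so create no
junction windows of their own; the terminal-Kungurian exposure that follows
them is a single 2-My junction window.  Only the first Zechstein
transgressive cycle is modelled.

### Area cladogram and branch capacity

The area cladogram is a chain along the timeline: each disjunction carries
an East/West branch pair below a split node at its onset; each junction
carries one merged pan-Pangaean branch below a merge node.  The root is
placed at the pre-accretion ephemeral Laurussia–Gondwana connection
(350 Ma in the fixture), which precedes the first SLB window, so the first
*merged* segment appears at 321 Ma.  Because merge nodes make the graph
reticulate, the area cladogram is serialised as node/branch CSV tables
rather than Newick.

Taxon histories are **clado-stratigraphic trees**: a Newick topology plus
a sidecar node table (`node_id,age_ma,territory,label`), where internal
node ages are split dates, leaf ages are extinction dates, and a branch
lives over `[parent age, own age)`.  Internal node labels name clades; a
clade comprises the subtree of the labelled node plus its stem branch.

**Branch capacity** — the model's central testable constraint — is
computed by explicit time-slice counting: the number of clade branches
alive at the query time, filtered to the queried territory when the time
falls in a disjunction and pooled across territories in a junction
(geodispersal makes every lineage recoverable on either side).  A closed
form `2^d` after `d` disjunctions is provided only as a documented upper
bound (`doubling_bound`); real trees fall short of it through extinction
and non-dispersing lineages, so the bound is never used as a capacity.
For interval-level conflict checks the capacity is the number of branches
whose life span *overlaps* the interval, not a midpoint slice: a branch
going extinct mid-interval is still recoverable from it, and midpoint
slicing would produce spurious violations on simulated data.

### Fitting rules

* **Assignment.**  A record hosted by a disjunction is attributed to the
  branch of its own territory (endemism); a record hosted by a junction to
  either territory.  Records straddling a phase boundary take the union of
  the touched intervals' rules and carry an audit flag rather than forcing
  a choice.
* **Conflicts.**  For every disjunction interval, clade and territory, the
  count of distinct genus-level lineages must not exceed the overlapping
  branch capacity; an excess is a `capacity_violation` (observed vs
  allowed).  Genus is the capacity-bearing rank; several species of one
  genus in one interval are downgraded to a `span_violation` candidate
  (anagenesis of a single lineage — chronospecies), never a capacity
  breach.  Junction intervals are geodispersal periods and carry no
  endemism bound; junction-window capacities are queried directly with
  `branch_capacity` (e.g. eight available synapsid branches at the
  Garnett/Kas 2 window).
* **Divergence dating.**  Two lineages separate during a disjunction and
  first *can* co-occur during the junction window that terminates it, so
  the divergence is reported as that window's onset age.  Operationally
  the older of the two first-appearance data locates the hosting interval:
  in a junction, that window dates the split; in a disjunction, the next
  younger junction does.  With no disjunction before the datum, the root
  age is returned with a `no_prior_disjunction` flag.
* **Biozone calibration.**  Ordered marine biostratigraphic units record
  *marine* geodispersal, which happens during terrestrial disjunction
  (highstand) intervals; unit *i* is assigned to the *i*-th available
  highstand at or younger than an optional anchor age, strictly
  order-preserving.  Excepted units (the Newwellian, whose amphi-Pangaean
  fauna reflects a temperature event rather than SLB vicariance) pass
  through with their input dates and a flag; units left over when
  highstands run out are reported unassigned, never dropped.
* **Chrones.**  Disjunctions are endemism (Ame) chrones, junctions
  geodispersal (Amg) chrones, numbered oldest-first within each kind.
  Amniote Chrone numbering starts at the Bash 3 junction — the window in
  which the first amniotes appear — so the lower *Tapinocephalus*
  Assemblage Zone interval (the Garlstorf disjunction, 265.1–263 Ma in the
  fixture) renders as "Amniote Chrone 10".

### Congruence score and its null

The congruence between a dated tree and the timeline is the fraction of
internal node dates lying within a tolerance (default 1 My, the order of
the model's window durations) of some disjunction onset.  The null
resamples node dates uniformly over the timeline span, preserving
topology; the p-value uses the `(1 + k)/(n_perm + 1)` permutation formula.
Because the score takes only `n_nodes + 1` distinct values, that exact
p-value is necessarily *conservative* (super-uniform) under the null —
a property of any discrete test statistic, not an implementation artefact.
Where calibration matters (e.g. the uniformity property test), the
`randomized=True` form breaks ties with one seeded uniform draw, which
makes the p-value exactly Uniform(0, 1) under the null.  The score is a
formalisation added by this package; the source presents congruence
qualitatively.

### Arido-eustasy rules

Under arido-eustasy, wet climates store fresh water in continental
aquifers and lower sea level; dry climates raise it.  The implemented
signatures:

* **Excursions.**  Departures from a running-median baseline (window 2 My,
  robust to single-sample spikes and to excursions shorter than half the
  window) of at least 1.5 ‰, built up at ≥ 1.0 ‰/My, are called as
  excursions; negative calls are wet-mode onsets.  The 1.5 ‰ magnitude
  gate is the stated "extreme" criterion; "abrupt" is not quantified at
  source, so the 1.0 ‰/My default is this package's documented choice.
  Magnitudes quoted as "~2%" are read as per-mil, consistent with the
  1.5 ‰ gate stated alongside them.
* **OTP.**  Positive culminations of marine carbonate δ¹³C exceeding a
  prominence gate (default 0.5 ‰) are Optimum-of-Terrestrial-Productivity
  peaks; the operation refuses non-carbonate sources.
* **Lithofacies.**  gypsum → lowstand, shale → highstand, dolomite →
  regressive systems tract (kept distinct from lowstand: it records
  diagenesis under rising fresh-water tables, not emergence), coal →
  wet-lowstand, red beds → dry-highstand, sandstone/limestone → context.
  Alignment to the curve matches lowstand-type labels to successive
  prominence-filtered troughs and highstand-type labels to crests,
  order-preserving and greedy, reporting unmatched units.

## Synthetic data

The generators are pure functions of a `SynthSpec` (same spec and seed →
bit-identical output) and return truth records for parameter-recovery
testing.  They emulate:

* a quasi-periodic eustatic curve — cycle period jittered within the
  1.4–1.6 My Milankovitch eccentricity band, mean level 30 units,
  amplitude 5, Gaussian noise (SD 1 by default; 0.5 for the packaged
  reference curve) — with deep troughs (15 units below threshold) carved
  at interval lowstand events and shallow 20-unit marker troughs at point
  lowstands.  Planted troughs are pinned to the threshold exactly at their
  window edges, so detection recovers planted onsets to within half a
  0.05-My sample step regardless of the noise seed;
* a lineage history in which splits occur only at disjunction onsets
  (isolation begins when the seaway opens), each split producing one
  eastern and one western daughter with probability 0.5 per lineage,
  lifetimes exponential with mean 25 My;
* fossil sampling at 3 records per My per territory, thinned by a
  preservation bias (East 0.35, West 1.0 — the eastern record is sparser),
  territory-restricted during disjunctions and unrestricted during
  junctions;
* δ¹³C series as a flat baseline (4 ‰, noise SD 0.15 ‰) with planted ramp
  excursions (ramp, plateau, ramp; overlaps rejected).

What the generators deliberately do **not** emulate: the spectral content
of the real reference curve beyond the stated cycle band, within-territory
geographic structure, taxonomic error, reworking, or time-averaging of
fossil horizons.  Passing round-trip tests therefore demonstrate that the
detectors and fitting rules are correct and calibrated *under the model's
own assumptions*, not that real Late Palaeozoic data satisfy those
assumptions.

## Fixtures and problem sizes

The packaged fixture curve spans 350–250 Ma at 0.05-My steps (2001
samples).  The early-synapsid tree is a synthetic, figure-digitised
stand-in (20 leaves) constructed so that its time-slice counts honour the
two branch counts stated verbatim in the source literature: eight synapsid
branches at the Garnett/Kas 2 window and eight tapinocephalid branches in
the lower *Tapinocephalus* Assemblage Zone; the eight tapinocephalid
branches are all western (the Karoo radiation — within-territory allopatry
is outside the E/W model and the subtree is data, not a model product).
Property suites run at the study's stated scales: 200 random curves
against the dense-grid oracle, 50 simulated occurrence sets for the
zero-conflict soundness check, 50 seeds for split recovery, 100 series for
excursion recovery, and 200 replicates × 999 permutations for p-value
calibration; the full suite completes in a few seconds on one CPU.

## Known limitations

* The exposure threshold, window durations and most passive-era interval
  bounds are figure-digitised, not printed; only the onset ages quoted
  above are authoritative.
* The source's Methods correlate the Joggins Formation with the Bash 5
  lowstand while its Results use Bash 3; the fixture follows the Results
  (321 Ma), on which the printed divergence date depends.  The
  contradiction is recorded, not resolved.
* Divergence dates inherit the source's convention of dating a split by
  the *closing* junction window onset, which can postdate the biological
  separation by the length of the preceding disjunction.
* The congruence statistic and its permutation null are this package's
  formalisation; no quantitative congruence value exists at source to
  compare against.
* No probabilistic biogeographic inference (DEC/DIVA-style likelihoods) is
  attempted; the procedure is rule-based by design.
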