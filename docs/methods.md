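# Methods

## Composition algebra and constants

All stages operate on non-negative C/H/N/O/S atom-count vectors
(`ElementalComposition`) and signed per-element deltas
(`CompositionDelta`). Monoisotopic masses and isotopic abundances are
pinned to the CIAAW/IUPAC 2021 representative values (¹²C = 12 exactly,
¹H = 1.00782503224 Da, …) so that every derived quantity is
bit-reproducible. Compositions are restricted to CHNOS because
pentose/hexose + proteinogenic-amino-acid model systems contain no other
elements. Double-bond equivalents use DBE = 1 + C − H/2 + N/2; oxygen and
sulphur (divalent) contribute nothing. DBE is integral exactly when H + N
is even, which for neutral even-electron molecules it must be — this
parity is part of the chemical plausibility filter.

Ions are singly deprotonated: M = m/z + 1.007276467 Da, with the electron
mass folded into the proton constant (the error from treating the proton
and the H-minus-electron masses separately is < 0.1 ppm, below every
tolerance used here).

Isotopic fine structure is predicted by exact per-element multinomial
statistics over the heavy-isotope counts (¹³C, ²H, ¹⁵N, ¹⁷O/¹⁸O,
³³S/³⁴S/³⁶S), keeping distinct substitutions as distinct peaks, with
abundances *relative to the monoisotopic peak* and pruning below 10⁻⁴ —
the detectable range of an instrument with four decades of dynamic range.

## Formula assignment

Candidate enumeration is exhaustive within element bounds (default
C 1–40, H 1–80, N 0–6, O 0–25, S 0–4, chosen to cover every composition
the chemistry here can produce — the largest planted cores are C₁₆
diketosamines — with margin) and a ppm window. The implementation
vectorises over a cached (C, N, O, S) grid and solves for the hydrogen
count; tests verify exact agreement with a plain nested-loop enumeration
driven by an independently typed mass table.

Two ppm thresholds coexist, mirroring the accuracy envelope of the
emulated instrument (better than ±0.2 ppm for most features, ±0.5 ppm at
worst):

* **hard cut, 0.5 ppm** — the envelope for *network-supported* candidates
  and an invariant of every accepted assignment;
* **strict tolerance, 0.2 ppm** — required of assignments with *no*
  network support (the unique-brute-force-candidate fallback), where mass
  accuracy is the only evidence.

This split is deliberate: a 0.2 ppm gate on network acceptance would
reject ~5 % of peaks per replicate at the simulated 0.1 ppm mass-error
s.d., and the all-replicates consensus would then lose ~13 % of genuine
formulas. With the hard cut carrying the network route, recovery through a
triplicate consensus stays at ~100 % while ≥ 90 % of accepted assignments
still fall within ±0.2 ppm.

Network annotation proceeds breadth-first from seed formulas (the sugar,
the amino acid, and their ARP) to a fixed point: a candidate is accepted
when it passes the chemical filter (DBE ≥ 0 and integral, H/C ≤ 3,
O/C ≤ 2), lies within the hard cut, and equals a seed or sits one
transformation away from an accepted formula. The default transformation
library — ±H₂O, ±H₂, ±O, +C₅H₈O₄ (pentose addition), +AA−H₂O
(condensation), −CO₂, −C₂H₄O₂, −C₃H₆O₃, −CH₂O — encodes the dehydration,
redox, diketosamine-formation, decarboxylation and C₂/C₃-cleavage
chemistry of the system; it is configurable because no canonical library
exists. Ties are broken by highest network support (number of accepted
neighbours), then smallest |ppm| error, and peaks are visited in ascending
m/z, so the result is deterministic and independent of input peak order.

Before annotation, peaks below an S/N floor (default 4) are ignored and
peaks recognisable as isotopologues of a stronger peak are removed: a peak
within ±0.8 mDa of a stronger peak's m/z plus the ¹³C₁ (+1.00335 Da) or
³⁴S₁ (+1.99580 Da) shift at a plausible intensity ratio (≤ 0.6) carries no
independent formula. The window must stay below 1.3 mDa because the real
chemical delta +C₃−H₂−O₂ (1.99452 Da) lies that close to the ³⁴S shift —
resolving the two is precisely what ultrahigh resolution buys.

Isotope validation requires the predicted ¹³C₁ peak (and ³⁴S₁ for
sulphur-bearing formulas) within 1 ppm of its theoretical position with an
observed/parent ratio within ±30 % (relative) of prediction.

Replicate consensus keeps a formula only if it was assigned in every
replicate of a condition; consensus intensity and S/N are replicate means
and the consensus error is the mean |ppm|. Consensus is applied *before*
blank comparison (the alternative order is not distinguishable from the
emulated study design; this one keeps blank tables and mixture tables
symmetric).

## Product classification

Per system and per time point, against time-matched blanks (blank
chemistry also evolves with heating): precursor compositions →
`PRECURSOR`; present in the sugar blank only → `SUGAR_DEG`; in the
amino-acid blank only → `AA_DEG`; in both → `AMBIGUOUS` (kept as its own
class rather than forced into a priority order); only in the mixture →
`MRP`. Presence is binary — no intensity-fold criterion — matching the
blank-comparison design being emulated. Classification is a partition:
every consensus formula receives exactly one class.

## Descriptors

Van Krevelen coordinates (H/C, O/C), DBE/C and the compositional space
label (CHO/CHNO/CHOS/CHNOS) are computed per formula; relative intensities
are normalised within the table so shares sum to 1 (±10⁻¹²). Weighted
means use the raw intensities as weights. Trend regressions are reported
both against time and in van Krevelen space (H/C on O/C), because
reaction trajectories are conventionally drawn in that plane; both
per-time-point aggregate fits are exposed rather than choosing one.
Carbon histograms are intensity shares per carbon number and are invariant
under rescaling of the whole sample. Odd-nitrogen screening partitions by
N mod 2 — an odd nitrogen count in a product of an even-N amino acid
(lysine) flags side-chain fragmentation.

## General-scheme detection

For each system, MRP formulas with S/N ≥ 8 are mapped to cores by
subtracting the amino-acid side chain R (R = amino acid − C₂H₄NO₂);
formulas that cannot carry R are skipped. The four branch roots live in
core space and are amino-acid independent: ARP core = sugar + backbone −
H₂O (C₇H₁₂NO₆ for ribose), diketosamine core = ARP core + sugar − H₂O,
and the cleavage roots subtract C₂H₄O₂ or C₃H₆O₃ from the diketosamine
(the C₃ by-product is configurable — C₃H₄O₂ is the documented alternative
— because only the C₂ by-product stoichiometry is established).

A core becomes a scheme node when it is present in ≥ 3 of the supplied
systems *and* lies on a branch: on the uninterrupted dehydration chain
from a root (up to 3 steps for the ARP branch, 6 for the others; chains
stop at gaps, no skipping) or one ±H₂ redox step off that chain.
Reachability is required, not bare co-occurrence: the scheme is defined by
shared reaction behaviour. Cores that meet the presence threshold but are
unreachable are reported separately, never silently dropped. Each node
carries per-system presence flags and intensity shares; the explained
share of a system is the summed intensity of scheme-member formulas over
all MRP intensity.

## The synthetic world

The generator's defaults state the emulated study: ribose with glycine,
isoleucine, lysine and cysteine, heated 2/4/6/10 h, measured in
triplicate, [M−H]⁻ ions in m/z 100–600 spanning about four orders of
magnitude in intensity at 0.1 ppm mass-error s.d.

Ground truth per system: the precursors; the four-branch scheme planted
deterministically (backbone dehydration chains) with redox partners
planted per system with probability 0.8 — in real spectra most but not
all intermediates show both redox forms; a stochastic expansion of generic
Maillard deltas (probability 0.18 per delta per formula per generation,
2 generations, capped at 160 formulas — a few hundred detected compounds
per system); and BFS-depth-2 sugar-only and amino-acid-only degradation
branches used for the blanks. All formulas pass the chemical filter and
the m/z window, and every formula is unique within a system, so the
planted class partition is exact. MRP expansion never removes the last
nitrogen — nitrogen-free products belong to the sugar branch — keeping
planted classes unambiguous. Because small amino acids' degradation
products fall below m/z 100, glycine ends up with no observable
degradation products, as in real ESI(−) spectra of such systems.

Intensities follow base 10⁸ × 0.45^step with log-normal static scatter
(σ = 0.35) and per-replicate scatter (σ = 0.15); the model is censored
below S/N 8 (8 × the 10⁴ noise floor) because a planted product is by
definition detectable — an uncensored tail would plant formulas that no
assignment could recover and make recovery scores meaningless. Products
gain weight with reaction time as 1.8^(step · t̂), which reproduces the
drift of intensity toward more dehydrated (lower H/C, O/C) compositions
over time; a record first appears at the time-point index equal to its
pathway depth. Noise peaks are drawn uniformly in m/z and redrawn (up to
100×) if any CHNOS mass lies within 0.5 ppm, so false positives are
unambiguously attributable. Isotopologue peaks (¹³C₁, ³⁴S₁) are emitted at
their theoretical relative abundance. Peak lists are sorted and merged at
a 1 mDa resolution floor (stronger centroid wins, intensities sum). All
randomness derives from numpy `SeedSequence` streams keyed by (seed,
purpose, system, time, replicate), so outputs are bitwise reproducible and
independent of call order.

What the simulator does **not** emulate: space-charge and coalescence
effects, ionisation suppression, adducts and multimers, peak-shape
interference, pH/temperature kinetics, and the true (unknown) topology of
the real product network. A green end-to-end test therefore establishes
that the pipeline's logic is correct on data matching its stated error
model — not that the emulated study's published counts are reproduced.

## Numerical choices and edge cases

* Enumeration hydrogen counts come from floor/ceil of an exact division —
  no float-equality comparisons; candidate lists are deduplicated and
  sorted by (|ppm|, composition) for determinism.
* Empty peak lists, empty candidate sets and empty consensus tables flow
  through as empty outputs; missing blanks raise a named error.
* Carbon-free formulas are excluded from van Krevelen tables with a
  warning (H/C is undefined).
* Degenerate regressions (single time point, constant predictor) raise
  rather than returning NaN slopes.
* CLI exit codes: 0 success, 2 validation error, 3 runtime error; every
  output directory receives the effective configuration and package
  version.

## Known limitations

* The transformation library is a declared approximation; chemistry
  outside it (e.g. disulphide-linked dimers from cysteine) is not
  annotated by the network route and falls back to unique-candidate
  assignment.
* Scheme detection tracks redox only as ±H₂ relative to the dehydration
  backbone; deeper redox chains are out of scope.
* Classification is presence/absence; quantitative blank subtraction is
  not implemented.
* No structure or isomer information: a node is an elemental composition,
  behind which many isomers may hide.
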