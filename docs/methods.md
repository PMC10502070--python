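# Methods

## System and scope

`dsdlogic` models toehold-mediated DNA strand displacement at *domain*
resolution. A domain is an indivisible block of bases; hybridization is
all-or-nothing per domain. A gate system is an annealed duplex — a
quencher-labelled (BHQ1) template strand paired with a fluorophore-labelled
(FAM) incumbent reporter over a contiguous footprint of template positions —
plus exactly three input strands, each complementary to a contiguous run of
template domains. Template positions are indexed 1..n in 5'→3' order;
intervals are 1-based and inclusive, matching the left-to-right reading of
gate diagrams.

Quenching is modelled as co-complexation: a reporter in the same complex as
the quencher-labelled template is dark, a free reporter is bright. There is
no geometric distance model, no nucleotide-level thermodynamics (no
nearest-neighbour ΔG or partition function), no pseudoknots, no 4-way branch
migration, and no fluorometer model.

Strand naming follows the figure convention of the gate designs: a strand is
named by the template domains it covers (`efh` covers E, F, H), and its
stored domain list follows that order. Antiparallel orientation is carried
entirely by the `complement` operation (which reverses and case-swaps);
derived strand sequences are the 5'→3' concatenation of domain sequences in
listed order. The MAJORITY gate's third input is the reporter's unlabelled
twin — same name, same domains, no label — and is the one sanctioned
name collision in a gate system.

## Logical engine: displacement-chain reachability

Input presence is a bit per input species; present species act with
unlimited copies (the logical layer encodes reachability, not yield).
Release is decided by growing *chains* to a fixpoint:

1. **Anchoring.** An input anchors *strongly* at an exposed toehold (a
   template position outside the footprint) it complements, or *weakly* at a
   template terminal position (1 or n) it complements even though paired —
   terminal base pairs fray transiently, which is the standard physical
   route for toehold-free invasion of a blunt duplex.
2. **Coverage.** An anchored chain claims the contiguous template run its
   members complement.
3. **Joining.** A present input overlapping a chain's coverage in ≥ 1
   position joins it and extends the coverage (hand-over-hand displacement:
   the junction left by the previous invader exposes an internal toehold).

The fixpoint is order-independent — a chain's final membership is the set of
present inputs transitively connected to its anchor by run overlap — so the
engine is deterministic regardless of input processing order.

**Release rule.** Output 1 iff some single chain's coverage contains the
whole footprint, or the union of strong-anchored chains' coverages does.
A union of *weak* chains does not release: two disconnected fray events
cannot sustain a continuous migration front, and admitting them would make
any blunt duplex strippable from its two ends (turning the AND gate into an
"at least the two flanks" gate). This rule is this package's mechanistic
model of cooperative displacement; the gate designs assert the cooperative
behaviour without specifying a mechanism.

## Verification oracle

An independent check explores explicit binding states — which strand
instance holds each template position, each instance holding a contiguous
interval — by breadth-first search under elementary moves: binding of a free
invader at an unpaired complementary position; fray binding at a template
terminal even while paired; junction binding where a duplex end abuts
another strand (junction breathing); zipping into an adjacent unpaired
position; single-position branch-migration steps in either direction; and
removal of a strand pushed to zero positions. One copy per species is
tracked (a displaced copy returns to the free pool); the state space is
bounded (template ≤ 8 domains, ≤ 6 species) and a state-budget overflow
raises an explicit inconclusive error rather than returning 0.

The anchoring constraint of the chain rules enters exactly once: the move
that strips the incumbent's last held position is legal only if the invaders
covering the footprint form valid displacement fronts — one front whose
members' complementary runs are transitively connected by overlap, or
strong-anchored fronts jointly covering the footprint. At base-pair
resolution a blunt duplex *is* eventually strippable from both ends by
neutral random-walk migration; the constraint encodes the kinetic reality
that disconnected fray-initiated fronts do not complete on the experiment's
timescale. Oracle and chain engine agree on all eight states of each
built-in gate and on every generated fixture exercised by the test suite.

## Kinetic engine

Logical moves are compiled one-to-one into reaction channels over *complex
configurations* (the multiset of chains a complex carries, with coverages
kept pairwise disjoint; a joining input merges every chain it overlaps):

| channel | type | default rate |
|---|---|---|
| strong-toehold anchoring | bimolecular | k_strong = 1 |
| terminal-fray anchoring | bimolecular | k_fray = 10⁻³ |
| overlap joining | bimolecular | k_join = 1 |
| reporter release (footprint displaced) | unimolecular | k_release = 10 |
| dissociation of a lone anchored invader | unimolecular | k_unbind1 = 0.1 |

Rates are in arbitrary reciprocal-time units; the three-orders-of-magnitude
gap between k_strong and k_fray mirrors the qualitative separation between
toehold-mediated and toehold-free invasion. Branch migration inside a chain
is collapsed into these channels — the experiment resolves endpoint
fluorescence, not migration intermediates. Bimolecular propensities are
k·nA·nB per copy (no volume factor). Released complexes are absorbing: the
freed reporter has no toehold left to re-invade. There are no leak channels
unless `k_leak` is set, so the zero-input baseline is exactly zero signal.

Initial counts follow the 1:1 stoichiometry of the annealing protocol:
`copies` (default 100) reporter duplexes and `copies` of each present input.
Trajectories are sampled with Gillespie's direct method from a seeded
generator; identical (network, t_end, seed) reproduce bitwise-identical
paths. The default horizon t_end = 10⁴ lets even the slowest fray-initiated
cascade complete. Readout: `free_fraction` of reporters not co-complexed
with the template, `signal = free_fraction × F_max` (F_max = 150 a.u.),
binarized at boundary = 50 a.u. — strictly above reads 1, below reads 0; a
signal exactly at the boundary is reported as 0 with a warning, since only
"above" and "below" are defined. The scale was chosen so partial-release
states (free fraction ≥ ½) still binarize to 1 while the baseline reads 0.
Truth-table runs take the median signal across seeds (default seeds 1..10).

Because bits, not magnitudes, are the published observable, absolute
fluorescence values are not calibrated; the signal scale is arbitrary, and
doubling `copies` leaves binarized outputs unchanged (the free fraction is
intensive).

## Sequence design

Domain lengths default to 6 nt for toeholds and 15 nt for recognition
domains — typical strand-displacement practice; the built-in gates assign
the toehold role to template positions outside the footprint. Sequences are
drawn per complement pair by rejection sampling: GC fraction within
[0.3, 0.7], no homopolymer run longer than 4, alphabet strictly ACGT, and —
by default — no shared 6-mer between a candidate and the already-placed
non-complementary domains or their reverse complements. The k-mer screen at
draw time is what keeps the post-hoc orthogonality report (`shared length-k
word with the reverse complement of the other`) empty for essentially all
seeds; fully random 15-mers would collide in a substantial fraction of
systems. Infeasible constraint combinations (e.g. a GC window admitting no
integer count for a domain's length) raise an error naming the domain.

## Synthetic fixtures

`generate_fixture` emits structurally valid systems in four families:
OR-like (toehold-flanked reporter, every input covers the footprint),
AND-like (blunt full-footprint duplex, three overlapping runs
[1,p], [p,q], [q,n]), MAJORITY-like (two flank inputs splitting the
footprint plus the reporter's anchorless twin run), and random-valid
(arbitrary contiguous footprint and input runs). Generation is
deterministic in (kind, n_domains, seed). These fixtures emulate the
*structure* of real gate systems but not sequence-dependent leak, coaxial
stacking, or concentration imbalances — passing tests on them demonstrates
the combinatorial logic of the designs, not wet-lab performance.

## Problem sizes and numerical choices

The test and verification suites run the oracle on templates of 4–7 domains
(hundreds to a few thousand states per query) and the kinetic engine at
100 copies × 10 seeds per state with the default horizon; both complete in
seconds to a couple of minutes on a single core. Chains are grown in the
deterministic order inputs are supplied; the fixpoint guarantees the result
is order-free, the ordering only stabilizes traces. Degenerate inputs —
empty input sets, zero-channel networks — are handled explicitly (empty
chain set, constant trajectory).

## Known limitations

* Domain-level granularity cannot express partial-domain toeholds,
  mismatches, or toehold-exchange energetics.
* The release rule is a discrete surrogate for slow, thermodynamically
  near-neutral blunt-end invasion; it deliberately ignores ultra-slow leak
  pathways (available as an optional `k_leak` channel).
* Kinetic rate constants are stylized, not fitted; only the *bits* of the
  kinetic truth table, not signal magnitudes or time constants, are
  meaningful.
* Reported sequences for the original gate strands are not bundled; the
  FASTA reader accepts them without code changes once available.
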