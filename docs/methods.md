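# Methods

## The game and its strategies

All interactions are simultaneous-move prisoner's dilemmas with payoffs
(R, S, T, P) = (3, 0, 5, 1), satisfying T > R > P ≥ S and 2R > T + S. A
move is the cooperation indicator X ∈ {0, 1}; a single game's payoff is
the bilinear form Ωᵢᵀ [[R,S],[T,P]] Ωⱼ with Ω = (X, 1−X).

Fourteen strategies are implemented. Ten are memory-one, written as the
cooperation-probability vector (p_CC, p_CD, p_DC, p_DD) conditioned on the
previous joint outcome (own move first):

| strategy | vector | note |
|---|---|---|
| AC | (1,1,1,1) | unconditional cooperator |
| AD | (0,0,0,0) | unconditional defector; opens with D |
| Random | (.5,.5,.5,.5) | fair coin, including the first move |
| TFT | (1,0,1,0) | copies the opponent's last move |
| GTFT | (1,1/3,1,1/3) | forgives a defection with probability 1/3 |
| WSLS | (1,0,0,1) | win-stay lose-shift |
| ZDe | (11/13,1/2,7/26,0) | extortionate zero-determinant, χ = 3 |
| ZDg | (1,2/11,1,4/11) | generous zero-determinant, χ = 3 |
| Hard Joss | (0.9,0,0.9,0) | TFT that sneak-defects 10% after a C |
| Grim | (1,0,0,0) | trigger; defects forever after one defection |

The other four need a longer history: TF2T defects only after two
consecutive opponent defections; Hard TFT after a defection anywhere in
the last three rounds; Hard TF2T after two consecutive defections within
the last three rounds; Hard Majority defects when the opponent's total
defections reach its total cooperations (ties defect) and opens with
defection. Every strategy opens cooperatively unless its definition forces
the first move (AD, Hard Majority, Random).

The tournament literature names these strategies but rarely pins exact
definitions. The definitions above were fixed by calibration: each choice
reproduces the corresponding cells of the published expected-payoff table
(e.g. GTFT's 1/3 gives E(GTFT,AD) = 2/3; the χ = 3 extortion vector gives
E(ZDe,AC) = 41/11 ≈ 3.73 and E(AC,ZDe) = 21/11 ≈ 1.91; Hard Majority's
tie-defects rule gives the published alternation value 2.5 against TFT).

A pairwise history is summarized by a sufficient statistic — own last
move, the opponent's last three moves, and running cooperation/defection
counts — rather than the unbounded move list; every policy above is a
function of that statistic.

## Exact expected payoffs

E(a, b) denotes a's long-run (limit-average) per-round payoff against b.
Three branches compute it, recorded in a method tag:

1. **determinant** — both strategies memory-one and the joint 4-state
   chain has a unique stationary law (|D(p, s, 1)| > 1e−9 after scaling):
   the determinant ratio D(p, s, S_x)/D(p, s, 1), where D's first three
   columns are built from p and s (with the CD/DC cross-indexing between
   the two players' frames) and the last column is the payoff vector.
   A unit test verifies stationarity (ΦM = Φ to 1e−10, payoff = Φ·S_x).
2. **cycle** — every other pair not involving Hard Majority: the joint
   play is a finite Markov chain over (own last move, opponent window,
   grim flag) per side, at most 1024 joint states. The chain is built
   exactly from the defined first moves; recurrent classes are found by
   strong-connectivity, each class's stationary law is solved directly,
   and the limit average weights class payoffs by absorption
   probabilities. Deterministic pairs degenerate to a trajectory entering
   a cycle; first-move-dependent pairs (TFT vs TFT, ZDe vs ZDe, ...) are
   resolved the way the defined first moves dictate. Hard Majority versus
   a deterministic opponent is played on the trajectory itself: a repeat
   of the reduced state counts as a period once the unbounded
   cooperation-minus-defection counter either returned exactly or drifted
   monotonically with its decision sign provably pinned.
3. **simulated** — Hard Majority versus a stochastic opponent (Random,
   GTFT, Hard Joss, ZDe, ZDg): 128 independent chains × 8192 rounds
   (≥ 10⁶ total) with a 1024-round burn-in; the standard error is taken
   across chain means.

The invasion statistic is δ(a, b) = E(a,a) − E(b,a).

### The published table

The published 14×14 table was transcribed from a concatenated text dump;
tokenization was accepted only where arithmetic pins it (e.g. the ZDe row
must read E(ZDe,ZDg) = 2.5 because both χ = 3 zero-determinant identities
force it). Three groups of cells are *not* reproducible as long-run
values and are excluded from the reproduction tests:

* cells printing a value inconsistent with exact play under any of the
  calibrated definitions (Grim vs Random; Hard Majority vs Hard TFT,
  where exact play reaches mutual defection);
* Hard Joss pairs against retaliators, where the printed numbers are the
  pre-absorption alternation averages — under the defined vector the
  sneak defection eventually triggers mutual defection almost surely, so
  the limit is P = 1;
* Hard Majority vs ZDe, whose chain absorbs into mutual defection so
  slowly that any printed number is horizon-dependent.

All remaining 170 readable cells are reproduced at their printed
precision by the exact branches (simulated cells within 4 s.e.).

## Networks and seeding

* **Watts–Strogatz**: ring lattice of even degree k; each edge's far
  endpoint is rewired independently with probability p, resampling on
  self-loop/duplicate collisions, so the edge count is exactly Nk/2.
  Presets regenerate until connected.
* **Barabási–Albert**: complete seed on m₀ nodes, preferential attachment
  of m distinct edges per new node; edge count C(m₀,2) + (N−m₀)m. The
  N = 1024, m = m₀ = 3 preset has 3,066 edges, matching the reference
  count; the same convention gives 6,138 edges at N = 2048 (the reference
  prints 6,135, which corresponds to an edgeless seed — the complete-seed
  convention was kept because only it reproduces the N = 1024 count).

Presets: `wssn1` (1024, 6, 0.1), `wssn2` (1024, 6, 0.2), `basn1`
(1024, 3, 3), `basn2` (2048, 3, 3).

**Assignment.** Half the nodes get the weak strategy. ε = ⌊α·N/2⌋ weak
players occupy the top of the degree sequence (descending); ties are
broken by a seeded shuffle before a stable sort, because the
nearly-regular WS graphs are dominated by tie handling and a fixed
tie-break would bias placement. The remaining weak players are placed
uniformly at random, which at α = 0 reduces to a uniform half/half split.

## The networked game

Each edge holds its own pair history; both endpoints move simultaneously
each round using their current strategy's policy on that edge's history.
Epoch length is R = 200 rounds; fitness is φ (accumulated) or ψ = φ/k.
The accumulator resets each epoch — the φ summation runs over the current
epoch only; an `EpochConfig` flag switches to cumulative accumulation for
sensitivity checks. Updates are synchronous from one fitness snapshot:
keep your strategy when your fitness ties or beats every neighbor's,
otherwise copy the strictly fittest neighbor (uniform among tied bests).
Histories persist across strategy changes, so a convert's next move is
its new strategy's response to the inherited history (a fresh TFT convert
facing a defecting history defects), and a fresh Grim convert inherits
the opponent-defection count.

Runs stop at strategy extinction — checked at epoch boundaries, the only
points where composition changes — or at 20,000 rounds, where the weak
frequency is averaged over the last 2,000 rounds (ten epochs' worth of
compositions, round-weighted). Extinct runs report 0 or 1.

The closed-form per-round fitness
G_i = k_i(Δ_i X_i + T W_i + P(1−W_i)), with W_i the local cooperation
frequency and Δ_i = S−P+(R−T+P−S)W_i, is exposed as a diagnostic. It is
exact precisely when a node played one uniform move with all neighbors —
a property test asserts equality with the edge-sum payoff there — and is
undefined under genuinely divided play, where the engine returns "not
applicable" rather than a wrong number.

Performance: rounds are evaluated vectorized over all half-edges (one
policy evaluation per strategy per round, payoffs via a lookup table and
bincount). A full 20,000-round preset run takes ~3 s on one core.

## Experiment grid and seeding

A sweep runs matches over an α grid (default 0, 0.01, ..., 1) with 10
replicates per α. Each (match, α, replicate) cell derives its generator
from `SeedSequence(root, spawn_key=(match, alpha, replicate))`, split into
network / assignment / game streams, so cells are individually
reproducible and sweeps resumable. By default every replicate draws a
fresh network; a plan flag fixes one network per replicate instead. The
protocol arithmetic (101 α-values × 10 replicates × 20,000 rounds =
20,200,000 rounds per match; ×54 matches ×8 configurations =
8,726,400,000) is a pure function of the plan.

The acceptance script runs the three representative network matches at
the full published scale (N = 1024, 10 replicates, 20,000-round cap); no
scaling down was needed.

## Known limitations

* The bimodal matches (a weak strategy that usually dies but occasionally
  rides a hub to takeover, e.g. Hard Majority vs TFT under φ at α = 0)
  give 10-replicate means with a cross-seed spread of several percentage
  points; single published point values for such matches are one draw
  from that distribution.
* Strategy definitions beyond the calibrated set (other χ values, other
  noise levels for Hard Joss) are out of scope; the strategy enumeration
  is closed.
* The round-robin's draw rule uses exact aggregate equality. Stochastic
  pairs are almost surely strictly ordered, so draws arise only from
  deterministic-on-path pairs, which is what makes the decided-match
  count (54) seed-independent in practice.
* Simulated Hard-Majority pairs report means with standard errors, not
  exact values; their published counterparts are themselves simulation
  artifacts at an unspecified horizon.
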