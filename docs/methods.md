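# Methods

## Scope

`phagedrop` quantifies droplet co-cultivation assays in which phage
particles, host cells and a cell-impermeant intercalating dye are
partitioned into picoliter water-in-oil droplets, incubated, measured on a
droplet cytometer (forward scatter + one fluorescence channel), and —
optionally — sorted one droplet per 96-well for regrowth. The package
covers the statistics only: encapsulation and signal simulation, event
gating, occupancy estimation, titer arithmetic, and recovery rates. It
does not model microfluidic physics, dye photochemistry, droplet
coalescence, sorter throughput, or host-growth kinetics.

## Occupancy model

Partitioning a well-mixed suspension into droplets puts a
Poisson-distributed number of particles in each droplet. With mean phage
occupancy λ_phg and mean cell occupancy λ_cell per droplet:

* empty-droplet fraction: `P(K=0) = exp(-λ_phg)`;
* single-particle purity: `P(K=1 | K≥1) = λ exp(-λ) / (1 - exp(-λ))`,
  strictly decreasing in λ and → 1 as λ → 0;
* forward estimator: `λ̂ = c · V` for a titer `c` (PFU/mL) and droplet
  volume `V` (1 pL = 1e-9 mL);
* backward (digital) estimator: if a droplet stays non-fluorescent exactly
  when it received no viable phage, the observed negative fraction p₀
  estimates `exp(-λ)`, so `λ̂ = -ln p₀`.

The backward estimator's 95% CI is a binomial interval on p₀ mapped
through `-ln`. The Wilson score interval is the default because it is
well-behaved as p₀ → 1 (the low-λ regime these assays operate in);
Clopper–Pearson is available where an exact, conservative interval is
preferred. The two estimator routes need not agree on real data: the
forward route counts *infectious* particles per volume while the backward
route counts droplets in which propagation *succeeded*, so non-viable
particles, dead co-encapsulated hosts or in-droplet losses depress the
backward estimate relative to the forward one (a ~2× gap is plausible).
The package reports both, never reconciles them silently.

Droplet geometry: `V = (π/6)d³` for a sphere. A nominal 30 μm droplet is
14.1 pL; a measured volume of 18.8 pL (≈33 μm) is the package default for
titer conversions because measured volumes supersede nominal diameters.
Both conventions are exposed; supplying both to `DropletGeometry`
explicitly keeps both without cross-checking, since nominal-diameter /
measured-volume pairs are routinely inconsistent.

## Synthetic experiments

The simulator generates the latent truth and the rendered measurements of
one experiment from a single seeded config.

**Encapsulation.** Per droplet, independently: `n_phage ~ Poisson(λ_phg)`,
`n_cells ~ Poisson(λ_cell)`, diameter lognormal with configured mean and
CV (lognormal keeps diameters strictly positive and recovers a
monodisperse limit as CV → 0).

**Propagation.** A deterministic burst-cycle ladder: genome-equivalent
copies stay at `n_phage` until the first latent period L completes, then
multiply by the burst size B once per elapsed L, capped at a per-droplet
resource limit:

```
g(t) = n_phage                                   if t < L, or no phage, or no cells
g(t) = min(cap, n_phage · B^⌊t/L⌋)               otherwise
```

This is intentionally phenomenological — real in-droplet kinetics are
stochastic and resource-coupled — but assays report only aggregate
outcomes (fluorescent fractions, titer plateaus), for which a monotone,
saturating ladder is sufficient: it reproduces the observed
rise-then-plateau of both the fluorescent fraction and the total genome
pool. It is a pure function of its inputs, monotone nondecreasing in t.

**Rendering.** Fluorescence = `(baseline + gain · genomes) · ε`,
forward scatter = `fsc_gain · π(d/2)² · ε'`, with ε, ε' mean-one lognormal
(cytometry intensities are positive and right-skewed, so noise is
multiplicative). Each timepoint draws from its own seed-derived stream, so
a (config, seed) pair yields byte-identical tables regardless of render
order.

**Starvation artifact.** Real no-phage controls show a rare medium-
fluorescence subpopulation at late times, attributed to starved cells
losing membrane integrity (dye entry / nucleic-acid leakage) in droplets
that happened to receive many cells. The simulator models this as a single
mechanism: a droplet is artifact-prone iff it is phage-free and its cell
count exceeds λ_cell + 2√λ_cell, with probability `artifact_prob`; the
flag is drawn once at encapsulation (a starved droplet stays starved), and
from `artifact_onset_h` onward the droplet's pre-noise intensity is
`artifact_intensity`, constrained strictly between the baseline and the
saturated level. Whether the real phenomenon is dye entry or debris is
undetermined; the channel is deliberately agnostic.

### Defaults and their rationale

| parameter | default | why |
|---|---|---|
| `lambda_phage` | 0.2 | reference co-cultivation occupancy (digital regime) |
| `lambda_cells` | 19 | 10⁹ cells/mL × 18.8 pL |
| `diameter_mean_um` / `diameter_cv` | 30 / 0.05 | nominal monodisperse generator output |
| `timepoints_h` | 0,1,3,5,7,9,24 | standard incubation ladder |
| `n_droplets` | 40,000 | events recorded per timepoint |
| `latent_period_h` | 0.4 | T-even phage on *E. coli* at ~30 °C (~25 min) |
| `burst_size` | 120 | T-even literature range (~100–150) |
| `genome_cap` | 1e5 | host-resource limit per ~19-cell droplet |
| `fl_baseline` | 10 a.u. | no-phage droplet median intensity scale |
| `fl_per_genome` | 0.005 a.u. | puts saturated droplets at ~510 a.u., matching the observed high-intensity mode (~400–500 a.u.) and leaving the 130 a.u. threshold in the inter-mode gap |
| `fl_noise_cv` / `fsc_noise_cv` | 0.25 / 0.02 | broad fluorescence spread vs tight optical size channel |
| `artifact_prob`, `artifact_onset_h`, `artifact_intensity` | 0.01, 7 h, 60 a.u. | rare, late, medium-intensity — visible but below threshold in the typical draw |

Latent period, burst size, per-genome gain and the artifact parameters are
free parameters: no deposited dataset constrains them, and none of the
package's quantitative guarantees depend on their exact values (only on
monotone growth, saturation, and mode separation). They are set once here
and not tuned.

### What the simulator does and does not emulate

It reproduces the *statistical structure* the downstream analysis assumes:
Poisson occupancy, a bimodal fluorescence density separable by one
threshold from ~3 h on, sub-0.5% false positives in artifact-free
controls, a rise-then-plateau fluorescent-fraction time course, and a
genome pool that grows then saturates. It does not emulate instrument
drift, spectral spillover, droplet doublets, partial propagation
(half-lysed droplets), or the continuous titer kinetics between burst
cycles. Passing tests therefore validate the analysis logic and estimator
calibration under the assay's idealized assumptions — not instrument
behavior on real emulsions.

## Gating

Order is fixed and documented: size filter first, threshold second.

**Size filter.** Within each (sample, timepoint) group — grouping absorbs
FSC-mean drift across a time course — events with
`|fsc − mean| > multiplier × SD` are removed. Sample SD (ddof = 1) is
used; the choice is conventional and immaterial at n ≈ 40,000 but fixed
for exactness on small fixtures. Ties (deviation exactly equal to the
bound) survive, so a zero-variance group is fully retained; a one-event
group has no SD and raises. For a normal FSC population the default
1.0-SD filter retains Φ(1)−Φ(−1) ≈ 68.3% of events; the filtered count,
not the input count, is the denominator for all downstream fractions.

**Threshold.** An event is fluorescent iff its intensity is *strictly*
greater than the threshold ("stronger than" semantics; equality is
non-fluorescent). The fixed default is 130 a.u. A control-derived
threshold is the smallest observed control intensity T with
`frac(control > T) ≤ fp_rate` — the `⌈n(1−fp)⌉`-th order statistic with no
interpolation, so it is exact on small fixtures and guarantees the
false-positive bound by construction. The measured cutoff on a real
instrument (130 a.u.) cannot be re-derived from synthetic data; the
derivation *procedure* is what the package reproduces.

## Titer arithmetic

`titer = mean(replicate plaque counts) × dilution / plated volume`.
Counts outside the conventional 3–300 countable window warn but are never
dropped; all-zero counts warn "below detection" and return 0. Per-aliquot
PFU is `titer × aliquot volume × recovery_dilution` with the rupture
dilution left explicit: when a fixed emulsion volume is ruptured in
oil + medium, the aqueous fraction is not exactly known, so results are
reported "per aliquot of emulsion" rather than per mL of aqueous phase.

## Isolation recovery

Well outcomes are already binary (positive / negative / excluded from a
spot assay); the package never infers positivity from intermediate
turbidity. Excluded wells leave the denominator. Rates get 95% Wilson
intervals (Clopper–Pearson optional); a zero-positive gate correctly gets
a lower bound of exactly 0. The high- vs low-gate contrast uses a
Newcombe score interval for the rate difference and a two-sided Fisher
exact test — exact because the low gate routinely has a zero cell, which
invalidates chi-square asymptotics.

End-to-end, observed recovery ≈ (1 − ℓ) × P(viable phage | high gate),
where ℓ is a single lumped loss probability covering mis-isolation,
failed rupture and adsorption of the picoliter droplet onto labware.
Against near-perfect gate purity, ℓ ≈ 0.64 reproduces the ~36% recovery
regime observed in practice; the decomposition into individual loss modes
is not identifiable from endpoint data and is not attempted.

## Numerical choices

* Burst-ladder exponentiation is guarded: when `B^cycles` would overflow a
  double, the cap is applied directly.
* `-expm1(-λ)` is used for `1 - exp(-λ)` at small λ.
* Wilson bounds are clipped to [0, 1] (the closed form can overshoot by an
  ulp at boundary counts), and the λ CI is widened by at most the O(1/n)
  rounding of p₀·n to an integer count so it always brackets λ̂.
* All fractions are serialized as decimals; percentages appear only in
  rendered text.
* Problem sizes in the test suite (e.g. 100–500 replicates of 20,000 to
  40,000 droplets for coverage and round-trip checks) are chosen so
  binomial 3-SE bands are decisive for the properties under test.

## Known limitations

* The deterministic ladder has no burst-size or latent-period variance, so
  early-timepoint fluorescent fractions are sharper than real data.
* Single-volume occupancy inversion: no polydispersity correction, even
  though simulated diameters vary (CV 0.05 contributes negligibly at the
  default settings).
* The starvation artifact is one mechanism with one intensity; real
  medium-fluorescence populations are likely a mixture.
* The forward/backward λ gap is reported, not modeled (no viability
  parameter).
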