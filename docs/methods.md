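# Methods

`evfccs` quantifies dual-labeled extracellular vesicles (EVs) from two-channel
photon time tags recorded under pulsed interleaved excitation (PIE): how many
vesicles carry fluorescent cargo, what fraction of the labeled vesicle
population that is, how large the vesicles are, and how many cargo molecules
each one holds. This note describes the models and procedures, the defaults
and why they were chosen, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Photon model and PIE gating

Input data are per-photon records: macrotime (absolute arrival, integer clock
ticks; 1 ns default tick), TCSPC nanotime (delay since the last 40 MHz sync
pulse, 5 ps bins) and detector id (green/red). The two excitation lasers fire
alternately within one 25 ns sync period, so the nanotime identifies the
exciting laser. Gating keeps, per detector, only photons whose nanotime falls
inside the half-open gate assigned to that detector's dye — by default the
green laser owns [0, 12.5) ns and the red laser [12.5, 25) ns. Photons on a
right gate edge are discarded; the convention is deterministic and costs a
vanishing fraction of photons. Fluorescence-lifetime tails that leak past a
gate edge are lost rather than reassigned; with 12.5 ns windows against 2-4 ns
lifetimes, the loss is ~2% and identical for signal and crosstalk, so it does
not bias amplitude ratios. The instrument response function and afterpulsing
are not modeled.

## Correlator

The estimator is the symmetric-normalized covariance

    G(tau) = <dF_a(t) dF_b(t+tau)> / (<F_a> <F_b>),

evaluated on a multi-tau cascade (base bin 2 us in the pipeline, 8 lags per
level, bin width doubling per level) with lag-local means taken over the
overlapping trace segments — the standard finite-trace bias correction.
Because photon streams are sparse, binned products are computed exactly by
photon-pair counting on sorted bin indices; `brute_force_correlate`
reproduces the identical estimator with dense binned arrays and is used as
the oracle (agreement is exact up to float round-off, since both routes sum
the same integers). Curve error bars come from splitting the acquisition
into 5 equal blocks and taking the standard error across block curves; the
fit weights are the inverse of these errors.

## Diffusion model and occupancies

Correlation curves are fit with the 3D free-diffusion model

    G_D(tau) = (1 - B/F)^2 / N * sum_i f_i
               * (1 + tau/tau_D,i)^-1 * (1 + tau/(kappa^2 tau_D,i))^-1/2,

where `N` is the occupancy of the effective volume
`V_eff = pi^1.5 w_xy^2 w_z`, `tau_D = w_xy^2/(4D)` the lateral dwell time,
`kappa = w_z/w_xy` the axial ratio (fixed at the calibration value, default
5, to avoid the known amplitude/kappa degeneracy), `B` the background rate
and `F` the mean detected rate. The `(1 - B/F)^2` factor corrects the
amplitude for uncorrelated background. The zero-lag amplitude is always the
fitted model amplitude, never the raw first lag point. A two-component
variant (fast free cargo + slow vesicle-bound, amplitude-weighted) is used
for EV samples that contain residual unincorporated cargo protein.

Occupancies follow the standard dual-color amplitude algebra:
`N_x = (1 - B_x/F_x)^2 / G_x(0)` per channel and

    N_rg = G_rg(0) N_r N_g^tot / [(1 - B_r/F_r)(1 - B_g/F_g)].

Two deliberate choices:

* **Total vs slow green amplitude.** The cross-correlation is normalized by
  the full green intensity, so the `N_g` in the product must be the
  total-amplitude occupancy. Using the slow-component amplitude instead
  over-counts by `((sum_i N_i eps_i)/(N_slow eps_slow))^2` (a factor ~7 in
  the stress-condition scenario). The slow-component occupancy is still what
  the report labels `N_g` — the vesicle-bound population — and what divides
  the green bound fraction. Residual bias from unequal label brightness
  (2-label vesicles vs 1-label free cargo) remains: the recovered dual
  occupancy is inflated by `eps_s (sum N eps)/(sum N eps^2)`, about +40% at
  the default free/bound ratio. No amplitude-only estimator can remove this
  without independent brightness knowledge; the report documents it instead.
* **Effective-volume correction.** The green and red volumes differ (287 vs
  372 nm waists, 300 nm axial offset), so the raw ratio `N_rg/N_r`
  underestimates the concentration ratio by `V_rg/V_eff,r` (~0.74 with the
  calibrated geometry). When the analysis config supplies both waist pairs
  and the offset, yields are rescaled to concentration ratios
  (`yield = (N_rg/N_r) V_eff,r / V_rg`); for matched volumes the correction
  is exactly 1. It can be disabled (`volume_correction=False`) to obtain the
  raw amplitude ratio.

Loading yield (FCCS) = `N_rg/N_r`; green bound fraction = `N_rg/N_g`.

## Background estimation

The iterative estimator starts from the global mean rate, detects bursts at
the current estimate, re-estimates from photons and time outside bursts, and
by default performs one refinement pass. On sparse streams this lands within
a few percent of the true rate. On occupancy >~0.05 streams the diffuse
transit tails bias the two-pass estimate upward (up to 2x); the pipeline
therefore iterates to a fixed point (`n_passes=12`, with a 1% convergence
stop), and accepts an externally measured background (a buffer/dark
measurement) through the analysis config, which is the recommended practice.

## Burst search and calibration

A photon is *hot* when the m-photon window centered on it spans at most
`m/(K B)` seconds (local rate >= K x background). Maximal runs of hot
photons form bursts; runs shorter than `min_photons` (default 20) are
dropped, so bursts are disjoint by construction. Burst duration is
first-to-last photon; the center time is the interval midpoint; burst
intensity is the background-subtracted mean rate `n/tau_burst - B`.
Defaults: m = 10, K = 6, rescaled per acquisition so K*B stays fixed when
the background varies. Note the burst *count* is not monotone in K (a
stricter threshold can split one long burst into several valid fragments);
the monotone object is the hot-photon set, which is nested in K.

Per channel, `(K, m)` are calibrated by grid search so the median burst
duration matches the FCCS diffusion time of that channel (ties break toward
the larger, stricter K). This is the closing-the-loop step that makes burst
durations readable as focal transits. For comparisons between conditions
the calibration is done once, on a reference condition, and the resulting
thresholds are carried to every other acquisition with K*B and m held fixed
(only K rescales with each acquisition's background); recalibrating per
condition puts different conditions on different operating points of the
multi-modal (K, m) landscape and makes their burst rates incomparable. The
analysis config accepts such fixed parameters.

## Coincidence, sizing, cargo

The matching tolerance is half the absolute difference of the two channels'
10% duration quantiles (two alternative readings are selectable:
half the 10% quantile of per-pair duration differences, and half of
min(q10)); candidate pairs with center times within the window are matched
greedily one-to-one by ascending offset. Each matched pair is read as one
dual-labeled vesicle.

Vesicle size uses the Stokes-Einstein sizing relation per channel,

    d = 4 k_B T tau_burst / (3 pi eta w_0^2),

the exact inverse of `tau_D = w^2/(4D)` with `D = k_B T/(3 pi eta d)`.
Size distributions are summarized by least-squares fitting the rescaled
gamma curve `C lam^a/Gamma(a) x^(a-1) e^(-lam x)` (free amplitude) to the
size histogram; the readout mean is `a/lam`. The histogram fit tracks the
bulk of the distribution; a maximum-likelihood alternative is available but
its mean equals the sample mean and is dragged ~+30% by the long-duration
tail of re-entrant transits.

Cargo count divides the green burst intensity by a *burst-referred*
molecular brightness. The FCS calibration brightness `eps = (F-B)/N` is a
volume average, `2^-3/2` of the beam-center rate; a detected burst averages
the intensity over the bright core of a transit, ~0.5 of beam center
(diffusive conditional-intensity decay over a +-tau_D/2 window, ~0.8, times
the impact-parameter average over the detection cross-section, ~0.65). The
burst-referred brightness is therefore `sqrt(2) * eps`; dividing by the raw
FCS brightness instead overstates the count by ~45% (2-label vesicles read
as 3). Raw (fractional) values are reported alongside integers (nearest,
half away from zero, floored at 0). Chance coincidences are reported as the
expectation `2 r_g r_r w` but not subtracted.

## Condition statistics

Acquisitions are split into consecutive subsets of 20 coincident events
(last partial subset dropped); subset spans run from the first event's start
to the last event's stop. Per-subset coincident rates and loading yields
feed Welch's unequal-variance t-test (two-sided, Welch-Satterthwaite
degrees of freedom, scipy implementation; the test suite checks it against
an independent implementation of the textbook formulas to 1e-10). Error
bars in summaries are standard deviations across subsets. No
multiple-testing correction is applied. Statistical power for rate
contrasts is assessed at the coincident-event level: event streams are
drawn as Poisson processes at the two conditions' rates and pushed through
the same subset-splitting and Welch machinery; a 3x rate contrast with 8
subsets of 20 events per condition is detected at p < 0.05 in essentially
every replicate.

## Synthetic-data generator

Species (vesicles, free dyes) perform periodic-boundary Brownian motion in
a cuboid box (3.8 x 3.8 x 19 um default — lateral dims >= 10x the largest
lateral waist, axial >= 10x the largest axial waist, so periodic images are
negligible per axis). Each species is integrated with its own time step
(lateral transit/20, discretization error of the intensity profile < ~1%);
species do not interact, so this is exact. Per step each label emits
detected photons as Poisson draws with mean
`brightness * I_c(r) * dt` for the anisotropic Gaussian profile of its
color (red focus axially shifted by 300 nm by default). Photon times are
uniform within the step and snapped to the sync grid: the macrotime is the
start tick of the photon's sync period, and the sub-period information
lives in the nanotime — gate start of the exciting laser plus an
exponential decay truncated to the gate, mirroring TCSPC hardware. Spectral
crosstalk is modeled as detector misassignment with the true laser's
nanotime statistics, which is exactly what PIE gating removes. Background
is homogeneous Poisson per channel with nanotimes uniform inside that
channel's gate, so the configured rate is the post-gating in-channel rate.
Every photon carries a ground-truth record (particle, species, origin).

Default study conditions: 287/372 nm lateral waists, kappa = 5, 300 nm red
axial offset, 200 cps background per channel, 40 MHz sync with 12.5 ns
interleave, water at 298.15 K (eta = 8.9e-4 Pa s; the acquisition
temperature is a config field, not a measured value), 2% green-into-red
crosstalk. Label brightness defaults: 12,000 cps per cargo label at beam
center (a bright but standard confocal EGFP-class value, CPM ~4.2 kcps) and
2,000 cps per membrane label (far-red FPs are ~5x dimmer), 8 membrane
labels per vesicle. Scenario presets: the measured-condition analogues
(`undifferentiated_like`, `partially_differentiated_like`) carry the
measured dual-labeled occupancies scaled up 100x (1.8e-4 -> 0.018,
2.8e-4 -> 0.028) so that desk-scale acquisitions of minutes, not hours,
collect usable statistics, plus a fixed red-only vesicle baseline
(occupancy 0.045) shared by both conditions — keeping the red channel in
the single-burst regime; the scaled loading fractions (0.29 / 0.38)
preserve the conditions' ordering but not the unscaled 3.1% / 4.4% values —
and a free unincorporated cargo species (D = 8e-11 m^2/s); a free-dye calibration
scenario (occupancy 0.3); an independent green-only/red-only null; a 30%
dual-labeled mixture at total occupancy 0.05; and monodisperse 90/120 nm
sizing scenarios at occupancy 0.05 (burst rates stay below ~5/s, the
single-vesicle-per-burst regime).

Not emulated: triplet/blinking photophysics, photobleaching, optical
saturation, detector dead time and afterpulsing, polarization, vesicle size
polydispersity within a species, label-number variation between vesicles of
a species, and non-ideal (non-Gaussian) detection profiles. Passing tests
therefore demonstrate the correctness of the estimators under the stated
model, not robustness to these instrument non-idealities.

## Numerical choices

Trajectories advance in float32 (position error << waist over a chunk);
photon emission uses exact Poisson thinning restricted to positions where
the log-intensity exceeds -25 (Poisson(mu)=0 almost surely below that).
Fits run through `lmfit` least squares with amplitude bounded at 0 and the
two-component slow time parameterized as fast x ratio (ratio >= 1) to keep
components ordered. Gamma histogram fits use 30 bins to the 99th
percentile. Quantiles interpolate linearly between order statistics.
Degenerate inputs (empty streams, constant size samples, zero-variance
Welch samples, single-color acquisitions) raise typed errors at the
operation level; the pipeline driver degrades gracefully for single-color
inputs (no calibration, zero-width tolerance window, NaN occupancies).

## Known limitations

* **Burst-based loading yield is a relative metric.** The coincident/red
  burst ratio underestimates the true dual-labeled fraction severalfold
  under the default geometry: the red channel detects transits out to
  larger impact parameters than the green channel (larger waist, more
  photons per transit), so ~40% of red bursts have no overlapping green
  burst at all, and burst fragmentation jitters center times by ~1 ms
  against a sub-ms tolerance window. The FCCS yield (volume-corrected) is
  the absolute estimator; the burst yield tracks differences between
  conditions measured with the same settings.
* **Coincidence selection biases matched-pair sizes.** Matching prefers
  pairs of similar duration, reading the wider channel's sizes low; size
  round trips are therefore evaluated on per-channel all-burst
  distributions, and the coincident-subset fits are reported for
  loaded-subpopulation selection only.
* **Two-component amplitude contamination.** With unequal label brightness
  the dual occupancy inherits a bias of order the brightness heterogeneity
  (+40% at default settings), as derived above.
* The calibration of burst parameters to the FCCS diffusion time makes the
  burst-duration scale deliberately circular with the FCS fit; sizing
  accuracy is limited by that of tau_D (a few percent here).
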