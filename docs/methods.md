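# Methods

## Analysis model

The package treats one assay run as four event tables (NEG, POS, H0.3,
H100) acquired on the same donor platelet-rich plasma (PRP). All stored
intensities are assumed linear; the pipeline applies its own log₁₀
transform (the instrument's amplification mode is not modelled). The
stages, in order:

1. **Compensation** (optional). Observed fluorescence is modelled as
   `observed = true @ S`, with `S` the spillover matrix (rows = source
   fluorophore, columns = detector, unit diagonal). Compensation solves
   the per-event linear system exactly; scatter channels are untouched.
   When no matrix is supplied the pipeline assumes compensation happened
   instrument-side and does nothing.
2. **Log transform.** Every value `x` becomes `log10(max(x, floor))`.
   The floor (default 0.1 instrument units) exists because compensation
   can produce non-positive values; it makes the transform total without
   affecting the populations of interest, which sit decades higher.
3. **Scatter gate.** Platelets form one compact cloud in log FSC /
   log SSC. The gate keeps events within median ± k·1.4826·MAD per axis
   (k = 3 default). The MAD-based spread makes the gate insensitive to
   debris; for a single Gaussian cloud k = 3 retains essentially all
   events. If ≥ 10 % of events fall outside the gate, a secondary
   scatter population is assumed and the run is flagged non-unique
   (flag only; the verdict logic is unaffected). Both k and the 10 %
   rule are config values; the 10 % convention quantifies "the
   population is unique", which is otherwise a visual judgement.
4. **CD41⁺ gate.** A Gaussian-kernel density (Silverman bandwidth,
   512-point grid over the data range) of log-FL2 within the scatter
   gate; the threshold is the deepest minimum between the two largest
   modes, and events above it are CD41⁺ platelets. A local maximum
   counts as a mode only if its peak reaches 2 % of the global maximum —
   below that, "modes" are kernel wiggles in the tails and chasing them
   would put the valley in the far tail of a unimodal density. A
   unimodal density (no resolvable debris) keeps all scatter-gated
   events and flags the result rather than failing, so clean data remain
   processable.
5. **Acquisition check.** Pass iff the CD41⁺ gate holds ≥ 10,000 events
   (configurable); otherwise a warning with the deficit. Simulated runs
   with 10,000 total events therefore always warn mildly — the check
   mirrors the acquisition target of real runs, where acquisition
   continues until the gate fills.
6. **Activation cutoff.** NEG and POS log-FL1 kernel densities are
   computed on a shared grid with a shared bandwidth (mean of the two
   Silverman choices) so their crossing is well defined; the cutoff is
   the crossing point strictly between the two modes, localised by
   linear interpolation between grid points. With multiple crossings the
   one minimising (NEG mass above + POS mass below) wins — the same
   misclassification-balancing motivation that justifies the
   intersection rule in the first place. No crossing between modes, or a
   NEG mode at/above the POS mode, raises a cutoff error: the PRP's
   control histograms are unusable. The historical rule (NEG mean + 2
   sample SD of log-FL1) is kept as `legacy_cutoff`; note it assumes a
   unimodal Gaussian NEG and overshoots when the baseline is partly
   activated.
7. **Percent activation.** `100 · #(log-FL1 > cutoff) / #gated`, strict
   inequality ("beyond" the threshold): boundary events are inactive.
   One cutoff per PRP, computed from NEG/POS and reused for both patient
   tubes.
8. **Index and decision.** `%HEPLA = 100·(%H0.3 − %H100)/(%POS − %NEG)`,
   negative values preserved. Decision thresholds (defaults): positive
   above 13, negative below 9.6 unless %H100 > 23 (then indeterminate
   with a high-%H100 flag), gray zone [9.6, 13] inclusive →
   indeterminate. The gray-zone lower bound is sometimes quoted as 9 %;
   9.6 is adopted as the authoritative value and the alternative remains
   a one-line config override. The high-%H100 flag is also reported in
   gray-zone results without changing the verdict. PRP validity: %NEG ∈
   [2.9, 19.3] (below: poorly reactive; above: over-reactive), %POS ≥
   84.9 (below: weak positive response), PRP age ≤ 180 min (inclusive —
   "not older than 3 h" is read as admitting the boundary). Across PRPs:
   any positive → positive; unanimous negatives → negative; otherwise
   indeterminate → repeat with new PRPs (initial round) or inconclusive
   (repeat round).

## Quality-control statistics

Batch series of control %HEPLA values are summarised as arithmetic mean,
sample (n−1) SD and %CV = 100·SD/mean; the n−1 convention is used
throughout (the population-SD alternative is within rounding at the
series sizes involved). Reporting rounds to one decimal; computation is
full precision. Control qualification: QCH ≥ 50, 13 < QCM < 50,
QCB < 9.6 (all %HEPLA). CV acceptability for QCH/QCM: ≤ 10 desired,
≤ 25 acceptable (warn), above fails; QCB is exempt — its mean is near
zero, so the ratio explodes and expresses donor variability, not assay
error. Reference limits from healthy-donor batch series: NEG mean ± 2 SD
and POS mean − 2 SD, with a warning below 20 batches.

## Synthetic data generator

The generator emulates the assay's measurement process, not any
particular instrument. Every component is log-normal (the standard
first-order model for cytometry intensities); all location/scale
parameters are in log₁₀ intensity units.

| parameter | default | rationale |
| --- | --- | --- |
| events per tube | 10,000 | the assay's acquisition target |
| platelet fraction | 0.90 | remainder is low-scatter CD41-dim debris |
| platelet scatter (logFSC, logSSC) | (2.0, 0.15), (1.7, 0.15) | compact platelet cloud |
| debris scatter | (1.0, 0.30), (0.7, 0.30) | a decade below platelets, broader |
| platelet FL2 vs debris FL2 | (2.5, 0.25) vs (0.8, 0.30) | CD41-bright vs CD41-dim, well separated |
| resting vs activated FL1 | (1.0, 0.30) vs (3.0, 0.30) | two-decade P-selectin shift; chosen so NEG ≈ 11 % and POS ≈ 93 % reproduce the published reference behaviour by construction |
| NEG / POS activation | 0.11 / 0.93 | healthy-donor baseline mean ≈ 11 %; strong agonist maximum |
| spillover | [[1, 0.12], [0.02, 1]] | FITC→PE-dominant crosstalk, applied last so the pipeline must compensate |
| low-responder frequency | 0.25 | population frequency of the low-affinity FcγRIIA variant |
| PRP drift | 0.03/h beyond 60 min | baseline creeps up, POS creeps down as the PRP ages (default age 90 min) |

Sample phenotypes set the patient-tube activation targets:
`hit_positive` (H0.3 = 0.85, H100 = baseline), `non_hit` (both
baseline), `heparin_independent` (both 0.75 — activation a heparin
excess cannot inhibit, the pattern that must come out indeterminate),
`low_responder_donor` (H0.3 collapses to baseline whatever the sample).
Control series back-solve the H0.3 target from the level's expected
index (QCH 92.6, QCM 26.5, QCB 2.6); reproducibility mode re-draws donor
baselines per run (SD 0.02 on NEG, 0.015 on POS), repeatability mode
repeats the same donor. A single seed derives fixed per-role substreams,
so tube order never changes results.

What the simulator does **not** model: doublets and aggregates,
microparticles, detector saturation and binned (integer) intensities,
time-dependent flow instabilities within an acquisition, continuous
heparin dose–response, and correlations between scatter and
fluorescence beyond population membership. Passing tests therefore show
the analysis chain is correct *given* a two-component log-normal world
with the configured separations; they do not certify performance on
instrument data whose populations overlap more or drift within a tube.

## Numerical choices

- Kernel densities use `scipy.stats.gaussian_kde` with an absolute
  bandwidth injected via the bandwidth factor; Silverman's rule
  `0.9·min(sd, IQR/1.34)·n^(−1/5)` is the default. Density grids are
  padded by 4 bandwidths so curves integrate to 1 within 1 %.
- The KDE mode (argmax) of a broad distribution is intrinsically noisy —
  for a standard normal at n = 10,000 its sampling SD is ≈ 0.1, because
  the density is flat at its peak. Mode-location checks in the tests are
  set accordingly; at the assay's realistic component spread (SD 0.3 in
  log-FL1) mode recovery is tight.
- Events are stored as float32 (instrument-like precision); the FCS
  writer emits `$DATATYPE F` list mode, so write/read round-trips are
  bit-exact. Compensation preserves the input dtype and is exact to
  float64 when given float64 data.
- Degenerate inputs: identical NEG/POS curves → cutoff error; zero
  scatter spread on an axis → that axis is ignored by the gate; constant
  FL2 → CD41 gate skipped with a flag; %POS ≤ %NEG → the index is
  refused and the PRP declared unusable; missing timestamps → stability
  is "warn", not a failure.

## Problem sizes

Tests and the acceptance script run every end-to-end check at the
assay's own scale — 10,000 events per tube, 9-run control series, 25
reference batches — which completes in seconds; nothing is scaled down.

## Known limitations

- The FCS reader handles FCS 3.0/3.1 list mode with uniform-width
  float/double/integer parameters and ignores analysis segments and
  non-channel keywords; it is intended for files this package writes and
  plain instrument exports, not as a general FCS library.
- The intersection cutoff needs both control modes resolvable; heavily
  overlapping NEG/POS histograms (a genuinely failed PRP) are rejected
  rather than guessed at.
- The decision layer implements the assay-internal algorithm only;
  integrating clinical pretest scores or immunoassay results is out of
  scope by design.
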