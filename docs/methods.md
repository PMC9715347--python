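# Methods

This note documents the models, protocols, and numerical choices behind
`fedstar`, and what the synthetic experiments do and do not demonstrate.

## Federated model and round semantics

A federation is a star: one aggregator, N collaborators, a plan agreed
before execution. Round r proceeds as

1. each collaborator asks for tasks and receives the plan's task list,
   exactly once per (collaborator, round);
2. it fetches the consensus weights of round r−1 (round −1 denotes the
   initial model), loads them into its local learner, runs the train
   task for `epochs_per_round` local epochs, and evaluates the validate
   task's metrics;
3. it submits the trained weights, its metrics, and its declared local
   dataset size n_i;
4. the round closes when the full roster has reported, or the abstract
   clock has advanced `round_cutoff` past the round opening and at least
   q = ⌈min_reporting_fraction × N⌉ submissions arrived. On close the
   plan's aggregation method combines the received updates per tensor
   name.

Rounds are strictly synchronous. Late submissions are acknowledged and
discarded; they are never merged into a closed round. Duplicate
submissions keep the first and log the second. If the cutoff passes with
fewer than q submissions the federation halts with an explicit error —
in a multi-institutional setting a silent partial aggregation is worse
than a loud stop. The default straggler policy is fraction 1.0 with an
infinite cutoff, i.e. wait for everyone, matching the synchronous design.

The clock is an injected float rather than wall time, which makes every
quorum/cutoff path deterministic and unit-testable, and the aggregator
journals every protocol action so a logged sequence replays into an
identical tensor store.

## Aggregation

The default rule is dataset-size-weighted averaging (FedAvg): consensus
= Σ n_i·x_i / Σ n_i element-wise. The weighting signal is the declared
local dataset size — the only per-site quantity the protocol carries that
is suitable as a weight. A coordinate-wise median (even counts: midpoint
of the two middle order statistics, the standard convention) is included
as a robust alternative, and a registry lets custom strategies plug in
under a plan-addressable name; custom aggregators receive the weighted
update group and the round index but never raw data.

Numerics: tensors travel as little-endian float32, row-major.
Aggregation stacks values in float64 and uses numpy's pairwise summation
before casting back to float32. The float64 headroom (29 extra mantissa
bits) means the order-dependence of the accumulation is far below
float32 resolution, so weighted means are bit-identical under submission
reordering after the final cast, and a single-member group reproduces
its input exactly. For the same reason the "all inputs equal x ⇒ output
is exactly x" conservation property holds in the emitted float32 even
though the intermediate float64 quotient may differ from x by ~k·2⁻⁵³.

## Built-in learners

Both reference adapters are logistic regressions trained by
(mini-)batch gradient descent, chosen because they make the federation's
correctness *provable* rather than merely plausible:

* with full-batch training and one local epoch per round, the weighted
  mean of per-site updates equals the pooled-gradient step exactly, so a
  federation must reproduce centralized descent to float precision — an
  internal oracle the tests exploit;
* a one-collaborator federation must be bit-identical to plain local
  training, because a single-member weighted mean round-trips float32
  values exactly through float64.

Parameters are held in float32 (the wire format), arithmetic runs in
float64, and mini-batch order is `default_rng(seed)` with seed =
(plan_seed XOR crc32(site_id) XOR round) masked to 31 bits — a pure
function of the federation configuration, never of wall time. Python's
builtin `hash` is deliberately avoided (it is salted per process).
Optimizer state beyond the weights is local and never transmitted.

The segmentation adapter classifies each pixel from three features
(intensity, 3×3 mean, 5×5 mean). This is intentionally the simplest
model that solves the synthetic lesion task; it keeps the federated
plumbing — not a deep network — the object under test. Defaults that
matter: learning rate 0.5 (tabular) is stable for standardized features
(|β|=2 logits); the segmentation task needs a larger step (≈5) because
the 8% foreground class imbalance shrinks the gradient.

## Synthetic multi-site data

The generators emulate the two study archetypes of real medical
federations — multi-hospital tabular risk modelling and multi-site
lesion segmentation — as pure functions of (config, seed).

**Tabular.** One ground-truth coefficient vector β (normalized to ‖β‖=2)
and intercept logit(class_balance) are drawn once per config. Site i
draws features from N(site_shift·u_i, I) with u_i a fixed per-site unit
direction, and labels Bernoulli(sigmoid(Xβ + b₀ + noise_sd·ε)).
site_shift = 0 gives an exactly IID split; site_shift ≈ 1.5–3 produces
clearly separated site means (non-IID covariate shift) while all sites
share the same conditional P(y|x). The held-out set is drawn per-site
with the same shifts and pooled, so both arms are scored identically.

**Segmentation.** Images are smoothed Gaussian noise plus 1–3 bright
elliptical lesions (semi-axes 2 to min(H,W)/6 px, placed fully in
bounds); the mask is the lesion union; each site adds
site_shift·v_i to the foreground intensity. The mean foreground
fraction is checked against an analytic ellipse-area band.

What these generators do **not** emulate: label shift between sites,
feature-schema mismatch, non-stationarity over rounds, realistic image
texture, or adversarial participants. Passing parity here shows the
*runtime* preserves the learning signal under sample-size and covariate
heterogeneity; it says nothing about deep-model behaviour on real scans.

## Parity experiments

The headline property is federated ≈ centralized. The parity harness
runs the federation (in-process transport), then trains the same
adapter from the same initialization on the pooled data with the same
total epoch budget (rounds × epochs_per_round), and compares held-out
accuracy. Experiments use 2 local epochs per round: with 1 epoch FedAvg
is algebraically identical to pooled descent and the comparison would
be vacuous; with 2 the optimization paths genuinely diverge and parity
is an empirical result (observed gaps ≲ 0.01 accuracy on 4-site IID
splits of n = 2000 over 20 rounds). The parity tolerance of 0.05
accuracy is this package's operationalization of "comparable
performance", not an externally reported number.

Problem sizes throughout (n = 2000 tabular samples, 32×32 images, ≤ 20
rounds) are chosen so the full suite runs in seconds on one CPU while
keeping every statistical check non-degenerate.

## Transport and identity

Only seven envelope kinds exist (tasks request/response, tensor
request/response, results submission, ack, finished); unknown kind bytes
fail decoding, and the aggregator dispatches nothing else — the protocol
surface is closed by construction. Frames carry CRC-32; corruption is an
integrity error, not a silent misread.

The in-process transport records every frame, which is how the data-
confinement tests byte-scan everything that would have crossed the wire
for any site's raw arrays. The TLS transport uses Python's `ssl` with
TLS ≥ 1.2, certificate verification required on both ends, and the
authenticated peer common name checked against the plan roster (the
aggregator refuses authenticated-but-unrostered peers; hostname checking
is disabled in favour of this roster binding).

PKI operations shell out to the `openssl` CLI; no cryptographic
primitive is implemented in this package. Floors enforced at creation
and at signing: RSA ≥ 3072 with SHA-384+, or ECDSA on secp384r1/
secp521r1. (Some references abbreviate the curve "secp384r"; secp384r1
is meant.) Validity windows and the verification clock are injectable
(`-not_before`/`-not_after`, `-attime`) so expiry is testable. The
internal CA is a research convenience only; production federations
should use an external CA.

## Design decisions and degenerate inputs

* **Plan dialect** is YAML restricted to scalars/maps/lists — anchors,
  aliases, and custom tags are rejected, keeping parsing deterministic
  and auditable. Canonical serialization fixes key order and emits
  defaults explicitly (a plan is a contract; elided settings invite
  disagreement). Only batch_size, the straggler block, and the seed may
  default.
* **Workspace archives** are tar.gz with sorted entries, zeroed
  timestamps and ownership, and gzip mtime 0, so identical inputs give
  identical bytes and a distributed workspace can be verified by hash.
  Import extracts to a temporary directory and validates the plan before
  materializing anything (a truncated or invalid archive leaves no
  partial files).
* **Tensor keys** use round ≥ 0 except round −1, reserved for the
  initial model that predates round 0.
* **Retention horizon**: the aggregator keeps tensors for the current
  and previous two-round window; older rounds are pruned to bound
  memory.
* **Empty model states, empty aggregation groups, NaN/Inf tensor
  values, zero-size sites, and out-of-range configs** are rejected with
  named errors at the boundary rather than propagated.

## Known limitations

Synchronous rounds only (no asynchronous/buffered aggregation); no
secure aggregation, differential privacy, or compression pipelines; no
vertical/cyclic/swarm topologies; the TLS transport is a reference
implementation, not a hardened network stack; and the wire format is
original — it is deliberately *not* compatible with any existing FL
framework's RPC schema.
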