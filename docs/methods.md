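# Model and methods

## The network

`whorfnet` simulates twelve cortical areas of the frontotemporal-occipital
cortex, arranged in four processing streams — ventral visual (V1–TO–AT),
dorsolateral motor (M1L–PML–PFL), auditory (A1–AB–PB) and articulatory
(M1i–PMi–PFi). Each stream chains a primary, a secondary and a multimodal
hub area; the four hubs (AT, PFL, PB, PFi) are fully interconnected and each
primary area additionally sends a "jumping" projection to its stream's hub.
Each area is a 25 × 25 grid of excitatory (e) cells, each paired with a
graded inhibitory (i) cell standing for the pooled local interneurons —
15,000 cells in total.

Synapses are sampled from clipped-Gaussian topographic kernels
(`p(dx,dy) = p0 · exp(-(dx²+dy²)/2σ²)` within a square neighborhood, zero
outside): within-area e→e links use p0 = 0.28, σ = 6.5 on a 19 × 19
neighborhood; between-area e→e links (only for area pairs in the macro
graph) p0 = 0.15, σ = 4.5; the local inhibitory loop (e→i and i→e) p0 =
0.295, σ = 2.0 on a 5 × 5 neighborhood. Grids wrap toroidally by default
(configurable to clipped borders) so every cell has a full neighborhood.
Created weights are uniform in [0, `w_init_max` = 0.1]; only e→e links are
plastic and they are hard-clipped to [0, `w_max` = 0.225].

## Cell dynamics

All state variables advance by explicit Euler steps with dt = 1 timestep, in
a fixed stage order (inputs → membrane → outputs → traces → plasticity);
outputs computed at step t drive inputs at step t+1 (one-step synaptic
transmission).

Membrane potential of an e-cell x:

    τ_e · dV/dt = −V + k1 · (g_syn·Σ_y w_xy φ(y) + Inp(x) − k_G ω_G(A_x))
                  − g_ie · Σ_i w_xi φ(i) + k1 k2 · η

with uniform white noise η ∈ [−0.5, 0.5] drawn freshly per cell and step
(i-cells receive no noise, k2 = 0 for them). An e-cell emits an
all-or-nothing spike when `V − α ω > thresh`; i-cells are graded,
`φ(i) = max(V(i), 0)`. Three first-order low-passes track slow variables:
adaptation `τ_adapt ω' = −ω + α_adapt φ` (τ = 10), the rate estimate
`τ_favg ω_E' = −ω_E + φ` (τ = 30 during learning, τ = 5 during circuit
extraction), and the area-wide global inhibition
`τ_glob ω_G' = −ω_G + Σ_area φ(e)` (τ = 12), which is subtracted from every
e-cell of the area and implements competition across the whole population.

### Parameter scales and calibration

The equation above carries three gain parameters whose values were fixed by
functional calibration of the regime, not by fitting any target quantity:

* `synaptic_gain` (g_syn = 100) sets the effective weight scale so that a
  handful of mature (w_max) links can ignite a quiescent cell
  (k1·g_syn·w_max ≈ 0.225 against thresh = 0.18), while the initial random
  weights produce only a 1–2σ bias relative to the membrane noise — enough
  for Hebbian correlation to bootstrap, not enough to fire anything on its
  own.
* `ei_gain` (20) makes an i-cell's potential track the spike count of its
  local 5 × 5 pool, and `ie_gain` (20) feeds that estimate back at membrane
  scale. This local loop is the fast brake: it reacts within ~τ_i = 5 steps
  and is spatially targeted, which is what permits per-link efficacies near
  threshold without runaway cascades (the global loop alone is too slow,
  τ_glob = 12, and too diffuse).
* `k_global` (k_G = 2.0) balances winner-take-all competition: with ~20-50
  cells of an area active, the subtracted inhibition is of threshold order,
  capping assembly size per area at a few tens of cells.
* `alpha_adapt` (0.14, with α = 7 at the threshold comparison) gives an
  effective adaptation of ≈ 1 × rate. This value matters for learning depth:
  adaptation much stronger than this caps every network-driven cell's
  sustained rate below the presynaptic plasticity threshold θ_pre, so no
  second-order recruitment (and hence no color-label binding) could ever
  occur; much weaker adaptation removes the per-cell brake and the network
  diverges.
* The noise discretization constant `dt` (0.15, giving amplitude
  k1·k2 = 0.01·3·√(24/dt) ≈ 0.38) is chosen so that noise excursions
  occasionally reach the plasticity band (θ± ≈ 0.15) of weakly driven cells
  — the mechanism by which new cells are recruited into assemblies — while
  staying mostly below the spiking threshold, so there is no sustained
  spontaneous firing to build spurious associations.

These calibration criteria were qualitative: distributed word circuits must
form across the perisylvian stream; perceptual-phase color circuits must
stay essentially confined to the visual stream; learning must be stable over
thousands of trials for arbitrary seeds. All gains are ordinary
configuration keys and can be overridden.

## Plasticity

Every plastic e→e synapse is updated once per timestep from the current
presynaptic rate estimate and postsynaptic potential, with a discretized
two-level rule (Δ = 0.008):

* LTP (+Δ): ω_E(pre) ≥ θ_pre and V(post) ≥ θ_+
* homosynaptic LTD (−Δ): ω_E(pre) ≥ θ_pre and θ_− ≤ V(post) < θ_+
* heterosynaptic LTD (−Δ): ω_E(pre) < θ_pre and V(post) ≥ θ_+

with θ_pre = θ_+ = 0.15 and θ_− = 0.14 (the homosynaptic band is half-open
at θ_+). Weights clip to [0, w_max]. Plasticity runs during stimulation and
the inter-stimulus interval of learning trials (configurable to
stimulation-only) and is frozen during extraction and recognition runs.

A consequence worth noting for interpretation: for a synapse from a
shade-specific visual cell onto a word-circuit cell under a *shared* label,
LTP during that shade's trials and heterosynaptic LTD during the sibling
shade's trials are exactly balanced, so these links follow a bounded random
walk rather than maturing monotonically. Links from word cells back to
visual cells, and links under one-to-one (distinct-label) pairings, mature
monotonically. Binding of a shared label therefore leans on the always-
co-active shared pattern core and on the word circuit's own attractor
dynamics, and is intrinsically less reliable than distinct-label binding at
small scale — see Limitations.

## Stimuli (synthetic-data generator)

All inputs are synthesized index sets over the 625 e-cells of a primary
area. Four color patterns target V1, each with 22 active cells (3.5% of the
area): the two shades of one color share a 5-cell core (22.8% of 22,
realized 22.7%) and every blue-green shade pair shares exactly one bridge
cell (5% of 22, realized 4.5%), drawn outside the cores so the overlap
matrix is exactly [[22,5,1,1],[5,22,1,1],[1,1,22,5],[1,1,5,22]]. Three word
forms are pairs of 22-cell patterns in A1 (auditory) and M1i (articulatory),
pairwise disjoint within an area — "no structural similarity" is
operationalized as zero overlap. The same pattern set is shared by all
simulated learners (configurable); only the connectivity seed varies across
networks. Non-relevant primary areas receive a fresh uncorrelated drive
every learning trial; the default form is a newly drawn 22-cell pattern at
full input strength (total drive matched to a learned pattern), with a
spread-over-all-cells variant available. The generator makes no attempt to
encode colorimetry (wavelength, hue, luminance); perceptual similarity is
represented purely as feature-neuron overlap, so passing tests demonstrate
label effects on overlap structure, not on realistic color encoding.

## Protocols

A learning trial stimulates the scheduled primary areas for 16 steps
(driven cells receive Inp = 700 inside the k1 rescaling, i.e. an effective
drive of 7 — far suprathreshold) followed by an inter-stimulus interval of
at most 30 steps, ended early once global inhibition has fallen below 0.55
in all of V1, TO, AT and PFL. Every trial begins with a membrane-potential
reset (V = 0 for all cells; adaptation, rate and inhibition traces persist,
read literally from the reset description; a full reset is available behind
a flag).

* Phase 1 (perceptual/phonological pre-exposure): the four color patterns
  and the three word pairs are presented separately, 1000 trials each at
  full scale, in one randomized sequence. Color trials drive V1 and noise
  drive goes to A1, M1i and M1L; word trials drive A1 and M1i simultaneously
  with noise to V1 and M1L.
* Phase 2 (semantic learning): from a byte-identical snapshot of the phase-1
  network per language model, each color is co-presented with its mapped
  word form (English: one label per color; Russian: distinct labels for the
  two blues, one for the greens), 1000 randomized trials per pairing at
  full scale, with noise drive to M1L.
* Extraction: plasticity frozen, V1 stimulated with a learned color pattern
  for 16 steps from a fully reset state, and the per-cell rate estimate
  (τ = 5) recorded over the following 30 steps for all 12 areas. The
  reactivation is repeated `extract_n_trials` = 3 times with independent
  noise and the rate tensors averaged: reactivation of marginally coupled
  circuits is noise-assisted (baseline noise scaled by
  `extract_noise_scale` = 1.4 during extraction and recognition), and
  averaging suppresses one-off noise ignitions while keeping consistently
  reactivated members.
* Recognition: plasticity frozen, a 2-step V1 stimulation embedded in a
  40-step recorded raster (10 baseline steps, 2 stimulation steps, 28
  post-offset steps).

Every random choice (connectivity, patterns, trial order, membrane noise,
extraction noise) descends from the experiment's master seed through named
substreams; a full experiment is exactly reproducible. A network whose
learning diverges (≥95% of an area firing in one step) is recorded as
diverged and excluded from analysis.

## Quantification

* Cell assemblies: per area, the membership threshold is γ times the peak
  rate estimate over all cells and the 30 recorded steps (γ = 0.5 default;
  the 20%-rule variant γ = 0.2 selectable); a cell is a member if its rate
  reaches the threshold at any step; areas with peak below 0.2 contribute
  nothing. Memberships are monotone in γ by construction.
* RSA: activation vectors are the unthresholded per-cell mean rates over
  the recorded window; dissimilarity is the Euclidean distance, and grouped
  values (visual, auditory, articulatory, hubs {AT, PFL, PB, PFi}, and the
  10 relevant regions excluding PML and M1L) average the per-region
  distances (concatenated-vector distance selectable).
* Neuron types: per region, shared = members of both shade assemblies,
  unique = members of exactly one; sharedness = shared/(shared+unique)·100.
* Mismatch proxy: recognition spikes are counted within the responsive-cell
  sets (20% rule) of the presented and sibling shade; the unique response is
  total minus shared, summed over the 10 relevant regions, and summarized as
  the mean over post-offset steps 2–12.
* Exclusion: a network is dropped when any two color assemblies exceed a
  Jaccard overlap of 0.8 over the relevant regions, when any single stimulus
  recruits more than half of an area, or when learning diverged. Both
  ceilings are configuration keys; no tuning of them was performed.

## Reduced-scale study and what it shows

The packaged acceptance study runs 4 network instantiations with 300
phase-1 trials per pattern and 300 phase-2 trials per pairing (the full
design uses 16 and 1000/1000); this fits in minutes on one CPU. At this
scale the pipeline reproduces the directional label effects: higher
blue-shade dissimilarity under distinct labels than under a shared label,
a much smaller between-model gap for the shared-label greens, unique-neuron
dominance with low sharedness (maximum regional mean ≈ 12%) for the
distinctly labeled blues, shared-neuron dominance for the shared-label
pairs, a larger blue-minus-green unique-response contrast in the
two-blue-label model, and the modulation of pre-formed visual
representations (same-label dissimilarity decreases, distinct-label
dissimilarity increases relative to the perceptual phase).

## Limitations

* Binding reliability: at reduced scale, ignition of a word circuit from a
  color stimulation crosses a narrow margin (a few mature converging cross
  links); whether a given same-label pairing binds in a given network is
  stochastic, with roughly a 70–80% per-network success rate. Mean-level
  shared-vs-unique dominance for one of the shared-label pairs can therefore
  fail for particular master seeds; the full-scale design averages this out
  over more networks and trials.
* The dynamical regime (gains, noise amplitude, adaptation gain) was
  calibrated qualitatively; the directional effects are robust within the
  calibrated neighborhood but the quantitative values (distances, counts)
  are specific to it.
* The stimulus model encodes similarity as set overlap only; no conclusions
  about real color encoding, hue spacing, or boundary placement follow from
  these simulations.
* Inhibitory weights are static; only e→e links learn.
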