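# mimenet

Directed causal-network inference for multichannel time series
(EEG-style recordings), built around a non-uniform mixed-embedding
conditional-mutual-information causality measure.

For every ordered channel pair the measure greedily assembles an embedding
from lagged values of both the driver and the driven series — each cycle
adds the candidate with the highest conditional mutual information with the
driven channel's future, stopping once the best addition contributes
almost nothing — and then scores the driver's share of that predictive
information as a ratio in [0, 1]. Moving-window matrices of these scores
feed a network layer:

- **intra networks** — thresholded at a fraction of the maximum
  time-averaged causality (per-subject fractions configurable);
- **contrast networks** — signed differences between two conditions,
  thresholded with the radius rule `R = (max − min)/2`, significant beyond
  `±R/2`;
- **degree centrality** — in/out degrees per node, window-averaged, with
  condition contrasts;
- **cross-subject networks** — synchronized recordings of two subjects are
  stacked into an augmented matrix whose off-diagonal blocks measure
  subject-to-subject flow; a directed link is drawn when one direction's
  electrode-averaged weight dominates per window and on average;
- **threshold sweeps** — edge-set stability reports under threshold
  perturbations (e.g. ±10 %).

Mutual information and conditional mutual information are estimated with
Kraskov–Stögbauer–Grassberger / Frenzel–Pompe k-nearest-neighbour
estimators on Chebyshev balls (numba-accelerated sorted-window scans).

A synthetic-data module generates multichannel signals with known
directed-coupling ground truth (linear AR, resonant band-limited "EEG-like"
AR(2), coupled Hénon-type maps; two-subject driver–responder pairs,
multi-subject ensembles with alternating "ping-pong" pairs, and
two-condition variants with planted contrast structure), which is what the
test-suite and the demo pipeline run on.

## CLI

```sh
# generate a synthetic scenario (CSV recordings + ground-truth JSON)
mimenet simulate --scenario reading --seed 1 --out sim/

# recording -> windowed causality matrices
mimenet analyze --input sim/condA.csv --fs 100 --window-s 10 --out mats/

# averaged matrices -> thresholded network edge list
mimenet networks --matrices mats/condA_w01.csv --matrices mats/condA_w02.csv \
    --frac 0.2 --out edges.csv

# windowed matrices -> degree-centrality table
mimenet centrality --matrices mats/condA_w01.csv --out degrees.csv

# threshold-stability report
mimenet sweep --matrix mats/condA_w01.csv --frac 0.2 --out sweep.json

# full demo pipeline on a synthetic scenario
mimenet run --scenario contrast --seed 1 --out out/
```

Scenarios: `intra` (single subject, planted couplings), `contrast` (two
conditions differing in one planted edge), `reading` (two-subject
driver–responder), `ensemble` (four subjects, star graph plus a ping-pong
pair). Every run writes its resolved config, a manifest naming the config
hash, and a log of all computed thresholds next to the artifacts.

## Layout

- `src/mimenet/cmi_estimation.py` — k-NN (C)MI estimators
- `src/mimenet/_neighbors.py` — neighbour-count backend
- `src/mimenet/mime_core.py` — embedding selection, causality index,
  causality matrices
- `src/mimenet/signal_io.py` — recordings, standardization, windowing,
  augmented stacking
- `src/mimenet/pipeline.py` — networks, contrasts, centrality, cross-subject
  links, sweeps
- `src/mimenet/synthetic_data.py` — ground-truth signal generators
- `src/mimenet/cli_config.py` — run config, orchestration, CLI
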