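# windcurtail

Curtailment-decision engine and evaluation pipeline for camera-based bird
detection at wind-power projects.

The package implements, end to end:

* **geometry** — turbines, spherical rotor-swept-zone (RSZ) models, camera
  towers, signed distance / time-to-collision kinematics, cylinder membership,
  and full/partial/none coverage classification of turbines by a camera
  network;
* **records** — archive ingestion (`records.csv`), multi-target and no-image
  exclusion filters, track assembly, and two-reviewer-plus-tiebreaker
  adjudication of track determinations;
* **identification** — confusion counts per time period (and optionally per
  tower), accuracy / false-negative / false-positive rates, and unweighted
  cross-period summaries;
* **engine** — the curtailment prescription (confidence > 89 % and either
  time-to-collision ≤ 60 s inside the outer cylinder, or presence in the
  inner cylinder) as a per-record rule plus an order state machine with a
  3-minute release hold and closest-approach distance classes;
* **evaluation** — pairing orders with determinations, per-week
  standardization, stratified summary tables and effectiveness metrics;
* **synthetic** — a seeded generator of complete input bundles (correlated
  random-walk tracks, forced RSZ transits, per-period label noise, reviewer
  noise, site layout) for testing and parameter-recovery experiments;
* **datasets** — the bundled reference counts of a year-long two-tower
  deployment, used by the acceptance checks.

## CLI

```bash
# generate a synthetic bundle
windcurtail simulate --out bundle/ --seed 7

# identification accuracy: confusion counts + rates
windcurtail evaluate-id --bundle bundle/ --out id_eval/

# run the curtailment prescription over every track
windcurtail curtail --bundle bundle/ --out orders/ [--prescription prescription.yaml]

# order summary by period, target class, coverage and distance class
windcurtail report --orders orders/orders.csv --bundle bundle/ --out report/
```

Each command writes a `manifest.json` with the configuration snapshot, input
digests and package version; fixed seeds give byte-identical outputs.

## File formats

All inputs and outputs are plain CSV/YAML/JSON: `records.csv`,
`reviews.csv`, `turbines.csv`, `cameras.csv`, `periods.yaml`,
`prescription.yaml`, `orders.csv`, `summary.csv`, `metrics.json`. Column
schemas are documented in the corresponding module docstrings.
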