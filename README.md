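# synkin

Kinematics and muscle-synergy analysis of repeated upper-limb motor tasks.

`synkin` implements a complete analysis pipeline for motor protocols in
which a subject repeats a set of movement variants — the motivating case
is the overhead volleyball set, nine variants of ten repetitions each —
while six upper-limb joint angles (100 Hz) and sixteen surface-EMG
channels (2000 Hz) are recorded. It is written for movement scientists,
biomechanists and sports researchers who need the full chain from raw
delimited-text exports to reliability tables:

* **Segmentation** — repetition onsets/offsets detected on the elbow
  flexion-extension velocity profile (3 Hz low-pass, derivative peaks
  above 20–30 % of the derivative amplitude, zero-crossing boundaries).
* **Joint-angle summaries** — per-set-type mean ± SD profiles (every
  repetition resampled to the longest) and range-of-motion (ROM) medians
  and quartiles per joint.
* **Muscle synergies** — EMG envelopes (10 Hz high-pass, rectification,
  5 Hz low-pass), padded 100-sample epochs assembled into an
  M × (K·T·N) matrix, and non-negative matrix factorization
  V ≈ W C (multiplicative updates, 20 random restarts per order) with the
  order chosen as the smallest S whose reconstruction
  R² = 1 − SSE/SST reaches 0.80.
* **Test–retest reliability** — optimal cosine-similarity matching of
  spatial synergies across sessions, Pearson correlation of temporal
  activation curves, and ICC(3,k) with 95 % CI and consistency bands
  (excellent > 0.90, good 0.75–0.90, moderate 0.50–0.75) for the
  joint-angle trajectories.
* **Synthetic sessions** — a ground-truth generator (known synergies,
  known event times, envelope-modulated band-limited EMG carriers) so the
  whole pipeline is testable without recordings.

See `docs/methods.md` for the model details, parameter choices and
limitations.

## Worked example

Simulate a reduced session (3 set types × 5 repetitions, five planted
synergies), run the full analysis at the generative order, and compare the
recovered spatial vectors with the truth:

```python
from synkin import (SimConfig, PipelineConfig, generate_ground_truth,
                    synthesize_session, analyze_session, match_synergies)

config = SimConfig(seed=7, n_set_types=3, n_reps=5)
truth = generate_ground_truth(config)
session = synthesize_session(truth, config)
result = analyze_session(session.kinematics, session.emg, session.manifest,
                         PipelineConfig(seed=7, n_restarts=10, synergy_order=5))

print("repetitions:", len(result.events))
print("R^2 at order 5:", round(result.synergy_model.r_squared, 3))
match = match_synergies(truth.spatial_in_normalized_units(),
                        result.synergy_model.W)
print("matched cosines:", [round(s, 3) for s in match.similarities])
```

prints

```
repetitions: 15
R^2 at order 5: 0.857
matched cosines: [0.985, 0.995, 0.999, 0.991, 0.993]
```

All fifteen planted repetitions were found, five synergies explain 85.7 %
of the envelope variance beyond each muscle's mean level, and every
recovered spatial vector matches its planted counterpart with cosine
similarity above 0.98. (Automatic order selection over orders 1..16 —
`PipelineConfig(synergy_threshold=0.80)` without a fixed order — behaves
the same way but scans all orders with 20 restarts each; on a full
9 × 10 session it recovers the generative order 5 and takes a few minutes.)

The same analysis is available from the shell:

```bash
synkin simulate --seed 7 --out session1/ --n-set-types 2 --n-reps 3
synkin run --kinematics session1/kinematics.csv --emg session1/emg.csv \
           --manifest session1/manifest.csv --out results1/
synkin retest --config1 session1.yaml --config2 session2.yaml --out report/
```

`run` writes the events, profile, ROM, W/C and R²-curve CSVs plus a JSON
run log (seeds, filters, restart count); `retest` writes the similarity,
temporal-correlation and kinematic-reliability tables.

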