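# pathint

Home-vector path integration under noise: simulators, closed-form error
records, and directed-walk ensemble statistics.

A navigating agent that keeps a running home vector (HV) by summing its own
movements can represent that vector in several ways: allocentric or
egocentric frames, with static (Cartesian-like) or dynamic (polar-like)
axis directions, or as a ring of many fixed directions with variable
moduli. Absent noise these representations are interchangeable. This
package simulates all of them under two noise sources — input noise
`delta` on every measured heading/rotation and update noise `eps` on every
state parameter written per step — and exposes the closed-form per-step
"neural records" showing why only the allocentric static-vectorial codes
(Cartesian, ring) degrade like an *allothetic* directed walk (fresh,
non-accumulating angular errors) while every egocentric or dynamic code
degrades like an *idiothetic* directed walk (accumulating errors, bounded
mean displacement, runaway variance).

## Layout

| module                 | contents |
|------------------------|----------|
| `pathint.core`         | angle wrapping, named RNG streams, `NoiseSpec`, `RealTrajectory` (+ CSV dialect) |
| `pathint.walks`        | straight walks, ADW/IDW generators, random turning walks, general biased elementary steps |
| `pathint.models`       | discrete-time HV updates for AC/AP/EC/EP/ring, sensing (compass, direct rotation, compass-differenced rotation), decoding, `run_pi` traces |
| `pathint.records`      | closed-form per-step records per class, reverse renumbering, record-sum vs sequential-simulation oracle |
| `pathint.stats`        | `E[cos delta]`, ADW mean shape, IDW finite limit, endpoint variance ordering, vectorized multi-model HV-error ensembles |
| `pathint.experiments`  | `ExperimentConfig`, the four-model ensemble experiment, deterministic fixtures |
| `pathint.cli`          | `pathint` command-line entry point |

## CLI

```sh
# one HV trace on a random turning walk
pathint simulate --model ac --steps 100 --seed 1 --delta-sd 0.0873 --out trace.csv

# closed-form neural records for one class and noise draw
pathint record --class esvr --n 5 --seed 3

# directed-walk statistics
pathint stats --what idw-limit --delta-sd 0.0873
pathint stats --what variance-ordering --n 100 --paths 10000 --seed 1

# the four-model ensemble experiment (defaults: 1000 paths x 1000 steps,
# turn SD 0.1, noise SDs pi/36); flags override a --config JSON file
pathint fig4 --paths 250 --steps 1000 --seed 7 --out-dir fig4_out

# deterministic worked-example bundle
pathint fixture --seed 0 --out fixture.json
```

Every run is fully determined by its config and seed; a structured config
echo is logged to stderr and written next to file outputs.

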