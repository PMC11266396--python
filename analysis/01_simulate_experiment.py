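"""Simulate the reference recording run and write per-column logfiles.

Ten individuals with mixed phototactic responses swim for five full days in
beam-barrier columns under a 15.5 h linear-ramp photoperiod; their beam
breaks are logged like the instrument would.  One column gets a dead
detector module injected to emulate the technical failure that cost one
animal in the reference deployment.
"""

import argparse
import os

import beambreak as bb


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--days", type=int, default=5)
    ap.add_argument("--individuals", type=int, default=10)
    ap.add_argument("--out-dir", default="scratch/logs")
    args = ap.parse_args()

    config = bb.default_config(n_individuals=args.individuals, days=args.days,
                               seed=args.seed)
    os.makedirs(args.out_dir, exist_ok=True)
    bb.save_config(config, os.path.join(args.out_dir, "experiment.yaml"))
    sensors = bb.sensor_frame(config)

    records = bb.simulate_experiment(config)
    faulty = config.individuals[-1].column_id
    records[faulty] = bb.inject_dead_module(records[faulty], 2)
    print(f"injected dead module 2 into column {faulty}")

    for col_id, df in records.items():
        path = os.path.join(args.out_dir, f"{col_id}.log")
        bb.write_log(df, path, sensors=sensors)
        gain = next(i.agent.phototaxis_gain for i in config.individuals
                    if i.column_id == col_id)
        print(f"{col_id}: {len(df):>8d} detections  (phototaxis_gain {gain:+.2f})")
    print(f"wrote logfiles and experiment.yaml to {args.out_dir}")


if __name__ == "__main__":
    main()
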