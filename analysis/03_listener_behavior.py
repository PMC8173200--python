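#!/usr/bin/env python
"""Simulate the listener experiment and score classification performance.

Draws a 51 familiar + 56 unfamiliar listener population whose choice
probabilities follow the configured logistic model over the *measured*
stimulus features (from 02_acoustic_features.py), then scores responses
against performer intent: pooled and per-participant confusion matrices,
accuracy, MCC with the zero-denominator rule, confidence summaries per
response quadrant, and the familiar-vs-unfamiliar Welch test on
per-participant MCCs.

Outputs: results/behavior/{responses,metrics,confusion,confidence}.csv and
behavior_summary.json
"""

import sys

import pandas as pd

from dundun.pipeline import run_behavior, write_csv
from dundun.synthetic import ListenerConfig, simulate_listeners


def main(seed: int = 1) -> None:
    stimuli = pd.read_csv("results/features/stimuli.csv")
    cfg = ListenerConfig(seed=seed + 1)
    responses = simulate_listeners(cfg, stimuli)
    write_csv(responses, "results/behavior/responses.csv")
    metrics, summary = run_behavior(responses, "results/behavior")
    print(f"{len(metrics)} participants, {len(responses)} responses")
    print(f"pooled accuracy: {summary['pooled_accuracy']:.3f}")
    print(f"mean per-participant MCC: {summary['mean_participant_mcc']:.3f}")
    print(f"familiar vs unfamiliar MCC: delta={summary['delta_mcc']:.3f}, "
          f"t({summary['df']:.1f})={summary['t']:.2f}, p={summary['p']:.2g}, "
          f"d={summary['d']:.2f}")
    print(f"unfamiliar MCC vs chance: mean={summary['mean_mcc_unfamiliar']:.3f}, "
          f"p={summary['unfamiliar_vs_zero_p']:.2g}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
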