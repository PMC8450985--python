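#!/usr/bin/env python
"""Simulate the cued motion-discrimination study and summarize behavior.

Generates the default synthetic study (222 participants, 5 blocks x 40
trials, half neutral cues, 80% cue validity, starting-point bias
ground truth), applies the 200-1500 ms RT filter, and writes the trial
table plus retention and behavioral summaries under the output
directory.  The printed table should show the signature cue-validity
pattern: valid trials fastest and most accurate, invalid least.
"""

import argparse
import logging

from cuebias.pipeline import RunConfig, cmd_simulate, prepare_study

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out", default="results/study")
parser.add_argument("--seed", type=int, default=20210525)
parser.add_argument("--n-participants", type=int, default=222)
args = parser.parse_args()

logging.basicConfig(level=logging.INFO)
config = RunConfig(
    output_dir=args.out,
    master_seed=args.seed,
    synthetic={"n_participants": args.n_participants},
)
cmd_simulate(config)
data, retention, summary = prepare_study(config)

print(f"\nmean retention: {retention['mean_retention_pct']:.2f}% "
      f"(range {retention['min_retention_pct']:.1f}-{retention['max_retention_pct']:.1f}%)")
print("\nper-condition behavior (mean of participant medians / accuracy):")
print(summary.to_frame().round(3).to_string(index=False))
print("\ncorrelations with the trait score (null by construction):")
print(summary.aq_correlations.round(3).to_string())
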