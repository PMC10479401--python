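#!/usr/bin/env python
"""Feedback-loop plasticity model: severed vs. intact vs. silenced loop.

Runs 100 pairings of sensory channel 1 with hippocampal feedback in the
three regimes and writes per-step traces plus a fold summary.  Expected
outcome: the severed ("slice") loop potentiates the paired weight 1.5-fold,
the intact loop compounds to ~2.29-fold, silencing the hippocampus abolishes
potentiation, and the unpaired channel never moves.
"""

import argparse
from pathlib import Path

from hcloop.validate import model_report


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/model"))
    args = ap.parse_args()

    summary = model_report(out_dir=args.out)
    print("Feedback-loop model, 100 pairings of S1 (alpha = 0.005):")
    for regime in ("severed", "intact", "silenced"):
        r = summary[regime]
        print(f"  {regime:9s} fold(w1) = {r['fold_w1']:.4f} "
              f"(closed form {r['closed_form_w1']:.4f}, "
              f"gap {r['closed_form_gap']:.2e})")
    print(f"  unpaired channel fold = {summary['severed']['fold_unpaired']:.1f}")
    print(f"traces and summary written to {args.out}/")


if __name__ == "__main__":
    main()
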