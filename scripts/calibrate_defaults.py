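"""Regenerate the packaged default scoring functions.

Fits the piecewise-linear scoring functions from the packaged
endpoint/score tables (goal-pinned knots, table/text-inconsistent cells
excluded) and freezes the result as ``src/aptqa/data/
scoring_functions.json``, the set returned by
``aptqa.io.default_scoring_functions``.

Run from the repository root:

    python scripts/calibrate_defaults.py
"""
from pathlib import Path

from aptqa.io import load_endpoint_fixture, load_scorecard_fixture, save_scoring_functions
from aptqa.scoring import calibrate


def main() -> None:
    result = calibrate(load_endpoint_fixture(), load_scorecard_fixture())
    out = Path(__file__).resolve().parent.parent / "src" / "aptqa" / "data" / "scoring_functions.json"
    save_scoring_functions(result.functions, out)
    kept = result.residuals[~result.residuals.excluded]
    print(f"wrote {out}")
    print(f"{len(kept)} calibration pairs, max |residual| = {kept.residual.abs().max():.4f}")
    for key, fn in result.functions.items():
        print(f"  {key}: {fn}")


if __name__ == "__main__":
    main()
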