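#!/usr/bin/env python
"""Regenerate the packaged synthetic example quality-score profile.

Trains match/mismatch matrices on the package's own simulator (binned
quality levels 27/31/34/37/40, independent errors plus first-strand shared
errors at 1e-3, ~1.2M overlap columns) and writes them to
src/pairstitch/data/. These matrices are synthetic — illustrative defaults
demonstrating the file format and the trained-profile code path, not
calibrations of any real instrument.

Usage: python scripts/train_example_profile.py [--out-dir DIR]
"""

import argparse
import sys
import warnings
from pathlib import Path

from pairstitch.align import AlignParams, find_best_alignment
from pairstitch.merge import stitch
from pairstitch.profiles import train_from_pairs
from pairstitch.quality import QualityModel, write_matrix_file
from pairstitch.simulate import SimConfig, simulate

SEED = 301


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument(
        "--out-dir",
        type=Path,
        default=Path(__file__).resolve().parents[1] / "src" / "pairstitch" / "data",
    )
    args = ap.parse_args()

    cfg = SimConfig(
        n_pairs=26_000,
        seed=SEED,
        quality=("levels", (27, 31, 34, 37, 40)),
        shared_error_rate=1e-3,
    )
    params = AlignParams(allow_dovetail=True)
    scheme = QualityModel.fastqjoin()
    merged, origs = [], []
    for pair, truth in simulate(cfg):
        origs.append((pair, truth))
        aln = find_best_alignment(pair, params)
        if aln is not None:
            merged.append((stitch(pair, aln, scheme), truth))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, _, tally = train_from_pairs(
            merged, origs, qual_max=40, min_mismatch=10
        )
    match_path = args.out_dir / "synthetic_match.tsv"
    mismatch_path = args.out_dir / "synthetic_mismatch.tsv"
    write_matrix_file(model, match_path, mismatch_path)
    for path in (match_path, mismatch_path):
        text = path.read_text()
        path.write_text(
            "# SYNTHETIC example profile: trained on pairstitch-simulated\n"
            "# reads (scripts/train_example_profile.py), not on instrument\n"
            "# data. Binned qualities 27/31/34/37/40, shared-error rate 1e-3,\n"
            f"# seed {SEED}, {tally.total_columns} overlap columns.\n" + text
        )
    print(f"wrote {match_path} and {mismatch_path}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
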