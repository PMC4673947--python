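"""Baseline-correct and 0-1 normalize the simulated spectra.

Applies asymmetric-least-squares baseline removal followed by per-spectrum
min-max normalization over the full 1000-3000 cm⁻¹ range — the same
treatment every spectrum receives before difference spectra are formed.

Reads results/spectra.csv; writes results/preprocessed.csv.
"""

import argparse
from pathlib import Path

from ftirdose.preprocess import PreprocessParams, preprocess_collection
from ftirdose.spectra import read_spectra, write_spectra


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    src = args.out_dir / "spectra.csv"
    if not src.exists():
        raise SystemExit(f"{src} not found - run analysis/01_simulate_spectra.py first")
    collection = read_spectra(src, dialect="wide")
    params = PreprocessParams()
    done = preprocess_collection(collection, params)
    write_spectra(done, args.out_dir / "preprocessed.csv", dialect="wide")
    print(f"preprocessed {len(done)} spectra "
          f"(ALS lambda={params.baseline_lambda:g}, p={params.baseline_p}; "
          f"normalized to [0, 1])")


if __name__ == "__main__":
    main()
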