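#!/usr/bin/env python
"""Generate the synthetic datasets every later stage consumes.

Writes site-A-like and site-B-like ground-truth models, triplicate MST
titration CSVs (pH 5.6-7.4, 16-point two-fold dilutions, noise SD 0.02) and
lambda titration CSVs (10-value pH subset, 400 frames to keep files small),
plus a checksum manifest, under results/data/.
"""

from pathlib import Path

from zincsite.synthetic_data import write_fixtures

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    manifest = write_fixtures(OUT, seed=2026)
    print(f"wrote {len(manifest['files'])} files to {OUT} (seed {manifest['seed']}):")
    for name in sorted(manifest["files"]):
        print(f"  {name}")


if __name__ == "__main__":
    main()
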