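#!/usr/bin/env python
"""One-time download of the deposited myosin-II structures used by the
deposited-structure checks (network required; nothing in the package or
the test defaults depends on it succeeding).

Fetches 6Z7T (myosin-II.ADP.blebbistatin), 6Z7U (apo rigor-like), 1VOM
(pre-power stroke) and 2AKA (dynamin-fusion rigor-like) from the PDB
into tests/data/deposited/.

Usage:  python scripts/fetch_structures.py [--dest tests/data/deposited]
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

ACCESSIONS = ("6Z7T", "6Z7U", "1VOM", "2AKA")
URL = "https://files.rcsb.org/download/{}.pdb"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--dest",
        type=Path,
        default=Path(__file__).resolve().parent.parent / "tests" / "data" / "deposited",
    )
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        out = args.dest / f"{acc.lower()}.pdb"
        if out.exists():
            print(f"{out} already present")
            continue
        print(f"downloading {acc} ...")
        urllib.request.urlretrieve(URL.format(acc), out)
        print(f"  -> {out}")


if __name__ == "__main__":
    main()
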