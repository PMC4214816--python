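#!/usr/bin/env python
"""One-time converter: field-study spreadsheet -> the package's CSV schema.

The analysis core reads only delimited text.  This helper splits a
spreadsheet workbook holding the field tables into the five CSV files the
pipeline expects (community.csv, biomass.csv, env.csv, coords.csv,
hierarchy.csv), written to --out (default data/field/).

The workbook must contain one sheet per table; sheet names are matched
case-insensitively against the table names above (rename sheets first if
the workbook uses different labels).  Every sheet needs a header row with
the sampling-point identifier in the first column; the hierarchy sheet
needs columns point_id, site_id, area_id, region_id.

Usage:
    python scripts/convert_field_xlsx.py dataset.xlsx --out data/field
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

TABLES = ("community", "biomass", "env", "coords", "hierarchy")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("workbook", type=Path)
    parser.add_argument("--out", type=Path, default=Path("data/field"))
    args = parser.parse_args()

    sheets = pd.read_excel(args.workbook, sheet_name=None, index_col=0)
    lookup = {name.strip().lower(): frame for name, frame in sheets.items()}
    missing = [t for t in TABLES if t not in lookup]
    if missing:
        raise SystemExit(
            f"workbook lacks sheet(s) {missing}; found {sorted(lookup)} — "
            "rename the sheets to the expected table names and retry"
        )

    args.out.mkdir(parents=True, exist_ok=True)
    for table in TABLES:
        frame = lookup[table]
        frame.index = frame.index.astype(str).str.strip()
        path = args.out / f"{table}.csv"
        frame.to_csv(path, float_format="%.17g")
        print(f"wrote {path} ({frame.shape[0]} rows x {frame.shape[1]} columns)")


if __name__ == "__main__":
    main()
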