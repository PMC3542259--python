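#!/usr/bin/env python
"""Download and assemble the lymphoma expression dataset (needs network).

Fetches the public two-channel microarray data hosted at
http://llmpp.nih.gov/lymphoma/data/figure1/ (log2 Cy5/Cy3 ratios; rows are
cDNA clones, columns are mRNA samples) and writes the two files the
lymphoma analysis and its acceptance test expect:

    data/lymphoma/expression.tsv   gene_id + one column per retained array
    data/lymphoma/groups.tsv       sample -> control / experimental

The analysis subset holds 4026 genes with 14 normal circulating B-cell
(NBC) arrays as the control group and 20 lymphoma arrays (9 follicular
lymphoma + 11 chronic lymphocytic leukaemia) as the experimental group.
Column selection is by sample-name prefix; verify the counts printed at the
end (14 / 20) before running the analysis, since the upstream file layout
may change.
"""

import re
import sys
import urllib.request
from pathlib import Path

import pandas as pd

URL = "http://llmpp.nih.gov/lymphoma/data/figure1/figure1.cdt"
OUT_DIR = Path(__file__).resolve().parent.parent / "data" / "lymphoma"

CONTROL_PATTERNS = [r"blood b", r"\bnbc\b", r"cord blood b"]
EXPERIMENTAL_PATTERNS = [r"\bfl\b", r"\bcll\b", r"follicular", r"chronic lymphocytic"]


def _matches(name: str, patterns) -> bool:
    low = name.lower()
    return any(re.search(p, low) for p in patterns)


def main() -> int:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    raw_path = OUT_DIR / "figure1.cdt"
    if not raw_path.exists():
        print(f"downloading {URL} ...")
        urllib.request.urlretrieve(URL, raw_path)
    table = pd.read_csv(raw_path, sep="\t", low_memory=False)
    # CDT layout: metadata columns first (GID/UNIQID/NAME/GWEIGHT), then arrays;
    # an EWEIGHT row may follow the header.
    table = table[table.iloc[:, 0].astype(str).str.upper() != "EWEIGHT"]
    id_col = "UNIQID" if "UNIQID" in table.columns else table.columns[1]
    meta = {c for c in table.columns if c.upper() in {"GID", "UNIQID", "NAME", "GWEIGHT"}}
    arrays = [c for c in table.columns if c not in meta]
    control = [c for c in arrays if _matches(c, CONTROL_PATTERNS)]
    experimental = [c for c in arrays if _matches(c, EXPERIMENTAL_PATTERNS)]
    print(f"genes: {len(table)}  control arrays: {len(control)}  "
          f"experimental arrays: {len(experimental)}")
    expr = table.set_index(id_col)[control + experimental]
    expr.index.name = "gene_id"
    expr = expr[~expr.index.duplicated()]
    expr.to_csv(OUT_DIR / "expression.tsv", sep="\t", na_rep="NA")
    groups = pd.DataFrame(
        {
            "sample": control + experimental,
            "group": ["control"] * len(control)
            + ["experimental"] * len(experimental),
        }
    )
    groups.to_csv(OUT_DIR / "groups.tsv", sep="\t", index=False)
    print(f"wrote {OUT_DIR / 'expression.tsv'} and {OUT_DIR / 'groups.tsv'}")
    if len(control) != 14 or len(experimental) != 20:
        print("WARNING: expected 14 control / 20 experimental arrays; "
              "adjust the name patterns for the analysis subset.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
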