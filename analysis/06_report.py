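"""Consolidate the analysis outputs into one markdown report."""

from pathlib import Path

import pandas as pd

RESULTS = Path(__file__).resolve().parent.parent / "results"

TABLES = [
    "diversity.tsv", "active_calls.tsv", "lifestyle_records.tsv",
    "lifestyle_summary.tsv", "network_stats.tsv", "zp_data.tsv",
]


def main() -> None:
    missing = [t for t in TABLES if not (RESULTS / t).exists()]
    if missing:
        raise SystemExit(f"run earlier analysis steps first; missing {missing}")
    lines = ["# Simulated particle-sinking analysis report", ""]
    for name in TABLES:
        df = pd.read_csv(RESULTS / name, sep="\t")
        lines += [f"## {name}", f"rows: {len(df)}", "",
                  df.head(15).to_markdown(index=False), ""]
    (RESULTS / "report.md").write_text("\n".join(lines))
    print(f"report with {len(TABLES)} tables -> {RESULTS / 'report.md'}")


if __name__ == "__main__":
    main()
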