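"""Metabolome: dry-weight normalisation and both contrasts
(C/N=150 vs C/N=10 at 9 h; 9 h vs 1 h within C/N=150) at p < 0.01.

Writes results/metabolites_diff.tsv.
"""

from pathlib import Path

from nlim import io_formats, metabolome

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "dataset"
RESULTS = ROOT / "results"


def main() -> None:
    table = io_formats.read_metabolite_table(DATA / "metabolites.tsv")
    res = metabolome.metabolite_contrasts(table, alpha=0.01)
    RESULTS.mkdir(exist_ok=True)
    res.to_csv(RESULTS / "metabolites_diff.tsv", sep="\t", index=False)
    for contrast, sub in res.groupby("contrast"):
        up = ((sub["significant"]) & (sub["log2fc"] > 0)).sum()
        down = ((sub["significant"]) & (sub["log2fc"] < 0)).sum()
        print(f"{contrast}: {up} metabolites up, {down} down (p<0.01, n={len(sub)})")


if __name__ == "__main__":
    main()
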