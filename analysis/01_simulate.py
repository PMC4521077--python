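"""Generate the reference synthetic multi-location dataset.

20 locations in 4 synthetic countries spanning cool to warm climates, 5 years
of daily deaths and temperatures each, driven by a known V-shaped cumulative
exposure function distributed over 21 days of lag.  Writes the per-location
CSVs and metadata under scratch/data/ (bulk inputs) and the true attributable
fractions — the oracle every later stage is judged against — under results/.
"""

from pathlib import Path

import tempmort as tm

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    cfg = tm.default_scenario(n_locations=20, years=5, seed=SEED)
    ds = tm.generate_dataset(cfg)
    data_dir = ROOT / "scratch" / "data"
    tm.write_dataset_csvs(ds, data_dir / "series", data_dir / "metadata.csv")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    ds.true_af.to_csv(out / "true_attributable_fractions.csv", index=False)
    print(f"wrote {len(ds.series)} locations under {data_dir / 'series'}")
    print(
        f"true pooled AF: total {100 * ds.pooled_true_af():.2f}%, "
        f"cold {100 * ds.pooled_true_af('cold'):.2f}%, "
        f"heat {100 * ds.pooled_true_af('heat'):.2f}%"
    )


if __name__ == "__main__":
    main()
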