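"""How the pooled estimates evolved as evidence accumulated.

For every preference: year-wise and study-wise cumulative traces, the
Proteus first-vs-rest test, the decades-since-publication meta-regression
and the sample-size trend. Traces land in results/cumulative/, the test
summaries in results/history.json.
"""

import json
from pathlib import Path

from agemeta import (
    cumulative_meta,
    load_dataset,
    proteus_test,
    sample_size_trend,
    trend_decades,
)

DATA = Path("results/data")
OUT = Path("results/cumulative")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    summary = {}
    for pref in ("risk", "time", "social", "effort"):
        ds = load_dataset(DATA / f"{pref}.csv")
        for order in ("by_year", "by_study"):
            trace = cumulative_meta(ds, order)
            trace.steps.to_csv(OUT / f"{pref}_{order}.csv", index=False)
        prot = proteus_test(ds)
        trend = trend_decades(ds, reference_year=2022)
        ssize = sample_size_trend(ds)
        summary[pref] = {
            "proteus": prot.to_dict(),
            "decades_slope": float(trend.beta[1]),
            "decades_slope_p": float(trend.p_robust[1]),
            "log_n_per_year_slope": ssize["slope"],
            "log_n_per_year_p": ssize["p"],
        }
        print(f"{pref:>7}: Proteus z = {prot.z:+.2f} (p = {prot.p:.3f}, "
              f"first study {prot.first_study_id}); effect-size trend "
              f"b = {trend.beta[1]:+.3f}/decade (p = {trend.p_robust[1]:.3f}); "
              f"log-n trend {ssize['slope']:+.4f}/yr (p = {ssize['p']:.3f})")
    (Path("results") / "history.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"\ntraces in {OUT}/, summary in results/history.json")


if __name__ == "__main__":
    main()
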