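#!/usr/bin/env python
"""Per-channel absolute band power (delta/theta/alpha/beta).

Welch PSD (2-s Hann segments, 50% overlap) per epoch set, integrated over
the four clinical bands, one row per subject x channel x band. The
group-level one-way ANOVA on mean power is reported per band. Note that the
generator assigns different source resonances to different groups, so the
synthetic cohort shows strong band-power group effects — unlike
connectivity, power was not a calibration target (see docs/methods.md).
"""

from pathlib import Path

import pandas as pd

from dmnpdc.band_power import absolute_band_power, welch_psd
from dmnpdc.group_stats import oneway_anova
from dmnpdc.preprocessing import preprocess
from dmnpdc.synthetic import GROUPS, load_cohort

OUT = Path("results/band_power.csv")

if __name__ == "__main__":
    cohort = load_cohort("results/cohort")
    tables = []
    for s in cohort.subjects:
        eps = preprocess(s.recording, apply_bandpass=False)
        freqs, psd = welch_psd(eps)
        tab = absolute_band_power(freqs, psd, labels=eps.labels)
        tab.insert(0, "subject_id", s.id)
        tab.insert(1, "group", s.group)
        tables.append(tab)
    power = pd.concat(tables, ignore_index=True)
    power.to_csv(OUT, index=False)
    print(f"wrote {len(power)} rows to {OUT}")
    for band in ("delta", "theta", "alpha", "beta"):
        per_subj = (
            power[power.band == band]
            .groupby(["group", "subject_id"])["power"]
            .mean()
        )
        res = oneway_anova([per_subj[g].values for g in GROUPS])
        print(f"{band:6s} power ANOVA: {res}")
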