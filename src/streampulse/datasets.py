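"""Bundled example data.

``load_peak_vs_composite_example`` returns a small published comparison of
maximum 20-minute concentrations against 3.5-day composite concentrations
for pesticides that exceeded their acute quality standard in a Swiss
agricultural stream, together with the applicable AQS and RAC values
(ng/l).  Compounds with an empty ``max_20min`` were only measured by the
composite program; the censored diuron composite carries its LOQ so the
underestimation factor can be reported as a lower bound.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_peak_vs_composite_example"]


def load_peak_vs_composite_example() -> pd.DataFrame:
    with resources.files("streampulse.data").joinpath(
        "peak_vs_composite_example.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df["composite_below_loq"] = df["composite_below_loq"].astype(bool)
    return df
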