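"""Bundled reference tables from a published straddle-harvester field campaign.

Three small summary tables accompany the package as worked-example inputs:

* ``volume_survey`` — per-variety, per-treatment transect volumes (convex
  hull and alpha shape), working alpha values and point-cloud densities
  before (BH) and after (AH) harvest for both scanner orientations;
* ``vibration_survey`` — per-tree maximum vector-magnitude acceleration (g)
  and vibration time (s) under each speed/beating-frequency treatment;
* ``harvest_efficiency_survey`` — per-treatment time to harvest, fruit
  removal % and fruit-on-ground %.

The raw field data behind these summaries were never deposited; the tables
carry the printed summary values only, which is what the differencing and
averaging utilities here operate on.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_volume_survey", "load_vibration_survey",
           "load_harvest_efficiency_survey"]


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("olivescan.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def load_volume_survey() -> pd.DataFrame:
    """Transect volume/density survey, one row per variety-treatment-sensor-phase."""
    return _load("volume_survey.csv")


def load_vibration_survey() -> pd.DataFrame:
    """Per-tree vibration maxima and durations, one row per monitored tree."""
    return _load("vibration_survey.csv")


def load_harvest_efficiency_survey() -> pd.DataFrame:
    """Per-treatment harvesting efficiency summary."""
    return _load("harvest_efficiency_survey.csv")
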