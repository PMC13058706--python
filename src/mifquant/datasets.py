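"""Small bundled reference tables from the assay's validation study.

Two plain-text tables ship with the package:

* the epitope elution-tolerance matrix measured for the 5-plex B-lineage
  panel (single-plex staining after 0-4 simulated elution cycles, % change
  in thresholded MFI relative to the non-eluted position), together with
  antibody clones, host species and the final published sequence positions;
* the cumulative per-gate cell counts from the tonsil (TN, 2 slides) and
  lupus-nephritis kidney (KD, 8 slides) validation cohorts.

They let the panel-ordering optimizer and the cohort proportion arithmetic
be exercised against published numbers without any image data.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .panel import ToleranceMatrix
from .report import CohortSummary, cohort_from_counts


def _data_path(name: str):
    return importlib.resources.files("mifquant").joinpath("data", name)


def elution_tolerance() -> ToleranceMatrix:
    """The measured 5-plex elution-tolerance matrix (markers x 5 positions)."""
    with importlib.resources.as_file(_data_path("elution_tolerance.csv")) as p:
        df = pd.read_csv(p, index_col="marker")
    pos_cols = [c for c in df.columns if c.startswith("position_")]
    return ToleranceMatrix(
        markers=list(df.index),
        hosts=list(df["host"]),
        values=df[pos_cols].to_numpy(float),
        clones=list(df["clone"]),
    )


def published_final_positions() -> dict[str, int]:
    """The sequence positions actually used in the published 5-plex panel."""
    with importlib.resources.as_file(_data_path("elution_tolerance.csv")) as p:
        df = pd.read_csv(p, index_col="marker")
    return {m: int(v) for m, v in df["final_position"].items()}


def cohort_counts() -> pd.DataFrame:
    """Cumulative per-gate counts for the TN and KD validation cohorts."""
    with importlib.resources.as_file(_data_path("cohort_counts.csv")) as p:
        return pd.read_csv(p)


def validation_cohorts() -> dict[str, CohortSummary]:
    """The validation cohorts as :class:`CohortSummary` objects.

    Only cumulative counts are bundled (area and per-slide data are not),
    so densities are not meaningful on these objects — the derived
    count-ratio proportions are.
    """
    df = cohort_counts()
    out: dict[str, CohortSummary] = {}
    for label, grp in df.groupby("cohort", sort=False):
        counts = dict(zip(grp["gate"], grp["count"].astype(int)))
        out[label] = cohort_from_counts(
            label, counts, n_slides=int(grp["n_slides"].iloc[0]),
        )
    return out
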