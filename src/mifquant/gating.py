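"""Marker-positivity thresholds, autofluorescence rejection, and phenotype gates.

A cell is positive for a marker when its MFI is at or above the marker's
cutoff (>= so boundary behaviour is deterministic).  Cells bright in the
autofluorescence channel are rejected outright before any gate membership
is computed — the standard guard against tissue artifacts masquerading as
stained cells.

The default gate set encodes a B-lineage panel:

* ``b_cell``          CD79a+ / CD138-
* ``plasma_cell``     CD138+ / CD38+ / Ki67-
* ``permissive_pb``   CD38+ / Ki67+  (deliberately CD138-agnostic)
* ``bona_fide_pb``    CD138+ / CD38+ / Ki67+

Gates are permissive about markers they do not mention, so one cell can
belong to several gates (e.g. an activated, proliferating B cell is both
``b_cell`` and ``permissive_pb``); by the gate algebra ``bona_fide_pb`` is
always a subset of ``permissive_pb`` and disjoint from ``plasma_cell``.
The CD38 co-requirement on the ASC gates is what keeps CD138+/CD38-
tubular epithelium out of the antibody-secreting-cell counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture


class ThresholdError(ValueError):
    pass


def fit_threshold(values, method: str = "gmm2", manual_value: float | None = None,
                  seed: int = 0) -> float:
    """Estimate a positive/negative cutoff from an intensity sample.

    Methods
    -------
    ``manual``
        Returns ``manual_value`` unchanged.
    ``otsu``
        Maximal between-class-variance split of the sample.
    ``gmm2``
        Two-component univariate Gaussian mixture fit by EM (k-means
        initialisation, fixed seed) on log-transformed intensities —
        fluorescence intensity is approximately lognormal, so the mixture
        is fit where its components are near-Gaussian.  The cutoff is the
        equal-posterior boundary between the two components, mapped back
        to the intensity scale.

    A constant sample cannot be split; any automatic method raises and
    advises a manual cutoff.
    """
    if method == "manual":
        if manual_value is None:
            raise ThresholdError("manual_value is required when method='manual'")
        return float(manual_value)

    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ThresholdError("cannot fit a threshold on an empty sample")
    if np.ptp(x) == 0:
        raise ThresholdError(
            "intensity sample is constant; automatic thresholding is undefined "
            "— supply a manual cutoff"
        )
    if method == "otsu":
        return float(threshold_otsu(x))
    if method == "gmm2":
        if np.any(x < 0):
            raise ThresholdError("gmm2 requires non-negative intensities")
        t = np.log1p(x)  # log scale; log1p tolerates exact zeros
        gm = GaussianMixture(n_components=2, init_params="kmeans",
                             n_init=1, random_state=seed)
        gm.fit(t.reshape(-1, 1))
        return float(np.expm1(_equal_posterior_boundary(gm)))
    raise ThresholdError(f"unknown threshold method {method!r}")


def _equal_posterior_boundary(gm: GaussianMixture) -> float:
    """Intensity where the two fitted components are equally likely."""
    means = gm.means_.ravel()
    lo, hi = float(means.min()), float(means.max())
    if np.isclose(lo, hi):
        return lo
    grid = np.linspace(lo, hi, 4097).reshape(-1, 1)
    post = gm.predict_proba(grid)
    hi_comp = int(np.argmax(means))
    diff = post[:, hi_comp] - 0.5
    sign_change = np.flatnonzero(np.diff(np.sign(diff)) != 0)
    if sign_change.size == 0:  # degenerate overlap: fall back to midpoint
        return 0.5 * (lo + hi)
    i = int(sign_change[0])
    # linear interpolation between grid points bracketing the crossing
    x0, x1 = grid[i, 0], grid[i + 1, 0]
    d0, d1 = diff[i], diff[i + 1]
    if d1 == d0:
        return float(0.5 * (x0 + x1))
    return float(x0 - d0 * (x1 - x0) / (d1 - d0))


@dataclass
class ThresholdSet:
    """Per-marker cutoffs plus the autofluorescence rejection cutoff."""

    cutoffs: dict[str, float]
    af_cutoff: float
    methods: dict[str, str] = field(default_factory=dict)
    af_channel: str = "AF"

    def __post_init__(self) -> None:
        for m, c in self.cutoffs.items():
            if c < 0:
                raise ThresholdError(f"cutoff for {m!r} must be >= 0")
        if self.af_cutoff < 0:
            raise ThresholdError("af_cutoff must be >= 0")

    @classmethod
    def fit(cls, cells: pd.DataFrame, markers, method: str = "gmm2",
            af_channel: str = "AF", af_method: str | None = None,
            manual_values: dict[str, float] | None = None,
            seed: int = 0) -> "ThresholdSet":
        """Fit all marker cutoffs (and the AF cutoff) from one CellTable.

        Cutoffs are per-slide by design — each slide's staining is
        thresholded independently; pass the same ThresholdSet to several
        slides to share it across a cohort instead.
        """
        manual_values = manual_values or {}
        sample = cells[cells["in_tissue"]] if "in_tissue" in cells else cells
        cutoffs, methods = {}, {}
        for m in markers:
            meth = "manual" if m in manual_values else method
            cutoffs[m] = fit_threshold(sample[f"mfi_{m}"], meth,
                                       manual_values.get(m), seed=seed)
            methods[m] = meth
        af_meth = af_method or ("manual" if af_channel in manual_values else method)
        af_cut = fit_threshold(sample[f"mfi_{af_channel}"], af_meth,
                               manual_values.get(af_channel), seed=seed)
        methods[af_channel] = af_meth
        return cls(cutoffs, af_cut, methods, af_channel)

    def to_yaml(self, path) -> None:
        doc = {
            "cutoffs": {m: float(c) for m, c in self.cutoffs.items()},
            "af_cutoff": float(self.af_cutoff),
            "methods": dict(self.methods),
            "af_channel": self.af_channel,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(doc["cutoffs"], doc["af_cutoff"], doc.get("methods", {}),
                   doc.get("af_channel", "AF"))


@dataclass
class GateSet:
    """Named gates: (required-positive markers, required-negative markers).

    ``subfractions`` lists (gate, marker) pairs reported as within-gate
    positive fractions, e.g. CD19+ B cells or CD79a+ plasma cells.  Gate
    definitions are plain data, so alternative signatures (e.g. a
    CD79a+/CD138+ plasma-cell gate for panels where CD38 is compromised)
    need no code changes.
    """

    gates: dict[str, tuple[frozenset, frozenset]]
    subfractions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gates = {
            name: (frozenset(pos), frozenset(neg))
            for name, (pos, neg) in self.gates.items()
        }

    @property
    def markers(self) -> set[str]:
        out = set()
        for pos, neg in self.gates.values():
            out |= pos | neg
        out |= {m for _, m in self.subfractions}
        return out

    def subfraction_column(self, gate: str, marker: str) -> str:
        return f"{gate}_{marker}"

    def to_yaml(self, path) -> None:
        doc = {
            "gates": {
                name: {"positive": sorted(pos), "negative": sorted(neg)}
                for name, (pos, neg) in self.gates.items()
            },
            "subfractions": [list(sf) for sf in self.subfractions],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "GateSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        gates = {
            name: (frozenset(g.get("positive", [])), frozenset(g.get("negative", [])))
            for name, g in doc["gates"].items()
        }
        return cls(gates, [tuple(sf) for sf in doc.get("subfractions", [])])


DEFAULT_GATES = GateSet(
    gates={
        "b_cell": (frozenset({"CD79a"}), frozenset({"CD138"})),
        "plasma_cell": (frozenset({"CD138", "CD38"}), frozenset({"Ki67"})),
        "permissive_pb": (frozenset({"CD38", "Ki67"}), frozenset()),
        "bona_fide_pb": (frozenset({"CD138", "CD38", "Ki67"}), frozenset()),
    },
    subfractions=[
        ("b_cell", "CD19"),
        ("plasma_cell", "CD79a"),
        ("permissive_pb", "CD79a"),
        ("bona_fide_pb", "CD79a"),
    ],
)


def classify_cells(cells: pd.DataFrame, thresholds: ThresholdSet,
                   gates: GateSet = DEFAULT_GATES) -> pd.DataFrame:
    """Turn a CellTable into a PhenotypeTable.

    Output columns: per-marker boolean status, ``af_rejected``,
    ``in_tissue``, one boolean per gate, and one boolean per subfraction.
    Gate membership is computed only for autofluorescence-passing,
    in-tissue cells; everything else has every membership False.
    """
    needed = sorted(gates.markers)
    missing = [m for m in needed if m not in thresholds.cutoffs]
    if missing:
        raise ThresholdError(
            f"no threshold for gated marker(s): {', '.join(missing)}"
        )

    out = pd.DataFrame({"cell_uid": cells.get("cell_uid", pd.Series(dtype=str))})
    n = len(cells)
    status: dict[str, np.ndarray] = {}
    for m in sorted(thresholds.cutoffs):
        col = f"mfi_{m}"
        if col not in cells.columns:
            raise KeyError(f"CellTable lacks column {col!r}")
        status[m] = cells[col].to_numpy(dtype=float) >= thresholds.cutoffs[m]
        out[m] = status[m]

    af_col = f"mfi_{thresholds.af_channel}"
    af_rejected = (cells[af_col].to_numpy(dtype=float) >= thresholds.af_cutoff
                   if af_col in cells.columns and n
                   else np.zeros(n, dtype=bool))
    in_tissue = (cells["in_tissue"].to_numpy(dtype=bool)
                 if "in_tissue" in cells.columns and n
                 else np.ones(n, dtype=bool))
    out["af_rejected"] = af_rejected
    out["in_tissue"] = in_tissue
    eligible = ~af_rejected & in_tissue

    for name, (pos, neg) in gates.gates.items():
        member = eligible.copy()
        for m in pos:
            member &= status[m]
        for m in neg:
            member &= ~status[m]
        out[name] = member
    for gate, marker in gates.subfractions:
        out[gates.subfraction_column(gate, marker)] = out[gate] & status[marker]
    return out


def write_phenotype_table(phenotypes: pd.DataFrame, path,
                          config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# mifquant config_hash={config_hash}\n")
        phenotypes.to_csv(fh, index=False)


def read_phenotype_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    for col in df.columns:
        if col != "cell_uid":
            df[col] = df[col].astype(bool)
    return df
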