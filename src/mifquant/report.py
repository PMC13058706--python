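"""Per-slide enumeration, cumulative cohort aggregation, derived proportions.

Each slide yields counts per gate plus two frequencies: spatial density
(cells per mm^2 of analyzable tissue) and fraction of total tissue cells.
Cohorts are aggregated *cumulatively*: counts and areas are summed across
slides and frequencies recomputed from the sums (count-weighted), rather
than averaging per-slide frequencies — the convention under which the
derived proportions follow directly from raw cumulative counts.  Per-slide
values are still reported for inspection.

Derived cohort proportions:

* CD19+ fraction of B cells; CD79a+ fraction of each ASC class
* bona fide PB share of the permissive (CD38+/Ki67+) class
* bona fide PB share of all antibody-secreting cells
  (ASC = plasma cells + bona fide PBs)

Proportions with a zero denominator are reported as missing, never as 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .gating import DEFAULT_GATES, GateSet

SCHEMA_VERSION = 1

#: Gate display order in tabular output.
GATE_ORDER = ["b_cell", "plasma_cell", "permissive_pb", "bona_fide_pb"]


@dataclass
class SlideSummary:
    slide_id: str
    area_mm2: float
    total_cells: int
    counts: dict[str, int]
    subfraction_counts: dict[str, int] = field(default_factory=dict)
    denominator: str = "af_pass"

    def density(self, gate: str) -> float:
        return self.counts[gate] / self.area_mm2

    def fraction(self, gate: str) -> float:
        """Percent of total tissue cells (0 when the slide has no cells)."""
        if self.total_cells == 0:
            return 0.0
        return 100.0 * self.counts[gate] / self.total_cells


@dataclass
class CohortSummary:
    label: str
    n_slides: int
    area_mm2: float
    total_cells: int
    counts: dict[str, int]
    subfraction_counts: dict[str, int] = field(default_factory=dict)
    denominator: str = "af_pass"

    def density(self, gate: str) -> float:
        return self.counts[gate] / self.area_mm2 if self.area_mm2 > 0 else float("nan")

    def fraction(self, gate: str) -> float | None:
        if self.total_cells == 0:
            return None
        return 100.0 * self.counts[gate] / self.total_cells

    # -- derived proportions (None when the denominator is zero) ---------

    @staticmethod
    def _pct(num: float, den: float) -> float | None:
        return 100.0 * num / den if den > 0 else None

    @property
    def asc_count(self) -> int:
        """Antibody-secreting cells: plasma cells + bona fide plasmablasts."""
        return self.counts.get("plasma_cell", 0) + self.counts.get("bona_fide_pb", 0)

    @property
    def pct_cd19_of_bcells(self) -> float | None:
        return self._pct(self.subfraction_counts.get("b_cell_CD19", 0),
                         self.counts.get("b_cell", 0))

    @property
    def pct_cd79a_of_pcs(self) -> float | None:
        return self._pct(self.subfraction_counts.get("plasma_cell_CD79a", 0),
                         self.counts.get("plasma_cell", 0))

    @property
    def pct_cd79a_of_permissive_pbs(self) -> float | None:
        return self._pct(self.subfraction_counts.get("permissive_pb_CD79a", 0),
                         self.counts.get("permissive_pb", 0))

    @property
    def pct_cd79a_of_bona_fide_pbs(self) -> float | None:
        return self._pct(self.subfraction_counts.get("bona_fide_pb_CD79a", 0),
                         self.counts.get("bona_fide_pb", 0))

    @property
    def pct_bona_fide_of_permissive(self) -> float | None:
        return self._pct(self.counts.get("bona_fide_pb", 0),
                         self.counts.get("permissive_pb", 0))

    @property
    def pct_bona_fide_of_asc(self) -> float | None:
        return self._pct(self.counts.get("bona_fide_pb", 0), self.asc_count)

    def derived(self) -> dict[str, float | None]:
        return {
            "pct_cd19_of_bcells": self.pct_cd19_of_bcells,
            "pct_cd79a_of_pcs": self.pct_cd79a_of_pcs,
            "pct_cd79a_of_permissive_pbs": self.pct_cd79a_of_permissive_pbs,
            "pct_cd79a_of_bona_fide_pbs": self.pct_cd79a_of_bona_fide_pbs,
            "pct_bona_fide_of_permissive": self.pct_bona_fide_of_permissive,
            "pct_bona_fide_of_asc": self.pct_bona_fide_of_asc,
        }


def enumerate_slide(phenotypes: pd.DataFrame, area_mm2: float, slide_id: str,
                    gates: GateSet = DEFAULT_GATES,
                    denominator: str = "af_pass") -> SlideSummary:
    """Count gate memberships on one slide.

    ``denominator`` selects the total-cell count used for fractions:
    ``af_pass`` (default) counts in-tissue cells that survived
    autofluorescence rejection; ``all`` counts every in-tissue cell.
    """
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be positive")
    if denominator not in ("af_pass", "all"):
        raise ValueError("denominator must be 'af_pass' or 'all'")

    if len(phenotypes) == 0:
        total = 0
        counts = {g: 0 for g in gates.gates}
        sub = {gates.subfraction_column(g, m): 0 for g, m in gates.subfractions}
    else:
        in_tissue = phenotypes["in_tissue"].to_numpy(dtype=bool)
        af_ok = ~phenotypes["af_rejected"].to_numpy(dtype=bool)
        total = int((in_tissue & af_ok).sum()) if denominator == "af_pass" \
            else int(in_tissue.sum())
        counts = {g: int(phenotypes[g].sum()) for g in gates.gates}
        sub = {
            gates.subfraction_column(g, m):
                int(phenotypes[gates.subfraction_column(g, m)].sum())
            for g, m in gates.subfractions
        }
    return SlideSummary(slide_id, float(area_mm2), total, counts, sub, denominator)


def aggregate_cohort(summaries: list[SlideSummary], label: str) -> CohortSummary:
    """Cumulative cohort aggregation: sum counts and areas, then derive."""
    if not summaries:
        raise ValueError("aggregate_cohort requires at least one slide summary")
    gates = sorted({g for s in summaries for g in s.counts})
    subs = sorted({k for s in summaries for k in s.subfraction_counts})
    return CohortSummary(
        label=label,
        n_slides=len(summaries),
        area_mm2=float(sum(s.area_mm2 for s in summaries)),
        total_cells=int(sum(s.total_cells for s in summaries)),
        counts={g: int(sum(s.counts.get(g, 0) for s in summaries)) for g in gates},
        subfraction_counts={
            k: int(sum(s.subfraction_counts.get(k, 0) for s in summaries))
            for k in subs
        },
        denominator=summaries[0].denominator,
    )


def cohort_from_counts(label: str, counts: dict[str, int],
                       subfraction_counts: dict[str, int] | None = None,
                       area_mm2: float = 1.0, total_cells: int = 0,
                       n_slides: int = 1) -> CohortSummary:
    """Build a cohort directly from cumulative counts.

    Convenience for recomputing derived proportions from published
    cumulative tallies without per-slide data.
    """
    return CohortSummary(label, n_slides, float(area_mm2), int(total_cells),
                         dict(counts), dict(subfraction_counts or {}))


# ---------------------------------------------------------------------------
# Output writers


_METRIC_ROWS = [
    ("count", lambda c, g: c.counts.get(g, 0)),
    ("density_per_mm2", lambda c, g: c.density(g)),
    ("pct_of_total", lambda c, g: c.fraction(g)),
]

_DERIVED_BY_GATE = {
    "b_cell": [("pct_cd19_of_bcells", "pct_cd19_of_bcells")],
    "plasma_cell": [("pct_cd79a_of_pcs", "pct_cd79a_of_pcs")],
    "permissive_pb": [("pct_cd79a_of_permissive_pbs", "pct_cd79a_of_permissive_pbs")],
    "bona_fide_pb": [
        ("pct_bona_fide_of_permissive", "pct_bona_fide_of_permissive"),
        ("pct_bona_fide_of_asc", "pct_bona_fide_of_asc"),
        ("pct_cd79a_of_bona_fide_pbs", "pct_cd79a_of_bona_fide_pbs"),
    ],
}


def cohort_table(cohorts: list[CohortSummary]) -> pd.DataFrame:
    """Long-form cohort table: one row per metric per gate, one column per
    cohort, percentages rounded to 2 dp (missing stays missing)."""
    rows = []
    gates = [g for g in GATE_ORDER
             if any(g in c.counts for c in cohorts)]
    extra = sorted({g for c in cohorts for g in c.counts} - set(gates))
    for gate in gates + extra:
        for metric, fn in _METRIC_ROWS:
            vals = {}
            for c in cohorts:
                v = fn(c, gate)
                if metric != "count" and v is not None and not np.isnan(v):
                    v = round(v, 2)
                vals[c.label] = v
            rows.append({"gate": gate, "metric": metric, **vals})
        for metric, prop in _DERIVED_BY_GATE.get(gate, []):
            vals = {
                c.label: (None if getattr(c, prop) is None else round(getattr(c, prop), 2))
                for c in cohorts
            }
            rows.append({"gate": gate, "metric": metric, **vals})
    return pd.DataFrame(rows)


def slide_table(slides: list[SlideSummary]) -> pd.DataFrame:
    """Per-slide long-form table: slide_id, gate, count, density, fraction."""
    rows = []
    for s in slides:
        for gate in s.counts:
            rows.append({
                "slide_id": s.slide_id, "gate": gate,
                "count": s.counts[gate],
                "density_per_mm2": s.density(gate),
                "pct_of_total": s.fraction(gate),
            })
    return pd.DataFrame(rows)


def cohorts_to_json(cohorts: list[CohortSummary],
                    slides: list[SlideSummary] | None = None,
                    config_hash: str | None = None) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "frequency_convention": "cumulative counts / cumulative area",
        "cohorts": [],
    }
    if config_hash:
        doc["config_hash"] = config_hash
    for c in cohorts:
        entry = asdict(c)
        entry["asc_count"] = c.asc_count
        entry["density_per_mm2"] = {g: c.density(g) for g in c.counts}
        entry["pct_of_total"] = {g: c.fraction(g) for g in c.counts}
        entry["derived"] = c.derived()
        doc["cohorts"].append(entry)
    if slides is not None:
        doc["slides"] = [asdict(s) for s in slides]
    return doc


def write_report(cohorts: list[CohortSummary], slides: list[SlideSummary],
                 path_prefix, config_hash: str | None = None) -> dict[str, str]:
    """Write the report triplet next to ``path_prefix``.

    ``<prefix>.json`` (full precision), ``<prefix>_cohorts.csv`` (one row
    per metric per gate, cohorts as columns, 2 dp), and
    ``<prefix>_slides.csv``.  Returns the paths written.
    """
    prefix = str(path_prefix)
    paths = {
        "json": prefix + ".json",
        "cohorts_csv": prefix + "_cohorts.csv",
        "slides_csv": prefix + "_slides.csv",
    }
    try:
        with open(paths["json"], "w") as fh:
            json.dump(cohorts_to_json(cohorts, slides, config_hash), fh, indent=1)
        header = f"# mifquant config_hash={config_hash}\n" if config_hash else ""
        with open(paths["cohorts_csv"], "w") as fh:
            fh.write(header)
            cohort_table(cohorts).to_csv(fh, index=False)
        with open(paths["slides_csv"], "w") as fh:
            fh.write(header)
            slide_table(slides).to_csv(fh, index=False)
    except OSError as exc:
        raise OSError(f"cannot write report to {prefix!r}: {exc}") from exc
    return paths


def read_report_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def cohort_from_json(entry: dict) -> CohortSummary:
    return CohortSummary(
        label=entry["label"], n_slides=entry["n_slides"],
        area_mm2=entry["area_mm2"], total_cells=entry["total_cells"],
        counts=entry["counts"],
        subfraction_counts=entry.get("subfraction_counts", {}),
        denominator=entry.get("denominator", "af_pass"),
    )


def plot_slide_metrics(slides: list[SlideSummary], metric: str = "density_per_mm2",
                       ax=None):
    """Simple per-slide density/fraction bar chart, one group per gate."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = slide_table(slides)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    pivot = df.pivot(index="slide_id", columns="gate", values=metric)
    pivot.plot.bar(ax=ax)
    ax.set_ylabel(metric)
    return ax
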