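"""Synthetic multiplex-IF phantom with planted, fully known ground truth.

The generator renders a seven-channel tile containing non-overlapping
disk-shaped cells of named B-lineage phenotypes, ring-shaped tubular
epithelium (CD138-positive but CD38-negative — the classic renal confound
for antibody-secreting-cell calls), and high-autofluorescence artifact
blobs, over a uniform autofluorescent tissue region.  Every rendered object
is recorded in a ground-truth table, so segmentation, feature extraction,
gating and reporting can all be validated end-to-end without any external
image.

Geometry is deliberately simple: each cell is a uniform-intensity disk,
with the nuclear compartment (DAPI, Ki-67) drawn on an inner disk and
membrane/cytoplasmic markers (CD79a, CD38, CD19, CD138) on the full disk.
Per-cell marker intensities are drawn from lognormal positive/negative
distributions, fluorescence being non-negative and right-skewed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import yaml
from shapely.geometry import Point, Polygon
from shapely.prepared import prep
from skimage.draw import disk as draw_disk

from .stack import DEFAULT_CHANNELS, DEFAULT_PIXEL_SIZE_UM, ChannelStack

MARKERS: tuple[str, ...] = ("CD79a", "CD38", "Ki67", "CD19", "CD138")

#: Anchor-marker truth per phenotype.  Values are probabilities of marker
#: positivity; anchors are 0/1 so planted gate counts are deterministic,
#: while subfraction markers (CD19 on B cells, CD79a on ASC classes) use
#: tonsil-scale Bernoulli rates so subfraction proportions look realistic.
PHENOTYPE_PROFILES: dict[str, dict[str, float]] = {
    "b_cell": {"CD79a": 1.0, "CD38": 0.0, "Ki67": 0.0, "CD19": 0.15, "CD138": 0.0},
    "plasma_cell": {"CD79a": 0.88, "CD38": 1.0, "Ki67": 0.0, "CD19": 0.0, "CD138": 1.0},
    "bona_fide_pb": {"CD79a": 0.84, "CD38": 1.0, "Ki67": 1.0, "CD19": 0.0, "CD138": 1.0},
    "t_nk_like": {"CD79a": 0.0, "CD38": 1.0, "Ki67": 1.0, "CD19": 0.0, "CD138": 0.0},
    "other": {"CD79a": 0.0, "CD38": 0.0, "Ki67": 0.0, "CD19": 0.0, "CD138": 0.0},
}

#: Tubular epithelium: endogenous CD138 without CD38.
TUBULE_PROFILE: dict[str, float] = {
    "CD79a": 0.0, "CD38": 0.0, "Ki67": 0.0, "CD19": 0.0, "CD138": 1.0,
}

GROUND_TRUTH_COLUMNS = [
    "cell_uid", "row", "col", "phenotype",
    "CD79a", "CD38", "Ki67", "CD19", "CD138",
    "is_artifact", "is_tubule",
]


class PackingError(RuntimeError):
    """Requested objects cannot be placed without overlap."""


@dataclass(frozen=True)
class IntensityModel:
    """Lognormal positive/negative intensity pair for one channel.

    ``mu_pos``/``mu_neg`` are the log-scale locations (so the median
    intensity is ``exp(mu)``); ``sigma`` is the common log-scale spread.
    Default medians 1000 vs 100 (10x separation) with sigma 0.25 keep the
    two classes ~4 sigma apart, so threshold recovery is near-perfect in
    the noiseless regime.
    """

    mu_pos: float = math.log(1000.0)
    mu_neg: float = math.log(100.0)
    sigma: float = 0.25

    def __post_init__(self):
        if not self.mu_pos > self.mu_neg:
            raise ValueError("intensity model requires mu_pos > mu_neg")


def ellipse_polygon(center: tuple[float, float], semi_axes: tuple[float, float],
                    n_vertices: int = 256) -> Polygon:
    """Ellipse in pixel (row, col) coordinates as a shapely polygon.

    Shapely works in (x, y) = (col, row); the returned polygon follows that
    convention, consistent with the ROI handling in :mod:`mifquant.tissue`.
    """
    cr, cc = center
    ar, ac = semi_axes
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return Polygon(np.column_stack([cc + ac * np.cos(t), cr + ar * np.sin(t)]))


@dataclass
class PhantomSpec:
    """Full description of a synthetic tile.

    All geometric quantities are in pixels.  ``tissue_region`` is a shapely
    polygon in (x=col, y=row) coordinates; when omitted, a centred ellipse
    covering most of the tile is used.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    tissue_region: Polygon | None = None
    phenotype_counts: dict[str, int] = field(default_factory=dict)
    intensity_model: dict[str, IntensityModel] = field(default_factory=dict)
    cell_radius_px: int = 6
    n_tubules: int = 0
    tubule_cells: int = 8
    tubule_radius_px: int = 22
    n_af_artifacts: int = 0
    artifact_radius_px: int = 9
    bleed_matrix: np.ndarray | None = None
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tissue_region is None:
            h, w = self.image_shape
            self.tissue_region = ellipse_polygon(
                (h / 2, w / 2), (0.42 * h, 0.42 * w)
            )
        model = {ch: IntensityModel() for ch in DEFAULT_CHANNELS}
        model.update(self.intensity_model)
        self.intensity_model = model
        if self.bleed_matrix is None:
            self.bleed_matrix = np.eye(len(DEFAULT_CHANNELS))
        self.bleed_matrix = np.asarray(self.bleed_matrix, dtype=float)

    @property
    def nucleus_radius_px(self) -> int:
        return max(2, round(0.6 * self.cell_radius_px))

    def validate(self) -> None:
        for name, n in self.phenotype_counts.items():
            if name not in PHENOTYPE_PROFILES:
                raise ValueError(
                    f"unknown phenotype {name!r}; known: {sorted(PHENOTYPE_PROFILES)}"
                )
            if n < 0:
                raise ValueError(f"phenotype_counts[{name!r}] must be >= 0")
        n_ch = len(DEFAULT_CHANNELS)
        if self.bleed_matrix.shape != (n_ch, n_ch):
            raise ValueError(f"bleed_matrix must be {n_ch}x{n_ch}")
        if not np.allclose(np.diag(self.bleed_matrix), 1.0):
            raise ValueError("bleed_matrix diagonal must be 1")
        h, w = self.image_shape
        minx, miny, maxx, maxy = self.tissue_region.bounds
        if minx < 0 or miny < 0 or maxx > w - 1 or maxy > h - 1:
            raise ValueError("tissue_region must lie strictly inside image_shape")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "image_shape" in raw:
            raw["image_shape"] = tuple(raw["image_shape"])
        if "tissue_ellipse" in raw:
            e = raw.pop("tissue_ellipse")
            raw["tissue_region"] = ellipse_polygon(
                tuple(e["center"]), tuple(e["semi_axes"])
            )
        if "intensity_model" in raw:
            raw["intensity_model"] = {
                ch: IntensityModel(**params)
                for ch, params in raw["intensity_model"].items()
            }
        if "bleed_matrix" in raw:
            raw["bleed_matrix"] = np.asarray(raw["bleed_matrix"], dtype=float)
        return cls(**raw)


#: A mild default off-diagonal mixing used as the documented "bleed on"
#: regime: 2% of each marker channel leaks into its spectral neighbours.
def default_bleed_matrix(leak: float = 0.02) -> np.ndarray:
    n = len(DEFAULT_CHANNELS)
    b = np.eye(n)
    for i in range(2, n):  # marker channels only (FITC..CY7 are adjacent)
        for j in range(2, n):
            if abs(i - j) == 1:
                b[i, j] = leak
    return b


def _sample_centers(rng: np.random.Generator, region: Polygon, n: int,
                    spacing: float, placed: list[tuple[float, float, float]],
                    what: str, max_attempts_per_cell: int = 400,
                    ) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` centers inside ``region``.

    ``spacing`` is this object's exclusion radius; a candidate is accepted
    when its distance to every placed object exceeds the sum of exclusion
    radii.  ``placed`` holds (row, col, exclusion_radius) and is extended
    in place.
    """
    minx, miny, maxx, maxy = region.bounds
    out: list[tuple[float, float]] = []
    prepared = prep(region)
    attempts_left = max_attempts_per_cell * max(n, 1)
    while len(out) < n:
        if attempts_left <= 0:
            raise PackingError(
                f"could not place {n} {what} objects without overlap "
                f"(placed {len(out)}); reduce counts or enlarge the tissue region"
            )
        attempts_left -= 1
        c = rng.uniform(minx, maxx)
        r = rng.uniform(miny, maxy)
        if not prepared.contains(Point(c, r)):
            continue
        ok = True
        for pr, pc, prad in placed:
            if (pr - r) ** 2 + (pc - c) ** 2 < (prad + spacing) ** 2:
                ok = False
                break
        if ok:
            out.append((r, c))
            placed.append((r, c, spacing))
    return out


def generate_phantom(spec: PhantomSpec) -> tuple[ChannelStack, pd.DataFrame]:
    """Render the phantom and its ground-truth table.

    Returns
    -------
    stack
        Seven-channel :class:`ChannelStack` (DAPI, AF, CD79a, CD38, Ki67,
        CD19, CD138).
    truth
        One row per planted object (phenotype cells, tubule epithelial
        cells, artifact blobs) with center, per-marker true status and
        is_artifact / is_tubule flags.

    Identical spec + seed gives bit-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    n_ch = len(DEFAULT_CHANNELS)
    data = np.zeros((n_ch, h, w), dtype=np.float64)
    ch_index = {name: i for i, name in enumerate(DEFAULT_CHANNELS)}

    # Uniform autofluorescent tissue bed: median of the AF negative class.
    af_model = spec.intensity_model["AF"]
    tissue_px = _rasterize_region(spec.tissue_region, (h, w))
    data[ch_index["AF"]][tissue_px] = math.exp(af_model.mu_neg)

    margin = spec.cell_radius_px + 8.0  # keep disks clear of the tissue edge
    placement_region = spec.tissue_region.buffer(-margin)
    if placement_region.is_empty and (
        sum(spec.phenotype_counts.values()) or spec.n_tubules or spec.n_af_artifacts
    ):
        raise PackingError("tissue_region too small for the requested objects")

    placed: list[tuple[float, float, float]] = []
    cell_spacing = spec.cell_radius_px + 1.5  # min center gap 2r + 3

    records: list[dict] = []

    # Tubules first (largest footprint): a ring of epithelial cells.
    ring_r = spec.tubule_radius_px
    tubule_region = spec.tissue_region.buffer(-(margin + ring_r))
    if spec.n_tubules and tubule_region.is_empty:
        raise PackingError(f"could not place {spec.n_tubules} tubule objects")
    tubule_centers = _sample_centers(
        rng, tubule_region, spec.n_tubules,
        ring_r + spec.cell_radius_px + 1.5, placed, "tubule",
    )
    for tr, tc in tubule_centers:
        angles = np.linspace(0, 2 * np.pi, spec.tubule_cells, endpoint=False)
        for a in angles:
            records.append(_make_record(
                rng, tr + ring_r * np.sin(a), tc + ring_r * np.cos(a),
                "tubule_epithelium", TUBULE_PROFILE,
                is_tubule=True,
            ))

    # Artifact blobs: bright in AF and every marker channel.
    artifact_centers = _sample_centers(
        rng, placement_region, spec.n_af_artifacts,
        spec.artifact_radius_px + 1.5, placed, "af_artifact",
    )
    for ar, ac in artifact_centers:
        records.append(_make_record(
            rng, ar, ac, "af_artifact",
            {m: 1.0 for m in MARKERS}, is_artifact=True,
        ))

    # Phenotype cells, in sorted-name order for a stable RNG stream.
    for phen in sorted(spec.phenotype_counts):
        n = spec.phenotype_counts[phen]
        centers = _sample_centers(
            rng, placement_region, n, cell_spacing, placed, phen,
        )
        profile = PHENOTYPE_PROFILES[phen]
        for r, c in centers:
            records.append(_make_record(rng, r, c, phen, profile))

    # Render every record; disks are disjoint by construction.
    for rec in records:
        _render_cell(data, ch_index, rec, spec, rng)

    truth = pd.DataFrame(records, columns=GROUND_TRUTH_COLUMNS + ["_radius"])
    truth["cell_uid"] = [f"gt-{i + 1}" for i in range(len(truth))]
    truth = truth[GROUND_TRUTH_COLUMNS]

    if not np.allclose(spec.bleed_matrix, np.eye(n_ch)):
        data = np.einsum("ck,khw->chw", spec.bleed_matrix, data)
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
        np.maximum(data, 0.0, out=data)

    stack = ChannelStack(data.astype(np.float32), DEFAULT_CHANNELS,
                         spec.pixel_size_um)
    return stack, truth


def _make_record(rng, row, col, phenotype, profile, *, is_artifact=False,
                 is_tubule=False) -> dict:
    rec = {
        "cell_uid": "", "row": float(row), "col": float(col),
        "phenotype": phenotype,
        "is_artifact": bool(is_artifact), "is_tubule": bool(is_tubule),
        "_radius": None,
    }
    for m in MARKERS:
        p = profile[m]
        rec[m] = bool(p == 1.0 or (0.0 < p < 1.0 and rng.random() < p))
    return rec


def _render_cell(data, ch_index, rec, spec: PhantomSpec, rng) -> None:
    h, w = spec.image_shape
    radius = spec.artifact_radius_px if rec["is_artifact"] else spec.cell_radius_px
    rec["_radius"] = radius
    center = (rec["row"], rec["col"])
    full = draw_disk(center, radius + 0.5, shape=(h, w))
    nuc = draw_disk(center, spec.nucleus_radius_px + 0.5, shape=(h, w))

    def sample(channel: str, positive: bool) -> float:
        m = spec.intensity_model[channel]
        mu = m.mu_pos if positive else m.mu_neg
        return math.exp(rng.normal(mu, m.sigma))

    data[ch_index["DAPI"]][nuc] = sample("DAPI", True)
    if rec["is_artifact"]:
        data[ch_index["AF"]][full] = sample("AF", True)
    for marker in MARKERS:
        region = nuc if marker == "Ki67" else full
        data[ch_index[marker]][region] = sample(marker, rec[marker])


def _rasterize_region(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside ``poly``."""
    h, w = shape
    minx, miny, maxx, maxy = poly.bounds
    c0, c1 = max(0, int(np.floor(minx))), min(w - 1, int(np.ceil(maxx)))
    r0, r1 = max(0, int(np.floor(miny))), min(h - 1, int(np.ceil(maxy)))
    mask = np.zeros(shape, dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    inside = shapely.contains_xy(poly, cols.ravel(), rows.ravel())
    mask[r0:r1 + 1, c0:c1 + 1] = inside.reshape(rows.shape)
    return mask


def expected_gate_counts(truth: pd.DataFrame, gates=None) -> dict[str, int]:
    """Planted per-gate counts implied by the ground-truth marker statuses.

    Artifact cells are excluded (they would be autofluorescence-rejected);
    every other record is gated on its true statuses.  This is the oracle
    the end-to-end recovery tests compare pipeline output against.
    """
    from .gating import DEFAULT_GATES  # local import to avoid a cycle

    gates = gates if gates is not None else DEFAULT_GATES
    eligible = truth[~truth["is_artifact"]]
    counts: dict[str, int] = {}
    for name, (pos, neg) in gates.gates.items():
        member = np.ones(len(eligible), dtype=bool)
        for m in pos:
            member &= eligible[m].to_numpy()
        for m in neg:
            member &= ~eligible[m].to_numpy()
        counts[name] = int(member.sum())
    return counts


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def read_ground_truth(path) -> pd.DataFrame:
    return pd.read_csv(
        path, dtype={m: bool for m in MARKERS} | {"is_artifact": bool, "is_tubule": bool}
    )
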