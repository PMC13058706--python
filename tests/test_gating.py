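"""Threshold fitting, autofluorescence rejection, and gate algebra."""

import numpy as np
import pandas as pd
import pytest

import mifquant as mq
from mifquant.gating import (
    DEFAULT_GATES, GateSet, ThresholdError, ThresholdSet, classify_cells,
    fit_threshold,
)

MARKERS = ("CD79a", "CD38", "Ki67", "CD19", "CD138")


def _cell_table(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df.insert(0, "cell_uid", [f"c{i}" for i in range(len(df))])
    if "in_tissue" not in df:
        df["in_tissue"] = True
    return df


def _thresholds(cut=500.0, af=500.0) -> ThresholdSet:
    return ThresholdSet({m: cut for m in MARKERS}, af_cutoff=af)


def _mfis(**kw) -> dict:
    out = {f"mfi_{m}": 100.0 for m in MARKERS}
    out["mfi_AF"] = 100.0
    for k, v in kw.items():
        out[f"mfi_{k}"] = v
    return out


# ---------------------------------------------------------------- thresholds

def test_otsu_splits_separated_modes():
    cut = fit_threshold([1, 1, 1, 9, 9, 9], "otsu")
    assert 1 < cut < 9


def test_manual_passthrough():
    assert fit_threshold([0], "manual", manual_value=7.5) == 7.5


def test_constant_sample_advises_manual():
    with pytest.raises(ThresholdError, match="manual"):
        fit_threshold([4.0] * 100, "gmm2")


def test_gmm2_misclassification_below_1pct():
    rng = np.random.default_rng(42)
    neg = np.exp(rng.normal(np.log(100), 0.25, 500))
    pos = np.exp(rng.normal(np.log(1000), 0.25, 500))
    cut = fit_threshold(np.concatenate([neg, pos]), "gmm2", seed=0)
    errors = (neg >= cut).sum() + (pos < cut).sum()
    assert errors / 1000 < 0.01


def test_gmm2_deterministic():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.exponential(10, 300), 200 + rng.exponential(30, 300)])
    assert fit_threshold(x, "gmm2", seed=0) == fit_threshold(x, "gmm2", seed=0)


# ------------------------------------------------------------------- gating

def test_activated_b_cell_is_b_cell_only():
    # CD79a+/CD138- stays a B cell regardless of CD38 positivity
    cells = _cell_table([_mfis(CD79a=1000, CD38=1000)])
    ph = classify_cells(cells, _thresholds())
    row = ph.iloc[0]
    assert row["b_cell"]
    assert not row["plasma_cell"] and not row["permissive_pb"] \
        and not row["bona_fide_pb"]


def test_tubular_epithelium_profile_has_no_gate():
    # CD138+ without CD38: the renal-tubule confound must not be an ASC
    cells = _cell_table([_mfis(CD138=1000)])
    ph = classify_cells(cells, _thresholds())
    assert not ph.iloc[0][list(DEFAULT_GATES.gates)].any()


def test_bona_fide_pb_is_also_permissive_but_not_pc():
    cells = _cell_table([_mfis(CD138=1000, CD38=1000, Ki67=1000)])
    row = classify_cells(cells, _thresholds()).iloc[0]
    assert row["bona_fide_pb"] and row["permissive_pb"]
    assert not row["plasma_cell"]


def test_high_af_rejects_all_memberships():
    cells = _cell_table([_mfis(CD79a=1000, CD38=1000, Ki67=1000,
                               CD138=1000, AF=1000)])
    row = classify_cells(cells, _thresholds()).iloc[0]
    assert row["af_rejected"]
    assert not row[list(DEFAULT_GATES.gates)].any()


def test_out_of_tissue_cells_get_no_membership():
    cells = _cell_table([_mfis(CD79a=1000)])
    cells["in_tissue"] = False
    row = classify_cells(cells, _thresholds()).iloc[0]
    assert not row["b_cell"]


def test_cutoff_attained_counts_positive():
    cells = _cell_table([_mfis(CD79a=500.0)])  # exactly at the cutoff
    assert classify_cells(cells, _thresholds()).iloc[0]["CD79a"]


def test_missing_threshold_names_marker():
    ts = ThresholdSet({m: 500.0 for m in MARKERS if m != "CD38"}, af_cutoff=500)
    with pytest.raises(ThresholdError, match="CD38"):
        classify_cells(_cell_table([_mfis()]), ts)


def test_empty_cell_table_allowed(pipeline_small):
    _, _, res = pipeline_small
    empty = res.cells.iloc[0:0]
    ph = classify_cells(empty, _thresholds())
    assert len(ph) == 0


def test_subfractions_computed_within_gate():
    cells = _cell_table([
        _mfis(CD79a=1000, CD19=1000),   # CD19+ B cell
        _mfis(CD79a=1000),              # CD19- B cell
        _mfis(CD38=1000, CD138=1000, CD79a=1000),  # CD79a+ PC
    ])
    ph = classify_cells(cells, _thresholds())
    assert ph["b_cell_CD19"].tolist() == [True, False, False]
    assert ph["plasma_cell_CD79a"].tolist() == [False, False, True]


# ------------------------------------------------------- algebraic invariants

def test_gate_algebra_on_random_cells(rng):
    n = 10_000
    cols = {f"mfi_{m}": rng.uniform(0, 1000, n) for m in MARKERS}
    cols["mfi_AF"] = rng.uniform(0, 1000, n)
    cells = _cell_table([])
    cells = pd.DataFrame(cols)
    cells["cell_uid"] = [f"c{i}" for i in range(n)]
    cells["in_tissue"] = rng.random(n) < 0.95
    ph = classify_cells(cells, _thresholds())
    assert not (ph["bona_fide_pb"] & ~ph["permissive_pb"]).any()
    assert not (ph["b_cell"] & ph["plasma_cell"]).any()
    assert not (ph["b_cell"] & ph["bona_fide_pb"]).any()
    assert not (ph["af_rejected"] & ph[list(DEFAULT_GATES.gates)].any(axis=1)).any()


def test_raising_cd138_cutoff_is_monotone(rng):
    n = 2000
    cols = {f"mfi_{m}": rng.uniform(0, 1000, n) for m in MARKERS}
    cols["mfi_AF"] = rng.uniform(0, 400, n)
    cells = pd.DataFrame(cols)
    cells["cell_uid"] = [f"c{i}" for i in range(n)]
    cells["in_tissue"] = True
    prev_asc, prev_b = None, None
    for cut in (100, 300, 500, 700, 900):
        ts = ThresholdSet({**{m: 500.0 for m in MARKERS}, "CD138": float(cut)},
                          af_cutoff=500.0)
        ph = classify_cells(cells, ts)
        asc = int(ph["plasma_cell"].sum() + ph["bona_fide_pb"].sum())
        b = int(ph["b_cell"].sum())
        if prev_asc is not None:
            assert asc <= prev_asc
            assert b >= prev_b
        prev_asc, prev_b = asc, b


def test_threshold_and_gate_yaml_round_trip(tmp_path):
    ts = ThresholdSet({m: float(i) for i, m in enumerate(MARKERS, 1)},
                      af_cutoff=9.5, methods={"CD38": "gmm2"})
    ts.to_yaml(tmp_path / "t.yaml")
    back = ThresholdSet.from_yaml(tmp_path / "t.yaml")
    assert back.cutoffs == ts.cutoffs and back.af_cutoff == ts.af_cutoff

    DEFAULT_GATES.to_yaml(tmp_path / "g.yaml")
    gates = GateSet.from_yaml(tmp_path / "g.yaml")
    assert gates.gates == DEFAULT_GATES.gates
    assert gates.subfractions == DEFAULT_GATES.subfractions


def test_alternative_pc_signature_via_config(tmp_path):
    # a CD79a+/CD138+ plasma-cell gate is pure configuration
    gates = GateSet(gates={"pc_alt": (frozenset({"CD79a", "CD138"}), frozenset())})
    cells = _cell_table([_mfis(CD79a=1000, CD138=1000), _mfis(CD138=1000)])
    ph = classify_cells(cells, _thresholds(), gates)
    assert ph["pc_alt"].tolist() == [True, False]
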