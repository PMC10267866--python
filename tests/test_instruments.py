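"""Instrument selection: significance, clumping, strength, confounders."""

import numpy as np
import pytest

from mrkit.errors import ConfigurationError
from mrkit.instruments import (LDMatrix, SelectionConfig, clump,
                               confounder_exclude, f_statistic,
                               significance_filter, strength_filter)
import pandas as pd

from conftest import make_dataset, make_variant
from mrkit.summary_io import SummaryDataset


def test_significance_filter_direct_comparison():
    ds = make_dataset([0.1, 0.1, 0.1], [0.01] * 3, [1e-9, 1e-7, 4e-8])
    kept = significance_filter(ds, 5e-8)
    assert kept.variant_ids() == ["rs0", "rs2"]


def test_significance_filter_can_empty():
    ds = make_dataset([0.1], [0.01], [0.5])
    assert len(significance_filter(ds, 5e-8)) == 0


def test_significance_filter_idempotent_and_matches_scan(rng):
    ps = rng.uniform(1e-10, 1e-6, 1000)
    ds = make_dataset([0.1] * 1000, [0.01] * 1000, list(ps))
    once = significance_filter(ds, 5e-8)
    twice = significance_filter(once, 5e-8)
    assert once.variant_ids() == twice.variant_ids()
    # brute-force linear-scan oracle
    expected = [r.variant_id for r in ds.records if r.pvalue < 5e-8]
    assert once.variant_ids() == expected


@pytest.mark.parametrize("beta,se,expected", [
    (0.1, 0.01, 100.0),
    (0.0, 0.01, 0.0),
])
def test_f_statistic_closed_form(beta, se, expected):
    v = make_variant(0, beta, se, 1e-9)
    assert f_statistic(v) == pytest.approx(expected)


def test_f_statistic_equals_squared_z(rng):
    for _ in range(50):
        beta = rng.normal(0, 0.1)
        se = rng.uniform(1e-3, 0.1)
        v = make_variant(0, beta, se, 1e-9)
        assert f_statistic(v) == pytest.approx((beta / se) ** 2, rel=1e-12)


def test_strength_filter_keeps_only_strong():
    ds = make_dataset([0.1, 0.01], [0.01, 0.01], [1e-9, 1e-9])
    kept = strength_filter(ds, f_min=10.0)
    assert [ir.variant.variant_id for ir in kept] == ["rs0"]
    assert all(ir.f_statistic > 10 for ir in kept)


def _two_close_variants(p1, p2):
    v1 = make_variant(0, 0.1, 0.01, p1, chrom="1", pos=1_000_000)
    v2 = make_variant(1, 0.1, 0.01, p2, chrom="1", pos=6_000_000)
    return SummaryDataset("t", [v1, v2], "binary")


def test_clump_within_window_keeps_lower_p_with_ld():
    ds = _two_close_variants(1e-10, 1e-9)  # 5,000 kb apart
    ld = LDMatrix(["rs0", "rs1"], np.array([[1.0, 0.5], [0.5, 1.0]]))
    kept = clump(ds, ld=ld)
    assert kept.variant_ids() == ["rs0"]


def test_clump_low_ld_within_window_keeps_both():
    ds = _two_close_variants(1e-10, 1e-9)
    ld = LDMatrix(["rs0", "rs1"], np.array([[1.0, 0.0], [0.0, 1.0]]))
    assert len(clump(ds, ld=ld)) == 2


def test_clump_without_ld_prunes_whole_window():
    assert clump(_two_close_variants(1e-10, 1e-9)).variant_ids() == ["rs0"]


def test_clump_never_spans_chromosomes():
    v1 = make_variant(0, 0.1, 0.01, 1e-10, chrom="1", pos=100)
    v2 = make_variant(1, 0.1, 0.01, 1e-9, chrom="2", pos=100)
    ds = SummaryDataset("t", [v1, v2], "binary")
    assert len(clump(ds)) == 2


def test_clump_ld_missing_variant_is_configuration_error():
    ds = _two_close_variants(1e-10, 1e-9)
    ld = LDMatrix(["rs0"], np.array([[1.0]]))
    with pytest.raises(ConfigurationError, match="rs1"):
        clump(ds, ld=ld)


def _reference_greedy(records, r2_of, window_bp, r2_max):
    """Independent exhaustive greedy clumping used as the oracle."""
    remaining = sorted(records, key=lambda r: (r.pvalue, r.variant_id))
    selected = []
    while remaining:
        best = remaining.pop(0)
        selected.append(best.variant_id)
        survivors = []
        for r in remaining:
            same_chrom = r.chrom == best.chrom
            close = same_chrom and abs(r.pos - best.pos) <= window_bp
            if close and r2_of(best.variant_id, r.variant_id) > r2_max:
                continue
            survivors.append(r)
        remaining = survivors
    return selected


def test_clump_matches_exhaustive_greedy_reference(rng):
    """50 variants, random positions and LD: greedy oracle equivalence."""
    k = 50
    ids = [f"rs{i}" for i in range(k)]
    chroms = [str(rng.integers(1, 4)) for _ in range(k)]
    positions = [int(rng.integers(1, 30_000_000)) for _ in range(k)]
    ps = rng.uniform(1e-12, 1e-8, k)
    raw = rng.uniform(0, 1, (k, k))
    r2 = (raw + raw.T) / 2
    np.fill_diagonal(r2, 1.0)
    records = [make_variant(i, 0.1, 0.01, float(ps[i]), chrom=chroms[i],
                            pos=positions[i]) for i in range(k)]
    ds = SummaryDataset("t", records, "binary")
    ld = LDMatrix(ids, r2)
    cfg = SelectionConfig(clump_window_kb=5000, clump_r2=0.3)
    result = clump(ds, ld=ld, config=cfg).variant_ids()
    expected = _reference_greedy(records, ld.lookup, 5_000_000, 0.3)
    assert result == expected


def test_clump_output_is_antichain(rng):
    k = 40
    positions = [int(rng.integers(1, 20_000_000)) for _ in range(k)]
    ps = rng.uniform(1e-12, 1e-8, k)
    records = [make_variant(i, 0.1, 0.01, float(ps[i]), chrom="1",
                            pos=positions[i]) for i in range(k)]
    ds = SummaryDataset("t", records, "binary")
    cfg = SelectionConfig(clump_window_kb=2000, clump_r2=0.5)
    kept = clump(ds, config=cfg).records
    for a in kept:
        for b in kept:
            if a.variant_id != b.variant_id:
                assert abs(a.pos - b.pos) > 2_000_000  # no LD: window rules


def test_confounder_exclude_removes_associated():
    ds = make_dataset([0.1, 0.1], [0.01, 0.01], [1e-9, 1e-9])
    assoc = pd.DataFrame({"variant_id": ["rs0"], "trait_label": ["BMI"],
                          "pvalue": [1e-10]})
    assert confounder_exclude(ds, assoc, 5e-8).variant_ids() == ["rs1"]


def test_confounder_exclude_empty_table_is_identity():
    ds = make_dataset([0.1], [0.01], [1e-9])
    empty = pd.DataFrame(columns=["variant_id", "trait_label", "pvalue"])
    assert confounder_exclude(ds, empty, 5e-8).variant_ids() == ["rs0"]


def test_confounder_exclude_matches_set_difference(rng):
    k = 60
    ds = make_dataset([0.1] * k, [0.01] * k, [1e-9] * k)
    ids = ds.variant_ids()
    rows = []
    for vid in rng.choice(ids, size=30, replace=False):
        rows.append({"variant_id": vid, "trait_label": "BMI",
                     "pvalue": float(rng.uniform(1e-12, 1e-4))})
    assoc = pd.DataFrame(rows)
    survivors = set(confounder_exclude(ds, assoc, 5e-8).variant_ids())
    hit = {r["variant_id"] for r in rows if r["pvalue"] < 5e-8}
    assert survivors == set(ids) - hit


def test_ld_matrix_validates_shape_and_symmetry():
    with pytest.raises(ConfigurationError):
        LDMatrix(["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]]))
    with pytest.raises(ConfigurationError):
        LDMatrix(["a"], np.array([[0.5]]))


def test_selection_config_rejects_bad_thresholds():
    with pytest.raises(ConfigurationError):
        SelectionConfig(p_threshold=0)
    with pytest.raises(ConfigurationError):
        SelectionConfig(clump_r2=1.5)
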