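"""Allele alignment: orientation, strand complements, palindromes."""

import dataclasses

import numpy as np
import pytest

from mrkit.errors import AnalysisError
from mrkit.estimators import ivw
from mrkit.harmonization import harmonize, orient_to_exposure_increasing
from mrkit.summary_io import SummaryDataset, VariantAssociation

from conftest import make_harmonized


def _pair_datasets(exp_alleles, out_alleles, eaf_exp=0.3, eaf_out=0.3,
                   beta_out=0.05):
    exp = SummaryDataset("exp", [VariantAssociation(
        "rs1", exp_alleles[0], exp_alleles[1], 0.1, 0.01, 1e-9,
        chrom="1", pos=100, eaf=eaf_exp)], "binary")
    out = SummaryDataset("out", [VariantAssociation(
        "rs1", out_alleles[0], out_alleles[1], beta_out, 0.02, 0.01,
        chrom="1", pos=100, eaf=eaf_out)], "binary")
    return exp, out


# Truth table over outcome allele configurations for exposure A/G:
# (outcome effect/other, expected kept, expected flipped)
TRUTH_TABLE = [
    (("A", "G"), True, False),   # same pair, same orientation
    (("G", "A"), True, True),    # same pair, swapped
    (("T", "C"), True, False),   # complement strand, same orientation
    (("C", "T"), True, True),    # complement strand, swapped
    (("A", "C"), False, None),
    (("A", "T"), False, None),
    (("C", "A"), False, None),
    (("C", "G"), False, None),
    (("G", "T"), False, None),
    (("G", "C"), False, None),
    (("T", "A"), False, None),
    (("T", "G"), False, None),
]


@pytest.mark.parametrize("out_alleles,kept,flipped", TRUTH_TABLE)
def test_allele_configuration_truth_table(out_alleles, kept, flipped):
    exp, out = _pair_datasets(("A", "G"), out_alleles)
    result = harmonize(exp, out)
    if kept:
        assert len(result) == 1
        pair = result.pairs[0]
        assert pair.flipped == flipped
        assert pair.beta_outcome == (-0.05 if flipped else 0.05)
        assert result.n_dropped_incompatible == 0
    else:
        assert len(result) == 0
        assert result.n_dropped_incompatible == 1


# Palindromic exposure A/T, exposure EAF 0.2:
# (outcome alleles, outcome EAF, kept, flipped)
PALINDROME_CASES = [
    (("A", "T"), 0.20, True, False),   # concordant frequencies
    (("A", "T"), 0.80, True, True),    # discordant: other strand
    (("T", "A"), 0.80, True, True),    # swapped report, freq of T
    (("T", "A"), 0.20, True, False),   # swapped + other strand
    (("A", "T"), 0.50, False, None),   # maximal ambiguity
    (("A", "T"), 0.55, False, None),   # inside the 0.42-0.58 band
    (("A", "T"), None, False, None),   # missing EAF
]


@pytest.mark.parametrize("out_alleles,eaf_out,kept,flipped", PALINDROME_CASES)
def test_palindromic_resolution_by_eaf(out_alleles, eaf_out, kept, flipped):
    exp, out = _pair_datasets(("A", "T"), out_alleles, eaf_exp=0.2,
                              eaf_out=eaf_out)
    result = harmonize(exp, out)
    if kept:
        assert len(result) == 1
        assert result.pairs[0].flipped == flipped
        assert result.pairs[0].palindromic
        assert result.n_dropped_palindromic == 0
    else:
        assert len(result) == 0
        assert result.n_dropped_palindromic == 1


def test_keep_palindromic_false_drops_all_palindromes():
    exp, out = _pair_datasets(("A", "T"), ("A", "T"), eaf_exp=0.2,
                              eaf_out=0.2)
    result = harmonize(exp, out, keep_palindromic=False)
    assert len(result) == 0
    assert result.n_dropped_palindromic == 1


def test_orientation_swap_example():
    exp, out = _pair_datasets(("A", "G"), ("G", "A"))
    pair = harmonize(exp, out).pairs[0]
    assert pair.beta_outcome == -0.05
    assert pair.flipped


def test_harmonize_never_alters_ses():
    exp, out = _pair_datasets(("A", "G"), ("C", "T"))
    pair = harmonize(exp, out).pairs[0]
    assert pair.se_exposure == 0.01
    assert pair.se_outcome == 0.02


def test_counts_partition_the_intersection(rng):
    # mixture of clean, palindromic-ambiguous, and incompatible variants
    exp_records, out_records = [], []
    for i in range(30):
        kind = i % 3
        if kind == 0:
            ea, oa = ("A", "G"), ("A", "G")
        elif kind == 1:
            ea, oa = ("A", "T"), ("A", "T")  # ambiguous EAF below
        else:
            ea, oa = ("A", "G"), ("A", "C")  # incompatible
        exp_records.append(VariantAssociation(
            f"rs{i}", ea[0], ea[1], 0.1, 0.01, 1e-9, eaf=0.5))
        out_records.append(VariantAssociation(
            f"rs{i}", oa[0], oa[1], 0.05, 0.02, 0.01, eaf=0.5))
    result = harmonize(SummaryDataset("e", exp_records),
                       SummaryDataset("o", out_records))
    assert result.n_input == 30
    assert (len(result) + result.n_dropped_palindromic
            + result.n_dropped_incompatible) == result.n_input


def test_empty_intersection_raises():
    exp, _ = _pair_datasets(("A", "G"), ("A", "G"))
    other = SummaryDataset("o", [VariantAssociation(
        "rs999", "A", "G", 0.1, 0.01, 1e-9)], "binary")
    with pytest.raises(AnalysisError, match="no shared instruments"):
        harmonize(exp, other)


def test_orient_joint_negation():
    data = make_harmonized([-0.1], [0.01], [0.05], [0.02])
    pair = orient_to_exposure_increasing(data).pairs[0]
    assert pair.beta_exposure == 0.1
    assert pair.beta_outcome == -0.05


def test_orient_identity_on_nonnegative(random_harmonized):
    oriented = orient_to_exposure_increasing(random_harmonized)
    assert oriented.pairs == random_harmonized.pairs


def test_orient_drops_exact_zero():
    data = make_harmonized([0.0, 0.1], [0.01, 0.01], [0.05, 0.05],
                           [0.02, 0.02])
    assert len(orient_to_exposure_increasing(data)) == 1


def test_orientation_swap_is_involution():
    data = make_harmonized([-0.1, 0.2], [0.01, 0.01], [0.05, -0.03],
                           [0.02, 0.02])
    flip = lambda p: dataclasses.replace(
        p, beta_exposure=-p.beta_exposure, beta_outcome=-p.beta_outcome,
        flipped=not p.flipped)
    assert [flip(flip(p)) for p in data.pairs] == data.pairs


def test_orientation_leaves_ivw_invariant(rng):
    k = 15
    bx = rng.normal(0, 0.05, k)
    bx[bx == 0] = 0.01
    by = rng.normal(0.5 * bx, 0.004)
    data = make_harmonized(bx, np.full(k, 0.002), by, np.full(k, 0.004))
    before, _ = ivw(data, model="fixed")
    after, _ = ivw(orient_to_exposure_increasing(data), model="fixed")
    assert abs(before.theta - after.theta) < 1e-12
    assert abs(before.se - after.se) < 1e-12
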