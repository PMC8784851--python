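import numpy as np
import pytest

from oracles import exhaustive_clump, proxy_by_rule
from tsmr.gwas_io import LDInfo, SummaryStats, VariantAssociation
from tsmr.instruments import (
    COMPLEMENT,
    NoInstrumentsError,
    f_statistic,
    find_proxy,
    harmonize,
    is_weak,
    select_instruments,
    variance_explained,
)

from conftest import make_stats


def _simple_stats(pvals, label="exp"):
    return make_stats(
        label,
        [(vid, "A", "G", 0.3, 0.1, 0.01, p, 50000) for vid, p in pvals.items()],
    )


# ---------------------------------------------------------------------------
# select_instruments


def test_clump_drops_linked_weaker_snp():
    stats = _simple_stats({"rs1": 1e-10, "rs2": 1e-9})
    ld = LDInfo()
    ld.set_r2("rs1", "rs2", 0.5)
    assert select_instruments(stats, ld) == ["rs1"]


def test_unlinked_snps_both_retained():
    stats = _simple_stats({"rs1": 1e-10, "rs2": 1e-9})
    assert select_instruments(stats, LDInfo()) == ["rs1", "rs2"]


def test_no_candidates_raises():
    stats = _simple_stats({"rs1": 0.5})
    with pytest.raises(NoInstrumentsError):
        select_instruments(stats, LDInfo())


def test_threshold_is_strict():
    stats = _simple_stats({"rs1": 5e-8, "rs2": 4.9e-8})
    assert select_instruments(stats, LDInfo()) == ["rs2"]


def test_clump_invariant_to_row_order(rng):
    pvals = {f"rs{i}": float(rng.uniform(1e-12, 1e-7)) for i in range(15)}
    ld = LDInfo()
    ids = list(pvals)
    for _ in range(30):
        a, b = rng.choice(ids, 2, replace=False)
        ld.set_r2(str(a), str(b), float(rng.random()))
    ref = select_instruments(_simple_stats(pvals), ld)
    for _ in range(5):
        shuffled = {k: pvals[k] for k in rng.permutation(ids)}
        assert select_instruments(_simple_stats(shuffled), ld) == ref


@pytest.mark.parametrize("trial", range(30))
def test_clump_matches_exhaustive_oracle(trial):
    rng = np.random.default_rng(1000 + trial)
    n = 12
    pvals = {f"rs{i:02d}": float(rng.uniform(1e-12, 1e-6)) for i in range(n)}
    ld = LDInfo()
    ids = list(pvals)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.4:
                ld.set_r2(ids[i], ids[j], float(rng.random()))
    thr = 0.1  # coarse threshold so LD actually bites
    got = select_instruments(_simple_stats(pvals), ld, p_threshold=1e-5, r2_clump=thr)
    expected = exhaustive_clump(list(pvals.items()), ld.r2, 1e-5, thr)
    assert sorted(got) == sorted(expected)


# ---------------------------------------------------------------------------
# find_proxy


def _proxy_setup(cands):
    """cands: {vid: (r2, p_exp)}; target 'rsT' absent from outcome."""
    exp_rows = [("rsT", "A", "G", 0.3, 0.1, 0.01, 1e-10, 50000)]
    out_rows = []
    ld = LDInfo()
    for vid, (r2, p) in cands.items():
        exp_rows.append((vid, "A", "G", 0.3, 0.1, 0.01, p, 50000))
        out_rows.append((vid, "A", "G", 0.3, 0.05, 0.01, 0.5, 90000))
        ld.set_r2("rsT", vid, r2)
    return make_stats("exp", exp_rows), make_stats("out", out_rows), ld


def test_proxy_argmax_r2():
    exp, out, ld = _proxy_setup({"rsA": (0.9, 1e-8), "rsB": (0.7, 1e-12)})
    assert find_proxy("rsT", exp, out, ld) == "rsA"


def test_proxy_below_threshold_none():
    exp, out, ld = _proxy_setup({"rsA": (0.5, 1e-8)})
    assert find_proxy("rsT", exp, out, ld, r2_min=0.6) is None


def test_proxy_threshold_is_strict():
    exp, out, ld = _proxy_setup({"rsA": (0.6, 1e-8)})
    assert find_proxy("rsT", exp, out, ld, r2_min=0.6) is None


def test_proxy_tie_break_by_exposure_p():
    exp, out, ld = _proxy_setup({"rsA": (0.8, 1e-8), "rsB": (0.8, 1e-12)})
    assert find_proxy("rsT", exp, out, ld) == "rsB"


def test_proxy_must_be_in_both_tables():
    exp, out, ld = _proxy_setup({"rsA": (0.9, 1e-8)})
    del exp.records["rsA"]
    assert find_proxy("rsT", exp, out, ld) is None


@pytest.mark.parametrize("trial", range(20))
def test_proxy_matches_rule_oracle(trial):
    rng = np.random.default_rng(2000 + trial)
    cands = {
        f"rs{i:02d}": (float(rng.choice([0.5, 0.7, 0.8, 0.8, 0.95])), float(rng.uniform(1e-12, 1e-6)))
        for i in range(8)
    }
    exp, out, ld = _proxy_setup(cands)
    expected = proxy_by_rule(
        "rsT", [(vid, r2, p) for vid, (r2, p) in cands.items()], 0.6
    )
    assert find_proxy("rsT", exp, out, ld, 0.6) == expected


# ---------------------------------------------------------------------------
# harmonize


def _pair(exp_alleles, out_alleles, out_beta, exp_eaf=0.2, out_eaf=0.2):
    exp = make_stats("e", [("rs1", *exp_alleles, exp_eaf, 0.1, 0.01, 1e-10, 50000)])
    out = make_stats("o", [("rs1", *out_alleles, out_eaf, out_beta, 0.02, 0.5, 90000)])
    return exp, out


def test_harmonize_matching_alleles():
    exp, out = _pair(("A", "G"), ("A", "G"), 0.05)
    iset = harmonize(exp, out, ["rs1"])
    inst = iset.instruments[0]
    assert inst.beta_out == 0.05 and not inst.flags


def test_harmonize_swapped_alleles_flip_beta():
    exp, out = _pair(("A", "G"), ("G", "A"), 0.05)
    inst = harmonize(exp, out, ["rs1"]).instruments[0]
    assert inst.beta_out == -0.05 and "flipped" in inst.flags


def test_harmonize_strand_complement_same_orientation():
    exp, out = _pair(("A", "G"), ("T", "C"), 0.05)
    inst = harmonize(exp, out, ["rs1"]).instruments[0]
    assert inst.beta_out == 0.05 and "flipped" not in inst.flags


def test_harmonize_strand_complement_swapped():
    exp, out = _pair(("A", "G"), ("C", "T"), 0.05)
    inst = harmonize(exp, out, ["rs1"]).instruments[0]
    assert inst.beta_out == -0.05 and "flipped" in inst.flags


def test_palindromic_intermediate_eaf_dropped():
    exp, out = _pair(("A", "T"), ("A", "T"), 0.05, exp_eaf=0.5)
    iset = harmonize(exp, out, ["rs1"])
    assert len(iset) == 0
    assert iset.provenance[0].decision == "palindrome_dropped"


@pytest.mark.parametrize("eaf,kept", [(0.39, True), (0.41, False), (0.59, False), (0.61, True)])
def test_palindrome_window_boundaries(eaf, kept):
    exp, out = _pair(("A", "T"), ("A", "T"), 0.05, exp_eaf=eaf)
    iset = harmonize(exp, out, ["rs1"])
    assert (len(iset) == 1) == kept


def test_palindromic_kept_when_extreme_eaf_flagged():
    exp, out = _pair(("C", "G"), ("C", "G"), 0.05, exp_eaf=0.1)
    inst = harmonize(exp, out, ["rs1"]).instruments[0]
    assert "palindromic" in inst.flags


def test_palindromic_missing_eaf_dropped():
    exp, out = _pair(("A", "T"), ("A", "T"), 0.05, exp_eaf=None)
    iset = harmonize(exp, out, ["rs1"])
    assert len(iset) == 0 and "EAF" in iset.provenance[0].detail


def test_irreconcilable_alleles_dropped():
    exp, out = _pair(("A", "G"), ("A", "C"), 0.05)
    iset = harmonize(exp, out, ["rs1"])
    assert len(iset) == 0 and iset.provenance[0].decision == "unmatched"


def test_proxy_flagged():
    exp, out = _pair(("A", "G"), ("A", "G"), 0.05)
    inst = harmonize(exp, out, ["rs1"], proxied={"rs1": "rs_orig"}).instruments[0]
    assert "proxy_used" in inst.flags


def _random_tables(rng, n):
    alleles = ["A", "C", "G", "T"]
    exp_rows, out_rows = [], []
    for i in range(n):
        ea = alleles[rng.integers(4)]
        oa = alleles[(alleles.index(ea) + 1 + rng.integers(3)) % 4]
        eaf = float(rng.uniform(0.01, 0.99))
        beta = float(rng.standard_normal() * 0.1)
        exp_rows.append((f"rs{i}", ea, oa, eaf, beta, 0.01, 1e-10, 50000))
        o_ea, o_oa, o_beta = ea, oa, float(rng.standard_normal() * 0.05)
        if rng.random() < 0.5:  # swap
            o_ea, o_oa, o_beta = o_oa, o_ea, -o_beta
        if rng.random() < 0.3 and {ea, oa} not in ({"A", "T"}, {"C", "G"}):
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        out_rows.append((f"rs{i}", o_ea, o_oa, eaf, o_beta, 0.02, 0.5, 90000))
    return make_stats("e", exp_rows), make_stats("o", out_rows)


def _as_tables(iset, exp, out):
    """Re-express a harmonized set as exposure/outcome SummaryStats."""
    e2 = SummaryStats(trait_label="e2")
    o2 = SummaryStats(trait_label="o2")
    for inst in iset:
        src = exp[inst.variant_id]
        e2.add(
            VariantAssociation(inst.variant_id, src.effect_allele, src.other_allele,
                               inst.eaf, inst.beta_exp, inst.se_exp, src.pval, src.n_total)
        )
        o2.add(
            VariantAssociation(inst.variant_id, src.effect_allele, src.other_allele,
                               inst.eaf, inst.beta_out, inst.se_out, 0.5, 90000)
        )
    return e2, o2


def test_harmonize_idempotent(rng):
    exp, out = _random_tables(rng, 1000)
    ids = [f"rs{i}" for i in range(1000)]
    first = harmonize(exp, out, ids)
    e2, o2 = _as_tables(first, exp, out)
    second = harmonize(e2, o2, first.variant_ids)
    assert len(second) == len(first)
    for a, b in zip(first, second):
        assert (a.variant_id, a.beta_exp, a.beta_out) == (b.variant_id, b.beta_exp, b.beta_out)
        assert "flipped" not in b.flags


def test_strand_complement_invariance(rng):
    """Complementing a non-palindromic outcome record's alleles must not
    change the harmonized effect pair."""
    exp, out = _random_tables(rng, 300)
    ids = [f"rs{i}" for i in range(300)]
    base = {i.variant_id: (i.beta_exp, i.beta_out) for i in harmonize(exp, out, ids)}
    for rec in out.records.values():
        if not rec.is_palindromic:
            rec.effect_allele = COMPLEMENT[rec.effect_allele]
            rec.other_allele = COMPLEMENT[rec.other_allele]
    flipped = {i.variant_id: (i.beta_exp, i.beta_out) for i in harmonize(exp, out, ids)}
    assert flipped == base


def test_harmonize_missing_variant_goes_to_provenance():
    exp, out = _pair(("A", "G"), ("A", "G"), 0.05)
    iset = harmonize(exp, out, ["rs1", "rs_missing"])
    decisions = {p.variant_id: p.decision for p in iset.provenance}
    assert decisions["rs_missing"] == "unmatched"


# ---------------------------------------------------------------------------
# variance_explained / f_statistic


def test_variance_explained_zero_beta(rng):
    from conftest import make_iset

    iset = make_iset([0.0], [0.01], [0.0], [0.02], eaf=[0.3])
    assert variance_explained(iset.instruments[0]) == 0.0


def test_variance_explained_hand_formula():
    from conftest import make_iset

    iset = make_iset([0.1], [0.01], [0.0], [0.02], eaf=[0.5], n_exp=10_000)
    # 2*0.01*0.25 / (2*0.01*0.25 + 2*1e-4*1e4*0.25) = 0.005/0.505
    expected = (2 * 0.1**2 * 0.25) / (2 * 0.1**2 * 0.25 + 2 * 0.01**2 * 10_000 * 0.25)
    assert variance_explained(iset.instruments[0]) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.005 / 0.505, rel=1e-12)


def test_variance_explained_monotone_in_beta():
    from conftest import make_iset

    lo = make_iset([0.1], [0.01], [0.0], [0.02]).instruments[0]
    hi = make_iset([0.2], [0.01], [0.0], [0.02]).instruments[0]
    assert variance_explained(hi) > variance_explained(lo)


def test_variance_explained_missing_eaf_none():
    from conftest import make_iset

    iset = make_iset([0.1], [0.01], [0.0], [0.02], eaf=[None])
    assert variance_explained(iset.instruments[0]) is None


def test_f_statistic_hand_values():
    assert f_statistic(0.5, 4) == pytest.approx(2.0)
    assert f_statistic(0.01, 1002) == pytest.approx(0.01 * 1000 / 0.99)
    assert f_statistic(0.0, 100) == 0.0


def test_f_statistic_weak_flag():
    assert is_weak(f_statistic(0.0, 100))
    assert is_weak(10.0)
    assert not is_weak(10.0001)


def test_f_statistic_domain_errors():
    with pytest.raises(ValueError):
        f_statistic(1.0, 100)
    with pytest.raises(ValueError):
        f_statistic(0.1, 2)


def test_instrument_set_summaries(rng):
    from conftest import make_iset

    iset = make_iset([0.1, 0.2], [0.01, 0.01], [0.0, 0.1], [0.02, 0.02], n_exp=10_000)
    f = iset.f_per_snp
    assert set(f) == {"rs0001", "rs0002"}
    assert iset.f_mean == pytest.approx(sum(f.values()) / 2)
    r2s = [variance_explained(i) for i in iset.instruments]
    assert iset.r2_total == pytest.approx(sum(r2s))
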