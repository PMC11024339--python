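"""Instrument selection: F statistic, significance filter, LD clumping,
confounder screening, and the composed cascade."""

import numpy as np
import pandas as pd
import pytest

from mrlink.exceptions import ConfigurationError, EmptyInstrumentsError
from mrlink.instruments import (LdReference, compute_f_statistic,
                                filter_significant, ld_clump,
                                screen_confounders, select_instruments)
from mrlink.simulate import (SimulationConfig,
                             simulate_confounder_annotations,
                             simulate_ld_panel, simulate_pair)
from mrlink.sumstats import SumstatsTable, make_table


def _table(rows):
    df = pd.DataFrame(rows)
    defaults = {"eaf": 0.3, "n": 1000.0, "effect_allele": "A",
                "other_allele": "G", "chrom": "1"}
    for key, val in defaults.items():
        if key not in df:
            df[key] = val
    return make_table(df, trait_id="exp", trait_type="continuous")


@pytest.mark.parametrize("beta,se,expected", [
    (0.03, 0.005, 36.0),
    (-0.02, 0.004, 25.0),
    (0.0, 0.1, 0.0),
])
def test_f_statistic_is_squared_z(beta, se, expected):
    assert compute_f_statistic(beta, se) == pytest.approx(expected, abs=1e-12)


def test_f_statistic_rejects_nonpositive_se():
    with pytest.raises(ConfigurationError):
        compute_f_statistic(0.1, 0.0)


def test_significance_filter_boundaries():
    table = _table([
        {"rsid": "kept", "pos": 1000, "beta": 0.1, "se": 0.005, "pval": 4e-8},
        {"rsid": "at_p", "pos": 2000, "beta": 0.1, "se": 0.005, "pval": 5e-8},
        {"rsid": "weak", "pos": 3000, "beta": 0.01, "se": 0.005, "pval": 4e-8},
    ])
    out = filter_significant(table)
    assert out.data["rsid"].tolist() == ["kept"]  # strict p and F inequalities


def test_significance_filter_matches_full_scan_oracle(rng):
    n = 1000
    table = _table([{"rsid": f"rs{i}", "pos": 1000 + i,
                     "beta": rng.normal(0, 0.05), "se": rng.uniform(0.005, 0.05),
                     "pval": 10 ** -rng.uniform(0, 12)} for i in range(n)])
    kept = set(filter_significant(table).data["rsid"])
    oracle = {row.rsid for row in table.data.itertuples()
              if row.pval < 5e-8 and (row.beta / row.se) ** 2 > 10}
    assert kept == oracle


def _pair_ld(entries):
    rows = [{"rsid_i": i, "rsid_j": j, "r2": r} for i, j, r in entries]
    return LdReference.from_pair_table(pd.DataFrame(rows))


def test_clump_worked_example():
    """Index A absorbs its LD partner B; distant low-LD C survives."""
    table = _table([
        {"rsid": "A", "pos": 100_000, "beta": 0.1, "se": 0.01, "pval": 1e-10},
        {"rsid": "B", "pos": 200_000, "beta": 0.1, "se": 0.01, "pval": 1e-9},
        {"rsid": "C", "pos": 2_500_000, "beta": 0.1, "se": 0.01, "pval": 4e-8},
    ])
    ld = _pair_ld([("A", "B", 0.5), ("A", "C", 0.0005), ("B", "C", 0.0)])
    out = ld_clump(table, ld)
    assert set(out.data["rsid"]) == {"A", "C"}


def test_clump_never_spans_chromosomes_and_keeps_singleton():
    table = _table([
        {"rsid": "A", "chrom": "1", "pos": 100, "beta": 0.1, "se": 0.01,
         "pval": 1e-10},
        {"rsid": "B", "chrom": "2", "pos": 100, "beta": 0.1, "se": 0.01,
         "pval": 1e-9},
    ])
    ld = _pair_ld([("A", "B", 1.0)])
    assert set(ld_clump(table, ld).data["rsid"]) == {"A", "B"}
    single = _table([{"rsid": "A", "pos": 100, "beta": 0.1, "se": 0.01,
                      "pval": 1e-10}])
    assert ld_clump(single, _pair_ld([("A", "A", 1.0)])).data["rsid"].tolist() \
        == ["A"]


def test_clump_rejects_bad_config():
    table = _table([{"rsid": "A", "pos": 100, "beta": 0.1, "se": 0.01,
                     "pval": 1e-10}])
    ld = _pair_ld([("A", "A", 1.0)])
    with pytest.raises(ConfigurationError):
        ld_clump(table, ld, r2_threshold=0.0)
    with pytest.raises(ConfigurationError):
        ld_clump(table, ld, window_kb=-5)


def _clump_oracle(df, ld, r2_thr, window_bp):
    """Independent greedy re-implementation enumerating discard decisions."""
    todo = df.sort_values(["pval", "chrom", "pos"], kind="mergesort")
    remaining = list(todo.itertuples())
    kept = []
    while remaining:
        idx = remaining.pop(0)
        kept.append(idx.rsid)
        survivors = []
        for other in remaining:
            conflict = (other.chrom == idx.chrom
                        and abs(other.pos - idx.pos) <= window_bp
                        and (ld.r2(idx.rsid, other.rsid) or 0) >= r2_thr)
            if not conflict:
                survivors.append(other)
        remaining = survivors
    return set(kept)


@pytest.mark.parametrize("seed", range(5))
def test_clump_matches_oracle_and_is_greedy_maximal(seed):
    rng = np.random.default_rng(seed)
    n = 40
    chroms = rng.choice(["1", "2"], n)
    pos = rng.integers(1, 5_000_000, n)
    table = _table([{"rsid": f"rs{i}", "chrom": chroms[i], "pos": int(pos[i]),
                     "beta": 0.1, "se": 0.01,
                     "pval": float(10 ** -rng.uniform(8, 15))}
                    for i in range(n)])
    entries = [(f"rs{i}", f"rs{j}", float(rng.random() ** 3))
               for i in range(n) for j in range(i, n)]
    ld = _pair_ld(entries)
    r2_thr, window_kb = 0.1, 1000
    kept = ld_clump(table, ld, r2_threshold=r2_thr, window_kb=window_kb)
    kept_set = set(kept.data["rsid"])
    assert kept_set == _clump_oracle(table.data, ld, r2_thr, window_kb * 1000)

    # no two kept SNPs on one chromosome are both close and in LD
    kept_df = kept.data
    for i in range(len(kept_df)):
        for j in range(i + 1, len(kept_df)):
            a, b = kept_df.iloc[i], kept_df.iloc[j]
            if a.chrom == b.chrom and abs(a.pos - b.pos) <= window_kb * 1000:
                assert ld.r2(a.rsid, b.rsid) < r2_thr
    # maximality: every discarded SNP conflicts with some kept SNP
    for row in table.data.itertuples():
        if row.rsid in kept_set:
            continue
        assert any(k.chrom == row.chrom
                   and abs(k.pos - row.pos) <= window_kb * 1000
                   and ld.r2(k.rsid, row.rsid) >= r2_thr
                   for k in kept_df.itertuples())


def test_confounder_screen_rules():
    table = _table([
        {"rsid": "bmi_snp", "pos": 1000, "beta": 0.1, "se": 0.01, "pval": 1e-10},
        {"rsid": "height_snp", "pos": 2000, "beta": 0.1, "se": 0.01, "pval": 1e-10},
        {"rsid": "weak_smoke", "pos": 3000, "beta": 0.1, "se": 0.01, "pval": 1e-10},
    ])
    ann = pd.DataFrame({
        "rsid": ["bmi_snp", "height_snp", "weak_smoke"],
        "trait": ["Body Mass Index", "height", "smoking"],
        "pval": [1e-12, 1e-20, 1e-6],
    })
    out = screen_confounders(table, ann)
    # BMI association below 5e-8 drops the SNP (case-insensitive match);
    # a non-confounder trait and an above-threshold association do not.
    assert out.data["rsid"].tolist() == ["height_snp", "weak_smoke"]


def _scenario(seed=7):
    cfg = SimulationConfig(n_snp=55, n_instrument=20, n_confounder_snps=5,
                           theta=0.3, seed=seed)
    exposure, _, truth = simulate_pair(cfg)
    ld = simulate_ld_panel(cfg)
    ann = simulate_confounder_annotations(cfg, truth)
    return cfg, exposure, truth, ld, ann


def test_selection_cascade_recovers_exactly_the_true_instruments():
    _, exposure, truth, ld, ann = _scenario()
    inst = select_instruments(exposure, ld, ann)
    assert set(inst.rsids) == set(truth.loc[truth.is_instrument, "rsid"])
    log = inst.selection_log
    stages = ["input", "with_eaf", "significant", "clumped",
              "confounder_screened"]
    counts = [log[s] for s in stages]
    assert counts == sorted(counts, reverse=True)  # filters only remove
    assert np.allclose(inst.data["f_stat"],
                       (inst.data["beta"] / inst.data["se"]) ** 2,
                       rtol=1e-12)


def test_selection_is_idempotent_and_order_invariant(rng):
    _, exposure, truth, ld, ann = _scenario()
    first = select_instruments(exposure, ld, ann)
    again = select_instruments(
        SumstatsTable(trait_id="exp", trait_type="continuous",
                      data=first.data.drop(columns="f_stat")), ld, ann)
    assert set(again.rsids) == set(first.rsids)

    shuffled = exposure.data.sample(frac=1.0, random_state=3).reset_index(
        drop=True)
    perm = select_instruments(
        SumstatsTable(trait_id="exp", trait_type="continuous", data=shuffled),
        ld, ann)
    assert set(perm.rsids) == set(first.rsids)


def test_all_null_exposure_raises_empty_signal():
    cfg = SimulationConfig(n_snp=30, n_instrument=0, seed=1)
    exposure, _, _ = simulate_pair(cfg)
    ld = simulate_ld_panel(cfg)
    with pytest.raises(EmptyInstrumentsError):
        select_instruments(exposure, ld, None)
    inst = select_instruments(exposure, ld, None, allow_empty=True)
    assert len(inst) == 0 and inst.selection_log["significant"] == 0
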