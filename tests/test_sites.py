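"""Filter cascade: boundary exactness, merge rules, motif filter, confidence."""

import numpy as np
import pandas as pd
import pytest

from dartcall.pileup import EditingTable
from dartcall.sites import (
    CallParams,
    call_candidates,
    call_sites,
    filter_rac,
    high_confidence,
    merge_replicates,
    sites_to_records,
    write_bed,
)
from tests.conftest import BOUNDARY_EXPECT, sites_of


def test_filter_boundaries_match_hand_derived_truth(boundary_dataset):
    """Each stage of the cascade reproduces the hand-derived site sets on a
    table spanning every threshold boundary."""
    d = boundary_dataset
    params = CallParams()
    controls = list(d["ko"].values())
    cands = {
        sid: call_candidates(t, controls, params) for sid, t in d["wt"].items()
    }
    assert sites_of(cands["wt1"]) == BOUNDARY_EXPECT["candidates_rep1"]
    assert sites_of(cands["wt2"]) == BOUNDARY_EXPECT["candidates_rep2"]
    merged = merge_replicates(cands, d["wt"], params)
    assert sites_of(merged) == BOUNDARY_EXPECT["merged"]
    rac = filter_rac(merged, d["genome"], d["annotation"])
    assert sites_of(rac) == BOUNDARY_EXPECT["rac"]
    hc = high_confidence(rac, d["wt"], d["ko"], params)
    assert sites_of(hc) == BOUNDARY_EXPECT["high_confidence"]
    full = call_sites(d["wt"], d["ko"], d["genome"], d["annotation"], params)
    assert sites_of(full) == BOUNDARY_EXPECT["high_confidence"]


def _tab(sample_id, rows):
    """rows: list of (pos, edited, unedited)."""
    return EditingTable.from_counts(
        sample_id,
        ["c"] * len(rows),
        [r[0] for r in rows],
        ["+"] * len(rows),
        ["g"] * len(rows),
        [r[1] for r in rows],
        [r[2] for r in rows],
    )


def test_zero_control_rate_passes_fold_criterion():
    dart = _tab("d", [(5, 1, 65)])  # rate ~1.52, coverage 66
    ctrl = _tab("k", [(5, 0, 50)])
    out = call_candidates(dart, [ctrl], CallParams(min_edited=1, min_coverage=50))
    # fold criterion is trivially satisfied at control rate 0: r >= 1.25*0
    assert len(out) == 1


def test_position_without_adequately_covered_control_rejected():
    dart = _tab("d", [(5, 10, 90)])
    ctrl = _tab("k", [(5, 0, 5)])  # coverage 5 < min_control_coverage
    assert len(call_candidates(dart, [ctrl], CallParams())) == 0


def test_empty_control_list_is_error():
    with pytest.raises(ValueError):
        call_candidates(_tab("d", [(5, 10, 90)]), [], CallParams())


def test_merge_requires_min_replicates():
    t1 = _tab("a", [(5, 10, 90), (9, 10, 90)])
    t2 = _tab("b", [(5, 10, 90)])
    cands = {"a": t1.df, "b": t2.df[t2.df.pos == 5]}
    tables = {"a": t1, "b": t2}
    merged = merge_replicates(cands, tables, CallParams(min_replicates=2))
    assert list(merged.pos) == [5]
    assert merged.n_replicates_called.iloc[0] == 2
    # degenerate parameter: one replicate suffices
    merged1 = merge_replicates(cands, tables, CallParams(min_replicates=1))
    assert set(merged1.pos) == {5, 9}
    # counts attached even for the replicate that did not call the site
    row9 = merged1[merged1.pos == 9].iloc[0]
    assert row9["edited_b"] == 0 and not row9["called_b"]


def test_high_confidence_threshold_and_zero_ko_flag():
    site = pd.DataFrame(
        {"chrom": ["c"], "pos": [5], "strand": ["+"], "gene_id": ["g"]}
    )
    wt = {"w1": _tab("w1", [(5, 8, 92)]), "w2": _tab("w2", [(5, 12, 88)])}
    ko = {"k1": _tab("k1", [(5, 2, 98)]), "k2": _tab("k2", [(5, 2, 98)])}
    out = high_confidence(site, wt, ko, CallParams())
    assert len(out) == 1  # mean 10 >= 1.5 * mean 2
    assert out.mean_rate_wt.iloc[0] == pytest.approx(10.0)
    # 6.0 < 1.5 * 4.5: dropped
    wt_lo = {"w1": _tab("w1", [(5, 6, 94)])}
    ko_hi = {"k1": _tab("k1", [(5, 45, 955)])}
    assert len(high_confidence(site, wt_lo, ko_hi, CallParams())) == 0
    # site uncovered in KO: retained with flag
    out2 = high_confidence(site, wt, {"k1": _tab("k1", [(99, 1, 99)])}, CallParams())
    assert out2["flags"].iloc[0] == "no-control-coverage"
    assert out2.mean_rate_ko.iloc[0] == 0.0


def test_threshold_monotonicity(sim_small):
    """Raising any threshold never increases the number of called sites."""
    from dartcall.simulate import simulate_editing

    wt, ko = simulate_editing(sim_small, n_wt=3, n_ko=3, seed=21, coverage_mean=120)
    controls = list(ko.values())
    base = CallParams()
    sweeps = {
        "min_coverage": [30, 50, 80, 150],
        "min_edited": [1, 3, 6, 12],
        "min_rate_pct": [0.5, 1.0, 5.0, 20.0],
        "fold_vs_each_control": [1.0, 1.25, 2.0, 5.0],
        "min_replicates": [1, 2, 3],
    }
    for name, values in sweeps.items():
        counts = []
        for v in values:
            params = CallParams(**{name: v})
            cands = {s: call_candidates(t, controls, params) for s, t in wt.items()}
            counts.append(len(merge_replicates(cands, wt, params)))
        assert counts == sorted(counts, reverse=True), name


def test_cascade_matches_flat_scan_on_small_tables(sim_small, sim_small_genome):
    from dartcall.simulate import simulate_editing
    from tests.test_acceptance import flat_scan_oracle

    wt, ko = simulate_editing(sim_small, n_wt=2, n_ko=2, seed=31, coverage_mean=120)
    params = CallParams()
    expected = flat_scan_oracle(wt, ko, sim_small_genome, params)
    got = call_sites(wt, ko, sim_small_genome, sim_small.annotation, params)
    assert set(zip(got.chrom, got.pos, got.strand)) == expected


def test_bed_output_and_records(boundary_dataset, tmp_path):
    d = boundary_dataset
    full = call_sites(d["wt"], d["ko"], d["genome"], d["annotation"], CallParams())
    bed = tmp_path / "sites.bed"
    write_bed(full, bed)
    lines = bed.read_text().strip().split("\n")
    assert len(lines) == len(full)
    f = lines[0].split("\t")
    assert int(f[2]) == int(f[1]) + 1 and f[5] in "+-"
    recs = sites_to_records(full)
    assert recs[0].pos_a == recs[0].pos_c - 1  # plus strand: A is 5' of C
    assert all(r.motif[1:] == "AC" for r in recs)
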