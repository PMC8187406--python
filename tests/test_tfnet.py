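import math

import numpy as np
import pandas as pd
import pytest

from secretomap.tfnet import (
    PWM, TFPrediction, build_network, consensus_tfs, default_threshold,
    filter_by_expression, motif_enrichment, read_meme, read_promoters,
    reverse_complement, scan_pwm, write_meme,
)
from tests._oracles import scan_oracle


@pytest.fixture
def pwm():
    rng = np.random.default_rng(5)
    cons = rng.integers(0, 4, 8)
    mat = np.full((8, 4), 0.02)
    mat[np.arange(8), cons] = 0.94
    return PWM("M1", mat, pseudocount=1e-6)


def test_consensus_scores_at_column_max_sum(pwm):
    seq = "T" * 20 + pwm.consensus + "A" * 20
    hits = scan_pwm({"g": seq}, pwm, pwm.max_score - 1e-9)
    plus = [h for h in hits if h.strand == "+"]
    assert len(plus) == 1
    assert plus[0].position == 20
    assert plus[0].score == pytest.approx(pwm.max_score, abs=1e-9)


def test_all_n_sequence_yields_no_hits(pwm):
    assert scan_pwm({"g": "N" * 100}, pwm, -100.0) == []


def test_window_containing_n_is_skipped(pwm):
    seq = pwm.consensus[:4] + "N" + pwm.consensus[5:]
    assert scan_pwm({"g": seq}, pwm, -1e6) == []


def test_sequence_shorter_than_motif_warns_and_yields_nothing(pwm, caplog):
    with caplog.at_level("WARNING", logger="secretomap"):
        assert scan_pwm({"g": "ACGT"}, pwm, 0.0) == []
    assert "shorter" in caplog.text


def test_scan_matches_position_by_position_oracle(pwm, rng):
    """20 random 200-bp promoters at a 6-bit threshold."""
    for _ in range(20):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        # plant one consensus so hits exist
        seq = seq[:50] + pwm.consensus + seq[58:]
        hits = scan_pwm({"g": seq}, pwm, 6.0)
        got = {(h.position, h.strand, round(h.score, 9)) for h in hits}
        want = {(p, s, round(sc, 9))
                for p, s, sc in scan_oracle(seq, pwm.matrix, pwm.background, 6.0)}
        assert got == want


def test_reverse_complementing_preserves_hit_count(pwm, rng):
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    seq = seq[:100] + pwm.consensus + seq[108:]
    thr = default_threshold(pwm)
    n_fwd = len(scan_pwm({"g": seq}, pwm, thr))
    n_rc = len(scan_pwm({"g": reverse_complement(seq)}, pwm, thr))
    assert n_fwd == n_rc


def test_meme_round_trip(tmp_path, pwm):
    path = tmp_path / "m.meme"
    write_meme([pwm], path)
    back = read_meme(path)
    assert len(back) == 1 and back[0].motif_id == "M1"
    assert np.allclose(back[0].matrix, pwm.matrix, atol=1e-4)
    assert back[0].consensus == pwm.consensus


def test_extreme_fisher_table_matches_closed_form(pwm):
    """10/10 foreground hits vs 0/10 background: p = 2/C(20,10)."""
    fg = {f"f{i}": "A" * 5 + pwm.consensus + "A" * 5 for i in range(10)}
    bg = {f"b{i}": "N" * 18 for i in range(10)}
    df = motif_enrichment(fg, bg, [pwm])
    assert df.loc[0, "fg_hits"] == 10 and df.loc[0, "bg_hits"] == 0
    assert df.loc[0, "p_value"] == pytest.approx(2 / math.comb(20, 10),
                                                 rel=1e-9)


def test_equal_hit_proportions_not_significant(pwm):
    fg = {f"f{i}": (pwm.consensus if i < 5 else "T" * 18) + "AA"
          for i in range(10)}
    bg = {f"b{i}": (pwm.consensus if i < 5 else "T" * 18) + "AA"
          for i in range(10)}
    df = motif_enrichment(fg, bg, [pwm])
    assert df.loc[0, "p_value"] >= 0.99


def test_overlapping_promoter_sets_rejected(pwm):
    with pytest.raises(ValueError, match="overlap"):
        motif_enrichment({"g": "ACGTACGT"}, {"g": "ACGTACGT"}, [pwm])


def test_planted_enrichment_detected_in_seeded_replicates(pwm):
    """0.6 vs 0.05 occurrence at n=50/50: q < 0.05 in >= 95% of 200 runs."""
    detected = 0
    reps = 200
    for rep in range(reps):
        rng = np.random.default_rng(10_000 + rep)
        fg, bg = {}, {}
        for d, rate, prefix in ((fg, 0.6, "f"), (bg, 0.05, "b")):
            for i in range(50):
                seq = list("ACGT"[j] for j in rng.integers(0, 4, 200))
                if rng.random() < rate:
                    pos = int(rng.integers(0, 193))
                    seq[pos:pos + 8] = pwm.consensus
                d[f"{prefix}{i}"] = "".join(seq)
        df = motif_enrichment(fg, bg, [pwm])
        if df.loc[0, "q_value"] < 0.05:
            detected += 1
    assert detected >= 0.95 * reps


def P(tf, target, source):
    return TFPrediction(tf, target, source)


def test_tf_in_one_source_only_is_excluded():
    both = consensus_tfs([P("T1", "g1", "A")], [P("T2", "g2", "B")])
    assert both == {}


def test_consensus_pools_targets_across_sources():
    both = consensus_tfs([P("T1", "g1", "A")], [P("T1", "g2", "B")])
    assert both == {"T1": {"g1", "g2"}}


def test_consensus_matches_set_intersection_oracle(rng):
    tfs = [f"T{i}" for i in range(20)]
    genes = [f"g{i}" for i in range(30)]
    a = [P(str(rng.choice(tfs)), str(rng.choice(genes)), "A") for _ in range(80)]
    b = [P(str(rng.choice(tfs)), str(rng.choice(genes)), "B") for _ in range(80)]
    both = consensus_tfs(a, b)
    assert set(both) == {p.tf for p in a} & {p.tf for p in b}


def test_expression_filter_requires_stb_tf_and_common_target():
    tf_targets = {"T1": {"g1", "g2"}, "T2": {"g3"}, "T3": {"g1"}}
    stb = {"T1", "T2", "g1"}
    secretome = {"g1", "g3"}
    out = filter_by_expression(tf_targets, stb, secretome)
    # T1 kept via g1; T2 expressed but g3 not STB-expressed; T3 not expressed
    assert out == {"T1": {"g1"}}


def test_expression_filter_is_idempotent(rng):
    tf_targets = {f"T{i}": {f"g{j}" for j in rng.integers(0, 20, 5)}
                  for i in range(10)}
    stb = {f"T{i}" for i in range(0, 10, 2)} | {f"g{j}" for j in range(10)}
    secretome = {f"g{j}" for j in range(5, 20)}
    once = filter_by_expression(tf_targets, stb, secretome)
    twice = filter_by_expression(once, stb, secretome)
    assert once == twice


def test_empty_tf_list_gives_empty_network():
    g = build_network({}, {}, {})
    assert g.number_of_nodes() == 0 and g.number_of_edges() == 0


def test_network_counts_and_flags():
    g = build_network(
        {"T1": {"g1", "g2", "g3"}},
        {"T1": {"GDM"}},
        {"GDM": {"g1"}, "PE": {"g2"}})
    assert g.number_of_edges() == 3
    flagged = [n for n, d in g.nodes(data=True)
               if d["kind"] == "target" and d["differential"]]
    assert sorted(flagged) == ["g1", "g2"]
    assert g.nodes["T1"]["dysregulated"]


def test_funnel_counts_match_stepwise_reapplication(noisy_study):
    """Composing the TF filters equals reapplying each filter separately."""
    gt = noisy_study.ground_truth
    preds_a = [P(tf, h, "motif_enrichment") for tf, h in sorted(gt.true_tf_edges)
               if tf in gt.true_motif_tfs]
    reg = pd.read_csv(noisy_study.paths["regulators"], sep="\t")
    preds_b = [P(r.tf, r.target, r.source) for r in reg.itertuples(index=False)]
    both = consensus_tfs(preds_a, preds_b)
    assert set(both) == {p.tf for p in preds_a} & {p.tf for p in preds_b}
    stb = set(noisy_study.paths["stb_expressed"].read_text().split())
    secretome = {gt.true_ortholog_pairs[m] for m in gt.true_shared_secretome}
    filtered = filter_by_expression(both, stb, secretome)
    manual = {tf: tg & secretome & stb for tf, tg in both.items()
              if tf in stb and tg & secretome & stb}
    assert filtered == manual
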