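import math

import pytest

from retroregistry.changes import ChangeTiming, extract_changes
from retroregistry.classify import AuditConfig, Category, classify_trial
from retroregistry.model import read_histories, write_histories_jsonl
from retroregistry.synth import (
    CohortSpec,
    CompositionSpec,
    SpecError,
    build_exact_fixture,
    generate_stochastic,
)


def test_same_seed_gives_byte_identical_jsonl(tmp_path):
    spec = CohortSpec(n_trials=60, seed=42)
    paths = []
    for name in ("a.jsonl", "b.jsonl"):
        histories, _ = generate_stochastic(spec)
        path = tmp_path / name
        write_histories_jsonl(histories, path)
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_different_seeds_differ(tmp_path):
    a, _ = generate_stochastic(CohortSpec(n_trials=20, seed=1))
    b, _ = generate_stochastic(CohortSpec(n_trials=20, seed=2))
    assert a != b


def test_zero_flip_probability_yields_no_flips(config):
    histories, _ = generate_stochastic(
        CohortSpec(n_trials=300, seed=7, p_flip_given_retrospective=0.0)
    )
    categories = {classify_trial(h, config).category for h in histories}
    assert Category.RETROACTIVELY_PROSPECTIVE not in categories


def test_generated_histories_satisfy_invariants_and_round_trip(tmp_path):
    histories, _ = generate_stochastic(CohortSpec(n_trials=50, seed=4))
    path = tmp_path / "cohort.jsonl"
    write_histories_jsonl(histories, path)
    assert read_histories(path, format="jsonl") == histories


def test_truth_labels_agree_with_classifier(config):
    histories, truths = generate_stochastic(
        CohortSpec(n_trials=400, seed=12, month_precision_probability=0.4)
    )
    for h, truth in zip(histories, truths):
        assert classify_trial(h, config).category is truth.category
        has_change = bool(extract_changes(h, config))
        assert has_change == truth.has_start_date_change


def test_flip_timing_labels_agree_with_change_analyzer(config):
    from retroregistry.changes import decisive_flip

    histories, truths = generate_stochastic(CohortSpec(n_trials=2000, seed=8))
    n_flips = 0
    for h, truth in zip(histories, truths):
        if truth.category is not Category.RETROACTIVELY_PROSPECTIVE:
            continue
        n_flips += 1
        c = classify_trial(h, config)
        assert decisive_flip(h, c, config).timing is truth.flip_timing
    assert n_flips > 0


def test_parameter_recovery_within_three_binomial_se(config):
    spec = CohortSpec(n_trials=5000, seed=2015, p_retrospective_initial=0.5)
    histories, _ = generate_stochastic(spec)
    classifications = [classify_trial(h, config) for h in histories]
    retro = [
        c
        for c in classifications
        if c.launch.status.value == "RETROSPECTIVE"
    ]
    # retrospective-at-launch rate recovers p_retrospective_initial
    p_hat = len(retro) / spec.n_trials
    se = math.sqrt(0.25 / spec.n_trials)
    assert abs(p_hat - spec.p_retrospective_initial) <= 3 * se
    # flip rate among retrospective trials recovers p_flip_given_retrospective
    n_flip = sum(1 for c in retro if c.category is Category.RETROACTIVELY_PROSPECTIVE)
    p = spec.p_flip_given_retrospective
    se_flip = math.sqrt(p * (1 - p) / len(retro))
    assert abs(n_flip / len(retro) - p) <= 3 * se_flip


def test_infeasible_cohort_spec_rejected():
    with pytest.raises(SpecError):
        CohortSpec(n_trials=0)
    with pytest.raises(SpecError):
        CohortSpec(p_flip_given_retrospective=1.5)
    with pytest.raises(SpecError):
        CohortSpec(version_count_max=2)


def test_inconsistent_composition_lists_violations():
    with pytest.raises(SpecError, match="post-completion flip count"):
        CompositionSpec(
            n_total=100,
            n_originally_retrospective=50,
            n_retroactively_prospective=10,
            n_retroactively_prospective_post_completion=11,
            n_originally_retrospective_with_change=20,
            n_control_latest_change_post_completion=5,
            n_phase1_total=10,
            n_phase1_retroactively_prospective=2,
            n_published_retroactively_prospective=5,
            n_published_claims_prospective=1,
        )


def test_packaged_paper_mirror_composition_is_consistent():
    comp = CompositionSpec.from_yaml()
    assert comp.n_total == 11908
    assert comp.n_retroactively_prospective == 235


def test_exact_fixture_realizes_every_cell(small_composition, audit_2015_config):
    from retroregistry.pipeline import audit_cohort

    fx = build_exact_fixture(small_composition, seed=5)
    assert len(fx.histories) == small_composition.n_total
    _, _, flips, summary, excluded = audit_cohort(
        fx.histories, audit_2015_config, fx.publications, fx.extractions
    )
    c = small_composition
    assert excluded == []
    assert summary["categories"]["RETROACTIVELY_PROSPECTIVE"]["count"] == (
        c.n_retroactively_prospective
    )
    assert summary["retroactively_prospective"]["post_completion_flip"]["count"] == (
        c.n_retroactively_prospective_post_completion
    )
    assert summary["originally_retrospective"]["n"] == c.n_originally_retrospective
    assert summary["originally_retrospective"]["with_start_date_change"]["count"] == (
        c.n_originally_retrospective_with_change
    )
    assert summary["controls"]["latest_change_post_completion"]["count"] == (
        c.n_control_latest_change_post_completion
    )
    assert summary["subgroups"]["phase"]["PHASE1"]["n"] == c.n_phase1_total
    assert summary["subgroups"]["phase"]["PHASE1"]["retroactively_prospective"]["count"] == (
        c.n_phase1_retroactively_prospective
    )
    pubs = summary["publications"]["retroactively_prospective"]
    assert pubs["n_extractions"] == c.n_published_retroactively_prospective
    assert pubs["claims_prospective"]["count"] == c.n_published_claims_prospective
    assert pubs["concordance"]["count"] == c.n_published_flips_concordant


def test_fixture_determinism(tmp_path, small_composition):
    paths = []
    for name in ("a.jsonl", "b.jsonl"):
        fx = build_exact_fixture(small_composition, seed=99)
        path = tmp_path / name
        write_histories_jsonl(fx.histories, path)
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()
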