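"""Masking statistics, multitask loss, optimization sanity, samplers."""

import numpy as np
import pytest

from ehrseq import cohort as co
from ehrseq import model_core as mc
from ehrseq import train as tr
from ehrseq.synthetic_ehr import CategoryMap


def _feature_batch(n_positions=200_000, seed=0, vocab_size=50):
    """Synthetic batch where every position is an eligible feature token."""
    rng = np.random.default_rng(seed)
    L = 100
    B = n_positions // L
    return {
        "code_ids": rng.integers(4, vocab_size, (B, L)),
        "type_ids": rng.integers(co.TYPE_PRINCIPAL, co.TYPE_PROC + 1, (B, L)),
        "attention_mask": np.ones((B, L), dtype=np.int64),
    }


class TestMasking:
    def test_selection_fraction_near_15_percent(self):
        batch = _feature_batch()
        plan, _ = tr.make_masking_plan(batch, seed=1)
        frac = plan.selected.mean()
        assert abs(frac - 0.15) < 0.01

    def test_conditional_action_fractions(self):
        batch = _feature_batch()
        plan, corrupted = tr.make_masking_plan(batch, seed=2)
        sel = plan.selected
        mask_frac = (corrupted[sel] == co.MASK_ID).mean()
        perm_frac = (plan.action[sel] == tr.ACTION_PERMUTE).mean()
        keep_frac = (plan.action[sel] == tr.ACTION_KEEP).mean()
        assert abs(mask_frac - 0.80) < 0.02
        assert abs(perm_frac - 0.10) < 0.02
        assert abs(keep_frac - 0.10) < 0.02

    def test_zero_probability_is_identity(self):
        batch = _feature_batch(n_positions=1000)
        plan, corrupted = tr.make_masking_plan(batch, p_select=0.0, seed=3)
        assert not plan.selected.any()
        assert np.array_equal(corrupted, batch["code_ids"])
        assert (plan.targets == -100).all()

    def test_specials_demographics_padding_never_selected(self):
        rng = np.random.default_rng(4)
        B, L = 50, 40
        codes = rng.integers(0, 30, (B, L))
        types = rng.integers(0, 6, (B, L))
        mask = rng.integers(0, 2, (B, L))
        batch = {"code_ids": codes, "type_ids": types, "attention_mask": mask}
        plan, _ = tr.make_masking_plan(batch, p_select=0.9, seed=5)
        sel = plan.selected
        assert not sel[codes < co.N_SPECIAL].any()
        assert not sel[types == co.TYPE_DEMO].any()
        assert not sel[types == co.TYPE_SPECIAL].any()
        assert not sel[mask == 0].any()

    def test_seed_determinism(self):
        batch = _feature_batch(n_positions=5000)
        a = tr.make_masking_plan(batch, seed=6)
        b = tr.make_masking_plan(batch, seed=6)
        assert np.array_equal(a[1], b[1])
        assert np.array_equal(a[0].selected, b[0].selected)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            tr.make_masking_plan(_feature_batch(1000), p_select=1.5)


class TestNextVisitExample:
    def test_final_visit_masked_earlier_intact(self, toy_trajectory, small_cohort):
        _, vocab, cmap = small_cohort
        cmap2 = CategoryMap(
            code_to_category={"A00": "cat_a", "C20": "cat_c", "B10": "cat_b",
                              "B11": "cat_b", "I50": "cat_i", "Z99": "outcome"},
            groups={"outcome": frozenset({"Z99"})},
        )
        vocab2 = co.build_vocabulary([toy_trajectory])
        tok, label = tr.make_next_visit_example(toy_trajectory, vocab2, cmap2, max_len=64)
        last = tok.visit_index == 2
        earlier = (tok.visit_index >= 0) & ~last
        assert (tok.code_ids[last] == co.MASK_ID).all()
        assert (tok.code_ids[earlier] != co.MASK_ID).all()
        # label is the category of the final visit's principal diagnosis
        cats = sorted(cmap2.categories)
        assert cats[label] == "cat_a"
        # demographics untouched
        assert (tok.code_ids[tok.type_ids == co.TYPE_DEMO] != co.MASK_ID).all()

    def test_time_buckets_relative_to_final_visit(self, toy_trajectory):
        vocab = co.build_vocabulary([toy_trajectory])
        cmap = CategoryMap(
            code_to_category={c: "x" for c in ["A00", "C20", "B10", "B11", "I50"]},
            groups={"outcome": frozenset()},
        )
        tok, _ = tr.make_next_visit_example(toy_trajectory, vocab, cmap, max_len=64)
        assert (tok.time_bucket_ids[tok.visit_index == 2] == 0).all()

    def test_single_visit_rejected(self, toy_trajectory):
        t = toy_trajectory
        t1 = co.Trajectory(
            patient_id=t.patient_id, visits=t.visits[:1], index_date=t.visits[0].date,
            label=0, prior_outcome=False, lag_days=None, demographics=t.demographics,
        )
        vocab = co.build_vocabulary([t])
        with pytest.raises(ValueError):
            tr.make_next_visit_example(t1, vocab, CategoryMap({}, {"outcome": frozenset()}))


class TestMultitaskLoss:
    def test_perfect_predictions_drive_loss_to_zero(self):
        big = 50.0
        mlm = np.full((4, 6), -big); mlm[np.arange(4), [1, 2, 3, 4]] = big
        cat = np.full((2, 3), -big); cat[[0, 1], [0, 2]] = big
        total, a, b = tr.multitask_loss(mlm, np.array([1, 2, 3, 4]), cat, np.array([0, 2]))
        assert total < 1e-12

    def test_uniform_scores_give_log_k(self):
        mlm = np.zeros((10, 7))
        cat = np.zeros((3, 4))
        total, a, b = tr.multitask_loss(mlm, np.zeros(10, dtype=int), cat, np.zeros(3, dtype=int))
        assert np.isclose(a, np.log(7)) and np.isclose(b, np.log(4))
        assert np.isclose(total, np.log(7) + np.log(4))

    def test_empty_mlm_term_is_zero(self):
        cat = np.zeros((2, 3))
        total, a, b = tr.multitask_loss(None, None, cat, np.array([0, 1]))
        assert a == 0.0 and np.isclose(total, b)


class TestSchedule:
    def test_warmup_then_linear_decay(self):
        lrs = [tr.lr_at_step(s, 100, 1.0, 0.1) for s in range(100)]
        assert lrs[0] < lrs[5] < lrs[9]
        assert np.isclose(max(lrs), 1.0)
        assert all(a >= b for a, b in zip(lrs[10:], lrs[11:]))
        assert lrs[-1] < 0.02


class TestWeightedSampler:
    def test_probabilities_sum_to_one_and_uniform_weight(self):
        y = np.array([0, 0, 1, 0])
        p = tr.weighted_sampler(y, 1.0)
        np.testing.assert_allclose(p, 0.25)
        assert np.isclose(tr.weighted_sampler(y, 10.0).sum(), 1.0)

    def test_balanced_sampling_yields_half_positive_batches(self):
        rng = np.random.default_rng(0)
        n = 10_000
        y = (rng.random(n) < 0.01).astype(int)
        w = (n - y.sum()) / y.sum()
        p = tr.weighted_sampler(y, w)
        draws = rng.choice(n, size=10_000, p=p)
        assert abs(y[draws].mean() - 0.5) < 0.05

    def test_single_class_degenerates_to_uniform_with_warning(self):
        with pytest.warns(UserWarning):
            p = tr.weighted_sampler(np.zeros(5, dtype=int), 3.0)
        np.testing.assert_allclose(p, 0.2)


def _toy_corpus(n, seed, n_cats=4, deterministic_next=True):
    """Hand-built trajectories whose next-visit category follows a fixed cycle."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    codes_by_cat = {k: [f"{chr(65 + k)}{i:02d}" for i in range(3)] for k in range(n_cats)}
    cmap = CategoryMap(
        code_to_category={
            c: f"cat{k}" for k, cs in codes_by_cat.items() for c in cs
        },
        groups={"outcome": frozenset()},
    )
    # gaps chosen so that, relative to the newest visit, every visit falls in
    # a distinct temporal bucket
    back_offsets = [500, 300, 150, 60, 20, 0]
    trajs = []
    for i in range(n):
        v = int(rng.integers(3, 6))
        cat = int(rng.integers(n_cats))
        visits = []
        day0 = pd.Timestamp("2018-01-01")
        for j, back in enumerate(back_offsets[-v:]):
            code = codes_by_cat[cat][int(rng.integers(3))]
            visits.append(
                co.Visit(
                    date=day0 + pd.Timedelta(days=500 - back),
                    principal_dx=code,
                    aux_dx=[codes_by_cat[cat][int(rng.integers(3))]],
                    ecause=[], procedures=[],
                )
            )
            cat = (cat + 1) % n_cats if deterministic_next else int(rng.integers(n_cats))
        trajs.append(
            co.Trajectory(
                patient_id=f"T{i}", visits=visits, index_date=visits[-1].date,
                label=int(rng.random() < 0.3), prior_outcome=False, lag_days=None,
                demographics={"age_decade": "3", "sex": "F"},
            )
        )
    return trajs, cmap


class TestPretraining:
    def test_loss_decreases_and_planted_rule_learned(self):
        trajs, cmap = _toy_corpus(200, seed=0)
        vocab = co.build_vocabulary(trajs)
        examples = [tr.make_next_visit_example(t, vocab, cmap, max_len=24) for t in trajs]
        cfg = mc.ModelConfig(
            vocab_size=len(vocab), d_model=24, n_layers=1, n_heads=2, d_ff=48,
            max_len=24, n_next_categories=len(cmap.categories), seed=1,
        )
        params = mc.init_params(cfg)
        tcfg = tr.TrainConfig(lr=5e-3, n_steps=400, batch_size=32, seed=2)
        params, hist = tr.pretrain(examples, params, cfg, tcfg, val_examples=examples[:50])
        assert np.mean([h["loss"] for h in hist[-10:]]) < hist[0]["loss"]
        # deterministic next-category cycle: accuracy must beat the majority rate
        acc = tr.next_category_accuracy(params, cfg, examples[:100])
        labels = np.array([lab for _, lab in examples[:100]])
        majority = np.bincount(labels).max() / len(labels)
        assert acc > majority

    def test_same_seed_identical_final_loss(self):
        trajs, cmap = _toy_corpus(40, seed=3)
        vocab = co.build_vocabulary(trajs)
        examples = [tr.make_next_visit_example(t, vocab, cmap, max_len=24) for t in trajs]
        cfg = mc.ModelConfig(
            vocab_size=len(vocab), d_model=8, n_layers=1, n_heads=2, d_ff=16,
            max_len=24, n_next_categories=len(cmap.categories), seed=4,
        )
        runs = []
        for _ in range(2):
            params = mc.init_params(cfg)
            _, hist = tr.pretrain(
                examples, params, cfg, tr.TrainConfig(n_steps=30, batch_size=8, seed=5)
            )
            runs.append(hist[-1]["loss"])
        assert runs[0] == runs[1]

    def test_empty_corpus_rejected(self):
        cfg = mc.ModelConfig(vocab_size=10, d_model=8, n_layers=1, n_heads=2, d_ff=16)
        with pytest.raises(ValueError):
            tr.pretrain([], mc.init_params(cfg), cfg, tr.TrainConfig())


class TestMlmMemorization:
    def test_overfit_small_corpus_recovers_masked_codes(self):
        """Recover >=90% of masked codes on a 20-trajectory corpus whose
        within-visit codes are duplicated, so every masked code is inferable
        from its surviving copies."""
        trajs, cmap = _toy_corpus(20, seed=6)
        for t in trajs:
            for v in t.visits:
                v.aux_dx = [v.principal_dx, v.principal_dx]
        vocab = co.build_vocabulary(trajs)
        examples = [tr.make_next_visit_example(t, vocab, cmap, max_len=24) for t in trajs]
        cfg = mc.ModelConfig(
            vocab_size=len(vocab), d_model=24, n_layers=1, n_heads=2, d_ff=48,
            max_len=24, n_next_categories=len(cmap.categories), seed=7,
        )
        params = mc.init_params(cfg)
        tcfg = tr.TrainConfig(lr=5e-3, n_steps=600, batch_size=20, seed=8)
        params, _ = tr.pretrain(examples, params, cfg, tcfg)
        # evaluate argmax recovery on freshly masked positions
        batch = co.stack_tokenized([t for t, _ in examples])
        plan, corrupted = tr.make_masking_plan(batch, seed=9, vocab_size=cfg.vocab_size)
        x0 = mc.embed_features(params, corrupted, batch["type_ids"], batch["time_bucket_ids"])
        hidden, _, _ = mc.encoder_forward(params, cfg, x0, batch["attention_mask"])
        logits = mc.head_mlm(hidden[plan.selected], params)
        acc = (logits.argmax(-1) == plan.targets[plan.selected]).mean()
        assert acc >= 0.9


class TestFinetune:
    def _toks(self, trajs, vocab):
        return [co.tokenize(t, vocab, max_len=24) for t in trajs]

    def test_overfit_training_auroc_approaches_one(self):
        from ehrseq.evaluate import auroc

        trajs, cmap = _toy_corpus(50, seed=10)
        # plant a perfectly informative code for positives
        for t in trajs:
            if t.label:
                t.visits[-1].aux_dx.append("Z55")
        vocab = co.build_vocabulary(trajs)
        toks = self._toks(trajs, vocab)
        cfg = mc.ModelConfig(
            vocab_size=len(vocab), d_model=16, n_layers=1, n_heads=2, d_ff=32,
            max_len=24, n_next_categories=2, seed=11,
        )
        params = mc.init_params(cfg)
        tcfg = tr.TrainConfig(lr=5e-3, n_steps=150, batch_size=16, seed=12)
        params, _ = tr.finetune(toks, params, cfg, tcfg)
        scores = tr.predict_binary(params, cfg, toks)
        assert auroc(scores, np.array([t.label for t in toks])) > 0.95

    def test_no_positive_examples_rejected(self):
        trajs, _ = _toy_corpus(10, seed=13)
        for t in trajs:
            t.label = 0
        vocab = co.build_vocabulary(trajs)
        cfg = mc.ModelConfig(vocab_size=len(vocab), d_model=8, n_layers=1, n_heads=2,
                             d_ff=16, max_len=24, n_next_categories=2)
        with pytest.raises(ValueError):
            tr.finetune(self._toks(trajs, vocab), mc.init_params(cfg), cfg, tr.TrainConfig())

    def test_scratch_and_pretrained_share_code_path(self):
        """The ablation differs only in starting parameters."""
        trajs, cmap = _toy_corpus(30, seed=14)
        vocab = co.build_vocabulary(trajs)
        toks = self._toks(trajs, vocab)
        cfg = mc.ModelConfig(vocab_size=len(vocab), d_model=8, n_layers=1, n_heads=2,
                             d_ff=16, max_len=24, n_next_categories=2, seed=15)
        tcfg = tr.TrainConfig(n_steps=10, batch_size=8, seed=16)
        a, _ = tr.finetune(toks, mc.init_params(cfg), cfg, tcfg)
        b, _ = tr.finetune(toks, mc.init_params(cfg), cfg, tcfg)
        for k in a:
            assert np.array_equal(a[k], b[k])


class TestRandomSearch:
    def test_budget_one_returns_single_trial(self):
        best, trials = tr.random_search({"lr": [0.1, 0.2]}, 1, seed=0, eval_fn=lambda c: c["lr"])
        assert len(trials) == 1 and best == trials[0]["config"]

    def test_best_dominates_log_and_seed_reproducible(self):
        space = {"lr": [0.1, 0.2, 0.3], "bs": [8, 16]}
        fn = lambda c: c["lr"] * c["bs"]
        best, trials = tr.random_search(space, 8, seed=1, eval_fn=fn)
        assert max(t["score"] for t in trials) == fn(best)
        best2, trials2 = tr.random_search(space, 8, seed=1, eval_fn=fn)
        assert [t["config"] for t in trials] == [t["config"] for t in trials2]

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError):
            tr.random_search({"lr": [0.1]}, 0, 0, lambda c: 0.0)
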