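"""End-to-end pipeline: simulation -> classification images -> classification.

Also provides the fixed-contrast cohort simulator used when only the analysis
chain is of interest (no staircase dynamics): each simulated participant is a
smoothly jittered variant of the base observer, run at each condition's
calibrated contrast.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import ci as ci_mod
from .classify import condition_signature, discrimination_ranking, featureize, stepwise_svm_loo
from .experiment import build_trial_schedule, run_simulated_experiment, summarize_log
from .io import RunConfig, SCHEMA_VERSION, stage_seed, write_trial_log
from .observer import jitter_observer, make_paperlike_observer, observer_p_correct_batch
from .stimuli import generate_snr_batch

__all__ = ["run_pipeline", "simulate_cohort", "cohort_zcis", "demo_words"]

log = logging.getLogger("temposample")


def demo_words(n: int, seed: int = 0) -> list[str]:
    """Deterministic bank of n distinct pronounceable 5-letter pseudo-words."""
    rng = np.random.default_rng(seed)
    cons, vow = "bcdfglmnprst", "aeiou"
    words: set[str] = set()
    while len(words) < n:
        w = "".join(
            rng.choice(list(cons if i % 2 == 0 else vow)) for i in range(5)
        )
        words.add(w)
    return sorted(words)


def simulate_cohort(
    n_participants: int,
    trials_per_condition: int,
    seed: int = 0,
    observer=None,
    jitter: float = 0.1,
    contrasts: dict | None = None,
):
    """Fixed-contrast cohort: per participant x condition trial arrays.

    Returns ``(data, observer)`` where ``data[(participant, condition)]`` is
    a ``(snr_matrix, correct)`` pair. Each participant is a jittered variant
    of the base observer; trials run at the observer's calibrated
    per-condition contrast (overridable via ``contrasts``).
    """
    base = observer if observer is not None else make_paperlike_observer(
        seed=stage_seed(seed, "observer")
    )
    data = {}
    for p in range(n_participants):
        obs = jitter_observer(base, seed=stage_seed(seed, "observer", p + 1), amount=jitter) \
            if jitter > 0 else base
        for c in sorted(base.time_kernel):
            s = stage_seed(seed, "experiment", p * 16 + c)
            S = generate_snr_batch(s, trials_per_condition)
            contrast = (contrasts or {}).get(c) or base.peak_table[c]["target_contrast_pct"]
            pvec = observer_p_correct_batch(obs, c, S, contrast)
            rng = np.random.default_rng(stage_seed(seed, "experiment", 10_000 + p * 16 + c))
            correct = rng.random(trials_per_condition) < pvec
            data[(p, c)] = (S, correct)
    return data, base


def cohort_zcis(data, domain: str = "time_frequency", n_boot: int = 500,
                seed: int = 0, smooth: bool = True) -> list:
    """Per-individual smoothed Z-scored CIs for every (participant, condition)."""
    compute = ci_mod.compute_time_ci if domain == "time" else ci_mod.compute_tf_ci
    out = []
    for i, ((p, c), (S, correct)) in enumerate(sorted(data.items())):
        raw = compute(S, correct, participant_id=p, condition=c)
        z = ci_mod.bootstrap_z(raw, S, correct, n_boot=n_boot,
                               seed=stage_seed(seed, "ci", i))
        out.append(ci_mod.smooth_ci(z) if smooth else z)
    return out


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run simulation, CI analysis and classification; write a run directory.

    Layout: ``trials.csv`` (all participants), ``summary.csv`` (per-condition
    accuracy and contrast, per participant and pooled), ``ci/`` (group CI
    arrays and Pixel-test masks per condition and domain, as ``.npz`` plus a
    flat CSV export), ``classifier.json`` and ``signature.json``, and
    ``run.json`` with the config, stage seeds and timings. Deterministic for
    a given config.
    """
    out = Path(out_dir)
    (out / "ci").mkdir(parents=True, exist_ok=True)
    timings, t0 = {}, time.time()

    words = demo_words(config.n_words, seed=stage_seed(config.seed, "schedule"))
    observer = make_paperlike_observer(seed=stage_seed(config.seed, "observer"))
    logs = []
    for p in range(config.n_participants):
        schedule = build_trial_schedule(
            words, config.n_sessions, config.blocks_per_session,
            config.trials_per_block, seed=stage_seed(config.seed, "schedule", p),
        )
        obs_p = jitter_observer(observer, seed=stage_seed(config.seed, "observer", p + 1))
        logs.append(run_simulated_experiment(
            schedule, obs_p, seed=stage_seed(config.seed, "experiment", p),
            participant_id=p,
        ))
        log.info("participant %d simulated (%d trials)", p, len(logs[-1]))
    trials = pd.concat(logs, ignore_index=True)
    write_trial_log(trials, out / "trials.csv")
    summary = (
        trials.groupby(["participant_id", "condition"])
        .agg(accuracy_pct=("correct", lambda s: 100.0 * s.mean()),
             mean_contrast_pct=("contrast", "mean"), n_trials=("correct", "size"))
        .reset_index()
    )
    pooled = summarize_log(trials).assign(participant_id="pooled")
    summary = pd.concat([summary, pooled[summary.columns]], ignore_index=True)
    summary.to_csv(out / "summary.csv", index=False)
    timings["simulate_s"] = round(time.time() - t0, 2)

    # Group CIs + Pixel tests, per condition and domain
    t1 = time.time()
    masks = {}
    for domain, tag in (("time", "time"), ("time_frequency", "tf")):
        for c in sorted(trials["condition"].unique()):
            per_part = []
            for p in range(config.n_participants):
                sl = trials[(trials.participant_id == p) & (trials.condition == c)]
                per_part.append((np.vstack(sl["snr_values"].to_numpy()),
                                 sl["correct"].to_numpy()))
            group, ptest = ci_mod.group_pixel_analysis(
                per_part, domain=domain, n_boot=config.n_boot, n_perm=config.n_perm,
                alpha=config.alpha, seed=stage_seed(config.seed, "ci", 100 + c),
                condition=int(c),
            )
            np.savez(out / "ci" / f"group_{tag}_c{c}.npz",
                     z=group.values, mask=ptest.significance_mask,
                     z_threshold=ptest.z_threshold_high)
            flat = pd.DataFrame({
                "cell": np.arange(group.values.size),
                "z": group.values.reshape(-1),
                "significant": ptest.significance_mask.reshape(-1).astype(int),
            })
            flat.to_csv(out / "ci" / f"group_{tag}_c{c}.csv", index=False)
            masks[f"{tag}_c{c}"] = {
                "z_threshold": ptest.z_threshold_high,
                "n_significant": int(ptest.significance_mask.sum()),
            }
    timings["ci_s"] = round(time.time() - t1, 2)

    # Individual CIs -> classifier
    t2 = time.time()
    data = {}
    for p in range(config.n_participants):
        for c in sorted(trials["condition"].unique()):
            sl = trials[(trials.participant_id == p) & (trials.condition == int(c))]
            data[(p, int(c))] = (np.vstack(sl["snr_values"].to_numpy()),
                                 sl["correct"].to_numpy())
    domain = "time" if config.representation in ("time", "time_fourier") else "time_frequency"
    zcis = cohort_zcis(data, domain=domain, n_boot=config.n_boot,
                       seed=stage_seed(config.seed, "ci"))
    fm = featureize(zcis, config.representation)
    try:
        ranking, _ = discrimination_ranking(fm)
        result = stepwise_svm_loo(fm, ranking, stop_accuracy=config.stop_accuracy)
        sig = condition_signature(fm, result.selected_features[: result.best_n_features])
    except ValueError as err:
        # e.g. a single-participant run: one CI per condition cannot be
        # cross-validated; the rest of the pipeline output stands.
        with open(out / "classifier.json", "w") as fh:
            json.dump({"schema_version": SCHEMA_VERSION, "error": str(err)}, fh, indent=1)
        log.warning("classifier stage refused: %s", err)
    else:
        with open(out / "classifier.json", "w") as fh:
            json.dump({
                "schema_version": SCHEMA_VERSION,
                "representation": config.representation,
                "n_features_available": int(fm.X.shape[1]),
                "accuracy_by_step_pct": result.accuracy_by_step.tolist(),
                "selected_features": result.selected_features.tolist(),
                "best_accuracy_pct": result.best_accuracy,
                "best_n_features": result.best_n_features,
                "p_value_vs_chance": result.p_value,
            }, fh, indent=1)
        with open(out / "signature.json", "w") as fh:
            json.dump({
                "schema_version": SCHEMA_VERSION,
                "conditions": sig.conditions.tolist(),
                "features": sig.features.tolist(),
                "values": sig.values.tolist(),
                "display_contrast": sig.display_contrast.tolist(),
                "omitted": sig.omitted.tolist(),
            }, fh, indent=1)
    timings["classify_s"] = round(time.time() - t2, 2)

    config.to_json(out / "config.json")
    with open(out / "run.json", "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION, "timings": timings,
                   "pixel_tests": masks, "seed": config.seed}, fh, indent=1)
    return out
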