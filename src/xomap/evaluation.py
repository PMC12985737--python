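"""Parameter-recovery studies run against the synthetic generators.

Each study regenerates data under the declared study conditions, pushes it
through the pipeline stages and measures how well the known truth is
recovered. They are the package's verification surface: tests assert on
their outputs and the reproduction script reports them.
"""

from __future__ import annotations

import numpy as np

from . import landscape as ls
from . import synthetic
from .seed_rf import SeedCount, estimate_rf
from .xo_mapper import CallStatus, SnpMap, map_population

__all__ = [
    "rf_recovery_study",
    "breakpoint_recovery_study",
    "landscape_conservation_check",
    "reduction_recovery_study",
    "default_study_map",
]


def default_study_map() -> SnpMap:
    """The default synthetic study interval: 101 markers over 40 kb."""
    return synthetic.make_snp_map(40_000, 101, rng_seed=0)


def rf_recovery_study(
    seed: int,
    r_true: float = 0.0033,
    n_total: int = 100_000,
    n_datasets: int = 1000,
    n_boot: int = 2000,
    level: float = 0.95,
) -> dict:
    """Repeatedly simulate seed counts and measure estimator recovery.

    Returns the mean recovered cM with its standard error and the
    fraction of percentile-bootstrap CIs covering the true value.
    """
    rng = np.random.default_rng(seed)
    probs = synthetic.expected_seed_class_probs(r_true)
    p = np.array([probs.p_green_only, probs.p_red_only, probs.p_other])
    true_cm = 100.0 * r_true
    cms = np.empty(n_datasets)
    covered = 0
    alpha = 1.0 - level
    for i in range(n_datasets):
        ng, nr, _ = rng.multinomial(n_total, p)
        cms[i] = estimate_rf(SeedCount(f"d{i}", int(ng), int(nr), n_total)).cm
        # percentile bootstrap from the observed class fractions
        p_obs = np.array([ng / n_total, nr / n_total, 1.0 - (ng + nr) / n_total])
        draws = rng.multinomial(n_total, p_obs, size=n_boot)
        q = 2.0 * (draws[:, 0] + draws[:, 1]) / n_total
        boot = 100.0 * (1.0 - np.sqrt(np.clip(1.0 - q, 0.0, None)))
        lo, hi = np.quantile(boot, [alpha / 2.0, 1.0 - alpha / 2.0])
        covered += lo <= true_cm <= hi
    return dict(
        mean_cm=float(cms.mean()),
        se_cm=float(cms.std(ddof=1) / np.sqrt(n_datasets)),
        true_cm=true_cm,
        coverage=covered / n_datasets,
        n_datasets=n_datasets,
    )


def breakpoint_recovery_study(
    seed: int,
    n_recombinants: int = 500,
    mean_depth: float = 1500.0,
    error_rate: float = 0.002,
    snps: SnpMap | None = None,
) -> dict:
    """Simulate recombinants under the hotspot mixture and map them back.

    Reports the fraction of recombinants with an OK call and the
    fraction of OK intervals containing the true breakpoint.
    """
    snps = snps or default_study_map()
    model = synthetic.chp_like_model(snps)
    truth = synthetic.simulate_recombinants(n_recombinants, model, rng_seed=seed)
    tables = synthetic.simulate_allele_depths(
        truth, snps, mean_depth=mean_depth, error_rate=error_rate, rng_seed=seed + 1
    )
    calls, tally = map_population(tables, snps)
    by_id = {t.recombinant_id: t for t in truth.recombinants}
    n_ok = tally[CallStatus.OK]
    contained = sum(
        1
        for c in calls
        if c.status is CallStatus.OK
        and c.left_pos <= by_id[c.recombinant_id].breakpoints[0] < c.right_pos
    )
    return dict(
        ok_rate=n_ok / n_recombinants,
        containment_rate=contained / n_ok if n_ok else float("nan"),
        n_ok=int(n_ok),
        n_recombinants=n_recombinants,
        tally={k.value: int(v) for k, v in tally.items()},
    )


def landscape_conservation_check(
    seed: int,
    n_recombinants: int = 300,
    interval_cm: float = 0.33,
    window: int = 1000,
    step: int = 100,
) -> dict:
    """Check the bookkeeping identities of the landscape stage.

    The sliding-window cM/Mb track must integrate back to the supplied
    interval cM, normalized distributions must sum to one, and a
    differential track must sum to zero.
    """
    snps = default_study_map()
    model = synthetic.chp_like_model(snps)
    truth = synthetic.simulate_recombinants(n_recombinants, model, rng_seed=seed)
    tables = synthetic.simulate_allele_depths(
        truth, snps, mean_depth=1500, error_rate=0.002, rng_seed=seed + 1
    )
    calls, _ = map_population(tables, snps)
    ok = [c for c in calls if c.status is CallStatus.OK]

    track = ls.moving_average_cm_per_mb(
        ok, interval_cm, (snps.start, snps.end), window=window, step=step
    )
    integral = ls.track_integral_cm(track)
    dist = ls.build_distribution(ok, snps.positions)

    truth_b = synthetic.simulate_recombinants(n_recombinants, model, rng_seed=seed + 2)
    tables_b = synthetic.simulate_allele_depths(
        truth_b, snps, mean_depth=1500, error_rate=0.002, rng_seed=seed + 3
    )
    calls_b, _ = map_population(tables_b, snps)
    dist_b = ls.build_distribution(
        [c for c in calls_b if c.status is CallStatus.OK], snps.positions
    )
    diff = ls.differential_track(dist, dist_b)
    return dict(
        integral_cm=float(integral),
        interval_cm=interval_cm,
        integral_rel_err=abs(integral - interval_cm) / interval_cm,
        distribution_sum=float(dist.values.sum()),
        difference_sum=float(diff.values.sum()),
        n_ok=len(ok),
    )


def reduction_recovery_study(
    seed: int,
    reduction_pct: float = 47.2,
    n_control: int = 243,
    n_sample: int = 164,
    n_replicates: int = 200,
    mean_depth: float = 1500.0,
    error_rate: float = 0.002,
) -> dict:
    """Paired-population recovery of a built-in hotspot suppression.

    For each replicate a control population and a population with a known
    share-space suppression of the central hotspot are simulated, mapped
    through the full genotyping/calling path, and their crossover
    midpoints pooled. The reduction statistic is computed from the pooled
    hotspot shares; the binomial SE is propagated from the pooled counts.
    """
    snps = default_study_map()
    model = synthetic.chp_like_model(snps)
    suppressed = synthetic.suppress_hotspot(model, "Coco", reduction_pct)
    coco = next(c for c in model.components if c.name == "Coco")
    in_ctrl = n_ctrl = in_samp = n_samp = 0
    for i in range(n_replicates):
        for mdl, n, is_sample in ((model, n_control, False), (suppressed, n_sample, True)):
            truth = synthetic.simulate_recombinants(
                n, mdl, rng_seed=seed + 17 * i + (7 if is_sample else 0)
            )
            tables = synthetic.simulate_allele_depths(
                truth,
                snps,
                mean_depth=mean_depth,
                error_rate=error_rate,
                rng_seed=seed + 1_000_000 + 17 * i + (7 if is_sample else 0),
            )
            calls, _ = map_population(tables, snps)
            mids = ls.ok_midpoints(calls)
            k = int(((mids >= coco.start) & (mids < coco.end)).sum())
            if is_sample:
                in_samp += k
                n_samp += mids.size
            else:
                in_ctrl += k
                n_ctrl += mids.size
    p_s, p_c = in_samp / n_samp, in_ctrl / n_ctrl
    recovered = 100.0 * (1.0 - p_s / p_c)
    se = (
        100.0
        * (p_s / p_c)
        * np.sqrt((1 - p_s) / (p_s * n_samp) + (1 - p_c) / (p_c * n_ctrl))
    )
    return dict(
        recovered_pct=float(recovered),
        true_pct=reduction_pct,
        se_pct=float(se),
        n_replicates=n_replicates,
        n_ok_sample=int(n_samp),
        n_ok_control=int(n_ctrl),
    )
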