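"""Genetic map distance from fluorescent seed segregation.

A fluorescence-tagged interval carries seed-expressed eGFP and dsRed
reporters at its two ends, in *cis* on one homolog of an F1 hybrid
(reporter haplotype ``RG``, reporter-free haplotype ``--``). A meiotic
crossover inside the interval produces the single-reporter gametes ``R-``
and ``-G``; with recombinant-gamete fraction ``r`` the four gamete classes
have frequencies::

    RG : (1 - r) / 2      R- : r / 2
    -- : (1 - r) / 2      -G : r / 2

An F2 seed unites two independent gametes and displays the union of their
reporters, so the two single-colour seed classes (green-only, red-only)
each occur with probability ``(1 - (1 - r)^2) / 4``. Inverting that
relation with observed counts of green-only (NG), red-only (NR) and total
(NT) seeds yields the map distance in centimorgans:

    cM = 100 * (1 - sqrt(1 - 2 (NG + NR) / NT))

which is exactly 100 * r when applied to the expected class frequencies,
and approaches the naive 100 * (NG + NR) / NT for small r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SeedCount",
    "SeedClassProbs",
    "RfEstimate",
    "estimate_rf",
    "expected_seed_class_probs",
    "rf_bootstrap_ci",
    "compare_rf",
    "read_seed_counts",
    "write_rf_table",
    "rf_table",
]


@dataclass(frozen=True)
class SeedCount:
    """Seed tallies for one cross: green-only, red-only and total seeds.

    Both-colour and non-fluorescent seeds are never split apart; only the
    two single-colour classes and the total enter the estimator.
    """

    cross_id: str
    n_green: int
    n_red: int
    n_total: int

    def __post_init__(self) -> None:
        if self.n_green < 0 or self.n_red < 0:
            raise ValueError("seed counts must be non-negative")
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if self.n_green + self.n_red > self.n_total:
            raise ValueError("single-colour seeds exceed total seeds")

    @property
    def n_recombinant(self) -> int:
        return self.n_green + self.n_red


@dataclass(frozen=True)
class SeedClassProbs:
    """Probabilities of the three observable F2 seed classes."""

    p_green_only: float
    p_red_only: float
    p_other: float

    def __post_init__(self) -> None:
        for p in (self.p_green_only, self.p_red_only, self.p_other):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.p_green_only + self.p_red_only + self.p_other - 1.0) > 1e-12:
            raise ValueError("class probabilities must sum to 1")


@dataclass(frozen=True)
class RfEstimate:
    """Map distance in centimorgans with optional bootstrap CI."""

    cm: float
    n_total: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.cm <= 100.0:
            raise ValueError("cm must lie in [0, 100]")
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValueError("both or neither CI bound must be given")
        if self.ci_low is not None and not self.ci_low <= self.cm <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def _cm_from_fraction(q: float) -> float:
    # q = 2 (NG + NR) / NT; the radicand 1 - q is (1 - r)^2 under the model
    if q > 1.0:
        raise ValueError(
            f"2*(NG+NR)/NT = {q:.4f} > 1: counts are impossible under the "
            "single-crossover gamete model"
        )
    return 100.0 * (1.0 - math.sqrt(1.0 - q))


def estimate_rf(counts: SeedCount) -> RfEstimate:
    """Point estimate of map distance (cM) from one cross's seed counts.

    Raises
    ------
    ValueError
        If ``2 * (NG + NR) / NT > 1``, i.e. more than half the seeds are
        single-colour, which no recombinant fraction can produce.
    """
    q = 2.0 * counts.n_recombinant / counts.n_total
    return RfEstimate(cm=_cm_from_fraction(q), n_total=counts.n_total)


def expected_seed_class_probs(r: float) -> SeedClassProbs:
    """Seed-class probabilities for recombinant-gamete fraction ``r``.

    ``p_green_only = p_red_only = (1 - (1 - r)^2) / 4``; the symmetric
    single-colour probabilities reflect the reciprocal ``R-``/``-G``
    gametes of the reporter scheme.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("recombinant fraction r must lie in [0, 1]")
    p_single = (1.0 - (1.0 - r) ** 2) / 4.0
    return SeedClassProbs(
        p_green_only=p_single,
        p_red_only=p_single,
        p_other=1.0 - 2.0 * p_single,
    )


def rf_bootstrap_ci(
    counts: SeedCount,
    n_boot: int = 2000,
    level: float = 0.95,
    rng_seed: int | None = None,
) -> RfEstimate:
    """Percentile bootstrap CI for the map distance of one cross.

    Resamples ``(NG, NR, other)`` multinomially at fixed ``NT`` from the
    observed class fractions. Resamples whose single-colour fraction
    exceeds the model's domain are clamped to the 100 cM boundary so the
    procedure never fails. Deterministic for a fixed ``rng_seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    nt = counts.n_total
    p_obs = np.array(
        [
            counts.n_green / nt,
            counts.n_red / nt,
            1.0 - counts.n_recombinant / nt,
        ]
    )
    draws = rng.multinomial(nt, p_obs, size=n_boot)
    q = 2.0 * (draws[:, 0] + draws[:, 1]) / nt
    cms = 100.0 * (1.0 - np.sqrt(np.clip(1.0 - q, 0.0, None)))
    alpha = 1.0 - level
    lo, hi = np.quantile(cms, [alpha / 2.0, 1.0 - alpha / 2.0])
    point = estimate_rf(counts).cm
    return RfEstimate(
        cm=point,
        n_total=nt,
        ci_low=float(min(lo, point)),
        ci_high=float(max(hi, point)),
    )


def compare_rf(
    group_a,
    group_b,
    method: str = "welch",
) -> tuple[float, float]:
    """Two-sided comparison of per-cross cM values between two groups.

    ``method`` is one of ``welch`` (unequal-variance t test), ``ttest``
    (pooled-variance t test) or ``mannwhitney`` (Mann-Whitney U with
    tie-corrected asymptotics; two fully identical groups give p = 1).

    Returns ``(statistic, p_value)``.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method in ("welch", "ttest"):
        if a.size < 2 or b.size < 2:
            raise ValueError(f"{method} requires at least 2 values per group")
        res = stats.ttest_ind(a, b, equal_var=(method == "ttest"))
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Tabular I/O: cross_id / n_green / n_red / n_total delimited tables


def read_seed_counts(path) -> list[SeedCount]:
    """Read a seed-count table (TSV or CSV, sniffed from the extension)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    required = {"cross_id", "n_green", "n_red", "n_total"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"seed-count table missing columns: {sorted(missing)}")
    return [
        SeedCount(
            cross_id=str(row.cross_id),
            n_green=int(row.n_green),
            n_red=int(row.n_red),
            n_total=int(row.n_total),
        )
        for row in df.itertuples()
    ]


def rf_table(
    counts: list[SeedCount],
    n_boot: int = 2000,
    level: float = 0.95,
    rng_seed: int | None = None,
) -> pd.DataFrame:
    """Per-cross estimates plus unweighted-mean and pooled summary rows.

    The unweighted mean across crosses mirrors the per-cross points with a
    mean line as plotted in this kind of experiment; the pooled row
    re-estimates from summed counts, weighting crosses by seed number.
    """
    rows = []
    for c in counts:
        est = rf_bootstrap_ci(c, n_boot=n_boot, level=level, rng_seed=rng_seed)
        rows.append(
            dict(
                cross_id=c.cross_id,
                n_green=c.n_green,
                n_red=c.n_red,
                n_total=c.n_total,
                cm=est.cm,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
            )
        )
    df = pd.DataFrame(rows)
    if len(counts) > 1:
        pooled = SeedCount(
            cross_id="POOLED",
            n_green=sum(c.n_green for c in counts),
            n_red=sum(c.n_red for c in counts),
            n_total=sum(c.n_total for c in counts),
        )
        pooled_est = rf_bootstrap_ci(pooled, n_boot=n_boot, level=level, rng_seed=rng_seed)
        summary = pd.DataFrame(
            [
                dict(
                    cross_id="MEAN",
                    n_green=pooled.n_green,
                    n_red=pooled.n_red,
                    n_total=pooled.n_total,
                    cm=float(df["cm"].mean()),
                    ci_low=np.nan,
                    ci_high=np.nan,
                ),
                dict(
                    cross_id="POOLED",
                    n_green=pooled.n_green,
                    n_red=pooled.n_red,
                    n_total=pooled.n_total,
                    cm=pooled_est.cm,
                    ci_low=pooled_est.ci_low,
                    ci_high=pooled_est.ci_high,
                ),
            ]
        )
        df = pd.concat([df, summary], ignore_index=True)
    return df


def write_rf_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
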